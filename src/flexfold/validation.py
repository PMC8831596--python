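"""Ensemble validation and downstream structural analytics.

Q-factor reports with held-out restraints, hydrogen-bond-based secondary
structure assignment (Kabsch–Sander-style energies), disorder fractions,
pore-radius profiles along the channel axis, lateral-portal bottlenecks and
salt-bridge distances.

Residue-span conventions for the α7 nicotinic receptor system this package
was built around: the TMD+ICD construct spans L209–V472 (264 residues) and
the intracellular domain H296–C443 (148 residues), author numbering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _sp_minimize

from .nmr_restraints import DistanceRestraint
from .scoring import QReport, q_factor, restraint_distances
from .structio import (
    Ensemble,
    Structure,
    SymmetryFrame,
    estimate_symmetry_axis,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TMD_ICD_SPAN",
    "ICD_SPAN",
    "PoreProfile",
    "SSAssignmentResult",
    "holdout_split",
    "q_report",
    "place_amide_hydrogens",
    "assign_secondary_structure",
    "disorder_fraction",
    "pore_profile",
    "lateral_portal_radius",
    "salt_bridge_distances",
]

TMD_ICD_SPAN = (209, 472)  # L209–V472
ICD_SPAN = (296, 443)  # H296–C443

DISORDERED_LABELS = {"T", "C"}  # 3_10 (G) counted ordered


@dataclass
class PoreProfile:
    z: np.ndarray  # axis coordinate, Å, strictly increasing
    centers: np.ndarray  # (n, 3)
    radii: np.ndarray  # Å, >= 0

    def min_radius(self, z_window: tuple[float, float] | None = None) -> tuple[float, float]:
        """(z, radius) of the tightest constriction, optionally within a window."""
        mask = np.ones_like(self.z, dtype=bool)
        if z_window is not None:
            mask = (self.z >= z_window[0]) & (self.z <= z_window[1])
        i = int(np.argmin(np.where(mask, self.radii, np.inf)))
        return float(self.z[i]), float(self.radii[i])


@dataclass
class SSAssignmentResult:
    labels: dict[str, dict[int, str]]  # chain -> residue -> {H, G, T, C}
    method: str = "hbond-pattern"


# ---------------------------------------------------------------------------
# Holdout split and Q report
# ---------------------------------------------------------------------------

def holdout_split(
    restraints: list[DistanceRestraint],
    fraction: float,
    seed: int = 0,
) -> tuple[list[DistanceRestraint], list[DistanceRestraint]]:
    """Seeded uniform split into (working, free) sets.

    The free set has ``round(fraction * N)`` members drawn without
    replacement; the disjoint union of the two sets equals the input.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    n = len(restraints)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    free_idx = set(rng.choice(n, size=k, replace=False).tolist())
    working = [r for i, r in enumerate(restraints) if i not in free_idx]
    free = [r for i, r in enumerate(restraints) if i in free_idx]
    return working, free


def _q_pairs(ensemble: Ensemble, restraints: list[DistanceRestraint]) -> list[tuple[float, float]]:
    """(r_exp, r_calc) pairs; r_calc is the ensemble-mean distance.

    Two-sided restraints contribute (d0, r_calc). Bound-only restraints
    contribute only when violated, with r_exp set to the violated bound.
    """
    if not restraints:
        return []
    dmat = np.stack([restraint_distances(m, restraints) for m in ensemble.models])
    r_calc = dmat.mean(axis=0)
    pairs = []
    for r, rc in zip(restraints, r_calc):
        if r.has_target:
            pairs.append((r.d0, float(rc)))
        elif np.isfinite(r.upper) and rc > r.upper:
            pairs.append((r.upper, float(rc)))
        elif r.lower > 0 and rc < r.lower:
            pairs.append((r.lower, float(rc)))
    return pairs


def q_report(
    ensemble: Ensemble,
    restraints_by_class: dict[str, list[DistanceRestraint]],
    free_set: list[DistanceRestraint] | None = None,
) -> QReport:
    """Per-class Q-factors plus the free-set Q of held-out restraints.

    Classes are keyed "NOE", "PRE", "DEER"; empty classes are omitted with a
    log entry. A fully satisfied bound-only-dominated class with no violated
    member yields Q = 0 by convention.
    """
    report = QReport()
    for key, attr in (("NOE", "q_noe"), ("PRE", "q_pre"), ("DEER", "q_deer")):
        rs = restraints_by_class.get(key, [])
        if not rs:
            logger.info("q_report: class %s empty, omitted", key)
            continue
        pairs = _q_pairs(ensemble, rs)
        report.n_restraints[key] = len(rs)
        setattr(report, attr, q_factor(pairs) if pairs else 0.0)
    if free_set:
        pairs = _q_pairs(ensemble, free_set)
        report.q_pre_free = q_factor(pairs) if pairs else 0.0
        report.n_restraints["PRE_free"] = len(free_set)
    return report


# ---------------------------------------------------------------------------
# Secondary structure (hydrogen-bond pattern assignment)
# ---------------------------------------------------------------------------

_HB_Q = 0.084 * 332.0  # kcal/mol·Å, Kabsch–Sander electrostatic H-bond model
_HB_CUTOFF = -0.5  # kcal/mol
_NH_BOND = 1.01  # Å


def place_amide_hydrogens(model: Structure) -> Structure:
    """Geometrically place missing backbone amide hydrogens.

    H sits 1.01 Å from N along the bisector of the C(i-1)→N and CA→N
    directions (the standard trans-amide construction). The first residue of
    each chain (no preceding carbonyl) is left without an H.
    """
    out = model.copy()
    from .structio import Atom, VDW_RADII

    for ch in out.chains:
        rlist = out.residues[ch]
        for i in range(1, len(rlist)):
            res = rlist[i]
            if "H" in res.atoms or res.name == "PRO":
                continue
            prev = rlist[i - 1]
            if not {"N", "CA"} <= set(res.atoms) or "C" not in prev.atoms:
                continue
            n_pos = res.atoms["N"].position
            u1 = n_pos - prev.atoms["C"].position
            u2 = n_pos - res.atoms["CA"].position
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            d = u1 + u2
            d /= np.linalg.norm(d)
            res.atoms["H"] = Atom("H", "H", n_pos + _NH_BOND * d, VDW_RADII["H"])
    return out


def _hbond_energy(o, c, n, h) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clash: treat as no bond
        return 0.0
    return _HB_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(model: Structure) -> SSAssignmentResult:
    """Backbone hydrogen-bond pattern assignment into {H, G, T, C}.

    Uses the electrostatic H-bond energy
    E = 27.9 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol with a bond
    threshold of -0.5 kcal/mol. Consecutive i→i+4 turns give α-helix (H),
    i→i+3 turns 3_10-helix (G), isolated turns T, everything else C.
    """
    model = place_amide_hydrogens(model)
    labels: dict[str, dict[int, str]] = {}
    for ch in model.chains:
        rlist = model.residues[ch]
        n = len(rlist)
        for r in rlist:
            if not {"N", "CA", "C", "O"} <= set(r.atoms):
                raise ValueError(
                    f"backbone atoms missing in chain {ch} residue {r.name}{r.number}"
                )
        def bonded(i: int, j: int) -> bool:  # CO(i) ... HN(j)
            if j >= n or "H" not in rlist[j].atoms:
                return False
            return _hbond_energy(
                rlist[i].atoms["O"].position, rlist[i].atoms["C"].position,
                rlist[j].atoms["N"].position, rlist[j].atoms["H"].position,
            ) < _HB_CUTOFF

        turn4 = np.array([bonded(i, i + 4) for i in range(n)])
        turn3 = np.array([bonded(i, i + 3) for i in range(n)])
        lab = ["C"] * n
        for i in range(n - 1):
            if turn4[i] and turn4[i + 1]:
                for j in range(i + 1, min(i + 5, n)):
                    lab[j] = "H"
        for i in range(n - 1):
            if turn3[i] and turn3[i + 1]:
                for j in range(i + 1, min(i + 4, n)):
                    if lab[j] == "C":
                        lab[j] = "G"
        for i in range(n):
            if turn4[i]:
                for j in range(i + 1, min(i + 4, n)):
                    if lab[j] == "C":
                        lab[j] = "T"
            if turn3[i]:
                for j in range(i + 1, min(i + 3, n)):
                    if lab[j] == "C":
                        lab[j] = "T"
        labels[ch] = {rlist[i].number: lab[i] for i in range(n)}
    return SSAssignmentResult(labels=labels)


def disorder_fraction(
    assignment: SSAssignmentResult | list[SSAssignmentResult],
    span: tuple[int, int],
    chain: str | None = None,
) -> float:
    """Fraction of residues in a span labelled turn or coil.

    For a list of per-model assignments (an ensemble) the mean fraction over
    models is returned. With ``chain=None`` all chains are pooled.
    """
    if isinstance(assignment, list):
        if not assignment:
            raise ValueError("empty assignment list")
        return float(np.mean([disorder_fraction(a, span, chain) for a in assignment]))
    lo, hi = span
    total, disordered = 0, 0
    chains = [chain] if chain else list(assignment.labels)
    for ch in chains:
        for num, lab in assignment.labels[ch].items():
            if lo <= num <= hi:
                total += 1
                disordered += lab in DISORDERED_LABELS
    if total == 0:
        raise ValueError("empty span")
    return disordered / total


# ---------------------------------------------------------------------------
# Pore profile / lateral portals / salt bridges
# ---------------------------------------------------------------------------

def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def pore_profile(
    model: Structure,
    frame: SymmetryFrame | None = None,
    z_range: tuple[float, float] | None = None,
    step: float = 0.5,
    clamp: float = 15.0,
    seed: int = 0,
) -> PoreProfile:
    """Largest-inscribed-sphere radius of the lumen along the symmetry axis.

    At each axis coordinate z, the in-plane center maximizing
    min_atoms(|c - atom| - vdw) is found by multi-start local search
    (axis point plus 8 seeded perturbed starts); the radius is clamped at
    ``clamp``. Deterministic for a fixed seed.
    """
    frame = frame or estimate_symmetry_axis(model)
    pos, rad = model.atom_array()
    axis, p0 = frame.axis_direction, frame.axis_point
    zs_atoms = (pos - p0) @ axis
    if z_range is None:
        z_range = (float(zs_atoms.min()), float(zs_atoms.max()))
    if z_range[1] <= z_range[0]:
        raise ValueError("empty z range")
    u, v = _plane_basis(axis)
    rng = np.random.default_rng(seed)
    starts = np.vstack([[0.0, 0.0], rng.normal(scale=1.5, size=(8, 2))])

    zgrid = np.arange(z_range[0], z_range[1] + 0.5 * step, step)
    centers, radii = [], []
    for z in zgrid:
        origin = p0 + z * axis
        near = np.abs(zs_atoms - z) < clamp + rad.max()
        apos, arad = pos[near], rad[near]

        if len(apos) == 0:
            centers.append(origin)
            radii.append(clamp)
            continue

        def neg_clearance(uv):
            c = origin + uv[0] * u + uv[1] * v
            return -(np.min(np.linalg.norm(apos - c, axis=1) - arad))

        best_uv, best_val = None, np.inf
        for s in starts:
            res = _sp_minimize(neg_clearance, s, method="Nelder-Mead",
                               options={"xatol": 1e-3, "fatol": 1e-4,
                                        "maxiter": 200})
            if res.fun < best_val:
                best_val, best_uv = res.fun, res.x
        r = min(max(-best_val, 0.0), clamp)
        centers.append(origin + best_uv[0] * u + best_uv[1] * v)
        radii.append(r)
    return PoreProfile(z=zgrid, centers=np.array(centers), radii=np.array(radii))


def lateral_portal_radius(
    model: Structure,
    interface: tuple[str, str] = ("A", "B"),
    girdle_z: float = 0.0,
    frame: SymmetryFrame | None = None,
    interface_residues: tuple[int, int] | None = None,
    step: float = 0.25,
    clamp: float = 15.0,
) -> float:
    """Bottleneck radius of the side opening between two adjacent subunits.

    A ray is cast from the vestibule axis point (at the height of the
    interface midpoint, above the girdle) outward through the midpoint of
    the adjacent-chain interface; the returned value is the smallest
    clearance (largest inscribed sphere) along the ray until it exits the
    protein envelope.
    """
    ia, ib = model.chains.index(interface[0]), model.chains.index(interface[1])
    if (ib - ia) % len(model.chains) not in (1, len(model.chains) - 1):
        raise ValueError("interface chains are not adjacent")
    frame = frame or estimate_symmetry_axis(model)
    axis, p0 = frame.axis_direction, frame.axis_point

    sel_pts = []
    for ch in interface:
        for r in model.residues[ch]:
            if interface_residues is None or (
                interface_residues[0] <= r.number <= interface_residues[1]
            ):
                pt = r.atoms["CA"].position
                if (pt - p0) @ axis >= girdle_z:
                    sel_pts.append(pt)
    if not sel_pts:
        raise ValueError("no interface residues above the girdle")
    mid = np.mean(sel_pts, axis=0)
    z_mid = (mid - p0) @ axis
    start = p0 + z_mid * axis
    direction = mid - start
    radial = np.linalg.norm(direction)
    if radial < 1e-9:
        raise ValueError("interface midpoint lies on the axis")
    direction = direction / radial

    pos, rad = model.atom_array()
    max_extent = np.max(np.linalg.norm((pos - p0) - np.outer((pos - p0) @ axis, axis), axis=1))
    ts = np.arange(0.0, max_extent + 3.0, step)
    bottleneck = clamp
    for t in ts:
        c = start + t * direction
        clearance = float(np.min(np.linalg.norm(pos - c, axis=1) - rad))
        bottleneck = min(bottleneck, max(clearance, 0.0))
    return bottleneck


_BASIC_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_ACIDIC_ATOMS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}


def salt_bridge_distances(
    model: Structure,
    pairs: list[tuple[int, int, str]],
) -> list[float | None]:
    """Minimum N(basic)–O(acidic) side-chain distance per requested pair.

    ``pairs`` holds (residue_a, residue_b, relation) with relation "intra"
    (same chain) or "adjacent" (neighbouring chains of the ring). For each
    pair the minimum over all chain instances is returned; no distance
    threshold is applied. A pair with missing side-chain atoms yields None
    (flagged in the log).
    """
    chains = model.chains
    n = len(chains)
    out: list[float | None] = []
    for res_a, res_b, relation in pairs:
        if relation not in ("intra", "adjacent"):
            raise ValueError(f"unknown chain relation {relation!r}")
        offsets = [0] if relation == "intra" else [1]
        best = None
        for k in range(n):
            for off in offsets:
                try:
                    ra = model.residue(chains[k], res_a)
                    rb = model.residue(chains[(k + off) % n], res_b)
                except Exception:
                    continue
                charged_a = _BASIC_ATOMS.get(ra.name) or _ACIDIC_ATOMS.get(ra.name)
                charged_b = _BASIC_ATOMS.get(rb.name) or _ACIDIC_ATOMS.get(rb.name)
                if not charged_a or not charged_b:
                    continue
                pts_a = [ra.atoms[a].position for a in charged_a if a in ra.atoms]
                pts_b = [rb.atoms[a].position for a in charged_b if a in rb.atoms]
                if not pts_a or not pts_b:
                    continue
                d = min(
                    float(np.linalg.norm(pa - pb)) for pa in pts_a for pb in pts_b
                )
                best = d if best is None else min(best, d)
        if best is None:
            logger.warning("salt bridge pair (%s, %s, %s): side-chain atoms missing",
                           res_a, res_b, relation)
        out.append(best)
    return out
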