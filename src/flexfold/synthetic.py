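"""Toy ground-truth pentamer and forward models for every observable the
pipeline consumes.

The toy subunit emulates the architecture of a flexible intracellular domain
anchored below a membrane domain: a short amphipathic helix, a large flexible
loop whose middle is anchored near the long helix (the "B"-shaped double
loop), and a long membrane-associated helix, assembled into an exact C5
pentamer. Forward models produce paramagnetic/diamagnetic intensity ratios,
IPAP splitting quartets, relaxation decay series, saturation pairs,
amide-shift temperature series, NOE contact lists and bimodal inter-subunit
DEER distributions — each the exact inverse of the corresponding restraint
derivation, so all round trips close at zero noise.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import esr_restraints as esr
from .nmr_restraints import (
    DistanceRestraint,
    PeakRecord,
    PREParams,
    RDCRecord,
    RelaxationSeries,
    pre_table_to_restraints,
    noes_to_restraints,
    peaks_to_frame,
    ratio_from_r2sp,
    r2sp_from_distance,
    write_restraints,
)
from .sampler import SSAnnotation, ideal_helix_coords, BOND_LENGTH
from .scoring import LABEL_ARM_LENGTH, pseudo_label_offsets
from .structio import (
    Structure,
    SymmetryFrame,
    structure_from_ca,
    symmetrize_c5,
    write_ensemble,
)

__all__ = [
    "SegmentPlan",
    "GroundTruth",
    "NoiseModel",
    "AlignmentTensor",
    "SyntheticBundle",
    "build_toy_pentamer",
    "forward_pre",
    "forward_deer",
    "forward_relaxation",
    "forward_rdc",
    "forward_temp_and_noe",
    "forward_shifts",
    "make_bundle",
    "restraints_from_bundle",
    "DEFAULT_LABEL_RESIDUES",
    "DEER_LABEL_RESIDUE",
]

# Physical constants for the model-free relaxation forward model (SI)
_GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1
_GAMMA_N = -2.7126e7
_R_NH = 1.02e-10  # m
_CSA_N = -172e-6
_MU0 = 4e-7 * math.pi
_HBAR = 1.054571817e-34

DEFAULT_LABEL_RESIDUES = (10, 30, 52)
# DEER is measured on every singly-labeled construct; three ring radii pin
# the subunit's placement relative to the symmetry axis
DEER_LABEL_RESIDUES = (10, 30, 52)
DEER_LABEL_RESIDUE = 52  # primary site (kept for single-site workflows)
_DIA_LINEWIDTH = 20.0  # Hz, diamagnetic reference linewidth of the toy peaks
_BASE_INTENSITY = 100.0

# Random-coil-referenced secondary-shift values emitted for each label
_SS_SECONDARY_SHIFTS = {"H": (3.0, -0.4), "E": (-2.0, 1.5),
                        "T": (0.0, 0.0), "C": (0.0, 0.0)}


@dataclass
class SegmentPlan:
    """Per-subunit segment layout: list of (kind, length) with kind H or L."""

    segments: list[tuple[str, int]] = field(
        default_factory=lambda: [("H", 18), ("L", 24), ("H", 18)]
    )
    first_residue: int = 1
    ring_radius: float = 20.0  # Å, distance of the subunit centroid from the axis

    @property
    def n_residues(self) -> int:
        return sum(n for _, n in self.segments)

    def labels(self) -> dict[int, str]:
        out, num = {}, self.first_residue
        for kind, n in self.segments:
            for _ in range(n):
                out[num] = "H" if kind == "H" else "C"
                num += 1
        return out


@dataclass
class NoiseModel:
    intensity_cv: float = 0.0
    shift_jitter_ppm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_cv < 0 or self.shift_jitter_ppm < 0:
            raise ValueError("noise magnitudes must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class AlignmentTensor:
    """Axial magnitude Da (Hz), rhombicity R in [0, 2/3], frame rotation."""

    da_hz: float = 10.0
    rhombicity: float = 0.3
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        if not (0.0 <= self.rhombicity <= 2.0 / 3.0):
            raise ValueError("rhombicity must be in [0, 2/3]")

    def rdc(self, nh_unit: np.ndarray) -> float:
        v = self.rotation.T @ nh_unit
        cos_t = v[2]
        sin2_t = 1.0 - cos_t * cos_t
        phi = math.atan2(v[1], v[0])
        return self.da_hz * (
            (3.0 * cos_t * cos_t - 1.0)
            + 1.5 * self.rhombicity * sin2_t * math.cos(2.0 * phi)
        )


@dataclass
class GroundTruth:
    structure: Structure  # exact-C5 pentamer, Cα level
    subunit_coords: np.ndarray
    residue_numbers: list[int]
    ss: SSAnnotation
    order_parameters: dict[int, float]  # S² in [0, 1]
    internal_times: dict[int, float]  # τe, s
    hbond_map: dict[int, bool]
    label_residues: tuple[int, ...]
    frame: SymmetryFrame
    tau_m: float = 5e-9  # toy-scale overall tumbling time, s

    def label_site(self, residue: int) -> np.ndarray:
        i = self.residue_numbers.index(residue)
        offs = pseudo_label_offsets(self.subunit_coords)
        return self.subunit_coords[i] + LABEL_ARM_LENGTH * offs[i]


def homolog_template(gt: GroundTruth, seed: int = 0,
                     n_moves: int = 150) -> np.ndarray:
    """Synthetic stand-in for a homolog starting template.

    Real determinations of this kind seed the first folding round with
    homolog structures; crucially, the template fixes the handedness of the
    assembly, which distance restraints alone cannot (a quasi-mirrored ring
    satisfies every distance within tolerance). Here the template is the
    ground truth diversified by many geometry-preserving moves until it is a
    poor but basin-correct model (typically 6-10 Å pentamer Cα RMSD).
    """
    from .sampler import _loop_indices, _propose

    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(77,)))
    loop_idx = _loop_indices(gt.residue_numbers, gt.ss)
    x = gt.subunit_coords.copy()
    for _ in range(n_moves):
        x = _propose(x, loop_idx, rng, rot_sigma=0.18, trans_sigma=0.5)
    return x


@dataclass
class SyntheticBundle:
    truth: GroundTruth
    template_subunit: np.ndarray
    pre_tables: dict[int, list[tuple[PeakRecord, PeakRecord]]]
    inter_pre_tables: dict[int, list[tuple[PeakRecord, PeakRecord]]]
    deer: dict[int, esr.DeerDistribution]
    noe_peaks: list[tuple[int, int, str]]
    shifts: pd.DataFrame
    temp_series: dict[int, list[tuple[float, PeakRecord]]]
    r1_series: list[RelaxationSeries]
    r2_series: list[RelaxationSeries]
    hetnoe_pairs: list[tuple[PeakRecord, PeakRecord]]
    rdc_records: list[RDCRecord]
    rdc_quartets: list[tuple[PeakRecord, PeakRecord, PeakRecord, PeakRecord]]
    pre_params: PREParams
    true_distances: dict[tuple, float]
    master_seed: int = 0


# ---------------------------------------------------------------------------
# Ground-truth construction
# ---------------------------------------------------------------------------

def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _place_helix(n: int, start: np.ndarray, direction: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    helix = ideal_helix_coords(n)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, direction)
    s, c = np.linalg.norm(v), float(z @ direction)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else _rot([1.0, 0, 0], math.pi)
    else:
        R = _rot(v / s, math.atan2(s, c))
    spin = _rot(direction, rng.uniform(0, 2 * math.pi))
    return (spin @ R @ helix.T).T + start


_MAX_TURN_COS = math.cos(math.radians(115.0))  # keep pseudo-angles above ~65°


def _bridge_walk(start: np.ndarray, target: np.ndarray, n_beads: int,
                 waypoints: list[tuple[float, np.ndarray]],
                 rng: np.random.Generator, existing: np.ndarray,
                 prev_bond: np.ndarray | None = None) -> np.ndarray | None:
    """Bridge of ``n_beads`` beads from ``start`` whose last bead lies exactly
    one bond from ``target``; detours through waypoints (fraction, point).

    Steps have exact bond length, limited turn angles and soft
    self-avoidance. Returns None when the bridge strands.
    """
    pts: list[np.ndarray] = []
    cur = start.copy()
    bond = prev_bond
    for k in range(n_beads):
        remaining = n_beads - k  # beads still to place, incl. this one
        if remaining == 2:
            # analytic closure: two beads, last exactly BOND from target
            d_vec = target - cur
            d = np.linalg.norm(d_vec)
            if d > 3 * BOND_LENGTH or d < 1e-9:
                return None
            # bead A on the intersection circle of spheres (cur, BOND) and
            # (target, 2*BOND); bead B then placed exactly BOND from target
            for _ in range(80):
                a = _two_sphere_point(cur, BOND_LENGTH, target, 2 * BOND_LENGTH, rng)
                if a is None:
                    return None
                b = _two_sphere_point(a, BOND_LENGTH, target, BOND_LENGTH, rng)
                if b is None:
                    continue
                vecs = [a - cur, b - a, target - b]
                if bond is not None:
                    vecs.insert(0, bond)
                turns_ok = all(
                    float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
                    >= _MAX_TURN_COS
                    for u, v in zip(vecs[:-1], vecs[1:])
                )
                if not turns_ok:
                    continue
                blocks = [np.asarray(existing)] if len(existing) else []
                if len(pts) > 1:
                    blocks.append(np.array(pts[:-1]))
                if blocks:
                    obstacles = np.vstack(blocks)
                    if min(
                        np.min(np.linalg.norm(obstacles - a, axis=1)),
                        np.min(np.linalg.norm(obstacles - b, axis=1)),
                    ) < 4.0:
                        continue
                pts.extend([a, b])
                return np.array(pts)
            return None
        frac = k / n_beads
        aim = target
        for wf, wp in waypoints:
            if frac < wf:
                aim = wp
                break
        cand = None
        for _ in range(150):
            d_aim = aim - cur
            bias = d_aim / max(np.linalg.norm(d_aim), 1e-9)
            budget = BOND_LENGTH * remaining
            need = np.linalg.norm(target - cur)
            w = 0.35 if need < 0.7 * budget else 0.9
            step = w * bias + (1 - w) * rng.normal(scale=0.7, size=3)
            step = step / np.linalg.norm(step) * BOND_LENGTH
            if bond is not None and float(bond @ step) / BOND_LENGTH**2 < _MAX_TURN_COS:
                continue  # too sharp a kink
            trial = cur + step
            beads_left = remaining - 1
            need_after = np.linalg.norm(target - trial)
            if beads_left >= 2 and need_after > BOND_LENGTH * (beads_left - 2) + 2.9 * BOND_LENGTH:
                continue  # would strand the bridge
            if need_after < 1.05 * BOND_LENGTH:
                continue  # would crowd the closure target
            if len(existing) and np.min(
                    np.linalg.norm(existing - trial, axis=1)) < 4.0:
                continue
            if len(pts) > 1 and np.min(
                    np.linalg.norm(np.array(pts[:-1]) - trial, axis=1)) < 4.0:
                continue
            cand = trial
            break
        if cand is None:
            return None
        bond = cand - cur
        cur = cand
        pts.append(cur.copy())
    return np.array(pts)


def _two_sphere_point(c1: np.ndarray, r1: float, c2: np.ndarray, r2: float,
                      rng: np.random.Generator) -> np.ndarray | None:
    """Seeded point on the intersection circle of two spheres."""
    d_vec = c2 - c1
    d = np.linalg.norm(d_vec)
    if d > r1 + r2 or d < abs(r1 - r2) or d < 1e-9:
        return None
    u = d_vec / d
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h2 = r1 * r1 - a * a
    if h2 < 0:
        return None
    h = math.sqrt(h2)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ u) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    phi = rng.uniform(0, 2 * math.pi)
    return c1 + a * u + h * (math.cos(phi) * e1 + math.sin(phi) * e2)


def build_toy_pentamer(plan: SegmentPlan | None = None, seed: int = 0) -> GroundTruth:
    """Deterministic toy C5 pentamer with two helices and one anchored loop.

    The first helix (amphipathic, roughly tangential) sits at the ring
    radius; the long second helix runs down along the pore; the loop bridges
    them with its middle anchored near the long helix of the same subunit.
    Internal retries (derived sub-seeds) reject assemblies with inter-chain
    Cα clashes; failure after 60 attempts raises.
    """
    plan = plan or SegmentPlan()
    if not (40 <= plan.n_residues <= 120):
        raise ValueError("plan must total 40–120 residues per subunit")
    kinds = [k for k, _ in plan.segments]
    if kinds.count("H") != 2 or "L" not in kinds:
        raise ValueError("plan must contain two helices and a loop")

    for attempt in range(60):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=seed, spawn_key=(attempt,)))
        x = _try_build(plan, rng)
        if x is None:
            continue
        frame = SymmetryFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        subunit = structure_from_ca(x, first_residue=plan.first_residue)
        pentamer = symmetrize_c5(subunit, frame)
        if _assembly_clashes(pentamer):
            continue
        numbers = [plan.first_residue + i for i in range(plan.n_residues)]
        labels = plan.labels()
        ss = SSAnnotation(labels=labels, source="template")
        s2 = {num: (0.85 if labels[num] == "H" else 0.30) for num in numbers}
        taue = {num: (20e-12 if labels[num] == "H" else 1.0e-9) for num in numbers}
        hbond = _hbond_map_from_labels(numbers, labels)
        return GroundTruth(
            structure=pentamer, subunit_coords=x, residue_numbers=numbers,
            ss=ss, order_parameters=s2, internal_times=taue,
            hbond_map=hbond, label_residues=DEFAULT_LABEL_RESIDUES, frame=frame,
        )
    raise RuntimeError("could not build a clash-free toy pentamer for this plan")


def _hbond_map_from_labels(numbers: list[int], labels: dict[int, str]) -> dict[int, bool]:
    # helix residues with a full i->i+4 donor context count as hydrogen bonded
    out = {}
    for num in numbers:
        inside = all(labels.get(num + d, "C") == "H" for d in range(-2, 3))
        out[num] = labels[num] == "H" and inside
    return out


def _try_build(plan: SegmentPlan, rng: np.random.Generator) -> np.ndarray | None:
    r0 = plan.ring_radius
    segs = plan.segments
    n1, n_loop, n2 = segs[0][1], segs[1][1], segs[2][1]

    # long helix (MA analog): downward, tilted slightly outward, at ~0.55*r0
    ma_top = np.array([0.55 * r0, 0.0, -2.0])
    ma_dir = np.array([0.12, 0.05, -1.0])
    ma = _place_helix(n2, ma_top, ma_dir, rng)

    # short helix (MX analog): roughly tangential near the membrane plane
    mx_start = np.array([0.95 * r0, -9.0, 8.0])
    mx_dir = np.array([0.25, 1.0, -0.1])
    mx = _place_helix(n1, mx_start, mx_dir, rng)

    # anchored loop: from MX end to MA start, detouring out to the rim and
    # back past an anchor point near the MA helix midpoint
    anchor = ma[n2 // 2] + np.array([5.5, 2.5, 0.0])
    rim = np.array([1.25 * r0, 6.0, 2.0])
    existing = np.vstack([mx[:-1], ma[1:]])  # junction beads excluded
    prev_bond = mx[-1] - mx[-2]
    loop = _bridge_walk(mx[-1], ma_top, n_loop,
                        [(0.4, rim), (0.75, anchor)], rng, existing,
                        prev_bond=prev_bond)
    if loop is None:
        return None

    x = np.vstack([mx, loop, ma])
    bonds = np.linalg.norm(np.diff(x, axis=0), axis=1)
    if np.any(np.abs(bonds - BOND_LENGTH) > 0.05):
        return None
    # anchor contract: some loop residue in the anchored stretch sits close
    # to the long helix
    lo = len(mx) + int(0.6 * n_loop)
    hi = len(mx) + n_loop
    from scipy.spatial.distance import cdist
    if np.min(cdist(x[lo:hi], ma)) >= 8.0:
        return None
    return x


def _assembly_clashes(pentamer: Structure, cutoff: float = 3.95) -> bool:
    from scipy.spatial.distance import cdist

    xa = pentamer.ca_coords(["A"])
    for other in ("B", "C"):
        if np.min(cdist(xa, pentamer.ca_coords([other]))) < cutoff:
            return True
    return False


# ---------------------------------------------------------------------------
# Ideal full-atom backbone (for hydrogen-bond secondary-structure tests)
# ---------------------------------------------------------------------------

_BB_GEOMETRY = {  # lengths Å / angles deg of the peptide backbone
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8,
}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension place of atom D from A-B-C internal coordinates."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_backbone_chain(
    n_res: int,
    phi: float = -57.0,
    psi: float = -47.0,
    chain: str = "A",
    first_residue: int = 1,
    residue_name: str = "ALA",
) -> Structure:
    """Full-backbone (N, CA, C, O) chain at uniform φ/ψ, built by NeRF.

    Defaults give an ideal α-helix; (-120, 120) an extended strand. Carbonyl
    oxygens are placed trans to the next nitrogen.
    """
    from .structio import Atom, Residue, VDW_RADII

    g = _BB_GEOMETRY
    omega = 180.0
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([g["n_ca"], 0.0, 0.0])
    ang = math.radians(g["ang_n_ca_c"])
    c0 = ca0 + g["ca_c"] * np.array([math.cos(math.pi - ang),
                                     math.sin(math.pi - ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = coords[-1]
        n = _nerf(prev["N"], prev["CA"], prev["C"],
                  g["c_n"], g["ang_ca_c_n"], psi)
        ca = _nerf(prev["CA"], prev["C"], n,
                   g["n_ca"], g["ang_c_n_ca"], omega)
        c = _nerf(prev["C"], n, ca, g["ca_c"], g["ang_n_ca_c"], phi)
        coords.append({"N": n, "CA": ca, "C": c})
    # carbonyl O: in the CA-C-N(next) plane, opposite the next N
    for i, atoms in enumerate(coords):
        if i + 1 < n_res:
            atoms["O"] = _nerf(coords[i + 1]["N"], atoms["CA"], atoms["C"],
                               g["c_o"], g["ang_ca_c_o"], 180.0)
        else:
            atoms["O"] = _nerf(atoms["N"], atoms["CA"], atoms["C"],
                               g["c_o"], g["ang_ca_c_o"], psi + 180.0)

    residues = []
    for i, atoms in enumerate(coords):
        residues.append(Residue(first_residue + i, residue_name, {
            name: Atom(name, name[0], pos, VDW_RADII.get(name[0], 1.7))
            for name, pos in atoms.items()
        }))
    return Structure(chains=[chain], residues={chain: residues},
                     resolution_level="full-atom")


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def forward_pre(
    gt: GroundTruth,
    label_residue: int,
    params: PREParams | None = None,
    noise: NoiseModel | None = None,
    observed_offset: int = 0,
) -> list[tuple[PeakRecord, PeakRecord]]:
    """Paired paramagnetic/diamagnetic peaks for every residue, from the
    label-to-amide-proxy distances of the ground truth (exact inverse of the
    PRE restraint derivation).

    ``observed_offset=1`` emulates the mixed-labelling inter-subunit PRE
    experiment: the observed amides belong to the chain one step around the
    ring from the labelled chain.
    """
    params = params or PREParams()
    noise = noise or NoiseModel()
    rng = noise.rng()
    if label_residue not in gt.residue_numbers:
        raise ValueError(f"no residue {label_residue} in ground truth")
    site = gt.label_site(label_residue)
    observed = gt.subunit_coords
    if observed_offset:
        from .structio import rotation_about_axis

        R, t = rotation_about_axis(gt.frame, 2 * math.pi * observed_offset / 5)
        observed = observed @ R.T + t
    out = []
    for i, num in enumerate(gt.residue_numbers):
        r = float(np.linalg.norm(observed[i] - site))
        r2sp = r2sp_from_distance(max(r, 0.1), params)
        ratio = ratio_from_r2sp(r2sp, _DIA_LINEWIDTH, params.t_evol)
        i0 = _BASE_INTENSITY * (1.0 + noise.intensity_cv * rng.standard_normal())
        ipara = ratio * _BASE_INTENSITY * (
            1.0 + noise.intensity_cv * rng.standard_normal())
        sigma = _BASE_INTENSITY * noise.intensity_cv
        out.append((
            PeakRecord(num, "paramagnetic", max(ipara, 0.0),
                       linewidth=_DIA_LINEWIDTH, noise_sigma=sigma),
            PeakRecord(num, "diamagnetic", max(i0, 1e-6),
                       linewidth=_DIA_LINEWIDTH, noise_sigma=sigma),
        ))
    return out


def forward_deer(
    gt: GroundTruth,
    label_residue: int,
    width: float = 2.0,
    noise: NoiseModel | None = None,
    r_max: float = 70.0,
    step: float = 0.25,
) -> esr.DeerDistribution:
    """Bimodal inter-subunit label distance distribution of the C5 ring.

    A pentagon of one label per subunit has 5 adjacent and 5 diagonal pairs,
    so the two Gaussian modes carry equal weight.
    """
    noise = noise or NoiseModel()
    site0 = gt.label_site(label_residue)
    d_adj, d_diag = pentamer_label_distances(gt.frame, site0)
    r = np.arange(2.0, r_max, step)
    p = (np.exp(-0.5 * ((r - d_adj) / width) ** 2)
         + np.exp(-0.5 * ((r - d_diag) / (width * 1.2)) ** 2))
    if noise.intensity_cv > 0:
        rng = noise.rng()
        p = np.clip(p + noise.intensity_cv * p.max()
                    * rng.standard_normal(len(p)), 0.0, None)
    p /= np.trapezoid(p, r)
    return esr.DeerDistribution(r_grid=r, p=p)


def pentamer_label_distances(frame: SymmetryFrame, site: np.ndarray) -> tuple[float, float]:
    """(adjacent, diagonal) distances of a point replicated by C5 symmetry."""
    from .structio import rotation_about_axis

    def at(k):
        R, t = rotation_about_axis(frame, 2 * math.pi * k / 5)
        return R @ site + t

    return (float(np.linalg.norm(site - at(1))),
            float(np.linalg.norm(site - at(2))))


# -- relaxation -------------------------------------------------------------

R2_DELAYS_S = np.array([16, 32, 64, 96, 128, 192, 320, 640]) * 1e-3
R1_DELAYS_S = np.array([20, 50, 100, 200, 400, 700, 1000, 1500]) * 1e-3


def _spectral_density(omega: float, s2: float, tau_m: float, tau_e: float) -> float:
    tau_p = tau_m * tau_e / (tau_m + tau_e)
    return 0.4 * (s2 * tau_m / (1.0 + (omega * tau_m) ** 2)
                  + (1.0 - s2) * tau_p / (1.0 + (omega * tau_p) ** 2))


def model_free_rates(s2: float, tau_e: float, tau_m: float,
                     field_mhz: float = 700.0) -> tuple[float, float, float]:
    """(R1, R2, hetNOE) of a backbone 15N under the two-timescale model-free
    spectral density with dipolar + CSA relaxation."""
    b0 = 2 * math.pi * field_mhz * 1e6 / _GAMMA_H
    w_h = _GAMMA_H * b0
    w_n = abs(_GAMMA_N) * b0
    d = _MU0 / (4 * math.pi) * _HBAR * _GAMMA_H * abs(_GAMMA_N) / _R_NH**3
    c = w_n * abs(_CSA_N) / math.sqrt(3.0)
    J = lambda w: _spectral_density(w, s2, tau_m, tau_e)
    j0, jn, jh = J(0.0), J(w_n), J(w_h)
    jhn_m, jhn_p = J(w_h - w_n), J(w_h + w_n)
    r1 = d * d / 4.0 * (jhn_m + 3 * jn + 6 * jhn_p) + c * c * jn
    r2 = (d * d / 8.0 * (4 * j0 + jhn_m + 3 * jn + 6 * jh + 6 * jhn_p)
          + c * c / 6.0 * (4 * j0 + 3 * jn))
    gamma_ratio = _GAMMA_H / _GAMMA_N  # negative
    noe = 1.0 + d * d / 4.0 * gamma_ratio * (6 * jhn_p - jhn_m) / r1
    return r1, r2, noe


def forward_relaxation(
    gt: GroundTruth,
    field_mhz: float = 700.0,
    noise: NoiseModel | None = None,
) -> tuple[list[RelaxationSeries], list[RelaxationSeries],
           list[tuple[PeakRecord, PeakRecord]]]:
    """Per-residue R1/R2 decay series and hetNOE saturation pairs."""
    noise = noise or NoiseModel()
    rng = noise.rng()
    r1_out, r2_out, noe_out = [], [], []
    for num in gt.residue_numbers:
        s2 = gt.order_parameters[num]
        taue = gt.internal_times[num]
        r1, r2, noe = model_free_rates(s2, taue, gt.tau_m, field_mhz)
        sigma = _BASE_INTENSITY * noise.intensity_cv

        def decay(delays, rate):
            ideal = _BASE_INTENSITY * np.exp(-rate * delays)
            return ideal + sigma * rng.standard_normal(len(delays))

        r1_out.append(RelaxationSeries(num, R1_DELAYS_S, decay(R1_DELAYS_S, r1),
                                       noise_sigma=sigma))
        r2_out.append(RelaxationSeries(num, R2_DELAYS_S, decay(R2_DELAYS_S, r2),
                                       noise_sigma=sigma))
        unsat = _BASE_INTENSITY * (1.0 + noise.intensity_cv * rng.standard_normal())
        sat = noe * _BASE_INTENSITY * (1.0 + noise.intensity_cv * rng.standard_normal())
        noe_out.append((
            PeakRecord(num, "saturated", sat, noise_sigma=sigma),
            PeakRecord(num, "unsaturated", unsat, noise_sigma=sigma),
        ))
    return r1_out, r2_out, noe_out


# -- RDC --------------------------------------------------------------------

J_NH_HZ = 93.0
_BASE_SHIFT_N = 120.0  # ppm


def forward_rdc(
    gt: GroundTruth,
    tensor: AlignmentTensor | None = None,
    noise: NoiseModel | None = None,
    field_mhz: float = 700.0,
) -> tuple[list[RDCRecord], list[tuple[PeakRecord, PeakRecord, PeakRecord, PeakRecord]]]:
    """Tensor-forward RDCs plus the synthetic IPAP shift quartets they imply.

    NH orientations are taken from the deterministic outward-bisector
    construction on the Cα trace (interior residues only).
    """
    from .nmr_restraints import N15_GYROMAGNETIC_RATIO_REL

    tensor = tensor or AlignmentTensor()
    noise = noise or NoiseModel()
    rng = noise.rng()
    n_freq = field_mhz * N15_GYROMAGNETIC_RATIO_REL
    offs = pseudo_label_offsets(gt.subunit_coords)
    records, quartets = [], []
    for i, num in enumerate(gt.residue_numbers[1:-1], start=1):
        nh = offs[i]
        d = tensor.rdc(nh) + noise.shift_jitter_ppm * n_freq * rng.standard_normal()
        records.append(RDCRecord(residue=num, d_hz=float(d)))
        half_dia_ppm = 0.5 * J_NH_HZ / n_freq
        half_para_ppm = 0.5 * (J_NH_HZ + d) / n_freq
        mk = lambda cond, shift: PeakRecord(num, cond, _BASE_INTENSITY,
                                            shift_n=shift)
        quartets.append((
            mk("inphase", _BASE_SHIFT_N + half_para_ppm),
            mk("antiphase", _BASE_SHIFT_N - half_para_ppm),
            mk("inphase", _BASE_SHIFT_N + half_dia_ppm),
            mk("antiphase", _BASE_SHIFT_N - half_dia_ppm),
        ))
    return records, quartets


# -- temperature coefficients and NOEs --------------------------------------

TEMPERATURES_K = np.array([298.15, 303.15, 308.15, 313.15, 318.15])
NOE_CUTOFF = 5.5  # Å on Cα-Cα distances
_BASE_SHIFT_H = 8.2  # ppm


def forward_temp_and_noe(
    gt: GroundTruth,
    noise: NoiseModel | None = None,
) -> tuple[dict[int, list[tuple[float, PeakRecord]]], list[tuple[int, int, str]]]:
    """Amide-shift temperature series honouring the hydrogen-bond map, and a
    classified NOE contact list from the Cα trace (pairs within 5.5 Å)."""
    noise = noise or NoiseModel()
    rng = noise.rng()
    series: dict[int, list[tuple[float, PeakRecord]]] = {}
    for num in gt.residue_numbers:
        if gt.hbond_map[num]:
            slope = rng.uniform(-4.4, -0.5)  # ppb/K, shielded by the H-bond
        else:
            slope = rng.uniform(-9.0, -4.6)
        pts = []
        for t in TEMPERATURES_K:
            shift = (_BASE_SHIFT_H + slope * (t - TEMPERATURES_K[0]) * 1e-3
                     + noise.shift_jitter_ppm * rng.standard_normal())
            pts.append((float(t), PeakRecord(num, f"temperature:{t}",
                                             _BASE_INTENSITY, shift_h=shift)))
        series[num] = pts

    x = gt.subunit_coords
    peaks = []
    for i in range(len(x)):
        for j in range(i + 2, len(x)):
            d = float(np.linalg.norm(x[i] - x[j]))
            if d < NOE_CUTOFF:
                klass = "strong" if d <= 3.5 else ("medium" if d <= 4.5 else "weak")
                peaks.append((gt.residue_numbers[i], gt.residue_numbers[j], klass))
    return series, peaks


def forward_shifts(gt: GroundTruth, noise: NoiseModel | None = None) -> pd.DataFrame:
    """Secondary Cα/Cβ chemical shifts consistent with the true annotation."""
    noise = noise or NoiseModel()
    rng = noise.rng()
    rows = []
    for num in gt.residue_numbers:
        dca, dcb = _SS_SECONDARY_SHIFTS[gt.ss.label(num)]
        rows.append({
            "residue": num,
            "dca": dca + noise.shift_jitter_ppm * rng.standard_normal(),
            "dcb": dcb + noise.shift_jitter_ppm * rng.standard_normal(),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle assembly and on-disk form
# ---------------------------------------------------------------------------

def make_bundle(
    master_seed: int = 0,
    plan: SegmentPlan | None = None,
    noise: NoiseModel | None = None,
    outdir: str | Path | None = None,
    pre_params: PREParams | None = None,
) -> SyntheticBundle:
    """Ground truth plus every forward-modeled observable; optionally written
    to ``outdir`` as the same text formats the pipeline reads, with a
    checksum manifest. Byte-identical for identical seeds."""
    gt = build_toy_pentamer(plan, seed=master_seed)
    pre_params = pre_params or PREParams()

    def sub_noise(tag: int) -> NoiseModel:
        if noise is None:
            return NoiseModel(seed=tag)
        return NoiseModel(noise.intensity_cv, noise.shift_jitter_ppm,
                          seed=int(np.random.SeedSequence(
                              entropy=noise.seed, spawn_key=(tag,)
                          ).generate_state(1)[0] % (2**31)))

    pre_tables = {
        res: forward_pre(gt, res, pre_params, sub_noise(100 + k))
        for k, res in enumerate(gt.label_residues)
    }
    inter_pre_tables = {
        res: forward_pre(gt, res, pre_params, sub_noise(150 + k),
                         observed_offset=1)
        for k, res in enumerate(gt.label_residues)
    }
    deer = {res: forward_deer(gt, res, noise=sub_noise(200 + k))
            for k, res in enumerate(DEER_LABEL_RESIDUES)}
    temp_series, noe_peaks = forward_temp_and_noe(gt, sub_noise(300))
    r1s, r2s, noes = forward_relaxation(gt, noise=sub_noise(400))
    rdcs, quartets = forward_rdc(gt, noise=sub_noise(500))
    shifts = forward_shifts(gt, sub_noise(600))

    # truth table keyed ("PRE", label_res, observed_res, offset) and
    # ("DEER", label_res, offset)
    true_d: dict[tuple, float] = {}
    offs = pseudo_label_offsets(gt.subunit_coords)
    sites = gt.subunit_coords + LABEL_ARM_LENGTH * offs
    from .structio import rotation_about_axis

    R1, t1 = rotation_about_axis(gt.frame, 2 * math.pi / 5)
    neighbor = gt.subunit_coords @ R1.T + t1
    for res in gt.label_residues:
        i = gt.residue_numbers.index(res)
        for j, num in enumerate(gt.residue_numbers):
            true_d[("PRE", res, num, 0)] = float(
                np.linalg.norm(sites[i] - gt.subunit_coords[j]))
            true_d[("PRE", res, num, 1)] = float(
                np.linalg.norm(sites[i] - neighbor[j]))
    for res in DEER_LABEL_RESIDUES:
        d_adj, d_diag = pentamer_label_distances(gt.frame, gt.label_site(res))
        true_d[("DEER", res, 1)] = d_adj
        true_d[("DEER", res, 2)] = d_diag

    bundle = SyntheticBundle(
        truth=gt, template_subunit=homolog_template(gt, master_seed),
        pre_tables=pre_tables, inter_pre_tables=inter_pre_tables,
        deer=deer, noe_peaks=noe_peaks,
        shifts=shifts, temp_series=temp_series, r1_series=r1s, r2_series=r2s,
        hetnoe_pairs=noes, rdc_records=rdcs, rdc_quartets=quartets,
        pre_params=pre_params, true_distances=true_d, master_seed=master_seed,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: SyntheticBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    write_ensemble(bundle.truth.structure, outdir / "truth_pentamer.pdb")
    files["truth_pentamer.pdb"] = None
    write_ensemble(
        symmetrize_c5(structure_from_ca(bundle.template_subunit),
                      bundle.truth.frame),
        outdir / "template_pentamer.pdb")
    files["template_pentamer.pdb"] = None

    for res, table in bundle.pre_tables.items():
        recs = [rec for pair in table for rec in pair]
        peaks_to_frame(recs).to_csv(outdir / f"pre_{res}.tsv", sep="\t", index=False)
        files[f"pre_{res}.tsv"] = None
    for res, table in bundle.inter_pre_tables.items():
        recs = [rec for pair in table for rec in pair]
        peaks_to_frame(recs).to_csv(outdir / f"pre_inter_{res}.tsv",
                                    sep="\t", index=False)
        files[f"pre_inter_{res}.tsv"] = None
    for res, dist in bundle.deer.items():
        esr.write_distribution(dist, outdir / f"deer_{res}.dat")
        files[f"deer_{res}.dat"] = None
    pd.DataFrame(bundle.noe_peaks,
                 columns=["residue_i", "residue_j", "class"]).to_csv(
        outdir / "noe_peaks.tsv", sep="\t", index=False)
    files["noe_peaks.tsv"] = None
    bundle.shifts.to_csv(outdir / "shifts.tsv", sep="\t", index=False)
    files["shifts.tsv"] = None

    truth_rows = [
        {"kind": key[0], "label_residue": key[1],
         "observed_residue": key[2] if key[0] == "PRE" else key[1],
         "offset": key[-1], "distance": d}
        for key, d in bundle.true_distances.items()
    ]
    pd.DataFrame(truth_rows).to_csv(outdir / "true_distances.tsv",
                                    sep="\t", index=False)
    files["true_distances.tsv"] = None

    restraints = restraints_from_bundle(bundle)
    write_restraints(restraints, outdir / "restraints.tsv")
    files["restraints.tsv"] = None

    manifest = {"master_seed": bundle.master_seed, "files": {}}
    for name in files:
        digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        manifest["files"][name] = digest
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def restraints_from_bundle(bundle: SyntheticBundle) -> list[DistanceRestraint]:
    """Run the full observable→restraint derivation on a bundle."""
    out: list[DistanceRestraint] = []
    for res, table in bundle.pre_tables.items():
        out.extend(pre_table_to_restraints(table, (res, "LABEL", 0),
                                           bundle.pre_params))
    for res, table in bundle.inter_pre_tables.items():
        out.extend(pre_table_to_restraints(table, (res, "LABEL", 0),
                                           bundle.pre_params,
                                           observed_offset=1))
    for res, dist in bundle.deer.items():
        modes = esr.split_pentamer_modes(dist)
        out.extend(esr.deer_to_distance_restraints(esr.to_restraints(modes, res)))
    out.extend(noes_to_restraints(bundle.noe_peaks))
    return out
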