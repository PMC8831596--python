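"""Restraint potentials, coarse-grained stand-in energy, ranking score, Q-factors.

The total score mirrors restraint-based ensemble ranking: a weighted sum of a
physics stand-in (virtual bonds, pseudo-angles, soft-sphere repulsion), a
knowledge stand-in (secondary-structure dihedral bias), harmonic DEER terms,
sigmoid PRE terms and flat-bottom NOE terms. Units are arbitrary score units;
only ranking matters. Lower is better.

Two evaluation paths exist: a reference path over :class:`Structure` objects
and a compiled :class:`SymmetricScorer` over subunit coordinate arrays for
the Monte Carlo sampler (exact-C5 models only). Both agree on symmetrized
pentamers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit

from .nmr_restraints import DistanceRestraint
from .structio import Structure, SymmetryFrame, rotation_about_axis

__all__ = [
    "ScoreBreakdown",
    "ScoreWeights",
    "CGParams",
    "QReport",
    "harmonic_energy",
    "sigmoid_energy",
    "flat_bottom_energy",
    "restraint_energy",
    "cg_energy",
    "total_score",
    "q_factor",
    "site_position",
    "label_site_position",
    "pseudo_label_offsets",
    "restraint_distances",
    "SymmetricScorer",
]

LABEL_ARM_LENGTH = 5.0  # Å from Cα along the pseudo-Cβ direction (MTSL proxy)
CB_LABEL_EXTENSION = 3.5  # Å past Cβ when a real Cβ exists


@dataclass
class ScoreBreakdown:
    s_physics: float = 0.0
    s_knowledge: float = 0.0
    s_deer: float = 0.0
    s_pre: float = 0.0
    s_noe: float = 0.0
    s_total: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "s_physics": self.s_physics,
            "s_knowledge": self.s_knowledge,
            "s_deer": self.s_deer,
            "s_pre": self.s_pre,
            "s_noe": self.s_noe,
            "s_total": self.s_total,
        }


@dataclass
class ScoreWeights:
    physics: float = 1.0
    knowledge: float = 1.0
    deer: float = 1.0
    pre: float = 1.0
    noe: float = 1.0

    def combine(self, s_physics, s_knowledge, s_deer, s_pre, s_noe) -> ScoreBreakdown:
        total = (self.physics * s_physics + self.knowledge * s_knowledge
                 + self.deer * s_deer + self.pre * s_pre + self.noe * s_noe)
        return ScoreBreakdown(s_physics, s_knowledge, s_deer, s_pre, s_noe, total)


@dataclass
class CGParams:
    """Coarse-grained stand-in energy parameters (score units, Å, radians)."""

    bond_target: float = 3.8
    bond_k: float = 5.0
    angle_min: float = math.radians(75.0)
    angle_max: float = math.pi  # no straightness penalty by default
    angle_k: float = 20.0
    helix_dihedral: float = math.radians(50.0)  # ideal Cα pseudo-dihedral of an α-helix
    dihedral_k: float = 5.0
    repulsion_onset: float = 4.0
    repulsion_k: float = 10.0
    sigmoid_steepness: float = 2.0  # 1/Å


@dataclass
class QReport:
    q_noe: float | None = None
    q_pre: float | None = None
    q_pre_free: float | None = None
    q_deer: float | None = None
    n_restraints: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Elementary potentials
# ---------------------------------------------------------------------------

def harmonic_energy(d: float, d0: float, k: float = 1.0):
    if np.any(np.asarray(k) < 0):
        raise ValueError("harmonic weight must be >= 0")
    return k * (d - d0) ** 2


def sigmoid_energy(d, d0, m: float = 2.0, sense: str = "upper"):
    """Logistic penalty in [0, 1]; 0.5 at d0, monotone in d.

    ``sense="upper"`` rises as d exceeds d0 (an upper bound being violated);
    ``sense="lower"`` is the mirror image.
    """
    if m <= 0:
        raise ValueError("steepness must be positive")
    x = m * (np.asarray(d, dtype=float) - d0)
    if sense == "lower":
        x = -x
    elif sense != "upper":
        raise ValueError(f"unknown sense {sense!r}")
    return expit(x)


def flat_bottom_energy(d, lower: float, upper: float, k: float = 1.0):
    """Zero inside [lower, upper]; harmonic in the violation outside (C¹)."""
    if lower > upper:
        raise ValueError("lower bound exceeds upper bound")
    d = np.asarray(d, dtype=float)
    viol = np.where(d < lower, lower - d, np.where(d > upper, d - upper, 0.0))
    return k * viol ** 2


# ---------------------------------------------------------------------------
# Site positions on structures
# ---------------------------------------------------------------------------

def pseudo_label_offsets(ca: np.ndarray) -> np.ndarray:
    """Unit pseudo-Cβ directions for interior residues of a Cα trace.

    Row i is the outward bisector of the two virtual bonds at residue i
    (rows 0 and n-1 are NaN: a terminal residue has no defined direction).
    """
    n = len(ca)
    out = np.full((n, 3), np.nan)
    v = (ca[1:-1] - ca[:-2]) + (ca[1:-1] - ca[2:])
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    out[1:-1] = v / norms
    return out


def label_site_position(model: Structure, chain: str, residue_number: int) -> np.ndarray:
    """Spin-label proxy coordinate for a residue.

    Full-atom structures with a Cβ: 3.5 Å past Cβ along Cα→Cβ. Cα-level
    structures: 5 Å from Cα along the outward bisector of the trace.
    """
    res = model.residue(chain, residue_number)
    if "CB" in res.atoms:
        ca = res.atoms["CA"].position
        cb = res.atoms["CB"].position
        u = cb - ca
        u = u / np.linalg.norm(u)
        return cb + CB_LABEL_EXTENSION * u
    rlist = model.residues[chain]
    idx = next(i for i, r in enumerate(rlist) if r.number == residue_number)
    if idx == 0 or idx == len(rlist) - 1:
        raise ValueError("cannot place a label on a terminal residue")
    ca = np.array([r.atoms["CA"].position for r in rlist])
    return ca[idx] + LABEL_ARM_LENGTH * pseudo_label_offsets(ca)[idx]


def site_position(model: Structure, chain: str, residue_number: int, atom: str) -> np.ndarray:
    if atom == "LABEL":
        return label_site_position(model, chain, residue_number)
    res = model.residue(chain, residue_number)
    if atom == "H" and "H" not in res.atoms:
        return res.atoms["CA"].position  # amide proxy at Cα resolution
    return res[atom].position


def restraint_distances(model: Structure, restraints: list[DistanceRestraint]) -> np.ndarray:
    """Per-restraint distance averaged over the five symmetric chain instances."""
    chains = model.chains
    n = len(chains)
    out = np.empty(len(restraints))
    for i, r in enumerate(restraints):
        ds = []
        for k in range(n):
            ca_chain = chains[(k + r.site_a[2]) % n]
            cb_chain = chains[(k + r.site_b[2]) % n]
            pa = site_position(model, ca_chain, r.site_a[0], r.site_a[1])
            pb = site_position(model, cb_chain, r.site_b[0], r.site_b[1])
            ds.append(np.linalg.norm(pa - pb))
        out[i] = np.mean(ds)
    return out


# ---------------------------------------------------------------------------
# Restraint energies (reference path)
# ---------------------------------------------------------------------------

def _single_restraint_energy(d: float, r: DistanceRestraint, m: float) -> float:
    if r.potential == "harmonic":
        return float(harmonic_energy(d, r.d0, r.weight))
    if r.potential == "flat-bottom":
        return float(flat_bottom_energy(d, r.lower, r.upper, r.weight))
    if r.potential == "sigmoid":
        e = 0.0
        if np.isfinite(r.upper):
            e += sigmoid_energy(d, r.upper, m, "upper")
        if r.lower > 0:
            e += sigmoid_energy(d, r.lower, m, "lower")
        return float(r.weight * e)
    raise ValueError(f"unknown potential {r.potential!r}")


def restraint_energy(
    model: Structure,
    restraints: list[DistanceRestraint],
    params: CGParams | None = None,
) -> dict[str, float]:
    """Summed restraint energy per class over all symmetric chain instances."""
    params = params or CGParams()
    chains = model.chains
    n = len(chains)
    energies = {"DEER": 0.0, "PRE": 0.0, "NOE": 0.0}
    for r in restraints:
        for k in range(n):
            try:
                pa = site_position(model, chains[(k + r.site_a[2]) % n],
                                   r.site_a[0], r.site_a[1])
                pb = site_position(model, chains[(k + r.site_b[2]) % n],
                                   r.site_b[0], r.site_b[1])
            except (KeyError, StopIteration) as exc:
                raise ValueError(f"unevaluable restraint {r}") from exc
            d = float(np.linalg.norm(pa - pb))
            energies[r.kind] += _single_restraint_energy(d, r, params.sigmoid_steepness)
    return energies


# ---------------------------------------------------------------------------
# Coarse-grained stand-in energy
# ---------------------------------------------------------------------------

def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _row_norms(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", a, a))


def _pseudo_dihedrals(x: np.ndarray) -> np.ndarray:
    b0 = x[1:-2] - x[:-3]
    b1 = x[2:-1] - x[1:-2]
    b2 = x[3:] - x[2:-1]
    n1 = _cross_rows(b0, b1)
    n2 = _cross_rows(b1, b2)
    m1 = _cross_rows(n1, b1 / _row_norms(b1)[:, None])
    xcomp = np.einsum("ij,ij->i", n1, n2)
    ycomp = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(ycomp, xcomp)


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu_k2(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _TRIU_CACHE:
        _TRIU_CACHE[n] = np.triu_indices(n, k=2)
    return _TRIU_CACHE[n]


def _chain_cg_terms(x: np.ndarray, ss: np.ndarray | None, p: CGParams) -> tuple[float, float]:
    """(physics, knowledge) terms for one chain's Cα trace."""
    bonds = _row_norms(np.diff(x, axis=0))
    e_bond = p.bond_k * np.sum((bonds - p.bond_target) ** 2)

    v1 = x[:-2] - x[1:-1]
    v2 = x[2:] - x[1:-1]
    cosang = np.einsum("ij,ij->i", v1, v2) / (_row_norms(v1) * _row_norms(v2))
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    viol = np.where(ang < p.angle_min, p.angle_min - ang,
                    np.where(ang > p.angle_max, ang - p.angle_max, 0.0))
    e_angle = p.angle_k * np.sum(viol ** 2)

    # intra-chain soft-sphere repulsion, |i-j| >= 2
    d2 = cdist(x, x, "sqeuclidean")[_triu_k2(len(x))]
    close = d2 < p.repulsion_onset**2
    e_rep = p.repulsion_k * np.sum(
        (p.repulsion_onset - np.sqrt(d2[close])) ** 2)

    e_knowledge = 0.0
    if ss is not None and len(x) >= 4:
        dih = _pseudo_dihedrals(x)
        # dihedral i spans residues i..i+3; bias only fully-helical windows
        helical = (ss[:-3] == "H") & (ss[1:-2] == "H") & (ss[2:-1] == "H") & (ss[3:] == "H")
        delta = np.angle(np.exp(1j * (dih[helical] - p.helix_dihedral)))
        e_knowledge = p.dihedral_k * float(np.sum(delta ** 2))
    return float(e_bond + e_angle + e_rep), float(e_knowledge)


def _interchain_repulsion(xa: np.ndarray, xb: np.ndarray, p: CGParams) -> float:
    d2 = cdist(xa, xb, "sqeuclidean").ravel()
    close = d2 < p.repulsion_onset**2
    return p.repulsion_k * float(
        np.sum((p.repulsion_onset - np.sqrt(d2[close])) ** 2))


def cg_energy(
    model: Structure,
    ss: dict[int, str] | None = None,
    params: CGParams | None = None,
) -> tuple[float, float]:
    """Physics/knowledge stand-in energies of a (multi-chain) Cα model.

    ``ss`` maps residue number -> label in {H, E, T, C}; without it the
    helix-bias (knowledge) term is skipped.
    """
    p = params or CGParams()
    e_phys, e_know = 0.0, 0.0
    coords = {}
    for ch in model.chains:
        x = model.ca_coords([ch])
        coords[ch] = x
        ss_arr = None
        if ss is not None:
            ss_arr = np.array([ss.get(r.number, "C") for r in model.residues[ch]])
        ep, ek = _chain_cg_terms(x, ss_arr, p)
        e_phys += ep
        e_know += ek
    labels = model.chains
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            e_phys += _interchain_repulsion(coords[labels[i]], coords[labels[j]], p)
    return e_phys, e_know


def total_score(
    model: Structure,
    restraints: list[DistanceRestraint],
    weights: ScoreWeights | None = None,
    ss: dict[int, str] | None = None,
    params: CGParams | None = None,
) -> ScoreBreakdown:
    """Reference total score of a pentamer model (lower is better)."""
    weights = weights or ScoreWeights()
    params = params or CGParams()
    s_phys, s_know = cg_energy(model, ss, params)
    re = restraint_energy(model, restraints, params)
    return weights.combine(s_phys, s_know, re["DEER"], re["PRE"], re["NOE"])


# ---------------------------------------------------------------------------
# Q-factor
# ---------------------------------------------------------------------------

def q_factor(pairs: list[tuple[float, float]]) -> float:
    """Normalized RMS discrepancy between experimental and calculated distances.

    Q = sqrt( sum_i (r_exp_i - r_calc_i)^2 / sum_i r_exp_i^2 ).
    """
    if len(pairs) == 0:
        raise ValueError("empty restraint list")
    arr = np.asarray(pairs, dtype=float)
    denom = float(np.sum(arr[:, 0] ** 2))
    if denom == 0:
        raise ValueError("all experimental distances are zero")
    num = float(np.sum((arr[:, 0] - arr[:, 1]) ** 2))
    return math.sqrt(num / denom)


# ---------------------------------------------------------------------------
# Fast exact-C5 scorer (array path used by the sampler)
# ---------------------------------------------------------------------------

try:  # compiled kernel: same maths as the numpy path, checked by parity tests
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


@_njit(cache=True, fastmath=False)
def _c5_energy_kernel(x, helix_win, rots, trans,
                      ia, ib, la, lb, rel, pot, kind, d0, lo, hi, w,
                      bond_target, bond_k, angle_min, angle_max, angle_k,
                      helix_dihedral, dihedral_k, rep_onset, rep_k,
                      sig_m, k_guide):
    n = x.shape[0]
    # --- label proxy sites (outward bisector, 5 Å arm) ---
    lab = np.empty((n, 3))
    for i in range(1, n - 1):
        vx = 2.0 * x[i, 0] - x[i - 1, 0] - x[i + 1, 0]
        vy = 2.0 * x[i, 1] - x[i - 1, 1] - x[i + 1, 1]
        vz = 2.0 * x[i, 2] - x[i - 1, 2] - x[i + 1, 2]
        nrm = (vx * vx + vy * vy + vz * vz) ** 0.5
        if nrm == 0.0:
            nrm = 1.0
        lab[i, 0] = x[i, 0] + 5.0 * vx / nrm
        lab[i, 1] = x[i, 1] + 5.0 * vy / nrm
        lab[i, 2] = x[i, 2] + 5.0 * vz / nrm

    # --- bonds & angles ---
    e_phys = 0.0
    for i in range(n - 1):
        dx = x[i + 1, 0] - x[i, 0]
        dy = x[i + 1, 1] - x[i, 1]
        dz = x[i + 1, 2] - x[i, 2]
        b = (dx * dx + dy * dy + dz * dz) ** 0.5
        e_phys += bond_k * (b - bond_target) ** 2
    for i in range(1, n - 1):
        ax = x[i - 1, 0] - x[i, 0]
        ay = x[i - 1, 1] - x[i, 1]
        az = x[i - 1, 2] - x[i, 2]
        bx = x[i + 1, 0] - x[i, 0]
        by = x[i + 1, 1] - x[i, 1]
        bz = x[i + 1, 2] - x[i, 2]
        ca = ((ax * bx + ay * by + az * bz)
              / ((ax * ax + ay * ay + az * az) ** 0.5
                 * (bx * bx + by * by + bz * bz) ** 0.5))
        if ca > 1.0:
            ca = 1.0
        elif ca < -1.0:
            ca = -1.0
        ang = np.arccos(ca)
        if ang < angle_min:
            e_phys += angle_k * (angle_min - ang) ** 2
        elif ang > angle_max:
            e_phys += angle_k * (ang - angle_max) ** 2

    # --- helix dihedral bias ---
    e_know = 0.0
    for i in range(n - 3):
        if helix_win[i]:
            b0x = x[i + 1, 0] - x[i, 0]
            b0y = x[i + 1, 1] - x[i, 1]
            b0z = x[i + 1, 2] - x[i, 2]
            b1x = x[i + 2, 0] - x[i + 1, 0]
            b1y = x[i + 2, 1] - x[i + 1, 1]
            b1z = x[i + 2, 2] - x[i + 1, 2]
            b2x = x[i + 3, 0] - x[i + 2, 0]
            b2y = x[i + 3, 1] - x[i + 2, 1]
            b2z = x[i + 3, 2] - x[i + 2, 2]
            n1x = b0y * b1z - b0z * b1y
            n1y = b0z * b1x - b0x * b1z
            n1z = b0x * b1y - b0y * b1x
            n2x = b1y * b2z - b1z * b2y
            n2y = b1z * b2x - b1x * b2z
            n2z = b1x * b2y - b1y * b2x
            b1n = (b1x * b1x + b1y * b1y + b1z * b1z) ** 0.5
            m1x = (n1y * b1z - n1z * b1y) / b1n
            m1y = (n1z * b1x - n1x * b1z) / b1n
            m1z = (n1x * b1y - n1y * b1x) / b1n
            xc = n1x * n2x + n1y * n2y + n1z * n2z
            yc = m1x * n2x + m1y * n2y + m1z * n2z
            dih = np.arctan2(yc, xc)
            delta = dih - helix_dihedral
            while delta > np.pi:
                delta -= 2.0 * np.pi
            while delta < -np.pi:
                delta += 2.0 * np.pi
            e_know += dihedral_k * delta * delta

    # --- repulsion: intra (|i-j|>=2) and vs chains B, C ---
    onset2 = rep_onset * rep_onset
    for i in range(n):
        for j in range(i + 2, n):
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < onset2:
                e_phys += rep_k * (rep_onset - d2 ** 0.5) ** 2
    for c in range(2):
        R = rots[c]
        t = trans[c]
        for j in range(n):
            bx = (R[0, 0] * x[j, 0] + R[0, 1] * x[j, 1] + R[0, 2] * x[j, 2]
                  + t[0])
            by = (R[1, 0] * x[j, 0] + R[1, 1] * x[j, 1] + R[1, 2] * x[j, 2]
                  + t[1])
            bz = (R[2, 0] * x[j, 0] + R[2, 1] * x[j, 1] + R[2, 2] * x[j, 2]
                  + t[2])
            for i in range(n):
                dx = x[i, 0] - bx
                dy = x[i, 1] - by
                dz = x[i, 2] - bz
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < onset2:
                    e_phys += rep_k * (rep_onset - d2 ** 0.5) ** 2

    # --- restraints ---
    e_deer = 0.0
    e_pre = 0.0
    e_noe = 0.0
    guide = 0.0
    for r in range(ia.shape[0]):
        if la[r]:
            pax, pay, paz = lab[ia[r], 0], lab[ia[r], 1], lab[ia[r], 2]
        else:
            pax, pay, paz = x[ia[r], 0], x[ia[r], 1], x[ia[r], 2]
        if lb[r]:
            qx, qy, qz = lab[ib[r], 0], lab[ib[r], 1], lab[ib[r], 2]
        else:
            qx, qy, qz = x[ib[r], 0], x[ib[r], 1], x[ib[r], 2]
        k = rel[r]
        if k > 0:
            R = rots[k + 1]  # rels 1..4 stored at offsets 2..5
            t = trans[k + 1]
            tx = R[0, 0] * qx + R[0, 1] * qy + R[0, 2] * qz + t[0]
            ty = R[1, 0] * qx + R[1, 1] * qy + R[1, 2] * qz + t[1]
            tz = R[2, 0] * qx + R[2, 1] * qy + R[2, 2] * qz + t[2]
            qx, qy, qz = tx, ty, tz
        dx = pax - qx
        dy = pay - qy
        dz = paz - qz
        d = (dx * dx + dy * dy + dz * dz) ** 0.5
        e = 0.0
        if pot[r] == 0:  # harmonic
            e = w[r] * (d - d0[r]) ** 2
        elif pot[r] == 1:  # sigmoid (bounded) + guidance bookkeeping
            if np.isfinite(hi[r]):
                z = sig_m * (d - hi[r])
                if z > 35.0:
                    e += w[r]
                elif z > -35.0:
                    e += w[r] / (1.0 + np.exp(-z))
            if lo[r] > 0.0:
                z = -sig_m * (d - lo[r])
                if z > 35.0:
                    e += w[r]
                elif z > -35.0:
                    e += w[r] / (1.0 + np.exp(-z))
            if d < lo[r]:
                guide += (lo[r] - d) ** 2
            elif np.isfinite(hi[r]) and d > hi[r]:
                guide += (d - hi[r]) ** 2
        else:  # flat-bottom
            if d < lo[r]:
                e = w[r] * (lo[r] - d) ** 2
            elif d > hi[r]:
                e = w[r] * (d - hi[r]) ** 2
        if kind[r] == 0:
            e_deer += e
        elif kind[r] == 1:
            e_pre += e
        else:
            e_noe += e

    return e_phys, e_know, e_deer, e_pre, e_noe, 5.0 * k_guide * guide

class SymmetricScorer:
    """Compiled scorer for exact-C5 pentamers built from one subunit.

    Evaluates the same terms as :func:`total_score` but on a subunit Cα
    coordinate array; the pentamer is implied by the symmetry frame. By C5
    symmetry, the total equals 5x the unique-instance energies (intra-chain,
    adjacent-pair and diagonal-pair), which is what the reference path sums
    explicitly over chains.
    """

    _KIND_CODE = {"DEER": 0, "PRE": 1, "NOE": 2}

    def __init__(
        self,
        residue_numbers: list[int],
        restraints: list[DistanceRestraint],
        ss: dict[int, str] | None = None,
        weights: ScoreWeights | None = None,
        params: CGParams | None = None,
        frame: SymmetryFrame | None = None,
    ) -> None:
        self.weights = weights or ScoreWeights()
        self.params = params or CGParams()
        self.frame = frame or SymmetryFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        self.residue_numbers = list(residue_numbers)
        self._index = {num: i for i, num in enumerate(self.residue_numbers)}
        n = len(self.residue_numbers)
        self.ss = np.array([(ss or {}).get(num, "C") for num in self.residue_numbers])
        self._rots = [rotation_about_axis(self.frame, 2 * math.pi * k / 5) for k in range(5)]

        m = len(restraints)
        self.restraints = list(restraints)
        self._ia = np.empty(m, dtype=int)
        self._ib = np.empty(m, dtype=int)
        self._la = np.zeros(m, dtype=bool)
        self._lb = np.zeros(m, dtype=bool)
        self._rel = np.zeros(m, dtype=int)
        self._pot = np.zeros(m, dtype=int)  # 0 harmonic, 1 sigmoid, 2 flat-bottom
        self._kind = np.zeros(m, dtype=int)
        self._d0 = np.zeros(m)
        self._lo = np.zeros(m)
        self._hi = np.zeros(m)
        self._w = np.zeros(m)
        pot_code = {"harmonic": 0, "sigmoid": 1, "flat-bottom": 2}
        for i, r in enumerate(restraints):
            self._ia[i] = self._index[r.site_a[0]]
            self._ib[i] = self._index[r.site_b[0]]
            self._la[i] = r.site_a[1] == "LABEL"
            self._lb[i] = r.site_b[1] == "LABEL"
            self._rel[i] = (r.site_b[2] - r.site_a[2]) % 5
            self._pot[i] = pot_code[r.potential]
            self._kind[i] = self._KIND_CODE[r.kind]
            self._d0[i], self._lo[i], self._hi[i], self._w[i] = (
                r.d0, r.lower, r.upper, r.weight)
        label_idx = set(self._ia[self._la]) | set(self._ib[self._lb])
        if 0 in label_idx or (n - 1) in label_idx:
            raise ValueError("label on terminal residue")
        self._needs_labels = bool(label_idx)
        self._rel_masks = [(k, self._rel == k) for k in np.unique(self._rel) if k]

        # index groups per potential term, for vectorized evaluation
        harm = np.nonzero(self._pot == 0)[0]
        self._harm = (harm, self._d0[harm], self._w[harm])
        sig = self._pot == 1
        up = np.nonzero(sig & np.isfinite(self._hi))[0]
        lo = np.nonzero(sig & (self._lo > 0))[0]
        self._sig_up = (up, self._hi[up], self._w[up])
        self._sig_lo = (lo, self._lo[lo], self._w[lo])
        sig_all = np.nonzero(sig)[0]
        self._sig_all = (sig_all, self._lo[sig_all],
                         np.where(np.isfinite(self._hi[sig_all]),
                                  self._hi[sig_all], np.inf))
        flat = np.nonzero(self._pot == 2)[0]
        self._flat = (flat, self._lo[flat], self._hi[flat], self._w[flat])

        # packed arrays for the compiled kernel
        s = self.ss
        self._helix_win = np.zeros(max(n - 3, 0), dtype=np.bool_)
        if n >= 4:
            self._helix_win = ((s[:-3] == "H") & (s[1:-2] == "H")
                               & (s[2:-1] == "H") & (s[3:] == "H"))
        rot_stack, trans_stack = [], []
        for k in (1, 2, 1, 2, 3, 4):  # B, C repulsion; rel 1..4 restraints
            R, t = self._rots[k]
            rot_stack.append(R)
            trans_stack.append(t)
        self._rot_stack = np.ascontiguousarray(np.stack(rot_stack))
        self._trans_stack = np.ascontiguousarray(np.stack(trans_stack))

    # -- geometry helpers ------------------------------------------------
    def _rotate(self, x: np.ndarray, k: int) -> np.ndarray:
        R, t = self._rots[k % 5]
        return x @ R.T + t

    def restraint_distances(self, x: np.ndarray) -> np.ndarray:
        """Per-restraint distances on the implied pentamer (one instance each)."""
        if self._needs_labels:
            lab = x + LABEL_ARM_LENGTH * pseudo_label_offsets(x)
        pa = x[self._ia].copy()
        pb = x[self._ib].copy()
        if self._needs_labels:
            pa[self._la] = lab[self._ia[self._la]]
            pb[self._lb] = lab[self._ib[self._lb]]
        for k, mask in self._rel_masks:
            R, t = self._rots[k]
            pb[mask] = pb[mask] @ R.T + t
        diff = pa - pb
        return np.sqrt(np.einsum("ij,ij->i", diff, diff))

    def restraint_energies(self, x: np.ndarray) -> np.ndarray:
        return self._energies_from_distances(self.restraint_distances(x))

    def _energies_from_distances(self, d: np.ndarray) -> np.ndarray:
        e = np.zeros_like(d)
        idx, d0, w = self._harm
        if len(idx):
            e[idx] = w * (d[idx] - d0) ** 2
        m = self.params.sigmoid_steepness
        idx, hi, w = self._sig_up
        if len(idx):
            e[idx] += w * expit(m * (d[idx] - hi))
        idx, lo, w = self._sig_lo
        if len(idx):
            e[idx] += w * expit(-m * (d[idx] - lo))
        idx, lo, hi, w = self._flat
        if len(idx):
            df = d[idx]
            viol = np.where(df < lo, lo - df, np.where(df > hi, df - hi, 0.0))
            e[idx] = w * viol ** 2
        return e

    def _guidance_from_distances(self, d: np.ndarray, k_guide: float) -> float:
        """Sampling-time quadratic pull on violated bounded restraints.

        The sigmoid restraint potential is bounded, so far from its bounds it
        offers no gradient for the sampler to follow. This auxiliary term —
        a weak harmonic on the bound violation of every sigmoid restraint —
        restores a long-range funnel. It enters Monte Carlo acceptance only;
        ranking and all reported scores use :meth:`score`.
        """
        idx, lo, hi = self._sig_all
        if not len(idx):
            return 0.0
        ds = d[idx]
        viol = np.where(ds < lo, lo - ds, np.where(ds > hi, ds - hi, 0.0))
        return 5.0 * k_guide * float(np.sum(viol * viol))

    # -- scoring ---------------------------------------------------------
    def score(self, x: np.ndarray) -> ScoreBreakdown:
        return self.score_with_guidance(x, 0.0)[0]

    def score_with_guidance(
        self, x: np.ndarray, k_guide: float = 0.02
    ) -> tuple[ScoreBreakdown, float]:
        """(spec-form score, spec total + guidance term), one geometry pass."""
        if _HAVE_NUMBA:
            p = self.params
            e_phys, e_know, e_deer, e_pre, e_noe, guide = _c5_energy_kernel(
                np.ascontiguousarray(x), self._helix_win,
                self._rot_stack, self._trans_stack,
                self._ia, self._ib, self._la, self._lb, self._rel,
                self._pot, self._kind, self._d0, self._lo, self._hi, self._w,
                p.bond_target, p.bond_k, p.angle_min, p.angle_max, p.angle_k,
                p.helix_dihedral, p.dihedral_k, p.repulsion_onset,
                p.repulsion_k, p.sigmoid_steepness, k_guide,
            )
            breakdown = self.weights.combine(
                5.0 * e_phys, 5.0 * e_know, 5.0 * e_deer, 5.0 * e_pre,
                5.0 * e_noe)
            return breakdown, breakdown.s_total + guide
        return self._score_with_guidance_numpy(x, k_guide)

    def _score_with_guidance_numpy(
        self, x: np.ndarray, k_guide: float = 0.02
    ) -> tuple[ScoreBreakdown, float]:
        """Pure-numpy evaluation; the compiled kernel must match it exactly."""
        p = self.params
        e_phys, e_know = _chain_cg_terms(x, self.ss, p)
        e_phys += _interchain_repulsion(x, self._rotate(x, 1), p)
        e_phys += _interchain_repulsion(x, self._rotate(x, 2), p)

        e_class = np.zeros(3)
        guide = 0.0
        if len(self._kind):
            d = self.restraint_distances(x)
            e_class = np.bincount(self._kind,
                                  weights=self._energies_from_distances(d),
                                  minlength=3)
            if k_guide > 0:
                guide = self._guidance_from_distances(d, k_guide)
        breakdown = self.weights.combine(
            5.0 * e_phys, 5.0 * e_know,
            5.0 * e_class[0], 5.0 * e_class[1], 5.0 * e_class[2],
        )
        return breakdown, breakdown.s_total + guide
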