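"""DEER inter-subunit distance distributions -> symmetric pentamer restraints.

A single spin label per subunit of a C5 ring produces exactly two unique
inter-label distances: adjacent (chain offset 1) and diagonal (chain offset
2), in the fixed pentagon ratio d_diag/d_adj = 2*cos(36°) ≈ 1.618. The
bimodal experimental distribution is decomposed accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import lmfit
import numpy as np
from scipy.signal import find_peaks

from .nmr_restraints import DistanceRestraint

__all__ = [
    "PENTAGON_RATIO",
    "DeerDistribution",
    "DeerModes",
    "DeerRestraint",
    "load_distribution",
    "write_distribution",
    "split_pentamer_modes",
    "to_restraints",
    "deer_to_distance_restraints",
]

#: d_diagonal / d_adjacent for one site per subunit of a regular pentagon.
PENTAGON_RATIO = 2.0 * math.cos(math.pi / 5.0)  # = golden ratio 1.618...


@dataclass
class DeerDistribution:
    """A normalized distance distribution P(r) on a uniform grid (Å)."""

    r_grid: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r_grid.ndim != 1 or self.r_grid.shape != self.p.shape:
            raise ValueError("grid/density shape mismatch")
        steps = np.diff(self.r_grid)
        if np.any(steps <= 0):
            raise ValueError("r grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("r grid must be uniform")

    @property
    def step(self) -> float:
        return float(self.r_grid[1] - self.r_grid[0])


@dataclass
class DeerModes:
    adjacent: tuple[float, float]  # (d0, width) Å
    diagonal: tuple[float, float]
    diagonal_inferred: bool = False


@dataclass
class DeerRestraint:
    label_residue: int
    geometry: str  # adjacent | diagonal
    d0: float
    width: float
    weight: float

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.width <= 0:
            raise ValueError("d0 and width must be positive")
        if self.geometry not in ("adjacent", "diagonal"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def load_distribution(path: str | Path, n_grid: int | None = None) -> DeerDistribution:
    """Load a two-column P(r) text file, resample to a uniform grid, normalize."""
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        raise ValueError(f"empty distribution file: {path}")
    if data.shape[1] < 2:
        raise ValueError(f"expected two columns in {path}")
    r, p = data[:, 0], data[:, 1]
    if np.any(np.diff(r) <= 0):
        raise ValueError("non-monotone distance grid")
    if np.any(p < -1e-9):
        raise ValueError("negative densities in distribution")
    p = np.clip(p, 0.0, None)
    steps = np.diff(r)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        n = n_grid or len(r)
        r_u = np.linspace(r[0], r[-1], n)
        p = np.interp(r_u, r, p)
        r = r_u
    area = np.trapezoid(p, r)
    if area <= 0:
        raise ValueError("distribution integrates to zero")
    return DeerDistribution(r_grid=r, p=p / area)


def write_distribution(dist: DeerDistribution, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([dist.r_grid, dist.p]), fmt="%.6f")


def _two_gaussian(r, a1, mu1, s1, a2, mu2, s2):
    g1 = a1 * np.exp(-0.5 * ((r - mu1) / s1) ** 2)
    g2 = a2 * np.exp(-0.5 * ((r - mu2) / s2) ** 2)
    return g1 + g2


def split_pentamer_modes(dist: DeerDistribution) -> DeerModes:
    """Decompose a pentamer DEER distribution into adjacent/diagonal modes.

    Fits a two-Gaussian mixture initialized with the pentagon constraint
    d_diag = 2*cos(36°)*d_adj. If only one mode is resolvable, it is assigned
    to the adjacent geometry and the diagonal is inferred from the ratio
    (``diagonal_inferred=True``); the inferred width scales with the ratio.
    """
    r, p = dist.r_grid, dist.p
    prominence = 0.05 * p.max()
    peaks, _ = find_peaks(p, prominence=prominence)
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(p))])

    if len(peaks) >= 2:
        # two most prominent candidate modes, in increasing r
        heights = p[peaks]
        top2 = peaks[np.argsort(heights)[-2:]]
        mu1_init, mu2_init = sorted(r[top2])
    else:
        mu1_init = float(r[peaks[0]])
        mu2_init = mu1_init * PENTAGON_RATIO
        if mu2_init > r[-1]:  # lone mode near grid end: treat as adjacent anyway
            mu2_init = r[-1]

    sigma0 = max(2.0, 2.0 * dist.step)
    model = lmfit.Model(_two_gaussian)
    params = model.make_params(
        a1=float(p.max()), mu1=mu1_init, s1=sigma0,
        a2=float(p.max()) / 2.0, mu2=mu2_init, s2=sigma0 * 1.2,
    )
    for name in ("a1", "a2"):
        params[name].min = 0.0
    for name in ("s1", "s2"):
        params[name].min = 0.25 * dist.step
    params["mu1"].min, params["mu1"].max = r[0], r[-1]
    params["mu2"].min, params["mu2"].max = r[0], r[-1] * 1.2

    result = model.fit(p, params, r=r)
    if not result.success:
        raise RuntimeError("two-Gaussian DEER mode fit did not converge")
    v = result.params.valuesdict()
    modes = sorted(
        [(v["mu1"], v["s1"], v["a1"]), (v["mu2"], v["s2"], v["a2"])]
    )
    (mu_a, s_a, amp_a), (mu_d, s_d, amp_d) = modes

    # A vanishing or degenerate second component means only one resolvable
    # mode: infer the diagonal from pentagon geometry.
    area_a = amp_a * s_a
    area_d = amp_d * s_d
    separated = abs(mu_d - mu_a) > 2.0 * max(s_a, s_d)
    if area_d < 0.05 * area_a or not separated:
        mu, s = (mu_a, s_a) if area_a >= area_d else (mu_d, s_d)
        return DeerModes(
            adjacent=(float(mu), float(s)),
            diagonal=(float(mu * PENTAGON_RATIO), float(s * PENTAGON_RATIO)),
            diagonal_inferred=True,
        )
    return DeerModes(
        adjacent=(float(mu_a), float(s_a)),
        diagonal=(float(mu_d), float(s_d)),
        diagonal_inferred=False,
    )


def to_restraints(modes: DeerModes, label_residue: int) -> list[DeerRestraint]:
    """One adjacent and one diagonal harmonic restraint; weight ∝ 1/width²."""
    out = []
    for geometry, (d0, width) in (("adjacent", modes.adjacent),
                                  ("diagonal", modes.diagonal)):
        out.append(DeerRestraint(
            label_residue=label_residue, geometry=geometry,
            d0=d0, width=width, weight=1.0 / (width * width),
        ))
    return out


def deer_to_distance_restraints(restraints: list[DeerRestraint]) -> list[DistanceRestraint]:
    """Express DEER mode restraints as generic site-pair distance restraints.

    Sites use the pseudo spin-label tag ``"LABEL"``; the chain offset encodes
    the geometry (1 adjacent, 2 diagonal).
    """
    offset = {"adjacent": 1, "diagonal": 2}
    return [
        DistanceRestraint(
            site_a=(r.label_residue, "LABEL", 0),
            site_b=(r.label_residue, "LABEL", offset[r.geometry]),
            d0=r.d0, lower=max(r.d0 - 3.0 * r.width, 0.0),
            upper=r.d0 + 3.0 * r.width,
            kind="DEER", weight=r.weight, potential="harmonic",
        )
        for r in restraints
    ]
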