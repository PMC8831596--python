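"""Conversion of raw NMR observables into restraints and dynamics parameters.

Covers paramagnetic relaxation enhancement (PRE) distances via the
Solomon–Bloembergen relation, residual dipolar couplings from IPAP splittings,
amide-proton temperature coefficients (hydrogen-bond flags), exponential
relaxation-rate fits (R1/R2) and heteronuclear NOE ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import linregress

logger = logging.getLogger(__name__)

__all__ = [
    "PeakRecord",
    "PREParams",
    "DistanceRestraint",
    "RelaxationSeries",
    "RelaxationResult",
    "HetNoeResult",
    "TempCoeffResult",
    "RDCRecord",
    "fit_relaxation_rate",
    "compute_hetnoe",
    "temperature_coefficient",
    "r2sp_from_ratio",
    "pre_distance",
    "r2sp_from_distance",
    "ratio_from_r2sp",
    "pre_table_to_restraints",
    "rdc_from_ipap",
    "noes_to_restraints",
    "read_peak_table",
    "write_restraints",
    "read_restraints",
    "N15_GYROMAGNETIC_RATIO_REL",
]

# |gamma(15N)| / gamma(1H); converts a proton field in MHz to the 15N
# resonance frequency in MHz.
N15_GYROMAGNETIC_RATIO_REL = 0.10136767


@dataclass
class PeakRecord:
    """One residue's peak under a named condition."""

    residue: int
    condition: str  # paramagnetic|diamagnetic|saturated|unsaturated|temperature:T|inphase|antiphase
    intensity: float
    linewidth: float | None = None  # Hz
    shift_h: float | None = None  # ppm
    shift_n: float | None = None  # ppm
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.linewidth is not None and self.linewidth <= 0:
            raise ValueError("linewidth must be positive when present")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PREParams:
    """Parameters of the nitroxide Solomon–Bloembergen distance conversion.

    ``k_sb`` is the nitroxide constant in cm^6 s^-2, ``tau_c`` the rotational
    correlation time in s, ``omega_h`` the proton Larmor frequency in rad/s
    and ``t_evol`` the transverse evolution period of the experiment in s.
    Ratio bounds and distance bounds control how intensity ratios map to
    bounded restraints. The default ``tau_c``/``t_evol`` pair is calibrated
    so that, at a 20 Hz diamagnetic linewidth, the ratio ceiling (0.85) and
    floor (0.10) cross over exactly at the distance bounds (23 and 12 Å):
    bound-type restraints are then consistent with the two-sided conversion.
    """

    tau_c: float = 33.23e-9
    omega_h: float = 2 * math.pi * 700e6
    k_sb: float = 1.23e-32
    t_evol: float = 52.83e-6
    ratio_floor: float = 0.10
    ratio_ceiling: float = 0.85
    r_min_bound: float = 12.0
    r_max_bound: float = 23.0
    tolerance: float = 4.0  # ± band of two-sided PRE restraints, Å

    def __post_init__(self) -> None:
        if not (0 < self.ratio_floor < self.ratio_ceiling < 1):
            raise ValueError("require 0 < ratio_floor < ratio_ceiling < 1")
        if self.tau_c <= 0 or self.t_evol <= 0:
            raise ValueError("tau_c and t_evol must be positive")

    def spectral_factor(self) -> float:
        """4*tau_c + 3*tau_c/(1 + (omega_h*tau_c)^2), in s."""
        wt = self.omega_h * self.tau_c
        return 4.0 * self.tau_c + 3.0 * self.tau_c / (1.0 + wt * wt)


@dataclass
class DistanceRestraint:
    """A site-pair distance restraint.

    Sites are ``(residue, atom, chain_offset)`` with offset 0 for
    intra-subunit pairs and 1/2 for adjacent/diagonal subunits of a pentamer.
    ``atom`` may be the pseudo-site tag ``"LABEL"`` for a spin-label proxy.
    """

    site_a: tuple[int, str, int]
    site_b: tuple[int, str, int]
    d0: float
    lower: float
    upper: float
    kind: str  # NOE | PRE | DEER
    weight: float = 1.0
    potential: str = "harmonic"  # harmonic | sigmoid | flat-bottom

    def __post_init__(self) -> None:
        if not (self.lower <= self.d0 <= self.upper):
            raise ValueError(
                f"restraint bounds violated: {self.lower} <= {self.d0} <= {self.upper}"
            )
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def two_sided(self) -> bool:
        return np.isfinite(self.upper) and self.lower > 0

    @property
    def has_target(self) -> bool:
        """Whether d0 is a measured target distance (vs a mere bound band).

        Harmonic restraints and two-sided sigmoid restraints carry a
        measured distance; flat-bottom (NOE-class) and single-bound
        restraints only constrain a range.
        """
        if self.potential == "harmonic":
            return True
        return self.potential == "sigmoid" and self.two_sided


@dataclass
class RelaxationSeries:
    residue: int
    delays: np.ndarray  # s
    intensities: np.ndarray
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.delays) < 4:
            raise ValueError("need >= 4 delay points")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if len(self.delays) != len(self.intensities):
            raise ValueError("delay/intensity length mismatch")


@dataclass
class RelaxationResult:
    residue: int
    rate: float  # s^-1
    rate_sigma: float
    amplitude: float
    converged: bool = True


@dataclass
class HetNoeResult:
    residue: int
    noe: float
    sigma: float


@dataclass
class TempCoeffResult:
    residue: int
    coefficient: float  # ppb/K
    hbond_flag: bool


@dataclass
class RDCRecord:
    residue: int
    d_hz: float
    sigma_hz: float = 0.0


# ---------------------------------------------------------------------------
# Relaxation & dynamics
# ---------------------------------------------------------------------------

def fit_relaxation_rate(series: RelaxationSeries) -> RelaxationResult:
    """Fit I(tau) = A*exp(-R*tau) by nonlinear least squares.

    The initializer comes from a log-linear fit so the result is
    deterministic. Degenerate data (constant intensities, non-convergence)
    yields ``converged=False`` rather than a silent default.
    """
    tau, I = series.delays, series.intensities
    if np.ptp(I) == 0:
        return RelaxationResult(series.residue, math.nan, math.nan, math.nan, False)
    # log-linear initializer on the positive part of the decay
    pos = I > 0
    if pos.sum() >= 2:
        slope, intercept, *_ = linregress(tau[pos], np.log(I[pos]))
        r0, a0 = max(-slope, 1e-6), math.exp(intercept)
    else:
        r0, a0 = 1.0, float(abs(I[0]))

    model = lmfit.Model(lambda t, amplitude, rate: amplitude * np.exp(-rate * t))
    params = model.make_params(amplitude=a0, rate=r0)
    params["rate"].min = 0.0
    try:
        res = model.fit(I, params, t=tau)
    except Exception:  # lmfit raises on pathological inputs
        return RelaxationResult(series.residue, math.nan, math.nan, math.nan, False)
    if not res.success or res.params["rate"].value <= 0:
        return RelaxationResult(series.residue, math.nan, math.nan, math.nan, False)
    rate = float(res.params["rate"].value)
    sigma = res.params["rate"].stderr
    return RelaxationResult(
        residue=series.residue,
        rate=rate,
        rate_sigma=float(sigma) if sigma is not None else math.nan,
        amplitude=float(res.params["amplitude"].value),
        converged=True,
    )


def compute_hetnoe(sat: PeakRecord, unsat: PeakRecord) -> HetNoeResult:
    """Heteronuclear NOE = I_sat / I_unsat, with propagated uncertainty."""
    if unsat.intensity == 0:
        raise ValueError("unsaturated intensity is zero")
    noe = sat.intensity / unsat.intensity
    if sat.intensity != 0:
        sigma = abs(noe) * math.sqrt(
            (sat.noise_sigma / sat.intensity) ** 2
            + (unsat.noise_sigma / unsat.intensity) ** 2
        )
    else:
        sigma = abs(sat.noise_sigma / unsat.intensity)
    return HetNoeResult(residue=sat.residue, noe=noe, sigma=sigma)


def temperature_coefficient(
    series: list[tuple[float, PeakRecord]] | list[PeakRecord],
    threshold: float = 4.5,
) -> TempCoeffResult:
    """Amide-proton temperature coefficient (ppb/K) and hydrogen-bond flag.

    Accepts ``(temperature_K, PeakRecord)`` pairs or PeakRecords whose
    condition is ``"temperature:<T>"``. Residues whose coefficient magnitude
    is below ``threshold`` (default 4.5 ppb/K) are flagged as hydrogen-bonded.
    """
    temps, shifts, residue = [], [], None
    for item in series:
        if isinstance(item, PeakRecord):
            rec = item
            if not rec.condition.startswith("temperature:"):
                raise ValueError("PeakRecord condition must be 'temperature:<T>'")
            t = float(rec.condition.split(":", 1)[1])
        else:
            t, rec = item
        if rec.shift_h is None:
            raise ValueError("shift_h required for temperature coefficients")
        temps.append(float(t))
        shifts.append(rec.shift_h * 1000.0)  # ppm -> ppb
        residue = rec.residue
    temps_arr = np.asarray(temps)
    if len(temps_arr) < 3 or np.ptp(temps_arr) < 10.0:
        raise ValueError("need >= 3 temperatures spanning >= 10 K")
    slope = linregress(temps_arr, np.asarray(shifts)).slope
    return TempCoeffResult(
        residue=residue,
        coefficient=float(slope),
        hbond_flag=bool(abs(slope) < threshold),
    )


# ---------------------------------------------------------------------------
# PRE
# ---------------------------------------------------------------------------

def ratio_from_r2sp(r2sp: float, linewidth_dia: float, t_evol: float) -> float:
    """Forward two-condition intensity model I/I0 for a given R2sp."""
    r2dia = math.pi * linewidth_dia
    return r2dia * math.exp(-r2sp * t_evol) / (r2dia + r2sp)


def r2sp_from_ratio(ratio: float, linewidth_dia: float, t_evol: float) -> float:
    """Invert the intensity-ratio model for the paramagnetic rate R2sp.

    Solves ``ratio = R2dia*exp(-R2sp*t)/(R2dia+R2sp)`` with
    ``R2dia = pi * linewidth``, by bracketed root finding; the map is a
    bijection (0, 1] -> [0, inf) so the solution is unique.
    """
    if linewidth_dia <= 0:
        raise ValueError("diamagnetic linewidth must be positive")
    if ratio > 1.0:
        raise ValueError(f"intensity ratio {ratio} > 1 is unphysical")
    if ratio <= 0.0:
        raise ValueError("nonpositive ratio: peak vanished (assign upper bound)")
    if ratio == 1.0:
        return 0.0
    hi = 1.0
    while ratio_from_r2sp(hi, linewidth_dia, t_evol) > ratio:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid inputs
            raise RuntimeError("bracketing failed")
    f = lambda r: ratio_from_r2sp(r, linewidth_dia, t_evol) - ratio
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


def pre_distance(r2sp: float, p: PREParams) -> float:
    """Solomon–Bloembergen distance (Å) from a paramagnetic rate.

    r = [ (K/R2sp) * (4*tau_c + 3*tau_c/(1+(omega_h*tau_c)^2)) ]^(1/6),
    converted from cm to Å. Strictly decreasing in R2sp.
    """
    if r2sp <= 0:
        raise ValueError("r2sp must be positive")
    r_cm6 = (p.k_sb / r2sp) * p.spectral_factor()
    return float(r_cm6 ** (1.0 / 6.0) * 1e8)


def r2sp_from_distance(r: float, p: PREParams) -> float:
    """Inverse of :func:`pre_distance` (r in Å)."""
    if r <= 0:
        raise ValueError("distance must be positive")
    return float(p.k_sb * p.spectral_factor() / (r * 1e-8) ** 6)


def pre_table_to_restraints(
    table: list[tuple[PeakRecord, PeakRecord]],
    label_site: tuple[int, str, int],
    p: PREParams | None = None,
    observed_offset: int = 0,
) -> list[DistanceRestraint]:
    """Convert paired paramagnetic/diamagnetic peaks into PRE restraints.

    Ratio >= ceiling: lower-bound-only restraint at ``r_max_bound`` (no
    measurable broadening). Ratio <= floor: upper-bound-only at
    ``r_min_bound`` (peak vanished). Otherwise a two-sided restraint centred
    on the Solomon–Bloembergen distance with a ±tolerance band. Unmatched
    pairs are skipped with a log entry.

    ``observed_offset`` is the subunit offset of the observed amides relative
    to the labelled chain: 0 for conventional intra-subunit PRE, 1 for the
    mixed-labelling inter-subunit (quaternary) experiment.
    """
    p = p or PREParams()
    out: list[DistanceRestraint] = []
    for para, dia in table:
        if para.residue != dia.residue:
            logger.warning(
                "unmatched PRE pair (residues %s/%s): skipped", para.residue, dia.residue
            )
            continue
        if dia.intensity <= 0:
            logger.warning("nonpositive diamagnetic intensity for residue %s: skipped",
                           para.residue)
            continue
        site_b = (para.residue, "H", observed_offset)
        ratio = para.intensity / dia.intensity
        if ratio >= p.ratio_ceiling:
            out.append(DistanceRestraint(
                site_a=label_site, site_b=site_b,
                d0=p.r_max_bound, lower=p.r_max_bound, upper=math.inf,
                kind="PRE", potential="sigmoid",
            ))
        elif ratio <= p.ratio_floor:
            out.append(DistanceRestraint(
                site_a=label_site, site_b=site_b,
                d0=p.r_min_bound, lower=0.0, upper=p.r_min_bound,
                kind="PRE", potential="sigmoid",
            ))
        else:
            lw = dia.linewidth if dia.linewidth is not None else 20.0
            r2sp = r2sp_from_ratio(ratio, lw, p.t_evol)
            d0 = pre_distance(r2sp, p)
            out.append(DistanceRestraint(
                site_a=label_site, site_b=site_b,
                d0=d0, lower=max(d0 - p.tolerance, 0.0), upper=d0 + p.tolerance,
                kind="PRE", potential="sigmoid",
            ))
    return out


# ---------------------------------------------------------------------------
# RDC
# ---------------------------------------------------------------------------

def rdc_from_ipap(
    para_inphase: PeakRecord,
    para_antiphase: PeakRecord,
    dia_inphase: PeakRecord,
    dia_antiphase: PeakRecord,
    field_mhz: float = 700.0,
) -> RDCRecord:
    """RDC from the 15N splitting difference between aligned and isotropic spectra.

    The splitting under each condition is the |in-phase − anti-phase| 15N
    shift difference converted ppm -> Hz at the 15N frequency of the given
    proton field; the RDC is the paramagnetic minus diamagnetic splitting.
    """
    quartet = (para_inphase, para_antiphase, dia_inphase, dia_antiphase)
    residues = {rec.residue for rec in quartet}
    if len(residues) != 1:
        raise ValueError("IPAP quartet spans multiple residues")
    for rec in quartet:
        if rec.shift_n is None:
            raise ValueError("missing 15N shift in IPAP quartet")
    n_freq = field_mhz * N15_GYROMAGNETIC_RATIO_REL  # MHz; 1 ppm == n_freq Hz
    split_para = abs(para_inphase.shift_n - para_antiphase.shift_n) * n_freq
    split_dia = abs(dia_inphase.shift_n - dia_antiphase.shift_n) * n_freq
    return RDCRecord(residue=para_inphase.residue, d_hz=split_para - split_dia)


# ---------------------------------------------------------------------------
# NOE
# ---------------------------------------------------------------------------

NOE_CLASS_BOUNDS: dict[str, float] = {"strong": 3.5, "medium": 4.5, "weak": 6.0}
NOE_LOWER_BOUND = 1.8


def noes_to_restraints(
    noe_peaks: list[tuple[int, int, str]],
    class_bounds: dict[str, float] | None = None,
    atom: str = "CA",
) -> list[DistanceRestraint]:
    """Flat-bottom restraints from classified NOE cross peaks."""
    bounds = class_bounds or NOE_CLASS_BOUNDS
    out = []
    for res_i, res_j, klass in noe_peaks:
        if klass not in bounds:
            raise ValueError(f"unknown NOE class {klass!r}")
        upper = bounds[klass]
        out.append(DistanceRestraint(
            site_a=(res_i, atom, 0), site_b=(res_j, atom, 0),
            d0=0.5 * (NOE_LOWER_BOUND + upper),
            lower=NOE_LOWER_BOUND, upper=upper,
            kind="NOE", potential="flat-bottom",
        ))
    return out


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

PEAK_COLUMNS = ["residue", "condition", "intensity", "linewidth_hz",
                "shift_h_ppm", "shift_n_ppm", "noise"]


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Read a TSV peak table (columns: residue, condition, intensity,
    linewidth_hz, shift_h_ppm, shift_n_ppm, noise)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        records.append(PeakRecord(
            residue=int(row.residue),
            condition=str(row.condition),
            intensity=float(row.intensity),
            linewidth=None if pd.isna(row.linewidth_hz) else float(row.linewidth_hz),
            shift_h=None if pd.isna(row.shift_h_ppm) else float(row.shift_h_ppm),
            shift_n=None if pd.isna(row.shift_n_ppm) else float(row.shift_n_ppm),
            noise_sigma=float(row.noise) if not pd.isna(row.noise) else 0.0,
        ))
    return records


def peaks_to_frame(records: list[PeakRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "residue": r.residue,
                "condition": r.condition,
                "intensity": r.intensity,
                "linewidth_hz": r.linewidth,
                "shift_h_ppm": r.shift_h,
                "shift_n_ppm": r.shift_n,
                "noise": r.noise_sigma,
            }
            for r in records
        ],
        columns=PEAK_COLUMNS,
    )


RESTRAINT_COLUMNS = ["residue_a", "atom_a", "offset_a", "residue_b", "atom_b",
                     "offset_b", "d0", "lower", "upper", "kind", "weight",
                     "potential"]


def write_restraints(restraints: list[DistanceRestraint], path: str | Path) -> None:
    rows = [
        {
            "residue_a": r.site_a[0], "atom_a": r.site_a[1], "offset_a": r.site_a[2],
            "residue_b": r.site_b[0], "atom_b": r.site_b[1], "offset_b": r.site_b[2],
            "d0": r.d0, "lower": r.lower, "upper": r.upper,
            "kind": r.kind, "weight": r.weight, "potential": r.potential,
        }
        for r in restraints
    ]
    pd.DataFrame(rows, columns=RESTRAINT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_restraints(path: str | Path) -> list[DistanceRestraint]:
    df = pd.read_csv(path, sep="\t")
    return [
        DistanceRestraint(
            site_a=(int(row.residue_a), str(row.atom_a), int(row.offset_a)),
            site_b=(int(row.residue_b), str(row.atom_b), int(row.offset_b)),
            d0=float(row.d0), lower=float(row.lower), upper=float(row.upper),
            kind=str(row.kind), weight=float(row.weight),
            potential=str(row.potential),
        )
        for row in df.itertuples(index=False)
    ]
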