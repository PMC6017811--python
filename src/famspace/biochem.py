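"""Biochemical calculations: Hill-equation binding fits, coupled-assay
ATPase turnover, and size-exclusion assembly fractions.

The Hill model describes the binding signal of a labelled species titrated
with its partner at concentration S:

    y(S) = U + (B - U) * S**h / (Kd**h + S**h)

with U the unbound-state signal, B the bound-state signal, Kd the
dissociation constant (signal midpoint) and h the Hill coefficient.
ATPase turnover is obtained from the NADH-coupled regeneration assay via
the NADH extinction coefficient at 340 nm (6.22 mM^-1 cm^-1); the
assembled (ring) fraction of an oligomerising ATPase is the hexamer plus
dodecamer share of the total integrated peak area in a size-exclusion
trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

#: NADH extinction coefficient at 340 nm, mM^-1 cm^-1.
NADH_EXTINCTION_MM_CM = 6.22

#: Cpa protomer mass in kDa and the ring stoichiometry.
PROTOMER_MASS_KDA = 75.0
HEXAMER_SUBUNITS = 6

ASSEMBLED_SPECIES = ("hexamer", "dodecamer")
ALL_SPECIES = ("monomer", "hexamer", "dodecamer")


class DegenerateDataError(ValueError):
    pass


def hexamer_mass_kda(protomer_kda: float = PROTOMER_MASS_KDA) -> float:
    """Expected mass of the hexameric ring (six protomers), kDa."""
    return HEXAMER_SUBUNITS * protomer_kda


@dataclass(frozen=True)
class BindingCurve:
    """Titration curve: concentrations S (µM, strictly increasing) vs signal."""

    S: np.ndarray
    y: np.ndarray
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if S.shape != y.shape or S.ndim != 1:
            raise ValueError("S and y must be 1-D arrays of equal length")
        if np.any(S < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(S) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.S)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with diagnostics."""

    U: float
    B: float
    Kd: float
    h: float
    residual_sum_squares: float
    converged: bool
    stderr: Mapping[str, float] = field(default_factory=dict)

    def predict(self, S) -> np.ndarray:
        return hill_predict((self.U, self.B, self.Kd, self.h), S)


def hill_predict(params: Sequence[float], S) -> np.ndarray:
    """Evaluate the Hill equation; y(0) = U exactly, y(Kd) = (U+B)/2."""
    U, B, Kd, h = params
    if Kd <= 0 or h <= 0:
        raise ValueError(f"Kd and h must be positive (got Kd={Kd}, h={h})")
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        frac = np.where(S > 0, S**h / (Kd**h + S**h), 0.0)
    return U + (B - U) * frac


def _auto_init(curve: BindingCurve) -> tuple[float, float, float, float]:
    U0 = float(curve.y[0])  # signal at the lowest concentration
    B0 = float(curve.y[-1])
    half = (U0 + B0) / 2.0
    Kd0 = float(curve.S[np.argmin(np.abs(curve.y - half))])
    if Kd0 <= 0:
        Kd0 = float(np.median(curve.S[curve.S > 0]))
    return U0, B0, Kd0, 1.0


def fit_hill(
    curve: BindingCurve,
    init: Sequence[float] | None = None,
    kd_max_factor: float = 100.0,
    h_max: float = 10.0,
) -> HillFit:
    """Unweighted least-squares fit of (U, B, Kd, h) to a binding curve.

    Auto-initialisation takes U from the lowest-concentration signal, B
    from the highest, Kd from the concentration nearest the half-signal
    and h = 1. Kd is bounded in (0, kd_max_factor * max(S)] and h in
    (0, h_max] — an unbounded Hill coefficient is unidentifiable on sparse
    curves. Non-convergence is reported via ``converged=False``, never
    silently.
    """
    if len(curve) < 4:
        raise ValueError(f"need >= 4 points to fit 4 parameters, got {len(curve)}")
    if np.ptp(curve.y) == 0:
        raise DegenerateDataError("signal is constant; nothing to fit")
    p0 = tuple(init) if init is not None else _auto_init(curve)
    span = np.ptp(curve.y) or 1.0
    lo = [-np.inf, -np.inf, 1e-12, 1e-6]
    hi = [np.inf, np.inf, kd_max_factor * float(curve.S.max()), h_max]
    p0 = np.clip(p0, lo, hi)

    def model(S, U, B, Kd, h):
        return hill_predict((U, B, Kd, h), S)

    try:
        popt, pcov = curve_fit(
            model, curve.S, curve.y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
        converged = True
    except RuntimeError:
        popt, pcov = np.asarray(p0, dtype=float), np.full((4, 4), np.nan)
        converged = False
    resid = curve.y - model(curve.S, *popt)
    rss = float(np.sum(resid**2))
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    names = ("U", "B", "Kd", "h")
    return HillFit(
        U=float(popt[0]),
        B=float(popt[1]),
        Kd=float(popt[2]),
        h=float(popt[3]),
        residual_sum_squares=rss,
        converged=converged,
        stderr={n: float(s) for n, s in zip(names, se)},
    )


def atpase_rate(
    slope_a340_per_min: float,
    path_cm: float,
    enzyme_conc_um: float,
) -> float:
    """ATP turnover (min^-1 per enzyme complex) from a coupled-assay slope.

    The regenerating system consumes one NADH per ATP hydrolysed, so the
    NADH depletion rate |dA340/dt| / (eps * l) in µM min^-1 equals the ATP
    hydrolysis rate; dividing by the complex concentration (µM, e.g.
    hexamer) gives the turnover number.
    """
    if path_cm <= 0:
        raise ValueError("optical path length must be positive")
    if enzyme_conc_um <= 0:
        raise ValueError("enzyme concentration must be positive")
    eps_per_um_cm = NADH_EXTINCTION_MM_CM * 1e-3  # µM^-1 cm^-1
    nadh_rate_um_min = abs(slope_a340_per_min) / (eps_per_um_cm * path_cm)
    return nadh_rate_um_min / enzyme_conc_um


@dataclass(frozen=True)
class Chromatogram:
    """A280 size-exclusion trace with named per-species elution windows."""

    volume: np.ndarray  # ml, strictly increasing
    absorbance: np.ndarray
    peak_windows: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.volume, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if v.shape != a.shape or v.ndim != 1:
            raise ValueError("volume and absorbance must match in shape")
        if np.any(np.diff(v) <= 0):
            raise ValueError("elution volume must be strictly increasing")
        for name, (lo, hi) in self.peak_windows.items():
            if not (v[0] <= lo < hi <= v[-1]):
                raise ValueError(
                    f"window {name!r} [{lo}, {hi}] outside data range "
                    f"[{v[0]}, {v[-1]}]"
                )
        spans = sorted(self.peak_windows.values())
        for (l0, h0), (l1, h1) in zip(spans, spans[1:]):
            if l1 < h0:
                raise ValueError("peak windows overlap")
        object.__setattr__(self, "volume", v)
        object.__setattr__(self, "absorbance", a)


def integrate_peaks(chrom: Chromatogram) -> dict[str, float]:
    """Baseline-subtracted trapezoidal area of each named peak window.

    The baseline is the straight line between the trace values at the two
    window endpoints (signal interpolated onto the exact window bounds).
    """
    areas: dict[str, float] = {}
    v, a = chrom.volume, chrom.absorbance
    for name, (lo, hi) in chrom.peak_windows.items():
        inside = (v > lo) & (v < hi)
        xs = np.concatenate(([lo], v[inside], [hi]))
        ys = np.concatenate(
            ([np.interp(lo, v, a)], a[inside], [np.interp(hi, v, a)])
        )
        baseline = np.interp(xs, [lo, hi], [ys[0], ys[-1]])
        areas[name] = float(np.trapezoid(ys - baseline, xs))
    return areas


def assembly_fraction(areas: Mapping[str, float]) -> float:
    """Assembled (hexamer + dodecamer) share of total peak area, in [0, 1]."""
    unknown = set(areas) - set(ALL_SPECIES)
    if unknown:
        raise KeyError(f"unknown species: {sorted(unknown)}")
    if any(a < 0 for a in areas.values()):
        raise ValueError("peak areas must be non-negative")
    total = sum(areas.get(s, 0.0) for s in ALL_SPECIES)
    if total == 0:
        raise DegenerateDataError("all peak areas are zero")
    assembled = sum(areas.get(s, 0.0) for s in ASSEMBLED_SPECIES)
    return assembled / total
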