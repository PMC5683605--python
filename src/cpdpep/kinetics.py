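"""Michaelis-Menten kinetics: model evaluation, fitting and pH summaries.

The rate law is v = Vmax * S / (Km + S).  Fits use Levenberg-Marquardt least
squares on log-parameterized (Vmax, Km) so both parameters stay positive.

Units: substrate concentrations in uM, enzyme concentration in nM, and rates
in uM of product per second unless a calibration factor is supplied.  Then
kcat (s^-1) = Vmax [uM/s] * rate_calibration / (enzyme [uM]), with
enzyme [uM] = enzyme_nM / 1000.  The calibration factor converts arbitrary
signal rates (e.g. fluorescence/min) to uM/s and defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

__all__ = [
    "KineticDataset",
    "KineticFit",
    "PhProfile",
    "mm_rate",
    "fit_mm",
    "efficiency",
    "ph_summary",
    "enzyme_nM_to_uM",
]


def enzyme_nM_to_uM(enzyme_nM: float) -> float:
    """Single documented unit conversion: nM -> uM."""
    return enzyme_nM * 1e-3


@dataclass(frozen=True)
class KineticDataset:
    substrate_conc: tuple[float, ...]  # uM
    rate: tuple[float, ...]            # uM/s (or signal units, see calibration)
    enzyme_conc: float                 # nM
    substrate_name: str = ""

    def __post_init__(self) -> None:
        if len(self.substrate_conc) != len(self.rate):
            raise ValueError("substrate_conc and rate must have equal length")
        if any(s <= 0 for s in self.substrate_conc):
            raise ValueError("substrate concentrations must be positive")
        if any(v < 0 for v in self.rate):
            raise ValueError("rates must be non-negative")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")


@dataclass(frozen=True)
class KineticFit:
    vmax: float                  # rate units
    km: float                    # uM
    kcat: float                  # s^-1
    kcat_over_km: float          # uM^-1 s^-1
    se: dict[str, float] = field(default_factory=dict, hash=False)
    converged: bool = True
    message: str = ""


def mm_rate(S, vmax: float, km: float):
    """Michaelis-Menten initial rate v = Vmax*S/(Km+S)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be >= 0")
    if vmax <= 0 or km <= 0:
        raise ValueError("Vmax and Km must be positive")
    out = vmax * S / (km + S)
    return float(out) if out.ndim == 0 else out


def fit_mm(
    d: KineticDataset,
    start: tuple[float, float] | None = None,
    rate_calibration: float = 1.0,
) -> KineticFit:
    """Nonlinear least-squares Michaelis-Menten fit.

    ``start`` is (Vmax0, Km0); the default start is Vmax0 = max rate and
    Km0 = median substrate concentration, which is robust across the assay's
    concentration range.  Degenerate data (fewer than three distinct
    concentrations, all-zero or all-equal rates) is reported unconverged.
    """
    S = np.asarray(d.substrate_conc, dtype=float)
    v = np.asarray(d.rate, dtype=float)
    if len(set(d.substrate_conc)) < 3:
        raise ValueError("at least three distinct substrate concentrations required")
    if np.allclose(v, v[0]) or np.all(v == 0):
        return KineticFit(
            vmax=float("nan"), km=float("nan"), kcat=float("nan"),
            kcat_over_km=float("nan"), converged=False,
            message="degenerate data: rates carry no concentration dependence",
        )
    vmax0, km0 = start if start is not None else (float(v.max()), float(np.median(S)))
    if vmax0 <= 0 or km0 <= 0:
        raise ValueError("start values must be positive")

    params = Parameters()
    params.add("log_vmax", value=np.log(vmax0))
    params.add("log_km", value=np.log(km0))

    def residual(pars):
        return v - mm_rate(S, np.exp(pars["log_vmax"]), np.exp(pars["log_km"]))

    result = minimize(residual, params, method="leastsq")
    vmax = float(np.exp(result.params["log_vmax"].value))
    km = float(np.exp(result.params["log_km"].value))
    se: dict[str, float] = {}
    if result.errorbars:
        # delta method: se(exp(x)) = exp(x) * se(x)
        se["vmax"] = vmax * float(result.params["log_vmax"].stderr)
        se["km"] = km * float(result.params["log_km"].stderr)
    enzyme_uM = enzyme_nM_to_uM(d.enzyme_conc)
    kcat = vmax * rate_calibration / enzyme_uM
    return KineticFit(
        vmax=vmax,
        km=km,
        kcat=kcat,
        kcat_over_km=kcat / km,
        se=se,
        converged=bool(result.success),
        message=str(result.message),
    )


def efficiency(fit: KineticFit) -> float:
    """Catalytic efficiency kcat/Km in uM^-1 s^-1."""
    if not fit.converged:
        raise ValueError("cannot compute efficiency of an unconverged fit")
    if fit.km == 0:
        raise ValueError("Km must be nonzero")
    return fit.kcat / fit.km


@dataclass(frozen=True)
class PhProfile:
    ph: tuple[float, ...]
    activity_pct: tuple[float, ...]  # normalized, max = 100
    optimum: float
    half_max_range: tuple[float, float]


def ph_summary(ph, activity, interpolate: bool = False) -> PhProfile:
    """Summarize a pH-activity series.

    Activities are normalized to percent of the maximum; the optimum is the
    pH of the maximum, and the half-maximal range is the outermost contiguous
    run of measured pH values around the optimum with activity >= 50%.  With
    ``interpolate=True`` the endpoints are refined to the linearly
    interpolated 50% crossings between grid points.
    """
    ph = np.asarray(ph, dtype=float)
    act = np.asarray(activity, dtype=float)
    if len(ph) != len(act) or len(ph) < 3:
        raise ValueError("need >= 3 paired (pH, activity) points")
    order = np.argsort(ph)
    ph, act = ph[order], act[order]
    if act.max() <= 0:
        raise ValueError("all-zero activity series")
    pct = act / act.max() * 100.0
    i_opt = int(np.argmax(pct))
    # expand from the optimum while >= 50%
    lo = i_opt
    while lo > 0 and pct[lo - 1] >= 50.0:
        lo -= 1
    hi = i_opt
    while hi < len(ph) - 1 and pct[hi + 1] >= 50.0:
        hi += 1
    low_ph, high_ph = ph[lo], ph[hi]
    if interpolate:
        if lo > 0:
            low_ph = ph[lo - 1] + (50.0 - pct[lo - 1]) / (pct[lo] - pct[lo - 1]) * (
                ph[lo] - ph[lo - 1]
            )
        if hi < len(ph) - 1:
            high_ph = ph[hi] + (pct[hi] - 50.0) / (pct[hi] - pct[hi + 1]) * (
                ph[hi + 1] - ph[hi]
            )
    return PhProfile(
        ph=tuple(float(x) for x in ph),
        activity_pct=tuple(float(x) for x in pct),
        optimum=float(ph[i_opt]),
        half_max_range=(float(low_ph), float(high_ph)),
    )
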