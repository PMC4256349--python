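"""Steady-state and pre-steady-state enzyme kinetics.

Covers the two fitting tasks of the mutant characterisation work on
ornithine 4,5-aminomutase (OAM):

* the coupled spectrophotometric assay, where NAD+ reduction at 340 nm
  (Δε = 6220 M⁻¹cm⁻¹) reports the OAM turnover rate, fitted to the
  Michaelis–Menten equation v = kcat·s/(Km + s) with catalytic efficiency
  kcat/Km and first-order error propagation;
* stopped-flow absorbance transients at 528 nm reporting
  adenosylcobalamin Co–C bond homolysis, fitted to a single exponential
  A(t) = a0 + ΔA·exp(−kobs·t).

Both fits are deterministic: starting values come from fixed heuristics on
the data, so identical input yields bit-identical parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from lmfit import Model

from .errors import ConfigurationError, FitFailureError, InvalidParameterError

__all__ = [
    "AssayConfig",
    "MMDataset",
    "MMFit",
    "ExpFit",
    "rate_from_slope",
    "fit_mm",
    "efficiency_with_error",
    "fit_exponential",
    "average_traces",
]


@dataclass(frozen=True)
class AssayConfig:
    """Coupled-assay conversion constants.

    epsilon : molar absorptivity of the reporter chromophore, M⁻¹cm⁻¹
        (default 6220, NAD+ → NADH at 340 nm).
    path : cuvette path length, cm.
    enzyme_conc : catalytic-site concentration, M (default 100 nM).
    """

    epsilon: float = 6220.0
    path: float = 1.0
    enzyme_conc: float = 100e-9

    def __post_init__(self) -> None:
        if not (self.epsilon > 0 and self.path > 0 and self.enzyme_conc > 0):
            raise InvalidParameterError("epsilon, path and enzyme_conc must all be > 0")


@dataclass
class MMDataset:
    """Rate-vs-substrate data for a Michaelis–Menten fit.

    ``v`` may be per-enzyme turnover rates (s⁻¹, ``unit="per_enzyme_s"``) or
    absolute rates (M·s⁻¹, ``unit="M_per_s"``); absolute rates are converted
    to per-enzyme on construction using ``config.enzyme_conc``.
    """

    s: np.ndarray  # substrate concentrations, μM
    v: np.ndarray  # rates
    unit: str = "per_enzyme_s"
    config: AssayConfig = field(default_factory=AssayConfig)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.s.shape != self.v.shape or self.s.ndim != 1:
            raise ConfigurationError("s and v must be 1-D arrays of equal length")
        if np.any(self.s < 0):
            raise ConfigurationError("substrate concentrations must be >= 0")
        if len(np.unique(self.s)) < 4:
            raise ConfigurationError("need at least 4 distinct substrate concentrations")
        if self.unit == "M_per_s":
            self.v = self.v / self.config.enzyme_conc
            self.unit = "per_enzyme_s"
        elif self.unit != "per_enzyme_s":
            raise ConfigurationError(f"unknown rate unit {self.unit!r}")


@dataclass
class MMFit:
    """Fitted Michaelis–Menten parameters with uncertainties.

    kcat is in s⁻¹, Km in μM; ``efficiency`` is kcat/Km in absolute
    M⁻¹s⁻¹ with the covariance term included in its propagated error.
    """

    kcat: float
    kcat_se: float
    km: float  # μM
    km_se: float
    covariance: np.ndarray  # 2×2, order (kcat, Km)
    efficiency: float  # M⁻¹ s⁻¹
    efficiency_se: float
    diagnostics: dict


@dataclass
class ExpFit:
    """Fitted single-exponential parameters A(t) = a0 + amplitude·exp(−kobs·t)."""

    a0: float
    amplitude: float
    kobs: float  # s⁻¹
    kobs_se: float
    diagnostics: dict
    low_confidence: bool = False


def rate_from_slope(dA_dt: float, config: AssayConfig) -> tuple[float, float]:
    """Convert an absorbance slope to reaction rates via Beer–Lambert.

    Returns ``(rate_M_per_s, per_enzyme_rate_s)`` where
    rate = (dA/dt)/(ε·l) and the per-enzyme rate divides by the enzyme
    concentration.  Negative slopes pass through with their sign.
    """
    rate = dA_dt / (config.epsilon * config.path)
    return rate, rate / config.enzyme_conc


def _mm(s, kcat, km):
    return kcat * s / (km + s)


def fit_mm(data: MMDataset, weighting: str = "relative") -> MMFit:
    """Nonlinear least-squares Michaelis–Menten fit.

    Starting values are deterministic: kcat₀ = max(v) and Km₀ = the substrate
    concentration at half-maximal rate by linear interpolation.

    ``weighting="relative"`` (default) weights residuals by 1/|v|, the
    matched estimator when rate noise has a constant coefficient of
    variation, as in initial-rate assays; ``"none"`` gives ordinary
    unweighted least squares.
    """
    s, v = data.s, data.v
    vmax = float(np.max(v))
    if not (vmax > 0):
        raise FitFailureError("rates are non-positive everywhere; nothing to fit")
    # Km0: s at half-max rate, by interpolation on the sorted design
    order = np.argsort(s)
    s_sorted, v_sorted = s[order], v[order]
    half = 0.5 * vmax
    km0 = float(np.interp(half, v_sorted, s_sorted)) if np.any(v_sorted >= half) else float(np.median(s_sorted))
    km0 = max(km0, 1e-6)

    if weighting == "relative":
        floor = 1e-3 * np.max(np.abs(v))
        weights = 1.0 / np.maximum(np.abs(v), floor)
    elif weighting == "none":
        weights = None
    else:
        raise ConfigurationError(f"weighting must be 'relative' or 'none', got {weighting!r}")

    model = Model(_mm)
    params = model.make_params(kcat=vmax, km=km0)
    params["kcat"].set(min=0.0)
    params["km"].set(min=1e-12)
    result = model.fit(v, params, s=s, weights=weights)
    if not result.success or result.covar is None:
        raise FitFailureError(f"Michaelis-Menten fit failed: {result.message}")
    kcat = float(result.params["kcat"].value)
    km = float(result.params["km"].value)
    if kcat <= 0 or km <= 1e-9:
        raise FitFailureError(
            f"Michaelis-Menten fit pinned at a boundary (kcat={kcat}, Km={km})"
        )
    names = list(result.var_names)
    idx = [names.index("kcat"), names.index("km")]
    cov = np.asarray(result.covar)[np.ix_(idx, idx)]
    kcat_se = math.sqrt(max(cov[0, 0], 0.0))
    km_se = math.sqrt(max(cov[1, 1], 0.0))
    eff, eff_se = efficiency_with_error(kcat, km, kcat_se, km_se, cov[0, 1])
    resid = v - _mm(s, kcat, km)
    return MMFit(
        kcat=kcat,
        kcat_se=kcat_se,
        km=km,
        km_se=km_se,
        covariance=cov,
        efficiency=eff,
        efficiency_se=eff_se,
        diagnostics={
            "n": len(s),
            "rss": float(np.sum(resid**2)),
            "residual_rms": float(np.sqrt(np.mean(resid**2))),
            "nfev": result.nfev,
        },
    )


def efficiency_with_error(
    kcat: float,
    km_uM: float,
    kcat_se: float = 0.0,
    km_se: float = 0.0,
    cov_kcat_km: float = 0.0,
) -> tuple[float, float]:
    """Catalytic efficiency kcat/Km in M⁻¹s⁻¹ with first-order error.

    Km is given in μM.  The variance of the ratio includes the covariance
    term:

        var(kcat/Km) = (∂/∂kcat)²σ²_kcat + (∂/∂Km)²σ²_Km + 2·(∂/∂kcat)(∂/∂Km)·cov

    with ∂/∂kcat = 1/Km and ∂/∂Km = −kcat/Km².
    """
    if not (kcat > 0 and km_uM > 0):
        raise InvalidParameterError("kcat and Km must be > 0")
    km_M = km_uM * 1e-6
    value = kcat / km_M
    a = 1.0 / km_M
    b = -kcat / km_M**2
    # covariance supplied on the μM scale for Km → convert to M
    var = (a * kcat_se) ** 2 + (b * km_se * 1e-6) ** 2 + 2.0 * a * b * cov_kcat_km * 1e-6
    return value, math.sqrt(max(var, 0.0))


def fit_exponential(
    t: Sequence[float],
    a: Sequence[float],
    dead_time: float = 1e-3,
    direction: Optional[str] = None,
) -> ExpFit:
    """Single-exponential fit of a stopped-flow absorbance transient.

    Points within ``dead_time`` seconds of the first sample are discarded
    (instrument mixing artifact).  Initialization is a log-linear fit of
    |A − a0| on baseline-subtracted data, with a0 estimated from the trace
    tail; the nonlinear fit then refines (a0, amplitude, kobs).  The fit is
    invariant to absorbance offset and amplitude sign.

    A result whose rate implies less than one half-life inside the observed
    window is flagged ``low_confidence`` rather than rejected.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    if t.shape != a.shape or t.ndim != 1:
        raise ConfigurationError("t and a must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError("time axis must be strictly increasing")
    keep = t >= t[0] + dead_time
    t, a = t[keep], a[keep]
    if len(t) < 5:
        raise ConfigurationError("need at least 5 points after dead-time removal")

    n_tail = max(3, len(a) // 20)
    a0_init = float(np.mean(a[-n_tail:]))
    amp_init = float(a[0] - a0_init)
    if direction == "decrease" and amp_init < 0:
        amp_init = abs(amp_init)
    scale = float(np.ptp(a))
    if abs(amp_init) < 1e-12 or scale < 1e-12:
        raise FitFailureError("trace shows no resolvable exponential amplitude")
    # log-linear rate estimate on the early, well-resolved part of the decay
    resid0 = (a - a0_init) / amp_init
    good = resid0 > 0.05
    if good.sum() >= 3:
        slope = np.polyfit(t[good], np.log(resid0[good]), 1)[0]
        k_init = max(-slope, 1e-9) if slope < 0 else 1.0 / (t[-1] - t[0])
    else:
        k_init = 1.0 / (t[-1] - t[0])

    def expo(t, a0, amplitude, kobs):
        return a0 + amplitude * np.exp(-kobs * t)

    model = Model(expo)
    params = model.make_params(a0=a0_init, amplitude=amp_init, kobs=k_init)
    params["kobs"].set(min=1e-12)
    result = model.fit(a, params, t=t)
    if not result.success:
        raise FitFailureError(f"exponential fit failed: {result.message}")
    kobs = float(result.params["kobs"].value)
    if kobs <= 0:
        raise FitFailureError(f"exponential fit returned non-positive rate {kobs}")
    kobs_se = float(result.params["kobs"].stderr or np.nan)
    resid = a - result.best_fit
    window = t[-1] - t[0]
    return ExpFit(
        a0=float(result.params["a0"].value),
        amplitude=float(result.params["amplitude"].value),
        kobs=kobs,
        kobs_se=kobs_se,
        low_confidence=bool(kobs * window < math.log(2.0)),
        diagnostics={
            "n": len(t),
            "residual_rms": float(np.sqrt(np.mean(resid**2))),
            "nfev": result.nfev,
        },
    )


def average_traces(traces: Sequence[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean of replicate traces on identical time grids.

    Averaging n white-noise replicates reduces the noise SD by ≈ 1/√n.
    """
    if not traces:
        raise ConfigurationError("no traces to average")
    t0 = np.asarray(traces[0][0], dtype=float)
    stack = []
    for t, a in traces:
        t = np.asarray(t, dtype=float)
        if t.shape != t0.shape or not np.allclose(t, t0, rtol=0, atol=0):
            raise ConfigurationError("all traces must share an identical time grid")
        stack.append(np.asarray(a, dtype=float))
    return t0.copy(), np.mean(stack, axis=0)
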