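"""Gastric-pH pharmacodynamics: sigmoid Emax with baseline, direct response.

The effect of plasma rabeprazole on gastric pH is modelled as

    E(C) = E0 + Emax * C^gamma / (EC50^gamma + C^gamma)

linked directly (no effect-compartment delay) to the central-compartment
concentration.  Effect metrics follow the clinical convention for proton
pump inhibitors: area under the effect curve (AUEC), maximum pH, and the
onset/offset/duration of time spent above the therapeutic threshold pH 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .model import ConcentrationProfile

__all__ = [
    "SigmoidEmaxParams",
    "EffectProfile",
    "EffectMetrics",
    "effect_at_concentration",
    "invert_effect",
    "effect_profile",
    "effect_metrics",
    "fit_pd",
    "PDFitReport",
]


@dataclass(frozen=True)
class SigmoidEmaxParams:
    """Baseline pH, maximal pH increase, half-maximal concentration, steepness."""

    E0: float
    Emax: float
    EC50: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("E0", "Emax", "EC50", "gamma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class EffectProfile:
    """Gastric pH on a time grid (h)."""

    times: np.ndarray
    pH: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ph = np.asarray(self.pH, dtype=float)
        if times.shape != ph.shape:
            raise ValueError("times and pH must be aligned")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pH", ph)


@dataclass(frozen=True)
class EffectMetrics:
    """AUEC, peak pH, and threshold-crossing summary over the window."""

    auec: float
    max_effect: float
    onset: float | None
    offset: float | None
    duration: float


def effect_at_concentration(c, p: SigmoidEmaxParams):
    """pH at plasma concentration ``c`` (ng/mL); strictly increasing in c."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        # work on the log scale for numerical range safety at large gamma
        ratio = np.exp(np.where(c > 0, p.gamma * (np.log(c) - math.log(p.EC50)), -np.inf))
    effect = p.E0 + p.Emax * ratio / (1.0 + ratio)
    return effect if effect.ndim else float(effect)


def invert_effect(target_pH: float, p: SigmoidEmaxParams) -> float:
    """Concentration (ng/mL) producing the target pH; the model inverse.

    Only values strictly between the baseline E0 and the plateau E0 + Emax
    are reachable at finite concentration.
    """
    if not (p.E0 < target_pH < p.E0 + p.Emax):
        raise ValueError(
            f"unreachable effect: target pH must lie in ({p.E0}, {p.E0 + p.Emax})"
        )

    def resid(log_c: float) -> float:
        return effect_at_concentration(math.exp(log_c), p) - target_pH

    # bracket around EC50 on the log scale, then root-find
    lo, hi = math.log(p.EC50) - 1.0, math.log(p.EC50) + 1.0
    while resid(lo) > 0:
        lo -= 2.0
    while resid(hi) < 0:
        hi += 2.0
    root = optimize.brentq(resid, lo, hi, xtol=1e-13, rtol=1e-15)
    return float(math.exp(root))


def effect_profile(conc: ConcentrationProfile, p: SigmoidEmaxParams) -> EffectProfile:
    """Pointwise direct-response mapping of a concentration profile to pH."""
    return EffectProfile(times=conc.times, pH=effect_at_concentration(conc.conc, p))


def _crossings(times: np.ndarray, values: np.ndarray, threshold: float) -> list[tuple[float, int]]:
    """Linear-interpolated crossing times of ``threshold``; +1 up, -1 down."""
    out: list[tuple[float, int]] = []
    above = values > threshold
    for i in range(len(times) - 1):
        if above[i] != above[i + 1]:
            t = times[i] + (threshold - values[i]) / (values[i + 1] - values[i]) * (
                times[i + 1] - times[i]
            )
            out.append((t, +1 if above[i + 1] else -1))
    return out


def effect_metrics(
    e: EffectProfile, threshold: float = 4.0, window: tuple[float, float] = (0.0, 10.0)
) -> EffectMetrics:
    """AUEC, max effect and pH-above-threshold timing over a window.

    AUEC is the trapezoidal integral of pH over the window; onset is the
    first up-crossing of the threshold (linear interpolation between
    samples), offset the last down-crossing, and duration the total time
    above the threshold (which may be fragmented).
    """
    w0, w1 = window
    if e.times[0] > w0 or e.times[-1] < w1:
        raise ValueError(f"profile does not cover the window {window}")
    mask = (e.times >= w0) & (e.times <= w1)
    t = e.times[mask]
    v = e.pH[mask]
    # make sure the window endpoints are represented exactly
    if t[0] > w0:
        t = np.insert(t, 0, w0)
        v = np.insert(v, 0, np.interp(w0, e.times, e.pH))
    if t[-1] < w1:
        t = np.append(t, w1)
        v = np.append(v, np.interp(w1, e.times, e.pH))

    auec = float(np.trapezoid(v, t))
    max_effect = float(v.max())

    crossings = _crossings(t, v, threshold)
    above = v > threshold
    duration = 0.0
    onset = offset = None
    if above.any() or crossings:
        ups = [c[0] for c in crossings if c[1] > 0]
        downs = [c[0] for c in crossings if c[1] < 0]
        if above[0]:
            ups.insert(0, t[0])
        if above[-1]:
            downs.append(t[-1])
        duration = float(sum(d - u for u, d in zip(ups, downs)))
        onset = float(ups[0])
        offset = float(downs[-1])
    return EffectMetrics(
        auec=auec, max_effect=max_effect, onset=onset, offset=offset, duration=duration
    )


# ---------------------------------------------------------------------------
# PD model fitting (concentration -> pH observation pairs)
# ---------------------------------------------------------------------------

@dataclass
class PDCandidateFit:
    name: str
    params: dict
    converged: bool
    rss: float = np.inf
    aic: float = np.inf
    minus2ll: float = np.inf
    r: float = np.nan
    se: dict | None = None
    rse_percent: dict | None = None
    ci95: dict | None = None
    message: str = ""


@dataclass
class PDFitReport:
    best: str
    candidates: dict[str, PDCandidateFit]

    @property
    def best_params(self) -> SigmoidEmaxParams:
        fit = self.candidates[self.best]
        if fit.name == "sigmoid_emax_baseline":
            return SigmoidEmaxParams(**fit.params)
        if fit.name == "emax_baseline":
            return SigmoidEmaxParams(gamma=1.0, **fit.params)
        raise ValueError(f"best model {fit.name!r} is not an Emax-family model")

    def to_dict(self) -> dict:
        return {
            "best": self.best,
            "candidates": {
                name: {
                    "params": c.params, "converged": c.converged, "AIC": c.aic,
                    "-2LL": c.minus2ll, "r": c.r, "SE": c.se,
                    "RSE_percent": c.rse_percent, "CI95": c.ci95,
                }
                for name, c in self.candidates.items()
            },
        }


_CANDIDATE_DEFS = {
    "linear": (("intercept", "slope"), lambda c, b: b[0] + b[1] * c),
    "emax_baseline": (
        ("E0", "Emax", "EC50"),
        lambda c, b: b[0] + b[1] * c / (b[2] + c),
    ),
    "sigmoid_emax_baseline": (
        ("E0", "Emax", "EC50", "gamma"),
        lambda c, b: b[0] + b[1] * np.power(c, b[3]) / (np.power(b[2], b[3]) + np.power(c, b[3])),
    ),
}


def _initial_values(name: str, conc: np.ndarray, ph: np.ndarray) -> np.ndarray:
    e0 = float(np.min(ph))
    emax = max(float(np.max(ph) - e0), 0.5)
    ec50 = float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0
    if name == "linear":
        slope = (ph.max() - ph.min()) / max(conc.max() - conc.min(), 1e-9)
        return np.array([e0, slope])
    if name == "emax_baseline":
        return np.array([max(e0, 0.1), emax, ec50])
    return np.array([max(e0, 0.1), emax, ec50, 2.0])


def fit_pd(
    obs, candidates: Sequence[str] = ("linear", "emax_baseline", "sigmoid_emax_baseline")
) -> PDFitReport:
    """Fit candidate concentration-effect models by nonlinear least squares.

    ``obs`` is a two-column structure (concentration ng/mL, pH) — a
    DataFrame with columns (conc, pH), a 2-column array, or a pair of
    sequences.  Each candidate is fitted by unweighted least squares; the
    report carries AIC, -2LL (Gaussian), Pearson r between fitted and
    observed values, standard errors (Jacobian-based), RSE% and 95% CIs.
    The winner is the converged candidate with the lowest AIC.
    """
    conc, ph = _as_obs_arrays(obs)
    if conc.size < 8:
        raise ValueError("need at least 8 observation pairs")

    results: dict[str, PDCandidateFit] = {}
    for name in candidates:
        if name not in _CANDIDATE_DEFS:
            raise ValueError(f"unknown candidate model {name!r}")
        pnames, fun = _CANDIDATE_DEFS[name]
        x0 = _initial_values(name, conc, ph)
        bounds = (
            (-np.inf, np.inf)
            if name == "linear"
            else (np.full(len(pnames), 1e-6), np.full(len(pnames), np.inf))
        )
        try:
            sol = optimize.least_squares(
                lambda b: fun(conc, b) - ph, x0, bounds=bounds, method="trf", xtol=1e-12
            )
            ok = sol.success
        except Exception as err:  # pragma: no cover - defensive
            results[name] = PDCandidateFit(name, {}, False, message=str(err))
            continue
        n, k = conc.size, len(pnames)
        rss = float(2.0 * sol.cost)
        sigma2 = rss / n
        minus2ll = n * (math.log(2.0 * math.pi * sigma2) + 1.0)
        aic = minus2ll + 2.0 * (k + 1)
        fitted = fun(conc, sol.x)
        r = float(np.corrcoef(fitted, ph)[0, 1]) if np.std(fitted) > 0 else np.nan
        se = rse = ci = None
        if ok and n > k:
            try:
                cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / (n - k)
                se_arr = np.sqrt(np.maximum(np.diag(cov), 0.0))
                se = dict(zip(pnames, se_arr))
                rse = {
                    p: 100.0 * s / abs(v) if v != 0 else np.inf
                    for (p, s), v in zip(se.items(), sol.x)
                }
                q = stats.norm.ppf(0.975)
                ci = {p: (v - q * s, v + q * s) for (p, s), v in zip(se.items(), sol.x)}
            except np.linalg.LinAlgError:
                pass
        results[name] = PDCandidateFit(
            name, dict(zip(pnames, map(float, sol.x))), ok, rss, aic, minus2ll, r,
            se, rse, ci, sol.message,
        )
    converged = {n: c for n, c in results.items() if c.converged}
    if not converged:
        raise RuntimeError("no candidate PD model converged")
    best = min(converged, key=lambda n: converged[n].aic)
    return PDFitReport(best=best, candidates=results)


def _as_obs_arrays(obs) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(obs, "columns"):
        cols = list(obs.columns)
        conc = np.asarray(obs[cols[0]], dtype=float)
        ph = np.asarray(obs[cols[1]], dtype=float)
    else:
        arr = np.asarray(obs, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 2:
            conc, ph = arr[:, 0], arr[:, 1]
        elif arr.ndim == 2 and arr.shape[0] == 2:
            conc, ph = arr[0], arr[1]
        else:
            raise ValueError("obs must be two aligned columns (conc, pH)")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    return conc, ph
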