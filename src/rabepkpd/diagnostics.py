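"""Model qualification: bootstrap CIs, visual predictive check, CWRES/GOF.

The bootstrap resamples subjects with replacement (stratified by gender)
and refits each replicate.  The VPC simulates replicate datasets at the
observed design and compares observed percentiles with the simulated
5th/50th/95th bands.  CWRES follow the standard FOCE construction:
first-order linearization of the model about the conditional eta modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import TrialDataset
from .nlme import FitResult, LaplaceFitter, PKModelSpec, PKStructuralModel, fit_population

__all__ = ["bootstrap", "BootstrapResult", "vpc", "VPCResult", "gof_diagnostics"]


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    table: pd.DataFrame          # parameter -> estimate, median, ci_lo, ci_hi
    n_requested: int
    n_failed: int
    reliable: bool
    replicates: pd.DataFrame     # one row per successful replicate


def bootstrap(
    dataset: TrialDataset,
    fit: FitResult,
    n_replicates: int = 200,
    seed: int = 0,
    maxiter: int = 80,
) -> BootstrapResult:
    """Stratified nonparametric bootstrap of the population fit.

    Each replicate resamples subjects with replacement within gender
    strata (preserving the gender split exactly), refits the model
    warm-started at the original estimates, and contributes one parameter
    vector; the table reports the median and percentile 95% CI.  More
    than 50% failed replicates flags the result unreliable.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    spec = fit.spec
    theta0 = np.array([fit.theta[n] for n in spec.theta_names])
    omega0 = np.array([fit.omega2[n] for n in spec.eta_names])
    rows, n_failed = [], 0
    for _ in range(n_replicates):
        rep = dataset.resample_subjects(rng, stratify_on="SEX")
        try:
            f = fit_population(
                rep, spec, initial=(theta0, omega0, fit.sigma),
                seed=0, maxiter=maxiter, restarts=0, max_rounds=2, polish=False,
            )
            if not np.isfinite(f.ofv):
                raise RuntimeError("non-finite OFV")
            rows.append({**f.theta, **{f"omega2_{k}": v for k, v in f.omega2.items()},
                         "sigma": f.sigma})
        except Exception:
            n_failed += 1
    reps = pd.DataFrame(rows)
    estimates = {**fit.theta, **{f"omega2_{k}": v for k, v in fit.omega2.items()},
                 "sigma": fit.sigma}
    records = []
    for name, est in estimates.items():
        if len(reps) and name in reps:
            med = float(reps[name].median())
            lo, hi = np.percentile(reps[name], [2.5, 97.5])
        else:  # pragma: no cover - no successful replicate
            med = lo = hi = float("nan")
        records.append({"parameter": name, "estimate": est, "bootstrap_median": med,
                        "ci95_lo": float(lo), "ci95_hi": float(hi)})
    return BootstrapResult(
        table=pd.DataFrame(records).set_index("parameter"),
        n_requested=n_replicates,
        n_failed=n_failed,
        reliable=n_failed <= n_replicates / 2,
        replicates=reps,
    )


# ---------------------------------------------------------------------------
# Visual predictive check
# ---------------------------------------------------------------------------

@dataclass
class VPCResult:
    bands: pd.DataFrame        # per bin: observed & simulated percentiles + CI
    coverage: float            # fraction of observations inside 5-95% envelope
    stratified: dict[str, "VPCResult"]


def _simulate_replicates(model: PKStructuralModel, theta, omega2, sigma,
                         n_simulations: int, rng) -> np.ndarray:
    """(n_sim, S, N) simulated DVs at the observed design."""
    S, N = model.dv.shape
    k = len(model.eta_names)
    sims = np.empty((n_simulations, S, N))
    for s in range(n_simulations):
        eta = rng.normal(0.0, np.sqrt(omega2), size=(S, 1, k)) if k else np.zeros((S, 1, 0))
        conc = model.mean(theta, eta)[:, 0, :]
        eps = rng.normal(0.0, sigma, size=conc.shape)
        sims[s] = np.where(conc > 0, conc * np.exp(eps), 0.0)
    return sims


def vpc(
    dataset: TrialDataset,
    fit: FitResult,
    n_simulations: int = 200,
    bins: np.ndarray | None = None,
    seed: int = 0,
    stratify_gender: bool = False,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
) -> VPCResult:
    """Visual predictive check at the observed design.

    Observations (quantifiable only) are binned by time — by default one
    bin per distinct nominal time, merging bins with fewer than 3
    observations into their neighbour — and compared against percentile
    bands of ``n_simulations`` model-simulated replicate datasets,
    including 95% CIs of each simulated percentile.  ``coverage`` is the
    fraction of observations inside the simulated 5th-95th percentile
    envelope widened to the 95% CI bounds of those outer percentiles
    (observations "within the 95% CIs" of the predictions).
    """
    if n_simulations < 100:
        raise ValueError("n_simulations must be >= 100")
    spec = fit.spec
    model = PKStructuralModel(spec, dataset.subjects())
    model.lloq = dataset.lloq
    theta = np.array([fit.theta[n] for n in spec.theta_names])
    omega2 = np.array([fit.omega2[n] for n in spec.eta_names])
    rng = np.random.default_rng(seed)
    sims = _simulate_replicates(model, theta, omega2, fit.sigma, n_simulations, rng)

    def build(mask_subjects: np.ndarray) -> tuple[pd.DataFrame, float]:
        obs_mask = model.mask & (model.dv >= dataset.lloq) & mask_subjects[:, None]
        times = model.obs_times[obs_mask]
        obs = model.dv[obs_mask]
        sim_obs = sims[:, obs_mask]  # (n_sim, n_obs)
        edges = _time_bins(times, bins)
        rows, inside_total, n_total = [], 0, 0
        for lo, hi in edges:
            sel = (times >= lo) & (times <= hi if hi == edges[-1][1] else times < hi)
            if sel.sum() == 0:
                continue
            o = obs[sel]
            sim_band = np.percentile(sim_obs[:, sel], percentiles, axis=1)
            # envelope = 95% CI band of the outer percentiles ("within the
            # 95% CIs of the predictions"): lower CI bound of the 5th
            # percentile up to the upper CI bound of the 95th
            env_lo = float(np.percentile(sim_band[0], 2.5))
            env_hi = float(np.percentile(sim_band[2], 97.5))
            inside = np.sum((o >= env_lo) & (o <= env_hi))
            inside_total += int(inside)
            n_total += int(sel.sum())
            row = {"t_lo": lo, "t_hi": hi, "n_obs": int(sel.sum()),
                   "env_lo": env_lo, "env_hi": env_hi,
                   "inside_fraction": inside / sel.sum()}
            for p, label in zip(percentiles, ("p5", "p50", "p95")):
                row[f"obs_{label}"] = float(np.percentile(o, p))
                per_sim = np.percentile(sim_obs[:, sel], p, axis=1)
                row[f"sim_{label}"] = float(np.median(per_sim))
                row[f"sim_{label}_ci_lo"] = float(np.percentile(per_sim, 2.5))
                row[f"sim_{label}_ci_hi"] = float(np.percentile(per_sim, 97.5))
            rows.append(row)
        cov = inside_total / n_total if n_total else float("nan")
        return pd.DataFrame(rows), cov

    all_subjects = np.ones(len(model.records), dtype=bool)
    bands, coverage = build(all_subjects)
    stratified: dict[str, VPCResult] = {}
    if stratify_gender:
        genders = np.array([r.covariates.gender for r in model.records])
        for level in ("male", "female"):
            b, c = build(genders == level)
            stratified[level] = VPCResult(bands=b, coverage=c, stratified={})
    return VPCResult(bands=bands, coverage=coverage, stratified=stratified)


def _time_bins(times: np.ndarray, bins) -> list[tuple[float, float]]:
    if bins is not None:
        edges = np.asarray(bins, float)
        out = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    else:
        uniq = np.unique(times)
        out = [(t, t) for t in uniq] if len(uniq) <= 25 else [
            (a, b) for a, b in zip(
                np.percentile(times, np.linspace(0, 100, 11))[:-1],
                np.percentile(times, np.linspace(0, 100, 11))[1:],
            )
        ]
    # merge bins holding fewer than 3 observations into their left neighbour
    merged: list[tuple[float, float]] = []
    for lo, hi in out:
        n = np.sum((times >= lo) & (times <= hi))
        if merged and n < 3:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    return merged


# ---------------------------------------------------------------------------
# Goodness of fit / CWRES
# ---------------------------------------------------------------------------

def gof_diagnostics(dataset: TrialDataset, fit: FitResult,
                    n_fallback_sims: int = 500, seed: int = 0) -> pd.DataFrame:
    """Residual table: PRED, IPRED (log scale), CWRES and QQ ordinates.

    CWRES use the FOCE linearization about the conditional eta modes:
    with G = d log f / d eta at eta_hat, the marginal moments are
    E[y] ~ log f(eta_hat) - G eta_hat and V = G Omega G' + sigma^2 I, and
    CWRES = V^{-1/2} (y - E[y]).  If V is singular for a subject, that
    subject falls back to simulation-based standardized residuals
    (``fallback`` flag set).
    """
    spec = fit.spec
    model = PKStructuralModel(spec, dataset.subjects())
    model.lloq = dataset.lloq
    fitter = LaplaceFitter(model)
    theta = np.array([fit.theta[n] for n in spec.theta_names])
    omega2 = np.array([fit.omega2[n] for n in spec.eta_names])
    sigma = fit.sigma
    etas = fitter.eta_modes(theta, omega2, sigma)
    k = len(spec.eta_names)
    rng = np.random.default_rng(seed)

    rows = []
    h = 1e-5
    for i, rec in enumerate(model.records):
        w = fitter.w[i]
        n = int(w.sum())
        if n == 0:
            continue
        y = fitter.y[i][w]
        eta_i = etas[i]
        # predictions
        pred_pop = model.mean(theta, np.zeros((len(model.records), 1, k)))[i, 0][w]
        ipred = model.mean(theta, etas[:, None, :])[i, 0][w]
        logf0 = np.log(np.maximum(ipred, 1e-12))
        # gradient of log f wrt eta by central differences
        G = np.zeros((n, k))
        for j in range(k):
            e = np.zeros(k); e[j] = h
            batch = np.broadcast_to(
                np.stack([eta_i + e, eta_i - e])[None, :, :],
                (len(model.records), 2, k),
            )
            f = model.mean(theta, batch)[i]
            G[:, j] = (
                np.log(np.maximum(f[0][w], 1e-12)) - np.log(np.maximum(f[1][w], 1e-12))
            ) / (2 * h)
        mean = logf0 - G @ eta_i
        V = G @ np.diag(omega2) @ G.T + sigma**2 * np.eye(n)
        fallback = False
        try:
            L = np.linalg.cholesky(V)
            cwres = np.linalg.solve(L, y - mean)
        except np.linalg.LinAlgError:
            # simulation fallback: standardize against simulated log-DV
            fallback = True
            eta_sim = rng.normal(0.0, np.sqrt(omega2), size=(n_fallback_sims, k))
            batch = np.broadcast_to(
                eta_sim[None, :, :], (len(model.records), n_fallback_sims, k)
            )
            f = model.mean(theta, batch)[i][:, w]
            ysim = np.log(np.maximum(f, 1e-12)) + rng.normal(0, sigma, size=f.shape)
            cwres = (y - ysim.mean(axis=0)) / ysim.std(axis=0)
        for j in range(n):
            rows.append({
                "ID": rec.subject_id,
                "TIME": float(model.obs_times[i][w][j] + rec.dose_time),
                "log_DV": y[j], "PRED": float(np.log(max(pred_pop[j], 1e-12))),
                "IPRED": float(logf0[j]), "CWRES": float(cwres[j]),
                "fallback": fallback,
            })
    table = pd.DataFrame(rows)
    n = len(table)
    table = table.sort_values("CWRES").reset_index(drop=True)
    table["qq_theoretical"] = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return table.sort_values(["ID", "TIME"]).reset_index(drop=True)
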