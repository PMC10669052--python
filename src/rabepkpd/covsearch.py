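"""Stepwise covariate selection: forward inclusion then backward elimination.

Forward selection adds, best-first, any candidate (parameter, covariate)
term whose OFV improvement exceeds the chi-square 0.05 critical value
(3.84 for 1 df); backward elimination then removes any retained term whose
removal worsens the OFV by less than the 0.01 critical value (6.63).
Every attempted step is logged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datasets import TrialDataset
from .nlme import (
    CHI2_BACKWARD_DF1,
    CHI2_FORWARD_DF1,
    FitResult,
    PKModelSpec,
    fit_population,
)

__all__ = ["stepwise_covariate_search", "SelectionResult", "DEFAULT_CANDIDATES"]

DEFAULT_CANDIDATES: tuple[tuple[str, str], ...] = tuple(
    (p, c) for c in ("gender", "bsa")
    for p in ("Ka1", "Ka2", "Ka3", "Tlag", "Vc", "CLc")
)


@dataclass
class SelectionResult:
    selected: tuple[tuple[str, str], ...]
    final_fit: FitResult
    base_fit: FitResult
    log: pd.DataFrame


def stepwise_covariate_search(
    dataset: TrialDataset,
    base_spec: PKModelSpec | None = None,
    candidates: tuple[tuple[str, str], ...] = DEFAULT_CANDIDATES,
    forward_crit: float = CHI2_FORWARD_DF1,
    backward_crit: float = CHI2_BACKWARD_DF1,
    maxiter: int = 60,
    seed: int = 0,
) -> SelectionResult:
    """Run the full forward/backward search over candidate covariate terms.

    Each candidate fit is warm-started from the current model's estimates
    (the new coefficient starting at zero).  Candidate fits that fail are
    logged and skipped.
    """
    base_spec = base_spec or PKModelSpec()
    base_fit = fit_population(
        dataset, base_spec, seed=seed, maxiter=maxiter, restarts=0, max_rounds=3,
        polish=False,
    )
    current_spec, current_fit = base_spec, base_fit
    remaining = list(candidates)
    rows: list[dict] = []

    import numpy as np

    cfg = base_spec.config
    records = dataset.subjects()

    def eta_slope(fit: FitResult, param: str, covariate: str) -> float:
        """Initial coefficient from the empirical-Bayes eta regression on
        the covariate (standard eta-screening start; the likelihood is
        nearly flat at coefficient zero because the base etas already
        absorb the effect)."""
        if fit.etas is None or param not in fit.eta_names:
            return 0.0
        j = fit.eta_names.index(param)
        x = np.array([cfg.covariate_value(covariate, r.covariates) for r in records])
        if np.std(x) == 0:
            return 0.0
        return float(np.polyfit(x, fit.etas[:, j], 1)[0])

    def warm_start(spec: PKModelSpec, fit: FitResult):
        theta = []
        for n in spec.theta_names:
            if n in fit.theta:
                theta.append(fit.theta[n])
            else:
                # a newly added coefficient: locate its (param, covariate)
                new = [t for t in spec.covariate_terms
                       if t not in fit.spec.covariate_terms]
                theta.append(eta_slope(fit, *new[0]) if new else 0.0)
        omega2 = [fit.omega2[n] for n in spec.eta_names]
        return np.asarray(theta), np.asarray(omega2), fit.sigma

    def screen_candidate(cand: tuple[str, str]) -> float:
        """Restricted candidate fit: optimize only the new coefficient, the
        IIV variance of its parameter and sigma, all other estimates fixed
        at the current model's values.  This is the standard fast screening
        shortcut; the resulting dOFV is a lower bound on the full-refit
        improvement, so selection stays conservative.  The accepted term is
        re-estimated in full afterwards."""
        from scipy import optimize as sopt

        from .nlme import LaplaceFitter, PKStructuralModel

        spec = current_spec.with_term(*cand)
        model = PKStructuralModel(spec, records)
        model.lloq = dataset.lloq
        fitter = LaplaceFitter(model)
        theta0, omega0, sigma0 = warm_start(spec, current_fit)
        p = cand[0]
        j = spec.eta_names.index(p) if p in spec.eta_names else None

        def unpack(x):
            theta = theta0.copy()
            theta[-1] = x[0]
            omega2 = omega0.copy()
            if j is not None:
                omega2[j] = np.exp(np.clip(x[1], -40, 40))
            sigma = float(np.exp(np.clip(x[-1], -40, 40)))
            return theta, omega2, sigma

        def objective(x):
            theta, omega2, sigma = unpack(x)
            try:
                return fitter.ofv(theta, omega2, sigma, global_search=False)
            except (ValueError, np.linalg.LinAlgError):
                return 1e12

        x0 = [theta0[-1]]
        if j is not None:
            x0.append(np.log(omega0[j]))
        x0.append(np.log(sigma0))
        fitter._eta_cache = None
        fitter.ofv(*unpack(np.asarray(x0)))
        res = sopt.minimize(objective, np.asarray(x0), method="L-BFGS-B",
                            options={"maxiter": 30, "eps": 1e-6, "ftol": 1e-12})
        theta, omega2, sigma = unpack(res.x)
        fitter._eta_cache = None
        return float(fitter.ofv(theta, omega2, sigma, global_search=True))

    # ---- forward inclusion ------------------------------------------------
    step = 0
    while remaining:
        step += 1
        trials: list[tuple[float, tuple[str, str]]] = []
        for cand in remaining:
            try:
                ofv_c = screen_candidate(cand)
            except Exception as err:
                rows.append({"phase": "forward", "step": step, "candidate": f"{cand[0]}~{cand[1]}",
                             "ofv": float("nan"), "delta_ofv": float("nan"),
                             "action": f"failed: {err}"})
                continue
            delta = ofv_c - current_fit.ofv
            trials.append((delta, cand))
            rows.append({"phase": "forward", "step": step, "candidate": f"{cand[0]}~{cand[1]}",
                         "ofv": ofv_c, "delta_ofv": delta, "action": "screened"})
        accepted = sorted((t for t in trials if -t[0] > forward_crit))
        added = False
        for delta, cand in accepted:
            spec = current_spec.with_term(*cand)
            fit = fit_population(
                dataset, spec, initial=warm_start(spec, current_fit),
                seed=seed, maxiter=maxiter, restarts=0, max_rounds=2, polish=False,
            )
            full_delta = fit.ofv - current_fit.ofv
            if full_delta > -forward_crit:
                # the full refit does not confirm the screened improvement
                rows.append({"phase": "forward", "step": step,
                             "candidate": f"{cand[0]}~{cand[1]}", "ofv": fit.ofv,
                             "delta_ofv": full_delta, "action": "not confirmed"})
                remaining.remove(cand)
                continue
            rows.append({"phase": "forward", "step": step,
                         "candidate": f"{cand[0]}~{cand[1]}", "ofv": fit.ofv,
                         "delta_ofv": full_delta, "action": "added"})
            current_spec = spec
            current_fit = fit
            remaining.remove(cand)
            added = True
            break
        if not added:
            break

    # ---- backward elimination --------------------------------------------
    changed = True
    while changed and current_spec.covariate_terms:
        changed = False
        for cand in list(current_spec.covariate_terms):
            spec = current_spec.without_term(*cand)
            try:
                fit = fit_population(
                    dataset, spec, initial=warm_start(spec, current_fit),
                    seed=seed, maxiter=maxiter, restarts=0, max_rounds=2,
                    polish=False,
                )
            except Exception as err:  # pragma: no cover - defensive
                rows.append({"phase": "backward", "step": step, "candidate": f"{cand[0]}~{cand[1]}",
                             "ofv": float("nan"), "delta_ofv": float("nan"),
                             "action": f"failed: {err}"})
                continue
            worsening = fit.ofv - current_fit.ofv
            keep = worsening > backward_crit
            rows.append({"phase": "backward", "step": step, "candidate": f"{cand[0]}~{cand[1]}",
                         "ofv": fit.ofv, "delta_ofv": worsening,
                         "action": "retained" if keep else "removed"})
            if not keep:
                current_spec, current_fit = spec, fit
                changed = True
                break
    return SelectionResult(
        selected=current_spec.covariate_terms,
        final_fit=current_fit,
        base_fit=base_fit,
        log=pd.DataFrame(rows),
    )
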