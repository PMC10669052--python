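"""Non-compartmental analysis, gender comparison, and covariate screening.

AUC uses the linear-up/log-down trapezoid rule.  The terminal slope
(lambda_z) is chosen by log-linear regression over suffixes of the
post-Tmax points (3-8 points), keeping the window with the best adjusted
R^2 (ties favouring more points); windows below adjusted R^2 0.80 are
rejected and lambda_z-dependent quantities reported as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "NCAResult",
    "GroupComparison",
    "nca_single",
    "nca_weight_normalized",
    "compare_groups",
    "correlation_screen",
    "CorrelationScreen",
]


@dataclass(frozen=True)
class NCAResult:
    auc_all: float
    auc_inf: float
    auc_extrap: float
    cl_f: float
    cmax: float
    thalf: float
    mrt: float
    tmax: float
    tlag: float
    vd_f: float
    lambda_z: float
    lambda_z_n_points: int
    lambda_z_r2: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _lin_up_log_down_auc(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """AUC and AUMC by linear-up/log-down trapezoids (log only when c declines
    between two positive samples); the first moment uses the linear rule."""
    auc = aumc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c1 > 0 and c2 > 0 and c2 < c1:
            k = np.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t[i] * c1 - t[i + 1] * c2) / k + (c1 - c2) / k**2
        else:
            auc += 0.5 * (c1 + c2) * dt
            aumc += 0.5 * (t[i] * c1 + t[i + 1] * c2) * dt
    return auc, aumc


def _terminal_slope(
    t: np.ndarray, c: np.ndarray, tmax: float, min_r2: float = 0.80
) -> tuple[float, int, float]:
    """Best log-linear terminal window after Tmax; (lambda_z, n, adj R^2)."""
    mask = (t > tmax) & (c > 0)
    tt, cc = t[mask], np.log(c[mask])
    best = (np.nan, 0, -np.inf)
    for n in range(3, min(8, len(tt)) + 1):
        x, y = tt[-n:], cc[-n:]
        slope, intercept, r, _, _ = stats.linregress(x, y)
        if slope >= 0:
            continue
        adj_r2 = 1.0 - (1.0 - r**2) * (n - 1) / (n - 2)
        # ties (within 1e-10) resolved in favour of more points
        if adj_r2 > best[2] + 1e-10 or (abs(adj_r2 - best[2]) <= 1e-10 and n > best[1]):
            best = (-slope, n, adj_r2)
    if best[2] < min_r2:
        return np.nan, 0, best[2] if np.isfinite(best[2]) else np.nan
    return best


def nca_single(times, concs, dose: float, lloq: float = 1.0) -> NCAResult:
    """NCA of one subject's concentration-time profile after a single dose.

    ``dose`` in ng, concentrations in ng/mL; clearances are reported in
    L/h and volumes in L.  Samples below ``lloq`` are treated as zero for
    lag-time determination and excluded from the terminal regression.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("times and concs must be aligned 1-D arrays")
    if not dose > 0:
        raise ValueError("dose must be > 0")
    order = np.argsort(t)
    t, c = t[order], c[order]
    quant = c >= lloq
    if len(t) < 5 or quant.sum() < 3:
        raise ValueError("need at least 5 samples with 3 quantifiable")

    first_q = int(np.argmax(quant))
    tlag = float(t[first_q - 1]) if first_q > 0 else 0.0
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])

    auc_all, aumc_all = _lin_up_log_down_auc(t, c)
    lam, n_lam, r2 = _terminal_slope(t, c, tmax)

    last_q = int(len(t) - 1 - np.argmax(quant[::-1]))
    clast, tlast = float(c[last_q]), float(t[last_q])
    if np.isfinite(lam):
        auc_inf = auc_all + clast / lam
        aumc_inf = aumc_all + clast * tlast / lam + clast / lam**2
        cl_f = dose / auc_inf / 1000.0  # mL/h -> L/h
        vd_f = cl_f / lam
        thalf = np.log(2.0) / lam
        mrt = aumc_inf / auc_inf
        extrap = 100.0 * (auc_inf - auc_all) / auc_inf
    else:
        auc_inf = aumc_inf = cl_f = vd_f = thalf = mrt = extrap = np.nan
    return NCAResult(
        auc_all=float(auc_all), auc_inf=float(auc_inf), auc_extrap=float(extrap),
        cl_f=float(cl_f), cmax=cmax, thalf=float(thalf), mrt=float(mrt), tmax=tmax,
        tlag=tlag, vd_f=float(vd_f), lambda_z=float(lam),
        lambda_z_n_points=int(n_lam), lambda_z_r2=float(r2),
    )


def nca_weight_normalized(
    times, concs, dose: float, weight: float, lloq: float = 1.0
) -> NCAResult:
    """NCA on concentrations normalized to body weight (per-kg scale).

    The profile is divided by ``weight`` (kg) before analysis, so AUC and
    Cmax carry /kg units while wCL/F and wVd/F come out of the normalized
    profile directly.  The LLOQ is scaled alongside the data so that the
    same samples remain quantifiable.
    """
    if not weight > 0:
        raise ValueError("weight must be > 0")
    c = np.asarray(concs, dtype=float) / weight
    return nca_single(times, c, dose, lloq=lloq / weight)


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    t_statistic: float
    p_value: float
    significant: bool


def compare_groups(values_by_gender: dict, parameter: str = "") -> GroupComparison:
    """Welch two-sample, two-tailed t-test between two groups (alpha 0.05)."""
    if len(values_by_gender) != 2:
        raise ValueError("exactly two groups are required")
    (name_a, a), (name_b, b) = values_by_gender.items()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        tstat, p = 0.0, 1.0  # identical degenerate groups
    else:
        tstat, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        parameter=parameter,
        means={name_a: float(np.mean(a)), name_b: float(np.mean(b))},
        sds={name_a: float(np.std(a, ddof=1)), name_b: float(np.std(b, ddof=1))},
        ns={name_a: len(a), name_b: len(b)},
        t_statistic=float(tstat), p_value=float(p), significant=bool(p < 0.05),
    )


@dataclass
class CorrelationScreen:
    matrix: pd.DataFrame                 # Pearson r, covariates x parameters
    flags: pd.DataFrame                  # |r| >= threshold
    stratified: dict[str, pd.DataFrame] = field(default_factory=dict)
    regressions: pd.DataFrame | None = None


def correlation_screen(
    covariate_table: pd.DataFrame,
    nca_table: pd.DataFrame,
    threshold: float = 0.3,
    gender: pd.Series | None = None,
) -> CorrelationScreen:
    """Pearson-correlation screen of covariates against NCA parameters.

    Every covariate x parameter pair gets an overall r (and per-gender r
    when a gender series is supplied); pairs with |r| >= ``threshold``
    are flagged and re-examined by ordinary least-squares regression,
    recording the slope p-value and significance at 0.05.  Constant
    columns yield missing correlations.
    """
    if len(covariate_table) != len(nca_table):
        raise ValueError("tables must have the same number of subject rows")
    if len(covariate_table) < 10:
        raise ValueError("need at least 10 complete subject rows")

    def corr_frame(cov: pd.DataFrame, nca: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=cov.columns, columns=nca.columns, dtype=float)
        for cc in cov.columns:
            for pc in nca.columns:
                x = pd.to_numeric(cov[cc], errors="coerce")
                y = pd.to_numeric(nca[pc], errors="coerce")
                ok = x.notna() & y.notna()
                if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                    out.loc[cc, pc] = np.nan
                else:
                    out.loc[cc, pc] = float(np.corrcoef(x[ok], y[ok])[0, 1])
        return out

    matrix = corr_frame(covariate_table, nca_table)
    flags = matrix.abs() >= threshold

    stratified: dict[str, pd.DataFrame] = {}
    if gender is not None:
        for level in pd.unique(gender):
            sel = np.asarray(gender == level)
            stratified[str(level)] = corr_frame(
                covariate_table.loc[sel], nca_table.loc[sel]
            )

    rows = []
    for cc in matrix.index:
        for pc in matrix.columns:
            if bool(flags.loc[cc, pc]) and np.isfinite(matrix.loc[cc, pc]):
                x = pd.to_numeric(covariate_table[cc], errors="coerce")
                y = pd.to_numeric(nca_table[pc], errors="coerce")
                ok = x.notna() & y.notna()
                ols = sm.OLS(y[ok].to_numpy(), sm.add_constant(x[ok].to_numpy())).fit()
                slope, pval = ols.params[1], ols.pvalues[1]
                rows.append(
                    {
                        "covariate": cc, "parameter": pc,
                        "r": matrix.loc[cc, pc], "slope": float(slope),
                        "p_value": float(pval), "significant": bool(pval < 0.05),
                    }
                )
    regressions = pd.DataFrame(rows) if rows else None
    return CorrelationScreen(
        matrix=matrix, flags=flags, stratified=stratified, regressions=regressions
    )
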