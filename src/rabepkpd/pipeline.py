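"""End-to-end analysis pipeline: simulate -> NCA -> screen -> fit -> diagnose -> PD.

``run_full_analysis`` reproduces the five-step study flow on either a
supplied trial CSV or a synthetic cohort, writing every stage's outputs
(CSV/JSON) plus a machine-readable summary.  All stage seeds derive from
one master seed so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import covsearch as covsearch_mod
from . import diagnostics, published
from .cohort import CohortSpec, generate_cohort, simulate_trial
from .datasets import TrialDataset
from .nca import compare_groups, correlation_screen, nca_single, nca_weight_normalized
from .nlme import PKModelSpec, fit_population
from .params import PopulationParameters
from .pd import SigmoidEmaxParams

logger = logging.getLogger(__name__)

__all__ = ["run_full_analysis", "replicate_effect_table", "nca_tables", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "cohort": {},                 # CohortSpec overrides
    "trial_csv": None,            # analyse an existing dataset instead
    "seed": 0,
    "fit": {"maxiter": 150, "estimate_se": False},
    "covsearch": {"enabled": True,
                  "candidates": [["Tlag", "gender"], ["Ka3", "bsa"],
                                 ["Vc", "bsa"], ["CLc", "bsa"]]},
    "vpc": {"n_simulations": 200},
    "bootstrap": {"enabled": False, "n_replicates": 50},
    "pdsim": {"n_subjects": 500, "n_replicate_cohorts": 20},
}


def _merged(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def nca_tables(dataset: TrialDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject NCA table and its gender comparison (Welch t-tests)."""
    rows = []
    for rec in dataset.subjects():
        try:
            res = nca_single(rec.times, rec.dv, rec.dose_amount, lloq=dataset.lloq)
            wres = nca_weight_normalized(
                rec.times, rec.dv, rec.dose_amount, rec.covariates.body_weight,
                lloq=dataset.lloq,
            )
        except ValueError as err:
            logger.warning("NCA skipped for subject %s: %s", rec.subject_id, err)
            continue
        rows.append({
            "ID": rec.subject_id, "gender": rec.covariates.gender,
            "weight": rec.covariates.body_weight, "bsa": rec.covariates.bsa,
            **res.as_dict(),
            "w_cmax": wres.cmax, "w_auc_inf": wres.auc_inf,
            "w_cl_f": wres.cl_f, "w_vd_f": wres.vd_f,
        })
    table = pd.DataFrame(rows)
    comparisons = []
    params = ["auc_all", "auc_inf", "cl_f", "cmax", "thalf", "mrt", "tmax",
              "tlag", "vd_f", "w_cmax", "w_auc_inf", "w_cl_f", "w_vd_f"]
    for p in params:
        groups = {
            g: table.loc[(table.gender == g) & table[p].notna(), p].to_numpy()
            for g in ("male", "female")
        }
        if min(len(v) for v in groups.values()) < 2:
            continue
        c = compare_groups(groups, parameter=p)
        comparisons.append({
            "parameter": p, "male_mean": c.means["male"], "male_sd": c.sds["male"],
            "female_mean": c.means["female"], "female_sd": c.sds["female"],
            "t": c.t_statistic, "p_value": c.p_value, "significant": c.significant,
        })
    return table, pd.DataFrame(comparisons)


def replicate_effect_table(
    pop: PopulationParameters,
    pd_params: SigmoidEmaxParams,
    config: dict | None = None,
    return_profiles: bool = False,
) -> pd.DataFrame:
    """Gender-comparison effect table from the population PK-PD simulation.

    Rows Total/Male/Female x percentile analogue (5%/50%/95% of the
    cohort-median pH profile), columns AUEC, max effect, onset-offset
    interval and duration above pH 4; values rounded to 2 decimals.
    """
    from .cohort import simulate_stratum_conc
    from .pd import EffectProfile, effect_at_concentration, effect_metrics

    cfg = _merged(config)
    pdsim = cfg["pdsim"]
    n = pdsim["n_subjects"]
    n_rep = pdsim["n_replicate_cohorts"]
    rng = np.random.default_rng(cfg["seed"])
    grid = np.arange(0.0, 10.0 + 0.005, 0.01)
    # the Total stratum pools male and female curves at the study's 24:21 ratio
    n_m_total = int(round(n * 24 / 45))
    conc_m = simulate_stratum_conc(pop, "male", 1.87, n, grid, rng)
    conc_f = simulate_stratum_conc(pop, "female", 1.58, n, grid, rng)
    ph_by_stratum = {
        "Total": effect_at_concentration(
            np.vstack([conc_m[:n_m_total], conc_f[: n - n_m_total]]), pd_params
        ),
        "Male": effect_at_concentration(conc_m, pd_params),
        "Female": effect_at_concentration(conc_f, pd_params),
    }
    rows = []
    profiles = {}
    for name, ph in ph_by_stratum.items():
        profiles[name] = (grid, np.median(ph, axis=0))
        entries: dict[str, object] = {}
        entries["p50"] = effect_metrics(
            EffectProfile(times=grid, pH=np.median(ph, axis=0))
        )
        if n_rep > 0:
            med_profiles = np.empty((n_rep, grid.size))
            for r in range(n_rep):
                sub = rng.choice(len(ph), size=45, replace=True)
                med_profiles[r] = np.median(ph[sub], axis=0)
            for label, q in (("p5", 5.0), ("p95", 95.0)):
                entries[label] = effect_metrics(
                    EffectProfile(times=grid, pH=np.percentile(med_profiles, q, axis=0))
                )
        for label in ("p5", "p50", "p95"):
            m = entries.get(label)
            if m is None:
                continue
            rows.append({
                "population": name, "percentile": label,
                "auec": round(m.auec, 2), "max_effect": round(m.max_effect, 2),
                "onset": None if m.onset is None else round(m.onset, 2),
                "offset": None if m.offset is None else round(m.offset, 2),
                "duration": round(m.duration, 2),
            })
    table = pd.DataFrame(rows)
    if return_profiles:
        return table, profiles
    return table


def run_full_analysis(config: dict | None = None, outdir: str | Path = "results") -> dict:
    """Execute the five analysis steps in order and write a report bundle.

    Steps: (1) obtain data (simulate or load), NCA + gender comparison;
    (2) covariate-parameter correlation screen; (3) population PK fit
    (+ optional covariate search); (4) diagnostics (VPC, CWRES, optional
    bootstrap); (5) gender-stratified PD simulation and effect table.
    Returns the summary dict (also written as ``report.json``).
    """
    cfg = _merged(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(cfg["seed"])
    stage_seeds = [int(s.generate_state(1)[0] % 2**31) for s in master.spawn(6)]
    summary: dict = {"config": cfg, "stages": {}}
    stage = "simulate"
    try:
        # -- stage 1: data -------------------------------------------------
        if cfg["trial_csv"]:
            dataset = TrialDataset.from_csv(cfg["trial_csv"])
            cohort = None
        else:
            spec = CohortSpec(**cfg["cohort"], seed=stage_seeds[0])
            cohort = generate_cohort(spec)
            gen_pop = published.published_pk()
            dataset = simulate_trial(cohort, gen_pop, spec, seed=stage_seeds[0])
            cohort.to_csv(out / "cohort.csv", index=False)
        dataset.to_csv(out / "trial.csv")
        summary["stages"]["simulate"] = {
            "n_subjects": dataset.n_subjects, "n_observations": dataset.n_observations,
        }

        stage = "nca"
        nca_table, comparison = nca_tables(dataset)
        nca_table.to_csv(out / "nca.csv", index=False)
        comparison.to_csv(out / "nca_gender_comparison.csv", index=False)
        summary["stages"]["nca"] = {
            "n_analysed": len(nca_table),
            "mean_cl_f": float(nca_table.cl_f.mean()),
            "significant": comparison.loc[comparison.significant, "parameter"].tolist(),
        }

        stage = "screen"
        cov_cols = nca_table[["weight", "bsa"]]
        par_cols = nca_table[["auc_inf", "cl_f", "cmax", "tmax", "tlag", "thalf"]]
        screen = correlation_screen(
            cov_cols.reset_index(drop=True), par_cols.reset_index(drop=True),
            gender=nca_table.gender.reset_index(drop=True),
        )
        screen.matrix.to_csv(out / "correlation_matrix.csv")
        from . import plots
        plots.plot_correlation_heatmap(screen.matrix, out / "correlation_heatmap.png")
        summary["stages"]["screen"] = {
            "flagged": int(screen.flags.to_numpy().sum()),
        }

        stage = "fit"
        fit = fit_population(
            dataset, PKModelSpec(), seed=stage_seeds[1], **cfg["fit"]
        )
        (out / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
        summary["stages"]["fit"] = {"ofv": fit.ofv, "aic": fit.aic,
                                    "converged": fit.converged}

        stage = "covsearch"
        if cfg["covsearch"]["enabled"]:
            sel = covsearch_mod.stepwise_covariate_search(
                dataset,
                candidates=tuple(tuple(c) for c in cfg["covsearch"]["candidates"]),
                seed=stage_seeds[2],
            )
            sel.log.to_csv(out / "covsearch_log.csv", index=False)
            fit = sel.final_fit
            (out / "fit_final.json").write_text(json.dumps(fit.to_dict(), indent=2))
            summary["stages"]["covsearch"] = {
                "selected": ["~".join(t) for t in sel.selected],
                "ofv": fit.ofv,
            }

        stage = "diagnostics"
        vpc_res = diagnostics.vpc(
            dataset, fit, n_simulations=cfg["vpc"]["n_simulations"],
            seed=stage_seeds[3],
        )
        vpc_res.bands.to_csv(out / "vpc_bands.csv", index=False)
        plots.plot_vpc(vpc_res.bands, out / "vpc.png")
        gof = diagnostics.gof_diagnostics(dataset, fit, seed=stage_seeds[3])
        gof.to_csv(out / "residuals.csv", index=False)
        plots.plot_gof(gof, out / "gof.png")
        summary["stages"]["diagnostics"] = {
            "vpc_coverage": vpc_res.coverage,
            "cwres_max_abs": float(gof.CWRES.abs().max()),
        }
        if cfg["bootstrap"]["enabled"]:
            boot = diagnostics.bootstrap(
                dataset, fit, n_replicates=cfg["bootstrap"]["n_replicates"],
                seed=stage_seeds[4],
            )
            boot.table.to_csv(out / "bootstrap.csv")
            summary["stages"]["bootstrap"] = {
                "n_failed": boot.n_failed, "reliable": boot.reliable,
            }

        stage = "pdsim"
        effect_table, profiles = replicate_effect_table(
            fit.population_parameters if cfg["covsearch"]["enabled"] else published.published_pk(),
            published.published_pd(),
            {"seed": stage_seeds[5], "pdsim": cfg["pdsim"]},
            return_profiles=True,
        )
        effect_table.to_csv(out / "effect_table.csv", index=False)
        plots.plot_ph_profiles(profiles, out / "ph_profiles.png")
        med = effect_table[effect_table.percentile == "p50"].set_index("population")
        summary["stages"]["pdsim"] = {
            "male_onset": med.loc["Male", "onset"],
            "female_onset": med.loc["Female", "onset"],
            "male_duration": med.loc["Male", "duration"],
            "female_duration": med.loc["Female", "duration"],
        }
    except Exception as err:
        summary["failed_stage"] = stage
        summary["error"] = str(err)
        (out / "report.json").write_text(json.dumps(summary, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    (out / "report.json").write_text(json.dumps(summary, indent=2, default=str))
    lines = ["rabeprazole PK-PD analysis summary", "=" * 34]
    for name, info in summary["stages"].items():
        lines.append(f"{name}: {json.dumps(info, default=str)}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return summary
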