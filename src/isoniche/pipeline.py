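"""End-to-end analysis pipeline.

Chains the stages

    simulate/load -> prep -> niche metrics -> bootstrap + Bayesian SEA
    -> variance & mixed models (H1) -> anomaly models with AIC (H2)
    -> logistic stress discriminator with ROC (H3)

writing every numeric table to ``out_dir`` (CSV + JSON) so that each stage
can also be rerun independently from the previous stage's exports.  One
global seed deterministically spawns per-stage substreams; the same config
and seed reproduce every export byte for byte (the run log carries no
timestamps for the same reason).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

import isoniche
from isoniche import io as iio
from isoniche import inference, niche, prep, simulate
from isoniche.inference import ClassifierReport, ModelFit, VarianceTestResult

logger = logging.getLogger(__name__)

#: fixed substream ids so stages can be rerun independently
_STAGE_IDS = {
    "simulate": 11,
    "bootstrap": 23,
    "bayes": 37,
    "models": 41,
    "classify": 53,
}

#: default stressed-treatment labels per experiment (low-quality food is
#: the nutritional stress in experiment 2)
DEFAULT_STRESSED = {1: ["exposure"], 2: ["reference", "lignin"]}

_H1_ENDPOINTS = {
    1: ["body_mass", "fecundity", "ve_pct", "d15n", "d13c_corr"],
    2: ["rna_dna", "cn_ratio", "body_mass", "d15n", "d13c_corr"],
}
_H2_PREDICTORS = {
    1: ["body_mass", "parasite", "fecundity", "ve_pct", "mortality"],
    2: ["body_mass", "rna_dna", "cn_ratio", "oxygen_depth", "mortality"],
}
_H3_PREDICTORS = {
    1: ["d15n_anom", "d13c_anom", "ed", "fecundity", "ve_pct"],
    2: ["d15n_anom", "d13c_anom", "ed", "body_mass", "rna_dna", "cn_ratio"],
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineResult:
    """In-memory mirror of everything the pipeline exports."""

    config: iio.RunConfig
    specimens: pd.DataFrame
    mesocosms: pd.DataFrame
    prepared: pd.DataFrame
    group_metrics: pd.DataFrame
    bootstrap: dict[str, dict[str, niche.BootstrapSummary]]
    posteriors: list[niche.PosteriorSeaDraws]
    comparisons: list[niche.SeaComparison]
    levene: list[VarianceTestResult]
    ed_model: ModelFit | None
    physiology_models: dict[str, ModelFit]
    h2_models: dict[str, tuple[ModelFit, pd.DataFrame]]
    classifier: ClassifierReport | None
    provenance: dict = field(default_factory=dict)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator spawned from the global seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, _STAGE_IDS[stage])))


def _provenance(config: iio.RunConfig) -> dict:
    return {
        "package": "isoniche",
        "version": isoniche.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }


def _comment(config: iio.RunConfig) -> str:
    return f"isoniche {isoniche.__version__} seed={config.seed}"


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict("records"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_json(data: Any, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n")


def _out(config: iio.RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _need(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(
            f"missing artifact {path.name}: run the '{producer}' stage first"
        )
    return path


def _stressed_labels(config: iio.RunConfig) -> list[str]:
    return list(config.stressed_treatments) or DEFAULT_STRESSED[config.experiment]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: iio.RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = _out(config)
    rng = stage_rng(config.seed, "simulate")
    spec = simulate.default_spec(config.experiment)
    specimens, mesocosms = simulate.generate_experiment(spec, rng)
    iio.write_specimens(specimens, out / "specimens.csv", _comment(config))
    iio.write_mesocosms(mesocosms, out / "mesocosms.csv", _comment(config))
    logger.info("simulate: %d specimens in %d mesocosms", len(specimens), len(mesocosms))
    return specimens, mesocosms


def _load_inputs(config: iio.RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = _out(config)
    spath = config.specimen_path or _need(out / "specimens.csv", "simulate")
    mpath = config.mesocosm_path or (out / "mesocosms.csv")
    specimens, mesocosms = iio.read_specimens(
        spath, config, mesocosm_path=mpath if Path(mpath).exists() else None
    )
    return iio.specimens_to_frame(specimens), iio.mesocosms_to_frame(mesocosms)


def stage_prep(config: iio.RunConfig) -> pd.DataFrame:
    """Outlier replacement, lipid correction, anomalies, ED, covariates."""
    out = _out(config)
    specimens, mesocosms = _load_inputs(config)
    if config.outlier_ids:
        specimens, log = iio.replace_outliers(
            specimens, config.outlier_ids, config.outlier_variables
        )
        for line in log:
            logger.info("prep: %s", line)
    prepared, group_means = prep.prepare_isotopes(specimens)
    with np.errstate(invalid="ignore", divide="ignore"):
        fec = prepared["fecundity"].astype(float)
        prepared["ve_pct"] = np.where(
            fec > 0, prepared["viable_embryos"].astype(float) / fec, np.nan
        )
    if not mesocosms.empty:
        mcov = mesocosms.copy()
        mcov["mortality"] = 100.0 - mcov["survival_pct"].astype(float)
        prepared = prepared.merge(
            mcov[["mesocosm", "survival_pct", "mortality", "oxygen_depth"]],
            on="mesocosm",
            how="left",
        )
    prepared["stressed"] = (
        prepared["treatment"].isin(_stressed_labels(config)).astype(int)
    )
    iio._write_csv(prepared, out / "prepared.csv", _comment(config))
    iio._write_csv(group_means, out / "group_means.csv", _comment(config))
    return prepared


def _read_prepared(config: iio.RunConfig) -> pd.DataFrame:
    out = _out(config)
    path = _need(out / "prepared.csv", "prep")
    df = pd.read_csv(path, comment="#")
    return df


def _metric_groups(config: iio.RunConfig, prepared: pd.DataFrame) -> dict[str, np.ndarray]:
    """Treatment-level point clouds (corrected d13C, d15N), with the
    parasitised individuals of stressed groups split out on request."""
    df = prepared
    groups: dict[str, np.ndarray] = {}
    for label, sub in df.groupby("treatment", sort=False):
        if (
            config.split_parasitized
            and sub["parasite"].notna().any()
            and label in _stressed_labels(config)
        ):
            par = sub[sub["parasite"] == True]  # noqa: E712
            rest = sub[sub["parasite"] != True]  # noqa: E712
            if len(par) >= 3:
                groups[f"{label}_parasitized"] = par[["d13c_corr", "d15n"]].to_numpy()
                sub = rest
        if len(sub) >= 3:
            groups[label] = sub[["d13c_corr", "d15n"]].to_numpy()
        else:
            logger.info("metrics: group %s has n=%d < 3, skipped", label, len(sub))
    return groups


def stage_metrics(config: iio.RunConfig) -> tuple[pd.DataFrame, dict]:
    out = _out(config)
    prepared = _read_prepared(config)
    groups = _metric_groups(config, prepared)
    rows = []
    for label, xy in groups.items():
        m = niche.niche_metrics(xy)
        rows.append({"group": label, **m.as_dict()})
    metrics_df = pd.DataFrame(rows)
    iio._write_csv(metrics_df, out / "niche_metrics.csv", _comment(config))

    rng = stage_rng(config.seed, "bootstrap")
    boot = niche.bootstrap_metrics(groups, reps=config.bootstrap_reps, rng=rng)
    long_rows = []
    summary_rows = []
    for label, by_metric in boot.items():
        for name, s in by_metric.items():
            summary_rows.append(
                {
                    "group": label,
                    "metric": name,
                    "resample_n": s.resample_n,
                    "reps": s.reps,
                    "mean": s.mean,
                    **{
                        f"q{level}_{side}": s.intervals[level][i]
                        for level in niche.INTERVAL_LEVELS
                        for i, side in enumerate(("lo", "hi"))
                    },
                }
            )
            long_rows.append(
                pd.DataFrame(
                    {
                        "group": label,
                        "metric": name,
                        "rep": np.arange(s.reps),
                        "value": s.draws,
                    }
                )
            )
    iio._write_csv(
        pd.DataFrame(summary_rows), out / "bootstrap_summary.csv", _comment(config)
    )
    iio._write_csv(
        pd.concat(long_rows, ignore_index=True),
        out / "bootstrap_draws.csv",
        _comment(config),
    )
    return metrics_df, boot


def stage_compare(config: iio.RunConfig) -> tuple[list, list]:
    out = _out(config)
    prepared = _read_prepared(config)
    groups = _metric_groups(config, prepared)
    rng = stage_rng(config.seed, "bayes")
    posteriors = [
        niche.bayesian_sea(xy, n_draws=config.posterior_draws, rng=rng, label=label)
        for label, xy in groups.items()
    ]
    comparisons = niche.pairwise_sea(posteriors)
    post_df = pd.concat(
        [
            pd.DataFrame(
                {"group": p.label, "draw": np.arange(p.n_draws), "sea_b": p.draws}
            )
            for p in posteriors
        ],
        ignore_index=True,
    )
    iio._write_csv(post_df, out / "posterior_sea.csv", _comment(config))
    _write_json(
        {
            "provenance": _provenance(config),
            "posterior_summaries": [
                {
                    "group": p.label,
                    "mean": p.mean,
                    "intervals": {str(k): v for k, v in p.intervals.items()},
                }
                for p in posteriors
            ],
            "comparisons": [
                {
                    "a": c.label_a,
                    "b": c.label_b,
                    "p_a_exceeds_b": c.p_exceed,
                    "significant": c.significant,
                    "level": c.level,
                }
                for c in comparisons
            ],
        },
        out / "sea_comparisons.json",
    )
    return posteriors, comparisons


def _levene_groups(
    config: iio.RunConfig, prepared: pd.DataFrame, variable: str
) -> dict[str, np.ndarray]:
    df = prepared[~prepared["is_initial"].astype(bool)]
    out = {}
    for label, sub in df.groupby("treatment", sort=False):
        v = sub[variable].astype(float).dropna().to_numpy()
        if len(v) >= 2:
            out[label] = v
    return out


def stage_models(config: iio.RunConfig):
    """H1 variance tests + ED/physiology mixed models, H2 anomaly models."""
    out = _out(config)
    prepared = _read_prepared(config)
    final = prepared[~prepared["is_initial"].astype(bool)].copy()
    final["meso_group"] = final["treatment"].astype(str) + ":" + final["mesocosm"].astype(str)

    levene_results = []
    for variable in _H1_ENDPOINTS[config.experiment]:
        if variable not in final.columns or final[variable].isna().all():
            continue
        groups = _levene_groups(config, prepared, variable)
        if len(groups) < 2:
            continue
        levene_results.append(
            inference.levene_test(groups, center=config.levene_center, variable=variable)
        )
    iio._write_csv(
        pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "statistic": r.statistic,
                    "df_num": r.df_num,
                    "df_den": r.df_den,
                    "p_value": r.p_value,
                    "center": r.center,
                }
                for r in levene_results
            ]
        ),
        out / "levene.csv",
        _comment(config),
    )

    # H1: treatment effect on the distance to centroid
    if config.experiment == 1:
        ed_fixed = ["stressed", "survival_pct"]
    else:
        ed_fixed = ["C(treatment, Treatment(reference='reference'))"]
    try:
        ed_model = inference.fit_mixed_model(
            final, "ed", ed_fixed, group="meso_group", family="gaussian"
        )
    except (inference.ConvergenceError, ValueError) as err:
        raise StageError(f"models stage failed on the ED mixed model: {err}") from err

    # physiology endpoints (Poisson for counts, Gaussian otherwise)
    physiology_models: dict[str, ModelFit] = {}
    phys = {
        1: [("body_mass", "gaussian"), ("ve_pct", "gaussian"), ("fecundity", "poisson")],
        2: [("body_mass", "gaussian"), ("rna_dna", "gaussian"), ("cn_ratio", "gaussian")],
    }[config.experiment]
    treat_term = "C(treatment, Treatment(reference='reference'))"
    for response, family in phys:
        if response not in final.columns or final[response].isna().all():
            continue
        fixed = [treat_term]
        if config.experiment == 1 and final["parasite"].notna().any():
            fixed = [treat_term, "parasite"]
        try:
            physiology_models[response] = inference.fit_mixed_model(
                final, response, fixed, group="meso_group", family=family
            )
        except (inference.ConvergenceError, ValueError) as err:
            logger.info("models: %s mixed model skipped (%s)", response, err)

    # H2: most parsimonious anomaly models
    h2_models: dict[str, tuple[ModelFit, pd.DataFrame]] = {}
    predictors = [
        p for p in _H2_PREDICTORS[config.experiment]
        if p in final.columns and final[p].notna().any()
    ]
    h2_frame = final.copy()
    if "parasite" in predictors:
        h2_frame["parasite"] = h2_frame["parasite"].astype(float)
    for response in ("d15n_anom", "d13c_anom"):
        candidates = list(inference.all_subsets(predictors))
        best, ranking = inference.select_by_aic(h2_frame, response, candidates)
        h2_models[response] = (best, ranking)
    iio._write_csv(
        pd.concat(
            [
                best.params.assign(response=resp, term=best.params.index)
                for resp, (best, _) in h2_models.items()
            ],
            ignore_index=True,
        )[["response", "term", "estimate", "se", "stat", "p"]],
        out / "models_h2.csv",
        _comment(config),
    )
    _write_json(
        {
            "provenance": _provenance(config),
            "ed_model": _model_dict(ed_model),
            "physiology_models": {k: _model_dict(v) for k, v in physiology_models.items()},
            "h2_models": {
                resp: {
                    "best": _model_dict(best),
                    "ranking": ranking.head(10),
                }
                for resp, (best, ranking) in h2_models.items()
            },
        },
        out / "models.json",
    )
    return levene_results, ed_model, physiology_models, h2_models


def _model_dict(m: ModelFit) -> dict:
    return {
        "formula": m.formula,
        "family": m.family,
        "link": m.link,
        "coefficients": m.params.reset_index().rename(columns={"index": "term"}),
        "loglik": m.loglik,
        "aic": m.aic,
        "n": m.n,
        "dropped_n": m.dropped_n,
        "random_variance": m.random_variance,
        "resid_variance": m.resid_variance,
        "boundary": m.boundary,
    }


def stage_classify(config: iio.RunConfig) -> ClassifierReport:
    """H3: logistic discrimination of stressed vs reference populations."""
    out = _out(config)
    prepared = _read_prepared(config)
    df = prepared[~prepared["is_initial"].astype(bool)].copy()
    if config.excluded_treatments:
        df = df[~df["treatment"].isin(config.excluded_treatments)]
    if df["stressed"].nunique() < 2:
        raise StageError("classify stage needs both stressed and reference records")
    if config.zscore_cn_within_treatment and "cn_ratio" in df.columns:
        df["cn_ratio"] = prep.zscore_within_group(
            df["cn_ratio"].to_numpy(float), df["treatment"].to_numpy()
        )
    predictors = [
        p for p in _H3_PREDICTORS[config.experiment]
        if p in df.columns and df[p].notna().any()
    ]
    candidates = list(inference.all_subsets(predictors))
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", inference.SeparationWarning)
        best, ranking = inference.select_by_aic(
            df, "stressed", candidates, fit=inference.fit_logistic
        )
        report = inference.classify_stress(
            df.dropna(subset=["stressed", *predictors]),
            "stressed",
            best.predictors,
            standardize=config.standardize_predictors,
            cutoff=config.roc_cutoff,
        )
    roc_df = pd.DataFrame(
        {"fpr": report.roc.fpr, "tpr": report.roc.tpr, "threshold": report.roc.thresholds}
    )
    iio._write_csv(roc_df, out / "roc_points.csv", _comment(config))
    _write_json(
        {
            "provenance": _provenance(config),
            "response": report.response,
            "predictors": report.predictors,
            "coefficients": report.params.reset_index().rename(columns={"index": "term"}),
            "aic": report.aic,
            "auc": report.auc,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "cutoff": report.cutoff,
            "separation": report.separation,
            "n": report.n,
            "aic_ranking": ranking.head(10),
        },
        out / "classifier.json",
    )
    return report


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: iio.RunConfig) -> PipelineResult:
    """Run every stage and write all exports plus ``summary.json``.

    Any stage failure raises :class:`StageError` naming the stage; partial
    outputs already written are marked incomplete in ``summary.json``.
    """
    out = _out(config)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("isoniche")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict[str, Any] = {"provenance": _provenance(config), "complete": False}
    try:
        if config.simulate or not config.specimen_path:
            specimens, mesocosms = _run_stage("simulate", stage_simulate, config)
        else:
            specimens, mesocosms = _run_stage("load", _load_inputs, config)
            iio.write_specimens(specimens, out / "specimens.csv", _comment(config))
            iio.write_mesocosms(mesocosms, out / "mesocosms.csv", _comment(config))
        prepared = _run_stage("prep", stage_prep, config)
        metrics_df, boot = _run_stage("metrics", stage_metrics, config)
        posteriors, comparisons = _run_stage("compare", stage_compare, config)
        levene_results, ed_model, phys_models, h2_models = _run_stage(
            "models", stage_models, config
        )
        classifier = _run_stage("classify", stage_classify, config)
        if config.make_plots:
            from isoniche import viz

            viz.biplot(prepared, out / "biplot.png")
            viz.sea_density_plot(posteriors, out / "sea_density.png")
        summary.update(
            {
                "complete": True,
                "n_specimens": len(prepared),
                "groups": metrics_df["group"].tolist(),
                "seac": dict(zip(metrics_df["group"], metrics_df["SEAc"])),
                "levene": {
                    r.variable: {"statistic": r.statistic, "p": r.p_value}
                    for r in levene_results
                },
                "ed_model_formula": ed_model.formula,
                "classifier_auc": classifier.auc,
                "classifier_predictors": classifier.predictors,
            }
        )
        return PipelineResult(
            config=config,
            specimens=specimens,
            mesocosms=mesocosms,
            prepared=prepared,
            group_metrics=metrics_df,
            bootstrap=boot,
            posteriors=posteriors,
            comparisons=comparisons,
            levene=levene_results,
            ed_model=ed_model,
            physiology_models=phys_models,
            h2_models=h2_models,
            classifier=classifier,
            provenance=summary["provenance"],
        )
    finally:
        _write_json(summary, out / "summary.json")
        root.removeHandler(handler)
        handler.close()


def _run_stage(name: str, fn, config: iio.RunConfig):
    try:
        return fn(config)
    except StageError:
        raise
    except Exception as err:
        raise StageError(f"stage '{name}' failed: {err}") from err
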