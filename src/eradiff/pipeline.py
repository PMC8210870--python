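"""End-to-end orchestration: inputs -> filtered clr table -> ordination
statistics -> sparse discriminant selection -> exposure covariates ->
covariate-adjusted regressions -> robustness screen -> report.

The report is a plain JSON-serializable dict; rerunning with the same
inputs and config reproduces it byte-for-byte (every permutation test gets
a sub-seed derived deterministically from the master seed and its stage
name).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from eradiff import differential, exposure, feature_table, ordination, splsda
from eradiff.feature_table import CountTable, InputError

logger = logging.getLogger("eradiff")


@dataclass
class PipelineConfig:
    pseudocount: float = 1.0
    min_sample_reads: int = 500
    min_taxon_frac: float = 0.0001
    keep: int = 50
    n_components: int = 2
    decay: float = 2.0
    n_permutations: int = 999
    effect_threshold: float = 2.0
    q_threshold: float = 0.05
    scale_splsda: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: SHA-256 of ``"{seed}:{stage}"``."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def per_class_era_ttests(summaries: pd.DataFrame, era) -> pd.DataFrame:
    """Welch two-sample t-test per antibiotic class on decayed scores by era.

    When both era groups have zero variance the p value is reported as 1
    (equal means, with a warning) or 0 (separated constants).
    """
    era = np.asarray(era)
    if len(set(era.tolist())) < 2:
        raise InputError("both eras must be present for era t-tests")
    rows = []
    for cls in summaries.columns:
        a = summaries.loc[era == "covid", cls].values.astype(float)
        b = summaries.loc[era == "pre", cls].values.astype(float)
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if a.mean() == b.mean():
                warnings.warn(
                    f"zero variance in both eras for {cls}; p set to 1", stacklevel=2
                )
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "antibiotic_class": cls,
                "t": float(t),
                "p": float(p),
                "mean_covid": float(a.mean()),
                "mean_pre": float(b.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("antibiotic_class")


@dataclass
class PipelineReport:
    config: dict
    stages: dict = field(default_factory=dict)
    final_taxa: dict = field(default_factory=dict)

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(
            {"config": self.config, "stages": self.stages, "final_taxa": self.final_taxa},
            indent=indent,
            sort_keys=True,
            default=_jsonify,
        )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(
    table: CountTable,
    exposures: pd.DataFrame,
    config: PipelineConfig,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Run every analysis stage on a cohort and return the report.

    Stage order: filter -> clr -> Aitchison PCA + era PERMANOVA -> sPLS-DA
    (top ``keep``) -> leave-one-out stability (100% set) -> exposure
    encoding and decayed scores -> per-class era t-tests -> exposure PCA
    covariates -> per-taxon regressions -> BH -> volcano ->
    leave-one-patient-out -> week-binned dispersion test.
    """
    report = PipelineReport(config=config.to_dict())
    stages = report.stages

    # -- filter + clr ------------------------------------------------------
    filtered = feature_table.filter_table(
        table,
        min_sample_reads=config.min_sample_reads,
        min_taxon_frac=config.min_taxon_frac,
    )
    stages["filter"] = {
        "n_samples_before": table.n_samples,
        "n_taxa_before": table.n_taxa,
        "n_samples_after": filtered.n_samples,
        "n_taxa_after": filtered.n_taxa,
    }
    logger.info("filter: %s", stages["filter"])
    clr = feature_table.clr_transform(filtered, pseudocount=config.pseudocount)
    meta = filtered.metadata
    era = meta["era"].values

    # -- ordination --------------------------------------------------------
    dist = feature_table.aitchison_distance(clr)
    n_pcs = min(3, clr.values.shape[0] - 1, clr.values.shape[1])
    pca_res = ordination.pca(clr.values.values, n_components=n_pcs)
    stages["pca"] = {
        "explained_variance_ratio": pca_res.explained_variance_ratio.tolist(),
        "scores_pc1": pca_res.scores[:, 0].tolist(),
    }
    perm = ordination.permanova(
        dist,
        era,
        n_perm=config.n_permutations,
        seed=stage_seed(config.seed, "permanova_era"),
    )
    stages["permanova_era"] = {
        "f": perm.f,
        "r2": perm.r2,
        "p": perm.p,
        "n_permutations": perm.n_permutations,
        "seed": perm.seed,
    }
    logger.info("PERMANOVA era: F=%.3f R2=%.4f p=%.4g", perm.f, perm.r2, perm.p)

    # -- sparse discriminant analysis -------------------------------------
    keep = min(config.keep, clr.values.shape[1])
    model = splsda.fit_splsda(
        clr.values,
        era,
        n_components=config.n_components,
        keep_per_component=keep,
        scale=config.scale_splsda,
        positive_class="covid",
    )
    loadings = splsda.top_loadings(model, component=1, k=keep)
    auroc_apparent = splsda.auroc(model.scores[:, 0], era, positive_class="covid")
    stability = splsda.loocv_stability(
        clr.values,
        era,
        n_components=1,
        keep=keep,
        scale=config.scale_splsda,
        positive_class="covid",
    )
    auroc_loocv = splsda.auroc(stability.predicted_scores, era, positive_class="covid")
    stages["splsda"] = {
        "keep": keep,
        "top_loadings": loadings.to_dict(orient="records"),
        "auroc_apparent": auroc_apparent,
        "auroc_loocv": auroc_loocv,
        "n_folds": stability.n_folds,
        "stable_set": stability.stable_set,
        "n_stable": len(stability.stable_set),
        "stability": {k: float(v) for k, v in stability.frequencies.items()},
    }
    logger.info(
        "sPLS-DA: %d/%d features stable at 100%%; AUROC apparent=%.3f loocv=%.3f",
        len(stability.stable_set), keep, auroc_apparent, auroc_loocv,
    )

    # -- antibiotic exposure ----------------------------------------------
    scores = exposure.exposure_matrix(meta, exposures, decay=config.decay)
    ttests = per_class_era_ttests(scores, era)
    covariates, exp_pca = exposure.exposure_pca_covariates(scores)
    if scores.values.std(axis=0).sum() > 0:
        exp_dist = feature_table.DistanceMatrix(
            values=np.sqrt(
                ((scores.values[:, None, :] - scores.values[None, :, :]) ** 2).sum(axis=2)
            ),
            ids=list(scores.index),
        )
        exp_perm = ordination.permanova(
            exp_dist,
            era,
            n_perm=config.n_permutations,
            seed=stage_seed(config.seed, "permanova_exposure"),
        )
        exp_perm_dict = {"f": exp_perm.f, "r2": exp_perm.r2, "p": exp_perm.p}
    else:
        exp_perm_dict = None
    stages["exposure"] = {
        "decay": config.decay,
        "era_ttests": ttests.reset_index().to_dict(orient="records"),
        "permanova": exp_perm_dict,
        "pca_explained_variance_ratio": (
            exp_pca.explained_variance_ratio.tolist() if exp_pca is not None else None
        ),
    }

    # -- differential abundance -------------------------------------------
    candidates = stability.stable_set
    if candidates:
        results = differential.fit_taxon_models(
            clr,
            candidates,
            era,
            meta["collection_day"].values,
            covariates["abx_pc1"].values,
            covariates["abx_pc2"].values,
        )
        covid_taxa, pre_taxa = differential.volcano_select(
            results, config.effect_threshold, config.q_threshold
        )
        lopo = differential.leave_one_patient_out(
            clr,
            meta,
            candidates,
            covariates["abx_pc1"].values,
            covariates["abx_pc2"].values,
            effect_threshold=config.effect_threshold,
            q_threshold=config.q_threshold,
        )
        stages["regression"] = {
            "n_candidates": len(candidates),
            "table": results.reset_index().to_dict(orient="records"),
        }
        stages["volcano"] = {"covid_taxa": covid_taxa, "pre_taxa": pre_taxa}
        stages["lopo"] = {
            "n_runs": lopo.n_runs,
            "stable_taxa": lopo.stable_taxa,
            "fractions": {k: float(v) for k, v in lopo.fractions.items()},
        }
        robust = sorted(set(covid_taxa + pre_taxa) & set(lopo.stable_taxa))
    else:
        stages["regression"] = {"n_candidates": 0, "table": []}
        stages["volcano"] = {"covid_taxa": [], "pre_taxa": []}
        stages["lopo"] = {"n_runs": 0, "stable_taxa": [], "fractions": {}}
        covid_taxa, pre_taxa, robust = [], [], []

    report.final_taxa = {
        "covid": covid_taxa,
        "pre": pre_taxa,
        "robust": robust,
    }
    logger.info("final taxa: %s", report.final_taxa)

    # -- week-binned dispersion (COVID-era samples over chemotherapy weeks) -
    covid_mask = era == "covid"
    stages["dispersion_weeks"] = None
    if covid_mask.sum() >= 4:
        weeks = ordination.week_bins(meta.loc[covid_mask, "collection_day"].values)
        sub_ids = [sid for sid, m in zip(clr.sample_ids, covid_mask) if m]
        sub = feature_table.DistanceMatrix(
            values=dist.values[np.ix_(covid_mask, covid_mask)], ids=sub_ids
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # singleton week bins are expected
                disp = ordination.dispersion_test(
                    sub,
                    weeks,
                    n_perm=config.n_permutations,
                    seed=stage_seed(config.seed, "dispersion_weeks"),
                )
            stages["dispersion_weeks"] = {
                "f": disp.f,
                "p": disp.p,
                "n_permutations": disp.n_permutations,
            }
        except InputError as exc:
            logger.warning("week-binned dispersion skipped: %s", exc)

    if outdir is not None:
        _write_outputs(Path(outdir), report, loadings, stability, results=stages["regression"])
    return report


def _write_outputs(outdir: Path, report: PipelineReport, loadings, stability, results) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    loadings.to_csv(outdir / "splsda_loadings.tsv", sep="\t", index=False)
    stability.frequencies.rename("stability").to_csv(outdir / "splsda_stability.tsv", sep="\t")
    pd.DataFrame(results["table"]).to_csv(outdir / "regression.tsv", sep="\t", index=False)
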