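"""Per-taxon covariate-adjusted era regressions and robustness screens.

For each candidate taxon an ordinary-least-squares model predicts its
clr abundance from era (pre=0, covid=1), collection day, and the first two
antibiotic-history PCA axes.  Era p values are BH-corrected across the
candidate set; taxa pass the volcano rule when |beta_era| > 2 and q < 0.05
(strict).  The leave-one-patient-out screen refits everything on each
patient-deleted subset and keeps taxa passing in every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from eradiff.feature_table import ClrMatrix, InputError

DESIGN_COLUMNS = ("intercept", "era", "collection_day", "abx_pc1", "abx_pc2")


@dataclass
class RobustnessReport:
    fractions: pd.Series  # per-taxon fraction of runs passing the volcano rule
    n_runs: int  # one run per distinct patient
    stable_taxa: list[str]  # taxa passing in every run
    per_run: pd.DataFrame  # runs x taxa boolean pass matrix


def _design_matrix(era, collection_day, abx_pc1, abx_pc2) -> np.ndarray:
    era = np.asarray(era)
    if era.dtype.kind in "OU":
        era = (era == "covid").astype(float)
    else:
        era = era.astype(float)
    return np.column_stack(
        [
            np.ones(len(era)),
            era,
            np.asarray(collection_day, dtype=float),
            np.asarray(abx_pc1, dtype=float),
            np.asarray(abx_pc2, dtype=float),
        ]
    )


def fit_taxon_models(
    clr: ClrMatrix,
    candidate_taxa,
    era,
    collection_day,
    abx_pc1,
    abx_pc2,
) -> pd.DataFrame:
    """OLS era-effect models for each candidate taxon.

    Returns one row per taxon with ``beta_era``, its standard error,
    two-sided t-test ``p``, BH-adjusted ``q``, the covariate coefficients
    and the sample count.  BH is applied across the candidate taxa only.
    """
    candidate_taxa = list(candidate_taxa)
    missing = set(candidate_taxa) - set(clr.taxa)
    if missing:
        raise InputError(f"candidate taxa absent from clr matrix: {sorted(missing)}")
    era_arr = np.asarray(era)
    if len(set(era_arr.tolist())) < 2:
        raise InputError("both eras must be present to estimate an era effect")
    x = _design_matrix(era_arr, collection_day, abx_pc1, abx_pc2)
    n, k = x.shape
    if n <= k + 1:
        raise InputError(f"too few samples (n={n}) for a {k}-parameter model")
    if np.linalg.matrix_rank(x) < k:
        raise InputError("rank-deficient design matrix (collinear covariates)")

    y = clr.values[candidate_taxa].values  # n x m
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # k x m
    resid = y - x @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # k x m
    with np.errstate(divide="ignore", invalid="ignore"):
        t_era = beta[1] / se[1]
    p = 2.0 * stats.t.sf(np.abs(t_era), dof)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "taxon": candidate_taxa,
            "beta_era": beta[1],
            "se": se[1],
            "p": p,
            "q": q,
            "beta_day": beta[2],
            "beta_abx_pc1": beta[3],
            "beta_abx_pc2": beta[4],
            "n_samples": n,
        }
    ).set_index("taxon")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def volcano_select(
    results: pd.DataFrame,
    effect_threshold: float = 2.0,
    q_threshold: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Split strong-significant taxa by era association.

    Strict thresholds: |beta_era| > effect_threshold and q < q_threshold.
    Positive coefficients are COVID-era-associated, negative pre-era.
    """
    strong = results[(results["beta_era"].abs() > effect_threshold) & (results["q"] < q_threshold)]
    covid_taxa = sorted(strong.index[strong["beta_era"] > 0].tolist())
    pre_taxa = sorted(strong.index[strong["beta_era"] < 0].tolist())
    return covid_taxa, pre_taxa


def leave_one_patient_out(
    clr: ClrMatrix,
    metadata: pd.DataFrame,
    candidate_taxa,
    abx_pc1,
    abx_pc2,
    effect_threshold: float = 2.0,
    q_threshold: float = 0.05,
) -> RobustnessReport:
    """Refit every candidate model on each patient-deleted subset.

    One run per distinct patient, dropping all of that patient's samples.
    BH is re-applied within each run before the volcano thresholds.  A taxon
    is robust when it passes the volcano rule in every run.
    """
    candidate_taxa = list(candidate_taxa)
    metadata = metadata.loc[clr.sample_ids]
    patients = sorted(metadata["patient_id"].unique().tolist())
    if len(patients) < 3:
        raise InputError("leave-one-patient-out needs at least 3 patients")
    abx_pc1 = np.asarray(abx_pc1, dtype=float)
    abx_pc2 = np.asarray(abx_pc2, dtype=float)

    passes = pd.DataFrame(False, index=patients, columns=candidate_taxa)
    for patient in patients:
        mask = (metadata["patient_id"] != patient).values
        sub_meta = metadata.loc[mask]
        if len(set(sub_meta["era"].tolist())) < 2:
            raise InputError(
                f"dropping patient {patient!r} removes an entire era; "
                "leave-one-patient-out is undefined"
            )
        sub_clr = ClrMatrix(
            values=clr.values.loc[mask], pseudocount=clr.pseudocount, source=clr.source
        )
        results = fit_taxon_models(
            sub_clr,
            candidate_taxa,
            sub_meta["era"].values,
            sub_meta["collection_day"].values,
            abx_pc1[mask],
            abx_pc2[mask],
        )
        covid_taxa, pre_taxa = volcano_select(results, effect_threshold, q_threshold)
        passes.loc[patient, covid_taxa + pre_taxa] = True

    fractions = passes.mean(axis=0)
    stable = sorted(fractions.index[fractions == 1.0].tolist())
    return RobustnessReport(
        fractions=fractions,
        n_runs=len(patients),
        stable_taxa=stable,
        per_run=passes,
    )
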