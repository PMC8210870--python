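"""Antibiotic exposure histories and decaying-average summaries.

Each sample gets, per antibiotic class, a daily binary exposure vector
spanning hospital admission through the day before sample collection
(day 0 = first day of chemotherapy).  The vector is summarized by an
unnormalized decaying weighted sum: the most recent completed day carries
weight ``decay**0`` and each earlier day is down-weighted by one more
factor of ``decay``.  Example: admission day -1, collection day 5,
drug on days 1-3, decay 2 -> series (0,0,1,1,1,0) -> 2**-1 + 2**-2 +
2**-3 = 0.875.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from eradiff.feature_table import InputError
from eradiff.ordination import pca

ANTIBIOTIC_CLASSES = (
    "fluoroquinolones",
    "cephalosporins_3plus",
    "metronidazole",
    "piperacillin_tazobactam",
    "iv_vancomycin_daptomycin_linezolid",
    "oral_vancomycin",
    "carbapenems",
)


@dataclass
class ExposureSeries:
    """Daily 0/1 exposure vector for one sample and one antibiotic class.

    ``values[j]`` covers day ``admission_day + j``; the vector runs
    oldest-first over ``[admission_day, collection_day - 1]``.
    """

    sample_id: str
    antibiotic_class: str
    admission_day: int
    collection_day: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        expected = self.collection_day - self.admission_day
        if len(self.values) != expected:
            raise InputError(
                f"exposure series length {len(self.values)} != window length {expected}"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise InputError("exposure series values must be 0 or 1")


def encode_exposures(
    sample_id: str,
    admission_day: int,
    collection_day: int,
    records,
) -> dict[str, ExposureSeries]:
    """Binary exposure series per antibiotic class for one sample.

    ``records`` is an iterable of ``(day, antibiotic_class)`` pairs (or a
    DataFrame with ``day`` and ``antibiotic_class`` columns) for the
    sample's patient.  Records on or after the collection day, or before
    admission, are ignored with a warning; unknown class names are an error.
    """
    if admission_day > collection_day:
        raise InputError(
            f"admission day {admission_day} after collection day {collection_day}"
        )
    if isinstance(records, pd.DataFrame):
        records = list(zip(records["day"].astype(int), records["antibiotic_class"]))
    length = collection_day - admission_day
    vectors = {cls: np.zeros(length, dtype=int) for cls in ANTIBIOTIC_CLASSES}
    for day, cls in records:
        if cls not in vectors:
            raise InputError(
                f"unknown antibiotic class {cls!r}; expected one of {ANTIBIOTIC_CLASSES}"
            )
        day = int(day)
        if day < admission_day or day >= collection_day:
            warnings.warn(
                f"exposure record (day {day}, {cls}) outside window "
                f"[{admission_day}, {collection_day - 1}] for sample {sample_id}; ignored",
                stacklevel=2,
            )
            continue
        vectors[cls][day - admission_day] = 1
    return {
        cls: ExposureSeries(
            sample_id=sample_id,
            antibiotic_class=cls,
            admission_day=admission_day,
            collection_day=collection_day,
            values=vec,
        )
        for cls, vec in vectors.items()
    }


def decaying_summary(series: ExposureSeries, decay: float = 2.0) -> float:
    """Decaying weighted sum of a binary exposure series.

    The last (most recent) day of the series gets weight ``decay**0``, the
    day before it ``decay**-1``, and so on; no normalization.  The score
    lies in ``[0, decay/(decay-1))``.
    """
    if decay <= 1:
        raise ValueError(f"decay factor must be > 1, got {decay}")
    vals = series.values[::-1].astype(float)
    weights = float(decay) ** -np.arange(len(vals))
    return float(vals @ weights)


def exposure_matrix(metadata: pd.DataFrame, records: pd.DataFrame, decay: float = 2.0) -> pd.DataFrame:
    """Per-sample decayed exposure scores, samples x 7 canonical classes.

    ``metadata`` is indexed by sample id with ``patient_id, admission_day,
    collection_day`` columns; ``records`` is long-format with
    ``patient_id, day, antibiotic_class``.
    """
    by_patient = {pid: grp for pid, grp in records.groupby("patient_id")} if len(records) else {}
    rows = np.zeros((len(metadata), len(ANTIBIOTIC_CLASSES)))
    empty = pd.DataFrame(columns=["day", "antibiotic_class"])
    for i, (sid, meta) in enumerate(metadata.iterrows()):
        admission = int(meta["admission_day"])
        collection = int(meta["collection_day"])
        patient_records = by_patient.get(meta["patient_id"], empty)
        # records outside this sample's window belong to other samples of the
        # same patient; trim silently rather than warn per sample
        in_window = patient_records[
            (patient_records["day"] >= admission) & (patient_records["day"] < collection)
        ]
        series = encode_exposures(str(sid), admission, collection, in_window)
        rows[i] = [decaying_summary(series[cls], decay) for cls in ANTIBIOTIC_CLASSES]
    return pd.DataFrame(rows, index=metadata.index, columns=list(ANTIBIOTIC_CLASSES))


def exposure_pca_covariates(scores: pd.DataFrame):
    """First two PCA axes of the exposure-score matrix as regression covariates.

    Returns ``(covariates, pca_result)`` where covariates is a DataFrame with
    columns ``abx_pc1, abx_pc2``.  A degenerate (constant) score matrix
    yields all-zero covariates with a warning; a rank-1 matrix pads the
    second axis with zeros.
    """
    x = scores.values.astype(float)
    cov = np.zeros((x.shape[0], 2))
    if np.allclose(x, x.mean(axis=0)):
        warnings.warn(
            "exposure score matrix is constant; PCA covariates set to 0", stacklevel=2
        )
        return (
            pd.DataFrame(cov, index=scores.index, columns=["abx_pc1", "abx_pc2"]),
            None,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank truncation handled by zero-padding
        result = pca(x, n_components=2)
    avail = result.scores.shape[1]
    if avail < 2:
        warnings.warn(
            "exposure PCA has rank < 2; missing axes padded with zeros", stacklevel=2
        )
    cov[:, :avail] = result.scores[:, :2]
    return (
        pd.DataFrame(cov, index=scores.index, columns=["abx_pc1", "abx_pc2"]),
        result,
    )
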