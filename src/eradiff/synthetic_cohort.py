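"""Ground-truthed synthetic cohorts for end-to-end pipeline testing.

Counts come from a logistic-normal-multinomial scheme: each sample's
log-composition is a per-cohort base abundance profile plus a planted era
effect (COVID-era samples of effect taxa), a per-patient intercept, a
per-taxon day slope, and i.i.d. noise; softmax gives multinomial
probabilities and the read depth is drawn negative-binomially.  Era is
assigned at the patient level, sampling days alternate 3/4-day gaps
(twice-weekly pattern), and antibiotic courses are generated per class
from a configurable policy.  Effects are additive on the clr scale, so
planted parameters are recoverable by the downstream analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from eradiff.exposure import ANTIBIOTIC_CLASSES
from eradiff.feature_table import CountTable


class ConfigError(ValueError):
    """Invalid cohort configuration."""


def default_antibiotic_policy() -> dict:
    """Per-class course generation parameters.

    ``p_pre``/``p_covid`` are per-patient course probabilities by era;
    courses start uniformly in ``[start_lo, start_hi]`` and last uniformly
    ``[dur_lo, dur_hi]`` days.  The default mimics near-universal
    fluoroquinolone prophylaxis from admission plus sporadic escalation
    courses of the other classes.
    """
    policy = {
        "fluoroquinolones": dict(p_pre=0.85, p_covid=0.85, start_lo=0, start_hi=2, dur_lo=8, dur_hi=18),
        "cephalosporins_3plus": dict(p_pre=0.35, p_covid=0.35, start_lo=4, start_hi=20, dur_lo=4, dur_hi=10),
        "metronidazole": dict(p_pre=0.2, p_covid=0.2, start_lo=4, start_hi=20, dur_lo=3, dur_hi=8),
        "piperacillin_tazobactam": dict(p_pre=0.3, p_covid=0.3, start_lo=4, start_hi=20, dur_lo=4, dur_hi=10),
        "iv_vancomycin_daptomycin_linezolid": dict(p_pre=0.25, p_covid=0.25, start_lo=4, start_hi=20, dur_lo=3, dur_hi=9),
        "oral_vancomycin": dict(p_pre=0.05, p_covid=0.05, start_lo=6, start_hi=22, dur_lo=5, dur_hi=12),
        "carbapenems": dict(p_pre=0.15, p_covid=0.15, start_lo=6, start_hi=22, dur_lo=4, dur_hi=10),
    }
    return policy


@dataclass
class CohortConfig:
    """Generator parameters; the seed fully determines the output."""

    n_patients_pre: int = 15
    n_patients_covid: int = 15
    n_taxa: int = 123
    max_day: int = 28
    depth_mean: float = 20000.0
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    low_depth_frac: float = 0.02  # fraction of samples drawn below 500 reads
    effect_taxa: tuple[int, ...] = ()
    effect_size_clr: tuple[float, ...] = ()  # signed, one per effect taxon
    patient_sd_clr: float = 1.0
    day_slope_clr: float = 0.0  # sd of per-taxon slopes (clr units per day)
    noise_sd_clr: float = 0.5
    base_log_sd: float = 1.5
    antibiotic_policy: dict = field(default_factory=default_antibiotic_policy)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients_pre, self.n_patients_covid, self.n_taxa, self.max_day) <= 0:
            raise ConfigError("patient, taxon, and day counts must be positive")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        self.effect_taxa = tuple(int(i) for i in self.effect_taxa)
        if np.isscalar(self.effect_size_clr):
            self.effect_size_clr = tuple([float(self.effect_size_clr)] * len(self.effect_taxa))
        else:
            self.effect_size_clr = tuple(float(e) for e in self.effect_size_clr)
        if len(self.effect_taxa) > self.n_taxa:
            raise ConfigError("more effect taxa than taxa")
        if len(self.effect_taxa) != len(self.effect_size_clr):
            raise ConfigError("effect_taxa and effect_size_clr lengths differ")
        if any(i < 0 or i >= self.n_taxa for i in self.effect_taxa):
            raise ConfigError("effect taxon index out of range")
        unknown = set(self.antibiotic_policy) - set(ANTIBIOTIC_CLASSES)
        if unknown:
            raise ConfigError(f"unknown antibiotic classes in policy: {sorted(unknown)}")


@dataclass
class SimulationTruth:
    """Planted parameters for recovery testing."""

    effect_taxa_labels: list[str]
    true_effect: pd.Series  # per-taxon planted era effect (0 off the effect set)
    patient_intercepts: pd.DataFrame  # patients x taxa
    taxon_day_slopes: pd.Series
    base_log_abundance: pd.Series
    exposure_records: pd.DataFrame
    config: CohortConfig


def _taxon_labels(n_taxa: int) -> list[str]:
    # a few family/order-level fallback labels, as real genus tables carry
    labels = []
    for i in range(n_taxa):
        if i % 17 == 15:
            labels.append(f"f__family_{i:03d}")
        elif i % 17 == 16:
            labels.append(f"o__order_{i:03d}")
        else:
            labels.append(f"g__genus_{i:03d}")
    return labels


def _sampling_days(rng: np.random.Generator, admission: int, last_day: int) -> list[int]:
    """Twice-weekly collection days: alternating 3- and 4-day gaps."""
    day = admission + int(rng.integers(0, 3))
    gap_first = int(rng.integers(0, 2))
    days = []
    k = 0
    while day <= last_day:
        days.append(day)
        gap = 3 if (k + gap_first) % 2 == 0 else 4
        day += gap
        k += 1
    return days


def _draw_depth(rng: np.random.Generator, config: CohortConfig) -> int:
    if rng.random() < config.low_depth_frac:
        return int(rng.integers(50, 500))
    # gamma-poisson mixture = negative binomial with size depth_dispersion
    lam = rng.gamma(config.depth_dispersion, config.depth_mean / config.depth_dispersion)
    return max(1, int(rng.poisson(lam)))


def _antibiotic_courses(
    rng: np.random.Generator, config: CohortConfig, era: str
) -> list[tuple[int, str]]:
    records = []
    for cls in ANTIBIOTIC_CLASSES:
        params = config.antibiotic_policy.get(cls)
        if params is None:
            continue
        prob = params["p_covid"] if era == "covid" else params["p_pre"]
        if rng.random() >= prob:
            continue
        start = int(rng.integers(params["start_lo"], params["start_hi"] + 1))
        duration = int(rng.integers(params["dur_lo"], params["dur_hi"] + 1))
        for day in range(start, start + duration):
            if day <= config.max_day:
                records.append((day, cls))
    return records


def simulate_cohort(config: CohortConfig) -> tuple[CountTable, pd.DataFrame, SimulationTruth]:
    """Generate (count table, long-format exposure records, ground truth).

    Deterministic given ``config.seed``.  Effect taxa are guaranteed a base
    abundance in the upper half of the profile so planted clr effects are
    not swamped by pseudocount attenuation at low counts.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_taxa
    taxa = _taxon_labels(p)

    base = rng.normal(0.0, config.base_log_sd, size=p)
    if config.effect_taxa:
        # swap effect taxa into the 50th-90th abundance percentile range
        order = np.argsort(base)
        lo, hi = int(0.5 * p), max(int(0.9 * p), int(0.5 * p) + len(config.effect_taxa))
        candidates = np.array([j for j in order[lo:hi] if j not in config.effect_taxa])
        in_band = set(order[lo:hi].tolist())
        movers = [idx for idx in config.effect_taxa if idx not in in_band]
        if len(movers) > len(candidates):
            raise ConfigError("not enough taxa to place all effect taxa at mid-high abundance")
        slots = rng.choice(candidates, size=len(movers), replace=False)
        for idx, slot in zip(movers, slots):
            base[[idx, slot]] = base[[slot, idx]]

    effect = np.zeros(p)
    for idx, size in zip(config.effect_taxa, config.effect_size_clr):
        effect[idx] = size
    slopes = (
        rng.normal(0.0, config.day_slope_clr, size=p) if config.day_slope_clr > 0 else np.zeros(p)
    )

    n_patients = config.n_patients_pre + config.n_patients_covid
    patient_ids = [f"P{i + 1:03d}" for i in range(n_patients)]
    eras = ["pre"] * config.n_patients_pre + ["covid"] * config.n_patients_covid
    intercepts = rng.normal(0.0, config.patient_sd_clr, size=(n_patients, p))

    count_rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    exposure_rows: list[dict] = []
    for i, (pid, era) in enumerate(zip(patient_ids, eras)):
        admission = int(rng.integers(-2, 1))
        stay_end = int(rng.integers(max(14, config.max_day // 2), config.max_day + 1))
        days = _sampling_days(rng, admission, stay_end)
        for day, cls in _antibiotic_courses(rng, config, era):
            exposure_rows.append({"patient_id": pid, "day": day, "antibiotic_class": cls})
        for day in days:
            eta = base + intercepts[i] + slopes * day
            if era == "covid":
                eta = eta + effect
            eta = eta + rng.normal(0.0, config.noise_sd_clr, size=p)
            probs = np.exp(eta - eta.max())
            probs /= probs.sum()
            depth = _draw_depth(rng, config)
            counts = rng.multinomial(depth, probs)
            sid = f"{pid}_d{day + 2:02d}"  # +2 keeps ids sortable for day >= -2
            count_rows.append(counts)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": pid,
                    "era": era,
                    "admission_day": admission,
                    "collection_day": day,
                }
            )

    counts = pd.DataFrame(
        np.asarray(count_rows, dtype=np.int64),
        index=[r["sample_id"] for r in meta_rows],
        columns=taxa,
    )
    counts.index.name = "sample_id"
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    exposures = pd.DataFrame(exposure_rows, columns=["patient_id", "day", "antibiotic_class"])
    table = CountTable(counts=counts, metadata=metadata)
    truth = SimulationTruth(
        effect_taxa_labels=[taxa[i] for i in config.effect_taxa],
        true_effect=pd.Series(effect, index=taxa),
        patient_intercepts=pd.DataFrame(intercepts, index=patient_ids, columns=taxa),
        taxon_day_slopes=pd.Series(slopes, index=taxa),
        base_log_abundance=pd.Series(base, index=taxa),
        exposure_records=exposures,
        config=config,
    )
    return table, exposures, truth


def write_cohort(
    outdir,
    table: CountTable,
    exposures: pd.DataFrame,
    truth: SimulationTruth,
) -> dict[str, Path]:
    """Write the three input TSVs plus a truth JSON.

    The count table is written taxa-major with a ``#OTU ID`` header
    (BIOM-style TSV export dialect).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "exposures": outdir / "exposures.tsv",
        "truth": outdir / "truth.json",
    }
    taxa_major = table.counts.T.copy()
    taxa_major.index = taxa_major.index.rename("#OTU ID")
    taxa_major.columns = taxa_major.columns.rename(None)
    taxa_major.to_csv(paths["counts"], sep="\t")
    table.metadata.to_csv(paths["metadata"], sep="\t")
    exposures.to_csv(paths["exposures"], sep="\t", index=False)
    truth_json = {
        "effect_taxa_labels": truth.effect_taxa_labels,
        "true_effect": truth.true_effect.to_dict(),
        "taxon_day_slopes": truth.taxon_day_slopes.to_dict(),
        "base_log_abundance": truth.base_log_abundance.to_dict(),
        "patient_intercepts": {
            pid: row.to_dict() for pid, row in truth.patient_intercepts.iterrows()
        },
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(truth.config).items()
        },
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    return paths
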