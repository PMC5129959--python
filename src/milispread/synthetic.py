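"""Synthetic cohort generator with planted, recoverable effects.

Emulates the statistical structure of a two-spread-type ovarian cancer
cohort: per patient up to four tissue origins (P primary, M metastatic, A
ascitic single cells, S spheroids), negative-binomial read counts over six
RNA biotypes, patient-level random intercepts shared by all samples of a
patient, and planted effects — miRNA-target suppression, globally reduced
lncRNA and circRNA abundance in miliary solid samples with unchanged miRNA
totals, spread-signature fold changes in primary tumors, and survival times
drawn from a proportional-hazards model. The planted truth is echoed in the
output so downstream recovery is testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cerna_stats import SpliceJunctionCounts
from .genemir_sets import TargetInteractionTable
from .io import write_gmt
from .normalization import ExpressionMatrix
from .spread_predictor import (
    DEFAULT_UP_MILIARY,
    DEFAULT_UP_NON_MILIARY,
    SpreadSignature,
)
from .survival import TRAINING_COEFFICIENTS

#: baseline log2 relative abundance per biotype (sn/snoRNA normalizers high,
#: lncRNAs low), before per-feature scatter
_BIOTYPE_BASE_LOG2 = {
    "coding": 6.0,
    "lncRNA": 4.0,
    "miRNA": 7.0,
    "piRNA": 5.0,
    "snRNA": 8.0,
    "snoRNA": 8.0,
}
_FEATURE_SCATTER_LOG2 = 1.5
_PATIENT_INTERCEPT_LOG2 = 0.25
_LIBSIZE_SIGMA_LOG2 = 0.35
_BACKSPLICE_BASE_RATE = 0.05
_BACKSPLICE_JITTER_LOG2 = 0.25
_JUNCTION_EVENTS_PER_LIB = 3e-3  # splice events per sequenced read

#: default censoring tuned to the training-cohort event fraction (78 of 165)
DEFAULT_CENSOR_RATE = 1.0 - 78.0 / 165.0


@dataclass
class CohortConfig:
    """Cohort layout and noise parameters; the seed fixes everything."""

    n_patients: int = 23
    spread_fraction: float = 11.0 / 23.0
    tissue_origins: tuple = ("P", "M", "A", "S")
    n_coding: int = 1200
    n_lncrna: int = 300
    n_mirna: int = 150
    n_pirna: int = 80
    n_snrna: int = 20
    n_snorna: int = 20
    nb_dispersion: float = 0.15
    lib_size_mean: float = 14.2e6
    seed: int = 0
    n_gene_sets: int = 100
    gene_set_size: int = 20
    n_up_mirnas: int = 8
    targets_per_mirna: int = 25

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.spread_fraction <= 1.0:
            raise ValueError("spread_fraction must lie in [0, 1]")
        for name in ("n_coding", "n_lncrna", "n_mirna", "n_pirna", "n_snrna", "n_snorna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.lib_size_mean <= 0:
            raise ValueError("lib_size_mean must be positive")
        unknown = set(self.tissue_origins) - {"P", "M", "A", "S"}
        if unknown:
            raise ValueError(f"unknown tissue origins: {sorted(unknown)}")
        if self.n_mirna < len(DEFAULT_UP_MILIARY) + 8 + self.n_up_mirnas:
            raise ValueError("n_mirna too small for signature and up-miRNA planting")
        if self.n_pirna < 2:
            raise ValueError("n_pirna must be at least 2 (signature piRNAs)")


@dataclass
class PlantedEffects:
    """Effect sizes planted into the cohort (log2 scale unless noted).

    ``mirna_target_logfc`` is applied to targets of the designated up-miRNAs
    in miliary solid samples; the up-miRNAs themselves receive the mirrored
    (opposite-sign) shift. ``lncrna_miliary_logfc`` shifts every lncRNA and
    ``circ_index_shift`` the log2 back-splice rate in miliary solid samples.
    ``signature_logfc`` separates the spread-signature sRNAs in primary (P)
    tumor samples. ``cox_coefficients`` are log hazard ratios. A zero vector
    yields null data with no group structure.
    """

    mirna_target_logfc: float = -1.0
    lncrna_miliary_logfc: float = -1.0
    circ_index_shift: float = -1.0
    signature_logfc: float = 2.0
    cox_coefficients: Dict[str, float] = field(
        default_factory=lambda: dict(TRAINING_COEFFICIENTS)
    )

    def __post_init__(self) -> None:
        scalars = [
            self.mirna_target_logfc,
            self.lncrna_miliary_logfc,
            self.circ_index_shift,
            self.signature_logfc,
            *self.cox_coefficients.values(),
        ]
        if not np.all(np.isfinite(scalars)):
            raise ValueError("all planted effect sizes must be finite")

    @classmethod
    def null(cls) -> "PlantedEffects":
        return cls(0.0, 0.0, 0.0, 0.0, {k: 0.0 for k in TRAINING_COEFFICIENTS})


@dataclass
class SyntheticCohort:
    """Generated cohort plus the planted truth needed for recovery tests."""

    counts: ExpressionMatrix
    junctions: SpliceJunctionCounts
    annotations: pd.DataFrame
    targets: TargetInteractionTable
    gene_sets: Dict[str, List[str]]
    survival: pd.DataFrame
    truth: PlantedEffects
    signature: SpreadSignature
    up_mirnas: List[str]
    planted_sets: List[str]
    config: CohortConfig

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.sample_ids

    def samples_where(self, **conditions) -> List[str]:
        """Sample ids matching annotation equalities, e.g. tissue_origin="P"."""
        mask = pd.Series(True, index=self.annotations.index)
        for col, val in conditions.items():
            vals = val if isinstance(val, (list, tuple, set)) else [val]
            mask &= self.annotations[col].isin(list(vals))
        return list(self.annotations.index[mask])


def _feature_table(config: CohortConfig) -> pd.DataFrame:
    """Feature ids and biotypes; signature member ids are injected verbatim."""
    sig_mirnas = list(DEFAULT_UP_MILIARY) + [
        m for m in DEFAULT_UP_NON_MILIARY if "piR" not in m
    ]
    sig_pirnas = [m for m in DEFAULT_UP_NON_MILIARY if "piR" in m]
    rows = []
    for i in range(config.n_coding):
        rows.append((f"gene_{i:05d}", "coding"))
    for i in range(config.n_lncrna):
        rows.append((f"lnc_{i:05d}", "lncRNA"))
    for mid in sig_mirnas:
        rows.append((mid, "miRNA"))
    for i in range(config.n_mirna - len(sig_mirnas)):
        rows.append((f"miR_{i:04d}", "miRNA"))
    for pid in sig_pirnas:
        rows.append((pid, "piRNA"))
    for i in range(config.n_pirna - len(sig_pirnas)):
        rows.append((f"piR_{i:04d}", "piRNA"))
    for i in range(config.n_snrna):
        rows.append((f"snRNA_{i:03d}", "snRNA"))
    for i in range(config.n_snorna):
        rows.append((f"snoRNA_{i:03d}", "snoRNA"))
    return pd.DataFrame(rows, columns=["feature_id", "biotype"]).set_index("feature_id")


def _annotations(config: CohortConfig) -> pd.DataFrame:
    n_miliary = int(round(config.n_patients * config.spread_fraction))
    rows = []
    for p in range(config.n_patients):
        patient = f"pt{p + 1:03d}"
        spread = "miliary" if p < n_miliary else "non_miliary"
        for origin in config.tissue_origins:
            rows.append(
                {
                    "sample_id": f"{patient}_{origin}",
                    "patient_id": patient,
                    "tissue_origin": origin,
                    "spread_type": spread,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; dispersion 0 is Poisson."""
    mean = np.maximum(mean, 1e-12)
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _build_targets_and_sets(
    rng: np.random.Generator,
    config: CohortConfig,
    coding_ids: List[str],
    up_mirnas: List[str],
    null_mirnas: List[str],
) -> tuple[TargetInteractionTable, Dict[str, List[str]], List[str]]:
    pairs = []
    targets_of: Dict[str, List[str]] = {}
    for mir in up_mirnas + null_mirnas:
        tg = list(rng.choice(coding_ids, size=config.targets_per_mirna, replace=False))
        targets_of[mir] = tg
        pairs.extend((mir, g, "verified") for g in tg)
    targets = TargetInteractionTable(
        pd.DataFrame(pairs, columns=["mirna_id", "gene_id", "evidence"])
    )
    gene_sets: Dict[str, List[str]] = {}
    planted_sets: List[str] = []
    size = config.gene_set_size
    for i, mir in enumerate(up_mirnas):
        n_core = min(size - size // 4, len(targets_of[mir]))
        core = list(rng.choice(targets_of[mir], size=n_core, replace=False))
        others = [g for g in coding_ids if g not in core]
        pad = list(rng.choice(others, size=size - n_core, replace=False))
        set_id = f"planted_set_{i:03d}"
        gene_sets[set_id] = core + pad
        planted_sets.append(set_id)
    for i in range(config.n_gene_sets - len(planted_sets)):
        gene_sets[f"null_set_{i:03d}"] = list(
            rng.choice(coding_ids, size=size, replace=False)
        )
    return targets, gene_sets, planted_sets


def generate_cohort(
    config: Optional[CohortConfig] = None,
    effects: Optional[PlantedEffects] = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort; identical inputs give identical output."""
    config = config or CohortConfig()
    effects = effects or PlantedEffects()
    rng = np.random.default_rng(config.seed)
    features = _feature_table(config)
    ann = _annotations(config)
    samples = list(ann.index)
    n_feat, n_samp = len(features), len(samples)

    signature = SpreadSignature.default()
    mirna_ids = list(features.index[features["biotype"] == "miRNA"])
    non_sig_mirnas = [m for m in mirna_ids if m not in signature.members]
    up_mirnas = non_sig_mirnas[: config.n_up_mirnas]
    n_null_mir = min(len(non_sig_mirnas) - len(up_mirnas), 4 * config.n_up_mirnas)
    null_mirnas = non_sig_mirnas[config.n_up_mirnas : config.n_up_mirnas + n_null_mir]
    coding_ids = list(features.index[features["biotype"] == "coding"])
    targets, gene_sets, planted_sets = _build_targets_and_sets(
        rng, config, coding_ids, up_mirnas, null_mirnas
    )

    # baseline per-feature abundance and patient-level intercepts (log2)
    base = np.array([_BIOTYPE_BASE_LOG2[b] for b in features["biotype"]])
    base = base + rng.normal(0.0, _FEATURE_SCATTER_LOG2, size=n_feat)
    patients = ann["patient_id"].unique()
    intercepts = pd.DataFrame(
        rng.normal(0.0, _PATIENT_INTERCEPT_LOG2, size=(n_feat, len(patients))),
        index=features.index,
        columns=patients,
    )

    # planted log2 offsets, features x samples
    offsets = pd.DataFrame(0.0, index=features.index, columns=samples)
    is_miliary = ann["spread_type"] == "miliary"
    is_solid = ann["tissue_origin"].isin(["P", "M"])
    miliary_solid = list(ann.index[is_miliary & is_solid])
    if miliary_solid:
        offsets.loc[features["biotype"] == "lncRNA", miliary_solid] += (
            effects.lncrna_miliary_logfc
        )
        offsets.loc[up_mirnas, miliary_solid] += -effects.mirna_target_logfc
        suppressed = sorted(set(targets.pairs.loc[
            targets.pairs["mirna_id"].isin(up_mirnas), "gene_id"
        ]))
        offsets.loc[suppressed, miliary_solid] += effects.mirna_target_logfc
    p_miliary = list(ann.index[is_miliary & (ann["tissue_origin"] == "P")])
    p_non_miliary = list(ann.index[~is_miliary & (ann["tissue_origin"] == "P")])
    offsets.loc[list(signature.up_ids), p_miliary] += effects.signature_logfc
    offsets.loc[list(signature.down_ids), p_non_miliary] += effects.signature_logfc

    lib_sizes = config.lib_size_mean * 2.0 ** rng.normal(
        0.0, _LIBSIZE_SIGMA_LOG2, size=n_samp
    )
    patient_of = ann["patient_id"]
    weights = 2.0 ** (
        base[:, None]
        + intercepts[patient_of.values].to_numpy()
        + offsets.to_numpy()
    )
    weights /= weights.sum(axis=0, keepdims=True)
    mean_counts = weights * lib_sizes[None, :]
    counts = pd.DataFrame(
        _nb_counts(rng, mean_counts, config.nb_dispersion),
        index=features.index,
        columns=samples,
    )
    matrix = ExpressionMatrix(values=counts, biotype=features["biotype"].copy())

    # splice junction events: totals scale with library size; back-splice rate
    # is shifted (log2) in miliary solid samples
    totals = rng.poisson(lib_sizes * _JUNCTION_EVENTS_PER_LIB)
    rate = _BACKSPLICE_BASE_RATE * 2.0 ** rng.normal(
        0.0, _BACKSPLICE_JITTER_LOG2, size=n_samp
    )
    shift = np.where(
        (is_miliary & is_solid).to_numpy(), 2.0**effects.circ_index_shift, 1.0
    )
    rate = np.clip(rate * shift, 0.0, 1.0)
    back = rng.binomial(np.maximum(totals, 1), rate) * (totals > 0)
    junctions = SpliceJunctionCounts(
        pd.DataFrame(
            {
                "back_splice_events": back,
                "linear_splice_events": totals - back,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )

    survival = _survival_for_patients(
        rng,
        ann,
        effects.cox_coefficients,
        censor_rate=DEFAULT_CENSOR_RATE,
    )
    return SyntheticCohort(
        counts=matrix,
        junctions=junctions,
        annotations=ann,
        targets=targets,
        gene_sets=gene_sets,
        survival=survival,
        truth=effects,
        signature=signature,
        up_mirnas=up_mirnas,
        planted_sets=planted_sets,
        config=config,
    )


# ---------------------------------------------------------------------------
# survival generation


def _default_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Clinicopathologic covariates with realistic HGSOC marginals."""
    return pd.DataFrame(
        {
            "age_decades": np.maximum(rng.normal(5.6, 1.1, size=n), 2.0),
            "figo": rng.choice([0, 1, 2], size=n, p=[0.05, 0.75, 0.20]).astype(float),
            "residual": rng.binomial(1, 0.5, size=n).astype(float),
            "grade": rng.binomial(1, 0.8, size=n).astype(float),
            "predictor": rng.binomial(1, 0.5, size=n).astype(float),
        }
    )


def _event_fraction(log_lambda0: float, lp: np.ndarray, tau: float) -> float:
    """Expected event fraction under exponential times, U(0, tau) censoring."""
    lam = np.exp(log_lambda0 + lp)
    x = lam * tau
    return float(np.mean(1.0 - (1.0 - np.exp(-x)) / x))


def _simulate_times(
    rng: np.random.Generator,
    lp: np.ndarray,
    censor_rate: float,
    follow_up_months: float,
) -> tuple[np.ndarray, np.ndarray]:
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    target = 1.0 - censor_rate
    lo, hi = -25.0, 10.0
    f = lambda g: _event_fraction(g, lp, follow_up_months) - target
    log_lambda0 = brentq(f, lo, hi)
    lam = np.exp(log_lambda0 + lp)
    event_time = rng.exponential(1.0 / lam)
    censor_time = rng.uniform(0.0, follow_up_months, size=len(lp))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return np.maximum(time, 1e-6), event


def generate_survival(
    n: int,
    coefficients: Optional[Mapping[str, float]] = None,
    covariate_distributions: Optional[Mapping[str, Callable]] = None,
    censor_rate: float = DEFAULT_CENSOR_RATE,
    seed: int = 0,
    covariates: Optional[pd.DataFrame] = None,
    follow_up_months: float = 120.0,
) -> pd.DataFrame:
    """Simulate a survival table from a proportional-hazards model.

    Event times are exponential with subject rate lambda0 * exp(linear
    predictor); the baseline rate lambda0 is calibrated so the expected event
    fraction equals ``1 - censor_rate`` under uniform administrative
    censoring on (0, ``follow_up_months``). ``covariate_distributions`` maps
    a covariate name to a ``f(rng, n) -> array`` sampler overriding the
    default clinicopathologic marginals; a fully-specified ``covariates``
    frame bypasses sampling entirely.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    coefficients = dict(coefficients if coefficients is not None else TRAINING_COEFFICIENTS)
    rng = np.random.default_rng(seed)
    if covariates is None:
        covariates = _default_covariates(rng, n)
        for name, sampler in (covariate_distributions or {}).items():
            covariates[name] = np.asarray(sampler(rng, n), dtype=float)
    else:
        covariates = covariates.reset_index(drop=True).astype(float)
        if len(covariates) != n:
            raise ValueError("covariates frame must have n rows")
    missing = [c for c in coefficients if c not in covariates.columns]
    if missing:
        raise ValueError(f"no distribution for covariates: {missing}")
    beta = np.array([coefficients[c] for c in coefficients])
    lp = covariates[list(coefficients)].to_numpy() @ beta
    time, event = _simulate_times(rng, lp, censor_rate, follow_up_months)
    out = pd.DataFrame(
        {
            "patient_id": [f"pt{i + 1:03d}" for i in range(n)],
            "time_months": time,
            "event": event,
        }
    )
    return pd.concat([out, covariates], axis=1).set_index("patient_id")


def _survival_for_patients(
    rng: np.random.Generator,
    annotations: pd.DataFrame,
    coefficients: Mapping[str, float],
    censor_rate: float,
) -> pd.DataFrame:
    """One survival record per cohort patient; predictor = miliary indicator."""
    per_patient = annotations.drop_duplicates("patient_id").set_index("patient_id")
    n = len(per_patient)
    covariates = _default_covariates(rng, n)
    covariates["predictor"] = (per_patient["spread_type"] == "miliary").to_numpy(float)
    coefficients = dict(coefficients)
    beta = np.array([coefficients[c] for c in coefficients])
    lp = covariates[list(coefficients)].to_numpy() @ beta
    time, event = _simulate_times(rng, lp, censor_rate, follow_up_months=120.0)
    covariates.index = per_patient.index
    out = pd.DataFrame(
        {"time_months": time, "event": event}, index=per_patient.index
    )
    return pd.concat([out, covariates], axis=1)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write counts, junctions, annotations, targets, gene sets, survival and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.counts.to_tsv(outdir / "counts.tsv")
    cohort.junctions.to_tsv(outdir / "junctions.tsv")
    cohort.annotations.to_csv(outdir / "annotations.tsv", sep="\t")
    cohort.targets.to_tsv(outdir / "targets.tsv")
    write_gmt(cohort.gene_sets, outdir / "gene_sets.gmt")
    cohort.survival.to_csv(outdir / "survival.tsv", sep="\t")
    cohort.signature.to_tsv(outdir / "signature.tsv")
    manifest = {
        "config": asdict(cohort.config),
        "truth": asdict(cohort.truth),
        "up_mirnas": cohort.up_mirnas,
        "planted_sets": cohort.planted_sets,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
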