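"""Single-sample gene expression outlier detection against a reference cohort.

The core statistic is the Tukey upper fence on log2(TPM+1): for each gene,
a focus tumor is an *up outlier* when its value exceeds
``Q3 + iqr_multiplier * IQR`` of the reference cohort and also clears a
minimum-expression floor that suppresses calls among unexpressed genes.
Quartiles use linear interpolation between order statistics (numpy's
default, the "type 7" convention) — the convention matters for calls near
the fence, so it is fixed here.

Two reference tracks are supported: *pan-cancer* (the whole compendium,
restricted to the filtered gene universe) and *pan-disease* (the most
similar compendium tumors by rank correlation over the most variable
genes, on the unfiltered universe). Only overexpression is called;
underexpressed genes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import CohortSizeError, ConfigError, InputError
from .io import ExpressionCompendium, FocusSample

TRACKS = ("pan_cancer", "pan_disease")


@dataclass(frozen=True)
class OutlierParams:
    """Parameters of the outlier fence.

    ``iqr_multiplier`` scales the fence above Q3 (1.5 is the classical
    boxplot whisker); ``min_log_expression`` is a log2(TPM+1) floor below
    which no call is made; ``min_cohort_size`` rejects reference cohorts
    too small for stable quartiles.
    """

    iqr_multiplier: float = 1.5
    min_log_expression: float = 2.5
    min_cohort_size: int = 20

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0:
            raise ConfigError("iqr_multiplier must be > 0")
        if self.min_cohort_size < 4:
            raise ConfigError("min_cohort_size must be >= 4")


@dataclass(frozen=True)
class OutlierCall:
    gene_id: str
    sample_log_value: float
    q1: float
    q3: float
    iqr: float
    threshold: float
    percentile: float
    track: str
    is_outlier: bool


@dataclass(frozen=True)
class CohortSpec:
    """The pan-disease reference cohort for one focus sample."""

    member_ids: tuple[str, ...]
    similarity: tuple[tuple[str, float], ...]  # nonincreasing by correlation
    disease_composition: dict[str, int] = field(default_factory=dict)

    def majority_disease(self) -> str | None:
        if not self.disease_composition:
            return None
        return max(sorted(self.disease_composition), key=self.disease_composition.get)


@dataclass(frozen=True)
class OutlierLists:
    """The three gene lists carried forward to actionability and enrichment."""

    pan_cancer: frozenset[str]
    pan_disease: frozenset[str]

    @property
    def intersection(self) -> frozenset[str]:
        return self.pan_cancer & self.pan_disease

    @property
    def union(self) -> frozenset[str]:
        return self.pan_cancer | self.pan_disease


def log2_tpm(values) -> np.ndarray:
    return np.log2(np.asarray(values, dtype=float) + 1.0)


def percentile_of(value: float, cohort: Sequence[float]) -> float:
    """Midrank percentile of ``value`` within ``cohort`` (0-100).

    Counts cohort members strictly below the value plus half of the ties,
    so a value equal to every member of a constant cohort sits at the 50th
    percentile. Invariant under any strictly monotone transform applied
    jointly to the value and the cohort.
    """
    cohort = np.asarray(cohort, dtype=float)
    if cohort.size == 0:
        raise InputError("percentile_of: empty cohort")
    below = float((cohort < value).sum())
    ties = float((cohort == value).sum())
    return 100.0 * (below + 0.5 * ties) / cohort.size


def call_outliers(
    sample: FocusSample,
    cohort: ExpressionCompendium,
    params: OutlierParams = OutlierParams(),
    track: str = "pan_cancer",
) -> pd.DataFrame:
    """Per-gene outlier calls for one focus sample against a cohort.

    Returns a DataFrame with one row per cohort gene and columns
    ``gene_id, sample_log_value, q1, q3, iqr, threshold, percentile,
    track, is_outlier``. The focus sample is excluded from its own
    reference cohort if present. Deterministic.
    """
    if track not in TRACKS:
        raise ConfigError(f"unknown track {track!r}")
    tpm = cohort.tpm
    if sample.sample_id in tpm.columns:
        tpm = tpm.drop(columns=[sample.sample_id])
    n = tpm.shape[1]
    if n < params.min_cohort_size:
        raise CohortSizeError(
            f"{track}: cohort of {n} samples is below min_cohort_size "
            f"{params.min_cohort_size}"
        )
    values = sample.tpm.reindex(tpm.index)
    if values.isna().any():
        missing = tpm.index[values.isna()][:5].tolist()
        raise InputError(f"focus sample missing genes {missing}")

    L = log2_tpm(tpm.to_numpy())
    v = log2_tpm(values.to_numpy())
    q1, q3 = np.percentile(L, [25, 75], axis=1)
    iqr = q3 - q1
    threshold = q3 + params.iqr_multiplier * iqr
    below = (L < v[:, None]).sum(axis=1)
    ties = (L == v[:, None]).sum(axis=1)
    percentile = 100.0 * (below + 0.5 * ties) / n
    is_outlier = (v > threshold) & (v >= params.min_log_expression)

    return pd.DataFrame(
        {
            "gene_id": tpm.index,
            "sample_log_value": v,
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "threshold": threshold,
            "percentile": percentile,
            "track": track,
            "is_outlier": is_outlier,
        }
    ).reset_index(drop=True)


def as_calls(df: pd.DataFrame) -> list[OutlierCall]:
    """Convert a :func:`call_outliers` DataFrame into call records."""
    return [
        OutlierCall(
            gene_id=r.gene_id,
            sample_log_value=float(r.sample_log_value),
            q1=float(r.q1),
            q3=float(r.q3),
            iqr=float(r.iqr),
            threshold=float(r.threshold),
            percentile=float(r.percentile),
            track=r.track,
            is_outlier=bool(r.is_outlier),
        )
        for r in df.itertuples()
    ]


def select_pan_disease_cohort(
    sample: FocusSample,
    compendium: ExpressionCompendium,
    k: int = 100,
    n_variable_genes: int = 1000,
    min_cohort_size: int = 20,
) -> CohortSpec:
    """Choose the ``k`` compendium tumors most similar to the focus sample.

    Similarity is Spearman (rank-based) correlation over the
    ``n_variable_genes`` compendium genes with the highest variance of
    log2(TPM+1) — rank correlation on variable genes is robust to scale
    and the standard practice for expression similarity. Ties in
    correlation are broken by sample id; the focus sample itself is never
    a member.
    """
    if k < min_cohort_size:
        raise ConfigError(f"cohort size k={k} below min_cohort_size {min_cohort_size}")
    tpm = compendium.tpm
    if sample.sample_id in tpm.columns:
        tpm = tpm.drop(columns=[sample.sample_id])
    if k > tpm.shape[1]:
        raise ConfigError(f"k={k} exceeds compendium size {tpm.shape[1]}")
    if n_variable_genes > tpm.shape[0]:
        raise ConfigError(
            f"n_variable_genes={n_variable_genes} exceeds gene count {tpm.shape[0]}"
        )

    L = log2_tpm(tpm.to_numpy())
    variances = L.var(axis=1)
    # stable top-N by variance: ties resolved by gene order
    order = np.argsort(-variances, kind="mergesort")[:n_variable_genes]
    Lv = L[order]
    v = log2_tpm(sample.tpm.reindex(tpm.index).to_numpy())[order]

    ranks = rankdata(Lv, axis=0)
    focus_ranks = rankdata(v)
    rc = ranks - ranks.mean(axis=0)
    fc = focus_ranks - focus_ranks.mean()
    denom = np.sqrt((rc**2).sum(axis=0)) * np.sqrt((fc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, (rc * fc[:, None]).sum(axis=0) / denom, 0.0)

    ranked = sorted(zip(tpm.columns, corr), key=lambda sc: (-sc[1], sc[0]))
    top = ranked[:k]
    member_ids = tuple(sid for sid, _ in top)
    composition: dict[str, int] = {}
    for sid in member_ids:
        disease = compendium.metadata.loc[sid, "disease"]
        composition[disease] = composition.get(disease, 0) + 1
    return CohortSpec(
        member_ids=member_ids,
        similarity=tuple((sid, float(c)) for sid, c in top),
        disease_composition=composition,
    )


def combine_lists(
    pan_cancer_calls: pd.DataFrame,
    pan_disease_calls: pd.DataFrame,
    symbols: Mapping[str, str] | None = None,
) -> OutlierLists:
    """Combine per-track calls into the three outlier gene lists.

    With ``symbols`` (gene id -> symbol) the lists are expressed as
    uppercase symbols, the currency of the actionable table and gene-set
    collections; otherwise raw gene ids are used.
    """

    def genes(calls: pd.DataFrame) -> frozenset[str]:
        ids = calls.loc[calls["is_outlier"], "gene_id"]
        if symbols is not None:
            return frozenset(str(symbols[g]).upper() for g in ids)
        return frozenset(ids)

    return OutlierLists(pan_cancer=genes(pan_cancer_calls), pan_disease=genes(pan_disease_calls))
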