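"""Gene set overlap (enrichment) analysis.

Each outlier gene list is tested against a curated gene-set collection
with a one-sided hypergeometric test (Fisher's exact enrichment): the
probability of drawing at least the observed overlap when ``list_size``
genes are sampled without replacement from a universe containing
``set_size`` members of the set. P values are adjusted across the whole
collection with Benjamini-Hochberg, results with q below the cutoff are
ranked by (q, p, name) and the report is truncated to the first
``max_report`` sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """A named collection of gene sets over a common gene universe.

    ``universe_size`` is the number of genes the lists are drawn from
    (the active analysis universe), which may exceed the union of the
    sets. ``universe`` optionally carries the universe membership itself;
    when present, query genes outside it are dropped before testing.
    """

    sets: Mapping[str, frozenset[str]]
    universe_size: int
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
        max_size = max((len(m) for m in self.sets.values()), default=0)
        if self.universe_size < max_size:
            raise FormatError(
                f"universe_size {self.universe_size} smaller than largest set ({max_size})"
            )

    def __len__(self) -> int:
        return len(self.sets)

    def with_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Return a copy bound to an explicit gene universe."""
        universe = frozenset(universe)
        return GeneSetCollection(self.sets, len(universe), universe)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    list_size: int
    universe_size: int
    p_value: float
    q_value: float
    rank: int


def hypergeom_overlap_p(overlap: int, list_size: int, set_size: int, universe_size: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X is the overlap between a fixed set of ``set_size`` genes and a
    uniformly drawn list of ``list_size`` genes from a universe of
    ``universe_size`` genes.
    """
    if not (0 <= overlap <= min(list_size, set_size)):
        raise InputError(
            f"overlap {overlap} inconsistent with list {list_size} / set {set_size}"
        )
    if set_size > universe_size or list_size > universe_size:
        raise InputError(
            f"margins exceed universe: set {set_size}, list {list_size}, "
            f"universe {universe_size}"
        )
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe_size, set_size, list_size))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    gene_list: Iterable[str],
    collection: GeneSetCollection,
    q_cut: float = 0.05,
    max_report: int = 100,
    universe_size: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric overlap of one gene list against every set.

    Returns a DataFrame with columns ``set_name, overlap, set_size,
    list_size, universe, p, q, rank`` holding the sets with q < ``q_cut``,
    sorted by (q, p, set_name) and truncated to ``max_report`` rows.
    Query genes outside the collection's universe (when membership is
    known) are dropped with a logged count.
    """
    genes = {g.upper() for g in gene_list}
    if collection.universe is not None:
        universe_upper = {g.upper() for g in collection.universe}
        dropped = len(genes) - len(genes & universe_upper)
        if dropped:
            logger.info("enrich: dropped %d query genes outside the universe", dropped)
        genes &= universe_upper
    M = universe_size if universe_size is not None else collection.universe_size
    if len(genes) > M:
        raise InputError(f"gene list ({len(genes)}) larger than universe ({M})")
    if not collection.sets:
        return _empty_result()

    names = sorted(collection.sets)
    rows = []
    for name in names:
        members = {g.upper() for g in collection.sets[name]}
        if collection.universe is not None:
            members &= universe_upper
        overlap = len(genes & members)
        # a set clipped to nothing cannot be enriched; keep p = 1
        p = hypergeom_overlap_p(overlap, len(genes), len(members), max(M, len(members)))
        rows.append((name, overlap, len(members), len(genes), M, p))
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "list_size", "universe", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    df = df[df["q"] < q_cut].sort_values(["q", "p", "set_name"], kind="mergesort")
    df = df.head(max_report).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def _empty_result() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["set_name", "overlap", "set_size", "list_size", "universe", "p", "q", "rank"]
    )


def pathway_outlier_summary(
    findings: Sequence,
    enriched_set_names: Iterable[str],
    group_to_sets: Mapping[str, Iterable[str]],
) -> dict[str, dict[str, object]]:
    """Per-pathway-group summary of gene-level and set-level overexpression.

    For each pathway group, reports whether an actionable gene of that
    group is an expression outlier (``gene_outlier``) and whether any of
    the gene sets mapped to the group is enriched (``set_enriched``).
    A group with actionable findings but no mapping to the collection is
    reported with ``set_enriched=None`` and a warning.
    """
    enriched = set(enriched_set_names)
    groups = set(group_to_sets) | {f.pathway_group for f in findings}
    summary: dict[str, dict[str, object]] = {}
    for group in sorted(groups):
        gene_outlier = any(f.pathway_group == group for f in findings)
        if group in group_to_sets:
            set_enriched: bool | None = bool(set(group_to_sets[group]) & enriched)
        else:
            warnings.warn(f"pathway group {group!r} has no gene-set mapping")
            set_enriched = None
        summary[group] = {"gene_outlier": gene_outlier, "set_enriched": set_enriched}
    return summary


def as_results(df: pd.DataFrame) -> list[EnrichmentResult]:
    """Convert an :func:`enrich` DataFrame into result records."""
    return [
        EnrichmentResult(
            set_name=r.set_name,
            overlap_count=int(r.overlap),
            set_size=int(r.set_size),
            list_size=int(r.list_size),
            universe_size=int(r.universe),
            p_value=float(r.p),
            q_value=float(r.q),
            rank=int(r.rank),
        )
        for r in df.itertuples()
    ]
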