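"""Actionability annotation of outlier gene lists.

Intersects the outlier lists produced for a focus tumor with a curated
table of actionable genes (genes whose protein products can be inhibited
directly, or that signal through a druggable pathway), and decorates the
hits with known drug-gene interactions from a local, offline table.

Symbol matching is exact after uppercase normalization; aliases belong in
the data files, not in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import FormatError

DRUG_SOURCES = (
    "CIViC",
    "Cancer Commons",
    "My Cancer Genome",
    "My Cancer Genome Clinical Trial",
)

ACTIONABLE_CLASSES = ("direct", "indirect")


@dataclass(frozen=True)
class ActionableGene:
    """One curated actionable gene.

    ``direct`` genes have protein products that available therapies can
    inhibit; ``indirect`` genes cannot be inhibited themselves but act in
    a pathway that can be targeted.
    """

    symbol: str
    klass: str
    pathway_group: str

    def __post_init__(self) -> None:
        if self.klass not in ACTIONABLE_CLASSES:
            raise FormatError(
                f"unknown actionability class {self.klass!r} for {self.symbol}"
            )
        if not self.pathway_group:
            raise FormatError(f"missing pathway_group for {self.symbol}")


@dataclass(frozen=True)
class ActionableGeneList:
    """Curated list of actionable genes, partitioned into direct/indirect."""

    entries: tuple[ActionableGene, ...]

    def __post_init__(self) -> None:
        symbols = [e.symbol.upper() for e in self.entries]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise FormatError(f"duplicate actionable gene symbols: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def direct(self) -> tuple[ActionableGene, ...]:
        return tuple(e for e in self.entries if e.klass == "direct")

    @property
    def indirect(self) -> tuple[ActionableGene, ...]:
        return tuple(e for e in self.entries if e.klass == "indirect")

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(e.symbol.upper() for e in self.entries)

    def get(self, symbol: str) -> ActionableGene | None:
        symbol = symbol.upper()
        for e in self.entries:
            if e.symbol.upper() == symbol:
                return e
        return None


@dataclass(frozen=True)
class DrugGeneTable:
    """Local drug-gene interaction table restricted to curated cancer sources."""

    rows: tuple[tuple[str, str, str], ...]  # (symbol, drug, source)

    def __post_init__(self) -> None:
        for symbol, drug, source in self.rows:
            if source not in DRUG_SOURCES:
                raise FormatError(
                    f"unknown drug-gene source {source!r} for {symbol}/{drug}"
                )

    def drugs_for(self, symbol: str) -> tuple[tuple[str, str], ...]:
        """All (drug, source) rows for a symbol, deterministically ordered."""
        symbol = symbol.upper()
        hits = [(d, s) for (g, d, s) in self.rows if g.upper() == symbol]
        return tuple(sorted(hits, key=lambda ds: (ds[1], ds[0])))


@dataclass(frozen=True)
class ActionableFinding:
    """An actionable gene observed as an expression outlier in one sample."""

    sample_id: str
    symbol: str
    klass: str
    pathway_group: str
    tracks: frozenset[str]
    drugs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError(f"finding for {self.symbol} has no supporting track")


def intersect_actionable(lists, actionable: ActionableGeneList, sample_id: str = "") -> list[ActionableFinding]:
    """Intersect a sample's outlier lists with the actionable gene table.

    ``lists`` is an :class:`~panoutlier.outliers.OutlierLists` whose members
    are gene symbols. One finding is emitted per actionable gene present in
    the union of the pan-cancer and pan-disease lists, recording which
    track(s) support it.
    """
    pan_cancer = {g.upper() for g in lists.pan_cancer}
    pan_disease = {g.upper() for g in lists.pan_disease}
    findings = []
    for entry in actionable.entries:
        sym = entry.symbol.upper()
        tracks = set()
        if sym in pan_cancer:
            tracks.add("pan_cancer")
        if sym in pan_disease:
            tracks.add("pan_disease")
        if tracks:
            findings.append(
                ActionableFinding(
                    sample_id=sample_id,
                    symbol=sym,
                    klass=entry.klass,
                    pathway_group=entry.pathway_group,
                    tracks=frozenset(tracks),
                )
            )
    findings.sort(key=lambda f: f.symbol)
    return findings


def annotate_drugs(findings: Sequence[ActionableFinding], table: DrugGeneTable) -> list[ActionableFinding]:
    """Attach drug-gene interaction rows to each finding.

    Findings without any matching row keep an empty drug list and remain
    findings: the local table is curated, not exhaustive.
    """
    return [replace(f, drugs=table.drugs_for(f.symbol)) for f in findings]


def flag_actionable_sample(findings: Sequence[ActionableFinding]) -> bool:
    """True iff the sample harbors at least one actionable outlier."""
    return len(findings) > 0
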