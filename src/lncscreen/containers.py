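"""Shared data containers for the screening pipeline.

The pipeline moves a probe-level expression table through four filters, a
PCA ranking, an alignment-consensus stage, a complementary-sequence scan and
a term-enrichment stage.  Every stage communicates through the small typed
containers defined here rather than bare arrays, so shape and labelling
errors surface at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Lesion conditions in increasing severity order.  The study design has two
#: replicate cortex samples per condition.
CONDITIONS: tuple[str, ...] = ("control", "weak", "moderate", "severe")

#: Ordinal severity covariate: control=0 < weak=1 < moderate=2 < severe=3.
SEVERITY: dict[str, int] = {c: i for i, c in enumerate(CONDITIONS)}


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity table with per-probe metadata.

    Parameters
    ----------
    intensities : DataFrame
        Strictly positive intensities, index = probe ids, columns = sample ids.
    confidence : DataFrame or None
        Per-probe, per-sample quantification-confidence scores in {0, 1, 2}
        (2 = highest confidence), aligned to ``intensities``.
    biotype : Series
        Probe id -> biotype label (e.g. ``"lncRNA"``).
    condition : Series or None
        Sample id -> condition label in :data:`CONDITIONS`.
    """

    intensities: pd.DataFrame
    confidence: pd.DataFrame | None = None
    biotype: pd.Series | None = None
    condition: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate probe ids: {sorted(set(dups))[:5]}")
        if self.confidence is not None:
            if self.confidence.shape != self.intensities.shape:
                raise ValueError(
                    "confidence matrix shape "
                    f"{self.confidence.shape} != intensity shape {self.intensities.shape}"
                )
            self.confidence = self.confidence.loc[
                self.intensities.index, self.intensities.columns
            ]
        if self.biotype is not None:
            missing = self.intensities.index.difference(self.biotype.index)
            if len(missing):
                raise ValueError(f"biotype missing for probes: {list(missing[:5])}")
            self.biotype = self.biotype.loc[self.intensities.index]
        if self.condition is not None:
            missing = self.intensities.columns.difference(self.condition.index)
            if len(missing):
                raise ValueError(f"condition missing for samples: {list(missing[:5])}")
            self.condition = self.condition.loc[self.intensities.columns]
            bad = set(self.condition) - set(CONDITIONS)
            if bad:
                raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    def severity(self) -> pd.Series:
        """Ordinal severity per sample (control=0 .. severe=3)."""
        if self.condition is None:
            raise ValueError("no condition labels attached to this matrix")
        return self.condition.map(SEVERITY)

    def subset(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        """Row subset preserving the given probe order."""
        idx = pd.Index(probe_ids)
        return ExpressionMatrix(
            intensities=self.intensities.loc[idx],
            confidence=None if self.confidence is None else self.confidence.loc[idx],
            biotype=None if self.biotype is None else self.biotype.loc[idx],
            condition=self.condition,
        )


@dataclass(frozen=True)
class FilterReport:
    """Audit record for one filtering stage."""

    stage: str
    probes_in: int
    probes_out: int
    removed_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.probes_out != self.probes_in - len(self.removed_ids):
            raise ValueError(
                f"inconsistent report for stage {self.stage!r}: "
                f"{self.probes_in} - {len(self.removed_ids)} != {self.probes_out}"
            )


@dataclass
class PCAResult:
    """Principal components of the probe-row population.

    ``loadings`` rows (one per component) are unit-norm weights over samples;
    ``scores`` columns are the per-probe projections used to rank lncRNAs;
    ``contribution_ratios`` are eigenvalue / trace fractions of variance.
    """

    contribution_ratios: np.ndarray
    loadings: np.ndarray  # component x sample
    scores: np.ndarray  # probe x component
    probe_ids: list[str]
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


@dataclass
class SelectionResult:
    """A chosen, oriented component and (after ``top_k``) the ranked probes."""

    component_index: int
    orientation: int  # +1 or -1
    selected_probe_ids: list[str] = field(default_factory=list)
    k: int = 0


@dataclass
class Alignment:
    """A gapped or gapless multiple alignment of nucleotide sequences.

    T and U are treated as the same symbol by all consumers; '-' is the gap.
    """

    ids: list[str]
    sequences: list[str]

    ALPHABET = frozenset("ACGTUN-")

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        norm = []
        for rid, seq in zip(self.ids, self.sequences):
            s = seq.upper().replace(".", "-")
            bad = set(s) - self.ALPHABET
            if bad:
                raise ValueError(f"record {rid!r}: illegal characters {sorted(bad)}")
            norm.append(s)
        self.sequences = norm
        if self.sequences:
            length = len(self.sequences[0])
            for rid, s in zip(self.ids, self.sequences):
                if len(s) != length:
                    raise ValueError(
                        f"ragged alignment: record {rid!r} has {len(s)} columns, "
                        f"expected {length}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_records(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        by_id = dict(zip(self.ids, self.sequences))
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise KeyError(f"ids not in alignment: {missing[:5]}")
        return Alignment(list(ids), [by_id[i] for i in ids])


@dataclass
class CommonSequence:
    """One consensus run: a maximal stretch of qualifying alignment columns.

    Coordinates are 0-based, half-open alignment columns.  ``sequence`` is in
    the RNA alphabet (T rendered as U); the complementary sequence is the
    reverse complement.
    """

    index: int
    sequence: str
    start_col: int
    end_col: int
    per_column_frequency: list[float]

    def __post_init__(self) -> None:
        if self.end_col - self.start_col != len(self.sequence):
            raise ValueError("span does not match sequence length")
        if len(self.per_column_frequency) != len(self.sequence):
            raise ValueError("frequency list does not match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def complement(self) -> str:
        from .consensus import reverse_complement

        return reverse_complement(self.sequence, alphabet="rna")


@dataclass(frozen=True)
class TranscriptRecord:
    """One sense-strand mRNA reference transcript."""

    transcript_id: str
    gene_symbol: str
    description: str
    sequence: str


@dataclass(frozen=True)
class ComplementHit:
    """One approximate, ungapped occurrence of a motif complement."""

    motif_index: int
    transcript_id: str
    gene_symbol: str
    description: str
    offset: int
    identity: float
    matched_span: str
    orientation: str = "sense"


@dataclass
class MatchSummary:
    """Per-motif funnel counts for the complementary-sequence search.

    ``table`` has one row per motif with columns ``n_transcripts``,
    ``n_genes``, ``n_genes_after_header_filter``, ``n_genes_after_whitelist``.
    Totals are reported both summed over motifs (with cross-motif duplicates)
    and over the union of genes (deduplicated).
    """

    table: pd.DataFrame
    total_genes_with_duplicates: int
    total_genes_deduplicated: int
    total_surviving_with_duplicates: int
    total_surviving_deduplicated: int


@dataclass
class AnnotationCatalog:
    """Term annotations grouped by category, over a fixed gene background."""

    categories: dict[str, dict[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self.background = frozenset(g.upper() for g in self.background)
        norm: dict[str, dict[str, frozenset[str]]] = {}
        for cat, terms in self.categories.items():
            norm[cat] = {}
            for term, genes in terms.items():
                gs = frozenset(g.upper() for g in genes)
                if not gs:
                    raise ValueError(f"term {term!r} in {cat!r} has an empty gene set")
                stray = gs - self.background
                if stray:
                    raise ValueError(
                        f"term {term!r} annotates genes outside the background: "
                        f"{sorted(stray)[:5]}"
                    )
                norm[cat][term] = gs
        self.categories = norm


@dataclass
class EnrichmentRow:
    """One scored term: contingency counts, fold enrichment, p and FDR.

    LH = list hits, LT = list total (list genes annotated in the category),
    PH = population hits, PT = population total (background genes annotated
    in the category); fold = (LH/LT)/(PH/PT).
    """

    category: str
    term: str
    lh: int
    lt: int
    ph: int
    pt: int
    fold: float
    p: float
    fdr: float = float("nan")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic-data generator."""

    probe_ids: list[str]
    suppressive_probe_ids: set[str]
    planted_motifs: list[tuple[str, int]]  # (RNA motif, alignment start column)
    planted_target_transcripts: dict[int, set[str]] = field(default_factory=dict)
    planted_target_genes: dict[int, set[str]] = field(default_factory=dict)
    enriched_terms: set[str] = field(default_factory=set)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.suppressive_probe_ids <= set(self.probe_ids):
            raise ValueError("suppressive ids are not a subset of all probe ids")
        for motif, col in self.planted_motifs:
            if len(motif) < 10:
                raise ValueError(f"planted motif {motif!r} shorter than 10 nt")
            if col < 0:
                raise ValueError(f"planted motif column {col} is negative")
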