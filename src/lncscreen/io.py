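"""Readers and writers for every file dialect the pipeline touches.

All tabular files are TSV; all coordinates in emitted files are 0-based,
half-open.  Sequence formats go through Biopython (``SeqIO``/``AlignIO``);
the expression table and GMT dialects are defined here and validated
strictly so malformed inputs fail with a row/record reference instead of
propagating NaNs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

from .containers import (
    Alignment,
    AnnotationCatalog,
    CommonSequence,
    ComplementHit,
    CONDITIONS,
    ExpressionMatrix,
    FilterReport,
    MatchSummary,
    TranscriptRecord,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression table


def write_expression_tsv(path: str | Path, m: ExpressionMatrix) -> None:
    """Write the probe-level table: probe_id, biotype, conf_*, then intensities."""
    df = pd.DataFrame(index=m.intensities.index.copy())
    df.index.name = "probe_id"  # on a copy: must not rename the caller's index
    df["biotype"] = m.biotype if m.biotype is not None else "lncRNA"
    if m.confidence is not None:
        for j, s in enumerate(m.sample_ids, start=1):
            df[f"conf_{j}"] = m.confidence[s].astype(int)
    for s in m.sample_ids:
        df[s] = m.intensities[s]
    df.to_csv(path, sep="\t")


def read_expression_tsv(
    path: str | Path, conditions: pd.Series | None = None
) -> ExpressionMatrix:
    """Read the expression TSV dialect back into an :class:`ExpressionMatrix`.

    Raises with the offending row/cell on duplicate probe ids or non-numeric
    intensities.  ``conditions`` (sample id -> condition label) may be read
    separately with :func:`read_condition_map`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'probe_id'")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        rows = (dup.index + 2).tolist()  # 1-based incl. header
        raise ValueError(f"{path}: duplicated probe id {dup.iloc[0]!r} at row {rows[0]}")
    df = df.set_index("probe_id")
    df.index.name = None
    conf_cols = [c for c in df.columns if c.startswith("conf_")]
    sample_cols = [c for c in df.columns if c not in conf_cols and c != "biotype"]
    if not sample_cols:
        raise ValueError(f"{path}: no sample intensity columns found")
    inten = df[sample_cols]
    for col in sample_cols:
        bad = pd.to_numeric(inten[col], errors="coerce").isna() & inten[col].notna()
        nan = inten[col].isna()
        if bad.any() or nan.any():
            probe = inten.index[(bad | nan)][0]
            raise ValueError(
                f"{path}: non-numeric intensity in column {col!r}, probe {probe!r}"
            )
    inten = inten.astype(float)
    confidence = None
    if conf_cols:
        if len(conf_cols) != len(sample_cols):
            raise ValueError(
                f"{path}: {len(conf_cols)} conf_* columns for {len(sample_cols)} samples"
            )
        confidence = df[conf_cols].astype(int)
        confidence.columns = sample_cols
    biotype = df["biotype"].astype(str) if "biotype" in df.columns else None
    return ExpressionMatrix(
        intensities=inten, confidence=confidence, biotype=biotype, condition=conditions
    )


def write_condition_map(path: str | Path, condition: pd.Series) -> None:
    condition.rename("condition").to_frame().rename_axis("sample_id").to_csv(
        path, sep="\t"
    )


def read_condition_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "condition"]:
        raise ValueError(f"{path}: expected columns sample_id, condition")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"{path}: unknown condition labels {sorted(bad)}")
    return df.set_index("sample_id")["condition"]


def write_filter_reports(path: str | Path, reports: Sequence[FilterReport]) -> None:
    pd.DataFrame(
        [
            {"stage": r.stage, "probes_in": r.probes_in, "probes_out": r.probes_out}
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / alignments


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs; the id may carry ``|``-joined metadata."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_transcript_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read an mRNA database with ``>transcript_id|gene_symbol|description`` headers."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id if rec.id == rec.description or not rec.description else rec.description
        parts = header.split("|", 2)
        if len(parts) != 3:
            raise ValueError(
                f"{path}: header {header!r} is not 'transcript_id|gene_symbol|description'"
            )
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTUN")
        if bad:
            raise ValueError(f"{path}: record {parts[0]!r} has illegal characters {sorted(bad)}")
        out.append(TranscriptRecord(parts[0], parts[1], parts[2], seq))
    return out


def write_transcript_fasta(path: str | Path, records: Iterable[TranscriptRecord]) -> None:
    write_fasta(
        path,
        (
            (f"{r.transcript_id}|{r.gene_symbol}|{r.description}", r.sequence)
            for r in records
        ),
    )


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> Alignment:
    """Read a multiple alignment in Clustal or aligned-FASTA dialect.

    ``-`` and ``.`` are both read as gaps; case is ignored; ragged rows fail
    with the first offending record named.
    """
    fmt = {"clustal": "clustal", "aligned-fasta": "fasta"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if fmt == "fasta":
        # AlignIO rejects ragged FASTA with a generic message; read records
        # ourselves so the error names the record.
        recs = list(SeqIO.parse(str(path), "fasta"))
        return Alignment([r.id for r in recs], [str(r.seq) for r in recs])
    aln = AlignIO.read(str(path), fmt)
    return Alignment([r.id for r in aln], [str(r.seq) for r in aln])


def write_alignment(path: str | Path, a: Alignment, dialect: str = "aligned-fasta") -> None:
    if dialect == "aligned-fasta":
        write_fasta(path, zip(a.ids, a.sequences))
    elif dialect == "clustal":
        msa = MultipleSeqAlignment(
            SeqRecord(Seq(s), id=i, description="") for i, s in zip(a.ids, a.sequences)
        )
        AlignIO.write(msa, str(path), "clustal")
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# whitelist / GMT


def read_whitelist(path: str | Path) -> set[str]:
    """One gene symbol per line; comments (#) and blanks ignored; upper-cased."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.upper())
    return out


def write_whitelist(path: str | Path, genes: Iterable[str]) -> None:
    Path(path).write_text("\n".join(sorted({g.upper() for g in genes})) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read one GMT file: term_id TAB description TAB gene symbols.

    Returns ``{term_id: (description, genes)}``; genes are upper-cased and
    de-duplicated; terms with a blank gene list are skipped with a warning.
    """
    out: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        term, desc = fields[0], fields[1]
        genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        if not genes:
            logger.warning("%s:%d: term %r has no genes; skipped", path, lineno, term)
            continue
        out[term] = (desc, genes)
    return out


def write_gmt(path: str | Path, terms: dict[str, tuple[str, Iterable[str]]]) -> None:
    lines = [
        "\t".join([term, desc, *sorted({g.upper() for g in genes})])
        for term, (desc, genes) in terms.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def catalog_from_gmt(
    paths: dict[str, str | Path], background: Iterable[str]
) -> AnnotationCatalog:
    """Build an :class:`AnnotationCatalog` from {category: gmt path}."""
    bg = frozenset(g.upper() for g in background)
    categories = {}
    for cat, path in paths.items():
        terms = read_gmt(path)
        categories[cat] = {t: genes & bg for t, (_, genes) in terms.items()}
        categories[cat] = {t: g for t, g in categories[cat].items() if g}
    return AnnotationCatalog(categories=categories, background=bg)


# ---------------------------------------------------------------------------
# stage-output tables


def write_common_sequences_tsv(path: str | Path, runs: Sequence[CommonSequence]) -> None:
    """Table of consensus runs with complements; columns 0-based half-open."""
    pd.DataFrame(
        [
            {
                "index": r.index,
                "sequence": r.sequence,
                "length": len(r),
                "complement": r.complement,
                "start_col": r.start_col,
                "end_col": r.end_col,
            }
            for r in runs
        ],
        columns=["index", "sequence", "length", "complement", "start_col", "end_col"],
    ).to_csv(path, sep="\t", index=False)


def read_common_sequences_tsv(path: str | Path) -> list[CommonSequence]:
    df = pd.read_csv(path, sep="\t")
    runs = []
    for _, row in df.iterrows():
        runs.append(
            CommonSequence(
                index=int(row["index"]),
                sequence=str(row["sequence"]),
                start_col=int(row["start_col"]),
                end_col=int(row["end_col"]),
                per_column_frequency=[float("nan")] * len(str(row["sequence"])),
            )
        )
    return runs


def write_hits_tsv(path: str | Path, hits: Sequence[ComplementHit]) -> None:
    pd.DataFrame(
        [
            {
                "motif_index": h.motif_index,
                "transcript_id": h.transcript_id,
                "gene_symbol": h.gene_symbol,
                "offset": h.offset,
                "identity": h.identity,
                "matched_span": h.matched_span,
                "orientation": h.orientation,
                "description": h.description,
            }
            for h in hits
        ],
        columns=[
            "motif_index",
            "transcript_id",
            "gene_symbol",
            "offset",
            "identity",
            "matched_span",
            "orientation",
            "description",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_match_summary_tsv(path: str | Path, s: MatchSummary) -> None:
    df = s.table.copy()
    total = {
        "motif_index": "total",
        "n_transcripts": int(df["n_transcripts"].sum()),
        "n_genes": f"{s.total_genes_deduplicated} ({s.total_genes_with_duplicates})",
        "n_genes_after_header_filter": int(df["n_genes_after_header_filter"].sum()),
        "n_genes_after_whitelist": (
            f"{s.total_surviving_deduplicated} ({s.total_surviving_with_duplicates})"
        ),
    }
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(path: str | Path, rows, fdr_method: str = "benjamini-hochberg") -> None:
    from .containers import EnrichmentRow  # noqa: F401  (typing only)

    df = pd.DataFrame(
        [
            {
                "category": r.category,
                "term": r.term,
                "LH": r.lh,
                "LT": r.lt,
                "PH": r.ph,
                "PT": r.pt,
                "fold_enrichment": r.fold,
                "p": r.p,
                "fdr": r.fdr,
            }
            for r in rows
        ],
        columns=["category", "term", "LH", "LT", "PH", "PT", "fold_enrichment", "p", "fdr"],
    )
    with open(path, "w") as fh:
        fh.write(f"# fdr_method: {fdr_method}\n")
        df.to_csv(fh, sep="\t", index=False)
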