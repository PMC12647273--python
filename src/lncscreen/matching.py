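"""Exhaustive complementary-sequence search over an mRNA database.

Each common-sequence complement is slid, ungapped, over the sense strand of
every transcript; a window is a hit when its identity — (motif length −
mismatches) / motif length — reaches the threshold (default 0.85, i.e. at
most two mismatches for an 11–15-nt motif).  For motifs this short an
exhaustive Hamming scan is both fast and strictly more sensitive than any
seeded heuristic at the same threshold.  Hits are then filtered by header
annotation ("PREDICTED"/"cDNA" records dropped) and by a cortex-expression
gene whitelist, and tabulated per motif with and without cross-motif
deduplication.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ComplementHit, MatchSummary, TranscriptRecord

logger = logging.getLogger(__name__)


def _as_dna(s: str) -> str:
    return s.upper().replace("U", "T")


def scan_database(
    motif: str,
    db: Sequence[TranscriptRecord],
    min_identity: float = 0.85,
    motif_index: int = 0,
) -> list[ComplementHit]:
    """All ungapped windows with identity >= ``min_identity`` (U == T).

    Only the sense strand is scanned; windows are full motif length, so
    transcripts shorter than the motif are skipped.  Every qualifying window
    is reported (use :func:`best_hits` for per-transcript summaries).
    """
    if not motif:
        raise ValueError("empty motif")
    if not 0 < min_identity <= 1:
        raise ValueError(f"min_identity must be in (0, 1], got {min_identity}")
    pat = np.frombuffer(_as_dna(motif).encode(), dtype=np.uint8)
    m = len(pat)
    hits: list[ComplementHit] = []
    for rec in db:
        seq = _as_dna(rec.sequence)
        if len(seq) < m:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, m)
        matches = (windows == pat).sum(axis=1)
        identity = matches / m
        for off in np.flatnonzero(identity >= min_identity):
            hits.append(
                ComplementHit(
                    motif_index=motif_index,
                    transcript_id=rec.transcript_id,
                    gene_symbol=rec.gene_symbol,
                    description=rec.description,
                    offset=int(off),
                    identity=float(identity[off]),
                    matched_span=seq[off : off + m],
                )
            )
    return hits


def best_hits(hits: Iterable[ComplementHit]) -> list[ComplementHit]:
    """Best hit per transcript (highest identity, then leftmost offset)."""
    best: dict[str, ComplementHit] = {}
    for h in hits:
        cur = best.get(h.transcript_id)
        if cur is None or (h.identity, -h.offset) > (cur.identity, -cur.offset):
            best[h.transcript_id] = h
    return list(best.values())


def filter_headers(
    hits: Iterable[ComplementHit],
    exclude_patterns: Sequence[str] = ("PREDICTED", "cDNA"),
) -> list[ComplementHit]:
    """Drop hits whose description contains any pattern (case-sensitive)."""
    return [
        h for h in hits if not any(p in h.description for p in exclude_patterns)
    ]


def filter_whitelist(
    hits: Iterable[ComplementHit], whitelist: set[str]
) -> list[ComplementHit]:
    """Keep hits whose gene symbol is whitelisted (case-insensitive)."""
    if not whitelist:
        logger.warning("empty whitelist: all hits dropped")
        return []
    wl = {g.upper() for g in whitelist}
    return [h for h in hits if h.gene_symbol.upper() in wl]


def _genes(hits: Iterable[ComplementHit]) -> set[str]:
    return {h.gene_symbol.upper() for h in hits}


def summarize(
    raw: Mapping[int, Sequence[ComplementHit]],
    after_header: Mapping[int, Sequence[ComplementHit]],
    after_whitelist: Mapping[int, Sequence[ComplementHit]],
) -> MatchSummary:
    """Per-motif funnel counts plus totals with/without cross-motif dedup."""
    rows = []
    for m in sorted(raw):
        rows.append(
            {
                "motif_index": m,
                "n_transcripts": len({h.transcript_id for h in raw[m]}),
                "n_genes": len(_genes(raw[m])),
                "n_genes_after_header_filter": len(_genes(after_header.get(m, []))),
                "n_genes_after_whitelist": len(_genes(after_whitelist.get(m, []))),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "motif_index",
            "n_transcripts",
            "n_genes",
            "n_genes_after_header_filter",
            "n_genes_after_whitelist",
        ],
    )
    all_raw = set().union(*[_genes(raw[m]) for m in raw]) if raw else set()
    all_surv = (
        set().union(*[_genes(after_whitelist.get(m, [])) for m in raw]) if raw else set()
    )
    return MatchSummary(
        table=table,
        total_genes_with_duplicates=int(table["n_genes"].sum()) if len(table) else 0,
        total_genes_deduplicated=len(all_raw),
        total_surviving_with_duplicates=(
            int(table["n_genes_after_whitelist"].sum()) if len(table) else 0
        ),
        total_surviving_deduplicated=len(all_surv),
    )


def run_match(
    complements: Mapping[int, str],
    db: Sequence[TranscriptRecord],
    whitelist: set[str],
    min_identity: float = 0.85,
    exclude_patterns: Sequence[str] = ("PREDICTED", "cDNA"),
) -> tuple[dict[int, list[ComplementHit]], MatchSummary]:
    """Scan every complement, apply both filters, and summarize.

    Returns the surviving (whitelist-filtered) best-hit-per-transcript lists
    per motif, plus the funnel summary.
    """
    raw, hdr, wl = {}, {}, {}
    for m, comp in complements.items():
        h = best_hits(scan_database(comp, db, min_identity, motif_index=m))
        raw[m] = h
        hdr[m] = filter_headers(h, exclude_patterns)
        wl[m] = filter_whitelist(hdr[m], whitelist)
    return wl, summarize(raw, hdr, wl)
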