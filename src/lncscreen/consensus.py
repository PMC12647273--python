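"""Consensus-run extraction from a multiple alignment, and complements.

A "common sequence" is a maximal stretch of consecutive alignment columns in
which a unique modal base reaches a frequency threshold (default 10% of the
rows) and the stretch is at least ``min_run_length`` columns (default 10).
Columns where two or more bases tie for the maximum are marked '+' and never
join a run, whatever their frequency; gaps count in the frequency
denominator (so heavily gapped columns dilute every base) unless
``count_gaps=False``.  T and U are the same symbol; runs are reported in the
RNA alphabet with their reverse complements.
"""

from __future__ import annotations

from collections import Counter

from .containers import Alignment, CommonSequence

BASES = ("A", "C", "G", "U")

_RNA_COMP = str.maketrans("ACGUN", "UGCAN")
_DNA_COMP = str.maketrans("ACGTN", "TGCAN")


def column_consensus(
    a: Alignment, min_frac: float = 0.10, count_gaps: bool = True
) -> list[tuple[str | None, float]]:
    """Per-column consensus symbols with their frequencies.

    Returns one ``(symbol, frequency)`` pair per column, where symbol is a
    base, ``'+'`` for a tie at the maximum, or ``None`` when no base reaches
    ``min_frac``.  The threshold is inclusive (a modal base at exactly
    ``min_frac`` qualifies).
    """
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    if a.n_records == 0:
        raise ValueError("empty alignment")
    out: list[tuple[str | None, float]] = []
    for col in range(a.length):
        counts = Counter()
        denom = 0
        for seq in a.sequences:
            c = seq[col]
            if c == "T":
                c = "U"
            if c == "-":
                if count_gaps:
                    denom += 1
                continue
            denom += 1
            if c in BASES:
                counts[c] += 1
            # N counts in the denominator only
        if not counts or denom == 0:
            out.append((None, 0.0))
            continue
        top = max(counts.values())
        frac = top / denom
        if frac < min_frac:
            out.append((None, frac))
            continue
        modal = [b for b in BASES if counts.get(b) == top]
        out.append(("+" if len(modal) > 1 else modal[0], frac))
    return out


def extract_runs(
    consensus: list[tuple[str | None, float]], min_run_length: int = 10
) -> list[CommonSequence]:
    """Maximal runs of consecutive base columns of length >= min_run_length.

    '+' and below-threshold columns break runs.  Runs are reported left to
    right with 0-based half-open column coordinates, 1-based indices, and
    sequences in the RNA alphabet.
    """
    if min_run_length < 1:
        raise ValueError(f"min_run_length must be >= 1, got {min_run_length}")
    runs: list[CommonSequence] = []
    start = None
    for col, (sym, _) in enumerate(list(consensus) + [(None, 0.0)]):
        if sym in BASES:
            if start is None:
                start = col
        else:
            if start is not None and col - start >= min_run_length:
                seq = "".join(s for s, _ in consensus[start:col])
                freqs = [f for _, f in consensus[start:col]]
                runs.append(
                    CommonSequence(
                        index=len(runs) + 1,
                        sequence=seq,
                        start_col=start,
                        end_col=col,
                        per_column_frequency=freqs,
                    )
                )
            start = None
    return runs


def reverse_complement(s: str, alphabet: str = "auto") -> str:
    """Reverse complement over the RNA or DNA alphabet (N maps to N).

    ``alphabet`` is ``"rna"``, ``"dna"`` or ``"auto"`` (RNA if the sequence
    contains U, DNA if it contains T, RNA otherwise).  The output alphabet
    matches the input.  Mixed T+U or other characters are rejected with the
    offending position named.
    """
    up = s.upper()
    if alphabet == "auto":
        if "U" in up and "T" in up:
            raise ValueError("sequence mixes T and U; pass alphabet explicitly")
        alphabet = "dna" if "T" in up else "rna"
    if alphabet not in ("rna", "dna"):
        raise ValueError(f"alphabet must be 'rna', 'dna' or 'auto', got {alphabet!r}")
    valid = set("ACGUN") if alphabet == "rna" else set("ACGTN")
    for i, c in enumerate(up):
        if c not in valid:
            raise ValueError(f"invalid {alphabet.upper()} character {c!r} at position {i}")
    table = _RNA_COMP if alphabet == "rna" else _DNA_COMP
    return up.translate(table)[::-1]


def extract_common_sequences(
    a: Alignment,
    min_frac: float = 0.10,
    min_run_length: int = 10,
    count_gaps: bool = True,
) -> list[CommonSequence]:
    """Convenience: consensus + run extraction in one call."""
    return extract_runs(column_consensus(a, min_frac, count_gaps), min_run_length)
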