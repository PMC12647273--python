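"""Probe-level filtering and Z-score standardization.

The screen keeps a probe only if it (1) reaches the highest quantification
confidence in at least one sample, (2) is annotated as an lncRNA, (3) shows
replicate agreement within each lesion condition, and (4) is expressed above
an intensity floor.  Surviving rows are standardized per probe:

    x_n = (I_n - mean(I)) / sigma        (population sigma, divisor N)

Each filter is a pure function returning the reduced matrix plus a
:class:`FilterReport`, and the canonical order is confidence -> biotype ->
replicate outlier -> low expression (see :func:`run_preprocess`).
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FilterReport

logger = logging.getLogger(__name__)


def _report(stage: str, m: ExpressionMatrix, kept: pd.Index) -> tuple[ExpressionMatrix, FilterReport]:
    removed = frozenset(m.intensities.index.difference(kept))
    out = m.subset([p for p in m.probe_ids if p in set(kept)])
    return out, FilterReport(stage, m.n_probes, out.n_probes, removed)


def filter_confidence(
    m: ExpressionMatrix, min_level: int = 2
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep probes with confidence >= ``min_level`` in at least one sample.

    With the platform's 0/1/2 confidence scale and the default
    ``min_level=2``, a probe survives iff any sample was quantified at the
    highest confidence.  ``min_level=0`` is the identity.
    """
    if m.confidence is None:
        raise ValueError(
            "no confidence matrix attached; pass min_level via run_preprocess "
            "with confidence=None to disable this stage explicitly"
        )
    keep = (m.confidence >= min_level).any(axis=1)
    return _report("confidence", m, m.intensities.index[keep])


def filter_biotype(
    m: ExpressionMatrix, keep: str = "lncRNA"
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep probes whose biotype equals ``keep`` (case-insensitive)."""
    if m.biotype is None:
        raise ValueError("no biotype annotation attached")
    mask = m.biotype.str.lower() == keep.lower()
    known = {keep.lower()}
    other = set(m.biotype[~mask].str.lower()) - known
    if other:
        counts = m.biotype[~mask].str.lower().value_counts()
        logger.info("biotype filter removed labels: %s", counts.to_dict())
    return _report("biotype", m, m.intensities.index[mask])


def filter_replicate_outliers(
    m: ExpressionMatrix, k_sd: float = 1.0, require: str = "all"
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove probes with aberrant within-condition replicate disagreement.

    For every within-condition sample pair ("comparison") the absolute
    intensity difference ``d`` is computed per probe; ``mean(d)`` and
    ``sd(d)`` are pooled over probes for that comparison, and a probe is
    flagged at a comparison when its ``d`` falls outside mean +/- k_sd * sd.
    With ``require="all"`` (default) a probe is removed only when flagged in
    every comparison; ``"any"`` removes on a single flag.  A comparison with
    ``sd(d) == 0`` flags nothing; conditions with fewer than two samples are
    skipped with a warning.
    """
    if k_sd <= 0:
        raise ValueError(f"k_sd must be positive, got {k_sd}")
    if require not in ("all", "any"):
        raise ValueError(f"require must be 'all' or 'any', got {require!r}")
    if m.condition is None:
        raise ValueError("condition labels required for the replicate-outlier filter")
    flags = []
    for cond in pd.unique(m.condition):
        samples = m.condition.index[m.condition == cond]
        if len(samples) < 2:
            logger.warning("condition %r has a single sample; comparison skipped", cond)
            continue
        for a, b in combinations(samples, 2):
            d = (m.intensities[a] - m.intensities[b]).abs()
            mu, sd = d.mean(), d.std(ddof=0)
            if sd == 0:
                flags.append(pd.Series(False, index=d.index))
            else:
                flags.append((d < mu - k_sd * sd) | (d > mu + k_sd * sd))
    if not flags:
        return _report("replicate_outlier", m, m.intensities.index)
    flagged = pd.concat(flags, axis=1)
    out = flagged.all(axis=1) if require == "all" else flagged.any(axis=1)
    return _report("replicate_outlier", m, m.intensities.index[~out])


def filter_low_expression(
    m: ExpressionMatrix, threshold: float = 100.0, mode: str = "any"
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove weakly expressed probes (strict ``< threshold``).

    ``mode="any"`` (default, the literal reading of the screen's rule)
    removes a probe if any sample is below the threshold; ``mode="all"``
    only if every sample is.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    below = m.intensities < threshold
    remove = below.any(axis=1) if mode == "any" else below.all(axis=1)
    return _report("low_expression", m, m.intensities.index[~remove])


def zscore(m: ExpressionMatrix) -> tuple[pd.DataFrame, FilterReport]:
    """Standardize each probe row to mean 0, population sd 1.

    Zero-variance rows cannot be standardized; they are removed (ids logged)
    rather than emitted as NaN.
    """
    x = m.intensities
    sd = x.std(axis=1, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.info(
            "zscore removed %d zero-variance probes: %s",
            int(degenerate.sum()),
            list(x.index[degenerate][:10]),
        )
    x = x.loc[~degenerate]
    sd = sd.loc[~degenerate]
    z = x.sub(x.mean(axis=1), axis=0).div(sd, axis=0)
    report = FilterReport(
        "zscore", m.n_probes, z.shape[0], frozenset(m.intensities.index[degenerate])
    )
    return z, report


def run_preprocess(
    m: ExpressionMatrix,
    min_conf: int = 2,
    biotype_keep: str = "lncRNA",
    outlier_k: float = 1.0,
    outlier_require: str = "all",
    low_expr_threshold: float = 100.0,
    low_expr_mode: str = "any",
) -> tuple[pd.DataFrame, ExpressionMatrix, list[FilterReport]]:
    """Run the four filters in canonical order, then standardize.

    Returns the standardized matrix, the filtered (unstandardized) matrix and
    the telescoping chain of :class:`FilterReport` records.
    """
    reports = []
    m, r = filter_confidence(m, min_conf)
    reports.append(r)
    m, r = filter_biotype(m, biotype_keep)
    reports.append(r)
    m, r = filter_replicate_outliers(m, outlier_k, outlier_require)
    reports.append(r)
    m, r = filter_low_expression(m, low_expr_threshold, low_expr_mode)
    reports.append(r)
    z, r = zscore(m)
    reports.append(r)
    filtered = m.subset(list(z.index))
    return z, filtered, reports
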