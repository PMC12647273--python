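"""Synthetic study generator with planted, recoverable ground truth.

Emulates the screen's 8-sample cortex microarray design — two replicate
samples at each of four lesion levels (severe, moderate, weak, control) —
with a planted subset of "suppressive" lncRNA probes whose expected
intensity decreases monotonically with lesion severity, shared subsequences
planted into those probes' (pre-aligned, gapless) sequences, reverse
complements of those motifs embedded in a decoy mRNA database, and
annotation terms planted over the target genes.  Every downstream stage can
therefore be checked against known truth without any external download.

All randomness flows from one explicit integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import reverse_complement
from .containers import (
    Alignment,
    CONDITIONS,
    ExpressionMatrix,
    SyntheticTruth,
    TranscriptRecord,
)
from .matching import scan_database

logger = logging.getLogger(__name__)

#: Default planted shared subsequences (RNA) and their alignment start
#: columns within the 60-nt probe sequences.
DEFAULT_MOTIFS: list[tuple[str, int]] = [
    ("UUCUUUCACAUA", 8),
    ("AUCAUCUUUCC", 34),
]

_SAMPLE_ORDER = ("severe", "severe", "moderate", "moderate", "weak", "weak", "control", "control")


@dataclass
class SyntheticMrnaDB:
    """The generated mRNA search space and its annotation resources."""

    transcripts: list[TranscriptRecord]
    whitelist: set[str]
    gmt: dict[str, tuple[str, frozenset[str]]]  # term -> (description, genes)
    category: str = "SYNTH_DB"


def generate_expression(
    n_probes: int = 1000,
    n_suppressive: int = 50,
    base_intensity: float = 1000.0,
    effect_size: float = 250.0,
    noise_sd: float = 50.0,
    seed: int = 0,
    frac_low_conf: float = 0.05,
    frac_non_lnc: float = 0.10,
    frac_low_expr: float = 0.05,
    frac_outlier: float = 0.02,
    planted_motifs: list[tuple[str, int]] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the 8-sample probe intensity table with planted signal.

    Suppressive probes have mean intensity ``base_intensity * (1 - d*sev)``
    with ``d = effect_size / base_intensity``: the expected drop per unit of
    severity equals ``effect_size`` in intensity units, so quoting it as a
    multiple of ``noise_sd`` gives the usual standardized effect size
    between adjacent lesion conditions.  Intensities are log-normal with the stated mean and sd
    ``noise_sd``, clipped at a floor of 1.  Fractions of the background
    probes are made to fail each preprocessing filter: confidence never
    reaching 2, a non-lncRNA biotype, one sample pushed below intensity 100,
    or replicate disagreement far outside the pooled spread.
    """
    if n_probes <= 0:
        raise ValueError(f"n_probes must be positive, got {n_probes}")
    if n_suppressive <= 0 or n_suppressive > n_probes:
        raise ValueError(
            f"n_suppressive must be in 1..n_probes, got {n_suppressive} (n_probes={n_probes})"
        )
    if base_intensity <= 0:
        raise ValueError(f"base_intensity must be positive, got {base_intensity}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if effect_size < 0:
        raise ValueError(f"effect_size must be >= 0, got {effect_size}")
    if 3 * effect_size >= base_intensity:
        raise ValueError(
            "3 * effect_size must be smaller than base_intensity so severe-lesion "
            "means stay positive"
        )
    rng = np.random.default_rng(seed)
    width = len(str(n_probes))
    probe_ids = [f"PROBE{str(i + 1).zfill(width)}" for i in range(n_probes)]
    sample_ids = []
    counts: dict[str, int] = {}
    for cond in _SAMPLE_ORDER:
        counts[cond] = counts.get(cond, 0) + 1
        sample_ids.append(f"{cond}_{counts[cond]}")
    condition = pd.Series(list(_SAMPLE_ORDER), index=sample_ids, name="condition")
    severity = condition.map({c: i for i, c in enumerate(CONDITIONS)}).to_numpy()

    suppressive = set(rng.choice(probe_ids, size=n_suppressive, replace=False))
    background = [p for p in probe_ids if p not in suppressive]
    rng.shuffle(background)
    n_bg = len(background)

    def take(frac: float) -> set[str]:
        n = int(round(frac * n_probes))
        n = min(n, len(background))
        picked = set(background[:n])
        del background[:n]
        return picked

    low_conf = take(frac_low_conf)
    non_lnc = take(frac_non_lnc)
    low_expr = take(frac_low_expr)
    outlier = take(frac_outlier)

    delta = effect_size / base_intensity
    mean = np.full((n_probes, 8), base_intensity)
    supp_mask = np.array([p in suppressive for p in probe_ids])
    mean[supp_mask] = base_intensity * (1.0 - delta * severity)

    if noise_sd > 0:
        v = noise_sd**2
        sigma2 = np.log1p(v / mean**2)
        mu = np.log(mean) - sigma2 / 2.0
        inten = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
    else:
        inten = mean.copy()

    for p in sorted(outlier):  # sorted: set order is hash-seed dependent
        i = probe_ids.index(p)
        # blow up every within-condition difference so the probe is flagged
        # at every comparison under require="all"
        inten[i, 0::2] += 40.0 * max(noise_sd, 1.0)
    for p in sorted(low_expr):
        i = probe_ids.index(p)
        j = int(rng.integers(0, 8))
        inten[i, j] = float(rng.uniform(10.0, 90.0))
    inten = np.maximum(inten, 1.0)

    conf = rng.integers(0, 3, size=(n_probes, 8))
    # guarantee each passing probe one top-confidence sample
    top_sample = rng.integers(0, 8, size=n_probes)
    conf[np.arange(n_probes), top_sample] = 2
    low_conf_mask = np.array([p in low_conf for p in probe_ids])
    conf[low_conf_mask] = rng.integers(0, 2, size=(int(low_conf_mask.sum()), 8))

    biotype = pd.Series("lncRNA", index=probe_ids, name="biotype")
    biotype.loc[sorted(non_lnc)] = "mRNA"

    m = ExpressionMatrix(
        intensities=pd.DataFrame(inten, index=probe_ids, columns=sample_ids),
        confidence=pd.DataFrame(conf, index=probe_ids, columns=sample_ids),
        biotype=biotype,
        condition=condition,
    )
    truth = SyntheticTruth(
        probe_ids=probe_ids,
        suppressive_probe_ids=suppressive,
        planted_motifs=list(planted_motifs or DEFAULT_MOTIFS),
        seed=seed,
    )
    return m, truth


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def generate_probe_sequences(
    truth: SyntheticTruth,
    probe_length: int = 60,
    seed: int | None = None,
    corruption: float = 0.0,
) -> Alignment:
    """Equal-length, gapless probe sequences (an implicit trivial alignment).

    Every suppressive probe carries each planted motif at its planted
    column; with ``corruption > 0`` each planted base is independently
    replaced by a random different base with that probability.  Background
    probes are uniform random RNA.
    """
    if probe_length <= 0:
        raise ValueError(f"probe_length must be positive, got {probe_length}")
    for motif, col in truth.planted_motifs:
        if col + len(motif) > probe_length:
            raise ValueError(
                f"motif {motif!r} at column {col} exceeds probe_length {probe_length}"
            )
    if not 0 <= corruption <= 1:
        raise ValueError(f"corruption must be in [0, 1], got {corruption}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    bases = np.array(list("ACGU"))
    seqs = []
    for pid in truth.probe_ids:
        s = list(_random_seq(rng, probe_length))
        if pid in truth.suppressive_probe_ids:
            for motif, col in truth.planted_motifs:
                for i, b in enumerate(motif):
                    if corruption > 0 and rng.random() < corruption:
                        s[col + i] = str(rng.choice(bases[bases != b]))
                    else:
                        s[col + i] = b
        seqs.append("".join(s))
    return Alignment(list(truth.probe_ids), seqs)


def generate_mrna_db(
    truth: SyntheticTruth,
    n_decoys: int = 200,
    seed: int | None = None,
    n_targets_per_motif: int = 12,
    mismatch_frac: float = 0.25,
    transcript_length: int = 400,
    predicted_frac: float = 0.30,
    whitelist_target_coverage: float = 1.0,
    whitelist_decoy_coverage: float = 0.80,
    n_terms_per_motif: int = 2,
    n_background_terms: int = 30,
    min_identity: float = 0.85,
    plant_terms: bool = True,
) -> SyntheticMrnaDB:
    """Generate the mRNA search space, whitelist and annotation sets.

    Target transcripts embed the reverse complement of a planted motif —
    some exact, a ``mismatch_frac`` fraction with one mismatch (still above
    the identity threshold for motifs >= 10 nt).  Decoys are verified by
    exhaustive scan to contain no complement occurrence at identity >=
    ``min_identity`` and resampled until clean.  A ``predicted_frac``
    fraction of decoy headers are labelled "PREDICTED"/"cDNA" so the header
    filter has work to do.  The whitelist covers ``whitelist_target_coverage``
    of target genes and ``whitelist_decoy_coverage`` of decoy genes.  With
    ``plant_terms``, ``n_terms_per_motif`` terms are planted over each
    motif's target genes (recorded in ``truth.enriched_terms``) on top of
    ``n_background_terms`` random background terms.

    Updates ``truth.planted_target_transcripts`` / ``planted_target_genes``
    in place and returns the database bundle.
    """
    if n_decoys == 0 and plant_terms:
        logger.warning("n_decoys=0 with enrichment terms requested: background will be tiny")
    rng = np.random.default_rng((truth.seed if seed is None else seed) + 1)
    complements = [
        reverse_complement(motif, alphabet="rna").replace("U", "T")
        for motif, _ in truth.planted_motifs
    ]

    def clean_backbone(length: int, forbid: list[str]) -> str:
        for _ in range(200):
            s = _random_seq(rng, length, "ACGT")
            rec = [TranscriptRecord("tmp", "tmp", "", s)]
            if all(not scan_database(c, rec, min_identity) for c in forbid):
                return s
        raise RuntimeError("could not generate a clean backbone; lower min_identity")

    transcripts: list[TranscriptRecord] = []
    truth.planted_target_transcripts = {}
    truth.planted_target_genes = {}
    for mi, comp in enumerate(complements):
        tids, genes = set(), set()
        for t in range(n_targets_per_motif):
            tid = f"TX_M{mi + 1}_{t + 1:03d}"
            gene = f"TG{mi + 1}G{t + 1:02d}"
            while True:
                backbone = clean_backbone(transcript_length, complements)
                pos = int(rng.integers(0, transcript_length - len(comp) + 1))
                embedded = comp
                if rng.random() < mismatch_frac:
                    j = int(rng.integers(0, len(comp)))
                    choices = [b for b in "ACGT" if b != comp[j]]
                    embedded = comp[:j] + str(rng.choice(choices)) + comp[j + 1 :]
                seq = backbone[:pos] + embedded + backbone[pos + len(comp) :]
                rec = [TranscriptRecord(tid, gene, "", seq)]
                others = [c for k, c in enumerate(complements) if k != mi]
                if all(not scan_database(c, rec, min_identity) for c in others):
                    break
            transcripts.append(
                TranscriptRecord(tid, gene, f"Mus musculus {gene.capitalize()} mRNA", seq)
            )
            tids.add(tid)
            genes.add(gene)
        truth.planted_target_transcripts[mi] = tids
        truth.planted_target_genes[mi] = genes

    decoy_genes = []
    for d in range(n_decoys):
        tid = f"TX_D{d + 1:04d}"
        gene = f"BG{d + 1:04d}"
        seq = clean_backbone(transcript_length, complements)
        if rng.random() < predicted_frac:
            desc = (
                f"PREDICTED: Mus musculus {gene.capitalize()} mRNA"
                if rng.random() < 0.5
                else f"Mus musculus {gene.capitalize()} cDNA clone"
            )
        else:
            desc = f"Mus musculus {gene.capitalize()} mRNA"
        transcripts.append(TranscriptRecord(tid, gene, desc, seq))
        decoy_genes.append(gene)

    whitelist: set[str] = set()
    for mi, genes in truth.planted_target_genes.items():
        gs = sorted(genes)
        n_cov = int(round(whitelist_target_coverage * len(gs)))
        whitelist.update(rng.choice(gs, size=n_cov, replace=False).tolist())
    n_cov = int(round(whitelist_decoy_coverage * len(decoy_genes)))
    if decoy_genes:
        whitelist.update(rng.choice(decoy_genes, size=n_cov, replace=False).tolist())

    all_genes = sorted({t.gene_symbol for t in transcripts})
    gmt: dict[str, tuple[str, frozenset[str]]] = {}
    truth.enriched_terms = set()
    if plant_terms:
        for mi, genes in truth.planted_target_genes.items():
            for t in range(n_terms_per_motif):
                term = f"TERM_PLANTED_M{mi + 1}_{t + 1}"
                extra = rng.choice(decoy_genes, size=min(3, len(decoy_genes)), replace=False)
                gmt[term] = (
                    f"planted function of motif {mi + 1} targets",
                    frozenset(genes) | frozenset(extra.tolist()),
                )
                truth.enriched_terms.add(term)
    for b in range(n_background_terms):
        size = int(rng.integers(10, 31))
        members = rng.choice(all_genes, size=min(size, len(all_genes)), replace=False)
        gmt[f"TERM_BG_{b + 1:03d}"] = ("background annotation", frozenset(members.tolist()))
    return SyntheticMrnaDB(transcripts=transcripts, whitelist=whitelist, gmt=gmt)
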