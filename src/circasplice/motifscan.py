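"""Clock transcription-factor binding-site prediction and enrichment.

Pseudocount-regularized PSSMs, promoter-region extraction (5 kb upstream of
the TSS through the end of the first intron), a both-strand log-odds window
scan, per-gene motif presence, seeded control-set sampling, and one-tailed
Fisher enrichment between rhythmic and non-rhythmic gene sets.

Default matrices for the four clock elements are consensus-derived
stand-ins; matrices can be supplied from file via :mod:`circasplice.cli_io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PSSM",
    "PromoterSequence",
    "MotifHit",
    "EnrichmentResult",
    "build_pssm",
    "pssm_from_consensus",
    "default_clock_pssms",
    "extract_promoter",
    "dedupe_promoters",
    "scan_sequence",
    "gene_motif_presence",
    "sample_control_set",
    "enrichment_test",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PSSM:
    """Per-position base probabilities over A/C/G/T."""

    name: str
    matrix: np.ndarray  # width x 4, rows sum to 1

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PSSM matrix must be width x 4")
        if np.any(m <= 0):
            raise ValueError("all probabilities must be > 0 after regularization")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PSSM position must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PSSM":
        return PSSM(name=self.name, matrix=self.matrix[::-1, ::-1].copy())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class PromoterSequence:
    gene_id: str
    mrna_id: str
    sequence: str
    reference: str
    start: int   # 1-based inclusive, on the reference
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("region length must equal sequence length")


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    motif: str
    position: int   # 1-based start on the scanned sequence
    strand: str
    score: float    # log-likelihood ratio, bits


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: rhythmic, control; cols: with, without
    odds_ratio: float
    p_value: float


def build_pssm(
    table: np.ndarray | Sequence[Sequence[float]],
    pseudocount: float = 0.01,
    name: str = "pssm",
) -> PSSM:
    """Regularize a 4-column count/probability table into a PSSM."""
    m = np.asarray(table, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError("PSSM table must be width x 4 (columns A C G T)")
    if m.shape[0] < 4:
        raise ValueError("PSSM width must be >= 4")
    if np.any(m < 0):
        raise ValueError("PSSM entries must be non-negative")
    if np.any(m.sum(axis=1) == 0):
        raise ValueError("all-zero PSSM position")
    m = m + pseudocount
    m = m / m.sum(axis=1, keepdims=True)
    return PSSM(name=name, matrix=m)


def pssm_from_consensus(consensus: str, name: str, pseudocount: float = 0.01) -> PSSM:
    """Count-1 columns on the (IUPAC) consensus bases, then regularize."""
    counts = np.zeros((len(consensus), 4))
    for i, c in enumerate(consensus.upper()):
        if c not in IUPAC:
            raise ValueError(f"unknown IUPAC code {c!r} in consensus")
        for b in IUPAC[c]:
            counts[i, _BASE_INDEX[b]] = 1.0
    return build_pssm(counts, pseudocount=pseudocount, name=name)


def default_clock_pssms(pseudocount: float = 0.01) -> dict[str, PSSM]:
    """Consensus-derived stand-in matrices for the four clock elements."""
    consensi = {
        "E-box": "CACGTG",
        "E'-box": "CACGTT",
        "D-box": "TTATGYAA",
        "RRE": "WAWNTRGGTCA",
    }
    return {
        name: pssm_from_consensus(cons, name=name, pseudocount=pseudocount)
        for name, cons in consensi.items()
    }


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def extract_promoter(
    gene_id: str,
    mrna_id: str,
    exons: Sequence[tuple[int, int]],
    strand: str,
    chromosome: str,
    reference: str = "chr",
    upstream: int = 5000,
) -> PromoterSequence:
    """Sense-strand sequence from ``upstream`` bases before the TSS to the
    end of the first intron.

    ``exons`` are 1-based inclusive (start, end) pairs in genomic order.
    Minus-strand genes are reverse-complemented so the output reads 5'->3'
    on the gene's sense strand. Regions are truncated at chromosome edges
    with a warning.
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    if len(exons) < 2:
        raise ValueError("transcript needs >= 2 exons (no first intron otherwise)")
    exons = sorted(exons)
    chrom_len = len(chromosome)
    if strand == "+":
        tss = exons[0][0]
        intron1_end = exons[1][0] - 1
        start, end = tss - upstream, intron1_end
    else:
        tss = exons[-1][1]
        intron1_end = exons[-2][1] + 1
        start, end = intron1_end, tss + upstream
    if end < 1 or start > chrom_len:
        raise ValueError("promoter region lies entirely off the chromosome")
    if start < 1 or end > chrom_len:
        warnings.warn(
            f"{mrna_id}: promoter region [{start}, {end}] truncated to chromosome bounds",
            stacklevel=2,
        )
        start, end = max(start, 1), min(end, chrom_len)
    window = chromosome[start - 1 : end].upper()
    seq = window if strand == "+" else reverse_complement(window)
    return PromoterSequence(
        gene_id=gene_id, mrna_id=mrna_id, sequence=seq,
        reference=reference, start=start, end=end, strand=strand,
    )


def dedupe_promoters(promoters: Iterable[PromoterSequence]) -> list[PromoterSequence]:
    """Drop duplicate sequences within each gene, keeping first occurrence."""
    seen: set[tuple[str, str]] = set()
    out = []
    for p in promoters:
        key = (p.gene_id, p.sequence)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def scan_sequence(
    seq: str,
    pssm: PSSM,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    threshold: float = 8.0,
    seq_id: str = "seq",
) -> list[MotifHit]:
    """Log-odds scan of every window on both strands.

    score = sum over positions of log2(p_motif(base)/p_background(base));
    windows containing N are skipped; hits (score >= threshold) are
    returned in ascending position, '+' before '-'.
    """
    bg = np.asarray(background, dtype=float)
    if len(bg) != 4 or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 positive frequencies summing to 1")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s = seq.upper()
    w = pssm.width
    if len(s) < w:
        return []
    logodds = {
        "+": np.log2(pssm.matrix / bg[None, :]),
        "-": np.log2(pssm.reverse_complement().matrix / bg[None, :]),
    }
    hits = []
    for pos in range(len(s) - w + 1):
        window = s[pos : pos + w]
        if any(c not in _BASE_INDEX for c in window):
            continue
        idx = [_BASE_INDEX[c] for c in window]
        for strand in "+-":
            score = float(sum(logodds[strand][i, b] for i, b in enumerate(idx)))
            if score >= threshold:
                hits.append(
                    MotifHit(seq_id=seq_id, motif=pssm.name, position=pos + 1,
                             strand=strand, score=score)
                )
    return hits


def gene_motif_presence(
    hits: Iterable[MotifHit],
    seq_to_gene: Mapping[str, str],
    motif_names: Sequence[str] | None = None,
) -> dict[str, bool]:
    """Flag each gene that has >= 1 hit for any motif in any of its sequences."""
    flags = {gene: False for gene in set(seq_to_gene.values())}
    wanted = set(motif_names) if motif_names is not None else None
    for hit in hits:
        if hit.seq_id not in seq_to_gene:
            raise KeyError(f"hit on unmapped sequence {hit.seq_id!r}")
        if wanted is not None and hit.motif not in wanted:
            continue
        flags[seq_to_gene[hit.seq_id]] = True
    return flags


def sample_control_set(pool: Sequence[str], n: int, seed: int) -> list[str]:
    """Seeded uniform sample of genes without replacement."""
    if n > len(pool):
        raise ValueError(f"cannot sample {n} from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    return [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]


def enrichment_test(
    flags_rhythmic: Mapping[str, bool] | Sequence[bool],
    flags_control: Mapping[str, bool] | Sequence[bool],
) -> EnrichmentResult:
    """One-tailed Fisher exact test for motif enrichment in the rhythmic set.

    The p value is the hypergeometric upper tail of the 2x2 table
    (rhythmic/control x with/without motif); the odds ratio is the sample
    odds ratio, reported as inf/0/nan under the zero-cell conventions.
    """
    rhythmic = list(flags_rhythmic.values()) if isinstance(flags_rhythmic, Mapping) else list(flags_rhythmic)
    control = list(flags_control.values()) if isinstance(flags_control, Mapping) else list(flags_control)
    if not rhythmic or not control:
        raise ValueError("both gene sets must be non-empty")
    a = sum(bool(x) for x in rhythmic)
    b = len(rhythmic) - a
    c = sum(bool(x) for x in control)
    d = len(control) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = np.inf
    else:
        odds = np.nan
    return EnrichmentResult(table=((a, b), (c, d)), odds_ratio=float(odds), p_value=float(p))
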