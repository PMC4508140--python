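"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the library's own code paths: the seed-site oracle
tests base pairing position by position at every anchor, the positional
oracle uses explicit per-base sets for overlap, and the alignment oracle is a
plain three-matrix Gotoh dynamic program.
"""
from __future__ import annotations

import numpy as np

from cerna_scan.models import GenomicInterval, TranscriptModel

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# seed-site oracle


def oracle_scan(target: str, mirna_seq: str, allow_imperfect: bool = False):
    """(anchor, site_type) pairs by sliding every anchor and testing pairing
    of each miRNA position directly."""
    t = target.upper().replace("U", "T")
    m = mirna_seq.upper().replace("U", "T")

    def paired(p: int, anchor: int) -> bool:
        idx = anchor - p + 1  # miRNA position p faces this target index
        return 0 <= idx < len(t) and t[idx] == _COMP.get(m[p - 1], "?")

    out = []
    # the anchor can overhang the target 3' end by one (offset-6mer leaves
    # miRNA positions 1-2 unpaired), hence len(t) + 2
    for a in range(0, len(t) + 2):
        seed = all(paired(p, a) for p in range(2, 8))
        m8 = paired(8, a)
        a1 = 0 <= a < len(t) and t[a] == "A"
        label = None
        if seed and m8 and a1:
            label = "8mer"
        elif seed and m8:
            label = "7mer-m8"
        elif seed and a1:
            label = "7mer-A1"
        elif seed:
            label = "6mer"
        elif m8 and all(paired(p, a) for p in range(3, 8)):
            label = "offset-6mer"
        elif allow_imperfect and a <= len(t):
            if a >= 6 and "N" not in t[a - 6 : a]:
                defects = sum(1 for p in range(2, 8) if not paired(p, a))
                if defects == 1:
                    label = "imperfect"
            if label is None and a >= 5 and "N" not in t[a - 5 : a]:
                motif6 = "".join(_COMP[c] for c in reversed(m[1:7]))
                window = t[a - 5 : a]
                for j in range(6):
                    if motif6[:j] + motif6[j + 1 :] == window:
                        label = "imperfect"
                        break
        if label is not None:
            out.append((a, label))
    return out


# ---------------------------------------------------------------------------
# positional oracle

_PRECEDENCE = (
    "sense_exon_overlap",
    "sense_intron_overlap",
    "antisense_exon_overlap",
    "antisense_intron_overlap",
    "bidirectional",
)


def oracle_relate(lnc: TranscriptModel, coding: TranscriptModel) -> str | None:
    if lnc.locus.chrom != coding.locus.chrom:
        return None
    lnc_locus = set(range(lnc.locus.start, lnc.locus.end))
    cod_locus = set(range(coding.locus.start, coding.locus.end))
    lnc_exonic = set()
    for ex in lnc.exons:
        lnc_exonic |= set(range(ex.start, ex.end))
    cod_exonic = set()
    for ex in coding.exons:
        cod_exonic |= set(range(ex.start, ex.end))
    same = lnc.locus.strand == coding.locus.strand
    if lnc_locus & cod_locus:
        if lnc_exonic & cod_exonic:
            return "sense_exon_overlap" if same else "antisense_exon_overlap"
        return "sense_intron_overlap" if same else "antisense_intron_overlap"
    if same:
        return None
    if lnc.locus.end <= coding.locus.start:
        left, right, gap = lnc, coding, coding.locus.start - lnc.locus.end
    else:
        left, right, gap = coding, lnc, lnc.locus.start - coding.locus.end
    head_to_head = left.locus.strand == "-" and right.locus.strand == "+"
    if head_to_head and 1 <= gap <= 1000:
        return "bidirectional"
    return None


def oracle_gap(a: TranscriptModel, b: TranscriptModel) -> int | None:
    if a.locus.chrom != b.locus.chrom:
        return None
    if a.locus.end <= b.locus.start:
        return b.locus.start - a.locus.end
    if b.locus.end <= a.locus.start:
        return a.locus.start - b.locus.end
    return 0


def oracle_classify(lnc: TranscriptModel, coding_set: list[TranscriptModel]):
    """(class_label, associated_gene) via exhaustive pair checks."""
    hits: dict[str, list[tuple[int, str]]] = {}
    gaps = []
    for coding in coding_set:
        gap = oracle_gap(lnc, coding)
        if gap is not None:
            gaps.append(gap)
        label = oracle_relate(lnc, coding)
        if label is not None:
            hits.setdefault(label, []).append((gap, coding.gene_name))
    for label in _PRECEDENCE:
        if label in hits:
            return label, min(hits[label])[1]
    if not gaps or min(gaps) > 30_000:
        return "intergenic", ""
    return "unclassified", ""


def random_transcript(
    rng: np.random.Generator,
    tid: str,
    biotype: str,
    *,
    chroms=("chr1", "chr2"),
    max_start: int = 60_000,
) -> TranscriptModel:
    chrom = chroms[int(rng.integers(0, len(chroms)))]
    strand = "+" if rng.integers(0, 2) else "-"
    start = int(rng.integers(0, max_start))
    n_exons = int(rng.integers(1, 4))
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(50, 400))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(30, 800))
    locus = GenomicInterval(chrom, start, exons[-1].end, strand)
    return TranscriptModel(tid, tid, biotype, locus, tuple(exons))


# ---------------------------------------------------------------------------
# alignment oracle


def gotoh_local_score(
    a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0
) -> float:
    """Exhaustive affine-gap Smith-Waterman score (a gap of length k costs
    open + (k-1)*extend); N scores as a mismatch against everything."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                s = match
            else:
                s = mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))
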