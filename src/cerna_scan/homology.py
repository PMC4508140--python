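"""Homology-based "mimicked gene" detection.

A lncRNA's mimicked gene is a protein-coding sequence with high similarity to
the lncRNA whose genomic locus lies on a *different* chromosome (>=90 %
identity by default). Pairs are found by optimal Smith-Waterman local
alignment of the transcript sequences on both strands; percent identity is
computed over all alignment columns, gap columns included, which penalizes
indels. N never matches anything, including another N.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

_ALPHABET = "ACGTN"
_VALID = frozenset(_ALPHABET)
_TO_DNA = str.maketrans("Uu", "Tt")
_RC = str.maketrans("ACGTN", "TGCAN")

#: Default identity threshold for a mimicked-gene call.
DEFAULT_MIN_IDENTITY = 0.90
#: Alignment must span at least this fraction of the shorter sequence for a
#: pair to pass: local alignment of unrelated sequences always contains short
#: perfect segments, which would otherwise satisfy any identity threshold.
DEFAULT_MIN_COVERAGE = 0.50


@dataclass(frozen=True)
class ScoringParams:
    """Nucleotide scoring: match +1, mismatch -1, gaps -2 to open then -1."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal local alignment and its identity statistics.

    ``percent_identity`` is matches / alignment_columns (gap columns count in
    the denominator). ``strand`` is '-' when the subject aligned better as its
    reverse complement; subject_span is always reported on the original
    subject coordinates.
    """

    query_id: str
    subject_id: str
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    matches: int
    alignment_columns: int
    percent_identity: float
    score: float
    strand: str = "+"


@dataclass(frozen=True)
class MimicPair:
    """One lncRNA/coding-gene candidate from the all-vs-all homology search."""

    lncrna_id: str
    gene_id: str
    percent_identity: float
    lnc_chrom: str
    gene_chrom: str
    passes: bool
    coverage: float = 0.0
    strand: str = "+"


def _check_sequence(seq: str, name: str) -> str:
    s = seq.upper().translate(_TO_DNA)
    if not s:
        raise ValueError(f"{name}: empty sequence")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"{name}: invalid characters {sorted(bad)}")
    return s


def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == b and a != "N":
                matrix[a, b] = params.match
            else:
                matrix[a, b] = params.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _align_one_strand(aligner, a: str, b: str):
    alignments = aligner.align(a, b)
    if len(alignments) == 0:
        return None
    return alignments[0]  # deterministic traceback: first optimal alignment


def local_align(
    a: str,
    b: str,
    params: ScoringParams = ScoringParams(),
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    strand_aware: bool = True,
) -> AlignmentResult:
    """Optimal local alignment of ``a`` (query) vs ``b`` (subject).

    With ``strand_aware`` the subject is also aligned as its reverse
    complement and the better-scoring strand kept.
    """
    a = _check_sequence(a, query_id)
    b = _check_sequence(b, subject_id)
    aligner = _make_aligner(params)
    candidates = [("+", b, _align_one_strand(aligner, a, b))]
    if strand_aware:
        b_rc = b.translate(_RC)[::-1]
        candidates.append(("-", b_rc, _align_one_strand(aligner, a, b_rc)))
    strand, b_used, best = max(
        candidates, key=lambda c: -float("inf") if c[2] is None else c[2].score
    )
    if best is None or best.score <= 0:
        return AlignmentResult(
            query_id, subject_id, (0, 0), (0, 0), 0, 0, 0.0, 0.0, "+"
        )
    aligned_a, aligned_b = str(best[0]), str(best[1])
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x not in ("-", "N")
    )
    columns = len(aligned_a)
    coords = best.coordinates
    q_span = (int(coords[0][0]), int(coords[0][-1]))
    s_lo, s_hi = int(coords[1][0]), int(coords[1][-1])
    if strand == "-":
        s_lo, s_hi = len(b) - s_hi, len(b) - s_lo
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        query_span=q_span,
        subject_span=(s_lo, s_hi),
        matches=matches,
        alignment_columns=columns,
        percent_identity=matches / columns if columns else 0.0,
        score=float(best.score),
        strand=strand,
    )


def find_mimicked_genes(
    lncs: dict[str, str],
    coding: dict[str, str],
    lnc_loci: dict[str, str],
    coding_loci: dict[str, str],
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    report_floor: float = 0.0,
    params: ScoringParams = ScoringParams(),
) -> list[MimicPair]:
    """All-vs-all mimicked-gene search between lncRNAs and coding sequences.

    ``lncs``/``coding`` map sequence ids to sequences; the loci maps give each
    id its chromosome. A pair passes when percent identity >= ``min_identity``,
    the chromosomes differ, and the alignment covers >= ``min_coverage`` of
    the shorter sequence. Every pair with identity >= ``report_floor`` is
    returned for audit, passing or not.
    """
    for name, seqs, loci in (("lncRNA", lncs, lnc_loci), ("coding", coding, coding_loci)):
        missing = sorted(set(seqs) - set(loci))
        if missing:
            raise KeyError(
                f"{name} id(s) present in sequences but absent from loci map: "
                f"{', '.join(missing)}"
            )
    pairs = []
    for lnc_id, lnc_seq in lncs.items():
        for gene_id, gene_seq in coding.items():
            aln = local_align(
                lnc_seq, gene_seq, params, query_id=lnc_id, subject_id=gene_id
            )
            coverage = aln.alignment_columns / min(len(lnc_seq), len(gene_seq))
            passes = (
                aln.percent_identity >= min_identity
                and lnc_loci[lnc_id] != coding_loci[gene_id]
                and coverage >= min_coverage
            )
            if aln.percent_identity >= report_floor or passes:
                pairs.append(
                    MimicPair(
                        lncrna_id=lnc_id,
                        gene_id=gene_id,
                        percent_identity=aln.percent_identity,
                        lnc_chrom=lnc_loci[lnc_id],
                        gene_chrom=coding_loci[gene_id],
                        passes=passes,
                        coverage=coverage,
                        strand=aln.strand,
                    )
                )
    pairs.sort(key=lambda p: (-p.percent_identity, p.lncrna_id, p.gene_id))
    return pairs


def mimic_table(pairs: list[MimicPair]) -> pd.DataFrame:
    """Audit table of the homology search, best pairs first."""
    rows = [
        {
            "lncRNA_ID": p.lncrna_id,
            "Mimicked_Gene": p.gene_id,
            "lncRNA_chromosome": p.lnc_chrom,
            "Gene_chromosome": p.gene_chrom,
            "Sequence_similarity_pct": round(100.0 * p.percent_identity, 1),
            "Coverage": round(p.coverage, 3),
            "Strand": p.strand,
            "Passes": p.passes,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lncRNA_ID",
            "Mimicked_Gene",
            "lncRNA_chromosome",
            "Gene_chromosome",
            "Sequence_similarity_pct",
            "Coverage",
            "Strand",
            "Passes",
        ],
    )
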