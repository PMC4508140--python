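"""Positional classification of lncRNAs against coding transcripts.

A lncRNA is related to each nearby coding transcript by one of six classes:

* ``sense_exon_overlap`` -- same strand, >=1 bp of exon-exon overlap;
* ``sense_intron_overlap`` -- same strand, loci overlap but no exon-exon overlap;
* ``antisense_exon_overlap`` / ``antisense_intron_overlap`` -- the same two
  cases on opposite strands;
* ``bidirectional`` -- opposite strands, no locus overlap, 5' ends facing each
  other (divergent, head-to-head transcription) across a gap of 1..1000 bp;
* ``intergenic`` -- no coding transcript within 30 kb on the lncRNA's
  chromosome (strictly more than 30000 bp to the nearest one, or none at all).

A lncRNA that has no overlap/bidirectional relation but does have a coding
transcript within 30 kb is ``unclassified``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .models import TranscriptModel

SENSE_EXON = "sense_exon_overlap"
SENSE_INTRON = "sense_intron_overlap"
ANTISENSE_EXON = "antisense_exon_overlap"
ANTISENSE_INTRON = "antisense_intron_overlap"
BIDIRECTIONAL = "bidirectional"
INTERGENIC = "intergenic"
UNCLASSIFIED = "unclassified"

#: Classes assignable by :func:`relate_pair`, from highest to lowest precedence.
PAIR_CLASSES = (SENSE_EXON, SENSE_INTRON, ANTISENSE_EXON, ANTISENSE_INTRON, BIDIRECTIONAL)

#: All class labels, in reporting precedence order.
CLASS_LABELS = PAIR_CLASSES + (UNCLASSIFIED, INTERGENIC)

#: Maximum head-to-head gap (bp) for the bidirectional class.
BIDIRECTIONAL_MAX_GAP = 1000

#: A lncRNA is intergenic when the nearest coding transcript is strictly
#: farther than this many bp.
INTERGENIC_MIN_GAP = 30_000


@dataclass(frozen=True)
class PositionalRelation:
    """The positional class of one lncRNA against a coding-transcript set."""

    lncrna_id: str
    class_label: str
    associated_gene: str = ""
    associated_gene_strand: str = ""
    distance: int | None = None
    co_qualifying: tuple[str, ...] = field(default_factory=tuple)


def _exon_exon_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(ea.overlaps(eb) for ea in a.exons for eb in b.exons)


def _head_to_head(a: TranscriptModel, b: TranscriptModel) -> bool:
    # Divergent orientation: the left transcript runs leftward ('-', TSS at its
    # right edge) and the right transcript rightward ('+', TSS at its left
    # edge), so both 5' ends face the inter-locus gap.
    left, right = (a, b) if a.locus.start <= b.locus.start else (b, a)
    return left.locus.strand == "-" and right.locus.strand == "+"


def relate_pair(lnc: TranscriptModel, coding: TranscriptModel) -> str | None:
    """Class of ``lnc`` relative to one coding transcript, or None.

    Transcripts on different chromosomes are unrelated. Overlap classes
    require >=1 bp of locus overlap; the exon variants additionally require
    >=1 bp of exon-exon overlap. Bidirectional requires opposite strands,
    disjoint loci, head-to-head orientation and a gap of 1..1000 bp
    (abutting loci, gap 0, do not qualify).
    """
    if lnc.locus.chrom != coding.locus.chrom:
        return None
    same_strand = lnc.locus.strand == coding.locus.strand
    if lnc.locus.overlaps(coding.locus):
        if _exon_exon_overlap(lnc, coding):
            return SENSE_EXON if same_strand else ANTISENSE_EXON
        return SENSE_INTRON if same_strand else ANTISENSE_INTRON
    gap = lnc.locus.gap(coding.locus)
    if (
        not same_strand
        and gap is not None
        and 1 <= gap <= BIDIRECTIONAL_MAX_GAP
        and _head_to_head(lnc, coding)
    ):
        return BIDIRECTIONAL
    return None


def classify_lncrna(
    lnc: TranscriptModel, coding_set: list[TranscriptModel]
) -> PositionalRelation:
    """Highest-precedence positional relation of ``lnc`` over ``coding_set``.

    Ties at equal precedence are broken by smallest locus gap, then by
    lexicographic gene name; every co-qualifying gene of the winning class is
    also reported. With no relation, the lncRNA is intergenic when the nearest
    same-chromosome coding transcript is strictly beyond 30 kb (or absent),
    otherwise unclassified.
    """
    by_class: dict[str, list[tuple[int, str, TranscriptModel]]] = {}
    min_gap: int | None = None
    for coding in coding_set:
        gap = lnc.locus.gap(coding.locus)
        if gap is not None and (min_gap is None or gap < min_gap):
            min_gap = gap
        label = relate_pair(lnc, coding)
        if label is not None:
            by_class.setdefault(label, []).append((gap, coding.gene_name, coding))

    for label in PAIR_CLASSES:
        if label in by_class:
            hits = sorted(by_class[label], key=lambda h: (h[0], h[1]))
            gap, gene_name, coding = hits[0]
            return PositionalRelation(
                lncrna_id=lnc.transcript_id,
                class_label=label,
                associated_gene=gene_name,
                associated_gene_strand=coding.locus.strand,
                distance=min_gap,
                co_qualifying=tuple(dict.fromkeys(h[1] for h in hits)),
            )
    if min_gap is None or min_gap > INTERGENIC_MIN_GAP:
        return PositionalRelation(
            lncrna_id=lnc.transcript_id, class_label=INTERGENIC, distance=min_gap
        )
    return PositionalRelation(
        lncrna_id=lnc.transcript_id, class_label=UNCLASSIFIED, distance=min_gap
    )


def classify_all(
    lncs: list[TranscriptModel], coding_set: list[TranscriptModel]
) -> pd.DataFrame:
    """Classify every lncRNA; one row per input, in input order.

    Columns mirror the classification report layout: SeqID, Chr, Strand,
    Relationship, associated gene and strand, distance to the nearest coding
    transcript and all co-qualifying genes.
    """
    ids = [t.transcript_id for t in lncs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate transcript_id(s): {', '.join(dupes)}")
    coding_ids = [t.transcript_id for t in coding_set]
    if len(set(coding_ids)) != len(coding_ids):
        raise ValueError("duplicate transcript_id(s) in coding set")
    rows = []
    for lnc in lncs:
        rel = classify_lncrna(lnc, coding_set)
        rows.append(
            {
                "SeqID": lnc.transcript_id,
                "Chr": lnc.locus.chrom,
                "Strand": lnc.locus.strand,
                "Relationship": rel.class_label,
                "Associated_gene_name": rel.associated_gene,
                "Associated_gene_strand": rel.associated_gene_strand,
                "Distance_bp": rel.distance,
                "Co_qualifying_genes": ",".join(rel.co_qualifying),
            }
        )
    columns = [
        "SeqID",
        "Chr",
        "Strand",
        "Relationship",
        "Associated_gene_name",
        "Associated_gene_strand",
        "Distance_bp",
        "Co_qualifying_genes",
    ]
    return pd.DataFrame(rows, columns=columns)
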