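"""miRNA response element (MRE) scanning with the canonical seed-site taxonomy.

A mature miRNA binds a target antiparallel; its 5' "seed" (positions 2-7)
dominates recognition. Sites on the target (written 5'->3') are classified by
which miRNA positions pair and whether an adenosine faces miRNA position 1:

===========  ==================================================  ====
type         definition                                          rank
===========  ==================================================  ====
8mer         perfect match to positions 2-8, followed by an A      1
7mer-m8      perfect match to positions 2-8                        2
7mer-A1      perfect match to positions 2-7, followed by an A      3
6mer         perfect match to the seed (positions 2-7)             4
offset-6mer  perfect match to positions 3-8                        5
imperfect    seed pairing with exactly one G:U wobble, mismatch    6
             or single-base deletion (off by default)
===========  ==================================================  ====

The "followed by an A" adenosine is required in the target regardless of the
identity of miRNA position 1. Every site is anchored at the target position
opposite miRNA position 1 and labelled with the best (lowest-rank) type whose
motif matches at that anchor, so an 8mer is never double-reported as the
7mer/6mer types it contains. Sites of one miRNA at distinct anchors all count.

All sites are treated as non-conserved: no conservation input is accepted and
no conservation weighting is applied anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer", "offset-6mer", "imperfect")
#: Efficacy hierarchy: 8mer > 7mer-m8 > 7mer-A1 > 6mer > offset-6mer > imperfect.
SITE_RANK = {label: i + 1 for i, label in enumerate(SITE_TYPES)}

_PERFECT_TYPES = SITE_TYPES[:5]

_TO_DNA = str.maketrans("Uu", "Tt")
_TO_RNA = str.maketrans("Tt", "Uu")
_DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_MIRNA_ALPHABET = frozenset("ACGU")
_TARGET_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3'. T is normalized to U on construction."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().translate(_TO_RNA))
        if len(self.sequence) < 8:
            raise ValueError(
                f"{self.mirna_id}: mature miRNA must be >=8 nt, got {len(self.sequence)}"
            )
        bad = set(self.sequence) - _MIRNA_ALPHABET
        if bad:
            raise ValueError(f"{self.mirna_id}: invalid miRNA characters {sorted(bad)}")


@dataclass(frozen=True)
class SeedSite:
    """One miRNA binding site on a target transcript.

    ``anchor_pos`` is the target position opposite miRNA position 1. It may
    reach len(target) for types that do not read a base there (7mer-m8, 6mer)
    and len(target)+1 for an offset-6mer at the extreme 3' end, where miRNA
    positions 1-2 dangle past the target.
    ``supplementary_pairing`` reports whether target bases opposite miRNA
    positions 13-16 also Watson-Crick pair (annotation only, never used for
    calling); None when the site sits too close to the target 5' end or the
    miRNA is shorter than 16 nt.
    """

    mirna_id: str
    target_id: str
    site_type: str
    target_start: int
    target_end: int
    anchor_pos: int
    supplementary_pairing: bool | None = None

    @property
    def rank(self) -> int:
        return SITE_RANK[self.site_type]


@dataclass(frozen=True)
class SiteReport:
    """Per-(miRNA, target) site census."""

    mirna_id: str
    target_id: str
    site_count: int
    site_types: tuple[str, ...]
    best_rank: int


def _revcomp_dna(s: str) -> str:
    return "".join(_DNA_COMPLEMENT[c] for c in reversed(s))


def normalize_target(seq: str) -> str:
    """Upper-case DNA-alphabet copy of a target sequence (U -> T)."""
    t = seq.upper().translate(_TO_DNA)
    bad = set(t) - _TARGET_ALPHABET
    if bad:
        raise ValueError(f"invalid target characters {sorted(bad)}")
    return t


def _dna_motifs(mirna: MiRNA) -> dict[str, str]:
    m = mirna.sequence.translate(_TO_DNA)
    seed_2_7 = _revcomp_dna(m[1:7])
    seed_2_8 = _revcomp_dna(m[1:8])
    seed_3_8 = _revcomp_dna(m[2:8])
    return {
        "8mer": seed_2_8 + "A",
        "7mer-m8": seed_2_8,
        "7mer-A1": seed_2_7 + "A",
        "6mer": seed_2_7,
        "offset-6mer": seed_3_8,
    }


def seed_motifs(mirna: MiRNA) -> dict[str, str]:
    """Target-strand motifs (5'->3', RNA alphabet) for the five perfect types.

    Each motif is the reverse complement of the miRNA positions it pairs,
    with the A1-anchor adenosine appended where the type requires one.
    """
    return {k: v.translate(_TO_RNA) for k, v in _dna_motifs(mirna).items()}


#: Offset from a motif match start to the site anchor, and the target span
#: of the site relative to the anchor, per perfect type.
_ANCHOR_OFFSET = {"8mer": 7, "7mer-m8": 7, "7mer-A1": 6, "6mer": 6, "offset-6mer": 7}
_SPAN_FROM_ANCHOR = {
    "8mer": (-7, 1),
    "7mer-m8": (-7, 0),
    "7mer-A1": (-6, 1),
    "6mer": (-6, 0),
    "offset-6mer": (-7, -1),
}


def _supplementary(t: str, mirna: MiRNA, anchor: int) -> bool | None:
    # miRNA position p faces target index anchor - p + 1 (p=1 at the anchor)
    if len(mirna.sequence) < 16 or anchor - 15 < 0:
        return None
    m = mirna.sequence.translate(_TO_DNA)
    window = t[anchor - 15 : anchor - 11]
    if "N" in window:
        return False
    return all(t[anchor - p + 1] == _DNA_COMPLEMENT[m[p - 1]] for p in range(13, 17))


def _imperfect_at(t: str, anchor: int, motif6: str) -> tuple[int, int] | None:
    """Span of an imperfect site anchored at ``anchor``, or None.

    Exactly one defect is allowed opposite miRNA positions 2-7: one G:U
    wobble, one mismatch, or one single-base deletion in the target window.
    Windows containing N are never reported (N pairs with nothing).
    """
    if anchor >= 6:
        window = t[anchor - 6 : anchor]
        if "N" not in window:
            defects = [i for i in range(6) if window[i] != motif6[i]]
            if len(defects) == 1:
                return (anchor - 6, anchor)
    if anchor >= 5:
        window = t[anchor - 5 : anchor]
        if "N" not in window:
            for j in range(6):
                if motif6[:j] + motif6[j + 1 :] == window:
                    return (anchor - 5, anchor)
    return None


def scan_sites(
    target: str,
    mirna: MiRNA,
    *,
    allow_imperfect: bool = False,
    target_id: str = "target",
) -> list[SeedSite]:
    """All seed sites of ``mirna`` on ``target`` (target given 5'->3').

    Each anchor is reported at most once, labelled with the best-rank type
    matching there; imperfect sites are only considered at anchors without a
    perfect type and only when ``allow_imperfect`` is set. The empty target
    yields an empty list. N matches nothing.
    """
    t = normalize_target(target)
    motifs = _dna_motifs(mirna)
    best: dict[int, str] = {}
    for label in _PERFECT_TYPES:
        motif = motifs[label]
        off = _ANCHOR_OFFSET[label]
        s = t.find(motif)
        while s != -1:
            best.setdefault(s + off, label)
            s = t.find(motif, s + 1)
    spans: dict[int, tuple[int, int]] = {}
    if allow_imperfect:
        motif6 = motifs["6mer"]
        for anchor in range(5, len(t) + 1):
            if anchor in best:
                continue
            span = _imperfect_at(t, anchor, motif6)
            if span is not None:
                best[anchor] = "imperfect"
                spans[anchor] = span
    sites = []
    for anchor in sorted(best):
        label = best[anchor]
        if label == "imperfect":
            start, end = spans[anchor]
        else:
            d0, d1 = _SPAN_FROM_ANCHOR[label]
            start, end = anchor + d0, anchor + d1
        sites.append(
            SeedSite(
                mirna_id=mirna.mirna_id,
                target_id=target_id,
                site_type=label,
                target_start=start,
                target_end=end,
                anchor_pos=anchor,
                supplementary_pairing=_supplementary(t, mirna, anchor),
            )
        )
    return sites


def site_report(
    target: str,
    mirnas: list[MiRNA],
    *,
    allow_imperfect: bool = False,
    target_id: str = "target",
) -> list[SiteReport]:
    """One report per miRNA with >=1 site on ``target``, sorted.

    Sort order: best rank ascending, site count descending, miRNA id.
    """
    ids = [m.mirna_id for m in mirnas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mirna_id in miRNA list")
    reports = []
    for mirna in mirnas:
        sites = scan_sites(
            target, mirna, allow_imperfect=allow_imperfect, target_id=target_id
        )
        if not sites:
            continue
        reports.append(
            SiteReport(
                mirna_id=mirna.mirna_id,
                target_id=target_id,
                site_count=len(sites),
                site_types=tuple(s.site_type for s in sites),
                best_rank=min(s.rank for s in sites),
            )
        )
    reports.sort(key=lambda r: (r.best_rank, -r.site_count, r.mirna_id))
    return reports


def report_table(reports: list[SiteReport]) -> pd.DataFrame:
    """Site census table: Identity, Site_no, Type_of_site per miRNA."""
    rows = [
        {
            "Target": r.target_id,
            "Identity": r.mirna_id,
            "Site_no": r.site_count,
            "Type_of_site": " ".join(
                sorted(set(r.site_types), key=lambda s: SITE_RANK[s])
            ),
            "Best_rank": r.best_rank,
        }
        for r in reports
    ]
    return pd.DataFrame(
        rows, columns=["Target", "Identity", "Site_no", "Type_of_site", "Best_rank"]
    )


def shared_mres(
    report_a: list[SiteReport], report_b: list[SiteReport]
) -> list[tuple[str, int, int]]:
    """miRNAs with >=1 site on both transcripts, with both best ranks.

    Sorted by combined rank (sum of the two best ranks), then miRNA id; an
    empty intersection is allowed.
    """
    rank_a = {r.mirna_id: r.best_rank for r in report_a}
    rank_b = {r.mirna_id: r.best_rank for r in report_b}
    shared = [
        (mid, rank_a[mid], rank_b[mid]) for mid in rank_a.keys() & rank_b.keys()
    ]
    shared.sort(key=lambda x: (x[1] + x[2], x[0]))
    return shared
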