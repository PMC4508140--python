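"""Synthetic data with planted, machine-readable ground truth.

The generator emulates the study design every downstream stage expects: two
groups of ten animals (normal vs fibrosis model), lncRNAs planted in each of
the six positional classes, lncRNA/coding-gene pairs with an exact planted
percent identity on different chromosomes, miRNA seed sites written into
transcript sequences, >=2-fold planted expression changes, positively
correlated lncRNA/mRNA and negatively correlated lncRNA/miRNA probes, and Ct
tables whose 2^(-ddCt) equals a planted fold. Every planted fact is emitted
as a :class:`TruthRecord` so tests can check recovery mechanically.

Intensities follow a log2-normal noise model around planted group means
(fold changes are planted on the linear scale); correlated probe triplets are
driven by a per-sample latent factor so the expected Pearson signs match the
plan. One integer seed drives the whole generator through fixed-stage derived
streams, so identical configs give byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import positional
from .expression import ExpressionMatrix
from .models import GenomicInterval, TranscriptModel
from .mre import _ANCHOR_OFFSET, _dna_motifs, MiRNA, scan_sites

DNA = "ACGT"
MAX_PLACEMENT_ATTEMPTS = 100

TRUTH_KINDS = (
    "positional_class",
    "homology_pair",
    "planted_site",
    "fold_change",
    "correlation",
    "ct_fold_change",
)

PLANTABLE_CLASSES = (
    positional.SENSE_EXON,
    positional.SENSE_INTRON,
    positional.ANTISENSE_EXON,
    positional.ANTISENSE_INTRON,
    positional.BIDIRECTIONAL,
    positional.INTERGENIC,
)


class SimulationInfeasibleError(RuntimeError):
    """The requested configuration cannot be realized (explicit failure
    instead of silent truncation)."""


@dataclass(frozen=True)
class TruthRecord:
    """One planted fact: what was planted, about which entity."""

    entity_id: str
    truth_kind: str
    payload: dict

    def __post_init__(self) -> None:
        if self.truth_kind not in TRUTH_KINDS:
            raise ValueError(f"unknown truth_kind {self.truth_kind!r}")


def truth_table(truths: list[TruthRecord]) -> pd.DataFrame:
    rows = [
        {
            "entity_id": t.entity_id,
            "truth_kind": t.truth_kind,
            "payload": json.dumps(t.payload, sort_keys=True),
        }
        for t in truths
    ]
    return pd.DataFrame(rows, columns=["entity_id", "truth_kind", "payload"])


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    rng_seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 1_000_000
    n_coding: int = 8
    n_lncrna_per_class: int = 1
    positional_classes: tuple[str, ...] = PLANTABLE_CLASSES
    homology_identity_targets: tuple[float, ...] = (0.85, 0.90, 0.93, 1.00)
    homolog_length: int = 400
    mirna_count: int = 10
    mirna_length: int = 22
    group_sizes: tuple[int, int] = (10, 10)  # ten animals per group
    n_extra_probes: int = 1000
    noise_sd: float = 0.10  # log2 intensity units
    ct_noise_sd: float = 0.20  # cycles
    fold_change_plan: dict = field(default_factory=dict)
    correlation_plan: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < 100_000:
            raise ValueError("need >=1 chromosome of >=100 kb")
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs >=2 samples")
        for ident in self.homology_identity_targets:
            if not 0.0 <= ident <= 1.0:
                raise ValueError(f"identity target {ident} outside [0, 1]")
        for probe, fold in self.fold_change_plan.items():
            if fold <= 0:
                raise ValueError(f"fold target for {probe} must be > 0")
        for triplet, (r_pos, r_neg) in self.correlation_plan.items():
            if abs(r_pos) > 1 or abs(r_neg) > 1:
                raise ValueError(f"|r| > 1 in correlation plan for {triplet}")
        unknown = set(self.positional_classes) - set(PLANTABLE_CLASSES)
        if unknown:
            raise ValueError(f"unknown positional classes {sorted(unknown)}")


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.rng_seed, spawn_key=(stage,)))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# annotation


def _make_coding(
    tid: str, chrom: str, start: int, strand: str, rng: np.random.Generator
) -> TranscriptModel:
    exon_lens = rng.integers(150, 300, 3)
    intron_lens = rng.integers(1500, 4000, 2)
    exons = []
    pos = start
    for i, length in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + int(length), strand))
        pos += int(length)
        if i < 2:
            pos += int(intron_lens[i])
    locus = GenomicInterval(chrom, start, exons[-1].end, strand)
    return TranscriptModel(tid, tid, "coding", locus, tuple(exons))


def _single_exon_lnc(tid: str, chrom: str, start: int, end: int, strand: str) -> TranscriptModel:
    iv = GenomicInterval(chrom, start, end, strand)
    return TranscriptModel(tid, tid, "lncRNA", iv, (iv,))


def _plant_class_lnc(
    cls: str,
    tid: str,
    host: TranscriptModel,
    coding_set: list[TranscriptModel],
    rng: np.random.Generator,
) -> TranscriptModel:
    hl = host.locus
    for _ in range(MAX_PLACEMENT_ATTEMPTS):
        length = int(rng.integers(200, 600))
        if cls in (positional.SENSE_EXON, positional.ANTISENSE_EXON):
            exon = host.exons[int(rng.integers(0, len(host.exons)))]
            lo = max(0, exon.start - length + 50)
            start = int(rng.integers(lo, exon.end - 50))
            strand = hl.strand if cls == positional.SENSE_EXON else _flip(hl.strand)
            cand = _single_exon_lnc(tid, hl.chrom, start, start + length, strand)
        elif cls in (positional.SENSE_INTRON, positional.ANTISENSE_INTRON):
            introns = host.introns
            if not introns:
                raise SimulationInfeasibleError(f"{host.transcript_id}: no introns")
            intron = introns[int(rng.integers(0, len(introns)))]
            length = min(length, len(intron) - 20)
            start = intron.start + int(rng.integers(5, len(intron) - length - 5))
            strand = hl.strand if cls == positional.SENSE_INTRON else _flip(hl.strand)
            cand = _single_exon_lnc(tid, hl.chrom, start, start + length, strand)
        elif cls == positional.BIDIRECTIONAL:
            gap = int(rng.integers(1, positional.BIDIRECTIONAL_MAX_GAP + 1))
            if hl.strand == "+":
                end = hl.start - gap
                cand = _single_exon_lnc(tid, hl.chrom, max(0, end - length), end, "-")
            else:
                start = hl.end + gap
                cand = _single_exon_lnc(tid, hl.chrom, start, start + length, "+")
        else:  # pragma: no cover - guarded by caller
            raise ValueError(cls)
        if positional.classify_lncrna(cand, coding_set).class_label == cls:
            return cand
    raise SimulationInfeasibleError(
        f"could not plant a {cls} lncRNA near {host.transcript_id} "
        f"after {MAX_PLACEMENT_ATTEMPTS} attempts"
    )


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _plant_intergenic(
    tid: str,
    idx: int,
    cfg: SimConfig,
    coding_set: list[TranscriptModel],
    rng: np.random.Generator,
    chrom: str | None = None,
) -> TranscriptModel:
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chrom = chrom or chroms[idx % len(chroms)]
    max_end = max(
        (t.locus.end for t in coding_set if t.locus.chrom == chrom), default=50_000
    )
    length = int(rng.integers(300, 800))
    start = (
        max_end
        + positional.INTERGENIC_MIN_GAP
        + 1_000
        + idx * 8_000
        + int(rng.integers(0, 2_000))
    )
    if start + length >= cfg.chromosome_length:
        raise SimulationInfeasibleError(
            f"chromosome {chrom} too short to place intergenic locus {tid} "
            f">{positional.INTERGENIC_MIN_GAP} bp from all coding loci"
        )
    cand = _single_exon_lnc(tid, chrom, start, start + length, "-")
    if positional.classify_lncrna(cand, coding_set).class_label != positional.INTERGENIC:
        raise SimulationInfeasibleError(f"intergenic placement of {tid} failed")
    return cand


def _homolog_pct_labels(cfg: SimConfig) -> list[int]:
    labels = [int(round(100 * t)) for t in cfg.homology_identity_targets]
    if len(set(labels)) != len(labels):
        raise ValueError("homology identity targets collide after rounding to %")
    return labels


def generate_annotation(
    cfg: SimConfig, *, include_homologs: bool = False
) -> tuple[list[TranscriptModel], list[TruthRecord]]:
    """Coding genes plus lncRNAs planted in each requested positional class.

    Every planted class is re-verified against the classifier before it is
    recorded as truth; infeasible geometry raises
    :class:`SimulationInfeasibleError`. With ``include_homologs``, an extra
    intergenic lncRNA and a coding partner gene on a different chromosome are
    added for every homology identity target (sequences come from
    :func:`generate_homolog_pair`).
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    non_intergenic = [c for c in cfg.positional_classes if c != positional.INTERGENIC]
    if cfg.n_coding == 0 and cfg.n_lncrna_per_class > 0 and non_intergenic:
        raise SimulationInfeasibleError(
            "no coding transcripts: only the intergenic class is plantable"
        )
    if include_homologs and cfg.homology_identity_targets and cfg.n_chromosomes < 2:
        raise SimulationInfeasibleError(
            "homolog pairs need >=2 chromosomes (pairs sit on different chromosomes)"
        )

    next_free = {c: 50_000 for c in chroms}

    def place_gene(tid: str, chrom: str) -> TranscriptModel:
        start = next_free[chrom] + int(rng.integers(0, 3_000))
        gene = _make_coding(tid, chrom, start, "+" if rng.integers(0, 2) else "-", rng)
        if gene.locus.end + 40_000 >= cfg.chromosome_length:
            raise SimulationInfeasibleError(f"chromosome {chrom} too short for {tid}")
        next_free[chrom] = gene.locus.end + 80_000
        return gene

    coding: list[TranscriptModel] = []
    for i in range(cfg.n_coding):
        coding.append(place_gene(f"gene_{i + 1:03d}", chroms[i % len(chroms)]))

    homolog_pairs: list[tuple[str, str, int]] = []  # (lnc_id, gene_id, pct)
    if include_homologs:
        for i, pct in enumerate(_homolog_pct_labels(cfg)):
            gene_chrom = chroms[(i + 1) % len(chroms)]
            gene = place_gene(f"mimic_gene_{pct}", gene_chrom)
            coding.append(gene)
            homolog_pairs.append((f"lncH{pct}", gene.transcript_id, pct))

    lncs: list[TranscriptModel] = []
    truths: list[TruthRecord] = []
    intergenic_idx = 0
    host_idx = 0
    for cls in cfg.positional_classes:
        for j in range(cfg.n_lncrna_per_class):
            tid = f"lnc_{cls}_{j + 1}"
            if cls == positional.INTERGENIC:
                lnc = _plant_intergenic(tid, intergenic_idx, cfg, coding, rng)
                intergenic_idx += 1
            else:
                host = coding[host_idx % max(1, cfg.n_coding)]
                host_idx += 1
                lnc = _plant_class_lnc(cls, tid, host, coding, rng)
            lncs.append(lnc)
            rel = positional.classify_lncrna(lnc, coding)
            truths.append(
                TruthRecord(
                    entity_id=tid,
                    truth_kind="positional_class",
                    payload={
                        "class": cls,
                        "associated_gene": rel.associated_gene,
                    },
                )
            )

    for i, (lnc_id, gene_id, pct) in enumerate(homolog_pairs):
        lnc_chrom = chroms[i % len(chroms)]
        lnc = _plant_intergenic(lnc_id, intergenic_idx, cfg, coding, rng, chrom=lnc_chrom)
        intergenic_idx += 1
        lncs.append(lnc)
        truths.append(
            TruthRecord(
                entity_id=lnc_id,
                truth_kind="positional_class",
                payload={"class": positional.INTERGENIC, "associated_gene": ""},
            )
        )

    return coding + lncs, truths


# ---------------------------------------------------------------------------
# sequences


def generate_homolog_pair(
    cfg: SimConfig,
    length: int,
    identity: float,
    *,
    rng: np.random.Generator | None = None,
    seq_a: str | None = None,
    protect: tuple[tuple[int, int], ...] = (),
) -> tuple[str, str, TruthRecord]:
    """A sequence pair with an exact planted identity.

    ``seq_b`` is ``seq_a`` with round((1-identity)*length) positions
    substituted (chosen without replacement, each to a different base).
    Substitutions avoid ``protect`` spans (planted site regions that must
    stay identical in both sequences).
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity {identity} outside [0, 1]")
    if length < 50:
        raise ValueError("length must be >= 50")
    rng = _rng(cfg, 1) if rng is None else rng
    if seq_a is None:
        seq_a = _random_dna(rng, length)
    elif len(seq_a) != length:
        raise ValueError("seq_a length does not match requested length")
    n_sub = int(round((1.0 - identity) * length))
    allowed = np.array(
        [p for p in range(length) if not any(s <= p < e for s, e in protect)]
    )
    if n_sub > len(allowed):
        raise ValueError("protected spans leave too few substitutable positions")
    positions = rng.choice(allowed, size=n_sub, replace=False)
    b = list(seq_a)
    for pos in sorted(int(p) for p in positions):
        alternatives = [c for c in DNA if c != b[pos]]
        b[pos] = alternatives[int(rng.integers(0, 3))]
    truth = TruthRecord(
        entity_id="homolog_pair",
        truth_kind="homology_pair",
        payload={"identity": identity, "n_substitutions": n_sub, "length": length},
    )
    return seq_a, "".join(b), truth


def _site_guards(site_type: str, motif: str, mirna: MiRNA) -> dict[int, str]:
    """Relative position -> base to write around a planted motif so that the
    scanner labels the site exactly ``site_type`` (e.g. a 7mer-m8 must not be
    followed by A, which would upgrade it to an 8mer)."""
    m = _dna_motifs(mirna)
    L = len(motif)
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    mir_dna = mirna.sequence.replace("U", "T")

    def not_base(b: str) -> str:
        return "C" if b != "C" else "G"

    if site_type == "8mer":
        return {}
    if site_type == "7mer-m8":
        return {L: not_base("A")}
    if site_type == "7mer-A1":
        return {-1: not_base(comp[mir_dna[7]])}
    if site_type == "6mer":
        return {-1: not_base(comp[mir_dna[7]]), L: not_base("A")}
    if site_type == "offset-6mer":
        return {L: not_base(comp[mir_dna[1]])}
    if site_type == "imperfect":
        return {}
    raise ValueError(f"unknown site type {site_type!r}")


def _planted_motif(site_type: str, mirna: MiRNA) -> str:
    motifs = _dna_motifs(mirna)
    if site_type != "imperfect":
        return motifs[site_type]
    # one mismatch in the seed window: replace position 2 of the 6mer motif
    motif = list(motifs["6mer"])
    motif[2] = "C" if motif[2] != "C" else "G"
    return "".join(motif)


def plant_mres(
    target_seq: str,
    mirna: MiRNA,
    site_type: str,
    offsets: list[int],
) -> tuple[str, list[TruthRecord]]:
    """Write the motif of ``site_type`` for ``mirna`` at each offset.

    Offsets are motif start positions on the target; planted sites (including
    their one-base guard flanks) must not overlap each other or run out of the
    sequence. After writing, the sequence is re-scanned and each planted site
    asserted present with the planted type.
    """
    motif = _planted_motif(site_type, mirna)
    guards = _site_guards(site_type, motif, mirna)
    seq = list(target_seq.upper())
    touched: set[int] = set()
    truths = []
    anchor_offset = _ANCHOR_OFFSET.get(site_type, 6)
    for off in offsets:
        span = [off + i for i in range(len(motif))] + [off + d for d in guards]
        if min(span) < 0 or max(span) >= len(seq):
            raise ValueError(f"offset {off} leaves no room for a {site_type} site")
        if touched & set(span):
            raise ValueError(f"planted site at offset {off} overlaps a previous one")
        touched |= set(span)
        for i, base in enumerate(motif):
            seq[off + i] = base
        for d, base in guards.items():
            seq[off + d] = base
        truths.append(
            TruthRecord(
                entity_id=f"{mirna.mirna_id}@{off}",
                truth_kind="planted_site",
                payload={
                    "mirna_id": mirna.mirna_id,
                    "site_type": site_type,
                    "offset": off,
                    "anchor_pos": off + anchor_offset,
                },
            )
        )
    out = "".join(seq)
    found = {
        s.anchor_pos: s.site_type
        for s in scan_sites(out, mirna, allow_imperfect=(site_type == "imperfect"))
    }
    for t in truths:
        anchor = t.payload["anchor_pos"]
        if found.get(anchor) != site_type:
            raise RuntimeError(
                f"self-check failed: planted {site_type} at anchor {anchor} "
                f"re-scanned as {found.get(anchor)!r}"
            )
    return out, truths


def generate_mirnas(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[MiRNA]:
    rng = _rng(cfg, 2) if rng is None else rng
    return [
        MiRNA(f"miR-sim-{i + 1:02d}", _random_dna(rng, cfg.mirna_length))
        for i in range(cfg.mirna_count)
    ]


def clean_background(
    length: int,
    mirnas: list[MiRNA],
    rng: np.random.Generator,
    *,
    protect: tuple[tuple[int, int], ...] = (),
    seq: str | None = None,
) -> str:
    """A random sequence with no perfect seed site for any given miRNA
    (outside protected spans). Used where planted site censuses must match
    generator truth exactly."""
    chars = list(seq if seq is not None else _random_dna(rng, length))
    for _ in range(200):
        dirty = []
        for mirna in mirnas:
            for site in scan_sites("".join(chars), mirna):
                if any(site.target_start < e and s < site.target_end for s, e in protect):
                    continue
                dirty.append(site)
        if not dirty:
            return "".join(chars)
        for site in dirty:
            candidates = [
                p
                for p in range(site.target_start, site.target_end)
                if not any(s <= p < e for s, e in protect)
            ]
            if not candidates:
                continue
            pos = candidates[int(rng.integers(0, len(candidates)))]
            chars[pos] = DNA[(DNA.index(chars[pos]) + 1 + int(rng.integers(0, 3))) % 4]
    raise SimulationInfeasibleError("could not scrub accidental seed sites")


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    cfg: SimConfig,
    probe_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, list[TruthRecord]]:
    """Two-group intensity matrix realizing the fold and correlation plans.

    Group means differ by the planted fold on the linear intensity scale;
    correlation-plan triplets share a per-sample latent factor with loadings
    chosen so the expected log-scale Pearson r is (+r_pos) for lncRNA-mRNA
    and (-|r_neg|) for lncRNA-miRNA; log2-normal noise of sd ``noise_sd`` is
    added everywhere.
    """
    cfg.validate()
    rng = _rng(cfg, 3) if rng is None else rng
    if probe_ids is None:
        probe_ids = sorted(
            set(cfg.fold_change_plan)
            | {pid for trip in cfg.correlation_plan for pid in trip}
        ) + [f"null_{i + 1:04d}" for i in range(cfg.n_extra_probes)]
    missing = (
        set(cfg.fold_change_plan)
        | {pid for trip in cfg.correlation_plan for pid in trip}
    ) - set(probe_ids)
    if missing:
        raise ValueError(f"plan references unknown probes: {sorted(missing)}")

    n_normal, n_model = cfg.group_sizes
    samples = [f"normal_{i + 1:02d}" for i in range(n_normal)] + [
        f"model_{i + 1:02d}" for i in range(n_model)
    ]
    groups = pd.Series(["normal"] * n_normal + ["model"] * n_model, index=samples)
    is_model = np.array([0.0] * n_normal + [1.0] * n_model)

    P, S = len(probe_ids), len(samples)
    index = {p: i for i, p in enumerate(probe_ids)}
    # Gaussian log2 baselines: bounded (e.g. uniform) baselines put planted
    # fold changes at the hard edge of the rank range, where quantile
    # normalization clips them; intensity distributions with tails do not.
    # Planted probes get central baselines — quantile normalization is known
    # to compress fold changes at the distribution extremes, and planted
    # truth must stay recoverable after normalization
    base = rng.normal(9.0, 1.5, P)
    planted_probes = sorted(
        set(cfg.fold_change_plan) | {pid for trip in cfg.correlation_plan for pid in trip}
    )
    for pid in planted_probes:
        base[index[pid]] = rng.normal(9.0, 0.5)
    deviates = rng.standard_normal((P, S))

    truths = []
    for (lnc, mrna, mir), (r_pos, r_neg) in sorted(cfg.correlation_plan.items()):
        if r_pos <= 0:
            raise ValueError("lncRNA-mRNA correlation target must be positive")
        loading_mir = abs(r_neg) / np.sqrt(r_pos)
        if loading_mir > 1:
            raise ValueError(
                f"infeasible correlation plan for {(lnc, mrna, mir)}: "
                f"|r_neg| must be <= sqrt(r_pos)"
            )
        latent = rng.standard_normal(S)
        for pid, loading in (
            (lnc, np.sqrt(r_pos)),
            (mrna, np.sqrt(r_pos)),
            (mir, -loading_mir),
        ):
            i = index[pid]
            deviates[i] = loading * latent + np.sqrt(1 - loading**2) * deviates[i]
        truths.append(
            TruthRecord(
                entity_id=f"{lnc}|{mrna}|{mir}",
                truth_kind="correlation",
                payload={"r_lnc_mrna": r_pos, "r_lnc_mirna": r_neg},
            )
        )

    log2fold = np.zeros(P)
    for pid, fold in cfg.fold_change_plan.items():
        log2fold[index[pid]] = np.log2(fold)
        truths.append(
            TruthRecord(
                entity_id=pid, truth_kind="fold_change", payload={"fold": fold}
            )
        )

    log2_values = base[:, None] + log2fold[:, None] * is_model[None, :]
    log2_values = log2_values + cfg.noise_sd * deviates
    values = pd.DataFrame(2.0**log2_values, index=probe_ids, columns=samples)
    return ExpressionMatrix(values, groups), truths


def generate_ct_table(
    cfg: SimConfig,
    true_fold: float,
    *,
    target_name: str = "target",
    target_kind: str = "lncRNA",
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """A qRT-PCR Ct table whose noiseless 2^(-ddCt) equals ``true_fold``.

    The reference gene follows assay convention: U6 for miRNA targets,
    beta-actin for lncRNA/mRNA targets.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be > 0")
    rng = _rng(cfg, 4) if rng is None else rng
    noise = cfg.ct_noise_sd if noise_sd is None else noise_sd
    reference = "U6" if target_kind == "miRNA" else "beta-actin"
    ref_ct, normal_dct = 16.0, 5.0
    rows = []
    for group, n in zip(("normal", "model"), cfg.group_sizes):
        dct = normal_dct if group == "normal" else normal_dct - np.log2(true_fold)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:02d}",
                    "group": group,
                    "target_name": target_name,
                    "reference_name": reference,
                    "ct_target": ref_ct + dct + noise * rng.standard_normal(),
                    "ct_reference": ref_ct + noise * rng.standard_normal(),
                }
            )
    table = pd.DataFrame(rows)
    truth = TruthRecord(
        entity_id=target_name,
        truth_kind="ct_fold_change",
        payload={"true_fold": true_fold, "reference": reference},
    )
    return table, truth


# ---------------------------------------------------------------------------
# the full dataset


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, plus the planted truth."""

    config: SimConfig
    transcripts: list[TranscriptModel]
    sequences: dict[str, str]
    mirnas: list[MiRNA]
    matrix: ExpressionMatrix
    ct_table: pd.DataFrame
    truths: list[TruthRecord]
    triplet: tuple[str, str, str]
    files: dict[str, Path] | None = None

    @property
    def lncrna_ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts if t.biotype == "lncRNA"]

    @property
    def coding_ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts if t.biotype == "coding"]


def default_config(seed: int = 0) -> SimConfig:
    """The default study-shaped dataset: one planted ceRNA triplet
    (lncRNA up 2.5x, homologous mRNA up 2.2x with r=+0.9, shared-seed miRNA
    down to 0.4x with r=-0.85), homolog pairs at 85/90/93/100 % identity."""
    return SimConfig(
        rng_seed=seed,
        fold_change_plan={"lncH93": 2.5, "mimic_gene_93": 2.2, "miR-sim-01": 0.4},
        correlation_plan={("lncH93", "mimic_gene_93", "miR-sim-01"): (0.9, -0.85)},
    )


def null_config(seed: int = 0) -> SimConfig:
    """Same structure as :func:`default_config` but with nothing planted in
    the expression layer (no fold changes, no correlations)."""
    return SimConfig(rng_seed=seed)


def generate_dataset(cfg: SimConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate the complete synthetic bundle (annotation, sequences, miRNAs,
    expression, Ct tables, truth), optionally writing it to ``out_dir``.

    The triplet pair (lncH93 and its mimicked gene) carries a planted shared
    8mer for the first miRNA on both sequences plus a lncRNA-only decoy site
    for the second miRNA.
    """
    from . import formats  # local import to avoid a cycle

    cfg.validate()
    transcripts, truths = generate_annotation(cfg, include_homologs=True)
    mirnas = generate_mirnas(cfg)
    rng_seq = _rng(cfg, 1)

    pcts = _homolog_pct_labels(cfg)
    triplet_pct = 93 if 93 in pcts else max((p for p in pcts if p >= 90), default=pcts[0])
    triplet = (f"lncH{triplet_pct}", f"mimic_gene_{triplet_pct}", mirnas[0].mirna_id)

    sequences: dict[str, str] = {}
    homolog_ids = {f"lncH{p}" for p in pcts} | {f"mimic_gene_{p}" for p in pcts}
    for t in transcripts:
        if t.transcript_id not in homolog_ids:
            sequences[t.transcript_id] = _random_dna(rng_seq, cfg.homolog_length)

    for pct, ident in zip(pcts, cfg.homology_identity_targets):
        lnc_id, gene_id = f"lncH{pct}", f"mimic_gene_{pct}"
        seq_a = clean_background(cfg.homolog_length, mirnas, rng_seq)
        protect: tuple[tuple[int, int], ...] = ()
        site_truths_a: list[TruthRecord] = []
        if lnc_id == triplet[0]:
            # shared MRE for the triplet miRNA plus a lncRNA-only decoy,
            # planted before substitution and protected so the planted
            # identity survives on the gene side
            seq_a, shared_truths = plant_mres(seq_a, mirnas[0], "8mer", [150])
            seq_a, decoy_truths = plant_mres(seq_a, mirnas[1], "7mer-m8", [60])
            site_truths_a = shared_truths + decoy_truths
            protect = ((59, 69), (149, 159))
        seq_a, seq_b, truth = generate_homolog_pair(
            cfg, cfg.homolog_length, ident, rng=rng_seq, seq_a=seq_a, protect=protect
        )
        truths.append(
            TruthRecord(
                entity_id=f"{lnc_id}|{gene_id}",
                truth_kind="homology_pair",
                payload=truth.payload,
            )
        )
        if lnc_id == triplet[0]:
            # break the decoy on the gene side: the decoy site is lncRNA-only
            b = list(seq_b)
            for pos in (61, 63):
                b[pos] = DNA[(DNA.index(b[pos]) + 2) % 4]
            seq_b = "".join(b)
            for t_ in site_truths_a:
                truths.append(
                    TruthRecord(f"{lnc_id}|{t_.entity_id}", "planted_site", t_.payload)
                )
            shared_anchor = shared_truths[0].payload
            truths.append(
                TruthRecord(
                    f"{gene_id}|{mirnas[0].mirna_id}@150", "planted_site", shared_anchor
                )
            )
        sequences[lnc_id] = seq_a
        sequences[gene_id] = seq_b

    probe_ids = [t.transcript_id for t in transcripts] + [m.mirna_id for m in mirnas] + [
        f"null_{i + 1:04d}" for i in range(cfg.n_extra_probes)
    ]
    matrix, expr_truths = generate_expression(cfg, probe_ids=probe_ids)
    truths.extend(expr_truths)

    rng_ct = _rng(cfg, 4)
    ct_parts = []
    kinds = {triplet[0]: "lncRNA", triplet[1]: "mRNA", triplet[2]: "miRNA"}
    for name, kind in kinds.items():
        fold = cfg.fold_change_plan.get(name, 1.0)
        table, truth = generate_ct_table(
            cfg, fold, target_name=name, target_kind=kind, rng=rng_ct
        )
        ct_parts.append(table)
        if name in cfg.fold_change_plan:
            truths.append(truth)
    ct_table = pd.concat(ct_parts, ignore_index=True)

    dataset = SyntheticDataset(
        config=cfg,
        transcripts=transcripts,
        sequences=sequences,
        mirnas=mirnas,
        matrix=matrix,
        ct_table=ct_table,
        truths=truths,
        triplet=triplet,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "gtf": out / "annotation.gtf",
            "lnc_fasta": out / "lncrna.fasta",
            "coding_fasta": out / "coding.fasta",
            "mirna_fasta": out / "mirnas.fasta",
            "matrix": out / "expression.tsv",
            "groups": out / "groups.tsv",
            "ct": out / "ct_tables.tsv",
            "truth": out / "truth.tsv",
            "config": out / "pipeline.yaml",
        }
        formats.write_gtf(transcripts, files["gtf"])
        lnc_records = [
            formats.FastaRecord(t.transcript_id, "", sequences[t.transcript_id])
            for t in transcripts
            if t.biotype == "lncRNA"
        ]
        coding_records = [
            formats.FastaRecord(t.transcript_id, "", sequences[t.transcript_id])
            for t in transcripts
            if t.biotype == "coding"
        ]
        mirna_records = [
            formats.FastaRecord(m.mirna_id, "", m.sequence) for m in mirnas
        ]
        formats.write_fasta(lnc_records, files["lnc_fasta"])
        formats.write_fasta(coding_records, files["coding_fasta"])
        formats.write_fasta(mirna_records, files["mirna_fasta"])
        formats.write_expression(matrix, files["matrix"], files["groups"])
        formats.write_tsv(ct_table, files["ct"])
        formats.write_tsv(truth_table(truths), files["truth"])
        # paths relative to the config file, so a bundle is relocatable and
        # two same-seed bundles are byte-identical
        pipeline_cfg = {
            "gtf": files["gtf"].name,
            "lnc_fasta": files["lnc_fasta"].name,
            "coding_fasta": files["coding_fasta"].name,
            "mirna_fasta": files["mirna_fasta"].name,
            "matrix": files["matrix"].name,
            "groups": files["groups"].name,
            "out_dir": "results",
            "seed": cfg.rng_seed,
        }
        import yaml

        with files["config"].open("w") as fh:
            yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
        dataset = dataclasses.replace(dataset, files=files)
    return dataset
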