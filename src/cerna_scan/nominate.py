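"""ceRNA triplet nomination and the end-to-end pipeline.

A candidate triplet (lncRNA, mRNA, shared miRNAs) is *nominated* when every
clause of the sponge pattern holds:

1. the two transcripts share >=1 miRNA response element;
2. both are differentially expressed in the same direction (the canonical
   case is both up; both down is accepted and flagged as the symmetric case);
3. their expression is positively correlated (r > 0, p < alpha) across all
   samples pooled;
4. at least one shared miRNA is differentially expressed in the opposite
   direction and negatively correlated with the lncRNA (r < 0, p < alpha).

Every failed clause is recorded in ``rejection_reasons`` for audit; all
shared miRNAs are reported with their per-clause status even when only one
qualifies. Candidate mRNA partners come from the homology route (mimicked
genes) or from an explicit user-supplied pair list; both are first-class.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (
    DEFAULT_FC_THRESHOLD,
    DEResult,
    ExpressionMatrix,
    de_table,
    fold_change_filter,
    pearson_r,
)
from .homology import DEFAULT_MIN_IDENTITY, find_mimicked_genes, mimic_table
from .mre import SiteReport, report_table, shared_mres, site_report
from .positional import classify_all

#: Version of the nomination rule set recorded in run manifests.
RULESET_VERSION = "1"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and thresholds for one pipeline run (flat key-value file)."""

    gtf: Path
    lnc_fasta: Path
    coding_fasta: Path
    mirna_fasta: Path
    matrix: Path
    groups: Path
    out_dir: Path
    pairs: Path | None = None
    min_identity: float = DEFAULT_MIN_IDENTITY
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    alpha: float = 0.05
    allow_imperfect: bool = False
    correlation_min_n: int = 6
    normalize: bool = True
    per_group_correlation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 <= self.min_identity <= 1:
            raise ValueError("min_identity must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent
        kwargs = {}
        for key, value in raw.items():
            if key in ("gtf", "lnc_fasta", "coding_fasta", "mirna_fasta", "matrix", "groups", "pairs", "out_dir"):
                kwargs[key] = base / value
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass(frozen=True)
class MirnaEvidence:
    """Per shared-miRNA clause status inside one candidate triplet."""

    mirna_id: str
    de: DEResult
    r_lnc_mirna: float
    p_lnc_mirna: float
    opposite_direction: bool
    negatively_correlated: bool

    @property
    def qualifies(self) -> bool:
        return self.de.passes and self.opposite_direction and self.negatively_correlated


@dataclass(frozen=True)
class CeRNATriplet:
    """A (lncRNA, mRNA, shared miRNAs) candidate with its verdict."""

    lncrna_id: str
    mrna_id: str
    shared_mirnas: tuple[str, ...]
    lnc_de: DEResult
    mrna_de: DEResult
    mirna_evidence: tuple[MirnaEvidence, ...]
    r_lnc_mrna: float
    p_lnc_mrna: float
    verdict: str
    direction: str
    rejection_reasons: tuple[str, ...] = field(default_factory=tuple)

    @property
    def qualifying_mirnas(self) -> tuple[str, ...]:
        return tuple(e.mirna_id for e in self.mirna_evidence if e.qualifies)


def _expression_row(matrix: ExpressionMatrix, probe_id: str) -> np.ndarray:
    if probe_id not in matrix.values.index:
        raise KeyError(f"no expression row for id {probe_id!r}")
    return np.log2(matrix.values.loc[probe_id].to_numpy(float) + 1e-12)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with an undefined correlation (a constant row, e.g. a probe
    pinned to one rank by quantile normalization) mapped to (nan, 1): the
    correlation clause simply fails instead of aborting the run."""
    try:
        return pearson_r(x, y)
    except ValueError:
        return float("nan"), 1.0


def nominate(
    lnc_id: str,
    mrna_id: str,
    site_reports: dict[str, list[SiteReport]],
    de_results: dict[str, DEResult],
    expr_matrix: ExpressionMatrix,
    cfg: PipelineConfig,
) -> CeRNATriplet:
    """Evaluate one candidate (lncRNA, mRNA) pair against the sponge clauses.

    Correlations are Pearson, on log2 intensities, across all samples pooled.
    Missing expression rows or DE results raise KeyError naming the id.
    """
    shared = shared_mres(site_reports.get(lnc_id, []), site_reports.get(mrna_id, []))
    shared_ids = tuple(mid for mid, _, _ in shared)
    reasons: list[str] = []
    if not shared_ids:
        reasons.append("no shared miRNA")

    for pid in (lnc_id, mrna_id):
        if pid not in de_results:
            raise KeyError(f"no DE result for id {pid!r}")
    lnc_de, mrna_de = de_results[lnc_id], de_results[mrna_id]
    if not lnc_de.passes:
        reasons.append("lncRNA not differentially expressed")
    if not mrna_de.passes:
        reasons.append("mRNA not differentially expressed")
    same_direction = lnc_de.direction == mrna_de.direction
    if lnc_de.passes and mrna_de.passes and not same_direction:
        reasons.append("lncRNA/mRNA direction discordant")

    x_lnc = _expression_row(expr_matrix, lnc_id)
    x_mrna = _expression_row(expr_matrix, mrna_id)
    if len(x_lnc) < cfg.correlation_min_n:
        raise PipelineError("nominate", f"fewer than {cfg.correlation_min_n} samples")
    r_lm, p_lm = _safe_pearson(x_lnc, x_mrna)
    if not (r_lm > 0 and p_lm < cfg.alpha):
        reasons.append("lncRNA/mRNA correlation not significantly positive")

    evidence = []
    for mid in shared_ids:
        if mid not in de_results:
            raise KeyError(f"no DE result for shared miRNA {mid!r}")
        mir_de = de_results[mid]
        r_lmir, p_lmir = _safe_pearson(x_lnc, _expression_row(expr_matrix, mid))
        evidence.append(
            MirnaEvidence(
                mirna_id=mid,
                de=mir_de,
                r_lnc_mirna=r_lmir,
                p_lnc_mirna=p_lmir,
                opposite_direction=mir_de.direction != lnc_de.direction,
                negatively_correlated=(r_lmir < 0 and p_lmir < cfg.alpha),
            )
        )
    if shared_ids and not any(e.qualifies for e in evidence):
        for e in evidence:
            if not e.de.passes:
                reasons.append(f"{e.mirna_id}: miRNA not differentially expressed")
            elif not e.opposite_direction:
                reasons.append(f"{e.mirna_id}: miRNA direction")
            elif not e.negatively_correlated:
                reasons.append(f"{e.mirna_id}: miRNA correlation not significantly negative")

    verdict = "nominated" if not reasons else "rejected"
    return CeRNATriplet(
        lncrna_id=lnc_id,
        mrna_id=mrna_id,
        shared_mirnas=shared_ids,
        lnc_de=lnc_de,
        mrna_de=mrna_de,
        mirna_evidence=tuple(evidence),
        r_lnc_mrna=r_lm,
        p_lnc_mrna=p_lm,
        verdict=verdict,
        direction=lnc_de.direction,
        rejection_reasons=tuple(reasons),
    )


def triplet_table(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    rows = [
        {
            "lncRNA": t.lncrna_id,
            "mRNA": t.mrna_id,
            "Shared_miRNAs": ",".join(t.shared_mirnas),
            "Qualifying_miRNAs": ",".join(t.qualifying_mirnas),
            "lnc_fold_change": t.lnc_de.fold_change,
            "mRNA_fold_change": t.mrna_de.fold_change,
            "Direction": t.direction,
            "r_lnc_mRNA": t.r_lnc_mrna,
            "p_lnc_mRNA": t.p_lnc_mrna,
            "Verdict": t.verdict,
            "Rejection_reasons": "; ".join(t.rejection_reasons),
        }
        for t in triplets
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lncRNA",
            "mRNA",
            "Shared_miRNAs",
            "Qualifying_miRNAs",
            "lnc_fold_change",
            "mRNA_fold_change",
            "Direction",
            "r_lnc_mRNA",
            "p_lnc_mRNA",
            "Verdict",
            "Rejection_reasons",
        ],
    )


@dataclass
class PipelineResult:
    """All tables from one run plus where they were written."""

    positional: pd.DataFrame
    mimic: pd.DataFrame
    sites: pd.DataFrame
    de: pd.DataFrame
    triplets: list[CeRNATriplet]
    nominated: list[CeRNATriplet]
    out_dir: Path


def _stage(stage_name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(stage_name, str(err)) from err

    return wrap


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """DE -> positional classification -> mimicked genes -> MRE scan ->
    correlation -> nomination, with every report written to ``cfg.out_dir``.

    The run manifest (JSON) records the configuration, seed, rule-set and
    package versions; identical config + seed give a byte-identical bundle.
    """
    from . import formats

    read = _stage("read_inputs")
    transcripts = read(formats.read_gtf, cfg.gtf)
    lnc_records = read(formats.read_fasta, cfg.lnc_fasta)
    coding_records = read(formats.read_fasta, cfg.coding_fasta)
    mirnas = read(formats.read_mirnas, cfg.mirna_fasta)
    matrix = read(formats.read_expression, cfg.matrix, cfg.groups)

    if cfg.normalize:
        matrix = _stage("normalize")(matrix.normalized)

    de_results = _stage("fold_change_filter")(fold_change_filter, matrix, cfg.fc_threshold)
    de_by_id = {r.probe_id: r for r in de_results}

    lncs = [t for t in transcripts if t.biotype == "lncRNA"]
    coding = [t for t in transcripts if t.biotype == "coding"]
    positional_df = _stage("positional_classifier")(classify_all, lncs, coding)

    chrom_of = {t.transcript_id: t.locus.chrom for t in transcripts}
    lnc_seqs = {r.id: r.sequence for r in lnc_records}
    coding_seqs = {r.id: r.sequence for r in coding_records}
    missing = sorted((set(lnc_seqs) | set(coding_seqs)) - set(chrom_of))
    if missing:
        raise PipelineError(
            "homology_mimic", f"sequence id(s) missing from annotation: {', '.join(missing)}"
        )
    mimic_pairs = _stage("homology_mimic")(
        find_mimicked_genes,
        lnc_seqs,
        coding_seqs,
        {k: chrom_of[k] for k in lnc_seqs},
        {k: chrom_of[k] for k in coding_seqs},
        min_identity=cfg.min_identity,
        report_floor=0.5,
    )
    mimic_df = mimic_table(mimic_pairs)

    scan = _stage("mre_scanner")
    site_reports: dict[str, list[SiteReport]] = {}
    site_frames = []
    for tid, seq in sorted({**lnc_seqs, **coding_seqs}.items()):
        reports = scan(
            site_report, seq, mirnas, allow_imperfect=cfg.allow_imperfect, target_id=tid
        )
        site_reports[tid] = reports
        site_frames.append(report_table(reports))
    sites_df = (
        pd.concat(site_frames, ignore_index=True)
        if site_frames
        else report_table([])
    )

    candidates = [(p.lncrna_id, p.gene_id) for p in mimic_pairs if p.passes]
    if cfg.pairs is not None:
        pairs_df = read(formats.read_tsv, cfg.pairs)
        for col in ("lncrna_id", "mrna_id"):
            if col not in pairs_df.columns:
                raise PipelineError("pairs", f"{cfg.pairs}: missing column {col!r}")
        candidates.extend(zip(pairs_df["lncrna_id"], pairs_df["mrna_id"]))
    seen = set()
    candidates = [c for c in candidates if not (c in seen or seen.add(c))]

    nom = _stage("nominate")
    triplets = [
        nom(nominate, lnc_id, mrna_id, site_reports, de_by_id, matrix, cfg)
        for lnc_id, mrna_id in candidates
    ]
    nominated = [t for t in triplets if t.verdict == "nominated"]

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    de_df = de_table(de_results)
    formats.write_tsv(positional_df, out / "positional.tsv")
    formats.write_tsv(mimic_df, out / "mimicked_genes.tsv")
    formats.write_tsv(sites_df, out / "mre_sites.tsv")
    formats.write_tsv(de_df, out / "differential_expression.tsv")
    formats.write_tsv(triplet_table(triplets), out / "triplets.tsv")
    manifest = {
        # path entries are recorded by basename (and the output directory not
        # at all) so equivalent bundles in different locations stay
        # byte-identical
        "config": {
            k: (Path(v).name if isinstance(v, Path) else v)
            for k, v in asdict(cfg).items()
            if k != "out_dir"
        },
        "seed": cfg.seed,
        "ruleset_version": RULESET_VERSION,
        "package_version": __version__,
        "n_candidates": len(candidates),
        "n_nominated": len(nominated),
        "outputs": [
            "positional.tsv",
            "mimicked_genes.tsv",
            "mre_sites.tsv",
            "differential_expression.tsv",
            "triplets.tsv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        positional=positional_df,
        mimic=mimic_df,
        sites=sites_df,
        de=de_df,
        triplets=triplets,
        nominated=nominated,
        out_dir=out,
    )
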