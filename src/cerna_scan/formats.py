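"""Readers, writers and validation for the external formats the pipeline uses.

GTF (1-based inclusive on disk, converted to the library's 0-based half-open
intervals), FASTA (60-column wrapping on write, via Biopython), TSV tables
(tab-separated, '.' for missing, mandatory header, no quoting) and BED export
for genome-browser viewing. All error messages name the file and the
line/record at fault.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import CT_COLUMNS, ExpressionMatrix, validate_ct_table
from .models import GenomicInterval, TranscriptModel, ValidationError
from .mre import MiRNA

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_DNA = frozenset("ACGTN")


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class PrimerRecord:
    """A qPCR primer pair (both orientations, DNA alphabet)."""

    name: str
    sense_seq: str
    antisense_seq: str

    def __post_init__(self) -> None:
        for seq in (self.sense_seq, self.antisense_seq):
            if not seq or set(seq) - _DNA:
                raise ValidationError(f"{self.name}: invalid primer sequence {seq!r}")


class GtfError(ValueError):
    """Malformed GTF content, reported with file and line number."""


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse transcript/exon features into TranscriptModels.

    Coordinates convert from 1-based inclusive to 0-based half-open. The
    ``biotype`` attribute defaults to "coding" when absent. Exons are grouped
    by transcript_id and sorted; an exon outside its transcript, or an unknown
    strand character, raises :class:`GtfError` naming the offending line.
    """
    path = Path(path)
    transcripts: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, GenomicInterval]]] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature not in ("transcript", "exon"):
                continue
            if strand not in ("+", "-"):
                raise GtfError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise GtfError(f"{path}:{lineno}: invalid coordinates {start}..{end}")
            attrs = _parse_attributes(attr_s)
            tid = attrs.get("transcript_id")
            if not tid:
                raise GtfError(f"{path}:{lineno}: missing transcript_id attribute")
            interval = GenomicInterval(chrom, start - 1, end, strand)
            if feature == "transcript":
                if tid in transcripts:
                    raise GtfError(f"{path}:{lineno}: duplicate transcript {tid!r}")
                transcripts[tid] = {
                    "locus": interval,
                    "gene_name": attrs.get("gene_id", tid),
                    "biotype": attrs.get("biotype", "coding"),
                    "line": lineno,
                }
                order.append(tid)
            else:
                exons.setdefault(tid, []).append((lineno, interval))
    models = []
    for tid in order:
        info = transcripts[tid]
        tid_exons = sorted(exons.get(tid, []), key=lambda e: e[1].start)
        if not tid_exons:
            raise GtfError(
                f"{path}:{info['line']}: transcript {tid!r} has no exon features"
            )
        for lineno, ex in tid_exons:
            if ex.start < info["locus"].start or ex.end > info["locus"].end:
                raise GtfError(
                    f"{path}:{lineno}: exon crosses the boundary of transcript {tid!r}"
                )
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_name=info["gene_name"],
                    biotype=info["biotype"],
                    locus=info["locus"],
                    exons=tuple(ex for _, ex in tid_exons),
                )
            )
        except ValidationError as err:
            raise GtfError(f"{path}:{info['line']}: {err}") from None
    orphans = sorted(set(exons) - set(transcripts))
    if orphans:
        raise GtfError(f"{path}: exon(s) without transcript feature: {', '.join(orphans)}")
    return models


def write_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Write transcript+exon features; read_gtf(write_gtf(x)) == x."""
    with Path(path).open("w") as fh:
        for t in transcripts:
            attrs = (
                f'transcript_id "{t.transcript_id}"; gene_id "{t.gene_name}"; '
                f'biotype "{t.biotype}";'
            )
            loc = t.locus
            fh.write(
                f"{loc.chrom}\tcerna_scan\ttranscript\t{loc.start + 1}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\t{attrs}\n"
            )
            for ex in t.exons:
                fh.write(
                    f"{ex.chrom}\tcerna_scan\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


def write_bed(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """BED6 export (one line per transcript) for browser viewing."""
    with Path(path).open("w") as fh:
        for t in transcripts:
            loc = t.locus
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{t.transcript_id}\t0\t{loc.strand}\n"
            )


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read FASTA; duplicate ids or empty sequences are errors."""
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: empty sequence for {rec.id!r}")
        desc = rec.description[len(rec.id) :].strip()
        records.append(FastaRecord(id=rec.id, description=desc, sequence=seq))
    return records


def write_fasta(records: list[FastaRecord], path: str | Path) -> None:
    """Write FASTA wrapped at 60 columns; round-trips through read_fasta."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_mirnas(path: str | Path) -> list[MiRNA]:
    """miRNAs from FASTA, or from TSV with columns mirna_id, sequence."""
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        df = read_tsv(path)
        return [MiRNA(row["mirna_id"], row["sequence"]) for _, row in df.iterrows()]
    return [MiRNA(r.id, r.sequence) for r in read_fasta(path)]


def write_tsv(df: pd.DataFrame, path: str | Path, *, index: bool = False) -> None:
    """The package TSV dialect: tabs, '.' for missing, header, no quoting."""
    df.to_csv(
        Path(path),
        sep="\t",
        index=index,
        na_rep=".",
        lineterminator="\n",
        float_format="%.10g",
    )


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", na_values=["."], keep_default_na=False, **kwargs)


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Expression TSV (first column probe id, header = sample ids) plus the
    sample -> group sidecar TSV (columns sample_id, group)."""
    values = read_tsv(matrix_path, index_col=0)
    groups_df = read_tsv(groups_path)
    for col in ("sample_id", "group"):
        if col not in groups_df.columns:
            raise ValueError(f"{groups_path}: missing column {col!r}")
    group_of = pd.Series(
        groups_df["group"].to_numpy(), index=groups_df["sample_id"].to_numpy()
    )
    return ExpressionMatrix(values.astype(float), group_of)


def write_expression(m: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path) -> None:
    values = m.values.copy()
    values.index.name = "probe_id"
    write_tsv(values, matrix_path, index=True)
    groups = pd.DataFrame(
        {"sample_id": m.sample_ids, "group": [m.group_of[s] for s in m.sample_ids]}
    )
    write_tsv(groups, groups_path)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {sorted(missing)}")
    return validate_ct_table(df)


def fixture_bundle() -> tuple[list[FastaRecord], list[PrimerRecord]]:
    """Packaged smoke-test inputs: 12 qPCR primer sequences and 2 ISH probe
    sequences for the rat pulmonary-fibrosis assay panel (MRAK088388,
    MRAK081523, N4bp2, Plxna4, beta-actin, U6). Parser/scanner fixtures only;
    no biological claims attached."""
    data = resources.files("cerna_scan.data")
    with resources.as_file(data / "fixtures.fasta") as p:
        records = read_fasta(p)
    with resources.as_file(data / "qpcr_primers.tsv") as p:
        primers_df = read_tsv(p)
    primers = [
        PrimerRecord(row["name"], row["sense_seq"], row["antisense_seq"])
        for _, row in primers_df.iterrows()
    ]
    return records, primers
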