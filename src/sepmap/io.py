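"""Readers and writers for the toolkit's interchange formats.

TSV is the interchange format for tables (probe intensities, event calls,
gene calls, words, RNA maps, ground truth); sequences travel as FASTA with
a BED6 sidecar giving the exon coordinates inside each record.  All
coordinates are 0-based half-open; records are sense-strand normalized, so
the BED strand column is always "+".  Every table is written with a header
row and a stable column order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifmap import ExonSequenceRecord
from .synthdata import GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "read_probe_table",
    "write_probe_table",
    "read_exon_sequences",
    "write_exon_sequences",
    "write_truth",
]

_SEQ_CHARS = set("ACGTN")
ANNOT_COLUMNS = ["probe_id", "gene_id", "event_id", "role"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class ParseError(ValueError):
    """A malformed input file; message carries the path and line number."""


def _find_line(path: Path, needle: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if needle in line:
                return i
    return 0


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an ordered id -> sequence mapping.

    Lowercase input is normalized to uppercase with a logged note; any
    character outside A/C/G/T/N raises a parse error locating the line.
    """
    path = Path(path)
    out: dict[str, str] = {}
    lowered = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            lowered += 1
            seq = seq.upper()
        bad = set(seq) - _SEQ_CHARS
        if bad:
            frag = next(s for s in seq.split() if set(s) & bad)
            raise ParseError(
                f"{path}: record {rec.id!r} near line "
                f"{_find_line(path, frag[:30]) or '?'} contains invalid "
                f"characters {sorted(bad)}"
            )
        if rec.id in out:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = seq
    if lowered:
        logger.info("normalized %d lowercase record(s) to uppercase", lowered)
    return out


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write an id -> sequence mapping as FASTA (fixed line wrapping)."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED intervals (0-based, half-open) as a DataFrame.

    BED6 is the native dialect; 3-column BED is accepted with name ".",
    score 0 and strand "+" filled in.  start must satisfy
    0 <= start < end or a parse error naming the line is raised.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} must be < end {end}"
                )
            name = parts[3] if len(parts) > 3 else "."
            try:
                score = float(parts[4]) if len(parts) > 4 else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = parts[5] if len(parts) > 5 else "+"
            if strand not in {"+", "-", "."}:
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Probe intensity TSV: annotation columns then one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ANNOT_COLUMNS})
    missing = [c for c in ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df["event_id"] = df["event_id"].fillna("")
    return df


def write_probe_table(table: pd.DataFrame, path: str | Path) -> None:
    samples = [c for c in table.columns if c not in ANNOT_COLUMNS]
    table[ANNOT_COLUMNS + samples].to_csv(path, sep="\t", index=False)


def write_exon_sequences(
    records: Sequence[ExonSequenceRecord],
    fasta_path: str | Path,
    bed_path: str | Path,
) -> None:
    """Sequences as FASTA (upstream+exon+downstream, sense strand) + BED6.

    The BED names the exon interval inside each record; strand is always
    "+" because records are sense-normalized.
    """
    seqs = {
        r.exon_id: r.upstream_intron + r.exon_seq + r.downstream_intron
        for r in records
    }
    write_fasta(seqs, fasta_path)
    with open(bed_path, "w") as fh:
        for r in records:
            start = len(r.upstream_intron)
            end = start + len(r.exon_seq)
            fh.write(f"{r.exon_id}\t{start}\t{end}\t{r.exon_id}\t0\t+\n")


def read_exon_sequences(
    fasta_path: str | Path,
    bed_path: str | Path,
    class_labels: Mapping[str, str] | None = None,
) -> list[ExonSequenceRecord]:
    """Rebuild exon records from a FASTA + BED6 pair.

    The BED chrom column names the FASTA record holding each exon; the
    interval splits it into upstream intron / exon / downstream intron.
    ``class_labels`` optionally maps exon id to its splicing class.
    """
    seqs = read_fasta(fasta_path)
    bed = read_bed(bed_path)
    records = []
    for row in bed.itertuples(index=False):
        if row.chrom not in seqs:
            raise ParseError(
                f"{bed_path}: BED record {row.name!r} references unknown "
                f"FASTA record {row.chrom!r}"
            )
        seq = seqs[row.chrom]
        if row.end > len(seq):
            raise ParseError(
                f"{bed_path}: interval of {row.name!r} exceeds record length"
            )
        label = (class_labels or {}).get(row.name, "unclassified")
        records.append(
            ExonSequenceRecord(
                exon_id=row.name,
                upstream_intron=seq[: row.start],
                exon_seq=seq[row.start : row.end],
                downstream_intron=seq[row.end :],
                class_label=label,
            )
        )
    return records


def write_truth(truth: GroundTruth, outdir: str | Path) -> list[Path]:
    """Ground-truth sidecar TSVs; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    if len(truth.gene_log2fc):
        p = outdir / "truth_genes.tsv"
        truth.gene_log2fc.rename_axis("gene_id").to_frame().to_csv(p, sep="\t")
        paths.append(p)
    if len(truth.event_sepscore):
        p = outdir / "truth_events.tsv"
        truth.event_sepscore.rename_axis("event_id").to_frame().to_csv(p, sep="\t")
        paths.append(p)
    if truth.planted_motifs:
        p = outdir / "truth_motifs.tsv"
        with open(p, "w") as fh:
            fh.write("exon_id\tplanted_starts\n")
            for exon_id, starts in truth.planted_motifs.items():
                fh.write(f"{exon_id}\t{','.join(map(str, starts))}\n")
        paths.append(p)
    return paths
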