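"""Readers and writers for the flat-file formats the pipeline exchanges.

Formats: BED3/BED6 for peak intervals, TSV count tables (first column id,
remaining columns samples), a TSV sample sheet, and indexed BAM for optional
read counting.  Lines beginning with ``#`` or ``track``/``browser`` are
treated as comments in BED and TSV inputs.
"""

from __future__ import annotations

import logging
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CountExperiment, PeakInterval, SampleInfo, ValidationError

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def read_peaks(path: str | Path, dialect: str = "bed6") -> list[PeakInterval]:
    """Read peaks from BED3 or BED6.

    BED is 0-based half-open; coordinates are preserved untouched.  For BED6
    the name column becomes ``peak_id`` and the strand column is kept; BED3
    rows get empty ids and strand '.'.
    """
    if dialect not in {"bed3", "bed6"}:
        raise ValueError(f"dialect must be bed3 or bed6, got {dialect!r}")
    n_fields = 3 if dialect == "bed3" else 6
    peaks: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < n_fields:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {n_fields} fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            name = fields[3] if n_fields == 6 else ""
            strand = fields[5] if n_fields == 6 else "."
            if strand not in {"+", "-", "."}:
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            try:
                peaks.append(
                    PeakInterval(fields[0], start, end, strand=strand, peak_id=name)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return peaks


def write_peaks_bed(peaks: list[PeakInterval], path: str | Path,
                    scores: dict[str, float] | None = None) -> None:
    """Write BED6.  ``scores`` maps peak_id to an FDR; the BED score column is
    int(min(1000, -10*log10 FDR)), the usual phred-like encoding."""
    with open(path, "w") as fh:
        for p in peaks:
            score = 0
            if scores is not None and p.peak_id in scores:
                fdr = scores[p.peak_id]
                if fdr > 0:
                    score = int(min(1000, -10.0 * math.log10(fdr)))
                else:
                    score = 1000
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\t{p.strand}\n")


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    """TSV with columns sample_id, fraction, condition, replicate[, library_size]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "fraction", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        lib = float(row["library_size"]) if "library_size" in df.columns else float("nan")
        samples.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                fraction=str(row["fraction"]),
                condition=str(row["condition"]),
                replicate=int(row["replicate"]),
                library_size=lib,
            )
        )
    return samples


def _read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.allclose(arr, np.round(arr)):
        raise ValidationError(f"{path}: count table contains non-integer values")
    if (arr < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return df.astype(np.int64)


def read_count_table(
    peak_counts_path: str | Path,
    sample_sheet_path: str | Path,
    gene_counts_path: str | Path | None = None,
    peaks_path: str | Path | None = None,
    peak_gene_path: str | Path | None = None,
) -> CountExperiment:
    """Assemble a validated CountExperiment from TSV tables and a sample sheet.

    Sample columns are reordered to sample-sheet order; a sample present in
    one but not the other raises a reconciliation error naming the offenders.
    library_size defaults to the peak-table column sum when absent from the
    sheet; all-zero columns are accepted with a warning.
    """
    samples = read_sample_sheet(sample_sheet_path)
    sheet_ids = [s.sample_id for s in samples]
    peak_df = _read_counts_tsv(peak_counts_path)
    table_ids = list(peak_df.columns)
    extra = sorted(set(table_ids) - set(sheet_ids))
    absent = sorted(set(sheet_ids) - set(table_ids))
    if extra or absent:
        raise ValidationError(
            f"sample reconciliation failed: in table but not sheet {extra}; "
            f"in sheet but not table {absent}"
        )
    peak_df = peak_df[sheet_ids]
    if gene_counts_path is not None:
        gene_df = _read_counts_tsv(gene_counts_path)[sheet_ids]
    else:
        # degenerate single-gene view: all peaks on one pseudo-gene
        gene_df = pd.DataFrame(
            [peak_df.sum(axis=0)], index=["gene_all"], columns=sheet_ids
        )
    filled = []
    for s in samples:
        lib = s.library_size
        if math.isnan(lib):
            lib = float(peak_df[s.sample_id].sum())
        if lib == 0:
            warnings.warn(f"sample {s.sample_id} has library size 0", stacklevel=2)
        filled.append(
            SampleInfo(s.sample_id, s.fraction, s.condition, s.replicate, lib)
        )
    p2g: dict[str, str] = {}
    if peak_gene_path is not None:
        mapping = pd.read_csv(peak_gene_path, sep="\t", comment="#",
                              dtype=str)
        p2g = dict(zip(mapping.iloc[:, 0], mapping.iloc[:, 1]))
    if peaks_path is not None:
        by_id = {p.peak_id: p for p in read_peaks(peaks_path, dialect="bed6")}
        missing_peaks = [pid for pid in peak_df.index if pid not in by_id]
        if missing_peaks:
            raise ValidationError(
                f"count-table peaks absent from BED: {missing_peaks[:5]}"
            )
        gene_ids = list(gene_df.index)
        peaks = []
        for i, pid in enumerate(peak_df.index):
            p = by_id[pid]
            gene = p2g.get(pid) or p.gene_id
            if not gene:
                if len(gene_ids) == 1:
                    gene = gene_ids[0]
                else:
                    raise ValidationError(
                        "peaks carry no gene assignment; provide a "
                        "peak-to-gene mapping (TSV peak_id<TAB>gene_id)"
                    )
            peaks.append(PeakInterval(p.chrom, p.start, p.end, p.strand,
                                      p.peak_id, gene))
    else:
        gene_ids = list(gene_df.index)
        peaks = [
            PeakInterval("chrU", 1000 * i, 1000 * i + 100, peak_id=str(pid),
                         gene_id=gene_ids[i % len(gene_ids)])
            for i, pid in enumerate(peak_df.index)
        ]
    return CountExperiment(peak_counts=peak_df, gene_counts=gene_df,
                           peaks=peaks, samples=filled)


def assign_peaks_to_genes(
    peaks: list[PeakInterval], genes: list[PeakInterval]
) -> list[PeakInterval]:
    """Assign each peak the gene with the longest overlap (>=1 base).

    Ties break lexicographically by gene_id; multi-gene assignments are
    logged.  ``genes`` are intervals whose peak_id field carries the gene id.
    """
    out = []
    for p in peaks:
        hits = []
        for g in genes:
            ov = min(p.end, g.end) - max(p.start, g.start)
            if g.chrom == p.chrom and ov > 0:
                hits.append((ov, g.peak_id))
        if not hits:
            out.append(p)
            continue
        hits.sort(key=lambda t: (-t[0], t[1]))
        if len(hits) > 1:
            logger.info(
                "peak %s overlaps %d genes; assigned %s (longest overlap)",
                p.peak_id, len(hits), hits[0][1],
            )
        out.append(PeakInterval(p.chrom, p.start, p.end, p.strand, p.peak_id, hits[0][1]))
    return out


def count_reads_in_peaks(
    alignment_path: str | Path,
    peaks: list[PeakInterval],
    stranded: bool = False,
) -> pd.Series:
    """Count reads overlapping each peak by >= 1 aligned base in one BAM.

    A read is counted at most once per peak (but may count toward several
    overlapping peaks).  Duplicate reads are not removed.  Unstranded by
    default; with ``stranded`` a read only counts toward a peak on its own
    strand (peaks with strand '.' accept both).
    """
    import pysam

    alignment_path = str(alignment_path)
    try:
        bam = pysam.AlignmentFile(alignment_path, "rb")
    except Exception as exc:  # pragma: no cover - pysam error text varies
        raise IOError(f"cannot open alignment file {alignment_path}: {exc}") from exc
    with bam:
        if not bam.has_index():
            raise IOError(
                f"{alignment_path} has no index; run 'samtools index' first"
            )
        refs = set(bam.references)
        counts = {}
        for p in peaks:
            if p.chrom not in refs:
                warnings.warn(
                    f"chromosome {p.chrom} absent from alignment header; "
                    f"peak {p.peak_id or p.chrom} gets count 0",
                    stacklevel=2,
                )
                counts[p.peak_id] = 0
                continue
            seen = set()
            for read in bam.fetch(p.chrom, p.start, p.end):
                if read.is_unmapped:
                    continue
                if stranded and p.strand in {"+", "-"}:
                    read_strand = "-" if read.is_reverse else "+"
                    if read_strand != p.strand:
                        continue
                # fetch already guarantees >=1 base overlap with [start, end)
                seen.add(read.query_name + ("/2" if read.is_read2 else "/1"))
            counts[p.peak_id] = len(seen)
    return pd.Series(counts, name="count")


def write_results(records: pd.DataFrame, path: str | Path, fmt: str = "tsv",
                  provenance: dict | None = None) -> None:
    """Write a results table as TSV (floats at 6 significant digits) or, for
    tables carrying chrom/start/end/peak_id/fdr columns, as BED6 with the FDR
    phred-encoded in the score column."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            if provenance:
                for k, v in provenance.items():
                    fh.write(f"# {k}: {v}\n")
            records.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    elif fmt == "bed":
        needed = {"chrom", "start", "end", "peak_id", "fdr"}
        if not needed.issubset(records.columns):
            raise ValueError(f"BED export needs columns {sorted(needed)}")
        peaks = [
            PeakInterval(r.chrom, int(r.start), int(r.end),
                         strand=getattr(r, "strand", "."), peak_id=r.peak_id)
            for r in records.itertuples()
        ]
        write_peaks_bed(peaks, path, scores=dict(zip(records["peak_id"], records["fdr"])))
    else:
        raise ValueError(f"format must be tsv or bed, got {fmt!r}")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id (first whitespace-delimited token)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
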