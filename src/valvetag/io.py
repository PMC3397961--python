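"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based half-open throughout (bedGraph/BED convention).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "tss"]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) triples from a FASTQ file.

    Raises ValueError with the record index on a malformed record.
    """
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record near record {i}: {exc}") from exc
            yield rec
            i += 1


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, chrom, strand, tss; 0-based TSS)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bedgraph(coverage: dict[str, np.ndarray], path) -> None:
    """Write per-base coverage arrays as a run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        for chrom in coverage:
            cov = np.asarray(coverage[chrom])
            if cov.size == 0:
                continue
            change = np.flatnonzero(np.diff(cov)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [cov.size]))
            vals = cov[starts]
            for s, e, v in zip(starts, ends, vals):
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, chrom_lengths: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-base coverage arrays.

    Intervals must be sorted and non-overlapping within each chromosome;
    an unsorted file is a hard error.  Bases not covered by any interval
    are zero.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str}, comment="#",
    )
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"bedGraph not sorted/non-overlapping on {chrom}")
        length = int(ends.max())
        if chrom_lengths and chrom in chrom_lengths:
            length = max(length, int(chrom_lengths[chrom]))
        cov = np.zeros(length, dtype=float)
        for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
            cov[s:e] = v
        out[chrom] = cov
    return out


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write a BED6 file from a frame with chrom/start/end/name/score/strand."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
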