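"""FASTQ reads -> per-gene, per-library expression matrix.

The processing chain mirrors classic SAGE/Tag-seq digital gene
expression: a Chastity-style quality filter, extraction of the 21-bp
NlaIII-anchored tag from the read start, collapse of 1-bp
sequencing-error satellites of highly expressed tags, virtual-tag
mapping against a transcriptome index (unambiguous sense hits only),
per-gene summation over transcript-variant tags, and tags-per-million
normalization with an expressed filter at >5 counts per library.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from valvetag import defaults
from valvetag.io import iter_fastq

TAG_LEN = 21
ANCHOR = "CATG"
_ILLUMINA_FLAG = re.compile(r"\s[12]:([YN]):")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TagCountTable:
    """Raw 21-bp tag counts for one library."""

    library: str
    counts: dict[str, int]
    total_reads: int = 0
    hq_reads: int = 0

    def total_tags(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class TagToGeneMap:
    """tag -> [(gene_id, orientation, rank)] with per-tag sense ambiguity."""

    hits: dict[str, list[tuple[str, str, int]]]
    untaggable_genes: list[str] = field(default_factory=list)

    def sense_genes(self, tag: str) -> list[str]:
        return sorted({g for g, ori, _ in self.hits.get(tag, []) if ori == "sense"})

    def is_ambiguous(self, tag: str) -> bool:
        return len(self.sense_genes(tag)) > 1


@dataclass
class GeneExpressionMatrix:
    """Per-gene raw counts and TPM across libraries."""

    raw: pd.DataFrame
    denominators: pd.Series
    tpm: pd.DataFrame | None = None


def filter_reads(fastq_path, chastity_threshold: float = defaults.CHASTITY_THRESHOLD):
    """Quality-filter a FASTQ file.

    Reads carrying the Illumina filter flag (``1:Y:...`` in the header,
    the simulator's convention) are removed.  Reads without a flag fall
    back to a mean-Phred proxy: mean quality over the first 21 bases must
    be >= Q20.  Returns (passing sequences, QC report dict).
    """
    passing: list[str] = []
    total = 0
    for title, seq, qual in iter_fastq(fastq_path):
        total += 1
        m = _ILLUMINA_FLAG.search(title)
        if m is not None:
            ok = m.group(1) == "N"
        else:
            q = qual[:TAG_LEN]
            ok = bool(q) and (sum(ord(c) for c in q) / len(q) - 33.0) >= 20.0
        if ok:
            passing.append(seq)
    report = {
        "total_reads": total,
        "hq_reads": len(passing),
        "failed_reads": total - len(passing),
        "chastity_threshold": chastity_threshold,
    }
    return passing, report


def extract_tags(reads, library: str = "", report: dict | None = None) -> TagCountTable:
    """Count 21-bp anchored tags from quality-passing reads.

    The tag is the first 21 bases of the read (case-insensitive).  Reads
    shorter than 21 bases, reads whose first 4 bases are not the NlaIII
    site CATG, and reads with N in the tag are discarded and tallied.
    """
    counts: Counter[str] = Counter()
    n_short = n_unanchored = n_with_n = 0
    total = 0
    for seq in reads:
        total += 1
        if len(seq) < TAG_LEN:
            n_short += 1
            continue
        tag = seq[:TAG_LEN].upper()
        if not tag.startswith(ANCHOR):
            n_unanchored += 1
            continue
        if "N" in tag:
            n_with_n += 1
            continue
        counts[tag] += 1
    table = TagCountTable(
        library=library,
        counts=dict(counts),
        total_reads=(report or {}).get("total_reads", total),
        hq_reads=total,
    )
    table_report = {
        "reads_in": total,
        "short": n_short,
        "unanchored": n_unanchored,
        "with_n": n_with_n,
        "tag_types": len(counts),
    }
    if report is not None:
        report.update(table_report)
    return table


def collapse_mismatch(
    table: TagCountTable,
    ratio: float = defaults.COLLAPSE_RATIO,
    parent_min: int = defaults.COLLAPSE_PARENT_MIN,
) -> tuple[TagCountTable, dict]:
    """Remove 1-bp-mismatch satellites of highly expressed tags.

    A tag t is removed iff some tag u at Hamming distance 1 satisfies
    count(u) >= parent_min and count(u) >= ratio x count(t).  Removal is
    decided against the original table in a single pass (no chaining),
    so the result is independent of input ordering.
    """
    counts = table.counts
    tags = sorted(counts)  # deterministic, order-independent
    removed: dict[str, int] = {}
    # bucket tags by the 20-mer obtained by deleting position i; tags in
    # the same bucket differ only at position i
    for i in range(TAG_LEN):
        buckets: dict[str, list[str]] = defaultdict(list)
        for t in tags:
            buckets[t[:i] + t[i + 1:]].append(t)
        for group in buckets.values():
            if len(group) < 2:
                continue
            cmax = max(counts[t] for t in group)
            if cmax < parent_min:
                continue
            for t in group:
                c = counts[t]
                if t in removed:
                    continue
                best = max(counts[u] for u in group if u != t)
                if best >= parent_min and best >= ratio * c:
                    removed[t] = c
    kept = {t: c for t, c in counts.items() if t not in removed}
    out = TagCountTable(table.library, kept, table.total_reads, table.hq_reads)
    report = {
        "removed_tag_types": len(removed),
        "removed_tag_count": int(sum(removed.values())),
        "removed_tags": removed,
        "ratio": ratio,
        "parent_min": parent_min,
    }
    return out, report


def build_virtual_tag_index(sequences: dict[str, str], gene_of=None) -> TagToGeneMap:
    """Index every NlaIII virtual tag of a transcriptome.

    For each transcript, sense virtual tags are CATG plus the 17
    downstream bases at each NlaIII site with enough remaining sequence,
    ranked 3'-most first (rank 1).  Antisense tags are indexed the same
    way from the reverse complement.  ``gene_of`` maps a record id to its
    gene id (identity by default).
    """
    gene_of = gene_of or (lambda x: x)
    hits: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
    untaggable = []
    for rec_id, seq in sequences.items():
        gene = gene_of(rec_id)
        seq = seq.upper()
        any_tag = False
        for oriented, orientation in ((seq, "sense"), (_revcomp(seq), "antisense")):
            sites = [m.start() for m in re.finditer(ANCHOR, oriented)
                     if m.start() + TAG_LEN <= len(oriented)]
            for rank, p in enumerate(reversed(sites), start=1):
                hits[oriented[p:p + TAG_LEN]].append((gene, orientation, rank))
                if orientation == "sense":
                    any_tag = True
        if not any_tag:
            untaggable.append(gene)
    return TagToGeneMap(hits=dict(hits), untaggable_genes=untaggable)


def map_and_aggregate(
    table: TagCountTable, index: TagToGeneMap
) -> tuple[pd.Series, dict]:
    """Aggregate tag counts to genes via unambiguous sense mappings.

    Tags with no index hit are excluded (unmapped); tags whose sense
    hits span more than one gene are excluded (ambiguous); tags with
    only antisense hits are excluded.  Each remaining tag's count adds
    to its unique sense gene; all tags of a gene are summed.
    """
    gene_counts: Counter[str] = Counter()
    unmapped: dict[str, int] = {}
    ambiguous: dict[str, int] = {}
    antisense_only: dict[str, int] = {}
    for tag, c in table.counts.items():
        tag_hits = index.hits.get(tag)
        if not tag_hits:
            unmapped[tag] = c
            continue
        genes = {g for g, ori, _ in tag_hits if ori == "sense"}
        if not genes:
            antisense_only[tag] = c
        elif len(genes) > 1:
            ambiguous[tag] = c
        else:
            gene_counts[next(iter(genes))] += c
    report = {
        "unmapped_tag_types": len(unmapped),
        "unmapped_count": int(sum(unmapped.values())),
        "ambiguous_tag_types": len(ambiguous),
        "ambiguous_count": int(sum(ambiguous.values())),
        "antisense_only_tag_types": len(antisense_only),
        "antisense_only_count": int(sum(antisense_only.values())),
        "unmapped_tags": unmapped,
        "ambiguous_tags": ambiguous,
    }
    return pd.Series(gene_counts, dtype="int64").sort_index(), report


def build_matrix(
    per_library_counts: dict[str, pd.Series],
    denominators: dict[str, int] | pd.Series,
) -> GeneExpressionMatrix:
    """Assemble per-library gene counts into one matrix (genes x libraries)."""
    raw = pd.DataFrame(per_library_counts).fillna(0).astype("int64")
    raw = raw.sort_index().rename_axis("gene_id")
    denom = pd.Series(denominators).reindex(raw.columns)
    return GeneExpressionMatrix(raw=raw, denominators=denom)


def tpm_normalize(matrix: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Fill tpm = raw x 1e6 / per-library denominator (exactly)."""
    if (matrix.denominators <= 0).any() or matrix.denominators.isna().any():
        bad = matrix.denominators[(matrix.denominators <= 0) | matrix.denominators.isna()]
        raise ValueError(f"invalid TPM denominators: {dict(bad)}")
    matrix.tpm = matrix.raw * 1e6 / matrix.denominators
    return matrix


def expressed_filter(raw, min_tags: int = defaults.MIN_EXPRESSED_COUNT):
    """Boolean mask: expressed iff raw count >= min_tags (i.e. > 5 by default)."""
    return raw >= min_tags


def count_library(fastq_path, library: str,
                  chastity_threshold: float = defaults.CHASTITY_THRESHOLD,
                  ratio: float = defaults.COLLAPSE_RATIO,
                  parent_min: int = defaults.COLLAPSE_PARENT_MIN):
    """Convenience chain: filter -> extract -> collapse for one FASTQ."""
    reads, qc = filter_reads(fastq_path, chastity_threshold)
    table = extract_tags(reads, library=library, report=qc)
    table, collapse_report = collapse_mismatch(table, ratio=ratio, parent_min=parent_min)
    qc["collapse"] = {k: v for k, v in collapse_report.items() if k != "removed_tags"}
    return table, qc


def write_tag_table(table: TagCountTable, path) -> None:
    pd.Series(table.counts, name="count").rename_axis("tag").sort_index().to_csv(
        path, sep="\t")


def read_tag_table(path, library: str = "") -> TagCountTable:
    s = pd.read_csv(path, sep="\t", index_col=0)["count"]
    return TagCountTable(library=library, counts=s.to_dict(),
                         total_reads=int(s.sum()), hq_reads=int(s.sum()))


def write_matrix(matrix: GeneExpressionMatrix, path) -> None:
    """Write raw (and tpm, if filled) columns plus denominator header lines."""
    df = matrix.raw.add_prefix("raw_")
    if matrix.tpm is not None:
        df = df.join(matrix.tpm.add_prefix("tpm_"))
    with open(path, "w") as fh:
        for lib, d in matrix.denominators.items():
            fh.write(f"#denominator\t{lib}\t{int(d)}\n")
        df.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_matrix(path) -> GeneExpressionMatrix:
    denominators = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#denominator"):
                fh.seek(pos)
                break
            _, lib, d = line.rstrip("\n").split("\t")
            denominators[lib] = int(d)
        df = pd.read_csv(fh, sep="\t", index_col="gene_id")
    raw = df[[c for c in df.columns if c.startswith("raw_")]]
    raw.columns = [c[4:] for c in raw.columns]
    matrix = GeneExpressionMatrix(raw=raw, denominators=pd.Series(denominators))
    tpm_cols = [c for c in df.columns if c.startswith("tpm_")]
    if tpm_cols:
        tpm = df[tpm_cols]
        tpm.columns = [c[4:] for c in tpm.columns]
        matrix.tpm = tpm
    return matrix
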