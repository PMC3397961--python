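"""Gene-set intersection statistics and category enrichment.

Region-set overlap reports (e.g. valve-region enriched genes shared
between two tissues, or mutant down-regulated genes against wild-type
enriched genes), a generic one-tailed Fisher exact over-representation
test with Benjamini-Hochberg adjustment, and ingestion of per-gene
supplementary expression tables so published set-level counts can be
recomputed from the stated rule (p < 0.05, no fold-change cutoff) rather
than read off sheet membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset
    provenance: str = "computed"

    def __post_init__(self):
        if not self.label:
            raise ValueError("label must be non-empty")

    def __len__(self):
        return len(self.members)


@dataclass
class OverlapReport:
    label_a: str
    label_b: str
    size_a: int
    size_b: int
    size_intersection: int
    pct_of_a: float
    pct_of_b: float
    members: list
    hypergeom_p: float | None = None


def intersect(set_a: GeneSet, set_b: GeneSet, universe: GeneSet | None = None) -> OverlapReport:
    """Exact set intersection with percentages (1 d.p. convention).

    With a universe, also reports the hypergeometric upper-tail p-value
    of observing at least this much overlap.
    """
    common = set_a.members & set_b.members
    na, nb, k = len(set_a.members), len(set_b.members), len(common)
    p = None
    if universe is not None:
        n_u = len(universe.members)
        p = float(hypergeom.sf(k - 1, n_u, na, nb))
    return OverlapReport(
        label_a=set_a.label, label_b=set_b.label,
        size_a=na, size_b=nb, size_intersection=k,
        pct_of_a=round(100.0 * k / na, 1) if na else 0.0,
        pct_of_b=round(100.0 * k / nb, 1) if nb else 0.0,
        members=sorted(common),
        hypergeom_p=p,
    )


def fisher_enrichment(
    query: GeneSet, categories: dict[str, GeneSet], universe: GeneSet
) -> pd.DataFrame:
    """One-tailed Fisher exact over-representation of each category.

    For category C the 2x2 table is (query∩C, query∖C, C∖query, rest)
    over the universe; the one-tailed p is the hypergeometric upper
    tail P(X >= |query∩C|).  A BH-adjusted p-value is added across the
    reported categories.
    """
    if not universe.members:
        raise ValueError("universe must be non-empty")
    n_u = len(universe.members)
    q = query.members & universe.members
    rows = []
    for name, cat in categories.items():
        c = cat.members & universe.members
        k = len(q & c)
        p = float(hypergeom.sf(k - 1, n_u, len(c), len(q)))
        rows.append({"category": name, "count": k, "category_size": len(c),
                     "query_size": len(q), "p_value": p})
    out = pd.DataFrame(rows).set_index("category")
    if len(out):
        out["p_adjusted"] = false_discovery_control(out["p_value"], method="bh")
    return out


# Supplementary-table schemas: required columns per sheet type.  Gene
# identity is keyed on the RefSeq accession (symbols can collide).
_TPM_COLS = ["tpm_avc", "tpm_oft", "tpm_atria", "tpm_ventricles", "tpm_avc_null"]
SCHEMAS = {
    "S2": ["gene_symbol", "accession", *_TPM_COLS],
    "S4": ["gene_symbol", "accession", *_TPM_COLS,
           "avc_fold_change", "avc_p_value", "oft_fold_change", "oft_p_value"],
    "S6": ["gene_symbol", "accession", *_TPM_COLS,
           "null_fold_change", "null_p_value", "avc_fold_change", "avc_p_value"],
    "S8": ["gene_symbol", "accession", *_TPM_COLS,
           "null_fold_change", "null_p_value", "peak_chrom", "peak_start",
           "peak_end", "peak_height"],
}


def ingest_supplementary(path, schema: str) -> pd.DataFrame:
    """Read a supplementary per-gene table (TSV or Excel), validated.

    Returns a frame indexed by RefSeq accession with the schema's
    columns; duplicate accessions keep the first occurrence with a
    warning.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    if path.suffix.lower() in {".xls", ".xlsx"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t")
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name} ({schema}): missing columns {missing}; found {list(df.columns)}")
    df = df[required].copy()
    dup = df["accession"].duplicated()
    if dup.any():
        warnings.warn(f"{path.name}: {int(dup.sum())} duplicate accessions; keeping first")
        df = df[~dup]
    return df.set_index("accession")


def enriched_from_table(df: pd.DataFrame, p_col: str, fc_col: str,
                        alpha: float = 0.05, direction: str = "enriched") -> GeneSet:
    """Recompute an enriched/depleted set from per-gene statistics.

    Applies the stated rule — p < alpha with no fold-change cutoff —
    with the fold change used only for direction.
    """
    sig = df[p_col] < alpha
    if direction == "enriched":
        sig &= df[fc_col] > 1
    elif direction == "depleted":
        sig &= df[fc_col] < 1
    else:
        raise ValueError("direction must be 'enriched' or 'depleted'")
    return GeneSet(label=f"{p_col}<{alpha}:{direction}",
                   members=frozenset(df.index[sig]), provenance="supplementary")


def expression_heatmap_matrix(tpm: pd.DataFrame, genes) -> pd.DataFrame:
    """Row-wise min-max normalization to [0, 1]; constant rows map to 0.5."""
    sub = tpm.loc[list(genes)].astype(float)
    lo = sub.min(axis=1)
    span = sub.max(axis=1) - lo
    out = sub.sub(lo, axis=0).div(span.where(span > 0, np.nan), axis=0)
    return out.fillna(0.5)
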