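"""ChIP-qPCR fold enrichment with negative-control normalization.

Fold enrichment of an immunoprecipitated target is 2 raised to the
cycle-threshold difference between the non-specific IgG control and the
antibody pulldown; values are normalized to a negative-control locus to
absorb between-ChIP variability, and replicates are summarized as mean
and sample standard deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["target", "replicate", "ct_antibody", "ct_igg"]


def fold_enrichment(ct_igg: float, ct_antibody: float) -> float:
    """FE = 2^(cT_IgG − cT_antibody); values below 1 represent depletion."""
    if not (np.isfinite(ct_igg) and np.isfinite(ct_antibody)):
        raise ValueError("cT values must be finite")
    return float(2.0 ** (ct_igg - ct_antibody))


def normalize_to_negative(fes: dict[str, float], negative_id: str) -> dict[str, float]:
    """Divide every fold enrichment by the negative control's."""
    if negative_id not in fes:
        raise ValueError(f"negative control {negative_id!r} not among targets")
    ref = fes[negative_id]
    if ref <= 0:
        raise ValueError("negative-control fold enrichment must be > 0")
    return {t: v / ref for t, v in fes.items()}


def summarize(measurements: pd.DataFrame, negative_id: str) -> pd.DataFrame:
    """Per-target mean +/- SD of normalized fold enrichment across replicates.

    ``measurements`` columns: target, replicate, ct_antibody, ct_igg.
    Normalization to the negative control happens within each replicate
    before summarization.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    per_rep = []
    for rep, sub in measurements.groupby("replicate"):
        fes = {r["target"]: fold_enrichment(r["ct_igg"], r["ct_antibody"])
               for _, r in sub.iterrows()}
        nfes = normalize_to_negative(fes, negative_id)
        per_rep.extend({"target": t, "replicate": rep, "nfe": v} for t, v in nfes.items())
    df = pd.DataFrame(per_rep)
    out = df.groupby("target")["nfe"].agg(mean_nfe="mean", sd_nfe="std", n="count")
    out["sd_nfe"] = out["sd_nfe"].fillna(0.0)
    return out.sort_index()
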