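"""Conditional negative-binomial exact test at fixed dispersion.

Differential expression between two groups of replicate-free tag
libraries: counts are linearly scaled to a common library size (the
geometric mean), group pseudo-count sums are compared with a conditional
exact test for negative-binomial counts at a fixed dispersion (default
0.12), and fold changes are estimated with a small prior count.

The test conditions on the total s = yA + yB.  Under the null the group
sums are NB with means proportional to the group sizes nA:nB (at the
pooled mean estimate) and dispersions phi/nA and phi/nB; the two-sided
p-value is the total conditional probability of all outcomes k in [0, s]
no more likely than the observed one (the small-probability method).
All pmf arithmetic is done in log space with log-gamma terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from valvetag import defaults
from valvetag.tagseq import GeneExpressionMatrix, expressed_filter

#: relative log-probability slack when comparing pmf values to the observed
#: one, so exact ties (e.g. the mirror outcome when nA == nB) are included
_TIE_RTOL = 1e-10


@dataclass
class TestConfig:
    dispersion: float = defaults.DISPERSION
    alpha: float = defaults.ALPHA
    prior_count: float = defaults.PRIOR_COUNT
    min_expressed: int = defaults.MIN_EXPRESSED_COUNT

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def equalize_library_sizes(counts: pd.DataFrame, sizes: pd.Series) -> pd.DataFrame:
    """Scale counts linearly to the geometric-mean common library size.

    pseudo_i = count_i x N*/size_i with N* = geometric mean of sizes.
    """
    sizes = pd.Series(sizes).astype(float).reindex(counts.columns)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    n_star = float(np.exp(np.log(sizes).mean()))
    return counts * (n_star / sizes)


def _nb_logpmf(k: np.ndarray, r: float, mu: float) -> np.ndarray:
    """log NB pmf with size r and mean mu over integer support k."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(k + r) - gammaln(r) - gammaln(k + 1)
        + r * np.log(r / (r + mu))
        + k * np.log(mu / (r + mu))
    )


def nb_exact_test(sum_a: float, n_a: int, sum_b: float, n_b: int,
                  dispersion: float = defaults.DISPERSION) -> float:
    """Two-sided conditional exact p-value for two NB group sums.

    Inputs are (possibly real-valued) pseudo-count sums; they are rounded
    half-to-even to integers before the conditional law.  s = 0 returns
    p = 1 by convention.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if sum_a < 0 or sum_b < 0:
        raise ValueError("group sums must be >= 0")
    ya = int(np.round(sum_a))
    yb = int(np.round(sum_b))
    s = ya + yb
    if s == 0:
        return 1.0
    mu = s / (n_a + n_b)
    k = np.arange(s + 1)
    logp = (_nb_logpmf(k, n_a / dispersion, n_a * mu)
            + _nb_logpmf(s - k, n_b / dispersion, n_b * mu))
    logp = logp - logsumexp(logp)
    cutoff = logp[ya] + _TIE_RTOL * abs(logp[ya])
    p = float(np.exp(logsumexp(logp[logp <= cutoff])))
    return min(p, 1.0)


def fold_change(sum_a: float, n_a: int, sum_b: float, n_b: int,
                prior_count: float = defaults.PRIOR_COUNT) -> float:
    """Prior-damped ratio of per-library group means (A over B)."""
    return ((sum_a + n_a * prior_count) / n_a) / ((sum_b + n_b * prior_count) / n_b)


def call_enrichment(
    matrix: GeneExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    config: TestConfig | None = None,
) -> pd.DataFrame:
    """Per-gene exact test of group A against group B.

    Genes passing the expressed filter (> 5 raw counts) in at least one
    involved library are tested; significance is p < alpha with no
    fold-change cutoff, and the direction column separates enriched
    (FC > 1) from depleted (FC < 1) calls.
    """
    config = config or TestConfig()
    if not group_a or not group_b:
        raise ValueError("both groups must contain at least one library")
    libs = list(group_a) + list(group_b)
    missing = [l for l in libs if l not in matrix.raw.columns]
    if missing:
        raise ValueError(f"libraries absent from matrix: {missing}")

    raw = matrix.raw[libs]
    keep = expressed_filter(raw, config.min_expressed).any(axis=1)
    raw = raw.loc[keep]
    pseudo = equalize_library_sizes(raw, matrix.denominators[libs])
    sum_a = pseudo[list(group_a)].sum(axis=1)
    sum_b = pseudo[list(group_b)].sum(axis=1)
    n_a, n_b = len(group_a), len(group_b)

    pvals = np.array([
        nb_exact_test(a, n_a, b, n_b, config.dispersion)
        for a, b in zip(sum_a.to_numpy(), sum_b.to_numpy())
    ])
    fc = np.array([
        fold_change(a, n_a, b, n_b, config.prior_count)
        for a, b in zip(sum_a.to_numpy(), sum_b.to_numpy())
    ])
    out = pd.DataFrame({
        "gene_id": raw.index,
        "sum_a": sum_a.to_numpy(),
        "sum_b": sum_b.to_numpy(),
        "fold_change": fc,
        "p_value": pvals,
    }).set_index("gene_id")
    out["significant"] = out["p_value"] < config.alpha
    out["direction"] = np.where(out["fold_change"] > 1, "enriched",
                                np.where(out["fold_change"] < 1, "depleted", "none"))
    return out


def significant_set(results: pd.DataFrame, direction: str = "enriched") -> set[str]:
    """Gene ids called significant in the given direction."""
    mask = results["significant"] & (results["direction"] == direction)
    return set(results.index[mask])
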