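"""Drift-group differential gene expression.

Genes overlapping drift CpG islands are tested for expression differences
between samples with low island methylation (mean beta < 0.2) and samples
with advanced methylation (mean beta >= 0.2; boundary inclusive on the
high side), using a two-sided Mann-Whitney-Wilcoxon U test per gene and
Benjamini-Hochberg adjustment across tested genes.  Promoter methylation
past the threshold is expected to repress transcription, so calls are
expected to be strongly asymmetric toward repression.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import DomainError
from .survey import bh_adjust

EXACT_MAX_N = 12


def split_samples(island_mean_beta: pd.Series, threshold: float = 0.2):
    """Split sample ids into low (< threshold) and high (>= threshold)
    island-methylation groups; NaN island means are dropped."""
    vals = island_mean_beta.dropna()
    if len(island_mean_beta) < 1:
        raise DomainError("need at least one sample")
    low = list(vals.index[vals < threshold])
    high = list(vals.index[vals >= threshold])
    return low, high


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for group x (ties contribute 1/2)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided MWW p by enumerating all group-label assignments of
    the pooled values.  The permutation distribution of U is symmetric
    about n1*n2/2 (midranks are invariant under rank reversal), so the
    two-sided p is P(|U - n1*n2/2| >= |u_obs - n1*n2/2|)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    center = n1 * len(y) / 2.0
    u_obs = _u_statistic(x, y)
    dev = abs(u_obs - center) - 1e-9
    hits = total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(comb)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        hits += abs(u - center) >= dev
        total += 1
    return hits / total


def test_gene(expr_low, expr_high, min_per_side: int = 3) -> dict:
    """Two-sided MWW U test of one gene's expression between groups.

    Exact enumeration when the pooled sample size is <= 12, normal
    approximation with tie correction otherwise.  Returns
    ``{"U", "p", "testable"}``; groups smaller than ``min_per_side`` are
    flagged untestable rather than silently dropped.
    """
    x = np.asarray(expr_low, dtype=float)
    y = np.asarray(expr_high, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < min_per_side or len(y) < min_per_side:
        return {"U": np.nan, "p": np.nan, "testable": False}
    u = _u_statistic(x, y)
    if len(x) + len(y) <= EXACT_MAX_N:
        p = _exact_two_sided_p(x, y)
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return {"U": u, "p": float(min(p, 1.0)), "testable": True}


def run_association(
    expr: pd.DataFrame,
    island_means: pd.DataFrame,
    gene_island_map: pd.DataFrame,
    threshold: float = 0.2,
    q_max: float = 0.01,
    min_per_side: int = 3,
) -> dict:
    """Test every mapped (gene, island) pair for drift-coupled expression.

    Parameters
    ----------
    expr : genes x samples normalized expression.
    island_means : islands x samples per-sample mean beta over each
        island's drift CpGs.
    gene_island_map : DataFrame with ``gene_id`` and ``island_id`` columns;
        many-to-many allowed, each pair tested once and BH-adjusted jointly.

    Returns ``{"results": DataFrame, "n_repressed", "n_overexpressed",
    "n_untestable"}``.  Direction comes from the median difference:
    high-drift median below low-drift median means repressed.
    """
    missing = set(gene_island_map["gene_id"]) - set(expr.index)
    if missing:
        raise DomainError(f"mapped genes absent from expression matrix: {sorted(missing)[:5]}")
    missing = set(gene_island_map["island_id"]) - set(island_means.index)
    if missing:
        raise DomainError(f"mapped islands absent from island means: {sorted(missing)[:5]}")
    shared = [s for s in expr.columns if s in island_means.columns]
    rows = []
    for gene_id, island_id in gene_island_map[["gene_id", "island_id"]].itertuples(index=False):
        means = island_means.loc[island_id, shared]
        low, high = split_samples(means, threshold)
        e_low = expr.loc[gene_id, low].to_numpy(dtype=float)
        e_high = expr.loc[gene_id, high].to_numpy(dtype=float)
        res = test_gene(e_low, e_high, min_per_side=min_per_side)
        rows.append(
            {
                "gene_id": gene_id,
                "island_id": island_id,
                "n_low": len(low),
                "n_high": len(high),
                "statistic": res["U"],
                "p": res["p"],
                "testable": res["testable"],
                "median_diff": (
                    float(np.median(e_high) - np.median(e_low)) if res["testable"] else np.nan
                ),
            }
        )
    results = pd.DataFrame(rows)
    results["q"] = np.nan
    results["direction"] = "none"
    if len(results) == 0 or not results["testable"].any():
        return {"results": results, "n_repressed": 0, "n_overexpressed": 0, "n_untestable": len(results)}
    ok = results["testable"].to_numpy()
    results.loc[ok, "q"] = bh_adjust(results.loc[ok, "p"].to_numpy())
    sig = ok & (results["q"].to_numpy() < q_max)
    results.loc[sig & (results["median_diff"] < 0), "direction"] = "repressed"
    results.loc[sig & (results["median_diff"] > 0), "direction"] = "overexpressed"
    return {
        "results": results,
        "n_repressed": int((results["direction"] == "repressed").sum()),
        "n_overexpressed": int((results["direction"] == "overexpressed").sum()),
        "n_untestable": int((~results["testable"]).sum()),
    }
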