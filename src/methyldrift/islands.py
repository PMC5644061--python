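"""Within-island pairwise correlation structure and island-size comparison.

CpG islands act as collective functional units: when an island drifts,
its CpGs tend to gain methylation together, so pairwise correlations
between island CpGs (across samples) are higher, and decay more slowly
with genomic distance, than in static islands.  This module computes
distance-binned mean pairwise Pearson correlations (default 10-bp bins)
for island CpGs paired with island/shore/shelf CpGs of the same island,
stratified by island class (static vs drift), plus a Welch t-test
comparing static and drift island sizes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .io import DomainError, MethylationMatrix

PARTNER_RELATIONS = ("island", "shore", "shelf")


def _pairwise_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r across samples with pairwise NaN deletion; NaN when fewer
    than 3 complete pairs or zero variance."""
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        return np.nan
    x, y = a[mask], b[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def correlation_profile(
    beta: MethylationMatrix,
    probes: pd.DataFrame,
    island_classes: dict,
    bin_bp: int = 10,
) -> pd.DataFrame:
    """Distance-binned mean pairwise correlations within islands.

    For every island in ``island_classes`` (island_id -> "static"/"drift"),
    each island-relation CpG is paired with every other island, shore or
    shelf CpG carrying the same island_id.  Pairs are assigned to
    left-closed ``bin_bp`` distance bins by |pos_a - pos_b| and aggregated
    into mean r and pair counts per (island_class, partner relation, bin).
    Self-pairs are excluded; zero-variance probes are skipped and counted
    in ``result.attrs["n_pairs_skipped"]``.
    """
    values = beta.values
    if values.shape[1] < 3:
        raise DomainError("need at least 3 samples for pairwise correlations")
    ann = probes[probes["island_id"].notna() & probes["relation"].isin(PARTNER_RELATIONS)]
    ann = ann[ann["probe_id"].isin(values.index)]
    records = []
    skipped = 0
    for island_id, grp in ann.groupby("island_id", sort=True):
        if island_id not in island_classes or len(grp) < 2:
            continue
        cls = island_classes[island_id]
        data = values.loc[grp["probe_id"]].to_numpy(dtype=float)
        pos = grp["pos"].to_numpy()
        rel = grp["relation"].to_numpy()
        idx_island = np.flatnonzero(rel == "island")
        seen = set()
        for i in idx_island:
            for j in range(len(grp)):
                if i == j:
                    continue
                key = (min(i, j), max(i, j))
                if key in seen:
                    continue
                seen.add(key)
                r = _pairwise_r(data[i], data[j])
                if not np.isfinite(r):
                    skipped += 1
                    continue
                partner = rel[j] if j not in idx_island else "island"
                dist = abs(int(pos[i]) - int(pos[j]))
                records.append(
                    {
                        "island_class": cls,
                        "relation_of_partner": partner,
                        "bin_left_bp": (dist // bin_bp) * bin_bp,
                        "r": r,
                    }
                )
    if not records:
        profile = pd.DataFrame(
            columns=["island_class", "relation_of_partner", "bin_left_bp", "mean_r", "n_pairs"]
        )
    else:
        df = pd.DataFrame(records)
        profile = (
            df.groupby(["island_class", "relation_of_partner", "bin_left_bp"])["r"]
            .agg(mean_r="mean", n_pairs="size")
            .reset_index()
        )
    profile.attrs["n_pairs_skipped"] = skipped
    profile.attrs["bin_bp"] = bin_bp
    return profile


def island_size_test(static_sizes, drift_sizes) -> dict:
    """Welch two-sided t-test comparing static vs drift island sizes (bp);
    group means reported in kb.

    Identical constant groups return t=0, p=1; constant groups with
    different means are flagged as the degenerate-variance path.
    """
    a = np.asarray(static_sizes, dtype=float)
    b = np.asarray(drift_sizes, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("need at least 2 sizes per group")
    out = {"mean_static_kb": float(a.mean() / 1000), "mean_drift_kb": float(b.mean() / 1000)}
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            out.update(t=0.0, p=1.0, degenerate_variance=False)
            return out
        raise DomainError(
            "degenerate variance in both groups with unequal means: t is unbounded"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    out.update(t=float(t), p=float(p), degenerate_variance=False)
    return out


def all_pairs_bruteforce(beta: MethylationMatrix, probes: pd.DataFrame, island_id: str):
    """Enumerate every admissible probe pair of one island with its raw r
    and distance (no binning).  Intended for cross-checks and inspection.
    """
    values = beta.values
    grp = probes[(probes["island_id"] == island_id) & probes["relation"].isin(PARTNER_RELATIONS)]
    grp = grp[grp["probe_id"].isin(values.index)]
    out = []
    rows = list(grp.itertuples())
    for a, b in itertools.combinations(rows, 2):
        if a.relation != "island" and b.relation != "island":
            continue
        r = _pairwise_r(
            values.loc[a.probe_id].to_numpy(dtype=float),
            values.loc[b.probe_id].to_numpy(dtype=float),
        )
        out.append((a.probe_id, b.probe_id, abs(a.pos - b.pos), r))
    return out
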