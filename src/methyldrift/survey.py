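"""Genome-wide drift-CpG survey referenced to a clock-probe set.

The scan is two-step.  (1) For each sample, compute its *clock drift*:
the mean, over a reference set of clock CpGs, of the sample's M value
minus the normal-tissue mean M at the same probe.  Differences in this
quantity across samples reflect differences in how long each tissue has
drifted.  (2) For every test probe (normally hypomethylated CpGs, mean
normal beta < 0.25), correlate its methylation with the per-sample clock
drift (Pearson, two-sided t-distribution p, Benjamini-Hochberg q across
the tested set) and call probes drifting when r > 0.5 and q < 0.01.

Islands with at least ``min_drift`` (default 5) drift probes are flagged
as drift islands; annotation-proportion summaries compare drift calls with
the hypomethylated background by island relation and gene region.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClockSet, DomainError, MethylationMatrix

CALLS = ("drift_positive", "drift_negative", "static", "excluded")


def select_hypomethylated(ns_matrix: MethylationMatrix, beta_max: float = 0.25) -> set[str]:
    """Probes whose mean beta across normal samples is strictly below
    ``beta_max`` (NaNs ignored per probe)."""
    beta = ns_matrix.to_beta().values
    if beta.shape[1] < 1:
        raise DomainError("need at least one normal sample")
    means = beta.mean(axis=1, skipna=True)
    return set(means.index[means < beta_max])


def split_by_ns_level(
    ns_matrix: MethylationMatrix, beta_max: float = 0.25, beta_hyper: float = 0.75
) -> tuple[set[str], set[str]]:
    """Split probes into hypo- (mean beta < beta_max) and hypermethylated
    (mean beta > beta_hyper) sets; the intermediate band belongs to neither."""
    beta = ns_matrix.to_beta().values
    means = beta.mean(axis=1, skipna=True)
    return set(means.index[means < beta_max]), set(means.index[means > beta_hyper])


def ns_reference(ns_matrix: MethylationMatrix, eps: float = 1e-6) -> pd.Series:
    """Per-probe mean M value over normal samples (the drift baseline)."""
    return ns_matrix.to_m(eps).values.mean(axis=1, skipna=True)


def compute_clock_drift(
    m_matrix: MethylationMatrix, clock: ClockSet, ns_ref: pd.Series
) -> pd.Series:
    """Per-sample mean M-value elevation over the clock probes, relative
    to the normal-tissue reference."""
    m = m_matrix.to_m().values
    missing = sorted(set(clock.probe_ids) - set(m.index))
    missing += sorted(set(clock.probe_ids) - set(ns_ref.index))
    if missing:
        raise DomainError(f"clock probes missing from input: {sorted(set(missing))[:10]}")
    diff = m.loc[clock.probe_ids].sub(ns_ref.loc[clock.probe_ids], axis=0)
    drift = diff.mean(axis=0, skipna=True)
    all_missing = drift.index[diff.isna().all(axis=0)]
    if len(all_missing):
        warnings.warn(f"samples with no clock-probe values excluded: {list(all_missing)}")
        drift = drift.drop(all_missing)
    return drift


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min over j >= i of (p_(j) * n / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def _masked_pearson(x: np.ndarray, y: np.ndarray):
    """Row-wise Pearson r of ``x`` (probes x samples, NaN allowed) against
    ``y`` (samples,), dropping missing pairs per row.

    Returns (r, n_pairs, zero_variance_flag)."""
    mask = np.isfinite(x) & np.isfinite(y)[None, :]
    n = mask.sum(axis=1)
    xz = np.where(mask, x, 0.0)
    yz = np.where(mask, y[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = xz.sum(1)
        sy = yz.sum(1)
        cov = (xz * yz).sum(1) - sx * sy / n
        vx = (xz**2).sum(1) - sx**2 / n
        vy = (yz**2).sum(1) - sy**2 / n
        r = cov / np.sqrt(vx * vy)
    scale = np.maximum(vx, vy)
    zero_var = (vx <= scale * 1e-14) | (vy <= 0)
    return np.clip(r, -1.0, 1.0), n, zero_var


def scan_probes(
    m_matrix: MethylationMatrix,
    clock_drift: pd.Series,
    test_set,
    clock: ClockSet | None = None,
    r_min: float = 0.5,
    q_max: float = 0.01,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Correlate each test probe with the per-sample clock drift and call
    drift CpGs.

    Returns a DriftCallTable DataFrame (probe_id index) with columns
    r, p, q, call, n_pairs.  Probes with fewer than ``min_pairs``
    informative samples or zero variance are ``excluded`` and do not enter
    the Benjamini-Hochberg adjustment.  Clock probes themselves are
    removed from the test set.
    """
    values = m_matrix.values
    test_ids = [pid for pid in values.index if pid in set(test_set)]
    if clock is not None:
        test_ids = [pid for pid in test_ids if pid not in set(clock.probe_ids)]
    samples = [s for s in values.columns if s in clock_drift.index]
    y = clock_drift.loc[samples].to_numpy(dtype=float)
    yv = y[np.isfinite(y)]
    if yv.size and np.var(yv) == 0:
        raise DomainError("clock drift has zero variance across samples")
    x = values.loc[test_ids, samples].to_numpy(dtype=float)

    r, n, zero_var = _masked_pearson(x, y)
    excluded = zero_var | (n < min_pairs)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1)))

    table = pd.DataFrame(
        {"r": r, "p": p, "q": np.nan, "call": "excluded", "n_pairs": n},
        index=pd.Index(test_ids, name="probe_id"),
    )
    ok = ~excluded
    if ok.any():
        q = bh_adjust(p[ok])
        table.loc[ok, "q"] = q
        call = np.full(ok.sum(), "static", dtype=object)
        call[(r[ok] > r_min) & (q < q_max)] = "drift_positive"
        call[(r[ok] < -r_min) & (q < q_max)] = "drift_negative"
        table.loc[ok, "call"] = call
    table.loc[excluded, ["r", "p"]] = np.nan
    return table


def aggregate_islands(
    calls: pd.DataFrame,
    probes: pd.DataFrame,
    beta_matrix: MethylationMatrix | None = None,
    min_drift: int = 5,
) -> pd.DataFrame:
    """Per-island drift summary over island-relation probes.

    An island is a drift island when it holds at least ``min_drift``
    drift-positive probes (boundary inclusive).  If a beta matrix is
    supplied, per-sample island mean beta over the island's drift probes
    is appended (one column per sample), for heatmap/karyograph export.
    """
    island_probes = probes[(probes["relation"] == "island") & probes["island_id"].notna()]
    tested = island_probes[island_probes["probe_id"].isin(calls.index)]
    rows = []
    per_sample = []
    beta = beta_matrix.to_beta().values if beta_matrix is not None else None
    for island_id, grp in tested.groupby("island_id", sort=True):
        sub = calls.loc[grp["probe_id"]]
        drift_ids = sub.index[sub["call"] == "drift_positive"]
        n_drift = len(drift_ids)
        rows.append(
            {
                "island_id": island_id,
                "n_probes_tested": len(sub),
                "n_drift": n_drift,
                "is_drift_island": n_drift >= min_drift,
            }
        )
        if beta is not None:
            if n_drift:
                per_sample.append(beta.loc[drift_ids].mean(axis=0, skipna=True))
            else:
                per_sample.append(pd.Series(np.nan, index=beta.columns))
    summary = pd.DataFrame(rows).set_index("island_id")
    if beta is not None and len(summary):
        means = pd.DataFrame(per_sample, index=summary.index)
        summary = pd.concat([summary, means], axis=1)
    return summary


def island_mean_beta(
    beta_matrix: MethylationMatrix, probes: pd.DataFrame, probe_subset=None
) -> pd.DataFrame:
    """Island x sample mean beta over island-relation probes (optionally
    restricted to a probe subset, e.g. drift CpGs only)."""
    beta = beta_matrix.to_beta().values
    island_probes = probes[(probes["relation"] == "island") & probes["island_id"].notna()]
    if probe_subset is not None:
        island_probes = island_probes[island_probes["probe_id"].isin(set(probe_subset))]
    island_probes = island_probes[island_probes["probe_id"].isin(beta.index)]
    grouped = beta.loc[island_probes["probe_id"]].groupby(
        island_probes.set_index("probe_id")["island_id"]
    )
    return grouped.mean()


def annotation_proportions(
    calls: pd.DataFrame, probes: pd.DataFrame, background_ids=None
) -> pd.DataFrame:
    """Fractions of drift-positive probes (vs a background set) by island
    relation and by gene region.

    Returns a tidy DataFrame with columns ``margin`` (relation /
    gene_region), ``level``, ``drift_fraction``, ``background_fraction``;
    fractions sum to 1 within each margin.  With zero drift-positive calls
    the result is an explicit empty DataFrame.
    """
    if len(calls) == 0:
        raise DomainError("empty call table")
    ann = probes.set_index("probe_id")
    drift_ids = calls.index[calls["call"] == "drift_positive"]
    if len(drift_ids) == 0:
        return pd.DataFrame(
            columns=["margin", "level", "drift_fraction", "background_fraction"]
        )
    if background_ids is None:
        background_ids = calls.index
    rows = []
    for margin, levels in (("relation", None), ("gene_region", None)):
        drift_counts = ann.loc[ann.index.intersection(drift_ids), margin].value_counts()
        bg_counts = ann.loc[ann.index.intersection(background_ids), margin].value_counts()
        levels = sorted(set(drift_counts.index) | set(bg_counts.index))
        for level in levels:
            rows.append(
                {
                    "margin": margin,
                    "level": level,
                    "drift_fraction": drift_counts.get(level, 0) / drift_counts.sum(),
                    "background_fraction": bg_counts.get(level, 0) / max(bg_counts.sum(), 1),
                }
            )
    return pd.DataFrame(rows)
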