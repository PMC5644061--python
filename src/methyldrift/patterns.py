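"""Per-sample drift-distribution classification (groups L / I / H).

A sample's beta values over its drift CpGs form a density on [0, 1].
Early in drift this density is unimodal near the hypomethylated baseline;
with time a second, advanced mode emerges.  Samples are classified as

* **L** — unimodal, mode below beta = 0.5 (low / no drift),
* **I** — bimodal with every mode below 0.5 (intermediate drift),
* **H** — major (highest) mode at or above 0.5 (high drift; a unimodal
  density with its single mode >= 0.5 also maps here, since drift level
  rather than modality alone drives the downstream stage analysis).

The grouping thresholds (kernel bandwidth, 5% mode prominence, 0.05 beta
mode separation) are a reproducible surrogate for what is, in the
literature, a visual call; they are exposed as parameters and echoed in
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

from .io import DomainError

GRID_SIZE = 512


@dataclass
class DriftGroupCall:
    sample_id: str
    group: str  # L, I, or H
    modes: list  # (beta_location, density_height), sorted by height desc
    n_modes: int
    major_mode_beta: float


def sample_density(
    beta_values,
    bandwidth: float = 0.05,
    grid_size: int = GRID_SIZE,
    min_values: int = 50,
):
    """Gaussian kernel density of beta values on a regular grid over [0, 1].

    The kernel mass falling outside [0, 1] is discarded and the density
    renormalized to integrate to 1 over the unit interval (trapezoid rule).
    Requires at least ``min_values`` observations: modality estimates from
    fewer points are unstable.

    Returns ``(grid, density)``.
    """
    values = np.asarray(beta_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < min_values:
        raise DomainError(
            f"need >= {min_values} beta values for a stable density, got {values.size}"
        )
    if np.any((values < 0) | (values > 1)):
        raise DomainError("beta values outside [0, 1]")
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = stats.norm.pdf((grid[:, None] - values[None, :]) / bandwidth).mean(axis=1) / bandwidth
    area = np.trapezoid(dens, grid)
    return grid, dens / area


def find_modes(
    grid: np.ndarray,
    density: np.ndarray,
    min_height_frac: float = 0.05,
    min_separation_beta: float = 0.05,
) -> list[tuple[float, float]]:
    """Local maxima of the density with height >= ``min_height_frac`` of
    the global maximum and pairwise separation >= ``min_separation_beta``.

    Boundary maxima (at beta = 0 or 1) count as modes.  Returns
    ``(beta_location, height)`` pairs sorted by height, descending.
    """
    spacing = grid[1] - grid[0]
    distance = max(1, int(np.ceil(min_separation_beta / spacing)))
    padded = np.concatenate([[-np.inf], density, [-np.inf]])
    peaks, props = find_peaks(
        padded, height=min_height_frac * density.max(), distance=distance
    )
    peaks = peaks - 1  # undo padding offset
    order = np.argsort(props["peak_heights"])[::-1]
    return [(float(grid[peaks[i]]), float(props["peak_heights"][i])) for i in order]


def classify_sample(
    grid: np.ndarray,
    density: np.ndarray,
    sample_id: str = "",
    min_height_frac: float = 0.05,
    min_separation_beta: float = 0.05,
    high_beta: float = 0.5,
) -> DriftGroupCall:
    """Assign drift group L / I / H from a sample's beta-value density."""
    modes = find_modes(grid, density, min_height_frac, min_separation_beta)
    major = modes[0][0]
    if len(modes) == 1:
        group = "L" if major < high_beta else "H"
    else:
        group = "H" if major >= high_beta else "I"
    return DriftGroupCall(
        sample_id=sample_id,
        group=group,
        modes=modes,
        n_modes=len(modes),
        major_mode_beta=major,
    )


def classify_cohort(
    matrix, drift_probe_ids, bandwidth: float = 0.05, **kwargs
) -> pd.DataFrame:
    """Classify every sample of a beta matrix over a drift-CpG set.

    Returns a DataFrame with columns sample_id, group, n_modes,
    major_mode_beta.
    """
    beta = matrix.to_beta().values
    sub = beta.loc[beta.index.intersection(drift_probe_ids)]
    rows = []
    for sample in sub.columns:
        grid, dens = sample_density(sub[sample].dropna().to_numpy(), bandwidth=bandwidth)
        call = classify_sample(grid, dens, sample_id=sample, **kwargs)
        rows.append(
            {
                "sample_id": call.sample_id,
                "group": call.group,
                "n_modes": call.n_modes,
                "major_mode_beta": call.major_mode_beta,
            }
        )
    return pd.DataFrame(rows)


def stage_association(
    groups: pd.DataFrame,
    sheet: pd.DataFrame,
    low_stages: tuple = ("I",),
    high_stages: tuple = ("III", "IV"),
) -> dict:
    """Drift group (H vs L+I) against tumor stage (low vs advanced).

    Stage II and unknown-stage samples are excluded by default, matching
    the stage I vs stage III+ contrast.  Returns the 2x2 table
    ``[[H & low, H & high], [L+I & low, L+I & high]]``, the two-sided
    Fisher exact p (hypergeometric), and the conditional-MLE odds ratio
    with its exact 95% CI.
    """
    merged = groups.merge(sheet[["sample_id", "stage"]], on="sample_id", how="inner")
    merged = merged[merged["stage"].isin(set(low_stages) | set(high_stages))]
    is_h = merged["group"] == "H"
    is_low = merged["stage"].isin(low_stages)
    table = np.array(
        [
            [int((is_h & is_low).sum()), int((is_h & ~is_low).sum())],
            [int((~is_h & is_low).sum()), int((~is_h & ~is_low).sum())],
        ]
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise DomainError("empty margin in drift-group x stage table")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    res = stats.contingency.odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return {
        "table": table,
        "odds_ratio": float(res.statistic),
        "ci_95": (float(ci.low), float(ci.high)),
        "p": float(p),
    }
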