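"""Multicellular stochastic model of CpG-island methylation drift.

An island of ``n_cpgs`` sites evolves independently in ``n_cells`` cells.
Each site is binary (methylated / unmethylated).  Unmethylated sites gain
methylation sporadically with a per-step probability drawn once per CpG
from a gamma distribution (mean 1e-4, variance 4e-8 by default), emulating
replication-coupled de novo methylation.  Methylated sites never revert.

The model's key nonlinearity is *ambient methylation feedback*: when the
mean methylation of the island crosses a threshold (beta = 0.2 by default)
the per-site rates jump ~100-fold (to a mean of 1e-2), which turns an
initially unimodal distribution of per-CpG beta values into a bimodal one
over time.  A linear control (``feedback="linear"``) disables the jump.

Randomness protocol (pinned so a naive per-site loop is bit-identical to
the vectorized engine): at every step, one uniform is drawn per
*unmethylated* site, in site-major order (CpG index outer, cell index
inner); a site methylates iff its uniform is below its effective rate.
``run`` derives three independent substreams from ``config.seed`` via
``SeedSequence(seed).spawn(3)`` for rates, initial states, and stepping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ConfigError


@dataclass
class SimConfig:
    n_cpgs: int = 50
    n_cells: int = 1000
    n_steps: int = 3000
    record_every: int = 100
    init_p: float = 0.06
    rate_mean: float = 1e-4
    rate_var: float = 4e-8
    threshold: float = 0.2
    post_threshold_rate: float = 1e-2
    feedback: str = "nonlinear"  # or "linear"
    feedback_scope: str = "island_population"  # or "per_cell"
    rate_jump_mode: str = "multiply_fold"  # or "set_to_post"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feedback not in ("nonlinear", "linear"):
            raise ConfigError(f"unknown feedback mode {self.feedback!r}")
        if self.feedback_scope not in ("island_population", "per_cell"):
            raise ConfigError(f"unknown feedback scope {self.feedback_scope!r}")
        if self.rate_jump_mode not in ("multiply_fold", "set_to_post"):
            raise ConfigError(f"unknown rate jump mode {self.rate_jump_mode!r}")
        for name in ("init_p", "threshold", "post_threshold_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.rate_mean <= 0 or self.rate_var < 0:
            raise ConfigError("rate_mean must be > 0 and rate_var >= 0")
        if min(self.n_cpgs, self.n_cells) < 1 or self.n_steps < 0:
            raise ConfigError("n_cpgs, n_cells >= 1 and n_steps >= 0 required")


@dataclass
class SimTrajectory:
    """Recorded per-CpG beta densities over time for one island."""

    recorded_steps: np.ndarray  # (n_records,)
    per_cpg_beta: np.ndarray  # (n_records, n_cpgs); fraction of cells methylated
    crossing_step: int | None  # first step with grand mean >= threshold
    config: SimConfig

    @property
    def island_mean(self) -> np.ndarray:
        return self.per_cpg_beta.mean(axis=1)


def sample_rates(n_cpgs: int, rate_mean: float, rate_var: float, seed) -> np.ndarray:
    """Draw per-CpG baseline methylation rates from a gamma distribution.

    Parameterized by method of moments: shape = mean^2/var, scale =
    var/mean.  ``rate_var=0`` degenerates to all rates equal to the mean.
    Rates are drawn once per island and shared by all cells.
    """
    if rate_mean <= 0 or rate_var < 0:
        raise ConfigError("rate_mean must be > 0 and rate_var >= 0")
    if rate_var == 0:
        return np.full(n_cpgs, rate_mean)
    rng = np.random.default_rng(seed)
    shape = rate_mean**2 / rate_var
    scale = rate_var / rate_mean
    return rng.gamma(shape, scale, size=n_cpgs)


def init_states(n_cpgs: int, n_cells: int, init_p: float, seed) -> np.ndarray:
    """Independent Bernoulli(init_p) initial states, shape (n_cpgs, n_cells)."""
    if not 0 <= init_p <= 1:
        raise ConfigError(f"init_p must be in [0, 1], got {init_p}")
    rng = np.random.default_rng(seed)
    return rng.random((n_cpgs, n_cells)) < init_p


def _effective_rates(rates: np.ndarray, config: SimConfig) -> np.ndarray:
    """Per-CpG rates once the ambient threshold has been crossed."""
    if config.rate_jump_mode == "set_to_post":
        return np.full_like(rates, config.post_threshold_rate)
    fold = config.post_threshold_rate / config.rate_mean
    return np.minimum(1.0, rates * fold)


def step(
    state: np.ndarray,
    rates: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    elevated=False,
):
    """Advance one synchronous time step.

    ``elevated`` carries the persistent crossed-threshold flag: a scalar
    bool for ``island_population`` scope, or a (n_cells,) bool array for
    ``per_cell`` scope.  Ambient means are evaluated on the start-of-step
    state.  Returns ``(new_state, elevated)``.
    """
    state = state.copy()
    n_cpgs, n_cells = state.shape
    if config.feedback == "linear":
        rate_matrix = np.broadcast_to(rates[:, None], state.shape)
    elif config.feedback_scope == "island_population":
        elevated = bool(elevated) or state.mean() >= config.threshold
        eff = _effective_rates(rates, config) if elevated else rates
        rate_matrix = np.broadcast_to(eff[:, None], state.shape)
    else:  # per_cell
        if np.isscalar(elevated) or elevated is False:
            elevated = np.zeros(n_cells, dtype=bool)
        elevated = elevated | (state.mean(axis=0) >= config.threshold)
        rate_matrix = np.where(
            elevated[None, :], _effective_rates(rates, config)[:, None], rates[:, None]
        )
    flat = state.ravel()
    idx = np.flatnonzero(~flat)  # site-major order (C layout)
    u = rng.random(idx.size)
    r = np.ascontiguousarray(rate_matrix).ravel()[idx]
    flat[idx[u < r]] = True
    return state, elevated


def run(config: SimConfig) -> SimTrajectory:
    """Initialize and propagate the island, recording per-CpG beta values
    every ``record_every`` steps (always including step 0)."""
    ss = np.random.SeedSequence(config.seed)
    rate_ss, init_ss, step_ss = ss.spawn(3)
    rates = sample_rates(config.n_cpgs, config.rate_mean, config.rate_var, rate_ss)
    state = init_states(config.n_cpgs, config.n_cells, config.init_p, init_ss)
    rng = np.random.default_rng(step_ss)

    recorded_steps = [0]
    snapshots = [state.mean(axis=1)]
    crossing_step = 0 if state.mean() >= config.threshold else None
    elevated: bool | np.ndarray = False
    for t in range(1, config.n_steps + 1):
        state, elevated = step(state, rates, config, rng, elevated)
        if crossing_step is None and state.mean() >= config.threshold:
            crossing_step = t
        if t % config.record_every == 0:
            recorded_steps.append(t)
            snapshots.append(state.mean(axis=1))
    return SimTrajectory(
        recorded_steps=np.asarray(recorded_steps),
        per_cpg_beta=np.asarray(snapshots),
        crossing_step=crossing_step,
        config=config,
    )


def multi_island_trajectories(config: SimConfig, n_islands: int = 10) -> list[SimTrajectory]:
    """Independent islands sharing the same rate-distribution parameters.

    Rates are redrawn per island (each island's CpGs get fresh gamma
    draws), mimicking many islands governed by one drift-rate law.
    """
    if n_islands < 1:
        raise ConfigError("n_islands must be >= 1")
    if n_islands == 1:
        return [run(config)]
    seeds = np.random.SeedSequence(config.seed).generate_state(n_islands) % (2**31)
    return [run(replace(config, seed=int(s))) for s in seeds]


def density_snapshots(trajectory: SimTrajectory, bandwidth: float = 0.05):
    """Kernel densities of the per-CpG beta values at each recorded step,
    mimicking what the array measures on a tissue sample.

    Returns a list of ``(step, grid, density)`` tuples using the same
    density estimator the sample classifier uses.
    """
    from .patterns import sample_density

    out = []
    for step_no, betas in zip(trajectory.recorded_steps, trajectory.per_cpg_beta):
        grid, dens = sample_density(betas, bandwidth=bandwidth)
        out.append((int(step_no), grid, dens))
    return out
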