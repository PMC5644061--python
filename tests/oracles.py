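"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (definitions and plain
loops), deliberately avoiding the code paths under test.
"""

from itertools import combinations
from math import comb

import numpy as np

from methyldrift import simulator


def pearson_loop(x: np.ndarray, y: np.ndarray):
    """Pearson r and two-sided t-based p from the covariance formula,
    dropping incomplete pairs; (nan, nan) if degenerate."""
    from scipy.stats import t as tdist

    mask = np.isfinite(x) & np.isfinite(y)
    xv, yv = x[mask], y[mask]
    n = len(xv)
    if n < 3:
        return np.nan, np.nan, n
    mx, my = xv.mean(), yv.mean()
    sxy = ((xv - mx) * (yv - my)).sum()
    sxx = ((xv - mx) ** 2).sum()
    syy = ((yv - my) ** 2).sum()
    if sxx == 0 or syy == 0:
        return np.nan, np.nan, n
    r = sxy / np.sqrt(sxx * syy)
    if abs(r) >= 1:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, 2 * tdist.sf(abs(t), n - 2), n


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """BH by the literal step-up definition: q_(i) = min_{j>=i} p_(j)*n/j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank_idx, i in enumerate(order):
        candidates = [p[order[j]] * n / (j + 1) for j in range(rank_idx, n)]
        q[i] = min(1.0, min(candidates))
    return q


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration over all
    2x2 tables with the observed margins."""
    (a, b), (c, d) = table
    r1, n, c1 = a + b, a + b + c + d, a + c

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def mww_u(x: np.ndarray, y: np.ndarray) -> float:
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mww_exact_two_sided(x, y) -> float:
    """Exact MWW p over all label assignments of the pooled values."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    center = n1 * len(y) / 2
    dev_obs = abs(mww_u(x, y) - center)
    hits = total = 0
    for comb_idx in combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), bool)
        sel[list(comb_idx)] = True
        dev = abs(mww_u(pooled[sel], pooled[~sel]) - center)
        hits += dev >= dev_obs - 1e-9
        total += 1
    return hits / total


def welch_t(a, b):
    """Welch statistic and two-sided p from the textbook formula."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, 2 * tdist.sf(abs(t), df)


def naive_sim_run(config: simulator.SimConfig):
    """Straight-loop reimplementation of the island model under the pinned
    draw protocol (one uniform per unmethylated site, site-major order).

    Returns (recorded_steps, per_cpg_beta) matching ``simulator.run``.
    """
    ss = np.random.SeedSequence(config.seed)
    rate_ss, init_ss, step_ss = ss.spawn(3)
    rates = simulator.sample_rates(config.n_cpgs, config.rate_mean, config.rate_var, rate_ss)
    state = simulator.init_states(config.n_cpgs, config.n_cells, config.init_p, init_ss)
    state = state.copy()
    rng = np.random.default_rng(step_ss)

    if config.rate_jump_mode == "set_to_post":
        jumped = np.full_like(rates, config.post_threshold_rate)
    else:
        jumped = np.minimum(1.0, rates * config.post_threshold_rate / config.rate_mean)

    recorded = [0]
    snaps = [state.mean(axis=1).copy()]
    elevated_pop = False
    elevated_cell = np.zeros(config.n_cells, bool)
    for t in range(1, config.n_steps + 1):
        if config.feedback == "linear":
            eff = np.tile(rates[:, None], (1, config.n_cells))
        elif config.feedback_scope == "island_population":
            if state.mean() >= config.threshold:
                elevated_pop = True
            base = jumped if elevated_pop else rates
            eff = np.tile(base[:, None], (1, config.n_cells))
        else:
            for c in range(config.n_cells):
                if state[:, c].mean() >= config.threshold:
                    elevated_cell[c] = True
            eff = np.empty((config.n_cpgs, config.n_cells))
            for c in range(config.n_cells):
                eff[:, c] = jumped if elevated_cell[c] else rates
        new = state.copy()
        for i in range(config.n_cpgs):
            for c in range(config.n_cells):
                if not state[i, c]:
                    if rng.random() < eff[i, c]:
                        new[i, c] = True
        state = new
        if t % config.record_every == 0:
            recorded.append(t)
            snaps.append(state.mean(axis=1).copy())
    return np.asarray(recorded), np.asarray(snaps)
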