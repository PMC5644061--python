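"""Synthetic HM450-like cohort generator.

Emulates the statistical structure the drift analyses assume, so every
downstream stage is testable without array data: a probe manifest with
islands, flanking shores/shelves and open-sea probes; normal squamous
(NS) samples hypomethylated around a mean beta of 0.06 at island loci;
Barrett's (BE) and adenocarcinoma (EAC) samples whose *drift islands*
advance with a latent per-sample dwell time (EAC dwell times
stochastically larger than BE); beta-distributed array noise; a planted
67-probe clock set; longitudinal biopsy pairs continuing one latent
trajectory; and expression with threshold-repression coupling at island
mean beta = 0.2.

Two drift-trajectory engines are available: a logistic-in-time mean with
per-island random onset (default; deterministic runtime) and forward runs
of the stochastic island simulator (``trajectory="simulator"``), mapped
to dwell time at 100 steps per year.

All randomness flows from ``CohortConfig.seed`` through named
``SeedSequence`` substreams, so identical configs give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import simulator
from .io import ConfigError, MethylationMatrix, validate_sample_sheet

STEPS_PER_YEAR = 100
_STREAMS = ("manifest", "model", "cohort", "longitudinal", "expression")


@dataclass
class CohortConfig:
    n_islands: int = 60
    probes_per_island: tuple[int, int] = (10, 10)  # inclusive range
    n_open_sea: int = 80
    frac_drift_islands: float = 0.25
    n_ns: int = 52
    n_be: int = 64
    n_eac: int = 24
    n_clock: int = 67
    ns_baseline_beta_mean: float = 0.06
    baseline_concentration: float = 200.0
    noise_precision: float | None = 100.0  # None = noise-free
    dwell_time_be: tuple[float, float] = (0.0, 20.0)
    dwell_time_eac: tuple[float, float] = (5.0, 30.0)
    dwell_time_longitudinal: tuple[float, float] = (2.0, 14.0)
    drift_plateau: float = 0.75
    drift_rate_per_year: float = 0.35
    onset_years: tuple[float, float] = (4.0, 20.0)
    clock_onset_years: tuple[float, float] = (2.0, 6.0)
    tss_frac_drift: float = 0.63
    frac_open_sea_hyper: float = 0.2
    trajectory: str = "logistic"  # or "simulator"
    sim_cells: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_drift_islands <= 1:
            raise ConfigError("frac_drift_islands must be in [0, 1]")
        if min(self.n_islands, self.n_open_sea, self.n_ns, self.n_be, self.n_eac) < 0:
            raise ConfigError("counts must be >= 0")
        if self.trajectory not in ("logistic", "simulator"):
            raise ConfigError(f"unknown trajectory mode {self.trajectory!r}")


def _streams(config: CohortConfig) -> dict:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return dict(zip(_STREAMS, children))


@dataclass
class SynthManifest:
    probes: pd.DataFrame
    islands: pd.DataFrame
    drift_island_ids: list[str]
    clock_island_ids: list[str]
    clock_probe_ids: list[str]


@dataclass
class GroundTruth:
    drift_probe_ids: list[str]
    drift_island_ids: list[str]
    clock_probe_ids: list[str]
    dwell_time: pd.Series  # per sample, years


@dataclass
class CohortResult:
    matrix: MethylationMatrix  # beta scale, all tissues
    sheet: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# manifest


def _island_gene_region(rng, drifting: bool, tss_frac_drift: float) -> str:
    tss, body = (tss_frac_drift, 0.11) if drifting else (0.73, 0.10)
    u = rng.random()
    if u < tss:
        return "TSS200" if rng.random() < 0.5 else "TSS1500"
    return "body" if u < tss + body else "intergenic"


def generate_manifest(config: CohortConfig) -> SynthManifest:
    """Lay islands on synthetic chromosomes with flanking shore/shelf
    probes, isolated open-sea probes, and dedicated clock islands."""
    rng = np.random.default_rng(_streams(config)["manifest"])
    lo, hi = config.probes_per_island
    if lo < 1 or hi < lo:
        raise ConfigError("probes_per_island range must satisfy 1 <= lo <= hi")

    n_drift = round(config.frac_drift_islands * config.n_islands)
    drift_idx = set(rng.choice(config.n_islands, size=n_drift, replace=False).tolist())
    clock_sizes = []
    remaining = config.n_clock
    while remaining > 0:
        take = min(hi, remaining)
        clock_sizes.append(take)
        remaining -= take

    probe_rows = []
    island_rows = []
    drift_island_ids: list[str] = []
    clock_island_ids: list[str] = []
    clock_probe_ids: list[str] = []
    probe_counter = 0

    def new_probe_id():
        nonlocal probe_counter
        probe_counter += 1
        return f"cg{probe_counter:08d}"

    specs = [("isl", i, None) for i in range(config.n_islands)]
    specs += [("clk", i, n) for i, n in enumerate(clock_sizes)]
    islands_per_chrom = 50
    for k, (kind, i, forced_n) in enumerate(specs):
        chrom = f"chr{1 + k // islands_per_chrom}"
        start = 10_000 + (k % islands_per_chrom) * 20_000
        n_p = forced_n if forced_n is not None else int(rng.integers(lo, hi + 1))
        length = int(rng.integers(600, 1401))
        if 2 * n_p > length:
            raise ConfigError(
                f"island of {length} bp cannot hold {n_p} probes at >= 2 bp spacing"
            )
        end = start + length - 1
        island_id = f"{kind}_{i:04d}"
        island_rows.append({"island_id": island_id, "chrom": chrom, "start": start, "end": end})
        drifting = kind == "clk" or i in drift_idx
        if kind == "isl" and i in drift_idx:
            drift_island_ids.append(island_id)
        if kind == "clk":
            clock_island_ids.append(island_id)
        region = _island_gene_region(rng, drifting, config.tss_frac_drift)
        grid = np.arange(start, end + 1, 2)
        positions = np.sort(rng.choice(grid, size=n_p, replace=False))
        for pos in positions:
            pid = new_probe_id()
            if kind == "clk":
                clock_probe_ids.append(pid)
            probe_rows.append(
                {
                    "probe_id": pid,
                    "chrom": chrom,
                    "pos": int(pos),
                    "island_id": island_id,
                    "relation": "island",
                    "gene_region": region,
                }
            )
        # one shore and one shelf probe per flank, carrying the island id
        for side in (-1, +1):
            anchor = start if side < 0 else end
            for relation, (d_lo, d_hi) in (("shore", (1, 2000)), ("shelf", (2001, 4000))):
                pos = anchor + side * int(rng.integers(d_lo, d_hi + 1))
                probe_rows.append(
                    {
                        "probe_id": new_probe_id(),
                        "chrom": chrom,
                        "pos": max(1, pos),
                        "island_id": island_id,
                        "relation": relation,
                        "gene_region": region,
                    }
                )
    for j in range(config.n_open_sea):
        probe_rows.append(
            {
                "probe_id": new_probe_id(),
                "chrom": "chr99",
                "pos": 10_000 + j * 10_000,
                "island_id": None,
                "relation": "open_sea",
                "gene_region": "intergenic" if rng.random() < 0.8 else "body",
            }
        )
    probes = pd.DataFrame(probe_rows)
    islands = pd.DataFrame(island_rows)
    islands["size_bp"] = islands["end"] - islands["start"] + 1
    islands = islands.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return SynthManifest(
        probes=probes,
        islands=islands,
        drift_island_ids=sorted(drift_island_ids),
        clock_island_ids=clock_island_ids,
        clock_probe_ids=clock_probe_ids,
    )


# ---------------------------------------------------------------------------
# latent drift model shared by cohort / longitudinal generators


@dataclass
class _DriftModel:
    baseline: pd.Series  # per-probe NS-level mean beta
    plateau: pd.Series  # per drift probe
    onset: dict  # island_id -> onset year t0
    rate_per_year: float
    drift_probe_island: pd.Series  # drift probe -> island_id (clock incl.)
    sim_traj: dict = field(default_factory=dict)  # island_id -> per-step per-cpg beta
    sim_probe_col: dict = field(default_factory=dict)  # probe -> cpg index

    def mean_beta(self, tau: np.ndarray, probe_ids: pd.Index) -> np.ndarray:
        """True mean beta, probes x samples, at latent dwell times tau."""
        mu = np.tile(self.baseline.loc[probe_ids].to_numpy()[:, None], (1, len(tau)))
        drift_ids = probe_ids.intersection(self.drift_probe_island.index)
        loc = probe_ids.get_indexer(drift_ids)
        if self.sim_traj:
            steps = np.round(np.asarray(tau) * STEPS_PER_YEAR).astype(int)
            for row, pid in zip(loc, drift_ids):
                traj = self.sim_traj[self.drift_probe_island.loc[pid]]
                col = self.sim_probe_col[pid]
                mu[row] = traj[np.minimum(steps, len(traj) - 1), col]
        else:
            b = self.baseline.loc[drift_ids].to_numpy()
            plateau = self.plateau.loc[drift_ids].to_numpy()
            t0 = self.drift_probe_island.loc[drift_ids].map(self.onset).to_numpy(dtype=float)
            k = self.rate_per_year
            gain = expit(k * (np.asarray(tau)[None, :] - t0[:, None])) - expit(-k * t0)[:, None]
            mu[loc] = b[:, None] + (plateau - b)[:, None] * gain
        return np.clip(mu, 1e-4, 1 - 1e-4)


def _build_model(man: SynthManifest, config: CohortConfig) -> _DriftModel:
    rng = np.random.default_rng(_streams(config)["model"])
    probes = man.probes
    n = len(probes)
    m, c = config.ns_baseline_beta_mean, config.baseline_concentration
    baseline = pd.Series(rng.beta(m * c, (1 - m) * c, size=n), index=probes["probe_id"])
    # a slice of open-sea probes is hypermethylated in normal tissue, so the
    # hypo/hyper NS split has both sides populated
    open_sea = probes.index[probes["relation"] == "open_sea"]
    n_hyper = int(round(config.frac_open_sea_hyper * len(open_sea)))
    if n_hyper:
        hyper_pos = rng.choice(len(open_sea), size=n_hyper, replace=False)
        hyper_ids = probes.loc[open_sea[hyper_pos], "probe_id"]
        baseline.loc[hyper_ids] = rng.beta(0.85 * c, 0.15 * c, size=n_hyper)

    drifting_islands = list(man.drift_island_ids) + list(man.clock_island_ids)
    onset = {}
    for isl in drifting_islands:
        lo, hi = (
            config.clock_onset_years if isl in set(man.clock_island_ids) else config.onset_years
        )
        onset[isl] = float(rng.uniform(lo, hi))
    mask = probes["island_id"].isin(drifting_islands) & (probes["relation"] == "island")
    drift_probe_island = probes.loc[mask].set_index("probe_id")["island_id"]
    plateau = pd.Series(
        config.drift_plateau + rng.uniform(-0.05, 0.05, size=mask.sum()),
        index=drift_probe_island.index,
    )
    model = _DriftModel(
        baseline=baseline,
        plateau=plateau,
        onset=onset,
        rate_per_year=config.drift_rate_per_year,
        drift_probe_island=drift_probe_island,
    )
    if config.trajectory == "simulator":
        max_years = max(config.dwell_time_be[1], config.dwell_time_eac[1], 1.0)
        n_steps = math.ceil(max_years * STEPS_PER_YEAR)
        for isl in drifting_islands:
            pids = drift_probe_island.index[drift_probe_island == isl]
            sim_cfg = simulator.SimConfig(
                n_cpgs=len(pids),
                n_cells=config.sim_cells,
                n_steps=n_steps,
                record_every=1,
                init_p=config.ns_baseline_beta_mean,
                seed=int(rng.integers(2**31)),
            )
            model.sim_traj[isl] = simulator.run(sim_cfg).per_cpg_beta
            model.sim_probe_col.update({pid: j for j, pid in enumerate(pids)})
    return model


def _observe(mu: np.ndarray, config: CohortConfig, rng) -> np.ndarray:
    """Array measurement noise: beta-distributed around the true mean with
    concentration ``noise_precision`` (None or inf = noise-free)."""
    kappa = config.noise_precision
    if kappa is None or not np.isfinite(kappa):
        return mu
    return rng.beta(mu * kappa, (1 - mu) * kappa)


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(man: SynthManifest, config: CohortConfig) -> CohortResult:
    """NS / BE / EAC beta matrix + sample sheet + ground truth."""
    model = _build_model(man, config)
    rng = np.random.default_rng(_streams(config)["cohort"])
    probe_ids = pd.Index(man.probes["probe_id"])

    sample_ids, tissues, taus = [], [], []
    for tissue, count, dwell in (
        ("NS", config.n_ns, (0.0, 0.0)),
        ("BE", config.n_be, config.dwell_time_be),
        ("EAC", config.n_eac, config.dwell_time_eac),
    ):
        for i in range(count):
            sample_ids.append(f"{tissue}_{i + 1:03d}")
            tissues.append(tissue)
            taus.append(float(rng.uniform(*dwell)))
    taus = np.asarray(taus)

    mu = model.mean_beta(taus, probe_ids)
    beta = _observe(mu, config, rng)
    matrix = MethylationMatrix(
        pd.DataFrame(beta, index=probe_ids.rename("probe_id"), columns=sample_ids), scale="beta"
    )

    eac_taus = taus[np.asarray(tissues) == "EAC"]
    eac_median = float(np.median(eac_taus)) if len(eac_taus) else 0.0
    rows = []
    for sid, tissue, tau in zip(sample_ids, tissues, taus):
        if tissue == "NS":
            age = float(rng.uniform(40, 80))
            stage = "unknown"
        else:
            age = 40 + tau + float(rng.uniform(0, 20))
            stage = "unknown"
        if tissue == "EAC":
            # advanced drift enriches for low stage (down-staging coupling)
            probs = (
                [0.60, 0.15, 0.15, 0.10] if tau > eac_median else [0.20, 0.20, 0.35, 0.25]
            )
            stage = rng.choice(["I", "II", "III", "IV"], p=probs)
        rows.append(
            {
                "sample_id": sid,
                "patient_id": f"P{len(rows) + 1:04d}",
                "tissue": tissue,
                "age_years": round(age, 1),
                "dx": {"NS": "normal", "BE": "BE non-dysplastic", "EAC": "EAC"}[tissue],
                "stage": stage,
            }
        )
    sheet = validate_sample_sheet(pd.DataFrame(rows))
    truth = GroundTruth(
        drift_probe_ids=sorted(
            set(model.drift_probe_island.index) - set(man.clock_probe_ids)
        ),
        drift_island_ids=list(man.drift_island_ids),
        clock_probe_ids=list(man.clock_probe_ids),
        dwell_time=pd.Series(taus, index=sample_ids, name="dwell_time"),
    )
    return CohortResult(matrix=matrix, sheet=sheet, truth=truth)


# ---------------------------------------------------------------------------
# longitudinal pairs


def generate_longitudinal(
    man: SynthManifest,
    config: CohortConfig,
    n_patients: int = 20,
    gap_years: float = 4.0,
) -> dict:
    """Paired biopsies continuing one latent drift trajectory per patient.

    Returns ``{"matrix_t1", "matrix_t2", "pairs", "truth"}`` where pairs
    holds patient_id, age1, age2 and the latent dwell time at first biopsy.
    Sample ids are shared between the two matrices (column i of t2 is the
    same patient as column i of t1).
    """
    if gap_years < 0:
        raise ConfigError("gap_years must be >= 0")
    model = _build_model(man, config)
    rng = np.random.default_rng(_streams(config)["longitudinal"])
    probe_ids = pd.Index(man.probes["probe_id"])
    dwell1 = rng.uniform(*config.dwell_time_longitudinal, size=n_patients)
    age1 = 45 + dwell1 + rng.uniform(0, 15, size=n_patients)
    ids = [f"L{i + 1:03d}" for i in range(n_patients)]

    mu1 = model.mean_beta(dwell1, probe_ids)
    mu2 = model.mean_beta(dwell1 + gap_years, probe_ids)
    beta1 = _observe(mu1, config, rng)
    beta2 = _observe(mu2, config, rng)
    m1 = MethylationMatrix(pd.DataFrame(beta1, index=probe_ids.rename("probe_id"), columns=ids))
    m2 = MethylationMatrix(pd.DataFrame(beta2, index=probe_ids.rename("probe_id"), columns=ids))
    pairs = pd.DataFrame(
        {
            "patient_id": ids,
            "age1": np.round(age1, 1),
            "age2": np.round(age1 + gap_years, 1),
            "dwell1": dwell1,
        }
    )
    truth = GroundTruth(
        drift_probe_ids=sorted(set(model.drift_probe_island.index) - set(man.clock_probe_ids)),
        drift_island_ids=list(man.drift_island_ids),
        clock_probe_ids=list(man.clock_probe_ids),
        dwell_time=pd.Series(dwell1, index=ids, name="dwell_time"),
    )
    return {"matrix_t1": m1, "matrix_t2": m2, "pairs": pairs, "truth": truth}


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    man: SynthManifest,
    config: CohortConfig,
    island_means: pd.DataFrame,
    n_repressed: int = 50,
    n_overexpressed: int = 5,
    n_null: int = 200,
    effect_size: float = 2.0,
    threshold: float = 0.2,
) -> dict:
    """Expression matrix with threshold-repression coupling.

    Genes mapped to repressed drift islands are shifted down by
    ``effect_size`` (log2 units) in samples whose island mean beta is at or
    above ``threshold``; a smaller overexpressed set is shifted up; null
    genes (mapped to static islands) are exchangeable across samples.

    Returns ``{"expr", "map", "gene_truth"}``.
    """
    if effect_size < 0:
        raise ConfigError("effect_size must be >= 0")
    rng = np.random.default_rng(_streams(config)["expression"])
    samples = list(island_means.columns)
    drift_islands = [i for i in man.drift_island_ids if i in island_means.index]
    static_islands = [
        i
        for i in man.islands["island_id"]
        if i not in set(man.drift_island_ids) and i not in set(man.clock_island_ids)
    ]
    if not drift_islands and (n_repressed or n_overexpressed):
        raise ConfigError("no drift islands available to couple genes to")

    rows, map_rows, truth_rows = [], [], []

    def add_gene(gene_id, island_id, effect):
        base = rng.normal(8.0, 1.0, size=len(samples))
        if effect != "null" and island_id in island_means.index:
            high = island_means.loc[island_id, samples].to_numpy() >= threshold
            shift = -effect_size if effect == "repressed" else effect_size
            base = base + shift * high
        rows.append(pd.Series(base, index=samples, name=gene_id))
        map_rows.append({"gene_id": gene_id, "island_id": island_id})
        truth_rows.append({"gene_id": gene_id, "island_id": island_id, "effect": effect})

    for g in range(n_repressed):
        add_gene(f"gene_R{g + 1:03d}", drift_islands[g % len(drift_islands)], "repressed")
    for g in range(n_overexpressed):
        add_gene(f"gene_O{g + 1:03d}", drift_islands[g % len(drift_islands)], "overexpressed")
    if n_null and not static_islands:
        raise ConfigError("no static islands available for null genes")
    for g in range(n_null):
        add_gene(f"gene_N{g + 1:03d}", static_islands[g % len(static_islands)], "null")

    expr = pd.DataFrame(rows)
    expr.index.name = "gene_id"
    return {
        "expr": expr,
        "map": pd.DataFrame(map_rows),
        "gene_truth": pd.DataFrame(truth_rows),
    }
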