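"""Core data types, tabular readers/writers and the beta/M transforms.

Methylation arrays report, per CpG probe and sample, a *beta value*: the
fraction of methylated alleles across the cells assayed, ``beta = M/(M+U)``.
Statistical analyses are often better behaved on the logit scale, the
*M value* ``M = log2(beta/(1-beta))``.  Both scales are supported; the
:class:`MethylationMatrix` container carries an explicit scale flag.

Coordinate convention: manifest positions are 1-based inclusive; genomic
distance between probes is ``|pos_a - pos_b|``.  BED export converts to
0-based half-open at write time only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RELATIONS = ("island", "shore", "shelf", "open_sea")
GENE_REGIONS = ("TSS200", "TSS1500", "body", "intergenic")
TISSUES = ("NS", "BE", "EAC", "other")
STAGES = ("I", "II", "III", "IV", "unknown")

#: sentinel used in TSV files for a null island_id
NULL_TOKEN = "."

PROBE_COLUMNS = ["probe_id", "chrom", "pos", "island_id", "relation", "gene_region"]
ISLAND_COLUMNS = ["island_id", "chrom", "start", "end"]
SHEET_COLUMNS = ["sample_id", "patient_id", "tissue", "age_years", "dx", "stage"]


class DomainError(ValueError):
    """Raised when a value violates a domain precondition."""


class ConfigError(ValueError):
    """Raised for invalid configuration parameters."""


# ---------------------------------------------------------------------------
# beta <-> M transforms


def beta_to_m(beta, eps: float = 1e-6):
    """logit2 transform of a beta value, with epsilon clamping at 0 and 1.

    Parameters
    ----------
    beta : float or array-like, values in [0, 1] (NaN passes through)
    eps : clamp applied before the logit so M values stay bounded;
        must satisfy 0 < eps < 0.5.
    """
    if not 0 < eps < 0.5:
        raise ConfigError(f"eps must be in (0, 0.5), got {eps}")
    b = np.asarray(beta, dtype=float)
    finite = np.isfinite(b)
    if np.any((b[finite] < 0) | (b[finite] > 1)):
        raise DomainError("beta values must lie in [0, 1]")
    clamped = np.clip(b, eps, 1.0 - eps)
    m = np.log2(clamped / (1.0 - clamped))
    m = np.where(finite, m, np.nan)
    return m if m.ndim else float(m)


def m_to_beta(m):
    """Inverse logit2: ``beta = 2**m / (1 + 2**m)``, numerically stable."""
    arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(arr) | np.isnan(arr)):
        raise DomainError("M values must be finite")
    # stable on both tails: never exponentiate a large positive argument
    with np.errstate(over="ignore"):
        pos = 1.0 / (1.0 + np.exp2(-np.abs(arr)))
    beta = np.where(arr >= 0, pos, 1.0 - pos)
    beta = np.where(np.isnan(arr), np.nan, beta)
    return beta if beta.ndim else float(beta)


# ---------------------------------------------------------------------------
# containers


@dataclass
class MethylationMatrix:
    """Probe x sample methylation values on an explicit scale.

    ``values`` is a DataFrame indexed by probe_id with one column per
    sample; missing entries are NaN and propagate (analyses drop them
    pairwise and report how many pairs were lost).
    """

    values: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "m"):
            raise ConfigError(f"scale must be 'beta' or 'm', got {self.scale!r}")
        if self.values.shape[1] < 1:
            raise DomainError("matrix must have at least one sample")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DomainError(f"duplicate probe ids: {list(dups[:5])}")
        self.values = self.values.astype(float)
        if self.scale == "beta":
            vals = self.values.to_numpy()
            bad = np.isfinite(vals) & ((vals < 0) | (vals > 1))
            if bad.any():
                raise DomainError("beta values outside [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_m(self, eps: float = 1e-6) -> "MethylationMatrix":
        if self.scale == "m":
            return self
        m = pd.DataFrame(
            beta_to_m(self.values.to_numpy(), eps=eps),
            index=self.values.index,
            columns=self.values.columns,
        )
        return MethylationMatrix(m, scale="m")

    def to_beta(self) -> "MethylationMatrix":
        if self.scale == "beta":
            return self
        b = pd.DataFrame(
            m_to_beta(self.values.to_numpy()),
            index=self.values.index,
            columns=self.values.columns,
        )
        return MethylationMatrix(b, scale="beta")


@dataclass
class ClockSet:
    """Ordered reference set of clock CpG probes (canonically 67)."""

    probe_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.probe_ids) == 0:
            raise DomainError("clock set must be non-empty")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise DomainError("clock set contains duplicate probe ids")

    def validate_against(self, probes: pd.DataFrame) -> None:
        missing = sorted(set(self.probe_ids) - set(probes["probe_id"]))
        if missing:
            raise DomainError(f"clock probes absent from manifest: {missing[:10]}")


# ---------------------------------------------------------------------------
# manifest I/O


def _validate_probes(probes: pd.DataFrame, islands: pd.DataFrame) -> pd.DataFrame:
    if probes["probe_id"].duplicated().any():
        dup = probes.loc[probes["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise DomainError(f"duplicate probe id: {dup}")
    if (probes["pos"] < 1).any():
        raise DomainError("probe positions must be >= 1")
    bad_rel = set(probes["relation"]) - set(RELATIONS)
    if bad_rel:
        raise DomainError(f"unknown relation token(s): {sorted(bad_rel)}")
    bad_reg = set(probes["gene_region"]) - set(GENE_REGIONS)
    if bad_reg:
        raise DomainError(f"unknown gene_region token(s): {sorted(bad_reg)}")
    declared = set(islands["island_id"])
    referenced = set(probes["island_id"].dropna())
    undeclared = referenced - declared
    if undeclared:
        raise DomainError(f"probes reference undeclared islands: {sorted(undeclared)[:10]}")
    return probes


def _validate_islands(islands: pd.DataFrame) -> pd.DataFrame:
    if islands["island_id"].duplicated().any():
        raise DomainError("duplicate island id in island table")
    if (islands["start"] > islands["end"]).any():
        raise DomainError("island start > end")
    islands = islands.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    islands["size_bp"] = islands["end"] - islands["start"] + 1
    return islands


def read_manifest(probes_path, islands_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read probe + island annotation TSVs.

    Returns ``(probes, islands)``: probes with columns
    ``probe_id chrom pos island_id relation gene_region`` (island_id NaN for
    probes with no associated island; shores/shelves carry the id of the
    island they flank), islands sorted by (chrom, start) with ``size_bp``.
    """
    probes = pd.read_csv(probes_path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = set(PROBE_COLUMNS) - set(probes.columns)
    if missing:
        raise DomainError(f"manifest missing columns: {sorted(missing)}")
    if not np.issubdtype(probes["pos"].dtype, np.number):
        raise DomainError("malformed probe coordinates")
    probes["island_id"] = probes["island_id"].mask(probes["island_id"] == NULL_TOKEN)
    islands = pd.read_csv(islands_path, sep="\t", dtype={"island_id": str, "chrom": str})
    if set(ISLAND_COLUMNS) - set(islands.columns):
        raise DomainError("island table missing columns")
    islands = _validate_islands(islands)
    probes = _validate_probes(probes, islands)
    return probes, islands


def write_manifest(probes: pd.DataFrame, islands: pd.DataFrame, probes_path, islands_path) -> None:
    out = probes[PROBE_COLUMNS].copy()
    out["island_id"] = out["island_id"].fillna(NULL_TOKEN)
    out.to_csv(probes_path, sep="\t", index=False)
    islands[ISLAND_COLUMNS].to_csv(islands_path, sep="\t", index=False)


def islands_to_bed(islands: pd.DataFrame, path) -> None:
    """Export island records as BED (0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": islands["chrom"],
            "start": islands["start"] - 1,
            "end": islands["end"],
            "name": islands["island_id"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# matrix / sample sheet / clock I/O


def read_methylation_matrix(path, scale: str = "beta") -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise DomainError("matrix must have at least one sample column")
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return MethylationMatrix(df, scale=scale)


def write_methylation_matrix(matrix: MethylationMatrix, path, decimals: int = 6) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=f"%.{decimals}f", index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise DomainError(f"sample sheet missing columns: {sorted(missing)}")
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    if sheet["sample_id"].duplicated().any():
        raise DomainError("duplicate sample id in sheet")
    bad = set(sheet["tissue"]) - set(TISSUES)
    if bad:
        raise DomainError(f"unknown tissue token(s): {sorted(bad)}")
    bad = set(sheet["stage"].dropna()) - set(STAGES)
    if bad:
        raise DomainError(f"unknown stage token(s): {sorted(bad)}")
    ages = pd.to_numeric(sheet["age_years"], errors="raise")
    if (ages.dropna() <= 0).any():
        raise DomainError("age_years must be > 0 when present")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clock(path) -> ClockSet:
    """Read a clock-probe list: one probe id per line (comments with #)."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line.split()[0])
    return ClockSet(ids)
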