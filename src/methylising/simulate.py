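"""WGBS read simulator with Ising ground truth.

The synthetic genome is a chain of isolated CpG islands: each island is 3 kb
with 200 uniformly spaced CpG sites (15-bp spacing), islands are separated
by 100-kb CpG-free gaps. Reads of fixed length are placed uniformly at
random over the genome at a chosen mean coverage; each read overlapping an
island draws its own complete latent methylation state of that island from
the island's Ising model (a read is one cell's molecule, so within-read
correlation carries the coupling signal) and reports the exact states of the
CpG sites it covers. No bisulfite-conversion or sequencing errors are
modeled. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ising import RegionModel, sample_states
from .layout import CpGLayout, RegionPartition, partition

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_layout",
    "simulate_reads",
    "label_truth",
    "island_model",
]


@dataclass
class SimulationConfig:
    """Synthetic design; defaults are the desk-scale study conditions
    (50 islands instead of the full-scale 5000)."""

    n_islands: int = 50
    island_len: int = 3000
    cpgs_per_island: int = 200
    gap: int = 100_000
    read_len: int = 300
    coverage: float = 15.0
    a: float = 0.0  # uniform per-site field within each island
    c: float = 0.0  # uniform nearest-neighbor coupling
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.island_len // self.cpgs_per_island < 2:
            raise ValueError("CpG spacing must be at least 2 bp")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.gap < self.read_len:
            raise ValueError("islands must be isolated: gap must be >= read_len")

    @property
    def spacing(self) -> int:
        return self.island_len // self.cpgs_per_island

    @property
    def island_starts(self) -> np.ndarray:
        """1-based start coordinate of each island."""
        return 1 + np.arange(self.n_islands, dtype=np.int64) * (self.island_len + self.gap)

    @property
    def genome_length(self) -> int:
        return self.n_islands * (self.island_len + self.gap)


@dataclass
class GroundTruth:
    """Per-island differential/null labels for a test/reference design."""

    labels: np.ndarray  # bool per island: True = differential
    island_intervals: np.ndarray  # (n, 2) 0-based half-open bp


def simulate_layout(config: SimulationConfig) -> tuple[CpGLayout, RegionPartition]:
    """Deterministic CpG layout and region/GU partition of the synthetic
    genome; interior island sites have density 0.067 at 15-bp spacing."""
    offsets = np.arange(config.cpgs_per_island, dtype=np.int64) * config.spacing
    positions = (config.island_starts[:, None] + offsets[None, :]).ravel()
    layout = CpGLayout.from_positions(config.chrom, positions)
    part = partition(config.genome_length, layout)
    return layout, part


def island_model(config: SimulationConfig, a: float | None = None, c: float | None = None) -> RegionModel:
    """Ising model of one island (uniform spacing makes all islands share it)."""
    R = config.cpgs_per_island
    av = a if a is not None else config.a
    cv = c if c is not None else config.c
    return RegionModel(a=np.full(R, float(av)), c=np.full(R - 1, float(cv)))


def simulate_reads(
    config: SimulationConfig,
    a: float | None = None,
    c: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one sample; returns the observation table with columns
    chrom, read_id, cpg_pos, state (one row per read x covered CpG site).

    Read count is ceil(coverage * genome_length / read_len); reads that fall
    entirely within CpG-free gaps contribute no rows.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    model = island_model(config, a, c)
    n_reads = int(np.ceil(config.coverage * config.genome_length / config.read_len))
    # 1-based read start positions, read covers [start, start + read_len - 1]
    starts = rng.integers(1, config.genome_length - config.read_len + 2, size=n_reads)
    period = config.island_len + config.gap
    within = (starts - 1) % period
    # a read touches the island of its own period if it starts inside it, and
    # the next island when its tail crosses the period boundary (possible
    # whenever read_len > 1; each case draws that island's own latent state)
    own = within < config.island_len
    island_of_read = np.where(own, (starts - 1) // period, (starts - 1) // period + 1)
    reaches_next = ~own & (within + config.read_len > period)
    touches = own | reaches_next
    touches &= island_of_read < config.n_islands
    site_pos = np.arange(config.cpgs_per_island, dtype=np.int64) * config.spacing
    ids: list[np.ndarray] = []
    pos: list[np.ndarray] = []
    val: list[np.ndarray] = []
    for isl in np.unique(island_of_read[touches]):
        sel = np.flatnonzero(touches & (island_of_read == isl))
        states = sample_states(model, len(sel), rng)
        isl_start = 1 + int(isl) * period
        rel = starts[sel] - isl_start  # read-start offset within island (can be < 0)
        lo = np.searchsorted(site_pos, rel)
        hi = np.searchsorted(site_pos, rel + config.read_len, side="left")
        for row in range(len(sel)):
            if hi[row] <= lo[row]:
                continue
            n = hi[row] - lo[row]
            ids.append(np.full(n, sel[row], dtype=np.int64))
            pos.append(isl_start + site_pos[lo[row]:hi[row]])
            val.append(states[row, lo[row]:hi[row]].astype(np.int64))
    if not ids:
        return pd.DataFrame(columns=["chrom", "read_id", "cpg_pos", "state"])
    df = pd.DataFrame(
        {
            "chrom": config.chrom,
            "read_id": np.concatenate(ids),
            "cpg_pos": np.concatenate(pos),
            "state": np.concatenate(val),
        }
    )
    df = df.sort_values(["read_id", "cpg_pos"], kind="stable").reset_index(drop=True)
    df["read_id"] = "r" + df["read_id"].astype(str)
    return df


def label_truth(
    config: SimulationConfig, c_test: float, c_ref: float
) -> GroundTruth:
    """An island is differential iff the test and reference couplings differ
    (with a = 0 in both, marginal means are 0.5 everywhere regardless)."""
    diff = bool(c_test != c_ref)
    starts0 = config.island_starts - 1
    intervals = np.stack([starts0, starts0 + config.island_len], axis=1)
    return GroundTruth(
        labels=np.full(config.n_islands, diff, dtype=bool),
        island_intervals=intervals,
    )
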