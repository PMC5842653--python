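"""CpG layout of a genome: positions, densities, distances, and the region/GU tiling.

All CpG coordinates are 1-based positions of the C in a CG dinucleotide
(a CpG is palindromic; one site per dinucleotide, no strand handling).
Genomic intervals (estimation regions, genomic units, emitted tracks) are
0-based half-open, the bedGraph convention.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CpGLayout",
    "RegionPartition",
    "scan_cpg_sites",
    "compute_density",
    "compute_distances",
    "partition",
    "layouts_from_fasta",
    "read_layout_tsv",
    "write_layout_tsv",
]


def scan_cpg_sites(sequence: str) -> np.ndarray:
    """1-based positions of the C of every CG dinucleotide, in order.

    Case-insensitive; N (or any non-ACGT letter) never forms a CpG.
    """
    if len(sequence) < 2:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    hits = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.flatnonzero(hits).astype(np.int64) + 1


def compute_density(positions: np.ndarray, window_halfwidth: int = 500) -> np.ndarray:
    """Per-site CpG density rho_n: CpG count within +/- window_halfwidth bp
    (site n included), divided by the full window width (2*halfwidth bp).

    Self-inclusion keeps rho strictly positive, so the density term of the
    parameterization is well-behaved at isolated sites.
    """
    pos = np.asarray(positions, dtype=np.int64)
    lo = np.searchsorted(pos, pos - window_halfwidth, side="left")
    hi = np.searchsorted(pos, pos + window_halfwidth, side="right")
    return (hi - lo) / (2.0 * window_halfwidth)


def compute_distances(positions: np.ndarray) -> np.ndarray:
    """Distances d_n = pos_n - pos_{n-1} in bp, defined for n >= 2 (length N-1).

    Raises ValueError on unsorted (non strictly increasing) input.
    """
    pos = np.asarray(positions, dtype=np.int64)
    d = np.diff(pos)
    if np.any(d <= 0):
        raise ValueError("CpG positions must be strictly increasing")
    return d


@dataclass
class CpGLayout:
    """Ordered CpG sites of one chromosome with density and distance covariates."""

    chrom: str
    positions: np.ndarray  # 1-based, strictly increasing
    rho: np.ndarray  # per-site density, > 0
    dist: np.ndarray  # length N-1; dist[i] = positions[i+1] - positions[i]

    @classmethod
    def from_positions(cls, chrom: str, positions: np.ndarray) -> "CpGLayout":
        pos = np.asarray(positions, dtype=np.int64)
        dist = compute_distances(pos) if len(pos) >= 2 else np.empty(0, dtype=np.int64)
        return cls(chrom=chrom, positions=pos, rho=compute_density(pos), dist=dist)

    @classmethod
    def from_sequence(cls, chrom: str, sequence: str) -> "CpGLayout":
        return cls.from_positions(chrom, scan_cpg_sites(sequence))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class RegionPartition:
    """Tiling of a chromosome into estimation regions and nested genomic units (GUs).

    Regions tile from coordinate 1; the trailing partial region is kept.
    ``regions``/``gus`` are 0-based half-open (start, end) intervals; because
    gu_size divides region_size and both tilings anchor at 1, a GU never
    straddles a region boundary.
    """

    chrom_length: int
    region_size: int
    gu_size: int
    regions: np.ndarray  # (n_regions, 2)
    gus: np.ndarray  # (n_gus, 2)
    cpg_region: np.ndarray = field(repr=False)  # per CpG site, region index
    cpg_gu: np.ndarray = field(repr=False)  # per CpG site, global GU index
    _region_bounds: np.ndarray = field(repr=False)  # searchsorted CpG-index bounds
    _gu_bounds: np.ndarray = field(repr=False)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_gus(self) -> int:
        return len(self.gus)

    @property
    def gus_per_region(self) -> int:
        return self.region_size // self.gu_size

    def region_sites(self, r: int) -> tuple[int, int]:
        """Half-open range [lo, hi) of CpG indices contained in region r."""
        return int(self._region_bounds[r]), int(self._region_bounds[r + 1])

    def gu_sites(self, g: int) -> tuple[int, int]:
        """Half-open range [lo, hi) of CpG indices contained in GU g."""
        return int(self._gu_bounds[g]), int(self._gu_bounds[g + 1])

    def gus_of_region(self, r: int) -> range:
        """Global GU indices tiling region r."""
        start, end = self.regions[r]
        g0 = int(start) // self.gu_size
        g1 = -(-int(end) // self.gu_size)  # ceil
        return range(g0, g1)

    def region_of_gu(self, g: int) -> int:
        return int(self.gus[g, 0]) // self.region_size


def _tile(length: int, size: int) -> np.ndarray:
    n = -(-length // size)
    starts = np.arange(n, dtype=np.int64) * size
    ends = np.minimum(starts + size, length)
    return np.stack([starts, ends], axis=1)


def partition(
    chrom_length: int,
    layout: CpGLayout,
    region_size: int = 3000,
    gu_size: int = 150,
) -> RegionPartition:
    """Tile the chromosome into estimation regions (default 3 kb) and GUs
    (default 150 bp) and assign every CpG site to exactly one of each.
    """
    if region_size % gu_size != 0:
        raise ValueError("region_size must be divisible by gu_size")
    if len(layout.positions) and layout.positions[-1] > chrom_length:
        raise ValueError("CpG position beyond chromosome length")
    regions = _tile(chrom_length, region_size)
    gus = _tile(chrom_length, gu_size)
    idx0 = layout.positions - 1  # 0-based
    cpg_region = idx0 // region_size
    cpg_gu = idx0 // gu_size
    region_bounds = np.searchsorted(cpg_region, np.arange(len(regions) + 1))
    gu_bounds = np.searchsorted(cpg_gu, np.arange(len(gus) + 1))
    return RegionPartition(
        chrom_length=chrom_length,
        region_size=region_size,
        gu_size=gu_size,
        regions=regions,
        gus=gus,
        cpg_region=cpg_region,
        cpg_gu=cpg_gu,
        _region_bounds=region_bounds,
        _gu_bounds=gu_bounds,
    )


def layouts_from_fasta(path: str | Path):
    """Yield (chrom, sequence length, CpGLayout) per record of a (possibly
    gzipped) multi-record FASTA file."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq)
            yield rec.id, len(seq), CpGLayout.from_sequence(rec.id, seq)


def write_layout_tsv(layouts: dict[str, CpGLayout], path: str | Path) -> None:
    """Persist layouts as TSV with columns chrom, pos, rho, dist (dist empty
    for the first site of each chromosome)."""
    frames = []
    for chrom, lay in layouts.items():
        dist = np.concatenate([[np.nan], lay.dist]) if len(lay) else lay.dist
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": lay.positions, "rho": lay.rho, "dist": dist}
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "rho", "dist"])
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_layout_tsv(path: str | Path) -> dict[str, CpGLayout]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, CpGLayout] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = CpGLayout.from_positions(
            str(chrom), sub["pos"].to_numpy(np.int64)
        )
    return out
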