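"""File formats: the observation TSV dialect, bedGraph/BED tracks, and the
fitted-model TSV.

Observation TSV: columns chrom, read_id, cpg_pos, state — one record per
read x CpG site, state in {0, 1}. Tracks are bedGraph4 (0-based half-open,
6-decimal values) and BED with textual class names; DMRs are BED6 with the
true score in column 7.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dmr import DMRCall
from .estimation import ObservationMatrix
from .layout import CpGLayout, RegionPartition

__all__ = [
    "ObservationError",
    "read_observation_tsv",
    "write_observation_tsv",
    "observations_by_region",
    "write_bedgraph",
    "read_bedgraph",
    "write_class_bed",
    "write_dmr_bed",
    "write_model_tsv",
    "read_model_tsv",
]


class ObservationError(ValueError):
    """Malformed observation record (carries the offending 1-based data line)."""


def read_observation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "read_id": str})
    missing = {"chrom", "read_id", "cpg_pos", "state"} - set(df.columns)
    if missing:
        raise ObservationError(f"missing columns: {sorted(missing)}")
    return df


def write_observation_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def observations_by_region(
    df: pd.DataFrame, layout: CpGLayout, part: RegionPartition
) -> dict[int, ObservationMatrix]:
    """Group observation records into per-region matrices.

    Reads spanning a region boundary are split at it (each fragment counts
    as one observation of its region). Unknown CpG positions, duplicate
    (read, site) pairs, and non-binary states raise ObservationError with
    the offending line number (1-based, header = line 1).
    """
    if df.empty:
        return {}
    states = df["state"].to_numpy()
    bad = ~np.isin(states, (0, 1))
    if bad.any():
        raise ObservationError(
            f"state not in {{0,1}} at line {int(np.flatnonzero(bad)[0]) + 2}"
        )
    pos = df["cpg_pos"].to_numpy(np.int64)
    n = len(layout.positions)
    idx = np.searchsorted(layout.positions, pos)
    bad = (idx >= n) | (layout.positions[np.minimum(idx, n - 1)] != pos)
    if bad.any():
        line = int(np.flatnonzero(bad)[0])
        raise ObservationError(f"unknown CpG position {pos[line]} at line {line + 2}")

    read_codes = pd.factorize(df["read_id"], sort=False)[0]
    order = np.lexsort((idx, read_codes))
    r, i, s = read_codes[order], idx[order], states.astype(np.int64)[order]
    if len(r) > 1:
        dup = (np.diff(r) == 0) & (np.diff(i) == 0)
        if dup.any():
            line = int(order[np.flatnonzero(dup)[0] + 1])
            raise ObservationError(f"duplicate (read, position) at line {line + 2}")
    region = part.cpg_region[i]
    new_read = np.concatenate([[True], np.diff(r) != 0])
    new_group = new_read | np.concatenate([[True], np.diff(region) != 0])
    new_run = new_group | np.concatenate([[True], np.diff(i) != 1])
    run_bounds = np.flatnonzero(new_run)
    run_ends = np.append(run_bounds[1:], len(r))

    per_region: dict[int, dict[str, list]] = {}
    for b, e in zip(run_bounds, run_ends):
        reg = int(region[b])
        acc = per_region.setdefault(
            reg, {"start": [], "off": [0], "vals": [], "n_reads": 0}
        )
        lo = int(part._region_bounds[reg])
        acc["start"].append(int(i[b]) - lo)
        acc["vals"].extend(int(x) for x in s[b:e])
        acc["off"].append(len(acc["vals"]))
        if new_group[b]:
            acc["n_reads"] += 1
    out = {}
    for reg, acc in per_region.items():
        lo, hi = part.region_sites(reg)
        out[reg] = ObservationMatrix(
            n_sites=hi - lo,
            n_reads=acc["n_reads"],
            run_start=acc["start"],
            run_off=acc["off"],
            run_vals=acc["vals"],
        )
    return out


def write_bedgraph(df: pd.DataFrame, path: str | Path, name: str = "track") -> None:
    """bedGraph4: track header then chrom/start/end/value lines (6 decimals).
    Records must be sorted and non-overlapping per chromosome."""
    _check_sorted(df)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.value:.6f}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, value = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _check_sorted(df: pd.DataFrame) -> None:
    for _, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
            raise ValueError("track records must be sorted and non-overlapping")


def write_class_bed(df: pd.DataFrame, path: str | Path) -> None:
    """BED with the class label in the name column."""
    _check_sorted(df)
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.label}\n")


def write_dmr_bed(calls: list[tuple[str, DMRCall]], path: str | Path) -> None:
    """DMRs as BED6+1: name = rank, score = sum-SQS capped at 1000 for BED,
    true score in column 7. Input is (chrom, call) pairs."""
    with open(path, "w") as fh:
        for chrom, d in sorted(calls, key=lambda cd: cd[1].rank):
            capped = int(min(round(d.score), 1000))
            fh.write(
                f"{chrom}\t{d.start}\t{d.end}\t{d.rank}\t{capped}\t.\t{d.score:.4f}\n"
            )


_MODEL_COLS = [
    "chrom",
    "region_start",
    "region_end",
    "alpha_p",
    "alpha",
    "alpha_pp",
    "beta",
    "gamma",
]


def write_model_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=_MODEL_COLS, float_format="%.8g")


def read_model_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_MODEL_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"model TSV missing columns: {sorted(missing)}")
    return df
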