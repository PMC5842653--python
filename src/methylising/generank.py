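"""Ranking epigenetically discordant genes from per-GU JSD.

Promoters are 4-kb windows centered at TSSs. Without replicate references a
promoter is scored by the mean JSD of its modeled GUs; with replicates, GU
p-values from the empirical JSD null (raw JSD, not sJSD) are combined per
promoter with Fisher's method. Rankings across several comparisons are
merged with rank products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import EmpiricalNull, empirical_null

__all__ = [
    "PromoterWindow",
    "promoter_windows",
    "score_avg_jsd",
    "gu_empirical_pvalues",
    "fisher_combine",
    "rank_product",
    "rank_promoters",
]

_P_FLOOR = 1e-300


@dataclass
class PromoterWindow:
    gene_id: str
    transcript_id: str
    chrom: str
    start: int  # 0-based half-open, width 4000 unless truncated at pos 0
    end: int
    gu_indices: np.ndarray  # global GU indices intersecting by >= 1 bp


def promoter_windows(
    tss: pd.DataFrame,
    gu_intervals: np.ndarray,
    gu_chroms: np.ndarray | None = None,
    half_width: int = 2000,
) -> list[PromoterWindow]:
    """Build [TSS - 2000, TSS + 2000) windows (strand-agnostic) and attach
    every GU intersecting by >= 1 bp.

    ``tss`` needs columns chrom, tss (0-based), gene, transcript; windows
    running past the chromosome start are truncated at 0.
    """
    iv = np.asarray(gu_intervals, dtype=np.int64)
    out: list[PromoterWindow] = []
    for row in tss.itertuples(index=False):
        start = int(row.tss) - half_width
        if start < 0:
            start = 0
        end = int(row.tss) + half_width
        if gu_chroms is not None:
            on_chrom = np.flatnonzero(np.asarray(gu_chroms) == row.chrom)
            sub = iv[on_chrom]
        else:
            on_chrom = np.arange(len(iv))
            sub = iv
        hit = (sub[:, 0] < end) & (sub[:, 1] > start)
        out.append(
            PromoterWindow(
                gene_id=str(row.gene),
                transcript_id=str(row.transcript),
                chrom=str(row.chrom),
                start=start,
                end=end,
                gu_indices=on_chrom[hit],
            )
        )
    return out


def score_avg_jsd(window: PromoterWindow, jsd_by_gu: dict[int, float]) -> float | None:
    """Mean JSD over the window's modeled GUs (missing GUs ignored); None if
    no GU in the window is modeled (the promoter is then unscored)."""
    vals = [jsd_by_gu[g] for g in window.gu_indices if g in jsd_by_gu]
    if not vals:
        return None
    return float(np.mean(vals))


def gu_empirical_pvalues(
    jsd: np.ndarray, replicate_pair_jsd: np.ndarray | EmpiricalNull
) -> np.ndarray:
    """Plus-one exceedance p-values of raw per-GU JSD against the pooled
    replicate-reference JSD null."""
    null = (
        replicate_pair_jsd
        if isinstance(replicate_pair_jsd, EmpiricalNull)
        else empirical_null(replicate_pair_jsd)
    )
    return np.asarray(null.pvalue(np.asarray(jsd, dtype=float)))


def fisher_combine(pvalues: np.ndarray) -> float:
    """Fisher's method: X = -2 sum ln p_i referred to chi-square with 2m
    degrees of freedom. Used as a ranking score (exact only under
    independence); p = 0 is clipped to 1e-300."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.maximum(p, _P_FLOOR)
    X = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(X, df=2 * len(p)))


def rank_product(rank_lists: list[dict[str, int]]) -> pd.DataFrame:
    """Combine per-comparison gene ranks by the rank product
    RP(g) = (prod_i r_i(g))^(1/k); genes missing from a list get rank
    (list length + 1). Ties break by mean rank, then gene id."""
    if not rank_lists or any(len(r) == 0 for r in rank_lists):
        raise ValueError("rank lists must be non-empty")
    genes = sorted(set().union(*rank_lists))
    rows = []
    for g in genes:
        ranks = [r.get(g, len(r) + 1) for r in rank_lists]
        rp = float(np.prod([float(x) for x in ranks]) ** (1.0 / len(ranks)))
        rows.append((g, rp, float(np.mean(ranks))))
    df = pd.DataFrame(rows, columns=["gene", "rank_product", "mean_rank"])
    df = df.sort_values(["rank_product", "mean_rank", "gene"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def rank_promoters(
    windows: list[PromoterWindow],
    jsd_by_gu: dict[int, float],
    replicate_pair_jsd: np.ndarray | None = None,
) -> pd.DataFrame:
    """Ranked gene table (gene, best_transcript, score, rank, method).

    Without replicates: score = mean JSD, higher = more discordant. With
    replicates: score = Fisher-combined empirical p-value, lower = more
    discordant. Per gene only its best-ranked promoter is kept; genes with
    no modeled GU in any promoter are omitted.
    """
    null = empirical_null(replicate_pair_jsd) if replicate_pair_jsd is not None else None
    rows = []
    for w in windows:
        gus = [g for g in w.gu_indices if g in jsd_by_gu]
        if not gus:
            continue
        vals = np.array([jsd_by_gu[g] for g in gus])
        if null is None:
            rows.append((w.gene_id, w.transcript_id, float(vals.mean()), "avg_jsd"))
        else:
            p = np.asarray(null.pvalue(vals))
            rows.append((w.gene_id, w.transcript_id, fisher_combine(p), "fisher"))
    if not rows:
        return pd.DataFrame(columns=["gene", "best_transcript", "score", "rank", "method"])
    df = pd.DataFrame(rows, columns=["gene", "best_transcript", "score", "method"])
    ascending = df["method"].iloc[0] == "fisher"
    df = df.sort_values("score", ascending=ascending, kind="stable")
    df = df.drop_duplicates("gene", keep="first").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[["gene", "best_transcript", "score", "rank", "method"]]
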