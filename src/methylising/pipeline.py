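"""Stage glue: per-sample region fitting, GU-level PMFs and statistics,
two-sample comparison, and DMR detection, all on one chromosome's layout.

The CLI and the acceptance/analysis scripts compose these; everything is
deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import differential as diff
from . import dmr as dmrmod
from . import single_sample as ss
from .config import PipelineConfig
from .estimation import (
    EstimationConfig,
    FitResult,
    ObservationMatrix,
    aic_compare,
    estimate_region_params,
    fit_general_ising,
    region_eligible,
)
from .ising import RegionModel, build_potentials, level_pmf
from .layout import CpGLayout, RegionPartition

__all__ = [
    "SampleFit",
    "estimation_config",
    "fit_sample",
    "models_from_fits",
    "models_from_table",
    "fit_table",
    "gu_level_pmfs",
    "single_sample_table",
    "differential_table",
    "attach_sjsd",
    "dmr_calls",
    "model_comparison_table",
]


@dataclass
class SampleFit:
    fits: dict[int, FitResult] = field(default_factory=dict)
    skips: list[tuple[int, str]] = field(default_factory=list)


def estimation_config(cfg: PipelineConfig) -> EstimationConfig:
    return EstimationConfig(
        budget=cfg.optimizer_budget,
        min_sites=cfg.min_cpgs,
        min_obs_fraction=cfg.min_obs_fraction,
        min_depth=cfg.min_depth,
    )


def fit_sample(
    layout: CpGLayout,
    part: RegionPartition,
    obs_map: dict[int, ObservationMatrix],
    config: PipelineConfig | None = None,
) -> SampleFit:
    """Fit every eligible region of one sample; ineligible or failing
    regions land in the skip log with their filter reason."""
    cfg = config or PipelineConfig()
    est = estimation_config(cfg)
    out = SampleFit()
    for r in range(part.n_regions):
        lo, hi = part.region_sites(r)
        n_sites = hi - lo
        obs = obs_map.get(r)
        if obs is None:
            if n_sites > 0:
                out.skips.append((r, "min_sites" if n_sites < est.min_sites else "coverage_fraction"))
            continue
        ok, reason = region_eligible(n_sites, obs, est)
        if not ok:
            out.skips.append((r, reason))
            continue
        fit = estimate_region_params(
            layout.rho[lo:hi], layout.positions[lo:hi], obs, est, seed=cfg.seed + r
        )
        if fit.ok:
            out.fits[r] = fit
        else:
            out.skips.append((r, fit.reason or "opt_fail"))
    return out


def models_from_fits(
    layout: CpGLayout, part: RegionPartition, sample: SampleFit
) -> dict[int, RegionModel]:
    models = {}
    for r, fit in sample.fits.items():
        lo, hi = part.region_sites(r)
        models[r] = build_potentials(
            tuple(fit.theta_hat), layout.rho[lo:hi], layout.positions[lo:hi]
        )
    return models


def fit_table(part: RegionPartition, chrom: str, sample: SampleFit) -> pd.DataFrame:
    """Fitted parameters as the persistable model table."""
    rows = []
    for r in sorted(sample.fits):
        t = sample.fits[r].theta_hat
        start, end = part.regions[r]
        rows.append((chrom, int(start), int(end), *[float(x) for x in t]))
    return pd.DataFrame(
        rows,
        columns=["chrom", "region_start", "region_end", "alpha_p", "alpha", "alpha_pp", "beta", "gamma"],
    )


def models_from_table(
    df: pd.DataFrame, layout: CpGLayout, part: RegionPartition, chrom: str
) -> dict[int, RegionModel]:
    models = {}
    for row in df[df["chrom"] == chrom].itertuples(index=False):
        r = int(row.region_start) // part.region_size
        lo, hi = part.region_sites(r)
        if hi <= lo:
            continue
        theta = (row.alpha_p, row.alpha, row.alpha_pp, row.beta, row.gamma)
        models[r] = build_potentials(theta, layout.rho[lo:hi], layout.positions[lo:hi])
    return models


def gu_level_pmfs(
    part: RegionPartition, models: dict[int, RegionModel]
) -> dict[int, np.ndarray]:
    """Level PMF of every CpG-containing GU of every modeled region,
    marginalizing the region's remaining sites exactly."""
    pmfs: dict[int, np.ndarray] = {}
    for r, model in models.items():
        rlo, _ = part.region_sites(r)
        for g in part.gus_of_region(r):
            glo, ghi = part.gu_sites(g)
            if ghi <= glo:
                continue  # CpG-free GU: track gap
            pmfs[g] = level_pmf(model, glo - rlo, ghi - rlo)
    return pmfs


def _gu_frame(part: RegionPartition, chrom: str, gus: list[int]) -> pd.DataFrame:
    iv = part.gus[gus]
    return pd.DataFrame(
        {"chrom": chrom, "gu": gus, "start": iv[:, 0], "end": iv[:, 1]}
    )


def single_sample_table(
    part: RegionPartition,
    chrom: str,
    pmfs: dict[int, np.ndarray],
    config: ss.ClassificationConfig | None = None,
) -> pd.DataFrame:
    """Per-GU MML, NME and classes for one sample."""
    gus = sorted(pmfs)
    df = _gu_frame(part, chrom, gus)
    df["mml"] = [ss.compute_mml(pmfs[g]) for g in gus]
    df["nme"] = [ss.compute_nme(pmfs[g]) for g in gus]
    df["level_class"] = [ss.classify_level(pmfs[g], config) for g in gus]
    df["entropy_class"] = [ss.classify_entropy(h, config) for h in df["nme"]]
    return df


def differential_table(
    part: RegionPartition,
    chrom: str,
    pmfs_t: dict[int, np.ndarray],
    pmfs_r: dict[int, np.ndarray],
    config: diff.DiffClassificationConfig | None = None,
    classify: bool = True,
) -> pd.DataFrame:
    """Per-GU dMML, dNME, JSD (and classes) over GUs modeled in both samples."""
    gus = sorted(set(pmfs_t) & set(pmfs_r))
    df = _gu_frame(part, chrom, gus)
    jsds, dmml, dnme, dml_cls, dnme_cls = [], [], [], [], []
    for g in gus:
        pt, pr = pmfs_t[g], pmfs_r[g]
        jsds.append(diff.jsd(pt, pr))
        dmml.append(ss.compute_mml(pt) - ss.compute_mml(pr))
        dh = ss.compute_nme(pt) - ss.compute_nme(pr)
        dnme.append(dh)
        if classify:
            dl = diff.diff_level_pmf(pt, pr)
            dml_cls.append(diff.classify_diff_level(dl, config))
            dnme_cls.append(diff.classify_diff_entropy(dh, config))
    df["jsd"] = jsds
    df["dmml"] = dmml
    df["dnme"] = dnme
    if classify:
        df["dml_class"] = dml_cls
        df["dnme_class"] = dnme_cls
    return df


def attach_sjsd(df: pd.DataFrame, bandwidth: float) -> pd.DataFrame:
    """Smooth the per-GU JSD column per chromosome (Nadaraya-Watson)."""
    out = []
    for _, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start").copy()
        centers = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
        sm = dmrmod.smooth_jsd(centers, sub["jsd"].to_numpy(), bandwidth)
        sub["sjsd"] = sm.sjsd
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def dmr_calls(
    df: pd.DataFrame,
    null_model,
    fdr: float = 0.01,
    closing_size: float | None = None,
    bandwidth: float = 50_000.0,
) -> tuple[pd.DataFrame, list]:
    """Test every GU's sJSD against the null (single genome-wide family,
    BY at ``fdr``), then close and score DMRs per chromosome.

    Returns the augmented GU table (p, q, sqs, is_dm) and (chrom, DMRCall)
    pairs ranked genome-wide by score."""
    if closing_size is None:
        closing_size = bandwidth
    df = df.copy()
    p = np.asarray(null_model.pvalue(df["sjsd"].to_numpy()))
    res = dmrmod.test_gus(p, fdr_level=fdr)
    df["p"], df["q"], df["sqs"], df["is_dm"] = res.p, res.q, res.sqs, res.is_dm
    calls = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        iv = sub[["start", "end"]].to_numpy()
        for call in dmrmod.close_and_score(
            iv, sub["is_dm"].to_numpy(), sub["sqs"].to_numpy(), closing_size
        ):
            calls.append((chrom, call))
    calls.sort(key=lambda cd: -cd[1].score)
    for i, (_, call) in enumerate(calls):
        call.rank = i + 1
    return df, calls


def model_comparison_table(
    layout: CpGLayout,
    part: RegionPartition,
    chrom: str,
    obs_map: dict[int, ObservationMatrix],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Constrained-vs-general Ising AIC comparison for every eligible region
    small enough for the general fit."""
    cfg = config or PipelineConfig()
    est = estimation_config(cfg)
    rows = []
    for r in sorted(obs_map):
        lo, hi = part.region_sites(r)
        obs = obs_map[r]
        ok, _ = region_eligible(hi - lo, obs, est)
        if not ok or hi - lo > est.general_cap:
            continue
        rho, pos = layout.rho[lo:hi], layout.positions[lo:hi]
        fit1 = estimate_region_params(rho, pos, obs, est, seed=cfg.seed + r)
        fit2 = fit_general_ising(pos, obs, est, start=fit1, rho=rho)
        if not (fit1.ok and fit2.ok):
            continue
        cmp = aic_compare(fit1, fit2)
        start, end = part.regions[r]
        rows.append((chrom, int(start), int(end), cmp.aic1, cmp.aic2, cmp.pi))
    return pd.DataFrame(
        rows, columns=["chrom", "region_start", "region_end", "aic1", "aic2", "pi"]
    )
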