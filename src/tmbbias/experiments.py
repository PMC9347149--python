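"""Desk-scale experiment drivers: each reproduces one bias analysis on
synthetic data and returns a tidy results table plus summary statistics.

The four experiments:

* ``run_truncation_bias`` -- estimated vs true frequency with and without the
  VAF-threshold truncation (binomial draws at fixed depth).
* ``run_threshold_crossing`` -- counts of sites whose sampling noise carries
  them up or down across the threshold, per cohort replicate.
* ``run_downsampling`` -- paired full-depth vs 50%-thinned TMB across a
  cohort, with a sign test on the paired differences.
* ``run_depth_correlation`` -- Spearman correlation of per-sample mean depth
  with estimated TMB, stratified by clonal fraction, with a seeded
  permutation p-value.

Every report echoes its full configuration and master seed, so the tables
are bit-reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata

from .spectrum_model import BetaSpectrum, pass_count
from .synthetic_data import (
    DepthModel,
    SimulationConfig,
    downsample_sample,
    simulate_cohort,
    simulate_sample,
)
from .tmb_pipeline import estimate_tmb_threshold
from .trunc_binom import TruncationSpec, mean_proportion_estimate

__all__ = [
    "ExperimentReport",
    "run_truncation_bias",
    "run_threshold_crossing",
    "run_downsampling",
    "run_depth_correlation",
    "spearman_permutation",
]

_MAX_SEED = 2**31 - 1

#: Detection cut used by the cohort-level experiments.  Somatic callers at
#: moderate depth are considerably less sensitive than an ideal "any 3
#: mutant reads" rule; requiring 5 supporting reads keeps the detection cut
#: binding when depth is reduced, which is the power effect these
#: experiments probe.
DEFAULT_EXPERIMENT_MIN_ALT = 5


@dataclass
class ExperimentReport:
    """A named experiment outcome: config echo, tidy table(s), summary."""

    name: str
    parameters: dict
    table: pd.DataFrame
    summary: dict
    runtime_s: float
    raw_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_truncation_bias(
    f_grid=None,
    size: int = 100,
    tau: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
) -> ExperimentReport:
    """Estimated vs true frequency, untruncated and threshold-truncated.

    For each true frequency ``f`` draw ``n_reps`` binomial counts at depth
    ``size``; report the mean proportion over all draws and over only the
    draws whose proportion reaches ``tau`` (count >= ceil(tau*size)).
    """
    t0 = time.perf_counter()
    if f_grid is None:
        f_grid = np.round(np.arange(0.01, 0.51, 0.01), 10)
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any((f_grid <= 0) | (f_grid >= 1)):
        raise ValueError("f grid must lie within (0, 1)")
    spec = TruncationSpec.from_tau(size, tau)
    rng = np.random.default_rng(seed)
    rows = []
    for f in f_grid:
        draws = rng.binomial(size, f, size=n_reps)
        retained = draws[draws >= spec.min_count]
        rows.append(
            {
                "f": f,
                "mean_untruncated": mean_proportion_estimate(draws, size),
                "mean_truncated": (
                    mean_proportion_estimate(retained, size)
                    if retained.size
                    else np.nan
                ),
                "n_retained": int(retained.size),
            }
        )
    table = pd.DataFrame(rows)
    return ExperimentReport(
        name="truncation_bias",
        parameters={
            "size": size,
            "tau": tau,
            "min_count": spec.min_count,
            "n_reps": n_reps,
            "seed": seed,
            "f_grid": list(map(float, f_grid)),
        },
        table=table,
        summary={
            "max_bias_truncated": float(
                np.nanmax(table["mean_truncated"] - table["f"])
            ),
            "max_abs_bias_untruncated": float(
                np.max(np.abs(table["mean_untruncated"] - table["f"]))
            ),
        },
        runtime_s=time.perf_counter() - t0,
    )


def run_threshold_crossing(
    spectrum: BetaSpectrum = BetaSpectrum(0.1, 100.0),
    S: int = 200,
    depth: int = 100,
    tau: float = 0.05,
    n_reps: int = 200,
    seed: int = 0,
    keep_sites: bool = True,
) -> ExperimentReport:
    """Count threshold up-crossers and down-crossers per cohort replicate.

    An up-crosser has true frequency below ``tau`` but observed proportion at
    or above it; a down-crosser the reverse.  With a steeply decreasing
    spectrum at ``tau`` the up-crossers dominate, so threshold counting
    overestimates the above-threshold burden.
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(seed)
    cut = pass_count(depth, tau)
    rows, site_frames = [], []
    for rep in range(n_reps):
        f = rng.beta(spectrum.alpha, spectrum.beta, size=S)
        x = rng.binomial(depth, f)
        obs_pass = x >= cut
        true_above = f >= tau
        up = int(np.sum(~true_above & obs_pass))
        down = int(np.sum(true_above & ~obs_pass))
        rows.append(
            {
                "rep": rep,
                "up_crossers": up,
                "down_crossers": down,
                "n_true_above": int(true_above.sum()),
                "n_observed_above": int(obs_pass.sum()),
            }
        )
        if keep_sites:
            site_frames.append(
                pd.DataFrame(
                    {"rep": rep, "true_f": f, "depth": depth, "alt_count": x}
                )
            )
    table = pd.DataFrame(rows)
    mean_up = float(table["up_crossers"].mean())
    mean_down = float(table["down_crossers"].mean())
    return ExperimentReport(
        name="threshold_crossing",
        parameters={
            "alpha": spectrum.alpha,
            "beta": spectrum.beta,
            "S": S,
            "depth": depth,
            "tau": tau,
            "pass_count": cut,
            "n_reps": n_reps,
            "seed": seed,
        },
        table=table,
        summary={
            "mean_up_crossers": mean_up,
            "mean_down_crossers": mean_down,
            "up_down_ratio": mean_up / mean_down if mean_down > 0 else np.inf,
        },
        runtime_s=time.perf_counter() - t0,
        raw_tables=(
            {"sites": pd.concat(site_frames, ignore_index=True)}
            if keep_sites
            else {}
        ),
    )


def _default_downsampling_config() -> SimulationConfig:
    # subclonal-heavy sample: steep Beta(0.1, 100) spectrum, WES-like region
    return SimulationConfig(
        n_clonal=1000,
        n_subclonal=20000,
        subclonal_spectrum=BetaSpectrum(0.1, 100.0),
        depth_model=DepthModel.poisson(100.0),
        region_size_mb=35.0,
        seed=0,
    )


def run_downsampling(
    config: SimulationConfig | None = None,
    n_samples: int = 20,
    fraction: float = 0.5,
    tau: float = 0.05,
    min_alt_reads: int = DEFAULT_EXPERIMENT_MIN_ALT,
    seed: int = 0,
) -> ExperimentReport:
    """Paired full-depth vs thinned TMB across a cohort.

    Each sample is simulated from ``config`` (fresh per-sample seed), thinned
    to ``fraction`` of its reads, and TMB-estimated both ways; the summary
    holds the paired sign counts and an exact binomial sign test.
    """
    t0 = time.perf_counter()
    if config is None:
        config = _default_downsampling_config()
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    master = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        sample = simulate_sample(
            replace(config, seed=int(master.integers(0, _MAX_SEED)))
        )
        thinned = downsample_sample(
            sample, fraction, seed=int(master.integers(0, _MAX_SEED))
        )
        tmb_full = estimate_tmb_threshold(sample, tau, min_alt_reads).tmb
        tmb_down = estimate_tmb_threshold(thinned, tau, min_alt_reads).tmb
        rows.append(
            {
                "sample": i,
                "tmb_full": tmb_full,
                "tmb_downsampled": tmb_down,
                "difference": tmb_down - tmb_full,
            }
        )
    table = pd.DataFrame(rows)
    lower = int((table["difference"] < 0).sum())
    higher = int((table["difference"] > 0).sum())
    ties = int((table["difference"] == 0).sum())
    n_informative = lower + higher
    sign_p = (
        float(binomtest(lower, n_informative, 0.5).pvalue)
        if n_informative
        else np.nan
    )
    rel = table["difference"].abs() / table["tmb_full"].replace(0, np.nan)
    return ExperimentReport(
        name="downsampling",
        parameters={
            "config": config,
            "n_samples": n_samples,
            "fraction": fraction,
            "tau": tau,
            "min_alt_reads": min_alt_reads,
            "seed": seed,
        },
        table=table,
        summary={
            "n_lower_after_downsampling": lower,
            "n_higher_after_downsampling": higher,
            "n_ties": ties,
            "sign_test_p": sign_p,
            "median_abs_relative_change": float(rel.median()),
        },
        runtime_s=time.perf_counter() - t0,
    )


def spearman_permutation(
    x, y, n_permutations: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Spearman rho and a two-sided permutation p-value (seeded).

    Permutes ``y`` against ``x``; the p-value is the proportion of permuted
    ``|rho|`` at least as large as observed, with the +1 correction.
    Returns ``(nan, nan)`` when either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = x.size
    rho = float(rx @ ry / n)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm[i] = rx @ rng.permutation(ry) / n
    p = (1.0 + np.sum(np.abs(perm) >= abs(rho) - 1e-12)) / (n_permutations + 1.0)
    return rho, float(p)


def run_depth_correlation(
    n_per_stratum: int = 100,
    n_sites: int = 400,
    subclonal_spectrum: BetaSpectrum = BetaSpectrum(2.0, 20.0),
    depth_range: tuple[float, float] = (50.0, 400.0),
    low_clonal_range: tuple[float, float] = (0.0, 0.2),
    high_clonal_range: tuple[float, float] = (0.8, 1.0),
    tau: float = 0.05,
    min_alt_reads: int = DEFAULT_EXPERIMENT_MIN_ALT,
    region_size_mb: float = 35.0,
    n_permutations: int = 10000,
    seed: int = 0,
) -> ExperimentReport:
    """Depth-TMB Spearman correlation in low- vs high-clonal-fraction strata.

    Samples draw their mean depth uniformly over ``depth_range``; the
    subclonal stratum should show a positive depth-TMB correlation (detection
    power and threshold-crossing both depend on depth) while the clonal
    stratum's mutations sit far above the threshold and are insensitive to
    depth.
    """
    t0 = time.perf_counter()
    if n_per_stratum < 30:
        raise ValueError("need >= 30 samples per stratum")
    base = SimulationConfig(
        n_clonal=0,
        n_subclonal=n_sites,
        subclonal_spectrum=subclonal_spectrum,
        depth_model=DepthModel.poisson(100.0),
        region_size_mb=region_size_mb,
        seed=0,
    )
    master = np.random.default_rng(seed)
    frames = []
    stratum_summaries = {}
    for label, cf_range in (
        ("low_clonal", low_clonal_range),
        ("high_clonal", high_clonal_range),
    ):
        cohort = simulate_cohort(
            base,
            n_samples=n_per_stratum,
            depth_range=depth_range,
            clonal_fraction_range=cf_range,
            seed=int(master.integers(0, _MAX_SEED)),
        )
        depths = np.array([s.depths().mean() for s in cohort])
        tmbs = np.array(
            [estimate_tmb_threshold(s, tau, min_alt_reads).tmb for s in cohort]
        )
        cfs = np.array([s.clonal_fraction for s in cohort])
        rho, p = spearman_permutation(
            depths, tmbs, n_permutations, seed=int(master.integers(0, _MAX_SEED))
        )
        frames.append(
            pd.DataFrame(
                {
                    "stratum": label,
                    "mean_depth": depths,
                    "tmb": tmbs,
                    "clonal_fraction": cfs,
                }
            )
        )
        stratum_summaries[label] = {"rho": rho, "permutation_p": p}
    table = pd.concat(frames, ignore_index=True)
    return ExperimentReport(
        name="depth_correlation",
        parameters={
            "n_per_stratum": n_per_stratum,
            "n_sites": n_sites,
            "alpha": subclonal_spectrum.alpha,
            "beta": subclonal_spectrum.beta,
            "depth_range": depth_range,
            "low_clonal_range": low_clonal_range,
            "high_clonal_range": high_clonal_range,
            "tau": tau,
            "min_alt_reads": min_alt_reads,
            "region_size_mb": region_size_mb,
            "n_permutations": n_permutations,
            "seed": seed,
        },
        table=table,
        summary=stratum_summaries,
        runtime_s=time.perf_counter() - t0,
    )
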