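"""Truncated binomial distributions and Fisher's ML frequency estimator.

When a somatic mutation is only recorded if its mutant-read count reaches a
minimum ``c`` (one read for bare detection, ``ceil(tau*N)`` for a variant-
allele-frequency threshold ``tau`` at depth ``N``), the retained counts follow
a left-truncated binomial distribution.  The naive frequency estimate -- the
retained proportion of mutant reads -- is biased upward; for the
zero-truncated case its expectation is ``f / (1 - (1-f)^N)``.  This module
provides the truncated pmf, its mean proportion, exact-seeded sampling, and
the maximum-likelihood estimator of the success probability from truncated
counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import binom

__all__ = [
    "TruncationSpec",
    "FrequencyEstimate",
    "truncated_pmf",
    "truncated_mean_proportion",
    "sample_truncated",
    "fit_truncated_ml",
    "mean_proportion_estimate",
]

_F_LO = 1e-8
_F_HI = 1.0 - 1e-8


@dataclass(frozen=True)
class TruncationSpec:
    """A binomial sampling scheme with left truncation.

    Parameters
    ----------
    size
        Number of reads ``N`` covering a site.
    min_count
        Minimum mutant-read count ``c`` for an observation to be retained.
        ``0`` is the untruncated binomial, ``1`` the zero-truncated case.
    """

    size: int
    min_count: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"size must be a positive integer, got {self.size}")
        if not 0 <= self.min_count <= self.size:
            raise ValueError(
                f"min_count must lie in [0, size={self.size}], got {self.min_count}"
            )

    @classmethod
    def from_tau(cls, size: int, tau: float) -> "TruncationSpec":
        """Truncation at the frequency threshold: retain when ``X/N >= tau``.

        The retained-count cut is ``ceil(tau*N)`` so that a non-integer
        ``tau*N`` never admits sub-threshold proportions.  A small epsilon
        guards against floating-point excess in the product (e.g.
        ``100 * 0.05`` evaluating just above 5).
        """
        if not 0.0 <= tau < 1.0:
            raise ValueError(f"tau must lie in [0, 1), got {tau}")
        return cls(size=size, min_count=ceil(size * tau - 1e-9))


@dataclass
class FrequencyEstimate:
    """An estimated mutant-allele frequency (binomial success probability)."""

    value: float
    n_obs: int
    stderr: float | None = None
    at_boundary: bool = field(default=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"value must lie in [0, 1], got {self.value}")
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1 for a defined estimate")


def _tail(spec: TruncationSpec, f: float) -> float:
    """Retention probability ``P(X >= min_count)`` under Binomial(size, f)."""
    if spec.min_count == 0:
        return 1.0
    return float(binom.sf(spec.min_count - 1, spec.size, f))


def _check_f(spec: TruncationSpec, f: float) -> None:
    if spec.min_count > 0:
        if not 0.0 < f < 1.0:
            raise ValueError(
                f"f must lie in (0, 1) when min_count > 0 (conditioning event "
                f"X >= {spec.min_count} may have zero probability), got {f}"
            )
    elif not 0.0 <= f <= 1.0:
        raise ValueError(f"f must lie in [0, 1], got {f}")


def truncated_pmf(x, spec: TruncationSpec, f: float):
    """Pmf of the left-truncated binomial at count(s) ``x``.

    ``P(X = x | X >= c)`` for ``X ~ Binomial(spec.size, f)``; ``x`` may be a
    scalar or array, every entry must lie in ``[min_count, size]``.
    """
    _check_f(spec, f)
    x_arr = np.asarray(x)
    if np.any(x_arr < spec.min_count) or np.any(x_arr > spec.size):
        raise ValueError(
            f"counts must lie in [{spec.min_count}, {spec.size}], got {x}"
        )
    tail = _tail(spec, f)
    if tail <= 0.0:
        raise ValueError(
            f"conditioning event X >= {spec.min_count} has zero probability "
            f"at f={f}"
        )
    out = binom.pmf(x_arr, spec.size, f) / tail
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def truncated_mean_proportion(spec: TruncationSpec, f: float) -> float:
    """Expected retained proportion ``E[X/N | X >= min_count]``.

    Equals ``f`` when ``min_count == 0`` and ``f / (1 - (1-f)^N)`` in the
    zero-truncated case.  The general case sums the retained support in log
    space (numerator and denominator share the same pmf terms, so the ratio
    stays accurate even when the retention probability is tiny).
    """
    _check_f(spec, f)
    N, c = spec.size, spec.min_count
    if c == 0:
        return float(f)
    xs = np.arange(c, N + 1)
    logpmf = binom.logpmf(xs, N, f)
    if not np.any(np.isfinite(logpmf)):
        raise ValueError(
            f"conditioning event X >= {c} has zero probability at f={f}"
        )
    log_num = logsumexp(logpmf + np.log(xs))  # xs >= c >= 1
    log_den = logsumexp(logpmf)
    return float(np.exp(log_num - log_den)) / N


def sample_truncated(
    spec: TruncationSpec, f: float, n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` i.i.d. counts from the truncated binomial, reproducibly.

    Rejection sampling against the untruncated binomial; when the acceptance
    probability ``P(X >= min_count)`` drops below 0.01 the sampler falls back
    to inverse-CDF sampling restricted to the conditioning event (uniform
    draws on the retained CDF mass mapped through ``binom.ppf``), which is
    exact for any truncation.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    _check_f(spec, f)
    N, c = spec.size, spec.min_count
    rng = np.random.default_rng(seed)
    if c == 0:
        return rng.binomial(N, f, size=n)
    accept = _tail(spec, f)
    if accept <= 1e-300:
        raise ValueError(
            f"conditioning event X >= {c} has numerically zero probability "
            f"under Binomial({N}, {f})"
        )
    if accept >= 0.01:
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            # draw enough that one round usually finishes
            m = int((n - filled) / accept * 1.2) + 16
            draws = rng.binomial(N, f, size=m)
            keep = draws[draws >= c]
            take = min(keep.size, n - filled)
            out[filled : filled + take] = keep[:take]
            filled += take
        return out
    # inverse-CDF fallback: map U(F(c-1), 1) through the binomial quantile
    lo = float(binom.cdf(c - 1, N, f))
    u = lo + (1.0 - lo) * rng.random(n)
    # guard the open upper end against u == 1.0 rounding
    u = np.minimum(u, np.nextafter(1.0, 0.0))
    return binom.ppf(u, N, f).astype(np.int64)


def _neg_loglik(f: float, n: int, sum_x: int, spec: TruncationSpec) -> float:
    N, c = spec.size, spec.min_count
    ll = sum_x * np.log(f) + (n * N - sum_x) * np.log1p(-f)
    if c > 0:
        tail = _tail(spec, f)
        if tail <= 0.0:
            return np.inf
        ll -= n * np.log(tail)
    return -ll


def fit_truncated_ml(counts, spec: TruncationSpec) -> FrequencyEstimate:
    """Fisher's maximum-likelihood estimate of ``f`` from truncated counts.

    Maximizes ``sum_i [log Binom(x_i; N, f) - log P(X >= c; N, f)]`` by
    bounded scalar search on ``[1e-8, 1 - 1e-8]`` (tolerance 1e-8 on ``f``);
    the truncated log-likelihood of this one-parameter exponential-family
    conditioning is unimodal.  Degenerate samples (all counts at ``size`` or
    at zero) pin the estimate at the clamped boundary with a warning flag.
    """
    x = np.asarray(counts)
    if x.size == 0:
        raise ValueError("cannot fit from an empty count list")
    if np.any(x < spec.min_count) or np.any(x > spec.size):
        raise ValueError(
            f"all counts must lie in [{spec.min_count}, {spec.size}]"
        )
    n, sum_x = int(x.size), int(x.sum())
    if sum_x == n * spec.size or sum_x == 0:
        value = _F_HI if sum_x else _F_LO
        warnings.warn(
            "degenerate counts: ML estimate pinned at the parameter boundary",
            RuntimeWarning,
            stacklevel=2,
        )
        return FrequencyEstimate(value=value, n_obs=n, at_boundary=True)
    res = minimize_scalar(
        _neg_loglik,
        bounds=(_F_LO, _F_HI),
        args=(n, sum_x, spec),
        method="bounded",
        options={"xatol": 1e-8},
    )
    f_hat = float(res.x)
    at_boundary = f_hat <= _F_LO * 1.01 or f_hat >= 1.0 - 1e-8 * 1.01
    stderr = _observed_info_stderr(f_hat, n, sum_x, spec)
    return FrequencyEstimate(
        value=f_hat, n_obs=n, stderr=stderr, at_boundary=at_boundary
    )


def _observed_info_stderr(
    f_hat: float, n: int, sum_x: int, spec: TruncationSpec
) -> float | None:
    """Standard error from the observed information (central differences)."""
    h = max(1e-6, 1e-4 * f_hat)
    if not (_F_LO + h < f_hat < _F_HI - h):
        return None
    d2 = (
        _neg_loglik(f_hat + h, n, sum_x, spec)
        - 2.0 * _neg_loglik(f_hat, n, sum_x, spec)
        + _neg_loglik(f_hat - h, n, sum_x, spec)
    ) / h**2
    if not np.isfinite(d2) or d2 <= 0.0:
        return None
    return float(1.0 / np.sqrt(d2))


def mean_proportion_estimate(counts, size: int, pooled: bool = False) -> float:
    """Naive frequency estimate from retained counts (no truncation correction).

    ``pooled=False`` (default) averages per-observation proportions ``x_i/N``
    -- the per-sample estimate; ``pooled=True`` pools mutant reads over all
    observations, ``sum(x_i) / (n*N)``.  For constant ``N`` the two coincide.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("cannot estimate from an empty count list")
    if pooled:
        return float(x.sum() / (x.size * size))
    return float(np.mean(x / size))
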