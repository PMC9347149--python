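"""Tumour mutation burden estimators: threshold counting and spectrum-model fits.

Two estimators of TMB (somatic mutations per megabase) from a sample's
per-site read counts:

* **threshold** -- the standard pipeline: keep sites passing a detection cut
  (minimum mutant-read count, a stand-in for a somatic caller) whose observed
  VAF reaches the threshold ``tau``, and divide by the region size.
* **model** -- fit a truncated beta-binomial likelihood to *all* detected
  mutant-read counts (sub-threshold sites included), recover the total
  mutation count by inverse-probability weighting over each site's detection
  probability (capture-recapture style), and report the above-``tau`` mass of
  the fitted spectrum plus the observed clonal count.

The model route exists because threshold counting is biased when the
frequency spectrum has a steep sub-threshold slope: sampling noise pushes far
more sites up across the threshold than down.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, logsumexp

from .spectrum_model import BetaSpectrum, beta_cdf, pass_count
from .synthetic_data import SimulatedSite, TumourSample

__all__ = [
    "TmbResult",
    "SpectrumFit",
    "detect_mutations",
    "estimate_tmb_threshold",
    "fit_spectrum_ml",
    "estimate_tmb_model",
    "purity_adjust",
]

#: Fixed (alpha, beta) starting points for the spectrum fit.
_FIT_STARTS = ((0.1, 10.0), (0.1, 100.0), (1.0, 10.0), (0.5, 50.0))
_LOG_PARAM_BOUND = 15.0  # |log alpha|, |log beta| box; outside is penalized


@dataclass
class TmbResult:
    """A TMB estimate and the filters that produced it."""

    n_detected: int
    n_pass: int
    tmb: float
    tau: float
    min_alt_reads: int
    method: str
    region_size_mb: float

    def __post_init__(self) -> None:
        if self.n_pass > self.n_detected:
            raise ValueError("n_pass cannot exceed n_detected")


@dataclass
class SpectrumFit:
    """A fitted truncated beta-binomial spectrum and abundance estimate."""

    alpha_hat: float
    beta_hat: float
    S_hat: float
    loglik: float
    converged: bool
    n_used: int
    message: str = ""

    @property
    def spectrum(self) -> BetaSpectrum:
        return BetaSpectrum(self.alpha_hat, self.beta_hat)

    @property
    def mean_hat(self) -> float:
        return self.alpha_hat / (self.alpha_hat + self.beta_hat)


def detect_mutations(
    sample: TumourSample, min_alt_reads: int = 3
) -> list[SimulatedSite]:
    """Sites with at least ``min_alt_reads`` mutant reads (order preserved).

    A minimum-alt-read cut stands in for a somatic caller: monotone in depth
    like real callers and analytically tractable (the retained counts are
    left-truncated binomials).
    """
    if min_alt_reads < 1:
        raise ValueError(f"min_alt_reads must be >= 1, got {min_alt_reads}")
    return [
        s for s in sample.sites if s.depth >= 1 and s.alt_count >= min_alt_reads
    ]


def _threshold_cut(depth: int, tau: float, min_alt_reads: int, vaf_divisor: float) -> int:
    # pass rule: (alt/depth) / vaf_divisor >= tau, i.e. alt >= ceil(depth*tau*divisor)
    return max(min_alt_reads, pass_count(depth, tau * vaf_divisor))


def estimate_tmb_threshold(
    sample: TumourSample, tau: float = 0.05, min_alt_reads: int = 3
) -> TmbResult:
    """Standard TMB: detected sites with observed VAF >= tau, per megabase.

    The pass rule is the same ceil convention as the spectrum theory
    (``alt >= ceil(depth * tau)``), honouring any purity adjustment recorded
    on the sample (observed VAFs divided by ``sample.vaf_divisor``).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    if sample.region_size_mb <= 0:
        raise ValueError("region_size_mb must be > 0")
    detected = detect_mutations(sample, min_alt_reads)
    n_pass = sum(
        1
        for s in detected
        if s.alt_count
        >= _threshold_cut(s.depth, tau, min_alt_reads, sample.vaf_divisor)
    )
    return TmbResult(
        n_detected=len(detected),
        n_pass=n_pass,
        tmb=n_pass / sample.region_size_mb,
        tau=tau,
        min_alt_reads=min_alt_reads,
        method="threshold",
        region_size_mb=sample.region_size_mb,
    )


# ---------------------------------------------------------------------------
# truncated beta-binomial spectrum fit


def _group_sites(alts: np.ndarray, depths: np.ndarray, cuts: np.ndarray):
    """Group observations by (depth, cut) and pre-compute binomial log terms."""
    groups = []
    for d, c in {(int(d), int(c)) for d, c in zip(depths, cuts)}:
        mask = (depths == d) & (cuts == c)
        ux, cnt = np.unique(alts[mask], return_counts=True)
        ux = ux.astype(float)
        sup = np.arange(c, d + 1, dtype=float)
        groups.append(
            {
                "d": float(d),
                "n": int(mask.sum()),
                "ux": ux,
                "cnt": cnt,
                "log_binom_ux": gammaln(d + 1.0) - gammaln(ux + 1.0) - gammaln(d - ux + 1.0),
                "sup": sup,
                "log_binom_sup": gammaln(d + 1.0) - gammaln(sup + 1.0) - gammaln(d - sup + 1.0),
            }
        )
    return groups


def _group_nll(log_ab: np.ndarray, groups) -> float:
    if np.any(np.abs(log_ab) > _LOG_PARAM_BOUND):
        return 1e10
    a, b = np.exp(log_ab)
    lbab = betaln(a, b)
    total = 0.0
    for g in groups:
        d = g["d"]
        log_tail = logsumexp(g["log_binom_sup"] + betaln(g["sup"] + a, d - g["sup"] + b) - lbab)
        ll = g["cnt"] * (g["log_binom_ux"] + betaln(g["ux"] + a, d - g["ux"] + b) - lbab - log_tail)
        total += ll.sum()
    return -total if np.isfinite(total) else 1e10


def fit_spectrum_ml(
    sites: list[SimulatedSite] | TumourSample,
    min_alt_reads: int = 3,
    tau_detect: float = 0.0,
    clonal_exclusion_vaf: float = 0.35,
) -> SpectrumFit:
    """Fit Beta(alpha, beta) to detected subclonal counts by truncated ML.

    Each retained mutant-read count ``x_i`` at depth ``d_i`` contributes
    ``pmf_BB(x_i; d_i, a, b) / P(X >= c_i; d_i, a, b)`` where
    ``c_i = max(min_alt_reads, ceil(d_i * tau_detect))`` is the truncation
    cut (``tau_detect=0`` keeps every detected site so sub-threshold counts
    inform the spectrum).  Sites with observed VAF at or above
    ``clonal_exclusion_vaf`` are excluded as clonal -- the beta component
    models subclonal mass only.  Optimization runs in log-parameters from
    four fixed starting points (Nelder-Mead, tolerance 1e-6); ties go to the
    highest log-likelihood, then the smallest alpha.  The total subclonal
    abundance is recovered by inverse-probability weighting,
    ``S_hat = sum_i 1 / P(X >= c_i; d_i, alpha_hat, beta_hat)``.
    """
    if isinstance(sites, TumourSample):
        sites = detect_mutations(sites, min_alt_reads)
    sites = [
        s
        for s in sites
        if s.depth >= 1
        and s.alt_count >= _cut_for(s.depth, min_alt_reads, tau_detect)
        and s.observed_vaf < clonal_exclusion_vaf
    ]
    if len(sites) < 10:
        raise ValueError(
            f"need >= 10 detected sub-clonal sites to fit a spectrum, got {len(sites)}"
        )
    alts = np.array([s.alt_count for s in sites], dtype=np.int64)
    depths = np.array([s.depth for s in sites], dtype=np.int64)
    cuts = np.array(
        [_cut_for(int(d), min_alt_reads, tau_detect) for d in depths], dtype=np.int64
    )
    groups = _group_sites(alts, depths, cuts)

    best = None
    for a0, b0 in _FIT_STARTS:
        res = minimize(
            _group_nll,
            np.log([a0, b0]),
            args=(groups,),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-6, "maxfev": 4000},
        )
        if best is None or res.fun < best.fun - 1e-9 or (
            abs(res.fun - best.fun) <= 1e-9 and res.x[0] < best.x[0]
        ):
            best = res
    a_hat, b_hat = np.exp(best.x)
    converged = bool(best.success) and np.all(np.abs(best.x) < _LOG_PARAM_BOUND)
    degenerate = np.all(alts == cuts)
    spectrum = BetaSpectrum(float(a_hat), float(b_hat))

    from .spectrum_model import beta_binomial_log_tail  # local to avoid cycle at import

    S_hat = 0.0
    for d, c in sorted({(int(d), int(c)) for d, c in zip(depths, cuts)}):
        n_dc = int(np.sum((depths == d) & (cuts == c)))
        S_hat += n_dc / np.exp(beta_binomial_log_tail(c, d, spectrum))
    msg = "" if converged else "optimizer did not converge from any start"
    if degenerate:
        msg = (msg + "; " if msg else "") + "degenerate data: all counts at the cut"
    return SpectrumFit(
        alpha_hat=float(a_hat),
        beta_hat=float(b_hat),
        S_hat=float(S_hat),
        loglik=float(-best.fun),
        converged=converged and not degenerate,
        n_used=len(sites),
        message=msg,
    )


def _cut_for(depth: int, min_alt_reads: int, tau_detect: float) -> int:
    return max(min_alt_reads, pass_count(depth, tau_detect)) if tau_detect > 0 else min_alt_reads


def estimate_tmb_model(
    fit: SpectrumFit,
    tau: float,
    region_size_mb: float,
    n_clonal_observed: int,
) -> TmbResult:
    """Model-based TMB from a fitted spectrum.

    ``TMB = [n_clonal_observed + S_hat * (1 - F_B(tau; alpha_hat, beta_hat))]
    / region_size_mb``: observed clonal mutations all count (they sit far
    above any threshold), and the subclonal contribution is the above-``tau``
    mass of the fitted spectrum scaled by the recovered abundance.
    """
    if not fit.converged:
        raise ValueError(f"refusing to use an unconverged spectrum fit: {fit.message}")
    if region_size_mb <= 0:
        raise ValueError("region_size_mb must be > 0")
    if n_clonal_observed < 0:
        raise ValueError("n_clonal_observed must be >= 0")
    subclonal_above = fit.S_hat * (1.0 - beta_cdf(tau, fit.spectrum))
    n_total = n_clonal_observed + fit.n_used
    return TmbResult(
        n_detected=n_total,
        n_pass=n_total,
        tmb=(n_clonal_observed + subclonal_above) / region_size_mb,
        tau=tau,
        min_alt_reads=0,
        method="model",
        region_size_mb=region_size_mb,
    )


def purity_adjust(sample: TumourSample, purity: float) -> TumourSample:
    """Record a purity correction: observed VAFs are divided by ``purity``.

    Downstream threshold estimation compares ``min(1, observed_vaf/purity)``
    against ``tau`` (the division is stored, not applied to read counts, so
    the adjustment is exact and reversible).  ``purity=1`` is the identity.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must lie in (0, 1], got {purity}")
    return TumourSample(
        sites=[replace(s) for s in sample.sites],
        purity=sample.purity,
        clonal_fraction=sample.clonal_fraction,
        region_size_mb=sample.region_size_mb,
        seed=sample.seed,
        config=sample.config,
        vaf_divisor=sample.vaf_divisor * purity,
    )
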