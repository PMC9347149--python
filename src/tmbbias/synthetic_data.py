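"""Synthetic tumour sequencing samples with a clonal + beta-subclonal VAF spectrum.

Each simulated sample consists of ``n_clonal`` mutations at a fixed cellular
frequency (0.5 by default, the heterozygous-diploid value) plus
``n_subclonal`` mutations whose frequencies are drawn from a
``BetaSpectrum``.  Tumour purity scales every frequency multiplicatively
(normal-cell contamination dilutes mutant reads), per-site depth follows a
configurable depth model, and mutant-read counts are binomial draws at the
purity-scaled frequency.  Read-level down-sampling is modelled as independent
binomial thinning of mutant and reference reads, the exact read-count analog
of randomly subsampling a BAM.  Samples round-trip through a commented TSV
dialect and export to a minimal VCF v4.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectrum_model import BetaSpectrum

__all__ = [
    "DepthModel",
    "SimulationConfig",
    "SimulatedSite",
    "TumourSample",
    "simulate_sample",
    "downsample_sample",
    "simulate_cohort",
    "write_sample_tsv",
    "read_sample_tsv",
    "write_sample_vcf",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class DepthModel:
    """Per-site sequencing-depth distribution (fixed, Poisson or NB).

    Negative-binomial dispersion follows the mean/dispersion convention
    ``var = mean + mean**2 / dispersion``; every model clamps depth to >= 1.
    """

    kind: str
    mean: float
    dispersion: float | None = None

    _KINDS = ("fixed", "poisson", "negative-binomial")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.mean <= 0:
            raise ValueError(f"mean depth must be > 0, got {self.mean}")
        if self.kind == "negative-binomial":
            if self.dispersion is None or self.dispersion <= 0:
                raise ValueError("negative-binomial depth needs dispersion > 0")

    @classmethod
    def fixed(cls, depth: int) -> "DepthModel":
        return cls(kind="fixed", mean=float(depth))

    @classmethod
    def poisson(cls, mean: float) -> "DepthModel":
        return cls(kind="poisson", mean=float(mean))

    @classmethod
    def negative_binomial(cls, mean: float, dispersion: float) -> "DepthModel":
        return cls(kind="negative-binomial", mean=float(mean), dispersion=float(dispersion))

    def with_mean(self, mean: float) -> "DepthModel":
        return replace(self, mean=float(mean))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            depths = np.full(n, int(round(self.mean)), dtype=np.int64)
        elif self.kind == "poisson":
            depths = rng.poisson(self.mean, size=n).astype(np.int64)
        else:
            r = self.dispersion
            p = r / (r + self.mean)
            depths = rng.negative_binomial(r, p, size=n).astype(np.int64)
        return np.maximum(depths, 1)


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one simulated tumour sample."""

    n_clonal: int
    n_subclonal: int
    subclonal_spectrum: BetaSpectrum
    clonal_vaf: float = 0.5
    purity: float = 1.0
    depth_model: DepthModel = field(default_factory=lambda: DepthModel.fixed(100))
    region_size_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_clonal < 0 or self.n_subclonal < 0:
            problems.append("n_clonal and n_subclonal must be >= 0")
        if self.n_clonal + self.n_subclonal < 1:
            problems.append("n_clonal + n_subclonal must be >= 1")
        if not 0.0 < self.clonal_vaf <= 1.0:
            problems.append(f"clonal_vaf must lie in (0, 1], got {self.clonal_vaf}")
        if not 0.0 < self.purity <= 1.0:
            problems.append(f"purity must lie in (0, 1], got {self.purity}")
        if self.region_size_mb <= 0:
            problems.append(f"region_size_mb must be > 0, got {self.region_size_mb}")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    @property
    def n_sites(self) -> int:
        return self.n_clonal + self.n_subclonal

    @property
    def clonal_fraction(self) -> float:
        return self.n_clonal / self.n_sites


@dataclass
class SimulatedSite:
    """One mutated site: its true (purity-scaled) VAF and read counts."""

    site_id: str
    true_vaf: float
    depth: int
    alt_count: int
    is_clonal: bool

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(
                f"alt_count must lie in [0, depth={self.depth}], got {self.alt_count}"
            )

    @property
    def observed_vaf(self) -> float:
        """Mutant-read proportion; NaN for sites with zero remaining depth."""
        return self.alt_count / self.depth if self.depth > 0 else float("nan")


@dataclass
class TumourSample:
    """A simulated sample: sites plus the sample-level context."""

    sites: list[SimulatedSite]
    purity: float
    clonal_fraction: float
    region_size_mb: float
    seed: int
    config: SimulationConfig | None = None
    vaf_divisor: float = 1.0  # set by purity adjustment; observed VAFs are divided by it

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("a TumourSample must contain at least one site")

    def __len__(self) -> int:
        return len(self.sites)

    def depths(self) -> np.ndarray:
        return np.array([s.depth for s in self.sites], dtype=np.int64)

    def alt_counts(self) -> np.ndarray:
        return np.array([s.alt_count for s in self.sites], dtype=np.int64)

    def true_vafs(self) -> np.ndarray:
        return np.array([s.true_vaf for s in self.sites], dtype=float)

    def clonal_flags(self) -> np.ndarray:
        return np.array([s.is_clonal for s in self.sites], dtype=bool)


def simulate_sample(config: SimulationConfig) -> TumourSample:
    """Simulate one tumour sample from a :class:`SimulationConfig`.

    Clonal sites carry frequency ``clonal_vaf * purity``; subclonal
    frequencies are Beta(alpha, beta) draws scaled by purity.  Depths follow
    the depth model and mutant-read counts are Binomial(depth, frequency).
    Fixed seed implies a bit-identical sample.
    """
    rng = np.random.default_rng(config.seed)
    n_cl, n_sub = config.n_clonal, config.n_subclonal
    sp = config.subclonal_spectrum
    f = np.concatenate(
        [
            np.full(n_cl, config.clonal_vaf),
            rng.beta(sp.alpha, sp.beta, size=n_sub) if n_sub else np.empty(0),
        ]
    )
    f *= config.purity
    depths = config.depth_model.sample(rng, config.n_sites)
    alts = rng.binomial(depths, f)
    width = len(str(config.n_sites))
    sites = [
        SimulatedSite(
            site_id=f"site_{i:0{width}d}",
            true_vaf=float(f[i]),
            depth=int(depths[i]),
            alt_count=int(alts[i]),
            is_clonal=i < n_cl,
        )
        for i in range(config.n_sites)
    ]
    return TumourSample(
        sites=sites,
        purity=config.purity,
        clonal_fraction=config.clonal_fraction,
        region_size_mb=config.region_size_mb,
        seed=config.seed,
        config=config,
    )


def downsample_sample(
    sample: TumourSample, fraction: float, seed: int
) -> TumourSample:
    """Thin every site's reads to ``fraction``, as random read subsampling.

    Retained mutant reads ~ Binomial(alt, fraction) and retained reference
    reads ~ Binomial(depth - alt, fraction), independently; the new depth is
    their sum.  ``fraction=1`` returns an identical copy; sites may end with
    zero depth (kept -- they are undetectable downstream).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if fraction == 1.0:
        return TumourSample(
            sites=[replace(s) for s in sample.sites],
            purity=sample.purity,
            clonal_fraction=sample.clonal_fraction,
            region_size_mb=sample.region_size_mb,
            seed=sample.seed,
            config=sample.config,
            vaf_divisor=sample.vaf_divisor,
        )
    rng = np.random.default_rng(seed)
    alts = sample.alt_counts()
    refs = sample.depths() - alts
    new_alts = rng.binomial(alts, fraction)
    new_refs = rng.binomial(refs, fraction)
    sites = [
        replace(s, depth=int(new_alts[i] + new_refs[i]), alt_count=int(new_alts[i]))
        for i, s in enumerate(sample.sites)
    ]
    return TumourSample(
        sites=sites,
        purity=sample.purity,
        clonal_fraction=sample.clonal_fraction,
        region_size_mb=sample.region_size_mb,
        seed=sample.seed,
        config=sample.config,
        vaf_divisor=sample.vaf_divisor,
    )


def simulate_cohort(
    base: SimulationConfig,
    n_samples: int,
    depth_range: tuple[float, float],
    clonal_fraction_range: tuple[float, float],
    seed: int,
) -> list[TumourSample]:
    """Simulate a cohort varying mean depth and clonal fraction per sample.

    Per sample, the mean depth is uniform on ``depth_range`` and the clonal
    fraction uniform on ``clonal_fraction_range`` (the total site count of
    ``base`` is held fixed; ``n_clonal = round(cf * S)``).  Per-sample seeds
    are derived from the master seed, so the cohort is fully reproducible.
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    d_lo, d_hi = depth_range
    c_lo, c_hi = clonal_fraction_range
    if d_lo <= 0 or d_hi < d_lo:
        raise ValueError(f"invalid depth_range {depth_range}")
    if not (0.0 <= c_lo <= c_hi <= 1.0):
        raise ValueError(f"invalid clonal_fraction_range {clonal_fraction_range}")
    master = np.random.default_rng(seed)
    S = base.n_sites
    samples = []
    for _ in range(n_samples):
        mean_depth = float(master.uniform(d_lo, d_hi))
        cf = float(master.uniform(c_lo, c_hi))
        n_clonal = int(round(cf * S))
        cfg = replace(
            base,
            n_clonal=n_clonal,
            n_subclonal=S - n_clonal,
            depth_model=base.depth_model.with_mean(mean_depth),
            seed=int(master.integers(0, _MAX_SEED)),
        )
        samples.append(simulate_sample(cfg))
    return samples


# ---------------------------------------------------------------------------
# serialization: commented-header TSV and minimal VCF v4.2


def _fmt(x: float) -> str:
    return repr(float(x))  # repr round-trips doubles bit-exactly


def write_sample_tsv(sample: TumourSample, path) -> None:
    """Write a sample as TSV with a commented metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# purity={_fmt(sample.purity)}\n")
        fh.write(f"# clonal_fraction={_fmt(sample.clonal_fraction)}\n")
        fh.write(f"# region_size_mb={_fmt(sample.region_size_mb)}\n")
        fh.write(f"# seed={sample.seed}\n")
        fh.write("site_id\ttrue_vaf\tdepth\talt_count\tis_clonal\n")
        for s in sample.sites:
            fh.write(
                f"{s.site_id}\t{_fmt(s.true_vaf)}\t{s.depth}\t{s.alt_count}\t"
                f"{int(s.is_clonal)}\n"
            )


def read_sample_tsv(path) -> TumourSample:
    """Read a sample written by :func:`write_sample_tsv` (bit-exact round trip)."""
    meta: dict[str, str] = {}
    sites: list[SimulatedSite] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line.lstrip("# ").split("=", 1)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed metadata line") from exc
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line.split("\t") != ["site_id", "true_vaf", "depth", "alt_count", "is_clonal"]:
                    raise ValueError(f"{path}:{lineno}: unexpected column header")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            try:
                sites.append(
                    SimulatedSite(
                        site_id=parts[0],
                        true_vaf=float(parts[1]),
                        depth=int(parts[2]),
                        alt_count=int(parts[3]),
                        is_clonal=bool(int(parts[4])),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    missing = {"purity", "clonal_fraction", "region_size_mb", "seed"} - meta.keys()
    if missing:
        raise ValueError(f"{path}: missing metadata keys {sorted(missing)}")
    return TumourSample(
        sites=sites,
        purity=float(meta["purity"]),
        clonal_fraction=float(meta["clonal_fraction"]),
        region_size_mb=float(meta["region_size_mb"]),
        seed=int(meta["seed"]),
    )


_VCF_SPACING = 100  # bp between successive synthetic positions


def write_sample_vcf(sample: TumourSample, path) -> None:
    """Write a minimal VCF v4.2: one record per site, AD/DP, INFO TRUE_VAF.

    Positions are synthetic (chr1, evenly spaced in site order); REF/ALT are
    placeholder A/T.  The dialect is documented in the header lines.
    """
    n = len(sample.sites)
    length = _VCF_SPACING * (n + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tmbbias-synthetic-sample\n")
        fh.write(
            "##comment=synthetic sites; positions are placeholders assigned "
            "deterministically from site order\n"
        )
        fh.write(f"##contig=<ID=chr1,length={length}>\n")
        fh.write(
            '##INFO=<ID=TRUE_VAF,Number=1,Type=Float,Description="True '
            'purity-scaled mutant allele frequency">\n'
        )
        fh.write('##INFO=<ID=CLONAL,Number=0,Type=Flag,Description="Clonal mutation">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth '
            'per allele (ref,alt)">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOUR\n")
        for i, s in enumerate(sample.sites):
            pos = _VCF_SPACING * (i + 1)
            info = f"TRUE_VAF={s.true_vaf:.6g}" + (";CLONAL" if s.is_clonal else "")
            ref_reads = s.depth - s.alt_count
            fh.write(
                f"chr1\t{pos}\t{s.site_id}\tA\tT\t.\tPASS\t{info}\t"
                f"GT:AD:DP\t0/1:{ref_reads},{s.alt_count}:{s.depth}\n"
            )
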