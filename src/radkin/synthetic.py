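"""Synthetic inputs for every downstream analysis.

Generates allele-frequency panels with U-shaped spectra typical of RAD
SNP ascertainment, Hardy–Weinberg founder genotypes, Mendelian
offspring, genotyping error/missingness with read-depth channels,
weakly structured populations (Balding–Nichols), and length-at-age
Gaussian mixtures — so the whole pipeline is testable without any
sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MISSING, GenotypeMatrix, LocusPanel, make_panel

DEFAULT_BETA = (0.7, 0.7)
DEFAULT_TRUNC = (0.05, 0.95)


def draw_allele_frequencies(
    n_loci: int,
    source: tuple[float, float] | dict[float, float] | np.ndarray = DEFAULT_BETA,
    rng_seed: int | np.random.Generator = 0,
    trunc: tuple[float, float] = DEFAULT_TRUNC,
    spacing_bp: int = 2_000_000,
) -> LocusPanel:
    """Draw a panel of ALT-allele frequencies.

    ``source`` is either ``(a, b)`` beta shape parameters (truncated to
    ``trunc`` by inverse-CDF sampling), an empirical histogram mapping
    frequency -> weight, or an array of observed frequencies resampled
    with replacement. Loci are laid out >= ``spacing_bp`` apart within
    scaffolds so the default panel behaves as independent loci.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if isinstance(source, dict):
        if not source:
            raise ValueError("empirical histogram is empty")
        vals = np.array(list(source.keys()), dtype=float)
        w = np.array(list(source.values()), dtype=float)
        freqs = rng.choice(vals, size=n_loci, p=w / w.sum())
    elif isinstance(source, tuple) and len(source) == 2 and np.isscalar(source[0]):
        a, b = source
        if a <= 0 or b <= 0:
            raise ValueError("beta shape parameters must be > 0")
        from scipy.stats import beta as beta_dist

        lo, hi = beta_dist.cdf(trunc[0], a, b), beta_dist.cdf(trunc[1], a, b)
        freqs = beta_dist.ppf(rng.uniform(lo, hi, size=n_loci), a, b)
    else:
        arr = np.asarray(source, dtype=float)
        if arr.size == 0:
            raise ValueError("empirical frequency array is empty")
        freqs = rng.choice(arr, size=n_loci)
    return make_panel(freqs, spacing_bp=spacing_bp)


def hwe_parent_genotypes(
    panel: LocusPanel, n_parents: int, rng_seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Founder genotypes at Hardy–Weinberg proportions, no missingness."""
    if n_parents < 2:
        raise ValueError("need at least 2 parents")
    rng = np.random.default_rng(rng_seed)
    g = rng.binomial(2, panel.alt_freq, size=(n_parents, len(panel))).astype(np.int8)
    samples = np.array([f"P{i + 1}" for i in range(n_parents)], dtype=object)
    return GenotypeMatrix(samples, panel, g)


def mendelian_offspring(
    mother_g: np.ndarray, father_g: np.ndarray, rng_seed: int | np.random.Generator = 0
) -> np.ndarray:
    """One offspring dosage vector: each parent transmits one of its two
    alleles uniformly at random, per locus. A missing parental genotype
    yields a missing offspring genotype at that locus."""
    mother_g = np.asarray(mother_g)
    father_g = np.asarray(father_g)
    if mother_g.shape != father_g.shape:
        raise ValueError("parental genotype vectors must share a panel")
    rng = np.random.default_rng(rng_seed)
    # transmitted ALT allele: P(alt) = dosage / 2
    u1 = rng.random(mother_g.shape)
    u2 = rng.random(father_g.shape)
    child = (u1 < mother_g / 2.0).astype(np.int8) + (u2 < father_g / 2.0).astype(np.int8)
    child[(mother_g == MISSING) | (father_g == MISSING)] = MISSING
    return child


@dataclass
class DepthModel:
    """Negative-binomial read depth (mean, dispersion) per genotype call."""

    mean: float = 30.0
    dispersion: float = 5.0
    error_read_rate: float = 0.005  # reads miscalled to the other allele

    def draw_depth(self, rng: np.random.Generator, shape) -> np.ndarray:
        k = self.dispersion
        p = k / (k + self.mean)
        return rng.negative_binomial(k, p, size=shape)


def corrupt_genotypes(
    gm: GenotypeMatrix,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    depth_model: DepthModel | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Apply genotyping error and missingness; attach depth channels.

    Each called genotype is independently replaced by a Hardy–Weinberg
    draw with probability ``error_rate`` and masked with probability
    ``missing_rate``. When a ``depth_model`` is given, per-cell DP is
    negative-binomial and heterozygote allele depths are
    Binomial(DP, 0.5); GQ is set high for kept calls (the generator
    models genotype-level error directly, not phred calibration).
    """
    if not (0 <= error_rate < 1 and 0 <= missing_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    g = gm.genotypes.copy()
    called = g != MISSING
    if error_rate > 0:
        err = called & (rng.random(g.shape) < error_rate)
        hwe = rng.binomial(2, np.broadcast_to(gm.panel.alt_freq, g.shape)).astype(np.int8)
        g[err] = hwe[err]
    if missing_rate > 0:
        g[called & (rng.random(g.shape) < missing_rate)] = MISSING

    gq = depth = ad = None
    if depth_model is not None:
        dp = depth_model.draw_depth(rng, g.shape).astype(np.int32)
        dp[g == MISSING] = 0
        # ref-read fraction by dosage: 0 -> ~1, 1 -> 0.5, 2 -> ~eps
        e = depth_model.error_read_rate
        p_ref = np.choose(np.clip(g, 0, 2), [1.0 - e, 0.5, e])
        ref = rng.binomial(dp, p_ref).astype(np.int32)
        ad = np.stack([ref, dp - ref], axis=2)
        gq = np.full(g.shape, 99, dtype=np.int16)
        gq[g == MISSING] = 0
        depth = dp
    return GenotypeMatrix(
        gm.samples, gm.panel, g, gq=gq, depth=depth, allele_depths=ad,
        populations=gm.populations,
    )


def structured_populations(
    panel: LocusPanel,
    n_pops: int,
    fst_target: float,
    n_per_pop: int,
    rng_seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Balding–Nichols structured populations around the panel's
    ancestral frequencies; genotypes at HWE within each population."""
    if n_pops < 2:
        raise ValueError("need at least 2 populations")
    if not (0 <= fst_target < 0.5):
        raise ValueError("fst_target must lie in [0, 0.5)")
    rng = np.random.default_rng(rng_seed)
    p = panel.alt_freq
    if fst_target == 0:
        pop_freq = np.broadcast_to(p, (n_pops, len(panel)))
    else:
        f = fst_target
        a = p * (1 - f) / f
        b = (1 - p) * (1 - f) / f
        pop_freq = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9), size=(n_pops, len(panel)))
    gs, samples, pops = [], [], []
    for k in range(n_pops):
        gs.append(rng.binomial(2, pop_freq[k], size=(n_per_pop, len(panel))).astype(np.int8))
        samples += [f"pop{k + 1}_{i + 1}" for i in range(n_per_pop)]
        pops += [f"pop{k + 1}"] * n_per_pop
    return GenotypeMatrix(
        np.array(samples, dtype=object),
        panel,
        np.vstack(gs),
        populations=np.array(pops, dtype=object),
    )


@dataclass
class AgeMixtureModel:
    """Four-component Gaussian length-at-age mixture (ages 0,1,2,3+)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    K: int = 4

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.means) == len(self.sds) == len(self.weights) == self.K):
            raise ValueError(f"expected {self.K} components")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("sds must be positive")
        order = np.argsort(self.means)
        self.means = self.means[order]
        self.sds = self.sds[order]
        self.weights = self.weights[order]

    @property
    def age_classes(self) -> list[str]:
        return ["0", "1", "2", "3+"]


# Defaults loosely calibrated to larval lamprey length-frequency modes.
DEFAULT_AGE_MIXTURE = AgeMixtureModel(
    means=np.array([35.0, 70.0, 105.0, 135.0]),
    sds=np.array([8.0, 10.0, 12.0, 14.0]),
    weights=np.array([0.15, 0.35, 0.35, 0.15]),
)


def simulate_lengths(
    model: AgeMixtureModel, n: int, rng_seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` body lengths (mm) with their true component labels."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    labels = rng.choice(model.K, size=n, p=model.weights)
    lengths = rng.normal(model.means[labels], model.sds[labels])
    return lengths, labels
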