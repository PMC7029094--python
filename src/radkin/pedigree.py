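"""Pedigree summaries: contributing adults, reproductive success,
group coancestry, and effective number of breeders.

A reconstructed cohort pedigree is a set of full-sib families, each
implying two unsampled parents ("slots"), with half-sib links merging
one slot between families. The effective number of breeders N_b is
estimated two ways: from sibship frequencies (probabilities that a
random dyad shares a mother/father) and from multilocus linkage
disequilibrium (Burrows composite r-squared with the Waples small-sample
bias adjustment and random-mating inversion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np

from .containers import GenotypeMatrix, TruePedigree
from .sibship import FamilySet

# coancestry coefficient per unordered dyad
FS_COANCESTRY = 0.125
HS_COANCESTRY = 0.0625


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[max(ra, rb)] = min(ra, rb)
        return True


def _merged_slots(families: FamilySet) -> _UnionFind:
    """Union-find over parent slots (2 per family) after HS merges.

    Each half-sib link merges one slot between the two families; a slot
    not yet shared with another family is preferred so that a family
    can share different parents with different families. Links are
    processed in sorted order, so the result is deterministic.
    """
    uf = _UnionFind(2 * families.n_families)
    shared: set[int] = set()  # slots already used in a merge
    for fi, fj in sorted(families.hs_links):
        if uf.find(2 * fi) in {uf.find(2 * fj), uf.find(2 * fj + 1)} or uf.find(
            2 * fi + 1
        ) in {uf.find(2 * fj), uf.find(2 * fj + 1)}:
            continue  # already share a parent
        si = next((s for s in (2 * fi, 2 * fi + 1) if s not in shared), 2 * fi)
        sj = next((s for s in (2 * fj, 2 * fj + 1) if s not in shared), 2 * fj)
        uf.union(si, sj)
        shared.update({si, sj})
    return uf


def count_parents(families: FamilySet) -> int:
    """Number of distinct adults implied by the family structure: two
    per full-sib family, minus slots merged by half-sib links."""
    uf = _merged_slots(families)
    return len({uf.find(s) for s in range(2 * families.n_families)})


def reproductive_success(families: FamilySet, n_offspring: int) -> tuple[float, float]:
    """Mean and sample variance of offspring per contributing adult.

    Each offspring credits one offspring to each of its family's two
    parent slots, so the mean is exactly 2 * n_offspring / N_s.
    """
    sizes = [len(f) for f in families.families]
    if sum(sizes) != n_offspring:
        raise ValueError("family sizes do not sum to n_offspring")
    uf = _merged_slots(families)
    per_parent: dict[int, int] = {}
    for i, size in enumerate(sizes):
        for s in (2 * i, 2 * i + 1):
            root = uf.find(s)
            per_parent[root] = per_parent.get(root, 0) + size
    counts = np.array(list(per_parent.values()), dtype=float)
    mean = 2.0 * n_offspring / len(counts)
    var = float(np.var(counts, ddof=1)) if len(counts) > 1 else 0.0
    return mean, var


def coancestry_from_counts(n: int, n_fs_dyads: int, n_hs_dyads: int) -> float:
    """Group coancestry from cohort size and sibling-dyad counts:
    (0.125 * FS + 0.0625 * HS) / C(n, 2). Zero when no dyads are
    related. Dyad counts exceeding C(n, 2) are flagged with a warning
    but still computed (printed counts are treated as opaque inputs)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if min(n_fs_dyads, n_hs_dyads) < 0:
        raise ValueError("dyad counts must be non-negative")
    total = comb(n, 2)
    if n_fs_dyads + n_hs_dyads > total:
        warnings.warn(
            "related-dyad counts exceed C(n,2); treating them as reported", stacklevel=2
        )
    return (FS_COANCESTRY * n_fs_dyads + HS_COANCESTRY * n_hs_dyads) / total


def _parent_pairs(source: FamilySet | TruePedigree, offspring=None):
    """Per-offspring (parent_a, parent_b) identifiers.

    For a known pedigree the pair is (mother, father). For an inferred
    family structure parents are the merged slot roots; slot sexes are
    unknown, so downstream sharing probabilities use the symmetric
    (unsexed) form.
    """
    if isinstance(source, TruePedigree):
        ids = list(source.parents) if offspring is None else list(offspring)
        return [source.parents[o] for o in ids], True
    uf = _merged_slots(source)
    pairs = []
    for i, fam in enumerate(source.families):
        pa, pb = uf.find(2 * i), uf.find(2 * i + 1)
        pairs.extend([(f"slot{pa}", f"slot{pb}")] * len(fam))
    return pairs, False


@dataclass
class NbEstimate:
    nb: float
    ci_low: float
    ci_high: float
    method: str
    n: int
    r2_prime: float | None = None  # LD method only


def _nb_from_pairs(
    pairs: list[tuple[str, str]], sexed: bool, orig: np.ndarray | None = None
) -> float:
    """Wright composition from dyad parent-sharing probabilities.

    With Q_m (Q_f) the probability a random dyad shares its mother
    (father), effective parent numbers are 1/Q and
    N_b = 4 / (1/N_f* + 1/N_m*) = 4 / (Q_m + Q_f). Unsexed parent
    slots use the symmetric split Q_m = Q_f = (2*FS + HS) / (2*D).

    ``orig`` (original-offspring index per entry) is supplied by the
    bootstrap so that dyads formed by two copies of the same offspring
    are excluded — such self-pairs trivially share both parents and
    would bias the resampled sharing rates upward.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 offspring")

    def pair_count(ids) -> float:
        _, counts = np.unique(np.asarray(ids), return_counts=True)
        return float((counts * (counts - 1) / 2.0).sum())

    self_pairs = 0.0 if orig is None else pair_count(orig)
    total = n * (n - 1) / 2.0 - self_pairs
    if total <= 0:
        return np.inf
    if sexed:
        qm = (pair_count([p[0] for p in pairs]) - self_pairs) / total
        qf = (pair_count([p[1] for p in pairs]) - self_pairs) / total
    else:
        # slot sexes unknown: split the total parent-sharing rate evenly
        shared_sum = pair_count([p for pair in pairs for p in pair]) - 2.0 * self_pairs
        qm = qf = shared_sum / (2.0 * total)
    denom = qm + qf
    return np.inf if denom == 0 else 4.0 / denom


def nb_sibship(
    source: FamilySet | TruePedigree,
    n_offspring: int | None = None,
    n_boot: int = 500,
    rng_seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
) -> NbEstimate:
    """Sibship-frequency N_b with a bootstrap-over-offspring CI."""
    pairs, sexed = _parent_pairs(source)
    if n_offspring is not None and len(pairs) != n_offspring:
        raise ValueError("n_offspring inconsistent with the pedigree")
    nb = _nb_from_pairs(pairs, sexed)
    lo = hi = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(rng_seed)
        alpha = (1.0 - ci_level) / 2.0
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(pairs), size=len(pairs))
            nb_b = _nb_from_pairs([pairs[i] for i in idx], sexed, orig=idx)
            boots.append(0.0 if np.isinf(nb_b) else 1.0 / nb_b)
        # percentile CI on the 1/N_b scale (finite even when draws censor)
        t_lo, t_hi = np.quantile(np.asarray(boots), [alpha, 1.0 - alpha])
        hi = np.inf if t_lo <= 0 else 1.0 / t_lo
        lo = np.inf if t_hi <= 0 else 1.0 / t_hi
        lo, hi = min(lo, hi), max(lo, hi)
    return NbEstimate(nb, float(lo), float(hi), "sibship", len(pairs))


@dataclass
class NbLdConfig:
    """LD-method settings: MAF cutoff, locus-pair scope, jackknife CI."""

    p_crit: float = 0.05
    pair_scope: str = "interscaffold"  # or "all"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.p_crit < 0.5):
            raise ValueError("p_crit must lie in (0, 0.5)")
        if self.pair_scope not in {"interscaffold", "all"}:
            raise ValueError("pair_scope must be 'interscaffold' or 'all'")


def _pairwise_r2(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Burrows composite r^2 for every locus pair.

    ``g`` is individuals x loci with -1 for missing. Returns (r2, S)
    upper-triangle matrices where S is the per-pair number of jointly
    genotyped individuals. The composite disequilibrium is
    Delta = cov(X, Y) / 2 (with the S/(S-1) correction) and the
    denominator uses the observed half-variances p(1-p) + D_A, which
    makes r the dosage correlation with Weir's normalization.
    """
    m = (g >= 0).astype(float)
    x = np.where(g >= 0, g, 0).astype(float)
    n_ij = m.T @ m
    sx = x.T @ m  # sum of X over joint support
    sy = m.T @ x
    sxy = x.T @ x
    sxx = (x * x).T @ m
    syy = m.T @ (x * x)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sx / n_ij
        mean_y = sy / n_ij
        cov = sxy / n_ij - mean_x * mean_y
        var_x = sxx / n_ij - mean_x**2
        var_y = syy / n_ij - mean_y**2
        corr = (n_ij / (n_ij - 1.0)) * cov / np.sqrt(var_x * var_y)
    return corr**2, n_ij


def _nb_from_r2prime(r2p: float) -> float:
    """Random-mating quadratic inversion of E[r^2'] ~ f(N_b)."""
    if r2p <= 0:
        return np.inf
    disc = 1.0 / 9.0 - 2.76 * r2p
    if disc < 0:
        return np.inf
    return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2p)


def nb_ld(
    gm: GenotypeMatrix,
    cfg: NbLdConfig | None = None,
    compute_ci: bool = True,
) -> NbEstimate:
    """LD-based N_b from the mean Burrows composite r^2.

    Loci are screened at MAF >= p_crit; only interscaffold pairs enter
    by default. The mean r^2 (weighted by per-pair S) is bias-adjusted
    by the sample-size expectation 1/S + 3.19/S^2 (valid for S >= 30;
    smaller samples are rejected) and inverted under random mating.
    The CI is a delete-one jackknife over individuals on the 1/N_b
    scale.
    """
    cfg = cfg or NbLdConfig()
    freq = gm.observed_alt_freq()
    maf = np.minimum(freq, 1 - freq)
    keep = np.flatnonzero(maf >= cfg.p_crit)
    if len(keep) < 2:
        raise ValueError("fewer than 2 loci pass the MAF screen")
    sub = gm.subset_loci(keep)
    S_total = sub.n_samples
    if S_total < 30:
        raise ValueError("LD method requires at least 30 individuals (S >= 30 correction)")

    L = sub.n_loci
    iu, ju = np.triu_indices(L, k=1)
    if cfg.pair_scope == "interscaffold":
        scaf = sub.panel.scaffold
        pair_ok = scaf[iu] != scaf[ju]
    else:
        pair_ok = np.ones(len(iu), dtype=bool)
    if not pair_ok.any():
        raise ValueError("no eligible locus pairs under the configured scope")
    iu, ju = iu[pair_ok], ju[pair_ok]

    def mean_r2_nb(g: np.ndarray) -> tuple[float, float, float]:
        r2, n_ij = _pairwise_r2(g)
        r2p_pair, s_pair = r2[iu, ju], n_ij[iu, ju]
        ok = np.isfinite(r2p_pair) & (s_pair >= 30)
        w = s_pair[ok]
        r2_mean = float(np.average(r2p_pair[ok], weights=w))
        s_mean = float(np.average(s_pair[ok], weights=w))
        r2_adj = r2_mean - (1.0 / s_mean + 3.19 / s_mean**2)
        return r2_mean, r2_adj, _nb_from_r2prime(r2_adj)

    _, r2_adj, nb = mean_r2_nb(sub.genotypes)
    lo = hi = np.nan
    if compute_ci:
        thetas = []
        for i in range(S_total):
            g_i = np.delete(sub.genotypes, i, axis=0)
            if g_i.shape[0] < 30:
                raise ValueError("too few individuals for jackknife with S >= 30")
            nb_i = mean_r2_nb(g_i)[2]
            thetas.append(0.0 if np.isinf(nb_i) else 1.0 / nb_i)
        thetas = np.asarray(thetas)
        theta_hat = 0.0 if np.isinf(nb) else 1.0 / nb
        se = np.sqrt((S_total - 1) / S_total * np.sum((thetas - thetas.mean()) ** 2))
        from scipy.stats import norm

        z = norm.ppf(0.5 + cfg.ci_level / 2.0)
        t_lo, t_hi = theta_hat - z * se, theta_hat + z * se
        hi = np.inf if t_lo <= 0 else 1.0 / t_lo
        lo = np.inf if t_hi <= 0 else 1.0 / t_hi
        lo, hi = min(lo, hi), max(lo, hi)
    return NbEstimate(nb, float(lo), float(hi), "ld", S_total, r2_prime=r2_adj)


@dataclass
class PedigreeSummary:
    """Table-style per-cohort pedigree summary."""

    n_offspring: int
    n_s: int
    rs_mean: float
    rs_variance: float
    n_fs_dyads: int
    n_hs_dyads: int
    coancestry: float
    nb_sibship: NbEstimate | None = None
    nb_ld: NbEstimate | None = None


def summarize_pedigree(
    families: FamilySet,
    gm: GenotypeMatrix | None = None,
    nb_cfg: NbLdConfig | None = None,
    rng_seed: int = 0,
) -> PedigreeSummary:
    """Assemble the per-cohort summary from a family structure (and
    genotypes, when LD-based N_b is wanted)."""
    n = sum(len(f) for f in families.families)
    n_s = count_parents(families)
    rs_mean, rs_var = reproductive_success(families, n)
    pairs, sexed = _parent_pairs(families)
    n_fs = n_hs = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = len(set(pairs[i]) & set(pairs[j]))
            if s == 2:
                n_fs += 1
            elif s == 1:
                n_hs += 1
    theta = coancestry_from_counts(n, n_fs, n_hs) if n >= 2 else 0.0
    nb_sib = nb_sibship(families, rng_seed=rng_seed) if n >= 2 else None
    nb_ld_est = None
    if gm is not None and gm.n_samples >= 30:
        nb_ld_est = nb_ld(gm, nb_cfg, compute_ci=False)
    return PedigreeSummary(n, n_s, rs_mean, rs_var, n_fs, n_hs, theta, nb_sib, nb_ld_est)
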