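"""Population-genomic summaries: diversity, differentiation, DAPC-style
ordination, an outlier scan on a trimmed F_ST distribution, and paralog
QC statistics from heterozygote read depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2, rankdata
from statsmodels.stats.multitest import multipletests

from .containers import MISSING, GenotypeMatrix


def _per_pop_stats(gm: GenotypeMatrix, labels: np.ndarray):
    """Per (population, locus): sample size, ALT freq, observed het."""
    pops = np.unique(labels)
    n = np.zeros((len(pops), gm.n_loci))
    p = np.full((len(pops), gm.n_loci), np.nan)
    ho = np.full((len(pops), gm.n_loci), np.nan)
    for k, pop in enumerate(pops):
        g = gm.genotypes[labels == pop]
        called = g != MISSING
        nk = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nk > 0, np.where(g == MISSING, 0, g).sum(axis=0) / (2 * nk), np.nan)
            ho[k] = np.where(nk > 0, (g == 1).sum(axis=0) / nk, np.nan)
        n[k] = nk
    return pops, n, p, ho


def locus_diversity(gm: GenotypeMatrix, labels=None) -> pd.DataFrame:
    """Per locus x population H_o, unbiased H_e, F_IS and MAF.

    H_e uses the small-sample correction 2pq * 2n/(2n-1); F_IS is
    1 - H_o/H_e and is left missing (NaN) where H_e = 0 (monomorphic
    cell).
    """
    if labels is None:
        labels = gm.populations
        if labels is None:
            labels = np.array(["all"] * gm.n_samples, dtype=object)
    labels = np.asarray(labels, dtype=object)
    pops, n, p, ho = _per_pop_stats(gm, labels)
    rows = []
    for k, pop in enumerate(pops):
        nk, pk, hk = n[k], p[k], ho[k]
        with np.errstate(invalid="ignore", divide="ignore"):
            he = 2 * pk * (1 - pk) * (2 * nk) / (2 * nk - 1)
            he = np.where(nk >= 2, he, np.nan)
            fis = np.where(he > 0, 1 - hk / he, np.nan)
        for j in range(gm.n_loci):
            rows.append(
                {
                    "locus_id": gm.panel.locus_id[j],
                    "population": pop,
                    "n": int(nk[j]),
                    "maf": min(pk[j], 1 - pk[j]) if np.isfinite(pk[j]) else np.nan,
                    "ho": hk[j],
                    "he": he[j],
                    "fis": fis[j],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DifferentiationResult:
    pairwise_gst: pd.DataFrame
    global_gst: float
    per_locus_fst: np.ndarray
    per_locus_fst_nocorr: np.ndarray


def _nei_chesser(n, p, ho):
    """Nei & Chesser sample-size-corrected H_S and H_T per locus for a
    set of populations (arrays pop x locus). Returns (hs, ht,
    hs_nocorr, ht_nocorr); NaN where any population lacks data."""
    K = n.shape[0]
    valid = np.all(n >= 2, axis=0) & np.all(np.isfinite(p), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_harm = K / (1.0 / n).sum(axis=0)
        ho_bar = ho.mean(axis=0)
        hs_plug = 1.0 - (p**2 + (1 - p) ** 2).mean(axis=0)
        hs = (n_harm / (n_harm - 1.0)) * (hs_plug - ho_bar / (2.0 * n_harm))
        p_bar = p.mean(axis=0)
        ht_plug = 1.0 - (p_bar**2 + (1 - p_bar) ** 2)
        ht = ht_plug + hs / (n_harm * K) - ho_bar / (2.0 * n_harm * K)
    hs = np.where(valid, hs, np.nan)
    ht = np.where(valid, ht, np.nan)
    hs_nc = np.where(valid, hs_plug, np.nan)
    ht_nc = np.where(valid, ht_plug, np.nan)
    return hs, ht, hs_nc, ht_nc


def nei_differentiation(
    gm: GenotypeMatrix, labels=None, ratio_of_averages: bool = True
) -> DifferentiationResult:
    """Nei G_ST differentiation: pairwise matrix, multilocus global
    value, and per-locus F_ST vectors (with and without the
    Nei–Chesser sample-size correction; the uncorrected vector feeds
    the outlier scan).

    The multilocus statistic defaults to the ratio of averages,
    sum(H_T - H_S) / sum(H_T); set ``ratio_of_averages=False`` for the
    average of per-locus ratios.
    """
    if labels is None:
        labels = gm.populations
    labels = np.asarray(labels, dtype=object)
    pops, n, p, ho = _per_pop_stats(gm, labels)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")

    def multilocus(hs, ht):
        ok = np.isfinite(hs) & np.isfinite(ht)
        if ratio_of_averages:
            return float((ht[ok] - hs[ok]).sum() / ht[ok].sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = (ht[ok] - hs[ok]) / ht[ok]
        return float(np.nanmean(ratios))

    hs, ht, hs_nc, ht_nc = _nei_chesser(n, p, ho)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(ht > 0, (ht - hs) / ht, np.nan)
        per_locus_nc = np.where(ht_nc > 0, (ht_nc - hs_nc) / ht_nc, np.nan)
    global_gst = multilocus(hs, ht)

    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            idx = np.array([a, b])
            hs_p, ht_p, _, _ = _nei_chesser(n[idx], p[idx], ho[idx])
            val = multilocus(hs_p, ht_p)
            mat.iloc[a, b] = mat.iloc[b, a] = val
    return DifferentiationResult(mat, global_gst, per_locus, per_locus_nc)


@dataclass
class DAPCResult:
    coords: pd.DataFrame  # individuals x discriminant axes
    loading_percentiles: pd.DataFrame  # loci x axes, in [0, 100]
    loadings: pd.DataFrame
    explained_pc_variance: float
    _impute_means: np.ndarray = None
    _pca: object = None
    _lda: object = None

    def predict(self, genotypes: np.ndarray) -> np.ndarray:
        """Assign new dosage rows (missing as -1) to groups."""
        x = np.asarray(genotypes, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        x = np.where(x < 0, self._impute_means, x)
        return self._lda.predict(self._pca.transform(x))


def dapc_ordinate(gm: GenotypeMatrix, labels=None, n_pcs: int = 10) -> DAPCResult:
    """PCA followed by linear discriminant analysis on retained PCs.

    Missing dosages are mean-imputed per locus before centering (the
    standard deterministic choice). Per-locus discriminant loadings are
    back-projected through the PCA rotation and reported as percentile
    ranks of their absolute values, spanning [0, 100] per axis.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    if labels is None:
        labels = gm.populations
    labels = np.asarray(labels, dtype=object)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 groups")
    if n_pcs > min(gm.n_samples - 1, gm.n_loci):
        raise ValueError("n_pcs exceeds min(individuals - 1, loci)")
    x = gm.genotypes.astype(float)
    x[x == MISSING] = np.nan
    means = np.nanmean(x, axis=0)
    means = np.where(np.isfinite(means), means, 0.0)
    x = np.where(np.isnan(x), means, x)

    pca = PCA(n_components=n_pcs, svd_solver="full")
    pcs = pca.fit_transform(x)
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(pcs, labels)
    coords = lda.transform(pcs)
    axes = [f"LD{i + 1}" for i in range(coords.shape[1])]
    # back-project discriminant directions to locus space
    locus_loadings = pca.components_.T @ lda.scalings_[:, : coords.shape[1]]
    ranks = rankdata(np.abs(locus_loadings), axis=0)
    # min-max normalize so each axis spans exactly [0, 100] despite ties
    ranks = ranks - ranks.min(axis=0)
    pct = ranks / np.where(ranks.max(axis=0) > 0, ranks.max(axis=0), 1.0) * 100.0
    return DAPCResult(
        coords=pd.DataFrame(coords, index=gm.samples, columns=axes),
        loading_percentiles=pd.DataFrame(pct, index=gm.panel.locus_id, columns=axes),
        loadings=pd.DataFrame(locus_loadings, index=gm.panel.locus_id, columns=axes),
        explained_pc_variance=float(pca.explained_variance_ratio_.sum()),
        _impute_means=means,
        _pca=pca,
        _lda=lda,
    )


@dataclass
class OutlierScanResult:
    table: pd.DataFrame  # per locus: fst, fst_nocorr, p_value, q_value, outlier
    fst_bar: float
    df: float
    n_trimmed_fit: int

    @property
    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["outlier"]]


def outlier_scan(
    fst: np.ndarray,
    fst_nocorr: np.ndarray | None = None,
    trim: float = 0.05,
    fdr: float = 0.10,
    locus_id=None,
) -> OutlierScanResult:
    """Detect high-F_ST outliers against a trimmed neutral distribution.

    The neutral model takes locus F_ST * df / Fbar ~ chi-square(df);
    (Fbar, df) are fitted by maximum likelihood on the doubly truncated
    sample obtained by trimming ``trim`` of loci from each tail of the
    (uncorrected) F_ST distribution. Right-tail p-values are computed
    for all loci and thresholded by Benjamini–Hochberg at ``fdr``.
    """
    fst = np.asarray(fst, dtype=float)
    x_all = np.asarray(fst_nocorr, dtype=float) if fst_nocorr is not None else fst.copy()
    valid = np.isfinite(x_all)
    if valid.sum() < 50:
        raise ValueError("need at least 50 loci with finite F_ST for a stable fit")
    x = x_all[valid]
    lo, hi = np.quantile(x, [trim, 1.0 - trim])
    lo = max(lo, 1e-9)
    core = x[(x >= lo) & (x <= hi)]

    def nll(params):
        log_fbar, log_df = params
        fbar, df = np.exp(log_fbar), np.exp(log_df)
        scale = df / fbar
        denom = chi2.cdf(hi * scale, df) - chi2.cdf(lo * scale, df)
        if denom <= 0 or not np.isfinite(denom):
            return 1e12
        ll = chi2.logpdf(core * scale, df) + np.log(scale) - np.log(denom)
        return -float(ll.sum())

    fbar0 = core.mean()
    var0 = max(core.var(), 1e-12)
    df0 = np.clip(2.0 * fbar0**2 / var0, 0.5, 200.0)
    res = minimize(nll, x0=[np.log(fbar0), np.log(df0)], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        raise RuntimeError(f"trimmed chi-square fit did not converge: {res.message}")
    fbar, df = np.exp(res.x)

    p = np.full(len(x_all), np.nan)
    p[valid] = chi2.sf(x_all[valid] * df / fbar, df)
    q = np.full(len(x_all), np.nan)
    rej = np.zeros(len(x_all), dtype=bool)
    rej_v, q_v, _, _ = multipletests(p[valid], alpha=fdr, method="fdr_bh")[:4]
    q[valid] = q_v
    rej[valid] = rej_v
    if locus_id is None:
        locus_id = np.arange(len(x_all))
    table = pd.DataFrame(
        {
            "locus_id": np.asarray(locus_id, dtype=object),
            "fst": fst,
            "fst_nocorr": x_all,
            "p_value": p,
            "q_value": q,
            "outlier": rej,
        }
    )
    return OutlierScanResult(table, float(fbar), float(df), len(core))


@dataclass
class HDplotStats:
    table: pd.DataFrame  # per locus: H, D, n_het, flagged

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def hdplot(gm: GenotypeMatrix, h_max: float = 0.60, d_max: float = 7.0) -> HDplotStats:
    """Paralog screen from heterozygote allele depths.

    Per locus, H is the fraction of called genotypes that are
    heterozygous; D is the z-score of total ref vs alt reads summed
    over heterozygotes, (nA - nB)/sqrt(nA + nB) — a collapsed paralog
    shows H near 1 and/or a skewed read ratio. Flags H > h_max or
    |D| > d_max.
    """
    if gm.allele_depths is None:
        raise ValueError("allele-depth channel required")
    het = gm.genotypes == 1
    called = gm.genotypes != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        h = het.sum(axis=0) / called.sum(axis=0)
    ad = gm.allele_depths
    na = np.where(het[:, :, None].repeat(2, axis=2), ad, 0)[:, :, 0].sum(axis=0).astype(float)
    nb = np.where(het[:, :, None].repeat(2, axis=2), ad, 0)[:, :, 1].sum(axis=0).astype(float)
    tot = na + nb
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, (na - nb) / np.sqrt(tot), np.nan)
    flagged = (h > h_max) | (np.abs(d) > d_max)
    table = pd.DataFrame(
        {
            "locus_id": gm.panel.locus_id,
            "H": h,
            "D": d,
            "n_het": het.sum(axis=0),
            "flagged": flagged,
        }
    )
    return HDplotStats(table)


def allele_balance(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP mean heterozygote ref-read fraction (AB), with a flag
    for loci outside the [0.3, 0.7] band considered well-behaved."""
    if gm.allele_depths is None:
        raise ValueError("allele-depth channel required")
    tot = gm.allele_depths.sum(axis=2).astype(float)
    het = (gm.genotypes == 1) & (tot > 0)
    ref = gm.allele_depths[:, :, 0].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(het, ref / np.where(tot > 0, tot, 1.0), 0.0)
        n_het = het.sum(axis=0)
        ab = np.where(n_het > 0, frac.sum(axis=0) / n_het, np.nan)
    return pd.DataFrame(
        {
            "locus_id": gm.panel.locus_id,
            "ab": ab,
            "n_het": n_het,
            "in_band": (ab >= 0.3) & (ab <= 0.7),
        }
    )
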