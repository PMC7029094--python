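"""VCF / metadata I/O, genotype and site filtering, independent-locus
panel selection, family downsampling, and length-based age assignment.

The filter cascade mirrors standard RAD-capture QC: genotype-level GQ
masking, removal of high-missingness individuals, then site removal by
mean depth and missingness. Defaults: GQ >= 10, site mean depth >= 10x,
site missingness <= 30%, individual missingness <= 75% (50% for
population-genetic summaries). Independent loci for pedigree work are
spaced >= 2 Mb apart within scaffolds and genotyped in > 80% of
individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, LocusPanel

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with GT (and GQ/DP/AD when present).

    Panels carry no nucleotide alleles, so REF/ALT are written as A/C;
    dosages count the ALT allele.
    """
    have_gq = gm.gq is not None
    have_dp = gm.depth is not None
    have_ad = gm.allele_depths is not None
    fmt_keys = ["GT"] + (["GQ"] if have_gq else []) + (["DP"] if have_dp else []) + (
        ["AD"] if have_ad else []
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if have_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if have_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if have_ad:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">\n'
            )
        for scaf in dict.fromkeys(gm.panel.scaffold):
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gm.samples))
            + "\n"
        )
        for j in range(gm.n_loci):
            cells = []
            for i in range(gm.n_samples):
                parts = [_GT_STR[int(gm.genotypes[i, j])]]
                if have_gq:
                    parts.append(str(int(gm.gq[i, j])))
                if have_dp:
                    parts.append(str(int(gm.depth[i, j])))
                if have_ad:
                    parts.append(f"{int(gm.allele_depths[i, j, 0])},{int(gm.allele_depths[i, j, 1])}")
                cells.append(":".join(parts))
            fh.write(
                f"{gm.panel.scaffold[j]}\t{gm.panel.position[j]}\t{gm.panel.locus_id[j]}"
                f"\tA\tC\t.\tPASS\t.\t{':'.join(fmt_keys)}\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Load biallelic SNP records with GT/GQ/DP/AD channels via cyvcf2;
    multiallelic records are skipped (count reported via logging)."""
    import logging

    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = np.array(vcf.samples, dtype=object)
    n = len(samples)
    geno, gq, dp, ad = [], [], [], []
    loc_id, scaf, pos, freqs = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        dosage = np.array([0, 1, MISSING, 2], dtype=np.int8)[var.gt_types]
        geno.append(dosage)
        def fmt(key):
            try:
                return var.format(key)
            except KeyError:
                return None

        g = fmt("GQ")
        gq.append(None if g is None else np.nan_to_num(g.astype(float)).ravel()[:n])
        d = fmt("DP")
        dp.append(None if d is None else np.nan_to_num(d.astype(float)).ravel()[:n])
        a = fmt("AD")
        ad.append(None if a is None else np.nan_to_num(a.astype(float))[:, :2])
        loc_id.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        scaf.append(var.CHROM)
        pos.append(var.POS)
        called = dosage != MISSING
        freqs.append(dosage[called].sum() / (2 * called.sum()) if called.any() else 0.0)
    if n_multi:
        logging.getLogger(__name__).info("skipped %d multiallelic records", n_multi)
    panel = LocusPanel(
        np.array(loc_id, dtype=object),
        np.array(scaf, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(freqs, dtype=float),
    )
    genotypes = np.vstack(geno).T  # loci-major -> individuals x loci
    has_gq = all(g is not None for g in gq) and len(gq) > 0
    has_dp = all(d is not None for d in dp) and len(dp) > 0
    has_ad = all(a is not None for a in ad) and len(ad) > 0
    return GenotypeMatrix(
        samples,
        panel,
        genotypes.copy(),
        gq=np.vstack(gq).T.astype(np.int16) if has_gq else None,
        depth=np.vstack(dp).T.astype(np.int32) if has_dp else None,
        allele_depths=np.stack(ad, axis=0).transpose(1, 0, 2).astype(np.int32)
        if has_ad
        else None,
    )


def write_metadata(meta: pd.DataFrame, path: str) -> None:
    cols = ["sample_id", "population", "location", "length_mm", "cohort"]
    meta.reindex(columns=cols).to_csv(path, sep="\t", index=False)


def read_metadata(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


@dataclass
class FilterConfig:
    """QC thresholds; set any to None to disable that rule."""

    gq_min: float | None = 10
    site_mean_depth_min: float | None = 10
    site_missing_max: float | None = 0.30
    individual_missing_max: float | None = 0.75
    maf_min: float | None = None
    genotyping_rate_min: float = 0.80
    spacing_bp: int = 2_000_000


def apply_filters(gm: GenotypeMatrix, cfg: FilterConfig | None = None):
    """Apply the QC cascade; returns (filtered matrix, report).

    Order is fixed: (1) mask genotypes with GQ below ``gq_min``;
    (2) remove individuals whose missingness exceeds
    ``individual_missing_max``; (3) remove sites with mean depth below
    ``site_mean_depth_min``; (4) remove sites with missingness above
    ``site_missing_max``. The report counts changes at each stage.
    """
    cfg = cfg or FilterConfig()
    report = {
        "n_samples_in": gm.n_samples,
        "n_loci_in": gm.n_loci,
        "genotypes_masked_gq": 0,
        "individuals_removed": 0,
        "sites_removed_depth": 0,
        "sites_removed_missing": 0,
    }
    g = gm.genotypes.copy()
    if cfg.gq_min is not None and gm.gq is not None:
        mask = (gm.gq < cfg.gq_min) & (g != MISSING)
        report["genotypes_masked_gq"] = int(mask.sum())
        g = np.where(mask, MISSING, g).astype(np.int8)
    work = GenotypeMatrix(
        gm.samples, gm.panel, g, gq=gm.gq, depth=gm.depth,
        allele_depths=gm.allele_depths, populations=gm.populations,
    )
    if cfg.individual_missing_max is not None:
        missing = work.missing_mask().mean(axis=1)
        keep = missing <= cfg.individual_missing_max
        report["individuals_removed"] = int((~keep).sum())
        work = work.subset_samples(np.flatnonzero(keep))
    keep_sites = np.ones(work.n_loci, dtype=bool)
    if cfg.site_mean_depth_min is not None and work.depth is not None:
        mean_depth = work.depth.mean(axis=0)
        drop = mean_depth < cfg.site_mean_depth_min
        report["sites_removed_depth"] = int(drop.sum())
        keep_sites &= ~drop
    if cfg.site_missing_max is not None:
        site_missing = work.missing_mask().mean(axis=0)
        drop = keep_sites & (site_missing > cfg.site_missing_max)
        report["sites_removed_missing"] = int(drop.sum())
        keep_sites &= ~drop
    work = work.subset_loci(np.flatnonzero(keep_sites))
    report["n_samples_out"] = work.n_samples
    report["n_loci_out"] = work.n_loci
    return work, report


def select_independent_loci(
    panel: LocusPanel, gm: GenotypeMatrix | None = None, cfg: FilterConfig | None = None
) -> np.ndarray:
    """Greedy spacing selection of (approximately) independent loci.

    Per scaffold, sorted by position: keep the first eligible locus
    (genotyping rate above ``genotyping_rate_min`` and, when set, MAF
    at least ``maf_min``), then the next eligible locus at least
    ``spacing_bp`` away, and so on. Returns indices into the panel.
    """
    cfg = cfg or FilterConfig()
    eligible = np.ones(len(panel), dtype=bool)
    if gm is not None:
        rate = 1.0 - gm.missing_mask().mean(axis=0)
        eligible &= rate > cfg.genotyping_rate_min
    if cfg.maf_min is not None:
        eligible &= panel.maf >= cfg.maf_min
    chosen = []
    for scaf in dict.fromkeys(panel.scaffold):
        idx = np.flatnonzero((panel.scaffold == scaf) & eligible)
        idx = idx[np.argsort(panel.position[idx], kind="stable")]
        last = -np.inf
        for j in idx:
            if panel.position[j] >= last + cfg.spacing_bp:
                chosen.append(j)
                last = panel.position[j]
    return np.array(sorted(chosen), dtype=int)


def downsample_families(gm: GenotypeMatrix, families: list[list[str]]) -> GenotypeMatrix:
    """Keep a single member per full-sib family: the one with the
    highest call rate, ties broken by id order."""
    members = [m for fam in families for m in fam]
    if sorted(members) != sorted(gm.samples):
        raise ValueError("families must partition the matrix's individuals")
    pos = {s: i for i, s in enumerate(gm.samples)}
    rate = gm.call_rate()
    keep = []
    for fam in families:
        best = min(fam, key=lambda m: (-rate[pos[m]], m))
        keep.append(pos[best])
    return gm.subset_samples(np.array(sorted(keep), dtype=int))
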