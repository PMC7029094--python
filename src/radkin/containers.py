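"""Core in-memory containers shared across the package.

A SNP panel is a set of biallelic loci with genomic coordinates and an
ALT-allele frequency; genotypes are ALT-allele dosages (0/1/2, -1 for
missing) with optional per-cell quality (GQ), read depth (DP) and
ref/alt allele depths (AD), mirroring the VCF FORMAT fields the package
reads and writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel


@dataclass
class LocusPanel:
    """Biallelic SNP loci with coordinates and ALT-allele frequencies.

    Positions are 1-based (VCF convention). Monomorphic loci
    (``alt_freq`` of 0 or 1) are allowed; :meth:`monomorphic` flags them.
    """

    locus_id: np.ndarray
    scaffold: np.ndarray
    position: np.ndarray
    alt_freq: np.ndarray

    def __post_init__(self) -> None:
        self.locus_id = np.asarray(self.locus_id, dtype=object)
        self.scaffold = np.asarray(self.scaffold, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.alt_freq = np.asarray(self.alt_freq, dtype=float)
        n = len(self.locus_id)
        if not (len(self.scaffold) == len(self.position) == len(self.alt_freq) == n):
            raise ValueError("panel field lengths differ")
        if np.any(self.position <= 0):
            raise ValueError("positions must be strictly positive (1-based)")
        if np.any((self.alt_freq < 0) | (self.alt_freq > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        pairs = list(zip(self.scaffold, self.position))
        if len(set(pairs)) != n:
            raise ValueError("(scaffold, position) pairs must be unique")

    def __len__(self) -> int:
        return len(self.locus_id)

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency, min(p, 1 - p) of the ALT frequency."""
        return np.minimum(self.alt_freq, 1.0 - self.alt_freq)

    @property
    def ref_allele_freq(self) -> np.ndarray:
        return 1.0 - self.alt_freq

    def monomorphic(self) -> np.ndarray:
        return (self.alt_freq <= 0.0) | (self.alt_freq >= 1.0)

    def subset(self, idx) -> "LocusPanel":
        idx = np.asarray(idx)
        return LocusPanel(
            self.locus_id[idx], self.scaffold[idx], self.position[idx], self.alt_freq[idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_id,
                "scaffold": self.scaffold,
                "position": self.position,
                "alt_freq": self.alt_freq,
            }
        )


def make_panel(alt_freq, spacing_bp: int = 2_000_000, prefix: str = "L") -> LocusPanel:
    """Build a panel around given ALT frequencies with loci laid out
    ``spacing_bp`` apart on a single synthetic scaffold per block of 14
    (the panel emulates many large scaffolds, so default spacing makes
    loci mutually independent)."""
    alt_freq = np.asarray(alt_freq, dtype=float)
    n = len(alt_freq)
    per_scaf = 14
    scaffold = np.array([f"scaf{i // per_scaf + 1}" for i in range(n)], dtype=object)
    position = np.array(
        [1 + (i % per_scaf) * spacing_bp for i in range(n)], dtype=np.int64
    )
    locus_id = np.array([f"{prefix}{i + 1}" for i in range(n)], dtype=object)
    return LocusPanel(locus_id, scaffold, position, alt_freq)


@dataclass
class GenotypeMatrix:
    """Individuals x loci ALT-dosage matrix with sequencing channels.

    ``genotypes`` holds 0/1/2 dosages with ``MISSING`` (-1) for no-calls.
    ``gq`` (phred-like), ``depth`` and ``allele_depths`` (ref, alt reads)
    are optional channels aligned cell-for-cell with ``genotypes``.
    """

    samples: np.ndarray
    panel: LocusPanel
    genotypes: np.ndarray
    gq: np.ndarray | None = None
    depth: np.ndarray | None = None
    allele_depths: np.ndarray | None = None
    populations: np.ndarray | None = None  # optional per-sample labels

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.panel):
            raise ValueError("genotype matrix shape inconsistent with samples/panel")
        if not np.all(np.isin(self.genotypes, [-1, 0, 1, 2])):
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        for name in ("gq", "depth"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).shape != (n, m):
                raise ValueError(f"{name} shape mismatch")
        if self.allele_depths is not None and self.allele_depths.shape != (n, m, 2):
            raise ValueError("allele_depths must have shape (n, m, 2)")
        if self.allele_depths is not None and self.depth is not None:
            ad_sum = self.allele_depths.sum(axis=2)
            if not np.array_equal(ad_sum, np.asarray(self.depth)):
                raise ValueError("depth must equal ref_reads + alt_reads")
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("populations length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.panel)

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-sample fraction of called genotypes."""
        return 1.0 - self.missing_mask().mean(axis=1)

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            samples=self.samples[idx],
            genotypes=self.genotypes[idx],
            gq=None if self.gq is None else self.gq[idx],
            depth=None if self.depth is None else self.depth[idx],
            allele_depths=None if self.allele_depths is None else self.allele_depths[idx],
            populations=None if self.populations is None else self.populations[idx],
        )

    def subset_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            panel=self.panel.subset(idx),
            genotypes=self.genotypes[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            allele_depths=None if self.allele_depths is None else self.allele_depths[:, idx],
        )

    def observed_alt_freq(self) -> np.ndarray:
        """Per-locus ALT frequency from called genotypes (NaN if none)."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        freq = g.mean(axis=0) / 2.0
        return freq.filled(np.nan)


@dataclass
class TruePedigree:
    """Known offspring -> (mother, father) map from a simulation."""

    parents: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        offspring = set(self.parents)
        parent_ids = {p for pair in self.parents.values() for p in pair}
        if offspring & parent_ids:
            raise ValueError("parent ids must be disjoint from offspring ids")
        for o, pair in self.parents.items():
            if len(pair) != 2:
                raise ValueError(f"offspring {o} must have exactly two parents")

    def true_label(self, a: str, b: str) -> str:
        """FS if the pair shares both parents, HS exactly one, else U."""
        if a not in self.parents or b not in self.parents:
            raise KeyError(f"individual absent from pedigree: {a if a not in self.parents else b}")
        ma, pa = self.parents[a]
        mb, pb = self.parents[b]
        shared = int(ma == mb) + int(pa == pb)
        return {2: "FS", 1: "HS", 0: "U"}[shared]
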