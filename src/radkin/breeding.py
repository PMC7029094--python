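"""Polygamous breeding-matrix simulator for sibship power studies.

A breeding matrix is females x males with expected offspring counts per
pair. Each female mates with a Poisson(lambda) number of males (at least
one, at most the males available); her fecundity, uniform on
25,000-100,000 eggs, is split among mates on a descending triangular
schedule (a female's i-th mate of m receives the fraction
(m - i + 1) / (1 + 2 + ... + m), mate order shuffled). Males left
unmated then repeat the procedure with the sexes mirrored, so the
realized sex ratio is preserved. Sampled offspring carry their parents'
ids, giving a known pedigree against which sibship inference is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, TruePedigree


@dataclass
class SimConfig:
    """Parameters of one power-study cell."""

    n_parents: int = 100
    n_loci: int = 500
    n_offspring_sampled: int = 100
    sex_ratio_range: tuple[float, float] = (1.0, 2.0)
    mate_lambda: float = 3.0
    fecundity_range: tuple[float, float] = (25_000.0, 100_000.0)
    n_replicates: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents < 2:
            raise ValueError("n_parents must be >= 2")
        if self.sex_ratio_range[0] > self.sex_ratio_range[1]:
            raise ValueError("sex_ratio_range bounds out of order")
        if self.fecundity_range[0] > self.fecundity_range[1]:
            raise ValueError("fecundity_range bounds out of order")
        if self.mate_lambda <= 0:
            raise ValueError("mate_lambda must be > 0")


@dataclass
class BreedingMatrix:
    """Expected offspring counts per female (row) x male (column).

    ``primary`` marks the matings drawn in the female-initiated phase;
    cells added by the unmated-male completion pass are part of
    ``expected`` but not of ``primary``. Mate-number summaries report
    the primary phase (each female's own mate draw, and the male
    occupancy it induces), which is the mating-structure quantity the
    study design targets; ``realized_*`` variants count all cells.
    """

    female_ids: np.ndarray
    male_ids: np.ndarray
    expected: np.ndarray  # (n_females, n_males) non-negative reals
    fecundity: np.ndarray  # per-female row total (incl. remated-male shares)
    primary: np.ndarray | None = None  # bool mask of female-phase matings

    def __post_init__(self) -> None:
        nf, nm = self.expected.shape
        if nf != len(self.female_ids) or nm != len(self.male_ids):
            raise ValueError("matrix dimensions inconsistent with id lists")
        if np.any(self.expected < 0):
            raise ValueError("expected counts must be non-negative")
        if np.any(self.expected.sum(axis=1) <= 0):
            raise ValueError("every female must have at least one positive cell")
        if self.primary is None:
            self.primary = self.expected > 0

    @property
    def n_females(self) -> int:
        return len(self.female_ids)

    @property
    def n_males(self) -> int:
        return len(self.male_ids)

    def mates_per_female(self) -> np.ndarray:
        return self.primary.sum(axis=1)

    def mates_per_male(self) -> np.ndarray:
        return self.primary.sum(axis=0)

    def realized_mates_per_female(self) -> np.ndarray:
        return (self.expected > 0).sum(axis=1)

    def realized_mates_per_male(self) -> np.ndarray:
        return (self.expected > 0).sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.expected, index=self.female_ids, columns=self.male_ids)


def split_sexes(n_parents: int, sex_ratio_draw: float) -> tuple[int, int]:
    """Split parents into (females, males) at a males:females ratio.

    Rounds half-to-even and floors each sex at 1.
    """
    if n_parents < 2:
        raise ValueError("n_parents must be >= 2")
    n_females = int(np.round(n_parents / (1.0 + sex_ratio_draw)))
    n_females = min(max(n_females, 1), n_parents - 1)
    return n_females, n_parents - n_females


def allocate_offspring(n_offspring: float, n_mates: int) -> np.ndarray:
    """Descending triangular split of a parent's offspring among mates."""
    if n_mates < 1:
        raise ValueError("n_mates must be >= 1")
    if n_offspring < 0:
        raise ValueError("n_offspring must be >= 0")
    ranks = np.arange(n_mates, 0, -1, dtype=float)
    return n_offspring * ranks / ranks.sum()


def _draw_mates(rng: np.random.Generator, lam: float, n_available: int) -> np.ndarray:
    """Poisson(lam) mate count, clamped to [1, n_available]; mates chosen
    uniformly without replacement, order randomized."""
    k = max(1, min(int(rng.poisson(lam)), n_available))
    return rng.choice(n_available, size=k, replace=False)


def build_breeding_matrix(cfg: SimConfig, rng: np.random.Generator | int = 0) -> BreedingMatrix:
    rng = np.random.default_rng(rng)
    ratio = rng.uniform(*cfg.sex_ratio_range)
    n_f, n_m = split_sexes(cfg.n_parents, ratio)
    female_ids = np.array([f"F{i + 1}" for i in range(n_f)], dtype=object)
    male_ids = np.array([f"M{i + 1}" for i in range(n_m)], dtype=object)
    expected = np.zeros((n_f, n_m))
    for i in range(n_f):
        mates = _draw_mates(rng, cfg.mate_lambda, n_m)
        fec = rng.uniform(*cfg.fecundity_range)
        expected[i, mates] = allocate_offspring(fec, len(mates))
    primary = expected > 0
    # mirrored pass for males that drew no mate, preserving the sex ratio
    for j in np.flatnonzero(expected.sum(axis=0) == 0):
        mates = _draw_mates(rng, cfg.mate_lambda, n_f)
        fec = rng.uniform(*cfg.fecundity_range)
        expected[mates, j] += allocate_offspring(fec, len(mates))
    return BreedingMatrix(female_ids, male_ids, expected, expected.sum(axis=1), primary)


def sample_offspring(
    bm: BreedingMatrix, n_sampled: int, rng: np.random.Generator | int = 0
) -> tuple[pd.DataFrame, TruePedigree]:
    """Multinomial draw of offspring over matrix cells; offspring ids
    embed their parents' ids."""
    if n_sampled < 1:
        raise ValueError("n_sampled must be >= 1")
    total = bm.expected.sum()
    if total <= 0:
        raise ValueError("breeding matrix has no expected offspring")
    rng = np.random.default_rng(rng)
    probs = (bm.expected / total).ravel()
    counts = rng.multinomial(n_sampled, probs).reshape(bm.expected.shape)
    rows = []
    parents = {}
    k = 0
    for i, j in zip(*np.nonzero(counts)):
        mother, father = bm.female_ids[i], bm.male_ids[j]
        for _ in range(counts[i, j]):
            k += 1
            oid = f"O{k}_{mother}x{father}"
            rows.append((oid, mother, father))
            parents[oid] = (mother, father)
    df = pd.DataFrame(rows, columns=["offspring_id", "mother_id", "father_id"])
    return df, TruePedigree(parents)


def simulate_cohort(
    cfg: SimConfig, rng: np.random.Generator | int = 0, error_rate: float = 0.0
) -> tuple[GenotypeMatrix, TruePedigree, "object"]:
    """One replicate: panel, breeding matrix, parent genotypes, sampled
    offspring genotypes. Returns (offspring genotypes, truth, panel)."""
    from . import synthetic

    rng = np.random.default_rng(rng)
    panel = synthetic.draw_allele_frequencies(cfg.n_loci, rng_seed=rng)
    bm = build_breeding_matrix(cfg, rng)
    offs, truth = sample_offspring(bm, cfg.n_offspring_sampled, rng)
    parent_ids = np.concatenate([bm.female_ids, bm.male_ids])
    pg = rng.binomial(2, panel.alt_freq, size=(len(parent_ids), len(panel))).astype(np.int8)
    geno_of = {pid: pg[i] for i, pid in enumerate(parent_ids)}
    child = np.empty((len(offs), len(panel)), dtype=np.int8)
    for r, (oid, mid, fid) in enumerate(offs.itertuples(index=False)):
        child[r] = synthetic.mendelian_offspring(geno_of[mid], geno_of[fid], rng)
    gm = GenotypeMatrix(offs["offspring_id"].to_numpy(dtype=object), panel, child)
    if error_rate > 0:
        gm = synthetic.corrupt_genotypes(gm, error_rate=error_rate, rng_seed=rng)
    return gm, truth, panel


def run_power_study(
    design: list[SimConfig],
    rng_seed: int = 0,
    error_rate: float = 0.01,
    model_error: float | None = None,
) -> pd.DataFrame:
    """Run every replicate of every design cell through the in-repo
    sibship classifier and score dyad calls against the known pedigree.

    Returns one row per replicate x relationship class with accuracy and
    false-negative rate.
    """
    from .sibship import classify_dyads, confusion_metrics

    if not design:
        raise ValueError("design must be non-empty")
    if model_error is None:
        model_error = max(error_rate, 1e-4)
    rows = []
    for cfg in design:
        for rep in range(cfg.n_replicates):
            rng = np.random.default_rng((rng_seed, cfg.n_parents, cfg.n_loci, rep))
            gm, truth, panel = simulate_cohort(cfg, rng, error_rate=error_rate)
            calls = classify_dyads(gm, panel, error_rate=model_error,
                                   min_shared_loci=min(100, cfg.n_loci))
            conf = confusion_metrics(truth, calls)
            for cls in ("FS", "HS", "U"):
                rows.append(
                    {
                        "n_parents": cfg.n_parents,
                        "n_loci": cfg.n_loci,
                        "replicate": rep,
                        "relationship": cls,
                        "accuracy": conf.accuracy[cls],
                        "fnr": conf.fnr[cls],
                    }
                )
    return pd.DataFrame(rows)


def full_design(
    parent_levels=(10, 100, 1000), locus_levels=(100, 200, 500), n_replicates: int = 100
) -> list[SimConfig]:
    """The 3 x 3 x replicates experimental design (900 datasets at the
    study's 100 replicates per cell)."""
    return [
        SimConfig(n_parents=p, n_loci=l, n_replicates=n_replicates)
        for p in parent_levels
        for l in locus_levels
    ]
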