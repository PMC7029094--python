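"""Pairwise likelihood classification of sibling dyads.

Each unordered pair of individuals is classified as full siblings (FS),
half siblings (HS) or unrelated (U) by maximum likelihood over the
Cotterman IBD-coefficient models

    FS: (k0, k1, k2) = (0.25, 0.5, 0.25)
    HS: (0.5, 0.5, 0)
    U : (1, 0, 0)

assuming known allele frequencies and Hardy–Weinberg parental
genotypes. Genotyping error enters as a genotype-level mixture: with
probability eps an observed genotype is an independent Hardy–Weinberg
draw. This composite pairwise classifier plays the role a joint
full-likelihood sibship partitioner (e.g. COLONY) plays in field
studies; it is a methodological substitute whose acceptance surface is
per-dyad accuracy, not a re-implementation of such software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, LocusPanel, TruePedigree

LABELS = ("U", "HS", "FS")  # argmax order = tie-break toward less related

K_COEFFS = {
    "FS": (0.25, 0.5, 0.25),
    "HS": (0.5, 0.5, 0.0),
    "U": (1.0, 0.0, 0.0),
}


@dataclass
class RelationshipModel:
    """One relationship hypothesis: IBD coefficients plus error rate."""

    label: str
    k0: float
    k1: float
    k2: float
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-12:
            raise ValueError("k coefficients must sum to 1")
        if min(self.k0, self.k1, self.k2) < 0:
            raise ValueError("k coefficients must be non-negative")
        if not (0 <= self.error_rate <= 0.1):
            raise ValueError("error rate must lie in [0, 0.1]")


def default_models(error_rate: float = 0.0) -> list[RelationshipModel]:
    return [RelationshipModel(lbl, *K_COEFFS[lbl], error_rate=error_rate) for lbl in LABELS]


def _joint_tables(alt_freq: np.ndarray) -> np.ndarray:
    """Joint dosage probability tables by number of IBD alleles.

    Returns an array J of shape (3, L, 3, 3): J[m, l, g1, g2] is the
    probability of observing dosages (g1, g2) at locus l given that the
    pair shares m alleles identical by descent, under HWE.
    Derivation by enumeration of transmitted alleles: with shared
    alleles a (and b for m=2) and private alleles drawn Bernoulli(p).
    """
    p = np.asarray(alt_freq, dtype=float)
    L = len(p)
    pa = np.stack([1 - p, p], axis=0)  # allele probs, shape (2, L)
    hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)  # (L, 3)

    J = np.zeros((3, L, 3, 3))
    # m = 0: independent HWE genotypes
    J[0] = hwe[:, :, None] * hwe[:, None, :]
    # m = 1: g1 = a + b, g2 = a + c with a shared, b,c private
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                J[1, :, a + b, a + c] += pa[a] * pa[b] * pa[c]
    # m = 2: identical genotypes at HWE marginal
    for g in (0, 1, 2):
        J[2, :, g, g] = hwe[:, g]
    return J


def locus_log_tables(
    panel: LocusPanel, models: list[RelationshipModel] | None = None, error_rate: float = 0.0
) -> tuple[np.ndarray, list[str]]:
    """Per-model log joint-probability tables, shape (n_models, L, 3, 3).

    The error mixture acts symmetrically on both genotypes: the joint
    table becomes (1-eps)^2 * J_model + (1 - (1-eps)^2) * J_U because a
    genotype replaced by an independent HWE draw is distributed exactly
    as an unrelated genotype.
    """
    if models is None:
        models = default_models(error_rate)
    p = np.clip(panel.alt_freq, 1e-6, 1 - 1e-6)  # keep logs finite
    J = _joint_tables(p)
    out = []
    labels = []
    for m in models:
        table = m.k0 * J[0] + m.k1 * J[1] + m.k2 * J[2]
        keep = (1.0 - m.error_rate) ** 2
        table = keep * table + (1.0 - keep) * J[0]
        out.append(np.log(table))
        labels.append(m.label)
    return np.stack(out, axis=0), labels


def dyad_loglik(
    g1: np.ndarray,
    g2: np.ndarray,
    panel: LocusPanel,
    model: RelationshipModel,
) -> float:
    """Log-likelihood of one relationship for one pair; loci where
    either genotype is missing are skipped."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 >= 0) & (g2 >= 0)
    if not ok.any():
        raise ValueError("no jointly non-missing loci")
    logt, _ = locus_log_tables(panel, [model])
    idx = np.flatnonzero(ok)
    return float(logt[0, idx, g1[idx], g2[idx]].sum())


def classify_dyads(
    gm: GenotypeMatrix,
    panel: LocusPanel | None = None,
    models: list[RelationshipModel] | None = None,
    error_rate: float = 0.0,
    min_shared_loci: int = 100,
) -> pd.DataFrame:
    """Classify every unordered pair of individuals.

    Returns a frame with columns id1, id2, n_loci, llFS, llHS, llU and
    ``call`` (argmax label; ties resolved toward the less-related
    label; pairs with fewer than ``min_shared_loci`` jointly called
    loci are labelled "uncalled").

    The computation is one-hot: with O[i, l, g] = 1 when individual i
    carries dosage g at locus l (all-zero row when missing), the
    log-likelihood matrix for a model with table T is
    einsum('ilg,lgh,jlh->ij', O, T, O) — missing loci drop out.
    """
    if panel is None:
        panel = gm.panel
    n = gm.n_samples
    if n < 2:
        return pd.DataFrame(columns=["id1", "id2", "n_loci", "llFS", "llHS", "llU", "call"])
    logt, labels = locus_log_tables(panel, models, error_rate)
    g = gm.genotypes
    L = len(panel)
    onehot = np.zeros((n, L, 3))
    for d in range(3):
        onehot[:, :, d] = g == d
    mask = (g >= 0).astype(float)
    n_shared = mask @ mask.T

    ll = np.empty((len(labels), n, n))
    for k in range(len(labels)):
        a = np.einsum("ilg,lgh->ilh", onehot, logt[k])
        ll[k] = a.reshape(n, -1) @ onehot.reshape(n, -1).T

    iu, ju = np.triu_indices(n, k=1)
    cols = {lbl: ll[k][iu, ju] for k, lbl in enumerate(labels)}
    present = [lbl for lbl in LABELS if lbl in labels]
    stacked = np.stack([ll[labels.index(lbl)][iu, ju] for lbl in present], axis=1)
    call_idx = np.argmax(stacked, axis=1)  # first max -> least-related wins ties
    calls = np.array([present[c] for c in call_idx], dtype=object)
    ns = n_shared[iu, ju].astype(int)
    calls[ns < min_shared_loci] = "uncalled"
    return pd.DataFrame(
        {
            "id1": gm.samples[iu],
            "id2": gm.samples[ju],
            "n_loci": ns,
            "llFS": cols.get("FS", np.nan),
            "llHS": cols.get("HS", np.nan),
            "llU": cols.get("U", np.nan),
            "call": calls,
        }
    )


@dataclass
class FamilySet:
    """Full-sib families plus half-sib links between families."""

    families: list[list[str]]
    hs_links: list[tuple[int, int]]

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_of(self) -> dict[str, int]:
        return {m: i for i, fam in enumerate(self.families) for m in fam}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"family_id": f"fam{i + 1}", "sample_id": m}
            for i, fam in enumerate(self.families)
            for m in fam
        ]
        return pd.DataFrame(rows)


def cluster_families(calls: pd.DataFrame, hs_link_threshold: float = 0.5) -> FamilySet:
    """Group individuals into full-sib families from dyad calls.

    Families are connected components of FS edges after transitivity
    repair: while a component's mean internal FS margin
    (llFS - max(llHS, llU), over all internal pairs) is negative, its
    weakest FS edge is demoted and components are recomputed. The
    result is deterministic given the calls. Half-sib links join family
    pairs whose cross-dyads are called HS in more than
    ``hs_link_threshold`` of cases.
    """
    import networkx as nx

    ids = sorted(set(calls["id1"]).union(calls["id2"]))
    margin = {}
    label = {}
    for row in calls.itertuples(index=False):
        key = (row.id1, row.id2) if row.id1 <= row.id2 else (row.id2, row.id1)
        margin[key] = row.llFS - max(row.llHS, row.llU)
        label[key] = row.call

    fs_edges = {k for k, lbl in label.items() if lbl == "FS"}
    while True:
        graph = nx.Graph()
        graph.add_nodes_from(ids)
        graph.add_edges_from(fs_edges)
        bad_edge = None
        worst = 0.0
        for comp in nx.connected_components(graph):
            comp = sorted(comp)
            if len(comp) < 2:
                continue
            pairs = [
                (a, b) for i, a in enumerate(comp) for b in comp[i + 1:] if (a, b) in margin
            ]
            mean_margin = float(np.mean([margin[p] for p in pairs]))
            if mean_margin < worst:
                comp_edges = [e for e in fs_edges if e[0] in comp and e[1] in comp]
                weakest = min(comp_edges, key=lambda e: (margin[e], e))
                worst = mean_margin
                bad_edge = weakest
        if bad_edge is None:
            break
        fs_edges.discard(bad_edge)

    families = [sorted(c) for c in nx.connected_components(graph)]
    families.sort(key=lambda fam: fam[0])
    fam_of = {m: i for i, fam in enumerate(families) for m in fam}

    cross_hs: dict[tuple[int, int], list[int]] = {}
    for key, lbl in label.items():
        fi, fj = fam_of[key[0]], fam_of[key[1]]
        if fi == fj:
            continue
        pair = (min(fi, fj), max(fi, fj))
        cross_hs.setdefault(pair, []).append(1 if lbl == "HS" else 0)
    hs_links = sorted(
        pair for pair, votes in cross_hs.items() if np.mean(votes) > hs_link_threshold
    )
    return FamilySet(families, hs_links)


@dataclass
class DyadConfusion:
    """3x3 true x inferred counts with per-class accuracy and FNR."""

    counts: pd.DataFrame  # index true, columns inferred
    accuracy: dict[str, float]
    fnr: dict[str, float]


def confusion_metrics(truth: TruePedigree, calls: pd.DataFrame) -> DyadConfusion:
    """Score dyad calls against a known pedigree.

    accuracy(class) = correctly assigned / all dyads inferred as that
    class; FNR(class) = incorrectly inferred / all true dyads of that
    class. Uncalled pairs are excluded.
    """
    called = calls[calls["call"] != "uncalled"]
    true_lbl = np.array(
        [truth.true_label(a, b) for a, b in zip(called["id1"], called["id2"])], dtype=object
    )
    inferred = called["call"].to_numpy()
    classes = list(LABELS)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, f in zip(true_lbl, inferred):
        counts.loc[t, f] += 1
    accuracy = {}
    fnr = {}
    for cls in classes:
        n_inf = counts[cls].sum()
        accuracy[cls] = counts.loc[cls, cls] / n_inf if n_inf else np.nan
        n_true = counts.loc[cls].sum()
        fnr[cls] = (n_true - counts.loc[cls, cls]) / n_true if n_true else np.nan
    return DyadConfusion(counts, accuracy, fnr)
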