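"""Dyad likelihoods against brute-force enumeration, classification on
simulated families, family clustering, and confusion metrics."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from radkin import synthetic
from radkin.containers import GenotypeMatrix, LocusPanel, TruePedigree
from radkin.sibship import (
    K_COEFFS,
    RelationshipModel,
    classify_dyads,
    cluster_families,
    confusion_metrics,
    dyad_loglik,
)


def enumerate_pair_prob(g1: int, g2: int, p: float, label: str) -> float:
    """Independent oracle: enumerate the two parental genotype pairs
    shared under each relationship and their Mendelian offspring.

    FS: one shared couple; HS: one shared parent, two private; U: two
    independent couples. Sums P(parents) * P(g1|parents) * P(g2|parents).
    """

    def hwe(g):
        return {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}[g]

    def trans(parent_g, allele):
        # P(transmitting `allele` | parent dosage)
        pr_alt = parent_g / 2
        return pr_alt if allele == 1 else 1 - pr_alt

    def child_prob(g, mom, dad):
        return sum(
            trans(mom, a) * trans(dad, b) for a, b in product((0, 1), (0, 1)) if a + b == g
        )

    total = 0.0
    gs = (0, 1, 2)
    if label == "FS":
        for mom, dad in product(gs, gs):
            total += hwe(mom) * hwe(dad) * child_prob(g1, mom, dad) * child_prob(g2, mom, dad)
    elif label == "HS":
        for shared, d1, d2 in product(gs, gs, gs):
            total += (
                hwe(shared)
                * hwe(d1)
                * hwe(d2)
                * child_prob(g1, shared, d1)
                * child_prob(g2, shared, d2)
            )
    else:
        total = hwe(g1) * hwe(g2)
    return total


class TestDyadLoglik:
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.8])
    @pytest.mark.parametrize("label", ["FS", "HS", "U"])
    def test_oracle_equivalence_single_locus(self, single_locus_panel, p, label):
        panel = single_locus_panel(p)
        model = RelationshipModel(label, *K_COEFFS[label])
        for g1, g2 in product((0, 1, 2), repeat=2):
            ll = dyad_loglik(np.array([g1]), np.array([g2]), panel, model)
            expected = enumerate_pair_prob(g1, g2, p, label)
            assert np.exp(ll) == pytest.approx(expected, rel=1e-9)

    def test_two_locus_product(self, single_locus_panel):
        panel = LocusPanel(
            np.array(["a", "b"], dtype=object),
            np.array(["s1", "s2"], dtype=object),
            np.array([1, 1]),
            np.array([0.3, 0.7]),
        )
        model = RelationshipModel("FS", *K_COEFFS["FS"])
        ll = dyad_loglik(np.array([1, 2]), np.array([0, 2]), panel, model)
        expected = enumerate_pair_prob(1, 0, 0.3, "FS") * enumerate_pair_prob(2, 2, 0.7, "FS")
        assert np.exp(ll) == pytest.approx(expected, rel=1e-12)

    def test_known_values_half_frequency(self, single_locus_panel):
        panel = single_locus_panel(0.5)
        u = dyad_loglik(np.array([0]), np.array([0]), panel, RelationshipModel("U", 1, 0, 0))
        fs = dyad_loglik(
            np.array([0]), np.array([0]), panel, RelationshipModel("FS", 0.25, 0.5, 0.25)
        )
        assert np.exp(u) == pytest.approx(0.0625, abs=1e-12)
        assert np.exp(fs) == pytest.approx(0.140625, abs=1e-12)

    def test_exchangeability(self, single_locus_panel):
        panel = single_locus_panel(0.27)
        model = RelationshipModel("HS", *K_COEFFS["HS"], error_rate=0.01)
        for g1, g2 in product((0, 1, 2), repeat=2):
            a = dyad_loglik(np.array([g1]), np.array([g2]), panel, model)
            b = dyad_loglik(np.array([g2]), np.array([g1]), panel, model)
            assert a == b

    def test_true_full_sibs_beat_unrelated(self):
        panel = synthetic.draw_allele_frequencies(500, rng_seed=21)
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            parents = synthetic.hwe_parent_genotypes(panel, 2, rng_seed=rng)
            c1 = synthetic.mendelian_offspring(parents.genotypes[0], parents.genotypes[1], rng)
            c2 = synthetic.mendelian_offspring(parents.genotypes[0], parents.genotypes[1], rng)
            fs = dyad_loglik(c1, c2, panel, RelationshipModel("FS", *K_COEFFS["FS"]))
            u = dyad_loglik(c1, c2, panel, RelationshipModel("U", *K_COEFFS["U"]))
            wins += fs > u
        assert wins == 20

    def test_all_missing_rejected(self, single_locus_panel):
        panel = single_locus_panel(0.5)
        with pytest.raises(ValueError):
            dyad_loglik(np.array([-1]), np.array([0]), panel, RelationshipModel("U", 1, 0, 0))


class TestClassifyDyads:
    def test_identical_twins_called_fs(self):
        panel = synthetic.draw_allele_frequencies(300, rng_seed=31)
        g = synthetic.hwe_parent_genotypes(panel, 1 + 1, rng_seed=31).genotypes
        gm = GenotypeMatrix(
            np.array(["a", "b"], dtype=object), panel, np.vstack([g[0], g[0]])
        )
        calls = classify_dyads(gm, min_shared_loci=10)
        assert calls.loc[0, "call"] == "FS"

    def test_single_individual_empty(self):
        panel = synthetic.draw_allele_frequencies(10, rng_seed=0)
        gm = synthetic.hwe_parent_genotypes(panel, 2, rng_seed=0).subset_samples([0])
        assert classify_dyads(gm, min_shared_loci=1).empty

    def test_call_maximizes_loglik(self):
        panel = synthetic.draw_allele_frequencies(200, rng_seed=41)
        gm = synthetic.hwe_parent_genotypes(panel, 6, rng_seed=41)
        calls = classify_dyads(gm, min_shared_loci=10)
        lls = calls[["llU", "llHS", "llFS"]].to_numpy()
        best = lls.max(axis=1)
        for row, b in zip(calls.itertuples(index=False), best):
            assert {"U": row.llU, "HS": row.llHS, "FS": row.llFS}[row.call] == b

    def test_below_min_shared_loci_uncalled(self):
        panel = synthetic.draw_allele_frequencies(50, rng_seed=5)
        gm = synthetic.hwe_parent_genotypes(panel, 3, rng_seed=5)
        g = gm.genotypes.copy()
        g[0, 25:] = -1
        g[1, :25] = -1  # pair (0,1) shares zero loci
        gm2 = GenotypeMatrix(gm.samples, panel, g)
        calls = classify_dyads(gm2, min_shared_loci=10)
        pair = calls[(calls.id1 == "P1") & (calls.id2 == "P2")].iloc[0]
        assert pair["call"] == "uncalled"

    def test_simulated_family_accuracy(self):
        """FS and U dyads from simulated polygamous families are almost
        always recovered with 500 loci."""
        from radkin.breeding import SimConfig, simulate_cohort

        accs = {"FS": [], "U": []}
        for rep in range(3):
            cfg = SimConfig(n_parents=100, n_loci=500, n_offspring_sampled=60)
            gm, truth, panel = simulate_cohort(cfg, rng_seed := (50 + rep), error_rate=0.01)
            calls = classify_dyads(gm, error_rate=0.01, min_shared_loci=100)
            conf = confusion_metrics(truth, calls)
            for cls in ("FS", "U"):
                if not np.isnan(conf.accuracy[cls]):
                    accs[cls].append(conf.accuracy[cls])
        assert np.mean(accs["U"]) >= 0.95
        if accs["FS"]:
            assert np.mean(accs["FS"]) >= 0.9


class TestClusterFamilies:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["id1", "id2", "n_loci", "llFS", "llHS", "llU", "call"])

    def test_clique_merges(self):
        calls = self._calls(
            [
                ("A", "B", 100, -1.0, -5.0, -9.0, "FS"),
                ("B", "C", 100, -1.0, -5.0, -9.0, "FS"),
                ("A", "C", 100, -1.0, -5.0, -9.0, "FS"),
            ]
        )
        fams = cluster_families(calls)
        assert fams.families == [["A", "B", "C"]]

    def test_transitivity_conflict_resolved_deterministically(self):
        # A-B and B-C called FS, but A-C strongly U: the component vote
        # decides; rerunning yields the same partition.
        calls = self._calls(
            [
                ("A", "B", 100, -1.0, -5.0, -9.0, "FS"),
                ("B", "C", 100, -2.0, -5.0, -9.0, "FS"),
                ("A", "C", 100, -50.0, -20.0, -1.0, "U"),
            ]
        )
        out1 = cluster_families(calls)
        out2 = cluster_families(calls)
        assert out1.families == out2.families
        sizes = sorted(len(f) for f in out1.families)
        assert sizes in ([1, 2], [3])

    def test_no_edges_all_singletons(self):
        rows = []
        ids = [f"x{i}" for i in range(33)]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append((ids[i], ids[j], 100, -9.0, -5.0, -1.0, "U"))
        fams = cluster_families(self._calls(rows))
        assert fams.n_families == 33
        assert all(len(f) == 1 for f in fams.families)

    def test_hs_link_between_families(self):
        calls = self._calls(
            [
                ("A", "B", 100, -1.0, -5.0, -9.0, "FS"),
                ("C", "D", 100, -1.0, -5.0, -9.0, "FS"),
                ("A", "C", 100, -5.0, -1.0, -9.0, "HS"),
                ("A", "D", 100, -5.0, -1.0, -9.0, "HS"),
                ("B", "C", 100, -5.0, -1.0, -9.0, "HS"),
                ("B", "D", 100, -5.0, -1.0, -9.0, "HS"),
            ]
        )
        fams = cluster_families(calls)
        assert fams.n_families == 2
        assert fams.hs_links == [(0, 1)]


class TestConfusionMetrics:
    def _truth(self):
        parents = {}
        # one FS family of 5 -> 10 FS dyads; rest unrelated
        for i in range(5):
            parents[f"f{i}"] = ("M", "D")
        for i in range(5):
            parents[f"u{i}"] = (f"Mu{i}", f"Du{i}")
        return TruePedigree(parents)

    def test_perfect_calls(self):
        truth = self._truth()
        ids = sorted(truth.parents)
        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                lbl = truth.true_label(ids[i], ids[j])
                rows.append((ids[i], ids[j], 100, 0.0, 0.0, 0.0, lbl))
        calls = pd.DataFrame(rows, columns=["id1", "id2", "n_loci", "llFS", "llHS", "llU", "call"])
        conf = confusion_metrics(truth, calls)
        assert conf.accuracy["FS"] == 1.0 and conf.fnr["FS"] == 0.0
        assert conf.accuracy["U"] == 1.0 and conf.fnr["U"] == 0.0

    def test_definitional_arithmetic(self):
        truth = TruePedigree(
            {f"a{i}": ("M", "D") for i in range(5)}  # C(5,2)=10 FS dyads
        )
        ids = sorted(truth.parents)
        rows = []
        k = 0
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                call = "FS" if k < 7 else "U"  # miss 3 of 10 true FS
                rows.append((ids[i], ids[j], 100, 0.0, 0.0, 0.0, call))
                k += 1
        calls = pd.DataFrame(rows, columns=["id1", "id2", "n_loci", "llFS", "llHS", "llU", "call"])
        conf = confusion_metrics(truth, calls)
        assert conf.fnr["FS"] == pytest.approx(0.3)
        assert conf.accuracy["FS"] == 1.0  # every inferred FS is truly FS

    def test_unknown_individual_rejected(self):
        truth = TruePedigree({"a": ("M", "D"), "b": ("M", "D")})
        calls = pd.DataFrame(
            [("a", "zzz", 100, 0.0, 0.0, 0.0, "FS")],
            columns=["id1", "id2", "n_loci", "llFS", "llHS", "llU", "call"],
        )
        with pytest.raises(KeyError):
            confusion_metrics(truth, calls)
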