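"""Tip trait imputation, pigment filtering, PD clustering, tree robustness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from conftest import enum_tip_marginal, random_tree
from traitscape import (classify_spore_pigment, assign_chemotypes,
                        estimate_tip_trait, faith_pd, trait_clustering_score,
                        assignment_consistency)
from traitscape._flat import FlatTree
from traitscape.exceptions import EstimationError, ValidationError
from traitscape.phylo_io import ReferenceAnnotations, parse_newick
from traitscape.synthetic_data import (LandscapeConfig, simulate_landscape,
                                       simulate_tree)
from traitscape.trait_inference import TraitProbabilities


def _refs(chemos: dict[str, str]) -> ReferenceAnnotations:
    return ReferenceAnnotations({k: "antibiotic" for k in chemos}, dict(chemos))


class TestEstimateTipTrait:
    def test_zero_distance_to_monolabel_clade(self):
        # query glued (0-length) to an A-labeled clade, B far away
        tree = parse_newick(
            "(((q:0.0,r1:0.0):0.01,(r2:0.01,r3:0.01):0.01):5,(r4:0.1,r5:0.1):5);")
        refs = _refs({"r1": "A", "r2": "A", "r3": "A", "r4": "B", "r5": "B"})
        est = estimate_tip_trait(tree, refs, "q", "chemotype")
        assert est.probabilities["A"] >= 0.99

    def test_long_pendant_goes_uniform(self):
        tree = parse_newick("((q:500,r1:0.1):0.1,(r2:0.1,r3:0.1):0.1);")
        refs = _refs({"r1": "A", "r2": "B", "r3": "B"})
        est = estimate_tip_trait(tree, refs, "q", "chemotype")
        np.testing.assert_allclose(est.probabilities.to_numpy(), 0.5, atol=0.01)

    def test_symmetric_query_gets_equal_probabilities(self):
        tree = parse_newick("((r1:1,q:1):1,r2:2);")
        refs = _refs({"r1": "A", "r2": "B"})
        est = estimate_tip_trait(tree, refs, "q", "chemotype")
        assert est.probabilities["A"] == pytest.approx(est.probabilities["B"],
                                                       abs=1e-9)

    def test_annotated_query_rejected(self):
        tree = parse_newick("((r1:1,q:1):1,r2:2);")
        refs = _refs({"r1": "A", "r2": "B", "q": "A"})
        with pytest.raises(EstimationError):
            estimate_tip_trait(tree, refs, "q", "chemotype")

    def test_single_label_rejected(self):
        tree = parse_newick("((r1:1,q:1):1,r2:2);")
        refs = _refs({"r1": "A", "r2": "A"})
        with pytest.raises(EstimationError):
            estimate_tip_trait(tree, refs, "q", "chemotype")

    def test_five_reference_toy_matches_enumeration(self):
        """Fixed topology and q: imputation equals the full Bayes marginal."""
        from traitscape.mk_model import ErModel, marginal_tip_probabilities

        tree = parse_newick(
            "(((q:0.4,r1:0.3):0.2,(r2:0.5,r3:0.2):0.3):0.4,(r4:0.6,r5:0.1):0.2);")
        flat = FlatTree.from_dendropy(tree)
        states = {"r1": 0, "r2": 0, "r3": 0, "r4": 1, "r5": 1, "q": None}
        for q_rate in (0.2, 0.7):
            ours = marginal_tip_probabilities(flat, states,
                                              ErModel(k=2, q=q_rate), "q")
            oracle = enum_tip_marginal(flat, states, 2, q_rate, "q")
            np.testing.assert_allclose(ours, oracle, atol=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_match_enumeration(self, seed):
        """End-to-end estimate (prune + fit + marginal) equals enumeration
        run at the fitted rate on the pruned, unrerooted tree."""
        rng = np.random.default_rng(3000 + seed)
        flat = random_tree(rng, 8)
        labels = [flat.labels[i] for i in flat.tip_ids]
        query = labels[0]
        ref_labels = labels[1:]
        chemos = {r: ("A" if i < 4 else "B")
                  for i, r in enumerate(ref_labels)}
        refs = _refs(chemos)
        est = estimate_tip_trait(flat, refs, query, "chemotype")
        sub = flat.induced([query] + ref_labels)
        states = {r: {"A": 0, "B": 1}[chemos[r]] for r in ref_labels}
        states[query] = None
        oracle = enum_tip_marginal(sub, states, 2, est.fit.q_hat, query)
        np.testing.assert_allclose(est.probabilities.to_numpy(), oracle,
                                   atol=1e-8)

    def test_pendant_length_monotone_toward_uniform(self):
        refs = _refs({"r1": "A", "r2": "A", "r3": "B"})
        prev_gap = None
        for t in (0.01, 0.1, 0.5, 1.0, 3.0, 10.0):
            tree = parse_newick(
                f"((q:{t},r1:0.1):0.2,(r2:0.1,r3:0.6):0.2);")
            est = estimate_tip_trait(tree, refs, "q", "chemotype")
            gap = abs(est.probabilities["A"] - 0.5)
            if prev_gap is not None:
                assert gap <= prev_gap + 1e-12
            prev_gap = gap

    def test_label_permutation_equivariance(self):
        tree = parse_newick(
            "(((q:0.4,r1:0.3):0.2,(r2:0.5,r3:0.2):0.3):0.4,(r4:0.6,r5:0.1):0.2);")
        chemos = {"r1": "A", "r2": "A", "r3": "B", "r4": "B", "r5": "C"}
        est = estimate_tip_trait(tree, _refs(chemos), "q", "chemotype")
        swapped = {r: {"A": "C", "B": "B", "C": "A"}[c]
                   for r, c in chemos.items()}
        est2 = estimate_tip_trait(tree, _refs(swapped), "q", "chemotype")
        assert est.probabilities["A"] == pytest.approx(est2.probabilities["C"],
                                                       abs=1e-12)
        assert est.probabilities["B"] == pytest.approx(est2.probabilities["B"],
                                                       abs=1e-12)

    def test_row_sums_enforced(self):
        bad = pd.DataFrame([[0.6, 0.3]], index=["q"], columns=["A", "B"])
        with pytest.raises(ValidationError):
            TraitProbabilities(bad)


class TestPigmentAndChemotypes:
    @pytest.fixture
    def two_clade_tree(self):
        # pigment clade {p1,p2} vs antibiotic clade {a1,a2}
        return parse_newick(
            "(((qp:0.001,p1:0.001):0.01,p2:0.01):2,"
            "((qa:0.001,a1:0.001):0.01,a2:0.01):2);")

    @pytest.fixture
    def two_clade_refs(self):
        return ReferenceAnnotations(
            {"p1": "spore_pigment", "p2": "spore_pigment",
             "a1": "antibiotic", "a2": "antibiotic"},
            {"a1": "angucycline", "a2": "tetracycline"})

    def test_pigment_neighbor_excluded(self, two_clade_tree, two_clade_refs):
        res = classify_spore_pigment(two_clade_tree, two_clade_refs,
                                     ["qp", "qa"])
        assert res.excluded == {"qp"}
        assert res.retained == ["qa"]

    def test_missing_category_rejected(self, two_clade_tree):
        refs = ReferenceAnnotations({"a1": "antibiotic", "a2": "antibiotic"},
                                    {"a1": "x", "a2": "y"})
        with pytest.raises(EstimationError):
            classify_spore_pigment(two_clade_tree, refs, ["qp"])

    def test_single_chemotype_rejected(self, two_clade_tree):
        refs = ReferenceAnnotations(
            {"a1": "antibiotic", "a2": "antibiotic"},
            {"a1": "angucycline", "a2": "angucycline"})
        with pytest.raises(EstimationError):
            assign_chemotypes(two_clade_tree, refs, ["qa"])

    def test_pigment_classification_accuracy_on_simulation(self):
        """Tips from pigment vs antibiotic clades separate with >= 90%
        balanced accuracy when the trait is strongly clustered."""
        cfg = LandscapeConfig(n_sequences=120, samples_per_continent=4,
                              sequences_per_sample=30, reference_fraction=0.25,
                              pigment_fraction=0.15, n_chemotypes=6, seed=21)
        b = simulate_landscape(cfg)
        queries = [u for u in b.tree.tip_index if u not in b.refs.category]
        res = classify_spore_pigment(b.tree, b.refs, queries)
        truth_pig = b.truth["pigment_tips"]
        tp = sum(1 for q in queries if q in truth_pig and q in res.excluded)
        tn = sum(1 for q in queries
                 if q not in truth_pig and q not in res.excluded)
        n_pig = sum(1 for q in queries if q in truth_pig)
        n_ab = len(queries) - n_pig
        balanced = 0.5 * (tp / n_pig + tn / n_ab)
        assert balanced >= 0.90


class TestFaithPD:
    def test_manual_path_sums(self, four_tip_tree):
        assert faith_pd(four_tip_tree, {"a", "b"}) == pytest.approx(3.0)
        assert faith_pd(four_tip_tree, {"a", "c"}) == pytest.approx(7.0)

    def test_singleton_is_zero(self, four_tip_tree):
        assert faith_pd(four_tip_tree, {"a"}) == 0.0

    def test_unknown_tip_rejected(self, four_tip_tree):
        with pytest.raises(ValidationError):
            faith_pd(four_tip_tree, {"a", "nope"})

    def test_all_tips_spans_whole_tree_below_root(self, four_tip_tree):
        assert faith_pd(four_tip_tree, set("abcd")) == pytest.approx(10.0)


class TestClusteringScore:
    def test_observed_below_all_draws(self):
        # two glued tips on an otherwise long-branch tree: PD ~ 0
        parts = ",".join(f"t{i}:5" for i in range(12))
        tree = parse_newick(f"((a:0.0001,b:0.0001):5,({parts}):5);")
        res = trait_clustering_score(tree, {"a", "b"}, n_draws=100, seed=4)
        assert res.quantile == pytest.approx(1 / 101)

    def test_star_tree_all_ties(self):
        tree = parse_newick("(a:1,b:1,c:1,d:1,e:1);")
        res = trait_clustering_score(tree, {"a", "b"}, n_draws=50, seed=0)
        assert res.quantile == 1.0

    def test_degenerate_full_set(self, four_tip_tree):
        res = trait_clustering_score(four_tip_tree, set("abcd"),
                                     n_draws=10, seed=0)
        assert res.degenerate and res.quantile == 1.0

    def test_null_quantile_uniform(self):
        """Trait tips drawn uniformly: the quantile is uniform."""
        flat = simulate_tree(60, seed=9)
        labels = [flat.labels[i] for i in flat.tip_ids]
        rng = np.random.default_rng(10)
        n_draws = 199
        qs = []
        for _ in range(400):
            tips = rng.choice(labels, size=8, replace=False)
            res = trait_clustering_score(flat, tips, n_draws=n_draws,
                                         seed=int(rng.integers(2 ** 31)))
            qs.append(res.quantile)
        stat = kstest(qs, "uniform").pvalue
        assert stat > 0.01


class TestReferenceDensity:
    def test_more_references_reduce_uncertainty(self):
        """Mean probability assigned to the true label increases with
        reference density (nested reference sets, paired across
        replicates)."""
        from traitscape.synthetic_data import chemotype_benchmark

        gains = []
        for rep in range(8):
            bench = chemotype_benchmark(n_tips=120, n_refs=60, n_queries=25,
                                        k=6, q=0.1, seed=800 + rep)
            flat = bench.tree
            ref_ids = bench.refs.ids
            means = []
            for n_ref in (12, 30, 60):
                sub_ids = ref_ids[:n_ref]
                chems = {r: bench.refs.chemotype[r] for r in sub_ids}
                if len(set(chems.values())) < 2:
                    continue
                refs = ReferenceAnnotations(
                    {r: "antibiotic" for r in sub_ids}, chems)
                probs = assign_chemotypes(flat, refs, bench.queries)
                vals = [probs.probs.loc[q, bench.truth[q]]
                        for q in bench.queries
                        if bench.truth[q] in probs.labels]
                means.append(np.mean(vals))
            if len(means) == 3:
                gains.append(means[-1] - means[0])
        # one-sided: densest reference set beats the sparsest on average
        assert np.mean(gains) > 0

    def test_batch_results_independent_of_query_order(self):
        from traitscape.synthetic_data import chemotype_benchmark

        bench = chemotype_benchmark(n_tips=60, n_refs=20, n_queries=10,
                                    k=4, q=0.1, seed=55)
        fwd = assign_chemotypes(bench.tree, bench.refs, bench.queries)
        rev = assign_chemotypes(bench.tree, bench.refs, bench.queries[::-1])
        pd.testing.assert_frame_equal(fwd.probs.sort_index(),
                                      rev.probs.sort_index())


class TestAssignmentConsistency:
    def test_identical_trees_agree_fully(self):
        tree = parse_newick(
            "(((q:0.4,r1:0.3):0.2,(r2:0.5,r3:0.2):0.3):0.4,(r4:0.6,r5:0.1):0.2);")
        refs = _refs({"r1": "A", "r2": "A", "r3": "A", "r4": "B", "r5": "B"})
        res = assignment_consistency([tree] * 5, refs, ["q"])
        assert res.per_query.loc["q", "agreement"] == 1.0

    def test_swapped_query_agreement_half(self):
        t1 = parse_newick("(((q:0.01,a1:0.01):0.01,a2:0.02):2,(b1:0.01,b2:0.01):2);")
        t2 = parse_newick("((a1:0.01,a2:0.02):2,((q:0.01,b1:0.01):0.01,b2:0.01):2);")
        refs = _refs({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = assignment_consistency([t1, t2], refs, ["q"])
        assert res.per_query.loc["q", "agreement"] == 0.5

    def test_tipset_mismatch_rejected(self):
        t1 = parse_newick("((q:1,r1:1):1,r2:1);")
        t2 = parse_newick("((q:1,r1:1):1,r3:1);")
        refs = _refs({"r1": "A", "r2": "B", "r3": "B"})
        with pytest.raises(ValidationError):
            assignment_consistency([t1, t2], refs, ["q"])
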