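"""SSR binary coding, Nei distance and UPGMA clustering."""

import math

import numpy as np
import pytest

from charkit import ssrtyping as ssr
from charkit import synthetic_data as sim
from charkit import trees


def profile(label, **calls):
    return ssr.SSRProfile(label=label,
                          calls={k: frozenset(v) for k, v in calls.items()})


class TestBinarize:
    def test_two_accessions_disjoint_alleles(self):
        bm = ssr.binarize([profile("a", L1={100}), profile("b", L1={102})])
        assert bm.shape == (2, 2)
        assert bm.loc["a", "L1:100"] == 1 and bm.loc["a", "L1:102"] == 0
        assert bm.loc["b", "L1:102"] == 1 and bm.loc["b", "L1:100"] == 0

    def test_heterozygote_sets_both_columns(self):
        bm = ssr.binarize([profile("a", L1={100, 102})])
        assert bm.loc["a", "L1:100"] == 1 and bm.loc["a", "L1:102"] == 1

    def test_three_accessions_hand_enumeration(self):
        profiles = [
            profile("a", L1={100, 102}, L2={200}),
            profile("b", L1={100}, L2={202}),
            profile("c", L1={104}, L2={200, 202}),
        ]
        bm = ssr.binarize(profiles)
        expected_cols = ["L1:100", "L1:102", "L1:104", "L2:200", "L2:202"]
        assert list(bm.columns) == expected_cols
        expected = {
            ("a", "L1:100"): 1, ("a", "L1:102"): 1, ("a", "L1:104"): 0,
            ("a", "L2:200"): 1, ("a", "L2:202"): 0,
            ("b", "L1:100"): 1, ("b", "L1:102"): 0, ("b", "L1:104"): 0,
            ("b", "L2:200"): 0, ("b", "L2:202"): 1,
            ("c", "L1:100"): 0, ("c", "L1:102"): 0, ("c", "L1:104"): 1,
            ("c", "L2:200"): 1, ("c", "L2:202"): 1,
        }
        for (r, c), v in expected.items():
            assert bm.loc[r, c] == v


class TestNeiDistance:
    def test_identical_profiles_at_zero(self):
        p = profile("a", L1={100}, L2={200, 202})
        q = profile("b", L1={100}, L2={200, 202})
        d = ssr.nei_distance([p, q])
        assert d["a", "b"] == pytest.approx(0.0)

    def test_no_shared_alleles_capped(self):
        p = profile("a", L1={100})
        q = profile("b", L1={102})
        with pytest.warns(UserWarning, match="capped"):
            d = ssr.nei_distance([p, q], cap=10.0)
        assert d["a", "b"] == 10.0

    def test_closed_form_single_locus(self):
        # frequencies (1, 0) vs (0.5, 0.5): D = -ln(0.5 / sqrt(0.5)) = 0.3466
        p = profile("a", L1={100})
        q = profile("b", L1={100, 102})
        d = ssr.nei_distance([p, q])
        assert d["a", "b"] == pytest.approx(-math.log(0.5 / math.sqrt(0.5)), abs=1e-4)

    def test_symmetric_zero_diagonal(self):
        profiles, _ = sim.gen_ssr_panel(sim.SSRSimSpec(seed=3))
        d = ssr.nei_distance(profiles)
        assert np.allclose(d.data, d.data.T)
        assert np.all(np.diag(d.data) == 0)

    def test_missing_locus_uses_shared_loci_only(self):
        p = profile("a", L1={100}, L2={200})
        q = profile("b", L1={100})  # L2 unscored
        d = ssr.nei_distance([p, q])
        assert d["a", "b"] == pytest.approx(0.0)

    def test_shared_band_alternative(self):
        p = profile("a", L1={100, 102})
        q = profile("b", L1={100})
        d = ssr.nei_distance([p, q], method="shared_band")
        assert d["a", "b"] == pytest.approx(1 - 2 * 1 / 3)


class TestUPGMA:
    def test_two_taxa(self):
        d = trees.distance_matrix(["A", "B"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        t = ssr.upgma(d)
        assert {x.name for x in t.tips()} == {"A", "B"}
        assert all(tip.length == pytest.approx(1.0) for tip in t.tips())

    def test_three_taxa_hand_run(self):
        d = trees.distance_matrix(
            list("ABC"), np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float))
        t = ssr.upgma(d)
        ab = t.lowest_common_ancestor(["A", "B"])
        assert {x.name for x in ab.tips()} == {"A", "B"}
        assert t.find("A").length == pytest.approx(1.0)
        assert ab.length == pytest.approx(2.0)
        assert t.find("C").length == pytest.approx(3.0)

    def test_reconstructs_random_ultrametric_matrix(self):
        """Cophenetic distances of the UPGMA tree equal the input exactly."""
        rng = np.random.default_rng(12)
        for _ in range(3):
            n = 6
            # random ultrametric: single-linkage-free construction via
            # random sequential merges at increasing heights
            heights = np.sort(rng.uniform(1, 10, n - 1))
            clusters = [{i} for i in range(n)]
            dmat = np.zeros((n, n))
            for h in heights:
                i, j = rng.choice(len(clusters), 2, replace=False)
                a, b = clusters[i], clusters[j]
                for x in a:
                    for y in b:
                        dmat[x, y] = dmat[y, x] = 2 * h
                clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
                clusters.append(a | b)
            labels = [f"t{i}" for i in range(n)]
            d = trees.distance_matrix(labels, dmat)
            t = ssr.upgma(d)
            for x in range(n):
                for y in range(x + 1, n):
                    got = t.find(labels[x]).distance(t.find(labels[y]))
                    assert got == pytest.approx(dmat[x, y], abs=1e-9)

    def test_ultrametric_and_matches_skbio_oracle(self):
        import skbio.tree

        profiles, _ = sim.gen_ssr_panel(sim.SSRSimSpec(seed=5))
        d = ssr.nei_distance(profiles)
        t = ssr.upgma(d)
        assert trees.is_ultrametric(t)
        oracle = skbio.tree.upgma(d)
        assert trees.bipartitions(t) == trees.bipartitions(oracle)

    def test_duplicate_accession_joins_its_twin_first(self):
        profiles, _ = sim.gen_ssr_panel(sim.SSRSimSpec(seed=6))
        twin = ssr.SSRProfile(label="twin", calls=profiles[0].calls)
        d = ssr.nei_distance(profiles + [twin])
        assert d[profiles[0].label, "twin"] == 0.0
        t = ssr.upgma(d)
        pair = t.lowest_common_ancestor([profiles[0].label, "twin"])
        assert {x.name for x in pair.tips()} == {profiles[0].label, "twin"}

    def test_planted_groups_split_first(self):
        profiles, truth = sim.gen_ssr_panel(
            sim.SSRSimSpec(n_groups=2, accessions_per_group=5,
                           within_sharing=0.9, between_sharing=0.05, seed=1))
        t = ssr.upgma(ssr.nei_distance(profiles))
        left = {x.name for x in t.children[0].tips()}
        groups = {lab for lab, g in truth.items() if g == 0}
        assert left in (groups, set(truth) - groups)

    def test_nonfinite_distance_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(Exception):
            ssr.upgma(trees.distance_matrix(["A", "B"], d))


class TestNewick:
    def test_round_trip_topology_and_lengths(self):
        d = trees.distance_matrix(
            list("ABC"), np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float))
        t = ssr.upgma(d)
        text = ssr.write_newick(t)
        back = trees.read_newick(text)
        assert trees.bipartitions(back) == trees.bipartitions(t)
        for tip in t.tips():
            assert back.find(tip.name).length == pytest.approx(tip.length)

    def test_reserved_characters_quoted_and_parseable_by_dendropy(self):
        import dendropy

        d = trees.distance_matrix(
            ["sp. nov", "B", "C"], np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float))
        text = ssr.write_newick(ssr.upgma(d))
        parsed = dendropy.Tree.get(data=text, schema="newick")
        labels = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert "sp. nov" in labels
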