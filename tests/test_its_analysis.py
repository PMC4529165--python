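"""ITS annotation, motif scanning, classification, diversity, phylogenetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from charkit import its_analysis as its
from charkit import synthetic_data as sim
from charkit import trees
from charkit.references import DEFAULT_MOTIFS, REFERENCE_58S

DNA = st.text(alphabet="ACGT", min_size=1, max_size=80)


def functional_sequence(seed=0):
    reads, truths = sim.gen_its_family(sim.ITSSimSpec(seed=seed, read_error_rate=0.0))
    return truths[0].sequence


class TestDelineation:
    def test_round_trip_on_generator_construction(self):
        seq = functional_sequence()
        ann = its.delineate_regions(seq)
        assert ann.its1_span == (0, 219)
        assert ann.r58s_span == (219, 219 + 155)
        assert ann.r58s == REFERENCE_58S
        assert ann.canonical_58s_length

    def test_deletion_shortens_58s_span(self):
        specs = (sim.ITSTypeSpec(kind="deletion", deletion_58s=2),)
        _, truths = sim.gen_its_family(sim.ITSSimSpec(type_specs=specs, seed=1))
        ann = its.delineate_regions(truths[0].sequence)
        assert ann.r58s_span[1] - ann.r58s_span[0] == 153

    def test_random_sequence_unannotatable(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 600))
        with pytest.raises(its.UnannotatableSequenceError):
            its.delineate_regions(seq)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            its.delineate_regions("ACGT" * 50)


class TestGCContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 50.0),
        ("GGCC", 100.0),
        ("ATAT", 0.0),
        ("GCSN", 100.0),  # S counts as G/C, N excluded from the denominator
    ])
    def test_definition(self, seq, expected):
        assert its.gc_content(seq) == pytest.approx(expected)

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError):
            its.gc_content("")

    @given(DNA)
    @settings(derandomize=True, max_examples=50)
    def test_complement_invariance(self, seq):
        comp = seq.translate(str.maketrans("ACGT", "TGCA"))
        assert its.gc_content(seq) == pytest.approx(its.gc_content(comp))


class TestMotifScan:
    def test_exact_copies_conserved(self):
        report = its.scan_58s_motifs(REFERENCE_58S)
        assert report.all_conserved
        assert report.n_changes == 0

    def test_single_substitution_reported_one_based(self):
        m2 = DEFAULT_MOTIFS[1]
        mutated = REFERENCE_58S.replace(m2, m2[:8] + "A" + m2[9:])
        assert mutated != REFERENCE_58S and m2[8] != "A"
        report = its.scan_58s_motifs(mutated)
        m2_result = report.motifs[1]
        assert m2_result.status == "changed"
        assert m2_result.changes == ((9, "A"),)
        assert m2_result.render_changes() == "nt-9 'A'"

    def test_deleted_motif_region_flagged(self):
        m3 = DEFAULT_MOTIFS[2]
        deleted = REFERENCE_58S.replace(m3, "")
        report = its.scan_58s_motifs(deleted)
        assert report.motifs[2].status == "absent-deletion"
        assert report.motifs[2].render_changes() == "not present-deletion"
        assert report.any_deleted

    def test_missing_58s_rejected(self):
        with pytest.raises(ValueError):
            its.scan_58s_motifs("")


class TestClassification:
    def test_intact_copy_not_pseudogene(self):
        call, reasons = its.classify_pseudogene_features(
            its2_formed=True, r58s_formed=True, gc_58s=57.0,
            n_motif_changes=0, any_motif_deleted=False)
        assert not call and reasons == ()

    def test_unfolded_structures_flagged(self):
        # feature pattern of a doubly unfolded copy
        call, reasons = its.classify_pseudogene_features(
            its2_formed=False, r58s_formed=False, gc_58s=53.59,
            n_motif_changes=1, any_motif_deleted=False)
        assert call
        assert len(reasons) == 2

    def test_motif_polymorphisms_alone_not_flagged(self):
        # three changed motif positions with intact structures and normal GC
        call, _ = its.classify_pseudogene_features(
            its2_formed=True, r58s_formed=True, gc_58s=54.19,
            n_motif_changes=3, any_motif_deleted=False)
        assert not call

    def test_gc_erosion_flagged(self):
        call, reasons = its.classify_pseudogene_features(
            its2_formed=True, r58s_formed=True, gc_58s=46.45,
            n_motif_changes=0, any_motif_deleted=False)
        assert call and "GC" in reasons[0]

    def test_record_with_missing_features_rejected(self):
        rec = its.ITSTypeRecord(
            accession="x", type_id="t", annotation=None, gc_its1=0, gc_58s=0,
            gc_its2=0, motif_report=None, fold_its2=None, fold_58s=None)
        with pytest.raises(ValueError):
            its.classify_pseudogene(rec)


class TestCollapse:
    def test_identical_reads_one_type(self):
        reads = ["ACGTACGTACGT" * 40] * 28
        types = its.collapse_to_types(reads)
        assert len(types) == 1
        assert types[0][1] == 28

    def test_planted_divergent_types_separate(self, two_type_family):
        reads, truths = two_type_family
        types = its.collapse_to_types([s for _, s in reads])
        assert len(types) == len(truths)
        assert sorted(n for _, n in types) == sorted(t.n_reads for t in truths)
        assert {c for c, _ in types} == {t.sequence for t in truths}

    def test_single_error_read_merges_with_cluster(self):
        base = functional_sequence()
        variant = "A" + base[1:] if base[0] != "A" else "C" + base[1:]
        types = its.collapse_to_types([base] * 27 + [variant])
        assert len(types) == 1
        assert types[0] == (base, 28)


class TestDiversity:
    def test_identical_pair(self):
        stats = its.nucleotide_diversity(["ACGT" * 30] * 2)
        assert stats.pi == 0.0 and stats.s == 0 and stats.n_haplotypes == 1

    def test_single_difference_definition(self):
        a = "A" * 100
        b = "C" + "A" * 99
        stats = its.nucleotide_diversity([a, b])
        assert stats.pi == pytest.approx(0.01)
        assert stats.s == 1
        assert stats.n_haplotypes == 2

    def test_matches_per_site_oracle(self):
        """pi equals the column-wise average pairwise-difference formula."""
        rng = np.random.default_rng(9)
        seqs = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(4)]
        stats = its.nucleotide_diversity(seqs)
        n = len(seqs)
        per_site = 0.0
        for col in zip(*seqs):
            from collections import Counter

            counts = Counter(col)
            same = sum(c * (c - 1) for c in counts.values())
            per_site += 1 - same / (n * (n - 1))
        assert stats.pi == pytest.approx(per_site / 150, abs=1e-12)

    def test_gap_columns_excluded_pairwise(self):
        stats = its.nucleotide_diversity(["AC-T", "ACGT"])
        assert stats.pi == 0.0 and stats.s == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            its.nucleotide_diversity(["ACGT", "ACG"])


class TestJukesCantor:
    @pytest.mark.parametrize("p,expected", [
        (0.0, 0.0),
        (0.3, -0.75 * math.log(0.6)),
    ])
    def test_closed_form(self, p, expected):
        assert its.jukes_cantor(p) == pytest.approx(expected, abs=1e-10)

    def test_saturation(self):
        with pytest.raises(its.SaturationError):
            its.jukes_cantor(0.75)
        assert its.jukes_cantor(0.8, cap=5.0) == 5.0

    @given(st.floats(0.001, 0.74), st.floats(0.001, 0.74))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_and_dominates_p(self, p, q):
        assert its.jukes_cantor(p) >= p
        if p < q:
            assert its.jukes_cantor(p) < its.jukes_cantor(q)


def random_additive_tree(rng, n):
    """Random binary tree with branch lengths; returns (tree, distance matrix)."""
    labels = [f"t{i}" for i in range(n)]
    nodes = [trees.TreeNode(name=l, length=float(rng.uniform(0.5, 3))) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = trees.TreeNode(children=[a, b], length=float(rng.uniform(0.5, 3)))
        nodes.append(parent)
    root = trees.TreeNode(children=nodes)
    dmat = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            dist = root.find(labels[x]).distance(root.find(labels[y]))
            dmat[x, y] = dmat[y, x] = dist
    return root, trees.distance_matrix(labels, dmat)


class TestBioNJ:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:1))
        dmat = np.array([
            [0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float)
        d = trees.distance_matrix(list("ABCD"), dmat)
        t = its.bionj(d)
        assert trees.bipartitions(t) == {frozenset({"A", "B"})}
        for x in "ABCD":
            for y in "ABCD":
                if x < y:
                    got = t.find(x).distance(t.find(y))
                    assert got == pytest.approx(d[x, y], abs=1e-9)

    def test_three_taxon_three_point_formulas(self):
        d = trees.distance_matrix(
            list("ABC"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        t = its.bionj(d)
        assert t.find("A").length == pytest.approx(1.0)
        assert t.find("B").length == pytest.approx(2.0)
        assert t.find("C").length == pytest.approx(3.0)

    def test_recovers_random_additive_trees(self):
        import skbio.tree

        rng = np.random.default_rng(31)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            true_tree, d = random_additive_tree(rng, n)
            t = its.bionj(d)
            assert trees.bipartitions(t) == trees.bipartitions(true_tree)
            for x in range(n):
                for y in range(x + 1, n):
                    lx, ly = f"t{x}", f"t{y}"
                    assert t.find(lx).distance(t.find(ly)) == pytest.approx(
                        d[lx, ly], abs=1e-8)
            # independent oracle on the same matrix
            oracle = skbio.tree.nj(d)
            assert trees.bipartitions(t) == trees.bipartitions(oracle)

    def test_ultrametric_matrix_matches_upgma_topology(self):
        from charkit import ssrtyping as ssr

        dmat = np.array([
            [0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float)
        d = trees.distance_matrix(list("ABCD"), dmat)
        assert trees.bipartitions(its.bionj(d)) == trees.bipartitions(ssr.upgma(d))

    def test_nonfinite_rejected(self):
        dmat = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(Exception):
            its.bionj(trees.distance_matrix(list("ABC"), dmat))


class TestBootstrap:
    def make_clades(self, seed=4, n_per=3, L=400, between=0.10, within=0.001):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ACGT"), L))
        clade_b = list(base)
        for p in rng.choice(L, int(between * L), replace=False):
            clade_b[p] = rng.choice([c for c in "ACGT" if c != clade_b[p]])
        clade_b = "".join(clade_b)
        seqs, labels = [], []
        for tag, anchor in (("A", base), ("B", clade_b)):
            for i in range(n_per):
                s = list(anchor)
                for p in range(L):
                    if rng.random() < within:
                        s[p] = rng.choice([c for c in "ACGT" if c != s[p]])
                seqs.append("".join(s))
                labels.append(f"{tag}{i}")
        return labels, seqs

    def test_clear_clades_get_high_support(self):
        labels, seqs = self.make_clades()
        tree = its.bootstrap_support(labels, seqs, n_reps=100, seed=1)
        all_leaves = frozenset(labels)
        clade = frozenset(l for l in labels if l.startswith("A"))
        canon = min(clade, all_leaves - clade, key=lambda s: (len(s), sorted(s)))
        supports = {
            min(frozenset(t.name for t in n.tips()),
                all_leaves - frozenset(t.name for t in n.tips()),
                key=lambda s: (len(s), sorted(s))): float(n.name)
            for n in tree.non_tips(include_self=False) if n.name
        }
        assert supports[canon] >= 95.0

    def test_deterministic_under_seed(self):
        labels, seqs = self.make_clades(seed=6)
        t1 = its.bootstrap_support(labels, seqs, n_reps=30, seed=42)
        t2 = its.bootstrap_support(labels, seqs, n_reps=30, seed=42)
        assert trees.write_newick(t1) == trees.write_newick(t2)

    def test_invalid_inputs_rejected(self):
        labels, seqs = self.make_clades()
        with pytest.raises(ValueError):
            its.bootstrap_support(labels, seqs, n_reps=0)
        with pytest.raises(ValueError):
            its.bootstrap_support(labels[:3], seqs[:3], n_reps=10)
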