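"""Alignment and tree inference: NW against exhaustive enumeration, identity
conventions, p-distance properties, and NJ recovery of additive matrices."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import skbio

from primerpanel._iupac import reverse_complement
from primerpanel.phylo import (
    AlignParams,
    DistanceMatrix,
    global_align,
    neighbor_joining,
    p_distance_matrix,
    percent_identity,
    reference_anchored_alignment,
)
from primerpanel.seqio import NucleotideSequence, SpeciesSequenceSet
from primerpanel.simulate import SimulationConfig, simulate_marker_set

from _oracles import brute_force_nw_score


def _alignment_score(aln, params: AlignParams) -> float:
    """Re-score an emitted alignment directly from its columns."""
    score = 0.0
    last = "m"
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" :
            score += params.gap_extend if last == "y" else params.gap_open
            last = "y"
        elif y == "-":
            score += params.gap_extend if last == "x" else params.gap_open
            last = "x"
        else:
            score += params.match if x == y else params.mismatch
            last = "m"
    return score


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.score == 4.0
        assert aln.aligned_a == aln.aligned_b == "ACGT"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_linear_gap_example_matches_enumeration(self):
        p = AlignParams(1, -1, -2, -2)
        aln = global_align("ACGT", "AGT", p)
        assert aln.score == brute_force_nw_score("ACGT", "AGT", 1, -1, -2, -2)

    def test_score_equals_brute_force_on_short_strings(self):
        rng = np.random.default_rng(23)
        params = AlignParams()
        for _ in range(200):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 9))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 9))))
            aln = global_align(a, b, params)
            oracle = brute_force_nw_score(
                a, b, params.match, params.mismatch, params.gap_open, params.gap_extend
            )
            assert aln.score == pytest.approx(oracle), (a, b)
            # the emitted alignment must itself realize the optimal score
            assert _alignment_score(aln, params) == pytest.approx(oracle), (a, b)

    def test_degapping_recovers_inputs(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40))))
            aln = global_align(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b

    def test_deterministic(self):
        a, b = "ACGTACGTAA", "ACGACGTTAA"
        r1 = global_align(a, b)
        r2 = global_align(a, b)
        assert (r1.aligned_a, r1.aligned_b) == (r2.aligned_a, r2.aligned_b)

    def test_degenerate_codes_compatible_as_match(self):
        aln = global_align("ACRT", "ACGT")
        assert aln.score == 4.0


class TestPercentIdentity:
    def test_identical_is_100(self):
        assert percent_identity("ACGTACGT", "ACGTACGT").percent_identity == 100.0

    def test_single_mismatch_quarter(self):
        for mode in ("exclude_end_gaps", "all_columns"):
            assert percent_identity("AAAA", "AAAT", mode=mode).percent_identity == 75.0

    def test_symmetric(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=30))
            b = "".join(rng.choice(list("ACGT"), size=28))
            assert (
                percent_identity(a, b).percent_identity
                == percent_identity(b, a).percent_identity
            )

    def test_invariant_under_joint_reverse_complement(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=25))
            b = "".join(rng.choice(list("ACGT"), size=25))
            direct = percent_identity(a, b).percent_identity
            flipped = percent_identity(
                reverse_complement(a), reverse_complement(b)
            ).percent_identity
            assert direct == pytest.approx(flipped)

    def test_end_gap_exclusion_scores_overlap_only(self):
        # fragment vs full-length: identical in the overlap
        full = "GGGGACGTACGTACGTAAAA"
        frag = "ACGTACGTACGT"
        res = percent_identity(full, frag)
        assert res.percent_identity == 100.0
        assert res.compared_columns == len(frag)
        assert percent_identity(full, frag, mode="all_columns").percent_identity < 100.0


class TestPDistance:
    def _set(self, seqs: dict[str, str], aligned=False) -> SpeciesSequenceSet:
        return SpeciesSequenceSet(
            {
                sp: [NucleotideSequence(f"{sp}_{i}", sp, s, aligned=aligned)
                     for i, s in enumerate(strs)]
                for sp, strs in seqs.items()
            },
            aligned=aligned,
        )

    def test_identical_pair_is_zero(self):
        dm = p_distance_matrix(self._set({"a": ["ACGTACGT", "ACGTACGT"]}))
        assert np.allclose(dm.matrix, 0.0)

    def test_three_sequences_symmetric_zero_diagonal(self):
        dm = p_distance_matrix(
            self._set({"a": ["ACGTACGT", "ACGAACGT"], "b": ["TCGTACGA"]})
        )
        assert dm.matrix.shape == (3, 3)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            p_distance_matrix(self._set({"a": ["ACGTACGT"]}))

    def test_jc_simulation_matches_closed_form(self):
        # interior (non-flank) p-distance between species should match the
        # Jukes-Cantor expectation for the two-branch separation
        cfg = SimulationConfig(seed=42, marker_length_bp=450)
        seq_set, _ = simulate_marker_set(cfg)
        lo, hi = cfg.flanks()[0][1], cfg.flanks()[1][0]
        interior = self._set(
            {
                sp: [r.residues[lo:hi] for r in seq_set[sp]]
                for sp in seq_set.species
            },
            aligned=True,
        )
        dm = p_distance_matrix(interior)
        labels = dm.labels
        cross = [
            dm.matrix[i, j]
            for i, j in itertools.combinations(range(len(labels)), 2)
            if labels[i].split("_", 2)[1] != labels[j].split("_", 2)[1]
        ]
        d_total = 2 * (cfg.between_divergence + cfg.within_divergence)
        p_expected = 0.75 * (1 - np.exp(-4 * d_total / 3))
        se_single_pair = np.sqrt(p_expected * (1 - p_expected) / (hi - lo))
        assert abs(np.mean(cross) - p_expected) < 3 * se_single_pair


def _random_binary_tree(rng, n_leaves: int):
    """Random agglomerated binary tree with positive branch lengths; returns
    (skbio tree, leaf labels)."""
    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = [skbio.TreeNode(name=lbl) for lbl in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent = skbio.TreeNode(children=[b, a])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = skbio.TreeNode(children=nodes)
    for child in root.children:
        if child.length is None:
            child.length = float(rng.uniform(0.05, 1.0))
    return root, labels


def _is_monophyletic(root, ids: set[str], all_ids: set[str]) -> bool:
    """A leaf set is monophyletic in an unrooted tree iff some edge splits
    it (or its complement) off exactly."""
    for node in root.traverse(include_self=False):
        side = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if side == ids or side == all_ids - ids:
            return True
    return False


def _tip_distance_matrix(tree, labels) -> np.ndarray:
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = tree.find(labels[i]).distance(tree.find(labels[j]))
        m[i, j] = m[j, i] = d
    return m


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], m))
        root = tree.root
        lengths = {t.name: t.length for t in root.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # hand-drawn tree: ((A:1,B:2):1,C:3,D:4) with central edge 1
        labels = ["A", "B", "C", "D"]
        m = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, m))
        recovered = _tip_distance_matrix(tree.root, labels)
        assert np.allclose(recovered, m)

    def test_recovers_50_random_additive_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(5, 9))
            true_tree, labels = _random_binary_tree(rng, n)
            m = _tip_distance_matrix(true_tree, labels)
            est = neighbor_joining(DistanceMatrix(labels, m))
            rf = est.root.compare_rfd(true_tree)
            assert rf == 0.0
            # additivity means exact path-length recovery too
            assert np.allclose(_tip_distance_matrix(est.root, labels), m)

    def test_agrees_with_library_nj_on_generic_matrices(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = 6
            noise = rng.uniform(0, 0.05, size=(n, n))
            tree, labels = _random_binary_tree(rng, n)
            m = _tip_distance_matrix(tree, labels) + noise + noise.T
            m = (m + m.T) / 2  # exact float symmetry
            np.fill_diagonal(m, 0)
            mine = neighbor_joining(DistanceMatrix(labels, m))
            oracle = skbio.tree.nj(skbio.DistanceMatrix(m, labels))
            assert mine.root.compare_rfd(oracle) == 0.0

    def test_requires_three_labels(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_newick_round_trip(self):
        m = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["x", "y", "z"], m))
        parsed = skbio.TreeNode.read([tree.newick()])
        assert sorted(t.name for t in parsed.tips()) == ["x", "y", "z"]

    def test_simulated_species_form_clades(self, sim_set):
        seq_set, _ = sim_set
        dm = p_distance_matrix(seq_set)
        tree = neighbor_joining(dm)
        all_ids = {r.id for r in seq_set}
        for sp in seq_set.species:
            ids = {r.id for r in seq_set[sp]}
            assert _is_monophyletic(tree.root, ids, all_ids), sp


class TestReferenceAnchoredAlignment:
    def _set(self, seqs: dict[str, list[str]]) -> SpeciesSequenceSet:
        return SpeciesSequenceSet(
            {
                sp: [NucleotideSequence(f"{sp}{i}", sp, s) for i, s in enumerate(strs)]
                for sp, strs in seqs.items()
            }
        )

    def test_identical_sequences_align_gap_free(self):
        s = "ACGTACGTACGTACGTACGT"
        aligned = reference_anchored_alignment(
            self._set({"a": [s, s], "b": [s]}), "a0"
        )
        assert aligned.aligned
        assert all(r.residues == s for r in aligned)

    def test_single_deletion_projects_to_gap(self):
        ref = "ACGTACGTACGTACGTACGT"
        deleted = ref[:10] + ref[11:]
        aligned = reference_anchored_alignment(
            self._set({"a": [ref], "b": [deleted]}), "a0"
        )
        rec = aligned.get_by_id("b0")
        assert len(rec.residues) == len(ref)
        assert rec.residues.count("-") == 1
        assert rec.residues.replace("-", "") == deleted

    def test_insertion_dropped_and_counted(self, caplog):
        ref = "ACGTACGTACGTACGTACGT"
        inserted = ref[:10] + "TT" + ref[10:]
        with caplog.at_level("WARNING", logger="primerpanel.phylo"):
            aligned = reference_anchored_alignment(
                self._set({"a": [ref], "b": [inserted]}), "a0"
            )
        assert len(aligned.get_by_id("b0").residues) == len(ref)
        assert "2" in caplog.text

    def test_prealigned_input_bypasses_unchanged(self, sim_set):
        seq_set, _ = sim_set
        assert reference_anchored_alignment(seq_set, "species_A_00") is seq_set

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            reference_anchored_alignment(
                self._set({"a": ["ACGTACGTAC"]}), "nope"
            )
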