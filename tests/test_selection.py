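import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from dupscape import selection as sel
from dupscape.selection import (
    CodonAlignment,
    PhyloTree,
    SelectionClass,
    Support,
    TreeNode,
    ancestral_codons,
    backtranslate_alignment,
    consensus_support,
    nj_tree,
    potential_synonymous_sites,
    site_selection,
    synonymous_site_fraction,
    translate_codon,
    trim_alignment,
)
from dupscape.synthdata import simulate_selection_alignment

import oracles


class TestBacktranslate:
    def test_gap_becomes_gap_triplet(self):
        aln = backtranslate_alignment({"x": "M-K"}, {"x": "ATGAAA"})
        assert aln.rows["x"] == "ATG---AAA"

    def test_trailing_stop_tolerated(self):
        aln = backtranslate_alignment({"x": "MK"}, {"x": "ATGAAATAA"})
        assert aln.rows["x"] == "ATGAAA"

    def test_mismatch_reports_sequence_and_position(self):
        with pytest.raises(ValueError, match="x.*position 2"):
            backtranslate_alignment({"x": "MM"}, {"x": "ATGAAA"})

    def test_wrong_cds_length_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            backtranslate_alignment({"x": "MK"}, {"x": "ATGAA"})

    def test_roundtrip_translation(self):
        msa = {"a": "MK-V", "b": "MKLV"}
        cds = {"a": "ATGAAAGTT", "b": "ATGAAACTGGTT"}
        aln = backtranslate_alignment(msa, cds)
        for sid in msa:
            codons = [
                aln.rows[sid][i : i + 3]
                for i in range(0, len(aln.rows[sid]), 3)
                if aln.rows[sid][i : i + 3] != "---"
            ]
            assert "".join(map(translate_codon, codons)) == msa[sid].replace("-", "")


class TestTrim:
    def make(self):
        return backtranslate_alignment(
            {"a": "MKVW", "b": "M-VW", "c": "MKVW"},
            {"a": "ATGAAAGTTTGG", "b": "ATGGTTTGG", "c": "ATGAAAGTATGG"},
        )

    def test_gapped_column_removed(self):
        trimmed = trim_alignment(self.make())
        assert trimmed.n_sites == 3
        assert trimmed.provenance == [1, 3, 4]

    def test_region_restricts_columns(self):
        trimmed = trim_alignment(self.make(), region=(3, 4))
        assert trimmed.n_sites == 2
        assert trimmed.provenance == [3, 4]

    def test_provenance_strictly_increasing(self):
        prov = trim_alignment(self.make()).provenance
        assert all(a < b for a, b in zip(prov, prov[1:]))

    def test_empty_result_raises(self):
        aln = backtranslate_alignment({"a": "M-", "b": "-K"}, {"a": "ATG", "b": "AAA"})
        with pytest.raises(ValueError, match="no analyzable"):
            trim_alignment(aln)


class TestNeighborJoining:
    def test_three_taxa_solves_three_point_equations(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"),
            columns=list("ABC"),
            dtype=float,
        )
        tree = nj_tree(d)
        lengths = {c.name: l for c, l in tree.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_matrix_recovers_topology(self):
        # tree ((A:1,B:2):1,C:3,D:4) with C,D hanging off the far node
        ids = list("ABCD")
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=ids,
            columns=ids,
            dtype=float,
        )
        tree = nj_tree(d)
        cherries = [
            {c.name for c, _ in node.children if c.is_leaf}
            for node in tree.postorder()
            if not node.is_leaf
        ]
        assert {"A", "B"} in cherries

    def test_matches_skbio_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        n = 6
        ids = [f"t{i}" for i in range(n)]
        base = rng.uniform(0.2, 1.0, size=(n, n))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 0.0)
        ours = nj_tree(pd.DataFrame(mat, index=ids, columns=ids))
        ref = skbio_nj(DistanceMatrix(mat, ids))

        def splits(edges, leaves):
            children = {}
            for p, c, _ in edges:
                children.setdefault(p, []).append(c)

            def clade(x):
                if x not in children:
                    return frozenset([x])
                return frozenset().union(*(clade(c) for c in children[x]))

            out = set()
            for p, c, _ in edges:
                cl = clade(c)
                if 1 < len(cl) < len(leaves) - 1:
                    out.add(min(cl, key=sorted))
                    out.add(cl)
            return {s for s in out if isinstance(s, frozenset)}

        ours_splits = splits(ours.edges(), ids)
        ref_splits = set()
        for node in ref.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < n - 1:
                ref_splits.add(tips)
        norm = lambda ss: {min(s, frozenset(ids) - s, key=sorted) for s in ss}
        assert norm(ours_splits) == norm(ref_splits)

    def test_deterministic_under_repeated_calls(self):
        rng = np.random.default_rng(8)
        n = 5
        ids = [f"t{i}" for i in range(n)]
        base = rng.uniform(0.2, 1.0, size=(n, n))
        mat = pd.DataFrame((base + base.T) / 2, index=ids, columns=ids)
        np.fill_diagonal(mat.values, 0.0)
        assert nj_tree(mat).newick() == nj_tree(mat).newick()

    def test_fewer_than_three_taxa_warns(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.warns(UserWarning):
            tree = nj_tree(d)
        assert set(tree.leaves()) == {"a", "b"}


def simple_tree():
    # ((a,b),c) with the root trifurcation collapsed to two children
    ab = TreeNode("ab", [(TreeNode("a"), 1.0), (TreeNode("b"), 1.0)])
    root = TreeNode("root", [(ab, 1.0), (TreeNode("c"), 1.0)])
    return PhyloTree(root)


def column_alignment(codons_by_leaf):
    ids = sorted(codons_by_leaf)
    return CodonAlignment(ids=ids, rows={i: codons_by_leaf[i] for i in ids})


class TestAncestralCodons:
    def test_invariant_column(self):
        aln = column_alignment({"a": "ATG", "b": "ATG", "c": "ATG"})
        anc = ancestral_codons(simple_tree(), aln)
        assert anc["ab"] == ["ATG"] and anc["root"] == ["ATG"]

    def test_outgroup_forces_root_state(self):
        aln = column_alignment({"a": "AAA", "b": "AAG", "c": "AAA"})
        anc = ancestral_codons(simple_tree(), aln)
        assert anc["root"] == ["AAA"]
        assert anc["ab"] == ["AAA"]

    def test_leaf_mismatch_raises(self):
        aln = column_alignment({"a": "AAA", "b": "AAG", "z": "AAA"})
        with pytest.raises(ValueError):
            ancestral_codons(simple_tree(), aln)

    def test_parsimony_score_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(17)
        states = ["AAA", "AAG", "AAT", "ACA"]
        from dupscape.synthdata import _random_topology

        tree = _random_topology(np.random.default_rng(2), 8)
        for node in tree.postorder():  # brute force ignores branch lengths
            node.children = [(c, 1.0) for c, _ in node.children]
        for _ in range(5):
            leaf_states = {
                name: str(rng.choice(states)) for name in tree.leaves()
            }
            aln = column_alignment(leaf_states)
            score = sel.parsimony_score(tree, aln, 0)
            oracle = oracles.min_codon_changes(tree.edges(), leaf_states)
            assert score == oracle


class TestSynonymousSites:
    def test_phe_third_position(self):
        # TTT: only TTC is synonymous among the third-position changes
        assert synonymous_site_fraction("TTT", 2) == pytest.approx(1 / 3)
        assert synonymous_site_fraction("TTT", 0) == 0.0

    def test_all_sense_codons_match_enumeration_oracle(self):
        code = {c: translate_codon(c) for c in sel.SENSE_CODONS}
        for codon in sel.SENSE_CODONS:
            expected = oracles.syn_fraction_by_enumeration(
                codon, sel.STOP_CODONS, code
            )
            assert potential_synonymous_sites(codon) == pytest.approx(expected)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            potential_synonymous_sites("TAA")


class TestPathCounts:
    def test_single_synonymous_change(self):
        syn, nonsyn, blocked = sel._path_counts("AAA", "AAG")
        assert (syn, nonsyn, blocked) == (1.0, 0.0, False)

    def test_identical_codons(self):
        assert sel._path_counts("ATG", "ATG") == (0.0, 0.0, False)

    def test_counts_sum_to_nucleotide_differences(self):
        rng = np.random.default_rng(23)
        sense = list(sel.SENSE_CODONS)
        for _ in range(50):
            a, b = rng.choice(sense, size=2)
            syn, nonsyn, blocked = sel._path_counts(str(a), str(b))
            d = sum(x != y for x, y in zip(a, b))
            assert syn + nonsyn == pytest.approx(d, abs=1e-9)

    def test_multiple_paths_averaged(self):
        # TTA (Leu) -> CTG (Leu): both orders stay Leu -> 2 synonymous steps
        syn, nonsyn, _ = sel._path_counts("TTA", "CTG")
        assert syn + nonsyn == pytest.approx(2.0)
        assert syn == pytest.approx(2.0)


class TestBinomialExtension:
    @pytest.mark.parametrize("k,n,p", [(0, 13, 0.25), (3, 20, 0.3), (7, 7, 0.5)])
    def test_matches_scipy_for_integer_counts(self, k, n, p):
        assert sel._binom_cdf(k, n, p) == pytest.approx(binom.cdf(k, n, p))
        assert sel._binom_sf(k, n, p) == pytest.approx(binom.sf(k - 1, n, p))


class TestSiteSelection:
    def test_invariant_alignment_is_neutral_with_p_one(self):
        aln = column_alignment({"a": "ATGATG", "b": "ATGATG", "c": "ATGATG"})
        calls = site_selection(simple_tree(), aln)
        assert all(c.selection_class is SelectionClass.NEUTRAL for c in calls)
        assert all(c.p_value == 1.0 for c in calls)
        assert all(c.observed_syn + c.observed_nonsyn == 0 for c in calls)

    def test_single_synonymous_substitution_counted(self):
        aln = column_alignment({"a": "AAA", "b": "AAG", "c": "AAA"})
        calls = site_selection(simple_tree(), aln)
        assert calls[0].observed_syn == pytest.approx(1.0)
        assert calls[0].observed_nonsyn == pytest.approx(0.0)

    def test_counts_conserve_parsimony_changes(self):
        aln, tree, _ = simulate_selection_alignment(8, 30, tree_depth=0.6, seed=5)
        anc = ancestral_codons(tree, aln)
        calls = site_selection(tree, aln, ancestors=anc)
        for site, call in enumerate(calls):
            nt = sum(
                sel._nt_diff(anc[p][site], anc[c][site]) for p, c, _ in tree.edges()
            )
            assert call.observed_syn + call.observed_nonsyn == pytest.approx(
                nt, abs=1e-9
            )

    def test_binomial_machinery_detects_planted_sites_on_true_counts(self):
        """With the true substitution history (no reconstruction error), the
        expected-fraction + binomial machinery finds most planted sites."""
        omega = {s: 5.0 for s in range(1, 11)}
        aln, tree, truth = simulate_selection_alignment(
            20, 200, tree_depth=1.0, omega_map=omega, seed=1
        )
        detected = 0
        for s in range(1, 11):
            syn, nonsyn = truth.true_syn[s], truth.true_nonsyn[s]
            total = syn + nonsyn
            column = aln.column(s - 1)
            expected = sum(map(potential_synonymous_sites, column)) / (
                3 * len(column)
            )
            p = min(
                1.0,
                2
                * min(
                    sel._binom_cdf(syn, total, expected),
                    sel._binom_sf(syn, total, expected),
                ),
            )
            if p < 0.05 and syn / total < expected:
                detected += 1
        assert detected >= 5


class TestConsensus:
    def test_two_of_four_methods_is_strong(self):
        support = consensus_support(
            {"m1": {3}, "m2": {3, 7}, "m3": set(), "m4": set()}, n_sites=10
        )
        assert support[3] is Support.STRONG
        assert support[7] is Support.MODERATE

    def test_empty_lists_give_none(self):
        support = consensus_support({"m1": set(), "m2": set()}, n_sites=4)
        assert all(v is Support.NONE for v in support.values())

    def test_out_of_range_site_raises(self):
        with pytest.raises(ValueError, match="outside"):
            consensus_support({"m1": {11}}, n_sites=10)

    def test_internal_caller_participates_in_consensus(self):
        aln = column_alignment({"a": "AAA", "b": "AAG", "c": "AAA"})
        calls = site_selection(simple_tree(), aln)
        merged = sel.apply_consensus(calls, {"external": {1}})
        assert merged[0].support is Support.MODERATE
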