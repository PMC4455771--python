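import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

import dendropy

from pbrhet.codon_alignment import CodonAlignment, PbrMask
from pbrhet.tree_ops import (
    AA_ORDER,
    JTT_MAX_DISTANCE,
    AnnotatedTree,
    TreeError,
    _load_jtt,
    _nj_newick,
    _splits,
    annotate_tree,
    fitch_events,
    fitch_map,
    fitch_site_score,
    jtt_distance,
    nj_tree_hky,
    parallel_census,
    read_tree,
)


def tree_from(newick, **kw):
    t = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return annotate_tree(t, **kw)


class TestReadTree:
    def test_three_leaf_tree(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n")
        aln = CodonAlignment({"A": "ATG", "B": "ATG", "C": "ATG"})
        at = read_tree(p, aln)
        assert sorted(at.leaf_names()) == ["A", "B", "C"]

    def test_bootstrap_labels_parsed(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1)95:1,C:2);\n")
        at = read_tree(p)
        assert at.bootstrap[("A", "B")] == 95.0

    def test_unmatched_leaf_errors(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,X:1):1,C:2);\n")
        aln = CodonAlignment({"A": "ATG", "B": "ATG", "C": "ATG"})
        with pytest.raises(TreeError):
            read_tree(p, aln)

    def test_malformed_newick_errors(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1;;;\n")
        with pytest.raises(TreeError):
            read_tree(p)

    def test_outgroup_rooting(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,(C:1,OG:1):1);\n")
        at = read_tree(p, outgroup=["OG"])
        root_children = at.tree.seed_node.child_nodes()
        sides = [at.branch_id(c) for c in root_children]
        assert ("OG",) in sides


class TestNeighborJoining:
    def test_additive_distances_recover_topology(self):
        # additive matrix for ((A,B),(C,D)) with internal branch 3
        names = ["A", "B", "C", "D"]
        dm = np.array(
            [
                [0, 2, 7, 7],
                [2, 0, 7, 7],
                [7, 7, 0, 2],
                [7, 7, 2, 0],
            ],
            dtype=float,
        )
        newick = _nj_newick(dm, names)
        splits = _splits(newick, names)
        assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits

    def test_identical_sequences_give_zero_lengths(self):
        aln = CodonAlignment(
            {n: "ATGGGTTTTAAA" for n in "ABCD"}, PbrMask((1,))
        )
        at = nj_tree_hky(aln, n_bootstrap=5, seed=0)
        assert all(l == 0 for l in at.branch_lengths().values())

    def test_bootstrap_deterministic_under_seed(self, small_synth):
        _, _, alignment, _ = small_synth
        sub = alignment.subset(alignment.names[:6])
        a = nj_tree_hky(sub, n_bootstrap=20, seed=42)
        b = nj_tree_hky(sub, n_bootstrap=20, seed=42)
        assert a.bootstrap == b.bootstrap
        assert a.as_newick() == b.as_newick()

    def test_leaf_order_invariance_on_ultrametric_data(self, small_synth):
        _, _, alignment, _ = small_synth
        names = alignment.names[:4]
        f = nj_tree_hky(alignment.subset(names), n_bootstrap=0, seed=0)
        r = nj_tree_hky(alignment.subset(names[::-1]), n_bootstrap=0, seed=0)
        assert _splits(f.as_newick(), names) == _splits(r.as_newick(), names)

    def test_saturated_pair_raises_naming_pair(self):
        rng = np.random.default_rng(0)
        # random unrelated sequences are saturated under ML distance
        nts = "ACGT"
        recs = {
            n: "".join(nts[i] for i in rng.integers(0, 4, size=300))
            for n in "ABCD"
        }
        aln = CodonAlignment(recs)
        with pytest.raises(TreeError, match=r"\("):
            nj_tree_hky(aln, n_bootstrap=0, seed=0)


class TestFitch:
    def test_uniform_site_no_events(self):
        at = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        events = fitch_events(at, {n: "V" for n in "ABCD"})
        assert events == {}

    def test_single_internal_event(self):
        at = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        fitch_map(at, {"A": "V", "B": "V", "C": "G", "D": "G"})
        assert at.total_pbr_events() == 1
        (bid,) = at.pbr_events.keys()
        assert set(bid) in ({"A", "B"}, {"C", "D"})

    def test_parallel_flip_flop_two_events(self):
        at = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        fitch_map(at, {"A": "V", "B": "G", "C": "V", "D": "G"})
        assert at.total_pbr_events() == 2
        census = parallel_census(at)
        assert len(census) == 1
        assert census[0].exchange == frozenset({"V", "G"})
        assert len(census[0].branches) == 2

    def test_score_equals_events_and_brute_force(self, rng):
        # random 5-leaf trees, random 3-state characters
        for _ in range(25):
            newick = random_topology(list("ABCDE"), rng)
            at = tree_from(newick)
            states = {n: "KLM"[rng.integers(0, 3)] for n in "ABCDE"}
            score = fitch_site_score(at.tree, states)
            events = fitch_events(at, states)
            n_events = sum(len(v) for v in events.values())
            assert n_events == score
            assert score == brute_force_score(at, states)

    def test_wildcard_states_are_free(self):
        at = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        events = fitch_events(at, {"A": "V", "B": "X", "C": "V", "D": "-"})
        assert events == {}

    def test_length_mismatch_errors(self):
        at = tree_from("((A:1,B:1):1,C:1);")
        with pytest.raises(TreeError):
            fitch_events(at, {"A": "VV", "B": "V", "C": "V"})

    def test_multifurcation_handled(self):
        at = tree_from("(A:1,B:1,C:1,(D:1,E:1):1);")
        fitch_map(at, {"A": "V", "B": "V", "C": "V", "D": "G", "E": "G"})
        assert at.total_pbr_events() == 1


def random_topology(names, rng):
    """Random rooted binary topology by sequential attachment."""
    lineages = [f"{n}:1" for n in names]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append(f"({a},{b}):1")
    return lineages[0] + ";"


def brute_force_score(at: AnnotatedTree, states):
    """Minimal mutation count by enumerating all internal-node labelings."""
    alphabet = sorted(set(states.values()))
    internals = [
        n for n in at.tree.preorder_node_iter() if not n.is_leaf()
    ]
    best = None
    for labels in itertools.product(alphabet, repeat=len(internals)):
        assign = dict(zip(map(id, internals), labels))
        for leaf in at.tree.leaf_node_iter():
            assign[id(leaf)] = states[leaf.taxon.label]
        cost = sum(
            assign[id(n)] != assign[id(n.parent_node)]
            for n in at.tree.preorder_node_iter()
            if n.parent_node is not None
        )
        best = cost if best is None else min(best, cost)
    return best


class TestJttDistance:
    def test_identical_strings_zero(self):
        assert jtt_distance("ACDEF" * 6, "ACDEF" * 6) == 0.0

    def test_symmetry_random_pairs(self, rng):
        for _ in range(100):
            a = "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=27))
            b = "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=27))
            assert jtt_distance(a, b) == pytest.approx(jtt_distance(b, a))

    def test_small_distance_against_expm_oracle(self):
        a = "A" * 26 + "R"
        b = "A" * 26 + "N"  # p-distance 1/27
        d = jtt_distance(a, b)
        assert 0.5 / 27 <= d <= 3 / 27
        model = _load_jtt()
        freqs = model.freqs

        def negll(t):
            p = expm(model.q * t)
            ll = 26 * np.log(freqs[0] * p[0, 0])
            ll += np.log(freqs[1] * p[1, 2] + freqs[2] * p[2, 1]) - np.log(2.0)
            return -ll

        res = minimize_scalar(negll, bounds=(1e-9, 10.0), method="bounded",
                              options={"xatol": 1e-12})
        assert d == pytest.approx(res.x, abs=1e-6)

    def test_saturated_pair_capped_with_warning(self):
        a = "AR" * 20
        b = "WY" * 20
        with pytest.warns(UserWarning):
            d = jtt_distance(a, b)
        assert d == JTT_MAX_DISTANCE

    def test_all_ambiguous_errors(self):
        with pytest.raises(ValueError):
            jtt_distance("XX-", "X-X")

    def test_monotone_in_p_distance(self):
        base = "A" * 27
        prev = 0.0
        for k in (1, 3, 6, 9):
            other = "R" * k + "A" * (27 - k)
            d = jtt_distance(base, other)
            assert d > prev
            prev = d
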