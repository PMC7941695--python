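import itertools

import numpy as np
import pandas as pd
import pytest

from ylineage.fixtures import make_toy_tree
from ylineage.phylogeny import (Alignment, Clade, generate_dating_inputs,
                                ibs_distance, parsimony_score,
                                preliminary_tree, read_alignment,
                                resolve_polytomies, summarize_dating_output,
                                _upgma)

from conftest import fitch_brute_force


def hg_table(pairs):
    return pd.DataFrame(
        {"SampleID": [p[0] for p in pairs], "Haplogroup": [p[1] for p in pairs]})


def random_alignment(names, n_sites, rng):
    return Alignment({n: "".join(rng.choice(list("ACGT"), size=n_sites))
                      for n in names})


class TestPreliminaryTree:
    def test_sibling_and_outgroup_topology(self, toy_tree):
        tree, _ = toy_tree
        hg = hg_table([("x", "A1"), ("y", "A2"), ("z", "B1")])
        pre = preliminary_tree(hg, tree)
        assert frozenset({"x", "y"}) in pre.clades()
        assert set(pre.leaf_names()) == {"x", "y", "z"}

    def test_shared_haplogroup_polytomy_kept(self, toy_tree):
        tree, _ = toy_tree
        hg = hg_table([("x", "A11"), ("y", "A11"), ("z", "B")])
        pre = preliminary_tree(hg, tree)
        node = next(n for n in pre.postorder()
                    if not n.is_leaf and set(n.leaf_names()) == {"x", "y"})
        assert node.label == "A11"

    def test_unknown_haplogroup_dropped_with_warning(self, toy_tree, caplog):
        tree, _ = toy_tree
        hg = hg_table([("x", "A1"), ("y", "A2"), ("w", "NOPE")])
        pre = preliminary_tree(hg, tree)
        assert "w" not in pre.leaf_names()

    def test_clades_are_source_tree_clades(self, medium_tree):
        tree, _ = medium_tree
        rng = np.random.default_rng(5)
        terminals = [n for n in tree.nodes() if not tree.children.get(n)]
        pairs = [(f"s{i}", terminals[rng.integers(0, len(terminals))])
                 for i in range(30)]
        pre = preliminary_tree(hg_table(pairs), tree)
        assign = dict(pairs)
        for clade in pre.clades():
            hgs = {assign[s] for s in clade}
            # find lowest common ancestor haplogroup; clade = all samples below
            # some haplogroup node, so each clade must be ancestor-closed
            paths = [set(tree.path_from_root(h)) | {h, tree.root}
                     for h in hgs]
            common = set.intersection(*paths)
            assert common, f"clade {clade} has no common ancestor haplogroup"


class TestPolytomyResolution:
    def test_identical_sequences_tie_caterpillar(self):
        poly = Clade(label="H", children=[Clade(label=s)
                                          for s in ("c", "a", "b")])
        aln = Alignment({s: "AAAA" for s in "abc"})
        out = resolve_polytomies(poly, aln, "upgma")
        assert out.is_bifurcating()
        assert set(out.leaf_names()) == {"a", "b", "c"}

    @pytest.mark.parametrize("method", ["upgma", "mp", "ibs"])
    def test_two_clear_pairs(self, method):
        aln = Alignment({
            "a": "AAAAAAAAAA", "b": "AAAAAAAAAT",
            "c": "GGGGGGGGGG", "d": "GGGGGGGGGC",
        })
        poly = Clade(label="H", children=[Clade(label=s) for s in "abcd"])
        out = resolve_polytomies(poly, aln, method)
        assert out.is_bifurcating()
        clades = out.clades()
        # the ab|cd split must be respected (root placement varies between
        # rooted UPGMA and unrooted MP/NJ): no clade mixes exactly one of
        # {a,b} with one of {c,d}
        for bad in ({"a", "c"}, {"a", "d"}, {"b", "c"}, {"b", "d"}):
            assert frozenset(bad) not in clades
        assert frozenset({"a", "b"}) in clades or frozenset({"c", "d"}) in clades

    def test_mp_matches_exhaustive_parsimony(self):
        rng = np.random.default_rng(17)
        aln = random_alignment(list("abcde"), 12, rng)
        poly = Clade(children=[Clade(label=s) for s in "abcde"])
        out = resolve_polytomies(poly, aln, "mp")
        best = min(
            parsimony_score(t, aln)
            for t in _all_rooted_trees(list("abcde"))
        )
        assert parsimony_score(out, aln) == best

    def test_backbone_preservation_random_fixtures(self):
        rng = np.random.default_rng(23)
        for trial in range(15):
            tree, _ = make_toy_tree(seed=int(rng.integers(1, 2 ** 30)),
                                    depth=3, branching=2, markers_per_node=1)
            terminals = [n for n in tree.nodes() if not tree.children.get(n)]
            pairs = [(f"s{i}", terminals[rng.integers(0, len(terminals))])
                     for i in range(12)]
            pre = preliminary_tree(hg_table(pairs), tree)
            before = pre.clades()
            aln = random_alignment([p[0] for p in pairs], 20, rng)
            method = ["upgma", "mp", "ibs"][trial % 3]
            out = resolve_polytomies(pre, aln, method)
            assert out.is_bifurcating()
            assert before <= out.clades()
            assert sorted(out.leaf_names()) == sorted(pre.leaf_names())

    def test_no_alignment_deterministic_caterpillar(self):
        poly = Clade(children=[Clade(label=s) for s in ("d", "b", "a", "c")])
        out1 = resolve_polytomies(poly, None)
        poly2 = Clade(children=[Clade(label=s) for s in ("d", "b", "a", "c")])
        out2 = resolve_polytomies(poly2, None)
        assert out1.newick() == out2.newick()
        assert out1.is_bifurcating()

    def test_upgma_recovers_ultrametric_topology(self):
        # ((a,b),(c,d)) with ultrametric heights 1, 2, 4
        names = list("abcd")
        D = np.array([
            [0, 2, 8, 8],
            [2, 0, 8, 8],
            [8, 8, 0, 4],
            [8, 8, 4, 0],
        ], dtype=float)
        out = _upgma([Clade(label=n) for n in names], D)
        assert frozenset({"a", "b"}) in out.clades()
        assert frozenset({"c", "d"}) in out.clades()


def _all_rooted_trees(names):
    """Exhaustive rooted bifurcating topologies (tiny n only)."""
    if len(names) == 1:
        yield Clade(label=names[0])
        return
    first, rest = names[0], names[1:]
    for k in range(1, len(names)):
        for left_set in itertools.combinations(rest, k - 1):
            left = [first, *left_set]
            right = [n for n in rest if n not in left_set]
            if not right:
                continue
            for lt in _all_rooted_trees(left):
                for rt in _all_rooted_trees(right):
                    yield Clade(children=[lt, rt])


class TestParsimony:
    def test_identical_sequences_score_zero(self):
        t = Clade(children=[Clade(label="a"), Clade(label="b")])
        assert parsimony_score(t, Alignment({"a": "ACGT", "b": "ACGT"})) == 0

    def test_two_leaves_three_differences(self):
        t = Clade(children=[Clade(label="a"), Clade(label="b")])
        assert parsimony_score(t, Alignment({"a": "AAAA", "b": "TTTA"})) == 3

    def test_matches_brute_force_small_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(6):
            n = int(rng.integers(3, 6))
            names = [f"l{i}" for i in range(n)]
            aln = random_alignment(names, int(rng.integers(3, 9)), rng)
            trees = list(_all_rooted_trees(names))
            t = trees[rng.integers(0, len(trees))]
            assert parsimony_score(t, aln) == fitch_brute_force(t, aln)


class TestIbsDistance:
    def test_mismatch_proportion_ignores_missing(self):
        assert ibs_distance("AACC", "AATC") == pytest.approx(0.25)
        assert ibs_distance("AANN", "AAGG") == 0.0
        assert ibs_distance("NNNN", "ACGT") == 1.0  # no overlap -> 1 + warning


class TestDatingScaffold:
    def _tree(self):
        return Clade(label="Y-Adam", children=[
            Clade(label="A1", children=[Clade(label="s1"), Clade(label="s2")]),
            Clade(label="s3"),
        ])

    def _aln(self):
        return Alignment({"s1": "AAAA", "s2": "AAAT", "s3": "TTTT"})

    def test_bundle_files_reference_each_other(self, tmp_path):
        paths = generate_dating_inputs(self._tree(), self._aln(), None,
                                       tmp_path)
        ctl = open(paths["ctlfile"]).read()
        import os

        assert os.path.basename(paths["seqfile"]) in ctl
        assert os.path.basename(paths["treefile"]) in ctl
        tree_text = open(paths["treefile"]).read()
        assert ">" in tree_text and "<" in tree_text

    def test_user_calibration_overrides_builtin(self, tmp_path):
        paths = generate_dating_inputs(
            self._tree(), self._aln(), {"A1": (10.0, 20.0)}, tmp_path)
        tree_text = open(paths["treefile"]).read()
        assert ">0.1<0.2" in tree_text

    def test_polytomy_refused(self, tmp_path):
        poly = Clade(label="Y-Adam", children=[
            Clade(label=s) for s in ("s1", "s2", "s3")])
        with pytest.raises(ValueError, match="polytom"):
            generate_dating_inputs(poly, self._aln(), None, tmp_path)

    def test_no_matching_calibration_errors(self, tmp_path):
        t = Clade(label="X0", children=[
            Clade(label="X1", children=[Clade(label="s1"), Clade(label="s2")]),
            Clade(label="s3"),
        ])
        with pytest.raises(ValueError, match="calibration"):
            generate_dating_inputs(t, self._aln(), None, tmp_path)


class TestDatingOutputParsing:
    def test_fixture_output_parsed_and_mapped(self, tmp_path):
        # synthetic stand-in for the dating program's node-time summary
        out = tmp_path / "dates.out"
        out.write_text("header line\nt_n4  0.25 (0.20, 0.31)\n"
                       "t_n5  0.07 (0.05, 0.10)\n")
        tree = Clade(label="Y-Adam", children=[
            Clade(label="A1", children=[Clade(label="s1"), Clade(label="s2")]),
            Clade(label="s3"),
        ])
        table = summarize_dating_output(out, tree)
        assert list(table["label"]) == ["Y-Adam", "A1"]
        assert table["mean"].iloc[0] == pytest.approx(0.25)

    def test_empty_file_is_parse_error(self, tmp_path):
        out = tmp_path / "empty.out"
        out.write_text("")
        with pytest.raises(ValueError):
            summarize_dating_output(out)

    def test_unknown_node_retained_unmapped(self, tmp_path):
        out = tmp_path / "extra.out"
        out.write_text("t_n4  0.25 (0.2, 0.3)\nt_n99  0.5 (0.4, 0.6)\n")
        tree = Clade(children=[Clade(label="s1"), Clade(label="s2")])
        table = summarize_dating_output(out, tree)
        assert len(table) == 2
        assert table["label"].iloc[1] == ""


def test_alignment_formats_roundtrip(tmp_path):
    fa = tmp_path / "a.fasta"
    fa.write_text(">s1\nACGT\n>s2\nACGA\n")
    a1 = read_alignment(fa, "fasta")
    phy = tmp_path / "a.phy"
    phy.write_text(" 2 4\ns1  ACGT\ns2  ACGA\n")
    a2 = read_alignment(phy, "phylip")
    meg = tmp_path / "a.meg"
    meg.write_text("#MEGA\n!Title t;\n#s1\nACGT\n#s2\nACGA\n")
    a3 = read_alignment(meg, "meg")
    assert a1.seqs == a2.seqs == a3.seqs
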