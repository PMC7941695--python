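import io

import numpy as np
import pytest

from ylineage.classify import (ClassifierConfig, HaplogroupMatch,
                               SampleGenotypes, classify_sample,
                               classify_samples, enumerate_tracks,
                               read_genotypes_variant_table, score_haplogroups,
                               select_track, refine_terminal, write_hg_table)
from ylineage.fixtures import make_toy_tree, simulate_genotype_table
from ylineage.tree import load_marker_panel

from conftest import brute_force_best_track

CHAIN_PANEL = """haplogroup\tparent\tmarker\tposition\tancestral\tderived\tkey
A\tY-Adam\tM1\t100\tA\tG\t1
A\tY-Adam\tM2\t110\tC\tT\t1
B\tA\tM3\t200\tG\tA\t1
B\tA\tM4\t210\tT\tC\t1
C\tB\tM5\t300\tA\tC\t1
C\tB\tM6\t310\tG\tT\t1
D\tY-Adam\tM7\t400\tC\tG\t1
"""


def chain_tree():
    return load_marker_panel(io.StringIO(CHAIN_PANEL))


def geno(calls, absent=(), source="variant-table"):
    return SampleGenotypes("s", calls, frozenset(absent), source)


class TestVcfReader:
    def test_derived_call_read(self, toy_tree, vcf_factory):
        tree, markers = toy_tree
        path, truth = vcf_factory(tree, 3, seed=5)
        gs = read_genotypes_variant_table(path, [m.position for m in markers])
        assert [g.sample for g in gs] == ["S001", "S002", "S003"]
        by_hg = {m.position: m for m in markers}
        for g in gs:
            onpath = set(tree.path_from_root(truth[g.sample]))
            for pos, base in g.calls.items():
                mk = by_hg[pos]
                expect = mk.derived if mk.haplogroup in onpath else mk.ancestral
                assert base == expect

    def test_missing_call_not_in_map_nor_absent_set(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=Y>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "Y\t100\t.\tA\tG\t.\tPASS\t.\tGT\t.\n"
        )
        g = read_genotypes_variant_table(vcf, [100, 200])[0]
        assert 100 not in g.calls and 100 not in g.absent
        assert 200 in g.absent

    def test_heterozygous_call_skipped(self, tmp_path):
        vcf = tmp_path / "h.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=Y>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "Y\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
            "Y\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\n"
        )
        g = read_genotypes_variant_table(vcf, [100, 200])[0]
        assert 100 not in g.calls
        assert g.calls[200] == "T"


class TestScoring:
    def test_direct_count(self):
        tree, _ = chain_tree()
        g = geno({100: "G", 110: "C", 200: "A", 210: "T"})
        m = score_haplogroups(g, tree, ClassifierConfig())
        assert (m["A"].n, m["A"].m) == (1, 2)
        assert (m["B"].n, m["B"].m) == (1, 2)
        assert m["A"].rate == 0.5

    def test_hidden_reference_rule_sequencing_mode(self):
        # derived allele equals the reference base; position absent from table
        panel = (
            "haplogroup\tparent\tmarker\tposition\tancestral\tderived\tkey\tref\n"
            "A\tY-Adam\tM1\t100\tA\tG\t1\tG\n"
            "A\tY-Adam\tM2\t110\tC\tT\t1\tC\n"
        )
        tree, _ = load_marker_panel(io.StringIO(panel))
        g = geno({110: "T"}, absent={100})
        m = score_haplogroups(g, tree, ClassifierConfig())
        assert (m["A"].n, m["A"].m) == (2, 2)  # hidden ref counted derived

    def test_array_mode_absent_is_unscorable(self):
        tree, _ = chain_tree()
        g = geno({110: "T"}, absent={100})
        m = score_haplogroups(g, tree, ClassifierConfig(array_mode=True))
        assert (m["A"].n, m["A"].m) == (1, 1)

    def test_hidden_reference_noop_when_ref_is_ancestral(self):
        tree, _ = chain_tree()  # every ref == ancestral
        g = geno({}, absent={100, 110, 200, 210, 300, 310, 400})
        m = score_haplogroups(g, tree, ClassifierConfig())
        assert all(mt.n == 0 for mt in m.values())


class TestTracks:
    def test_full_support_track(self):
        tree, _ = chain_tree()
        g = geno({100: "G", 110: "T", 200: "A", 210: "C", 300: "C", 310: "T",
                  400: "C"})
        cfg = ClassifierConfig()
        m = score_haplogroups(g, tree, cfg)
        tracks = enumerate_tracks(m, tree, cfg)
        best = select_track(tracks, m)
        assert best.path == ("A", "B", "C")
        assert best.r == 3 and best.t == 1.0

    def test_unscorable_middle_level_lowers_t(self):
        tree, _ = chain_tree()
        g = geno({100: "G", 110: "T", 300: "C", 310: "T", 400: "C"})
        cfg = ClassifierConfig()
        m = score_haplogroups(g, tree, cfg)
        tracks = enumerate_tracks(m, tree, cfg)
        c_track = next(tr for tr in tracks if tr.terminal == "C")
        assert c_track.t == pytest.approx(2 / 3)
        assert c_track.support == (1, 0, 1)

    def test_selection_prefers_higher_t_then_deeper(self):
        tree, _ = chain_tree()
        cfg = ClassifierConfig()
        full = geno({100: "G", 110: "T", 200: "A", 210: "C", 300: "C",
                     310: "T", 400: "G"})  # D also derived at its key marker
        m = score_haplogroups(full, tree, cfg)
        tracks = enumerate_tracks(m, tree, cfg)
        assert {tr.terminal for tr in tracks} >= {"C", "D"}
        best = select_track(tracks, m)
        # both t=1.0; C wins on resolution r=3 vs 1
        assert best.terminal == "C"

    def test_single_error_candidate_excluded_by_selection(self):
        tree, _ = chain_tree()
        cfg = ClassifierConfig()
        # true lineage A->B->C, plus one sequencing error deriving D
        g = geno({100: "G", 110: "T", 200: "A", 210: "C", 300: "C", 310: "T",
                  400: "G"})
        m = score_haplogroups(g, tree, cfg)
        dts = [tr for tr in enumerate_tracks(m, tree, cfg)
               if tr.terminal == "D"]
        assert dts and dts[0].t == 1.0  # candidate exists (r=1)
        assert select_track(enumerate_tracks(m, tree, cfg), m).terminal == "C"

    def test_empty_tracks_raise(self):
        with pytest.raises(ValueError):
            select_track([], {})

    def test_lowering_cutoff_never_decreases_t(self, medium_tree):
        tree, markers = medium_tree
        rng = np.random.default_rng(3)
        calls = {m.position: (m.derived if rng.random() < 0.4 else m.ancestral)
                 for m in markers}
        g = geno(calls)
        for hi, lo in [(0.9, 0.6), (0.7, 0.3)]:
            mh = score_haplogroups(g, tree, ClassifierConfig(cutoff=hi))
            ml = score_haplogroups(g, tree, ClassifierConfig(cutoff=lo))
            for term in mh:
                hi_tr = next(
                    (t for t in enumerate_tracks(
                        mh, tree, ClassifierConfig(cutoff=hi), False)
                     if t.terminal == term), None)
                lo_tr = next(
                    (t for t in enumerate_tracks(
                        ml, tree, ClassifierConfig(cutoff=lo), False)
                     if t.terminal == term), None)
                if hi_tr and lo_tr:
                    assert lo_tr.t >= hi_tr.t - 1e-12


class TestRefinement:
    def test_descends_through_ordinary_support(self):
        panel = CHAIN_PANEL + (
            "C1\tC\tM8\t500\tA\tG\t0\n"
            "C1\tC\tM9\t510\tT\tA\t0\n"
        )
        tree, _ = load_marker_panel(io.StringIO(panel))
        cfg = ClassifierConfig()
        g = geno({100: "G", 110: "T", 200: "A", 210: "C", 300: "C", 310: "T",
                  500: "G", 510: "A"})
        m = score_haplogroups(g, tree, cfg)
        best = select_track(enumerate_tracks(m, tree, cfg), m)
        assert best.terminal == "C"  # C1 has no key marker
        final, ann = refine_terminal(best, m, tree, cfg)
        assert final == "C1"
        assert set(ann.split(",")) == {"M8", "M9"}

    def test_no_supported_descendants_keeps_terminal(self):
        tree, _ = chain_tree()
        cfg = ClassifierConfig()
        g = geno({100: "G", 110: "T", 200: "A", 210: "C"})
        m = score_haplogroups(g, tree, cfg)
        best = select_track(enumerate_tracks(m, tree, cfg), m)
        final, ann = refine_terminal(best, m, tree, cfg)
        assert final == best.terminal == "B"
        assert ann == ""


class TestOracleEquivalence:
    def test_selection_matches_brute_force_on_random_instances(self):
        """Spot check of the exhaustive-search equivalence (full sweep in the
        acceptance suite)."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            tree, markers = make_toy_tree(
                seed=int(rng.integers(1, 2 ** 30)),
                depth=int(rng.integers(2, 5)), branching=2,
                markers_per_node=3)
            calls = {m.position: (m.derived if rng.random() < 0.35
                                  else m.ancestral) for m in markers}
            g = geno(calls)
            cfg = ClassifierConfig()
            m = score_haplogroups(g, tree, cfg)
            tracks = enumerate_tracks(m, tree, cfg) or \
                enumerate_tracks(m, tree, cfg, require_key=False)
            if not tracks:
                continue
            best = select_track(tracks, m)
            bt, terms = brute_force_best_track(m, tree, cfg.cutoff)
            assert best.t == pytest.approx(bt)
            assert best.terminal in terms


class TestEndToEnd:
    def test_error_free_recovery(self, medium_tree, vcf_factory):
        tree, _ = medium_tree
        path, truth = vcf_factory(tree, 20, seed=9)
        results = classify_samples([path], tree)
        assert all(r.final_terminal == truth[r.sample] for r in results)
        assert all(r.t == 1.0 for r in results)

    def test_empty_table_all_unresolved(self, tmp_path, toy_tree):
        tree, _ = toy_tree
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=Y>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        )
        results = classify_samples(
            [vcf], tree, ClassifierConfig(array_mode=True))
        assert all(r.final_terminal == tree.root for r in results)
        assert all(r.mutations == "unresolved" for r in results)

    def test_output_is_deterministic(self, medium_tree, vcf_factory, tmp_path):
        tree, _ = medium_tree
        path, _ = vcf_factory(tree, 10, seed=3, error_rate=0.05)
        outs = []
        for i in range(2):
            res = classify_samples([path], tree)
            out = tmp_path / f"o{i}.hg"
            write_hg_table(res, out)
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]


class TestPileupReader:
    def _bam(self, tmp_path, pos, bases, quals=None):
        import pysam

        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "Y", "LN": 60_000_000}],
                  "RG": [{"ID": "rg1", "SM": "PS1"}]}
        path = tmp_path / "p.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for i, b in enumerate(bases):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"r{i}"
                a.query_sequence = "A" * 10 + b + "A" * 10
                a.flag = 0
                a.reference_id = 0
                a.reference_start = pos - 1 - 10
                a.mapping_quality = 60
                a.cigarstring = "21M"
                a.query_qualities = pysam.qualitystring_to_array("I" * 21)
                a.set_tag("RG", "rg1")
                bam.write(a)
        pysam.index(str(path))
        return path

    def test_unanimous_reads_called(self, tmp_path):
        path = self._bam(tmp_path, 500, ["G"] * 10)
        from ylineage.classify import read_genotypes_pileup

        res = read_genotypes_pileup(path, [500], ClassifierConfig())
        assert res.sample == "PS1"
        assert res.calls[500] == "G"

    def test_majority_wins(self, tmp_path):
        path = self._bam(tmp_path, 500, ["G"] * 6 + ["T"] * 4)
        from ylineage.classify import read_genotypes_pileup

        res = read_genotypes_pileup(path, [500], ClassifierConfig())
        assert res.calls[500] == "G"

    def test_below_min_depth_unscorable(self, tmp_path):
        path = self._bam(tmp_path, 500, ["G"])
        from ylineage.classify import read_genotypes_pileup

        res = read_genotypes_pileup(path, [500],
                                    ClassifierConfig(min_depth=2))
        assert 500 not in res.calls

    def test_tied_majority_unscorable(self, tmp_path):
        path = self._bam(tmp_path, 500, ["G", "G", "T", "T"])
        from ylineage.classify import read_genotypes_pileup

        res = read_genotypes_pileup(path, [500], ClassifierConfig())
        assert 500 not in res.calls
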