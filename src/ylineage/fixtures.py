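"""Synthetic data generators for every input the analysis modules consume.

Toy haplogroup trees with marker panels, multi-sample haploid VCFs with
known terminal-haplogroup truth, STR read windows/alignments with known
repeat numbers, and star-genealogy STR tables under symmetric single-step
mutation.  All generators are deterministic under a fixed seed; emitted
files validate against the package's own readers.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import HaploTree, Marker
from .strpanel import STRLocus

__all__ = [
    "make_toy_tree",
    "simulate_genotype_table",
    "simulate_str_reads",
    "simulate_star_strs",
]

_BASES = "ACGT"


@dataclass
class ToyTreeSpec:
    depth: int = 3
    branching: int = 2
    markers_per_node: int = 3
    key_fraction: float = 0.5
    ref_derived_fraction: float = 0.1  # markers whose derived allele is the
    # reference base (exercises the hidden-reference rule)


def make_toy_tree(seed: int, depth: int = 3, branching: int = 2,
                  markers_per_node: int = 3, key_fraction: float = 0.5,
                  ref_derived_fraction: float = 0.1
                  ) -> tuple[HaploTree, list[Marker]]:
    """Balanced toy haplogroup tree with synthetic marker positions/alleles.

    Node names follow ISOGG-like nesting (A, A1, A12, ...).  Every node gets
    at least one key marker; additional markers are key with probability
    ``key_fraction``.  A ``ref_derived_fraction`` of markers have their
    reference base equal to the derived allele, the situation the
    hidden-reference rule exists for.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if branching < 1 or branching > 26:
        raise ValueError("branching must be in 1..26")
    rng = np.random.default_rng(seed)
    tree = HaploTree()
    # breadth-first node creation
    level = []
    for i in range(branching):
        name = string.ascii_uppercase[i]
        tree.add_node(name, tree.root)
        level.append(name)
    for _ in range(depth - 1):
        nxt = []
        for parent in level:
            for i in range(branching):
                name = f"{parent}{i + 1}"
                tree.add_node(name, parent)
                nxt.append(name)
        level = nxt

    markers: list[Marker] = []
    pos = 2_700_000
    for node in tree.nodes():
        if node == tree.root:
            continue
        for k in range(markers_per_node):
            pos += int(rng.integers(50, 500))
            anc, der = rng.choice(list(_BASES), size=2, replace=False)
            ref = der if rng.random() < ref_derived_fraction else anc
            m = Marker(
                name=f"M{pos}", haplogroup=node, position=pos,
                ancestral=str(anc), derived=str(der),
                is_key=(k == 0) or (rng.random() < key_fraction),
                ref=str(ref),
            )
            tree.add_marker(m)
            markers.append(m)
    return tree, markers


def _terminals(tree: HaploTree) -> list[str]:
    return sorted(n for n in tree.nodes()
                  if n != tree.root and not tree.children.get(n))


def simulate_genotype_table(tree: HaploTree, n_samples: int, seed: int,
                            error_rate: float = 0.0, missing_rate: float = 0.0,
                            path=None) -> tuple[str, dict[str, str]]:
    """Multi-sample haploid VCF text with known terminal-haplogroup truth.

    Each sample is assigned a terminal haplogroup (cycled deterministically
    over terminals, order shuffled by the seed); it carries the derived
    allele at every marker on its root path and the ancestral allele
    elsewhere.  Genotype errors flip a call to the opposite allele; missing
    calls become '.'.  Positions where every sample's base equals the
    reference are omitted from the records — the hidden-reference situation
    of real sequencing VCFs.

    Returns ``(vcf_text, truth)``; also writes to ``path`` when given.
    """
    rng = np.random.default_rng(seed)
    terminals = _terminals(tree)
    order = list(rng.permutation(terminals))
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    truth = {s: order[i % len(order)] for i, s in enumerate(samples)}
    path_sets = {t: set(tree.path_from_root(t)) for t in terminals}

    markers = sorted(tree.all_markers(), key=lambda m: m.position)
    rows = []
    for mk in markers:
        bases = []
        for s in samples:
            b = mk.derived if mk.haplogroup in path_sets[truth[s]] else mk.ancestral
            if error_rate and rng.random() < error_rate:
                b = mk.ancestral if b == mk.derived else mk.derived
            if missing_rate and rng.random() < missing_rate:
                b = "."
            bases.append(b)
        non_missing = [b for b in bases if b != "."]
        if non_missing and all(b == mk.ref for b in non_missing) and \
                "." not in bases:
            continue  # all samples match the reference: record not emitted
        alts = sorted({b for b in non_missing if b != mk.ref})
        allele_idx = {mk.ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
        gts = [("." if b == "." else str(allele_idx[b])) for b in bases]
        alt_field = ",".join(alts) if alts else "."
        rows.append(
            f"Y\t{mk.position}\t{mk.name}\t{mk.ref}\t{alt_field}\t.\tPASS\t."
            f"\tGT\t" + "\t".join(gts)
        )
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=Y,length=60000000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    text = header + "\n".join(rows) + ("\n" if rows else "")
    if path is not None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(text)
    return text, truth


def _random_flank(rng, length: int, forbid: str) -> str:
    """Random sequence guaranteed not to start with the motif."""
    while True:
        s = "".join(rng.choice(list(_BASES), size=length))
        if not s.startswith(forbid):
            return s


def simulate_str_reads(locus: STRLocus, true_repeat: int, coverage: int,
                       seed: int, read_length: int = 150, flank: int = 20,
                       path=None, sample: str = "S1"):
    """Aligned reads carrying a known STR allele, written as a BAM.

    The sample allele replaces the last motif block's count so the total
    repeat number equals ``true_repeat``; reads span the locus with the
    left flank anchored upstream of the locus start.  Requires an output
    ``path`` (BAM + index are created there).
    """
    import pysam

    rng = np.random.default_rng(seed)
    delta = true_repeat - locus.p
    last_motif, last_count = locus.motifs[-1]
    if last_count + delta < 1:
        raise ValueError("true_repeat leaves the last motif block empty")
    allele_motifs = locus.motifs[:-1] + ((last_motif, last_count + delta),)
    allele_seq = "".join(m * c for m, c in allele_motifs)
    left = _random_flank(rng, flank, locus.motifs[0][0])
    right = _random_flank(rng, max(read_length, flank), last_motif)

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "Y", "LN": 60_000_000}],
              "RG": [{"ID": "rg1", "SM": sample}]}
    if path is None:
        raise ValueError("simulate_str_reads requires an output path")
    reads = []
    for i in range(coverage):
        jitter = int(rng.integers(0, max(flank // 2, 1)))
        ref_start0 = locus.start - 1 - flank + jitter
        seq = (left[jitter:] + allele_seq + right)[:read_length]
        reads.append((f"r{i + 1:03d}", ref_start0, seq))
    reads.sort(key=lambda r: r[1])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, start0, seq in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start0
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("RG", "rg1")
            bam.write(a)
    pysam.index(str(path))
    return path


def simulate_star_strs(n: int, loci, mu: float, depth: float, seed: int
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Star-genealogy STR haplotypes under symmetric single-step mutation.

    Every lineage accumulates Poisson(mu * depth) mutations per locus, each
    shifting the repeat number by +/-1 with equal probability.  Returns the
    haplotype table and the ancestral haplotype.
    """
    rng = np.random.default_rng(seed)
    if isinstance(loci, int):
        loci = [f"L{i + 1}" for i in range(loci)]
    loci = list(loci)
    anc = pd.Series(rng.integers(10, 21, size=len(loci)).astype(float),
                    index=loci)
    k = rng.poisson(mu * depth, size=(n, len(loci)))
    steps = np.zeros_like(k, dtype=float)
    flat = k.ravel()
    draws = [rng.choice([-1, 1], size=int(c)).sum() if c else 0 for c in flat]
    steps = np.array(draws, dtype=float).reshape(k.shape)
    table = pd.DataFrame(
        steps + anc.to_numpy()[None, :], columns=loci,
        index=[f"S{i + 1:03d}" for i in range(n)],
    )
    return table, anc
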