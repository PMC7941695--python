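"""NRY haplogroup classification by lineage tracking.

A male sample's Y-chromosome haplogroup is determined by which
haplogroup-defining SNPs carry the derived allele.  Rather than reporting the
single deepest matching haplogroup (which is sensitive to genotyping error),
classification here scores whole root-to-terminal *lineage tracks*:

* per haplogroup, the **matching rate** ``n/m`` — the fraction of its
  scorable markers observed in the derived state;
* per candidate track ending at a terminal of resolution (depth) ``r``, the
  **tracking rate** ``t = (sum_i R_i) / r`` where ``R_i = 1`` iff the i-th
  haplogroup on the track has matching rate ``>= U`` (the cutoff).

The track maximizing ``t`` is selected; haplogroups matched only through
sporadic errors sit on tracks whose other levels fail the cutoff and are
thereby excluded.  Terminals are first restricted to haplogroups supported
by at least one derived *key* marker; when no key haplogroup passes (e.g.
genotyping-array input), the same procedure runs on ordinary haplogroups.

For sequencing-derived VCFs, a panel position absent from the file is taken
to carry the reference base for every sample (sites where all samples match
the reference are not emitted); this *hidden-reference* rule lets markers
whose derived allele equals the reference base still score.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import pysam

from .tree import HaploTree

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "SampleGenotypes",
    "HaplogroupMatch",
    "LineageTrack",
    "ClassificationResult",
    "read_genotypes_variant_table",
    "read_genotypes_pileup",
    "score_haplogroups",
    "enumerate_tracks",
    "select_track",
    "refine_terminal",
    "classify_sample",
    "classify_samples",
    "write_hg_table",
]

HG_COLUMNS = ["SampleID", "KeyHaplogroup", "Haplogroup", "TrackingRate", "Mutations"]


@dataclass
class ClassifierConfig:
    """Tunables for haplogroup classification.

    cutoff : matching-rate threshold U in (0, 1]; default 0.7 tolerates one
        miss among small marker sets while rejecting single-marker
        coincidences.
    array_mode : True for non-sequencing (genotyping-array) variant tables,
        where panel positions absent from the table are unscorable rather
        than reference-equal.
    """

    cutoff: float = 0.7
    min_depth: int = 2
    min_base_quality: int = 13
    min_mapping_quality: int = 20
    array_mode: bool = False

    def __post_init__(self):
        if not 0 < self.cutoff <= 1:
            raise ValueError("cutoff U must be in (0, 1]")


@dataclass
class SampleGenotypes:
    """Observed haploid base calls of one sample at panel positions."""

    sample: str
    calls: dict[int, str]
    absent: frozenset[int] = frozenset()  # panel positions with no table record
    source: str = "variant-table"


@dataclass
class HaplogroupMatch:
    haplogroup: str
    n: int  # markers observed derived
    m: int  # scorable markers
    key_derived: bool
    derived_markers: tuple[str, ...] = ()

    @property
    def rate(self) -> float:
        return self.n / self.m


@dataclass
class LineageTrack:
    """A root-to-terminal candidate path with its tracking rate."""

    path: tuple[str, ...]  # child of root ... terminal
    support: tuple[int, ...]  # R_i per haplogroup on the path

    @property
    def terminal(self) -> str:
        return self.path[-1]

    @property
    def r(self) -> int:
        return len(self.path)

    @property
    def t(self) -> float:
        return sum(self.support) / self.r


@dataclass
class ClassificationResult:
    sample: str
    key_haplogroup: str
    final_terminal: str
    t: float
    track: LineageTrack | None
    mutations: str = ""

    @property
    def resolved(self) -> bool:
        return self.track is not None


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------

_CHRY = {"Y", "chrY", "y", "24"}


def read_genotypes_variant_table(path, panel_positions) -> list[SampleGenotypes]:
    """Read haploid chrY base calls for every sample of a VCF.

    Heterozygous diploid calls (pseudo-autosomal leakage or errors) and
    missing calls are excluded from the per-sample map; only positions with
    no record at all enter the absent-set (the substrate of the
    hidden-reference rule).
    """
    panel_positions = set(panel_positions)
    seen_positions: set[int] = set()
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    calls: dict[str, dict[int, str]] = {s: {} for s in samples}
    n_y = 0
    for rec in vf:
        if rec.chrom not in _CHRY:
            continue
        n_y += 1
        if rec.pos not in panel_positions:
            continue
        seen_positions.add(rec.pos)
        alleles = rec.alleles
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                continue
            idx = {a for a in gt if a is not None}
            if len(idx) != 1:
                logger.warning(
                    "%s: heterozygous chrY call at %d skipped", s, rec.pos
                )
                continue
            allele = alleles[idx.pop()]
            if allele is None or len(allele) != 1 or allele.upper() not in "ACGT":
                continue
            calls[s][rec.pos] = allele.upper()
    vf.close()
    if n_y == 0:
        logger.warning("%s: no chrY records found", path)
    absent = frozenset(panel_positions - seen_positions)
    return [
        SampleGenotypes(sample=s, calls=calls[s], absent=absent, source="variant-table")
        for s in samples
    ]


def read_genotypes_pileup(path, panel_positions, cfg: ClassifierConfig,
                          sample: str | None = None) -> SampleGenotypes:
    """Majority base call per panel position from one sample's alignments.

    Positions below ``cfg.min_depth`` passing reads, or with a tied majority,
    are unscorable.  The absent-set stays empty: alignments observe
    reference-equal bases directly, so no hidden-reference inference is
    needed.
    """
    panel_positions = sorted(set(panel_positions))
    af = pysam.AlignmentFile(os.fspath(path))
    if sample is None:
        rgs = af.header.to_dict().get("RG", [])
        sample = rgs[0]["SM"] if rgs and "SM" in rgs[0] else os.path.basename(
            os.fspath(path)).rsplit(".", 1)[0]
    contig = next((c for c in af.references if c in _CHRY), None)
    calls: dict[int, str] = {}
    if contig is not None:
        for pos in panel_positions:
            counts: dict[str, int] = {}
            for col in af.pileup(contig, pos - 1, pos, truncate=True,
                                 min_base_quality=cfg.min_base_quality,
                                 min_mapping_quality=cfg.min_mapping_quality):
                for pr in col.pileups:
                    if pr.is_del or pr.is_refskip or pr.query_position is None:
                        continue
                    b = pr.alignment.query_sequence[pr.query_position].upper()
                    if b in "ACGT":
                        counts[b] = counts.get(b, 0) + 1
            depth = sum(counts.values())
            if depth < cfg.min_depth or not counts:
                continue
            top = max(counts.values())
            winners = [b for b, c in counts.items() if c == top]
            if len(winners) == 1:  # ties are unscorable
                calls[pos] = winners[0]
    af.close()
    return SampleGenotypes(sample=sample, calls=calls, absent=frozenset(),
                           source="pileup")


# ---------------------------------------------------------------------------
# scoring and track selection
# ---------------------------------------------------------------------------

def score_haplogroups(g: SampleGenotypes, tree: HaploTree,
                      cfg: ClassifierConfig) -> dict[str, HaplogroupMatch]:
    """Matching rate n/m for every haplogroup with >= 1 scorable marker."""
    sequencing = (g.source == "variant-table") and not cfg.array_mode
    out: dict[str, HaplogroupMatch] = {}
    for hg, markers in tree.markers.items():
        n = m = 0
        key_derived = False
        derived: list[str] = []
        for mk in markers:
            base = g.calls.get(mk.position)
            if base is None:
                if sequencing and mk.position in g.absent:
                    base = mk.ref  # hidden-reference rule
                else:
                    continue  # unscorable
            m += 1
            if base == mk.derived:
                n += 1
                derived.append(mk.name)
                if mk.is_key:
                    key_derived = True
        if m:
            out[hg] = HaplogroupMatch(hg, n, m, key_derived, tuple(derived))
    return out


def _track_for_terminal(terminal: str, matches, tree: HaploTree,
                        U: float) -> LineageTrack:
    path = tuple(tree.path_from_root(terminal))
    support = tuple(
        1 if (h in matches and matches[h].rate >= U) else 0 for h in path
    )
    return LineageTrack(path=path, support=support)


def enumerate_tracks(matches: dict[str, HaplogroupMatch], tree: HaploTree,
                     cfg: ClassifierConfig,
                     require_key: bool = True) -> list[LineageTrack]:
    """Candidate lineage tracks ending at every cutoff-passing haplogroup.

    With ``require_key`` the terminal must additionally carry a derived key
    marker (the key pass); the ordinary fallback re-runs without it.
    Haplogroups with no scorable markers contribute R_i = 0 on any track
    through them.
    """
    U = cfg.cutoff
    terms = [
        h for h, mt in matches.items()
        if mt.rate >= U and (mt.key_derived or not require_key)
    ]
    return [_track_for_terminal(h, matches, tree, U) for h in sorted(terms)]


def _n_key_on_track(track: LineageTrack, matches) -> int:
    return sum(
        1 for h in track.path if h in matches and matches[h].key_derived
    )


def select_track(tracks: list[LineageTrack],
                 matches: dict[str, HaplogroupMatch]) -> LineageTrack:
    """The maximal-tracking-rate track.

    Ties break deterministically: greater resolution r, then more
    key-derived haplogroups on the track, then lexicographically smallest
    terminal name.
    """
    if not tracks:
        raise ValueError("no candidate tracks: sample unresolved")
    return sorted(
        tracks,
        key=lambda tr: (-tr.t, -tr.r, -_n_key_on_track(tr, matches), tr.terminal),
    )[0]


def refine_terminal(track: LineageTrack, matches: dict[str, HaplogroupMatch],
                    tree: HaploTree, cfg: ClassifierConfig) -> tuple[str, str]:
    """Greedy descent below the key terminal through ordinary support.

    Downstream haplogroups lacking key markers can still be supported by
    derived ordinary markers; descending through children whose matching
    rate passes the cutoff refines the final terminal.  Returns
    ``(final_terminal, mutation_annotation)``; the annotation lists the
    supporting derived markers of the refined levels.
    """
    node = track.terminal
    supporting: list[str] = []
    while True:
        cands = [
            c for c in tree.children.get(node, [])
            if c in matches and matches[c].rate >= cfg.cutoff
        ]
        if not cands:
            break
        if len(cands) > 1:
            logger.info(
                "ambiguous refinement below %s: %s", node, sorted(cands)
            )
        # highest matching rate, then lexicographic name
        node = sorted(cands, key=lambda c: (-matches[c].rate, c))[0]
        supporting.extend(matches[node].derived_markers)
    annotation = ",".join(supporting)
    return node, annotation


def classify_sample(g: SampleGenotypes, tree: HaploTree,
                    cfg: ClassifierConfig) -> ClassificationResult:
    matches = score_haplogroups(g, tree, cfg)
    tracks = enumerate_tracks(matches, tree, cfg, require_key=True)
    if not tracks:  # ordinary fallback (non-sequencing input / low resolution)
        tracks = enumerate_tracks(matches, tree, cfg, require_key=False)
    if not tracks:
        return ClassificationResult(
            sample=g.sample, key_haplogroup=tree.root,
            final_terminal=tree.root, t=0.0, track=None,
            mutations="unresolved",
        )
    best = select_track(tracks, matches)
    final, annotation = refine_terminal(best, matches, tree, cfg)
    return ClassificationResult(
        sample=g.sample, key_haplogroup=best.terminal, final_terminal=final,
        t=best.t, track=best, mutations=annotation,
    )


def classify_samples(paths, tree: HaploTree, cfg: ClassifierConfig | None = None,
                     bam: bool = False) -> list[ClassificationResult]:
    """Classify every sample of one or more VCF (or alignment) files."""
    cfg = cfg or ClassifierConfig()
    positions = [m.position for m in tree.all_markers()]
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    genotypes: list[SampleGenotypes] = []
    for p in paths:
        if bam:
            genotypes.append(read_genotypes_pileup(p, positions, cfg))
        else:
            genotypes.extend(read_genotypes_variant_table(p, positions))
    return [classify_sample(g, tree, cfg) for g in genotypes]


def write_hg_table(results: list[ClassificationResult], path) -> None:
    """Write the tab-delimited '.hg' classification table."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(HG_COLUMNS) + "\n")
        for r in results:
            fh.write(
                f"{r.sample}\t{r.key_haplogroup}\t{r.final_terminal}\t"
                f"{r.t:.4f}\t{r.mutations or '.'}\n"
            )


def read_hg_table(path) -> "pandas.DataFrame":
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ("SampleID", "Haplogroup") if c not in df.columns]
    if missing:
        raise ValueError(f".hg table missing columns {missing}")
    return df
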