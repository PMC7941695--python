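"""Y-STR repeat-number genotyping by iterative extension.

Given a reference locus ``L = (M_1)_{p_1}...(M_n)_{p_n}`` with total repeat
number ``p``, a sample's allele is read from a sequence window that starts
at the locus start and extends into trailing context.  The initial window is
the reference span plus one extension unit ``s`` (the last-motif length);
motif repeats are counted in order giving ``q = sum_i q_i``:

* ``q <= p``  — the allele is ``q`` (equal or contracted);
* ``q == p + 1`` — the sample carries more motifs than the current window
  can show: grow the window by ``s``, set ``p <- p + 1``, recount, and
  repeat until ``p`` equals the updated ``q``.

The extension strictly increases ``p`` each round, so it terminates for any
finite window (an iteration cap guards pathological input).

Two sources are supported: read alignments (per-read windows, modal
consensus) and VCF indel records (repeat number shifted by the net in-frame
indel length).
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
import pysam

from .strpanel import STRLocus

logger = logging.getLogger(__name__)

__all__ = [
    "genotype_window",
    "genotype_from_reads",
    "genotype_from_indels",
    "write_haplotype_table",
    "read_haplotype_table",
]

_CHRY = {"Y", "chrY", "y", "24"}


def _count_repeats(window: str, motifs, limit: int) -> int:
    """Greedy in-order motif count over ``window[:limit]``."""
    off = 0
    q = 0
    for motif, _ in motifs:
        k = len(motif)
        while off + k <= limit and window[off:off + k] == motif:
            off += k
            q += 1
    return q


def genotype_window(window: str, ref: STRLocus, cap: int = 30):
    """Repeat number of one sequence window, or ``(None, reason)``.

    ``window`` must begin at the locus start in the reference frame.
    Returns ``(q, reason)`` with ``reason`` empty on success.
    """
    window = window.upper()
    ref_len = ref.end - ref.start + 1
    if len(window) < ref_len:
        return None, "truncated"
    core = window[:ref_len]
    if any(b not in "ACGT" for b in core):
        return None, "ambiguous"
    s = ref.s
    p = ref.p
    for _ in range(cap):
        limit = min(len(window), ref_len + s * (p - ref.p + 1))
        q = _count_repeats(window, ref.motifs, limit)
        if q <= p:
            return q, ""
        p += 1  # q == p + 1 (greedy count can exceed by at most one unit)
    return None, "iteration-cap"


def _window_from_read(read, locus: STRLocus) -> str | None:
    """Query subsequence aligned from the locus start to the read end."""
    start0 = locus.start - 1
    qpos = None
    for q, r in read.get_aligned_pairs():
        if r is not None and r >= start0 and q is not None:
            qpos = q
            break
    if qpos is None or read.query_sequence is None:
        return None
    return read.query_sequence[qpos:]


def genotype_from_reads(path, loci: list[STRLocus], *, flank: int = 5,
                        min_span_reads: int = 2, modal_fraction: float = 0.6,
                        cap: int = 30, sample: str | None = None) -> pd.Series:
    """Per-locus consensus repeat numbers for one sample's alignments.

    Only reads fully spanning ``[start - flank, end + flank]`` are used;
    the consensus is the modal per-read call, no-call when fewer than
    ``min_span_reads`` calls or the modal fraction is below
    ``modal_fraction`` (favouring no-call over a wrong call).
    """
    af = pysam.AlignmentFile(os.fspath(path))
    if sample is None:
        rgs = af.header.to_dict().get("RG", [])
        sample = rgs[0]["SM"] if rgs and "SM" in rgs[0] else os.path.basename(
            os.fspath(path)).rsplit(".", 1)[0]
    contig = next((c for c in af.references if c in _CHRY), None)
    out: dict[str, float] = {}
    for locus in loci:
        call = np.nan
        if contig is not None:
            calls = []
            for read in af.fetch(contig, locus.start - 1, locus.end):
                if read.is_unmapped or read.query_sequence is None:
                    continue
                if (read.reference_start > locus.start - 1 - flank
                        or read.reference_end < locus.end + flank):
                    continue  # not spanning
                window = _window_from_read(read, locus)
                if window is None:
                    continue
                q, reason = genotype_window(window, locus, cap=cap)
                if q is not None:
                    calls.append(q)
            if len(calls) >= min_span_reads:
                vals, counts = np.unique(calls, return_counts=True)
                top = counts.max()
                if top / len(calls) >= modal_fraction:
                    call = float(vals[counts.argmax()])
        out[locus.name] = call
    af.close()
    return pd.Series(out, name=sample)


def genotype_from_indels(path, loci: list[STRLocus]) -> pd.DataFrame:
    """Repeat numbers from VCF indel records overlapping the locus intervals.

    The repeat number is the reference ``p`` shifted by (net indel length /
    extension-unit length); off-frame net lengths and mutually overlapping
    indels give no-calls.  Indel representations are normalized by trimming
    shared allele prefixes/suffixes before computing overlap.
    """
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    # collect per-sample indels on chrY: (start, end, net_length)
    indels: dict[str, list[tuple[int, int, int]]] = {s: [] for s in samples}
    for rec in vf:
        if rec.chrom not in _CHRY:
            continue
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None:
                continue
            idx = {a for a in gt if a is not None}
            if len(idx) != 1:
                continue
            ai = idx.pop()
            if ai == 0:
                continue
            ref_a, alt_a = rec.alleles[0], rec.alleles[ai]
            if alt_a is None or len(ref_a) == len(alt_a):
                continue  # SNV or symbolic
            pos, ref_a, alt_a = _trim(rec.pos, ref_a, alt_a)
            net = len(alt_a) - len(ref_a)
            span_end = pos + max(len(ref_a), 1) - 1
            indels[s].append((pos, span_end, net))
    vf.close()

    rows = {}
    for s in samples:
        row = {}
        for locus in loci:
            hits = [iv for iv in indels[s]
                    if iv[0] <= locus.end and iv[1] >= locus.start]
            if not hits:
                row[locus.name] = float(locus.p)
                continue
            conflict = any(
                a[0] <= b[1] and b[0] <= a[1]
                for i, a in enumerate(hits) for b in hits[i + 1:]
            )
            if conflict:
                logger.warning("%s %s: overlapping conflicting indels", s,
                               locus.name)
                row[locus.name] = np.nan
                continue
            net = sum(h[2] for h in hits)
            if net % locus.s != 0:
                logger.warning("%s %s: off-frame indel (%+d bp)", s,
                               locus.name, net)
                row[locus.name] = np.nan
                continue
            rep = locus.p + net // locus.s
            row[locus.name] = float(rep) if rep >= 1 else np.nan
        rows[s] = row
    return pd.DataFrame.from_dict(rows, orient="index")[
        [l.name for l in loci]]


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: strip shared suffix then prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def write_haplotype_table(df: pd.DataFrame, path) -> None:
    """Samples x loci integer repeat matrix as TSV; missing as '.'."""
    out = df.copy()
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("SampleID\t" + "\t".join(out.columns) + "\n")
        for idx, row in out.iterrows():
            vals = [
                "." if pd.isna(v) else str(int(v)) for v in row.to_numpy()
            ]
            fh.write(f"{idx}\t" + "\t".join(vals) + "\n")


def read_haplotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."], comment="#")
    return df.astype(float)
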