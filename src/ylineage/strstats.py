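"""Population statistics over Y-STR haplotypes.

Implements the standard descriptive statistics used on Y-STR data:

* haplotype diversity  HD = n/(n-1) * (1 - sum_i p_i^2) over distinct
  multi-locus haplotype frequencies;
* mean pairwise distance (locus mismatch count by default, squared repeat
  difference optionally);
* Nei's G_ST = (H_T - H_S)/H_T per locus, averaged over polymorphic loci;
* one-level AMOVA: sums of squares from the pairwise distance matrix,
  variance components sigma^2_a (among) and sigma^2_w (within),
  Phi_ST = sigma^2_a / (sigma^2_a + sigma^2_w), with a label-permutation
  p-value;
* Bayesian haplogroup prediction from a Y-STR allele-frequency reference:
  posterior(h) ∝ prior(h) * prod_l f_h,l(allele), with additive smoothing
  for unseen alleles.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "haplotype_diversity",
    "mean_pairwise_distance",
    "pairwise_distance_matrix",
    "gst",
    "amova",
    "AmovaTable",
    "STRFrequencyReference",
    "predict_haplogroup",
]


def _complete(haps: pd.DataFrame) -> pd.DataFrame:
    out = haps.dropna(axis=0)
    if len(out) < len(haps):
        logger.warning("dropped %d incomplete haplotypes", len(haps) - len(out))
    return out


def haplotype_diversity(haps: pd.DataFrame) -> float:
    """HD over complete multi-locus haplotypes; requires n >= 2."""
    h = _complete(haps)
    n = len(h)
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    counts = h.apply(tuple, axis=1).value_counts().to_numpy()
    p = counts / n
    return n / (n - 1) * (1.0 - float(np.sum(p ** 2)))


def _pair_distance(a: np.ndarray, b: np.ndarray, metric: str) -> float | None:
    shared = ~(np.isnan(a) | np.isnan(b))
    if not shared.any():
        return None
    if metric == "mismatch":
        return float(np.sum(a[shared] != b[shared]))
    if metric == "squared":
        return float(np.sum((a[shared] - b[shared]) ** 2))
    raise ValueError(f"unknown distance metric {metric!r}")


def pairwise_distance_matrix(haps: pd.DataFrame,
                             metric: str = "mismatch") -> np.ndarray:
    X = haps.to_numpy(dtype=float)
    n = len(X)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = _pair_distance(X[i], X[j], metric)
        if d is None:
            logger.warning("pair (%d,%d) shares no called loci; distance 0", i, j)
            d = 0.0
        D[i, j] = D[j, i] = d
    return D


def mean_pairwise_distance(haps: pd.DataFrame, metric: str = "mismatch") -> float:
    """Mean over unordered pairs of the per-pair distance."""
    X = haps.to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("MPD undefined for n < 2")
    ds = []
    for i, j in itertools.combinations(range(len(X)), 2):
        d = _pair_distance(X[i], X[j], metric)
        if d is not None:
            ds.append(d)
    if not ds:
        raise ValueError("no pair shares called loci")
    return float(np.mean(ds))


def gst(haps: pd.DataFrame, popmap: dict[str, str]) -> float:
    """Per-locus Nei G_ST averaged over polymorphic loci, clamped to [0,1]."""
    pops = sorted({popmap[s] for s in haps.index if s in popmap})
    if len(pops) < 2:
        raise ValueError("G_ST needs >= 2 populations")
    by_pop = {p: haps.loc[[s for s in haps.index if popmap.get(s) == p]]
              for p in pops}
    vals = []
    for locus in haps.columns:
        freqs = []
        for p in pops:
            col = by_pop[p][locus].dropna()
            if len(col) == 0:
                freqs = []
                break
            freqs.append(col.value_counts(normalize=True))
        if not freqs:
            continue
        alleles = sorted(set().union(*[f.index for f in freqs]))
        mat = np.array([[f.get(a, 0.0) for a in alleles] for f in freqs])
        hs = float(np.mean(1.0 - np.sum(mat ** 2, axis=1)))
        pbar = mat.mean(axis=0)
        ht = 1.0 - float(np.sum(pbar ** 2))
        if ht <= 0:
            continue  # monomorphic locus
        vals.append((ht - hs) / ht)
    if not vals:
        raise ValueError("all loci monomorphic")
    return float(np.clip(np.mean(vals), 0.0, 1.0))


@dataclass
class AmovaTable:
    """One-level AMOVA decomposition from a pairwise distance matrix."""

    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "df": [self.df_among, self.df_within, self.df_among + self.df_within],
            "SS": [self.ss_among, self.ss_within, self.ss_total],
            "variance": [self.sigma2_among, self.sigma2_within,
                         self.sigma2_among + self.sigma2_within],
        }, index=["among populations", "within populations", "total"])


def _amova_components(D: np.ndarray, groups: np.ndarray):
    """SS identities on the (squared-)distance matrix D."""
    N = len(D)
    labels = np.unique(groups)
    ss_total = D[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    sizes = []
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sizes.append(len(idx))
        sub = D[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_a, df_w = len(labels) - 1, N - len(labels)
    sizes = np.asarray(sizes, dtype=float)
    n_bar = (N - np.sum(sizes ** 2) / N) / df_a
    ms_w = ss_within / df_w if df_w > 0 else 0.0
    ms_a = ss_among / df_a
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n_bar
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom > 0 else 0.0
    return ss_among, ss_within, df_a, df_w, sigma_a, sigma_w, phi


def amova(haps: pd.DataFrame, popmap: dict[str, str],
          n_permutations: int = 999, seed: int | None = None,
          metric: str = "mismatch") -> AmovaTable:
    """One-level AMOVA with a permutation test on Phi_ST.

    Distances follow the same metric as MPD (locus mismatch count by
    default), used as squared distances in the SS identities, the standard
    convention for molecular data.
    """
    h = _complete(haps)
    groups = np.array([popmap.get(s) for s in h.index])
    if any(g is None for g in groups):
        keep = np.array([g is not None for g in groups])
        h, groups = h.loc[keep], groups[keep]
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or counts.min() < 2:
        raise ValueError("AMOVA needs >= 2 populations with n >= 2 each")
    D = pairwise_distance_matrix(h, metric)
    ss_a, ss_w, df_a, df_w, s_a, s_w, phi = _amova_components(D, groups)
    pval = None
    if n_permutations >= 1:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(groups)
            *_, phi_p = _amova_components(D, perm)
            if phi_p >= phi - 1e-12:
                hits += 1
        pval = (hits + 1) / (n_permutations + 1)
    return AmovaTable(ss_a, ss_w, df_a, df_w, s_a, s_w, phi,
                      p_value=pval, n_permutations=max(n_permutations, 0),
                      seed=seed)


@dataclass
class STRFrequencyReference:
    """Per-haplogroup, per-locus allele counts with additive smoothing.

    ``pseudocount`` is added to every allele bin when converting counts to
    frequencies, so alleles unseen under a haplogroup keep nonzero
    likelihood; the bins at a locus are the alleles observed there across
    all haplogroups (plus the queried allele).
    """

    counts: dict[str, dict[str, dict[float, float]]]  # hg -> locus -> allele -> n
    priors: dict[str, float] = field(default_factory=dict)
    pseudocount: float = 0.5

    def __post_init__(self):
        hgs = sorted(self.counts)
        if not hgs:
            raise ValueError("empty frequency reference")
        if not self.priors:
            self.priors = {h: 1.0 / len(hgs) for h in hgs}
        tot = sum(self.priors.values())
        self.priors = {h: v / tot for h, v in self.priors.items()}

    @classmethod
    def from_tsv(cls, path=None, **kw) -> "STRFrequencyReference":
        if path is None:
            from importlib.resources import files

            path = files("ylineage.data").joinpath(
                "str_freq_reference_synthetic.tsv")
        counts: dict = {}
        with open(str(path), "rt", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("haplogroup"):
                    continue
                hg, locus, allele, n = line.split("\t")[:4]
                counts.setdefault(hg, {}).setdefault(locus, {})
                counts[hg][locus][float(allele)] = \
                    counts[hg][locus].get(float(allele), 0.0) + float(n)
        return cls(counts=counts, **kw)

    def loci(self) -> set[str]:
        return {l for per in self.counts.values() for l in per}

    def likelihood(self, hg: str, locus: str, allele: float) -> float:
        bins = set()
        for per in self.counts.values():
            bins.update(per.get(locus, {}))
        bins.add(allele)
        table = self.counts[hg].get(locus, {})
        num = table.get(allele, 0.0) + self.pseudocount
        den = sum(table.values()) + self.pseudocount * len(bins)
        if den == 0:
            return 0.0
        return num / den


def predict_haplogroup(hap: dict[str, float] | pd.Series,
                       ref: STRFrequencyReference,
                       top_k: int | None = None) -> pd.Series:
    """Posterior probability of each haplogroup given one Y-STR haplotype."""
    if isinstance(hap, pd.Series):
        hap = {k: v for k, v in hap.items() if pd.notna(v)}
    shared = sorted(set(hap) & ref.loci())
    if not shared:
        raise ValueError("haplotype shares no loci with the reference")
    post = {}
    for hg in sorted(ref.counts):
        p = ref.priors.get(hg, 0.0)
        for locus in shared:
            p *= ref.likelihood(hg, locus, float(hap[locus]))
        post[hg] = p
    total = sum(post.values())
    if total == 0:
        raise ValueError("zero posterior mass for every haplogroup")
    s = pd.Series({h: v / total for h, v in post.items()}).sort_values(
        ascending=False)
    return s.head(top_k) if top_k else s
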