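"""Population-level clustering from haplogroup assignments.

Haplogroup counts per population are turned into a frequency table; structure
among populations is then visualized either by PCA of the (column-centred)
frequency matrix or by classical multidimensional scaling of the pairwise
Fst matrix.  Treating haplogroup identity as a single multi-allelic locus,
Fst between two populations is estimated in the Nei G_ST form

    Fst = (H_T - H_S) / H_T,     H = 1 - sum_i p_i^2

with H_S the mean within-population heterozygosity and H_T the
heterozygosity of the unweighted mean frequency vector.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .tree import HaploTree

logger = logging.getLogger(__name__)

__all__ = [
    "read_population_map",
    "haplogroup_frequencies",
    "pairwise_fst",
    "pairwise_fst_matrix",
    "pca_embedding",
    "mds_embedding",
    "EmbeddingResult",
]


def read_population_map(path) -> dict[str, str]:
    """Sample -> population label from a two-column TSV (no header or
    'SampleID<TAB>Population' header)."""
    out: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"population map line lacks two columns: {line!r}")
            if parts[0] in ("SampleID", "sample", "Sample"):
                continue
            out[parts[0]] = parts[1]
    return out


def haplogroup_frequencies(hg_table: pd.DataFrame, popmap: dict[str, str],
                           level: int | None = None,
                           tree: HaploTree | None = None) -> pd.DataFrame:
    """Populations x haplogroups frequency table (rows sum to 1).

    With ``level`` given, haplogroups are first simplified to their ancestor
    at that depth so samples classified at different resolutions are
    comparable; this requires ``tree``.
    """
    if level is not None and tree is None:
        raise ValueError("haplogroup simplification requires the haplogroup tree")
    counts: dict[str, dict[str, int]] = {}
    for _, row in hg_table.iterrows():
        s, hg = row["SampleID"], row["Haplogroup"]
        if s not in popmap:
            logger.warning("sample %s absent from population map; dropped", s)
            continue
        if level is not None:
            hg = tree.simplify(hg, level)
        pop = popmap[s]
        counts.setdefault(pop, {}).setdefault(hg, 0)
        counts[pop][hg] += 1
    counts = {p: c for p, c in counts.items() if sum(c.values()) > 0}
    if not counts:
        raise ValueError("no mapped samples")
    freq = pd.DataFrame(counts).T.fillna(0.0).sort_index()
    freq = freq[sorted(freq.columns)]
    freq = freq.div(freq.sum(axis=1), axis=0)
    return freq


def _heterozygosity(p: np.ndarray) -> float:
    return 1.0 - float(np.sum(p ** 2))


def pairwise_fst(p1: np.ndarray, p2: np.ndarray,
                 n1: int | None = None, n2: int | None = None,
                 corrected: bool = False) -> float:
    """Nei-style Fst between two haplogroup frequency vectors.

    ``corrected`` applies the small-sample correction H -> n/(n-1) * H to the
    within-population heterozygosities (requires sample counts).
    """
    h1, h2 = _heterozygosity(p1), _heterozygosity(p2)
    if corrected:
        if not (n1 and n2 and n1 > 1 and n2 > 1):
            raise ValueError("corrected Fst needs per-population n > 1")
        h1 *= n1 / (n1 - 1)
        h2 *= n2 / (n2 - 1)
    hs = (h1 + h2) / 2.0
    ht = _heterozygosity((p1 + p2) / 2.0)
    if ht <= 0:
        return 0.0
    return max(0.0, (ht - hs) / ht)


def pairwise_fst_matrix(freq: pd.DataFrame, sizes: dict[str, int] | None = None,
                        corrected: bool = False) -> pd.DataFrame:
    """Symmetric zero-diagonal matrix of pairwise Fst between populations."""
    pops = list(freq.index)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    d = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            f = pairwise_fst(
                freq.loc[a].to_numpy(), freq.loc[b].to_numpy(),
                None if sizes is None else sizes.get(a),
                None if sizes is None else sizes.get(b),
                corrected=corrected,
            )
            d.loc[a, b] = d.loc[b, a] = f
    return d


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # units x axes
    eigenvalues: np.ndarray  # non-increasing
    method: str  # "pca" | "mds"

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        if tot <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / tot


def pca_embedding(freq: pd.DataFrame, k: int = 2) -> EmbeddingResult:
    """PCA of the column-centred frequency matrix.

    Eigenvalues are the variances along the principal axes; their sum equals
    the total variance of the centred matrix.
    """
    X = freq.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 populations for PCA")
    kmax = min(X.shape)
    if k > kmax:
        logger.warning("k=%d clipped to %d", k, kmax)
        k = kmax
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eig = (s ** 2) / (n - 1)
    coords = U[:, :k] * s[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return EmbeddingResult(
        coordinates=pd.DataFrame(coords, index=freq.index, columns=cols),
        eigenvalues=eig, method="pca",
    )


def mds_embedding(dist: pd.DataFrame, k: int = 2) -> EmbeddingResult:
    """Classical (Torgerson) MDS of a symmetric zero-diagonal distance matrix.

    Double-centres -D^2/2 and eigendecomposes; on exact Euclidean distances
    the embedding reproduces them up to rigid motion.  Deterministic, no
    seed.
    """
    D = dist.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    k = min(k, n)
    wk = np.clip(w[:k], 0.0, None)
    coords = V[:, :k] * np.sqrt(wk)
    cols = [f"Dim{i + 1}" for i in range(k)]
    return EmbeddingResult(
        coordinates=pd.DataFrame(coords, index=dist.index, columns=cols),
        eigenvalues=np.clip(w, 0.0, None), method="mds",
    )


def plot_embedding(emb: EmbeddingResult, path, popmap_colors=None) -> None:
    """Scatter of the first two axes, one point per unit (PDF/PNG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = emb.coordinates.iloc[:, :2]
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, row in xy.iterrows():
        x = row.iloc[0]
        y = row.iloc[1] if xy.shape[1] > 1 else 0.0
        ax.scatter(x, y, s=30)
        ax.annotate(str(name), (x, y), fontsize=7,
                    textcoords="offset points", xytext=(3, 3))
    labels = ("PC1", "PC2") if emb.method == "pca" else ("Dim1", "Dim2")
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1] if xy.shape[1] > 1 else "")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
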