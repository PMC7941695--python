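"""Median-joining networks over Y-STR haplotypes, fdi export, and TMRCA.

Haplotypes are integer repeat-number vectors; the distance between two is
the sum of absolute repeat differences (consistent with the stepwise
mutation model).  The median-joining construction iterates

1. build the sparse network of minimum-spanning edges within tolerance
   ``epsilon`` (an edge survives iff its endpoints cannot be connected by
   strictly lighter edges, lighter meaning weight < w - epsilon);
2. propose, for every connected triplet, the locus-wise median vector; add
   the candidate that most shortens the minimum spanning length (strict
   improvement only, deterministic sorted order);
3. at the fixed point, prune median vectors whose removal leaves the
   spanning length unchanged.

TMRCA estimators:

* rho — mean mutational steps (shortest network path) from a designated
  root haplotype, divided by the per-haplotype mutation rate;
* ASD — average squared repeat difference from the ancestral haplotype,
  divided by the per-locus mutation rate; unbiased for star genealogies
  under symmetric single-step mutation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

logger = logging.getLogger(__name__)

__all__ = [
    "mj_network",
    "write_fdi",
    "parse_fdi",
    "rho_tmrca",
    "asd_tmrca",
    "TmrcaResult",
]


def _l1(a: tuple, b: tuple) -> int:
    return int(sum(abs(x - y) for x, y in zip(a, b)))


def _mst_length(vectors: list[tuple]) -> int:
    n = len(vectors)
    if n < 2:
        return 0
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = _l1(vectors[i], vectors[j])
    return int(round(minimum_spanning_tree(D + D.T).sum()))


def _msn_edges(vectors: list[tuple], epsilon: int) -> list[tuple[int, int, int]]:
    """Minimum-spanning-network edges within tolerance epsilon.

    Edge (i, j) of weight w is kept iff i and j are not connected using only
    edges of weight < w - epsilon.
    """
    n = len(vectors)
    edges = sorted(
        (_l1(vectors[i], vectors[j]), i, j)
        for i, j in itertools.combinations(range(n), 2)
    )
    kept = []
    for w, i, j in edges:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((a, b) for ww, a, b in edges if ww < w - epsilon)
        if not nx.has_path(g, i, j):
            kept.append((i, j, w))
    return kept


def _median(a: tuple, b: tuple, c: tuple) -> tuple:
    return tuple(int(np.median([x, y, z])) for x, y, z in zip(a, b, c))


def mj_network(haps: pd.DataFrame, popmap: dict[str, str] | None = None,
               epsilon: int = 0) -> nx.Graph:
    """Median-joining network of a samples x loci repeat matrix.

    Rows with no-calls are dropped (with a warning).  Node attributes:
    ``vector``, ``multiplicity`` (0 for inferred medians), ``observed``,
    ``populations`` (label -> count), ``samples``.  Edges carry ``weight`` =
    summed absolute repeat difference.
    """
    h = haps.dropna(axis=0)
    if len(h) < len(haps):
        logger.warning("dropped %d haplotypes with no-calls", len(haps) - len(h))
    if len(h) == 0:
        raise ValueError("no complete haplotypes")
    info: dict[tuple, dict] = {}
    for sample, row in h.iterrows():
        v = tuple(int(x) for x in row.to_numpy())
        rec = info.setdefault(v, {"multiplicity": 0, "samples": [],
                                  "populations": {}})
        rec["multiplicity"] += 1
        rec["samples"].append(str(sample))
        if popmap and str(sample) in popmap:
            p = popmap[str(sample)]
            rec["populations"][p] = rec["populations"].get(p, 0) + 1

    observed = sorted(info)
    vectors = list(observed)
    if len(vectors) >= 3:
        while True:
            edges = _msn_edges(vectors, epsilon)
            adj: dict[int, set[int]] = {}
            for i, j, _ in edges:
                adj.setdefault(i, set()).add(j)
                adj.setdefault(j, set()).add(i)
            base_len = _mst_length(vectors)
            present = set(vectors)
            best = None  # (new_len, median)
            seen = set()
            for v, nbrs in adj.items():
                for a, b in itertools.combinations(sorted(nbrs), 2):
                    med = _median(vectors[a], vectors[v], vectors[b])
                    if med in present or med in seen:
                        continue
                    seen.add(med)
                    new_len = _mst_length(vectors + [med])
                    if new_len < base_len and (best is None or
                                               (new_len, med) < best):
                        best = (new_len, med)
            if best is None:
                break
            vectors.append(best[1])
        # prune obsolete medians
        changed = True
        while changed:
            changed = False
            for med in sorted(v for v in vectors if v not in info):
                rest = [v for v in vectors if v != med]
                if _mst_length(rest) <= _mst_length(vectors):
                    vectors = rest
                    changed = True

    g = nx.Graph(epsilon=epsilon, loci=list(h.columns))
    names = {}
    n_obs = n_med = 0
    for v in vectors:
        if v in info:
            n_obs += 1
            name = f"H{n_obs}"
            g.add_node(name, vector=v, observed=True,
                       multiplicity=info[v]["multiplicity"],
                       populations=dict(info[v]["populations"]),
                       samples=list(info[v]["samples"]))
        else:
            n_med += 1
            name = f"mv{n_med}"
            g.add_node(name, vector=v, observed=False, multiplicity=0,
                       populations={}, samples=[])
        names[v] = name
    for i, j, w in _msn_edges(vectors, epsilon):
        g.add_edge(names[vectors[i]], names[vectors[j]], weight=w)
    return g


# ---------------------------------------------------------------------------
# fdi export (Network/Fluxus dialect)
# ---------------------------------------------------------------------------

def write_fdi(g: nx.Graph, path) -> None:
    """Write the network in a Network-software fdi dialect.

    Taxon records carry multiplicity and population composition; link
    records carry mutational-step weights.  Node coordinates use a
    deterministic circular layout, so output is byte-identical across runs
    on the same input.
    """
    nodes = sorted(g.nodes)
    pops = sorted({p for n in nodes for p in g.nodes[n]["populations"]})
    lines = []
    lines.append(f"NUMBER_OF_TAXA;{len(nodes)}")
    lines.append(f"NUMBER_OF_POPULATIONS;{len(pops)}")
    for i, p in enumerate(pops, 1):
        lines.append(f"POPULATION;{i};{p}")
    R = 1000
    for i, n in enumerate(nodes):
        ang = 2 * math.pi * i / max(len(nodes), 1)
        x, y = int(R + R * math.cos(ang)), int(R + R * math.sin(ang))
        a = g.nodes[n]
        vec = ",".join(str(v) for v in a["vector"])
        popstr = ",".join(f"{p}:{a['populations'].get(p, 0)}" for p in pops)
        lines.append(
            f"TAXON_NAME;{n};TAXON_X;{x};TAXON_Y;{y};"
            f"TAXON_FREQUENCY;{a['multiplicity']};TAXON_MEDIAN;"
            f"{0 if a['observed'] else 1};TAXON_VECTOR;{vec};"
            f"TAXON_POPULATIONS;{popstr}"
        )
    edges = sorted((min(u, v), max(u, v), d["weight"])
                   for u, v, d in g.edges(data=True))
    lines.append(f"NUMBER_OF_LINKS;{len(edges)}")
    for u, v, w in edges:
        lines.append(f"LINK_TAXON1;{u};LINK_TAXON2;{v};LINK_WEIGHT;{w}")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def parse_fdi(path) -> nx.Graph:
    """Re-read a network written by :func:`write_fdi`."""
    g = nx.Graph()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            parts = line.strip().split(";")
            if parts[0] == "TAXON_NAME":
                kv = dict(zip(parts[0::2], parts[1::2]))
                vec = tuple(int(x) for x in kv["TAXON_VECTOR"].split(","))
                pops = {}
                if kv.get("TAXON_POPULATIONS"):
                    for item in kv["TAXON_POPULATIONS"].split(","):
                        k, _, v = item.partition(":")
                        if k:
                            pops[k] = int(v)
                g.add_node(kv["TAXON_NAME"], vector=vec,
                           multiplicity=int(kv["TAXON_FREQUENCY"]),
                           observed=kv["TAXON_MEDIAN"] == "0",
                           populations=pops)
            elif parts[0] == "LINK_TAXON1":
                kv = dict(zip(parts[0::2], parts[1::2]))
                g.add_edge(kv["LINK_TAXON1"], kv["LINK_TAXON2"],
                           weight=int(kv["LINK_WEIGHT"]))
    return g


# ---------------------------------------------------------------------------
# TMRCA estimation
# ---------------------------------------------------------------------------

@dataclass
class TmrcaResult:
    estimator: str  # "rho" | "asd"
    statistic: float  # rho or ASD value
    t_generations: float
    t_years: float
    mu: float  # per haplotype (rho) / per locus (asd), per generation
    generation_time: float
    se_generations: float | None = None

    def summary(self) -> str:
        lines = [
            f"estimator: {self.estimator}",
            f"{self.estimator} statistic: {self.statistic:.4f}",
            f"mu ({'per haplotype' if self.estimator == 'rho' else 'per locus'}"
            f"/generation): {self.mu:g}",
            f"TMRCA: {self.t_generations:.1f} generations = "
            f"{self.t_years:.0f} years (generation time "
            f"{self.generation_time:g} y)",
        ]
        if self.se_generations is not None:
            # SE convention: sqrt(rho * sum w_i^2) / mu, w_i multiplicity shares
            lines.append(f"SE: {self.se_generations:.1f} generations")
        return "\n".join(lines)


def rho_tmrca(g: nx.Graph, root: str, mu_per_haplotype: float,
              generation_time: float = 30.0) -> TmrcaResult:
    """Rho estimate of the TMRCA from a haplotype network.

    rho is the multiplicity-weighted mean shortest-path mutational distance
    from the root node over observed haplotypes; T = rho / mu generations.
    """
    if root not in g:
        raise KeyError(f"root node {root!r} not in network")
    if mu_per_haplotype <= 0:
        raise ValueError("mu must be positive")
    dist = nx.single_source_dijkstra_path_length(g, root, weight="weight")
    total_w = 0.0
    rho = 0.0
    sumw2 = 0.0
    N = sum(d["multiplicity"] for _, d in g.nodes(data=True) if d["observed"])
    for n, d in g.nodes(data=True):
        if not d["observed"] or d["multiplicity"] == 0:
            continue
        if n not in dist:
            raise ValueError(f"node {n} disconnected from root")
        w = d["multiplicity"] / N
        rho += w * dist[n]
        sumw2 += w ** 2
        total_w += w
    rho /= total_w
    t = rho / mu_per_haplotype
    se = math.sqrt(max(rho, 0.0) * sumw2) / mu_per_haplotype
    return TmrcaResult("rho", rho, t, t * generation_time, mu_per_haplotype,
                       generation_time, se_generations=se)


def asd_tmrca(haps: pd.DataFrame, ancestral: dict[str, float] | pd.Series,
              mu_per_locus: float,
              generation_time: float = 30.0) -> TmrcaResult:
    """ASD estimate of the TMRCA from haplotypes and an ancestral haplotype.

    ASD = mean over samples and shared loci of (repeat - ancestral)^2;
    E[ASD] = mu * T under symmetric single-step mutation, so T = ASD / mu.
    """
    if mu_per_locus <= 0:
        raise ValueError("mu must be positive")
    anc = pd.Series(ancestral, dtype=float)
    shared = [c for c in haps.columns if c in anc.index]
    if not shared:
        raise ValueError("no loci shared with the ancestral haplotype")
    diff = haps[shared].to_numpy(dtype=float) - anc[shared].to_numpy()
    sq = diff ** 2
    asd = float(np.nanmean(sq))
    t = asd / mu_per_locus
    return TmrcaResult("asd", asd, t, t * generation_time, mu_per_locus,
                       generation_time)


def modal_haplotype(haps: pd.DataFrame) -> pd.Series:
    """Locus-wise modal repeat numbers (fallback ancestral haplotype)."""
    logger.warning("using modal haplotype as the ancestral haplotype")
    return haps.mode(axis=0).iloc[0]
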