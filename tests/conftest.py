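import numpy as np
import pandas as pd
import pytest

from ylineage.fixtures import make_toy_tree, simulate_genotype_table


@pytest.fixture(scope="session")
def toy_tree():
    """Small balanced tree: 14 haplogroups below the root, 3 markers each."""
    tree, markers = make_toy_tree(seed=11, depth=3, branching=2,
                                  markers_per_node=3)
    return tree, markers


@pytest.fixture(scope="session")
def medium_tree():
    """62 haplogroups below the root, 5 markers each (classifier fixtures)."""
    tree, markers = make_toy_tree(seed=7, depth=5, branching=2,
                                  markers_per_node=5)
    return tree, markers


@pytest.fixture()
def vcf_factory(tmp_path):
    def make(tree, n_samples, seed, **kw):
        path = tmp_path / f"sim_{seed}.vcf"
        text, truth = simulate_genotype_table(tree, n_samples, seed,
                                              path=path, **kw)
        return path, truth

    return make


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def brute_force_best_track(matches, tree, U):
    """Exhaustive max-tracking-rate search over all root-to-node paths.

    Returns (max_t, set of argmax terminals) over candidate terminals
    (cutoff-passing key haplogroups, falling back to all cutoff-passing).
    """
    passing = {h for h, mt in matches.items() if mt.n / mt.m >= U}
    key_cands = [h for h in passing if matches[h].key_derived]
    cands = key_cands or sorted(passing)
    best_t, arg = None, set()
    for term in cands:
        path = []
        node = term
        while node != tree.root:
            path.append(node)
            node = tree.parent[node]
        hits = sum(1 for h in path if h in passing)
        t = hits / len(path)
        if best_t is None or t > best_t + 1e-15:
            best_t, arg = t, {term}
        elif abs(t - best_t) <= 1e-15:
            arg.add(term)
    return best_t, arg


def maximal_run_count(window, motif):
    """Longest k with window starting with motif repeated k times."""
    k = 0
    while window.startswith(motif * (k + 1)):
        k += 1
    return k


def fitch_brute_force(tree, aln):
    """Minimum change count over all internal-state assignments per site."""
    import itertools

    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0
    for site in range(aln.n_sites):
        best = None
        for combo in itertools.product("ACGT", repeat=len(internals)):
            state = {id(n): b for n, b in zip(internals, combo)}
            changes = 0
            for n in internals:
                nb = state[id(n)]
                for c in n.children:
                    cb = aln[c.label][site] if c.is_leaf else state[id(c)]
                    if cb != nb:
                        changes += 1
            if best is None or changes < best:
                best = changes
        total += best
    return total


def amova_ss_brute_force(D, groups):
    """Naive double-loop SS identities on the pairwise distance matrix."""
    N = len(D)
    pops = sorted(set(groups))
    ss_total = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            ss_total += D[i][j]
    ss_total /= N
    ss_within = 0.0
    for p in pops:
        idx = [i for i, g in enumerate(groups) if g == p]
        s = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                s += D[idx[a]][idx[b]]
        ss_within += s / len(idx)
    return ss_total - ss_within, ss_within


def steiner_mst_brute_force(vectors):
    """Minimum Steiner-augmented MST length over the bounded median lattice.

    Exhaustive over subsets of up to two lattice points within the
    coordinate bounding box; feasible only for tiny instances.
    """
    import itertools

    from scipy.sparse.csgraph import minimum_spanning_tree

    def mst_len(pts):
        n = len(pts)
        if n < 2:
            return 0
        D = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            D[i, j] = sum(abs(x - y) for x, y in zip(pts[i], pts[j]))
        return int(round(minimum_spanning_tree(D + D.T).sum()))

    lows = [min(v[k] for v in vectors) for k in range(len(vectors[0]))]
    highs = [max(v[k] for v in vectors) for k in range(len(vectors[0]))]
    lattice = [p for p in itertools.product(
        *[range(lo, hi + 1) for lo, hi in zip(lows, highs)])
        if p not in set(vectors)]
    best = mst_len(list(vectors))
    for k in (1, 2):
        for extra in itertools.combinations(lattice, k):
            best = min(best, mst_len(list(vectors) + list(extra)))
    return best
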