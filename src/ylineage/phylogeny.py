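"""Two-step phylogeny construction from haplogroup assignments.

Step one places every sample as a leaf under its haplogroup node on the
haplogroup tree, then prunes haplogroup nodes with no sample descendants and
collapses unary chains — a *preliminary tree* whose topology is fixed by the
classification alone.  Samples sharing a haplogroup, or haplogroups with
several sampled children, leave polytomies.

Step two resolves each polytomy, in post order, into a bifurcating subtree
built from only its member units using sequence data: UPGMA on the IBS
(identity-by-state mismatch) distance, exhaustive/stepwise maximum parsimony
(Fitch), or neighbor-joining on the IBS distance.  The replacement keeps the
backbone unchanged: every clade of the preliminary tree is still a clade of
the resolved tree.

The module also prepares the file bundle (alignment, calibrated tree,
control file) consumed by an external Bayesian MCMC dating program and
parses its output summary back into a node-time table; the MCMC itself is
delegated to that executable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import HaploTree

logger = logging.getLogger(__name__)

__all__ = [
    "Clade",
    "Alignment",
    "read_alignment",
    "preliminary_tree",
    "resolve_polytomies",
    "parsimony_score",
    "ibs_distance",
    "generate_dating_inputs",
    "summarize_dating_output",
    "load_calibrations",
]


# ---------------------------------------------------------------------------
# tree container
# ---------------------------------------------------------------------------

@dataclass
class Clade:
    """A rooted tree node; leaves are samples, internal labels haplogroups."""

    label: str = ""
    children: list["Clade"] = field(default_factory=list)
    length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.label for lf in self.leaves()]

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def is_bifurcating(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.postorder() if not n.is_leaf
        )

    def clades(self) -> set[frozenset[str]]:
        """Leaf-name sets of every internal node (size >= 2)."""
        out = set()
        for n in self.postorder():
            if not n.is_leaf:
                names = frozenset(n.leaf_names())
                if len(names) >= 2:
                    out.add(names)
        return out

    def newick(self, lengths: bool = True, labels: bool = True) -> str:
        return self._nwk(lengths, labels) + ";"

    def _nwk(self, lengths, labels) -> str:
        if self.is_leaf:
            s = _quote(self.label)
        else:
            s = "(" + ",".join(c._nwk(lengths, labels) for c in self.children) + ")"
            if labels and self.label:
                s += _quote(self.label)
        if lengths and self.length is not None:
            s += f":{self.length:g}"
        return s


def _quote(name: str) -> str:
    if re.search(r"[\s(),:;]", name):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Sample -> equal-length sequence over {A,C,G,T,N,-}."""

    seqs: dict[str, str]

    def __post_init__(self):
        lens = {len(s) for s in self.seqs.values()}
        if len(lens) > 1:
            raise ValueError("alignment sequences differ in length")

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    def __contains__(self, name):
        return name in self.seqs

    def __getitem__(self, name):
        return self.seqs[name]


def read_alignment(path, fmt: str = "fasta") -> Alignment:
    """Read a multiple sequence alignment (FASTA / relaxed PHYLIP / MEGA)."""
    fmt = fmt.lower()
    if fmt == "fasta":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(path), "fasta")}
    elif fmt in ("phylip", "phy"):
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(path), "phylip-relaxed")}
    elif fmt == "meg" or fmt == "mega":
        seqs = _read_mega(path)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if not seqs:
        raise ValueError(f"no sequences read from {path}")
    return Alignment(seqs)


def _read_mega(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    current = None
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#MEGA", "!", "TITLE")):
                continue
            if line.startswith("#"):
                current = line[1:].split()[0]
                seqs.setdefault(current, [])
                rest = line[1 + len(current):].strip()
                if rest:
                    seqs[current].append(rest)
            elif current is not None:
                seqs[current].append(line)
    return {k: "".join(v).upper() for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# step 1: preliminary tree
# ---------------------------------------------------------------------------

def preliminary_tree(hg_table: pd.DataFrame, tree: HaploTree) -> Clade:
    """Samples hung as leaves under their haplogroup node, pruned, collapsed."""
    by_hg: dict[str, list[str]] = {}
    for _, row in hg_table.iterrows():
        s, hg = row["SampleID"], row["Haplogroup"]
        if hg not in tree:
            logger.warning("sample %s: haplogroup %s not in tree; dropped", s, hg)
            continue
        by_hg.setdefault(hg, []).append(s)
    if not by_hg:
        raise ValueError("no samples with resolvable haplogroups")

    def build(hg: str) -> Clade | None:
        kids = [build(c) for c in sorted(tree.children.get(hg, []))]
        kids = [k for k in kids if k is not None]
        leaves = [Clade(label=s) for s in sorted(by_hg.get(hg, []))]
        if not kids and not leaves:
            return None
        node = Clade(label=hg, children=kids + leaves)
        return node

    root = build(tree.root)
    return _collapse_unary(root)


def _collapse_unary(node: Clade) -> Clade:
    node.children = [_collapse_unary(c) for c in node.children]
    # a haplogroup node with a single child is redundant; keep the deeper
    # (more derived) label
    while len(node.children) == 1 and not node.children[0].is_leaf:
        node = node.children[0]
    if len(node.children) == 1 and node.children[0].is_leaf:
        node = node.children[0]
    return node


# ---------------------------------------------------------------------------
# distances and parsimony
# ---------------------------------------------------------------------------

_MISSING = frozenset("N-")


def ibs_distance(a: str, b: str) -> float:
    """Mismatch proportion over sites where both sequences are called."""
    tot = mis = 0
    for x, y in zip(a, b):
        if x in _MISSING or y in _MISSING:
            continue
        tot += 1
        if x != y:
            mis += 1
    if tot == 0:
        logger.warning("sequence pair with no overlapping called sites")
        return 1.0
    return mis / tot


def parsimony_score(tree: Clade, aln: Alignment) -> int:
    """Fitch small-parsimony change count summed over alignment sites."""
    leaves = tree.leaf_names()
    missing = [s for s in leaves if s not in aln]
    if missing:
        raise ValueError(f"alignment lacks sequences for {missing}")
    full = frozenset("ACGT")
    total = 0
    for site in range(aln.n_sites):
        def fitch(n: Clade) -> frozenset:
            nonlocal total
            if n.is_leaf:
                b = aln[n.label][site]
                return frozenset(b) if b in "ACGT" else full
            sets = [fitch(c) for c in n.children]
            inter = frozenset.intersection(*sets)
            if inter:
                return inter
            # pairwise Fitch generalized to multifurcations: greedy union
            acc = sets[0]
            for s in sets[1:]:
                i = acc & s
                if i:
                    acc = i
                else:
                    acc = acc | s
                    total += 1
            return acc

        fitch(tree)
    return total


# ---------------------------------------------------------------------------
# step 2: polytomy resolution
# ---------------------------------------------------------------------------

def resolve_polytomies(ptree: Clade, aln: Alignment | None = None,
                       method: str = "upgma") -> Clade:
    """Replace every polytomy, in post order, by a bifurcating subtree.

    Each polytomy's children are treated as units represented by one member
    sequence (the lexicographically first leaf); the unit topology comes
    from ``method`` (upgma | mp | ibs=neighbor-joining, all on IBS
    distances).  Without an alignment, units are joined as a caterpillar in
    sorted representative order (deterministic, with a warning).
    """
    method = method.lower()
    if method not in ("upgma", "mp", "ibs"):
        raise ValueError(f"unknown resolution method {method!r}")
    if aln is None:
        logger.warning("no alignment given: polytomies broken by sample-id order")

    def resolve(node: Clade) -> Clade:
        node.children = [resolve(c) for c in node.children]
        if len(node.children) <= 2:
            return node
        units = sorted(node.children, key=lambda c: min(c.leaf_names()))
        if aln is None:
            sub = _caterpillar(units)
        else:
            reps = [min(u.leaf_names()) for u in units]
            miss = [r for r in reps if r not in aln]
            if miss:
                raise ValueError(f"alignment lacks sequences for {miss}")
            if method == "mp":
                sub = _mp_topology(units, reps, aln)
            else:
                D = np.array([[ibs_distance(aln[a], aln[b]) for b in reps]
                              for a in reps])
                sub = _upgma(units, D) if method == "upgma" else _nj(units, D)
        sub.label = node.label
        return sub

    out = resolve(ptree)
    return out


def _caterpillar(units: list[Clade]) -> Clade:
    node = units[0]
    for u in units[1:]:
        node = Clade(children=[node, u])
    return node


def _upgma(units: list[Clade], D: np.ndarray) -> Clade:
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(D, checks=False), method="average")
    nodes: list[Clade] = list(units)
    for a, b, _, _ in Z:
        nodes.append(Clade(children=[nodes[int(a)], nodes[int(b)]]))
    return nodes[-1]


def _nj(units: list[Clade], D: np.ndarray) -> Clade:
    """Neighbor-joining unit topology (scikit-bio), rooted deterministically."""
    if len(units) == 3:
        # NJ is uninformative for 3 taxa; join the closest pair
        pairs = [(0, 1), (0, 2), (1, 2)]
        i, j = min(pairs, key=lambda p: (D[p[0], p[1]], p))
        k = ({0, 1, 2} - {i, j}).pop()
        return Clade(children=[Clade(children=[units[i], units[j]]), units[k]])
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = [f"u{i}" for i in range(len(units))]
    t = nj(DistanceMatrix(D, ids))
    by_id = {ids[i]: units[i] for i in range(len(units))}

    def convert(n) -> Clade:
        if n.is_tip():
            return by_id[n.name]
        return Clade(children=[convert(c) for c in n.children])

    # NJ trees have a trifurcating root; binarize deterministically by
    # pairing the last two subtrees in sorted representative order
    return _binarize(convert(t.root()))


def _binarize(node: Clade) -> Clade:
    node.children = [_binarize(c) for c in node.children]
    while len(node.children) > 2:
        kids = sorted(node.children, key=lambda c: min(c.leaf_names()))
        merged = Clade(children=kids[-2:])
        node.children = kids[:-2] + [merged]
    return node


def _mp_topology(units: list[Clade], reps: list[str], aln: Alignment,
                 exhaustive_max: int = 8) -> Clade:
    """Minimum-Fitch-score rooted topology over the units.

    Exhaustive over all rooted bifurcating shapes up to ``exhaustive_max``
    units; stepwise addition (greedy best insertion, sorted unit order)
    above.
    """
    rep_aln = Alignment({f"u{i}": aln[r] for i, r in enumerate(reps)})
    names = [f"u{i}" for i in range(len(units))]

    def score(shape) -> int:
        return parsimony_score(_shape_to_clade(shape), rep_aln)

    if len(units) <= exhaustive_max:
        best, best_s = None, None
        for shape in _rooted_shapes(names):
            s = score(shape)
            if best_s is None or s < best_s:
                best, best_s = shape, s
    else:
        best = (names[0], (names[1], names[2]))
        for nm in names[3:]:
            cands = [_insert(best, pos, nm) for pos in range(_n_edges(best))]
            best = min(cands, key=lambda sh: (score(sh), _shape_key(sh)))
    by_name = dict(zip(names, units))

    def materialize(shape) -> Clade:
        if isinstance(shape, str):
            return by_name[shape]
        return Clade(children=[materialize(shape[0]), materialize(shape[1])])

    return materialize(best)


def _shape_to_clade(shape) -> Clade:
    if isinstance(shape, str):
        return Clade(label=shape)
    return Clade(children=[_shape_to_clade(shape[0]), _shape_to_clade(shape[1])])


def _rooted_shapes(names: list[str]):
    """All rooted bifurcating shapes by recursive edge insertion."""
    if len(names) == 1:
        yield names[0]
        return
    for sub in _rooted_shapes(names[:-1]):
        for pos in range(_n_edges(sub) + 1):  # +1: new root above everything
            yield _insert_with_root(sub, pos, names[-1])


def _n_edges(shape) -> int:
    if isinstance(shape, str):
        return 1
    return 1 + _n_edges(shape[0]) + _n_edges(shape[1])


def _insert(shape, pos, name):
    """Insert ``name`` splitting the ``pos``-th edge (preorder count)."""
    new, _ = _insert_walk(shape, pos, name)
    return new


def _insert_walk(shape, pos, name):
    if pos == 0:
        return (shape, name), -1
    pos -= 1
    if isinstance(shape, str):
        return shape, pos
    left, pos = _insert_walk(shape[0], pos, name)
    if pos < 0:
        return (left, shape[1]), -1
    right, pos = _insert_walk(shape[1], pos, name)
    if pos < 0:
        return (shape[0], right), -1
    return shape, pos


def _insert_with_root(shape, pos, name):
    if pos == _n_edges(shape):
        return (shape, name)  # above the old root
    return _insert(shape, pos, name)


def _shape_key(shape):
    if isinstance(shape, str):
        return (0, shape)
    return (1, _shape_key(shape[0]), _shape_key(shape[1]))


# ---------------------------------------------------------------------------
# divergence-time scaffolding for the external Bayesian dating executable
# ---------------------------------------------------------------------------

_DEFAULT_CTL = {
    "seed": -1,
    "ndata": 1,
    "seqtype": 0,
    "usedata": 1,
    "clock": 2,
    "model": 4,
    "alpha": 0.5,
    "burnin": 2000,
    "sampfreq": 2,
    "nsample": 20000,
}


def load_calibrations(path=None) -> dict[str, tuple[float, float]]:
    """Haplogroup -> (lower, upper) calibration bounds in kyr.

    Without a path, the packaged main-trunk table is used; it is
    configuration data, not asserted as scientific truth.
    """
    if path is None:
        from importlib.resources import files

        path = files("ylineage.data").joinpath("calibrations.tsv")
    out: dict[str, tuple[float, float]] = {}
    with open(str(path), "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("haplogroup"):
                continue
            hg, lo, hi = line.split("\t")[:3]
            lo, hi = float(lo), float(hi)
            if not lo < hi:
                raise ValueError(f"calibration {hg}: lower must be < upper")
            out[hg] = (lo, hi)
    return out


def generate_dating_inputs(tree: Clade, aln: Alignment,
                           calibrations: dict[str, tuple[float, float]] | None,
                           outdir, prefix: str = "dating",
                           time_unit_kyr: float = 100.0,
                           ctl_overrides: dict | None = None) -> dict[str, str]:
    """Write the (alignment, calibrated tree, control) bundle for dating.

    The tree must be rooted and strictly bifurcating, without branch
    lengths; calibration bounds are injected at internal nodes whose label
    matches, in the '>lower<upper' annotation style, scaled by
    ``time_unit_kyr``.  User calibrations override the packaged table.
    """
    import os

    if not tree.is_bifurcating():
        raise ValueError(
            "tree contains polytomies; run resolve_polytomies first"
        )
    leaves = tree.leaf_names()
    missing = [s for s in leaves if s not in aln]
    if missing:
        raise ValueError(f"alignment lacks sequences for {missing}")
    calib = dict(load_calibrations())
    if calibrations:
        calib.update(calibrations)

    used = []

    def nwk(n: Clade) -> str:
        if n.is_leaf:
            return _quote(n.label)
        s = "(" + ",".join(nwk(c) for c in n.children) + ")"
        if n.label in calib:
            lo, hi = calib[n.label]
            s += f"'>{lo / time_unit_kyr:g}<{hi / time_unit_kyr:g}'"
            used.append(n.label)
        return s

    tree_str = nwk(tree)
    if not used:
        raise ValueError("no calibration matched any internal node label")

    os.makedirs(outdir, exist_ok=True)
    seq_path = os.path.join(outdir, f"{prefix}.phy")
    tree_path = os.path.join(outdir, f"{prefix}.trees")
    ctl_path = os.path.join(outdir, f"{prefix}.ctl")
    with open(seq_path, "w") as fh:
        fh.write(f"{len(leaves)} {aln.n_sites}\n")
        for s in leaves:
            fh.write(f"{s}  {aln[s]}\n")
    with open(tree_path, "w") as fh:
        fh.write(f"{len(leaves)} 1\n{tree_str};\n")
    ctl = dict(_DEFAULT_CTL)
    if ctl_overrides:
        ctl.update(ctl_overrides)
    with open(ctl_path, "w") as fh:
        fh.write(f"seqfile = {os.path.basename(seq_path)}\n")
        fh.write(f"treefile = {os.path.basename(tree_path)}\n")
        fh.write(f"outfile = {prefix}.out\n")
        for k, v in ctl.items():
            fh.write(f"{k} = {v}\n")
    return {"seqfile": seq_path, "treefile": tree_path, "ctlfile": ctl_path}


def node_numbering(tree: Clade) -> dict[int, str]:
    """Dating-program node numbers: leaves 1..s in newick order, internal
    nodes s+1.. in preorder (root first).  Returns number -> label."""
    leaves = tree.leaves()
    num: dict[int, str] = {}
    for i, lf in enumerate(leaves, 1):
        num[i] = lf.label
    counter = len(leaves)
    stack = [tree]
    while stack:
        n = stack.pop(0)
        if n.is_leaf:
            continue
        counter += 1
        num[counter] = n.label or f"node{counter}"
        stack = n.children + stack
    return num


_TIME_RE = re.compile(
    r"^t_n(\d+)\s+([0-9.eE+-]+)\s*\(\s*([0-9.eE+-]+)\s*,\s*([0-9.eE+-]+)\s*\)"
)


def summarize_dating_output(path, tree: Clade | None = None) -> pd.DataFrame:
    """Parse the external dating program's node-time summary.

    Expects lines of the form ``t_n<k>  <mean>  (<low>, <high>)``; node
    numbers are mapped back to haplogroup labels when the dated tree is
    supplied.
    """
    rows = []
    numbering = node_numbering(tree) if tree is not None else {}
    n_parsed = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or not line.startswith("t_n"):
                continue
            m = _TIME_RE.match(line)
            if not m:
                raise ValueError(f"line {lineno}: cannot parse node time {line!r}")
            n_parsed += 1
            k = int(m.group(1))
            label = numbering.get(k)
            if tree is not None and label is None:
                logger.warning("node t_n%d not present in tree", k)
            rows.append({
                "node": f"t_n{k}",
                "label": label or "",
                "mean": float(m.group(2)),
                "ci_low": float(m.group(3)),
                "ci_high": float(m.group(4)),
            })
    if n_parsed == 0:
        raise ValueError(f"{path}: no node-time lines found")
    return pd.DataFrame(rows)
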