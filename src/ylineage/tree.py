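"""Haplogroup tree and mutation-marker panel model.

The Y-chromosome haplogroup hierarchy is a rooted tree whose nodes are
haplogroups (clades of paternal lineages defined by shared derived SNP
alleles).  Each haplogroup carries one or more *markers*: SNPs whose derived
allele defines membership in the clade.  Markers conventionally used in labs
(shown in bold on ISOGG-style trees) are flagged as *key* markers; the rest
are *ordinary*.

The panel file format is a tab-delimited table with a header row and columns

    haplogroup  parent  marker  position[ or position_hg19/position_hg38]
    ancestral  derived  key  [ref]

``key`` is 1/0 (or yes/no, true/false).  ``ref`` is the reference-genome base
at the marker position; when absent it defaults to the ancestral base.  Lines
starting with '#' are ignored.  Build tag "19"/"38" selects the position
column when both build columns are present.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

__all__ = [
    "Marker",
    "HaploTree",
    "PanelError",
    "load_marker_panel",
    "write_marker_panel",
]

_BASES = frozenset("ACGT")
_TRUE = {"1", "y", "yes", "true", "t", "key"}
_FALSE = {"0", "n", "no", "false", "f", "ordinary", ""}

ROOT_NAME = "Y-Adam"


class PanelError(ValueError):
    """Structural, parse or conflict error in a marker panel file."""


@dataclass(frozen=True)
class Marker:
    """A haplogroup-defining SNP.

    Parameters
    ----------
    name : marker identifier (e.g. ``M175``)
    haplogroup : haplogroup the derived allele defines
    position : 1-based chrY coordinate on the declared build
    ancestral, derived : single bases, distinct
    is_key : True for key (lab-standard) markers
    ref : reference-genome base at ``position`` (defaults to ancestral)
    """

    name: str
    haplogroup: str
    position: int
    ancestral: str
    derived: str
    is_key: bool
    ref: str = ""

    def __post_init__(self):
        if self.ancestral not in _BASES or self.derived not in _BASES:
            raise PanelError(
                f"marker {self.name}: alleles must be A/C/G/T, got "
                f"{self.ancestral!r}/{self.derived!r}"
            )
        if self.ancestral == self.derived:
            raise PanelError(f"marker {self.name}: ancestral == derived")
        if self.position < 1:
            raise PanelError(f"marker {self.name}: position must be >= 1")
        if not self.ref:
            object.__setattr__(self, "ref", self.ancestral)
        elif self.ref not in _BASES:
            raise PanelError(f"marker {self.name}: ref base {self.ref!r}")


@dataclass
class HaploTree:
    """Rooted haplogroup hierarchy with per-haplogroup markers.

    The root ("Y-Adam") is the ancestral Y chromosome without any derived
    mutation.  Every non-root node has exactly one parent.
    """

    root: str = ROOT_NAME
    parent: dict[str, str] = field(default_factory=dict)
    children: dict[str, list[str]] = field(default_factory=dict)
    markers: dict[str, list[Marker]] = field(default_factory=dict)
    build: str = "19"

    def __post_init__(self):
        self.children.setdefault(self.root, [])

    # -- construction -------------------------------------------------

    def add_node(self, name: str, parent: str) -> None:
        if name in self.parent or name == self.root:
            raise PanelError(f"haplogroup {name!r} defined twice")
        if parent != self.root and parent not in self.parent:
            raise PanelError(
                f"haplogroup {name!r} lists parent {parent!r} which is not defined"
            )
        self.parent[name] = parent
        self.children.setdefault(parent, []).append(name)
        self.children.setdefault(name, [])

    def add_marker(self, m: Marker) -> None:
        if m.haplogroup not in self:
            raise PanelError(
                f"marker {m.name} references unknown haplogroup {m.haplogroup!r}"
            )
        self.markers.setdefault(m.haplogroup, []).append(m)

    # -- queries ------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name == self.root or name in self.parent

    def nodes(self):
        """All haplogroup names, root first, parents before children."""
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children.get(n, [])))
        return out

    def depth(self, name: str) -> int:
        """Number of edges from the root; used as the resolution r."""
        if name not in self:
            raise KeyError(f"unknown haplogroup {name!r}")
        d = 0
        while name != self.root:
            name = self.parent[name]
            d += 1
        return d

    def path_from_root(self, name: str) -> list[str]:
        """Haplogroups from the child of the root down to ``name``."""
        if name not in self:
            raise KeyError(f"unknown haplogroup {name!r}")
        path = []
        while name != self.root:
            path.append(name)
            name = self.parent[name]
        path.reverse()
        return path

    def simplify(self, name: str, level: int) -> str:
        """Ancestor of ``name`` at depth ``level``; ``name`` if at most that deep.

        Collapsing haplogroups to a common level puts samples classified at
        different resolutions on an equal footing for frequency-based
        analyses.
        """
        if level < 1:
            raise ValueError("level must be >= 1")
        if name not in self:
            raise KeyError(f"unknown haplogroup {name!r}")
        chain = self.path_from_root(name)
        if len(chain) <= level:
            return name
        return chain[level - 1]

    def all_markers(self) -> list[Marker]:
        return [m for ms in self.markers.values() for m in ms]

    def is_descendant(self, node: str, ancestor: str) -> bool:
        """True if ``node`` equals or descends from ``ancestor``."""
        if node not in self or ancestor not in self:
            raise KeyError("unknown haplogroup")
        while True:
            if node == ancestor:
                return True
            if node == self.root:
                return False
            node = self.parent[node]


def _parse_key(raw: str, row: int) -> bool:
    v = raw.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise PanelError(f"row {row}: cannot parse key flag {raw!r}")


def load_marker_panel(source, build: str = "19") -> tuple[HaploTree, list[Marker]]:
    """Load a haplogroup tree plus its marker panel from a panel TSV.

    ``source`` is a path or an open text handle.  Duplicate identical
    (marker, haplogroup) rows are collapsed; duplicate rows with conflicting
    alleles raise :class:`PanelError`.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh = open(source, "rt", encoding="utf-8")
        close = True
    else:
        fh = source
    try:
        header = None
        rows = []
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [h.strip().lower() for h in fields]
                continue
            rows.append((lineno, dict(zip(header, fields))))
        if header is None:
            raise PanelError("panel file has no header row")
    finally:
        if close:
            fh.close()

    build = str(build).lstrip("hg")
    if f"position_hg{build}" in header:
        pos_col = f"position_hg{build}"
    elif "position" in header:
        pos_col = "position"
    else:
        raise PanelError(f"no position column for build hg{build}")

    required = {"haplogroup", "parent", "marker", "ancestral", "derived", "key"}
    missing = required - set(header)
    if missing:
        raise PanelError(f"panel missing columns: {sorted(missing)}")

    tree = HaploTree(build=build)
    # first pass: nodes (in file order, parents must precede children except
    # for parents equal to the root)
    pending: list[tuple[int, str, str]] = []
    seen_nodes: dict[str, str] = {}
    for lineno, r in rows:
        hg, parent = r["haplogroup"].strip(), r["parent"].strip()
        if not hg:
            raise PanelError(f"row {lineno}: empty haplogroup name")
        if hg in seen_nodes:
            if seen_nodes[hg] != parent:
                raise PanelError(
                    f"row {lineno}: haplogroup {hg!r} listed with two parents"
                )
            continue
        seen_nodes[hg] = parent
        pending.append((lineno, hg, parent))

    # topological insert; detects orphans and cycles
    remaining = pending
    while remaining:
        progressed = []
        deferred = []
        for lineno, hg, parent in remaining:
            if parent == tree.root or parent in tree:
                tree.add_node(hg, parent)
                progressed.append(hg)
            else:
                deferred.append((lineno, hg, parent))
        if not progressed:
            lineno, hg, parent = deferred[0]
            raise PanelError(
                f"row {lineno}: haplogroup {hg!r} has undefined parent {parent!r}"
            )
        remaining = deferred

    markers: list[Marker] = []
    seen_markers: dict[tuple[str, str], Marker] = {}
    for lineno, r in rows:
        name = r["marker"].strip()
        if not name or name == ".":
            continue  # node-only row
        try:
            m = Marker(
                name=name,
                haplogroup=r["haplogroup"].strip(),
                position=int(r[pos_col]),
                ancestral=r["ancestral"].strip().upper(),
                derived=r["derived"].strip().upper(),
                is_key=_parse_key(r.get("key", "0"), lineno),
                ref=r.get("ref", "").strip().upper(),
            )
        except ValueError as e:
            if isinstance(e, PanelError):
                raise
            raise PanelError(f"row {lineno}: {e}") from e
        kk = (m.name, m.haplogroup)
        if kk in seen_markers:
            prev = seen_markers[kk]
            if prev != m:
                raise PanelError(
                    f"row {lineno}: marker {m.name} at {m.haplogroup} conflicts "
                    f"with an earlier row"
                )
            continue
        seen_markers[kk] = m
        tree.add_marker(m)
        markers.append(m)
    return tree, markers


def write_marker_panel(tree: HaploTree, path_or_handle) -> None:
    """Serialize a tree + markers back to the panel TSV format."""
    buf = io.StringIO()
    buf.write("haplogroup\tparent\tmarker\tposition\tancestral\tderived\tkey\tref\n")
    for node in tree.nodes():
        if node == tree.root:
            continue
        ms = tree.markers.get(node, [])
        if not ms:
            buf.write(f"{node}\t{tree.parent[node]}\t.\t1\tA\tC\t0\tA\n")
        for m in ms:
            buf.write(
                f"{node}\t{tree.parent[node]}\t{m.name}\t{m.position}\t"
                f"{m.ancestral}\t{m.derived}\t{int(m.is_key)}\t{m.ref}\n"
            )
    text = buf.getvalue()
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "wt", encoding="utf-8") as fh:
            fh.write(text)
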