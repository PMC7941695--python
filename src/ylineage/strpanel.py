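"""Y-STR reference panel registry.

A Y-STR locus is described by its interval on chrY and an ordered motif
composition ``(M_1)_{p_1} (M_2)_{p_2} ... (M_n)_{p_n}``; the reference
repeat number is ``p = sum_i p_i`` and the *extension unit* is the last
motif (length ``s``), the block that varies between alleles.

The built-in panels mirror the nested commercial genotyping kits:

    minimal (9)  ⊂  powerplex-y (12)  ⊂  yfiler (17)  ⊂  powerplex-y23 (23)

plus ``named`` (every named locus in the panel file) and ``all`` (every
locus).  The packaged locus table carries synthetic coordinates and flanks
(see ``data/str_panel_synthetic.tsv``); user panels are plain TSVs with the
same columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

__all__ = ["STRLocus", "PanelRegistry", "load_str_panel", "PANEL_NAMES"]

MINIMAL = [
    "DYS19", "DYS385a", "DYS385b", "DYS389I", "DYS389II",
    "DYS390", "DYS391", "DYS392", "DYS393",
]
POWERPLEX_Y = MINIMAL + ["DYS437", "DYS438", "DYS439"]
YFILER = POWERPLEX_Y + ["DYS448", "DYS456", "DYS458", "DYS635", "YGATAH4"]
POWERPLEX_Y23 = YFILER + ["DYS481", "DYS533", "DYS549", "DYS570", "DYS576",
                          "DYS643"]

PANEL_NAMES = ("minimal", "powerplex-y", "yfiler", "powerplex-y23", "named",
               "all")


@dataclass(frozen=True)
class STRLocus:
    """A reference Y-STR locus as an ordered motif composition."""

    name: str
    start: int  # 1-based inclusive, declared build
    end: int
    motifs: tuple[tuple[str, int], ...]  # (motif, repeat count) in order
    named: bool = True

    def __post_init__(self):
        if not self.motifs or any(not m for m, _ in self.motifs):
            raise ValueError(f"{self.name}: empty motif")
        length = sum(c * len(m) for m, c in self.motifs)
        if self.end - self.start + 1 != length:
            raise ValueError(
                f"locus {self.name}: interval length {self.end - self.start + 1} "
                f"!= motif composition length {length}"
            )

    @property
    def p(self) -> int:
        """Reference total repeat number."""
        return sum(c for _, c in self.motifs)

    @property
    def s(self) -> int:
        """Extension-unit (last motif) length."""
        return len(self.motifs[-1][0])

    @property
    def reference_sequence(self) -> str:
        return "".join(m * c for m, c in self.motifs)


class PanelRegistry:
    """Named panels over a locus collection, nested per the kit hierarchy."""

    def __init__(self, loci: list[STRLocus]):
        self.loci = {l.name: l for l in loci}
        named = [l.name for l in loci if l.named]
        self.panels: dict[str, list[str]] = {
            "minimal": list(MINIMAL),
            "powerplex-y": list(POWERPLEX_Y),
            "yfiler": list(YFILER),
            "powerplex-y23": list(POWERPLEX_Y23),
            "named": named,
            "all": [l.name for l in loci],
        }

    def get(self, panel: str) -> list[STRLocus]:
        key = panel.lower()
        if key not in self.panels:
            raise KeyError(
                f"unknown panel {panel!r}; valid names: {', '.join(PANEL_NAMES)}"
            )
        missing = [n for n in self.panels[key] if n not in self.loci]
        if missing:
            raise KeyError(f"panel {panel!r} loci absent from locus table: {missing}")
        return [self.loci[n] for n in self.panels[key]]


def _parse_motifs(text: str) -> tuple[tuple[str, int], ...]:
    out = []
    for part in text.strip().split(","):
        motif, _, count = part.partition(":")
        motif = motif.strip().upper()
        if not motif or not count.strip().isdigit():
            raise ValueError(f"bad motif composition {text!r}")
        out.append((motif, int(count)))
    return tuple(out)


def load_str_panel(source=None, build: str = "19") -> tuple[PanelRegistry, list[STRLocus]]:
    """Load the packaged (default) or a user STR locus table.

    Columns: name, start_hg19, end_hg19, start_hg38, end_hg38, motifs,
    named — or single start/end columns for single-build tables.  Motif
    composition syntax: ``TCTG:3,TCTA:9``.
    """
    if source is None:
        source = files("ylineage.data").joinpath("str_panel_synthetic.tsv")
    build = str(build).lstrip("hg")
    loci: list[STRLocus] = []
    with open(str(source), "rt", encoding="utf-8") as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [h.strip().lower() for h in fields]
                continue
            r = dict(zip(header, fields))
            s_col = f"start_hg{build}" if f"start_hg{build}" in r else "start"
            e_col = f"end_hg{build}" if f"end_hg{build}" in r else "end"
            if s_col not in r or e_col not in r:
                raise ValueError(f"no start/end columns for build hg{build}")
            try:
                loci.append(STRLocus(
                    name=r["name"].strip(),
                    start=int(r[s_col]),
                    end=int(r[e_col]),
                    motifs=_parse_motifs(r["motifs"]),
                    named=r.get("named", "1").strip().lower() not in ("0", "no", "false"),
                ))
            except ValueError as e:
                raise ValueError(f"row {lineno}: {e}") from e
    return PanelRegistry(loci), loci
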