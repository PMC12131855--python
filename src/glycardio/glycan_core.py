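"""Glycan composition notation, monoisotopic mass arithmetic and N-glycan
class taxonomy.

N-glycans are built on a Man3GlcNAc2 core attached to asparagine.  After
release (PNGase F) and reduction the free glycan is an alditol; all masses
here are monoisotopic and refer to that reduced form unless stated
otherwise.  Compositions are written in the compact ``H{h}N{n}F{f}S{s}``
notation (Hex, HexNAc, deoxyhexose/Fuc, NeuAc), e.g. ``H5N4F1S2`` for a
disialylated core-fucosylated biantennary glycan.

Two classification levels are provided:

* composition level — the coarse paucimannose / oligomannose / processed
  split that can be read off H/N/F/S counts alone;
* structure level — the fine eight-class vocabulary (paucimannose,
  high-mannose, hybrid, complex mono/bi/tri/tetra-antennary, bisecting)
  plus terminal/core motif flags, which requires the branching topology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

__all__ = [
    "MassTable",
    "MASSES",
    "GlycanComposition",
    "parse_composition",
    "ResidueNode",
    "GlycanStructure",
    "parse_structure",
    "GlycanClassLabel",
    "COARSE_CLASSES",
    "FINE_CLASSES",
    "classify_composition",
    "classify_structure",
    "composition_property",
    "class_distribution",
    "read_library",
    "write_library",
]


# --------------------------------------------------------------------------
# Mass table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MassTable:
    """Monoisotopic residue masses (Da) — the single source of truth for all
    mass arithmetic in the package.

    Residue masses are the dehydrated (in-chain) values; a free glycan adds
    one water, and the reducing-end alditol adds 2H.
    """

    hex: float = 162.052824
    hexnac: float = 203.079373
    dhex: float = 146.057909
    neuac: float = 291.095417
    water: float = 18.010565
    proton: float = 1.007276
    reduction: float = 2.015650  # open-ring alditol, +2H

    def residue_mass(self, residue: str) -> float:
        """Mass of a named residue (monosaccharide symbol or mass class)."""
        try:
            return _RESIDUE_CLASS_MASS[_RESIDUE_CLASS[residue]](self)
        except KeyError:
            raise KeyError(f"unknown residue {residue!r}") from None


#: Module-level default mass table.
MASSES = MassTable()

# Symbol -> H/N/F/S mass class for structure-level residues.
_RESIDUE_CLASS: dict[str, str] = {
    "Hex": "hex", "Man": "hex", "Gal": "hex", "Glc": "hex",
    "HexNAc": "hexnac", "GlcNAc": "hexnac", "GalNAc": "hexnac",
    "Fuc": "dhex", "dHex": "dhex",
    "NeuAc": "neuac", "Neu5Ac": "neuac",
}
_RESIDUE_CLASS_MASS = {
    "hex": lambda t: t.hex,
    "hexnac": lambda t: t.hexnac,
    "dhex": lambda t: t.dhex,
    "neuac": lambda t: t.neuac,
}


# --------------------------------------------------------------------------
# Composition
# --------------------------------------------------------------------------

class CompositionError(ValueError):
    """Raised for malformed composition strings."""


_TOKEN_RE = re.compile(r"([A-Za-z]+)(\d+)")


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts of an N-glycan candidate.

    Fields follow the H/N/F/S shorthand: ``hex`` (Hex), ``hexnac``
    (HexNAc), ``fuc`` (deoxyhexose), ``neuac`` (sialic acid).
    """

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "fuc", "neuac"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise CompositionError(
                    f"count {name}={v!r} must be a non-negative integer"
                )

    # -- notation ---------------------------------------------------------

    def __str__(self) -> str:
        return self.format()

    def format(self) -> str:
        """Canonical ``H{h}N{n}F{f}S{s}`` string; zero counts omitted."""
        parts = []
        for letter, count in zip("HNFS", self.as_tuple()):
            if count:
                parts.append(f"{letter}{count}")
        return "".join(parts)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.hex, self.hexnac, self.fuc, self.neuac)

    # -- algebra ----------------------------------------------------------

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hex + other.hex, self.hexnac + other.hexnac,
            self.fuc + other.fuc, self.neuac + other.neuac,
        )

    def distance(self, other: "GlycanComposition") -> int:
        """Manhattan distance over (H, N, F, S) counts."""
        return sum(abs(a - b) for a, b in zip(self.as_tuple(), other.as_tuple()))

    @property
    def total(self) -> int:
        return sum(self.as_tuple())

    # -- masses -----------------------------------------------------------

    def neutral_mass(self, reduced: bool = True, masses: MassTable = MASSES) -> float:
        """Monoisotopic neutral mass in Da.

        Sum of residue masses plus one water; ``reduced`` adds the +2H
        alditol delta of reducing-end reduction.
        """
        m = (self.hex * masses.hex + self.hexnac * masses.hexnac
             + self.fuc * masses.dhex + self.neuac * masses.neuac
             + masses.water)
        if reduced:
            m += masses.reduction
        return m

    def mz(self, charge: int, reduced: bool = True,
           masses: MassTable = MASSES) -> float:
        """m/z of the deprotonated negative ion [M − zH]^z−."""
        if not isinstance(charge, int) or charge < 1:
            raise ValueError(f"charge must be a positive integer, got {charge!r}")
        return (self.neutral_mass(reduced, masses) - charge * masses.proton) / charge


_LETTER_FIELD = {"H": "hex", "N": "hexnac", "F": "fuc", "S": "neuac", "A": "neuac"}


def parse_composition(text: str) -> GlycanComposition:
    """Parse an ``H{h}N{n}F{f}S{s}`` composition string (any token order).

    ``A`` is accepted as a NeuAc synonym on input; ``S`` is canonical on
    output.  Each letter may appear at most once.
    """
    if not isinstance(text, str):
        raise CompositionError(f"composition must be a string, got {type(text).__name__}")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(s):
        if m.start() != pos:
            raise CompositionError(
                f"malformed composition {text!r}: unexpected {s[pos:m.start()]!r}"
            )
        pos = m.end()
        letter, num = m.group(1), m.group(2)
        if letter not in _LETTER_FIELD:
            raise CompositionError(
                f"malformed composition {text!r}: unknown residue letter {letter!r}"
            )
        fieldname = _LETTER_FIELD[letter]
        if fieldname in counts:
            raise CompositionError(
                f"malformed composition {text!r}: repeated letter {letter!r}"
            )
        counts[fieldname] = int(num)
    if pos != len(s) or (s and not counts):
        raise CompositionError(
            f"malformed composition {text!r}: unexpected {s[pos:]!r}"
        )
    return GlycanComposition(**counts)


# --------------------------------------------------------------------------
# Structure trees
# --------------------------------------------------------------------------

#: Recognised arm tags on tree nodes.  ``core`` marks the chitobiose/
#: trimannosyl scaffold, ``3``/``6`` the two core-mannose arms, ``bis`` the
#: bisecting GlcNAc, ``cf`` the core fucose; plain antenna residues carry
#: no tag or a numeric antenna index.
ARM_TAGS = {"core", "3", "6", "bis", "cf"}


@dataclass
class ResidueNode:
    """One residue in a rooted glycan tree."""

    residue: str
    tag: Optional[str] = None
    children: list["ResidueNode"] = field(default_factory=list)

    def add(self, child: "ResidueNode") -> "ResidueNode":
        self.children.append(child)
        return child

    def walk(self) -> Iterator["ResidueNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def serialize(self) -> str:
        tag = f"[{self.tag}]" if self.tag else ""
        return self.residue + tag + "".join(
            f"({c.serialize()})" for c in self.children
        )


class StructureError(ValueError):
    """Raised for ill-formed glycan trees or serializations."""


@dataclass
class GlycanStructure:
    """Rooted N-glycan tree; root is the reducing-end GlcNAc (alditol when
    ``reduced``)."""

    id: str
    root: ResidueNode
    reduced: bool = True

    def __post_init__(self) -> None:
        if _RESIDUE_CLASS.get(self.root.residue) != "hexnac":
            raise StructureError(
                f"{self.id}: root must be the reducing-end HexNAc, "
                f"got {self.root.residue!r}"
            )
        bis = [n for n in self.root.walk() if n.tag == "bis"]
        if len(bis) > 1:
            raise StructureError(f"{self.id}: more than one bisecting node")
        cf = [n for n in self.root.children if n.tag == "cf"]
        if len([n for n in self.root.walk() if n.tag == "cf"]) != len(cf):
            raise StructureError(f"{self.id}: core fucose must sit on the root")
        if len(cf) > 1:
            raise StructureError(f"{self.id}: more than one core fucose")

    # -- residue accounting ----------------------------------------------

    def nodes(self) -> list[ResidueNode]:
        return list(self.root.walk())

    @property
    def composition(self) -> GlycanComposition:
        counts = {"hex": 0, "hexnac": 0, "dhex": 0, "neuac": 0}
        for node in self.root.walk():
            try:
                counts[_RESIDUE_CLASS[node.residue]] += 1
            except KeyError:
                raise StructureError(
                    f"{self.id}: unknown residue {node.residue!r}"
                ) from None
        return GlycanComposition(
            counts["hex"], counts["hexnac"], counts["dhex"], counts["neuac"]
        )

    def neutral_mass(self, masses: MassTable = MASSES) -> float:
        return self.composition.neutral_mass(self.reduced, masses)

    def mz(self, charge: int, masses: MassTable = MASSES) -> float:
        return self.composition.mz(charge, self.reduced, masses)

    # -- topology helpers -------------------------------------------------

    def core(self) -> Optional[dict[str, ResidueNode]]:
        """Locate the canonical GlcNAc2-Man(β) core.

        Returns a mapping with keys ``root``, ``core_glcnac``, ``beta_man``
        and, when present, ``arm3``/``arm6`` (the 3- and 6-linked core
        mannoses) — or None when the trimmed structure lacks the scaffold.
        """
        glcnac2 = next(
            (c for c in self.root.children
             if _RESIDUE_CLASS.get(c.residue) == "hexnac" and c.tag != "bis"),
            None,
        )
        if glcnac2 is None:
            return None
        beta = next(
            (c for c in glcnac2.children
             if _RESIDUE_CLASS.get(c.residue) == "hex"),
            None,
        )
        if beta is None:
            return None
        out = {"root": self.root, "core_glcnac": glcnac2, "beta_man": beta}
        for child in beta.children:
            if child.tag == "3":
                out["arm3"] = child
            elif child.tag == "6":
                out["arm6"] = child
        return out

    def antennae(self) -> list[ResidueNode]:
        """HexNAc-initiated branches on the core mannoses (bisecting
        excluded)."""
        core = self.core()
        if core is None:
            return []
        out = []
        for arm in ("arm3", "arm6"):
            node = core.get(arm)
            if node is None:
                continue
            for sub in node.walk():
                if sub.residue not in ("Man", "Hex"):
                    continue  # antennae initiate on mannoses, not on caps
                out.extend(
                    c for c in sub.children
                    if _RESIDUE_CLASS.get(c.residue) == "hexnac" and c.tag != "bis"
                )
        return out

    def bisecting(self) -> Optional[ResidueNode]:
        return next((n for n in self.root.walk() if n.tag == "bis"), None)

    def core_fucose(self) -> Optional[ResidueNode]:
        return next((n for n in self.root.children if n.tag == "cf"), None)

    def serialize(self) -> str:
        return self.root.serialize()


_STRUCT_TOKEN = re.compile(r"([A-Za-z0-9]+)(?:\[([A-Za-z0-9]+)\])?")


def parse_structure(text: str, id: str = "", reduced: bool = True) -> GlycanStructure:
    """Parse the bracket serialization of a glycan tree.

    Grammar: ``node = residue[tag] ( '(' node ')' )*`` — e.g. the
    trimannosyl core is ``GlcNAc(GlcNAc(Man(Man[3])(Man[6])))`` and core
    fucose appears as a ``Fuc[cf]`` child of the root.
    """

    def parse_node(s: str, i: int) -> tuple[ResidueNode, int]:
        m = _STRUCT_TOKEN.match(s, i)
        if not m:
            raise StructureError(f"bad structure string at position {i}: {s[i:i + 20]!r}")
        node = ResidueNode(m.group(1), m.group(2))
        i = m.end()
        while i < len(s) and s[i] == "(":
            child, i = parse_node(s, i + 1)
            if i >= len(s) or s[i] != ")":
                raise StructureError(f"unbalanced parentheses in {s!r}")
            node.children.append(child)
            i += 1
        return node, i

    root, end = parse_node(text.strip(), 0)
    if end != len(text.strip()):
        raise StructureError(f"trailing characters in structure string {text!r}")
    return GlycanStructure(id=id or text, root=root, reduced=reduced)


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

COARSE_CLASSES = ("paucimannose", "oligomannose", "processed")
FINE_CLASSES = (
    "paucimannose", "high-mannose", "hybrid",
    "complex-mono", "complex-bi", "complex-tri", "complex-tetra", "bisecting",
)
UNCLASSIFIED = "unclassified"

_FINE_TO_COARSE = {
    "paucimannose": "paucimannose",
    "high-mannose": "oligomannose",
}


def fine_to_coarse(fine: str) -> str:
    return _FINE_TO_COARSE.get(fine, "processed")


@dataclass(frozen=True)
class GlycanClassLabel:
    """Structure-level class assignment: one fine class, its implied coarse
    class, and the set of terminal/core motifs present."""

    fine: str
    motifs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.fine not in FINE_CLASSES:
            raise ValueError(f"unknown fine class {self.fine!r}")

    @property
    def coarse(self) -> str:
        return fine_to_coarse(self.fine)


def classify_composition(
    comp: GlycanComposition,
    pauci_hex_max: int = 4,
    oligo_hex_max: int = 12,
) -> str:
    """Coarse class from counts alone.

    HexNAc2 with 1–``pauci_hex_max`` Hex and no sialic acid is
    paucimannose; HexNAc2 with more Hex (up to ``oligo_hex_max``) is
    oligomannose — fucosylated variants stay in class (core-fucosylated
    high mannose is a real, if uncommon, cardiac species).  HexNAc ≥ 3 is
    processed (hybrid/complex).  Anything else — HexNAc < 2, sialylated
    HexNAc2, or Hex out of range — returns ``"unclassified"``.
    """
    if comp.hexnac == 2 and comp.neuac == 0:
        if 1 <= comp.hex <= pauci_hex_max:
            return "paucimannose"
        if pauci_hex_max < comp.hex <= oligo_hex_max:
            return "oligomannose"
        return UNCLASSIFIED
    if comp.hexnac >= 3:
        return "processed"
    return UNCLASSIFIED


def classify_structure(
    s: GlycanStructure, pauci_hex_max: int = 4
) -> GlycanClassLabel:
    """Fine class and motif flags from branching topology.

    Antenna count = number of HexNAc-initiated branches on the two core-
    mannose arms (bisecting GlcNAc excluded).  A structure with no antennae
    is paucimannose or high-mannose by Hex count; one arm carrying only
    mannoses alongside ≥1 antenna is hybrid; a bisecting GlcNAc pre-empts
    the antenna-count classes; otherwise the class is complex-mono/bi/tri/
    tetra by antenna count.
    """
    comp = s.composition
    ants = s.antennae()
    n_ant = len(ants)
    motifs = set()
    if s.core_fucose() is not None:
        motifs.add("core-fucose")
    if comp.fuc > (1 if s.core_fucose() is not None else 0):
        motifs.add("terminal-fucose")
    if comp.neuac > 0:
        motifs.add("sialylated")
    for ant in ants:
        for child in ant.children:
            cls = _RESIDUE_CLASS.get(child.residue)
            if cls == "hex":
                motifs.add("LacNAc")
            elif cls == "hexnac":
                motifs.add("LacdiNAc")

    if n_ant == 0:
        if comp.hexnac == 2:
            fine = "paucimannose" if comp.hex <= pauci_hex_max else "high-mannose"
            return GlycanClassLabel(fine, frozenset(motifs))
        raise StructureError(
            f"{s.id}: no antennae but HexNAc={comp.hexnac}; not in class vocabulary"
        )
    if s.bisecting() is not None:
        return GlycanClassLabel("bisecting", frozenset(motifs))

    core = s.core()
    arm_has_ant = {}
    for arm in ("arm3", "arm6"):
        node = core.get(arm) if core else None
        arm_has_ant[arm] = bool(node) and any(
            _RESIDUE_CLASS.get(c.residue) == "hexnac" and c.tag != "bis"
            for sub in node.walk() if sub.residue in ("Man", "Hex")
            for c in sub.children
        )
    # hybrid: exactly one arm processed, the other *retaining* mannoses —
    # i.e. carrying only hexoses and still extended (>=2), so that a plain
    # mono-antennary structure on an intact Man3 core stays complex-mono
    if core and ("arm3" in core and "arm6" in core):
        if arm_has_ant["arm3"] != arm_has_ant["arm6"]:
            bare = core["arm6" if arm_has_ant["arm3"] else "arm3"]
            bare_nodes = list(bare.walk())
            if (len(bare_nodes) >= 2 and all(
                    _RESIDUE_CLASS.get(n.residue) == "hex" for n in bare_nodes)):
                return GlycanClassLabel("hybrid", frozenset(motifs))
    by_count = {1: "complex-mono", 2: "complex-bi", 3: "complex-tri", 4: "complex-tetra"}
    if n_ant not in by_count:
        raise StructureError(
            f"{s.id}: {n_ant} antennae is outside the class vocabulary"
        )
    return GlycanClassLabel(by_count[n_ant], frozenset(motifs))


PROPERTY_CATEGORIES = (
    "neutral", "fuco", "sialylated", "fuco-sialylated",
    "oligomannose/paucimannose",
)


def composition_property(comp: GlycanComposition) -> str:
    """Composition property bucket: the HexNAc2 backbone goes to the
    oligomannose/paucimannose bucket; everything else is classified by its
    fucose/sialic-acid decoration."""
    if comp.hexnac == 2:
        return "oligomannose/paucimannose"
    if comp.fuc > 0 and comp.neuac > 0:
        return "fuco-sialylated"
    if comp.fuc > 0:
        return "fuco"
    if comp.neuac > 0:
        return "sialylated"
    return "neutral"


def class_distribution(
    rel_abund: pd.DataFrame, classes: Mapping[str, str]
) -> pd.Series:
    """Percentage of total abundance per glycan class.

    ``rel_abund`` is glycans × samples in percent (columns summing to 100);
    per class the relative abundances are summed within each sample and
    averaged over samples, so the result sums to 100.
    """
    missing = [g for g in rel_abund.index if g not in classes]
    if missing:
        raise KeyError(f"no class mapping for glycans: {missing}")
    labels = pd.Series({g: classes[g] for g in rel_abund.index})
    per_sample = rel_abund.groupby(labels).sum()
    return per_sample.mean(axis=1)


# --------------------------------------------------------------------------
# Library I/O
# --------------------------------------------------------------------------

LIBRARY_COLUMNS = [
    "glycan_id", "composition", "fine_class", "structure",
    "theoretical_mz", "charge", "rrt", "glytoucan_id",
]


def read_library(path) -> pd.DataFrame:
    """Read a glycan library CSV/TSV and validate its schema.

    Columns: glycan_id, composition (H/N/F/S string), fine_class,
    structure (bracket serialization), theoretical_mz, charge, rrt,
    glytoucan_id.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"glycan_id": str})
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"library file {path} missing columns: {missing}")
    if df["glycan_id"].duplicated().any():
        dups = df.loc[df["glycan_id"].duplicated(), "glycan_id"].tolist()
        raise ValueError(f"duplicate glycan ids in {path}: {dups}")
    for c in df["composition"]:
        parse_composition(c)
    return df


def write_library(df: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)
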