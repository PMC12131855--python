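"""Theoretical fragment generation and diagnostic-ion matching for
negative-mode glycan MS/MS.

Collision-induced dissociation of deprotonated glycan alditols yields
glycosidic B/C (non-reducing side) and Y/Z (reducing side) ions
(Domon–Costello nomenclature) plus a small set of double-cleavage
diagnostic ions that carry branching information:

* D ion — B-type fragment retaining the 6-arm antennae, the 6-linked core
  mannose and the β-mannose; its presence pins residues to the 6-arm.
* D−18 — the D ion after water loss.
* D−221 — for bisected structures the bisecting GlcNAc is lost from D as
  a 221.09 Da neutral (HexNAc residue + water), a classic bisecting
  diagnostic.
* E ion — the tri-antennary diagnostic; its exact residue inclusion varies
  between conventions, so it is a configurable rule-table entry whose
  default retains the 3-arm antennae + 3-linked core mannose + β-mannose
  (the 3-arm counterpart of D, where the third antenna sits in most
  mammalian N-glycans).

One cross-ring rule (0,2A on the reducing-end GlcNAc-ol) is included;
full A/X enumeration is deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from pyteomics import mgf as _mgf

from .glycan_core import (
    MASSES,
    MassTable,
    GlycanStructure,
    ResidueNode,
    StructureError,
    _RESIDUE_CLASS,
)

__all__ = [
    "FragmentIon",
    "Spectrum",
    "TopologyEvidence",
    "DiagnosticRule",
    "DEFAULT_DIAGNOSTIC_RULES",
    "enumerate_glycosidic_fragments",
    "diagnostic_ions",
    "match_peaks",
    "PeakAnnotation",
    "infer_topology",
    "read_mgf",
    "write_mgf",
    "write_annotation_tsv",
]

#: Matching priority when two theoretical ions tie on ppm error.
ION_KIND_PRIORITY = ["B", "C", "Y", "Z", "D", "D-18", "D-221", "E", "0,2A-core"]

#: Neutral loss of C1–C2 (with the N-acetyl) of the reducing-end
#: GlcNAc-alditol, C4H9NO2 — the default 0,2A cross-ring rule.
A02_LOSS = 103.063329


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment: kind, residue multiset (H/N/F/S counts of
    the retained residues), neutral mass, charge, m/z and the cleaved
    edge(s) it came from."""

    kind: str
    residues: tuple[int, int, int, int]
    neutral_mass: float
    charge: int
    mz: float
    provenance: str = ""


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum: precursor and (m/z, intensity) peaks
    sorted by m/z."""

    precursor_mz: float
    precursor_charge: int
    peaks: list[tuple[float, float]] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be non-negative")
        self.peaks = sorted(self.peaks)


@dataclass
class TopologyEvidence:
    """Diagnostic-ion readout: each True flag cites the supporting matched
    peak indices."""

    six_arm_confirmed: bool = False
    three_arm_confirmed: bool = False
    bisecting: bool = False
    tri_antennary: bool = False
    supporting_peaks: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Glycosidic fragments
# --------------------------------------------------------------------------

def _residue_counts(nodes: Iterable[ResidueNode]) -> tuple[int, int, int, int]:
    counts = {"hex": 0, "hexnac": 0, "dhex": 0, "neuac": 0}
    for n in nodes:
        counts[_RESIDUE_CLASS[n.residue]] += 1
    return (counts["hex"], counts["hexnac"], counts["dhex"], counts["neuac"])


def _counts_mass(counts: Sequence[int], masses: MassTable) -> float:
    h, n, f, s = counts
    return h * masses.hex + n * masses.hexnac + f * masses.dhex + s * masses.neuac


def _neg_mz(neutral: float, charge: int, masses: MassTable) -> float:
    return (neutral - charge * masses.proton) / charge


def enumerate_glycosidic_fragments(
    s: GlycanStructure, max_charge: int = 2, masses: MassTable = MASSES
) -> list[FragmentIon]:
    """All single-glycosidic-cleavage B/C/Y/Z ions at charges 1..max_charge.

    For a cleavage separating a non-reducing subtree (mass R = sum of its
    residue masses) from the rest: B = R, C = R + water; the reducing-side
    complement keeps the free glycan's water (and alditol 2H when reduced):
    Y = M − R, Z = Y − water.  Hence B + Y = M + water for every edge.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    total_neutral = s.neutral_mass(masses)
    ions: list[FragmentIon] = []

    def emit(kind: str, counts, neutral: float, edge: str) -> None:
        if neutral <= 0:
            return
        for z in range(1, max_charge + 1):
            ions.append(FragmentIon(
                kind=kind, residues=tuple(counts), neutral_mass=neutral,
                charge=z, mz=_neg_mz(neutral, z, masses),
                provenance=edge,
            ))

    full = s.composition.as_tuple()
    for parent in s.root.walk():
        for child in parent.children:
            sub = list(child.walk())
            b_counts = _residue_counts(sub)
            b_neutral = _counts_mass(b_counts, masses)
            y_counts = tuple(a - b for a, b in zip(full, b_counts))
            y_neutral = total_neutral - b_neutral
            edge = f"{parent.residue}-{child.residue}"
            emit("B", b_counts, b_neutral, edge)
            emit("C", b_counts, b_neutral + masses.water, edge)
            emit("Y", y_counts, y_neutral, edge)
            emit("Z", y_counts, y_neutral - masses.water, edge)
    return ions


# --------------------------------------------------------------------------
# Diagnostic ions
# --------------------------------------------------------------------------

def _six_arm_with_bmannose(s: GlycanStructure) -> Optional[list[ResidueNode]]:
    core = s.core()
    if core is None:
        return None
    nodes = [core["beta_man"]]
    if "arm6" in core:
        nodes.extend(core["arm6"].walk())
    return nodes


def _three_arm_with_bmannose(s: GlycanStructure) -> Optional[list[ResidueNode]]:
    core = s.core()
    if core is None:
        return None
    nodes = [core["beta_man"]]
    if "arm3" in core:
        nodes.extend(core["arm3"].walk())
    return nodes


_SELECTORS: dict[str, Callable] = {
    "six_arm_with_bmannose": _six_arm_with_bmannose,
    "three_arm_with_bmannose": _three_arm_with_bmannose,
}


@dataclass(frozen=True)
class DiagnosticRule:
    """One entry of the diagnostic-ion rule table.

    ``selector`` names the retained subtree, ``offset`` a mass delta (Da)
    applied to the sum of retained residue masses, ``condition`` gates
    emission (``always`` / ``bisecting`` / ``tri_antennary``).
    """

    kind: str
    selector: str
    offset: float = 0.0
    condition: str = "always"


DEFAULT_DIAGNOSTIC_RULES: tuple[DiagnosticRule, ...] = (
    DiagnosticRule("D", "six_arm_with_bmannose", 0.0, "always"),
    DiagnosticRule("D-18", "six_arm_with_bmannose", -MASSES.water, "always"),
    DiagnosticRule("D-221", "six_arm_with_bmannose",
                   -(MASSES.hexnac + MASSES.water), "bisecting"),
    DiagnosticRule("E", "three_arm_with_bmannose", 0.0, "tri_antennary"),
)


def diagnostic_ions(
    s: GlycanStructure,
    rules: Sequence[DiagnosticRule] = DEFAULT_DIAGNOSTIC_RULES,
    include_a_core: bool = True,
    max_charge: int = 1,
    masses: MassTable = MASSES,
) -> list[FragmentIon]:
    """Diagnostic D-family/E ions per the rule table, plus the optional
    0,2A-core cross-ring ion.

    Requires the canonical Man3GlcNAc2-type core (raises StructureError
    otherwise).  The D ion's retained set for a bisected structure still
    excludes the bisecting GlcNAc — its loss is what the −221 satellite
    reports.
    """
    if s.core() is None:
        raise StructureError(f"{s.id}: no canonical core; diagnostic ions undefined")
    n_ant = len(s.antennae())
    has_bis = s.bisecting() is not None
    ions: list[FragmentIon] = []
    for rule in rules:
        if rule.condition == "bisecting" and not has_bis:
            continue
        if rule.condition == "tri_antennary" and n_ant < 3:
            continue
        nodes = _SELECTORS[rule.selector](s)
        if nodes is None:
            continue
        nodes = [n for n in nodes if n.tag != "bis"]
        counts = _residue_counts(nodes)
        neutral = _counts_mass(counts, masses) + rule.offset
        if neutral <= 0:
            continue
        for z in range(1, max_charge + 1):
            ions.append(FragmentIon(
                kind=rule.kind, residues=counts, neutral_mass=neutral,
                charge=z, mz=_neg_mz(neutral, z, masses),
                provenance=rule.selector,
            ))
    if include_a_core:
        neutral = s.neutral_mass(masses) - A02_LOSS
        for z in range(1, max_charge + 1):
            ions.append(FragmentIon(
                kind="0,2A-core", residues=s.composition.as_tuple(),
                neutral_mass=neutral, charge=z,
                mz=_neg_mz(neutral, z, masses),
                provenance="reducing-end cross-ring",
            ))
    return ions


# --------------------------------------------------------------------------
# Peak matching
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakAnnotation:
    peak_index: int
    mz: float
    intensity: float
    ion: FragmentIon
    ppm_error: float


def match_peaks(
    spec: Spectrum,
    theoretical: Sequence[FragmentIon],
    tol_ppm: float = 20.0,
) -> list[PeakAnnotation]:
    """Greedily annotate each peak with its nearest theoretical ion within
    ``tol_ppm``; ties broken by smaller |ppm error| then ion-kind priority.

    Deterministic: peaks are processed in m/z order and each peak receives
    at most one annotation.  Several peaks may match the same ion (isotope
    pick-up is not modelled).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    prio = {k: i for i, k in enumerate(ION_KIND_PRIORITY)}
    out: list[PeakAnnotation] = []
    for idx, (mz, inten) in enumerate(spec.peaks):
        best = None
        for ion in theoretical:
            ppm = (mz - ion.mz) / ion.mz * 1e6
            if abs(ppm) > tol_ppm:
                continue
            key = (abs(ppm), prio.get(ion.kind, len(prio)), ion.mz)
            if best is None or key < best[0]:
                best = (key, ion, ppm)
        if best is not None:
            out.append(PeakAnnotation(idx, mz, inten, best[1], best[2]))
    return out


def infer_topology(annotations: Sequence[PeakAnnotation]) -> TopologyEvidence:
    """Read arm/bisecting/antennarity evidence off the matched diagnostic
    ions: any D-family match confirms the 6-arm assignment, D−221 reports
    a bisecting GlcNAc, E reports ≥3 antennae (and confirms the 3-arm)."""
    ev = TopologyEvidence()
    support: dict[str, list[int]] = {}
    for ann in annotations:
        kind = ann.ion.kind
        if kind in ("D", "D-18", "D-221"):
            ev.six_arm_confirmed = True
            support.setdefault("six_arm_confirmed", []).append(ann.peak_index)
        if kind == "D-221":
            ev.bisecting = True
            support.setdefault("bisecting", []).append(ann.peak_index)
        if kind == "E":
            ev.tri_antennary = True
            ev.three_arm_confirmed = True
            support.setdefault("tri_antennary", []).append(ann.peak_index)
            support.setdefault("three_arm_confirmed", []).append(ann.peak_index)
    ev.supporting_peaks = support
    return ev


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_mgf(path) -> list[Spectrum]:
    """Read spectra from an MGF file."""
    out = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params.get("pepmass", (0.0,))
            charge = params.get("charge", [1])
            z = abs(int(charge[0])) if charge else 1
            peaks = list(zip(
                (float(x) for x in entry["m/z array"]),
                (float(x) for x in entry["intensity array"]),
            ))
            out.append(Spectrum(
                precursor_mz=float(pepmass[0]), precursor_charge=z,
                peaks=peaks, title=str(params.get("title", "")),
            ))
    return out


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra to MGF (negative-mode charges)."""
    entries = []
    for i, s in enumerate(spectra):
        entries.append({
            "m/z array": [p[0] for p in s.peaks],
            "intensity array": [p[1] for p in s.peaks],
            "params": {
                "title": s.title or f"spectrum_{i}",
                "pepmass": s.precursor_mz,
                "charge": [-(s.precursor_charge)],
            },
        })
    _mgf.write(entries, str(path), file_mode="w")


def write_annotation_tsv(
    annotations: Sequence[PeakAnnotation], path
) -> None:
    with open(path, "w") as fh:
        fh.write("peak_mz\tintensity\tion_kind\tcharge\tppm_error\tresidues\n")
        for a in annotations:
            h, n, f, s = a.ion.residues
            fh.write(
                f"{a.mz:.6f}\t{a.intensity:.3f}\t{a.ion.kind}\t{a.ion.charge}"
                f"\t{a.ppm_error:.3f}\tH{h}N{n}F{f}S{s}\n"
            )
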