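"""Synthetic data generation for every pipeline stage.

Nothing here downloads anything: the generators emit glycan structure
libraries, per-sample peak-area cohorts with planted group effects and
confounders, toy negative-mode MS/MS spectra, and glycogene DE tables in
exactly the schemas the analysis modules read, always together with the
ground truth needed to score recovery (sensitivity, FDR, log2FC bias).

Libraries are grown biosynthetically: every structure is produced by a
single-residue addition (or mannose trimming) applied to a structure
already in the library, starting from the Man3GlcNAc2 core — so the
composition graph of any generated library is connected to H3N2 by
construction, mirroring the completeness of a real tissue glycome.

Cohorts emulate the study design this package targets: two groups of
autopsy samples (16 control / 18 infected by default), log-normal peak
areas with ~10% technical CV, group effects planted on selected glycan
classes (paucimannose down by default), and comorbidity/age/sex
confounders correlated with group membership.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .glycan_core import (
    FINE_CLASSES,
    GlycanStructure,
    ResidueNode,
    classify_structure,
    fine_to_coarse,
    _RESIDUE_CLASS,
)
from .fragment_annotation import (
    FragmentIon,
    Spectrum,
    diagnostic_ions,
    enumerate_glycosidic_fragments,
)

__all__ = [
    "TISSUE_CLASS_MIX",
    "CARDIOMYOCYTE_CLASS_MIX",
    "EffectSpec",
    "GroundTruth",
    "generate_library",
    "generate_cohort",
    "generate_spectrum",
    "generate_de_gene_table",
    "library_table",
]

#: Default fine-class abundance mixes emulating whole-tissue and isolated-
#: cardiomyocyte N-glycome profiles (complex-bi-dominated vs high-mannose-
#: dominated).
TISSUE_CLASS_MIX: dict[str, float] = {
    "complex-bi": 0.46, "high-mannose": 0.32, "paucimannose": 0.067,
    "hybrid": 0.046, "bisecting": 0.053, "complex-tri": 0.033,
    "complex-mono": 0.02, "complex-tetra": 0.002,
}
CARDIOMYOCYTE_CLASS_MIX: dict[str, float] = {
    "high-mannose": 0.72, "paucimannose": 0.11, "complex-bi": 0.082,
    "hybrid": 0.06, "complex-mono": 0.025, "bisecting": 0.01,
    "complex-tri": 0.006,
}


# --------------------------------------------------------------------------
# Structure construction
# --------------------------------------------------------------------------

def _man3_core() -> GlycanStructure:
    root = ResidueNode("GlcNAc")
    core = root.add(ResidueNode("GlcNAc", "core"))
    beta = core.add(ResidueNode("Man", "core"))
    beta.add(ResidueNode("Man", "3"))
    beta.add(ResidueNode("Man", "6"))
    return GlycanStructure(id="H3N2", root=root)


def _core_parts(s: GlycanStructure) -> dict:
    parts = s.core()
    assert parts is not None
    return parts


def _clone(s: GlycanStructure, new_id: str = "") -> GlycanStructure:
    return GlycanStructure(
        id=new_id or s.id, root=copy.deepcopy(s.root), reduced=s.reduced
    )


def _arm_mannoses(s: GlycanStructure, arm: str) -> list[ResidueNode]:
    arm = arm if arm.startswith("arm") else f"arm{arm}"
    node = _core_parts(s).get(arm)
    if node is None:
        return []
    return [n for n in node.walk() if _RESIDUE_CLASS.get(n.residue) == "hex"]


def _add_man(s: GlycanStructure, arm: str) -> Optional[GlycanStructure]:
    """Extend an arm with one mannose (attached to the arm mannose with
    the fewest hexose children, depth-first)."""
    out = _clone(s)
    cands = _arm_mannoses(out, arm) or _arm_mannoses(
        out, "3" if arm.endswith("6") else "6"
    )
    if not cands:
        return None
    cands.sort(key=lambda n: sum(
        1 for c in n.children if _RESIDUE_CLASS.get(c.residue) == "hex"
    ))
    cands[0].add(ResidueNode("Man"))
    return out

def _trim_man(s: GlycanStructure, rng: np.random.Generator) -> Optional[GlycanStructure]:
    """Remove one terminal arm mannose (paucimannose trimming); the leaf
    is chosen at random so trimmed isomers differ."""
    out = _clone(s)
    beta = _core_parts(out)["beta_man"]
    leaves = [
        (parent, child)
        for parent in beta.walk() for child in parent.children
        if _RESIDUE_CLASS.get(child.residue) == "hex" and not child.children
    ]
    if not leaves:
        return None
    parent, child = leaves[int(rng.integers(len(leaves)))]
    parent.children.remove(child)
    return out

def _add_antenna(s: GlycanStructure, arm: str) -> GlycanStructure:
    out = _clone(s)
    arm_node = _core_parts(out).get(arm)
    arm_node.add(ResidueNode("GlcNAc"))
    return out

def _cap_antenna(
    s: GlycanStructure, index: int, residue: str
) -> Optional[GlycanStructure]:
    """Cap antenna ``index`` (walk order) with Gal (LacNAc) or GalNAc
    (LacdiNAc) if still open."""
    out = _clone(s)
    ants = out.antennae()
    if index >= len(ants) or any(
        _RESIDUE_CLASS.get(c.residue) in ("hex", "hexnac")
        for c in ants[index].children
    ):
        return None
    ants[index].add(ResidueNode(residue))
    return out

def _add_sia(s: GlycanStructure, index: int) -> Optional[GlycanStructure]:
    """Sialylate the cap of antenna ``index``."""
    out = _clone(s)
    ants = out.antennae()
    if index >= len(ants):
        return None
    caps = [
        c for c in ants[index].children
        if _RESIDUE_CLASS.get(c.residue) in ("hex", "hexnac")
        and not any(ch.residue == "NeuAc" for ch in c.children)
    ]
    if not caps:
        return None
    caps[0].add(ResidueNode("NeuAc"))
    return out

def _extend_lacnac(
    s: GlycanStructure, index: int, step: str
) -> Optional[GlycanStructure]:
    """Poly-LacNAc growth on antenna ``index``: ``step='glcnac'`` adds a
    GlcNAc to the terminal unsialylated Gal, ``step='gal'`` caps the
    terminal bare GlcNAc of an existing repeat."""
    out = _clone(s)
    ants = out.antennae()
    if index >= len(ants):
        return None
    nodes = list(ants[index].walk())
    if step == "glcnac":
        targets = [n for n in nodes if n.residue == "Gal" and not n.children]
        child = "GlcNAc"
    else:
        targets = [n for n in nodes[1:] if n.residue == "GlcNAc" and not n.children]
        child = "Gal"
    if not targets:
        return None
    targets[-1].add(ResidueNode(child))
    return out


def _add_antenna_fuc(s: GlycanStructure, index: int) -> Optional[GlycanStructure]:
    """Terminal (Lewis-type) fucose on the antenna GlcNAc."""
    out = _clone(s)
    ants = out.antennae()
    if index >= len(ants) or any(c.residue == "Fuc" for c in ants[index].children):
        return None
    ants[index].add(ResidueNode("Fuc"))
    return out

def _add_core_fuc(s: GlycanStructure) -> Optional[GlycanStructure]:
    if s.core_fucose() is not None:
        return None
    out = _clone(s)
    out.root.add(ResidueNode("Fuc", "cf"))
    return GlycanStructure(id=out.id, root=out.root, reduced=out.reduced)

def _add_bisect(s: GlycanStructure) -> Optional[GlycanStructure]:
    if s.bisecting() is not None:
        return None
    out = _clone(s)
    _core_parts(out)["beta_man"].add(ResidueNode("GlcNAc", "bis"))
    return out


def _chain_to_class(
    target: str, rng: np.random.Generator
) -> list[GlycanStructure]:
    """A biosynthetic chain from the Man3GlcNAc2 core to one structure of
    the target fine class, one residue per step; every intermediate is a
    valid structure and is returned too."""
    chain = [_man3_core()]

    def push(s: Optional[GlycanStructure]) -> None:
        if s is not None:
            chain.append(s)

    if target == "paucimannose":
        steps = int(rng.integers(0, 3))          # trim toward Man2/Man1
        for _ in range(steps):
            push(_trim_man(chain[-1], rng))
        if rng.random() < 0.4:
            push(_add_core_fuc(chain[-1]))
    elif target == "high-mannose":
        extra = int(rng.integers(2, 8))           # Man5..Man10
        for _ in range(extra):                    # random arm -> isomers
            push(_add_man(chain[-1], str(rng.choice(["3", "6"]))))
        if rng.random() < 0.1:                    # core-fucosylated high mannose
            push(_add_core_fuc(chain[-1]))
    elif target == "hybrid":
        for _ in range(int(rng.integers(2, 4))):  # Man5/Man6-based hybrids
            push(_add_man(chain[-1], "6"))
        push(_add_antenna(chain[-1], "arm3"))
        if rng.random() < 0.7:
            push(_cap_antenna(chain[-1], 0, "Gal"))
            if rng.random() < 0.4:
                push(_add_sia(chain[-1], 0))
        if rng.random() < 0.2:
            push(_add_core_fuc(chain[-1]))
    else:
        n_ant = {"complex-mono": 1, "complex-bi": 2, "bisecting": 2,
                 "complex-tri": 3, "complex-tetra": 4}[target]
        if n_ant == 1:
            arm_seq = [str(rng.choice(["arm3", "arm6"]))]
        elif n_ant == 2:
            arm_seq = ["arm3", "arm6"]
        elif n_ant == 3:
            arm_seq = ["arm3", "arm6", str(rng.choice(["arm3", "arm6"]))]
        else:
            arm_seq = ["arm3", "arm6", "arm3", "arm6"]
        for arm in arm_seq:
            push(_add_antenna(chain[-1], arm))
        for idx in range(n_ant):                  # per-antenna decoration
            if rng.random() < 0.15:
                continue                          # agalactosylated antenna
            cap = "GalNAc" if rng.random() < 0.15 else "Gal"
            push(_cap_antenna(chain[-1], idx, cap))
            if cap == "Gal" and rng.random() < 0.12:  # poly-LacNAc repeat
                push(_extend_lacnac(chain[-1], idx, "glcnac"))
                push(_extend_lacnac(chain[-1], idx, "gal"))
            if rng.random() < 0.5:
                push(_add_sia(chain[-1], idx))
            if rng.random() < 0.08:               # Lewis-type fucose
                push(_add_antenna_fuc(chain[-1], idx))
        if rng.random() < 0.35:
            push(_add_core_fuc(chain[-1]))
        if target == "bisecting":
            push(_add_bisect(chain[-1]))
    return chain


#: Minimum library size needed to realise a chain to each class.
_MIN_CHAIN = {
    "paucimannose": 1, "high-mannose": 3, "hybrid": 4, "complex-mono": 2,
    "complex-bi": 3, "bisecting": 4, "complex-tri": 4, "complex-tetra": 5,
}


def generate_library(
    n: int,
    class_mix: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Grow a biosynthetically coherent library of ``n`` structures.

    ``class_mix`` (default: the whole-tissue profile) sets both the target
    fine-class proportions of the library and, downstream, the abundance
    calibration of :func:`generate_cohort`.  Chains of single-residue
    additions from the Man3GlcNAc2 core guarantee that every composition
    in the library connects to H3N2 in the composition graph.

    Returns the standard library table (glycan_id, composition,
    fine_class, structure, theoretical_mz, charge, rrt, glytoucan_id)
    with the class mix stored in ``df.attrs["class_mix"]``.
    """
    mix = dict(class_mix or TISSUE_CLASS_MIX)
    bad = set(mix) - set(FINE_CLASSES)
    if bad:
        raise ValueError(f"unknown fine classes in mix: {sorted(bad)}")
    tot = sum(mix.values())
    if not np.isclose(tot, 1.0, atol=0.05):
        raise ValueError(f"class_mix proportions must sum to 1, got {tot}")
    mix = {k: v / tot for k, v in mix.items()}
    if n < 5:
        raise ValueError("library size n must be >= 5")
    infeasible = [c for c, w in mix.items() if w > 0 and _MIN_CHAIN[c] > n]
    if infeasible:
        raise ValueError(f"class mix infeasible at n={n}: {infeasible}")

    rng = np.random.default_rng(seed)
    structures: dict[str, GlycanStructure] = {}
    class_counts = {c: 0 for c in mix}

    def admit(s: GlycanStructure) -> None:
        key = s.serialize()
        if key in structures or len(structures) >= n:
            return
        structures[key] = s
        fine = classify_structure(s).fine
        if fine in class_counts:
            class_counts[fine] += 1

    guard = 0
    failures = {c: 0 for c in mix}
    while len(structures) < n and guard < 200 * n:
        guard += 1
        # relative deficit so rare classes are realised before bulk ones;
        # classes whose structure space is exhausted are penalised so the
        # remaining slots go to classes that can still grow
        deficit = {
            c: 1.0 - class_counts[c] / (mix[c] * n) - 0.05 * failures[c]
            for c in mix if mix[c] > 0
        }
        target = max(deficit, key=lambda c: (deficit[c], c))
        before = len(structures)
        for s in _chain_to_class(target, rng):
            admit(s)
        if len(structures) == before:
            failures[target] += 1
        else:
            failures[target] = 0
    if len(structures) < n:
        raise RuntimeError("library growth stalled; relax the class mix")

    rows = []
    rrt = 0.0
    for i, s in enumerate(structures.values(), 1):
        comp = s.composition
        label = classify_structure(s)
        rrt = comp.total + rng.uniform(-0.3, 0.3)   # crude PGC-like ordering
        rows.append({
            "glycan_id": f"G{i:04d}",
            "composition": str(comp),
            "fine_class": label.fine,
            "structure": s.serialize(),
            "theoretical_mz": round(s.mz(2), 4),
            "charge": 2,
            "rrt": round(rrt, 3),
            "glytoucan_id": f"GSYN{i:04d}",
        })
    df = pd.DataFrame(rows)
    df.attrs["class_mix"] = mix
    return df


def library_table(df: pd.DataFrame) -> list[GlycanStructure]:
    """Materialise GlycanStructure objects from a library table."""
    from .glycan_core import parse_structure

    return [
        parse_structure(row.structure, id=row.glycan_id)
        for row in df.itertuples()
    ]


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

#: Comorbidity prevalences (negative, positive) emulating an autopsy
#: cohort in which cardiovascular history is unevenly distributed across
#: groups.
DEFAULT_COMORBIDITY_PREVALENCE: dict[str, tuple[float, float]] = {
    "hypertension": (9 / 16, 12 / 18),
    "cardiovascular_disease": (9 / 16, 4 / 18),
    "type2_diabetes": (3 / 16, 6 / 18),
    "copd": (4 / 16, 3 / 18),
}


@dataclass
class EffectSpec:
    """Planted effects and study conditions for a synthetic cohort.

    ``target_fine_classes`` selects the glycans carrying the group effect
    ``log2fc`` (alternatively give explicit ``target_glycan_ids``).
    Covariate effects are additive on the log2-abundance scale and apply
    to the same target glycans, which is what makes an imbalanced
    comorbidity a genuine confounder of the group contrast.
    """

    target_fine_classes: tuple[str, ...] = ("paucimannose",)
    target_glycan_ids: Optional[tuple[str, ...]] = None
    log2fc: float = -1.0
    age_slope: float = 0.0              # log2 units per year (centred age)
    sex_offset: float = 0.0             # log2 units added for male samples
    comorbidity_effects: Mapping[str, float] = field(default_factory=dict)
    comorbidity_prevalence: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE)
    )
    cv: float = 0.10                    # technical coefficient of variation
    n_negative: int = 16
    n_positive: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.n_negative < 2 or self.n_positive < 2:
            raise ValueError("group sizes must be >= 2")


@dataclass
class GroundTruth:
    """Everything needed to score recovery without reading generator
    internals."""

    true_log2fc: pd.Series          # per glycan
    baseline_weight: pd.Series      # per glycan expected share of signal
    classes: pd.Series              # glycan -> fine class
    covariates: pd.DataFrame        # per sample
    spec: EffectSpec


def generate_cohort(
    library: pd.DataFrame, spec: EffectSpec
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a two-group peak-area cohort over a generated library.

    Baseline glycan abundances follow the library's class mix (log-normal
    split within class, giving the wide per-glycan dynamic range real
    glycomes show), the group effect multiplies target glycans by
    2**log2fc, covariate effects enter additively on the log2 scale, and
    multiplicative log-normal noise is calibrated to the technical CV.

    Returns (PeakAreaMatrix glycans × samples, SampleMetadata,
    GroundTruth).
    """
    rng = np.random.default_rng(spec.seed)
    glycans = library["glycan_id"].tolist()
    classes = pd.Series(library["fine_class"].values, index=glycans)
    mix = library.attrs.get("class_mix")
    if mix is None:
        counts = classes.value_counts(normalize=True)
        mix = counts.to_dict()

    # baseline expected relative share per glycan
    weight = pd.Series(0.0, index=glycans)
    for cls, w in mix.items():
        members = classes.index[classes == cls]
        if len(members) == 0:
            continue
        raw = np.exp(rng.normal(0.0, 1.0, len(members)))  # wide dynamic range
        weight.loc[members] = w * raw / raw.sum()
    orphan = weight.index[weight == 0]
    if len(orphan):                      # classes grown but absent from mix
        weight.loc[orphan] = weight[weight > 0].min() / 10.0
    weight /= weight.sum()

    # target selection
    if spec.target_glycan_ids is not None:
        targets = [g for g in glycans if g in set(spec.target_glycan_ids)]
    else:
        targets = list(classes.index[classes.isin(spec.target_fine_classes)])
    if not targets:
        raise ValueError("effect selector matches no glycans in the library")
    true_lfc = pd.Series(0.0, index=glycans)
    true_lfc.loc[targets] = spec.log2fc

    # samples and covariates
    n = spec.n_negative + spec.n_positive
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    group = np.array(["negative"] * spec.n_negative
                     + ["positive"] * spec.n_positive)
    age = np.where(
        group == "negative",
        rng.normal(63.0, 10.0, n), rng.normal(66.0, 10.0, n),
    ).round(0).clip(30, 95)
    p_male = np.where(group == "negative", 10 / 16, 13 / 18)
    sex = np.where(rng.random(n) < p_male, "M", "F")
    meta = pd.DataFrame({
        "sample_id": sample_ids, "group": group,
        "age": age, "sex": sex, "region": "LV",
    }).set_index("sample_id", drop=False)
    for name, (p_neg, p_pos) in spec.comorbidity_prevalence.items():
        p = np.where(group == "negative", p_neg, p_pos)
        meta[name] = (rng.random(n) < p).astype(int)

    # log2 abundance model
    log2_mu = np.log2(weight.values)[:, None] * np.ones((1, n))
    is_target = np.isin(glycans, targets)[:, None]
    log2_mu += is_target * (
        spec.log2fc * (group == "positive")[None, :]
        + spec.age_slope * (age - age.mean())[None, :]
        + spec.sex_offset * (sex == "M")[None, :]
    )
    for name, eff in spec.comorbidity_effects.items():
        log2_mu += is_target * eff * meta[name].values[None, :]
    sigma_ln = np.sqrt(np.log1p(spec.cv ** 2))
    noise = rng.normal(0.0, sigma_ln, size=log2_mu.shape)
    areas = 1e6 * np.exp2(log2_mu) * np.exp(noise)

    area_df = pd.DataFrame(areas, index=glycans, columns=sample_ids)
    truth = GroundTruth(
        true_log2fc=true_lfc, baseline_weight=weight,
        classes=classes, covariates=meta.copy(), spec=spec,
    )
    return area_df, meta, truth


# --------------------------------------------------------------------------
# Spectra
# --------------------------------------------------------------------------

def generate_spectrum(
    structure: GlycanStructure,
    jitter_ppm: float = 5.0,
    n_noise: int = 10,
    seed: int = 0,
    max_charge: int = 1,
) -> tuple[Spectrum, list[Optional[FragmentIon]]]:
    """Theoretical fragment spectrum with Gaussian ppm jitter plus uniform
    noise peaks.

    Returns the spectrum and the ground-truth annotation: element i is the
    FragmentIon behind peak i, or None for a noise peak.
    """
    if jitter_ppm < 0:
        raise ValueError("jitter_ppm must be >= 0")
    rng = np.random.default_rng(seed)
    ions = enumerate_glycosidic_fragments(structure, max_charge=max_charge)
    try:
        ions += diagnostic_ions(structure, max_charge=max_charge)
    except Exception:
        pass                                       # trimmed cores: glycosidic only
    # deduplicate identical m/z targets (keep first by priority order)
    seen: dict[float, FragmentIon] = {}
    for ion in ions:
        key = round(ion.mz, 6)
        seen.setdefault(key, ion)
    peaks: list[tuple[float, float]] = []
    truth: list[Optional[FragmentIon]] = []
    for ion in seen.values():
        mz = ion.mz * (1.0 + rng.normal(0.0, jitter_ppm) * 1e-6)
        peaks.append((mz, float(rng.lognormal(4.0, 0.5))))
        truth.append(ion)
    if peaks:
        lo, hi = min(p[0] for p in peaks), max(p[0] for p in peaks)
    else:
        lo, hi = 100.0, 2000.0
    for _ in range(n_noise):
        peaks.append((float(rng.uniform(lo, hi)),
                      float(rng.lognormal(2.0, 0.5))))
        truth.append(None)
    order = np.argsort([p[0] for p in peaks], kind="stable")
    spec = Spectrum(
        precursor_mz=structure.mz(2), precursor_charge=2,
        peaks=[peaks[i] for i in order], title=structure.id,
    )
    return spec, [truth[i] for i in order]


# --------------------------------------------------------------------------
# Glycogene DE tables
# --------------------------------------------------------------------------

def generate_de_gene_table(
    ref: pd.DataFrame,
    n_significant: Mapping[str, int],
    cell_types: Sequence[str] = ("cardiomyocytes", "endothelial", "fibroblast"),
    regions: Sequence[str] = ("LV", "RV"),
    n_background: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant significant glycogene DE calls per pathway.

    ``n_significant`` maps pathway -> number of significant genes planted
    in *each* (cell type, region) stratum; ``n_background`` non-
    significant rows per stratum are added.  Returns (DEGeneTable,
    ground-truth table of planted significant rows).
    """
    rng = np.random.default_rng(seed)
    bad = set(n_significant) - set(ref["pathway"])
    if bad:
        raise ValueError(f"pathways not in reference: {sorted(bad)}")
    rows, truth_rows = [], []
    for ct in cell_types:
        for rg in regions:
            for pathway, k in n_significant.items():
                pool = ref.loc[ref["pathway"] == pathway, "gene"].tolist()
                if k > len(pool):
                    raise ValueError(
                        f"{pathway}: requested {k} > {len(pool)} genes"
                    )
                genes = rng.choice(pool, size=k, replace=False)
                for g in genes:
                    lfc = float(rng.uniform(1.2, 3.0) * rng.choice([-1, 1]))
                    row = {"gene": g, "cell_type": ct, "region": rg,
                           "log2FC": lfc,
                           "adj_p": float(rng.uniform(1e-6, 0.049))}
                    rows.append(row)
                    truth_rows.append(dict(row, pathway=pathway))
            bg = rng.choice(ref["gene"], size=n_background, replace=False)
            planted = {r["gene"] for r in rows
                       if r["cell_type"] == ct and r["region"] == rg}
            for g in bg:
                if g in planted:
                    continue
                rows.append({
                    "gene": g, "cell_type": ct, "region": rg,
                    "log2FC": float(rng.uniform(-0.9, 0.9)),
                    "adj_p": float(rng.uniform(0.05, 1.0)),
                })
    de = pd.DataFrame(rows, columns=["gene", "cell_type", "region",
                                     "log2FC", "adj_p"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "cell_type", "region", "log2FC", "adj_p", "pathway"],
    )
    return de, truth
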