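"""Composition notation, mass arithmetic and class taxonomy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import glycardio as gc
from glycardio.glycan_core import (
    MASSES,
    CompositionError,
    GlycanComposition,
    StructureError,
    UNCLASSIFIED,
    classify_composition,
    classify_structure,
    class_distribution,
    composition_property,
    parse_composition,
    parse_structure,
)

compositions = st.builds(
    GlycanComposition,
    hex=st.integers(0, 12), hexnac=st.integers(0, 8),
    fuc=st.integers(0, 4), neuac=st.integers(0, 4),
)


# -- parsing ----------------------------------------------------------------

@pytest.mark.parametrize("text,expected", [
    ("H5N4F1S2", (5, 4, 1, 2)),
    ("H3N2", (3, 2, 0, 0)),
    ("N2H3", (3, 2, 0, 0)),           # order-insensitive
    ("H5N4A2", (5, 4, 0, 2)),         # 'A' accepted for NeuAc
    ("F1", (0, 0, 1, 0)),
])
def test_parse_composition(text, expected):
    assert parse_composition(text).as_tuple() == expected


@pytest.mark.parametrize("bad", ["H5X1", "H5H2", "H", "5N2", "H-1N2", "H2.5"])
def test_parse_rejects_malformed(bad):
    with pytest.raises(CompositionError):
        parse_composition(bad)


@given(compositions)
@settings(max_examples=200, deadline=None)
def test_parse_format_round_trip(comp):
    assert parse_composition(comp.format()) == comp


def test_canonical_format_omits_zeros():
    assert parse_composition("H7N6F1S1").format() == "H7N6F1S1"
    assert str(GlycanComposition(3, 2)) == "H3N2"


# -- masses -----------------------------------------------------------------

def test_neutral_mass_reduced_fucosylated_man6():
    comp = parse_composition("H6N2F1")
    assert comp.neutral_mass(reduced=True) == pytest.approx(1544.5598, abs=1e-4)


def test_neutral_mass_edge_cases():
    assert GlycanComposition().neutral_mass(reduced=False) == pytest.approx(
        MASSES.water)
    assert parse_composition("H2N2").neutral_mass(True) == pytest.approx(
        750.2906, abs=1e-4)


def test_negative_mode_mz():
    assert parse_composition("H6N2F1").mz(2) == pytest.approx(771.2726, abs=1e-4)
    assert round(parse_composition("H6N2F1").mz(2)) == 771
    assert parse_composition("H2N2").mz(1) == pytest.approx(749.2833, abs=1e-4)


@given(compositions.filter(lambda c: c.total > 0), st.integers(1, 4))
@settings(max_examples=100, deadline=None)
def test_mz_charge_identity(comp, z):
    """m/z·z + z·proton recovers the neutral mass for every charge."""
    assert comp.mz(z) * z + z * MASSES.proton == pytest.approx(
        comp.neutral_mass(True), abs=1e-9)


def test_mz_requires_positive_charge():
    with pytest.raises(ValueError):
        parse_composition("H3N2").mz(0)


@given(compositions, compositions)
@settings(max_examples=100, deadline=None)
def test_mass_additivity_glycosidic_condensation(a, b):
    combined = (a + b).neutral_mass(reduced=False)
    assert combined == pytest.approx(
        a.neutral_mass(False) + b.neutral_mass(False) - MASSES.water, abs=1e-9)


# -- composition classification ---------------------------------------------

PAUCI = ["H1N2", "H4N2", "H4N2F1"]
OLIGO = ["H5N2", "H5N2F1", "H10N2"]
COMPLEX = ["H4N3S1", "H3N4S1", "H4N4S1", "H3N5F1", "H6N3S1", "H5N3F1S1",
           "H4N4F1S1", "H3N5F1S1", "H6N3F1S1", "H5N5S1", "H4N5F1S1",
           "H3N6F1S1", "H5N4F1S2", "H6N5F1S1"]


@pytest.mark.parametrize("text,expected", (
    [(t, "paucimannose") for t in PAUCI]
    + [(t, "oligomannose") for t in OLIGO]
    + [(t, "processed") for t in COMPLEX]
    + [("H5N1", UNCLASSIFIED), ("H5N2S1", UNCLASSIFIED)]
))
def test_classify_composition(text, expected):
    assert classify_composition(parse_composition(text)) == expected


@given(compositions)
@settings(max_examples=300, deadline=None)
def test_classification_is_a_partition(comp):
    assert classify_composition(comp) in (
        "paucimannose", "oligomannose", "processed", UNCLASSIFIED)


# -- structure classification -----------------------------------------------

CORE = "GlcNAc(GlcNAc(Man(Man[3])(Man[6])))"
BIANT_DIGAL = ("GlcNAc(GlcNAc(Man(Man[3](GlcNAc(Gal)))"
               "(Man[6](GlcNAc(Gal)))))")
BIANT_BISECT = ("GlcNAc(GlcNAc(Man(Man[3](GlcNAc(Gal)))"
                "(Man[6](GlcNAc(Gal)))(GlcNAc[bis])))")
MAN5_HYBRID = ("GlcNAc(GlcNAc(Man(Man[3](GlcNAc(Gal)))"
               "(Man[6](Man)(Man))))")


@pytest.mark.parametrize("serial,fine", [
    (CORE, "paucimannose"),
    (BIANT_DIGAL, "complex-bi"),
    (BIANT_BISECT, "bisecting"),         # bisecting pre-empts antenna count
    (MAN5_HYBRID, "hybrid"),
])
def test_classify_structure(serial, fine):
    assert classify_structure(parse_structure(serial)).fine == fine


def test_structure_motifs_and_roundtrip():
    s = parse_structure(BIANT_BISECT)
    assert parse_structure(s.serialize()).composition == s.composition
    lacdinac = BIANT_DIGAL.replace("GlcNAc(Gal)", "GlcNAc(GalNAc)", 1)
    label = classify_structure(parse_structure(lacdinac))
    assert "LacdiNAc" in label.motifs and "LacNAc" in label.motifs


def test_structure_invariants_enforced():
    with pytest.raises(StructureError):
        parse_structure("Man(GlcNAc)")           # root must be HexNAc
    with pytest.raises(StructureError):
        parse_structure(CORE.replace(
            "(Man[6])", "(Man[6])(GlcNAc[bis])(GlcNAc[bis])"))


def test_structure_and_composition_classes_agree(small_structures):
    """Structure-level coarse class matches the counts-only rule."""
    for s in small_structures:
        coarse_comp = classify_composition(s.composition)
        if coarse_comp != UNCLASSIFIED:
            assert classify_structure(s).coarse == coarse_comp


# -- property buckets and class distribution --------------------------------

@pytest.mark.parametrize("text,expected", [
    ("H7N6F1S1", "fuco-sialylated"),
    ("H6N4F1", "fuco"),
    ("H5N2", "oligomannose/paucimannose"),
    ("H5N4S2", "sialylated"),
    ("H5N4", "neutral"),
])
def test_composition_property(text, expected):
    assert composition_property(parse_composition(text)) == expected


def test_class_distribution_simple_cases():
    rel = pd.DataFrame({"s1": [60.0, 40.0], "s2": [50.0, 50.0]},
                       index=["g1", "g2"])
    one_class = class_distribution(rel, {"g1": "high-mannose",
                                         "g2": "high-mannose"})
    assert one_class["high-mannose"] == pytest.approx(100.0)
    two = class_distribution(rel, {"g1": "high-mannose", "g2": "complex-bi"})
    assert two["high-mannose"] == pytest.approx(55.0)
    assert two.sum() == pytest.approx(100.0)
    with pytest.raises(KeyError):
        class_distribution(rel, {"g1": "high-mannose"})


def test_class_distribution_recovers_generator_mix(cm_library):
    """High-mannose-dominated profile is recovered from a null cohort."""
    from glycardio import synthetic_data as sd

    spec = sd.EffectSpec(log2fc=0.0, seed=5)
    areas, _, _ = sd.generate_cohort(cm_library, spec)
    rel = gc.relative_abundance(areas)
    classes = dict(zip(cm_library["glycan_id"], cm_library["fine_class"]))
    dist = class_distribution(rel, classes)
    assert dist.sum() == pytest.approx(100.0, abs=1e-9)
    mix = cm_library.attrs["class_mix"]
    assert dist["high-mannose"] == pytest.approx(100 * mix["high-mannose"], abs=5)
    assert dist["paucimannose"] == pytest.approx(100 * mix["paucimannose"], abs=4)
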