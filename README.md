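# glycardio

A cardiac N-glycomics analysis pipeline for comparing the N-glycome of
heart tissue and isolated cardiomyocytes between patient groups. It is
written for glycomics and clinical-proteomics analysts who have exported
per-glycan peak areas from an LC-MS workflow (PGC chromatography of
reduced glycan alditols, negative-mode detection) and want a tested,
scriptable route from peak areas to class profiles, composition graphs,
MS/MS structural evidence, and differential-abundance statistics that
hold up under confounding — plus a glycogene pathway-profiling stage for
published single-nucleus RNA-seq differential-expression tables.

## What it computes

**Mass and notation.** Glycan compositions `H{h}N{n}F{f}S{s}` (Hex,
HexNAc, Fuc, NeuAc) with monoisotopic masses for reduced (alditol)
glycans and deprotonated negative-mode ions, m/z = (M − z·1.00728)/z.

**Classes.** Composition-level (paucimannose / oligomannose / processed:
HexNAc₂ with Hex ≤ 4, HexNAc₂ with Hex 5–12, HexNAc ≥ 3) and
structure-level (paucimannose, high-mannose, hybrid, complex-mono/bi/
tri/tetra-antennary, bisecting, with core/terminal motif flags), plus
relative-abundance class distributions.

**Composition graph.** Observed compositions as nodes, edges between
compositions differing by one monosaccharide — a biosynthetic
completeness check and a library-overlap display (shared / A-only /
B-only node colouring), with GraphML/TSV exports.

**MS/MS annotation.** Theoretical B/C/Y/Z ions for every glycosidic
cleavage (complementary pairs conserve the precursor mass: B + Y =
C + Z = M) and the negative-mode diagnostic ions — D (6-arm + β-Man),
D−18, D−221 (bisecting GlcNAc), E (tri-antennary) and a configurable
0,2A cross-ring rule — matched greedily to peak lists within a ppm
tolerance and read out as arm/bisecting/antennarity evidence.

**Differential abundance.** Relative abundance (% of total per sample)
→ median normalization → log2 → per-glycan linear models. The
univariate test uses an empirical-Bayes **moderated t**: per-glycan
variances s²_g are shrunk toward a prior estimated from the moments of
log s²,

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),   t̃_g = β̂_g / (SE_g·s̃_g),

referred to t with d₀ + d degrees of freedom (the implementation agrees
with Bioconductor limma to 1e-10 in the test suite). The multivariate
model adds age, sex and comorbidity indicators so the group coefficient
is the confounder-adjusted log2FC. Benjamini–Hochberg step-up FDR is
reported alongside raw p-values.

**Glycogene profiling.** Filters DE tables at |log2FC| > 1 and adjusted
p < 0.05 against a 950-gene / 19-pathway glycogene reference and
computes each pathway's percentage contribution per cell type and
ventricular region (the bundled reference is a synthetic stand-in; pass
your own export for real analyses).

**Synthetic data.** Generators for biosynthetically coherent glycan
libraries (every composition connected to the H3N2 core), two-group
cohorts with planted effects, correlated confounders and 10% technical
CV, fragment spectra with ppm jitter, and DE gene tables — each with
ground truth for scoring recovery.

## Worked example

```python
import glycardio as gc
from glycardio import synthetic_data as sd

# the printed m/z of core-fucosylated Man6 (reduced, doubly deprotonated)
comp = gc.parse_composition("H6N2F1")
comp.neutral_mass(reduced=True)   # 1544.5598 Da
comp.mz(charge=2)                 # 771.2726  -> nominal m/z 771

# a study-scale synthetic cohort: 155 glycans, 16 vs 18 samples,
# paucimannose glycans planted one log2 unit down
lib = sd.generate_library(155, sd.TISSUE_CLASS_MIX, seed=42)
areas, meta, truth = sd.generate_cohort(lib, sd.EffectSpec(seed=7))

rel  = gc.relative_abundance(areas)          # columns sum to 100
logm = gc.median_normalize_log(rel)          # per-sample median log2 = 0
mod  = gc.empirical_bayes_moderation(
    gc.fit_linear_models(logm, gc.build_design(meta)))
tab  = gc.differential_table(mod, dict(zip(lib.glycan_id, lib.fine_class)))
print(tab.head(3)[["glycan_id", "fine_class", "log2FC", "q"]])
```

prints

```
glycan_id   fine_class    log2FC             q
    G0061 paucimannose -1.025441  5.732375e-76
    G0134 paucimannose -0.977306  1.035571e-70
    G0092 paucimannose -0.967920  3.198781e-69
```

The top hits are the planted paucimannose glycans with estimated log2FC
near the true −1 (the ~0.05 upward pull is compositional closure: when
one class drops, every other glycan's *relative* abundance inflates
slightly). In this run 18 of 155 glycans pass q < 0.05, and the class
distribution computed from the same cohort recovers the tissue profile
used to calibrate it (46.8% complex-bi, 32.6% high-mannose, …).

The same pipeline is available from the shell:

```bash
glycardio simulate --outdir demo --n-glycans 60 --seed 3
glycardio diff demo/areas.csv demo/metadata.csv demo/library.csv --outdir out
glycardio annotate demo/spectra.mgf demo/library.csv --outdir out
glycardio glycogenes demo/de_genes.csv --outdir out
```

Every output directory contains `run_config.json` (resolved settings,
config hash, seed); reruns with identical configs are byte-identical.

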