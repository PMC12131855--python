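# Methods

`glycardio` implements a cardiac N-glycomics analysis as a tested,
reusable pipeline: glycan composition algebra and monoisotopic mass
computation for reduced (alditol) N-glycans, a class taxonomy at
composition and structure level, a composition relatedness graph for
library comparison, negative-mode MS/MS diagnostic-ion annotation,
relative-abundance quantification, univariate and confounder-adjusted
differential abundance with empirical-Bayes moderated statistics and
Benjamini–Hochberg FDR, and a glycogene pathway-profiling stage for
published single-nucleus RNA-seq differential-expression tables. A
synthetic-data module generates inputs for every stage together with the
ground truth needed to score recovery.

## Mass model

Compositions are monosaccharide counts over Hex (H), HexNAc (N),
deoxyhexose/Fuc (F) and NeuAc (S), written canonically as
`H{h}N{n}F{f}S{s}` with zero counts omitted (`A` is accepted for NeuAc on
input). All masses are monoisotopic and derive from a single frozen
residue table (Hex 162.052824, HexNAc 203.079373, dHex 146.057909, NeuAc
291.095417 Da; water 18.010565, proton 1.007276). A free glycan adds one
water; PNGase-released glycans reduced to alditols add a further
2.015650 Da (+2H). Negative-mode ions are deprotonated:
m/z = (M − z·1.007276)/z. Example: reduced Hex6HexNAc2Fuc1
(core-fucosylated Man6) has M = 1544.5598 Da and [M−2H]²⁻ at m/z
771.2726, nominal 771. Average masses are out of scope.

## Class taxonomy

Composition level (counts only): HexNAc2 backbones with 1–4 Hex and no
sialic acid are **paucimannose**; HexNAc2 with 5–12 Hex are
**oligomannose**; HexNAc ≥ 3 is **processed**. Everything else (HexNAc <
2, sialylated HexNAc2, Hex out of range) returns an `unclassified`
sentinel rather than a guess. The paucimannose Hex bound of 4 follows the
treatment of Man4 structures as paucimannose isomers in cardiac work;
some literature caps paucimannose at Man3, so the bound is a keyword
argument. The oligomannose upper bound of 12 leaves room for
glucosylated precursors; it too is configurable. Fucosylated variants
stay in class — core-fucosylated high mannose (e.g. Man6Fuc) is a real,
if uncommon, species in heart tissue.

Structure level: glycans are rooted trees (root = reducing-end GlcNAc)
with arm tags `3`/`6` on the core mannoses, `bis` for a bisecting GlcNAc
on the β-mannose, `cf` for core fucose on the root, serialized as nested
parentheses (`GlcNAc(GlcNAc(Man(Man[3])(Man[6])))` is the trimannosyl
core). The antenna count is the number of HexNAc-initiated branches on
core-arm mannoses (bisecting excluded; HexNAc caps such as LacdiNAc
GalNAc do not count because antennae initiate on mannoses). Fine classes:
no antennae → paucimannose/high-mannose by Hex count; a bisecting GlcNAc
pre-empts antenna-count classes (a pie-chart convention: each structure
gets exactly one label); one arm with antennae while the other is
all-mannose **and still extended (≥ 2 hexoses)** → hybrid; otherwise
complex-mono/bi/tri/tetra by antenna count. The extension requirement in
the hybrid rule is deliberate: without it every mono-antennary structure
on an intact Man3 core would be "hybrid" and the complex-mono class would
be unreachable, contradicting how these classes are tallied in practice.
Motif flags (core-fucose, terminal-fucose, LacNAc, LacdiNAc, sialylated)
are read off the tree.

Composition property buckets mirror qualitative profile plots: HexNAc2
backbones → `oligomannose/paucimannose`; otherwise
`fuco-sialylated`/`fuco`/`sialylated` by decoration, else `neutral`.

## Composition graph

Unique compositions are nodes; an undirected edge joins two nodes whose
H/N/F/S counts differ by exactly one residue (Manhattan distance 1).
Because biosynthesis adds or removes one monosaccharide at a time,
connectedness of this graph is a completeness check on a library. Only
observed compositions become nodes (no inferred "virtual" intermediates).
Node attributes carry library membership (A-only/B-only/both) and the
property bucket; exports are GraphML, a sorted TSV edge list, and a node
attribute table. Construction is brute-force O(n²), which is exact and
ample at library scale (10²).

## Negative-mode fragment rules

For each glycosidic cleavage the package emits B (Σ non-reducing residue
masses), C (B + water), Y (Σ reducing-side residues + water + alditol)
and Z (Y − water), so each complementary pair reassembles the precursor:
B + Y = C + Z = M. Diagnostic double-cleavage ions follow a configurable
rule table:

- **D**: retains the 6-arm antennae + 6-linked core Man + β-Man (the
  bisecting GlcNAc, when present, is not part of the retained set).
- **D−18**: D after water loss.
- **D−221**: emitted only when a bisecting GlcNAc exists; offset
  −221.0899 Da (HexNAc residue + water) from D — the classic bisecting
  diagnostic.
- **E**: emitted for ≥ 3 antennae. Conventions for the E ion's residue
  inclusion differ between laboratories, so it is a rule-table entry; the
  default retains the 3-arm antennae + 3-linked core Man + β-Man (the
  3-arm counterpart of D, where the third antenna sits in most mammalian
  N-glycans). Users can override the selector/offset.
- **0,2A-core**: a single cross-ring rule on the reducing-end GlcNAc-ol,
  default neutral loss 103.0633 Da (C1–C2 with the N-acetyl, C4H9NO2);
  full A/X enumeration is out of scope.

Peak matching is greedy nearest-match within a ppm tolerance (default
20 ppm for MS/MS; the 15 ppm figure used for MS1 peak integration is a
precursor-level setting), each peak annotated by at most one ion, ties
broken by smaller |ppm| then by ion-kind priority (B, C, Y, Z, D, …).
Topology evidence is a direct readout: any D-family match confirms the
6-arm assignment, D−221 reports bisecting, E reports tri-antennarity;
every set flag cites its supporting peak indices.

## Quantification and normalization

Relative abundance = peak area / total area per sample × 100 (columns
sum to 100; scale-invariant and idempotent). Before log transformation,
zeros/missing values are imputed (policy switch): the default is
half-minimum per glycan (half the glycan's smallest positive value across
samples, falling back to half the matrix-wide minimum positive value when
a glycan has none), preserving matrix shape for the linear models;
`pseudocount` and `drop` are alternatives. Median normalization is
applied on the log2 scale — each sample's median log2 value is
subtracted. For an odd number of glycans this is identical to dividing by
the median abundance first; for an even number it is the variant that
makes the per-sample median exactly zero (the arithmetic even-n median
does not commute with the logarithm). Either order yields identical test
statistics for location-shift models. Control-analyte %CV (100·sd/mean,
sample sd) monitors technical quality, flagging analytes at ≥ 10% by
default, matching the dextran-ladder column-stability criterion of the
LC-MS workflow this mirrors.

## Differential abundance

Per glycan, ordinary least squares of log2 normalized abundance on a
design with intercept and group indicator (positive = 1); the group
coefficient is the log2 fold change (exactly the group-mean difference in
the unadjusted two-group case). The multivariate analysis adds
confounders: age (years), sex (indicator `sex_M`), and binary comorbidity
flags (hypertension, cardiovascular disease, type 2 diabetes, COPD by
default — the encoding is configurable since cohort tables typically
report these as separate rows). Rank deficiency is an error naming the
collinear columns.

The univariate test uses empirical-Bayes variance moderation: per-glycan
s²_g (d residual df) are modelled as draws from a scaled F distribution
with hyperparameters (d0, s0²) estimated by matching the first two
moments of log s² (digamma/trigamma inversion; Newton iteration for the
trigamma inverse). Posterior variance s̃²_g = (d0·s0² + d·s²_g)/(d0 + d)
replaces s²_g in the t statistic, referred to t with d0 + d df. Edge
cases: d0 = 0 reproduces the ordinary t exactly; when log s² shows no
excess dispersion the prior df is infinite and every posterior variance
equals the pooled arithmetic-mean variance (normal reference
distribution). The implementation is cross-checked against Bioconductor
limma's `lmFit`/`eBayes` on a fixture in the test suite, where it agrees
to 1e-10. By default moderation is applied to the univariate model and
plain OLS t to the multivariate model (a flag moderates both).

BH step-up adjusted p-values (via `statsmodels`, with a brute-force
step-up oracle in the tests) give q-values; results report significance
at both conventions — raw p < 0.05 (univariate reading) and q < 0.05
(adjusted reading). Tests are two-sided throughout.

Composition-level differential sums isomer abundances within each
composition per sample and reports the group-mean log2 ratio with
increase/decrease/unchanged labels (|log2FC| < 0.05 → unchanged).
Opposite-moving isomers cancel here by construction, which is why the
structure-level test remains the primary analysis.

## Glycogene pathway profiling

Differential-expression tables (gene, cell type, region, log2FC,
adjusted p) are filtered at |log2FC| **strictly** > 1 and adjusted p <
0.05 (boundary rows excluded; thresholds configurable), joined to a
glycogene reference mapping each gene to one of 19 glycosylation-pathway
categories, and summarised as percentage contributions per (cell type,
region) stratum. Two weightings are implemented because the natural
phrasing is ambiguous: `gene-count` (default; each significant glycogene
counts once) and `abs-log2FC`. Percentages sum to 100 per non-empty
stratum; unmapped genes are dropped with a warning (and the CLI escalates
a > 50% unmapped fraction to an error). The bundled reference is a
**synthetic stand-in** shaped like a GlycoMaple-style export — 950 genes
in 19 categories, anchored by well-known glycogene families
(MGAT/FUT/ST6GAL/PIG/SLC35 …) and padded with clearly synthetic symbols
(`SYNGG…`); real analyses should supply their own export via
`load_reference(path)`.

## Synthetic-data generator

The generator defines the conditions every statistical guarantee is
tested under; its defaults emulate the targeted study design.

**Libraries** are grown biosynthetically: every structure arises from a
single-residue addition (or mannose trimming) applied to a structure
already in the library, starting from the Man3GlcNAc2 core, so the
composition graph of any generated library is connected to H3N2 by
construction. Chains target a fine-class mix; two presets mirror the two
sample types analysed — a whole-tissue profile (46% complex-bi, 32%
high-mannose, 6.7% paucimannose, …) and a cardiomyocyte profile (72%
high-mannose, 11% paucimannose, …). Decorations (per-antenna
galactosylation, LacdiNAc, sialylation, Lewis-type and core fucose,
poly-LacNAc repeats, bisecting GlcNAc) are sampled with fixed
probabilities chosen to resemble reported motif frequencies. Exhausted
classes (paucimannose has only ~20 distinct structures under these
rules) yield their remaining slots to classes that can still grow, so
library class *counts* approximate the mix while the class *abundance*
distribution is enforced exactly in expectation by the cohort model.

**Cohorts**: baseline expected relative abundances follow the library's
class mix, split within class by a log-normal spread (σ = 1 on the
natural-log scale) giving the wide per-glycan dynamic range real glycomes
show. Per sample, areas are 10⁶ · 2^(log2 baseline + effects) ·
exp(ε) with ε ~ N(0, σ²), σ = √log(1+CV²) and CV = 0.10 (the
technical-noise ceiling of the mirrored LC-MS workflow). Group sizes
default to 16 negative / 18 positive. The default planted effect is
log2FC = −1 on paucimannose glycans (the paucimannose-down scenario);
covariates are age (normal around 63/66 y per group), sex (group-specific
male fractions), and Bernoulli comorbidity flags with group-specific
prevalences. Covariate effects act additively on log2 abundance **on the
target glycans**, which is what makes an imbalanced comorbidity a genuine
confounder of the group contrast. The emitted ground truth (true per-
glycan log2FC, baseline weights, class labels, covariates) suffices to
score bias, sensitivity and observed FDR without reading generator
internals. All sampling is driven by a single `numpy` Generator seeded
from the effect specification, so outputs are bit-reproducible.

**Spectra**: theoretical B/C/Y/Z + diagnostic ions with Gaussian ppm
jitter plus uniform noise peaks, with the true peak↔ion map returned.
**DE tables**: significant glycogenes planted per pathway and stratum
(|log2FC| ∈ [1.2, 3], adjusted p < 0.049) over a non-significant
background.

What the generator does *not* model — chromatographic peak shapes,
isotope envelopes, missingness mechanisms, between-sample biological
variance beyond the planted effects, batch structure — bounds what
passing tests show: they validate the algebra, the estimators' bias/
calibration under log-normal noise with compositional closure, and the
confounder-adjustment logic, not robustness to real-data pathologies.

## Numerical and design notes

- Compositional closure: planting a decrease on ~7% of total signal
  inflates every other glycan's relative abundance by ~0.05 log2 units
  and shifts the sample median slightly; recovery of a planted −1 effect
  is therefore biased by about +0.05 to +0.07 under the default design.
  This is a property of relative quantification itself, not of the
  estimator, and stays well inside the ±0.1 recovery bound at study
  scale (155 glycans); it is why simulations are run at that scale.
- Simulation sizes (4×500 glycans for null calibration, 40 cohorts for
  recovery, 20 for the confounded design) were chosen to keep Monte
  Carlo error well below the decision margins while the whole suite runs
  in seconds.
- Greedy peak matching is deterministic: peaks in m/z order, ties by
  |ppm| then ion-kind priority.
- `adjust_bh` validates p ∈ [0,1] and is order-preserving; q ≥ p
  elementwise.
- The CLI serializes the resolved configuration (with hash and seed,
  no timestamps) into every output directory; identical configs produce
  byte-identical outputs.

## Known limitations

- Linkage stereochemistry (α2-3 vs α2-6 NeuAc, arm assignment of
  specific isomers) is carried as annotation, never inferred from mass.
- Only the D-family double cleavages are enumerated; other internal
  fragments are not (combinatorially large, not needed for the evidence
  rules implemented).
- Retention-time evidence is a pass-through numeric field (library RRT),
  not predicted.
- The multivariate model is fixed-effects OLS; no mixed effects, batch
  correction, or robust/trend variants.
- The glycogene stage consumes published DE tables; it performs no
  transcript-level testing of its own.
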