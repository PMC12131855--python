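"""glycardio — cardiac N-glycomics analysis pipeline.

Glycan composition algebra and monoisotopic mass calculation, N-glycan
class taxonomy, composition-graph comparison of glycan libraries,
negative-mode MS/MS diagnostic-ion annotation, relative-abundance
quantification, univariate and confounder-adjusted differential abundance
with empirical-Bayes moderated statistics and BH FDR, and glycogene
pathway profiling — plus synthetic-data generators for every stage.
"""

from .glycan_core import (
    MASSES,
    MassTable,
    GlycanComposition,
    GlycanStructure,
    GlycanClassLabel,
    parse_composition,
    parse_structure,
    classify_composition,
    classify_structure,
    composition_property,
    class_distribution,
    read_library,
    write_library,
)
from .composition_graph import build_graph, compare_libraries, graph_summary
from .fragment_annotation import (
    DiagnosticRule,
    FragmentIon,
    Spectrum,
    TopologyEvidence,
    diagnostic_ions,
    enumerate_glycosidic_fragments,
    infer_topology,
    match_peaks,
)
from .quantify import (
    median_normalize_log,
    qc_cv,
    relative_abundance,
)
from .diffabund import (
    GlycanFits,
    ModeratedResult,
    adjust_bh,
    build_design,
    composition_differential,
    differential_table,
    empirical_bayes_moderation,
    fit_linear_models,
)
from .glycogene_profile import (
    filter_significant,
    load_reference,
    pathway_contribution,
    radial_heatmap_table,
)
from .synthetic_data import (
    CARDIOMYOCYTE_CLASS_MIX,
    TISSUE_CLASS_MIX,
    EffectSpec,
    GroundTruth,
    generate_cohort,
    generate_de_gene_table,
    generate_library,
    generate_spectrum,
)

__version__ = "0.1.0"
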