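"""plastedit: chloroplast RNA-editing detection, annotation and
comparative gain/loss analysis, with a synthetic-cohort generator."""

import importlib.resources

from .core import (
    EditingSite,
    FormatError,
    GeneModel,
    GenomeRecord,
    PileupRecord,
    ValidationError,
)
from .io import (
    Pileup,
    read_features,
    read_genes,
    read_genome,
    read_pileup,
    read_site_table,
    read_tree,
    write_genes,
    write_genome,
    write_pileup,
    write_site_table,
)
from .caller import CallerParams, call_sites, classify_type, flag_gta_support, rescue_indel_adjacent
from .annotate import (
    DEFAULT_SCHEME,
    HydropathyScheme,
    annotate_site,
    annotate_sites,
    codon_effect,
    context,
    hydropathy_change,
    locate,
    minus_one_base,
    position_frequency_matrix,
)
from .simulate import (
    PlantedSite,
    SimConfig,
    SimTruth,
    plant_sites,
    simulate_dataset,
    simulate_pileups,
    simulate_reference,
    simulate_site_matrix,
)
from .compare import density, intersections, map_to_columns, needleman_wunsch, progressive_align
from .gainloss import (
    GainLossModel,
    GainLossResult,
    expected_events,
    fit_rates,
    fitch_parsimony,
    likelihood,
    stochastic_mapping,
)
from .stats import (
    CorrelationResult,
    cohort_totals,
    correlate_features,
    load_table1,
    pearson,
    species_totals,
    summarize_cohort,
)

__version__ = "0.1.0"


def default_tree():
    """The fixed 19-taxon gymnosperm species tree used by the
    simulation studies (invented branch lengths)."""
    ref = importlib.resources.files("plastedit.data").joinpath("gymnosperm_tree.nwk")
    with importlib.resources.as_file(ref) as path:
        return read_tree(path)
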