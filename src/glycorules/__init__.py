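"""glycorules: interpretable diagnostic-fragment rules for O-glycan MS2 spectra.

Mines entropy-tree decision rules — thresholds on normalized fragment bins
and fragment intensity ratios — that distinguish O-glycan isomers sharing a
precursor mass, scores each rule by confidence and coverage on spectra from
held-out experiments, and applies serialized rule sets to annotate new
negative-mode spectra of reduced glycans.
"""

__version__ = "0.1.0"

from .config import RunConfig
from .glycan_core import (
    Composition,
    GlycanParseError,
    GlycanStructure,
    Linkage,
    Monosaccharide,
    composition_of,
    formula_mass,
    formula_nominal_mass,
    parse_composition,
    parse_structure,
    precursor_mz,
    residue_mass,
    serialize,
    topology_key,
)
from .spectra_prep import (
    AnnotatedSpectrum,
    BinnedSpectrum,
    FeatureSpec,
    Peak,
    Spectrum,
    bin_spectrum,
    build_feature_matrix,
    normalize,
    read_spectra,
)
from .dataset_split import (
    MassGroup,
    SplitAssignment,
    assign_mass_groups,
    grouped_stratified_split,
)
from .entropy_tree import (
    ClassDistribution,
    DecisionTree,
    best_split,
    entropy,
    fit_tree,
    information_gain,
    predict,
    select_depth,
)
from .fragment_annotation import (
    FragmentCatalog,
    FragmentLabel,
    annotate_mz,
    enumerate_fragments,
    loss_variants,
)
from .rule_extraction import (
    AnnotationResult,
    Rule,
    RuleCondition,
    RuleSet,
    annotate,
    confidence,
    coverage,
    extract_best_paths,
    load_ruleset,
    serialize_ruleset,
    train_group,
)
from .synthetic_data import (
    CorpusConfig,
    IsomerProfile,
    fig1c_like_fixture,
    generate_corpus,
    three_topology_fixture,
)


def load_example_ruleset():
    """Literature-transcribed example rule sets packaged with glycorules.

    Returns a list of :class:`RuleSet`, one per mass group.  Thresholds and
    performance figures appear only where the source text prints them; the
    rest are flagged "transcribed" and are not executable.
    """
    import json
    from importlib import resources

    from .rule_extraction import ruleset_from_payload

    ref = resources.files("glycorules").joinpath("data/example_rules.json")
    payloads = json.loads(ref.read_text(encoding="utf-8"))
    return [ruleset_from_payload(p) for p in payloads]
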