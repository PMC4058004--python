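"""tamoxsim: virtual clinical trials of tamoxifen-endoxifen dosing under
CYP2D6 phenotype stratification.

A reduced linear metabolite-cascade PK model (tamoxifen and its three
measured metabolites, one compartment each, first-order absorption) is
calibrated to phenotype-specific steady-state trough concentrations and
driven through the three study groups of a simulated dosing trial:
standard dose, tamoxifen dose escalation, and tamoxifen-endoxifen
fixed-dose combination with phenotype-adjusted endoxifen dose finding.
"""

from importlib import resources

from .network import (
    ANALYTES,
    DEFAULT_ACTIVITIES,
    Edge,
    MetabolicNetwork,
    PhenotypeActivity,
    SubjectParameters,
    TYPICAL_SUBJECT,
    default_network,
    phenotype_activity,
)
from .regimen import DoseBlock, Regimen, combine, once_daily, twice_daily
from .kinetics import (
    LinearPKSystem,
    build_system,
    periodic_trough,
    population_troughs,
    simulate,
    trough_css,
)
from .targets import derive_default_targets, read_targets_csv, write_targets_csv
from .calibrate import (
    CalibratedModel,
    CalibrationError,
    calibrate,
    calibration_report,
    endoxifen_unit_exposure,
)
from .population import (
    PopulationSpec,
    calibrate_sigma_2d6,
    calibrate_variability,
    population_spec,
    sample_population,
)
from .trial import (
    StudyArm,
    TrialDesign,
    compare_to_reference,
    default_design,
    find_minimal_dose,
    reference_range,
    run_arm,
    run_trial,
    summarize,
)

__version__ = "0.1.0"


def packaged_targets_path():
    """Path to the shipped target-table CSV."""
    return resources.files("tamoxsim") / "data" / "trough_targets.csv"


def packaged_template_path():
    """Path to the shipped network-template YAML."""
    return resources.files("tamoxsim") / "data" / "network_template.yaml"


def build_default_model() -> CalibratedModel:
    """Calibrate the default template to the default target table and
    calibrate the population variability against the EM endoxifen spread."""
    model = calibrate(derive_default_targets(), default_network())
    calibrate_variability(model)
    return model
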