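"""aquanir: aquaphotomics chemometrics for near-infrared spectra of
aqueous solutions.

Detection and quantification of solutes (and of UV-induced thymine-dimer
photoproducts in DNA solutions) from the water absorbance bands of the
first overtone region, via NIPALS PLSR/PCR calibration, PLS-DA and SIMCA
class modeling, orthogonal signal correction and leave-one-out
cross-validation, plus a seeded synthetic NIR spectrum generator.
"""

from .bands import (
    Peak,
    PeakAnnotation,
    WaterBand,
    annotate_peaks,
    default_band_table,
    detect_peaks,
)
from .calibration import (
    CalibrationResults,
    PCRCalibration,
    PLSDACalibration,
    PLSRCalibration,
)
from .latent import (
    LatentModel,
    classify_plsda,
    fit_pca,
    fit_pcr,
    fit_plsda,
    fit_plsr,
    predict_regression,
)
from .pipeline import ExperimentConfig, run_experiment, write_report
from .pretreat import (
    CenteringModel,
    OSCModel,
    apply_osc,
    fit_centering,
    fit_osc,
    smooth_spectra,
)
from .simca import (
    SIMCA,
    SIMCAModel,
    SIMCAResult,
    classify_simca,
    fit_simca,
    simca_discriminating_power,
    simca_interclass_distance,
)
from .simulate import (
    SyntheticConfig,
    simulate_dataset,
    simulate_dose_response,
    water_baseline,
)
from .spectra import (
    SampleMeta,
    SpectraSet,
    WavelengthGrid,
    make_grid,
    read_spectra_table,
    select_wavelength_range,
    write_spectra_table,
)
from .validation import (
    CalibrationResult,
    ClassificationSummary,
    calibration_metrics,
    group_holdout_validate,
    loo_crossvalidate,
    max_factors,
    misclassification_summary,
    select_factors,
)

__version__ = "0.1.0"
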