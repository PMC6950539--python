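"""Shared fixtures: a default synthetic cohort carried through the pipeline.

Session-scoped so the 94-spectrum cohort is synthesized once and reused by
preprocessing, quantification, multivariate and acceptance tests.
"""

import numpy as np
import pytest

from netmet.cohort import (CohortConfig, SynthesisParams, generate_cohort,
                           simulate_cohort_spectra)
from netmet.panel import default_panel, default_templates
from netmet.quantify import (build_quant_table,
                             reference_calibration_from_template)
from netmet.spectra import (build_bucket_table, normalize_by_weight,
                            reference_to_lactate, scale_unit_variance)

COHORT_SEED = 11
SPECTRA_SEED = 13


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def calibration(panel, templates):
    return reference_calibration_from_template(
        templates["lactate"], panel.window("lactate")
    )


@pytest.fixture(scope="session")
def default_cohort():
    """(manifest, ground truth) for the default study composition."""
    return generate_cohort(CohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def referenced_spectra(default_cohort):
    manifest, truth = default_cohort
    spectra = simulate_cohort_spectra(manifest, truth, seed=SPECTRA_SEED)
    return [reference_to_lactate(s) for s in spectra]


@pytest.fixture(scope="session")
def quant_table(referenced_spectra, panel, calibration):
    return build_quant_table(referenced_spectra, panel, calibration)


@pytest.fixture(scope="session")
def bucket_table_uv(referenced_spectra):
    normalized = [normalize_by_weight(s) for s in referenced_spectra]
    return scale_unit_variance(build_bucket_table(normalized))


@pytest.fixture(scope="session")
def noiseless_sample(default_cohort, templates):
    """One noiseless, jitter-free synthetic spectrum plus its planted truth."""
    from netmet.cohort import synthesize_spectrum

    manifest, truth = default_cohort
    rec = manifest.iloc[0]
    synth = SynthesisParams(noise_sd=0.0, baseline_scale=0.0,
                            water_area=0.0, shift_jitter_ppm=0.0)
    spec = synthesize_spectrum(truth.loc[rec.sample_id], rec, templates,
                               synth=synth, seed=1)
    return spec, truth.loc[rec.sample_id]
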