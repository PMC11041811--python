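import numpy as np
import pytest

from oxcal import GroundTruth, StimulusParadigm, generate_run


@pytest.fixture(scope="session")
def hypercapnia_run():
    """Noise-free isometabolic hypercapnia run with non-trivial true gammas."""
    return generate_run(
        StimulusParadigm.hypercapnia(),
        GroundTruth(seed=7, rcbf_peak=1.30, gamma_r_true=0.8, gamma_t_true=1.4),
    )


@pytest.fixture(scope="session")
def plateau_run():
    """Noise-free isometabolic run with a fast rise, so the calibration
    window sits on an essentially exact plateau."""
    return generate_run(
        StimulusParadigm.hypercapnia(),
        GroundTruth(seed=11, rcbf_peak=1.45, alpha_true=0.38, tau_rise_s=2.0),
    )


def make_cohort(seed0: int, noise_sd: float = 0.0, n_animals: int = 7,
                rcmro2_peak: float = 1.06):
    """Synthetic cohort: per animal one hypercapnia calibration run and one
    whisker run with an injected metabolic change."""
    rng = np.random.default_rng(seed0)
    calib, stim = [], []
    for i in range(n_animals):
        calib.append(
            generate_run(
                StimulusParadigm.hypercapnia(),
                GroundTruth(
                    seed=seed0 * 1000 + i,
                    rcbf_peak=1.30 + 0.05 * rng.standard_normal(),
                    noise_sd=noise_sd,
                ),
            )
        )
        stim.append(
            generate_run(
                StimulusParadigm.whisker(),
                GroundTruth(
                    seed=seed0 * 1000 + 500 + i,
                    rcbf_peak=1.15 + 0.02 * rng.standard_normal(),
                    rcmro2_peak=rcmro2_peak,
                    noise_sd=noise_sd,
                ),
            )
        )
    return calib, stim


@pytest.fixture(scope="session")
def noisefree_cohort():
    return make_cohort(1)
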