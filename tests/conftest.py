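import pytest

from qkat import SimConfig, builtin_reference_haplotypes, load_assay_panel, sample_cohort


@pytest.fixture(scope="session")
def panel():
    return load_assay_panel()


@pytest.fixture(scope="session")
def builtin_table():
    return builtin_reference_haplotypes()


@pytest.fixture(scope="session")
def noise_free_cohort(panel):
    """96-sample noise-free cohort with an A/A control as the first sample."""
    from qkat import synthesize_cq

    config = SimConfig(n_samples=96, cq_noise_sd=0.0, concentration_drift_sd=0.3,
                       seed=11, control_pair=("A-2DS4FL", "A-2DS4FL"))
    truth = sample_cohort(config)
    cq = synthesize_cq(truth, config, panel)
    return config, truth, cq
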