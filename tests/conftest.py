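import pytest

from exonrnp import ExonSimConfig, SilacSimConfig, generate_exon_cohort, generate_silac_experiment


@pytest.fixture
def noise_free_config():
    """A noise-free SILAC simulation with planted fold changes and mixing error."""
    return SilacSimConfig(
        n_proteins=20,
        peptides_per_protein=(5, 5),
        log2_noise_sd=0.0,
        mixing_error=1.3,
        missing_rate=0.0,
        fold_changes={
            "TRA2B": {"active_vs_repressed": 1.0, "edc_vs_repressed": 4.0},
            "LUC7L2": {"active_vs_repressed": 1.0, "edc_vs_repressed": 8.0},
            "DDX17": {"active_vs_repressed": 3.0, "edc_vs_repressed": 1.0},
            "PTBP1": {"active_vs_repressed": 0.5, "edc_vs_repressed": 0.25},
        },
        seed=11,
    )


@pytest.fixture
def noise_free_experiment(noise_free_config):
    return generate_silac_experiment(noise_free_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 95-exon cohort with planted zones (session-scoped: read-only)."""
    return generate_exon_cohort(ExonSimConfig(seed=7))
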