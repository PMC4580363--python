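import pytest

from somaticlens.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Scaled-down cohort under default generator conditions (12 samples)."""
    return simulate_cohort(SimConfig(n_samples=12, seed=11))


@pytest.fixture(scope="session")
def survival_sim_config():
    """Survival-focused configuration: few variants, pathway-weighted panel.

    The small panel puts ~40% of variant mass on the hazard pathway so
    roughly a third of samples are pathway-altered, which keeps both
    strata populated at modest cohort sizes.
    """
    def make(n_samples, seed, hazard_ratio=3.3):
        return SimConfig(
            n_samples=n_samples,
            n_germline_per_sample=0,
            n_somatic_per_sample=3,
            gene_universe=[
                ("NOTCH1", 3000), ("NOTCH2", 3000), ("EP300", 3000),
                ("CREBBP", 3000), ("F1", 10000), ("F2", 10000),
                ("F3", 10000), ("F4", 10000), ("F5", 12000),
            ],
            hazard_ratio_pathway=hazard_ratio,
            seed=seed,
        )
    return make
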