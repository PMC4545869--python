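import pytest

from ewasrf import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """One moderately sized synthetic dataset shared across tests that only
    read it: 300 probes (8 informative, 20 SNP, 20 sex), 90 samples in two
    batches with a batch shift and mild cell-type confounding."""
    cfg = SimulationConfig(
        n_samples_stage1=60, n_samples_stage2=30, n_probes=300,
        n_informative=8, effect_size=2.0, n_snp_probes=20, n_sex_probes=20,
        batch_shift=0.4, detection_fail_rate=0.02, confound_strength=0.08,
        seed=11,
    )
    return cfg, generate_dataset(cfg)
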