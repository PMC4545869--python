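"""Generate a small synthetic 450K-like dataset and inspect its structure."""

from ewasrf import SimulationConfig, generate_dataset

cfg = SimulationConfig(n_samples_stage1=80, n_samples_stage2=40, n_probes=500,
                       n_informative=8, effect_size=2.0, n_snp_probes=20,
                       n_sex_probes=20, batch_shift=0.4,
                       detection_fail_rate=0.01, confound_strength=0.08,
                       seed=1)
dataset, manifest, phenotype, reference, truth = generate_dataset(cfg)

print(f"beta matrix: {dataset.n_probes} probes x {dataset.n_samples} samples")
print(f"outcome prevalence: {phenotype['atopy'].mean():.3f} "
      f"(configured {cfg.prevalence})")
print(f"planted informative probes: {len(truth.informative_probes)}; "
      f"SNP probes: {len(truth.snp_probes)}; sex probes: {len(truth.sex_probes)}")
print(f"mean granulocyte proportion, cases vs controls: "
      f"{truth.true_cell_proportions['Gran'][phenotype['atopy'] == 1].mean():.3f} vs "
      f"{truth.true_cell_proportions['Gran'][phenotype['atopy'] == 0].mean():.3f}")
# The prevalence tracks the configured rate, the three special probe sets are
# disjoint, and the case/control granulocyte gap reflects confound_strength.
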