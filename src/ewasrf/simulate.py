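"""Synthetic 450K-like methylation data with known ground truth.

The generator emulates the statistical structure of a whole-blood
methylation study of a binary allergic outcome measured in a two-part
sample (a discovery subsample and a later addition, processed as separate
array batches and of different sex):

* a small planted subset of autosomal probes whose M-values shift between
  outcome classes by a configurable effect size;
* per-sample leukocyte mixtures (6 cell types by default) drawn from a
  Dirichlet whose granulocyte mean can shift with the outcome, confounding
  probes that differ between cell types;
* sex-chromosome probes whose methylation depends on sex, SNP-affected
  probes with the trimodal beta pattern of a common variant under the
  probe, an additive M-scale batch offset, and sporadic detection failures.

Bulk methylation is mixed on the beta (proportion) scale across cell types,
then perturbed on the M (logit) scale, so betas remain strictly inside
(0, 1) and planted effects have linear M-scale semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .transforms import beta_to_m, m_to_beta
from .types import MethylationDataset

#: Default cell types of a blood reference, granulocytes last.
DEFAULT_CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")

#: Approximate mean whole-blood proportions for the six default types.
DEFAULT_CELL_MEANS = (0.10, 0.16, 0.05, 0.08, 0.08, 0.53)

_GENE_REGIONS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")
_ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``n_samples_stage1`` is the discovery subsample used for recursive
    feature selection; ``n_samples_stage2`` is the later addition pooled in
    for association testing (second batch, opposite sex, mirroring a
    two-part cohort design).  ``effect_size`` is the mean M-value shift at
    informative probes between outcome classes; ``confound_strength`` shifts
    the granulocyte Dirichlet mean for cases.  ``prevalence`` is
    P(outcome = 1).
    """

    n_samples_stage1: int = 245
    n_samples_stage2: int = 122
    n_probes: int = 5000
    n_informative: int = 10
    effect_size: float = 2.0
    n_cell_types: int = 6
    confound_strength: float = 0.0
    n_snp_probes: int = 0
    n_sex_probes: int = 0
    batch_shift: float = 0.0
    detection_fail_rate: float = 0.0
    prevalence: float = 0.35
    noise_sd: float = 1.5
    ige_rate_control: float = 0.15
    ige_rate_case: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ConfigurationError("prevalence must lie strictly in (0, 1)")
        if not 0 <= self.detection_fail_rate <= 1:
            raise ConfigurationError("detection_fail_rate must lie in [0, 1]")
        counts = (self.n_samples_stage1, self.n_samples_stage2, self.n_probes,
                  self.n_informative, self.n_snp_probes, self.n_sex_probes)
        if any(c < 0 for c in counts):
            raise ConfigurationError("counts must be nonnegative")
        if self.n_informative > self.n_probes:
            raise ConfigurationError("n_informative exceeds n_probes")
        if self.n_informative + self.n_snp_probes + self.n_sex_probes > self.n_probes:
            raise ConfigurationError(
                "informative + SNP + sex probe counts exceed n_probes"
            )
        if self.n_cell_types < 2:
            raise ConfigurationError("need at least two cell types")


@dataclass
class GroundTruth:
    """Truth channel for parameter-recovery tests.

    The informative, SNP and sex probe sets are disjoint by construction;
    each row of ``true_cell_proportions`` is a simplex point.
    """

    informative_probes: set[str]
    snp_probes: set[str]
    sex_probes: set[str]
    true_effect: dict[str, float]
    true_cell_proportions: pd.DataFrame  # samples x cell types

    def to_json(self) -> str:
        payload = {
            "informative_probes": sorted(self.informative_probes),
            "snp_probes": sorted(self.snp_probes),
            "sex_probes": sorted(self.sex_probes),
            "true_effect": {k: self.true_effect[k]
                            for k in sorted(self.true_effect)},
            "true_cell_proportions": {
                s: [float(v) for v in row]
                for s, row in self.true_cell_proportions.iterrows()
            },
            "cell_types": list(self.true_cell_proportions.columns),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _cell_type_names(k: int) -> list[str]:
    if k == len(DEFAULT_CELL_TYPES):
        return list(DEFAULT_CELL_TYPES)
    return [f"cell{i + 1}" for i in range(k)]


def _cell_mean_proportions(k: int) -> np.ndarray:
    if k == len(DEFAULT_CELL_MEANS):
        return np.asarray(DEFAULT_CELL_MEANS, dtype=float)
    w = np.ones(k) / k
    return w


def make_cell_reference(rng: np.random.Generator, probe_ids,
                        cell_types=DEFAULT_CELL_TYPES,
                        frac_discriminating: float = 0.3,
                        discrim_sd: float = 2.0) -> pd.DataFrame:
    """Reference beta profiles (probes x cell types).

    Baseline probe methylation is bimodal on the logit scale, the typical
    450K pattern; a fraction of probes carries large cell-type-specific
    logit offsets so the columns are mutually distinguishable.
    """
    p, k = len(probe_ids), len(cell_types)
    comp = rng.choice(3, size=p, p=[0.4, 0.4, 0.2])
    base = np.where(comp == 0, rng.normal(-3.0, 1.0, p),
                    np.where(comp == 1, rng.normal(3.0, 1.0, p),
                             rng.normal(0.0, 1.5, p)))
    offsets = rng.normal(0.0, 0.2, size=(p, k))
    discrim = rng.random(p) < frac_discriminating
    offsets[discrim] = rng.normal(0.0, discrim_sd, size=(int(discrim.sum()), k))
    m = base[:, None] + offsets
    return pd.DataFrame(m_to_beta(m), index=pd.Index(probe_ids, name="IlmnID"),
                        columns=list(cell_types))


def simulate_mixtures(reference: pd.DataFrame, proportions: np.ndarray,
                      noise_sd: float, rng: np.random.Generator) -> pd.DataFrame:
    """Bulk beta profiles from reference columns and mixing weights.

    ``proportions`` is (n_samples x n_cell_types); Gaussian noise of the
    given SD is added on the beta scale and the result clipped to (0, 1).
    Used directly by deconvolution-recovery experiments.
    """
    mix = reference.to_numpy() @ np.asarray(proportions).T
    mix = mix + rng.normal(0.0, noise_sd, size=mix.shape)
    mix = np.clip(mix, 1e-6, 1 - 1e-6)
    cols = [f"mix{i + 1}" for i in range(mix.shape[1])]
    return pd.DataFrame(mix, index=reference.index, columns=cols)


def _draw_proportions(rng, outcome, names, confound_strength, concentration=60.0):
    """Per-sample Dirichlet cell proportions; case granulocyte mean is shifted
    upward by ``confound_strength`` (renormalized)."""
    k = len(names)
    base = _cell_mean_proportions(k)
    gran = k - 1  # granulocyte-like compartment is the last column
    props = np.empty((len(outcome), k))
    for cls in (0, 1):
        mean = base.copy()
        if cls == 1 and confound_strength:
            mean[gran] += confound_strength
            mean = np.clip(mean, 1e-3, None)
            mean = mean / mean.sum()
        idx = np.flatnonzero(outcome == cls)
        if len(idx):
            props[idx] = rng.dirichlet(mean * concentration, size=len(idx))
    return props


def generate_dataset(config: SimulationConfig):
    """Generate one synthetic dataset.

    Returns ``(dataset, manifest, phenotype, cell_reference, truth)``:
    a :class:`~ewasrf.types.MethylationDataset` (beta + detection-p),
    a manifest DataFrame indexed by probe ID, a phenotype table
    (sample_id, atopy, high_ige, sex, batch, stage), the cell-type
    reference betas, and the :class:`GroundTruth`.  Identical seeds give
    bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n1, n2 = cfg.n_samples_stage1, cfg.n_samples_stage2
    n = n1 + n2
    p = cfg.n_probes

    probe_ids = np.array([f"cg{i:08d}" for i in range(p)])
    sample_ids = np.array([f"S{i:04d}" for i in range(n)])

    # disjoint special probe sets
    shuffled = rng.permutation(p)
    sex_idx = shuffled[:cfg.n_sex_probes]
    snp_idx = shuffled[cfg.n_sex_probes:cfg.n_sex_probes + cfg.n_snp_probes]
    info_idx = shuffled[cfg.n_sex_probes + cfg.n_snp_probes:
                        cfg.n_sex_probes + cfg.n_snp_probes + cfg.n_informative]

    outcome = rng.binomial(1, cfg.prevalence, size=n)
    # secondary biomarker correlated with the outcome
    ige_p = np.where(outcome == 1, cfg.ige_rate_case, cfg.ige_rate_control)
    high_ige = rng.binomial(1, ige_p)
    sex = np.array(["F"] * n1 + ["M"] * n2)
    batch = np.array([1] * n1 + [2] * n2)
    stage = np.array([1] * n1 + [2] * n2)

    names = _cell_type_names(cfg.n_cell_types)
    reference = make_cell_reference(rng, probe_ids, names)
    props = _draw_proportions(rng, outcome, names, cfg.confound_strength)

    # bulk mixing on the beta scale, then perturbations on the M scale
    bulk_beta = reference.to_numpy() @ props.T          # p x n
    bulk_beta = np.clip(bulk_beta, 1e-6, 1 - 1e-6)
    m = np.log2(bulk_beta / (1 - bulk_beta))

    signs = rng.choice([-1.0, 1.0], size=cfg.n_informative)
    effects = signs * cfg.effect_size
    m[info_idx] += np.outer(effects, outcome)
    m += cfg.batch_shift * (batch == 2)[None, :]
    m += rng.normal(0.0, cfg.noise_sd, size=m.shape)

    # sex probes: X-inactivation-like pattern, hemimethylated in females
    if len(sex_idx):
        female = (sex == "F").astype(float)
        sex_base = rng.normal(-3.0, 0.5, size=len(sex_idx))
        m[sex_idx] = (sex_base[:, None] + 3.0 * female[None, :]
                      + rng.normal(0.0, cfg.noise_sd, size=(len(sex_idx), n)))

    beta = m_to_beta(m)

    # SNP probes: trimodal betas from a genotype under the probe
    if len(snp_idx):
        maf = rng.uniform(0.1, 0.5, size=len(snp_idx))
        geno = rng.binomial(2, maf[:, None], size=(len(snp_idx), n))
        centers = np.array([0.03, 0.5, 0.97])
        g_logit = beta_to_m(centers[geno]) + rng.normal(
            0.0, 0.3, size=(len(snp_idx), n))
        beta[snp_idx] = m_to_beta(g_logit)

    detection_p = rng.uniform(0.0, 0.005, size=(p, n))
    if cfg.detection_fail_rate > 0:
        fail = rng.random((p, n)) < cfg.detection_fail_rate
        detection_p = np.where(fail, rng.uniform(0.02, 1.0, size=(p, n)),
                               detection_p)

    # manifest: special probes mapped to the labels the QC filters act on
    chrom = rng.choice([str(c) for c in range(1, 23)], size=p)
    chrom[sex_idx] = rng.choice(["X", "Y"], size=len(sex_idx), p=[0.9, 0.1])
    snp_flag = np.zeros(p, dtype=bool)
    snp_flag[snp_idx] = True
    has_gene = rng.random(p) < 0.7
    manifest = pd.DataFrame({
        "CHR": chrom,
        "MAPINFO": rng.integers(10_000, 50_000_000, size=p),
        "UCSC_RefGene_Name": np.where(has_gene,
                                      [f"GENE{i % 997}" for i in range(p)], ""),
        "UCSC_RefGene_Group": rng.choice(_GENE_REGIONS, size=p),
        "Relation_to_UCSC_CpG_Island": rng.choice(_ISLAND_RELATIONS, size=p),
        "SNP_flag": snp_flag,
    }, index=pd.Index(probe_ids, name="IlmnID"))

    dataset = MethylationDataset(
        beta=pd.DataFrame(beta, index=pd.Index(probe_ids, name="IlmnID"),
                          columns=sample_ids),
        detection_p=pd.DataFrame(detection_p,
                                 index=pd.Index(probe_ids, name="IlmnID"),
                                 columns=sample_ids),
    )
    phenotype = pd.DataFrame({
        "sample_id": sample_ids,
        "atopy": outcome,
        "high_ige": high_ige,
        "sex": sex,
        "batch": batch,
        "stage": stage,
    }).set_index("sample_id")

    truth = GroundTruth(
        informative_probes=set(probe_ids[info_idx]),
        snp_probes=set(probe_ids[snp_idx]),
        sex_probes=set(probe_ids[sex_idx]),
        true_effect={pid: float(e)
                     for pid, e in zip(probe_ids[info_idx], effects)},
        true_cell_proportions=pd.DataFrame(props, index=sample_ids,
                                           columns=names),
    )
    return dataset, manifest, phenotype, reference, truth


def write_dataset(outdir, dataset: MethylationDataset, manifest: pd.DataFrame,
                  phenotype: pd.DataFrame, reference: pd.DataFrame,
                  truth: GroundTruth | None = None) -> None:
    """Write the generator outputs in their plain-text exchange formats:
    beta/detection TSV, manifest and phenotype and reference CSV, truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.beta.to_csv(out / "beta.tsv", sep="\t")
    if dataset.detection_p is not None:
        dataset.detection_p.to_csv(out / "detection_p.tsv", sep="\t")
    manifest.to_csv(out / "manifest.csv")
    phenotype.to_csv(out / "phenotype.csv")
    reference.to_csv(out / "cell_reference.csv")
    if truth is not None:
        (out / "truth.json").write_text(truth.to_json())


def read_dataset(indir) -> tuple[MethylationDataset, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read back the formats written by :func:`write_dataset` (truth excluded)."""
    ind = Path(indir)
    beta = pd.read_csv(ind / "beta.tsv", sep="\t", index_col=0)
    det_path = ind / "detection_p.tsv"
    det = pd.read_csv(det_path, sep="\t", index_col=0) if det_path.exists() else None
    manifest = pd.read_csv(ind / "manifest.csv", index_col=0,
                           dtype={"CHR": str}, keep_default_na=False,
                           na_values=[])
    manifest["SNP_flag"] = manifest["SNP_flag"].astype(str).isin(
        ["True", "true", "1"])
    manifest["MAPINFO"] = manifest["MAPINFO"].astype(int)
    phenotype = pd.read_csv(ind / "phenotype.csv", index_col=0)
    reference = pd.read_csv(ind / "cell_reference.csv", index_col=0)
    return MethylationDataset(beta=beta, detection_p=det), manifest, phenotype, reference
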