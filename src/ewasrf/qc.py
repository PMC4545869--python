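"""Probe-level quality control and value preparation.

The cleaning funnel applies three probe filters in a fixed order —
failed-detection probes, sex-chromosome probes, SNP-flagged probes — and
records exact counts at every stage, then converts betas to M-values for
parametric modelling.  Filters only ever drop probes; the sample set is
never altered here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .types import FilterReport, MethylationDataset, require_annotated


def filter_detection(dataset: MethylationDataset, p_threshold: float = 0.01,
                     sample_fraction: float = 0.10,
                     ) -> tuple[MethylationDataset, list[str]]:
    """Drop probes whose detection p exceeds ``p_threshold`` in strictly more
    than ``sample_fraction`` of samples.

    A probe failing in exactly the boundary fraction (e.g. 1 of 10 samples at
    the default 10 %) is retained.  Returns the filtered dataset and the list
    of removed probe IDs.
    """
    if dataset.detection_p is None:
        raise DegenerateInputError("detection-p matrix required for this filter")
    fail_frac = (dataset.detection_p.to_numpy() > p_threshold).mean(axis=1)
    keep = fail_frac <= sample_fraction
    removed = list(dataset.probe_ids[~keep])
    return dataset.subset_probes(dataset.probe_ids[keep]), removed


def remove_sex_chromosomes(dataset: MethylationDataset, manifest: pd.DataFrame,
                           ) -> tuple[MethylationDataset, list[str]]:
    """Drop probes mapped to chromosome X or Y.  Every probe must be
    annotated; an unannotated probe raises an error naming it."""
    require_annotated(dataset, manifest)
    chrom = manifest.loc[dataset.probe_ids, "CHR"].astype(str)
    keep = ~chrom.isin(["X", "Y"])
    removed = list(dataset.probe_ids[~keep.to_numpy()])
    return dataset.subset_probes(dataset.probe_ids[keep.to_numpy()]), removed


def remove_snp_probes(dataset: MethylationDataset, manifest: pd.DataFrame,
                      ) -> tuple[MethylationDataset, list[str]]:
    """Drop probes whose manifest SNP flag is set (possible variant in the
    probe body or at single-base extension)."""
    require_annotated(dataset, manifest)
    flagged = manifest.loc[dataset.probe_ids, "SNP_flag"].astype(bool)
    removed = list(dataset.probe_ids[flagged.to_numpy()])
    return dataset.subset_probes(dataset.probe_ids[~flagged.to_numpy()]), removed


def run_qc(dataset: MethylationDataset, manifest: pd.DataFrame,
           p_threshold: float = 0.01, sample_fraction: float = 0.10,
           ) -> tuple[MethylationDataset, FilterReport]:
    """Full funnel: detection -> sex chromosomes -> SNP flags, with a
    reconciled :class:`~ewasrf.types.FilterReport`."""
    n_entry = dataset.n_probes
    dataset, det_removed = filter_detection(dataset, p_threshold, sample_fraction)
    dataset, sex_removed = remove_sex_chromosomes(dataset, manifest)
    dataset, snp_removed = remove_snp_probes(dataset, manifest)
    report = FilterReport(
        n_entry=n_entry,
        n_detection_removed=len(det_removed),
        n_sex_removed=len(sex_removed),
        n_snp_removed=len(snp_removed),
        detection_removed=det_removed,
        sex_removed=sex_removed,
        snp_removed=snp_removed,
    )
    report.validate()
    assert report.n_remaining == dataset.n_probes
    return dataset, report


def probe_accounting(entry: int, sex_removed: int, snp_removed: int,
                     detection_removed: int = 0) -> tuple[int, FilterReport]:
    """Arithmetic check of a cleaning funnel reported as counts only.

    ``entry`` is the probe count after any detection filtering already
    reflected in it (pass ``detection_removed`` separately when it is not).
    Returns the remaining count and a validated report.
    """
    report = FilterReport(
        n_entry=entry + detection_removed,
        n_detection_removed=detection_removed,
        n_sex_removed=sex_removed,
        n_snp_removed=snp_removed,
    )
    report.validate()
    return report.n_remaining, report


def beta_matrix_to_m(beta: pd.DataFrame, *, eps: float | None = None) -> pd.DataFrame:
    """Elementwise M-value transform of a beta matrix (NaN passes through)."""
    from .transforms import beta_to_m
    return pd.DataFrame(beta_to_m(beta.to_numpy(dtype=float), eps=eps),
                        index=beta.index, columns=beta.columns)


def adjust_batch(m_matrix: pd.DataFrame, batch_labels,
                 location_only: bool = False) -> pd.DataFrame:
    """Location-scale batch alignment on the M scale.

    Per probe, each batch's values are standardized and mapped onto the
    pooled mean and pooled SD, removing additive and multiplicative
    inter-array differences.  Probes with zero variance within any batch
    pass through unchanged (their scale is undefined).  Batches of a single
    sample are rejected unless ``location_only`` is set, in which case only
    means are aligned.

    This is a deliberately simple stand-in behind the batch-adjustment
    extension point; an empirical-Bayes adjuster can be slotted in its
    place.
    """
    batch = pd.Series(np.asarray(batch_labels), index=m_matrix.columns)
    sizes = batch.value_counts()
    if (sizes < 2).any() and not location_only:
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(
            f"singleton batch(es) {small}: scale undefined; "
            "use location_only=True"
        )
    x = m_matrix.to_numpy(dtype=float).copy()
    pooled_mean = np.nanmean(x, axis=1)
    pooled_sd = np.nanstd(x, axis=1, ddof=1)
    adjustable = np.ones(x.shape[0], dtype=bool)
    parts = {}
    for b in sizes.index:
        cols = np.flatnonzero((batch == b).to_numpy())
        mu = np.nanmean(x[:, cols], axis=1)
        sd = np.nanstd(x[:, cols], axis=1, ddof=1) if len(cols) > 1 else \
            np.zeros(x.shape[0])
        parts[b] = (cols, mu, sd)
        if not location_only:
            adjustable &= sd > 0
    if len(sizes) > 1:
        for b, (cols, mu, sd) in parts.items():
            if location_only:
                x[np.ix_(adjustable, cols)] += (
                    pooled_mean[adjustable, None] - mu[adjustable, None])
            else:
                z = (x[np.ix_(adjustable, cols)] - mu[adjustable, None]) \
                    / sd[adjustable, None]
                x[np.ix_(adjustable, cols)] = (
                    pooled_mean[adjustable, None]
                    + pooled_sd[adjustable, None] * z)
    return pd.DataFrame(x, index=m_matrix.index, columns=m_matrix.columns)


def recode_outliers(m_matrix: pd.DataFrame, strata, fence_k: float = 3.0,
                    ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Set extreme M-values to missing using a Tukey fence within strata.

    Within each stratum (typically the outcome classes), values outside
    [Q1 - k*IQR, Q3 + k*IQR] per probe are recoded NaN.  Returns the recoded
    matrix and the list of (probe, sample) cells changed; constant probes
    are never touched (IQR = 0 but every value sits at the quartiles).
    """
    if fence_k <= 0:
        raise ValueError("fence_k must be positive")
    strata = pd.Series(np.asarray(strata), index=m_matrix.columns)
    x = m_matrix.to_numpy(dtype=float).copy()
    recoded: list[tuple[str, str]] = []
    for _, cols in strata.groupby(strata).groups.items():
        ci = m_matrix.columns.get_indexer(cols)
        block = x[:, ci]
        q1 = np.nanpercentile(block, 25, axis=1)
        q3 = np.nanpercentile(block, 75, axis=1)
        iqr = q3 - q1
        lo = q1 - fence_k * iqr
        hi = q3 + fence_k * iqr
        out = (block < lo[:, None]) | (block > hi[:, None])
        out &= ~np.isnan(block)
        rows, cells = np.nonzero(out)
        for r, c in zip(rows, cells):
            recoded.append((m_matrix.index[r], cols[c]))
        block[out] = np.nan
        x[:, ci] = block
    return pd.DataFrame(x, index=m_matrix.index, columns=m_matrix.columns), recoded
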