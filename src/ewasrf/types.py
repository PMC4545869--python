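"""Core data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingAnnotationError

#: Chromosome labels accepted in a probe manifest.
VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])

#: Manifest columns, mirroring a 450K GenomeStudio export.
MANIFEST_COLUMNS = [
    "IlmnID",
    "CHR",
    "MAPINFO",
    "UCSC_RefGene_Name",
    "UCSC_RefGene_Group",
    "Relation_to_UCSC_CpG_Island",
    "SNP_flag",
]


@dataclass
class MethylationDataset:
    """A beta-value matrix (probes x samples) with an optional same-shape
    detection-p matrix.

    Betas lie in [0, 1] wherever non-missing; NaN entries are permitted
    (they appear after outlier recoding).  Probe and sample identifiers are
    the DataFrame index/columns and must be unique.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.beta.index.is_unique or not self.beta.columns.is_unique:
            raise ValueError("probe and sample identifiers must be unique")
        vals = self.beta.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("beta values outside [0, 1]")
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise ValueError("detection_p shape differs from beta shape")
            if not self.detection_p.index.equals(self.beta.index) or \
                    not self.detection_p.columns.equals(self.beta.columns):
                raise ValueError("detection_p index/columns differ from beta")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        """New dataset restricted to ``probe_ids`` (order preserved)."""
        idx = pd.Index(probe_ids)
        missing = idx.difference(self.beta.index)
        if len(missing):
            raise KeyError(f"unknown probes: {list(missing[:5])}")
        det = None if self.detection_p is None else self.detection_p.loc[idx]
        return MethylationDataset(beta=self.beta.loc[idx], detection_p=det)

    def subset_samples(self, sample_ids) -> "MethylationDataset":
        idx = pd.Index(sample_ids)
        missing = idx.difference(self.beta.columns)
        if len(missing):
            raise KeyError(f"unknown samples: {list(missing[:5])}")
        det = None if self.detection_p is None else self.detection_p[idx]
        return MethylationDataset(beta=self.beta[idx], detection_p=det)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check a probe manifest and return it indexed by probe ID.

    Required columns follow the GenomeStudio export convention
    (:data:`MANIFEST_COLUMNS`); chromosome labels must come from 1-22, X, Y.
    """
    df = manifest
    if "IlmnID" in df.columns:
        df = df.set_index("IlmnID")
    if not df.index.is_unique:
        raise ValueError("manifest has duplicate probe records")
    chroms = df["CHR"].astype(str)
    bad = sorted(set(chroms) - VALID_CHROMOSOMES)
    if bad:
        raise ValueError(f"manifest contains invalid chromosome labels: {bad}")
    return df


def require_annotated(dataset: MethylationDataset, manifest: pd.DataFrame) -> None:
    """Raise :class:`MissingAnnotationError` naming the first probe of the
    dataset that has no manifest record."""
    missing = dataset.probe_ids.difference(manifest.index)
    if len(missing):
        raise MissingAnnotationError(
            f"probe {missing[0]!r} has no manifest annotation "
            f"({len(missing)} unannotated in total)"
        )


@dataclass
class FilterReport:
    """Accounting of the probe-cleaning funnel.

    Removal stages are applied in the fixed order detection -> sex
    chromosomes -> SNP-flagged; the removed sets are disjoint by
    construction and entry minus removals equals remaining.
    """

    n_entry: int
    n_detection_removed: int = 0
    n_sex_removed: int = 0
    n_snp_removed: int = 0
    detection_removed: list[str] = field(default_factory=list)
    sex_removed: list[str] = field(default_factory=list)
    snp_removed: list[str] = field(default_factory=list)

    @property
    def n_remaining(self) -> int:
        return (self.n_entry - self.n_detection_removed
                - self.n_sex_removed - self.n_snp_removed)

    def validate(self) -> None:
        if min(self.n_entry, self.n_detection_removed, self.n_sex_removed,
               self.n_snp_removed) < 0:
            raise ValueError("negative counts in filter report")
        if self.n_remaining < 0:
            raise ValueError(
                f"filter funnel inconsistent: removals exceed entry "
                f"({self.n_entry} entry, remainder {self.n_remaining})"
            )
        sets = [set(self.detection_removed), set(self.sex_removed),
                set(self.snp_removed)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("removal stages overlap")

    def to_dict(self) -> dict:
        return {
            "n_entry": self.n_entry,
            "n_detection_removed": self.n_detection_removed,
            "n_sex_removed": self.n_sex_removed,
            "n_snp_removed": self.n_snp_removed,
            "n_remaining": self.n_remaining,
            "stages": ["detection", "sex_chromosomes", "snp_flagged"],
        }
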