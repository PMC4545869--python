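"""Reference-based cell-type deconvolution.

Whole blood is a mixture of leukocyte subtypes with distinct methylomes, so
bulk methylation at many probes reflects cell composition rather than the
phenotype under study.  Given reference profiles R (probes x cell types)
for sorted cell populations, each sample's bulk profile y is projected onto
the reference by constrained least squares:

    minimize ||R w - y||^2   subject to  w >= 0  and  sum(w) <= 1
                                         (or sum(w) = 1 in normalized mode)

The fitted w are the estimated cell proportions used as adjustment
covariates in stage-2 association models.  Projection is done on the beta
scale by default, where the nonnegativity geometry is natural.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import RankDeficientError

_COND_LIMIT = 1e8


@dataclass
class CellProportions:
    """Estimated mixture weights for one sample plus the fit residual."""

    proportions: pd.Series  # indexed by cell type
    residual_norm: float
    mode: str

    def __post_init__(self) -> None:
        w = self.proportions.to_numpy()
        if (w < -1e-9).any():
            raise ValueError("negative proportion")
        if self.mode == "normalized":
            if abs(w.sum() - 1.0) > 1e-6:
                raise ValueError("normalized-mode proportions must sum to 1")
        elif w.sum() > 1 + 1e-6:
            raise ValueError("proportions exceed 1")


def _check_reference(R: np.ndarray, k: int) -> None:
    if R.shape[0] < k:
        raise ValueError(
            f"need at least as many shared probes ({R.shape[0]}) as cell "
            f"types ({k})"
        )
    if np.linalg.matrix_rank(R) < k or np.linalg.cond(R) > _COND_LIMIT:
        raise RankDeficientError(
            "reference columns are linearly dependent on the shared probes"
        )


def estimate_proportions(sample_profile: pd.Series, reference: pd.DataFrame,
                         mode: str = "sum_le_one") -> CellProportions:
    """Project one bulk profile onto the reference.

    ``sample_profile`` is indexed by probe ID; only probes shared with the
    reference are used (missing values dropped).  ``mode`` selects the sum
    constraint: ``sum_le_one`` (default; the unexplained remainder is
    reported via the residual) or ``normalized`` (weights forced onto the
    simplex).
    """
    if mode not in ("sum_le_one", "normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    shared = reference.index.intersection(sample_profile.dropna().index)
    R = reference.loc[shared].to_numpy(dtype=float)
    y = sample_profile.loc[shared].to_numpy(dtype=float)
    k = reference.shape[1]
    _check_reference(R, k)

    # sum(w) <= 1 via a slack variable s >= 0 with w_1 + ... + w_k + s = 1,
    # the equality itself enforced as a heavily weighted extra row of an
    # ordinary NNLS system.  With rho >> ||R|| the constraint is satisfied
    # to machine-level accuracy while the fit term is undisturbed.
    rho = 1e6 * max(1.0, float(np.abs(R).max())) * max(1.0, np.sqrt(len(y)))
    if mode == "sum_le_one":
        A = np.zeros((len(y) + 1, k + 1))
        A[:len(y), :k] = R
        A[len(y), :] = rho
        b = np.concatenate([y, [rho]])
        w, _ = nnls(A, b)
        w = w[:k]
    else:
        A = np.vstack([R, np.full((1, k), rho)])
        b = np.concatenate([y, [rho]])
        w, _ = nnls(A, b)
        total = w.sum()
        if total <= 0:
            raise RankDeficientError("degenerate fit: all-zero weights")
        w = w / total
    w = np.where(w < 1e-12, 0.0, w)
    resid = float(np.linalg.norm(R @ w - y))
    return CellProportions(
        proportions=pd.Series(w, index=reference.columns),
        residual_norm=resid, mode=mode,
    )


def estimate_proportions_matrix(beta: pd.DataFrame, reference: pd.DataFrame,
                                mode: str = "sum_le_one") -> pd.DataFrame:
    """Per-sample proportions for every column of a beta matrix
    (samples x cell types)."""
    rows = {}
    for sample in beta.columns:
        rows[sample] = estimate_proportions(beta[sample], reference,
                                            mode=mode).proportions
    return pd.DataFrame(rows).T[reference.columns.tolist()]
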