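"""Methylation value transforms.

The 450K array reports, per CpG probe, a methylated intensity M and an
unmethylated intensity U.  The proportion-scale summary is the beta value

    beta = M / (c + M + U)

with a small constant c guarding against a zero denominator; beta is
interpretable as percent methylation but is heteroscedastic near 0 and 1.
Parametric models therefore use the logit-scale M-value

    m = log2(beta / (1 - beta))

which is the transform applied before every regression in this package.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError

#: Illumina-convention intensity offset used when none is given.
DEFAULT_OFFSET_C = 100.0


def beta_from_intensities(methylated, unmethylated, offset_c=DEFAULT_OFFSET_C):
    """Beta value from methylated/unmethylated intensities.

    Accepts scalars or arrays (broadcast).  All inputs must be nonnegative
    and at least one of the three strictly positive; with ``offset_c > 0``
    the result is strictly below 1.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    c = float(offset_c)
    if np.any(m < 0) or np.any(u < 0) or c < 0:
        raise ValueError("intensities and offset must be nonnegative")
    denom = c + m + u
    if np.any(denom == 0):
        raise DegenerateInputError(
            "all-zero intensities with offset_c=0: beta undefined"
        )
    out = m / denom
    return out.item() if out.ndim == 0 else out


def beta_to_m(beta, *, eps: float | None = None):
    """M-value log2(beta/(1-beta)).

    ``beta`` must lie strictly in (0, 1).  Values at exactly 0 or 1 raise a
    domain error unless an explicit ``eps`` clip is requested, in which case
    beta is clipped to [eps, 1-eps] first.  Scalar in, scalar out.
    """
    b = np.asarray(beta, dtype=float)
    if eps is not None:
        if not 0 < eps < 0.5:
            raise ValueError("eps must be in (0, 0.5)")
        b = np.clip(b, eps, 1.0 - eps)
    valid = (b > 0) & (b < 1)
    if not np.all(valid | np.isnan(b)):
        raise ValueError(
            "beta values at or outside {0, 1}; pass eps=... to clip explicitly"
        )
    out = np.log2(b / (1.0 - b))
    return out.item() if out.ndim == 0 else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^m / (1 + 2^m)."""
    mv = np.asarray(m, dtype=float)
    # expit formulation avoids overflow for large |m|
    out = 1.0 / (1.0 + np.exp2(-mv))
    return out.item() if out.ndim == 0 else out
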