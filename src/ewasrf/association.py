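"""Stage-2 association testing.

Each selected CpG's M-values are tested against a binary outcome by
logistic regression, crude and adjusted for estimated cell-type proportions
and sex; the coefficient is a log-odds per unit M-value.  Family-wise error
is controlled by Bonferroni over the selected set.  The module also carries
the crude-versus-adjusted confounding diagnostic and the 2x2 prevalence
chi-square used to compare subsamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, DegenerateInputError, SeparationError

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e8
_SEPARATION_COEF = 50.0


@dataclass
class LogisticFit:
    coef: float
    se: float
    wald_p: float
    n_used: int


def _design(exposure: pd.Series, covariates: pd.DataFrame | None):
    cols = [exposure.rename("exposure")]
    if covariates is not None:
        cov = covariates.loc[exposure.index]
        cols.extend(cov[c].rename(str(c)) for c in cov.columns)
    X = pd.concat(cols, axis=1).astype(float)
    return X


def fit_logistic(outcome, exposure: pd.Series, covariates: pd.DataFrame | None = None,
                 ) -> LogisticFit:
    """Maximum-likelihood logistic fit; returns the exposure coefficient,
    its standard error and the two-sided Wald p-value.

    Rows with any missing value are dropped (case-wise deletion).  Raises
    :class:`SeparationError` on complete or quasi-complete separation and
    :class:`CollinearityError` (naming columns) when the design is
    ill-conditioned.
    """
    exposure = pd.Series(exposure) if not isinstance(exposure, pd.Series) else exposure
    y = pd.Series(np.asarray(outcome, dtype=float), index=exposure.index)
    X = _design(exposure, covariates)
    keep = ~(X.isna().any(axis=1) | y.isna())
    X, y = X[keep], y[keep]
    n_used = len(y)
    if n_used <= X.shape[1] + 1:
        raise DegenerateInputError(
            f"n_used={n_used} too small for {X.shape[1] + 1} parameters"
        )
    if y.nunique() < 2:
        raise DegenerateInputError("outcome constant after case-wise deletion")

    # conditioning guard on the standardized design (constant-column safe)
    Z = X.to_numpy()
    sd = Z.std(axis=0)
    if (sd == 0).any():
        bad = list(X.columns[sd == 0])
        raise CollinearityError(f"constant design columns: {bad}")
    cond = np.linalg.cond((Z - Z.mean(axis=0)) / sd)
    if cond > _COND_LIMIT:
        raise CollinearityError(
            f"design condition number {cond:.2e} exceeds {_COND_LIMIT:.0e}; "
            f"columns: {list(X.columns)}"
        )

    Xc = sm.add_constant(X, prepend=True)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(method="newton", maxiter=100,
                                      tol=1e-8, disp=False, warn_convergence=False)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    coef = float(fit.params["exposure"])
    se = float(fit.bse["exposure"])
    if (not np.isfinite(coef) or not np.isfinite(se)
            or abs(coef) > _SEPARATION_COEF):
        raise SeparationError(
            f"diverging coefficient ({coef:.3g} +/- {se:.3g}): separation"
        )
    wald_p = float(2 * stats.norm.sf(abs(coef) / se))
    return LogisticFit(coef=coef, se=se, wald_p=wald_p, n_used=n_used)


@dataclass
class AssociationResult:
    """Crude and covariate-adjusted association of one CpG with one outcome."""

    probe_id: str
    outcome: str
    crude_beta: float
    crude_se: float
    crude_p: float
    adjusted_beta: float
    adjusted_se: float
    wald_p: float
    n_used: int
    alpha: float

    @property
    def adjusted_or(self) -> float:
        return float(np.exp(self.adjusted_beta))

    @property
    def pct_diff_beta(self) -> float | None:
        """Percent change of the coefficient on adjustment,
        100 * (adjusted - crude) / crude; undefined when crude is 0."""
        if self.crude_beta == 0:
            return None
        return 100.0 * (self.adjusted_beta - self.crude_beta) / self.crude_beta

    @property
    def significant(self) -> bool:
        return self.wald_p < self.alpha

    def to_dict(self) -> dict:
        return {
            "probe_id": self.probe_id, "outcome": self.outcome,
            "crude_beta": self.crude_beta, "crude_se": self.crude_se,
            "crude_p": self.crude_p, "adjusted_beta": self.adjusted_beta,
            "adjusted_se": self.adjusted_se, "wald_p": self.wald_p,
            "adjusted_or": self.adjusted_or,
            "pct_diff_beta": self.pct_diff_beta, "n_used": self.n_used,
            "significant": self.significant,
        }


def crude_vs_adjusted(outcome, exposure: pd.Series, covariates: pd.DataFrame,
                      probe_id: str = "", outcome_name: str = "",
                      alpha: float = 0.05) -> AssociationResult:
    """Fit the crude and the covariate-adjusted model for one CpG and report
    both coefficients plus the percent change on adjustment."""
    crude = fit_logistic(outcome, exposure, None)
    adj = fit_logistic(outcome, exposure, covariates)
    return AssociationResult(
        probe_id=probe_id, outcome=outcome_name,
        crude_beta=crude.coef, crude_se=crude.se, crude_p=crude.wald_p,
        adjusted_beta=adj.coef, adjusted_se=adj.se, wald_p=adj.wald_p,
        n_used=adj.n_used, alpha=alpha,
    )


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test alpha controlling family-wise error at ``family_alpha``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def significance_filter(results, alpha: float):
    """Subset with p strictly below ``alpha``, input order preserved.

    ``results`` may be a sequence of p-values or of objects exposing
    ``wald_p``.  Returns (retained list, count).
    """
    retained = []
    for r in results:
        p = r.wald_p if hasattr(r, "wald_p") else float(r)
        if not 0 <= p <= 1:
            raise ValueError(f"invalid p-value {p}")
        if p < alpha:
            retained.append(r)
    return retained, len(retained)


def prevalence_chi2(table, continuity_correction: bool = True,
                    ) -> tuple[float, float]:
    """Pearson chi-square (1 df) on a 2x2 prevalence table.

    With ``continuity_correction`` the Yates adjustment reduces |ad - bc| by
    n/2 (clamped at 0) before squaring; the p-value is the chi-square upper
    tail.  Zero row or column margins are rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero margin in contingency table")
    stat, p, _, _ = stats.chi2_contingency(t, correction=continuity_correction)
    return float(stat), float(p)


def associate_all(m_matrix: pd.DataFrame, outcome: pd.Series,
                  covariates: pd.DataFrame, outcome_name: str,
                  family_alpha: float = 0.05) -> tuple[list[AssociationResult], list[str]]:
    """Crude + adjusted fits for every probe (rows of ``m_matrix``), with a
    Bonferroni per-test alpha of ``family_alpha`` / n_probes.

    If the covariate set trips the collinearity guard, the
    largest-mean-proportion cell-type column is dropped (logged) and the fit
    retried.  Probes failing with separation are skipped and returned in the
    second element.
    """
    alpha = bonferroni_alpha(m_matrix.shape[0], family_alpha)
    results, skipped = [], []
    for probe in m_matrix.index:
        exposure = m_matrix.loc[probe]
        cov = covariates
        for attempt in range(2):
            try:
                res = crude_vs_adjusted(outcome.loc[exposure.index], exposure,
                                        cov, probe_id=probe,
                                        outcome_name=outcome_name, alpha=alpha)
                results.append(res)
                break
            except CollinearityError:
                if attempt == 1 or cov.shape[1] < 2:
                    skipped.append(probe)
                    break
                # drop a constant column if one is the culprit, otherwise the
                # largest-mean cell-type proportion
                rows = exposure.dropna().index
                const = cov.loc[rows].std()
                drop = const.idxmin() if (const == 0).any() \
                    else cov.mean().idxmax()
                logger.info("probe %s: collinear covariates, dropping %s",
                            probe, drop)
                cov = cov.drop(columns=[drop])
            except (SeparationError, DegenerateInputError) as exc:
                logger.info("probe %s skipped: %s", probe, exc)
                skipped.append(probe)
                break
    return results, skipped


def results_frame(results) -> pd.DataFrame:
    """Tabular view of association results (one row per probe/outcome)."""
    return pd.DataFrame([r.to_dict() for r in results])
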