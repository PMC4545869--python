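"""Random-Forest primitive for class-imbalanced methylation data.

The recursive selection loop needs three quantities from each forest: the
overall out-of-bag (OOB) error, per-class OOB misclassification rates, and
per-variable importance.  With an imbalanced outcome a standard bootstrap
lets the majority class dominate every training set, so each tree is grown
on a *per-class* bootstrap: ``sampsize`` gives the number of draws (with
replacement) from each class, e.g. (50, 50) for a balanced forest.  Samples
outside a tree's bootstrap are its OOB set; aggregating their majority
votes across trees yields the OOB error estimates without a held-out set.

Importance is the mean decrease in Gini impurity (MDG): the impurity
reduction attributable to splits on a variable, summed over each tree
(normalized by the tree's root sample weight) and averaged over the
forest.  MDG is preferred here over permutation importance for its
robustness to small perturbations of the data.

Individual trees are grown with scikit-learn's CART implementation; the
per-class bootstrap, OOB vote ledger and MDG aggregation are implemented
on top of it because no stock forest estimator exposes this sampling
contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateInputError

#: Recognized mtry rules, p = number of variables.
MTRY_RULES = ("sqrt_p", "2sqrt_p", "0.05p", "0.1p", "0.5p")


def resolve_mtry(rule, p: int) -> int:
    """Number of candidate variables per split from a rule tag or integer.

    Fractional results round down; the result is clamped to [1, p].
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if isinstance(rule, str):
        if rule == "sqrt_p":
            m = math.floor(math.sqrt(p))
        elif rule == "2sqrt_p":
            m = math.floor(2 * math.sqrt(p))
        elif rule == "0.05p":
            m = math.floor(0.05 * p)
        elif rule == "0.1p":
            m = math.floor(0.1 * p)
        elif rule == "0.5p":
            m = math.floor(0.5 * p)
        else:
            raise ValueError(f"unknown mtry rule {rule!r}")
    else:
        m = int(rule)
    return max(1, min(m, p))


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.

    ``sampsize`` maps class label -> per-tree bootstrap draw count; ``None``
    means an ordinary bootstrap of n samples from the pooled data
    (imbalanced sampling).  ``mtry`` is an integer or a rule tag from
    :data:`MTRY_RULES`.
    """

    ntree: int = 500
    mtry: int | str = "sqrt_p"
    sampsize: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be positive")


@dataclass
class ForestResult:
    """Outputs of one grown forest.

    ``oob_votes`` holds per-sample OOB vote counts per class;
    ``class_error`` maps class label -> OOB misclassification rate among
    covered samples of that class.  ``oob_error`` equals the class-size
    weighted mean of the class errors over covered samples, a conservation
    law checked by the tests.
    """

    oob_error: float
    class_error: dict
    vim: pd.Series
    oob_votes: pd.DataFrame
    n_oob_covered: int
    classes: list = field(default_factory=list)
    params: ForestParams | None = None

    def errors_from_votes(self, y: pd.Series) -> tuple[float, dict]:
        """Recompute (oob_error, class_error) from the stored vote matrix —
        the independent bookkeeping check."""
        return _errors_from_votes(self.oob_votes.to_numpy(),
                                  y.loc[self.oob_votes.index].to_numpy(),
                                  np.asarray(self.classes))


def _errors_from_votes(votes: np.ndarray, y: np.ndarray, classes: np.ndarray):
    covered = votes.sum(axis=1) > 0
    # ties broken toward the class with lower label order (argmax is first max)
    pred = classes[np.argmax(votes, axis=1)]
    wrong = (pred != y) & covered
    class_error = {}
    for c in classes:
        in_c = (y == c) & covered
        class_error[c] = float(wrong[in_c].sum() / in_c.sum()) if in_c.sum() \
            else float("nan")
    oob = float(wrong.sum() / covered.sum()) if covered.sum() else float("nan")
    return oob, class_error


def _tree_gini_importance(tree, p: int) -> np.ndarray:
    """Total weighted Gini decrease per feature for one fitted tree,
    normalized by the root sample weight."""
    t = tree.tree_
    imp = np.zeros(p)
    left, right = t.children_left, t.children_right
    internal = np.flatnonzero(left != -1)
    w = t.weighted_n_node_samples
    g = t.impurity
    for n in internal:
        gain = w[n] * g[n] - w[left[n]] * g[left[n]] - w[right[n]] * g[right[n]]
        imp[t.feature[n]] += gain
    return imp / w[0]


def _bootstrap_indices(rng, y_codes, class_counts, sampsize):
    if sampsize is None:
        n = len(y_codes)
        return rng.integers(0, n, size=n)
    parts = []
    for code, size in enumerate(sampsize):
        members = np.flatnonzero(y_codes == code)
        parts.append(members[rng.integers(0, len(members), size=size)])
    return np.concatenate(parts)


def grow_forest(X: pd.DataFrame, y, params: ForestParams) -> ForestResult:
    """Grow one forest on ``X`` (samples x variables) and binary labels ``y``.

    Each tree is fit on a per-class bootstrap (see ``params.sampsize``),
    unpruned, with ``mtry`` candidate variables per split.  Identical seeds
    give identical results.
    """
    y = pd.Series(np.asarray(y), index=X.index)
    vals = X.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("input matrix contains NaN; impute upstream")
    classes, y_codes = np.unique(y.to_numpy(), return_inverse=True)
    if len(classes) < 2:
        raise DegenerateInputError("outcome has a single class")
    counts = np.bincount(y_codes)
    if counts.min() < 2:
        raise DegenerateInputError("need at least 2 samples per class")
    if params.sampsize is not None and len(params.sampsize) != len(classes):
        raise ValueError("sampsize must give one draw count per class")

    n, p = vals.shape
    mtry = resolve_mtry(params.mtry, p)
    rng = np.random.default_rng(params.seed)
    votes = np.zeros((n, len(classes)), dtype=np.int64)
    vim = np.zeros(p)
    all_idx = np.arange(n)

    for _ in range(params.ntree):
        boot = _bootstrap_indices(rng, y_codes, counts, params.sampsize)
        oob = np.setdiff1d(all_idx, boot, assume_unique=False)
        tree = DecisionTreeClassifier(
            criterion="gini", max_features=mtry,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(vals[boot], y_codes[boot])
        if len(oob):
            pred = tree.predict(vals[oob])
            votes[oob, pred] += 1
        vim += _tree_gini_importance(tree, p)

    vim /= params.ntree
    oob_error, class_error = _errors_from_votes(votes, y_codes,
                                                np.arange(len(classes)))
    class_error = {classes[c]: e for c, e in class_error.items()}
    return ForestResult(
        oob_error=oob_error,
        class_error=class_error,
        vim=pd.Series(vim, index=X.columns),
        oob_votes=pd.DataFrame(votes, index=X.index, columns=list(classes)),
        n_oob_covered=int((votes.sum(axis=1) > 0).sum()),
        classes=list(classes),
        params=params,
    )


def tune_parameters(X: pd.DataFrame, y, mtry_rules=("sqrt_p",),
                    ntree_grid=(500,), balanced_sampsize=(50, 50),
                    seed: int = 0) -> pd.DataFrame:
    """Grid evaluation of forest hyperparameters.

    Returns one row per (mtry rule, ntree) combination grown with the
    balanced ``sampsize``, plus two comparison rows at default mtry
    (sqrt_p) and ntree 500 contrasting imbalanced (no sampsize) against
    balanced sampling.  Each row comes from an independently seeded run;
    the whole table is deterministic in ``seed``.
    """
    if not len(mtry_rules) or not len(ntree_grid):
        raise ValueError("grids must be non-empty")
    rows = []
    run = 0
    for balance, sampsize in (("imbalanced", None), ("balanced", balanced_sampsize)):
        res = grow_forest(X, y, ForestParams(ntree=500, mtry="sqrt_p",
                                             sampsize=sampsize,
                                             seed=seed + run))
        rows.append(_tune_row("sqrt_p", 500, balance, res, comparison=True))
        run += 1
    for rule in mtry_rules:
        for ntree in ntree_grid:
            res = grow_forest(X, y, ForestParams(ntree=int(ntree), mtry=rule,
                                                 sampsize=balanced_sampsize,
                                                 seed=seed + run))
            rows.append(_tune_row(rule, int(ntree), "balanced", res,
                                  comparison=False))
            run += 1
    return pd.DataFrame(rows)


def _tune_row(rule, ntree, balance, res: ForestResult, comparison: bool) -> dict:
    row = {
        "mtry": rule, "ntree": ntree, "sampling": balance,
        "balance_comparison": comparison, "oob_error": res.oob_error,
    }
    for c, e in res.class_error.items():
        row[f"class_error_{c}"] = e
    return row
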