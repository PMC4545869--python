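"""Recursive Random-Forest feature elimination (stage 1).

Starting from all QC-surviving probes, a forest is grown, probes are ranked
by mean-decrease-Gini importance, the bottom half is dropped, and the forest
is regrown on the survivors — repeatedly, while tracking the overall OOB
error and the per-class misclassification rates.  Selection focuses on one
class (the *focal* class, e.g. the atopic participants) whose correct
classification the study cares most about:

* ``first_increase`` stops at the first iteration whose focal-class error
  strictly rises and selects the iteration before it — the literal stated
  rule;
* ``global_min`` (default) runs the full schedule and selects the iteration
  minimizing the focal-class error, ties broken by fewer variables then by
  lower overall OOB error — the behavior that tolerates an early transient
  uptick in the error trajectory.

Per-iteration forests are reseeded deterministically from the master seed,
so a trace is reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forest import ForestParams, grow_forest

STOP_POLICIES = ("global_min", "first_increase")


def halving_schedule(p0: int, n_iterations: int) -> list[int]:
    """Variable counts of the elimination: p0, floor(p0/2), ... stopping
    after at most ``n_iterations`` entries or upon reaching 1."""
    if p0 < 1:
        raise ValueError("p0 must be >= 1")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    counts = [p0]
    while len(counts) < n_iterations and counts[-1] > 1:
        counts.append(counts[-1] // 2)
    return counts


def rank_and_keep(vim: pd.Series, keep_n: int) -> list[str]:
    """IDs of the ``keep_n`` variables with highest importance.

    Ties are broken by lexicographic variable ID, making the ranking stable
    and reproducible.
    """
    if keep_n > len(vim):
        raise ValueError(f"keep_n={keep_n} exceeds {len(vim)} variables")
    order = (vim.rename("vim").rename_axis("vid").reset_index()
             .sort_values(["vim", "vid"], ascending=[False, True],
                          kind="mergesort"))
    return order["vid"].head(keep_n).tolist()


@dataclass
class IterationRecord:
    iteration: int
    n_variables: int
    oob_error: float
    class_error: dict
    variables: list[str]


@dataclass
class SelectionTrace:
    """Ordered per-iteration records plus the selected iteration/variables."""

    records: list[IterationRecord]
    selected_iteration: int
    selected_variables: list[str]
    focal_class: object
    stop_policy: str

    def to_frame(self) -> pd.DataFrame:
        """One row per iteration: variable count and error rates (in %),
        the shape of the published trajectory tables."""
        rows = []
        for r in self.records:
            row = {"iteration": r.iteration, "n_variables": r.n_variables,
                   "oob_error_pct": 100 * r.oob_error}
            for c, e in r.class_error.items():
                row[f"error_{c}_pct"] = 100 * e
            rows.append(row)
        return pd.DataFrame(rows)

    def focal_errors(self) -> list[float]:
        return [r.class_error[self.focal_class] for r in self.records]


def recursive_rf(X: pd.DataFrame, y, params: ForestParams, focal_class,
                 stop_policy: str = "global_min", max_iterations: int = 15,
                 forest_fn=grow_forest) -> SelectionTrace:
    """Run the elimination loop on ``X`` (samples x probes).

    ``params.mtry`` rule tags are re-resolved against the shrinking variable
    count each iteration.  ``forest_fn`` is injectable for testing.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if stop_policy not in STOP_POLICIES:
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    y = pd.Series(np.asarray(y), index=X.index)
    if focal_class not in set(y):
        raise ValueError(f"focal class {focal_class!r} absent from outcome")

    variables = list(X.columns)
    records: list[IterationRecord] = []
    stopped_by_increase = False
    for it in range(1, max_iterations + 1):
        it_params = ForestParams(
            ntree=params.ntree, mtry=params.mtry, sampsize=params.sampsize,
            seed=(params.seed + it) % 2**31,
        )
        res = forest_fn(X[variables], y, it_params)
        records.append(IterationRecord(
            iteration=it, n_variables=len(variables),
            oob_error=res.oob_error, class_error=dict(res.class_error),
            variables=list(variables),
        ))
        focal_err = res.class_error[focal_class]
        if (stop_policy == "first_increase" and len(records) >= 2
                and focal_err > records[-2].class_error[focal_class]):
            stopped_by_increase = True
            break
        next_n = len(variables) // 2
        if next_n < 2 or it == max_iterations:
            break
        variables = rank_and_keep(res.vim, next_n)

    if stop_policy == "first_increase" and stopped_by_increase:
        sel = len(records) - 1  # iteration prior to the increase (1-based idx)
    else:
        focal = [r.class_error[focal_class] for r in records]
        # argmin; ties -> fewer variables (later iteration) then lower OOB
        best = min(range(len(records)),
                   key=lambda i: (focal[i], records[i].n_variables,
                                  records[i].oob_error))
        sel = best + 1
    selected = records[sel - 1]
    return SelectionTrace(
        records=records,
        selected_iteration=sel,
        selected_variables=list(selected.variables),
        focal_class=focal_class,
        stop_policy=stop_policy,
    )
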