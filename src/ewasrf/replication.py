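"""Independent-cohort replication filter.

A discovery hit replicates when the external cohort shows the same
direction of association (odds ratios on the same side of 1) with a nominal
p-value below the replication alpha.  Probes absent from the external
result set are marked unavailable and excluded from the tested denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ReplicationRecord:
    probe_id: str
    discovery_direction: int     # sign of log-OR: -1, 0, +1
    replication_direction: int | None
    replication_p: float | None
    available: bool
    replicated: bool


def _direction(or_value: float) -> int:
    if or_value <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    return int(np.sign(np.log(or_value)))


def replicate(discovery: pd.DataFrame, external: pd.DataFrame,
              alpha: float = 0.05,
              ) -> tuple[list[ReplicationRecord], int, int]:
    """Apply the replication criteria.

    Both inputs need columns ``probe_id``, ``odds_ratio`` and (for the
    external set) ``p_value``.  Returns (records, n_tested, n_replicated);
    an external OR exactly equal to 1 has no direction and never counts as
    concordant (logged).  Row order of either input does not affect the
    result; records follow the discovery order.
    """
    ext = external.set_index("probe_id") if "probe_id" in external.columns \
        else external
    records = []
    tested = replicated = 0
    for _, row in discovery.iterrows():
        pid = row["probe_id"] if "probe_id" in row else row.name
        d_dir = _direction(float(row["odds_ratio"]))
        avail = pid in ext.index and not (
            pd.isna(ext.loc[pid, "odds_ratio"]) or pd.isna(ext.loc[pid, "p_value"]))
        if not avail:
            records.append(ReplicationRecord(pid, d_dir, None, None, False, False))
            continue
        r_or = float(ext.loc[pid, "odds_ratio"])
        r_p = float(ext.loc[pid, "p_value"])
        r_dir = _direction(r_or)
        tested += 1
        if d_dir == 0 or r_dir == 0:
            logger.info("probe %s: OR exactly 1, direction undefined", pid)
        rep = (r_dir != 0) and (r_dir == d_dir) and (r_p < alpha)
        replicated += rep
        records.append(ReplicationRecord(pid, d_dir, r_dir, r_p, True, bool(rep)))
    return records, tested, replicated


def replication_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "probe_id": r.probe_id,
        "discovery_direction": r.discovery_direction,
        "replication_direction": r.replication_direction,
        "replication_p": r.replication_p,
        "available": r.available,
        "replicated": r.replicated,
    } for r in records])
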