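"""Packaged published summary statistics.

``atopy_ewas_summary.csv`` carries, for the 22 CpGs reaching
Bonferroni significance for atopy in the motivating discovery cohort,
the printed adjusted odds ratios and p-values for atopy and for high
total IgE, plus the replication cohort's odds ratios and p-values where
the probe was available on that cohort's arrays.  These printed columns
are the inputs to the threshold/replication filters and to the worked
examples; they are summary statistics, not individual-level data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_atopy_summary() -> pd.DataFrame:
    """Published discovery + replication summary table (22 rows).

    Columns: probe_id, chromosome, gene, region, atopy_or, atopy_p,
    ige_or, ige_p, repl_or, repl_p (the last two NaN for probes absent
    from the replication cohort).
    """
    with resources.files("ewasrf.data").joinpath(
            "atopy_ewas_summary.csv").open() as fh:
        return pd.read_csv(fh)
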