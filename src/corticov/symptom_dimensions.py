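"""Composite symptom dimensions from scale global scores.

The two negative-symptom dimensions are integer sums of SANS 0-5 global
scores: amotivation = avolition-apathy + anhedonia-asociality, and diminished
expression = alogia + blunted affect.  The SAPS positive dimension sums the
delusion and hallucination globals; the SAPS disorganization dimension sums
bizarre behavior and formal thought disorder.  Missing components propagate
to a missing dimension — values are never imputed.
"""

from __future__ import annotations

import logging

import pandas as pd

from .atlas_io import CohortTable

logger = logging.getLogger("corticov")

DIMENSION_COMPONENTS: dict[str, tuple[str, str]] = {
    "amotivation": ("sans_avolition_apathy", "sans_anhedonia_asociality"),
    "diminished_expression": ("sans_alogia", "sans_blunted_affect"),
    "saps_positive": ("saps_delusion", "saps_hallucination"),
    "saps_disorganization": ("saps_bizarre_behavior", "saps_formal_thought"),
}


def compute_dimensions(cohort: CohortTable) -> CohortTable:
    """Append the four composite dimension columns to the cohort table.

    Row-wise integer sums of the component global scores; a row missing any
    component gets a missing dimension.  Scores outside 0-5 raise.
    """
    table = cohort.table.copy()
    for dim, (a, b) in DIMENSION_COMPONENTS.items():
        missing_cols = [c for c in (a, b) if c not in table.columns]
        if missing_cols:
            raise ValueError(f"cannot compute {dim}: missing columns {missing_cols}")
        for c in (a, b):
            v = table[c].dropna()
            if len(v) and ((v < 0) | (v > 5)).any():
                raise ValueError(f"{c} contains scores outside the 0-5 ordinal range")
        table[dim] = table[a] + table[b]
        n_missing = int(table[dim].isna().sum())
        if n_missing:
            logger.info("%s missing for %d subject(s) (component scores absent)", dim, n_missing)
    return CohortTable(table=table, atlas=cohort.atlas)
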