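"""Small bundled example data.

The single dataset here is one simulated realization of a 10-cluster,
2-period crossover trial of a bloodstream-infection prevention measure:
per-unit event totals for the control and treatment periods, each cell
accumulating 2100 at-risk days.  It is convenient for demonstrating the
cluster-level fixed-effects analysis without running the simulator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["crossover_count_table", "crude_irr"]

# (control events, treatment events) per unit; equal exposure in both cells
_COUNTS = [
    (14, 10),
    (17, 7),
    (8, 3),
    (6, 4),
    (11, 5),
    (20, 7),
    (12, 15),
    (5, 5),
    (4, 4),
    (9, 8),
]


def crossover_count_table() -> pd.DataFrame:
    """Synthetic 10×2 count table from a simulated two-period crossover.

    Columns: ``unit`` (1..10), ``control`` and ``treatment`` event totals.
    """
    return pd.DataFrame(
        [(i + 1, c, t) for i, (c, t) in enumerate(_COUNTS)],
        columns=["unit", "control", "treatment"],
    )


def crude_irr(table: pd.DataFrame) -> pd.Series:
    """Crude per-unit incidence rate ratio: treatment events / control events.

    Valid as a rate ratio because both cells of a unit share the same total
    at-risk time.
    """
    return (table["treatment"] / table["control"]).astype(float)


def table_summaries():
    """The bundled table as cluster-period summaries for the estimators.

    Exposures are equal (2100 at-risk days) in every cell; period 0 is the
    control period of units on the control-first sequence, so treatment
    status alternates by unit to mimic the two sequences.
    """
    from .datagen import ClusterPeriodSummary

    out = []
    for i, (control, treatment) in enumerate(_COUNTS):
        # period assignment is irrelevant without a period effect; alternate
        # the sequences so a period-adjusted model stays identifiable
        first_treated = i % 2 == 0
        for period, (events, treated) in enumerate(
            [(treatment, 1), (control, 0)] if first_treated
            else [(control, 0), (treatment, 1)]
        ):
            out.append(
                ClusterPeriodSummary(
                    cluster=i,
                    period=period,
                    treatment=treated,
                    n=210,
                    family="poisson",
                    events=float(events),
                    exposure=2100.0,
                )
            )
    return out
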