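"""Published summary statistics used as inputs to the CFD analysis.

These are the printed per-sector capillary flow density (CFD, percent of
sector area occupied by vessel lumens; ``thickness`` in um) group summaries
for the case/control comparison, plus the cohort composition counts.  They
are inputs: the group t-tests and cohort shares are recomputed from them at
run time, never copied.

The case/control table is self-contained with its own header sample sizes
(41 cases, 35 controls), which differ from the narrative eye counts
(40 case eyes, 13 control eyes); the header Ns are what make the table's
tests reproducible, so they are used as printed.
"""

from __future__ import annotations

import pandas as pd

N_CASE = 41
N_CONTROL = 35

SECTORS = (
    "whole",
    "fovea",
    "parafovea",
    "superior_hemi",
    "inferior_hemi",
    "temporal",
    "superior",
    "nasal",
    "inferior",
    "thickness",
    "A",
    "B",
    "C",
)

# sector: (mean_case, sd_case, mean_control, sd_control)
_CASE_CONTROL = {
    "whole": (51.39, 4.81, 55.77, 4.81),
    "fovea": (29.84, 10.1, 30.44, 6.96),
    "parafovea": (53.02, 5.41, 58.72, 5.41),
    "superior_hemi": (52.64, 6.09, 59.48, 5.14),
    "inferior_hemi": (53.3, 5.35, 58.73, 5.44),
    "temporal": (51.29, 5.71, 58.52, 5.17),
    "superior": (53.96, 6.98, 59.93, 5.27),
    "nasal": (52.31, 5.58, 58.63, 5.06),
    "inferior": (54.38, 6.13, 58.81, 6.04),
    "thickness": (338.38, 84.57, 311.3, 120.86),
    "A": (54.15, 5.71, 58.43, 5.37),
    "B": (46.1, 5.11, 50.47, 4.09),
    "C": (53.97, 5.55, 58.16, 5.76),
}

#: sectors whose printed p-values recompute cleanly from the printed
#: summaries; the remaining rows are reported but not used as benchmarks
RELIABLE_SECTORS = ("parafovea", "superior_hemi", "temporal", "nasal")

# patient-only per-layer summaries: sector -> layer -> (mean, sd)
_CASE_BY_LAYER = {
    "whole": {"CCL": (49.5, 13.9), "SCP": (48.99, 4.66), "DCP": (53.66, 3.76)},
    "fovea": {"CCL": (50.6, 16.0), "SCP": (29.37, 8.24), "DCP": (30.29, 11.68)},
    "parafovea": {"CCL": (51.5, 14.1), "SCP": (50.71, 5.69), "DCP": (55.21, 4.1)},
    "superior_hemi": {"CCL": (50.5, 15.8), "SCP": (50.56, 6.43), "DCP": (54.63, 5.07)},
    "inferior_hemi": {"CCL": (52.6, 15.8), "SCP": (50.86, 5.26), "DCP": (55.63, 4.35)},
    "temporal": {"CCL": (51.1, 15.7), "SCP": (49.96, 5.78), "DCP": (52.57, 5.42)},
    "superior": {"CCL": (50.0, 18.7), "SCP": (51.14, 7.18), "DCP": (56.63, 5.68)},
    "nasal": {"CCL": (52.3, 17.8), "SCP": (50.5, 6.03), "DCP": (54.02, 4.56)},
    "inferior": {"CCL": (53.5, 17.5), "SCP": (51.25, 5.94), "DCP": (57.34, 4.72)},
    "thickness": {"CCL": (347.0, 84.0), "SCP": (338.95, 86.24), "DCP": (337.85, 84.08)},
    "A": {"CCL": (46.2, 18.2), "SCP": (51.25, 5.36), "DCP": (56.9, 4.6)},
    "B": {"CCL": (51.8, 13.7), "SCP": (44.91, 5.02), "DCP": (47.23, 4.99)},
    "C": {"CCL": (49.5, 16.2), "SCP": (50.87, 4.71), "DCP": (56.91, 4.63)},
}

# cohort composition (39 patients, 40 case eyes, 13 control eyes)
N_PATIENTS = 39
CLINICAL_COUNTS = {"acute": 23, "chronic": 9, "recurrent": 7}
PATTERN_A_COUNT = 3  # of N_PATIENTS


def case_control_summary() -> pd.DataFrame:
    """Per-sector case/control mean, SD and n (the summary-CSV layout)."""
    rows = [
        {
            "sector": s,
            "mean_case": m1,
            "sd_case": s1,
            "n_case": N_CASE,
            "mean_control": m2,
            "sd_control": s2,
            "n_control": N_CONTROL,
        }
        for s, (m1, s1, m2, s2) in _CASE_CONTROL.items()
    ]
    return pd.DataFrame(rows)


def case_layer_summary() -> pd.DataFrame:
    """Patient-only per-layer (CCL/SCP/DCP) sector summaries."""
    rows = [
        {"sector": s, "layer": layer, "mean": m, "sd": sd}
        for s, layers in _CASE_BY_LAYER.items()
        for layer, (m, sd) in layers.items()
    ]
    return pd.DataFrame(rows)
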