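"""Reference values from the original masking experiments.

Group-mean points of subjective equality (PSE, mm) reported for the two
texture-discrimination experiments, and the integration-model parameters
fitted to the second experiment's mean JNDs.  These are published summary
numbers used as inputs (e.g. to seed simulated observers or to check table
arithmetic); the raw trial data live in a public deposit
(doi:10.5281/zenodo.3907325) and are not shipped here.
"""

from __future__ import annotations

import pandas as pd

from .model import ModelParams

__all__ = [
    "REFERENCE_MODEL_PARAMS",
    "EXP1_PSE_MM",
    "EXP2_PSE_MM",
    "exp1_pse_table",
    "exp2_pse_table",
]

#: Integration-model parameters fitted to the second experiment's mean JNDs
#: (single-stroke variance, mask / no-mask process noise, all mm^2; decay
#: exponent and comparison stroke count held fixed).
REFERENCE_MODEL_PARAMS = ModelParams(
    sigma2_single=0.075,
    sigma2_w_mask=0.031,
    sigma2_w_ctrl=0.012,
    decay_exponent=0.442,
    n2=4,
)

#: Experiment 1 group-mean PSEs (mm) by standard period and condition.
EXP1_PSE_MM: dict[float, dict[str, float]] = {
    1.69: {
        "one-stroke control": 1.77,
        "mask": 1.74,
        "smooth": 1.75,
        "three-strokes control": 1.77,
    },
    1.95: {
        "one-stroke control": 2.02,
        "mask": 1.87,
        "smooth": 1.94,
        "three-strokes control": 2.05,
    },
}

#: Experiment 2 group-mean PSEs (mm) by masking, standard period and stroke
#: number (1, 3, 5, 7).
EXP2_PSE_MM: dict[str, dict[float, dict[int, float]]] = {
    "mask": {
        1.69: {1: 1.83, 3: 1.84, 5: 1.84, 7: 1.85},
        1.95: {1: 1.90, 3: 2.01, 5: 2.00, 7: 1.99},
    },
    "control": {
        1.69: {1: 1.79, 3: 1.84, 5: 1.84, 7: 1.82},
        1.95: {1: 2.02, 3: 2.07, 5: 2.07, 7: 2.07},
    },
}


def exp1_pse_table() -> pd.DataFrame:
    """Experiment 1 PSE means as a tidy frame (standard_mm, condition, pse_mm)."""
    rows = [
        {"standard_mm": std, "condition": cond, "pse_mm": pse}
        for std, conds in EXP1_PSE_MM.items()
        for cond, pse in conds.items()
    ]
    return pd.DataFrame(rows)


def exp2_pse_table() -> pd.DataFrame:
    """Experiment 2 PSE means as a tidy frame (masking, standard_mm, n1, pse_mm)."""
    rows = [
        {"masking": masking, "standard_mm": std, "n1": n1, "pse_mm": pse}
        for masking, stds in EXP2_PSE_MM.items()
        for std, by_n in stds.items()
        for n1, pse in by_n.items()
    ]
    return pd.DataFrame(rows)
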