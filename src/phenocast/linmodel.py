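"""Evaluation of named linear-model coefficient sets.

A coefficient set is a mapping from term labels to numbers, e.g.
``{"Intercept": 312.7, "CV": 15.1, "CV:BB": -3.5}``. Interaction terms are
colon-joined variable names and evaluate to the product of the variables.
The two published final flowering models live in :mod:`phenocast.config`
(``FULL_DATA_COEFFICIENTS`` and ``SINGLE_ORCHARD_COEFFICIENTS``).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np


def evaluate_coefficients(coefficients: Mapping[str, float], data: Mapping) -> np.ndarray | float:
    """Linear predictor of a named coefficient set at the given covariates.

    ``data`` maps variable names to scalars or equal-length arrays;
    pandas DataFrames work as-is. The ``"Intercept"`` term contributes its
    coefficient unchanged.
    """
    total = 0.0
    for term, coef in coefficients.items():
        if term == "Intercept":
            contrib = coef
        else:
            factor = 1.0
            for var in term.split(":"):
                factor = factor * np.asarray(data[var], dtype=float)
            contrib = coef * factor
        total = total + contrib
    return total


def interval_critical_value(level: float = 0.99) -> float:
    """Two-sided standard-normal critical value for a prediction interval.

    At the 99% level this is 2.576 (to three decimals).
    """
    from scipy.stats import norm

    return float(norm.ppf(0.5 + level / 2.0))
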