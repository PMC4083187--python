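"""Shared fixtures and the independent Thompson-Tau oracle."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

# Two-sided Student-t critical values at alpha = 0.05 (i.e. the 0.975
# quantile) for 1..48 degrees of freedom, from standard t tables.  Kept
# explicit so the oracle shares nothing with the implementation under test.
T_CRIT_975 = (
    12.706205, 4.302653, 3.182446, 2.776445, 2.570582, 2.446912,
    2.364624, 2.306004, 2.262157, 2.228139, 2.200985, 2.178813,
    2.160369, 2.144787, 2.13145, 2.119905, 2.109816, 2.100922,
    2.093024, 2.085963, 2.079614, 2.073873, 2.068658, 2.063899,
    2.059539, 2.055529, 2.051831, 2.048407, 2.04523, 2.042272,
    2.039513, 2.036933, 2.034515, 2.032245, 2.030108, 2.028094,
    2.026192, 2.024394, 2.022691, 2.021075, 2.019541, 2.018082,
    2.016692, 2.015368, 2.014103, 2.012896, 2.011741, 2.010635,
)


def thompson_tau_oracle(values) -> tuple[list, list]:
    """Brute-force modified Thompson Tau: explicit loop, explicit t-table.

    One removal per pass: drop the point with the largest absolute
    deviation from the mean (on ties, the largest value) when it exceeds
    tau * SD, with tau = t * (n-1) / (sqrt(n) * sqrt(n-2+t^2)) and t the
    two-sided 5% critical value on n-2 degrees of freedom.  Supports
    n up to 50 (the t-table's reach).
    """
    working = [(float(v), i) for i, v in enumerate(values)]
    removed = []
    if len(working) < 3:
        return [v for v, _ in working], removed
    while len(working) >= 3:
        n = len(working)
        mean = sum(v for v, _ in working) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v, _ in working) / (n - 1))
        if sd == 0.0:
            break
        best_dev, best_pos = -1.0, -1
        for pos, (v, _) in enumerate(working):
            dev = abs(v - mean)
            if dev > best_dev or (dev == best_dev
                                  and v > working[best_pos][0]):
                best_dev, best_pos = dev, pos
        t = T_CRIT_975[n - 2 - 1]
        tau = t * (n - 1) / (math.sqrt(n) * math.sqrt(n - 2 + t * t))
        if best_dev > tau * sd:
            removed.append(working[best_pos][1])
            del working[best_pos]
        else:
            break
    return [v for v, _ in working], removed


@pytest.fixture
def toy_comet_df() -> pd.DataFrame:
    """A tiny deterministic per-comet table: one sample, 4 comets/group."""
    rows = []
    tails = {"control": [2.0, 3.0, 2.5, 2.1],
             "HpaII": [40.0, 42.0, 39.5, 41.0],
             "MspI": [80.0, 78.0, 81.0, 79.5]}
    for treatment, values in tails.items():
        for i, v in enumerate(values):
            rows.append({"sample_id": "toy", "condition": "untreated",
                         "well": i % 2 + 1, "cell_id": i + 1,
                         "treatment": treatment, "tail_intensity": v})
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
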