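"""Statistical comparison of accuracy maps across train/test conditions.

Across-sample accuracies of different (training sample, test sample)
conditions are compared with independent two-sample t-tests over the
top-fraction parcel accuracies, treating parcels as independent
observations (the spatial dependence between parcels is a known caveat
of this convention and is documented, not corrected). Significance is
Bonferroni-gated per comparison family: each family of m tests uses the
threshold alpha / m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateDataError

__all__ = [
    "TTestResult",
    "ComparisonResult",
    "ttest_independent",
    "bonferroni_gate",
    "compare_condition_families",
]


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


@dataclass
class ComparisonResult:
    """One pairwise condition comparison inside a Bonferroni family."""

    family: str
    condition_a: str
    condition_b: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    family_size: int
    gate: float
    significant: bool


def ttest_independent(a, b, welch: bool = False) -> TTestResult:
    """Two-sample t-test; equal-variance (pooled) by default.

    The t statistic is positive when mean(a) > mean(b). With the pooled
    form df = n_a + n_b - 2; ``welch=True`` switches to the unequal-
    variance form with Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("each group needs >= 2 values")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant groups: no evidence of a difference
            df = a.size + b.size - 2
            return TTestResult(0.0, float(df), 1.0)
        raise DegenerateDataError("zero pooled variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
    else:
        df = a.size + b.size - 2
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def bonferroni_gate(
    p_values: Sequence[float], family_size: int, alpha: float = 0.05
) -> list[bool]:
    """Per-test significance flags at the family-corrected level alpha/m."""
    p_values = list(p_values)
    if family_size < 1:
        raise ConfigurationError("family_size must be >= 1")
    if family_size < len(p_values):
        raise ConfigurationError(
            f"family_size {family_size} smaller than number of tests "
            f"{len(p_values)}"
        )
    gate = alpha / family_size
    return [float(p) < gate for p in p_values]


def compare_condition_families(
    tile: Mapping[str, Sequence[float]],
    families: Mapping[str, Sequence[tuple[str, str]]],
    alpha: float = 0.05,
    welch: bool = False,
    on_degenerate: str = "raise",
) -> pd.DataFrame:
    """All pairwise t-tests of named condition families.

    Parameters
    ----------
    tile : mapping from condition label to its accuracy vector (the
        top-fraction parcel accuracies of one (train, eval) condition).
    families : mapping from family name to the list of (a, b) condition
        pairs tested in that family; each family is Bonferroni-gated at
        alpha / len(pairs).
    on_degenerate : "raise" (default) propagates zero-variance errors;
        "nan" records the pair with NaN statistics and significant=False
        (useful when small maps saturate).

    Returns a DataFrame with columns
    family, cond_a, cond_b, t, df, p, gate, significant.
    """
    if on_degenerate not in ("raise", "nan"):
        raise ConfigurationError("on_degenerate must be 'raise' or 'nan'")
    rows = []
    for family, pairs in families.items():
        pairs = list(pairs)
        m = len(pairs)
        if m == 0:
            continue
        gate = alpha / m
        for cond_a, cond_b in pairs:
            for cond in (cond_a, cond_b):
                if cond not in tile:
                    raise ConfigurationError(
                        f"unknown condition {cond!r} in family {family!r}"
                    )
            try:
                t, df, p = ttest_independent(
                    tile[cond_a], tile[cond_b], welch=welch
                )
            except DegenerateDataError:
                if on_degenerate == "raise":
                    raise
                t = df = p = float("nan")
            rows.append(
                {
                    "family": family,
                    "cond_a": cond_a,
                    "cond_b": cond_b,
                    "t": t,
                    "df": df,
                    "p": p,
                    "gate": gate,
                    "significant": p < gate,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "family", "cond_a", "cond_b", "t", "df", "p", "gate", "significant",
        ],
    )
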