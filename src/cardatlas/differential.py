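"""Two-condition differential protein analysis.

Per feature, an unpaired two-sample t-test between case and control samples at
a configurable alpha (default 0.05, raw p — no multiplicity gate, mirroring
small-cohort practice where an FDR cut would discard most biology; a
Benjamini-Hochberg column is emitted for transparency). Student's pooled-
variance t is the default, Welch's unequal-variance t behind a flag. Values
are log2-transformed before testing unless the input is already on a log
scale (``log_input=True``), since lognormal-like abundance noise is variance-
stabilised by the log.

Degenerate features are handled explicitly rather than propagating NaN: zero
variance in both groups with equal means gives t = 0, p = 1; zero variance
with unequal means gives p = 0 with a ``degenerate`` flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import benjamini_hochberg
from .matrix import QuantMatrix

__all__ = ["differential_expression"]


class DifferentialError(ValueError):
    pass


def differential_expression(
    matrix: QuantMatrix,
    case,
    control,
    alpha: float = 0.05,
    log_input: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Unpaired t-test of case vs control samples for every feature.

    Returns one row per feature: group means (log2 scale), log2 fold-change
    (case minus control), t statistic, degrees of freedom, two-sided p,
    BH-adjusted p, ``significant`` (p < alpha) and ``degenerate`` flags.
    Missing values are dropped per feature; a feature must keep >= 2 samples
    per group or an error names it.
    """
    case, control = list(case), list(control)
    for name, s in (("case", case), ("control", control)):
        absent = [x for x in s if x not in matrix.values.columns]
        if absent:
            raise DifferentialError(f"{name} sample(s) not in matrix: {absent}")
        if len(s) < 2:
            raise DifferentialError(f"{name} group needs >= 2 samples")
    x = matrix.values[case].to_numpy(dtype=float)
    y = matrix.values[control].to_numpy(dtype=float)
    if not log_input:
        if np.nanmin(x, initial=np.inf) <= 0 or np.nanmin(y, initial=np.inf) <= 0:
            raise DifferentialError(
                "nonpositive values cannot be log2-transformed; impute first or "
                "pass log_input=True"
            )
        x, y = np.log2(x), np.log2(y)

    n1 = np.sum(np.isfinite(x), axis=1)
    n2 = np.sum(np.isfinite(y), axis=1)
    bad = np.flatnonzero((n1 < 2) | (n2 < 2))
    if bad.size:
        feat = matrix.values.index[bad[0]]
        raise DifferentialError(
            f"feature {feat!r} has < 2 observed samples in a group"
        )
    m1 = np.nanmean(x, axis=1)
    m2 = np.nanmean(y, axis=1)
    v1 = np.nanvar(x, axis=1, ddof=1)
    v2 = np.nanvar(y, axis=1, ddof=1)
    diff = m1 - m2

    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            t = diff / np.sqrt(se2)
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            df = (n1 + n2 - 2).astype(float)
            t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))

    zero_var = (v1 == 0) & (v2 == 0)
    degenerate = zero_var & (diff != 0)
    flat = zero_var & (diff == 0)
    p = np.where(
        flat, 1.0,
        np.where(degenerate, 0.0, 2.0 * stats.t.sf(np.abs(t), df)),
    )
    t = np.where(flat, 0.0, t)
    if welch:
        df = np.where(zero_var, np.nan, df)

    out = pd.DataFrame(
        {
            "feature": matrix.values.index,
            "mean_case": m1,
            "mean_control": m2,
            "log2fc": diff,
            "t": t,
            "df": df,
            "p_value": p,
            "p_bh": benjamini_hochberg(p),
            "significant": p < alpha,
            "degenerate": degenerate,
        }
    ).set_index("feature")
    return out
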