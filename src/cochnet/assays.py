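"""Wet-lab summary statistics: relative qPCR quantification and viability.

These are the two closed-form summaries used to validate network predictions
in vitro: the 2**(-ddCt) relative expression fold change against a reference
gene (GAPDH-role) and a control condition, and the background-corrected
relative cell viability from plate-reader optical densities.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import ValidationError


def _mean_ct(value, name: str) -> float:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if np.any(arr <= 0):
        raise ValidationError(f"{name}: Ct values must be positive")
    return float(arr.mean())


def delta_delta_ct(ct_target_trt, ct_ref_trt, ct_target_ctl, ct_ref_ctl) -> float:
    """Fold change 2**(-ddCt).

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control).

    Scalars or replicate arrays are accepted; replicate Ct values are
    averaged before the subtraction (the standard workflow).
    """
    tt = _mean_ct(ct_target_trt, "ct_target_trt")
    rt = _mean_ct(ct_ref_trt, "ct_ref_trt")
    tc = _mean_ct(ct_target_ctl, "ct_target_ctl")
    rc = _mean_ct(ct_ref_ctl, "ct_ref_ctl")
    ddct = (tt - rt) - (tc - rc)
    return float(2.0 ** (-ddct))


def relative_viability(od_exp, od_pos, od_neg) -> tuple[float, bool]:
    """(OD_exp - OD_pos) / (OD_neg - OD_pos) x 100.

    OD_pos is the no-cell (background) control and OD_neg the untreated
    100%-viability control.  The value may leave [0, 100]; it is reported
    as-is with an out-of-range flag rather than clipped.
    """
    od_exp, od_pos, od_neg = (float(np.mean(v)) for v in (od_exp, od_pos, od_neg))
    if od_neg == od_pos:
        raise ValidationError("OD_negative equals OD_positive: zero dynamic range")
    pct = (od_exp - od_pos) / (od_neg - od_pos) * 100.0
    return pct, not (0.0 <= pct <= 100.0)


def two_sided_ttest(a, b) -> tuple[float, float]:
    """Plain two-sided two-sample t-test helper for assay group comparisons."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
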