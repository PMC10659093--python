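"""Survey-weighted prevalence with simplified design-based standard errors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PrevalenceEstimate:
    definition: str
    weighted_prevalence: float  # percent
    standard_error: float  # percent
    n: int


def weighted_prevalence(
    cohort: pd.DataFrame, statuses: pd.DataFrame, definition_name: str
) -> PrevalenceEstimate:
    """Weighted proportion meeting a definition, with a stratified Taylor SE.

    The point estimate is the Horvitz-Thompson ratio ``sum(w*y)/sum(w)``.
    The variance is the with-replacement stratified Taylor linearization of
    the ratio estimator: with ``z_i = w_i*(y_i - p)``,

        var(p) = sum_h n_h/(n_h-1) * sum_i (z_hi - mean_h(z))^2 / (sum w)^2.

    This is a simplified design-based SE (first-stage sampling only).
    """
    w = cohort["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    y = statuses[definition_name].to_numpy(dtype=bool).astype(float)
    strata = cohort["stratum_id"].to_numpy()
    total_w = w.sum()
    p = float(np.dot(w, y) / total_w)
    z = w * (y - p)
    var = 0.0
    for h in np.unique(strata):
        zh = z[strata == h]
        nh = len(zh)
        if nh > 1:
            var += nh / (nh - 1) * float(((zh - zh.mean()) ** 2).sum())
    var /= total_w**2
    return PrevalenceEstimate(
        definition=definition_name,
        weighted_prevalence=100.0 * p,
        standard_error=100.0 * float(np.sqrt(var)),
        n=len(cohort),
    )
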