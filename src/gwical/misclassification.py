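"""Disease-misclassification correction and intrinsic-specificity calibration.

Symptom-questionnaire case definitions misclassify some non-cases as cases.
Mixing false positives (whose exposure prevalence is that of non-cases,
``p_C``) into the case group dilutes the exposure odds ratios and biases the
RERI of a gene-environment interaction toward zero.  With the control group
fixed (it is assumed to contain no true cases), each genotype stratum's 2x2
table can be corrected for a hypothesised specificity ``Sp``:

    a' = G*Sp*p_R + G*(1-Sp)*p_C          (exposed cases)
    b' = G*Sp*(1-p_R) + G*(1-Sp)*(1-p_C)  (unexposed cases)
    c' = N_C*p_C                          (exposed controls)
    d' = N_C*(1-p_C)                      (unexposed controls)

where ``G`` is the number of subjects the definition classifies as cases,
``N_C`` the common control count, and ``p_R`` the exposure prevalence of true
cases (taken from the perfectly specific reference definition's cases).
``Sp`` here operates as the fraction of diagnosed cases that are true cases.
Sweeping ``Sp`` downward from 1 dilutes the corrected RERI monotonically
(when ``p_R > p_C``); the specificity at which the corrected RERI equals the
RERI computed directly from the biased data is the definition's *intrinsic
specificity*.  Sensitivities then follow from the definitions' population
prevalences via the identity ``true-positive prevalence = diagnosed
prevalence x Sp``, with the perfectly sensitive reference definition
anchoring the true-case prevalence.

Under perfect specificity, nondifferential sensitivity losses remove true
cases at random, leaving the exposure distribution of the case group — and
hence the odds ratios and the RERI — unchanged; the correction equations
therefore contain no sensitivity term.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interaction import FourByTwoTable, InteractionEstimate, crude_interaction_estimate

logger = logging.getLogger(__name__)


@dataclass
class MisclassInputs:
    """Inputs of the correction for one genotype stratum."""

    g: float  # number classified as cases by the definition
    n_controls: float  # common control count in this stratum
    p_r: float  # exposure prevalence in true cases (reference definition)
    p_c: float  # exposure prevalence in controls

    def __post_init__(self):
        if self.g < 0 or self.n_controls < 0:
            raise ValueError("counts must be nonnegative")
        for name in ("p_r", "p_c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a proportion")
        if self.p_c > self.p_r:
            logger.warning(
                "p_C (%.3f) exceeds p_R (%.3f): exposure is not enriched in "
                "true cases; the corrected RERI will not be monotone in Sp",
                self.p_c,
                self.p_r,
            )


@dataclass
class CorrectedTable:
    """Misclassification-corrected 2x2 cells (fractional counts allowed)."""

    a: float
    b: float
    c: float
    d: float


@dataclass
class CalibrationResult:
    """Outcome of matching corrected to biased RERI over specificity."""

    definition: str
    intrinsic_specificity: float
    biased_reri: float
    converged: bool
    tolerance: float
    corrected_reri_curve: list[tuple[float, float]] = field(default_factory=list)


def _check_sp(specificity: float) -> None:
    if not 0.0 < specificity <= 1.0:
        raise ValueError(f"specificity {specificity} outside (0, 1]")


def _check_se(sensitivity: float) -> None:
    if not 0.0 < sensitivity <= 1.0:
        raise ValueError(f"sensitivity {sensitivity} outside (0, 1]")


def correct_table(inputs: MisclassInputs, specificity: float) -> CorrectedTable:
    """Apply the correction equations to one stratum at a given specificity.

    At ``Sp = 1`` the false-positive term drops out and ``a' = G * p_R``
    exactly; controls never change.
    """
    _check_sp(specificity)
    g, sp = inputs.g, specificity
    a = g * sp * inputs.p_r + g * (1.0 - sp) * inputs.p_c
    b = g * sp * (1.0 - inputs.p_r) + g * (1.0 - sp) * (1.0 - inputs.p_c)
    c = inputs.n_controls * inputs.p_c
    d = inputs.n_controls * (1.0 - inputs.p_c)
    return CorrectedTable(a=a, b=b, c=c, d=d)


def corrected_four_by_two(
    inputs_qq: MisclassInputs, inputs_rr: MisclassInputs, specificity: float
) -> FourByTwoTable:
    qq = correct_table(inputs_qq, specificity)
    rr = correct_table(inputs_rr, specificity)
    return FourByTwoTable(
        a_qq=qq.a, b_qq=qq.b, c_qq=qq.c, d_qq=qq.d,
        a_rr=rr.a, b_rr=rr.b, c_rr=rr.c, d_rr=rr.d,
    )


def corrected_reri(
    inputs_qq: MisclassInputs,
    inputs_rr: MisclassInputs,
    specificity: float,
    sensitivity: float = 1.0,
) -> float:
    """Crude RERI from the corrected cells (QQ-unexposed reference).

    ``sensitivity`` is accepted for completeness of the sensitivity-analysis
    grid but never enters the cell arithmetic: nondifferential sensitivity
    rescales the true-case counts uniformly and cancels from the odds
    ratios, so the corrected RERI is identical for any assumed value.
    """
    _check_se(sensitivity)
    table = corrected_four_by_two(inputs_qq, inputs_rr, specificity)
    zeros = table.zero_cells()
    if zeros:
        raise ValueError(
            f"corrected cell(s) {', '.join(zeros)} are zero; consider a "
            "continuity correction or a narrower specificity bracket"
        )
    or10, or01, or11 = table.odds_ratios()
    return or11 - or10 - or01 + 1.0


def corrected_interaction(
    inputs_qq: MisclassInputs,
    inputs_rr: MisclassInputs,
    specificity: float,
    alpha: float = 0.05,
) -> InteractionEstimate:
    """Corrected RERI with an approximate MOVER CI.

    The fractional corrected cells are treated as counts in the crude-OR
    covariance formula; the interval is approximate and cannot be adjusted
    for confounding.
    """
    table = corrected_four_by_two(inputs_qq, inputs_rr, specificity)
    return crude_interaction_estimate(table, alpha=alpha)


def specificity_grid(
    inputs_qq: MisclassInputs,
    inputs_rr: MisclassInputs,
    specificities,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sensitivity-analysis grid: corrected RERI (with approximate CI) per Sp."""
    rows = []
    for sp in specificities:
        est = corrected_interaction(inputs_qq, inputs_rr, sp, alpha=alpha)
        rows.append(
            {
                "se": 1.0,
                "sp": sp,
                "corrected_reri": est.reri,
                "ci_lower": est.reri_ci[0],
                "ci_upper": est.reri_ci[1],
            }
        )
    return pd.DataFrame(rows)


def find_intrinsic_specificity(
    inputs_qq: MisclassInputs,
    inputs_rr: MisclassInputs,
    biased_reri: float,
    bracket: tuple[float, float] = (0.5, 1.0),
    tol: float = 1e-4,
    max_iter: int = 100,
    definition: str = "",
) -> CalibrationResult:
    """Bisect on specificity until the corrected RERI equals the biased RERI.

    Requires the biased RERI to lie between the corrected RERIs at the
    bracket ends (the corrected RERI is monotone increasing in Sp whenever
    p_R > p_C in both strata).  If the corrected RERI at Sp = 1 already
    equals the biased value within tolerance, the definition's specificity
    is perfect and Sp* = 1 is returned directly.
    """
    lo, hi = bracket
    _check_sp(lo)
    _check_sp(hi)
    if lo >= hi:
        raise ValueError("bracket must satisfy lo < hi")
    curve: list[tuple[float, float]] = []

    def f(sp: float) -> float:
        val = corrected_reri(inputs_qq, inputs_rr, sp)
        curve.append((sp, val))
        return val - biased_reri

    f_lo, f_hi = f(lo), f(hi)
    if abs(f_hi) <= tol:
        return CalibrationResult(
            definition, hi, biased_reri, True, tol, sorted(curve)
        )
    if abs(f_lo) <= tol:
        return CalibrationResult(
            definition, lo, biased_reri, True, tol, sorted(curve)
        )
    if f_lo * f_hi > 0:
        raise ValueError(
            "biased RERI outside attainable range: corrected RERI spans "
            f"[{f_lo + biased_reri:.4g}, {f_hi + biased_reri:.4g}] over the "
            f"bracket but the biased value is {biased_reri:.4g}"
        )
    converged = False
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        # require both the residual and the specificity interval to be small:
        # on nearly flat stretches of the curve the residual alone would stop
        # far from the matching specificity
        if abs(f_mid) <= tol and (hi - lo) <= tol:
            converged = True
            break
        if f_lo * f_mid < 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return CalibrationResult(
        definition, mid, biased_reri, converged, tol, sorted(curve)
    )


# ---------------------------------------------------------------------------
# Sensitivity estimation from prevalences (spreadsheet arithmetic)
# ---------------------------------------------------------------------------


def estimate_sesp_summary(
    prev_diagnosed: dict[str, float],
    specificity: dict[str, float],
    reference_definition: str,
    perfect_sensitivity: set[str],
    perfect_specificity: set[str] = frozenset(),
) -> pd.DataFrame:
    """Sensitivities and misclassification consequences per definition.

    ``prev_diagnosed`` holds population prevalences in percent.  For every
    definition, the true-positive prevalence is ``prev * Sp`` (unrounded);
    sensitivity is its ratio to the reference definition's true-positive
    prevalence (the reference must belong to the perfect-sensitivity set, so
    its true positives are all the true cases).  Percent false-positive
    share is ``100*(1-Sp)``; percent of true cases falsely negative is
    ``100*(1-Se)``.  All intermediates stay unrounded; use
    :func:`format_sesp` for presentation rounding.
    """
    if reference_definition not in perfect_sensitivity:
        raise ValueError("reference definition must have perfect sensitivity")
    for name, p in prev_diagnosed.items():
        if not 0.0 <= p <= 100.0:
            raise ValueError(f"prevalence for {name!r} must be in [0, 100] percent")
    sp = {
        name: 1.0 if name in perfect_specificity else specificity[name]
        for name in prev_diagnosed
    }
    tp_prev = {name: prev_diagnosed[name] * sp[name] for name in prev_diagnosed}
    ref_tp = tp_prev[reference_definition]
    if ref_tp == 0:
        raise ValueError("reference definition has zero true-positive prevalence")
    rows = []
    for name in prev_diagnosed:
        se = 1.0 if name in perfect_sensitivity else tp_prev[name] / ref_tp
        rows.append(
            {
                "definition": name,
                "sensitivity": se,
                "specificity": sp[name],
                "prev_diagnosed": prev_diagnosed[name],
                "prev_true_positive": tp_prev[name],
                "pct_diagnosed_false_positive": 100.0 * (1.0 - sp[name]),
                "pct_true_cases_false_negative": 100.0 * (1.0 - se),
            }
        )
    return pd.DataFrame(rows).set_index("definition")


def format_sesp(summary: pd.DataFrame) -> pd.DataFrame:
    """Presentation rounding: Se/Sp to 2 d.p., percentages to 1 d.p."""
    out = summary.copy()
    for col in ("sensitivity", "specificity"):
        out[col] = out[col].round(2)
    for col in (
        "prev_diagnosed",
        "prev_true_positive",
        "pct_diagnosed_false_positive",
        "pct_true_cases_false_negative",
    ):
        out[col] = out[col].round(1)
    return out


def misclass_inputs_from_tables(
    reference_table: FourByTwoTable, definition_table: FourByTwoTable
) -> tuple[MisclassInputs, MisclassInputs]:
    """Derive per-stratum correction inputs from scored 4x2 tables.

    ``p_R`` per genotype stratum comes from the reference (perfectly
    specific) definition's cases in that stratum; ``p_C`` from the common
    controls; ``G`` from the definition under correction.
    """
    def stratum(ref_a, ref_b, def_a, def_b, c, d):
        g = def_a + def_b
        n_c = c + d
        p_r = ref_a / (ref_a + ref_b) if (ref_a + ref_b) > 0 else float("nan")
        p_c = c / n_c if n_c > 0 else float("nan")
        return MisclassInputs(g=g, n_controls=n_c, p_r=p_r, p_c=p_c)

    qq = stratum(
        reference_table.a_qq,
        reference_table.b_qq,
        definition_table.a_qq,
        definition_table.b_qq,
        definition_table.c_qq,
        definition_table.d_qq,
    )
    rr = stratum(
        reference_table.a_rr,
        reference_table.b_rr,
        definition_table.a_rr,
        definition_table.b_rr,
        definition_table.c_rr,
        definition_table.d_rr,
    )
    return qq, rr
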