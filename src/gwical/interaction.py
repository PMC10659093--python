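"""Additive and multiplicative gene-environment interaction estimation.

The analysis follows the Knol-VanderWeele presentation: cases and controls
are cross-classified by binary exposure within two genotype strata (QQ
reference, RR index) in a 4x2 table with the QQ-unexposed cell as the single
reference category.  Additive interaction is measured by the relative excess
risk due to interaction,

    RERI = OR11 - OR10 - OR01 + 1,

with asymmetric confidence limits by the method of variance estimates
recovery (MOVER): Wald limits for the three odds ratios on the log scale are
recombined using their estimated pairwise correlations.  Multiplicative
interaction is the prevalence odds ratio (POR), the exponentiated
interaction coefficient of the logistic model, with a Wald CI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

_CELL_NAMES = ("a_qq", "b_qq", "c_qq", "d_qq", "a_rr", "b_rr", "c_rr", "d_rr")


@dataclass
class FourByTwoTable:
    """Case/control x exposed/unexposed counts in the QQ and RR strata.

    ``a`` = exposed cases, ``b`` = unexposed cases, ``c`` = exposed controls,
    ``d`` = unexposed controls.  Fractional counts are allowed (they arise
    from misclassification correction).
    """

    a_qq: float
    b_qq: float
    c_qq: float
    d_qq: float
    a_rr: float
    b_rr: float
    c_rr: float
    d_rr: float

    def __post_init__(self):
        for name in _CELL_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")

    def cells(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _CELL_NAMES}

    def zero_cells(self) -> list[str]:
        return [name for name, v in self.cells().items() if v == 0]

    def odds_ratios(self) -> tuple[float, float, float]:
        """(OR10, OR01, OR11) against the QQ-unexposed reference."""
        ref = self.b_qq / self.d_qq
        or10 = (self.b_rr / self.d_rr) / ref
        or01 = (self.a_qq / self.c_qq) / ref
        or11 = (self.a_rr / self.c_rr) / ref
        return or10, or01, or11

    def with_continuity(self, k: float = 0.5) -> "FourByTwoTable":
        return FourByTwoTable(**{n: v + k for n, v in self.cells().items()})


@dataclass
class InteractionEstimate:
    """The three relative effects, RERI with asymmetric CI, and the POR."""

    or_10: float
    or_01: float
    or_11: float
    reri: float
    reri_ci: tuple[float, float]
    por: float | None = None
    por_ci: tuple[float, float] | None = None
    adjusted: bool = False
    covariate_list: tuple[str, ...] = ()
    alpha: float = 0.05
    scale: str = "odds-ratio"

    def to_dict(self) -> dict:
        return {
            "or_10": self.or_10,
            "or_01": self.or_01,
            "or_11": self.or_11,
            "reri": self.reri,
            "reri_ci": list(self.reri_ci),
            "por": self.por,
            "por_ci": list(self.por_ci) if self.por_ci else None,
            "adjusted": self.adjusted,
            "covariate_list": list(self.covariate_list),
            "alpha": self.alpha,
            "scale": self.scale,
        }


@dataclass
class InteractionFit:
    """Logistic-fit output needed for downstream CI construction."""

    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    n_cases: int
    n_controls: int
    covariates: tuple[str, ...] = ()

    TERMS = ("gene", "exposure", "gene_x_exposure")

    def core(self) -> tuple[np.ndarray, np.ndarray]:
        """(b, cov) restricted to the gene, exposure and interaction terms."""
        terms = list(self.TERMS)
        b = self.params[terms].to_numpy(dtype=float)
        v = self.cov.loc[terms, terms].to_numpy(dtype=float)
        return b, v


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------


def build_four_by_two(
    cohort: pd.DataFrame,
    statuses: pd.DataFrame,
    definition_name: str,
    exclude_definition: str | None = None,
    case_col: str | None = None,
) -> FourByTwoTable:
    """Tally the genotype-stratified 2x2 tables for one case definition.

    Cases satisfy ``definition_name`` (minus those satisfying
    ``exclude_definition``, for "not research"-style subsets); controls
    satisfy no definition; QR heterozygotes are excluded.  ``case_col``
    bypasses the scored statuses and uses a boolean cohort column (e.g. the
    synthetic latent truth) as the case state, with controls its complement.
    """
    genotype = cohort["genotype"].to_numpy()
    exposed = cohort["heard_alarms"].to_numpy(dtype=bool)
    if case_col is not None:
        cases = cohort[case_col].to_numpy(dtype=bool)
        controls = ~cases
    else:
        cases = statuses[definition_name].to_numpy(dtype=bool)
        if exclude_definition is not None:
            cases = cases & ~statuses[exclude_definition].to_numpy(dtype=bool)
        controls = statuses["is_control"].to_numpy(dtype=bool)
    if not cases.any():
        raise ValueError(f"no cases for definition {definition_name!r}")
    if not controls.any():
        raise ValueError("no controls (subjects meeting no definition)")

    def cell(case, exp, geno):
        m = (genotype == geno) & (exposed == exp) & (cases if case else controls)
        return float(m.sum())

    table = FourByTwoTable(
        a_qq=cell(True, True, "QQ"),
        b_qq=cell(True, False, "QQ"),
        c_qq=cell(False, True, "QQ"),
        d_qq=cell(False, False, "QQ"),
        a_rr=cell(True, True, "RR"),
        b_rr=cell(True, False, "RR"),
        c_rr=cell(False, True, "RR"),
        d_rr=cell(False, False, "RR"),
    )
    zeros = table.zero_cells()
    if zeros:
        logger.warning(
            "4x2 table for %s has empty cells: %s", definition_name, ", ".join(zeros)
        )
    return table


# ---------------------------------------------------------------------------
# MOVER recombination (Zou-style asymmetric CI for a difference of ORs)
# ---------------------------------------------------------------------------


def _mover_reri(log_est: np.ndarray, log_cov: np.ndarray, alpha: float):
    """RERI and MOVER CI from log-scale (OR11, OR10, OR01) estimates.

    ``log_est`` and ``log_cov`` are the point estimates and covariance of
    (log OR11, log OR10, log OR01).  Individual Wald limits on the log scale
    are recombined on the natural scale with the estimated correlations.
    """
    try:
        np.linalg.cholesky(log_cov + 1e-12 * np.eye(3))
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(np.diag(log_cov))
    theta = np.exp(log_est)
    lo = np.exp(log_est - z * se)
    hi = np.exp(log_est + z * se)
    denom = np.outer(se, se)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, log_cov / np.where(denom > 0, denom, 1.0), 0.0)
    t1, t2, t3 = theta
    l1, l2, l3 = lo
    u1, u2, u3 = hi
    r12, r13, r23 = r[0, 1], r[0, 2], r[1, 2]
    reri = t1 - t2 - t3 + 1.0
    low_sq = (
        (t1 - l1) ** 2
        + (u2 - t2) ** 2
        + (u3 - t3) ** 2
        - 2 * r12 * (t1 - l1) * (u2 - t2)
        - 2 * r13 * (t1 - l1) * (u3 - t3)
        + 2 * r23 * (u2 - t2) * (u3 - t3)
    )
    upp_sq = (
        (u1 - t1) ** 2
        + (t2 - l2) ** 2
        + (t3 - l3) ** 2
        - 2 * r12 * (u1 - t1) * (t2 - l2)
        - 2 * r13 * (u1 - t1) * (t3 - l3)
        + 2 * r23 * (t2 - l2) * (t3 - l3)
    )
    lower = reri - math.sqrt(max(low_sq, 0.0))
    upper = reri + math.sqrt(max(upp_sq, 0.0))
    return reri, (lower, upper), (t2, t3, t1)


def reri_with_mover_ci(
    params, cov, alpha: float = 0.05, adjusted: bool = False,
    covariate_list: tuple[str, ...] = (),
) -> InteractionEstimate:
    """RERI point estimate and MOVER CI from a logistic fit.

    ``params``/``cov`` must carry the ``gene``, ``exposure`` and
    ``gene_x_exposure`` terms (a :class:`pandas.Series` / DataFrame, or the
    3-vector and 3x3 covariance in that order).  The point estimate is
    ``exp(b1+b2+b3) - exp(b1) - exp(b2) + 1``.
    """
    if isinstance(params, pd.Series):
        terms = list(InteractionFit.TERMS)
        b = params[terms].to_numpy(dtype=float)
        v = (
            cov.loc[terms, terms].to_numpy(dtype=float)
            if isinstance(cov, pd.DataFrame)
            else np.asarray(cov, dtype=float)
        )
    else:
        b = np.asarray(params, dtype=float)
        v = np.asarray(cov, dtype=float)
    # Linear combinations giving (log OR11, log OR10, log OR01).
    w = np.array([[1.0, 1.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    log_est = w @ b
    log_cov = w @ v @ w.T
    reri, ci, (or10, or01, or11) = _mover_reri(log_est, log_cov, alpha)
    por, por_ci = por_from_fit(b, v, alpha)
    return InteractionEstimate(
        or_10=or10,
        or_01=or01,
        or_11=or11,
        reri=reri,
        reri_ci=ci,
        por=por,
        por_ci=por_ci,
        adjusted=adjusted,
        covariate_list=tuple(covariate_list),
        alpha=alpha,
    )


def por_from_fit(params, cov, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Prevalence odds ratio (exp of the interaction coefficient), Wald CI."""
    if isinstance(params, pd.Series):
        b3 = float(params["gene_x_exposure"])
        se = math.sqrt(float(cov.loc["gene_x_exposure", "gene_x_exposure"]))
    else:
        b = np.asarray(params, dtype=float)
        v = np.asarray(cov, dtype=float)
        b3 = float(b[2])
        se = math.sqrt(float(v[2, 2]))
    por = math.exp(b3)
    if se == 0:
        logger.warning("interaction coefficient has zero SE; CI is degenerate")
        return por, (por, por)
    z = stats.norm.ppf(1 - alpha / 2)
    return por, (math.exp(b3 - z * se), math.exp(b3 + z * se))


def crude_interaction_estimate(
    table: FourByTwoTable, alpha: float = 0.05, continuity: float = 0.0
) -> InteractionEstimate:
    """Closed-form crude RERI/POR from the 4x2 cell counts.

    A continuity constant is added to every cell only when explicitly
    requested; zero cells otherwise raise.
    """
    if continuity:
        table = table.with_continuity(continuity)
    zeros = table.zero_cells()
    if zeros:
        raise ValueError(
            f"zero cells {', '.join(zeros)}; enable a continuity correction"
        )
    c = table.cells()
    inv = {k: 1.0 / v for k, v in c.items()}
    log11 = math.log((c["a_rr"] / c["c_rr"]) / (c["b_qq"] / c["d_qq"]))
    log10 = math.log((c["b_rr"] / c["d_rr"]) / (c["b_qq"] / c["d_qq"]))
    log01 = math.log((c["a_qq"] / c["c_qq"]) / (c["b_qq"] / c["d_qq"]))
    ref = inv["b_qq"] + inv["d_qq"]
    v11 = inv["a_rr"] + inv["c_rr"] + ref
    v10 = inv["b_rr"] + inv["d_rr"] + ref
    v01 = inv["a_qq"] + inv["c_qq"] + ref
    log_cov = np.array([[v11, ref, ref], [ref, v10, ref], [ref, ref, v01]])
    log_est = np.array([log11, log10, log01])
    reri, ci, (or10, or01, or11) = _mover_reri(log_est, log_cov, alpha)
    b3 = log11 - log10 - log01
    se3 = math.sqrt(sum(inv.values()))
    z = stats.norm.ppf(1 - alpha / 2)
    return InteractionEstimate(
        or_10=or10,
        or_01=or01,
        or_11=or11,
        reri=reri,
        reri_ci=ci,
        por=math.exp(b3),
        por_ci=(math.exp(b3 - z * se3), math.exp(b3 + z * se3)),
        adjusted=False,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Logistic regression path
# ---------------------------------------------------------------------------


def _design(cohort: pd.DataFrame, mask: np.ndarray, covariates) -> pd.DataFrame:
    g = (cohort.loc[mask, "genotype"] == "RR").astype(float)
    e = cohort.loc[mask, "heard_alarms"].astype(float)
    X = pd.DataFrame(
        {"const": 1.0, "gene": g, "exposure": e, "gene_x_exposure": g * e},
        index=cohort.index[mask],
    )
    for cov in covariates:
        col = cohort.loc[mask, cov].astype(float)
        if cov == "age":
            col = col - col.mean()  # centered for a stable intercept
        X[cov] = col
    return X


def fit_interaction_model(
    cohort: pd.DataFrame,
    statuses: pd.DataFrame,
    definition_name: str,
    covariates=(),
    exclude_definition: str | None = None,
) -> InteractionFit:
    """Maximum-likelihood logistic fit of case status on genotype, exposure
    and their product (plus covariates), QR heterozygotes excluded.

    Survey weights are deliberately not used; confounding is handled through
    covariates.
    """
    cases = statuses[definition_name].to_numpy(dtype=bool)
    if exclude_definition is not None:
        cases = cases & ~statuses[exclude_definition].to_numpy(dtype=bool)
    controls = statuses["is_control"].to_numpy(dtype=bool)
    keep = (cases | controls) & cohort["genotype"].isin(["QQ", "RR"]).to_numpy()
    y = cases[keep].astype(float)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError(f"empty case or control set for {definition_name!r}")

    table = build_four_by_two(
        cohort, statuses, definition_name, exclude_definition=exclude_definition
    )
    zeros = table.zero_cells()
    if zeros:
        raise ValueError(
            f"zero margin(s) {', '.join(zeros)} in the 4x2 table for "
            f"{definition_name!r}: logistic fit would not converge (separation)"
        )

    X = _design(cohort, keep, covariates)
    model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return InteractionFit(
        params=params,
        cov=cov,
        converged=bool(res.converged),
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        covariates=tuple(covariates),
    )


def cohort_risk_reri(
    cohort: pd.DataFrame, case_col: str = "true_case", alpha: float = 0.05
) -> InteractionEstimate:
    """Crude risk-scale RERI from full-cohort cumulative incidence.

    With cohort (rather than case-control) data the additive interaction can
    be measured directly with risk ratios: RERI = RR11 - RR10 - RR01 + 1.
    MOVER limits use log-risk-ratio variances with the shared reference-cell
    covariance.  This is the natural estimand of the synthetic generator's
    additive risk model.
    """
    genotype = cohort["genotype"].to_numpy()
    exposed = cohort["heard_alarms"].to_numpy(dtype=bool)
    case = cohort[case_col].to_numpy(dtype=bool)

    def cell(geno, exp):
        m = (genotype == geno) & (exposed == exp)
        return float(case[m].sum()), float(m.sum())

    x00, n00 = cell("QQ", False)
    x10, n10 = cell("RR", False)
    x01, n01 = cell("QQ", True)
    x11, n11 = cell("RR", True)
    for label, x, n in [
        ("QQ-unexposed", x00, n00),
        ("RR-unexposed", x10, n10),
        ("QQ-exposed", x01, n01),
        ("RR-exposed", x11, n11),
    ]:
        if n == 0 or x == 0:
            raise ValueError(f"no subjects or no cases in the {label} cell")
    ref_var = 1.0 / x00 - 1.0 / n00
    log_est = np.array(
        [
            math.log((x11 / n11) / (x00 / n00)),
            math.log((x10 / n10) / (x00 / n00)),
            math.log((x01 / n01) / (x00 / n00)),
        ]
    )
    v11 = 1.0 / x11 - 1.0 / n11 + ref_var
    v10 = 1.0 / x10 - 1.0 / n10 + ref_var
    v01 = 1.0 / x01 - 1.0 / n01 + ref_var
    log_cov = np.array(
        [[v11, ref_var, ref_var], [ref_var, v10, ref_var], [ref_var, ref_var, v01]]
    )
    reri, ci, (rr10, rr01, rr11) = _mover_reri(log_est, log_cov, alpha)
    return InteractionEstimate(
        or_10=rr10,
        or_01=rr01,
        or_11=rr11,
        reri=reri,
        reri_ci=ci,
        alpha=alpha,
        scale="risk-ratio",
    )


def heterogeneity_across_strata(
    cohort: pd.DataFrame,
    statuses: pd.DataFrame,
    definition_name: str,
    stratifier: str,
    alpha: float = 0.05,
):
    """Stratum-specific crude interaction estimates plus a likelihood-ratio
    test of RERI heterogeneity across the stratifier's levels.

    The LRT compares logistic models with and without products of the
    stratifier dummies with the gene, exposure and interaction terms.
    Strata whose 4x2 table has an empty margin are dropped with a warning.
    """
    cases = statuses[definition_name].to_numpy(dtype=bool)
    controls = statuses["is_control"].to_numpy(dtype=bool)
    keep = (cases | controls) & cohort["genotype"].isin(["QQ", "RR"]).to_numpy()
    levels = sorted(pd.unique(cohort.loc[keep, stratifier]))
    if len(levels) < 2:
        raise ValueError(f"stratifier {stratifier!r} has fewer than 2 levels")

    estimates: dict = {}
    usable = []
    for lev in levels:
        sub = cohort[stratifier].to_numpy() == lev
        try:
            tab = build_four_by_two(
                cohort[sub].reset_index(drop=True),
                statuses[sub].reset_index(drop=True),
                definition_name,
            )
            estimates[lev] = crude_interaction_estimate(tab, alpha=alpha)
            usable.append(lev)
        except ValueError as exc:
            logger.warning("dropping stratum %r: %s", lev, exc)
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable strata after dropping empty margins")

    sub = keep & cohort[stratifier].isin(usable).to_numpy()
    y = cases[sub].astype(float)
    base = _design(cohort, sub, covariates=())
    strat = cohort.loc[sub, stratifier]
    dummies = pd.get_dummies(strat, prefix=stratifier, drop_first=True).astype(float)
    reduced = pd.concat([base, dummies], axis=1)
    full = reduced.copy()
    for col in dummies.columns:
        for term in ("gene", "exposure", "gene_x_exposure"):
            full[f"{col}_x_{term}"] = dummies[col] * base[term]
    fam = sm.families.Binomial()
    res_red = sm.GLM(y, reduced.to_numpy(), family=fam).fit(maxiter=200)
    res_full = sm.GLM(y, full.to_numpy(), family=fam).fit(maxiter=200)
    lr = 2.0 * (res_full.llf - res_red.llf)
    df = 3 * (len(usable) - 1)
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    return {"estimates": estimates, "lr_stat": float(lr), "df": df, "p_value": p}
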