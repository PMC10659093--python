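"""Cohort parameters, the record schema, and the additive GxE risk model.

A cohort is held as a :class:`pandas.DataFrame`, one row per veteran, with the
columns listed in :data:`COHORT_COLUMNS`.  The generative risk model is
additive on the cumulative-incidence (risk) scale:

    risk(QQ, unexposed) = p0
    risk(RR, unexposed) = p0 * rr_genotype
    risk(QQ, exposed)   = p0 * rr_exposure
    risk(RR, exposed)   = p0 * (rr_genotype + rr_exposure - 1 + target_reri)

so that ``target_reri`` is exactly the relative excess risk due to interaction
on the risk-ratio scale.  QR heterozygotes receive an intermediate relative
risk (geometric mean of the homozygote effects by default) and a
proportionally scaled interaction excess; they are generated so that genotype
frequencies follow Hardy-Weinberg equilibrium, but downstream 4x2 analyses
contrast RR against QQ only.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

GENOTYPES = ("QQ", "QR", "RR")

#: Exclusionary comorbid conditions for the Kansas-style definition.
COMORBIDITIES = (
    "cancer",
    "diabetes",
    "heart_disease",
    "liver_disease",
    "multiple_sclerosis",
    "bipolar_disorder",
    "schizophrenia",
)

DEFAULT_COMORBIDITY_PREVS = {
    "cancer": 0.03,
    "diabetes": 0.08,
    "heart_disease": 0.05,
    "liver_disease": 0.01,
    "multiple_sclerosis": 0.003,
    "bipolar_disorder": 0.02,
    "schizophrenia": 0.005,
}

N_KANSAS = 28
N_CDC = 10

KANSAS_COLS = [f"k{i:02d}" for i in range(1, N_KANSAS + 1)]
KANSAS_6MO_COLS = [f"k{i:02d}_6mo" for i in range(1, N_KANSAS + 1)]
CDC_COLS = [f"c{i:02d}" for i in range(1, N_CDC + 1)]
CDC_6MO_COLS = [f"c{i:02d}_6mo" for i in range(1, N_CDC + 1)]

COHORT_COLUMNS = (
    ["subject_id", "genotype", "heard_alarms"]
    + KANSAS_COLS
    + KANSAS_6MO_COLS
    + CDC_COLS
    + CDC_6MO_COLS
    + list(COMORBIDITIES)
    + [
        "age",
        "sex",
        "combat_scale",
        "stratum_id",
        "weight",
        "sf12_mcs",
        "sf12_pcs",
        "research_latent",
        "true_case",
    ]
)

_BOOL_COLS = (
    ["heard_alarms"]
    + KANSAS_6MO_COLS
    + CDC_6MO_COLS
    + list(COMORBIDITIES)
    + ["research_latent", "true_case"]
)


class ParameterError(ValueError):
    """Raised when cohort parameters imply an invalid probability."""


@dataclass
class CohortParams:
    """Parameters of the synthetic deployed-veteran cohort.

    Defaults describe a deployed force of the size of the survey sample with a
    moderately common R allele, a baseline true-illness risk of 5% in
    QQ-unexposed veterans, and a strong positive additive interaction, giving
    an overall true-illness prevalence near 10%.
    """

    n_deployed: int = 6500
    r_allele_freq: float = 0.3
    baseline_risk: float = 0.05
    rr_genotype: float = 2.0
    rr_exposure: float = 3.0
    target_reri: float = 4.0
    exposure_prev_noncase: float = 0.25
    strict_sensitivity: float = 0.5
    loose_false_positive_frac: float = 0.20
    comorbidity_prevs: dict = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVS)
    )
    rr_heterozygote: float | None = None  # default: geometric mean of 1 and rr_genotype
    n_strata: int = 8
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- risk model ---------------------------------------------------------

    def heterozygote_rr(self) -> float:
        if self.rr_heterozygote is not None:
            return self.rr_heterozygote
        return math.sqrt(self.rr_genotype)

    def risk_cells(self) -> dict[tuple[str, int], float]:
        """True-illness probability for every genotype x exposure cell."""
        p0 = self.baseline_risk
        rg, re, reri = self.rr_genotype, self.rr_exposure, self.target_reri
        rq = self.heterozygote_rr()
        # QR interaction excess scaled by the heterozygote's share of the
        # genotype effect (zero when there is no genotype effect).
        if rg != 1.0:
            reri_qr = reri * (rq - 1.0) / (rg - 1.0)
        else:
            reri_qr = 0.0
        cells = {
            ("QQ", 0): p0,
            ("QR", 0): p0 * rq,
            ("RR", 0): p0 * rg,
            ("QQ", 1): p0 * re,
            ("QR", 1): p0 * (rq + re - 1.0 + reri_qr),
            ("RR", 1): p0 * (rg + re - 1.0 + reri),
        }
        return cells

    def genotype_freqs(self) -> dict[str, float]:
        q = self.r_allele_freq
        return {"QQ": (1 - q) ** 2, "QR": 2 * q * (1 - q), "RR": q**2}

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        props = {
            "r_allele_freq": self.r_allele_freq,
            "baseline_risk": self.baseline_risk,
            "exposure_prev_noncase": self.exposure_prev_noncase,
            "strict_sensitivity": self.strict_sensitivity,
            "loose_false_positive_frac": self.loose_false_positive_frac,
            **{f"comorbidity_prevs[{k}]": v for k, v in self.comorbidity_prevs.items()},
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} is not a proportion in [0, 1]")
        if self.n_deployed <= 0:
            raise ParameterError("n_deployed must be positive")
        if self.n_strata <= 0:
            raise ParameterError("n_strata must be positive")
        for cell, risk in self.risk_cells().items():
            if not 0.0 <= risk <= 1.0:
                raise ParameterError(
                    f"risk for genotype={cell[0]}, exposed={cell[1]} is {risk:.4g}, "
                    "outside [0, 1]; adjust baseline_risk / relative risks / target_reri"
                )

    # -- derived closed forms ----------------------------------------------

    def true_case_prevalence(self) -> float:
        """Marginal probability of true illness implied by the risk model."""
        cells = self.risk_cells()
        freqs = self.genotype_freqs()
        pe = self.exposure_prev_noncase
        return sum(
            freqs[g] * (pe * cells[(g, 1)] + (1 - pe) * cells[(g, 0)])
            for g in GENOTYPES
        )

    def expected_exposure_prevalences(self) -> tuple[float, float]:
        """Closed-form (p_R, p_C): exposure prevalence in true cases / non-cases.

        Bayes' rule applied to the generative direction (genotype and exposure
        drawn independently, then illness from the additive risk model).
        """
        cells = self.risk_cells()
        freqs = self.genotype_freqs()
        pe = self.exposure_prev_noncase
        p_case_and_exp = sum(freqs[g] * pe * cells[(g, 1)] for g in GENOTYPES)
        p_case = self.true_case_prevalence()
        p_noncase_and_exp = sum(
            freqs[g] * pe * (1 - cells[(g, 1)]) for g in GENOTYPES
        )
        p_r = p_case_and_exp / p_case if p_case > 0 else float("nan")
        p_c = p_noncase_and_exp / (1 - p_case) if p_case < 1 else float("nan")
        return p_r, p_c

    # -- serialisation ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortParams":
        return cls(**json.loads(Path(path).read_text()))


def write_cohort(cohort: pd.DataFrame, path: str | Path,
                 params: CohortParams | None = None) -> None:
    """Write a cohort as CSV (plus a JSON parameter sidecar if given)."""
    cohort.to_csv(path, index=False)
    if params is not None:
        params.to_json(Path(path).with_suffix(".params.json"))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV back with the dtypes the generator produces."""
    df = pd.read_csv(path)
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
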