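"""Scoring of symptom-questionnaire case definitions.

Implements three families of Gulf War illness case definitions:

* **CDC** (Fukuda-style): 10 symptoms in 3 domains (fatigue, mood-cognition,
  musculoskeletal); a case endorses at least one qualifying symptom (any
  severity, present >= 6 months) in at least 2 of the 3 domains.  The
  **CDC Severe** subgroup additionally requires a severe-rated symptom in
  every case-qualifying domain (configurable to the stricter "all endorsed
  symptoms severe" variant).
* **Modified Kansas** (Steele-style, 28-item reduced set): 28 symptoms in 6
  domains; a domain qualifies with >= 2 mild symptoms or >= 1
  moderate-or-severe symptom (six-month symptoms only); a case has >= 3
  qualifying domains; the with-exclusions variant excludes subjects with any
  of 7 comorbid conditions.
* A strict factor-analytic "research-like" definition, provided either by the
  synthetic latent channel or by :mod:`gwical.factor`.

Severities are coded 0 = absent, 1 = mild, 2 = moderate, 3 = severe.  Missing
severities are treated as absent (conservative toward non-case) and the
number of such imputations is logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    CDC_6MO_COLS,
    CDC_COLS,
    COMORBIDITIES,
    KANSAS_6MO_COLS,
    KANSAS_COLS,
    N_CDC,
    N_KANSAS,
)

logger = logging.getLogger(__name__)

# 0-based item index -> domain.  The 28-item Kansas set drops four original
# items (joint stiffness, generalized body pain, heat/cold sensitivity, other
# skin problems) from their domains without replacement.
KANSAS_DOMAIN_MAP: dict[int, str] = {}
for _i in range(4):
    KANSAS_DOMAIN_MAP[_i] = "fatigue_sleep"
for _i in range(4, 7):
    KANSAS_DOMAIN_MAP[_i] = "pain"
for _i in range(7, 19):
    KANSAS_DOMAIN_MAP[_i] = "neurological_cognitive_mood"
for _i in range(19, 22):
    KANSAS_DOMAIN_MAP[_i] = "gastrointestinal"
for _i in range(22, 25):
    KANSAS_DOMAIN_MAP[_i] = "respiratory"
for _i in range(25, 28):
    KANSAS_DOMAIN_MAP[_i] = "skin"

CDC_DOMAIN_MAP: dict[int, str] = {0: "fatigue"}
for _i in range(1, 7):
    CDC_DOMAIN_MAP[_i] = "mood_cognition"
for _i in range(7, 10):
    CDC_DOMAIN_MAP[_i] = "musculoskeletal"

DEFINITIONS = ("research", "cdc", "cdc_severe", "kansas_no_excl", "kansas_excl")


@dataclass
class DefinitionSpec:
    """Machine-readable case-definition rule (item sets swappable via config)."""

    name: str
    domain_map: dict[int, str]
    rule: dict = field(default_factory=dict)
    exclusion_conditions: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.domain_map) == 0:
            raise ValueError("domain_map is empty")

    def domains(self) -> list[str]:
        return list(dict.fromkeys(self.domain_map.values()))

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["domain_map"] = {str(k): v for k, v in self.domain_map.items()}
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "DefinitionSpec":
        d = dict(d)
        d["domain_map"] = {int(k): v for k, v in d["domain_map"].items()}
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "DefinitionSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_specs() -> dict[str, DefinitionSpec]:
    return {
        "cdc": DefinitionSpec(
            "cdc",
            dict(CDC_DOMAIN_MAP),
            rule={"min_domains": 2, "min_severity": 1},
        ),
        "kansas": DefinitionSpec(
            "kansas",
            dict(KANSAS_DOMAIN_MAP),
            rule={"min_domains": 3, "mild_count": 2, "moderate_count": 1},
            exclusion_conditions=list(COMORBIDITIES),
        ),
    }


def _as_frame(record_or_frame) -> tuple[pd.DataFrame, bool]:
    if isinstance(record_or_frame, pd.Series):
        return record_or_frame.to_frame().T, True
    return record_or_frame, False


def _severities(frame: pd.DataFrame, cols: list[str]) -> np.ndarray:
    vals = frame[cols].to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        logger.info("treating %d missing severities as absent", n_missing)
        vals = np.nan_to_num(vals, nan=0.0)
    return vals


def _domain_matrix(domain_map: dict[int, str]) -> tuple[list[str], np.ndarray]:
    """Domains and an (n_items, n_domains) 0/1 membership matrix."""
    domains = list(dict.fromkeys(domain_map.values()))
    m = np.zeros((len(domain_map), len(domains)))
    for item, dom in domain_map.items():
        m[item, domains.index(dom)] = 1.0
    return domains, m


def score_cdc(record_or_frame, severe_rule: str = "per-domain"):
    """CDC and CDC Severe status.

    A symptom qualifies if endorsed (severity >= 1) and present >= 6 months.
    CDC: qualifying symptoms in >= 2 of the 3 domains.  CDC Severe (with the
    default ``severe_rule='per-domain'``): CDC positive and every qualifying
    domain contains >= 1 severe-rated qualifying symptom;
    ``severe_rule='all-symptoms'`` instead requires every qualifying symptom
    to be severe.
    """
    if severe_rule not in ("per-domain", "all-symptoms"):
        raise ValueError(f"unknown severe_rule {severe_rule!r}")
    frame, single = _as_frame(record_or_frame)
    sev = _severities(frame, CDC_COLS)
    six = frame[CDC_6MO_COLS].to_numpy(dtype=bool)
    qualifying = (sev >= 1) & six
    _, member = _domain_matrix(CDC_DOMAIN_MAP)
    dom_qual = (qualifying @ member) >= 1
    cdc = dom_qual.sum(axis=1) >= 2
    severe_sym = qualifying & (sev == 3)
    if severe_rule == "per-domain":
        dom_severe = (severe_sym @ member) >= 1
        severe_ok = np.all(~dom_qual | dom_severe, axis=1)
    else:
        severe_ok = ~np.any(qualifying & (sev < 3), axis=1)
    cdc_severe = cdc & severe_ok
    if single:
        return bool(cdc[0]), bool(cdc_severe[0])
    return cdc, cdc_severe


def score_modified_kansas(record_or_frame, apply_exclusions: bool):
    """Modified Kansas (28-item) case status.

    A domain qualifies with >= 2 mild (severity 1) or >= 1 moderate-or-severe
    (severity >= 2) six-month symptoms; a case has >= 3 of 6 qualifying
    domains.  With ``apply_exclusions``, any of the 7 exclusionary
    comorbidities forces non-case.
    """
    frame, single = _as_frame(record_or_frame)
    sev = _severities(frame, KANSAS_COLS)
    six = frame[KANSAS_6MO_COLS].to_numpy(dtype=bool)
    mild = (sev == 1) & six
    modsev = (sev >= 2) & six
    _, member = _domain_matrix(KANSAS_DOMAIN_MAP)
    dom_qual = ((mild @ member) >= 2) | ((modsev @ member) >= 1)
    case = dom_qual.sum(axis=1) >= 3
    if apply_exclusions:
        excl = frame[list(COMORBIDITIES)].to_numpy(dtype=bool).any(axis=1)
        case = case & ~excl
    if single:
        return bool(case[0])
    return case


def number_severity_score(record_or_frame):
    """Sum over the 28 Kansas symptoms of 0/1/2 for absent/mild/moderate+.

    Range 0 (no symptoms endorsed) to 56 (all endorsed at moderate or
    greater severity).  Missing severities count as absent.
    """
    frame, single = _as_frame(record_or_frame)
    sev = _severities(frame, KANSAS_COLS)
    score = np.minimum(sev, 2.0).sum(axis=1).astype(int)
    if single:
        return int(score[0])
    return score


def score_cohort(
    cohort: pd.DataFrame,
    research_col: str = "research_latent",
    severe_rule: str = "per-domain",
) -> pd.DataFrame:
    """Score every definition for every subject.

    Returns one row per subject with boolean flags ``research``, ``cdc``,
    ``cdc_severe``, ``kansas_no_excl``, ``kansas_excl``, the derived
    ``is_control`` (no definition satisfied) and the ``number_severity_score``.
    The strict research-like flag is taken from ``research_col`` when present
    (the synthetic latent channel); otherwise it can be supplied afterwards
    from :class:`gwical.factor.TwoStageFactorDefinition`.
    """
    cdc, cdc_severe = score_cdc(cohort, severe_rule=severe_rule)
    kansas_no = score_modified_kansas(cohort, apply_exclusions=False)
    kansas_ex = score_modified_kansas(cohort, apply_exclusions=True)
    if research_col in cohort.columns:
        research = cohort[research_col].to_numpy(dtype=bool)
    else:
        research = np.zeros(len(cohort), dtype=bool)
    statuses = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "research": research,
            "cdc": cdc,
            "cdc_severe": cdc_severe,
            "kansas_no_excl": kansas_no,
            "kansas_excl": kansas_ex,
            "number_severity_score": number_severity_score(cohort),
        }
    )
    statuses["is_control"] = ~statuses[list(DEFINITIONS)].any(axis=1)
    return statuses


def overlap_statistics(
    statuses: pd.DataFrame, weights: np.ndarray | pd.Series | None = None
) -> pd.DataFrame:
    """Counts and (weighted) proportions for every region of the Venn diagram.

    One row per observed combination of definition flags, plus convenience
    rows for each definition's margin and its "not research" subset.
    """
    flags = statuses[list(DEFINITIONS)].astype(bool)
    if weights is None:
        w = np.ones(len(statuses))
    else:
        w = np.asarray(weights, dtype=float)
    total_w = w.sum()

    rows = []
    grouped = flags.copy()
    grouped["_w"] = w
    for pattern, grp in grouped.groupby(list(DEFINITIONS), sort=True):
        label = (
            "&".join(d for d, on in zip(DEFINITIONS, pattern) if on) or "none"
        )
        rows.append(
            {
                "region": label,
                "kind": "disjoint",
                "n": len(grp),
                "weighted_n": grp["_w"].sum(),
                "proportion_pct": 100.0 * grp["_w"].sum() / total_w,
            }
        )
    for d in DEFINITIONS:
        mask = flags[d].to_numpy()
        rows.append(
            {
                "region": d,
                "kind": "margin",
                "n": int(mask.sum()),
                "weighted_n": w[mask].sum(),
                "proportion_pct": 100.0 * w[mask].sum() / total_w,
            }
        )
        if d != "research":
            sub = mask & ~flags["research"].to_numpy()
            rows.append(
                {
                    "region": f"{d}&not_research",
                    "kind": "margin",
                    "n": int(sub.sum()),
                    "weighted_n": w[sub].sum(),
                    "proportion_pct": 100.0 * w[sub].sum() / total_w,
                }
            )
    return pd.DataFrame(rows)
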