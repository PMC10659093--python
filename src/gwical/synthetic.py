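"""Seeded synthetic-cohort generator.

Generative direction: genotype (Hardy-Weinberg) and reported alarm exposure
are drawn first and independently; latent true illness follows from the
additive genotype-x-exposure risk model; symptoms are drawn conditional on
illness.  True cases endorse many symptoms concentrated at moderate/severe
ratings; non-cases endorse few, mostly mild, symptoms, except for a
configurable fraction planted with just enough mild six-month symptoms to
satisfy the loose (CDC / Kansas-style) definitions but not the strict one.
Exposure enrichment among true cases (p_R > p_C) arises endogenously from the
risk model whenever the exposure relative risk exceeds 1.

All randomness flows from a single integer seed through per-stage
``numpy.random.SeedSequence`` children, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    CDC_6MO_COLS,
    CDC_COLS,
    COHORT_COLUMNS,
    COMORBIDITIES,
    GENOTYPES,
    KANSAS_6MO_COLS,
    KANSAS_COLS,
    N_CDC,
    N_KANSAS,
    CohortParams,
)
from .definitions import CDC_DOMAIN_MAP, KANSAS_DOMAIN_MAP, number_severity_score

# Symptom endorsement model.  Severity probabilities are conditional on
# endorsement, over ratings (mild, moderate, severe).
_CASE_ENDORSE_P = 0.80
_CASE_SEVERITY_P = (0.10, 0.45, 0.45)
_NONCASE_ENDORSE_P = 0.06
_NONCASE_SEVERITY_P = (0.75, 0.20, 0.05)
_SIX_MONTH_P = 0.90

_STAGES = (
    "genotype",
    "exposure",
    "illness",
    "research",
    "symptoms",
    "comorbid",
    "demography",
    "sf12",
)


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def _draw_severities(rng, n_items, is_case):
    """(n, n_items) ordinal severities in {0..3} given case status per row."""
    n = is_case.shape[0]
    endorse_p = np.where(is_case, _CASE_ENDORSE_P, _NONCASE_ENDORSE_P)[:, None]
    endorsed = rng.random((n, n_items)) < endorse_p
    u = rng.random((n, n_items))
    case_t1, case_t2 = _CASE_SEVERITY_P[0], _CASE_SEVERITY_P[0] + _CASE_SEVERITY_P[1]
    non_t1, non_t2 = (
        _NONCASE_SEVERITY_P[0],
        _NONCASE_SEVERITY_P[0] + _NONCASE_SEVERITY_P[1],
    )
    t1 = np.where(is_case, case_t1, non_t1)[:, None]
    t2 = np.where(is_case, case_t2, non_t2)[:, None]
    sev = (1 + (u >= t1).astype(np.int8) + (u >= t2).astype(np.int8)) * endorsed
    return sev.astype(np.int8)


def _first_items_of_domains(domain_map: dict[int, str], domains, per_domain: int):
    """Indices (0-based) of the first `per_domain` items of each listed domain."""
    out = []
    for dom in domains:
        items = [i for i, d in domain_map.items() if d == dom]
        out.extend(items[:per_domain])
    return np.asarray(out, dtype=int)


# Planted loose-false-positive pattern: two mild symptoms in each of three
# Kansas domains (domain rule: >=2 mild), one mild symptom in each of two CDC
# domains (domain rule: >=1 endorsed).
_KANSAS_FP_ITEMS = None
_CDC_FP_ITEMS = None


def _fp_items():
    global _KANSAS_FP_ITEMS, _CDC_FP_ITEMS
    if _KANSAS_FP_ITEMS is None:
        kansas_domains = list(dict.fromkeys(KANSAS_DOMAIN_MAP.values()))[:3]
        _KANSAS_FP_ITEMS = _first_items_of_domains(KANSAS_DOMAIN_MAP, kansas_domains, 2)
        cdc_domains = list(dict.fromkeys(CDC_DOMAIN_MAP.values()))[:2]
        _CDC_FP_ITEMS = _first_items_of_domains(CDC_DOMAIN_MAP, cdc_domains, 1)
    return _KANSAS_FP_ITEMS, _CDC_FP_ITEMS


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Generate a synthetic deployed cohort, one row per veteran.

    Deterministic given ``params.seed``.  The returned frame carries the
    latent columns ``true_case`` (the additive-risk illness state) and
    ``research_latent`` (true cases selected by the strict definition with
    probability ``strict_sensitivity``), which exist only in synthetic data.
    """
    params.validate()
    n = params.n_deployed
    rngs = _stage_rngs(params.seed)

    freqs = params.genotype_freqs()
    genotype = rngs["genotype"].choice(
        GENOTYPES, size=n, p=[freqs[g] for g in GENOTYPES]
    )
    exposed = rngs["exposure"].random(n) < params.exposure_prev_noncase

    cells = params.risk_cells()
    risk = np.empty(n)
    for g in GENOTYPES:
        for e in (0, 1):
            mask = (genotype == g) & (exposed == bool(e))
            risk[mask] = cells[(g, e)]
    true_case = rngs["illness"].random(n) < risk

    research_latent = true_case & (
        rngs["research"].random(n) < params.strict_sensitivity
    )

    sym_rng = rngs["symptoms"]
    kansas = _draw_severities(sym_rng, N_KANSAS, true_case)
    cdc = _draw_severities(sym_rng, N_CDC, true_case)
    kansas_6mo = (sym_rng.random((n, N_KANSAS)) < _SIX_MONTH_P) & (kansas > 0)
    cdc_6mo = (sym_rng.random((n, N_CDC)) < _SIX_MONTH_P) & (cdc > 0)

    # Loose false positives: non-cases planted with mild qualifying symptoms.
    fp = (~true_case) & (sym_rng.random(n) < params.loose_false_positive_frac)
    k_items, c_items = _fp_items()
    if fp.any():
        rows = np.where(fp)[0][:, None]
        kansas[rows, k_items[None, :]] = np.maximum(kansas[rows, k_items[None, :]], 1)
        kansas_6mo[rows, k_items[None, :]] = True
        cdc[rows, c_items[None, :]] = np.maximum(cdc[rows, c_items[None, :]], 1)
        cdc_6mo[rows, c_items[None, :]] = True

    com_rng = rngs["comorbid"]
    comorbid = {
        c: com_rng.random(n) < params.comorbidity_prevs.get(c, 0.0)
        for c in COMORBIDITIES
    }

    dem = rngs["demography"]
    age = np.clip(np.round(dem.normal(38.0, 9.0, n)), 22, 65).astype(int)
    sex = (dem.random(n) < 0.07).astype(int)  # 1 = female
    combat_scale = dem.choice(5, size=n, p=[0.20, 0.30, 0.25, 0.15, 0.10])

    # Strata: age x sex x combat cells folded into n_strata; survey weight is
    # the inverse of a per-stratum nominal sampling fraction.
    cell = (
        (age > np.median(age)).astype(int) * 4
        + sex * 2
        + (combat_scale >= 2).astype(int)
    )
    stratum = cell % params.n_strata
    h_max = max(params.n_strata - 1, 1)
    sampling_frac = 0.1 + 0.8 * (stratum / h_max)
    weight = 1.0 / sampling_frac

    score = number_severity_score(pd.DataFrame(kansas, columns=KANSAS_COLS))
    sf_rng = rngs["sf12"]
    sf12_mcs = np.clip(55.0 - 0.25 * score + sf_rng.normal(0, 8.0, n), 0, 100)
    sf12_pcs = np.clip(53.0 - 0.22 * score + sf_rng.normal(0, 9.0, n), 0, 100)

    data = {
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "genotype": genotype,
        "heard_alarms": exposed,
    }
    data.update({c: kansas[:, i] for i, c in enumerate(KANSAS_COLS)})
    data.update({c: kansas_6mo[:, i] for i, c in enumerate(KANSAS_6MO_COLS)})
    data.update({c: cdc[:, i] for i, c in enumerate(CDC_COLS)})
    data.update({c: cdc_6mo[:, i] for i, c in enumerate(CDC_6MO_COLS)})
    data.update(comorbid)
    data.update(
        age=age,
        sex=sex,
        combat_scale=combat_scale,
        stratum_id=stratum,
        weight=weight,
        sf12_mcs=np.round(sf12_mcs, 2),
        sf12_pcs=np.round(sf12_pcs, 2),
        research_latent=research_latent,
        true_case=true_case,
    )
    return pd.DataFrame(data, columns=COHORT_COLUMNS)


def draw_case_control_subsample(
    cohort: pd.DataFrame,
    statuses: pd.DataFrame,
    n_controls: int,
    seed: int,
) -> pd.DataFrame:
    """All definition-positive subjects plus a random sample of controls.

    Controls are subjects satisfying no case definition.  The control
    sampling fraction is recorded in ``result.attrs['control_sampling_fraction']``.
    """
    if n_controls < 0:
        raise ValueError("n_controls must be nonnegative")
    is_control = statuses["is_control"].to_numpy()
    case_idx = np.where(~is_control)[0]
    control_pool = np.where(is_control)[0]
    if len(control_pool) < n_controls:
        raise ValueError(
            f"only {len(control_pool)} eligible controls, {n_controls} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(control_pool, size=n_controls, replace=False))
    idx = np.concatenate([case_idx, chosen])
    sub = cohort.iloc[np.sort(idx)].reset_index(drop=True)
    sub.attrs["control_sampling_fraction"] = (
        n_controls / len(control_pool) if len(control_pool) else float("nan")
    )
    sub.attrs["n_controls"] = int(n_controls)
    sub.attrs["controls_empty"] = n_controls == 0
    return sub
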