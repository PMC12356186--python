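"""Synthetic road-survey data with the structure the analyses assume.

The generator emulates the survey design of the field study: per survey
night the number of encounters is Poisson, species are drawn from the
community's relative abundances, demographic class per species, sizes
from truncated normals matching the published per-class means/sds and
observed ranges, positions uniform along the route, and dead-on-road
status from a logistic model in total length, weight and demographic
class.  Weight is drawn conditionally on SVL through a log-log linear
predictor with noise so the two covariates are collinear, as in real
snakes, while the marginal moments stay close to the published ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import fielddata
from .encounters import SnakeEncounter, SurveyEffort, STANDARD_SURVEY_KM

__all__ = [
    "SizeModel",
    "MonthPlan",
    "SyntheticConfig",
    "default_config",
    "generate_community",
    "generate_atrox_adults",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class SizeModel:
    """Truncated-normal parameters for svl/tail (cm) and weight (g).

    Each trait is (mean, sd, low, high); sd = 0 yields the constant mean.
    ``weight`` may be None for classes never weighed.
    """

    svl: tuple[float, float, float, float]
    tail: tuple[float, float, float, float]
    weight: tuple[float, float, float, float] | None
    #: allometric exponent linking weight to SVL on the log-log scale
    weight_svl_exponent: float = 3.0

    def __post_init__(self):
        for tr in (self.svl, self.tail, self.weight):
            if tr is None:
                continue
            _, sd, lo, hi = tr
            if sd < 0 or lo > hi:
                raise ValueError("trait sd must be >= 0 and bounds ordered")


@dataclass(frozen=True)
class MonthPlan:
    """Survey plan for one calendar month."""

    year: int
    month: int
    n_surveys: int
    rate: float  # expected encounters per survey night

    def __post_init__(self):
        if self.n_surveys < 0 or self.rate < 0:
            raise ValueError("n_surveys and rate must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    months: tuple[MonthPlan, ...]
    species_mix: dict[str, float]
    demo_mix: dict[str, dict[str, float]]
    size_models: dict[tuple[str, str], SizeModel]
    dor_model: dict[str, float]
    route_length_km: float = 37.0
    survey_distance_km: float = STANDARD_SURVEY_KM

    def __post_init__(self):
        _check_probs(self.species_mix, "species_mix")
        for sp, mix in self.demo_mix.items():
            _check_probs(mix, f"demo_mix[{sp}]")


def _check_probs(mix: dict[str, float], name: str) -> None:
    if not mix:
        raise ValueError(f"{name} is empty")
    vals = np.array(list(mix.values()), dtype=float)
    if (vals < 0).any():
        raise ValueError(f"{name} has negative probabilities")
    if abs(vals.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} does not sum to 1 (got {vals.sum():.12f})")


def default_config() -> SyntheticConfig:
    """Study conditions: 2017 survey design with published mixes and models."""
    total = sum(fielddata.SPECIES_TOTALS.values())
    species_mix = {sp: n / total for sp, n in fielddata.SPECIES_TOTALS.items()}
    demo_counts: dict[str, dict[str, int]] = {}
    for (sp, cls), cm in fielddata.MORPHOMETRY.items():
        demo_counts.setdefault(sp, {})[cls] = cm.n
    demo_mix = {
        sp: {cls: n / sum(counts.values()) for cls, n in counts.items()}
        for sp, counts in demo_counts.items()
    }
    size_models = {}
    for (sp, cls), cm in fielddata.MORPHOMETRY.items():
        if cm.svl is None or cm.tail is None:
            continue
        size_models[(sp, cls)] = SizeModel(
            svl=(cm.svl.mean, cm.svl.sd, cm.svl.min, cm.svl.max),
            tail=(cm.tail.mean, cm.tail.sd, cm.tail.min, cm.tail.max),
            weight=None if cm.weight is None else
            (cm.weight.mean, cm.weight.sd, cm.weight.min, cm.weight.max),
        )
    months = tuple(
        MonthPlan(
            fielddata.SURVEY_YEAR, m, fielddata.SURVEYS_PER_MONTH,
            sum(tallies[i][0] + tallies[i][1]
                for tallies in fielddata.MONTHLY_TALLIES.values())
            / fielddata.SURVEYS_PER_MONTH,
        )
        for i, m in enumerate(fielddata.SURVEY_MONTHS)
    )
    return SyntheticConfig(
        months=months,
        species_mix=species_mix,
        demo_mix=demo_mix,
        size_models=size_models,
        dor_model=dict(fielddata.DOR_MODEL_ALL_SIZES),
    )


def _draw_trunc_normal(rng, trait, n):
    mean, sd, lo, hi = trait
    if sd == 0 or lo == hi:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _draw_weight_given_svl(rng, model: SizeModel, svl):
    """Weight | SVL on the log-log scale, moment-matched to the marginal.

    ln W = mu + b (ln svl - E ln svl) + eps, with eps variance chosen so
    Var(W) approximates the published marginal variance; draws are clipped
    to the observed weight range.
    """
    mw, sw, lo, hi = model.weight
    if sw == 0 or lo == hi:
        return np.full(svl.shape, mw)
    ms, ss = model.svl[0], model.svl[1]
    cv_s2 = (ss / ms) ** 2 if ms > 0 else 0.0
    cv_w2 = (sw / mw) ** 2
    v_lns = math.log1p(cv_s2)
    m_lns = math.log(ms) - v_lns / 2 if ms > 0 else 0.0
    v_lnw = math.log1p(cv_w2)
    b = model.weight_svl_exponent
    v_eps = max(v_lnw - b * b * v_lns, 1e-6)
    mu = math.log(mw) - v_lnw / 2
    lnw = mu + b * (np.log(svl) - m_lns) + rng.normal(0.0, math.sqrt(v_eps), svl.shape)
    return np.clip(np.exp(lnw), lo, hi)


def _dor_linear_predictor(coeffs, total_length, weight, demo_class):
    lp = coeffs["intercept"] + coeffs["total_length"] * total_length
    lp = lp + coeffs.get("weight", 0.0) * weight
    lp = lp + np.where(demo_class == "male", coeffs.get("male", 0.0), 0.0)
    lp = lp + np.where(demo_class == "juvenile", coeffs.get("juvenile", 0.0), 0.0)
    return lp


def generate_community(config: SyntheticConfig, seed):
    """Draw one synthetic season: (encounters, efforts).

    Fully reproducible from ``seed`` (any value accepted by
    ``numpy.random.default_rng``).
    """
    rng = np.random.default_rng(seed)
    species = list(config.species_mix)
    sp_probs = np.array([config.species_mix[s] for s in species])
    encounters: list[SnakeEncounter] = []
    efforts: list[SurveyEffort] = []
    for plan in config.months:
        days = np.linspace(3, 27, plan.n_surveys, dtype=int) if plan.n_surveys else []
        for day in days:
            d = date(plan.year, plan.month, int(day))
            efforts.append(SurveyEffort(survey_date=d, survey_type="standardized",
                                        distance_km=config.survey_distance_km))
            n = int(rng.poisson(plan.rate))
            if n == 0:
                continue
            sp_draw = rng.choice(len(species), size=n, p=sp_probs)
            for k in range(n):
                sp = species[sp_draw[k]]
                mix = config.demo_mix.get(sp, {"unknown": 1.0})
                classes = list(mix)
                cls = classes[rng.choice(len(classes), p=np.array([mix[c] for c in classes]))]
                model = config.size_models.get((sp, cls))
                svl = tail = weight = None
                if model is not None:
                    svl = float(_draw_trunc_normal(rng, model.svl, 1)[0])
                    tail = float(_draw_trunc_normal(rng, model.tail, 1)[0])
                    if model.weight is not None:
                        weight = float(_draw_weight_given_svl(rng, model, np.array([svl]))[0])
                tl = (svl + tail) if svl is not None else 0.0
                lp = _dor_linear_predictor(
                    config.dor_model, tl, weight if weight is not None else 0.0,
                    np.array(cls))
                dor = bool(rng.random() < expit(float(lp)))
                minute = int(rng.integers(0, 180))  # within the nightly window
                encounters.append(SnakeEncounter(
                    species=sp,
                    encounter_date=d,
                    survey_type="standardized",
                    status="DOR" if dor else "AOR",
                    demo_class=cls,
                    svl_cm=svl, tail_cm=tail, weight_g=weight,
                    route_km=float(rng.uniform(0, config.route_length_km)),
                    time_hhmm=f"{20 + minute // 60:02d}:{minute % 60:02d}",
                ))
    return encounters, efforts


#: Adult C. atrox sex ratio among measured adults (males : females).
_ADULT_SEX_COUNTS = {"male": 47, "female": 17}


def generate_atrox_adults(
    n: int,
    coeffs: dict[str, float] | None = None,
    size_models: dict[str, SizeModel] | None = None,
    seed=None,
    years: tuple[int, ...] = (2014, 2015, 2016, 2017),
    months: tuple[int, ...] = fielddata.SURVEY_MONTHS,
) -> pd.DataFrame:
    """Modeling table of synthetic adult *C. atrox*.

    Columns: svl, tail, total_length, weight, sex, month, year, dor.
    Sizes come from the published adult male/female truncated normals;
    DOR is Bernoulli under the supplied logistic coefficients (default:
    the published adults-only model).  Month and year are drawn uniformly
    so the seasonal model terms are estimable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if coeffs is None:
        coeffs = dict(fielddata.DOR_MODEL_ADULTS)
    if size_models is None:
        cfg = default_config()
        size_models = {
            "male": cfg.size_models[("Crotalus atrox", "male")],
            "female": cfg.size_models[("Crotalus atrox", "female")],
        }
    p_male = _ADULT_SEX_COUNTS["male"] / sum(_ADULT_SEX_COUNTS.values())
    sex = np.where(rng.random(n) < p_male, "male", "female")
    svl = np.empty(n)
    tail = np.empty(n)
    weight = np.empty(n)
    for s in ("male", "female"):
        idx = np.flatnonzero(sex == s)
        if idx.size == 0:
            continue
        model = size_models[s]
        svl[idx] = _draw_trunc_normal(rng, model.svl, idx.size)
        tail[idx] = _draw_trunc_normal(rng, model.tail, idx.size)
        weight[idx] = _draw_weight_given_svl(rng, model, svl[idx])
    tl = svl + tail
    lp = _dor_linear_predictor(coeffs, tl, weight, sex)
    dor = (rng.random(n) < expit(lp)).astype(int)
    return pd.DataFrame({
        "svl": svl,
        "tail": tail,
        "total_length": tl,
        "weight": weight,
        "sex": pd.Categorical(sex, categories=["female", "juvenile", "male"]),
        "month": rng.choice(months, size=n),
        "year": rng.choice(years, size=n),
        "dor": dor,
    })


def encounters_to_model_frame(encounters) -> pd.DataFrame:
    """Build the DOR modeling table from encounter records.

    Rows without a given morphometric carry NaN; listwise handling is the
    model layer's job.
    """
    rows = []
    for e in encounters:
        tl = (e.svl_cm + e.tail_cm) if (e.svl_cm is not None and e.tail_cm is not None) else np.nan
        rows.append({
            "svl": np.nan if e.svl_cm is None else e.svl_cm,
            "tail": np.nan if e.tail_cm is None else e.tail_cm,
            "total_length": tl,
            "weight": np.nan if e.weight_g is None else e.weight_g,
            "sex": e.demo_class if e.demo_class in ("male", "female", "juvenile") else np.nan,
            "month": e.encounter_date.month,
            "year": e.encounter_date.year,
            "dor": int(e.status == "DOR"),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["sex"] = pd.Categorical(df["sex"], categories=["female", "juvenile", "male"])
    return df
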