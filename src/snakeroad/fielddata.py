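"""Published summaries from the Chihuahuan Desert road-cruising study.

These constants are the printed results of the original field study near
Chaparral, New Mexico (2014--2017 surveys on the 37-km War Road transect):
monthly encounter tallies from the 2017 standardized surveys, per-species
morphometric summaries, the fitted dead-on-road (DOR) logistic
coefficients, the road/vehicle geometry used in the crossing simulations,
and the evolutionary-projection parameters.  They serve two purposes:

* defaults for the synthetic-data generator, so simulated communities
  carry the statistical structure the downstream analyses assume; and
* direct inputs where the analysis operates on published summaries
  (survey summary tables, the crossing-length mixture, the breeder's
  equation inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

from .encounters import SnakeEncounter, SurveyEffort, STANDARD_SURVEY_KM

SURVEY_YEAR = 2017
SURVEY_MONTHS = (4, 5, 6, 7, 8, 9, 10, 11)
SURVEYS_PER_MONTH = 3

#: Monthly (AOR, DOR) tallies per species from the 2017 standardized
#: surveys, April through November.
MONTHLY_TALLIES: dict[str, tuple[tuple[int, int], ...]] = {
    "Arizona elegans":        ((2, 0), (4, 1), (1, 1), (0, 0), (1, 1), (1, 2), (0, 0), (0, 0)),
    "Crotalus atrox":         ((5, 0), (0, 1), (5, 1), (1, 1), (9, 4), (8, 4), (3, 4), (1, 1)),
    "Crotalus viridis":       ((1, 0), (0, 0), (0, 0), (0, 1), (2, 0), (3, 1), (1, 1), (0, 0)),
    "Hypsiglena jani":        ((0, 0), (0, 0), (1, 0), (0, 0), (2, 0), (0, 0), (0, 0), (0, 1)),
    "Lampropeltis splendida": ((0, 0), (0, 0), (0, 0), (1, 0), (0, 0), (0, 0), (0, 0), (0, 0)),
    "Masticophis flagellum":  ((0, 0), (0, 0), (0, 0), (0, 0), (0, 1), (0, 0), (0, 0), (0, 0)),
    "Pituophis catenifer":    ((1, 0), (0, 0), (0, 0), (0, 0), (1, 0), (1, 3), (2, 2), (0, 0)),
    "Rhinocheilus lecontei":  ((1, 1), (1, 1), (1, 1), (1, 0), (1, 0), (0, 1), (1, 0), (0, 0)),
    "Salvadora deserticola":  ((0, 0), (0, 0), (0, 0), (0, 0), (0, 0), (0, 1), (0, 0), (0, 0)),
    "Tantilla nigriceps":     ((0, 0), (0, 0), (1, 0), (1, 0), (0, 0), (0, 0), (0, 0), (0, 0)),
}

#: Species totals across the 2017 standardized surveys (relative abundances).
SPECIES_TOTALS: dict[str, int] = {
    sp: sum(a + d for a, d in months) for sp, months in MONTHLY_TALLIES.items()
}


def survey_encounters() -> list[SnakeEncounter]:
    """Expand the 2017 monthly tallies into one record per snake.

    Dates are placed mid-month (day 15); morphometrics and positions are
    not part of the published monthly table and are left missing.
    """
    out = []
    for sp, months in MONTHLY_TALLIES.items():
        for month, (aor, dor) in zip(SURVEY_MONTHS, months):
            d = date(SURVEY_YEAR, month, 15)
            out.extend(
                SnakeEncounter(species=sp, encounter_date=d,
                               survey_type="standardized", status="AOR")
                for _ in range(aor)
            )
            out.extend(
                SnakeEncounter(species=sp, encounter_date=d,
                               survey_type="standardized", status="DOR")
                for _ in range(dor)
            )
    return out


def survey_efforts() -> list[SurveyEffort]:
    """The 24 standardized surveys of 2017: three per month at 74 km each."""
    return [
        SurveyEffort(survey_date=date(SURVEY_YEAR, month, day),
                     survey_type="standardized", distance_km=STANDARD_SURVEY_KM)
        for month in SURVEY_MONTHS
        for day in (5, 15, 25)
    ]


@dataclass(frozen=True)
class TraitSummary:
    """Published mean +/- sd with observed range for one trait."""

    mean: float
    sd: float  # 0.0 for single-animal or constant groups
    min: float
    max: float


@dataclass(frozen=True)
class ClassMorphometry:
    n: int
    svl: TraitSummary | None
    tail: TraitSummary | None
    weight: TraitSummary | None
    pct_dor: float


def _t(mean, sd, lo, hi):
    return TraitSummary(mean, sd, lo, hi)


#: Per species x demographic class morphometric summaries (cm, cm, g) and
#: %DOR from the pooled 2014--2017 surveys.  Classes recorded but never
#: measured carry ``None`` traits.
MORPHOMETRY: dict[tuple[str, str], ClassMorphometry] = {
    ("Arizona elegans", "male"): ClassMorphometry(
        8, _t(33.51, 10.26, 21.7, 54.2), _t(6.15, 1.81, 3.6, 9.6), _t(12.33, 7.39, 3, 22), 37.5),
    ("Arizona elegans", "female"): ClassMorphometry(
        5, _t(62.84, 7.06, 55.2, 69.6), _t(11.80, 1.34, 10.3, 13.8), _t(112.50, 32.77, 69, 147), 0.0),
    ("Arizona elegans", "juvenile"): ClassMorphometry(
        7, _t(26.44, 5.35, 20.4, 33.2), _t(4.31, 1.04, 3.1, 5.8), _t(7.86, 5.27, 3, 18), 14.3),
    ("Arizona elegans", "unknown"): ClassMorphometry(2, None, None, None, 100.0),
    ("Crotalus atrox", "male"): ClassMorphometry(
        47, _t(78.86, 21.20, 40.6, 123), _t(7.05, 1.89, 3.2, 11.7), _t(391.66, 363.70, 42, 1511), 36.2),
    ("Crotalus atrox", "female"): ClassMorphometry(
        17, _t(68.76, 14.29, 43.5, 86.5), _t(4.70, 0.96, 3, 6.3), _t(243.69, 151.27, 38, 505), 35.3),
    ("Crotalus atrox", "juvenile"): ClassMorphometry(
        21, _t(32.66, 3.02, 29.1, 39.5), _t(2.83, 0.54, 2.2, 4.1), _t(19.89, 4.57, 15, 28), 14.3),
    ("Crotalus atrox", "unknown"): ClassMorphometry(6, None, None, None, 50.0),
    ("Crotalus viridis", "male"): ClassMorphometry(
        14, _t(66.39, 15.38, 37, 93.5), _t(5.99, 1.45, 2.7, 8.2), _t(205.50, 149.69, 25, 556), 7.1),
    ("Crotalus viridis", "female"): ClassMorphometry(
        6, _t(68.90, 7.14, 62.5, 80.0), _t(4.54, 0.82, 3.7, 5.6), _t(174.50, 70.0, 125, 224), 66.7),
    ("Crotalus viridis", "juvenile"): ClassMorphometry(
        5, _t(30.65, 0.49, 30.3, 31), _t(2.30, 0.0, 2.3, 2.3), _t(13.50, 7.78, 8, 19), 20.0),
    ("Crotalus viridis", "unknown"): ClassMorphometry(2, None, None, None, 0.0),
    ("Hypsiglena jani", "male"): ClassMorphometry(
        5, _t(29.56, 5.27, 24.9, 37.5), _t(5.46, 0.74, 4.7, 6.3), _t(16.0, 4.24, 13, 19), 0.0),
    ("Hypsiglena jani", "female"): ClassMorphometry(
        3, _t(36.70, 7.37, 28.4, 42.5), _t(5.27, 1.01, 4.1, 5.9), _t(15.50, 10.61, 8, 23), 66.7),
    ("Lampropeltis splendida", "male"): ClassMorphometry(
        1, _t(72.5, 0.0, 72.5, 72.5), _t(11.0, 0.0, 11, 11), _t(124.0, 0.0, 124, 124), 0.0),
    ("Lampropeltis splendida", "female"): ClassMorphometry(
        1, _t(82.0, 0.0, 82, 82), _t(12.8, 0.0, 12.8, 12.8), None, 100.0),
    ("Lampropeltis splendida", "juvenile"): ClassMorphometry(
        2, _t(32.55, 1.34, 31.6, 33.5), _t(6.30, 2.12, 4.8, 7.8), _t(11.0, 1.41, 10, 12), 0.0),
    ("Masticophis flagellum", "male"): ClassMorphometry(
        2, _t(111.0, 0.0, 111, 111), _t(34.5, 0.0, 34.5, 34.5), None, 100.0),
    ("Masticophis flagellum", "unknown"): ClassMorphometry(2, None, None, None, 100.0),
    ("Pituophis catenifer", "male"): ClassMorphometry(
        8, _t(54.86, 24.67, 37.9, 98.4), _t(8.77, 3.78, 5.8, 14.9), _t(23.0, 5.10, 16, 30), 50.0),
    ("Pituophis catenifer", "female"): ClassMorphometry(
        9, _t(51.31, 20.97, 39.7, 106.5), _t(7.18, 2.17, 5.5, 12.8), _t(74.88, 128.66, 23, 393), 44.4),
    ("Rhinocheilus lecontei", "male"): ClassMorphometry(
        11, _t(48.85, 13.92, 24.1, 66.2), _t(8.18, 2.37, 3.9, 11), _t(43.57, 35.88, 5, 102), 63.6),
    ("Rhinocheilus lecontei", "female"): ClassMorphometry(
        1, _t(71.3, 0.0, 71.3, 71.3), _t(10.8, 0.0, 10.8, 10.8), _t(110.0, 0.0, 110, 110), 0.0),
    ("Rhinocheilus lecontei", "juvenile"): ClassMorphometry(
        3, _t(22.53, 1.01, 21.6, 23.6), _t(3.73, 0.55, 3.2, 4.3), _t(5.33, 1.53, 4, 7), 33.3),
    ("Salvadora deserticola", "male"): ClassMorphometry(
        1, _t(52.3, 0.0, 52.3, 52.3), _t(14.1, 0.0, 14.1, 14.1), _t(34.0, 0.0, 34, 34), 100.0),
    ("Tantilla nigriceps", "female"): ClassMorphometry(
        2, _t(19.65, 0.07, 19.6, 19.7), _t(4.05, 0.07, 4, 4.1), _t(2.50, 0.71, 2, 3), 0.0),
}

#: Fitted DOR logistic coefficients (log-odds): adults-only model
#: (C. atrox with SVL > 40 cm, n = 48, reference sex = female).
DOR_MODEL_ADULTS = {
    "intercept": -6.4924,
    "total_length": 0.0908,
    "weight": -0.0045,
    "male": -1.1640,
}

#: Fitted DOR logistic coefficients: all-sizes model (n = 57), with a
#: juvenile level alongside male (reference = adult female).
DOR_MODEL_ALL_SIZES = {
    "intercept": -6.8484,
    "total_length": 0.0966,
    "weight": -0.0048,
    "male": -1.1958,
    "juvenile": 2.8061,
}

#: Measured total-length summaries for all measured C. atrox, by status:
#: (mean cm, sd cm, n).  These feed the crossing simulator's length
#: mixture (component spreads are standard errors, sd/sqrt(n)).
ATROX_TOTAL_LENGTH_AOR = (71.83, 27.35, 50)
ATROX_TOTAL_LENGTH_DOR = (81.14, 24.25, 21)
#: Adults-only (SVL > 40 cm) total-length summaries, by status.
ATROX_ADULT_TOTAL_LENGTH_AOR = (79.93, 23.26, 41)
ATROX_ADULT_TOTAL_LENGTH_DOR = (88.46, 17.07, 18)
#: Largest total length observed in the study; truncation cap for
#: simulated crossing lengths.
MAX_OBSERVED_TOTAL_LENGTH_CM = 135.0

# Road and vehicle geometry for the crossing simulations.
ROAD_WIDTH_CM = 732.0
WHEEL_WIDTH_CM = 20.0
WHEEL_TRACK_CM = 177.0

# Breeder's-equation projection inputs.
HERITABILITY_MEAN = 0.59   # neonatal body-length h2 from a wild pitviper
HERITABILITY_SD = 0.27
SELECTION_S_MEAN = -0.421  # standardized AOR-DOR total-length differential
SELECTION_S_SD = 0.268     # bootstrap SD of s
START_MEAN_TOTAL_LENGTH_CM = 80.66  # adult C. atrox mean total length
SELECTION_DECAY_K = 0.005
GENERATION_TIME_YR = 3.3
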