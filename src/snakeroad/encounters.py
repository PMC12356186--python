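"""Encounter records, survey effort, and descriptive community statistics.

The unit of observation is a single snake found on the road during a
nocturnal road-cruising survey, either alive-on-road (AOR) or dead-on-road
(DOR).  Records carry standard snake morphometrics: snout--vent length
(SVL) and tail length to 0.1 cm, and mass to 1 g.  Carcasses too degraded
to measure are kept with missing morphometrics so that counts and %DOR
still include them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROUTE_LENGTH_KM",
    "SnakeEncounter",
    "SurveyEffort",
    "GroupStats",
    "read_encounters",
    "write_encounters",
    "read_efforts",
    "write_efforts",
    "total_length",
    "filter_adult_atrox",
    "monthly_summary",
    "bin_route_positions",
    "uniformity_chi_square",
    "species_morphometry",
    "welch_t",
    "size_range_overlap",
]

logger = logging.getLogger(__name__)

#: Length of the surveyed road transect.
ROUTE_LENGTH_KM = 37.0

SURVEY_TYPES = ("standardized", "opportunistic")
STATUSES = ("AOR", "DOR")
DEMO_CLASSES = ("male", "female", "juvenile", "unknown")
IMPACT_POINTS = ("head", "midbody", "tail", "unknown")

ENCOUNTER_COLUMNS = [
    "species", "encounter_date", "survey_type", "status", "demo_class",
    "svl_cm", "tail_cm", "weight_g", "route_km", "time_hhmm", "impact_point",
]
EFFORT_COLUMNS = ["survey_date", "survey_type", "distance_km"]

#: Default distance of one standardized survey (out and back on the 37-km road).
STANDARD_SURVEY_KM = 74.0


class ValidationError(ValueError):
    """Raised when a record or file violates the documented schema."""


@dataclass(frozen=True)
class SnakeEncounter:
    """One snake found on the road."""

    species: str
    encounter_date: date
    survey_type: str
    status: str
    demo_class: str = "unknown"
    svl_cm: float | None = None
    tail_cm: float | None = None
    weight_g: float | None = None
    route_km: float | None = None
    time_hhmm: str | None = None
    impact_point: str | None = None

    def __post_init__(self):
        if not self.species:
            raise ValidationError("species is required")
        if self.status not in STATUSES:
            raise ValidationError(f"status must be one of {STATUSES}, got {self.status!r}")
        if self.survey_type not in SURVEY_TYPES:
            raise ValidationError(f"survey_type must be one of {SURVEY_TYPES}")
        if self.demo_class not in DEMO_CLASSES:
            raise ValidationError(f"demo_class must be one of {DEMO_CLASSES}")
        if self.svl_cm is not None and not self.svl_cm > 0:
            raise ValidationError("svl_cm must be positive when present")
        if self.tail_cm is not None and self.tail_cm < 0:
            raise ValidationError("tail_cm must be non-negative when present")
        if self.weight_g is not None and not self.weight_g > 0:
            raise ValidationError("weight_g must be positive when present")
        if self.route_km is not None and not 0 <= self.route_km <= ROUTE_LENGTH_KM:
            raise ValidationError(f"route_km must lie in [0, {ROUTE_LENGTH_KM}]")
        if self.impact_point is not None and self.impact_point not in IMPACT_POINTS:
            raise ValidationError(f"impact_point must be one of {IMPACT_POINTS}")


@dataclass(frozen=True)
class SurveyEffort:
    """Distance driven on one survey night."""

    survey_date: date
    survey_type: str
    distance_km: float = STANDARD_SURVEY_KM

    def __post_init__(self):
        if self.survey_type not in SURVEY_TYPES:
            raise ValidationError(f"survey_type must be one of {SURVEY_TYPES}")
        if not self.distance_km > 0:
            raise ValidationError("distance_km must be positive")


@dataclass(frozen=True)
class GroupStats:
    """Summary of one trait within one group: n, mean, sd, range."""

    n: int
    mean: float
    sd: float | None
    min: float
    max: float

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.sd is not None and self.sd < 0:
            raise ValidationError("sd must be >= 0")


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_encounters(path) -> list[SnakeEncounter]:
    """Read encounter records from CSV.

    Empty cells become missing values.  Rows violating the schema are
    reported together with their (1-based, data-row) numbers.
    """
    df = pd.read_csv(path, dtype={"time_hhmm": "string"})
    missing = [c for c in ENCOUNTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out: list[SnakeEncounter] = []
    bad: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(SnakeEncounter(
                species=str(row.species),
                encounter_date=date.fromisoformat(str(row.encounter_date)),
                survey_type=str(row.survey_type),
                status=str(row.status),
                demo_class=str(row.demo_class) if pd.notna(row.demo_class) else "unknown",
                svl_cm=_opt_float(row.svl_cm),
                tail_cm=_opt_float(row.tail_cm),
                weight_g=_opt_float(row.weight_g),
                route_km=_opt_float(row.route_km),
                time_hhmm=None if pd.isna(row.time_hhmm) else str(row.time_hhmm),
                impact_point=None if pd.isna(row.impact_point) else str(row.impact_point),
            ))
        except (ValidationError, ValueError) as exc:
            bad.append(f"row {i}: {exc}")
    if bad:
        raise ValidationError(f"{path}: invalid rows:\n" + "\n".join(bad))
    return out


def encounters_to_frame(encounters) -> pd.DataFrame:
    """Flatten records to a DataFrame with the documented column order."""
    rows = []
    for e in encounters:
        rows.append({f.name: getattr(e, f.name) for f in fields(SnakeEncounter)})
    df = pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)
    if not df.empty:
        df["encounter_date"] = df["encounter_date"].map(lambda d: d.isoformat())
    return df


def write_encounters(encounters, path) -> None:
    encounters_to_frame(encounters).to_csv(path, index=False)


def read_efforts(path) -> list[SurveyEffort]:
    df = pd.read_csv(path)
    missing = [c for c in EFFORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return [
        SurveyEffort(
            survey_date=date.fromisoformat(str(r.survey_date)),
            survey_type=str(r.survey_type),
            distance_km=float(r.distance_km),
        )
        for r in df.itertuples(index=False)
    ]


def write_efforts(efforts, path) -> None:
    df = pd.DataFrame(
        [(e.survey_date.isoformat(), e.survey_type, e.distance_km) for e in efforts],
        columns=EFFORT_COLUMNS,
    )
    df.to_csv(path, index=False)


def total_length(e: SnakeEncounter) -> float | None:
    """SVL plus tail length (rattle excluded); missing if either part is."""
    if e.svl_cm is None or e.tail_cm is None:
        return None
    return e.svl_cm + e.tail_cm


_REQUIRE_FIELDS = {"svl": "svl_cm", "tail": "tail_cm", "weight": "weight_g"}


def filter_adult_atrox(
    encounters,
    svl_min: float | None = 40.0,
    require: frozenset | set = frozenset({"svl", "tail", "weight"}),
    species: str = "Crotalus atrox",
) -> list[SnakeEncounter]:
    """Subset to *C. atrox* above a strict SVL cutoff with complete measurements.

    ``svl_min=None`` disables the size filter (all sizes retained).  ``require``
    names the morphometrics that must be present ({'svl', 'tail', 'weight'}).
    Input order is preserved.
    """
    unknown = set(require) - set(_REQUIRE_FIELDS)
    if unknown:
        raise ValueError(f"unknown required fields: {sorted(unknown)}")
    out = []
    for e in encounters:
        if e.species != species:
            continue
        if any(getattr(e, _REQUIRE_FIELDS[r]) is None for r in require):
            continue
        if svl_min is not None and not (e.svl_cm is not None and e.svl_cm > svl_min):
            continue
        out.append(e)
    return out


def monthly_summary(encounters, efforts) -> pd.DataFrame:
    """Per-month survey summary plus an all-months total row.

    Columns: aor_count, dor_count, species_count, snakes_per_km,
    snakes_per_visit, pct_dor, aor_dor_ratio; indexed by year-month period
    with a final ``total`` row.  Every encounter month must have at least
    one effort record.
    """
    enc = pd.DataFrame({
        "month": [pd.Period(e.encounter_date, freq="M") for e in encounters],
        "species": [e.species for e in encounters],
        "dor": [e.status == "DOR" for e in encounters],
    })
    eff = pd.DataFrame({
        "month": [pd.Period(f.survey_date, freq="M") for f in efforts],
        "distance_km": [f.distance_km for f in efforts],
    })
    if not enc.empty:
        uncovered = sorted(set(enc["month"]) - set(eff["month"]))
        if uncovered:
            raise ValueError(f"encounter months with no recorded effort: {uncovered}")

    months = sorted(set(eff["month"]))
    rows = []

    def _row(label, e_sub, dist, visits):
        aor = int((~e_sub["dor"]).sum()) if not e_sub.empty else 0
        dor = int(e_sub["dor"].sum()) if not e_sub.empty else 0
        n = aor + dor
        rows.append({
            "month": label,
            "aor_count": aor,
            "dor_count": dor,
            "species_count": int(e_sub["species"].nunique()) if n else 0,
            "snakes_per_km": n / dist if dist > 0 else np.nan,
            "snakes_per_visit": n / visits if visits > 0 else np.nan,
            "pct_dor": 100.0 * dor / n if n else np.nan,
            "aor_dor_ratio": aor / dor if dor else np.nan,
        })

    for m in months:
        _row(str(m), enc[enc["month"] == m] if not enc.empty else enc,
             eff.loc[eff["month"] == m, "distance_km"].sum(),
             int((eff["month"] == m).sum()))
    _row("total", enc, eff["distance_km"].sum(), len(eff))
    return pd.DataFrame(rows).set_index("month")


def bin_route_positions(
    encounters, bin_km: float = 2.0, route_length_km: float = ROUTE_LENGTH_KM
):
    """Histogram of encounter positions along the route.

    The route is divided into full ``bin_km`` bins; a remainder shorter
    than one bin is merged into the final bin, so with the 37-km route and
    2-km bins there are 18 bins and the last spans 3 km.  Records without
    a position are skipped (and counted).

    Returns ``(counts, edges, n_skipped)``.
    """
    if bin_km <= 0:
        raise ValueError("bin_km must be positive")
    n_full = int(route_length_km // bin_km)
    edges = [i * bin_km for i in range(n_full)] + [route_length_km]
    if len(edges) < 2:
        edges = [0.0, route_length_km]
    edges = np.asarray(edges, dtype=float)
    positions = [e.route_km for e in encounters]
    n_skipped = sum(p is None for p in positions)
    if n_skipped:
        logger.info("bin_route_positions: skipped %d records without route_km", n_skipped)
    kept = np.array([p for p in positions if p is not None], dtype=float)
    counts, _ = np.histogram(kept, bins=edges)
    # np.histogram closes the last bin on the right, matching the route end.
    return counts, edges, n_skipped


def uniformity_chi_square(counts, bin_widths):
    """Goodness-of-fit test of spatial uniformity over (possibly unequal) bins.

    Expected counts are proportional to bin width.  Returns
    ``(statistic, df, p_value)`` with df = bins - 1 and the p-value from
    the upper tail of the chi-square distribution.
    """
    counts = np.asarray(counts, dtype=float)
    widths = np.asarray(bin_widths, dtype=float)
    if counts.shape != widths.shape:
        raise ValueError("counts and bin_widths must have equal length")
    total = counts.sum()
    if total < 1:
        raise ValueError("need at least one observation")
    expected = total * widths / widths.sum()
    if np.any(expected <= 0):
        raise ValueError("every bin must have positive expected count")
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = len(counts) - 1
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else float("nan")
    return statistic, df, p


_TRAITS = {"svl": "svl_cm", "tail": "tail_cm", "weight": "weight_g"}


def _group_stats(values) -> GroupStats | None:
    vals = np.array([v for v in values if v is not None], dtype=float)
    if vals.size == 0:
        return None
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else None
    return GroupStats(n=int(vals.size), mean=float(vals.mean()), sd=sd,
                      min=float(vals.min()), max=float(vals.max()))


def species_morphometry(encounters) -> pd.DataFrame:
    """Trait summaries and %DOR per species x demographic class.

    One row per species x class plus a per-species ``overall`` row.  %DOR
    uses every group member; trait summaries use only measured animals,
    and a trait with no measurements in the group is left missing.
    """
    rows = []
    by_species: dict[str, list[SnakeEncounter]] = {}
    for e in encounters:
        by_species.setdefault(e.species, []).append(e)
    for species in sorted(by_species):
        groups = {}
        for e in by_species[species]:
            groups.setdefault(e.demo_class, []).append(e)
        ordered = [c for c in DEMO_CLASSES if c in groups]
        for label, members in [(c, groups[c]) for c in ordered] + [
            ("overall", by_species[species])
        ]:
            row = {
                "species": species,
                "demo_class": label,
                "n_group": len(members),
                "pct_dor": 100.0 * sum(e.status == "DOR" for e in members) / len(members),
            }
            for trait, attr in _TRAITS.items():
                gs = _group_stats(getattr(e, attr) for e in members)
                if gs is None:
                    row.update({f"{trait}_{k}": np.nan for k in ("n", "mean", "sd", "min", "max")})
                else:
                    row.update({
                        f"{trait}_n": gs.n, f"{trait}_mean": gs.mean,
                        f"{trait}_sd": np.nan if gs.sd is None else gs.sd,
                        f"{trait}_min": gs.min, f"{trait}_max": gs.max,
                    })
            rows.append(row)
    return pd.DataFrame(rows)


def welch_t(a: GroupStats, b: GroupStats):
    """Welch's two-sample t-test from group summaries.

    Returns ``(t, df, p)`` with Welch--Satterthwaite degrees of freedom and
    a two-sided p-value.  Requires n >= 2 and an sd in each group.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("welch_t requires n >= 2 in both groups")
    if a.sd is None or b.sd is None:
        raise ValueError("welch_t requires sd in both groups")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se = math.sqrt(va + vb)
    if se == 0:
        # Identical constant groups: no evidence of a difference.
        return 0.0, float(a.n + b.n - 2), 1.0
    t = (a.mean - b.mean) / se
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def size_range_overlap(encounters) -> pd.DataFrame:
    """Per-species SVL range and count, split by AOR/DOR status.

    Groups with no measured SVL are reported with n = 0 and missing range.
    """
    rows = []
    species = sorted({e.species for e in encounters})
    for sp in species:
        for status in STATUSES:
            vals = [e.svl_cm for e in encounters
                    if e.species == sp and e.status == status and e.svl_cm is not None]
            rows.append({
                "species": sp, "status": status, "n": len(vals),
                "svl_min": min(vals) if vals else np.nan,
                "svl_max": max(vals) if vals else np.nan,
            })
    return pd.DataFrame(rows)
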