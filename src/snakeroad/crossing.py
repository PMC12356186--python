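"""Geometric Monte-Carlo simulation of snakes crossing a two-lane road.

The crossing is modeled as a static snapshot: the snake is a 1-D segment
of length L perpendicular to traffic, its head at a uniform position
over the paved width, the body extending toward the far edge (and past
it if the snake is longer than the remaining pavement).  A car
contributes two wheel intervals of width w whose centers sit one track
width apart; the snake dies if any wheel interval overlaps its body.
For a single car with both kill zones interior to the pavement the exact
kill probability is 2(L + w)/W, which anchors the Monte-Carlo estimate.

The two-car lateral-placement convention is configurable because the
published analysis does not state one; the default places each car
independently and uniformly across the full paved width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from . import fielddata

__all__ = [
    "RoadGeometry",
    "VehicleGeometry",
    "LengthMixture",
    "CrossingResult",
    "PLACEMENTS",
    "kill_zone",
    "analytic_single_car",
    "simulate_crossings",
    "mortality_by_length_curve",
    "default_length_mixture",
]

PLACEMENTS = ("centered_in_lane", "uniform_in_lane", "uniform_on_road", "same_lane")


@dataclass(frozen=True)
class RoadGeometry:
    """Two-lane paved road; lanes split the width equally."""

    width_cm: float = fielddata.ROAD_WIDTH_CM
    lane_count: int = 2

    def __post_init__(self):
        if self.width_cm <= 0 or self.lane_count < 1:
            raise ValueError("road width and lane count must be positive")

    @property
    def lane_width_cm(self) -> float:
        return self.width_cm / self.lane_count


@dataclass(frozen=True)
class VehicleGeometry:
    """Two wheels of ``wheel_width_cm`` with centers ``track_cm`` apart.

    ``track_convention`` selects whether the track is measured
    center-to-center (automotive convention, default) or edge-to-edge.
    """

    wheel_width_cm: float = fielddata.WHEEL_WIDTH_CM
    track_cm: float = fielddata.WHEEL_TRACK_CM
    track_convention: str = "center"

    def __post_init__(self):
        if self.wheel_width_cm <= 0:
            raise ValueError("wheel width must be positive")
        if self.track_center_cm <= self.wheel_width_cm:
            raise ValueError("track must exceed wheel width")
        if self.track_convention not in ("center", "edge"):
            raise ValueError("track_convention must be 'center' or 'edge'")

    @property
    def track_center_cm(self) -> float:
        """Center-to-center wheel separation."""
        if self.track_convention == "edge":
            return self.track_cm + self.wheel_width_cm
        return self.track_cm

    @property
    def footprint_cm(self) -> float:
        """Outer-edge-to-outer-edge width of the wheel pair."""
        return self.track_center_cm + self.wheel_width_cm

    def wheels_at(self, center: float) -> list[tuple[float, float]]:
        """Wheel intervals for a car whose lateral center is ``center``."""
        half = self.track_center_cm / 2
        w = self.wheel_width_cm / 2
        return [(center - half - w, center - half + w),
                (center + half - w, center + half + w)]


@dataclass(frozen=True)
class LengthMixture:
    """Normal mixture of snake total lengths, truncated to (low, high]."""

    components: tuple[tuple[float, float, float], ...]  # (mean, spread, weight)
    truncation: tuple[float, float] = (0.0, fielddata.MAX_OBSERVED_TOTAL_LENGTH_CM)

    def __post_init__(self):
        w = sum(c[2] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if any(c[1] < 0 for c in self.components):
            raise ValueError("spreads must be >= 0")
        if self.truncation[0] >= self.truncation[1]:
            raise ValueError("truncation bounds must be ordered")

    def mass_inside(self) -> float:
        """Probability mass the untruncated mixture places inside the bounds."""
        lo, hi = self.truncation
        total = 0.0
        for mean, spread, weight in self.components:
            if spread == 0:
                total += weight * (lo < mean <= hi)
            else:
                total += weight * (stats.norm.cdf(hi, mean, spread)
                                   - stats.norm.cdf(lo, mean, spread))
        return total

    def draw(self, n: int, rng) -> np.ndarray:
        if self.mass_inside() < 1e-12:
            raise ValueError("length mixture has no mass inside the truncation bounds")
        means = np.array([c[0] for c in self.components])
        spreads = np.array([c[1] for c in self.components])
        weights = np.array([c[2] for c in self.components])
        lo, hi = self.truncation
        out = np.empty(n)
        todo = np.arange(n)
        while todo.size:
            comp = rng.choice(len(means), size=todo.size, p=weights)
            draw = rng.normal(means[comp], spreads[comp])
            ok = (draw > lo) & (draw <= hi)
            out[todo[ok]] = draw[ok]
            todo = todo[~ok]
        return out


def default_length_mixture() -> LengthMixture:
    """The study's empirical mixture: measured AOR and DOR *C. atrox*
    total lengths as Normal(mean, standard error) components weighted by
    sample size, capped at the largest snake observed (135 cm)."""
    m_aor, sd_aor, n_aor = fielddata.ATROX_TOTAL_LENGTH_AOR
    m_dor, sd_dor, n_dor = fielddata.ATROX_TOTAL_LENGTH_DOR
    n = n_aor + n_dor
    return LengthMixture(components=(
        (m_aor, sd_aor / math.sqrt(n_aor), n_aor / n),
        (m_dor, sd_dor / math.sqrt(n_dor), n_dor / n),
    ))


@dataclass
class CrossingResult:
    """Per-trial outcomes and the binomial summary of a crossing run."""

    lengths: np.ndarray = field(repr=False)
    killed: np.ndarray = field(repr=False)
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_trials: int
    scenario: str
    placement: str


def kill_zone(wheels, L: float, domain: tuple[float, float]) -> list[tuple[float, float]]:
    """Head positions for which a snake of length ``L`` is struck.

    A wheel occupying [p, p + w] kills any snake whose body [head,
    head + L] overlaps it, i.e. heads in (p - L, p + w).  Returns the
    merged union of these intervals clipped to the head-position domain.
    """
    if L < 0:
        raise ValueError("snake length must be >= 0")
    lo_d, hi_d = domain
    raw = sorted((max(a - L, lo_d), min(b, hi_d)) for a, b in wheels)
    merged: list[tuple[float, float]] = []
    for a, b in raw:
        if b <= a:
            continue
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _zone_measure(intervals) -> float:
    return sum(b - a for a, b in intervals)


def analytic_single_car(
    L: float,
    road: RoadGeometry = RoadGeometry(),
    vehicle: VehicleGeometry = VehicleGeometry(),
    lane: int | None = None,
) -> float:
    """Exact kill probability for one car centered in a lane.

    With ``lane=None`` the probability is averaged over lanes (the body
    extends toward the far edge, so lanes are not symmetric once the
    kill zone clips at the near edge).  Equals 2(L + w)/W whenever both
    kill zones are interior to the pavement.
    """
    lanes = range(road.lane_count) if lane is None else [lane]
    domain = (0.0, road.width_cm)
    probs = []
    for i in lanes:
        center = (i + 0.5) * road.lane_width_cm
        zones = kill_zone(vehicle.wheels_at(center), L, domain)
        probs.append(_zone_measure(zones) / road.width_cm)
    return float(np.mean(probs))


def _car_centers(scenario, placement, road, vehicle, n, rng):
    """Per-trial lateral car centers, shape (n, n_cars)."""
    lane_w = road.lane_width_cm
    half = vehicle.footprint_cm / 2
    if lane_w < vehicle.footprint_cm and placement in ("centered_in_lane",
                                                       "uniform_in_lane", "same_lane"):
        raise ValueError("vehicle footprint does not fit in a lane")
    if road.width_cm < vehicle.footprint_cm:
        raise ValueError("vehicle footprint does not fit on the road")

    def uniform_in(lo, hi, size):
        return rng.uniform(lo, hi, size) if hi > lo else np.full(size, lo)

    if scenario == "one_car":
        lane = rng.integers(0, road.lane_count, n)
        if placement == "centered_in_lane":
            c = (lane + 0.5) * lane_w
        elif placement == "uniform_in_lane":
            c = lane * lane_w + uniform_in(half, lane_w - half, n)
        else:  # uniform_on_road (same_lane is meaningless for one car)
            c = uniform_in(half, road.width_cm - half, n)
        return c[:, None]
    if scenario == "two_car":
        if placement == "centered_in_lane":
            c1 = np.full(n, 0.5 * lane_w)
            c2 = np.full(n, 1.5 * lane_w)
        elif placement == "uniform_in_lane":
            c1 = uniform_in(half, lane_w - half, n)
            c2 = lane_w + uniform_in(half, lane_w - half, n)
        elif placement == "same_lane":
            lane = rng.integers(0, road.lane_count, n) * lane_w
            c1 = lane + uniform_in(half, lane_w - half, n)
            c2 = lane + uniform_in(half, lane_w - half, n)
        else:  # uniform_on_road
            c1 = uniform_in(half, road.width_cm - half, n)
            c2 = uniform_in(half, road.width_cm - half, n)
        return np.column_stack([c1, c2])
    raise ValueError("scenario must be 'one_car' or 'two_car'")


def _killed(heads, lengths, centers, vehicle):
    """Vectorized strike test for per-trial car centers."""
    k = np.zeros(heads.shape, dtype=bool)
    half = vehicle.track_center_cm / 2
    w = vehicle.wheel_width_cm / 2
    for j in range(centers.shape[1]):
        for s in (-1.0, 1.0):
            a = centers[:, j] + s * half - w
            b = centers[:, j] + s * half + w
            k |= (heads > a - lengths) & (heads < b)
    return k


def simulate_crossings(
    road: RoadGeometry = RoadGeometry(),
    vehicle: VehicleGeometry = VehicleGeometry(),
    mixture: LengthMixture | None = None,
    scenario: str = "one_car",
    n_trials: int = 10_000,
    seed=None,
    placement: str | None = None,
) -> CrossingResult:
    """Monte-Carlo road-crossing mortality under one- or two-car traffic.

    Each trial draws a snake length from the (truncated) mixture and a
    head position uniform over the paved width, places the car(s) per
    the placement policy, and records a kill if any wheel interval
    overlaps the body.  ``placement=None`` selects the scenario default:
    centered-in-a-random-lane for one car, independent uniform placement
    over the full width for two cars.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if mixture is None:
        mixture = default_length_mixture()
    if placement is None:
        placement = "centered_in_lane" if scenario == "one_car" else "uniform_on_road"
    if placement not in PLACEMENTS:
        raise ValueError(f"placement must be one of {PLACEMENTS}")
    rng = np.random.default_rng(seed)
    lengths = mixture.draw(n_trials, rng)
    heads = rng.uniform(0.0, road.width_cm, n_trials)
    centers = _car_centers(scenario, placement, road, vehicle, n_trials, rng)
    killed = _killed(heads, lengths, centers, vehicle)
    p = float(killed.mean())
    sd = math.sqrt(p * (1 - p))
    half_ci = 1.96 * sd / math.sqrt(n_trials)
    return CrossingResult(
        lengths=lengths,
        killed=killed,
        mean=p,
        sd=sd,
        ci_low=max(0.0, p - half_ci),
        ci_high=min(1.0, p + half_ci),
        n_trials=n_trials,
        scenario=scenario,
        placement=placement,
    )


def mortality_by_length_curve(
    result: CrossingResult, level: float = 0.95, grid=None
) -> pd.DataFrame:
    """Smoothed kill probability versus snake length with pointwise CIs.

    A univariate logistic regression of the per-trial kill flag on
    length; the CI is a normal interval on the log-odds scale.  Requires
    at least 100 trials spanning at least two distinct lengths.  A run
    where every trial had the same outcome yields a flat curve at the
    Jeffreys-adjusted rate.
    """
    if result.n_trials < 100:
        raise ValueError("need >= 100 trials")
    x = np.asarray(result.lengths, float)
    y = np.asarray(result.killed, float)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct lengths")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, float)
    if y.min() == y.max():
        p = (y.sum() + 0.5) / (len(y) + 1.0)  # Jeffreys-style pull off 0/1
        return pd.DataFrame({"length": grid, "prob": np.full_like(grid, p),
                             "ci_low": np.full_like(grid, p),
                             "ci_high": np.full_like(grid, p)})
    X = sm.add_constant(x)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-10)
    Xg = sm.add_constant(grid)
    eta = Xg @ res.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, res.cov_params(), Xg))
    z = stats.norm.ppf(0.5 + level / 2)
    return pd.DataFrame({
        "length": grid,
        "prob": expit(eta),
        "ci_low": expit(eta - z * se),
        "ci_high": expit(eta + z * se),
    })
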