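"""Viability selection on body size and its projected evolutionary response.

The standardized selection differential *s* contrasts survivors (AOR)
with casualties (DOR): all total lengths are pooled and standardized to
zero mean and unit sample SD, and s = mean(z | AOR) - mean(z | DOR), so
s is negative when road-killed snakes run larger.  Its sampling SD comes
from a case-resampling bootstrap.

The projection iterates the breeder's equation Z = h2 * s per
generation in 1,000 independent populations: each population draws its
heritability and selection differential once from Normal distributions
and holds them fixed, and the per-generation response decays as
exp(-k t) to mimic acclimation to road mortality.  The response is
applied directly in centimeters (an SD-scaled variant is available).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import fielddata

__all__ = [
    "SelectionEstimate",
    "EvoSimConfig",
    "EvoTrajectories",
    "selection_differential",
    "bootstrap_differential",
    "simulate_response",
    "expected_final_mean",
    "summarize_trajectories",
    "h2_final_regression",
    "generations_to_years",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionEstimate:
    """Standardized selection differential (SD units of total length)."""

    s: float
    sd_boot: float | None
    n_boot: int
    n_aor: int
    n_dor: int

    def __post_init__(self):
        if self.sd_boot is not None and self.sd_boot < 0:
            raise ValueError("sd_boot must be >= 0")


def _split_lengths(total_lengths, statuses):
    x = np.asarray(total_lengths, dtype=float)
    st = np.asarray(statuses)
    aor = x[st == "AOR"]
    dor = x[st == "DOR"]
    if len(aor) < 2 or len(dor) < 2:
        raise ValueError("need at least two snakes of each status")
    return x, aor, dor


def _point_s(x, aor, dor) -> float:
    z_sd = np.std(x, ddof=1)
    if z_sd == 0:
        return 0.0
    return float(((aor - x.mean()) / z_sd).mean() - ((dor - x.mean()) / z_sd).mean())


def selection_differential(total_lengths, statuses) -> SelectionEstimate:
    """Point estimate of s from total lengths and AOR/DOR labels."""
    x, aor, dor = _split_lengths(total_lengths, statuses)
    return SelectionEstimate(
        s=_point_s(x, aor, dor), sd_boot=None, n_boot=0,
        n_aor=len(aor), n_dor=len(dor),
    )


def bootstrap_differential(
    total_lengths, statuses, n_boot: int = 1000, seed=None, stratified: bool = False
) -> SelectionEstimate:
    """s with its bootstrap SD over ``n_boot`` case-resampling replicates.

    Replicates that lose one status entirely are redrawn (and logged).
    ``stratified=True`` resamples within status groups instead.
    """
    x, aor, dor = _split_lengths(total_lengths, statuses)
    st = np.asarray(statuses)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    n = len(x)
    redrawn = 0
    for b in range(n_boot):
        while True:
            if stratified:
                ia = rng.integers(0, len(aor), len(aor))
                idr = rng.integers(0, len(dor), len(dor))
                xa, xd = aor[ia], dor[idr]
            else:
                idx = rng.integers(0, n, n)
                sb = st[idx]
                if (sb == "AOR").sum() < 2 or (sb == "DOR").sum() < 2:
                    redrawn += 1
                    continue
                xa, xd = x[idx][sb == "AOR"], x[idx][sb == "DOR"]
            pooled = np.concatenate([xa, xd])
            sd = np.std(pooled, ddof=1)
            reps[b] = 0.0 if sd == 0 else float(
                ((xa - pooled.mean()) / sd).mean() - ((xd - pooled.mean()) / sd).mean()
            )
            break
    if redrawn:
        logger.info("bootstrap_differential: redrew %d degenerate replicates", redrawn)
    est = selection_differential(total_lengths, statuses)
    return SelectionEstimate(
        s=est.s, sd_boot=float(np.std(reps, ddof=1)), n_boot=n_boot,
        n_aor=est.n_aor, n_dor=est.n_dor,
    )


@dataclass(frozen=True)
class EvoSimConfig:
    """Breeder's-equation projection settings (defaults: study conditions)."""

    n_pops: int = 1000
    n_gens: int = 50
    h2_mean: float = fielddata.HERITABILITY_MEAN
    h2_sd: float = fielddata.HERITABILITY_SD
    s_mean: float = fielddata.SELECTION_S_MEAN
    s_sd: float = fielddata.SELECTION_S_SD
    start_mean_cm: float = fielddata.START_MEAN_TOTAL_LENGTH_CM
    decay_k: float = fielddata.SELECTION_DECAY_K
    generation_time_yr: float = fielddata.GENERATION_TIME_YR
    decay_form: str = "exp"          # 'exp': e^(-k t); 'geometric': (1-k)^t
    response_scale: str = "cm"       # 'cm': response applied directly in cm
    trait_sd_cm: float | None = None  # required for response_scale='sd'
    seed: int | None = None

    def __post_init__(self):
        if self.n_pops < 1 or self.n_gens < 1:
            raise ValueError("n_pops and n_gens must be >= 1")
        if self.h2_sd < 0 or self.s_sd < 0:
            raise ValueError("sds must be >= 0")
        if self.decay_form not in ("exp", "geometric"):
            raise ValueError("decay_form must be 'exp' or 'geometric'")
        if self.response_scale not in ("cm", "sd"):
            raise ValueError("response_scale must be 'cm' or 'sd'")
        if self.response_scale == "sd" and not self.trait_sd_cm:
            raise ValueError("response_scale='sd' requires trait_sd_cm")


@dataclass
class EvoTrajectories:
    """Simulated per-population mean total lengths by generation."""

    means: np.ndarray = field(repr=False)  # (n_pops, n_gens + 1)
    h2: np.ndarray = field(repr=False)
    s: np.ndarray = field(repr=False)
    config: EvoSimConfig

    def to_frame(self) -> pd.DataFrame:
        n_pops, n_cols = self.means.shape
        return pd.DataFrame({
            "population": np.repeat(np.arange(n_pops), n_cols),
            "generation": np.tile(np.arange(n_cols), n_pops),
            "mean_cm": self.means.ravel(),
            "h2": np.repeat(self.h2, n_cols),
            "s": np.repeat(self.s, n_cols),
        })


def _decay_weights(config: EvoSimConfig) -> np.ndarray:
    t = np.arange(config.n_gens)
    if config.decay_form == "exp":
        return np.exp(-config.decay_k * t)
    return (1.0 - config.decay_k) ** t


def simulate_response(config: EvoSimConfig = EvoSimConfig()) -> EvoTrajectories:
    """Iterate the breeder's equation with decaying selection.

    Per population p: draw h2_p ~ N(h2_mean, h2_sd) and s_p ~ N(s_mean,
    s_sd) once (untruncated, so sign-flipping draws can produce growing
    populations); then mean_{t+1} = mean_t + h2_p s_p d(t) with decay
    d(t) = exp(-k t), the response applied in centimeters.
    """
    rng = np.random.default_rng(config.seed)
    h2 = rng.normal(config.h2_mean, config.h2_sd, config.n_pops)
    s = rng.normal(config.s_mean, config.s_sd, config.n_pops)
    scale = config.trait_sd_cm if config.response_scale == "sd" else 1.0
    decay = _decay_weights(config)
    # cumulative response: start + h2*s*scale * cumsum(decay)
    cum = np.concatenate([[0.0], np.cumsum(decay)])
    means = config.start_mean_cm + np.outer(h2 * s * scale, cum)
    return EvoTrajectories(means=means, h2=h2, s=s, config=config)


def expected_final_mean(config: EvoSimConfig) -> float:
    """Closed-form expectation of the final grand mean (h2 and s independent)."""
    scale = config.trait_sd_cm if config.response_scale == "sd" else 1.0
    return config.start_mean_cm + (
        config.h2_mean * config.s_mean * scale * float(_decay_weights(config).sum())
    )


def summarize_trajectories(traj: EvoTrajectories, level: float = 0.95) -> dict:
    """Grand-mean final length with CI, shrinking/growing subset means,
    and the per-generation mean curve with a normal CI over populations."""
    means = traj.means
    if means.shape[0] < 2:
        raise ValueError("need >= 2 trajectories")
    z = stats.norm.ppf(0.5 + level / 2)
    final = means[:, -1]
    start = traj.config.start_mean_cm

    def _ci(vals):
        m = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        return m, m - z * se, m + z * se

    grand, g_lo, g_hi = _ci(final)
    dec = final[final < start]
    inc = final[final >= start]
    curve_mean = means.mean(axis=0)
    curve_se = means.std(axis=0, ddof=1) / math.sqrt(means.shape[0])
    curve = pd.DataFrame({
        "generation": np.arange(means.shape[1]),
        "mean_cm": curve_mean,
        "ci_low": curve_mean - z * curve_se,
        "ci_high": curve_mean + z * curve_se,
    })
    return {
        "grand_mean_final_cm": grand,
        "grand_mean_ci": (g_lo, g_hi),
        "n_decreasing": int(len(dec)),
        "n_increasing": int(len(inc)),
        "mean_final_decreasing_cm": float(dec.mean()) if len(dec) else float("nan"),
        "mean_final_increasing_cm": float(inc.mean()) if len(inc) else float("nan"),
        "curve": curve,
    }


def h2_final_regression(traj: EvoTrajectories):
    """OLS of final mean length on the drawn heritability.

    Returns ``(slope, intercept, p_value)`` with a two-sided test of the
    slope.  Larger h2 should shorten snakes when selection is negative.
    """
    h2 = traj.h2
    if len(h2) < 3:
        raise ValueError("need >= 3 trajectories")
    if np.std(h2) == 0:
        raise ValueError("heritability draws have zero variance")
    res = stats.linregress(h2, traj.means[:, -1])
    return float(res.slope), float(res.intercept), float(res.pvalue)


def generations_to_years(n_gens: float, generation_time_yr: float = fielddata.GENERATION_TIME_YR) -> float:
    """Calendar span of ``n_gens`` generations."""
    if n_gens < 0 or generation_time_yr <= 0:
        raise ValueError("inputs must be positive")
    return n_gens * generation_time_yr
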