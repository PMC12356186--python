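"""Logistic models of dead-on-road (DOR) status versus body size.

The modeling table has one row per snake with columns ``svl``, ``tail``,
``total_length`` (cm), ``weight`` (g), ``sex`` (female/juvenile/male,
reference female), ``month``, ``year`` and the binary response ``dor``.
The candidate set is ranked by AIC; the top model is summarised with
odds ratios (profile-likelihood CIs by default), discrimination (AUC),
a prediction curve over total length, a nonparametric cubic-spline
smooth of the fitted probabilities, and a length-by-weight selection
surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, stats
from scipy.interpolate import make_smoothing_spline
from scipy.special import expit
from scipy.stats import rankdata

__all__ = [
    "ModelSpec",
    "LogisticFit",
    "ConvergenceError",
    "STUDY_MODEL_SET",
    "fit_logistic",
    "rank_models",
    "odds_ratios",
    "auc",
    "auc_scores",
    "prediction_curve",
    "cubic_spline_probability",
    "selection_surface",
]


class ConvergenceError(RuntimeError):
    """Fit failed to converge (typically complete separation)."""


_TERM_LABELS = {
    "total_length": "Total length",
    "svl": "SVL",
    "weight": "Weight",
    "sex": "Sex",
    "month": "Month",
    "year": "Year",
}
_FORMULA_TERMS = {
    "total_length": "total_length",
    "svl": "svl",
    "weight": "weight",
    "sex": "C(sex, Treatment('female'))",
    "month": "C(month)",
    "year": "C(year)",
}


@dataclass(frozen=True)
class ModelSpec:
    """A DOR model as a list of terms.

    Terms are main effects (``total_length``, ``svl``, ``weight``,
    ``sex``, ``month``, ``year``) or ``a*b`` for a pair of main effects
    plus their interaction.
    """

    terms: tuple[str, ...]

    def __post_init__(self):
        seen = set()
        for t in self.terms:
            parts = t.split("*")
            for p in parts:
                if p not in _FORMULA_TERMS:
                    raise ValueError(f"unknown term {p!r}")
            if t in seen:
                raise ValueError(f"duplicate term {t!r}")
            seen.add(t)

    @classmethod
    def from_formula(cls, text: str) -> "ModelSpec":
        """Parse ``"DOR ~ Total length + Weight + Sex"`` style notation.

        Interactions may be written ``A:B`` or ``A*B``; either way the
        main effects are implied.
        """
        lhs, _, rhs = text.partition("~")
        if lhs.strip().lower() not in ("dor", ""):
            raise ValueError(f"response must be DOR, got {lhs.strip()!r}")
        label_map = {v.lower(): k for k, v in _TERM_LABELS.items()}
        label_map.update({k: k for k in _TERM_LABELS})

        def canon(name):
            key = name.strip().lower()
            if key not in label_map:
                raise ValueError(f"unknown variable {name.strip()!r}")
            return label_map[key]

        terms = []
        for chunk in rhs.split("+"):
            chunk = chunk.strip()
            if not chunk:
                continue
            for sep in ("*", ":"):
                if sep in chunk:
                    parts = [canon(p) for p in chunk.split(sep)]
                    terms.append("*".join(parts))
                    break
            else:
                terms.append(canon(chunk))
        return cls(tuple(terms))

    @property
    def variables(self) -> tuple[str, ...]:
        out = []
        for t in self.terms:
            for p in t.split("*"):
                if p not in out:
                    out.append(p)
        return tuple(out)

    @property
    def formula(self) -> str:
        rhs = " + ".join(
            " * ".join(_FORMULA_TERMS[p] for p in t.split("*")) for t in self.terms
        )
        return f"dor ~ {rhs}"

    @property
    def label(self) -> str:
        rhs = " + ".join(
            " * ".join(_TERM_LABELS[p] for p in t.split("*")) for t in self.terms
        )
        return f"DOR ~ {rhs}"


#: The candidate model set of the original analysis (same eleven
#: formulas for the adults-only and the all-sizes tables).
STUDY_MODEL_SET: tuple[ModelSpec, ...] = tuple(
    ModelSpec(t)
    for t in [
        ("total_length", "weight", "sex"),
        ("svl", "weight", "sex"),
        ("total_length*sex", "weight"),
        ("total_length", "sex"),
        ("svl*sex", "weight"),
        ("svl", "sex"),
        ("weight*sex", "svl"),
        ("total_length", "weight", "sex", "month", "year"),
        ("svl", "weight", "sex", "month", "year"),
        ("total_length", "weight", "sex", "month"),
        ("svl", "weight", "sex", "month"),
    ]
)


@dataclass
class LogisticFit:
    """A converged maximum-likelihood binomial logistic fit."""

    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    aic: float
    df: int
    n: int
    result: object = field(repr=False)
    data: pd.DataFrame = field(repr=False)


def _prepare(data: pd.DataFrame, variables) -> pd.DataFrame:
    sub = data.dropna(subset=[*variables, "dor"]).copy()
    if "sex" in sub.columns:
        sub["sex"] = sub["sex"].astype(str)
    return sub


def _separating_terms(sub: pd.DataFrame, spec: ModelSpec) -> list[str]:
    """Heuristic scan for covariates that completely separate the response."""
    y = sub["dor"].to_numpy()
    offenders = []
    for v in spec.variables:
        x = sub[v]
        if np.issubdtype(np.asarray(x).dtype, np.number):
            x = x.to_numpy(dtype=float)
            if y.min() != y.max() and (
                x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min()
            ):
                offenders.append(v)
        else:
            per_level = sub.groupby(x, observed=True)["dor"].nunique()
            if (per_level == 1).all() and len(per_level) > 1:
                offenders.append(v)
    return offenders


def fit_logistic(data: pd.DataFrame, spec: ModelSpec) -> LogisticFit:
    """Maximum-likelihood logistic fit of one model spec.

    Rows with a missing value in any used variable are dropped.  The
    response must show both classes, and complete separation raises
    :class:`ConvergenceError` naming the offending term(s).
    """
    sub = _prepare(data, spec.variables)
    y = sub["dor"] if "dor" in sub else pd.Series(dtype=float)
    if len(sub) == 0 or y.nunique() < 2:
        raise ValueError("response must contain both AOR and DOR rows")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            result = smf.glm(spec.formula, data=sub, family=sm.families.Binomial()).fit(
                tol=1e-10, maxiter=200
            )
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            offenders = _separating_terms(sub, spec)
            raise ConvergenceError(
                f"{spec.label}: complete separation"
                + (f" (offending terms: {', '.join(offenders)})" if offenders else "")
            ) from exc
    if not result.converged:
        raise ConvergenceError(f"{spec.label}: IRLS did not converge")
    k = len(result.params)
    if len(sub) < k + 1:
        raise ValueError(f"{spec.label}: needs at least {k + 1} rows, got {len(sub)}")
    mu = np.asarray(result.fittedvalues)
    if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
        offenders = _separating_terms(sub, spec)
        raise ConvergenceError(
            f"{spec.label}: fitted probabilities degenerate (separation)"
            + (f" (offending terms: {', '.join(offenders)})" if offenders else "")
        )
    return LogisticFit(
        spec=spec,
        params=result.params,
        cov=result.cov_params(),
        loglik=float(result.llf),
        aic=2 * k - 2 * float(result.llf),
        df=k,
        n=len(sub),
        result=result,
        data=sub,
    )


def rank_models(data: pd.DataFrame, specs) -> pd.DataFrame:
    """Fit a candidate set on the shared complete-case rows; rank by AIC.

    Ties break toward fewer parameters, then spec order.  Models that
    fail to fit are excluded with a warning.
    """
    specs = list(specs)
    all_vars = sorted({v for s in specs for v in s.variables})
    shared = data.dropna(subset=[*all_vars, "dor"])
    rows = []
    fits = {}
    for order, spec in enumerate(specs):
        try:
            fit = fit_logistic(shared, spec)
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"excluding model {spec.label}: {exc}", stacklevel=2)
            continue
        fits[spec.label] = fit
        rows.append({"model": spec.label, "df": fit.df, "aic": fit.aic, "_order": order})
    if not rows:
        table = pd.DataFrame(columns=["model", "df", "aic"])
        table.attrs["fits"] = {}
        return table
    table = pd.DataFrame(rows).sort_values(["aic", "df", "_order"]).drop(columns="_order")
    table = table.reset_index(drop=True)
    table.attrs["fits"] = fits
    return table


def _profile_ci_one(fit: LogisticFit, j: int, level: float):
    """Profile-likelihood interval for coefficient ``j`` via constrained refits."""
    model = fit.result.model
    X = np.asarray(model.exog, dtype=float)
    y = np.asarray(model.endog, dtype=float)
    xj = X[:, j]
    X_del = np.delete(X, j, axis=1)
    crit = stats.chi2.ppf(level, 1)
    bhat = float(fit.params.iloc[j])
    se = float(np.sqrt(fit.cov.iloc[j, j]))

    def dev_excess(bj):
        res = sm.GLM(y, X_del, family=sm.families.Binomial(), offset=bj * xj).fit(
            tol=1e-10, maxiter=200
        )
        return 2 * (fit.loglik - float(res.llf)) - crit

    bounds = []
    for sign in (-1.0, 1.0):
        hi = None
        for m in range(1, 41):
            cand = bhat + sign * m * 0.5 * se
            if dev_excess(cand) > 0:
                hi = cand
                break
        if hi is None:
            raise RuntimeError("profile bound not bracketed")
        lo = hi - sign * 0.5 * se
        bounds.append(optimize.brentq(dev_excess, *sorted((lo, hi)), xtol=1e-6 * max(se, 1e-8)))
    return min(bounds), max(bounds)


def odds_ratios(fit: LogisticFit, level: float = 0.95, method: str = "profile") -> pd.DataFrame:
    """Odds ratios with confidence intervals for every non-intercept term.

    ``method='profile'`` inverts the likelihood-ratio test (falling back
    to Wald with a warning if a bound cannot be bracketed);
    ``method='wald'`` uses the normal approximation on the log-odds scale.
    """
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for j, name in enumerate(fit.params.index):
        if name == "Intercept":
            continue
        b = float(fit.params.iloc[j])
        se = float(np.sqrt(fit.cov.iloc[j, j]))
        if method == "wald":
            lo, hi = b - z * se, b + z * se
            used = "wald"
        elif method == "profile":
            try:
                lo, hi = _profile_ci_one(fit, j, level)
                used = "profile"
            except RuntimeError:
                warnings.warn(
                    f"profile CI for {name} failed to bracket; falling back to Wald",
                    stacklevel=2,
                )
                lo, hi = b - z * se, b + z * se
                used = "wald"
        else:
            raise ValueError("method must be 'profile' or 'wald'")
        rows.append({
            "term": name, "estimate": b, "se": se,
            "odds_ratio": float(np.exp(b)),
            "ci_low": float(np.exp(lo)), "ci_high": float(np.exp(hi)),
            "method": used,
        })
    return pd.DataFrame(rows)


def auc_scores(scores, labels) -> float:
    """Rank-statistic AUC: concordance of scores with binary labels, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc(fit: LogisticFit, data: pd.DataFrame | None = None) -> float:
    """Area under the ROC curve of the fitted probabilities."""
    if data is None:
        data = fit.data
    else:
        data = _prepare(data, fit.spec.variables)
    probs = np.asarray(fit.result.predict(data))
    return auc_scores(probs, data["dor"].to_numpy())


def _reference_frame(fit: LogisticFit, overrides: dict) -> pd.DataFrame:
    """Covariates at sample means (numeric) / reference or modal level."""
    n = max(len(v) for v in overrides.values())
    cols = {}
    for v in fit.spec.variables:
        if v in overrides:
            cols[v] = np.asarray(overrides[v])
        elif v in ("total_length", "svl", "weight", "tail"):
            cols[v] = np.full(n, float(fit.data[v].mean()))
        elif v == "sex":
            cols[v] = np.full(n, "female", dtype=object)
        else:
            cols[v] = np.full(n, fit.data[v].mode().iloc[0])
    return pd.DataFrame(cols)


def _predict_with_ci(fit: LogisticFit, frame: pd.DataFrame, level: float):
    pred = fit.result.get_prediction(frame)
    sf = pred.summary_frame(alpha=1 - level)
    return (
        np.asarray(sf["mean"]),
        np.asarray(sf["mean_ci_lower"]),
        np.asarray(sf["mean_ci_upper"]),
    )


def prediction_curve(
    fit: LogisticFit,
    grid=None,
    covariate: str = "total_length",
    level: float = 0.95,
) -> pd.DataFrame:
    """DOR probability versus one covariate with pointwise CIs.

    Other numeric covariates are held at their sample means and
    categorical ones at the reference (female) or modal level; the CI is
    a normal interval on the log-odds scale mapped through the inverse
    link.  Grid points outside the observed range are allowed but
    flagged with a warning.
    """
    observed = fit.data[covariate].to_numpy(dtype=float)
    if grid is None:
        grid = np.linspace(observed.min(), observed.max(), 100)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < observed.min() or grid.max() > observed.max():
        warnings.warn(f"grid extends beyond observed {covariate} range (extrapolation)",
                      stacklevel=2)
    frame = _reference_frame(fit, {covariate: grid})
    prob, lo, hi = _predict_with_ci(fit, frame, level)
    return pd.DataFrame({covariate: grid, "prob": prob, "ci_low": lo, "ci_high": hi})


def cubic_spline_probability(
    lengths,
    fitted_probabilities,
    n_boot: int = 500,
    seed=None,
    grid=None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Cubic smoothing spline of per-individual DOR probabilities vs length.

    Smoothing is chosen by generalized cross-validation; the CI is a
    case-resampling bootstrap percentile band.  Outputs are clamped to
    [0, 1].  Requires at least 10 points.
    """
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(fitted_probabilities, dtype=float)
    if len(x) < 10:
        raise ValueError("cubic_spline_probability requires >= 10 points")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, dtype=float)

    def smooth(xs, ys):
        # average duplicate abscissae; the spline needs strictly increasing x
        order = np.argsort(xs)
        xs, ys = xs[order], ys[order]
        xu, inv = np.unique(xs, return_inverse=True)
        yu = np.bincount(inv, weights=ys) / np.bincount(inv)
        if len(xu) < 5:
            return None
        if np.allclose(yu, yu[0]):
            return lambda g: np.full_like(g, yu[0])
        spl = make_smoothing_spline(xu, yu)
        return spl

    base = smooth(x, y)
    if base is None:
        raise ValueError("need at least 5 distinct length values")
    fit_vals = np.clip(base(grid), 0.0, 1.0)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(grid)))
    b = 0
    attempts = 0
    while b < n_boot and attempts < 20 * n_boot:
        attempts += 1
        idx = rng.integers(0, len(x), len(x))
        spl = smooth(x[idx], y[idx])
        if spl is None:
            continue
        boots[b] = np.clip(spl(grid), 0.0, 1.0)
        b += 1
    if b < n_boot:
        boots = boots[:b]
    alpha = 1 - level
    lo = np.quantile(boots, alpha / 2, axis=0)
    hi = np.quantile(boots, 1 - alpha / 2, axis=0)
    return pd.DataFrame({
        "total_length": grid, "prob": fit_vals,
        "ci_low": np.clip(lo, 0, 1), "ci_high": np.clip(hi, 0, 1),
    })


def selection_surface(fit: LogisticFit, length_grid, weight_grid) -> pd.DataFrame:
    """Predicted DOR probability over a total-length x weight grid.

    Sex is held at the reference (female).  Returns a long-format frame
    with columns total_length, weight, prob.
    """
    L, W = np.meshgrid(np.asarray(length_grid, float), np.asarray(weight_grid, float))
    frame = _reference_frame(fit, {"total_length": L.ravel(), "weight": W.ravel()})
    prob = np.asarray(fit.result.predict(frame))
    return pd.DataFrame({
        "total_length": L.ravel(), "weight": W.ravel(), "prob": prob,
    })
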