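"""Population statistics relating chromatin-texture features to growth behavior.

Per-cell features are pooled per sample into mean +/- SD summaries; sample
means are correlated (Pearson) against growth rate, defined as the inverse of
the population doubling time with senescent samples (infinite doubling time)
mapped to rate 0.  Feature-versus-growth trends are fitted with a logistic
curve, and alternative models (linear, logarithmic, quadratic, exponential)
are compared by extra-sum-of-squares F-tests between models of different
complexity, with the small-sample-corrected information criterion (AICc)
breaking ties between equally complex, non-nested models.  Group contrasts
use Welch's two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ("volume_px", "mean_dapi", "mean_mec", "lid_pct", "lim_pct", "cond", "meth", "assoc")


@dataclass
class SampleRecord:
    """One immunofluorescence sample: metadata plus its per-cell feature table."""

    sample_id: str
    cell_type: str = ""
    passage: str | int = ""
    doubling_time_days: float = np.inf
    condition: str = "normal"
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        dt = float(self.doubling_time_days)
        if not (dt > 0):  # rejects 0, negatives and NaN; inf allowed
            raise ValueError(f"doubling time must be positive or infinite, got {dt}")
        self.doubling_time_days = dt

    @property
    def growth_rate(self) -> float:
        """Inverse doubling time (1/day); 0 for growth-arrested samples."""
        return 0.0 if math.isinf(self.doubling_time_days) else 1.0 / self.doubling_time_days


@dataclass
class FitResult:
    """Outcome of one model fit (and optionally its model-selection table)."""

    model: str
    params: dict[str, float]
    rss: float
    dof: int
    r2: float
    n: int
    aicc: float
    degenerate: bool = False
    message: str = ""
    comparisons: pd.DataFrame | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _MODELS[self.model].predict(np.asarray(x, dtype=float), self.params)


def summarize(sample: SampleRecord, features: Sequence[str] = FEATURE_COLUMNS) -> pd.DataFrame:
    """Mean +/- SD (n-1 denominator) per feature, plus the cell count.

    Returns a frame indexed by feature with columns ``mean``, ``sd`` and ``n``.
    """
    cells = sample.cells
    if len(cells) < 2:
        raise ValueError(f"sample {sample.sample_id}: need >= 2 cells, got {len(cells)}")
    present = [f for f in features if f in cells.columns]
    out = pd.DataFrame({
        "mean": cells[present].mean(),
        "sd": cells[present].std(ddof=1),
        "n": len(cells),
    })
    out.index.name = "feature"
    return out


def pearson_vs_growth(
    samples: Sequence[SampleRecord],
    feature: str,
) -> tuple[float, float]:
    """Pearson r (and r^2) of sample-mean feature versus growth rate.

    One point per sample: x is the inverse doubling time, y the sample-mean
    feature.  Samples whose feature is undefined are dropped and logged.
    """
    xs, ys = [], []
    for s in samples:
        if feature not in s.cells.columns or len(s.cells) == 0:
            logger.info("pearson_vs_growth: dropping sample %s (no %s)", s.sample_id, feature)
            continue
        y = float(s.cells[feature].mean())
        if not np.isfinite(y):
            logger.info("pearson_vs_growth: dropping sample %s (undefined %s)", s.sample_id, feature)
            continue
        xs.append(s.growth_rate)
        ys.append(y)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 usable samples, got {len(xs)}")
    x = np.array(xs)
    y = np.array(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in growth rate or feature")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


# ---------------------------------------------------------------------------
# Model registry for trend fitting / model selection
# ---------------------------------------------------------------------------

@dataclass
class _Model:
    name: str
    n_params: int
    fit: Callable[[np.ndarray, np.ndarray, int], tuple[dict[str, float], float]]
    predict: Callable[[np.ndarray, dict[str, float]], np.ndarray]


def _fit_linear(x, y, seed):
    coef = np.polyfit(x, y, 1)
    params = {"slope": float(coef[0]), "intercept": float(coef[1])}
    rss = float(np.sum((np.polyval(coef, x) - y) ** 2))
    return params, rss


def _predict_linear(x, p):
    return p["slope"] * x + p["intercept"]


def _fit_poly2(x, y, seed):
    coef = np.polyfit(x, y, 2)
    params = {"a2": float(coef[0]), "a1": float(coef[1]), "a0": float(coef[2])}
    rss = float(np.sum((np.polyval(coef, x) - y) ** 2))
    return params, rss


def _predict_poly2(x, p):
    return p["a2"] * x**2 + p["a1"] * x + p["a0"]


def _log_shift(x):
    positive = x[x > 0]
    if len(positive) == 0:
        raise FitError("logarithmic model needs at least one positive x")
    return 0.0 if x.min() > 0 else 0.5 * float(positive.min())


def _fit_log(x, y, seed):
    shift = _log_shift(x)
    lx = np.log(x + shift)
    coef = np.polyfit(lx, y, 1)
    params = {"slope": float(coef[0]), "intercept": float(coef[1]), "shift": shift}
    rss = float(np.sum((np.polyval(coef, lx) - y) ** 2))
    return params, rss


def _predict_log(x, p):
    return p["slope"] * np.log(x + p["shift"]) + p["intercept"]


def _logistic(x, L, k, x0, b):
    return L / (1.0 + np.exp(-np.clip(k * (x - x0), -500, 500))) + b


def _fit_logistic_raw(x, y, seed):
    span = float(np.ptp(y)) or 1.0
    sx = float(np.std(x)) or 1.0
    starts = []
    for L0 in (span, 1.5 * span):
        for b0 in (float(y.min()), float(y.min()) - 0.1 * span):
            for x00 in np.quantile(x, (0.25, 0.5, 0.75)):
                for k0 in (2.0 / sx, -2.0 / sx, 8.0 / sx):
                    starts.append((L0, k0, float(x00), b0))
    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: _logistic(x, *p) - y, p0, method="lm", max_nfev=2000
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1] - 1e-15:
            best = (res.x, rss)
    if best is None:
        raise FitError("logistic fit failed from every start")
    p = best[0]
    params = {"L": float(p[0]), "k": float(p[1]), "x0": float(p[2]), "b": float(p[3])}
    return params, best[1]


def _predict_logistic(x, p):
    return _logistic(x, p["L"], p["k"], p["x0"], p["b"])


def _fit_exp(x, y, seed):
    sx = float(np.std(x)) or 1.0
    span = float(np.ptp(y)) or 1.0
    starts = []
    for c0 in (1.0 / sx, -1.0 / sx, 3.0 / sx, -3.0 / sx):
        for b0 in (span, -span):
            starts.append((float(y.min()), b0, c0))
    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: p[0] + p[1] * np.exp(np.clip(p[2] * x, -500, 500)) - y,
                p0, method="lm", max_nfev=2000,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1] - 1e-15:
            best = (res.x, rss)
    if best is None:
        raise FitError("exponential fit failed from every start")
    p = best[0]
    return {"a": float(p[0]), "b": float(p[1]), "c": float(p[2])}, best[1]


def _predict_exp(x, p):
    return p["a"] + p["b"] * np.exp(p["c"] * x)


_MODELS = {
    "linear": _Model("linear", 2, _fit_linear, _predict_linear),
    "logarithmic": _Model("logarithmic", 2, _fit_log, _predict_log),
    "polynomial2": _Model("polynomial2", 3, _fit_poly2, _predict_poly2),
    "exponential": _Model("exponential", 3, _fit_exp, _predict_exp),
    "logistic": _Model("logistic", 4, _fit_logistic_raw, _predict_logistic),
}

DEFAULT_CANDIDATES = ("linear", "logarithmic", "polynomial2", "exponential", "logistic")


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = math.inf
    return aic


def _make_result(name: str, params: dict, rss: float, x: np.ndarray, y: np.ndarray) -> FitResult:
    n = len(x)
    k = _MODELS[name].n_params
    tss = float(np.sum((y - y.mean()) ** 2))
    degenerate = np.ptp(y) == 0
    r2 = 0.0 if degenerate else max(0.0, 1.0 - rss / tss)
    return FitResult(
        model=name, params=params, rss=rss, dof=max(n - k, 1), r2=r2, n=n,
        aicc=_aicc(rss, n, k),
        degenerate=degenerate,
        message="response is constant; parameters unidentifiable" if degenerate else "",
    )


def fit_logistic(x: Sequence[float], y: Sequence[float], seed: int = 0) -> FitResult:
    """Least-squares logistic fit y = L / (1 + exp(-k (x - x0))) + b.

    Multi-start initialization over amplitude, midpoint and slope; the best
    residual sum of squares wins.  A constant response is returned flagged as
    degenerate (the slope k is unidentifiable) rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError(f"need >= 5 points for a 4-parameter logistic, got {len(x)}")
    if np.ptp(y) == 0:
        params = {"L": 0.0, "k": 0.0, "x0": float(x.mean()), "b": float(y[0])}
        return _make_result("logistic", params, 0.0, x, y)
    params, rss = _fit_logistic_raw(x, y, seed)
    return _make_result("logistic", params, rss, x, y)


def select_model(
    x: Sequence[float],
    y: Sequence[float],
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    alpha: float = 0.05,
    seed: int = 0,
) -> FitResult:
    """Fit every candidate and pick a winner by F-test / information criterion.

    Models are ordered by parameter count.  Within a complexity tier the best
    AICc wins (non-nested models cannot be F-tested); a more complex model
    replaces the incumbent only when the extra-sum-of-squares F-test justifies
    its additional parameters at level ``alpha``.  The winner carries the full
    comparison table.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError(f"need >= 5 points, got {len(x)}")
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for name in candidates:
        if name not in _MODELS:
            raise ValueError(f"unknown model {name!r}; available: {sorted(_MODELS)}")
        try:
            params, rss = _MODELS[name].fit(x, y, seed)
            if len(x) - _MODELS[name].n_params < 1:
                raise FitError(f"{name}: no residual degrees of freedom at n={len(x)}")
            fits[name] = _make_result(name, params, rss, x, y)
        except (FitError, np.linalg.LinAlgError) as exc:
            failures[name] = str(exc)
            logger.warning("select_model: %s failed: %s", name, exc)
    if not fits:
        raise FitError(f"all candidate fits failed: {failures}")

    tiers: dict[int, list[FitResult]] = {}
    for fr in fits.values():
        tiers.setdefault(_MODELS[fr.model].n_params, []).append(fr)

    f_pvalues: dict[str, float] = {}
    current: FitResult | None = None
    for k in sorted(tiers):
        tier_best = min(tiers[k], key=lambda fr: fr.aicc)
        if current is None:
            current = tier_best
            continue
        p_val = _extra_ss_ftest(current, tier_best, len(x))
        f_pvalues[tier_best.model] = p_val
        if p_val < alpha and tier_best.rss < current.rss:
            current = tier_best
    assert current is not None
    table = pd.DataFrame([
        {
            "model": fr.model, "n_params": _MODELS[fr.model].n_params,
            "rss": fr.rss, "r2": fr.r2, "aicc": fr.aicc,
            "f_p_vs_incumbent": f_pvalues.get(fr.model, np.nan),
            "selected": fr.model == current.model,
        }
        for fr in sorted(fits.values(), key=lambda fr: (_MODELS[fr.model].n_params, fr.model))
    ])
    winner = fits[current.model]
    winner.comparisons = table
    return winner


def _extra_ss_ftest(simple: FitResult, complex_: FitResult, n: int) -> float:
    """Extra-sum-of-squares F-test p-value for the more complex model."""
    k0 = _MODELS[simple.model].n_params
    k1 = _MODELS[complex_.model].n_params
    dfn = k1 - k0
    dfd = n - k1
    if dfn <= 0 or dfd <= 0:
        return float("nan")
    if complex_.rss <= 0:
        return 0.0
    f = ((simple.rss - complex_.rss) / dfn) / (complex_.rss / dfd)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, dfn, dfd))


def two_sample_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sample t statistic and two-sided p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must be finite")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise ValueError("degenerate groups: both constant with different values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def correlation_table(
    samples: Sequence[SampleRecord],
    features: Sequence[str] = ("cond", "meth", "assoc"),
) -> pd.DataFrame:
    """Pearson r and r^2 of each feature versus growth rate, one row per feature."""
    rows = []
    for feature in features:
        r, r2 = pearson_vs_growth(samples, feature)
        rows.append({"feature": feature, "r": r, "r2": r2})
    return pd.DataFrame(rows)
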