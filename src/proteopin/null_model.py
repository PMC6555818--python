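"""Weibull null model converting cohort PIN values into P-values.

The PIN values of the non-degraded samples of a cohort are modeled as
draws from a Weibull distribution with scale ``lambda`` and shape ``k``.
The degradation P-value of a sample with PIN ``x`` is then the lower
tail of that null,

    P = F(x; lambda, k) = 1 - exp(-(x / lambda) ** k),

i.e. the probability of observing so small a PIN in an intact sample.
Because degraded samples contaminate the cohort, the null is fitted
iteratively: fit on the currently included samples and measure the
Kolmogorov-Smirnov distance D (step A); compute P-values for all
samples from that fit and exclude those below an exclusion threshold
(0.02 by default, step B); repeat until the excluded set stabilizes or
the fit stops improving (smallest D wins), and score every sample with
the converged parameters.

Fitting is exact maximum likelihood via the one-dimensional profile
likelihood in ``k`` (deterministic bracketed root search, so results
are bit-stable across runs), with ``lambda`` recovered in closed form:

    lambda_hat ** k = mean(x_i ** k)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "NullModel",
    "weibull_pvalue",
    "fit_weibull",
    "ks_statistic",
    "fit_null_iterative",
    "score_cohort",
]

MIN_COHORT = 5

_TINY = np.finfo(float).tiny


@dataclass
class NullModel:
    """A converged Weibull null fit for one cohort.

    ``trace`` holds one entry per iteration:
    ``(scale_lambda, shape_k, ks_d, excluded_ids_frozenset)``.
    """

    scale_lambda: float
    shape_k: float
    ks_d: float
    included_samples: frozenset[str]
    excluded_samples: frozenset[str]
    exclusion_p: float = 0.02
    n_iterations: int = 1
    trace: list[tuple[float, float, float, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale_lambda <= 0 or self.shape_k <= 0:
            raise ValueError("Weibull parameters must be positive")
        if not self.included_samples:
            raise ValueError("included_samples must be non-empty")

    def pvalue(self, pin) -> float | np.ndarray:
        return weibull_pvalue(pin, self.scale_lambda, self.shape_k)

    def to_dict(self) -> dict:
        return {
            "scale_lambda": self.scale_lambda,
            "shape_k": self.shape_k,
            "ks_d": self.ks_d,
            "exclusion_p": self.exclusion_p,
            "n_iterations": self.n_iterations,
            "included_samples": sorted(self.included_samples),
            "excluded_samples": sorted(self.excluded_samples),
            "trace": [
                {
                    "scale_lambda": lam,
                    "shape_k": k,
                    "ks_d": d,
                    "excluded_samples": sorted(excl),
                }
                for lam, k, d, excl in self.trace
            ],
        }


def weibull_pvalue(pin, scale_lambda: float, shape_k: float):
    """Lower-tail Weibull probability ``1 - exp(-(pin/lambda)**k)``.

    Strictly increasing in ``pin``; vectorized.  PIN values of exactly 0
    are clamped to the smallest positive float (the tail below machine
    resolution), keeping the map defined on [0, 1].
    """
    if scale_lambda <= 0 or shape_k <= 0:
        raise ValueError("Weibull parameters must be positive")
    x = np.asarray(pin, dtype=float)
    if (x < 0).any():
        raise ValueError("PIN must be non-negative")
    x = np.maximum(x, _TINY)
    p = -np.expm1(-((x / scale_lambda) ** shape_k))
    return float(p) if np.isscalar(pin) else p


def _profile_score(k: float, x: np.ndarray, mean_logx: float) -> float:
    # d/dk of the profile log-likelihood, zero at the MLE:
    #   sum(x^k log x)/sum(x^k) - 1/k - mean(log x) = 0
    xk = x**k
    return float(np.sum(xk * np.log(x)) / np.sum(xk) - 1.0 / k - mean_logx)


def fit_weibull(pins) -> tuple[float, float]:
    """Maximum-likelihood Weibull (scale, shape) estimates.

    Requires at least :data:`MIN_COHORT` positive values with non-zero
    variance.  The shape is found by bracketed root search on the
    profile-likelihood score (relative tolerance 1e-10); the scale then
    follows in closed form.  Scale-equivariant: fitting ``c * pins``
    yields ``(c * lambda, k)``.
    """
    x = np.asarray(pins, dtype=float)
    if x.size < MIN_COHORT:
        raise ValueError(
            f"Weibull fit needs a cohort of at least {MIN_COHORT} PIN values, "
            f"got {x.size}"
        )
    if (x <= 0).any() or np.isnan(x).any():
        raise ValueError("PIN values must be positive and finite for fitting")
    if np.ptp(x) == 0:
        raise ValueError(
            "PIN values are all identical; a cohort with variation is required"
        )
    # work on x/max(x) for overflow safety; k is scale-invariant
    scale0 = float(x.max())
    y = x / scale0
    mean_logy = float(np.mean(np.log(y)))

    # moment-based starting point: CV of a Weibull ~ 1.2825/k for large k
    cv = float(np.std(y) / np.mean(y))
    k0 = min(max(1.2825 / cv, 0.05), 1e5)

    # the profile score increases in k from -inf to -mean(log y) > 0
    lo, hi = k0, k0
    while _profile_score(lo, y, mean_logy) > 0:
        lo /= 2.0
        if lo < 1e-8:
            raise ValueError("Weibull shape bracketing failed (k -> 0)")
    while _profile_score(hi, y, mean_logy) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError("Weibull shape bracketing failed (k -> inf)")
    if lo == hi:  # k0 was an exact root
        k_hat = lo
    else:
        k_hat = optimize.brentq(
            _profile_score, lo, hi, args=(y, mean_logy), rtol=1e-10, maxiter=200
        )
    lam_hat = float(np.mean(y**k_hat) ** (1.0 / k_hat)) * scale0
    return lam_hat, float(k_hat)


def ks_statistic(pins, scale_lambda: float, shape_k: float) -> float:
    """Kolmogorov-Smirnov D between the empirical CDF and a Weibull CDF.

    The supremum is attained at an ECDF jump, so D is evaluated at both
    one-sided limits of every observation.
    """
    x = np.sort(np.asarray(pins, dtype=float))
    if x.size == 0:
        raise ValueError("pins must be non-empty")
    cdf = weibull_pvalue(x, scale_lambda, shape_k)
    n = x.size
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def fit_null_iterative(
    scores,
    exclusion_p: float = 0.02,
    max_iterations: int = 50,
) -> NullModel:
    """Iteratively fit the Weibull null, excluding degraded samples.

    Parameters
    ----------
    scores
        Either a DataFrame with ``sample`` and ``pin`` columns, a Series
        of PINs indexed by sample id, or a plain sequence of PINs (ids
        are then positional strings).
    exclusion_p
        Samples with P below this under the current fit are excluded
        from the next fit (cumulatively: a sample never re-enters).
    max_iterations
        Hard iteration cap.

    Stops when the excluded set is unchanged between iterations, or when
    D worsens relative to the best fit seen (the best-D iteration's
    model is returned), or at *max_iterations*.
    """
    ids, pins = _as_cohort(scores)
    if not 0 < exclusion_p < 1:
        raise ValueError("exclusion_p must be in (0, 1)")
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")

    excluded: set[str] = set()
    trace: list[tuple[float, float, float, frozenset[str]]] = []
    best: tuple[float, int] | None = None  # (ks_d, iteration index)

    for _ in range(max_iterations):
        mask = np.array([i not in excluded for i in ids])
        if mask.sum() < MIN_COHORT:
            raise ValueError(
                "cohort too degraded to define a null: fewer than "
                f"{MIN_COHORT} samples remain after exclusion"
            )
        lam, k = fit_weibull(pins[mask])
        d = ks_statistic(pins[mask], lam, k)
        trace.append((lam, k, d, frozenset(excluded)))

        if best is None or d < trace[best[1]][2]:
            best = (d, len(trace) - 1)
        elif d > trace[best[1]][2]:
            best_iter = best[1]
            lam, k, d, excl = trace[best_iter]
            return _model(lam, k, d, ids, excl, exclusion_p, trace)

        p = weibull_pvalue(pins, lam, k)
        new_excluded = excluded | {i for i, pv in zip(ids, p) if pv < exclusion_p}
        if new_excluded == excluded:
            return _model(lam, k, d, ids, frozenset(excluded), exclusion_p, trace)
        excluded = new_excluded

    lam, k, d, excl = trace[best[1]]
    return _model(lam, k, d, ids, excl, exclusion_p, trace)


def _model(lam, k, d, ids, excluded, exclusion_p, trace) -> NullModel:
    return NullModel(
        scale_lambda=lam,
        shape_k=k,
        ks_d=d,
        included_samples=frozenset(i for i in ids if i not in excluded),
        excluded_samples=frozenset(excluded),
        exclusion_p=exclusion_p,
        n_iterations=len(trace),
        trace=trace,
    )


def score_cohort(
    scores,
    model: NullModel,
    significance: float = 0.01,
) -> pd.DataFrame:
    """P-values and degradation flags for every sample of a cohort.

    All samples — including those excluded during fitting — are scored
    with the converged parameters; a sample is flagged degraded when its
    P-value is strictly below *significance*.
    """
    ids, pins = _as_cohort(scores)
    p = weibull_pvalue(pins, model.scale_lambda, model.shape_k)
    out = pd.DataFrame({"sample": ids, "pin": pins, "p_value": p})
    if isinstance(scores, pd.DataFrame) and "n_proteins" in scores.columns:
        out.insert(2, "n_proteins", scores["n_proteins"].to_numpy())
    out["degraded"] = out["p_value"] < significance
    return out


def _as_cohort(scores) -> tuple[list[str], np.ndarray]:
    if isinstance(scores, pd.DataFrame):
        if "pin" not in scores.columns or "sample" not in scores.columns:
            raise ValueError("scores DataFrame needs 'sample' and 'pin' columns")
        return [str(s) for s in scores["sample"]], scores["pin"].to_numpy(dtype=float)
    if isinstance(scores, pd.Series):
        return [str(s) for s in scores.index], scores.to_numpy(dtype=float)
    pins = np.asarray(list(scores), dtype=float)
    return [str(i) for i in range(pins.size)], pins
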