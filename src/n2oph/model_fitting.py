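"""Polynomial regression with small-sample AICc model selection and peak location.

Unimodal ("hump-shaped") responses to soil pH are modelled throughout the
package as concave second-order polynomials fitted by (optionally weighted)
ordinary least squares.  A degree-1 and a degree-2 fit compete on AICc; the
quadratic is retained only when it beats the line by more than a threshold
(default 2 AICc units), otherwise the simpler model wins on parsimony.  For a
concave quadratic ``c0 + c1*x + c2*x**2`` the peak is the vertex
``x* = -c1 / (2*c2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FitResult",
    "fit_polynomial",
    "aicc",
    "select_model",
    "vertex",
    "confidence_band",
]

ModelKind = Literal["linear", "quadratic"]


@dataclass(frozen=True)
class FitResult:
    """A fitted degree-1 or degree-2 polynomial.

    Coefficients are stored in ascending order: ``c0`` intercept, ``c1``
    slope, ``c2`` curvature (``None`` for a linear fit).  ``peak_x`` is set
    only for concave quadratics; ``peak_in_range`` flags whether the vertex
    falls inside the observed x-range.
    """

    model_kind: ModelKind
    c0: float
    c1: float
    c2: float | None
    n_obs: int
    rss: float
    adj_r2: float
    aicc: float
    peak_x: float | None = None
    peak_y: float | None = None
    peak_in_range: bool | None = None
    x_min: float = field(default=float("nan"), repr=False)
    x_max: float = field(default=float("nan"), repr=False)
    # retained for confidence bands: unscaled covariance (X' W X)^-1 and sigma^2
    _xtwx_inv: tuple | None = field(default=None, repr=False, compare=False)
    _sigma2: float = field(default=float("nan"), repr=False, compare=False)

    @property
    def degree(self) -> int:
        return 1 if self.model_kind == "linear" else 2

    @property
    def coefficients(self) -> tuple[float, ...]:
        if self.model_kind == "linear":
            return (self.c0, self.c1)
        return (self.c0, self.c1, self.c2)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.c0 + self.c1 * x
        if self.c2 is not None:
            y = y + self.c2 * x**2
        return y

    def to_dict(self) -> dict:
        return {
            "model": self.model_kind,
            "coefficients": list(self.coefficients),
            "n": self.n_obs,
            "rss": self.rss,
            "adj_r2": self.adj_r2,
            "aicc": self.aicc,
            "peak": None
            if self.peak_x is None
            else {
                "x": self.peak_x,
                "y": self.peak_y,
                "x_rounded": round(self.peak_x, 1),
                "in_range": self.peak_in_range,
            },
        }


def quadratic_fit_result(c2: float, c1: float, c0: float, n_obs: int = 0) -> FitResult:
    """Build a quadratic :class:`FitResult` from published coefficients.

    Coefficients are given in the order they are conventionally printed for a
    fit ``y = c2*x**2 + c1*x + c0`` (curvature first).  RSS and information
    criteria are unknown for an externally reported fit and are set to NaN;
    the vertex is computed so peak locations can be read off directly.
    """
    px, py = _vertex_of(c0, c1, c2)
    return FitResult(
        model_kind="quadratic",
        c0=c0,
        c1=c1,
        c2=c2,
        n_obs=n_obs,
        rss=float("nan"),
        adj_r2=float("nan"),
        aicc=float("nan"),
        peak_x=px,
        peak_y=py,
        peak_in_range=None,
    )


def _vertex_of(c0: float, c1: float, c2: float) -> tuple[float | None, float | None]:
    if c2 >= 0:
        return None, None
    px = -c1 / (2.0 * c2)
    py = c0 + c1 * px + c2 * px * px
    return px, py


def aicc(rss: float, n_obs: int, n_params: int) -> float:
    """Small-sample corrected Akaike information criterion for a Gaussian fit.

    ``AICc = n ln(rss/n) + 2k + 2k(k+1)/(n - k - 1)`` with ``k = n_params + 1``
    counting the error variance as an estimated parameter (the convention of
    common model-selection packages).

    Parameters
    ----------
    rss : residual sum of squares, must be > 0.
    n_obs : number of observations; must exceed ``n_params + 1`` by at least 1
        so that the correction term is defined.
    n_params : number of mean-model parameters (degree + 1 for a polynomial).
    """
    if rss <= 0:
        raise ValueError("aicc requires rss > 0 (a perfect fit has AICc = -inf)")
    k = n_params + 1
    if n_obs - k - 1 <= 0:
        raise ValueError(
            f"aicc undefined: need n_obs > n_params + 2 (got n_obs={n_obs}, k={k})"
        )
    n = float(n_obs)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_polynomial(
    x: Sequence[float],
    y: Sequence[float],
    degree: int,
    weights: Sequence[float] | None = None,
) -> FitResult:
    """Weighted least-squares polynomial fit of degree 1 or 2.

    The design is the plain Vandermonde matrix in ``x``; weights (if given)
    multiply squared residuals.  Adjusted R² uses the weighted total sum of
    squares about the weighted mean:
    ``adj_r2 = 1 - (1 - R²)(n - 1)/(n - p - 1)`` with ``p = degree``.

    Raises
    ------
    ValueError
        On mismatched lengths, too few points, non-positive weights, or a
        rank-deficient design (e.g. all x identical).
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape:
            raise ValueError("weights must match x in length")
        if not (w > 0).all():
            raise ValueError("weights must be strictly positive")

    X = np.vander(x, degree + 1, increasing=True)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    rank = np.linalg.matrix_rank(Xw)
    if rank < degree + 1:
        raise ValueError(
            "rank-deficient design: x values do not span a degree-"
            f"{degree} polynomial basis (rank {rank} < {degree + 1})"
        )
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)

    resid = y - X @ beta
    rss = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    tss = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    p = degree
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    if rss <= 0:
        fit_aicc = -math.inf
    elif n - (p + 2) - 1 <= 0:  # too few points for the small-sample correction
        fit_aicc = math.nan
    else:
        fit_aicc = aicc(rss, n, p + 1)

    sigma2 = rss / (n - p - 1)
    xtwx_inv = np.linalg.inv(Xw.T @ Xw)

    c0, c1 = float(beta[0]), float(beta[1])
    c2 = float(beta[2]) if degree == 2 else None
    peak_x = peak_y = None
    in_range = None
    if degree == 2:
        peak_x, peak_y = _vertex_of(c0, c1, c2)
        if peak_x is not None:
            in_range = bool(x.min() <= peak_x <= x.max())
    return FitResult(
        model_kind="linear" if degree == 1 else "quadratic",
        c0=c0,
        c1=c1,
        c2=c2,
        n_obs=n,
        rss=rss,
        adj_r2=adj_r2,
        aicc=fit_aicc,
        peak_x=peak_x,
        peak_y=peak_y,
        peak_in_range=in_range,
        x_min=float(x.min()),
        x_max=float(x.max()),
        _xtwx_inv=tuple(map(tuple, xtwx_inv)),
        _sigma2=sigma2,
    )


@dataclass(frozen=True)
class ModelSelection:
    chosen: FitResult
    delta_aicc: float
    tie: bool


def select_model(
    linear: FitResult, quadratic: FitResult, threshold: float = 2.0
) -> ModelSelection:
    """Choose between a linear and a quadratic fit of the same data by AICc.

    If the two AICc values differ by more than ``threshold`` the lower-AICc
    model is chosen; within the threshold the models are considered
    statistically indistinguishable and the linear fit wins on parsimony
    (``tie=True``).
    """
    if linear.model_kind != "linear" or quadratic.model_kind != "quadratic":
        raise ValueError("arguments must be (linear fit, quadratic fit)")
    if linear.n_obs != quadratic.n_obs:
        raise ValueError(
            f"fits are not on the same data: n={linear.n_obs} vs {quadratic.n_obs}"
        )
    delta = linear.aicc - quadratic.aicc  # > 0 favours the quadratic
    if abs(delta) > threshold:
        chosen = quadratic if delta > 0 else linear
        return ModelSelection(chosen=chosen, delta_aicc=delta, tie=False)
    return ModelSelection(chosen=linear, delta_aicc=delta, tie=True)


def vertex(fit: FitResult) -> tuple[float, float] | None:
    """Peak of a concave quadratic fit: ``(-c1/(2 c2), y(peak))``.

    Returns ``None`` for a convex (or degenerate, ``c2 >= 0``) quadratic.
    Raises for a linear fit, which has no vertex.
    """
    if fit.model_kind != "quadratic":
        raise ValueError("vertex is defined only for quadratic fits")
    if fit.c2 is None or fit.c2 >= 0:
        return None
    px, py = _vertex_of(fit.c0, fit.c1, fit.c2)
    return px, py


def confidence_band(
    fit: FitResult, x_grid: Sequence[float], level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise t-based confidence band for the fitted mean response.

    Half-width at x0 is ``t * sqrt(sigma2 * x0' (X'WX)^-1 x0)``; the band
    collapses onto the fitted line as the residual sum of squares goes to 0.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if fit._xtwx_inv is None:
        raise ValueError("fit carries no design information (external coefficients?)")
    p = fit.degree
    df = fit.n_obs - p - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom for a band")
    xg = np.asarray(x_grid, dtype=float)
    X0 = np.vander(xg, p + 1, increasing=True)
    cov = np.asarray(fit._xtwx_inv)
    var_mean = fit._sigma2 * np.einsum("ij,jk,ik->i", X0, cov, X0)
    half = stats.t.ppf(0.5 + level / 2.0, df) * np.sqrt(np.maximum(var_mean, 0.0))
    yhat = fit.predict(xg)
    return yhat - half, yhat + half
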