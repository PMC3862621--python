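"""Bivariate polynomial response surfaces for germination vs temperature.

The germination fraction Y is modelled as a full bivariate polynomial in the
two regime temperatures (T1, T2):

    degree 2:  Y = A0 + A1*T1 + A2*T2 + A3*T1^2 + A4*T1*T2 + A5*T2^2
    degree 5:  Y = A0' + f(A)  with the 21 monomials up to total degree 5

The basis is ordered canonically: for total degree k = 0..d, the terms
T1^(k-j) * T2^j for j = 0..k, i.e. 1, T1, T2, T1^2, T1*T2, T2^2, ...

Two fitting backends are provided: ordinary least squares and a robust
Tukey-bisquare IRLS.  Temperatures may be normalized by a divisor (40 °C =
the design maximum) before basis expansion, and the orientation decides
which of (cool, warm) occupies the T1 slot.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ORIENTATIONS",
    "basis_exponents",
    "build_basis",
    "PolynomialSurfaceModel",
    "PolynomialSurface",
    "SurfaceResults",
    "fit_ols",
    "fit_bisquare",
    "r_squared",
    "evaluate_model",
    "load_printed_equations",
    "calibrate_orientation",
]

ORIENTATIONS = ("cool_as_t1", "warm_as_t1")


def n_coefficients(degree: int) -> int:
    return (degree + 1) * (degree + 2) // 2


def basis_exponents(degree: int) -> list[tuple[int, int]]:
    """Canonical (T1 exponent, T2 exponent) pairs for a full bivariate basis."""
    if degree not in (2, 5):
        raise ValueError(f"unsupported degree {degree}; expected 2 or 5")
    return [(k - j, j) for k in range(degree + 1) for j in range(k + 1)]


def _orient(cool, warm, orientation: str):
    if orientation == "cool_as_t1":
        return cool, warm
    if orientation == "warm_as_t1":
        return warm, cool
    raise ValueError(f"unknown orientation {orientation!r}")


def build_basis(
    cool,
    warm,
    degree: int,
    normalizer: float = 1.0,
    orientation: str = "cool_as_t1",
) -> np.ndarray:
    """Monomial basis at (cool, warm) in canonical order.

    Scalar inputs give a 1-D vector of length (d+1)(d+2)/2; array inputs give
    a design matrix with one row per point.
    """
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    t1, t2 = _orient(np.asarray(cool, float), np.asarray(warm, float), orientation)
    t1, t2 = t1 / normalizer, t2 / normalizer
    scalar = t1.ndim == 0
    t1, t2 = np.atleast_1d(t1), np.atleast_1d(t2)
    cols = [t1 ** a * t2 ** b for a, b in basis_exponents(degree)]
    X = np.column_stack(cols)
    return X[0] if scalar else X


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST (in-sample definition)."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("zero total sum of squares: observed values are constant")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


@dataclass
class PolynomialSurfaceModel:
    """A fitted (or transcribed) bivariate polynomial germination surface.

    ``coefficients`` follow the canonical basis order; ``normalizer`` is the
    °C divisor applied to inputs before expansion (1 = raw temperatures,
    40 = normalized by the design maximum); ``orientation`` names which of
    (cool, warm) maps to the equation's T1.
    """

    degree: int
    coefficients: np.ndarray
    normalizer: float = 1.0
    orientation: str = "cool_as_t1"
    response_scale: float = 1.0
    cultivar: str | None = None
    backend: str | None = None
    r_squared_printed: float | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        expected = n_coefficients(self.degree)
        if self.coefficients.shape != (expected,):
            raise ValueError(
                f"degree {self.degree} needs {expected} coefficients, "
                f"got shape {self.coefficients.shape}"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def predict_unclamped(self, cool, warm):
        X = build_basis(cool, warm, self.degree, self.normalizer, self.orientation)
        return X @ self.coefficients

    def predict(self, cool, warm):
        """Germination fraction in [0, 1] at the given temperatures."""
        return np.clip(self.predict_unclamped(cool, warm), 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "cultivar": self.cultivar,
            "degree": self.degree,
            "backend": self.backend,
            "normalizer": self.normalizer,
            "orientation": self.orientation,
            "coefficients": [float(c) for c in self.coefficients],
            "response_scale": self.response_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialSurfaceModel":
        return cls(
            degree=int(d["degree"]),
            coefficients=np.asarray(d["coefficients"], float),
            normalizer=float(d.get("normalizer", 1.0)),
            orientation=d.get("orientation", "cool_as_t1"),
            response_scale=float(d.get("response_scale", 1.0)),
            cultivar=d.get("cultivar"),
            backend=d.get("backend"),
            r_squared_printed=d.get("r_squared_printed"),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PolynomialSurfaceModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def evaluate_model(model: PolynomialSurfaceModel, cool, warm):
    """Clamped germination fraction prediction (see predict_unclamped for raw)."""
    return model.predict(cool, warm)


class PolynomialSurface:
    """Polynomial response-surface model of a germination matrix.

    Parameters
    ----------
    endog : array-like
        Germination fractions (response), one per observation.
    cool, warm : array-like
        Regime temperatures in °C.
    degree : {2, 5}
    normalizer : float
        °C divisor applied before basis expansion.
    orientation : {"cool_as_t1", "warm_as_t1"}

    Use :meth:`fit` with ``method="ols"`` or ``"bisquare"``; both return a
    :class:`SurfaceResults`.
    """

    def __init__(self, endog, cool, warm, degree=2, normalizer=1.0,
                 orientation="cool_as_t1", cultivar=None):
        self.endog = np.asarray(endog, float)
        self.cool = np.asarray(cool, float)
        self.warm = np.asarray(warm, float)
        if not (self.endog.shape == self.cool.shape == self.warm.shape):
            raise ValueError("endog, cool and warm must have equal shapes")
        self.degree = int(degree)
        self.normalizer = float(normalizer)
        self.orientation = orientation
        self.cultivar = cultivar
        self.exog = build_basis(self.cool, self.warm, self.degree,
                                self.normalizer, self.orientation)
        k = n_coefficients(self.degree)
        if self.endog.size < k:
            raise ValueError(
                f"need at least {k} observations for degree {degree}, "
                f"got {self.endog.size}"
            )
        if np.linalg.matrix_rank(self.exog) < k:
            raise np.linalg.LinAlgError(
                f"rank-deficient design: rank {np.linalg.matrix_rank(self.exog)}"
                f" < {k} basis terms (degenerate temperature layout)"
            )

    @classmethod
    def from_matrix(cls, matrix, degree=2, normalizer=1.0,
                    orientation="cool_as_t1") -> "PolynomialSurface":
        """Build from a GerminationMatrix (response = mean fraction per cell)."""
        cool, warm, frac = matrix.arrays()
        return cls(frac, cool, warm, degree=degree, normalizer=normalizer,
                   orientation=orientation, cultivar=matrix.cultivar)

    @classmethod
    def from_dataframe(cls, df, degree=2, normalizer=1.0,
                       orientation="cool_as_t1", response="mean_percent"):
        y = np.asarray(df[response], float)
        if response == "mean_percent":
            y = y / 100.0
        return cls(y, df["cool_temp"], df["warm_temp"], degree=degree,
                   normalizer=normalizer, orientation=orientation)

    def fit(self, method: str = "ols", tuning_c: float = 4.685,
            tol: float = 1e-8, max_iter: int = 100) -> "SurfaceResults":
        if method == "ols":
            return self._fit_ols()
        if method == "bisquare":
            return self._fit_bisquare(tuning_c, tol, max_iter)
        raise ValueError(f"unknown fit method {method!r}")

    def _fit_ols(self) -> "SurfaceResults":
        import statsmodels.api as sm

        res = sm.OLS(self.endog, self.exog).fit()
        return SurfaceResults(self, np.asarray(res.params), backend="ols",
                              bse=np.asarray(res.bse), converged=True,
                              weights=np.ones_like(self.endog))

    def _fit_bisquare(self, tuning_c, tol, max_iter) -> "SurfaceResults":
        # IRLS with Tukey biweight w(u) = (1-(u/c)^2)^2 for |u|<=c else 0,
        # scale re-estimated each iteration as MAD/0.6745.
        X, y = self.exog, self.endog
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        converged = False
        weights = np.ones_like(y)
        for _ in range(max_iter):
            resid = y - X @ beta
            scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
            if scale <= np.finfo(float).tiny:
                # (near-)exact fit: nothing left to down-weight
                converged = True
                break
            u = resid / (tuning_c * scale)
            weights = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
            sw = np.sqrt(weights)
            beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            if np.max(np.abs(beta_new - beta)) < tol:
                beta = beta_new
                converged = True
                break
            beta = beta_new
        return SurfaceResults(self, beta, backend="bisquare",
                              converged=converged, weights=weights)


class SurfaceResults:
    """Fit results: coefficient vector, R² (on unweighted residuals),
    residuals, and the portable :class:`PolynomialSurfaceModel`."""

    def __init__(self, model: PolynomialSurface, params: np.ndarray,
                 backend: str, bse=None, converged=True, weights=None):
        self.model = model
        self.params = np.asarray(params, float)
        self.backend = backend
        self.bse = None if bse is None else np.asarray(bse, float)
        self.converged = bool(converged)
        self.weights = weights
        self.fittedvalues = model.exog @ self.params
        self.resid = model.endog - self.fittedvalues

    @property
    def rsquared(self) -> float:
        return r_squared(self.model.endog, self.fittedvalues)

    @property
    def surface(self) -> PolynomialSurfaceModel:
        return PolynomialSurfaceModel(
            degree=self.model.degree,
            coefficients=self.params.copy(),
            normalizer=self.model.normalizer,
            orientation=self.model.orientation,
            cultivar=self.model.cultivar,
            backend=self.backend,
        )

    def predict(self, cool, warm):
        return self.surface.predict(cool, warm)

    def summary(self) -> str:
        terms = [
            "*".join(filter(None, [f"T1^{a}" if a > 1 else "T1" * (a == 1),
                                   f"T2^{b}" if b > 1 else "T2" * (b == 1)]))
            or "1"
            for a, b in basis_exponents(self.model.degree)
        ]
        lines = [
            f"Polynomial surface fit ({self.backend})",
            f"  cultivar:    {self.model.cultivar or '-'}",
            f"  degree:      {self.model.degree}",
            f"  normalizer:  {self.model.normalizer:g} °C",
            f"  orientation: {self.model.orientation}",
            f"  n obs:       {self.model.endog.size}",
            f"  R²:          {self.rsquared:.4f}",
            f"  converged:   {self.converged}",
            "  " + "-" * 38,
            f"  {'term':<12}{'coef':>14}" + ("" if self.bse is None else f"{'se':>12}"),
        ]
        for i, t in enumerate(terms):
            row = f"  {t:<12}{self.params[i]:>14.6g}"
            if self.bse is not None:
                row += f"{self.bse[i]:>12.3g}"
            lines.append(row)
        return "\n".join(lines)


def fit_ols(matrix, degree=2, normalizer=1.0,
            orientation="cool_as_t1") -> SurfaceResults:
    """OLS polynomial surface fit to a germination matrix (fractions)."""
    return PolynomialSurface.from_matrix(
        matrix, degree=degree, normalizer=normalizer, orientation=orientation
    ).fit("ols")


def fit_bisquare(matrix, degree=2, normalizer=1.0, orientation="cool_as_t1",
                 tuning_c=4.685, tol=1e-8, max_iter=100) -> SurfaceResults:
    """Tukey-bisquare IRLS polynomial surface fit to a germination matrix."""
    return PolynomialSurface.from_matrix(
        matrix, degree=degree, normalizer=normalizer, orientation=orientation
    ).fit("bisquare", tuning_c=tuning_c, tol=tol, max_iter=max_iter)


def calibrate_orientation(model: PolynomialSurfaceModel, matrix) -> str:
    """Orientation (cool- or warm-as-T1) maximizing R² against a matrix."""
    cool, warm, frac = matrix.arrays()
    best, best_r2 = None, -np.inf
    for orientation in ORIENTATIONS:
        cand = replace(model, orientation=orientation)
        r2 = r_squared(frac, cand.predict(cool, warm))
        if r2 > best_r2:
            best, best_r2 = orientation, r2
    return best


def _fixture_checksum(entries: list[dict]) -> str:
    payload = json.dumps(
        [[e["cultivar"], e["backend"], e["coefficients"]] for e in entries],
        separators=(",", ":"),
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def load_printed_equations(path=None) -> list[PolynomialSurfaceModel]:
    """Load the nine transcribed fitted equations (3 cultivars × quadratic /
    quintic+bisquare / quintic+BP-ANN) with their calibrated metadata."""
    if path is None:
        from importlib.resources import files

        path = files("thermogerm.data") / "printed_equations.json"
    with open(str(path), encoding="utf-8") as fh:
        doc = json.load(fh)
    if _fixture_checksum(doc["models"]) != doc["sha256"]:
        raise ValueError("printed-equation fixture checksum mismatch")
    return [PolynomialSurfaceModel.from_dict(e) for e in doc["models"]]
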