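"""Diffusion-coefficient estimation from observed release curves.

The estimator normalizes an observed concentration series to the fractional
release ``C_S(t)/C_S,inf``, picks the appropriate forward model for the
volume ratio ``alpha`` (eigenfunction series, or the erfc short-time form
when ``alpha < 0.01``), and minimizes the sum of squared residuals over
``log10(D)`` with a deterministic bounded search.  Goodness of fit is the
coefficient of determination ``R^2 = 1 - SS_res / SS_tot``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .release_model import (
    ModelKind,
    ReleaseGeometry,
    RootSet,
    compute_alpha,
    find_roots,
    fractional_release_erfc,
    fractional_release_series,
    select_model,
)

__all__ = [
    "ReleaseCurve",
    "FitResult",
    "DiffusionEstimator",
    "estimate_equilibrium",
    "fit_diffusion",
    "r_squared",
    "ct_over_c0",
    "D_BOUNDS",
]

#: search bounds for the diffusivity, m^2/s
D_BOUNDS = (1e-18, 1e-8)


@dataclass(frozen=True)
class ReleaseCurve:
    """An observed or simulated (time, concentration) release series.

    Times are in seconds (strictly increasing, first >= 0); concentrations
    are in mg GAE per kg simulant and non-negative.
    """

    times: np.ndarray = field(repr=False)
    concentrations: np.ndarray = field(repr=False)
    simulant_label: str = ""
    temperature_label: str = ""
    C_S_inf: float | None = None
    C0_film: float | None = None
    replicate: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValueError("times and concentrations must be 1-d and equal length")
        if t.size < 4:
            raise ValueError(f"a release curve needs at least 4 points, got {t.size}")
        if t[0] < 0.0:
            raise ValueError("times must start at or after 0")
        d = np.diff(t)
        if np.any(d == 0.0):
            raise ValueError("duplicate timepoints are not allowed")
        if np.any(d < 0.0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0.0):
            raise ValueError("concentrations must be non-negative")
        if self.C_S_inf is not None and self.C_S_inf <= 0.0:
            raise ValueError("C_S_inf must be positive when provided")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a diffusion-coefficient fit."""

    D_hat: float
    alpha_used: float
    model_used: ModelKind
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    converged: bool
    C_S_inf_used: float
    n_roots_used: int

    @property
    def D_display_1e14(self) -> float:
        """Fitted D in the conventional reporting unit of 1e-14 m^2/s."""
        return self.D_hat * 1e14


def estimate_equilibrium(curve: ReleaseCurve, plateau_points: int = 3) -> float:
    """Equilibrium concentration ``C_S,inf`` for normalizing a curve.

    If the curve carries a preset ``C_S_inf`` it is returned unchanged;
    otherwise the mean of the last ``plateau_points`` concentrations is used
    (the release plateaus at late times, so a tail average is a robust
    plug-in estimate).
    """
    if curve.C_S_inf is not None:
        return float(curve.C_S_inf)
    plateau_points = int(plateau_points)
    if plateau_points < 1:
        raise ValueError("plateau_points must be >= 1")
    if len(curve) < plateau_points:
        raise ValueError(
            f"curve has {len(curve)} points, fewer than plateau_points={plateau_points}"
        )
    return float(np.mean(curve.concentrations[-plateau_points:]))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    May be negative for a fit worse than the mean; that value is reported
    as-is.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-d series (n >= 2)")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 is undefined: observed values are all identical")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def ct_over_c0(
    curve: ReleaseCurve,
    simulant_mass_kg: float,
    film_mass_kg: float,
) -> np.ndarray:
    """Fraction of the film's initial antioxidant load released by time t.

    ``C_t/C_0 = C_S(t) * m_S / (C0_film * m_F)`` where ``C0_film`` is the
    initial load in mg GAE per kg film.  Values outside [0, 1] are flagged
    with a warning but returned unmodified.
    """
    if curve.C0_film is None or curve.C0_film <= 0.0:
        raise ValueError("curve.C0_film must be set and positive for C_t/C_0 reporting")
    if simulant_mass_kg <= 0.0 or film_mass_kg <= 0.0:
        raise ValueError("simulant and film masses must be positive")
    ratio = curve.concentrations * simulant_mass_kg / (curve.C0_film * film_mass_kg)
    if np.any(ratio < 0.0) or np.any(ratio > 1.0):
        import warnings

        warnings.warn(
            "C_t/C_0 outside [0, 1]: check C0_film and the mass bookkeeping",
            RuntimeWarning,
            stacklevel=2,
        )
    return ratio


class DiffusionEstimator(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the diffusion coefficient.

    ``fit(X, y)`` takes times in seconds (``X`` of shape ``(n,)`` or
    ``(n, 1)``) and concentrations ``y`` (mg GAE/kg simulant), normalizes by
    the equilibrium concentration, and estimates ``D`` by a deterministic
    bounded scalar search over ``log10(D)`` (coarse grid, then Brent
    refinement).  ``predict(X)`` returns model concentrations on the original
    scale.

    Parameters
    ----------
    geometry : ReleaseGeometry
        Film/simulant geometry; supplies the diffusion length ``L`` (and the
        volumes if ``alpha`` is derived from ``K_FS``).
    alpha : float, optional
        Volume ratio.  Exactly one of ``alpha`` or ``K_FS`` must be given
        (unless ``fit_alpha=True``).
    K_FS : float, optional
        Partition coefficient from which ``alpha`` is derived via the
        geometry volumes.
    C_S_inf : float, optional
        Known equilibrium concentration; otherwise a plateau average of the
        last ``plateau_points`` observations is used.
    n_roots : int
        Eigenvalue roots retained in the series model.
    model : {"series", "erfc", None}
        Force a model variant; ``None`` selects by the ``alpha < 0.01`` rule.
    fit_alpha : bool
        Extension: co-estimate ``(D, alpha)`` by a nested search over
        ``log10(alpha)``; the curve alone only weakly constrains ``alpha``,
        so this is off by default.
    bounds : tuple of float
        Search bounds on D, m^2/s.
    grid_points : int
        Points of the deterministic coarse grid over ``log10(D)``.
    log_tol : float
        Absolute tolerance of the Brent refinement in ``log10(D)``.

    Attributes
    ----------
    D_ : float
        Estimated diffusivity, m^2/s.
    alpha_used_ : float
        Volume ratio used (or co-estimated).
    model_used_ : ModelKind
        Which forward model was fitted.
    r_squared_ : float
        ``1 - SS_res/SS_tot`` on the normalized release ratios.
    residuals_ : ndarray
        Observed minus predicted normalized ratios.
    converged_ : bool
        Whether the scalar search converged away from the bounds.
    C_S_inf_used_ : float
        Equilibrium concentration used for normalization.
    """

    def __init__(
        self,
        geometry: ReleaseGeometry | None = None,
        alpha: float | None = None,
        K_FS: float | None = None,
        C_S_inf: float | None = None,
        n_roots: int = 12,
        plateau_points: int = 3,
        model: str | None = None,
        fit_alpha: bool = False,
        alpha_bounds: tuple = (1e-5, 1e4),
        bounds: tuple = D_BOUNDS,
        grid_points: int = 201,
        log_tol: float = 1e-10,
    ):
        self.geometry = geometry
        self.alpha = alpha
        self.K_FS = K_FS
        self.C_S_inf = C_S_inf
        self.n_roots = n_roots
        self.plateau_points = plateau_points
        self.model = model
        self.fit_alpha = fit_alpha
        self.alpha_bounds = alpha_bounds
        self.bounds = bounds
        self.grid_points = grid_points
        self.log_tol = log_tol

    # ---- internal helpers -------------------------------------------------

    def _resolve_alpha(self) -> float:
        given = [p for p in (self.alpha, self.K_FS) if p is not None]
        if len(given) != 1:
            raise ValueError("exactly one of alpha or K_FS must be supplied")
        if self.alpha is not None:
            a = float(self.alpha)
            if a <= 0.0:
                raise ValueError("alpha must be positive")
            return a
        if self.geometry is None:
            raise ValueError("deriving alpha from K_FS requires a geometry")
        return compute_alpha(
            self.geometry.volume_simulant, self.geometry.volume_film, self.K_FS
        )

    def _forward(self, t: np.ndarray, D: float, alpha: float, kind: ModelKind,
                 roots: RootSet | None) -> np.ndarray:
        if kind is ModelKind.SERIES:
            return fractional_release_series(t, D, self.geometry, alpha, roots)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return fractional_release_erfc(t, D, self.geometry, alpha)

    def _search_D(self, t: np.ndarray, ratio: np.ndarray, alpha: float,
                  kind: ModelKind, roots: RootSet | None):
        lo, hi = (math.log10(b) for b in self.bounds)

        def sse(logD: float) -> float:
            pred = self._forward(t, 10.0**logD, alpha, kind, roots)
            return float(np.sum((pred - ratio) ** 2))

        grid = np.linspace(lo, hi, int(self.grid_points))
        values = np.array([sse(g) for g in grid])
        i = int(np.argmin(values))
        b_lo = grid[max(i - 1, 0)]
        b_hi = grid[min(i + 1, grid.size - 1)]
        res = minimize_scalar(
            sse, bounds=(b_lo, b_hi), method="bounded",
            options={"xatol": self.log_tol},
        )
        logD = float(res.x)
        # converged if the optimum is interior to the global bounds
        margin = (hi - lo) / (self.grid_points - 1)
        converged = bool(res.success) and (lo + margin < logD < hi - margin)
        return 10.0**logD, float(res.fun), converged

    # ---- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        if self.geometry is None:
            raise ValueError("a ReleaseGeometry is required")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be 1-d times or a single-column array")
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("y must match X in length")
        curve = ReleaseCurve(times=t, concentrations=y, C_S_inf=self.C_S_inf)
        if not np.any(y > 0.0):
            raise ValueError("all concentrations are zero: no release to fit")

        c_inf = estimate_equilibrium(curve, self.plateau_points)
        ratio = y / c_inf

        if self.fit_alpha:
            D, alpha, kind, roots, sse_val, converged = self._fit_alpha_nested(t, ratio)
        else:
            alpha = self._resolve_alpha()
            kind = ModelKind(self.model) if self.model is not None else select_model(alpha)
            roots = find_roots(alpha, self.n_roots) if kind is ModelKind.SERIES else None
            D, sse_val, converged = self._search_D(t, ratio, alpha, kind, roots)

        pred = self._forward(t, D, alpha, kind, roots)
        self.D_ = float(D)
        self.alpha_used_ = float(alpha)
        self.model_used_ = kind
        self.residuals_ = ratio - pred
        self.r_squared_ = r_squared(ratio, pred)
        self.converged_ = converged
        self.C_S_inf_used_ = float(c_inf)
        self.n_roots_used_ = int(self.n_roots) if kind is ModelKind.SERIES else 0
        self.n_features_in_ = 1
        return self

    def _fit_alpha_nested(self, t: np.ndarray, ratio: np.ndarray):
        """Co-estimate (D, alpha): outer bounded search over log10(alpha)."""
        a_lo, a_hi = (math.log10(b) for b in self.alpha_bounds)

        def outer(log_a: float) -> float:
            import warnings

            a = 10.0**log_a
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                kind = select_model(a)
            roots = find_roots(a, self.n_roots) if kind is ModelKind.SERIES else None
            _, sse_val, _ = self._search_D(t, ratio, a, kind, roots)
            return sse_val

        grid = np.linspace(a_lo, a_hi, 41)
        values = np.array([outer(g) for g in grid])
        i = int(np.argmin(values))
        res = minimize_scalar(
            outer,
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]),
            method="bounded",
            options={"xatol": 1e-6},
        )
        alpha = 10.0 ** float(res.x)
        kind = select_model(alpha)
        roots = find_roots(alpha, self.n_roots) if kind is ModelKind.SERIES else None
        D, sse_val, converged = self._search_D(t, ratio, alpha, kind, roots)
        return D, alpha, kind, roots, sse_val, converged

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "D_")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        roots = (
            find_roots(self.alpha_used_, self.n_roots)
            if self.model_used_ is ModelKind.SERIES
            else None
        )
        ratio = self._forward(t, self.D_, self.alpha_used_, self.model_used_, roots)
        return ratio * self.C_S_inf_used_

    def score(self, X, y, sample_weight=None):
        """R^2 between observed concentrations and predictions."""
        return r_squared(np.asarray(y, dtype=float), self.predict(X))


def fit_diffusion(
    curve: ReleaseCurve,
    geometry: ReleaseGeometry,
    K_FS: float | None = None,
    alpha: float | None = None,
    **options,
) -> FitResult:
    """Estimate D from a release curve; thin wrapper over DiffusionEstimator.

    Exactly one of ``K_FS`` (with geometry volumes) or ``alpha`` must be
    given.  A preset ``curve.C_S_inf`` takes precedence over the plateau
    average when normalizing.
    """
    est = DiffusionEstimator(
        geometry=geometry, alpha=alpha, K_FS=K_FS, C_S_inf=curve.C_S_inf, **options
    )
    est.fit(curve.times, curve.concentrations)
    return FitResult(
        D_hat=est.D_,
        alpha_used=est.alpha_used_,
        model_used=est.model_used_,
        r_squared=est.r_squared_,
        residuals=est.residuals_,
        converged=est.converged_,
        C_S_inf_used=est.C_S_inf_used_,
        n_roots_used=est.n_roots_used_,
    )
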