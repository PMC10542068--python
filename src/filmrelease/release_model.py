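"""Forward models for release of a solute from a plane sheet into a finite bath.

The physical picture: an antioxidant-loaded polymer film (a plane sheet of
half-thickness ``L``) is immersed in a well-stirred food simulant of finite
volume.  Transport through the film follows Fick's second law with constant
diffusivity ``D``; at the film--simulant interface the concentrations stay in
local equilibrium with partition coefficient ``K_FS = C_F,inf / C_S,inf``.
The simulant concentration approaches its equilibrium value ``C_S,inf`` and
the normalized release ``C_S(t)/C_S,inf`` admits the classical eigenfunction
expansion

    C_S(t)/C_S,inf = 1 - sum_n  2*a*(1+a) / (1 + a + a^2 q_n^2)
                               * exp(-D q_n^2 t / L^2)

where ``a = V_S / (K_FS * V_F)`` is the effective volume ratio and the
eigenvalues ``q_n`` are the positive roots of ``tan(q) = -a q``.  For very
small ``a`` (low migration) the series converges slowly and the
complementary-error-function short-time form

    C_S(t)/C_S,inf = (1 + a) * (1 - exp(w) * erfc(sqrt(w))),   w = D t/(a L)^2

is used instead.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfcx

__all__ = [
    "Exposure",
    "ModelKind",
    "ReleaseGeometry",
    "PartitionParameters",
    "RootSet",
    "DiffusionParams",
    "compute_alpha",
    "partition_coefficient",
    "find_roots",
    "series_weights",
    "fractional_release_series",
    "fractional_release_erfc",
    "select_model",
]

#: validated range of the volume ratio for the 12-root series model
SERIES_ALPHA_MIN = 0.01
SERIES_ALPHA_MAX = 1000.0

#: default number of eigenvalue roots retained in the series
DEFAULT_N_ROOTS = 12


class Exposure(str, enum.Enum):
    """How the measured film thickness maps onto the diffusion length ``L``.

    A film exposed to the simulant on both faces is symmetric about its
    midplane, so the characteristic length is half the measured thickness.
    A film glued to an impermeable backing releases through one face only
    and the full thickness is the diffusion length.
    """

    TWO_SIDED = "two_sided"
    ONE_SIDED = "one_sided"


class ModelKind(str, enum.Enum):
    SERIES = "series"
    ERFC = "erfc"


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")
    return value


@dataclass(frozen=True)
class ReleaseGeometry:
    """Film and simulant geometry defining the transport problem.

    Parameters
    ----------
    thickness : float
        Measured film thickness in meters.
    volume_film : float
        Film volume ``V_F`` in cubic meters.
    volume_simulant : float
        Simulant volume ``V_S`` in cubic meters.
    exposure : Exposure
        Whether both film faces contact the simulant (default) or one.
    """

    thickness: float
    volume_film: float
    volume_simulant: float
    exposure: Exposure = Exposure.TWO_SIDED

    def __post_init__(self) -> None:
        _require_positive("thickness", self.thickness)
        _require_positive("volume_film", self.volume_film)
        _require_positive("volume_simulant", self.volume_simulant)
        object.__setattr__(self, "exposure", Exposure(self.exposure))

    @property
    def characteristic_length(self) -> float:
        """Diffusion length ``L`` entering ``exp(-D q^2 t / L^2)`` (m)."""
        if self.exposure is Exposure.TWO_SIDED:
            return self.thickness / 2.0
        return self.thickness

    def alpha(self, K_FS: float) -> float:
        """Volume ratio ``a = V_S / (K_FS V_F)`` for this geometry."""
        return compute_alpha(self.volume_simulant, self.volume_film, K_FS)

    @classmethod
    def from_characteristic_length(
        cls,
        L: float,
        volume_film: float = 2e-7,
        volume_simulant: float = 1e-4,
        exposure: Exposure = Exposure.TWO_SIDED,
    ) -> "ReleaseGeometry":
        """Build a geometry whose diffusion length is exactly ``L``."""
        exposure = Exposure(exposure)
        thickness = 2.0 * L if exposure is Exposure.TWO_SIDED else L
        return cls(thickness, volume_film, volume_simulant, exposure)


@dataclass(frozen=True)
class PartitionParameters:
    """Partition coefficient and the volume ratio it induces."""

    K_FS: float
    alpha: float

    def __post_init__(self) -> None:
        _require_positive("K_FS", self.K_FS)
        _require_positive("alpha", self.alpha)

    @classmethod
    def from_geometry(cls, geometry: ReleaseGeometry, K_FS: float) -> "PartitionParameters":
        return cls(K_FS=K_FS, alpha=geometry.alpha(K_FS))


@dataclass(frozen=True)
class DiffusionParams:
    """Constant diffusivity of the antioxidant in the film (m^2/s)."""

    D: float

    def __post_init__(self) -> None:
        _require_positive("D", self.D)

    @property
    def display_1e14(self) -> float:
        """D in the conventional reporting unit of 1e-14 m^2/s."""
        return self.D * 1e14


def compute_alpha(V_S: float, V_F: float, K_FS: float) -> float:
    """Volume ratio ``a = V_S / (K_FS * V_F)``.

    ``a`` measures the effective capacity of the simulant relative to the
    film: small ``a`` means the simulant saturates after only a small
    fraction of the film load has migrated.
    """
    _require_positive("V_S", V_S)
    _require_positive("V_F", V_F)
    _require_positive("K_FS", K_FS)
    return V_S / (K_FS * V_F)


def partition_coefficient(C_F_inf: float, C_S_inf: float) -> float:
    """Equilibrium partition coefficient ``K_FS = C_F,inf / C_S,inf``."""
    C_F_inf = float(C_F_inf)
    if C_F_inf < 0.0 or not math.isfinite(C_F_inf):
        raise ValueError(f"C_F_inf must be >= 0, got {C_F_inf!r}")
    _require_positive("C_S_inf", C_S_inf)
    return C_F_inf / C_S_inf


@dataclass(frozen=True)
class RootSet:
    """The first positive eigenvalues ``q_n`` of ``tan(q) = -alpha q``.

    The k-th root lies strictly inside ``((k - 1/2) pi, k pi)``; as
    ``alpha -> 0`` the roots approach ``k pi`` and as ``alpha -> inf`` they
    approach the tangent poles ``(2k - 1) pi / 2``.
    """

    alpha: float
    roots: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _require_positive("alpha", self.alpha)
        roots = np.asarray(self.roots, dtype=float)
        if roots.ndim != 1 or roots.size < 1:
            raise ValueError("roots must be a non-empty 1-d array")
        if np.any(np.diff(roots) <= 0.0):
            raise ValueError("roots must be strictly increasing")
        k = np.arange(1, roots.size + 1)
        if np.any(roots <= (k - 0.5) * np.pi) or np.any(roots >= k * np.pi):
            raise ValueError("root k must lie in ((k - 1/2) pi, k pi)")
        object.__setattr__(self, "roots", roots)

    @property
    def n_roots(self) -> int:
        return int(self.roots.size)

    def residuals(self) -> np.ndarray:
        """Characteristic-equation residuals ``sin(q) + alpha q cos(q)``."""
        q = self.roots
        return np.sin(q) + self.alpha * q * np.cos(q)


def _root_in_bracket(alpha: float, k: int) -> float:
    # The tan form has a pole at the left bracket edge; sin(q) + a*q*cos(q)
    # has the same roots and is smooth, with guaranteed opposite signs at
    # the closed bracket ends.
    lo = (k - 0.5) * math.pi
    hi = k * math.pi
    q = brentq(
        lambda q: math.sin(q) + alpha * q * math.cos(q),
        lo,
        hi,
        xtol=1e-15,
        rtol=8.9e-16,
    )
    # one Newton polish on the tan form where it is well conditioned
    c = math.cos(q)
    if abs(c) > 1e-8:
        g = math.tan(q) + alpha * q
        gp = 1.0 / (c * c) + alpha
        q_new = q - g / gp
        if lo < q_new < hi:
            q = q_new
    return q


def find_roots(alpha: float, n_roots: int = DEFAULT_N_ROOTS) -> RootSet:
    """Solve ``tan(q) = -alpha q`` for the first ``n_roots`` positive roots.

    Each root is bracketed in ``((k - 1/2) pi, k pi)`` and refined by a
    guaranteed-convergence bracketing method on the pole-free equivalent
    ``sin(q) + alpha q cos(q) = 0``.
    """
    _require_positive("alpha", alpha)
    n_roots = int(n_roots)
    if n_roots < 1:
        raise ValueError(f"n_roots must be >= 1, got {n_roots}")
    roots = np.array([_root_in_bracket(float(alpha), k) for k in range(1, n_roots + 1)])
    return RootSet(alpha=float(alpha), roots=roots)


def series_weights(alpha: float, roots: RootSet | np.ndarray) -> np.ndarray:
    """Series coefficients ``2a(1+a) / (1 + a + a^2 q_n^2)``.

    Over the complete (infinite) eigenvalue set these sum to 1; the shortfall
    of a truncated sum is the value the truncated series erroneously reports
    at ``t = 0``.
    """
    q = roots.roots if isinstance(roots, RootSet) else np.asarray(roots, dtype=float)
    a = float(alpha)
    return 2.0 * a * (1.0 + a) / (1.0 + a + a * a * q * q)


def _check_roots(alpha: float, roots: RootSet) -> None:
    if not isinstance(roots, RootSet):
        raise TypeError("roots must be a RootSet from find_roots()")
    if not math.isclose(roots.alpha, alpha, rel_tol=1e-12, abs_tol=0.0):
        raise ValueError(
            f"RootSet was solved for alpha={roots.alpha!r} but the release "
            f"is requested at alpha={alpha!r}"
        )


def fractional_release_series(
    t,
    D: float,
    geometry: ReleaseGeometry,
    alpha: float,
    roots: RootSet | None = None,
    clip: bool = True,
):
    """Normalized release ``C_S(t)/C_S,inf`` from the eigenfunction series.

    Parameters
    ----------
    t : float or array_like
        Time(s) in seconds, >= 0.
    D : float
        Diffusivity in m^2/s.
    geometry : ReleaseGeometry
        Supplies the diffusion length ``L``.
    alpha : float
        Volume ratio; must match ``roots.alpha``.
    roots : RootSet, optional
        Precomputed eigenvalues; defaults to the first 12 roots.
    clip : bool
        Clamp the truncated series to the physical range [0, 1].  Pass
        ``False`` to inspect the raw truncated value (at ``t = 0`` the raw
        value equals the weight deficit of the truncation).
    """
    _require_positive("D", D)
    _require_positive("alpha", alpha)
    if roots is None:
        roots = find_roots(alpha)
    _check_roots(float(alpha), roots)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("t must be >= 0")
    L = geometry.characteristic_length
    w = series_weights(alpha, roots)
    rates = D * roots.roots**2 / (L * L)
    val = 1.0 - np.exp(-np.multiply.outer(t_arr, rates)) @ w
    if clip:
        val = np.clip(val, 0.0, 1.0)
    return val if t_arr.ndim else float(val)


def fractional_release_erfc(t, D: float, geometry: ReleaseGeometry, alpha: float):
    """Normalized release from the short-time / low-migration erfc model.

    Computes ``w = D t / (alpha^2 L^2)`` and returns
    ``(1 + alpha) * (1 - exp(w) erfc(sqrt(w)))`` using the scaled
    complementary error function, so large ``w`` does not overflow.

    The asymptote for large ``w`` is ``1 + alpha`` rather than 1; values
    exceeding 1 are flagged with a warning but returned untruncated.
    """
    _require_positive("D", D)
    _require_positive("alpha", alpha)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("t must be >= 0")
    L = geometry.characteristic_length
    omega = D * t_arr / (alpha * alpha * L * L)
    val = (1.0 + alpha) * (1.0 - erfcx(np.sqrt(omega)))
    if np.any(val > 1.0):
        warnings.warn(
            "erfc release model exceeds 1 (its large-time asymptote is 1 + alpha); "
            "the model is only meaningful while release is small",
            RuntimeWarning,
            stacklevel=2,
        )
    return val if t_arr.ndim else float(val)


def select_model(alpha: float) -> ModelKind:
    """Choose the forward model for a given volume ratio.

    The truncated series is used on its validated range
    ``0.01 <= alpha <= 1000``; below 0.01 the series converges too slowly
    at practical truncations and the erfc form is used.  Above 1000 the
    series is still used, with a warning.
    """
    _require_positive("alpha", alpha)
    if alpha < SERIES_ALPHA_MIN:
        return ModelKind.ERFC
    if alpha > SERIES_ALPHA_MAX:
        warnings.warn(
            f"alpha={alpha:g} is above the validated series range "
            f"(<= {SERIES_ALPHA_MAX:g}); using the series model anyway",
            RuntimeWarning,
            stacklevel=2,
        )
    return ModelKind.SERIES
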