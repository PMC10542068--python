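import numpy as np
import pytest

from filmrelease import ReleaseGeometry


@pytest.fixture
def geometry():
    """Geometry with diffusion length L = 5e-5 m (100 um film, two-sided)."""
    return ReleaseGeometry.from_characteristic_length(5e-5)


@pytest.fixture
def geometry_for_alpha():
    """Factory: geometry whose volumes yield a requested alpha at given K_FS."""

    def make(alpha: float, K_FS: float = 1.0, L: float = 5e-5) -> ReleaseGeometry:
        V_F = 2e-7
        return ReleaseGeometry.from_characteristic_length(
            L, volume_film=V_F, volume_simulant=alpha * K_FS * V_F
        )

    return make


def bisect_root(alpha: float, k: int, tol: float = 1e-12) -> float:
    """Independent bisection oracle on tan(q) + alpha*q in ((k-1/2)pi, k*pi).

    Deliberately uses the tan form and plain bisection so it shares nothing
    with the production solver.
    """
    lo = (k - 0.5) * np.pi + 1e-9
    hi = k * np.pi - 1e-9
    f_lo = np.tan(lo) + alpha * lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = np.tan(mid) + alpha * mid
        if (f_lo < 0) == (f_mid < 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
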