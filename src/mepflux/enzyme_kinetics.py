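"""HDR assay analysis: progress curves, Michaelis-Menten parameters, product ratios.

Initial velocities come from fitting each progress curve with the
saturating exponential y = a * (1 - exp(-b * t)); the slope at the origin,
v0 = a * b, is the initial velocity.  Km and Vmax are estimated either by
nonlinear Michaelis-Menten least squares (default) or by an ordinary
least-squares Lineweaver-Burk double-reciprocal line.  The LB transform
inflates the influence of low-velocity points under noise; it is kept
because it is the classical workflow, with the nonlinear fit as the
recommended estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    AllZeroProductError,
    InsufficientLevelsError,
    MissingEnzymeMolarityError,
    MissingKcatError,
    ZeroDmadpError,
    ZeroVelocityError,
)

__all__ = [
    "ProgressCurve",
    "BoxLucasFit",
    "MMKinetics",
    "ProductRatio",
    "fit_progress_curve",
    "fit_mm_nls",
    "fit_lineweaver_burk",
    "kcat_from_vmax",
    "with_kcat",
    "efficiency_fold",
    "dmadp_idp_ratio",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProgressCurve:
    """Combined DMADP+IDP product (uM) over time (min) at one HMBDP level (uM)."""

    times: np.ndarray
    product: np.ndarray
    substrate_conc: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        product = np.asarray(self.product, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "product", product)
        if times.shape != product.shape or times.ndim != 1:
            raise ValueError("times and product must be 1-D of equal length")
        if times.size and times[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(product < 0):
            raise ValueError("product concentrations must be non-negative")
        if self.substrate_conc <= 0:
            raise ValueError("substrate_conc must be positive")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class BoxLucasFit:
    """Saturating-exponential fit y = a(1 - exp(-b t)); v0 = a*b is the origin slope."""

    a: float
    b: float
    v0: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("a and b must be non-negative")


@dataclass(frozen=True)
class MMKinetics:
    """Michaelis-Menten constants for one enzyme.

    kcat (min^-1) and efficiency (uM^-1 min^-1) are present only when the
    enzyme molar concentration is known; ``method`` records the estimator.
    """

    km: float
    vmax: float
    kcat: float | None = None
    method: str = "nonlinear"

    def __post_init__(self) -> None:
        if self.km <= 0 or self.vmax <= 0:
            raise ValueError("km and vmax must be positive")

    @property
    def efficiency(self) -> float | None:
        """Catalytic efficiency kcat/Km, or None when kcat is unknown."""
        return None if self.kcat is None else self.kcat / self.km


@dataclass(frozen=True)
class ProductRatio:
    """DMADP and IDP amounts normalized as 1 : idp/dmadp."""

    dmadp: float
    idp: float

    def __post_init__(self) -> None:
        if self.dmadp <= 0:
            raise ZeroDmadpError("DMADP amount must be positive to normalize the ratio")
        if self.idp < 0:
            raise ValueError("IDP amount must be non-negative")

    @property
    def normalized(self) -> tuple[float, float]:
        return (1.0, self.idp / self.dmadp)

    def render(self, decimals: int = 0) -> str:
        """Format as "1:x"; x rounded to ``decimals`` places (default integer)."""
        x = self.idp / self.dmadp
        if decimals == 0:
            return f"1:{round(x):d}"
        return f"1:{x:.{decimals}f}"


def fit_progress_curve(pc: ProgressCurve) -> BoxLucasFit:
    """Fit y = a(1 - exp(-b t)) to a progress curve and report v0 = a*b.

    Initialization: a from the largest observed product, b from the early
    slope.  For nearly linear data (small b) the individual a and b are
    poorly determined but their product — the initial velocity — remains
    well constrained.
    """
    if len(pc) < 4:
        raise ValueError("need at least 4 points to fit a progress curve")
    if np.all(pc.product == 0):
        raise AllZeroProductError("all product concentrations are zero")

    t, y = pc.times, pc.product
    a0 = max(y.max(), 1e-12)
    # early-slope guess for v0, then b0 = v0/a0
    nz = np.nonzero(t > 0)[0]
    slope0 = y[nz[0]] / t[nz[0]] if nz.size else 1.0
    b0 = max(slope0 / a0, 1e-12)

    def resid(theta):
        a, b = theta
        return a * (1.0 - np.exp(-b * t)) - y

    sol = least_squares(resid, [a0, b0], bounds=([0.0, 0.0], [np.inf, np.inf]), x_scale="jac")
    a, b = sol.x
    if not sol.success:
        logger.warning("progress-curve fit did not converge at S=%g uM", pc.substrate_conc)
    return BoxLucasFit(a=float(a), b=float(b), v0=float(a * b), converged=bool(sol.success))


def _check_levels(substrate: np.ndarray, v0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    substrate = np.asarray(substrate, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    if substrate.shape != v0.shape or substrate.ndim != 1:
        raise ValueError("substrate and v0 must be 1-D of equal length")
    if np.any(substrate <= 0):
        raise ValueError("substrate concentrations must be positive")
    if np.unique(substrate).size < 3:
        raise InsufficientLevelsError("need at least 3 distinct substrate levels")
    return substrate, v0


def fit_mm_nls(substrate, v0) -> MMKinetics:
    """Nonlinear least-squares fit of v = Vmax*S/(Km+S)."""
    s, v = _check_levels(substrate, v0)
    if np.any(v < 0):
        raise ValueError("initial velocities must be non-negative")
    vmax0 = max(v.max() * 1.2, 1e-12)
    km0 = float(np.median(s))

    def resid(theta):
        vmax, km = theta
        return vmax * s / (km + s) - v

    sol = least_squares(resid, [vmax0, km0], bounds=([1e-12, 1e-12], [np.inf, np.inf]))
    if not sol.success:
        logger.warning("Michaelis-Menten fit did not converge")
    vmax, km = sol.x
    return MMKinetics(km=float(km), vmax=float(vmax), method="nonlinear")


def fit_lineweaver_burk(substrate, v0) -> MMKinetics:
    """Double-reciprocal OLS: 1/v = (Km/Vmax)(1/S) + 1/Vmax.

    Km = slope/intercept, Vmax = 1/intercept.  Biased under heteroscedastic
    noise (reciprocals inflate low-velocity errors); prefer fit_mm_nls.
    """
    s, v = _check_levels(substrate, v0)
    if np.any(v <= 0):
        raise ZeroVelocityError("zero velocity cannot be reciprocal-transformed")
    slope, intercept = np.polyfit(1.0 / s, 1.0 / v, 1)
    if intercept <= 0:
        raise ZeroVelocityError(
            f"Lineweaver-Burk intercept {intercept:g} is non-physical (<= 0); "
            "use the nonlinear fit"
        )
    return MMKinetics(km=float(slope / intercept), vmax=float(1.0 / intercept), method="lineweaver_burk")


def kcat_from_vmax(vmax: float, enzyme_molar: float) -> float:
    """kcat = Vmax / [E], with [E] the enzyme molar concentration in uM."""
    if enzyme_molar is None or enzyme_molar <= 0:
        raise MissingEnzymeMolarityError("enzyme molar concentration must be positive")
    return vmax / enzyme_molar


def with_kcat(kin: MMKinetics, enzyme_molar: float) -> MMKinetics:
    """Return a copy of ``kin`` with kcat derived from the enzyme molarity."""
    return MMKinetics(
        km=kin.km,
        vmax=kin.vmax,
        kcat=kcat_from_vmax(kin.vmax, enzyme_molar),
        method=kin.method,
    )


def efficiency_fold(e1: MMKinetics, e2: MMKinetics) -> float:
    """Fold difference in catalytic efficiency, (kcat1/Km1)/(kcat2/Km2)."""
    if e1.kcat is None or e2.kcat is None:
        raise MissingKcatError("both enzymes need kcat to compare catalytic efficiencies")
    return e1.efficiency / e2.efficiency


def dmadp_idp_ratio(dmadp: float, idp: float) -> ProductRatio:
    """Normalized DMADP:IDP product ratio (1 : idp/dmadp)."""
    return ProductRatio(dmadp=dmadp, idp=idp)
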