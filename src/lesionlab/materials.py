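"""Constitutive models for the angioplasty components, evaluated at material
points: strain-energy densities, incompressible uniaxial Cauchy stress,
small-strain moduli, and a 1D elastic-plastic path integrator with
piecewise-linear hardening.

Shipped parameter sets (see :data:`MATERIAL_LIBRARY`): neo-Hookean lipidic
plaque with a plastic stress cap (kPa), linear elastic perfectly plastic
calcium, sixth-order reduced-polynomial media and adventitia with hardening
tables, elastic-plastic platinum-chromium stent, and a first-order Ogden
balloon.  Soft lesion tissue uses kPa; everything else MPa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "StretchState",
    "PlasticTable",
    "NeoHookeanPlastic",
    "LinearElasticPlastic",
    "OgdenFirstOrder",
    "ReducedPolynomial6",
    "Modulus",
    "strain_energy",
    "uniaxial_cauchy_stress",
    "small_strain_modulus",
    "hardening_stress",
    "uniaxial_elastoplastic_path",
    "MATERIAL_LIBRARY",
    "get_material",
]


@dataclass(frozen=True)
class StretchState:
    """Principal stretches of a material point."""

    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        if min(self.l1, self.l2, self.l3) <= 0:
            raise ValueError("principal stretches must be positive")

    @classmethod
    def uniaxial_incompressible(cls, lam: float) -> "StretchState":
        """Uniaxial stretch with incompressible lateral contraction."""
        if lam <= 0:
            raise ValueError("stretch must be positive")
        return cls(lam, lam**-0.5, lam**-0.5)

    @property
    def I1(self) -> float:
        return self.l1**2 + self.l2**2 + self.l3**2

    @property
    def J(self) -> float:
        return self.l1 * self.l2 * self.l3

    def require_incompressible(self, tol: float = 1e-9) -> None:
        if abs(self.J - 1.0) > tol:
            raise ValueError(f"stretch state is not isochoric: J = {self.J}")


class PlasticTable:
    """Ordered (plastic strain, stress) hardening pairs.

    Interpolation is piecewise linear between knots and constant beyond the
    last knot (perfectly plastic extension).
    """

    def __init__(self, pairs: Sequence[tuple[float, float]]):
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
            raise ValueError("plastic table needs (strain, stress) pairs")
        eps, sig = arr[:, 0], arr[:, 1]
        if not np.all(np.diff(eps) > 0):
            raise ValueError("plastic strains must be strictly increasing")
        if np.any(np.diff(sig) < 0):
            raise ValueError("hardening stresses must be non-decreasing")
        if eps[0] < 0:
            raise ValueError("plastic strains must be nonnegative")
        self.eps = eps
        self.sig = sig

    def stress(self, eps_p: float | np.ndarray) -> float | np.ndarray:
        eps_p = np.asarray(eps_p, dtype=float)
        if np.any(eps_p < 0):
            raise ValueError("plastic strain must be nonnegative")
        out = np.interp(eps_p, self.eps, self.sig)
        return float(out) if out.ndim == 0 else out

    @property
    def initial_yield(self) -> float:
        return float(self.sig[0])

    def __repr__(self) -> str:  # pragma: no cover
        return f"PlasticTable({list(zip(self.eps, self.sig))})"


# ---------------------------------------------------------------------------
# model definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeoHookeanPlastic:
    """Incompressible neo-Hookean solid with a plastic stress cap (kPa)."""

    c10: float = 13.3
    yield_stress: float = 70.0
    stress_unit: str = "kPa"

    def __post_init__(self) -> None:
        if self.c10 <= 0 or self.yield_stress <= 0:
            raise ValueError("C10 and yield stress must be positive")


@dataclass(frozen=True)
class LinearElasticPlastic:
    """Linear elastic, plastic solid (MPa); perfectly plastic when no table."""

    youngs_modulus: float
    poisson: float = 0.3
    yield_stress: float | None = None
    hardening: PlasticTable | None = None
    stress_unit: str = "MPa"

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("E must be positive")
        if not 0.0 <= self.poisson < 0.5:
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")
        if self.yield_stress is None and self.hardening is None:
            raise ValueError("need a yield stress or a hardening table")

    def yield_curve(self, eps_p: float) -> float:
        if self.hardening is not None:
            return float(self.hardening.stress(eps_p))
        return float(self.yield_stress)


@dataclass(frozen=True)
class OgdenFirstOrder:
    """First-order Ogden solid.

    ``convention='quadratic'`` (default) scales the energy by 2 mu / alpha^2,
    giving a positive small-strain modulus 3 mu for any alpha sign;
    ``'as_printed'`` uses 2 mu / alpha, which with a negative alpha yields a
    negative modulus and is kept for evaluation only.
    """

    mu: float = 80.0
    alpha: float = -15.0
    convention: str = "quadratic"
    stress_unit: str = "MPa"

    def __post_init__(self) -> None:
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        if self.convention not in ("quadratic", "as_printed"):
            raise ValueError(f"unknown Ogden convention {self.convention!r}")

    @property
    def scale(self) -> float:
        if self.convention == "quadratic":
            return 2.0 * self.mu / self.alpha**2
        return 2.0 * self.mu / self.alpha


@dataclass(frozen=True)
class ReducedPolynomial6:
    """Sixth-order reduced polynomial, Psi = sum_i C_i0 (I1 - 3)^i (MPa)."""

    coefficients: tuple[float, ...]
    plastic: PlasticTable | None = None
    stress_unit: str = "MPa"

    def __post_init__(self) -> None:
        if len(self.coefficients) != 6:
            raise ValueError("exactly six coefficients C_10..C_60 required")


HyperelasticModel = Union[NeoHookeanPlastic, OgdenFirstOrder, ReducedPolynomial6, LinearElasticPlastic]


# ---------------------------------------------------------------------------
# material-point evaluators
# ---------------------------------------------------------------------------

def strain_energy(model: HyperelasticModel, state: StretchState) -> float:
    """Strain-energy density at the given principal stretches.

    Hyperelastic models are evaluated on the isochoric invariants as printed;
    the linear elastic model uses isotropic Hooke energy on the small strains
    ``eps_i = lambda_i - 1``.  Vanishes at the identity for every model.
    """
    if isinstance(model, NeoHookeanPlastic):
        return model.c10 * (state.I1 - 3.0)
    if isinstance(model, OgdenFirstOrder):
        a = model.alpha
        return model.scale * (state.l1**a + state.l2**a + state.l3**a - 3.0)
    if isinstance(model, ReducedPolynomial6):
        x = state.I1 - 3.0
        # Horner form over C_10..C_60
        acc = 0.0
        for c in reversed(model.coefficients):
            acc = x * (c + acc)
        return acc
    if isinstance(model, LinearElasticPlastic):
        e = np.array([state.l1, state.l2, state.l3]) - 1.0
        E, nu = model.youngs_modulus, model.poisson
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return float(0.5 * lam * e.sum() ** 2 + mu * (e**2).sum())
    raise TypeError(f"unsupported model {type(model).__name__}")


def uniaxial_cauchy_stress(model: HyperelasticModel, lam: float) -> float:
    """Cauchy stress in incompressible uniaxial tension at stretch ``lam``.

    For the hyperelastic laws this is ``lam * d/d lam`` of the energy along
    the isochoric path ``(lam, lam^-1/2, lam^-1/2)``; the linear elastic model
    returns ``E (lam - 1)`` (a uniaxial-test reading).
    """
    if lam <= 0:
        raise ValueError("stretch must be positive")
    if isinstance(model, NeoHookeanPlastic):
        return 2.0 * model.c10 * (lam**2 - 1.0 / lam)
    if isinstance(model, OgdenFirstOrder):
        a = model.alpha
        return model.scale * a * (lam**a - lam ** (-0.5 * a))
    if isinstance(model, ReducedPolynomial6):
        I1 = lam**2 + 2.0 / lam
        x = I1 - 3.0
        dpsi = 0.0
        for i, c in enumerate(model.coefficients, start=1):
            dpsi += i * c * x ** (i - 1)
        return dpsi * (2.0 * lam**2 - 2.0 / lam)
    if isinstance(model, LinearElasticPlastic):
        return model.youngs_modulus * (lam - 1.0)
    raise TypeError(f"unsupported model {type(model).__name__}")


@dataclass(frozen=True)
class Modulus:
    """Small-strain Young's modulus with a stability flag."""

    value: float
    stable: bool
    unit: str


def small_strain_modulus(model: HyperelasticModel, h: float = 1e-6) -> Modulus:
    """Numerical slope d sigma / d lambda of the uniaxial response at identity.

    A non-positive slope (e.g. the Ogden law under the as-printed scaling
    with a negative exponent) is returned flagged rather than raised.
    """
    slope = (uniaxial_cauchy_stress(model, 1.0 + h) - uniaxial_cauchy_stress(model, 1.0 - h)) / (2.0 * h)
    stable = slope > 0
    if not stable:
        warnings.warn(
            f"{type(model).__name__} has a non-positive small-strain modulus "
            f"({slope:.4g} {model.stress_unit}); unstable at the identity",
            stacklevel=2,
        )
    return Modulus(value=float(slope), stable=bool(stable), unit=model.stress_unit)


def hardening_stress(table: PlasticTable, eps_p: float | np.ndarray) -> float | np.ndarray:
    """Flow stress at accumulated plastic strain (piecewise linear in the
    table, constant beyond the last knot)."""
    return table.stress(eps_p)


def uniaxial_elastoplastic_path(
    model: LinearElasticPlastic | NeoHookeanPlastic,
    strains: Sequence[float],
) -> np.ndarray:
    """Stress history along a 1D strain path (return-mapping integration).

    Linear elastic-plastic models unload with slope E and harden along their
    table (or hold the yield plateau when perfectly plastic).  The capped
    neo-Hookean lipidic model returns its hyperelastic uniaxial stress with
    magnitude clipped at the yield cap.
    """
    strains = np.asarray(strains, dtype=float)
    if strains.ndim != 1 or strains.size == 0:
        raise ValueError("strain history must be a non-empty 1D sequence")
    if abs(strains[0]) > 1e-12:
        raise ValueError("strain history must start at zero strain")

    if isinstance(model, NeoHookeanPlastic):
        sig = np.array([uniaxial_cauchy_stress(model, 1.0 + e) for e in strains])
        return np.clip(sig, -model.yield_stress, model.yield_stress)

    E = model.youngs_modulus
    eps_p = 0.0  # signed plastic strain
    p = 0.0  # accumulated plastic strain
    out = np.empty_like(strains)
    for k, eps in enumerate(strains):
        trial = E * (eps - eps_p)
        f = abs(trial) - model.yield_curve(p)
        if f <= 0:
            out[k] = trial
            continue
        if model.hardening is None:
            dp = f / E
        else:
            def resid(dp: float) -> float:
                return abs(trial) - E * dp - model.yield_curve(p + dp)

            hi = f / E  # non-decreasing hardening => root is below the
            dp = brentq(resid, 0.0, hi, xtol=1e-14)  # perfectly-plastic step
        sign = math.copysign(1.0, trial)
        eps_p += sign * dp
        p += dp
        out[k] = sign * (abs(trial) - E * dp)
    return out


# ---------------------------------------------------------------------------
# shipped parameter library
# ---------------------------------------------------------------------------

STENT_PLASTIC = PlasticTable([(0.0, 480.0), (0.35, 1208.0), (0.62, 1300.0)])
MEDIA_PLASTIC = PlasticTable([(0.0, 0.7), (0.07, 1.1), (0.4, 2.0)])
ADVENTITIA_PLASTIC = PlasticTable([(0.0, 1.6), (0.07, 2.3), (0.4, 4.0)])

MEDIA_COEFFS = (7.21e-2, 3.71e0, -1.56e2, 9.18e3, -2.61e5, 2.91e6)
ADVENTITIA_COEFFS = (2.60e-1, 4.76e1, -4.09e3, 5.29e5, -2.69e7, 5.65e8)

MATERIAL_LIBRARY: dict[str, HyperelasticModel] = {
    # lesion soft tissue in kPa
    "lipidic": NeoHookeanPlastic(c10=13.3, yield_stress=70.0),
    # calcified plaque: perfectly plastic at 0.48 MPa
    "calcium": LinearElasticPlastic(youngs_modulus=44.0, poisson=0.3, yield_stress=0.48),
    "media": ReducedPolynomial6(MEDIA_COEFFS, plastic=MEDIA_PLASTIC),
    "adventitia": ReducedPolynomial6(ADVENTITIA_COEFFS, plastic=ADVENTITIA_PLASTIC),
    # platinum-chromium stent: E = 203 GPa in MPa
    "stent": LinearElasticPlastic(
        youngs_modulus=203_000.0, poisson=0.3, yield_stress=480.0, hardening=STENT_PLASTIC
    ),
    "balloon": OgdenFirstOrder(mu=80.0, alpha=-15.0, convention="quadratic"),
}


def get_material(name: str) -> HyperelasticModel:
    """Look up a shipped material model by its component name."""
    try:
        return MATERIAL_LIBRARY[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(MATERIAL_LIBRARY)}"
        ) from None
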