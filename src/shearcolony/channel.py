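"""Laminar flow and solute transport in a shallow rectangular culture channel.

The culture chamber is a straight cuboid duct (length ``L`` along the flow,
width ``w``, height ``h``, with ``w > h``) perfused at a constant volumetric
rate ``Q``.  At the low Reynolds numbers of microfluidic perfusion the
velocity field is the Stokes (Poiseuille) solution for a rectangular duct,
which is available as a classical Fourier series.  Attached bacteria sit in
the first few microns above the floor, so the mechanical forcing they feel is
the wall shear rate, gamma = dv/dz, averaged over the height of the cell
monolayer, and the corresponding shear stress tau_w = mu * gamma.

Transport limitation is screened with Damkohler numbers: the ratio of a
transport time (diffusion of oxygen through the gas-permeable membrane, or
advection of glucose along the channel) to the consumption time
``tau_c = c h / (mu_X B)`` of the attached population.  Values well below one
mean that neither oxygen nor nutrients limit growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelGeometry",
    "FlowRegime",
    "TransportParams",
    "InvalidGeometryError",
    "duct_velocity_profile",
    "wall_shear_rate",
    "flow_rate_for_shear",
    "shear_stress",
    "damkohler_numbers",
    "PAPER_REGIMES",
    "WATER_VISCOSITY_37C_MPA_S",
]

#: dynamic viscosity of water at 37 degrees C, in mPa*s
WATER_VISCOSITY_37C_MPA_S = 0.691


class InvalidGeometryError(ValueError):
    """Raised for non-physical channel dimensions or parameters."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Culture-channel dimensions, SI units (metres).

    ``monolayer_height`` is the height of the attached bacterial monolayer
    over which the wall shear rate is averaged (cells occupy the first ~3 um
    above the floor).  ``membrane_thickness_e`` is the thickness of the
    gas-permeable membrane separating the culture channel from the air
    channel above it.
    """

    length_L: float = 10e-3
    width_w: float = 1e-3
    height_h: float = 1.5e-4
    membrane_thickness_e: float = 1.5e-4
    monolayer_height: float = 3e-6

    def __post_init__(self) -> None:
        for name in ("length_L", "width_w", "height_h", "membrane_thickness_e",
                     "monolayer_height"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be strictly positive")
        if self.monolayer_height >= self.height_h / 2:
            raise InvalidGeometryError(
                "monolayer_height must be small compared to the channel height")
        if self.width_w <= self.height_h:
            raise InvalidGeometryError(
                "wide-channel geometry requires width_w > height_h")


@dataclass(frozen=True)
class FlowRegime:
    """A named flow condition: shear rate at the floor and resulting stress.

    ``shear_stress_mPa`` must equal ``viscosity_mu_mPa_s * shear_rate_s``
    within rounding; the constructor enforces this to 0.5 mPa.
    """

    name: str
    shear_rate_s: float
    shear_stress_mPa: float
    flow_rate_Q: float | None = None
    viscosity_mu_mPa_s: float = WATER_VISCOSITY_37C_MPA_S

    def __post_init__(self) -> None:
        if self.shear_rate_s < 0:
            raise InvalidGeometryError("shear_rate must be non-negative")
        if self.viscosity_mu_mPa_s <= 0:
            raise InvalidGeometryError("viscosity must be positive")
        expected = self.viscosity_mu_mPa_s * self.shear_rate_s
        if abs(expected - self.shear_stress_mPa) > 0.5:
            raise InvalidGeometryError(
                f"shear_stress {self.shear_stress_mPa} mPa inconsistent with "
                f"viscosity*shear_rate = {expected:.2f} mPa")


#: The four flow regimes of the reference experiment: printed shear rates
#: (s^-1) and the shear stresses (mPa) they imply at 37 C.
PAPER_REGIMES: tuple[FlowRegime, ...] = (
    FlowRegime("ulow", 7.0, 5.0),
    FlowRegime("low", 29.0, 20.0),
    FlowRegime("med", 72.0, 50.0),
    FlowRegime("high", 116.0, 80.0),
)


def _series_terms(geometry: ChannelGeometry, rtol: float = 1e-6,
                  max_terms: int = 2000) -> int:
    """Number of odd Fourier terms so the mid-width wall shear is converged.

    Terms are added until the next one changes the mid-width wall shear
    correction by less than ``rtol`` relative.  For wide channels
    (w/h >~ 3) the corrections decay like sech(n*pi*w/(2h)) and one or two
    terms suffice.
    """
    h, w = geometry.height_h, geometry.width_w
    total = 0.0
    n_terms = 1
    for i in range(max_terms):
        n = 2 * i + 1
        term = (1.0 / n**2) / np.cosh(n * np.pi * w / (2 * h))
        total += term
        n_terms = i + 1
        if total > 0 and term < rtol * max(total, 1e-300):
            break
    return n_terms


def _pressure_gradient(geometry: ChannelGeometry, flow_rate: float,
                       mu: float, n_terms: int) -> float:
    """Pressure gradient G = -dp/dx driving ``flow_rate`` through the duct."""
    h, w = geometry.height_h, geometry.width_w
    n = 2 * np.arange(n_terms) + 1
    series = np.sum(np.tanh(n * np.pi * w / (2 * h)) / n**5)
    denom = w * h**3 / 6.0 - (32.0 * h**4 / np.pi**5) * series
    return 2.0 * mu * flow_rate / denom


def duct_velocity_profile(geometry: ChannelGeometry, flow_rate: float,
                          n_points: int = 201, viscosity_Pa_s: float = 1e-3,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Streamwise velocity sampled on a vertical line at mid-width.

    Returns ``(z, v)`` with ``z`` a uniform grid over [0, h] (m) and ``v``
    the velocity (m/s) from the truncated Fourier-series solution of the
    Stokes equation in a rectangular duct.  ``v(0) = v(h) = 0`` and
    integrating the full 2-D profile over the cross-section recovers
    ``flow_rate``.

    The shape of the profile (and every shear rate derived from it) is
    independent of the viscosity, which cancels between the pressure
    gradient and the velocity solution.
    """
    if flow_rate < 0:
        raise InvalidGeometryError("flow_rate must be non-negative")
    h, w = geometry.height_h, geometry.width_w
    z = np.linspace(0.0, h, n_points)
    if flow_rate == 0:
        return z, np.zeros_like(z)
    n_terms = _series_terms(geometry)
    G = _pressure_gradient(geometry, flow_rate, viscosity_Pa_s, n_terms)
    v = _velocity_at(geometry, G, viscosity_Pa_s, 0.0, z, n_terms)
    return z, v


def _velocity_at(geometry: ChannelGeometry, G: float, mu: float, y: float,
                 z: np.ndarray, n_terms: int) -> np.ndarray:
    h = geometry.height_h
    w = geometry.width_w
    n = (2 * np.arange(n_terms) + 1)[:, None]
    zz = np.atleast_1d(z)[None, :]
    series = np.sum(
        np.cosh(n * np.pi * y / h) / np.cosh(n * np.pi * w / (2 * h))
        * np.sin(n * np.pi * zz / h) / n**3,
        axis=0,
    )
    v = (G / (2 * mu)) * (zz[0] * (h - zz[0]) - (8 * h**2 / np.pi**3) * series)
    return v


def cross_section_flow_rate(geometry: ChannelGeometry, flow_rate: float,
                            n_y: int = 201, n_z: int = 201) -> float:
    """Recompute Q by 2-D quadrature of the duct profile (consistency check)."""
    mu = 1e-3
    n_terms = _series_terms(geometry)
    G = _pressure_gradient(geometry, flow_rate, mu, n_terms)
    h, w = geometry.height_h, geometry.width_w
    ys = np.linspace(-w / 2, w / 2, n_y)
    zs = np.linspace(0.0, h, n_z)
    profile = np.stack([_velocity_at(geometry, G, mu, y, zs, n_terms)
                        for y in ys])
    return float(np.trapezoid(np.trapezoid(profile, zs, axis=1), ys))


def wall_shear_rate(geometry: ChannelGeometry, flow_rate: float) -> float:
    """Shear rate dv/dz (s^-1) averaged over the monolayer height at mid-width.

    Because v(0) = 0, the average of dv/dz over [0, z_m] is exactly
    v(z_m)/z_m, which is evaluated from the series solution directly.
    """
    if flow_rate < 0:
        raise InvalidGeometryError("flow_rate must be non-negative")
    if flow_rate == 0:
        return 0.0
    zm = geometry.monolayer_height
    mu = 1e-3
    n_terms = _series_terms(geometry)
    G = _pressure_gradient(geometry, flow_rate, mu, n_terms)
    v_zm = _velocity_at(geometry, G, mu, 0.0, np.array([zm]), n_terms)[0]
    return float(v_zm / zm)


def flow_rate_for_shear(geometry: ChannelGeometry, shear_rate: float) -> float:
    """Volumetric flow rate (m^3/s) producing a given monolayer-averaged shear.

    The duct problem is linear, so the answer is a single rescaling of a
    reference solution.
    """
    if shear_rate < 0:
        raise InvalidGeometryError("shear_rate must be non-negative")
    if shear_rate == 0:
        return 0.0
    q_ref = 1e-10
    return q_ref * shear_rate / wall_shear_rate(geometry, q_ref)


def shear_stress(shear_rate: float, viscosity: float = WATER_VISCOSITY_37C_MPA_S,
                 ) -> float:
    """Wall shear stress tau_w = mu * dv/dz.

    ``shear_rate`` in s^-1 and ``viscosity`` in mPa*s give the stress in mPa.
    """
    if shear_rate < 0 or viscosity <= 0:
        raise InvalidGeometryError(
            "shear_rate must be >= 0 and viscosity must be > 0")
    return viscosity * shear_rate


@dataclass(frozen=True)
class TransportParams:
    """Concentrations, consumption rates and transport scales, SI units.

    ``mu_O2`` / ``mu_glu`` are per-cell consumption rates (kg cell^-1 s^-1);
    they are deliberately named apart from the dynamic viscosity.  ``B`` is
    the surface density of attached cells (cell m^-2) and ``v_mean`` the mean
    flow velocity in the channel.  ``D_O2_pdms``, the diffusivity of oxygen
    through the membrane material, has no single canonical value and must be
    supplied explicitly (literature values are around 3.4e-9 m^2/s).
    ``advection_length_L`` is the streamwise length scale used for the
    nutrient advection time; it defaults to the 1e-3 m scale of the original
    transport estimate, which is shorter than the full channel length.
    """

    B: float
    v_mean: float
    c_O2: float = 6.6e-3
    c_glu: float = 2e-3
    mu_O2: float = 7e-21
    mu_glu: float = 5e-20
    D_O2_pdms: float | None = None
    advection_length_L: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("v_mean", "c_O2", "c_glu", "mu_O2", "mu_glu",
                     "advection_length_L"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be strictly positive")
        if self.B < 0:
            raise InvalidGeometryError("B must be non-negative")


class MissingDiffusivityError(ValueError):
    """Raised when the membrane oxygen diffusivity is not configured."""


def damkohler_numbers(params: TransportParams, geometry: ChannelGeometry,
                      ) -> tuple[float, float]:
    """Damkohler numbers (Da_O2, Da_nutrient) for the culture channel.

    ``Da_O2 = tau_D / tau_c^O2`` with ``tau_D = e^2 / D`` the membrane
    diffusion time, and ``Da_n = tau_a / tau_c^glu`` with ``tau_a = L / v``
    the advection time.  Consumption times are ``tau_c = c h / (mu_X B)``.
    Both numbers vanish with the cell density B (no consumption, no
    limitation).
    """
    if params.D_O2_pdms is None:
        raise MissingDiffusivityError(
            "D_O2_pdms must be supplied explicitly; there is no universal "
            "default for oxygen diffusivity through the membrane material")
    if params.D_O2_pdms <= 0:
        raise InvalidGeometryError("D_O2_pdms must be strictly positive")
    e = geometry.membrane_thickness_e
    h = geometry.height_h
    tau_D = e**2 / params.D_O2_pdms
    tau_a = params.advection_length_L / params.v_mean
    if params.B == 0:
        return 0.0, 0.0
    tau_c_O2 = params.c_O2 * h / (params.mu_O2 * params.B)
    tau_c_glu = params.c_glu * h / (params.mu_glu * params.B)
    return tau_D / tau_c_O2, tau_a / tau_c_glu
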