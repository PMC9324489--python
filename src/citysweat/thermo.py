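"""Steady-state human heat balance and sweat-rate prediction.

The central quantity is the sweating rate ``m_sw`` (g·m⁻²·h⁻¹) of a clothed
person in thermal steady state, predicted by the piecewise (PW) regression

    m_sw = 147 + 1.527·E_req − 0.87·E_max

where ``E_req`` (W/m²) is the evaporative heat loss required to close the
body's heat balance,

    E_req = M − W − C − R − Q_res,

and ``E_max`` (W/m²) is the maximal evaporative capacity of the environment,
set by the skin-to-air vapor-pressure gradient working against the clothing
evaporative resistance and the boundary-layer mass-transfer resistance:

    E_max = (P_sk − P_a) / (I_e,cl + 1/(f_cl·h_e)).

Dry heat losses are evaluated at the clothing surface temperature ``t_cl``,
which solves the steady conduction balance through the clothing layer:

    (T_sk − t_cl)/I_cl = f_cl·h_c·(t_cl − t_a) + f_r·h_r·(t_cl − t_r).

Mean skin temperature follows Saltin's linear regression on air temperature,
and skin/ambient vapor pressures come from an Antoine-form saturation curve
whose native unit is mmHg (converted to kPa before use in the heat balance).

All fluxes are per unit nude body surface area (DuBois area, ``A_D``).
Whole-body evaporation is ``m_sw × A_D × time``, with 1 g of water ≡ 1 mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Environment",
    "ActivityLevel",
    "ClothingEnsemble",
    "PersonProfile",
    "ModelConstants",
    "HeatBalanceResult",
    "DEFAULT_CONSTANTS",
    "SLEEP",
    "LIGHT_WORK",
    "MODERATE_WORK",
    "ACTIVITY_LEVELS",
    "SEASONAL_CLOTHING",
    "SEASONS",
    "skin_temperature",
    "saturation_vapor_pressure",
    "skin_vapor_pressure",
    "ambient_vapor_pressure",
    "metabolic_rate_from_gas",
    "mechanical_work",
    "clothing_surface_temperature",
    "convective_loss",
    "radiant_loss",
    "respiratory_loss",
    "required_evaporation",
    "evaporative_resistance",
    "mass_transfer_coefficient",
    "max_evaporative_capacity",
    "sweat_rate",
    "person_evaporation_mass",
    "heat_balance",
    "body_surface_area_dubois",
]

#: 1 mmHg in kPa.
MMHG_TO_KPA = 0.133322
#: 1 clo of clothing insulation in m²·K/W.
CLO_TO_SI = 0.155

SEASONS = ("spring", "summer", "autumn", "winter")


@dataclass(frozen=True)
class ModelConstants:
    """Literal constants of the sweat model, immutable after construction.

    ``vapor_unit`` selects the interpretation of the Antoine saturation
    formula: ``"mmHg"`` (default) treats its output as mmHg and converts to
    kPa; ``"as_printed"`` takes the raw exponential as kPa. ``e11_grouping``
    selects the clothing evaporative-resistance reading: ``"divide"``
    (default, the standard clothing-science convention I_cl/(i_cl·LR)) or
    ``"product"`` (I_cl·i_cl/LR).
    """

    sweat_intercept: float = 147.0          # g·m⁻²·h⁻¹
    ereq_coef: float = 1.527                # g·m⁻²·h⁻¹ per W/m²
    emax_coef: float = 0.87                 # g·m⁻²·h⁻¹ per W/m²
    lewis_ratio: float = 16.5               # °C/kPa, typical indoor air
    resp_latent_coef: float = 0.0173
    resp_dry_coef: float = 0.0014
    resp_ref_pressure: float = 5.867        # kPa
    resp_ref_temp: float = 34.0             # °C
    tsk_slope: float = 0.215
    tsk_intercept: float = 26.6             # °C
    antoine_a: float = 18.6686
    antoine_b: float = 4030.183
    antoine_c: float = 235.0                # °C
    hr: float = 4.7                         # W/(m²·K), linearized radiation
    vapor_unit: str = "mmHg"
    e11_grouping: str = "divide"

    def __post_init__(self) -> None:
        for name in (
            "sweat_intercept", "ereq_coef", "emax_coef", "lewis_ratio",
            "resp_latent_coef", "resp_dry_coef", "resp_ref_pressure",
            "resp_ref_temp", "tsk_slope", "tsk_intercept", "antoine_a",
            "antoine_b", "antoine_c", "hr",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"ModelConstants.{name} must be positive")
        if self.vapor_unit not in ("mmHg", "as_printed"):
            raise ValueError(f"unknown vapor_unit {self.vapor_unit!r}")
        if self.e11_grouping not in ("divide", "product"):
            raise ValueError(f"unknown e11_grouping {self.e11_grouping!r}")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class Environment:
    """Thermal environment around the body.

    Parameters
    ----------
    ta : float
        Air temperature around the body, °C.
    tr : float
        Mean radiant temperature, °C. Defaults to ``ta`` (indoor assumption).
    rh : float
        Relative humidity as a fraction in [0, 1].
    """

    ta: float
    tr: float | None = None
    rh: float = 0.5

    def __post_init__(self) -> None:
        if not (-50.0 < self.ta < 60.0):
            raise ValueError(f"air temperature {self.ta} °C outside (-50, 60)")
        if not (0.0 <= self.rh <= 1.0):
            raise ValueError(f"relative humidity {self.rh} outside [0, 1]")
        if self.tr is None:
            object.__setattr__(self, "tr", self.ta)

    def pa(self, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
        """Ambient water-vapor pressure, kPa."""
        return ambient_vapor_pressure(self.ta, self.rh, constants)


@dataclass(frozen=True)
class ActivityLevel:
    """Activity class: metabolic rate and surface transfer coefficients.

    ``M`` is the metabolic rate (W/m²), ``hc`` the convective heat-transfer
    coefficient (W/(m²·K)), ``fr`` the effective radiation area factor and
    ``eta`` the mechanical efficiency (≈0 for ordinary activities).
    """

    name: str
    M: float
    hc: float
    fr: float
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.M <= 0 or self.hc <= 0:
            raise ValueError("metabolic rate and hc must be positive")
        if not (0.0 <= self.fr <= 1.0):
            raise ValueError("radiation area factor must lie in [0, 1]")
        if not (0.0 <= self.eta <= 0.10):
            raise ValueError("mechanical efficiency must lie in [0, 0.10]")


SLEEP = ActivityLevel("sleep", M=40.0, hc=2.7, fr=0.35)
LIGHT_WORK = ActivityLevel("light_work", M=75.0, hc=4.0, fr=0.7)
MODERATE_WORK = ActivityLevel("moderate_work", M=220.0, hc=8.2, fr=0.73)
ACTIVITY_LEVELS = {a.name: a for a in (SLEEP, LIGHT_WORK, MODERATE_WORK)}


@dataclass(frozen=True)
class ClothingEnsemble:
    """Seasonal clothing ensemble.

    ``fcl`` is the clothing area factor (clothed/nude surface ratio),
    ``Icl`` the intrinsic clothing insulation and ``icl`` the water-vapor
    permeability index. ``Icl_unit`` declares how ``Icl`` is expressed:
    ``"clo"`` (default; converted with 1 clo = 0.155 m²·K/W) or ``"si"``
    (already m²·K/W).
    """

    season: str
    fcl: float
    Icl: float
    icl: float
    Icl_unit: str = "clo"

    def __post_init__(self) -> None:
        if self.fcl < 1.0:
            raise ValueError("clothing area factor must be >= 1")
        if self.Icl <= 0:
            raise ValueError("clothing insulation must be positive")
        if not (0.0 < self.icl <= 1.0):
            raise ValueError("vapor permeability index must lie in (0, 1]")
        if self.Icl_unit not in ("clo", "si"):
            raise ValueError(f"unknown Icl_unit {self.Icl_unit!r}")

    @property
    def icl_si(self) -> float:
        """Clothing insulation in m²·K/W under the declared unit."""
        return self.Icl * CLO_TO_SI if self.Icl_unit == "clo" else self.Icl

    def with_unit(self, unit: str) -> "ClothingEnsemble":
        return replace(self, Icl_unit=unit)


SEASONAL_CLOTHING = {
    "spring": ClothingEnsemble("spring", fcl=1.22, Icl=0.89, icl=0.50),
    "summer": ClothingEnsemble("summer", fcl=1.10, Icl=0.36, icl=0.55),
    "autumn": ClothingEnsemble("autumn", fcl=1.28, Icl=1.01, icl=0.48),
    "winter": ClothingEnsemble("winter", fcl=1.33, Icl=1.20, icl=0.43),
}


def body_surface_area_dubois(mass_kg: float, height_m: float) -> float:
    """DuBois & DuBois body-surface area, m²: 0.202·m^0.425·h^0.725."""
    if mass_kg <= 0 or height_m <= 0:
        raise ValueError("mass and height must be positive")
    return 0.202 * mass_kg ** 0.425 * height_m ** 0.725


@dataclass(frozen=True)
class PersonProfile:
    """Representative person; ``AD`` is the nude body surface area in m²."""

    AD: float = 1.8

    def __post_init__(self) -> None:
        if not (1.0 < self.AD < 2.6):
            raise ValueError(f"body surface area {self.AD} m² outside (1.0, 2.6)")

    @classmethod
    def from_mass_height(cls, mass_kg: float, height_m: float) -> "PersonProfile":
        return cls(AD=body_surface_area_dubois(mass_kg, height_m))


@dataclass(frozen=True)
class HeatBalanceResult:
    """All intermediate and final quantities of one heat-balance evaluation."""

    Tsk: float      # mean skin temperature, °C
    tcl: float      # clothing surface temperature, °C
    Psk: float      # skin saturation vapor pressure, kPa
    Pa: float       # ambient vapor pressure, kPa
    C: float        # convective loss, W/m²
    R: float        # radiant loss, W/m²
    Qres: float     # respiratory loss, W/m²
    W: float        # mechanical work, W/m²
    Ereq: float     # required evaporation, W/m²
    Emax: float     # maximal evaporative capacity, W/m²
    msw: float      # sweat rate, g·m⁻²·h⁻¹ (clamped at 0)
    msw_raw: float  # unclamped regression value
    clamped: bool = field(default=False)


# ---------------------------------------------------------------------------
# elementary operations

def skin_temperature(ta: float, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Mean skin temperature (°C) from air temperature via Saltin's regression."""
    if not math.isfinite(ta):
        raise ValueError("air temperature must be finite")
    return constants.tsk_slope * ta + constants.tsk_intercept


def saturation_vapor_pressure(
    t: float, constants: ModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Saturation water-vapor pressure at temperature ``t`` (°C), in kPa.

    Antoine form exp(A − B/(t + C)); the fitted constants are native to mmHg
    (the curve passes ≈1 atm at 100 °C), converted to kPa unless the
    constants request the as-printed reading.
    """
    if t <= -constants.antoine_c:
        raise ValueError(f"temperature {t} °C at or below -{constants.antoine_c} °C")
    native = math.exp(constants.antoine_a - constants.antoine_b / (t + constants.antoine_c))
    if constants.vapor_unit == "mmHg":
        return native * MMHG_TO_KPA
    return native


def skin_vapor_pressure(
    tsk: float, constants: ModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Vapor pressure of water on the skin surface (saturated at ``tsk``), kPa."""
    return saturation_vapor_pressure(tsk, constants)


def ambient_vapor_pressure(
    ta: float, rh: float, constants: ModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Ambient vapor pressure, kPa: relative humidity × saturation at ``ta``."""
    if not (0.0 <= rh <= 1.0):
        raise ValueError(f"relative humidity {rh} outside [0, 1]")
    return rh * saturation_vapor_pressure(ta, constants)


def metabolic_rate_from_gas(rq: float, vo2_ml_s: float, ad: float) -> float:
    """Metabolic rate (W/m²) from respiratory gas exchange.

    ``rq`` is the respiratory quotient (CO₂/O₂ molar ratio), ``vo2_ml_s`` the
    oxygen consumption at STP (mL/s) and ``ad`` the body surface area (m²):
    M = 21·(0.23·RQ + 0.77)·V_O2/A_D.
    """
    if vo2_ml_s <= 0:
        raise ValueError("oxygen consumption must be positive")
    if ad <= 0:
        raise ValueError("body surface area must be positive")
    return 21.0 * (0.23 * rq + 0.77) * vo2_ml_s / ad


def mechanical_work(m: float, eta: float) -> float:
    """Rate of accomplished mechanical work, W/m²: W = η·M."""
    if not (0.0 <= eta <= 0.10):
        raise ValueError("mechanical efficiency must lie in [0, 0.10]")
    return eta * m


def clothing_surface_temperature(
    tsk: float,
    env: Environment,
    act: ActivityLevel,
    clo: ClothingEnsemble,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Clothing surface temperature ``t_cl`` (°C).

    Solves the steady conduction balance through the clothing layer,

        (T_sk − t_cl)/I_cl = f_cl·h_c·(t_cl − t_a) + f_r·h_r·(t_cl − t_r),

    which is linear in ``t_cl`` for a fixed linearized radiation coefficient,
    so the exact fixed point is computed directly. The residual is asserted
    below 1e−6 W/m² on every call.
    """
    icl = clo.icl_si
    if icl <= 0:
        raise ValueError("effective clothing insulation must be positive")
    k_cond = 1.0 / icl
    k_conv = clo.fcl * act.hc
    k_rad = act.fr * constants.hr
    tcl = (k_cond * tsk + k_conv * env.ta + k_rad * env.tr) / (k_cond + k_conv + k_rad)
    residual = k_cond * (tsk - tcl) - k_conv * (tcl - env.ta) - k_rad * (tcl - env.tr)
    if abs(residual) > 1e-6:
        raise ArithmeticError(f"clothing balance residual {residual:g} W/m² > 1e-6")
    return tcl


def convective_loss(fcl: float, hc: float, tcl: float, ta: float) -> float:
    """Convective heat loss, W/m²: C = f_cl·h_c·(t_cl − t_a)."""
    return fcl * hc * (tcl - ta)


def radiant_loss(fr: float, hr: float, tcl: float, tr: float) -> float:
    """Radiant heat loss, W/m²: R = f_r·h_r·(t_cl − t_r)."""
    return fr * hr * (tcl - tr)


def respiratory_loss(
    m: float, pa: float, ta: float, constants: ModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Respiratory heat loss, W/m² (latent + dry term).

    Q_res = 0.0173·M·(5.867 − P_a) + 0.0014·M·(34 − t_a), with P_a in kPa.
    """
    if pa < 0:
        raise ValueError("ambient vapor pressure must be non-negative")
    return (
        constants.resp_latent_coef * m * (constants.resp_ref_pressure - pa)
        + constants.resp_dry_coef * m * (constants.resp_ref_temp - ta)
    )


def required_evaporation(m: float, w: float, c: float, r: float, qres: float) -> float:
    """Evaporation required to close the heat balance: E_req = M − W − C − R − Q_res."""
    return m - w - c - r - qres


def evaporative_resistance(
    icl_si: float,
    icl_perm: float,
    lr: float = DEFAULT_CONSTANTS.lewis_ratio,
    grouping: str = "divide",
) -> float:
    """Clothing evaporative resistance I_e,cl, m²·kPa/W.

    Default convention I_e,cl = I_cl/(i_cl·LR); the alternate ``"product"``
    grouping I_cl·i_cl/LR is selectable for sensitivity to the reading.
    """
    if icl_perm <= 0:
        raise ValueError("vapor permeability index must be positive")
    if lr <= 0:
        raise ValueError("Lewis ratio must be positive")
    if grouping == "divide":
        return icl_si / (icl_perm * lr)
    if grouping == "product":
        return icl_si * icl_perm / lr
    raise ValueError(f"unknown grouping {grouping!r}")


def mass_transfer_coefficient(
    hc: float, lr: float = DEFAULT_CONSTANTS.lewis_ratio
) -> float:
    """Convective mass-transfer coefficient on the garment surface: h_e = LR·h_c."""
    if hc <= 0 or lr <= 0:
        raise ValueError("hc and Lewis ratio must be positive")
    return lr * hc


def max_evaporative_capacity(
    psk: float, pa: float, ie_cl: float, fcl: float, he: float
) -> float:
    """Maximal evaporative capacity of the environment, W/m².

    E_max = (P_sk − P_a)/(I_e,cl + 1/(f_cl·h_e)): the vapor-pressure gradient
    across the series resistance of clothing and boundary layer.
    """
    denom = ie_cl + 1.0 / (fcl * he)
    if denom <= 0:
        raise ValueError("total evaporative resistance must be positive")
    return (psk - pa) / denom


def sweat_rate(
    ereq: float, emax: float, constants: ModelConstants = DEFAULT_CONSTANTS
) -> tuple[float, bool]:
    """PW sweat rate, g·m⁻²·h⁻¹, with negative predictions clamped at zero.

    Returns ``(msw, clamped)`` where ``clamped`` records that the raw
    regression value 147 + 1.527·E_req − 0.87·E_max was negative.
    """
    raw = (
        constants.sweat_intercept
        + constants.ereq_coef * ereq
        - constants.emax_coef * emax
    )
    if raw < 0:
        return 0.0, True
    return raw, False


def person_evaporation_mass(msw: float, ad: float, hours: float) -> float:
    """Whole-body evaporated mass, g: m_sw × body surface area × time."""
    if hours < 0:
        raise ValueError("duration must be non-negative")
    return msw * ad * hours


# ---------------------------------------------------------------------------
# full chain

def heat_balance(
    env: Environment,
    act: ActivityLevel,
    clo: ClothingEnsemble,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> HeatBalanceResult:
    """Evaluate the complete heat-balance chain for one steady state."""
    tsk = skin_temperature(env.ta, constants)
    psk = skin_vapor_pressure(tsk, constants)
    pa = ambient_vapor_pressure(env.ta, env.rh, constants)
    tcl = clothing_surface_temperature(tsk, env, act, clo, constants)
    c = convective_loss(clo.fcl, act.hc, tcl, env.ta)
    r = radiant_loss(act.fr, constants.hr, tcl, env.tr)
    qres = respiratory_loss(act.M, pa, env.ta, constants)
    w = mechanical_work(act.M, act.eta)
    ereq = required_evaporation(act.M, w, c, r, qres)
    ie_cl = evaporative_resistance(
        clo.icl_si, clo.icl, constants.lewis_ratio, constants.e11_grouping
    )
    he = mass_transfer_coefficient(act.hc, constants.lewis_ratio)
    emax = max_evaporative_capacity(psk, pa, ie_cl, clo.fcl, he)
    msw, clamped = sweat_rate(ereq, emax, constants)
    raw = msw if not clamped else (
        constants.sweat_intercept + constants.ereq_coef * ereq - constants.emax_coef * emax
    )
    return HeatBalanceResult(
        Tsk=tsk, tcl=tcl, Psk=psk, Pa=pa, C=c, R=r, Qres=qres, W=w,
        Ereq=ereq, Emax=emax, msw=msw, msw_raw=raw, clamped=clamped,
    )
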