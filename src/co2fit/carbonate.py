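"""Carbonate-system chemistry for CO2-bubbled cultivation media.

Implements the dissolved inorganic carbon speciation used to design
bicarbonate-buffered media for cyanobacterial cultivation under elevated
CO2: Henry's-law CO2 solubility, apparent (stoichiometric) dissociation
of the diprotic carbonate system, the NaHCO3 dose that buffers a medium
at a target pH under a given CO2 partial pressure, the inverse problem
(equilibrium pH at a given dose), and a closed-system titration model
from which the apparent pKa values can be fitted.

Conventions
-----------
* Concentrations are exposed in mM; all internal algebra is in mol/L.
* ``pco2`` is the CO2 partial pressure in atm (a gas phase with 30% CO2
  at 1 atm total pressure has pco2 = 0.30).
* Apparent equilibrium constants (concentration based, medium-specific)
  are given as pKa exponents; activity corrections are folded into them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "CarbonateParams",
    "SpeciationResult",
    "TitrationCurve",
    "PkaFit",
    "kh_weiss",
    "speciate_at_ph",
    "nahco3_dose",
    "equilibrium_ph",
    "total_sodium",
    "simulate_titration",
    "fit_pka",
]

#: Baseline Na+ of the buffered growth medium (BG-11 + HEPES/NaOH) before
#: any NaHCO3 addition, mM. Back-calculated from reported Na+ totals.
BASELINE_NA_MM = 32.03


class CarbonateError(ValueError):
    """Domain or solver error in the carbonate model."""


def kh_weiss(temperature: float, salinity: float = 0.0) -> float:
    """CO2 solubility K_H in mol L^-1 atm^-1 (Weiss 1974, volumetric fit).

    ln K0 = A1 + A2(100/T) + A3 ln(T/100) + S [B1 + B2(T/100) + B3(T/100)^2]
    with the mol/(L atm) coefficient set.

    Parameters
    ----------
    temperature : Kelvin. Outside the fit range (271, 313) a warning is
        emitted but the value is still returned.
    salinity : practical salinity (dimensionless).
    """
    if not 271.0 < temperature < 313.0:
        warnings.warn(
            f"temperature {temperature} K outside the Weiss fit range "
            "(271, 313) K; extrapolating",
            stacklevel=2,
        )
    t = temperature / 100.0
    ln_k = (
        -58.0931
        + 90.5069 / t
        + 22.2940 * math.log(t)
        + salinity * (0.027766 - 0.025888 * t + 0.0050578 * t * t)
    )
    return math.exp(ln_k)


#: Default K_H for BG-11-like medium at 30 degC, salinity 1.5. Evaluating
#: the Weiss formula at full precision (0.0296399..., printed as 0.02964)
#: is what reproduces the reference medium-chemistry table cell-for-cell.
KH_DEFAULT = kh_weiss(303.15, 1.5)


@dataclass(frozen=True)
class CarbonateParams:
    """Apparent equilibrium constants of the medium.

    Attributes
    ----------
    kh : CO2 solubility, mol L^-1 atm^-1.
    pka1, pka2 : apparent dissociation exponents of CO2/HCO3- and
        HCO3-/CO3^2- (empirical, titration-derived; defaults 6.35/10.15
        for BG-11-like medium at 30 degC).
    pkw : water self-ionization exponent (13.83 at 30 degC).
    temperature : K. salinity : practical salinity.
    """

    kh: float = field(default=KH_DEFAULT)
    pka1: float = 6.35
    pka2: float = 10.15
    pkw: float = 13.83
    temperature: float = 303.15
    salinity: float = 1.5

    def __post_init__(self) -> None:
        if self.kh <= 0:
            raise CarbonateError(f"kh must be > 0, got {self.kh}")
        if self.pka2 <= self.pka1:
            raise CarbonateError(
                f"pka2 ({self.pka2}) must exceed pka1 ({self.pka1})"
            )
        if self.temperature <= 0:
            raise CarbonateError("temperature must be > 0 K")

    @property
    def ka1(self) -> float:
        return 10.0 ** -self.pka1

    @property
    def ka2(self) -> float:
        return 10.0 ** -self.pka2

    @property
    def kw(self) -> float:
        return 10.0 ** -self.pkw


DEFAULT_PARAMS = CarbonateParams()


@dataclass(frozen=True)
class SpeciationResult:
    """Inorganic-carbon state of a medium, concentrations in mM.

    ``ca`` is the carbonate alkalinity [HCO3-] + 2[CO3^2-]; ``tic`` the
    total inorganic carbon [CO2] + [HCO3-] + [CO3^2-].
    """

    co2: float
    hco3: float
    co3: float
    ca: float
    tic: float
    ph: float
    pco2: float


def speciate_at_ph(
    pco2: float, ph: float, params: CarbonateParams = DEFAULT_PARAMS
) -> SpeciationResult:
    """Speciation of an open system at fixed pH and CO2 partial pressure.

    [CO2] = K_H * pCO2 (Henry's law); [HCO3-] and [CO3^2-] follow from the
    apparent dissociation constants at the given pH.
    """
    if pco2 < 0:
        raise CarbonateError(f"pco2 must be >= 0, got {pco2}")
    if not 0.0 < ph < 14.0:
        raise CarbonateError(f"ph must be in (0, 14), got {ph}")
    co2 = params.kh * pco2  # mol/L
    hco3 = co2 * 10.0 ** (ph - params.pka1)
    co3 = hco3 * 10.0 ** (ph - params.pka2)
    ca = hco3 + 2.0 * co3
    tic = co2 + hco3 + co3
    to_mm = 1000.0
    return SpeciationResult(
        co2=co2 * to_mm,
        hco3=hco3 * to_mm,
        co3=co3 * to_mm,
        ca=ca * to_mm,
        tic=tic * to_mm,
        ph=ph,
        pco2=pco2,
    )


def nahco3_dose(
    pco2: float, target_ph: float, params: CarbonateParams = DEFAULT_PARAMS
) -> float:
    """NaHCO3 addition (mM) that buffers the medium at ``target_ph``.

    The dose is equimolar to the carbonate alkalinity predicted at the
    target pH in equilibrium with the gas phase: each mole of NaHCO3
    contributes one mole of Na+, and at equilibrium the charge carried by
    Na+ is balanced by HCO3- + 2 CO3^2-.
    """
    return speciate_at_ph(pco2, target_ph, params).ca


def equilibrium_ph(
    ca: float,
    pco2: float,
    params: CarbonateParams = DEFAULT_PARAMS,
    include_water: bool = False,
) -> float:
    """pH of a medium with carbonate alkalinity ``ca`` (mM) bubbled at ``pco2``.

    Root of f(pH) = alkalinity_predicted(pH, pco2) - ca, bracketed on
    pH in [2, 12]. With ``include_water=False`` (default) the predicted
    alkalinity is the carbonate alkalinity only, making this the exact
    inverse of :func:`nahco3_dose`. With ``include_water=True`` the
    OH- - H+ terms enter, which is required for low/zero alkalinity (an
    unbuffered medium under CO2 equilibrates at the acidic pH where
    [H+] ~ sqrt(Ka1 [CO2])).
    """
    if ca < 0:
        raise CarbonateError(f"ca must be >= 0, got {ca}")
    if pco2 <= 0:
        raise CarbonateError(f"pco2 must be > 0, got {pco2}")
    ca_m = ca / 1000.0

    def residual(ph: float) -> float:
        co2 = params.kh * pco2
        hco3 = co2 * 10.0 ** (ph - params.pka1)
        co3 = hco3 * 10.0 ** (ph - params.pka2)
        alk = hco3 + 2.0 * co3
        if include_water:
            h = 10.0 ** -ph
            alk += params.kw / h - h
        return alk - ca_m

    lo, hi = 2.0, 12.0
    flo, fhi = residual(lo), residual(hi)
    if flo * fhi > 0:
        raise CarbonateError(
            f"no pH root in [{lo}, {hi}] for ca={ca} mM, pco2={pco2} atm "
            "(alkalinity residual does not change sign; for ca near zero "
            "use include_water=True)"
        )
    return brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)


def total_sodium(dose: float, baseline_na: float = BASELINE_NA_MM) -> float:
    """Total medium Na+ (mM, one decimal): baseline plus NaHCO3 dose."""
    if dose < 0 or baseline_na < 0:
        raise CarbonateError("dose and baseline_na must be >= 0")
    return round(dose + baseline_na, 1)


@dataclass(frozen=True)
class TitrationCurve:
    """Acid titration of a carbonate solution.

    ``acid_added`` in mmol HCl per L of initial solution; ``ph`` the
    modelled or measured pH at each point; ``c0`` the initial carbonate
    (Na2CO3) concentration in mM; ``acid_conc`` the titrant molarity.
    """

    acid_added: np.ndarray
    ph: np.ndarray
    c0: float
    acid_conc: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "acid_added", np.asarray(self.acid_added, float))
        object.__setattr__(self, "ph", np.asarray(self.ph, float))
        if self.acid_added.shape != self.ph.shape:
            raise CarbonateError("acid_added and ph must have equal length")


def _titration_ph(
    acid_mmol: float,
    c0: float,
    acid_conc: float,
    pka1: float,
    pka2: float,
    pkw: float,
) -> float:
    """pH of a closed carbonate system after adding ``acid_mmol`` of HCl.

    Per litre of initial solution: Na+ = 2*c0, TIC = c0 (conserved, no
    degassing), Cl- = acid added; titrant dilution is accounted for.
    Solves the charge balance Na+ + H+ = Cl- + OH- + HCO3- + 2 CO3^2-.
    """
    ka1, ka2, kw = 10.0 ** -pka1, 10.0 ** -pka2, 10.0 ** -pkw
    n_na = 2.0 * c0 / 1000.0
    n_tic = c0 / 1000.0
    n_cl = acid_mmol / 1000.0
    volume = 1.0 + acid_mmol / 1000.0 / acid_conc

    def charge_balance(ph: float) -> float:
        h = 10.0 ** -ph
        oh = kw / h
        a1 = ka1 / h
        a2 = ka1 * ka2 / (h * h)
        denom = 1.0 + a1 + a2
        tic = n_tic / volume
        hco3 = tic * a1 / denom
        co3 = tic * a2 / denom
        return (n_na - n_cl) / volume + h - oh - hco3 - 2.0 * co3

    return brentq(charge_balance, 0.5, 13.8, xtol=1e-13, rtol=8.9e-16)


def simulate_titration(
    c0: float,
    acid_conc: float,
    acid_grid,
    params: CarbonateParams = DEFAULT_PARAMS,
) -> TitrationCurve:
    """Model titration of ``c0`` mM Na2CO3 with HCl of molarity ``acid_conc``.

    The system is treated as closed (TIC conserved, no CO2 escape): the
    simplest model consistent with a rapid titration. pH at each grid
    point solves the charge balance; equivalence points fall at c0 and
    2*c0 mmol/L acid (CO3^2- -> HCO3- -> CO2 stoichiometry).
    """
    if c0 <= 0:
        raise CarbonateError(f"c0 must be > 0, got {c0}")
    acid_grid = np.asarray(acid_grid, float)
    if acid_grid.size and (np.any(acid_grid < 0) or np.any(np.diff(acid_grid) < 0)):
        raise CarbonateError("acid_grid must be non-negative and increasing")
    ph = np.empty_like(acid_grid)
    for i, a in enumerate(acid_grid):
        try:
            ph[i] = _titration_ph(a, c0, acid_conc, params.pka1, params.pka2, params.pkw)
        except Exception as exc:  # pragma: no cover - defensive
            raise CarbonateError(
                f"titration solver failed at acid step {a} mmol/L"
            ) from exc
    return TitrationCurve(acid_added=acid_grid, ph=ph, c0=c0, acid_conc=acid_conc)


@dataclass(frozen=True)
class PkaFit:
    pka1: float
    pka2: float
    residual: float  # root-mean-square pH residual of the fit


def fit_pka(curve: TitrationCurve, params: CarbonateParams = DEFAULT_PARAMS) -> PkaFit:
    """Least-squares estimate of (pKa1, pKa2) from a full titration curve.

    Fits the two apparent dissociation exponents of the closed-system
    titration model to the observed pH values over the whole curve; pKw
    is taken from ``params``. The curve must span both equivalence points
    (acid beyond 2*c0) so that both protonation steps inform the fit.
    """
    if curve.acid_added.size < 4:
        raise CarbonateError("need at least 4 titration points")
    if curve.acid_added.max() < 2.0 * curve.c0:
        raise CarbonateError(
            "titration curve must span both equivalence points "
            f"(max acid {curve.acid_added.max()} < 2*c0 = {2 * curve.c0} mmol/L)"
        )

    def model_residuals(theta):
        pk1, pk2 = theta
        if pk2 <= pk1:  # keep the solver in the physical ordering
            return np.full(curve.ph.shape, 1e3)
        model = np.array(
            [
                _titration_ph(a, curve.c0, curve.acid_conc, pk1, pk2, params.pkw)
                for a in curve.acid_added
            ]
        )
        return model - curve.ph

    fit = least_squares(model_residuals, x0=(6.0, 10.0), method="lm")
    rms = float(np.sqrt(np.mean(fit.fun**2)))
    return PkaFit(pka1=float(fit.x[0]), pka2=float(fit.x[1]), residual=rms)
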