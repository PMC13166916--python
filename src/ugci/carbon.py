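"""Closed-form carbon-component models.

Vegetation carbon stocks follow the IPCC stock-coefficient form
``VCS = A * V * BEF * D * (1 + R) * CF`` with an optional 0.8 correction
for open-grown urban (roadside) trees; tree-level ground truth uses
species-specific allometry ``sum a_j * DBH^b_j``.  Net carbon uptake is
net ecosystem productivity, NEP = GPP - R_eco, with GPP from a
light-use-efficiency model and ecosystem respiration from an empirical
productivity x temperature model, integrated from hourly flux to
tC ha^-1 yr^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StockCoefficients",
    "TreeInventory",
    "GppDrivers",
    "RecoDrivers",
    "URBAN_TREE_CORRECTION",
    "vegetation_c_storage",
    "allometric_c_storage",
    "gpp_lue",
    "reco",
    "trailing_gpp_acc",
    "annual_nep",
]

#: Multiplicative correction for open-grown urban trees relative to
#: closed-canopy natural forest stands.
URBAN_TREE_CORRECTION = 0.8

# Empirical temperature/VPD scalar coefficients of the light-use-efficiency
# GPP model (units: per degC, per kPa, offset).
_GPP_T_COEF = 0.382
_GPP_VPD_COEF = 0.0905
_GPP_OFFSET = 17.72

# Ecosystem-respiration model coefficients: productivity gain per unit
# accumulated GPP, and the exponential temperature sensitivity.
_RECO_GPP_COEF = 0.20
_RECO_T_COEF = 1.16

# 1 umol CO2 m^-2 s^-1 sustained for 1 hour, expressed in tC ha^-1:
# 3600 s * 12e-6 gC/umol * 1e4 m2/ha * 1e-6 t/g
_TC_HA_PER_UMOL_HOUR = 3600.0 * 12e-6 * 1e4 * 1e-6


@dataclass(frozen=True)
class StockCoefficients:
    """IPCC stock-change coefficients for one land-cover class.

    V: growing stock volume (m3/ha); BEF: biomass expansion factor;
    D: basic wood density (t biomass/m3); R: belowground:aboveground
    biomass ratio; CF: carbon fraction of biomass (tC / t biomass).
    """

    V: float
    BEF: float
    D: float
    R: float
    CF: float

    def __post_init__(self) -> None:
        for name in ("V", "BEF", "D", "R", "CF"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.CF > 1:
            raise ValueError(f"CF is a carbon fraction and must be <= 1, got {self.CF}")


def vegetation_c_storage(
    area_ha: float,
    coeffs: StockCoefficients,
    urban_correction: bool = False,
) -> float:
    """Vegetation carbon stock (tC) of ``area_ha`` hectares of one class.

    ``A * V * BEF * D * (1+R) * CF``, times 0.8 when ``urban_correction``
    flags open-grown urban trees assessed with natural-forest coefficients.
    """
    if area_ha < 0:
        raise ValueError(f"area_ha must be >= 0, got {area_ha}")
    stock = area_ha * coeffs.V * coeffs.BEF * coeffs.D * (1.0 + coeffs.R) * coeffs.CF
    if urban_correction:
        stock *= URBAN_TREE_CORRECTION
    return stock


@dataclass
class TreeInventory:
    """Measured trees plus the per-species allometric coefficients.

    ``records`` needs columns ``species`` and ``dbh_cm`` (> 0);
    ``coefficients`` is indexed by species with columns ``a`` and ``b``.
    The coefficients are taken in whatever unit system they were fitted in;
    the defaults shipped with the synthetic generator yield tC per tree.
    """

    records: pd.DataFrame
    coefficients: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"species", "dbh_cm"} - set(self.records.columns)
        if missing:
            raise ValueError(f"inventory records lack columns {sorted(missing)}")
        missing = {"a", "b"} - set(self.coefficients.columns)
        if missing:
            raise ValueError(f"coefficient table lacks columns {sorted(missing)}")
        if len(self.records) and (self.records["dbh_cm"] <= 0).any():
            raise ValueError("all DBH values must be > 0")

    def __len__(self) -> int:
        return len(self.records)


def allometric_c_storage(inventory: TreeInventory) -> float:
    """Total tree carbon of an inventory by species-specific allometry.

    Sums ``a_j * DBH_ij ** b_j`` over every measured tree; an empty
    inventory contributes zero.
    """
    if inventory.coefficients.empty:
        raise ValueError("allometric coefficient table is empty")
    if len(inventory.records) == 0:
        return 0.0
    known = set(inventory.coefficients.index)
    present = set(inventory.records["species"])
    unknown = sorted(present - known)
    if unknown:
        raise ValueError(f"no allometric coefficients for species: {unknown}")
    coef = inventory.coefficients.loc[inventory.records["species"]]
    a = coef["a"].to_numpy(dtype=float)
    b = coef["b"].to_numpy(dtype=float)
    dbh = inventory.records["dbh_cm"].to_numpy(dtype=float)
    return float(np.sum(a * dbh**b))


@dataclass
class GppDrivers:
    """Inputs of the light-use-efficiency GPP model (scalars or arrays).

    LUE in umol CO2 / umol PPFD; nPAR and fPAR dimensionless in [0, 1];
    T_air in degC; VPD in kPa; LSWI and its per-grid growing-season
    maximum LSWI_max dimensionless.
    """

    LUE: float | np.ndarray
    nPAR: float | np.ndarray
    fPAR: float | np.ndarray
    T_air: float | np.ndarray
    VPD: float | np.ndarray
    LSWI: float | np.ndarray
    LSWI_max: float | np.ndarray

    def __post_init__(self) -> None:
        for name in ("nPAR", "fPAR"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")


def gpp_lue(d: GppDrivers) -> float | np.ndarray:
    """Gross primary productivity (umol CO2 m^-2 s^-1).

    ``LUE * nPAR * fPAR * (0.382*T_air + 0.0905*VPD + 17.72)
    * (1 + LSWI) / (1 + LSWI_max)``.  The water scalar equals 1 at
    LSWI = LSWI_max; no floor at zero is applied.
    """
    lswi_max = np.asarray(d.LSWI_max, dtype=float)
    if np.any(1.0 + lswi_max == 0.0):
        raise ValueError("1 + LSWI_max must be nonzero")
    t_scalar = _GPP_T_COEF * np.asarray(d.T_air, dtype=float) \
        + _GPP_VPD_COEF * np.asarray(d.VPD, dtype=float) + _GPP_OFFSET
    water = (1.0 + np.asarray(d.LSWI, dtype=float)) / (1.0 + lswi_max)
    out = np.asarray(d.LUE, dtype=float) * np.asarray(d.nPAR, dtype=float) \
        * np.asarray(d.fPAR, dtype=float) * t_scalar * water
    return float(out) if np.isscalar(d.LUE) and out.ndim == 0 else out


@dataclass
class RecoDrivers:
    """Inputs of the ecosystem-respiration model.

    GPP_acc is the GPP accumulated over the preceding 7 days expressed as a
    mean flux (umol CO2 m^-2 s^-1); T_air in degC; T_air_max the maximum
    air temperature of the evaluated period (nonzero).
    """

    GPP_acc: float | np.ndarray
    T_air: float | np.ndarray
    T_air_max: float | np.ndarray


def reco(d: RecoDrivers) -> float | np.ndarray:
    """Ecosystem respiration (umol CO2 m^-2 s^-1).

    ``(1 + 0.20 * GPP_acc) * exp(1.16 * T_air / max(T_air))``; strictly
    increasing in both accumulated productivity and temperature.
    """
    t_max = np.asarray(d.T_air_max, dtype=float)
    if np.any(t_max == 0.0):
        raise ValueError("T_air_max must be nonzero")
    out = (1.0 + _RECO_GPP_COEF * np.asarray(d.GPP_acc, dtype=float)) * np.exp(
        _RECO_T_COEF * np.asarray(d.T_air, dtype=float) / t_max
    )
    return float(out) if out.ndim == 0 else out


def trailing_gpp_acc(gpp_hourly: np.ndarray, window_hours: int = 7 * 24) -> np.ndarray:
    """Mean-preserving trailing accumulation of hourly GPP.

    Returns, for each hour, the mean of the trailing ``window_hours`` values
    (shorter leading windows use whatever history exists), i.e. the
    accumulated GPP expressed as a mean flux in the units of the input.
    """
    s = pd.Series(np.asarray(gpp_hourly, dtype=float))
    return s.rolling(window_hours, min_periods=1).mean().to_numpy()


def annual_nep(
    gpp_series: np.ndarray,
    reco_series: np.ndarray,
    step_seconds: float = 3600.0,
) -> float:
    """Integrate hourly GPP and R_eco fluxes to net uptake in tC ha^-1.

    NEP = sum (GPP - R_eco) * dt, converted from umol CO2 m^-2 s^-1 via
    12 g C per mol CO2 and 10^4 m^2 per hectare.  A constant net flux of
    1 umol m^-2 s^-1 over a 365-day year integrates to 3.78432 tC ha^-1;
    negative totals are net carbon emissions.
    """
    gpp = np.asarray(gpp_series, dtype=float)
    re = np.asarray(reco_series, dtype=float)
    if gpp.shape != re.shape:
        raise ValueError(
            f"GPP and R_eco series lengths differ: {gpp.shape} vs {re.shape}"
        )
    per_step = _TC_HA_PER_UMOL_HOUR * step_seconds / 3600.0
    return float(np.sum(gpp - re) * per_step)
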