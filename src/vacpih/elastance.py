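"""Non-invasive ventriculo-arterial coupling (VAC) indices.

Single-beat estimation of left-ventricular end-systolic elastance (Ees),
effective arterial elastance (Ea) and their ratio Ea/Ees from routine
transthoracic echocardiography plus brachial blood pressure:

    Pes      = 0.9 * SAP
    Ea       = Pes / SV
    End(est) = single-beat normalised elastance at ejection onset
               (Chen et al. group-averaged polynomial in tNd = PEP/TSP,
               corrected for EF and the DAP/Pes pressure ratio)
    Ees      = [DAP - End(est) * Pes] / (End(est) * SV)

The ratio Ea/Ees simplifies algebraically to x / (DAP - x) with
x = End(est) * Pes, so it does not depend on stroke volume.  A ratio
strictly greater than 1 flags ventriculo-arterial uncoupling.

Also provided: stroke volume from LVOT diameter and velocity-time
integral, and diameter-based aortic mechanics (strain, stiffness index,
distensibility).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, NonPhysiologicalElastance, SchemaError

__all__ = [
    "EchoMeasurements",
    "VACIndices",
    "AorticMechanics",
    "compute_ea",
    "compute_end_est",
    "compute_ees",
    "compute_ratio",
    "compute_vac",
    "derive_sv",
    "aortic_mechanics",
    "compute_table",
]

# Single-beat normalised-elastance estimator of Chen et al. (JACC 2001).
# End(avg) is a 7th-order group-averaged polynomial in tNd = PEP/TSP;
# End(est) adds linear corrections in EF (fraction) and DAP/Pes.
# Coefficients transcribed from the original publication.
_END_AVG_COEFFS = (
    0.35695,
    -7.2266,
    74.376,
    -307.39,
    684.54,
    -856.92,
    571.95,
    -159.1,
)
_END_EST_INTERCEPT = 0.0275
_END_EST_EF_SLOPE = -0.165
_END_EST_PRESSURE_SLOPE = 0.3656
_END_EST_AVG_SLOPE = 0.515

# tNd range over which the group-averaged polynomial is trusted; outside
# it the 7th-order fit extrapolates wildly, so tNd is clipped with a warning.
TND_CALIBRATION_RANGE = (0.05, 0.60)

MMHG_TO_DYN_CM2 = 1333.22

PES_FACTOR = 0.9  # end-systolic pressure proxy: Pes = 0.9 * SAP


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise DomainError(f"{name} must be > 0, got {value!r}")


def compute_ea(sap: float, sv: float) -> float:
    """Effective arterial elastance Ea = 0.9 * SAP / SV [mmHg/ml]."""
    _require_positive("sap", sap)
    _require_positive("sv", sv)
    return PES_FACTOR * sap / sv


def compute_end_est(
    ef: float, pep: float, tsp: float, sap: float, dap: float
) -> float:
    """Estimated normalised ventricular elastance at ejection onset.

    Parameters
    ----------
    ef : ejection fraction as a fraction in (0, 1)
    pep, tsp : pre-ejection period and total systolic period, ms
    sap, dap : systolic / diastolic arterial pressure, mmHg

    Returns a dimensionless value in (0, 1).  tNd = pep/tsp outside the
    calibration range of the group-averaged polynomial is clipped with a
    warning; an End(est) outside (0, 1) is likewise clipped.
    """
    if not 0 < ef < 1:
        raise DomainError(f"ef must be a fraction in (0,1), got {ef!r}")
    _require_positive("pep", pep)
    if not pep < tsp:
        raise DomainError(f"pep must be < tsp, got pep={pep!r}, tsp={tsp!r}")
    if not sap > dap > 0:
        raise DomainError(f"require sap > dap > 0, got sap={sap!r}, dap={dap!r}")

    tnd = pep / tsp
    lo, hi = TND_CALIBRATION_RANGE
    if not lo <= tnd <= hi:
        warnings.warn(
            f"tNd={tnd:.3f} outside calibration range [{lo}, {hi}]; clipping",
            stacklevel=2,
        )
        tnd = min(max(tnd, lo), hi)

    end_avg = 0.0
    for k, c in enumerate(_END_AVG_COEFFS):
        end_avg += c * tnd**k
    pes = PES_FACTOR * sap
    end_est = (
        _END_EST_INTERCEPT
        + _END_EST_EF_SLOPE * ef
        + _END_EST_PRESSURE_SLOPE * (dap / pes)
        + _END_EST_AVG_SLOPE * end_avg
    )
    if not 0.0 < end_est < 1.0:
        warnings.warn(
            f"End(est)={end_est:.4f} outside (0,1); clipping", stacklevel=2
        )
        end_est = min(max(end_est, 1e-6), 1.0 - 1e-6)
    return end_est


def compute_ees(dap: float, sap: float, sv: float, end_est: float) -> float:
    """Single-beat end-systolic elastance [mmHg/ml].

    Ees = [DAP - End(est) * 0.9 * SAP] / (End(est) * SV).
    Raises when the numerator would be non-positive (Ees <= 0 is not a
    physiological elastance).
    """
    if not sap > dap > 0:
        raise DomainError(f"require sap > dap > 0, got sap={sap!r}, dap={dap!r}")
    _require_positive("sv", sv)
    if not 0 < end_est < 1:
        raise DomainError(f"end_est must be in (0,1), got {end_est!r}")
    x = end_est * (PES_FACTOR * sap)
    if dap <= x:
        raise NonPhysiologicalElastance(
            f"non-physiological elastance: dap={dap} <= End(est)*0.9*SAP={x:.4g}"
        )
    return (dap - x) / (end_est * sv)


def compute_ratio(
    sap: float, dap: float, sv: float, end_est: float
) -> tuple[float, bool]:
    """Ea/Ees ratio and the uncoupling flag (strictly ratio > 1).

    Computed through the cancellation identity x / (DAP - x) with
    x = End(est) * Pes, which equals Ea / Ees algebraically but is
    bit-identical across stroke volumes.
    """
    compute_ea(sap, sv)
    compute_ees(dap, sap, sv, end_est)  # validation + error propagation
    x = end_est * (PES_FACTOR * sap)
    ratio = x / (dap - x)
    return ratio, ratio > 1.0


def derive_sv(lvot_diameter: float, vti: float) -> float:
    """Stroke volume [ml] from LVOT diameter [cm] and VTI [cm]."""
    _require_positive("lvot_diameter", lvot_diameter)
    _require_positive("vti", vti)
    return math.pi * (lvot_diameter / 2.0) ** 2 * vti


@dataclass(frozen=True)
class EchoMeasurements:
    """Haemodynamic / echocardiographic primitives for one patient.

    Stroke volume may be given directly (``sv``) or via ``lvot_diameter``
    and ``vti``; a direct value takes precedence, and a > 20% mismatch
    between the two routes is reported as a warning.
    """

    sap: float  # systolic arterial pressure, mmHg
    dap: float  # diastolic arterial pressure, mmHg
    ef: float  # ejection fraction, fraction in (0,1)
    pep: float  # pre-ejection period, ms
    tsp: float  # total systolic period, ms
    sv: float | None = None  # stroke volume, ml
    lvot_diameter: float | None = None  # cm
    vti: float | None = None  # cm
    aos: float | None = None  # aortic systolic diameter, cm
    aod: float | None = None  # aortic diastolic diameter, cm

    def __post_init__(self):
        if not self.sap > self.dap > 0:
            raise DomainError(
                f"require sap > dap > 0, got sap={self.sap!r}, dap={self.dap!r}"
            )
        if not 0 < self.ef < 1:
            raise DomainError(f"ef must be in (0,1), got {self.ef!r}")
        if not 0 < self.pep < self.tsp:
            raise DomainError(
                f"require 0 < pep < tsp, got pep={self.pep!r}, tsp={self.tsp!r}"
            )
        if self.sv is None and (self.lvot_diameter is None or self.vti is None):
            raise DomainError("provide sv, or both lvot_diameter and vti")
        if self.sv is not None:
            _require_positive("sv", self.sv)
        if self.aos is not None or self.aod is not None:
            if self.aos is None or self.aod is None:
                raise DomainError("aos and aod must be provided together")
            if not self.aos >= self.aod > 0:
                raise DomainError(
                    f"require aos >= aod > 0, got aos={self.aos!r}, aod={self.aod!r}"
                )

    @property
    def stroke_volume(self) -> float:
        """Resolved stroke volume, ml (direct value wins over LVOT*VTI)."""
        if self.sv is not None:
            if self.lvot_diameter is not None and self.vti is not None:
                derived = derive_sv(self.lvot_diameter, self.vti)
                if abs(derived - self.sv) / self.sv > 0.20:
                    warnings.warn(
                        f"direct SV {self.sv:.1f} ml and LVOT*VTI SV "
                        f"{derived:.1f} ml differ by more than 20%",
                        stacklevel=2,
                    )
            return self.sv
        return derive_sv(self.lvot_diameter, self.vti)


@dataclass(frozen=True)
class VACIndices:
    """Derived coupling indices for one patient."""

    pes: float  # end-systolic pressure, mmHg
    end_est: float  # normalised elastance at ejection onset
    ea: float  # mmHg/ml
    ees: float  # mmHg/ml
    ratio: float  # Ea/Ees
    uncoupled: bool  # ratio > 1 (strict)


@dataclass(frozen=True)
class AorticMechanics:
    """Diameter-based aortic mechanical properties."""

    strain: float  # %
    stiffness_index: float  # dimensionless
    distensibility: float  # cm^2/dyn x 10^-6


def compute_vac(echo: EchoMeasurements) -> VACIndices:
    """All coupling indices for one set of measurements."""
    sv = echo.stroke_volume
    end_est = compute_end_est(echo.ef, echo.pep, echo.tsp, echo.sap, echo.dap)
    ea = compute_ea(echo.sap, sv)
    ees = compute_ees(echo.dap, echo.sap, sv, end_est)
    x = end_est * (PES_FACTOR * echo.sap)
    ratio = x / (echo.dap - x)  # = Ea/Ees, SV-free form
    return VACIndices(
        pes=PES_FACTOR * echo.sap,
        end_est=end_est,
        ea=ea,
        ees=ees,
        ratio=ratio,
        uncoupled=ratio > 1.0,
    )


def aortic_mechanics(
    aos: float, aod: float, sap: float, dap: float
) -> AorticMechanics:
    """Aortic strain, stiffness index and distensibility from diameters.

    strain%        = 100 * (AoS - AoD) / AoD
    stiffness      = ln(SAP/DAP) / [(AoS - AoD)/AoD]
    distensibility = 2 * (AoS - AoD) / (AoD * PP), PP in dyn/cm^2,
                     reported in units of cm^2/dyn x 10^-6

    A rigid aorta (AoS == AoD) has strain 0, distensibility 0 and an
    infinite stiffness index (returned as ``inf``).
    """
    if not aos >= aod > 0:
        raise DomainError(f"require aos >= aod > 0, got aos={aos!r}, aod={aod!r}")
    if not sap > dap > 0:
        raise DomainError(f"require sap > dap > 0, got sap={sap!r}, dap={dap!r}")
    rel = (aos - aod) / aod
    strain = 100.0 * rel
    if rel == 0.0:
        return AorticMechanics(strain=0.0, stiffness_index=math.inf, distensibility=0.0)
    stiffness = math.log(sap / dap) / rel
    pp_dyn = (sap - dap) * MMHG_TO_DYN_CM2
    distensibility = 2.0 * rel / pp_dyn * 1e6
    return AorticMechanics(
        strain=strain, stiffness_index=stiffness, distensibility=distensibility
    )


_BATCH_REQUIRED = ["sap", "dap", "ef", "pep", "tsp"]
_BATCH_APPENDED = ["pes", "end_est", "ea", "ees", "ea_ees_ratio", "uncoupled"]


def compute_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Batch VAC computation over a measurement table.

    The input needs columns {sap, dap, ef, pep, tsp} and either ``sv`` or
    both ``lvot`` and ``vti``.  Returns a copy with
    {pes, end_est, ea, ees, ea_ees_ratio, uncoupled} appended.
    """
    missing = [c for c in _BATCH_REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    has_sv = "sv" in frame.columns
    has_lvot = "lvot" in frame.columns and "vti" in frame.columns
    if not (has_sv or has_lvot):
        raise SchemaError("need an 'sv' column or both 'lvot' and 'vti'")

    out = frame.copy()
    results = {k: np.empty(len(frame)) for k in _BATCH_APPENDED[:-1]}
    uncoupled = np.empty(len(frame), dtype=bool)
    for i, row in enumerate(frame.itertuples(index=False)):
        kwargs = dict(
            sap=row.sap, dap=row.dap, ef=row.ef, pep=row.pep, tsp=row.tsp
        )
        if has_sv and not pd.isna(getattr(row, "sv")):
            kwargs["sv"] = row.sv
        elif has_lvot:
            kwargs["lvot_diameter"] = row.lvot
            kwargs["vti"] = row.vti
        vac = compute_vac(EchoMeasurements(**kwargs))
        results["pes"][i] = vac.pes
        results["end_est"][i] = vac.end_est
        results["ea"][i] = vac.ea
        results["ees"][i] = vac.ees
        results["ea_ees_ratio"][i] = vac.ratio
        uncoupled[i] = vac.uncoupled
    for k, v in results.items():
        out[k] = v
    out["uncoupled"] = uncoupled
    return out
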