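"""Blood-gas and gas-exchange primitives.

Pure functions linking the quantities a closed-loop oxygen controller and its
virtual patient need to exchange: delivered flow to inspired oxygen fraction
(FiO2), FiO2 to arterial oxygen tension (PaO2) through the alveolar gas
equation and the alveolar-arterial (A-a) gradient, PaO2 to pulse-oximeter
saturation (SpO2) through the Severinghaus approximation of the
oxyhemoglobin dissociation curve, and PaCO2/bicarbonate to pH through
Henderson-Hasselbalch.

All pressures are mmHg, saturations are percent (0-100), FiO2 is a fraction
(0.21-1.0), flow is L/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from scipy.optimize import bisect

__all__ = [
    "BloodGas",
    "Phenotype",
    "NotInRespiratoryFailure",
    "aa_gradient",
    "pao2_from_alveolar",
    "spo2_from_pao2",
    "pao2_from_spo2",
    "fio2_from_flow",
    "ph_from_paco2",
    "classify_arf",
]

# Alveolar O2 tension at sea level: FiO2 * (P_B - P_H2O) with P_B = 760 and
# P_H2O = 47 mmHg, i.e. 713 * FiO2; CO2 term uses R = 0.8 (1/R = 1.25).
_PIO2_COEF = 713.0
_PACO2_COEF = 1.25

#: Minimum arterial oxygen tension returned by :func:`pao2_from_alveolar`.
PAO2_FLOOR = 1.0

#: Default linear FiO2 gain of a nasal cannula, fraction per L/min.
CANNULA_FIO2_PER_LPM = 0.03
#: Default FiO2 ceiling achievable through a nasal cannula.
CANNULA_FIO2_CAP = 0.90

ROOM_AIR_FIO2 = 0.21

#: PaCO2 above which respiratory failure is classed as hypercapnic, mmHg.
HYPERCAPNIA_PACO2 = 45.0
#: Room-air PaO2 below which respiratory failure is classed as hypoxemic, mmHg.
HYPOXEMIA_PAO2 = 60.0


class Phenotype(Enum):
    """Acute-respiratory-failure phenotype.

    ``HYPERCAPNIC``: PaCO2 > 45 mmHg on room air (regardless of PaO2).
    ``PURELY_HYPOXEMIC``: PaO2 < 60 mmHg with normal or low PaCO2.
    """

    HYPERCAPNIC = "hypercapnic"
    PURELY_HYPOXEMIC = "purely_hypoxemic"


class NotInRespiratoryFailure(ValueError):
    """Raised when a room-air blood gas meets neither ARF definition."""


@dataclass(frozen=True)
class BloodGas:
    """One arterial blood-gas snapshot.

    Attributes
    ----------
    pao2 : float
        Arterial oxygen tension, mmHg (> 0).
    paco2 : float
        Arterial carbon-dioxide tension, mmHg (> 0).
    ph : float
        Arterial pH (6.5-8.0).
    spo2 : float
        Oxygen saturation, percent (0-100).
    fio2 : float
        Inspired oxygen fraction at the time of sampling (0.21-1.0).
    """

    pao2: float
    paco2: float
    ph: float
    spo2: float
    fio2: float = ROOM_AIR_FIO2

    def __post_init__(self) -> None:
        if not self.pao2 > 0:
            raise ValueError(f"pao2 must be positive, got {self.pao2}")
        if not self.paco2 > 0:
            raise ValueError(f"paco2 must be positive, got {self.paco2}")
        if not 6.5 < self.ph < 8.0:
            raise ValueError(f"ph out of physiological range: {self.ph}")
        if not 0.0 <= self.spo2 <= 100.0:
            raise ValueError(f"spo2 must be in [0, 100], got {self.spo2}")
        _check_fio2(self.fio2)


def _check_fio2(fio2: float) -> None:
    if not ROOM_AIR_FIO2 <= fio2 <= 1.0:
        raise ValueError(f"fio2 must be in [0.21, 1.0], got {fio2}")


def aa_gradient(fio2: float, paco2: float, pao2: float) -> float:
    """Alveolar-arterial oxygen gradient, mmHg.

    ``P(A-a)O2 = (713 * FiO2 - 1.25 * PaCO2) - PaO2``.  Not clamped: the
    result may be negative for mutually inconsistent inputs.

    Parameters
    ----------
    fio2 : float
        Inspired oxygen fraction, 0.21-1.0.
    paco2, pao2 : float
        Arterial CO2 and O2 tensions, mmHg.  ``paco2`` may be 0 (the pure
        alveolar-oxygen limit); ``pao2`` must be positive.
    """
    _check_fio2(fio2)
    if paco2 < 0:
        raise ValueError(f"paco2 must be nonnegative, got {paco2}")
    if not pao2 > 0:
        raise ValueError(f"pao2 must be positive, got {pao2}")
    return (_PIO2_COEF * fio2 - _PACO2_COEF * paco2) - pao2


def pao2_from_alveolar(fio2: float, paco2: float, aado2: float) -> float:
    """Arterial oxygen tension implied by FiO2, PaCO2 and an A-a gradient.

    Inverts :func:`aa_gradient`; floored at ``PAO2_FLOOR`` (1 mmHg) so that
    extreme configurations cannot produce a nonpositive tension.
    """
    _check_fio2(fio2)
    return max(PAO2_FLOOR, _PIO2_COEF * fio2 - _PACO2_COEF * paco2 - aado2)


def spo2_from_pao2(pao2: float) -> float:
    """Oxyhemoglobin saturation from oxygen tension (Severinghaus 1979).

    ``SpO2 = 100 / (23400 / (PaO2^3 + 150 PaO2) + 1)``; strictly increasing
    with asymptote 100 %.
    """
    if not pao2 > 0:
        raise ValueError(f"pao2 must be positive, got {pao2}")
    return 100.0 / (23400.0 / (pao2**3 + 150.0 * pao2) + 1.0)


_SPO2_INV_LO = 1.0
_SPO2_INV_HI = 700.0


def pao2_from_spo2(spo2: float) -> float:
    """Oxygen tension from saturation: numeric inverse of the dissociation curve.

    Bisection on [1, 700] mmHg to an absolute tolerance of 1e-6 mmHg.
    ``spo2`` must lie in [1, 99.9]; the curve saturates so values at or above
    100 % have no finite preimage.
    """
    if not 1.0 <= spo2 <= 99.9:
        raise ValueError(f"spo2 must be in [1, 99.9], got {spo2}")
    return float(
        bisect(lambda p: spo2_from_pao2(p) - spo2, _SPO2_INV_LO, _SPO2_INV_HI, xtol=1e-6)
    )


def fio2_from_flow(
    flow: float,
    coef: float = CANNULA_FIO2_PER_LPM,
    cap: float = CANNULA_FIO2_CAP,
) -> float:
    """Inspired oxygen fraction delivered by a nasal cannula at ``flow`` L/min.

    Linear model: room air (0.21) plus ``coef`` per L/min, saturating at
    ``cap``.  The default 3 % per L/min is the usual bedside rule of thumb;
    the cap reflects entrainment limits of open interfaces.
    """
    if flow < 0:
        raise ValueError(f"flow must be nonnegative, got {flow}")
    return min(ROOM_AIR_FIO2 + coef * flow, cap)


def ph_from_paco2(paco2: float, hco3: float) -> float:
    """Arterial pH from the bicarbonate buffer (Henderson-Hasselbalch).

    ``pH = 6.1 + log10(HCO3 / (0.03 * PaCO2))`` with ``hco3`` in mmol/L.
    """
    if not paco2 > 0:
        raise ValueError(f"paco2 must be positive, got {paco2}")
    if not hco3 > 0:
        raise ValueError(f"hco3 must be positive, got {hco3}")
    return 6.1 + math.log10(hco3 / (0.03 * paco2))


def hco3_from_ph(paco2: float, ph: float) -> float:
    """Bicarbonate consistent with a measured PaCO2/pH pair, mmol/L."""
    if not paco2 > 0:
        raise ValueError(f"paco2 must be positive, got {paco2}")
    return 0.03 * paco2 * 10.0 ** (ph - 6.1)


def classify_arf(bg: BloodGas) -> Phenotype:
    """Classify a room-air blood gas as hypercapnic or purely hypoxemic ARF.

    Hypercapnia (PaCO2 > 45 mmHg) takes precedence: hypercapnic patients are
    usually also hypoxemic, and the oxygen-titration target band is chosen by
    the hypercapnic risk, not the degree of hypoxemia.  Raises
    :class:`NotInRespiratoryFailure` if neither definition is met, and
    :class:`ValueError` if the gas was not drawn on room air.
    """
    if not math.isclose(bg.fio2, ROOM_AIR_FIO2, abs_tol=1e-9):
        raise ValueError(
            f"classification requires a room-air gas (fio2 0.21), got fio2 {bg.fio2}"
        )
    if bg.paco2 > HYPERCAPNIA_PACO2:
        return Phenotype.HYPERCAPNIC
    if bg.pao2 < HYPOXEMIA_PAO2:
        return Phenotype.PURELY_HYPOXEMIC
    raise NotInRespiratoryFailure(
        f"pao2 {bg.pao2} >= {HYPOXEMIA_PAO2} and paco2 {bg.paco2} <= "
        f"{HYPERCAPNIA_PACO2}: not in respiratory failure"
    )
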