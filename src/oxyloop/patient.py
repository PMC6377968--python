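"""Virtual ARF patients: a minimal forward model of oxygen response.

The study device was evaluated on hospitalized patients with acute
respiratory failure; only cohort summary statistics were published.  This
module supplies a synthetic stand-in: each virtual patient is a gas-exchange
model whose arterial oxygen tension relaxes first-order toward the alveolar
value implied by the delivered flow, with

* a patient-constant baseline A-a gradient (plus transient Poisson-timed
  disturbance steps standing in for coughing, secretions, position changes),
* hypercapnic CO2-retention risk: PaCO2 drifts upward while SpO2 sits above
  a retention threshold (loss of hypoxic drive under hyperoxia) and recovers
  toward baseline symmetrically below it,
* Gaussian pulse-oximeter measurement noise.

The cohort generator draws admission blood gases matching the study
population: 23 patients, 13 hypercapnic / 10 purely hypoxemic, admission
PaO2 52.73 +/- 7.65 mmHg and pooled PaCO2 48.48 +/- 17.33 mmHg on room air.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .physiology import (
    ROOM_AIR_FIO2,
    BloodGas,
    Phenotype,
    aa_gradient,
    classify_arf,
    fio2_from_flow,
    hco3_from_ph,
    pao2_from_alveolar,
    ph_from_paco2,
    spo2_from_pao2,
)

__all__ = [
    "PatientParams",
    "PatientState",
    "VirtualPatient",
    "AdmissionInconsistency",
    "init_from_admission",
    "advance",
    "measure_spo2",
    "generate_cohort",
    "cohort_roster",
]

# Reference dynamics: the conditions under which the controller is evaluated.
DEFAULT_TAU_O2 = 60.0  # s; minutes-scale equilibration of PaO2 after a flow change
DEFAULT_NOISE_SD = 0.5  # % SpO2; modern finger-probe oximeter
DEFAULT_DISTURBANCE_RATE = 2.0  # events/hour
DEFAULT_DISTURBANCE_MAGNITUDE = 15.0  # mmHg added to the A-a gradient
DEFAULT_DISTURBANCE_DURATION = 120.0  # s
DEFAULT_CO2_RETENTION_RATE = 0.5  # mmHg/min per % SpO2 above threshold
DEFAULT_RETENTION_THRESHOLD = 94.0  # % SpO2

# Admission blood-gas distributions for the synthetic cohort (room air).
ADMISSION_PAO2_MEAN = 52.73
ADMISSION_PAO2_SD = 7.65
ADMISSION_PAO2_BOUNDS = (30.0, 59.9)
HYPERCAPNIC_PACO2_MEAN = 55.0
HYPERCAPNIC_PACO2_SD = 8.0
HYPERCAPNIC_PACO2_BOUNDS = (45.1, 90.0)
HYPOXEMIC_PACO2_MEAN = 38.0
HYPOXEMIC_PACO2_SD = 4.0
HYPOXEMIC_PACO2_BOUNDS = (25.0, 45.0)

_NORMAL_HCO3 = 24.0  # mmol/L
# Chronic respiratory acidosis: renal compensation raises bicarbonate by
# roughly 3.5 mmol/L per 10 mmHg of sustained PaCO2 elevation.
_HCO3_COMPENSATION_PER_MMHG = 0.35


class AdmissionInconsistency(ValueError):
    """Admission blood gas fails an internal-consistency check."""


@dataclass(frozen=True)
class PatientParams:
    """Fixed parameters of one virtual patient.

    Attributes
    ----------
    phenotype : Phenotype
        ARF phenotype (sets the retention mechanism on/off and the default
        controller band).
    aado2_base : float
        Baseline alveolar-arterial gradient, mmHg (>= 0).
    paco2_base : float
        Baseline PaCO2 toward which retention recovers, mmHg.
    hco3 : float
        Bicarbonate, mmol/L; held constant over a 4-h session (no metabolic
        compensation dynamics at that time scale).
    tau_o2 : float
        First-order PaO2 equilibration time constant, s.
    co2_retention_rate : float
        PaCO2 drift, mmHg/min per % SpO2 above ``retention_threshold``
        (hypercapnic phenotype only).
    retention_threshold : float
        SpO2 above which retention drift is active, percent.
    noise_sd : float
        Pulse-oximeter measurement noise SD, percent SpO2.
    disturbance_rate : float
        Poisson rate of transient desaturation events, events/hour.
    disturbance_magnitude : float
        A-a gradient increase during a disturbance, mmHg.
    disturbance_duration : float
        Disturbance length, s.
    seed : int
        Per-patient random seed (measurement noise and disturbances).
    """

    phenotype: Phenotype
    aado2_base: float
    paco2_base: float
    hco3: float = _NORMAL_HCO3
    tau_o2: float = DEFAULT_TAU_O2
    co2_retention_rate: float = DEFAULT_CO2_RETENTION_RATE
    retention_threshold: float = DEFAULT_RETENTION_THRESHOLD
    noise_sd: float = DEFAULT_NOISE_SD
    disturbance_rate: float = DEFAULT_DISTURBANCE_RATE
    disturbance_magnitude: float = DEFAULT_DISTURBANCE_MAGNITUDE
    disturbance_duration: float = DEFAULT_DISTURBANCE_DURATION
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau_o2 > 0:
            raise ValueError("tau_o2 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.disturbance_rate < 0:
            raise ValueError("disturbance_rate must be nonnegative")
        if self.aado2_base < 0:
            raise ValueError("aado2_base must be nonnegative")


@dataclass
class PatientState:
    """Instantaneous physiological state.

    ``spo2_true`` is always the dissociation-curve image of ``pao2``;
    ``aado2_now`` is the baseline gradient plus any active disturbance.
    ``disturbance_until`` is the absolute time (s) at which the current
    disturbance ends (-inf when none is active).
    """

    pao2: float
    paco2: float
    spo2_true: float
    aado2_now: float
    t: float = 0.0
    disturbance_until: float = -math.inf


def init_from_admission(
    admission: BloodGas,
    phenotype: Phenotype,
    **overrides,
) -> tuple[PatientParams, PatientState]:
    """Build a virtual patient from a room-air admission blood gas.

    The admission gas pins the baseline: A-a gradient from the alveolar gas
    equation at FiO2 0.21, PaCO2 baseline, and bicarbonate chosen so
    Henderson-Hasselbalch reproduces the admission pH exactly.  Validation
    rejects gases whose SpO2 is more than 2 % off the dissociation curve,
    whose phenotype contradicts the room-air classification, or whose
    implied A-a gradient is negative.
    """
    if not math.isclose(admission.fio2, ROOM_AIR_FIO2, abs_tol=1e-9):
        raise AdmissionInconsistency(
            f"admission gas must be on room air, got fio2 {admission.fio2}"
        )
    curve_spo2 = spo2_from_pao2(admission.pao2)
    if abs(admission.spo2 - curve_spo2) > 2.0:
        raise AdmissionInconsistency(
            f"admission spo2 {admission.spo2:.2f}% is {abs(admission.spo2 - curve_spo2):.2f}% "
            f"from the dissociation-curve value {curve_spo2:.2f}% at pao2 {admission.pao2}"
        )
    observed = classify_arf(admission)
    if observed is not phenotype:
        raise AdmissionInconsistency(
            f"admission gas classifies as {observed.value}, not {phenotype.value} "
            f"(pao2 {admission.pao2}, paco2 {admission.paco2})"
        )
    aado2 = aa_gradient(ROOM_AIR_FIO2, admission.paco2, admission.pao2)
    if aado2 < 0:
        raise AdmissionInconsistency(
            f"admission gas implies a negative A-a gradient ({aado2:.2f} mmHg)"
        )
    kwargs = dict(
        phenotype=phenotype,
        aado2_base=aado2,
        paco2_base=admission.paco2,
        hco3=hco3_from_ph(admission.paco2, admission.ph),
    )
    kwargs.update(overrides)
    params = PatientParams(**kwargs)
    state = PatientState(
        pao2=admission.pao2,
        paco2=admission.paco2,
        spo2_true=curve_spo2,
        aado2_now=params.aado2_base,
        t=0.0,
    )
    return params, state


def advance(
    params: PatientParams,
    st: PatientState,
    flow: float,
    dt: float,
    rng: np.random.Generator,
) -> PatientState:
    """Advance the physiological state by ``dt`` seconds under ``flow`` L/min.

    PaO2 relaxes first-order (time constant ``tau_o2``) toward the alveolar
    target implied by the delivered FiO2, the current PaCO2 and the current
    (possibly disturbed) A-a gradient.  For the hypercapnic phenotype PaCO2
    drifts up while the pre-step SpO2 exceeds the retention threshold and
    recovers toward baseline at the symmetric rate below it.  Disturbance
    onsets are Poisson with rate ``disturbance_rate``/hour; an onset raises
    the gradient by ``disturbance_magnitude`` for ``disturbance_duration``.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if flow < 0:
        raise ValueError("flow must be nonnegative")

    t_new = st.t + dt
    disturbance_until = st.disturbance_until
    # Disturbance onsets during (t, t+dt]; a new onset restarts the clock.
    if rng.poisson(params.disturbance_rate * dt / 3600.0) > 0:
        disturbance_until = t_new + params.disturbance_duration
    aado2_now = params.aado2_base + (
        params.disturbance_magnitude if t_new <= disturbance_until else 0.0
    )

    # CO2 retention uses the pre-step saturation (the exposure during dt).
    paco2 = st.paco2
    if params.phenotype is Phenotype.HYPERCAPNIC:
        excess = st.spo2_true - params.retention_threshold
        drift = params.co2_retention_rate * abs(excess) * dt / 60.0
        if excess > 0:
            paco2 += drift
        elif paco2 > params.paco2_base:
            paco2 = max(params.paco2_base, paco2 - drift)

    target = pao2_from_alveolar(fio2_from_flow(flow), paco2, aado2_now)
    pao2 = st.pao2 + (target - st.pao2) * (1.0 - math.exp(-dt / params.tau_o2))
    return PatientState(
        pao2=pao2,
        paco2=paco2,
        spo2_true=spo2_from_pao2(pao2),
        aado2_now=aado2_now,
        t=t_new,
        disturbance_until=disturbance_until,
    )


def measure_spo2(
    params: PatientParams, st: PatientState, rng: np.random.Generator
) -> float:
    """One pulse-oximeter reading: true SpO2 plus Gaussian noise, clipped to
    [0, 100].  With ``noise_sd`` 0 the reading equals the true value."""
    return float(np.clip(st.spo2_true + rng.normal(0.0, params.noise_sd), 0.0, 100.0))


@dataclass
class VirtualPatient:
    """A parameter set bound to a state and a private random stream."""

    params: PatientParams
    state: PatientState
    patient_id: str = "P00"

    def fresh(self) -> "VirtualPatient":
        """Copy with the state reset (sessions do not mutate the original)."""
        return VirtualPatient(self.params, replace(self.state), self.patient_id)

    @property
    def admission(self) -> BloodGas:
        return BloodGas(
            pao2=self.state.pao2,
            paco2=self.state.paco2,
            ph=ph_from_paco2(self.state.paco2, self.params.hco3),
            spo2=self.state.spo2_true,
            fio2=ROOM_AIR_FIO2,
        )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_cohort(
    n_hypercapnic: int,
    n_hypoxemic: int,
    seed: int = 0,
    **param_overrides,
) -> list[VirtualPatient]:
    """Draw a synthetic admission cohort on room air.

    PaCO2 is drawn first (truncated normal per phenotype), then PaO2 from a
    truncated normal whose upper bound is additionally capped 1 mmHg below
    the alveolar oxygen tension so every admission gas has a nonnegative A-a
    gradient.  Admission SpO2 is the dissociation-curve image of PaO2, never
    drawn independently.  Each patient receives an independent seed spawned
    from ``seed``; keyword overrides (e.g. ``noise_sd=0``) apply to all
    patients.
    """
    if n_hypercapnic < 0 or n_hypoxemic < 0:
        raise ValueError("patient counts must be nonnegative")
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)
    n = n_hypercapnic + n_hypoxemic
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]

    cohort: list[VirtualPatient] = []
    phenos = [Phenotype.HYPERCAPNIC] * n_hypercapnic + [
        Phenotype.PURELY_HYPOXEMIC
    ] * n_hypoxemic
    for i, pheno in enumerate(phenos):
        if pheno is Phenotype.HYPERCAPNIC:
            paco2 = _truncated_normal(
                rng, HYPERCAPNIC_PACO2_MEAN, HYPERCAPNIC_PACO2_SD, *HYPERCAPNIC_PACO2_BOUNDS
            )
            hco3 = _NORMAL_HCO3 + _HCO3_COMPENSATION_PER_MMHG * (paco2 - 40.0)
        else:
            paco2 = _truncated_normal(
                rng, HYPOXEMIC_PACO2_MEAN, HYPOXEMIC_PACO2_SD, *HYPOXEMIC_PACO2_BOUNDS
            )
            hco3 = _NORMAL_HCO3
        alveolar_po2 = 713.0 * ROOM_AIR_FIO2 - 1.25 * paco2
        lo, hi = ADMISSION_PAO2_BOUNDS
        hi = min(hi, alveolar_po2 - 1.0)
        pao2 = _truncated_normal(rng, ADMISSION_PAO2_MEAN, ADMISSION_PAO2_SD, lo, hi)
        admission = BloodGas(
            pao2=pao2,
            paco2=paco2,
            ph=ph_from_paco2(paco2, hco3),
            spo2=spo2_from_pao2(pao2),
            fio2=ROOM_AIR_FIO2,
        )
        params, state = init_from_admission(
            admission, pheno, seed=child_seeds[i], **param_overrides
        )
        cohort.append(VirtualPatient(params, state, patient_id=f"P{i + 1:02d}"))
    return cohort


_ROSTER_COLUMNS = [
    "id",
    "phenotype",
    "admission_pao2",
    "admission_paco2",
    "admission_ph",
    "admission_spo2",
    "aado2_base",
    "hco3",
    "tau_o2",
    "co2_retention_rate",
    "retention_threshold",
    "noise_sd",
    "disturbance_rate",
    "disturbance_magnitude",
    "disturbance_duration",
    "seed",
]


def cohort_roster(cohort: Iterable[VirtualPatient]) -> pd.DataFrame:
    """Cohort roster table, one row per patient (exportable as CSV)."""
    rows = []
    for vp in cohort:
        p, s = vp.params, vp.state
        rows.append(
            {
                "id": vp.patient_id,
                "phenotype": p.phenotype.value,
                "admission_pao2": s.pao2,
                "admission_paco2": s.paco2,
                "admission_ph": ph_from_paco2(s.paco2, p.hco3),
                "admission_spo2": s.spo2_true,
                "aado2_base": p.aado2_base,
                "hco3": p.hco3,
                "tau_o2": p.tau_o2,
                "co2_retention_rate": p.co2_retention_rate,
                "retention_threshold": p.retention_threshold,
                "noise_sd": p.noise_sd,
                "disturbance_rate": p.disturbance_rate,
                "disturbance_magnitude": p.disturbance_magnitude,
                "disturbance_duration": p.disturbance_duration,
                "seed": p.seed,
            }
        )
    return pd.DataFrame(rows, columns=_ROSTER_COLUMNS)
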