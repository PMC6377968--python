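"""Discrete-time closed-loop session runner.

Reproduces the study protocol in simulation: the controller is applied for
4 hours per patient with one SpO2 reading consumed every 3 seconds, and
arterial blood gases (the reference measurement) are snapshotted at 1 h and
3 h.  Every sample is logged; the record at t=0 is taken before the first
adjustment, so a session of duration D at step dt yields D/dt + 1 records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import patient as vp_mod
from .controller import ControllerConfig, ControllerState, SignalFault, default_config, step
from .patient import VirtualPatient
from .physiology import BloodGas, Phenotype, fio2_from_flow, ph_from_paco2

__all__ = ["SessionResult", "run_session", "run_cohort", "CSV_COLUMNS"]

SESSION_DURATION = 14400.0  # s; the 4-hour study protocol
ABG_TIMES = (3600.0, 10800.0)  # scheduled blood draws at 1 h and 3 h

CSV_COLUMNS = [
    "t_s",
    "spo2_measured",
    "spo2_true",
    "flow_lpm",
    "pao2_mmhg",
    "paco2_mmhg",
    "ph",
    "alarm",
    "in_band",
]


@dataclass
class SessionResult:
    """One patient's logged titration session.

    ``records`` has one row per sample with the columns of ``CSV_COLUMNS``;
    ``abg_1h``/``abg_3h`` are the true physiological state at 3600 s and
    10800 s (a simulated blood draw, not the noisy oximeter value).
    ``n_signal_faults`` counts out-of-range oximeter readings that were
    logged with flow held.
    """

    patient_id: str
    phenotype: Phenotype | None
    config: ControllerConfig | None
    records: pd.DataFrame
    abg_1h: BloodGas | None
    abg_3h: BloodGas | None
    n_signal_faults: int = 0

    @property
    def sample_period(self) -> float:
        t = self.records["t_s"].to_numpy()
        return float(t[1] - t[0]) if len(t) > 1 else 1.0

    def to_csv(self, path) -> None:
        """Write the record table as CSV with the canonical header."""
        self.records.to_csv(path, index=False, columns=CSV_COLUMNS)

    @classmethod
    def from_csv(
        cls,
        path,
        patient_id: str = "",
        phenotype: Phenotype | None = None,
        config: ControllerConfig | None = None,
    ) -> "SessionResult":
        """Load a session log; ABG snapshots are recovered from the true-state
        columns at the scheduled draw times when those rows are present."""
        records = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"{path}: missing session columns {missing}")
        abgs = {}
        for t_abg in ABG_TIMES:
            row = records.loc[records["t_s"] == t_abg]
            if len(row):
                r = row.iloc[0]
                abgs[t_abg] = BloodGas(
                    pao2=float(r["pao2_mmhg"]),
                    paco2=float(r["paco2_mmhg"]),
                    ph=float(r["ph"]),
                    spo2=float(r["spo2_true"]),
                    fio2=fio2_from_flow(float(r["flow_lpm"])),
                )
        return cls(
            patient_id=patient_id,
            phenotype=phenotype,
            config=config,
            records=records,
            abg_1h=abgs.get(ABG_TIMES[0]),
            abg_3h=abgs.get(ABG_TIMES[1]),
        )


def run_session(
    vp: VirtualPatient,
    cfg: ControllerConfig | None = None,
    duration: float = SESSION_DURATION,
    dt: float | None = None,
    rng: np.random.Generator | None = None,
    log=None,
) -> SessionResult:
    """Run one closed-loop titration session.

    Per sample: draw an oximeter reading, log the record (the flow column is
    the flow being delivered at that instant, i.e. before this sample's
    adjustment), let the controller adjust, then advance the patient by
    ``dt``.  ``dt`` defaults to the controller sample period; ``duration``
    must be a multiple of it.  The random stream defaults to one seeded from
    the patient's own seed, so results are reproducible per patient and
    independent of cohort ordering.  Signal faults (readings outside
    [0, 100] %) hold the flow and are counted, not raised.
    """
    cfg = cfg if cfg is not None else default_config(vp.params.phenotype)
    dt = dt if dt is not None else cfg.sample_period
    n_steps = duration / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"duration {duration} is not a multiple of dt {dt}")
    n_steps = round(n_steps)
    rng = rng if rng is not None else np.random.default_rng(vp.params.seed)

    params = vp.params
    state = replace(vp.state)
    ctrl = ControllerState(flow=cfg.flow_min)
    n_samples = n_steps + 1
    t_arr = np.empty(n_samples)
    meas_arr = np.empty(n_samples)
    true_arr = np.empty(n_samples)
    flow_arr = np.empty(n_samples)
    pao2_arr = np.empty(n_samples)
    paco2_arr = np.empty(n_samples)
    ph_arr = np.empty(n_samples)
    alarm_arr = np.zeros(n_samples, dtype=int)
    inband_arr = np.zeros(n_samples, dtype=int)
    abgs: dict[float, BloodGas] = {}
    n_faults = 0

    for k in range(n_samples):
        t = k * dt
        measured = vp_mod.measure_spo2(params, state, rng)
        t_arr[k] = t
        meas_arr[k] = measured
        true_arr[k] = state.spo2_true
        flow_arr[k] = ctrl.flow
        pao2_arr[k] = state.pao2
        paco2_arr[k] = state.paco2
        ph_arr[k] = ph_from_paco2(state.paco2, params.hco3)
        alarm_arr[k] = int(measured <= cfg.alarm_low or measured >= cfg.alarm_high)
        inband_arr[k] = int(cfg.target_low <= measured <= cfg.target_high)
        try:
            ctrl = step(cfg, ctrl, measured, t)
        except SignalFault as exc:
            n_faults += 1
            if log is not None:
                print(f"[{vp.patient_id}] signal fault: {exc}", file=log)
        if t in ABG_TIMES:
            abgs[t] = BloodGas(
                pao2=state.pao2,
                paco2=state.paco2,
                ph=ph_arr[k],
                spo2=state.spo2_true,
                fio2=fio2_from_flow(ctrl.flow),
            )
        if k < n_steps:
            state = vp_mod.advance(params, state, ctrl.flow, dt, rng)

    records = pd.DataFrame(
        {
            "t_s": t_arr,
            "spo2_measured": meas_arr,
            "spo2_true": true_arr,
            "flow_lpm": flow_arr,
            "pao2_mmhg": pao2_arr,
            "paco2_mmhg": paco2_arr,
            "ph": ph_arr,
            "alarm": alarm_arr,
            "in_band": inband_arr,
        },
        columns=CSV_COLUMNS,
    )
    return SessionResult(
        patient_id=vp.patient_id,
        phenotype=params.phenotype,
        config=cfg,
        records=records,
        abg_1h=abgs.get(ABG_TIMES[0]),
        abg_3h=abgs.get(ABG_TIMES[1]),
        n_signal_faults=n_faults,
    )


def run_cohort(
    cohort: Iterable[VirtualPatient],
    configs: Mapping[Phenotype, ControllerConfig] | None = None,
    duration: float = SESSION_DURATION,
    seed: int | None = None,
    log=None,
) -> list[SessionResult]:
    """Run a session for every patient in the cohort.

    Each patient gets the default configuration of its phenotype unless
    ``configs`` overrides it.  When ``seed`` is given, each patient's random
    stream is derived from (``seed``, patient seed), so permuting the cohort
    never changes an individual trajectory; otherwise the patients' own
    seeds are used directly.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must be nonempty")
    configs = configs or {}
    results = []
    for vp in cohort:
        cfg = configs.get(vp.params.phenotype) or default_config(vp.params.phenotype)
        if seed is not None:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(seed, vp.params.seed))
            )
        else:
            rng = np.random.default_rng(vp.params.seed)
        if log is not None:
            print(
                f"[{vp.patient_id}] {vp.params.phenotype.value}: "
                f"band [{cfg.target_low:g}, {cfg.target_high:g}], "
                f"duration {duration:g} s",
                file=log,
            )
        results.append(run_session(vp.fresh(), cfg, duration=duration, rng=rng, log=log))
    return results
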