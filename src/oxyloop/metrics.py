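"""Outcome statistics for titration sessions.

Time-in-range is operationalized as the fraction of recorded 3-s oximeter
samples, not interpolated wall-clock time.  The fixed excursion thresholds
(SpO2 >= 93 % and <= 87 %) are reported for both phenotypes even though
they coincide with band edges only for the hypercapnic 88-92 % band.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SessionResult

__all__ = [
    "MetricsReport",
    "CorrelationResult",
    "CorrelationMethod",
    "session_metrics",
    "cohort_metrics",
    "spo2_pao2_correlation",
    "summarize_run",
    "longest_run",
]

HIGH_EXCURSION_SPO2 = 93.0  # % ; fixed reporting threshold
LOW_EXCURSION_SPO2 = 87.0  # %


@dataclass(frozen=True)
class MetricsReport:
    """Per-session time-in-range and excursion statistics.

    Percentages are over recorded samples; ``max_excursion_s`` is the longest
    run of consecutive out-of-band samples times the sampling period.
    """

    pct_in_band: float
    pct_at_or_above_93: float
    pct_at_or_below_87: float
    max_excursion_s: float
    n_samples: int


class CorrelationMethod(Enum):
    PEARSON = "pearson"
    SPEARMAN = "spearman"
    AUTO = "auto"


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation coefficient with its two-sided p-value."""

    r: float
    p: float
    n: int
    method: CorrelationMethod


def longest_run(mask: Sequence[bool] | np.ndarray) -> int:
    """Length of the longest run of consecutive True values."""
    arr = np.asarray(mask, dtype=bool)
    if arr.size == 0:
        return 0
    padded = np.concatenate(([False], arr, [False])).astype(int)
    edges = np.flatnonzero(np.diff(padded))
    if edges.size == 0:
        return 0
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def session_metrics(result: SessionResult) -> MetricsReport:
    """Compute the time-in-range report for one session."""
    rec = result.records
    n = len(rec)
    if n == 0:
        raise ValueError("session has no records")
    measured = rec["spo2_measured"].to_numpy()
    in_band = rec["in_band"].to_numpy().astype(bool)
    return MetricsReport(
        pct_in_band=100.0 * in_band.mean(),
        pct_at_or_above_93=100.0 * (measured >= HIGH_EXCURSION_SPO2).mean(),
        pct_at_or_below_87=100.0 * (measured <= LOW_EXCURSION_SPO2).mean(),
        max_excursion_s=result.sample_period * longest_run(~in_band),
        n_samples=n,
    )


_METRIC_FIELDS = (
    "pct_in_band",
    "pct_at_or_above_93",
    "pct_at_or_below_87",
    "max_excursion_s",
    "n_samples",
)


def cohort_metrics(results: Iterable[SessionResult]) -> pd.DataFrame:
    """Mean and sample SD (n-1) of each session metric per phenotype group.

    Grouping uses the patients' ARF phenotype, not the configured band.
    Groups with a single session report SD as NaN (undefined), never 0.
    Returns a table indexed by phenotype with ``<metric>_mean``/``<metric>_sd``
    columns plus ``n_sessions``.
    """
    results = list(results)
    if not results:
        raise ValueError("no sessions given")
    rows = []
    for res in results:
        if res.phenotype is None:
            raise ValueError(f"session {res.patient_id!r} has no phenotype label")
        m = session_metrics(res)
        rows.append({"phenotype": res.phenotype.value, **m.__dict__})
    df = pd.DataFrame(rows)
    out = {}
    for pheno, grp in df.groupby("phenotype", sort=True):
        row: dict[str, float] = {"n_sessions": len(grp)}
        for f in _METRIC_FIELDS:
            row[f"{f}_mean"] = grp[f].mean()
            row[f"{f}_sd"] = grp[f].std(ddof=1) if len(grp) >= 2 else float("nan")
        out[pheno] = row
    return pd.DataFrame(out).T.rename_axis("phenotype")


def _ks_normal(x: np.ndarray) -> float:
    """Kolmogorov-Smirnov p-value against a normal fitted by moments."""
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0  # degenerate margin: not normal
    return float(stats.kstest((x - x.mean()) / sd, "norm").pvalue)


def spo2_pao2_correlation(
    results: Iterable[SessionResult],
    at_t: float,
    method: CorrelationMethod | str = CorrelationMethod.AUTO,
) -> CorrelationResult:
    """Cross-sectional SpO2-PaO2 correlation at a scheduled sample time.

    Pairs each session's oximeter reading at ``at_t`` seconds with its
    arterial PaO2 at the same instant (the simulated blood draw).  With
    ``method='auto'`` a Kolmogorov-Smirnov normality screen (alpha 0.05) on
    both margins selects Pearson when both pass, Spearman otherwise.
    """
    method = CorrelationMethod(method)
    spo2, pao2 = [], []
    for res in results:
        row = res.records.loc[res.records["t_s"] == at_t]
        if not len(row):
            raise ValueError(
                f"session {res.patient_id!r} has no record at t={at_t} s"
            )
        spo2.append(float(row.iloc[0]["spo2_measured"]))
        pao2.append(float(row.iloc[0]["pao2_mmhg"]))
    x, y = np.asarray(spo2), np.asarray(pao2)
    if len(x) < 3:
        raise ValueError(f"need at least 3 sessions, got {len(x)}")
    if method is CorrelationMethod.AUTO:
        normal = _ks_normal(x) > 0.05 and _ks_normal(y) > 0.05
        method = CorrelationMethod.PEARSON if normal else CorrelationMethod.SPEARMAN
    if method is CorrelationMethod.PEARSON:
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x), method=method)


def summarize_run(results: Iterable[SessionResult]) -> pd.DataFrame:
    """ABG summary table: PaCO2 and pH at the 1-h and 3-h draws.

    Mean, sample SD, min and max per phenotype group and pooled.  Single-
    session groups report SD as NaN.
    """
    results = list(results)
    if not results:
        raise ValueError("no sessions given")
    rows = []
    for res in results:
        for label, abg in (("1h", res.abg_1h), ("3h", res.abg_3h)):
            if abg is None:
                continue
            rows.append(
                {
                    "timepoint": label,
                    "phenotype": res.phenotype.value if res.phenotype else "unknown",
                    "paco2": abg.paco2,
                    "ph": abg.ph,
                }
            )
    if not rows:
        raise ValueError("no ABG snapshots found in the given sessions")
    df = pd.DataFrame(rows)
    groups = [(pheno, grp) for pheno, grp in df.groupby("phenotype", sort=True)]
    groups.append(("pooled", df))
    out_rows = []
    for pheno, grp in groups:
        for tp, sub in grp.groupby("timepoint", sort=True):
            row = {"phenotype": pheno, "timepoint": tp, "n": len(sub)}
            for var in ("paco2", "ph"):
                row[f"{var}_mean"] = sub[var].mean()
                row[f"{var}_sd"] = sub[var].std(ddof=1) if len(sub) >= 2 else float("nan")
                row[f"{var}_min"] = sub[var].min()
                row[f"{var}_max"] = sub[var].max()
            out_rows.append(row)
    return pd.DataFrame(out_rows)
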