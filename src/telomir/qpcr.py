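"""Relative leukocyte telomere length (LTL) from qPCR Ct values.

LTL is expressed as the relative T/S ratio: the abundance of the telomere (T)
amplicon relative to a single-copy reference gene (S, here HBG1), quantified
against a calibrator sample with the Livak relative-quantification rule

    dCt      = Ct_tel - Ct_ref            (per sample)
    ddCt     = dCt_sample - dCt_calibrator
    T/S      = 2 ** (-ddCt)

Replicate Ct values, when provided, are averaged before dCt; a replicate SD
above 0.5 cycles is flagged for QC.  Group comparison (Welch or Student t) and
the LTL-age Pearson correlation used in the downstream analyses live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrSample",
    "TsRatio",
    "ts_ratio",
    "ts_ratios_from_frame",
    "compare_groups",
    "ltl_age_correlation",
]

#: replicate-scatter QC threshold, cycles
REPLICATE_SD_FLAG = 0.5


@dataclass(frozen=True)
class QpcrSample:
    """Ct values for one sample: telomere and single-copy reference amplicons."""

    sample_id: str
    ct_tel: float
    ct_ref: float
    replicate_cts_tel: tuple[float, ...] | None = None
    replicate_cts_ref: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for ct in (self.ct_tel, self.ct_ref):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{self.sample_id}: Ct values must be finite and > 0")

    @classmethod
    def from_replicates(cls, sample_id: str, cts_tel, cts_ref) -> "QpcrSample":
        return cls(
            sample_id=sample_id,
            ct_tel=float(np.mean(cts_tel)),
            ct_ref=float(np.mean(cts_ref)),
            replicate_cts_tel=tuple(cts_tel),
            replicate_cts_ref=tuple(cts_ref),
        )

    @property
    def delta_ct(self) -> float:
        return self.ct_tel - self.ct_ref

    def qc_flags(self) -> list[str]:
        flags = []
        for name, reps in (("tel", self.replicate_cts_tel), ("ref", self.replicate_cts_ref)):
            if reps and len(reps) > 1 and float(np.std(reps, ddof=1)) > REPLICATE_SD_FLAG:
                flags.append(f"{name} replicate SD > {REPLICATE_SD_FLAG} cycles")
        return flags


@dataclass(frozen=True)
class TsRatio:
    sample_id: str
    delta_ct: float
    delta_delta_ct: float
    relative_ts: float
    qc_flags: tuple[str, ...] = field(default=())


def ts_ratio(sample: QpcrSample, calibrator: QpcrSample) -> TsRatio:
    """Relative T/S ratio of ``sample`` against ``calibrator``: 2^(-ddCt)."""
    ddct = sample.delta_ct - calibrator.delta_ct
    return TsRatio(
        sample_id=sample.sample_id,
        delta_ct=sample.delta_ct,
        delta_delta_ct=ddct,
        relative_ts=2.0 ** (-ddct),
        qc_flags=tuple(sample.qc_flags()),
    )


def ts_ratios_from_frame(frame: pd.DataFrame, calibrator_id: str) -> pd.DataFrame:
    """Batch T/S computation from a table with sample_id, ct_tel, ct_ref columns.

    Rows with missing Ct values are kept but flagged (``missing`` column) with
    NaN T/S, rather than aborting the batch.
    """
    need = {"sample_id", "ct_tel", "ct_ref"}
    if not need.issubset(frame.columns):
        raise ValueError(f"qPCR table must have columns {sorted(need)}")
    cal_rows = frame[frame["sample_id"] == calibrator_id]
    if cal_rows.empty:
        raise ValueError(f"calibrator sample {calibrator_id!r} not found")
    cal = QpcrSample(calibrator_id, float(cal_rows.iloc[0]["ct_tel"]), float(cal_rows.iloc[0]["ct_ref"]))
    out = []
    for _, row in frame.iterrows():
        missing = pd.isna(row["ct_tel"]) or pd.isna(row["ct_ref"])
        if missing:
            out.append((row["sample_id"], np.nan, np.nan, np.nan, True))
            continue
        r = ts_ratio(QpcrSample(str(row["sample_id"]), float(row["ct_tel"]), float(row["ct_ref"])), cal)
        out.append((r.sample_id, r.delta_ct, r.delta_delta_ct, r.relative_ts, False))
    return pd.DataFrame(out, columns=["sample_id", "delta_ct", "delta_delta_ct", "relative_ts", "missing"])


def compare_groups(values_a, values_b, method: str = "welch"):
    """Two-sided independent-sample t-test between two groups.

    Returns a dict with t, p, and per-group n/mean/sd.  ``method`` is ``welch``
    (default, unequal variances) or ``student``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if method not in ("welch", "student"):
        raise ValueError("method must be 'welch' or 'student'")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            raise ValueError("t statistic undefined: zero variance in both groups")
    else:
        t, p = stats.ttest_ind(a, b, equal_var=(method == "student"))
        t, p = float(t), float(p)
    return {
        "t": t,
        "p": p,
        "n_a": len(a),
        "n_b": len(b),
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "sd_a": float(np.std(a, ddof=1)),
        "sd_b": float(np.std(b, ddof=1)),
        "method": method,
    }


def ltl_age_correlation(ltl, age) -> tuple[float, float]:
    """Pearson correlation of LTL with age; returns (r, two-sided P)."""
    x = np.asarray(ltl, dtype=float)
    y = np.asarray(age, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
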