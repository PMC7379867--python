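"""TSI computation, stand-onset alignment and quality control.

Raw near-infrared spectroscopy recordings carry oxygenated (HbO2) and
deoxygenated (HHb) hemoglobin concentrations in micromolar. The tissue
saturation index is the oxygenated fraction in percent,
``TSI = 100 * HbO2 / (HbO2 + HHb)``. Every recording is aligned so that
t = 0 s is the stand onset and the analysis window is the closed interval
[-60, +180] s (12,001 samples at 50 Hz); recordings suspected of measurement
error are excluded by a fixed set of rules, each reported with a
machine-readable reason code and the diagnostic number that triggered it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WINDOW = (-60.0, 180.0)

#: QC reason codes, in evaluation-independent canonical order.
REASON_CODES = (
    "MISSING_STAND_MARKER",
    "TSI_BELOW_10",
    "CHROMOPHORE_NEAR_ZERO",
    "TSI_RANGE_OVER_45",
    "FLAT_FIRST_30S",
    "BASELINE_VARIATION_OVER_10",
    "FIT_FACTOR_BELOW_98",
)


class InsufficientSpanError(ValueError):
    """Recording does not cover the requested analysis window."""


@dataclass
class NIRSRecording:
    """Raw per-subject recording with a stand-onset annotation.

    ``time`` must be uniformly sampled; ``stand_onset`` is on the same clock.
    ``fit_factor`` (sensor-agreement percentage) may be a per-sample channel
    or a single per-recording average; ``tsi`` may be supplied directly when
    chromophore channels are unavailable (already-computed TSI input).
    """

    subject_id: str
    time: np.ndarray
    hbo2: np.ndarray | None = None
    hhb: np.ndarray | None = None
    fit_factor: float | np.ndarray | None = None
    stand_onset: float | None = None
    rest_marker: float | None = None
    tsi: np.ndarray | None = None

    @property
    def sampling_rate(self) -> float:
        dt = np.diff(self.time)
        if dt.size == 0 or np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        step = float(np.median(dt))
        if not np.allclose(dt, step, rtol=1e-6, atol=1e-9):
            raise ValueError("time must be uniformly sampled")
        return 1.0 / step


@dataclass
class TSISeries:
    """QC-ready TSI curve on the aligned common grid [-60, +180] s."""

    subject_id: str
    grid: np.ndarray
    values: np.ndarray
    sampling_rate: float = 50.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same length")

    @property
    def n_samples(self) -> int:
        return self.grid.size


@dataclass
class QCReport:
    """Per-subject QC outcome: pass flag, violated rules, backing metrics."""

    subject_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)
    metrics: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion-rule thresholds; defaults are the published values.

    ``relative`` switches the range rules (tsi_range, baseline_variation)
    from percentage points to percent of the pre-stand baseline mean.
    """

    min_tsi: float = 10.0
    chromophore_abs_um: float = 0.1
    chromophore_max_frac: float = 0.25
    max_tsi_range: float = 45.0
    flat_first30_range: float = 0.1
    max_baseline_variation: float = 10.0
    min_fit_factor: float = 98.0
    relative: bool = False
    require_rest_marker: bool = False


def compute_tsi(hbo2: np.ndarray, hhb: np.ndarray) -> np.ndarray:
    """Elementwise tissue saturation index, 100*HbO2/(HbO2+HHb), in percent.

    Samples with a zero denominator are returned as NaN (undefined-sample
    flag) rather than dropped; QC decides the recording's fate.
    """
    hbo2 = np.asarray(hbo2, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    if hbo2.shape != hhb.shape:
        raise ValueError("hbo2 and hhb must have the same length")
    total = hbo2 + hhb
    with np.errstate(divide="ignore", invalid="ignore"):
        tsi = np.where(total != 0.0, 100.0 * hbo2 / total, np.nan)
    return tsi


def _window_slice(rec: NIRSRecording, window: tuple[float, float]) -> slice:
    fs = rec.sampling_rate
    onset = rec.stand_onset
    if onset is None or (isinstance(onset, float) and math.isnan(onset)):
        raise ValueError(f"{rec.subject_id}: no stand-onset marker")
    i0 = int(round((onset - rec.time[0]) * fs))
    lo = i0 + int(round(window[0] * fs))
    hi = i0 + int(round(window[1] * fs))
    if lo < 0 or hi > rec.time.size - 1:
        missing = []
        if lo < 0:
            missing.append(f"[{window[0]:.1f}, {(rec.time[0] - onset):.1f}) s")
        if hi > rec.time.size - 1:
            missing.append(f"({(rec.time[-1] - onset):.1f}, {window[1]:.1f}] s")
        raise InsufficientSpanError(
            f"{rec.subject_id}: recording does not cover the window; "
            f"missing {' and '.join(missing)}"
        )
    return slice(lo, hi + 1)


def align_window(
    rec: NIRSRecording,
    tsi: np.ndarray | None = None,
    window: tuple[float, float] = WINDOW,
) -> TSISeries:
    """Extract the aligned analysis window with t = 0 at stand onset.

    No resampling is performed: the recording's own samples are windowed and
    the grid shifted, so the output has ``(hi - lo) * fs + 1`` samples
    (12,001 for the default window at 50 Hz). Already-aligned input is
    returned unchanged (idempotent).
    """
    if tsi is None:
        tsi = rec.tsi if rec.tsi is not None else compute_tsi(rec.hbo2, rec.hhb)
    tsi = np.asarray(tsi, dtype=float)
    if tsi.shape != rec.time.shape:
        raise ValueError("tsi must align with the recording's time channel")
    sl = _window_slice(rec, window)
    fs = rec.sampling_rate
    n = sl.stop - sl.start
    grid = np.linspace(window[0], window[1], n)
    return TSISeries(
        subject_id=rec.subject_id,
        grid=grid,
        values=tsi[sl].copy(),
        sampling_rate=fs,
    )


def qc_evaluate(
    series: TSISeries,
    rec: NIRSRecording | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Evaluate all exclusion rules on an aligned series; report every violation.

    Rules (defaults, TSI in percentage points): missing stand/rest marker;
    minimum TSI below 10%; |HbO2| or |HHb| below 0.1 uM in over a quarter of
    window samples (or any undefined TSI sample); overall TSI range over 45;
    TSI range below 0.1 over the first 30 s of stand (flatline); pre-stand
    baseline range over 10; average sensor fit factor below 98%.
    """
    th = thresholds
    reasons: list[str] = []
    metrics: dict[str, float] = {}
    v = series.values
    t = series.grid

    has_marker = True
    if rec is not None:
        onset = rec.stand_onset
        if onset is None or (isinstance(onset, float) and math.isnan(onset)):
            has_marker = False
        if th.require_rest_marker and rec.rest_marker is None:
            has_marker = False
    metrics["has_stand_marker"] = float(has_marker)
    if not has_marker:
        reasons.append("MISSING_STAND_MARKER")

    finite = np.isfinite(v)
    vmin = float(np.nanmin(v)) if finite.any() else np.nan
    vmax = float(np.nanmax(v)) if finite.any() else np.nan
    metrics["min_tsi"] = vmin
    if not np.isnan(vmin) and vmin < th.min_tsi:
        reasons.append("TSI_BELOW_10")

    base_mask = t <= 0.0
    base = v[base_mask & finite]
    base_mean = float(base.mean()) if base.size else np.nan
    scale = base_mean / 100.0 if th.relative and base_mean else 1.0

    frac = 0.0
    if rec is not None and rec.hbo2 is not None and rec.hhb is not None and has_marker:
        sl = _window_slice(rec, (t[0], t[-1])) if rec.time.size != v.size else slice(None)
        hbo2, hhb = rec.hbo2[sl], rec.hhb[sl]
        frac = max(
            float(np.mean(np.abs(hbo2) < th.chromophore_abs_um)),
            float(np.mean(np.abs(hhb) < th.chromophore_abs_um)),
        )
    metrics["chromophore_near_zero_frac"] = frac
    n_undefined = int(np.sum(~finite))
    metrics["n_undefined_tsi"] = float(n_undefined)
    if frac > th.chromophore_max_frac or n_undefined > 0:
        reasons.append("CHROMOPHORE_NEAR_ZERO")

    tsi_range = vmax - vmin if finite.any() else np.nan
    metrics["tsi_range"] = tsi_range
    if not np.isnan(tsi_range) and tsi_range > th.max_tsi_range * scale:
        reasons.append("TSI_RANGE_OVER_45")

    first30 = v[(t > 0.0) & (t <= 30.0) & finite]
    r30 = float(first30.max() - first30.min()) if first30.size else np.nan
    metrics["first30_range"] = r30
    if not np.isnan(r30) and r30 < th.flat_first30_range * scale:
        reasons.append("FLAT_FIRST_30S")

    base_range = float(base.max() - base.min()) if base.size else np.nan
    metrics["baseline_range"] = base_range
    if not np.isnan(base_range) and base_range > th.max_baseline_variation * scale:
        reasons.append("BASELINE_VARIATION_OVER_10")

    ff = rec.fit_factor if rec is not None else None
    ff_mean = float(np.mean(ff)) if ff is not None else np.nan
    metrics["fit_factor_mean"] = ff_mean
    if not np.isnan(ff_mean) and ff_mean < th.min_fit_factor:
        reasons.append("FIT_FACTOR_BELOW_98")

    ordered = [r for r in REASON_CODES if r in reasons]
    return QCReport(
        subject_id=series.subject_id,
        passed=not ordered,
        reasons=ordered,
        metrics=metrics,
    )


def preprocess_cohort(
    recordings: list[NIRSRecording],
    thresholds: QCThresholds = QCThresholds(),
    window: tuple[float, float] = WINDOW,
) -> tuple[list[TSISeries], list[QCReport]]:
    """Batch pipeline: TSI, alignment, QC; passing series plus all reports."""
    if not recordings:
        raise ValueError("no recordings supplied")
    series_out: list[TSISeries] = []
    reports: list[QCReport] = []
    for rec in recordings:
        onset = rec.stand_onset
        if onset is None or (isinstance(onset, float) and math.isnan(onset)):
            reports.append(
                QCReport(
                    subject_id=rec.subject_id,
                    passed=False,
                    reasons=["MISSING_STAND_MARKER"],
                    metrics={"has_stand_marker": 0.0},
                )
            )
            continue
        series = align_window(rec, window=window)
        report = qc_evaluate(series, rec, thresholds)
        reports.append(report)
        if report.passed:
            series_out.append(series)
    return series_out, reports


def qc_summary(reports: list[QCReport]) -> pd.DataFrame:
    """Exclusion counts per reason code plus the pass count."""
    rows = [{"reason": "PASSED", "count": sum(r.passed for r in reports)}]
    for code in REASON_CODES:
        rows.append(
            {"reason": code, "count": sum(code in r.reasons for r in reports)}
        )
    return pd.DataFrame(rows)


def reports_to_frame(reports: list[QCReport]) -> pd.DataFrame:
    """One row per subject: pass flag, semicolon-joined reasons, metrics."""
    rows = []
    for r in reports:
        row = {"subject_id": r.subject_id, "passed": r.passed,
               "reasons": ";".join(r.reasons)}
        row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delimited-text input adapters


def read_signal_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format signal table (CSV/TSV autodetected by default)."""
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")


def recordings_from_table(
    df: pd.DataFrame,
    stand_onsets: dict[str, float] | float | None = 0.0,
    fit_factors: dict[str, float] | float | None = None,
) -> list[NIRSRecording]:
    """Build recordings from a long table.

    Accepts either the chromophore layout (``subject_id, time_s, hbo2_um,
    hhb_um``) or the TSI layout (``subject_id, time_s, value``). In the TSI
    layout time is assumed already stand-aligned (t = 0 at onset), hence the
    default ``stand_onsets=0.0``.
    """
    required = {"subject_id", "time_s"}
    if not required <= set(df.columns):
        raise ValueError(f"signal table must contain columns {sorted(required)}")
    chromo = {"hbo2_um", "hhb_um"} <= set(df.columns)
    if not chromo and "value" not in df.columns:
        raise ValueError(
            "signal table needs either hbo2_um/hhb_um or a value column"
        )
    recs = []
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("time_s")
        onset = (
            stand_onsets.get(str(sid)) if isinstance(stand_onsets, dict) else stand_onsets
        )
        ff = fit_factors.get(str(sid)) if isinstance(fit_factors, dict) else fit_factors
        recs.append(
            NIRSRecording(
                subject_id=str(sid),
                time=g["time_s"].to_numpy(dtype=float),
                hbo2=g["hbo2_um"].to_numpy(dtype=float) if chromo else None,
                hhb=g["hhb_um"].to_numpy(dtype=float) if chromo else None,
                tsi=None if chromo else g["value"].to_numpy(dtype=float),
                stand_onset=onset,
                fit_factor=ff,
            )
        )
    return recs
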