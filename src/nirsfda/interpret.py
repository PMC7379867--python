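"""Interpretability devices: 10-s bin averages, bin-score correlations, scree elbow.

Because eigenfunctions live in an abstract function space, components are
easier to read off two simpler artifacts: per-subject means of the *raw*
(pre-smoothing) TSI in consecutive 10-s bins, and the correlation of each
bin column with each component's scores — a loadings-like matrix showing
which regions of the response each component tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fpca import FunctionalPCA
from .preprocess import TSISeries, WINDOW


@dataclass
class BinSummary:
    """Per-subject raw-TSI means over consecutive fixed-width time bins."""

    bin_edges: np.ndarray  # (n_bins + 1,)
    bin_means: np.ndarray  # (n_subjects, n_bins)
    subject_ids: list[str]

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1


@dataclass
class ScoreCorrelationMatrix:
    """Bin-mean x component-score correlations (entries in [-1, 1] or NaN)."""

    values: np.ndarray  # (n_bins, n_retained)
    method: str
    bin_edges: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        mid = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame(
            self.values,
            index=pd.Index(mid, name="bin_center_s"),
            columns=[f"fPC{j + 1}" for j in range(self.values.shape[1])],
        )


def bin_average(
    series: list[TSISeries],
    bin_width: float = 10.0,
    window: tuple[float, float] = WINDOW,
) -> BinSummary:
    """Average each subject's raw TSI over consecutive ``bin_width``-s bins.

    Bins are [edge, edge + width) except the last, which also takes the
    closing sample at the window's right endpoint.
    """
    if not series:
        raise ValueError("empty cohort")
    span = window[1] - window[0]
    n_bins = span / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide the {span}-s window")
    n_bins = int(round(n_bins))
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    grid = series[0].grid
    idx = np.clip(np.floor((grid - window[0]) / bin_width).astype(int), 0, n_bins - 1)
    means = np.empty((len(series), n_bins))
    counts = np.bincount(idx, minlength=n_bins)
    for i, s in enumerate(series):
        if s.grid.shape != grid.shape or not np.allclose(s.grid, grid):
            raise ValueError("all series must share the aligned grid")
        means[i] = np.bincount(idx, weights=s.values, minlength=n_bins) / counts
    return BinSummary(
        bin_edges=edges, bin_means=means, subject_ids=[s.subject_id for s in series]
    )


def score_bin_correlations(
    bins: BinSummary,
    result: FunctionalPCA,
    method: str = "pearson",
) -> ScoreCorrelationMatrix:
    """Correlate every bin-mean column with every retained score column.

    Zero-variance bin columns give NaN entries (undefined correlation) rather
    than an error. Invariant to affine rescaling of scores, so raw scores
    and Z-scores give the same matrix.
    """
    scores = result.scores_[:, : result.n_retained_]
    if bins.bin_means.shape[0] != scores.shape[0]:
        raise ValueError("bin summary and scores cover different subject sets")
    corr_fn = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]
    n_bins, k = bins.n_bins, scores.shape[1]
    out = np.full((n_bins, k), np.nan)
    for b in range(n_bins):
        col = bins.bin_means[:, b]
        if np.ptp(col) == 0:
            continue
        for j in range(k):
            if np.ptp(scores[:, j]) == 0:
                continue
            out[b, j] = corr_fn(col, scores[:, j]).statistic
    return ScoreCorrelationMatrix(values=out, method=method, bin_edges=bins.bin_edges)


def elbow_from_proportions(p: np.ndarray) -> int:
    """Elbow of the cumulative variance curve by maximal chord distance.

    The cumulative proportions are compared against the straight chord
    joining the first and last points of the scree curve; the elbow is the
    component index (1-based) where the curve rises furthest above the
    chord — the point a reader would mark as the visual bend. If the curve
    never leaves the chord (a single dominant mode with a numerically empty
    tail), one component is retained. Ties take the smaller k.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 3:
        raise ValueError("elbow detection needs at least 3 components")
    if np.ptp(p) == 0:
        raise ValueError("degenerate spectrum (all proportions equal): no elbow")
    cum = np.cumsum(p)
    k = np.arange(p.size)
    chord = cum[0] + (cum[-1] - cum[0]) * k / (p.size - 1)
    gap = cum - chord
    if gap.max() <= 1e-12:
        return 1
    return int(np.argmax(gap)) + 1


def scree_elbow(result: FunctionalPCA, method: str = "max_distance") -> int:
    """Automated scree-elbow estimate for component retention.

    The published analyses picked the elbow of the cumulative scree plot
    visually; ``max_distance`` automates that reading (see
    :func:`elbow_from_proportions`). The rule is a convenience only — the
    full scree table remains available for a manual override, which is then
    recorded in provenance.
    """
    if method != "max_distance":
        raise ValueError(f"unknown elbow method: {method}")
    return elbow_from_proportions(result.variance_ratio_)
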