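"""Homotopic synchronization lag from region-level BOLD time series.

The lag between the two members of a homotopic region pair is estimated from
their windowed cross-correlation

    C_ij(tau) = (1 / n_tau) * sum_t s_i(t) * s_j(t + tau)

evaluated at integer temporal shifts tau in [-tau_max, +tau_max] (in TR
steps), where s_i and s_j are the de-meaned, sd-normalized signals and
n_tau = T - |tau| is the number of overlapping samples at shift tau. The
synchronization lag is the shift maximizing C, refined to sub-TR resolution
by parabolic interpolation through the peak and its two neighbours.

Sign convention: ``cross_correlogram(s_i, s_j)`` peaks at +k when s_j is a
delayed copy of s_i (s_i leads). ``homotopic_lags`` passes (right, left), so
a positive signed lag means the right-hemisphere signal leads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import homotopic_pairs, validate_regions
from .exceptions import DegenerateSignalError

__all__ = [
    "standardize",
    "cross_correlogram",
    "peak_lag",
    "homotopic_lags",
    "mean_lag",
    "classify_affected",
    "lag_histogram",
    "BoldMatrix",
    "CrossCorrelogram",
    "HomotopicLagModel",
    "HomotopicLagResults",
]

DEFAULT_TAU_MAX = 10.0  # seconds


@dataclass
class BoldMatrix:
    """Region x time BOLD matrix with its sampling interval (TR, seconds)."""

    values: np.ndarray
    tr_seconds: float
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a regions x timepoints matrix")
        if self.region_ids.shape != (self.values.shape[0],):
            raise ValueError("region_ids must match the number of rows")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD matrix contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def series(self, region_id) -> np.ndarray:
        idx = np.flatnonzero(self.region_ids == region_id)
        if idx.size != 1:
            raise ValueError(f"region {region_id!r} not present exactly once")
        return self.values[idx[0]]


@dataclass
class CrossCorrelogram:
    """Cross-correlation values on a symmetric integer-shift grid."""

    shifts_seconds: np.ndarray
    values: np.ndarray
    n_overlap: np.ndarray
    tr_seconds: float


def standardize(series: np.ndarray) -> np.ndarray:
    """De-mean a series and scale it to unit population (1/T) sd."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    sd = x.std()  # population sd
    if sd == 0:
        raise DegenerateSignalError("constant series has no variance")
    return (x - x.mean()) / sd


def _tau_max_samples(tau_max: float, tr: float) -> int:
    k = int(np.floor(tau_max / tr + 1e-12))
    if k < 1:
        raise ValueError("tau_max must be at least one TR")
    return k


def cross_correlogram(
    s_i: np.ndarray,
    s_j: np.ndarray,
    tr: float,
    tau_max: float = DEFAULT_TAU_MAX,
) -> CrossCorrelogram:
    """Windowed cross-correlation of two signals over shifts of +-tau_max.

    Both signals are standardized over the full series; the value at shift k
    samples is ``sum(s_i[t] * s_j[t+k]) / (T - |k|)``.
    """
    s_i = standardize(s_i)
    s_j = standardize(s_j)
    if s_i.shape != s_j.shape:
        raise ValueError("signals must have equal length")
    T = s_i.size
    kmax = _tau_max_samples(tau_max, tr)
    if T <= 2 * kmax:
        raise ValueError(
            f"need more than {2 * kmax} timepoints for tau_max={tau_max}s at TR={tr}s, got {T}"
        )
    shifts = np.arange(-kmax, kmax + 1)
    values = np.empty(shifts.size)
    n_overlap = T - np.abs(shifts)
    for idx, k in enumerate(shifts):
        if k >= 0:
            prod = s_i[: T - k] * s_j[k:]
        else:
            prod = s_i[-k:] * s_j[: T + k]
        values[idx] = prod.sum() / (T - abs(k))
    return CrossCorrelogram(shifts * float(tr), values, n_overlap, float(tr))


def peak_lag(ccf: CrossCorrelogram) -> tuple[float, float, bool]:
    """Locate the correlogram peak with sub-sample parabolic refinement.

    Returns ``(lag_seconds, peak_correlation, at_boundary)``. The integer
    argmax k* (ties broken toward the smallest |shift|, then toward negative
    shifts) is refined by the vertex of the parabola through k*-1, k*, k*+1:

        delta = (C[k*-1] - C[k*+1]) / (2 * (C[k*-1] - 2*C[k*] + C[k*+1]))

    A peak on the grid boundary is returned unrefined with
    ``at_boundary=True`` so saturated estimates can be excluded downstream.
    """
    c = np.asarray(ccf.values, dtype=float)
    if c.size == 0:
        raise ValueError("empty correlogram")
    if np.allclose(c, c[0]):
        raise DegenerateSignalError("flat correlogram has no peak")
    shifts = ccf.shifts_seconds / ccf.tr_seconds  # integer sample shifts
    cmax = c.max()
    candidates = np.flatnonzero(c >= cmax - 1e-12)
    # ties: smallest |shift| first, negative before positive
    order = sorted(candidates, key=lambda i: (abs(shifts[i]), shifts[i]))
    k_idx = order[0]
    if k_idx == 0 or k_idx == c.size - 1:
        return float(shifts[k_idx] * ccf.tr_seconds), float(c[k_idx]), True
    cm, c0, cp = c[k_idx - 1], c[k_idx], c[k_idx + 1]
    denom = 2.0 * (cm - 2.0 * c0 + cp)
    delta = 0.0 if denom == 0 else (cm - cp) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    lag = (shifts[k_idx] + delta) * ccf.tr_seconds
    peak = c0 - 0.25 * (cm - cp) * delta
    return float(lag), float(max(peak, c0)), False


def homotopic_lags(
    bold: BoldMatrix,
    regions: pd.DataFrame,
    tau_max: float = DEFAULT_TAU_MAX,
) -> pd.DataFrame:
    """Per-pair synchronization lag table.

    One row per homotopic pair, indexed by the right-hemisphere region id
    (``pair_id``), with columns ``lag_seconds`` (signed; positive = right
    hemisphere leads), ``abs_lag_seconds``, ``peak_correlation`` and
    ``boundary_flag``. Pairs with degenerate (constant) signals are flagged
    via ``degenerate=True`` and carry NaN estimates.
    """
    tab = validate_regions(regions)
    pairs = homotopic_pairs(tab)
    if not pairs:
        raise ValueError("region table contains no homotopic pairs")
    rows = []
    for right_id, left_id in pairs:
        s_r = bold.series(right_id)
        s_l = bold.series(left_id)
        try:
            ccf = cross_correlogram(s_r, s_l, bold.tr_seconds, tau_max)
            lag, peak, boundary = peak_lag(ccf)
            rows.append((right_id, lag, abs(lag), peak, boundary, False))
        except DegenerateSignalError:
            rows.append((right_id, np.nan, np.nan, np.nan, False, True))
    out = pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "lag_seconds",
            "abs_lag_seconds",
            "peak_correlation",
            "boundary_flag",
            "degenerate",
        ],
    ).set_index("pair_id", drop=False)
    return out


def mean_lag(table: pd.DataFrame, pair_subset=None) -> float:
    """Mean absolute lag (seconds) over a subset of pairs.

    ``pair_subset=None`` means all pairs. Degenerate pairs are excluded; an
    empty subset after exclusions raises ``ValueError``.
    """
    tab = table
    if pair_subset is not None:
        pair_subset = set(pair_subset)
        tab = tab[tab["pair_id"].isin(pair_subset)]
    tab = tab[~tab["degenerate"]]
    if len(tab) == 0:
        raise ValueError("no usable pairs in subset")
    return float(tab["abs_lag_seconds"].mean())


def classify_affected(regions: pd.DataFrame, subject) -> dict[str, set[int]]:
    """Partition homotopic pairs by whether their subnetwork contains a lesion.

    A subnetwork is *affected* for a subject when at least one of its regions
    is lesioned; every pair in an affected subnetwork is affected, including
    pairs whose own regions are intact. Returns pair-id sets under keys
    ``"affected"``, ``"unaffected"`` and ``"affected_intact"`` (affected
    pairs with both member regions intact).
    """
    tab = validate_regions(regions)
    lesioned = set(subject.lesion_regions)
    affected_nets = set(tab.loc[tab["region_id"].isin(lesioned), "subnetwork"])
    affected, unaffected, intact = set(), set(), set()
    for right_id, left_id in homotopic_pairs(tab):
        net = tab.at[right_id, "subnetwork"]
        if net in affected_nets:
            affected.add(right_id)
            if right_id not in lesioned and left_id not in lesioned:
                intact.add(right_id)
        else:
            unaffected.add(right_id)
    return {"affected": affected, "unaffected": unaffected, "affected_intact": intact}


def lag_histogram(
    lags, bin_width: float = 0.5, drop_zero_bin: bool = False
) -> pd.DataFrame:
    """Counts of lags over half-open bins [k*w, (k+1)*w).

    ``drop_zero_bin`` removes the bin containing lag zero, exposing the tail
    of the distribution. Returns a frame with ``bin_left``, ``bin_right``,
    ``count``; empty input yields an empty frame.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lags = np.asarray(list(lags), dtype=float)
    if lags.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    idx = np.floor(lags / bin_width + 1e-12).astype(int)
    uniq, counts = np.unique(idx, return_counts=True)
    out = pd.DataFrame(
        {
            "bin_left": uniq * bin_width,
            "bin_right": (uniq + 1) * bin_width,
            "count": counts,
        }
    )
    if drop_zero_bin:
        out = out[out["bin_left"] != 0.0].reset_index(drop=True)
    return out


class HomotopicLagModel:
    """Synchronization-lag estimator for one subject's BOLD matrix.

    Parameters
    ----------
    bold : BoldMatrix
        Region x time signals with their TR.
    regions : DataFrame
        Region table defining the homotopic pairing.
    tau_max : float
        Half-width of the shift grid in seconds (default 10 s, rounded down
        to an integer number of TRs).
    """

    def __init__(self, bold: BoldMatrix, regions: pd.DataFrame, tau_max: float = DEFAULT_TAU_MAX):
        self.bold = bold
        self.regions = validate_regions(regions)
        self.tau_max = float(tau_max)

    def fit(self) -> "HomotopicLagResults":
        table = homotopic_lags(self.bold, self.regions, self.tau_max)
        return HomotopicLagResults(self, table)


class HomotopicLagResults:
    """Per-pair lag estimates with convenience summaries."""

    def __init__(self, model: HomotopicLagModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def mean_abs_lag(self) -> float:
        return mean_lag(self.table)

    def mean_over(self, pair_subset) -> float:
        return mean_lag(self.table, pair_subset)

    def histogram(self, bin_width: float = 0.5, drop_zero_bin: bool = False) -> pd.DataFrame:
        ok = self.table[~self.table["degenerate"]]
        return lag_histogram(ok["abs_lag_seconds"], bin_width, drop_zero_bin)

    def plot_histogram(self, ax=None, bin_width: float = 0.5, drop_zero_bin: bool = False):
        """Bar plot of the |lag| distribution (0.5 s bins by default)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.histogram(bin_width, drop_zero_bin)
        ax.bar(h["bin_left"], h["count"], width=bin_width, align="edge",
               edgecolor="black", linewidth=0.5)
        ax.set_xlabel("synchronization lag (s)")
        ax.set_ylabel("pair count")
        return ax

    def summary(self) -> str:
        t = self.table[~self.table["degenerate"]]
        lines = [
            "Homotopic synchronization lag",
            f"  pairs: {len(self.table)} ({int(self.table['degenerate'].sum())} degenerate)",
            f"  mean |lag|: {self.mean_abs_lag:.4f} s",
            f"  max |lag|:  {t['abs_lag_seconds'].max():.4f} s",
            f"  boundary peaks: {int(t['boundary_flag'].sum())}",
        ]
        return "\n".join(lines)
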