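"""Template backfitting, temporal smoothing and per-state temporal statistics.

A :class:`Segmentation` carries one label per sample (``UNASSIGNED`` = -1 for
samples failing the minimum-correlation gate or lying outside the analysis
window), the signed correlation of every sample with every template, and the
GFP trace used for explained-variance weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .clustering import MicrostateSet
from .core import Recording, gfp_series

__all__ = [
    "UNASSIGNED",
    "Segmentation",
    "TemporalStats",
    "normalize_gfp_median",
    "backfit",
    "smooth_labels",
    "enforce_min_segment",
    "temporal_stats",
    "runs_of",
]

UNASSIGNED = -1


@dataclass
class Segmentation:
    """Per-sample state assignment for one recording."""

    labels: np.ndarray  # (n_samples,) int, UNASSIGNED allowed
    corr_matrix: np.ndarray  # (n_samples, k) signed spatial correlation
    gfp_trace: np.ndarray
    sr: float
    polarity_mode: str = "invariant"
    window: Optional[tuple[float, float]] = None  # ms, inclusive
    analyzed: Optional[np.ndarray] = None  # bool mask of samples inside the window
    states: Optional[MicrostateSet] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.corr_matrix = np.atleast_2d(np.asarray(self.corr_matrix, dtype=float))
        self.gfp_trace = np.asarray(self.gfp_trace, dtype=float)
        n = len(self.labels)
        if self.corr_matrix.shape[0] != n or len(self.gfp_trace) != n:
            raise ValueError("labels, corr_matrix and gfp_trace must share length")
        if self.analyzed is None:
            self.analyzed = np.ones(n, dtype=bool)
        else:
            self.analyzed = np.asarray(self.analyzed, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def k(self) -> int:
        return self.corr_matrix.shape[1]

    @property
    def corr(self) -> np.ndarray:
        """Signed correlation with the assigned template; NaN where unassigned."""
        out = np.full(self.n_samples, np.nan)
        mask = self.labels != UNASSIGNED
        out[mask] = self.corr_matrix[np.flatnonzero(mask), self.labels[mask]]
        return out

    def fits(self) -> np.ndarray:
        """Per-sample, per-template fit: squared (invariant) or signed (variant)."""
        if self.polarity_mode == "invariant":
            return self.corr_matrix**2
        return self.corr_matrix

    def copy_with(self, labels: np.ndarray) -> "Segmentation":
        return Segmentation(
            labels=labels.copy(),
            corr_matrix=self.corr_matrix,
            gfp_trace=self.gfp_trace,
            sr=self.sr,
            polarity_mode=self.polarity_mode,
            window=self.window,
            analyzed=self.analyzed,
            states=self.states,
        )


@dataclass
class TemporalStats:
    gev: dict[int, float]
    mean_duration: dict[int, float]  # ms; NaN when no interior run exists
    coverage: dict[int, float]
    occurrence: dict[int, float]  # per second
    unassigned_fraction: float

    def to_dict(self) -> dict:
        def clean(d):
            return {str(k): (None if not np.isfinite(v) else float(v)) for k, v in d.items()}

        return {
            "gev": clean(self.gev),
            "mean_duration_ms": clean(self.mean_duration),
            "coverage": clean(self.coverage),
            "occurrence_per_s": clean(self.occurrence),
            "unassigned_fraction": float(self.unassigned_fraction),
        }


def normalize_gfp_median(rec: Recording) -> Recording:
    """Divide every sample by the median per-sample GFP (output median GFP = 1)."""
    if rec.kind != "continuous":
        raise ValueError("normalize_gfp_median expects continuous data")
    med = float(np.median(gfp_series(rec.data)))
    if med <= 0:
        raise ValueError("median GFP is zero; cannot normalize")
    return rec.copy(data=rec.data / med)


def backfit(
    rec: Recording,
    states: MicrostateSet,
    min_corr: float = 0.50,
    polarity_mode: Optional[str] = None,
    window: Optional[tuple[float, float]] = None,
) -> Segmentation:
    """Label every sample with the best-correlated template, gated by ``min_corr``.

    In invariant mode the winner maximizes \|C\| and the gate applies to \|C\|;
    in variant mode both use the signed correlation. Samples outside ``window``
    (ms, closed interval on the recording's time axis) stay UNASSIGNED.
    """
    if not 0.0 <= min_corr <= 1.0:
        raise ValueError("min_corr must lie in [0, 1]")
    if polarity_mode is None:
        polarity_mode = states.polarity_mode
    if rec.kind != "continuous":
        raise ValueError("backfit expects a continuous (or averaged) recording")
    if rec.n_channels != states.n_channels:
        raise ValueError("channel count mismatch between recording and templates")
    X = rec.data.T  # samples × channels
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    safe = norms > 0
    C = np.zeros((X.shape[0], states.k))
    C[safe] = (Xc[safe] / norms[safe, None]) @ states.maps.T
    C = np.clip(C, -1.0, 1.0)

    analyzed = np.ones(X.shape[0], dtype=bool)
    if window is not None:
        times = rec.times_ms()
        analyzed = (times >= window[0]) & (times <= window[1])
        if not np.any(analyzed):
            raise ValueError("empty backfitting window")

    fit = np.abs(C) if polarity_mode == "invariant" else C
    labels = np.argmax(fit, axis=1)
    win_fit = fit[np.arange(len(labels)), labels]
    labels[win_fit < min_corr] = UNASSIGNED
    labels[~safe] = UNASSIGNED
    labels[~analyzed] = UNASSIGNED
    return Segmentation(
        labels=labels,
        corr_matrix=C,
        gfp_trace=gfp_series(rec.data),
        sr=rec.sr,
        polarity_mode=polarity_mode,
        window=window,
        analyzed=analyzed,
        states=states,
    )


def smooth_labels(
    seg: Segmentation, window_half_size: float = 32.0, besag: float = 10.0, max_passes: int = 100
) -> Segmentation:
    """Besag-penalized iterative relabeling of assigned samples.

    Each assigned sample takes the label minimizing
    ``(1 - fit[t, k]) - (besag / (2*h)) * N[t, k]`` where ``h`` is the window
    half-size in samples and ``N[t, k]`` counts same-label assigned samples
    within ±h. UNASSIGNED samples are frozen and excluded from neighbor
    counts. Iterates to a label fixed point.
    """
    h = int(round(window_half_size * seg.sr / 1000.0))
    if h < 1:
        raise ValueError("window half-size must span at least one sample")
    fits = seg.fits()
    n, k = fits.shape
    labels = seg.labels.copy()
    assigned = labels != UNASSIGNED
    if besag == 0 or not np.any(assigned):
        return seg.copy_with(labels)
    penalty_scale = besag / (2.0 * h)
    for _ in range(max_passes):
        # one-hot neighbor counts via a box filter over assigned labels
        onehot = np.zeros((n, k))
        idx = np.flatnonzero(assigned)
        onehot[idx, labels[idx]] = 1.0
        kernel = np.ones(2 * h + 1)
        counts = np.empty_like(onehot)
        for j in range(k):
            counts[:, j] = np.convolve(onehot[:, j], kernel, mode="same")
        # exclude the sample itself from its own neighbor count
        counts[idx, labels[idx]] -= 1.0
        cost = (1.0 - fits) - penalty_scale * counts
        new_labels = labels.copy()
        new_labels[idx] = np.argmin(cost[idx], axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return seg.copy_with(labels)


def runs_of(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (label, start, stop_exclusive)."""
    runs = []
    n = len(labels)
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            runs.append((int(labels[start]), start, i))
            start = i
    return runs


def enforce_min_segment(seg: Segmentation, min_dur: float = 32.0) -> Segmentation:
    """Split runs shorter than ``min_dur`` ms between their neighbors.

    The first ``floor(len/2)`` samples join the preceding run, the rest join
    the following run; edge runs merge wholly into their single neighbor.
    Shortest runs are fixed first, re-scanning after every fix.
    """
    min_samples = int(np.ceil(min_dur * seg.sr / 1000.0))
    if min_samples < 1:
        raise ValueError("min_dur must cover at least one sample period")
    labels = seg.labels.copy()
    # operate on analyzed samples only; outside-window samples are untouched
    region = np.flatnonzero(seg.analyzed)
    if region.size == 0:
        return seg.copy_with(labels)
    lo, hi = region[0], region[-1] + 1
    sub = labels[lo:hi].copy()
    while True:
        runs = runs_of(sub)
        if len(runs) <= 1:
            break
        short = [
            (stop - start, i)
            for i, (_, start, stop) in enumerate(runs)
            if stop - start < min_samples
        ]
        if not short:
            break
        _, i = min(short)  # shortest first; ties to the earlier run
        _, start, stop = runs[i]
        if i == 0:
            sub[start:stop] = runs[1][0]
        elif i == len(runs) - 1:
            sub[start:stop] = runs[i - 1][0]
        else:
            half = (stop - start) // 2
            sub[start : start + half] = runs[i - 1][0]
            sub[start + half : stop] = runs[i + 1][0]
    labels[lo:hi] = sub
    return seg.copy_with(labels)


def temporal_stats(seg: Segmentation) -> TemporalStats:
    """GEV, coverage, occurrence and mean duration per state.

    GEV for state k sums ``(gfp_t * corr_t)^2`` over samples labeled k
    (correlation recomputed against the final label's template) and divides by
    the analyzed-range GFP energy. Runs touching the analyzed-range edges are
    censored for occurrence and duration but counted in coverage and GEV.
    """
    analyzed = seg.analyzed
    n_analyzed = int(np.count_nonzero(analyzed))
    if n_analyzed == 0:
        raise ValueError("no analyzed samples")
    g = seg.gfp_trace
    denom = float(np.sum(g[analyzed] ** 2))
    region = np.flatnonzero(analyzed)
    lo, hi = region[0], region[-1] + 1
    sub_labels = seg.labels[lo:hi]
    duration_s = n_analyzed / seg.sr

    k = seg.k
    gev = {}
    coverage = {}
    occurrence = {}
    mean_duration = {}
    corr = seg.corr  # vs the (possibly relabeled) assigned template
    runs = runs_of(sub_labels)
    for state in range(k):
        mask = analyzed & (seg.labels == state)
        if denom > 0:
            gev[state] = float(np.sum((g[mask] * corr[mask]) ** 2) / denom)
        else:
            gev[state] = 0.0
        coverage[state] = float(np.count_nonzero(mask) / n_analyzed)
        interior = [
            (stop - start)
            for lab, start, stop in runs
            if lab == state and start > 0 and stop < (hi - lo)
        ]
        occurrence[state] = len(interior) / duration_s
        mean_duration[state] = (
            float(np.mean(interior) * 1000.0 / seg.sr) if interior else float("nan")
        )
    unassigned = float(np.count_nonzero(analyzed & (seg.labels == UNASSIGNED)) / n_analyzed)
    return TemporalStats(
        gev=gev,
        mean_duration=mean_duration,
        coverage=coverage,
        occurrence=occurrence,
        unassigned_fraction=unassigned,
    )


def write_segmentation_tsv(seg: Segmentation, path: str) -> None:
    times = np.arange(seg.n_samples) * 1000.0 / seg.sr
    corr = seg.corr
    with open(path, "w") as fh:
        fh.write("sample\ttime_ms\tlabel\tcorr\tgfp\n")
        for t in range(seg.n_samples):
            c = "" if np.isnan(corr[t]) else f"{corr[t]:.6f}"
            fh.write(
                f"{t}\t{times[t]:.3f}\t{seg.labels[t]}\t{c}\t{seg.gfp_trace[t]:.6f}\n"
            )
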