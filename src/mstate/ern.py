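"""Response-locked averaging and microstate-guided error-related potential scoring.

Epochs span -500..800 ms around the button press with baseline window
[-500, -300] ms. The grand-average difference wave (erroneous no-go minus
correct go) is segmented with polarity-variant clustering; the state whose run
contains t=0 defines the scoring window and (via its negative pole) the
channel region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .backfitting import Segmentation, enforce_min_segment, smooth_labels
from .clustering import MicrostateSet, cluster_with_selection
from .core import Recording, gfp_series

__all__ = [
    "ErpAverage",
    "ErnScore",
    "filter_trials",
    "average_condition",
    "difference_wave",
    "grand_average",
    "segment_grand_average",
    "identify_error_microstate",
    "score_ern",
    "residualize_ern",
    "MIN_TRIALS",
]

BASELINE_MS = (-500.0, -300.0)
MIN_TRIALS = {"go_correct": 21, "nogo_error": 6, "difference": 1}


@dataclass
class ErpAverage:
    """Per-condition, baseline-corrected response-locked average."""

    condition: str
    data: np.ndarray  # (n_channels, n_samples)
    times: np.ndarray  # ms, t=0 at the button press
    n_trials: int
    baseline: tuple[float, float] = BASELINE_MS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape[1] != len(self.times):
            raise ValueError("data/time axis mismatch")

    @property
    def sr(self) -> float:
        return 1000.0 / float(np.median(np.diff(self.times)))

    def baseline_mask(self) -> np.ndarray:
        return (self.times >= self.baseline[0]) & (self.times <= self.baseline[1])


@dataclass
class ErnScore:
    participant: str
    go_mean: float
    nogo_mean: float
    residualized: Optional[float] = None
    window: Optional[tuple[float, float]] = None
    roi: Optional[list[int]] = None


def filter_trials(
    epochs: Recording, rt: np.ndarray, rt_min: float = 100.0, rt_max: float = 2000.0
) -> Recording:
    """Keep trials whose response time lies in the closed interval [rt_min, rt_max] ms."""
    rt = np.asarray(rt, dtype=float)
    if epochs.kind != "epoched":
        raise ValueError("filter_trials expects epoched data")
    if len(rt) != epochs.n_trials:
        raise ValueError("rt length must equal trial count")
    keep = (rt >= rt_min) & (rt <= rt_max)
    return epochs.copy(data=epochs.data[keep])


def average_condition(
    epochs: Recording,
    condition: str,
    baseline: tuple[float, float] = BASELINE_MS,
    min_trials: Optional[int] = None,
) -> ErpAverage:
    """Trial mean followed by per-channel baseline correction.

    Raises when the trial count falls below the condition's quality gate
    (21 correct-go / 6 erroneous-no-go trials).
    """
    if epochs.kind != "epoched":
        raise ValueError("average_condition expects epoched data")
    gate = MIN_TRIALS.get(condition, 1) if min_trials is None else min_trials
    if epochs.n_trials < gate:
        raise ValueError(
            f"condition {condition!r} has {epochs.n_trials} trials; gate is {gate}"
        )
    avg = epochs.data.mean(axis=0)
    times = epochs.times_ms()
    bmask = (times >= baseline[0]) & (times <= baseline[1])
    if not np.any(bmask):
        raise ValueError("baseline window contains no samples")
    avg = avg - avg[:, bmask].mean(axis=1, keepdims=True)
    return ErpAverage(
        condition=condition,
        data=avg,
        times=times,
        n_trials=epochs.n_trials,
        baseline=baseline,
    )


def difference_wave(err: ErpAverage, corr: ErpAverage) -> ErpAverage:
    """Pointwise erroneous-no-go minus correct-go activity."""
    if err.data.shape != corr.data.shape or not np.allclose(err.times, corr.times):
        raise ValueError("averages have mismatching axes")
    return ErpAverage(
        condition="difference",
        data=err.data - corr.data,
        times=err.times.copy(),
        n_trials=min(err.n_trials, corr.n_trials),
        baseline=err.baseline,
    )


def grand_average(waves: Sequence[ErpAverage]) -> ErpAverage:
    """Unweighted mean across participants' averages."""
    if not waves:
        raise ValueError("no averages to combine")
    ref = waves[0]
    for w in waves[1:]:
        if w.data.shape != ref.data.shape or not np.allclose(w.times, ref.times):
            raise ValueError("averages have mismatching axes")
    data = np.mean([w.data for w in waves], axis=0)
    return ErpAverage(
        condition=ref.condition,
        data=data,
        times=ref.times.copy(),
        n_trials=len(waves),
        baseline=ref.baseline,
    )


def segment_grand_average(
    grand: ErpAverage,
    k_range: tuple[int, int] = (1, 20),
    restarts: int = 300,
    seed: Optional[int] = None,
    smooth_half_ms: float = 32.0,
    besag: float = 10.0,
    min_seg_ms: float = 32.0,
) -> tuple[MicrostateSet, Segmentation]:
    """Polarity-variant clustering of every non-baseline timepoint.

    Every analyzed timepoint is labeled sequentially (no correlation gate),
    then the temporal smoothing and small-segment rules are applied.
    """
    analyzed = grand.times > grand.baseline[1]
    maps = grand.data[:, analyzed].T
    res, _profile = cluster_with_selection(
        maps, k_range, polarity_mode="variant", n_restarts=restarts, seed=seed
    )
    states = MicrostateSet(maps=res.states.maps, polarity_mode="variant", level="group")

    X = grand.data.T
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    C = np.zeros((X.shape[0], states.k))
    safe = norms > 0
    C[safe] = (Xc[safe] / norms[safe, None]) @ states.maps.T
    labels = np.argmax(C, axis=1)
    labels[~analyzed] = -1
    seg = Segmentation(
        labels=labels,
        corr_matrix=np.clip(C, -1, 1),
        gfp_trace=gfp_series(grand.data),
        sr=grand.sr,
        polarity_mode="variant",
        window=(float(grand.times[analyzed][0]), float(grand.times[-1])),
        analyzed=analyzed,
        states=states,
    )
    seg = smooth_labels(seg, smooth_half_ms, besag)
    seg = enforce_min_segment(seg, min_seg_ms)
    return states, seg


def identify_error_microstate(
    seg: Segmentation,
    times: np.ndarray,
    roi_sd: float = 1.0,
    tiebreak_window: tuple[float, float] = (-100.0, 150.0),
) -> tuple[int, tuple[float, float], list[int]]:
    """State whose labeled run contains t=0; its extent and negative-pole ROI.

    If several runs touch t=0 (a boundary sample), the run covering the most
    samples inside ``tiebreak_window`` wins. The ROI contains channels whose
    template value lies below the template mean minus ``roi_sd`` SDs.
    """
    times = np.asarray(times, dtype=float)
    zero_idx = int(np.argmin(np.abs(times)))
    from .backfitting import runs_of

    runs = [
        (lab, start, stop)
        for lab, start, stop in runs_of(seg.labels)
        if lab >= 0 and start <= zero_idx < stop
    ]
    if not runs:
        # t=0 may sit exactly on a run boundary; accept runs whose edge touches it
        runs = [
            (lab, start, stop)
            for lab, start, stop in runs_of(seg.labels)
            if lab >= 0 and (start == zero_idx + 1 or stop == zero_idx)
        ]
    if not runs:
        raise ValueError(
            "no labeled run contains t=0; select the error microstate manually "
            "(CLI: --window START,END --roi CH,...)"
        )
    if len(runs) > 1:
        tmask = (times >= tiebreak_window[0]) & (times <= tiebreak_window[1])

        def overlap(run):
            _, start, stop = run
            return int(np.count_nonzero(tmask[start:stop]))

        runs.sort(key=lambda r: (-overlap(r), r[1]))
    lab, start, stop = runs[0]
    window = (float(times[start]), float(times[stop - 1]))
    if seg.states is None:
        raise ValueError("segmentation carries no template maps")
    template = seg.states.maps[lab]
    thresh = template.mean() - roi_sd * template.std()
    roi = np.flatnonzero(template < thresh).tolist()
    if not roi:
        roi = [int(np.argmin(template))]
    return lab, window, roi


def score_ern(
    avg_go: ErpAverage,
    avg_nogo: ErpAverage,
    window: tuple[float, float],
    roi: Sequence[int],
    participant: str = "",
) -> ErnScore:
    """Mean amplitude over the ROI channels and scoring window, per condition."""
    if len(roi) == 0:
        raise ValueError("empty ROI")
    roi = np.asarray(roi, dtype=int)
    for avg in (avg_go, avg_nogo):
        if np.any(roi < 0) or np.any(roi >= avg.data.shape[0]):
            raise ValueError("ROI channel out of range")
        tmask = (avg.times >= window[0]) & (avg.times <= window[1])
        if not np.any(tmask):
            raise ValueError("scoring window contains no samples")
    tmask_go = (avg_go.times >= window[0]) & (avg_go.times <= window[1])
    tmask_ng = (avg_nogo.times >= window[0]) & (avg_nogo.times <= window[1])
    return ErnScore(
        participant=participant,
        go_mean=float(avg_go.data[np.ix_(roi, np.flatnonzero(tmask_go))].mean()),
        nogo_mean=float(avg_nogo.data[np.ix_(roi, np.flatnonzero(tmask_ng))].mean()),
        window=(float(window[0]), float(window[1])),
        roi=roi.tolist(),
    )


def residualize_ern(scores: list[ErnScore]) -> list[ErnScore]:
    """Residual of no-go amplitude regressed on go amplitude (OLS with intercept)."""
    if len(scores) < 3:
        raise ValueError("residualization needs at least 3 participants")
    go = np.array([s.go_mean for s in scores])
    nogo = np.array([s.nogo_mean for s in scores])
    if np.var(go) == 0:
        raise ValueError("zero variance in go scores; cannot residualize")
    X = np.column_stack([np.ones_like(go), go])
    beta, *_ = np.linalg.lstsq(X, nogo, rcond=None)
    resid = nogo - X @ beta
    out = []
    for s, r in zip(scores, resid):
        out.append(
            ErnScore(
                participant=s.participant,
                go_mean=s.go_mean,
                nogo_mean=s.nogo_mean,
                residualized=float(r),
                window=s.window,
                roi=s.roi,
            )
        )
    return out
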