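"""Synthetic EEG with known ground truth for every pipeline stage.

Sensors live on a synthetic unit sphere (Fibonacci lattice). Resting data is a
hidden semi-Markov sequence of template topographies with a slowly drifting
positive amplitude envelope, random per-segment polarity and additive white
sensor noise. Go/no-go epochs share background microstate activity across
conditions, with planted response-locked components (central-negative error
component flanked by pre- and post-response states) added to error trials
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import MicrostateSet
from .core import Recording, build_neighbor_graph

__all__ = [
    "GroundTruth",
    "GoNogoEpochs",
    "sensor_sphere",
    "make_template_maps",
    "simulate_resting",
    "simulate_gonogo",
    "simulate_cohort",
]


@dataclass
class GroundTruth:
    """Planted parameters serialized alongside every generated dataset."""

    seed: int
    true_maps: Optional[np.ndarray] = None
    label_sequence: Optional[np.ndarray] = None
    snr: Optional[float] = None
    dwell_mean_ms: Optional[dict] = None
    coverages: Optional[dict] = None
    ern_amplitude_uv: Optional[float] = None
    ern_window_ms: Optional[tuple[float, float]] = None
    ern_roi: Optional[list[int]] = None
    out_of_range_trials: Optional[dict] = None
    loadings: Optional[dict] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {str(k): conv(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            return v

        return {
            k: conv(v)
            for k, v in self.__dict__.items()
            if v is not None and (not isinstance(v, dict) or v)
        }


def sensor_sphere(n_channels: int) -> np.ndarray:
    """Fibonacci-lattice sensor layout on the unit sphere."""
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / n_channels
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.maximum(1 - z**2, 0))
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pos / np.linalg.norm(pos, axis=1, keepdims=True)


def make_template_maps(
    n_channels: int,
    K: int,
    smoothness: int = 3,
    seed: Optional[int] = None,
    max_pairwise_corr: float = 0.3,
) -> MicrostateSet:
    """K mutually near-orthogonal, spatially smooth, unit-norm zero-mean maps.

    Random channel noise is smoothed over the sensor neighbor graph and then
    symmetrically orthogonalized within the zero-mean subspace, which keeps the
    maps smooth while driving pairwise correlation to zero (well under the
    ``max_pairwise_corr`` contract).
    """
    if K > n_channels - 1:
        raise ValueError("cannot fit K near-orthogonal zero-mean maps: K > n_channels - 1")
    rng = np.random.default_rng(seed)
    pos = sensor_sphere(n_channels)
    graph = build_neighbor_graph(pos, k_neighbors=min(6, n_channels - 1))
    M = rng.standard_normal((K, n_channels))
    idx = np.concatenate([np.arange(n_channels)[:, None], graph.neighbors], axis=1)
    for _ in range(smoothness):
        M = M[:, idx].mean(axis=2)
    M = M - M.mean(axis=1, keepdims=True)
    # symmetric (Loewdin) orthogonalization
    G = M @ M.T
    evals, evecs = np.linalg.eigh(G)
    if np.min(evals) < 1e-10 * np.max(evals):
        raise ValueError("degenerate smooth maps; try another seed or more channels")
    W = evecs @ np.diag(evals**-0.5) @ evecs.T
    M = W @ M
    M = M / np.linalg.norm(M, axis=1, keepdims=True)
    C = np.abs(M @ M.T)
    np.fill_diagonal(C, 0.0)
    if C.max() > max_pairwise_corr:
        raise ValueError("orthogonalization failed to reach the correlation bound")
    return MicrostateSet(maps=M, polarity_mode="invariant")


def _truncnorm_dwell(rng, mean_ms: float, jitter_frac: float, floor_ms: float) -> float:
    sd = max(mean_ms * jitter_frac, 1.0)
    for _ in range(100):
        d = rng.normal(mean_ms, sd)
        if d >= floor_ms:
            return d
    return floor_ms


def _state_sequence(
    rng,
    K: int,
    n_samples: int,
    sr: float,
    mean_dwell_ms: float,
    coverages: Optional[Sequence[float]],
    jitter_frac: float = 0.25,
    floor_ms: float = 40.0,
) -> np.ndarray:
    if coverages is None:
        dwell = np.full(K, mean_dwell_ms)
    else:
        coverages = np.asarray(coverages, dtype=float)
        coverages = coverages / coverages.sum()
        # uniform switching + dwell proportional to coverage -> stationary
        # occupancy proportional to the requested coverage
        dwell = np.maximum(K * coverages * mean_dwell_ms, floor_ms)
    labels = np.empty(n_samples, dtype=int)
    t = 0
    state = int(rng.integers(K))
    while t < n_samples:
        d_ms = _truncnorm_dwell(rng, dwell[state], jitter_frac, floor_ms)
        d = max(int(round(d_ms * sr / 1000.0)), 1)
        labels[t : t + d] = state
        t += d
        if K > 1:
            nxt = int(rng.integers(K - 1))
            state = nxt if nxt < state else nxt + 1
    return labels


def _gfp_envelope(rng, n_samples: int, rho: float = 0.98, scale: float = 0.25) -> np.ndarray:
    z = np.empty(n_samples)
    z[0] = rng.standard_normal()
    eps = rng.standard_normal(n_samples)
    for t in range(1, n_samples):
        z[t] = rho * z[t - 1] + np.sqrt(1 - rho**2) * eps[t]
    return np.exp(scale * z)


def simulate_resting(
    states: MicrostateSet,
    duration_s: float = 157.0,
    sr: float = 250.0,
    mean_dwell_ms: float = 80.0,
    snr: float = 10.0,
    seed: Optional[int] = None,
    coverages: Optional[Sequence[float]] = None,
    amplitude_uv: float = 10.0,
) -> tuple[Recording, GroundTruth]:
    """Hidden-state resting recording with GFP-modulated amplitude and noise.

    ``snr`` is the amplitude ratio of the state signal to the white sensor
    noise; ``np.inf`` yields a noiseless recording.
    """
    if mean_dwell_ms < 40:
        raise ValueError("mean dwell must be at least 40 ms")
    rng = np.random.default_rng(seed)
    K, n_ch = states.k, states.n_channels
    n_samples = int(round(duration_s * sr))
    labels = _state_sequence(rng, K, n_samples, sr, mean_dwell_ms, coverages)
    env = _gfp_envelope(rng, n_samples)
    # random polarity per maximal segment
    pol = np.empty(n_samples)
    start = 0
    for t in range(1, n_samples + 1):
        if t == n_samples or labels[t] != labels[start]:
            pol[start:t] = rng.choice([-1.0, 1.0])
            start = t
    sig = states.maps[labels].T * (amplitude_uv * env * pol)[None, :]
    if np.isfinite(snr):
        noise_sd = amplitude_uv * float(np.mean(env)) / (np.sqrt(n_ch) * snr)
        sig = sig + rng.standard_normal(sig.shape) * noise_sd
    sig = sig - sig.mean(axis=0, keepdims=True)
    rec = Recording(
        data=sig,
        sr=sr,
        channel_positions=sensor_sphere(n_ch),
        kind="continuous",
    )
    gt = GroundTruth(
        seed=-1 if seed is None else int(seed),
        true_maps=states.maps.copy(),
        label_sequence=labels,
        snr=float(snr) if np.isfinite(snr) else None,
        dwell_mean_ms={"global": float(mean_dwell_ms)},
        coverages=(
            {str(i): float(c) for i, c in enumerate(np.asarray(coverages) / np.sum(coverages))}
            if coverages is not None
            else None
        ),
    )
    return rec, gt


@dataclass
class GoNogoEpochs:
    go: Recording
    nogo: Recording

    @property
    def times_ms(self) -> np.ndarray:
        return self.go.times_ms()


def _central_negative_map(n_channels: int, width: float = 0.6) -> np.ndarray:
    """Smooth negative pole at the vertex (the +z sensor), zero-mean."""
    pos = sensor_sphere(n_channels)
    ang = np.arccos(np.clip(pos[:, 2], -1, 1))
    m = -np.exp(-(ang**2) / (2 * width**2))
    return m - m.mean()


def _scaled_component(shape: np.ndarray, target_roi_mean: float, roi_sd: float = 1.0) -> tuple[np.ndarray, list[int]]:
    """Scale a map so its own negative-pole ROI mean equals ``target_roi_mean``."""
    thresh = shape.mean() - roi_sd * shape.std()
    roi = np.flatnonzero(shape < thresh)
    if roi.size == 0:
        roi = np.array([int(np.argmin(shape))])
    scale = target_roi_mean / float(shape[roi].mean())
    return shape * scale, roi.tolist()


def _background(rng, states, n_trials, n_samples, sr, amplitude, snr):
    """Independent microstate background per trial, shared process across conditions."""
    n_ch = states.n_channels
    out = np.empty((n_trials, n_ch, n_samples))
    for t in range(n_trials):
        labels = _state_sequence(rng, states.k, n_samples, sr, 80.0, None)
        env = _gfp_envelope(rng, n_samples)
        pol = rng.choice([-1.0, 1.0], size=n_samples)  # fast polarity scramble
        out[t] = states.maps[labels].T * (amplitude * env)[None, :]
        if np.isfinite(snr):
            noise_sd = amplitude * float(np.mean(env)) / (np.sqrt(n_ch) * snr)
            out[t] += rng.standard_normal((n_ch, n_samples)) * noise_sd
    return out


def simulate_gonogo(
    states: MicrostateSet,
    n_go: int = 120,
    n_nogo: int = 80,
    ern_amplitude_uv: float = -5.0,
    ern_window_ms: tuple[float, float] = (-64.0, 108.0),
    snr: float = 10.0,
    seed: Optional[int] = None,
    sr: float = 250.0,
    epoch_ms: tuple[float, float] = (-500.0, 800.0),
    out_of_range_frac: float = 0.0,
    background_uv: float = 2.0,
) -> tuple[GoNogoEpochs, pd.DataFrame, GroundTruth]:
    """Response-locked go/no-go epochs with a planted error component.

    Error (no-go) trials carry a central-negative boxcar component over
    ``ern_window_ms`` whose mean over its own negative-pole ROI equals
    ``ern_amplitude_uv``, flanked by a pre-response and a post-response
    component so the difference wave segments into crisp states. Reaction
    times are uniform on [300, 900] ms, with ``out_of_range_frac`` of trials
    pushed outside the [100, 2000] ms validity interval.
    """
    if not (epoch_ms[0] <= ern_window_ms[0] < ern_window_ms[1] <= epoch_ms[1]):
        raise ValueError("error-component window must lie inside the epoch")
    rng = np.random.default_rng(seed)
    n_ch = states.n_channels
    n_samples = int(round((epoch_ms[1] - epoch_ms[0]) * sr / 1000.0)) + 1
    time_zero = int(round(-epoch_ms[0] * sr / 1000.0))
    times = (np.arange(n_samples) - time_zero) * 1000.0 / sr

    go = _background(rng, states, n_go, n_samples, sr, background_uv, snr)
    nogo = _background(rng, states, n_nogo, n_samples, sr, background_uv, snr)

    ern_map, roi = _scaled_component(_central_negative_map(n_ch), ern_amplitude_uv)
    # flanking components: a distinct smooth pre-response map and a
    # sign-flipped central map after the error (the positivity following it)
    flank_states = make_template_maps(n_ch, 2, seed=0 if seed is None else seed + 7)
    amp_flank = max(abs(ern_amplitude_uv) * 0.8, 1.0)
    pre_map = flank_states.maps[0] * amp_flank
    post_map = -0.8 * ern_map

    in_ern = (times >= ern_window_ms[0]) & (times <= ern_window_ms[1])
    in_pre = (times >= max(epoch_ms[0] + 200.0, ern_window_ms[0] - 250.0)) & (
        times < ern_window_ms[0]
    )
    in_post = (times > ern_window_ms[1]) & (times <= ern_window_ms[1] + 200.0)
    component = np.zeros((n_ch, n_samples))
    component[:, in_ern] = ern_map[:, None]
    component[:, in_pre] = pre_map[:, None]
    component[:, in_post] = post_map[:, None]
    nogo = nogo + component[None, :, :]

    go -= go.mean(axis=1, keepdims=True)
    nogo -= nogo.mean(axis=1, keepdims=True)

    pos = sensor_sphere(n_ch)
    epochs = GoNogoEpochs(
        go=Recording(data=go, sr=sr, kind="epoched", time_zero=time_zero, channel_positions=pos),
        nogo=Recording(
            data=nogo, sr=sr, kind="epoched", time_zero=time_zero, channel_positions=pos
        ),
    )
    n_total = n_go + n_nogo
    rt = rng.uniform(300.0, 900.0, size=n_total)
    n_bad = int(round(out_of_range_frac * n_total))
    bad_idx = rng.choice(n_total, size=n_bad, replace=False) if n_bad else np.array([], int)
    for i in bad_idx:
        rt[i] = rng.uniform(0, 99.0) if rng.random() < 0.5 else rng.uniform(2001.0, 2500.0)
    cond = np.array(["go"] * n_go + ["nogo"] * n_nogo)
    rt_table = pd.DataFrame({"trial": np.arange(n_total), "condition": cond, "rt_ms": rt})
    gt = GroundTruth(
        seed=-1 if seed is None else int(seed),
        true_maps=states.maps.copy(),
        snr=float(snr) if np.isfinite(snr) else None,
        ern_amplitude_uv=float(ern_amplitude_uv),
        ern_window_ms=(float(ern_window_ms[0]), float(ern_window_ms[1])),
        ern_roi=roi,
        out_of_range_trials={"indices": bad_idx.tolist()},
        extra={"ern_map": ern_map.tolist(), "background_uv": background_uv},
    )
    return epochs, rt_table, gt


def simulate_cohort(
    n_participants: int = 90,
    effect_sizes: Optional[dict] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Participant table with planted couplings through one latent factor.

    ``effect_sizes`` maps a variable name to its loading on a latent
    error-processing strength; the planted correlation between two variables
    is the product of their loadings. Variables with no entry load 0
    (independent). Available variables: ``ern_resid``, ``error_gev``,
    ``rest_gev``, ``effortful_control``, ``pas``, ``bis``.
    """
    if n_participants < 20:
        raise ValueError("cohort needs at least 20 participants")
    rng = np.random.default_rng(seed)
    loadings = {
        "ern_resid": 0.0,
        "error_gev": 0.0,
        "rest_gev": 0.0,
        "effortful_control": 0.0,
        "pas": 0.0,
        "bis": 0.0,
    }
    if effect_sizes:
        for k, v in effect_sizes.items():
            if k not in loadings:
                raise ValueError(f"unknown variable {k!r}")
            if not -1 <= v <= 1:
                raise ValueError("loadings must lie in [-1, 1]")
            loadings[k] = float(v)
    u = rng.standard_normal(n_participants)
    cols = {}
    for name, lam in loadings.items():
        eps = rng.standard_normal(n_participants)
        cols[name] = lam * u + np.sqrt(max(1 - lam**2, 0.0)) * eps
    table = pd.DataFrame(
        {
            "id": [f"P{i:03d}" for i in range(n_participants)],
            "age": rng.uniform(4.5, 9.0, size=n_participants),
            "sex": rng.integers(0, 2, size=n_participants),
            **cols,
        }
    )
    gt = GroundTruth(
        seed=-1 if seed is None else int(seed),
        loadings=loadings,
        extra={"latent": u.tolist()},
    )
    return table, gt
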