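"""Core scalp-topography representations and sample-level operations.

All potentials are in microvolts. Continuous recordings are stored as a
``(n_channels, n_samples)`` matrix, epoched recordings as
``(n_trials, n_channels, n_samples)``. Sample indices are 0-based; epoch time
axes are in milliseconds with t=0 at the response event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "Topography",
    "Recording",
    "NeighborGraph",
    "average_reference",
    "gfp",
    "gfp_series",
    "build_neighbor_graph",
    "spatial_filter",
    "extract_gfp_peaks",
    "reject_epochs",
    "trim_continuous",
]


@dataclass
class Topography:
    """One instantaneous scalp potential map.

    Parameters
    ----------
    values : ndarray, shape (n_channels,)
        Per-channel potential in microvolts.
    referenced : bool
        True when the values are average-referenced (zero mean).
    """

    values: np.ndarray
    referenced: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Topography values must be a 1-D vector")
        if self.referenced:
            scale = max(float(np.max(np.abs(self.values))), 1.0)
            if abs(float(np.mean(self.values))) >= 1e-9 * scale:
                raise ValueError("referenced=True but values are not zero-mean")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class Recording:
    """A continuous or epoched multichannel EEG recording."""

    data: np.ndarray
    sr: float = 250.0
    channel_names: Optional[Sequence[str]] = None
    channel_positions: Optional[np.ndarray] = None
    kind: str = "continuous"
    time_zero: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sr <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.kind == "continuous":
            if self.data.ndim != 2:
                raise ValueError("continuous data must be (channels, samples)")
        elif self.kind == "epoched":
            if self.data.ndim != 3:
                raise ValueError("epoched data must be (trials, channels, samples)")
        else:
            raise ValueError(f"unknown recording kind {self.kind!r}")
        if self.channel_positions is not None:
            pos = np.asarray(self.channel_positions, dtype=float)
            if pos.shape != (self.n_channels, 3):
                raise ValueError("channel_positions must be (n_channels, 3)")
            norms = np.linalg.norm(pos, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("channel positions must lie on the unit sphere")
            self.channel_positions = pos
        if self.channel_names is not None:
            self.channel_names = list(self.channel_names)
            if len(self.channel_names) != self.n_channels:
                raise ValueError("channel_names length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0] if self.kind == "continuous" else self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def n_trials(self) -> int:
        if self.kind != "epoched":
            raise ValueError("n_trials is defined for epoched recordings only")
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sr

    def times_ms(self) -> np.ndarray:
        """Time axis in ms; for epoched data t=0 sits at ``time_zero``."""
        idx = np.arange(self.n_samples, dtype=float)
        zero = self.time_zero if (self.kind == "epoched" and self.time_zero is not None) else 0
        return (idx - zero) * 1000.0 / self.sr

    def copy(self, **changes) -> "Recording":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out


@dataclass
class NeighborGraph:
    """Per-channel nearest neighbors by great-circle distance on the sensor sphere."""

    neighbors: np.ndarray  # (n_channels, k_neighbors) integer indices
    k_neighbors: int = 6

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=int)
        if self.neighbors.ndim != 2 or self.neighbors.shape[1] != self.k_neighbors:
            raise ValueError("neighbors must be (n_channels, k_neighbors)")
        rows = np.arange(self.neighbors.shape[0])[:, None]
        if np.any(self.neighbors == rows):
            raise ValueError("self-neighbors are not allowed")

    @property
    def n_channels(self) -> int:
        return self.neighbors.shape[0]


def average_reference(topo: Topography) -> Topography:
    """Subtract the spatial mean so the map sums to zero."""
    if not np.all(np.isfinite(topo.values)):
        raise ValueError("cannot reference a topography with non-finite values")
    vals = topo.values - np.mean(topo.values)
    return Topography(values=vals, referenced=True)


def reference_recording(rec: Recording) -> Recording:
    """Average-reference every sample of a recording in place of the channel axis."""
    axis = 0 if rec.kind == "continuous" else 1
    data = rec.data - rec.data.mean(axis=axis, keepdims=True)
    return rec.copy(data=data)


def gfp(topo: Topography) -> float:
    """Global field power: spatial standard deviation of an average-referenced map."""
    if topo.n_channels < 2:
        raise ValueError("GFP requires at least 2 channels")
    return float(np.sqrt(np.mean(topo.values**2)))


def gfp_series(data: np.ndarray) -> np.ndarray:
    """GFP per sample for a (channels, samples) matrix (assumed referenced)."""
    return np.sqrt(np.mean(np.asarray(data, dtype=float) ** 2, axis=0))


def build_neighbor_graph(positions: np.ndarray, k_neighbors: int = 6) -> NeighborGraph:
    """Nearest ``k_neighbors`` channels by great-circle (angular) distance."""
    pos = np.asarray(positions, dtype=float)
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    np.fill_diagonal(cosang, -2.0)  # exclude self
    order = np.argsort(-cosang, axis=1, kind="stable")
    return NeighborGraph(neighbors=order[:, :k_neighbors], k_neighbors=k_neighbors)


def _trimmed_neighborhood_mean(frame: np.ndarray, graph: NeighborGraph) -> np.ndarray:
    """Min/max-trimmed mean over {self + neighbors} for each channel.

    ``frame`` is (n_channels,) or (n_channels, n_samples).
    """
    idx = np.concatenate(
        [np.arange(graph.n_channels)[:, None], graph.neighbors], axis=1
    )  # (ch, k+1)
    hood = frame[idx]  # (ch, k+1[, samples])
    total = hood.sum(axis=1)
    total -= hood.max(axis=1)
    total -= hood.min(axis=1)
    return total / (idx.shape[1] - 2)


def spatial_filter(rec: Recording, graph: NeighborGraph) -> Recording:
    """Outlier-trimmed neighborhood smoothing followed by re-referencing.

    Each output value is the mean of the channel's own value and its
    ``k_neighbors`` values after dropping the single maximum and minimum of
    that set.
    """
    if graph.k_neighbors < 2:
        raise ValueError("spatial filter needs k_neighbors >= 2")
    if graph.n_channels != rec.n_channels:
        raise ValueError("neighbor graph channel count does not match recording")
    if rec.kind == "continuous":
        out = _trimmed_neighborhood_mean(rec.data, graph)
        out = out - out.mean(axis=0, keepdims=True)
    else:
        out = np.empty_like(rec.data)
        for t in range(rec.n_trials):
            f = _trimmed_neighborhood_mean(rec.data[t], graph)
            out[t] = f - f.mean(axis=0, keepdims=True)
    return rec.copy(data=out)


def extract_gfp_peaks(rec: Recording) -> list[Topography]:
    """Topographies at strict local maxima of the GFP time series.

    Endpoints and plateaus never qualify; order is preserved.
    """
    if rec.kind != "continuous":
        raise ValueError("GFP peak extraction expects a continuous recording")
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if rec.n_samples < 3:
        return []
    g = gfp_series(rec.data)
    interior = np.arange(1, len(g) - 1)
    mask = (g[interior] > g[interior - 1]) & (g[interior] > g[interior + 1])
    peaks = interior[mask]
    return [Topography(values=rec.data[:, p].copy()) for p in peaks]


def gfp_peak_indices(rec: Recording) -> np.ndarray:
    """Sample indices of strict GFP local maxima (helper mirroring extract_gfp_peaks)."""
    if rec.n_samples < 3:
        return np.array([], dtype=int)
    g = gfp_series(rec.data)
    interior = np.arange(1, len(g) - 1)
    mask = (g[interior] > g[interior - 1]) & (g[interior] > g[interior + 1])
    return interior[mask]


@dataclass
class RejectionReport:
    """Per-epoch outcome of :func:`reject_epochs`."""

    dropped: list[int] = field(default_factory=list)
    interpolated: dict[int, list[int]] = field(default_factory=dict)
    offending: dict[int, list[int]] = field(default_factory=dict)
    n_input: int = 0
    n_kept: int = 0
    interpolation_method: str = "trimmed_neighborhood_mean"

    def to_dict(self) -> dict:
        return {
            "dropped": list(self.dropped),
            "interpolated": {str(k): v for k, v in self.interpolated.items()},
            "offending": {str(k): v for k, v in self.offending.items()},
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "interpolation_method": self.interpolation_method,
        }

    @property
    def empty(self) -> bool:
        return not self.dropped and not self.interpolated


def _p2p_offenders(
    epoch: np.ndarray, sr: float, limit: float, window_ms: float, step_ms: float
) -> np.ndarray:
    win = int(round(window_ms * sr / 1000.0))
    if win < 2:
        raise ValueError("peak-to-peak window shorter than 2 samples")
    step = max(int(round(step_ms * sr / 1000.0)), 1)
    n = epoch.shape[1]
    bad = np.zeros(epoch.shape[0], dtype=bool)
    for start in range(0, max(n - win + 1, 1), step):
        seg = epoch[:, start : start + win]
        bad |= (seg.max(axis=1) - seg.min(axis=1)) > limit
    return bad


def _joint_prob_offenders(data: np.ndarray, n_sd: float) -> np.ndarray:
    """Improbable-activity flags per (trial, channel).

    For each channel, epoch amplitudes are scored by their mean negative
    log-density under a Gaussian kernel estimate pooled across epochs; flags
    mark scores more than ``n_sd`` SDs above the channel mean (local) or the
    all-channel mean (global).
    """
    n_trials, n_ch, n_samp = data.shape
    scores = np.empty((n_trials, n_ch))
    rng = np.random.default_rng(0)  # deterministic pooling subsample
    for c in range(n_ch):
        pooled = data[:, c, :].ravel()
        if pooled.size > 2000:
            pooled = rng.choice(pooled, 2000, replace=False)
        if np.ptp(pooled) == 0:
            scores[:, c] = 0.0
            continue
        kde = _sstats.gaussian_kde(pooled)
        for t in range(n_trials):
            dens = kde(data[t, c, :: max(n_samp // 50, 1)])
            scores[t, c] = -np.mean(np.log(np.maximum(dens, 1e-300)))
    local_mu = scores.mean(axis=0)
    local_sd = scores.std(axis=0)
    local_sd[local_sd == 0] = np.inf
    flags = (scores - local_mu) / local_sd > n_sd
    gsd = scores.std()
    if gsd > 0:
        flags |= (scores - scores.mean()) / gsd > n_sd
    return flags


def reject_epochs(
    rec: Recording,
    amp_limit: float = 100.0,
    p2p_limit: Optional[float] = None,
    p2p_window: float = 200.0,
    p2p_step: float = 20.0,
    joint_prob_sd: Optional[float] = 3.0,
    channel_threshold: int = 10,
    graph: Optional[NeighborGraph] = None,
) -> tuple[Recording, RejectionReport]:
    """Drop or repair epochs with artifacted channels.

    An epoch is dropped when at least ``channel_threshold`` channels offend on
    any criterion (absolute amplitude, sliding peak-to-peak when ``p2p_limit``
    is given, joint probability when ``joint_prob_sd`` is given). Epochs with
    fewer offending channels are kept, with those channels replaced by the
    trimmed neighborhood mean for that epoch only.
    """
    if rec.kind != "epoched":
        raise ValueError("reject_epochs expects an epoched recording")
    report = RejectionReport(n_input=rec.n_trials)
    offend = np.zeros((rec.n_trials, rec.n_channels), dtype=bool)
    if np.isfinite(amp_limit):
        offend |= np.abs(rec.data).max(axis=2) > amp_limit
    if p2p_limit is not None and np.isfinite(p2p_limit):
        for t in range(rec.n_trials):
            offend[t] |= _p2p_offenders(rec.data[t], rec.sr, p2p_limit, p2p_window, p2p_step)
    elif p2p_limit is not None:
        # still validate the window even when the limit is infinite
        if int(round(p2p_window * rec.sr / 1000.0)) < 2:
            raise ValueError("peak-to-peak window shorter than 2 samples")
    if joint_prob_sd is not None and np.isfinite(joint_prob_sd) and rec.n_trials >= 3:
        offend |= _joint_prob_offenders(rec.data, joint_prob_sd)

    keep = []
    data = rec.data.copy()
    for t in range(rec.n_trials):
        bad = np.flatnonzero(offend[t])
        if bad.size:
            report.offending[t] = bad.tolist()
        if bad.size >= channel_threshold:
            report.dropped.append(t)
            continue
        if bad.size:
            if graph is None:
                if rec.channel_positions is None:
                    raise ValueError(
                        "channel interpolation needs a neighbor graph or channel positions"
                    )
                graph = build_neighbor_graph(rec.channel_positions)
            smoothed = _trimmed_neighborhood_mean(data[t], graph)
            data[t, bad, :] = smoothed[bad, :]
            report.interpolated[t] = bad.tolist()
        keep.append(t)
    report.n_kept = len(keep)
    out = rec.copy(data=data[keep])
    return out, report


def trim_continuous(rec: Recording, seconds: float) -> Recording:
    """Keep the first ``seconds`` of a continuous recording."""
    if rec.kind != "continuous":
        raise ValueError("trim_continuous expects a continuous recording")
    n_keep = int(round(seconds * rec.sr))
    if n_keep > rec.n_samples:
        short = (n_keep - rec.n_samples) / rec.sr
        raise ValueError(
            f"recording is {short:.3f} s shorter than the requested {seconds} s"
        )
    return rec.copy(data=rec.data[:, :n_keep].copy())
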