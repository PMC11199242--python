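"""Modified k-means topographic clustering and cluster-count selection.

Topographies are clustered on spatial correlation. In *invariant* mode a map
and its sign-flip are the same state: samples are assigned to the template
with the largest squared correlation and templates are updated as the
principal eigenvector of the assigned maps' scatter. In *variant* mode signed
correlation is used and templates are the normalized mean of assigned maps.

The number of clusters is chosen by a meta-criterion: seven cluster-validity
criteria each vote for their best k and the (lower) median vote wins.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Topography

__all__ = [
    "MicrostateSet",
    "CriterionProfile",
    "ResampleConfig",
    "KMeansResult",
    "spatial_correlation",
    "modified_kmeans",
    "compute_criterion_matrix",
    "meta_criterion",
    "resample_cluster",
    "group_aggregate",
    "write_maps_tsv",
    "read_maps_tsv",
    "CRITERION_NAMES",
]

CRITERION_NAMES = (
    "silhouette",
    "davies_bouldin_inv",
    "dunn",
    "point_biserial",
    "calinski_harabasz",
    "krzanowski_lai",
    "cross_validation",
)


@dataclass
class MicrostateSet:
    """K unit-norm, zero-mean template topographies."""

    maps: np.ndarray  # (k, n_channels)
    polarity_mode: str = "invariant"
    level: str = "individual"

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.polarity_mode not in ("invariant", "variant"):
            raise ValueError("polarity_mode must be 'invariant' or 'variant'")
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm template map")
        self.maps = self.maps - self.maps.mean(axis=1, keepdims=True)
        self.maps = self.maps / np.linalg.norm(self.maps, axis=1, keepdims=True)

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def topographies(self) -> list[Topography]:
        return [Topography(values=m.copy(), referenced=True) for m in self.maps]


@dataclass
class CriterionProfile:
    """Per-criterion scores over candidate cluster counts and the median vote."""

    k_values: np.ndarray
    criterion_matrix: np.ndarray  # (n_criteria, n_k); NaN = undefined
    votes: dict[str, int]
    meta_k: int
    criterion_names: Sequence[str] = CRITERION_NAMES

    def to_dict(self) -> dict:
        mat = [
            [None if not np.isfinite(v) else float(v) for v in row]
            for row in self.criterion_matrix
        ]
        return {
            "k_values": [int(k) for k in self.k_values],
            "criterion_names": list(self.criterion_names),
            "criterion_matrix": mat,
            "votes": {k: int(v) for k, v in self.votes.items()},
            "meta_k": int(self.meta_k),
        }


@dataclass
class ResampleConfig:
    n_epochs: int = 50
    n_samples_per_epoch: int = 833
    k_range: tuple[int, int] = (1, 12)
    n_restarts: int = 50
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.k_range[0] > self.k_range[1]:
            raise ValueError("invalid k_range")


@dataclass
class KMeansResult:
    states: MicrostateSet
    labels: np.ndarray
    explained_variance: float
    ev_trace: list[float] = field(default_factory=list)


def _as_matrix(maps) -> np.ndarray:
    if isinstance(maps, MicrostateSet):
        return maps.maps.copy()
    if isinstance(maps, np.ndarray):
        X = np.atleast_2d(np.asarray(maps, dtype=float))
    else:
        X = np.stack([m.values if isinstance(m, Topography) else np.asarray(m, float) for m in maps])
    return X


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm topography")
    return X / norms


def spatial_correlation(a, b, polarity_invariant: bool = True) -> float:
    """Cosine similarity of two zero-mean maps; absolute value when invariant."""
    av = a.values if isinstance(a, Topography) else np.asarray(a, float)
    bv = b.values if isinstance(b, Topography) else np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError("channel count mismatch")
    av = av - av.mean()
    bv = bv - bv.mean()
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm topography")
    c = float(np.dot(av, bv) / (na * nb))
    return abs(c) if polarity_invariant else c


def _fix_template_signs(T: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-magnitude channel is positive."""
    idx = np.argmax(np.abs(T), axis=1)
    signs = np.sign(T[np.arange(T.shape[0]), idx])
    signs[signs == 0] = 1.0
    return T * signs[:, None]


def _assign(C: np.ndarray, invariant: bool) -> np.ndarray:
    fit = C**2 if invariant else C
    return np.argmax(fit, axis=1)  # ties -> lowest template index


def _objective(C: np.ndarray, labels: np.ndarray, invariant: bool) -> float:
    picked = C[np.arange(C.shape[0]), labels]
    return float(np.mean(picked**2 if invariant else picked))


def _update_templates(
    Xn: np.ndarray, labels: np.ndarray, k: int, T: np.ndarray, invariant: bool
) -> np.ndarray:
    out = T.copy()
    for j in range(k):
        members = Xn[labels == j]
        if members.shape[0] == 0:
            continue
        if invariant:
            scatter = members.T @ members
            # power iteration warm-started at the current template
            v = T[j].copy()
            for _ in range(50):
                v_new = scatter @ v
                nrm = np.linalg.norm(v_new)
                if nrm == 0:
                    break
                v_new /= nrm
                if np.abs(np.dot(v_new, v)) > 1 - 1e-12:
                    v = v_new
                    break
                v = v_new
            out[j] = v
        else:
            m = members.mean(axis=0)
            nrm = np.linalg.norm(m)
            if nrm > 0:
                out[j] = m / nrm
    out = out - out.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(out, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return out / nrm


def _partition_value(members: np.ndarray, invariant: bool) -> float:
    """Closed-form per-cluster objective contribution (sum over members)."""
    if members.shape[0] == 0:
        return 0.0
    if invariant:
        return float(np.linalg.eigvalsh(members.T @ members)[-1])
    return float(np.linalg.norm(members.sum(axis=0)))


def _hartigan_refine(
    Xn: np.ndarray, labels: np.ndarray, k: int, invariant: bool, max_sweeps: int = 60
) -> np.ndarray:
    """Single-sample move refinement of a converged partition.

    Stronger than Lloyd-style alternation: each sample is tentatively moved to
    every other cluster and the move is kept when the exact partition
    objective improves. Only used on small inputs, where the per-cluster
    closed forms are cheap.
    """
    n = Xn.shape[0]
    labels = labels.copy()
    values = [
        _partition_value(Xn[labels == j], invariant) for j in range(k)
    ]
    for _ in range(max_sweeps):
        improved = False
        for i in range(n):
            src = labels[i]
            if np.count_nonzero(labels == src) == 1:
                continue  # keep clusters nonempty
            src_without = _partition_value(Xn[(labels == src) & (np.arange(n) != i)], invariant)
            best_gain, best_dst, best_vals = 0.0, -1, None
            for dst in range(k):
                if dst == src:
                    continue
                dst_with = _partition_value(
                    np.vstack([Xn[labels == dst], Xn[i][None, :]]), invariant
                )
                gain = (src_without + dst_with) - (values[src] + values[dst])
                if gain > best_gain + 1e-12:
                    best_gain, best_dst = gain, dst
                    best_vals = (src_without, dst_with)
            if best_dst >= 0:
                values[src], values[best_dst] = best_vals
                labels[i] = best_dst
                improved = True
        if not improved:
            break
    return labels


def modified_kmeans(
    maps,
    k: int,
    polarity_mode: str = "invariant",
    n_restarts: int = 20,
    seed: Optional[int] = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    refine_below: int = 64,
) -> KMeansResult:
    """Best-of-``n_restarts`` modified k-means on spatial correlation.

    The objective is the mean squared correlation (invariant mode) or the mean
    signed correlation (variant mode) between each map and its assigned
    template; it is non-decreasing across iterations within a restart.
    """
    X = _as_matrix(maps)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of maps ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    invariant = polarity_mode == "invariant"
    Xn = _normalize_rows(X)
    rng = np.random.default_rng(seed)

    best: Optional[KMeansResult] = None
    for restart in range(max(n_restarts, 1)):
        if restart % 2 == 0 or n <= k:
            # templates seeded from k distinct samples
            init = rng.choice(n, size=k, replace=False)
            T = Xn[init].copy()
        else:
            # templates from a random partition (reaches basins that
            # sample-seeded starts cannot)
            part = rng.integers(k, size=n)
            part[rng.choice(n, size=k, replace=False)] = np.arange(k)  # no empties
            T = _update_templates(Xn, part, k, Xn[rng.choice(n, size=k, replace=False)], invariant)
        labels = np.full(n, -1)
        prev_obj = -np.inf
        trace: list[float] = []
        for _ in range(max_iter):
            C = Xn @ T.T
            labels_new = _assign(C, invariant)
            # rescue empty clusters from the worst-fit sample
            fit = C[np.arange(n), labels_new] ** 2 if invariant else C[np.arange(n), labels_new]
            for j in range(k):
                if not np.any(labels_new == j):
                    worst = int(np.argmin(fit))
                    labels_new[worst] = j
                    T[j] = Xn[worst]
                    fit[worst] = np.inf  # don't reuse for another empty cluster
            C = Xn @ T.T
            obj = _objective(C, labels_new, invariant)
            trace.append(obj)
            if np.array_equal(labels_new, labels) and obj - prev_obj <= tol * max(abs(prev_obj), 1e-12):
                labels = labels_new
                break
            labels = labels_new
            prev_obj = obj
            T = _update_templates(Xn, labels, k, T, invariant)
        if n <= refine_below and k > 1:
            refined = _hartigan_refine(Xn, labels, k, invariant)
            if not np.array_equal(refined, labels):
                labels = refined
                T = _update_templates(Xn, labels, k, T, invariant)
        C = Xn @ T.T
        labels = _assign(C, invariant)
        obj = _objective(C, labels, invariant)
        if best is None or obj > best.explained_variance:
            if invariant:
                T = _fix_template_signs(T)
            best = KMeansResult(
                states=MicrostateSet(maps=T, polarity_mode=polarity_mode),
                labels=labels,
                explained_variance=obj,
                ev_trace=trace,
            )
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# cluster-validity criteria


def _distance_matrix(Xn: np.ndarray, invariant: bool) -> np.ndarray:
    C = np.clip(Xn @ Xn.T, -1.0, 1.0)
    D = 1.0 - C**2 if invariant else 1.0 - C
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _within_dispersion(Xn: np.ndarray, result: KMeansResult, invariant: bool) -> float:
    C = Xn @ result.states.maps.T
    picked = C[np.arange(Xn.shape[0]), result.labels]
    fit = picked**2 if invariant else picked
    return float(np.sum(1.0 - fit))


def _silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    if len(np.unique(labels)) < 2:
        return np.nan
    return float(silhouette_score(D, labels, metric="precomputed"))


def _dunn(D: np.ndarray, labels: np.ndarray) -> float:
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return np.nan
    max_diam = 0.0
    for u in uniq:
        idx = np.flatnonzero(labels == u)
        if idx.size > 1:
            max_diam = max(max_diam, float(D[np.ix_(idx, idx)].max()))
    min_inter = np.inf
    for i, u in enumerate(uniq):
        for v in uniq[i + 1 :]:
            iu, iv = np.flatnonzero(labels == u), np.flatnonzero(labels == v)
            min_inter = min(min_inter, float(D[np.ix_(iu, iv)].min()))
    if max_diam == 0:
        return np.nan
    return min_inter / max_diam


def _point_biserial(D: np.ndarray, labels: np.ndarray) -> float:
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    d = D[iu]
    same = (labels[iu[0]] == labels[iu[1]]).astype(float)
    if same.std() == 0 or d.std() == 0:
        return np.nan
    # larger distances between clusters -> positive criterion
    return float(np.corrcoef(d, 1.0 - same)[0, 1])


def _davies_bouldin_inv(D_templates: np.ndarray, scatter: np.ndarray) -> float:
    k = len(scatter)
    if k < 2:
        return np.nan
    worst = np.empty(k)
    for i in range(k):
        ratios = [
            (scatter[i] + scatter[j]) / D_templates[i, j]
            for j in range(k)
            if j != i and D_templates[i, j] > 0
        ]
        if not ratios:
            return np.nan
        worst[i] = max(ratios)
    return -float(np.mean(worst))


def compute_criterion_matrix(
    maps,
    results: dict[int, KMeansResult],
    polarity_mode: str = "invariant",
    max_pairwise: int = 1200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seven validity criteria (rows) for every candidate k (columns).

    All criteria are oriented so that larger is better; NaN marks
    combinations where a criterion is undefined (e.g. k=1).
    """
    X = _as_matrix(maps)
    Xn = _normalize_rows(X)
    invariant = polarity_mode == "invariant"
    n, p = Xn.shape
    if n > max_pairwise:
        rng = np.random.default_rng(seed)
        sub = np.sort(rng.choice(n, size=max_pairwise, replace=False))
    else:
        sub = np.arange(n)
    D = _distance_matrix(Xn[sub], invariant)

    k_values = np.array(sorted(results))
    mat = np.full((len(CRITERION_NAMES), len(k_values)), np.nan)
    W = {}
    for col, k in enumerate(k_values):
        res = results[k]
        labels = res.labels
        W[k] = _within_dispersion(Xn, res, invariant)
        sub_labels = labels[sub]
        if k >= 2 and len(np.unique(sub_labels)) >= 2:
            mat[0, col] = _silhouette(D, sub_labels)
            mat[2, col] = _dunn(D, sub_labels)
            mat[3, col] = _point_biserial(D, sub_labels)
            # Davies-Bouldin on template distances and mean member distance
            T = res.states.maps
            Ct = np.clip(T @ T.T, -1, 1)
            Dt = 1 - Ct**2 if invariant else 1 - Ct
            C = Xn @ T.T
            fit = C[np.arange(n), labels] ** 2 if invariant else C[np.arange(n), labels]
            scatter = np.array(
                [
                    np.mean(1.0 - fit[labels == j]) if np.any(labels == j) else 0.0
                    for j in range(k)
                ]
            )
            mat[1, col] = _davies_bouldin_inv(Dt, scatter)
    # Calinski-Harabasz analogue from dispersions (needs the k=1 baseline)
    W1 = W.get(1)
    if W1 is None:
        base = modified_kmeans(Xn, 1, polarity_mode, n_restarts=1, seed=0)
        W1 = _within_dispersion(Xn, base, invariant)
    for col, k in enumerate(k_values):
        if k >= 2 and W[k] > 0:
            mat[4, col] = ((W1 - W[k]) / (k - 1)) / (W[k] / (n - k))
    # Krzanowski-Lai on successive dispersion differences
    diff = {}
    for k in k_values:
        if (k - 1) in W and k >= 2:
            diff[k] = (k - 1) ** (2.0 / p) * W[k - 1] - k ** (2.0 / p) * W[k]
    for col, k in enumerate(k_values):
        if k in diff and (k + 1) in diff and diff[k + 1] != 0:
            mat[5, col] = abs(diff[k] / diff[k + 1])
    # predictive-residual (cross-validation) criterion, minimized -> negate
    for col, k in enumerate(k_values):
        if p - 1 - k > 0:
            sigma2 = W[k] / (n * (p - 1))
            mat[6, col] = -sigma2 * ((p - 1) / (p - 1 - k)) ** 2
    return k_values, mat


def meta_criterion(
    criterion_matrix: np.ndarray,
    k_values: Sequence[int],
    criterion_names: Sequence[str] = CRITERION_NAMES,
) -> CriterionProfile:
    """Median vote over per-criterion optimal k (ties to the smaller k).

    Criteria that are constant or undefined across k abstain; if every
    criterion abstains an error is raised.
    """
    k_values = np.asarray(list(k_values))
    mat = np.asarray(criterion_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != len(k_values):
        raise ValueError("criterion_matrix must be (n_criteria, n_k)")
    if len(k_values) < 2 or mat.shape[0] < 2:
        raise ValueError("need at least 2 candidate k values and 2 criteria")
    votes: dict[str, int] = {}
    for row, name in zip(mat, criterion_names):
        finite = np.isfinite(row)
        if finite.sum() < 2:
            continue
        vals = row[finite]
        if np.allclose(vals, vals[0]):
            continue  # constant criterion abstains
        ks = k_values[finite]
        best = ks[int(np.argmax(vals))]  # argmax ties -> first (smaller k)
        votes[name] = int(best)
    if not votes:
        raise ValueError("all criteria abstained; cannot select k")
    voted = np.sort(np.array(list(votes.values())))
    meta_k = int(voted[(len(voted) - 1) // 2])  # lower median
    return CriterionProfile(
        k_values=k_values,
        criterion_matrix=mat,
        votes=votes,
        meta_k=meta_k,
        criterion_names=list(criterion_names),
    )


def cluster_with_selection(
    maps,
    k_range: tuple[int, int],
    polarity_mode: str = "invariant",
    n_restarts: int = 20,
    seed: Optional[int] = None,
) -> tuple[KMeansResult, CriterionProfile]:
    """Run modified k-means for every k in range and pick k by meta-criterion."""
    X = _as_matrix(maps)
    rng = np.random.default_rng(seed)
    results = {}
    kmax = min(k_range[1], X.shape[0])
    for k in range(max(k_range[0], 1), kmax + 1):
        results[k] = modified_kmeans(
            X, k, polarity_mode, n_restarts=n_restarts, seed=int(rng.integers(2**31))
        )
    k_values, mat = compute_criterion_matrix(X, results, polarity_mode)
    profile = meta_criterion(mat, k_values)
    return results[profile.meta_k], profile


def resample_cluster(
    peak_maps,
    cfg: ResampleConfig,
    polarity_mode: str = "invariant",
) -> list[tuple[MicrostateSet, CriterionProfile]]:
    """Repeated subsample-and-cluster; one meta-criterion winner per epoch."""
    X = _as_matrix(peak_maps)
    n = X.shape[0]
    if cfg.n_samples_per_epoch > n:
        raise ValueError(
            f"n_samples_per_epoch={cfg.n_samples_per_epoch} exceeds available maps ({n})"
        )
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(cfg.n_epochs):
        sub = rng.choice(n, size=cfg.n_samples_per_epoch, replace=False)
        res, profile = cluster_with_selection(
            X[sub],
            cfg.k_range,
            polarity_mode,
            n_restarts=cfg.n_restarts,
            seed=int(rng.integers(2**31)),
        )
        out.append((res.states, profile))
    return out


def group_aggregate(
    individual_sets: Sequence[MicrostateSet],
    cfg_stage2: Optional[ResampleConfig] = None,
    cfg_stage3_restarts: int = 100,
    cfg_stage3_k_range: tuple[int, int] = (1, 15),
    polarity_mode: str = "invariant",
    seed: Optional[int] = None,
) -> tuple[MicrostateSet, CriterionProfile]:
    """Two more clustering stages over pooled individual template maps.

    Stage 2 resamples sets of pooled maps and keeps each epoch's meta-criterion
    winner; stage 3 clusters the pooled stage-2 winners once.
    """
    if not individual_sets:
        raise ValueError("no individual microstate sets supplied")
    pooled = np.concatenate([s.maps for s in individual_sets], axis=0)
    if cfg_stage2 is None:
        cfg_stage2 = ResampleConfig(
            n_epochs=100,
            n_samples_per_epoch=min(1000, pooled.shape[0]),
            k_range=(1, 15),
            n_restarts=100,
            seed=seed,
        )
    stage2 = resample_cluster(pooled, cfg_stage2, polarity_mode)
    pooled2 = np.concatenate([s.maps for s, _ in stage2], axis=0)
    res, profile = cluster_with_selection(
        pooled2,
        cfg_stage3_k_range,
        polarity_mode,
        n_restarts=cfg_stage3_restarts,
        seed=None if seed is None else seed + 1,
    )
    states = MicrostateSet(maps=res.states.maps, polarity_mode=polarity_mode, level="group")
    return states, profile


def match_templates(
    estimated: MicrostateSet, truth: MicrostateSet, polarity_invariant: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one matching by |spatial correlation|.

    Returns (truth index per estimated map, correlation per estimated map).
    """
    C = estimated.maps @ truth.maps.T
    score = np.abs(C) if polarity_invariant else C
    pairs = []
    used_e, used_t = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(-score, axis=None), score.shape))[0]
    for e, t in order:
        if e in used_e or t in used_t:
            continue
        used_e.add(int(e))
        used_t.add(int(t))
        pairs.append((int(e), int(t)))
        if len(used_e) == min(score.shape):
            break
    assign = np.full(estimated.k, -1)
    corr = np.full(estimated.k, np.nan)
    for e, t in pairs:
        assign[e] = t
        corr[e] = score[e, t]
    return assign, corr


def write_maps_tsv(states: MicrostateSet, path: str, channel_names=None) -> None:
    """Rows = channels, columns = microstates; first line carries metadata."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow([f"#polarity_mode={states.polarity_mode}", f"level={states.level}"])
        w.writerow(["channel"] + [f"state_{i}" for i in range(states.k)])
        names = channel_names or [f"CH{i}" for i in range(states.n_channels)]
        for ch in range(states.n_channels):
            w.writerow([names[ch]] + [f"{states.maps[s, ch]:.10g}" for s in range(states.k)])


def read_maps_tsv(path: str) -> MicrostateSet:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        meta = next(r)
        polarity = meta[0].split("=", 1)[1]
        level = meta[1].split("=", 1)[1]
        next(r)  # column header
        rows = [[float(v) for v in row[1:]] for row in r if row]
    maps = np.asarray(rows).T
    return MicrostateSet(maps=maps, polarity_mode=polarity, level=level)
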