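"""EEG/ERP microstate segmentation.

The microstate model treats the multichannel potential at each sample
as (approximately) one of a small set of fixed scalp topographies, each
active for tens to hundreds of milliseconds. This module implements:

* GFP — the per-sample spatial standard deviation of potentials, the
  field-strength measure all fitting is weighted by;
* a polarity-SENSITIVE topographic K-means (ERP components carry
  meaningful polarity, so a map and its negation are different states —
  unlike in spontaneous-EEG microstate analysis);
* GEV — the GFP-weighted fraction of topographic variance a template
  set explains, used both as the K-means objective and as the
  cross-validation score for choosing the number of classes;
* split-half cross-validated selection of k (cluster the training half
  of the cohort, back-fit the held-out half, repeat);
* permutation alignment of per-participant template sets into a global
  mean set (optimal class matching by signed spatial correlation);
* back-fitting (per-sample labelling by maximum signed spatial
  correlation) and per-class durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as _opt
from scipy import signal as _signal

from msconn.preprocess import ERP

__all__ = [
    "compute_gfp",
    "spatial_correlation",
    "MicrostateTemplateSet",
    "Segmentation",
    "kmeans_microstates",
    "compute_gev",
    "cross_validate_k",
    "align_templates",
    "backfit",
    "microstate_durations",
    "gfp_peak_indices",
]


def compute_gfp(data: np.ndarray) -> np.ndarray:
    """Global field power per sample.

    GFP(t) = sqrt( (1/N) sum_i (V_i(t) - Vbar(t))^2 ) over the N
    electrodes — the spatial RMS deviation from the instantaneous mean
    potential. It is reference-invariant and zero only for a spatially
    flat map.

    Parameters
    ----------
    data : channels x samples (or a single channels-vector).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise ValueError("GFP is undefined for fewer than 2 channels")
    centered = data - data.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(centered**2, axis=0))


def _standardize_maps(maps: np.ndarray) -> np.ndarray:
    """Center each map across channels and scale to unit GFP.

    Input samples x channels; zero-GFP (flat) maps are left as zero
    vectors so they correlate 0 with everything.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    centered = maps - maps.mean(axis=1, keepdims=True)
    gfp = np.sqrt(np.mean(centered**2, axis=1, keepdims=True))
    out = np.zeros_like(centered)
    np.divide(centered, gfp, out=out, where=gfp > 0)
    return out


def spatial_correlation(map1: np.ndarray, map2: np.ndarray) -> float:
    """Signed Pearson correlation of two maps across channels.

    Polarity is preserved: a map and its negation correlate -1.
    """
    a = _standardize_maps(np.asarray(map1, dtype=float)[None, :])[0]
    b = _standardize_maps(np.asarray(map2, dtype=float)[None, :])[0]
    return float(np.dot(a, b) / len(a))


def _correlation_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Signed spatial correlations: (samples x channels) vs (channels x k)
    -> samples x k."""
    m = _standardize_maps(maps)
    t = _standardize_maps(templates.T).T
    return m @ t / maps.shape[1]


@dataclass
class MicrostateTemplateSet:
    """k unit-GFP, average-referenced topographies (channels x k)."""

    maps: np.ndarray
    labels: list[str]
    scope: str = "individual"  # "individual" | "global"
    gev: float = float("nan")

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be channels x k")
        if self.maps.shape[1] != len(self.labels):
            raise ValueError("one label per map required")

    @property
    def k(self) -> int:
        return self.maps.shape[1]


@dataclass
class Segmentation:
    """Per-sample microstate labelling of one ERP."""

    labels: np.ndarray  # class index per sample, -1 = unassigned
    correlation: np.ndarray  # winning signed spatial correlation
    times: np.ndarray  # ms
    sampling_rate: float
    class_labels: list[str] = field(default_factory=list)

    def durations_ms(self) -> dict[int, float]:
        return microstate_durations(self, self.sampling_rate)


def _class_names(k: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(k)]


def compute_gev(
    maps: np.ndarray, templates: np.ndarray, labels: np.ndarray
) -> float:
    """Global explained variance of an assignment.

    GEV = sum_t (GFP_t * corr(map_t, template_{label_t}))^2
        / sum_t GFP_t^2, in [0, 1]; samples labelled -1 contribute
    nothing to the numerator.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    labels = np.asarray(labels)
    gfp = compute_gfp(maps.T)
    corr = _correlation_matrix(maps, templates)
    assigned = labels >= 0
    num = np.sum((gfp[assigned] * corr[assigned, labels[assigned]]) ** 2)
    den = np.sum(gfp**2)
    if den == 0:
        return 0.0
    return float(num / den)


def _kmeans_single(
    maps: np.ndarray,
    gfp: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One restart of polarity-sensitive topographic K-means.

    ``maps`` must already be standardized (samples x channels, unit
    GFP); ``gfp`` holds the original field strengths used as weights.
    Returns (centroids channels x k standardized, labels, gev, trace).
    The reported state ratchets: the best (assignment, centroids) seen
    is kept, so the GEV trace is non-decreasing even in pathological
    sign configurations.
    """
    n = maps.shape[0]
    centroids = maps[rng.choice(n, size=k, replace=False)].T.copy()
    w = gfp**2
    den = float(w.sum())
    best_gev = -np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    prev_labels = None
    trace: list[float] = []
    for _ in range(max_iter):
        corr = maps @ centroids / maps.shape[1]
        labels = np.argmax(corr, axis=1)
        win = corr[np.arange(n), labels]
        gev = float(np.sum(w * win**2) / den)
        trace.append(max(gev, best_gev))
        if gev > best_gev:
            best_gev = gev
            best = (centroids.copy(), labels.copy())
        if prev_labels is not None and (
            np.array_equal(labels, prev_labels) or gev - trace[-2] < tol
        ):
            break
        prev_labels = labels
        # update: GFP^2-weighted mean of assigned maps, renormalized
        new = np.zeros_like(centroids)
        for j in range(k):
            members = labels == j
            if not members.any():
                # reseed an empty centroid at the currently worst-fit map
                worst = int(np.argmin(np.abs(win)))
                new[:, j] = maps[worst]
                continue
            new[:, j] = (w[members][:, None] * maps[members]).sum(axis=0)
        centroids = _standardize_maps(new.T).T
    assert best is not None
    centroids, labels = best
    return centroids, labels, best_gev, trace


def kmeans_microstates(
    maps: np.ndarray,
    k: int,
    n_restarts: int = 20,
    seed: int | np.random.Generator = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    return_trace: bool = False,
):
    """Cluster topographies into k microstate classes.

    Similarity is the SIGNED spatial correlation (no polarity folding):
    ERP topographies of opposite polarity belong to different classes.
    Centroids are recomputed as GFP^2-weighted means of their members
    and renormalized to unit GFP each iteration; the best of
    ``n_restarts`` random initializations by GEV is returned.

    Parameters
    ----------
    maps : samples x channels matrix of topographies.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n, _ = maps.shape
    if k > n:
        raise ValueError(f"k={k} exceeds the number of maps ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gfp = compute_gfp(maps.T)
    std_maps = _standardize_maps(maps)
    best_gev = -np.inf
    best_centroids = None
    best_trace: list[float] = []
    for _ in range(n_restarts):
        centroids, _, gev, trace = _kmeans_single(std_maps, gfp, k, rng, max_iter, tol)
        if gev > best_gev:
            best_gev, best_centroids, best_trace = gev, centroids, trace
    result = MicrostateTemplateSet(
        maps=best_centroids, labels=_class_names(k), scope="individual", gev=best_gev
    )
    if return_trace:
        return result, best_trace
    return result


def gfp_peak_indices(data: np.ndarray) -> np.ndarray:
    """Indices of local GFP maxima of a channels x samples array."""
    gfp = compute_gfp(data)
    peaks, _ = _signal.find_peaks(gfp)
    return peaks


def _erp_maps(erp: ERP | np.ndarray, gfp_peaks_only: bool = False) -> np.ndarray:
    data = erp.data if isinstance(erp, ERP) else np.asarray(erp, dtype=float)
    if gfp_peaks_only:
        idx = gfp_peak_indices(data)
        if len(idx) == 0:
            idx = np.arange(data.shape[1])
        return data[:, idx].T
    return data.T


def _silhouette(distance: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    if len(np.unique(labels)) < 2:
        return -1.0
    return float(silhouette_score(distance, labels, metric="precomputed"))


def cross_validate_k(
    participant_erps: dict[str, list[ERP]] | list[list[ERP]],
    k_range: tuple[int, int] = (3, 10),
    n_repeats: int = 50,
    split: float = 0.5,
    n_restarts: int = 5,
    seed: int = 0,
    gfp_peaks_only: bool = False,
    criterion: str = "silhouette",
    silhouette_subsample: int = 1500,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of microstate classes by split-half cross-validation.

    Each repeat randomly splits the participants into a training and a
    testing half; for each candidate k the pooled training topographies
    are clustered and the resulting templates back-fitted to the pooled
    held-out topographies. Three held-out scores are recorded per
    (repeat, k):

    * ``test_gev`` — GEV of the back-fit. Because back-fitting takes the
      maximum correlation over templates, this score is effectively
      non-decreasing in k and cannot identify the true number of
      classes on its own; it is recorded for inspection.
    * ``cv_crit`` — the residual variance penalized by
      ((C-1)/(C-1-k))^2 over the C channels, the classic
      cross-validation criterion for microstate model selection
      (smaller is better).
    * ``silhouette`` — cluster-validity silhouette of the back-fit
      labels under the signed-correlation distance (1 - r), computed on
      a GFP^2-weighted subsample of held-out maps. Splitting a true
      class produces two nearly collinear templates and a sharp
      silhouette drop, which makes this score peak at the true k; it
      is the default selection criterion.

    The selected k optimizes the mean of the chosen ``criterion`` over
    repeats (ties go to the smallest k).

    Returns ``(selected_k, table)`` with one row per (repeat, k).
    """
    if isinstance(participant_erps, dict):
        erp_lists = list(participant_erps.values())
    else:
        erp_lists = list(participant_erps)
    n_part = len(erp_lists)
    if n_part < 4:
        raise ValueError("cross-validation needs at least 4 participants")
    n_train = int(round(n_part * split))
    if n_train < 2 or n_part - n_train < 2:
        raise ValueError("need at least 2 participants in each half")
    if criterion not in {"silhouette", "cv", "gev"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    rng = np.random.default_rng(seed)
    k_lo, k_hi = k_range
    ks = list(range(k_lo, k_hi + 1))
    part_maps = [
        np.vstack([_erp_maps(e, gfp_peaks_only) for e in erps]) for erps in erp_lists
    ]
    n_channels = part_maps[0].shape[1]
    rows = []
    for rep in range(n_repeats):
        order = rng.permutation(n_part)
        train = np.vstack([part_maps[i] for i in order[:n_train]])
        test = np.vstack([part_maps[i] for i in order[n_train:]])
        test_gfp = compute_gfp(test.T)
        test_std = _standardize_maps(test)
        w = test_gfp**2
        den = float(w.sum())
        # high-GFP (signal-dominated) subsample for the silhouette score
        n_sub = min(silhouette_subsample, len(test))
        idx = rng.choice(len(test), size=n_sub, replace=False, p=w / den)
        sub = test_std[idx]
        dist = np.clip(1.0 - sub @ sub.T / n_channels, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        for k in ks:
            tset = kmeans_microstates(train, k, n_restarts=n_restarts, seed=rng)
            corr = test_std @ tset.maps / n_channels
            labels = np.argmax(corr, axis=1)
            win = corr[np.arange(test.shape[0]), labels]
            gev = float(np.sum(w * win**2) / den)
            if k < n_channels - 1:
                cv_crit = (1.0 - gev) * ((n_channels - 1) / (n_channels - 1 - k)) ** 2
            else:
                cv_crit = np.inf
            sil = _silhouette(dist, labels[idx])
            rows.append((rep, k, gev, cv_crit, sil))
    table = pd.DataFrame(rows, columns=["repeat", "k", "test_gev", "cv_crit", "silhouette"])
    column = {"silhouette": "silhouette", "cv": "cv_crit", "gev": "test_gev"}[criterion]
    means = table.groupby("k")[column].mean()
    scores = means.to_numpy()
    pick = np.argmin(scores) if criterion == "cv" else np.argmax(scores)
    selected = int(means.index[pick])  # first optimum = smallest k on ties
    return selected, table


def align_templates(
    individual_sets: list[MicrostateTemplateSet], max_iter: int = 100
) -> tuple[MicrostateTemplateSet, list[np.ndarray]]:
    """Average per-participant template sets into a global mean set.

    Class correspondence across participants is unknown, so the mean is
    built iteratively: each participant's classes are matched to the
    provisional mean classes by maximizing total SIGNED spatial
    correlation (optimal assignment on the k x k correlation matrix —
    a sign-flipped copy of a map is NOT matched as the same class),
    then the mean maps are recomputed and renormalized, until the
    permutations stabilize.

    Returns the global set and each participant's class permutation
    ``perm`` with ``individual.maps[:, perm[j]]`` matching global class j.
    """
    if not individual_sets:
        raise ValueError("need at least one template set")
    k = individual_sets[0].k
    if any(s.k != k for s in individual_sets):
        raise ValueError("all participants must have the same number of classes")
    mean_maps = _standardize_maps(individual_sets[0].maps.T).T
    perms = [np.arange(k) for _ in individual_sets]
    for _ in range(max_iter):
        new_perms = []
        for s in individual_sets:
            corr = _correlation_matrix(s.maps.T, mean_maps)  # individual x global
            row, col = _opt.linear_sum_assignment(-corr)
            perm = np.empty(k, dtype=int)
            perm[col] = row  # global class j <- individual class perm[j]
            new_perms.append(perm)
        stacked = np.stack(
            [s.maps[:, p] for s, p in zip(individual_sets, new_perms)], axis=0
        )
        mean_maps = _standardize_maps(stacked.mean(axis=0).T).T
        if all(np.array_equal(a, b) for a, b in zip(perms, new_perms)):
            perms = new_perms
            break
        perms = new_perms
    return (
        MicrostateTemplateSet(maps=mean_maps, labels=_class_names(k), scope="global"),
        perms,
    )


def backfit(
    templates: MicrostateTemplateSet | np.ndarray,
    erp: ERP | np.ndarray,
    times: np.ndarray | None = None,
    sampling_rate: float | None = None,
    min_duration_ms: float = 0.0,
) -> Segmentation:
    """Label every sample with the template of maximum signed spatial
    correlation.

    Tie-break: if the winning correlation is exactly tied, the previous
    sample's label is kept when it is among the winners (temporal
    smoothness), otherwise the lowest class index wins. With
    ``min_duration_ms`` > 0, runs shorter than the minimum are merged
    into the neighbouring state with the higher correlation (off by
    default).
    """
    if isinstance(templates, MicrostateTemplateSet):
        tmaps, class_labels = templates.maps, templates.labels
    else:
        tmaps = np.asarray(templates, dtype=float)
        class_labels = _class_names(tmaps.shape[1])
    if isinstance(erp, ERP):
        data, times, sampling_rate = erp.data, erp.times, erp.sampling_rate
    else:
        data = np.asarray(erp, dtype=float)
        if times is None or sampling_rate is None:
            raise ValueError("times and sampling_rate required for raw arrays")
    corr = _correlation_matrix(data.T, tmaps)  # samples x k
    row_max = corr.max(axis=1)
    labels = np.empty(corr.shape[0], dtype=int)
    prev = -1
    for t in range(corr.shape[0]):
        winners = np.flatnonzero(corr[t] == row_max[t])
        labels[t] = prev if prev in winners else winners[0]
        prev = labels[t]
    winning = row_max
    seg = Segmentation(
        labels=labels,
        correlation=winning,
        times=np.asarray(times, dtype=float),
        sampling_rate=float(sampling_rate),
        class_labels=list(class_labels),
    )
    if min_duration_ms > 0:
        seg = _smooth_segmentation(seg, corr, min_duration_ms)
    return seg


def _smooth_segmentation(seg: Segmentation, corr: np.ndarray, min_ms: float) -> Segmentation:
    min_samples = int(np.ceil(min_ms * seg.sampling_rate / 1000.0))
    labels = seg.labels.copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(labels)
        for start, stop, lab in runs:
            if stop - start >= min_samples or len(runs) == 1:
                continue
            left = labels[start - 1] if start > 0 else None
            right = labels[stop] if stop < len(labels) else None
            candidates = [c for c in (left, right) if c is not None and c != lab]
            if not candidates:
                continue
            best = max(candidates, key=lambda c: corr[start:stop, c].sum())
            labels[start:stop] = best
            changed = True
            break
    winning = corr[np.arange(len(labels)), labels]
    return Segmentation(
        labels=labels,
        correlation=winning,
        times=seg.times,
        sampling_rate=seg.sampling_rate,
        class_labels=seg.class_labels,
    )


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    runs = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            runs.append((start, t, int(labels[start])))
            start = t
    return runs


def microstate_durations(segmentation: Segmentation, sampling_rate: float | None = None) -> dict[int, float]:
    """Total labelled time per class in ms: count x (1000 / rate).

    Classes never assigned get 0; together with unassigned samples the
    durations partition the epoch length exactly.
    """
    rate = sampling_rate if sampling_rate is not None else segmentation.sampling_rate
    step = 1000.0 / rate
    k = len(segmentation.class_labels) or int(segmentation.labels.max()) + 1
    return {
        j: float(np.count_nonzero(segmentation.labels == j) * step) for j in range(k)
    }
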