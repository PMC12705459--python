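"""Brain-state extraction by replicated k-means with correlation distance.

The 1 - Pearson-r metric is realized by standardizing each frame (mean 0,
unit L2 norm after demeaning) and running Lloyd iterations with centroids
re-standardized every update, so squared Euclidean distance on standardized
rows equals 2 * (1 - r) and the closed-form mean update is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score

from brainte.cohort import ParcellationScheme, SubjectTimeSeries

#: Sentinel frame label for zero-variance (unassignable) frames.
UNASSIGNABLE = -1


def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation of two vectors; ranges over [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0 or nb == 0:
        which = "first" if na == 0 else "second"
        raise ValueError(f"zero-variance vector ({which} argument); correlation undefined")
    return float(1.0 - (ac @ bc) / (na * nb))


def _standardize_rows(x: np.ndarray, context: str = "frame") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-variance {context}(s) at index {bad.tolist()}")
    return xc / norms[:, None]


@dataclass(frozen=True)
class Partition:
    """One clustering solution over concatenated frames.

    ``centroids`` live in the standardized (mean-zero, unit-norm) space of
    the correlation metric: each is the re-standardized mean of its
    members' standardized frames.
    """

    labels: np.ndarray
    centroids: np.ndarray
    within_cluster_distance_total: float
    converged: bool = True

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


@dataclass(frozen=True)
class BrainStateSet:
    """Group-level brain states: raw-space centroids plus signed network labels."""

    k: int
    group_centroids: np.ndarray
    labels: tuple[str, ...]
    explained_variance_by_k: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SubjectCentroids:
    subject_id: str
    centroids: np.ndarray
    frames_per_state: np.ndarray
    imputed_states: frozenset[int] = frozenset()


def _kmeans_pp(xs: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding on standardized rows (D^2 = 2(1 - r))."""
    n = xs.shape[0]
    centers = np.empty((k, xs.shape[1]))
    idx = int(rng.integers(n))
    centers[0] = xs[idx]
    d2 = np.clip(2.0 - 2.0 * (xs @ centers[0]), 0.0, None)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers[j] = xs[idx]
        d2 = np.minimum(d2, np.clip(2.0 - 2.0 * (xs @ centers[j]), 0.0, None))
    return centers


def _update_centroids(xs: np.ndarray, labels: np.ndarray, k: int, old: np.ndarray) -> np.ndarray:
    cents = np.empty((k, xs.shape[1]))
    for j in range(k):
        mask = labels == j
        cents[j] = xs[mask].mean(axis=0) if mask.any() else old[j]
    cents -= cents.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(cents, axis=1)
    norms[norms == 0] = 1.0
    return cents / norms[:, None]


def _lloyd(
    xs: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    centers = _kmeans_pp(xs, k, rng)
    labels = np.full(xs.shape[0], -1)
    converged = False
    for _ in range(max_iter):
        sims = xs @ centers.T
        new_labels = np.argmax(sims, axis=1)
        # empty-cluster repair: reseed from the frame farthest from its centroid
        counts = np.bincount(new_labels, minlength=k)
        for j in np.flatnonzero(counts == 0):
            worst = int(np.argmin(sims[np.arange(xs.shape[0]), new_labels]))
            new_labels[worst] = j
            sims[worst, :] = -np.inf  # not eligible to seed another empty cluster
            sims[worst, j] = np.inf
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        centers = _update_centroids(xs, labels, k, centers)
    final_sims = (xs @ centers.T)[np.arange(xs.shape[0]), labels]
    objective = float(np.sum(1.0 - final_sims))
    return labels, centers, objective, converged


def run_kmeans(
    data: np.ndarray,
    k: int,
    n_replicates: int = 10,
    max_iter: int = 300,
    seed: int | np.random.SeedSequence = 0,
) -> Partition:
    """Best-of-``n_replicates`` correlation-distance k-means.

    Replicates differ only in their seeded initialization; the solution
    with the lowest total within-cluster correlation distance wins (ties
    break to the lowest replicate index).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] <= k:
        raise ValueError("need more frames than clusters")
    xs = _standardize_rows(data)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(entropy=seed)
    best: tuple[np.ndarray, np.ndarray, float, bool] | None = None
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        labels, centers, obj, converged = _lloyd(xs, k, rng, max_iter)
        if best is None or obj < best[2]:
            best = (labels, centers, obj, converged)
    assert best is not None
    labels, centers, obj, converged = best
    if not converged:
        warnings.warn(f"k-means did not converge within max_iter={max_iter}", RuntimeWarning)
    return Partition(
        labels=labels,
        centroids=centers,
        within_cluster_distance_total=obj,
        converged=converged,
    )


def ami(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted mutual information with arithmetic-mean normalization."""
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))


def select_stable_partition(partitions: list[Partition]) -> tuple[Partition, np.ndarray]:
    """Pick the partition with the greatest total pairwise AMI.

    Returns the winner and the full pairwise AMI matrix; ties break to the
    lowest partition index.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two partitions")
    m = len(partitions)
    mat = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            mat[i, j] = mat[j, i] = ami(partitions[i].labels, partitions[j].labels)
    totals = mat.sum(axis=1)
    return partitions[int(np.argmax(totals))], mat


def explained_variance(xs_std: np.ndarray, labels: np.ndarray, k: int) -> float:
    """1 - within-cluster SS / total SS on standardized rows."""
    mu = xs_std.mean(axis=0)
    sst = float(np.sum((xs_std - mu) ** 2))
    ssw = 0.0
    for j in range(k):
        mask = labels == j
        if mask.any():
            ssw += float(np.sum((xs_std[mask] - xs_std[mask].mean(axis=0)) ** 2))
    return 1.0 - ssw / sst if sst > 0 else 0.0


def choose_k(
    data: np.ndarray,
    k_range: range = range(2, 15),
    gain_threshold: float = 0.01,
    n_replicates: int = 10,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Elbow rule on the explained-variance curve.

    k* is the last k before the first sub-threshold gain, i.e. the largest
    k at which adding a cluster still buys >= ``gain_threshold`` explained
    variance (clamped into ``k_range``). If every gain clears the
    threshold, the top of the range is returned with a warning.
    """
    ks = list(k_range)
    if not ks or ks[0] <= 1:
        raise ValueError("k_range must start at k >= 2")
    data = np.asarray(data, dtype=float)
    if ks[-1] >= data.shape[0]:
        raise ValueError("k_range must stay below the number of frames")
    xs = _standardize_rows(data)
    ss = np.random.SeedSequence(entropy=seed)
    children = iter(ss.spawn(len(ks) + 1))

    ev: dict[int, float] = {}
    prev_k = ks[0] - 1
    if prev_k >= 2:
        part = run_kmeans(data, prev_k, n_replicates, max_iter, next(children))
        prev_ev = explained_variance(xs, part.labels, prev_k)
    else:
        prev_ev = 0.0  # k=1 explains nothing by definition
    k_star: int | None = None
    for k in ks:
        part = run_kmeans(data, k, n_replicates, max_iter, next(children))
        ev[k] = explained_variance(xs, part.labels, k)
        gain = ev[k] - prev_ev
        if k_star is None and gain < gain_threshold:
            k_star = max(k - 1, ks[0])
        prev_ev = ev[k]
    if k_star is None:
        warnings.warn(
            f"no explained-variance gain below {gain_threshold}; returning max of range",
            RuntimeWarning,
        )
        k_star = ks[-1]
    return k_star, ev


def label_states(centroids: np.ndarray, parcellation: ParcellationScheme) -> tuple[str, ...]:
    """Signed network labels by cosine similarity to binary network templates.

    Each centroid c is compared (and -c too) against the indicator vector
    of every populated network; the best of the 2 x 9 candidates names the
    state, '+' if c itself won. Exact ties resolve to the lexicographically
    first network name with a warning.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[1] != parcellation.n_regions:
        raise ValueError("centroid width does not match parcellation")
    nets = parcellation.present_networks
    templates = np.stack([parcellation.indicator(n) for n in nets])
    templates = templates / np.linalg.norm(templates, axis=1, keepdims=True)
    labels = []
    for c in centroids:
        norm = np.linalg.norm(c)
        if norm == 0:
            raise ValueError("all-zero centroid cannot be labeled")
        sims = templates @ (c / norm)
        cands = [(float(s), n, "+") for s, n in zip(sims, nets)]
        cands += [(float(-s), n, "-") for s, n in zip(sims, nets)]
        best = max(s for s, _, _ in cands)
        winners = sorted((n, sign) for s, n, sign in cands if s == best)
        if len(winners) > 1:
            warnings.warn(
                f"cosine-similarity tie among {winners}; choosing {winners[0]}", RuntimeWarning
            )
        net, sign = winners[0]
        labels.append(f"{net}{sign}")
    return tuple(labels)


def assign_frames(
    series: SubjectTimeSeries, states: BrainStateSet, group_labels: np.ndarray | None = None
) -> np.ndarray:
    """Per-frame state labels.

    Subjects that entered the group clustering pass their slice of the
    selected partition via ``group_labels`` and get it back verbatim;
    held-out subjects are labeled by the nearest group centroid under
    correlation distance. Zero-variance frames get the UNASSIGNABLE
    sentinel and a warning; ties resolve to the lowest state index.
    """
    if series.n_regions != states.group_centroids.shape[1]:
        raise ValueError("series region count does not match state centroids")
    if group_labels is not None:
        group_labels = np.asarray(group_labels)
        if group_labels.shape[0] != series.n_frames:
            raise ValueError("group_labels must align with frames")
        return group_labels
    data = series.data
    xc = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    bad = norms == 0
    norms_safe = np.where(bad, 1.0, norms)
    xs = xc / norms_safe[:, None]
    cs = _standardize_rows(states.group_centroids, context="centroid")
    labels = np.argmax(xs @ cs.T, axis=1)  # argmax breaks ties to lowest index
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance frame(s) in {series.subject_id} marked unassignable",
            RuntimeWarning,
        )
        labels = np.where(bad, UNASSIGNABLE, labels)
    return labels


def subject_centroids(
    series: SubjectTimeSeries, labels: np.ndarray, states: BrainStateSet
) -> SubjectCentroids:
    """Per-subject state centroids: the mean of the subject's frames in each
    state; states the subject never visits are imputed from the group
    centroid and recorded in ``imputed_states``."""
    labels = np.asarray(labels)
    if labels.shape[0] != series.n_frames:
        raise ValueError("labels must align with frames")
    k = states.k
    cents = np.empty((k, series.n_regions))
    counts = np.zeros(k, dtype=int)
    imputed = []
    for j in range(k):
        mask = labels == j
        counts[j] = int(mask.sum())
        if counts[j] > 0:
            cents[j] = series.data[mask].mean(axis=0)
        else:
            cents[j] = states.group_centroids[j]
            imputed.append(j)
    if imputed:
        warnings.warn(
            f"{series.subject_id}: states {imputed} unvisited; centroids imputed from group",
            RuntimeWarning,
        )
    return SubjectCentroids(
        subject_id=series.subject_id,
        centroids=cents,
        frames_per_state=counts,
        imputed_states=frozenset(imputed),
    )


@dataclass(frozen=True)
class StateExtractionResult:
    states: BrainStateSet
    partition: Partition
    ami_matrix: np.ndarray
    frame_slices: dict[str, slice]
    subject_labels: dict[str, np.ndarray]
    k_selected: int


def extract_states(
    series_list: list[SubjectTimeSeries],
    parcellation: ParcellationScheme,
    k: int | str = 4,
    k_range: range = range(2, 15),
    gain_threshold: float = 0.01,
    n_replicates: int = 10,
    stability_runs: int = 10,
    max_iter: int = 300,
    seed: int = 0,
) -> StateExtractionResult:
    """Full extraction stage on a cohort.

    Concatenates all subjects' frames (manifest order), optionally selects
    k by the elbow rule, runs ``stability_runs`` independent best-of-
    ``n_replicates`` clusterings, keeps the most AMI-central partition,
    and labels group centroids (raw-space cluster means) by network.
    """
    if not series_list:
        raise ValueError("no subjects provided")
    widths = {s.n_regions for s in series_list}
    if widths != {parcellation.n_regions}:
        raise ValueError(
            f"series region counts {sorted(widths)} do not match parcellation N={parcellation.n_regions}"
        )
    data = np.concatenate([s.data for s in series_list], axis=0)
    slices: dict[str, slice] = {}
    start = 0
    for s in series_list:
        slices[s.subject_id] = slice(start, start + s.n_frames)
        start += s.n_frames

    ss = np.random.SeedSequence(entropy=seed)
    choose_ss, *run_ss = ss.spawn(stability_runs + 1)

    ev_by_k: dict[int, float] = {}
    if k == "auto":
        k_selected, ev_by_k = choose_k(
            data,
            k_range=k_range,
            gain_threshold=gain_threshold,
            n_replicates=n_replicates,
            max_iter=max_iter,
            seed=int(choose_ss.generate_state(1)[0]),
        )
    else:
        k_selected = int(k)

    partitions = [
        run_kmeans(data, k_selected, n_replicates, max_iter, child) for child in run_ss
    ]
    if len(partitions) >= 2:
        partition, ami_matrix = select_stable_partition(partitions)
    else:
        partition, ami_matrix = partitions[0], np.ones((1, 1))

    group_centroids = np.stack(
        [data[partition.labels == j].mean(axis=0) for j in range(k_selected)]
    )
    state_labels = label_states(group_centroids, parcellation)
    states = BrainStateSet(
        k=k_selected,
        group_centroids=group_centroids,
        labels=state_labels,
        explained_variance_by_k=ev_by_k,
    )
    subject_labels = {
        sid: partition.labels[sl] for sid, sl in slices.items()
    }
    return StateExtractionResult(
        states=states,
        partition=partition,
        ami_matrix=ami_matrix,
        frame_slices=slices,
        subject_labels=subject_labels,
        k_selected=k_selected,
    )
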