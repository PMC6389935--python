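"""Circular self-organising-map clustering of circadian model profiles.

Circadian probes are summarised by their fixed-effect model profile
(cosinor + trend evaluated at the averaged sampling times, then z-scored) so
that clustering sees shape and phase, not expression level. Profiles are
clustered with a batch SOM whose nodes live on a ring — the natural topology
for phase-ordered curves — and the cluster count is chosen by a BIC score on
the resulting partition. Clusters whose circular-mean peak time lies within
a window of DLMO are labelled "evening", the rest "morning".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelProfile",
    "ClusterModel",
    "averaged_sampling_times",
    "build_model_profiles",
    "fit_circular_som",
    "select_k_by_bic",
    "label_morning_evening",
    "circular_mean_hours",
    "phase_set_sizes",
    "partition_bic",
]


@dataclass(frozen=True)
class ModelProfile:
    probe_id: str
    profile: np.ndarray  # z-scored, length = number of sampling points
    peak_time_h: float


@dataclass
class ClusterModel:
    k: int
    node_weights: np.ndarray                 # (k, d) ring-ordered nodes
    labels: np.ndarray                       # per-profile cluster index
    probe_ids: list[str]
    cluster_peak_times_h: np.ndarray         # circular-mean peak per cluster
    cluster_mean_profiles: np.ndarray        # (k, d)
    cluster_sizes: np.ndarray
    bic: float = np.nan
    bic_by_k: dict[int, float] = field(default_factory=dict)
    phase_labels: list[str] = field(default_factory=list)  # morning | evening


def circular_mean_hours(hours: np.ndarray, period_h: float = 24.0) -> float:
    """Circular mean of peak times, reported in [-period/2, period/2)."""
    hours = np.asarray(hours, dtype=float)
    hours = hours[np.isfinite(hours)]
    if len(hours) == 0:
        return np.nan
    ang = hours * 2 * np.pi / period_h
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean * period_h / (2 * np.pi) + period_h / 2) % period_h
                 - period_h / 2)


def averaged_sampling_times(metadata: pd.DataFrame) -> np.ndarray:
    """Mean aligned time per sampling index across subjects.

    Requires ``subject_id`` and ``time_rel_dlmo_h`` columns; within each
    subject, samples are taken in ascending aligned time. Subjects must
    share the number of sampling points.
    """
    per_subject = [
        np.sort(grp["time_rel_dlmo_h"].to_numpy())
        for _, grp in metadata.groupby("subject_id", sort=True)
    ]
    lengths = {len(t) for t in per_subject}
    if len(lengths) != 1:
        raise ValueError("subjects differ in number of sampling points")
    return np.vstack(per_subject).mean(axis=0)


def build_model_profiles(
    fits: pd.DataFrame, averaged_times_h: np.ndarray, period_h: float = 24.0
) -> list[ModelProfile]:
    """Fixed-effect cosinor + trend evaluated at averaged times, z-scored.

    ``fits`` must carry mesor, trend_slope, beta_cos, beta_sin and
    peak_time_h (one row per circadian probe).
    """
    t = np.asarray(averaged_times_h, dtype=float)
    w = 2 * np.pi / period_h
    profiles = []
    for _, row in fits.iterrows():
        y = (
            row["mesor"]
            + row["trend_slope"] * t
            + row["beta_cos"] * np.cos(w * t)
            + row["beta_sin"] * np.sin(w * t)
        )
        sd = y.std()
        if sd == 0:
            raise ValueError(
                f"{row['probe_id']}: constant model profile cannot be z-scored"
            )
        profiles.append(
            ModelProfile(
                probe_id=str(row["probe_id"]),
                profile=(y - y.mean()) / sd,
                peak_time_h=float(row["peak_time_h"]),
            )
        )
    return profiles


def _ring_distance(k: int) -> np.ndarray:
    """Pairwise node distance on a ring of k nodes."""
    idx = np.arange(k)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, k - d)


def _init_nodes(X: np.ndarray, peak_times: np.ndarray, k: int) -> np.ndarray:
    """Phase-ordered quantile initialisation: order profiles by peak time and
    seed node i with the mean of the i-th contiguous slice."""
    order = np.argsort(peak_times)
    slices = np.array_split(order, k)
    nodes = np.vstack([
        X[s].mean(axis=0) if len(s) else X.mean(axis=0) for s in slices
    ])
    return nodes


def fit_circular_som(
    profiles: list[ModelProfile],
    k: int,
    seed: int | None = None,
    epochs: int = 200,
    radius_start: float | None = None,
    radius_end: float = 0.5,
) -> ClusterModel:
    """Batch-train a SOM with k nodes on a ring and assign profiles.

    Neighbourhood is Gaussian in ring distance with radius decaying
    geometrically from ``radius_start`` (default k/2) to ``radius_end``
    over ``epochs``. Initialisation is deterministic (phase-ordered
    quantiles); ``seed`` is accepted for API symmetry with stochastic
    variants. Empty nodes are permitted. Clusters are relabelled canonically
    by ascending circular-mean peak time.
    """
    n = len(profiles)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles ({n})")
    X = np.vstack([p.profile for p in profiles])
    peaks = np.array([p.peak_time_h for p in profiles])
    nodes = _init_nodes(X, peaks, k)

    if radius_start is None:
        radius_start = max(k / 2.0, radius_end)
    ring = _ring_distance(k)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        radius = radius_start * (radius_end / radius_start) ** frac
        d2 = ((X[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
        bmu = np.argmin(d2, axis=1)
        h = np.exp(-(ring[:, bmu] ** 2) / (2 * radius**2))  # (k, n)
        wsum = h.sum(axis=1)
        new = (h @ X) / np.where(wsum > 0, wsum, 1.0)[:, None]
        nodes = np.where(wsum[:, None] > 0, new, nodes)

    d2 = ((X[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)

    # canonical relabelling by ascending circular-mean peak time
    means = np.array([
        circular_mean_hours(peaks[labels == j]) if (labels == j).any() else np.inf
        for j in range(k)
    ])
    order = np.argsort(means, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    nodes = nodes[order]

    sizes = np.bincount(labels, minlength=k)
    mean_profiles = np.vstack([
        X[labels == j].mean(axis=0) if sizes[j] else nodes[j] for j in range(k)
    ])
    cluster_peaks = np.array([
        circular_mean_hours(peaks[labels == j]) if sizes[j] else np.nan
        for j in range(k)
    ])
    return ClusterModel(
        k=k,
        node_weights=nodes,
        labels=labels,
        probe_ids=[p.probe_id for p in profiles],
        cluster_peak_times_h=cluster_peaks,
        cluster_mean_profiles=mean_profiles,
        cluster_sizes=sizes,
    )


def partition_bic(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    """BIC of a hard-assignment spherical-Gaussian mixture.

    -2 log classification likelihood + penalty:

        BIC = n d ln(2 pi sigma^2) + n d + 2 sum_j n_j ln(n / n_j)
              + (k d + 1) ln(n d)

    with sigma^2 the mean squared deviation from the assigned centroid (the
    ML mean of the members, not the neighbourhood-smoothed SOM code vector).
    The mixing-proportion (classification entropy) term is essential: without
    it, splitting an isotropic cloud always buys ~2/pi of one dimension's
    variance and the score decreases monotonically in k.
    """
    n, d = X.shape
    k = centroids.shape[0]
    resid = X - centroids[labels]
    sigma2 = max(float((resid**2).sum()) / (n * d), 1e-12)
    sizes = np.bincount(labels, minlength=k)
    nz = sizes[sizes > 0]
    entropy = 2.0 * float((nz * np.log(n / nz)).sum())
    p = k * d + 1
    return (n * d * np.log(2 * np.pi * sigma2) + n * d + entropy
            + p * np.log(n * d))


def select_k_by_bic(
    profiles: list[ModelProfile],
    k_range=range(1, 7),
    seed: int | None = None,
    epochs: int = 200,
) -> ClusterModel:
    """Fit a circular SOM per candidate k and keep the BIC-minimal model."""
    X = np.vstack([p.profile for p in profiles])
    best: ClusterModel | None = None
    bics: dict[int, float] = {}
    for k in k_range:
        if k > len(profiles):
            continue
        model = fit_circular_som(profiles, k, seed=seed, epochs=epochs)
        bic = partition_bic(X, model.cluster_mean_profiles, model.labels)
        model.bic = bic
        bics[k] = bic
        if best is None or bic < best.bic:
            best = model
    if best is None:
        raise ValueError("no candidate k is feasible for this profile set")
    best.bic_by_k = bics
    return best


def label_morning_evening(
    model: ClusterModel, window_h: float = 5.0, period_h: float = 24.0
) -> ClusterModel:
    """Label each cluster by its circular-mean peak time relative to DLMO.

    Clusters peaking within ``window_h`` hours of DLMO (time 0) are
    "evening" (melatonin onset marks the biological evening); all others
    are "morning". Evening clusters are pooled downstream.
    """
    labels = []
    for peak in model.cluster_peak_times_h:
        if np.isfinite(peak) and abs(peak) <= window_h:
            labels.append("evening")
        else:
            labels.append("morning")
    model.phase_labels = labels
    return model


def phase_set_sizes(model: ClusterModel) -> dict[str, int]:
    """Pooled probe counts per phase label (evening clusters merged)."""
    out: dict[str, int] = {}
    for j, lab in enumerate(model.phase_labels):
        out[lab] = out.get(lab, 0) + int(model.cluster_sizes[j])
    return out


def clusters_to_tsv(model: ClusterModel, path) -> None:
    df = pd.DataFrame(
        {
            "probe_id": model.probe_ids,
            "cluster": model.labels,
            "phase_label": [
                model.phase_labels[j] if model.phase_labels else ""
                for j in model.labels
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)
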