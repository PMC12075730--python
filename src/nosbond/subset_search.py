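"""Exhaustive descriptor-subset search for NOS-candidate separation.

Every subset of the fifteen descriptors with at least three members
(Σ_{i=3..15} C(15, i) = 32,647 subsets in the full search) is embedded into
at most three dimensions with UMAP and clustered by mean-shift.  A subset is
accepted when the embedding yields two or three clusters with Silhouette
score ≥ 0.5 and the experimentally verified reference linkages fall almost
entirely inside one or two clusters ("probable clusters"); the accepted
subsets are ranked by size, reference leakage and Silhouette, and the top
one is the minimal descriptor set.  Candidate pairs then inherit their
cluster's probable/improbable label.

Columns are z-score standardized before embedding; descriptors mix degrees,
Å, Å² and counts, so raw Euclidean distances would be meaningless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import MeanShift, estimate_bandwidth
from sklearn.metrics import silhouette_score as _sk_silhouette

from .config import ScreeningConfig

__all__ = [
    "ReferenceSet",
    "SubsetEvaluation",
    "CandidateVerdict",
    "SelectionResult",
    "enumerate_subsets",
    "standardize",
    "embed",
    "cluster",
    "silhouette",
    "evaluate_subset",
    "select_best",
    "label_candidates",
    "inject_references",
]


@dataclass
class ReferenceSet:
    """Experimentally verified linkages used to anchor probable clusters.

    Either a list of candidate ids already present in the matrix, or
    precomputed descriptor vectors to inject as extra rows (used when
    screening a pair class different from the one the references belong to).
    """

    ids: list[str] = field(default_factory=list)
    vectors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("reference ids must be unique")


@dataclass
class SubsetEvaluation:
    """Outcome of embedding + clustering one descriptor subset."""

    subset: tuple[int, ...]
    embedding: np.ndarray
    labels: np.ndarray
    cluster_sizes: list[int]
    silhouette: float | None
    ref_counts: list[int]
    accepted: bool
    rejection_reason: str | None = None
    leak_tolerance: int = 2

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def ref_leak(self) -> int:
        """References outside probable clusters."""
        probable = probable_clusters(self.ref_counts, self.leak_tolerance)
        return sum(c for k, c in enumerate(self.ref_counts) if k not in probable)


@dataclass(frozen=True)
class CandidateVerdict:
    candidate_id: str
    cluster: int
    label: str  # "probable" | "improbable"


@dataclass
class SelectionResult:
    """Ranked accepted subsets plus diagnostics when nothing is accepted."""

    ranked: list[SubsetEvaluation]
    n_evaluated: int
    best_silhouette_seen: float | None

    @property
    def best(self) -> SubsetEvaluation | None:
        return self.ranked[0] if self.ranked else None


def enumerate_subsets(n_descriptors: int, min_size: int) -> Iterator[tuple[int, ...]]:
    """All index subsets of size ≥ *min_size*, in (size, lexicographic) order."""
    for size in range(min_size, n_descriptors + 1):
        yield from combinations(range(n_descriptors), size)


def count_subsets(n_descriptors: int, min_size: int) -> int:
    from math import comb

    return sum(comb(n_descriptors, i) for i in range(min_size, n_descriptors + 1))


def standardize(X: np.ndarray) -> np.ndarray:
    """Column z-scores; constant columns become zeros rather than NaN."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def embed(
    X: np.ndarray,
    dims: int,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """UMAP embedding of (standardized) descriptor columns into ≤ 3 dims.

    Deterministic for a fixed seed (single-threaded layout).  Degenerate
    input where all rows coincide maps every point to the origin.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if dims > 3:
        raise ValueError("embedding dimension is capped at 3")
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} rows, got {n}")
    dims = min(dims, X.shape[1])
    if np.allclose(X, X[0]):
        return np.zeros((n, dims))
    import umap  # deferred: numba-backed import is slow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=dims,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric="euclidean",
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(X), dtype=float)


def cluster(coords: np.ndarray, quantile: float = 0.3) -> tuple[np.ndarray, int]:
    """Mean-shift clustering; clusters renumbered by descending size.

    Bandwidth is estimated from the embedded coordinates with the
    median-quantile heuristic.  Degenerate input (all points coincide, or a
    non-positive bandwidth estimate) collapses to a single cluster.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2 or np.allclose(coords, coords[0]):
        return np.zeros(n, dtype=int), 1
    bw = estimate_bandwidth(coords, quantile=quantile)
    if not np.isfinite(bw) or bw <= 0:
        return np.zeros(n, dtype=int), 1
    # bin seeding with a minimum bin occupancy suppresses spurious
    # low-density satellite modes that plain seeding produces on a single
    # Gaussian cloud
    ms = MeanShift(bandwidth=bw, bin_seeding=True, min_bin_freq=3)
    raw = ms.fit_predict(coords)
    # renumber by descending cluster size, ties by original label
    unique, counts = np.unique(raw, return_counts=True)
    order = unique[np.lexsort((unique, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[v] for v in raw], dtype=int)
    return labels, len(unique)


def silhouette(coords: np.ndarray, labels: np.ndarray) -> float | None:
    """Mean Silhouette score, Euclidean; ``None`` when only one cluster."""
    if len(np.unique(labels)) < 2:
        return None
    return float(_sk_silhouette(coords, labels, metric="euclidean"))


def probable_clusters(ref_counts: Sequence[int], leak_tolerance: int = 2) -> set[int]:
    """Clusters holding more references than the leak tolerance."""
    return {k for k, c in enumerate(ref_counts) if c > leak_tolerance}


def acceptance_gate(
    n_clusters: int,
    sil: float | None,
    ref_counts: Sequence[int],
    cfg: ScreeningConfig,
) -> tuple[bool, str | None]:
    """Accept/reject decision for one subset evaluation.

    Accepted iff the cluster count lies in the configured range, the
    Silhouette score meets the minimum, and the partition discriminates:
    at least one probable cluster holds the references, at least one
    improbable cluster is nearly free of them, and at most
    ``ref_leak_tolerance`` references lie outside probable clusters.
    """
    if n_clusters < 2:
        return False, "single_cluster"
    if not (cfg.min_clusters <= n_clusters <= cfg.max_clusters):
        return False, "cluster_count"
    if sil is None or sil < cfg.min_silhouette:
        return False, "silhouette"
    probable = probable_clusters(ref_counts, cfg.ref_leak_tolerance)
    leak = sum(c for k, c in enumerate(ref_counts) if k not in probable)
    if not probable or len(probable) == n_clusters or leak > cfg.ref_leak_tolerance:
        return False, "reference_leak"
    return True, None


def evaluate_subset(
    matrix: np.ndarray | pd.DataFrame,
    subset: Sequence[int],
    ref_flags: np.ndarray,
    cfg: ScreeningConfig | None = None,
    seed: int | None = None,
) -> SubsetEvaluation:
    """Embed + cluster one descriptor subset and apply the acceptance gate.

    Accepted iff the cluster count lies in ``[min_clusters, max_clusters]``,
    the Silhouette score is ≥ ``min_silhouette`` and at most
    ``ref_leak_tolerance`` reference rows fall outside probable clusters.
    The embedding uses 3 dimensions for subsets larger than 3 descriptors,
    else 2.
    """
    cfg = cfg or ScreeningConfig()
    seed = cfg.umap_seed if seed is None else seed
    X = np.asarray(matrix, dtype=float)[:, list(subset)]
    ref_flags = np.asarray(ref_flags, dtype=bool)
    dims = 3 if len(subset) > 3 else 2
    coords = embed(
        standardize(X), dims,
        n_neighbors=cfg.umap_n_neighbors, min_dist=cfg.umap_min_dist, seed=seed,
    )
    labels, n_clusters = cluster(coords, quantile=cfg.meanshift_quantile)
    sizes = [int((labels == k).sum()) for k in range(n_clusters)]
    ref_counts = [int((ref_flags & (labels == k)).sum()) for k in range(n_clusters)]
    sil = silhouette(coords, labels)
    accepted, reason = acceptance_gate(n_clusters, sil, ref_counts, cfg)
    return SubsetEvaluation(
        subset=tuple(subset),
        embedding=coords,
        labels=labels,
        cluster_sizes=sizes,
        silhouette=sil,
        ref_counts=ref_counts,
        accepted=accepted,
        rejection_reason=reason,
        leak_tolerance=cfg.ref_leak_tolerance,
    )


def select_best(evaluations: Iterable[SubsetEvaluation]) -> SelectionResult:
    """Rank accepted subsets by (size, reference leak, −Silhouette).

    The top-ranked subset is the minimal descriptor set.  When nothing is
    accepted the result carries diagnostics (best Silhouette observed).
    """
    accepted: list[SubsetEvaluation] = []
    n_seen = 0
    best_sil: float | None = None
    for ev in evaluations:
        n_seen += 1
        if ev.silhouette is not None and (best_sil is None or ev.silhouette > best_sil):
            best_sil = ev.silhouette
        if ev.accepted:
            accepted.append(ev)
    accepted.sort(key=lambda e: (len(e.subset), e.ref_leak, -(e.silhouette or -2.0), e.subset))
    return SelectionResult(ranked=accepted, n_evaluated=n_seen, best_silhouette_seen=best_sil)


def label_candidates(
    evaluation: SubsetEvaluation,
    ref_flags: np.ndarray,
    candidate_ids: Sequence[str],
    leak_tolerance: int = 2,
) -> list[CandidateVerdict]:
    """Probable/improbable verdict for every non-reference row.

    A cluster is probable iff it holds more reference points than the leak
    tolerance; all its members inherit the label.  Reference rows are
    excluded from the returned list.
    """
    ref_flags = np.asarray(ref_flags, dtype=bool)
    probable = probable_clusters(evaluation.ref_counts, leak_tolerance)
    verdicts = []
    for i, cid in enumerate(candidate_ids):
        if ref_flags[i]:
            continue
        k = int(evaluation.labels[i])
        verdicts.append(
            CandidateVerdict(
                candidate_id=cid,
                cluster=k,
                label="probable" if k in probable else "improbable",
            )
        )
    return verdicts


def inject_references(
    matrix: pd.DataFrame,
    refs: ReferenceSet,
    descriptor_columns: Sequence[str],
    id_column: str = "candidate_id",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Append reference descriptor rows (or flag in-matrix reference ids).

    Returns ``(augmented_matrix, ref_flags)``.  Reference vectors computed on
    their own (Lys–Cys) pairs are appended to every pair-class matrix so the
    probable clusters can be anchored even when the class itself contains no
    verified linkage.
    """
    flags = matrix[id_column].isin(set(refs.ids)).to_numpy(dtype=bool)
    if refs.vectors is not None and len(refs.vectors):
        missing = [c for c in descriptor_columns if c not in refs.vectors.columns]
        if missing:
            raise ValueError(f"reference vectors missing descriptor columns {missing}")
        extra = refs.vectors.copy()
        if id_column not in extra.columns:
            extra[id_column] = [f"ref_{i}" for i in range(len(extra))]
        matrix = pd.concat([matrix, extra], ignore_index=True, sort=False)
        flags = np.concatenate([flags, np.ones(len(extra), dtype=bool)])
    return matrix, flags
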