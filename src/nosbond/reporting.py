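"""Cluster summaries, candidate exports and optional plots.

The per-cluster summary mirrors the descriptor density-distribution view:
for each cluster of the winning subset evaluation, the dominant mode of each
descriptor's kernel density estimate is reported together with cluster size,
label and reference count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .subset_search import CandidateVerdict, SubsetEvaluation, probable_clusters

__all__ = [
    "ClusterSummary",
    "ConsistencyError",
    "density_mode",
    "summarize_clusters",
    "export_candidates",
    "plot_embedding",
    "plot_density",
]


class ConsistencyError(ValueError):
    """Verdicts and descriptor vectors are keyed inconsistently."""


@dataclass
class ClusterSummary:
    cluster: int
    label: str
    size: int
    ref_count: int
    modes: dict[str, float]  # descriptor name -> dominant density mode


def density_mode(values: Sequence[float], bw_method: str | float = "scott") -> float:
    """Dominant mode: argmax of a Gaussian KDE on a 512-point [min, max] grid.

    Constant input returns that constant directly (a KDE is undefined there).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("density_mode of empty input")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    kde = gaussian_kde(values, bw_method=bw_method)
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def summarize_clusters(
    evaluation: SubsetEvaluation,
    matrix: pd.DataFrame,
    ref_flags: np.ndarray,
    descriptor_columns: Sequence[str],
) -> list[ClusterSummary]:
    """One summary per cluster of an accepted evaluation.

    Modes are computed per cluster on the winning subset's descriptors
    (reference rows included; sizes therefore sum to the matrix row count).
    """
    ref_flags = np.asarray(ref_flags, dtype=bool)
    probable = probable_clusters(evaluation.ref_counts, evaluation.leak_tolerance)
    cols = [descriptor_columns[i] for i in evaluation.subset]
    summaries = []
    for k in range(evaluation.n_clusters):
        members = evaluation.labels == k
        modes = {c: density_mode(matrix.loc[members, c].to_numpy()) for c in cols}
        summaries.append(
            ClusterSummary(
                cluster=k,
                label="probable" if k in probable else "improbable",
                size=int(members.sum()),
                ref_count=evaluation.ref_counts[k],
                modes=modes,
            )
        )
    return summaries


def export_candidates(
    verdicts: Sequence[CandidateVerdict],
    vectors: pd.DataFrame,
    destination: str | Path,
    id_column: str = "candidate_id",
) -> dict[str, Path]:
    """Write probable.tsv / improbable.tsv with full ids and descriptors.

    Every verdict id must be present in *vectors* (checked before anything
    is written); reference rows are never exported because verdicts only
    cover non-reference rows.
    """
    destination = Path(destination)
    by_id = {v.candidate_id: v for v in verdicts}
    known = set(vectors[id_column])
    unknown = sorted(set(by_id) - known)
    if unknown:
        raise ConsistencyError(f"verdict ids missing from vectors: {unknown[:5]}")
    destination.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for label in ("probable", "improbable"):
        ids = [v.candidate_id for v in verdicts if v.label == label]
        sub = vectors[vectors[id_column].isin(set(ids))].copy()
        sub["cluster"] = [by_id[c].cluster for c in sub[id_column]]
        sub["label"] = label
        path = destination / f"{label}.tsv"
        sub.to_csv(path, sep="\t", index=False)
        out[label] = path
    return out


def _colors(evaluation: SubsetEvaluation) -> list[str]:
    probable = probable_clusters(evaluation.ref_counts, evaluation.leak_tolerance)
    palette = ["#56b4e9", "#4169e1", "#e69f00", "#999999"]
    colors = []
    p_i = 0
    for k in range(evaluation.n_clusters):
        colors.append(palette[min(p_i, 1)] if k in probable else palette[2])
        if k in probable:
            p_i += 1
    return colors


def plot_embedding(
    evaluation: SubsetEvaluation, ref_flags: np.ndarray, path: str | Path
) -> Path:
    """Scatter of the embedding, probable/improbable colouring, references as
    black squares.  Cosmetic output; requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref_flags = np.asarray(ref_flags, dtype=bool)
    coords = evaluation.embedding
    three_d = coords.shape[1] >= 3
    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(111, projection="3d" if three_d else None)
    colors = _colors(evaluation)
    for k in range(evaluation.n_clusters):
        m = (evaluation.labels == k) & ~ref_flags
        xyz = [coords[m, i] for i in range(3 if three_d else 2)]
        ax.scatter(*xyz, s=12, color=colors[k], label=f"cluster {k} (n={m.sum()})")
    if ref_flags.any():
        xyz = [coords[ref_flags, i] for i in range(3 if three_d else 2)]
        ax.scatter(*xyz, s=20, marker="s", color="black", label="reference")
    ax.legend(fontsize=7)
    sil = evaluation.silhouette
    ax.set_title(f"subset {evaluation.subset}, silhouette {sil:.2f}" if sil else "")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_density(
    evaluation: SubsetEvaluation,
    matrix: pd.DataFrame,
    column: str,
    path: str | Path,
) -> Path:
    """Per-cluster KDE curves of one descriptor.  Cosmetic output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    colors = _colors(evaluation)
    values = matrix[column].to_numpy(dtype=float)
    for k in range(evaluation.n_clusters):
        v = values[evaluation.labels == k]
        if len(v) > 1 and v.std() > 0:
            kde = gaussian_kde(v)
            grid = np.linspace(v.min(), v.max(), 256)
            ax.plot(grid, kde(grid), color=colors[k], label=f"cluster {k}")
        else:
            ax.axvline(v[0], color=colors[k], label=f"cluster {k}")
    ax.set_xlabel(column)
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
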