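"""Screening configuration: every threshold and tuning knob in one place."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ScreeningConfig:
    """Thresholds and algorithm settings for the NOS-candidate screen.

    The quality cutoffs are the published screening criteria: X-ray entries
    at resolution ≤ 2.0 Å, S–N separation ≤ 3.2 Å (the covalent-interaction
    cutoff established for Lys/Cys), target-atom occupancy strictly > 0.8,
    per-residue RSRZ strictly < 2.0, and both target atoms present in the
    BDB B-factor table.  The embedding/clustering fields control the
    descriptor-subset search and carry this package's defaults.
    """

    # entry-level
    max_resolution: float = 2.0  # Å, inclusive
    # pair-level
    max_sn_dist: float = 3.2  # Å, inclusive
    min_occupancy: float = 0.8  # exclusive: occ must be > this
    max_rsrz: float = 2.0  # exclusive: rsrz must be < this
    include_nondefault_classes: bool = False  # keep Met-S / His-N / Cys-Cys pairs
    # descriptors
    neighbor_radius: float = 4.0  # Å around Cα, inclusive
    sasa_probe_radius: float = 1.4  # Å
    sasa_points: int = 960
    # subset search
    min_subset_size: int = 3
    min_silhouette: float = 0.5
    min_clusters: int = 2
    max_clusters: int = 3
    ref_leak_tolerance: int = 2  # max reference points outside probable clusters
    umap_seed: int = 0
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    meanshift_quantile: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "max_resolution",
            "max_sn_dist",
            "min_occupancy",
            "max_rsrz",
            "neighbor_radius",
            "sasa_probe_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_clusters > self.max_clusters:
            raise ValueError("min_clusters must not exceed max_clusters")


DEFAULT_CONFIG = ScreeningConfig()
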