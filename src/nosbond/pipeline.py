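"""End-to-end orchestration: screen → describe → search → report.

A corpus is a directory of entries, each holding ``structure.cif`` (or
``structure.pdb``), ``bdb.pdb`` and ``validation.xml``.  The screen applies
entry-level and pair-level filters, the descriptor stage builds the
15-column matrix, and the subset search selects the minimal descriptor set
and labels candidates probable/improbable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ScreeningConfig
from .contact_screen import (
    ContactPair,
    annotate_close_contacts,
    apply_quality_filters,
    find_sn_contacts,
    is_default_target_class,
)
from .descriptors import DESCRIPTOR_COLUMNS, build_descriptor_table
from .structure_io import (
    FormatError,
    passes_entry_filters,
    read_bdb_bfactors,
    read_structure,
    read_validation_report,
)
from .subset_search import (
    ReferenceSet,
    SelectionResult,
    enumerate_subsets,
    evaluate_subset,
    inject_references,
    label_candidates,
    select_best,
)

__all__ = ["ScreenResult", "SearchOutput", "screen_corpus", "run_search", "run_pipeline"]


@dataclass
class ScreenResult:
    """Retained descriptor rows plus a per-entry rejection log.

    ``rejections`` maps entry id → reason for every entry that contributed
    no retained pair (entry-filter failure, no contact in range, or all
    pairs dropped by quality filters — then the first pair's reason).
    ``pair_log`` holds per-pair (candidate_id, reason) rows for dropped pairs.
    """

    table: pd.DataFrame
    rejections: dict[str, str] = field(default_factory=dict)
    pair_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def retained_ids(self) -> list[str]:
        return list(self.table["candidate_id"]) if len(self.table) else []


def screen_entry(
    entry_dir: str | Path, cfg: ScreeningConfig
) -> tuple[pd.DataFrame, str | None, list[tuple[ContactPair, str]]]:
    """Screen one corpus entry; returns (descriptor rows, entry-level reason,
    pair rejection log)."""
    entry_dir = Path(entry_dir)
    cif = entry_dir / "structure.cif"
    pdb = entry_dir / "structure.pdb"
    s = read_structure(cif if cif.exists() else pdb)
    ok, reason = passes_entry_filters(s, cfg)
    empty = pd.DataFrame()
    if not ok:
        return empty, reason, []
    pairs = find_sn_contacts(s, cfg)
    if not cfg.include_nondefault_classes:
        pairs = [p for p in pairs if is_default_target_class(p)]
    if not pairs:
        return empty, "no_contact", []
    bdb = read_bdb_bfactors(entry_dir / "bdb.pdb")
    val = read_validation_report(entry_dir / "validation.xml")
    retained, rejected = apply_quality_filters(pairs, s, bdb, val, cfg)
    retained = annotate_close_contacts(retained, val)
    if not retained:
        return empty, rejected[0][1] if rejected else "no_contact", rejected
    table, excluded = build_descriptor_table(s, retained, bdb, cfg)
    rejected = rejected + excluded
    return table, None, rejected


def screen_corpus(root: str | Path, cfg: ScreeningConfig | None = None) -> ScreenResult:
    """Screen every entry directory under *root* (sorted by id)."""
    cfg = cfg or ScreeningConfig()
    root = Path(root)
    tables: list[pd.DataFrame] = []
    rejections: dict[str, str] = {}
    pair_log: list[tuple[str, str]] = []
    for entry in sorted(d for d in root.iterdir() if d.is_dir()):
        try:
            table, reason, dropped = screen_entry(entry, cfg)
        except (FormatError, FileNotFoundError) as exc:
            rejections[entry.name] = f"unreadable: {exc}"
            continue
        pair_log.extend((p.candidate_id, r) for p, r in dropped)
        if reason is not None:
            rejections[entry.name] = reason
        elif len(table):
            tables.append(table)
    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=DESCRIPTOR_COLUMNS + ["candidate_id"])
    )
    return ScreenResult(table=table, rejections=rejections, pair_log=pair_log)


@dataclass
class SearchOutput:
    selection: SelectionResult
    verdicts: list
    matrix: pd.DataFrame
    ref_flags: np.ndarray


def run_search(
    matrix: pd.DataFrame,
    refs: ReferenceSet,
    cfg: ScreeningConfig | None = None,
    subsets: Sequence[Sequence[int]] | None = None,
    seed: int | None = None,
) -> SearchOutput:
    """Subset search over a descriptor matrix with injected references.

    ``subsets`` restricts the stream (indices into ``DESCRIPTOR_COLUMNS``);
    by default every subset of size ≥ ``cfg.min_subset_size`` is evaluated.
    Candidates are labelled under the top-ranked accepted subset.
    """
    cfg = cfg or ScreeningConfig()
    matrix, ref_flags = inject_references(matrix, refs, DESCRIPTOR_COLUMNS)
    X = matrix[DESCRIPTOR_COLUMNS].to_numpy(dtype=float)
    if subsets is None:
        subsets = enumerate_subsets(len(DESCRIPTOR_COLUMNS), cfg.min_subset_size)
    evaluations = (
        evaluate_subset(X, tuple(sub), ref_flags, cfg, seed=seed) for sub in subsets
    )
    selection = select_best(evaluations)
    verdicts = []
    if selection.best is not None:
        verdicts = label_candidates(
            selection.best, ref_flags, list(matrix["candidate_id"]),
            leak_tolerance=cfg.ref_leak_tolerance,
        )
    return SearchOutput(selection=selection, verdicts=verdicts,
                        matrix=matrix, ref_flags=ref_flags)


def run_pipeline(
    root: str | Path,
    refs: ReferenceSet,
    cfg: ScreeningConfig | None = None,
    subsets: Sequence[Sequence[int]] | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[ScreenResult, SearchOutput]:
    """Full run over a corpus; optionally exports candidate TSVs."""
    cfg = cfg or ScreeningConfig()
    screened = screen_corpus(root, cfg)
    search = run_search(screened.table, refs, cfg, subsets=subsets, seed=seed)
    if out_dir is not None and search.verdicts:
        from .reporting import export_candidates

        export_candidates(search.verdicts, search.matrix, out_dir)
    return screened, search
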