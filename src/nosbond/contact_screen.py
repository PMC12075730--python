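"""Sulfur–nitrogen contact enumeration and per-pair quality filtering.

Candidate pairs are side-chain sulfurs (Cys SG, Met SD) against backbone and
selected side-chain nitrogens of the twenty standard residues, within a
distance cutoff (3.2 Å by default, inclusive).  Retained pairs must then
survive occupancy (> 0.8, strict), per-residue RSRZ (< 2.0, strict) and
BDB-presence filters; the first failed criterion per dropped pair is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import ScreeningConfig
from .structure_io import AtomKey, AtomRecord, BfactorTable, StructureModel, ValidationInfo

__all__ = [
    "ContactPair",
    "find_sn_contacts",
    "apply_quality_filters",
    "tabulate_pair_frequencies",
    "annotate_close_contacts",
    "is_default_target_class",
]

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: side-chain sulfur donors
SULFUR_ATOMS = {("CYS", "SG"), ("MET", "SD")}

#: side-chain nitrogen acceptors
SIDECHAIN_N = {
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("TRP", "NE1"),
    ("ASN", "ND2"),
    ("GLN", "NE2"),
}

_EPS = 1e-9  # absorbs coordinate-format rounding at threshold boundaries


@dataclass(frozen=True)
class ContactPair:
    """One candidate S–N atom pair with provenance identifiers."""

    pdb_id: str
    sulfur: AtomKey
    nitrogen: AtomKey
    dist_sn: float
    nitrogen_class: str  # "backbone" | "sidechain"
    flagged_close_contact: bool = False

    @property
    def pair_class(self) -> tuple[str, str, str, str]:
        """(S-residue, N-residue, nitrogen class, nitrogen atom name)."""
        return (self.sulfur[3], self.nitrogen[3], self.nitrogen_class, self.nitrogen[4])

    @property
    def candidate_id(self) -> str:
        s, n = self.sulfur, self.nitrogen
        return (
            f"{self.pdb_id}:{s[0]}.{s[3]}{s[1]}{s[2]}.{s[4]}"
            f"-{n[0]}.{n[3]}{n[1]}{n[2]}.{n[4]}"
        )


def _is_sulfur_donor(a: AtomRecord) -> bool:
    return (a.residue_name, a.atom_name) in SULFUR_ATOMS


def _nitrogen_class(a: AtomRecord) -> str | None:
    if a.residue_name not in STANDARD_RESIDUES:
        return None
    if a.atom_name == "N":
        return "backbone"
    if (a.residue_name, a.atom_name) in SIDECHAIN_N:
        return "sidechain"
    return None


def is_default_target_class(pair: ContactPair) -> bool:
    """Default target classes: Cys sulfur, excluding Cys–Cys and Cys–His pairs.

    Cys–Cys backbone proximity is usually a disulfide-bridge artefact and
    His–Cys proximity is often metal coordination; both are enumerated and
    tabulated but excluded from candidate screening unless configured in.
    """
    s_res, n_res = pair.sulfur[3], pair.nitrogen[3]
    return s_res == "CYS" and n_res not in ("CYS", "HIS")


def find_sn_contacts(s: StructureModel, cfg: ScreeningConfig) -> list[ContactPair]:
    """Enumerate all S–N pairs within ``cfg.max_sn_dist`` (inclusive).

    Intra-residue pairs are excluded.  Each pair appears exactly once, in
    (sulfur key, nitrogen key) order.
    """
    sulfurs = [a for a in s.atoms if _is_sulfur_donor(a)]
    nitrogens = [(a, _nitrogen_class(a)) for a in s.atoms]
    nitrogens = [(a, c) for a, c in nitrogens if c is not None]
    if not sulfurs or not nitrogens:
        return []

    n_coords = np.array([a.coords for a, _ in nitrogens])
    tree = cKDTree(n_coords)
    pairs: list[ContactPair] = []
    for sa in sulfurs:
        for j in tree.query_ball_point(sa.coords, cfg.max_sn_dist + _EPS):
            na, nclass = nitrogens[j]
            if na.residue_key == sa.residue_key:
                continue
            d = float(np.linalg.norm(sa.coords - na.coords))
            if d <= cfg.max_sn_dist + _EPS:
                pairs.append(
                    ContactPair(
                        pdb_id=s.pdb_id,
                        sulfur=sa.atom_key,
                        nitrogen=na.atom_key,
                        dist_sn=d,
                        nitrogen_class=nclass,
                    )
                )
    pairs.sort(key=lambda p: (p.sulfur, p.nitrogen))
    return pairs


def _check_pair(
    pair: ContactPair,
    s: StructureModel,
    bdb: BfactorTable,
    val: ValidationInfo,
    cfg: ScreeningConfig,
) -> str | None:
    """Return the first failed criterion for *pair*, or None if it passes."""
    sa, na = s.atom(pair.sulfur), s.atom(pair.nitrogen)
    if sa is None or na is None:
        return "missing_atom"
    for a in (sa, na):
        if not a.occupancy > cfg.min_occupancy:
            return "occupancy"
    for key in (pair.sulfur[:4], pair.nitrogen[:4]):
        if key not in val.rsrz:
            return "missing_rsrz"
        if not val.rsrz[key] < cfg.max_rsrz:
            return "rsrz"
    for a in (sa, na):
        if bdb.get(a) is None:
            return "bdb_missing"
    return None


def apply_quality_filters(
    pairs: Iterable[ContactPair],
    s: StructureModel,
    bdb: BfactorTable,
    val: ValidationInfo,
    cfg: ScreeningConfig,
) -> tuple[list[ContactPair], list[tuple[ContactPair, str]]]:
    """Apply occupancy, RSRZ and BDB-presence filters to contact pairs.

    Returns ``(retained, rejection_log)`` where the log holds one
    ``(pair, reason)`` entry per dropped pair, *reason* being the first
    failed criterion in the fixed order occupancy → RSRZ → BDB presence.
    """
    retained: list[ContactPair] = []
    rejected: list[tuple[ContactPair, str]] = []
    for pair in pairs:
        reason = _check_pair(pair, s, bdb, val, cfg)
        if reason is None:
            retained.append(pair)
        else:
            rejected.append((pair, reason))
    return retained, rejected


def tabulate_pair_frequencies(
    pairs: Iterable[ContactPair], grouping: str
) -> pd.Series:
    """Count pair classes within one nitrogen grouping, descending.

    ``grouping`` is ``"backbone"`` or ``"sidechain"``.  Ties are broken
    alphabetically on the pair-class tuple, so the ordering is stable.
    """
    if grouping not in ("backbone", "sidechain"):
        raise ValueError(f"unknown grouping {grouping!r}")
    counts: dict[tuple, int] = {}
    for p in pairs:
        if p.nitrogen_class == grouping:
            counts[p.pair_class] = counts.get(p.pair_class, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    idx = pd.Index([k for k, _ in items], tupleize_cols=False, name="pair_class")
    return pd.Series([v for _, v in items], index=idx, dtype=int, name="count")


def annotate_close_contacts(
    pairs: Iterable[ContactPair], val: ValidationInfo
) -> list[ContactPair]:
    """Flag pairs that appear in the validation report's close-contact list."""
    return [
        replace(p, flagged_close_contact=val.has_close_contact(p.sulfur, p.nitrogen))
        for p in pairs
    ]
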