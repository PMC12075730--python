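"""The fifteen per-pair descriptors.

For each retained S–N contact pair the screen gathers:

* five geometric descriptors — the angles ∠CSN (at sulfur) and ∠CNS (at
  nitrogen), the torsion φ(C_S–S–N–C_N) across the S···N axis, and the
  distances dist(C_S, N) and dist(S, N), where C_S / C_N are the closest
  carbons covalently bound to the sulfur / nitrogen;
* four B-factor descriptors — deposited (PDB) and recalibrated (BDB)
  isotropic B-factors of the nitrogen and sulfur atoms;
* two packing descriptors — the number of neighbouring residues within a
  radius (4 Å default) of the Cα of the nitrogen- and sulfur-bearing
  residues;
* four solvent-accessibility descriptors — Shrake–Rupley SASA of the two
  target atoms and of their residues.

A pair for which any component cannot be computed (no covalently bound
carbon, missing Cα, absent BDB value) is excluded with a logged reason
rather than filled with a default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .config import ScreeningConfig
from .contact_screen import ContactPair
from .sasa import structure_sasa
from .structure_io import AtomRecord, BfactorTable, StructureModel

__all__ = [
    "DESCRIPTOR_COLUMNS",
    "ID_COLUMNS",
    "DescriptorError",
    "nearest_bonded_carbon",
    "compute_geometry",
    "count_neighbors",
    "build_descriptor_table",
    "vec_angle",
    "vec_dihedral",
]

#: fixed, versioned descriptor column order of the output matrix
DESCRIPTOR_COLUMNS = [
    "angle_csn",    # degrees, at S between C_S and N
    "angle_cns",    # degrees, at N between C_N and S
    "torsion_cs_nc",  # degrees, C_S–S–N–C_N, (−180, 180]
    "dist_cn",      # Å, C_S to N
    "dist_sn",      # Å
    "bfac_pdb_n",   # Å², deposited
    "bfac_pdb_s",
    "bfac_bdb_n",   # Å², BDB recalibrated
    "bfac_bdb_s",
    "ngb_n",        # residues within neighbor_radius of N-residue Cα
    "ngb_s",
    "sasa_atom_n",  # Å²
    "sasa_atom_s",
    "sasa_res_n",
    "sasa_res_s",
]

ID_COLUMNS = [
    "candidate_id", "pdb_id",
    "chain_s", "resnum_s", "icode_s", "resname_s", "atom_s",
    "chain_n", "resnum_n", "icode_n", "resname_n", "atom_n",
    "nitrogen_class", "flagged_close_contact",
]

COVALENT_C_MAX = 1.9  # Å, upper bound for a covalent C–S / C–N bond


class DescriptorError(ValueError):
    """A descriptor component could not be computed for a pair."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


def vec_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at *b* formed by a–b–c, degrees in [0, 180]."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def vec_dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion angle p1–p2–p3–p4 in (−180, 180], right-hand rule.

    Uses the atan2 formulation, which is numerically stable near 0 and 180°.
    """
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = -float(np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2))))
    return 180.0 if ang == -180.0 else ang


def nearest_bonded_carbon(s: StructureModel, atom: AtomRecord) -> AtomRecord:
    """Closest carbon covalently bound (≤ 1.9 Å) to a target S or N atom.

    Candidates are same-residue carbons; for a backbone nitrogen the
    preceding residue's carbonyl carbon is also a candidate (it is the actual
    covalent partner at ~1.33 Å, closer than the own Cα at ~1.46 Å).
    """
    candidates = [
        a for a in s.residues.get(atom.residue_key, ())
        if a.element.capitalize() == "C" and a.atom_name != atom.atom_name
    ]
    if atom.atom_name == "N":
        prev_key_prefix = (atom.chain_id, atom.residue_number - 1)
        for key, atoms in s.residues.items():
            if key[:2] == prev_key_prefix:
                candidates.extend(a for a in atoms if a.atom_name == "C")
    best, best_d = None, COVALENT_C_MAX
    for c in candidates:
        d = float(np.linalg.norm(c.coords - atom.coords))
        if d <= best_d:
            best, best_d = c, d
    if best is None:
        raise DescriptorError("no_bonded_carbon", f"{atom.atom_key}")
    return best


@dataclass(frozen=True)
class PairGeometry:
    angle_csn: float
    angle_cns: float
    torsion_cs_nc: float
    dist_cn: float
    dist_sn: float


def compute_geometry(s: StructureModel, pair: ContactPair) -> PairGeometry:
    """Five geometric descriptors for one contact pair."""
    sa, na = s.atom(pair.sulfur), s.atom(pair.nitrogen)
    if sa is None or na is None:
        raise DescriptorError("missing_atom", pair.candidate_id)
    cs = nearest_bonded_carbon(s, sa)
    cn = nearest_bonded_carbon(s, na)
    return PairGeometry(
        angle_csn=vec_angle(cs.coords, sa.coords, na.coords),
        angle_cns=vec_angle(cn.coords, na.coords, sa.coords),
        torsion_cs_nc=vec_dihedral(cs.coords, sa.coords, na.coords, cn.coords),
        dist_cn=float(np.linalg.norm(cs.coords - na.coords)),
        dist_sn=float(np.linalg.norm(sa.coords - na.coords)),
    )


def count_neighbors(s: StructureModel, residue_key, radius: float) -> int:
    """Distinct other residues with any non-hydrogen atom within *radius*
    (inclusive) of this residue's Cα."""
    ca = None
    for a in s.residues.get(tuple(residue_key), ()):
        if a.atom_name == "CA":
            ca = a
            break
    if ca is None:
        raise DescriptorError("missing_ca", f"{residue_key}")
    neighbors = set()
    r_eps = radius + 1e-9
    for a in s.atoms:
        if a.residue_key == ca.residue_key or a.element.capitalize() == "H":
            continue
        if np.linalg.norm(a.coords - ca.coords) <= r_eps:
            neighbors.add(a.residue_key)
    return len(neighbors)


def build_descriptor_table(
    s: StructureModel,
    pairs: Iterable[ContactPair],
    bdb: BfactorTable,
    cfg: ScreeningConfig | None = None,
) -> tuple[pd.DataFrame, list[tuple[ContactPair, str]]]:
    """Assemble the 15-descriptor matrix for retained pairs of one structure.

    Returns ``(table, exclusions)``; the table holds one row per pair with
    ``DESCRIPTOR_COLUMNS`` in fixed order followed by ``ID_COLUMNS``.
    Exclusions carry the reason a pair yielded no vector.
    """
    cfg = cfg or ScreeningConfig()
    per_atom_sasa, per_res_sasa = structure_sasa(
        s, probe=cfg.sasa_probe_radius, n_points=cfg.sasa_points
    )
    rows: list[dict] = []
    excluded: list[tuple[ContactPair, str]] = []
    for pair in pairs:
        try:
            rows.append(_assemble_row(s, pair, bdb, cfg, per_atom_sasa, per_res_sasa))
        except DescriptorError as exc:
            excluded.append((pair, exc.reason))
    table = pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS + ID_COLUMNS)
    return table, excluded


def _assemble_row(s, pair, bdb, cfg, per_atom_sasa, per_res_sasa) -> dict:
    sa, na = s.atom(pair.sulfur), s.atom(pair.nitrogen)
    if sa is None or na is None:
        raise DescriptorError("missing_atom", pair.candidate_id)
    geom = compute_geometry(s, pair)
    bdb_n, bdb_s = bdb.get(na), bdb.get(sa)
    if bdb_n is None or bdb_s is None:
        raise DescriptorError("bdb_missing", pair.candidate_id)
    row = {
        "angle_csn": geom.angle_csn,
        "angle_cns": geom.angle_cns,
        "torsion_cs_nc": geom.torsion_cs_nc,
        "dist_cn": geom.dist_cn,
        "dist_sn": geom.dist_sn,
        "bfac_pdb_n": na.bfactor,
        "bfac_pdb_s": sa.bfactor,
        "bfac_bdb_n": bdb_n,
        "bfac_bdb_s": bdb_s,
        "ngb_n": count_neighbors(s, na.residue_key, cfg.neighbor_radius),
        "ngb_s": count_neighbors(s, sa.residue_key, cfg.neighbor_radius),
        "sasa_atom_n": per_atom_sasa.get(na.atom_key),
        "sasa_atom_s": per_atom_sasa.get(sa.atom_key),
        "sasa_res_n": per_res_sasa.get(na.residue_key),
        "sasa_res_s": per_res_sasa.get(sa.residue_key),
    }
    if any(v is None for v in row.values()):
        missing = [k for k, v in row.items() if v is None]
        raise DescriptorError("sasa_missing", f"{pair.candidate_id}: {missing}")
    row.update(
        candidate_id=pair.candidate_id,
        pdb_id=pair.pdb_id,
        chain_s=pair.sulfur[0], resnum_s=pair.sulfur[1], icode_s=pair.sulfur[2],
        resname_s=pair.sulfur[3], atom_s=pair.sulfur[4],
        chain_n=pair.nitrogen[0], resnum_n=pair.nitrogen[1], icode_n=pair.nitrogen[2],
        resname_n=pair.nitrogen[3], atom_n=pair.nitrogen[4],
        nitrogen_class=pair.nitrogen_class,
        flagged_close_contact=pair.flagged_close_contact,
    )
    return row
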