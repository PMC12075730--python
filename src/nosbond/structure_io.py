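"""Readers for the three input data sources of the screening pipeline.

A screened entry consists of a coordinate file (mmCIF or legacy PDB, e.g. a
PDB-REDO model), a companion BDB file (PDB-format coordinates whose B-factor
column carries consistent full isotropic B-factors) and a wwPDB-style
validation report (XML) providing per-residue real-space R-value Z-scores
(RSRZ) and "too-close contact" records.

Coordinate parsing is delegated to :mod:`gemmi`; this module flattens the
first model into plain :class:`AtomRecord` objects keyed the way every
downstream stage expects, resolves alternate locations, and applies the
entry-level metadata filters (X-ray only, resolution cutoff).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "BfactorTable",
    "ValidationInfo",
    "FormatError",
    "EmptyStructureError",
    "read_structure",
    "passes_entry_filters",
    "read_bdb_bfactors",
    "read_validation_report",
]

#: (chain_id, residue_number, insertion_code, residue_name)
ResidueKey = tuple[str, int, str, str]
#: residue key + atom name
AtomKey = tuple[str, int, str, str, str]


class FormatError(ValueError):
    """Input file is not parseable in the stated dialect."""


class EmptyStructureError(FormatError):
    """File parsed but contains no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the first model, after altloc resolution."""

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    icode: str
    chain_id: str
    altloc: str
    coords: np.ndarray  # (3,) float64, Å
    occupancy: float
    bfactor: float  # Å²

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.icode, self.residue_name)

    @property
    def atom_key(self) -> AtomKey:
        return (*self.residue_key, self.atom_name)


@dataclass
class StructureModel:
    """Parsed coordinates and metadata of one deposited entry."""

    pdb_id: str
    method: Literal["xray", "other"] | None
    resolution: float | None
    atoms: list[AtomRecord]
    residues: dict[ResidueKey, list[AtomRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            for a in self.atoms:
                self.residues.setdefault(a.residue_key, []).append(a)

    def atom(self, key: AtomKey) -> AtomRecord | None:
        for a in self.residues.get(key[:4], ()):
            if a.atom_name == key[4]:
                return a
        return None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


class BfactorTable:
    """Atom-keyed B-factors (Å²) with explicit absence.

    Lookup of an atom that is not in the table reports absence (``None`` from
    :meth:`get`, ``KeyError`` from ``[]``); there is no default value.
    """

    def __init__(self, values: dict[tuple, float], source: str = "bdb") -> None:
        for v in values.values():
            if v < 0:
                raise ValueError(f"negative B-factor {v!r}")
        self._values = dict(values)
        self.source = source

    @staticmethod
    def key_for(atom: AtomRecord) -> tuple:
        return (atom.chain_id, atom.residue_number, atom.icode, atom.atom_name, atom.altloc)

    def get(self, atom: AtomRecord) -> float | None:
        return self._values.get(self.key_for(atom))

    def __getitem__(self, atom: AtomRecord) -> float:
        return self._values[self.key_for(atom)]

    def __contains__(self, atom: AtomRecord) -> bool:
        return self.key_for(atom) in self._values

    def __len__(self) -> int:
        return len(self._values)


@dataclass
class ValidationInfo:
    """Per-residue RSRZ and deduplicated unordered close-contact pairs."""

    rsrz: dict[ResidueKey, float]
    close_contacts: list[tuple[AtomKey, AtomKey, float]]

    def has_close_contact(self, a: AtomKey, b: AtomKey) -> bool:
        pair = frozenset((a, b))
        return any(frozenset((x, y)) == pair for x, y, _ in self.close_contacts)


_XRAY_METHODS = {"X-RAY DIFFRACTION"}


def _method_enum(raw: str | None) -> Literal["xray", "other"] | None:
    if raw is None or not raw.strip():
        return None
    return "xray" if raw.strip().upper() in _XRAY_METHODS else "other"


def _resolve_altlocs(raw_atoms: Iterable[AtomRecord]) -> list[AtomRecord]:
    # For duplicated atom positions keep the highest-occupancy conformer;
    # ties broken by lexicographically smallest altloc.
    best: dict[AtomKey, AtomRecord] = {}
    order: list[AtomKey] = []
    for a in raw_atoms:
        k = a.atom_key
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            if a.occupancy > b.occupancy or (
                a.occupancy == b.occupancy and (a.altloc or "~") < (b.altloc or "~")
            ):
                best[k] = a
    return [best[k] for k in order]


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a coordinate file (mmCIF or PDB) into a :class:`StructureModel`.

    Only the first model of multi-model files is used.  Alternate locations
    are collapsed to the highest-occupancy conformer.  Metadata (experimental
    method, resolution) is ``None`` when the file does not state it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "pdb": gemmi.CoorFormat.Pdb,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise EmptyStructureError(f"{path}: no atoms in first model")

    raw: list[AtomRecord] = []
    for chain in st[0]:
        for res in chain:
            for at in res:
                raw.append(
                    AtomRecord(
                        atom_name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        icode=(res.seqid.icode or " ").strip() or "",
                        chain_id=chain.name,
                        altloc=at.altloc.strip("\x00") if at.altloc else "",
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
                        # gemmi stores occ/B as float32; round back to the
                        # text-format precision so strict thresholds behave
                        occupancy=round(float(at.occ), 6),
                        bfactor=round(float(at.b_iso), 4),
                    )
                )
    atoms = _resolve_altlocs(raw)
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    info = dict(st.info)
    method = _method_enum(info.get("_exptl.method"))
    return StructureModel(
        pdb_id=(st.name or path.stem).lower() or path.stem.lower(),
        method=method,
        resolution=resolution,
        atoms=atoms,
    )


def passes_entry_filters(s: StructureModel, cfg) -> tuple[bool, str | None]:
    """Entry-level metadata filter: X-ray method, resolution ≤ cutoff.

    The resolution cutoff is inclusive.  Returns ``(ok, reason)`` where
    *reason* names the first failed criterion (``"method"``, ``"resolution"``
    or ``"missing_resolution"``).
    """
    if s.method != "xray":
        return False, "method"
    if s.resolution is None:
        return False, "missing_resolution"
    if s.resolution > cfg.max_resolution:
        return False, "resolution"
    return True, None


def read_bdb_bfactors(path: str | Path) -> BfactorTable:
    """Read a BDB file (PDB dialect; recalibrated B-factor column).

    The table is keyed by ``(chain, residue_number, icode, atom_name,
    altloc)``.  A malformed ATOM/HETATM line or a negative B-factor raises a
    :class:`FormatError` carrying the line number.
    """
    path = Path(path)
    values: dict[tuple, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            try:
                atom_name = line[12:16].strip()
                altloc = line[16].strip()
                chain = line[21].strip()
                resnum = int(line[22:26])
                icode = line[26].strip()
                bfac = float(line[60:66])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed ATOM record: {exc}") from exc
            if bfac < 0:
                raise FormatError(f"{path}:{lineno}: negative B-factor {bfac}")
            values[(chain, resnum, icode, atom_name, altloc)] = bfac
    return BfactorTable(values, source="bdb")


def read_validation_report(path: str | Path) -> ValidationInfo:
    """Parse the wwPDB validation-report XML subset used by the screen.

    Residue entries (``ModelledSubgroup``) carrying an ``rsrz`` attribute are
    mapped to their residue key; residues without the attribute are absent
    from the map, never defaulted.  ``clash`` child records sharing a ``cid``
    across two residues become one unordered close-contact pair.
    """
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise FormatError(f"{path}: invalid XML: {exc}") from exc
    root = tree.getroot()
    subgroups = root.iter("ModelledSubgroup")

    rsrz: dict[ResidueKey, float] = {}
    by_cid: dict[str, list[tuple[AtomKey, float]]] = {}
    found_any = False
    for sg in subgroups:
        found_any = True
        try:
            key: ResidueKey = (
                sg.attrib["chain"],
                int(sg.attrib["resnum"]),
                sg.attrib.get("icode", " ").strip(),
                sg.attrib["resname"],
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: ModelledSubgroup missing residue id: {exc}") from exc
        if "rsrz" in sg.attrib:
            rsrz[key] = float(sg.attrib["rsrz"])
        for clash in sg.findall("clash"):
            atom_key: AtomKey = (*key, clash.attrib["atom"])
            by_cid.setdefault(clash.attrib["cid"], []).append(
                (atom_key, float(clash.attrib["dist"]))
            )
    if not found_any:
        raise FormatError(f"{path}: no ModelledSubgroup elements")

    seen: set[frozenset] = set()
    contacts: list[tuple[AtomKey, AtomKey, float]] = []
    for members in by_cid.values():
        if len(members) != 2:
            continue
        (a, dist), (b, _) = members
        pair = frozenset((a, b))
        if pair not in seen:
            seen.add(pair)
            contacts.append((a, b, dist))
    return ValidationInfo(rsrz=rsrz, close_contacts=contacts)
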