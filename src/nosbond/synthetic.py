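"""Synthetic fixtures: structures with planted S–N contacts, and descriptor
matrices with planted cluster structure.

The structure generator works *inversely*: given target geometry
(dist(S,N), ∠CSN, ∠CNS, torsion) it places the four core atoms C_S, S, N,
C_N exactly, then hangs minimal residue scaffolds (idealized bond lengths:
peptide C–N 1.33 Å, N–Cα 1.46 Å, Cβ–Sγ 1.81 Å) off them so that descriptor
extraction on the written files reproduces the requested geometry to format
precision.  Every entry is emitted in the same on-disk layout the real
pipeline consumes: ``<id>/structure.cif``, ``<id>/bdb.pdb``,
``<id>/validation.xml``.

The blob generator emulates the statistical situation the subset search is
built for: well-separated Gaussian clusters on a small informative
descriptor subset, pure noise elsewhere, with reference rows concentrated
in one blob.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .config import ScreeningConfig
from .descriptors import DESCRIPTOR_COLUMNS

__all__ = [
    "ContactSpec",
    "BlobSpec",
    "place_atom",
    "make_contact_structure",
    "make_corpus",
    "make_descriptor_blobs",
    "read_manifest",
]

# idealized bond lengths, Å
B_SG_CB = 1.81
B_PEPTIDE_CN = 1.33
B_N_CA = 1.46
B_C_C = 1.53
B_NZ_CE = 1.49
B_NE_CZ = 1.33


class ConstructionError(ValueError):
    """Spec asks for unrealizable geometry or an unsupported pair class."""


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    r: float, theta_deg: float, phi_deg: float,
) -> np.ndarray:
    """Place atom D with |D−c| = r, ∠(D,c,b) = theta, torsion(a,b,c,D) = phi."""
    th, ph = math.radians(theta_deg), math.radians(phi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ConstructionError("collinear frame atoms for placement")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -r * math.cos(th),
        r * math.sin(th) * math.cos(ph),
        r * math.sin(th) * math.sin(ph),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class ContactSpec:
    """One planted S–N contact and all its quality attributes."""

    pdb_id: str
    n_residue: str = "GLY"          # nitrogen-bearing residue
    n_atom: str = "N"               # target nitrogen atom name
    dist_sn: float = 2.70
    angle_csn: float = 94.02
    angle_cns: float = 95.11
    torsion: float = 60.0
    occ_s: float = 1.0
    occ_n: float = 1.0
    bfac_pdb_s: float = 20.0
    bfac_pdb_n: float = 20.0
    bfac_bdb_s: float = 22.0
    bfac_bdb_n: float = 22.0
    rsrz_s: float | None = 0.5
    rsrz_n: float | None = 0.5
    resolution: float = 1.80
    method: str = "X-RAY DIFFRACTION"
    flag_close_contact: bool = False
    omit_bdb: tuple[str, ...] = ()  # subset of ("S", "N") absent from the BDB file

    def __post_init__(self) -> None:
        if self.dist_sn <= 0:
            raise ConstructionError("dist_sn must be positive")
        for name in ("angle_csn", "angle_cns"):
            v = getattr(self, name)
            if not (0.0 < v < 180.0):
                raise ConstructionError(f"{name} must lie in (0, 180), got {v}")
        if not (-180.0 < self.torsion <= 180.0):
            raise ConstructionError("torsion must lie in (-180, 180]")


_Atom = tuple[int, str, str, str, np.ndarray, float, float, float]
# (resnum, resname, atom_name, element, pos, occ, b_pdb, b_bdb)


def _core_geometry(spec: ContactSpec, bond_cn: float):
    s = np.zeros(3)
    n = np.array([spec.dist_sn, 0.0, 0.0])
    a = math.radians(spec.angle_csn)
    c_s = np.array([B_SG_CB * math.cos(a), B_SG_CB * math.sin(a), 0.0])
    c_n = place_atom(c_s, s, n, bond_cn, spec.angle_cns, spec.torsion)
    return s, n, c_s, c_n


def _build_atoms(spec: ContactSpec) -> tuple[list[_Atom], int, int]:
    """Atom list plus the residue numbers of the S- and N-bearing residues."""
    rn, natom = spec.n_residue.upper(), spec.n_atom.upper()
    sres, nres = 10, 2

    def scaffold_cys(s, n, c_s):
        ca = place_atom(n, s, c_s, B_C_C, 114.0, 180.0)
        nb = place_atom(s, c_s, ca, B_N_CA, 110.0, 180.0)
        cb = place_atom(s, c_s, ca, B_C_C, 110.0, -65.0)
        return [
            (sres, "CYS", "SG", "S", s, spec.occ_s, spec.bfac_pdb_s, spec.bfac_bdb_s),
            (sres, "CYS", "CB", "C", c_s, 1.0, 20.0, 22.0),
            (sres, "CYS", "CA", "C", ca, 1.0, 20.0, 22.0),
            (sres, "CYS", "N", "N", nb, 1.0, 20.0, 22.0),
            (sres, "CYS", "C", "C", cb, 1.0, 20.0, 22.0),
        ]

    if natom == "N":  # backbone nitrogen of any standard residue
        s, n, c_s, c_n = _core_geometry(spec, B_PEPTIDE_CN)
        ca2 = place_atom(s, c_n, n, B_N_CA, 121.0, 150.0)
        c2 = place_atom(c_n, n, ca2, B_C_C, 110.0, 180.0)
        o1 = place_atom(ca2, n, c_n, 1.23, 123.0, 180.0)
        ca1 = place_atom(ca2, n, c_n, B_C_C, 116.0, 0.0)
        atoms = [
            (1, "GLY", "C", "C", c_n, 1.0, 20.0, 22.0),
            (1, "GLY", "O", "O", o1, 1.0, 20.0, 22.0),
            (1, "GLY", "CA", "C", ca1, 1.0, 20.0, 22.0),
            (nres, rn, "N", "N", n, spec.occ_n, spec.bfac_pdb_n, spec.bfac_bdb_n),
            (nres, rn, "CA", "C", ca2, 1.0, 20.0, 22.0),
            (nres, rn, "C", "C", c2, 1.0, 20.0, 22.0),
        ]
    elif (rn, natom) == ("LYS", "NZ"):
        s, n, c_s, c_n = _core_geometry(spec, B_NZ_CE)  # c_n = CE
        cd = place_atom(s, n, c_n, 1.52, 111.0, 180.0)
        cg = place_atom(n, c_n, cd, 1.52, 111.0, 180.0)
        cb = place_atom(c_n, cd, cg, 1.52, 111.0, 180.0)
        ca = place_atom(cd, cg, cb, B_C_C, 111.0, 180.0)
        nb = place_atom(cg, cb, ca, B_N_CA, 110.0, 60.0)
        atoms = [
            (nres, "LYS", "NZ", "N", n, spec.occ_n, spec.bfac_pdb_n, spec.bfac_bdb_n),
            (nres, "LYS", "CE", "C", c_n, 1.0, 20.0, 22.0),
            (nres, "LYS", "CD", "C", cd, 1.0, 20.0, 22.0),
            (nres, "LYS", "CG", "C", cg, 1.0, 20.0, 22.0),
            (nres, "LYS", "CB", "C", cb, 1.0, 20.0, 22.0),
            (nres, "LYS", "CA", "C", ca, 1.0, 20.0, 22.0),
            (nres, "LYS", "N", "N", nb, 1.0, 20.0, 22.0),
        ]
    elif rn == "ARG" and natom in ("NE", "NH1"):
        s, n, c_s, c_n = _core_geometry(spec, B_NE_CZ)  # c_n = CZ
        # minimal guanidinium fragment: further side-chain nitrogens omitted
        # so exactly one acceptor is planted
        cd = place_atom(s, c_n, n, B_N_CA, 124.0, 160.0) if natom == "NE" else None
        ca = place_atom(s, c_n, n, 4.2, 150.0, 90.0)
        atoms = [
            (nres, "ARG", natom, "N", n, spec.occ_n, spec.bfac_pdb_n, spec.bfac_bdb_n),
            (nres, "ARG", "CZ", "C", c_n, 1.0, 20.0, 22.0),
            (nres, "ARG", "CA", "C", ca, 1.0, 20.0, 22.0),
        ]
        if cd is not None:
            atoms.append((nres, "ARG", "CD", "C", cd, 1.0, 20.0, 22.0))
    else:
        raise ConstructionError(f"unsupported pair class {rn}/{natom}")

    atoms.extend(scaffold_cys(s, n, c_s))
    return atoms, sres, nres


def _gemmi_structure(spec: ContactSpec, atoms: list[_Atom], use_bdb: bool) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = spec.pdb_id.upper()
    st.info["_exptl.method"] = spec.method
    ref = gemmi.RefinementInfo()
    ref.resolution_high = spec.resolution
    st.meta.refinement = [ref]
    st.resolution = spec.resolution
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for resnum in sorted({a[0] for a in atoms}):
        res_atoms = [a for a in atoms if a[0] == resnum]
        res = gemmi.Residue()
        res.name = res_atoms[0][1]
        res.seqid = gemmi.SeqId(resnum, " ")
        for _, _, name, element, pos, occ, b_pdb, b_bdb in res_atoms:
            if use_bdb and _is_omitted(spec, name):
                continue
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(element)
            at.pos = gemmi.Position(*np.round(pos, 6))
            at.occ = occ
            at.b_iso = b_bdb if use_bdb else b_pdb
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _is_omitted(spec: ContactSpec, atom_name: str) -> bool:
    return ("S" in spec.omit_bdb and atom_name == "SG") or (
        "N" in spec.omit_bdb and atom_name == spec.n_atom.upper()
    )


def _validation_xml(spec: ContactSpec, atoms: list[_Atom], sres: int, nres: int) -> str:
    import xml.etree.ElementTree as ET

    root = ET.Element("wwPDB-validation-information")
    entry = ET.SubElement(root, "Entry", pdbid=spec.pdb_id)
    rn = spec.n_residue.upper()
    for resnum, resname in sorted({(a[0], a[1]) for a in atoms}):
        attrs = {
            "chain": "A",
            "resnum": str(resnum),
            "icode": " ",
            "resname": resname,
        }
        rsrz = None
        if resnum == sres:
            rsrz = spec.rsrz_s
        elif resnum == nres:
            rsrz = spec.rsrz_n
        if rsrz is not None:
            attrs["rsrz"] = f"{rsrz:.2f}"
        sg = ET.SubElement(entry, "ModelledSubgroup", attrs)
        if spec.flag_close_contact:
            if resnum == sres:
                ET.SubElement(sg, "clash", cid="1", atom="SG", dist=f"{spec.dist_sn:.2f}")
            elif resnum == nres:
                ET.SubElement(sg, "clash", cid="1", atom=spec.n_atom.upper(),
                              dist=f"{spec.dist_sn:.2f}")
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def make_contact_structure(spec: ContactSpec) -> tuple[str, str, str]:
    """Render one spec into (mmCIF text, BDB PDB text, validation XML text)."""
    atoms, sres, nres = _build_atoms(spec)
    st = _gemmi_structure(spec, atoms, use_bdb=False)
    doc = st.make_mmcif_document()
    cif_text = doc.as_string()
    bdb_st = _gemmi_structure(spec, atoms, use_bdb=True)
    pdb_text = bdb_st.make_pdb_string()
    xml_text = _validation_xml(spec, atoms, sres, nres)
    return cif_text, pdb_text, xml_text


def expected_screening_outcome(
    spec: ContactSpec, cfg: ScreeningConfig | None = None
) -> tuple[str, str | None]:
    """Planted truth for one spec: ("retain", None) or ("reject", reason).

    Mirrors the screen's first-failure order: entry filters, then contact
    distance, then occupancy → RSRZ → BDB presence.
    """
    cfg = cfg or ScreeningConfig()
    if spec.method != "X-RAY DIFFRACTION":
        return "reject", "method"
    if spec.resolution > cfg.max_resolution:
        return "reject", "resolution"
    if spec.dist_sn > cfg.max_sn_dist + 1e-9:
        return "reject", "no_contact"
    if not (spec.occ_s > cfg.min_occupancy and spec.occ_n > cfg.min_occupancy):
        return "reject", "occupancy"
    if spec.rsrz_s is None or spec.rsrz_n is None:
        return "reject", "missing_rsrz"
    if not (spec.rsrz_s < cfg.max_rsrz and spec.rsrz_n < cfg.max_rsrz):
        return "reject", "rsrz"
    if spec.omit_bdb:
        return "reject", "bdb_missing"
    return "retain", None


def make_corpus(
    specs: list[ContactSpec],
    root: str | Path,
    cfg: ScreeningConfig | None = None,
) -> Path:
    """Write a corpus directory tree plus a manifest of planted expectations.

    Layout per entry: ``<id>/structure.cif``, ``<id>/bdb.pdb``,
    ``<id>/validation.xml``; ``manifest.json`` at the root records the
    expected screening decision for each entry under the given (default)
    thresholds.
    """
    root = Path(root)
    ids = [s.pdb_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pdb_id in corpus specs")
    manifest: dict[str, dict] = {}
    for spec in specs:
        cif, bdb, xml = make_contact_structure(spec)
        d = root / spec.pdb_id
        d.mkdir(parents=True, exist_ok=False)
        (d / "structure.cif").write_text(cif)
        (d / "bdb.pdb").write_text(bdb)
        (d / "validation.xml").write_text(xml)
        expect, reason = expected_screening_outcome(spec, cfg)
        manifest[spec.pdb_id] = {"expect": expect, "reason": reason}
    root.mkdir(parents=True, exist_ok=True)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return root


def read_manifest(root: str | Path) -> dict[str, dict]:
    return json.loads((Path(root) / "manifest.json").read_text())


@dataclass
class BlobSpec:
    """Planted-cluster descriptor matrix specification."""

    n_rows: tuple[int, ...] = (100, 100)       # per blob
    centers: np.ndarray | None = None          # (n_blobs, len(informative))
    spreads: tuple[float, ...] | None = None   # per blob, isotropic sigma
    informative: tuple[int, ...] = (0, 1, 2)   # descriptor indices carrying structure
    n_descriptors: int = 15
    n_reference: int = 74
    reference_blob: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_rows) < 1:
            raise ValueError("at least one blob required")
        if self.centers is None:
            # default: blobs spaced 20 sigma apart along every informative axis
            self.centers = np.array(
                [[20.0 * b] * len(self.informative) for b in range(len(self.n_rows))]
            )
        self.centers = np.asarray(self.centers, dtype=float)
        if self.spreads is None:
            self.spreads = tuple(1.0 for _ in self.n_rows)
        if self.centers.shape != (len(self.n_rows), len(self.informative)):
            raise ValueError("centers must be (n_blobs, n_informative)")
        if self.n_reference > sum(self.n_rows):
            raise ValueError("more reference rows than total rows")
        if not (0 <= self.reference_blob < len(self.n_rows)):
            raise ValueError("reference_blob out of range")


def make_descriptor_blobs(
    spec: BlobSpec,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Descriptor matrix with planted Gaussian blobs.

    Rows are drawn from isotropic Gaussians at the stated centers on the
    informative descriptor subset and i.i.d. standard normal noise on every
    other descriptor.  Reference rows are extra draws from their assigned
    blob and flagged.  Returns ``(matrix, ref_flags, planted_labels)``;
    the matrix carries ``DESCRIPTOR_COLUMNS`` plus a ``candidate_id``.
    """
    rng = np.random.default_rng(spec.seed)
    blocks, labels, flags = [], [], []
    for b, (n, sigma) in enumerate(zip(spec.n_rows, spec.spreads)):
        n_extra = spec.n_reference if b == spec.reference_blob else 0
        total = n + n_extra
        X = rng.standard_normal((total, spec.n_descriptors))
        X[:, list(spec.informative)] = (
            spec.centers[b] + sigma * rng.standard_normal((total, len(spec.informative)))
        )
        blocks.append(X)
        labels.extend([b] * total)
        flags.extend([False] * n + [True] * n_extra)
    X = np.vstack(blocks)
    labels = np.array(labels)
    flags = np.array(flags, dtype=bool)

    cols = DESCRIPTOR_COLUMNS[: spec.n_descriptors]
    if spec.n_descriptors > len(DESCRIPTOR_COLUMNS):
        cols = cols + [f"extra_{i}" for i in range(len(DESCRIPTOR_COLUMNS), spec.n_descriptors)]
    matrix = pd.DataFrame(X, columns=cols)
    matrix["candidate_id"] = [
        f"ref_{i}" if flags[i] else f"syn_{i}" for i in range(len(matrix))
    ]
    return matrix, flags, labels
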