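"""Shared fixtures: synthetic entries on disk and in-memory structures."""

from __future__ import annotations

import numpy as np
import pytest

from nosbond.config import ScreeningConfig
from nosbond.structure_io import AtomRecord, StructureModel
from nosbond.synthetic import ContactSpec, make_corpus


@pytest.fixture
def cfg() -> ScreeningConfig:
    return ScreeningConfig()


@pytest.fixture
def entry_factory(tmp_path):
    """Write one ContactSpec as a corpus entry; returns its directory."""
    counter = {"n": 0}

    def _make(spec: ContactSpec | None = None, **kwargs):
        if spec is None:
            counter["n"] += 1
            kwargs.setdefault("pdb_id", f"fx{counter['n']:02d}")
            spec = ContactSpec(**kwargs)
        root = tmp_path / f"corpus_{spec.pdb_id}"
        make_corpus([spec], root)
        return root / spec.pdb_id

    return _make


def make_atom(
    name: str,
    element: str,
    coords,
    resname: str = "GLY",
    resnum: int = 1,
    chain: str = "A",
    occ: float = 1.0,
    bfac: float = 20.0,
    icode: str = "",
    altloc: str = "",
) -> AtomRecord:
    return AtomRecord(
        atom_name=name,
        element=element,
        residue_name=resname,
        residue_number=resnum,
        icode=icode,
        chain_id=chain,
        altloc=altloc,
        coords=np.asarray(coords, dtype=float),
        occupancy=occ,
        bfactor=bfac,
    )


def make_structure(atoms, pdb_id="test", method="xray", resolution=1.5) -> StructureModel:
    return StructureModel(pdb_id=pdb_id, method=method, resolution=resolution, atoms=list(atoms))
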