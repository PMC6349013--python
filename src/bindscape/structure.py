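"""Reference-structure handling: PDB parsing, atom selectors, frame anchors.

A reference structure supplies three anchor atoms — the frame origin (e.g. the
pocket Zn2+) and two C-alpha axis anchors — plus the protein heavy-atom cloud
used by the bound-state distance criterion.  Parsing is delegated to biotite;
this module adds a small, validated selector language:

selector strings are comma-separated ``key=value`` pairs with keys

    chain     chain identifier
    res       residue id (integer)
    resname   residue name
    name      atom name (e.g. CA)
    element   element symbol (e.g. ZN)

e.g. ``"element=ZN"`` or ``"chain=A,res=706,name=CA"``.  A selector must
resolve to exactly one atom; anything else raises :class:`SelectorError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import SelectorError
from .geometry import ReferenceFrame, build_frame

__all__ = ["Selector", "StructureModel", "load_structure", "read_reference"]

_KEYS = ("chain", "res", "resname", "name", "element")


@dataclass(frozen=True)
class Selector:
    chain: str | None = None
    res: int | None = None
    resname: str | None = None
    name: str | None = None
    element: str | None = None

    @classmethod
    def parse(cls, text: str) -> "Selector":
        fields: dict = {}
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            if "=" not in part:
                raise SelectorError(f"malformed selector term {part!r} in {text!r}")
            key, value = (s.strip() for s in part.split("=", 1))
            if key not in _KEYS:
                raise SelectorError(
                    f"unknown selector key {key!r} in {text!r}; valid keys: {_KEYS}"
                )
            fields[key] = int(value) if key == "res" else value
        if not fields:
            raise SelectorError(f"empty selector: {text!r}")
        return cls(**fields)

    def __str__(self) -> str:
        parts = [f"{k}={getattr(self, k)}" for k in _KEYS if getattr(self, k) is not None]
        return ",".join(parts)


@dataclass
class StructureModel:
    """Atom records of one structure (coordinates in Å)."""

    atoms: struc.AtomArray

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.atoms.element != "H"

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.atoms.coord[self.heavy_mask]

    @property
    def ca_coords(self) -> np.ndarray:
        return self.atoms.coord[self.atoms.atom_name == "CA"]

    def select_one(self, selector: Selector) -> np.ndarray:
        """Coordinates of the unique atom matching ``selector``."""
        mask = np.ones(self.atoms.array_length(), dtype=bool)
        if selector.chain is not None:
            mask &= self.atoms.chain_id == selector.chain
        if selector.res is not None:
            mask &= self.atoms.res_id == selector.res
        if selector.resname is not None:
            mask &= self.atoms.res_name == selector.resname
        if selector.name is not None:
            mask &= self.atoms.atom_name == selector.name
        if selector.element is not None:
            mask &= self.atoms.element == selector.element.upper()
        n = int(mask.sum())
        if n == 0:
            raise SelectorError(f"selector {selector!s} matched no atom")
        if n > 1:
            raise SelectorError(f"selector {selector!s} is ambiguous ({n} atoms)")
        return self.atoms.coord[mask][0].astype(float)


def load_structure(pdb_path, model: int = 1) -> StructureModel:
    """Read one model of a PDB file into a :class:`StructureModel`."""
    pdb = PDBFile.read(str(pdb_path))
    atoms = pdb.get_structure(model=model)
    return StructureModel(atoms=atoms)


def read_reference(
    pdb_path,
    origin: Selector | str,
    x_anchor: Selector | str,
    y_anchor: Selector | str,
) -> tuple[StructureModel, ReferenceFrame]:
    """Load the reference PDB and build the anchored frame from selectors."""
    model = load_structure(pdb_path)
    sels = [
        s if isinstance(s, Selector) else Selector.parse(s)
        for s in (origin, x_anchor, y_anchor)
    ]
    o, ax, ay = (model.select_one(s) for s in sels)
    return model, build_frame(o, ax, ay)
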