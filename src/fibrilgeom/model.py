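"""Core in-memory representation of a fibril coordinate model.

A fibril model is a flat table of heavy atoms plus three pieces of
fibril-specific bookkeeping: the fibril axis (a unit vector, conventionally
+z for deposited amyloid structures), a mapping of each chain to a molecular
layer (one rung of the fibril), and a mapping of each chain to a protein
stack (one of the columns of subunits running along the fibril, labelled
"A" and "B").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA1_TO_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3_TO_AA1 = {v: k for k, v in AA1_TO_AA3.items()}

ATOM_COLUMNS = ["chain_id", "residue_number", "residue_name",
                "atom_name", "element", "x", "y", "z"]


class StructureError(ValueError):
    """Raised for unreadable or degenerate coordinate input."""


class LayerAssignmentError(ValueError):
    """Raised when chains cannot be unambiguously decomposed into
    layers and stacks."""


class AtomRecord(NamedTuple):
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class AxisConvention:
    """How the fibril axis is obtained.

    ``as_deposited_z`` trusts the file's frame (deposited fibril models are
    aligned with the helical axis on z).  ``pca_estimate`` takes the
    principal direction of the per-chain C-alpha centroids.  In either case
    the sign is fixed so the inter-layer translation (rise) is positive,
    which makes the twist sign alone carry handedness.
    """

    mode: str = "as_deposited_z"
    orientation_rule: str = "rise positive"

    def __post_init__(self):
        if self.mode not in ("as_deposited_z", "pca_estimate"):
            raise ValueError(f"unknown axis mode {self.mode!r}")


@dataclass
class FibrilModel:
    """Atomic model of a fibril segment.

    Parameters
    ----------
    atoms
        DataFrame with columns ``chain_id, residue_number, residue_name,
        atom_name, element, x, y, z`` (coordinates in Angstrom).
    axis
        Unit 3-vector of the fibril axis.
    layer_of
        chain_id -> 0-based layer index (contiguous from 0).
    stack_of
        chain_id -> stack label ("A" or "B").
    provenance
        Free-form record of how the model was obtained (file path or
        generator ground truth).
    """

    atoms: pd.DataFrame
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    layer_of: dict = field(default_factory=dict)
    stack_of: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if not np.isfinite(n) or n == 0:
            raise ValueError("fibril axis must be a finite nonzero vector")
        self.axis = self.axis / n
        if not np.isfinite(self.atoms[["x", "y", "z"]].to_numpy()).all():
            raise StructureError("non-finite atom coordinates")

    # -- basic accessors -------------------------------------------------

    @property
    def chains(self) -> list:
        """Chain identifiers in order of first appearance."""
        return list(dict.fromkeys(self.atoms["chain_id"]))

    @property
    def n_layers(self) -> int:
        return len(set(self.layer_of.values())) if self.layer_of else 0

    @property
    def stacks(self) -> list:
        return sorted(set(self.stack_of.values())) if self.stack_of else []

    def chain_atoms(self, chain_id: str) -> pd.DataFrame:
        sub = self.atoms[self.atoms["chain_id"] == chain_id]
        if sub.empty:
            raise KeyError(f"no chain {chain_id!r} in model")
        return sub

    def ca_table(self, chain_id: str) -> pd.DataFrame:
        """C-alpha rows of one chain, sorted by residue number."""
        sub = self.chain_atoms(chain_id)
        ca = sub[sub["atom_name"] == "CA"].sort_values("residue_number")
        return ca

    def ca_coords(self, chain_id: str):
        ca = self.ca_table(chain_id)
        return (ca["residue_number"].to_numpy(),
                ca[["x", "y", "z"]].to_numpy(dtype=float))

    def atom_xyz(self, chain_id: str, residue_number: int, atom_name: str) -> np.ndarray:
        sub = self.atoms[(self.atoms["chain_id"] == chain_id)
                         & (self.atoms["residue_number"] == residue_number)
                         & (self.atoms["atom_name"] == atom_name)]
        if sub.empty:
            raise KeyError(
                f"atom {atom_name} of residue {residue_number} chain {chain_id} absent")
        return sub[["x", "y", "z"]].to_numpy(dtype=float)[0]

    def chain_centroid(self, chain_id: str) -> np.ndarray:
        _, xyz = self.ca_coords(chain_id)
        if len(xyz) == 0:
            raise StructureError(f"chain {chain_id!r} has no C-alpha atoms")
        return xyz.mean(axis=0)

    def chains_in_layer(self, layer: int) -> list:
        return [c for c in self.chains if self.layer_of.get(c) == layer]

    def chains_in_stack(self, stack: str) -> list:
        return [c for c in self.chains if self.stack_of.get(c) == stack]

    def chain_for(self, layer: int, stack: str):
        for c in self.chains_in_layer(layer):
            if self.stack_of.get(c) == stack:
                return c
        return None

    def central_layer(self) -> int:
        """Index of the central layer (lower median for even layer counts)."""
        layers = sorted(set(self.layer_of.values()))
        if not layers:
            raise LayerAssignmentError("layers not assigned")
        return layers[(len(layers) - 1) // 2]

    # -- transforms ------------------------------------------------------

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Iterable[float] | None = None,
                    rotate_axis: bool = True) -> "FibrilModel":
        """Return a rigidly transformed copy (x' = R x + t)."""
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        axis = self.axis.copy()
        if rotation is not None:
            rotation = np.asarray(rotation, dtype=float)
            xyz = xyz @ rotation.T
            if rotate_axis:
                axis = rotation @ axis
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = xyz
        return replace(self, atoms=atoms, axis=axis,
                       layer_of=dict(self.layer_of), stack_of=dict(self.stack_of))

    def mirrored(self) -> "FibrilModel":
        """Reflect through the plane x = 0 (x -> -x).

        A mirror image inverts chirality: every backbone dihedral changes
        sign and the helical twist flips handedness.
        """
        atoms = self.atoms.copy()
        atoms["x"] = -atoms["x"].to_numpy()
        axis = self.axis.copy()
        axis[0] = -axis[0]
        return replace(self, atoms=atoms, axis=axis,
                       layer_of=dict(self.layer_of), stack_of=dict(self.stack_of))

    def subset_chains(self, chain_ids: Iterable[str]) -> "FibrilModel":
        keep = list(chain_ids)
        atoms = self.atoms[self.atoms["chain_id"].isin(keep)].reset_index(drop=True)
        return replace(self, atoms=atoms,
                       layer_of={c: v for c, v in self.layer_of.items() if c in keep},
                       stack_of={c: v for c, v in self.stack_of.items() if c in keep})

    # -- validation ------------------------------------------------------

    def validate_assignment(self) -> None:
        """Check layer/stack bookkeeping invariants."""
        chains = set(self.chains)
        if set(self.layer_of) != chains or set(self.stack_of) != chains:
            raise LayerAssignmentError("every chain needs one layer and one stack")
        layers = sorted(set(self.layer_of.values()))
        if layers != list(range(len(layers))):
            raise LayerAssignmentError(f"layer indices not contiguous from 0: {layers}")
        seen = set()
        for c in chains:
            key = (self.layer_of[c], self.stack_of[c])
            if key in seen:
                raise LayerAssignmentError(
                    f"more than one chain in layer {key[0]} stack {key[1]}")
            seen.add(key)


def atoms_frame(records: Iterable[AtomRecord]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=ATOM_COLUMNS)
    df["residue_number"] = df["residue_number"].astype(int)
    return df
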