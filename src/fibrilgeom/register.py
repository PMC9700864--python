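"""Axial register: z-shifts between reference C-alpha atoms.

The two AA fibril polymorphs differ in where the subunit N-terminus sits
along the fibril axis relative to the central part of the fold (reference
residue Tyr29): in the vascular fibril Ser2 lies below Tyr29, in the
glomerular fibril above.  These are signed axial coordinate differences,
with "lower" meaning a smaller coordinate along the axis oriented so the
rise is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FibrilModel


@dataclass
class AxialShift:
    chain_id: str
    residue_a: int
    residue_b: int
    shift_A: float  # axial coord of residue_a's CA minus residue_b's

    @property
    def label(self) -> str:
        if self.shift_A == 0:
            return "level"
        return "lower" if self.shift_A < 0 else "higher"


def axial_shift(model: FibrilModel, chain_id: str,
                residue_a: int, residue_b: int) -> AxialShift:
    """Signed axial displacement of residue_a's C-alpha relative to
    residue_b's in one chain (negative = residue_a lower)."""
    pa = model.atom_xyz(chain_id, residue_a, "CA")
    pb = model.atom_xyz(chain_id, residue_b, "CA")
    shift = float(np.dot(pa - pb, model.axis))
    return AxialShift(chain_id, residue_a, residue_b, shift)


def axial_shift_report(model: FibrilModel, residue_a: int, residue_b: int):
    """Per-chain axial shifts for every chain containing both residues."""
    out = []
    for c in model.chains:
        try:
            out.append(axial_shift(model, c, residue_a, residue_b))
        except KeyError:
            continue
    return out


def estimate_rise(model: FibrilModel) -> float:
    """Median axial spacing of consecutive layer C-alpha centroids."""
    layers = sorted(set(model.layer_of.values()))
    if len(layers) < 2:
        raise ValueError("rise estimate needs at least 2 layers")
    z = []
    for layer in layers:
        chains = model.chains_in_layer(layer)
        cents = np.array([model.chain_centroid(c) for c in chains])
        z.append(float(np.dot(cents.mean(axis=0), model.axis)))
    return float(np.median(np.diff(sorted(z))))


def stack_stagger(model: FibrilModel, reference_residue: int,
                  rise_A: float | None = None) -> float:
    """Axial offset of stack B relative to stack A at a reference residue.

    Measured in the central layer, reported modulo the rise and mapped to
    (-rise/2, rise/2]; a value near +-rise/2 indicates half-layer stagger
    of the two stacks.
    """
    if len(model.stacks) < 2:
        raise ValueError("stack stagger needs a two-stack model")
    rise = rise_A if rise_A is not None else estimate_rise(model)
    layer = model.central_layer()
    chain_a = model.chain_for(layer, "A")
    chain_b = model.chain_for(layer, "B")
    if chain_a is None or chain_b is None:
        raise ValueError(f"central layer {layer} lacks a chain in one stack")
    za = float(np.dot(model.atom_xyz(chain_a, reference_residue, "CA"), model.axis))
    zb = float(np.dot(model.atom_xyz(chain_b, reference_residue, "CA"), model.axis))
    off = (zb - za) % rise
    if off > rise / 2:
        off -= rise
    if np.isclose(off, -rise / 2):
        off = rise / 2
    return float(off)
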