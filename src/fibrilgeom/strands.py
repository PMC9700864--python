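"""Beta-sheet residue flagging and strand segmentation.

The default criterion is a Ramachandran window: a residue is beta when its
Phi falls in [-180, -30] and its Psi in the (wrapped) beta branch
[60, 180] u (-180, -150].  This is deliberately a single-chain criterion:
in an amyloid fibril the cross-beta partners of a strand live in the
axially adjacent layers, not in the same chain, so DSSP-style H-bond
assignment on an isolated chain sees no sheet at all.  An alternative
cross-layer hydrogen-bond mode and an explicit segments-file bypass are
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import DihedralRecord
from .model import FibrilModel


@dataclass
class BetaWindow:
    """Dihedral window defining the beta region.

    ``psi_ranges`` is a union of intervals on the wrapped circle, which
    lets the beta region cross the +-180 seam.
    """

    phi_range: tuple = (-180.0, -30.0)
    psi_ranges: tuple = ((60.0, 180.0), (-180.0, -150.0))

    def contains(self, phi: float | None, psi: float | None) -> bool:
        if phi is None or psi is None:
            return False
        if not (self.phi_range[0] <= phi <= self.phi_range[1]):
            return False
        return any(lo <= psi <= hi for lo, hi in self.psi_ranges)


@dataclass
class StrandSegment:
    chain_id: str
    start_residue: int
    end_residue: int
    length: int = field(init=False)

    def __post_init__(self):
        if self.start_residue > self.end_residue:
            raise ValueError("segment start after end")
        self.length = self.end_residue - self.start_residue + 1


def classify_beta(records: Sequence[DihedralRecord],
                  window: BetaWindow | None = None) -> list[DihedralRecord]:
    """Return copies of the records with ``is_beta`` set from the dihedral
    window.  Residues with undefined angles are never beta."""
    window = window or BetaWindow()
    return [replace(r, is_beta=window.contains(r.phi_deg, r.psi_deg))
            for r in records]


def segment_strands(records: Sequence[DihedralRecord],
                    min_length: int = 2,
                    max_gap: int = 1) -> list[StrandSegment]:
    """Segment beta-flagged residues of one chain into strands.

    Maximal runs of beta residues are found; runs separated by at most
    ``max_gap`` non-beta residues are merged (the merged segment spans the
    gap); merged runs shorter than ``min_length`` are dropped.  Gaps in
    the residue numbering are treated as hard breaks.
    """
    if not records:
        return []
    chains = {r.chain_id for r in records}
    if len(chains) > 1:
        out = []
        for c in sorted(chains):
            out.extend(segment_strands(
                [r for r in records if r.chain_id == c], min_length, max_gap))
        return out
    chain_id = records[0].chain_id
    recs = sorted(records, key=lambda r: r.residue_number)

    runs = []  # [start_resnum, end_resnum] of merged beta stretches
    for r in recs:
        if not r.is_beta:
            continue
        if (runs
                and r.residue_number - runs[-1][1] - 1 <= max_gap
                and _contiguous(recs, runs[-1][1], r.residue_number)):
            runs[-1][1] = r.residue_number
        else:
            runs.append([r.residue_number, r.residue_number])
    segs = [StrandSegment(chain_id, a, b) for a, b in runs]
    return [s for s in segs if s.length >= min_length]


def _contiguous(recs, a: int, b: int) -> bool:
    """True when every residue number in (a, b) is present in the chain
    (no numbering gap)."""
    present = {r.residue_number for r in recs}
    return all(n in present for n in range(a + 1, b))


def hydrogen_bond_beta(model: FibrilModel, chain_id: str,
                       cutoff_A: float = 3.5) -> dict[int, bool]:
    """Cross-layer hydrogen-bond beta criterion.

    A residue is flagged beta when the backbone N-O distance between it
    and the same-numbered residue of the axially adjacent chain (same
    stack, layer above or below) is under ``cutoff_A`` on either side.
    This is a simplified cross-beta criterion: it ignores H-bond energies
    and the one-residue register shifts real sheets can have.
    """
    layer = model.layer_of.get(chain_id)
    stack = model.stack_of.get(chain_id)
    if layer is None or stack is None:
        raise ValueError(f"chain {chain_id!r} has no layer/stack assignment")
    neighbors = [c for c in (model.chain_for(layer - 1, stack),
                             model.chain_for(layer + 1, stack)) if c is not None]
    if not neighbors:
        raise ValueError(
            f"chain {chain_id!r} has no axially adjacent chains; use the "
            "dihedral beta criterion for isolated chains")
    own = _backbone_no(model, chain_id)
    flags = {}
    for resnum, (n_own, o_own) in own.items():
        hit = False
        for nb in neighbors:
            other = _backbone_no(model, nb).get(resnum)
            if other is None:
                continue
            n_nb, o_nb = other
            pairs = [(n_own, o_nb), (o_own, n_nb)]
            if any(p is not None and q is not None
                   and np.linalg.norm(p - q) < cutoff_A for p, q in pairs):
                hit = True
                break
        flags[resnum] = hit
    return flags


def _backbone_no(model, chain_id):
    sub = model.chain_atoms(chain_id)
    out = {}
    for resnum, grp in sub.groupby("residue_number", sort=True):
        pos = {row.atom_name: np.array([row.x, row.y, row.z])
               for row in grp.itertuples() if row.atom_name in ("N", "O")}
        out[int(resnum)] = (pos.get("N"), pos.get("O"))
    return out


def read_segments_tsv(path) -> list[StrandSegment]:
    """Explicit strand definitions: TSV with columns chain_id,
    start_residue, end_residue (1-based, inclusive)."""
    df = pd.read_csv(Path(path), sep="\t")
    need = {"chain_id", "start_residue", "end_residue"}
    if not need <= set(df.columns):
        raise ValueError(f"segments file must have columns {sorted(need)}")
    return [StrandSegment(str(r.chain_id), int(r.start_residue), int(r.end_residue))
            for r in df.itertuples()]


def apply_segments(records: Sequence[DihedralRecord],
                   segments: Sequence[StrandSegment]) -> list[DihedralRecord]:
    """Set is_beta from an explicit segment list."""
    spans = {}
    for s in segments:
        spans.setdefault(s.chain_id, []).append((s.start_residue, s.end_residue))
    return [replace(r, is_beta=any(a <= r.residue_number <= b
                                   for a, b in spans.get(r.chain_id, ())))
            for r in records]
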