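"""Reading, writing and layer/stack decomposition of fibril models.

Coordinate files (PDB or mmCIF) are parsed with gemmi.  Only protein heavy
atoms are kept: hydrogens, waters and non-amino-acid heterogens are
dropped, and alternate conformations are resolved to the highest-occupancy
location (ties broken by altloc identifier order).  Author residue
numbering is used verbatim, since fibril papers refer to precursor
positions (Ser2, Tyr29, ...).

Layer/stack decomposition
-------------------------
Deposited fibril models contain an explicit stack of molecular layers,
each layer holding one chain per protein stack.  Chains are grouped into
stacks first -- by residue-range signature when the two stacks are
non-equal (as in the vascular AA fibril), otherwise by clustering their
cross-sectional centroids -- and then layers are the per-stack axial
ranks, aligned across stacks by nearest axial position.  This is robust to
staggered stacks, where a naive one-dimensional clustering of axial
centroids would see evenly spaced chains and no layer gaps at all.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import gemmi
import numpy as np

from .model import (
    ATOM_COLUMNS,
    AtomRecord,
    AxisConvention,
    FibrilModel,
    LayerAssignmentError,
    STANDARD_AA3,
    StructureError,
    atoms_frame,
)

log = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "DOD", "WAT"}


def load_structure(path, fmt: str = "auto",
                   convention: AxisConvention | None = None) -> FibrilModel:
    """Read a fibril coordinate model from PDB or mmCIF.

    Parameters
    ----------
    path
        Coordinate file.
    fmt
        ``pdb``, ``mmcif`` or ``auto`` (detect from contents/extension).
    convention
        Axis convention; the default trusts the deposited frame (axis = z).

    Returns
    -------
    FibrilModel with the axis set and layers/stacks assigned.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    convention = convention or AxisConvention()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    records, nonstandard = _extract_atoms(st)
    if not records:
        raise StructureError(f"{path}: no protein heavy atoms found")
    for name in sorted(nonstandard):
        log.warning("nonstandard residue %s kept (flagged)", name)

    model = FibrilModel(atoms=atoms_frame(records),
                        provenance={"source": str(path), "format": fmt,
                                    "nonstandard_residues": sorted(nonstandard)})
    _check_backbone(model)
    if convention.mode == "pca_estimate":
        model.axis = estimate_axis(model, convention)
    model = assign_layers(model)
    return model


def _extract_atoms(st: gemmi.Structure):
    """First model only; heavy protein atoms; best altloc per atom."""
    records = []
    nonstandard = set()
    if len(st) == 0:
        return records, nonstandard
    for chain in st[0]:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if res.name in _WATER_NAMES:
                continue
            if info is None or not info.is_amino_acid():
                continue
            if res.name not in STANDARD_AA3:
                nonstandard.add(res.name)
            best = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                # highest occupancy wins; ties by altloc identifier order
                key = (-atom.occ, atom.altloc or "~")
                if prev is None or key < prev[0]:
                    best[atom.name] = (key, atom)
            for _, atom in best.values():
                records.append(AtomRecord(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    residue_name=res.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    x=atom.pos.x, y=atom.pos.y, z=atom.pos.z))
    return records, nonstandard


def _check_backbone(model: FibrilModel) -> None:
    """Require at least one chain with 3+ consecutive backbone-complete residues."""
    for chain in model.chains:
        sub = model.chain_atoms(chain)
        ok = 0
        for _, grp in sub.groupby("residue_number"):
            names = set(grp["atom_name"])
            if {"N", "CA", "C"} <= names:
                ok += 1
                if ok >= 3:
                    return
            else:
                ok = 0
    raise StructureError("no chain with >=3 consecutive backbone-complete residues")


def estimate_axis(model: FibrilModel,
                  convention: AxisConvention | None = None) -> np.ndarray:
    """Estimate the fibril axis.

    ``as_deposited_z`` returns +z.  ``pca_estimate`` returns the principal
    direction of the per-chain C-alpha centroids (which march along the
    axis), signed so its largest-magnitude component is positive; layer
    ordering along the axis then makes the rise positive by construction.
    """
    convention = convention or AxisConvention()
    if convention.mode == "as_deposited_z":
        return np.array([0.0, 0.0, 1.0])
    cents = np.array([model.chain_centroid(c) for c in model.chains])
    if len(cents) < 2:
        raise StructureError("pca_estimate needs at least 2 chains/layers")
    cents = cents - cents.mean(axis=0)
    _, _, vt = np.linalg.svd(cents, full_matrices=False)
    axis = vt[0]
    i = int(np.argmax(np.abs(axis)))
    if axis[i] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


# ---------------------------------------------------------------------------
# layer / stack assignment


def assign_layers(model: FibrilModel) -> FibrilModel:
    """Fill the chain -> layer and chain -> stack maps.

    Deterministic given the model; invariant to the order in which chains
    appear in the file.  Raises :class:`LayerAssignmentError` with a
    diagnostic listing of axial centroid positions when the decomposition
    is ambiguous.
    """
    chains = sorted(model.chains)
    axis = model.axis
    cents = {c: model.chain_centroid(c) for c in chains}
    z = {c: float(np.dot(cents[c], axis)) for c in chains}

    if len(chains) == 1:
        model.layer_of = {chains[0]: 0}
        model.stack_of = {chains[0]: "A"}
        return model

    stacks = _split_stacks(model, chains, cents, z)
    _check_spacing(stacks, z)
    layer_of, stack_of = _rank_layers(stacks, z)
    model.layer_of = layer_of
    model.stack_of = stack_of
    model.validate_assignment()
    return model


def _split_stacks(model, chains, cents, z):
    """Partition chains into 1 or 2 stacks; returns {label: [chains]}."""
    # non-equal stacks: distinguishable by residue-number signature
    sigs = {}
    for c in chains:
        resnums = model.ca_table(c)["residue_number"].to_numpy()
        sigs[c] = (int(resnums.min()), int(resnums.max()), len(resnums))
    uniq = sorted(set(sigs.values()))
    if len(uniq) == 2:
        counts = [sum(1 for c in chains if sigs[c] == u) for u in uniq]
        if counts[0] == counts[1]:
            # stack A = the stack of shorter subunits (fewer residues)
            uniq.sort(key=lambda u: (u[2], u))
            return {"A": [c for c in chains if sigs[c] == uniq[0]],
                    "B": [c for c in chains if sigs[c] == uniq[1]]}
    if len(uniq) > 2:
        raise LayerAssignmentError(
            f"more than two residue-range signatures among chains: {uniq}")

    # equal stacks: cluster cross-sectional centroids
    axis = model.axis
    cross = {c: cents[c] - np.dot(cents[c], axis) * axis for c in chains}
    pts = np.array([cross[c] for c in chains])
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    if d.max() < 3.0:
        return {"A": list(chains)}
    # deterministic 2-means seeded with the farthest pair
    i, j = np.unravel_index(np.argmax(d), d.shape)
    centers = pts[[min(i, j), max(i, j)]]
    for _ in range(50):
        lab = np.argmin(np.linalg.norm(pts[:, None, :] - centers[None], axis=-1), axis=1)
        new = np.array([pts[lab == k].mean(axis=0) for k in (0, 1)])
        if np.allclose(new, centers):
            break
        centers = new
    g0 = [c for c, l in zip(chains, lab) if l == 0]
    g1 = [c for c, l in zip(chains, lab) if l == 1]
    if not g0 or not g1 or abs(len(g0) - len(g1)) > 1:
        raise LayerAssignmentError(
            "ambiguous stack decomposition; axial centroids: "
            + ", ".join(f"{c}:{z[c]:.2f}" for c in chains))
    spread = max(np.linalg.norm(pts[lab == k] - centers[k], axis=1).max()
                 for k in (0, 1))
    sep = np.linalg.norm(centers[0] - centers[1])
    if sep < 2.0 * max(spread, 0.5):
        raise LayerAssignmentError(
            f"stack clusters not separated (sep {sep:.2f} A, spread {spread:.2f} A); "
            "axial centroids: " + ", ".join(f"{c}:{z[c]:.2f}" for c in chains))
    # label deterministically: stack A contains the lexicographically first chain
    if min(g1) < min(g0):
        g0, g1 = g1, g0
    return {"A": g0, "B": g1}


def _check_spacing(stacks, z):
    """Within each stack the chains must be evenly spaced along the axis;
    strongly bimodal spacings mean two interleaved stacks were merged (for
    example, exactly superposed staggered stacks) and the decomposition is
    ambiguous."""
    for label, cs in stacks.items():
        zs = sorted(z[c] for c in cs)
        gaps = np.diff(zs)
        if len(gaps) >= 2 and gaps.min() > 0 and gaps.max() > 2.0 * gaps.min():
            raise LayerAssignmentError(
                f"uneven axial spacing within stack {label} "
                f"(gaps {gaps.round(2).tolist()}); clustering is ambiguous; "
                "axial centroids: "
                + ", ".join(f"{c}:{z[c]:.2f}" for c in sorted(cs, key=z.get)))


def _rank_layers(stacks, z):
    """Axial rank within each stack; align stack B ranks to stack A by
    nearest axial position."""
    order = {lab: sorted(cs, key=lambda c: (z[c], c)) for lab, cs in stacks.items()}
    layer_of, stack_of = {}, {}
    ref = order.get("A", [])
    for r, c in enumerate(ref):
        layer_of[c] = r
        stack_of[c] = "A"
    if "B" in order:
        zb = [z[c] for c in order["B"]]
        za = [z[c] for c in ref]
        best_off, best_cost = 0, np.inf
        for off in (-1, 0, 1):
            cost, ok = 0.0, True
            for r, zc in enumerate(zb):
                ra = r + off
                if 0 <= ra < len(za):
                    cost += abs(zc - za[ra])
                else:
                    ok = False
            if ok and cost < best_cost:
                best_off, best_cost = off, cost
        for r, c in enumerate(order["B"]):
            layer_of[c] = r + best_off
            stack_of[c] = "B"
        lo = min(layer_of.values())
        layer_of = {c: v - lo for c, v in layer_of.items()}
    return layer_of, stack_of


# ---------------------------------------------------------------------------
# writing


def write_pdb(model: FibrilModel, path, sidecar: bool = True) -> None:
    """Write the model as a PDB file, plus a JSON sidecar with the
    layer/stack assignment and any generator ground truth."""
    st = gemmi.Structure()
    st.name = "fibrilgeom"
    md = gemmi.Model("1")
    for chain_id in model.chains:
        ch = gemmi.Chain(chain_id)
        sub = model.chain_atoms(chain_id)
        for resnum, grp in sub.groupby("residue_number", sort=True):
            res = gemmi.Residue()
            res.name = str(grp["residue_name"].iloc[0])
            res.seqid = gemmi.SeqId(int(resnum), " ")
            for row in grp.itertuples():
                at = gemmi.Atom()
                at.name = row.atom_name
                at.element = gemmi.Element(row.element)
                at.pos = gemmi.Position(row.x, row.y, row.z)
                at.occ = 1.0
                res.add_atom(at)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))
    if sidecar:
        write_assignment_json(model, Path(path).with_suffix(".json"))


def write_assignment_json(model: FibrilModel, path) -> None:
    payload = {
        "axis": [float(v) for v in model.axis],
        "chains": model.chains,
        "layer_of": {c: int(v) for c, v in model.layer_of.items()},
        "stack_of": dict(model.stack_of),
        "provenance": _jsonable(model.provenance),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
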