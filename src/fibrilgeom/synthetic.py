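"""Synthetic fibril models with known ground truth.

Every analysis in this package can be exercised without external
coordinate files: an ideal-geometry backbone builder produces a strand
with exactly prescribed (Phi, Psi), and a helical assembler stacks copies
of it into a fibril with prescribed signed twist, rise, inter-stack
stagger and symmetry.  The generated models are geometric idealizations:
bond lengths and angles are canonical, omega is fixed trans, side chains
stop at C-beta, and no steric or hydrogen-bond optimization is performed.

Presets emulating the two renal AA amyloid polymorphs are provided.  The
vascular-variant fibril has two non-equal stacks (serum amyloid A1
residues 2-40 and 2-69), C1 symmetry, a left-hand twist giving a ~52 nm
crossover at a 4.8 A rise, and beta backbones whose delta = Psi + Phi
matches the reported per-stack means (+12 and +11 deg).  The
glomerular-variant fibril has two equal stacks (residues 2-55),
pseudo-2_1 screw symmetry (stack B rotated 180 deg and shifted half a
rise) and a right-hand twist with delta = -2 deg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AA1_TO_AA3, AtomRecord, FibrilModel, atoms_frame

# ideal backbone geometry (Engh-Huber-style values), Angstrom / degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 110.1
IMPROPER_N_C_CA_CB = -122.6  # L-amino-acid branch

# Mature human serum amyloid A1, SAA1.1 allele (104 residues; position 1 = Arg,
# so the fibril proteins starting at Ser2 lack only the N-terminal arginine).
SAA1_1_MATURE = (
    "RSFFSFLGEAFDGARDMWRAYSDMREANYIGSDKYFHARGNYDAAKRGPGGVWAAEAISD"
    "ARENIQRFFGHGAEDSLADQAANEWGRSGKDPNHFRPAGLPEKY"
)


@dataclass
class GeneratorSpec:
    """Ground-truth parameters of a synthetic fibril.

    Scalars for ``phi_deg``/``psi_deg`` apply to every residue; lists give
    per-residue values (first Phi and last Psi are undefined by
    construction and their entries are ignored).
    """

    sequence: str
    phi_deg: float | list = -120.0
    psi_deg: float | list = 132.0
    omega_deg: float = 180.0
    twist_deg_per_layer: float = -1.66
    rise_A: float = 4.8
    n_layers: int = 6
    n_stacks: int = 1
    stagger_A: float = 0.0
    symmetry: str = "C1"  # C1 | pseudo_21
    stack_offset_xy: tuple = (0.0, 0.0)  # in-plane offset of stack B (C1 only)
    noise_sd_A: float = 0.0
    seed: int = 0
    residue_start: int = 1  # author number of the first residue

    def __post_init__(self):
        if self.rise_A <= 0:
            raise ValueError("rise_A must be positive")
        if abs(self.twist_deg_per_layer) >= 180:
            raise ValueError("|twist| must be < 180 deg")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.n_stacks not in (1, 2):
            raise ValueError("n_stacks must be 1 or 2")
        if self.noise_sd_A < 0:
            raise ValueError("noise_sd_A must be >= 0")
        if self.symmetry not in ("C1", "pseudo_21"):
            raise ValueError("symmetry must be C1 or pseudo_21")
        for i, aa in enumerate(self.sequence):
            if aa not in AA1_TO_AA3:
                raise ValueError(
                    f"non-standard amino-acid letter {aa!r} at position {i + 1}")

    def angles(self, name: str) -> np.ndarray:
        v = getattr(self, name)
        n = len(self.sequence)
        if np.isscalar(v):
            return np.full(n, float(v))
        v = np.asarray(v, dtype=float)
        if len(v) != n:
            raise ValueError(f"{name} list length {len(v)} != sequence length {n}")
        return v


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement: the point d with |c-d| = bond, angle(b,c,d) =
    angle_deg and dihedral(a,b,c,d) = torsion_deg."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d2 = bond * np.array([-np.cos(ang), np.sin(ang) * np.cos(tor),
                          np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_strand(spec: GeneratorSpec, chain_id: str = "A") -> FibrilModel:
    """Build one chain with ideal covalent geometry and exactly the
    requested backbone dihedrals (N, CA, C, O, and CB except glycine)."""
    seq = spec.sequence
    if len(seq) < 3:
        raise ValueError("sequence must have at least 3 residues")
    phi = spec.angles("phi_deg")
    psi = spec.angles("psi_deg")
    omega = spec.omega_deg

    N = np.zeros((len(seq), 3))
    CA = np.zeros_like(N)
    C = np.zeros_like(N)
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, len(seq)):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N,
                      psi[i - 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega)
        C[i] = _place(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi[i])

    records = []
    for i, aa in enumerate(seq):
        resnum = spec.residue_start + i
        resname = AA1_TO_AA3[aa]
        tor_o = (psi[i] - 180.0) if i + 1 < len(seq) else 180.0
        O = _place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, tor_o)
        for name, pos, elem in (("N", N[i], "N"), ("CA", CA[i], "C"),
                                ("C", C[i], "C"), ("O", O, "O")):
            records.append(AtomRecord(chain_id, resnum, resname, name, elem,
                                      *pos))
        if aa != "G":
            CB = _place(N[i], C[i], CA[i], BOND_CA_CB, ANGLE_C_CA_CB,
                        IMPROPER_N_C_CA_CB)
            records.append(AtomRecord(chain_id, resnum, resname, "CB", "C", *CB))
    model = FibrilModel(atoms=atoms_frame(records),
                        layer_of={chain_id: 0}, stack_of={chain_id: "A"},
                        provenance={"generator": asdict(spec)})
    return model


def _rot_z(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def build_fibril(spec: GeneratorSpec) -> FibrilModel:
    """Assemble a helical fibril from the strand defined by ``spec``.

    Layer i of stack A is the strand rotated by i * twist about +z
    (right-hand rule) and translated by i * rise along +z.  Stack B, when
    present, is the strand shifted axially by ``stagger_A`` (and rotated
    180 deg about the axis for pseudo-2_1 symmetry, or shifted in-plane by
    ``stack_offset_xy`` for C1) before the same per-layer transforms.
    Gaussian noise of sd ``noise_sd_A`` is added i.i.d. per coordinate
    after assembly, seeded by ``spec.seed``.
    """
    strand = build_strand(spec)
    base = {"A": strand.atoms[["x", "y", "z"]].to_numpy(dtype=float)}
    if spec.n_stacks == 2:
        xyz = base["A"].copy()
        if spec.symmetry == "pseudo_21":
            # half the per-layer twist on top of the 180 deg flip makes the
            # two-stack assembly an exact screw when stagger = rise/2
            xyz = xyz @ _rot_z(180.0 + spec.twist_deg_per_layer / 2.0).T
        else:
            xyz = xyz + np.array([*spec.stack_offset_xy, 0.0])
        xyz = xyz + np.array([0.0, 0.0, spec.stagger_A])
        base["B"] = xyz

    frames = []
    layer_of, stack_of, transforms = {}, {}, {}
    k = 0
    for layer in range(spec.n_layers):
        R = _rot_z(layer * spec.twist_deg_per_layer)
        t = np.array([0.0, 0.0, layer * spec.rise_A])
        for stack in (["A", "B"] if spec.n_stacks == 2 else ["A"]):
            chain_id = _CHAIN_IDS[k]
            k += 1
            atoms = strand.atoms.copy()
            atoms["chain_id"] = chain_id
            atoms[["x", "y", "z"]] = base[stack] @ R.T + t
            frames.append(atoms)
            layer_of[chain_id] = layer
            stack_of[chain_id] = stack
            transforms[chain_id] = {"layer": layer, "stack": stack,
                                    "twist_deg": layer * spec.twist_deg_per_layer,
                                    "rise_A": layer * spec.rise_A
                                    + (spec.stagger_A if stack == "B" else 0.0)}
    atoms = pd.concat(frames, ignore_index=True)
    if spec.noise_sd_A > 0:
        rng = np.random.default_rng(spec.seed)
        atoms[["x", "y", "z"]] += rng.normal(
            0.0, spec.noise_sd_A, size=(len(atoms), 3))
    return FibrilModel(atoms=atoms, layer_of=layer_of, stack_of=stack_of,
                       provenance={"generator": asdict(spec),
                                   "chain_transforms": transforms})


def combine_stacks(model_a: FibrilModel, model_b: FibrilModel) -> FibrilModel:
    """Merge two single-stack fibrils (layer-aligned) into one two-stack
    model; model_b's chains are relabelled and become stack B.

    Used to build fibrils whose two stacks carry different sequences, as
    in the vascular AA polymorph.
    """
    used = list(model_a.chains)
    rename = {}
    pool = [c for c in _CHAIN_IDS if c not in used]
    for c in model_b.chains:
        rename[c] = pool.pop(0)
    atoms_b = model_b.atoms.copy()
    atoms_b["chain_id"] = atoms_b["chain_id"].map(rename)
    atoms = pd.concat([model_a.atoms, atoms_b], ignore_index=True)
    layer_of = dict(model_a.layer_of)
    stack_of = {c: "A" for c in model_a.chains}
    for c, new in rename.items():
        layer_of[new] = model_b.layer_of[c]
        stack_of[new] = "B"
    return FibrilModel(atoms=atoms, axis=model_a.axis,
                       layer_of=layer_of, stack_of=stack_of,
                       provenance={"combined": [model_a.provenance,
                                                model_b.provenance]})


# ---------------------------------------------------------------------------
# study-condition presets

VASCULAR_TWIST_DEG = -1.66   # left-handed; 52 nm crossover at 4.8 A rise
GLOMERULAR_TWIST_DEG = 1.66  # right-handed
RISE_A = 4.8

# beta-region backbones with delta = Psi + Phi at the reported per-stack means
VASCULAR_PHI_PSI_A = (-123.0, 135.0)   # delta = +12 deg (stack A)
VASCULAR_PHI_PSI_B = (-124.0, 135.0)   # delta = +11 deg (stack B)
GLOMERULAR_PHI_PSI = (-137.0, 135.0)   # delta = -2 deg


def vascular_like_model(n_layers: int = 6, noise_sd_A: float = 0.0,
                        seed: int = 0) -> FibrilModel:
    """Synthetic stand-in for the vascular AA fibril: two non-equal stacks
    (SAA1.1 residues 2-40 and 2-69), C1 symmetry, left-hand twist."""
    common = dict(twist_deg_per_layer=VASCULAR_TWIST_DEG, rise_A=RISE_A,
                  n_layers=n_layers, n_stacks=1, residue_start=2,
                  noise_sd_A=noise_sd_A)
    spec_a = GeneratorSpec(sequence=SAA1_1_MATURE[1:40],
                           phi_deg=VASCULAR_PHI_PSI_A[0],
                           psi_deg=VASCULAR_PHI_PSI_A[1],
                           seed=seed, **common)
    spec_b = GeneratorSpec(sequence=SAA1_1_MATURE[1:69],
                           phi_deg=VASCULAR_PHI_PSI_B[0],
                           psi_deg=VASCULAR_PHI_PSI_B[1],
                           seed=seed + 1, **common)
    fib_a = build_fibril(spec_a)
    fib_b = build_fibril(spec_b).transformed(
        translation=(0.0, 14.0, 2.4))  # side by side, staggered half a rise
    return combine_stacks(fib_a, fib_b)


def glomerular_like_model(n_layers: int = 6, noise_sd_A: float = 0.0,
                          seed: int = 0) -> FibrilModel:
    """Synthetic stand-in for the glomerular AA fibril: two equal stacks
    (SAA1.1 residues 2-55), pseudo-2_1 symmetry, right-hand twist."""
    spec = GeneratorSpec(sequence=SAA1_1_MATURE[1:55],
                         phi_deg=GLOMERULAR_PHI_PSI[0],
                         psi_deg=GLOMERULAR_PHI_PSI[1],
                         twist_deg_per_layer=GLOMERULAR_TWIST_DEG,
                         rise_A=RISE_A, n_layers=n_layers, n_stacks=2,
                         stagger_A=RISE_A / 2, symmetry="pseudo_21",
                         residue_start=2, noise_sd_A=noise_sd_A, seed=seed)
    return build_fibril(spec)


# ---------------------------------------------------------------------------
# mass-spectrometry fixture


def make_mass_fixture(precursor: str, start: int, end_range,
                      ppm_jitter: float = 0.0, seed: int = 0):
    """Observed-mass fixture for the fragment matcher.

    Emits the monoisotopic mass of precursor[start..e] for every e in
    ``end_range`` (1-based inclusive positions), each perturbed
    multiplicatively by (1 + u * 1e-6) with u uniform in
    [-ppm_jitter, +ppm_jitter].

    Returns (observed_masses, truth) where truth is the list of
    (start, end) ground-truth ranges in emission order.
    """
    from .fragments import peptide_mass

    ends = list(end_range)
    if not ends:
        raise ValueError("end_range is empty")
    if not (2 <= start <= min(ends)):
        raise ValueError("need 2 <= start <= min(end_range)")
    if max(ends) > len(precursor):
        raise ValueError("end_range exceeds precursor length")
    rng = np.random.default_rng(seed)
    masses, truth = [], []
    for e in ends:
        m = peptide_mass(precursor[start - 1:e])
        u = rng.uniform(-ppm_jitter, ppm_jitter)
        masses.append(m * (1.0 + u * 1e-6))
        truth.append((start, e))
    return masses, truth


def write_ground_truth(model: FibrilModel, path) -> None:
    Path(path).write_text(json.dumps(model.provenance, indent=1, sort_keys=True,
                                     default=float))
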