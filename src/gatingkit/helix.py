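"""Backbone H-bond secondary-structure classification with ester handling.

Voltage-sensor S4 helices mix alpha-helical (i+4 -> i H-bonds) and 3_10
(i+3 -> i) stretches.  This module classifies per-residue secondary structure
across the frames of a multi-model PDB using the classic DSSP electrostatic
hydrogen-bond criterion,

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   kcal/mol,

recording a bond when E < -0.5 kcal/mol, with amide hydrogens reconstructed
geometrically where the file provides none.  An amide-to-ester (alpha-hydroxy
acid) substitution replaces the backbone N-H of the marked residue with an
ester oxygen: that residue can no longer *donate* a hydrogen bond, while every
carbonyl acceptor is untouched.  Marking a residue as an ester site therefore
deletes exactly the H-bonds donated by it.

Label conventions follow DSSP: G = 3_10 helix, H = alpha helix, I = pi helix,
T = hydrogen-bonded turn, C = coil, with minimal helices requiring two
consecutive turns of the same period and overlap priority H > G > I.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

BACKBONE_ATOMS = ("N", "CA", "C", "O", "H")

#: DSSP electrostatic prefactor, kcal/mol * Angstrom (q1*q2*332).
_DSSP_Q = 27.888
#: H-bond energy cutoff, kcal/mol.
HBOND_CUTOFF = -0.5
#: reconstructed amide N-H bond length, Angstrom.
NH_BOND_LENGTH = 1.01

# Shaker <-> Kv1.2/2.1 chimera S4 numbering for the sites studied by
# amide-to-ester substitution (Shaker residue -> chimera residue).
SHAKER_TO_KV_CHIMERA = {363: 291, 369: 297}
KV_CHIMERA_TO_SHAKER = {v: k for k, v in SHAKER_TO_KV_CHIMERA.items()}

SS_CLASSES = ("H", "G", "I", "T", "C")


@dataclass
class Structure:
    """Backbone coordinates for a (possibly multi-frame) protein chain.

    ``coords[name]`` has shape (n_frames, n_res, 3) in Angstrom with NaN for
    missing atoms.  ``ester_sites`` holds residue *positions* (0-based indices
    into the residue list) whose backbone amide N-H has been replaced by an
    ester oxygen and which therefore cannot donate H-bonds.
    """

    res_ids: np.ndarray
    res_names: list
    chain_ids: list
    coords: dict
    ester_sites: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        for name in BACKBONE_ATOMS:
            if name not in self.coords:
                n_frames = next(iter(self.coords.values())).shape[0] if self.coords else 1
                self.coords[name] = np.full((n_frames, self.n_res, 3), np.nan)

    @property
    def n_res(self) -> int:
        return self.res_ids.size

    @property
    def n_frames(self) -> int:
        return next(iter(self.coords.values())).shape[0]

    def position_of(self, res_id: int, chain: str | None = None) -> int:
        """Residue position (0-based) for a residue id (and optional chain)."""
        for i, (rid, ch) in enumerate(zip(self.res_ids, self.chain_ids)):
            if rid == res_id and (chain is None or ch == chain):
                return i
        raise KeyError(f"residue {chain or ''}:{res_id} not found")

    def has_atom(self, name: str, pos: int, frame: int = 0) -> bool:
        return bool(np.all(np.isfinite(self.coords[name][frame, pos])))

    def copy(self) -> "Structure":
        return Structure(
            self.res_ids.copy(), list(self.res_names), list(self.chain_ids),
            {k: v.copy() for k, v in self.coords.items()}, self.ester_sites,
        )


@dataclass(frozen=True)
class HBond:
    """A backbone N-H...O=C hydrogen bond within one frame."""

    donor_index: int
    acceptor_index: int
    donor_id: int
    acceptor_id: int
    energy: float

    @property
    def separation(self) -> int:
        """Acceptor -> donor sequence offset k (k=4 for an alpha bond)."""
        return self.donor_index - self.acceptor_index


# --------------------------------------------------------------------------
# PDB I/O (via biotite)
# --------------------------------------------------------------------------

def read_structure(source) -> Structure:
    """Parse a (multi-model) PDB file or text into a backbone Structure.

    MODEL records become frames; all frames must share the residue topology.
    Residues missing backbone atoms keep NaN coordinates and are skipped as
    donors/acceptors, with a warning.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    if isinstance(source, (str, Path)) and "\n" in str(source):
        pdb_file = pdbio.PDBFile.read(io.StringIO(str(source)))
    else:
        pdb_file = pdbio.PDBFile.read(source)
    stack = pdb_file.get_structure()  # AtomArrayStack
    if stack.array_length() == 0:
        raise ValueError("no ATOM records found")
    amino = stack[:, struc.filter_amino_acids(stack)]
    if amino.array_length() > 0:
        stack = amino
    n_frames = stack.stack_depth()
    # residue order as encountered
    keys: list = []
    seen = set()
    for ch, rid, rname in zip(stack.chain_id, stack.res_id, stack.res_name):
        k = (str(ch), int(rid))
        if k not in seen:
            seen.add(k)
            keys.append((str(ch), int(rid), str(rname)))
    n_res = len(keys)
    coords = {name: np.full((n_frames, n_res, 3), np.nan) for name in BACKBONE_ATOMS}
    index = {(ch, rid): i for i, (ch, rid, _) in enumerate(keys)}
    for a in range(stack.array_length()):
        name = str(stack.atom_name[a])
        if name not in BACKBONE_ATOMS:
            continue
        i = index[(str(stack.chain_id[a]), int(stack.res_id[a]))]
        coords[name][:, i, :] = stack.coord[:, a, :]
    st = Structure(
        res_ids=np.array([rid for _, rid, _ in keys]),
        res_names=[rn for _, _, rn in keys],
        chain_ids=[ch for ch, _, _ in keys],
        coords=coords,
    )
    incomplete = [
        int(st.res_ids[i]) for i in range(n_res)
        if not all(st.has_atom(n, i) for n in ("N", "CA", "C", "O"))
    ]
    if incomplete:
        warnings.warn(
            f"residues missing backbone atoms (excluded where relevant): {incomplete}",
            UserWarning, stacklevel=2,
        )
    return st


def structure_to_pdb(structure: Structure, path=None, include_h: bool = False):
    """Write a Structure back to (multi-model) PDB via biotite.

    Returns the PDB text when ``path`` is None.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    names = [n for n in BACKBONE_ATOMS if include_h or n != "H"]
    entries = []  # (pos, atom_name) with finite coords in all frames
    for i in range(structure.n_res):
        for name in names:
            if np.all(np.isfinite(structure.coords[name][:, i])):
                entries.append((i, name))
    arrays = []
    for f in range(structure.n_frames):
        arr = struc.AtomArray(len(entries))
        for a, (i, name) in enumerate(entries):
            arr.coord[a] = structure.coords[name][f, i]
            arr.chain_id[a] = structure.chain_ids[i]
            arr.res_id[a] = int(structure.res_ids[i])
            arr.res_name[a] = structure.res_names[i]
            arr.atom_name[a] = name
            arr.element[a] = name[0]
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    if path is None:
        buf = io.StringIO()
        pdb_file.write(buf)
        return buf.getvalue()
    pdb_file.write(str(path))
    return None


# --------------------------------------------------------------------------
# Hydrogen placement and H-bond energies
# --------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def place_amide_hydrogens(structure: Structure) -> Structure:
    """Reconstruct missing backbone amide hydrogens.

    H sits ``NH_BOND_LENGTH`` Angstrom from N along the normalized sum of the
    unit vectors N-C(prev) and N-O(prev) (the carbonyl-bisector convention).
    Prolines and ester sites get no hydrogen; existing H records are kept.
    """
    st = structure.copy()
    N, C, O, H = (st.coords[k] for k in ("N", "C", "O", "H"))
    for i in range(1, st.n_res):
        if st.res_names[i] == "PRO" or i in st.ester_sites:
            continue
        for f in range(st.n_frames):
            if np.all(np.isfinite(H[f, i])):
                continue  # keep recorded hydrogens
            n, c_prev, o_prev = N[f, i], C[f, i - 1], O[f, i - 1]
            if not (np.all(np.isfinite(n)) and np.all(np.isfinite(c_prev)) and np.all(np.isfinite(o_prev))):
                continue
            direction = _unit(_unit(n - c_prev) + _unit(n - o_prev))
            H[f, i] = n + NH_BOND_LENGTH * direction
    return st


def hbond_energy(
    structure: Structure, donor: int, acceptor: int, frame: int = 0
) -> float | None:
    """DSSP electrostatic H-bond energy (kcal/mol) for donor NH -> acceptor CO.

    Returns ``None`` (a no-energy sentinel, never numeric 0) when the donor
    cannot donate: ester site, proline, or missing H.
    """
    if donor in structure.ester_sites or structure.res_names[donor] == "PRO":
        return None
    if not structure.has_atom("H", donor, frame) or not structure.has_atom("N", donor, frame):
        return None
    if not (structure.has_atom("C", acceptor, frame) and structure.has_atom("O", acceptor, frame)):
        return None
    n = structure.coords["N"][frame, donor]
    h = structure.coords["H"][frame, donor]
    c = structure.coords["C"][frame, acceptor]
    o = structure.coords["O"][frame, acceptor]
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # atom clash: treat as no bond
        return None
    return float(_DSSP_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def find_hbonds(
    structure: Structure,
    frame: int = 0,
    cutoff: float = HBOND_CUTOFF,
    min_separation: int = 2,
) -> list:
    """All backbone H-bonds of one frame with energy below ``cutoff``.

    Pairs closer than ``min_separation`` in sequence are excluded (a donor's
    own and covalently adjacent carbonyls are not hydrogen-bond partners).
    """
    bonds = []
    for d in range(structure.n_res):
        for a in range(structure.n_res):
            if abs(d - a) < min_separation:
                continue
            e = hbond_energy(structure, d, a, frame)
            if e is not None and e < cutoff:
                bonds.append(HBond(d, a, int(structure.res_ids[d]), int(structure.res_ids[a]), e))
    return bonds


# --------------------------------------------------------------------------
# Ester semantics
# --------------------------------------------------------------------------

def apply_ester(structure: Structure, res_id: int, chain: str | None = None) -> Structure:
    """Mark a residue as an amide-to-ester (alpha-hydroxy acid) substitution.

    The residue loses its backbone N-H donor (its hydrogen, if placed, is
    removed); all acceptor carbonyls, including its own, are unchanged.
    Idempotent; unknown residues raise ``KeyError``.
    """
    pos = structure.position_of(res_id, chain)
    st = structure.copy()
    st.ester_sites = frozenset(st.ester_sites | {pos})
    st.coords["H"][:, pos, :] = np.nan
    return st


# --------------------------------------------------------------------------
# Secondary-structure assignment
# --------------------------------------------------------------------------

def assign_secondary_structure(hbonds: list, n_res: int) -> np.ndarray:
    """Per-residue labels (H/G/I/T/C) from one frame's H-bond list.

    A k-turn at i means a bond from donor i+k to acceptor i (k = 3, 4, 5).
    Two consecutive turns of the same period make a minimal helix covering
    residues i+1..i+k (G for k=3, H for k=4, I for k=5), applied with overlap
    priority H > G > I.  Residues bracketed by an isolated turn are labeled T;
    everything else is coil C.
    """
    turns = {k: np.zeros(n_res, dtype=bool) for k in (3, 4, 5)}
    for b in hbonds:
        k = b.separation
        if k in turns and 0 <= b.acceptor_index < n_res:
            turns[k][b.acceptor_index] = True
    labels = np.full(n_res, "C", dtype="<U1")
    for k, lab in ((4, "H"), (3, "G"), (5, "I")):  # priority order
        tk = turns[k]
        for i in range(n_res - k - 1):
            if tk[i] and tk[i + 1]:
                for j in range(i + 1, min(i + k + 1, n_res)):
                    if labels[j] == "C" or labels[j] == "T":
                        labels[j] = lab
    for k in (3, 4, 5):
        for i in np.nonzero(turns[k])[0]:
            for j in range(i + 1, min(i + k, n_res)):
                if labels[j] == "C":
                    labels[j] = "T"
    return labels


def classify(structure: Structure, cutoff: float = HBOND_CUTOFF) -> np.ndarray:
    """Labels for every frame: shape (n_frames, n_res).

    Hydrogens are reconstructed if absent; ester sites never donate.
    """
    st = place_amide_hydrogens(structure)
    out = np.full((st.n_frames, st.n_res), "C", dtype="<U1")
    for f in range(st.n_frames):
        out[f] = assign_secondary_structure(find_hbonds(st, frame=f, cutoff=cutoff), st.n_res)
    return out


def helical_content(
    labels: np.ndarray,
    res_ids: np.ndarray | None = None,
    residue_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-residue fraction of frames spent in each class.

    ``labels`` is (n_frames, n_res) as returned by :func:`classify`.  Rows are
    indexed by residue id; columns H, G, I, T, C sum to 1.
    """
    labels = np.atleast_2d(labels)
    n_frames, n_res = labels.shape
    if n_frames < 1:
        raise ValueError("need at least one frame")
    ids = np.arange(1, n_res + 1) if res_ids is None else np.asarray(res_ids)
    if residue_range is not None:
        lo, hi = residue_range
        keep = (ids >= lo) & (ids <= hi)
        if not keep.any():
            raise ValueError("residue_range selects no residues")
        labels = labels[:, keep]
        ids = ids[keep]
    frac = {c: (labels == c).mean(axis=0) for c in SS_CLASSES}
    return pd.DataFrame(frac, index=pd.Index(ids, name="res_id"))


# --------------------------------------------------------------------------
# Ideal-helix fixture builder
# --------------------------------------------------------------------------

_GEOM = {
    "b_NCA": 1.458, "b_CAC": 1.525, "b_CN": 1.329, "b_CO": 1.231,
    "ang_NCAC": 111.2, "ang_CACN": 116.2, "ang_CNCA": 121.7, "ang_CACO": 120.8,
}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension reference frame: place D from A-B-C internal coords."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_helix(
    n_res: int, phi_deg: float, psi_deg: float, omega_deg: float = 180.0
) -> Structure:
    """Poly-alanine-like backbone with uniform (phi, psi, omega) dihedrals.

    Built by internal-coordinate chain extension with standard bond geometry;
    (-57, -47) gives a textbook alpha helix (rise ~1.5 A, ~3.6 res/turn),
    (-49, -26) a 3_10 helix (~2.0 A, ~3.1 res/turn), (180, 180) an extended
    strand.  Amide hydrogens are reconstructed by the bisector rule.
    """
    if n_res < 4:
        raise ValueError("n_res must be >= 4")
    g = _GEOM
    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    O = np.empty((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (g["b_NCA"], 0.0, 0.0)
    th = np.deg2rad(180.0 - g["ang_NCAC"])
    C[0] = CA[0] + g["b_CAC"] * np.array([np.cos(th), np.sin(th), 0.0])
    for i in range(n_res - 1):
        N[i + 1] = _nerf(N[i], CA[i], C[i], g["b_CN"], g["ang_CACN"], psi_deg)
        CA[i + 1] = _nerf(CA[i], C[i], N[i + 1], g["b_NCA"], g["ang_CNCA"], omega_deg)
        C[i + 1] = _nerf(C[i], N[i + 1], CA[i + 1], g["b_CAC"], g["ang_NCAC"], phi_deg)
    for i in range(n_res):
        O[i] = _nerf(N[i], CA[i], C[i], g["b_CO"], g["ang_CACO"], psi_deg + 180.0)
    coords = {
        "N": N[None], "CA": CA[None], "C": C[None], "O": O[None],
        "H": np.full((1, n_res, 3), np.nan),
    }
    st = Structure(
        res_ids=np.arange(1, n_res + 1),
        res_names=["ALA"] * n_res,
        chain_ids=["A"] * n_res,
        coords=coords,
    )
    return place_amide_hydrogens(st)


def helix_parameters(structure: Structure, frame: int = 0) -> tuple[float, float]:
    """(rise per residue in A, residues per turn) measured from CA positions.

    The helix axis is the principal direction of the centered CA cloud; rise
    is the mean axial spacing of successive CA atoms and the turn count comes
    from the mean rotation of their radial components about the axis.
    """
    ca = structure.coords["CA"][frame]
    ca = ca[np.all(np.isfinite(ca), axis=1)]
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    z = centered @ axis
    radial = centered - np.outer(z, axis)
    rise = float(np.mean(np.diff(z)))
    angles = []
    for i in range(len(ca) - 1):
        r1, r2 = radial[i], radial[i + 1]
        cosang = np.dot(r1, r2) / (np.linalg.norm(r1) * np.linalg.norm(r2))
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        angles.append(ang)
    twist = float(np.mean(angles))
    return rise, float(2.0 * np.pi / twist)
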