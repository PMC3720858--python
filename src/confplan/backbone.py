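"""Dihedral-space representation of a protein backbone with idealized geometry.

A conformation is parameterized by the backbone torsion angles (phi, psi) of
each residue; bond lengths, bond angles and the peptide torsion omega are
held fixed at idealized values.  Cartesian coordinates for the N/CA/C atoms
are derived from the torsions by sequential natural-extension (NeRF-style)
placement, so every structure built here has exactly ideal covalent geometry.

Angles are degrees everywhere at the API boundary, wrapped to (-180, 180],
IUPAC torsion sign.  Undefined terminal torsions (phi of residue 1, psi of
the last residue) are marked with NaN.  Residue indices are 1-based.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "IdealGeometry",
    "Conformation",
    "wrap_angle",
    "build_backbone",
    "extract_dihedrals",
    "defined_dihedrals",
    "n_defined",
    "superpose_rmsd",
    "dihedral_distance",
    "read_pdb",
    "write_pdb",
]

ATOMS_PER_RESIDUE = 3  # N, CA, C


@dataclass(frozen=True)
class IdealGeometry:
    """Idealized covalent geometry of the peptide backbone.

    Lengths in Angstrom, angles in degrees.  Defaults are standard published
    idealized peptide values; any fixed set works as long as it is used
    consistently for building and never perturbed.
    """

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    omega: float = 180.0

    def __post_init__(self) -> None:
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca"):
            a = getattr(self, name)
            if not 0.0 < a < 180.0:
                raise ValueError(f"{name} must lie in (0, 180)")


DEFAULT_GEOMETRY = IdealGeometry()


def wrap_angle(angle):
    """Wrap an angle (degrees) into (-180, 180].

    Accepts scalars or arrays; NaN (the undefined-torsion sentinel) passes
    through unchanged.  Non-finite inputs other than NaN raise.
    """
    a = np.asarray(angle, dtype=float)
    if np.isinf(a).any():
        raise ValueError("cannot wrap a non-finite angle")
    wrapped = np.mod(a - 180.0, -360.0) + 180.0
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass
class Conformation:
    """Backbone conformation: sequence + torsions + derived coordinates.

    ``dihedrals`` has shape (n_residues, 2) holding (phi, psi) per residue
    with NaN for undefined terminal angles.  ``coords`` has shape
    (3 * n_residues, 3) in N, CA, C order per residue.  ``energy`` caches the
    last evaluated score (dimensionless, lower is better).
    """

    sequence: str
    dihedrals: np.ndarray
    coords: np.ndarray
    energy: float | None = None

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def ca_coords(self) -> np.ndarray:
        return self.coords[1::ATOMS_PER_RESIDUE]

    def copy(self) -> "Conformation":
        return Conformation(
            self.sequence, self.dihedrals.copy(), self.coords.copy(), self.energy
        )

    def __post_init__(self) -> None:
        self.dihedrals = np.asarray(self.dihedrals, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.dihedrals.shape != (self.n_residues, 2):
            raise ValueError("dihedral array must have shape (n_residues, 2)")
        if self.coords.shape != (ATOMS_PER_RESIDUE * self.n_residues, 3):
            raise ValueError("coordinate array must have one N/CA/C triple per residue")


def n_defined(dihedrals: np.ndarray) -> int:
    """Number of defined torsions (non-NaN entries)."""
    return int(np.isfinite(dihedrals).sum())


def defined_dihedrals(dihedrals: np.ndarray) -> np.ndarray:
    """Flatten the defined torsions in fixed (phi1, psi1, phi2, ...) order."""
    flat = np.asarray(dihedrals, dtype=float).ravel()
    return flat[np.isfinite(flat)]


@njit(cache=False)
def _place(ax_, ay_, az_, bx_, by_, bz_, cx_, cy_, cz_,
           r, theta_deg, chi_deg):
    """Place the next atom from the previous three by length/angle/torsion."""
    bcx, bcy, bcz = cx_ - bx_, cy_ - by_, cz_ - bz_
    nb = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / nb, bcy / nb, bcz / nb
    abx, aby, abz = bx_ - ax_, by_ - ay_, bz_ - az_
    # n = ab x bc, normal to the ABC plane
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    # m = n x bc completes the right-handed frame
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    theta = math.radians(theta_deg)
    chi = math.radians(chi_deg)
    d_bc = -r * math.cos(theta)
    s = r * math.sin(theta)
    d_m = s * math.cos(chi)
    d_n = -s * math.sin(chi)  # IUPAC sign: matches the torsion measurement
    return (
        cx_ + d_bc * bcx + d_m * mx + d_n * nx,
        cy_ + d_bc * bcy + d_m * my + d_n * ny,
        cz_ + d_bc * bcz + d_m * mz + d_n * nz,
    )


@njit(cache=False)
def _nerf_chain(dih, coords, b_nca, b_cac, b_cn,
                a_ncac, a_cacn, a_cnca, omega):
    """Sequential backbone placement (JIT: inner loop of every rebuild)."""
    n_res = dih.shape[0]
    coords[0, 0] = coords[0, 1] = coords[0, 2] = 0.0
    coords[1, 0], coords[1, 1], coords[1, 2] = b_nca, 0.0, 0.0
    th = math.radians(a_ncac)
    coords[2, 0] = b_nca - b_cac * math.cos(th)
    coords[2, 1] = b_cac * math.sin(th)
    coords[2, 2] = 0.0
    for i in range(1, n_res):
        base = 3 * i
        p = base - 3
        n = _place(coords[p, 0], coords[p, 1], coords[p, 2],
                   coords[p + 1, 0], coords[p + 1, 1], coords[p + 1, 2],
                   coords[p + 2, 0], coords[p + 2, 1], coords[p + 2, 2],
                   b_cn, a_cacn, dih[i - 1, 1])
        coords[base, 0], coords[base, 1], coords[base, 2] = n
        ca = _place(coords[p + 1, 0], coords[p + 1, 1], coords[p + 1, 2],
                    coords[p + 2, 0], coords[p + 2, 1], coords[p + 2, 2],
                    n[0], n[1], n[2],
                    b_nca, a_cnca, omega)
        coords[base + 1, 0], coords[base + 1, 1], coords[base + 1, 2] = ca
        c = _place(coords[p + 2, 0], coords[p + 2, 1], coords[p + 2, 2],
                   n[0], n[1], n[2], ca[0], ca[1], ca[2],
                   b_cac, a_ncac, dih[i, 0])
        coords[base + 2, 0], coords[base + 2, 1], coords[base + 2, 2] = c


def build_backbone(
    sequence: str,
    dihedrals: np.ndarray,
    geometry: IdealGeometry = DEFAULT_GEOMETRY,
) -> Conformation:
    """Build Cartesian N/CA/C coordinates from backbone torsions.

    The chain is placed in a canonical frame: residue 1's N at the origin,
    its CA on the +x axis and its C in the xy-plane (positive y).  phi of
    residue 1 and psi of the last residue are not used and come back as NaN.

    Raises on an empty sequence or a torsion-count mismatch.
    """
    n_res = len(sequence)
    if n_res == 0:
        raise ValueError("empty sequence")
    dih = np.asarray(dihedrals, dtype=float)
    if dih.shape != (n_res, 2):
        raise ValueError(
            f"need one (phi, psi) pair per residue: got {dih.shape}, "
            f"expected {(n_res, 2)}"
        )
    dih = wrap_angle(np.where(np.isfinite(dih), dih, np.nan))
    dih = dih.reshape(n_res, 2).copy()
    dih[0, 0] = np.nan
    dih[-1, 1] = np.nan

    g = geometry
    coords = np.empty((ATOMS_PER_RESIDUE * n_res, 3), dtype=float)
    _nerf_chain(dih, coords, g.bond_n_ca, g.bond_ca_c, g.bond_c_n,
                g.angle_n_ca_c, g.angle_ca_c_n, g.angle_c_n_ca, g.omega)
    return Conformation(sequence, dih, coords)


def _torsions(p0, p1, p2, p3):
    """Vectorized IUPAC torsion angles (degrees) for stacked quadruples."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    bad = (np.linalg.norm(n1, axis=-1) < 1e-9) | (np.linalg.norm(n2, axis=-1) < 1e-9)
    return np.degrees(np.arctan2(y, x)), bad


def extract_dihedrals(conformation: Conformation) -> np.ndarray:
    """Measure (phi, psi) per residue from the stored coordinates.

    phi_i is the torsion C(i-1)-N(i)-CA(i)-C(i); psi_i is
    N(i)-CA(i)-C(i)-N(i+1).  Terminal undefined angles are NaN.  A collinear
    quadruple (degenerate torsion) raises, naming the residue.
    """
    xyz = conformation.coords
    n_res = conformation.n_residues
    out = np.full((n_res, 2), np.nan)
    N = xyz[0::ATOMS_PER_RESIDUE]
    CA = xyz[1::ATOMS_PER_RESIDUE]
    C = xyz[2::ATOMS_PER_RESIDUE]
    if n_res >= 2:
        phi, bad_phi = _torsions(C[:-1], N[1:], CA[1:], C[1:])
        psi, bad_psi = _torsions(N[:-1], CA[:-1], C[:-1], N[1:])
        if bad_phi.any():
            res = int(np.nonzero(bad_phi)[0][0]) + 2
            raise ValueError(f"collinear atoms: phi of residue {res} is degenerate")
        if bad_psi.any():
            res = int(np.nonzero(bad_psi)[0][0]) + 1
            raise ValueError(f"collinear atoms: psi of residue {res} is degenerate")
        out[1:, 0] = phi
        out[:-1, 1] = psi
    # the torsion formula returns (-180, 180] except exact -180; normalize
    return wrap_angle(out)


def dihedral_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute wrapped difference (degrees) over defined torsions."""
    da = np.asarray(a, float).ravel()
    db = np.asarray(b, float).ravel()
    mask = np.isfinite(da) & np.isfinite(db)
    if not mask.any():
        return 0.0
    return float(np.mean(np.abs(wrap_angle(da[mask] - db[mask]))))


def _atom_selection(conf: Conformation, atoms) -> np.ndarray:
    if isinstance(atoms, str):
        if atoms == "all":
            return conf.coords
        if atoms == "ca":
            return conf.ca_coords
        raise ValueError(f"unknown atom selection {atoms!r}")
    return conf.coords[np.asarray(atoms, dtype=int)]


def superpose_rmsd(a: Conformation, b: Conformation, atoms="all"):
    """Minimal RMSD of ``a`` onto ``b`` over proper rotations + translation.

    ``atoms`` is "all", "ca", or an explicit atom-index array applied to
    both conformations.  Returns ``(rmsd, (R, t))`` where the Kabsch
    transform ``x -> R @ x + t`` maps the selected atoms of ``a`` onto
    ``b``'s (no reflections).
    """
    from scipy.spatial.transform import Rotation

    pa = _atom_selection(a, atoms)
    pb = _atom_selection(b, atoms)
    if pa.shape != pb.shape:
        raise ValueError(f"selection size mismatch: {pa.shape} vs {pb.shape}")
    ca_, cb_ = pa.mean(axis=0), pb.mean(axis=0)
    rot, _ = Rotation.align_vectors(pb - cb_, pa - ca_)
    R = rot.as_matrix()
    t = cb_ - R @ ca_
    # recompute the RMSD from the residuals: scipy's rssd comes from the
    # singular values and loses ~sqrt(eps) precision near zero
    resid = pa @ R.T + t - pb
    rmsd = math.sqrt(float((resid ** 2).sum()) / len(pa))
    return rmsd, (R, t)


# --- PDB I/O (single chain, N/CA/C backbone) --------------------------------

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


def write_pdb(conformation: Conformation, path) -> None:
    """Write the backbone as standard ATOM records, one chain, serials from 1."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_res = conformation.n_residues
    n_atoms = ATOMS_PER_RESIDUE * n_res
    arr = struc.AtomArray(n_atoms)
    arr.coord = conformation.coords.astype(np.float64)
    arr.chain_id = np.full(n_atoms, "A")
    arr.res_id = np.repeat(np.arange(1, n_res + 1), ATOMS_PER_RESIDUE)
    arr.res_name = np.repeat(
        [_AA1TO3.get(c, "GLY") for c in conformation.sequence], ATOMS_PER_RESIDUE
    )
    arr.atom_name = np.tile(["N", "CA", "C"], n_res)
    arr.element = np.tile(["N", "C", "C"], n_res)
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_pdb(path) -> Conformation:
    """Read a single-chain backbone from PDB ATOM records.

    Requires N, CA and C for every residue, in chain order.  Insertion codes
    are an unsupported dialect and raise; a multi-model file yields the first
    model with a warning.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models > 1:
        warnings.warn(f"{path}: {n_models} models present, using the first")
    arr = pdb.get_structure(model=1)
    arr = arr[~arr.hetero]
    if np.any(arr.ins_code != ""):
        raise ValueError(f"{path}: insertion codes are not supported")
    res_ids = arr.res_id
    order = np.unique(res_ids)
    seq = []
    coords = []
    for rid in order:
        sel = arr[res_ids == rid]
        triple = []
        for name in ("N", "CA", "C"):
            hit = sel[sel.atom_name == name]
            if len(hit) == 0:
                raise ValueError(f"{path}: residue {int(rid)} is missing atom {name}")
            triple.append(hit.coord[0])
        coords.extend(triple)
        seq.append(_AA3TO1.get(str(sel.res_name[0]), "G"))
    coords = np.asarray(coords, dtype=float)
    conf = Conformation("".join(seq), np.full((len(seq), 2), np.nan), coords)
    conf.dihedrals = extract_dihedrals(conf)
    return conf
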