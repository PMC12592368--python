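"""Structure I/O and geometric analysis of divalent-cation binding sites.

Implements the geometric criterion for Mg2+ sites — two or more acidic
residues (ASP/GLU) whose Calpha atoms are close enough for a cation to
bridge both carboxyl groups directly — plus Calpha distances, acidic
side-chain dihedrals and a simple largest-empty-sphere pore profiler.

PDB/mmCIF parsing and writing is delegated to gemmi; coordinates are
Angstrom at the file boundary and nm everywhere inside this package.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .constants import VDW_RADII_NM, VDW_RADIUS_DEFAULT_NM

log = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0

ACIDIC = {"ASP", "GLU"}
#: Calpha-to-carboxyl-carbon offsets entering the pair cutoff, nm.
CA_TO_CARBOXYL_NM = {"ASP": 0.25, "GLU": 0.35}
#: Twice the carboxyl-carbon-to-bound-cation distance, nm.
CATION_BRIDGE_NM = 0.6


# ----------------------------------------------------------------------
# containers

@dataclass
class AtomRecord:
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    altloc: str
    occupancy: float
    pos: np.ndarray  # nm

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("atom coordinates must be finite")


@dataclass
class Structure:
    """Flat atom list with author residue numbering; coordinates in nm."""

    atoms: list
    model_id: int = 1

    def residues(self) -> dict:
        """Ordered mapping ``(chain_id, residue_number) -> {atom_name: AtomRecord}``."""
        out: dict = {}
        for a in self.atoms:
            out.setdefault((a.chain_id, a.residue_number), {})[a.name] = a
        return out

    def residue(self, ref) -> dict:
        res = self.residues().get(tuple(ref))
        if res is None:
            raise KeyError(f"no residue {ref} in structure")
        return res

    def residue_name(self, ref) -> str:
        return next(iter(self.residue(ref).values())).residue_name

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])


@dataclass
class CandidatePair:
    residue_a: tuple
    residue_b: tuple
    pair_class: str          # DD, DE or EE
    ca_distance: float       # nm
    threshold: float         # nm


@dataclass
class BindingSite:
    site_id: int
    residues: tuple          # sorted residue refs
    member_pairs: list
    centroid: np.ndarray     # nm, mean of member Calpha positions


@dataclass
class PoreProfile:
    axis: np.ndarray
    samples: list = field(default_factory=list)  # (z_nm, radius_nm, center)

    def as_arrays(self):
        z = np.array([s[0] for s in self.samples])
        r = np.array([s[1] for s in self.samples])
        return z, r


# ----------------------------------------------------------------------
# I/O (gemmi behind the surface)

def read_structure(path, format: str | None = None, model_id: int | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Keeps author residue numbering; for duplicated altlocs the highest
    occupancy wins (ties: first in file).  Hydrogens are retained but
    ignored by the geometry operations that do not need them.
    """
    import gemmi

    fmt_map = {None: gemmi.CoorFormat.Detect,
               "pdb": gemmi.CoorFormat.Pdb,
               "mmcif": gemmi.CoorFormat.Mmcif}
    if format not in fmt_map:
        raise ValueError(f"unknown structure format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"structure file {path} contains no model")

    if model_id is None:
        model = st[0]
        mid = 1
    else:
        model = None
        for m in st:
            if int(m.num) == model_id:
                model, mid = m, model_id
                break
        if model is None:
            raise ValueError(f"model {model_id} not found in {path}")

    atoms: list = []
    for chain in model:
        for res in chain:
            best: dict = {}
            order: list = []
            for at in res:
                key = at.name
                if key not in best:
                    best[key] = at
                    order.append(key)
                elif at.occ > best[key].occ:
                    best[key] = at
            for key in order:
                at = best[key]
                atoms.append(AtomRecord(
                    name=at.name,
                    element=at.element.name,
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain_id=chain.name,
                    altloc=at.altloc or "",
                    occupancy=at.occ,
                    pos=np.array([at.pos.x, at.pos.y, at.pos.z]) / ANGSTROM_PER_NM,
                ))
    if not atoms:
        raise ValueError(f"structure file {path} contains an empty model")
    return Structure(atoms=atoms, model_id=mid)


def write_pdb(structure: Structure, path) -> None:
    """Write a :class:`Structure` as a standard PDB file (Angstrom)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "mgbind"
    model = gemmi.Model(1)
    chains: dict = {}
    for a in structure.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        chain = chains[a.chain_id]
        if len(chain) == 0 or chain[-1].seqid.num != a.residue_number:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            chain.add_residue(res)
        res = chain[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.occ = a.occupancy
        at.altloc = a.altloc if a.altloc else "\0"
        xyz = a.pos * ANGSTROM_PER_NM
        at.pos = gemmi.Position(*xyz)
        res.add_atom(at)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ----------------------------------------------------------------------
# geometry primitives

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees, IUPAC convention) in (-180, 180].

    A right-handed rotation of the distal atom about the p1->p2 axis
    increases the angle.
    """
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(dih),
                               np.sin(ang) * np.sin(dih)])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


# ----------------------------------------------------------------------
# site scanning

def pair_threshold(type_a: str, type_b: str) -> float:
    """Calpha-Calpha cutoff (nm) for a bridging divalent cation.

    Sum of the Calpha-to-carboxyl-carbon offsets of the two acidic
    residues (0.25 nm for ASP, 0.35 nm for GLU) plus twice the
    carboxyl-carbon-to-cation distance (2 x 0.3 nm): 1.1 nm for a DD
    pair, 1.2 for DE, 1.3 for EE.
    """
    for t in (type_a, type_b):
        if t not in ACIDIC:
            raise ValueError(f"pair_threshold requires acidic residue types, got {t!r}")
    return CA_TO_CARBOXYL_NM[type_a] + CA_TO_CARBOXYL_NM[type_b] + CATION_BRIDGE_NM


def _axial_coordinate(pos: np.ndarray, axis) -> float:
    ax = np.asarray(axis, float)
    return float(pos @ (ax / np.linalg.norm(ax)))


def scan_sites(structure: Structure, region: tuple | None = None,
               merge: bool = True, axis=(0.0, 0.0, 1.0)) -> list:
    """Detect candidate divalent-cation sites from acidic residue pairs.

    Every ASP/GLU pair (intra- and inter-chain) whose Calpha distance is
    strictly below :func:`pair_threshold` becomes a :class:`CandidatePair`;
    with ``merge`` pairs sharing a residue are unioned (single linkage)
    into :class:`BindingSite` records.  ``region`` is an optional
    ``(lo, hi)`` axial slab (nm along ``axis``) selecting e.g. the
    intracellular side of a membrane domain.
    """
    acidic: list = []
    for ref, atoms in structure.residues().items():
        name = next(iter(atoms.values())).residue_name
        if name not in ACIDIC:
            continue
        ca = atoms.get("CA")
        if ca is None:
            log.warning("acidic residue %s/%s has no CA atom; skipped", *ref)
            continue
        if region is not None:
            z = _axial_coordinate(ca.pos, axis)
            if not (region[0] <= z <= region[1]):
                continue
        acidic.append((ref, name, ca.pos))

    pairs: list = []
    for i in range(len(acidic)):
        for j in range(i + 1, len(acidic)):
            (ref_a, name_a, pos_a), (ref_b, name_b, pos_b) = acidic[i], acidic[j]
            thr = pair_threshold(name_a, name_b)
            d = float(np.linalg.norm(pos_a - pos_b))
            if d < thr:  # strict: exactly at threshold is excluded
                cls = "".join(sorted(("D" if name_a == "ASP" else "E",
                                      "D" if name_b == "ASP" else "E")))
                pairs.append(CandidatePair(ref_a, ref_b, cls, d, thr))

    if not merge:
        sites = [BindingSite(i, tuple(sorted((p.residue_a, p.residue_b))), [p],
                             _site_centroid(structure, (p.residue_a, p.residue_b)))
                 for i, p in enumerate(pairs)]
    else:
        parent: dict = {}

        def find(x):
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for p in pairs:
            ra, rb = find(p.residue_a), find(p.residue_b)
            if ra != rb:
                parent[ra] = rb
        groups: dict = {}
        for p in pairs:
            groups.setdefault(find(p.residue_a), []).append(p)
        sites = []
        for members in groups.values():
            refs = sorted({r for p in members for r in (p.residue_a, p.residue_b)})
            sites.append(BindingSite(0, tuple(refs), members,
                                     _site_centroid(structure, refs)))
    sites.sort(key=lambda s: s.residues[0])
    for i, s in enumerate(sites):
        s.site_id = i
    return sites


def _site_centroid(structure: Structure, refs) -> np.ndarray:
    cas = [structure.residue(r)["CA"].pos for r in refs]
    return np.mean(cas, axis=0)


def ca_distance(structure: Structure, ref_a, ref_b) -> float:
    """Calpha-Calpha Euclidean distance, nm."""
    out = []
    for ref in (ref_a, ref_b):
        atoms = structure.residue(ref)
        if "CA" not in atoms:
            raise ValueError(f"residue {ref} has no CA atom")
        out.append(atoms["CA"].pos)
    return float(np.linalg.norm(out[0] - out[1]))


def sidechain_dihedrals(structure: Structure, ref) -> tuple:
    """(chi1, chi2) in degrees for an ASP or GLU residue.

    chi1 = N-CA-CB-CG; chi2 = CA-CB-CG-OD1 for ASP, CA-CB-CG-CD for GLU.
    """
    atoms = structure.residue(ref)
    name = next(iter(atoms.values())).residue_name
    if name not in ACIDIC:
        raise ValueError(f"residue {ref} is {name}, expected ASP or GLU")
    last = "OD1" if name == "ASP" else "CD"
    for req in ("N", "CA", "CB", "CG", last):
        if req not in atoms:
            raise ValueError(f"residue {ref} is missing atom {req}")
    chi1 = dihedral_angle(atoms["N"].pos, atoms["CA"].pos,
                          atoms["CB"].pos, atoms["CG"].pos)
    chi2 = dihedral_angle(atoms["CA"].pos, atoms["CB"].pos,
                          atoms["CG"].pos, atoms[last].pos)
    return chi1, chi2


# ----------------------------------------------------------------------
# pore profiler

def pore_profile(structure: Structure, z_min: float, z_max: float, step: float,
                 axis=(0.0, 0.0, 1.0), axis_point=None,
                 radii: dict | None = None, max_radius: float = 1.5,
                 slab_half_width: float = 1.0) -> PoreProfile:
    """Largest-empty-sphere pore radius along an axis.

    For each axial slice the pore radius is the maximum over sphere
    centres in the slice plane of ``min_i(|x - atom_i| - vdW_i)``, found
    by local optimisation from multiple starts around the axis; radii
    are clipped at zero.  Slices with no atoms within
    ``slab_half_width + max_radius`` report the ``max_radius`` sentinel.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    radii = dict(VDW_RADII_NM, **(radii or {}))
    ax = np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    coords = structure.coords()
    if axis_point is None:
        axis_point = coords.mean(axis=0)
        axis_point = axis_point - (axis_point @ ax) * ax  # keep only the in-plane part
    axis_point = np.asarray(axis_point, float)
    # orthonormal in-plane basis
    trial = np.array([1.0, 0.0, 0.0])
    if abs(trial @ ax) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ax, trial)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(ax, e1)

    atom_r = np.array([radii.get(a.element, VDW_RADIUS_DEFAULT_NM)
                       for a in structure.atoms])
    atom_z = coords @ ax

    profile = PoreProfile(axis=ax)
    n_starts = [(0.0, 0.0)] + [(0.08 * np.cos(t), 0.08 * np.sin(t))
                               for t in np.linspace(0, 2 * np.pi, 6, endpoint=False)] \
                            + [(0.25 * np.cos(t), 0.25 * np.sin(t))
                               for t in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
    for z in np.arange(z_min, z_max + 0.5 * step, step):
        sel = np.abs(atom_z - z) <= slab_half_width + max_radius
        if not np.any(sel):
            center = axis_point + z * ax
            profile.samples.append((float(z), float(max_radius), center))
            continue
        pts = coords[sel]
        rr = atom_r[sel]

        def neg_radius(uv):
            c = axis_point + z * ax + uv[0] * e1 + uv[1] * e2
            return -(np.min(np.linalg.norm(pts - c, axis=1) - rr))

        best_val, best_uv = np.inf, np.zeros(2)
        for start in n_starts:
            res = minimize(neg_radius, np.asarray(start), method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200})
            if res.fun < best_val:
                best_val, best_uv = res.fun, res.x
        r = min(max(-best_val, 0.0), max_radius)
        center = axis_point + z * ax + best_uv[0] * e1 + best_uv[1] * e2
        profile.samples.append((float(z), float(r), center))
    return profile
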