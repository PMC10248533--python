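"""Quantitative structure comparison: rigid superposition and RMSD,
solvent-accessible surface area and interface burial, salt bridges,
cis-peptide detection, hydropathy mapping and cavity volume.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .cluster import _make_aligner
from .structio import Chain, StructureModel

log = logging.getLogger(__name__)

#: fixed van der Waals radii (Angstrom); chosen for reproducibility
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4

#: Kyte-Doolittle hydropathy by three-letter residue name
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

#: volume of one residue of ideal alpha-helix, used for the chamber
#: capacity estimate (explicit documented constant)
HELIX_RESIDUE_VOLUME = 170.0


# ------------------------------------------------------------ superposition
@dataclass
class Superposition:
    rotation: np.ndarray      # (3,3), orthonormal, det +1
    translation: np.ndarray   # (3,)
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(fixed: np.ndarray, mobile: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of mobile onto fixed (SVD method,
    reflection excluded). Requires >= 3 non-collinear point pairs."""
    F = np.asarray(fixed, dtype=float)
    M = np.asarray(mobile, dtype=float)
    if F.shape != M.shape or F.ndim != 2 or F.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n,3) arrays")
    n = F.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    Fc, Mc = F - F.mean(axis=0), M - M.mean(axis=0)
    if np.linalg.matrix_rank(Fc, tol=1e-9) < 2 or np.linalg.matrix_rank(Mc, tol=1e-9) < 2:
        raise ValueError("points are collinear")
    H = Mc.T @ Fc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = F.mean(axis=0) - R @ M.mean(axis=0)
    moved = M @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - F) ** 2, axis=1))))
    return Superposition(R, t, rmsd, n)


BACKBONE_ATOMS = ("N", "CA", "C", "O")


def _chain_backbone_pairs(a: Chain, b: Chain) -> Tuple[np.ndarray, np.ndarray]:
    """Paired backbone coordinates for two chains, residue correspondence
    from a global sequence alignment; only aligned residue pairs with all
    four backbone atoms present on both sides contribute."""
    aligner = _make_aligner()
    aln = aligner.align(a.sequence(), b.sequence())[0]
    ra, rb = str(aln[0]), str(aln[1])
    ia = ib = 0
    fa, fb = [], []
    for ca, cb in zip(ra, rb):
        if ca != "-" and cb != "-":
            res_a, res_b = a.residues[ia], b.residues[ib]
            atoms_a = [res_a.atom(n) for n in BACKBONE_ATOMS]
            atoms_b = [res_b.atom(n) for n in BACKBONE_ATOMS]
            if all(x is not None for x in atoms_a + atoms_b):
                fa.extend(x.xyz for x in atoms_a)
                fb.extend(x.xyz for x in atoms_b)
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    if not fa:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.stack(fa), np.stack(fb)


def backbone_rmsd(a: StructureModel, b: StructureModel) -> float:
    """Backbone (N, CA, C, O) RMSD after one rigid superposition over all
    aligned residue pairs of greedily identity-matched chains."""
    from .cluster import pairwise_identity
    from .records import SequenceRecord

    remaining = list(b.chains)
    pairs: List[Tuple[Chain, Chain]] = []
    for ca in a.chains:
        best, best_ident = None, -1.0
        for cb in remaining:
            ident = pairwise_identity(SequenceRecord("a", ca.sequence()),
                                      SequenceRecord("b", cb.sequence()))
            if ident > best_ident:
                best, best_ident = cb, ident
        if best is not None:
            pairs.append((ca, best))
            remaining.remove(best)
    fa, fb = [], []
    for ca, cb in pairs:
        xa, xb = _chain_backbone_pairs(ca, cb)
        fa.append(xa)
        fb.append(xb)
    FA = np.concatenate(fa) if fa else np.empty((0, 3))
    FB = np.concatenate(fb) if fb else np.empty((0, 3))
    if FA.shape[0] == 0:
        raise ValueError("no aligned residues with complete backbones")
    return kabsch_superpose(FA, FB).rmsd


# ---------------------------------------------------------------------- SASA
def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere
    (golden-section spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def atom_radii(model: StructureModel) -> np.ndarray:
    out = []
    for _, _, a in model.atoms():
        r = VDW_RADII.get(a.element.capitalize())
        if r is None:
            warnings.warn(f"unknown element {a.element!r}; "
                          f"using default radius {DEFAULT_RADIUS} A")
            r = DEFAULT_RADIUS
        out.append(r)
    return np.array(out)


def shrake_rupley_sasa(model: StructureModel, probe: float = PROBE_RADIUS,
                       n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point sampling."""
    coords = model.coordinates()
    if coords.shape[0] == 0:
        return np.empty(0)
    radii = atom_radii(model) + probe
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.empty(len(coords))
    rmax = radii.max()
    for i, (c, r) in enumerate(zip(coords, radii)):
        test = c + pts * r
        neigh = [j for j in tree.query_ball_point(c, r + rmax) if j != i]
        if neigh:
            d = np.linalg.norm(test[:, None, :] - coords[neigh][None, :, :], axis=2)
            buried = (d < radii[neigh][None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r * r * frac
    return areas


def total_sasa(model: StructureModel, probe: float = PROBE_RADIUS,
               n_points: int = 960) -> float:
    return float(shrake_rupley_sasa(model, probe, n_points).sum())


# ----------------------------------------------------------------- interface
Selection = Iterable[Tuple[str, Optional[int]]]


@dataclass
class InterfaceReport:
    delta_sasa_total: float      # SASA(A) + SASA(B) - SASA(A+B)
    delta_sasa_half: float       # the common "interface area" convention
    salt_bridges: List[Tuple[str, str]]
    contacts: List[Tuple[str, str, str]]   # (residue A, residue B, type)


def buried_interface_area(model: StructureModel, part_a: Selection,
                          part_b: Selection, probe: float = PROBE_RADIUS,
                          n_points: int = 960,
                          contact_cutoff: float = 4.0) -> InterfaceReport:
    """Surface buried between two disjoint parts of a structure.

    delta-SASA = SASA(A alone) + SASA(B alone) - SASA(A and B together);
    both the total and the half convention are reported because published
    interface areas use either.
    """
    part_a, part_b = list(part_a), list(part_b)
    sub_a = model.subset(part_a)
    sub_b = model.subset(part_b)
    keys_a = {(c.id, r.number) for c in sub_a.chains for r in c.residues}
    keys_b = {(c.id, r.number) for c in sub_b.chains for r in c.residues}
    if keys_a & keys_b:
        raise ValueError("interface parts overlap")
    if not keys_a or not keys_b:
        raise ValueError("both parts must be nonempty")
    both = model.subset(part_a + part_b)
    ds = (total_sasa(sub_a, probe, n_points) + total_sasa(sub_b, probe, n_points)
          - total_sasa(both, probe, n_points))
    bridges = detect_salt_bridges(model, part_a, part_b, cutoff=contact_cutoff)
    contacts = [(a, b, "salt bridge") for a, b in bridges]
    contacts.extend(_contact_pairs(sub_a, sub_b, contact_cutoff, {t[:2] for t in contacts}))
    return InterfaceReport(ds, ds / 2.0, bridges, contacts)


def _contact_pairs(sub_a: StructureModel, sub_b: StructureModel,
                   cutoff: float, skip: set) -> List[Tuple[str, str, str]]:
    out = []
    polar = {"N", "O"}
    for ca, ra, aa in sub_a.atoms():
        for cb, rb, ab in sub_b.atoms():
            if np.linalg.norm(aa.xyz - ab.xyz) <= cutoff:
                la = f"{ca.id}:{ra.name}{ra.number}"
                lb = f"{cb.id}:{rb.name}{rb.number}"
                if (la, lb) in skip:
                    continue
                kind = ("hydrogen bond candidate"
                        if aa.element in polar and ab.element in polar
                        else "hydrophobic")
                out.append((la, lb, kind))
                skip.add((la, lb))
                break
    return out


_BASIC_SIDECHAIN_N = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_SIDECHAIN_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


def detect_salt_bridges(model: StructureModel, part_a: Selection,
                        part_b: Selection, cutoff: float = 4.0) -> List[Tuple[str, str]]:
    """Arg/Lys/His side-chain N within ``cutoff`` of an Asp/Glu side-chain
    carboxylate O across the partition, reported as residue label pairs."""
    sub_a = model.subset(list(part_a))
    sub_b = model.subset(list(part_b))

    def groups(sub: StructureModel):
        basic, acidic = [], []
        for c in sub.chains:
            for r in c.residues:
                label = f"{c.id}:{r.name}{r.number}"
                if r.name in _BASIC_SIDECHAIN_N:
                    pts = [a.xyz for a in r.atoms if a.name in _BASIC_SIDECHAIN_N[r.name]]
                    if pts:
                        basic.append((label, np.stack(pts)))
                if r.name in _ACIDIC_SIDECHAIN_O:
                    pts = [a.xyz for a in r.atoms if a.name in _ACIDIC_SIDECHAIN_O[r.name]]
                    if pts:
                        acidic.append((label, np.stack(pts)))
        return basic, acidic

    basic_a, acidic_a = groups(sub_a)
    basic_b, acidic_b = groups(sub_b)
    out = []
    for basics, acidics in ((basic_a, acidic_b), (basic_b, acidic_a)):
        for lb, bpts in basics:
            for la, apts in acidics:
                d = np.linalg.norm(bpts[:, None, :] - apts[None, :, :], axis=2)
                if d.min() <= cutoff:
                    out.append((lb, la))
    return sorted(set(out))


# -------------------------------------------------------------- cis peptides
def _dihedral(p0, p1, p2, p3) -> float:
    # 0 degrees = p0 and p3 eclipsed (cis), +/-180 = anti (trans)
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def detect_cis_peptides(model: StructureModel, max_abs_omega: float = 30.0,
                        chain_break_cutoff: float = 2.5) -> List[Tuple[str, int, str, float]]:
    """Peptide bonds with |omega| <= 30 degrees (cis), as
    (chain id, residue number of the following residue, residue name, omega).
    Bonds across chain breaks (C-N distance > 2.5 A) are skipped."""
    out = []
    for ch in model.chains:
        for r0, r1 in zip(ch.residues, ch.residues[1:]):
            ca0, c0 = r0.atom("CA"), r0.atom("C")
            n1, ca1 = r1.atom("N"), r1.atom("CA")
            if None in (ca0, c0, n1, ca1):
                continue
            if np.linalg.norm(c0.xyz - n1.xyz) > chain_break_cutoff:
                log.info("chain break %s %d-%d skipped", ch.id, r0.number, r1.number)
                continue
            omega = _dihedral(ca0.xyz, c0.xyz, n1.xyz, ca1.xyz)
            if abs(omega) <= max_abs_omega:
                out.append((ch.id, r1.number, r1.name, omega))
    return out


# ------------------------------------------------------------- hydropathy
def hydrophobicity_map(model: StructureModel,
                       scale: Optional[Dict[str, float]] = None) -> Dict[Tuple[str, int], float]:
    """Residue -> hydropathy value lookup (Kyte-Doolittle by default);
    unknown residue names map to 0 with a warning."""
    scale = scale or KYTE_DOOLITTLE
    out = {}
    for ch in model.chains:
        for r in ch.residues:
            v = scale.get(r.name)
            if v is None:
                warnings.warn(f"no hydropathy value for residue {r.name!r}; using 0")
                v = 0.0
            out[(ch.id, r.number)] = v
    return out


# ---------------------------------------------------------------- cavities
@dataclass
class CavityReport:
    volume: float                 # A^3 of interior voids
    helix_residue_capacity: float


def cavity_volume(model: StructureModel, grid: float = 0.5,
                  probe: float = PROBE_RADIUS) -> CavityReport:
    """Interior void volume by grid flood fill.

    Grid cells inside the probe-inflated atoms are blocked; free cells
    connected to the bounding-box boundary are outside; the remaining free
    cells are interior voids. Capacity divides the volume by the volume of
    one helical residue."""
    coords = model.coordinates()
    if coords.shape[0] == 0:
        raise ValueError("empty structure")
    radii = atom_radii(model) + probe
    margin = radii.max() + 2 * grid
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / grid).astype(int) + 1
    axes = [lo[d] + grid * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    tree = cKDTree(coords)
    k = min(4, len(coords))      # radii differ, nearest centre is not enough
    dist, idx = tree.query(pts, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    blocked = (dist <= radii[idx]).any(axis=1)
    free = ~blocked.reshape(shape)
    labels, _ = ndimage.label(free)
    border = set()
    for d in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[d] = edge
            border.update(np.unique(labels[tuple(sl)]))
    border.discard(0)
    interior = free & ~np.isin(labels, sorted(border))
    vol = float(interior.sum()) * grid ** 3
    return CavityReport(vol, vol / HELIX_RESIDUE_VOLUME)
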