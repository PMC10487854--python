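"""Quartet detection and structural descriptors for G-quadruplex cores.

Implements the descriptors used to characterise a tetramolecular
quadruplex: glycosidic torsion classification (syn/anti), Hoogsteen and
amino-O2 hydrogen-bond detection, planar base-quartet detection via
directed 4-cycles of donor->acceptor bonds, quartet plane/center fits,
hydrogen-bond cycle polarity, inter-quartet step parameters (the in-plane
center offset d, the axial rise and the helical twist), ring-overlap
stacking modes, groove widths and channel-ion binding-site assignment.

The in-plane offset d is the distance between the center of one quartet
and the projection of the neighbouring quartet's center onto its plane; it
measures how well the negative charge centers (the carbonyl oxygens that
coordinate the channel cation) of adjacent quartets are aligned.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import Polygon

from .structure_io import AtomRecord, StructureEnsemble

__all__ = [
    "ResidueRef",
    "HydrogenBond",
    "Quartet",
    "StepGeometry",
    "GlycosidicAngle",
    "IonAssignment",
    "GeometryError",
    "compute_chi",
    "detect_hbonds",
    "detect_quartets",
    "quartet_plane",
    "polarity",
    "step_geometry",
    "stacking_mode",
    "classify_grooves",
    "assign_ions",
    "ion_pair_distances",
    "base_type",
    "G_BASE_ATOMS",
    "C_BASE_ATOMS",
]


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


# base heavy-atom names (ring + exocyclic substituents on the base)
G_BASE_ATOMS = ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4")
C_BASE_ATOMS = ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6")

G_RING5 = ("N9", "C8", "N7", "C5", "C4")
G_RING6 = ("C5", "C6", "N1", "C2", "N3", "C4")
C_RING6 = ("N1", "C2", "N3", "C4", "C5", "C6")

_G_NAMES = {"G", "DG", "GUA", "RG"}
_C_NAMES = {"C", "DC", "CYT", "RC"}

#: donor atom -> names of its hydrogens (when present in the file)
_DONOR_HYDROGENS = {
    "N1": ("H1",),
    "N2": ("H21", "H22"),
    "N4": ("H41", "H42"),
}


def base_type(res_name: str) -> str | None:
    """'G', 'C' or None for non-G/C residues (ions, other bases)."""
    rn = res_name.strip().upper()
    if rn in _G_NAMES:
        return "G"
    if rn in _C_NAMES:
        return "C"
    return None


@dataclass(frozen=True, order=True)
class ResidueRef:
    chain_id: str
    res_seq: int
    res_name: str = field(compare=False, default="")

    def __str__(self) -> str:  # e.g. A:DG1
        return f"{self.chain_id}:{self.res_name}{self.res_seq}"


@dataclass(frozen=True)
class HydrogenBond:
    donor_atom: AtomRecord
    acceptor_atom: AtomRecord
    distance: float
    type: str  # G-Hoogsteen-N1H...O6 | G-Hoogsteen-N2H...N7 | C-amino-N4H...O2 | other

    @property
    def donor_res(self) -> ResidueRef:
        a = self.donor_atom
        return ResidueRef(a.chain_id, a.res_seq, a.res_name)

    @property
    def acceptor_res(self) -> ResidueRef:
        a = self.acceptor_atom
        return ResidueRef(a.chain_id, a.res_seq, a.res_name)


@dataclass
class Quartet:
    """Planar cyclic quartet of four same-type bases.

    ``residues`` are in donor->acceptor cyclic order starting at the lowest
    chain id.  ``normal`` is unit length and, when produced by
    :func:`detect_quartets` on a stack, oriented 5'->3' along the channel
    axis.  ``base_points`` carries per-chain base-atom coordinates so the
    step/stacking/polarity operations are self-contained.
    """

    residues: tuple[ResidueRef, ResidueRef, ResidueRef, ResidueRef]
    base_type: Literal["G", "C"]
    hbonds: tuple[HydrogenBond, ...]
    center: np.ndarray
    normal: np.ndarray
    planarity_rmsd: float
    base_points: Mapping[str, Mapping[str, np.ndarray]] = field(default_factory=dict)
    anchor_points: Mapping[str, np.ndarray] = field(default_factory=dict)  # chain -> C1'
    model_index: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) != 4:
            raise GeometryError("a quartet has exactly 4 residues")
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise GeometryError("quartet normal must be unit length")

    @property
    def polarity(self) -> str:
        """H-bond cycle sense viewed from the 5' side (along ``normal``)."""
        return polarity(self, self.normal)

    @property
    def ring_points(self) -> np.ndarray:
        """(4, 3) base centroids in cyclic residue order."""
        pts = []
        for r in self.residues:
            atoms = self.base_points[r.chain_id]
            pts.append(np.mean(list(atoms.values()), axis=0))
        return np.array(pts)


@dataclass(frozen=True)
class StepGeometry:
    """Geometry between two stacked quartets."""

    d: float  # in-plane center offset, A
    rise: float  # axial separation, A
    twist: float  # mean strand rotation, degrees, in (-180, 180]
    stacking_mode: str  # five_five | five_six | six_six | partial_six | none

    def __post_init__(self) -> None:
        if self.d < 0:
            raise GeometryError("d must be non-negative")
        if not (-180.0 < self.twist <= 180.0):
            raise GeometryError("twist must lie in (-180, 180]")


@dataclass(frozen=True)
class GlycosidicAngle:
    residue: ResidueRef
    chi: float  # degrees in [0, 360)
    conformation: Literal["syn", "anti"]


@dataclass(frozen=True)
class IonAssignment:
    ion_atom: AtomRecord
    site: str  # O5 | I | O3 | OGC | OGG | bulk (core-2 sites get a trailing ')
    axial_coordinate: float
    radial_distance: float


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def compute_chi(
    structure: StructureEnsemble, model: int, residue: tuple[str, int] | ResidueRef
) -> GlycosidicAngle:
    """Glycosidic torsion of one residue, wrapped to [0, 360).

    chi is O4'-C1'-N9-C4 for purines and O4'-C1'-N1-C2 for pyrimidines.
    Classification: syn when chi (wrapped to (-180, 180]) lies in
    (-90, 90], anti otherwise — a deliberate superset of the 30-90 and
    200-280 degree windows typical of refinement restraints, so near-border
    conformers still classify.
    """
    chain_id, res_seq = (residue.chain_id, residue.res_seq) if isinstance(residue, ResidueRef) else residue
    atoms = structure.residue_atoms(chain_id, res_seq, model)
    if not atoms:
        raise GeometryError(f"residue {chain_id}:{res_seq} not found in model {model}")
    res_name = next(iter(atoms.values())).res_name
    bt = base_type(res_name)
    if "N9" in atoms:  # purine
        names = ("O4'", "C1'", "N9", "C4")
    else:  # pyrimidine
        names = ("O4'", "C1'", "N1", "C2")
    missing = [n for n in names if n not in atoms]
    if missing:
        raise GeometryError(
            f"residue {chain_id}:{res_name}{res_seq} lacks chi-defining atom(s) {missing}"
        )
    pts = [np.array(atoms[n].xyz) for n in names]
    chi_signed = dihedral(*pts)
    conformation = "syn" if -90.0 < chi_signed <= 90.0 else "anti"
    chi = chi_signed % 360.0
    return GlycosidicAngle(ResidueRef(chain_id, res_seq, res_name), chi, conformation)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

_BOND_TYPES = (
    # (donor base, donor atom, acceptor base, acceptor atom, label)
    ("G", "N1", "G", "O6", "G-Hoogsteen-N1H...O6"),
    ("G", "N2", "G", "N7", "G-Hoogsteen-N2H...N7"),
    ("C", "N4", "C", "O2", "C-amino-N4H...O2"),
)


def detect_hbonds(
    structure: StructureEnsemble,
    model: int = 0,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> list[HydrogenBond]:
    """Quartet-pairing hydrogen bonds of one model.

    Candidate donor/acceptor pairs are the quartet-defining identities
    (guanine Hoogsteen N1H...O6 and N2H...N7, cytosine amino N4H...O2)
    between distinct residues.  A pair qualifies when the heavy-atom
    distance is at most ``distance_cutoff``; when the donor hydrogen exists
    in the file, additionally the best D-H...A angle must be at least
    ``angle_cutoff`` (deposited NMR models sometimes omit hydrogens, in
    which case the distance criterion alone applies).
    """
    atoms = structure.atoms(model)
    by_res: dict[tuple[str, int], dict[str, AtomRecord]] = {}
    for a in atoms:
        by_res.setdefault((a.chain_id, a.res_seq), {})[a.name] = a

    bonds: list[HydrogenBond] = []
    for dkey, datoms in by_res.items():
        d_base = base_type(next(iter(datoms.values())).res_name)
        if d_base is None:
            continue
        for (db, dn, ab, an, label) in _BOND_TYPES:
            if d_base != db or dn not in datoms:
                continue
            donor = datoms[dn]
            dpos = np.array(donor.xyz)
            for akey, aatoms in by_res.items():
                if akey == dkey:
                    continue
                a_base = base_type(next(iter(aatoms.values())).res_name)
                if a_base != ab or an not in aatoms:
                    continue
                acceptor = aatoms[an]
                apos = np.array(acceptor.xyz)
                dist = float(np.linalg.norm(apos - dpos))
                if dist > distance_cutoff or dist <= 0.0:
                    continue
                h_names = [h for h in _DONOR_HYDROGENS.get(dn, ()) if h in datoms]
                if h_names:
                    best = 0.0
                    for hn in h_names:
                        hpos = np.array(datoms[hn].xyz)
                        v1, v2 = dpos - hpos, apos - hpos
                        cosang = float(
                            v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        )
                        best = max(best, math.degrees(math.acos(max(-1.0, min(1.0, cosang)))))
                    if best < angle_cutoff:
                        continue
                bonds.append(HydrogenBond(donor, acceptor, dist, label))
    return bonds


# ---------------------------------------------------------------------------
# quartet detection
# ---------------------------------------------------------------------------

def _base_atom_map(
    structure: StructureEnsemble, model: int, residues: Iterable[ResidueRef]
) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    for r in residues:
        names = G_BASE_ATOMS if base_type(r.res_name) == "G" else C_BASE_ATOMS
        atoms = structure.residue_atoms(r.chain_id, r.res_seq, model)
        out[r.chain_id] = {n: np.array(atoms[n].xyz) for n in names if n in atoms}
    return out


def quartet_plane(
    base_points: Mapping[str, Mapping[str, np.ndarray]],
    base: str = "G",
    center_convention: Literal["carbonyl", "all_heavy"] = "carbonyl",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through the quartet's base heavy atoms.

    Returns (center, unit normal, planarity rmsd).  The default center is
    the centroid of the four carbonyl oxygens that line the channel (O6
    for G-quartets, O2 for C-quartets) — the cation coordination cage;
    ``all_heavy`` uses the centroid of all base heavy atoms instead.  The
    normal's sign is arbitrary here; stack-aware callers orient it.
    """
    pts = np.array([p for chain in base_points.values() for p in chain.values()])
    if pts.shape[0] < 4:
        raise GeometryError("need at least 4 atoms to fit a quartet plane")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9:  # collinear points: no unique plane
        raise GeometryError("degenerate (collinear) atom arrangement")
    normal = vt[2]
    normal = normal / np.linalg.norm(normal)
    planarity_rmsd = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    carbonyl = "O6" if base == "G" else "O2"
    if center_convention == "carbonyl":
        cpts = [chain[carbonyl] for chain in base_points.values() if carbonyl in chain]
        if len(cpts) != 4:
            raise GeometryError(f"center convention 'carbonyl' needs four {carbonyl} atoms")
        center = np.mean(cpts, axis=0)
    elif center_convention == "all_heavy":
        center = centroid
    else:
        raise GeometryError(f"unknown center convention {center_convention!r}")
    return center, normal, planarity_rmsd


def detect_quartets(
    structure: StructureEnsemble,
    model: int = 0,
    planarity_threshold: float = 1.0,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    center_convention: Literal["carbonyl", "all_heavy"] = "carbonyl",
) -> list[Quartet]:
    """Detect planar base quartets as directed 4-cycles of pairing bonds.

    A directed edge runs from each residue to the residue its primary
    quartet-pairing donor bonds to (guanine N1H...O6, cytosine N4H...O2).
    Every simple directed 4-cycle of same-type bases whose base atoms are
    coplanar within ``planarity_threshold`` (maximum deviation from the
    fitted plane) becomes a quartet.  Quartets are returned sorted along
    the channel axis in the 5'->3' direction of the first chain, with
    their normals oriented the same way.
    """
    bonds = detect_hbonds(structure, model, distance_cutoff, angle_cutoff)
    primary = {"G-Hoogsteen-N1H...O6", "C-amino-N4H...O2"}
    graph = nx.DiGraph()
    edge_bonds: dict[tuple[ResidueRef, ResidueRef], list[HydrogenBond]] = {}
    for b in bonds:
        u, v = b.donor_res, b.acceptor_res
        edge_bonds.setdefault((u, v), []).append(b)
        if b.type in primary:
            graph.add_edge(u, v)

    seen: set[frozenset[ResidueRef]] = set()
    quartets: list[Quartet] = []
    for cycle in nx.simple_cycles(graph, length_bound=4):
        if len(cycle) != 4:
            continue
        types = {base_type(r.res_name) for r in cycle}
        if len(types) != 1:
            continue
        key = frozenset(cycle)
        if key in seen:
            continue
        bt = types.pop()
        base_points = _base_atom_map(structure, model, cycle)
        if len(base_points) < 4:  # two residues on one chain cannot both map
            continue
        try:
            center, normal, prmsd = quartet_plane(base_points, bt, center_convention)
        except GeometryError:
            continue
        pts = np.array([p for chain in base_points.values() for p in chain.values()])
        max_dev = float(np.max(np.abs((pts - pts.mean(axis=0)) @ normal)))
        if max_dev >= planarity_threshold:
            continue
        seen.add(key)
        # canonical cyclic order: start at lowest chain_id, follow edges
        start = min(range(4), key=lambda i: (cycle[i].chain_id, cycle[i].res_seq))
        ordered = tuple(cycle[(start + i) % 4] for i in range(4))
        cyc_bonds = []
        for i in range(4):
            cyc_bonds.extend(edge_bonds.get((ordered[i], ordered[(i + 1) % 4]), []))
        anchors: dict[str, np.ndarray] = {}
        for r in ordered:
            atoms = structure.residue_atoms(r.chain_id, r.res_seq, model)
            if "C1'" in atoms:
                anchors[r.chain_id] = np.array(atoms["C1'"].xyz)
        quartets.append(
            Quartet(
                residues=ordered,
                base_type=bt,
                hbonds=tuple(cyc_bonds),
                center=center,
                normal=normal,
                planarity_rmsd=prmsd,
                base_points=base_points,
                anchor_points=anchors,
                model_index=model + 1,
            )
        )

    if len(quartets) >= 2:
        centers = np.array([q.center for q in quartets])
        axis = _stack_axis(centers)
        axis = _orient_axis(structure, model, axis)
        order = np.argsort(centers @ axis)
        quartets = [quartets[i] for i in order]
        for q in quartets:
            if float(q.normal @ axis) < 0:
                q.normal = -q.normal
    return quartets


def _stack_axis(centers: np.ndarray) -> np.ndarray:
    """Principal direction of the quartet centers (best-fit line)."""
    c = centers - centers.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt[0] / np.linalg.norm(vt[0])


def _orient_axis(structure: StructureEnsemble, model: int, axis: np.ndarray) -> np.ndarray:
    """Flip the axis so it points 5'->3' along the first chain."""
    first_chain = structure.chains()[0]
    res = [(s, n) for c, s, n in structure.residues(model) if c == first_chain and base_type(n)]
    if len(res) >= 2:
        lo, hi = min(res)[0], max(res)[0]
        a5 = structure.residue_atoms(first_chain, lo, model)
        a3 = structure.residue_atoms(first_chain, hi, model)
        p5 = np.mean([np.array(a.xyz) for a in a5.values()], axis=0)
        p3 = np.mean([np.array(a.xyz) for a in a3.values()], axis=0)
        if float((p3 - p5) @ axis) < 0:
            axis = -axis
    return axis


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------

def polarity(quartet: Quartet, viewing_direction: np.ndarray | None = None) -> str:
    """Sense of the donor->acceptor hydrogen-bond cycle.

    ``viewing_direction`` points from the viewer into the scene; the
    default is the quartet normal, i.e. the view from the 5' side when the
    quartet came from a stack.  The circulation vector of the cyclic base
    centroids points at the viewer for an anticlockwise cycle (right-hand
    rule), so the label flips when either the structure is mirrored in a
    plane containing the view axis or the viewing direction is reversed.
    """
    if not quartet.hbonds:
        raise GeometryError("polarity requires a closed hydrogen-bond cycle")
    donors = {b.donor_res for b in quartet.hbonds}
    if not set(quartet.residues) <= donors:
        raise GeometryError("polarity requires a closed hydrogen-bond cycle")
    view = quartet.normal if viewing_direction is None else np.asarray(viewing_direction, float)
    view = view / np.linalg.norm(view)
    pts = quartet.ring_points
    c = pts.mean(axis=0)
    circ = np.zeros(3)
    for i in range(4):
        circ += np.cross(pts[i] - c, pts[(i + 1) % 4] - pts[i])
    s = float(circ @ view)
    if s == 0.0:
        raise GeometryError("degenerate cycle: zero circulation")
    return "anticlockwise" if s < 0 else "clockwise"


# ---------------------------------------------------------------------------
# step geometry & stacking
# ---------------------------------------------------------------------------

def _strand_pairs(q1: Quartet, q2: Quartet) -> list[tuple[str, str]]:
    """Corresponding strands of two stacked quartets.

    Within one core, strands correspond by chain id.  Across a stacking
    interface (no shared chains, as in a 5'-5' dimer) residues are paired
    by nearest projected base centroid (optimal assignment), i.e. by which
    base actually stacks on which.
    """
    shared = sorted(set(q1.anchor_points) & set(q2.anchor_points))
    if len(shared) >= 2:
        return [(c, c) for c in shared]
    from scipy.optimize import linear_sum_assignment

    n = q1.normal
    c1 = [r.chain_id for r in q1.residues]
    c2 = [r.chain_id for r in q2.residues]
    p1 = q1.ring_points
    p2 = q2.ring_points
    # project onto q1's plane before measuring pair distances
    def proj(p):
        rel = p - q1.center
        return rel - np.outer(rel @ n, n)
    d = np.linalg.norm(proj(p1)[:, None, :] - proj(p2)[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(d)
    return [(c1[i], c2[j]) for i, j in zip(rows, cols)]


def step_geometry(q1: Quartet, q2: Quartet, overlap_threshold: float = 0.05) -> StepGeometry:
    """Geometry of the q1 -> q2 step (q1 on the 5' side).

    d is the norm of the in-plane component of the center displacement
    with respect to q1's plane and rise the out-of-plane component, so
    d^2 + rise^2 equals the squared center distance identically.  The
    twist is the circular mean over the four strands of the signed angle
    between the center->C1' directions of corresponding residues,
    projected onto the mean plane; positive twist is a right-handed
    rotation advancing 5'->3'.
    """
    if set(q1.residues) & set(q2.residues):
        raise GeometryError("step quartets must not share residues")
    if q1.model_index != q2.model_index:
        raise GeometryError("step quartets must come from the same model")
    delta = q2.center - q1.center
    n1 = q1.normal
    axial = float(delta @ n1)
    rise = abs(axial)
    in_plane = delta - axial * n1
    d = float(np.linalg.norm(in_plane))

    n2 = q2.normal if float(q2.normal @ n1) >= 0 else -q2.normal
    n_mean = n1 + n2
    n_mean = n_mean / np.linalg.norm(n_mean)

    pairs = [
        (ca, cb)
        for ca, cb in _strand_pairs(q1, q2)
        if ca in q1.anchor_points and cb in q2.anchor_points
    ]
    if len(pairs) < 2:
        raise GeometryError("twist needs C1' anchors on at least two paired strands")
    sines, cosines = [], []
    for ca, cb in pairs:
        v1 = q1.anchor_points[ca] - q1.center
        v2 = q2.anchor_points[cb] - q2.center
        v1 = v1 - (v1 @ n_mean) * n_mean
        v2 = v2 - (v2 @ n_mean) * n_mean
        ang = math.atan2(float(np.cross(v1, v2) @ n_mean), float(v1 @ v2))
        sines.append(math.sin(ang))
        cosines.append(math.cos(ang))
    twist = math.degrees(math.atan2(np.mean(sines), np.mean(cosines)))
    if twist <= -180.0:
        twist += 360.0
    mode = stacking_mode(q1, q2, overlap_threshold)
    return StepGeometry(d=d, rise=rise, twist=twist, stacking_mode=mode)


def _ring_polygon(points: Mapping[str, np.ndarray], names: Sequence[str],
                  origin: np.ndarray, u: np.ndarray, v: np.ndarray) -> Polygon | None:
    if any(n not in points for n in names):
        return None
    pts2 = [((points[n] - origin) @ u, (points[n] - origin) @ v) for n in names]
    poly = Polygon(pts2)
    return poly if poly.is_valid and poly.area > 0 else None


def stacking_mode(q1: Quartet, q2: Quartet, area_fraction: float = 0.05) -> str:
    """Ring-overlap stacking classification of an adjacent quartet pair.

    For each strand the five- and six-membered ring polygons of the two
    stacked residues are projected onto the mean quartet plane and clipped
    against each other.  The step is labelled by the ring pair with the
    largest mean overlap area (``five_six`` pools 5-on-6 with 6-on-5);
    ``partial_six`` is the case where only the six-ring overlap survives
    the ``area_fraction`` threshold (a fraction of a six-ring's area) but
    covers less than half a ring; ``none`` when every overlap is below
    threshold.  Pyrimidine quartets contribute six-membered rings only.
    """
    n1 = q1.normal
    n2 = q2.normal if float(q2.normal @ n1) >= 0 else -q2.normal
    n_mean = n1 + n2
    n_mean = n_mean / np.linalg.norm(n_mean)
    # in-plane basis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(float(seed @ n_mean)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - (seed @ n_mean) * n_mean
    u = u / np.linalg.norm(u)
    v = np.cross(n_mean, u)
    origin = 0.5 * (q1.center + q2.center)

    overlaps = {"55": [], "56": [], "66": []}
    six_areas = []
    for ca, cb in _strand_pairs(q1, q2):
        p1, p2 = q1.base_points[ca], q2.base_points[cb]
        r5_names = G_RING5 if q1.base_type == "G" else None
        s5_names = G_RING5 if q2.base_type == "G" else None
        r6_names = G_RING6 if q1.base_type == "G" else C_RING6
        s6_names = G_RING6 if q2.base_type == "G" else C_RING6
        r5 = _ring_polygon(p1, r5_names, origin, u, v) if r5_names else None
        s5 = _ring_polygon(p2, s5_names, origin, u, v) if s5_names else None
        r6 = _ring_polygon(p1, r6_names, origin, u, v)
        s6 = _ring_polygon(p2, s6_names, origin, u, v)
        if r6 is None or s6 is None:
            continue
        six_areas.append(0.5 * (r6.area + s6.area))
        overlaps["55"].append(r5.intersection(s5).area if r5 and s5 else 0.0)
        a56 = r5.intersection(s6).area if r5 else 0.0
        a65 = s5.intersection(r6).area if s5 else 0.0
        overlaps["56"].append(max(a56, a65))
        overlaps["66"].append(r6.intersection(s6).area)
    if not six_areas:
        return "none"
    m55 = float(np.mean(overlaps["55"]))
    m56 = float(np.mean(overlaps["56"]))
    m66 = float(np.mean(overlaps["66"]))
    six_area = float(np.mean(six_areas))
    thr = area_fraction * six_area
    if max(m55, m56, m66) < thr:
        return "none"
    if m55 < thr and m56 < thr:
        return "partial_six" if m66 < 0.5 * six_area else "six_six"
    best = max(("five_five", m55), ("five_six", m56), ("six_six", m66), key=lambda t: t[1])
    return best[0]


# ---------------------------------------------------------------------------
# grooves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrooveRecord:
    chains: tuple[str, str]
    width: float  # A
    groove_class: str  # narrow | medium | wide


def classify_grooves(
    structure: StructureEnsemble,
    model: int,
    quartets: Sequence[Quartet],
    thresholds: tuple[float, float] = (14.0, 19.0),
) -> list[GrooveRecord]:
    """Widths of the four grooves between adjacent strands.

    The groove between two adjacent strands (adjacent in the quartet's
    cyclic residue order) is measured as the mean, over the phosphorus
    atoms of the quartet residues of both strands, of the closest P-P
    distance to the other strand.  Classes by ``thresholds``:
    below the first bound narrow, above the second wide, else medium.
    """
    if len(quartets) < 2:
        raise GeometryError("groove classification needs at least two quartets")
    cyc_chains = [r.chain_id for r in quartets[0].residues]
    p_atoms: dict[str, list[np.ndarray]] = {c: [] for c in cyc_chains}
    missing: list[str] = []
    for q in quartets:
        for r in q.residues:
            atoms = structure.residue_atoms(r.chain_id, r.res_seq, model)
            if "P" not in atoms:
                missing.append(str(r))
            elif r.chain_id in p_atoms:
                p_atoms[r.chain_id].append(np.array(atoms["P"].xyz))
    if missing:
        raise GeometryError(f"phosphorus atoms missing for residues: {missing}")
    lo, hi = thresholds
    records = []
    for i in range(4):
        c1, c2 = cyc_chains[i], cyc_chains[(i + 1) % 4]
        a = np.array(p_atoms[c1])
        b = np.array(p_atoms[c2])
        dmat = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        width = float(0.5 * (dmat.min(axis=1).mean() + dmat.min(axis=0).mean()))
        cls = "narrow" if width < lo else ("wide" if width > hi else "medium")
        records.append(GrooveRecord((c1, c2), width, cls))
    return records


# ---------------------------------------------------------------------------
# ion binding-site assignment
# ---------------------------------------------------------------------------

def _site_names(quartets: Sequence[Quartet]) -> list[str]:
    """Names of the inter-quartet intervals, in stack order.

    G/G intervals are named from the residue numbers: the interval below
    the second G-quartet of a core is the 5'-outer site O5, the one above
    the second-to-last the 3'-outer site O3, interior ones I; a G/C
    interval is the OGC cavity; two 5' G-quartets facing each other (equal
    residue numbers, as in a 5'-5' stacked dimer) enclose the interface
    site OGG.  Sites formed purely by second-core chains get a prime.
    """
    g_seqs = sorted({r.res_seq for q in quartets if q.base_type == "G" for r in q.residues})
    all_chains = sorted({r.chain_id for q in quartets for r in q.residues})
    core1_chains = next(
        chains
        for q in quartets
        if all_chains[0] in (chains := {r.chain_id for r in q.residues})
    )
    names = []
    for qa, qb in zip(quartets, quartets[1:]):
        pair = {qa.base_type, qb.base_type}
        sa = qa.residues[0].res_seq
        sb = qb.residues[0].res_seq
        if pair == {"G", "C"}:
            name = "OGC"
        elif sa == sb:
            name = "OGG"
        else:
            if min(sa, sb) == g_seqs[0]:
                name = "O5"
            elif max(sa, sb) == g_seqs[-1]:
                name = "O3"
            else:
                name = "I"
        chains = {r.chain_id for r in qa.residues} | {r.chain_id for r in qb.residues}
        if not (chains & core1_chains):
            name += "'"
        names.append(name)
    # disambiguate repeated interior labels when a core has >4 G-quartets
    if sum(1 for n in names if n == "I") > 1:
        k = 0
        for i, n in enumerate(names):
            if n == "I":
                k += 1
                names[i] = f"I{k}"
    return names


def assign_ions(
    structure: StructureEnsemble,
    model: int,
    quartets: Sequence[Quartet],
    radial_cutoff: float = 3.0,
) -> list[IonAssignment]:
    """Assign channel ions to named inter-quartet binding sites.

    The channel axis is the best-fit line through the quartet centers,
    oriented 5'->3'.  An ion whose radial distance from the axis is at
    most ``radial_cutoff`` and whose axial coordinate falls inside an
    inter-quartet interval is assigned that interval's site name;
    everything else is bulk.
    """
    if not quartets:
        raise GeometryError("ion assignment requires detected quartets")
    if len(quartets) < 2:
        raise GeometryError("ion assignment needs at least two quartets to define the axis")
    centers = np.array([q.center for q in quartets])
    axis = _stack_axis(centers)
    if float((centers[-1] - centers[0]) @ axis) < 0:
        axis = -axis
    origin = centers[0]
    s_quartets = (centers - origin) @ axis
    names = _site_names(quartets)

    out: list[IonAssignment] = []
    for a in structure.atoms(model):
        if not a.is_ion:
            continue
        p = np.array(a.xyz)
        s = float((p - origin) @ axis)
        radial = float(np.linalg.norm(p - origin - s * axis))
        site = "bulk"
        if radial <= radial_cutoff:
            for j in range(len(quartets) - 1):
                lo, hi = sorted((s_quartets[j], s_quartets[j + 1]))
                if lo <= s <= hi:
                    site = names[j]
                    break
        out.append(IonAssignment(a, site, s, radial))
    return out


def ion_pair_distances(assignments: Sequence[IonAssignment]) -> dict[tuple[str, str], float]:
    """All pairwise ion-ion distances, keyed by site labels (ties keep
    serial order)."""
    dists: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(assignments, 2):
        key = (f"{a.site}#{a.ion_atom.serial}", f"{b.site}#{b.ion_atom.serial}")
        dists[key] = float(
            np.linalg.norm(np.array(a.ion_atom.xyz) - np.array(b.ion_atom.xyz))
        )
    return dists
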