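"""Synthetic test-input generators.

Three generators feed the rest of the package:

* :func:`build_quadruplex` — idealized C4-symmetric parallel tetramolecular
  quadruplex coordinates (G-quartet stack, optional C-quartet, channel ions,
  optional 5'-5' stacked dimer) with exactly controllable per-step rise,
  twist and in-plane offset and per-quartet glycosidic class.
* :func:`simulate_exchange` — NzExHSQC-style peak-volume curves from a
  site-exchange master equation with per-site spin-lattice relaxation,
  the oracle for the exchange-rate fitting.
* :func:`sample_gaussian_work` — seeded Gaussian nonequilibrium work
  samples, the oracle for the Jarzynski estimator.

The quadruplex builder places four symmetry copies of an idealized planar
nucleobase template.  The template's in-plane position/orientation is
calibrated (once, numerically) so that the inter-base hydrogen-bond
heavy-atom distances take their canonical ~2.9 A values; nothing downstream
depends on the template's absolute coordinates, only on the constructed
relations (rise, twist, offset, chi).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

from .structure_io import AtomRecord, StructureEnsemble

__all__ = [
    "BuilderSpec",
    "ExchangeNetworkSpec",
    "VolumeSeries",
    "build_quadruplex",
    "simulate_exchange",
    "sample_gaussian_work",
]

# ---------------------------------------------------------------------------
# idealized planar base templates (x, y in the base plane, Angstrom)
# ---------------------------------------------------------------------------

_GUANINE = {
    "C1'": (-2.477, 5.399),
    "N9": (-1.289, 4.551),
    "C8": (0.023, 4.962),
    "N7": (0.870, 3.969),
    "C5": (0.071, 2.833),
    "C6": (0.424, 1.460),
    "O6": (1.554, 0.955),
    "N1": (-0.700, 0.641),
    "C2": (-1.999, 1.087),
    "N2": (-2.949, 0.139),
    "N3": (-2.342, 2.364),
    "C4": (-1.265, 3.177),
}

_CYTOSINE = {
    "C1'": (-2.477, 5.402),
    "N1": (-1.285, 4.542),
    "C2": (-1.472, 3.158),
    "O2": (-2.628, 2.709),
    "N3": (-0.391, 2.344),
    "C4": (0.837, 2.868),
    "N4": (1.875, 2.027),
    "C5": (1.056, 4.275),
    "C6": (-0.023, 5.068),
}

_NH_BOND = 1.01  # N-H bond length, A
_HB_DIST = 2.86  # target donor-acceptor heavy-atom distance, A
_O6_RADIUS = 2.45  # carbonyl-oxygen ring radius around the channel axis, A
_O2_RADIUS = 2.55


def _rot2(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _add_amino_hydrogens(coords: dict[str, np.ndarray], base: str) -> None:
    """In-plane hydrogens on the quartet donor groups (2D template stage)."""
    if base == "G":
        # H1 on N1 along the exterior bisector of C2-N1-C6
        n1, c2, c6 = coords["N1"], coords["C2"], coords["C6"]
        u = n1 - 0.5 * (c2 + c6)
        coords["H1"] = n1 + _NH_BOND * u / np.linalg.norm(u)
        # amino H21/H22 on N2, +-60 degrees off the C2->N2 direction
        n2, c2 = coords["N2"], coords["C2"]
        u = (n2 - c2) / np.linalg.norm(n2 - c2)
        coords["H21"] = n2 + _NH_BOND * (_rot2(math.radians(60)) @ u)
        coords["H22"] = n2 + _NH_BOND * (_rot2(math.radians(-60)) @ u)
    else:
        n4, c4 = coords["N4"], coords["C4"]
        u = (n4 - c4) / np.linalg.norm(n4 - c4)
        coords["H41"] = n4 + _NH_BOND * (_rot2(math.radians(60)) @ u)
        coords["H42"] = n4 + _NH_BOND * (_rot2(math.radians(-60)) @ u)


@functools.lru_cache(maxsize=None)
def _quartet_template(base: str) -> tuple[tuple[str, float, float], ...]:
    """Calibrated in-plane template of one residue of a C4 quartet.

    The carbonyl oxygen that lines the channel (O6 for G, O2 for C) is
    pinned on a fixed ring radius around the axis and the base is rotated
    about it so that the donor-acceptor distances to the +90-degree
    symmetry copy take the canonical H-bond length:

    * G: N1...O6' = N2...N7' ~ 2.86 A  (Hoogsteen pairing)
    * C: N4...O2' = 2.86 A             (amino-O2 pairing)

    The rotation has two roots (a bonding and a mirror arrangement); the
    one whose amino hydrogens point at the acceptor is selected.
    """
    tmpl = {k: np.array(v) for k, v in (_GUANINE if base == "G" else _CYTOSINE).items()}
    rot90 = _rot2(math.pi / 2)
    anchor, radius = ("O6", _O6_RADIUS) if base == "G" else ("O2", _O2_RADIUS)
    fix = np.array([radius, 0.0])

    def placed_at(phi: float) -> dict[str, np.ndarray]:
        rot = _rot2(phi)
        a = tmpl[anchor]
        return {k: rot @ (v - a) + fix for k, v in tmpl.items()}

    if base == "G":
        pairs = [("N1", "O6"), ("N2", "N7")]
    else:
        pairs = [("N4", "O2")]

    def residuals(p: np.ndarray) -> np.ndarray:
        placed = placed_at(p[0])
        return np.array(
            [np.linalg.norm(rot90 @ placed[acc] - placed[don]) - _HB_DIST for don, acc in pairs]
        )

    def donor_angle(placed: dict[str, np.ndarray]) -> float:
        """Best D-H...A angle of the primary donor, degrees."""
        _add_amino_hydrogens(placed, base)
        don, acc = pairs[0]
        a = rot90 @ placed[acc]
        hs = ["H1"] if base == "G" else ["H41", "H42"]
        best = 0.0
        for h in hs:
            v1, v2 = placed[don] - placed[h], a - placed[h]
            cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            best = max(best, math.degrees(math.acos(max(-1.0, min(1.0, cosang)))))
        return best

    best_sol: tuple[float, float] | None = None  # (cost, phi)
    for phi0 in np.linspace(0.0, 2 * math.pi, 36, endpoint=False):
        sol = least_squares(residuals, x0=[phi0])
        if donor_angle(placed_at(float(sol.x[0]))) < 120.0:
            continue  # mirror root: hydrogens face away from the acceptor
        if best_sol is None or sol.cost < best_sol[0]:
            best_sol = (float(sol.cost), float(sol.x[0]))
    assert best_sol is not None and best_sol[0] < 5e-3, "template calibration failed"
    placed = placed_at(best_sol[1])
    if base == "C":
        # rotate the whole quartet so the C1' azimuth matches the guanine
        # template's: step twists between G- and C-quartets are then measured
        # against a common strand reference (backbone continuity)
        g_c1 = _place(_quartet_template("G"), "C1'")
        az_g = math.atan2(g_c1[1], g_c1[0])
        az_c = math.atan2(placed["C1'"][1], placed["C1'"][0])
        rot = _rot2(az_g - az_c)
        placed = {k: rot @ v for k, v in placed.items()}
    _add_amino_hydrogens(placed, base)
    return tuple((name, float(x), float(y)) for name, (x, y) in placed.items())


def _place(template: tuple[tuple[str, float, float], ...], name: str) -> np.ndarray:
    for n, x, y in template:
        if n == name:
            return np.array([x, y])
    raise KeyError(name)


# ---------------------------------------------------------------------------
# internal-coordinate atom placement (NeRF)
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, phi: float) -> np.ndarray:
    """Place atom d with |d-c| = r, angle(d,c,b) = theta, dihedral(a,b,c,d) = phi
    (IUPAC sign convention)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(phi), -r * math.sin(theta) * math.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# builder specification
# ---------------------------------------------------------------------------

def _per_step(value: float | Sequence[float], n_steps: int, name: str) -> list[float]:
    if isinstance(value, (int, float)):
        return [float(value)] * n_steps
    vals = [float(v) for v in value]
    if len(vals) != n_steps:
        raise ValueError(f"{name}: expected {n_steps} per-step values, got {len(vals)}")
    return vals


@dataclass
class BuilderSpec:
    """Parameters of the idealized quadruplex.

    Defaults reproduce the topology of the [d(G4C2)]4 quadruplex studied
    here: four G-quartets plus a C-quartet, an all-syn 5' quartet with all
    later quartets anti, a 3.3 A stacking rise, the 21.6 degree twist
    measured for this structure, the printed inter-quartet center offsets
    (0.4/0.5/0.6 A for the three G-steps), and ammonium ions at the three
    channel binding sites.  The dimer interface defaults (rise 3.57 A,
    twist 14.8 degrees) are the converged 5'-5' stacking geometry.
    """

    n_g_quartets: int = 4
    include_c_quartet: bool = True
    rise: float | Sequence[float] = 3.3
    twist: float | Sequence[float] = 21.6
    offset: float | Sequence[float] = (0.4, 0.5, 0.6, 0.5)
    offset_azimuth: float | Sequence[float] = 0.0
    glycosidic: Sequence[str] | None = None  # per quartet, "syn" | "anti"
    ions: Sequence[tuple[str, str]] = (("O5", "NH4"), ("I", "NH4"), ("O3", "NH4"))
    n_cores: int = 1
    interface_rise: float = 3.57
    interface_twist: float = 14.8

    @property
    def n_quartets(self) -> int:
        return self.n_g_quartets + (1 if self.include_c_quartet else 0)

    def __post_init__(self) -> None:
        if self.n_g_quartets < 2:
            raise ValueError("need at least 2 G-quartets")
        if self.n_cores not in (1, 2):
            raise ValueError("n_cores must be 1 or 2")
        n_steps = self.n_quartets - 1
        if isinstance(self.offset, Sequence) and not isinstance(self.offset, str):
            # per-step offsets: truncate or pad (repeating the last value) so
            # the paper-geometry default applies to any quartet count
            off = list(self.offset)[:n_steps]
            off += [off[-1]] * (n_steps - len(off))
            self.offset = tuple(off)
        self.rises = _per_step(self.rise, n_steps, "rise")
        self.twists = _per_step(self.twist, n_steps, "twist")
        self.offsets = _per_step(self.offset, n_steps, "offset")
        self.azimuths = _per_step(self.offset_azimuth, n_steps, "offset_azimuth")
        if any(r <= 0 for r in self.rises):
            raise ValueError("rise must be positive")
        if any(off >= _O6_RADIUS for off in self.offsets):
            raise ValueError(f"in-plane offset must be < quartet radius ({_O6_RADIUS} A)")
        if self.glycosidic is None:
            self.glycosidic = ["syn"] + ["anti"] * (self.n_quartets - 1)
        self.glycosidic = [g.lower() for g in self.glycosidic]
        if len(self.glycosidic) != self.n_quartets:
            raise ValueError("glycosidic needs one entry per quartet")
        if any(g not in ("syn", "anti") for g in self.glycosidic):
            raise ValueError("glycosidic entries must be 'syn' or 'anti'")


_CHAINS_CORE1 = ("A", "B", "C", "D")
_CHAINS_CORE2 = ("E", "F", "G", "H")


def _residue_atoms_3d(base: str, chi_deg: float) -> list[tuple[str, np.ndarray]]:
    """One residue in the quartet frame: planar base at z=0 plus sugar atoms
    (O4' placed to realize the requested glycosidic torsion, a backbone P
    marker placed radially outward)."""
    template = _quartet_template(base)
    atoms: list[tuple[str, np.ndarray]] = [
        (name, np.array([x, y, 0.0])) for name, x, y in template
    ]
    pos = {name: p for name, p in atoms}
    if base == "G":
        n_gly, c_ref = pos["N9"], pos["C4"]
    else:
        n_gly, c_ref = pos["N1"], pos["C2"]
    c1p = pos["C1'"]
    o4p = _nerf(
        c_ref, n_gly, c1p,
        r=1.42, theta=math.radians(108.2), phi=math.radians(chi_deg),
    )
    atoms.append(("O4'", o4p))
    # backbone phosphorus marker: radially outward from the channel axis,
    # C4-symmetric by construction (grooves only need P-P distances); the
    # radial extension puts groove P-P widths in the medium class typical
    # of all-parallel quadruplexes
    radial = c1p.copy()
    radial[2] = 0.0
    p_atom = c1p + 5.0 * radial / np.linalg.norm(radial) + np.array([0.0, 0.0, 1.0])
    atoms.append(("P", p_atom))
    return atoms


def _element_of(atom_name: str) -> str:
    if atom_name.startswith(("H", "1H", "2H")):
        return "H"
    return atom_name[0]


def build_quadruplex(spec: BuilderSpec) -> StructureEnsemble:
    """Construct a single-model :class:`StructureEnsemble` from *spec*.

    Strands run 5'->3' with increasing z; quartet j (0-based) is rotated by
    the cumulative twist about +z (right-handed), shifted by the cumulative
    in-plane offset and raised by the cumulative rise, so every requested
    step parameter is recovered exactly by the geometry module.
    """
    records: list[AtomRecord] = []
    serial = 0

    def emit(core: int):
        """Build one core in its local frame; returns (centers, sites, records)."""
        chains = _CHAINS_CORE1 if core == 0 else _CHAINS_CORE2
        centers: list[np.ndarray] = []
        core_records: list[tuple[str, int, str, str, np.ndarray]] = []
        z = 0.0
        theta = 0.0
        t = np.zeros(2)
        for j in range(spec.n_quartets):
            base = "C" if (spec.include_c_quartet and j == spec.n_g_quartets) else "G"
            chi = 60.0 if spec.glycosidic[j] == "syn" else 240.0
            res_atoms = _residue_atoms_3d(base, chi)
            for si in range(4):
                srot = _rot2(theta + si * math.pi / 2)
                for name, p in res_atoms:
                    xy = srot @ p[:2] + t
                    xyz = np.array([xy[0], xy[1], p[2] + z])
                    res_name = "DG" if base == "G" else "DC"
                    core_records.append((chains[si], j + 1, res_name, name, xyz))
            centers.append(np.array([t[0], t[1], z]))
            if j < spec.n_quartets - 1:
                z += spec.rises[j]
                theta += math.radians(spec.twists[j])
                az = math.radians(spec.azimuths[j])
                t = t + spec.offsets[j] * np.array([math.cos(az), math.sin(az)])
        # ion site midpoints in this core's frame
        sites: dict[str, np.ndarray] = {}
        site_names = ["O5", "I", "O3", "OGC"]
        for j in range(min(len(centers) - 1, len(site_names))):
            sites[site_names[j]] = 0.5 * (centers[j] + centers[j + 1])
        return centers, sites, core_records

    # the head-to-head mirror flips the C1' azimuth, so the rotation applied
    # to core 2 is offset by twice the template C1' azimuth to make the
    # requested interface twist equal the measured quartet-quartet twist
    g_c1 = _place(_quartet_template("G"), "C1'")
    az_c1 = math.atan2(g_c1[1], g_c1[0])

    def flip_and_shift(p: np.ndarray) -> np.ndarray:
        """Core-2 placement: 180-degree flip about x (5' quartet facing down
        toward core 1's 5' quartet), interface twist about z, then shifted so
        the two G1 planes are interface_rise apart below core 1."""
        q = np.array([p[0], -p[1], -p[2]])
        phi = 2.0 * az_c1 - math.radians(spec.interface_twist)
        xy = _rot2(phi) @ q[:2]
        return np.array([xy[0], xy[1], q[2] - spec.interface_rise])

    centers1, sites1, recs1 = emit(0)
    all_recs = [(c, s, rn, an, xyz) for c, s, rn, an, xyz in recs1]
    ion_sites = dict(sites1)
    if spec.n_cores == 2:
        centers2, sites2, recs2 = emit(1)
        all_recs += [(c, s, rn, an, flip_and_shift(xyz)) for c, s, rn, an, xyz in recs2]
        g1_core2 = flip_and_shift(centers2[0])
        ion_sites["OGG"] = 0.5 * (centers1[0] + g1_core2)

    for chain, seq, res_name, name, xyz in all_recs:
        serial += 1
        records.append(
            AtomRecord(
                serial=serial, name=name, element=_element_of(name),
                res_name=res_name, res_seq=seq, chain_id=chain,
                xyz=tuple(float(v) for v in xyz), model_index=1, het=False,
            )
        )
    for k, (site, ion_name) in enumerate(spec.ions, start=1):
        if site not in ion_sites:
            raise ValueError(f"ion site {site!r} not present in this spec "
                             f"(available: {sorted(ion_sites)})")
        xyz = ion_sites[site]
        element = "N" if ion_name.upper() in ("NH4", "N") else ion_name.upper()
        serial += 1
        records.append(
            AtomRecord(
                serial=serial, name=element, element=element,
                res_name=ion_name.upper(), res_seq=100 + k, chain_id="Z",
                xyz=tuple(float(v) for v in xyz), model_index=1, het=True,
            )
        )
    return StructureEnsemble(models=[records], metadata="build_quadruplex")


# ---------------------------------------------------------------------------
# exchange-network simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeSeries:
    """Normalized peak volumes against NzExHSQC mixing time."""

    peak_label: str
    mixing_times: tuple[float, ...]
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.mixing_times, float)
        v = np.asarray(self.volumes, float)
        if t.size != v.size:
            raise ValueError("mixing_times and volumes must have equal length")
        if t.size and (np.any(t <= 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("mixing_times must be strictly increasing and positive")

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.mixing_times, float)

    @property
    def v(self) -> np.ndarray:
        return np.asarray(self.volumes, float)


#: mixing-time grid of the experiment this emulates: 13 ms to 3 s
DEFAULT_MIXING_TIMES: tuple[float, ...] = tuple(
    float(x) for x in np.geomspace(0.013, 3.0, 16)
)


@dataclass
class ExchangeNetworkSpec:
    """Site-exchange network with per-site T1 relaxation.

    ``rates[(src, dst)]`` are first-order site-to-site rate constants in
    1/s.  The default network mirrors the cation kinetics observed for
    [d(G4C2)]4: fastest movement out of the 3'-outer site (O3 -> I and
    O3 -> bulk, whose fitted apparent rates come out near the observed
    ~2/s ceiling), slower interior hops, no detectable bulk -> O3 return,
    and initial magnetization in the 2:1:1 occupancy ratio of the
    O5/I/O3 sites over a large bulk pool.  Note the cross-peak equation's
    apparent rate tracks the origin site's total escape rate, so the
    microscopic defaults are set below the apparent-rate targets.
    """

    sites: tuple[str, ...] = ("B", "O5", "I", "O3")
    rates: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("O5", "I"): 0.3,
            ("I", "O5"): 0.5,
            ("I", "O3"): 0.4,
            ("O3", "I"): 0.9,
            ("O3", "B"): 0.9,
        }
    )
    t1: Mapping[str, float] = field(
        default_factory=lambda: {"B": 0.45, "O5": 0.6, "I": 0.5, "O3": 0.5}
    )
    m0: Mapping[str, float] = field(
        default_factory=lambda: {"B": 8.0, "O5": 2.0, "I": 1.0, "O3": 1.0}
    )
    mixing_times: Sequence[float] = DEFAULT_MIXING_TIMES
    noise_sigma: float = 0.0
    seed: int | None = None

    def generator(self) -> np.ndarray:
        """Master-equation generator K: K[dst, src] = rate src->dst,
        K[s, s] = -(total outflow of s)."""
        n = len(self.sites)
        idx = {s: i for i, s in enumerate(self.sites)}
        K = np.zeros((n, n))
        for (src, dst), k in self.rates.items():
            if k < 0:
                raise ValueError(f"negative rate {src}->{dst}")
            if src not in idx or dst not in idx:
                raise ValueError(f"unknown site in rate {src}->{dst}")
            K[idx[dst], idx[src]] += k
        K -= np.diag(K.sum(axis=0))
        return K

    def relaxation(self) -> np.ndarray:
        for s in self.sites:
            if self.t1[s] <= 0:
                raise ValueError(f"T1 of site {s} must be positive")
        return np.diag([1.0 / self.t1[s] for s in self.sites])


def simulate_exchange(spec: ExchangeNetworkSpec) -> dict[str, VolumeSeries]:
    """Propagate M(tau) = expm[(K - R) tau] M(0) and read off peak volumes.

    Autocorrelation peak of site s is the s->s transfer amplitude times the
    initial magnetization of s; the cross-peak labelled ``f"{src}{dst}"`` is
    the src->dst transfer amplitude times M0(src).  Optional seeded
    multiplicative Gaussian noise emulates integration error.
    """
    K = spec.generator()
    if not np.allclose(K.sum(axis=0), 0.0, atol=1e-12):
        raise ValueError("non-conservative exchange generator")
    R = spec.relaxation()
    A = K - R
    taus = np.asarray(list(spec.mixing_times), float)
    m0 = np.array([spec.m0[s] for s in spec.sites], float)
    n = len(spec.sites)

    transfer = np.empty((taus.size, n, n))
    for i, tau in enumerate(taus):
        transfer[i] = expm(A * tau)

    rng = np.random.default_rng(spec.seed)

    def noisy(v: np.ndarray) -> np.ndarray:
        if spec.noise_sigma > 0:
            return v * (1.0 + spec.noise_sigma * rng.standard_normal(v.shape))
        return v

    out: dict[str, VolumeSeries] = {}
    for j, s in enumerate(spec.sites):
        v = noisy(transfer[:, j, j] * m0[j])
        out[s] = VolumeSeries(s, tuple(taus), tuple(v))
    for (src, dst) in spec.rates:
        i, j = spec.sites.index(src), spec.sites.index(dst)
        v = noisy(transfer[:, j, i] * m0[i])
        out[f"{src}{dst}"] = VolumeSeries(f"{src}{dst}", tuple(taus), tuple(v))
    return out


def sample_gaussian_work(mu: float, sigma: float, n: int, seed: int | None = None) -> np.ndarray:
    """n Gaussian work samples (kcal/mol); identical seed, identical output."""
    if n < 1:
        raise ValueError("need at least one work sample")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    return mu + sigma * rng.standard_normal(n)
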