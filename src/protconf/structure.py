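"""Structure-based FRET prediction and structural measurements.

Theoretical FRET efficiencies for a dye pair attached to a structural model
are obtained with the accessible-volume (AV) approach: each dye is
represented by the cloud of sterically allowed positions reachable from its
attachment atom through a flexible linker of length L and width w, and the
mean efficiency is averaged over donor-acceptor position pairs,

    <E> = < 1 / (1 + (R / R0)^6) >,

the dynamic-averaging convention.  The module also computes Ca-Ca distances
and buried surface area (BSA) between domain groups via Shrake-Rupley
solvent-accessible surface area (SASA).

Prothrombin convention: residues numbered 1-579 with domains Gla 1-46,
kringle-1 65-143, kringle-2 170-248, protease 285-579.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

logger = logging.getLogger("protconf")

#: prothrombin domain boundaries (1-579 numbering)
PROTHROMBIN_DOMAINS: dict[str, tuple[int, int]] = {
    "gla": (1, 46),
    "kringle1": (65, 143),
    "kringle2": (170, 248),
    "protease": (285, 579),
}

#: labelling sites used for the smFRET pairs
FRET_SITES = (34, 101, 120, 160, 210, 478)

#: Forster radius for the AF555/AF647 pair, Angstrom
DEFAULT_R0 = 51.0

_FALLBACK_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}


def _vdw_radius(element: str) -> float:
    try:
        r = gemmi.Element(element).vdw_r
        if r and r > 0:
            return float(r)
    except Exception:
        pass
    return _FALLBACK_VDW.get(element.upper(), 1.70)


@dataclass
class StructureModel:
    """Flat atomic model: parallel arrays plus named domain residue ranges."""

    element: np.ndarray          # str
    name: np.ndarray             # atom name, str
    resnum: np.ndarray           # int
    chain: np.ndarray            # str
    xyz: np.ndarray              # (n, 3) float, Angstrom
    radius: np.ndarray           # vdW radius, Angstrom
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = len(self.xyz)
        self.element = np.asarray(self.element, dtype=object)
        self.name = np.asarray(self.name, dtype=object)
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.chain = np.asarray(self.chain, dtype=object)
        self.radius = np.asarray(self.radius, dtype=float)
        if not (len(self.element) == len(self.name) == len(self.resnum)
                == len(self.chain) == len(self.radius) == n):
            raise ValueError("atom arrays must have equal length")
        if n and not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        if n and not np.all(self.radius > 0):
            raise ValueError("vdW radii must be positive")

    def __len__(self) -> int:
        return len(self.xyz)

    # ---- selections -------------------------------------------------------

    def residue_mask(self, lo: int, hi: int) -> np.ndarray:
        return (self.resnum >= lo) & (self.resnum <= hi)

    def subset(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.element[mask], self.name[mask], self.resnum[mask],
            self.chain[mask], self.xyz[mask], self.radius[mask],
            dict(self.domains),
        )

    def find_atom(self, resnum: int, name: str, chain: str | None = None) -> int:
        m = (self.resnum == resnum) & (self.name == name)
        if chain is not None:
            m &= self.chain == chain
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise KeyError(f"atom {name} of residue {resnum} not found")
        return int(idx[0])

    # ---- I/O ---------------------------------------------------------------

    def to_pdb(self, path: str | Path) -> None:
        st = gemmi.Structure()
        st.name = "model"
        model = gemmi.Model("1")
        for ch_name in sorted(set(self.chain)):
            chain = gemmi.Chain(str(ch_name))
            m = self.chain == ch_name
            order = np.argsort(self.resnum[m], kind="stable")
            idxs = np.flatnonzero(m)[order]
            cur_res = None
            res = None
            for i in idxs:
                rn = int(self.resnum[i])
                if rn != cur_res:
                    res = gemmi.Residue()
                    res.name = "ALA"
                    res.seqid = gemmi.SeqId(rn, " ")
                    chain.add_residue(res)
                    cur_res = rn
                at = gemmi.Atom()
                at.name = str(self.name[i])
                at.element = gemmi.Element(str(self.element[i]))
                at.pos = gemmi.Position(*self.xyz[i])
                at.occ = 1.0
                at.b_iso = 0.0
                chain[-1].add_atom(at)
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))


def read_structure(
    path: str | Path,
    renumber: dict[int, int] | None = None,
    include_hetero: bool = False,
) -> StructureModel:
    """Load heavy atoms from PDB or mmCIF into a :class:`StructureModel`.

    Waters and (by default) hetero groups are excluded; for alternate
    locations the highest-occupancy conformer is kept.  ``renumber`` maps
    deposited author residue numbers onto the prothrombin 1-579 scheme
    (identity when omitted).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    el, nm, rn, ch, xyz, rad = [], [], [], [], [], []
    n_alt_dropped = 0
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            het = res.het_flag == "H"
            if het and not include_hetero:
                continue
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element == gemmi.Element("H"):
                    continue
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    if prev is not None:
                        n_alt_dropped += 1
                    by_name[atom.name] = atom
                elif prev is not None:
                    n_alt_dropped += 1
            for atom in by_name.values():
                num = res.seqid.num
                if renumber is not None:
                    if num not in renumber:
                        continue
                    num = renumber[num]
                el.append(atom.element.name)
                nm.append(atom.name)
                rn.append(num)
                ch.append(chain.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                rad.append(_vdw_radius(atom.element.name))
    if not xyz:
        raise ValueError(f"empty model in {path}")
    if n_alt_dropped:
        logger.info("read_structure: dropped %d alternate-location atoms", n_alt_dropped)
    return StructureModel(
        np.array(el, dtype=object), np.array(nm, dtype=object),
        np.array(rn), np.array(ch, dtype=object),
        np.array(xyz), np.array(rad),
        dict(PROTHROMBIN_DOMAINS),
    )


# --------------------------------------------------------------------------
# distances and surface areas
# --------------------------------------------------------------------------

def ca_distance(structure: StructureModel, res_a: int, res_b: int) -> float:
    """Euclidean Ca-Ca distance (Angstrom) between two residues."""
    ia = structure.find_atom(res_a, "CA")
    ib = structure.find_atom(res_b, "CA")
    return float(np.linalg.norm(structure.xyz[ia] - structure.xyz[ib]))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(
    structure: StructureModel,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley), Angstrom^2."""
    n = len(structure)
    if n == 0:
        return np.zeros(0)
    sphere = _fibonacci_sphere(n_sphere_points)
    xyz = structure.xyz
    rext = structure.radius + probe
    tree = cKDTree(xyz)
    reach = 2.0 * rext.max()
    areas = np.zeros(n)
    for i in range(n):
        pts = xyz[i] + rext[i] * sphere
        nb = tree.query_ball_point(xyz[i], rext[i] + rext.max())
        nb = [j for j in nb if j != i]
        free = np.ones(n_sphere_points, dtype=bool)
        if nb:
            d2 = np.sum((pts[:, None, :] - xyz[nb][None, :, :]) ** 2, axis=2)
            free = ~np.any(d2 < (rext[nb] ** 2)[None, :], axis=1)
        areas[i] = 4.0 * np.pi * rext[i] ** 2 * free.mean()
    return areas


def buried_surface_area(
    structure: StructureModel,
    group_a: tuple[int, int],
    group_b: tuple[int, int],
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> float:
    """Total buried surface area between two residue ranges (Angstrom^2).

    BSA = SASA(A alone) + SASA(B alone) - SASA(A u B); both sides counted
    (divide by two for the per-side convention).
    """
    ma = structure.residue_mask(*group_a)
    mb = structure.residue_mask(*group_b)
    if not ma.any() or not mb.any():
        raise ValueError("empty residue group")
    if np.any(ma & mb):
        raise ValueError("residue groups overlap")
    sa = sasa(structure.subset(ma), probe, n_sphere_points).sum()
    sb = sasa(structure.subset(mb), probe, n_sphere_points).sum()
    sab = sasa(structure.subset(ma | mb), probe, n_sphere_points).sum()
    return float(sa + sb - sab)


# --------------------------------------------------------------------------
# accessible-volume dye clouds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DyeParams:
    """Single-radius (AV1) dye model: linker length L, linker width w,
    dye radius r, lattice spacing (all Angstrom).  Defaults are conventional
    values for AF555/AF647 C2-maleimide dyes."""

    linker_length: float = 20.0
    linker_width: float = 4.5
    dye_radius: float = 3.5
    grid_spacing: float = 0.9

    def __post_init__(self) -> None:
        if min(self.linker_length, self.linker_width,
               self.dye_radius, self.grid_spacing) <= 0:
            raise ValueError("all dye parameters must be positive")
        if self.grid_spacing > self.dye_radius:
            raise ValueError("grid_spacing must not exceed dye_radius")


@dataclass
class AVCloud:
    """Uniformly weighted cloud of sterically allowed dye positions."""

    points: np.ndarray           # (n, 3) Angstrom
    attachment: np.ndarray       # (3,)
    grid_spacing: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.attachment = np.asarray(self.attachment, float).reshape(3)
        if len(self.points) == 0:
            raise ValueError("empty accessible volume")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def to_xyz(self, path: str | Path, label: str = "D") -> None:
        with open(path, "w") as f:
            f.write(f"{len(self.points)}\naccessible volume\n")
            for p in self.points:
                f.write(f"{label} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")

    def to_dx(self, path: str | Path) -> None:
        """Write the cloud as an OpenDX occupancy grid (1 inside, 0 outside)."""
        g = self.grid_spacing
        lo = self.points.min(axis=0)
        idx = np.round((self.points - lo) / g).astype(int)
        shape = idx.max(axis=0) + 1
        occ = np.zeros(shape)
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0
        nx, ny, nz = shape
        with open(path, "w") as f:
            f.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            f.write(f"origin {lo[0]:.4f} {lo[1]:.4f} {lo[2]:.4f}\n")
            f.write(f"delta {g:.4f} 0 0\ndelta 0 {g:.4f} 0\ndelta 0 0 {g:.4f}\n")
            f.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            f.write(f"object 3 class array type double rank 0 items "
                    f"{occ.size} data follows\n")
            flat = occ.ravel()
            for s in range(0, len(flat), 3):
                f.write(" ".join(f"{v:.1f}" for v in flat[s:s + 3]) + "\n")
            f.write('attribute "dep" string "positions"\n'
                    'object "density" class field\n')


def compute_av(
    structure: StructureModel,
    residue: int,
    atom: str = "auto",
    params: DyeParams | None = None,
) -> AVCloud:
    """Accessible volume of a dye attached at ``residue``.

    Attachment at CB when present, else CA (``atom='auto'``); an explicit
    atom name overrides.  Grid points within linker length L of the
    attachment are kept when (a) the dye sphere of radius r does not clash
    with any protein atom (inflated by its vdW radius) and (b) the point is
    reachable from the attachment through linker-width clearance w/2 with
    geodesic path length <= L (Dijkstra flood fill on the lattice).
    """
    if params is None:
        params = DyeParams()
    if atom == "auto":
        try:
            ia = structure.find_atom(residue, "CB")
        except KeyError:
            ia = structure.find_atom(residue, "CA")
    else:
        ia = structure.find_atom(residue, atom)
    a = structure.xyz[ia]
    L, g = params.linker_length, params.grid_spacing

    # local lattice centred on the attachment atom
    n_side = int(np.floor(L / g))
    offs = np.arange(-n_side, n_side + 1) * g
    shape = (len(offs),) * 3
    gx, gy, gz = np.meshgrid(offs, offs, offs, indexing="ij")
    pts = np.column_stack((gx.ravel(), gy.ravel(), gz.ravel())) + a
    within = np.linalg.norm(pts - a, axis=1) <= L + 1e-9

    # clearance to protein vdW surface (attachment atom excluded)
    keep = np.ones(len(structure), dtype=bool)
    keep[ia] = False
    prot_xyz = structure.xyz[keep]
    prot_rad = structure.radius[keep]
    if len(prot_xyz):
        local = (np.linalg.norm(prot_xyz - a, axis=1)
                 <= L + prot_rad.max() + params.dye_radius + g)
        prot_xyz, prot_rad = prot_xyz[local], prot_rad[local]
    if len(prot_xyz):
        clear = np.full(len(pts), np.inf)
        chunk = 200
        for s in range(0, len(prot_xyz), chunk):
            d = np.linalg.norm(pts[:, None, :] - prot_xyz[None, s:s + chunk, :], axis=2)
            clear = np.minimum(clear, (d - prot_rad[None, s:s + chunk]).min(axis=1))
    else:
        clear = np.full(len(pts), np.inf)

    free_path = within & (clear >= params.linker_width / 2.0)
    free_dye = within & (clear >= params.dye_radius)

    # geodesic flood fill on the free-path lattice (26-neighbour Dijkstra)
    nfree = int(free_path.sum())
    if nfree == 0:
        raise ValueError(f"accessible volume empty at residue {residue} (occluded site)")
    comp = -np.ones(len(pts), dtype=np.int64)
    comp[free_path] = np.arange(nfree)
    start_flat = np.ravel_multi_index((n_side, n_side, n_side), shape)
    if not free_path[start_flat]:
        # the attachment cell may sit inside protein clearance; seed from the
        # nearest free-path cell (the linker emerges from the atom), but only
        # within one linker width — farther free space is not connected to
        # the attachment point
        free_idx = np.flatnonzero(free_path)
        d_free = np.linalg.norm(pts[free_idx] - a, axis=1)
        near = d_free <= max(2 * g, params.linker_width)
        if not near.any():
            raise ValueError(
                f"accessible volume empty at residue {residue} (occluded site)")
        free_idx, d_free = free_idx[near], d_free[near]
        start_flat = int(free_idx[np.argmin(d_free)])
    rows, cols, wts = [], [], []
    grid_idx = np.arange(len(pts)).reshape(shape)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) <= (0, 0, 0):
                    continue
                src = grid_idx[max(0, -dx):shape[0] - max(0, dx),
                               max(0, -dy):shape[1] - max(0, dy),
                               max(0, -dz):shape[2] - max(0, dz)].ravel()
                dst = grid_idx[max(0, dx):shape[0] + min(0, dx) or None,
                               max(0, dy):shape[1] + min(0, dy) or None,
                               max(0, dz):shape[2] + min(0, dz) or None].ravel()
                ok = free_path[src] & free_path[dst]
                rows.append(comp[src[ok]])
                cols.append(comp[dst[ok]])
                wts.append(np.full(int(ok.sum()), g * np.sqrt(dx * dx + dy * dy + dz * dz)))
    graph = coo_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nfree, nfree),
    ).tocsr()
    dist = dijkstra(graph, directed=False, indices=int(comp[start_flat]))
    geo = np.full(len(pts), np.inf)
    geo[free_path] = dist
    # include the start's own Euclidean offset from the attachment atom
    geo = geo + np.linalg.norm(pts[start_flat] - a)

    allowed = free_dye & (geo <= L + 1e-9)
    if not allowed.any():
        raise ValueError(f"accessible volume empty at residue {residue} (occluded site)")
    return AVCloud(pts[allowed], a, g)


@dataclass(frozen=True)
class FretPrediction:
    """Dye-averaged theoretical FRET for one donor/acceptor site pair."""

    mean_e: float
    mean_r: float
    r0: float
    n_pairs: int


def mean_fret(
    donor: AVCloud,
    acceptor: AVCloud,
    r0: float = DEFAULT_R0,
    n_samples: int = 200_000,
    seed: int = 0,
) -> FretPrediction:
    """Average FRET efficiency over donor-acceptor position pairs.

    <E> = mean over pairs of 1/(1 + (R/R0)^6) (dynamic averaging).
    Exhaustive when |D| x |A| <= n_samples, else uniform Monte-Carlo pairs.
    """
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    nd, na = len(donor), len(acceptor)
    if nd * na <= n_samples:
        # chunked exhaustive pairwise distances
        rs = []
        for s in range(0, nd, 512):
            d = np.linalg.norm(
                donor.points[s:s + 512, None, :] - acceptor.points[None, :, :], axis=2
            )
            rs.append(d.ravel())
        r = np.concatenate(rs)
        n_pairs = nd * na
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, nd, n_samples)
        j = rng.integers(0, na, n_samples)
        r = np.linalg.norm(donor.points[i] - acceptor.points[j], axis=1)
        n_pairs = n_samples
    e = 1.0 / (1.0 + (r / r0) ** 6)
    return FretPrediction(float(e.mean()), float(r.mean()), float(r0), int(n_pairs))


def predict_pair(
    structure: StructureModel,
    res_donor: int,
    res_acceptor: int,
    r0: float = DEFAULT_R0,
    params: DyeParams | None = None,
    n_samples: int = 200_000,
    seed: int = 0,
) -> FretPrediction:
    """AV clouds at both sites, then dye-averaged FRET."""
    d = compute_av(structure, res_donor, params=params)
    a = compute_av(structure, res_acceptor, params=params)
    return mean_fret(d, a, r0=r0, n_samples=n_samples, seed=seed)
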