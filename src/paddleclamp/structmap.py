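"""Geometric analysis of toxin-channel binding surfaces.

The structural questions here are all rigid-body geometry on atomic
coordinates:

* optimal least-squares superposition (Kabsch) of matched atom sets,
  e.g. the cystine C-alphas of two inhibitor-cystine-knot toxins,
* solvent-accessible surface area (Shrake-Rupley sphere quadrature,
  1.4 A probe) per atom and per residue,
* per-residue Delta-SASA — the area a component buries upon complex
  formation — which maps a binding footprint onto a toxin,
* the connected hydrophobic patch area on a toxin surface,
* register-shifted grafting: placing a toxin against a target helix in
  whole-residue frames, each frame one helical step (default 100 deg
  twist, 1.5 A rise) about the target helix axis,
* steric-clash and interface-residue screens between chains.

Structures are biotite ``AtomArray`` objects; standard PDB files are
read and written through :mod:`biotite.structure.io.pdb`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

__all__ = [
    "VDW_RADII",
    "Transform",
    "SasaReport",
    "DeltaSasaReport",
    "GraftModel",
    "read_structure",
    "write_structure",
    "assign_vdw_radii",
    "kabsch_superpose",
    "fibonacci_sphere",
    "shrake_rupley_sasa",
    "delta_sasa",
    "hydrophobic_patch_area",
    "helix_axis",
    "axis_step_transform",
    "graft_by_register",
    "detect_clashes",
    "interface_residues",
    "GeometryError",
]

#: Element-wise van der Waals radii (Angstrom), Bondi-type values.
#: The probe radius (1.4 A water) is separate and configurable.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "SE": 1.90, "F": 1.47,
    "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70


class GeometryError(ValueError):
    """A geometric precondition failed (degenerate or too-short input)."""


# ---------------------------------------------------------------------------
# I/O and bookkeeping

def read_structure(path, model: int = 1) -> struc.AtomArray:
    """Read one model from a PDB file (first model by default)."""
    pdb = PDBFile.read(str(path))
    return pdb.get_structure(model=model)


def write_structure(atoms: struc.AtomArray, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def assign_vdw_radii(atoms: struc.AtomArray) -> np.ndarray:
    """Per-atom vdW radii from the element table (1.7 A fallback)."""
    return np.array(
        [VDW_RADII.get(str(e).upper(), _DEFAULT_RADIUS) for e in atoms.element]
    )


def _heavy(atoms: struc.AtomArray) -> struc.AtomArray:
    return atoms[atoms.element != "H"]


# ---------------------------------------------------------------------------
# Rigid transforms and superposition

@dataclass
class Transform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def apply_to(self, atoms: struc.AtomArray) -> struc.AtomArray:
        out = atoms.copy()
        out.coord = self.apply(atoms.coord).astype(np.float32)
        return out

    def compose(self, other: "Transform") -> "Transform":
        """Return self o other (other applied first)."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)


def _as_coords(x) -> np.ndarray:
    if isinstance(x, struc.AtomArray):
        x = x.coord
    return np.asarray(x, dtype=float)


def kabsch_superpose(mobile, reference) -> tuple[Transform, float]:
    """Optimal proper-rotation superposition of matched point sets.

    Returns the transform that moves ``mobile`` onto ``reference`` with
    minimal RMSD, and that RMSD. Reflections are never returned: in the
    degenerate case where the best orthogonal map is a reflection, the
    nearest proper rotation is used instead.
    """
    P = _as_coords(mobile)
    Q = _as_coords(reference)
    if P.shape != Q.shape:
        raise ValueError("mobile and reference point counts differ")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    tf = Transform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply(P) - Q) ** 2, axis=1))))
    return tf, rmsd


# ---------------------------------------------------------------------------
# Solvent-accessible surface area

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere quadrature points."""
    k = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(golden * k), r * np.sin(golden * k), z])


@dataclass
class SasaReport:
    """Per-atom and per-residue solvent-accessible surface areas."""

    probe_radius: float
    n_points: int
    per_atom: np.ndarray
    per_residue: pd.DataFrame  # chain_id, res_id, res_name, sasa_A2

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def shrake_rupley_sasa(
    atoms: struc.AtomArray,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: np.ndarray | None = None,
) -> SasaReport:
    """Shrake-Rupley SASA with a deterministic Fibonacci quadrature.

    Each atom's expanded sphere (vdW + probe) is sampled with
    ``n_points`` lattice points; a point is buried if it falls inside
    any neighbour's expanded sphere. An atom exactly coincident with an
    identical earlier atom is treated as fully occluded by it (the
    lower-index atom keeps the area), so duplicated atoms never double
    count.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 92:
        raise ValueError("need at least 92 quadrature points")
    if radii is None:
        radii = assign_vdw_radii(atoms)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("vdW radii must be positive")
    coords = atoms.coord.astype(float)
    n_atoms = coords.shape[0]
    expanded = radii + probe_radius
    sphere = fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    per_atom = np.zeros(n_atoms)
    for i in range(n_atoms):
        ri = expanded[i]
        pts = coords[i] + ri * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], ri + expanded.max())
                 if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(coords[j] - coords[i])
            if d >= ri + expanded[j]:
                continue
            if d < 1e-9 and np.isclose(radii[j], radii[i]):
                # exact duplicate: lower index wins the whole surface
                if j < i:
                    exposed[:] = False
                    break
                continue
            dist2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= dist2 >= expanded[j] ** 2
            if not exposed.any():
                break
        per_atom[i] = 4.0 * np.pi * ri * ri * exposed.sum() / n_points

    df = pd.DataFrame({
        "chain_id": atoms.chain_id,
        "res_id": atoms.res_id,
        "res_name": atoms.res_name,
        "sasa_A2": per_atom,
    })
    per_res = (
        df.groupby(["chain_id", "res_id", "res_name"], sort=True, as_index=False)
        .agg(sasa_A2=("sasa_A2", "sum"))
    )
    return SasaReport(probe_radius=probe_radius, n_points=n_points,
                      per_atom=per_atom, per_residue=per_res)


@dataclass
class DeltaSasaReport:
    """Per-residue area buried by a component upon complex formation."""

    component_chains: tuple
    table: pd.DataFrame  # chain_id, res_id, res_name, sasa_free, sasa_complex, dsasa_A2

    def top_residues(self, n: int = 4) -> pd.DataFrame:
        return self.table.nlargest(n, "dsasa_A2")

    @property
    def total(self) -> float:
        return float(self.table["dsasa_A2"].sum())


def delta_sasa(
    complex_atoms: struc.AtomArray,
    component_chains,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> DeltaSasaReport:
    """Per-residue Delta-SASA = SASA(component alone) - SASA(in complex).

    Both states use the identical probe and quadrature, so residues far
    from the interface cancel to zero exactly.
    """
    chains = tuple(component_chains)
    if not chains:
        raise ValueError("empty component chain selection")
    present = set(np.unique(complex_atoms.chain_id))
    missing = [c for c in chains if c not in present]
    if missing:
        raise ValueError(f"chains not in complex: {missing}")
    mask = np.isin(complex_atoms.chain_id, chains)
    component = complex_atoms[mask]

    free = shrake_rupley_sasa(component, probe_radius, n_points)
    bound_all = shrake_rupley_sasa(complex_atoms, probe_radius, n_points)
    bound = pd.DataFrame({
        "chain_id": complex_atoms.chain_id[mask],
        "res_id": complex_atoms.res_id[mask],
        "res_name": complex_atoms.res_name[mask],
        "sasa_A2": bound_all.per_atom[mask],
    }).groupby(["chain_id", "res_id", "res_name"], sort=True, as_index=False).agg(
        sasa_A2=("sasa_A2", "sum")
    )
    table = free.per_residue.merge(
        bound, on=["chain_id", "res_id", "res_name"],
        suffixes=("_free", "_complex"),
    ).rename(columns={"sasa_A2_free": "sasa_free", "sasa_A2_complex": "sasa_complex"})
    table["dsasa_A2"] = table["sasa_free"] - table["sasa_complex"]
    table = table.sort_values("dsasa_A2", ascending=False, ignore_index=True)
    return DeltaSasaReport(component_chains=chains, table=table)


def hydrophobic_patch_area(
    atoms: struc.AtomArray,
    hydrophobic_res_ids,
    sasa: SasaReport,
    chain_id: str | None = None,
    contact_cutoff: float = 4.5,
) -> float:
    """Surface area (A^2) of the largest connected hydrophobic patch.

    Residues from the given set are clustered by heavy-atom proximity
    (any pair within ``contact_cutoff``); the result is the summed
    per-residue SASA over the largest cluster, which is how a "single
    hydrophobic surface" on a toxin is quantified.
    """
    res_ids = sorted(set(hydrophobic_res_ids))
    if not res_ids:
        raise ValueError("empty hydrophobic residue set")
    sel = atoms if chain_id is None else atoms[atoms.chain_id == chain_id]
    present = set(np.unique(sel.res_id).tolist())
    found = [r for r in res_ids if r in present]
    if not found:
        raise ValueError("hydrophobic residue set disjoint from structure")

    heavy = _heavy(sel)
    coords_by_res = {r: heavy.coord[heavy.res_id == r].astype(float) for r in found}
    # single-linkage clustering on residue heavy-atom min distances
    parent = {r: r for r in found}

    def find(r):
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    for a_i, ra in enumerate(found):
        ta = cKDTree(coords_by_res[ra])
        for rb in found[a_i + 1:]:
            d = ta.query(coords_by_res[rb], k=1)[0].min()
            if d <= contact_cutoff:
                parent[find(ra)] = find(rb)
    clusters: dict[str, list[int]] = {}
    for r in found:
        clusters.setdefault(find(r), []).append(r)
    largest = max(clusters.values(), key=len)

    per_res = sasa.per_residue
    if chain_id is not None:
        per_res = per_res[per_res["chain_id"] == chain_id]
    return float(per_res[per_res["res_id"].isin(largest)]["sasa_A2"].sum())


# ---------------------------------------------------------------------------
# Helix axis and register grafting

def helix_axis(ca_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axis of a helical C-alpha trace as (point, unit direction).

    The direction is the common normal of the second differences of the
    trace (for a helix these lie in planes perpendicular to the axis);
    the point is an algebraic circle-fit centre of the trace projected
    onto that plane. Exact for ideal helices, stable for real ones.
    The direction points from the N- toward the C-terminal end.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.shape[0] < 4:
        raise GeometryError("helix too short to estimate an axis (<4 residues)")
    d2 = ca[2:] - 2.0 * ca[1:-1] + ca[:-2]
    _, _, vt = np.linalg.svd(d2)
    direction = vt[-1]
    if direction @ (ca[-1] - ca[0]) < 0:
        direction = -direction
    # orthonormal basis of the perpendicular plane
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    xy = np.column_stack([ca @ u, ca @ v])
    # Kasa algebraic circle fit: exact for points on a circle
    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = np.sum(xy * xy, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre_2d = sol[:2]
    point = centre_2d[0] * u + centre_2d[1] * v
    # place the axis point at the height of the trace centroid
    point = point + (ca.mean(axis=0) @ direction) * direction
    return point, direction


def axis_step_transform(
    point: np.ndarray,
    direction: np.ndarray,
    twist_deg: float,
    rise_A: float,
) -> Transform:
    """Screw transform: rotate by twist about the axis, translate rise along it."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ang = np.deg2rad(twist_deg)
    K = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    p = np.asarray(point, dtype=float)
    t = p - R @ p + rise_A * d
    return Transform(R, t)


@dataclass
class GraftModel:
    """A register-offset placement of a toxin against a target helix."""

    offset: int
    transform: Transform
    toxin: struc.AtomArray
    model: struc.AtomArray
    clash_count: int
    clash_pairs: list = field(default_factory=list)
    interface: dict = field(default_factory=dict)


def _helix_window_ca(atoms: struc.AtomArray, chain: str, start: int, stop: int) -> np.ndarray:
    mask = (
        (atoms.chain_id == chain)
        & (atoms.res_id >= start)
        & (atoms.res_id <= stop)
        & (atoms.atom_name == "CA")
    )
    ca = atoms.coord[mask].astype(float)
    order = np.argsort(atoms.res_id[mask])
    return ca[order]


def graft_by_register(
    toxin: struc.AtomArray,
    template: struc.AtomArray,
    template_range: tuple[str, int, int],
    target: struc.AtomArray,
    target_range: tuple[str, int, int],
    offset: int = 0,
    twist_deg_per_res: float = 100.0,
    rise_A_per_res: float = 1.5,
    clash_cutoff: float = 2.5,
    interface_threshold: float = 12.0,
    frame_offsets: tuple = (-2, -1, 0, 1, 2),
) -> GraftModel:
    """Place a toxin against a target helix in a whole-residue register.

    The base placement superposes the template-helix C-alphas (the helix
    the toxin is known to bind, e.g. residues of an acid-sensing-channel
    thumb helix) onto the target-helix C-alphas (e.g. an S3b voltage-
    sensor segment). A nonzero ``offset`` then advances the toxin by
    that many elementary helical steps about the target helix axis —
    ``twist_deg_per_res`` rotation plus ``rise_A_per_res`` translation
    per residue — producing the family of register frames.

    The returned model concatenates the target structure with the
    grafted toxin and carries the clash count and interface residues.
    """
    if offset not in frame_offsets:
        raise ValueError(f"offset {offset} outside configured frames {frame_offsets}")
    t_chain, t_start, t_stop = template_range
    g_chain, g_start, g_stop = target_range
    tpl_ca = _helix_window_ca(template, t_chain, t_start, t_stop)
    tgt_ca = _helix_window_ca(target, g_chain, g_start, g_stop)
    if tpl_ca.shape[0] != tgt_ca.shape[0]:
        raise ValueError("template and target helix windows differ in length")
    if tgt_ca.shape[0] < 4:
        raise GeometryError("helix too short to estimate an axis (<4 residues)")

    base, _ = kabsch_superpose(tpl_ca, tgt_ca)
    tf = base
    if offset != 0:
        point, direction = helix_axis(tgt_ca)
        step = axis_step_transform(
            point, direction, offset * twist_deg_per_res, offset * rise_A_per_res
        )
        tf = step.compose(base)

    placed = tf.apply_to(toxin)
    model = target + placed
    toxin_chains = set(np.unique(placed.chain_id))
    target_chains = set(np.unique(target.chain_id))
    n_clash = 0
    pairs: list = []
    for tc in sorted(toxin_chains):
        for gc in sorted(target_chains):
            c, p = detect_clashes(model, tc, gc, clash_cutoff)
            n_clash += c
            pairs.extend(p)
    iface: dict = {}
    for tc in sorted(toxin_chains):
        for gc in sorted(target_chains):
            res = interface_residues(model, tc, gc, interface_threshold)
            for ch, ids in res.items():
                iface.setdefault(ch, set()).update(ids)
    iface = {ch: sorted(ids) for ch, ids in iface.items()}
    return GraftModel(offset=offset, transform=tf, toxin=placed, model=model,
                      clash_count=n_clash, clash_pairs=pairs, interface=iface)


# ---------------------------------------------------------------------------
# Contacts

def detect_clashes(
    atoms: struc.AtomArray,
    chain_a: str,
    chain_b: str,
    clash_cutoff: float = 2.5,
) -> tuple[int, list[tuple[int, int, float]]]:
    """Inter-chain heavy-atom pairs closer than the cutoff.

    Returns the count and a deterministically ordered list of
    (atom index in chain_a, atom index in chain_b, distance) tuples,
    indices referring to positions within ``atoms``.
    """
    for c in (chain_a, chain_b):
        if c not in set(np.unique(atoms.chain_id)):
            raise ValueError(f"chain {c!r} not present")
    heavy = atoms.element != "H"
    ia = np.where((atoms.chain_id == chain_a) & heavy)[0]
    ib = np.where((atoms.chain_id == chain_b) & heavy)[0]
    if ia.size == 0 or ib.size == 0:
        return 0, []
    ta = cKDTree(atoms.coord[ia].astype(float))
    tb = cKDTree(atoms.coord[ib].astype(float))
    pairs = []
    for la, lbs in enumerate(ta.query_ball_tree(tb, clash_cutoff)):
        for lb in lbs:
            d = float(np.linalg.norm(
                atoms.coord[ia[la]].astype(float) - atoms.coord[ib[lb]].astype(float)
            ))
            if d < clash_cutoff:
                pairs.append((int(ia[la]), int(ib[lb]), d))
    pairs.sort(key=lambda p: (p[0], p[1]))
    return len(pairs), pairs


def interface_residues(
    atoms: struc.AtomArray,
    chain_a: str,
    chain_b: str,
    distance_threshold: float = 12.0,
) -> dict[str, list[int]]:
    """Residues of each chain with any heavy atom within the threshold
    of the partner chain (12 A default, the masking distance used for
    interface display)."""
    if distance_threshold <= 0:
        raise ValueError("threshold must be positive")
    heavy = atoms.element != "H"
    out: dict[str, list[int]] = {}
    for ca, cb in ((chain_a, chain_b), (chain_b, chain_a)):
        ia = np.where((atoms.chain_id == ca) & heavy)[0]
        ib = np.where((atoms.chain_id == cb) & heavy)[0]
        if ia.size == 0 or ib.size == 0:
            out[ca] = []
            continue
        tb = cKDTree(atoms.coord[ib].astype(float))
        d, _ = tb.query(atoms.coord[ia].astype(float), k=1)
        res = np.unique(atoms.res_id[ia[d <= distance_threshold]])
        out[ca] = [int(r) for r in res]
    return out
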