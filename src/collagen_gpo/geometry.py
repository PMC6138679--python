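"""Triple-helix coordinates, dihedrals, ring pucker and perturbation.

Each collagen chain adopts a polyproline-II-like conformation near
(φ, ψ) = (−75°, 150°).  The five-membered proline ring superimposes two
discrete pucker states on this backbone: *endo*, with Cγ on the same side
as the residue's carbonyl group, and *exo*, with Cγ pointing away.  This
module reads and writes triple-helix models in PDB format, computes
backbone dihedrals and signed Cγ-displacement pucker states, samples
conformers by rigid-group rotations about covalent axes, filters them to
the collagen φ/ψ window, deduplicates them by greedy leader clustering in
(φ, ψ, pucker) space, and measures backbone extension/compression as an
end-to-end span.

All angles are degrees wrapped to (−180°, 180°]; all coordinates are Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
import biotite.structure.io.pdb as pdbio

from collagen_gpo.errors import ParameterError, StructureError

# backbone geometry (Engh-Huber-style ideal values, Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA_TRANS = 180.0

#: canonical polyproline-II dihedrals of the collagen chain
PPII_PHI = -75.0
PPII_PSI = 150.0

#: |signed Cγ displacement| below which a ring is called planar (Å)
DELTA_MIN = 0.1

#: default out-of-plane Cγ displacement used when building rings (Å)
RING_DISPLACEMENT = 0.45

BACKBONE_ATOMS = ("N", "CA", "C")
RING_ATOMS = ("CB", "CG", "CD")

THREE_TO_ONE = {"GLY": "G", "PRO": "P", "HYP": "O", "ALA": "A"}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


# ---------------------------------------------------------------------------
# model containers


@dataclass
class Residue:
    """One residue: name (GLY/PRO/HYP/ALA/...), 1-based id and its atoms."""

    res_id: int
    name: str
    atoms: dict[str, np.ndarray]

    def copy(self) -> "Residue":
        return Residue(self.res_id, self.name, {k: v.copy() for k, v in self.atoms.items()})

    @property
    def is_imino(self) -> bool:
        return self.name in ("PRO", "HYP")


@dataclass
class TripleHelixModel:
    """Three chains of residues with atomic coordinates.

    ``chains`` maps chain id (e.g. ``"A"``, ``"B"``, ``"C"``) to its
    ordered residue list.  Hydroxyproline is recognised either by the
    residue name ``HYP`` or by a proline carrying an ``OD1`` atom.
    """

    chains: dict[str, list[Residue]]

    def copy(self) -> "TripleHelixModel":
        return TripleHelixModel(
            {cid: [r.copy() for r in residues] for cid, residues in self.chains.items()}
        )

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def residue(self, chain_id: str, res_id: int) -> Residue:
        chain = self.chains[chain_id]
        idx = res_id - chain[0].res_id
        if not 0 <= idx < len(chain) or chain[idx].res_id != res_id:
            for r in chain:  # fall back to scan for non-contiguous ids
                if r.res_id == res_id:
                    return r
            raise StructureError(f"residue {chain_id}:{res_id} not in model")
        return chain[idx]

    def atom(self, chain_id: str, res_id: int, name: str) -> np.ndarray:
        res = self.residue(chain_id, res_id)
        try:
            return res.atoms[name]
        except KeyError:
            raise StructureError(
                f"atom {name} missing from residue {chain_id}:{res_id} ({res.name})"
            ) from None

    def iter_atoms(self) -> Iterable[tuple[tuple[str, int, str], np.ndarray]]:
        for cid, residues in self.chains.items():
            for res in residues:
                for name, coord in res.atoms.items():
                    yield (cid, res.res_id, name), coord

    def prolines(self) -> list[tuple[str, int]]:
        """(chain_id, res_id) of every PRO or HYP residue."""
        return [
            (cid, r.res_id)
            for cid, residues in self.chains.items()
            for r in residues
            if r.is_imino
        ]


def validate_model(model: TripleHelixModel, *, require_three_chains: bool = True) -> None:
    """Check chain count, backbone/ring completeness and covalent
    geometry (bonded distances within 0.8–2.0 Å)."""
    if require_three_chains and len(model.chains) != 3:
        raise StructureError(
            f"triple helix must have 3 chains, found {len(model.chains)}"
        )
    for cid, residues in model.chains.items():
        if not residues:
            raise StructureError(f"chain {cid} is empty")
        for res in residues:
            for name in BACKBONE_ATOMS:
                if name not in res.atoms:
                    raise StructureError(
                        f"backbone atom {name} missing from {cid}:{res.res_id} ({res.name})"
                    )
            if res.is_imino:
                for name in RING_ATOMS:
                    if name not in res.atoms:
                        raise StructureError(
                            f"ring atom {name} missing from {cid}:{res.res_id} ({res.name})"
                        )
        for prev, nxt in zip(residues, residues[1:]):
            _check_bond(prev.atoms["C"], nxt.atoms["N"], f"{cid}:{prev.res_id} C–N")
        for res in residues:
            _check_bond(res.atoms["N"], res.atoms["CA"], f"{cid}:{res.res_id} N–CA")
            _check_bond(res.atoms["CA"], res.atoms["C"], f"{cid}:{res.res_id} CA–C")
            if res.is_imino:
                for a, b in (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")):
                    _check_bond(res.atoms[a], res.atoms[b], f"{cid}:{res.res_id} {a}–{b}")


def _check_bond(a: np.ndarray, b: np.ndarray, label: str) -> None:
    d = float(np.linalg.norm(a - b))
    if not 0.8 <= d <= 2.0:
        raise StructureError(f"bond {label} has unphysical length {d:.2f} Å")


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)


def read_structure(path: str | Path, *, validate: bool = True) -> TripleHelixModel:
    """Read a PDB file into a :class:`TripleHelixModel`.

    Hydroxyproline is recognised by residue name ``HYP`` or by a ``PRO``
    carrying an ``OD1`` atom (renamed to ``HYP`` on input).
    """
    pdb_file = pdbio.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1)
    atoms = atoms[atoms.element != "H"]
    chains: dict[str, list[Residue]] = {}
    for cid in np.unique(atoms.chain_id):
        sub = atoms[atoms.chain_id == cid]
        residues: list[Residue] = []
        for res_id in np.unique(sub.res_id):
            rsub = sub[sub.res_id == res_id]
            name = str(rsub.res_name[0])
            coords = {
                str(an): rsub.coord[i].astype(float)
                for i, an in enumerate(rsub.atom_name)
            }
            if name == "PRO" and "OD1" in coords:
                name = "HYP"
            residues.append(Residue(int(res_id), name, coords))
        chains[str(cid)] = residues
    model = TripleHelixModel(chains)
    if validate:
        validate_model(model)
    return model


def write_structure(model: TripleHelixModel, path: str | Path) -> None:
    """Write the model as PDB ATOM/HETATM records (3-decimal coordinates)."""
    n_atoms = sum(1 for _ in model.iter_atoms())
    arr = struc.AtomArray(n_atoms)
    i = 0
    for cid, residues in model.chains.items():
        for res in residues:
            for name, coord in res.atoms.items():
                arr.chain_id[i] = cid
                arr.res_id[i] = res.res_id
                arr.res_name[i] = res.name
                arr.atom_name[i] = name
                arr.hetero[i] = res.name == "HYP"
                arr.element[i] = name[0] if name[0] in ("N", "C", "O") else "C"
                arr.coord[i] = coord
                i += 1
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# dihedrals


def wrap_angle(angle: float) -> float:
    """Wrap degrees into (−180°, 180°]."""
    wrapped = ((angle + 180.0) % 360.0) - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention,
    in (−180°, 180°]."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n2 = np.linalg.norm(b2)
    if n2 < 1e-9:
        raise ParameterError("degenerate dihedral: central atoms coincide")
    c12 = np.cross(b1, b2)
    c23 = np.cross(b2, b3)
    if np.linalg.norm(c12) < 1e-9 or np.linalg.norm(c23) < 1e-9:
        raise ParameterError("degenerate dihedral: collinear atoms")
    x = float(np.dot(c12, c23))
    y = float(np.dot(np.cross(c12, c23), b2) / n2)
    return wrap_angle(float(np.degrees(np.arctan2(y, x))))


@dataclass(frozen=True)
class ResidueConformation:
    """Backbone dihedrals of one residue; terminal residues leave the
    missing angle as ``None``."""

    chain_id: str
    res_id: int
    phi: float | None
    psi: float | None


def phi_psi(model: TripleHelixModel, chain_id: str, res_id: int) -> ResidueConformation:
    """φ = C(i−1)-N-CA-C and ψ = N-CA-C-N(i+1) of one residue."""
    chain = model.chains[chain_id]
    ids = [r.res_id for r in chain]
    res = model.residue(chain_id, res_id)
    phi = psi = None
    if res_id - 1 in ids:
        prev = model.residue(chain_id, res_id - 1)
        phi = dihedral(prev.atoms["C"], res.atoms["N"], res.atoms["CA"], res.atoms["C"])
    if res_id + 1 in ids:
        nxt = model.residue(chain_id, res_id + 1)
        psi = dihedral(res.atoms["N"], res.atoms["CA"], res.atoms["C"], nxt.atoms["N"])
    return ResidueConformation(chain_id, res_id, phi, psi)


# ---------------------------------------------------------------------------
# ring pucker


@dataclass(frozen=True)
class RingPucker:
    """Proline ring pucker state from the signed Cγ displacement
    relative to the N–CA–CD plane; positive displacement = same side as
    the residue's carbonyl carbon (endo)."""

    state: str  # endo | exo | planar
    cg_displacement: float
    chain_id: str = ""
    res_id: int = 0


def ring_pucker(
    model: TripleHelixModel,
    chain_id: str,
    res_id: int,
    *,
    delta_min: float = DELTA_MIN,
) -> RingPucker:
    """Classify a proline/hydroxyproline ring as endo, exo or planar.

    A plane is fitted through N, CA and CD; the Cγ displacement along its
    normal is signed positive toward the residue's carbonyl carbon.
    endo ⇔ displacement > +δ_min; exo ⇔ displacement < −δ_min.
    """
    res = model.residue(chain_id, res_id)
    if not res.is_imino:
        raise StructureError(f"residue {chain_id}:{res_id} ({res.name}) has no ring")
    n, ca, cd = res.atoms["N"], res.atoms["CA"], res.atoms["CD"]
    cg, c = res.atoms["CG"], res.atoms["C"]
    normal = np.cross(ca - n, cd - n)
    norm = np.linalg.norm(normal)
    if norm < 1e-9:
        raise StructureError(f"degenerate N-CA-CD plane at {chain_id}:{res_id}")
    normal = normal / norm
    centroid = (n + ca + cd) / 3.0
    if float(np.dot(c - centroid, normal)) < 0:
        normal = -normal
    disp = float(np.dot(cg - centroid, normal))
    if disp > delta_min:
        state = "endo"
    elif disp < -delta_min:
        state = "exo"
    else:
        state = "planar"
    return RingPucker(state, disp, chain_id, res_id)


# ---------------------------------------------------------------------------
# chain building (internal coordinates / NeRF)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom d given bond length c–d, angle b-c-d and torsion
    a-b-c-d (natural extension of reference frame)."""
    angle_r = np.radians(angle)
    torsion_r = np.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle_r),
            bond * np.sin(angle_r) * np.cos(torsion_r),
            bond * np.sin(angle_r) * np.sin(torsion_r),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@lru_cache(maxsize=1)
def _proline_ring_internal() -> dict[str, tuple[float, float, float]]:
    """Ideal CB/CD internal coordinates extracted from the CCD proline
    template: (bond, angle, torsion) for the NeRF placements
    CB ← (C, N, CA) and CD ← (C, CA, N)."""
    tmpl = struc_info.residue("PRO")

    def coord(name: str) -> np.ndarray:
        return tmpl.coord[tmpl.atom_name == name][0].astype(float)

    n, ca, c, cb, cg, cd = (coord(x) for x in ("N", "CA", "C", "CB", "CG", "CD"))
    return {
        "CB": (
            float(np.linalg.norm(cb - ca)),
            _angle(n, ca, cb),
            dihedral(c, n, ca, cb),
        ),
        "CD": (
            float(np.linalg.norm(cd - n)),
            _angle(ca, n, cd),
            dihedral(c, ca, n, cd),
        ),
        "CG": (
            float(np.linalg.norm(cg - cb)),
            _angle(ca, cb, cg),
            dihedral(n, ca, cb, cg),
        ),
    }


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosv = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def _rotate_to_plane_displacement(
    point: np.ndarray,
    anchor: np.ndarray,
    axis: np.ndarray,
    normal: np.ndarray,
    plane_centroid: np.ndarray,
    target: float,
) -> np.ndarray:
    """Rotate ``point`` about the axis through ``anchor`` until its signed
    displacement from the plane equals ``target``.

    Bond lengths and angles to atoms on the axis are preserved exactly
    (the rotation is an isometry).  The displacement along the rotation
    is d(θ) = c0 + a·cosθ + b·sinθ (Rodrigues expansion), solved in
    closed form; of the two solutions the one nearest θ = 0 is taken, so
    the geometry stays closest to the ideal template.
    """
    k = axis / np.linalg.norm(axis)
    v = point - anchor
    a = float(np.dot(normal, v - k * np.dot(k, v)))
    b = float(np.dot(normal, np.cross(k, v)))
    c0 = float(np.dot(normal, anchor - plane_centroid) + np.dot(normal, k) * np.dot(k, v))
    amp = float(np.hypot(a, b))
    if abs(target - c0) > amp:
        raise ParameterError(
            f"ring displacement {target:.2f} Å unreachable "
            f"(range [{c0 - amp:.2f}, {c0 + amp:.2f}])"
        )
    base = float(np.arctan2(b, a))
    alpha = float(np.arccos(np.clip((target - c0) / amp, -1.0, 1.0)))
    # d(base + t) = c0 + amp*cos(t): solutions t = ±alpha
    theta = min(
        (((t + np.pi) % (2 * np.pi)) - np.pi for t in (base + alpha, base - alpha)),
        key=abs,
    )
    return anchor + (
        v * np.cos(theta)
        + np.cross(k, v) * np.sin(theta)
        + k * np.dot(k, v) * (1 - np.cos(theta))
    )


def attach_ring(
    res: Residue,
    *,
    pucker: str,
    displacement: float = RING_DISPLACEMENT,
    hydroxylate: bool = False,
) -> None:
    """Build CB, CG, CD (and OD1 when ``hydroxylate``) onto a residue's
    backbone with the designed pucker.

    CB, CD and an initial CG take ideal template geometry; CG is then
    rotated about the Cβ–Cδ axis (which preserves both ring bond
    lengths) until its signed displacement from the N–CA–CD plane equals
    ``displacement`` toward the carbonyl carbon for *endo* and away from
    it for *exo*.
    """
    if pucker not in ("endo", "exo", "planar"):
        raise ParameterError(f"unknown pucker label {pucker!r}")
    n, ca, c = res.atoms["N"], res.atoms["CA"], res.atoms["C"]
    internal = _proline_ring_internal()
    bond, angle, torsion = internal["CB"]
    cb = place_atom(c, n, ca, bond, angle, torsion)
    bond, angle, torsion = internal["CD"]
    cd = place_atom(c, ca, n, bond, angle, torsion)
    bond, angle, torsion = internal["CG"]
    cg0 = place_atom(n, ca, cb, bond, angle, torsion)

    normal = np.cross(ca - n, cd - n)
    normal = normal / np.linalg.norm(normal)
    centroid = (n + ca + cd) / 3.0
    if float(np.dot(c - centroid, normal)) < 0:
        normal = -normal
    z = {"endo": displacement, "exo": -displacement, "planar": 0.0}[pucker]

    # a real pucker flip moves both ring carbons: put CB slightly on the
    # opposite side of the plane, then solve CG for the full displacement
    cb = _rotate_to_plane_displacement(cb, ca, n - ca, normal, centroid, -z / 3.0)
    cg = _rotate_to_plane_displacement(cg0, cb, cd - cb, normal, centroid, z)

    res.atoms["CB"] = cb
    res.atoms["CG"] = cg
    res.atoms["CD"] = cd
    if hydroxylate:
        od_dir = cg - (n + ca + cb + cd) / 4.0
        od_dir = od_dir / np.linalg.norm(od_dir)
        res.atoms["OD1"] = cg + 1.42 * od_dir
        res.name = "HYP"


def build_chain(
    sequence: Sequence[str],
    *,
    phi: float = PPII_PHI,
    psi: float = PPII_PSI,
    omega: float = OMEGA_TRANS,
    puckers: Mapping[int, str] | None = None,
    ring_displacement: float = RING_DISPLACEMENT,
) -> list[Residue]:
    """Build one chain at fixed (φ, ψ, ω) from one-letter residues
    (G/P/O/A...).  ``puckers`` maps 1-based residue ids of imino residues
    to designed pucker states (default endo)."""
    puckers = dict(puckers or {})
    residues: list[Residue] = []
    # seed frame for residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    c0 = place_atom(
        np.array([-1.0, 1.0, 0.0]), n0, ca0, BOND_CA_C, ANGLE_N_CA_C, 0.0
    )
    prev = {"N": n0, "CA": ca0, "C": c0}
    for i, letter in enumerate(sequence, start=1):
        name = ONE_TO_THREE.get(letter.upper())
        if name is None:
            raise ParameterError(f"unsupported residue letter {letter!r}")
        if i == 1:
            atoms = dict(prev)
        else:
            p = residues[-1].atoms
            n = place_atom(p["N"], p["CA"], p["C"], BOND_C_N, ANGLE_CA_C_N, psi)
            ca = place_atom(p["CA"], p["C"], n, BOND_N_CA, ANGLE_C_N_CA, omega)
            c = place_atom(p["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
            atoms = {"N": n, "CA": ca, "C": c}
        residues.append(Residue(i, name, atoms))
    # carbonyl oxygens, anti to the following amide nitrogen (torsion ψ+180)
    for res in residues:
        res.atoms["O"] = place_atom(
            res.atoms["N"], res.atoms["CA"], res.atoms["C"], BOND_C_O,
            ANGLE_CA_C_O, wrap_angle(psi + 180.0),
        )
    for res in residues:
        if res.name in ("PRO", "HYP"):
            attach_ring(
                res,
                pucker=puckers.get(res.res_id, "endo"),
                displacement=ring_displacement,
                hydroxylate=res.name == "HYP",
            )
        elif res.name == "ALA":
            internal = _proline_ring_internal()
            bond, angle, torsion = internal["CB"]
            res.atoms["CB"] = place_atom(
                res.atoms["C"], res.atoms["N"], res.atoms["CA"], bond, angle, torsion
            )
    return residues


def backbone_span(arg, chain_id: str | None = None, **kwargs) -> float:
    """End-to-end backbone length in Å.

    Called with a :class:`TripleHelixModel` (plus ``chain_id``) it
    measures the distance from the first N to the last C of that chain;
    called with an integer residue count plus ``phi=…, psi=…`` it builds
    an ideal glycine chain at those dihedrals and measures it.
    """
    if isinstance(arg, TripleHelixModel):
        cid = chain_id or arg.chain_ids[0]
        chain = arg.chains[cid]
        return float(np.linalg.norm(chain[-1].atoms["C"] - chain[0].atoms["N"]))
    n_residues = int(arg)
    if n_residues < 1:
        raise ParameterError("need at least one residue")
    residues = build_chain(["G"] * n_residues, **kwargs)
    return float(np.linalg.norm(residues[-1].atoms["C"] - residues[0].atoms["N"]))


# ---------------------------------------------------------------------------
# rigid-group perturbation


AtomKey = tuple[str, int, str]  # (chain_id, res_id, atom_name)


@dataclass(frozen=True)
class PerturbationSpec:
    """Rigid-rotation sampling specification.

    Each group is a pair of atoms joined by a covalent path; one sampled
    conformer rotates the atoms strictly between each pair (plus their
    side branches) about the pair axis by an independent angle drawn
    uniformly from (−max_amplitude, +max_amplitude).
    """

    groups: tuple[tuple[AtomKey, AtomKey], ...]
    max_amplitude: float
    n_perturbations: int
    seed: int

    def __post_init__(self) -> None:
        if self.max_amplitude < 0:
            raise ParameterError("max_amplitude must be >= 0")
        if self.n_perturbations < 1:
            raise ParameterError("n_perturbations must be >= 1")


def bond_graph(model: TripleHelixModel, cutoff: float = 1.9) -> nx.Graph:
    """Covalent bond graph inferred from heavy-atom distances."""
    keys: list[AtomKey] = []
    coords: list[np.ndarray] = []
    for key, coord in model.iter_atoms():
        keys.append(key)
        coords.append(coord)
    xyz = np.array(coords)
    g = nx.Graph()
    g.add_nodes_from(keys)
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=-1)
    cut2 = cutoff**2
    ii, jj = np.nonzero((d2 < cut2) & (d2 > 1e-6))
    for i, j in zip(ii, jj):
        if i < j:
            g.add_edge(keys[i], keys[j])
    return g


def rotating_atoms(
    graph: nx.Graph, a: AtomKey, b: AtomKey
) -> set[AtomKey]:
    """Atoms strictly between ``a`` and ``b`` on the covalent path,
    together with any side branches hanging off that path (reached
    without passing through ``a`` or ``b``)."""
    if a not in graph or b not in graph:
        raise ParameterError(f"axis atom not in model: {a if a not in graph else b}")
    try:
        path = nx.shortest_path(graph, a, b)
    except nx.NetworkXNoPath:
        raise ParameterError(f"axis atoms {a} and {b} are not path-connected") from None
    interior = set(path[1:-1])
    if not interior:
        return set()
    pruned = graph.copy()
    pruned.remove_nodes_from([a, b])
    out: set[AtomKey] = set()
    for comp in nx.connected_components(pruned):
        if comp & interior:
            out |= comp
    return out


def _rotation_matrix(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.radians(theta_deg)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


@dataclass
class Conformer:
    """One perturbed conformer and the rotation angles that produced it."""

    model: TripleHelixModel
    angles: tuple[float, ...]
    index: int


def perturb(model: TripleHelixModel, spec: PerturbationSpec) -> list[Conformer]:
    """Sample ``spec.n_perturbations`` conformers by rigid rotations.

    Rotations are isometries of each rigid group, so all intra-group
    distances are preserved exactly; atoms outside every group are
    untouched.  The generator is seeded by ``spec.seed``.
    """
    graph = bond_graph(model)
    groups = [
        (a, b, rotating_atoms(graph, a, b)) for a, b in spec.groups
    ]
    rng = np.random.default_rng(spec.seed)
    conformers: list[Conformer] = []
    for k in range(spec.n_perturbations):
        conf = model.copy()
        thetas = []
        for a, b, atoms in groups:
            theta = float(rng.uniform(-spec.max_amplitude, spec.max_amplitude))
            thetas.append(theta)
            if not atoms or theta == 0.0:
                continue
            origin = conf.atom(*a)
            axis = conf.atom(*b) - origin
            rot = _rotation_matrix(axis, theta)
            for cid, rid, name in atoms:
                coord = conf.atom(cid, rid, name)
                conf.residue(cid, rid).atoms[name] = origin + rot @ (coord - origin)
        conformers.append(Conformer(conf, tuple(thetas), k))
    return conformers


# ---------------------------------------------------------------------------
# PPII window filtering and clustering


@dataclass(frozen=True)
class FilterWindow:
    """Closed φ/ψ acceptance window of the collagen chain
    (defaults: φ ∈ [−90°, −50°], ψ ∈ [130°, 170°])."""

    phi_min: float = -90.0
    phi_max: float = -50.0
    psi_min: float = 130.0
    psi_max: float = 170.0

    def __post_init__(self) -> None:
        if self.phi_min >= self.phi_max or self.psi_min >= self.psi_max:
            raise ParameterError("window bounds must satisfy min < max")

    def contains(self, phi: float | None, psi: float | None) -> bool:
        if phi is None or psi is None:
            return False
        return (
            self.phi_min <= phi <= self.phi_max
            and self.psi_min <= psi <= self.psi_max
        )


def ppii_filter(
    conformers: Sequence[Conformer],
    residues: Sequence[tuple[str, int]],
    window: FilterWindow = FilterWindow(),
) -> list[Conformer]:
    """Accept conformers whose every perturbed residue lies inside the
    closed φ/ψ window."""
    accepted = []
    for conf in conformers:
        ok = True
        for cid, rid in residues:
            rc = phi_psi(conf.model, cid, rid)
            if not window.contains(rc.phi, rc.psi):
                ok = False
                break
        if ok:
            accepted.append(conf)
    return accepted


@dataclass(frozen=True)
class ConformerCluster:
    """A unique conformation: leader (φ, ψ) per tracked residue, the
    pucker-state combination, and the member conformer indices."""

    angles: tuple[tuple[float, float], ...]
    puckers: tuple[str, ...]
    members: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.members)


def _circ_diff(a: float, b: float) -> float:
    return abs(((a - b + 180.0) % 360.0) - 180.0)


def conformer_features(
    conf: Conformer, residues: Sequence[tuple[str, int]]
) -> tuple[tuple[tuple[float, float], ...], tuple[str, ...]]:
    angles = []
    puckers = []
    for cid, rid in residues:
        rc = phi_psi(conf.model, cid, rid)
        angles.append((rc.phi if rc.phi is not None else 0.0,
                       rc.psi if rc.psi is not None else 0.0))
        res = conf.model.residue(cid, rid)
        if res.is_imino:
            puckers.append(ring_pucker(conf.model, cid, rid).state)
    return tuple(angles), tuple(puckers)


def cluster_conformers(
    conformers: Sequence[Conformer],
    residues: Sequence[tuple[str, int]],
    *,
    tol: float = 5.0,
) -> list[ConformerCluster]:
    """Greedy leader clustering in (φ, ψ, pucker) space.

    Two conformers share a cluster iff they have the same pucker-state
    combination over the tracked imino residues and every φ/ψ circular
    difference from the cluster leader is ≤ ``tol`` degrees.  Clusters
    are reported in order of first appearance, partitioned by pucker
    combination by construction.
    """
    if not conformers:
        raise ParameterError("no conformers to cluster")
    leaders: list[tuple[tuple[tuple[float, float], ...], tuple[str, ...], list[int]]] = []
    for conf in conformers:
        angles, puckers = conformer_features(conf, residues)
        placed = False
        for l_angles, l_puckers, members in leaders:
            if l_puckers != puckers:
                continue
            if all(
                _circ_diff(a[0], la[0]) <= tol and _circ_diff(a[1], la[1]) <= tol
                for a, la in zip(angles, l_angles)
            ):
                members.append(conf.index)
                placed = True
                break
        if not placed:
            leaders.append((angles, puckers, [conf.index]))
    return [
        ConformerCluster(angles, puckers, tuple(members))
        for angles, puckers, members in leaders
    ]


def standard_rotation_groups(
    model: TripleHelixModel, chain_id: str, res_id: int
) -> tuple[tuple[AtomKey, AtomKey], ...]:
    """The rotation-group set used to sample one perturbed X-position
    imino residue and its Y neighbour.

    Groups: the Cβ–Cδ proline ring tip of the X residue; the Cα–Cα axis
    of the X–Y peptide bond; the Y residue's own axis (Cβ–Cδ ring tip if
    Y is imino, else its N–C axis); and the Cα–Cα axis of the peptide
    bond trailing Y.  Together these sample φ/ψ of X and Y, the flanking
    glycine dihedrals, and the ring pucker states.
    """
    res = model.residue(chain_id, res_id)
    if not res.is_imino:
        raise ParameterError(f"{chain_id}:{res_id} is not an imino residue")
    nxt = model.residue(chain_id, res_id + 1)
    groups: list[tuple[AtomKey, AtomKey]] = [
        ((chain_id, res_id, "CB"), (chain_id, res_id, "CD")),
        ((chain_id, res_id, "CA"), (chain_id, res_id + 1, "CA")),
    ]
    if nxt.is_imino:
        groups.append(((chain_id, res_id + 1, "CB"), (chain_id, res_id + 1, "CD")))
    else:
        groups.append(((chain_id, res_id + 1, "N"), (chain_id, res_id + 1, "C")))
    groups.append(((chain_id, res_id + 1, "CA"), (chain_id, res_id + 2, "CA")))
    return tuple(groups)


def pucker_table(model: TripleHelixModel) -> list[RingPucker]:
    """Pucker classification of every imino residue in the model."""
    return [ring_pucker(model, cid, rid) for cid, rid in model.prolines()]
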