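"""Coordinate I/O, geometry primitives, superposition and five-fold symmetry.

Structures are held as lightweight per-chain residue lists (full-atom or
Cα-level). PDB reading/writing goes through :mod:`gemmi`; only
ATOM/HETATM/MODEL/ENDMDL/TER records are honoured, the highest-occupancy
altloc is kept and insertion codes are rejected. Author residue numbering is
authoritative throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Ensemble",
    "SymmetryFrame",
    "TopologyError",
    "read_structure",
    "write_ensemble",
    "kabsch_superpose",
    "ca_rmsd",
    "symmetrize_c5",
    "measure_distance",
    "estimate_symmetry_axis",
    "structure_from_ca",
    "span_length",
    "VDW_RADII",
]

# Bondi-style van der Waals radii (Å). Pore radii depend on this table, so it
# is fixed here rather than configurable per call.
VDW_RADII: dict[str, float] = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "SE": 1.90,
}
_DEFAULT_VDW = 1.70

CHAIN_LABELS = ("A", "B", "C", "D", "E")


class TopologyError(ValueError):
    """Raised when chain/residue/atom topology violates an operation's contract."""


class ParseError(ValueError):
    """Raised on malformed coordinate input."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) Å
    vdw_radius: float = _DEFAULT_VDW

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    def __getitem__(self, atom_name: str) -> Atom:
        try:
            return self.atoms[atom_name]
        except KeyError:
            raise TopologyError(
                f"atom {atom_name!r} missing from residue {self.name}{self.number}"
            ) from None


@dataclass
class Structure:
    """A (possibly pentameric) protein structure.

    ``residues`` maps chain label -> ordered residue list. ``resolution_level``
    is ``"full-atom"`` or ``"calpha"``.
    """

    chains: list[str]
    residues: dict[str, list[Residue]]
    resolution_level: str = "full-atom"

    def __post_init__(self) -> None:
        for ch in self.chains:
            nums = [r.number for r in self.residues[ch]]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise TopologyError(
                    f"residue numbers not strictly increasing in chain {ch}"
                )
            for r in self.residues[ch]:
                if "CA" not in r.atoms:
                    raise TopologyError(
                        f"missing CA in chain {ch} residue {r.name}{r.number}"
                    )

    # -- accessors -------------------------------------------------------
    def chain(self, label: str) -> list[Residue]:
        return self.residues[label]

    def residue(self, chain: str, number: int) -> Residue:
        for r in self.residues[chain]:
            if r.number == number:
                return r
        raise TopologyError(f"residue {number} not found in chain {chain}")

    def atom(self, chain: str, number: int, atom_name: str) -> Atom:
        return self.residue(chain, number)[atom_name]

    def ca_coords(self, chains: Sequence[str] | None = None) -> np.ndarray:
        chains = list(chains) if chains is not None else self.chains
        return np.array(
            [r.atoms["CA"].position for ch in chains for r in self.residues[ch]]
        )

    def all_atoms(self) -> Iterable[tuple[str, Residue, Atom]]:
        for ch in self.chains:
            for r in self.residues[ch]:
                for a in r.atoms.values():
                    yield ch, r, a

    def atom_array(self) -> tuple[np.ndarray, np.ndarray]:
        """All atom positions and vdW radii as arrays (for pore profiling)."""
        pos, rad = [], []
        for _, _, a in self.all_atoms():
            pos.append(a.position)
            rad.append(a.vdw_radius)
        return np.array(pos), np.array(rad)

    def topology_signature(self) -> tuple:
        return tuple(
            (ch, tuple((r.number, r.name, tuple(sorted(r.atoms))) for r in self.residues[ch]))
            for ch in self.chains
        )

    def copy(self) -> "Structure":
        return Structure(
            chains=list(self.chains),
            residues={
                ch: [
                    Residue(
                        r.number,
                        r.name,
                        {
                            n: Atom(a.name, a.element, a.position.copy(), a.vdw_radius)
                            for n, a in r.atoms.items()
                        },
                    )
                    for r in self.residues[ch]
                ]
                for ch in self.chains
            },
            resolution_level=self.resolution_level,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.copy()
        R = np.asarray(rotation)
        t = np.asarray(translation)
        for _, _, a in out.all_atoms():
            a.position = R @ a.position + t
        return out


@dataclass
class Ensemble:
    models: list[Structure]
    scores: list | None = None  # optional per-model ScoreBreakdown

    def __post_init__(self) -> None:
        if self.models:
            sig = self.models[0].topology_signature()
            for i, m in enumerate(self.models[1:], 2):
                if m.topology_signature() != sig:
                    raise TopologyError(f"model {i} topology differs from model 1")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


@dataclass
class SymmetryFrame:
    axis_point: np.ndarray
    axis_direction: np.ndarray
    order: int = 5

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        d = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis_direction must be nonzero")
        self.axis_direction = d / n
        if self.order < 2:
            raise ValueError("symmetry order must be >= 2")


def span_length(first: int, last: int) -> int:
    """Number of residues in an inclusive author-numbered span."""
    if last < first:
        raise ValueError("span end precedes start")
    return last - first + 1


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    return el if el else "C"


def read_structure(path: str | Path, model_selector: str | int = "all") -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    ``model_selector`` is ``"all"`` or a 0-based model index. Chain order is
    preserved and author residue numbering kept verbatim. Every residue must
    carry a CA atom; insertion codes are rejected.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"no models in {path}")
    st.remove_alternative_conformations()  # keeps first (highest-occupancy) altloc

    if model_selector == "all":
        model_indices = range(len(st))
    else:
        model_indices = [int(model_selector)]

    models = []
    for mi in model_indices:
        model = st[mi]
        chains: list[str] = []
        residues: dict[str, list[Residue]] = {}
        full_atom = False
        for chain in model:
            label = chain.name
            chains.append(label)
            rlist = []
            for res in chain:
                if res.het_flag == "W":
                    continue
                if res.seqid.icode not in (" ", "", "\x00"):
                    raise ParseError(
                        f"insertion code on residue {res.name} {res.seqid.num} "
                        f"in chain {label} not supported"
                    )
                atoms: dict[str, Atom] = {}
                for at in res:
                    el = _element_of(at)
                    atoms[at.name] = Atom(
                        name=at.name,
                        element=el,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        vdw_radius=VDW_RADII.get(el, _DEFAULT_VDW),
                    )
                if not atoms:
                    continue
                if set(atoms) != {"CA"}:
                    full_atom = True
                rlist.append(Residue(res.seqid.num, res.name, atoms))
            if rlist:
                residues[label] = rlist
        chains = [c for c in chains if c in residues]
        models.append(
            Structure(
                chains=chains,
                residues=residues,
                resolution_level="full-atom" if full_atom else "calpha",
            )
        )
    return Ensemble(models=models)


def write_ensemble(ensemble: Ensemble | Structure, path: str | Path) -> None:
    """Write models as a multi-model PDB file."""
    if isinstance(ensemble, Structure):
        ensemble = Ensemble(models=[ensemble])
    st = gemmi.Structure()
    st.name = "flexfold"
    for i, model in enumerate(ensemble.models, start=1):
        gm = gemmi.Model(i)
        for ch in model.chains:
            gc = gemmi.Chain(ch)
            for r in model.residues[ch]:
                gr = gemmi.Residue()
                gr.name = r.name
                gr.seqid = gemmi.SeqId(r.number, " ")
                for a in r.atoms.values():
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element.capitalize())
                    ga.pos = gemmi.Position(*a.position)
                    ga.occ = 1.0
                    gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def _selected_ca(s: Structure, selection: set[int] | None) -> np.ndarray:
    pts = []
    for ch in s.chains:
        for r in s.residues[ch]:
            if selection is None or r.number in selection:
                pts.append(r.atoms["CA"].position)
    return np.array(pts)


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    selection: Iterable[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid transform of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where
    ``x' = rotation @ x + translation`` and ``rmsd`` is the post-superposition
    Cα RMSD over the selection (residue numbers, applied in every chain).
    """
    sel = set(selection) if selection is not None else None
    P = _selected_ca(mobile, sel)
    Q = _selected_ca(reference, sel)
    if len(P) != len(Q):
        raise TopologyError("selection size differs between structures")
    if len(P) < 3:
        raise ValueError("need at least 3 points for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(Q - qc, P - pc)
    R = rot.as_matrix()
    t = qc - R @ pc
    rmsd = float(rssd / np.sqrt(len(P)))
    return R, t, rmsd


def ca_rmsd(a: Structure, b: Structure, superpose: bool = True) -> float:
    """Cα RMSD between two topology-matched structures (symmetric, >= 0)."""
    P, Q = a.ca_coords(), b.ca_coords()
    if P.shape != Q.shape:
        raise TopologyError("structures have different Cα counts")
    if superpose:
        if len(P) < 3:
            raise ValueError("need at least 3 points for superposed RMSD")
        pc, qc = P.mean(axis=0), Q.mean(axis=0)
        _, rssd = Rotation.align_vectors(Q - qc, P - pc)
        return float(rssd / np.sqrt(len(P)))
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Five-fold symmetry
# ---------------------------------------------------------------------------

def rotation_about_axis(frame: SymmetryFrame, angle_rad: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix + translation implementing rotation about the frame axis."""
    R = Rotation.from_rotvec(angle_rad * frame.axis_direction).as_matrix()
    t = frame.axis_point - R @ frame.axis_point
    return R, t


def symmetrize_c5(subunit: Structure, frame: SymmetryFrame) -> Structure:
    """Replicate a single-chain subunit into a C5 pentamer about ``frame``.

    Chain k (labels A–E in ring order) is the subunit rotated by k*72° about
    the symmetry axis.
    """
    if frame.order != 5:
        raise ValueError("symmetrize_c5 requires a frame of order 5")
    if len(subunit.chains) != 1:
        raise TopologyError("symmetrize_c5 expects a single-chain subunit")
    src = subunit.chains[0]
    residues: dict[str, list[Residue]] = {}
    for k, label in enumerate(CHAIN_LABELS):
        R, t = rotation_about_axis(frame, 2.0 * np.pi * k / 5.0)
        rlist = []
        for r in subunit.residues[src]:
            atoms = {
                n: Atom(a.name, a.element, R @ a.position + t, a.vdw_radius)
                for n, a in r.atoms.items()
            }
            rlist.append(Residue(r.number, r.name, atoms))
        residues[label] = rlist
    return Structure(
        chains=list(CHAIN_LABELS),
        residues=residues,
        resolution_level=subunit.resolution_level,
    )


def measure_distance(
    s: Structure,
    site_a: tuple[str, int, str],
    site_b: tuple[str, int, str],
) -> float:
    """Euclidean distance (Å) between two named atoms (chain, residue, atom)."""
    a = s.atom(*site_a)
    b = s.atom(*site_b)
    return float(np.linalg.norm(a.position - b.position))


def estimate_symmetry_axis(pentamer: Structure) -> SymmetryFrame:
    """Estimate the C5 symmetry frame of a pentamer from its Cα coordinates.

    The axis point is the centroid of all Cα atoms; the direction is the
    normal of the plane best fitting the five per-chain centroids (smallest
    principal component), signed to have a positive dot product with +z
    (ties broken by +x, then +y).
    """
    if len(pentamer.chains) != 5:
        raise TopologyError("symmetry-axis estimation requires 5 chains")
    centroids = np.array(
        [pentamer.ca_coords([ch]).mean(axis=0) for ch in pentamer.chains]
    )
    center = pentamer.ca_coords().mean(axis=0)
    X = centroids - centroids.mean(axis=0)
    # smallest singular direction = ring-plane normal
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[1] < 1e-8:
        raise ValueError("degenerate geometry: chain centroids are collinear")
    axis = vt[-1]
    for comp in (2, 0, 1):
        if abs(axis[comp]) > 1e-12:
            if axis[comp] < 0:
                axis = -axis
            break
    return SymmetryFrame(axis_point=center, axis_direction=axis, order=5)


# ---------------------------------------------------------------------------
# Construction helpers
# ---------------------------------------------------------------------------

def structure_from_ca(
    coords: np.ndarray,
    chain: str = "A",
    residue_names: Sequence[str] | None = None,
    first_residue: int = 1,
) -> Structure:
    """Build a Cα-level single-chain Structure from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = list(residue_names) if residue_names is not None else ["ALA"] * n
    rlist = [
        Residue(
            first_residue + i,
            names[i],
            {"CA": Atom("CA", "C", coords[i], VDW_RADII["C"])},
        )
        for i in range(n)
    ]
    return Structure(chains=[chain], residues={chain: rlist}, resolution_level="calpha")
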