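"""Mapping sequence-level findings onto structure, and dimer-interface analysis.

The sequence analysis ends with consensus-core positions (landmarks, SDPs,
motif slots); this module translates those into residues of an actual
structural model, filters them by proximity to bound ligands, and quantifies
the homodimer: protomer-versus-protomer superposition (Kabsch least-squares)
and buried solvent-accessible surface area at the dimer interface
(Shrake–Rupley numerical SASA).  It also emits ChimeraX-style command scripts
so annotated structures can be rendered reproducibly.

Conventions: first coordinate model only; alternate locations resolved to the
highest-occupancy conformer (ties to altloc 'A'); hydrogens parsed but
excluded from SASA and contact distances by default (typical crystal
structures at ~2 A resolution model none).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .profiling import ConsensusSequence
from .sdp_grid import global_align

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ResidueMap",
    "ContactSet",
    "SuperpositionResult",
    "InterfaceReport",
    "read_structure",
    "chain_sequence",
    "map_consensus_to_chain",
    "ligand_contacts",
    "kabsch",
    "superpose",
    "sphere_points",
    "sasa",
    "buried_interface",
    "emit_annotation_script",
]

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

#: Van der Waals radii (A) by element; unknown elements fall back to the
#: default carbon-like radius unless an override is supplied.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_VDW = 1.70


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    name: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def one_letter(self) -> str:
        return AA3TO1.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if not a.is_hydrogen]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class StructureModel:
    """Parsed coordinates: polymer chains and hetero (ligand) groups."""

    chains: dict[str, list[Residue]]
    ligands: list[tuple[str, Residue]] = field(default_factory=list)

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not in structure "
                           f"(available: {sorted(self.chains)})")
        return self.chains[chain_id]


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties to 'A'."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    resolved = []
    for name in order:
        group = by_name[name]
        resolved.append(
            min(group, key=lambda a: (-a.occupancy, a.altloc or "A"))
        )
    return resolved


def read_structure(path) -> StructureModel:
    """Parse a PDB file (first model only) into a :class:`StructureModel`."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"no coordinate model in {path}")
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    ligands: list[tuple[str, Residue]] = []
    n_atoms = 0
    for chain in model:
        for res in chain:
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name.upper(),
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    altloc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in res
            ]
            atoms = _resolve_altlocs(atoms)
            n_atoms += len(atoms)
            is_het = res.het_flag == "H"
            residue = Residue(
                name=res.name,
                number=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                atoms=atoms,
                is_hetero=is_het,
            )
            if is_het and res.name not in AA3TO1:
                ligands.append((chain.name, residue))
            else:
                chains.setdefault(chain.name, []).append(residue)
    if n_atoms == 0:
        raise ValueError(f"no ATOM records in {path}")
    for residues in chains.values():
        residues.sort(key=lambda r: (r.number, r.icode))
    return StructureModel(chains=chains, ligands=ligands)


def chain_sequence(residues) -> str:
    """One-letter sequence of a polymer chain (unknown residues -> 'X')."""
    return "".join(r.one_letter for r in residues)


# ---------------------------------------------------------------------------
# Sequence-to-structure mapping


@dataclass
class ResidueMap:
    """Consensus position -> structure residue correspondence.

    ``mapping`` sends 1-based consensus positions to ``(chain_id, residue
    number, insertion code)``.  ``percent_identity`` of the underlying
    alignment flags low-confidence maps.
    """

    mapping: dict[int, tuple[str, int, str]]
    unmapped: list[int]
    percent_identity: float
    chain_id: str


def map_consensus_to_chain(
    consensus: ConsensusSequence | str, residues, chain_id: str = "A"
) -> ResidueMap:
    """Globally align a consensus core to a chain's sequence.

    Aligned non-gap pairs become map entries; consensus positions opposite a
    gap are reported as unmapped.
    """
    seq = consensus if isinstance(consensus, str) else consensus.residues
    chain_seq = chain_sequence(residues)
    if not chain_seq:
        raise ValueError(f"chain {chain_id!r} has no polymer residues")
    aln = global_align(seq, chain_seq)
    mapping: dict[int, tuple[str, int, str]] = {}
    unmapped: list[int] = []
    for k in range(aln.n_columns):
        pa, pb = aln.map_a[k], aln.map_b[k]
        if pa is not None and pb is not None:
            res = residues[pb - 1]
            mapping[pa] = (chain_id, res.number, res.icode)
        elif pa is not None:
            unmapped.append(pa)
    return ResidueMap(
        mapping=mapping,
        unmapped=unmapped,
        percent_identity=aln.percent_identity,
        chain_id=chain_id,
    )


# ---------------------------------------------------------------------------
# Ligand contacts


@dataclass
class ContactSet:
    """Residues within ``cutoff`` of any ligand heavy atom.

    ``min_distances`` maps ``(chain_id, residue number, icode)`` to the
    minimum heavy-atom distance (A).
    """

    min_distances: dict[tuple[str, int, str], float]
    cutoff: float
    ligand_names: list[str]

    def __contains__(self, key) -> bool:
        return key in self.min_distances

    def __len__(self) -> int:
        return len(self.min_distances)


def ligand_contacts(
    structure: StructureModel,
    ligand: str,
    cutoff: float = 4.0,
    chains: list[str] | None = None,
    include_hydrogens: bool = False,
) -> ContactSet:
    """Residues whose minimum heavy-atom distance to the ligand is <= cutoff.

    ``ligand`` selects hetero groups by residue name (e.g. ``"DAV"``) or
    ``"chain:name"``.  The cutoff is inclusive.
    """
    if ":" in ligand:
        lig_chain, lig_name = ligand.split(":", 1)
    else:
        lig_chain, lig_name = None, ligand
    lig_atoms = []
    for ch, res in structure.ligands:
        if res.name == lig_name and (lig_chain is None or ch == lig_chain):
            for a in res.atoms:
                if include_hydrogens or not a.is_hydrogen:
                    lig_atoms.append(a.coords)
    if not lig_atoms:
        raise ValueError(f"no ligand matching {ligand!r} in structure")
    tree = cKDTree(np.array(lig_atoms))
    min_distances: dict[tuple[str, int, str], float] = {}
    for chain_id, residues in structure.chains.items():
        if chains is not None and chain_id not in chains:
            continue
        for res in residues:
            pts = [
                a.coords
                for a in res.atoms
                if include_hydrogens or not a.is_hydrogen
            ]
            if not pts:
                continue
            d = float(tree.query(np.array(pts))[0].min())
            if d <= cutoff:
                min_distances[(chain_id, res.number, res.icode)] = d
    return ContactSet(
        min_distances=min_distances, cutoff=cutoff, ligand_names=[lig_name]
    )


# ---------------------------------------------------------------------------
# Superposition


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_matched: int


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of point set P onto Q (Kabsch).

    Returns the proper rotation R and translation t minimising
    ``||(P @ R.T + t) - Q||`` and the residual RMSD.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 paired points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    t = cq - R @ cp
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_matched=len(P))


def superpose(chain_a, chain_b) -> SuperpositionResult:
    """Superpose two protomers on their paired C-alpha atoms.

    Residues are paired by global sequence alignment (not residue numbering),
    so chains with differently modelled ranges still pair correctly; only
    pairs with a C-alpha on both sides enter the fit.
    """
    seq_a, seq_b = chain_sequence(chain_a), chain_sequence(chain_b)
    aln = global_align(seq_a, seq_b)
    P, Q = [], []
    for k in range(aln.n_columns):
        pa, pb = aln.map_a[k], aln.map_b[k]
        if pa is None or pb is None:
            continue
        ca_a = chain_a[pa - 1].atom("CA")
        ca_b = chain_b[pb - 1].atom("CA")
        if ca_a is not None and ca_b is not None:
            P.append(ca_a.coords)
            Q.append(ca_b.coords)
    if len(P) < 3:
        raise ValueError(f"only {len(P)} paired C-alpha atoms; need at least 3")
    return kabsch(np.array(P), np.array(Q))


# ---------------------------------------------------------------------------
# SASA and buried interface


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n)
    golden = (1 + math.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * math.pi * i / golden
    r = np.sqrt(np.clip(1 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    coords: np.ndarray,
    elements,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake–Rupley.

    Each atom's extended sphere (vdW radius + probe) is sampled with
    ``n_points`` quasi-uniform test points; the accessible area is the
    sphere area times the fraction of points outside every neighbour's
    extended sphere.
    """
    coords = np.asarray(coords, float)
    table = dict(VDW_RADII)
    if radii:
        table.update(radii)
    r = np.array([table.get(e, DEFAULT_VDW) for e in elements]) + probe
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = r.max()
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + r[i] * unit
        neighbors = [
            j for j in tree.query_ball_point(coords[i], r[i] + rmax) if j != i
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > r[j] ** 2
        areas[i] = 4 * math.pi * r[i] ** 2 * accessible.mean()
    return areas


@dataclass
class InterfaceReport:
    """Buried-area bookkeeping for a two-chain interface.

    ``buried_area`` (A^2) per protomer = SASA(chain alone) - SASA(chain in the
    complex); ``interface_residues`` lists, per chain, residues burying more
    than the quadrature tolerance with their individual buried areas.
    """

    buried_area: dict[str, float]
    total_buried: float
    interface_residues: dict[str, list[tuple[int, str, str, float]]]
    probe: float
    n_points: int
    burial_tolerance: float = 0.1


def _chain_heavy_atoms(residues):
    coords, elements, owner = [], [], []
    for idx, res in enumerate(residues):
        for a in res.atoms:
            if not a.is_hydrogen:
                coords.append(a.coords)
                elements.append(a.element)
                owner.append(idx)
    return np.array(coords), elements, owner


def buried_interface(
    structure: StructureModel,
    chain_a: str,
    chain_b: str,
    probe: float = 1.4,
    n_points: int = 960,
    burial_tolerance: float = 0.1,
) -> InterfaceReport:
    """Quantify the interface buried between two chains.

    Heavy atoms only.  Interface residues are those burying more than
    ``burial_tolerance`` A^2 (a floor just above quadrature noise).
    """
    res_a = structure.chain(chain_a)
    res_b = structure.chain(chain_b)
    ca, ea, oa = _chain_heavy_atoms(res_a)
    cb, eb, ob = _chain_heavy_atoms(res_b)
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("both chains must contain heavy atoms")
    alone_a = sasa(ca, ea, probe, n_points)
    alone_b = sasa(cb, eb, probe, n_points)
    complex_areas = sasa(
        np.vstack([ca, cb]), list(ea) + list(eb), probe, n_points
    )
    in_complex_a = complex_areas[: len(ca)]
    in_complex_b = complex_areas[len(ca):]

    def per_residue(residues, owner, alone, in_complex):
        burial = np.zeros(len(residues))
        for atom_idx, res_idx in enumerate(owner):
            burial[res_idx] += alone[atom_idx] - in_complex[atom_idx]
        return [
            (res.number, res.icode, res.name, float(b))
            for res, b in zip(residues, burial)
            if b > burial_tolerance
        ]

    buried_a = float(alone_a.sum() - in_complex_a.sum())
    buried_b = float(alone_b.sum() - in_complex_b.sum())
    return InterfaceReport(
        buried_area={chain_a: buried_a, chain_b: buried_b},
        total_buried=buried_a + buried_b,
        interface_residues={
            chain_a: per_residue(res_a, oa, alone_a, in_complex_a),
            chain_b: per_residue(res_b, ob, alone_b, in_complex_b),
        },
        probe=probe,
        n_points=n_points,
        burial_tolerance=burial_tolerance,
    )


# ---------------------------------------------------------------------------
# Annotation script emission

_CATEGORY_COLORS = {"landmark": "gold", "sdp": "red", "contact": "cyan"}


def emit_annotation_script(categories: dict[str, list[tuple[str, int]]]) -> str:
    """Render per-residue annotations as a deterministic ChimeraX command script.

    ``categories`` maps a category name (e.g. ``"sdp"``) to ``(chain,
    residue number)`` pairs.  One selection + colour command pair is emitted
    per non-empty category; residues are listed in lexicographic
    (chain, number) order so identical inputs give byte-identical scripts.
    """
    lines = ["# residue annotations (generated)"]
    for category in sorted(categories):
        residues = sorted(set(categories[category]))
        if not residues:
            continue
        spec = " ".join(f"/{ch}:{num}" for ch, num in residues)
        color = _CATEGORY_COLORS.get(category, "magenta")
        lines.append(f"# {category} ({len(residues)} residues)")
        lines.append(f"select {spec}")
        lines.append(f"color sel {color}")
    lines.append("select clear")
    return "\n".join(lines) + "\n"
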