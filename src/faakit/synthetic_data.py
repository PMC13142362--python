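"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs to the analysis — curated subtype families, aligned MSAs, crystal
structures, mass-photometry event lists — are bulky, external, and carry no
ground truth.  These generators emit inputs with the same statistical
structure and a record of what was planted, so recovery can be verified
end-to-end offline:

* aligned families with controlled per-column conservation and occupancy,
  optional planted catalytic-motif columns;
* subtype *pairs* sharing a template except at planted specificity positions,
  where the target residue's frequency in the comparison family is forced
  under an explicit ceiling;
* toy structures (C-alpha chains, ligand atoms at exact minimum distances,
  dimers built by a rigid transform);
* mass-event lists drawn from Gaussian mixtures with planted means, widths
  and weights.

All generators are pure functions of (spec, seed) using numpy's seeded
PCG64 generator, so identical calls reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .profiling import CANONICAL, MultipleAlignment
from .structmap import Atom, ContactSet, Residue, StructureModel

__all__ = [
    "FamilySpec",
    "PlantedTruth",
    "simulate_family",
    "simulate_subtype_pair",
    "simulate_structure",
    "simulate_mass_events",
    "write_pdb",
    "write_events_csv",
]

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class FamilySpec:
    """Recipe for one aligned subtype family.

    ``conservation`` and ``occupancy`` may be scalars or per-column arrays;
    the noise model is uniform over the 19 non-consensus canonical residues.
    """

    template: str
    n_sequences: int
    conservation: float | np.ndarray = 0.95
    occupancy: float | np.ndarray = 1.0
    subtype: str = "other"

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("n_sequences must be at least 2")
        if not self.template:
            raise ValueError("template must be non-empty")
        bad = set(self.template) - set(CANONICAL)
        if bad:
            raise ValueError(f"template contains non-canonical residues: {sorted(bad)}")
        for name in ("conservation", "occupancy"):
            v = np.asarray(getattr(self, name), float)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
            if v.ndim == 1 and v.size != len(self.template):
                raise ValueError(f"per-column {name} must match template length")

    def per_column(self, name: str) -> np.ndarray:
        v = np.asarray(getattr(self, name), float)
        if v.ndim == 0:
            return np.full(len(self.template), float(v))
        return v


@dataclass
class PlantedTruth:
    """What a generator planted, for recovery checks downstream."""

    sdp_positions: list[int] = field(default_factory=list)
    sdp_residues: dict[int, str] = field(default_factory=dict)
    landmark_positions: list[int] = field(default_factory=list)
    motif_columns: list[int] = field(default_factory=list)
    realized_frequencies: dict[int, dict[str, float]] = field(default_factory=dict)
    population_counts: list[int] = field(default_factory=list)
    populations: list[tuple[float, float, float]] = field(default_factory=list)


def _draw_column(
    rng: np.random.Generator,
    consensus_res: str,
    n: int,
    conservation: float,
    occupancy: float,
    forbidden: str | None = None,
    forced_count: int = 0,
    forced_res: str | None = None,
) -> list[str]:
    """Draw one alignment column.

    ``forced_res`` is injected into exactly ``forced_count`` rows (these may
    be gap rows turned occupied? no — forced rows are taken from the occupied
    set first); ``forbidden`` is excluded from the noise alphabet.
    """
    n_occ = int(round(occupancy * n))
    col = ["-"] * n
    occupied = list(rng.permutation(n)[:n_occ])
    noise_alphabet = [
        r for r in CANONICAL if r != consensus_res and r != forbidden
    ]
    forced_rows = set(occupied[: min(forced_count, n_occ)]) if forced_count else set()
    for row in occupied:
        if row in forced_rows:
            col[row] = forced_res
        elif rng.random() < conservation:
            col[row] = consensus_res
        else:
            col[row] = noise_alphabet[rng.integers(len(noise_alphabet))]
    return col


def simulate_family(
    spec: FamilySpec, seed: int
) -> tuple[MultipleAlignment, PlantedTruth]:
    """Generate an aligned family drawn column-by-column from the spec.

    Each occupied cell carries the template residue with probability equal to
    the column's conservation level, otherwise a uniformly random other
    canonical residue; gaps are placed uniformly at random to hit the
    occupancy level exactly (rounded to whole rows).
    """
    rng = np.random.default_rng(seed)
    n = spec.n_sequences
    length = len(spec.template)
    cons = spec.per_column("conservation")
    occ = spec.per_column("occupancy")
    columns = []
    realized: dict[int, dict[str, float]] = {}
    for j in range(length):
        col = _draw_column(rng, spec.template[j], n, cons[j], occ[j])
        columns.append(col)
        counts: dict[str, int] = {}
        for c in col:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        realized[j + 1] = {r: c / n for r, c in counts.items()}
    rows = ["".join(columns[j][i] for j in range(length)) for i in range(n)]
    ids = [f"{spec.subtype}_{i + 1:04d}" for i in range(n)]
    truth = PlantedTruth(
        landmark_positions=[
            j + 1 for j in range(length) if cons[j] >= 0.85 and occ[j] >= 0.80
        ],
        realized_frequencies=realized,
    )
    return (
        MultipleAlignment(ids=ids, rows=rows, subtype=spec.subtype),
        truth,
    )


def simulate_subtype_pair(
    target_spec: FamilySpec,
    comparison_spec: FamilySpec,
    planted_sdps: dict[int, str],
    seed: int,
    comparison_ceiling: float = 0.10,
) -> tuple[MultipleAlignment, MultipleAlignment, PlantedTruth]:
    """Generate a target/comparison family pair with planted SDPs.

    Both families share the target template except at the planted positions
    (1-based template coordinates).  There the target consensus becomes the
    planted residue, while in the comparison family that residue is injected
    into exactly ``floor(ceiling * n)`` rows and excluded from the noise
    alphabet elsewhere, so its frequency over the entire comparison
    distribution is exactly ``floor(ceiling * n) / n``.
    """
    if len(target_spec.template) != len(comparison_spec.template):
        raise ValueError("templates must have equal length (indels not supported)")
    length = len(target_spec.template)
    for pos, res in planted_sdps.items():
        if not 1 <= pos <= length:
            raise ValueError(f"planted position {pos} outside template (1..{length})")
        if res not in CANONICAL:
            raise ValueError(f"planted residue {res!r} is not canonical")
        if comparison_spec.template[pos - 1] == res:
            raise ValueError(
                f"contradictory plant at position {pos}: comparison consensus "
                f"already is {res!r}"
            )
    rng = np.random.default_rng(seed)
    n_t, n_c = target_spec.n_sequences, comparison_spec.n_sequences
    cons_t = target_spec.per_column("conservation")
    occ_t = target_spec.per_column("occupancy")
    cons_c = comparison_spec.per_column("conservation")
    occ_c = comparison_spec.per_column("occupancy")

    cols_t, cols_c = [], []
    for j in range(length):
        pos = j + 1
        if pos in planted_sdps:
            res = planted_sdps[pos]
            cols_t.append(
                _draw_column(rng, res, n_t, cons_t[j], occ_t[j])
            )
            forced = int(math.floor(comparison_ceiling * n_c))
            cols_c.append(
                _draw_column(
                    rng,
                    comparison_spec.template[j],
                    n_c,
                    cons_c[j],
                    occ_c[j],
                    forbidden=res,
                    forced_count=forced,
                    forced_res=res,
                )
            )
        else:
            cols_t.append(
                _draw_column(rng, target_spec.template[j], n_t, cons_t[j], occ_t[j])
            )
            cols_c.append(
                _draw_column(
                    rng, comparison_spec.template[j], n_c, cons_c[j], occ_c[j]
                )
            )
    aln_t = MultipleAlignment(
        ids=[f"{target_spec.subtype}_{i + 1:04d}" for i in range(n_t)],
        rows=["".join(cols_t[j][i] for j in range(length)) for i in range(n_t)],
        subtype=target_spec.subtype,
    )
    aln_c = MultipleAlignment(
        ids=[f"{comparison_spec.subtype}_{i + 1:04d}" for i in range(n_c)],
        rows=["".join(cols_c[j][i] for j in range(length)) for i in range(n_c)],
        subtype=comparison_spec.subtype,
    )
    truth = PlantedTruth(
        sdp_positions=sorted(planted_sdps),
        sdp_residues=dict(planted_sdps),
    )
    return aln_t, aln_c, truth


# ---------------------------------------------------------------------------
# Toy structures


def _backbone_coords(n: int, geometry: str) -> np.ndarray:
    if geometry == "extended":
        return np.column_stack(
            [3.8 * np.arange(n), np.zeros(n), np.zeros(n)]
        )
    if geometry == "helix":
        # ideal alpha-helix C-alpha trace: radius 2.3 A, rise 1.5 A/res, 100 deg
        t = np.deg2rad(100.0) * np.arange(n)
        return np.column_stack(
            [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)]
        )
    raise ValueError(f"unknown geometry {geometry!r}")


def simulate_structure(
    sequence: str,
    geometry: str = "extended",
    ligand_placements: dict[int, float] | None = None,
    dimer_transform: tuple[np.ndarray, np.ndarray] | None = None,
    contact_cutoff: float = 4.0,
) -> tuple[StructureModel, ContactSet]:
    """Build a toy structure with exact, known geometry.

    C-alpha-only chain A along the chosen backbone; one carbon ligand atom
    per entry of ``ligand_placements`` (1-based residue index -> minimum
    distance in A), placed perpendicular to the chain so the distance to the
    named residue is exact and larger to every other residue.  An optional
    chain B is the rigid transform ``(R, t)`` of chain A.  Returns the model
    plus the ground-truth contact set at ``contact_cutoff``.
    """
    sequence = sequence.upper()
    if set(sequence) - set(AA1TO3):
        raise ValueError("sequence must be canonical")
    coords = _backbone_coords(len(sequence), geometry)
    ligand_placements = ligand_placements or {}

    def make_chain(chain_coords) -> list[Residue]:
        return [
            Residue(
                name=AA1TO3[sequence[i]],
                number=i + 1,
                atoms=[Atom(name="CA", element="C", coords=np.array(chain_coords[i]))],
            )
            for i in range(len(sequence))
        ]

    chains = {"A": make_chain(coords)}
    if dimer_transform is not None:
        R, t = dimer_transform
        R = np.asarray(R, float)
        t = np.asarray(t, float)
        coords_b = coords @ R.T + t
        from scipy.spatial.distance import cdist

        if cdist(coords, coords_b).min() < 1.0:
            raise ValueError("dimer transform clashes with chain A (< 1 A)")
        chains["B"] = make_chain(coords_b)

    ligands = []
    lig_atoms = []
    for k, (res_i, dist) in enumerate(sorted(ligand_placements.items())):
        if dist <= 0:
            raise ValueError("ligand distances must be positive")
        if not 1 <= res_i <= len(sequence):
            raise ValueError(f"ligand anchor residue {res_i} outside chain")
        if geometry == "extended":
            direction = np.array([0.0, 0.0, 1.0])
        else:
            # radially outward from the helix axis, away from all neighbours
            xy = coords[res_i - 1].copy()
            xy[2] = 0.0
            direction = xy / np.linalg.norm(xy)
        pos = coords[res_i - 1] + dist * direction
        for prev in lig_atoms:
            if np.linalg.norm(pos - prev) < 1.0:
                raise ValueError("clashing ligand placements (< 1 A apart)")
        lig_atoms.append(pos)
        ligands.append(
            (
                "X",
                Residue(
                    name="LIG",
                    number=k + 1,
                    atoms=[Atom(name=f"C{k + 1}", element="C", coords=pos)],
                    is_hetero=True,
                ),
            )
        )
    model = StructureModel(chains=chains, ligands=ligands)

    # ground-truth contacts: exact distances from every residue to every
    # ligand atom, thresholded at the cutoff
    min_distances = {}
    if lig_atoms:
        lig = np.array(lig_atoms)
        for chain_id, residues in chains.items():
            pts = np.array([r.atoms[0].coords for r in residues])
            d = np.sqrt(((pts[:, None, :] - lig[None, :, :]) ** 2).sum(-1)).min(axis=1)
            for r, dist in zip(residues, d):
                if dist <= contact_cutoff:
                    min_distances[(chain_id, r.number, "")] = float(dist)
    truth = ContactSet(
        min_distances=min_distances, cutoff=contact_cutoff, ligand_names=["LIG"]
    )
    return model, truth


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as a minimal fixed-column PDB file."""
    serial = 1
    lines = []
    for chain_id in sorted(model.chains):
        for res in model.chains[chain_id]:
            for a in res.atoms:
                lines.append(_pdb_line("ATOM", serial, a, res, chain_id))
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    for chain_id, res in model.ligands:
        for a in res.atoms:
            lines.append(_pdb_line("HETATM", serial, a, res, chain_id))
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _pdb_line(record: str, serial: int, a: Atom, res: Residue, chain_id: str) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    x, y, z = a.coords
    return (
        f"{record:<6s}{serial:>5d} {name}{a.altloc or ' '}"
        f"{res.name:>3s} {chain_id:1s}{res.number:>4d}{res.icode or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


# ---------------------------------------------------------------------------
# Mass events


def simulate_mass_events(
    populations,
    n: int,
    seed: int,
    floor: float | None = None,
) -> tuple[list[float], PlantedTruth]:
    """Draw n single-event masses (kDa) from a Gaussian mixture.

    ``populations`` is a list of (mean, sd, weight) with weights summing to
    1.  Per-population draw counts are multinomial; events are shuffled.
    The returned truth records the planted parameters and the realised
    per-population counts.  ``floor`` is recorded only — no events are
    removed here (the fitting stage owns the exclusion).
    """
    populations = [(float(m), float(s), float(w)) for m, s, w in populations]
    if n < 1:
        raise ValueError("n must be at least 1")
    if any(s < 0 for _, s, _ in populations):
        raise ValueError("population sd must be non-negative")
    weights = np.array([w for _, _, w in populations])
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("population weights must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, weights)
    events = np.concatenate(
        [
            rng.normal(mean, sd, size=c)
            for (mean, sd, _), c in zip(populations, counts)
        ]
    )
    rng.shuffle(events)
    truth = PlantedTruth(
        population_counts=[int(c) for c in counts],
        populations=populations,
    )
    return [float(e) for e in events], truth


def write_events_csv(events, path) -> None:
    with open(path, "w") as fh:
        fh.write("mass_kda\n")
        for e in events:
            fh.write(f"{e:.6f}\n")
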