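"""Shared-grid comparison of subtype consensus cores and SDP identification.

The consensus cores of two condensation-domain subtypes (e.g. the
fatty-acid-amide clade versus the canonical L-to-L class) are globally aligned
to build a *shared grid*: a common coordinate system in which each position
carries both subtypes' full column statistics.  Positions are classified by
the chemical relationship of the two consensus residues, and
*specificity-determining positions* (SDPs) are the grid positions where the
target subtype is strongly conserved while the very same residue is rare
across the whole comparison family — the residues most likely to underlie the
subtype's distinct donor/acceptor chemistry.

The pairwise aligner is a deterministic Needleman–Wunsch with affine gap
costs (Gotoh three-state recursion).  A gap run of length L costs
``gap_open + gap_extend * L``.  Traceback ties are resolved in the fixed
order diagonal > up > left, so results are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import substitution_matrices

from .profiling import CANONICAL, ColumnProfile, ConsensusSequence

GAP = "-"
NEG_INF = float("-inf")

#: Chemical classes used to call two consensus residues "similar":
#: aliphatic/hydrophobic, aromatic, polar-uncharged, basic, acidic, and the
#: conformationally special glycine and proline, each its own class.
CHEMICAL_CLASSES = (
    frozenset("AVLIMC"),
    frozenset("FWY"),
    frozenset("STNQ"),
    frozenset("KRH"),
    frozenset("DE"),
    frozenset("G"),
    frozenset("P"),
)

__all__ = [
    "PairwiseAlignment",
    "GridPosition",
    "SharedGrid",
    "SDPRecord",
    "load_matrix",
    "global_align",
    "same_chemical_class",
    "build_shared_grid",
    "identify_sdps",
    "grid_to_frame",
    "sdps_to_frame",
]


def load_matrix(name: str = "BLOSUM62"):
    """Load a published substitution matrix by name (symmetric, 20x20 core)."""
    return substitution_matrices.load(name)


@dataclass
class PairwiseAlignment:
    """Global alignment of two ungapped sequences.

    ``map_a[k]``/``map_b[k]`` give the 1-based position in the respective
    input consumed at alignment column ``k`` (None where that side is
    gapped).
    """

    aligned_a: str
    aligned_b: str
    score: float
    map_a: list[int | None] = field(repr=False)
    map_b: list[int | None] = field(repr=False)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def percent_identity(self) -> float:
        """Identities as a percentage of alignment columns."""
        ident = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != GAP
        )
        return 100.0 * ident / len(self.aligned_a) if self.aligned_a else 0.0


def global_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global alignment under an affine gap model.

    A gap run of length L costs ``gap_open + gap_extend * L`` (both charged
    on the first gapped column).  Gaps in opposite sequences open
    independently.  Traceback is deterministic: at equal score the diagonal
    move is preferred over a gap in ``b`` ("up", consuming ``a``), which is
    preferred over a gap in ``a`` ("left").
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    for name, seq in (("a", a), ("b", b)):
        bad = set(seq) - set(CANONICAL)
        if bad:
            raise ValueError(
                f"sequence {name} contains non-canonical residues: {sorted(bad)}"
            )
    if matrix is None:
        matrix = load_matrix()
    n, m = len(a), len(b)
    oe = gap_open + gap_extend

    # Three DP states per cell: M (diagonal), X (gap in b, consumes a),
    # Y (gap in a, consumes b).
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    # Backpointers: state entered from, per (state, i, j).
    bM = [[None] * (m + 1) for _ in range(n + 1)]
    bX = [[None] * (m + 1) for _ in range(n + 1)]
    bY = [[None] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
        bX[i][0] = "M" if i == 1 else "X"
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
        bY[0][j] = "M" if j == 1 else "Y"

    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = matrix[ai, b[j - 1]]
            # M: consume both; come from any state at (i-1, j-1)
            best, src = Mp[j - 1], "M"
            if Xp[j - 1] > best:
                best, src = Xp[j - 1], "X"
            if Yp[j - 1] > best:
                best, src = Yp[j - 1], "Y"
            Mi[j] = best + s
            bM[i][j] = src
            # X: gap in b; come from (i-1, j)
            best, src = Mp[j] - oe, "M"
            if Xp[j] - gap_extend > best:
                best, src = Xp[j] - gap_extend, "X"
            if Yp[j] - oe > best:
                best, src = Yp[j] - oe, "Y"
            Xi[j] = best
            bX[i][j] = src
            # Y: gap in a; come from (i, j-1)
            best, src = Mi[j - 1] - oe, "M"
            if Xi[j - 1] - oe > best:
                best, src = Xi[j - 1] - oe, "X"
            if Yi[j - 1] - gap_extend > best:
                best, src = Yi[j - 1] - gap_extend, "Y"
            Yi[j] = best
            bY[i][j] = src

    # Final state preference mirrors the move order: M > X > Y.
    end_scores = {"M": M[n][m], "X": X[n][m], "Y": Y[n][m]}
    state = max(("M", "X", "Y"), key=lambda s: end_scores[s])
    # max() keeps the first of equal candidates, i.e. M > X > Y on ties
    score = end_scores[state]

    cols_a: list[str] = []
    cols_b: list[str] = []
    map_a: list[int | None] = []
    map_b: list[int | None] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            prev = bM[i][j]
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            map_a.append(i)
            map_b.append(j)
            i, j = i - 1, j - 1
        elif state == "X":
            prev = bX[i][j]
            cols_a.append(a[i - 1])
            cols_b.append(GAP)
            map_a.append(i)
            map_b.append(None)
            i -= 1
        else:
            prev = bY[i][j]
            cols_a.append(GAP)
            cols_b.append(b[j - 1])
            map_a.append(None)
            map_b.append(j)
            j -= 1
        state = prev
    cols_a.reverse()
    cols_b.reverse()
    map_a.reverse()
    map_b.reverse()
    return PairwiseAlignment(
        aligned_a="".join(cols_a),
        aligned_b="".join(cols_b),
        score=float(score),
        map_a=map_a,
        map_b=map_b,
    )


def same_chemical_class(x: str, y: str) -> bool:
    """Whether two canonical residues fall in the same chemical class."""
    return any(x in cls and y in cls for cls in CHEMICAL_CLASSES)


@dataclass
class GridPosition:
    """One shared-grid position carrying both subtypes' evidence.

    ``cons_pos_a/b`` are 1-based positions in the respective consensus cores,
    ``orig_col_a/b`` the corresponding original MSA columns; all are None on
    the gapped side of an unpaired position.
    """

    grid_index: int
    residue_a: str
    residue_b: str
    classification: str
    cons_pos_a: int | None = None
    cons_pos_b: int | None = None
    orig_col_a: int | None = None
    orig_col_b: int | None = None
    profile_a: ColumnProfile | None = field(default=None, repr=False)
    profile_b: ColumnProfile | None = field(default=None, repr=False)


@dataclass
class SharedGrid:
    """Ordered grid positions plus the alignment that generated them."""

    positions: list[GridPosition]
    alignment: PairwiseAlignment = field(repr=False)
    subtype_a: str = ""
    subtype_b: str = ""

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SDPRecord:
    """A grid position passing the specificity-determining criteria."""

    grid_index: int
    target_residue: str
    target_conservation: float
    target_occupancy: float
    comparison_frequency: float
    cons_pos_target: int
    cons_pos_comparison: int
    orig_col_target: int
    orig_col_comparison: int


def classify_pair(x: str, y: str) -> str:
    if x == GAP or y == GAP:
        return "unpaired"
    if x == y:
        return "identical"
    if same_chemical_class(x, y):
        return "similar"
    return "divergent"


def build_shared_grid(
    cons_a: ConsensusSequence,
    cons_b: ConsensusSequence,
    profiles_a,
    profiles_b,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> SharedGrid:
    """Align two consensus cores and resolve each grid position's profiles.

    ``profiles_a``/``profiles_b`` are the full per-column profile lists of the
    *original* subtype alignments; the consensus ``column_map``s link each
    consensus position back to its source column.
    """
    prof_a = {p.column_index: p for p in profiles_a}
    prof_b = {p.column_index: p for p in profiles_b}
    for cons, prof, label in ((cons_a, prof_a, "a"), (cons_b, prof_b, "b")):
        for col in cons.column_map:
            if col not in prof:
                raise ValueError(
                    f"inconsistent column_map: consensus {label} references "
                    f"column {col} absent from its profiles"
                )
    aln = global_align(cons_a.residues, cons_b.residues, matrix, gap_open, gap_extend)
    positions = []
    for k in range(aln.n_columns):
        x, y = aln.aligned_a[k], aln.aligned_b[k]
        pa = aln.map_a[k]
        pb = aln.map_b[k]
        col_a = cons_a.column_map[pa - 1] if pa else None
        col_b = cons_b.column_map[pb - 1] if pb else None
        positions.append(
            GridPosition(
                grid_index=k + 1,
                residue_a=x,
                residue_b=y,
                classification=classify_pair(x, y),
                cons_pos_a=pa,
                cons_pos_b=pb,
                orig_col_a=col_a,
                orig_col_b=col_b,
                profile_a=prof_a[col_a] if col_a else None,
                profile_b=prof_b[col_b] if col_b else None,
            )
        )
    return SharedGrid(
        positions=positions,
        alignment=aln,
        subtype_a=cons_a.subtype,
        subtype_b=cons_b.subtype,
    )


def identify_sdps(
    grid: SharedGrid,
    conservation_min: float = 0.85,
    comparison_max: float = 0.25,
    occupancy_min: float = 0.80,
    require_occupancy: bool = True,
    comparison_denominator: str = "all",
) -> list[SDPRecord]:
    """Specificity-determining positions of the target (side *a*) subtype.

    A paired grid position is an SDP iff the target consensus residue's
    intra-subtype conservation is >= ``conservation_min`` and the frequency of
    that identical residue in the comparison family at the paired column is
    <= ``comparison_max``.  The comparison frequency is computed over the
    entire sequence distribution (gap rows in the denominator) by default;
    pass ``comparison_denominator="nongap"`` for the non-gap convention.
    ``require_occupancy`` additionally restricts candidacy to well-occupied
    target columns (the landmark occupancy rule); switch off to apply the two
    written criteria alone.
    """
    records = []
    for pos in grid.positions:
        if pos.classification == "unpaired":
            continue
        pa, pb = pos.profile_a, pos.profile_b
        if pa is None or pb is None or pa.conservation is None:
            continue
        if pa.conservation < conservation_min:
            continue
        if require_occupancy and pa.occupancy < occupancy_min:
            continue
        freq = pb.frequency(pos.residue_a, denominator=comparison_denominator)
        if freq > comparison_max:
            continue
        records.append(
            SDPRecord(
                grid_index=pos.grid_index,
                target_residue=pos.residue_a,
                target_conservation=pa.conservation,
                target_occupancy=pa.occupancy,
                comparison_frequency=freq,
                cons_pos_target=pos.cons_pos_a,
                cons_pos_comparison=pos.cons_pos_b,
                orig_col_target=pos.orig_col_a,
                orig_col_comparison=pos.orig_col_b,
            )
        )
    return records


def grid_to_frame(grid: SharedGrid, sdps=None) -> pd.DataFrame:
    """Tabulate a shared grid (with optional SDP flags) for TSV export."""
    sdp_indices = {r.grid_index for r in (sdps or [])}
    rows = []
    for p in grid.positions:
        rows.append(
            {
                "grid_index": p.grid_index,
                "residue_a": p.residue_a,
                "residue_b": p.residue_b,
                "classification": p.classification,
                "conservation_a": p.profile_a.conservation if p.profile_a else None,
                "occupancy_a": p.profile_a.occupancy if p.profile_a else None,
                "orig_col_a": p.orig_col_a,
                "orig_col_b": p.orig_col_b,
                "sdp": p.grid_index in sdp_indices,
            }
        )
    return pd.DataFrame(rows)


def sdps_to_frame(sdps) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "grid_index": r.grid_index,
                "target_residue": r.target_residue,
                "target_conservation": r.target_conservation,
                "target_occupancy": r.target_occupancy,
                "comparison_frequency": r.comparison_frequency,
                "cons_pos_target": r.cons_pos_target,
                "cons_pos_comparison": r.cons_pos_comparison,
                "orig_col_target": r.orig_col_target,
                "orig_col_comparison": r.orig_col_comparison,
            }
            for r in sdps
        ],
        columns=[
            "grid_index",
            "target_residue",
            "target_conservation",
            "target_occupancy",
            "comparison_frequency",
            "cons_pos_target",
            "cons_pos_comparison",
            "orig_col_target",
            "orig_col_comparison",
        ],
    )
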