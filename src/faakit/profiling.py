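"""Per-column alignment statistics, occupancy trimming and consensus cores.

A subtype family arrives as a multiple sequence alignment.  Each column is
summarised by its non-gap *occupancy* (fraction of rows with a residue) and its
*conservation* (fraction of the non-gap cells carrying the most frequent
canonical residue).  Poorly occupied columns — the divergent loop regions —
are dropped, and the most frequent residue of each surviving column becomes the
ungapped "consensus core" of the subtype.  Columns that are both strongly
conserved and well occupied are *landmarks*: the stable scaffold positions
used downstream to anchor subtype-versus-subtype comparisons.  The module also
tabulates per-slot residue frequencies over a catalytic-motif window, e.g. the
(D/H)HxxxDS motif that distinguishes fatty-acid-amide condensation domains
from the canonical HHxxxDG.

Coordinates are 1-based throughout, and every derived object carries a
``column_map`` back to the original alignment columns so provenance is never
lost by trimming.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import AlignIO

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
NONCANONICAL = set("XBZU")
GAP = "-"

__all__ = [
    "MultipleAlignment",
    "ColumnProfile",
    "TrimmedAlignment",
    "ConsensusSequence",
    "MotifTable",
    "read_alignment",
    "write_alignment",
    "column_profiles",
    "trim_columns",
    "extract_consensus",
    "classify_landmarks",
    "find_motif_columns",
    "motif_table",
    "profiles_to_frame",
]


@dataclass
class MultipleAlignment:
    """Aligned family: parallel lists of ids and equal-length gapped rows."""

    ids: list[str]
    rows: list[str]
    subtype: str = "other"

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        width = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ValueError(
                    f"ragged alignment: row {self.ids[i]!r} has length "
                    f"{len(row)}, expected {width}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, index: int) -> str:
        """Column content by 1-based index."""
        return "".join(row[index - 1] for row in self.rows)


@dataclass
class ColumnProfile:
    """Summary statistics for one alignment column (1-based ``column_index``).

    ``conservation`` is top-residue count over non-gap count and is ``None``
    for an all-gap column.  Non-canonical residues (X/B/Z/U) count toward
    occupancy but can never be the top residue.
    """

    column_index: int
    n_rows: int
    occupancy: float
    residue_counts: Counter = field(repr=False)
    top_residue: str | None
    conservation: float | None

    @property
    def n_nongap(self) -> int:
        return sum(self.residue_counts.values())

    def frequency(self, residue: str, denominator: str = "all") -> float:
        """Frequency of ``residue`` at this column.

        ``denominator="all"`` divides by the total row count (gap rows
        included — the "entire sequence distribution" convention);
        ``"nongap"`` divides by the non-gap count.
        """
        count = self.residue_counts.get(residue, 0)
        if denominator == "all":
            return count / self.n_rows
        if denominator == "nongap":
            n = self.n_nongap
            return count / n if n else 0.0
        raise ValueError(f"unknown denominator {denominator!r}")


@dataclass
class TrimmedAlignment:
    """Alignment restricted to well-occupied columns.

    ``column_map[t]`` is the original 1-based column index of trimmed column
    ``t + 1``; it is strictly increasing.
    """

    alignment: MultipleAlignment
    column_map: list[int]


@dataclass
class ConsensusSequence:
    """Ungapped consensus core of a subtype with provenance back to the MSA."""

    subtype: str
    residues: str
    column_map: list[int]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MotifTable:
    """Per-slot residue frequencies over an ordered set of motif columns.

    ``frequencies[k]`` maps residue -> fraction of the non-gap cells at the
    k-th motif column (original 1-based index ``columns[k]``).
    """

    columns: list[int]
    frequencies: list[dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        """Frequency matrix (slots x residues), suitable for logo tools."""
        residues = sorted(CANONICAL)
        data = [
            [freq.get(r, 0.0) for r in residues] for freq in self.frequencies
        ]
        return pd.DataFrame(data, index=self.columns, columns=residues)


# ---------------------------------------------------------------------------


def read_alignment(path, fmt: str | None = None, subtype: str = "other") -> MultipleAlignment:
    """Read an aligned FASTA or Stockholm file.

    Gap characters '.' and '-' are normalised to '-' and residues are folded
    to upper case.  ``fmt`` defaults to Stockholm for ``.sto``/``.stk``
    extensions, FASTA otherwise.
    """
    path = str(path)
    if fmt is None:
        fmt = "stockholm" if path.endswith((".sto", ".stk", ".stockholm")) else "fasta"
    aln = AlignIO.read(path, fmt)
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper().replace(".", "-") for rec in aln]
    return MultipleAlignment(ids=ids, rows=rows, subtype=subtype)


def write_alignment(alignment: MultipleAlignment, path, width: int = 60) -> None:
    """Write an alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for sid, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def column_profiles(alignment: MultipleAlignment) -> list[ColumnProfile]:
    """Per-column occupancy, residue counts, top residue and conservation."""
    n = alignment.n_rows
    profiles = []
    for j in range(1, alignment.n_columns + 1):
        col = alignment.column(j)
        counts = Counter(c for c in col if c != GAP)
        nongap = sum(counts.values())
        canonical = {r: c for r, c in counts.items() if r in CANONICAL}
        if canonical:
            # highest count wins; ties broken lexicographically
            top = min(canonical, key=lambda r: (-canonical[r], r))
            conservation = canonical[top] / nongap
        else:
            top, conservation = None, None
        profiles.append(
            ColumnProfile(
                column_index=j,
                n_rows=n,
                occupancy=nongap / n,
                residue_counts=counts,
                top_residue=top,
                conservation=conservation,
            )
        )
    return profiles


def trim_columns(
    alignment: MultipleAlignment, occupancy_min: float = 0.70
) -> TrimmedAlignment:
    """Drop columns with non-gap occupancy below ``occupancy_min``.

    The threshold is a strict lower cut: a column at exactly the threshold is
    retained.
    """
    profiles = column_profiles(alignment)
    keep = [p.column_index for p in profiles if p.occupancy >= occupancy_min]
    if not keep:
        raise ValueError("empty core: every column falls below the occupancy threshold")
    rows = ["".join(row[j - 1] for j in keep) for row in alignment.rows]
    trimmed = MultipleAlignment(
        ids=list(alignment.ids), rows=rows, subtype=alignment.subtype
    )
    return TrimmedAlignment(alignment=trimmed, column_map=keep)


def extract_consensus(trimmed: TrimmedAlignment) -> ConsensusSequence:
    """Most frequent canonical residue of each retained column.

    Ties are broken lexicographically by one-letter code.  A column whose
    non-gap cells are all non-canonical cannot yield a consensus residue and
    is an error.
    """
    residues = []
    for t, profile in enumerate(column_profiles(trimmed.alignment)):
        if profile.top_residue is None:
            raise ValueError(
                "no canonical residue in retained column "
                f"{trimmed.column_map[t]} (trimmed position {t + 1})"
            )
        residues.append(profile.top_residue)
    return ConsensusSequence(
        subtype=trimmed.alignment.subtype,
        residues="".join(residues),
        column_map=list(trimmed.column_map),
    )


def classify_landmarks(
    profiles,
    conservation_min: float = 0.85,
    occupancy_min: float = 0.80,
) -> set[int]:
    """Column indices that are "highly conserved" scaffold landmarks.

    Both thresholds are inclusive: conservation >= 0.85 and occupancy >= 0.80
    at the defaults.
    """
    return {
        p.column_index
        for p in profiles
        if p.conservation is not None
        and p.conservation >= conservation_min
        and p.occupancy >= occupancy_min
    }


DEFAULT_MOTIF_PATTERN = r"[DH]H...D."


def find_motif_columns(
    consensus: ConsensusSequence, pattern: str = DEFAULT_MOTIF_PATTERN
) -> list[int]:
    """Locate the catalytic motif in a consensus core by regex scan.

    Returns the original alignment column indices of the motif slots.  The
    scan must anchor exactly once; zero or multiple matches raise, in which
    case explicit anchor columns must be supplied to :func:`motif_table`.
    """
    matches = list(re.finditer(pattern, consensus.residues))
    if not matches:
        raise ValueError(f"motif pattern {pattern!r} not found in consensus")
    if len(matches) > 1:
        starts = [m.start() + 1 for m in matches]
        raise ValueError(
            f"motif pattern {pattern!r} is ambiguous (matches at consensus "
            f"positions {starts}); supply anchor columns explicitly"
        )
    m = matches[0]
    return [consensus.column_map[i] for i in range(m.start(), m.end())]


def motif_table(alignment: MultipleAlignment, anchor_columns) -> MotifTable:
    """Per-slot residue frequency table over the given motif columns.

    Fractions are over the non-gap cells of each column (non-canonical
    residues included), so each slot's fractions sum to 1 whenever the column
    is not all-gap.
    """
    frequencies = []
    for j in anchor_columns:
        if not 1 <= j <= alignment.n_columns:
            raise ValueError(f"anchor column {j} outside alignment (1..{alignment.n_columns})")
        col = alignment.column(j)
        counts = Counter(c for c in col if c != GAP)
        nongap = sum(counts.values())
        frequencies.append(
            {r: c / nongap for r, c in sorted(counts.items())} if nongap else {}
        )
    return MotifTable(columns=list(anchor_columns), frequencies=frequencies)


def profiles_to_frame(profiles, landmarks: set[int] | None = None) -> pd.DataFrame:
    """Tabulate profiles (and optional landmark flags) for TSV export."""
    landmarks = landmarks or set()
    return pd.DataFrame(
        {
            "column_index": [p.column_index for p in profiles],
            "occupancy": [p.occupancy for p in profiles],
            "top_residue": [p.top_residue or "" for p in profiles],
            "conservation": [p.conservation for p in profiles],
            "landmark": [p.column_index in landmarks for p in profiles],
        }
    )
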