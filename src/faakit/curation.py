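"""Assembly and filtering of condensation-domain subtype sequence sets.

Condensation (C) domains pulled from annotated biosynthetic gene clusters come
with two independent sources of evidence: a profile-HMM hit against the C-domain
family model (PF00668) and the cluster's own annotated domain boundaries.  A
sequence enters the comparative analysis only when both agree: the hit must
cover enough of the HMM model, overlap the annotated span, and the domain must
fall in the length window typical of a complete C domain.  The profile search
itself is an upstream step; this module consumes its tabular output and applies
the filters, producing an auditable retained/rejected record per sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "DomainHit",
    "DomainAnnotation",
    "CurationThresholds",
    "CuratedSet",
    "read_sequences",
    "read_domain_hits",
    "read_annotations",
    "write_fasta",
    "length_filter",
    "model_coverage",
    "boundary_overlap",
    "curate",
]

#: Subtype labels recognised throughout the package.  ``C_FAA`` is the
#: fatty-acid-amide clade; the remainder are the established functional classes.
SUBTYPES = ("C_FAA", "LCL", "DCL", "C_Dual", "C_Starter", "C_Glyc", "other")

_ALLOWED_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY" + "XBZU")


@dataclass(frozen=True)
class SequenceRecord:
    """One ungapped protein sequence with its subtype label and provenance."""

    id: str
    residues: str
    subtype: str = "other"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - _ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainHit:
    """One per-domain hit from a profile-HMM search.

    Coordinates are 1-based inclusive: ``model_from``/``model_to`` on the HMM
    model, ``env_from``/``env_to`` (envelope) on the target sequence.
    """

    sequence_id: str
    model_from: int
    model_to: int
    env_from: int
    env_to: int
    model_length: int

    def __post_init__(self) -> None:
        if self.model_length <= 0:
            raise ValueError("model_length must be positive")
        if not (1 <= self.model_from <= self.model_to <= self.model_length):
            raise ValueError(
                f"invalid model span {self.model_from}-{self.model_to} "
                f"for model of length {self.model_length}"
            )
        if self.env_from > self.env_to:
            raise ValueError("env_from must not exceed env_to")


@dataclass(frozen=True)
class DomainAnnotation:
    """Annotated domain boundaries on a parent sequence, 1-based inclusive."""

    sequence_id: str
    start: int
    end: int
    subtype: str = "other"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must not exceed end")


@dataclass(frozen=True)
class CurationThresholds:
    """Retention thresholds; defaults are the protocol's standard values."""

    min_model_coverage: float = 0.70
    min_boundary_overlap: float = 0.90
    min_length: int = 300
    max_length: int = 520

    def __post_init__(self) -> None:
        for name in ("min_model_coverage", "min_boundary_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")


@dataclass
class CuratedSet:
    """Result of :func:`curate`: retained records plus a per-record audit table."""

    retained: list[SequenceRecord]
    audit: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.retained)


# ---------------------------------------------------------------------------
# I/O


def read_sequences(path, subtype_map: dict[str, str] | None = None) -> list[SequenceRecord]:
    """Read ungapped protein sequences from a FASTA file.

    ``subtype_map`` optionally assigns a subtype label per sequence id;
    unmapped ids get ``"other"``.
    """
    subtype_map = subtype_map or {}
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("-", "").replace(".", "")
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                subtype=subtype_map.get(rec.id, "other"),
                source=str(path),
            )
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as FASTA with lines wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_domain_hits(path, fmt: str = "auto") -> list[DomainHit]:
    """Read per-domain hits from an hmmsearch ``domtblout`` file or a 6-column TSV.

    The TSV layout is ``sequence_id  model_from  model_to  env_from  env_to
    model_length`` (header line optional).  ``fmt`` is ``"auto"``,
    ``"domtblout"`` or ``"tsv"``.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"no domain hits in {path}")
    if fmt == "auto":
        data = [ln for ln in lines if not ln.startswith("#")]
        fmt = "domtblout" if (data and len(data[0].split()) >= 21) else "tsv"
    for ln in lines:
        if ln.startswith("#"):
            continue
        parts = ln.split() if fmt == "domtblout" else ln.split("\t")
        if fmt == "domtblout":
            # HMMER3 per-domain table: target name, -, tlen, query, -, qlen,
            # ... hmm_from(15) hmm_to(16) ali_from ali_to env_from(19) env_to(20)
            hits.append(
                DomainHit(
                    sequence_id=parts[0],
                    model_from=int(parts[15]),
                    model_to=int(parts[16]),
                    env_from=int(parts[19]),
                    env_to=int(parts[20]),
                    model_length=int(parts[5]),
                )
            )
        else:
            if parts[0].lower() in ("sequence_id", "id"):
                continue
            sid, mf, mt, ef, et, ml = parts[:6]
            hits.append(
                DomainHit(sid, int(mf), int(mt), int(ef), int(et), int(ml))
            )
    return hits


def read_annotations(path) -> list[DomainAnnotation]:
    """Read domain-boundary annotations from a TSV:
    ``sequence_id  start  end  subtype`` (header optional)."""
    annots: list[DomainAnnotation] = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if parts[0].lower() in ("sequence_id", "id"):
                continue
            sid, start, end = parts[:3]
            subtype = parts[3] if len(parts) > 3 else "other"
            annots.append(DomainAnnotation(sid, int(start), int(end), subtype))
    return annots


# ---------------------------------------------------------------------------
# Filters


def length_filter(
    records, thresholds: CurationThresholds = CurationThresholds()
) -> list[SequenceRecord]:
    """Keep records whose length lies in the inclusive window
    [min_length, max_length]."""
    return [
        r for r in records if thresholds.min_length <= len(r) <= thresholds.max_length
    ]


def model_coverage(hit: DomainHit) -> float:
    """Fraction of the HMM model covered by the hit, counting positions
    inclusively: ``(model_to - model_from + 1) / model_length``."""
    return (hit.model_to - hit.model_from + 1) / hit.model_length


def boundary_overlap(hit: DomainHit, annotation: DomainAnnotation) -> float:
    """Fraction of the annotated span covered by the hit envelope.

    Both intervals are 1-based inclusive; the denominator is the annotated
    span, so the value is the share of the annotated domain the hit recovers.
    """
    if hit.sequence_id != annotation.sequence_id:
        raise ValueError(
            f"hit is for {hit.sequence_id!r} but annotation is for "
            f"{annotation.sequence_id!r}"
        )
    lo = max(hit.env_from, annotation.start)
    hi = min(hit.env_to, annotation.end)
    inter = max(0, hi - lo + 1)
    return inter / (annotation.end - annotation.start + 1)


def _best_hit(hits, annots):
    """Best (hit, annotation) pair: highest model coverage, ties broken by
    larger boundary overlap, then by first occurrence."""
    best = None
    best_key = None
    for i, hit in enumerate(hits):
        ov = max((boundary_overlap(hit, a) for a in annots), default=0.0)
        key = (model_coverage(hit), ov, -i)
        if best_key is None or key > best_key:
            best, best_key = (hit, ov), key
    return best


def curate(
    records,
    hits,
    annotations,
    thresholds: CurationThresholds = CurationThresholds(),
) -> CuratedSet:
    """Apply the full retention protocol and return retained records + audit.

    A record is retained iff its length is within the window, its best hit
    covers at least ``min_model_coverage`` of the HMM model, and that hit
    overlaps the annotated boundaries by at least ``min_boundary_overlap``.
    The audit table carries every computed value and, for rejects, the first
    failing rule (checked in the order length, model_coverage,
    boundary_overlap; records with no hit or no annotation are rejected with
    reason ``no_hit`` / ``no_annotation``).
    """
    hits_by_id: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_id.setdefault(h.sequence_id, []).append(h)
    annots_by_id: dict[str, list[DomainAnnotation]] = {}
    for a in annotations:
        annots_by_id.setdefault(a.sequence_id, []).append(a)

    retained: list[SequenceRecord] = []
    rows = []
    for rec in records:
        row = {
            "sequence_id": rec.id,
            "subtype": rec.subtype,
            "length": len(rec),
            "n_hits": len(hits_by_id.get(rec.id, [])),
            "model_coverage": float("nan"),
            "boundary_overlap": float("nan"),
            "length_pass": thresholds.min_length <= len(rec) <= thresholds.max_length,
            "coverage_pass": False,
            "overlap_pass": False,
            "retained": False,
            "reason": "",
        }
        rec_hits = hits_by_id.get(rec.id)
        rec_annots = annots_by_id.get(rec.id)
        if not rec_hits:
            row["reason"] = "no_hit"
        elif not rec_annots:
            row["reason"] = "no_annotation"
        else:
            hit, overlap = _best_hit(rec_hits, rec_annots)
            cov = model_coverage(hit)
            row["model_coverage"] = cov
            row["boundary_overlap"] = overlap
            row["coverage_pass"] = cov >= thresholds.min_model_coverage
            row["overlap_pass"] = overlap >= thresholds.min_boundary_overlap
            if not row["length_pass"]:
                row["reason"] = "length"
            elif not row["coverage_pass"]:
                row["reason"] = "model_coverage"
            elif not row["overlap_pass"]:
                row["reason"] = "boundary_overlap"
            else:
                row["retained"] = True
                retained.append(rec)
        rows.append(row)
    return CuratedSet(retained=retained, audit=pd.DataFrame(rows))
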