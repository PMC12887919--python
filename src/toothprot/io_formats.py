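"""Readers and writers for the external formats the pipeline touches.

The pipeline consumes protein quantification tables (TSV), pathway
annotations (GMT), 3D-Slicer-style fiducial landmark files (CSV with
``#`` comment headers), and a specimen design table; it emits CSV
reports.  All formats are plain text.

Missing abundances are represented in memory as ``None`` and on disk as
empty cells — never 0 or a textual NaN.  A zero abundance is invalid by
construction (label-free intensities are positive).

Quant-table dialect
-------------------
Tab-separated, UTF-8, one protein per row.  Mandatory columns:
``accession``, ``q_value``, ``n_peptides``, ``n_psms`` and one
``Abundance: <specimen_id>`` column per designed specimen.  Optional
columns: ``gene``, ``description``, ``peptide_id``.  Rows with a
non-empty ``peptide_id`` carry peptide-level abundances for the protein
named in ``accession``; all other fields on such rows are ignored.
Column order is not significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "DuplicateRecordError",
    "QuantRecord",
    "SpecimenDesign",
    "GroupDataset",
    "PathwaySet",
    "LandmarkSet",
    "read_quant_table",
    "write_quant_table",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "read_landmarks",
    "write_landmarks",
]

ARMS = ("treatment", "control")

LANDMARK_ROLES = {"skull": 2, "molar": 25}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class DuplicateRecordError(FormatError):
    """Two rows claim the same protein accession."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SpecimenDesign:
    """One specimen's position in the experimental design.

    ``batch`` distinguishes the two LC-MS/MS acquisition batches
    ("group1" / "group2"); ``arm`` is the diet arm.
    """

    specimen_id: str
    batch: str
    arm: str
    litter_id: str = ""
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"arm must be one of {ARMS}, got {self.arm!r}")


@dataclass(frozen=True)
class QuantRecord:
    """One protein row of a label-free quantification table.

    ``q_value`` is the protein's minimum identification FDR,
    ``n_peptides`` the distinct-peptide count and ``n_psms`` the
    peptide-spectrum-match count used by the QC filters.  ``abundances``
    maps specimen id to a positive intensity or ``None`` (missing);
    ``peptide_abundances`` optionally maps peptide id -> specimen id ->
    intensity or ``None``.
    """

    accession: str
    q_value: float
    n_peptides: int
    n_psms: int
    abundances: Mapping[str, Optional[float]]
    gene: Optional[str] = None
    description: str = ""
    peptide_abundances: Optional[Mapping[str, Mapping[str, Optional[float]]]] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValidationError(
                f"{self.accession}: q_value {self.q_value} outside [0, 1]"
            )
        if self.n_peptides < 0 or self.n_psms < 0:
            raise ValidationError(f"{self.accession}: negative peptide/PSM count")
        for sid, value in self.abundances.items():
            if value is not None and not (value > 0 and math.isfinite(value)):
                raise ValidationError(
                    f"{self.accession}: abundance for {sid} must be positive, "
                    f"got {value!r}"
                )
        if self.peptide_abundances is not None:
            for pid, per_spec in self.peptide_abundances.items():
                for sid, value in per_spec.items():
                    if value is not None and not (value > 0 and math.isfinite(value)):
                        raise ValidationError(
                            f"{self.accession}/{pid}: abundance for {sid} must be "
                            f"positive, got {value!r}"
                        )
        if self.n_peptides >= 1 and self.abundances and not any(
            v is not None for v in self.abundances.values()
        ):
            raise ValidationError(
                f"{self.accession}: identified protein has no observed abundance"
            )


@dataclass
class GroupDataset:
    """One batch's quantification table plus the matching design rows."""

    batch: str
    records: list[QuantRecord]
    design: list[SpecimenDesign]

    def __post_init__(self) -> None:
        designed = {d.specimen_id for d in self.design}
        for d in self.design:
            if d.batch != self.batch:
                raise ValidationError(
                    f"design row {d.specimen_id} belongs to batch {d.batch}, "
                    f"not {self.batch}"
                )
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise DuplicateRecordError(f"duplicate accession {rec.accession}")
            seen.add(rec.accession)
            unknown = set(rec.abundances) - designed
            if unknown:
                raise ValidationError(
                    f"{rec.accession}: abundances for undesigned specimens {sorted(unknown)}"
                )

    @property
    def specimen_ids(self) -> list[str]:
        return [d.specimen_id for d in self.design]

    def accessions(self) -> list[str]:
        return [rec.accession for rec in self.records]

    def by_accession(self) -> dict[str, QuantRecord]:
        return {rec.accession: rec for rec in self.records}


@dataclass(frozen=True)
class PathwaySet:
    """A named pathway with a deduplicated membership set."""

    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_id} has no members")

    @property
    def size(self) -> int:
        """Pathway size K (deduplicated member count)."""
        return len(self.members)


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered, labelled 3D landmarks for one specimen.

    Two roles exist: ``skull`` (2 landmarks spanning the straight-line
    skull length) and ``molar`` (25 landmarks outlining the crown
    footprint).  Coordinates are millimetres.
    """

    specimen_id: str
    landmarks: tuple[tuple[str, float, float, float], ...]
    role: str

    def __post_init__(self) -> None:
        expected = LANDMARK_ROLES.get(self.role)
        if expected is None:
            raise ValidationError(f"unknown landmark role {self.role!r}")
        if len(self.landmarks) != expected:
            raise ValidationError(
                f"{self.specimen_id}: role {self.role!r} requires {expected} "
                f"landmarks, got {len(self.landmarks)}"
            )
        for label, x, y, z in self.landmarks:
            if not all(math.isfinite(c) for c in (x, y, z)):
                raise ValidationError(
                    f"{self.specimen_id}: non-finite coordinate at {label!r}"
                )

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in file order."""
        return np.array([[x, y, z] for _, x, y, z in self.landmarks], dtype=float)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, *_ in self.landmarks)


# ---------------------------------------------------------------------------
# quant tables

_MANDATORY = ("accession", "q_value", "n_peptides", "n_psms")


def _abundance_column(specimen_id: str) -> str:
    return f"Abundance: {specimen_id}"


def _parse_abundance(cell: str) -> Optional[float]:
    cell = cell.strip()
    if not cell:
        return None
    try:
        value = float(cell)
    except ValueError:
        return None  # unparseable cells become MISSING
    return value


def read_quant_table(
    source: IO[str], design: Sequence[SpecimenDesign]
) -> GroupDataset:
    """Parse a tab-separated quantification table into a :class:`GroupDataset`.

    ``design`` supplies the specimen roster (all rows must share one
    batch); one ``Abundance: <specimen_id>`` column is required per
    specimen.  Empty or unparseable abundance cells become missing
    values.  Column order is irrelevant.
    """
    design = list(design)
    if not design:
        raise ValidationError("design must list at least one specimen")
    batches = {d.batch for d in design}
    if len(batches) != 1:
        raise ValidationError(f"design spans multiple batches: {sorted(batches)}")
    batch = design[0].batch

    header_line = source.readline()
    if not header_line:
        raise FormatError("empty quantification table")
    header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
    col = {name: i for i, name in enumerate(header)}
    missing_cols = [c for c in _MANDATORY if c not in col]
    for d in design:
        if _abundance_column(d.specimen_id) not in col:
            missing_cols.append(_abundance_column(d.specimen_id))
    if missing_cols:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing_cols)}")

    def cell(fields: list[str], name: str) -> str:
        i = col.get(name)
        if i is None or i >= len(fields):
            return ""
        return fields[i].strip()

    protein_rows: list[dict] = []
    peptide_rows: dict[str, dict[str, dict[str, Optional[float]]]] = {}
    for lineno, line in enumerate(source, start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        accession = cell(fields, "accession")
        if not accession:
            raise FormatError(f"line {lineno}: missing accession")
        abundances = {
            d.specimen_id: _parse_abundance(
                cell(fields, _abundance_column(d.specimen_id))
            )
            for d in design
        }
        peptide_id = cell(fields, "peptide_id") if "peptide_id" in col else ""
        if peptide_id:
            peptide_rows.setdefault(accession, {})[peptide_id] = abundances
            continue
        try:
            q_value = float(cell(fields, "q_value"))
            n_peptides = int(cell(fields, "n_peptides"))
            n_psms = int(cell(fields, "n_psms"))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        protein_rows.append(
            dict(
                accession=accession,
                gene=cell(fields, "gene") or None,
                description=cell(fields, "description"),
                q_value=q_value,
                n_peptides=n_peptides,
                n_psms=n_psms,
                abundances=abundances,
            )
        )

    records = []
    for row in protein_rows:
        peptides = peptide_rows.pop(row["accession"], None)
        records.append(QuantRecord(peptide_abundances=peptides, **row))
    if peptide_rows:
        orphans = sorted(peptide_rows)
        raise FormatError(f"peptide rows for unknown accession(s): {orphans}")
    return GroupDataset(batch=batch, records=records, design=design)


def write_quant_table(dataset: GroupDataset, sink: IO[str]) -> None:
    """Emit the dialect accepted by :func:`read_quant_table`."""
    sids = dataset.specimen_ids
    header = (
        ["accession", "gene", "description", "q_value", "n_peptides", "n_psms",
         "peptide_id"]
        + [_abundance_column(s) for s in sids]
    )
    sink.write("\t".join(header) + "\n")

    def fmt(value: Optional[float]) -> str:
        return "" if value is None else repr(float(value))

    for rec in dataset.records:
        row = [
            rec.accession,
            rec.gene or "",
            rec.description,
            repr(float(rec.q_value)),
            str(rec.n_peptides),
            str(rec.n_psms),
            "",
        ] + [fmt(rec.abundances.get(s)) for s in sids]
        sink.write("\t".join(row) + "\n")
        if rec.peptide_abundances:
            for pid in rec.peptide_abundances:
                per_spec = rec.peptide_abundances[pid]
                row = [rec.accession, "", "", "", "", "", pid] + [
                    fmt(per_spec.get(s)) for s in sids
                ]
                sink.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# specimen design tables

_DESIGN_COLUMNS = ("specimen_id", "batch", "arm", "litter_id", "sex")


def read_design(source: IO[str]) -> list[SpecimenDesign]:
    """Read a tab-separated specimen design table."""
    header_line = source.readline()
    if not header_line:
        raise FormatError("empty design table")
    header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
    col = {name: i for i, name in enumerate(header)}
    for required in ("specimen_id", "batch", "arm"):
        if required not in col:
            raise FormatError(f"missing mandatory column(s): {required}")
    rows = []
    seen: set[str] = set()
    for lineno, line in enumerate(source, start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")

        def cell(name: str) -> str:
            i = col.get(name)
            return fields[i].strip() if i is not None and i < len(fields) else ""

        sid = cell("specimen_id")
        if sid in seen:
            raise DuplicateRecordError(f"line {lineno}: duplicate specimen {sid}")
        seen.add(sid)
        rows.append(
            SpecimenDesign(
                specimen_id=sid,
                batch=cell("batch"),
                arm=cell("arm"),
                litter_id=cell("litter_id"),
                sex=cell("sex") or None,
            )
        )
    return rows


def write_design(design: Sequence[SpecimenDesign], sink: IO[str]) -> None:
    sink.write("\t".join(_DESIGN_COLUMNS) + "\n")
    for d in design:
        sink.write(
            "\t".join([d.specimen_id, d.batch, d.arm, d.litter_id, d.sex or ""])
            + "\n"
        )


# ---------------------------------------------------------------------------
# GMT pathway sets


def read_gmt(source: IO[str]) -> list[PathwaySet]:
    """Parse GMT lines ``id TAB name TAB member TAB member ...``.

    Duplicate members within a line are silently deduplicated, so the
    pathway size K always equals the member-set cardinality.
    """
    pathways = []
    for lineno, line in enumerate(source, start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.rstrip("\n").split("\t")]
        if len(fields) < 3:
            raise FormatError(
                f"line {lineno}: GMT line needs id, name and >=1 member "
                f"(got {len(fields)} fields)"
            )
        members = frozenset(m for m in fields[2:] if m)
        pathways.append(PathwaySet(fields[0], fields[1], members))
    return pathways


def write_gmt(pathways: Iterable[PathwaySet], sink: IO[str]) -> None:
    for pw in pathways:
        sink.write(
            "\t".join([pw.pathway_id, pw.name] + sorted(pw.members)) + "\n"
        )


# ---------------------------------------------------------------------------
# landmark fiducial files

_FCSV_LABEL_COLUMN = 11


def read_landmarks(
    source: IO[str],
    specimen_id: str = "",
    role: Optional[str] = None,
) -> LandmarkSet:
    """Read a 3D-Slicer-style fiducial CSV.

    Lines starting with ``#`` are comments; data rows are comma
    separated with the point id first, x/y/z in columns 2-4 and (when
    present) the label in column 12.  ``role`` may be given explicitly;
    otherwise it is inferred from the landmark count (2 -> skull,
    25 -> molar).
    """
    landmarks: list[tuple[str, float, float, float]] = []
    for lineno, line in enumerate(source, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = [f.strip() for f in stripped.split(",")]
        if len(fields) < 4:
            raise FormatError(f"line {lineno}: need id,x,y,z columns")
        try:
            x, y, z = (float(fields[i]) for i in (1, 2, 3))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric coordinate") from exc
        label = ""
        if len(fields) > _FCSV_LABEL_COLUMN:
            label = fields[_FCSV_LABEL_COLUMN]
        landmarks.append((label or fields[0], x, y, z))
    if not landmarks:
        raise FormatError("landmark file holds no data rows")
    if role is None:
        by_count = {count: name for name, count in LANDMARK_ROLES.items()}
        role = by_count.get(len(landmarks))
        if role is None:
            raise ValidationError(
                f"cannot infer role from {len(landmarks)} landmarks; "
                "pass role explicitly"
            )
    return LandmarkSet(specimen_id=specimen_id, landmarks=tuple(landmarks), role=role)


def write_landmarks(lm: LandmarkSet, sink: IO[str]) -> None:
    """Write a minimal Slicer-compatible fiducial CSV."""
    sink.write("# Markups fiducial file version = 4.11\n")
    sink.write("# CoordinateSystem = LPS\n")
    sink.write(
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n"
    )
    for i, (label, x, y, z) in enumerate(lm.landmarks, start=1):
        sink.write(
            f"F_{i},{x!r},{y!r},{z!r},0,0,0,1,1,1,0,{label},,\n"
        )
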