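"""Template registry: shared domain types, TSV loading/validation, filtering.

The registry is a flat tab-separated table with one row per PDB entry
(sequence and seven-helix transmembrane definition inline), replacing any
external spreadsheet or database dependency.  All sequence coordinates in the
public API are 1-based inclusive; conversion to Python slices happens only
inside function bodies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger("gpcrsel")

N_HELICES = 7
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
GPCR_CLASSES = ("A", "B1", "B2", "C", "D", "E", "F", "unknown")
STATES = ("inactive", "active", "intermediate")

#: Canonical class A orthosteric-pocket positions in Ballesteros-Weinstein
#: numbering (helix.offset, where offset 50 is the most conserved residue).
DEFAULT_HOTSPOT_LABELS = (
    "3.28", "3.29", "3.32", "3.33", "3.36", "3.37",
    "4.52",
    "5.39", "5.40", "5.43", "5.44", "5.47", "5.53",
    "6.44", "6.48", "6.51", "6.52", "6.55", "6.58",
    "7.31", "7.34", "7.38", "7.41", "7.42",
)

#: Registry TSV column order (header required, tab-separated).
REGISTRY_COLUMNS = (
    "receptor_id", "receptor_name", "class", "pdb_id",
    "resolution", "state", "coverage", "sequence",
) + tuple(
    f"tm{k}_{part}" for k in range(1, N_HELICES + 1)
    for part in ("start", "end", "center")
)


class RegistryError(ValueError):
    """Raised for malformed registry files or invalid records."""


# ---------------------------------------------------------------------------
# Hydrophobicity scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydrophobicityScale:
    """Per-residue hydrophobicity values (Eisenberg consensus units).

    Lookups of non-standard one-letter codes (X, B, Z, U, ...) return the
    scale mean and log a warning, so engineered constructs do not abort a
    whole comparison.
    """

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_RESIDUES):
            missing = set(STANDARD_RESIDUES) - set(self.values)
            extra = set(self.values) - set(STANDARD_RESIDUES)
            raise RegistryError(
                f"scale {self.name!r} must define exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )

    @property
    def mean(self) -> float:
        return sum(self.values.values()) / len(self.values)

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            logger.warning(
                "scale %s: non-standard residue %r mapped to scale mean",
                self.name, residue,
            )
            return self.mean


def load_scale(path: Optional[Union[str, Path]] = None) -> HydrophobicityScale:
    """Load a two-column (residue, value) TSV; default is the packaged
    Eisenberg consensus scale."""
    if path is None:
        ref = resources.files("gpcrsel.data") / "eisenberg.tsv"
        with resources.as_file(ref) as p:
            return load_scale(p)
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"residue": str, "value": float})
    if list(df.columns) != ["residue", "value"]:
        raise RegistryError(
            f"{path}: expected columns ['residue', 'value'], got {list(df.columns)}"
        )
    return HydrophobicityScale(
        name=path.stem, values=dict(zip(df["residue"], df["value"]))
    )


# ---------------------------------------------------------------------------
# Substitution matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric amino-acid substitution score table.

    Scores for pairs involving a residue outside the 20 standard codes are 0
    by policy (engineering artifacts should not dominate hotspot sums).
    """

    name: str
    scores: Mapping[tuple, float]

    def __post_init__(self) -> None:
        for a in STANDARD_RESIDUES:
            for b in STANDARD_RESIDUES:
                if (a, b) not in self.scores:
                    raise RegistryError(
                        f"matrix {self.name!r} lacks pair ({a}, {b})"
                    )
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise RegistryError(
                        f"matrix {self.name!r} asymmetric at ({a}, {b})"
                    )

    def score(self, a: str, b: str) -> float:
        if a not in STANDARD_RESIDUES or b not in STANDARD_RESIDUES:
            return 0.0
        return self.scores[(a, b)]


def unit_matrix() -> SubstitutionMatrix:
    """Identity-count matrix: 1 on the diagonal, 0 elsewhere."""
    scores = {
        (a, b): (1.0 if a == b else 0.0)
        for a in STANDARD_RESIDUES for b in STANDARD_RESIDUES
    }
    return SubstitutionMatrix(name="unit", scores=scores)


def load_matrix(
    path: Optional[Union[str, Path]] = None, name: str = "BLOSUM62"
) -> SubstitutionMatrix:
    """Load a substitution matrix.

    With ``path``, parse a square NCBI-style matrix text file (header row and
    column of residue letters); this is the hook for matrices transcribed from
    the literature, e.g. the GPCRtm matrix derived from class A transmembrane
    regions.  Without a path, load one of biopython's named matrices
    (default BLOSUM62).
    """
    from Bio.Align import substitution_matrices

    if path is not None:
        arr = substitution_matrices.read(str(path))
        label = Path(path).stem
    else:
        arr = substitution_matrices.load(name)
        label = name
    scores = {}
    alphabet = arr.alphabet
    for a in alphabet:
        for b in alphabet:
            scores[(a, b)] = float(arr[a, b])
    return SubstitutionMatrix(name=label, scores=scores)


# ---------------------------------------------------------------------------
# Sequences and TM definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TMDefinition:
    """Seven (start, end, center) triples, 1-based inclusive, one per helix.

    ``center`` of helix k is the residue numbered k.50 in the
    Ballesteros-Weinstein scheme; helices are ordered and non-overlapping.
    """

    helices: tuple  # 7 x (start, end, center)

    def __post_init__(self) -> None:
        if len(self.helices) != N_HELICES:
            raise RegistryError(
                f"expected {N_HELICES} helices, got {len(self.helices)}"
            )
        prev_end = 0
        for k, (s, e, c) in enumerate(self.helices, start=1):
            if not (1 <= s <= c <= e):
                raise RegistryError(
                    f"tm{k}: require start <= center <= end, got ({s}, {e}, {c})"
                )
            if s <= prev_end:
                raise RegistryError(
                    f"tm{k}: overlaps previous helix (start {s} <= end {prev_end})"
                )
            prev_end = e

    def span(self, k: int) -> tuple:
        """(start, end, center) of helix k in 1..7."""
        return self.helices[k - 1]

    def start(self, k: int) -> int:
        return self.helices[k - 1][0]

    def end(self, k: int) -> int:
        return self.helices[k - 1][1]

    def center(self, k: int) -> int:
        return self.helices[k - 1][2]

    def validate_against(self, sequence: str) -> None:
        if self.helices[-1][1] > len(sequence):
            raise RegistryError(
                f"tm7 end {self.helices[-1][1]} exceeds sequence length "
                f"{len(sequence)}"
            )


@dataclass(frozen=True)
class GPCRSequence:
    """A receptor sequence with its seven-helix TM annotation."""

    id: str
    name: str
    gpcr_class: str
    sequence: str
    tm: TMDefinition

    def __post_init__(self) -> None:
        if not self.sequence:
            raise RegistryError(f"{self.id}: empty sequence")
        if self.gpcr_class not in GPCR_CLASSES:
            raise RegistryError(
                f"{self.id}: unknown class {self.gpcr_class!r}"
            )
        self.tm.validate_against(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, i: int) -> str:
        """Residue at 1-based position i."""
        return self.sequence[i - 1]


@dataclass(frozen=True)
class TemplateRecord:
    """One candidate template structure (a PDB entry of some receptor)."""

    receptor: GPCRSequence
    pdb_id: str
    resolution: Optional[float]  # Angstrom; None when not reported
    state: str
    coverage: float  # percent of receptor positions resolved, 0-100

    def __post_init__(self) -> None:
        if len(self.pdb_id) != 4:
            raise RegistryError(f"pdb_id {self.pdb_id!r} is not a 4-char code")
        if self.state not in STATES:
            raise RegistryError(
                f"{self.pdb_id}: unknown state {self.state!r}"
            )
        if self.resolution is not None and self.resolution <= 0:
            raise RegistryError(
                f"{self.pdb_id}: non-positive resolution {self.resolution}"
            )
        if not 0 <= self.coverage <= 100:
            raise RegistryError(
                f"{self.pdb_id}: coverage {self.coverage} outside [0, 100]"
            )


# ---------------------------------------------------------------------------
# Ballesteros-Weinstein label resolution
# ---------------------------------------------------------------------------

def parse_bw_label(label: str) -> tuple:
    """Split 'k.NN' into (helix, offset); raises on anything unparseable."""
    try:
        helix_str, off_str = label.split(".")
        helix, offset = int(helix_str), int(off_str)
    except (ValueError, AttributeError) as exc:
        raise RegistryError(f"unparseable BW label {label!r}") from exc
    if not 1 <= helix <= N_HELICES:
        raise RegistryError(f"BW label {label!r}: helix outside 1..7")
    return helix, offset


def bw_to_index(
    tm: TMDefinition, label: str, seq_length: Optional[int] = None
) -> Optional[int]:
    """Resolve a Ballesteros-Weinstein label to a 1-based sequence index.

    Position k.NN sits at center_k + (NN - 50).  Labels may resolve outside
    the annotated helix span (7.31 commonly precedes the TM7 annotation);
    only indices outside [1, seq_length] return None.
    """
    helix, offset = parse_bw_label(label)
    idx = tm.center(helix) + (offset - 50)
    if idx < 1:
        return None
    if seq_length is not None and idx > seq_length:
        return None
    return idx


# ---------------------------------------------------------------------------
# Registry I/O and filtering
# ---------------------------------------------------------------------------

def _record_from_row(row: Mapping[str, str], rownum: int) -> TemplateRecord:
    try:
        helices = tuple(
            (int(row[f"tm{k}_start"]), int(row[f"tm{k}_end"]),
             int(row[f"tm{k}_center"]))
            for k in range(1, N_HELICES + 1)
        )
    except ValueError as exc:
        raise RegistryError(f"row {rownum}: non-integer TM index ({exc})") from exc
    try:
        tm = TMDefinition(helices)
        receptor = GPCRSequence(
            id=row["receptor_id"],
            name=row["receptor_name"],
            gpcr_class=row["class"],
            sequence=row["sequence"],
            tm=tm,
        )
        res_cell = str(row["resolution"]).strip()
        resolution = float(res_cell) if res_cell else None
        return TemplateRecord(
            receptor=receptor,
            pdb_id=row["pdb_id"],
            resolution=resolution,
            state=row["state"],
            coverage=float(row["coverage"]),
        )
    except RegistryError as exc:
        raise RegistryError(f"row {rownum}: {exc}") from exc


def load_registry(
    path: Union[str, Path], strict: bool = True
) -> list:
    """Read a registry TSV into TemplateRecords, preserving row order.

    strict: any invalid row raises (with its row number); lenient: invalid
    rows are skipped with a logged warning.  pdb_id must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"registry file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != REGISTRY_COLUMNS:
        raise RegistryError(
            f"{path}: malformed header; expected {list(REGISTRY_COLUMNS)}"
        )
    records = []
    seen_pdb = set()
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            rec = _record_from_row(row, i)
            if rec.pdb_id in seen_pdb:
                raise RegistryError(f"row {i}: duplicate pdb_id {rec.pdb_id}")
        except RegistryError as exc:
            if strict:
                raise
            logger.warning("skipping invalid registry row: %s", exc)
            continue
        seen_pdb.add(rec.pdb_id)
        records.append(rec)
    return records


def write_registry(records: Iterable[TemplateRecord], path: Union[str, Path]) -> None:
    """Write TemplateRecords back to the TSV schema (round-trip exact for
    valid files)."""
    rows = []
    for rec in records:
        row = {
            "receptor_id": rec.receptor.id,
            "receptor_name": rec.receptor.name,
            "class": rec.receptor.gpcr_class,
            "pdb_id": rec.pdb_id,
            "resolution": "" if rec.resolution is None else _fmt_num(rec.resolution),
            "state": rec.state,
            "coverage": _fmt_num(rec.coverage),
            "sequence": rec.receptor.sequence,
        }
        for k in range(1, N_HELICES + 1):
            s, e, c = rec.receptor.tm.span(k)
            row[f"tm{k}_start"], row[f"tm{k}_end"], row[f"tm{k}_center"] = s, e, c
        rows.append(row)
    pd.DataFrame(rows, columns=list(REGISTRY_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def _fmt_num(x: float) -> str:
    """Render 2.0 as '2', 2.25 as '2.25' (keeps TSV round-trips tidy)."""
    return f"{x:g}"


def filter_templates(
    records: Sequence[TemplateRecord],
    state: Optional[str] = None,
    max_resolution: Optional[float] = None,
    min_coverage: Optional[float] = None,
) -> list:
    """Apply the search-mode shortlist predicates, preserving order.

    max_resolution is inclusive (a 2.5 A structure passes a 2.5 A cut) and
    excludes records lacking a resolution value; min_coverage is exclusive
    (coverage must be strictly greater, matching the >75% completeness rule).
    """
    out = []
    for rec in records:
        if state is not None and rec.state != state:
            continue
        if max_resolution is not None and (
            rec.resolution is None or rec.resolution > max_resolution
        ):
            continue
        if min_coverage is not None and not rec.coverage > min_coverage:
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Query-side loaders (FASTA + sidecar TM definition)
# ---------------------------------------------------------------------------

TM_SIDECAR_COLUMNS = REGISTRY_COLUMNS[8:]  # tm1_start .. tm7_center


def load_tm_sidecar(path: Union[str, Path]) -> TMDefinition:
    """Read a single-row TSV with tm1_start..tm7_center columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != TM_SIDECAR_COLUMNS:
        raise RegistryError(
            f"{path}: expected columns {list(TM_SIDECAR_COLUMNS)}"
        )
    if len(df) != 1:
        raise RegistryError(f"{path}: expected exactly one row, got {len(df)}")
    row = df.iloc[0]
    try:
        helices = tuple(
            (int(row[f"tm{k}_start"]), int(row[f"tm{k}_end"]),
             int(row[f"tm{k}_center"]))
            for k in range(1, N_HELICES + 1)
        )
    except ValueError as exc:
        raise RegistryError(f"{path}: non-integer TM index ({exc})") from exc
    return TMDefinition(helices)


def load_query(
    fasta_path: Union[str, Path], tm_path: Union[str, Path],
    gpcr_class: str = "unknown",
) -> GPCRSequence:
    """Load a query as the first FASTA record plus its sidecar TM TSV."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise RegistryError(f"{fasta_path}: no FASTA records")
    rec = records[0]
    return GPCRSequence(
        id=rec.id,
        name=rec.description,
        gpcr_class=gpcr_class,
        sequence=str(rec.seq).upper(),
        tm=load_tm_sidecar(tm_path),
    )
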