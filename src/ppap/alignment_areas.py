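"""Sequences, alignments and reference-anchored segments ("Areas").

Plant type III polyketide synthases are classified here by a three-part
reaction-type label (starter substrate - extension count - cyclization
mechanism, e.g. ``R-4-C`` for chalcone synthases).  Prediction relies on
four short protein segments, Areas 1-4, whose 3D structure differs between
the Claisen- and aldol-cyclizing enzymes.  This module provides:

* FASTA / aligned-FASTA reading with alphabet normalization,
* :class:`AreaMap` — 1-based inclusive residue ranges on a reference
  sequence — and its projection onto alignment columns,
* extraction and concatenation of Area segments,
* gap-based column filtering for correlated mutation analysis, and
* addition of a query sequence to an existing alignment (external aligner
  adapter with a built-in profile-alignment fallback).
"""

from __future__ import annotations

import json
import logging
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

_SEQ_ALPHABET = frozenset(AA20 + UNKNOWN)
_ALN_ALPHABET = frozenset(AA20 + UNKNOWN + GAP)
#: Non-standard one-letter codes mapped to 'X' (unknown) at read time.
AMBIGUOUS_RESIDUES = "BZUJO"


class MissingExternalToolError(RuntimeError):
    """An external command-line tool required for this operation is absent."""


def normalize_residues(raw: str, *, allow_gap: bool = False, seq_id: str = "?") -> str:
    """Uppercase, map ambiguous codes (B/Z/U/J/O) to 'X', validate alphabet.

    ``.`` is accepted as a gap alias in aligned input; a trailing ``*``
    (stop) is stripped.
    """
    s = raw.upper().rstrip("*")
    if allow_gap:
        s = s.replace(".", GAP)
    hit = set(s) & set(AMBIGUOUS_RESIDUES)
    if hit:
        logger.warning(
            "sequence %s: non-standard residue(s) %s mapped to 'X'",
            seq_id, "".join(sorted(hit)),
        )
        s = s.translate(str.maketrans({c: UNKNOWN for c in AMBIGUOUS_RESIDUES}))
    allowed = _ALN_ALPHABET if allow_gap else _SEQ_ALPHABET
    bad = set(s) - allowed
    if bad:
        raise ValueError(
            f"sequence {seq_id!r} contains invalid symbol(s): {''.join(sorted(bad))}"
        )
    return s


@dataclass(frozen=True)
class ProteinSequence:
    """An ungapped protein sequence over the 20 standard residues plus 'X'."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid symbol(s): "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# Reaction-type labels
# ---------------------------------------------------------------------------

_STARTER = r"[RSL][bchn]?"
_EXTENSION = r"\d+[mead]?"
_CYCLIZATION = r"[LCAXn+]{1,2}"
_LABEL_RE = re.compile(
    rf"^(?P<starter>{_STARTER}|\*)-(?P<extension>{_EXTENSION}|\*)"
    rf"-(?P<cyclization>{_CYCLIZATION}|\*)$"
)


@dataclass(frozen=True, order=True)
class ReactionTypeLabel:
    """Three-element reaction-type identifier, e.g. ``R-4-C``.

    * starter: ring (R), short chain (S) or long chain (L), with an optional
      specific acyl-group suffix (b: branched, c: carboxyl, h: hydroxyl,
      n: nitrogen);
    * extension: number of methylenecarbonyl units in the intermediate, with
      an optional unusual-extender suffix (m/e/a/d);
    * cyclization: lactone (L), Claisen (C), aldol (A), none (X),
      nitrogen-carbon (n) or miscellaneous (+); compound mechanisms such as
      ``AL`` or ``Cn`` are accepted.

    ``*`` wildcards are allowed only when ``allow_wildcard`` is passed to
    :meth:`parse` (grouping contexts such as ``S-*-*``).
    """

    starter: str
    extension: str
    cyclization: str

    @classmethod
    def parse(cls, text: str, *, allow_wildcard: bool = False) -> "ReactionTypeLabel":
        m = _LABEL_RE.match(text)
        if m is None:
            raise ValueError(f"invalid reaction-type label: {text!r}")
        parts = m.groupdict()
        if not allow_wildcard and "*" in parts.values():
            raise ValueError(f"wildcard not allowed in concrete label: {text!r}")
        return cls(parts["starter"], parts["extension"], parts["cyclization"])

    def matches(self, other: "ReactionTypeLabel | str") -> bool:
        """Wildcard-aware comparison (either side may carry ``*``)."""
        if isinstance(other, str):
            other = ReactionTypeLabel.parse(other, allow_wildcard=True)
        return all(
            a == b or "*" in (a, b)
            for a, b in (
                (self.starter, other.starter),
                (self.extension, other.extension),
                (self.cyclization, other.cyclization),
            )
        )

    def __str__(self) -> str:
        return f"{self.starter}-{self.extension}-{self.cyclization}"


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """Rows of equal-length gapped protein sequences with unique ids."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    family_label: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(
                    f"ragged alignment: row {sid!r} has length {len(row)}, "
                    f"expected {width}"
                )
        if width == 0:
            raise ValueError("alignment has zero columns")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def index(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def row(self, seq_id: str) -> str:
        return self.rows[self.index(seq_id)]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.ids

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def gap_fractions(self) -> list[float]:
        n = self.n_rows
        return [self.column(j).count(GAP) / n for j in range(self.n_cols)]

    def subset(self, ids: Sequence[str], family_label: str | None = None) -> "Alignment":
        """Row subset in the given order; columns are untouched."""
        return Alignment(
            ids=tuple(ids),
            rows=tuple(self.row(i) for i in ids),
            family_label=family_label if family_label is not None else self.family_label,
        )

    def drop(self, seq_id: str) -> "Alignment":
        i = self.index(seq_id)
        return Alignment(
            ids=self.ids[:i] + self.ids[i + 1:],
            rows=self.rows[:i] + self.rows[i + 1:],
            family_label=self.family_label,
        )

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        for c in columns:
            if not 0 <= c < self.n_cols:
                raise ValueError(f"column index {c} out of range (n_cols={self.n_cols})")
        return Alignment(
            ids=self.ids,
            rows=tuple("".join(row[c] for c in columns) for row in self.rows),
            family_label=self.family_label,
        )

    def sequences(self) -> list[ProteinSequence]:
        """Degapped rows as plain sequences."""
        return [
            ProteinSequence(sid, row.replace(GAP, ""))
            for sid, row in zip(self.ids, self.rows)
        ]

    @classmethod
    def from_fasta(cls, path: str | Path, family_label: str | None = None) -> "Alignment":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(normalize_residues(str(rec.seq), allow_gap=True, seq_id=rec.id))
        if not ids:
            raise ValueError(f"no FASTA records in {path}")
        return cls(ids=tuple(ids), rows=tuple(rows), family_label=family_label)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


def read_sequences(path: str | Path, format: str = "fasta"):
    """Read FASTA input.

    ``format="fasta"`` returns a list of :class:`ProteinSequence` (gaps, if
    any, are stripped with a warning).  ``format="aligned-fasta"`` returns an
    :class:`Alignment` and raises on ragged rows, naming the offending id.
    """
    if format == "aligned-fasta":
        return Alignment.from_fasta(path)
    if format != "fasta":
        raise ValueError(f"unknown format {format!r}")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = normalize_residues(str(rec.seq), allow_gap=True, seq_id=rec.id)
        if GAP in s:
            logger.warning("sequence %s: gaps stripped from unaligned input", rec.id)
            s = s.replace(GAP, "")
        out.append(ProteinSequence(rec.id, s, rec.description))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


# ---------------------------------------------------------------------------
# Area maps and column bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AreaSegment:
    """1-based inclusive residue range on the reference sequence."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid segment {self.name}: [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AreaMap:
    """Ordered, non-overlapping reference-anchored segment definitions."""

    reference_id: str
    segments: tuple[AreaSegment, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate area names in AreaMap")
        prev_end = 0
        for seg in self.segments:
            if seg.start <= prev_end:
                raise ValueError(
                    f"area {seg.name} overlaps or is out of order "
                    f"(starts at {seg.start}, previous ends at {prev_end})"
                )
            prev_end = seg.end

    @property
    def area_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.segments)

    def to_dict(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "segments": [
                {"name": s.name, "start": s.start, "end": s.end} for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AreaMap":
        return cls(
            reference_id=d["reference_id"],
            segments=tuple(
                AreaSegment(s["name"], int(s["start"]), int(s["end"]))
                for s in d["segments"]
            ),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AreaMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ColumnIndexSet:
    """Per-area ordered 0-based alignment-column indices."""

    columns: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        for name, cols in self.columns.items():
            if any(b <= a for a, b in zip(cols, cols[1:])):
                raise ValueError(f"columns for area {name} not strictly ascending")

    @property
    def area_names(self) -> tuple[str, ...]:
        return tuple(self.columns.keys())

    def combined(self, area_names: Sequence[str]) -> tuple[int, ...]:
        """Concatenated column indices for the selected areas, in area order."""
        out: list[int] = []
        for name in area_names:
            if name not in self.columns:
                raise ValueError(f"unknown area name {name!r}")
            out.extend(self.columns[name])
        return tuple(out)


def map_reference_positions(alignment: Alignment, area_map: AreaMap) -> ColumnIndexSet:
    """Translate reference residue ranges into alignment columns.

    Reference gap columns are skipped, so each area's column count equals its
    residue count on the reference.
    """
    ref_row = alignment.row(area_map.reference_id)
    # residue index (1-based) -> alignment column
    pos_to_col: dict[int, int] = {}
    r = 0
    for col, ch in enumerate(ref_row):
        if ch != GAP:
            r += 1
            pos_to_col[r] = col
    columns: dict[str, tuple[int, ...]] = {}
    for seg in area_map.segments:
        if seg.end > r:
            raise ValueError(
                f"area {seg.name} ends at residue {seg.end} but reference "
                f"{area_map.reference_id!r} has only {r} residues"
            )
        columns[seg.name] = tuple(pos_to_col[p] for p in range(seg.start, seg.end + 1))
    return ColumnIndexSet(columns)


def extract_area_segments(
    alignment: Alignment,
    column_index_set: ColumnIndexSet,
    area_names: Sequence[str],
) -> Alignment:
    """Restrict every row to the selected areas' columns, concatenated in order."""
    if not area_names:
        raise ValueError("area_names must be non-empty")
    return alignment.take_columns(column_index_set.combined(area_names))


# ---------------------------------------------------------------------------
# Column filtering for correlated mutation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilteredAlignment:
    """A column-filtered alignment plus the filtered->original column map."""

    alignment: Alignment
    kept_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.kept_columns, self.kept_columns[1:])):
            raise ValueError("kept_columns must be strictly ascending")
        if len(self.kept_columns) != self.alignment.n_cols:
            raise ValueError("kept_columns length must equal filtered column count")

    @property
    def n_cols(self) -> int:
        return self.alignment.n_cols

    def project_row(self, full_row: str) -> str:
        """Restrict a row given in original coordinates to the kept columns."""
        if len(full_row) <= self.kept_columns[-1]:
            raise ValueError(
                f"row of length {len(full_row)} cannot be projected: kept "
                f"columns extend to {self.kept_columns[-1]}"
            )
        return "".join(full_row[c] for c in self.kept_columns)


def filter_columns(
    alignment: Alignment,
    max_gap_fraction: float = 0.8,
    trim_terminal: bool = True,
    terminal_max_gap_fraction: float = 0.0,
) -> FilteredAlignment:
    """Remove terminal gapped columns and highly gapped internal columns.

    Terminal trimming drops columns from each end until the first column
    whose gap fraction is <= ``terminal_max_gap_fraction`` (default 0.0, i.e.
    any terminal column containing a gap is dropped).  Internal columns are
    removed when their gap fraction exceeds ``max_gap_fraction`` (default
    0.8, i.e. >80% gaps).  The operation is idempotent.
    """
    if not 0 < max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    fracs = alignment.gap_fractions()
    n = len(fracs)
    lo, hi = 0, n - 1
    if trim_terminal:
        while lo < n and fracs[lo] > terminal_max_gap_fraction:
            lo += 1
        while hi >= lo and fracs[hi] > terminal_max_gap_fraction:
            hi -= 1
    kept = tuple(j for j in range(lo, hi + 1) if fracs[j] <= max_gap_fraction)
    if not kept:
        raise ValueError("all columns removed by gap filtering")
    return FilteredAlignment(alignment.take_columns(kept), kept)


# ---------------------------------------------------------------------------
# Query addition (external-aligner adapter + fallback)
# ---------------------------------------------------------------------------

def add_query_to_alignment(
    query: ProteinSequence,
    alignment: Alignment,
    method: str = "auto",
) -> Alignment:
    """Align a query onto an existing alignment, preserving row correspondences.

    ``method`` is ``"mafft"`` (external adapter, `mafft --add`), ``"builtin"``
    (profile-to-sequence global alignment with affine gaps, BLOSUM62,
    open 11 / extend 1) or ``"auto"`` (mafft when installed, else builtin).
    Original rows may gain all-gap columns where the query has insertions;
    their mutual residue correspondences are unchanged.
    """
    from . import _aligner  # local import: keeps numpy/Bio.Align off the hot path

    if alignment.n_rows == 0:  # pragma: no cover - Alignment forbids this
        raise ValueError("alignment is empty")
    if method == "auto":
        method = "mafft" if shutil.which("mafft") else "builtin"
    if method == "mafft":
        return _aligner.mafft_add(alignment, query)
    if method == "builtin":
        return _aligner.builtin_add(alignment, query)
    raise ValueError(f"unknown alignment method {method!r}")


def aligned_query_row(
    query: ProteinSequence,
    alignment: Alignment,
    method: str = "auto",
) -> str:
    """The query's gapped row expressed in ``alignment``'s original columns.

    Runs :func:`add_query_to_alignment`, then drops columns newly inserted by
    the aligner (columns in which every original row is a gap), so existing
    model column indices remain valid ("column reconciliation").
    """
    merged = add_query_to_alignment(query, alignment, method=method)
    qrow = merged.rows[-1]
    orig = merged.rows[:-1]
    row = []
    for j in range(merged.n_cols):
        if any(r[j] != GAP for r in orig):
            row.append(qrow[j])
    if len(row) != alignment.n_cols:
        raise ValueError(
            "column reconciliation failed: original alignment has "
            f"{alignment.n_cols} non-empty columns, merged has {len(row)}"
        )
    return "".join(row)


# ---------------------------------------------------------------------------
# Redundancy filtering (data-prep wrapper)
# ---------------------------------------------------------------------------

def cluster_representatives(
    sequences: Sequence[ProteinSequence],
    identity: float = 0.9,
    binary: str = "cd-hit",
) -> list[ProteinSequence]:
    """Thin wrapper around an external CD-HIT-style clusterer.

    Training-set curation keeps within-type sequence identity below 90% by
    clustering and retaining representatives.  This is a documented data-prep
    step delegated to the external tool; it is not re-implemented.
    """
    exe = shutil.which(binary)
    if exe is None:
        raise MissingExternalToolError(
            f"{binary!r} not found on PATH; install CD-HIT or pre-filter the "
            "input and skip redundancy clustering"
        )
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        out = Path(tmp) / "out.fa"
        with open(inp, "w") as fh:
            for s in sequences:
                fh.write(f">{s.id}\n{s.residues}\n")
        subprocess.run(
            [exe, "-i", str(inp), "-o", str(out), "-c", str(identity)],
            check=True, capture_output=True,
        )
        keep = {rec.id for rec in SeqIO.parse(str(out), "fasta")}
    return [s for s in sequences if s.id in keep]
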