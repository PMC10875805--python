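"""Reading substrate sequences and phosphosite tables; 13-mer extraction.

A phosphosite is reported as a (substrate accession, 1-based position)
pair; :func:`centralize` cuts the 13-residue window around it, padding
overhang positions past either protein terminus with ``J`` placeholders.
:func:`build_substrate_sets` joins a site table against a FASTA of
substrate sequences and groups the centered peptides by kinase —
the local stand-in for the UniProt ID-mapping step used when curating
large in-vitro phosphoproteomics tables.

Profile persistence (:func:`write_profiles` / :func:`read_profiles`)
round-trips fitted kinase profiles losslessly through a JSON document.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO

from ._alphabet import (
    ACCEPTORS,
    AMINO_ACIDS,
    HALF_WINDOW,
    PAD,
    WINDOW,
)
from .exceptions import (
    CenterResidueError,
    InvalidPeptideError,
    InvalidSequenceError,
    KinamotifError,
    ProfileStoreError,
    SiteTableError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .motif import KinaseProfile

_CANONICAL = set(AMINO_ACIDS)

PROFILE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ProteinRecord:
    """A substrate protein: UniProt-style accession plus its sequence."""

    accession: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise InvalidSequenceError(self.accession, {"<empty>"})
        bad = set(seq) - _CANONICAL
        if bad:
            raise InvalidSequenceError(self.accession, bad)


@dataclass(frozen=True)
class CenteredPeptide:
    """A 13-residue window with the phosphoacceptor at offset 0.

    ``residues`` covers offsets -6..+6; ``J`` marks positions beyond a
    protein terminus and may appear only as a contiguous prefix and/or
    suffix.  The center must be S, T or Y.
    """

    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        r = self.residues
        if len(r) != WINDOW:
            raise InvalidPeptideError(
                f"peptide {r!r} has length {len(r)}, expected {WINDOW}"
            )
        bad = set(r) - _CANONICAL - {PAD}
        if bad:
            raise InvalidPeptideError(
                f"peptide {r!r} contains invalid characters: {sorted(bad)}"
            )
        if r[HALF_WINDOW] not in ACCEPTORS:
            raise CenterResidueError(r[HALF_WINDOW], context=f"peptide {r!r}")
        core = r.strip(PAD)
        if PAD in core:
            raise InvalidPeptideError(
                f"peptide {r!r}: J placeholders must be a contiguous "
                "prefix and/or suffix"
            )

    def __getitem__(self, offset: int) -> str:
        """Residue at a window offset in -6..+6."""
        return self.residues[offset + HALF_WINDOW]

    @property
    def center(self) -> str:
        return self.residues[HALF_WINDOW]

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class PhosphositeRow:
    """One line of a kinase -> substrate site table.

    Either (accession, position) identifying the site within a substrate
    sequence, or a pre-centralized 13-mer ``peptide`` that bypasses the
    sequence lookup.
    """

    kinase: str
    accession: str | None = None
    position: int | None = None
    peptide: CenteredPeptide | None = None

    def __post_init__(self):
        if self.position is not None and self.position < 1:
            raise SiteTableError(
                f"1-based position must be >= 1, got {self.position} "
                f"(kinase {self.kinase!r})"
            )
        if self.peptide is None and (self.accession is None or self.position is None):
            raise SiteTableError(
                f"row for kinase {self.kinase!r} needs either a peptide or "
                "an (accession, position) pair"
            )


@dataclass
class SubstrateSet:
    """All observed centered peptides for one kinase.

    Duplicates are retained: each observed site counts once per
    observation in the input table.
    """

    kinase: str
    peptides: list[CenteredPeptide] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peptides)


def _accession_from_header(header_token: str) -> str:
    """First whitespace token of a FASTA header; UniProt ``sp|ACC|NAME``
    headers yield the accession field."""
    parts = header_token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_token


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read substrate sequences from a FASTA file.

    Raises on a missing/empty file and on any record whose sequence
    contains characters outside the 20 canonical codes (the error names
    the offending accession).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = _accession_from_header(rec.id)
        records.append(ProteinRecord(accession, str(rec.seq)))
    if not records:
        raise KinamotifError(f"FASTA file {path} contains no records")
    return records


def _sniff_delimiter(path: str | os.PathLike, first_line: str) -> str:
    name = str(path).lower()
    if name.endswith(".tsv") or name.endswith(".tab"):
        return "\t"
    if name.endswith(".csv"):
        return ","
    return "\t" if "\t" in first_line else ","


def read_site_table(path: str | os.PathLike) -> list[PhosphositeRow]:
    """Read a kinase/phosphosite table (TSV or CSV; delimiter sniffed).

    The header must contain either ``kinase, accession, position`` or
    ``kinase, peptide``.  Positions are 1-based integers; peptide fields
    must be valid centered 13-mers.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"site table not found: {path}")
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise SiteTableError(f"site table {path} is empty")
        delim = _sniff_delimiter(path, first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        cols = {c.strip().lower() for c in reader.fieldnames or []}
        by_site = {"kinase", "accession", "position"} <= cols
        by_peptide = {"kinase", "peptide"} <= cols
        if not (by_site or by_peptide):
            raise SiteTableError(
                f"site table {path} must have columns kinase/accession/position "
                f"or kinase/peptide; found {sorted(cols)}"
            )
        rows: list[PhosphositeRow] = []
        for lineno, raw in enumerate(reader, start=2):
            raw = {(k or "").strip().lower(): (v or "").strip() for k, v in raw.items()}
            kinase = raw.get("kinase", "")
            if not kinase:
                raise SiteTableError(f"{path}:{lineno}: empty kinase name")
            if by_peptide and raw.get("peptide"):
                try:
                    pep = CenteredPeptide(raw["peptide"])
                except KinamotifError as exc:
                    raise SiteTableError(f"{path}:{lineno}: {exc}") from exc
                rows.append(PhosphositeRow(kinase=kinase, peptide=pep))
                continue
            try:
                position = int(raw["position"])
            except (KeyError, ValueError) as exc:
                raise SiteTableError(
                    f"{path}:{lineno}: position {raw.get('position')!r} "
                    "is not an integer"
                ) from exc
            try:
                rows.append(
                    PhosphositeRow(
                        kinase=kinase, accession=raw["accession"], position=position
                    )
                )
            except KinamotifError as exc:
                raise SiteTableError(f"{path}:{lineno}: {exc}") from exc
    return rows


def centralize(sequence: str, position: int) -> CenteredPeptide:
    """Cut the 13-mer window centered on a 1-based site position.

    Offsets running past either terminus are padded with ``J``.  The
    residue at the site must be S, T or Y.
    """
    sequence = sequence.upper()
    if not 1 <= position <= len(sequence):
        raise KinamotifError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    center = sequence[position - 1]
    if center not in ACCEPTORS:
        raise CenterResidueError(center, context=f"position {position}")
    chars = []
    for off in range(-HALF_WINDOW, HALF_WINDOW + 1):
        idx = position - 1 + off
        chars.append(sequence[idx] if 0 <= idx < len(sequence) else PAD)
    return CenteredPeptide("".join(chars))


#: skip-reason keys reported by :func:`build_substrate_sets`
SKIP_REASONS = ("unresolved_accession", "position_out_of_range", "center_not_acceptor")


def build_substrate_sets(
    rows: Iterable[PhosphositeRow],
    records: Iterable[ProteinRecord] = (),
) -> tuple[list[SubstrateSet], dict[str, int]]:
    """Group centralized peptides by kinase.

    Rows whose accession is absent from ``records``, whose position lies
    beyond the sequence, or whose site residue is not S/T/Y are dropped
    and tallied in the returned skip summary rather than aborting the
    build — curated tables routinely contain isoform or sequence-version
    mismatches.
    """
    seq_by_acc = {r.accession: r.sequence for r in records}
    sets: dict[str, SubstrateSet] = {}
    skips = {reason: 0 for reason in SKIP_REASONS}
    for row in rows:
        if row.peptide is not None:
            pep = row.peptide
        else:
            seq = seq_by_acc.get(row.accession)
            if seq is None:
                skips["unresolved_accession"] += 1
                continue
            if not 1 <= row.position <= len(seq):
                skips["position_out_of_range"] += 1
                continue
            try:
                pep = centralize(seq, row.position)
            except CenterResidueError:
                skips["center_not_acceptor"] += 1
                continue
        sets.setdefault(row.kinase, SubstrateSet(row.kinase)).peptides.append(pep)
    return list(sets.values()), skips


# ---------------------------------------------------------------------------
# profile store (JSON)
# ---------------------------------------------------------------------------

def write_profiles(profiles: list["KinaseProfile"], path: str | os.PathLike) -> None:
    """Serialize fitted kinase profiles to a JSON profile store.

    The round trip through :func:`read_profiles` is lossless: floats are
    written with full ``repr`` precision so every matrix element is
    reproduced bit-for-bit.
    """
    if not profiles:
        raise KinamotifError("cannot write an empty profile list")
    doc = {
        "format_version": PROFILE_FORMAT_VERSION,
        "alphabet": AMINO_ACIDS,
        "offsets": list(range(-HALF_WINDOW, HALF_WINDOW + 1)),
        "profiles": [p.to_dict() for p in profiles],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_profiles(path: str | os.PathLike) -> list["KinaseProfile"]:
    """Load kinase profiles written by :func:`write_profiles`."""
    from .motif import KinaseProfile  # deferred: motif builds on seqio types

    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ProfileStoreError(f"malformed profile store {path}: {exc}") from exc
    for key in ("format_version", "alphabet", "offsets", "profiles"):
        if key not in doc:
            raise ProfileStoreError(f"profile store {path} missing field {key!r}")
    if doc["alphabet"] != AMINO_ACIDS:
        raise ProfileStoreError(
            f"profile store {path} alphabet {doc['alphabet']!r} differs from "
            f"the canonical order {AMINO_ACIDS!r}"
        )
    if doc["offsets"] != list(range(-HALF_WINDOW, HALF_WINDOW + 1)):
        raise ProfileStoreError(f"profile store {path} has a non-standard offset range")
    return [KinaseProfile.from_dict(d) for d in doc["profiles"]]
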