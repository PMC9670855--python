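"""Sequence and variant I/O: FASTA reading, mutation parsing and application.

Positions are 1-based and inclusive throughout. A sequence carries a
``numbering_offset`` so a domain excised from a larger protein keeps its
full-protein coordinates (e.g. the TDP-43 low-complexity domain can be
loaded as residues 262-414 of UniProt Q13148 without the rest of the
protein).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class SequenceError(ValueError):
    """Raised for invalid sequences or mutation specifications."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with an explicit numbering frame.

    Parameters
    ----------
    id : str
        Record identifier.
    residues : str
        One-letter amino-acid string; only the 20 canonical letters.
    numbering_offset : int
        1-based position of the first residue (default 1).
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        for i, aa in enumerate(self.residues):
            if aa not in _CANONICAL_SET:
                raise SequenceError(
                    f"sequence {self.id!r}: non-canonical residue {aa!r} "
                    f"at position {self.numbering_offset + i}"
                )
        if len(self.residues) < 5:
            raise SequenceError(
                f"sequence {self.id!r}: length {len(self.residues)} < 5 "
                "(smallest scoring region)"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> range:
        """All residue positions in the sequence's numbering frame."""
        return range(self.numbering_offset, self.numbering_offset + len(self))

    def residue_at(self, position: int) -> str:
        """Residue letter at a 1-based position in the numbering frame."""
        idx = position - self.numbering_offset
        if not 0 <= idx < len(self.residues):
            raise SequenceError(
                f"position {position} outside sequence {self.id!r} "
                f"({self.numbering_offset}-{self.numbering_offset + len(self) - 1})"
            )
        return self.residues[idx]


@dataclass(frozen=True)
class MutationSpec:
    """A single missense substitution in the sequence's numbering frame."""

    wt_residue: str
    position: int
    mut_residue: str

    def __post_init__(self) -> None:
        for aa, label in ((self.wt_residue, "wild-type"), (self.mut_residue, "mutant")):
            if aa not in _CANONICAL_SET:
                raise SequenceError(f"{label} residue {aa!r} is not a canonical amino acid")
        if self.wt_residue == self.mut_residue:
            raise SequenceError(
                f"silent substitution {self.wt_residue}{self.position}{self.mut_residue}: "
                "wild-type and mutant residues must differ"
            )

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"


def format_mutations(muts: list[MutationSpec]) -> str:
    """Comma-joined canonical string form, inverse of :func:`parse_mutations`."""
    return ",".join(str(m) for m in muts)


def parse_mutations(spec: str) -> list[MutationSpec]:
    """Parse a comma-separated mutation string such as ``"G294V,A315T"``.

    Each token has the form ``<WT><POS><MUT>``. Duplicate positions are
    rejected: two substitutions at one site cannot both apply.
    """
    if not spec or not spec.strip():
        return []
    out: list[MutationSpec] = []
    seen: set[int] = set()
    for token in spec.split(","):
        token = token.strip()
        m = _MUTATION_RE.match(token)
        if m is None:
            raise SequenceError(f"malformed mutation token {token!r} (expected e.g. 'A315T')")
        wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        if pos in seen:
            raise SequenceError(f"duplicate mutated position {pos} in {spec!r}")
        seen.add(pos)
        out.append(MutationSpec(wt, pos, mut))
    return out


def apply_mutations(seq: ProteinSequence, muts: list[MutationSpec]) -> ProteinSequence:
    """Return a new sequence with the given substitutions applied.

    The wild-type letter of every spec is checked against the sequence; a
    mismatch is an error (it usually means the numbering frame is wrong).
    """
    if not muts:
        return seq
    residues = list(seq.residues)
    for m in muts:
        found = seq.residue_at(m.position)  # raises if out of range
        if found != m.wt_residue:
            raise SequenceError(
                f"wild-type mismatch at position {m.position}: "
                f"spec says {m.wt_residue!r}, sequence has {found!r}"
            )
        residues[m.position - seq.numbering_offset] = m.mut_residue
    return ProteinSequence(
        id=f"{seq.id}_{format_mutations(muts)}",
        residues="".join(residues),
        numbering_offset=seq.numbering_offset,
    )


_OFFSET_RE = re.compile(r"\boffset=(\d+)\b")


def read_fasta(path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file.

    An optional ``offset=N`` token in the header sets the numbering frame
    (``>tdp43_lc offset=262``). Records with non-canonical letters are
    rejected with a diagnostic naming the letter and position.
    """
    sequences = []
    for record in SeqIO.parse(str(path), "fasta"):
        offset = 1
        m = _OFFSET_RE.search(record.description)
        if m:
            offset = int(m.group(1))
        residues = str(record.seq).upper()
        for i, aa in enumerate(residues):
            if aa not in _CANONICAL_SET:
                raise SequenceError(
                    f"record {record.id!r}: non-canonical character {aa!r} "
                    f"at position {offset + i}"
                )
        sequences.append(ProteinSequence(id=record.id, residues=residues, numbering_offset=offset))
    return sequences


def write_fasta(path, sequences: list[ProteinSequence]) -> None:
    """Write sequences as FASTA, recording non-default offsets in the header."""
    with open(path, "w") as fh:
        for seq in sequences:
            header = seq.id
            if seq.numbering_offset != 1:
                header += f" offset={seq.numbering_offset}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i : i + 60] + "\n")


def read_variant_table(path) -> pd.DataFrame:
    """Read a variant CSV with columns ``variant_id``, ``mutations`` and
    optionally ``e_tox`` (measured cytotoxicity change)."""
    df = pd.read_csv(path, dtype={"variant_id": str, "mutations": str})
    missing = {"variant_id", "mutations"} - set(df.columns)
    if missing:
        raise SequenceError(f"variant table {path}: missing columns {sorted(missing)}")
    df["mutations"] = df["mutations"].fillna("")
    return df
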