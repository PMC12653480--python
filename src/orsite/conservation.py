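"""Alignment handling and per-column conservation scoring.

A protein family is held as a gapped multiple alignment with one designated
*reference* sequence (the focal species). Conservation of column *i* is the
frequency of the most common valid residue,

    C_i = max_r count(r in column i) / n_i,

where ``n_i`` counts valid residues only: the gap character ``-`` and the
ambiguity codes ``X``, ``B`` and ``Z`` are excluded from both numerator and
denominator. A column with no valid residue at all is reported with
``C_i = 0`` and an explicit no-data flag so that downstream thresholding can
never select it. Columns are mapped back to 1-based ungapped positions of the
reference sequence, matching the "Thr103"-style coordinates used for
membrane-protein residues.
"""

from __future__ import annotations

import io
import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FormatError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS = "XBZ"
GAP = "-"
ALPHABET = frozenset(AMINO_ACIDS + AMBIGUOUS + GAP)

#: residues that count toward n_i
VALID_RESIDUES = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence, possibly gapped, with a unique identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record has an empty id")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} has no residues")
        residues = self.residues.upper()
        bad = set(residues) - ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains characters outside the "
                f"amino-acid alphabet: {sorted(bad)!r}"
            )
        object.__setattr__(self, "residues", residues)

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)


@dataclass(frozen=True)
class AlignedFamily:
    """A gapped multiple alignment with a designated reference sequence."""

    members: tuple[SequenceRecord, ...]
    reference_id: str

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if len(members) < 2:
            raise ValidationError("an aligned family needs at least 2 members")
        ids = [m.id for m in members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sequence ids: {dupes}")
        lengths = {len(m.residues) for m in members}
        if len(lengths) != 1:
            raise FormatError(
                "aligned sequences must share one length; saw lengths "
                f"{sorted(lengths)}"
            )
        if self.reference_id not in ids:
            raise ValidationError(
                f"reference id {self.reference_id!r} is not a member"
            )
        object.__setattr__(self, "members", members)

    @property
    def length(self) -> int:
        """Number of alignment columns (L)."""
        return len(self.members[0].residues)

    @property
    def reference(self) -> SequenceRecord:
        return next(m for m in self.members if m.id == self.reference_id)

    def column(self, i: int) -> str:
        """Residues of 1-based column *i*, one character per member."""
        if not 1 <= i <= self.length:
            raise ValidationError(f"column {i} outside 1..{self.length}")
        return "".join(m.residues[i - 1] for m in self.members)

    def reference_positions(self) -> list[int | None]:
        """Per column: 1-based ungapped reference position, or None on a gap."""
        out: list[int | None] = []
        pos = 0
        for ch in self.reference.residues:
            if ch == GAP:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out


@dataclass(frozen=True)
class ColumnConservation:
    """Conservation of one alignment column."""

    column: int
    score: float
    n_valid: int
    modal_residue: str | None
    ref_position: int | None
    no_data: bool = False


@dataclass(frozen=True)
class ConservationSummary:
    mean: float
    median: float
    n_high: int
    n_variable: int
    t_var: float
    t_high: float


def read_fasta(
    source: str | Path | io.TextIOBase,
    aligned: bool = False,
    reference_id: str | None = None,
) -> AlignedFamily | list[SequenceRecord]:
    """Read a FASTA file into sequence records.

    With ``aligned=True`` an equal-length check is enforced and an
    :class:`AlignedFamily` is returned; ``reference_id`` defaults to the
    first record. Ids are kept verbatim up to the first whitespace.
    """
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        records = [
            SequenceRecord(id=rec.id, residues=str(rec.seq))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    if not records:
        raise FormatError(f"no FASTA records found in {source!r}")
    if not aligned:
        return records
    if reference_id is None:
        reference_id = records[0].id
    return AlignedFamily(members=tuple(records), reference_id=reference_id)


def write_fasta(
    records: Iterable[SequenceRecord] | AlignedFamily,
    destination: str | Path | io.TextIOBase,
) -> None:
    """Write records to FASTA, 60 residues per line."""
    if isinstance(records, AlignedFamily):
        records = records.members
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="")
        for r in records
    ]
    if isinstance(destination, (str, Path)):
        with open(destination, "w") as fh:
            SeqIO.write(bio, fh, "fasta")
    else:
        SeqIO.write(bio, destination, "fasta")


def conservation_profile(family: AlignedFamily) -> list[ColumnConservation]:
    """Score every alignment column.

    Gaps and ambiguity codes never contribute to the counts; ties for the
    modal residue report the alphabetically first residue so output is
    reproducible.
    """
    ref_positions = family.reference_positions()
    rows = [m.residues for m in family.members]
    profile: list[ColumnConservation] = []
    for i in range(family.length):
        counts = Counter(
            row[i] for row in rows if row[i] in VALID_RESIDUES
        )
        n_valid = sum(counts.values())
        if n_valid == 0:
            profile.append(
                ColumnConservation(
                    column=i + 1,
                    score=0.0,
                    n_valid=0,
                    modal_residue=None,
                    ref_position=ref_positions[i],
                    no_data=True,
                )
            )
            continue
        top = max(counts.values())
        modal = min(r for r, c in counts.items() if c == top)
        profile.append(
            ColumnConservation(
                column=i + 1,
                score=top / n_valid,
                n_valid=n_valid,
                modal_residue=modal,
                ref_position=ref_positions[i],
            )
        )
    return profile


def summarize(
    profile: Sequence[ColumnConservation],
    t_var: float = 0.7,
    t_high: float = 0.9,
) -> ConservationSummary:
    """Mean/median of the profile plus counts of highly conserved
    (``C_i > t_high``) and variable (``C_i <= t_var``) columns."""
    if not profile:
        raise ValidationError("cannot summarize an empty profile")
    if not 0.0 <= t_var <= t_high <= 1.0:
        raise ValidationError(
            f"need 0 <= t_var <= t_high <= 1, got ({t_var}, {t_high})"
        )
    scores = [c.score for c in profile]
    return ConservationSummary(
        mean=statistics.fmean(scores),
        median=statistics.median(scores),
        n_high=sum(s > t_high for s in scores),
        n_variable=sum(s <= t_var for s in scores),
        t_var=t_var,
        t_high=t_high,
    )


def residue_conservation(
    profile: Sequence[ColumnConservation],
) -> dict[int, float]:
    """Map 1-based reference positions to the conservation of their column.

    Columns where the reference is gapped carry no reference position and do
    not appear; every ungapped reference position appears exactly once.
    """
    return {
        c.ref_position: c.score for c in profile if c.ref_position is not None
    }


def reference_residues(family: AlignedFamily) -> dict[int, str]:
    """Map 1-based reference positions to the reference residue letter."""
    out: dict[int, str] = {}
    pos = 0
    for ch in family.reference.residues:
        if ch != GAP:
            pos += 1
            out[pos] = ch
    return out


def profile_to_tsv(
    profile: Sequence[ColumnConservation],
    destination: str | Path | io.TextIOBase,
) -> None:
    """Export the per-column profile as TSV
    (column, ref_position, modal_residue, ni, Ci)."""
    lines = ["column\tref_position\tmodal_residue\tni\tCi"]
    for c in profile:
        lines.append(
            "\t".join(
                [
                    str(c.column),
                    "" if c.ref_position is None else str(c.ref_position),
                    c.modal_residue or "",
                    str(c.n_valid),
                    f"{c.score:.4f}",
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)
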