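"""FASTA sequences and interval annotations.

All coordinates are 0-based half-open everywhere inside the package;
conversion to and from the 1-based inclusive dialect happens only at the
I/O boundary, so off-by-one drift cannot accumulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .regions_eval import RegionSet

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid letters.
AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Standard letters plus the ambiguity/rare codes and the stop symbol.
#: Non-standard letters are kept as literal characters: the method is purely
#: lexical and dropping them would shift every downstream index.
EXTENDED_ALPHABET = AMINO_ALPHABET + "XBZUO*"

_ALLOWED = frozenset(EXTENDED_ALPHABET)


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid string.

    Residues are stored uppercased and must be drawn from the extended
    amino-acid alphabet (20 standard letters plus X, B, Z, U, O, ``*``).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} has no residues")
        res = self.residues.upper()
        bad = set(res) - _ALLOWED
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-amino-acid "
                f"characters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)


class SequenceSet:
    """An ordered collection of :class:`ProteinSequence` with unique ids.

    ``n`` is the number of sequences and ``N`` the total residue length.
    """

    def __init__(self, sequences: Iterable[ProteinSequence] = ()) -> None:
        self._sequences: list[ProteinSequence] = []
        self._by_id: dict[str, ProteinSequence] = {}
        for seq in sequences:
            self.add(seq)

    def add(self, seq: ProteinSequence) -> None:
        if seq.id in self._by_id:
            raise InputError(f"duplicate sequence id {seq.id!r}")
        self._sequences.append(seq)
        self._by_id[seq.id] = seq

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self._sequences)

    def __len__(self) -> int:
        return len(self._sequences)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __getitem__(self, seq_id: str) -> ProteinSequence:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise InputError(f"unknown sequence id {seq_id!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self._sequences == other._sequences

    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self._sequences)

    @property
    def total_length(self) -> int:
        """N — the summed residue length of all member sequences."""
        return sum(len(s) for s in self._sequences)

    def ids(self) -> list[str]:
        return [s.id for s in self._sequences]

    def drop_duplicate_sequences(self) -> "SequenceSet":
        """Return a copy with exact-duplicate residue strings removed.

        Keeps the first occurrence of each distinct residue string. Off by
        default in every pipeline stage; redundancy removal is a dataset
        preparation choice, not part of the method.
        """
        seen: set[str] = set()
        kept = []
        for s in self._sequences:
            if s.residues not in seen:
                seen.add(s.residues)
                kept.append(s)
        if len(kept) < self.n:
            logger.info(
                "removed %d exact-duplicate sequences", self.n - len(kept)
            )
        return SequenceSet(kept)


@dataclass(frozen=True)
class AnnotatedRegion:
    """A labelled interval on a sequence, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid region [{self.start}, {self.end}) on "
                f"{self.seq_id!r}: need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Record order is preserved; residues are uppercased. The first
    whitespace-delimited token of each header is the id. An empty file yields
    an empty set with a logged warning; malformed records and duplicate ids
    raise.
    """
    path = Path(path)
    seqs = SequenceSet()
    try:
        with path.open() as handle:
            for record in SeqIO.parse(handle, "fasta"):
                try:
                    seqs.add(ProteinSequence(record.id, str(record.seq)))
                except FormatError as exc:
                    raise FormatError(
                        f"{path}: malformed record {record.id!r}: {exc}"
                    ) from exc
    except ValueError as exc:
        if isinstance(exc, (FormatError, InputError)):
            raise
        raise FormatError(f"{path}: not valid FASTA: {exc}") from exc
    if seqs.n == 0:
        logger.warning("%s: no FASTA records found", path)
    return seqs


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    """Write sequences as multi-line FASTA (default 60 columns)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with Path(path).open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_annotations(
    path: str | Path,
    seqs: SequenceSet | None = None,
    coords: str = "0-based",
) -> list[AnnotatedRegion]:
    """Read tab-separated interval annotations.

    Columns are ``seq_id``, ``start``, ``end`` and an optional ``label``.
    ``coords`` selects the file's convention: ``"0-based"`` (half-open, the
    default) or ``"1-based"`` (inclusive); either way the result is internal
    0-based half-open. When ``seqs`` is given, regions naming unknown ids or
    exceeding sequence bounds are rejected.
    """
    if coords not in ("0-based", "1-based"):
        raise InputError(f"unknown coordinate convention {coords!r}")
    path = Path(path)
    regions: list[AnnotatedRegion] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            seq_id = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if coords == "1-based":
                start -= 1  # inclusive 1-based -> half-open 0-based
            label = fields[3] if len(fields) > 3 else ""
            if start >= end or start < 0:
                raise InputError(
                    f"{path}:{lineno}: invalid interval "
                    f"[{start}, {end}) after conversion"
                )
            if seqs is not None:
                if seq_id not in seqs:
                    raise InputError(
                        f"{path}:{lineno}: unknown sequence id {seq_id!r}"
                    )
                if end > len(seqs[seq_id]):
                    raise InputError(
                        f"{path}:{lineno}: region end {end} exceeds "
                        f"|{seq_id}| = {len(seqs[seq_id])}"
                    )
            regions.append(AnnotatedRegion(seq_id, start, end, label))
    return regions


def write_annotations(
    regions: Iterable[AnnotatedRegion], path: str | Path
) -> None:
    """Write regions as annotation TSV (0-based half-open, optional label)."""
    with Path(path).open("w") as handle:
        handle.write("#seq_id\tstart\tend\tlabel\n")
        for r in regions:
            handle.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.label}\n")


def write_regions(
    regions: "RegionSet", path: str | Path, format: str = "tsv"
) -> None:
    """Write a predicted :class:`~nadda.regions_eval.RegionSet`.

    ``tsv`` emits 0-based half-open intervals and round-trips exactly through
    :func:`read_annotations`; ``gff3`` emits 1-based inclusive features of
    type ``conserved_region`` with source ``NADDA``.
    """
    path = Path(path)
    if format == "tsv":
        with path.open("w") as handle:
            handle.write("#seq_id\tstart\tend\n")
            for seq_id, start, end in regions.iter_intervals():
                handle.write(f"{seq_id}\t{start}\t{end}\n")
    elif format == "gff3":
        with path.open("w") as handle:
            handle.write("##gff-version 3\n")
            for i, (seq_id, start, end) in enumerate(
                regions.iter_intervals(), start=1
            ):
                handle.write(
                    f"{seq_id}\tNADDA\tconserved_region\t{start + 1}\t{end}"
                    f"\t.\t.\t.\tID=conserved_region_{i}\n"
                )
    else:
        raise InputError(f"unknown region output format {format!r}")
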