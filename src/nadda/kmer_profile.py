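"""Dataset k-mer frequencies and per-sequence k-mer profiles.

The *frequency* of a k-mer is the number of distinct sequences in the dataset
that contain it at least once — never an occurrence count. The *profile* of a
sequence is an integer vector of its own length whose entry at index ``i`` is
the frequency of the k-mer originating at ``i``. Only the first
``|s| - k + 1`` positions originate a k-mer; the trailing ``k - 1`` entries
are set to 0 and ``valid_len`` records where the informative prefix ends.

Serial construction is a two-pass hash procedure: pass one groups
(position, sequence id) occurrences by k-mer, collapsing repeats within one
sequence to a single membership; pass two re-keys by sequence id and lays the
frequencies back down at their originating indices.
:func:`parallel_build_profiles` reproduces the same computation through
explicit map / shuffle / reduce stages over sequence chunks and is
bit-for-bit identical to the serial path for every worker count.
"""

from __future__ import annotations

import logging
import multiprocessing
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, InputError, ParameterError
from .sequence_io import ProteinSequence, SequenceSet

logger = logging.getLogger(__name__)

#: Upper bound on k, to bound hash-table memory (20^12 possible keys is
#: already far beyond what distinct-sequence counting can populate usefully).
MAX_K = 12


@dataclass(frozen=True)
class KmerFrequencyTable:
    """Map from k-mer string to its distinct-sequence frequency."""

    k: int
    counts: Mapping[str, int]

    def __getitem__(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class KmerProfile:
    """Per-sequence vector of k-mer frequencies by originating index."""

    seq_id: str
    values: np.ndarray
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.int64)
        )

    @property
    def valid_len(self) -> int:
        """Number of positions that originate a k-mer: max(|s|-k+1, 0)."""
        return max(len(self.values) - self.k + 1, 0)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerProfile):
            return NotImplemented
        return (
            self.seq_id == other.seq_id
            and self.k == other.k
            and np.array_equal(self.values, other.values)
        )


def _check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ParameterError(f"k must be a positive integer, got {k!r}")
    if k > MAX_K:
        raise ParameterError(f"k={k} exceeds the supported maximum {MAX_K}")


def count_kmer_frequencies(seqs: SequenceSet, k: int) -> KmerFrequencyTable:
    """Count, for every k-mer, the number of sequences containing it.

    Sequences shorter than ``k`` contribute nothing (logged). A k-mer
    occurring several times in one sequence still counts that sequence once.
    """
    _check_k(k)
    counts: dict[str, int] = {}
    n_short = 0
    for seq in seqs:
        res = seq.residues
        if len(res) < k:
            n_short += 1
            continue
        seen = {res[i : i + k] for i in range(len(res) - k + 1)}
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    if n_short:
        logger.info(
            "%d sequence(s) shorter than k=%d contribute no k-mers",
            n_short,
            k,
        )
    return KmerFrequencyTable(k=k, counts=counts)


def build_profiles(
    seqs: SequenceSet, table: KmerFrequencyTable
) -> list[KmerProfile]:
    """Build one profile per sequence, in input order, from ``table``.

    K-mers absent from the table (possible when profiling new sequences
    against a stored table) get frequency 0 with a logged warning.
    """
    k = table.k
    profiles = []
    n_missing = 0
    for seq in seqs:
        res = seq.residues
        values = np.zeros(len(res), dtype=np.int64)
        for i in range(len(res) - k + 1):
            freq = table.counts.get(res[i : i + k])
            if freq is None:
                n_missing += 1
            else:
                values[i] = freq
        profiles.append(KmerProfile(seq_id=seq.id, values=values, k=k))
    if n_missing:
        logger.warning(
            "%d k-mer position(s) absent from the frequency table; "
            "assigned frequency 0",
            n_missing,
        )
    return profiles


# ---------------------------------------------------------------------------
# map / shuffle / reduce profile construction


def _map_chunk(args: tuple[int, list[tuple[str, str]]]):
    """Map stage: emit one (k-mer, seq_id, positions) record per membership.

    Repeated occurrences of a k-mer within one sequence collapse into a
    single record carrying all originating positions.
    """
    k, items = args
    grouped: dict[str, dict[str, list[int]]] = {}
    for sid, res in items:
        for j in range(len(res) - k + 1):
            grouped.setdefault(res[j : j + k], {}).setdefault(sid, []).append(j)
    return [
        (kmer, sid, tuple(pos))
        for kmer, per_seq in grouped.items()
        for sid, pos in per_seq.items()
    ]


def parallel_build_profiles(
    seqs: SequenceSet, k: int, workers: int = 1
) -> list[KmerProfile]:
    """Profile construction via explicit map / shuffle / reduce stages.

    The sequence set is split into ``workers`` contiguous chunks; mappers
    emit k-mer membership records, a shuffle groups them by k-mer, the first
    reduce computes distinct-sequence counts and re-keys by sequence id, and
    the second reduce assembles each profile in position order. The result is
    identical to ``build_profiles(seqs, count_kmer_frequencies(seqs, k))``
    for every worker count.
    """
    _check_k(k)
    if not isinstance(workers, (int, np.integer)) or workers < 1:
        raise ParameterError(f"workers must be >= 1, got {workers!r}")
    items = [(s.id, s.residues) for s in seqs]
    if not items:
        return []
    n_chunks = min(workers, len(items))
    bounds = np.linspace(0, len(items), n_chunks + 1).astype(int)
    chunks = [
        (k, items[bounds[i] : bounds[i + 1]]) for i in range(n_chunks)
    ]
    if n_chunks == 1:
        mapped = [_map_chunk(chunks[0])]
    else:
        ctx = multiprocessing.get_context("fork")
        with ctx.Pool(processes=n_chunks) as pool:
            mapped = pool.map(_map_chunk, chunks)

    # shuffle: group membership records by k-mer
    by_kmer: dict[str, list[tuple[str, tuple[int, ...]]]] = {}
    for records in mapped:
        for kmer, sid, positions in records:
            by_kmer.setdefault(kmer, []).append((sid, positions))

    # reduce 1: frequency = number of distinct sequences; re-key by seq id
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for entries in by_kmer.values():
        freq = len(entries)  # one record per distinct sequence
        for sid, positions in entries:
            by_seq.setdefault(sid, []).extend(
                (pos, freq) for pos in positions
            )

    # reduce 2: order by position and assemble each profile
    profiles = []
    for seq in seqs:
        values = np.zeros(len(seq), dtype=np.int64)
        for pos, freq in by_seq.get(seq.id, ()):
            values[pos] = freq
        profiles.append(KmerProfile(seq_id=seq.id, values=values, k=k))
    return profiles


# ---------------------------------------------------------------------------
# statistics and serialization


@dataclass(frozen=True)
class ProfileStats:
    """Pooled mean and population variance of valid profile entries."""

    mean: float
    variance: float
    n_positions: int


def profile_stats(profiles: Sequence[KmerProfile]) -> ProfileStats:
    """Mean and population variance over all valid positions, pooled.

    Tail zeros (indices at or beyond ``valid_len``) are excluded; with no
    valid positions at all the statistics are undefined and an error is
    raised.
    """
    pooled = [p.values[: p.valid_len] for p in profiles if p.valid_len > 0]
    if not pooled:
        raise InputError(
            "profile statistics are undefined: no valid positions"
        )
    values = np.concatenate(pooled)
    return ProfileStats(
        mean=float(values.mean()),
        variance=float(values.var()),  # population variance
        n_positions=int(values.size),
    )


def write_profiles(
    profiles: Sequence[KmerProfile], path: str | Path
) -> None:
    """Serialize profiles as TSV: header records k; one row per valid position."""
    if not profiles:
        raise InputError("no profiles to write")
    k = profiles[0].k
    with Path(path).open("w") as handle:
        handle.write(f"#k={k}\n")
        handle.write("#seq_id\tindex\tfrequency\n")
        for p in profiles:
            if p.k != k:
                raise InputError("profiles mix different k values")
            if p.valid_len == 0:
                logger.warning(
                    "sequence %s shorter than k=%d: no rows written",
                    p.seq_id,
                    k,
                )
            for i in range(p.valid_len):
                handle.write(f"{p.seq_id}\t{i}\t{p.values[i]}\n")


def read_profiles(path: str | Path) -> list[KmerProfile]:
    """Load profiles written by :func:`write_profiles`."""
    path = Path(path)
    k = None
    per_seq: dict[str, dict[int, int]] = {}
    order: list[str] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line.startswith("#k="):
                k = int(line[3:])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            sid, idx, freq = fields[0], int(fields[1]), int(fields[2])
            if sid not in per_seq:
                per_seq[sid] = {}
                order.append(sid)
            per_seq[sid][idx] = freq
    if k is None:
        raise FormatError(f"{path}: missing '#k=' header")
    profiles = []
    for sid in order:
        entries = per_seq[sid]
        length = max(entries) + k  # valid_len - 1 + k == |s|
        values = np.zeros(length, dtype=np.int64)
        for idx, freq in entries.items():
            values[idx] = freq
        profiles.append(KmerProfile(seq_id=sid, values=values, k=k))
    return profiles


def write_frequency_table(
    table: KmerFrequencyTable, path: str | Path
) -> None:
    """Serialize a frequency table as two-column TSV with a k header."""
    with Path(path).open("w") as handle:
        handle.write(f"#k={table.k}\n")
        handle.write("#kmer\tfrequency\n")
        for kmer in sorted(table.counts):
            handle.write(f"{kmer}\t{table.counts[kmer]}\n")


def read_frequency_table(path: str | Path) -> KmerFrequencyTable:
    """Load a table written by :func:`write_frequency_table`."""
    path = Path(path)
    k = None
    counts: dict[str, int] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line.startswith("#k="):
                k = int(line[3:])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            counts[fields[0]] = int(fields[1])
    if k is None:
        raise FormatError(f"{path}: missing '#k=' header")
    for kmer in counts:
        if len(kmer) != k:
            raise FormatError(
                f"{path}: k-mer {kmer!r} does not have length k={k}"
            )
    return KmerFrequencyTable(k=k, counts=counts)
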