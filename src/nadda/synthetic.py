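"""Synthetic protein families with implanted, mutated domains.

Each family shares one master domain string. Every sequence is random left
flank + a noisy copy of the domain (i.i.d. substitutions at ``mutation_rate``,
replacement drawn from the other letters) + random right flank, with flank
lengths uniform on [flank_len/2, 3*flank_len/2]. This reproduces the
statistical structure the detector exploits: domain k-mers recur across the
family and so carry high dataset frequency, while flank k-mers over a
20-letter alphabet almost never collide between sequences and sit at
frequency ~1. Truth annotations are the exact implanted intervals.

Substitution-only noise (no indels) keeps the conservation signal positional,
matching the exact-k-mer-matching notion of conservation the detector is
built on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .sequence_io import (
    AMINO_ALPHABET,
    AnnotatedRegion,
    ProteinSequence,
    SequenceSet,
)


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a simulated set of protein families.

    n_seqs: sequences per family.
    domain_len: residues in the shared domain.
    flank_len: mean flank length per side; actual lengths are uniform on
        [flank_len/2, 3*flank_len/2].
    mutation_rate: per-residue substitution probability in domain copies.
    n_families: number of distinct master domains.
    domains_per_seq: implanted copies of the family domain per sequence
        (2 exercises region separation).
    """

    n_seqs: int = 200
    domain_len: int = 60
    flank_len: int = 80
    mutation_rate: float = 0.05
    n_families: int = 5
    alphabet: str = AMINO_ALPHABET
    seed: int = 0
    domains_per_seq: int = 1

    def __post_init__(self) -> None:
        if self.n_seqs < 2:
            raise ParameterError(f"n_seqs must be >= 2, got {self.n_seqs}")
        if self.domain_len < 1:
            raise ParameterError(
                f"domain_len must be positive, got {self.domain_len}"
            )
        if self.flank_len < 2:
            raise ParameterError(
                f"flank_len must be >= 2, got {self.flank_len}"
            )
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ParameterError(
                f"mutation_rate must be in [0, 1], got {self.mutation_rate}"
            )
        if self.n_families < 1:
            raise ParameterError(
                f"n_families must be >= 1, got {self.n_families}"
            )
        if self.domains_per_seq < 1:
            raise ParameterError(
                f"domains_per_seq must be >= 1, got {self.domains_per_seq}"
            )
        if len(set(self.alphabet)) < 2:
            raise ParameterError("alphabet needs at least 2 distinct letters")


def _random_string(rng: np.random.Generator, alphabet: str, length: int) -> str:
    letters = np.frombuffer(alphabet.encode(), dtype="S1")
    return b"".join(rng.choice(letters, size=length)).decode()


def _mutate(rng: np.random.Generator, domain: str, rate: float, alphabet: str) -> str:
    if rate == 0.0:
        return domain
    chars = list(domain)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        # substitute with a uniformly chosen *different* letter
        others = alphabet.replace(chars[i], "")
        chars[i] = others[rng.integers(len(others))]
    return "".join(chars)


def generate(
    spec: FamilySpec,
) -> tuple[SequenceSet, list[AnnotatedRegion]]:
    """Simulate families and exact truth annotations, reproducibly from seed."""
    rng = np.random.default_rng(spec.seed)
    lo = spec.flank_len // 2
    hi = (3 * spec.flank_len) // 2  # inclusive
    seqs = SequenceSet()
    truth: list[AnnotatedRegion] = []
    for f in range(spec.n_families):
        master = _random_string(rng, spec.alphabet, spec.domain_len)
        for i in range(spec.n_seqs):
            seq_id = f"fam{f:02d}_seq{i:03d}"
            parts: list[str] = []
            pos = 0
            for d in range(spec.domains_per_seq):
                flank = _random_string(
                    rng, spec.alphabet, int(rng.integers(lo, hi + 1))
                )
                parts.append(flank)
                pos += len(flank)
                copy = _mutate(rng, master, spec.mutation_rate, spec.alphabet)
                parts.append(copy)
                truth.append(
                    AnnotatedRegion(
                        seq_id, pos, pos + spec.domain_len, f"fam{f:02d}"
                    )
                )
                pos += spec.domain_len
            parts.append(
                _random_string(rng, spec.alphabet, int(rng.integers(lo, hi + 1)))
            )
            seqs.add(ProteinSequence(seq_id, "".join(parts)))
    return seqs, truth


def make_benchmark(
    spec: FamilySpec, holdout_families: int
) -> tuple[
    tuple[SequenceSet, list[AnnotatedRegion]],
    tuple[SequenceSet, list[AnnotatedRegion]],
]:
    """Train/test partition for evaluating de novo detection.

    With ``holdout_families > 0`` the last that many families go entirely to
    the test side, so no master domain is shared between splits (detection of
    genuinely unseen domains). With ``holdout_families = 0`` the split is a
    plain random 80/20 over sequences, which measures retrieval of domains
    the model has already seen.
    """
    if not 0 <= holdout_families < spec.n_families:
        raise ParameterError(
            f"holdout_families must be in [0, n_families), got "
            f"{holdout_families} with n_families={spec.n_families}"
        )
    seqs, truth = generate(spec)
    regions_by_seq: dict[str, list[AnnotatedRegion]] = {}
    for r in truth:
        regions_by_seq.setdefault(r.seq_id, []).append(r)

    if holdout_families == 0:
        rng = np.random.default_rng(spec.seed + 1)
        ids = seqs.ids()
        test_ids = set(
            rng.choice(ids, size=max(1, round(0.2 * len(ids))), replace=False)
        )
        in_test = lambda sid: sid in test_ids  # noqa: E731
    else:
        test_fams = {
            f"fam{f:02d}"
            for f in range(spec.n_families - holdout_families, spec.n_families)
        }
        in_test = lambda sid: sid.split("_")[0] in test_fams  # noqa: E731

    train_seqs, test_seqs = SequenceSet(), SequenceSet()
    train_regions: list[AnnotatedRegion] = []
    test_regions: list[AnnotatedRegion] = []
    for seq in seqs:
        if in_test(seq.id):
            test_seqs.add(seq)
            test_regions.extend(regions_by_seq.get(seq.id, []))
        else:
            train_seqs.add(seq)
            train_regions.extend(regions_by_seq.get(seq.id, []))
    return (train_seqs, train_regions), (test_seqs, test_regions)
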