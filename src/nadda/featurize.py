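"""Per-index classification instances from k-mer profiles.

Each residue index ``i`` of a sequence becomes one instance: the ``2w + 1``
profile values in the window ``[i - w, i + w]``, with 0 filling positions
beyond either end of the sequence (0 is the natural "no shared k-mer"
frequency, and keeps the features integer-valued). The label, when attached,
is whether index ``i`` falls inside a reference conserved region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InputError, ParameterError
from .kmer_profile import KmerProfile
from .sequence_io import AnnotatedRegion


@dataclass(frozen=True)
class FeatureConfig:
    """Half-window size; the feature vector has length ``2w + 1``."""

    w: int = 10

    def __post_init__(self) -> None:
        if not isinstance(self.w, (int, np.integer)) or self.w < 1:
            raise ParameterError(f"w must be a positive integer, got {self.w!r}")

    @property
    def width(self) -> int:
        return 2 * self.w + 1


@dataclass(frozen=True)
class InstanceBlock:
    """One feature row per residue index of a single sequence.

    ``rows[i, j]`` is the profile value at index ``i - w + j`` (0 when out of
    range), so the middle column ``j = w`` is the profile value at ``i``
    itself. ``labels`` is optional: ``True`` marks a conserved index.
    """

    seq_id: str
    rows: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.int64)
        if rows.ndim != 2 or rows.shape[1] % 2 == 0:
            raise InputError(
                f"instance rows must be 2-D with odd width, got {rows.shape}"
            )
        object.__setattr__(self, "rows", rows)
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=bool)
            if labels.shape != (rows.shape[0],):
                raise InputError("labels length must equal row count")
            object.__setattr__(self, "labels", labels)

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def width(self) -> int:
        return self.rows.shape[1]

    @property
    def w(self) -> int:
        return (self.width - 1) // 2

    def index_map(self) -> list[tuple[str, int]]:
        """Row number -> (seq_id, sequence index)."""
        return [(self.seq_id, i) for i in range(self.n_rows)]


def make_instances(
    profile: KmerProfile, config: FeatureConfig = FeatureConfig()
) -> InstanceBlock:
    """Window the profile into one instance per sequence index.

    Instances are generated for every index, including the zero tail (the
    last ``k - 1`` positions): tail instances still carry informative
    left-window content.
    """
    w = config.w
    padded = np.concatenate(
        [
            np.zeros(w, dtype=np.int64),
            profile.values,
            np.zeros(w, dtype=np.int64),
        ]
    )
    rows = sliding_window_view(padded, config.width).copy()
    return InstanceBlock(seq_id=profile.seq_id, rows=rows)


def label_instances(
    block: InstanceBlock, regions: Iterable[AnnotatedRegion]
) -> InstanceBlock:
    """Attach labels: index ``i`` is positive iff covered by some region."""
    labels = np.zeros(block.n_rows, dtype=bool)
    for region in regions:
        if region.seq_id != block.seq_id:
            raise InputError(
                f"region on {region.seq_id!r} applied to block for "
                f"{block.seq_id!r}"
            )
        if region.end > block.n_rows:
            raise InputError(
                f"region [{region.start}, {region.end}) exceeds sequence "
                f"length {block.n_rows} for {block.seq_id!r}"
            )
        labels[region.start : region.end] = True
    return InstanceBlock(seq_id=block.seq_id, rows=block.rows, labels=labels)


def make_labeled_blocks(
    profiles: Sequence[KmerProfile],
    regions: Iterable[AnnotatedRegion],
    config: FeatureConfig = FeatureConfig(),
) -> list[InstanceBlock]:
    """Convenience: window every profile and label it from ``regions``."""
    by_seq: dict[str, list[AnnotatedRegion]] = {}
    for region in regions:
        by_seq.setdefault(region.seq_id, []).append(region)
    return [
        label_instances(make_instances(p, config), by_seq.get(p.seq_id, []))
        for p in profiles
    ]


def dump_instances(
    blocks: Sequence[InstanceBlock], path
) -> None:
    """Debug dump: TSV with seq_id, index, f0..f(2w) and label (if any)."""
    if not blocks:
        raise InputError("no instance blocks to dump")
    width = blocks[0].width
    with open(path, "w") as handle:
        cols = "\t".join(f"f{j}" for j in range(width))
        handle.write(f"#seq_id\tindex\t{cols}\tlabel\n")
        for block in blocks:
            if block.width != width:
                raise InputError("instance blocks mix feature widths")
            for i in range(block.n_rows):
                feats = "\t".join(str(v) for v in block.rows[i])
                label = (
                    "" if block.labels is None else str(int(block.labels[i]))
                )
                handle.write(f"{block.seq_id}\t{i}\t{feats}\t{label}\n")
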