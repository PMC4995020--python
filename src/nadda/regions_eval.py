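"""Maximal conserved regions and per-index evaluation.

A conserved region is a maximal run of indices predicted conserved: every
index inside is conserved and the indices immediately flanking it (when they
exist) are not. Evaluation is per-index against reference annotations:

    AC = (TP + TN) / N      SN = TP / (TP + FN)      SP = TN / (TN + FP)

where N is the total residue length of the evaluated set. Undefined ratios
(zero denominators) are reported as NaN, never silently as 0 or 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .kmer_profile import ProfileStats
from .sequence_io import AnnotatedRegion, SequenceSet

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    if math.isnan(x):
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, ROUND_HALF_UP))


@dataclass
class RegionSet:
    """Per-sequence sorted, disjoint, non-adjacent half-open intervals."""

    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seq_id, intervals in self.regions.items():
            prev_end = None
            for start, end in intervals:
                if start >= end:
                    raise InputError(
                        f"empty interval [{start}, {end}) on {seq_id!r}"
                    )
                if prev_end is not None and start <= prev_end:
                    raise InputError(
                        f"intervals on {seq_id!r} not sorted/merged at "
                        f"[{start}, {end})"
                    )
                prev_end = end

    @classmethod
    def from_annotations(cls, regions: Iterable[AnnotatedRegion]) -> "RegionSet":
        """Build from possibly overlapping annotations, merging as needed."""
        raw: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            raw.setdefault(r.seq_id, []).append((r.start, r.end))
        merged: dict[str, list[tuple[int, int]]] = {}
        for seq_id, intervals in raw.items():
            intervals.sort()
            out: list[tuple[int, int]] = []
            for start, end in intervals:
                if out and start <= out[-1][1]:  # overlap or adjacency
                    out[-1] = (out[-1][0], max(out[-1][1], end))
                else:
                    out.append((start, end))
            merged[seq_id] = out
        return cls(regions=merged)

    def iter_intervals(self) -> Iterable[tuple[str, int, int]]:
        for seq_id in self.regions:
            for start, end in self.regions[seq_id]:
                yield seq_id, start, end

    def indicator(self, seq_id: str, length: int) -> np.ndarray:
        """Boolean coverage vector of ``length`` for one sequence."""
        vec = np.zeros(length, dtype=bool)
        for start, end in self.regions.get(seq_id, ()):
            if end > length:
                raise InputError(
                    f"region [{start}, {end}) exceeds |{seq_id}| = {length}"
                )
            vec[start:end] = True
        return vec

    def n_regions(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def to_annotations(self, label: str = "predicted") -> list[AnnotatedRegion]:
        return [
            AnnotatedRegion(seq_id, start, end, label)
            for seq_id, start, end in self.iter_intervals()
        ]


def extract_regions(
    predictions: Mapping[str, np.ndarray]
) -> RegionSet:
    """Maximal runs of True in per-index prediction vectors.

    The union of the returned intervals equals the set of True indices
    exactly; sequences with no positive index contribute no entry.
    """
    regions: dict[str, list[tuple[int, int]]] = {}
    for seq_id, vec in predictions.items():
        vec = np.asarray(vec, dtype=bool)
        edges = np.flatnonzero(
            np.diff(np.concatenate(([False], vec, [False])).astype(np.int8))
        )
        intervals = [
            (int(edges[i]), int(edges[i + 1]))
            for i in range(0, len(edges), 2)
        ]
        if intervals:
            regions[seq_id] = intervals
    return RegionSet(regions=regions)


def filter_min_length(region_set: RegionSet, min_length: int) -> RegionSet:
    """Optional post-hoc filter dropping regions shorter than ``min_length``.

    Off by default throughout the pipeline: regions are defined purely as
    maximal runs.
    """
    kept = {
        seq_id: [iv for iv in intervals if iv[1] - iv[0] >= min_length]
        for seq_id, intervals in region_set.regions.items()
    }
    return RegionSet(regions={s: iv for s, iv in kept.items() if iv})


@dataclass(frozen=True)
class EvalReport:
    """Per-index confusion counts and the derived AC/SN/SP ratios."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def ac(self) -> float:
        if self.n_total == 0:
            logger.warning("accuracy undefined: no indices evaluated")
            return float("nan")
        return (self.tp + self.tn) / self.n_total

    @property
    def sn(self) -> float:
        if self.tp + self.fn == 0:
            logger.warning("sensitivity undefined: no reference-positive indices")
            return float("nan")
        return self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        if self.tn + self.fp == 0:
            logger.warning("specificity undefined: no reference-negative indices")
            return float("nan")
        return self.tn / (self.tn + self.fp)


def evaluate(
    predicted: RegionSet,
    reference: Iterable[AnnotatedRegion],
    seqs: SequenceSet,
) -> EvalReport:
    """Score predictions against reference annotations over all N indices.

    Sequences without reference regions still contribute (as true negatives
    or false positives); a region falling outside its sequence raises.
    """
    ref_set = RegionSet.from_annotations(reference)
    for seq_id in list(ref_set.regions) + list(predicted.regions):
        if seq_id not in seqs:
            raise InputError(f"region on unknown sequence id {seq_id!r}")
    tp = tn = fp = fn = 0
    for seq in seqs:
        pred_vec = predicted.indicator(seq.id, len(seq))
        ref_vec = ref_set.indicator(seq.id, len(seq))
        tp += int(np.sum(pred_vec & ref_vec))
        tn += int(np.sum(~pred_vec & ~ref_vec))
        fp += int(np.sum(pred_vec & ~ref_vec))
        fn += int(np.sum(~pred_vec & ref_vec))
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn)


def summarize(
    reports: Sequence[EvalReport | Mapping[str, float]],
    names: Sequence[str],
    stats: Sequence[ProfileStats | tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-set AC/SN/SP percentages plus an arithmetic-mean Average row.

    Each report is either an :class:`EvalReport` or a mapping with keys
    ``ac``/``sn``/``sp`` holding fractions in [0, 1]. Percentages are rounded
    half-up to one decimal; the Average row is the arithmetic mean of the
    per-set (rounded) percentages, rounded the same way. ``stats`` optionally
    adds mean-frequency and frequency-variance columns (two decimals).
    """
    if not reports:
        raise InputError("no reports to summarize")
    if len(names) != len(reports):
        raise InputError("names and reports must have equal length")
    if stats is not None and len(stats) != len(reports):
        raise InputError("stats and reports must have equal length")

    rows = []
    for i, report in enumerate(reports):
        if isinstance(report, EvalReport):
            row = {
                "set": names[i],
                "n_indices": report.n_total,
                "tp": report.tp,
                "tn": report.tn,
                "fp": report.fp,
                "fn": report.fn,
                "ac_pct": round_half_up(report.ac * 100),
                "sn_pct": round_half_up(report.sn * 100),
                "sp_pct": round_half_up(report.sp * 100),
            }
        else:
            row = {
                "set": names[i],
                "ac_pct": round_half_up(float(report["ac"]) * 100),
                "sn_pct": round_half_up(float(report["sn"]) * 100),
                "sp_pct": round_half_up(float(report["sp"]) * 100),
            }
        if stats is not None:
            st = stats[i]
            mean, var = (
                (st.mean, st.variance)
                if isinstance(st, ProfileStats)
                else (st[0], st[1])
            )
            row["mean_freq"] = round_half_up(mean, 2)
            row["freq_variance"] = round_half_up(var, 2)
        rows.append(row)

    table = pd.DataFrame(rows)
    avg: dict[str, object] = {"set": "Average"}
    for col in table.columns:
        if col == "set":
            continue
        ndigits = 2 if col in ("mean_freq", "freq_variance") else 1
        if col in ("n_indices", "tp", "tn", "fp", "fn"):
            avg[col] = round_half_up(float(table[col].mean()), 1)
        else:
            avg[col] = round_half_up(float(table[col].mean()), ndigits)
    return pd.concat([table, pd.DataFrame([avg])], ignore_index=True)


def write_report(table: pd.DataFrame, path) -> None:
    """Write a summarize() table as TSV."""
    table.to_csv(path, sep="\t", index=False)
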