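"""Peak calling on the residue profile and refinement to minimal motifs.

The bait is split into N- and C-terminal halves (default split at floor(L/2))
and the best peak — the maximal contiguous run of above-threshold residues
containing the half's maximum profile value — is taken per half.  Each peak
is then refined to a contiguous minimal motif by extracting the run of
contacting residues (gaps up to ``gap_tolerance`` allowed) with the largest
total contact count inside the peak's best-scoring supporting fragment.

All tie-breaks are leftmost; given identical inputs the calls are identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .scoring import ContactSet, FragmentScore, ResidueProfile
from .tiling import BaitSequence, FragmentSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdPolicy",
    "MeanPlusSD",
    "Quantile",
    "Absolute",
    "PeakRegion",
    "MotifCall",
    "NoMotifError",
    "call_peaks",
    "refine_motif",
    "report_motifs",
    "interval_jaccard",
    "parse_threshold_policy",
]


class NoMotifError(ValueError):
    """Raised when a peak yields no qualifying contact run."""


@dataclass(frozen=True)
class MeanPlusSD:
    """Threshold at mean + k*sd of the defined profile values."""

    k: float = 1.0

    def resolve(self, values: np.ndarray) -> float:
        return float(np.mean(values) + self.k * np.std(values))


@dataclass(frozen=True)
class Quantile:
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"quantile must be in [0, 1], got {self.q}")

    def resolve(self, values: np.ndarray) -> float:
        return float(np.quantile(values, self.q))


@dataclass(frozen=True)
class Absolute:
    value: float

    def resolve(self, values: np.ndarray) -> float:
        return self.value


ThresholdPolicy = MeanPlusSD | Quantile | Absolute


def parse_threshold_policy(text: str) -> ThresholdPolicy:
    """Parse 'mean_plus_sd:k', 'quantile:q' or 'absolute:v' strings."""
    name, _, arg = text.partition(":")
    name = name.strip().lower()
    if name in ("mean_plus_sd", "mean_plus_k_sd"):
        return MeanPlusSD(float(arg) if arg else 1.0)
    if name == "quantile":
        if not arg:
            raise ValueError("quantile policy needs a value, e.g. quantile:0.9")
        return Quantile(float(arg))
    if name == "absolute":
        if not arg:
            raise ValueError("absolute policy needs a value, e.g. absolute:50")
        return Absolute(float(arg))
    raise ValueError(f"unknown threshold policy {text!r}")


@dataclass(frozen=True)
class PeakRegion:
    """Best above-threshold run of one sequence half."""

    half: str  # "N" or "C"
    start: int
    end: int
    peak_score: float
    supporting_fragments: Tuple[str, ...]


@dataclass(frozen=True)
class MotifCall:
    """A called minimal motif in global bait coordinates."""

    name: str
    start: int
    end: int
    sequence: str
    mean_per_residue_contacts: float
    source_fragment: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _runs_above(
    values: np.ndarray, lo: int, hi: int, threshold: float
) -> List[Tuple[int, int]]:
    """Maximal runs of defined values >= threshold within [lo, hi], 1-based."""
    runs: List[Tuple[int, int]] = []
    run_start: Optional[int] = None
    for i in range(lo, hi + 1):
        v = values[i - 1]
        ok = not np.isnan(v) and v >= threshold
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            runs.append((run_start, i - 1))
            run_start = None
    if run_start is not None:
        runs.append((run_start, hi))
    return runs


def call_peaks(
    profile: ResidueProfile,
    fragments: Sequence[FragmentSpec],
    split: Optional[int] = None,
    threshold_policy: ThresholdPolicy = MeanPlusSD(1.0),
) -> List[PeakRegion]:
    """Call the best peak in each half of the residue profile.

    The threshold is resolved once over all defined profile values.  Within
    each half, residues at or above it are grouped into maximal contiguous
    runs (undefined residues break runs); the run containing the half's
    maximum value is that half's peak, ties going to the leftmost such run.
    A half with no qualifying residues yields no peak, with a warning.
    """
    L = profile.length
    if split is None:
        split = L // 2
    if not (1 <= split < L):
        raise ValueError(f"split {split} outside (1, {L})")
    defined = profile.defined()
    if not defined.any():
        raise ValueError("profile has no defined values")
    threshold = threshold_policy.resolve(profile.values[defined])

    peaks: List[PeakRegion] = []
    for half, lo, hi in (("N", 1, split), ("C", split + 1, L)):
        half_vals = profile.values[lo - 1 : hi]
        half_defined = ~np.isnan(half_vals)
        if not half_defined.any():
            logger.warning("no defined profile values in %s half", half)
            continue
        runs = _runs_above(profile.values, lo, hi, threshold)
        if not runs:
            logger.warning(
                "%s half: all values below threshold %.6g, no peak",
                half,
                threshold,
            )
            continue
        half_max = np.nanmax(half_vals)
        best = None
        for start, end in runs:  # leftmost run holding the half's maximum
            if np.nanmax(profile.values[start - 1 : end]) >= half_max:
                best = (start, end)
                break
        if best is None:  # maximum lies below threshold: take highest run
            best = max(
                runs,
                key=lambda r: (np.nanmax(profile.values[r[0] - 1 : r[1]]), -r[0]),
            )
        start, end = best
        support = tuple(
            f.fragment_id
            for f in fragments
            if f.start <= end and f.end >= start
        )
        peaks.append(
            PeakRegion(
                half=half,
                start=start,
                end=end,
                peak_score=float(np.nanmax(profile.values[start - 1 : end])),
                supporting_fragments=support,
            )
        )
    return peaks


def _contact_runs(
    residues: List[int], gap_tolerance: int
) -> List[List[int]]:
    runs: List[List[int]] = []
    for r in sorted(residues):
        if runs and r - runs[-1][-1] - 1 <= gap_tolerance:
            runs[-1].append(r)
        else:
            runs.append([r])
    return runs


def refine_motif(
    peak: PeakRegion,
    contact_sets: Mapping[str, ContactSet],
    fragment_scores: Mapping[str, FragmentScore],
    fragments: Mapping[str, FragmentSpec],
    bait: BaitSequence,
    gap_tolerance: int = 1,
    min_motif_length: int = 5,
) -> MotifCall:
    """Refine a peak to a contiguous motif from its best supporting fragment.

    The supporting fragment with the highest weighted score is selected
    (ties to the leftmost fragment).  Its contacting bait residues are
    grouped into runs allowing internal gaps of up to ``gap_tolerance``
    residues; the run with the largest total contact count whose span is at
    least ``min_motif_length`` becomes the motif (shorter runs are discarded
    and the next-best run considered).
    """
    candidates = [
        fid
        for fid in peak.supporting_fragments
        if fid in contact_sets and fid in fragment_scores
    ]
    if not candidates:
        raise NoMotifError(
            f"{peak.half} half peak [{peak.start}, {peak.end}]: "
            "no supporting fragment with contacts available"
        )
    best_frag = max(
        candidates,
        key=lambda fid: (
            fragment_scores[fid].weighted_score,
            -fragments[fid].start,
        ),
    )
    per_residue = contact_sets[best_frag].per_residue_contact_count
    contacting = sorted(per_residue)
    if not contacting:
        raise NoMotifError(
            f"{peak.half} half peak: fragment {best_frag} has no contacts"
        )
    runs = _contact_runs(contacting, gap_tolerance)
    # largest total contact count first, leftmost on ties
    runs.sort(key=lambda run: (-sum(per_residue[r] for r in run), run[0]))
    for run in runs:
        start, end = run[0], run[-1]
        if end - start + 1 < min_motif_length:
            continue
        start = max(start, 1)
        end = min(end, bait.length)
        span = range(start, end + 1)
        mean_contacts = sum(per_residue.get(r, 0) for r in span) / len(span)
        name = "MotifA" if peak.half == "N" else "MotifB"
        return MotifCall(
            name=name,
            start=start,
            end=end,
            sequence=bait.subsequence(start, end),
            mean_per_residue_contacts=mean_contacts,
            source_fragment=best_frag,
        )
    raise NoMotifError(
        f"{peak.half} half peak: no contact run of length >= "
        f"{min_motif_length} in fragment {best_frag}"
    )


def interval_jaccard(
    a: Tuple[int, int], b: Tuple[int, int]
) -> float:
    """Jaccard overlap of two 1-based inclusive residue intervals."""
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union


def report_motifs(
    calls: Sequence[MotifCall],
    bait: BaitSequence,
    tsv_path: str | Path,
    fasta_path: str | Path,
    bed_path: str | Path | None = None,
) -> None:
    """Write motifs.tsv, motifs.fasta and optionally a BED of intervals."""
    for call in calls:
        if bait.subsequence(call.start, call.end) != call.sequence:
            raise ValueError(
                f"motif {call.name} sequence does not match bait at "
                f"[{call.start}, {call.end}]"
            )
    with open(tsv_path, "w") as fh:
        fh.write(
            "name\tstart\tend\tlength\tsequence\t"
            "mean_per_residue_contacts\tsource_fragment\n"
        )
        for c in calls:
            fh.write(
                f"{c.name}\t{c.start}\t{c.end}\t{c.length}\t{c.sequence}\t"
                f"{c.mean_per_residue_contacts:.6g}\t{c.source_fragment}\n"
            )
    with open(fasta_path, "w") as fh:
        for c in calls:
            fh.write(f">{c.name} {bait.id}:{c.start}-{c.end}\n{c.sequence}\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in calls:
                fh.write(f"{bait.id}\t{c.start - 1}\t{c.end}\t{c.name}\n")
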