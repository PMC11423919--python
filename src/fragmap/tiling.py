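"""Sliding-window tiling of a bait protein into overlapping fragments.

A bait sequence (e.g. a vitellogenin receptor-binding domain) is cut into
fixed-length windows advanced by a fixed step.  Every downstream stage of the
pipeline — per-fragment complex scoring, per-residue profile aggregation,
motif calling — addresses residues in the bait's 1-based global coordinate
frame established here.  Coordinates are 1-based and inclusive throughout;
conversion to 0-based half-open happens only at BED/bedGraph export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BaitSequence",
    "FragmentSpec",
    "tile_sequence",
    "coverage_count",
    "read_bait_fasta",
    "write_fragments_tsv",
    "write_fragments_fasta",
]

_VALID_SEQ = re.compile(r"^[A-Za-z]+$")


@dataclass(frozen=True)
class BaitSequence:
    """Full-length bait protein with a 1-based residue coordinate frame."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("bait sequence must be non-empty")
        if not _VALID_SEQ.match(self.sequence):
            raise ValueError(
                f"bait sequence for {self.id!r} contains non-letter characters"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Substring at 1-based inclusive coordinates [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(
                f"coordinates [{start}, {end}] outside bait [1, {self.length}]"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class FragmentSpec:
    """One tiled window of the bait, in global 1-based inclusive coordinates."""

    fragment_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid fragment interval [{self.start}, {self.end}]"
            )
        if len(self.sequence) != self.length:
            raise ValueError(
                f"fragment {self.fragment_id}: sequence length "
                f"{len(self.sequence)} != interval length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end

    def to_local(self, global_residue: int) -> int:
        """Map a global bait residue to this fragment's 1-based local number."""
        if not self.contains(global_residue):
            raise ValueError(
                f"residue {global_residue} outside fragment "
                f"[{self.start}, {self.end}]"
            )
        return global_residue - self.start + 1

    def to_global(self, local_residue: int) -> int:
        if not (1 <= local_residue <= self.length):
            raise ValueError(
                f"local residue {local_residue} outside [1, {self.length}]"
            )
        return self.start + local_residue - 1


def tile_sequence(
    bait: BaitSequence,
    window: int = 50,
    step: int = 25,
    tail_policy: str = "anchor_tail",
) -> List[FragmentSpec]:
    """Tile the bait into overlapping windows of fixed length.

    Full windows start at 1, 1+step, 1+2*step, ... while they fit inside the
    bait.  When the last full-step window does not end at the C-terminus,
    ``tail_policy`` decides what happens to the remaining tail:

    - ``anchor_tail`` (default): one extra full-length window anchored at the
      C-terminus, [L-window+1, L], so every residue is covered;
    - ``drop_tail``: no extra window; trailing residues stay uncovered.

    Tail windows are always full length (anchored, never truncated).
    """
    if tail_policy not in ("anchor_tail", "drop_tail"):
        raise ValueError(f"unknown tail_policy {tail_policy!r}")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if window < step:
        raise ValueError(f"step ({step}) must not exceed window ({window})")
    L = bait.length
    if window > L:
        raise ValueError(
            f"window ({window}) exceeds bait length ({L}); "
            "cannot tile a sequence shorter than one window"
        )

    starts = list(range(1, L - window + 2, step))
    if tail_policy == "anchor_tail" and starts[-1] + window - 1 < L:
        starts.append(L - window + 1)

    n_digits = len(str(L))
    fragments = []
    for i, start in enumerate(starts, 1):
        end = start + window - 1
        frag_id = f"F{i:02d}_{start:0{n_digits}d}-{end:0{n_digits}d}"
        fragments.append(
            FragmentSpec(frag_id, start, end, bait.subsequence(start, end))
        )
    return fragments


def coverage_count(fragments: Iterable[FragmentSpec], L: int) -> np.ndarray:
    """Per-residue fragment coverage: entry i-1 counts fragments containing i."""
    coverage = np.zeros(L, dtype=np.int64)
    for frag in fragments:
        if frag.start < 1 or frag.end > L:
            raise ValueError(
                f"fragment {frag.fragment_id} [{frag.start}, {frag.end}] "
                f"outside bait [1, {L}]"
            )
        coverage[frag.start - 1 : frag.end] += 1
    return coverage


def read_bait_fasta(path: str | Path) -> BaitSequence:
    """Read a single-record protein FASTA; multi-record input is rejected."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA records found in {path}")
    if len(records) > 1:
        raise ValueError(
            f"expected exactly one bait record in {path}, found {len(records)}"
        )
    rec = records[0]
    return BaitSequence(id=rec.id, sequence=str(rec.seq))


def write_fragments_tsv(
    fragments: Sequence[FragmentSpec], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_id\tstart\tend\tsequence\n")
        for f in fragments:
            fh.write(f"{f.fragment_id}\t{f.start}\t{f.end}\t{f.sequence}\n")


def write_fragments_fasta(
    fragments: Sequence[FragmentSpec], path: str | Path
) -> None:
    records = [
        SeqRecord(
            Seq(f.sequence),
            id=f.fragment_id,
            description=f"residues {f.start}-{f.end}",
        )
        for f in fragments
    ]
    SeqIO.write(records, str(path), "fasta")
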