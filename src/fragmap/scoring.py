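"""Inter-chain contact counting and pLDDT-weighted interaction scoring.

The core statistic of the pipeline:

- contacts: a bait residue i and receptor residue j are in contact when any
  heavy-atom pair between them is within the distance cutoff (default 4.0 A,
  inclusive).  The default counting unit is the deduplicated residue pair;
  atom-pair counting is selectable.
- fragment score: S_f = C_f * mean(pLDDT over the bait fragment's residues),
  with C_f the contact count.  The mean runs over all bait-fragment residues,
  contacting or not, on the native 0-100 pLDDT scale.
- per-residue profile: r_i = mean of S_f over the scored fragments covering
  residue i.  Residues covered by no scored fragment are undefined (NaN in
  the profile array, "NA" in TSV output) — never silently zero.

Contact search uses a KD-tree over receptor atoms; it returns exactly the
all-pairs answer (verified against an exhaustive oracle in the test suite).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ComplexStructure
from .tiling import FragmentSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ContactSet",
    "FragmentScore",
    "ResidueProfile",
    "count_interchain_contacts",
    "score_fragment",
    "build_residue_profile",
    "write_fragment_scores_tsv",
    "write_residue_profile_tsv",
    "write_profile_bedgraph",
]

DEFAULT_CUTOFF = 4.0


@dataclass
class ContactSet:
    """Inter-chain contacts of one fragment's predicted complex.

    ``pairs`` maps (bait_global_residue, receptor_local_residue) to the
    number of qualifying heavy-atom pairs and their minimum distance.
    """

    fragment_id: str
    pairs: Dict[Tuple[int, int], Tuple[int, float]]
    unit: str = "residue_pair"

    @property
    def count(self) -> int:
        """Contact count in the configured unit."""
        if self.unit == "residue_pair":
            return len(self.pairs)
        return sum(n for n, _ in self.pairs.values())

    @property
    def per_residue_contact_count(self) -> Dict[int, int]:
        """Bait residue -> number of receptor residues it contacts."""
        counts: Dict[int, int] = {}
        for (bait_res, _rec), _ in self.pairs.items():
            counts[bait_res] = counts.get(bait_res, 0) + 1
        return counts

    def min_distance(self, bait_res: int, receptor_res: int) -> float:
        return self.pairs[(bait_res, receptor_res)][1]


def count_interchain_contacts(
    structure: ComplexStructure,
    cutoff: float = DEFAULT_CUTOFF,
    unit: str = "residue_pair",
) -> ContactSet:
    """Count bait/receptor contacts within ``cutoff`` (inclusive).

    Bait residues are reported in the global frame via the structure's
    ``global_start`` anchor; receptor residues keep their file-local numbers.
    An empty chain yields zero contacts with a warning.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if unit not in ("residue_pair", "atom_pair"):
        raise ValueError(f"unknown contact unit {unit!r}")

    bait_atoms = structure.chain_atoms(structure.bait_chain)
    rec_atoms = structure.chain_atoms(structure.receptor_chain)
    if not bait_atoms or not rec_atoms:
        logger.warning(
            "%s: empty chain, zero contacts", structure.fragment_id
        )
        return ContactSet(structure.fragment_id, {}, unit)

    rec_xyz = np.array([a.position for a in rec_atoms])
    rec_res = np.array([a.residue_number for a in rec_atoms])
    tree = cKDTree(rec_xyz)

    pairs: Dict[Tuple[int, int], Tuple[int, float]] = {}
    bait_xyz = np.array([a.position for a in bait_atoms])
    neighbour_lists = tree.query_ball_point(bait_xyz, r=cutoff)
    for atom, pos, neighbours in zip(bait_atoms, bait_xyz, neighbour_lists):
        if not neighbours:
            continue
        bait_global = structure.local_to_global(atom.residue_number)
        dists = np.linalg.norm(rec_xyz[neighbours] - pos, axis=1)
        for j, dist in zip(neighbours, dists):
            key = (bait_global, int(rec_res[j]))
            n, dmin = pairs.get(key, (0, math.inf))
            pairs[key] = (n + 1, min(dmin, float(dist)))
    return ContactSet(structure.fragment_id, pairs, unit)


@dataclass(frozen=True)
class FragmentScore:
    """Contact count, mean pLDDT and weighted score of one fragment."""

    fragment_id: str
    contact_count: int
    mean_plddt: float
    weighted_score: float


def score_fragment(
    contact_set: ContactSet, plddt: Mapping[int, float]
) -> FragmentScore:
    """Weight the contact count by the fragment's mean pLDDT.

    ``plddt`` maps every bait-fragment residue (any consistent keying) to its
    confidence; the mean is unweighted over all entries, not only contacting
    residues.  S_f = C_f * mean(pLDDT); zero contacts give S_f = 0 exactly.
    """
    if not plddt:
        raise ValueError(
            f"{contact_set.fragment_id}: empty pLDDT map"
        )
    c = contact_set.count
    mean_plddt = sum(plddt.values()) / len(plddt)
    return FragmentScore(
        fragment_id=contact_set.fragment_id,
        contact_count=c,
        mean_plddt=mean_plddt,
        weighted_score=c * mean_plddt if c > 0 else 0.0,
    )


@dataclass
class ResidueProfile:
    """Per-residue normalized interaction track over the bait.

    ``values[i-1]`` is the mean weighted score of the scored fragments
    covering residue i; NaN where coverage is zero.
    """

    length: int
    values: np.ndarray
    coverage: np.ndarray
    contributors: List[Tuple[str, ...]] = field(repr=False, default=None)

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def value_at(self, residue: int) -> float:
        return float(self.values[residue - 1])


def build_residue_profile(
    fragment_scores: Sequence[FragmentScore],
    fragments: Sequence[FragmentSpec],
    L: int,
) -> ResidueProfile:
    """Average fragment scores into the per-residue interaction profile.

    Fragments without a score (e.g. missing predictions) are excluded from
    both the numerator and the coverage denominator, and logged.
    """
    spec_by_id = {f.fragment_id: f for f in fragments}
    unknown = [s.fragment_id for s in fragment_scores
               if s.fragment_id not in spec_by_id]
    if unknown:
        raise ValueError(f"scores for unknown fragments: {unknown}")
    seen: set[str] = set()
    for s in fragment_scores:
        if s.fragment_id in seen:
            raise ValueError(
                f"fragment {s.fragment_id} scored more than once"
            )
        seen.add(s.fragment_id)
    missing = sorted(set(spec_by_id) - seen)
    if missing:
        logger.warning(
            "%d fragments without scores excluded from profile: %s",
            len(missing),
            missing,
        )

    total = np.zeros(L, dtype=float)
    coverage = np.zeros(L, dtype=np.int64)
    contributors: List[List[str]] = [[] for _ in range(L)]
    for score in fragment_scores:
        frag = spec_by_id[score.fragment_id]
        if frag.end > L:
            raise ValueError(
                f"fragment {frag.fragment_id} ends at {frag.end} > L={L}"
            )
        sl = slice(frag.start - 1, frag.end)
        total[sl] += score.weighted_score
        coverage[sl] += 1
        for i in range(frag.start - 1, frag.end):
            contributors[i].append(frag.fragment_id)

    values = np.full(L, np.nan)
    covered = coverage > 0
    values[covered] = total[covered] / coverage[covered]
    return ResidueProfile(
        length=L,
        values=values,
        coverage=coverage,
        contributors=[tuple(c) for c in contributors],
    )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_fragment_scores_tsv(
    scores: Sequence[FragmentScore],
    fragments: Sequence[FragmentSpec],
    path: str | Path,
) -> None:
    spec_by_id = {f.fragment_id: f for f in fragments}
    with open(path, "w") as fh:
        fh.write(
            "fragment_id\tstart\tend\tcontact_count\t"
            "mean_plddt\tweighted_score\n"
        )
        for s in scores:
            f = spec_by_id[s.fragment_id]
            fh.write(
                f"{s.fragment_id}\t{f.start}\t{f.end}\t{s.contact_count}\t"
                f"{_fmt(s.mean_plddt)}\t{_fmt(s.weighted_score)}\n"
            )


def write_residue_profile_tsv(
    profile: ResidueProfile, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tcoverage\tscore\n")
        for i in range(profile.length):
            v = profile.values[i]
            score = "NA" if np.isnan(v) else _fmt(v)
            fh.write(f"{i + 1}\t{profile.coverage[i]}\t{score}\n")


def write_profile_bedgraph(
    profile: ResidueProfile,
    path: str | Path,
    name: str = "bait",
    merge_runs: bool = True,
) -> None:
    """Export defined profile values as bedGraph (0-based, half-open)."""
    with open(path, "w") as fh:
        fh.write(
            'track type=bedGraph name="residue_interaction_profile"\n'
        )
        run_start = None
        run_value = None
        for i in range(profile.length + 1):
            v = profile.values[i] if i < profile.length else np.nan
            same = (
                run_value is not None
                and not np.isnan(v)
                and v == run_value
                and merge_runs
            )
            if same:
                continue
            if run_value is not None:
                fh.write(f"{name}\t{run_start}\t{i}\t{_fmt(run_value)}\n")
            run_start, run_value = (i, None if np.isnan(v) else float(v))
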