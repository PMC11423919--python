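"""Synthetic two-chain complex generator with planted interfaces.

Stands in for structure-prediction output so the whole pipeline can run and
be validated without external predictions.  Each fragment's complex is a
coarse geometric model:

- the bait chain is a CA/CB trace along the x axis at the canonical 3.8 A
  CA-CA spacing;
- the receptor chain is a CA trace on a parallel line 20 A away, so baseline
  receptor atoms are far outside the contact cutoff;
- for every bait residue inside the planted segment, one or more extra
  receptor atoms are placed 2.5-3.2 A from that residue's CA, guaranteeing
  an inter-chain contact there; decoy contacts are injected at non-planted
  residues at a configurable rate, and every injected pair is recorded so
  oracle tests stay exact;
- per-residue pLDDT is written into every atom's B-factor (constant per
  residue, the structure-predictor convention), with optional noise;
- Gaussian coordinate noise is applied last, with rejection resampling so
  the planted/non-planted contact classification is preserved exactly.

Geometry is deliberately unphysical (no side chains, no folding): scoring
only sees heavy-atom distances, residue numbers and B-factors, and those are
all modelled.  Fixtures are tiny and generation is deterministic per seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ManifestRow, write_manifest
from .tiling import BaitSequence, FragmentSpec, tile_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "PlantSpec",
    "GeneratedComplex",
    "SyntheticDataset",
    "generate_bait",
    "generate_complex",
    "generate_dataset",
    "DEFAULT_PLANTED_N",
    "DEFAULT_PLANTED_C",
    "DEFAULT_RECEPTOR_LENGTH",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

CA_SPACING = 3.8
RECEPTOR_OFFSET = 20.0  # baseline receptor distance from the bait trace, A
CONTACT_CUTOFF = 4.0
# planted-segment defaults reproduce the study's motif coordinates
DEFAULT_PLANTED_N = (28, 36)
DEFAULT_PLANTED_C = (197, 209)
DEFAULT_RECEPTOR_LENGTH = 119  # three LDL repeats of the receptor N-terminus


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one planted interface.

    contact_density is the expected number of receptor partner residues per
    planted bait residue: every planted residue receives floor(density)
    partners plus one more with probability equal to the fractional part
    (always at least one), so integer densities give exact counts and the
    planted interface strength is not left to sampling noise.  decoy_rate is
    the expected spurious contacts per non-planted residue (Poisson).
    pLDDT levels are on the native 0-100 scale.
    """

    planted_segment: Tuple[int, int]
    contact_density: float = 2.0
    decoy_rate: float = 0.0
    planted_plddt: float = 80.0
    background_plddt: float = 80.0
    plddt_noise_sd: float = 0.0
    coordinate_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        s, e = self.planted_segment
        if s < 1 or e < s:
            raise ValueError(f"invalid planted segment [{s}, {e}]")
        if self.contact_density <= 0:
            raise ValueError("contact_density must be positive")
        if self.decoy_rate < 0:
            raise ValueError("decoy_rate must be non-negative")


@dataclass
class GeneratedComplex:
    """One generated fragment complex plus its exact ground truth."""

    fragment_id: str
    pdb: str
    contact_pairs: Set[Tuple[int, int]]  # planted (bait_global, receptor)
    decoy_pairs: Set[Tuple[int, int]]
    plddt: Dict[int, float]  # bait global residue -> pLDDT written


def generate_bait(L: int, seed: int) -> BaitSequence:
    """Uniform-random 20-letter bait sequence, deterministic per seed."""
    if L < 1:
        raise ValueError(f"bait length must be >= 1, got {L}")
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(AMINO_ACIDS), size=L)
    return BaitSequence(id=f"synthetic_bait_L{L}_s{seed}",
                        sequence="".join(letters))


def _round3(x: float) -> float:
    # match PDB coordinate precision so the written file is what we verified
    return round(x, 3)


def _contact_position(
    rng: np.random.Generator, bait_ca: np.ndarray
) -> np.ndarray:
    d = rng.uniform(2.5, 3.2)
    dx = rng.uniform(-0.3, 0.3)
    dz = rng.uniform(-0.3, 0.3)
    return bait_ca + np.array([dx, -d, dz])


def generate_complex(
    fragment: FragmentSpec,
    receptor_length: int,
    plant: PlantSpec,
    max_noise_attempts: int = 200,
    warn_no_overlap: bool = True,
) -> GeneratedComplex:
    """Build one fragment/receptor complex PDB with a planted interface.

    When the planted segment does not overlap the fragment the complex is
    contact-free apart from sampled decoys (a warning is logged).
    """
    rng = np.random.default_rng(plant.seed)
    n = fragment.length
    ps, pe = plant.planted_segment
    planted_local = [
        i for i in range(1, n + 1) if ps <= fragment.to_global(i) <= pe
    ]
    if not planted_local:
        logger.log(
            logging.WARNING if warn_no_overlap else logging.DEBUG,
            "%s: planted segment [%d, %d] outside fragment, "
            "generating a contact-free complex",
            fragment.fragment_id, ps, pe,
        )

    bait_ca = {
        i: np.array([CA_SPACING * (i - 1), 0.0, 0.0])
        for i in range(1, n + 1)
    }
    # sample contacts: (bait_local, receptor_residue, position)
    contact_atoms: List[Tuple[int, int, np.ndarray]] = []
    planted_pairs: Set[Tuple[int, int]] = set()
    decoy_pairs: Set[Tuple[int, int]] = set()
    for i in range(1, n + 1):
        is_planted = i in planted_local
        if is_planted:
            base, frac = divmod(plant.contact_density, 1.0)
            k = int(base) + (1 if rng.random() < frac else 0)
            k = max(1, k)
        else:
            k = int(rng.poisson(plant.decoy_rate)) if plant.decoy_rate else 0
        k = min(k, receptor_length)
        if k == 0:
            continue
        partners = rng.choice(receptor_length, size=k, replace=False) + 1
        for j in sorted(int(j) for j in partners):
            contact_atoms.append((i, j, _contact_position(rng, bait_ca[i])))
            pair = (fragment.to_global(i), j)
            (planted_pairs if is_planted else decoy_pairs).add(pair)

    intended = planted_pairs | decoy_pairs

    # pLDDT per bait residue (constant across the residue's atoms)
    plddt: Dict[int, float] = {}
    for i in range(1, n + 1):
        g = fragment.to_global(i)
        base = plant.planted_plddt if ps <= g <= pe else plant.background_plddt
        if plant.plddt_noise_sd > 0:
            base += rng.normal(0.0, plant.plddt_noise_sd)
        plddt[g] = float(np.clip(base, 0.0, 100.0))

    # assemble noiseless coordinates: (chain, resnum, atom_name, xyz)
    def base_atoms() -> List[Tuple[str, int, str, np.ndarray]]:
        atoms: List[Tuple[str, int, str, np.ndarray]] = []
        for i in range(1, n + 1):
            atoms.append(("A", i, "CA", bait_ca[i]))
            atoms.append(("A", i, "CB",
                          bait_ca[i] + np.array([0.0, 1.4, 0.8])))
        for j in range(1, receptor_length + 1):
            atoms.append(("B", j, "CA",
                          np.array([CA_SPACING * (j - 1),
                                    RECEPTOR_OFFSET, 0.0])))
        extra_count: Dict[int, int] = {}
        for i, j, pos in contact_atoms:
            extra_count[j] = extra_count.get(j, 0) + 1
            atoms.append(("B", j, f"C{extra_count[j]}", pos))
        return atoms

    atoms0 = base_atoms()

    def classify(atoms: Sequence[Tuple[str, int, str, np.ndarray]]
                 ) -> Set[Tuple[int, int]]:
        bait = [(r, p) for ch, r, _an, p in atoms if ch == "A"]
        rec = [(r, p) for ch, r, _an, p in atoms if ch == "B"]
        tree = cKDTree(np.array([p for _r, p in rec]))
        rec_res = [r for r, _p in rec]
        found: Set[Tuple[int, int]] = set()
        for r, p in bait:
            for idx in tree.query_ball_point(p, r=CONTACT_CUTOFF):
                found.add((fragment.to_global(r), rec_res[idx]))
        return found

    for attempt in range(max_noise_attempts):
        if plant.coordinate_noise_sd > 0:
            noise_rng = np.random.default_rng(
                np.random.SeedSequence([plant.seed, attempt + 1])
            )
            noisy = [
                (ch, r, an,
                 np.array([_round3(v) for v in
                           p + noise_rng.normal(
                               0.0, plant.coordinate_noise_sd, 3)]))
                for ch, r, an, p in atoms0
            ]
        else:
            noisy = [(ch, r, an, np.array([_round3(v) for v in p]))
                     for ch, r, an, p in atoms0]
        if classify(noisy) == intended:
            atoms_final = noisy
            break
    else:
        raise RuntimeError(
            f"{fragment.fragment_id}: could not preserve planted contact "
            f"classification after {max_noise_attempts} noise draws"
        )

    pdb = _build_pdb(fragment, atoms_final, plddt, plant.background_plddt)
    return GeneratedComplex(
        fragment_id=fragment.fragment_id,
        pdb=pdb,
        contact_pairs=planted_pairs,
        decoy_pairs=decoy_pairs,
        plddt=plddt,
    )


def _build_pdb(
    fragment: FragmentSpec,
    atoms: Sequence[Tuple[str, int, str, np.ndarray]],
    plddt: Dict[int, float],
    receptor_plddt: float,
) -> str:
    st = gemmi.Structure()
    st.name = fragment.fragment_id
    model = gemmi.Model("1")
    by_chain: Dict[str, Dict[int, List[Tuple[str, np.ndarray]]]] = {}
    for ch, r, an, p in atoms:
        by_chain.setdefault(ch, {}).setdefault(r, []).append((an, p))
    for ch_name in sorted(by_chain):
        chain = gemmi.Chain(ch_name)
        for resnum in sorted(by_chain[ch_name]):
            res = gemmi.Residue()
            if ch_name == "A":
                letter = fragment.sequence[resnum - 1]
                res.name = THREE_LETTER.get(letter, "ALA")
                b = plddt[fragment.to_global(resnum)]
            else:
                res.name = "ALA"
                b = receptor_plddt
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "A"
            for an, p in by_chain[ch_name][resnum]:
                atom = gemmi.Atom()
                atom.name = an
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*p)
                atom.b_iso = round(b, 2)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


@dataclass
class SyntheticDataset:
    """A generated bait, tiling, structure set and its exact ground truth."""

    out_dir: Path
    bait: BaitSequence
    fragments: List[FragmentSpec]
    manifest_path: Path
    bait_fasta_path: Path
    ground_truth_path: Path
    ground_truth: dict = field(repr=False, default=None)


def generate_dataset(
    out_dir: str | Path,
    L: int = 315,
    window: int = 50,
    step: int = 25,
    receptor_length: int = DEFAULT_RECEPTOR_LENGTH,
    plants: Optional[Sequence[PlantSpec]] = None,
    seed: int = 0,
    tail_policy: str = "anchor_tail",
    bait: Optional[BaitSequence] = None,
) -> SyntheticDataset:
    """Generate one structure per tiled fragment plus manifest and truth.

    Each fragment uses the plant whose segment overlaps it (fragments
    overlapping no planted segment still receive decoys from the first
    plant).  All per-fragment randomness derives from ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if plants is None:
        plants = (
            PlantSpec(DEFAULT_PLANTED_N),
            PlantSpec(DEFAULT_PLANTED_C),
        )
    if bait is None:
        bait = generate_bait(L, seed)
    elif bait.length != L:
        raise ValueError(
            f"provided bait length {bait.length} != requested L {L}"
        )
    fragments = tile_sequence(bait, window=window, step=step,
                              tail_policy=tail_policy)

    bait_fasta = out_dir / "bait.fasta"
    with open(bait_fasta, "w") as fh:
        fh.write(f">{bait.id}\n{bait.sequence}\n")

    rows: List[ManifestRow] = []
    truth_contacts: Dict[str, List[List[int]]] = {}
    truth_decoys: Dict[str, List[List[int]]] = {}
    for idx, frag in enumerate(fragments):
        overlapping = [
            p for p in plants
            if p.planted_segment[0] <= frag.end
            and p.planted_segment[1] >= frag.start
        ]
        plant = overlapping[0] if overlapping else plants[0]
        frag_seed = (seed * 1000003 + idx * 7919 + plant.seed) % (2**31 - 1)
        gen = generate_complex(
            frag, receptor_length, replace(plant, seed=frag_seed),
            warn_no_overlap=False,
        )
        pdb_path = out_dir / f"{frag.fragment_id}.pdb"
        pdb_path.write_text(gen.pdb)
        rows.append(
            ManifestRow(
                fragment_id=frag.fragment_id,
                # relative to the manifest's own directory
                structure_path=Path(pdb_path.name),
                bait_chain="A",
                receptor_chain="B",
                global_start=frag.start,
            )
        )
        truth_contacts[frag.fragment_id] = sorted(
            list(p) for p in gen.contact_pairs
        )
        truth_decoys[frag.fragment_id] = sorted(
            list(p) for p in gen.decoy_pairs
        )

    manifest_path = out_dir / "manifest.tsv"
    write_manifest(rows, manifest_path)

    ground_truth = {
        "seed": seed,
        "L": L,
        "window": window,
        "step": step,
        "receptor_length": receptor_length,
        "tail_policy": tail_policy,
        "planted_segments": [list(p.planted_segment) for p in plants],
        "plants": [
            {
                "planted_segment": list(p.planted_segment),
                "contact_density": p.contact_density,
                "decoy_rate": p.decoy_rate,
                "planted_plddt": p.planted_plddt,
                "background_plddt": p.background_plddt,
                "plddt_noise_sd": p.plddt_noise_sd,
                "coordinate_noise_sd": p.coordinate_noise_sd,
            }
            for p in plants
        ],
        "contacts": truth_contacts,
        "decoys": truth_decoys,
    }
    ground_truth_path = out_dir / "ground_truth.json"
    with open(ground_truth_path, "w") as fh:
        json.dump(ground_truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return SyntheticDataset(
        out_dir=out_dir,
        bait=bait,
        fragments=fragments,
        manifest_path=manifest_path,
        bait_fasta_path=bait_fasta,
        ground_truth_path=ground_truth_path,
        ground_truth=ground_truth,
    )
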