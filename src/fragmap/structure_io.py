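"""Parsing of predicted two-chain complex structures (PDB/mmCIF via gemmi).

Predicted complexes in the AlphaFold style carry per-residue model confidence
(pLDDT, 0-100) in the atomic B-factor column, and number each chain from 1.
This module extracts the two chains of interest as plain atom records, reads
pLDDT per bait residue, and maps the bait chain's file-local numbering onto
the bait's global coordinate frame using the manifest's ``global_start`` —
the manifest, not the file, is the numbering authority.

Filtering rules: hydrogens, waters and non-amino-acid heteroatoms are
excluded; alternate locations are resolved to the highest-occupancy atom
(ties to the first encountered); only the first model of an ensemble is read.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import gemmi

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ComplexStructure",
    "ManifestRow",
    "parse_complex",
    "extract_plddt",
    "read_manifest",
    "write_manifest",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = (
    "fragment_id",
    "structure_path",
    "bait_chain",
    "receptor_chain",
    "global_start",
)


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a polymer residue."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: Tuple[float, float, float]
    b_factor: float


@dataclass
class ComplexStructure:
    """A parsed two-chain predicted complex.

    ``global_start`` anchors the bait chain: its first (lowest-numbered)
    residue corresponds to global bait residue ``global_start``.
    """

    fragment_id: str
    bait_chain: str
    receptor_chain: str
    atoms: List[AtomRecord]
    global_start: int
    _first_local: Dict[str, int] = field(default_factory=dict, repr=False)

    def chain_atoms(self, chain_id: str) -> List[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def residue_atoms(self, chain_id: str) -> Dict[int, List[AtomRecord]]:
        """Atoms grouped by file-local residue number, in residue order."""
        grouped: Dict[int, List[AtomRecord]] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                grouped.setdefault(a.residue_number, []).append(a)
        return dict(sorted(grouped.items()))

    def _bait_first_local(self) -> int:
        if self.bait_chain not in self._first_local:
            nums = [
                a.residue_number
                for a in self.atoms
                if a.chain_id == self.bait_chain
            ]
            if not nums:
                raise ValueError(
                    f"{self.fragment_id}: bait chain {self.bait_chain!r} "
                    "has no atoms"
                )
            self._first_local[self.bait_chain] = min(nums)
        return self._first_local[self.bait_chain]

    def local_to_global(self, local_residue: int) -> int:
        """Map a bait-chain file-local residue number to the global frame."""
        return self.global_start + (local_residue - self._bait_first_local())

    def global_to_local(self, global_residue: int) -> int:
        return global_residue - self.global_start + self._bait_first_local()


def _collect_chain_atoms(
    chain: gemmi.Chain, chain_id: str
) -> List[AtomRecord]:
    """Heavy polymer atoms of one chain, altlocs resolved by occupancy."""
    records: List[AtomRecord] = []
    for residue in chain:
        if residue.is_water():
            continue
        info = gemmi.find_tabulated_residue(residue.name)
        if info is not None and not info.is_amino_acid():
            continue
        # pick one atom per atom name: highest occupancy, ties first seen
        best: Dict[str, gemmi.Atom] = {}
        for atom in residue:
            if atom.element.is_hydrogen:
                continue
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                best[atom.name] = atom
        for atom in best.values():
            records.append(
                AtomRecord(
                    chain_id=chain_id,
                    residue_number=residue.seqid.num,
                    residue_name=residue.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    b_factor=atom.b_iso,
                )
            )
    return records


def parse_complex(
    path: str | Path,
    bait_chain: str,
    receptor_chain: str,
    global_start: int,
    format: str = "auto",
    fragment_id: str | None = None,
) -> ComplexStructure:
    """Parse a predicted two-chain complex from PDB or mmCIF.

    Only the two named chains are retained (others are ignored with a
    warning); hydrogens, waters and non-amino-acid residues are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown structure format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse structure file {path}: {exc}")

    if len(st) == 0:
        raise ValueError(f"{path}: structure contains no models")
    if len(st) > 1:
        logger.warning(
            "%s: %d models present, using the first only", path, len(st)
        )
    model = st[0]

    chain_ids = [ch.name for ch in model]
    for wanted in (bait_chain, receptor_chain):
        if wanted not in chain_ids:
            raise ValueError(
                f"{path}: chain {wanted!r} not found "
                f"(available: {sorted(set(chain_ids))})"
            )
    extra = sorted(set(chain_ids) - {bait_chain, receptor_chain})
    if extra:
        logger.warning("%s: ignoring extra chains %s", path, extra)

    atoms: List[AtomRecord] = []
    for chain in model:
        if chain.name in (bait_chain, receptor_chain):
            atoms.extend(_collect_chain_atoms(chain, chain.name))
    if not atoms:
        raise ValueError(f"{path}: no atoms left after filtering")
    for wanted in (bait_chain, receptor_chain):
        if not any(a.chain_id == wanted for a in atoms):
            raise ValueError(
                f"{path}: chain {wanted!r} has no polymer heavy atoms"
            )

    return ComplexStructure(
        fragment_id=fragment_id or path.stem,
        bait_chain=bait_chain,
        receptor_chain=receptor_chain,
        atoms=atoms,
        global_start=global_start,
    )


def extract_plddt(
    structure: ComplexStructure, chain: str, mode: str = "ca"
) -> Dict[int, float]:
    """Per-residue pLDDT from B-factors, keyed by file-local residue number.

    ``mode='ca'`` reads the CA atom's B-factor (AlphaFold writes the same
    pLDDT on every atom of a residue, so this matches the per-residue value);
    a residue without CA falls back to the mean over its atoms.
    ``mode='atom_mean'`` averages B-factors over all of a residue's atoms.
    Values outside [0, 100] are passed through with a warning.
    """
    if mode not in ("ca", "atom_mean"):
        raise ValueError(f"unknown pLDDT mode {mode!r}")
    grouped = structure.residue_atoms(chain)
    if not grouped:
        raise ValueError(
            f"{structure.fragment_id}: chain {chain!r} not present"
        )
    plddt: Dict[int, float] = {}
    for resnum, atoms in grouped.items():
        if not atoms:
            logger.warning(
                "%s: residue %d has no atoms, skipped",
                structure.fragment_id,
                resnum,
            )
            continue
        if mode == "ca":
            ca = [a for a in atoms if a.atom_name == "CA"]
            value = (
                ca[0].b_factor
                if ca
                else sum(a.b_factor for a in atoms) / len(atoms)
            )
        else:
            value = sum(a.b_factor for a in atoms) / len(atoms)
        if not (0.0 <= value <= 100.0):
            logger.warning(
                "%s: residue %d pLDDT %.2f outside [0, 100]",
                structure.fragment_id,
                resnum,
                value,
            )
        plddt[resnum] = value
    return plddt


@dataclass(frozen=True)
class ManifestRow:
    fragment_id: str
    structure_path: Path
    bait_chain: str
    receptor_chain: str
    global_start: int


def read_manifest(path: str | Path) -> List[ManifestRow]:
    """Read manifest.tsv mapping fragments to structure files.

    The header must be exactly: fragment_id, structure_path, bait_chain,
    receptor_chain, global_start.  Relative structure paths are resolved
    against the manifest's directory.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"manifest {path} is empty")
        if tuple(header) != MANIFEST_COLUMNS:
            raise ValueError(
                f"manifest {path}: header must be "
                f"{list(MANIFEST_COLUMNS)}, got {header}"
            )
        rows: List[ManifestRow] = []
        seen = set()
        for lineno, fields in enumerate(reader, start=2):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if len(fields) != len(MANIFEST_COLUMNS):
                raise ValueError(
                    f"manifest {path} line {lineno}: expected "
                    f"{len(MANIFEST_COLUMNS)} columns, got {len(fields)}"
                )
            frag_id, struct_path, bait_ch, rec_ch, g_start = fields
            if frag_id in seen:
                raise ValueError(
                    f"manifest {path}: duplicate fragment_id {frag_id!r}"
                )
            seen.add(frag_id)
            sp = Path(struct_path)
            if not sp.is_absolute():
                sp = path.parent / sp
            rows.append(
                ManifestRow(
                    fragment_id=frag_id,
                    structure_path=sp,
                    bait_chain=bait_ch,
                    receptor_chain=rec_ch,
                    global_start=int(g_start),
                )
            )
    return rows


def write_manifest(rows: Sequence[ManifestRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.fragment_id}\t{r.structure_path}\t{r.bait_chain}\t"
                f"{r.receptor_chain}\t{r.global_start}\n"
            )
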