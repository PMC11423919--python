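"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fragmap.pipeline import RunConfig, run_synthetic
from fragmap.structure_io import AtomRecord, ComplexStructure

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def brute_force_contact_pairs(
    structure: ComplexStructure, cutoff: float
) -> Dict[Tuple[int, int], Tuple[int, float]]:
    """Exhaustive all-pairs inter-chain contact oracle.

    Independent of the package's KD-tree search: a plain double loop over
    heavy atoms using math.dist.  Returns (bait_global, receptor_local) ->
    (atom pair count, min distance).
    """
    bait = [a for a in structure.atoms
            if a.chain_id == structure.bait_chain]
    rec = [a for a in structure.atoms
           if a.chain_id == structure.receptor_chain]
    pairs: Dict[Tuple[int, int], Tuple[int, float]] = {}
    for a in bait:
        ga = structure.local_to_global(a.residue_number)
        for b in rec:
            d = math.dist(a.position, b.position)
            if d <= cutoff:
                n, dmin = pairs.get((ga, b.residue_number),
                                    (0, math.inf))
                pairs[(ga, b.residue_number)] = (n + 1, min(dmin, d))
    return pairs


def make_structure(
    bait_atoms: List[Tuple[int, str, Tuple[float, float, float], float]],
    receptor_atoms: List[Tuple[int, str, Tuple[float, float, float], float]],
    global_start: int = 1,
    fragment_id: str = "test",
) -> ComplexStructure:
    """Build a ComplexStructure from (resnum, atom_name, xyz, b) tuples."""
    atoms = [
        AtomRecord("A", r, "ALA", name, "C", pos, b)
        for r, name, pos, b in bait_atoms
    ] + [
        AtomRecord("B", r, "ALA", name, "C", pos, b)
        for r, name, pos, b in receptor_atoms
    ]
    return ComplexStructure(
        fragment_id=fragment_id,
        bait_chain="A",
        receptor_chain="B",
        atoms=atoms,
        global_start=global_start,
    )


def random_complex(
    rng: np.random.Generator,
    max_atoms_per_chain: int = 300,
    box: float = 40.0,
    max_residues: int = 30,
) -> ComplexStructure:
    """Random two-chain point cloud in a cubic box for oracle tests."""

    def chain(chain_id: str) -> List[AtomRecord]:
        n = int(rng.integers(1, max_atoms_per_chain + 1))
        xyz = rng.uniform(0.0, box, size=(n, 3))
        res = rng.integers(1, max_residues + 1, size=n)
        return [
            AtomRecord(chain_id, int(r), "ALA", f"C{i}", "C",
                       tuple(p), 80.0)
            for i, (r, p) in enumerate(zip(res, xyz), 1)
        ]

    return ComplexStructure(
        fragment_id="random",
        bait_chain="A",
        receptor_chain="B",
        atoms=chain("A") + chain("B"),
        global_start=1,
    )


N_RECOVERY_SEEDS = 20


@pytest.fixture(scope="session")
def clean_runs(tmp_path_factory):
    """Default-condition synthetic runs (no decoys, uniform pLDDT 80)."""
    base = tmp_path_factory.mktemp("clean_runs")
    return {
        seed: run_synthetic(RunConfig(seed=seed), base / str(seed))
        for seed in range(N_RECOVERY_SEEDS)
    }


@pytest.fixture(scope="session")
def stressed_runs(tmp_path_factory):
    """Stressed synthetic runs: 5% decoy rate and noisy pLDDT."""
    base = tmp_path_factory.mktemp("stressed_runs")
    return {
        seed: run_synthetic(
            RunConfig(seed=seed),
            base / str(seed),
            decoy_rate=0.05,
            plddt_noise_sd=5.0,
        )
        for seed in range(N_RECOVERY_SEEDS)
    }
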