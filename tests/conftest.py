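import logging

import numpy as np
import pytest

from thermodesign.fixtures import (
    FixtureSpec,
    build_assembly,
    build_chain,
    build_salt_bridge_toy,
)
from thermodesign import mpnn_core as mc


@pytest.fixture(scope="session")
def helix20():
    return build_chain(FixtureSpec(n_res=20, secondary="helix", seed=7))


@pytest.fixture(scope="session")
def polyala_helix20():
    return build_chain(FixtureSpec(n_res=20, secondary="helix",
                                   sequence="A" * 20, seed=0))


@pytest.fixture(scope="session")
def two_chain_assembly():
    """Two 14-residue helices at a controlled 7 A minimum CB separation."""
    return build_assembly(
        FixtureSpec(n_res=14, secondary="helix", chains=2, seed=3),
        min_cb_distance=7.0)


@pytest.fixture(scope="session")
def salt_bridge_toy_two_pairs():
    return build_salt_bridge_toy([("K", "D", 3.0), ("R", "E", 5.0)], seed=0)


@pytest.fixture(scope="session")
def tiny_model():
    """Random-initialised small network; adequate for contract tests that do
    not need trained weights (determinism, masking, normalisation)."""
    cfg = mc.TrainConfig(hidden_dim=32, k_neighbors=10, seed=0)
    return mc.InverseFoldingModel(cfg)


@pytest.fixture(scope="session")
def memorization_run():
    """One full memorization training run shared by the tests that probe
    convergence behaviour."""
    from thermodesign.benchmarks import run_memorization

    logging.disable(logging.WARNING)
    try:
        weights, log, structures = run_memorization(seed=11)
    finally:
        logging.disable(logging.NOTSET)
    return weights, log, structures


def rigid_transform(rng: np.random.Generator):
    """Random proper rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    shift = rng.normal(scale=20.0, size=3)
    return rot, shift


def apply_rigid(structure, rot, shift):
    """Return a rigidly moved deep copy of a structure."""
    import copy

    moved = copy.deepcopy(structure)
    for _, res in moved.residues():
        res.n_xyz = rot @ res.n_xyz + shift
        res.ca_xyz = rot @ res.ca_xyz + shift
        res.c_xyz = rot @ res.c_xyz + shift
        res.o_xyz = rot @ res.o_xyz + shift
        if res.cb_xyz is not None:
            res.cb_xyz = rot @ res.cb_xyz + shift
        res.sidechain_atoms = {k: rot @ v + shift
                               for k, v in res.sidechain_atoms.items()}
    return moved


def monte_carlo_sasa(structure, n_points_total: int = 1_000_000,
                     probe: float = 1.4, seed: int = 0) -> float:
    """Independent Monte-Carlo estimate of total SASA.

    Uniform random directions on each atom's solvent-extended sphere; a point
    counts as accessible when it lies outside every other atom's extended
    sphere. Same radii and decomposition as the package implementation, but
    random sampling instead of a deterministic lattice.
    """
    from thermodesign.metrics import _atom_radius

    coords, radii = [], []
    for _, res in structure.residues():
        for name, xyz in res.heavy_atoms().items():
            coords.append(xyz)
            radii.append(_atom_radius(name))
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    extended = radii + probe
    n_atoms = len(coords)
    per_atom = max(1, n_points_total // n_atoms)
    rng = np.random.default_rng(seed)
    total = 0.0
    for i in range(n_atoms):
        dirs = rng.normal(size=(per_atom, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        points = coords[i] + extended[i] * dirs
        accessible = np.ones(per_atom, dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            d2 = ((points - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > extended[j] ** 2
        total += 4.0 * np.pi * extended[i] ** 2 * accessible.mean()
    return total


def brute_force_salt_bridges(structure, cutoff: float,
                             his_basic: bool = True) -> int:
    """All-pairs scan over charged-group atoms, counting residue pairs."""
    from thermodesign.metrics import ACIDIC_OXYGENS, BASIC_NITROGENS

    basic_letters = "RKH" if his_basic else "RK"
    pairs = set()
    residues = list(structure.residues())
    for i, (_, ri) in enumerate(residues):
        if ri.aa not in basic_letters:
            continue
        n_atoms = [xyz for name, xyz in ri.sidechain_atoms.items()
                   if name in BASIC_NITROGENS[ri.aa]]
        for j, (_, rj) in enumerate(residues):
            if rj.aa not in "DE":
                continue
            o_atoms = [xyz for name, xyz in rj.sidechain_atoms.items()
                       if name in ACIDIC_OXYGENS[rj.aa]]
            for n in n_atoms:
                for o in o_atoms:
                    if np.linalg.norm(n - o) <= cutoff:
                        pairs.add((i, j))
    return len(pairs)


def brute_force_contact_order(structure, cutoff: float, min_sep: int) -> float:
    """Direct double loop over residue pairs and their heavy atoms."""
    seps = []
    for chain in structure.chains:
        residues = chain.residues
        for i in range(len(residues)):
            for j in range(len(residues)):
                if j - i < min_sep:
                    continue
                dmin = min(
                    np.linalg.norm(a - b)
                    for a in residues[i].heavy_atoms().values()
                    for b in residues[j].heavy_atoms().values())
                if dmin <= cutoff:
                    seps.append(j - i)
    return float(np.mean(seps)) if seps else 0.0


def brute_force_interface(structure, target_chain: str, partner_chains,
                          cutoff: float) -> set[int]:
    from thermodesign.structio import infer_cb

    target = structure.chain(target_chain).residues
    partners = [r for pid in partner_chains
                for r in structure.chain(pid).residues]
    out = set()
    for i, res in enumerate(target):
        for p in partners:
            if np.linalg.norm(infer_cb(res) - infer_cb(p)) <= cutoff:
                out.add(i)
                break
    return out
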