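"""Deterministic synthetic protein structures with known geometric properties.

Chains are built atom-by-atom with ideal bond lengths and angles (natural
extension reference frames), so every generated coordinate is an exact
function of the requested backbone dihedrals and the seed. Side chains are
generated only for the charged residues the electrostatics metrics need
(Arg, Lys, His, Asp, Glu); everything else is backbone + CB. The generators
make no claim of physical-energy realism — they exist so that geometry-level
code (SASA, salt bridges, interfaces, featurization) can be tested against
brute-force oracles without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from thermodesign.structio import (
    ALPHABET,
    BackboneStructure,
    ChainRecord,
    ResidueRecord,
)

# ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.52
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_CA_CB = 110.1
OMEGA = 180.0

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "coil": (-75.0, 150.0),
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given predecessors A-B-C, the C-D bond length, the B-C-D
    angle and the A-B-C-D torsion (natural extension reference frame)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class FixtureSpec:
    """Recipe for a synthetic structure; the seed fully determines the output."""

    n_res: int = 20
    secondary: str = "helix"
    chains: int = 1
    chain_separation: float = 20.0
    sequence: str = "random"
    seed: int = 0
    plddt_profile: float | list[float] | None = None

    def __post_init__(self) -> None:
        if self.n_res < 2:
            raise ValueError("n_res must be >= 2")
        if self.secondary not in PHI_PSI:
            raise ValueError(
                f"unknown secondary structure {self.secondary!r}; "
                f"expected one of {sorted(PHI_PSI)}")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")


def _build_backbone(n_res: int, phi: float, psi: float) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O/CB coordinate arrays for one chain of ideal geometry."""
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    CB = np.zeros((n_res, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    # first C placed off-axis to define the initial frame
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi)
    for i in range(n_res):
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        CB[i] = place_atom(N[i], C[i], CA[i], BOND_CA_CB, ANGLE_C_CA_CB, 122.6)
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


CHARGED_TERMINAL = {
    # residue -> (intermediate atom names, charged-group atom names)
    "K": (["CG", "CD", "CE"], ["NZ"]),
    "R": (["CG", "CD", "NE", "CZ"], ["NH1", "NH2"]),
    "H": (["CG", "CD2"], ["ND1", "NE2"]),
    "D": (["CG"], ["OD1", "OD2"]),
    "E": (["CG", "CD"], ["OE1", "OE2"]),
}


def _extend_sidechain(aa: str, ca: np.ndarray, cb: np.ndarray,
                      tip: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Simplified extended side chain for a charged residue.

    Atoms march from CB toward ``tip`` (default: straight out along CA->CB) in
    1.5 A steps; the charged-group atoms sit at the end, split laterally by
    0.6 A when the group has two equivalent atoms.
    """
    if aa not in CHARGED_TERMINAL:
        return {}
    chain_atoms, terminal = CHARGED_TERMINAL[aa]
    direction = (cb - ca) if tip is None else (tip - cb)
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise ValueError("degenerate side-chain direction")
    direction = direction / norm
    # lateral unit vector for branching, orthogonal to direction
    ref = np.array([0.0, 0.0, 1.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    lateral = np.cross(direction, ref)
    lateral /= np.linalg.norm(lateral)

    atoms: dict[str, np.ndarray] = {}
    pos = cb.copy()
    for name in chain_atoms:
        pos = pos + 1.5 * direction
        atoms[name] = pos.copy()
    end = tip if tip is not None else pos + 1.5 * direction
    if len(terminal) == 1:
        atoms[terminal[0]] = end.copy()
    else:
        atoms[terminal[0]] = end.copy()
        atoms[terminal[1]] = end + 0.6 * lateral
    return atoms


def _make_residues(coords: dict[str, np.ndarray], sequence: str,
                   plddt: list[float] | None,
                   with_sidechains: bool = True) -> list[ResidueRecord]:
    residues = []
    for i, aa in enumerate(sequence):
        side = {}
        cb = None if aa == "G" else coords["CB"][i]
        if with_sidechains and aa in CHARGED_TERMINAL and cb is not None:
            side = _extend_sidechain(aa, coords["CA"][i], cb)
        residues.append(ResidueRecord(
            aa=aa, resnum=i + 1,
            n_xyz=coords["N"][i].copy(), ca_xyz=coords["CA"][i].copy(),
            c_xyz=coords["C"][i].copy(), o_xyz=coords["O"][i].copy(),
            cb_xyz=None if cb is None else cb.copy(),
            sidechain_atoms=side,
            confidence=None if plddt is None else float(plddt[i]),
        ))
    return residues


def _resolve_plddt(spec: FixtureSpec) -> list[float] | None:
    if spec.plddt_profile is None:
        return None
    if np.isscalar(spec.plddt_profile):
        return [float(spec.plddt_profile)] * spec.n_res
    profile = [float(v) for v in spec.plddt_profile]
    if len(profile) != spec.n_res:
        raise ValueError("plddt_profile length must equal n_res")
    return profile


# residue propensities by secondary structure: 75% of the probability mass on
# the favoured set, the rest uniform — gives synthetic sequence/structure
# pairs a learnable signal, like real proteins
_PROPENSITY_SETS = {"helix": "AELKQRM", "strand": "VIFYTWL", "coil": "GPSNDTK"}


def _propensity_sequence(secondary: str, n_res: int,
                         rng: np.random.Generator) -> str:
    favoured = _PROPENSITY_SETS[secondary]
    p = np.full(len(ALPHABET), 0.25 / len(ALPHABET))
    for aa in favoured:
        p[ALPHABET.index(aa)] += 0.75 / len(favoured)
    p /= p.sum()
    return "".join(rng.choice(list(ALPHABET), size=n_res, p=p))


def _resolve_sequence(spec: FixtureSpec, rng: np.random.Generator) -> str:
    if spec.sequence == "random":
        return "".join(rng.choice(list(ALPHABET), size=spec.n_res))
    if spec.sequence == "propensity":
        return _propensity_sequence(spec.secondary, spec.n_res, rng)
    if len(spec.sequence) != spec.n_res:
        raise ValueError("explicit sequence length must equal n_res")
    return spec.sequence


def build_chain(spec: FixtureSpec, id: str | None = None) -> BackboneStructure:
    """Build a structure of ``spec.chains`` identical-geometry chains with the
    requested secondary structure; chain k is translated by
    ``k * chain_separation`` along x."""
    rng = np.random.default_rng(spec.seed)
    phi, psi = PHI_PSI[spec.secondary]
    coords = _build_backbone(spec.n_res, phi, psi)
    plddt = _resolve_plddt(spec)
    chains = []
    for k in range(spec.chains):
        sequence = _resolve_sequence(spec, rng)
        offset = np.array([k * spec.chain_separation, 0.0, 0.0])
        shifted = {name: xyz + offset for name, xyz in coords.items()}
        chains.append(ChainRecord(
            chain_id=chr(ord("A") + k),
            residues=_make_residues(shifted, sequence, plddt),
        ))
    source = "predicted" if plddt is not None else "experimental"
    structure = BackboneStructure(
        id=id or f"fixture-{spec.secondary}-{spec.n_res}x{spec.chains}-s{spec.seed}",
        chains=chains, source=source)
    structure.validate()
    return structure


def build_salt_bridge_toy(pairs: list[tuple[str, str, float]],
                          seed: int = 0) -> BackboneStructure:
    """Extended chain whose only charged groups are the requested
    (basic, acidic, N-O distance) pairs.

    Each pair's basic side-chain nitrogen is placed exactly at the requested
    distance from one carboxylate oxygen of its partner; charged groups of
    different pairs are separated by > 8 A. Residues not involved in a pair
    are alanine.
    """
    for basic, acidic, dist in pairs:
        if basic not in ("K", "R", "H"):
            raise ValueError(f"basic residue must be K/R/H, got {basic!r}")
        if acidic not in ("D", "E"):
            raise ValueError(f"acidic residue must be D/E, got {acidic!r}")
        if not (0.5 <= dist <= 8.0):
            raise ValueError(
                f"infeasible N-O distance {dist} A (supported range 0.5-8)")

    spacing = 10  # residues between pairs; extended rise ~3.45 A/res keeps groups apart
    n_res = max(4, spacing * len(pairs) + 4)
    phi, psi = PHI_PSI["strand"]
    coords = _build_backbone(n_res, phi, psi)
    sequence = ["A"] * n_res
    residues = _make_residues(coords, "".join(sequence), None, with_sidechains=False)

    for p, (basic, acidic, dist) in enumerate(pairs):
        i = spacing * p        # basic residue index
        j = i + 2              # acidic partner, same face of the strand
        residues[i].aa = basic
        residues[j].aa = acidic
        mid = 0.5 * (residues[i].cb_xyz + residues[j].cb_xyz)
        # charged groups hover above the strand plane between the two CBs
        normal = np.array([0.0, 0.0, 4.0])
        axis = residues[j].cb_xyz - residues[i].cb_xyz
        axis /= np.linalg.norm(axis)
        n_pos = mid + normal - 0.5 * dist * axis
        o_pos = mid + normal + 0.5 * dist * axis
        basic_atoms = _extend_sidechain(
            basic, residues[i].ca_xyz, residues[i].cb_xyz, tip=n_pos)
        acidic_atoms = _extend_sidechain(
            acidic, residues[j].ca_xyz, residues[j].cb_xyz, tip=o_pos)
        # lateral twins (NH2/OD2/OE2/NE2) may fall closer than the requested
        # distance; push them away along the strand axis instead
        _, basic_terminal = CHARGED_TERMINAL[basic]
        _, acidic_terminal = CHARGED_TERMINAL[acidic]
        for extra in basic_terminal[1:]:
            basic_atoms[extra] = n_pos - 1.0 * axis
        for extra in acidic_terminal[1:]:
            acidic_atoms[extra] = o_pos + 1.0 * axis
        residues[i].sidechain_atoms = basic_atoms
        residues[j].sidechain_atoms = acidic_atoms

    structure = BackboneStructure(
        id=f"saltbridge-toy-{len(pairs)}p-s{seed}",
        chains=[ChainRecord(chain_id="A", residues=residues)])
    structure.validate()
    return structure


def min_interchain_cb_distance(structure: BackboneStructure,
                               chain_a: str, chain_b: str) -> float:
    """Brute-force minimum CB-CB distance between two chains (virtual CB for
    glycine)."""
    from thermodesign.structio import infer_cb
    cbs_a = np.array([infer_cb(r) for r in structure.chain(chain_a).residues])
    cbs_b = np.array([infer_cb(r) for r in structure.chain(chain_b).residues])
    diff = cbs_a[:, None, :] - cbs_b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).min())


def build_assembly(spec: FixtureSpec, min_cb_distance: float | None = None,
                   id: str | None = None) -> BackboneStructure:
    """Multi-chain assembly with a controllable minimum inter-chain CB
    distance between consecutive chains (bisection on the translation axis,
    converged to 0.01 A)."""
    if spec.chains < 2:
        raise ValueError("an assembly needs >= 2 chains")
    structure = build_chain(spec, id=id)
    if min_cb_distance is None:
        return structure

    base = build_chain(FixtureSpec(
        n_res=spec.n_res, secondary=spec.secondary, chains=1,
        sequence=spec.sequence, seed=spec.seed,
        plddt_profile=spec.plddt_profile))

    def shift_chain(chain_idx: int, x_offset: float) -> None:
        ref = base.chains[0].residues
        target = structure.chains[chain_idx].residues
        offset = np.array([x_offset, 0.0, 0.0])
        for res, ref_res in zip(target, ref):
            res.n_xyz = ref_res.n_xyz + offset
            res.ca_xyz = ref_res.ca_xyz + offset
            res.c_xyz = ref_res.c_xyz + offset
            res.o_xyz = ref_res.o_xyz + offset
            if ref_res.cb_xyz is not None:
                res.cb_xyz = ref_res.cb_xyz + offset
            res.sidechain_atoms = {
                name: xyz + offset for name, xyz in ref_res.sidechain_atoms.items()}

    for k in range(1, spec.chains):
        prev_id = structure.chains[k - 1].chain_id
        this_id = structure.chains[k].chain_id
        prev_offset = (k - 1) * spec.chain_separation

        def gap(x: float) -> float:
            shift_chain(k, prev_offset + x)
            return min_interchain_cb_distance(structure, prev_id, this_id) - min_cb_distance

        lo, hi = 0.1, 200.0
        if gap(lo) > 0:
            raise ValueError("cannot reach requested min CB distance: chains too small")
        for _ in range(60):
            mid_x = 0.5 * (lo + hi)
            if gap(mid_x) < 0:
                lo = mid_x
            else:
                hi = mid_x
        gap(hi)
    structure.validate()
    return structure
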