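"""Structural thermo-adaptation analytics.

The quantities that distinguish hyperthermophile proteins from mesophile
ones, computed per structure and aggregated over sets:

* per-residue solvent-accessible surface area (Shrake-Rupley) and the
  surface/core classification at a 30 A^2 threshold;
* amino-acid class composition per region (positively/negatively charged,
  polar, apolar, other) and between-set composition differences;
* sequence net charge at a given pH and isoelectric point
  (Henderson-Hasselbalch summation over titratable groups);
* salt bridges (basic side-chain nitrogen within a distance cutoff of an
  acidic carboxylate oxygen);
* absolute contact order and radius of gyration.

Charged side-chain geometry is taken from the structure when present; for
backbone-only inputs the salt-bridge count falls back to a documented
CB-proxy (charged-pair CB-CB distance), flagged approximate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from thermodesign.structio import (
    ALPHABET,
    BackboneStructure,
    infer_cb,
    validate_sequence,
)

logger = logging.getLogger(__name__)


@dataclass
class MetricsConfig:
    sasa_threshold: float = 30.0        # A^2, surface/core split
    probe_radius: float = 1.4           # A, water probe
    sasa_points: int = 960              # sphere points per atom
    salt_bridge_cutoff: float = 4.0     # A, N-O distance
    include_his_basic: bool = True
    cb_proxy_cutoff: float = 6.0        # A, CB-CB fallback for backbone-only input
    contact_cutoff: float = 6.0         # A, heavy-atom
    min_seq_separation: int = 3
    ph: float = 7.0

    def __post_init__(self) -> None:
        for name in ("sasa_threshold", "probe_radius", "sasa_points",
                     "salt_bridge_cutoff", "cb_proxy_cutoff",
                     "contact_cutoff", "min_seq_separation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# default residue class scheme; His sits in "other", not positively charged
DEFAULT_CLASS_SCHEME: dict[str, str] = {
    **{aa: "positively_charged" for aa in "RK"},
    **{aa: "negatively_charged" for aa in "DE"},
    **{aa: "polar" for aa in "NQST"},
    **{aa: "apolar" for aa in "ILMFWYV"},
    **{aa: "other" for aa in "ACGHP"},
}
CLASS_NAMES = ("positively_charged", "negatively_charged", "polar", "apolar", "other")


def validate_class_scheme(scheme: dict[str, str]) -> None:
    if sorted(scheme) != sorted(ALPHABET):
        raise ValueError("class scheme must cover exactly the 20 standard letters")
    unknown = {v for v in scheme.values()} - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown classes {unknown}")


# ---------------------------------------------------------------------------
# SASA

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


def _atom_radius(atom_name: str) -> float:
    return VDW_RADII[atom_name[0]]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere point set (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _collect_atoms(structure: BackboneStructure):
    coords, radii, owner = [], [], []
    for idx, (_, res) in enumerate(structure.residues()):
        for name, xyz in res.heavy_atoms().items():
            coords.append(xyz)
            radii.append(_atom_radius(name))
            owner.append(idx)
    if not coords:
        raise ValueError("structure has no atoms")
    return np.asarray(coords), np.asarray(radii), np.asarray(owner)


def sasa_of_spheres(coords: np.ndarray, radii: np.ndarray,
                    probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley SASA per input sphere.

    Each atom's solvent-extended sphere (r + probe) is sampled with a
    quasi-uniform point lattice; a point is accessible when outside every
    other atom's extended sphere. Returns one area per atom in A^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    extended = radii + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(coords))
    max_reach = extended.max()
    for i in range(len(coords)):
        points = coords[i] + extended[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], extended[i] + max_reach)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((points - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > extended[j] ** 2
        areas[i] = 4.0 * math.pi * extended[i] ** 2 * accessible.mean()
    return areas


def per_residue_sasa(structure: BackboneStructure,
                     cfg: MetricsConfig | None = None) -> dict[int, float]:
    """Map global residue index -> SASA (sum over the residue's atoms).

    Backbone-only structures are handled with backbone+CB atoms only and are
    therefore approximate; a warning is logged once per structure.
    """
    cfg = cfg or MetricsConfig()
    coords, radii, owner = _collect_atoms(structure)
    if all(not res.sidechain_atoms for _, res in structure.residues()):
        logger.warning("%s: no side-chain atoms; SASA computed on backbone+CB only",
                       structure.id)
    areas = sasa_of_spheres(coords, radii, cfg.probe_radius, cfg.sasa_points)
    result: dict[int, float] = {}
    for idx in range(structure.n_residues):
        result[idx] = float(areas[owner == idx].sum())
    return result


def classify_surface_core(sasa: dict[int, float],
                          cfg: MetricsConfig | None = None) -> dict[int, str]:
    """surface iff SASA strictly above the threshold; exact ties are core."""
    cfg = cfg or MetricsConfig()
    return {idx: ("surface" if a > cfg.sasa_threshold else "core")
            for idx, a in sasa.items()}


# ---------------------------------------------------------------------------
# composition


@dataclass
class CompositionTable:
    counts: pd.DataFrame        # index: letters, columns: surface/core, integer counts
    n_structures: int

    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts / totals.replace(0, np.nan)

    def class_frequencies(self, scheme: dict[str, str] | None = None) -> pd.DataFrame:
        scheme = scheme or DEFAULT_CLASS_SCHEME
        validate_class_scheme(scheme)
        freq = self.frequencies()
        grouped = freq.groupby(pd.Series(scheme)).sum()
        return grouped.reindex(CLASS_NAMES)


def composition(structures: list[BackboneStructure],
                cfg: MetricsConfig | None = None) -> CompositionTable:
    """Pooled surface/core residue counts over a set of structures."""
    cfg = cfg or MetricsConfig()
    counts = pd.DataFrame(0, index=list(ALPHABET), columns=["surface", "core"])
    for s in structures:
        region = classify_surface_core(per_residue_sasa(s, cfg), cfg)
        for idx, (_, res) in enumerate(s.residues()):
            counts.loc[res.aa, region[idx]] += 1
    return CompositionTable(counts=counts, n_structures=len(structures))


def composition_difference(a: CompositionTable, b: CompositionTable,
                           scheme: dict[str, str] | None = None) -> pd.DataFrame:
    """Signed per-class difference in percentage points (a minus b)."""
    fa = a.class_frequencies(scheme) * 100.0
    fb = b.class_frequencies(scheme) * 100.0
    return fa - fb


# ---------------------------------------------------------------------------
# charge

EMBOSS_PKA = {
    "N_term": 8.6, "C_term": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}


@dataclass
class ChargeModel:
    """Henderson-Hasselbalch charge model with a named, swappable pKa table."""

    pka: dict[str, float] = field(default_factory=lambda: dict(EMBOSS_PKA))
    name: str = "EMBOSS"
    titrate_cys: bool = True
    titrate_tyr: bool = True

    def __post_init__(self) -> None:
        for group, value in self.pka.items():
            if not (0.0 < value < 14.0):
                raise ValueError(f"pKa of {group} out of range: {value}")

    def positive_groups(self, sequence: str) -> list[float]:
        pkas = [self.pka["N_term"]]
        pkas += [self.pka[aa] for aa in sequence if aa in ("K", "R", "H")]
        return pkas

    def negative_groups(self, sequence: str) -> list[float]:
        pkas = [self.pka["C_term"]]
        for aa in sequence:
            if aa in ("D", "E"):
                pkas.append(self.pka[aa])
            elif aa == "C" and self.titrate_cys:
                pkas.append(self.pka["C"])
            elif aa == "Y" and self.titrate_tyr:
                pkas.append(self.pka["Y"])
        return pkas


def net_charge(sequence: str, ph: float = 7.0,
               model: ChargeModel | None = None) -> float:
    """Net charge of a free peptide at the given pH.

    Positive groups contribute 10^pKa / (10^pKa + 10^pH); negative groups
    contribute -10^pH / (10^pKa + 10^pH).
    """
    validate_sequence(sequence)
    model = model or ChargeModel()
    pos = sum(10 ** pka / (10 ** pka + 10 ** ph)
              for pka in model.positive_groups(sequence))
    neg = sum(-(10 ** ph) / (10 ** pka + 10 ** ph)
              for pka in model.negative_groups(sequence))
    return pos + neg


def isoelectric_point(sequence: str, model: ChargeModel | None = None) -> float:
    """pH at which the net charge vanishes (bisection to |z| < 1e-4)."""
    validate_sequence(sequence)
    model = model or ChargeModel()
    lo, hi = 0.0, 14.0
    z_lo = net_charge(sequence, lo, model)
    z_hi = net_charge(sequence, hi, model)
    if z_lo < 0 or z_hi > 0:
        raise ValueError("net charge does not change sign on pH 0-14")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        z = net_charge(sequence, mid, model)
        if abs(z) < 1e-4:
            return mid
        if z > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# salt bridges

BASIC_NITROGENS = {"R": ("NE", "NH1", "NH2"), "K": ("NZ",), "H": ("ND1", "NE2")}
ACIDIC_OXYGENS = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}


def count_salt_bridges(structure: BackboneStructure,
                       cfg: MetricsConfig | None = None) -> int:
    """Number of (basic, acidic) residue pairs with any basic side-chain
    nitrogen within ``salt_bridge_cutoff`` of any carboxylate oxygen; each
    residue pair is counted at most once.

    Structures without side-chain atoms on their charged residues fall back
    to the CB-proxy: a charged pair counts when the CB-CB distance is at
    most ``cb_proxy_cutoff`` (logged as approximate).
    """
    cfg = cfg or MetricsConfig()
    basic_letters = "RKH" if cfg.include_his_basic else "RK"

    basics, acidics = [], []
    has_sidechains = True
    for idx, (_, res) in enumerate(structure.residues()):
        if res.aa in basic_letters:
            names = BASIC_NITROGENS[res.aa]
            atoms = [res.sidechain_atoms[n] for n in names if n in res.sidechain_atoms]
            if not atoms:
                has_sidechains = False
            basics.append((idx, res, atoms))
        elif res.aa in "DE":
            names = ACIDIC_OXYGENS[res.aa]
            atoms = [res.sidechain_atoms[n] for n in names if n in res.sidechain_atoms]
            if not atoms:
                has_sidechains = False
            acidics.append((idx, res, atoms))
    if not basics or not acidics:
        return 0

    count = 0
    if has_sidechains:
        for bi, bres, batoms in basics:
            for ai, ares, aatoms in acidics:
                dmin = min(np.linalg.norm(n - o) for n in batoms for o in aatoms)
                if dmin <= cfg.salt_bridge_cutoff:
                    count += 1
    else:
        logger.warning("%s: charged side chains missing; using CB-proxy "
                       "(CB-CB <= %.1f A)", structure.id, cfg.cb_proxy_cutoff)
        for bi, bres, _ in basics:
            cb_b = infer_cb(bres)
            for ai, ares, _ in acidics:
                if np.linalg.norm(cb_b - infer_cb(ares)) <= cfg.cb_proxy_cutoff:
                    count += 1
    return count


# ---------------------------------------------------------------------------
# topology


def contact_order(structure: BackboneStructure,
                  cfg: MetricsConfig | None = None) -> float:
    """Absolute contact order: mean sequence separation |i-j| over same-chain
    residue pairs with any heavy-atom distance <= ``contact_cutoff`` and
    |i-j| >= ``min_seq_separation``. Returns 0 with a warning when the
    structure has no qualifying contacts."""
    cfg = cfg or MetricsConfig()
    total, n_contacts = 0, 0
    for chain in structure.chains:
        atom_sets = [np.asarray(list(r.heavy_atoms().values())) for r in chain.residues]
        n = len(chain.residues)
        for i in range(n):
            for j in range(i + cfg.min_seq_separation, n):
                diff = atom_sets[i][:, None, :] - atom_sets[j][None, :, :]
                if (np.einsum("ijk,ijk->ij", diff, diff).min()
                        <= cfg.contact_cutoff ** 2):
                    total += j - i
                    n_contacts += 1
    if n_contacts == 0:
        logger.warning("%s: no contacts at cutoff %.1f A; contact order 0",
                       structure.id, cfg.contact_cutoff)
        return 0.0
    return total / n_contacts


def radius_of_gyration(structure: BackboneStructure) -> float:
    """Unweighted RMS distance of CA atoms from their centroid, in A."""
    ca = np.array([r.ca_xyz for _, r in structure.residues()])
    centroid = ca.mean(axis=0)
    return float(np.sqrt(((ca - centroid) ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# reports


@dataclass
class MetricsReport:
    per_structure: pd.DataFrame   # index: structure id
    aggregate: pd.DataFrame       # median / q1 / q3 / iqr per metric


def aggregate_report(structures: list[BackboneStructure],
                     cfg: MetricsConfig | None = None) -> MetricsReport:
    """Per-structure net charge, pI, salt bridges, contact order and radius
    of gyration, with medians and interquartile ranges."""
    if not structures:
        raise ValueError("no structures to report on")
    cfg = cfg or MetricsConfig()
    rows = {}
    for s in structures:
        rows[s.id] = {
            "net_charge": net_charge(s.sequence, cfg.ph),
            "pI": isoelectric_point(s.sequence),
            "n_salt_bridges": count_salt_bridges(s, cfg),
            "contact_order": contact_order(s, cfg),
            "radius_of_gyration": radius_of_gyration(s),
        }
    per_structure = pd.DataFrame.from_dict(rows, orient="index")
    q1 = per_structure.quantile(0.25)
    q3 = per_structure.quantile(0.75)
    aggregate = pd.DataFrame({
        "median": per_structure.median(),
        "q1": q1, "q3": q3, "iqr": q3 - q1,
    })
    return MetricsReport(per_structure=per_structure, aggregate=aggregate)
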