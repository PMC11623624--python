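"""Dataset curation for training on predicted structures.

Three stages, mirroring how proteome-scale predicted-structure sets are
prepared for inverse-folding training:

1. confidence filtering — drop models whose mean per-residue pLDDT falls
   below a cutoff (default 70), optionally also requiring every residue to
   clear a local cutoff;
2. sequence clustering — greedy incremental clustering (longest-first,
   CD-HIT style) at a configurable identity/coverage threshold, or adoption
   of an externally computed representative->member table (mmseqs
   easy-cluster TSV dialect);
3. cluster-level splitting — train/validation/test assignment of whole
   clusters (never individual members), deterministic under a seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.sequence.align as align
from biotite.sequence import ProteinSequence

from thermodesign.structio import BackboneStructure, validate_sequence

logger = logging.getLogger(__name__)


@dataclass
class CurationConfig:
    plddt_mean_cutoff: float = 70.0
    plddt_local_cutoff: float | None = None  # disabled by default
    collection_identity: float = 0.50
    train_identity: float = 0.30
    coverage: float = 0.80

    def __post_init__(self) -> None:
        if not (0.0 <= self.plddt_mean_cutoff <= 100.0):
            raise ValueError("plddt_mean_cutoff must be in [0, 100]")
        for name in ("collection_identity", "train_identity", "coverage"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class ClusterSet:
    """Partition of sequence ids into clusters keyed by representative id."""

    clusters: dict[str, list[str]]
    method: str = "native_greedy"  # "native_greedy" | "external_tsv"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rep, members in self.clusters.items():
            if rep not in members:
                raise ValueError(f"representative {rep!r} not a member of its cluster")
            for m in members:
                if m in seen:
                    raise ValueError(f"id {m!r} appears in more than one cluster")
                seen.add(m)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_ids(self) -> set[str]:
        return {m for members in self.clusters.values() for m in members}


@dataclass
class SplitAssignment:
    train: set[str]
    validation: set[str]
    test: set[str]
    seed: int
    fractions: tuple[float, float, float] = (0.90, 0.06, 0.04)

    def __post_init__(self) -> None:
        buckets = [self.train, self.validation, self.test]
        for a in range(3):
            for b in range(a + 1, 3):
                if buckets[a] & buckets[b]:
                    raise ValueError("split buckets are not disjoint")


def filter_by_confidence(structures: list[BackboneStructure],
                         cfg: CurationConfig) -> tuple[list[BackboneStructure],
                                                       list[tuple[BackboneStructure, str]]]:
    """Keep structures whose mean pLDDT clears the cutoff (and, when the local
    cutoff is enabled, whose every residue clears it). Structures lacking
    confidence raise rather than passing silently."""
    kept, rejected = [], []
    for s in structures:
        mean = s.mean_confidence()  # raises on missing confidence
        if mean < cfg.plddt_mean_cutoff:
            rejected.append((s, "mean_plddt"))
            continue
        if cfg.plddt_local_cutoff is not None:
            local_min = min(r.confidence for _, r in s.residues())
            if local_min < cfg.plddt_local_cutoff:
                rejected.append((s, "local_plddt"))
                continue
        kept.append(s)
    assert len(kept) + len(rejected) == len(structures)
    return kept, rejected


# ---------------------------------------------------------------------------
# pairwise identity and greedy clustering

_IDENTITY_MATRIX = None


def _identity_matrix() -> align.SubstitutionMatrix:
    global _IDENTITY_MATRIX
    if _IDENTITY_MATRIX is None:
        alph = ProteinSequence.alphabet
        _IDENTITY_MATRIX = align.SubstitutionMatrix(
            alph, alph, np.eye(len(alph), dtype=np.int32))
    return _IDENTITY_MATRIX


def alignment_score(a: str, b: str) -> int:
    """Optimal global-alignment score under the clustering scoring scheme
    (match +1, mismatch 0, gap open -10 / extend -1, free terminal gaps)."""
    validate_sequence(a)
    validate_sequence(b)
    ali = align.align_optimal(
        ProteinSequence(a), ProteinSequence(b), _identity_matrix(),
        gap_penalty=(-10, -1), terminal_penalty=False, max_number=1)[0]
    return int(ali.score)


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Global alignment identity and coverage between two sequences.

    Scoring: match +1, mismatch 0, affine gaps (open -10, extend -1), free
    terminal gaps. Identity is matches over alignment columns excluding
    terminal-gap columns; coverage is aligned (residue-on-residue) columns
    over the shorter sequence length. The pair is canonically ordered before
    aligning so that the result is symmetric even when several co-optimal
    alignments exist.
    """
    validate_sequence(a)
    validate_sequence(b)
    if (len(b), b) < (len(a), a):
        a, b = b, a
    ali = align.align_optimal(
        ProteinSequence(a), ProteinSequence(b), _identity_matrix(),
        gap_penalty=(-10, -1), terminal_penalty=False, max_number=1)[0]
    trace = ali.trace  # (n_cols, 2); -1 marks a gap
    both = np.where((trace[:, 0] >= 0) & (trace[:, 1] >= 0))[0]
    if len(both) == 0:
        return 0.0, 0.0
    # columns outside the first/last aligned column are terminal gaps
    core = trace[both[0]: both[-1] + 1]
    matches = sum(
        1 for i, j in core
        if i >= 0 and j >= 0 and a[i] == b[j])
    identity = matches / len(core)
    coverage = len(both) / min(len(a), len(b))
    return float(identity), float(coverage)


def greedy_cluster(sequences: dict[str, str], identity_threshold: float,
                   coverage_threshold: float) -> ClusterSet:
    """Greedy incremental clustering: sequences are visited longest-first
    (ties by id) and join the first existing representative meeting both the
    identity and coverage thresholds, else found a new cluster."""
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    reps: list[str] = []
    clusters: dict[str, list[str]] = {}
    for sid in order:
        assigned = False
        for rep in reps:
            identity, coverage = pairwise_identity(sequences[rep], sequences[sid])
            if identity >= identity_threshold and coverage >= coverage_threshold:
                clusters[rep].append(sid)
                assigned = True
                break
        if not assigned:
            reps.append(sid)
            clusters[sid] = [sid]
    result = ClusterSet(clusters=clusters, method="native_greedy")
    assert result.member_ids() == set(sequences)
    return result


def read_clusters_tsv(path) -> ClusterSet:
    """Read an externally computed representative->member table (two
    tab-separated columns, one member per line; mmseqs easy-cluster
    dialect)."""
    clusters: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            rep, member = parts
            clusters.setdefault(rep, [])
            if member not in clusters[rep]:
                clusters[rep].append(member)
    for rep in clusters:
        if rep not in clusters[rep]:
            clusters[rep].insert(0, rep)
    return ClusterSet(clusters=clusters, method="external_tsv")


# ---------------------------------------------------------------------------
# splitting


def split_clusters(clusters: ClusterSet,
                   fractions: tuple[float, float, float] = (0.90, 0.06, 0.04),
                   seed: int = 0) -> SplitAssignment:
    """Random cluster-level split. Bucket sizes are the floors of the exact
    fractional counts with the remainder distributed by largest fractional
    part, so 100 clusters at 0.90/0.06/0.04 give exactly 90/6/4."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    reps = sorted(clusters.clusters)
    rng = np.random.default_rng(seed)
    reps = [reps[i] for i in rng.permutation(len(reps))]
    n = len(reps)
    exact = [f * n for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    remainder = n - sum(counts)
    by_frac = sorted(range(3), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in range(remainder):
        counts[by_frac[i % 3]] += 1
    train = set(reps[:counts[0]])
    validation = set(reps[counts[0]:counts[0] + counts[1]])
    test = set(reps[counts[0] + counts[1]:])
    assignment = SplitAssignment(train=train, validation=validation, test=test,
                                 seed=seed, fractions=tuple(fractions))
    assert train | validation | test == set(clusters.clusters)
    return assignment


# ---------------------------------------------------------------------------
# export


def pseudo_id(source_id: str, salt: int = 0) -> str:
    """Stable 4-character lowercase base-36 pseudo-id from a source id."""
    digest = hashlib.sha1(f"{source_id}:{salt}".encode()).digest()
    value = int.from_bytes(digest[:8], "big")
    chars = "0123456789abcdefghijklmnopqrstuvwxyz"
    out = []
    for _ in range(4):
        out.append(chars[value % 36])
        value //= 36
    return "".join(out)


def export_training_set(structures: list[BackboneStructure],
                        split: SplitAssignment,
                        clusters: ClusterSet,
                        out_dir) -> dict:
    """Write one HDF5 record per structure (sequence, backbone coordinates,
    chain metadata, confidence) plus a JSON manifest listing records per
    split. Pseudo-id collisions regenerate deterministically from the hash
    salt. Returns the manifest."""
    import h5py

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {s.id: s for s in structures}
    member_to_rep = {m: rep for rep, members in clusters.clusters.items()
                     for m in members}

    taken: dict[str, str] = {}
    pseudo: dict[str, str] = {}
    for sid in sorted(by_id):
        salt = 0
        pid = pseudo_id(sid, salt)
        while pid in taken:
            salt += 1
            pid = pseudo_id(sid, salt)
        taken[pid] = sid
        pseudo[sid] = pid

    records_dir = out_dir / "records"
    records_dir.mkdir(exist_ok=True)
    manifest: dict = {"splits": {"train": [], "validation": [], "test": []},
                      "records": {}}
    split_of_rep = {}
    for name, bucket in (("train", split.train), ("validation", split.validation),
                         ("test", split.test)):
        for rep in bucket:
            split_of_rep[rep] = name

    for sid, s in sorted(by_id.items()):
        pid = pseudo[sid]
        rep = member_to_rep.get(sid)
        split_name = split_of_rep.get(rep)
        if split_name is None:
            logger.warning("structure %s not covered by the split; skipping", sid)
            continue
        path = records_dir / f"{pid}.h5"
        with h5py.File(path, "w") as h5:
            h5.attrs["source_id"] = sid
            h5.attrs["pseudo_id"] = pid
            h5.attrs["cluster"] = rep
            h5.attrs["source"] = s.source
            for chain in s.chains:
                grp = h5.create_group(f"chain_{chain.chain_id}")
                grp.attrs["sequence"] = chain.sequence
                coords = np.stack([r.backbone() for r in chain.residues])
                grp.create_dataset("backbone", data=coords)
                conf = [r.confidence if r.confidence is not None else np.nan
                        for r in chain.residues]
                grp.create_dataset("confidence", data=np.asarray(conf))
        manifest["splits"][split_name].append(pid)
        manifest["records"][pid] = {"source_id": sid, "cluster": rep,
                                    "path": str(path.relative_to(out_dir))}

    for bucket in manifest["splits"].values():
        bucket.sort()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_training_record(path) -> BackboneStructure:
    """Inverse of the per-structure record written by
    :func:`export_training_set`."""
    import h5py

    from thermodesign.structio import ChainRecord, ResidueRecord

    with h5py.File(path, "r") as h5:
        chains = []
        for key in sorted(h5.keys()):
            if not key.startswith("chain_"):
                continue
            grp = h5[key]
            sequence = grp.attrs["sequence"]
            coords = grp["backbone"][...]
            conf = grp["confidence"][...]
            residues = [
                ResidueRecord(
                    aa=aa, resnum=i + 1,
                    n_xyz=coords[i, 0], ca_xyz=coords[i, 1],
                    c_xyz=coords[i, 2], o_xyz=coords[i, 3],
                    confidence=None if np.isnan(conf[i]) else float(conf[i]))
                for i, aa in enumerate(sequence)]
            chains.append(ChainRecord(chain_id=key.removeprefix("chain_"),
                                      residues=residues))
        return BackboneStructure(
            id=str(h5.attrs["source_id"]), chains=chains,
            source=str(h5.attrs["source"]))
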