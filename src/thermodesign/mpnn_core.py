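"""Message-passing inverse-folding network.

The model follows the established graph formulation for fixed-backbone
sequence design: each residue is a node in a k-nearest-neighbour graph built
on CA distances; edges carry radial-basis-expanded inter-atomic distances
(all 25 ordered pairs of N/CA/C/O/virtual-CB between the two residues, 16
Gaussian bases spanning 2-22 A), a relative sequence-position encoding
clipped to +/-32, and a same-chain flag. An encoder stack of message-passing
layers (with edge updates) builds structure representations; an
autoregressive decoder predicts amino acids under a random decoding order,
conditioning each position on the structure plus previously decoded
identities. Training adds isotropic Gaussian noise (default 0.2 A) to the
backbone coordinates of every example; evaluation and sampling run with the
noise disabled.

Perplexity is the exponentiated mean categorical cross-entropy per residue
(20 = uniform guessing); accuracy is the fraction of argmax-recovered
amino acids. Sampling divides logits by a temperature, emits fixed positions
verbatim (while conditioning on them), and reports a global score: the mean
negative log-likelihood over all positions (lower is better).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from thermodesign import autograd as ag
from thermodesign.autograd import Tensor, concat, log_softmax
from thermodesign.structio import ALPHABET, BackboneStructure, infer_cb, _CB_COEFF, CB_BOND_LENGTH

logger = logging.getLogger(__name__)

N_AA = 20
N_RBF = 16
RBF_MIN, RBF_MAX = 2.0, 22.0
RELPOS_CLIP = 32
N_EDGE_FEATURES = 25 * N_RBF + (2 * RELPOS_CLIP + 1) + 1  # 466


@dataclass
class TrainConfig:
    backbone_noise_sd: float = 0.2      # Angstrom
    dropout: float = 0.10
    epochs: int = 300
    batch_tokens: int = 10_000
    examples_per_epoch: int = 20_000
    k_neighbors: int = 48
    hidden_dim: int = 128
    n_encoder_layers: int = 3
    n_decoder_layers: int = 3
    seed: int = 0
    lr_schedule: str = "reference"      # "reference" (warmup) | "constant"
    learning_rate: float = 1e-3         # used by the "constant" schedule

    def __post_init__(self) -> None:
        if self.backbone_noise_sd < 0:
            raise ValueError("backbone_noise_sd must be >= 0")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        for name in ("epochs", "batch_tokens", "examples_per_epoch",
                     "k_neighbors", "hidden_dim", "n_encoder_layers",
                     "n_decoder_layers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def fingerprint(self) -> str:
        arch = (self.k_neighbors, self.hidden_dim, self.n_encoder_layers,
                self.n_decoder_layers, N_RBF, RBF_MIN, RBF_MAX, RELPOS_CLIP)
        return hashlib.sha1(repr(arch).encode()).hexdigest()[:16]


@dataclass
class KnnGraph:
    n_res: int
    k: int
    neighbor_index: np.ndarray          # (n, k) int
    edge_features: np.ndarray           # (n, k, N_EDGE_FEATURES)
    node_features: np.ndarray           # (n, 0) — the graph is edge-centric
    chain_index: np.ndarray             # (n,) int chain label per residue
    designed_mask: np.ndarray           # (n,) bool; True = position is designed
    sequence: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.edge_features)):
            raise ValueError("non-finite edge features")


@dataclass
class EvalMetrics:
    loss: float
    perplexity: float
    accuracy: float
    n_residues: int


def _virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    return _CB_COEFF[0] * a + _CB_COEFF[1] * b + _CB_COEFF[2] * cvec + ca


def _rbf(d: np.ndarray) -> np.ndarray:
    centers = np.linspace(RBF_MIN, RBF_MAX, N_RBF)
    sigma = (RBF_MAX - RBF_MIN) / N_RBF
    return np.exp(-(((d[..., None] - centers) / sigma) ** 2))


def featurize(structure: BackboneStructure, noise_sd: float = 0.0,
              seed: int = 0, k: int = 48,
              designed_mask: np.ndarray | None = None) -> KnnGraph:
    """Build the k-NN graph for one structure.

    Gaussian noise (sd = ``noise_sd``) is added independently to every
    backbone atom coordinate before any distance computation; the virtual CB
    is placed from the (noised) backbone frame. ``k`` is capped at
    ``n_res - 1`` with a warning.
    """
    n_res = structure.n_residues
    if n_res < 2:
        raise ValueError("featurize needs >= 2 residues")
    if k >= n_res:
        logger.warning("k=%d >= n_res=%d; capping at %d", k, n_res, n_res - 1)
        k = n_res - 1

    backbone = np.zeros((n_res, 4, 3))
    chain_index = np.zeros(n_res, dtype=int)
    within_chain_pos = np.zeros(n_res, dtype=int)
    i = 0
    for ci, chain in enumerate(structure.chains):
        for pos, res in enumerate(chain.residues):
            backbone[i] = res.backbone()
            chain_index[i] = ci
            within_chain_pos[i] = pos
            i += 1
    if not np.all(np.isfinite(backbone)):
        raise ValueError(f"NaN coordinate in structure {structure.id!r}")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        backbone = backbone + rng.normal(0.0, noise_sd, size=backbone.shape)

    cb = _virtual_cb(backbone[:, 0], backbone[:, 1], backbone[:, 2])
    atoms = np.concatenate([backbone, cb[:, None, :]], axis=1)  # (n, 5, 3)

    ca = atoms[:, 1]
    d_ca = np.sqrt(((ca[:, None, :] - ca[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d_ca, np.inf)
    # distances rounded before sorting so that exactly equidistant neighbours
    # (ideal geometry) keep a rotation-independent order; ties break by index
    keys = np.round(d_ca, 6)
    neighbor_index = np.argsort(keys, axis=1, kind="stable")[:, :k]

    # (n, k, 25) distances over ordered atom pairs (a of i, b of j)
    a_i = atoms[:, None, :, None, :]                    # (n, 1, 5, 1, 3)
    a_j = atoms[neighbor_index][:, :, None, :, :]       # (n, k, 1, 5, 3)
    d_pairs = np.sqrt(((a_i - a_j) ** 2).sum(-1))       # (n, k, 5, 5)
    rbf = _rbf(d_pairs.reshape(n_res, k, 25)).reshape(n_res, k, 25 * N_RBF)

    same_chain = (chain_index[:, None] == chain_index[neighbor_index])
    offset = within_chain_pos[neighbor_index] - within_chain_pos[:, None]
    offset = np.clip(offset, -RELPOS_CLIP, RELPOS_CLIP) + RELPOS_CLIP
    relpos = np.zeros((n_res, k, 2 * RELPOS_CLIP + 1))
    rows, cols = np.nonzero(same_chain)
    relpos[rows, cols, offset[rows, cols]] = 1.0

    edge_features = np.concatenate(
        [rbf, relpos, same_chain[..., None].astype(float)], axis=-1)

    if designed_mask is None:
        designed_mask = np.ones(n_res, dtype=bool)
    return KnnGraph(
        n_res=n_res, k=k, neighbor_index=neighbor_index,
        edge_features=edge_features, node_features=np.zeros((n_res, 0)),
        chain_index=chain_index, designed_mask=np.asarray(designed_mask, bool),
        sequence=structure.sequence)


# ---------------------------------------------------------------------------
# model


class _EncoderLayer:
    def __init__(self, rng, hidden):
        self.message = ag.MLP(rng, [3 * hidden, hidden, hidden, hidden])
        self.ffn = ag.MLP(rng, [hidden, 4 * hidden, hidden])
        self.edge_update = ag.MLP(rng, [3 * hidden, hidden, hidden, hidden])
        self.norm1 = ag.LayerNorm(hidden)
        self.norm2 = ag.LayerNorm(hidden)
        self.norm3 = ag.LayerNorm(hidden)

    def parameters(self):
        return (self.message.parameters() + self.ffn.parameters()
                + self.edge_update.parameters() + self.norm1.parameters()
                + self.norm2.parameters() + self.norm3.parameters())


class _DecoderLayer:
    def __init__(self, rng, hidden):
        self.message = ag.MLP(rng, [4 * hidden, hidden, hidden, hidden])
        self.ffn = ag.MLP(rng, [hidden, 4 * hidden, hidden])
        self.norm1 = ag.LayerNorm(hidden)
        self.norm2 = ag.LayerNorm(hidden)

    def parameters(self):
        return (self.message.parameters() + self.ffn.parameters()
                + self.norm1.parameters() + self.norm2.parameters())


class InverseFoldingModel:
    """Encoder/decoder message-passing network over a residue k-NN graph."""

    def __init__(self, config: TrainConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        self.edge_embed = ag.Linear(rng, N_EDGE_FEATURES, h)
        self.seq_embed = ag.Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(h), size=(N_AA + 1, h)))  # +1: "unknown"
        self.encoder = [_EncoderLayer(rng, h) for _ in range(config.n_encoder_layers)]
        self.decoder = [_DecoderLayer(rng, h) for _ in range(config.n_decoder_layers)]
        self.out = ag.Linear(rng, h, N_AA)

    def parameters(self):
        params = self.edge_embed.parameters() + [self.seq_embed]
        for layer in self.encoder + self.decoder:
            params += layer.parameters()
        params += self.out.parameters()
        return params

    # -- forward ----------------------------------------------------------

    def _tile_nodes(self, h: Tensor, n: int, k: int):
        return h.take(np.repeat(np.arange(n), k)).reshape(n, k, -1)

    def encode(self, graph: KnnGraph, dropout_rng=None) -> tuple[Tensor, Tensor]:
        n, k = graph.n_res, graph.k
        drop = self.config.dropout if dropout_rng is not None else 0.0
        e = self.edge_embed(Tensor(graph.edge_features))
        h = Tensor(np.zeros((n, self.config.hidden_dim)))
        for layer in self.encoder:
            h_i = self._tile_nodes(h, n, k)
            h_j = h.take(graph.neighbor_index)
            m = layer.message(concat([h_i, h_j, e], axis=-1)).mean(axis=1)
            if dropout_rng is not None:
                m = ag.dropout(m, drop, dropout_rng)
            h = layer.norm1(h + m)
            f = layer.ffn(h)
            if dropout_rng is not None:
                f = ag.dropout(f, drop, dropout_rng)
            h = layer.norm2(h + f)
            h_i = self._tile_nodes(h, n, k)
            h_j = h.take(graph.neighbor_index)
            e = layer.norm3(e + layer.edge_update(concat([h_i, e, h_j], axis=-1)))
        return h, e

    def decode(self, graph: KnnGraph, seq_idx: np.ndarray,
               decoded_before: np.ndarray, h_enc: Tensor, e: Tensor,
               dropout_rng=None) -> Tensor:
        """One parallel decoder pass.

        ``decoded_before[i, slot]`` is True when the neighbour in that slot
        was decoded before position i; those neighbours expose their sequence
        identity (and current decoder state), all others expose only encoder
        state. Returns (n, 20) log-probabilities.
        """
        n, k = graph.n_res, graph.k
        drop = self.config.dropout if dropout_rng is not None else 0.0
        mask = Tensor(decoded_before[..., None].astype(float))   # (n, k, 1)
        s = self.seq_embed.take(seq_idx)                         # (n, h)
        s_j = s.take(graph.neighbor_index)
        h_enc_j = h_enc.take(graph.neighbor_index)
        context_static = concat([e, s_j * mask, h_enc_j * (1.0 - mask)], axis=-1)
        h = h_enc
        for layer in self.decoder:
            h_j = h.take(graph.neighbor_index)
            # decoded neighbours contribute their live decoder state
            context = context_static + concat(
                [e * 0.0, s_j * 0.0, h_j * mask], axis=-1)
            h_i = self._tile_nodes(h, n, k)
            m = layer.message(concat([h_i, context], axis=-1)).mean(axis=1)
            if dropout_rng is not None:
                m = ag.dropout(m, drop, dropout_rng)
            h = layer.norm1(h + m)
            f = layer.ffn(h)
            if dropout_rng is not None:
                f = ag.dropout(f, drop, dropout_rng)
            h = layer.norm2(h + f)
        return log_softmax(self.out(h), axis=-1)


def sequence_to_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([ALPHABET.index(c) for c in sequence])
    except ValueError:
        bad = sorted({c for c in sequence if c not in ALPHABET})
        raise ValueError(f"sequence letters outside the 20-letter alphabet: {bad}")


def random_decoding_order(n: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).permutation(n)


def _decoded_before(graph: KnnGraph, order: np.ndarray) -> np.ndarray:
    rank = np.empty(graph.n_res, dtype=int)
    rank[order] = np.arange(graph.n_res)
    return rank[graph.neighbor_index] < rank[:, None]


def score_teacher_forced(model: InverseFoldingModel, graph: KnnGraph,
                         sequence: str, decoding_order_seed: int = 0,
                         decoding_order: np.ndarray | None = None,
                         dropout_rng=None) -> np.ndarray:
    """(n, 20) per-residue log-probabilities under teacher forcing with a
    random permutation decoding order."""
    seq_idx = sequence_to_indices(sequence)
    if len(seq_idx) != graph.n_res:
        raise ValueError("sequence length does not match graph size")
    if decoding_order is None:
        decoding_order = random_decoding_order(graph.n_res, decoding_order_seed)
    h_enc, e = model.encode(graph, dropout_rng=dropout_rng)
    logprobs = model.decode(graph, seq_idx, _decoded_before(graph, decoding_order),
                            h_enc, e, dropout_rng=dropout_rng)
    return logprobs.data


def _teacher_forced_loss(model: InverseFoldingModel, graph: KnnGraph,
                         sequence: str, decoding_order: np.ndarray,
                         dropout_rng=None) -> tuple[Tensor, EvalMetrics]:
    seq_idx = sequence_to_indices(sequence)
    h_enc, e = model.encode(graph, dropout_rng=dropout_rng)
    logprobs = model.decode(graph, seq_idx, _decoded_before(graph, decoding_order),
                            h_enc, e, dropout_rng=dropout_rng)
    onehot = np.zeros((graph.n_res, N_AA))
    onehot[np.arange(graph.n_res), seq_idx] = 1.0
    loss = -(logprobs * Tensor(onehot)).sum(axis=-1).mean()
    metrics = loss_perplexity_accuracy(logprobs.data, sequence)
    return loss, metrics


def loss_perplexity_accuracy(logprobs: np.ndarray, true_sequence: str) -> EvalMetrics:
    """loss = mean over residues of -log p(true aa); perplexity = exp(loss);
    accuracy = fraction of argmax-correct positions."""
    seq_idx = sequence_to_indices(true_sequence)
    n = len(seq_idx)
    if logprobs.shape != (n, N_AA):
        raise ValueError(f"logprobs shape {logprobs.shape} != ({n}, {N_AA})")
    nll = -logprobs[np.arange(n), seq_idx]
    loss = float(nll.mean())
    accuracy = float((logprobs.argmax(axis=1) == seq_idx).mean())
    return EvalMetrics(loss=loss, perplexity=float(np.exp(loss)),
                       accuracy=accuracy, n_residues=n)


# ---------------------------------------------------------------------------
# weights


@dataclass
class ModelWeights:
    arrays: dict[str, np.ndarray]
    config: TrainConfig
    provenance: dict = field(default_factory=dict)


def extract_weights(model: InverseFoldingModel,
                    provenance: dict | None = None) -> ModelWeights:
    arrays = {f"p{i}": p.data.copy() for i, p in enumerate(model.parameters())}
    return ModelWeights(arrays=arrays, config=copy.deepcopy(model.config),
                        provenance=provenance or {})


def build_model(weights: ModelWeights) -> InverseFoldingModel:
    model = InverseFoldingModel(weights.config)
    params = model.parameters()
    if len(params) != len(weights.arrays):
        raise ValueError("weight count does not match architecture")
    for i, p in enumerate(params):
        arr = weights.arrays[f"p{i}"]
        if arr.shape != p.data.shape:
            raise ValueError(f"shape mismatch at parameter {i}")
        p.data = arr.copy()
    return model


def save_weights(weights: ModelWeights, path) -> None:
    meta = {"config": asdict(weights.config),
            "fingerprint": weights.config.fingerprint(),
            "provenance": weights.provenance}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **weights.arrays)


def load_weights(path, expected_config: TrainConfig | None = None) -> ModelWeights:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    config = TrainConfig(**meta["config"])
    if config.fingerprint() != meta["fingerprint"]:
        raise ValueError("checkpoint fingerprint does not match its config")
    if expected_config is not None and \
            expected_config.fingerprint() != meta["fingerprint"]:
        raise ValueError("checkpoint architecture does not match requested config")
    return ModelWeights(arrays=arrays, config=config,
                        provenance=meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# training


def _dataset_hash(clusters: dict[str, list[BackboneStructure]]) -> str:
    h = hashlib.sha1()
    for rep in sorted(clusters):
        for s in clusters[rep]:
            h.update(s.id.encode())
            h.update(s.sequence.encode())
    return h.hexdigest()[:16]


def evaluate(model: InverseFoldingModel,
             structures: list[BackboneStructure], seed: int = 0,
             noise_sd: float = 0.0) -> EvalMetrics:
    """Pooled metrics over structures (noise disabled by default)."""
    if not structures:
        raise ValueError("nothing to evaluate")
    total_nll, total_correct, total_n = 0.0, 0.0, 0
    for j, s in enumerate(structures):
        graph = featurize(s, noise_sd=noise_sd, seed=seed + j,
                          k=model.config.k_neighbors)
        order = random_decoding_order(graph.n_res, seed + 7919 * (j + 1))
        logprobs = score_teacher_forced(model, graph, s.sequence,
                                        decoding_order=order)
        m = loss_perplexity_accuracy(logprobs, s.sequence)
        total_nll += m.loss * m.n_residues
        total_correct += m.accuracy * m.n_residues
        total_n += m.n_residues
    loss = total_nll / total_n
    return EvalMetrics(loss=loss, perplexity=float(np.exp(loss)),
                       accuracy=total_correct / total_n, n_residues=total_n)


def train(train_clusters: dict[str, list[BackboneStructure]],
          cfg: TrainConfig,
          validation: list[BackboneStructure] | None = None,
          ) -> tuple[ModelWeights, list[dict]]:
    """Train from scratch on cluster-organised structures.

    Each epoch samples one random member per training cluster (up to
    ``examples_per_epoch``), packs examples into batches of at most
    ``batch_tokens`` residues, and takes one optimizer step per batch.
    Validation (when given) runs with noise disabled; the
    best-validation-loss checkpoint is retained. Returns the weights and a
    per-epoch log.
    """
    if not train_clusters:
        raise ValueError("empty training split")
    model = InverseFoldingModel(cfg)
    steps_per_epoch = max(1, min(len(train_clusters), cfg.examples_per_epoch))
    optimizer = ag.Adam(model.parameters(),
                        lr=cfg.learning_rate, schedule=cfg.lr_schedule,
                        model_dim=cfg.hidden_dim,
                        total_steps=cfg.epochs * steps_per_epoch)
    master_rng = np.random.default_rng(cfg.seed)
    log: list[dict] = []
    best_val = np.inf
    best_arrays = None
    reps = sorted(train_clusters)

    for epoch in range(cfg.epochs):
        epoch_rng = np.random.default_rng(master_rng.integers(2**31))
        picks = [train_clusters[rep][epoch_rng.integers(len(train_clusters[rep]))]
                 for rep in reps]
        epoch_rng.shuffle(picks)
        picks = picks[:cfg.examples_per_epoch]

        batches: list[list[BackboneStructure]] = [[]]
        tokens = 0
        for s in picks:
            if batches[-1] and tokens + s.n_residues > cfg.batch_tokens:
                batches.append([])
                tokens = 0
            batches[-1].append(s)
            tokens += s.n_residues
        epoch_nll, epoch_correct, epoch_n = 0.0, 0.0, 0
        for batch in batches:
            if not batch:
                continue
            optimizer.zero_grad()
            losses = []
            for s in batch:
                graph = featurize(s, noise_sd=cfg.backbone_noise_sd,
                                  seed=int(epoch_rng.integers(2**31)),
                                  k=cfg.k_neighbors)
                order = random_decoding_order(
                    graph.n_res, int(epoch_rng.integers(2**31)))
                drop_rng = (np.random.default_rng(epoch_rng.integers(2**31))
                            if cfg.dropout > 0 else None)
                loss, m = _teacher_forced_loss(model, graph, s.sequence, order,
                                               dropout_rng=drop_rng)
                losses.append(loss)
                epoch_nll += m.loss * m.n_residues
                epoch_correct += m.accuracy * m.n_residues
                epoch_n += m.n_residues
            batch_loss = losses[0]
            for extra in losses[1:]:
                batch_loss = batch_loss + extra
            batch_loss = batch_loss * (1.0 / len(losses))
            if not np.isfinite(batch_loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; aborting "
                    f"(last batch ids: {[s.id for s in batch]})")
            batch_loss.backward()
            optimizer.step()

        entry = {"epoch": epoch, "split": "train",
                 "loss": epoch_nll / epoch_n,
                 "perplexity": float(np.exp(epoch_nll / epoch_n)),
                 "accuracy": epoch_correct / epoch_n}
        log.append(entry)
        if validation:
            vm = evaluate(model, validation, seed=cfg.seed + epoch)
            log.append({"epoch": epoch, "split": "validation", "loss": vm.loss,
                        "perplexity": vm.perplexity, "accuracy": vm.accuracy})
            if vm.loss < best_val:
                best_val = vm.loss
                best_arrays = [p.data.copy() for p in model.parameters()]

    if best_arrays is not None:
        for p, arr in zip(model.parameters(), best_arrays):
            p.data = arr
    provenance = {"dataset_hash": _dataset_hash(train_clusters),
                  "seed": cfg.seed, "epochs_completed": cfg.epochs}
    return extract_weights(model, provenance), log


def write_training_log(log: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\tsplit\tloss\tperplexity\taccuracy\n")
        for entry in log:
            fh.write(f"{entry['epoch']}\t{entry['split']}\t{entry['loss']:.6f}"
                     f"\t{entry['perplexity']:.6f}\t{entry['accuracy']:.6f}\n")


# ---------------------------------------------------------------------------
# sampling


def sample(weights: ModelWeights | InverseFoldingModel,
           structure: BackboneStructure, temperature: float = 0.001,
           fixed_positions: set[int] | None = None, seed: int = 0,
           ) -> tuple[str, float, np.ndarray]:
    """Autoregressively sample one sequence for a backbone.

    ``fixed_positions`` are 0-based global residue indices whose input
    identity is emitted verbatim (and conditioned on). Returns the sequence,
    the global score (mean -log p over ALL positions under a teacher-forced
    re-scoring with the same decoding order; lower is better), and the
    (n, 20) per-position probabilities seen at each position's decoding step.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    model = weights if isinstance(weights, InverseFoldingModel) else build_model(weights)
    graph = featurize(structure, noise_sd=0.0, seed=seed,
                      k=model.config.k_neighbors)
    n = graph.n_res
    fixed = set() if fixed_positions is None else set(fixed_positions)
    for p in fixed:
        if not (0 <= p < n):
            raise IndexError(f"fixed position {p} out of range for {n} residues")
    parent_idx = sequence_to_indices(structure.sequence)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    h_enc, e = model.encode(graph)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)

    seq_idx = np.full(n, N_AA)  # "unknown" token until decoded
    probs_out = np.zeros((n, N_AA))
    for t, pos in enumerate(order):
        decoded = rank[graph.neighbor_index] < t
        logprobs = model.decode(graph, np.minimum(seq_idx, N_AA), decoded,
                                h_enc, e)
        row = logprobs.data[pos]
        probs_out[pos] = np.exp(row)
        if pos in fixed:
            seq_idx[pos] = parent_idx[pos]
        else:
            scaled = row / temperature
            scaled -= scaled.max()
            p_t = np.exp(scaled)
            p_t /= p_t.sum()
            seq_idx[pos] = rng.choice(N_AA, p=p_t)

    sequence = "".join(ALPHABET[i] for i in seq_idx)
    for p in fixed:
        assert sequence[p] == structure.sequence[p], "fixed position mutated"
    logprobs = score_teacher_forced(model, graph, sequence, decoding_order=order)
    global_score = float(-logprobs[np.arange(n), seq_idx].mean())
    return sequence, global_score, probs_out


def score_designed(weights: ModelWeights | InverseFoldingModel,
                   structure: BackboneStructure, sequence: str,
                   designed_positions: set[int], seed: int = 0) -> float:
    """Mean -log p restricted to designed positions (variant of the global
    score)."""
    model = weights if isinstance(weights, InverseFoldingModel) else build_model(weights)
    graph = featurize(structure, noise_sd=0.0, seed=seed,
                      k=model.config.k_neighbors)
    order = random_decoding_order(graph.n_res, seed)
    logprobs = score_teacher_forced(model, graph, sequence, decoding_order=order)
    idx = sequence_to_indices(sequence)
    designed = sorted(designed_positions)
    return float(-logprobs[designed, idx[designed]].mean())
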