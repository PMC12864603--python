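"""Fusion of the sequence and graph views, training, prediction, checkpoints.

The full model is: xLSTM sequence embedding (128) and MPNN graph embedding
(128), combined by one of three fusion strategies and classified by a
three-layer fully connected head (two hidden blocks with dropout, one
logistic output unit).  Training minimizes binary cross-entropy with Adam
and decoupled weight decay; every random draw (initialization, minibatch
order, dropout masks) comes from generators derived from one seed, so a
run is bit-reproducible.

Single-view variants (sequence-only, graph-only) are built from the same
components for ablation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .chem import FEATURIZER_VERSION, GraphCache, MolGraph
from .data import DatasetManifest
from .mpnn import (MPNNConfig, batch_graphs, forward_graph_batch,
                   init_graph_params)
from .nn import (Adam, ParamDict, add_linear, clone_params, count_params,
                 dropout, linear, rng_for, zero_grads)
from .sequence import (TOKEN_TABLE, XLSTMConfig, forward_sequence_batch,
                       init_sequence_params, tokenize_batch)

FUSION_STRATEGIES = ("concatenation", "cross_attention", "hierarchical")
VIEWS = ("fused", "sequence", "graph")

DECISION_THRESHOLD = 0.5  # ties go to the positive class


@dataclass(frozen=True)
class FusionConfig:
    """Fusion head layout; defaults follow the selected configuration."""

    strategy: str = "hierarchical"
    fc_layers: int = 3
    dropout: float = 0.2
    stage1_dim: int = 64
    hidden_dims: tuple[int, int] = (64, 32)

    def __post_init__(self):
        if self.strategy not in FUSION_STRATEGIES:
            raise ValueError(f"strategy must be one of {FUSION_STRATEGIES}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults are the tuned full-scale values."""

    learning_rate: float = 1e-5
    weight_decay: float = 3e-3
    dropout: float = 0.2
    batch_size: int = 64
    max_epochs: int = 300
    patience: int = 30
    seed: int = 0


@dataclass(frozen=True)
class Prediction:
    id: str
    probability: float
    label: int


@dataclass
class FusionModel:
    """All configuration plus the flat parameter dictionary of the model."""

    view: str = "fused"
    fusion: FusionConfig = field(default_factory=FusionConfig)
    seq_config: XLSTMConfig = field(default_factory=XLSTMConfig)
    graph_config: MPNNConfig = field(default_factory=MPNNConfig)
    seed: int = 0
    dtype: str = "float64"
    params: ParamDict = field(default_factory=dict)
    train_config: TrainConfig | None = None

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")
        if not self.params:
            self.params = _init_all_params(self)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def _head_input_dim(model: FusionModel) -> int:
    d = model.seq_config.model_dim
    s = model.fusion.strategy
    two = model.view == "fused"
    if s == "hierarchical":
        return model.fusion.stage1_dim * (2 if two else 1)
    return d * (2 if two else 1)


def _init_all_params(model: FusionModel) -> ParamDict:
    dtype = model.np_dtype
    params: ParamDict = {}
    if model.view in ("fused", "sequence"):
        seq = init_sequence_params(model.seq_config,
                                   rng_for(model.seed, "seq_init"), dtype=dtype)
        params.update({f"seq.{k}": v for k, v in seq.items()})
    if model.view in ("fused", "graph"):
        gr = init_graph_params(model.graph_config,
                               rng_for(model.seed, "graph_init"), dtype=dtype)
        params.update({f"graph.{k}": v for k, v in gr.items()})
    rng = rng_for(model.seed, "head_init")
    d = model.seq_config.model_dim
    strat = model.fusion.strategy
    if strat == "hierarchical":
        if model.view in ("fused", "sequence"):
            add_linear(params, "head.s1seq", rng, d, model.fusion.stage1_dim,
                       dtype=dtype)
        if model.view in ("fused", "graph"):
            add_linear(params, "head.s1graph", rng, d, model.fusion.stage1_dim,
                       dtype=dtype)
    elif strat == "cross_attention":
        for side in (("seq", "graph") if model.view == "fused" else (model.view,)):
            for proj in ("Wq", "Wk", "Wv"):
                add_linear(params, f"head.att.{side}.{proj}", rng, d, d,
                           dtype=dtype)
    h1, h2 = model.fusion.hidden_dims
    add_linear(params, "head.fc1", rng, _head_input_dim(model), h1, dtype=dtype)
    add_linear(params, "head.fc2", rng, h1, h2, dtype=dtype)
    add_linear(params, "head.out", rng, h2, 1, dtype=dtype)
    return params


def _sub(params: ParamDict, prefix: str) -> ParamDict:
    n = len(prefix) + 1
    return {k[n:]: v for k, v in params.items() if k.startswith(prefix + ".")}


# ---------------------------------------------------------------------------
# fusion head
# ---------------------------------------------------------------------------

def fuse(config: FusionConfig, params: ParamDict, seq_emb: Tensor | None,
         graph_emb: Tensor | None, training: bool = False,
         rng=None, return_logit: bool = False) -> Tensor:
    """Combine the available views and classify.  Returns probability (B, 1).

    Hierarchical: per-view linear + ReLU, then concatenation.  Concatenation:
    raw views concatenated.  Cross-attention: scaled dot-product attention of
    each view over the other, the views being length-1 token sets (with a
    single key the attention weight is identically 1, so each view receives
    the other's value projection).
    """
    views = [v for v in (seq_emb, graph_emb) if v is not None]
    if not views:
        raise ValueError("fuse requires at least one view")
    if config.strategy == "hierarchical":
        staged = []
        if seq_emb is not None:
            staged.append(ad.relu(linear(params, "s1seq", seq_emb)))
        if graph_emb is not None:
            staged.append(ad.relu(linear(params, "s1graph", graph_emb)))
        z = staged[0] if len(staged) == 1 else ad.concat(staged, axis=-1)
    elif config.strategy == "concatenation":
        z = views[0] if len(views) == 1 else ad.concat(views, axis=-1)
    else:  # cross_attention
        if seq_emb is not None and graph_emb is not None:
            att_seq = linear(_sub(params, "att.graph"), "Wv", graph_emb)
            att_graph = linear(_sub(params, "att.seq"), "Wv", seq_emb)
            z = ad.concat([att_seq, att_graph], axis=-1)
        else:
            side = "seq" if seq_emb is not None else "graph"
            z = linear(_sub(params, f"att.{side}"), "Wv", views[0])
    h = ad.relu(linear(params, "fc1", z))
    h = dropout(h, config.dropout, rng, training)
    h = ad.relu(linear(params, "fc2", h))
    h = dropout(h, config.dropout, rng, training)
    logit = linear(params, "out", h)
    return logit if return_logit else ad.sigmoid(logit)


# ---------------------------------------------------------------------------
# batched forward
# ---------------------------------------------------------------------------

@dataclass
class _Featurized:
    tokens: np.ndarray | None
    lengths: np.ndarray | None
    graphs: list[MolGraph] | None
    labels: np.ndarray | None
    ids: list[str]
    seq_lengths: np.ndarray = None  # type: ignore[assignment]


def featurize_manifest(model: FusionModel, manifest: DatasetManifest,
                       cache: GraphCache | None = None) -> _Featurized:
    seqs = manifest.sequences()
    tokens = lengths = None
    graphs = None
    if model.view in ("fused", "sequence"):
        tokens, lengths = tokenize_batch(seqs)
    if model.view in ("fused", "graph"):
        cache = cache or GraphCache()
        graphs = [cache.get(s) for s in seqs]
    labels = manifest.labels() if all(r.label is not None
                                      for r in manifest.records) else None
    return _Featurized(tokens=tokens, lengths=lengths, graphs=graphs,
                       labels=labels, ids=[r.id for r in manifest.records],
                       seq_lengths=np.array([len(s) for s in seqs]))


def _length_bucketed_batches(feats: _Featurized, batch_size: int,
                             rng) -> list[np.ndarray]:
    """Shuffled batches of records with similar lengths.

    Grouping by length keeps the recurrent unroll of each batch short; the
    record order within buckets and the batch order are reshuffled every
    epoch, deterministically from the generator.
    """
    order = rng.permutation(len(feats.ids))
    by_length = order[np.argsort(feats.seq_lengths[order], kind="stable")]
    batches = [by_length[i:i + batch_size]
               for i in range(0, len(by_length), batch_size)]
    return [batches[i] for i in rng.permutation(len(batches))]


def forward_batch(model: FusionModel, feats: _Featurized,
                  index: np.ndarray, training: bool = False,
                  rng=None) -> Tensor:
    """Logits (B, 1) for the records selected by ``index``."""
    seq_emb = graph_emb = None
    if feats.tokens is not None:
        seq_emb = forward_sequence_batch(_sub(model.params, "seq"),
                                         model.seq_config,
                                         feats.tokens[index],
                                         feats.lengths[index])
    if feats.graphs is not None:
        gb = batch_graphs([feats.graphs[i] for i in index])
        graph_emb = forward_graph_batch(_sub(model.params, "graph"),
                                        model.graph_config, gb)
    return fuse(model.fusion, _sub(model.params, "head"), seq_emb, graph_emb,
                training=training, rng=rng, return_logit=True)


def _bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    y = y.reshape(-1, 1).astype(logits.dtype)
    return ad.mean_(ad.add(ad.softplus(logits), ad.mul(logits, -y)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(model: FusionModel, config: TrainConfig,
          train_set: DatasetManifest, valid_set: DatasetManifest | None = None,
          cache: GraphCache | None = None,
          verbose: bool = False) -> tuple[FusionModel, list[dict]]:
    """Fit the model in place; returns (model at best validation loss, history).

    With an empty/absent validation set there is no early stopping and the
    final-epoch weights are kept.
    """
    cache = cache or GraphCache()
    feats = featurize_manifest(model, train_set, cache)
    if feats.labels is None:
        raise ValueError("training requires a fully labeled manifest")
    vfeats = None
    if valid_set is not None and len(valid_set):
        vfeats = featurize_manifest(model, valid_set, cache)
    optimizer = Adam(model.params, lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    shuffle_rng = rng_for(config.seed, "shuffle")
    dropout_rng = rng_for(config.seed, "dropout")
    history: list[dict] = []
    best_loss, best_params, best_epoch = np.inf, None, -1
    n = len(train_set)
    fusion = FusionConfig(**{**asdict(model.fusion), "dropout": config.dropout})
    model.fusion = fusion
    model.train_config = config
    for epoch in range(config.max_epochs):
        epoch_loss = 0.0
        for idx in _length_bucketed_batches(feats, config.batch_size,
                                            shuffle_rng):
            logits = forward_batch(model, feats, idx, training=True,
                                   rng=dropout_rng)
            loss = _bce_with_logits(logits, feats.labels[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}")
            zero_grads(model.params)
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        entry = {"epoch": epoch, "train_loss": epoch_loss / n}
        if vfeats is not None:
            vloss, vacc = _evaluate(model, vfeats, config.batch_size)
            entry.update(valid_loss=vloss, valid_accuracy=vacc)
            if vloss < best_loss:
                best_loss, best_epoch = vloss, epoch
                best_params = clone_params(model.params)
            elif epoch - best_epoch >= config.patience:
                history.append(entry)
                break
        history.append(entry)
        if verbose:  # pragma: no cover
            print(entry)
    if best_params is not None:
        model.params = best_params
    return model, history


def _eval_batches(n: int, seq_lengths: np.ndarray,
                  batch_size: int) -> list[np.ndarray]:
    by_length = np.argsort(seq_lengths, kind="stable")
    return [by_length[i:i + batch_size] for i in range(0, n, batch_size)]


def _evaluate(model: FusionModel, feats: _Featurized,
              batch_size: int) -> tuple[float, float]:
    n = len(feats.ids)
    losses, correct = 0.0, 0
    for idx in _eval_batches(n, feats.seq_lengths, batch_size):
        logits = forward_batch(model, feats, idx, training=False)
        losses += float(_bce_with_logits(logits, feats.labels[idx]).data) * len(idx)
        pred = (logits.data.ravel() >= 0.0).astype(int)
        correct += int(np.sum(pred == feats.labels[idx]))
    return losses / n, correct / n


def predict(model: FusionModel, manifest: DatasetManifest,
            cache: GraphCache | None = None,
            batch_size: int = 128) -> list[Prediction]:
    """Deterministic eval-mode predictions; unconvertible records are skipped
    with a report attached to the cache."""
    cache = cache or GraphCache()
    keep, skipped = [], []
    if model.view in ("fused", "graph"):
        for i, rec in enumerate(manifest.records):
            try:
                cache.get(rec.sequence)
                keep.append(i)
            except ValueError as err:
                skipped.append(f"{rec.id}: {err}")
    else:
        keep = list(range(len(manifest)))
    sub = manifest.subset(keep)
    feats = featurize_manifest(model, sub, cache)
    n = len(sub)
    slots: list[Prediction | None] = [None] * n
    for idx in _eval_batches(n, feats.seq_lengths, batch_size):
        logits = forward_batch(model, feats, idx, training=False)
        probs = 1.0 / (1.0 + np.exp(-logits.data.ravel()))
        for j, p in zip(idx, probs):
            slots[j] = Prediction(id=feats.ids[j], probability=float(p),
                                  label=int(p >= DECISION_THRESHOLD))
    cache.skipped.extend(skipped)
    return [p for p in slots if p is not None]


# ---------------------------------------------------------------------------
# parameter accounting and checkpoints
# ---------------------------------------------------------------------------

def count_total_params(model: FusionModel) -> int:
    return count_params(model.params)


def parameter_breakdown(model: FusionModel) -> dict[str, int]:
    return {"sequence": count_params(model.params, "seq."),
            "graph": count_params(model.params, "graph."),
            "head": count_params(model.params, "head."),
            "total": count_total_params(model)}


def save_checkpoint(model: FusionModel, path) -> None:
    meta = {
        "featurizer_version": FEATURIZER_VERSION,
        "token_table": TOKEN_TABLE,
        "view": model.view,
        "seed": model.seed,
        "dtype": model.dtype,
        "fusion": asdict(model.fusion),
        "seq_config": asdict(model.seq_config),
        "graph_config": asdict(model.graph_config),
        "train_config": asdict(model.train_config) if model.train_config else None,
    }
    arrays = {k: v.data for k, v in model.params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


class CheckpointVersionError(RuntimeError):
    pass


def load_checkpoint(path) -> FusionModel:
    with np.load(path) as payload:
        meta = json.loads(bytes(payload["__meta__"].tobytes()).decode())
        if meta["featurizer_version"] != FEATURIZER_VERSION:
            raise CheckpointVersionError(
                f"checkpoint featurizer {meta['featurizer_version']!r} != "
                f"library featurizer {FEATURIZER_VERSION!r}")
        params = {k: Tensor(payload[k].copy(), requires_grad=True)
                  for k in payload.files if k != "__meta__"}
    seq_cfg = dict(meta["seq_config"])
    seq_cfg["block_pattern"] = tuple(seq_cfg["block_pattern"])
    fus = dict(meta["fusion"])
    fus["hidden_dims"] = tuple(fus["hidden_dims"])
    model = FusionModel(view=meta["view"], fusion=FusionConfig(**fus),
                        seq_config=XLSTMConfig(**seq_cfg),
                        graph_config=MPNNConfig(**meta["graph_config"]),
                        seed=meta["seed"], dtype=meta["dtype"], params=params)
    if meta.get("train_config"):
        model.train_config = TrainConfig(**meta["train_config"])
    return model
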