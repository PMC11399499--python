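"""Supervised graph-convolutional link prediction for regulatory edges.

The filtered regulatory network becomes an undirected message-passing
graph with self-loops; node inputs are each gene's expression vector,
adaptively pooled to a fixed length (which is what lets a model trained on
one expression atlas score a species with a different sample count) and
passed through an affine reduction.  Two GCN layers with symmetric
normalization D̃^(−1/2)(A+I)D̃^(−1/2) produce node embeddings; a directed
edge (t, u) is represented by the outer product of its endpoint
embeddings, an asymmetric d×d map classified by a small CNN head into a
probability that t regulates u.

Training balances ChIP-validated positives with per-TF sampled negative
non-targets, splits 8:1:1, minimizes binary cross-entropy with Adam
(lr 0.005, weight decay 1e-4), and early-stops on validation loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .io_formats import ExpressionMatrix
from .nn import Adam, Parameter, Tensor, _sigmoid, bce_with_logits

__all__ = [
    "RegGraph",
    "EdgeSplit",
    "ModelConfig",
    "TrainedModel",
    "build_graph",
    "sample_negatives",
    "adaptive_avg_pool",
    "reduce_features",
    "normalized_adjacency",
    "edge_embed",
    "train",
    "evaluate",
    "threshold_postprocess",
    "ablate",
    "transfer_predict",
]


@dataclass
class RegGraph:
    """Node set, directed edge set, and per-gene expression features."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    X: np.ndarray  # |V| × n_samples

    def __post_init__(self) -> None:
        if any(t == u for t, u in self.edges):
            raise ValueError("self-loop in edge set")
        if self.X.shape[0] != len(self.nodes):
            raise ValueError("feature row count != |V|")
        self._index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, gene: str) -> int:
        return self._index[gene]

    def neighbours(self, tf: str) -> set[str]:
        return {u for t, u in self.edges if t == tf}


def build_graph(edges: pd.DataFrame, expr: ExpressionMatrix) -> RegGraph:
    """Graph over the union of edge endpoints with raw expression features."""
    if edges.empty:
        raise ValueError("empty edge set")
    pairs = list(dict.fromkeys(zip(edges["tf"], edges["target"])))
    nodes = list(dict.fromkeys([g for p in pairs for g in p]))
    gene_idx = expr.gene_index()
    missing = [g for g in nodes if g not in gene_idx]
    if missing:
        raise ValueError(f"edge genes absent from expression: {missing[:5]}")
    X = expr.values[[gene_idx[g] for g in nodes]]
    return RegGraph(nodes, pairs, X)


@dataclass
class EdgeSplit:
    """Positive and sampled-negative edges with an 8:1:1 partition."""

    edges: list[tuple[str, str]]
    labels: np.ndarray  # 1 = positive, 0 = sampled negative
    partition: np.ndarray  # 'train' | 'val' | 'test'

    def part(self, name: str) -> tuple[list[tuple[str, str]], np.ndarray]:
        m = self.partition == name
        return [e for e, keep in zip(self.edges, m) if keep], self.labels[m]


def sample_negatives(
    graph: RegGraph,
    positives: set[tuple[str, str]],
    seed: int,
    ratios: tuple[int, int, int] = (8, 1, 1),
) -> EdgeSplit:
    """Per-TF balanced negative sampling plus a stratified 8:1:1 split.

    For each TF t, |S(t)| = min(|N(t)|, |V − N(t) − {t}|) non-targets are
    drawn without replacement; L_N never intersects the positive set.
    """
    bad = positives - set(graph.edges)
    if bad:
        raise ValueError(f"positives outside graph edge set: {sorted(bad)[:3]}")
    rng = np.random.default_rng(seed)
    nodes = np.array(graph.nodes)
    pos_by_tf: dict[str, set[str]] = {}
    for t, u in positives:
        pos_by_tf.setdefault(t, set()).add(u)
    negatives: list[tuple[str, str]] = []
    for t in sorted(pos_by_tf):
        n_t = pos_by_tf[t]
        eligible = np.array(sorted(set(graph.nodes) - graph.neighbours(t) - {t}))
        if len(eligible) == 0:
            warnings.warn(f"TF {t} has no eligible non-targets; zero negatives")
            continue
        k = min(len(n_t), len(eligible))
        chosen = rng.choice(eligible, size=k, replace=False)
        negatives.extend((t, str(v)) for v in chosen)

    def split_one(items: list, rng: np.random.Generator) -> np.ndarray:
        n = len(items)
        order = rng.permutation(n)
        n_val = int(round(n * ratios[1] / sum(ratios)))
        n_test = int(round(n * ratios[2] / sum(ratios)))
        part = np.full(n, "train", dtype=object)
        part[order[:n_val]] = "val"
        part[order[n_val : n_val + n_test]] = "test"
        return part

    pos_list = sorted(positives)
    part = np.concatenate([split_one(pos_list, rng), split_one(negatives, rng)])
    edges = pos_list + negatives
    labels = np.concatenate([np.ones(len(pos_list)), np.zeros(len(negatives))])
    return EdgeSplit(edges, labels, part)


def adaptive_avg_pool(x: np.ndarray, out_len: int) -> np.ndarray:
    """Adaptive 1-D average pooling of each row to ``out_len`` values."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    starts = (np.arange(out_len) * n) // out_len
    ends = -(-(np.arange(1, out_len + 1) * n) // out_len)  # ceil
    return np.stack([x[:, s:e].mean(axis=1) for s, e in zip(starts, ends)], axis=1)


def reduce_features(
    X: np.ndarray, feature_len: int, log1p: bool = True
) -> np.ndarray:
    """Pool expression vectors to a fixed length and z-score per feature."""
    Xp = np.log1p(X) if log1p else np.asarray(X, dtype=float)
    Xp = adaptive_avg_pool(Xp, feature_len)
    mu = Xp.mean(axis=0)
    sd = Xp.std(axis=0)
    sd[sd == 0] = 1.0
    return (Xp - mu) / sd


def normalized_adjacency(graph: RegGraph) -> np.ndarray:
    """Symmetric D̃^(−1/2)(A+I)D̃^(−1/2) over the undirected edge support."""
    n = graph.n_nodes
    A = np.zeros((n, n))
    for t, u in graph.edges:
        i, j = graph.index(t), graph.index(u)
        A[i, j] = A[j, i] = 1.0
    A += np.eye(n)
    dinv = 1.0 / np.sqrt(A.sum(axis=1))
    return A * dinv[:, None] * dinv[None, :]


def edge_embed(h_t: np.ndarray, h_u: np.ndarray) -> np.ndarray:
    """Outer product e(t,u)[i,j] = h_t[i]·h_u[j]; asymmetric in (t,u)."""
    h_t, h_u = np.asarray(h_t), np.asarray(h_u)
    if h_t.shape != h_u.shape:
        raise ValueError("embedding length mismatch")
    return np.outer(h_t, h_u)


@dataclass(frozen=True)
class ModelConfig:
    feature_len: int = 256
    embed_dim: int = 64
    hidden_dim: int = 64
    dropout: float = 0.5
    lr: float = 0.005
    weight_decay: float = 1e-4
    patience: int = 200
    max_epochs: int = 1000
    conv_channels: tuple[int, int] = (8, 16)
    log1p: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class _Net:
    """Parameters and forward pass; dropout only when training."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d, h, f = cfg.embed_dim, cfg.hidden_dim, cfg.feature_len
        c1, c2 = cfg.conv_channels

        def glorot(*shape):
            fan_in = shape[-2] if len(shape) == 2 else int(np.prod(shape[1:]))
            fan_out = shape[-1] if len(shape) == 2 else shape[0]
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return Parameter(rng.uniform(-s, s, size=shape))

        def bias(n, fan_in):
            # nonzero init: with all-zero inputs (feature ablation) a zero
            # bias is a stationary point of relu and would never train
            b = 1.0 / np.sqrt(fan_in)
            return Parameter(rng.uniform(-b, b, size=n))

        self.Wr, self.br = glorot(f, h), bias(h, f)
        self.W1 = glorot(h, h)
        self.W2 = glorot(h, d)
        self.Kc1 = glorot(c1, 1, 3, 3)
        self.bc1 = bias(c1, 9)
        self.Kc2 = glorot(c2, c1, 3, 3)
        self.bc2 = bias(c2, 9 * c1)
        self.Wo, self.bo = glorot(c2, 1), bias(1, c2)
        self.cfg = cfg

    def params(self) -> list[Parameter]:
        return [self.Wr, self.br, self.W1, self.W2, self.Kc1, self.bc1,
                self.Kc2, self.bc2, self.Wo, self.bo]

    def node_embeddings(
        self, A: np.ndarray, Xp: np.ndarray,
        training: bool, rng: np.random.Generator,
    ) -> Tensor:
        H0 = Tensor(Xp).matmul(self.Wr).add(self.br).relu()
        H1 = H0.left_matmul(A).matmul(self.W1).relu()
        if training and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            mask = (rng.random(H1.shape) < keep) / keep
            H1 = H1.mul_mask(mask)
        return H1.left_matmul(A).matmul(self.W2)

    def edge_logits(
        self, H: Tensor, src_idx: np.ndarray, dst_idx: np.ndarray,
        training: bool, rng: np.random.Generator,
    ) -> Tensor:
        E = Tensor.outer_batch(H.gather_rows(src_idx), H.gather_rows(dst_idx))
        B, d = len(src_idx), self.cfg.embed_dim
        x = E.reshape(B, 1, d, d)
        x = x.conv2d(self.Kc1, self.bc1).relu()
        x = x.conv2d(self.Kc2, self.bc2).relu()
        x = x.global_avg_pool()
        return x.matmul(self.Wo).add(self.bo).reshape(B)

    def forward(self, A, Xp, src_idx, dst_idx, training, rng) -> Tensor:
        H = self.node_embeddings(A, Xp, training, rng)
        return self.edge_logits(H, src_idx, dst_idx, training, rng)

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p.data = s.copy()


@dataclass
class TrainedModel:
    """Weights, config, chosen decision threshold, and training metrics."""

    config: ModelConfig
    weights: list[np.ndarray]
    threshold: float = 0.5
    metrics: dict = field(default_factory=dict)

    def _net(self) -> _Net:
        net = _Net(self.config, np.random.default_rng(0))
        net.load_state(self.weights)
        return net

    def score_edges(
        self, graph: RegGraph, edges: list[tuple[str, str]]
    ) -> np.ndarray:
        """Probability per edge under fixed weights (deterministic)."""
        A = normalized_adjacency(graph)
        Xp = reduce_features(graph.X, self.config.feature_len, self.config.log1p)
        src = np.array([graph.index(t) for t, _ in edges])
        dst = np.array([graph.index(u) for _, u in edges])
        net = self._net()
        logits = net.forward(A, Xp, src, dst, False, np.random.default_rng(0))
        return _sigmoid(logits.data)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez(outdir / "weights.npz",
                 **{f"p{i}": w for i, w in enumerate(self.weights)})
        cfg = asdict(self.config)
        cfg["conv_channels"] = list(cfg["conv_channels"])
        with open(outdir / "model.json", "w") as fh:
            json.dump({"config": cfg, "threshold": self.threshold,
                       "metrics": self.metrics}, fh, indent=1)

    @classmethod
    def load(cls, outdir: str | Path) -> "TrainedModel":
        outdir = Path(outdir)
        with open(outdir / "model.json") as fh:
            meta = json.load(fh)
        meta["config"]["conv_channels"] = tuple(meta["config"]["conv_channels"])
        cfg = ModelConfig(**meta["config"])
        with np.load(outdir / "weights.npz") as z:
            weights = [z[f"p{i}"] for i in range(len(z.files))]
        return cls(cfg, weights, meta["threshold"], meta["metrics"])


def _classification_metrics(y: np.ndarray, scores: np.ndarray,
                            threshold: float = 0.5) -> dict:
    pred = scores >= threshold
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "accuracy": float(skmetrics.accuracy_score(y, pred)),
            "precision": float(skmetrics.precision_score(y, pred, zero_division=0)),
            "recall": float(skmetrics.recall_score(y, pred, zero_division=0)),
            "f1": float(skmetrics.f1_score(y, pred, zero_division=0)),
            "auc": float(skmetrics.roc_auc_score(y, scores))
            if len(np.unique(y)) == 2 else float("nan"),
        }


def train(
    graph: RegGraph, split: EdgeSplit, cfg: ModelConfig,
    A: np.ndarray | None = None,
) -> tuple[TrainedModel, dict]:
    """Train to best validation loss; returns model and per-partition metrics."""
    for part in ("train", "val", "test"):
        _, y = split.part(part)
        if len(np.unique(y)) < 2:
            raise ValueError(f"partition {part!r} lacks both classes")
    rng = np.random.default_rng(cfg.seed)
    if A is None:
        A = normalized_adjacency(graph)
    Xp = reduce_features(graph.X, cfg.feature_len, cfg.log1p)
    net = _Net(cfg, rng)
    opt = Adam(net.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)

    def idx(edges):
        return (np.array([graph.index(t) for t, _ in edges]),
                np.array([graph.index(u) for _, u in edges]))

    tr_e, tr_y = split.part("train")
    va_e, va_y = split.part("val")
    te_e, te_y = split.part("test")
    tr_s, tr_d = idx(tr_e)
    va_s, va_d = idx(va_e)
    te_s, te_d = idx(te_e)

    best_val = np.inf
    best_state = net.state()
    best_epoch = 0
    history = []
    for epoch in range(cfg.max_epochs):
        logits = net.forward(A, Xp, tr_s, tr_d, True, rng)
        loss = bce_with_logits(logits, tr_y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        val_logits = net.forward(A, Xp, va_s, va_d, False, rng)
        val_loss = float(bce_with_logits(val_logits, va_y).data)
        history.append({"epoch": epoch, "train_loss": float(loss.data),
                        "val_loss": val_loss})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = net.state()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    net.load_state(best_state)

    def scores(s, d):
        logits = net.forward(A, Xp, s, d, False, rng)
        return _sigmoid(logits.data)

    report = {
        part: _classification_metrics(y, scores(s, d))
        for part, y, s, d in (
            ("train", tr_y, tr_s, tr_d),
            ("val", va_y, va_s, va_d),
            ("test", te_y, te_s, te_d),
        )
    }
    report["best_epoch"] = best_epoch
    report["history"] = history
    model = TrainedModel(cfg, net.state(), threshold=0.5, metrics=report)
    return model, report


def evaluate(model: TrainedModel, graph: RegGraph, split: EdgeSplit,
             part: str = "test") -> dict:
    edges, y = split.part(part)
    return _classification_metrics(y, model.score_edges(graph, edges))


def grid_search(
    graph: RegGraph, split: EdgeSplit, base: ModelConfig,
    param_grid: dict[str, list],
) -> tuple[TrainedModel, dict, list[dict]]:
    """Optional hyperparameter search: train every combination, pick the
    best validation AUC.  Not run by default anywhere in the pipeline."""
    import itertools as it
    from dataclasses import replace

    keys = sorted(param_grid)
    trials = []
    best = None
    for combo in it.product(*(param_grid[k] for k in keys)):
        overrides = dict(zip(keys, combo))
        cfg = replace(base, **overrides)
        model, report = train(graph, split, cfg)
        val_auc = report["val"]["auc"]
        trials.append({"params": overrides, "val_auc": val_auc,
                       "test": report["test"]})
        if best is None or val_auc > best[2]:
            best = (model, report, val_auc)
    return best[0], best[1], trials


@dataclass
class ThresholdSweep:
    grid: np.ndarray
    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    chosen: float
    warned: bool = False


def threshold_postprocess(
    scores: np.ndarray, labels: np.ndarray,
    grid_start: float = 0.5, grid_end: float = 1.0, grid_step: float = 0.01,
    f1_floor: float = 0.8,
) -> ThresholdSweep:
    """Sweep the decision threshold and pick the largest with F1 >= floor."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    grid = np.round(np.arange(grid_start, grid_end + 1e-9, grid_step), 10)
    acc, prec, rec, f1 = (np.zeros(len(grid)) for _ in range(4))
    for i, thr in enumerate(grid):
        m = _classification_metrics(labels, scores, thr)
        acc[i], prec[i], rec[i], f1[i] = (
            m["accuracy"], m["precision"], m["recall"], m["f1"]
        )
    ok = np.nonzero(f1 >= f1_floor)[0]
    if len(ok) == 0:
        warnings.warn(
            f"no grid threshold reaches F1 >= {f1_floor}; defaulting to 0.5"
        )
        return ThresholdSweep(grid, acc, prec, rec, f1, 0.5, warned=True)
    return ThresholdSweep(grid, acc, prec, rec, f1, float(grid[ok[-1]]))


def ablate(
    graph: RegGraph, split: EdgeSplit, cfg: ModelConfig, mode: str,
) -> dict:
    """Retrain under an ablation and report metrics.

    ``shuffle_graph`` rewires the message-passing edges uniformly at
    random, preserving |E|; ``zero_features`` zeroes every node feature.
    Labels and splits are untouched.
    """
    if mode == "shuffle_graph":
        rng = np.random.default_rng(cfg.seed + 7)
        n = graph.n_nodes
        m = len(graph.edges)
        pairs: set[tuple[int, int]] = set()
        while len(pairs) < m:
            i, j = rng.integers(0, n, size=2)
            if i != j:
                pairs.add((int(i), int(j)))
        shuffled = RegGraph(
            graph.nodes,
            [(graph.nodes[i], graph.nodes[j]) for i, j in sorted(pairs)],
            graph.X,
        )
        A = normalized_adjacency(shuffled)
        _, report = train(graph, split, cfg, A=A)
    elif mode == "zero_features":
        zeroed = RegGraph(graph.nodes, graph.edges, np.zeros_like(graph.X))
        _, report = train(zeroed, split, cfg)
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")
    return report


def transfer_predict(
    model: TrainedModel, new_graph: RegGraph,
    edges: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Score a new graph's candidate edges with pre-trained weights.

    Pooling to the stored ``feature_len`` makes the sample count of the
    new expression atlas irrelevant; gene identity plays no role.
    """
    if edges is None:
        edges = new_graph.edges
    scores = model.score_edges(new_graph, edges)
    return pd.DataFrame({
        "tf": [t for t, _ in edges],
        "target": [u for _, u in edges],
        "gcn_score": scores,
        "predicted": scores >= model.threshold,
    })
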