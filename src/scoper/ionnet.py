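"""Graph neural network classifying probe neighborhoods as Mg2+ sites vs water.

The classifier sees only chemistry one-hots and interatomic distances, so its
output is invariant to rigid motions and node order by construction.  The
architecture is one multi-head graph-attention layer followed by
edge-conditioned graph-convolution layers, gated by Gaussian radial basis
encodings of edge distances, with mean+max global pooling and a two-layer
head.  It is sized to train on a CPU in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_score, recall_score, roc_auc_score
from sklearn.model_selection import GroupKFold

from . import nn
from .structure_io import Structure
from .surface_probes import (GraphDataset, NeighborhoodError, NeighborhoodGraph,
                             N_NODE_FEATURES, Probe, extract_neighborhood)


class TrainingError(ValueError):
    """Raised for unusable training inputs."""


class UntrainedModelError(RuntimeError):
    """Raised when predict is called on a model that was never trained."""


@dataclass
class IonPrediction:
    position: np.ndarray
    confidence: float


@dataclass
class GraphBatch:
    x: np.ndarray          # (n_nodes, F)
    edge_src: np.ndarray   # directed edges incl. reverse + self loops
    edge_dst: np.ndarray
    edge_dist: np.ndarray
    node_graph: np.ndarray  # graph id per node
    n_graphs: int
    # cached sparse operators: row selection by src/dst, and graph pooling
    P_src: object = None
    P_srcT: object = None
    P_dst: object = None
    P_dstT: object = None
    P_pool: object = None
    P_poolT: object = None


def make_batch(graphs: list[NeighborhoodGraph]) -> GraphBatch:
    from scipy import sparse

    xs, srcs, dsts, dists, gids = [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        n = g.n_nodes
        xs.append(g.node_features)
        gids.append(np.full(n, gi))
        if len(g.edges):
            e = g.edges + offset
            srcs.extend([e[:, 0], e[:, 1]])
            dsts.extend([e[:, 1], e[:, 0]])
            dists.extend([g.edge_distances, g.edge_distances])
        loop = np.arange(offset, offset + n)
        srcs.append(loop)
        dsts.append(loop)
        dists.append(np.zeros(n))
        offset += n
    src = np.concatenate(srcs).astype(np.int64)
    dst = np.concatenate(dsts).astype(np.int64)
    node_graph = np.concatenate(gids).astype(np.int64)
    n_nodes, n_edges = offset, len(src)
    ones = np.ones(n_edges, dtype=nn.DTYPE)

    def selector(idx, n_cols):
        S = sparse.csr_matrix((ones[:len(idx)], (np.arange(len(idx)), idx)),
                              shape=(len(idx), n_cols))
        return S, S.T.tocsr()

    P_src, P_srcT = selector(src, n_nodes)
    P_dst, P_dstT = selector(dst, n_nodes)
    P_pool = sparse.csr_matrix(
        (np.ones(n_nodes, dtype=nn.DTYPE), (node_graph, np.arange(n_nodes))),
        shape=(len(graphs), n_nodes))
    return GraphBatch(
        x=np.concatenate(xs),
        edge_src=src,
        edge_dst=dst,
        edge_dist=np.concatenate(dists),
        node_graph=node_graph,
        n_graphs=len(graphs),
        P_src=P_src, P_srcT=P_srcT, P_dst=P_dst, P_dstT=P_dstT,
        P_pool=P_pool, P_poolT=P_pool.T.tocsr(),
    )


class IonNetModel:
    """Probe-neighborhood classifier emitting P(Mg2+ site) in [0, 1]."""

    def __init__(self, n_features: int = N_NODE_FEATURES, hidden: int = 32,
                 heads: int = 4, n_rbf: int = 16, rbf_max: float = 8.0,
                 conv_layers: int = 2, seed: int = 0):
        self.config = dict(n_features=n_features, hidden=hidden, heads=heads,
                           n_rbf=n_rbf, rbf_max=rbf_max, conv_layers=conv_layers,
                           seed=seed)
        self.trained = False
        rng = np.random.default_rng(seed)
        self.params: dict[str, nn.Tensor] = {}
        dh = hidden // heads

        def glorot(*shape):
            scale = np.sqrt(2.0 / sum(shape[:2])) if len(shape) > 1 else 0.1
            return nn.Tensor(rng.normal(0.0, scale, size=shape))

        for h in range(heads):
            self.params[f"gat_W{h}"] = glorot(n_features, dh)
            self.params[f"gat_as{h}"] = glorot(dh, 1)
            self.params[f"gat_ad{h}"] = glorot(dh, 1)
            self.params[f"gat_ae{h}"] = glorot(n_rbf, 1)
        self.params["gat_b"] = nn.Tensor(np.zeros(hidden))
        for layer in range(conv_layers):
            self.params[f"conv_Wmsg{layer}"] = glorot(hidden, hidden)
            self.params[f"conv_Wself{layer}"] = glorot(hidden, hidden)
            self.params[f"conv_Wgate{layer}"] = glorot(n_rbf, hidden)
            self.params[f"conv_bgate{layer}"] = nn.Tensor(np.zeros(hidden))
            self.params[f"conv_b{layer}"] = nn.Tensor(np.zeros(hidden))
        self.params["head_W1"] = glorot(2 * hidden, hidden)
        self.params["head_b1"] = nn.Tensor(np.zeros(hidden))
        self.params["head_W2"] = glorot(hidden, 1)
        self.params["head_b2"] = nn.Tensor(np.zeros(1))

    # ---- forward ---------------------------------------------------------
    def _rbf(self, d: np.ndarray) -> np.ndarray:
        n_rbf, rbf_max = self.config["n_rbf"], self.config["rbf_max"]
        centers = np.linspace(0.0, rbf_max, n_rbf)
        gamma = 0.5 / (centers[1] - centers[0]) ** 2
        return np.exp(-gamma * (d[:, None] - centers[None, :]) ** 2)

    def forward(self, batch: GraphBatch) -> nn.Tensor:
        p = self.params
        n_nodes = batch.x.shape[0]
        dst = batch.edge_dst
        rbf = nn.Tensor(self._rbf(batch.edge_dist), requires_grad=False)
        x = nn.Tensor(batch.x, requires_grad=False)

        def gather_src(t):
            return nn.sparse_apply(batch.P_src, t, batch.P_srcT)

        def gather_dst(t):
            return nn.sparse_apply(batch.P_dst, t, batch.P_dstT)

        def scatter_dst(t):  # sum edge values into their destination node
            return nn.sparse_apply(batch.P_dstT, t, batch.P_dst)

        # graph attention, one softmax per destination node and head
        head_outs = []
        for h in range(self.config["heads"]):
            Hh = x @ p[f"gat_W{h}"]
            h_src = gather_src(Hh)
            e = (h_src @ p[f"gat_as{h}"]
                 + gather_dst(Hh) @ p[f"gat_ad{h}"]
                 + rbf @ p[f"gat_ae{h}"]).leaky_relu(0.2)
            # softmax over incoming edges, stabilized by a detached max
            m = np.full((n_nodes, 1), -np.inf, dtype=e.data.dtype)
            np.maximum.at(m, dst, e.data)
            e_exp = (e - nn.Tensor(m[dst], requires_grad=False)).exp()
            alpha = e_exp / gather_dst(scatter_dst(e_exp))
            head_outs.append(scatter_dst(h_src * alpha))
        hidden = (nn.concat(head_outs, axis=1) + p["gat_b"]).relu()

        # edge-conditioned graph convolutions
        inv_deg = 1.0 / np.maximum(np.bincount(dst, minlength=n_nodes), 1)
        inv_deg = nn.Tensor(inv_deg[:, None], requires_grad=False)
        for layer in range(self.config["conv_layers"]):
            gate = (rbf @ p[f"conv_Wgate{layer}"] + p[f"conv_bgate{layer}"]).sigmoid()
            msg = gather_src(hidden @ p[f"conv_Wmsg{layer}"]) * gate
            agg = scatter_dst(msg) * inv_deg
            hidden = (agg + hidden @ p[f"conv_Wself{layer}"] + p[f"conv_b{layer}"]).relu()

        # mean + max pooling per graph, then the classifier head
        counts = np.bincount(batch.node_graph, minlength=batch.n_graphs)
        inv_counts = nn.Tensor(1.0 / np.maximum(counts, 1)[:, None], requires_grad=False)
        pooled_mean = nn.sparse_apply(batch.P_pool, hidden, batch.P_poolT) * inv_counts
        pooled_max = nn.segment_max(hidden, batch.node_graph, batch.n_graphs)
        pooled = nn.concat([pooled_mean, pooled_max], axis=1)
        z = (pooled @ p["head_W1"] + p["head_b1"]).relu()
        return z @ p["head_W2"] + p["head_b2"]

    def predict_proba(self, graphs: list[NeighborhoodGraph]) -> np.ndarray:
        if not self.trained:
            raise UntrainedModelError("model has not been trained or loaded")
        if not graphs:
            return np.zeros(0)
        out = []
        for lo in range(0, len(graphs), 512):  # bound peak memory
            logits = self.forward(make_batch(graphs[lo:lo + 512])).data.ravel()
            out.append(1.0 / (1.0 + np.exp(-logits)))
        return np.concatenate(out)

    # ---- persistence -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {k: t.data for k, t in self.params.items()}
        arrays["__config__"] = np.array(json.dumps({**self.config,
                                                    "trained": self.trained}))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "IonNetModel":
        z = np.load(path, allow_pickle=False)
        config = json.loads(str(z["__config__"]))
        trained = config.pop("trained")
        model = cls(**config)
        for k in model.params:
            model.params[k] = nn.Tensor(z[k])
        model.trained = trained
        return model

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, w in weights.items():
            self.params[k].data = w.copy()


def _bce_with_logits(logits: nn.Tensor, y: np.ndarray) -> nn.Tensor:
    # softplus(z) - y z, with softplus(z) = relu(z) + log(1 + exp(-|z|))
    z = logits.reshape(-1)
    abs_z = z.relu() + (-z).relu()
    softplus = z.relu() + ((-abs_z).exp() + 1.0).log()
    yt = nn.Tensor(np.asarray(y, dtype=float), requires_grad=False)
    return (softplus - yt * z).mean()


def train(dataset: GraphDataset, folds: int = 4, seed: int = 0,
          epochs: int = 40, lr: float = 1e-3, patience: int = 6,
          hidden: int = 32, batch_size: int = 512, verbose: bool = False):
    """Cross-validated training with structure-level fold splitting.

    All graphs from one source structure land in the same fold, preventing
    leakage of near-duplicate neighborhoods across the train/validation
    boundary.  Each epoch resamples the majority class to a 1:1 balance and
    sweeps the balanced set in minibatches; early stopping monitors held-out
    AUROC.  Returns (models, metrics): one trained model and one metrics
    dict (AUROC, precision, recall at 0.5) per fold.
    """
    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise TrainingError("training set must contain both classes")
    if folds < 2:
        raise TrainingError("at least 2 folds required")
    groups = dataset.groups
    rng = np.random.default_rng(seed)
    # permute group ids so fold assignment is seed-controlled
    perm = rng.permutation(groups.max() + 1)
    shuffled_groups = perm[groups]

    models, metrics = [], []
    splitter = GroupKFold(n_splits=folds)
    indices = np.arange(len(dataset))
    for fold, (tr, va) in enumerate(splitter.split(indices, labels, shuffled_groups)):
        frng = np.random.default_rng(seed * 1000 + fold)
        model = IonNetModel(hidden=hidden, seed=seed * 1000 + fold)
        opt = nn.Adam(model.params, lr=lr)
        val_graphs = [dataset.graphs[i] for i in va]
        val_batch = make_batch(val_graphs)
        y_val = labels[va]
        pos = tr[labels[tr] == 1]
        neg = tr[labels[tr] == 0]
        n_per_class = min(len(pos), len(neg))
        if n_per_class == 0:
            raise TrainingError(f"fold {fold}: a class is absent from the training split")

        best_auc, best_weights, stall = -np.inf, None, 0
        loss = None
        for epoch in range(epochs):
            chosen = np.concatenate([
                frng.choice(pos, n_per_class, replace=False),
                frng.choice(neg, n_per_class, replace=False),
            ])
            frng.shuffle(chosen)
            for lo in range(0, len(chosen), batch_size):
                sub = chosen[lo:lo + batch_size]
                batch = make_batch([dataset.graphs[i] for i in sub])
                logits = model.forward(batch)
                loss = _bce_with_logits(logits, labels[sub])
                opt.zero_grad()
                loss.backward()
                opt.step()

            model.trained = True
            val_logits = model.forward(val_batch).data.ravel()
            auc = roc_auc_score(y_val, val_logits) if len(np.unique(y_val)) > 1 else 0.5
            if verbose:
                print(f"fold {fold} epoch {epoch}: loss={float(loss.data):.4f} "
                      f"val AUROC={auc:.4f}")
            if auc > best_auc + 1e-4:
                best_auc, best_weights, stall = auc, model.copy_weights(), 0
            else:
                stall += 1
                if stall >= patience:
                    break
        if best_weights is not None:
            model.set_weights(best_weights)
        model.trained = True
        proba = model.predict_proba(val_graphs)
        pred = (proba >= 0.5).astype(int)
        metrics.append({
            "fold": fold,
            "auroc": float(roc_auc_score(y_val, proba)) if len(np.unique(y_val)) > 1 else 0.5,
            "precision": float(precision_score(y_val, pred, zero_division=0)),
            "recall": float(recall_score(y_val, pred, zero_division=0)),
            "n_val": int(len(va)),
        })
        models.append(model)
    return models, metrics


def predict(model: IonNetModel, rna: Structure, probes: list[Probe],
            radius: float = 8.0) -> list[IonPrediction]:
    """One confidence per probe; probes with empty neighborhoods are dropped."""
    if not model.trained:
        raise UntrainedModelError("model has not been trained or loaded")
    graphs, kept = [], []
    for probe in probes:
        try:
            graphs.append(extract_neighborhood(rna, probe.position, radius))
            kept.append(probe)
        except NeighborhoodError:
            continue
    proba = model.predict_proba(graphs)
    return [IonPrediction(position=np.asarray(p.position, dtype=float), confidence=float(c))
            for p, c in zip(kept, proba)]


def threshold_and_cluster(predictions: list[IonPrediction], threshold: float = 0.5,
                          merge_radius: float = 3.5) -> list[IonPrediction]:
    """Greedy confidence-first selection of well-separated binding sites.

    Drop predictions below the threshold, then repeatedly take the
    highest-confidence survivor and remove everything within merge_radius of
    it.  The result is confidence-sorted with pairwise separation >=
    merge_radius.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    survivors = sorted((p for p in predictions if p.confidence >= threshold),
                       key=lambda p: -p.confidence)
    selected: list[IonPrediction] = []
    while survivors:
        top = survivors.pop(0)
        selected.append(top)
        survivors = [p for p in survivors
                     if np.linalg.norm(p.position - top.position) >= merge_radius]
    return selected
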