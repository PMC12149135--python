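"""The multi-view Nm-site network.

Three feature views are processed by dedicated branches and fused:

* sequence one-hot and chemical-property views each pass through a 1-D CNN
  (same-padded convolution, ReLU, max-pool 2, flatten, linear) yielding the
  deep representations X_seq2 and X_chem2;
* the base-pair matrix defines the edge set of a graph over window
  positions (pair edges + backbone edges + self-loops) whose one-hot node
  features are refined by two stacked multi-head graph-attention layers
  (per head: e_ij = LeakyReLU(a^T [W h_i || W h_j]), attention softmaxed
  over the neighborhood, heads averaged, ELU), giving per-node X_str2;
* cross-attention fuses the views: Q = X_seq2 W_q, K = X_str2 W_k,
  V = X_str2 W_v, A = softmax(Q K^T / sqrt(D_k)), O = A V.

O (averaged over queries) is concatenated with X_chem2 and classified by
two fully connected layers ending in a sigmoid. Ablation switches disable
views: without the sequence or structure view the cross-attention step is
skipped and the remaining deep features are concatenated directly.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

EPS = 1e-7


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the fixed settings)."""

    n_kernels: int = 64
    kernel_size: int = 3
    embed_dim: int = 64
    n_heads: int = 8
    n_gat_layers: int = 2
    pool_size: int = 2
    dropout: float = 0.2
    leaky_slope: float = 0.2
    fc_hidden: int = 64
    use_seq: bool = True
    use_chem: bool = True
    use_str: bool = True
    threshold: float = 0.5

    def __post_init__(self):
        if not (self.use_seq or self.use_chem or self.use_str):
            raise ConfigError("at least one feature view must be enabled")
        for name in ("n_kernels", "embed_dim", "n_heads", "n_gat_layers",
                     "pool_size", "fc_hidden"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    def head_input_dim(self, window_len: int) -> int:
        dim = 0
        if self.use_str:
            if self.use_seq:
                dim += self.embed_dim            # fused O, mean over queries
            else:
                # no queries available: pooled GAT output enters the head
                # flattened, preserving positional structure
                dim += (window_len // self.pool_size) * self.embed_dim
        elif self.use_seq:
            dim += self.embed_dim                # X_seq2 directly
        if self.use_chem:
            dim += self.embed_dim
        return dim


@dataclass
class Prediction:
    prob: float
    label_hat: int


def _glorot(rng, shape):
    fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    s = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


def init_params(config: ModelConfig, window_len: int, seed=0,
                dtype=np.float32) -> dict[str, Tensor]:
    """Create the trainable parameter set for a given window length."""
    rng = np.random.default_rng(seed)
    L = window_len
    Lp = L // config.pool_size
    K, E, H = config.n_kernels, config.embed_dim, config.n_heads
    k = config.kernel_size
    p: dict[str, np.ndarray] = {}

    if config.use_seq:
        p["seq_conv_w"] = _glorot(rng, (k, 4, K))
        p["seq_conv_b"] = np.zeros(K)
        p["seq_fc_w"] = _glorot(rng, (Lp * K, E))
        p["seq_fc_b"] = np.zeros(E)
    if config.use_chem:
        p["chem_conv_w"] = _glorot(rng, (k, 3, K))
        p["chem_conv_b"] = np.zeros(K)
        p["chem_fc_w"] = _glorot(rng, (Lp * K, E))
        p["chem_fc_b"] = np.zeros(E)
    if config.use_str:
        f_in = 4
        for layer in range(1, config.n_gat_layers + 1):
            p[f"gat{layer}_w"] = _glorot(rng, (H, f_in, E))
            p[f"gat{layer}_a_src"] = _glorot(rng, (H, E))
            p[f"gat{layer}_a_dst"] = _glorot(rng, (H, E))
            f_in = E
        if config.use_seq:
            p["xatt_wq"] = _glorot(rng, (E, E))
            p["xatt_wk"] = _glorot(rng, (E, E))
            p["xatt_wv"] = _glorot(rng, (E, E))

    d_in = config.head_input_dim(window_len)
    p["head_fc1_w"] = _glorot(rng, (d_in, config.fc_hidden))
    p["head_fc1_b"] = np.zeros(config.fc_hidden)
    p["head_fc2_w"] = _glorot(rng, (config.fc_hidden, 1))
    p["head_fc2_b"] = np.zeros(1)
    return {name: ad.parameter(arr.astype(dtype)) for name, arr in p.items()}


# ------------------------------------------------------------- CNN branch

def cnn_branch(x, params: dict, config: ModelConfig, prefix: str = "seq") -> Tensor:
    """Conv(kernel 3, same padding) + ReLU + max-pool 2 + flatten + linear.

    ``x`` is (L, C) for a single window or (B, L, C) batched; returns the
    embed_dim representation (X_seq2 / X_chem2), batched as (B, embed_dim).
    """
    x = x if isinstance(x, Tensor) else ad.tensor(np.asarray(x, dtype=params[f"{prefix}_conv_w"].data.dtype))
    squeeze = x.ndim == 2
    if squeeze:
        x = ad.reshape(x, (1,) + x.shape)
    B, L, _ = x.shape
    if L < config.kernel_size:
        raise ValueError("window shorter than the convolution kernel")
    h = ad.relu(ad.conv1d_same(x, params[f"{prefix}_conv_w"], params[f"{prefix}_conv_b"]))
    h = ad.maxpool1d(h, config.pool_size)
    h = ad.reshape(h, (B, h.shape[1] * h.shape[2]))
    out = ad.matmul(h, params[f"{prefix}_fc_w"]) + params[f"{prefix}_fc_b"]
    return ad.reshape(out, (out.shape[1],)) if squeeze else out


# ------------------------------------------------------------- GAT branch

def _graph_arrays(adj: np.ndarray):
    """Padded neighbor lists from a boolean (B, L, L) adjacency.

    Returns (nbr, nbr_mask, pidx): neighbor indices (B, L, D) in ascending
    order, their validity mask, and the partner index pidx[b, l, d] giving
    the slot of l inside nbr[b, nbr[b, l, d]] (defined because the
    adjacency is symmetric); D is the maximum degree in the batch.
    """
    B, L, _ = adj.shape
    deg = adj.sum(axis=-1)
    if (deg == 0).any():
        raise ValueError("graph has an isolated node (self-loops missing)")
    D = int(deg.max())
    order = np.argsort(~adj, axis=-1, kind="stable")
    nbr = np.ascontiguousarray(order[:, :, :D])
    nbr_mask = np.take_along_axis(adj, nbr, axis=-1)
    slot = np.zeros((B, L, L), dtype=np.int32)
    np.put_along_axis(slot, nbr, np.arange(D, dtype=np.int32)[None, None], axis=-1)
    pidx = slot[np.arange(B)[:, None, None], nbr, np.arange(L)[None, :, None]]
    return nbr.astype(np.int32), nbr_mask, pidx.astype(np.int32)


def _gather_nodes(x: np.ndarray, nbr: np.ndarray):
    """x (B, H, L, ...) gathered at node index nbr (B, L, D) -> (B, H, L, D, ...)."""
    B, H = x.shape[:2]
    return x[np.arange(B)[:, None, None, None],
             np.arange(H)[None, :, None, None],
             nbr[:, None]]


def _gat_layer_fused(h: Tensor, w: Tensor, a_src: Tensor, a_dst: Tensor,
                     graph, slope: float):
    """One multi-head graph-attention layer as a fused autodiff primitive.

    Per head: e_ij = LeakyReLU(a_src . W h_i + a_dst . W h_j) for neighbors
    j of i, attention softmaxed over the neighborhood, attention-weighted
    neighbor aggregation, heads averaged, ELU. Scores are computed only on
    the padded neighbor lists (``graph`` from :func:`_graph_arrays`), then
    scattered into a dense attention matrix for BLAS aggregation. Backward
    is hand-derived; it is checked against finite differences and a
    loop-based evaluation in the tests.
    """
    nbr, nbr_mask, pidx = graph
    B, L, F = h.shape
    H, _, E = w.shape
    hd, wd = h.data, w.data
    asrc, adst = a_src.data, a_dst.data          # (H, E)
    nbr_bh = np.broadcast_to(nbr[:, None], (B, H, L, nbr.shape[-1]))

    wh = np.matmul(hd[:, None], wd)              # (B, H, L, E)
    s_src = np.einsum("bhle,he->bhl", wh, asrc)
    s_dst = np.einsum("bhle,he->bhl", wh, adst)
    sd_n = _gather_nodes(s_dst[..., None], nbr)[..., 0]      # (B, H, L, D)
    e_raw = s_src[..., None] + sd_n
    pos = e_raw > 0
    e = np.where(pos, e_raw, slope * e_raw)
    mask4 = nbr_mask[:, None]                                # (B, 1, L, D)
    e = np.where(mask4, e, -np.inf)
    e -= e.max(axis=-1, keepdims=True)
    np.exp(e, out=e)
    e *= mask4
    alpha = e / e.sum(axis=-1, keepdims=True)                # (B, H, L, D)

    attn = np.empty((B, H, L, L), dtype=wh.dtype)            # dense, row-stochastic
    attn.fill(0)
    np.put_along_axis(attn, nbr_bh, alpha, axis=-1)
    zm = np.matmul(attn, wh).mean(axis=1)                    # (B, L, E)
    out_data = np.where(zm > 0, zm, np.expm1(np.minimum(zm, 0)))

    def backward(gout):
        iB4 = np.arange(B)[:, None, None, None]
        iH4 = np.arange(H)[None, :, None, None]
        dzm = (gout * np.where(zm > 0, 1.0, out_data + 1.0)).astype(wh.dtype)
        dz = np.broadcast_to(dzm[:, None] / H, wh.shape)     # head-uniform
        dalpha_dense = np.matmul(dz, np.swapaxes(wh, -1, -2))
        dalpha = np.take_along_axis(dalpha_dense, nbr_bh, axis=-1)
        de = alpha * (dalpha - (dalpha * alpha).sum(axis=-1, keepdims=True))
        de *= np.where(pos, 1.0, slope).astype(de.dtype)
        de *= mask4
        ds_src = de.sum(axis=-1)                             # (B, H, L)
        # incoming-edge sums via the symmetric partner index: contributions
        # to node j come from its own neighbors l at slot pidx[j].
        de_in = de[iB4, iH4, nbr[:, None], pidx[:, None]] * mask4
        ds_dst = de_in.sum(axis=-1)                          # (B, H, L)
        dwh = np.matmul(np.swapaxes(attn, -1, -2), dz)       # aggregate path
        dwh += ds_src[..., None] * asrc[None, :, None, :]
        dwh += ds_dst[..., None] * adst[None, :, None, :]
        if a_src.requires_grad:
            a_src._accumulate(np.einsum("bhl,bhle->he", ds_src, wh))
        if a_dst.requires_grad:
            a_dst._accumulate(np.einsum("bhl,bhle->he", ds_dst, wh))
        if w.requires_grad:
            hd_flat = hd.reshape(B * L, F)
            dwh_flat = dwh.transpose(1, 0, 2, 3).reshape(H, B * L, E)
            w._accumulate(np.matmul(hd_flat.T, dwh_flat))
        if h.requires_grad:
            dh = np.matmul(dwh, wd.transpose(0, 2, 1)).sum(axis=1)
            h._accumulate(dh)

    out = ad._make(out_data, (h, w, a_src, a_dst), backward)
    return out, alpha


def _gat_layer_batched(h: Tensor, graph, w: Tensor, a_src: Tensor,
                       a_dst: Tensor, slope: float,
                       return_attention: bool = False):
    out, alpha = _gat_layer_fused(h, w, a_src, a_dst, graph, slope)
    return (out, alpha) if return_attention else out


def gat_layer(node_feats, edges, params: dict, config: ModelConfig,
              return_attention: bool = False):
    """Single-graph attention layer on (N, F) node features.

    ``edges`` is an iterable of undirected (i, j) index pairs and must
    include the self-loops (i, i); ``params`` holds "w" (H, F, E) and the
    split attention vectors "a_src"/"a_dst" (H, E). With
    ``return_attention`` the head-wise dense attention matrix (H, N, N)
    is also returned (zero outside the neighborhoods).
    """
    node_feats = np.asarray(node_feats, dtype=float)
    N = node_feats.shape[0]
    adj = np.zeros((N, N), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    if not adj.diagonal().all():
        raise ValueError("edge set must include all self-loops")
    graph = _graph_arrays(adj[None])
    h = ad.tensor(node_feats[None])
    out, alpha = _gat_layer_fused(h, params["w"], params["a_src"],
                                  params["a_dst"], graph, config.leaky_slope)
    if not return_attention:
        return out.data[0]
    nbr, nbr_mask, _ = graph
    H = alpha.shape[1]
    dense = np.zeros((H, N, N))
    for head in range(H):
        for i in range(N):
            for d in range(nbr.shape[-1]):
                if nbr_mask[0, i, d]:
                    dense[head, i, nbr[0, i, d]] = alpha[0, head, i, d]
    return out.data[0], dense


def build_adjacency(x_str: np.ndarray) -> np.ndarray:
    """Edge mask for the structure graph: pairs + backbone + self-loops."""
    x_str = np.asarray(x_str)
    single = x_str.ndim == 2
    if single:
        x_str = x_str[None]
    if not np.array_equal(x_str, np.swapaxes(x_str, -1, -2)):
        raise ValueError("base-pair matrix must be symmetric")
    L = x_str.shape[-1]
    backbone = np.eye(L, k=1, dtype=bool) | np.eye(L, k=-1, dtype=bool)
    mask = (x_str > 0) | backbone | np.eye(L, dtype=bool)
    return mask[0] if single else mask


def gat_branch(x_str, x_node, params: dict, config: ModelConfig) -> Tensor:
    """Structure branch: stacked GAT layers, then max-pool over positions.

    Returns X_str2 pooled to (B, L // pool_size, embed_dim).
    """
    x_str = np.asarray(x_str)
    x_node = np.asarray(x_node, dtype=params["gat1_w"].data.dtype)
    squeeze = x_str.ndim == 2
    if squeeze:
        x_str, x_node = x_str[None], x_node[None]
    graph = _graph_arrays(build_adjacency(x_str))
    h = ad.tensor(x_node)
    for layer in range(1, config.n_gat_layers + 1):
        h = _gat_layer_batched(
            h, graph, params[f"gat{layer}_w"], params[f"gat{layer}_a_src"],
            params[f"gat{layer}_a_dst"], config.leaky_slope)
    pooled = ad.maxpool1d(h, config.pool_size)
    return ad.reshape(pooled, pooled.shape[1:]) if squeeze else pooled


# -------------------------------------------------------- cross-attention

def cross_attention(x_seq2, x_str2, params: dict,
                    return_attention: bool = False):
    """Scaled dot-product cross-attention, queries from the sequence view.

    Accepts (N, Dx)/(M, Dy) single inputs or (B, N, Dx)/(B, M, Dy) batches;
    every attention row sums to 1.
    """
    q_in = x_seq2 if isinstance(x_seq2, Tensor) else ad.tensor(np.asarray(x_seq2, dtype=params["xatt_wq"].data.dtype))
    kv_in = x_str2 if isinstance(x_str2, Tensor) else ad.tensor(np.asarray(x_str2, dtype=params["xatt_wq"].data.dtype))
    squeeze = q_in.ndim == 2
    if squeeze:
        q_in = ad.reshape(q_in, (1,) + q_in.shape)
        kv_in = ad.reshape(kv_in, (1,) + kv_in.shape)
    q = ad.matmul(q_in, params["xatt_wq"])
    k = ad.matmul(kv_in, params["xatt_wk"])
    v = ad.matmul(kv_in, params["xatt_wv"])
    dk = q.shape[-1]
    scores = ad.matmul(q, ad.swap_last_axes(k)) * (1.0 / math.sqrt(dk))
    attn = ad.softmax(scores, axis=-1)
    out = ad.matmul(attn, v)
    if squeeze:
        out = ad.reshape(out, out.shape[1:])
        attn = ad.reshape(attn, attn.shape[1:])
    return (out, attn) if return_attention else out


# ----------------------------------------------------------------- forward

def _forward_batch(x_seq, x_chem, x_str, x_node, params: dict,
                   config: ModelConfig, train: bool = False,
                   rng: np.random.Generator | None = None) -> Tensor:
    """Batched forward pass; returns predicted probabilities (B,)."""
    blocks: list[Tensor] = []
    if config.use_str:
        x_str2 = gat_branch(x_str, x_node, params, config)   # (B, L', E)
        if config.use_seq:
            x_seq2 = cnn_branch(x_seq, params, config, "seq")  # (B, E)
            queries = ad.reshape(x_seq2, (x_seq2.shape[0], 1, x_seq2.shape[1]))
            fused = cross_attention(queries, x_str2, params)   # (B, 1, Dv)
            blocks.append(ad.tmean(fused, axis=1))             # mean over queries
        else:
            B, Lp, E = x_str2.shape
            blocks.append(ad.reshape(x_str2, (B, Lp * E)))
    elif config.use_seq:
        blocks.append(cnn_branch(x_seq, params, config, "seq"))
    if config.use_chem:
        blocks.append(cnn_branch(x_chem, params, config, "chem"))

    h = blocks[0] if len(blocks) == 1 else ad.concat(blocks, axis=-1)
    h = ad.relu(ad.matmul(h, params["head_fc1_w"]) + params["head_fc1_b"])
    if train and config.dropout > 0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        keep = (rng.random(h.shape) >= config.dropout) / (1.0 - config.dropout)
        h = h * ad.tensor(keep.astype(h.data.dtype))
    logits = ad.matmul(h, params["head_fc2_w"]) + params["head_fc2_b"]
    return ad.reshape(ad.sigmoid(logits), (logits.shape[0],))


def forward(sample, params: dict, config: ModelConfig) -> Prediction:
    """Deterministic (evaluation-mode) forward pass for one EncodedSample."""
    probs = _forward_batch(
        sample.x_seq[None], sample.x_chem[None], sample.x_str[None],
        sample.x_node[None], params, config, train=False)
    prob = float(probs.data[0])
    return Prediction(prob=prob, label_hat=int(prob >= config.threshold))


def predict_probs(dataset, params: dict, config: ModelConfig,
                  batch_size: int = 256) -> np.ndarray:
    """Evaluation-mode probabilities for a whole Dataset."""
    out = np.empty(len(dataset), dtype=float)
    for lo in range(0, len(dataset), batch_size):
        hi = min(lo + batch_size, len(dataset))
        probs = _forward_batch(
            dataset.x_seq[lo:hi], dataset.x_chem[lo:hi], dataset.x_str[lo:hi],
            dataset.x_node[lo:hi], params, config, train=False)
        out[lo:hi] = probs.data
    return out


def bce_loss(probs, labels):
    """Mean binary cross-entropy; probabilities clamped at 1e-7.

    Accepts a Tensor (training graph) or plain arrays (returns a float).
    """
    labels = np.asarray(labels, dtype=float)
    if isinstance(probs, Tensor):
        if probs.shape[0] != labels.shape[0]:
            raise ValueError("probs and labels differ in length")
        p = ad.clip(probs, EPS, 1.0 - EPS)
        y = ad.tensor(labels.astype(probs.data.dtype))
        return -ad.tmean(y * ad.log(p) + (1.0 - y) * ad.log(1.0 - p))
    probs = np.asarray(probs, dtype=float)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("probs and labels differ in length")
    p = np.clip(probs, EPS, 1.0 - EPS)
    return float(-(labels * np.log(p) + (1 - labels) * np.log(1 - p)).mean())


# -------------------------------------------------------------- checkpoint

def save_checkpoint(path, params: dict, config: ModelConfig) -> None:
    """Single-archive checkpoint: named parameter arrays + a JSON config."""
    arrays = {name: t.data for name, t in params.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(config)).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> tuple[dict, ModelConfig]:
    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig(**json.loads(bytes(z["__config__"]).decode()))
        params = {name: ad.parameter(z[name]) for name in z.files
                  if name != "__config__"}
    return params, cfg
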