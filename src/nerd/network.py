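"""The multichannel drug-response network.

Four feature extractors produce fixed-width embeddings that a fusion head
combines into a single normalized IC50 prediction in (0, 1):

* DSE (drug structure extractor): three graph-convolution layers
  ``H' = relu(D^-1/2 (A+I) D^-1/2 H W)`` widening 78 -> 78 -> 156 -> 312
  (f, f, 2f, 4f with f = 78), global max pooling over atoms, and a fully
  connected map to 128.
* MFE (molecular fingerprint extractor): three 1-D convolution blocks with
  4, 8 and 16 kernels of size 8 (stride 1, no padding), each followed by
  non-overlapping max pooling with window 3, then flatten and map to 128.
* mEE (miRNA expression extractor): the same 1-D CNN architecture applied to
  the standardized miRNA vector.
* CNE (copy number extractor): the encoder of a stacked autoencoder with
  hidden sizes 1024, 512, 256 (decoder mirrored), pretrained to reconstruct
  the standardized copy-number vector under mean squared error; the 256-wide
  bottleneck is the embedding.

The fusion head concatenates the active channel embeddings, applies fully
connected layers with batch standardization before each activation, and a
sigmoid output.  Channel subsets are supported for ablation: removed channels
are omitted from the concatenation and the fusion input shrinks accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, concat, gather_rows
from . import nn
from .featurize import ATOM_FEATURE_DIM, FINGERPRINT_BITS, MolecularGraph

CHANNELS = ("dse", "mfe", "mee", "cne")


# --------------------------------------------------------------------- specs

@dataclass
class Conv1DSpec:
    n_layers: int = 3
    kernels_per_layer: tuple[int, ...] = (4, 8, 16)
    kernel_size: int = 8
    stride: int = 1
    padding: int = 0
    pool_window: int = 3
    pool_stride: int = 3
    output_dim: int = 128


@dataclass
class GCNSpec:
    input_dim: int = ATOM_FEATURE_DIM  # f = 78
    width_multipliers: tuple[int, ...] = (1, 2, 4)  # H^(1..3): n x f, n x 2f, n x 4f
    output_dim: int = 128

    @property
    def pooled_dim(self) -> int:
        return self.input_dim * self.width_multipliers[-1]  # 4f


@dataclass
class AutoencoderSpec:
    encoder_hidden: tuple[int, ...] = (1024, 512)
    bottleneck: int = 256


@dataclass
class FusionSpec:
    hidden: tuple[int, ...] = (1024, 512, 128)
    dropout: float = 0.1


@dataclass
class NetworkSpec:
    channels: tuple[str, ...] = CHANNELS
    conv: Conv1DSpec = field(default_factory=Conv1DSpec)
    gcn: GCNSpec = field(default_factory=GCNSpec)
    autoencoder: AutoencoderSpec = field(default_factory=AutoencoderSpec)
    fusion: FusionSpec = field(default_factory=FusionSpec)

    def __post_init__(self):
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")

    def channel_dim(self, channel: str) -> int:
        return {"dse": self.gcn.output_dim, "mfe": self.conv.output_dim,
                "mee": self.conv.output_dim, "cne": self.autoencoder.bottleneck}[channel]

    @property
    def fusion_input_dim(self) -> int:
        return sum(self.channel_dim(c) for c in self.channels)


# ----------------------------------------------------------- length formulas

def conv_output_length(length: int, kernel_size: int, padding: int = 0,
                       stride: int = 1) -> int:
    """Output length of a valid cross-correlation: (L + 2p - f) / s + 1."""
    out = (length + 2 * padding - kernel_size) // stride + 1
    if out < 1:
        raise ValueError(f"input length {length} too short for kernel {kernel_size}")
    return out


def pool_output_length(length: int, window: int = 3, stride: int | None = None) -> int:
    """Output length of strided max pooling; floor(L / 3) for window = stride = 3."""
    if stride is None:
        stride = window
    if length < window:
        raise ValueError(f"input length {length} too short for pooling window {window}")
    return (length - window) // stride + 1


# ------------------------------------------------------------ graph plumbing

def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^-1/2 (A + I) D^-1/2 with self-loops added."""
    adjacency = np.asarray(adjacency, dtype=float)
    n = adjacency.shape[0]
    if adjacency.shape != (n, n):
        raise ValueError("adjacency must be square")
    if not np.allclose(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adjacency) != 0):
        raise ValueError("adjacency must not carry self-loops; they are added here")
    a_tilde = adjacency + np.eye(n)
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer_forward(H, adjacency, W):
    """One graph-convolution layer: relu(D^-1/2 (A+I) D^-1/2 H W).

    ``H`` (n x d) and ``W`` (d x d') may be Tensors or arrays; ``adjacency``
    is the raw binary adjacency (self-loops added internally).  Disconnected
    nodes are fine: the self-loop guarantees every degree is at least 1.
    """
    H = H if isinstance(H, Tensor) else Tensor(np.asarray(H, dtype=float))
    W = W if isinstance(W, Tensor) else Tensor(np.asarray(W, dtype=float))
    if H.shape[-1] != W.shape[0]:
        raise ValueError(f"feature dim {H.shape[-1]} does not match W rows {W.shape[0]}")
    S = Tensor(normalized_adjacency(adjacency).astype(H.dtype))
    return (S @ H @ W).relu()


@dataclass
class GraphBatch:
    """Dense padded representation of a set of molecular graphs."""
    node_features: np.ndarray  # (n_graphs, n_max, 78)
    norm_adjacency: np.ndarray  # (n_graphs, n_max, n_max), zero-padded
    mask: np.ndarray           # (n_graphs, n_max) 1 for real atoms

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph], dtype=np.float32) -> "GraphBatch":
        if any(g.n_atoms == 0 for g in graphs):
            raise ValueError("graphs must have at least one atom")
        n_max = max(g.n_atoms for g in graphs)
        B = len(graphs)
        X = np.zeros((B, n_max, graphs[0].node_features.shape[1]), dtype=dtype)
        S = np.zeros((B, n_max, n_max), dtype=dtype)
        mask = np.zeros((B, n_max), dtype=dtype)
        for i, g in enumerate(graphs):
            n = g.n_atoms
            X[i, :n] = g.node_features
            S[i, :n, :n] = normalized_adjacency(g.adjacency)
            mask[i, :n] = 1.0
        return cls(X, S, mask)

    def take(self, idx: np.ndarray) -> "GraphBatch":
        return GraphBatch(self.node_features[idx], self.norm_adjacency[idx],
                          self.mask[idx])


# ------------------------------------------------------------------ modules

class GCNExtractor(nn.Module):
    """DSE: stacked graph convolutions, masked global max pooling, FC to 128."""

    def __init__(self, spec: GCNSpec, rng: np.random.Generator, dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        self.spec = spec
        f = spec.input_dim
        dims = [f] + [f * m for m in spec.width_multipliers]
        self.weights = [
            nn.Parameter(nn.glorot_uniform(rng, dims[i], dims[i + 1],
                                           (dims[i], dims[i + 1]), dtype))
            for i in range(len(spec.width_multipliers))
        ]
        self.fc = nn.Linear(spec.pooled_dim, spec.output_dim, rng, dtype)

    def forward(self, batch: GraphBatch) -> Tensor:
        H = Tensor(batch.node_features)
        S = Tensor(batch.norm_adjacency)
        for W in self.weights:
            H = (S @ (H @ W)).relu()
        # padded rows are exactly zero; push them to -inf before the node max
        neg = Tensor(((batch.mask - 1.0) * 1e9)[:, :, None].astype(H.dtype))
        pooled = (H + neg).max(axis=1)
        return self.fc(pooled)


class CNNExtractor(nn.Module):
    """MFE / mEE: three conv(+relu)+maxpool blocks, flatten, FC to 128."""

    def __init__(self, input_length: int, spec: Conv1DSpec,
                 rng: np.random.Generator, dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        self.spec = spec
        channels = (1,) + tuple(spec.kernels_per_layer)
        layers: list[nn.Module] = []
        length = input_length
        for i in range(spec.n_layers):
            try:
                length = conv_output_length(length, spec.kernel_size,
                                            spec.padding, spec.stride)
            except ValueError as err:
                raise ValueError(f"conv layer {i + 1}: {err}") from None
            layers += [nn.Conv1d(channels[i], channels[i + 1], spec.kernel_size,
                                 rng, spec.stride, dtype), nn.ReLU()]
            try:
                length = pool_output_length(length, spec.pool_window, spec.pool_stride)
            except ValueError as err:
                raise ValueError(f"pool layer {i + 1}: {err}") from None
            layers.append(nn.MaxPool1d(spec.pool_window, spec.pool_stride))
        self.body = nn.Sequential(*layers)
        self.flat_dim = spec.kernels_per_layer[-1] * length
        self.fc = nn.Linear(self.flat_dim, spec.output_dim, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = x.reshape(x.shape[0], 1, x.shape[1])
        h = self.body(x)
        return self.fc(h.reshape(h.shape[0], -1))


class StackedAutoencoder(nn.Module):
    """CNE: symmetric encoder/decoder trained to reconstruct its input."""

    def __init__(self, input_dim: int, spec: AutoencoderSpec,
                 rng: np.random.Generator, dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        self.spec = spec
        enc_dims = (input_dim,) + spec.encoder_hidden + (spec.bottleneck,)
        enc_layers: list[nn.Module] = []
        for i in range(len(enc_dims) - 1):
            enc_layers.append(nn.Linear(enc_dims[i], enc_dims[i + 1], rng, dtype))
            if i < len(enc_dims) - 2:
                enc_layers.append(nn.ReLU())
        self.encoder = nn.Sequential(*enc_layers)
        dec_dims = enc_dims[::-1]
        dec_layers: list[nn.Module] = []
        for i in range(len(dec_dims) - 1):
            dec_layers.append(nn.Linear(dec_dims[i], dec_dims[i + 1], rng, dtype))
            if i < len(dec_dims) - 2:
                dec_layers.append(nn.ReLU())
        self.decoder = nn.Sequential(*dec_layers)

    def encode(self, x: Tensor) -> Tensor:
        return self.encoder(x)

    def forward(self, x: Tensor) -> Tensor:
        return self.decoder(self.encoder(x))


class FusionHead(nn.Module):
    """Concatenated representations -> FC layers with batch standardization
    before each activation -> sigmoid prediction in (0, 1)."""

    def __init__(self, input_dim: int, spec: FusionSpec,
                 rng: np.random.Generator, dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        self.spec = spec
        dims = (input_dim,) + tuple(spec.hidden)
        self.blocks = []
        for i in range(len(dims) - 1):
            self.blocks.append(nn.Sequential(
                nn.Linear(dims[i], dims[i + 1], rng, dtype),
                nn.BatchNorm1d(dims[i + 1], dtype=dtype),
                nn.ReLU(),
                nn.Dropout(spec.dropout),
            ))
        self.out = nn.Linear(dims[-1], 1, rng, dtype)

    def forward(self, x: Tensor, return_hidden: bool = False):
        h = x
        for block in self.blocks:
            h = block(h)
        pred = self.out(h).sigmoid().reshape(-1)
        if return_hidden:
            return pred, h
        return pred


@dataclass
class FeatureTensors:
    """Entity-level feature arrays the network consumes.

    Rows are aligned with the drug/cell index orders used by the response
    pairs; extractor outputs are computed per unique entity and gathered."""
    fingerprints: np.ndarray | None  # (n_drugs, 881)
    graphs: GraphBatch | None
    mirna: np.ndarray | None  # (n_cells, M) standardized
    cnv: np.ndarray | None    # (n_cells, C) standardized


class NeRDNetwork(nn.Module):
    """The full multichannel network over a (possibly ablated) channel subset."""

    def __init__(self, spec: NetworkSpec, mirna_dim: int, cnv_dim: int,
                 seed: int = 0, dtype=nn.DEFAULT_DTYPE):
        super().__init__()
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.dse = (GCNExtractor(spec.gcn, rng, dtype)
                    if "dse" in spec.channels else None)
        self.mfe = (CNNExtractor(FINGERPRINT_BITS, spec.conv, rng, dtype)
                    if "mfe" in spec.channels else None)
        self.mee = (CNNExtractor(mirna_dim, spec.conv, rng, dtype)
                    if "mee" in spec.channels else None)
        self.cne = (StackedAutoencoder(cnv_dim, spec.autoencoder, rng, dtype)
                    if "cne" in spec.channels else None)
        self.fusion = FusionHead(spec.fusion_input_dim, spec.fusion, rng, dtype)

    # -- per-entity embeddings ----------------------------------------------
    def drug_embeddings(self, features: FeatureTensors,
                        drug_rows: np.ndarray) -> list[Tensor]:
        parts = []
        if self.dse is not None:
            parts.append(self.dse(features.graphs.take(drug_rows)))
        if self.mfe is not None:
            fp = Tensor(features.fingerprints[drug_rows].astype(self.dtype))
            parts.append(self.mfe(fp))
        return parts

    def cell_embeddings(self, features: FeatureTensors,
                        cell_rows: np.ndarray) -> list[Tensor]:
        parts = []
        if self.mee is not None:
            parts.append(self.mee(Tensor(features.mirna[cell_rows].astype(self.dtype))))
        if self.cne is not None:
            parts.append(self.cne.encode(
                Tensor(features.cnv[cell_rows].astype(self.dtype))))
        return parts

    def forward(self, features: FeatureTensors, drug_idx: np.ndarray,
                cell_idx: np.ndarray, return_stages: bool = False):
        """Predict normalized responses for (drug_idx[i], cell_idx[i]) pairs."""
        if not np.all(np.isfinite(drug_idx)) or not np.all(np.isfinite(cell_idx)):
            raise ValueError("non-finite pair indices")
        uniq_d, inv_d = np.unique(np.asarray(drug_idx, dtype=np.intp),
                                  return_inverse=True)
        uniq_c, inv_c = np.unique(np.asarray(cell_idx, dtype=np.intp),
                                  return_inverse=True)
        parts = [gather_rows(p, inv_d) for p in self.drug_embeddings(features, uniq_d)]
        parts += [gather_rows(p, inv_c) for p in self.cell_embeddings(features, uniq_c)]
        fused_in = concat(parts, axis=1) if len(parts) > 1 else parts[0]
        if return_stages:
            pred, hidden = self.fusion(fused_in, return_hidden=True)
            return pred, {"extractor_concat": fused_in.numpy().copy(),
                          "fusion_hidden": hidden.numpy().copy()}
        return self.fusion(fused_in)


# -------------------------------------------------------------- CNE pretrain

def mse_loss(pred: Tensor, target: np.ndarray | Tensor) -> Tensor:
    """Mean squared error  sum((yhat - y)^2) / n  over all elements."""
    t = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=pred.dtype))
    diff = pred - t
    return (diff * diff).mean()


def cne_pretrain(autoencoder: StackedAutoencoder, cnv_matrix: np.ndarray,
                 epochs: int = 30, lr: float = 1e-3, batch_size: int | None = None,
                 seed: int = 0) -> list[float]:
    """Train the autoencoder to reconstruct standardized copy-number rows.

    Returns the per-epoch reconstruction-loss history (full-data loss)."""
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    x_all = np.asarray(cnv_matrix, dtype=autoencoder.encoder.layers[0].weight.dtype)
    n = x_all.shape[0]
    opt = nn.Adam(autoencoder.parameters(), lr=lr)
    history: list[float] = []
    autoencoder.train()
    for _ in range(epochs):
        order = rng.permutation(n)
        bs = n if batch_size is None else batch_size
        for start in range(0, n, bs):
            rows = order[start:start + bs]
            x = Tensor(x_all[rows])
            loss = mse_loss(autoencoder(x), x_all[rows])
            opt.zero_grad()
            loss.backward()
            opt.step()
        autoencoder.eval()
        history.append(float(mse_loss(autoencoder(Tensor(x_all)), x_all).item()))
        autoencoder.train()
    autoencoder.eval()
    return history
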