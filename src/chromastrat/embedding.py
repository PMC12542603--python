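"""Gene filtering, normalization, and the three-layer autoencoder.

The pipeline reduces expression profiles to a 10-dimensional representation
with a three-layer autoencoder: an input layer holding the (filtered,
normalized) expression data, an embedded layer of ``latent_dim`` units
(default 10), and an output layer that reconstructs the input.  The model is
trained to minimize mean squared reconstruction error; the embedded layer is
the representation handed to UMAP/DBSCAN downstream.

The autoencoder is a small numpy implementation: one hidden (latent) layer,
tanh or linear encoder (default tanh), linear decoder, trained full-batch
with Adam for a fixed number of epochs from a seeded initialization, so that
identical inputs and hyperparameters always yield identical weights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_LATENT_DIM = 10
DEFAULT_EPOCHS = 500
DEFAULT_LEARNING_RATE = 0.01


@dataclass
class GeneFilterResult:
    """Output of :func:`filter_rare_genes`.

    ``removed_genes`` is retained because the rare-gene filter is temporary:
    it applies to the embedding input only, while marker analysis runs on
    the full gene set.
    """

    matrix: ExpressionMatrix
    removed_genes: list[str]
    min_fraction: float


def filter_rare_genes(
    matrix: ExpressionMatrix, min_fraction: float = 0.01
) -> GeneFilterResult:
    """Temporarily drop genes expressed in fewer than ``min_fraction`` of cells.

    A gene is kept iff its number of nonzero cells is >= ceil-free strict
    comparison: it is removed when ``nonzero_cells < min_fraction * n_cells``
    ("fewer than"), so a gene exactly at the threshold is retained.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    nonzero = matrix.counts.getnnz(axis=1)
    threshold = min_fraction * matrix.n_cells
    keep = np.flatnonzero(nonzero >= threshold)
    if keep.size == 0:
        raise ValueError("rare-gene filter removed every gene")
    removed = [matrix.gene_symbols[i] for i in np.flatnonzero(nonzero < threshold)]
    if removed:
        logger.info(
            "rare-gene filter: removed %d/%d genes (<%.3g%% of cells)",
            len(removed), matrix.n_genes, 100 * min_fraction,
        )
    return GeneFilterResult(matrix.subset_genes(keep), removed, min_fraction)


@dataclass
class NormalizedMatrix:
    """Median-library-scaled, log1p-transformed expression (genes x cells)."""

    values: np.ndarray
    gene_symbols: list[str]
    cell_ids: list[str]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cells_by_genes(self) -> np.ndarray:
        return np.ascontiguousarray(self.values.T)

    def subset_cells(self, cols) -> "NormalizedMatrix":
        cols = list(cols)
        return NormalizedMatrix(
            self.values[:, cols], list(self.gene_symbols),
            [self.cell_ids[i] for i in cols],
        )


def normalize(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """Scale each cell to the median library size, then log(1 + x).

    Deterministic; raises on cells with zero total counts (they carry no
    expression signal and would divide by zero), naming the barcodes.
    """
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [matrix.cell_ids[i] for i in zero[:5]]
        raise ValueError(
            f"{zero.size} cells have zero total counts, e.g. {names}; "
            "remove them before normalization"
        )
    median_lib = float(np.median(totals))
    scale = median_lib / totals
    dense = matrix.to_dense().astype(np.float64)
    values = np.log1p(dense * scale[None, :])
    return NormalizedMatrix(values, list(matrix.gene_symbols), list(matrix.cell_ids))


@dataclass
class AutoencoderModel:
    """Weights and training record of the three-layer autoencoder."""

    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray
    activation: str
    latent_dim: int
    seed: int
    training_log: list[float] = field(default_factory=list, repr=False)

    @property
    def input_dim(self) -> int:
        return self.W_enc.shape[0]

    def encode_array(self, X: np.ndarray) -> np.ndarray:
        H = X @ self.W_enc + self.b_enc
        if self.activation == "tanh":
            H = np.tanh(H)
        return H

    def decode_array(self, H: np.ndarray) -> np.ndarray:
        return H @ self.W_dec + self.b_dec

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "activation": self.activation,
            "latent_dim": self.latent_dim,
            "seed": self.seed,
            "input_dim": self.input_dim,
        }
        np.savez(
            path,
            W_enc=self.W_enc, b_enc=self.b_enc,
            W_dec=self.W_dec, b_dec=self.b_dec,
            training_log=np.asarray(self.training_log),
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "AutoencoderModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            return cls(
                W_enc=z["W_enc"], b_enc=z["b_enc"],
                W_dec=z["W_dec"], b_dec=z["b_dec"],
                activation=meta["activation"],
                latent_dim=int(meta["latent_dim"]),
                seed=int(meta["seed"]),
                training_log=list(z["training_log"]),
            )


@dataclass
class EmbeddingMatrix:
    """Cells x latent_dim representation from the encoder."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("embedding rows do not match cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite values")

    @property
    def latent_dim(self) -> int:
        return self.values.shape[1]


def train_autoencoder(
    X: NormalizedMatrix | np.ndarray,
    latent_dim: int = DEFAULT_LATENT_DIM,
    epochs: int = DEFAULT_EPOCHS,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    seed: int = 0,
    activation: str = "tanh",
) -> AutoencoderModel:
    """Fit the autoencoder by full-batch Adam on mean squared error.

    Fixed epoch count, no early stopping: two calls with identical data,
    hyperparameters and seed produce identical weights.  The per-epoch
    reconstruction loss is recorded in ``training_log``.
    """
    if activation not in ("tanh", "linear"):
        raise ValueError(f"unknown activation {activation!r}")
    data = X.cells_by_genes() if isinstance(X, NormalizedMatrix) else np.asarray(X, dtype=float)
    n_cells, n_features = data.shape
    if latent_dim < 1:
        raise ValueError("latent_dim must be >= 1")
    if n_cells <= latent_dim:
        raise ValueError(f"need more cells ({n_cells}) than latent dims ({latent_dim})")
    if not np.all(np.isfinite(data)):
        raise ValueError("input matrix contains non-finite values")

    rng = np.random.default_rng(seed)
    # training runs in float32: reconstruction MSE needs no more precision
    # and the matmuls are the pipeline's hot spot
    data32 = data.astype(np.float32)
    # centring the features speeds optimization; the offset folds into b_dec
    mean = data32.mean(axis=0)
    Xc = data32 - mean
    W1 = rng.normal(0.0, 1.0 / np.sqrt(n_features), size=(n_features, latent_dim)).astype(np.float32)
    b1 = np.zeros(latent_dim, dtype=np.float32)
    W2 = rng.normal(0.0, 1.0 / np.sqrt(latent_dim), size=(latent_dim, n_features)).astype(np.float32)
    b2 = np.zeros(n_features, dtype=np.float32)

    params = [W1, b1, W2, b2]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    log: list[float] = []
    inv = 1.0 / (n_cells * n_features)

    for epoch in range(1, epochs + 1):
        Z = Xc @ W1 + b1
        H = np.tanh(Z) if activation == "tanh" else Z
        R = H @ W2 + b2
        E = R - Xc
        loss = float(np.mean(E * E))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite reconstruction loss at epoch {epoch}")
        log.append(loss)

        G = np.float32(2.0 * inv) * E
        gW2 = H.T @ G
        gb2 = G.sum(axis=0)
        GH = G @ W2.T
        if activation == "tanh":
            GH = GH * (1.0 - H * H)
        gW1 = Xc.T @ GH
        gb1 = GH.sum(axis=0)

        for p, g, m, v in zip(params, [gW1, gb1, gW2, gb2], m_t, v_t):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            m_hat = m / (1 - beta1**epoch)
            v_hat = v / (1 - beta2**epoch)
            p -= learning_rate * m_hat / (np.sqrt(v_hat) + eps_adam)

    model = AutoencoderModel(
        W_enc=W1, b_enc=b1 - mean @ W1,  # fold the centring into the encoder bias
        W_dec=W2, b_dec=b2 + mean,
        activation=activation, latent_dim=latent_dim, seed=seed, training_log=log,
    )
    logger.info(
        "autoencoder: %d cells x %d genes -> %d dims, loss %.4g -> %.4g",
        n_cells, n_features, latent_dim, log[0], log[-1],
    )
    return model


def encode(model: AutoencoderModel, X: NormalizedMatrix | np.ndarray,
           cell_ids: list[str] | None = None) -> EmbeddingMatrix:
    """Deterministic forward pass through the encoder only."""
    if isinstance(X, NormalizedMatrix):
        data, ids = X.cells_by_genes(), list(X.cell_ids)
    else:
        data = np.asarray(X, dtype=float)
        ids = cell_ids if cell_ids is not None else [str(i) for i in range(data.shape[0])]
    if data.shape[1] != model.input_dim:
        raise ValueError(
            f"input has {data.shape[1]} features but model expects {model.input_dim}"
        )
    return EmbeddingMatrix(model.encode_array(data), ids)


def reconstruction_mse(model: AutoencoderModel, X: NormalizedMatrix | np.ndarray) -> float:
    data = X.cells_by_genes() if isinstance(X, NormalizedMatrix) else np.asarray(X, dtype=float)
    R = model.decode_array(model.encode_array(data))
    return float(np.mean((R - data) ** 2))
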