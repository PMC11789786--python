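"""Per-omics network components.

Each omics view owns an independent branch (the model is fusion-free): a
two-layer GCN encoder producing low-level features Z, a mirrored attribute
decoder (one dense tanh layer followed by two graph-convolution layers), an
inner-product structure decoder reconstructing the KNN graph, a one-layer
feature head producing high-level features H, and a one-layer label head whose
softmax output Q holds soft cluster assignments.

All forward functions accept plain ndarrays or autodiff Tensors and return the
same kind; training runs them on Tensors, tests and users can call them on
arrays directly.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["ModelConfig", "OmicsBranch", "init_branch", "init_autoencoder",
           "init_heads", "encode", "decode_attributes", "decode_structure",
           "feature_head", "label_head"]


@dataclass
class ModelConfig:
    """Layer widths shared by all branches.

    Encoder per view is [D_m, hidden_dim, latent_dim] (two graph-conv layers);
    the feature head maps latent_dim -> head_dim, the label head
    latent_dim -> n_clusters.
    """

    hidden_dim: int = 256
    latent_dim: int = 64
    head_dim: int = 64
    n_clusters: int = 3

    def validate(self) -> None:
        if min(self.hidden_dim, self.latent_dim, self.head_dim) < 1:
            raise ValueError("layer widths must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.latent_dim < self.n_clusters:
            warnings.warn("latent_dim < n_clusters; consider a wider latent layer",
                          stacklevel=2)


@dataclass
class OmicsBranch:
    """Trainable weights of one omics branch (leaf Tensors during training)."""

    W1: Tensor        # D x hidden        encoder layer 1 (graph conv)
    W2: Tensor        # hidden x latent   encoder layer 2 (graph conv)
    Wd2: Tensor       # latent x latent   attribute decoder, dense layer
    Wd1: Tensor       # latent x hidden   attribute decoder, graph conv
    Wd0: Tensor       # hidden x D        attribute decoder, graph conv
    Wstruct: Tensor   # latent x latent   structure decoder
    Wf: Tensor        # latent x head     feature head
    bf: Tensor        # head              feature head bias
    Wq: Tensor        # latent x K        label head
    bq: Tensor        # K                 label head bias

    def parameters(self):
        return [self.W1, self.W2, self.Wd2, self.Wd1, self.Wd0,
                self.Wstruct, self.Wf, self.bf, self.Wq, self.bq]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


def init_autoencoder(d_in: int, config: ModelConfig, rng: np.random.Generator) -> dict:
    """Encoder/decoder weights only (the parts that do not depend on K)."""
    h, z = config.hidden_dim, config.latent_dim
    return {
        "W1": _glorot(rng, d_in, h),
        "W2": _glorot(rng, h, z),
        "Wd2": _glorot(rng, z, z),
        "Wd1": _glorot(rng, z, h),
        "Wd0": _glorot(rng, h, d_in),
        "Wstruct": _glorot(rng, z, z),
    }


def init_heads(config: ModelConfig, rng: np.random.Generator) -> dict:
    """Feature- and label-head weights; biases start at zero."""
    z, dh, k = config.latent_dim, config.head_dim, config.n_clusters
    return {
        "Wf": _glorot(rng, z, dh),
        "bf": Tensor(np.zeros(dh)),
        "Wq": _glorot(rng, z, k),
        "bq": Tensor(np.zeros(k)),
    }


def init_branch(d_in: int, config: ModelConfig, rng: np.random.Generator) -> OmicsBranch:
    """Glorot-uniform initialization of one full branch."""
    config.validate()
    return OmicsBranch(**init_autoencoder(d_in, config, rng),
                       **init_heads(config, rng))


def _any_tensor(*args) -> bool:
    return any(isinstance(a, Tensor) for a in args)


def _finish(out, *inputs):
    """Return a Tensor if any input was a Tensor, else its ndarray value."""
    return out if _any_tensor(*inputs) else out.value


def _check_matmul(name: str, left_cols: int, right_rows: int) -> None:
    if left_cols != right_rows:
        raise ValueError(f"{name}: got input dim {left_cols}, "
                         f"weight expects {right_rows}")


def encode(X, A_norm, weights):
    """Two-layer GCN encoder: Z_l = tanh(A_norm @ Z_{l-1} @ W_l), Z_0 = X."""
    W1, W2 = (as_tensor(w) for w in weights)
    Xt, At = as_tensor(X), as_tensor(A_norm)
    _check_matmul("encoder layer 1", Xt.shape[1], W1.shape[0])
    _check_matmul("encoder layer 2", W1.shape[1], W2.shape[0])
    if At.shape[0] != Xt.shape[0]:
        raise ValueError("encoder: A_norm and X disagree on sample count")
    Z1 = (At @ Xt @ W1).tanh()
    Z = (At @ Z1 @ W2).tanh()
    return _finish(Z, X, A_norm, *weights)


def decode_attributes(Z, A_norm, weights):
    """Mirrored attribute decoder: dense tanh layer, then two graph convs."""
    Wd2, Wd1, Wd0 = (as_tensor(w) for w in weights)
    Zt, At = as_tensor(Z), as_tensor(A_norm)
    _check_matmul("decoder dense layer", Zt.shape[1], Wd2.shape[0])
    _check_matmul("decoder conv layer 1", Wd2.shape[1], Wd1.shape[0])
    _check_matmul("decoder conv layer 0", Wd1.shape[1], Wd0.shape[0])
    Zh2 = (Zt @ Wd2).tanh()
    Zh1 = (At @ Zh2 @ Wd1).tanh()
    Xhat = (At @ Zh1 @ Wd0).tanh()
    return _finish(Xhat, Z, A_norm, *weights)


def decode_structure(Z, Wstruct):
    """Inner-product structure decoder: A_hat = tanh(Z @ W @ Z^T)."""
    Zt, Wt = as_tensor(Z), as_tensor(Wstruct)
    if Wt.shape[0] != Wt.shape[1] or Wt.shape[0] != Zt.shape[1]:
        raise ValueError("structure decoder weight must be latent x latent")
    Ahat = (Zt @ Wt @ Zt.T).tanh()
    return _finish(Ahat, Z, Wstruct)


def feature_head(Z, Wf, bf=None):
    """One-layer projection to high-level features: H = tanh(Z @ Wf + bf)."""
    Zt, Wt = as_tensor(Z), as_tensor(Wf)
    _check_matmul("feature head", Zt.shape[1], Wt.shape[0])
    H = Zt @ Wt
    if bf is not None:
        H = H + as_tensor(bf)
    out = H.tanh()
    return _finish(out, Z, Wf, *(() if bf is None else (bf,)))


def label_head(Z, Wq, bq=None):
    """One-layer label head with row-wise softmax; rows of Q sum to 1."""
    Zt, Wt = as_tensor(Z), as_tensor(Wq)
    _check_matmul("label head", Zt.shape[1], Wt.shape[0])
    logits = Zt @ Wt
    if bq is not None:
        logits = logits + as_tensor(bq)
    # constant max-shift: exact softmax shift-invariance, no gradient impact
    shift = logits.value.max(axis=1, keepdims=True)
    e = (logits - shift).exp()
    Q = e / e.sum(axis=1, keepdims=True)
    return _finish(Q, Z, Wq, *(() if bq is None else (bq,)))
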