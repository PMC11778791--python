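"""Omics-specific autoencoders, the two-layer GCN, and the training losses.

The model co-embeds a labeled source modality and an unlabeled target
modality in two stages.  Stage 1 trains one autoencoder per modality with a
reconstruction loss plus multi-kernel maximum mean discrepancy (MK-MMD) and
a best-match cosine loss that pull the two latent distributions together.
Stage 2 trains a graph convolutional network on the concatenated latents
over the hybrid MNN graph, minimizing cross-entropy on the labeled source
nodes plus MK-MMD between the source and target hidden embeddings.

Each autoencoder treats its input profile as n_sub contiguous sub-vectors
of length s_sub (zero-padded tail) passed through a shared per-sub-vector
encoder before projection to the K-dimensional latent space; the decoder
mirrors this.  Sharing weights across sub-vectors keeps the parameter count
independent of the feature count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import pdist

from . import _autograd as ag
from ._autograd import Tensor
from .io import FeatureMatrix, LabelSet
from .graph import HybridGraph

__all__ = [
    "AutoencoderConfig",
    "MMDConfig",
    "TrainConfig",
    "Autoencoder",
    "GCNModel",
    "ModelState",
    "EmbeddingMatrix",
    "mk_mmd",
    "cosine_loss",
    "cross_entropy",
    "gcn_forward",
    "ae_encode",
    "ae_decode",
    "train",
]


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------


@dataclass
class AutoencoderConfig:
    n_sub: int = 8              # number of sub-vectors per profile
    s_sub: int | None = None    # sub-vector length; None -> ceil(m / n_sub)
    latent_dim: int = 32        # K
    hidden: int = 16            # shared per-sub-vector hidden width

    def resolved_s_sub(self, n_features: int) -> int:
        if self.s_sub is not None:
            if self.n_sub * self.s_sub < n_features:
                raise ValueError("n_sub * s_sub must cover the feature count")
            return self.s_sub
        return math.ceil(n_features / self.n_sub)


@dataclass
class MMDConfig:
    """Multi-kernel MMD: Gaussian bandwidths and their convex weights.

    ``bandwidths=None`` uses the median-distance heuristic scaled by the
    geometric ladder {1/4, 1/2, 1, 2, 4}; beta defaults to uniform.
    """

    bandwidths: list[float] | None = None
    beta: list[float] | None = None
    estimator: str = "biased"
    ladder: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)

    def __post_init__(self):
        if self.estimator not in ("biased", "unbiased"):
            raise ValueError("estimator must be 'biased' or 'unbiased'")
        if self.bandwidths is not None and any(b <= 0 for b in self.bandwidths):
            raise ValueError("bandwidths must be positive")
        if self.beta is not None:
            beta = np.asarray(self.beta, dtype=float)
            if np.any(beta < 0) or abs(beta.sum() - 1.0) > 1e-9:
                raise ValueError("beta must be nonnegative and sum to 1")

    def resolve(self, src: np.ndarray, tgt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.bandwidths is not None:
            bw = np.asarray(self.bandwidths, dtype=float)
        else:
            pooled = np.vstack([src, tgt])
            if pooled.shape[0] > 400:  # deterministic thinning for the heuristic
                pooled = pooled[:: pooled.shape[0] // 400 + 1]
            med = np.median(pdist(pooled)) if pooled.shape[0] > 1 else 1.0
            med = float(med) if med > 0 else 1.0
            bw = med * np.asarray(self.ladder)
        beta = (
            np.asarray(self.beta, dtype=float)
            if self.beta is not None
            else np.full(len(bw), 1.0 / len(bw))
        )
        if len(beta) != len(bw):
            raise ValueError("beta length must match number of bandwidths")
        return bw, beta


@dataclass
class TrainConfig:
    lambda_mmd: float = 1.0
    lambda_cos: float = 0.1
    lambda_ce: float = 1.0
    epochs_stage1: int = 60
    epochs_stage2: int = 150
    lr: float = 1e-3
    batch_size: int = 256
    gcn_hidden: int = 64
    single_conv: bool = False   # one graph-convolved layer + dense head
    mmd_on_output: bool = False  # stage-2 MMD on softmax output as well
    seed: int = 0

    def __post_init__(self):
        if min(self.lambda_mmd, self.lambda_cos, self.lambda_ce) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.batch_size < 2:
            raise ValueError("batch size must be >= 2")


# ---------------------------------------------------------------------
# losses (public numpy API wrapping the differentiable core)
# ---------------------------------------------------------------------


def _pairwise_sq_dists(x: Tensor, y: Tensor) -> Tensor:
    xx = (x * x).sum(axis=1, keepdims=True)          # [n, 1]
    yy = (y * y).sum(axis=1, keepdims=True).T        # [1, m]
    d2 = xx + yy - 2.0 * (x @ y.T)
    return ag.relu(d2)  # clamp tiny negatives from cancellation


def _kernel_mean(x: Tensor, y: Tensor, bw: np.ndarray, beta: np.ndarray,
                 exclude_diagonal: bool) -> Tensor:
    d2 = _pairwise_sq_dists(x, y)
    n, m = d2.shape
    total = None
    for b, w in zip(bw, beta):
        k = ag.exp(d2 * (-1.0 / (2.0 * b * b)))
        total = k * w if total is None else total + k * w
    if exclude_diagonal:
        if n != m or n < 2:
            raise ValueError("unbiased estimator needs >= 2 paired samples")
        mask = 1.0 - np.eye(n)
        return (total * mask).sum() / (n * (n - 1))
    return total.mean()


def _mk_mmd_tensor(src: Tensor, tgt: Tensor, cfg: MMDConfig) -> Tensor:
    bw, beta = cfg.resolve(src.value, tgt.value)
    excl = cfg.estimator == "unbiased"
    k_ss = _kernel_mean(src, src, bw, beta, exclude_diagonal=excl)
    k_tt = _kernel_mean(tgt, tgt, bw, beta, exclude_diagonal=excl)
    k_st = _kernel_mean(src, tgt, bw, beta, exclude_diagonal=False)
    return k_ss + k_tt - 2.0 * k_st


def mk_mmd(src_emb: np.ndarray, tgt_emb: np.ndarray, cfg: MMDConfig | None = None) -> float:
    """Squared multi-kernel MMD between two embedded samples.

    D^2 = sum_u beta_u [ mean k_u(s,s') + mean k_u(t,t') - 2 mean k_u(s,t) ]
    with Gaussian kernels k_u(a,b) = exp(-||a-b||^2 / (2 bw_u^2)).  The
    biased estimator keeps diagonal terms (and is >= 0 up to rounding); the
    unbiased one excludes them and needs >= 2 samples per side.
    """
    cfg = cfg or MMDConfig()
    src = np.atleast_2d(np.asarray(src_emb, dtype=float))
    tgt = np.atleast_2d(np.asarray(tgt_emb, dtype=float))
    if src.shape[1] != tgt.shape[1]:
        raise ValueError("embeddings must share dimensionality")
    return float(_mk_mmd_tensor(Tensor(src), Tensor(tgt), cfg).value)


def _normalize_rows(x: Tensor, eps: float = 1e-9) -> Tensor:
    norm = ag.sqrt((x * x).sum(axis=1, keepdims=True) + eps * eps)
    # max(norm, eps) via relu keeps nonzero rows exactly unit after division
    norm = ag.relu(norm - eps) + eps
    return x / norm


def _cosine_loss_tensor(src: Tensor, tgt: Tensor) -> Tensor:
    sims = _normalize_rows(tgt) @ _normalize_rows(src).T   # [n_t, n_s]
    best = ag.row_max(sims)
    return 1.0 - best.mean()


def cosine_loss(src_emb: np.ndarray, tgt_emb: np.ndarray) -> float:
    """1 minus the mean over target cells of their best cosine match in the
    source batch; 0 when every target row coincides with a source row, 2 at
    the antipodal extreme."""
    src = np.atleast_2d(np.asarray(src_emb, dtype=float))
    tgt = np.atleast_2d(np.asarray(tgt_emb, dtype=float))
    if not np.all(np.linalg.norm(src, axis=1) > 0) or not np.all(
        np.linalg.norm(tgt, axis=1) > 0
    ):
        raise ValueError("zero-norm embedding row")
    return float(_cosine_loss_tensor(Tensor(src), Tensor(tgt)).value)


def cross_entropy(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Mean categorical cross-entropy of row-stochastic predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("shape mismatch between labels and predictions")
    if np.any(np.abs(y_prob.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("prediction rows must sum to 1")
    eps = 1e-12
    y_prob = np.clip(y_prob, eps, 1.0 - eps)
    return float(-(y_true * np.log(y_prob)).sum(axis=1).mean())


def _log_softmax_tensor(logits: Tensor) -> Tensor:
    shift = logits - Tensor(logits.value.max(axis=1, keepdims=True))  # detached max
    log_z = ag.log(ag.exp(shift).sum(axis=1, keepdims=True))
    return shift - log_z


def _ce_with_logits(logits: Tensor, onehot: np.ndarray) -> Tensor:
    return -(Tensor(onehot) * _log_softmax_tensor(logits)).sum(axis=1).mean()


# ---------------------------------------------------------------------
# autoencoder
# ---------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


class Autoencoder:
    """Sub-vector autoencoder: shared block encoder, linear latent head."""

    def __init__(self, n_features: int, cfg: AutoencoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.n_features = n_features
        self.s_sub = cfg.resolved_s_sub(n_features)
        self.n_sub = cfg.n_sub
        self.padded = self.n_sub * self.s_sub
        h, k = cfg.hidden, cfg.latent_dim
        self.w_block = _glorot(rng, self.s_sub, h)
        self.b_block = Tensor(np.zeros(h), requires_grad=True)
        self.w_latent = _glorot(rng, self.n_sub * h, k)
        self.b_latent = Tensor(np.zeros(k), requires_grad=True)
        self.w_delat = _glorot(rng, k, self.n_sub * h)
        self.b_delat = Tensor(np.zeros(self.n_sub * h), requires_grad=True)
        self.w_deblock = _glorot(rng, h, self.s_sub)
        self.b_deblock = Tensor(np.zeros(self.s_sub), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.w_block, self.b_block, self.w_latent, self.b_latent,
                self.w_delat, self.b_delat, self.w_deblock, self.b_deblock]

    def pad(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] > self.padded:
            raise ValueError("feature length exceeds n_sub * s_sub")
        if x.shape[1] < self.padded:
            x = np.hstack([x, np.zeros((x.shape[0], self.padded - x.shape[1]))])
        return x

    def encode_t(self, x: np.ndarray) -> Tensor:
        x = self.pad(x)
        n = x.shape[0]
        blocks = Tensor(x.reshape(n * self.n_sub, self.s_sub))
        hidden = ag.relu(blocks @ self.w_block + self.b_block)
        hidden = hidden.reshape(n, self.n_sub * self.cfg.hidden)
        return hidden @ self.w_latent + self.b_latent

    def decode_t(self, z: Tensor) -> Tensor:
        n = z.shape[0]
        hidden = ag.relu(z @ self.w_delat + self.b_delat)
        blocks = hidden.reshape(n * self.n_sub, self.cfg.hidden)
        out = blocks @ self.w_deblock + self.b_deblock
        return out.reshape(n, self.padded)

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encode_t(x).value

    def decode(self, z: np.ndarray) -> np.ndarray:
        out = self.decode_t(Tensor(np.atleast_2d(np.asarray(z, dtype=float))))
        return out.value[:, : self.n_features]


def ae_encode(x, ae: Autoencoder) -> np.ndarray:
    """Latent coordinates Z for a cells-by-features block."""
    x = x.values if isinstance(x, FeatureMatrix) else x
    return ae.encode(x)


def ae_decode(z, ae: Autoencoder) -> np.ndarray:
    """Reconstruction, truncated back to the original feature count."""
    return ae.decode(z)


# ---------------------------------------------------------------------
# GCN
# ---------------------------------------------------------------------


class GCNModel:
    """Two-layer graph convolutional classifier (no biases, per Eq form
    softmax(A ReLU(A X W0) W1)); optionally a single convolved layer with a
    dense softmax head."""

    def __init__(self, d_in: int, hidden: int, n_classes: int,
                 rng: np.random.Generator, single_conv: bool = False):
        self.w0 = _glorot(rng, d_in, hidden)
        self.w1 = _glorot(rng, hidden, n_classes)
        self.single_conv = single_conv
        self.trained_epochs = 0

    @property
    def params(self) -> list[Tensor]:
        return [self.w0, self.w1]

    def forward_t(self, features: np.ndarray, a_norm: np.ndarray) -> tuple[Tensor, Tensor]:
        x = Tensor(np.asarray(features, dtype=float))
        a = Tensor(np.asarray(a_norm, dtype=float))
        h1 = ag.relu((a @ x) @ self.w0)
        logits = (h1 if self.single_conv else a @ h1) @ self.w1
        return h1, logits


def gcn_forward(
    features: np.ndarray, a_norm: np.ndarray, model: GCNModel
) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass: hidden activations H1 and row-stochastic probabilities."""
    h1, logits = model.forward_t(features, a_norm)
    probs = np.exp(_log_softmax_tensor(logits).value)
    if not np.all(np.isfinite(probs)):
        raise FloatingPointError("non-finite GCN output (exploding weights?)")
    return h1.value, probs


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------


@dataclass
class EmbeddingMatrix:
    values: np.ndarray          # [n_cells, dim]
    cell_ids: list[str]
    modalities: np.ndarray      # 'source' / 'target' per cell
    labels: np.ndarray | None = None


@dataclass
class ModelState:
    ae_src: Autoencoder
    ae_tgt: Autoencoder
    gcn: GCNModel
    classes: list[str]
    train_cfg: TrainConfig
    mmd_cfg: MMDConfig
    loss_trace_stage1: list[float] = field(default_factory=list)
    loss_trace_stage2: list[float] = field(default_factory=list)
    probabilities: np.ndarray | None = None

    def manifest(self) -> dict:
        return {
            "classes": self.classes,
            "train_cfg": asdict(self.train_cfg),
            "mmd_cfg": {
                "bandwidths": self.mmd_cfg.bandwidths,
                "beta": self.mmd_cfg.beta,
                "estimator": self.mmd_cfg.estimator,
            },
        }


def _check_finite(loss_val: float, stage: str):
    if not np.isfinite(loss_val):
        raise FloatingPointError(f"training diverged ({stage}): non-finite loss")


def train(
    src: FeatureMatrix,
    src_labels: LabelSet,
    tgt: FeatureMatrix,
    graph: HybridGraph,
    ae_cfg: AutoencoderConfig | None = None,
    mmd_cfg: MMDConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int | None = None,
) -> tuple[ModelState, EmbeddingMatrix]:
    """Two-stage semi-supervised training; node order is [source | target].

    Returns the trained state and the stage-2 hidden embedding for every
    cell (the space used for k-NN label transfer), with per-node class
    probabilities attached to the state.
    """
    ae_cfg = ae_cfg or AutoencoderConfig()
    mmd_cfg = mmd_cfg or MMDConfig()
    cfg = train_cfg or TrainConfig()
    if seed is not None:
        cfg.seed = seed
    if src.feature_ids != tgt.feature_ids:
        raise ValueError("source and target features must be harmonized")
    if graph.n_s != src.n_cells or graph.n_t != tgt.n_cells:
        raise ValueError("graph node counts do not match the matrices")
    rng = np.random.default_rng(cfg.seed)

    n_s, n_t, m = src.n_cells, tgt.n_cells, src.n_features
    ae_s = Autoencoder(m, ae_cfg, rng)
    ae_t = Autoencoder(m, ae_cfg, rng)
    xs_pad, xt_pad = ae_s.pad(src.values), ae_t.pad(tgt.values)

    # ---- stage 1: align the autoencoder latent spaces -----------------
    params = ae_s.params + ae_t.params
    opt = ag.Adam(params, lr=cfg.lr)
    state = ModelState(ae_s, ae_t, None, src_labels.classes, cfg, mmd_cfg)
    bs = cfg.batch_size
    for _ in range(cfg.epochs_stage1):
        order_s, order_t = rng.permutation(n_s), rng.permutation(n_t)
        n_batches = max(1, math.ceil(max(n_s, n_t) / bs))
        epoch_loss = 0.0
        for b in range(n_batches):
            idx_s = order_s[(b * bs) % n_s: (b * bs) % n_s + bs]
            idx_t = order_t[(b * bs) % n_t: (b * bs) % n_t + bs]
            if len(idx_s) < 2 or len(idx_t) < 2:
                continue
            zs, zt = ae_s.encode_t(src.values[idx_s]), ae_t.encode_t(tgt.values[idx_t])
            rec_s = ((ae_s.decode_t(zs) - Tensor(xs_pad[idx_s])) ** 2).mean()
            rec_t = ((ae_t.decode_t(zt) - Tensor(xt_pad[idx_t])) ** 2).mean()
            loss = rec_s + rec_t
            if cfg.lambda_mmd > 0:
                loss = loss + cfg.lambda_mmd * _mk_mmd_tensor(zs, zt, mmd_cfg)
            if cfg.lambda_cos > 0:
                loss = loss + cfg.lambda_cos * _cosine_loss_tensor(zs, zt)
            _check_finite(float(loss.value), "stage 1")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.value)
        state.loss_trace_stage1.append(epoch_loss / n_batches)

    # ---- stage 2: GCN over the hybrid graph ---------------------------
    z_all = np.vstack([ae_s.encode(src.values), ae_t.encode(tgt.values)])
    classes = src_labels.classes
    y_idx = np.array([classes.index(l) for l in src_labels.labels_for(src.cell_ids)])
    onehot = np.eye(len(classes))[y_idx]
    gcn = GCNModel(z_all.shape[1], cfg.gcn_hidden, len(classes), rng,
                   single_conv=cfg.single_conv)
    state.gcn = gcn
    opt2 = ag.Adam(gcn.params, lr=cfg.lr)
    a_norm = graph.normalized
    for _ in range(cfg.epochs_stage2):
        h1, logits = gcn.forward_t(z_all, a_norm)
        loss = Tensor(0.0)
        if cfg.lambda_ce > 0:
            loss = loss + cfg.lambda_ce * _ce_with_logits(logits.rows(0, n_s), onehot)
        if cfg.lambda_mmd > 0:
            loss = loss + cfg.lambda_mmd * _mk_mmd_tensor(
                h1.rows(0, n_s), h1.rows(n_s, n_s + n_t), mmd_cfg
            )
            if cfg.mmd_on_output:
                sm = ag.exp(_log_softmax_tensor(logits))
                loss = loss + cfg.lambda_mmd * _mk_mmd_tensor(
                    sm.rows(0, n_s), sm.rows(n_s, n_s + n_t), mmd_cfg
                )
        _check_finite(float(loss.value), "stage 2")
        opt2.zero_grad()
        loss.backward()
        opt2.step()
        gcn.trained_epochs += 1
        state.loss_trace_stage2.append(float(loss.value))

    h1, probs = gcn_forward(z_all, a_norm, gcn)
    state.probabilities = probs
    modalities = np.array(["source"] * n_s + ["target"] * n_t)
    emb = EmbeddingMatrix(
        values=h1,
        cell_ids=list(src.cell_ids) + list(tgt.cell_ids),
        modalities=modalities,
    )
    return state, emb
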