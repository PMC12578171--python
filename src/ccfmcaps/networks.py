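"""Assembly, training and accounting of the two-lane capsule network.

The full model feeds one lane with a CLAHE-enhanced copy of the input image
and the other with its colour-difference-histogram (CDH) response map; both
feature extractors are parameter-free.  Each lane runs
Conv(256, 3x3) -> batch-norm -> max-pool -> Conv(128, 3x3) -> batch-norm ->
max-pool; the lane outputs are concatenated on channels, passed through
dropout and a batch-norm, into a primary capsule layer (16 channels of 8-D
capsules, 3x3 stride 2), then to 16-D class capsules via dynamic routing,
and finally to a three-stage fully connected decoder (512, 1024, H*W*C) that
reconstructs the input from the winning class capsule.  On a 32x32x3 input
the per-lane shape chain is 30x30x256 -> 15x15x256 -> 13x13x128 -> 7x7x128,
and 7x7x256 after concatenation.

The module also builds the original single-lane capsule network baseline
(Conv 256 9x9 -> primary capsules 32x8 9x9 stride 2 -> class capsules ->
decoder), exposes ablation toggles mirroring the published ablation study,
counts parameters layer by layer (batch-norm moving statistics included,
routing logits excluded), and provides the training / inference drivers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .capsules import (MarginLossConfig, margin_loss, margin_loss_grad,
                       total_loss)
from .cdh import CdhConfig, cdh_feature_map
from .nn import (Adam, BatchNorm, ClassCaps, Conv2D, Dense, Dropout, Layer,
                 MaxPool2D, PrimaryCaps)
from .preprocessing import ClaheConfig, apply_clahe

__all__ = [
    "ABLATABLE_COMPONENTS",
    "ArchitectureConfig",
    "TrainConfig",
    "ParamBreakdown",
    "build_ccfm",
    "build_baseline",
    "count_parameters",
    "ablate",
    "train",
    "predict_and_reconstruct",
    "export_activations",
    "save_weights",
    "load_weights",
]

ABLATABLE_COMPONENTS = frozenset(
    {"CDH", "CLAHE", "Conv1&3", "MP1&3", "Conv2&4", "MP2&4", "Dropout"})


@dataclass(frozen=True)
class ArchitectureConfig:
    """Declarative description of the two-lane capsule network."""

    input_shape: tuple[int, int, int] = (32, 32, 3)
    num_classes: int = 2
    conv_filters: tuple[int, int] = (256, 128)
    conv_kernel: int = 3
    primary_channels: int = 16
    primary_dim: int = 8
    primary_kernel: int = 3
    primary_stride: int = 2
    class_caps_dim: int = 16
    decoder_widths: tuple[int, int] = (512, 1024)
    dropout_rate: float = 0.5
    routing_iters: int = 3
    ablation_flags: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        bad = set(self.ablation_flags) - ABLATABLE_COMPONENTS
        if bad:
            raise ValueError(f"unknown ablation flags: {sorted(bad)}")

    @property
    def decoder_output(self) -> int:
        h, w, c = self.input_shape
        return h * w * c


@dataclass
class TrainConfig:
    """Optimization hyperparameters (Adam, per-epoch exponential decay)."""

    learning_rate: float = 0.001
    decay_rate: float = 0.9
    batch_size: int = 100
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.decay_rate, self.batch_size,
               self.epochs) <= 0:
            raise ValueError("training hyperparameters must be positive")


@dataclass
class ParamBreakdown:
    """Ordered per-layer parameter ledger."""

    rows: list[tuple[str, int]]
    total: int

    @property
    def millions(self) -> float:
        """Total in millions, rounded half-up to two decimals."""
        return float((Decimal(self.total) / Decimal(10 ** 6))
                     .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.rows, columns=["layer", "parameters"])
        return df


def _norm(v: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.sqrt((v * v).sum(axis=axis) + 1e-14)


class _CapsNetBase:
    """Shared training/inference machinery of both architectures."""

    cfg: ArchitectureConfig
    num_classes: int

    # subclasses populate: _entries (ordered (name, layer-or-None) ledger),
    # decoder layers, class caps, primary caps
    def prepare_inputs(self, X: np.ndarray):
        raise NotImplementedError

    def forward(self, inputs, training: bool = False, mask_labels=None,
                collect: dict | None = None) -> dict:
        raise NotImplementedError

    def backward(self, d_v: np.ndarray, d_recon: np.ndarray) -> None:
        raise NotImplementedError

    # -- decoder (shared) --------------------------------------------------
    def _decode(self, v: np.ndarray, scores: np.ndarray, mask_labels,
                collect) -> tuple[np.ndarray, np.ndarray]:
        """Mask all but the chosen class capsule and reconstruct."""
        b, k, d = v.shape
        if mask_labels is None:
            chosen = scores.argmax(axis=1)
            onehot = np.zeros((b, k))
            onehot[np.arange(b), chosen] = 1.0
        else:
            onehot = np.asarray(mask_labels, dtype=np.float64)
        x = (v * onehot[:, :, None]).reshape(b, k * d)
        self._mask_cache = onehot
        for name, layer in self.decoder_entries:
            x = layer.forward(x, training=False)
            if collect is not None:
                collect[name] = x
        return x, onehot

    def _decode_backward(self, d_recon: np.ndarray) -> np.ndarray:
        grad = d_recon
        for _, layer in reversed(self.decoder_entries):
            grad = layer.backward(grad)
        b = grad.shape[0]
        onehot = self._mask_cache
        dv = grad.reshape(b, self.num_classes, -1) * onehot[:, :, None]
        return dv

    # -- parameter plumbing ------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        return [lay for _, lay in self._entries if lay is not None]

    @property
    def trainable_params(self):
        return [p for lay in self.layers for p in lay.params]

    def get_state(self) -> dict[str, np.ndarray]:
        state = {}
        for lay in self.layers:
            for p in lay.params:
                state[p.name] = p.value.copy()
            if isinstance(lay, BatchNorm):
                state[f"{lay.name}/moving_mean"] = lay.moving_mean.copy()
                state[f"{lay.name}/moving_var"] = lay.moving_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for lay in self.layers:
            for p in lay.params:
                p.value[...] = state[p.name]
            if isinstance(lay, BatchNorm):
                lay.moving_mean[...] = state[f"{lay.name}/moving_mean"]
                lay.moving_var[...] = state[f"{lay.name}/moving_var"]

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for lay in self.layers:
            if isinstance(lay, Dropout):
                lay.rng = rng


class CCFMNet(_CapsNetBase):
    """The two-lane CLAHE/CDH capsule network."""

    def __init__(self, cfg: ArchitectureConfig,
                 clahe_cfg: ClaheConfig | None = None,
                 cdh_cfg: CdhConfig | None = None):
        h, w, c_in = cfg.input_shape
        self.cfg = cfg
        self.num_classes = cfg.num_classes
        self.clahe_cfg = clahe_cfg or ClaheConfig(
            tile_grid=(min(8, h), min(8, w)))
        self.cdh_cfg = cdh_cfg or CdhConfig()
        flags = cfg.ablation_flags
        self.use_clahe = "CLAHE" not in flags
        self.use_cdh = "CDH" not in flags
        rng = np.random.default_rng(cfg.seed)
        self.shapes: dict[str, tuple] = {"Input": (h, w, c_in)}

        lane1, sh1 = self._build_lane(1, (h, w, c_in), cfg, rng)
        lane2, sh2 = self._build_lane(2, (h, w, c_in), cfg, rng)
        assert sh1[:2] == sh2[:2]
        self.lane1, self.lane2 = lane1, lane2
        self._lane_channels = (sh1[2], sh2[2])
        ch, cw, cc = sh1[0], sh1[1], sh1[2] + sh2[2]
        self.shapes["Concat"] = (ch, cw, cc)

        self.trunk: list[tuple[str, Layer]] = []
        if "Dropout" not in flags:
            self.trunk.append(("Dropout", Dropout(cfg.dropout_rate,
                                                  name="Dropout")))
        self.trunk.append(("BN_concat", BatchNorm(cc, name="BN_concat")))

        gh = Conv2D.out_size(ch, cfg.primary_kernel, cfg.primary_stride)
        gw = Conv2D.out_size(cw, cfg.primary_kernel, cfg.primary_stride)
        if gh < 1 or gw < 1:
            raise ValueError("primary capsule grid is empty for this config")
        n_caps = gh * gw * cfg.primary_channels
        self.primary = PrimaryCaps(cc, cfg.primary_channels, cfg.primary_dim,
                                   cfg.primary_kernel, cfg.primary_stride,
                                   rng=rng, name="PrimaryCaps")
        self.shapes["PrimaryCaps"] = (n_caps, cfg.primary_dim)
        self.classcaps = ClassCaps(n_caps, cfg.primary_dim, cfg.num_classes,
                                   cfg.class_caps_dim, cfg.routing_iters,
                                   rng=rng, name="ClassCaps")
        self.shapes["ClassCaps"] = (cfg.num_classes, cfg.class_caps_dim)

        widths = [cfg.num_classes * cfg.class_caps_dim,
                  *cfg.decoder_widths, cfg.decoder_output]
        acts = ["relu"] * len(cfg.decoder_widths) + ["sigmoid"]
        self.decoder_entries = [
            (f"Decoder{i + 1}", Dense(widths[i], widths[i + 1], acts[i],
                                      rng=rng, name=f"Decoder{i + 1}"))
            for i in range(len(acts))]

        self._entries: list[tuple[str, Layer | None]] = []
        self._entries.append(("CLAHE", None) if self.use_clahe else ("(raw)", None))
        self._entries += lane1
        self._entries.append(("CDH", None) if self.use_cdh else ("(raw)", None))
        self._entries += lane2
        self._entries += self.trunk
        self._entries.append(("PrimaryCaps", self.primary))
        self._entries.append(("ClassCaps", self.classcaps))
        self._entries += self.decoder_entries

    def _build_lane(self, lane_idx: int, shape, cfg: ArchitectureConfig, rng):
        h, w, c = shape
        flags = cfg.ablation_flags
        f1, f2 = cfg.conv_filters
        k = cfg.conv_kernel
        conv_names = ("Conv1", "Conv2") if lane_idx == 1 else ("Conv3", "Conv4")
        bn_names = ("BN1", "BN2") if lane_idx == 1 else ("BN3", "BN4")
        mp_names = ("MP1", "MP2") if lane_idx == 1 else ("MP3", "MP4")
        layers: list[tuple[str, Layer]] = []
        if "Conv1&3" not in flags:
            layers.append((conv_names[0],
                           Conv2D(c, f1, k, 1, "relu", rng, conv_names[0])))
            h, w, c = Conv2D.out_size(h, k, 1), Conv2D.out_size(w, k, 1), f1
            self.shapes[conv_names[0]] = (h, w, c)
            layers.append((bn_names[0], BatchNorm(c, name=bn_names[0])))
        if "MP1&3" not in flags:
            layers.append((mp_names[0], MaxPool2D(name=mp_names[0])))
            h, w = MaxPool2D.out_size(h), MaxPool2D.out_size(w)
            self.shapes[mp_names[0]] = (h, w, c)
        if "Conv2&4" not in flags:
            layers.append((conv_names[1],
                           Conv2D(c, f2, k, 1, "relu", rng, conv_names[1])))
            h, w, c = Conv2D.out_size(h, k, 1), Conv2D.out_size(w, k, 1), f2
            self.shapes[conv_names[1]] = (h, w, c)
            layers.append((bn_names[1], BatchNorm(c, name=bn_names[1])))
        if "MP2&4" not in flags:
            layers.append((mp_names[1], MaxPool2D(name=mp_names[1])))
            h, w = MaxPool2D.out_size(h), MaxPool2D.out_size(w)
            self.shapes[mp_names[1]] = (h, w, c)
        return layers, (h, w, c)

    # -- data plumbing -----------------------------------------------------
    def prepare_inputs(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Compute the (parameter-free) lane inputs for a batch of images.

        Both feature extractors are deterministic, so callers precompute
        this once per dataset rather than per epoch.
        """
        X = np.asarray(X, dtype=np.float64)
        if self.use_clahe:
            x1 = np.stack([apply_clahe(img, self.clahe_cfg) for img in X])
        else:
            x1 = X
        if self.use_cdh:
            x2 = np.stack([cdh_feature_map(img, self.cdh_cfg) for img in X])
        else:
            x2 = X
        return x1, x2

    def forward(self, inputs, training: bool = False, mask_labels=None,
                collect: dict | None = None) -> dict:
        x1, x2 = inputs
        if collect is not None:
            collect["CLAHE" if self.use_clahe else "(raw)"] = x1
            collect["CDH" if self.use_cdh else "(raw)"] = x2
        for name, lay in self.lane1:
            x1 = lay.forward(x1, training=training)
            if collect is not None:
                collect[name] = x1
        for name, lay in self.lane2:
            x2 = lay.forward(x2, training=training)
            if collect is not None:
                collect[name] = x2
        z = np.concatenate([x1, x2], axis=-1)
        if collect is not None:
            collect["Concat"] = z
        for name, lay in self.trunk:
            z = lay.forward(z, training=training)
            if collect is not None:
                collect[name] = z
        u = self.primary.forward(z, training=training)
        v = self.classcaps.forward(u, training=training)
        scores = _norm(v)
        if collect is not None:
            collect["PrimaryCaps"] = u
            collect["ClassCaps"] = v
        recon, onehot = self._decode(v, scores, mask_labels, collect)
        return {"v": v, "scores": scores, "recon": recon, "mask": onehot}

    def backward(self, d_v: np.ndarray, d_recon: np.ndarray) -> None:
        d_v = d_v + self._decode_backward(d_recon)
        du = self.classcaps.backward(d_v)
        dz = self.primary.backward(du)
        for _, lay in reversed(self.trunk):
            dz = lay.backward(dz)
        c1 = self._lane_channels[0]
        d1, d2 = dz[..., :c1], dz[..., c1:]
        for _, lay in reversed(self.lane1):
            d1 = lay.backward(d1)
        for _, lay in reversed(self.lane2):
            d2 = lay.backward(d2)


class BaselineCapsNet(_CapsNetBase):
    """The original single-lane capsule network baseline.

    Conv(256, 9x9, stride 1, ReLU) -> primary capsules (32 channels x 8
    dims, 9x9, stride 2) -> 16-D class capsules via routing -> decoder
    (512, 1024, H*W*C).  No batch normalization, no pooling.
    """

    def __init__(self, cfg: ArchitectureConfig):
        h, w, c_in = cfg.input_shape
        self.cfg = cfg
        self.num_classes = cfg.num_classes
        rng = np.random.default_rng(cfg.seed)
        self.shapes: dict[str, tuple] = {"Input": (h, w, c_in)}

        self.conv1 = Conv2D(c_in, 256, 9, 1, "relu", rng, "Conv1")
        h1, w1 = Conv2D.out_size(h, 9, 1), Conv2D.out_size(w, 9, 1)
        self.shapes["Conv1"] = (h1, w1, 256)
        gh, gw = Conv2D.out_size(h1, 9, 2), Conv2D.out_size(w1, 9, 2)
        n_caps = gh * gw * 32
        self.primary = PrimaryCaps(256, 32, 8, 9, 2, rng=rng,
                                   name="PrimaryCaps")
        self.shapes["PrimaryCaps"] = (n_caps, 8)
        self.classcaps = ClassCaps(n_caps, 8, cfg.num_classes,
                                   cfg.class_caps_dim, cfg.routing_iters,
                                   rng=rng, name="ClassCaps")
        self.shapes["ClassCaps"] = (cfg.num_classes, cfg.class_caps_dim)

        widths = [cfg.num_classes * cfg.class_caps_dim,
                  *cfg.decoder_widths, cfg.decoder_output]
        acts = ["relu"] * len(cfg.decoder_widths) + ["sigmoid"]
        self.decoder_entries = [
            (f"Decoder{i + 1}", Dense(widths[i], widths[i + 1], acts[i],
                                      rng=rng, name=f"Decoder{i + 1}"))
            for i in range(len(acts))]

        self._entries = [("Conv1", self.conv1),
                         ("PrimaryCaps", self.primary),
                         ("ClassCaps", self.classcaps),
                         *self.decoder_entries]

    def prepare_inputs(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64)

    def forward(self, inputs, training: bool = False, mask_labels=None,
                collect: dict | None = None) -> dict:
        x = inputs
        x = self.conv1.forward(x, training=training)
        if collect is not None:
            collect["Conv1"] = x
        u = self.primary.forward(x, training=training)
        v = self.classcaps.forward(u, training=training)
        if collect is not None:
            collect["PrimaryCaps"] = u
            collect["ClassCaps"] = v
        scores = _norm(v)
        recon, onehot = self._decode(v, scores, mask_labels, collect)
        return {"v": v, "scores": scores, "recon": recon, "mask": onehot}

    def backward(self, d_v: np.ndarray, d_recon: np.ndarray) -> None:
        d_v = d_v + self._decode_backward(d_recon)
        du = self.classcaps.backward(d_v)
        dx = self.primary.backward(du)
        self.conv1.backward(dx)


def build_ccfm(cfg: ArchitectureConfig,
               clahe_cfg: ClaheConfig | None = None,
               cdh_cfg: CdhConfig | None = None) -> CCFMNet:
    """Build the two-lane network described by ``cfg``."""
    return CCFMNet(cfg, clahe_cfg=clahe_cfg, cdh_cfg=cdh_cfg)


def build_baseline(cfg: ArchitectureConfig) -> BaselineCapsNet:
    """Build the original capsule-network baseline for ``cfg``."""
    return BaselineCapsNet(cfg)


def count_parameters(net: _CapsNetBase) -> ParamBreakdown:
    """Per-layer parameter ledger of a built network.

    Counts every weight, bias, and batch-norm scale/shift/moving statistic
    (4 per channel).  Parameter-free stages (CLAHE, CDH, pooling, dropout)
    appear with a count of 0; routing logits are transient and not counted.
    """
    rows = [(name, 0 if lay is None else lay.param_count())
            for name, lay in net._entries]
    return ParamBreakdown(rows=rows, total=sum(n for _, n in rows))


def ablate(cfg: ArchitectureConfig, remove) -> ArchitectureConfig:
    """Return a config with the named components removed (both lanes)."""
    remove = frozenset(remove)
    bad = remove - ABLATABLE_COMPONENTS
    if bad:
        raise ValueError(f"cannot ablate unknown components: {sorted(bad)}")
    return replace(cfg, ablation_flags=cfg.ablation_flags | remove)


def _onehot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), y] = 1.0
    return out


def _eval_scores(net: _CapsNetBase, inputs, batch_size: int = 100):
    n = (inputs[0] if isinstance(inputs, tuple) else inputs).shape[0]
    scores, recons = [], []
    for lo in range(0, n, batch_size):
        sl = slice(lo, lo + batch_size)
        binp = tuple(a[sl] for a in inputs) if isinstance(inputs, tuple) \
            else inputs[sl]
        out = net.forward(binp, training=False)
        scores.append(out["scores"])
        recons.append(out["recon"])
    return np.concatenate(scores), np.concatenate(recons)


def train(net: _CapsNetBase, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig | None = None,
          validation: tuple[np.ndarray, np.ndarray] | None = None,
          loss_cfg: MarginLossConfig | None = None,
          verbose: bool = False) -> list[dict]:
    """Optimize the composite loss with Adam and per-epoch decay.

    The best state by validation accuracy (training accuracy when no
    validation set is given) is restored into ``net`` at the end.  Returns
    the per-epoch history as a list of dicts.
    """
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or MarginLossConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    k = net.num_classes
    if y.min() < 0 or y.max() >= k:
        raise ValueError(
            f"labels span [{y.min()}, {y.max()}] but network has {k} classes")
    rng = np.random.default_rng(cfg.seed)
    net.set_dropout_rng(np.random.default_rng(rng.integers(2 ** 31)))
    inputs = net.prepare_inputs(X)
    is_tuple = isinstance(inputs, tuple)
    x_flat = X.reshape(len(X), -1)
    onehot = _onehot(y, k)
    val_inputs = None
    if validation is not None:
        Xv, yv = validation
        val_inputs = net.prepare_inputs(np.asarray(Xv, dtype=np.float64))

    opt = Adam(net.trainable_params, lr=cfg.learning_rate)
    history: list[dict] = []
    best_acc, best_state = -1.0, None
    n = len(X)
    for epoch in range(cfg.epochs):
        opt.lr = cfg.learning_rate * cfg.decay_rate ** epoch
        perm = rng.permutation(n)
        ep_loss = ep_margin = ep_recon = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            binp = tuple(a[idx] for a in inputs) if is_tuple else inputs[idx]
            opt.zero_grad()
            out = net.forward(binp, training=True, mask_labels=onehot[idx])
            m = margin_loss(out["scores"], onehot[idx], loss_cfg)
            err = out["recon"] - x_flat[idx]
            recon_mse = float((err ** 2).mean())
            loss = total_loss(m, recon_mse, loss_cfg)
            # gradient of margin loss wrt v, through the norm
            dnorm = margin_loss_grad(out["scores"], onehot[idx], loss_cfg)
            v = out["v"]
            norms = _norm(v)[..., None]
            d_v = dnorm[..., None] * v / norms
            d_recon = loss_cfg.recon_coeff * 2.0 * err / err.size
            net.backward(d_v, d_recon)
            opt.step()
            w = len(idx) / n
            ep_loss += loss * w
            ep_margin += m * w
            ep_recon += recon_mse * w
        scores, _ = _eval_scores(net, inputs, cfg.batch_size)
        train_acc = float((scores.argmax(axis=1) == y).mean())
        record = {"epoch": epoch, "loss": ep_loss, "margin": ep_margin,
                  "recon_mse": ep_recon, "train_acc": train_acc,
                  "lr": opt.lr}
        if val_inputs is not None:
            vs, _ = _eval_scores(net, val_inputs, cfg.batch_size)
            record["val_acc"] = float((vs.argmax(axis=1) == yv).mean())
        history.append(record)
        monitor = record.get("val_acc", train_acc)
        if monitor > best_acc:
            best_acc, best_state = monitor, net.get_state()
        if verbose:
            print(f"epoch {epoch:3d}  loss {ep_loss:.4f}  "
                  f"train_acc {train_acc:.3f}  "
                  + (f"val_acc {record['val_acc']:.3f}" if val_inputs
                     is not None else ""))
    if best_state is not None:
        net.set_state(best_state)
    return history


def predict_and_reconstruct(net: _CapsNetBase, images: np.ndarray,
                            batch_size: int = 100
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Class scores (capsule lengths) and argmax-masked reconstructions."""
    images = np.asarray(images, dtype=np.float64)
    inputs = net.prepare_inputs(images)
    scores, recons = _eval_scores(net, inputs, batch_size)
    return scores, recons.reshape(images.shape)


def export_activations(net: _CapsNetBase, image: np.ndarray,
                       layer_name: str) -> np.ndarray:
    """Output array of the named layer for one image (visualization hook)."""
    image = np.asarray(image, dtype=np.float64)
    inputs = net.prepare_inputs(image[None])
    collect: dict = {}
    net.forward(inputs, training=False, collect=collect)
    if layer_name not in collect:
        raise KeyError(
            f"unknown layer {layer_name!r}; have {sorted(collect)}")
    return collect[layer_name][0]


def save_weights(net: _CapsNetBase, path: str) -> None:
    """Serialize all weights and batch-norm statistics to an .npz file."""
    state = net.get_state()
    np.savez(path, **{k.replace("/", "__"): v for k, v in state.items()})


def load_weights(net: _CapsNetBase, path: str) -> None:
    with np.load(path) as data:
        net.set_state({k.replace("__", "/"): data[k] for k in data.files})
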