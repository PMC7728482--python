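"""The dual-channel MLCNN-BiLSTM classifier, statsmodels-style.

:class:`MLCNNBiLSTM` is built from data (the 12-lead matrices for the
spatial channel, the lead-II sequences for the temporal channel, and integer
labels); :meth:`MLCNNBiLSTM.fit` runs minibatch optimisation and returns an
:class:`MLCNNBiLSTMResults` carrying the training history, the learned
fusion weight and prediction / feature-extraction / evaluation methods.

Architecture (defaults):

* spatial channel — three blocks of cross-masked 5x5 convolution (pad 2,
  stride 1; 32, 64, 128 maps) + batch-norm + ReLU + 2x2 max-pool, then a
  256-unit fully-connected layer.  On a 12 x 1900 input the lead axis
  collapses 12 -> 6 -> 3 -> 1 and the time axis 1900 -> 950 -> 475 -> 237.
* temporal channel — a bidirectional LSTM (128 hidden units per direction)
  over the lead-II sequence; the two final hidden states concatenate to the
  same 256-d width.
* fusion — v = alpha * v1 + (1 - alpha) * v2, elementwise, with alpha a
  learnable scalar initialised at 0.7 (unconstrained by default; a sigmoid
  reparameterisation is available).
* head — fully-connected 512 -> 128 -> 64 with ReLU + dropout, then a
  linear projection to the class logits and softmax.  The 64-d penultimate
  activation is the record's feature vector.

Training minimises the categorical cross-entropy (the mean negative
log-probability of the true class) with Adam at learning rate 1e-3, batch
size 128.  One integer seed controls parameter initialisation, shuffling
and dropout, so seeded runs are bit-reproducible on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .metrics import evaluation_report


def _logit(p):
    return float(np.log(p / (1.0 - p)))


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters."""

    input_shape: tuple = (12, 1900)
    conv_channels: tuple = (32, 64, 128)
    kernel_size: tuple = (5, 5)
    conv_padding: int = 2
    use_mask: bool = True               # False = plain dense CNN ablation
    mask_mode: str = "full_cross"
    mlcnn_fc: int = 256
    bilstm_hidden: int = 128            # per direction
    bilstm_reduce: str = "last"         # or "mean"
    fusion_alpha_init: float = 0.7
    fusion_sigmoid: bool = False        # reparameterise alpha through a sigmoid
    head: tuple = (512, 128, 64)
    n_classes: int = 6
    dropout: float = 0.5
    lr: float = 0.001
    batch_size: int = 128
    epochs: int = 100
    optimizer: str = "Adam"
    channels: str = "both"              # "both" | "mlcnn" | "bilstm"
    seed: int = 0

    def validate(self) -> None:
        if self.channels not in ("both", "mlcnn", "bilstm"):
            raise ValueError("channels must be 'both', 'mlcnn' or 'bilstm'")
        if self.channels == "both" and self.mlcnn_fc != 2 * self.bilstm_hidden:
            raise ValueError(
                "fusion requires mlcnn_fc == 2 * bilstm_hidden "
                f"(got {self.mlcnn_fc} != 2*{self.bilstm_hidden})")
        if not (0.0 < self.fusion_alpha_init < 1.0):
            raise ValueError("fusion_alpha_init must lie in (0, 1)")
        kh, kw = self.kernel_size
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dims must be odd")
        if self.n_classes < 2:
            raise ValueError("need n_classes >= 2")

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """A desk-scale variant with reduced widths for CPU experiments."""
        base = dict(conv_channels=(4, 8, 16), mlcnn_fc=32, bilstm_hidden=16,
                    head=(64, 32, 16), dropout=0.1, batch_size=20, epochs=30,
                    n_classes=2)
        base.update(overrides)
        return cls(**base)

    def flatten_dim(self) -> int:
        h, w = self.input_shape
        for _ in self.conv_channels:
            h, w = h // 2, w // 2
        return self.conv_channels[-1] * h * w


class _Fusion(nn.Layer):
    """v = alpha*v1 + (1-alpha)*v2 with a learnable scalar alpha."""

    def __init__(self, alpha_init, sigmoid=False):
        super().__init__()
        self.sigmoid = sigmoid
        raw = _logit(alpha_init) if sigmoid else float(alpha_init)
        self.params = {"alpha": np.array([raw], dtype=np.float64)}

    @property
    def alpha(self) -> float:
        raw = float(self.params["alpha"][0])
        return 1.0 / (1.0 + np.exp(-raw)) if self.sigmoid else raw

    def forward(self, v1, v2):
        if v1.shape != v2.shape:
            raise ValueError(f"fusion inputs differ: {v1.shape} vs {v2.shape}")
        self._v1, self._v2 = v1, v2
        return self.alpha * v1 + (1.0 - self.alpha) * v2

    def backward(self, dout):
        a = self.alpha
        da = float(np.sum(dout * (self._v1 - self._v2)))
        if self.sigmoid:
            da *= a * (1.0 - a)
        self.grads = {"alpha": np.array([da])}
        return a * dout, (1.0 - a) * dout


class MLCNNBiLSTM:
    """Dual-channel multilead-ECG classifier.

    Parameters
    ----------
    x12 : ndarray (n, 12, T) or None
        Spatial-channel input (all leads).  May be None for the
        BiLSTM-only variant.
    x2 : ndarray (n, T) or None
        Temporal-channel input (lead II).  May be None for the MLCNN-only
        variant.
    y : ndarray (n,)
        Integer class labels in ``[0, n_classes)``.
    config : ModelConfig
    """

    def __init__(self, x12, x2, y, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.config.validate()
        cfg = self.config
        self.x12 = None if x12 is None else np.asarray(x12, dtype=np.float64)
        self.x2 = None if x2 is None else np.asarray(x2, dtype=np.float64)
        self.y = None if y is None else np.asarray(y, dtype=int)
        if self.x12 is not None and self.x12.ndim == 3:
            if self.x12.shape[1:] != tuple(cfg.input_shape):
                raise ValueError(
                    f"x12 shape {self.x12.shape[1:]} != expected "
                    f"{tuple(cfg.input_shape)}")
        self.rng = np.random.default_rng(cfg.seed)
        self._build()
        self.set_training(False)

    @classmethod
    def from_dataset(cls, dataset, config: ModelConfig | None = None,
                     pipeline_config=None) -> "MLCNNBiLSTM":
        """Build from a labelled record collection, running the
        preprocessing pipeline to derive both channel inputs."""
        from .pipeline import PipelineConfig, run_pipeline
        pipe = pipeline_config or PipelineConfig()
        x12, x2 = run_pipeline(dataset.records, pipe)
        return cls(x12, x2, dataset.labels, config)

    # -- construction -----------------------------------------------------

    def _build(self):
        cfg, rng = self.config, self.rng
        kh, kw = cfg.kernel_size
        self.mask = (nn.build_mask((kh, kw), cfg.mask_mode)
                     if cfg.use_mask else None)
        blocks = []
        in_ch = 1
        for out_ch in cfg.conv_channels:
            blocks += [
                nn.MaskedConv2d(in_ch, out_ch, (kh, kw), rng, mask=self.mask,
                                stride=1, padding=cfg.conv_padding),
                nn.BatchNorm2d(out_ch),
                nn.ReLU(),
                nn.MaxPool2d(),
            ]
            in_ch = out_ch
        blocks += [nn.Flatten(),
                   nn.Linear(cfg.flatten_dim(), cfg.mlcnn_fc, rng),
                   nn.ReLU(), nn.Dropout(cfg.dropout, rng)]
        self.mlcnn = nn.Sequential(*blocks)

        self.bilstm = nn.BiLSTM(cfg.bilstm_hidden, rng,
                                reduce=cfg.bilstm_reduce)
        self.fusion = _Fusion(cfg.fusion_alpha_init, cfg.fusion_sigmoid)

        fused_dim = (cfg.mlcnn_fc if cfg.channels != "bilstm"
                     else 2 * cfg.bilstm_hidden)
        trunk = []
        d = fused_dim
        for width in cfg.head:
            trunk += [nn.Linear(d, width, rng), nn.ReLU(),
                      nn.Dropout(cfg.dropout, rng)]
            d = width
        self.head_trunk = nn.Sequential(*trunk)
        self.classifier = nn.Linear(d, cfg.n_classes, rng)

    def parameters(self):
        cfg = self.config
        ps = []
        if cfg.channels in ("both", "mlcnn"):
            ps += self.mlcnn.parameters()
        if cfg.channels in ("both", "bilstm"):
            ps += self.bilstm.parameters()
        if cfg.channels == "both":
            ps += self.fusion.parameters()
        ps += self.head_trunk.parameters() + self.classifier.parameters()
        return ps

    def set_training(self, flag: bool):
        for mod in (self.mlcnn, self.bilstm, self.head_trunk,
                    self.classifier, self.fusion):
            mod.training = flag

    @property
    def alpha(self) -> float:
        """Current value of the fusion weight."""
        return self.fusion.alpha

    # -- spec-surface forward operations ----------------------------------

    def mlcnn_channel_forward(self, x12: np.ndarray) -> np.ndarray:
        """Spatial features, shape (n, mlcnn_fc)."""
        x12 = np.asarray(x12, dtype=np.float64)
        if x12.ndim == 3:
            x12 = x12[:, None]
        if x12.shape[2:] != tuple(self.config.input_shape):
            raise ValueError(
                f"expected input shape (n, 1, {self.config.input_shape[0]}, "
                f"{self.config.input_shape[1]}), got {x12.shape}")
        return self.mlcnn.forward(x12)

    def bilstm_channel_forward(self, x2: np.ndarray) -> np.ndarray:
        """Temporal features, shape (n, 2 * bilstm_hidden)."""
        x2 = np.asarray(x2, dtype=np.float64)
        if x2.shape[1] != self.config.input_shape[1]:
            raise ValueError(
                f"expected sequences of length {self.config.input_shape[1]}, "
                f"got {x2.shape[1]}")
        return self.bilstm.forward(x2)

    def fuse(self, v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
        """alpha * v1 + (1 - alpha) * v2 with the current alpha."""
        return self.fusion.forward(v1, v2)

    def head_forward(self, v: np.ndarray) -> tuple:
        """(class probabilities, penultimate feature vectors)."""
        feats = self.head_trunk.forward(v)
        probs = nn.softmax(self.classifier.forward(feats))
        return probs, feats

    @staticmethod
    def loss(probs: np.ndarray, labels) -> float:
        """Mean categorical cross-entropy of predicted probabilities."""
        return nn.cross_entropy(probs, labels)

    def _forward(self, x12, x2):
        cfg = self.config
        if cfg.channels == "mlcnn":
            v = self.mlcnn_channel_forward(x12)
        elif cfg.channels == "bilstm":
            v = self.bilstm_channel_forward(x2)
        else:
            v1 = self.mlcnn_channel_forward(x12)
            v2 = self.bilstm_channel_forward(x2)
            v = self.fusion.forward(v1, v2)
        return self.head_forward(v)

    def _backward(self, probs, labels):
        cfg = self.config
        dlogits = nn.softmax_ce_grad(probs, labels)
        dfeats = self.classifier.backward(dlogits)
        dv = self.head_trunk.backward(dfeats)
        if cfg.channels == "mlcnn":
            self.mlcnn.backward(dv)
        elif cfg.channels == "bilstm":
            self.bilstm.backward(dv)
        else:
            dv1, dv2 = self.fusion.backward(dv)
            self.mlcnn.backward(dv1)
            self.bilstm.backward(dv2)

    def _remask(self):
        for lay in self.mlcnn.layers:
            if isinstance(lay, nn.MaskedConv2d):
                lay.remask()

    # -- fitting -----------------------------------------------------------

    def fit(self, epochs: int | None = None, verbose: bool = False,
            callback=None) -> "MLCNNBiLSTMResults":
        """Minibatch training; returns a results object.

        ``callback(epoch, record)`` is invoked after every epoch with the
        history row just appended.
        """
        cfg = self.config
        if self.y is None or len(self.y) == 0:
            raise ValueError("cannot fit without labelled data")
        if len(np.unique(self.y)) < 2:
            raise ValueError("training requires at least two classes")
        n = len(self.y)
        epochs = cfg.epochs if epochs is None else epochs
        opt = nn.make_optimizer(cfg.optimizer, self.parameters(), cfg.lr)
        history = []
        self.set_training(True)
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                bx12 = None if self.x12 is None else self.x12[idx]
                bx2 = None if self.x2 is None else self.x2[idx]
                by = self.y[idx]
                probs, _ = self._forward(bx12, bx2)
                losses.append(nn.cross_entropy(probs, by))
                correct += int(np.sum(probs.argmax(axis=1) == by))
                self._backward(probs, by)
                opt.step()
                self._remask()
            row = {"epoch": epoch, "loss": float(np.mean(losses)),
                   "acc": correct / n, "alpha": self.alpha}
            history.append(row)
            if verbose:
                print(f"epoch {epoch:3d}  loss {row['loss']:.4f}  "
                      f"acc {row['acc']:.3f}  alpha {row['alpha']:.3f}")
            if callback is not None:
                callback(epoch, row)
        self.set_training(False)
        return MLCNNBiLSTMResults(self, pd.DataFrame(history))

    # -- persistence -------------------------------------------------------

    def save(self, path):
        """Checkpoint: parameters + batch-norm statistics + config."""
        path = Path(path)
        arrays = {}
        for i, (layer, name) in enumerate(self.parameters()):
            arrays[f"p{i}_{name}"] = layer.params[name]
        for j, lay in enumerate(self.mlcnn.layers):
            if isinstance(lay, nn.BatchNorm2d):
                arrays[f"bn{j}_mean"] = lay.running_mean
                arrays[f"bn{j}_var"] = lay.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        cfgd = asdict(self.config)
        for k, v in cfgd.items():
            if isinstance(v, tuple):
                cfgd[k] = list(v)
        path.with_suffix(".json").write_text(json.dumps(cfgd, indent=1))

    @classmethod
    def load(cls, path) -> "MLCNNBiLSTM":
        path = Path(path)
        cfgd = json.loads(path.with_suffix(".json").read_text())
        for k in ("input_shape", "conv_channels", "kernel_size", "head"):
            cfgd[k] = tuple(cfgd[k])
        model = cls(None, None, None, ModelConfig(**cfgd))
        data = np.load(path.with_suffix(".npz"))
        for i, (layer, name) in enumerate(model.parameters()):
            layer.params[name] = data[f"p{i}_{name}"]
        for j, lay in enumerate(model.mlcnn.layers):
            if isinstance(lay, nn.BatchNorm2d):
                lay.running_mean = data[f"bn{j}_mean"]
                lay.running_var = data[f"bn{j}_var"]
        return model


class MLCNNBiLSTMResults:
    """Fit results: history, learned fusion weight, prediction utilities."""

    def __init__(self, model: MLCNNBiLSTM, history: pd.DataFrame):
        self.model = model
        self.history = history

    @property
    def alpha(self) -> float:
        return self.model.alpha

    @property
    def final_loss(self) -> float:
        return float(self.history["loss"].iloc[-1])

    @property
    def train_accuracy(self) -> float:
        return float(self.history["acc"].iloc[-1])

    def predict_proba(self, x12, x2, batch_size: int = 64) -> np.ndarray:
        self.model.set_training(False)
        out = []
        n = len(x12) if x12 is not None else len(x2)
        for s in range(0, n, batch_size):
            bx12 = None if x12 is None else np.asarray(x12)[s:s + batch_size]
            bx2 = None if x2 is None else np.asarray(x2)[s:s + batch_size]
            probs, _ = self.model._forward(bx12, bx2)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def predict(self, x12, x2, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x12, x2, batch_size).argmax(axis=1)

    def featurize(self, x12, x2, batch_size: int = 64) -> np.ndarray:
        """Penultimate feature vectors (64-d under the default head)."""
        self.model.set_training(False)
        out = []
        n = len(x12) if x12 is not None else len(x2)
        for s in range(0, n, batch_size):
            bx12 = None if x12 is None else np.asarray(x12)[s:s + batch_size]
            bx2 = None if x2 is None else np.asarray(x2)[s:s + batch_size]
            _, feats = self.model._forward(bx12, bx2)
            out.append(feats)
        return np.concatenate(out, axis=0)

    def evaluate(self, x12, x2, labels, class_names=None) -> pd.DataFrame:
        """Per-class confusion counts and ACC/SE/SP table."""
        preds = self.predict(x12, x2)
        return evaluation_report(preds, labels, self.model.config.n_classes,
                                 class_names)

    def summary(self) -> str:
        cfg = self.model.config
        n_par = sum(int(np.prod(layer.params[name].shape))
                    for layer, name in self.model.parameters())
        mask_note = (f"{cfg.mask_mode} ({self.model.mask.n_active}/"
                     f"{cfg.kernel_size[0] * cfg.kernel_size[1]} weights)"
                     if cfg.use_mask else "dense (no mask)")
        lines = [
            "                    MLCNN-BiLSTM Results",
            "=" * 64,
            f"channels:            {cfg.channels}",
            f"input shape:         {cfg.input_shape}",
            f"conv channels:       {cfg.conv_channels}  kernel {cfg.kernel_size}",
            f"kernel mask:         {mask_note}",
            f"BiLSTM hidden:       {cfg.bilstm_hidden} per direction",
            f"classes:             {cfg.n_classes}",
            f"trainable params:    {n_par}",
            f"optimizer:           {cfg.optimizer}  lr={cfg.lr}  "
            f"batch={cfg.batch_size}",
            "-" * 64,
            f"epochs run:          {len(self.history)}",
            f"final loss:          {self.final_loss:.4f}",
            f"final train acc:     {self.train_accuracy:.4f}",
            f"fusion alpha:        init {cfg.fusion_alpha_init:.3f} -> "
            f"learned {self.alpha:.4f}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def plot_history(self, path=None):
        """Loss and accuracy curves; saved to ``path`` when given."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
        axes[0].plot(self.history["epoch"], self.history["loss"])
        axes[0].set(xlabel="epoch", ylabel="loss")
        axes[1].plot(self.history["epoch"], self.history["acc"])
        axes[1].set(xlabel="epoch", ylabel="training accuracy")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
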