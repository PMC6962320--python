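"""The seven-network zoo: baseline, multi-stage and multi-context CNNs in
2D, 2.5D and 3D.

All architectures share the same design vocabulary: stacks of two 3x3
(or 3x3x3) convolutions in place of single 5x5 ones, few pooling steps to
limit spatial-information loss, a batch-normalization layer after every
pooling operation, and a dense classification head with dropout ending in
an 8-way softmax.

* BCNN — the baseline: a deeper LeNet-style trunk.
* MSTAGE — branches the middle-level features after the first block,
  globally pools them and concatenates them with the final features
  before classification, mixing local and global receptive-field scales.
* MCONTEXT (2D only) — a parallel trunk processes a larger-scale view of
  the patch (extracted at twice the side length, downsampled back), fused
  with the main features before the dense layers.

3D variants use 3x3x3 kernels on the 48 x 48 x 7 slab and pool only
in-plane so the thin z-extent survives to the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .nn.core import (TrainConfig, TrainedState, evaluate_in_batches,
                      softmax, train_network)
from .nn.layers import (BatchNorm, Conv2D, Conv3D, Dense, Dropout, Flatten,
                        GlobalAvgPool, MaxPool2x2, ReLU, Sequential)
from .sampling import PATCH, SLAB_DEPTH, ROISample
from .tissue import N_CLASSES

ARCH_NAMES = (
    "BCNN2D", "MSTAGE_CNN2D", "MCONTEXT_CNN2D",
    "BCNN2p5D", "MSTAGE_CNN2p5D", "BCNN3D", "MSTAGE_CNN3D",
)

#: Canonical ensemble member order (w1..w7) used for weight vectors.
ENSEMBLE_ORDER = (
    "BCNN2D", "MSTAGE_CNN2D", "MCONTEXT_CNN2D",
    "BCNN3D", "MSTAGE_CNN3D", "BCNN2p5D", "MSTAGE_CNN2p5D",
)

_INPUT_MODES = {
    "BCNN2D": "axial2d", "MSTAGE_CNN2D": "axial2d", "MCONTEXT_CNN2D": "axial2d",
    "BCNN2p5D": "ortho2p5d", "MSTAGE_CNN2p5D": "ortho2p5d",
    "BCNN3D": "slab3d", "MSTAGE_CNN3D": "slab3d",
}


class ArchSpecError(ValueError):
    """Unknown architecture name or inconsistent layer plan."""


class InputModeError(ValueError):
    """Sample dimensionality does not match the network's input mode."""


@dataclass(frozen=True)
class ArchSpec:
    """Layer plan of one zoo member.

    ``channels`` are the widths of (block 1, block 2, final conv pair);
    ``dense_units`` the width of the hidden classification layer. The
    defaults are the full-scale plan; :func:`tiny_arch_specs` provides a
    narrow desk-scale preset for CPU experiments.
    """

    name: str
    channels: Tuple[int, int, int] = (32, 32, 64)
    dense_units: int = 128
    dropout_p: float = 0.5
    n_classes: int = N_CLASSES

    def __post_init__(self):
        if self.name not in ARCH_NAMES:
            raise ArchSpecError(
                f"unknown architecture {self.name!r}; expected one of {ARCH_NAMES}")

    @property
    def input_mode(self) -> str:
        return _INPUT_MODES[self.name]

    def to_dict(self) -> dict:
        return {"name": self.name, "channels": list(self.channels),
                "dense_units": self.dense_units, "dropout_p": self.dropout_p,
                "n_classes": self.n_classes}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        return cls(name=d["name"], channels=tuple(d["channels"]),
                   dense_units=int(d["dense_units"]),
                   dropout_p=float(d["dropout_p"]),
                   n_classes=int(d["n_classes"]))


def default_arch_specs() -> List[ArchSpec]:
    """Full-scale plans for all seven members, in ensemble order."""
    return [ArchSpec(name) for name in ENSEMBLE_ORDER]


def tiny_arch_specs(channels=(8, 8, 16), dense_units=32) -> List[ArchSpec]:
    """Narrow desk-scale plans (same topology, fewer filters) suited to
    CPU-only experiments on synthetic phantoms."""
    return [ArchSpec(name, channels=channels, dense_units=dense_units)
            for name in ENSEMBLE_ORDER]


# ----------------------------------------------------------------- trunks

def _trunk2d(in_ch: int, ch, rng) -> Tuple[Sequential, Sequential]:
    """Returns (block1, rest-of-trunk); output side = PATCH/4."""
    c1, c2, c3 = ch
    block1 = Sequential([
        Conv2D(in_ch, c1, rng), ReLU(), Conv2D(c1, c1, rng), ReLU(),
        MaxPool2x2(), BatchNorm(c1),
    ])
    rest = Sequential([
        Conv2D(c1, c2, rng), ReLU(), Conv2D(c2, c2, rng), ReLU(),
        MaxPool2x2(), BatchNorm(c2),
        Conv2D(c2, c3, rng), ReLU(), Conv2D(c3, c3, rng), ReLU(),
    ])
    return block1, rest


def _trunk3d(in_ch: int, ch, rng) -> Tuple[Sequential, Sequential]:
    c1, c2, c3 = ch
    block1 = Sequential([
        Conv3D(in_ch, c1, rng), ReLU(), Conv3D(c1, c1, rng), ReLU(),
        MaxPool2x2(), BatchNorm(c1),
    ])
    rest = Sequential([
        Conv3D(c1, c2, rng), ReLU(), Conv3D(c2, c2, rng), ReLU(),
        MaxPool2x2(), BatchNorm(c2),
        Conv3D(c2, c3, rng), ReLU(), Conv3D(c3, c3, rng), ReLU(),
    ])
    return block1, rest


def _head(n_in: int, spec: ArchSpec, rng) -> Sequential:
    return Sequential([
        Dense(n_in, spec.dense_units, rng), ReLU(), Dropout(spec.dropout_p),
        Dense(spec.dense_units, spec.n_classes, rng),
    ])


def _feat_len(spec: ArchSpec) -> int:
    side = PATCH // 4
    c3 = spec.channels[2]
    if spec.input_mode == "slab3d":
        return c3 * SLAB_DEPTH * side * side
    return c3 * side * side


# ------------------------------------------------------------- topologies

class _BaseNet:
    """Common bookkeeping: parameter iteration and Grad-CAM capture."""

    def param_layers(self):
        out = []
        for seq in self._sequentials():
            out.extend(seq.layers)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for lyr in self.param_layers()
                   for p in lyr.params.values())

    def _sequentials(self):
        raise NotImplementedError


class PlainNet(_BaseNet):
    """trunk -> flatten -> dense head (BCNN family)."""

    def __init__(self, spec: ArchSpec, rng):
        self.spec = spec
        in_ch = 3 if spec.input_mode == "ortho2p5d" else 1
        maker = _trunk3d if spec.input_mode == "slab3d" else _trunk2d
        self.block1, self.rest = maker(in_ch, spec.channels, rng)
        self.flat = Flatten()
        self.head = _head(_feat_len(spec), spec, rng)

    def _sequentials(self):
        return [self.block1, self.rest, self.head]

    def forward_logits(self, inputs, training=False, rng=None):
        (x,) = inputs
        a = self.block1.forward(x, training, rng)
        self._feat = self.rest.forward(a, training, rng)
        f = self.flat.forward(self._feat, training, rng)
        return self.head.forward(f, training, rng)

    def backward_from_logits(self, dlogits, capture_feat=False):
        d, _ = self.head.backward(dlogits)
        d = self.flat.backward(d)
        if capture_feat:
            dfeat = d
        d, _ = self.rest.backward(d)
        self.block1.backward(d)
        return dfeat if capture_feat else None

    def last_feature_map(self):
        return self._feat


class MultiStageNet(_BaseNet):
    """trunk with a mid-level branch: global-average-pooled block-1
    features are concatenated with the flattened final features."""

    def __init__(self, spec: ArchSpec, rng):
        self.spec = spec
        in_ch = 3 if spec.input_mode == "ortho2p5d" else 1
        maker = _trunk3d if spec.input_mode == "slab3d" else _trunk2d
        self.block1, self.rest = maker(in_ch, spec.channels, rng)
        self.flat = Flatten()
        self.gap = GlobalAvgPool()
        self.head = _head(_feat_len(spec) + spec.channels[0], spec, rng)

    def _sequentials(self):
        return [self.block1, self.rest, self.head]

    def forward_logits(self, inputs, training=False, rng=None):
        (x,) = inputs
        a = self.block1.forward(x, training, rng)
        self._feat = self.rest.forward(a, training, rng)
        f = self.flat.forward(self._feat, training, rng)
        g = self.gap.forward(a, training, rng)
        self._split = f.shape[1]
        return self.head.forward(np.concatenate([f, g], axis=1), training, rng)

    def backward_from_logits(self, dlogits, capture_feat=False):
        d, _ = self.head.backward(dlogits)
        df, dg = d[:, :self._split], d[:, self._split:]
        dfeat = self.flat.backward(df)
        da_rest, _ = self.rest.backward(dfeat)
        da_gap = self.gap.backward(dg)
        self.block1.backward(da_rest + da_gap)
        return dfeat if capture_feat else None

    def last_feature_map(self):
        return self._feat


class MultiContextNet(_BaseNet):
    """Two parallel 2D trunks: the native patch and a larger-scale view,
    fused by feature concatenation before the dense layers."""

    def __init__(self, spec: ArchSpec, rng):
        self.spec = spec
        b1, r1 = _trunk2d(1, spec.channels, rng)
        b2, r2 = _trunk2d(1, spec.channels, rng)
        self.main = Sequential(b1.layers + r1.layers)
        self.ctx = Sequential(b2.layers + r2.layers)
        self.flat_main = Flatten()
        self.flat_ctx = Flatten()
        self.head = _head(2 * _feat_len(spec), spec, rng)

    def _sequentials(self):
        return [self.main, self.ctx, self.head]

    def forward_logits(self, inputs, training=False, rng=None):
        x, xc = inputs
        self._feat = self.main.forward(x, training, rng)
        fc = self.ctx.forward(xc, training, rng)
        f1 = self.flat_main.forward(self._feat, training, rng)
        f2 = self.flat_ctx.forward(fc, training, rng)
        self._split = f1.shape[1]
        return self.head.forward(np.concatenate([f1, f2], axis=1), training, rng)

    def backward_from_logits(self, dlogits, capture_feat=False):
        d, _ = self.head.backward(dlogits)
        d1, d2 = d[:, :self._split], d[:, self._split:]
        dfeat = self.flat_main.backward(d1)
        self.main.backward(dfeat)
        self.ctx.backward(self.flat_ctx.backward(d2))
        return dfeat if capture_feat else None

    def last_feature_map(self):
        return self._feat


def _make_net(spec: ArchSpec, rng) -> _BaseNet:
    if spec.name == "MCONTEXT_CNN2D":
        return MultiContextNet(spec, rng)
    if spec.name.startswith("MSTAGE"):
        return MultiStageNet(spec, rng)
    return PlainNet(spec, rng)


# ---------------------------------------------------------- input plumbing

def prepare_inputs(spec: ArchSpec, samples: Sequence[ROISample]) -> Tuple[np.ndarray, ...]:
    """Stack ROI samples into the network's input arrays, checking modes."""
    for s in samples:
        if s.mode != spec.input_mode:
            raise InputModeError(
                f"{spec.name} expects {spec.input_mode} samples, got {s.mode}")
    if spec.input_mode == "axial2d":
        x = np.stack([s.data for s in samples])[:, None]  # (N,1,H,W)
        if spec.name == "MCONTEXT_CNN2D":
            for s in samples:
                if s.context is None:
                    raise InputModeError(
                        "MCONTEXT_CNN2D requires the larger-scale context "
                        "plane; extract ROIs with with_context=True")
            xc = np.stack([s.context for s in samples])[:, None]
            return x, xc
        return (x,)
    if spec.input_mode == "ortho2p5d":
        return (np.stack([s.data for s in samples]),)  # (N,3,H,W)
    # slab3d: (48,48,7) -> (1,7,48,48)
    x = np.stack([s.data.transpose(2, 0, 1) for s in samples])[:, None]
    return (x,)


def labels_of(samples: Sequence[ROISample]) -> np.ndarray:
    return np.asarray([int(s.label) for s in samples])


# ------------------------------------------------------------------ model

@dataclass
class PatchClassifier:
    """One zoo member: an architecture plus its (possibly trained) weights.

    ``predict_proba`` returns one 8-way probability vector per sample
    (rows sum to 1); ``fit`` runs the shared early-stopping procedure.
    """

    spec: ArchSpec
    seed: int = 0
    net: object = None
    state: Optional[TrainedState] = None

    def __post_init__(self):
        if self.net is None:
            self.net = _make_net(self.spec, np.random.default_rng(self.seed))

    # -- training ----------------------------------------------------
    def fit(self, train_samples: Sequence[ROISample],
            val_samples: Sequence[ROISample],
            cfg: Optional[TrainConfig] = None) -> "PatchClassifier":
        cfg = cfg or TrainConfig()
        xt = prepare_inputs(self.spec, train_samples)
        xv = prepare_inputs(self.spec, val_samples)
        self.state = train_network(self.net, xt, labels_of(train_samples),
                                   xv, labels_of(val_samples), cfg)
        return self

    def fit_arrays(self, train_inputs, train_labels, val_inputs, val_labels,
                   cfg: Optional[TrainConfig] = None) -> "PatchClassifier":
        cfg = cfg or TrainConfig()
        self.state = train_network(self.net, train_inputs, train_labels,
                                   val_inputs, val_labels, cfg)
        return self

    @property
    def is_trained(self) -> bool:
        return self.state is not None

    # -- inference ---------------------------------------------------
    def predict_proba(self, samples: Sequence[ROISample],
                      batch_size: int = 128) -> np.ndarray:
        inputs = prepare_inputs(self.spec, samples)
        return evaluate_in_batches(self.net, inputs, batch_size)

    def predict_proba_arrays(self, inputs, batch_size: int = 128) -> np.ndarray:
        return evaluate_in_batches(self.net, inputs, batch_size)

    def predict(self, samples: Sequence[ROISample]) -> np.ndarray:
        return self.predict_proba(samples).argmax(axis=1)

    def classify_points(self, vol, points, batch_size: int = 128,
                        norm_stats=None, pad: bool = True) -> np.ndarray:
        """Probabilities at annotated points of a volume; extracts this
        member's ROI mode (reflect-padded) and optionally standardizes."""
        from .sampling import apply_normalization, extract_roi

        out = []
        for start in range(0, len(points), batch_size):
            chunk = [extract_roi(vol, p, self.spec.input_mode, pad=pad)
                     for p in points[start:start + batch_size]]
            if norm_stats is not None:
                chunk = [apply_normalization(s, norm_stats) for s in chunk]
            out.append(self.predict_proba(chunk, batch_size=batch_size))
        return np.concatenate(out, axis=0)

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def summary(self) -> str:
        return (f"{self.spec.name}: input={self.spec.input_mode}, "
                f"channels={self.spec.channels}, dense={self.spec.dense_units}, "
                f"parameters={self.n_parameters()}, "
                f"trained={'yes' if self.is_trained else 'no'}")

    # -- interpretability --------------------------------------------
    def gradcam(self, sample: ROISample, target_class: int) -> np.ndarray:
        """Gradient-weighted class activation map over the input patch.

        Channel weights are the spatial means of the gradient of the
        target-class logit with respect to the last convolutional feature
        map; the rectified weighted sum is upsampled to the input size.
        """
        if not self.is_trained:
            raise RuntimeError("gradcam requires a trained model")
        inputs = prepare_inputs(self.spec, [sample])
        logits = self.net.forward_logits(inputs, training=False, rng=None)
        if not 0 <= int(target_class) < logits.shape[1]:
            raise ValueError(f"target_class out of range: {target_class}")
        dlogits = np.zeros_like(logits)
        dlogits[0, int(target_class)] = 1.0
        dfeat = self.net.backward_from_logits(dlogits, capture_feat=True)
        feat = self.net.last_feature_map()[0]      # (C, *spatial)
        grad = dfeat[0]
        spatial_axes = tuple(range(1, feat.ndim))
        alpha = grad.mean(axis=spatial_axes)
        cam = np.maximum((alpha.reshape((-1,) + (1,) * (feat.ndim - 1))
                          * feat).sum(axis=0), 0.0)
        # upsample to the network's spatial input size
        if self.spec.input_mode == "slab3d":
            target_shape = (SLAB_DEPTH, PATCH, PATCH)
        else:
            target_shape = (PATCH, PATCH)
        factors = [t / s for t, s in zip(target_shape, cam.shape)]
        cam = ndimage.zoom(cam, factors, order=1, mode="nearest", grid_mode=True)
        return np.maximum(cam, 0.0)

    # -- persistence -------------------------------------------------
    def save(self, path, train_cfg: Optional[TrainConfig] = None,
             norm_stats=None) -> None:
        """Save weights as .npz plus a JSON sidecar carrying the layer
        plan and, when given, the training configuration and the
        normalization statistics the model expects at inference."""
        path = Path(path)
        arrays = {}
        for i, lyr in enumerate(self.net.param_layers()):
            for key, val in lyr.params.items():
                arrays[f"{i}:{key}"] = val
            if isinstance(lyr, BatchNorm):
                arrays[f"{i}:__rm"] = lyr.running_mean
                arrays[f"{i}:__rv"] = lyr.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {"arch": self.spec.to_dict(), "seed": self.seed,
                   "trained": self.is_trained}
        if train_cfg is not None:
            sidecar["train_config"] = train_cfg.to_dict()
        if norm_stats is not None:
            sidecar["normalization"] = {"mean": norm_stats.mean,
                                        "std": norm_stats.std}
        if self.state is not None:
            sidecar["stopped_epoch"] = self.state.stopped_epoch
            sidecar["best_epoch"] = self.state.best_epoch
            sidecar["best_val_loss"] = self.state.best_val_loss
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "PatchClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(spec=ArchSpec.from_dict(sidecar["arch"]),
                    seed=int(sidecar.get("seed", 0)))
        data = np.load(path.with_suffix(".npz"))
        for i, lyr in enumerate(model.net.param_layers()):
            for key in lyr.params:
                lyr.params[key] = data[f"{i}:{key}"].copy()
            if isinstance(lyr, BatchNorm):
                lyr.running_mean = data[f"{i}:__rm"].copy()
                lyr.running_var = data[f"{i}:__rv"].copy()
        if sidecar.get("trained"):
            model.state = TrainedState(
                stopped_epoch=int(sidecar.get("stopped_epoch", 0)),
                best_epoch=int(sidecar.get("best_epoch", 0)),
                best_val_loss=float(sidecar.get("best_val_loss", np.nan)))
        return model


def build_model(spec, seed: int = 0) -> PatchClassifier:
    """Build an untrained zoo member from an :class:`ArchSpec` or name."""
    if isinstance(spec, str):
        spec = ArchSpec(spec)
    return PatchClassifier(spec=spec, seed=seed)
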