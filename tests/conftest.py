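"""Shared fixtures.

The expensive fixtures are session-scoped: one balanced phantom patch set
in all three ROI modes, and the seven-member zoo trained on it at desk
scale (narrow channel widths, ~40 training patches per class, a handful
of epochs). Training-dependent tests all reuse the same trained members.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest

from lungtex.nn.core import TrainConfig
from lungtex.phantoms import generate_patchset
from lungtex.sampling import apply_normalization, fit_normalization
from lungtex.tissue import TissueClass
from lungtex.zoo import ENSEMBLE_ORDER, ArchSpec, PatchClassifier

PATCHSET_SEED = 101
N_PER_CLASS = 56          # 40 train + 16 validation per class
N_TRAIN = 40

# desk-scale widths: narrow 2D trunks, narrower still in 3D where each
# convolution costs ~20x its 2D counterpart
CHANNELS_2D = (8, 8, 16)
CHANNELS_3D = (4, 4, 8)
DENSE_UNITS = 32
EPOCHS_2D = 18
EPOCHS_3D = 8


def desk_arch_spec(name: str) -> ArchSpec:
    channels = CHANNELS_3D if name.endswith("3D") else CHANNELS_2D
    return ArchSpec(name, channels=channels, dense_units=DENSE_UNITS)


def _split_by_class(samples, n_train):
    by = defaultdict(list)
    for s in samples:
        by[int(s.label)].append(s)
    train = [s for c in sorted(by) for s in by[c][:n_train]]
    val = [s for c in sorted(by) for s in by[c][n_train:]]
    return train, val


@pytest.fixture(scope="session")
def patchsets():
    """Aligned balanced patch sets in all three ROI modes (HU units)."""
    return generate_patchset(N_PER_CLASS, rng_seed=PATCHSET_SEED,
                             modes=["axial2d", "ortho2p5d", "slab3d"])


@pytest.fixture(scope="session")
def normalized_splits(patchsets):
    """Per-mode (train, val) lists of standardized samples."""
    out = {}
    for mode, samples in patchsets.items():
        tr, va = _split_by_class(samples, N_TRAIN)
        stats = fit_normalization(tr + va)
        out[mode] = ([apply_normalization(s, stats) for s in tr],
                     [apply_normalization(s, stats) for s in va])
    return out


@pytest.fixture(scope="session")
def trained_zoo(normalized_splits):
    """All seven members trained at desk scale; returns a dict with the
    models, their validation accuracies, the stacked member validation
    probabilities (7, N, 8) and the validation labels."""
    models = {}
    val_probs = []
    labels = None
    for i, name in enumerate(ENSEMBLE_ORDER):
        spec = desk_arch_spec(name)
        tr, va = normalized_splits[spec.input_mode]
        epochs = EPOCHS_3D if name.endswith("3D") else EPOCHS_2D
        cfg = TrainConfig(batch_size=32, max_epochs=epochs, patience=30,
                          rng_seed=1000 + i)
        model = PatchClassifier(spec=spec, seed=2000 + i).fit(tr, va, cfg)
        models[name] = model
        probs = model.predict_proba(va)
        val_probs.append(probs)
        if labels is None:
            labels = np.asarray([int(s.label) for s in va])
    return {
        "models": models,
        "val_probs": np.stack(val_probs),
        "labels": labels,
        "val_acc": {n: float((p.argmax(1) == labels).mean())
                    for n, p in zip(ENSEMBLE_ORDER, val_probs)},
        "val_samples": {m: normalized_splits[m][1] for m in normalized_splits},
    }
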