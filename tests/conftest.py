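"""Shared fixtures: small synthetic embryos and label-matching helpers."""

from __future__ import annotations

import numpy as np
import pytest

from nucleoscope.synthetic import DynamicsSpec, EmbryoSpec, generate_embryo


def mean_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean IoU over ground-truth objects, matching by majority overlap."""
    ious = []
    for t in np.unique(truth):
        if t <= 0:
            continue
        m = truth == t
        vals, counts = np.unique(pred[m], return_counts=True)
        s = vals[np.argmax(counts)]
        if s == 0:
            ious.append(0.0)
            continue
        sm = pred == s
        ious.append(float((m & sm).sum() / (m | sm).sum()))
    return float(np.mean(ious))


@pytest.fixture(scope="session")
def static_embryo():
    """Noise-free single-frame 3x3 embryo without oscillation."""
    spec = EmbryoSpec(grid_shape=(3, 3), n_frames=1, seed=4)
    dyn = DynamicsSpec(osc_rel_amplitude=0.0, signal_noise=0.0)
    volume, truth = generate_embryo(spec, dynamics=dyn)
    return spec, volume, truth


@pytest.fixture(scope="session")
def default_embryo():
    """Single frame with the default dynamics (oscillation on)."""
    spec = EmbryoSpec(grid_shape=(3, 3), n_frames=1, seed=0)
    volume, truth = generate_embryo(spec)
    return spec, volume, truth
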