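"""Shared fixtures: programmatically generated phantoms and a smoke-scale
training experiment (session-scoped — training runs once for all tests)."""

from __future__ import annotations

import numpy as np
import pytest

from blobcut import hessian, identify, metrics, phantom
from blobcut.model import BlobTranslator, smoke_config
from blobcut.phantom import BlobSpec, NoiseConfig, Phantom


def make_pair(seed: int, shape=(16, 32, 32), n_blobs=(5, 10)):
    """One clean phantom and its noisy counterpart under the study noise model."""
    ph = phantom.compose_phantom(shape, n_blobs, (0.5, 1.5), seed=seed)
    noisy = phantom.add_noise(ph.image, NoiseConfig(0.01, 1.0, seed=seed + 5000))
    return ph, noisy


@pytest.fixture(scope="session")
def separated_phantom() -> Phantom:
    """Three well-separated isotropic blobs; components == blobs by design."""
    shape = (20, 32, 32)
    specs = [
        BlobSpec((6.0, 8.0, 8.0), 0.0, 0.0, 1.2, 1.2, 1.2),
        BlobSpec((10.0, 24.0, 10.0), 0.0, 0.0, 1.2, 1.2, 1.2),
        BlobSpec((14.0, 12.0, 24.0), 0.0, 0.0, 1.2, 1.2, 1.2),
    ]
    field = np.zeros(shape)
    mask = np.zeros(shape, dtype=np.uint8)
    for s in specs:
        np.maximum(field, phantom.render_blob(s, shape), out=field)
        pts = phantom.blob_support(s, shape)
        mask[pts[:, 0], pts[:, 1], pts[:, 2]] = 1
    return Phantom(image=(1.0 - field).astype(np.float32), mask=mask, blobs=specs)


@pytest.fixture(scope="session")
def small_phantom() -> Phantom:
    return phantom.compose_phantom((16, 32, 32), (5, 10), (0.5, 1.5), seed=42)


@pytest.fixture(scope="session")
def noisy_pair():
    return make_pair(42)


@pytest.fixture(scope="session")
def smoke_experiment():
    """The reduced end-to-end study: 8 train + 4 validation volumes of
    (16, 32, 32), 5-10 blobs each, study noise, 2 training epochs on CPU.

    Returns a dict with the trained model, its loss history, and per-volume
    validation measurements for the pipeline, the Hessian-only baseline and
    the convexity trend.
    """
    train_pairs = [make_pair(100 + i) for i in range(8)]
    val_pairs = [make_pair(900 + i) for i in range(4)]
    targets = [
        phantom.compose_phantom((16, 32, 32), (5, 10), (0.5, 1.5), seed=700 + i).image
        for i in range(8)
    ]
    model = BlobTranslator(smoke_config(), seed=0)
    state = model.train([n for _, n in train_pairs], targets, epochs=2)

    records = []
    for ph, noisy in val_pairs:
        det = identify.detect(noisy, model.translate)
        rep = metrics.evaluate_run(det, ph)
        conv = hessian.convexity_mask_of_image(noisy, invert=True)
        det_base = identify.connected_components(conv, volume=noisy)
        rep_base = metrics.evaluate_run(det_base, ph)
        rep_identity = metrics.evaluate_run(identify.detect(noisy, None), ph)
        records.append(
            {
                "report": rep,
                "baseline_report": rep_base,
                "identity_report": rep_identity,
                "convexity_input": hessian.convexity_count(conv),
                "convexity_translated": hessian.convexity_count(
                    hessian.convexity_mask_of_image(det.translated, invert=True)
                ),
            }
        )
    return {"model": model, "history": state.history, "validation": records}
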