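import numpy as np
import pytest

from prored.closure import ClosureEvent
from prored.model import ProredModel, tiny_config
from prored.synthetic import PhantomConfig, generate_phantom_sequence, periodic_schedule


@pytest.fixture(scope="session")
def phantom8():
    """Eight 64×64 phantom frames with two scheduled closure events."""
    cfg = PhantomConfig(frames=8, size=(64, 64),
                        closure_schedule=(ClosureEvent(1, 2), ClosureEvent(5, 6)),
                        seed=0)
    images, masks, closure = generate_phantom_sequence(cfg)
    return {"config": cfg, "images": images, "masks": masks, "closure": closure}


@pytest.fixture(scope="session")
def phantom_series32():
    """A longer, smaller-frame phantom series for closure-pipeline tests."""
    cfg = PhantomConfig(frames=30, size=(32, 32),
                        closure_schedule=periodic_schedule(30, period=10, duty=4, offset=3),
                        seed=1)
    images, masks, closure = generate_phantom_sequence(cfg)
    return {"config": cfg, "images": images, "masks": masks, "closure": closure}


@pytest.fixture(scope="session")
def tiny_model():
    return ProredModel(tiny_config(seed=0))


def numerical_grad(f, x: np.ndarray, eps: float = 1e-2, samples: int = 12,
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient of scalar f at a random subset of entries.

    Returns (flat indices, finite-difference gradients)."""
    rng = np.random.default_rng(seed)
    flat_idx = rng.choice(x.size, size=min(samples, x.size), replace=False)
    grads = np.empty(len(flat_idx))
    for j, idx in enumerate(flat_idx):
        orig = x.flat[idx]
        x.flat[idx] = orig + eps
        fp = f()
        x.flat[idx] = orig - eps
        fm = f()
        x.flat[idx] = orig
        grads[j] = (fp - fm) / (2 * eps)
    return flat_idx, grads
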