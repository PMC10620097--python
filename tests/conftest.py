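import numpy as np
import pandas as pd
import pytest

import metamerlab as ml
from metamerlab.behavior import RESPONSE_COLUMNS
from metamerlab.models import IMAGE_CLASS_VOCAB


@pytest.fixture(scope="session")
def image_model8():
    """Briefly trained 8-class image model shared across tests."""
    return ml.make_toy_model("image", 8, "briefly_trained", seed=0)


@pytest.fixture(scope="session")
def image_model4():
    return ml.make_toy_model("image", 4, "briefly_trained", seed=0)


@pytest.fixture(scope="session")
def image_train8():
    return ml.generate_stimuli("image", 20, IMAGE_CLASS_VOCAB, seed=1)


@pytest.fixture(scope="session")
def image_stims4():
    return ml.generate_stimuli("image", 15, IMAGE_CLASS_VOCAB[:4], seed=1)


def make_response_table(rng, accuracies, n_per_group=6, n_trials=20,
                        groups=("human", "model"), classes=("a", "b", "c")):
    """Trial-level table with per-(group, condition) accuracy."""
    rows = []
    for g in groups:
        for i in range(n_per_group):
            pid = f"{g}{i}"
            for cond, p in accuracies[g].items():
                for t in range(n_trials):
                    ok = rng.random() < p
                    true = classes[t % len(classes)]
                    if ok:
                        resp = true
                    else:
                        others = [c for c in classes if c != true]
                        resp = others[rng.integers(len(others))]
                    rows.append((pid, g, cond, f"st{t}", true, resp, ok))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
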