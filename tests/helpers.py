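"""Shared test utilities."""

import numpy as np
import pandas as pd

from heartframe.features import FEATURE_NAMES


def gaussian_table(n_per_class, classes=("A", "B"), shift=2.0, n_shifted=5, seed=0):
    """Gaussian class clouds in 33-D, separated by ``shift`` SDs on the
    first ``n_shifted`` features; returned as a frame-feature table."""
    rng = np.random.default_rng(seed)
    rows = []
    for ci, label in enumerate(classes):
        x = rng.standard_normal((n_per_class, len(FEATURE_NAMES)))
        sign = 1 if ci % 2 == 0 else -1
        x[:, :n_shifted] += sign * shift * (1 + ci // 2)
        for i, row in enumerate(x):
            d = {"signal_id": f"{label}{i}", "frame_index": i, "label": label, "split": "none"}
            d.update(dict(zip(FEATURE_NAMES, row)))
            rows.append(d)
    return pd.DataFrame(rows)
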