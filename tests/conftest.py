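"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths
(KD-trees, linkage, DBSCAN): plain O(n^2) loops the tests can trust.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from focipair.model import FocusSet


def make_foci(records, nuclei=None) -> FocusSet:
    rows = list(records)
    if not rows:
        return FocusSet(nuclei=nuclei)
    return FocusSet(pd.DataFrame(rows), nuclei=nuclei)


def focus_row(nucleus_id="a", channel="RAD51", x=0.0, y=0.0, intensity=1.0, **extra):
    row = {
        "nucleus_id": nucleus_id,
        "channel": channel,
        "x_nm": float(x),
        "y_nm": float(y),
        "intensity": float(intensity),
    }
    row.update(extra)
    return row


def brute_nn_same(pts: np.ndarray) -> np.ndarray:
    """O(n^2) same-set nearest-neighbor distances."""
    pts = np.asarray(pts, float)
    out = []
    for i in range(len(pts)):
        best = np.inf
        for j in range(len(pts)):
            if i == j:
                continue
            best = min(best, float(np.hypot(*(pts[i] - pts[j]))))
        out.append(best)
    return np.asarray(out)


def brute_nn_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """O(n*m) cross-set nearest-neighbor distances (one per a-point)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    out = []
    for p in a:
        out.append(min(float(np.hypot(*(p - q))) for q in b))
    return np.asarray(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
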