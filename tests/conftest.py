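"""Shared fixtures and independent oracle helpers for the test suite."""

import numpy as np
import pandas as pd
import pytest

from beadphos.bead_quant import CodeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_codes():
    """Four well-separated 3-channel reference vectors."""
    return CodeTable(
        codes={
            "cA": np.array([1.0, 0.0, 0.0]),
            "cB": np.array([0.0, 1.0, 0.0]),
            "cC": np.array([0.0, 0.0, 1.0]),
            "cD": np.array([1.0, 1.0, 1.0]),
        },
        negative_control_code="cD",
    )


def make_bead_frame(records):
    """records: iterable of (code intensity, condition, replicate, code_id)."""
    rows = []
    for i, (intensity, condition, rep, code) in enumerate(records):
        rows.append(
            {
                "bead_id": f"b{i}",
                "intensity": float(intensity),
                "condition": float(condition),
                "replicate_id": rep,
                "sample_id": "s1",
                "code_id": code,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Independent oracles (hand-rolled, no reuse of package internals)
# ---------------------------------------------------------------------------

def welch_oracle(x, y):
    """Welch t, Welch-Satterthwaite df, and two-sided p from the textbook formulas."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    v1 = x.var(ddof=1) / n1
    v2 = y.var(ddof=1) / n2
    t = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


def langmuir_oracle(c, y_max, kd):
    c = np.asarray(c, dtype=float)
    return y_max * c / (c + kd)


def grid_search_kd(conc, intensity, shared_ymax, n_grid=20001, lo=-2.0, hi=6.0):
    """Dense log10(K_d) grid-search oracle for the one-parameter global fit."""
    grid = np.logspace(lo, hi, n_grid)
    c = np.asarray(conc, dtype=float)
    y = np.asarray(intensity, dtype=float)
    sse = ((shared_ymax * c[None, :] / (c[None, :] + grid[:, None]) - y[None, :]) ** 2).sum(
        axis=1
    )
    return grid[int(np.argmin(sse))]
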