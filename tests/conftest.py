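import numpy as np
import pandas as pd
import pytest

from mirnet import MINetwork, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort with one planted block and planted DE, 40 samples."""
    cfg = SimConfig(
        n_mirnas=300,
        group_sizes={"dnPD": 20, "CTR": 20},
        module_spec=[(12, 0.7)],
        de_spec={"dnPD": (0.05, 1.5)},
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Label-exchangeable cohort: no planted effects, no blocks."""
    cfg = SimConfig(
        n_mirnas=1000,
        group_sizes={"dnPD": 30, "CTR": 30},
        dispersion=0.1,
        seed=7,
    )
    return generate_cohort(cfg)


def make_network(edges, nodes=None):
    """MINetwork from an iterable of (u, v, weight) triples."""
    df = pd.DataFrame(edges, columns=["source", "target", "mi"])
    if nodes is None:
        nodes = sorted(set(df["source"]) | set(df["target"]))
    return MINetwork(nodes=list(nodes), edges=df)


def brute_force_dpi(m: np.ndarray, eps: float, tau: float):
    """Oracle: explicit all-triangles scan of the DPI rule."""
    p = m.shape[0]
    adj = np.where(m > eps, m, 0.0)
    np.fill_diagonal(adj, 0.0)
    marked = np.zeros_like(adj, dtype=bool)
    for i in range(p):
        for j in range(i + 1, p):
            if adj[i, j] == 0:
                continue
            for k in range(p):
                if k in (i, j) or adj[i, k] == 0 or adj[j, k] == 0:
                    continue
                if adj[i, j] < adj[j, k] * (1 - tau) and adj[i, j] < adj[i, k] * (1 - tau):
                    marked[i, j] = marked[j, i] = True
                    break
    keep = (adj > 0) & ~marked
    return {(i, j) for i in range(p) for j in range(i + 1, p) if keep[i, j]}
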