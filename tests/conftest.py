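import numpy as np
import pytest

from dcnet import ExpressionStudy, WeightedNetwork


def make_study(values, n_baseline=None, gene_prefix="G"):
    """Build a paired two-condition study from a genes x samples array.

    The first half of the columns are baseline, the second half treated,
    paired by position (subject j gives columns j and j + n/2).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if n_baseline is None:
        n_baseline = n // 2
    genes = [f"{gene_prefix}{i:04d}" for i in range(values.shape[0])]
    samples = [f"S{j}_b" for j in range(n_baseline)] + [
        f"S{j}_t" for j in range(n - n_baseline)
    ]
    condition = {s: ("baseline" if s.endswith("_b") else "treated") for s in samples}
    subject = {s: s.split("_")[0] for s in samples}
    return ExpressionStudy(genes, values, samples, condition, subject)


def make_network(edge_weights):
    """WeightedNetwork from {(u, v): w} mapping."""
    return WeightedNetwork.from_edge_weights(edge_weights)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
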