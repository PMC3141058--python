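import numpy as np
import pandas as pd
import pytest

from mirconcord.expression_io import ExpressionMatrix
from mirconcord.diffexpr import DEResult


def make_matrix(values, probe_ids=None, sample_ids=None, groups=None, calls=None):
    """Build an ExpressionMatrix from a plain array with sensible defaults."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"p{i}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = {
            s: ("case" if j < half else "control") for j, s in enumerate(sample_ids)
        }
    return ExpressionMatrix.from_arrays(
        values, probe_ids, sample_ids, groups,
        calls=None if calls is None else np.asarray(calls, dtype=object),
    )


def make_de_result(probes, lfc, p, q=None, t=None):
    """Assemble a DEResult directly from per-probe statistics."""
    tbl = pd.DataFrame(
        {
            "lfc": np.asarray(lfc, dtype=float),
            "t": np.zeros(len(probes)) if t is None else np.asarray(t, dtype=float),
            "p": np.asarray(p, dtype=float),
        },
        index=list(probes),
    )
    if q is not None:
        tbl["q"] = np.asarray(q, dtype=float)
    return DEResult(tbl)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
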