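import numpy as np
import pandas as pd
import pytest

from methdyn.core import IntervalSet, Methylome


def make_methylome(positions, meth, unmeth, chrom="chr1", context="CpG",
                   strand="+", name="") -> Methylome:
    """Small methylome from parallel arrays (scalars broadcast)."""
    positions = np.asarray(positions)
    df = pd.DataFrame({
        "chrom": chrom, "pos": positions, "strand": strand,
        "context": context,
        "meth": np.broadcast_to(np.asarray(meth), positions.shape).copy(),
        "unmeth": np.broadcast_to(np.asarray(unmeth), positions.shape).copy(),
    })
    return Methylome(df, name=name)


def make_intervals(rows, name="") -> IntervalSet:
    """IntervalSet from (chrom, start, end[, strand[, label]]) tuples."""
    full = [(r + (".", ""))[:5] for r in rows]
    return IntervalSet(pd.DataFrame(full, columns=IntervalSet._COLUMNS),
                       name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
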