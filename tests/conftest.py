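import numpy as np
import pandas as pd
import pytest

from mesa_cfdna.io import FragmentSet, TargetRegion


def fragset(intervals, chrom="chr1", sample_id="s1"):
    """FragmentSet from a list of (start, end) pairs."""
    starts = [s for s, _ in intervals]
    ends = [e for _, e in intervals]
    return FragmentSet([chrom] * len(starts), starts, ends, sample_id=sample_id)


@pytest.fixture
def region2kb():
    return TargetRegion("chr1", 10_000, 12_000, "TSS_x", "tss", 11_000)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_fragments(rng, n, lo=0, hi=2000, min_len=60, max_len=220,
                     chrom="chr1"):
    starts = rng.integers(lo, hi, size=n)
    lengths = rng.integers(min_len, max_len + 1, size=n)
    return fragset(list(zip(starts.tolist(), (starts + lengths).tolist())),
                   chrom=chrom)


def calls_frame(rows):
    """Methylation call table from (chrom, pos, n_meth, n_total) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_total"])
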