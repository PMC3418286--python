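import numpy as np
import pytest

from groupnorm import ProbeTable


def make_table(starts, probe_len=25, chrom="chr1", eligible=None):
    starts = np.asarray(starts, dtype=np.int64)
    n = starts.size
    if eligible is None:
        eligible = np.ones(n, dtype=bool)
    return ProbeTable(
        chrom=np.full(n, chrom, dtype=object),
        start=starts,
        end=starts + probe_len,
        probe_id=np.array([f"p{i}" for i in range(n)], dtype=object),
        eligible=np.asarray(eligible, dtype=bool),
    )


@pytest.fixture
def tiled_table():
    """100 probes of 25 bp tiled every 10 bp on one chromosome."""
    return make_table(np.arange(100) * 10)


def write_probe_tsv(path, rows, conditions=("c1",)):
    """rows: iterable of (chrom, start, end, probe_id, *values)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tprobe_id\t" + "\t".join(conditions) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path
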