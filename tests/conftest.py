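import numpy as np
import pandas as pd
import pytest

from arraycnv.regions import RegionSpec
from arraycnv.signals import SignalPanel


@pytest.fixture
def toy_region():
    """Small interval with a round 10 kb buffer for hand-checkable windows."""
    return RegionSpec(chromosome="chr1", start=100_000, stop=200_000, buffer=10_000)


def make_panel(positions, samples, baf=None, lrr=None, gentrain=None, chromosome="chr1"):
    """Build a SignalPanel from per-SNP vectors shared across samples."""
    positions = np.asarray(positions)
    n = len(positions)
    baf = np.full(n, 0.5) if baf is None else np.asarray(baf, dtype=float)
    lrr = np.zeros(n) if lrr is None else np.asarray(lrr, dtype=float)
    gentrain = np.full(n, 0.8) if gentrain is None else np.asarray(gentrain, dtype=float)
    frames = []
    for sid in samples:
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"snp{i}" for i in range(n)],
                    "chromosome": chromosome,
                    "position": positions,
                    "sample_id": sid,
                    "baf": baf,
                    "lrr": lrr,
                    "gentrain": gentrain,
                }
            )
        )
    return SignalPanel(pd.concat(frames, ignore_index=True))


@pytest.fixture
def signal_table_text():
    """A 3-row toy signal table in the default external schema."""
    return (
        "snpID\tchromosome\tposition\tsampleID\tBAF\tLRR\tGenTrain_Score\n"
        "rs1\tchr1\t100100\tA\t0.50\t0.01\t0.85\n"
        "rs2\tchr1\t100200\tA\t0.98\t-0.05\t0.71\n"
        "rs3\tchr1\t100300\tA\t0.02\t0.03\t0.66\n"
    )
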