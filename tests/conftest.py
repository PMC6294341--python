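import numpy as np
import pandas as pd
import pytest

from synergyseq import LandmarkGeneSet, PerturbationProfileSet

META_COLS = ["compound_id", "cell_line", "dose", "dose_unit", "time_h", "replicate_id"]


@pytest.fixture
def genes10() -> LandmarkGeneSet:
    return LandmarkGeneSet.from_iterable([f"G{i:04d}" for i in range(10)])


def make_profiles(z: np.ndarray, meta: list[tuple], gene_ids=None) -> PerturbationProfileSet:
    """Build a profile set from a raw z array and per-sample metadata tuples.

    Each meta tuple is (compound_id, cell_line, dose, dose_unit, time_h,
    replicate_id).
    """
    z = np.asarray(z, dtype=float)
    gene_ids = gene_ids or [f"G{i:04d}" for i in range(z.shape[0])]
    sample_ids = [f"S{i:03d}" for i in range(z.shape[1])]
    zdf = pd.DataFrame(z, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"), columns=META_COLS)
    return PerturbationProfileSet(z=zdf, samples=samples)


def sample_meta(compound="cpd", line="CL01", time_h=24.0, n=1, start=0):
    return [(compound, line, 10.0, "uM", time_h, f"r{start + i}") for i in range(n)]
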