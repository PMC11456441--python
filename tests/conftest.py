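import numpy as np
import pytest

from harmburden.data_model import MISSING, GenotypeMatrix, SampleInfo
from harmburden.deleteriousness import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def build_matrix(case_rows, control_rows, variant_ids=None, extra_groups=()):
    """Assemble a GenotypeMatrix from per-group dosage row lists.

    ``extra_groups`` is an iterable of (group_name, rows) for family members.
    """
    rows, samples = [], []
    for i, r in enumerate(case_rows):
        samples.append(SampleInfo(f"case_{i}", "case"))
        rows.append(r)
    for i, r in enumerate(control_rows):
        samples.append(SampleInfo(f"control_{i}", "control"))
        rows.append(r)
    for group, grows in extra_groups:
        for i, r in enumerate(grows):
            samples.append(SampleInfo(f"{group}_{i}", group))
            rows.append(r)
    arr = np.array(rows, dtype=np.int8) if rows else np.zeros((0, 0), dtype=np.int8)
    nv = arr.shape[1] if arr.size else (len(variant_ids) if variant_ids else 0)
    if variant_ids is None:
        variant_ids = [f"chr1:{1000 + j}:A:G" for j in range(nv)]
    return GenotypeMatrix(samples, variant_ids, arr.reshape(len(samples), len(variant_ids)))


@pytest.fixture
def toy_matrix():
    """3 cases x 3 controls over 3 variants, including a missing call."""
    return build_matrix(
        case_rows=[[1, 0, 1], [0, 1, 0], [0, 0, 2]],
        control_rows=[[0, 0, 0], [0, MISSING, 1], [0, 0, 0]],
    )
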