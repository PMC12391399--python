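import numpy as np
import pandas as pd
import pytest

from lfqpipe.tables_io import IntensityMatrix, SampleDesign


def make_design(isolates=("ISO1",), reps=3, treatments=("control", "treated")):
    rows = []
    for iso in isolates:
        for trt in treatments:
            for r in range(1, reps + 1):
                rows.append({
                    "sample_id": f"{iso}_{trt}_r{r}", "isolate": iso,
                    "treatment": trt, "dose": 10.0 if trt == "treated" else 0.0,
                    "replicate": r,
                })
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def design_1iso():
    return make_design()


@pytest.fixture
def design_3iso():
    return make_design(isolates=("4A+", "CC-1009", "CC-2931"))


def make_matrix(values, design, prefix="P"):
    """Build an IntensityMatrix from a 2-D array (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    idx = [f"{prefix}{i:03d}" for i in range(arr.shape[0])]
    return IntensityMatrix(
        pd.DataFrame(arr, index=idx, columns=design.sample_ids), design
    )
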