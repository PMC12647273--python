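import numpy as np
import pandas as pd
import pytest

from lncscreen.containers import ExpressionMatrix
from lncscreen.pipeline import PipelineConfig, run_all

CONDITION8 = pd.Series(
    ["severe", "severe", "moderate", "moderate", "weak", "weak", "control", "control"],
    index=[f"s{i}" for i in range(1, 9)],
)


def make_matrix(intensities, confidence=None, biotype=None, probe_ids=None):
    """Small 8-sample ExpressionMatrix from a nested list."""
    arr = np.asarray(intensities, dtype=float)
    ids = probe_ids or [f"p{i}" for i in range(arr.shape[0])]
    inten = pd.DataFrame(arr, index=ids, columns=CONDITION8.index)
    conf = None
    if confidence is not None:
        conf = pd.DataFrame(np.asarray(confidence), index=ids, columns=CONDITION8.index)
    bt = pd.Series(biotype if biotype is not None else "lncRNA", index=ids)
    return ExpressionMatrix(inten, conf, bt, CONDITION8)


@pytest.fixture(scope="session")
def planted_run(tmp_path_factory):
    """One full synthetic screen at the reference planted-signal condition:

    1000 probes, 50 suppressive, per-step effect 5x the noise sd, no
    sequence corruption, top-50 selection.  Reused by the end-to-end and
    acceptance tests.
    """
    out = tmp_path_factory.mktemp("planted")
    cfg = PipelineConfig(outdir=str(out), seed=1, k=50, n_probes=1000, n_suppressive=50,
                         effect_size=250.0, noise_sd=50.0, corruption=0.0)
    report, results = run_all(cfg)
    return cfg, report, results
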