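import numpy as np
import pandas as pd
import pytest

from conformal_qsar.curation import MANDATORY_COLUMNS


def make_record(**overrides) -> dict:
    """A clean activity record; override fields to exercise filters."""
    base = {
        "target_id": "T000",
        "family": "gpcr",
        "compound_id": "C0001",
        "smiles": "S0001",
        "relation": "=",
        "pchembl": 7.0,
        "doc_id": "D01",
        "src_id": 1,
        "duplicate_flag": False,
        "data_validity_comment": "",
        "activity_comment": "",
    }
    base.update(overrides)
    return base


def records_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_benchmark():
    """One modest target run through both arms (shared across tests)."""
    from conformal_qsar import (
        BenchmarkProtocol,
        RFConfig,
        SplitPlan,
        generate_features,
    )

    bits, phys, y = generate_features(200, 4 / 9, 0.6, 8, seed=5)
    plan = SplitPlan(n_repeats=8, master_seed=5)
    proto = BenchmarkProtocol(bits, y, plan, RFConfig(n_trees=60, seed=5), physchem=phys)
    return proto.run()
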