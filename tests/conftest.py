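import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from tcrinfo.repertoire_io import RepertoireTable


def make_table(rows, **prov) -> RepertoireTable:
    """Build a repertoire table from partial row dicts."""
    return RepertoireTable(pd.DataFrame(rows), provenance=prov)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_specific():
    """Two epitopes, paired chains, small enough to enumerate by hand."""
    rows = []
    for i, (cb, vb) in enumerate(
        [("CASSF", "TRBV1"), ("CASSF", "TRBV1"), ("CASSG", "TRBV1"), ("CASSG", "TRBV2")]
    ):
        rows.append(
            dict(clone_id=f"e1_{i}", cdr3_beta=cb, v_beta=vb, j_beta="TRBJ1",
                 cdr3_alpha="CAAF", v_alpha="TRAV1", j_alpha="TRAJ1", epitope="ep1")
        )
    for i, (cb, vb) in enumerate(
        [("CGGGW", "TRBV3"), ("CGGGW", "TRBV3"), ("CGGGW", "TRBV3"), ("CGGTW", "TRBV3")]
    ):
        rows.append(
            dict(clone_id=f"e2_{i}", cdr3_beta=cb, v_beta=vb, j_beta="TRBJ2",
                 cdr3_alpha="CGGF", v_alpha="TRAV2", j_alpha="TRAJ2", epitope="ep2")
        )
    return make_table(rows)


@pytest.fixture
def toy_background(rng):
    """Background of short beta CDR3s with plenty of coincidences."""
    alphabet = ["CASSF", "CASSG", "CGGGW", "CGGTW", "CAAAF", "CTTTW"]
    vs = ["TRBV1", "TRBV2", "TRBV3"]
    rows = [
        dict(
            clone_id=f"bg_{i}",
            cdr3_beta=alphabet[rng.integers(len(alphabet))],
            v_beta=vs[rng.integers(len(vs))],
            j_beta="TRBJ1",
            cdr3_alpha=alphabet[rng.integers(len(alphabet))],
            v_alpha="TRAV1",
            j_alpha="TRAJ1",
        )
        for i in range(120)
    ]
    return make_table(rows)
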