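import numpy as np
import pytest

import rankwin as rw

TOY_DESIGN = {
    "NR_1": (rw.N_REPLETE, 1),
    "NR_2": (rw.N_REPLETE, 2),
    "ND_1": (rw.N_DEPLETED, 1),
    "ND_2": (rw.N_DEPLETED, 2),
}


def make_record(est_id, length=500, counts=(50, 50, 50, 50), fpkm=None, description=None):
    samples = list(TOY_DESIGN)
    rec_counts = dict(zip(samples, counts))
    rec_fpkm = dict(zip(samples, fpkm)) if fpkm is not None else {}
    return rw.ESTRecord(
        est_id=est_id, length_bp=length, counts=rec_counts, fpkm=rec_fpkm,
        description=description,
    )


@pytest.fixture
def toy_table():
    """Six ESTs, descending replete-level order e1 > e2 > ... > e6."""
    records = []
    for i, level in enumerate([640, 320, 160, 80, 40, 20], start=1):
        # depleted counts of e5/e6 are doubled: their ratio is 2
        dep = level * 2 if i >= 5 else level
        records.append(make_record(f"e{i}", length=1000, counts=(level, level, dep, dep)))
    return rw.AnnotatedESTTable(records, TOY_DESIGN)


@pytest.fixture(scope="session")
def default_table():
    """One full-size synthetic table with a planted 3x term, reused across tests."""
    config = rw.GeneratorConfig(
        seed=7,
        planted_terms=(
            rw.PlantedTerm("GO:7999999", size=60, windows=(1,), density_multiplier=3.0),
        ),
    )
    return rw.generate_table(config)


@pytest.fixture(scope="session")
def default_matrix(default_table):
    table, _truth = default_table
    return rw.expression_matrix(table)
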