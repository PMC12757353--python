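import io

import numpy as np
import pytest
from hypothesis import settings

import allomix as am

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_data():
    return am.make_fixture("tiny")


@pytest.fixture(scope="session")
def small_data():
    return am.make_fixture("small")


@pytest.fixture(scope="session")
def small_truth():
    return am.make_fixture("small", return_truth=True)[1]


@pytest.fixture(scope="session")
def preset_fit():
    """The published genotype mixed model, no fitting required."""
    return am.published_catalpa_fit()


@pytest.fixture(scope="session")
def small_nlme_fit(small_data):
    """One NLME fit on the small fixture, shared across tests."""
    return am.fit_nlme(small_data, am.ModelForm("power", "on_b"),
                       ("b1", "b2"), "power", "lh")


@pytest.fixture
def csv_text():
    return (
        "genotype_id,p1,dbh,h,cd,lh,lcd\n"
        "G1,0,4.2,3.1,1.5,3.3,1.6\n"
        "G1,1,5.0,3.8,1.9,4.0,2.0\n"
        "G2,0,2.1,2.0,0.8,2.2,0.9\n"
    )


def dataset_from_text(text):
    return am.read_tree_table(io.StringIO(text))


@pytest.fixture
def three_row_dataset(csv_text):
    return dataset_from_text(csv_text)


def make_grid_dataset(n_genotypes, n_trees, seed=0, dbh_from=None, p1_frac=0.0):
    """Small deterministic datasets for unit tests (not the stand generator)."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genotypes):
        lh = rng.uniform(1.5, 9.0, n_trees)
        lcd = rng.uniform(0.3, 4.0, n_trees)
        p1 = (rng.random(n_trees) < p1_frac).astype(int)
        if dbh_from is None:
            dbh = 1.2 * lh**1.1 * lcd**0.3
        else:
            dbh = dbh_from(lh, lcd, p1, rng)
        for j in range(n_trees):
            rows.append(am.TreeRecord(genotype_id=f"g{g}", p1=int(p1[j]),
                                      lh=float(lh[j]), lcd=float(lcd[j]),
                                      dbh=float(max(dbh[j], 0.05)),
                                      h=float(lh[j]), cd=float(lcd[j])))
    return am.Dataset.from_records(rows)
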