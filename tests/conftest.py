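import numpy as np
import pandas as pd
import pytest

from crustrisk.core import (
    ConcentrationTable, CongenerCatalog, CongenerRecord, default_catalog,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def mini_catalog(abbrevs, cls="alkyl", lod=0.5, rfd=None):
    """Small catalog for toy tables; cls/lod/rfd may be scalars or dicts."""
    def get(v, a, default=None):
        return v.get(a, default) if isinstance(v, dict) else v
    return CongenerCatalog(tuple(
        CongenerRecord(abbrev=a, full_name=a, cls=get(cls, a, "alkyl"),
                       lod=get(lod, a), rfd=get(rfd, a))
        for a in abbrevs))


def make_table(values, catalog, species="freshwater_shrimp", region="Hangzhou",
               month=6, year=2024):
    """Build a ConcentrationTable from {sample_id: {congener: conc}}.

    A cell is flagged detected iff its concentration is positive.
    """
    rows = []
    for sid, cell in values.items():
        for abbrev in catalog.abbrevs:
            conc = float(cell.get(abbrev, 0.0))
            rows.append((sid, species, region, month, year, abbrev, conc,
                         conc > 0))
    df = pd.DataFrame(rows, columns=[
        "sample_id", "species", "region", "month", "year", "congener",
        "concentration", "detected"])
    return ConcentrationTable(df, catalog)


def random_table(catalog, n=20, seed=0, p_detect=0.5, species="freshwater_shrimp"):
    """Random censored table over the full catalog, reproducible from seed."""
    rng = np.random.default_rng(seed)
    values = {}
    for i in range(n):
        cell = {}
        for a in catalog.abbrevs:
            if rng.random() < p_detect:
                cell[a] = float(rng.lognormal(0.0, 1.0))
        values[f"s{i:03d}"] = cell
    return make_table(values, catalog, species=species)


@pytest.fixture
def toy_catalog():
    return mini_catalog(["TEP", "TCEP", "TiBP"], lod={"TEP": 0.5, "TCEP": 0.5, "TiBP": 0.5})
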