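import numpy as np
import pandas as pd
import pytest

from cytolv.panel import CytokinePanel, Units
from cytolv.profiles import AnalysisSpec, Objective
from cytolv.synthetic import generate_panel, preset_scenarios


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_csv(tmp_path):
    """Hand-written 3-sample x 2-analyte panel + metadata files."""
    panel = tmp_path / "panel.csv"
    panel.write_text(
        "sample_id,IL-6,TNF-a\n"
        "m1,10.0,5.0\n"
        "m2,12.5,n.d.\n"
        "m3,8.0,4.5\n"
    )
    meta = tmp_path / "meta.csv"
    meta.write_text(
        "sample_id,group,sex\n"
        "m1,WT,M\n"
        "m2,APP_PS1,F\n"
        "m3,WT,F\n"
    )
    return panel, meta


def make_panel(values, groups, *, lod=None, units=Units.PG_PER_MG, analytes=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    analytes = analytes or [f"a{j}" for j in range(p)]
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    return CytokinePanel(
        values=pd.DataFrame(values, index=idx, columns=analytes),
        group=pd.Series(list(groups), index=idx),
        units=units,
        lod=None if lod is None else pd.Series(lod, index=analytes),
    )


@pytest.fixture
def make_panel_factory():
    return make_panel


@pytest.fixture
def random_panel(rng):
    """Seeded 21-sample x 8-analyte panel over three balanced groups."""
    values = np.exp(rng.normal(2.0, 0.5, size=(21, 8)))
    groups = ["A"] * 7 + ["B"] * 7 + ["C"] * 7
    return make_panel(values, groups)


@pytest.fixture
def dbdb_panel():
    """Preset combined-pathology scenario, filtered for detectability."""
    from cytolv.panel import filter_detectable

    truth = preset_scenarios("dbdb_like", seed=7)
    panel, phenotypes, _ = generate_panel(truth)
    filtered, _ = filter_detectable(panel)
    return filtered, phenotypes, truth


@pytest.fixture
def contrast_spec(dbdb_panel):
    _, _, truth = dbdb_panel
    return AnalysisSpec(
        mode="plsda",
        objective=Objective(
            kind="contrast_separation", positive_group=truth.combined_group
        ),
    )
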