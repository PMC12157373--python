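import numpy as np
import pandas as pd
import pytest

from neolung import synthetic_data as sd


def make_transcripts(rows: list[dict]) -> pd.DataFrame:
    """Build a transcript table from row dicts, filling schema defaults."""
    defaults = {
        "feature": "G0001",
        "x_um": 0.0,
        "y_um": 0.0,
        "qv": 40.0,
        "cell_id": "c1",
        "overlaps_nucleus": 1,
        "sample_id": "S1",
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults, transcript_id=f"t{i}", **row)
        out.append(rec)
    return pd.DataFrame(out)


def make_cells(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "sample_id": "S1",
        "section_id": "S1_s0",
        "centroid_x_um": 0.0,
        "centroid_y_um": 0.0,
        "nuclear_area_um2": 30.0,
        "cell_type": "AT1",
        "lineage": "epithelial",
    }
    out = []
    for i, row in enumerate(rows):
        out.append({"cell_id": f"c{i}", **defaults, **row})
    return pd.DataFrame(out, columns=["cell_id", *defaults] if not out else None)


@pytest.fixture(scope="session")
def small_cohort() -> sd.Cohort:
    """A 4-sample, 6-type cohort reused by read-only tests."""
    samples = (
        sd.SampleSpec("S1", 22, 1, 1, False),
        sd.SampleSpec("S2", 27, 4, 2, False),
        sd.SampleSpec("S3", 38, 1, 0, False),
        sd.SampleSpec("S4", 30, 2, 3, True),
    )
    tax = sd.make_taxonomy(6)
    cts = sorted(tax)
    panel = sd.make_panel(12, 6, 0, cell_types=cts, markers_per_type=2)
    cfg = sd.CohortConfig(
        samples=samples,
        taxonomy=tax,
        panel=panel,
        niche_layout=sd.uniform_layout(cts),
        cells_per_sample=250,
        section_um=500.0,
        seed=42,
    )
    return sd.simulate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
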