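import pandas as pd
import pytest

import flavoromics as fl


@pytest.fixture(scope="session")
def fx():
    """The packaged study tables (loaded once per session)."""
    return fl.load_fixtures()


@pytest.fixture(scope="session")
def roav(fx):
    """ROAV scores of the fixture volatile table (per-sample reference)."""
    return fl.compute_roav(fx.voc_table, fx.voc_thresholds)


def flat_table(n_analytes: int, groups: str = "ABCDE", mean: float = 10.0,
               sd: float = 1.0) -> fl.AnalyteTable:
    """Featureless template: every analyte has the same mean/SD in every group."""
    rows = [
        {"analyte_id": f"V{i:02d}", "sample_group": g, "value": mean, "sd": sd}
        for i in range(n_analytes)
        for g in groups
    ]
    return fl.AnalyteTable(pd.DataFrame(rows), "concentration_mg_per_kg")
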