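import pytest

from mmvdscreen.pipeline import PipelineConfig, run_screen
from mmvdscreen.simulate import REGION_WINDOWS, make_printed_fixture, printed_variant_table

#: Predictive-marker ids of the proximal nebulette perfect-LD block.
NEBL13_MARKERS = ["arr2_11822980", "arr2_11832538", "arr2_11979724"]


@pytest.fixture(scope="session")
def printed_cohort():
    """Deterministic cohort mirroring the published study composition."""
    cohort, records = make_printed_fixture()
    return cohort, records


@pytest.fixture(scope="session")
def fixture_screen(printed_cohort, tmp_path_factory):
    """Full pipeline result on the printed-composition fixture."""
    cohort, records = printed_cohort
    config = PipelineConfig(
        region_windows=dict(REGION_WINDOWS),
        out_dir=str(tmp_path_factory.mktemp("screen")),
    )
    return run_screen(
        config, cohort=cohort, records=records, variants=printed_variant_table()
    )
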