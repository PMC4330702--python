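import pandas as pd
import pytest
from importlib.resources import files

from ckresponse import PipelineConfig, PromoterSet, RatioTable
from ckresponse.io import read_ratio_table


@pytest.fixture(scope="session")
def timecourse_table() -> RatioTable:
    """Two-time-point cytokinin induction ratios for 25 induced genes."""
    return read_ratio_table(files("ckresponse") / "data" / "ba_timecourse_ratios.tsv")


@pytest.fixture()
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def small_promoters() -> tuple[PromoterSet, PromoterSet]:
    """Tiny hand-built target/control promoter pair for exact-count checks."""
    target = PromoterSet(
        {
            "TGT1": "AAGATTTTGGGG",
            "TGT2": "CCCCAAGATCTT",
            "TGT3": "GGGGGGGGGGGG",
        }
    )
    control = PromoterSet(
        {
            "CTL1": "GGGGGGGGGGGG",
            "CTL2": "CCCCCCCCCCCC",
            "CTL3": "TTTTAAAACCCC",
        }
    )
    return target, control
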