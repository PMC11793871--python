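import numpy as np
import pandas as pd
import pytest

from screenscore import GuideLibrary, SampleSheet


def write_tsv(path, text: str) -> str:
    """Write literal TSV content (pipe-separated here for readability)."""
    path.write_text(text.replace("|", "\t"))
    return str(path)


@pytest.fixture
def small_library() -> GuideLibrary:
    frame = pd.DataFrame(
        {
            "guide_id": ["sgA_1", "sgA_2", "sgA_3", "sgB_1", "sgB_2", "sgB_3"],
            "gene": ["A", "A", "A", "B", "B", "B"],
        }
    )
    return GuideLibrary(frame=frame)


@pytest.fixture
def small_sheet() -> SampleSheet:
    frame = pd.DataFrame(
        {
            "sample_id": ["T0_r1", "MOCK_r1", "DRUG_r1"],
            "condition": ["T0", "MOCK", "DRUG"],
            "bio_rep": [1, 1, 1],
            "tech_rep": [1, 1, 1],
            "t0_ref": ["", "T0_r1", "T0_r1"],
        }
    ).set_index("sample_id")
    return SampleSheet(frame=frame)
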