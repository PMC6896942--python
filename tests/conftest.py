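import numpy as np
import pandas as pd
import pytest

import reefcal as rc


@pytest.fixture(scope="session")
def study_covers():
    """One study-sized synthetic dataset (21 sites, 6 components + filler)."""
    covers, truth = rc.simulate.gen_site_level(rc.simulate.study_spec(),
                                               seed=3)
    return covers, truth


@pytest.fixture(scope="session")
def study_pairs(study_covers):
    covers, _ = study_covers
    pairs = rc.io.pair_methods(covers)
    return pairs[pairs["component"] != "other"].reset_index(drop=True)


@pytest.fixture(scope="session")
def hard_coral_diffs(study_pairs):
    return rc.agreement.difference_and_average(
        study_pairs[study_pairs["component"] == "hard_corals"])


def make_points(rows):
    return pd.DataFrame(
        rows,
        columns=["site_id", "reef_type", "method", "transect_id",
                 "point_index", "label"],
    )
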