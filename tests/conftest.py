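import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def make_trials():
    """Build a trial-record DataFrame from compact per-row tuples.

    Rows are (participant, item, interval, initial_correct, final_blank,
    final_correct, did_before).
    """

    def _make(rows):
        return pd.DataFrame(
            rows,
            columns=[
                "participant_id",
                "item_id",
                "interval",
                "initial_correct",
                "final_blank",
                "final_correct",
                "did_before",
            ],
        )

    return _make


@pytest.fixture
def balanced_trials(make_trials):
    """A small balanced dataset: 6 participants x 4 items per condition.

    Final-test outcomes are deterministic per participant x interval so that
    condition means can be recomputed by hand.
    """
    rows = []
    rng = np.random.default_rng(42)
    for p in range(6):
        pid = f"p{p}"
        counter = 0
        for interval, n_correct in zip((2, 20, 80), (4, 3, rng.integers(0, 3))):
            for k in range(4):
                counter += 1
                rows.append(
                    (pid, f"it{counter}", interval, 1, 0, int(k < n_correct), 0)
                )
    return make_trials(rows)
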