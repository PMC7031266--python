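import numpy as np
import pandas as pd
import pytest

import chromdyn as cd


@pytest.fixture(scope="session")
def default_truth():
    """Desk-scale planted genome shared by recovery tests."""
    return cd.make_genome(cd.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def merged_matrix(default_truth):
    """Replicate-merged condition-A contact matrix at 10 kb."""
    mats = cd.simulate_contacts(default_truth)
    return cd.merge_replicates([mats[("A", 0)], mats[("A", 1)]])


@pytest.fixture(scope="session")
def capture_pipeline(default_truth):
    """Capture counts scored per condition, differential tests, classification.

    The full promoter-capture analysis chain on planted data; reused by the
    dynamics, association and acceptance tests.
    """
    truth = default_truth
    cap = cd.simulate_capture(truth)
    truth = cd.simulate_peaks_expression_cage(truth)
    cap = cap.copy()
    for cond in ("A", "B"):
        cap[f"count_{cond}"] = cap[f"count_{cond}1"] + cap[f"count_{cond}2"]
    scored_a = cd.score_capture_interactions(
        cap, truth.fragments, count_col="count_A"
    )
    scored_b = cd.score_capture_interactions(
        cap, truth.fragments, count_col="count_B"
    )
    called = cap[
        (scored_a["significant"] | scored_b["significant"]).to_numpy()
    ].reset_index(drop=True)
    ccols = ["count_A1", "count_A2", "count_B1", "count_B2"]
    idiff = cd.nb_count_test(
        called[ccols].to_numpy(),
        ["A", "A", "B", "B"],
        kind="interaction",
        unit_ids=called["unit_id"].to_numpy(),
    )
    ac = truth.acetyl_peaks
    accols = [f"count_{c}{r}" for c in ("A", "B") for r in (1, 2, 3)]
    pdiff = cd.nb_count_test(
        ac[accols].to_numpy(),
        ["A", "A", "A", "B", "B", "B"],
        kind="peak",
        unit_ids=ac["peak_id"].to_numpy(),
    )
    pdiff = pdiff.merge(
        ac[["peak_id", "chrom", "start", "end"]],
        left_on="unit_id",
        right_on="peak_id",
    )
    records = cd.classify_loop_dynamics(called, idiff, pdiff, truth.fragments)
    return {
        "truth": truth,
        "capture": cap,
        "scored_a": scored_a,
        "scored_b": scored_b,
        "called": called,
        "interaction_diffs": idiff,
        "peak_diffs": pdiff,
        "records": records,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=1_000_000,
                     max_len=5_000):
    start = rng.integers(0, max_pos - max_len, size=n)
    length = rng.integers(1, max_len, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": start,
            "end": start + length,
        }
    )
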