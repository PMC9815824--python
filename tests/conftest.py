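import numpy as np
import pandas as pd
import pytest

from remap import synth


@pytest.fixture
def params():
    return synth.SimParams(seed=7)


@pytest.fixture
def designs():
    """A consistent initial/emotional design pair (72 trials)."""
    d_init = synth.generate_design("initial", 72, seed=11)
    d_emo = synth.generate_design("emotional", 72, seed=12,
                                  pair_conditions=d_init.pair_conditions())
    return d_init, d_emo


@pytest.fixture
def small_designs():
    """A fast 12-trial design pair for pattern tests."""
    d_init = synth.generate_design("initial", 12, seed=21)
    d_emo = synth.generate_design("emotional", 12, seed=22,
                                  pair_conditions=d_init.pair_conditions())
    return d_init, d_emo


@pytest.fixture
def behavioral_table():
    """Hand-built 12-row table with known bin accuracies."""
    rows = []
    # subject s1, aversive: confidences 4,4,1,2 with correct T,F,T,F
    for conf, corr in [(4, True), (4, False), (1, True), (2, False)]:
        rows.append(("s1", "aversive", conf, corr))
    # subject s1, neutral: confidences 3,3,3,1 with correct T,T,F,T
    for conf, corr in [(3, True), (3, True), (3, False), (1, True)]:
        rows.append(("s1", "neutral", conf, corr))
    # subject s2, aversive: all high-confidence and correct
    for conf, corr in [(4, True), (3, True), (4, True), (3, True)]:
        rows.append(("s2", "aversive", conf, corr))
    df = pd.DataFrame(rows, columns=["subject", "condition", "confidence",
                                     "chosen_correct"])
    df["pair_id"] = np.arange(len(df))
    df["vividness"] = df["confidence"]
    return df
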