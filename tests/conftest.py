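import numpy as np
import pytest

import pvasync as pv


@pytest.fixture(scope="session")
def study_asy_run():
    """One 600 s asynchrony-arm run with classifier output (shared)."""
    res = pv.run_scenario(pv.make_scenario("study_asy"), duration=600, seed=11)
    table, report = pv.classify_record(res.record)
    return res, table, report


@pytest.fixture(scope="session")
def study_syn_run():
    res = pv.run_scenario(pv.make_scenario("study_syn"), duration=600, seed=11)
    table, report = pv.classify_record(res.record)
    return res, table, report


def label_agreement(res, table, merge_other=True):
    """(agreeing, total) per-cycle label agreement classifier vs truth."""
    truth_t = res.cycles["t_start"].values
    truth_lab = res.cycles["sva_truth"].values
    agree = total = 0
    for _, row in table.iterrows():
        i = int(np.argmin(np.abs(truth_t - row["t_insp_start"])))
        if abs(truth_t[i] - row["t_insp_start"]) < 0.3:
            lab = row["label"]
            if merge_other and lab == "OTHER":
                lab = "NORMAL"
            total += 1
            agree += lab == truth_lab[i]
    return agree, total
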