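"""Shared fixtures: synthetic corpora and a fully trained default pipeline.

The default-scale pipeline (the generator's default study conditions) is
expensive, so it is built once per session and shared by the evaluation,
feature-analysis and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from codonspeed import corpus as cp
from codonspeed import evaluation as ev
from codonspeed import predictor as pr
from codonspeed import synthetic_data as sd


@pytest.fixture(scope="session")
def small_corpus():
    """A reduced corpus for fast structural tests (not the default conditions)."""
    cfg = sd.SyntheticConfig(n_genes=140, mean_length=150, seed=1)
    return sd.simulate_corpus(cfg)


@pytest.fixture(scope="session")
def small_tables(small_corpus):
    c = small_corpus
    fm = cp.cluster_and_fold(c.records, c.clusters40, c.clusters70, test_species=c.test_species, seed=1)
    table = cp.compute_test_weights(cp.build_position_table(c.records, c.labels, fm))
    balanced = cp.balance_training(table, seed=1)
    return fm, table, balanced


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline at the default synthetic conditions: balanced CV heads,
    out-of-fold scores, plus an unbalanced head for the debiasing contrast."""
    cfg = sd.SyntheticConfig(seed=1)
    c = sd.simulate_corpus(cfg)
    fm = cp.cluster_and_fold(c.records, c.clusters40, c.clusters70, test_species=c.test_species, seed=1)
    table = cp.compute_test_weights(cp.build_position_table(c.records, c.labels, fm))
    balanced = cp.balance_training(table, seed=1)
    config = pr.HeadConfig(seed=1)
    heads = pr.train_cv_heads(balanced, c.store, config)
    scores = pr.predict_out_of_fold(table, c.store, heads, dict(fm.fold))
    test_table = table[table["fold"] == cp.TEST_FOLD]

    unbalanced_head = pr.train_head(table[table["fold"] != cp.TEST_FOLD], c.store, config)
    rows = []
    for pid, grp in test_table.groupby("protein_id"):
        s = unbalanced_head.model.predict_proba(c.store.rows(pid, grp["position"].to_numpy()))
        rows += [
            (pid, int(r["position"]), float(v), -1) for (_, r), v in zip(grp.iterrows(), s)
        ]
    unbalanced_scores = pd.DataFrame(rows, columns=["protein_id", "position", "score", "fold_used"])
    return {
        "corpus": c,
        "fold_map": fm,
        "table": table,
        "test_table": test_table,
        "balanced": balanced,
        "heads": heads,
        "scores": scores,
        "unbalanced_scores": unbalanced_scores,
    }


def weighted_accuracy_bruteforce(scores, table, threshold=0.5):
    """Independent row-by-row loop used as the oracle for weighted metrics."""
    merged = scores.merge(table, on=["protein_id", "position"])
    num = den = 0.0
    for _, r in merged.iterrows():
        if r["weight"] <= 0:
            continue
        pred_fast = r["score"] >= threshold
        if pred_fast == (r["label"] == "FAST"):
            num += r["weight"]
        den += r["weight"]
    return num / den
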