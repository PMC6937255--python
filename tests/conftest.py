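"""Shared synthetic fixtures.

Heavy objects (the 9-class family, its 180-sequence batch, calibrated
profiles) are session-scoped so unit and acceptance tests share one build.
"""

from __future__ import annotations

import numpy as np
import pytest

import ligperox as lp
from ligperox.msa import MultipleAlignment
from ligperox.profiles import build_profile, calibrate_thresholds, family_conserved_mask

FAMILY_SEED = 11
SEQ_SEED = 12


@pytest.fixture(scope="session")
def family_model():
    return lp.generate_family(n_subclasses=9, length=350, seed=FAMILY_SEED)


@pytest.fixture(scope="session")
def sequence_batch(family_model):
    """9 sub-classes x 20 records at substitution rate 0.15, no indels."""
    records, truth = lp.generate_sequences(
        family_model, n_per_class=20, sub_rate=0.15, seed=SEQ_SEED)
    return records, truth


@pytest.fixture(scope="session")
def indel_batch(family_model):
    records, truth = lp.generate_sequences(
        family_model, n_per_class=20, sub_rate=0.15, seed=SEQ_SEED + 1, indels=True)
    return records, truth


@pytest.fixture(scope="session")
def batch_alignment(sequence_batch):
    records, _ = sequence_batch
    return MultipleAlignment(records)


@pytest.fixture(scope="session")
def batch_labels(sequence_batch):
    _, truth = sequence_batch
    return {k: v["subclass"] for k, v in truth.sequence_labels.items()}


@pytest.fixture(scope="session")
def cluster_alignments(batch_alignment, batch_labels):
    clusters = sorted(set(batch_labels.values()))
    return {
        c: batch_alignment.subalignment(
            [k for k in batch_alignment.ids if batch_labels[k] == c])
        for c in clusters
    }


@pytest.fixture(scope="session")
def family_mask(cluster_alignments):
    return family_conserved_mask(list(cluster_alignments.values()))


@pytest.fixture(scope="session")
def calibrated_profiles(cluster_alignments, family_mask):
    profs = [
        build_profile(aln, family_mask, downweight=0.1, label=c)
        for c, aln in cluster_alignments.items()
    ]
    calibrate_thresholds(profs, length=350, n_null=1000, alpha=0.01, seed=77)
    return profs
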