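import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from reticulotype import (
    ExpressionMatrix,
    Interactome,
    Reticulotype,
    canonical_pair,
)
from reticulotype.synthetic import SyntheticCohortSpec, generate

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_matrix(counts: dict, groups=None, biotype=None) -> ExpressionMatrix:
    """counts: gene_id -> list of per-sample counts; samples auto-named
    C1..Ck then P1.. according to ``groups`` (default: all controls)."""
    n = len(next(iter(counts.values())))
    if groups is None:
        groups = ["control"] * n
    sample_ids = []
    c = p = 0
    for g in groups:
        if g == "control":
            c += 1
            sample_ids.append(f"C{c}")
        else:
            p += 1
            sample_ids.append(f"P{p}")
    frame = pd.DataFrame(counts, index=sample_ids).T
    bio = pd.Series(biotype) if biotype else None
    return ExpressionMatrix(
        counts=frame,
        biotype=bio,
        group=pd.Series(groups, index=sample_ids),
    )


def make_interactome(pairs) -> Interactome:
    edges = {canonical_pair(*p) for p in pairs}
    return Interactome(proteins={x for e in edges for x in e}, edges=edges)


def make_net(patient_id, pairs) -> Reticulotype:
    edges = {canonical_pair(*p) for p in pairs}
    return Reticulotype(
        patient_id=patient_id,
        nodes={x for e in edges for x in e},
        edges=edges,
        records={},
    )


@pytest.fixture
def tiny_matrix():
    return make_matrix(
        {
            "GA": [10, 12, 14, 16, 18, 40, 5],
            "GB": [20, 24, 28, 32, 36, 10, 50],
            "GC": [5, 5, 5, 5, 5, 5, 5],
            "GD": [0, 0, 0, 0, 0, 9, 9],
        },
        groups=["control"] * 5 + ["patient"] * 2,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The study-emulating synthetic cohort (5 controls, 18 patients)."""
    return generate(SyntheticCohortSpec.default(seed=42))


@pytest.fixture(scope="session")
def default_networks(default_cohort):
    from reticulotype import run_cohort

    res = run_cohort(
        default_cohort.expression,
        default_cohort.interactome,
        family="interactome_pairs",
    )
    return res.networks
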