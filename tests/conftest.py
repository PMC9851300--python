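"""Shared fixtures: the k-mer filter bank and (session-scoped, trained
once) the synthetic model bundle with its companion genome and pipeline
runs, reused by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from ltrnet.kmer_conv import build_filter_bank
from ltrnet.pipeline import run_pipeline, train_synthetic_bundle
from ltrnet.synthetic_data import gen_genome

E2E_SEED = 11


@pytest.fixture(scope="session")
def bank():
    return build_filter_bank()


@pytest.fixture(scope="session")
def demo_bundle():
    """A complete bundle trained on synthetic data at the 50 kb window."""
    return train_synthetic_bundle(seed=E2E_SEED)


@pytest.fixture(scope="session")
def synthetic_genome():
    """500 kb genome, 10 intact implants, one straddling a window boundary."""
    return gen_genome(length=500_000, n_implants=10, seed=E2E_SEED, straddle=True)


@pytest.fixture(scope="session")
def e2e_run_c1(demo_bundle, synthetic_genome):
    genome, _ = synthetic_genome
    return run_pipeline(genome, demo_bundle, cycles=1, curation=True)


@pytest.fixture(scope="session")
def e2e_run_c2(demo_bundle, synthetic_genome):
    genome, _ = synthetic_genome
    return run_pipeline(genome, demo_bundle, cycles=2, curation=True)


def match_truth(preds, truth, tol: int = 50):
    """Predictions within +/-tol bp of each truth record (or None)."""
    out = []
    for t in truth:
        m = [p for p in preds
             if p.source_id == t.source_id
             and max(abs(p.start - t.start), abs(p.end - t.end)) <= tol]
        out.append(m[0] if m else None)
    return out
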