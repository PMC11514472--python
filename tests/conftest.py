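"""Shared fixtures: tiny deterministic stores, documents and simulations."""

from __future__ import annotations

import numpy as np
import pytest

import hic_curator as hc

RESOLUTIONS = [5000, 10000, 25000, 50000]


@pytest.fixture(scope="session")
def resolutions():
    return list(RESOLUTIONS)


@pytest.fixture()
def toy_doc():
    """Three provenance-named fragments, lengths 100/200/300, one scaffold."""
    fragments = [
        hc.Fragment("ctg:0-100", 1, 100),
        hc.Fragment("ctg:100-300", 2, 200),
        hc.Fragment("ctg:300-600", 3, 300),
    ]
    return hc.AssemblyDoc(fragments, [[1, 2, 3]])


@pytest.fixture()
def tiny_store():
    """10-bin store at 1 kb with a distance-decay pattern, genome 10 kb."""
    n = 10
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    mat = 100.0 / (1.0 + d)
    return hc.ContactStore(10_000, {1000: mat})


def simulate_case(
    seed: int,
    n_events: int,
    categories=("translocation", "inversion"),
    n_contigs: int = 2,
    length_range=(400_000, 500_000),
    noise: str = "none",
):
    """One misassembled genome with its truth, store and map provider."""
    contigs, doc = hc.make_genome(n_contigs, length_range, seed=seed)
    shuffled, truth = hc.fragment_and_shuffle(
        doc, seed=seed + 10_000, n_events=n_events, categories=categories
    )
    model = hc.ContactModel(noise=noise, seed=seed)
    store = hc.synth_contact_map(truth, RESOLUTIONS, model)
    provider = hc.SyntheticMapProvider(truth.contig_lengths, RESOLUTIONS, model)
    return contigs, doc, shuffled, truth, store, provider


@pytest.fixture()
def single_translocation_case():
    return simulate_case(seed=5, n_events=1, categories=("translocation",))


@pytest.fixture()
def single_inversion_case():
    return simulate_case(seed=7, n_events=1, categories=("inversion",))
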