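"""Shared fixtures: small hand-built populations and their datasets."""

from __future__ import annotations

import pytest

from mti import (
    MatingTypeAssignment,
    ParentTable,
    TruthAssignment,
    derive_observations,
)


def make_truth(alleles: dict[str, tuple[int, int]], parents: list[tuple[str, str]]) -> TruthAssignment:
    return TruthAssignment(MatingTypeAssignment(alleles), ParentTable(tuple(parents)))


@pytest.fixture
def four_strain_truth() -> TruthAssignment:
    """Two dikaryons; the non-sibling pair (s3, s4) shares an A allele,
    giving one incompatible pair among six."""
    return make_truth(
        {"s1": (1, 1), "s2": (2, 2), "s3": (3, 3), "s4": (3, 4)},
        [("s1", "D1"), ("s3", "D1"), ("s2", "D2"), ("s4", "D2")],
    )


@pytest.fixture
def four_strain_dataset(four_strain_truth):
    """Derived observations: 5 compatible pairs + (s3,s4) incompatible A=B≠."""
    return derive_observations(four_strain_truth)


@pytest.fixture
def two_sibling_dataset():
    """Smallest inferable dataset: one dikaryon, one compatible pair."""
    truth = make_truth({"m1": (1, 1), "m2": (2, 2)}, [("m1", "D1"), ("m2", "D1")])
    return derive_observations(truth)
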