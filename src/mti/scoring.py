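"""Consistency scoring of a candidate mating-type assignment.

Every observed pair contributes an integer in [-2, +2]:

* a compatible pair expects the strains to differ at both loci — two ±1
  locus-level checks;
* an incompatible pair with an OWE-SOJ record expects exactly the recorded
  relations — again two ±1 locus-level checks;
* an incompatible pair without a record carries a single ±1
  compatibility-level check (+1 when the assignment predicts
  incompatibility, i.e. shares an allele at A or at B);
* an untested pair contributes 0.

For a complete, fully informed dataset of n strains the maximum achievable
score is therefore 2·C(n, 2) — 870 for 30 strains — and an assignment
reaches it iff it satisfies every observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    Compatibility,
    Dataset,
    LociRelation,
    MTIError,
    MatingTypeAssignment,
    PairKey,
)

__all__ = [
    "PairExpectation",
    "pair_expectation",
    "expectations",
    "pair_contribution",
    "pair_max",
    "ScoreBreakdown",
    "score_assignment",
    "max_possible_score",
]


@dataclass(frozen=True)
class PairExpectation:
    """What an observation implies about a pair's per-locus relations.

    ``compat_only`` marks incompatible pairs without locus-level evidence:
    both relations are UNKNOWN and only the compatibility prediction is
    checked.
    """

    a_rel: LociRelation
    b_rel: LociRelation
    compat_only: bool = False

    def __post_init__(self) -> None:
        unknown = self.a_rel is LociRelation.UNKNOWN and self.b_rel is LociRelation.UNKNOWN
        if self.compat_only != unknown:
            raise MTIError("compat_only iff both relations are UNKNOWN")


_COMPAT_EXPECTATION = PairExpectation(LociRelation.DIFFERENT, LociRelation.DIFFERENT)
_COMPAT_ONLY = PairExpectation(LociRelation.UNKNOWN, LociRelation.UNKNOWN, compat_only=True)


def pair_expectation(
    obs: Optional[Compatibility],
    loci_record: Optional[tuple[LociRelation, LociRelation]] = None,
) -> Optional[PairExpectation]:
    """Expected per-locus relations for one observed pair.

    Compatible pairs must differ at both loci.  Incompatible pairs with an
    OWE-SOJ record expect the recorded relations; without one, only the
    incompatibility itself is checkable.  Untested pairs yield None.
    """
    if obs is Compatibility.COMPATIBLE:
        if loci_record is not None:
            raise MTIError("loci record supplied with a compatible observation")
        return _COMPAT_EXPECTATION
    if obs is Compatibility.INCOMPATIBLE:
        if loci_record is None:
            return _COMPAT_ONLY
        return PairExpectation(*loci_record)
    if obs is None:
        return None
    raise MTIError(f"unknown observation {obs!r}")


def expectations(ds: Dataset) -> dict[PairKey, PairExpectation]:
    """Expectation for every observed pair of the dataset."""
    out: dict[PairKey, PairExpectation] = {}
    for pk, obs in ds.matrix.observations.items():
        record = ds.loci.records.get(pk) if obs is Compatibility.INCOMPATIBLE else None
        exp = pair_expectation(obs, record)
        if exp is not None:
            out[pk] = exp
    return out


def _locus_term(rel: LociRelation, same: bool) -> int:
    if rel is LociRelation.SAME:
        return 1 if same else -1
    return -1 if same else 1


def pair_contribution(
    exp: PairExpectation, s_alleles: tuple[int, int], t_alleles: tuple[int, int]
) -> int:
    """Score contribution of one pair under one assignment."""
    same_a = s_alleles[0] == t_alleles[0]
    same_b = s_alleles[1] == t_alleles[1]
    if exp.compat_only:
        return 1 if (same_a or same_b) else -1
    return _locus_term(exp.a_rel, same_a) + _locus_term(exp.b_rel, same_b)


def pair_max(exp: PairExpectation) -> int:
    """Largest contribution the pair can make (its term in the max score)."""
    return 1 if exp.compat_only else 2


@dataclass
class ScoreBreakdown:
    """Total score with the per-pair contributions behind it."""

    total: int
    per_pair: dict[PairKey, int]
    max_possible: int


def score_assignment(asg: MatingTypeAssignment, ds: Dataset) -> ScoreBreakdown:
    """Score an assignment against all observations of the dataset."""
    for s in ds.matrix.strains:
        if s not in asg.alleles:
            raise MTIError(f"strain {s!r} has no allele pair in the assignment")
    exps = expectations(ds)
    per_pair: dict[PairKey, int] = {}
    for pk, exp in exps.items():
        a, b = pk
        per_pair[pk] = pair_contribution(exp, asg.alleles[a], asg.alleles[b])
    total = sum(per_pair.values())
    return ScoreBreakdown(total=total, per_pair=per_pair,
                          max_possible=sum(pair_max(e) for e in exps.values()))


def max_possible_score(ds: Dataset) -> int:
    """Sum over observed pairs of the largest contribution each can make."""
    return sum(pair_max(e) for e in expectations(ds).values())
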