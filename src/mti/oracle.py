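"""Exhaustive reference for small populations.

Enumerates every pair of set partitions (one per locus) of the strain set,
scores each against the observations, and returns the exact optimum set.
Exists for verification of the branch-and-bound engine, not for production
use: the partition count is the Bell number, so the enumeration is guarded
to eight strains (Bell(8) = 4140).

The scoring here is an independent, vectorized route: per-locus terms are
accumulated over the partition list with numpy and the cross-locus coupling
of record-free incompatible pairs is a single matrix product, so agreement
with :func:`mti.scoring.score_assignment` is a genuine cross-check.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional

import numpy as np

from .model import (
    Compatibility,
    Dataset,
    LociRelation,
    MTIError,
    MatingTypeAssignment,
    MergePolicy,
    ValidationError,
    validate_dataset,
)
from .scoring import expectations, max_possible_score, pair_max
from .inference import InferenceResult, detect_suspect_records, evidence_graph
from .stats import summarize_dataset

__all__ = ["enumerate_partitions", "brute_force_infer"]

_MAX_N = 8


def enumerate_partitions(n: int) -> list[tuple[int, ...]]:
    """All set partitions of n items as canonical restricted-growth strings.

    Labels are 1-based; the first item always takes label 1 and each new
    class takes the smallest unused label.  Sequences come out in
    lexicographic order without duplicates; there are Bell(n) of them.
    """
    if not 1 <= n <= _MAX_N:
        raise MTIError(f"partition enumeration guarded to 1..{_MAX_N} items (got {n})")
    out: list[tuple[int, ...]] = []
    cur = [0] * n

    def rec(i: int, mx: int) -> None:
        if i == n:
            out.append(tuple(cur))
            return
        for lab in range(1, mx + 2):
            cur[i] = lab
            rec(i + 1, max(mx, lab))

    rec(0, 0)
    return out


@lru_cache(maxsize=None)
def _partition_array(n: int) -> np.ndarray:
    return np.array(enumerate_partitions(n), dtype=np.int16)


def _evidence_valid(parts: np.ndarray, strains: list[str], graph) -> np.ndarray:
    """For each partition, is every class of size >= 2 connected in the graph."""
    adj = {s: set(graph.adj[s]) for s in graph.nodes}
    valid = np.ones(parts.shape[0], dtype=bool)
    for p_idx in range(parts.shape[0]):
        labels = parts[p_idx]
        classes: dict[int, list[str]] = {}
        for s_idx, lab in enumerate(labels):
            classes.setdefault(int(lab), []).append(strains[s_idx])
        for members in classes.values():
            if len(members) < 2:
                continue
            member_set = set(members)
            seen = {members[0]}
            stack = [members[0]]
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v in member_set and v not in seen:
                        seen.add(v)
                        stack.append(v)
            if len(seen) != len(member_set):
                valid[p_idx] = False
                break
    return valid


def brute_force_infer(
    ds: Dataset,
    policy: MergePolicy = MergePolicy.EVIDENCE_REQUIRED,
    max_optima: Optional[int] = None,
) -> InferenceResult:
    """Score every (A-partition, B-partition) pair and return all maximizers.

    Under EVIDENCE_REQUIRED only partitions whose every same-class pair is
    connected through OWE-SOJ SAME relations at that locus are admitted;
    under FREE the full space is scored.
    """
    report = validate_dataset(ds)
    if not report.ok:
        raise ValidationError("dataset has validation errors")
    strains = sorted(ds.matrix.strains)
    n = len(strains)
    if n > _MAX_N:
        raise MTIError(f"brute force guarded to {_MAX_N} strains (got {n})")
    idx = {s: i for i, s in enumerate(strains)}
    parts = _partition_array(n)
    P = parts.shape[0]

    exps = expectations(ds)
    a_score = np.zeros(P, dtype=np.int32)
    b_score = np.zeros(P, dtype=np.int32)
    compat_only_not_a = []  # per record-free incompatible pair: A labels differ
    compat_only_not_b = []
    for pk, exp in exps.items():
        i, j = idx[pk[0]], idx[pk[1]]
        same_a = parts[:, i] == parts[:, j]
        if exp.compat_only:
            compat_only_not_a.append(~same_a)
            compat_only_not_b.append(parts[:, i] != parts[:, j])  # same columns, B partition side
            continue
        a_score += np.where(same_a == (exp.a_rel is LociRelation.SAME), 1, -1)
        same_b = parts[:, i] == parts[:, j]
        b_score += np.where(same_b == (exp.b_rel is LociRelation.SAME), 1, -1)

    total = a_score[:, None] + b_score[None, :]
    if compat_only_not_a:
        notA = np.stack(compat_only_not_a, axis=1).astype(np.int32)
        notB = np.stack(compat_only_not_b, axis=1).astype(np.int32)
        k = notA.shape[1]
        # pair contributes +1 unless labels differ at both loci: 1 - 2*(notA & notB)
        total = total + (k - 2 * (notA @ notB.T))

    if policy is MergePolicy.EVIDENCE_REQUIRED:
        valid_a = _evidence_valid(parts, strains, evidence_graph(ds, 0))
        valid_b = _evidence_valid(parts, strains, evidence_graph(ds, 1))
    else:
        valid_a = np.ones(P, dtype=bool)
        valid_b = np.ones(P, dtype=bool)
    big = np.int64(10 ** 9)
    total = total.astype(np.int64)
    total[~valid_a, :] = -big
    total[:, ~valid_b] = -big

    best = int(total.max())
    ai, bi = np.nonzero(total == best)
    assignments = []
    for a_part, b_part in zip(ai, bi):
        alleles = {
            s: (int(parts[a_part, i]), int(parts[b_part, i])) for s, i in idx.items()
        }
        assignments.append(MatingTypeAssignment(alleles))
    assignments.sort(key=lambda a: a.labels(strains))
    n_opt = len(assignments)
    truncated = False
    if max_optima is not None and n_opt > max_optima:
        assignments = assignments[:max_optima]
        truncated = True
    result = InferenceResult(
        best_score=best,
        max_score=max_possible_score(ds),
        assignments=assignments,
        n_enumerated=int(valid_a.sum()) * int(valid_b.sum()),
        flagged_pairs=[],
        allele_counts=[a.allele_counts() for a in assignments],
        n_optima=n_opt,
        truncated=truncated,
        statistics=summarize_dataset(ds),
    )
    result.flagged_pairs = detect_suspect_records(result, ds)
    return result
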