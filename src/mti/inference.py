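"""Combinatorial pruning traversal for mating-type inference.

The search anchors a sibling starting pair at A1B1/A2B2, seeds a greedy
pairwise-compatible sub-population whose members can safely receive fresh
mutually distinct alleles, and then runs an exact branch-and-bound over the
remaining strains, extending one strain at a time with candidate allele
labels and pruning any branch whose score can no longer reach the best
complete assignment found.  All co-optimal assignments are collected,
canonicalized and deduplicated, and pairs that score negatively in every
co-optimal assignment are flagged as suspect records.

Allele-merge candidates depend on the merge policy.  Under
EVIDENCE_REQUIRED (the default) a strain may adopt an existing allele label
only when OWE-SOJ SAME evidence connects it, at that locus, to a strain
carrying the label; connectivity is taken over the whole per-locus evidence
graph, and complete assignments are additionally required to have every
allele class connected inside itself.  Together these two rules make the
branch-and-bound enumerate exactly the evidence-consistent partition space,
so it provably agrees with the exhaustive reference in
:mod:`mti.oracle` — including on datasets whose records have been corrupted.
Under FREE every existing label is a candidate for every strain; nothing
can then be fixed up front (with corrupted observations even a merged
starting pair can tie for the optimum), so the traversal covers the full
restricted-growth space and is guarded to small populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .model import (
    Compatibility,
    Dataset,
    LociRelation,
    MTIError,
    MatingTypeAssignment,
    MergePolicy,
    PairKey,
    ValidationError,
    pair_key,
    validate_dataset,
)
from .scoring import (
    PairExpectation,
    expectations,
    pair_contribution,
    pair_max,
    score_assignment,
)
from .stats import DatasetSummary, summarize_dataset

__all__ = [
    "InferenceConfig",
    "InferenceResult",
    "select_starting_pair",
    "seed_compatible_clique",
    "evidence_graph",
    "candidate_alleles",
    "canonicalize",
    "infer_mating_types",
    "detect_suspect_records",
]

_FREE_POLICY_MAX_STRAINS = 12


@dataclass
class InferenceConfig:
    """Tunable knobs of the traversal.

    ``starting_pair`` must be a sibling pair when given.  ``max_optima``
    caps how many co-optimal assignments are stored (the count of optima is
    still exact).  ``prune`` disables the bound test when False, for
    pruning-benefit measurements.
    """

    starting_pair: Optional[tuple[str, str]] = None
    merge_policy: MergePolicy = MergePolicy.EVIDENCE_REQUIRED
    max_optima: int = 100
    report_trace: bool = False
    prune: bool = True


@dataclass
class InferenceResult:
    """Outcome of one inference run."""

    best_score: int
    max_score: int
    assignments: list[MatingTypeAssignment]
    n_enumerated: int
    flagged_pairs: list[tuple[PairKey, str]]
    allele_counts: list[tuple[int, int]]
    n_optima: int
    truncated: bool
    statistics: Optional[DatasetSummary] = None
    trace: list[str] = field(default_factory=list)


def select_starting_pair(ds: Dataset, cfg: Optional[InferenceConfig] = None) -> tuple[str, str]:
    """Pick the anchor sibling pair, designated A1B1 and A2B2.

    Uses the configured pair when given (it must be a sibling pair), else
    both monokaryons of the lexicographically first dikaryon with two
    strains in the dataset.
    """
    cfg = cfg or InferenceConfig()
    present = set(ds.matrix.strains)
    if cfg.starting_pair is not None:
        a, b = cfg.starting_pair
        if a not in present or b not in present:
            raise MTIError(f"starting pair ({a!r}, {b!r}) not in the dataset")
        if not ds.parents.are_siblings(a, b):
            raise MTIError(f"starting pair ({a!r}, {b!r}) is not a sibling pair")
        return (a, b)
    for dik in sorted(ds.parents.dikaryons):
        strains = ds.parents.dikaryons[dik]
        if len(strains) == 2 and all(s in present for s in strains):
            return (strains[0], strains[1])
    raise MTIError("no complete sibling pair in the dataset")


def seed_compatible_clique(ds: Dataset, start: tuple[str, str]) -> list[str]:
    """Greedy maximal pairwise-compatible sub-population containing ``start``.

    Remaining strains are visited in identifier order and added iff their
    observed relation to every current member is compatible (missing or
    incompatible observations exclude a strain).
    """
    if ds.matrix.lookup(*start) is not Compatibility.COMPATIBLE:
        raise MTIError("starting pair is not observed compatible")
    members = list(start)
    for s in sorted(set(ds.matrix.strains) - set(start)):
        if all(ds.matrix.lookup(s, m) is Compatibility.COMPATIBLE for m in members):
            members.append(s)
    return members


def evidence_graph(ds: Dataset, locus: int) -> nx.Graph:
    """Per-locus graph whose edges are OWE-SOJ SAME relations (locus 0=A, 1=B)."""
    g = nx.Graph()
    g.add_nodes_from(ds.matrix.strains)
    for pk, rels in ds.loci.records.items():
        if rels[locus] is LociRelation.SAME:
            g.add_edge(*pk)
    return g


def _components(graph: nx.Graph) -> dict[str, int]:
    comp: dict[str, int] = {}
    for i, nodes in enumerate(nx.connected_components(graph)):
        for n in nodes:
            comp[n] = i
    return comp


def candidate_alleles(
    strain: str,
    locus: int,
    partial: dict[str, tuple[int, int]],
    ds: Dataset,
    policy: MergePolicy = MergePolicy.EVIDENCE_REQUIRED,
) -> list[int]:
    """Allele labels the strain may take at a locus, given a partial assignment.

    Always ends with one fresh label.  Under EVIDENCE_REQUIRED the existing
    labels offered are those carried by an assigned strain in the same
    SAME-evidence connected component; under FREE all existing labels are
    offered.  Deterministic: existing labels ascending, fresh last.
    """
    existing = {ab[locus] for ab in partial.values()}
    fresh = max(existing, default=0) + 1
    if policy is MergePolicy.FREE:
        return sorted(existing) + [fresh]
    comp = _components(evidence_graph(ds, locus))
    allowed = {
        partial[t][locus]
        for t in partial
        if comp.get(t) == comp.get(strain)
    }
    return sorted(allowed) + [fresh]


def canonicalize(asg: MatingTypeAssignment, strain_order=None) -> MatingTypeAssignment:
    """Relabel classes by first appearance over sorted strain identifiers."""
    return asg.canonical(strain_order)


def detect_suspect_records(result: InferenceResult, ds: Dataset) -> list[tuple[PairKey, str]]:
    """Pairs whose contribution is negative in every co-optimal assignment.

    An observed-incompatible flagged pair is a possible false negative; any
    other flagged pair is labelled inconsistent.  Empty whenever the best
    score equals the maximum achievable score.
    """
    if not result.assignments:
        return []
    neg: Optional[set] = None
    for asg in result.assignments:
        bd = score_assignment(asg, ds)
        negs = {pk for pk, v in bd.per_pair.items() if v < 0}
        neg = negs if neg is None else (neg & negs)
        if not neg:
            return []
    flagged = []
    for pk in sorted(neg):
        obs = ds.matrix.observations.get(pk)
        reason = (
            "possible_false_negative" if obs is Compatibility.INCOMPATIBLE else "inconsistent"
        )
        flagged.append((pk, reason))
    return flagged


def _incompatible_degree(ds: Dataset) -> dict[str, int]:
    deg = {s: 0 for s in ds.matrix.strains}
    for pk, obs in ds.matrix.observations.items():
        if obs is Compatibility.INCOMPATIBLE:
            deg[pk[0]] += 1
            deg[pk[1]] += 1
    return deg


def _classes_connected(labels: dict[str, tuple[int, int]], locus: int, adj: dict[str, set]) -> bool:
    """Every allele class of size >= 2 must be connected in the evidence graph."""
    classes: dict[int, list[str]] = {}
    for s, ab in labels.items():
        classes.setdefault(ab[locus], []).append(s)
    for members in classes.values():
        if len(members) < 2:
            continue
        member_set = set(members)
        seen = {members[0]}
        stack = [members[0]]
        while stack:
            u = stack.pop()
            for v in adj.get(u, ()):
                if v in member_set and v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != len(member_set):
            return False
    return True


def infer_mating_types(ds: Dataset, cfg: Optional[InferenceConfig] = None) -> InferenceResult:
    """Infer all highest-scoring mating-type assignments for a dataset.

    The dataset must pass :func:`mti.model.validate_dataset` with no
    errors.  Returns the best and maximum achievable scores, all co-optimal
    canonical assignments (capped at ``cfg.max_optima``), the number of
    complete candidate assignments examined, and flagged suspect pairs.
    """
    cfg = cfg or InferenceConfig()
    report = validate_dataset(ds)
    if not report.ok:
        raise ValidationError(
            "dataset has validation errors: "
            + "; ".join(f"{code}: {msg}" for code, _, msg in report.errors)
        )
    strains = list(ds.matrix.strains)
    n = len(strains)
    if n == 0:
        raise MTIError("empty dataset")
    policy = cfg.merge_policy
    if policy is MergePolicy.FREE and n > _FREE_POLICY_MAX_STRAINS:
        raise MTIError(
            f"FREE merge policy enumerates the full partition space and is "
            f"guarded to {_FREE_POLICY_MAX_STRAINS} strains (got {n})"
        )

    exps = expectations(ds)
    max_score = sum(pair_max(e) for e in exps.values())

    graphs = (evidence_graph(ds, 0), evidence_graph(ds, 1))
    adj = tuple({s: set(g.adj[s]) for s in g.nodes} for g in graphs)
    comps = tuple(_components(g) for g in graphs)
    has_record = {s for pk in ds.loci.records for s in pk}

    trace: list[str] = []
    if policy is MergePolicy.EVIDENCE_REQUIRED:
        start = select_starting_pair(ds, cfg)
        clique = seed_compatible_clique(ds, start)
        # only evidence-isolated members (singletons in every evidence-consistent
        # assignment) plus the sibling anchor may be fixed without losing optima
        fixed = [s for s in clique if s in start or s not in has_record]
        if cfg.report_trace:
            trace.append(f"starting pair: {start[0]},{start[1]}")
            trace.append(f"compatible sub-population: {','.join(clique)}")
            trace.append(f"fixed strains: {','.join(fixed)}")
    else:
        fixed = []

    deg = _incompatible_degree(ds)
    unresolved = sorted((s for s in strains if s not in fixed), key=lambda s: (-deg[s], s))
    order = fixed + unresolved
    pos = {s: i for i, s in enumerate(order)}

    # expectations keyed by (earlier position, later position)
    exp_pos: dict[int, list[tuple[int, PairExpectation]]] = {i: [] for i in range(n)}
    bucket = [0] * (n + 1)
    for pk, exp in exps.items():
        i, j = sorted((pos[pk[0]], pos[pk[1]]))
        exp_pos[j].append((i, exp))
        bucket[j] += pair_max(exp)
    # rem[d] = best possible total from pairs resolved at position >= d
    rem = [0] * (n + 1)
    for d in range(n - 1, -1, -1):
        rem[d] = rem[d + 1] + bucket[d]

    labels: dict[str, tuple[int, int]] = {}
    row: list[Optional[tuple[int, int]]] = [None] * n
    partial0 = 0
    for k, s in enumerate(fixed):
        lab = (k + 1, k + 1)
        labels[s] = lab
        row[k] = lab
        for i, exp in exp_pos[k]:
            partial0 += pair_contribution(exp, lab, row[i])

    evidence_required = policy is MergePolicy.EVIDENCE_REQUIRED

    best = float("-inf")
    stored: list[dict[str, tuple[int, int]]] = []
    n_opt = 0
    n_enum = 0
    truncated = False
    n_fixed = len(fixed)

    def candidates(d: int, locus: int) -> list[int]:
        s = order[d]
        existing = {row[i][locus] for i in range(d)}
        fresh = max(existing, default=0) + 1
        if not evidence_required:
            return sorted(existing) + [fresh]
        my_comp = comps[locus].get(s)
        allowed = {
            row[i][locus]
            for i in range(d)
            if comps[locus].get(order[i]) == my_comp
        }
        return sorted(allowed) + [fresh]

    def dfs(d: int, partial: int) -> None:
        nonlocal best, stored, n_opt, n_enum, truncated
        if d == n:
            n_enum += 1
            if partial < best:
                return
            if evidence_required and has_record:
                if not (
                    _classes_connected(labels, 0, adj[0])
                    and _classes_connected(labels, 1, adj[1])
                ):
                    return
            if partial > best:
                best = partial
                stored = [dict(labels)]
                n_opt = 1
                truncated = False
            else:
                n_opt += 1
                if len(stored) < cfg.max_optima:
                    stored.append(dict(labels))
                else:
                    truncated = True
            return
        s = order[d]
        pairs_here = exp_pos[d]
        for a in candidates(d, 0):
            for b in candidates(d, 1):
                lab = (a, b)
                delta = 0
                for i, exp in pairs_here:
                    delta += pair_contribution(exp, lab, row[i])
                nxt = partial + delta
                if cfg.prune and nxt + rem[d + 1] < best:
                    continue
                labels[s] = lab
                row[d] = lab
                dfs(d + 1, nxt)
                del labels[s]
                row[d] = None

    dfs(n_fixed, partial0)

    strain_order = sorted(strains)
    canon = [MatingTypeAssignment(d).canonical(strain_order) for d in stored]
    canon.sort(key=lambda a: a.labels(strain_order))
    result = InferenceResult(
        best_score=int(best),
        max_score=max_score,
        assignments=canon,
        n_enumerated=n_enum,
        flagged_pairs=[],
        allele_counts=[a.allele_counts() for a in canon],
        n_optima=n_opt,
        truncated=truncated,
        statistics=summarize_dataset(ds),
        trace=trace,
    )
    result.flagged_pairs = detect_suspect_records(result, ds)
    return result
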