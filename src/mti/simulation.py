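"""Synthetic monokaryon populations and error-injection experiments.

A population is built dikaryon by dikaryon: each dikaryon contributes two
protoplast-derived sibling monokaryons whose true (A, B) allele pairs must
differ at both loci (they coexisted in a fertile dikaryon).  Error-free
observations follow mechanically from the truth: a pair is compatible iff
the strains differ at both loci, and every incompatible pair receives the
OWE-SOJ record implied by the true allele identities.

Two perturbations model the common wet-lab mistakes:

* a *false positive* turns a truly incompatible pair compatible — and its
  OWE-SOJ record is deleted, because a pair scored compatible would never
  have entered the OWE-SOJ assay;
* a *false negative* turns a truly compatible non-sibling pair
  incompatible, with no OWE-SOJ record added, because the assay is only
  performed after an (apparently) failed cross.

:func:`run_error_experiment` sweeps error type and count over replicates
and records how the optimum, its score and the suspect-pair detection
respond.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Union

import numpy as np
import pandas as pd

from .model import (
    Compatibility,
    CompatibilityMatrix,
    Dataset,
    LociConsistencyTable,
    LociRelation,
    MTIError,
    MatingTypeAssignment,
    MergePolicy,
    PairKey,
    ParentTable,
    pair_key,
)
from .scoring import score_assignment
from .inference import InferenceConfig, infer_mating_types

__all__ = [
    "PopulationConfig",
    "TruthAssignment",
    "PerturbationRecord",
    "generate_population",
    "paired_sharing_population",
    "derive_observations",
    "inject_errors",
    "run_error_experiment",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Shape of a synthetic population.

    ``a_pool``/``b_pool`` are the numbers of distinct alleles drawn from at
    each locus; pools smaller than twice the dikaryon count make
    cross-dikaryon allele sharing (hence incompatible pairs) likely.  With
    ``distinct=True`` every strain receives unique alleles at both loci
    (requires pools >= 2 * n_dikaryons), giving a fully compatible matrix.
    """

    n_dikaryons: int = 15
    a_pool: int = 30
    b_pool: int = 30
    seed: int = 0
    distinct: bool = False

    def __post_init__(self) -> None:
        if self.n_dikaryons < 1:
            raise MTIError("need at least one dikaryon")
        if self.a_pool < 2 or self.b_pool < 2:
            raise MTIError("allele pools must hold at least two alleles")
        if self.distinct and (
            self.a_pool < 2 * self.n_dikaryons or self.b_pool < 2 * self.n_dikaryons
        ):
            raise MTIError("distinct draw mode needs pools >= 2 * n_dikaryons")


@dataclass(frozen=True)
class TruthAssignment:
    """Ground-truth mating types plus the parent table they came with."""

    assignment: MatingTypeAssignment
    parents: ParentTable

    def __post_init__(self) -> None:
        for pk in self.parents.sibling_pairs:
            a, b = self.assignment.alleles[pk[0]], self.assignment.alleles[pk[1]]
            if a[0] == b[0] or a[1] == b[1]:
                raise MTIError(
                    f"sibling pair {pk} shares an allele; dikaryon nuclei must differ at both loci"
                )

    @property
    def strains(self) -> tuple[str, ...]:
        return self.parents.strains


@dataclass(frozen=True)
class PerturbationRecord:
    """Which pairs were flipped by :func:`inject_errors`."""

    injected_fp: tuple[PairKey, ...]
    injected_fn: tuple[PairKey, ...]


def _strain_names(n_dikaryons: int) -> list[tuple[str, str]]:
    width = max(2, len(str(2 * n_dikaryons)))
    out = []
    for k in range(n_dikaryons):
        dik = f"D{k + 1:0{width}d}"
        out.append((f"m{2 * k + 1:0{width}d}", dik))
        out.append((f"m{2 * k + 2:0{width}d}", dik))
    return out


def generate_population(cfg: PopulationConfig) -> TruthAssignment:
    """Draw a ground-truth population from the configured allele pools."""
    rng = np.random.default_rng(cfg.seed)
    names = _strain_names(cfg.n_dikaryons)
    parents = ParentTable(tuple(names))
    alleles: dict[str, tuple[int, int]] = {}
    if cfg.distinct:
        a_labels = rng.permutation(cfg.a_pool)[: 2 * cfg.n_dikaryons] + 1
        b_labels = rng.permutation(cfg.b_pool)[: 2 * cfg.n_dikaryons] + 1
        for i, (strain, _) in enumerate(names):
            alleles[strain] = (int(a_labels[i]), int(b_labels[i]))
    else:
        for k in range(cfg.n_dikaryons):
            s1, s2 = names[2 * k][0], names[2 * k + 1][0]
            a1 = int(rng.integers(1, cfg.a_pool + 1))
            b1 = int(rng.integers(1, cfg.b_pool + 1))
            while True:
                a2 = int(rng.integers(1, cfg.a_pool + 1))
                b2 = int(rng.integers(1, cfg.b_pool + 1))
                if a2 != a1 and b2 != b1:
                    break
            alleles[s1] = (a1, b1)
            alleles[s2] = (a2, b2)
    return TruthAssignment(MatingTypeAssignment(alleles), parents)


def paired_sharing_population(
    n_dikaryons: int = 15,
    n_a_shared: int = 6,
    n_b_shared: int = 4,
    seed: int = 0,
) -> TruthAssignment:
    """All-distinct truth with disjoint two-strain allele-sharing classes.

    ``n_a_shared`` disjoint non-sibling strain pairs are made to share an A
    allele and ``n_b_shared`` further pairs a B allele, so every sharing
    class has exactly two members and every strain belongs to at most one.
    The defaults give a 30-strain population with 10 incompatible pairs and
    24 A / 26 B alleles — the regime observed in real monokaryon panels,
    where most strains are fully compatible and incompatibilities come in
    isolated pairs.
    """
    n_pairs = n_a_shared + n_b_shared
    if 2 * n_pairs > 2 * n_dikaryons:
        raise MTIError("too many sharing pairs for the population size")
    rng = np.random.default_rng(seed)
    base = generate_population(
        PopulationConfig(
            n_dikaryons=n_dikaryons,
            a_pool=2 * n_dikaryons,
            b_pool=2 * n_dikaryons,
            seed=int(rng.integers(0, 2 ** 31)),
            distinct=True,
        )
    )
    strains = list(base.strains)
    sibs = base.parents.sibling_pairs
    for _ in range(1000):
        picked = list(rng.permutation(strains)[: 2 * n_pairs])
        pairs = [pair_key(picked[2 * i], picked[2 * i + 1]) for i in range(n_pairs)]
        if all(pk not in sibs for pk in pairs):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise MTIError("could not place non-sibling sharing pairs")
    alleles = dict(base.assignment.alleles)
    for i, (s, t) in enumerate(pairs):
        if i < n_a_shared:
            alleles[t] = (alleles[s][0], alleles[t][1])
        else:
            alleles[t] = (alleles[t][0], alleles[s][1])
    return TruthAssignment(MatingTypeAssignment(alleles), base.parents)


def derive_observations(truth: TruthAssignment) -> Dataset:
    """Error-free complete observations implied by a ground truth.

    Every pair is compatible iff the strains differ at both loci; every
    incompatible pair carries the OWE-SOJ record implied by the true
    identities.  No pair is missing.
    """
    alleles = truth.assignment.alleles
    strains = truth.strains
    obs: dict[PairKey, Compatibility] = {}
    records: dict[PairKey, tuple[LociRelation, LociRelation]] = {}
    ordered = sorted(strains)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            pk = (a, b)
            same_a = alleles[a][0] == alleles[b][0]
            same_b = alleles[a][1] == alleles[b][1]
            if same_a or same_b:
                obs[pk] = Compatibility.INCOMPATIBLE
                records[pk] = (
                    LociRelation.SAME if same_a else LociRelation.DIFFERENT,
                    LociRelation.SAME if same_b else LociRelation.DIFFERENT,
                )
            else:
                obs[pk] = Compatibility.COMPATIBLE
    return Dataset(
        parents=truth.parents,
        matrix=CompatibilityMatrix(strains=strains, observations=obs),
        loci=LociConsistencyTable(records),
    )


def inject_errors(
    ds: Dataset,
    truth: TruthAssignment,
    n_fp: int = 0,
    n_fn: int = 0,
    seed: int = 0,
) -> tuple[Dataset, PerturbationRecord]:
    """Flip pairs in the compatibility matrix, reproducibly from the seed.

    False positives pick truly incompatible pairs uniformly without
    replacement, record them compatible and delete their OWE-SOJ record.
    False negatives pick truly compatible non-sibling pairs, record them
    incompatible and add no record.
    """
    alleles = truth.assignment.alleles
    sibs = truth.parents.sibling_pairs
    truly_incompatible = sorted(
        pk
        for pk in ds.matrix.observations
        if alleles[pk[0]][0] == alleles[pk[1]][0] or alleles[pk[0]][1] == alleles[pk[1]][1]
    )
    truly_compatible = sorted(
        pk
        for pk in ds.matrix.observations
        if pk not in sibs
        and alleles[pk[0]][0] != alleles[pk[1]][0]
        and alleles[pk[0]][1] != alleles[pk[1]][1]
    )
    if n_fp > len(truly_incompatible):
        raise MTIError(
            f"requested {n_fp} false positives but only "
            f"{len(truly_incompatible)} truly incompatible pairs exist"
        )
    if n_fn > len(truly_compatible):
        raise MTIError(
            f"requested {n_fn} false negatives but only "
            f"{len(truly_compatible)} eligible truly compatible pairs exist"
        )
    rng = np.random.default_rng(seed)
    fp = [truly_incompatible[i] for i in rng.choice(len(truly_incompatible), n_fp, replace=False)] if n_fp else []
    fn = [truly_compatible[i] for i in rng.choice(len(truly_compatible), n_fn, replace=False)] if n_fn else []
    obs = dict(ds.matrix.observations)
    records = dict(ds.loci.records)
    for pk in fp:
        obs[pk] = Compatibility.COMPATIBLE
        records.pop(pk, None)
    for pk in fn:
        obs[pk] = Compatibility.INCOMPATIBLE
    perturbed = Dataset(
        parents=ds.parents,
        matrix=CompatibilityMatrix(strains=ds.matrix.strains, observations=obs),
        loci=LociConsistencyTable(records),
    )
    return perturbed, PerturbationRecord(injected_fp=tuple(sorted(fp)), injected_fn=tuple(sorted(fn)))


PopulationFactory = Callable[[int], TruthAssignment]


def run_error_experiment(
    population: Union[PopulationConfig, PopulationFactory],
    k_values: Iterable[int] = (1, 2, 3, 4, 5),
    reps: int = 50,
    policy: MergePolicy = MergePolicy.EVIDENCE_REQUIRED,
    seed: int = 0,
    error_types: Iterable[str] = ("FP", "FN"),
    max_optima: int = 100,
) -> pd.DataFrame:
    """Sweep error type and count over replicates and tabulate the outcomes.

    ``population`` is either a :class:`PopulationConfig` (regenerated per
    replicate with a derived seed) or a callable ``seed -> TruthAssignment``.
    Each row records the scores, the number of co-optimal assignments,
    whether some co-optimal assignment equals the canonical truth, and
    whether the flagged suspect pairs exactly match the injected set.
    """
    error_types = list(error_types)
    for et in error_types:
        if et not in {"FP", "FN"}:
            raise MTIError(f"unknown error type {et!r}")
    rows = []
    for et_idx, et in enumerate(error_types):
        for k in k_values:
            for rep in range(reps):
                ss = np.random.SeedSequence([seed, et_idx, int(k), rep])
                pop_seed, inj_seed = (int(x % 2 ** 31) for x in ss.generate_state(2))
                if isinstance(population, PopulationConfig):
                    cfg = PopulationConfig(
                        n_dikaryons=population.n_dikaryons,
                        a_pool=population.a_pool,
                        b_pool=population.b_pool,
                        seed=pop_seed,
                        distinct=population.distinct,
                    )
                    truth = generate_population(cfg)
                else:
                    truth = population(pop_seed)
                clean = derive_observations(truth)
                perturbed, record = inject_errors(
                    clean,
                    truth,
                    n_fp=k if et == "FP" else 0,
                    n_fn=k if et == "FN" else 0,
                    seed=inj_seed,
                )
                result = infer_mating_types(
                    perturbed,
                    InferenceConfig(merge_policy=policy, max_optima=max_optima),
                )
                strain_order = sorted(truth.strains)
                canon_truth = truth.assignment.canonical(strain_order)
                truth_labels = canon_truth.labels(strain_order)
                truth_recovered = any(
                    a.labels(strain_order) == truth_labels for a in result.assignments
                )
                injected = set(record.injected_fp) | set(record.injected_fn)
                flagged = {pk for pk, _ in result.flagged_pairs}
                rows.append(
                    {
                        "error_type": et,
                        "k": int(k),
                        "replicate": rep,
                        "best_score": result.best_score,
                        "max_score": result.max_score,
                        "truth_score": score_assignment(canon_truth, perturbed).total,
                        "n_optima": result.n_optima,
                        "truth_recovered": truth_recovered,
                        "detection_exact": flagged == injected,
                    }
                )
    return pd.DataFrame(rows)
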