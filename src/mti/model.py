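"""Domain model for tetrapolar mating-type inference.

In a tetrapolar basidiomycete two unlinked multiallelic loci, A and B,
control sexual compatibility: a cross between two monokaryons is fertile
(produces clamp connections) only when the partners carry different alleles
at *both* loci.  Protoplasting a dikaryon yields two sibling monokaryons
that by construction differ at both loci.

Three observation tables describe a monokaryon population:

* a parent table mapping every monokaryon to the dikaryon it was isolated
  from (two strains sharing a dikaryon form a *sibling pair*);
* a symmetric compatibility matrix holding the clamp-connection outcome of
  every tested unordered pair (compatible / incompatible / missing);
* an A/B loci consistency table for incompatible pairs, derived from
  OWE-SOJ plate assays, recording per pair whether the A loci and the B
  loci are the same or different.

This module defines those containers, their invariants, and the dataset
error scan run before inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Optional

__all__ = [
    "MTIError",
    "ParseError",
    "ValidationError",
    "Compatibility",
    "LociRelation",
    "MergePolicy",
    "PairKey",
    "pair_key",
    "OWE_SOJ_TOKENS",
    "relations_to_token",
    "ParentTable",
    "CompatibilityMatrix",
    "LociConsistencyTable",
    "Dataset",
    "MatingTypeAssignment",
    "ValidationReport",
    "validate_dataset",
]


class MTIError(Exception):
    """Base class for all package errors."""


class ParseError(MTIError):
    """An input table violates its format contract."""


class ValidationError(MTIError):
    """A dataset with validation errors was passed to inference."""


class Compatibility(Enum):
    """Clamp-connection outcome of one pairwise cross."""

    COMPATIBLE = "compatible"
    INCOMPATIBLE = "incompatible"


class LociRelation(Enum):
    """Relation between the alleles of two strains at one locus."""

    SAME = "same"
    DIFFERENT = "different"
    UNKNOWN = "unknown"


class MergePolicy(Enum):
    """How freely the search may propose shared alleles.

    EVIDENCE_REQUIRED: two strains may share an allele only when OWE-SOJ
    SAME evidence connects them at that locus.  FREE: any allele sharing
    may be proposed (exhaustive partition space; kept for cross-checks
    against the brute-force reference).
    """

    EVIDENCE_REQUIRED = "evidence"
    FREE = "free"


#: Canonically ordered unordered strain pair.
PairKey = tuple


def pair_key(a: str, b: str) -> PairKey:
    """Canonical (lexicographically ordered) key for an unordered pair."""
    if a == b:
        raise MTIError(f"self pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


# ASCII encodings of the OWE-SOJ outcomes; the UTF-8 spellings used in
# lab notebooks are accepted as aliases.
OWE_SOJ_TOKENS: dict[str, tuple[LociRelation, LociRelation]] = {
    "AeqBne": (LociRelation.SAME, LociRelation.DIFFERENT),
    "AneBeq": (LociRelation.DIFFERENT, LociRelation.SAME),
    "AeqBeq": (LociRelation.SAME, LociRelation.SAME),
    "A=B≠": (LociRelation.SAME, LociRelation.DIFFERENT),
    "A≠B=": (LociRelation.DIFFERENT, LociRelation.SAME),
    "A=B=": (LociRelation.SAME, LociRelation.SAME),
}

_RELATIONS_TO_TOKEN = {
    (LociRelation.SAME, LociRelation.DIFFERENT): "AeqBne",
    (LociRelation.DIFFERENT, LociRelation.SAME): "AneBeq",
    (LociRelation.SAME, LociRelation.SAME): "AeqBeq",
}


def relations_to_token(a_rel: LociRelation, b_rel: LociRelation) -> str:
    """ASCII OWE-SOJ token for a (A-relation, B-relation) record."""
    try:
        return _RELATIONS_TO_TOKEN[(a_rel, b_rel)]
    except KeyError:
        raise MTIError(f"no OWE-SOJ token for relations ({a_rel}, {b_rel})")


def _check_strain_id(s: str) -> str:
    if not isinstance(s, str) or not s or s != s.strip() or any(c.isspace() for c in s):
        raise MTIError(f"invalid strain id: {s!r}")
    return s


@dataclass(frozen=True)
class ParentTable:
    """Monokaryon-to-dikaryon parentage; defines sibling pairs."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple((str(s), str(d)) for s, d in self.entries))
        seen: set[str] = set()
        per_dik: dict[str, int] = {}
        for strain, dik in self.entries:
            _check_strain_id(strain)
            if not dik or any(c.isspace() for c in dik):
                raise MTIError(f"invalid dikaryon id: {dik!r}")
            if strain in seen:
                raise MTIError(f"duplicate strain: {strain!r}")
            seen.add(strain)
            per_dik[dik] = per_dik.get(dik, 0) + 1
            if per_dik[dik] > 2:
                raise MTIError(f"dikaryon {dik!r} has more than two monokaryons")

    @cached_property
    def strains(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.entries)

    @cached_property
    def dikaryons(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for strain, dik in self.entries:
            out.setdefault(dik, []).append(strain)
        return {d: tuple(ss) for d, ss in out.items()}

    @cached_property
    def dikaryon_of(self) -> dict[str, str]:
        return {s: d for s, d in self.entries}

    @cached_property
    def sibling_pairs(self) -> frozenset[PairKey]:
        return frozenset(
            pair_key(*ss) for ss in self.dikaryons.values() if len(ss) == 2
        )

    def are_siblings(self, a: str, b: str) -> bool:
        return pair_key(a, b) in self.sibling_pairs


@dataclass
class CompatibilityMatrix:
    """Symmetric pairwise cross outcomes; pairs absent from the map are missing."""

    strains: tuple[str, ...]
    observations: dict[PairKey, Compatibility]

    def __post_init__(self) -> None:
        self.strains = tuple(self.strains)
        known = set(self.strains)
        if len(known) != len(self.strains):
            raise MTIError("duplicate strain in matrix strain list")
        for pk in self.observations:
            a, b = pk
            if pk != pair_key(a, b):
                raise MTIError(f"non-canonical pair key: {pk!r}")
            if a not in known or b not in known:
                raise MTIError(f"pair {pk!r} references unknown strain")

    def lookup(self, a: str, b: str) -> Optional[Compatibility]:
        """Order-independent observation lookup; None when untested."""
        return self.observations.get(pair_key(a, b))

    def all_pairs(self) -> Iterator[PairKey]:
        for a, b in combinations(sorted(self.strains), 2):
            yield (a, b)

    def missing_pairs(self) -> list[PairKey]:
        return [pk for pk in self.all_pairs() if pk not in self.observations]


@dataclass
class LociConsistencyTable:
    """Per incompatible pair, the OWE-SOJ A/B relations."""

    records: dict[PairKey, tuple[LociRelation, LociRelation]]

    def __post_init__(self) -> None:
        for pk, (a_rel, b_rel) in self.records.items():
            if pk != pair_key(*pk):
                raise MTIError(f"non-canonical pair key: {pk!r}")
            for rel in (a_rel, b_rel):
                if not isinstance(rel, LociRelation) or rel is LociRelation.UNKNOWN:
                    raise MTIError(f"loci record {pk!r} has non-definite relation {rel!r}")

    def lookup(self, a: str, b: str) -> Optional[tuple[LociRelation, LociRelation]]:
        return self.records.get(pair_key(a, b))


@dataclass
class Dataset:
    """Parent table + compatibility matrix + loci consistency table.

    The constructor is deliberately permissive so that inconsistent inputs
    can be assembled and then reported by :func:`validate_dataset`; only
    structurally impossible objects are rejected by the member types.
    """

    parents: ParentTable
    matrix: CompatibilityMatrix
    loci: LociConsistencyTable = field(default_factory=lambda: LociConsistencyTable({}))

    @property
    def strains(self) -> tuple[str, ...]:
        return self.matrix.strains

    @property
    def sibling_pairs(self) -> frozenset[PairKey]:
        present = set(self.matrix.strains)
        return frozenset(
            pk for pk in self.parents.sibling_pairs if pk[0] in present and pk[1] in present
        )


@dataclass(frozen=True)
class MatingTypeAssignment:
    """Per-strain (A-allele, B-allele) labels.

    Allele labels are arbitrary identifiers of equivalence classes: two
    assignments are equivalent iff they induce the same partition of
    strains at each locus.  :meth:`canonical` relabels classes by first
    appearance over strains in sorted identifier order (restricted-growth
    labelling), so equivalent assignments share one canonical form.
    """

    alleles: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "alleles", {s: (int(a), int(b)) for s, (a, b) in dict(self.alleles).items()}
        )

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(sorted(self.alleles))

    def labels(self, strain_order: Optional[Iterable[str]] = None) -> tuple[tuple[int, int], ...]:
        order = list(strain_order) if strain_order is not None else list(self.strains)
        return tuple(self.alleles[s] for s in order)

    def canonical(self, strain_order: Optional[Iterable[str]] = None) -> "MatingTypeAssignment":
        order = list(strain_order) if strain_order is not None else list(self.strains)
        if set(order) != set(self.alleles):
            raise MTIError("canonicalization requires a full assignment over the given strains")
        maps: tuple[dict[int, int], dict[int, int]] = ({}, {})
        out: dict[str, tuple[int, int]] = {}
        for s in order:
            pair = []
            for locus in (0, 1):
                lab = self.alleles[s][locus]
                m = maps[locus]
                if lab not in m:
                    m[lab] = len(m) + 1
                pair.append(m[lab])
            out[s] = (pair[0], pair[1])
        return MatingTypeAssignment(out)

    def allele_counts(self) -> tuple[int, int]:
        """Number of distinct classes at the A and B locus."""
        return (
            len({ab[0] for ab in self.alleles.values()}),
            len({ab[1] for ab in self.alleles.values()}),
        )

    def mating_type(self, strain: str) -> str:
        a, b = self.alleles[strain]
        return f"A{a}B{b}"

    def same_at(self, a: str, b: str, locus: int) -> bool:
        return self.alleles[a][locus] == self.alleles[b][locus]


@dataclass
class ValidationReport:
    """Outcome of the dataset error scan.

    ``errors`` block inference; ``warnings`` do not.  Each item is a
    ``(code, subject, message)`` triple where subject is a strain id or a
    canonical pair key.
    """

    errors: list[tuple[str, object, str]] = field(default_factory=list)
    warnings: list[tuple[str, object, str]] = field(default_factory=list)
    missing_pairs: list[PairKey] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Scan a dataset for input errors before inference.

    Errors: matrix strains absent from the parent table; sibling pairs
    recorded incompatible (same-dikaryon pairs are inherently compatible);
    loci records whose relations are both DIFFERENT (which would imply
    compatibility); loci records for pairs not observed incompatible.
    Warnings: incompatible pairs lacking a loci record.  ``missing_pairs``
    lists every unordered pair with no observation.
    """
    rep = ValidationReport()
    known = set(ds.parents.strains)
    for s in ds.matrix.strains:
        if s not in known:
            rep.errors.append(("unknown_strain", s, f"strain {s!r} missing from parent table"))
    sibs = ds.sibling_pairs
    for pk, obs in sorted(ds.matrix.observations.items()):
        if obs is Compatibility.INCOMPATIBLE and pk in sibs:
            rep.errors.append(
                ("sibling_incompatible", pk,
                 f"sibling pair {pk} recorded incompatible; same-dikaryon pairs are inherently compatible")
            )
    for pk, (a_rel, b_rel) in sorted(ds.loci.records.items()):
        if a_rel is LociRelation.DIFFERENT and b_rel is LociRelation.DIFFERENT:
            rep.errors.append(
                ("loci_both_different", pk,
                 f"loci record {pk} marks both loci different, which would imply compatibility")
            )
        if ds.matrix.observations.get(pk) is not Compatibility.INCOMPATIBLE:
            rep.errors.append(
                ("loci_record_not_incompatible", pk,
                 f"loci record for pair {pk} that is not observed incompatible")
            )
    for pk, obs in sorted(ds.matrix.observations.items()):
        if obs is Compatibility.INCOMPATIBLE and pk not in ds.loci.records:
            rep.warnings.append(
                ("missing_loci_record", pk, f"incompatible pair {pk} has no OWE-SOJ record")
            )
    rep.missing_pairs = ds.matrix.missing_pairs()
    return rep
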