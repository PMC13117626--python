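"""Hybridization-experiment summary statistics."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .model import Compatibility, Dataset, MTIError

__all__ = ["DatasetSummary", "count_pairs", "summarize_dataset"]


def count_pairs(n: int) -> int:
    """Number of unordered pairs among n strains: n(n-1)/2."""
    if n < 0:
        raise MTIError("strain count must be non-negative")
    return n * (n - 1) // 2


@dataclass(frozen=True)
class DatasetSummary:
    """Counts describing one hybridization dataset.

    Sibling pairs are recorded compatible without experimental testing, so
    they count toward ``n_compatible_total`` but not toward the tested
    counts.  ``compatibility_rate`` uses observed (non-missing) pairs as
    its denominator.
    """

    n_strains: int
    n_dikaryons: int
    n_pairs_total: int
    n_sibling_pairs: int
    n_tested_pairs: int
    n_compatible_total: int
    n_compatible_tested: int
    n_incompatible: int
    n_missing: int
    compatibility_rate: float
    n_loci_records: int

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_dataset(ds: Dataset) -> DatasetSummary:
    """Compute all summary counts for a dataset."""
    strains = ds.matrix.strains
    n = len(strains)
    total = count_pairs(n)
    sibs = ds.sibling_pairs
    obs = ds.matrix.observations
    n_compat_total = sum(1 for v in obs.values() if v is Compatibility.COMPATIBLE)
    n_incompat = sum(1 for v in obs.values() if v is Compatibility.INCOMPATIBLE)
    n_missing = total - len(obs)
    tested = [pk for pk in obs if pk not in sibs]
    n_compat_tested = sum(1 for pk in tested if obs[pk] is Compatibility.COMPATIBLE)
    rate = (n_compat_total / len(obs)) if obs else 0.0
    return DatasetSummary(
        n_strains=n,
        n_dikaryons=len(ds.parents.dikaryons) if ds.parents.entries else 0,
        n_pairs_total=total,
        n_sibling_pairs=len(sibs),
        n_tested_pairs=len(tested),
        n_compatible_total=n_compat_total,
        n_compatible_tested=n_compat_tested,
        n_incompatible=n_incompat,
        n_missing=n_missing,
        compatibility_rate=rate,
        n_loci_records=len(ds.loci.records),
    )
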