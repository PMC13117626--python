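# mti — mating-type inference for tetrapolar fungi

Breeding and population-genetic work on tetrapolar basidiomycetes
(*Flammulina velutipes*, *Lentinula edodes*, and most other cultivated
mushrooms) starts with knowing the mating type of every monokaryon in a
panel. Mating type is controlled by two unlinked multiallelic loci, A and
B: a cross is fertile — clamp connections form — only when the partners
differ at **both** loci. The raw data are a pairwise compatibility matrix
from hybridization experiments and, for incompatible pairs, an OWE-SOJ
plate assay that tells whether the pair shares the A locus (A=B≠), the B
locus (A≠B=), or both. Reading an (A, B) allele assignment for dozens of
strains off those tables by hand takes days and is error-prone; `mti`
does it exactly, in seconds, and also says which records look wrong.

## The method

An assignment gives every strain an (A-allele, B-allele) label pair —
equivalently one set partition of the strains per locus. Each observed
pair is scored against the assignment:

* compatible pair → the strains must differ at A **and** at B (two ±1
  checks);
* incompatible pair with an OWE-SOJ record → the per-locus relations must
  match the record (two ±1 checks);
* incompatible pair without a record → one ±1 check that the assignment
  predicts incompatibility (shared allele at A or B);
* untested pair → 0.

The maximum achievable score for a complete, fully informed panel of *n*
strains is therefore 2·C(n, 2) — **870 for 30 strains** — and an
assignment attains it iff it satisfies every observation. Inference
searches for *all* maximum-score assignments: a sibling pair (two
monokaryons protoplasted from one dikaryon, necessarily A₁B₁ / A₂B₂)
anchors the labelling, a greedy pairwise-compatible sub-population is
fixed with fresh distinct alleles, and an exact branch-and-bound
traverses the remaining strains, proposing allele merges only where
OWE-SOJ SAME evidence supports them and pruning any branch that can no
longer reach the incumbent score. Pairs that score negatively in every
co-optimal assignment are flagged as suspect records — in practice these
are false-negative crosses. A brute-force enumerator over all partition
pairs (`mti.oracle`) provides an independent reference for small panels,
and `mti.simulation` generates synthetic populations and injects
false-positive/false-negative errors to study how such mistakes distort
inference.

## Worked example

Simulate a 30-strain panel (15 dikaryons) in the regime of a real
*F. velutipes* panel — 10 isolated incompatible pairs — with one injected
false-negative record, then infer:

```bash
mti simulate --dikaryons 15 --mode paired --fn 1 --seed 7 --out fv
mti stats --parents fv_parents.csv --matrix fv_matrix.csv --loci fv_loci.csv
mti infer --parents fv_parents.csv --matrix fv_matrix.csv --loci fv_loci.csv --out run
```

`stats` prints (abridged):

```
n_strains: 30
n_pairs_total: 435
n_sibling_pairs: 15
n_tested_pairs: 420
n_incompatible: 11
n_loci_records: 10
```

435 pairwise combinations, of which 15 sibling pairs are recorded
compatible without testing, leaving 420 performed crosses; 11
incompatible records (10 real + 1 injected error). `infer` prints:

```
best score: 867 / max 869
co-optimal combinations: 1
candidate combinations examined: 1
alleles in combination 1: 24 at A, 26 at B
  m01: A1B1
  m02: A2B2
  ...
suspect pair m23,m25: possible_false_negative
```

The unique optimum falls 2 short of the 869 achievable points — the
signature of a single inconsistent record — and the flagged pair is
exactly the injected false negative. On the clean dataset the same
command reports `best score: 870 / max 870` with nothing flagged. The
full result set is written to `run_assignments.csv` (one row per strain
per co-optimal combination) and `run_result.json` (scores, counts,
flagged pairs, statistics).

The error-injection experiments (`--reps N`) reproduce the asymmetry
between the two error types: a single false negative leaves the true
combination as the unique optimum and is pinpointed exactly, while any
false positive yields a *perfect-scoring wrong* optimum and is
fundamentally undetectable from the compatibility data alone.

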