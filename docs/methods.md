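# Methods

## The entrapment benchmark model

A search database is the concatenation of three labeled parts: *sample*
targets (the proteome actually measured), *entrapment* targets (proteins
known to be absent from the sample), and *decoys* (the reversal of every
target). Accepted hits at a score threshold decompose into `N_target`
(sample- or entrapment-labeled) and `N_decoy`; `N_trap` counts the
entrapment-labeled members of the accepted target set. Two standard FDR
estimators are provided — `N_decoy / N_target` for a separate
target/decoy search and `2·N_decoy / (N_target + N_decoy)` for a
concatenated one — and the false match rate is `FMR = N_trap /
N_target`. Entrapment-labeled hits count as targets in FDR estimation:
they are target-database hits by construction, and the FMR measures how
many accepted targets are observably wrong.

The method is informative when (a) the entrapment side is much larger
than the sample side, so that nearly all random target matches land in
entrapment sequences, and (b) the two sides share almost no tryptic
peptides, so that a true sample peptide practically never maps to an
entrapment protein. The `overlap_report` audit quantifies (b); for the
published benchmark databases the shared/sample peptide ratios are
0.06–0.21%.

## Labeling and precedence rules

A PSM's label is a pure function of its accession set: any non-decoy
sample accession makes it a sample identification (shared sample/
entrapment matches count as sample); otherwise any non-decoy entrapment
accession makes it entrapment; only all-decoy sets are decoys. The same
sample-over-entrapment-over-decoy precedence is reused when peptides
aggregate the accessions of their supporting PSMs and when protein
groups aggregate their peptides, so the three labels partition every
level. Target-over-decoy precedence for mixed target/decoy mappings is
the usual concatenated-search convention.

## q-values and thresholding

Records are ranked by descending score (lower-is-better scores are
negated on input, a monotone map). At each distinct score value the
running FDR uses the cumulative target and decoy counts at the end of
the tie block, and the q-value is the minimum running FDR at or below
that rank, which makes q non-decreasing down the ranking. Tied scores
are admitted or rejected together: a threshold is a property of the
score value, never of an arbitrary sort order. `filter_at_fdr` accepts
all targets with q ≤ α, reports the decoys above the same threshold
(needed to keep pooled subsets estimable downstream), and the FMR of the
accepted set. Degenerate conventions: 0/0 is reported as 0 rather than
raised; an empty accepted set has threshold +∞.

## Peptide and protein rollup

Peptides collapse PSMs by exact bare-sequence identity (modification
annotations are stripped on input so engines are comparable; I/L are
kept distinct). Peptides shorter than 7 residues are dropped by default.
Protein inference is greedy parsimony: repeatedly pick the accession
covering the most unexplained peptides (ties by accession order), and
merge accessions with identical full evidence sets into one group, so
the accepted peptides are partitioned. The group score is its best
peptide score, and group-level FDR is plain target-decoy counting on
groups. This is deliberately simpler than hypergeometric protein-FDR
corrections; protein-level numbers from this package are comparable
within the package, not with tools that apply such corrections.

## Multi-engine integration

Each engine's α-filtered output (accepted targets plus the decoys above
its threshold) is pooled on exact (spectrum id, peptide) keys; k is the
number of engines carrying a pair, and the pools for each k form
agreement subgroups with their own sub-FDR and sub-FMR. Engines agree
on correct matches far more often than on random ones, so the error
concentrates in low-k subgroups; filtering every subgroup to sub-FDR ≤ α
on a consensus score and taking the union restores overall control
(if every subgroup's `D/T ≤ α`, the pooled `ΣD/ΣT ≤ α`) while retaining
the high-k matches a single engine would have missed. The default
consensus score is minus the best per-engine q-value; a mean-rank
alternative is exposed. Cross-engine spectrum-id normalization is the
caller's responsibility.

## The simulator and what it does (not) show

`synthetic_data` generates random protein sequences over a uniform
20-letter alphabet, digests them, and emits per-spectrum, per-engine
PSMs from a two-component score mixture. Defaults (the study conditions
used throughout the tests): 200 sample and 2,000 entrapment proteins
(the 1:10 ratio of the benchmark construction), mean length 300, 20,000
spectra, 5 engines, `pi_correct = 0.5` of spectra with a correct match
available, per-engine detection probabilities 0.9 (correct) and 0.8
(incorrect), and unit-variance normal scores with means 3 (correct) and
0 (incorrect). Correct matches carry a per-spectrum latent N(0, 1) score
shift shared across engines, which is what makes engine agreement
informative; random matches are drawn independently per engine, land on
the decoy half of the search space with probability 1/2 (targets and
decoys are equal-sized by construction), and otherwise on a target
peptide drawn uniformly from the pooled sample+entrapment digest, i.e.
in proportion to peptide content.

Under this generator the separate-search estimator `N_decoy/N_target` is
the consistent estimator of the realized false-discovery proportion
(random matches split 1:1 between decoy and target), so the calibration
and integration checks use it; the concatenated form remains the library
default for real concatenated searches, where accepted decoys are
conventionally kept in the denominator. Likewise the expected FMR of an
accepted set is FDP × (entrapment share of the target peptide pool),
which the tests verify over 20 replicates at 10% relative tolerance on
the means — a budget chosen from the Monte-Carlo error of ~1,600
entrapment hits per 20-replicate average.

What the simulator does **not** emulate: real engine score laws and
their inter-engine dependence structure, shared fragmentation biases
that make engines agree on *wrong* answers, modification-bearing
peptides, I/L ambiguity, homologous sequences between sample and
entrapment sides, and spectrum-level effects (mass error, retention
time). Passing the synthetic checks therefore shows the estimators and
the integration logic are implemented correctly and are calibrated under
the stated assumptions; it does not show that any particular real
engine's scores are calibrated.

## Numerical and design choices

- Digestion cleaves after Lys/Arg with ≤ 1 missed cleavage and a
  7-residue length floor by default; the proline suppression rule is off
  by default and available as `proline_rule`. Non-standard residues are
  kept verbatim, warned about, and never cleaved.
- Entrapment expansion ("randomize N times") is per-sequence residue
  shuffling of independent copies, copy 1 being the originals and each
  further copy suffixed into a fresh accession; record-order shuffling
  alone could not create new sequences. Shuffling preserves length and
  residue multiset and is deterministic per seed.
- Accession prefixes default to `trap_` (entrapment) and `rev_` (decoy)
  and are configurable; they are applied before any labeling.
- The overlap percentage is reported rounded to 3 decimals (matching the
  convention of published tables) with the raw ratio also available.
- One best PSM per spectrum per engine is enforced on input; duplicate
  spectrum rows are resolved by score and logged.
- Problem sizes in the test suite and acceptance script (20,000-spectrum
  simulations, 20 replicates for the FMR average, 1,000 sequences for
  the digestion oracle) were chosen so the full validation runs in a few
  minutes on one CPU while keeping binomial confidence intervals tight
  enough to be meaningful.

## Known limitations

- Protein-level FMR/FDR is not numerically comparable to corrected
  protein-FDR pipelines (see rollup above).
- The q-value filter assumes scores are comparable across all records of
  one list; mixing engines in one list without rescoring is not
  supported (that is what the integrator is for).
- pepXML/mzIdentML are not parsed natively; result tables must be
  delimited text with a configurable column map.
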