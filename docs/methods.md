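# Methods

## The problem and the model

Two protein lineages that diverged before the emergence of their modern
folds can still share a short contiguous element — a *theme* — if that
element predates the divergence. The detectable signature is asymmetric
conservation: a ~20–30 residue segment whose cross-lineage alignment is
far stronger than its amino-acid composition explains, flanked by
regions with no detectable similarity. themebridge implements the full
chain from theme search to statistical validation, plus the two
companion analyses (consensus/conservation of the shared region, and
ligand-pose modelling by loop superposition).

## Alignment engine

All stages use one affine-gap dynamic program (Gotoh three-state, local
and global variants) over sequences or position-score tables. A gap of
length L costs `gap_open + L·gap_extend`; defaults are BLOSUM62 with
11/1, the standard protein-alignment setting, overridable everywhere.
Direct switches between insertions and deletions are permitted, each
opening a new gap; this makes the optimum identical to a maximum over
monotone matchings, which is what the test oracle enumerates.
Traceback is fully deterministic (diagonal > up > left on ties; the
local alignment ends at the first best cell in row-major order), so
identical inputs give bit-identical results. `X` is accepted in input
and scores the matrix minimum (−4) against everything. Global
alignments penalize end gaps. Identity is matches over aligned
(non-gap) columns; the clustering stage instead normalises matches by
the shorter sequence, the CD-HIT convention.

The inner loops are numba-compiled; a score-only kernel without
traceback serves the null-score sampling, where ~10⁶ small alignments
per analysis are routine.

## Theme profiles and the scan null

A theme MSA becomes a log-odds profile: `score(c, r) = log2((n_cr +
τ·b_r) / ((n_c + τ)·b_r))`, counts over non-gap rows only, pseudocount
τ = 1 (must be positive so unseen residues stay finite), background `b`
taken from the database residue frequencies by default. Coverage of a
hit is the fraction of profile columns inside the local alignment —
the threshold is about how much of the *theme* is matched, not how much
of the domain.

E-values are calibrated empirically because profile score distributions
depend on the profile: each of `n_shuffles` (default 1000) draws picks
a random database sequence, permutes its residues, and records the best
local profile score; a Gumbel EVD is fitted (method of moments, then ML
refinement via `scipy.stats.gumbel_r.fit`) and `E(s) = |db|·SF(s)`.
Retention requires E < 10⁻³ (strict), coverage ≥ 0.85 and alignment
length ≥ 20 (both inclusive).

## The bridging p-value

For a cross-lineage pair matched to the same theme, each domain is cut
at its hit interval into left flank / match segment / right flank. The
match segments are re-aligned locally; if the local alignment covers
less than 50 % of either segment the global alignment is used instead
and recorded (the fallback threshold is this package's rule — both
modes occur in practice, local being typical for genuinely shared
elements). The null is composition-only: 1000 segments drawn i.i.d.
from the partner segment's empirical amino-acid frequencies (the
direction is fixed — sample from the lineage-B segment, align to the
lineage-A segment), aligned with the same mode and penalties, Gumbel
fitted as above, and `p = 1 − exp(−exp(−(s_obs − μ)/β))`.

One numerical subtlety: with integer-valued substitution and gap
scores, all alignment scores sit on the integer lattice, and evaluating
the continuous survival function exactly at a lattice point biases the
p-value (measurably: the 500-pair uniformity check sat right at the
rejection boundary). The implementation therefore applies a half-step
continuity correction — `SF(s_obs − ½)` — whenever the null scores are
integral, which restores uniformity under the null. The closed-form
relation `p(μ) = 1 − e⁻¹` holds for the uncorrected survival function
exposed as `pvalue_from_fit`.

Flank dissimilarity is the sum of the two flank-vs-flank local scores
(empty flanks contribute 0); representatives per theme are the k = 2
retained pairs ranked lexicographically by (p-value ↑, flank score ↑,
ids) — the spec of "most similar matching parts, most dissimilar
flanks" needs a combination rule, and the lexicographic one is
deterministic and permutation-invariant.

No multiple-testing correction is applied across themes or pairs; the
statistic is per-pair, as in the procedure it implements.

## Conservation

Redundancy reduction is greedy incremental clustering: sequences sorted
by length (descending), each joining the first centroid with global
identity ≥ 70 %, identity normalised by the shorter length. At the
scale this package targets no k-mer prefilter is needed. Consensus is
the per-column most frequent non-gap residue (alphabetical tie-break);
conservation is that residue's frequency among the column's non-gap
rows — a monotone column-agreement score chosen for testability over
physicochemical schemes.

## Loop superposition

Kabsch least squares on matched Cα coordinates via SVD, with the
determinant sign flip so reflections are never returned. Loop
correspondence is positional (equal-length residue ranges, i-th to
i-th); insertion codes order after their base number, and every residue
in the range must carry the named atom. The ligand transplant applies
the fitted rigid map to all atoms of the named HETATM residue(s),
appends them to the acceptor with the donor's residue and atom names,
renumbered past the acceptor chain's highest residue number; the RMSD
and both selections go into REMARK lines. Waters or metals accompanying
the ligand are not carried over unless named.

For validation, the expected fitted RMSD when one point set carries
i.i.d. Gaussian noise of σ per coordinate is `σ·√(3 − 6/n)`: the
residual has 3n − 6 degrees of freedom after fitting a rotation and
translation. The Monte-Carlo check (100 seeds, n = 11, σ = 0.3 Å)
agrees within a few percent.

## The synthetic benchmark

The generator emulates the structure of the real detection problem, not
its biology in detail. Each lineage has 6 families × 4 sequences; each
family derives from its own random consensus. Planted families (half,
by default) carry a copy of a 25-residue core — beta-hydrophobics, a
Gly-rich Walker-A-like loop with its lysine, a helical stretch, a
downstream Asp — mutated per sequence at rate 0.4 except at the five
anchor positions (G/G/G/K/D), embedded between flanks of 60–120
uniform-random residues mutated at rate 0.95. Cross-lineage flanks are
therefore unrelated by construction while the theme stays detectable;
these rates are deliberately the hard end of the regime the pipeline is
meant to handle. The theme MSA used to build the scan profile is 8
core copies at rate 0.2, a realistic divergence for curated homologs.

What passing on this benchmark does **not** show: real domain databases
have phylogenetic correlation between families, composition biases,
indels inside conserved elements, and themes that partially overlap —
none of which the generator models (flank-length variation stands in
for indels). Detection rates here bound the idealised, not the real,
problem.

## Problem sizes and determinism

Default analysis sizes — 48-domain database, 1000-shuffle calibration,
1000-segment nulls, 20-replicate recovery runs, 500-pair calibration
checks — were chosen so a full validation pass completes in well under
a minute on one core while keeping every statistical check adequately
powered (binomial SE ≈ 0.01 at 500 pairs). Every stochastic stage
derives its generator from the single run seed via SHA-256, so a config
reproduces its reports byte for byte, and no stage shares a stream with
any other.

## Known limitations

- The profile scan is profile-to-sequence; profile-profile methods
  (HMM-HMM) are more sensitive for genuinely remote matches.
- The composition-multinomial null ignores residue order and local
  correlation; segments with strong periodicity may be mis-calibrated.
- Greedy clustering depends on the length-sorted insertion order
  (as does CD-HIT); it is deterministic but not order-free.
- The Gumbel fit uses all null scores, not a tail fit; extreme
  p-values (≪ 10⁻⁶) are extrapolations.
- Structure parsing takes the first model and altlocs blank/'A' only;
  mmCIF is not supported.
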