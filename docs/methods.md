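# Methods

## Scope

conservscape quantifies per-site evolutionary conservation in a protein
family and reports it in a reference sequence's residue numbering: site
scores and grades, region-level percentages (e.g. the six substrate
recognition sites of cytochrome P450s), residue reports with per-clade
substitution notes, family-unique residues from a paired cross-family
alignment, clade-stratified motif presence, and structure painting.
Alignment computation (HMMER/MAFFT), homology modeling, and
structural-alignment computation are out of scope: alignments, trees (when
supplied) and structures are consumed as inputs.

## Rate model and scoring

Site rates are estimated by empirical Bayes under a discrete-gamma prior,
the approach of Bayesian site-rate methods in the rate4site/ConSurf
tradition.

- **Substitution model.** JTT (Jones–Taylor–Thornton 1992) exchangeabilities
  and stationary frequencies, assembled into a time-reversible rate matrix
  Q with detailed balance π_a Q_ab = π_b Q_ba and calibrated so that
  −Σ_a π_a Q_aa = 1: branch lengths are expected substitutions per site at
  relative rate 1. The model is a loadable 190+20-number table
  (`data/jtt.txt`), so WAG/LG tables can be substituted. Transition
  matrices P(t) = exp(Qt) come from one cached eigendecomposition of the
  π-symmetrised matrix.
- **Prior.** K = 16 equiprobable categories (configurable); category rates
  are the analytic bin means of gamma(α, 1/α) via the incomplete-gamma
  identity, so they average to one exactly. K = 16 follows the convention
  of the empirical-Bayes rate literature.
- **Guide tree.** Neighbor joining (scikit-bio) on Kimura-corrected
  p-distances d = −ln(1 − p − p²/5) with p the mismatch fraction over
  mutually non-gap columns. p ≥ 0.85 makes the correction undefined; such
  pairs are capped at d = 5.2 with a warning. Negative NJ branch lengths
  are clamped to zero. Branch lengths are *not* re-optimised by maximum
  likelihood — a deliberate desk-scale simplification, which is one reason
  absolute scores from a server-based analysis of the same data would
  differ; the package asserts orderings and contracts, not external score
  values.
- **Likelihood.** Felsenstein pruning, vectorised across columns, with
  per-node per-site rescaling against underflow. Gaps and `X` are missing
  data (all-ones partial vectors), not a 21st state, keeping likelihoods
  comparable across columns.
- **Gamma shape.** α̂ maximises Σ_i log[(1/K) Σ_k L_i(r_k)] over
  log α ∈ [ln 0.05, ln 10], bounded scalar minimisation with tolerance
  1e-3. Hitting the lower bound (near-invariant alignments) is flagged.
- **Normalization.** Scores are (r̂_i − mean)/sd with the *population*
  (1/N) standard deviation, over all columns with nonzero coverage;
  all-gap columns carry the prior-mean rate, are excluded from the moments
  and left ungraded. The normalization is a rescaling of the complete
  score set, not an estimate, hence 1/N. Low score ⇔ low rate ⇔ conserved.
- **Grades.** Nine equal-count bins of the scores by rank, grade 9 = most
  conserved; tied scores all take the grade of their most-conserved rank,
  which is the conservative choice for "highly conserved" calls.

## Reference mapping

The k-th non-gap residue of the chosen reference row maps to residue number
`offset + k − 1` (1-based, inclusive — D309/T310-style numbering). The
offset absorbs differences between a crystal-construct sequence and
full-length numbering; default 1. Columns where the reference is gapped are
reported with an empty residue number.

## Region statistics, reports, fingerprints

- **"Conserved" for percentages** defaults to grades {8, 9} (top two of
  nine). The cut-off behind published percentages of this kind is usually
  unstated; it is therefore an explicit, logged configuration value, and
  exact reproduction of any particular published percentage is not claimed.
- **Pairwise identity/similarity** are computed over mutually non-gap
  columns (X treated as missing); similarity ("% homology") counts
  BLOSUM62-positive pairs — a documented interpretation, as similarity
  definitions vary between tools. Identity ≤ similarity always holds since
  the BLOSUM62 diagonal is positive.
- **Consensus residue** is the modal residue over all sequences, ties
  broken alphabetically; per-clade notes list every non-consensus state
  with its within-clade frequency to 2 decimals.
- **Fingerprint classification** compares a within-family score s_w with a
  cross-family score s_c at the same reference residue: variable if
  s_w > τ_c; shared-conserved if both ≤ τ_c; family-unique if s_w ≤ τ_c and
  s_c > τ_v; ambiguous in the band τ_c < s_c ≤ τ_v. Defaults τ_c = −0.5,
  τ_v = 0.0 on the normalized scale; both are logged. The ambiguous band
  exists precisely because a z-score near zero carries no evidence either
  way.
- Percentages are printed to 1 decimal, rounding half away from zero.

## Motif scanning

Patterns use a PROSITE-flavoured grammar (`R-x(1,2)-[ST]-x`); tokens carry
residue sets with repeat bounds (≤ 10). The scanner enumerates *all* matches
of all repeat expansions, overlapping included, as unique (start, end) spans
in 1-based ungapped coordinates. `X` in a sequence matches no token:
unknown is not a wildcard, so presence calls are conservative. Window
anchoring maps a reference-residue interval to alignment columns once, then
to each sequence's own ungapped coordinates, which makes presence fractions
invariant to all-gap column insertion. Presence is existence (≥ 1 hit
inside the window); fractions are reported with clade sizes.

## Structure painting

Every atom of a residue with a score gets B = score (2 decimals) or
B = grade; unmapped residues get a sentinel distinguishable from real
values (−9.99 in score mode, the format minimum; −1.00 in grade mode, since
grades are 1..9). HETATM records (heme) and other chains are untouched.
The PDB writer emits fixed-width columns (B-factor %6.2f) and re-reads
bit-exactly; only ATOM/HETATM/TER/END records are interpreted and insertion
codes are rejected — the supported dialect is deliberately small and
validated hard.

## Synthetic test-bed

`seqsim` generates the ground-truth datasets every stage is tested on:

- **Trees**: pure-birth topologies grown by uniform lineage splitting,
  i.i.d. exponential branch lengths with mean 0.1 substitutions/site.
- **Sequences**: root drawn from π, sites evolved independently down the
  tree with P(t·r_i); per-site true rates either block-constant or i.i.d.
  gamma(α_true). The default condition is 60 taxa × 300 sites with 10% of
  sites at rate 0.1 against a background of 1.5 — strong but realistic
  conservation contrast for a substrate-specific enzyme family.
- **Clades**: contiguous leaf blocks in traversal order, approximating
  monophyletic groups; the default composition mirrors a vertebrate
  homolog survey scaled to 60 taxa (mammal 11, bird 1, reptile 2,
  amphibian 3, fish 42, invertebrate 1).
- **Motif plants** overwrite residues after evolution, so planted windows
  are exact and motif truth is not entangled with substitution noise.
- No indels are simulated; gap handling is exercised with hand-made
  fixtures instead, keeping the simulation truth unambiguous.

The fingerprint recovery experiment pairs a family alignment that conserves
half its sites (10 family-unique positions plus a 140-site shared core at
rate 0.05, background 2.0) with a cross-family alignment sharing only the
core. The sizable conserved core matters structurally, not cosmetically:
with a small conserved fraction f, background sites sit only
√(f/(1−f)) z-units above the fixed τ_v = 0 threshold, so no estimator could
separate family-unique sites reliably; a half-conserved family — as
observed in highly conserved substrate-specific P450s — yields ≈1 z-unit
margins.

What passing these tests shows — and does not show. The simulator matches
the scoring model's assumptions (correct substitution model, no indels,
no alignment error, no heterotachy, clade sampling balance chosen by
design). Passing therefore validates the machinery (likelihood, estimator,
normalization, classification logic), not robustness to model
misspecification, alignment error, or the heavy taxon-sampling bias of
real survey datasets, where fish-dominated sampling is known to bias
conservation scores.

## Numerical choices

- Per-site rescaling in pruning; log-sum-exp over rate categories.
- Eigendecomposition of the symmetrised rate matrix (exact for reversible
  models); transition probabilities clipped to [0, 1] against round-off.
- Posterior weights computed in log space (softmax).
- Zero-variance score vectors and <2 scored columns are hard errors
  ("degenerate alignment"), not NaNs.
- All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; pipeline TSV outputs are byte-identical for
  identical config + seed.

## Problem sizes

Test-bed simulations use 60 taxa × 300 sites (scoring in ~1 s), 200 taxa
for the stationarity check, 100 random ≤4-leaf trees for the
likelihood-vs-enumeration oracle, and 1000 random 50-mers × 4 patterns for
the scanner oracle — sizes at which the independent oracles (exhaustive
enumeration, brute-force regex expansion) remain exact and fast.

## Known limitations

- NJ branch lengths without ML re-optimisation bias absolute rates
  (orderings are robust; absolute score values are not comparable across
  tools).
- The empirical-Bayes posterior mean shrinks extreme rates toward 1;
  scores are a ranking tool, not rate point estimates.
- Clade assignment by traversal order is only approximately monophyletic
  on the simulated trees.
- Stockholm input is read for sequences only (no GC/GR annotation use).
- Single-model runs: no mixture over substitution models, no heterotachy.
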