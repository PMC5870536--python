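# Methods

## The prediction problem

Plant type III polyketide synthases (PKSs) are a paralogous enzyme family
whose members diverged rapidly after gene duplications and repeatedly
acquired similar catalytic functions in independent lineages.  Overall
sequence similarity therefore tracks phylogeny, not reaction chemistry, and
homology search alone cannot tell a chalcone synthase from a stilbene
synthase.  `ppap` predicts a query's *reaction type* — a three-part label
(starter substrate – number of extensions – cyclization mechanism, e.g.
`R-4-C` = ring starter, four keto groups, Claisen cyclization) — as one of
four calls: `R-4-A`, `R-4-C`, `R-2-X` or `other`.

Two complementary similarity measures feed the classifier:

1. **Area profile scores.**  Four short segments (Areas 1–4) differ in 3D
   structure between the R-4-C and R-4-A archetypes.  Per reaction type, a
   profile HMM is built from the concatenated Area segments of that type's
   alignment (default combination Area 1+3+4; Area 2 is excluded because
   several aldol-cyclizing enzymes share the chalcone-synthase Area 2 motif
   `TTSGVDM`, so it carries little discriminative signal).  A query segment's
   bit score is clamped: a negative score, or no significant match at all,
   becomes exactly 0.
2. **Correlation scores.**  Compensatory mutations couple residue positions
   within a functional class.  Per type, mutual information between filtered
   alignment columns is corrected by the average product correction
   (MIp = MI − APC) and pairs with Z(MIp) > 3 are retained.  A query is then
   scored by how compatible its residue pairs are with the type's smoothed
   pair statistics (S_cor below).

Three binary Fisher LDA classifiers (target-vs-rest on the six standardized
scores) are applied in the fixed order R-4-A → R-4-C → R-2-X; the first
"yes" is the call and an all-"no" query is `other`.

## Formulas and conventions

**Mutual information** over columns i, j, with the alphabet being the
symbols actually observed at each column (amino acids, the gap character,
and `X`), unsmoothed empirical frequencies, natural logarithm:

    MI(i,j) = sum_{X,Y} p_ij(X,Y) ln [ p_ij(X,Y) / (p_i(X) p_j(Y)) ]

The log base is a pure scale factor: MIp and the Z-scores below are
invariant to it up to that common factor, so pair selection at a Z
threshold does not depend on the choice.  0·log terms are skipped.

**APC correction** with row means excluding the diagonal:

    APC(i,j)  = mean_x MI(i,x) · mean_x MI(j,x) / mean MI
    MIp(i,j)  = MI(i,j) − APC(i,j)
    Z(i,j)    = (MIp(i,j) − mu) / SD

mu and SD are the mean and *population* standard deviation over all pairs
i < j (the pairs form a complete finite population, not a sample).  The
selection threshold is Z > 3.0.

**Columns entering CMA** are the type alignment's columns after gap
filtering: terminal columns are trimmed from each end until the first
column containing no gap, and internal columns with a gap fraction > 0.8
(i.e. >80%) are removed.  The terminal rule intentionally differs from the
internal rule — terminal gaps indicate ragged ends rather than indel
polymorphism — and the combined operation is idempotent.

**Correlation score** of a query aligned into the type's column space, over
the selected pair set A with C = |A|:

    S_cor = (1/C) sum_{(i,j) in A} ln [ p_ij(Xq,Yq) / (p_i(Xq) p_j(Yq)) ]

C standardizes models with different numbers of selected pairs.
Frequencies are additively smoothed over the 21-symbol alphabet (20 amino
acids + gap, d_s = 21, d_p = 21²):

    p_i(X)    = (n_i(X) + alpha)   / (N + alpha·d_s),   alpha = 1/21
    p_ij(X,Y) = (n_ij(X,Y) + beta) / (N + beta·d_p)
    beta      = alpha² / (N + 2·alpha·d_s)

beta is derived from the requirement that a pair of residues never observed
at (i, j) — jointly or singly — has ratio exactly 1 and thus contributes
exactly 0 to S_cor; the test suite verifies this identity to 1e-12 for
N = 1..200.  A query `X` (unknown residue) is treated as unobserved and
receives the pure pseudocount.

**LDA.**  Two-class Fisher discriminant on standardized features
(population mean/SD from the LDA training matrix): w = S_pooled⁻¹(μ₁−μ₀),
with the intercept at the prior-adjusted midpoint, priors proportional to
class sizes (the target-vs-rest splits are heavily unbalanced, and this
matches the default behavior of standard LDA implementations).  A pooled
covariance with condition number above 1e10 falls back to ridge
regularization (λ = 1e-6 · trace/p) with a logged warning.  The
implementation is verified against scikit-learn's `svd`-solver LDA in the
test suite.

## Pipeline defaults

| parameter | default | notes |
|---|---|---|
| Area combination | Area 1+3+4 | clearest separation; Area 2 shared between R-4-C and some R-4-A |
| Z threshold | 3.0 | pair selection, strict inequality |
| max gap fraction | 0.8 | internal column filter (> 0.8 removed) |
| terminal gap rule | any gap | trim from ends to first gap-free column |
| profile engine | `pyhmmer` (HMMER3) when importable, else builtin | builder seed pinned (42); builds are byte-reproducible |
| query aligner | `builtin` | `mafft --add` adapter available (`aligner="mafft"`); `auto` prefers mafft |
| RRSV | fraction 0.5, 10 repetitions | training size ceil(n/2) per type — the decimal rounds up |

The builtin profile engine is a position-specific scoring model (log₂-odds
of Laplace-smoothed match emissions against a uniform background, no
insert/delete states; a length-mismatched segment is scored at its best
gapless offset).  The builtin query aligner is a global profile-to-sequence
alignment with affine gaps (BLOSUM62, open 11, extend 1) in which column
scores are occupancy-weighted mean substitution scores.  Both exist so the
whole pipeline runs and is testable with no external binaries; when HMMER
(via pyhmmer) or MAFFT are available they are the preferred adapters.

**Column reconciliation.**  Adding a query can insert columns in which
every original row is a gap.  After alignment these inserted columns are
dropped, so stored model column indices remain valid.  Round-tripping a
training sequence (degap, re-align, project) reproduces its original row
exactly on the synthetic benchmark; this is tested.

**Leave-one-out scoring.**  Inside the cross-validation harnesses the
held-out sequence is excluded from every artifact of its fold — alignments,
profiles, pair selection (re-run at Z > 3 on the reduced alignment),
correlation counts, standardizer and LDA fits — and this is asserted per
fold through training-id provenance hashes.  The public scoring API always
uses full-model counts.  As an optimization the harness rebuilds only the
held-out sequence's own type model per fold: the other types' models never
contained it, so they are shared across folds; equivalence with the naive
full rebuild is verified in the test suite.

## The synthetic benchmark

Real training data are curated family alignments (sequences with
experimentally characterized reactions, within-type identity capped at 90%,
aligned per type).  The generator emulates what the method exploits, in one
shared truth-alignment coordinate system (180 columns, 20 sequences per
family by default):

* a family-specific background archetype with per-column conservation 0.85
  and uniform substitutions elsewhere;
* conserved Area motifs per family (conservation 0.92–0.97); the R-4-C-like
  and R-4-A-like families deliberately share the Area 2 motif `TTSGVDM`,
  reproducing why Area 2 is excluded from the default profile combination;
* 10 planted covarying pairs per target family (5 per "other" family),
  each with joint mass 0.5/0.5 on two residue combinations (per-pair
  MI → ln 2), pair positions disjoint across families and from Areas;
* deletion-only indels (per-position rate 0.01) outside Areas and planted
  pairs, so truth alignments stay exact;
* a gap-free anchor row (the R-4-C-like archetype) that carries no label
  and serves as the AreaMap reference, so Area-to-column mapping never
  depends on a held-out sequence;
* two "other" families with distinct motifs: one participates in LDA
  fitting, the other is held out of fitting entirely but must still be
  classified `other` — emulating reaction types excluded from training.

What the generator does **not** emulate: phylogenetic correlation between
sequences (sequences are exchangeable draws), insertion columns, length
variation between families, and compositional biases of real proteomes.
Passing tests therefore demonstrate the pipeline's correctness and its
behavior under the stated generative assumptions, not field performance on
GenBank data.  Given real per-type alignments, a label table and a
verified Area map, `ppap eval --mode loocv` produces the same per-type
classifier report for real data.

The dedicated correlated-columns fixture for pair-recovery studies
(50 sequences × 100 columns, 10 planted pairs) uses a nearly invariant
background (conservation 0.998), emulating a strongly conserved family
core.  This is a deliberate regime choice: at n = 50, two background
columns co-substituted in even a single sequence acquire MIp ≈ ln(n)/n ≈
0.08–0.13, while ten planted pairs can raise the population SD only to
≈ 0.03, putting the Z > 3 cutoff near 0.09 — so at higher background
diversity the Z > 3 selection keeps recall ≈ 1 but its precision degrades
to 0.5–0.85 from such chance co-substitutions.  This finite-sample limit
is a property of MI-based pair selection itself, not of this
implementation, and is the reason published applications of this scheme
select on the order of a thousand pairs from ~80 sequences: the selection
is deliberately permissive, and the downstream C-normalized score, not the
selection, carries the discrimination.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
oracle comparisons on 50–100 random miniature alignments (≤ 20 × ≤ 14),
pair recovery on ten 50 × 100 fixtures, and cross-validation on the default
benchmark (5 families × 20 sequences, 180 columns; 100 LOOCV folds, 10 RRSV
repetitions).  These sizes were chosen to match the generator's default
study conditions while keeping a full run on one CPU in the low minutes.

## Known limitations

* The Area 1–4 residue ranges on the M. sativa CHS2 reference are not
  bundled as verified data; `configs/area_map_chs2_reconstructed.json` is an
  explicitly marked placeholder the user must check against the structural
  literature before real use.
* The builtin profile engine has no insert/delete states; with the HMMER
  engine unavailable, queries with indels inside Areas are scored at their
  best gapless offset.
* The builtin query aligner is profile-to-sequence; it does not realign
  existing rows.  For distant queries prefer the MAFFT adapter.
* Pair-selection precision at small n (see above): Z > 3 is not a
  false-discovery control, and selected pair sets should be read as
  enriched, not pure.
* Bifunctional enzymes receive their main type only; the cascade records
  all three binary calls so multi-hit queries can be flagged downstream.
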