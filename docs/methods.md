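# Methods

`sirmsmix` implements a quantitative structure–property relationship (QSPR)
pipeline for the auto-ignition temperature (AIT, kelvin) of binary miscible
liquid mixtures: simplex fragment descriptors for the mixture, genetic-
algorithm descriptor selection wrapped around multiple linear regression
(GA-MLR), leave-one-out and external validation, Y-randomization, and a
leverage-based applicability domain.  This note records the model, its
assumptions, the tunable parameters, and the design choices made where the
methodology left them open.

## Simplex descriptors for mixtures

Each pure compound is a 2D molecular graph (explicit hydrogens included by
default; configurable).  Every atom carries four labelling properties:

* partial charge (e) — iteratively-equalised (Gasteiger) charges;
* lipophilicity — Crippen atomic logP contribution (unitless);
* molar refractivity — Crippen atomic MR contribution (unitless);
* H-bond role — `A` acceptor, `D` donor, `I` indifferent, from SMARTS-based
  donor/acceptor perception.

The three numeric properties are binned into four classes with fixed,
upper-inclusive cut points:

| scheme | A ≤ | B ≤ | C ≤ | D > |
|---|---|---|---|---|
| CHARGE | −0.05 | 0 | 0.05 | 0.05 |
| LIPOPHILICITY | −0.5 | 0 | 0.5 | 0.5 |
| REFRACTIVITY | 1.5 | 3 | 8 | 8 |

Two categorical schemes complete the set: `HB` (the H-bond role) and `elm`
(the element symbol).  An amphiprotic heavy atom (e.g. a hydroxyl oxygen)
is labelled `D` when it bears a donatable hydrogen, else `A`: the labelling
is single-valued by construction and donor capability is the rarer, more
informative state.  The numeric property values come from open empirical
schemes; a pipeline built on a different atomic-property backend will
produce different descriptor *values* but an identical descriptor *algebra*.

A **simplex** is a 4-atom fragment: every 4-subset of a molecule's atoms
together with its induced bonds, so fully bonded, partially bonded and
completely unbonded topologies all occur (a molecule with n atoms yields
exactly C(n, 4) fragments).  Hydrogens participate by default because
several library compounds have fewer than four heavy atoms and would
otherwise produce no fragments at all.

Each fragment labelled under a scheme is rendered into a canonical
descriptor name, e.g.

```
|S|n|||4|||CHARGE|A.A-A-B      |M|n|||4|||elm|C-C(-C)=O
```

`S`/`M` marks single-compound vs cross-compound scope and `n` marks a
count-valued descriptor.  In the pattern, `-`/`=`/`#` are bond glyphs
(orders are rendered only under `elm`; every other scheme draws all bonds
as `-`, and aromatic bonds render as `-` by default, `:` optionally),
`(...)` encloses branches, `.` separates disconnected parts, and rings
close with SMILES-style digits.  The canonical pattern is the minimum over
all depth-first renderings of each connected part under a comparison key
that sorts `(` *after* atom and bond glyphs — so an unbranched chain
(`B-B-B-B`) beats its branched rewriting (`B(-B)-B-B`); plain byte order
would prefer the branch because `(` < `-` in ASCII.  Parts are sorted and
joined with `.`.  Canonicalisation is exhaustive (≤ 4 atoms), cached, and
permutation-invariant by construction.

## Mixture blocks and mixing rules

A binary sample is (compound 1, compound 2, mole fractions x1 ≤ x2,
x1 + x2 = 1).  Volume fractions are converted first:
x_i ∝ v_i ρ_i / M_i.  Two descriptor blocks are assembled:

* **D_S** — mole-fraction-weighted single-compound counts,
  `D_S = x1·D1 + x2·D2` (union of names, zero-filled). Every D_S value is
  a convex combination of the two pure-compound values.
* **D_M** — cross-compound simplexes: 4-atom fragments taking a ∈ {1,2,3}
  atoms from compound 1 and 4−a from compound 2, bonds induced only within
  each compound, scaled by the doubled minor fraction:
  `D_M = 2·x1·D_{1+2}`.  At x1 = 0.5 the raw cross counts are kept; at
  x1 → 0 the mixture block vanishes; 0 ≤ D_M ≤ D_{1+2} always.

Because no bond spans the compounds, the connected parts of a cross
fragment are parts of each compound's own sub-fragment.  The matrix builder
exploits this: per molecule, scheme and part size s ∈ {1,2,3} it tabulates
how often each multiset of canonical part strings occurs among the C(n, s)
subsets, then counts all cross fragments of a pair by combining the two
tables.  The literal fragment-by-fragment enumeration is kept as the
reference route and the two are cross-checked in the test suite.

The sample matrix concatenates D_S then D_M over the union of names,
zero-filled, with zero-variance columns dropped (they carry no information
and make least-squares designs singular).  Swapping the compound labels of
a sample (with its fractions) leaves its row unchanged.

## Model fitting and descriptor selection

The response model is ordinary least squares on p selected descriptors:

    AIT = b0 + Σ_j b_j d_j,    R² = 1 − RSS/TSS,
    s = √(RSS/(n−p−1)),        F = (R²/p) / ((1−R²)/(n−p−1)).

Leave-one-out (LOO) prediction residuals use the closed form
e_i / (1 − h_ii) — algebraically identical to n refits — so the selection
fitness, rmsecv = √(mean LOO residual²), costs one QR decomposition per
candidate subset.

**Genetic algorithm.** Fixed-size subset encoding (k distinct column
indices); tournament selection (size 3); uniform-union crossover with
repair (shared genes kept, the remainder drawn from the symmetric
difference); per-gene mutation with default rate 1/k, i.e. about one gene
swap per child — a rate tied to the total column count instead would
mutate almost no children at realistic matrix widths and the population
collapses onto its initial material; elitism 1; everything driven by one
seeded generator, so a fixed seed reproduces the search exactly.  Fitness
ties break on the lexicographically smallest name subset.  Defaults:
population 100, generations 200 (doubling both was measured to triple the
cost without improving planted-subset recovery on seeded replicate
batches); the y-scrambling protocol uses a reduced budget (below).

**Incremental size search.** k grows 1, 2, … (cap k_max = 8, and never
beyond n/5 to guard against overfitting); half of each size-k population is
seeded with one-column extensions of the best (k−1)-subset, so the search
refines rather than restarts.  Growth stops at the first k whose relative
rmsecv improvement falls below 2% and the model at the elbow (k−1) is
returned; `tol=0` runs to k_max.  Note that best-subset selection bias
makes chance LOO improvements of a few percent common at small n, so the
elbow tends to sit one or two sizes above the planted dimension on
synthetic data — the selected set is then a superset of the true one.

**Mean effects.** The contribution of descriptor j is

    ME_j = 100 · β_j Σ_i d_ij / Σ_k β_k Σ_i d_ik ,

a signed percent scale that sums to 100 over the model's descriptors.  A
`centered` variant replaces the raw column sums with sums of absolute
deviations from the column mean (weighting by contributed variability);
literal centring is degenerate — centred sums are identically zero — so
this is the meaningful alternative reading.  Default is raw.

## Validation

* **Q²_LOO** = 1 − PRESS / Σ(y − ȳ)²  (internal robustness).
* **Compounds-out split**: candidate held-out subsets of 1–3 pure
  compounds are scored by how close the induced test-set count is to the
  target fraction (default 25%); every mixture containing a held-out
  compound goes to test, so no test mixture is built solely from training
  compounds.  All subsets are examined when there are at most 500 of them
  (there are 175 for 10 compounds), otherwise a seeded random sample of
  500.  The split fails if the best achievable fraction misses the target
  by more than 15% relative.
* **Q²_EXT** = 1 − Σ(y − ŷ)² / Σ(y − ȳ_train)² with the *training* mean in
  the denominator, plus RMSE, AAE, mean and max percent error.
* **Y-randomization**: the response is permuted n_iter times (default
  100); descriptor selection is rerun per scramble and the highest R²
  recorded.  No chance correlation is declared when the true model's R²
  exceeds the mean highest random R² by more than 2.3 SD (1% level) or
  3 SD (0.1% level).  Rerunning the full GA per scramble is supported but
  the default protocol uses a budget-reduced GA (population 30,
  generations 20) at the model's subset size — the scrambles only need the
  *ceiling* of chance fits, and a reduced search biases that ceiling
  downwards far less than it saves time; the full protocol is one config
  switch away.

## Applicability domain

Leverage h_i = x_i (XᵀX)⁻¹ x_iᵀ with the intercept-augmented training
matrix; training leverages sum to p+1.  Warning threshold h* = 3(p+1)/n.
The Williams plot's response axis uses cross-validated standardized
residuals: LOO residuals for training rows, plain residuals for test rows,
both divided by the *training* LOO-residual standard deviation (the
methodology names the quantity without fixing the test-row scale; the
training SD is the scale the domain was calibrated on).  Flags use strict
inequalities — h > h* (structural extrapolation), |r| > 3 (response
outlier); a sample at exactly the boundary is inside.  High-leverage
samples predicted within 3 SD are flagged but acceptable.  An identically
zero residual vector (noiseless fits) returns zeros rather than dividing.

## Synthetic data

Experimental AIT collections for binary mixtures are small and not
redistributable, so the pipeline ships a generator that mirrors their
statistical shape: an 11-compound library spanning alcohols, acids,
esters, benzenes, ketones and alkanes (handbook densities and molar
masses); binary mixtures with uniformly drawn mole fractions ordered
x1 ≤ x2; descriptors computed through the real chemistry/simplex/mixture
code; and a response

    AIT = b0 + Σ_{j∈active} β_j d_j + ε,   ε ~ N(0, σ²),

affinely rescaled to span 496.15–798.15 K, the range of measured mixture
AITs.  Defaults: 132 mixtures, 6 active descriptors, σ = 10 K, per-SD
effect sizes uniform in 30–80 K.  The rescaled truth (names, effective
coefficients, noise SD, affine map, seed) is recorded with every dataset.

**Identifiability of the planted model.**  Simplex descriptor matrices are
intrinsically collinear: all mixture-block columns share the 2·x1 factor
over only ~50 compound pairs, and single-block columns live in a similarly
low-dimensional compositional space.  Recovery of a planted column that
has a near-duplicate, that varies in only a handful of samples, or whose
effect is cancelled by correlated co-actives is ill-posed for *any*
selection method, so the generator plants detectable, separable effects:
active columns must have support ≥ 0.15 (fraction of samples off the modal
value), max |corr| < 0.8 against every other column, pairwise |corr| < 0.3
(both relaxed stepwise only when the matrix cannot supply enough columns),
and the signed coefficients are redrawn until each active column keeps a
marginal correlation ≥ 0.15 with the noiseless signal.

`make_splittable_dataset` arranges the 132 mixtures over 10 compounds
(28 pairs of eight "core" compounds carry 99 mixtures; the 17 pairs
involving the last two compounds carry 33) so that a compounds-out split
at 25% can hold out exactly 33 mixtures.  For this dataset the active
columns' identifiability statistics are evaluated on the core-pair
mixtures only: a planted signal supported mainly on held-out-pair columns
would make the external set unpredictable by construction and the
validation meaningless.  With this condition, refits on the true columns
reach Q²_EXT ≈ 0.99 across seeds.

**What the generator does not emulate:** real AIT chemistry (measured
values are not linear in fragment counts), measurement protocol error
structure, tautomers or 3D effects, ternary mixtures.  Passing tests
demonstrate that the pipeline's statistics and search behave correctly
under the model's own assumptions — not that a six-descriptor linear model
is adequate for laboratory AIT data.

## Numerical choices and degenerate inputs

* Bin boundaries upper-inclusive (value ≤ cut goes to the lower class).
* Rank deficiency raises an error naming removable collinear columns; a
  LOO fold with leverage 1 is reported as a singular fold (inside the GA
  such subsets simply score +inf).
* Constant-column pruning is exact (zero variance), applied before
  selection, with the dropped names reported.
* GA tie-breaks are lexicographic on descriptor names; all stochastic
  steps flow from explicit integer seeds.
* Mole fractions are validated to sum to 1 within 1e−9 and samples are
  reordered on construction so x1 ≤ x2, recording the swap.

## Problem sizes

The test suite and the acceptance script run at the study's native scale —
132 mixtures, 10 compounds, ~1000 descriptor columns — for the end-to-end
paths, and at 25–60 samples for unit-level oracle checks.  The
planted-recovery study uses 10 seeded replicates of the default generator.
Y-randomization in the end-to-end runs uses 20 scrambles with the reduced
GA; the 100-scramble protocol is available through configuration.

## Known limitations

* The GA can lock into deceptive local optima when families of correlated
  columns jointly mimic part of the planted signal; on 10-replicate
  batches typically one to three replicates recover fewer than 5 of the 6
  planted descriptors (a LASSO path probe fails on the same instances, so
  the hardness is the dictionary's, not the GA's).  Mimicking models still
  interpolate well (rmsecv within a factor ~3 of the planted optimum) but
  can extrapolate poorly: on compounds-out runs where selection missed the
  planted subset, Q²_EXT can drop below zero — the external split doing
  exactly its job of exposing spurious selection.
* Descriptor values depend on the empirical atomic-property backend;
  models are transferable only between matrices computed with the same
  backend and hydrogen convention.
* Binary mixtures only; the mixing rules have no ternary extension here.
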