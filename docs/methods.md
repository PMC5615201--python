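# Methods

## Cuticle-redness quantification

The redness score operates directly on 8-bit integer RGB values
(0 ≤ R, G, B ≤ 255) with no gamma correction or color-space conversion.
From a user-supplied rectangle bounding the metasternum, the maximal
inscribed square is extracted, centered along the rectangle's longer axis;
when the leftover is odd, the floor of the offset is used, biasing the
square one pixel toward the top/left. Automatic metasternum detection is
out of scope: locating the rectangle is the operator's job.

**Brightness and masking.** Brightness is the arithmetic mean of the three
channels — chosen because the redness index itself is expressed relative to
mean(R, G, B), so mask and statistic live on the same scale. Max-channel
and BT.601 luma are selectable alternatives. The top/bottom 10% cuts are
pixel-count quantiles (rank-based), not fractions of the intensity range,
which makes the mask invariant to exposure shifts. Quantiles use the
nearest-rank method (value at 1-based rank ⌈q·N⌉, floored at rank 1), and
masking uses *strict* inequalities against the two quantile values. Two
consequences are deliberate: a uniform image masks nothing (rather than
everything), and at least (1 − low − high)·N pixels always survive, so the
index is defined whenever low + high < 1.

**The index.** Over unmasked pixels, index = Σ[R − (R+G+B)/3]/n. Bounds are
±170 (pure red / pure cyan); any grayscale input scores exactly 0; adding a
constant to all channels (without clipping) changes neither the mask nor
the index; pixel order is irrelevant. Arithmetic is float64 throughout.

## Sequence composition

AT content is 100·(A+T)/(A+C+G+T). Gaps and IUPAC ambiguity codes are
excluded from numerator and denominator rather than fractionally allocated —
deterministic, and ambiguity is rare in deposited 16S sequences. U is
folded into T so rRNA-style input behaves like DNA. FASTA output wraps at
70 columns for bit-stable files. Reading validates the alphabet line by
line so errors can name the offending line.

## Distances and the relative rate test

Distance corrections are the standard closed forms: JC69
d = −¾ ln(1 − 4p/3), and K2P d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), where P
and Q are transition (A↔G, C↔T) and transversion fractions over shared
unambiguous sites. Arguments at or past saturation raise a dedicated
`SaturationError` instead of returning infinities. K2P is the default for
rRNA; JC69 is selectable. Complete deletion is the default site filter so
that a single fixed site count applies to every pair; pairwise deletion is
available.

For lineage sets L1, L2 and outgroup O, the test decomposes each triplet's
distances into K1 = (d_ab + d_ao − d_bo)/2 and K2 = (d_ab + d_bo − d_ao)/2
and averages unweighted over triplets; K1 + K2 = d_ab holds to machine
precision per triplet. Negative K values (possible with noisy distances)
are reported unclamped with a warning flag. Multi-taxon lineages use plain
means; phylogenetically weighted averaging is not implemented — for
single-taxon lineages the two coincide exactly.

**Bootstrap variance.** The standard error of K1 − K2 is estimated by
resampling alignment columns with replacement (default 2,000 replicates).
Implementation detail: the alignment is collapsed to unique site patterns
and replicate counts are drawn from a multinomial over pattern frequencies.
This is *exactly* a column bootstrap — the statistic depends on the columns
only through their counts — but runs in O(replicates × patterns) rather
than O(replicates × sites). Replicates with saturated distances are dropped
with a warning. z = (K1 − K2)/SE and a two-sided normal P value follow. The
analytic variance used by some rate-test programs is intentionally not
reproduced; the bootstrap is model-agnostic and directly checkable by
simulation (type-I error at α = 0.05 calibrates to 3–7% at 10-kb
alignments; see `tests/test_acceptance.py`).

## Neighbor joining

Saitou–Nei agglomeration with the Studier–Keppler Q criterion. Ties in Q
are broken by the lowest (row, column) pair — row-major argmin — so results
are platform-deterministic. On an additive matrix NJ recovers the unique
generating topology and exact branch lengths (verified against an
exhaustive least-squares search over all unrooted topologies for 5–8 taxa).
Negative branch lengths arising from noisy matrices are clamped to zero on
the final tree and logged. Bootstrap supports are mapped by bipartition
identity, not node identity, and attached as internal-node labels (integer
percent of non-skipped replicates); replicates whose distances saturate are
skipped and counted, with a warning if more than 1% are. Trees are dendropy
objects; Newick round-trips preserve topology, lengths (6 decimals), and
supports. Maximum-likelihood and Bayesian inference and substitution-model
selection are out of scope.

## Phenotype statistics

The symbiotic/aposymbiotic contrasts use a two-sided Welch t test by
default (Student's pooled test selectable): the unequal-variance form is
the safer default when group variances are unknown. Degrees of freedom are
Welch–Satterthwaite; if both samples have zero variance and equal means,
P = 1 by convention. Significance codes: * P < 0.05, ** P < 0.01,
*** P < 0.001, ns otherwise. Exactly two planned comparisons (redness,
weight) are made, so no multiple-testing correction is applied; users
adding comparisons should correct accordingly.

## Synthetic-data generators

The generators define the conditions under which the pipeline is validated.

* **Images** — every pixel is independently a specular highlight
  (probability `highlight_frac`, default color (250,250,250)), a shadow
  (`shadow_frac`, default (5,5,5)), or body: base color + i.i.d. Gaussian
  channel noise, rounded and clipped to [0,255]. Defaults used in the
  validation suite: 200×200 px, base (150,100,100) (redness 33.33), noise
  sd 8, 5% highlights, 5% shadows. Highlight/shadow placement is per-pixel
  Bernoulli, not spatially clustered — the mask is rank-based, so spatial
  structure cannot affect the statistic. The model deliberately omits
  optics: no vignetting, specular gradients, chromatic aberration, or
  exposure variation between specimens. Passing tests therefore show the
  masking-plus-index machinery is correct, not that any particular camera
  setup is unbiased.
* **Alignments** — sites evolve independently down a rooted Newick tree
  from a uniform-composition root using the exact JC69/K2P transition
  probability matrices (branch length = expected substitutions per site);
  no Gillespie simulation, no indels, no rate heterogeneity across sites.
  The root composition is the models' stationary distribution, matching the
  distance corrections exactly; compositional bias is exercised by the
  separate i.i.d. generator rather than a nonstationary process.
* **Composition sequences** — i.i.d. draws from a fixed (A,C,G,T)
  frequency vector; the AT-content estimator is binomial, so its sampling
  error is known in closed form.
* **Weights** — Gaussian draws truncated at zero by rejection. Cohort
  defaults for the validation suite: n = 25/25 redness cohorts separated by
  8 index units with between-specimen sd 3; n = 30/30 weight groups with a
  10% mean difference at sd 0.05 mg — effect sizes at which the power of
  the t test is essentially 1.

Every generator is bit-deterministic given its seed; a pipeline-level seed
is split into per-stage substreams (images, alignments, composition,
weights — in that fixed order) via `numpy.random.SeedSequence.spawn`.

## Validation problem sizes

The acceptance checks run at: 1,000 equal-rate datasets of 3 taxa × 10,000
sites with 500 bootstrap replicates each (type-I error); 50 datasets of
50,000 sites for 2:1 rate-asymmetry recovery; 20 random additive matrices
of 5–8 taxa against the exhaustive least-squares oracle (up to 10,395
topologies at 8 taxa); and 100 replicate synthetic phenotype cohorts. These
sizes give Monte-Carlo intervals comfortably narrower than the acceptance
bands while keeping a full run under a minute.

## Known limitations

* The brightness definition (mean RGB) and the rank-based reading of the
  10% cuts are explicit assumptions; acquisition software may implement
  either differently, so absolute index values are comparable only within a
  protocol.
* Which distance correction and deletion policy external rate-test programs
  apply is not standardized; exact reproduction of third-party K values can
  depend on those choices.
* NJ tie-breaking on exactly tied Q values is implementation-defined across
  programs; tied (e.g., equidistant) inputs yield an arbitrary but
  deterministic resolution here, with zero-length internal branches.
* The test suite validates against the synthetic generators' assumptions
  (i.i.d. sites, stationary composition, Bernoulli highlight placement);
  real photographs and real alignments violate these in ways the suite does
  not measure.
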