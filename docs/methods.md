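# Methods

This note documents the models and procedures implemented in
`namingnorms`, the defaults chosen where the design was open, and what
the synthetic-study tests do and do not demonstrate about real data.

## The norming computation

**Response coding.** Raw typed responses are whitespace-collapsed,
lowercased (simple lowercase; diacritics preserved — these are norms for
English, and locale-dependent case folding would be a liability), and
mapped through a variant table that clusters misspellings onto canonical
names.  Categories are then assigned in a fixed decision order: explicit
don't-know tokens → *invalid*; blank or pure-punctuation strings →
*unknown* (a blank is a failure to answer, not an explicit "DK");
dictionary entries → *non-object* or *physically dissimilar* when listed
in the curated tables, else *valid*; out-of-dictionary strings →
*idiosyncratic* when understandable, else *unknown*.  Whether a response
is "understandable in relationship to the image" is a human judgement
that cannot be computed; the pipeline makes it declarative: an explicit
`understandable` table, plus one safe heuristic (a multi-word compound
whose component words are all dictionary entries, e.g. *road flattening
machine*, is understandable).  This keeps the judgement auditable and
replaceable per dataset.

**Inclusion flags.** Name agreement is computed against *all* responses
(invalid responses stay in the denominator); the H-statistic over valid
responses only; RT means over valid, known responses only.  Equivocal
responses (unknown, idiosyncratic, non-object, physically dissimilar)
count as valid names everywhere except that unknowns are excluded from
RT.  The weighted-variable flag is provisional at coding time because
its real exclusions (singletons; missing frequencies) are properties of
the per-image tally, applied at norming time.

**H and normalised H.** `H = Σ pᵢ log₂(1/pᵢ)` over the valid-response
proportions, computed by direct summation (zero-count terms absent).
Normalised H is `H / log₂(n_valid)`, defined as 0 when an image has
fewer than two valid responses; dividing by the sample-size bound makes
images with different response counts comparable and guarantees values
in [0, 1].  *Known limitation:* the source norms print no formula for
their normalisation, and their summary statistics (mean normalised H
0.56 at mean H 1.38 with ~32 valid responses per image) are more
consistent with a per-image `log₂(k)` (distinct-name) denominator.  The
`log₂(n_valid)` convention is retained as the documented contract; both
quantities are monotone transforms of H per image.

**Zipf frequencies.** `zipf = log₁₀(raw count / (corpus tokens / 10⁹))`,
i.e. log frequency per billion tokens, so 1 occurrence per 100 million
tokens → 1.0 and 1 per 100 tokens → 7.0.  Two-word names use raw bigram
counts on the same scale.  A name absent from the lexicon yields a
missing marker (NaN), never Zipf 0 — a zero would assert an observed
(astronomically low) frequency rather than an unavailable one.

**Weighted lexical variables.** Names produced only once for an image
are excluded (they are mostly equivocal and unrepresentative of what the
image activates); for the weighted frequency, names without a lexicon
entry are additionally excluded; weights are renormalised over the
retained names, making each value a convex combination.  The weighted
length applies the same singleton rule but does not require lexicon
presence, since frequency availability is a property of the frequency
source only.  Modal ties are broken by higher Zipf frequency, then
alphabetically — deterministic, and favouring the name most likely to
recur in replication.

**RT cleaning.** Stages run in a fixed order: absolute bounds first
(> 10 000 ms, then < 200 ms) so that inattention outliers cannot
contaminate the per-participant statistics; then a single-pass removal
of trials ≥ 2.5 sample SDs (n−1 denominator) from the owning
participant's mean, computed once on the surviving pool (iterating the
SD criterion would make removal counts depend on convergence behaviour).
Bounds are closed ("at least 2.5 SD" removes a trial exactly at
criterion).  Participants with fewer than two surviving trials, or zero
SD, skip the stage and are logged.  The participant-level screen
(means ≥ 2.5 SD from the grand mean of participant means) runs after
trimming, matching the narrative order of the procedure it implements.

**Model comparison.** All regressions are image-level OLS with an
intercept.  Both hierarchical models (frequency at Step 1, length at
Step 2) are fit on the complete cases of the *union* of modal and
weighted predictors, because `BF₁₀ = exp((BIC₀ − BIC₁)/2)` is only
meaningful for models fit to identical observations; dropped images are
counted and logged.  The suppression diagnostic flags a predictor whose
coefficient sign contradicts its zero-order correlation with the
response while it correlates at |r| > .5 with its co-predictor —  the
classic signature of a suppression artefact in the frequency/length
pair, which are strongly negatively correlated in English object names.

## The synthetic-study generator

The generator emulates the design that motivated the pipeline: 800
images of 200 objects (four per object; half natural kinds, half
artefacts), 16 lists of 50 trials with every image in exactly one list
and each object's images spread over at least two lists
(greatest-remaining-capacity greedy), 60 participants completing
contiguous wrap-around blocks of 4–16 lists from four balanced starting
points.  List counts are drawn from a shifted binomial with mean 8.62
(the reported mean; the full empirical distribution of completed lists
is not published, so a two-parameter family matching range and mean was
chosen).  This rotation guarantees 15–60 responses per image.

**Latent naming.** Each object draws a base distribution over 8
candidate names from a symmetric Dirichlet with concentration 0.16;
each image re-draws from Dirichlet(150 × base).  The concentration was
set once so that the simulated image-level estimated mean H (~1.35
bits) and agreement (~63%) match the reported conditions (1.38 bits,
66.25%); the image-level concentration of 150 makes uncertainty an
object-level property (per-object min/max normalised H correlate at
r ≈ .85 in the compiled norms, matching the reported r = .85).
Candidate names are unique pseudo-words (12% two-word names) with Zipf
values drawn around 4.0 over a 201-million-token corpus, the typical
scale of concrete object names in a subtitle corpus.

**Response noise.** Per-trial category probabilities default to the
emulated study's prevalences: 2.18% invalid, 0.06% unknown, 2.3%
idiosyncratic (modifier + sampled name compounds), ~1% non-object,
0.05% physically dissimilar; sampled names are misspelt at 5% using a
deterministic variant table (vowel deletion / letter doubling,
collision-checked), so spelling normalisation is exactly invertible and
the coding round trip can be asserted with zero tolerance.

**Latencies.** `rt = intercept + slope·x + participant + residual` with
x the image's true H (185.27 ms/bit, the reported unstandardised
coefficient) or, alternatively, its true weighted Zipf frequency
(−145.24 ms per Zipf unit); intercept 800 ms (grand RT 1055 ms minus
185.27 × mean H 1.38); Gaussian participant effects (SD 150 ms) and
Gaussian residuals (SD 300 ms).  Residuals are deliberately *not*
heavy-tailed: extremes are injected only by replacement (rates 95/25271
long, 31/25271 short), and clean latencies are clamped to
[250, 9500] ms, so the absolute trimming stages have exact ground-truth
removal counts.  Consequences: simulated RT distributions lack the
right skew of empirical latencies (per-image RT SD ~100 ms vs the ~220
ms reported), and the per-participant SD stage removes ~1–3% rather
than the ~3% seen with skewed data.

**What passing tests show.** The synthetic studies validate the
*computation* — coding, tallies, entropy, exclusion rules, trimming
accounting, model comparison — under known ground truth.  They do not
validate the human coding judgements, the frequency lexicon, or the
empirical RT distribution of any real dataset; reproducing the source
norms' published values requires their trial-level deposit, for which
the pipeline's real-data mode (CSV/TSV inputs) is the entry point.

## Numerical choices

* Internal computation at full precision; rounding (2 decimals) only at
  CSV serialisation; JSON carries full precision with NaN → null.
* All randomness flows from one integer master seed through
  `numpy.random.SeedSequence.spawn`, one stream per stage; identical
  seeds give byte-identical output files (outputs contain no
  timestamps).
* Degenerate inputs are explicit: empty images raise; zero-variance
  consistency correlations return a missing value with a diagnostic;
  rank-deficient regression designs raise naming the collinear columns;
  malformed trial rows are routed to a rejects file, never dropped.

## Known limitations

* Slope recovery through the full pipeline is attenuated by ~20%: the
  per-participant SD trim clips the upper tail of high-uncertainty
  trials more than low-uncertainty ones (~6%), and regressing on H
  estimated from ~32 responses per image adds errors-in-variables
  attenuation (~17%).  This mirrors what the same procedure does to any
  real dataset's latent effect; tests therefore assert sign and an
  attenuation band for the recovered slope, and model *selection* (which
  survives attenuation) for the weighted-vs-modal comparison.
* The normalised-H denominator convention is contractual, not
  empirically confirmed (see above).
* No lemmatisation or plural folding; no modelling of fatigue or
  practice effects; analyses are image-level only (no trial-level mixed
  models), matching the procedure implemented.
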