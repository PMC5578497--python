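# Methods

## Visual front end

Strings are exactly four uppercase A–Z letters. Rendering uses a packaged
5×7 dot-matrix font, integer-upscaled and centred in four fixed-width
slots (default raster 40 px tall, 30 px per slot) with at least one blank
pixel of margin, so rasters are bit-reproducible and strictly
slot-confined. Gradients are central differences with zero padding;
orientation is unsigned (θ and θ+180° identified) and quantized into 8
bins with edges uniform on [0°, 180°); each slot is divided into a 5×6
cell grid (near-equal pixel partition, row-major, origin top-left, slot
intervals half-open). A cue `s{slot}r{row}c{col}o{bin}l{level}` fires
when the cell's summed gradient magnitude in that orientation bin exceeds
the level's threshold; the default thresholds (0.5, 2.5) make typical
letter strokes activate level 0 and dense strokes additionally level 1.
The default inventory is 4·5·6·8·2 = 1,920 cues; a `large_scale` preset
(7×8 cells, 16 bins, 4 levels → 14,336 cues) exists for experiments at a
larger inventory. The analyses here depend on cues being discrete,
binary, and slot-tagged — not on the exact count.

Because rendering is slot-confined and gradients are local, a string's
cue set is exactly the union of per-(slot, letter) patterns; the cue
cache exploits this for speed, and a test holds the composed sets equal
to direct extraction. Under the default configuration all 26 letters have
pairwise distinct slot patterns, and strings differing in one letter
differ only in that slot's cues.

## Learning rule

The network is a single layer from cues to the outcomes WORD and
NONWORD. The Rescorla–Wagner/Widrow–Hoff update with the salience–rate
product collapsed into one constant η is applied to all active cues, with
λ = 1 for the outcome that occurred and 0 for the other, computing the
prediction *before* the update. Predictions during training are emitted
before any update, so they reflect strictly past experience. Decisions
are argmax with exact ties resolved to NONWORD by default (mirroring the
early response bias the synthetic subjects exhibit); a seeded random
tie-break is available.

η defaults to 0.0055. On binary cue vectors the rule is stable for
η < 2/λ_max of the cue covariance; with ~300 active cues per stimulus
this puts divergence near η ≈ 0.007, and rates at or above that
oscillate. 0.0055 was chosen as the rate at which a 20-word/20-nonword
task reaches 100% training accuracy within 10 passes in 29 of 30
sampled task instances (the remaining tail — occasional instances
needing up to ~14 passes — is intrinsic to plain LMS when a random
nonword happens to overlap a trained word heavily). λ_present = 1 and
λ_absent = 0 make the fixed point interpretable as outcome support.

The **double-learning** regime updates first toward the subject's
recorded response, then toward the feedback, in that order, both on the
current trial's cues; when responses always equal the truth it reduces
exactly to two composed feedback updates, which the tests assert
bitwise.

`equilibrium_oracle` solves the stationary condition E[Δw] = 0 — the
normal equations of the cue-by-outcome regression — with a minimum-norm
solution and a nullity report for singular systems. It is used only as an
independent check that long-run feedback training converges to it.

## Synthetic subjects

Real trial logs for this task are not publicly deposited, so the package
generates stand-ins with the statistical structure the analyses assume;
nothing is fitted to real animals, and agreement with the synthetic
subjects shows internal consistency of model plus analysis, not fidelity
to any particular animal.

*Schedules.* Word trials occur with probability 0.5; the word presented
is a uniform draw from the currently introduced vocabulary, and nonwords
are one-shot draws (without replacement) from a pool of random four-letter
strings excluding the lexicon. A new word is introduced when the trailing
`window` (default 5) presentations of the newest word reach the criterion
accuracy (default 0.8) under a repetition proxy: a presentation counts as
proxy-correct from the word's second presentation onward, an idealization
of fast error-driven memorization (the learner module in fact shows
stimuli are classified correctly from their second encounter in the
disjoint-cue case). Because the newest word only receives a uniform share
of word trials, introductions slow as the vocabulary grows, giving
vocabularies of roughly 30–110 words over 3,000–60,000 trials — the same
order as trained animals — and making novel words sparse relative to
novel nonwords by construction.

*Agents.* Each simulated subject owns a feedback-trained internal network
(rate 0.005) but responds through an attentional filter: with the current
lapse probability it responds uniformly at random; otherwise it takes its
internal argmax, overridden to NONWORD with probability
`bias_nonword · 0.5^(t/halflife)`. The lapse rate performs a reflected
random walk per 100-trial block. Six presets span a
persistent-bias/small-vocabulary profile to a fast/low-lapse profile;
they are qualitative archetypes only. What the generator does **not**
emulate: reaction times, motivation cycles, session boundaries, stimulus
repetition effects beyond learning, or any fitted parameters of real
animals — so passing tests say nothing about quantitative fit to real
baboon data.

*Ground-truth generators.* For parameter recovery, two further
generators exist: nonword trials whose accuracy carries a known OLD20
log-odds slope under subject-specific smooth trends, and mixed word/
nonword logs whose word-trial correctness carries genuine per-word
intercepts (sd 0.8 by default) and no n-gram structure. The study
conditions used by the acceptance checks are 20,000 trials for the OLD20
slope (recovery within ±0.15) and six subjects × 2,000 trials × 60 words
for the random-effects comparison; at much larger trial counts the
n-gram factors inherit enough word-level variance to reach significance
themselves (any fixed nonzero group-mean difference does, as n grows),
so the comparison is only meaningful at finite, pre-registered sizes.

## Behavioural statistics

Accuracy is binned in blocks of exactly 100 trials (trailing partial bin
dropped); Fig-style panels that compare fluctuation exclude the first
5,000 trials by default (1,000 or 500 in reduced runs). Cross-correlograms
are plain Pearson correlations on the overlapping window, no detrending,
displayed against ±1.96/√n. The derivative Spearman correlation is rank
correlation of the two series' first differences; its large-sample p is
exact under exchangeable deltas (random-walk series) and approximate when
the deltas are autocorrelated — differencing white noise produces MA(1)
deltas, which is why the calibration tests use random-walk inputs.
Run-length exceedance uses maximal runs of consecutive correct responses
as the denominator, P(run length > k). OLD-n is the mean unit-cost edit
distance to the n closest lexicon entries (self excluded, stable sort,
flagged when fewer than n are available); the scalar dynamic program is
the reference and a vectorized batch version is tested against it.

## Model-based fits

Fits use binomial GLMs with spline bases (statsmodels/patsy). The OLD20
model is `accuracy ~ OLD20 + per-subject B-spline of trial`. The
transposition experiment trains, per run, eight independent feedback-only
networks on all lexicon words admitting both derivations (~800) against
2× random nonword pools (4 shuffled passes), probes one transposition and
two substitution nonwords per word, and fits P(word response) on nonword
type with TRANSPOSITION as reference, so a negative SUBSTITUTION
coefficient reproduces the sign convention "transpositions attract more
word responses". The per-run effect for the across-run sign test is the
network-mean difference in word-response rates. A matched null control —
two independently drawn batches of substitution-type nonwords under
arbitrary labels — is fitted identically and is expected non-significant.
The effect's mechanism under slot-confined cues is letter-position
statistics (transposed-in letters are English-typical; substituted-in
same-class letters include rare ones that the random nonword pool ties to
NONWORD), which attenuates it relative to position-tolerant codes; small
per-run protocols (≤300 sampled words, one network) show the correct mean
direction but are underpowered for a per-run sign test.

The random-effects comparison fits, per subject, a base logistic model
`correct ~ B-spline(trial)` on word trials and adds dummy-coded blocks
for (a) word identity, (b) both trigrams, (c) all three bigrams. Each
factor is tested by a likelihood-ratio test against the nested model
without that block, with degrees of freedom taken as the **rank** gain of
the design (n-gram blocks are near-collinear with word identity and with
each other; column counts would overstate df), and the LR statistic
deflated by (1−ρ)/(1+ρ), ρ being the lag-1 autocorrelation of the base
model's Pearson residuals (an AR(1) working correction). All 6 tests ×
subjects form one Bonferroni family (α = 0.05/n). Model comparison uses
AIC within subject. Slot-weight summaries report, per slot, the count of
cues with nonzero weight and the median |w| pooled over both outcomes
(signed pooling available via an option).

## Numerical and serialization choices

Weight CSVs print floats with 17 significant digits, so write→read is
bit-exact; Matrix Market export uses the same precision with a sidecar
row/column index. Trial logs use a fixed CSV dialect (LF, uppercase
values) and are validated on read — contiguous 1-based trials, response/
correct consistency, first-encounter consistency. All randomness flows
through explicit numpy Generators; pipeline commands fan a single global
seed out to per-module seeds by fixed offsets and write manifests with
SHA-256 hashes of their outputs, making every command re-entrant and
byte-reproducible.

## Known limitations

Strictly slot-aligned cues cannot carry cross-slot positional overlap, so
transposition effects are weaker than under position-tolerant feature
codes. The repetition proxy in the scheduler is an idealization of the
original staircase, whose exact criterion is not public. The AR(1)
correction is a working approximation, not full ML with correlated
errors, and the factor tests are fixed-effects LRTs rather than variance
-component tests. The derived-nonword CSV dialect does not carry the base
word, so provenance is lost on a round trip through a trial-log file.
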