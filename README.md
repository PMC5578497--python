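# widelex

Can animals that master a word/nonword discrimination task be doing so
without any orthographic representations — no letters, no bigrams, no
words? `widelex` implements a *wide learning* account of lexical
decision: a single-layer Rescorla–Wagner network whose only inputs are
thousands of discrete low-level visual cues (local gradient orientation
and contrast measurements on the rendered letter string) and whose only
outputs are the two response categories WORD and NONWORD. The package is
aimed at computational cognitive modellers who want to train such
networks trial-by-trial along behavioural logs, generate synthetic
subjects when real logs are unavailable, and run the full behavioural
comparison battery between animal and model.

## The model

Each four-letter uppercase string is rendered deterministically from a
packaged bitmap font into four letter slots; per slot, a grid of cells
summarizes the image gradient into unsigned orientation histograms, and a
binary cue fires for every (slot, cell, orientation bin, contrast level)
whose summed gradient magnitude exceeds its threshold (1,920 cues under
the default geometry). Active cues project to the two outcomes through
associative weights `V` updated by the delta rule: on every trial, for
each outcome `o` with target λ_o (1 if `o` occurred, 0 otherwise), every
active cue `i` receives

    V[i, o] += η · (λ_o − Σ_{j active} V[j, o])

with a single free rate η (default 0.0055). Decisions are the argmax of
the summed activations. Two training regimes exist:

* **feedback-only** — the classic rule: one update toward the true label;
* **double learning** — to model an individual subject, the weights are
  first updated toward the response the subject actually gave on that
  trial, then toward the experimenter's feedback.

Because the rule is least-mean-squares on binary cues, its stationary
point is a cue-by-outcome linear regression; `equilibrium_oracle` solves
it in closed form and the test suite holds training to it.

## Worked example

```
python analysis/01_simulate_agents.py --trials 3000
python analysis/02_train_networks.py
python analysis/03_behavior_battery.py --exclude-first 500
```

which prints (seed 1):

```
subject-level tracking of agent by model:
  S1: agent acc 0.693, model acc 0.832, deriv-Spearman rho 0.171 (p 0.425)
  S2: agent acc 0.555, model acc 0.803, deriv-Spearman rho -0.284 (p 0.179)
  ...
OLD20 -> nonword accuracy: agent beta 0.632 (z 7.37), model beta 1.307 (z 20.20);
greater distance from words predicts more correct rejections.
```

Each synthetic subject learns the discrimination while its double-trained
network runs alongside it; the network is consistently more accurate than
its subject, and nonwords farther from the vocabulary (higher OLD20, the
mean edit distance to the 20 closest words) are rejected more reliably by
both. `analysis/04_transposition_experiment.py` then probes freshly
trained networks with nonwords derived from known words:

```
pooled type effect: beta -0.107, z -10.67, p 1.4e-26
sign test across runs: p = 0.001953
matched null control: beta 0.002, z 0.17 (expected n.s.)
```

i.e. swapping a word's middle letters fools the network into word
responses more often than replacing them, in every run, with a clean
matched control. Finally `analysis/05_random_effects.py` fits per-subject
logistic additive models of word-trial correctness with word, trigram, or
bigram factor blocks under one Bonferroni family:

```
agent: word factor significant for 6/6 subjects; n-gram factors significant in 3/30 tests
model: word factor significant for 6/6 subjects; n-gram factors significant in 0/30 tests
```

The generating subjects carry genuine per-word effects and no n-gram
structure — and the network's predictions show the very same signature,
although the network contains no words, bigrams or trigrams at any level
of representation. Statistical "evidence for lexical units" of this kind
therefore cannot establish that such units exist in the learner.

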