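"""Model-based statistics over trial logs and trained networks.

Four analyses live here:

* the effect of orthographic neighbourhood density (OLD20) on nonword
  accuracy, estimated by a logistic additive model with per-subject
  spline smooths of trial;
* the transposition-vs-substitution experiment: freshly trained
  feedback-only networks are probed with nonwords derived from known
  words, and the probability of an (erroneous) word response is modelled
  as a function of nonword type;
* slot-wise summaries of trained cue weights (how much associative
  support each letter position carries);
* the random-effects comparison: per subject, logistic additive models
  of word-trial correctness over training with word identity, trigram, or
  bigram random-effect factors, an AR(1) working correction on the
  trial series, and a Bonferroni-controlled family of significance tests.

Model fitting goes through statsmodels (binomial GLM with spline bases);
factor significance uses likelihood-ratio tests of the factor's block
against the nested model without it, with the likelihood-ratio statistic
deflated by the AR(1) effective-sample-size factor (1-rho)/(1+rho).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .learner import (
    LearnerConfig,
    TrainMode,
    TrialLog,
    WeightMatrix,
    decide,
    rw_update,
)
from .stimuli import (
    CueId,
    Derivation,
    FeatureConfig,
    Lexicon,
    Outcome,
    RejectionError,
    ValidationError,
    cue_cache,
    make_substitution_nonword,
    make_transposition_nonword,
    ngrams,
)
from .synthetic_behavior import sample_nonword_pool

__all__ = [
    "FitResult",
    "SlotWeightSummary",
    "MultipleTestPlan",
    "old20_frame",
    "old20_effect",
    "TranspositionResult",
    "transposition_experiment",
    "slot_weight_summary",
    "RandomEffectsResult",
    "random_effects_comparison",
]


@dataclass
class FitResult:
    """A fitted model's interesting numbers."""

    model_id: str
    coefficients: dict[str, tuple[float, float, float]]  # term -> (beta, z, p)
    smooth_terms: list[tuple[str, float, float]] = field(default_factory=list)
    ar1_rho: float | None = None
    fit_criterion: float = float("nan")  # penalized-likelihood score (AIC)
    n_obs: int = 0
    converged: bool = True
    extras: dict = field(default_factory=dict)

    def coef(self, term: str) -> tuple[float, float, float]:
        return self.coefficients[term]


@dataclass(frozen=True)
class MultipleTestPlan:
    """A Bonferroni family: per-test alpha = family alpha / n tests."""

    n_tests: int
    family_alpha: float = 0.05

    @property
    def per_test_alpha(self) -> float:
        return self.family_alpha / self.n_tests


# --------------------------------------------------------------------------
# OLD20 effect on nonword accuracy


def old20_frame(
    logs: Iterable[TrialLog],
    lex: Lexicon,
    n: int = 20,
    correctness: Mapping[str, Sequence[int]] | None = None,
    old20_values: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Tidy frame of nonword trials with an OLD20 covariate.

    ``correctness`` optionally substitutes another correctness sequence per
    subject (e.g. model-prediction correctness aligned with the log) for
    the subject's own; OLD20 values are computed against ``lex`` and cached
    per distinct string, or reused from ``old20_values``.
    """
    from .behavior_metrics import levenshtein_to_all

    entries = list(lex)
    cache: dict[str, float] = dict(old20_values or {})

    def old20_of(s: str) -> float:
        v = cache.get(s)
        if v is None:
            pool = [e for e in entries if e != s] if s in lex else entries
            d = levenshtein_to_all(s, pool)
            take = min(n, len(d))
            v = float(np.mean(np.partition(d, take - 1)[:take]))
            cache[s] = v
        return v

    rows = []
    for log in logs:
        corr_override = None if correctness is None else correctness[log.subject]
        for i, r in enumerate(log):
            if r.stimulus.lexicality is not Outcome.NONWORD:
                continue
            s = r.stimulus.string
            corr = r.correct if corr_override is None else int(corr_override[i])
            rows.append((log.subject, r.trial, s, old20_of(s), corr))
    return pd.DataFrame(
        rows, columns=["subject", "trial", "stimulus", "old20", "correct"]
    )


def _fit_glm(formula: str, df: pd.DataFrame) -> tuple[object, bool]:
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.glm(formula, df, family=sm.families.Binomial()).fit(maxiter=200)
            converged = bool(getattr(fit, "converged", True))
        except Exception as exc:  # separation / degenerate design
            raise ValidationError(f"GLM fit failed: {exc}") from exc
    return fit, converged


def old20_effect(
    trials: pd.DataFrame, spline_df: int = 5, grid: int = 50
) -> FitResult:
    """Logistic additive model of nonword accuracy on OLD20.

    ``accuracy ~ OLD20 + per-subject spline of trial``; returns the OLD20
    coefficient (log-odds per OLD20 unit) and a partial-effect curve on an
    OLD20 grid in ``extras['partial_effect']``.
    """
    req = {"subject", "trial", "old20", "correct"}
    missing = req - set(trials.columns)
    if missing:
        raise ValidationError(f"missing column(s): {sorted(missing)}")
    if trials["subject"].nunique() < 2:
        raise ValidationError("need at least two subjects")
    if trials["old20"].nunique() < 2:
        raise ValidationError("OLD20 covariate does not vary")
    df = trials.copy()
    df["trial_s"] = df.groupby("subject")["trial"].transform(
        lambda t: (t - t.min()) / max(t.max() - t.min(), 1)
    )
    formula = (
        "correct ~ old20 + C(subject) "
        f"+ C(subject):bs(trial_s, df={spline_df})"
    )
    fit, converged = _fit_glm(formula, df)
    beta = float(fit.params["old20"])
    z = float(fit.tvalues["old20"])
    p = float(fit.pvalues["old20"])
    g = np.linspace(df["old20"].min(), df["old20"].max(), grid)
    return FitResult(
        model_id="old20_effect",
        coefficients={"old20": (beta, z, p)},
        smooth_terms=[(f"by-subject bs(trial, df={spline_df})", float(spline_df), float("nan"))],
        fit_criterion=float(fit.aic),
        n_obs=int(fit.nobs),
        converged=converged,
        extras={"partial_effect": (g, beta * (g - g.mean()))},
    )


# --------------------------------------------------------------------------
# transposition / substitution experiment


@dataclass
class TranspositionResult:
    per_run: list[FitResult]
    pooled: FitResult
    control: FitResult
    sign_test_p: float
    run_effects: list[float]  # per-run P(word|transp) - P(word|subst)
    data: pd.DataFrame


def _type_fit(df: pd.DataFrame, model_id: str, reference: str,
              factor: str = "ntype") -> FitResult:
    """Logistic fit of P(word response) on nonword type.

    ``df`` carries one row per probed item with the number of networks
    probed (``n``) and the proportion of word responses (``word_resp``);
    the binomial fit with ``var_weights=n`` is the exact aggregated ML
    equivalent of the response-level fit.
    """
    formula = f"word_resp ~ C({factor}, Treatment('{reference}'))"
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.glm(
            formula, df, family=sm.families.Binomial(),
            var_weights=np.asarray(df["n"], dtype=float),
        ).fit(maxiter=200)
        converged = bool(getattr(fit, "converged", True))
    coefs = {}
    for name in fit.params.index:
        if name == "Intercept":
            continue
        level = name.split("T.")[-1].rstrip("]")
        coefs[level] = (
            float(fit.params[name]),
            float(fit.tvalues[name]),
            float(fit.pvalues[name]),
        )
    return FitResult(
        model_id=model_id,
        coefficients=coefs,
        fit_criterion=float(fit.aic),
        n_obs=int(fit.nobs),
        converged=converged,
    )


def transposition_experiment(
    lex: Lexicon,
    n_runs: int = 10,
    *,
    n_words: int | None = None,
    n_networks: int = 8,
    n_sub_draws: int = 2,
    pool_mult: int = 2,
    n_passes: int = 4,
    feature_cfg: FeatureConfig = FeatureConfig(),
    learner_cfg: LearnerConfig = LearnerConfig(),
    reference: str = "TRANSPOSITION",
    seed: int = 0,
) -> TranspositionResult:
    """Probe freshly trained networks with transposition vs substitution
    nonwords.

    Per run: take the words admitting both derivations (all of them by
    default, or a sample of ``n_words``), derive one transposition and
    ``n_sub_draws`` substitution nonwords per word, then train
    ``n_networks`` independent feedback-only networks on the words against
    ``pool_mult`` times as many random pool nonwords (``n_passes``
    shuffled passes each) and record whether each network calls each
    derived nonword a word. The type effect is a logistic coefficient on
    the pooled responses with ``reference`` as reference level, so with
    the default coding a negative SUBSTITUTION coefficient means
    transpositions attract more erroneous word responses. The run effect
    (for the across-run sign test) is the mean over networks of
    P(word | transposition) - P(word | substitution). A matched null
    contrast (two independent batches of substitution-type nonwords,
    arbitrarily labelled) is fitted the same way as a calibration control.
    Runs use the single-stage feedback update only — there is no observed
    subject to couple to.
    """
    cues = cue_cache(feature_cfg)
    rows = []
    per_run: list[FitResult] = []
    effects: list[float] = []
    for run in range(n_runs):
        rng = np.random.default_rng(seed + 1000 + run)
        candidates = [w for w in lex if w[1] != w[2]]
        rng.shuffle(candidates)
        picked, transp, subst, ctrl_a, ctrl_b = [], [], [], [], []
        for w in candidates:
            try:
                t_item = make_transposition_nonword(w, lex)
                s_items = [
                    make_substitution_nonword(w, lex, rng)
                    for _ in range(n_sub_draws)
                ]
                a_item = make_substitution_nonword(w, lex, rng)
                b_item = make_substitution_nonword(w, lex, rng)
            except RejectionError:
                continue
            picked.append(w)
            transp.append(t_item)
            subst.extend(s_items)
            ctrl_a.append(a_item)
            ctrl_b.append(b_item)
            if n_words is not None and len(picked) == n_words:
                break
        if n_words is not None and len(picked) < n_words:
            raise ValidationError(
                f"lexicon supports only {len(picked)} of {n_words} stimulus sets"
            )
        if not picked:
            raise ValidationError("no derivable stimulus sets in the lexicon")
        pools = [
            sample_nonword_pool(lex, pool_mult * len(picked), rng)
            for _ in range(n_networks)
        ]
        # shared cue->row index over every string this run touches
        strings = set(picked)
        strings.update(it.string for it in transp + subst + ctrl_a + ctrl_b)
        for pool in pools:
            strings.update(pool)
        cue_to_row: dict[str, int] = {}
        idx_of: dict[str, np.ndarray] = {}
        for s in sorted(strings):
            rows_s = []
            for c in sorted(cues(s)):
                r = cue_to_row.setdefault(c, len(cue_to_row))
                rows_s.append(r)
            idx_of[s] = np.asarray(rows_s, dtype=np.intp)
        probe_sets = {
            "TRANSPOSITION": transp,
            "SUBSTITUTION": subst,
            "CTRL_A": ctrl_a,
            "CTRL_B": ctrl_b,
        }
        net_effects = []
        # per-item word-response counts pooled over the run's networks
        success = {
            kind: np.zeros(len(items), dtype=int)
            for kind, items in probe_sets.items()
        }
        for net in range(n_networks):
            w_mat = WeightMatrix.with_index(cue_to_row)
            train_items = [(w, Outcome.WORD) for w in picked] * pool_mult + [
                (s, Outcome.NONWORD) for s in pools[net]
            ]
            for _ in range(n_passes):
                for i in rng.permutation(len(train_items)):
                    s, o = train_items[i]
                    w_mat.update_rows(idx_of[s], o, learner_cfg)
            rates = {}
            for kind, items in probe_sets.items():
                hits = np.array(
                    [
                        int(
                            decide(
                                w_mat.activations_rows(idx_of[it.string]),
                                learner_cfg,
                            )
                            == Outcome.WORD
                        )
                        for it in items
                    ]
                )
                success[kind] += hits
                rates[kind] = float(hits.mean())
            net_effects.append(rates["TRANSPOSITION"] - rates["SUBSTITUTION"])
        effects.append(float(np.mean(net_effects)))
        for kind, items in probe_sets.items():
            for j, it in enumerate(items):
                rows.append(
                    (
                        run,
                        kind,
                        it.string,
                        it.base,
                        n_networks,
                        success[kind][j] / n_networks,
                    )
                )
        run_df = pd.DataFrame(
            [r for r in rows if r[0] == run],
            columns=["run", "ntype", "stimulus", "base", "n", "word_resp"],
        )
        main_r = run_df[run_df["ntype"].isin(["TRANSPOSITION", "SUBSTITUTION"])]
        per_run.append(_type_fit(main_r, f"run{run}", reference))
    data = pd.DataFrame(
        rows, columns=["run", "ntype", "stimulus", "base", "n", "word_resp"]
    )
    main = data[data["ntype"].isin(["TRANSPOSITION", "SUBSTITUTION"])]
    pooled = _type_fit(main, "pooled", reference)
    ctrl = data[data["ntype"].isin(["CTRL_A", "CTRL_B"])]
    control = _type_fit(ctrl, "control", "CTRL_A")
    nonzero = [e for e in effects if e != 0]
    if nonzero:
        k = sum(e > 0 for e in nonzero)
        sign_p = float(sps.binomtest(k, len(nonzero), 0.5).pvalue)
    else:
        sign_p = 1.0
    return TranspositionResult(
        per_run=per_run,
        pooled=pooled,
        control=control,
        sign_test_p=sign_p,
        run_effects=effects,
        data=data,
    )


# --------------------------------------------------------------------------
# slot-wise weight summary


@dataclass(frozen=True)
class SlotWeightSummary:
    """Per-slot count and median magnitude of supported cue weights."""

    n_cues: tuple[int, ...]
    median_weight: tuple[float, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"slot": range(len(self.n_cues)), "n_cues": self.n_cues,
             "median_weight": self.median_weight}
        )


def slot_weight_summary(
    w: WeightMatrix,
    slot_of: Callable[[object], int] | None = None,
    mode: str = "pooled_abs",
) -> SlotWeightSummary:
    """Summarize trained weights by letter slot.

    Cues with any nonzero weight count as supported. ``mode`` selects the
    statistic: ``"pooled_abs"`` (default) takes the median of |w| pooled
    over both outcomes, ``"pooled_signed"`` the median of signed weights.
    ``slot_of`` maps a cue key to its slot; by default cue-id strings are
    parsed.
    """
    if mode not in ("pooled_abs", "pooled_signed"):
        raise ValidationError(f"unknown mode {mode!r}")
    if slot_of is None:
        slot_of = lambda c: CueId.parse(str(c)).slot  # noqa: E731
    per_slot: dict[int, list[float]] = {}
    counts: dict[int, int] = {}
    for cue, oname, val in w.to_rows():
        slot = slot_of(cue)
        per_slot.setdefault(slot, []).append(val)
    for slot, vals in per_slot.items():
        pairs = np.asarray(vals).reshape(-1, 2)
        nz = np.any(pairs != 0, axis=1)
        counts[slot] = int(nz.sum())
        per_slot[slot] = pairs[nz].ravel()
    slots = range(max(per_slot, default=-1) + 1)
    meds = []
    ns = []
    for s in slots:
        vals = np.asarray(per_slot.get(s, []))
        ns.append(counts.get(s, 0))
        if vals.size == 0:
            meds.append(0.0)
        elif mode == "pooled_abs":
            meds.append(float(np.median(np.abs(vals))))
        else:
            meds.append(float(np.median(vals)))
    return SlotWeightSummary(n_cues=tuple(ns), median_weight=tuple(meds))


# --------------------------------------------------------------------------
# random-effects comparison (word vs trigram vs bigram factors)


@dataclass
class RandomEffectsResult:
    fits: list[FitResult]
    table: pd.DataFrame
    plan: MultipleTestPlan


def _word_frame(log: TrialLog) -> pd.DataFrame:
    rows = [
        (r.trial, r.stimulus.string, r.correct)
        for r in log
        if r.stimulus.lexicality is Outcome.WORD
    ]
    df = pd.DataFrame(rows, columns=["trial", "word", "correct"])
    if len(df):
        df["trial_s"] = (df["trial"] - df["trial"].min()) / max(
            df["trial"].max() - df["trial"].min(), 1
        )
        df["tri1"] = df["word"].map(lambda w: ngrams(w, 3)[0])
        df["tri2"] = df["word"].map(lambda w: ngrams(w, 3)[1])
        df["bi1"] = df["word"].map(lambda w: ngrams(w, 2)[0])
        df["bi2"] = df["word"].map(lambda w: ngrams(w, 2)[1])
        df["bi3"] = df["word"].map(lambda w: ngrams(w, 2)[2])
    return df


def _ar1_rho(fit) -> float:
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        res = np.asarray(fit.resid_pearson, dtype=float)
    if len(res) < 3 or np.ptp(res) == 0:
        return 0.0
    r = np.corrcoef(res[:-1], res[1:])[0, 1]
    return float(r) if np.isfinite(r) else 0.0


def random_effects_comparison(
    logs: Sequence[TrialLog],
    *,
    spline_df: int = 8,
    family_alpha: float = 0.05,
    correctness: Mapping[str, Sequence[int]] | None = None,
) -> RandomEffectsResult:
    """Compare word, trigram and bigram factors as predictors of word-trial
    correctness, per subject.

    Per subject, three logistic additive models of correctness over
    training (spline of trial) add dummy-coded blocks for (a) word
    identity, (b) the two trigrams, (c) the three bigrams. Each factor is
    tested by a likelihood-ratio test against the model without that
    block; the LR statistic is deflated by (1-rho)/(1+rho) with rho the
    lag-1 autocorrelation of the base model's Pearson residuals (the AR(1)
    working correction). Tests form a single Bonferroni family of
    ``6 * n_subjects`` tests. ``correctness`` substitutes per-subject
    correctness sequences (e.g. model predictions aligned with the log).
    """
    if len(logs) < 2:
        raise ValidationError("need at least two subjects' logs")
    fits: list[FitResult] = []
    rows = []
    factor_terms = {
        "word": "C(word)",
        "tri1": "C(tri1)",
        "tri2": "C(tri2)",
        "bi1": "C(bi1)",
        "bi2": "C(bi2)",
        "bi3": "C(bi3)",
    }
    model_factors = {
        "word": ["word"],
        "trigram": ["tri1", "tri2"],
        "bigram": ["bi1", "bi2", "bi3"],
    }
    for log in logs:
        df = _word_frame(log)
        if correctness is not None:
            corr = np.asarray(correctness[log.subject])
            word_pos = [
                i for i, r in enumerate(log)
                if r.stimulus.lexicality is Outcome.WORD
            ]
            df["correct"] = corr[word_pos].astype(int)
        subj = log.subject
        base_formula = f"correct ~ bs(trial_s, df={spline_df})"
        base_fit, _ = _fit_glm(base_formula, df)
        rho = _ar1_rho(base_fit)
        deflate = (1 - rho) / (1 + rho)
        for model_name, factors in model_factors.items():
            unfittable = [f for f in factors if df[f].nunique() < 2]
            full_terms = " + ".join(factor_terms[f] for f in factors
                                    if f not in unfittable)
            if full_terms:
                full_formula = f"{base_formula} + {full_terms}"
                full_fit, conv = _fit_glm(full_formula, df)
            else:
                full_fit, conv = base_fit, True
            fits.append(
                FitResult(
                    model_id=f"{subj}:{model_name}",
                    coefficients={},
                    smooth_terms=[(f"bs(trial, df={spline_df})",
                                   float(spline_df), float("nan"))],
                    ar1_rho=rho,
                    fit_criterion=float(full_fit.aic),
                    n_obs=int(full_fit.nobs),
                    converged=conv,
                )
            )
            for f in factors:
                label = "word" if f == "word" else {
                    "tri1": "trigram1", "tri2": "trigram2",
                    "bi1": "bigram1", "bi2": "bigram2", "bi3": "bigram3",
                }[f]
                if f in unfittable:
                    rows.append((subj, label, float("nan"), 0, float("nan"), False))
                    continue
                others = [x for x in factors if x != f and x not in unfittable]
                red_terms = " + ".join(factor_terms[x] for x in others)
                red_formula = (
                    f"{base_formula} + {red_terms}" if red_terms else base_formula
                )
                red_fit, _ = _fit_glm(red_formula, df)
                lr = 2.0 * (full_fit.llf - red_fit.llf)
                # n-gram blocks can be near-collinear with each other (and
                # with word identity), so the honest df is the rank gain of
                # the design, not the column count
                dof = int(
                    np.linalg.matrix_rank(full_fit.model.exog)
                    - np.linalg.matrix_rank(red_fit.model.exog)
                )
                if dof <= 0 or lr < 0:
                    rows.append((subj, label, float("nan"), dof, float("nan"), False))
                    continue
                stat = deflate * lr
                p = float(sps.chi2.sf(stat, dof))
                rows.append((subj, label, float(stat), dof, p, p))
    plan = MultipleTestPlan(n_tests=6 * len(logs), family_alpha=family_alpha)
    table = pd.DataFrame(
        rows, columns=["subject", "factor", "statistic", "df", "p", "significant"]
    )
    table["significant"] = table["p"] < plan.per_test_alpha
    return RandomEffectsResult(fits=fits, table=table, plan=plan)
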