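"""Synthetic experiment schedules and simulated subjects.

The original lexical-decision trial logs from the baboon touch-screen
experiments are not publicly deposited, so this module generates stand-in
logs that carry the statistical structure every downstream analysis
assumes: words enter the schedule incrementally and are repeated to a
criterion, so novel words are sparse; nonwords are abundant and almost
always novel (drawn once from a large pool); simulated subjects hold an
internal error-driven learner but respond through an attentional filter —
a nonword response bias that decays over training and a lapse rate that
drifts from block to block, producing the block-to-block accuracy
fluctuation the time-series analyses feed on.

Everything here is seeded and byte-reproducible; none of it is fitted to
the real animals.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .learner import LearnerConfig, TrialLog, TrialRecord, WeightMatrix, decide, rw_update
from .stimuli import (
    Derivation,
    Lexicon,
    Outcome,
    StimulusItem,
    ValidationError,
    pool_item,
    word_item,
)

__all__ = [
    "ScheduleConfig",
    "AgentConfig",
    "AGENT_PRESETS",
    "build_schedule",
    "sample_nonword_pool",
    "simulate_agent",
    "simulate_word_effect_log",
    "simulate_old20_trials",
    "write_trial_log",
    "read_trial_log",
    "TRIAL_LOG_HEADER",
]

TRIAL_LOG_HEADER = [
    "subject",
    "trial",
    "stimulus",
    "lexicality",
    "response",
    "correct",
    "first_encounter",
    "derivation",
]

_BLOCK = 100  # trials per attentional block


@dataclass(frozen=True)
class ScheduleConfig:
    """Design of one subject's trial sequence.

    ``intro_criterion = (window, accuracy)`` governs the staircase: a new
    word is introduced once the trailing ``window`` presentations of the
    newest word reach the criterion accuracy under a repetition proxy (a
    presentation counts as proxy-correct from the word's second
    presentation onward — an idealization of error-driven one-shot
    memorization). Nonwords are one-shot: drawn without replacement from
    ``nonword_pool``.
    """

    n_trials: int = 60_000
    p_word_trial: float = 0.5
    words_pool: Lexicon = None  # type: ignore[assignment]
    nonword_pool: tuple[str, ...] = ()
    intro_criterion: tuple[int, float] = (5, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        # the endpoints are permitted as degenerate all-word / all-nonword designs
        if not (0 <= self.p_word_trial <= 1):
            raise ValidationError("p_word_trial must lie in [0, 1]")
        window, acc = self.intro_criterion
        if window < 1 or not (0 < acc <= 1):
            raise ValidationError("intro_criterion must satisfy window>=1, 0<acc<=1")
        if self.words_pool is None or len(self.words_pool) == 0:
            raise ValidationError("words_pool must be a non-empty Lexicon")


@dataclass(frozen=True)
class AgentConfig:
    """Internal state of a simulated subject.

    ``internal_eta`` drives the agent's own feedback-trained network;
    ``bias_nonword`` is the initial probability of overriding a word
    decision with NONWORD, decaying exponentially with ``bias_halflife``
    trials; the lapse rate starts at ``lapse_rate`` and performs a
    reflected random walk (sd ``lapse_drift_sd``) from one 100-trial block
    to the next — lapsed trials are answered uniformly at random.
    """

    internal_eta: float = 0.005
    bias_nonword: float = 0.5
    bias_halflife: float = 10_000.0
    lapse_rate: float = 0.1
    lapse_drift_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.bias_nonword, self.lapse_rate):
            if not (0 <= p <= 1):
                raise ValidationError("probabilities must lie in [0, 1]")
        if not self.bias_halflife > 0:
            raise ValidationError("bias_halflife must be positive")
        if self.lapse_drift_sd < 0:
            raise ValidationError("lapse_drift_sd must be non-negative")


#: Six qualitative subject profiles. S2 is the persistent-bias,
#: small-vocabulary profile (strong nonword bias that never fully decays,
#: frequent lapses); S4 the fast, large-vocabulary profile (weak bias,
#: rare lapses, upward late trend). The others interpolate. Qualitative
#: targets only — nothing is fitted to the real animals.
AGENT_PRESETS: dict[str, AgentConfig] = {
    "S1": AgentConfig(bias_nonword=0.5, bias_halflife=8_000, lapse_rate=0.10,
                      lapse_drift_sd=0.02),
    "S2": AgentConfig(bias_nonword=0.9, bias_halflife=40_000, lapse_rate=0.18,
                      lapse_drift_sd=0.03),
    "S3": AgentConfig(bias_nonword=0.6, bias_halflife=15_000, lapse_rate=0.12,
                      lapse_drift_sd=0.025),
    "S4": AgentConfig(bias_nonword=0.3, bias_halflife=3_000, lapse_rate=0.05,
                      lapse_drift_sd=0.015),
    "S5": AgentConfig(bias_nonword=0.7, bias_halflife=12_000, lapse_rate=0.08,
                      lapse_drift_sd=0.02),
    "S6": AgentConfig(bias_nonword=0.4, bias_halflife=6_000, lapse_rate=0.15,
                      lapse_drift_sd=0.03),
}


def sample_nonword_pool(
    lex: Lexicon, n: int, rng: np.random.Generator
) -> tuple[str, ...]:
    """Rejection-sample ``n`` distinct random four-letter nonwords."""
    letters = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
    pool: dict[str, None] = {}
    while len(pool) < n:
        draw = rng.integers(0, 26, size=(max(64, n - len(pool)), 4))
        for row in draw:
            s = "".join(letters[row])
            if s not in lex and s not in pool:
                pool[s] = None
                if len(pool) == n:
                    break
    return tuple(pool)


def build_schedule(cfg: ScheduleConfig) -> list[StimulusItem]:
    """Emit one subject's ordered stimulus sequence.

    Word trials occur with probability ``p_word_trial`` and present a
    uniform draw from the currently introduced words; because the newest
    word gets only its uniform share of presentations, the introduction
    rate slows as the vocabulary grows — first encounters of words become
    increasingly sparse, as in the staircase design the analyses assume.
    """
    rng = np.random.default_rng(cfg.seed)
    window, criterion = cfg.intro_criterion
    words = list(cfg.words_pool)
    introduced = 1  # the first word is available from trial 1
    newest_count = 0  # presentations of the newest word so far
    proxy: list[int] = []  # trailing proxy-correctness of the newest word
    pool_iter = iter(cfg.nonword_pool)
    out: list[StimulusItem] = []
    for t in range(1, cfg.n_trials + 1):
        if rng.random() < cfg.p_word_trial:
            i = int(rng.integers(introduced))
            w = words[i]
            if i == introduced - 1:
                newest_count += 1
                proxy.append(int(newest_count >= 2))
                if len(proxy) > window:
                    proxy.pop(0)
                if (
                    len(proxy) == window
                    and sum(proxy) / window >= criterion
                    and introduced < len(words)
                ):
                    introduced += 1
                    newest_count = 0
                    proxy = []
            out.append(word_item(w))
        else:
            try:
                s = next(pool_iter)
            except StopIteration:
                raise ValidationError(
                    f"nonword pool exhausted at trial {t}"
                ) from None
            out.append(pool_item(s))
    return out


def _reflect01(x: float) -> float:
    """Reflect a real into [0, 1]."""
    x = math.fmod(x, 2.0)
    if x < 0:
        x += 2.0
    return 2.0 - x if x > 1.0 else x


def simulate_agent(
    schedule: Sequence[StimulusItem],
    stimuli_cues: Callable[[str], Iterable] | dict,
    a_cfg: AgentConfig,
    subject: str = "S1",
) -> TrialLog:
    """Run one simulated subject through a schedule and log its behaviour.

    The agent's internal network learns from feedback only (truth label,
    single-stage update). Per trial: with probability lapse(block) the
    response is uniform random; otherwise the internal argmax decision is
    overridden to NONWORD with probability bias(t). The log is fully
    reproducible from the config seed.
    """
    if not callable(stimuli_cues):
        mapping = stimuli_cues
        stimuli_cues = lambda s: mapping[s]  # noqa: E731
    rng = np.random.default_rng(a_cfg.seed)
    l_cfg = LearnerConfig(eta=a_cfg.internal_eta, tie_break="NONWORD")
    w = WeightMatrix()
    lapse = a_cfg.lapse_rate
    seen: set[str] = set()
    records: list[TrialRecord] = []
    for t, item in enumerate(schedule, start=1):
        if t > 1 and (t - 1) % _BLOCK == 0 and a_cfg.lapse_drift_sd > 0:
            lapse = _reflect01(lapse + rng.normal(0.0, a_cfg.lapse_drift_sd))
        cues = stimuli_cues(item.string)
        if rng.random() < lapse:
            resp = Outcome.WORD if rng.random() < 0.5 else Outcome.NONWORD
        else:
            resp = decide(w.activations(cues), l_cfg)
            bias = a_cfg.bias_nonword * 0.5 ** ((t - 1) / a_cfg.bias_halflife)
            if bias > 0 and rng.random() < bias:
                resp = Outcome.NONWORD
        rw_update(w, cues, item.lexicality, l_cfg)
        fe = int(item.string not in seen)
        seen.add(item.string)
        records.append(
            TrialRecord(
                subject=subject,
                trial=t,
                stimulus=item,
                response=resp,
                correct=int(resp == item.lexicality),
                first_encounter=fe,
            )
        )
    return TrialLog(records)


def simulate_word_effect_log(
    words: Sequence[str],
    n_trials: int,
    *,
    word_sd: float = 0.8,
    p_word: float = 0.5,
    lexicon: Lexicon | None = None,
    base_logit: Callable[[np.ndarray], np.ndarray] | None = None,
    subject: str = "G1",
    seed: int = 0,
) -> TrialLog:
    """Trial log with genuine per-word random intercepts and no n-gram
    structure.

    On word trials, correctness is Bernoulli with logit
    ``base_logit(t) + b_word``, ``b_word ~ N(0, word_sd)``; on nonword
    trials (one-shot random strings, proportion ``1 - p_word``) the word
    intercept term is absent. Used for parameter/structure recovery of the
    random-effects comparison: by construction, word identity carries
    signal while bigrams and trigrams carry none beyond what they inherit
    from words. The nonword trials give a network trained along the log a
    meaningful decision boundary, so its word-trial predictions can
    express the word effect too.
    """
    rng = np.random.default_rng(seed)
    if base_logit is None:
        base_logit = lambda t: -0.5 + 1.5 * t / max(n_trials, 1)  # noqa: E731
    b = {w: rng.normal(0.0, word_sd) for w in words}
    n_nonword_max = int(n_trials * (1 - p_word) + 4 * math.sqrt(n_trials) + 10)
    pool = iter(
        sample_nonword_pool(
            lexicon if lexicon is not None else Lexicon(words),
            min(n_nonword_max, n_trials),
            rng,
        )
    )
    idx = rng.integers(0, len(words), size=n_trials)
    t_arr = np.arange(1, n_trials + 1, dtype=float)
    base = base_logit(t_arr)
    records = []
    seen: set[str] = set()
    for t in range(1, n_trials + 1):
        if rng.random() < p_word:
            wstr = words[int(idx[t - 1])]
            item = word_item(wstr)
            logit = base[t - 1] + b[wstr]
        else:
            item = pool_item(next(pool))
            logit = base[t - 1]
        p = 1.0 / (1.0 + math.exp(-logit))
        corr = int(rng.random() < p)
        truth = item.lexicality
        resp = truth if corr else Outcome(1 - int(truth))
        fe = int(item.string not in seen)
        seen.add(item.string)
        records.append(TrialRecord(subject, t, item, resp, corr, fe))
    return TrialLog(records)


def simulate_old20_trials(
    lex: Lexicon,
    n_trials: int = 20_000,
    *,
    slope: float = 0.8,
    n_subjects: int = 2,
    trend_amp: float = 1.0,
    seed: int = 0,
):
    """Nonword trials whose accuracy carries a known OLD20 log-odds slope.

    One-shot random nonwords are scored against ``lex``; correctness is
    Bernoulli with logit ``trend(t) + slope * (OLD20 - mean OLD20)``,
    where each subject gets its own smooth trend. Ground truth for
    parameter recovery of the OLD20 effect model. Returns a tidy frame
    with columns subject, trial, stimulus, old20, correct.
    """
    import pandas as pd

    from .behavior_metrics import levenshtein_to_all

    rng = np.random.default_rng(seed)
    strings = sample_nonword_pool(lex, n_trials, rng)
    entries = list(lex)
    old20 = np.array(
        [
            float(np.mean(np.partition(levenshtein_to_all(s, entries), 19)[:20]))
            for s in strings
        ]
    )
    centered = old20 - old20.mean()
    per_subj = n_trials // n_subjects
    rows = []
    k = 0
    for j in range(n_subjects):
        phase = rng.uniform(0, 2 * np.pi)
        amp = trend_amp * rng.uniform(0.5, 1.0)
        for t in range(1, per_subj + 1):
            trend = amp * np.sin(2 * np.pi * t / per_subj + phase)
            logit = trend + slope * centered[k]
            p = 1.0 / (1.0 + np.exp(-logit))
            rows.append(
                (f"O{j + 1}", t, strings[k], old20[k], int(rng.random() < p))
            )
            k += 1
    return pd.DataFrame(
        rows, columns=["subject", "trial", "stimulus", "old20", "correct"]
    )


# --------------------------------------------------------------------------
# trial-log CSV dialect (bit-exact: LF endings, uppercase values)


def write_trial_log(log: TrialLog, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh, lineterminator="\n")
        wr.writerow(TRIAL_LOG_HEADER)
        for r in log:
            wr.writerow(
                [
                    r.subject,
                    r.trial,
                    r.stimulus.string,
                    r.stimulus.lexicality.name,
                    r.response.name,
                    r.correct,
                    r.first_encounter,
                    r.stimulus.derivation.value,
                ]
            )


def read_trial_log(path: str | Path) -> TrialLog:
    with open(path, newline="", encoding="utf-8") as fh:
        rd = csv.reader(fh)
        header = next(rd)
        missing = [c for c in TRIAL_LOG_HEADER if c not in header]
        if missing:
            raise ValidationError(
                f"trial-log {path} missing column(s): {', '.join(missing)}"
            )
        col = {c: header.index(c) for c in TRIAL_LOG_HEADER}
        records = []
        for row in rd:
            item = StimulusItem(
                row[col["stimulus"]],
                Outcome[row[col["lexicality"]]],
                Derivation(row[col["derivation"]]),
            )
            records.append(
                TrialRecord(
                    subject=row[col["subject"]],
                    trial=int(row[col["trial"]]),
                    stimulus=item,
                    response=Outcome[row[col["response"]]],
                    correct=int(row[col["correct"]]),
                    first_encounter=int(row[col["first_encounter"]]),
                )
            )
    return TrialLog(records)
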