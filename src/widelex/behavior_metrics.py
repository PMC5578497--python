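"""Descriptive time-series and similarity statistics for trial logs.

Binned accuracy trajectories, their first differences, lagged
cross-correlations between two trajectories, Spearman correlation of
first derivatives, generalization curves (cumulative novel-word accuracy,
first-encounter nonword accuracy), the survival function of
correct-response run lengths, and the OLD-n orthographic neighbourhood
measure built on a unit-cost Levenshtein distance.

Conventions used throughout: accuracy bins hold exactly ``bin_size``
trials (a trailing partial bin is dropped); cross-correlograms are plain
Pearson correlations on the overlapping window with no detrending, shown
against the usual +-1.96/sqrt(n) white-noise bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .learner import TrialLog
from .stimuli import Lexicon, Outcome, ValidationError

__all__ = [
    "AccuracySeries",
    "CrossCorrResult",
    "RunLengthDist",
    "Old20Value",
    "binned_accuracy",
    "bin_series",
    "accuracy_deltas",
    "cross_correlation",
    "derivative_spearman",
    "cumulative_novel_word_accuracy",
    "novel_nonword_accuracy",
    "run_length_exceedance",
    "levenshtein",
    "old_n",
]


@dataclass(frozen=True)
class AccuracySeries:
    """Accuracy means over consecutive fixed-size bins of trials."""

    bin_size: int
    values: tuple[float, ...]
    start_trial: int = 1

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class CrossCorrResult:
    """Lagged Pearson correlations between two aligned series."""

    lags: tuple[int, ...]
    r: tuple[float, ...]  # NaN where a window had zero variance
    n: int
    conf_bound: float  # 1.96 / sqrt(n)
    n_overlap: tuple[int, ...] = ()

    def r_at(self, lag: int) -> float:
        return self.r[self.lags.index(lag)]


@dataclass(frozen=True)
class RunLengthDist:
    """Survival function of maximal correct-run lengths."""

    ks: tuple[int, ...]
    p_exceed: tuple[float, ...]
    n_runs: int


@dataclass(frozen=True)
class Old20Value:
    """Mean Levenshtein distance to the n closest lexicon entries."""

    target: str
    n_neighbors: int
    value: float
    insufficient: bool = False  # fewer than n_neighbors entries available


def _correct_array(log: TrialLog | Sequence[int]) -> np.ndarray:
    if isinstance(log, TrialLog):
        return log.correctness().astype(float)
    return np.asarray(log, dtype=float)


def bin_series(x: Sequence[float], B: int) -> np.ndarray:
    """Means of consecutive bins of ``B`` values; trailing partial bin dropped."""
    if B < 1:
        raise ValidationError("bin size must be >= 1")
    x = np.asarray(x, dtype=float)
    n_bins = len(x) // B
    if n_bins == 0:
        return np.empty(0)
    return x[: n_bins * B].reshape(n_bins, B).mean(axis=1)


def binned_accuracy(
    log: TrialLog | Sequence[int], B: int = 100, exclude_first: int = 0
) -> AccuracySeries:
    """Binned accuracy after dropping the first ``exclude_first`` trials.

    Fewer than ``B`` remaining trials yield an empty series, not an error.
    """
    if exclude_first < 0:
        raise ValidationError("exclude_first must be >= 0")
    x = _correct_array(log)[exclude_first:]
    return AccuracySeries(
        bin_size=B, values=tuple(bin_series(x, B)), start_trial=exclude_first + 1
    )


def accuracy_deltas(s: AccuracySeries | Sequence[float]) -> np.ndarray:
    """First differences of a binned accuracy series."""
    x = s.as_array() if isinstance(s, AccuracySeries) else np.asarray(s, dtype=float)
    if len(x) < 2:
        raise ValidationError("need at least two bins to difference")
    return np.diff(x)


def cross_correlation(
    a: Sequence[float], b: Sequence[float], max_lag: int
) -> CrossCorrResult:
    """Pearson correlation of ``a[t]`` with ``b[t + lag]`` for each lag.

    Windows with zero variance on either side produce NaN for that lag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("series must be 1-D and of equal length")
    n = len(a)
    if n < max_lag + 2:
        raise ValidationError("series too short for the requested max_lag")
    lags = tuple(range(-max_lag, max_lag + 1))
    rs, overlaps = [], []
    for lag in lags:
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        overlaps.append(len(x))
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rs.append(float("nan"))
        else:
            rs.append(float(sps.pearsonr(x, y).statistic))
    return CrossCorrResult(
        lags=lags,
        r=tuple(rs),
        n=n,
        conf_bound=1.96 / np.sqrt(n),
        n_overlap=tuple(overlaps),
    )


def derivative_spearman(
    a: AccuracySeries | Sequence[float], b: AccuracySeries | Sequence[float]
) -> tuple[float, float]:
    """Spearman correlation of the two series' first derivatives.

    Returns (rho, p) with the standard large-sample p-value; a constant
    delta vector makes the statistic undefined and yields (nan, nan) with
    a warning.
    """
    da, db = accuracy_deltas(a), accuracy_deltas(b)
    if len(da) != len(db):
        raise ValidationError("series must have equal length")
    if np.ptp(da) == 0 or np.ptp(db) == 0:
        warnings.warn("constant delta vector: Spearman rho undefined")
        return float("nan"), float("nan")
    res = sps.spearmanr(da, db)
    return float(res.statistic), float(res.pvalue)


def cumulative_novel_word_accuracy(log: TrialLog) -> np.ndarray:
    """Running-mean accuracy over first encounters of words, in order.

    The curve's length equals the number of distinct words in the log.
    """
    firsts = [
        r.correct
        for r in log
        if r.stimulus.lexicality is Outcome.WORD and r.first_encounter
    ]
    if not firsts:
        return np.empty(0)
    x = np.asarray(firsts, dtype=float)
    return np.cumsum(x) / np.arange(1, len(x) + 1)


def novel_nonword_accuracy(log: TrialLog, B: int = 100) -> AccuracySeries:
    """First-encounter nonword accuracy binned by ``B`` in encounter order."""
    firsts = [
        r.correct
        for r in log
        if r.stimulus.lexicality is Outcome.NONWORD and r.first_encounter
    ]
    return AccuracySeries(bin_size=B, values=tuple(bin_series(firsts, B)))


def run_length_exceedance(
    log: TrialLog | Sequence[int], k_max: int
) -> RunLengthDist:
    """P(maximal correct-run length > k) for k = 0..k_max.

    The denominator is the number of maximal runs of consecutive correct
    responses. With no correct responses at all, every probability is 0
    and ``n_runs`` is 0.
    """
    x = _correct_array(log).astype(int)
    runs: list[int] = []
    cur = 0
    for v in x:
        if v == 1:
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    ks = tuple(range(k_max + 1))
    if not runs:
        return RunLengthDist(ks=ks, p_exceed=(0.0,) * len(ks), n_runs=0)
    arr = np.asarray(runs)
    p = tuple(float(np.mean(arr > k)) for k in ks)
    return RunLengthDist(ks=ks, p_exceed=p, n_runs=len(runs))


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def levenshtein_to_all(target: str, entries: Sequence[str]) -> np.ndarray:
    """Unit-cost edit distance from ``target`` to every entry, vectorized.

    Runs the same dynamic program as :func:`levenshtein` with the entry
    axis vectorized; the scalar implementation is the reference the tests
    check this against.
    """
    if not entries:
        return np.empty(0, dtype=int)
    L = max(len(e) for e in entries)
    codes = np.full((len(entries), L), -1, dtype=np.int16)
    for i, e in enumerate(entries):
        codes[i, : len(e)] = [ord(c) for c in e]
    lens = np.array([len(e) for e in entries])
    prev = np.tile(np.arange(L + 1), (len(entries), 1))
    for i, ca in enumerate(target, start=1):
        cur = np.empty_like(prev)
        cur[:, 0] = i
        oa = ord(ca)
        for j in range(1, L + 1):
            sub = prev[:, j - 1] + (codes[:, j - 1] != oa)
            cur[:, j] = np.minimum(np.minimum(prev[:, j] + 1, cur[:, j - 1] + 1), sub)
        prev = cur
    return prev[np.arange(len(entries)), lens]


def old_n(target: str, lex: Lexicon, n: int = 20) -> Old20Value:
    """Mean distance from ``target`` to its ``n`` closest lexicon entries.

    One instance of the target itself is excluded when present. Distances
    are sorted ascending with ties kept in lexicon order; when fewer than
    ``n`` entries are available the mean is over all of them and the
    result is flagged insufficient.
    """
    entries = list(lex)
    if target in lex:
        entries.remove(target)
    if not entries:
        raise ValidationError("lexicon is empty after excluding the target")
    dists = sorted(levenshtein(target, w) for w in entries)
    take = min(n, len(dists))
    return Old20Value(
        target=target,
        n_neighbors=n,
        value=float(np.mean(dists[:take])),
        insufficient=take < n,
    )
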