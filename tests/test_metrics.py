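"""Time-series and similarity statistics: exact examples, calibrations,
metric properties of the edit distance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp

from widelex.behavior_metrics import (
    AccuracySeries,
    accuracy_deltas,
    bin_series,
    binned_accuracy,
    cross_correlation,
    cumulative_novel_word_accuracy,
    derivative_spearman,
    levenshtein,
    levenshtein_to_all,
    novel_nonword_accuracy,
    old_n,
    run_length_exceedance,
)
from widelex.learner import TrialLog, TrialRecord
from widelex.stimuli import Lexicon, Outcome, ValidationError, pool_item, word_item

W, NW = Outcome.WORD, Outcome.NONWORD


def _log_from_pattern(pattern):
    """Build a trial log realizing a (lexicality, correct) pattern."""
    records, seen = [], set()
    strings = iter(
        f"{a}{b}{c}{d}"
        for a in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        for b in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        for c in "AB"
        for d in "AB"
    )
    for i, (lex_label, correct) in enumerate(pattern, start=1):
        s = next(strings)
        item = word_item(s) if lex_label is W else pool_item(s)
        resp = item.lexicality if correct else Outcome(1 - int(item.lexicality))
        records.append(TrialRecord("M1", i, item, resp, correct, 1))
        seen.add(s)
    return TrialLog(records)


# -- binning ---------------------------------------------------------------


def test_binned_accuracy_examples():
    assert binned_accuracy([1] * 300, 100).values == (1.0, 1.0, 1.0)
    alt = [1, 0] * 125  # 250 trials alternating
    assert binned_accuracy(alt, 100).values == (0.5, 0.5)
    series = binned_accuracy([1] * 6000, 100, exclude_first=5000)
    assert len(series) == 10
    assert binned_accuracy([1] * 50, 100).values == ()


def test_accuracy_deltas():
    assert np.allclose(accuracy_deltas([0.5, 0.7, 0.6]), [0.2, -0.1])
    assert np.allclose(accuracy_deltas([0.4] * 5), 0.0)
    x = np.array([0.1, 0.3, 0.2, 0.5])
    assert np.allclose(accuracy_deltas(np.cumsum(x)), x[1:] + 0)  # inverse
    with pytest.raises(ValidationError):
        accuracy_deltas([0.5])


# -- cross-correlation -----------------------------------------------------


def test_crosscorr_identity_and_shift(rng):
    a = rng.normal(size=60)
    cc = cross_correlation(a, a, 5)
    assert cc.r_at(0) == pytest.approx(1.0)
    assert np.nanargmax(cc.r) == cc.lags.index(0)
    # b lagging a by 3 (b[t+3] == a[t]) puts the argmax at lag +3
    base = rng.normal(size=80)
    cc3 = cross_correlation(base[3:], base[:-3], 5)
    assert cc3.lags[int(np.nanargmax(cc3.r))] == 3


def test_crosscorr_flags_zero_variance_windows():
    a = np.ones(30)
    b = np.arange(30.0)
    cc = cross_correlation(a, b, 2)
    assert all(np.isnan(r) for r in cc.r)


def test_crosscorr_conf_bound_calibration(rng):
    """|r(0)| should exceed 1.96/sqrt(n) in about 5% of white-noise pairs."""
    n, reps, hits = 200, 1000, 0
    bound = 1.96 / np.sqrt(n)
    for _ in range(reps):
        a, b = rng.normal(size=n), rng.normal(size=n)
        r = np.corrcoef(a, b)[0, 1]
        hits += abs(r) > bound
    frac = hits / reps
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


# -- derivative Spearman ---------------------------------------------------


def test_derivative_spearman_examples():
    rho, _ = derivative_spearman([0, 1, 3], [0, 2, 3])
    assert rho == pytest.approx(-1.0)
    a = [0.1, 0.5, 0.2, 0.9, 0.4]
    rho, _ = derivative_spearman(a, a)
    assert rho == pytest.approx(1.0)
    with pytest.warns(UserWarning):
        rho, p = derivative_spearman([1, 2, 3], [0.3, 0.1, 0.9])
    assert np.isnan(rho) and np.isnan(p)


def test_derivative_spearman_p_uniform_under_null(rng):
    """Permutation-style null: random-walk inputs give i.i.d. (hence
    exchangeable) deltas, under which the reported p is uniform."""
    reps, n = 1000, 51
    ps = []
    for _ in range(reps):
        a = np.cumsum(rng.normal(size=n))
        b = np.cumsum(rng.normal(size=n))
        ps.append(derivative_spearman(a, b)[1])
    ps = np.asarray(ps)
    for q in (0.05, 0.25, 0.5):
        assert abs((ps < q).mean() - q) < 3 * np.sqrt(q * (1 - q) / reps)


# -- generalization curves -------------------------------------------------


def test_cumulative_novel_word_accuracy_running_mean():
    log = _log_from_pattern([(W, 1), (W, 0), (NW, 1), (W, 1)])
    assert np.allclose(cumulative_novel_word_accuracy(log), [1, 0.5, 2 / 3])
    log0 = _log_from_pattern([(W, 0), (W, 0)])
    assert np.allclose(cumulative_novel_word_accuracy(log0), [0, 0])
    assert cumulative_novel_word_accuracy(_log_from_pattern([(NW, 1)])).size == 0


def test_novel_nonword_accuracy_matches_brute_force(rng):
    pattern = [(W if rng.random() < 0.4 else NW, int(rng.random() < 0.7))
               for _ in range(500)]
    log = _log_from_pattern(pattern)
    series = novel_nonword_accuracy(log, 50)
    brute = [r.correct for r in log
             if r.stimulus.lexicality is NW and r.first_encounter]
    expected = [np.mean(brute[i:i + 50])
                for i in range(0, len(brute) - len(brute) % 50, 50)]
    assert np.allclose(series.values, expected)
    assert series.bin_size == 50


# -- run lengths -----------------------------------------------------------


def test_run_length_exceedance_hand_enumeration():
    d = run_length_exceedance([1, 1, 0, 1], 3)
    # maximal runs {2, 1}: P(len > 1) = 1/2
    assert d.n_runs == 2
    assert d.p_exceed[0] == 1.0
    assert d.p_exceed[1] == 0.5
    assert d.p_exceed[2] == 0.0


def test_run_length_exceedance_degenerate_cases():
    all_c = run_length_exceedance([1] * 10, 5)
    assert all_c.p_exceed == (1.0,) * 6 and all_c.n_runs == 1
    alt = run_length_exceedance([1, 0, 1, 0], 2)
    assert alt.p_exceed == (1.0, 0.0, 0.0)
    none = run_length_exceedance([0, 0, 0], 2)
    assert none.n_runs == 0 and none.p_exceed == (0.0, 0.0, 0.0)


def test_run_length_survival_is_monotone(rng):
    x = (rng.random(400) < 0.7).astype(int)
    d = run_length_exceedance(x, 20)
    assert all(a >= b for a, b in zip(d.p_exceed, d.p_exceed[1:]))


# -- edit distance and OLD-n ----------------------------------------------


def _lev_recursive(a, b):
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        _lev_recursive(a[1:], b) + 1,
        _lev_recursive(a, b[1:]) + 1,
        _lev_recursive(a[1:], b[1:]) + (a[0] != b[0]),
    )


@pytest.mark.parametrize(
    "a,b,d", [("TORE", "TORE", 0), ("TORE", "TARE", 1), ("EFTD", "TORE", 4)]
)
def test_levenshtein_examples(a, b, d):
    assert levenshtein(a, b) == d


def test_levenshtein_against_recursive_oracle(rng):
    letters = "ABC"  # small alphabet exercises ties and repeats
    for _ in range(300):
        a = "".join(rng.choice(list(letters), rng.integers(0, 6)))
        b = "".join(rng.choice(list(letters), rng.integers(0, 6)))
        assert levenshtein(a, b) == _lev_recursive(a, b)


def test_levenshtein_metric_properties(rng):
    letters = list("ABCDE")
    trips = [
        tuple("".join(rng.choice(letters, rng.integers(0, 5))) for _ in range(3))
        for _ in range(1000)
    ]
    for a, b, c in trips:
        dab, dba = levenshtein(a, b), levenshtein(b, a)
        assert dab == dba
        assert (dab == 0) == (a == b)
        assert levenshtein(a, c) <= dab + levenshtein(b, c)


def test_levenshtein_against_edlib(rng):
    edlib = pytest.importorskip("edlib")
    letters = list("ABCDEFGH")
    for _ in range(200):
        a = "".join(rng.choice(letters, rng.integers(1, 8)))
        b = "".join(rng.choice(letters, rng.integers(1, 8)))
        assert levenshtein(a, b) == edlib.align(a, b, task="distance")["editDistance"]


def test_levenshtein_to_all_matches_scalar(lex, rng):
    entries = list(lex.entries[:100])
    for _ in range(20):
        s = "".join(rng.choice(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"), 4))
        batch = levenshtein_to_all(s, entries)
        assert list(batch) == [levenshtein(s, e) for e in entries]


def test_old_n_examples():
    lex20 = Lexicon([f"A{c}XX" for c in "BCDEFGHIJKLMNOPQRSTU"])
    v = old_n("AAXX", lex20, 20)
    assert v.value == 1.0 and not v.insufficient

    worked = Lexicon(["TARE", "BORE", "WEND"])
    v3 = old_n("TORE", worked, 3)
    assert v3.value == pytest.approx(2.0)  # (1 + 1 + 4) / 3
    assert v3.insufficient is False


def test_old_n_excludes_self_and_flags_insufficient(small_lex):
    v = old_n("TORE", small_lex, 3)
    dists = sorted([1, 3, 3, 4])  # TARE=1, WEND/BOOR/KRIS by hand DP
    assert v.value > 0  # the zero self-distance is ignored
    v_all = old_n("TORE", small_lex, 20)
    assert v_all.insufficient


def test_old_n_unaffected_by_far_entries(lex):
    base = Lexicon(list(lex.entries[:50]))
    v1 = old_n("EFTD", base, 20)
    extended = Lexicon(list(base.entries) + ["QQQQ"])  # distance 4, far
    v2 = old_n("EFTD", extended, 20)
    assert v1.value == v2.value


def test_old_n_empty_after_exclusion_errors():
    with pytest.raises(ValidationError):
        old_n("TORE", Lexicon(["TORE"]), 3)


# -- property: binning consistency ----------------------------------------


@settings(max_examples=30, derandomize=True)
@given(st_hyp.integers(1, 7), st_hyp.lists(st_hyp.integers(0, 1), max_size=60))
def test_bin_series_partial_bins_dropped(B, xs):
    out = bin_series(xs, B)
    assert len(out) == len(xs) // B
    for i, v in enumerate(out):
        assert v == pytest.approx(np.mean(xs[i * B:(i + 1) * B]))
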