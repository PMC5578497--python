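"""The wide Rescorla-Wagner network: updates, decisions, training, oracle."""

import numpy as np
import pytest

from widelex.learner import (
    LearnerConfig,
    TrainMode,
    TrialLog,
    TrialRecord,
    WeightMatrix,
    activations,
    decide,
    double_update,
    equilibrium_oracle,
    rw_update,
    train_on_log,
)
from widelex.stimuli import Outcome, ValidationError, pool_item, word_item

W, NW = Outcome.WORD, Outcome.NONWORD


def _cfg(**kw):
    return LearnerConfig(**{"eta": 0.01, **kw})


# -- activations and decisions --------------------------------------------


def test_activations_sum_active_cue_weights():
    w = WeightMatrix()
    assert activations(w, {"c1"}) == {W: 0.0, NW: 0.0}
    w.set("c1", W, 0.2)
    w.set("c2", W, 0.1)
    a = activations(w, {"c1", "c2"})
    assert a[W] == pytest.approx(0.3) and a[NW] == 0.0
    assert activations(w, {"c3"}) == {W: 0.0, NW: 0.0}


def test_decide_argmax_and_tie_rules():
    assert decide({W: 0.4, NW: 0.1}, _cfg()) is W
    assert decide({W: 0.0, NW: 0.0}, _cfg(tie_break="NONWORD")) is NW
    cfg = _cfg(tie_break="SEEDED_RANDOM", seed=9)
    first = decide({W: 0.0, NW: 0.0}, cfg)
    assert all(decide({W: 0.0, NW: 0.0}, cfg) is first for _ in range(5))


# -- the delta rule --------------------------------------------------------


def test_rw_update_first_and_second_step_hand_values():
    w = WeightMatrix()
    cues = {"a", "b", "c"}
    rw_update(w, cues, W, _cfg())
    for c in cues:
        assert w.get(c, W) == pytest.approx(0.01)
        assert w.get(c, NW) == 0.0
    rw_update(w, cues, W, _cfg())
    # second step: 0.01 + 0.01 * (1 - 0.03)
    for c in cues:
        assert w.get(c, W) == pytest.approx(0.0197)


def test_update_locality_inactive_cues_never_change():
    w = WeightMatrix()
    w.set("other", W, 0.5)
    rw_update(w, {"a"}, W, _cfg())
    assert w.get("other", W) == 0.5
    assert w.get("other", NW) == 0.0


def test_zero_eta_is_a_no_op():
    w = WeightMatrix()
    w.set("a", W, 0.3)
    before = w.copy()
    double_update(w, {"a"}, NW, W, _cfg(eta=0.0))
    assert w == before


def test_repeated_training_converges_to_lambda_present():
    w = WeightMatrix()
    cues = {"a", "b", "c"}
    cfg = _cfg(eta=0.1)
    for _ in range(500):
        rw_update(w, cues, W, cfg)
    total = sum(w.get(c, W) for c in cues)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_double_update_composes_two_feedback_steps_exactly():
    w1, w2 = WeightMatrix(), WeightMatrix()
    cues = {"a", "b", "c"}
    double_update(w1, cues, W, W, _cfg())
    rw_update(w2, cues, W, _cfg())
    rw_update(w2, cues, W, _cfg())
    assert w1 == w2
    for c in cues:
        assert w1.get(c, W) == pytest.approx(0.0197)


def test_double_update_mismatch_hand_computation():
    w = WeightMatrix()
    cues = {"a", "b", "c"}
    double_update(w, cues, response=NW, truth=W, cfg=_cfg())
    for c in cues:
        assert w.get(c, W) == pytest.approx(0.01)
        # stage 1 gave 0.01 toward NONWORD; stage 2's absent-outcome term:
        # 0.01 + 0.01 * (0 - 0.03)
        assert w.get(c, NW) == pytest.approx(0.0097)


# -- training along logs ---------------------------------------------------


def _make_log(items_responses, subject="T1"):
    records, seen = [], set()
    for i, (item, resp) in enumerate(items_responses, start=1):
        fe = int(item.string not in seen)
        seen.add(item.string)
        records.append(
            TrialRecord(subject, i, item, resp,
                        int(resp == item.lexicality), fe)
        )
    return TrialLog(records)


def test_train_on_empty_log():
    res = train_on_log(TrialLog([]), {}, _cfg())
    assert res.predictions == [] and len(res.weights) == 0


def test_first_prediction_uses_zero_weights():
    log = _make_log([(word_item("TORE"), W)])
    res = train_on_log(log, {"TORE": {"c1"}}, _cfg(tie_break="NONWORD"))
    assert res.predictions == [NW]  # tie rule before any learning
    assert np.array_equal(res.activations[0], [0.0, 0.0])


def test_disjoint_stimuli_learned_from_second_encounter():
    """Brute-force oracle: two disjoint cue sets, interleaved feedback."""
    seq = []
    for _ in range(50):
        seq.append((word_item("AAAA"), W))
        seq.append((pool_item("BBBB"), NW))
    log = _make_log(seq)
    cue_map = {"AAAA": frozenset({"a1", "a2"}), "BBBB": frozenset({"b1", "b2"})}
    res = train_on_log(log, cue_map, _cfg(eta=0.1), TrainMode.FEEDBACK_ONLY)

    # independent simulation of the same two decoupled systems
    wa = wb = 0.0  # summed own-outcome support per stimulus
    expect = []
    for rec in log:
        if rec.stimulus.string == "AAAA":
            expect.append(W if wa > 0 else NW)
            wa += 0.1 * (1 - wa) * 2  # two cues, shared delta
        else:
            expect.append(NW)  # ties also fall to NONWORD
            wb += 0.1 * (1 - wb) * 2
    assert res.predictions == expect
    correct = res.prediction_correct(log)
    assert correct[2:].all()  # everything after the first encounters


def test_double_mode_equals_composed_updates_when_responses_match_truth():
    seq = [(word_item("TORE"), W), (pool_item("XQZJ"), NW)] * 20
    log = _make_log(seq)
    cue_map = {"TORE": frozenset({"t1", "t2"}), "XQZJ": frozenset({"x1"})}
    res = train_on_log(log, cue_map, _cfg(), TrainMode.DOUBLE)
    w = WeightMatrix()
    for rec in log:
        cues = cue_map[rec.stimulus.string]
        rw_update(w, cues, rec.stimulus.lexicality, _cfg())
        rw_update(w, cues, rec.stimulus.lexicality, _cfg())
    assert res.weights == w


def test_missing_cue_mapping_names_the_stimulus():
    log = _make_log([(word_item("TORE"), W)])
    with pytest.raises(ValidationError, match="TORE"):
        train_on_log(log, {}, _cfg())


# -- trial log invariants --------------------------------------------------


def test_trial_log_rejects_gapped_indices():
    r1 = TrialRecord("s", 1, word_item("TORE"), W, 1, 1)
    r3 = TrialRecord("s", 3, word_item("WEND"), W, 1, 1)
    with pytest.raises(ValidationError):
        TrialLog([r1, r3])


def test_trial_record_rejects_inconsistent_correct():
    with pytest.raises(ValidationError):
        TrialRecord("s", 1, word_item("TORE"), NW, 1, 1)


def test_trial_log_rejects_wrong_first_encounter():
    r1 = TrialRecord("s", 1, word_item("TORE"), W, 1, 1)
    r2 = TrialRecord("s", 2, word_item("TORE"), W, 1, 1)  # seen before
    with pytest.raises(ValidationError):
        TrialLog([r1, r2])


# -- equilibrium oracle ----------------------------------------------------


def test_oracle_single_event_splits_weight_equally():
    w = equilibrium_oracle([({"a", "b", "c"}, W, 1.0)])
    for c in "abc":
        assert w.get(c, W) == pytest.approx(1 / 3)
        assert w.get(c, NW) == pytest.approx(0.0)


def test_oracle_disjoint_events_decouple():
    w = equilibrium_oracle(
        [({"a1", "a2"}, W, 0.5), ({"b1", "b2", "b3"}, NW, 0.5)]
    )
    assert w.get("a1", W) + w.get("a2", W) == pytest.approx(1.0)
    assert w.get("a1", NW) + w.get("a2", NW) == pytest.approx(0.0)
    assert sum(w.get(b, NW) for b in ("b1", "b2", "b3")) == pytest.approx(1.0)


def test_oracle_reports_nullity_on_singular_systems():
    # duplicated cue column -> rank-deficient normal equations
    w, info = equilibrium_oracle(
        [({"a", "b"}, W, 1.0)], return_info=True
    )
    assert info["nullity"] >= 1
    assert w.get("a", W) == pytest.approx(w.get("b", W))


def test_oracle_matches_long_run_training_on_correlated_cues():
    events = [
        (frozenset({"x", "shared"}), W, 0.5),
        (frozenset({"y", "shared"}), NW, 0.5),
    ]
    oracle = equilibrium_oracle(events)
    rng = np.random.default_rng(3)
    w = WeightMatrix()
    cfg = LearnerConfig(eta=0.001)
    for _ in range(100_000):
        cues, out, _ = events[int(rng.random() > 0.5)]
        rw_update(w, cues, out, cfg)
    for c in ("x", "y", "shared"):
        for o in (W, NW):
            assert w.get(c, o) == pytest.approx(oracle.get(c, o), abs=0.01)


# -- serialization ---------------------------------------------------------


def test_weight_csv_round_trip_is_bit_exact(tmp_path, rng):
    w = WeightMatrix()
    for i in range(50):
        w.set(f"s0r{i}c0o0l0", W, float(rng.normal() * 1e-4))
        w.set(f"s0r{i}c0o0l0", NW, float(rng.normal()))
    p = tmp_path / "w.csv"
    w.write_csv(p)
    assert WeightMatrix.read_csv(p) == w


def test_weight_mtx_export_round_trips(tmp_path):
    from scipy.io import mmread

    w = WeightMatrix()
    w.set("c1", W, 0.123456789012345)
    w.set("c2", NW, -1e-7)
    w.write_mtx(tmp_path / "w.mtx", tmp_path / "w_idx.csv")
    m = np.asarray(mmread(tmp_path / "w.mtx").todense())
    assert m.shape == (2, 2)
    assert m[0, 0] == 0.123456789012345
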