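"""The wide discrimination network.

A single layer of associative weights links every discrete visual cue to
the two response outcomes (WORD, NONWORD). Learning follows the
Rescorla-Wagner delta rule with the salience/rate product collapsed into a
single learning rate ``eta``: on each event, every active cue's weight
toward outcome ``o`` moves by ``eta * (lambda_o - a_o)``, where ``a_o`` is
the summed pre-update activation of ``o`` over the active cues and
``lambda_o`` is 1 for the outcome that occurred and 0 otherwise. With
binary cues this is the Widrow-Hoff / least-mean-squares rule, whose
stationary point is the least-squares regression of outcome indicators on
cue indicators — which is what :func:`equilibrium_oracle` solves in closed
form as an independent check.

Two training regimes are provided. ``FEEDBACK_ONLY`` is the classic rule:
one update per trial toward the true label. ``DOUBLE`` is the two-stage
update used to couple the model to an observed subject: the weights are
first nudged toward the response the subject actually gave on that trial,
then toward the experimenter's feedback. Predictions are always emitted
before any update, so they reflect strictly past experience.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np

from .stimuli import Outcome, StimulusItem, ValidationError

__all__ = [
    "Outcome",
    "LearnerConfig",
    "TrainMode",
    "WeightMatrix",
    "activations",
    "decide",
    "rw_update",
    "double_update",
    "TrialRecord",
    "TrialLog",
    "TrainResult",
    "train_on_log",
    "equilibrium_oracle",
]

Cue = Hashable
_OUTCOMES = (Outcome.WORD, Outcome.NONWORD)


class TrainMode(enum.Enum):
    FEEDBACK_ONLY = "FEEDBACK_ONLY"
    DOUBLE = "DOUBLE"


@dataclass(frozen=True)
class LearnerConfig:
    """Parameters of the network.

    ``eta`` is the single free parameter of the model (the alpha*beta
    product of the classic rule). The default 0.0055 sits just below the
    least-mean-squares stability bound for the default cue density
    (~300 active cues per stimulus) and lets a small word/nonword set be
    mastered within a handful of passes. ``lambda_present`` /
    ``lambda_absent`` are the asymptotes for present and absent outcomes.
    Exact activation ties are broken per ``tie_break``: ``"NONWORD"``
    (deterministic, mirroring the animals' early nonword bias) or
    ``"SEEDED_RANDOM"``.
    """

    eta: float = 0.0055
    lambda_present: float = 1.0
    lambda_absent: float = 0.0
    tie_break: str = "NONWORD"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.eta < 1):
            raise ValidationError(f"eta must be in [0, 1), got {self.eta}")
        if not self.lambda_present > self.lambda_absent:
            raise ValidationError("lambda_present must exceed lambda_absent")
        if self.tie_break not in ("NONWORD", "SEEDED_RANDOM"):
            raise ValidationError(f"unknown tie_break {self.tie_break!r}")


class WeightMatrix:
    """Sparse cue-by-outcome associative strengths, default 0.

    Rows are allocated lazily as cues are first seen; unseen cues have
    weight exactly 0 toward both outcomes. Cue keys may be any hashable;
    throughout the pipeline they are cue-id strings.
    """

    def __init__(self) -> None:
        self._index: dict[Cue, int] = {}
        self._w = np.zeros((0, 2), dtype=np.float64)

    @classmethod
    def with_index(cls, cue_to_row: Mapping[Cue, int]) -> "WeightMatrix":
        """Zero matrix over a pre-built cue -> row mapping (fast path)."""
        out = cls()
        out._index = dict(cue_to_row)
        out._w = np.zeros((len(out._index), 2), dtype=np.float64)
        return out

    # -- bookkeeping -------------------------------------------------------

    def _rows(self, cues: Iterable[Cue], grow: bool) -> np.ndarray:
        idx = self._index
        rows = []
        new: list[Cue] = []
        for c in cues:
            r = idx.get(c)
            if r is None:
                if grow:
                    r = len(idx) + len(new)
                    new.append(c)
                else:
                    continue
            rows.append(r)
        if new:
            for c in new:
                idx[c] = len(idx)
            extra = np.zeros((len(new), 2), dtype=np.float64)
            self._w = np.vstack([self._w, extra]) if self._w.size else extra
        return np.asarray(rows, dtype=np.intp)

    def get(self, cue: Cue, outcome: Outcome) -> float:
        r = self._index.get(cue)
        return 0.0 if r is None else float(self._w[r, int(outcome)])

    def set(self, cue: Cue, outcome: Outcome, value: float) -> None:
        r = self._rows([cue], grow=True)[0]
        self._w[r, int(outcome)] = value

    @property
    def cues(self) -> tuple[Cue, ...]:
        return tuple(self._index)

    def __len__(self) -> int:
        return len(self._index)

    def copy(self) -> "WeightMatrix":
        out = WeightMatrix()
        out._index = dict(self._index)
        out._w = self._w.copy()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightMatrix):
            return NotImplemented
        mine = {c: (self._w[r, 0], self._w[r, 1]) for c, r in self._index.items()}
        theirs = {c: (other._w[r, 0], other._w[r, 1]) for c, r in other._index.items()}
        keys = set(mine) | set(theirs)
        return all(mine.get(k, (0.0, 0.0)) == theirs.get(k, (0.0, 0.0)) for k in keys)

    # -- core computation --------------------------------------------------

    def activations(self, cues: Iterable[Cue]) -> np.ndarray:
        """Summed weights of the active cues toward (WORD, NONWORD)."""
        rows = self._rows(cues, grow=False)
        if rows.size == 0:
            return np.zeros(2)
        return self._w[rows].sum(axis=0)

    def update(self, cues: Iterable[Cue], present: Outcome, cfg: LearnerConfig) -> None:
        """One in-place Rescorla-Wagner step; see :func:`rw_update`."""
        rows = self._rows(cues, grow=True)
        if rows.size == 0:
            return
        a = self._w[rows].sum(axis=0)
        lam = np.full(2, cfg.lambda_absent)
        lam[int(present)] = cfg.lambda_present
        self._w[rows] += cfg.eta * (lam - a)

    # -- pre-indexed fast path --------------------------------------------
    #
    # Training loops touch the same cue sets thousands of times; callers
    # may resolve a cue set to row indices once and reuse the array.

    def index_cues(self, cues: Iterable[Cue]) -> np.ndarray:
        """Resolve cues to row indices, allocating rows as needed."""
        return self._rows(cues, grow=True)

    def activations_rows(self, rows: np.ndarray) -> np.ndarray:
        if rows.size == 0:
            return np.zeros(2)
        return self._w[rows].sum(axis=0)

    def update_rows(self, rows: np.ndarray, present: Outcome, cfg: LearnerConfig) -> None:
        if rows.size == 0:
            return
        a = self._w[rows].sum(axis=0)
        lam = np.full(2, cfg.lambda_absent)
        lam[int(present)] = cfg.lambda_present
        self._w[rows] += cfg.eta * (lam - a)

    # -- serialization -----------------------------------------------------

    def to_rows(self) -> list[tuple[str, str, float]]:
        out = []
        for cue, r in self._index.items():
            for o in _OUTCOMES:
                out.append((str(cue), o.name, float(self._w[r, int(o)])))
        return out

    def write_csv(self, path: str | Path) -> None:
        """Flat CSV (cue_id, outcome, weight); values round-trip bit-exactly."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            wr = csv.writer(fh, lineterminator="\n")
            wr.writerow(["cue_id", "outcome", "weight"])
            for cue, oname, w in self.to_rows():
                wr.writerow([cue, oname, format(w, ".17g")])

    @classmethod
    def read_csv(
        cls, path: str | Path, key_parser: Callable[[str], Cue] = str
    ) -> "WeightMatrix":
        out = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            rd = csv.reader(fh)
            header = next(rd)
            if header != ["cue_id", "outcome", "weight"]:
                raise ValidationError(f"unexpected weight CSV header {header}")
            for cue_s, oname, w in rd:
                out.set(key_parser(cue_s), Outcome[oname], float(w))
        return out

    def write_mtx(self, path: str | Path, sidecar_csv: str | Path) -> None:
        """Matrix Market export plus a sidecar CSV mapping row -> cue id."""
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        n = len(self._index)
        mat = coo_matrix(self._w[:n] if n else np.zeros((0, 2)))
        mmwrite(str(path), mat, precision=17)
        with open(sidecar_csv, "w", newline="", encoding="utf-8") as fh:
            wr = csv.writer(fh, lineterminator="\n")
            wr.writerow(["row", "cue_id"])
            for cue, r in self._index.items():
                wr.writerow([r + 1, str(cue)])  # MTX rows are 1-based
            wr.writerow([])
            wr.writerow(["column", "outcome"])
            for o in _OUTCOMES:
                wr.writerow([int(o) + 1, o.name])


def activations(w: WeightMatrix, cues: Iterable[Cue]) -> dict[Outcome, float]:
    """Activation of each outcome given the active cues (empty set -> zeros)."""
    a = w.activations(cues)
    return {o: float(a[int(o)]) for o in _OUTCOMES}


def decide(
    a: Mapping[Outcome, float] | np.ndarray,
    cfg: LearnerConfig,
    rng: np.random.Generator | None = None,
) -> Outcome:
    """Argmax over outcome activations; exact ties resolved per config."""
    if isinstance(a, np.ndarray):
        aw, an = float(a[0]), float(a[1])
    else:
        aw, an = a[Outcome.WORD], a[Outcome.NONWORD]
    if aw > an:
        return Outcome.WORD
    if an > aw:
        return Outcome.NONWORD
    if cfg.tie_break == "NONWORD":
        return Outcome.NONWORD
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return _OUTCOMES[int(rng.integers(2))]


def rw_update(
    w: WeightMatrix, cues: Iterable[Cue], present: Outcome, cfg: LearnerConfig
) -> WeightMatrix:
    """Rescorla-Wagner update toward the outcome that occurred.

    For each outcome ``o``, every active cue gets
    ``w[i, o] += eta * (lambda_o - a_o)`` with ``a_o`` computed before the
    update; inactive cues never change. Updates ``w`` in place and returns
    it, so calls compose naturally.
    """
    w.update(cues, present, cfg)
    return w


def double_update(
    w: WeightMatrix,
    cues: Iterable[Cue],
    response: Outcome,
    truth: Outcome,
    cfg: LearnerConfig,
) -> WeightMatrix:
    """Two-stage update: first toward the subject's own response, then
    toward the feedback, in that order."""
    rw_update(w, cues, response, cfg)
    return rw_update(w, cues, truth, cfg)


# --------------------------------------------------------------------------
# trial logs


@dataclass(frozen=True)
class TrialRecord:
    """One trial of one subject: stimulus, truth, response, bookkeeping."""

    subject: str
    trial: int
    stimulus: StimulusItem
    response: Outcome
    correct: int
    first_encounter: int

    def __post_init__(self) -> None:
        expected = int(self.response == self.stimulus.lexicality)
        if self.correct != expected:
            raise ValidationError(
                f"trial {self.trial}: correct={self.correct} inconsistent with "
                f"response {self.response.name} on a "
                f"{self.stimulus.lexicality.name} stimulus"
            )
        if self.first_encounter not in (0, 1):
            raise ValidationError("first_encounter must be 0 or 1")


class TrialLog(Sequence[TrialRecord]):
    """Ordered per-subject trial records with contiguous 1-based indices."""

    def __init__(self, records: Iterable[TrialRecord]):
        recs = tuple(records)
        seen: set[str] = set()
        for i, r in enumerate(recs, start=1):
            if r.trial != i:
                raise ValidationError(
                    f"trial indices must be contiguous from 1; "
                    f"found {r.trial} at position {i}"
                )
            fe = int(r.stimulus.string not in seen)
            if r.first_encounter != fe:
                raise ValidationError(
                    f"trial {i}: first_encounter={r.first_encounter} "
                    f"inconsistent with history"
                )
            seen.add(r.stimulus.string)
        self._records = recs
        self.subject = recs[0].subject if recs else ""

    def __getitem__(self, i):  # type: ignore[override]
        return self._records[i]

    def __len__(self) -> int:
        return len(self._records)

    def correctness(self) -> np.ndarray:
        return np.array([r.correct for r in self._records], dtype=np.int8)


@dataclass
class TrainResult:
    """Outcome of training a network along a trial log."""

    predictions: list[Outcome]
    weights: WeightMatrix
    activations: np.ndarray  # (n_trials, 2): pre-update (WORD, NONWORD)

    def prediction_correct(self, log: TrialLog) -> np.ndarray:
        return np.array(
            [int(p == r.stimulus.lexicality) for p, r in zip(self.predictions, log)],
            dtype=np.int8,
        )


def train_on_log(
    log: TrialLog,
    cue_map: Mapping[str, Iterable[Cue]] | Callable[[str], Iterable[Cue]],
    cfg: LearnerConfig,
    mode: TrainMode = TrainMode.DOUBLE,
    weights: WeightMatrix | None = None,
) -> TrainResult:
    """Train a network along a subject's trial sequence.

    Per trial, the emitted prediction uses only weights from earlier trials
    (predict-then-update). ``DOUBLE`` applies the two-stage update with the
    log's recorded response followed by the true label; ``FEEDBACK_ONLY``
    applies the classic single update with the true label. ``cue_map`` maps
    stimulus strings to active cue sets (mapping or callable); a missing
    stimulus raises an error naming it.
    """
    if callable(cue_map):
        cues_of = cue_map
    else:
        def cues_of(s: str):
            try:
                return cue_map[s]
            except KeyError:
                raise ValidationError(f"no cue set for stimulus {s!r}") from None

    w = weights if weights is not None else WeightMatrix()
    rng = np.random.default_rng(cfg.seed)
    preds: list[Outcome] = []
    acts = np.zeros((len(log), 2))
    for t, rec in enumerate(log):
        cues = cues_of(rec.stimulus.string)
        a = w.activations(cues)
        acts[t] = a
        preds.append(decide(a, cfg, rng))
        truth = rec.stimulus.lexicality
        if mode is TrainMode.DOUBLE:
            double_update(w, cues, rec.response, truth, cfg)
        elif mode is TrainMode.FEEDBACK_ONLY:
            rw_update(w, cues, truth, cfg)
        else:  # pragma: no cover
            raise ValidationError(f"unknown mode {mode!r}")
    return TrainResult(predictions=preds, weights=w, activations=acts)


# --------------------------------------------------------------------------
# closed-form equilibrium (test oracle)


def equilibrium_oracle(
    event_dist: Sequence[tuple[Iterable[Cue], Outcome, float]],
    *,
    lambda_present: float = 1.0,
    lambda_absent: float = 0.0,
    return_info: bool = False,
):
    """Least-squares stationary point of the feedback-only update.

    For a stationary distribution over (cue set, outcome) events the
    expected weight change vanishes at the solution of the normal equations
    ``E[x x^T] W = E[x lambda^T]`` — the cue-by-outcome linear regression.
    Singular systems are solved in the minimum-norm sense and the nullity
    is reported via ``return_info``. Used only as an independent oracle in
    tests; never by the training path.
    """
    probs = np.array([p for _, _, p in event_dist], dtype=float)
    if probs.size == 0 or not np.isclose(probs.sum(), 1.0):
        raise ValidationError("event probabilities must sum to 1")
    cue_index: dict[Cue, int] = {}
    for cues, _, _ in event_dist:
        for c in cues:
            cue_index.setdefault(c, len(cue_index))
    n = len(cue_index)
    X = np.zeros((len(event_dist), n))
    L = np.zeros((len(event_dist), 2))
    for i, (cues, outcome, _) in enumerate(event_dist):
        for c in cues:
            X[i, cue_index[c]] = 1.0
        L[i] = lambda_absent
        L[i, int(outcome)] = lambda_present
    A = X.T @ (X * probs[:, None])
    B = X.T @ (L * probs[:, None])
    sol, _, rank, _ = np.linalg.lstsq(A, B, rcond=None)
    w = WeightMatrix()
    for c, j in cue_index.items():
        for o in _OUTCOMES:
            w.set(c, o, float(sol[j, int(o)]))
    if return_info:
        nullity = n - rank
        info = {"rank": int(rank), "nullity": int(nullity)}
        if nullity:
            # orthonormal basis of the null space of A
            _, s, vt = np.linalg.svd(A)
            info["null_space"] = vt[rank:].T
        return w, info
    return w
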