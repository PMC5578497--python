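"""Orchestration: generate synthetic experiments, train networks on logs,
run the analysis battery, and emit report tables.

Every command is a plain function over a :class:`RunConfig`; the CLI in
:mod:`widelex.cli` and the numbered scripts under ``analysis/`` are thin
wrappers. Commands are deterministic under the global seed, which fans
out to per-module seeds by fixed offsets, and each command writes a
manifest (inputs, resolved config, seed, output hashes) so a run can be
audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import behavior_metrics as bm
from . import stats_models as sm_mod
from .learner import LearnerConfig, TrainMode, TrialLog, train_on_log
from .stimuli import (
    FeatureConfig,
    Lexicon,
    Outcome,
    ValidationError,
    bundled_lexicon,
    cue_cache,
    write_cue_inventory,
)
from .synthetic_behavior import (
    AGENT_PRESETS,
    AgentConfig,
    ScheduleConfig,
    build_schedule,
    sample_nonword_pool,
    simulate_agent,
    write_trial_log,
    read_trial_log,
    TRIAL_LOG_HEADER,
)

log = logging.getLogger("widelex")

__all__ = [
    "AnalysisConfig",
    "RunConfig",
    "cmd_generate",
    "cmd_train",
    "cmd_analyze",
    "cmd_transposition",
    "cmd_report",
]

# fixed seed fan-out offsets (global seed + offset -> module seed)
_SCHEDULE_OFF = 101
_AGENT_OFF = 201
_LEARNER_OFF = 301
_TRANSPOSITION_OFF = 401


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the analysis battery."""

    bin_size: int = 100
    exclude_first: int = 5000
    max_lag: int = 20
    k_max: int = 25
    old_n: int = 20
    spline_df: int = 5
    random_effects: bool = False
    random_effects_spline_df: int = 8


@dataclass(frozen=True)
class ScheduleSpec:
    """Schedule section of a run config (pools are built at run time)."""

    n_trials: int = 60_000
    p_word_trial: float = 0.5
    intro_window: int = 5
    intro_accuracy: float = 0.8


@dataclass
class RunConfig:
    features: FeatureConfig = field(default_factory=FeatureConfig)
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    agents: dict[str, AgentConfig] = field(
        default_factory=lambda: dict(AGENT_PRESETS)
    )
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    transposition_runs: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kw: dict = {}
        if "features" in raw:
            f = dict(raw["features"])
            for tup in ("cells_per_slot", "magnitude_thresholds"):
                if tup in f:
                    f[tup] = tuple(f[tup])
            kw["features"] = FeatureConfig(**f)
        if "learner" in raw:
            kw["learner"] = LearnerConfig(**raw["learner"])
        if "schedule" in raw:
            kw["schedule"] = ScheduleSpec(**raw["schedule"])
        if "agents" in raw:
            kw["agents"] = {
                name: AgentConfig(**a) for name, a in raw["agents"].items()
            }
        if "analysis" in raw:
            kw["analysis"] = AnalysisConfig(**raw["analysis"])
        for scalar in ("transposition_runs", "seed"):
            if scalar in raw:
                kw[scalar] = raw[scalar]
        return cls(**kw)

    def resolved(self) -> dict:
        d = {
            "features": asdict(self.features),
            "learner": asdict(self.learner),
            "schedule": asdict(self.schedule),
            "agents": {k: asdict(v) for k, v in self.agents.items()},
            "analysis": asdict(self.analysis),
            "transposition_runs": self.transposition_runs,
            "seed": self.seed,
        }
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(
    out_dir: Path, command: str, cfg: RunConfig, inputs: list[str],
    outputs: list[Path],
) -> None:
    manifest = {
        "command": command,
        "inputs": inputs,
        "seed": cfg.seed,
        "config": cfg.resolved(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def cmd_generate(cfg: RunConfig, out_dir: str | Path,
                 lexicon: Lexicon | None = None) -> list[Path]:
    """Generate one trial-log CSV per configured agent plus a schedule
    manifest; deterministic under the global seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lex = lexicon if lexicon is not None else bundled_lexicon()
    cues = cue_cache(cfg.features)
    outputs: list[Path] = []
    spec = cfg.schedule
    n_nonwords = spec.n_trials  # upper bound: every trial could be a nonword
    for i, (name, a_cfg) in enumerate(sorted(cfg.agents.items())):
        sched_seed = cfg.seed + _SCHEDULE_OFF + i
        rng = np.random.default_rng(sched_seed)
        s_cfg = ScheduleConfig(
            n_trials=spec.n_trials,
            p_word_trial=spec.p_word_trial,
            words_pool=lex,
            nonword_pool=sample_nonword_pool(lex, n_nonwords, rng),
            intro_criterion=(spec.intro_window, spec.intro_accuracy),
            seed=sched_seed,
        )
        schedule = build_schedule(s_cfg)
        a_cfg = dataclasses.replace(a_cfg, seed=cfg.seed + _AGENT_OFF + i)
        log.info("simulating agent %s (%d trials)", name, len(schedule))
        trial_log = simulate_agent(schedule, cues, a_cfg, subject=name)
        path = out / f"{name}.csv"
        write_trial_log(trial_log, path)
        outputs.append(path)
    inv = out / "cue_inventory.csv"
    write_cue_inventory(cfg.features, inv)
    outputs.append(inv)
    resolved = out / "resolved_config.yaml"
    resolved.write_text(yaml.safe_dump(cfg.resolved(), sort_keys=True))
    outputs.append(resolved)
    _write_manifest(out, "generate", cfg, [], outputs)
    return outputs


def cmd_train(
    log_path: str | Path,
    cfg: RunConfig,
    mode: TrainMode = TrainMode.DOUBLE,
    out_dir: str | Path = ".",
) -> list[Path]:
    """Train one network along a trial log; write per-trial predictions
    (CSV columns appended to the log dialect) and final weights (flat CSV
    + Matrix Market with sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial_log = read_trial_log(log_path)
    cues = cue_cache(cfg.features)
    l_cfg = dataclasses.replace(cfg.learner, seed=cfg.seed + _LEARNER_OFF)
    result = train_on_log(trial_log, cues, l_cfg, mode)
    subj = trial_log.subject or Path(log_path).stem
    pred_path = out / f"{subj}_predictions.csv"
    df = pd.read_csv(log_path)
    df["model_response"] = [p.name for p in result.predictions]
    df["model_a_word"] = result.activations[:, 0]
    df["model_a_nonword"] = result.activations[:, 1]
    df.to_csv(pred_path, index=False, lineterminator="\n")
    w_csv = out / f"{subj}_weights.csv"
    result.weights.write_csv(w_csv)
    w_mtx = out / f"{subj}_weights.mtx"
    w_sidecar = out / f"{subj}_weights_index.csv"
    result.weights.write_mtx(w_mtx, w_sidecar)
    outputs = [pred_path, w_csv, w_mtx, w_sidecar]
    _write_manifest(out, f"train_{subj}", cfg, [str(log_path)], outputs)
    return outputs


def _model_correctness(df: pd.DataFrame) -> np.ndarray:
    return (df["model_response"] == df["lexicality"]).to_numpy().astype(int)


def cmd_analyze(
    in_dir: str | Path, cfg: RunConfig, out_dir: str | Path,
    lexicon: Lexicon | None = None,
) -> dict:
    """Run the descriptive battery (and optionally the model-based fits)
    over every ``<subject>_predictions.csv`` in ``in_dir``.

    Writes tidy CSVs (one row per bin / lag / k) and a JSON summary;
    returns the summary dict.
    """
    in_p, out = Path(in_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lex = lexicon if lexicon is not None else bundled_lexicon()
    a = cfg.analysis
    pred_files = sorted(in_p.glob("*_predictions.csv"))
    if not pred_files:
        raise ValidationError(f"no *_predictions.csv files under {in_p}")
    bins_rows, cc_rows, run_rows, novel_rows = [], [], [], []
    summary: dict = {"subjects": {}}
    logs: dict[str, TrialLog] = {}
    model_correct: dict[str, np.ndarray] = {}
    for f in pred_files:
        df = pd.read_csv(f)
        missing = [c for c in TRIAL_LOG_HEADER + ["model_response"]
                   if c not in df.columns]
        if missing:
            raise ValidationError(
                f"{f.name} missing column(s): {', '.join(missing)}"
            )
        subj = str(df["subject"].iloc[0])
        tl = read_trial_log(f)
        logs[subj] = tl
        mc = _model_correctness(df)
        model_correct[subj] = mc
        agent_acc = bm.binned_accuracy(tl, a.bin_size)
        model_acc = bm.binned_accuracy(mc, a.bin_size)
        for series, acc in (("agent", agent_acc), ("model", model_acc)):
            for b, v in enumerate(acc.values):
                bins_rows.append((subj, series, b, v))
        ex_agent = bm.binned_accuracy(tl, a.bin_size, a.exclude_first)
        ex_model = bm.binned_accuracy(mc, a.bin_size, a.exclude_first)
        subj_summary: dict = {}
        if len(ex_agent) >= max(a.max_lag + 2, 3):
            cc = bm.cross_correlation(
                ex_agent.as_array(), ex_model.as_array(), a.max_lag
            )
            for lag, r in zip(cc.lags, cc.r):
                cc_rows.append((subj, lag, r, cc.conf_bound))
            rho, p = bm.derivative_spearman(ex_agent, ex_model)
            subj_summary["derivative_spearman"] = {"rho": rho, "p": p}
            subj_summary["crosscorr_lag0"] = cc.r_at(0)
            subj_summary["crosscorr_conf_bound"] = cc.conf_bound
        rl = bm.run_length_exceedance(tl, a.k_max)
        rl_m = bm.run_length_exceedance(mc, a.k_max)
        for k, pa, pm_ in zip(rl.ks, rl.p_exceed, rl_m.p_exceed):
            run_rows.append((subj, k, pa, pm_))
        cum = bm.cumulative_novel_word_accuracy(tl)
        for i, v in enumerate(cum):
            novel_rows.append((subj, "word_cumulative", i, v))
        nn = bm.novel_nonword_accuracy(tl, a.bin_size)
        for i, v in enumerate(nn.values):
            novel_rows.append((subj, "nonword_first_encounter", i, v))
        subj_summary["n_trials"] = len(tl)
        subj_summary["n_words_encountered"] = int(len(cum))
        subj_summary["agent_accuracy"] = float(tl.correctness().mean())
        subj_summary["model_accuracy"] = float(mc.mean())
        summary["subjects"][subj] = subj_summary

    pd.DataFrame(
        bins_rows, columns=["subject", "series", "bin", "accuracy"]
    ).to_csv(out / "accuracy_bins.csv", index=False, lineterminator="\n")
    pd.DataFrame(
        cc_rows, columns=["subject", "lag", "r", "conf_bound"]
    ).to_csv(out / "crosscorrelations.csv", index=False, lineterminator="\n")
    pd.DataFrame(
        run_rows, columns=["subject", "k", "p_exceed_agent", "p_exceed_model"]
    ).to_csv(out / "run_length_exceedance.csv", index=False, lineterminator="\n")
    pd.DataFrame(
        novel_rows, columns=["subject", "curve", "index", "accuracy"]
    ).to_csv(out / "generalization.csv", index=False, lineterminator="\n")

    if len(logs) >= 2:
        frame = sm_mod.old20_frame(logs.values(), lex, a.old_n)
        if frame["old20"].nunique() >= 2:
            fit_agent = sm_mod.old20_effect(frame, spline_df=a.spline_df)
            # same trials and covariate, model-prediction correctness
            known = dict(zip(frame["stimulus"], frame["old20"]))
            frame_m = sm_mod.old20_frame(
                logs.values(), lex, a.old_n,
                correctness=model_correct, old20_values=known,
            )
            fit_model = sm_mod.old20_effect(frame_m, spline_df=a.spline_df)
            summary["old20"] = {
                "agent": fit_agent.coefficients["old20"],
                "model": fit_model.coefficients["old20"],
            }
    if a.random_effects and len(logs) >= 2:
        re_agent = sm_mod.random_effects_comparison(
            list(logs.values()), spline_df=a.random_effects_spline_df
        )
        re_model = sm_mod.random_effects_comparison(
            list(logs.values()),
            spline_df=a.random_effects_spline_df,
            correctness=model_correct,
        )
        re_agent.table.assign(source="agent").to_csv(
            out / "random_effects_agent.csv", index=False, lineterminator="\n"
        )
        re_model.table.assign(source="model").to_csv(
            out / "random_effects_model.csv", index=False, lineterminator="\n"
        )
        summary["random_effects"] = {
            "per_test_alpha": re_agent.plan.per_test_alpha,
            "agent_significant": int(re_agent.table["significant"].sum()),
            "model_significant": int(re_model.table["significant"].sum()),
        }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
    )
    outputs = sorted(out.glob("*.csv")) + [out / "summary.json"]
    _write_manifest(out, "analyze", cfg, [str(f) for f in pred_files], outputs)
    return summary


def cmd_transposition(
    cfg: RunConfig, out_dir: str | Path, lexicon: Lexicon | None = None,
    **kwargs,
) -> sm_mod.TranspositionResult:
    """Run the transposition/substitution simulation and write per-run and
    pooled fit JSON plus the item-level response table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lex = lexicon if lexicon is not None else bundled_lexicon()
    res = sm_mod.transposition_experiment(
        lex,
        n_runs=cfg.transposition_runs,
        feature_cfg=cfg.features,
        learner_cfg=cfg.learner,
        seed=cfg.seed + _TRANSPOSITION_OFF,
        **kwargs,
    )
    payload = {
        "per_run": [
            {"model_id": f.model_id, "coefficients": f.coefficients,
             "n_obs": f.n_obs}
            for f in res.per_run
        ],
        "pooled": {"coefficients": res.pooled.coefficients,
                   "n_obs": res.pooled.n_obs},
        "control": {"coefficients": res.control.coefficients,
                    "n_obs": res.control.n_obs},
        "sign_test_p": res.sign_test_p,
        "run_effects": res.run_effects,
    }
    fit_path = out / "transposition_fits.json"
    fit_path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    data_path = out / "transposition_responses.csv"
    res.data.to_csv(data_path, index=False, lineterminator="\n")
    _write_manifest(out, "transposition", cfg, [], [fit_path, data_path])
    return res


def cmd_report(analyze_dir: str | Path, out_path: str | Path) -> Path:
    """Collate an analyze run's summary into a small markdown report."""
    summary = json.loads((Path(analyze_dir) / "summary.json").read_text())
    lines = ["# widelex run report", ""]
    lines.append("| subject | trials | words | agent acc | model acc | deriv. Spearman rho |")
    lines.append("|---|---|---|---|---|---|")
    for subj, s in sorted(summary.get("subjects", {}).items()):
        rho = s.get("derivative_spearman", {}).get("rho", float("nan"))
        lines.append(
            f"| {subj} | {s['n_trials']} | {s['n_words_encountered']} "
            f"| {s['agent_accuracy']:.3f} | {s['model_accuracy']:.3f} "
            f"| {rho:.3f} |"
        )
    if "old20" in summary:
        a_b, a_z, a_p = summary["old20"]["agent"]
        m_b, m_z, m_p = summary["old20"]["model"]
        lines += [
            "",
            f"OLD20 effect on nonword accuracy: agent beta={a_b:.3f} "
            f"(z={a_z:.2f}, p={a_p:.2g}); model beta={m_b:.3f} "
            f"(z={m_z:.2f}, p={m_p:.2g}).",
        ]
    if "random_effects" in summary:
        re = summary["random_effects"]
        lines += [
            "",
            f"Random-effect tests at per-test alpha {re['per_test_alpha']:.4f}: "
            f"{re['agent_significant']} significant for agents, "
            f"{re['model_significant']} for model predictions.",
        ]
    out = Path(out_path)
    out.write_text("\n".join(lines) + "\n")
    return out
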