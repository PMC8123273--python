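"""End-to-end orchestration: generate -> denoise -> detect -> featurize
-> select -> extract -> train -> evaluate.

A :class:`PipelineConfig` (YAML-serializable) drives one fully seeded
run.  The pipeline can start from synthesized ECG waveforms (the full
signal chain) or directly from synthesized RR series (``signal_level =
"rr"``), which skips waveform rendering and peak detection; the two
entries share every stage from windowing onward.  All intermediates are
written as CSV/JSON, and the run report captures record counts, the
selected features, the retained components, and the final evaluation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, featstats, hrv, preprocess, rpeak, synth
from .signals import RRSeries

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "make_fixtures",
           "build_feature_table", "session_feature_rows"]

logger = logging.getLogger("fatiguehrv")

# Confusion counts of a published three-state test evaluation (96 samples
# per true class), used as a literal fixture for the metric chain.
REFERENCE_CONFUSION = [[79, 10, 7], [13, 75, 8], [4, 10, 82]]


@dataclass
class PipelineConfig:
    signal_level: str = "rr"            # "rr" or "ecg"
    n_participants: int = 30
    session_duration: float = 1800.0
    sampling_rate: float = 512.0
    window_length: float = 100.0
    noise: dict = field(default_factory=lambda: {
        "white_sd": 0.02, "powerline_amp": 0.05,
        "baseline_amp": 0.1, "baseline_freq": 0.25, "emg_amp": 0.01})
    alpha: float = 0.05
    cum_threshold: float = 0.85
    n_test_participants: int = 8
    lvq: dict = field(default_factory=lambda: {
        "n_prototypes": 13, "learning_rate": 0.01,
        "max_iterations": 1000, "target_error": 0.1})
    with_baselines: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_level not in ("rr", "ecg"):
            raise ValueError("signal_level must be 'rr' or 'ecg'")
        if not 0 < self.n_test_participants < self.n_participants:
            raise ValueError("test split must leave both train and test participants")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    config_hash: str
    seed: int
    n_sessions: int
    n_windows: int
    n_effective_windows: int
    selected_features: list
    retained_components: int
    contribution_rates: list
    evaluation: dict
    baseline_evaluations: dict
    version: str = "0.1.0"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def session_feature_rows(session: synth.SessionRecord, rr: RRSeries,
                         window_length: float = 100.0,
                         total_duration: float | None = None) -> list:
    """Per-effective-window feature dicts with identity columns."""
    rows = []
    for k, sub, effective in rpeak.segment_windows(rr, window_length,
                                                   total_duration=total_duration):
        if not effective:
            continue
        feats = hrv.compute_feature_vector(sub)
        if feats.pop("undefined", False):
            continue
        feats.pop("T2_AVHR_rounded", None)
        feats.pop("N4_Aplus_count", None)
        feats.pop("N5_Bminus_count", None)
        feats.update({"participant": session.participant,
                      "period": session.period,
                      "state": session.state, "window_index": k})
        rows.append(feats)
    return rows


def build_feature_table(config: PipelineConfig, outdir: Path | None = None) -> pd.DataFrame:
    """Generate the cohort and compute the windows x features table."""
    spec = synth.SyntheticCohortSpec(
        n_participants=config.n_participants,
        session_duration=config.session_duration,
        sampling_rate=config.sampling_rate,
        noise=synth.NoiseSpec(**config.noise),
        seed=config.seed)
    render = config.signal_level == "ecg"
    sessions = synth.generate_cohort(spec, render_ecg=render)
    logger.info("generated %d sessions (%s level)", len(sessions), config.signal_level)
    rows = []
    n_windows = 0
    for s in sessions:
        if render:
            clean = preprocess.denoise(s.ecg)
            peaks = rpeak.detect_r_peaks(clean)
            rr = rpeak.to_rr_intervals(peaks)
            if outdir is not None:
                rr.to_csv(outdir / f"rr_p{s.participant}_s{s.period}.csv")
        else:
            rr = s.rr_true
        wins = rpeak.segment_windows(rr, config.window_length,
                                     total_duration=config.session_duration)
        n_windows += len(wins)
        rows.extend(session_feature_rows(s, rr, config.window_length,
                                         total_duration=config.session_duration))
    table = pd.DataFrame(rows)
    table.attrs["n_sessions"] = len(sessions)
    table.attrs["n_windows"] = n_windows
    logger.info("feature table: %d effective windows of %d candidates",
                len(table), n_windows)
    return table


def participant_split(table: pd.DataFrame, n_test: int, seed: int):
    """Hold out whole participants for testing (seeded random choice)."""
    rng = np.random.default_rng(seed)
    participants = np.sort(table["participant"].unique())
    test_ids = rng.choice(participants, size=n_test, replace=False)
    is_test = table["participant"].isin(test_ids)
    return table[~is_test].copy(), table[is_test].copy()


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    """Execute every stage in order and write all artifacts under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    table = build_feature_table(config, outdir=outdir if config.signal_level == "ecg" else None)
    table.to_csv(outdir / "feature_table.csv", index=False)

    train_tab, test_tab = participant_split(table, config.n_test_participants,
                                            seed=config.seed + 1)
    selection = featstats.select_features(
        train_tab, features=hrv.FEATURE_NAMES, alpha=config.alpha)
    selection.report.to_csv(outdir / "selection_report.csv", index=False)
    logger.info("selected %d features: %s", len(selection.selected), selection.selected)
    if len(selection.selected) < 2:
        raise RuntimeError("selection stage retained fewer than 2 features")

    pca = featstats.fit_pca(train_tab, features=selection.selected,
                            cum_threshold=config.cum_threshold)
    pca.to_json(outdir / "pca_model.json")
    train_scores = featstats.transform_pca(pca, train_tab)
    test_scores = featstats.transform_pca(pca, test_tab)
    train_scores.to_csv(outdir / "train_scores.csv", index=False)
    test_scores.to_csv(outdir / "test_scores.csv", index=False)
    pc_cols = [c for c in train_scores.columns if c.startswith("PC")]
    logger.info("retained %d components (cumulative %.1f%%)", pca.retained,
                100 * pca.cumulative[pca.retained - 1])

    xtr = train_scores[pc_cols].to_numpy()
    ytr = train_scores["state"].to_numpy(dtype=int)
    xte = test_scores[pc_cols].to_numpy()
    yte = test_scores["state"].to_numpy(dtype=int)
    cfg = classify.LVQConfig(seed=config.seed + 2, **config.lvq)
    model = classify.train_lvq(xtr, ytr, cfg)
    model.to_json(outdir / "lvq_model.json")
    pred = classify.predict_lvq(model, xte)
    report = classify.evaluate(yte, pred)
    pd.DataFrame(report.confusion).to_csv(outdir / "confusion.csv", index=False)
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    logger.info("LVQ test accuracy %.2f%%", report.accuracy)

    baselines = {}
    if config.with_baselines:
        base = classify.train_baselines(xtr, ytr, xte, yte, seed=config.seed + 3)
        baselines = {k: v["report"].to_dict() for k, v in base.items()}
        with open(outdir / "baseline_evaluations.json", "w") as fh:
            json.dump(baselines, fh, indent=1)

    run = RunReport(
        config_hash=config.config_hash(), seed=config.seed,
        n_sessions=table.attrs["n_sessions"], n_windows=table.attrs["n_windows"],
        n_effective_windows=len(table),
        selected_features=selection.selected,
        retained_components=pca.retained,
        contribution_rates=[float(w) for w in pca.contribution[:pca.retained]],
        evaluation=report.to_dict(), baseline_evaluations=baselines)
    run.to_json(outdir / "run_report.json")
    return run


def make_fixtures(kind: str, seed: int, outdir) -> Path:
    """Write small deterministic fixture files for testing."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "paper_confusion":
        path = outdir / "reference_confusion.csv"
        pd.DataFrame(REFERENCE_CONFUSION).to_csv(path, index=False, header=False)
    elif kind == "rr_only":
        rr = synth.generate_rr_series(synth.DEFAULT_STATE_PARAMS[0], 120.0, seed)
        path = outdir / "rr_fixture.csv"
        rr.to_csv(path)
    elif kind == "clean_ecg":
        rr = synth.generate_rr_series(synth.DEFAULT_STATE_PARAMS[0], 60.0, seed)
        ecg = synth.synthesize_ecg(rr)
        path = outdir / "clean_ecg.csv"
        ecg.to_csv(path)
    elif kind == "noisy_ecg":
        rr = synth.generate_rr_series(synth.DEFAULT_STATE_PARAMS[0], 60.0, seed)
        ecg = synth.inject_noise(
            synth.synthesize_ecg(rr),
            synth.NoiseSpec(white_sd=0.03, powerline_amp=0.1, baseline_amp=0.15,
                            emg_amp=0.02, seed=seed))
        path = outdir / "noisy_ecg.csv"
        ecg.to_csv(path)
    elif kind == "feature_table":
        cfg = PipelineConfig(n_participants=4, session_duration=400.0,
                             n_test_participants=1, seed=seed)
        table = build_feature_table(cfg)
        path = outdir / "feature_table_fixture.csv"
        table.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown fixture kind: {kind}")
    return path
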