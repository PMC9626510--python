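"""End-to-end orchestration: simulate -> preprocess -> cross-validate -> report."""

from __future__ import annotations

import logging
import time
from pathlib import Path

from . import io
from .baselines import BASELINE_METHODS, BaselineScorer
from .config import RunConfig, stage_seed
from .evaluate import EvalReport, ITRParams, crossval
from .preprocess import average_repetitions, preprocess_session
from .sepcnn import (SepCNNConfig, TrainHyper, build_sepcnn,
                     build_standard_cnn, train)
from .simulate import SimParams, make_schedule, simulate_session

__all__ = ["make_model_factory", "run_pipeline"]

log = logging.getLogger("arp300")


class _NetFactory:
    """Picklable fit/score adapter for the CNN variants."""

    def __init__(self, spec, hyper: TrainHyper):
        self.spec = spec
        self.hyper = hyper
        self.scorer = None

    def fit(self, epochs):
        self.scorer = train(self.spec, epochs, self.hyper)
        return self

    def score(self, epochs):
        return self.scorer.score(epochs)


def make_model_factory(config: RunConfig, input_len: int, n_channels: int):
    """Return a zero-argument factory of fit/score objects for config.model."""
    model = config.model
    if model in ("sepcnn", "cnn"):
        arch_keys = {"depth_kernel", "stride", "padding", "n_pointwise"}
        arch = {k: v for k, v in config.train.items() if k in arch_keys}
        cnn_config = SepCNNConfig(input_len=input_len, n_channels=n_channels, **arch)
        spec = build_sepcnn(cnn_config) if model == "sepcnn" else build_standard_cnn(cnn_config)
        hyper_kw = {k: v for k, v in config.train.items() if k not in arch_keys}
        hyper_kw.setdefault("seed", stage_seed(config.seed, "train"))
        hyper = TrainHyper(**hyper_kw)
        return lambda: _NetFactory(spec, hyper)
    if model in BASELINE_METHODS:
        return lambda: BaselineScorer(model, dict(config.train))
    raise ValueError(f"unknown model {model!r}")


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> EvalReport:
    """Run the full pipeline described by ``config``.

    Stage artifacts (session, epochs, report) are written under ``out_dir``
    when given.  One master seed yields a bit-identical report.
    """
    t0 = time.time()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        log.info("[%s] %.1fs elapsed", name, time.time() - t0)

    try:
        schedule = make_schedule(
            config.runs, config.blocks_per_run, config.trials_per_block,
            config.n_stimuli, config.soa_ms, config.flash_ms,
            config.prep_ms, config.lock_ms,
            seed=stage_seed(config.seed, "schedule"),
        )
        params = SimParams(environment=config.environment, **config.sim)
        session = simulate_session(schedule, params,
                                   seed=stage_seed(config.seed, "session"))
        _stage("simulate")
        if out_dir is not None:
            io.write_session(session, out_dir / "session.h5")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {e}") from e

    try:
        epochs = preprocess_session(
            session, drop=config.drop_channels, lo_hz=config.lo_hz,
            hi_hz=config.hi_hz, window_ms=config.window_ms,
            downsample=config.downsample,
        )
        if config.averages > 1:
            epochs = average_repetitions(epochs, config.averages)
        _stage("preprocess")
        if out_dir is not None:
            io.write_epochs(epochs, out_dir / "epochs.h5")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'preprocess' failed: {e}") from e

    try:
        factory = make_model_factory(config, epochs.n_samples, epochs.n_channels)
        report = crossval(
            epochs, factory, schedule.target_of_block,
            folds=config.folds, seed=stage_seed(config.seed, "crossval"),
            itr_params=ITRParams(config.itr_n_targets, config.itr_selection_time_s),
        )
        _stage("evaluate")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'evaluate' failed: {e}") from e

    if out_dir is not None:
        io.write_report(report, out_dir / "report.json")
    return report
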