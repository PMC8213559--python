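"""End-to-end orchestration: simulate/load -> preprocess -> ANOVA -> fit both
models -> bridge-sampling comparison -> posterior predictive checks.

A :class:`PipelineConfig` pins every input (study design or CSV path,
methods, sampler settings, seeds), round-trips through JSON/YAML, and is
hashed into every report file so outputs are reproducible bit-for-bit from
config + seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparison, models, ppc, preprocessing, synthetic
from .anova import mixed_anova
from .synthetic import RatingDataset

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("magest")

_STUDY_METHODS = {
    1: ("standard", "reversal"),
    2: ("standard", "unidirectional"),
    3: ("standard", "unidirectional"),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one analysis run depends on."""

    study: int = 2
    methods: tuple[str, ...] = ()
    input_csv: str | None = None  # None -> simulate the study design
    bias_lambda: float = 1.0
    chains: int = 4
    warmup: int = 2000
    total_draws: int = 20000
    bridge_reps: int = 10
    n_ppc_rep: int = 10
    seed: int = 0
    out_dir: str = "magest_output"

    def __post_init__(self) -> None:
        if self.study not in _STUDY_METHODS:
            raise ValueError(f"unknown study label {self.study!r} (use 1, 2 or 3)")
        if not self.methods:
            object.__setattr__(self, "methods", _STUDY_METHODS[self.study])
        unknown = set(self.methods) - set(_STUDY_METHODS[self.study])
        if unknown:
            raise ValueError(f"methods {unknown} not part of study {self.study}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _simulate_arm(config: PipelineConfig, method: str) -> RatingDataset:
    pop = synthetic.study_population(config.study, method, seed=config.seed)
    stim = synthetic.study_stimuli(config.study)
    participants = synthetic.draw_participants(pop)
    ds = synthetic.simulate_ratings(participants, stim, method, pop)
    if method in ("standard", "binary_standard") and config.bias_lambda < 1.0:
        ds = synthetic.apply_anchoring_bias(ds, config.bias_lambda)
    return ds


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                log.error("pipeline stage %r failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain and write all artifacts.

    Returns a report dict (also serialised to ``report.json``): preprocessing
    counts, the ANOVA table, per-method posterior summaries for both models,
    WAIC/LOOIC, repeated log marginal likelihoods, the log Bayes factor
    power vs. linear, and PPC summaries.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stim = synthetic.study_stimuli(config.study)
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    # ---- load or simulate -------------------------------------------------
    @_stage("input")
    def _load() -> dict[str, RatingDataset]:
        if config.input_csv is not None:
            full = RatingDataset.from_csv(config.input_csv, stim)
            return {
                m: full.copy_with(
                    full.trials[full.trials["method"] == m].reset_index(drop=True)
                )
                for m in config.methods
            }
        return {m: _simulate_arm(config, m) for m in config.methods}

    arms = _load()

    # ---- preprocess -------------------------------------------------------
    @_stage("preprocess")
    def _prep():
        clean, reports = {}, {}
        for m, ds in arms.items():
            cds, rep = preprocessing.preprocess(ds)
            clean[m] = cds
            reports[m] = dataclasses.asdict(rep)
            cds.to_csv(out / f"clean_{m}.csv")
        return clean, reports

    clean, prep_reports = _prep()
    report["preprocessing"] = prep_reports

    # ---- ANOVA ------------------------------------------------------------
    @_stage("anova")
    def _anova():
        pooled = pd.concat([clean[m].trials for m in config.methods], ignore_index=True)
        if config.study == 1:
            # same simulated panel does both formats in a within design
            between = None
        else:
            # between design: disambiguate participant ids across arms
            pooled = pooled.copy()
            pooled["participant_id"] = (
                pooled["method"].astype(str) + "_" + pooled["participant_id"].astype(str)
            )
            between = "method"
        logged = preprocessing.log_responses(
            clean[config.methods[0]].copy_with(pooled)
        )
        res = mixed_anova(logged, between=between)
        res.to_json(out / "anova.json")
        return res

    if len(config.methods) >= 2:
        _anova()
        report["anova"] = json.loads((out / "anova.json").read_text())
    else:
        report["anova"] = None  # a single arm has no method contrast

    # ---- model fitting + comparison --------------------------------------
    power_spec, linear_spec = models.PowerModelSpec(), models.LinearModelSpec()
    report["models"] = {}
    for m in config.methods:
        mdata = models.prepare_model_data(clean[m], stim)
        arm_seed = int(
            np.random.SeedSequence([config.seed, config.methods.index(m)]).generate_state(1)[0]
            % (2**31 - 1)
        )

        @_stage(f"fit[{m}]")
        def _fit(mdata=mdata, arm_seed=arm_seed):
            fits = {}
            for spec in (power_spec, linear_spec):
                fits[spec.name] = models.fit(
                    spec,
                    mdata,
                    chains=config.chains,
                    warmup=config.warmup,
                    total_draws=config.total_draws,
                    seed=arm_seed,
                )
            return fits

        fits = _fit()

        @_stage(f"compare[{m}]")
        def _compare(fits=fits, arm_seed=arm_seed, m=m):
            res = {}
            mls = {}
            for name, s in fits.items():
                ml = comparison.bridge_logml(
                    s, n_reps=config.bridge_reps, seed=arm_seed, dataset_label=m
                )
                ic = comparison.fit_indices(s.pointwise_loglik)
                mls[name] = ml
                res[name] = {
                    "posterior": s.summary().reset_index().to_dict(orient="records"),
                    "rhat": s.rhat,
                    "converged": s.converged,
                    "logml_mean": ml.mean,
                    "logml_sd": ml.sd,
                    "logml_reps": list(ml.logml_reps),
                    "waic": ic.waic,
                    "waic_se": ic.waic_se,
                    "looic": ic.looic,
                    "looic_se": ic.looic_se,
                }
                s.summary().to_csv(out / f"posterior_{m}_{name}.csv")
            bf = comparison.log_bayes_factor(mls["power"], mls["linear"])
            res["log_bf_power_vs_linear"] = {
                "mean": bf.mean,
                "sd": bf.sd,
                "reps": list(bf.log_bf_reps),
            }
            return res

        arm_report = _compare()

        @_stage(f"ppc[{m}]")
        def _ppc(fits=fits, arm_seed=arm_seed, m=m):
            out_ppc = {}
            for name, s in fits.items():
                rep = ppc.posterior_predictive(
                    s, n_rep=config.n_ppc_rep, seed=arm_seed, condition_label=m
                )
                out_ppc[name] = {
                    "replicate_means": rep.replicate_means().tolist(),
                    "observed_mean": float(rep.y.mean()),
                    "observed_mean_quantile": rep.observed_mean_quantile(),
                }
            return out_ppc

        arm_report["ppc"] = _ppc()
        report["models"][m] = arm_report

    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    config.to_json(out / "config.json")
    return report
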