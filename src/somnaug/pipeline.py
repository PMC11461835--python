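"""End-to-end orchestration: generate -> preprocess -> MCSA -> features ->
CTGAN -> classify -> report.

A run writes, under its output directory: the real / MCSA-augmented /
CTGAN-synthetic feature CSVs, the GAN validation JSON, one evaluation
report per requested band subset plus the combined set, and a manifest
stamping every artifact with the config hash and seed.  ``ablate_layers``
runs the four augmentation arms (none / layer-1 only / layer-2 only /
both) on the same base cohort for the augmentation comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify
from .ctgan import CTGAN, validate_synthetic
from .features import extract_table
from .mcsa import McsaConfig, run_mcsa
from .preprocessing import bandpass_filter, decompose_bands, denoise_wavelet, segment
from .sleep_metrics import summaries_frame
from .synthetic import ArtifactConfig, CohortSpec, generate_cohort

log = logging.getLogger("somnaug.pipeline")

_LAYERS = ("none", "mcsa_only", "ctgan_only", "both")


@dataclass
class PreprocessConfig:
    lo_hz: float = 0.5
    hi_hz: float = 45.0
    order: int = 4
    epoch_s: float = 30.0
    denoise_level: int = 5


@dataclass
class CtganConfig:
    epochs: int = 2000
    batch: int = 500
    n_samples: int = 10000
    seed: int = 0


@dataclass
class EvalConfig:
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma", "combined")
    test_fraction: float = 0.25
    kfold_k: int = 5
    subject_folds: int = 6
    models: tuple[str, ...] = ("DT", "EBDT", "GB", "RF", "SC")


@dataclass
class PipelineConfig:
    """Full run configuration; every stage's knobs in one sectioned object."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    mcsa: McsaConfig = field(default_factory=McsaConfig)
    ctgan: CtganConfig = field(default_factory=CtganConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    layers: str = "both"
    seed: int = 0
    out_dir: str = "somnaug_run"

    def __post_init__(self) -> None:
        if self.layers not in _LAYERS:
            raise ValueError(f"layers must be one of {_LAYERS}, got {self.layers!r}")

    # ---- config file round-trip -------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        raw = yaml.safe_load(p.read_text() if p.exists() else str(source))
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, data: dict):
            names = {f.name: f for f in dataclasses.fields(klass)}
            unknown = set(data) - set(names)
            if unknown:
                raise ValueError(
                    f"unknown config keys for {klass.__name__}: {sorted(unknown)}"
                )
            kwargs = {}
            for k, v in data.items():
                sub = _SECTION_TYPES.get((klass, k))
                if sub is not None and isinstance(v, dict):
                    kwargs[k] = build(sub, v)
                elif k in _TUPLE_KEYS.get(klass, ()) and isinstance(v, list):
                    kwargs[k] = tuple(v)
                else:
                    kwargs[k] = v
            return klass(**kwargs)

        return build(cls, raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


_SECTION_TYPES = {
    (PipelineConfig, "cohort"): CohortSpec,
    (PipelineConfig, "preprocess"): PreprocessConfig,
    (PipelineConfig, "mcsa"): McsaConfig,
    (PipelineConfig, "ctgan"): CtganConfig,
    (PipelineConfig, "eval"): EvalConfig,
    (CohortSpec, "artifact_config"): ArtifactConfig,
}
_TUPLE_KEYS = {EvalConfig: ("bands", "models")}


def _selected_models(cfg: PipelineConfig) -> list[classify.ModelSpec]:
    wanted = set(cfg.eval.models)
    return [m for m in classify.build_models() if m.name in wanted]


def build_training_table(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run generation, preprocessing, augmentation and feature extraction.

    Returns the intermediate tables: ``real`` (one row per subject),
    ``mcsa`` (layer-1 rows, empty if disabled), ``ctgan`` (layer-2 rows,
    empty if disabled) and ``training`` (their concatenation per the
    configured ``layers``), plus the GAN validation report when layer 2 ran.
    """
    cohort = generate_cohort(cfg.cohort)
    log.info("stage=simulate signals_out=%d", len(cohort))

    pp = cfg.preprocess
    pairs = []
    filtered = []
    for sig in cohort:
        den = denoise_wavelet(sig, level=pp.denoise_level)
        filt = bandpass_filter(den, lo=pp.lo_hz, hi=pp.hi_hz, order=pp.order)
        seg = segment(decompose_bands(filt), epoch_s=pp.epoch_s)
        pairs.append((seg, filt))
        filtered.append(filt)
    log.info("stage=preprocess signals_out=%d segments=%d",
             len(pairs), pairs[0][0].n_segments if pairs else 0)

    real = extract_table(cohort)
    tables = {"real": real}

    if cfg.layers in ("mcsa_only", "both"):
        aug = run_mcsa(pairs, cfg.mcsa)
        log.info("stage=mcsa signals_out=%d", len(aug))
        tables["mcsa"] = extract_table(aug)
    else:
        tables["mcsa"] = real.iloc[0:0]
    log.info("stage=features rows_out=%d", len(real) + len(tables["mcsa"]))

    base = pd.concat([real, tables["mcsa"]], ignore_index=True)
    if cfg.layers in ("ctgan_only", "both"):
        gan = CTGAN()
        gan.fit(
            base.drop(columns=["subject_id", "provenance"]),
            discrete_columns=("label",),
            epochs=cfg.ctgan.epochs,
            batch_size=cfg.ctgan.batch,
            seed=cfg.ctgan.seed,
        )
        fake = gan.sample(cfg.ctgan.n_samples, seed=cfg.ctgan.seed)
        fake["subject_id"] = "ctgan"
        fake["provenance"] = "ctgan"
        tables["ctgan"] = fake[base.columns]
        tables["gan_validation"] = validate_synthetic(
            base.drop(columns=["subject_id", "provenance"]),
            fake.drop(columns=["subject_id", "provenance"])[
                base.drop(columns=["subject_id", "provenance"]).columns
            ],
        )
        log.info("stage=ctgan rows_out=%d", len(fake))
    else:
        tables["ctgan"] = real.iloc[0:0]

    tables["training"] = pd.concat(
        [base, tables["ctgan"]], ignore_index=True
    )
    tables["cohort_meta"] = summaries_frame([s.meta for s in cohort])
    return tables


def run(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline and write all artifacts; returns run dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    try:
        tables = build_training_table(cfg)
    except Exception as exc:  # surface the failing stage
        raise RuntimeError(f"pipeline failed during data build: {exc}") from exc

    cfg.to_yaml(out / "config.yaml")
    for name in ("real", "mcsa", "ctgan", "training"):
        tables[name].to_csv(out / f"features_{name}.csv", index=False)
    tables["cohort_meta"].to_csv(out / "cohort_sleep_summary.csv", index=False)
    if "gan_validation" in tables:
        (out / "gan_validation.json").write_text(
            json.dumps({**stamp, **tables["gan_validation"]}, indent=2)
        )

    models = _selected_models(cfg)
    training = tables["training"]
    reports = {}
    for band in cfg.eval.bands:
        try:
            hold = classify.holdout_eval(
                training, cfg.eval.test_fraction, band=band, models=models
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed during evaluate[{band}]: {exc}") from exc
        reports[band] = {name: r.to_dict() for name, r in hold.items()}
        (out / f"eval_{band}.json").write_text(
            json.dumps({**stamp, "band": band, "holdout": reports[band]}, indent=2)
        )
    log.info("stage=evaluate bands=%d models=%d", len(cfg.eval.bands), len(models))

    manifest = {
        **stamp,
        "layers": cfg.layers,
        "rows": {k: len(tables[k]) for k in ("real", "mcsa", "ctgan", "training")},
        "reports": [f"eval_{b}.json" for b in cfg.eval.bands],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def ablate_layers(cfg: PipelineConfig, model: str = "EBDT") -> pd.DataFrame:
    """Run the four augmentation arms on the same cohort and seed.

    Returns one accuracy per arm (holdout, combined band) for the chosen
    model, with the training-set size of each arm.
    """
    rows = []
    for arm in _LAYERS:
        arm_cfg = dataclasses.replace(cfg, layers=arm)
        tables = build_training_table(arm_cfg)
        training = tables["training"]
        spec = [m for m in classify.build_models() if m.name == model]
        if not spec:
            raise ValueError(f"unknown model {model!r}")
        hold = classify.holdout_eval(
            training, cfg.eval.test_fraction, band="combined", models=spec
        )
        rows.append(
            {
                "arm": arm,
                "model": model,
                "training_rows": len(training),
                "accuracy": hold[model].accuracy,
            }
        )
        log.info("stage=ablate arm=%s rows=%d acc=%.3f",
                 arm, len(training), hold[model].accuracy)
    return pd.DataFrame(rows)
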