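"""End-to-end orchestration: simulate -> preprocess -> features -> train -> evaluate.

One global seed fans out deterministically (via numpy's SeedSequence) to
the simulation, split, cross-validation and swarm stages, so a rerun with
the same config is reproducible bit for bit.  No fitting step ever sees
validation samples: the multiplicative-scatter-correction reference, the
fresh reference spectrum, feature standardization and every classifier are
learned on the calibration split alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import corr2d, evaluation, lda, preprocess, svm, threshold
from .dataio import SpectralDataset, write_spectra
from .exceptions import ConfigError
from .synthetic import SynthConfig, generate_dataset

FEATURE_SPACES = ("visnir", "corr2d_auto")
MODELS = ("threshold", "lda", "svm")


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    seed: int = 0
    outdir: str | None = None
    synth: SynthConfig | None = None
    preprocess_method: str = "raw"
    feature_space: str = "corr2d_auto"
    model: str = "svm"
    svm_kernel: str = "rbf"
    optimize: str = "grid"  # none | grid | grid+pso
    cv_folds: int = 5
    lda_dimensions: int | None = None
    threshold_k_sd: float = 3.0
    pso: svm.PSOConfig | None = None

    def __post_init__(self) -> None:
        if self.feature_space not in FEATURE_SPACES:
            raise ConfigError(f"feature_space must be one of {FEATURE_SPACES}")
        if self.model not in MODELS:
            raise ConfigError(f"model must be one of {MODELS}")
        if self.optimize not in ("none", "grid", "grid+pso"):
            raise ConfigError("optimize must be none | grid | grid+pso")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Build a run configuration from a YAML mapping.

        Top-level keys mirror the dataclass fields; the nested ``synth`` and
        ``pso`` mappings are forwarded to SynthConfig / PSOConfig.
        """
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigError("run config must be a YAML mapping")
        if "synth" in doc and doc["synth"] is not None:
            doc["synth"] = SynthConfig(**doc["synth"])
        if "pso" in doc and doc["pso"] is not None:
            doc["pso"] = svm.PSOConfig(**doc["pso"])
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**doc)


def derive_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("synth", "split", "cv", "pso")
    return {k: int(v % (2**31)) for k, v in zip(names, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_features(
    ds: SpectralDataset, ref: np.ndarray, feature_space: str
) -> np.ndarray:
    """Raw absorbance rows, or per-sample autocorrelation (squared dynamic) rows."""
    if feature_space == "visnir":
        return ds.values.copy()
    d = ds.values - ref
    return d * d


def run_pipeline(cfg: RunConfig) -> evaluation.EvaluationReport:
    """Run the configured pipeline and return the validation report.

    Artifacts (dataset CSV, model JSON, report JSON, each with a sha256
    recorded in the report metadata) are written under cfg.outdir when one
    is given.
    """
    seeds = derive_seeds(cfg.seed)
    synth_cfg = cfg.synth or SynthConfig()
    synth_cfg = replace(synth_cfg, seed=seeds["synth"])
    ds = generate_dataset(synth_cfg)
    cal, val = ds.calibration, ds.validation

    # pretreatment fitted on calibration only (MSC reference = calibration mean)
    pp_cfg = preprocess.PreprocessConfig(
        method=cfg.preprocess_method,
        msc_reference=cal.mean_spectrum()
        if cfg.preprocess_method == "msc"
        else None,
    )
    cal_p = preprocess.apply_preprocessing(cal, pp_cfg)
    val_p = preprocess.apply_preprocessing(val, pp_cfg)

    # fresh reference from calibration A-samples only
    ref = corr2d.reference_spectrum(cal_p.where_label("A"))

    X_cal = build_features(cal_p, ref.absorbance, cfg.feature_space)
    X_val = build_features(val_p, ref.absorbance, cfg.feature_space)
    y_cal = cal_p.labels.astype(str)
    y_val = val_p.labels.astype(str)

    metadata: dict = {
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "preprocess": cfg.preprocess_method,
        "feature_space": cfg.feature_space,
        "model": cfg.model,
        "n_calibration": len(cal),
        "n_validation": len(val),
    }
    model_doc: dict

    if cfg.model == "threshold":
        model = threshold.fit_thresholds(
            cal_p.where_label("A"), ref, k_sd=cfg.threshold_k_sd
        )
        pred = np.array(
            [threshold.classify_threshold(s, ref, model) for s in val_p],
            dtype=object,
        )
        truth = np.where(y_val == "A", threshold.FRESH, threshold.NON_FRESH)
        report = evaluation.evaluate(
            truth, pred, classes=(threshold.FRESH, threshold.NON_FRESH),
            metadata=metadata,
        )
        model_doc = model.to_dict()
    elif cfg.model == "lda":
        d = lda.LabeledSpectralMatrix.build(X_cal, y_cal)
        model = lda.fit_lda(
            d, m=cfg.lda_dimensions, feature_space=cfg.feature_space
        )
        pred = lda.classify_lda_batch(X_val, model)
        report = evaluation.evaluate(y_val, pred, metadata=metadata)
        model_doc = model.to_dict()
    else:
        base = svm.SVMConfig(
            kernel=cfg.svm_kernel, cv_folds=cfg.cv_folds, seed=seeds["cv"]
        )
        if cfg.optimize in ("grid", "grid+pso"):
            grid = svm.grid_search(X_cal, y_cal, base)
            base = replace(base, C_penalty=grid.best_C, G_gamma=grid.best_G)
            metadata["grid_best"] = {"C": grid.best_C, "G": grid.best_G,
                                     "cv_accuracy": grid.best_score}
        if cfg.optimize == "grid+pso":
            pso_cfg = cfg.pso or svm.PSOConfig()
            pso_cfg = replace(
                pso_cfg,
                seed=seeds["pso"],
                log2C_bounds=_refine_bounds(np.log2(base.C_penalty),
                                            svm.DEFAULT_LOG2C_RANGE),
                log2G_bounds=_refine_bounds(np.log2(base.G_gamma),
                                            svm.DEFAULT_LOG2G_RANGE),
            )
            res = svm.pso_optimize(X_cal, y_cal, base, pso_cfg)
            base = replace(base, C_penalty=res.best_C, G_gamma=res.best_G)
            metadata["pso_best"] = {"C": res.best_C, "G": res.best_G,
                                    "cv_accuracy": res.best_score}
        model = svm.train_svm(X_cal, y_cal, base, feature_space=cfg.feature_space)
        metadata["cv_accuracy"] = svm.cross_val_accuracy(X_cal, y_cal, base)
        metadata["support_count"] = model.support_count
        pred = model.predict(X_val)
        report = evaluation.evaluate(y_val, pred, metadata=metadata)
        model_doc = model.to_dict()

    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        ds_path = out / "dataset.csv"
        write_spectra(ds, ds_path)
        model_path = out / "model.json"
        model_path.write_text(json.dumps(model_doc, indent=1))
        report.metadata["artifacts"] = {
            "dataset.csv": _sha256(ds_path),
            "model.json": _sha256(model_path),
        }
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    return report


def _refine_bounds(center: float, outer: tuple[float, float],
                   half_width: float = 4.0) -> tuple[float, float]:
    """A +/- half_width log2 window around the grid optimum, clipped to the box."""
    return (max(outer[0], center - half_width), min(outer[1], center + half_width))
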