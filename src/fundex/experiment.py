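"""End-to-end experiment orchestration.

One experiment: generate or load a dataset, hold out a fixed 80/20
validation split, train the codec on the training side only, then for each
requested training-data fraction train two classifiers — *baseline* on the
subsample alone and *enhanced* on the subsample plus its 100 % latent-space
expansion — and evaluate both on the same untouched validation set.  The
comparison across fractions traces the learning curve with and without
enhancement.

Every stage is seeded; the run manifest records the configuration and all
derived seeds so a run can be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from .augment import ExpansionPlan, expand_dataset
from .classifier import (SplitSpec, TrainRecipe, predict, split_dataset,
                         subsample_train, train_classifier)
from .codec import CodecConfig, CodecState, train_codec
from .data import ImageDataset
from .fixtures import FixtureConfig, generate_fixture
from .metrics import EvalReport, evaluate_scores

__all__ = ["ExperimentConfig", "FractionResult", "run_experiment"]


@dataclasses.dataclass
class ExperimentConfig:
    fixture: FixtureConfig = dataclasses.field(default_factory=FixtureConfig)
    codec: CodecConfig | None = None  # defaults to fixture image size
    plan: ExpansionPlan = dataclasses.field(default_factory=ExpansionPlan)
    recipe: TrainRecipe = dataclasses.field(
        default_factory=lambda: TrainRecipe(input_side=32, epochs=15))
    split: SplitSpec = dataclasses.field(default_factory=SplitSpec)
    fractions: tuple[float, ...] = (1.0,)
    codec_steps_level1: int = 400
    codec_steps_level2: int = 200
    n_boot: int = 500
    seed: int = 0

    def resolve_codec(self) -> CodecConfig:
        if self.codec is not None:
            return self.codec
        return CodecConfig(image_size=self.fixture.image_size, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["codec"] = self.resolve_codec().to_dict()
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclasses.dataclass
class FractionResult:
    fraction: float
    n_train_baseline: int
    n_train_enhanced: int
    baseline: EvalReport
    enhanced: EvalReport

    def row(self) -> dict:
        return {
            "fraction": self.fraction,
            "n_train_baseline": self.n_train_baseline,
            "n_train_enhanced": self.n_train_enhanced,
            "auc_baseline": self.baseline.auc,
            "auc_enhanced": self.enhanced.auc,
            "sens_baseline": self.baseline.sensitivity,
            "sens_enhanced": self.enhanced.sensitivity,
            "spec_baseline": self.baseline.specificity,
            "spec_enhanced": self.enhanced.specificity,
        }


def run_experiment(config: ExperimentConfig,
                   dataset: ImageDataset | None = None,
                   out_dir: str | Path | None = None,
                   ) -> tuple[list[FractionResult], CodecState]:
    """Run the baseline-vs-enhanced comparison at each training fraction.

    Returns the per-fraction paired reports and the trained codec.  If
    ``out_dir`` is given, writes ``comparison.csv``, per-arm report JSONs
    and a reproducibility manifest.
    """
    if dataset is None:
        fx = dataclasses.replace(config.fixture, seed=config.fixture.seed)
        dataset = generate_fixture(fx)

    split = dataclasses.replace(config.split, seed=config.split.seed)
    train, val = split_dataset(dataset, split)
    val_ids = tuple(val.ids)

    codec_cfg = config.resolve_codec()
    codec = train_codec(train, codec_cfg, 1, steps=config.codec_steps_level1,
                        seed=config.seed * 9973 + 1)
    codec = train_codec(train, codec_cfg, 2, steps=config.codec_steps_level2,
                        state=codec, seed=config.seed * 9973 + 2)

    results: list[FractionResult] = []
    for fi, frac in enumerate(config.fractions):
        sub = (train if frac == 1.0
               else subsample_train(train, frac, seed=config.seed * 131 + fi))
        plan = dataclasses.replace(config.plan,
                                   seed=config.plan.seed * 131 + fi)
        expanded = expand_dataset(sub, codec, plan)

        recipe = dataclasses.replace(config.recipe, seed=config.seed * 17 + fi)
        base_state = train_classifier(sub, recipe, validation=val)
        enh_state = train_classifier(expanded, recipe, validation=val)

        # the validation set must be byte-identical across arms and fractions
        assert tuple(val.ids) == val_ids
        y = val.labels
        base_rep = evaluate_scores(predict(base_state, val), y,
                                   n_boot=config.n_boot, seed=config.seed)
        enh_rep = evaluate_scores(predict(enh_state, val), y,
                                  n_boot=config.n_boot, seed=config.seed)
        results.append(FractionResult(
            fraction=frac, n_train_baseline=len(sub),
            n_train_enhanced=len(expanded),
            baseline=base_rep, enhanced=enh_rep,
        ))

    if out_dir is not None:
        _write_outputs(config, results, Path(out_dir))
    return results, codec


def _write_outputs(config: ExperimentConfig, results: list[FractionResult],
                   out_dir: Path) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([r.row() for r in results]).to_csv(
        out_dir / "comparison.csv", index=False)
    for r in results:
        tag = f"frac{int(round(100 * r.fraction)):03d}"
        r.baseline.save_json(out_dir / f"report_{tag}_baseline.json")
        r.enhanced.save_json(out_dir / f"report_{tag}_enhanced.json")
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
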