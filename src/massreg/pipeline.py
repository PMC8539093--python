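"""End-to-end demo pipeline: fixtures through evaluation in one call.

``run_full_demo`` wires the whole workflow together on synthetic data:
generate fixtures, preprocess a phantom sample, build the simulated
datasets, run the two-stage registration curriculum and the three-stage
similarity curriculum, register and score held-out pairs, and emit a dice
/ FRE / sensitivity report.  Every artifact lands under one output
directory and is listed in a manifest traceable to the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, metrics, regnet, siamese, simulate
from .checkpoint import save_model
from .config import RunConfig, config_hash, save_config
from .fixtures import PhantomSpec, make_demo_fold, make_phantom_slide
from .preprocess import PreprocessParams, preprocess_pair
from .types import IMAGE_SIZE, LabeledPair

log = logging.getLogger("massreg")

STAGES = (
    "fixtures",
    "preprocess",
    "simulate",
    "train_reg_exp1",
    "train_reg_exp2",
    "train_eval_exp3",
    "train_eval_exp4",
    "train_eval_exp5",
    "evaluate",
)


def _write_masks(out_dir: Path, masks, prefix: str):
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, m in enumerate(masks):
        p = out_dir / f"{prefix}{i:03d}.png"
        io.write_image(p, m)
        paths.append(p.name)
    return paths


def run_full_demo(config: RunConfig, out_dir) -> dict:
    """Run the full scaled-down workflow; returns the pipeline manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    manifest: dict = {
        "config_hash": config_hash(config),
        "seed": int(config.seed),
        "stages": {},
    }

    def done(stage, **info):
        manifest["stages"][stage] = {"status": "complete", **info}
        log.info("stage %s complete", stage)

    try:
        # 1. fixtures -------------------------------------------------------
        train_masks, test_masks = make_demo_fold(
            config.n_train_masks, config.n_test_masks, seed=config.seed
        )
        rgb, cube, truth = make_phantom_slide(PhantomSpec(seed=config.seed))
        _write_masks(out / "masks_train", train_masks, "train")
        _write_masks(out / "masks_test", test_masks, "test")
        done("fixtures", n_train=len(train_masks), n_test=len(test_masks))

        # 2. preprocess the phantom sample ---------------------------------
        fixed_ph, moving_ph = preprocess_pair(
            rgb, cube, PreprocessParams(), calibrate=False
        )
        io.write_image(out / "phantom_fixed.png", fixed_ph)
        io.write_image(out / "phantom_moving.png", moving_ph)
        from skimage.transform import resize

        truth64 = (
            resize(truth, (IMAGE_SIZE, IMAGE_SIZE), order=0, preserve_range=True)
            > 0.5
        ).astype(float)
        phantom_dice = metrics.dice(fixed_ph, truth64)
        done("preprocess", phantom_dice=round(phantom_dice, 4))

        # 3. simulated datasets --------------------------------------------
        sims = {}
        for which, salt in (("sim1", 1), ("sim2", 2), ("sim3", 3)):
            pairs = simulate.build_dataset(
                which, train_masks, config.rng(salt), noise=config.noise,
                n_virtual_cores=config.n_virtual_cores,
            )
            io.write_pairset(out / which, pairs)
            sims[which] = pairs
        done("simulate", counts={k: len(v) for k, v in sims.items()})

        # 4-5. registration curriculum -------------------------------------
        reg = regnet.RegistrationNet(config.reg)
        reg, hist1 = regnet.train_registration(reg, sims["sim1"], config.reg, "exp1")
        save_model(out / "reg_exp1.npz", reg)
        done("train_reg_exp1", final_loss=round(hist1[-1], 6), epochs=len(hist1))

        standin = simulate.make_multimodal_standin(
            train_masks, config.rng(4), noise=config.noise
        )
        reg, hist2 = regnet.train_registration(reg, standin, config.reg, "exp2")
        save_model(out / "reg_exp2.npz", reg)
        done("train_reg_exp2", final_loss=round(hist2[-1], 6), standin=True)

        # 6-8. similarity curriculum ---------------------------------------
        sia = siamese.SiameseNet(config.eval)
        histories = {}
        for stage, data in (
            ("exp3", sims["sim2"]),
            ("exp4", sims["sim3"]),
            ("exp5", standin),
        ):
            sia, h = siamese.train_siamese(sia, stage, data, config.eval)
            save_model(out / f"siamese_{stage}.npz", sia)
            histories[stage] = h["one_shot"]
            done(
                f"train_eval_{stage}",
                one_shot=h["one_shot"][-1][1] if h["one_shot"] else None,
                standin=stage == "exp5",
            )

        # 9. held-out registration + report --------------------------------
        rng = config.rng(5)
        rows = []
        for i, mask in enumerate(test_masks):
            pair = simulate.make_misaligned_pair(
                mask, simulate._random_misalignment(rng)
            )
            moved, field = regnet.register(reg, pair.fixed, pair.moving)
            io.write_image(out / f"registered_{i:02d}.png", np.clip(moved, 0, 1))
            rows.append(
                {
                    "pair": i,
                    "dice_before": metrics.dice(pair.fixed, pair.moving),
                    "dice_after": metrics.dice(pair.fixed, moved),
                    "similarity": siamese.predict_similarity(
                        sia, pair.fixed, np.clip(moved, 0, 1)
                    ),
                }
            )
        report = pd.DataFrame(rows)
        report.to_csv(out / "report.csv", index=False)
        sweep = metrics.sensitivity_sweep(sia, test_masks)
        sweep.to_csv(out / "sweep.csv", index=False)
        done(
            "evaluate",
            mean_dice_before=round(float(report.dice_before.mean()), 4),
            mean_dice_after=round(float(report.dice_after.mean()), 4),
            mean_similarity=round(float(report.similarity.mean()), 4),
        )
    except Exception as exc:
        failed = next((s for s in STAGES if s not in manifest["stages"]), "unknown")
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
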