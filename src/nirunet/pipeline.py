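"""End-to-end pipeline: simulate -> train -> evaluate -> report + plots."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from . import phantom_sim, quality_metrics
from .config import RunConfig, derive_seeds
from .train import (TrainConfig, load_split, reconstruct_batch,
                    train as train_model)
from .wiener import wiener_reconstruct

log = logging.getLogger(__name__)


class _HashAdapter(logging.LoggerAdapter):
    def process(self, msg, kwargs):
        return f"[cfg {self.extra['cfg_hash']}] {msg}", kwargs


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full study on one configuration.

    Stages: simulate a paired dataset, train the configured network variant,
    evaluate it on the held-out test split against the Wiener baseline and
    the raw captured images, and write a metrics report plus an intensity-
    profile plot.  Every artifact is stamped with the config hash and seed;
    per-stage wall times and seeds are logged.

    Returns a dict of artifact paths: ``manifest``, ``checkpoint``,
    ``report_csv``, ``report_json``, ``profile_png``.
    """
    clog = _HashAdapter(log, {"cfg_hash": config.hash})
    seeds = derive_seeds(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clog.info("derived stage seeds: %s", seeds)

    t0 = time.perf_counter()
    manifest = phantom_sim.build_dataset(
        n=config.n_pairs, params=config.phantom, seed=seeds["simulate"],
        out_dir=out / "data", fractions=config.fractions,
        size=config.image_size, glyph_kinds=config.glyph_kinds)
    clog.info("simulate: %d pairs (seed %d) in %.1fs", config.n_pairs,
              seeds["simulate"], time.perf_counter() - t0)

    t0 = time.perf_counter()
    tcfg = TrainConfig(**{**config.training.to_dict(), "seed": seeds["init"]})
    checkpoint = train_model(config.unet, tcfg, manifest)
    ckpt_path = out / "checkpoint"
    checkpoint.save(ckpt_path)
    clog.info("train: %s, best epoch %d (seed %d) in %.1fs",
              config.unet.variant, checkpoint.best_epoch, seeds["init"],
              time.perf_counter() - t0)

    t0 = time.perf_counter()
    model = checkpoint.restore()
    x_test, y_test = load_split(manifest, "test")
    recon = reconstruct_batch(model, x_test)
    pairs = list(zip(y_test, x_test))
    methods = {
        config.unet.variant:
            lambda c: model.forward(c[None].astype("float32"))[0],
        "wiener":
            lambda c: wiener_reconstruct(c, config.wiener_window,
                                         config.wiener_noise_power,
                                         normalize=True),
    }
    report = quality_metrics.evaluate_methods(pairs, methods, config.metrics)
    report_csv, report_json = out / "report.csv", out / "report.json"
    report.to_csv(report_csv)
    report.to_json(report_json)
    clog.info("evaluate: %d test pairs in %.1fs\n%s", len(pairs),
              time.perf_counter() - t0, report)

    profile_png = out / "profile.png"
    quality_metrics.plot_profiles(y_test[0], recon[0],
                                  row_index=y_test[0].shape[0] // 2,
                                  out_path=profile_png)

    stamp = {"config_hash": config.hash, "seed": config.seed,
             "stage_seeds": seeds}
    (out / "run_stamp.json").write_text(json.dumps(stamp, indent=1))

    return {"manifest": out / "data" / "manifest.json",
            "checkpoint": ckpt_path.with_suffix(".npz"),
            "report_csv": report_csv, "report_json": report_json,
            "profile_png": profile_png}
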