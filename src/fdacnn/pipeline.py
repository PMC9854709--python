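"""End-to-end runs driven by a manifest.

A manifest (YAML mapping or dict) pins every stage — phantom generation,
mask construction, training, reconstruction and evaluation — to seeds
and explicit parameters, so a run is reproducible from the manifest
alone. All artifact paths are created under ``outdir``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .kspace import MaskSpec, make_mask
from .metrics import evaluate_batch
from .network import ModelConfig, build_model, build_unet_baseline
from .phantoms import PhantomSpec, generate_dataset, save_dataset
from .training import TrainConfig, reconstruct, train

__all__ = ["default_manifest", "run_end_to_end"]


def default_manifest(outdir: str = "run", seed: int = 0) -> dict:
    """A small end-to-end demo manifest (64x64, minutes on one CPU)."""
    return {
        "seed": seed,
        "outdir": outdir,
        "phantom": {"n": 30, "image_size": 64, "n_ellipses": 6, "noise_sd": 0.01},
        "mask": {"kind": "mcp", "sampling_rate": 0.20},
        "model": {"arch": "fdacnn", "k1": 2, "f1": 16, "stem_channels": 8},
        "train": {"lr0": 1e-3, "epochs": 5, "batch_size": 8},
    }


def load_manifest(path) -> dict:
    import yaml

    with open(path) as f:
        manifest = yaml.safe_load(f)
    if not isinstance(manifest, dict):
        raise ConfigurationError("manifest must be a mapping")
    return manifest


def run_end_to_end(manifest: dict) -> dict[str, str]:
    """phantom -> mask -> subsample -> train -> reconstruct -> evaluate.

    Returns a dict of output paths; raises with the failing stage name
    on error.
    """
    seed = int(manifest.get("seed", 0))
    outdir = Path(manifest.get("outdir", "run"))
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    stage = "phantom"
    try:
        ph = dict(manifest.get("phantom", {}))
        n = int(ph.pop("n", 30))
        spec = PhantomSpec(seed=seed, **ph)
        data = generate_dataset(n, spec)
        paths["dataset"] = str(outdir / "dataset.h5")
        save_dataset(data, paths["dataset"])

        stage = "mask"
        mk = dict(manifest.get("mask", {}))
        mask_spec = MaskSpec(image_size=spec.image_size, seed=seed, **mk)
        mask = make_mask(mask_spec)
        paths["mask"] = str(outdir / "mask.npy")
        np.save(paths["mask"], mask.matrix)

        stage = "model"
        md = dict(manifest.get("model", {}))
        arch = md.pop("arch", "fdacnn")
        config = ModelConfig(input_size=spec.image_size, init_seed=seed, **md)
        model = build_model(config) if arch == "fdacnn" else build_unet_baseline(config)

        stage = "train"
        tc = dict(manifest.get("train", {}))
        train_config = TrainConfig(seed=seed, **tc)
        model, history = train(model, data, mask_spec, train_config)
        paths["checkpoint"] = str(outdir / "model.npz")
        model.save(paths["checkpoint"])
        paths["history"] = str(outdir / "history.json")
        with open(paths["history"], "w") as f:
            json.dump(
                {"train_loss": history.train_loss, "val_loss": history.val_loss, "lr": history.lr},
                f,
                indent=2,
            )

        stage = "reconstruct"
        test_idx = data.indices("test")
        targets = [data.images[i] for i in test_idx]
        from .kspace import zero_filled_recon

        zero_filled = [zero_filled_recon(data.kspaces[i].values, mask) for i in test_idx]
        recons = [reconstruct(model, data.kspaces[i].values, mask) for i in test_idx]

        stage = "evaluate"
        report = evaluate_batch(targets, recons, labels=test_idx, mask_kind=mask_spec.kind)
        zf_report = evaluate_batch(targets, zero_filled, labels=test_idx, mask_kind=mask_spec.kind)
        paths["report_csv"] = str(outdir / "report.csv")
        report.to_csv(paths["report_csv"])
        paths["report_json"] = str(outdir / "report.json")
        with open(paths["report_json"], "w") as f:
            json.dump(
                {"model": report.to_json(), "zero_filled": zf_report.to_json()},
                f,
                indent=2,
            )

        manifest_out = dict(manifest)
        manifest_out["outputs"] = paths
        paths["manifest"] = str(outdir / "manifest.json")
        with open(paths["manifest"], "w") as f:
            json.dump(manifest_out, f, indent=2, default=str)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return paths
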