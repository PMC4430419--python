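"""File round-trips: TIFF stacks/labels, CSV tables, YAML configs, Newick."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .image_pipeline import ImageStack, LabeledObjects, PipelineConfig
from .synthetic_data import GroundTruth


def write_stack(path, stack: ImageStack) -> None:
    """Multi-page TIFF with pixel size recorded in the resolution tags."""
    res = 1.0 / stack.pixel_size_um  # pixels per micrometer
    tifffile.imwrite(path, stack.voxels, resolution=(res, res),
                     resolutionunit="MICROMETER",
                     metadata={"pixel_size_um": stack.pixel_size_um,
                               **{k: v for k, v in stack.metadata.items()
                                  if isinstance(v, (str, int, float))}})


def read_stack(path, pixel_size_um: float | None = None) -> ImageStack:
    """Read a single-channel multi-page TIFF as an ImageStack."""
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        if pixel_size_um is None:
            pixel_size_um = 0.2
            try:
                tags = tf.pages[0].tags
                num, den = tags["XResolution"].value
                if tags["ResolutionUnit"].value and num:
                    pixel_size_um = den / num
            except (KeyError, TypeError, ZeroDivisionError):
                pass
    if voxels.ndim == 2:
        voxels = voxels[None]
    return ImageStack(voxels, pixel_size_um=pixel_size_um)


def write_labels(path, objects: LabeledObjects) -> None:
    tifffile.imwrite(path, objects.label_image.astype(np.uint16))


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def write_ground_truth(stem, truth: GroundTruth) -> None:
    """Label TIFF + JSON sidecar with per-structure generator parameters."""
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".labels.tif"),
                     truth.object_labels.astype(np.uint16))
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump({"n_objects": truth.n_objects,
                   "per_object_shape": truth.per_object_shape}, fh, indent=2)


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "laplacian_scales_px" in data:
        data["laplacian_scales_px"] = tuple(data["laplacian_scales_px"])
    return PipelineConfig.from_dict(data)


def write_config(path, config: PipelineConfig) -> None:
    data = {**config.__dict__}
    data["laplacian_scales_px"] = list(data["laplacian_scales_px"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
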