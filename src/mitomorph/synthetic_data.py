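"""Synthetic data with known ground truth for every pipeline stage.

Emulates the three mitochondrial network phenotypes seen in *C. elegans*
body-wall muscle under mitotoxic drug exposure:

* ``tubular``    — long, persistent tubules (complex networks),
* ``fragmented`` — blob-like ellipses (fission-dominated networks),
* ``control``    — a semi-aligned network of intermediate-length tubules,

plus tabular fixtures: feature tables with planted class structure, qPCR
Ct tables generated from a log-linear standard curve, and linear oxygen
consumption traces.

All randomness flows through one ``numpy.random.Generator`` seeded from the
``seed`` field/argument; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, morphology
from skimage.measure import label as _cc_label

from .assay_stats import StandardCurve
from .image_pipeline import ImageStack
from .morphometry import SHAPE_COLUMNS, TEXTURE_COLUMNS

PHENOTYPES = ("control", "tubular", "fragmented")


@dataclass
class PhenotypeParams:
    """Generator settings for one phenotype.

    ``filament_length_px`` / ``blob_radius_px`` are (mean, sd) of normal
    draws; which family is active depends on the phenotype: ``tubular`` and
    ``control`` render persistent-random-walk tubules (long vs intermediate),
    ``fragmented`` renders elliptical blobs. ``persistence`` in [0, 1] is the
    curvature memory of the walk (1 = straight). ``snr`` is the peak-signal
    to noise-sd ratio at the brightest pixel.
    """

    phenotype: str = "control"
    n_structures: int = 14
    filament_length_px: tuple[float, float] = (28.0, 8.0)
    persistence: float = 0.7
    blob_radius_px: tuple[float, float] = (4.0, 1.0)
    width_px: float = 3.0
    psf_sigma_px: float = 1.0
    snr: float = 10.0
    background_level: float = 20.0
    n_defocused_slices: int = 2
    seed: int = 0
    # rendering geometry
    shape: tuple[int, int] = (256, 256)
    n_focus_slices: int = 3
    peak_level: float = 220.0
    pixel_size_um: float = 0.2

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.n_structures < 0:
            raise ValueError("n_structures must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if min(self.shape) <= 0:
            raise ValueError("non-positive image dimensions")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")


def phenotype_params(phenotype: str, seed: int = 0, **overrides) -> PhenotypeParams:
    """Default parameter sets for the three phenotypes."""
    presets = {
        "control": dict(n_structures=14, filament_length_px=(28.0, 8.0),
                        persistence=0.7),
        "tubular": dict(n_structures=12, filament_length_px=(75.0, 15.0),
                        persistence=0.88),
        "fragmented": dict(n_structures=26, blob_radius_px=(4.0, 1.0)),
    }
    kw = {**presets[phenotype], **overrides}
    return PhenotypeParams(phenotype=phenotype, seed=seed, **kw)


@dataclass
class GroundTruth:
    """True in-focus content of a simulated stack.

    ``object_labels`` labels the connected components of the union mask
    with consecutive positive integers (structures that happen to touch
    merge into one object, exactly as a segmenter would see them);
    ``per_object_shape`` records the generator parameters of each drawn
    structure.
    """

    mask: np.ndarray
    object_labels: np.ndarray
    per_object_shape: list = field(default_factory=list)

    @property
    def n_objects(self) -> int:
        return int(self.object_labels.max())


def _draw_filament(rng: np.random.Generator, params: PhenotypeParams,
                   heading0: float | None = None) -> tuple[np.ndarray, dict]:
    """Rasterize one persistent random walk dilated to the tubule width."""
    h, w = params.shape
    mean, sd = params.filament_length_px
    length = max(3, int(round(rng.normal(mean, sd))))
    r = rng.uniform(0.1 * h, 0.9 * h)
    c = rng.uniform(0.1 * w, 0.9 * w)
    theta = rng.uniform(0, 2 * np.pi) if heading0 is None else heading0
    turn_sd = 0.8 * (1.0 - params.persistence)
    pts = [(r, c)]
    for _ in range(length):
        theta += rng.normal(0.0, turn_sd)
        r += np.sin(theta)
        c += np.cos(theta)
        pts.append((r, c))
    mask = np.zeros(params.shape, dtype=bool)
    rr = np.clip(np.round([p[0] for p in pts]).astype(int), 0, h - 1)
    cc = np.clip(np.round([p[1] for p in pts]).astype(int), 0, w - 1)
    mask[rr, cc] = True
    radius = max(1, int(round(params.width_px / 2)))
    mask = morphology.dilation(mask, morphology.disk(radius))
    return mask, {"kind": "filament", "length_px": length,
                  "persistence": params.persistence, "width_px": params.width_px}


def _draw_blob(rng: np.random.Generator, params: PhenotypeParams) -> tuple[np.ndarray, dict]:
    """Rasterize one elliptical blob with mild eccentricity."""
    h, w = params.shape
    mean, sd = params.blob_radius_px
    radius = max(2.0, rng.normal(mean, sd))
    ecc = rng.uniform(0.8, 1.25)
    rot = rng.uniform(0, np.pi)
    r0 = rng.uniform(0.08 * h, 0.92 * h)
    c0 = rng.uniform(0.08 * w, 0.92 * w)
    rr, cc = draw.ellipse(r0, c0, radius * ecc, radius / ecc,
                          shape=params.shape, rotation=rot)
    mask = np.zeros(params.shape, dtype=bool)
    mask[rr, cc] = True
    return mask, {"kind": "blob", "radius_px": radius, "eccentricity": ecc}


def _render_slice(rng: np.random.Generator, mask: np.ndarray,
                  params: PhenotypeParams) -> np.ndarray:
    """Blur a binary structure slice with the PSF and add shot + read noise."""
    amplitude = params.peak_level - params.background_level
    signal = ndimage.gaussian_filter(mask.astype(np.float64) * amplitude,
                                     params.psf_sigma_px)
    noise_sd = amplitude / params.snr
    # half the noise power as Poisson shot noise, half as Gaussian read noise
    gain = 2.0 * params.snr**2 / max(amplitude, 1e-9)
    shot = rng.poisson(np.clip(signal, 0, None) * gain) / gain
    read = rng.normal(0.0, noise_sd / np.sqrt(2.0), size=mask.shape)
    return shot + read + params.background_level


def simulate_network_stack(params: PhenotypeParams) -> tuple[ImageStack, GroundTruth]:
    """Simulate a confocal stack of one phenotype with ground truth.

    The structures are distributed over ``n_focus_slices`` in-focus slices;
    ``n_defocused_slices`` heavily blurred, near-uniform slices are appended
    at the stack borders so that slice triage has something to reject. The
    ground-truth mask is the union of all structures (= the in-focus
    content of the maximum projection).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    masks, shapes = [], []
    base_heading = rng.uniform(0, 2 * np.pi)  # control networks are semi-aligned
    for _ in range(params.n_structures):
        if params.phenotype == "fragmented":
            m, info = _draw_blob(rng, params)
        elif params.phenotype == "tubular":
            m, info = _draw_filament(rng, params)
        else:
            m, info = _draw_filament(rng, params,
                                     heading0=rng.normal(base_heading, 0.4))
        masks.append(m)
        shapes.append(info)

    union = np.zeros((h, w), dtype=bool)
    for m in masks:
        union |= m
    labels = _cc_label(union, connectivity=2).astype(np.int32)

    # assign each structure to one in-focus slice
    per_slice = [np.zeros((h, w), dtype=bool) for _ in range(params.n_focus_slices)]
    for m in masks:
        per_slice[rng.integers(params.n_focus_slices)] |= m

    focus = [_render_slice(rng, m, params) for m in per_slice]

    defocused = []
    for _ in range(params.n_defocused_slices):
        src = focus[rng.integers(len(focus))] - params.background_level
        # heavy blur + strong attenuation: flattens toward the background so
        # the slice variance drops far below the triage threshold
        blurred = ndimage.gaussian_filter(src, sigma=0.2 * min(h, w)) * 0.05
        defocused.append(blurred + params.background_level)

    n_front = params.n_defocused_slices // 2
    slices = defocused[:n_front] + focus + defocused[n_front:]
    defocused_idx = list(range(n_front)) + list(
        range(n_front + len(focus), len(slices)))

    voxels = np.clip(np.rint(np.stack(slices)), 0, 255).astype(np.uint8)
    stack = ImageStack(
        voxels, pixel_size_um=params.pixel_size_um,
        metadata={"phenotype": params.phenotype, "seed": params.seed,
                  "defocused_slices": defocused_idx,
                  "params": asdict(params)},
    )
    return stack, GroundTruth(mask=union, object_labels=labels,
                              per_object_shape=shapes)


#: baseline feature values used by the tabular fixture generator
_BASELINE = {
    "Mean": 120.0, "Area": 60.0, "AR": 1.8, "Feret": 12.0, "Solidity": 0.85,
    "Circ": 0.6, "Round": 0.6, "Entropy": 1.5, "Contrast": 40.0,
    "Correlation": 0.7,
}


def simulate_feature_table(
    n_per_class: int,
    class_effects: dict[str, dict[str, float]],
    noise_sd: float | dict[str, float] = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table with known class structure.

    Rows are baseline metric values plus the per-class mean shifts in
    ``class_effects`` plus iid Gaussian noise (scalar or per-metric sd).
    Every row carries its generating class in ``Condition``.
    """
    if len(class_effects) < 2:
        raise ValueError("need at least 2 classes")
    if n_per_class < 2:
        raise ValueError("need n_per_class >= 2")
    metrics = SHAPE_COLUMNS + TEXTURE_COLUMNS
    sds = {m: (noise_sd[m] if isinstance(noise_sd, dict) else float(noise_sd))
           for m in metrics}
    if any(s < 0 for s in sds.values()):
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for cls, effects in class_effects.items():
        for i in range(n_per_class):
            row = {"image_id": f"{cls}_{i}", "Condition": cls,
                   "NObjects": int(rng.integers(8, 30))}
            for m in metrics:
                row[m] = (_BASELINE[m] + effects.get(m, 0.0)
                          + rng.normal(0.0, sds[m]))
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_qpcr_run(
    true_copies: Sequence[float],
    curve: StandardCurve,
    ct_noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table from a log-linear standard curve with Gaussian cycle noise.

    Each input copy number yields ``replicates`` rows with
    ``ct = slope * log10(copies) + intercept + N(0, ct_noise_sd)``.
    """
    copies = np.asarray(true_copies, dtype=np.float64)
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i, n in enumerate(copies):
        base = curve.slope * np.log10(n) + curve.intercept
        for rep in range(replicates):
            rows.append({"sample": i, "copies": n, "replicate": rep,
                         "ct": base + rng.normal(0.0, ct_noise_sd)})
    return pd.DataFrame(rows)


def simulate_o2_trace(
    rate: float,
    duration_min: float = 10.0,
    sampling_hz: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    o2_start: float = 250.0,
    equilibration_frac: float = 0.0,
) -> pd.DataFrame:
    """Linear oxygen-decline trace with optional equilibration transient.

    O2(t) = o2_start - rate * t + noise; with ``equilibration_frac`` > 0 a
    decaying exponential bump distorts the first fraction of the trace,
    emulating chamber equilibration before the straight portion.
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(0.0, duration_min, 1.0 / (sampling_hz * 60.0))
    o2 = o2_start - rate * t
    if equilibration_frac > 0:
        tau = equilibration_frac * duration_min / 3.0
        o2 = o2 + 0.15 * o2_start * np.exp(-t / tau)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        o2 = o2 + rng.normal(0.0, noise_sd, size=t.shape)
    return pd.DataFrame({"time_min": t, "o2": o2})
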