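"""File formats: NIfTI slices, landmark JSON, label maps, CSV, config.

Images are stored as single-slice NIfTI (.nii.gz) with the pixel spacing
in the affine; landmarks as JSON keyed by disc id, with 0-based (row,
col) pixel coordinates (row increases downward); masks as label-map
NIfTI with one integer code per ROI label; tables as plain CSV.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import ImageSeries, KineticsParams, PhantomConfig
from .segmentation import ROI_LABELS, DiscROIs, LandmarkSet

__all__ = [
    "save_image", "load_image",
    "save_series", "load_series",
    "save_landmarks", "load_landmarks",
    "save_masks", "load_masks",
    "save_config", "load_config",
    "write_manifest",
]

#: Integer code of each ROI label in a label-map NIfTI (0 = background).
ROI_CODES = {label: i + 1 for i, label in enumerate(ROI_LABELS)}


def _affine(spacing: float) -> np.ndarray:
    return np.diag([spacing, spacing, 1.0, 1.0])


def save_image(image: np.ndarray, path, pixel_spacing: float) -> None:
    img = nib.Nifti1Image(np.asarray(image, dtype=np.float32)[:, :, None],
                          _affine(pixel_spacing))
    nib.save(img, os.fspath(path))


def load_image(path) -> tuple[np.ndarray, float]:
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[:, :, 0]
    spacing = float(abs(img.affine[0, 0]))
    return data, spacing


def save_series(series: ImageSeries, out_dir) -> Path:
    """One directory per disc: <label>.nii.gz per time point plus T2."""
    d = Path(out_dir) / series.disc_id
    d.mkdir(parents=True, exist_ok=True)
    for label, image in series.images.items():
        save_image(image, d / f"{label}.nii.gz", series.pixel_spacing)
    save_image(series.t2, d / "T2.nii.gz", series.pixel_spacing)
    (d / "times.json").write_text(json.dumps(
        {"times_min": list(series.times)}))
    return d


def load_series(disc_dir) -> ImageSeries:
    d = Path(disc_dir)
    times = json.loads((d / "times.json").read_text())["times_min"]
    from .phantom import minutes_to_label
    images = {}
    spacing = None
    for t in times:
        label = minutes_to_label(t)
        p = d / f"{label}.nii.gz"
        if p.exists():
            images[label], spacing = load_image(p)
    t2, sp2 = load_image(d / "T2.nii.gz")
    return ImageSeries(disc_id=d.name, times=tuple(times), images=images,
                       t2=t2, pixel_spacing=spacing or sp2)


def save_landmarks(landmarks: dict[str, LandmarkSet], path,
                   csf_rects: dict[str, tuple[int, int]] | None = None) -> None:
    """Landmark JSON: per disc the 3 upper and 3 lower (row, col) points.

    Coordinates are 0-based pixel indices, row increasing downward;
    sub-pixel values allowed.  The optional per-disc ``csf_rect`` is the
    top-left corner of the 5x3 CSF reference rectangle.
    """
    payload = {}
    for disc_id, lms in landmarks.items():
        entry = {
            "upper": np.asarray(lms.upper, dtype=float).tolist(),
            "lower": np.asarray(lms.lower, dtype=float).tolist(),
            "pixel_spacing": lms.pixel_spacing,
        }
        if csf_rects and disc_id in csf_rects:
            entry["csf_rect"] = list(map(int, csf_rects[disc_id]))
        payload[disc_id] = entry
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_landmarks(path) -> tuple[dict[str, LandmarkSet],
                                  dict[str, tuple[int, int]]]:
    payload = json.loads(Path(path).read_text())
    landmarks, rects = {}, {}
    for disc_id, entry in payload.items():
        landmarks[disc_id] = LandmarkSet(
            disc_id=disc_id,
            upper=np.asarray(entry["upper"], dtype=float),
            lower=np.asarray(entry["lower"], dtype=float),
            pixel_spacing=float(entry["pixel_spacing"]),
        )
        if "csf_rect" in entry:
            rects[disc_id] = tuple(entry["csf_rect"])
    return landmarks, rects


def save_masks(rois: DiscROIs, path, pixel_spacing: float) -> None:
    """Write the seven ROI masks as one integer label map."""
    shape = rois.masks[ROI_LABELS[0]].shape
    label_map = np.zeros(shape, dtype=np.int16)
    for name, code in ROI_CODES.items():
        label_map[rois.masks[name]] = code
    img = nib.Nifti1Image(label_map[:, :, None], _affine(pixel_spacing))
    nib.save(img, os.fspath(path))


def load_masks(path, disc_id: str | None = None):
    """Read a label map back into a {label: bool mask} dict."""
    data, spacing = load_image(path)
    data = data.astype(int)
    masks = {name: data == code for name, code in ROI_CODES.items()}
    return masks, spacing


# ---------------------------------------------------------------------------
# Flat phantom config file
# ---------------------------------------------------------------------------

_KIN_PREFIX = "kinetics_"


def save_config(config: PhantomConfig, path) -> None:
    """Flat key/value YAML covering every scalar phantom setting.

    Kinetic parameters carry a ``kinetics_`` prefix; tuple-valued fields
    (grid_shape, time_points, csf_columns) are YAML lists.
    """
    flat: dict = {
        "grid_rows": config.grid_shape[0],
        "grid_cols": config.grid_shape[1],
        "pixel_spacing": config.pixel_spacing,
        "time_points": list(config.time_points),
        "noise_sd": config.noise_sd,
        "baseline": config.baseline,
        "background": config.background,
        "csf_col_start": config.csf_columns[0],
        "csf_col_stop": config.csf_columns[1],
        "csf_t2_intensity": config.csf_t2_intensity,
        "csf_t1_intensity": config.csf_t1_intensity,
        "t2_background": config.t2_background,
        "t2_disc_gain": config.t2_disc_gain,
        "n_nodes": config.n_nodes,
        "dt": config.dt,
        "seed": config.seed,
    }
    for name in ("blood_amplitude", "uptake_time", "decay_time", "diffusivity",
                 "endplate_permeability", "perfusion_rate", "signal_gain"):
        flat[_KIN_PREFIX + name] = getattr(config.kinetics, name)
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))


def load_config(path) -> PhantomConfig:
    flat = yaml.safe_load(Path(path).read_text()) or {}
    kin_kwargs = {k[len(_KIN_PREFIX):]: v for k, v in flat.items()
                  if k.startswith(_KIN_PREFIX)}
    kwargs = {}
    if "grid_rows" in flat or "grid_cols" in flat:
        kwargs["grid_shape"] = (int(flat.get("grid_rows", 96)),
                                int(flat.get("grid_cols", 96)))
    if "csf_col_start" in flat or "csf_col_stop" in flat:
        kwargs["csf_columns"] = (int(flat.get("csf_col_start", 68)),
                                 int(flat.get("csf_col_stop", 76)))
    if "time_points" in flat:
        kwargs["time_points"] = tuple(flat["time_points"])
    for key in ("pixel_spacing", "noise_sd", "baseline", "background",
                "csf_t2_intensity", "csf_t1_intensity", "t2_background",
                "t2_disc_gain", "n_nodes", "dt", "seed"):
        if key in flat:
            kwargs[key] = flat[key]
    if kin_kwargs:
        kwargs["kinetics"] = KineticsParams(**kin_kwargs)
    return PhantomConfig(**kwargs)


def write_manifest(out_dir, entries: dict, files: list | None = None) -> Path:
    """Run manifest: settings plus SHA-256 checksums of listed files."""
    out_dir = Path(out_dir)
    checksums = {}
    for f in files or []:
        f = Path(f)
        if f.exists():
            checksums[str(f.relative_to(out_dir))] = hashlib.sha256(
                f.read_bytes()).hexdigest()
    payload = dict(entries)
    payload["checksums"] = checksums
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
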