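"""NIfTI and configuration I/O.

Volumes travel as NIfTI-1 files; z maps must be finite, masks strictly
binary.  Configuration is YAML, validated field by field with explicit
error messages.  Every report bundle carries a manifest with the config
hash, seed and software version so runs can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from digitsel.constants import DIGITS
from digitsel.synthetic import ContrastProfile, SyntheticConfig

__all__ = [
    "read_volume",
    "read_zmap",
    "read_mask",
    "write_volume",
    "AnalysisConfig",
    "load_analysis_config",
    "synthetic_config_from_dict",
    "synthetic_config_to_dict",
    "config_hash",
    "write_manifest",
]


def read_volume(path, expect_ndim: int | None = None):
    """Load a NIfTI volume; returns (data, affine, voxel_size_mm).

    Byte order and scaling slopes are handled by nibabel per the NIfTI-1
    standard; ``expect_ndim`` (3 or 4) rejects the wrong dimensionality.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"not a readable NIfTI file: {path}: {exc}") from exc
    data = np.asarray(img.get_fdata())
    if expect_ndim is not None and data.ndim != expect_ndim:
        raise ValueError(
            f"{path}: expected a {expect_ndim}-D volume, got {data.ndim}-D"
        )
    zooms = img.header.get_zooms()[:3]
    return data, img.affine, tuple(float(v) for v in zooms)


def read_zmap(path):
    """Load a 3-D z-statistic map; NaN or infinite values are rejected."""
    data, affine, vox = read_volume(path, expect_ndim=3)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"z map contains non-finite values: {path}")
    return data, affine, vox


def read_mask(path):
    """Load a 3-D binary mask; values outside {0, 1} are rejected."""
    data, affine, vox = read_volume(path, expect_ndim=3)
    vals = np.unique(data)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError(
            f"mask contains values outside {{0, 1}}: {path} (found {vals[:5]})"
        )
    return data.astype(bool), affine, vox


def write_volume(path, data, affine=None, description: str = "") -> Path:
    """Write an array as NIfTI-1; the description lands in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data), affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))
    return path


# --- configuration -------------------------------------------------------

def synthetic_config_from_dict(d: dict) -> SyntheticConfig:
    """Build a SyntheticConfig from a YAML-style mapping."""
    d = dict(d)
    if "contrasts" in d:
        d["contrasts"] = {
            name: ContrastProfile(**prof) for name, prof in d["contrasts"].items()
        }
    for key in ("grid_shape", "voxel_size_mm", "digit_centers_mm"):
        if key in d:
            d[key] = tuple(d[key])
    return SyntheticConfig(**d)


def synthetic_config_to_dict(c: SyntheticConfig) -> dict:
    return {
        "grid_shape": list(c.grid_shape),
        "voxel_size_mm": list(c.voxel_size_mm),
        "digit_centers_mm": list(c.digit_centers_mm),
        "tuning_sigma_mm": c.tuning_sigma_mm,
        "neural_overlap": c.neural_overlap,
        "contrasts": {
            name: {"psf_fwhm_mm": p.psf_fwhm_mm, "amplitude": p.amplitude}
            for name, p in c.contrasts.items()
        },
        "noise_sd": c.noise_sd,
        "ribbon_floor": c.ribbon_floor,
        "seed": c.seed,
    }


_POLICY_CHOICES = {
    "roi_conjunction": ("and", "or", "per-contrast"),
    "os_outlier_policy": ("exclude", "clamp", "raw"),
    "ds_aggregation": ("voxel-mean", "means-of-means"),
}


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration.

    Exactly one of ``inputs`` (paths to real z maps and ROI masks) or
    ``synthetic`` (simulation parameters) must be given.

    ``inputs`` layout::

        inputs:
          rois: {M1: m1.nii.gz, S1: s1.nii.gz}
          zmaps:
            VASO-CBV: {D1: path, D2: path, D5: path}
            BOLD: {D1: path, D2: path, D5: path}

    ``synthetic`` layout::

        synthetic:
          n_subjects: 6
          regions:
            M1: {digit_centers_mm: [20, 24, 28], ...}
            S1: {digit_centers_mm: [19.5, 24, 28.5], ...}
    """

    inputs: dict | None = None
    synthetic: dict | None = None
    threshold: float = 2.5
    sweep_thresholds: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0)
    roi_conjunction: str = "and"
    os_outlier_policy: str = "exclude"
    ds_aggregation: str = "voxel-mean"
    out_dir: str = "digitsel_out"
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of 'inputs' (real data paths) or 'synthetic' "
                "(simulation block) must be present"
            )
        for key, choices in _POLICY_CHOICES.items():
            val = getattr(self, key)
            if val not in choices:
                raise ValueError(f"{key} must be one of {choices}, got {val!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.inputs is not None:
            self._validate_inputs()

    def _validate_inputs(self) -> None:
        inputs = self.inputs
        if "rois" not in inputs or "zmaps" not in inputs:
            raise ValueError("inputs must contain 'rois' and 'zmaps'")
        paths = list(inputs["rois"].values())
        for contrast, per_digit in inputs["zmaps"].items():
            missing = [d for d in DIGITS if d not in per_digit]
            if missing:
                raise ValueError(f"zmaps[{contrast}] missing digits {missing}")
            paths.extend(per_digit.values())
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


def load_analysis_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in AnalysisConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    if "sweep_thresholds" in kwargs:
        kwargs["sweep_thresholds"] = tuple(kwargs["sweep_thresholds"])
    return AnalysisConfig(**kwargs, extra=extra)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(out_dir, config_dict: dict, seed: int, extra: dict | None = None) -> Path:
    from digitsel import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config_dict,
        "config_hash": config_hash(config_dict),
        "seed": int(seed),
        "software": {"name": "digitsel", "version": __version__},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
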