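"""File interchange: WAV for sounds, NIfTI-1 plus JSON sidecars for volumes."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.io import wavfile

from .core import CONDITION_NAMES, GridSpec, SoundToken


def save_wav(token: SoundToken, path: str | Path,
             subtype: str = "float32") -> Path:
    """Write a token as RIFF WAV (float32 by default, or 16-bit PCM)."""
    path = Path(path)
    x = np.asarray(token.samples, dtype=np.float64)
    if subtype == "float32":
        wavfile.write(path, token.sample_rate, x.astype(np.float32))
    elif subtype == "pcm16":
        wavfile.write(path, token.sample_rate,
                      np.clip(x * 32767, -32768, 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
    return path


def load_wav(path: str | Path, category: str = "nonvoice",
             variant: str = "orig") -> SoundToken:
    sr, data = wavfile.read(Path(path))
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = data.astype(np.float64)
    return SoundToken(data, int(sr), category, variant,
                      token_id=Path(path).stem)


def _affine(grid: GridSpec) -> np.ndarray:
    return np.diag([grid.voxel_size_mm] * 3 + [1.0])


def save_volume(data: np.ndarray, grid: GridSpec, path: str | Path) -> Path:
    """Write a 3-D (or 4-D) grid volume as NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(grid))
    nib.save(img, path)
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj)
    voxel = float(img.header.get_zooms()[0])
    grid = GridSpec(shape=tuple(data.shape[:3]), voxel_size_mm=voxel)
    return data, grid


def save_cohort(cohort, directory: str | Path) -> Path:
    """One 4-D NIfTI per subject (x, y, z, run*condition) + JSON sidecar,
    plus the ground-truth labels as an integer NIfTI volume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = cohort.grid
    n_runs = cohort.n_runs
    for s in range(cohort.n_subjects):
        vol = cohort.betas[s].reshape(-1, *grid.shape)  # (run*cond, x, y, z)
        vol = np.moveaxis(vol, 0, -1)
        save_volume(vol, grid, directory / f"sub-{s:02d}_betas.nii.gz")
    sidecar = {
        "condition_order": list(CONDITION_NAMES),
        "n_runs": n_runs,
        "n_subjects": cohort.n_subjects,
        "volume_order": "run-major (run0 cond0..11, run1 cond0..11, ...)",
        "seed": cohort.seed,
        "effect_size": cohort.effect_size,
        "noise_sd": cohort.noise_sd,
        "grid_shape": list(grid.shape),
        "voxel_size_mm": grid.voxel_size_mm,
    }
    (directory / "cohort.json").write_text(json.dumps(sidecar, indent=2))
    save_volume(cohort.ground_truth.voxel_class.astype(np.float32), grid,
                directory / "ground_truth_labels.nii.gz")
    return directory


def save_stat_map(stat_map, path_prefix: str | Path) -> list[Path]:
    """Write t, p and mask volumes plus a JSON threshold descriptor."""
    prefix = Path(path_prefix)
    grid = stat_map.grid
    paths = [
        save_volume(stat_map.t, grid, prefix.with_suffix(".t.nii.gz")),
        save_volume(stat_map.p, grid, prefix.with_suffix(".p.nii.gz")),
        save_volume(stat_map.mask.astype(np.float32), grid,
                    prefix.with_suffix(".mask.nii.gz")),
    ]
    meta = {"contrast": stat_map.contrast, "df": stat_map.df,
            "threshold": {"kind": stat_map.threshold.kind,
                          "alpha": stat_map.threshold.alpha}}
    meta_path = prefix.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=2))
    return paths + [meta_path]


def save_parcellation(parc, path: str | Path) -> Path:
    """Label volume: 0 outside, 1 core, 2 acoustic, 3 accessory."""
    return save_volume(parc.labels.astype(np.float32), parc.grid, path)
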