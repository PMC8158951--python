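"""NIfTI and configuration IO.

Volumes and masks are exchanged as NIfTI-1 files on a shared grid;
masks are uint8 {0, 1}.  The measurement axis of a 4D acquisition is
always ordered by the canonical (TE, then b) cross product, whether the
input arrives as one 4D file or as one 3D file per measurement.
Configuration is a single JSON document.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .calibration import GridSpec
from .fitting import FitMaps, SignalVolume
from .phantom import CohortSpec, PhantomSpec
from .signal_models import AcquisitionScheme

__all__ = [
    "PipelineConfig",
    "read_acquisition",
    "read_mask",
    "write_volume",
    "write_mask",
    "write_maps",
]


def _check_grid(name: str, shape, affine, ref_shape, ref_affine) -> None:
    if tuple(shape[:3]) != tuple(ref_shape):
        raise ValueError(f"{name}: spatial shape {tuple(shape[:3])} != expected {tuple(ref_shape)}")
    if ref_affine is not None and not np.allclose(affine, ref_affine, atol=1e-4):
        raise ValueError(f"{name}: affine differs from the reference volume")


def read_mask(path: str | Path, ref_shape=None, ref_affine=None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if ref_shape is not None:
        _check_grid(str(path), data.shape, img.affine, ref_shape, ref_affine)
    return data.astype(bool)


def read_acquisition(
    paths: list[str | Path],
    scheme: AcquisitionScheme,
    box_mask: str | Path | None = None,
    background_mask: str | Path | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> SignalVolume:
    """Assemble a SignalVolume from NIfTI files.

    ``paths`` is either a single 4D file or one 3D file per measurement
    in canonical (TE, b) order.  Shapes and affines must agree across
    all files; mismatches are reported with the offending filename.
    """
    paths = [Path(p) for p in paths]
    first = nib.load(str(paths[0]))
    ref_affine = first.affine
    if len(paths) == 1:
        data = np.asarray(first.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{paths[0]}: expected a 4D volume")
    else:
        if len(paths) != scheme.n_measurements:
            raise ValueError(
                f"got {len(paths)} files, scheme defines {scheme.n_measurements} measurements"
            )
        vols = []
        for p in paths:
            img = nib.load(str(p))
            arr = np.asarray(img.dataobj, dtype=float)
            if arr.ndim != 3:
                raise ValueError(f"{p}: expected a 3D volume per measurement")
            _check_grid(str(p), arr.shape, img.affine, first.shape[:3], ref_affine)
            vols.append(arr)
        data = np.stack(vols, axis=-1)
    spatial = data.shape[:3]
    box = read_mask(box_mask, spatial, ref_affine) if box_mask else None
    bg = read_mask(background_mask, spatial, ref_affine) if background_mask else None
    if voxel_size is None:
        zooms = first.header.get_zooms()[:3]
        voxel_size = tuple(float(z) for z in zooms)
    return SignalVolume(
        data=data, scheme=scheme, voxel_size=voxel_size,
        box_mask=box, background_mask=bg, affine=ref_affine,
    )


def write_volume(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine if affine is not None else np.eye(4)), str(path))
    return path


def write_mask(mask: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine if affine is not None else np.eye(4)),
        str(path),
    )
    return path


def write_maps(fit_maps: FitMaps, out_dir: str | Path, affine: np.ndarray | None = None) -> dict[str, Path]:
    """One NIfTI per parameter map plus the validity mask and QC JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, arr in fit_maps.maps.items():
        written[name] = write_volume(arr, out / f"{fit_maps.model}_{name}.nii", affine)
    written["valid"] = write_mask(fit_maps.valid, out / f"{fit_maps.model}_valid.nii", affine)
    qc_path = out / f"{fit_maps.model}_qc.json"
    qc_path.write_text(json.dumps(fit_maps.qc, indent=2, sort_keys=True))
    written["qc"] = qc_path
    return written


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything a full phantom-cohort run needs.

    Either a fixed ``(t2_slow, t2_fast)`` pair is given (the grid search
    is skipped) or the calibration grid is used; both absent is an
    error at validation time, never silently defaulted.
    """

    seed: int = 0
    out_dir: str = "results"
    scheme: AcquisitionScheme = field(default_factory=AcquisitionScheme)
    adc_slow: float = 0.3
    adc_fast: float = 2.6
    t2_slow: float | None = None
    t2_fast: float | None = None
    t2_grid: GridSpec | None = field(default_factory=GridSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    calibration_max_voxels: int = 8000
    alpha: float = 0.05
    n_comparisons: int = 9

    def __post_init__(self) -> None:
        fixed = self.t2_slow is not None and self.t2_fast is not None
        if not fixed and self.t2_grid is None:
            raise ValueError("provide a fixed t2 pair or a calibration grid")
        if (self.t2_slow is None) != (self.t2_fast is None):
            raise ValueError("fix both t2_slow and t2_fast, or neither")

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scheme"] = {"echo_times": list(self.scheme.echo_times), "b_values": list(self.scheme.b_values)}
        if self.t2_grid is not None:
            d["t2_grid"] = {
                "t2_slow_values": list(self.t2_grid.t2_slow_values),
                "t2_fast_values": list(self.t2_grid.t2_fast_values),
            }
        return d

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scheme" in d and isinstance(d["scheme"], dict):
            d["scheme"] = AcquisitionScheme(
                tuple(d["scheme"]["echo_times"]), tuple(d["scheme"]["b_values"])
            )
        if d.get("t2_grid") is not None and isinstance(d["t2_grid"], dict):
            d["t2_grid"] = GridSpec(
                tuple(d["t2_grid"]["t2_slow_values"]), tuple(d["t2_grid"]["t2_fast_values"])
            )
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if "phantom" in c and isinstance(c["phantom"], dict):
                ph = dict(c["phantom"])
                if "classes" in ph and isinstance(ph["classes"], dict):
                    from .phantom import TissueClassSpec

                    ph["classes"] = {
                        k: TissueClassSpec(**v) if isinstance(v, dict) else v
                        for k, v in ph["classes"].items()
                    }
                for key in ("grid_shape", "lesion_radii"):
                    if key in ph:
                        ph[key] = tuple(ph[key])
                c["phantom"] = PhantomSpec(**ph)
            d["cohort"] = CohortSpec(**c)
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
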