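"""Synthetic prostate T2-DWI phantom cohort.

Stands in for a patient cohort: each "patient" is a small 3D volume with
a box region of prostate-like tissue surrounded by air, containing
ellipsoidal lesion ROIs.  Voxels carry ground-truth two-component
parameters per tissue class, forward signals follow the two-component
model on the acquisition scheme, and magnitudes receive Rician noise
(root of sum of squares of two noisy quadrature channels), which creates
the nonzero background noise floor the exclusion rules need.

Tissue classes and their signal-fraction distributions are chosen so
that tumor > BPH > stroma > normal peripheral zone in ``sf_slow`` — the
contrast direction seen in prostate T2-DWI — with overlap large enough
to keep discrimination imperfect.  A small fraction of tissue voxels are
"signal voids" (near-zero intensity, emulating calcification,
post-biopsy hemorrhage and susceptibility dropout), which is what the
noise-floor exclusion rule removes in real data.

Cancer patients carry one tumor ROI (plus one normal-tissue ROI when the
tumor is peripheral-zone); BPH patients carry one BPH nodule ROI.  Tumor
aggressiveness labels (Gleason Grade Group, 1-5) are linked monotonically
to the patient-level mean tumor signal fraction with additive label
noise, giving fair (not perfect) rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import SignalVolume
from .signal_models import AcquisitionScheme, ComponentBasis, B_ADC_SCALE

__all__ = [
    "TissueClassSpec",
    "PhantomSpec",
    "CohortSpec",
    "PhantomTruth",
    "PatientRecord",
    "Cohort",
    "default_tissue_classes",
    "build_phantom",
    "simulate_signals",
    "noise_sigma_for_snr",
    "simulate_cohort",
]


@dataclass(frozen=True)
class TissueClassSpec:
    """Ground-truth parameter distribution of one tissue class.

    ``sf_sd_between`` spreads the class mean across patients,
    ``sf_sd_within`` spreads voxels around the patient mean; their
    quadrature sum is the total voxel-level spread.
    """

    name: str
    sf_mean: float
    sf_sd_between: float
    sf_sd_within: float
    si0_mean: float = 100.0
    t2_slow: float = 45.0
    t2_fast: float = 180.0

    def __post_init__(self) -> None:
        if not 0 < self.sf_mean < 1:
            raise ValueError("sf_mean must lie in (0, 1)")


def default_tissue_classes() -> dict[str, TissueClassSpec]:
    """Class parameters; tumor > bph > stroma > normal in sf_slow."""
    return {
        "tumor": TissueClassSpec("tumor", 0.75, 0.06, 0.05),
        "bph": TissueClassSpec("bph", 0.65, 0.08, 0.06),
        "stroma": TissueClassSpec("stroma", 0.45, 0.05, 0.12),
        "normal": TissueClassSpec("normal", 0.30, 0.06, 0.05),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise description of one phantom volume."""

    grid_shape: tuple[int, int, int] = (48, 48, 8)
    box_margin: int = 10
    background_gap: int = 2
    lesion_radii: tuple[float, float, float] = (5.0, 5.0, 2.0)
    si0_cv: float = 0.2
    void_fraction: float = 0.10
    void_scale: float = 0.02
    snr: float = 40.0
    classes: dict[str, TissueClassSpec] = field(default_factory=default_tissue_classes)

    @property
    def box_slices(self) -> tuple[slice, slice, slice]:
        m = self.box_margin
        nx, ny, nz = self.grid_shape
        return (slice(m, nx - m), slice(m, ny - m), slice(1, nz - 1))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure: arms, splits, zones, noise, seed."""

    n_train: int = 31
    n_test: int = 31
    n_bph: int = 14
    n_nonpz_train: int = 6
    n_nonpz_test: int = 7
    seed: int = 0
    grade_noise_sd: float = 2.0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)


@dataclass
class PhantomTruth:
    """Ground-truth maps and masks for one phantom volume."""

    sf_slow: np.ndarray
    si0: np.ndarray
    t2_slow: np.ndarray
    t2_fast: np.ndarray
    class_map: np.ndarray  # strings, "" = air
    masks: dict[str, np.ndarray]
    adc_pair: tuple[float, float] = (0.3, 2.6)
    patient_means: dict[str, float] = field(default_factory=dict)


@dataclass
class PatientRecord:
    patient_id: str
    group: str  # "cancer" | "bph"
    split: str  # "train" | "test"
    zone: str  # "PZ" | "non-PZ"
    ggg: int | None
    truth: PhantomTruth
    volume: SignalVolume
    roi_masks: dict[str, np.ndarray]


@dataclass
class Cohort:
    spec: CohortSpec
    scheme: AcquisitionScheme
    patients: list[PatientRecord]
    sigma: float

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": p.patient_id,
                "group": p.group,
                "split": p.split,
                "zone": p.zone,
                "ggg": p.ggg,
            }
            for p in self.patients
        ]
        return pd.DataFrame(rows)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def build_phantom(
    spec: PhantomSpec,
    rng: np.random.Generator,
    lesion_class: str = "tumor",
    with_normal_roi: bool = True,
) -> PhantomTruth:
    """Assemble ground-truth maps and masks for one patient volume.

    The lesion ellipsoid sits in one half of the tissue box, the
    normal-tissue ROI (if requested) in the other half; remaining box
    voxels are stroma, everything outside the box is air.
    """
    shape = spec.grid_shape
    box = np.zeros(shape, dtype=bool)
    box[spec.box_slices] = True

    gap = spec.background_gap
    dilated = np.zeros(shape, dtype=bool)
    m = spec.box_margin
    nx, ny, nz = shape
    dilated[
        max(m - gap, 0) : min(nx - m + gap, nx),
        max(m - gap, 0) : min(ny - m + gap, ny),
        :,
    ] = True
    background = ~dilated

    xs, ys, zs = spec.box_slices
    rx, ry, rz = spec.lesion_radii
    z_c = (zs.start + zs.stop - 1) / 2.0

    def place(x_lo: float, x_hi: float) -> np.ndarray:
        cx = rng.uniform(x_lo + rx + 1, x_hi - rx - 1)
        cy = rng.uniform(ys.start + ry + 1, ys.stop - ry - 1)
        return _ellipsoid_mask(shape, (cx, cy, z_c), spec.lesion_radii) & box

    x_mid = (xs.start + xs.stop) / 2.0
    lesion = place(xs.start, x_mid)
    normal = place(x_mid, xs.stop) if with_normal_roi else np.zeros(shape, dtype=bool)

    class_map = np.full(shape, "", dtype=object)
    class_map[box] = "stroma"
    class_map[normal] = "normal"
    class_map[lesion] = lesion_class

    sf = np.zeros(shape)
    si0 = np.zeros(shape)
    t2s = np.full(shape, np.nan)
    t2f = np.full(shape, np.nan)
    patient_means: dict[str, float] = {}
    for name, cls in spec.classes.items():
        region = class_map == name
        if not region.any():
            continue
        p_mean = float(np.clip(rng.normal(cls.sf_mean, cls.sf_sd_between), 0.02, 0.98))
        patient_means[name] = p_mean
        sf[region] = np.clip(rng.normal(p_mean, cls.sf_sd_within, int(region.sum())), 0.0, 1.0)
        si0[region] = cls.si0_mean * rng.lognormal(
            mean=-0.5 * np.log1p(spec.si0_cv**2), sigma=np.sqrt(np.log1p(spec.si0_cv**2)), size=int(region.sum())
        )
        t2s[region] = cls.t2_slow
        t2f[region] = cls.t2_fast

    voids = box & (rng.random(shape) < spec.void_fraction)
    si0[voids] *= spec.void_scale

    masks = {"box": box, "background": background, lesion_class: lesion}
    if with_normal_roi:
        masks["normal"] = normal
    return PhantomTruth(
        sf_slow=sf, si0=si0, t2_slow=t2s, t2_fast=t2f,
        class_map=class_map, masks=masks, patient_means=patient_means,
    )


def _clean_signal(truth: PhantomTruth, scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free forward signal, allowing voxel-wise T2 maps."""
    te = scheme.te_array()
    b = scheme.b_array()
    adc_slow, adc_fast = truth.adc_pair
    with np.errstate(divide="ignore", invalid="ignore"):
        att_slow = np.exp(-te / truth.t2_slow[..., None]) * np.exp(-b * adc_slow * B_ADC_SCALE)
        att_fast = np.exp(-te / truth.t2_fast[..., None]) * np.exp(-b * adc_fast * B_ADC_SCALE)
    sf = truth.sf_slow[..., None]
    clean = truth.si0[..., None] * (sf * att_slow + (1.0 - sf) * att_fast)
    return np.where(np.isfinite(clean), clean, 0.0)


def noise_sigma_for_snr(spec: PhantomSpec, scheme: AcquisitionScheme | None = None) -> float:
    """Channel noise sigma giving the target tissue SNR at the first measurement.

    The reference signal is a stroma voxel at the class-mean parameters,
    evaluated at the lowest (TE, b) measurement.
    """
    scheme = scheme or AcquisitionScheme()
    cls = spec.classes["stroma"]
    te, b = scheme.measurements[0]
    basis = ComponentBasis(0.3, 2.6, cls.t2_slow, cls.t2_fast)
    att_s = np.exp(-te / basis.t2_slow - b * basis.adc_slow * B_ADC_SCALE)
    att_f = np.exp(-te / basis.t2_fast - b * basis.adc_fast * B_ADC_SCALE)
    ref = cls.si0_mean * (cls.sf_mean * att_s + (1 - cls.sf_mean) * att_f)
    return float(ref / spec.snr)


def simulate_signals(
    truth: PhantomTruth,
    scheme: AcquisitionScheme,
    sigma: float,
    rng: np.random.Generator,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 3.0),
) -> SignalVolume:
    """Rician-noisy magnitude volume from ground truth.

    ``noisy = sqrt((clean + e1)^2 + e2^2)`` with independent zero-mean
    Gaussian channels of standard deviation ``sigma``; ``sigma = 0``
    returns the clean signal exactly.
    """
    clean = _clean_signal(truth, scheme)
    if sigma > 0:
        e1 = rng.normal(0.0, sigma, clean.shape)
        e2 = rng.normal(0.0, sigma, clean.shape)
        data = np.sqrt((clean + e1) ** 2 + e2**2)
    else:
        data = clean
    return SignalVolume(
        data=data,
        scheme=scheme,
        voxel_size=voxel_size,
        box_mask=truth.masks["box"],
        background_mask=truth.masks["background"],
    )


def _grade_from_sf(sf_patient_mean: float, cls: TissueClassSpec, noise_sd: float,
                   rng: np.random.Generator) -> int:
    """Monotone affine link from patient tumor sf_slow to GGG 1-5 plus label noise."""
    spread = cls.sf_sd_between if cls.sf_sd_between > 0 else 1.0
    z = (sf_patient_mean - cls.sf_mean) / spread
    raw = 3.0 + z + rng.normal(0.0, noise_sd)
    return int(np.clip(np.rint(raw), 1, 5))


def simulate_cohort(spec: CohortSpec, scheme: AcquisitionScheme | None = None) -> Cohort:
    """Generate the full patient cohort, seeded and reproducible.

    Cancer patients are split into training/test arms with fixed
    peripheral-zone counts; PZ cancer patients get tumor + normal ROIs,
    non-PZ cancer patients a tumor ROI only, BPH patients one BPH nodule
    ROI.  Geometry, parameters and noise derive deterministically from
    ``spec.seed`` (geometry and noise use independent streams).
    """
    scheme = scheme or AcquisitionScheme()
    sigma = noise_sigma_for_snr(spec.phantom, scheme)
    cohort_rng = np.random.default_rng([spec.seed, 0xC0])

    plan: list[tuple[str, str, str]] = []  # (group, split, zone)
    for split, n, n_nonpz in (("train", spec.n_train, spec.n_nonpz_train),
                              ("test", spec.n_test, spec.n_nonpz_test)):
        zones = np.array(["PZ"] * (n - n_nonpz) + ["non-PZ"] * n_nonpz)
        cohort_rng.shuffle(zones)
        plan += [("cancer", split, z) for z in zones]
    plan += [("bph", "none", "non-PZ")] * spec.n_bph  # BPH arm is not split

    patients: list[PatientRecord] = []
    n_cancer = 0
    n_bph = 0
    for i, (group, split, zone) in enumerate(plan):
        geom_rng = np.random.default_rng([spec.seed, i, 0])
        noise_rng = np.random.default_rng([spec.seed, i, 1])
        lesion_class = "tumor" if group == "cancer" else "bph"
        with_normal = group == "cancer" and zone == "PZ"
        truth = build_phantom(spec.phantom, geom_rng, lesion_class, with_normal)
        volume = simulate_signals(truth, scheme, sigma, noise_rng)
        if group == "cancer":
            n_cancer += 1
            pid = f"C{n_cancer:02d}"
            ggg = _grade_from_sf(
                truth.patient_means["tumor"], spec.phantom.classes["tumor"],
                spec.grade_noise_sd, noise_rng,
            )
        else:
            n_bph += 1
            pid = f"B{n_bph:02d}"
            ggg = None
        roi_masks = {k: v for k, v in truth.masks.items() if k in ("tumor", "normal", "bph")}
        patients.append(
            PatientRecord(pid, group, split, zone, ggg, truth, volume, roi_masks)
        )
    return Cohort(spec=spec, scheme=scheme, patients=patients, sigma=sigma)
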