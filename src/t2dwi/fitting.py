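"""Per-voxel parameter estimation and pre-fit voxel exclusion.

With both diffusivities and both T2s fixed, the two-component model is
linear in the rescaled amplitudes ``(a, b) = (si0*sf_slow, si0*sf_fast)``,
so each voxel reduces to a 2-column non-negative least-squares problem
against the attenuation basis.  The problem is convex with independent
columns, hence has a unique global minimizer and needs no initialization
or random seed.  The solver below is a closed form for the 2-column case
(unconstrained normal equations, falling back to the best single-column
fit when a sign constraint activates), vectorized over voxels.

Voxels are screened before fitting: any measurement at or below three
times the noise floor (mean background magnitude) excludes the voxel, as
does a negative apparent decay rate in either direction of the design
(apparent ADC per TE, apparent T2 per b-value).  Excluded voxels carry
NaN in every fitted map — never zero, since zero is a legal value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .signal_models import (
    B_ADC_SCALE,
    AcquisitionScheme,
    ComponentBasis,
    attenuation_basis,
)

__all__ = [
    "SignalVolume",
    "FitMaps",
    "nnls_two_column",
    "build_exclusion_mask",
    "fit_two_component_voxel",
    "fit_two_component_table",
    "fit_bi_exponential_voxel",
    "fit_bi_exponential_table",
    "fit_mono_adc_voxel",
    "fit_mono_adc_table",
    "fit_volume",
]

NOISE_FLOOR_FACTOR = 3.0

ModelName = Literal["two_component", "bi_exponential", "mono"]


@dataclass
class SignalVolume:
    """4D magnitude data (x, y, z, measurement) with masks and scheme."""

    data: np.ndarray
    scheme: AcquisitionScheme
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 3.0)
    box_mask: np.ndarray | None = None
    background_mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, measurement)")
        if self.data.shape[-1] != self.scheme.n_measurements:
            raise ValueError(
                f"measurement axis has length {self.data.shape[-1]}, "
                f"scheme defines {self.scheme.n_measurements}"
            )
        spatial = self.data.shape[:3]
        for name in ("box_mask", "background_mask"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m, dtype=bool)
            if m.shape != spatial:
                raise ValueError(f"{name} shape {m.shape} != data spatial shape {spatial}")
            setattr(self, name, m)
        if self.box_mask is not None and self.background_mask is not None:
            if np.any(self.box_mask & self.background_mask):
                raise ValueError("box_mask and background_mask must be disjoint")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class FitMaps:
    """Per-voxel parameter maps for one model, plus a QC report.

    ``maps`` holds 3D arrays keyed by parameter name (si0, sf_slow or
    adc, rmse); ``valid`` marks voxels that were inside the box, passed
    exclusion and produced a finite fit.  Invalid voxels are NaN.
    """

    model: str
    maps: dict[str, np.ndarray]
    valid: np.ndarray
    qc: dict

    def __getitem__(self, key: str) -> np.ndarray:
        return self.maps[key]


# ---------------------------------------------------------------------------
# core solver


def nnls_two_column(A: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve min ||A @ p - s||, p >= 0, for a 2-column A, batched over rows of S.

    Parameters
    ----------
    A : (m, 2) design matrix with strictly positive entries.
    S : (n, m) stack of signal vectors.

    Returns
    -------
    coef : (n, 2) non-negative coefficients.
    rmse : (n,) root-mean-square residual over the m measurements.
    """
    A = np.asarray(A, dtype=float)
    S = np.atleast_2d(np.asarray(S, dtype=float))
    m = A.shape[0]
    g11 = A[:, 0] @ A[:, 0]
    g12 = A[:, 0] @ A[:, 1]
    g22 = A[:, 1] @ A[:, 1]
    det = g11 * g22 - g12 * g12
    c1 = S @ A[:, 0]
    c2 = S @ A[:, 1]

    # unconstrained stationary point of the normal equations
    p1 = (g22 * c1 - g12 * c2) / det
    p2 = (g11 * c2 - g12 * c1) / det

    # single-column candidates (one constraint active), clipped at zero
    q1 = np.maximum(c1 / g11, 0.0)
    q2 = np.maximum(c2 / g22, 0.0)
    ss = np.einsum("ij,ij->i", S, S)
    r1 = ss - 2 * q1 * c1 + q1 * q1 * g11
    r2 = ss - 2 * q2 * c2 + q2 * q2 * g22
    use_first = r1 <= r2
    coef = np.where(
        use_first[:, None],
        np.column_stack([q1, np.zeros_like(q1)]),
        np.column_stack([np.zeros_like(q2), q2]),
    )
    interior = (p1 >= 0) & (p2 >= 0)
    coef[interior, 0] = p1[interior]
    coef[interior, 1] = p2[interior]

    resid = coef @ A.T - S  # direct evaluation avoids cancellation at tiny residuals
    rmse = np.sqrt(np.einsum("ij,ij->i", resid, resid) / m)
    return coef, rmse


# ---------------------------------------------------------------------------
# exclusion rules


def _decay_violations(data: np.ndarray, scheme: AcquisitionScheme) -> tuple[np.ndarray, np.ndarray]:
    """Negative apparent ADC / T2 masks over the leading axes of ``data``.

    Apparent ADC at fixed TE is ``ln(S_b1/S_b2)/((b2-b1)*1e-3)``; it is
    negative iff the signal rises with b.  Apparent T2 at fixed b is
    ``(TE2-TE1)/ln(S_TE1/S_TE2)``; negative iff the signal rises with TE.
    Every adjacent pair in each direction is tested.
    """
    tes = scheme.echo_times
    bs = scheme.b_values
    idx = {m: i for i, m in enumerate(scheme.measurements)}
    neg_adc = np.zeros(data.shape[:-1], dtype=bool)
    neg_t2 = np.zeros(data.shape[:-1], dtype=bool)
    for te in tes:
        for b_lo, b_hi in zip(bs[:-1], bs[1:]):
            neg_adc |= data[..., idx[(te, b_lo)]] < data[..., idx[(te, b_hi)]]
    for b in bs:
        for te_lo, te_hi in zip(tes[:-1], tes[1:]):
            neg_t2 |= data[..., idx[(te_lo, b)]] < data[..., idx[(te_hi, b)]]
    return neg_adc, neg_t2


def build_exclusion_mask(volume: SignalVolume) -> tuple[np.ndarray, dict]:
    """Keep-mask over box voxels plus QC counts.

    The noise floor is the mean magnitude over background voxels across
    all measurements.  A box voxel is kept only if every measurement is
    strictly above ``3 * noise_floor`` and no apparent decay rate is
    negative.
    """
    if volume.box_mask is None:
        raise ValueError("volume has no box_mask")
    if volume.background_mask is None or not volume.background_mask.any():
        raise ValueError("background_mask is empty; cannot estimate the noise floor")
    noise_floor = float(volume.data[volume.background_mask].mean())
    threshold = NOISE_FLOOR_FACTOR * noise_floor

    low_signal = (volume.data <= threshold).any(axis=-1)
    neg_adc, neg_t2 = _decay_violations(volume.data, volume.scheme)
    box = volume.box_mask
    excluded = box & (low_signal | neg_adc | neg_t2)
    keep = box & ~excluded
    n_box = int(box.sum())
    qc = {
        "noise_floor": noise_floor,
        "threshold": threshold,
        "n_box": n_box,
        "n_below_noise_floor": int((box & low_signal).sum()),
        "n_negative_adc": int((box & neg_adc).sum()),
        "n_negative_t2": int((box & neg_t2).sum()),
        "n_excluded": int(excluded.sum()),
        "n_kept": int(keep.sum()),
        "excluded_fraction": float(excluded.sum() / n_box) if n_box else float("nan"),
    }
    return keep, qc


# ---------------------------------------------------------------------------
# per-voxel fits (table = vectorized over an (n, m) stack of voxels)


def fit_two_component_table(
    signals: np.ndarray, scheme: AcquisitionScheme, basis: ComponentBasis
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit (si0, sf_slow) per row of ``signals``; returns si0, sf_slow, rmse, valid."""
    S = np.atleast_2d(np.asarray(signals, dtype=float))
    valid = np.isfinite(S).all(axis=1) & (S != 0).any(axis=1)
    A = attenuation_basis(scheme, basis)
    coef, rmse = nnls_two_column(A, np.where(valid[:, None], S, 0.0))
    total = coef.sum(axis=1)
    valid &= total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        sf_slow = np.where(valid, coef[:, 0] / total, np.nan)
    si0 = np.where(valid, total, np.nan)
    rmse = np.where(valid, rmse, np.nan)
    return si0, sf_slow, rmse, valid


def fit_two_component_voxel(
    signal: np.ndarray, scheme: AcquisitionScheme, basis: ComponentBasis
) -> tuple[float, float, float, bool]:
    """Single-voxel convenience wrapper; returns (si0, sf_slow, rmse, valid)."""
    si0, sf, rmse, valid = fit_two_component_table(np.asarray(signal)[None, :], scheme, basis)
    return float(si0[0]), float(sf[0]), float(rmse[0]), bool(valid[0])


def fit_bi_exponential_table(
    s_b1: np.ndarray,
    s_b2: np.ndarray,
    b1: float,
    b2: float,
    adc_pair: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact 2-point bi-exponential fit; sf_slow clipped to [0, 1].

    Solves the 2-equation system for (si0, sf_slow); when the solution
    leaves [0, 1] the fraction is clipped and si0 refit by least squares
    at the clipped fraction.  Returns (si0, sf_slow, valid).
    """
    s1 = np.atleast_1d(np.asarray(s_b1, dtype=float))
    s2 = np.atleast_1d(np.asarray(s_b2, dtype=float))
    adc_slow, adc_fast = adc_pair
    es1 = np.exp(-b1 * adc_slow * B_ADC_SCALE)
    ef1 = np.exp(-b1 * adc_fast * B_ADC_SCALE)
    es2 = np.exp(-b2 * adc_slow * B_ADC_SCALE)
    ef2 = np.exp(-b2 * adc_fast * B_ADC_SCALE)
    valid = np.isfinite(s1) & np.isfinite(s2) & (s1 > 0)
    # s2*(f*es1+(1-f)*ef1) = s1*(f*es2+(1-f)*ef2), linear in f
    denom = s2 * (es1 - ef1) - s1 * (es2 - ef2)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 0, (s1 * ef2 - s2 * ef1) / denom, np.nan)
    f = np.clip(f, 0.0, 1.0)
    # least-squares si0 at the (possibly clipped) fraction
    m1 = f * es1 + (1.0 - f) * ef1
    m2 = f * es2 + (1.0 - f) * ef2
    with np.errstate(invalid="ignore", divide="ignore"):
        si0 = (s1 * m1 + s2 * m2) / (m1 * m1 + m2 * m2)
    valid &= np.isfinite(f) & np.isfinite(si0)
    si0 = np.where(valid, np.maximum(si0, 0.0), np.nan)
    f = np.where(valid, f, np.nan)
    return si0, f, valid


def fit_bi_exponential_voxel(
    s_b1: float, s_b2: float, b1: float, b2: float, adc_pair: tuple[float, float]
) -> tuple[float, float, bool]:
    si0, f, valid = fit_bi_exponential_table(s_b1, s_b2, b1, b2, adc_pair)
    return float(si0[0]), float(f[0]), bool(valid[0])


def fit_mono_adc_table(
    s_b1: np.ndarray, s_b2: np.ndarray, b1: float, b2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form 2-point ADC fit; returns (si0, adc [um^2/ms], valid).

    The ADC may come out negative for rising signal; the sign is passed
    through so the exclusion rule can act on it.
    """
    s1 = np.atleast_1d(np.asarray(s_b1, dtype=float))
    s2 = np.atleast_1d(np.asarray(s_b2, dtype=float))
    valid = np.isfinite(s1) & np.isfinite(s2) & (s1 > 0) & (s2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        adc = np.log(np.where(valid, s1 / s2, np.nan)) / ((b2 - b1) * B_ADC_SCALE)
        si0 = s1 * np.exp(b1 * adc * B_ADC_SCALE)
    adc = np.where(valid, adc, np.nan)
    si0 = np.where(valid, si0, np.nan)
    return si0, adc, valid


def fit_mono_adc_voxel(s_b1: float, s_b2: float, b1: float, b2: float) -> tuple[float, float, bool]:
    si0, adc, valid = fit_mono_adc_table(s_b1, s_b2, b1, b2)
    return float(si0[0]), float(adc[0]), bool(valid[0])


# ---------------------------------------------------------------------------
# whole-volume driver


def _te73_pair(volume: SignalVolume) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Signals at the two b-values of the longest TE, flattened spatially."""
    scheme = volume.scheme
    te = scheme.echo_times[-1]
    b1, b2 = scheme.b_values[0], scheme.b_values[-1]
    i1 = scheme.measurement_index(te, b1)
    i2 = scheme.measurement_index(te, b2)
    flat = volume.data.reshape(-1, scheme.n_measurements)
    return flat[:, i1], flat[:, i2], b1, b2


def fit_volume(
    volume: SignalVolume,
    model: ModelName,
    basis: ComponentBasis | None = None,
    keep: np.ndarray | None = None,
) -> FitMaps:
    """Fit one model to every kept voxel inside the box mask.

    Exclusion (noise floor, negative apparent decays) is applied before
    fitting unless a precomputed keep-mask is supplied.  Voxels outside
    the box or excluded are NaN in every map and False in ``valid``.
    """
    if keep is None:
        keep, qc = build_exclusion_mask(volume)
    else:
        keep = np.asarray(keep, dtype=bool) & (
            volume.box_mask if volume.box_mask is not None else True
        )
        qc = {"n_kept": int(keep.sum())}
    shape = volume.spatial_shape
    flat_keep = keep.reshape(-1)
    n_meas = volume.scheme.n_measurements
    flat = volume.data.reshape(-1, n_meas)

    def blank() -> np.ndarray:
        return np.full(shape, np.nan)

    maps: dict[str, np.ndarray]
    if model == "two_component":
        if basis is None:
            raise ValueError("two_component model needs a ComponentBasis")
        si0, sf, rmse, valid = fit_two_component_table(flat[flat_keep], volume.scheme, basis)
        maps = {"si0": blank(), "sf_slow": blank(), "rmse": blank()}
        maps["si0"].reshape(-1)[flat_keep] = si0
        maps["sf_slow"].reshape(-1)[flat_keep] = sf
        maps["rmse"].reshape(-1)[flat_keep] = rmse
    elif model == "bi_exponential":
        if basis is None:
            raise ValueError("bi_exponential model needs a ComponentBasis for its ADC pair")
        s1, s2, b1, b2 = _te73_pair(volume)
        si0, sf, valid = fit_bi_exponential_table(
            s1[flat_keep], s2[flat_keep], b1, b2, basis.adc_pair
        )
        maps = {"si0": blank(), "sf_slow": blank()}
        maps["si0"].reshape(-1)[flat_keep] = si0
        maps["sf_slow"].reshape(-1)[flat_keep] = sf
    elif model == "mono":
        s1, s2, b1, b2 = _te73_pair(volume)
        si0, adc, valid = fit_mono_adc_table(s1[flat_keep], s2[flat_keep], b1, b2)
        maps = {"si0": blank(), "adc": blank()}
        maps["si0"].reshape(-1)[flat_keep] = si0
        maps["adc"].reshape(-1)[flat_keep] = adc
    else:
        raise ValueError(f"unknown model {model!r}")

    valid_map = np.zeros(shape, dtype=bool)
    valid_map.reshape(-1)[np.flatnonzero(flat_keep)] = valid
    qc = dict(qc)
    qc["n_valid_fits"] = int(valid_map.sum())
    return FitMaps(model=model, maps=maps, valid=valid_map, qc=qc)
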