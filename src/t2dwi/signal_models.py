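"""Forward signal models for combined T2- and diffusion-weighted MRI.

Three models of the voxel magnitude signal acquired on a grid of echo
times (TE, ms) and diffusion weightings (b, s/mm^2):

* two-component: a slow-diffusion/short-T2 compartment and a
  fast-diffusion/long-T2 compartment, mixed by a signal fraction,
* bi-exponential: the same two diffusivities without T2 dependence,
* mono-exponential: a single apparent diffusion coefficient (ADC).

Units follow the field's convention: b in s/mm^2, ADC in um^2/ms, so
the exponent is ``b * ADC * 1e-3``.  That conversion lives in exactly
one place (:func:`attenuation_basis` / :func:`_b_decay`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "ComponentBasis",
    "attenuation_basis",
    "two_component_signal",
    "bi_exponential_signal",
    "mono_exponential_signal",
]

#: b [s/mm^2] * ADC [um^2/ms] * B_ADC_SCALE is dimensionless.
B_ADC_SCALE = 1e-3


@dataclass(frozen=True)
class AcquisitionScheme:
    """TE x b measurement design.

    The measurement axis of every signal table and 4D volume follows the
    full cross product of ``echo_times`` and ``b_values``, ordered by
    (TE, then b).  The default is the 2x2 protocol TE = {55, 73} ms,
    b = {50, 700} s/mm^2.
    """

    echo_times: tuple[float, ...] = (55.0, 73.0)
    b_values: tuple[float, ...] = (50.0, 700.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "echo_times", tuple(sorted(float(t) for t in self.echo_times)))
        object.__setattr__(self, "b_values", tuple(sorted(float(b) for b in self.b_values)))
        if any(te <= 0 for te in self.echo_times):
            raise ValueError("all echo times must be > 0 ms")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b-values must be >= 0 s/mm^2")

    @property
    def measurements(self) -> tuple[tuple[float, float], ...]:
        """Ordered (TE, b) pairs, TE-major."""
        return tuple((te, b) for te in self.echo_times for b in self.b_values)

    @property
    def n_measurements(self) -> int:
        return len(self.echo_times) * len(self.b_values)

    def measurement_index(self, te: float, b: float) -> int:
        """Position of the (te, b) measurement on the canonical axis."""
        try:
            return self.measurements.index((float(te), float(b)))
        except ValueError:
            raise KeyError(f"measurement (TE={te}, b={b}) not in scheme") from None

    def te_array(self) -> np.ndarray:
        return np.array([m[0] for m in self.measurements])

    def b_array(self) -> np.ndarray:
        return np.array([m[1] for m in self.measurements])


@dataclass(frozen=True)
class ComponentBasis:
    """Fixed per-component diffusivities and relaxation times.

    ADCs (um^2/ms) are fixed a priori; the population T2 pair (ms) is
    determined by the pooled grid-search calibration.  Defaults are the
    literature diffusivities 0.3 / 2.6 um^2/ms.
    """

    adc_slow: float = 0.3
    adc_fast: float = 2.6
    t2_slow: float = 45.0
    t2_fast: float = 180.0

    def __post_init__(self) -> None:
        if not 0 < self.adc_slow < self.adc_fast:
            raise ValueError("require 0 < adc_slow < adc_fast")
        if not 0 < self.t2_slow < self.t2_fast:
            raise ValueError("require 0 < t2_slow < t2_fast")

    @property
    def adc_pair(self) -> tuple[float, float]:
        return (self.adc_slow, self.adc_fast)

    @property
    def t2_pair(self) -> tuple[float, float]:
        return (self.t2_slow, self.t2_fast)


def _b_decay(b: np.ndarray | float, adc: float) -> np.ndarray:
    """Diffusion attenuation exp(-b * adc * 1e-3)."""
    return np.exp(-np.asarray(b, dtype=float) * adc * B_ADC_SCALE)


def attenuation_basis(scheme: AcquisitionScheme, basis: ComponentBasis) -> np.ndarray:
    """Per-measurement attenuation of each component.

    Returns an (n_measurements, 2) array; column 0 is the slow component
    ``exp(-TE/t2_slow) * exp(-b*adc_slow*1e-3)``, column 1 the fast one.
    All entries lie in (0, 1].
    """
    te = scheme.te_array()
    b = scheme.b_array()
    slow = np.exp(-te / basis.t2_slow) * _b_decay(b, basis.adc_slow)
    fast = np.exp(-te / basis.t2_fast) * _b_decay(b, basis.adc_fast)
    return np.column_stack([slow, fast])


def two_component_signal(
    si0: float | np.ndarray,
    sf_slow: float | np.ndarray,
    basis: ComponentBasis,
    scheme: AcquisitionScheme,
) -> np.ndarray:
    """Two-component signal at every measurement of the scheme.

    ``SI_m = si0 * [sf_slow * A_slow(m) + (1 - sf_slow) * A_fast(m)]``
    with A the attenuation basis.  ``si0`` and ``sf_slow`` may be arrays
    (broadcast against the measurement axis on the last dimension).
    """
    si0 = np.asarray(si0, dtype=float)
    sf = np.asarray(sf_slow, dtype=float)
    if np.any(sf < 0) or np.any(sf > 1):
        raise ValueError("sf_slow must lie in [0, 1]")
    if np.any(si0 < 0):
        raise ValueError("si0 must be >= 0")
    a = attenuation_basis(scheme, basis)
    return si0[..., None] * (sf[..., None] * a[:, 0] + (1.0 - sf[..., None]) * a[:, 1])


def bi_exponential_signal(
    si0: float | np.ndarray,
    sf_slow: float | np.ndarray,
    adc_pair: tuple[float, float],
    b_values: np.ndarray | tuple[float, ...],
) -> np.ndarray:
    """Bi-exponential (ADC-only) signal at the given b-values."""
    si0 = np.asarray(si0, dtype=float)
    sf = np.asarray(sf_slow, dtype=float)
    adc_slow, adc_fast = adc_pair
    b = np.asarray(b_values, dtype=float)
    return si0[..., None] * (
        sf[..., None] * _b_decay(b, adc_slow) + (1.0 - sf[..., None]) * _b_decay(b, adc_fast)
    )


def mono_exponential_signal(
    si0: float | np.ndarray,
    adc: float | np.ndarray,
    b_values: np.ndarray | tuple[float, ...],
) -> np.ndarray:
    """Mono-exponential signal ``si0 * exp(-b * adc * 1e-3)``."""
    si0 = np.asarray(si0, dtype=float)
    adc = np.asarray(adc, dtype=float)
    b = np.asarray(b_values, dtype=float)
    return si0[..., None] * np.exp(-b * adc[..., None] * B_ADC_SCALE)
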