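"""Scikit-learn style estimators for the three signal models.

Each estimator consumes an ``(n_voxels, n_measurements)`` array of
magnitudes on the canonical (TE, b) measurement axis and transforms it
into per-voxel parameters.  ``TwoComponentModel.fit`` performs the
population T2 calibration (pooled grid search) when no T2 pair is fixed,
so the model composes with sklearn pipelines and model selection; the
other two models are stateless transformers with trivial ``fit``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .calibration import CostSurface, GridSpec, calibrate_t2
from .fitting import (
    fit_bi_exponential_table,
    fit_mono_adc_table,
    fit_two_component_table,
)
from .signal_models import AcquisitionScheme, ComponentBasis

__all__ = ["TwoComponentModel", "BiExponentialModel", "MonoExponentialModel"]


def _validate_signals(X: np.ndarray, n_measurements: int) -> np.ndarray:
    X = check_array(X, ensure_all_finite="allow-nan", dtype=float)
    if X.shape[1] != n_measurements:
        raise ValueError(
            f"X has {X.shape[1]} measurement columns, scheme defines {n_measurements}"
        )
    return X


class TwoComponentModel(TransformerMixin, BaseEstimator):
    """Two-compartment T2 + diffusion signal-fraction model.

    Parameters
    ----------
    scheme : AcquisitionScheme
        The TE x b measurement design; columns of X follow its order.
    adc_slow, adc_fast : float
        Fixed component diffusivities in um^2/ms.
    t2_slow, t2_fast : float or None
        Fixed component T2s in ms.  When both are given, ``fit`` only
        validates them; when None, ``fit`` calibrates the pair by pooled
        grid search over ``t2_grid``.
    t2_grid : GridSpec or None
        Candidate T2 values for calibration (default grid if None).

    Attributes
    ----------
    t2_slow_, t2_fast_ : float
        The fixed or calibrated T2 pair.
    basis_ : ComponentBasis
        Full component basis used by ``transform``.
    cost_surface_ : CostSurface or None
        The pooled-cost grid (None when the pair was fixed).
    """

    def __init__(
        self,
        scheme: AcquisitionScheme | None = None,
        adc_slow: float = 0.3,
        adc_fast: float = 2.6,
        t2_slow: float | None = None,
        t2_fast: float | None = None,
        t2_grid: GridSpec | None = None,
    ) -> None:
        self.scheme = scheme
        self.adc_slow = adc_slow
        self.adc_fast = adc_fast
        self.t2_slow = t2_slow
        self.t2_fast = t2_fast
        self.t2_grid = t2_grid

    def _scheme(self) -> AcquisitionScheme:
        return self.scheme if self.scheme is not None else AcquisitionScheme()

    def fit(self, X: np.ndarray, y: None = None) -> "TwoComponentModel":
        """Calibrate (or accept) the population T2 pair from pooled voxels."""
        scheme = self._scheme()
        if (self.t2_slow is None) != (self.t2_fast is None):
            raise ValueError("fix both t2_slow and t2_fast, or neither")
        if self.t2_slow is not None:
            self.t2_slow_ = float(self.t2_slow)
            self.t2_fast_ = float(self.t2_fast)
            self.cost_surface_: CostSurface | None = None
        else:
            X = _validate_signals(X, scheme.n_measurements)
            surface = calibrate_t2(
                X, scheme, adc_pair=(self.adc_slow, self.adc_fast), grid=self.t2_grid
            )
            self.t2_slow_, self.t2_fast_ = surface.optimum
            self.cost_surface_ = surface
        self.basis_ = ComponentBasis(self.adc_slow, self.adc_fast, self.t2_slow_, self.t2_fast_)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Per-voxel fits; columns (si0, sf_slow, rmse), NaN where invalid."""
        check_is_fitted(self, "basis_")
        X = _validate_signals(X, self._scheme().n_measurements)
        si0, sf, rmse, _ = fit_two_component_table(X, self._scheme(), self.basis_)
        return np.column_stack([si0, sf, rmse])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(["si0", "sf_slow", "rmse"])


class _TwoPointModel(TransformerMixin, BaseEstimator):
    """Shared plumbing for the two-point (b1, b2) ADC-only fits."""

    scheme: AcquisitionScheme | None

    def _scheme(self) -> AcquisitionScheme:
        return self.scheme if self.scheme is not None else AcquisitionScheme()

    def _b_pair_columns(self) -> tuple[int, int, float, float]:
        scheme = self._scheme()
        te = scheme.echo_times[-1]  # longest TE, as in the reference analysis
        b1, b2 = scheme.b_values[0], scheme.b_values[-1]
        return scheme.measurement_index(te, b1), scheme.measurement_index(te, b2), b1, b2

    def fit(self, X: np.ndarray, y: None = None):
        self.n_features_in_ = self._scheme().n_measurements
        return self


class BiExponentialModel(_TwoPointModel):
    """ADC-only two-compartment model fitted at the longest TE.

    Exact two-point solution for (si0, sf_slow) with fixed diffusivities,
    the fraction clipped to [0, 1].
    """

    def __init__(
        self,
        scheme: AcquisitionScheme | None = None,
        adc_slow: float = 0.3,
        adc_fast: float = 2.6,
    ) -> None:
        self.scheme = scheme
        self.adc_slow = adc_slow
        self.adc_fast = adc_fast

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = _validate_signals(X, self._scheme().n_measurements)
        i1, i2, b1, b2 = self._b_pair_columns()
        si0, sf, _ = fit_bi_exponential_table(
            X[:, i1], X[:, i2], b1, b2, (self.adc_slow, self.adc_fast)
        )
        return np.column_stack([si0, sf])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(["si0", "sf_slow"])


class MonoExponentialModel(_TwoPointModel):
    """Conventional mono-exponential ADC at the longest TE (closed form)."""

    def __init__(self, scheme: AcquisitionScheme | None = None) -> None:
        self.scheme = scheme

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = _validate_signals(X, self._scheme().n_measurements)
        i1, i2, b1, b2 = self._b_pair_columns()
        si0, adc, _ = fit_mono_adc_table(X[:, i1], X[:, i2], b1, b2)
        return np.column_stack([si0, adc])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(["si0", "adc"])
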