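"""Regional time series -> functional connectivity and derived features.

Mirrors an M/EEG source-space pipeline from the band-pass step onward:
signals are band-pass filtered (8-40 Hz, 3rd-order Bessel, applied
forward-backward so the filter is zero phase), optionally resampled to a
common rate, and reduced to Pearson-correlation functional connectivity
(FC) matrices. Per-region nodal strength, proportional-threshold
binarization, upper-triangle vectorization and mean-shift harmonization
of FC sets are provided as the downstream feature operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal


@dataclass
class RegionalTimeSeries:
    """Source-space signals: ``data`` is (n_regions, n_samples), in Hz."""

    data: np.ndarray
    sampling_rate: float
    region_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(self.data.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region matrix, correlation-valued or binary."""

    values: np.ndarray
    kind: str = "correlation"
    region_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if self.kind == "correlation":
            if not np.allclose(np.diag(self.values), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.any(np.abs(self.values) > 1 + 1e-9):
                raise ValueError("correlation entries must lie in [-1, 1]")
        elif self.kind == "binary":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binary matrix entries must be 0 or 1")
            if np.any(np.diag(self.values) != 0):
                raise ValueError("binary matrix must have zero diagonal")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(n)]

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class RegionalMap:
    """One scalar per region (nodal strength, effect size, term map, ...)."""

    values: np.ndarray
    name: str = ""
    region_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"map {self.name!r} contains non-finite values")
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(self.values.size)]

    @property
    def n_regions(self) -> int:
        return self.values.size


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)


def bandpass_filter(
    ts: RegionalTimeSeries, low: float = 8.0, high: float = 40.0, order: int = 3
) -> RegionalTimeSeries:
    """Zero-phase Bessel band-pass.

    The Bessel filter is applied forward and backward (``filtfilt``) so the
    net response has no group delay; the effective magnitude response is the
    square of the one-pass response.
    """
    nyq = ts.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cut {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.bessel(order, [low, high], btype="bandpass", fs=ts.sampling_rate,
                        output="sos")
    out = signal.sosfiltfilt(sos, ts.data, axis=1)
    return RegionalTimeSeries(out, ts.sampling_rate, list(ts.region_labels))


def resample(ts: RegionalTimeSeries, target_rate: float) -> RegionalTimeSeries:
    """Polyphase resampling to ``target_rate`` (duration preserved)."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == ts.sampling_rate:
        return RegionalTimeSeries(ts.data.copy(), ts.sampling_rate,
                                  list(ts.region_labels))
    frac = Fraction(target_rate / ts.sampling_rate).limit_denominator(1000)
    out = signal.resample_poly(ts.data, frac.numerator, frac.denominator, axis=1)
    return RegionalTimeSeries(out, target_rate, list(ts.region_labels))


def compute_fc(ts: RegionalTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlation FC among regions.

    Raises if any region has zero variance (correlation undefined).
    """
    bad = np.flatnonzero(np.ptp(ts.data, axis=1) == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance region(s): {[ts.region_labels[i] for i in bad]}"
        )
    fc = np.corrcoef(ts.data)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return ConnectivityMatrix(fc, "correlation", list(ts.region_labels))


def nodal_strength(fc: ConnectivityMatrix) -> RegionalMap:
    """Per-region sum of off-diagonal connectivity (nodal strength)."""
    if fc.kind != "correlation":
        raise ValueError("nodal_strength expects a correlation matrix")
    v = fc.values.sum(axis=1) - np.diag(fc.values)
    return RegionalMap(v, "nodal_strength", list(fc.region_labels))


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def proportional_threshold(fc: ConnectivityMatrix, rho: float) -> ConnectivityMatrix:
    """Binarize by keeping the top ``rho`` fraction of edges.

    Edges are ranked on signed correlation value (highest kept); the retained
    count is ``rho * n(n-1)/2`` rounded half away from zero. Ties are broken
    by upper-triangle row-major index order, so the edge sets are nested
    across thresholds and the operation is deterministic.
    """
    if fc.kind != "correlation":
        raise ValueError("proportional_threshold expects a correlation matrix")
    if not 0 < rho <= 1:
        raise ValueError("rho must be in (0, 1]")
    n = fc.n_regions
    iu, ju = np.triu_indices(n, k=1)
    vals = fc.values[iu, ju]
    k = _round_half_away(rho * vals.size)
    if k == 0:
        raise ValueError(f"rho={rho} retains zero edges for n={n}")
    # lexsort: primary key descending value, secondary ascending index
    order = np.lexsort((np.arange(vals.size), -vals))
    keep = order[:k]
    out = np.zeros((n, n))
    out[iu[keep], ju[keep]] = 1.0
    out[ju[keep], iu[keep]] = 1.0
    return ConnectivityMatrix(out, "binary", list(fc.region_labels))


def vectorize_fc(fc: ConnectivityMatrix) -> np.ndarray:
    """Upper-triangle entries in row-major order; length n(n-1)/2."""
    if fc.kind != "correlation":
        raise ValueError("vectorize_fc expects a correlation matrix")
    iu, ju = np.triu_indices(fc.n_regions, k=1)
    return fc.values[iu, ju].copy()


def devectorize_fc(vec: np.ndarray, region_labels=None) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_fc`."""
    vec = np.asarray(vec, float).ravel()
    n = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if n * (n - 1) // 2 != vec.size:
        raise ValueError(f"vector length {vec.size} is not n(n-1)/2 for integer n")
    out = np.eye(n)
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return ConnectivityMatrix(out, "correlation",
                              list(region_labels) if region_labels else [])


def harmonize_fc(target_set, reference_mean: ConnectivityMatrix):
    """Additive edgewise shift of a set of FCs onto a reference mean.

    The target set's mean matrix is moved to the reference mean while
    between-subject differences are preserved exactly (before the final
    clip to [-1, 1] and diagonal restoration). This emulates adjusting one
    acquisition modality's FCs to another's average connectivity level.
    """
    mats = [_values(m) for m in target_set]
    ref = _values(reference_mean)
    if any(m.shape != ref.shape for m in mats):
        raise ValueError("dimension mismatch between target set and reference")
    shift = ref - np.mean(mats, axis=0)
    out = []
    for m, orig in zip(mats, target_set):
        v = np.clip(m + shift, -1.0, 1.0)
        np.fill_diagonal(v, 1.0)
        labels = (list(orig.region_labels)
                  if isinstance(orig, ConnectivityMatrix) else None)
        out.append(ConnectivityMatrix(v, "correlation", labels or []))
    return out
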