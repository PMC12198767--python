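"""Region time series to weighted connectivity matrices.

The pipeline mirrors standard resting-state practice: least-squares removal
of intercept, linear trend and nuisance regressors; winsorization to the
5th/95th percentiles; wavelet decomposition with retention of the dyadic
sub-band covering 0.03-0.06 Hz (detail level 3 at TR = 2 s); Pearson
correlation between region series; and deletion of dropout / primary-lesion
regions from the resulting matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pywt

from .core import WeightedConnectome

__all__ = [
    "RegionTimeSeries",
    "detrend_and_regress",
    "winsorize",
    "wavelet_band",
    "correlation_matrix",
    "exclude_regions",
    "preprocess_to_connectome",
    "wavelet_level_for_band",
    "TARGET_BAND_HZ",
]

#: frequency band retained for connectivity estimation
TARGET_BAND_HZ = (0.03, 0.06)


@dataclass(frozen=True)
class RegionTimeSeries:
    """Region-by-time BOLD-like samples with optional nuisance regressors."""

    region_ids: tuple[str, ...]
    samples: np.ndarray  # regions x time
    tr_seconds: float = 2.0
    nuisance: np.ndarray | None = None  # time x k

    def __post_init__(self) -> None:
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 2 or x.shape[0] != len(self.region_ids):
            raise ValueError("samples must be (n_regions, n_time)")
        if x.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.isfinite(x)):
            raise ValueError("samples contain missing/non-finite values")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region ids")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "samples", x)
        if self.nuisance is not None:
            nz = np.asarray(self.nuisance, dtype=float)
            if nz.ndim != 2 or nz.shape[0] != x.shape[1]:
                raise ValueError("nuisance must be (n_time, k)")
            object.__setattr__(self, "nuisance", nz)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_time(self) -> int:
        return self.samples.shape[1]


def detrend_and_regress(ts: RegionTimeSeries) -> RegionTimeSeries:
    """Project out intercept, linear trend and any nuisance columns.

    Residuals are orthogonal to the design; a rank-deficient nuisance block
    triggers a warning and a pseudo-inverse projection.
    """
    t = ts.n_time
    design = [np.ones(t), np.arange(t, dtype=float)]
    if ts.nuisance is not None:
        design.extend(np.asarray(ts.nuisance, dtype=float).T)
    X = np.column_stack(design)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"nuisance design rank-deficient ({rank} < {X.shape[1]}); "
            "using pseudo-inverse projection",
            stacklevel=2,
        )
    beta = np.linalg.pinv(X) @ ts.samples.T
    resid = ts.samples - (X @ beta).T
    return replace(ts, samples=resid)


def winsorize(
    ts: RegionTimeSeries, lower_pct: float = 5.0, upper_pct: float = 95.0
) -> RegionTimeSeries:
    """Clip each region series to its own percentile limits.

    Percentiles use linear interpolation between closest ranks (numpy's
    default convention). Constant series pass through unchanged.
    """
    if not lower_pct < upper_pct:
        raise ValueError("lower_pct must be < upper_pct")
    lo = np.percentile(ts.samples, lower_pct, axis=1, keepdims=True)
    hi = np.percentile(ts.samples, upper_pct, axis=1, keepdims=True)
    return replace(ts, samples=np.clip(ts.samples, lo, hi))


def wavelet_level_for_band(
    tr_seconds: float, band_hz: tuple[float, float] = TARGET_BAND_HZ
) -> int:
    """Wavelet detail level whose dyadic band best covers the target band.

    Detail level j spans [1/(2^(j+1) TR), 1/(2^j TR)] Hz; the level with the
    largest overlap with ``band_hz`` is selected (level 3 for TR = 2 s).
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    lo, hi = band_hz
    best, best_overlap = None, -1.0
    for j in range(1, 16):
        f_hi = 1.0 / (2.0**j * tr_seconds)
        f_lo = f_hi / 2.0
        overlap = max(0.0, min(hi, f_hi) - max(lo, f_lo))
        if overlap > best_overlap:
            best, best_overlap = j, overlap
    if best_overlap <= 0.0:
        raise ValueError(
            f"no dyadic band overlaps {band_hz} Hz at TR={tr_seconds}s"
        )
    return best


def wavelet_band(
    ts: RegionTimeSeries,
    wavelet: str = "sym8",
    band_hz: tuple[float, float] = TARGET_BAND_HZ,
) -> RegionTimeSeries:
    """Reconstruct the wavelet sub-band covering 0.03-0.06 Hz.

    Each region series is decomposed (periodized DWT) and only the detail
    level whose dyadic band covers the target band is reconstructed. The
    wavelet family is configurable; an orthogonal symlet is the default for
    its near-symmetric, reasonably sharp band-pass response.
    """
    level = wavelet_level_for_band(ts.tr_seconds, band_hz)
    min_len = 2 ** (level + 1)
    if ts.n_time < min_len:
        raise ValueError(
            f"series length {ts.n_time} too short for wavelet level {level}; "
            f"need at least {min_len} time points"
        )
    out = np.empty_like(ts.samples)
    for i in range(ts.n_regions):
        coeffs = pywt.wavedec(
            ts.samples[i], wavelet, mode="periodization", level=level
        )
        kept = [np.zeros_like(c) for c in coeffs]
        # coeffs = [a_level, d_level, d_level-1, ..., d_1]; keep d_level
        kept[1] = coeffs[1]
        rec = pywt.waverec(kept, wavelet, mode="periodization")
        out[i] = rec[: ts.n_time]
    return replace(ts, samples=out)


def correlation_matrix(ts: RegionTimeSeries) -> WeightedConnectome:
    """Pearson correlation between all region pairs."""
    sd = ts.samples.std(axis=1)
    flat = np.flatnonzero(sd == 0.0)
    if flat.size:
        bad = [ts.region_ids[i] for i in flat]
        raise ValueError(f"zero-variance regions: {bad}")
    w = np.corrcoef(ts.samples)
    w = np.clip(w, -1.0, 1.0)
    return WeightedConnectome(ts.region_ids, w)


def exclude_regions(
    conn: WeightedConnectome,
    dropout_ids: Iterable[str] = (),
    primary_lesioned: Iterable[str] = (),
) -> WeightedConnectome:
    """Delete dropout and primary-lesion regions from the matrix.

    The removed-node ledger records the reason for each deletion; the
    operation is idempotent (replaying a removal is a no-op).
    """
    out = conn.drop_nodes(set(dropout_ids), reason="dropout")
    return out.drop_nodes(set(primary_lesioned), reason="primary_lesion")


def preprocess_to_connectome(
    ts: RegionTimeSeries,
    dropout_ids: Iterable[str] = (),
    primary_lesioned: Iterable[str] = (),
    wavelet: str = "sym8",
) -> WeightedConnectome:
    """Full fixed-order pipeline: detrend/regress, winsorize, band, correlate,
    exclude."""
    ts = detrend_and_regress(ts)
    ts = winsorize(ts)
    ts = wavelet_band(ts, wavelet=wavelet)
    conn = correlation_matrix(ts)
    return exclude_regions(conn, dropout_ids, primary_lesioned)
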