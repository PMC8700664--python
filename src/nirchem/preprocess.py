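"""Noise pipeline: scatter/baseline correction and wavelet smoothing.

The fixed pipeline order is absorbance -> scatter correction -> wavelet
smoothing. Absorbance conversion lives in :mod:`nirchem.spectra`; this module
provides the remaining two steps plus the config that drives them.

The discrete wavelet transform is implemented here as a periodized orthogonal
filter bank. For an orthonormal wavelet and even signal length the analysis
operator is orthogonal, so synthesis is its transpose and reconstruction is
exact to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra import SpectraSet

__all__ = [
    "PreprocessConfig",
    "correct_scatter",
    "smooth_wavelet",
    "preprocess_pipeline",
    "WAVELET_FILTERS",
]

# Decomposition low-pass filters of orthonormal wavelets (standard published
# coefficients). High-pass follows by the quadrature-mirror relation.
WAVELET_FILTERS: dict[str, np.ndarray] = {
    "haar": np.array([0.7071067811865476, 0.7071067811865476]),
    "db2": np.array([-0.12940952255126037, 0.2241438680420134,
                     0.8365163037378079, 0.48296291314453416]),
    "db4": np.array([-0.010597401785069032, 0.0328830116668852,
                     0.030841381835560764, -0.18703481171909309,
                     -0.027983769416859854, 0.6308807679298589,
                     0.7148465705529157, 0.2303778133088965]),
    "sym4": np.array([-0.07576571478927333, -0.02963552764599851,
                      0.49761866763201545, 0.8037387518059161,
                      0.29785779560527736, -0.09921954357684722,
                      -0.012603967262037833, 0.0322231006040427]),
    "sym8": np.array([-0.0033824159510061256, -0.0005421323317911481,
                      0.03169508781149298, 0.007607487324917605,
                      -0.1432942383508097, -0.061273359067658524,
                      0.4813596512583722, 0.7771857517005235,
                      0.3644418948353314, -0.05194583810770904,
                      -0.027219029917056003, 0.049137179673607506,
                      0.003808752013890615, -0.01495225833704823,
                      -0.0003029205147213668, 0.0018899503327594609]),
}
WAVELET_FILTERS["db1"] = WAVELET_FILTERS["haar"]

_SCATTER_METHODS = ("snv", "msc", "none")
_THRESHOLD_RULES = ("universal", "none")


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the scatter-correction and smoothing steps."""

    scatter_method: str = "snv"
    wavelet_family: str = "sym4"
    wavelet_level: int = 3
    threshold_rule: str = "universal"

    def __post_init__(self) -> None:
        if self.scatter_method not in _SCATTER_METHODS:
            raise ValueError(f"scatter_method must be one of {_SCATTER_METHODS}")
        if self.wavelet_family not in WAVELET_FILTERS:
            raise ValueError(
                f"unsupported wavelet {self.wavelet_family!r}; "
                f"choose from {sorted(WAVELET_FILTERS)}"
            )
        if self.wavelet_level < 1:
            raise ValueError("wavelet_level must be >= 1")
        if self.threshold_rule not in _THRESHOLD_RULES:
            raise ValueError(f"threshold_rule must be one of {_THRESHOLD_RULES}")


# ---------------------------------------------------------------------------
# scatter / baseline correction
# ---------------------------------------------------------------------------

def correct_scatter(s: SpectraSet, method: str = "snv") -> SpectraSet:
    """Row-wise light-scatter and baseline correction.

    ``snv`` standardizes every row to zero mean and unit (sample) standard
    deviation; ``msc`` regresses every row on the mean spectrum and returns
    (row - intercept) / slope; ``none`` is the identity.
    """
    if method not in _SCATTER_METHODS:
        raise ValueError(f"unknown scatter method {method!r}")
    if method == "none":
        return SpectraSet(s.grid, s.intensities.copy(), list(s.sample_ids),
                          s.mode, s.scan_of)
    if s.mode != "absorbance":
        raise ValueError("scatter correction expects absorbance spectra")
    X = s.intensities
    if method == "snv":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        degenerate = np.where(sd[:, 0] == 0)[0]
        if degenerate.size:
            raise ValueError(
                f"constant spectrum (zero variance) for sample "
                f"{s.sample_ids[degenerate[0]]!r}; SNV undefined"
            )
        out = (X - mu) / sd
    else:  # msc
        if s.n_samples < 2:
            raise ValueError("MSC needs at least 2 samples (mean reference)")
        ref = X.mean(axis=0)
        ref_c = ref - ref.mean()
        denom = float(ref_c @ ref_c)
        if denom == 0:
            raise ValueError("mean reference spectrum is constant; MSC undefined")
        rows_c = X - X.mean(axis=1, keepdims=True)
        slope = rows_c @ ref_c / denom
        intercept = X.mean(axis=1) - slope * ref.mean()
        if np.any(slope == 0):
            i = int(np.where(slope == 0)[0][0])
            raise ValueError(f"zero MSC slope for sample {s.sample_ids[i]!r}")
        out = (X - intercept[:, None]) / slope[:, None]
    return SpectraSet(s.grid, out, list(s.sample_ids), s.mode, s.scan_of)


# ---------------------------------------------------------------------------
# periodized orthogonal DWT
# ---------------------------------------------------------------------------

def _qmf(lo: np.ndarray) -> np.ndarray:
    hi = lo[::-1].copy()
    hi[1::2] *= -1.0
    return hi


def _analysis_step(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    n = x.size
    if n % 2:  # periodization padding: repeat the last sample
        x = np.concatenate([x, x[-1:]])
        n += 1
    pos = (np.arange(0, n, 2)[:, None] + np.arange(lo.size)[None, :]) % n
    xs = x[pos]
    return xs @ lo, xs @ hi


def _synthesis_step(a: np.ndarray, d: np.ndarray, lo: np.ndarray,
                    hi: np.ndarray, n_out: int) -> np.ndarray:
    n = 2 * a.size
    y = np.zeros(n)
    ks = 2 * np.arange(a.size)
    for j in range(lo.size):
        np.add.at(y, (ks + j) % n, lo[j] * a + hi[j] * d)
    return y[:n_out]


def wavelet_decompose(x: np.ndarray, family: str, level: int):
    """Periodized multi-level DWT. Returns (approx, [details...], [lengths...])."""
    lo = WAVELET_FILTERS[family]
    hi = _qmf(lo)
    details, lengths = [], []
    a = np.asarray(x, dtype=float)
    for _ in range(level):
        lengths.append(a.size)
        a, d = _analysis_step(a, lo, hi)
        details.append(d)
    return a, details, lengths


def wavelet_reconstruct(a: np.ndarray, details: list[np.ndarray],
                        lengths: list[int], family: str) -> np.ndarray:
    lo = WAVELET_FILTERS[family]
    hi = _qmf(lo)
    for d, n_out in zip(details[::-1], lengths[::-1]):
        a = _synthesis_step(a, d, lo, hi, n_out)
    return a


def _denoise_row(x: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    a, details, lengths = wavelet_decompose(x, cfg.wavelet_family,
                                            cfg.wavelet_level)
    if cfg.threshold_rule == "universal":
        # VisuShrink: sigma from the MAD of the finest detail band,
        # soft threshold sigma * sqrt(2 log n) applied to all detail bands.
        finest = details[0]
        sigma = np.median(np.abs(finest)) / 0.6744897501960817
        thr = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))
        details = [np.sign(d) * np.maximum(np.abs(d) - thr, 0.0)
                   for d in details]
    return wavelet_reconstruct(a, details, lengths, cfg.wavelet_family)


def smooth_wavelet(s: SpectraSet, cfg: PreprocessConfig) -> SpectraSet:
    """Per-row wavelet shrinkage smoothing; output length equals input length."""
    n = len(s.grid)
    if n < 2 ** cfg.wavelet_level:
        raise ValueError(
            f"grid length {n} too short for wavelet level {cfg.wavelet_level}"
        )
    out = np.stack([_denoise_row(row, cfg) for row in s.intensities])
    return SpectraSet(s.grid, out, list(s.sample_ids), s.mode, s.scan_of)


def preprocess_pipeline(s: SpectraSet, cfg: PreprocessConfig,
                        scans_per_sample: int | None = None) -> SpectraSet:
    """Fixed-order pipeline: average scans -> absorbance -> scatter -> wavelet.

    Accepts a scan-level or sample-level reflectance set (or an absorbance
    set, in which case conversion is skipped).
    """
    from .spectra import average_scans, to_absorbance

    if scans_per_sample is not None or s.scan_of is not None:
        s = average_scans(s, scans_per_sample)
    if s.mode == "reflectance":
        s = to_absorbance(s)
    s = correct_scatter(s, cfg.scatter_method)
    return smooth_wavelet(s, cfg)
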