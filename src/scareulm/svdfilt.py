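"""SVD clutter filtering on casorati matrices, short- and long-ensemble.

Coherent tissue/skull signal concentrates in the leading singular
components of the space x time (casorati) matrix; removing a fixed number
of leading components (default 20) acts as a clutter filter.  The spectral
report reproduces the singular-spectrum analysis used to argue for long
ensembles: the periodogram (Tukey 0.2 apodization) of each temporal
singular vector, its power-weighted central frequency, the first vector at
or above the 100 Hz tissue criterion, and the first inflection of the
central-frequency curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla
from scipy.linalg import svd as _full_svd
from scipy.signal import periodogram

from .frames import CasoratiMatrix, FrameStack, from_casorati, to_casorati

TISSUE_FREQ_HZ = 100.0
DEFAULT_CUTOFF = 20


@dataclass
class SVDReport:
    singular_values: np.ndarray
    central_frequency_hz: np.ndarray
    tissue_cutoff_index: int          # 1-based: first vector with cf >= 100 Hz
    inflection_index: int             # 1-based
    ensemble_size: int
    tissue_criterion_valid: bool = True
    smoothed_cf_hz: np.ndarray | None = field(default=None, repr=False)


def standardize_slow_time(c: CasoratiMatrix) -> CasoratiMatrix:
    """Remove per-pixel slow-time mean and (where nonzero) standard deviation.

    Zero-variance pixels are left at zero.  Idempotent up to numerical
    round-off.
    """
    if c.ensemble_size < 2:
        raise ValueError("need at least two frames to standardize")
    m = c.matrix.astype(np.float64, copy=True)
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    m -= mean
    nz = sd[:, 0] > 0
    m[nz] /= sd[nz]
    m[~nz] = 0.0
    return CasoratiMatrix(matrix=m, frame_shape=c.frame_shape)


def svd_filter(c: CasoratiMatrix, cutoff: int = DEFAULT_CUTOFF,
               full_threshold: int = 2000) -> CasoratiMatrix:
    """Zero the first ``cutoff`` singular components of the casorati matrix.

    Equivalent to residual = input - rank-``cutoff`` truncated-SVD
    approximation.  For matrices whose smaller dimension exceeds
    ``full_threshold`` a Lanczos partial SVD of the leading components is
    used instead of a dense decomposition.
    """
    m = c.matrix
    rank_bound = min(m.shape)
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if cutoff == 0:
        return CasoratiMatrix(matrix=m.copy(), frame_shape=c.frame_shape)
    if cutoff >= rank_bound:
        warnings.warn("cutoff >= matrix rank bound; filtered output is empty",
                      stacklevel=2)
        return CasoratiMatrix(matrix=np.zeros_like(m), frame_shape=c.frame_shape)
    if rank_bound > full_threshold and cutoff < rank_bound // 4:
        u, s, vt = spla.svds(m.astype(np.float64), k=cutoff)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    else:
        u, s, vt = _full_svd(m, full_matrices=False)
        u, s, vt = u[:, :cutoff], s[:cutoff], vt[:cutoff]
    resid = m - (u * s) @ vt
    return CasoratiMatrix(matrix=resid.astype(m.dtype, copy=False),
                          frame_shape=c.frame_shape)


def filter_stack(fs: FrameStack, ensemble_size: int,
                 cutoff: int = DEFAULT_CUTOFF,
                 standardize: bool = True) -> FrameStack:
    """Filter a whole stack in consecutive ensembles ("stitched").

    Each ensemble of ``ensemble_size`` frames is standardized in slow time,
    SVD-filtered independently, and the outputs concatenated; a final
    partial ensemble is processed the same way when it still has more
    frames than the cutoff, otherwise it is zeroed.  With
    ``ensemble_size >= n_frames`` this is the long-ensemble (LE) filter.
    """
    n = fs.n_frames
    ensemble_size = min(ensemble_size, n)
    out = np.zeros_like(fs.frames, dtype=np.float64)
    for start in range(0, n, ensemble_size):
        size = min(ensemble_size, n - start)
        if size <= cutoff + 1:
            continue
        c = to_casorati(fs, start, size)
        if standardize:
            c = standardize_slow_time(c)
        filt = svd_filter(c, cutoff)
        out[:, :, start:start + size] = from_casorati(filt)
    return FrameStack(frames=out, pixel_pitch_um=fs.pixel_pitch_um,
                      frame_rate_hz=fs.frame_rate_hz,
                      wavelength_um=fs.wavelength_um, origin_um=fs.origin_um,
                      t0_s=fs.t0_s, n_clipped=fs.n_clipped)


def spectral_report(c: CasoratiMatrix, frame_rate_hz: float,
                    max_vectors: int | None = None,
                    smooth_window: int = 5) -> SVDReport:
    """Singular spectrum + per-vector central frequency analysis.

    The central frequency of each temporal singular vector is the
    power-weighted mean of its Tukey(0.2)-apodized periodogram frequencies
    (absolute frequency).  ``tissue_cutoff_index`` is the 1-based index of
    the first vector whose central frequency reaches 100 Hz;
    ``inflection_index`` is the first sign change of the second difference
    of the smoothed central-frequency curve.
    """
    if c.ensemble_size < 64:
        raise ValueError("need >= 64 frames for a meaningful spectral report")
    valid = frame_rate_hz > 2 * TISSUE_FREQ_HZ
    if not valid:
        warnings.warn("frame rate too low for the 100 Hz tissue criterion",
                      stacklevel=2)
    u, s, vt = _full_svd(np.asarray(c.matrix, dtype=np.float64),
                         full_matrices=False)
    if max_vectors is not None:
        s, vt = s[:max_vectors], vt[:max_vectors]
    cf = np.empty(len(s))
    for i, v in enumerate(vt):
        f, p = periodogram(v, fs=frame_rate_hz, window=("tukey", 0.2))
        total = p.sum()
        cf[i] = (p * f).sum() / total if total > 0 else 0.0

    n = len(cf)
    tissue_idx = int(np.argmax(cf >= TISSUE_FREQ_HZ)) + 1 if np.any(
        cf >= TISSUE_FREQ_HZ) else n

    # smoothed second difference -> first curvature sign change
    w = min(smooth_window, n)
    kern = np.ones(w) / w
    sm = np.convolve(cf, kern, mode="same")
    d2 = np.diff(sm, n=2)
    sign = np.sign(d2)
    inflect = 1
    for i in range(1, len(sign)):
        if sign[i] != 0 and sign[i - 1] != 0 and sign[i] != sign[i - 1]:
            inflect = i + 1  # 1-based position in the cf curve
            break
    inflect = int(np.clip(inflect, 1, tissue_idx))
    return SVDReport(singular_values=s, central_frequency_hz=cf,
                     tissue_cutoff_index=int(tissue_idx),
                     inflection_index=inflect, ensemble_size=c.ensemble_size,
                     tissue_criterion_valid=valid, smoothed_cf_hz=sm)


def report_to_json(report: SVDReport, path: str) -> None:
    import json
    with open(path, "w") as f:
        json.dump({
            "singular_values": report.singular_values.tolist(),
            "central_frequency_hz": report.central_frequency_hz.tolist(),
            "tissue_cutoff_index": report.tissue_cutoff_index,
            "inflection_index": report.inflection_index,
            "ensemble_size": report.ensemble_size,
            "tissue_criterion_valid": report.tissue_criterion_valid,
            "inflection_tissue_ratio": report.inflection_index
            / max(report.tissue_cutoff_index, 1),
        }, f, indent=2)
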