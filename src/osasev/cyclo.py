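"""Cyclostationary features: cyclic spectral density, NMF compression, statistics.

Breathing and snoring are cyclostationary: their second-order statistics repeat
at the breath rate. The cyclic spectral density (CSD) S(alpha, f) — the 2-D
Fourier transform of the time-varying autocorrelation C(t, tau) over lag tau
(-> spectral frequency f) and time t (-> cyclic frequency alpha) — is nonzero
at alpha != 0 only for such signals, exposing hidden periodicity an ordinary
spectrum cannot show.

Per 60 s window the CSD magnitude grid is estimated on a fixed (f, alpha) grid
(54 x 889 by default); a running (incremental) mean folds the whole night into
one grid with bounded memory. Otsu thresholding suppresses the near-zero
background, and a shared non-negative matrix factorization basis (rank 45, fit
on the transposed grids of the whole cohort) compresses each subject's grid to
a 45 x 54 activation matrix. Seven statistics (maximum, minimum, median,
standard deviation, variance, kurtosis, skewness) over each of the 45 rows and
54 columns give the 693 cyclostationary features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from skimage.filters import threshold_otsu

from .audio import AudioSignal
from .config import CsdConfig, NmfConfig
from .errors import ValidationError

#: the seven summary statistics, in canonical order
STAT_NAMES = ("max", "min", "median", "std", "var", "kurtosis", "skewness")

_EPS = 1e-12


@dataclass
class CSDGrid:
    """One window's CSD magnitudes over (spectral f, cyclic alpha)."""

    magnitudes: np.ndarray          # (n_f, n_alpha), non-negative
    f_grid: np.ndarray              # Hz, one-sided
    alpha_grid: np.ndarray          # Hz, fftfreq-ordered (alpha=0 at index 0)
    window_s: float = 60.0

    def __post_init__(self) -> None:
        if self.magnitudes.shape != (len(self.f_grid), len(self.alpha_grid)):
            raise ValidationError("CSD grid shape does not match its axes")
        if np.any(self.magnitudes < 0):
            raise ValidationError("CSD magnitudes must be non-negative")


@dataclass
class RunningCSDMean:
    """Incremental mean of CSD grids: after k updates it equals the batch mean."""

    rms: np.ndarray
    k: int = 0
    window_s: float = 60.0
    f_grid: np.ndarray | None = None
    alpha_grid: np.ndarray | None = None


@dataclass
class OtsuResult:
    """Otsu-thresholded matrix; ``degenerate`` flags a constant input."""

    threshold: float
    masked: np.ndarray
    degenerate: bool = False


@dataclass
class NMFBasis:
    """Shared non-negative basis W (n_alpha x rank) with fit metadata."""

    W: np.ndarray
    rank: int
    seed: int
    fit_residual: float   # relative Frobenius residual on the training stack

    def __post_init__(self) -> None:
        if np.any(self.W < 0):
            raise ValidationError("basis must be non-negative")
        if self.W.shape[1] != self.rank:
            raise ValidationError("basis column count must equal the rank")


@dataclass
class ActivationMatrix:
    """Per-subject NMF activations H (rank x n_f), 45 x 54 under defaults."""

    H: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.H < 0):
            raise ValidationError("activations must be non-negative")


def cyclic_spectral_density(window: AudioSignal, cfg: CsdConfig | None = None) -> CSDGrid:
    """Estimate the CSD magnitude grid of one analysis window.

    The symmetric-lag instantaneous autocorrelation
    ``C(t, tau) = x(t + ceil(tau/2)) * x(t - floor(tau/2))`` is averaged over
    ``n_alpha`` contiguous time blocks (smoothing the estimate without
    blurring modulation periods far longer than one block) at
    ``2*(n_f-1)+1`` symmetric lags, then Fourier-transformed over tau
    (one-sided -> f) and over t (full FFT -> alpha, fftfreq order), keeping
    magnitudes. With the defaults (54 f-steps, 889 alpha-steps per 60 s
    window) the grid is 54 x 889; alpha resolution is ~1/window_s and the f
    axis spans up to Nyquist in rate/(2*n_f - 1) steps.
    """
    cfg = cfg or CsdConfig()
    x = window.samples
    n_lags = 2 * (cfg.n_f - 1) + 1
    half = n_lags // 2
    margin = (half + 1) // 2
    usable = len(x) - 2 * margin
    if usable < cfg.n_alpha:
        raise ValidationError(
            f"window of {len(x)} samples too short for an {cfg.n_alpha}-point "
            f"time grid with {n_lags} lags"
        )
    hop = usable // cfg.n_alpha
    n_used = hop * cfg.n_alpha
    # C over non-negative lags; negative lags are identical by the symmetric split
    c_pos = np.empty((cfg.n_alpha, half + 1))
    for tau in range(half + 1):
        o1 = (tau + 1) // 2
        o2 = o1 - tau
        prod = x[margin + o1 : margin + o1 + n_used] * x[margin + o2 : margin + o2 + n_used]
        c_pos[:, tau] = prod.reshape(cfg.n_alpha, hop).mean(axis=1)
    c_full = np.concatenate([c_pos, c_pos[:, :0:-1]], axis=1)  # fft lag order
    s_tf = np.fft.fft(c_full, axis=1)[:, : cfg.n_f]            # one-sided f
    s_af = np.fft.fft(s_tf, axis=0)                            # full alpha axis
    mags = np.abs(s_af).T / (cfg.n_alpha * n_lags)
    hop_s = hop / window.rate_hz
    return CSDGrid(
        magnitudes=mags,
        f_grid=np.arange(cfg.n_f) * window.rate_hz / n_lags,
        alpha_grid=np.fft.fftfreq(cfg.n_alpha, d=hop_s),
        window_s=len(x) / window.rate_hz,
    )


def update_running_mean(state: RunningCSDMean, csd: CSDGrid) -> RunningCSDMean:
    """Fold one CSD grid into the running mean: rms += (S - rms) / k."""
    if state.k < 0:
        raise ValidationError("window count cannot be negative")
    if state.k > 0 and state.rms.shape != csd.magnitudes.shape:
        raise ValidationError(
            f"shape mismatch: running mean {state.rms.shape} vs "
            f"CSD {csd.magnitudes.shape}"
        )
    k = state.k + 1
    if state.k == 0:
        rms = csd.magnitudes.copy()
    else:
        rms = state.rms + (csd.magnitudes - state.rms) / k
    return RunningCSDMean(
        rms=rms, k=k, window_s=csd.window_s,
        f_grid=csd.f_grid, alpha_grid=csd.alpha_grid,
    )


def subject_running_mean(
    signal: AudioSignal,
    cfg: CsdConfig | None = None,
    state: RunningCSDMean | None = None,
) -> RunningCSDMean:
    """Mean CSD of a recording over consecutive non-overlapping windows.

    Windows shorter than ``window_s`` at the end are dropped. Passing a
    ``state`` continues an existing running mean (e.g. across non-contiguous
    sleep-stage segments of one subject).
    """
    cfg = cfg or CsdConfig()
    win = int(round(cfg.window_s * signal.rate_hz))
    n_windows = len(signal) // win
    if n_windows == 0 and (state is None or state.k == 0):
        raise ValidationError(
            f"recording of {signal.duration_s:.1f} s is shorter than one "
            f"{cfg.window_s:.0f} s analysis window"
        )
    if state is None:
        state = RunningCSDMean(rms=np.zeros(0), k=0, window_s=cfg.window_s)
    for i in range(n_windows):
        seg = AudioSignal(signal.samples[i * win : (i + 1) * win], signal.rate_hz)
        state = update_running_mean(state, cyclic_spectral_density(seg, cfg))
    return state


def otsu_mask(m: np.ndarray) -> OtsuResult:
    """Zero all entries below the Otsu threshold (256-bin histogram).

    The threshold maximizes the between-class variance of the entry
    histogram; masking preserves the matrix shape (downstream factorization
    needs fixed dimensions). A constant matrix has no threshold: it is
    returned unchanged with the degenerate flag set.
    """
    m = np.asarray(m, dtype=np.float64)
    if np.any(m < 0):
        raise ValidationError("otsu_mask expects non-negative magnitudes")
    if np.ptp(m) < _EPS:
        return OtsuResult(threshold=float(m.flat[0]) if m.size else 0.0,
                          masked=m.copy(), degenerate=True)
    thr = float(threshold_otsu(m.ravel(), nbins=256))
    masked = np.where(m < thr, 0.0, m)
    return OtsuResult(threshold=thr, masked=masked, degenerate=False)


def _nmf_init(V: np.ndarray, rank: int, rng: np.random.Generator):
    # uniform init scaled so that E[(WH)_ij] matches mean(V)
    scale = np.sqrt(max(V.mean(), _EPS) / rank) * 2.0
    W = rng.uniform(0.0, scale, size=(V.shape[0], rank))
    H = rng.uniform(0.0, scale, size=(rank, V.shape[1]))
    return W, H


def nmf_decompose(
    V: np.ndarray,
    rank: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    W_fixed: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative-update NMF for the Frobenius objective.

    Returns (W, H, objective trajectory). The objective (||V - WH||_F) is
    non-increasing under the updates; iteration stops at ``max_iter`` or when
    the relative objective change drops below ``tol``. With ``W_fixed`` only H
    is updated (projection onto a frozen basis).
    """
    V = np.asarray(V, dtype=np.float64)
    if np.any(V < 0):
        raise ValidationError("NMF input must be non-negative")
    if rank < 1 or rank > min(V.shape):
        raise ValidationError(
            f"rank {rank} out of range for a {V.shape[0]}x{V.shape[1]} matrix"
        )
    rng = np.random.default_rng(seed)
    W, H = _nmf_init(V, rank, rng)
    if W_fixed is not None:
        if W_fixed.shape != (V.shape[0], rank):
            raise ValidationError(
                f"fixed basis shape {W_fixed.shape} incompatible with "
                f"V {V.shape} at rank {rank}"
            )
        W = W_fixed
    objectives: list[float] = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        if W_fixed is None:
            W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(V - W @ H))
        objectives.append(obj)
        if prev is not None and prev > 0 and (prev - obj) / prev < tol:
            break
        prev = obj
    return W, H, objectives


def fit_shared_basis(
    rms_list: list[RunningCSDMean | np.ndarray],
    rank: int = 45,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NMFBasis:
    """Fit the cohort-shared NMF basis on horizontally stacked transposed grids.

    Each (n_f x n_alpha) mean-CSD grid is transposed so rows index cyclic
    frequency, then all subjects are concatenated into V (n_alpha x n_f *
    n_subjects); the rank-45 basis W then captures cohort-wide cyclic
    structure and each subject is later projected onto it.
    """
    mats = [m.rms if isinstance(m, RunningCSDMean) else np.asarray(m) for m in rms_list]
    if not mats:
        raise ValidationError("need at least one mean-CSD grid")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValidationError("all mean-CSD grids must share one shape")
    V = np.hstack([m.T for m in mats])
    W, H, _ = nmf_decompose(V, rank=rank, seed=seed, max_iter=max_iter, tol=tol)
    denom = np.linalg.norm(V)
    residual = float(np.linalg.norm(V - W @ H) / denom) if denom > 0 else 0.0
    return NMFBasis(W=W, rank=rank, seed=seed, fit_residual=residual)


def project_activations(
    basis: NMFBasis,
    rms: RunningCSDMean | np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ActivationMatrix:
    """Project one subject's mean CSD onto the frozen shared basis.

    Solves min_H ||rms.T - W H||_F over H >= 0 with H-only multiplicative
    updates; H is rank x n_f (45 x 54 under defaults).
    """
    m = rms.rms if isinstance(rms, RunningCSDMean) else np.asarray(rms)
    V = m.T
    if V.shape[0] != basis.W.shape[0]:
        raise ValidationError(
            f"grid with {V.shape[0]} cyclic bins incompatible with basis of "
            f"{basis.W.shape[0]}"
        )
    _, H, _ = nmf_decompose(
        V, rank=basis.rank, seed=basis.seed, max_iter=max_iter, tol=tol,
        W_fixed=basis.W,
    )
    return ActivationMatrix(H=H)


def _seven_stats(x: np.ndarray, include_mean: bool) -> dict[str, float]:
    m2 = float(np.var(x))  # population moment, for the degeneracy check
    degenerate = m2 < _EPS
    out = {
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "median": float(np.median(x)),
        "std": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "var": float(np.var(x, ddof=1)) if len(x) > 1 else 0.0,
        "kurtosis": 0.0 if degenerate else float(sstats.kurtosis(x, fisher=False, bias=True)),
        "skewness": 0.0 if degenerate else float(sstats.skew(x, bias=True)),
    }
    if include_mean:
        out["mean"] = float(np.mean(x))
    return out


def summarize_statistics(
    H: ActivationMatrix | np.ndarray, include_mean: bool = False
) -> dict[str, float]:
    """The named statistical features of an activation matrix.

    For each of the rank rows (base: dimension-reduced cyclic index, observed
    over f) and each of the n_f columns (base: spectral index, observed over
    the cyclic axis) the seven statistics are computed; names follow
    ``c_<base>_<obs>_<stat>_<seq>`` with 1-based sequence numbers, e.g.
    ``c_alpha_f_max_40`` = maximum over f for cyclic index 40. A 45 x 54
    matrix yields 45*7 + 54*7 = 693 features. Degenerate (constant) rows or
    columns report skewness and kurtosis as 0. ``include_mean`` adds the mean
    as an optional eighth statistic.
    """
    h = H.H if isinstance(H, ActivationMatrix) else np.asarray(H)
    features: dict[str, float] = {}
    for i in range(h.shape[0]):
        stats = _seven_stats(h[i, :], include_mean)
        for stat, value in stats.items():
            features[f"c_alpha_f_{stat}_{i + 1}"] = value
    for j in range(h.shape[1]):
        stats = _seven_stats(h[:, j], include_mean)
        for stat, value in stats.items():
            features[f"c_f_alpha_{stat}_{j + 1}"] = value
    return features


def save_basis(path: str, basis: NMFBasis) -> None:
    """Persist a basis as a portable text file with a metadata header."""
    header = f"rank={basis.rank} seed={basis.seed} fit_residual={basis.fit_residual!r} shape={basis.W.shape[0]}x{basis.W.shape[1]}"
    np.savetxt(path, basis.W, header=header)


def load_basis(path: str) -> NMFBasis:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = dict(item.split("=", 1) for item in header.split())
    W = np.loadtxt(path)
    return NMFBasis(
        W=W, rank=int(meta["rank"]), seed=int(meta["seed"]),
        fit_residual=float(meta["fit_residual"]),
    )
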