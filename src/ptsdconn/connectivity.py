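"""From per-run parcel time series to one intrinsic Fisher-z connectome.

The stages mirror a standard intrinsic-connectivity pipeline for task fMRI:
motion/DVARS censoring, nuisance regression (task covariates, Friston-24
motion expansion, tissue signals, per-frame spike regressors), zero-phase
band-pass filtering of the residuals, and Pearson correlation over the
retained frames of all usable runs, Fisher z-transformed.

Filtering is applied after regression with spike regressors so it operates
on a regular temporal grid; censored frames are then excluded when the
correlations are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .atlas import ParcelAtlas
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: Default framewise-displacement censoring threshold (mm).
DEFAULT_FD_THRESHOLD = 0.5
#: Default DVARS threshold, in median-normalised units.
DEFAULT_DVARS_THRESHOLD = 1.5
#: Band edges (Hz) of the intrinsic-fluctuation pass band.
DEFAULT_BAND = (0.009, 0.08)
#: Correlations are clamped to +/- (1 - Z_CLAMP_EPS) before atanh.
Z_CLAMP_EPS = 1e-7


@dataclass
class SubjectRunTimeSeries:
    """One fMRI run: parcel time series plus nuisance ingredients.

    ``data`` is nodes x time; ``motion_params`` is 6 x time (mm/radians);
    ``task_covariates`` is k x time; ``nuisance_signals`` (e.g. eroded
    white-matter and ventricle mean signals) is m x time; ``fd_trace`` is
    framewise displacement in mm with ``fd_trace[0] == 0``.
    """

    subject_id: str
    session: str  # "baseline" | "post"
    run_id: str
    data: np.ndarray
    tr_seconds: float
    motion_params: np.ndarray
    task_covariates: np.ndarray
    nuisance_signals: np.ndarray
    fd_trace: np.ndarray

    def __post_init__(self) -> None:
        t = self.data.shape[1]
        for name in ("motion_params", "task_covariates", "nuisance_signals"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                arr = arr.reshape(0, t)
            if arr.shape[1] != t:
                raise InputError(f"{name} has {arr.shape[1]} frames, data has {t}")
            setattr(self, name, arr)
        self.fd_trace = np.asarray(self.fd_trace, dtype=float)
        if self.fd_trace.shape != (t,):
            raise InputError("fd_trace length must match data frames")
        if np.any(self.fd_trace < 0):
            raise InputError("fd_trace must be nonnegative")
        if not np.isfinite(self.data).all():
            raise InputError("time-series data contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class CensorMask:
    """Boolean retention mask for one run, with the thresholds that made it."""

    retained: np.ndarray
    fd_threshold: float
    dvars_threshold: float
    usable: bool = True

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass
class Connectome:
    """Symmetric Fisher-z connectivity matrix for one subject/session."""

    subject_id: str
    session: str
    z_matrix: np.ndarray
    atlas_id: str
    n_retained_frames: int = 0

    def __post_init__(self) -> None:
        z = np.asarray(self.z_matrix, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise InputError("z_matrix must be square")
        self.z_matrix = z

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle (row-major) edge values."""
        iu, ju = np.triu_indices(self.z_matrix.shape[0], k=1)
        return self.z_matrix[iu, ju]


def dvars(data: np.ndarray) -> np.ndarray:
    """Frame-to-frame RMS signal change; element 0 is NaN (undefined)."""
    d = np.sqrt(np.mean(np.diff(data, axis=1) ** 2, axis=0))
    return np.concatenate(([np.nan], d))


def compute_censor_mask(
    fd_trace: np.ndarray,
    data: np.ndarray,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
    dvars_threshold: float = DEFAULT_DVARS_THRESHOLD,
) -> CensorMask:
    """Flag high-motion frames by FD and median-normalised DVARS.

    A frame is retained iff ``fd <= fd_threshold`` and its DVARS, divided
    by the run's median DVARS, is ``<= dvars_threshold``.  Frame 0 has no
    DVARS and is judged on FD alone.  A run retaining fewer than
    ``max(5, 0.1 * n_timepoints)`` frames is marked unusable.
    """
    if fd_threshold <= 0 or dvars_threshold <= 0:
        raise ConfigurationError("censoring thresholds must be positive")
    fd_trace = np.asarray(fd_trace, dtype=float)
    n = fd_trace.shape[0]
    dv = dvars(np.asarray(data, dtype=float))
    med = np.nanmedian(dv)
    if not np.isfinite(med) or med == 0:
        dv_norm = np.zeros(n)
    else:
        dv_norm = dv / med
    dvars_ok = ~(dv_norm > dvars_threshold)  # NaN (frame 0) -> retained
    retained = (fd_trace <= fd_threshold) & dvars_ok
    usable = retained.sum() >= max(5, int(np.ceil(0.1 * n)))
    if not usable:
        logger.warning(
            "run unusable: only %d/%d frames retained", int(retained.sum()), n
        )
    return CensorMask(
        retained=retained,
        fd_threshold=fd_threshold,
        dvars_threshold=dvars_threshold,
        usable=usable,
    )


def _friston24(motion_params: np.ndarray) -> np.ndarray:
    """Volterra expansion of the 6 realignment parameters.

    [R, R(t-1), R^2, R(t-1)^2]; the lag repeats the first frame so a
    constant trace stays constant (and is later dropped as zero-variance).
    """
    r = motion_params
    lag = np.concatenate([r[:, :1], r[:, :-1]], axis=1)
    return np.vstack([r, lag, r**2, lag**2])


def build_nuisance_design(run: SubjectRunTimeSeries, mask: CensorMask) -> np.ndarray:
    """Assemble the nuisance design matrix (time x columns).

    Columns: intercept, linear drift, task covariates, Friston-24 motion
    set, tissue signals, and one spike indicator per censored frame.
    Columns (other than the intercept) with zero variance on retained
    frames are dropped.
    """
    t = run.n_timepoints
    if mask.retained.shape[0] != t:
        raise InputError("mask and run are not aligned")
    cols = [np.ones(t), np.linspace(-1.0, 1.0, t)]
    blocks = [run.task_covariates, _friston24(run.motion_params), run.nuisance_signals]
    for block in blocks:
        for row in block:
            cols.append(row)
    censored = np.flatnonzero(~mask.retained)
    for fr in censored:
        spike = np.zeros(t)
        spike[fr] = 1.0
        cols.append(spike)
    design = np.column_stack(cols)
    # drop zero-variance columns judged on retained frames; the intercept
    # and the spike indicators (zero on retained frames by construction)
    # are always kept
    ret = design[mask.retained]
    keep = np.ptp(ret, axis=0) > 0
    keep[0] = True
    if len(censored):
        keep[-len(censored) :] = True
    dropped = int((~keep).sum())
    if dropped:
        logger.debug("dropped %d zero-variance design columns", dropped)
    return design[:, keep]


def denoise(run_data: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of every node series against the nuisance design.

    Uses least squares with the minimum-norm convention, so rank-deficient
    designs are handled (with a logged warning) rather than rejected.
    """
    if not (np.isfinite(run_data).all() and np.isfinite(design).all()):
        raise InputError("non-finite values in data or design")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient nuisance design (rank %d < %d columns); "
            "proceeding with minimum-norm least squares",
            rank,
            design.shape[1],
        )
    beta, *_ = np.linalg.lstsq(design, run_data.T, rcond=None)
    return run_data - (design @ beta).T


def bandpass_coeffs(tr_seconds: float, low_hz: float, high_hz: float):
    nyq = 0.5 / tr_seconds
    if not (0 < low_hz < high_hz):
        raise ConfigurationError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ConfigurationError(
            f"high edge {high_hz} Hz >= Nyquist {nyq:.4g} Hz at TR {tr_seconds}s"
        )
    return signal.butter(4, [low_hz, high_hz], btype="band", fs=1.0 / tr_seconds)


def bandpass(
    residuals: np.ndarray,
    tr_seconds: float,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the time axis."""
    b, a = bandpass_coeffs(tr_seconds, low_hz, high_hz)
    flen = max(len(a), len(b))
    if residuals.shape[1] < 3 * flen:
        raise ConfigurationError(
            f"run too short to filter: {residuals.shape[1]} frames < {3 * flen}"
        )
    return signal.filtfilt(b, a, residuals, axis=1)


def preprocess_run(
    run: SubjectRunTimeSeries,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
    dvars_threshold: float = DEFAULT_DVARS_THRESHOLD,
    band: tuple[float, float] = DEFAULT_BAND,
) -> tuple[np.ndarray, CensorMask]:
    """Censor, denoise and filter one run; returns (filtered, mask)."""
    mask = compute_censor_mask(run.fd_trace, run.data, fd_threshold, dvars_threshold)
    design = build_nuisance_design(run, mask)
    resid = denoise(run.data, design)
    filtered = bandpass(resid, run.tr_seconds, *band)
    return filtered, mask


def compute_connectome(
    runs: list[tuple[np.ndarray, CensorMask]],
    atlas: ParcelAtlas,
    subject_id: str = "",
    session: str = "baseline",
) -> Connectome:
    """Correlate node series over the retained frames of all usable runs.

    Node series are z-scored per run on retained frames before
    concatenation, then Pearson-correlated; r is clamped to
    ``1 - 1e-7`` in magnitude and Fisher z-transformed; the diagonal is 0.
    Zero-variance node series have their edges set to 0 with a warning.
    """
    usable = [(d, m) for d, m in runs if m.usable]
    if not usable:
        raise InputError("no usable runs")
    segments = []
    for data, mask in usable:
        if data.shape[0] != atlas.n_nodes:
            raise InputError(
                f"run has {data.shape[0]} nodes, atlas has {atlas.n_nodes}"
            )
        seg = data[:, mask.retained]
        sd = seg.std(axis=1, ddof=0)
        mu = seg.mean(axis=1)
        safe = np.where(sd > 0, sd, 1.0)
        segments.append((seg - mu[:, None]) / safe[:, None])
    cat = np.concatenate(segments, axis=1)
    n_frames = cat.shape[1]

    sd = cat.std(axis=1, ddof=0)
    dead = sd == 0
    if dead.any():
        logger.warning("%d zero-variance node series; their edges set to 0", dead.sum())
    r = np.corrcoef(cat)
    r[np.isnan(r)] = 0.0
    r[dead, :] = 0.0
    r[:, dead] = 0.0
    r = np.clip(r, -(1 - Z_CLAMP_EPS), 1 - Z_CLAMP_EPS)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return Connectome(
        subject_id=subject_id,
        session=session,
        z_matrix=z,
        atlas_id=atlas.atlas_id,
        n_retained_frames=n_frames,
    )
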