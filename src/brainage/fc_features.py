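"""Functional-connectivity features from ROI time series.

Turns ROI×frame signal matrices (or precomputed correlation matrices) into
harmonization-ready feature vectors: framewise motion censoring (FD and
DVARS rules), scan-level QC, Pearson correlation over retained frames,
Fisher z transform, and row-major upper-triangle vectorization with stable
edge names ``roiI__roiJ`` (I < J).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: framewise displacement censoring threshold (mm)
FD_THRESHOLD_MM = 0.3
#: DVARS censoring threshold (SDs above the participant's mean DVARS)
DVARS_THRESHOLD_SD = 2.5
#: scan-level QC: mean FD must be strictly below this (mm)
MEAN_FD_LIMIT_MM = 0.30
#: scan-level QC: retained-frame fraction must strictly exceed this
MIN_RETAINED_FRACTION = 0.5


@dataclass
class RoiTimeseries:
    """One participant's ROI-averaged BOLD series with framewise motion traces."""

    participant_id: str
    data: np.ndarray          # frames × n_roi
    fd: np.ndarray            # mm, per frame
    dvars: np.ndarray         # per frame
    sampling_interval: float = 2.2  # seconds
    # participant-level DVARS baseline; carried across frame subsetting so
    # that the censoring rule always refers to the pre-censoring statistics
    dvars_mean: float | None = None
    dvars_sd: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        n = self.data.shape[0]
        if self.fd.shape != (n,) or self.dvars.shape != (n,):
            raise ValueError("FD/DVARS length must equal the frame count")
        if self.dvars_mean is None:
            self.dvars_mean = float(self.dvars.mean())
            self.dvars_sd = float(self.dvars.std(ddof=0))

    def subset(self, frames) -> "RoiTimeseries":
        """Frame-subset series inheriting this participant's DVARS baseline."""
        idx = np.asarray(frames)
        return RoiTimeseries(self.participant_id, self.data[idx], self.fd[idx],
                             self.dvars[idx], self.sampling_interval,
                             dvars_mean=self.dvars_mean, dvars_sd=self.dvars_sd)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]

    @property
    def mean_fd(self) -> float:
        return float(self.fd.mean())


@dataclass
class ConnectivityFeatures:
    """Fisher-z edge vector for one participant, in fixed upper-triangle order."""

    participant_id: str
    values: np.ndarray
    edge_names: list[str]
    n_roi: int
    frames_retained: float
    mean_fd: float
    qc_pass: bool

    def __post_init__(self) -> None:
        m = self.n_roi * (self.n_roi - 1) // 2
        if self.values.shape != (m,):
            raise ValueError(f"expected {m} edges for {self.n_roi} ROIs, "
                             f"got {self.values.shape}")
        if not np.isfinite(self.values).all():
            bad = np.flatnonzero(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite Fisher z at edge {self.edge_names[bad]}")


def edge_names(n_roi: int) -> list[str]:
    """Row-major upper-triangle edge names, fixed across participants."""
    i, j = np.triu_indices(n_roi, k=1)
    return [f"roi{a + 1}__roi{b + 1}" for a, b in zip(i, j)]


def n_edges(n_roi: int) -> int:
    return n_roi * (n_roi - 1) // 2


def censor_frames(ts: RoiTimeseries,
                  fd_thresh: float = FD_THRESHOLD_MM,
                  dvars_thresh: float = DVARS_THRESHOLD_SD):
    """Framewise censoring: drop frames with FD > ``fd_thresh`` mm or DVARS
    more than ``dvars_thresh`` SDs above the participant's mean DVARS.

    The DVARS mean/SD are computed once over all frames before censoring
    (single pass, not iterative). Returns ``(retained_indices, fraction)``.
    """
    if fd_thresh <= 0 or dvars_thresh <= 0:
        raise ValueError("censoring thresholds must be > 0")
    mu, sd = ts.dvars_mean, ts.dvars_sd
    bad = (ts.fd > fd_thresh) | (ts.dvars > mu + dvars_thresh * sd)
    retained = np.flatnonzero(~bad)
    return retained, retained.size / ts.n_frames


def scan_qc(ts: RoiTimeseries, retained_fraction: float,
            mean_fd_limit: float = MEAN_FD_LIMIT_MM,
            min_retained: float = MIN_RETAINED_FRACTION) -> bool:
    """Scan-level inclusion: mean FD strictly below the limit AND retained
    fraction strictly above the minimum."""
    if not 0 <= retained_fraction <= 1:
        raise ValueError("retained_fraction must be in [0, 1]")
    return (ts.mean_fd < mean_fd_limit) and (retained_fraction > min_retained)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing Fisher transform, z = atanh(r)."""
    return np.arctanh(r)


def correlation_to_features(source: RoiTimeseries | np.ndarray,
                            retained: np.ndarray | None = None,
                            participant_id: str = "",
                            mean_fd: float = float("nan"),
                            frames_retained: float = 1.0,
                            qc_pass: bool = True) -> ConnectivityFeatures:
    """Correlation matrix -> Fisher z -> row-major upper-triangle vector.

    ``source`` is either a :class:`RoiTimeseries` (Pearson correlation is
    computed over the ``retained`` frames, which default to all frames) or a
    precomputed square correlation matrix (must be symmetric with unit
    diagonal and off-diagonal values strictly inside (-1, 1)).
    """
    if isinstance(source, RoiTimeseries):
        idx = np.arange(source.n_frames) if retained is None else np.asarray(retained)
        if idx.size < 3:
            raise ValueError("need >= 3 retained frames to estimate correlations")
        frames = source.data[idx]
        if np.any(frames.std(axis=0) == 0):
            roi = int(np.flatnonzero(frames.std(axis=0) == 0)[0])
            raise ValueError(f"ROI {roi + 1} is constant over retained frames")
        corr = np.corrcoef(frames, rowvar=False)
        pid = source.participant_id
        mean_fd = source.mean_fd
        frames_retained = idx.size / source.n_frames
    else:
        corr = np.asarray(source, dtype=float)
        if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have a unit diagonal")
        pid = participant_id

    n = corr.shape[0]
    names = edge_names(n)
    iu = np.triu_indices(n, k=1)
    r = corr[iu]
    at_limit = np.abs(r) >= 1.0 - 1e-15
    if at_limit.any():
        k = int(np.flatnonzero(at_limit)[0])
        raise ValueError(f"|r| = 1 at edge {names[k]}: Fisher z is infinite")
    return ConnectivityFeatures(
        participant_id=pid, values=fisher_z(r), edge_names=names, n_roi=n,
        frames_retained=float(frames_retained), mean_fd=float(mean_fd),
        qc_pass=bool(qc_pass))


def process_timeseries(ts: RoiTimeseries,
                       fd_thresh: float = FD_THRESHOLD_MM,
                       dvars_thresh: float = DVARS_THRESHOLD_SD) -> ConnectivityFeatures:
    """Censor -> QC -> correlate -> Fisher z for one scan.

    QC failures raise; callers wanting to keep failing scans should call the
    individual steps and inspect ``qc_pass`` themselves.
    """
    retained, frac = censor_frames(ts, fd_thresh, dvars_thresh)
    if retained.size == 0:
        raise ValueError(f"{ts.participant_id}: all frames censored")
    ok = scan_qc(ts, frac)
    if not ok:
        raise ValueError(f"{ts.participant_id}: failed scan QC "
                         f"(mean FD {ts.mean_fd:.3f} mm, retained {frac:.2f})")
    return correlation_to_features(ts, retained)


def read_timeseries(signal_path: str | Path, motion_path: str | Path,
                    participant_id: str = "",
                    sampling_interval: float = 2.2) -> RoiTimeseries:
    """Read a frames × ROI delimited matrix plus a (frame, fd, dvars) sidecar."""
    data = pd.read_csv(signal_path, sep="\t").to_numpy(dtype=float)
    motion = pd.read_csv(motion_path, sep="\t")
    return RoiTimeseries(participant_id or Path(signal_path).stem, data,
                         motion["fd"].to_numpy(), motion["dvars"].to_numpy(),
                         sampling_interval)


def features_to_frame(feats: list[ConnectivityFeatures]) -> pd.DataFrame:
    """Stack per-participant edge vectors into a participants × edges table."""
    if not feats:
        raise ValueError("no feature vectors given")
    names = feats[0].edge_names
    for f in feats[1:]:
        if f.edge_names != names:
            raise ValueError("inconsistent edge order across participants")
    return pd.DataFrame([f.values for f in feats],
                        index=pd.Index([f.participant_id for f in feats], name="id"),
                        columns=names)
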