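"""Functional network construction from ROI time-series and trial timing.

The pipeline mirrors standard task-fMRI practice for short memory tasks:
zero-phase high-pass filtering of each ROI's signal (removing slow scanner
drift), concatenation of the task-phase windows across trials (dropping
incorrect trials), and a Spearman correlation matrix between all ROI pairs.
Two phase windows are used downstream as multiplex layers: ``encmaint``
(encoding plus maintenance) and ``probe`` (shifted +2 s to reduce overlap
with the preceding window and catch the hemodynamic peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .graph import GraphError, WeightedNetwork


class ConnectivityError(ValueError):
    pass


TRIAL_COLUMNS = [
    "trial_id",
    "encoding_onset",
    "encoding_duration",
    "maintenance_duration",
    "probe_onset",
    "probe_duration",
    "correct",
]


@dataclass
class RoiTimeSeries:
    """ROI x time signal matrix with its sampling rate in Hz."""

    roi_labels: list
    data: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.roi_labels = list(self.roi_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConnectivityError("data must be an N x T matrix")
        if len(self.roi_labels) != self.data.shape[0]:
            raise ConnectivityError(
                f"{len(self.roi_labels)} labels for {self.data.shape[0]} rows"
            )
        if self.data.shape[1] < 2:
            raise ConnectivityError("need at least two samples per ROI")
        if self.sampling_rate <= 0:
            raise ConnectivityError("sampling_rate must be positive")
        if np.isnan(self.data).any():
            raise ConnectivityError("time-series contain NaN")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def tr(self) -> float:
        """Repetition time (s per volume)."""
        return 1.0 / self.sampling_rate


@dataclass
class PhaseSpec:
    """Defines how a task-phase window is read off the trial table.

    ``onset_column`` names the trial column holding the window onset (s);
    ``duration_columns`` are summed to give the window length;
    ``onset_shift`` (s) is added to the onset before selecting volumes.
    """

    name: str
    onset_column: str
    duration_columns: tuple
    onset_shift: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.onset_shift):
            raise ConnectivityError("onset_shift must be finite")

    @classmethod
    def encmaint(cls) -> "PhaseSpec":
        """Encoding + maintenance as one window, no shift."""
        return cls(
            name="encmaint",
            onset_column="encoding_onset",
            duration_columns=("encoding_duration", "maintenance_duration"),
            onset_shift=0.0,
        )

    @classmethod
    def probe(cls, shift: float = 2.0) -> "PhaseSpec":
        """Probe window shifted forward (default +2 s)."""
        return cls(
            name="probe",
            onset_column="probe_onset",
            duration_columns=("probe_duration",),
            onset_shift=shift,
        )


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ConnectivityError(f"trial table missing columns: {missing}")
    dur_cols = ["encoding_duration", "maintenance_duration", "probe_duration"]
    if (trials[dur_cols] <= 0).any().any():
        raise ConnectivityError("trial durations must be positive")
    onsets = trials["encoding_onset"].to_numpy()
    if np.any(np.diff(onsets) < 0):
        raise ConnectivityError("trial onsets must be nondecreasing")
    return trials


def highpass_filter(ts: RoiTimeSeries, cutoff: float = 0.06, order: int = 4) -> RoiTimeSeries:
    """Zero-phase Butterworth high-pass filter applied per ROI.

    Forward-backward filtering (filtfilt) avoids phase distortion of the
    short task windows; the DC component is removed exactly.
    """
    nyquist = ts.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ConnectivityError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    if cutoff <= 0:
        raise ConnectivityError("cutoff must be positive")
    sos = _signal.butter(order, cutoff, btype="highpass", fs=ts.sampling_rate,
                         output="sos")
    filtered = _signal.sosfiltfilt(sos, ts.data, axis=1)
    filtered = filtered - filtered.mean(axis=1, keepdims=True)
    return RoiTimeSeries(ts.roi_labels, filtered, ts.sampling_rate)


def _window_volumes(ts: RoiTimeSeries, start: float, end: float) -> np.ndarray:
    """Indices of volumes whose acquisition midpoint falls in [start, end)."""
    tr = ts.tr
    mid = (np.arange(ts.n_samples) + 0.5) * tr
    return np.flatnonzero((mid >= start) & (mid < end))


def extract_phase_series(
    ts: RoiTimeSeries,
    trials: pd.DataFrame,
    spec: PhaseSpec,
    correct_only: bool = True,
) -> RoiTimeSeries:
    """Concatenate the phase windows of all (correct) trials, in trial order.

    A volume belongs to a window when its acquisition midpoint lies in the
    half-open interval [onset + shift, onset + shift + duration).
    """
    trials = validate_trials(trials)
    if correct_only:
        trials = trials[trials["correct"].astype(bool)]
        if len(trials) == 0:
            raise ConnectivityError("no correct trials survive the selection")
    recording_end = ts.n_samples * ts.tr
    chunks = []
    for _, row in trials.iterrows():
        start = float(row[spec.onset_column]) + spec.onset_shift
        duration = float(sum(row[c] for c in spec.duration_columns))
        end = start + duration
        if end > recording_end + 1e-9:
            raise ConnectivityError(
                f"trial {row['trial_id']}: window [{start}, {end}) s exceeds the "
                f"recording end at {recording_end} s"
            )
        idx = _window_volumes(ts, start, end)
        chunks.append(ts.data[:, idx])
    if not chunks:
        raise ConnectivityError("no trials to extract")
    return RoiTimeSeries(ts.roi_labels, np.concatenate(chunks, axis=1), ts.sampling_rate)


def spearman_network(ts: RoiTimeSeries, absolute: bool = True) -> WeightedNetwork:
    """Spearman rank-correlation network between all ROI pairs.

    Ties get average ranks.  With ``absolute`` (default) the entries are
    |rho|, the convention used before modularity maximization, which treats
    negative weights as equal to positive ones.  Constant ROI series make
    the correlation undefined and raise, naming the offending ROIs.
    """
    if ts.n_samples < 3:
        raise ConnectivityError("need at least 3 samples for a rank correlation")
    constant = np.flatnonzero(np.ptp(ts.data, axis=1) == 0)
    if constant.size:
        names = [ts.roi_labels[i] for i in constant]
        raise ConnectivityError(
            f"constant ROI series make Spearman undefined: {names}"
        )
    rho = np.asarray(_stats.spearmanr(ts.data, axis=1).statistic, dtype=float)
    if rho.ndim == 0:  # scipy returns a scalar for exactly two variables
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    if absolute:
        rho = np.abs(rho)
    np.fill_diagonal(rho, 0.0)
    return WeightedNetwork(ts.roi_labels, rho)


def phase_networks(
    ts: RoiTimeSeries,
    trials: pd.DataFrame,
    specs=None,
    cutoff: float = 0.06,
    correct_only: bool = True,
    absolute: bool = True,
):
    """Filter, window and correlate: one WeightedNetwork per phase spec.

    Default specs are ``encmaint`` and ``probe`` — the two layers of the
    task multiplex network.
    """
    if specs is None:
        specs = [PhaseSpec.encmaint(), PhaseSpec.probe()]
    filtered = highpass_filter(ts, cutoff)
    nets = {}
    for spec in specs:
        phase_ts = extract_phase_series(filtered, trials, spec, correct_only)
        nets[spec.name] = spearman_network(phase_ts, absolute=absolute)
    return nets
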