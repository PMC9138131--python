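"""EMG filtering, IMU smoothing, and aligned sliding-window segmentation.

EMG is band-pass filtered (5th-order Butterworth, 20-450 Hz) to suppress
motion artifact and high-frequency noise, then notch filtered at 50 Hz for
power-line interference.  IMU channels are smoothed with a centered moving
average.  Both streams are then cut into 150 ms analysis windows advanced
in 50 ms steps (100 ms overlap), with EMG and IMU windows sharing start
times so each window describes one time span at both sampling rates.

Filtering is zero-phase (forward-backward) and applied once per recording
before segmentation, so window contents do not depend on segmentation
order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt, iirnotch, sosfiltfilt

from emgrasp.simulate import RawRecording

BANDPASS_LOW_HZ = 20.0
BANDPASS_HIGH_HZ = 450.0
BANDPASS_ORDER = 5
NOTCH_HZ = 50.0
NOTCH_Q = 30.0
WINDOW_S = 0.150
STEP_S = 0.050
DEFAULT_IMU_SMOOTH = 5


@dataclass
class SessionWindow:
    """One 150 ms analysis window: 6 x N EMG samples and 6 x M IMU samples."""

    emg: np.ndarray
    imu: np.ndarray
    subject: int
    grasp: str
    position: str
    rep: int
    index: int


def _check_rate(rate: float) -> None:
    # the 450 Hz band edge must sit below Nyquist
    if rate <= 2 * BANDPASS_HIGH_HZ:
        raise ValueError(
            f"sampling rate {rate} Hz too low for a {BANDPASS_HIGH_HZ} Hz "
            "band edge (need > 900 Hz)")


def bandpass_emg(signal: np.ndarray, rate: float) -> np.ndarray:
    """5th-order Butterworth band-pass 20-450 Hz, zero-phase."""
    _check_rate(rate)
    sos = butter(BANDPASS_ORDER, [BANDPASS_LOW_HZ, BANDPASS_HIGH_HZ],
                 btype="bandpass", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def notch_emg(signal: np.ndarray, rate: float) -> np.ndarray:
    """Narrow 50 Hz notch (2nd-order IIR, Q=30), zero-phase."""
    _check_rate(rate)
    b, a = iirnotch(NOTCH_HZ, NOTCH_Q, fs=rate)
    return filtfilt(b, a, np.asarray(signal, dtype=float), axis=-1)


def smooth_imu(signal: np.ndarray, window_len: int = DEFAULT_IMU_SMOOTH) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at edges."""
    if window_len < 1 or window_len % 2 == 0:
        raise ValueError(f"window_len must be odd and positive, got {window_len}")
    x = np.asarray(signal, dtype=float)
    if window_len == 1:
        return x.copy()
    half = window_len // 2
    n = x.shape[-1]
    csum = np.cumsum(np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (np.take(csum, hi, axis=-1) - np.take(csum, lo, axis=-1)) / (hi - lo)


def preprocess_recording(recording: RawRecording,
                         imu_smooth: int = DEFAULT_IMU_SMOOTH) -> RawRecording:
    """Apply band-pass + notch to EMG and the moving average to IMU."""
    emg = notch_emg(bandpass_emg(recording.emg, recording.emg_rate),
                    recording.emg_rate)
    imu = smooth_imu(recording.imu, imu_smooth)
    return replace(recording, emg=emg, imu=imu)


def segment(recording: RawRecording, win_s: float = WINDOW_S,
            step_s: float = STEP_S) -> list[SessionWindow]:
    """Cut one recording into aligned EMG/IMU sliding windows.

    Window/step lengths in samples are round(t * rate) per stream
    (1024 Hz -> N=154, step 51; 60 Hz -> M=9, step 3); windows are emitted
    while they fit inside both streams, which for a 2 s trial yields 38
    windows.
    """
    if recording.duration < win_s:
        raise ValueError(
            f"recording of {recording.duration:.3f} s is shorter than one "
            f"{win_s:.3f} s window")
    n_emg = int(round(win_s * recording.emg_rate))
    step_emg = int(round(step_s * recording.emg_rate))
    n_imu = int(round(win_s * recording.imu_rate))
    step_imu = int(round(step_s * recording.imu_rate))

    count_emg = (recording.emg.shape[1] - n_emg) // step_emg + 1
    count_imu = (recording.imu.shape[1] - n_imu) // step_imu + 1
    count = min(count_emg, count_imu)

    windows = []
    for k in range(count):
        windows.append(SessionWindow(
            emg=recording.emg[:, k * step_emg:k * step_emg + n_emg],
            imu=recording.imu[:, k * step_imu:k * step_imu + n_imu],
            subject=recording.subject, grasp=recording.grasp,
            position=recording.position, rep=recording.rep, index=k))
    return windows


def preprocess_and_segment(recordings: list[RawRecording],
                           imu_smooth: int = DEFAULT_IMU_SMOOTH,
                           win_s: float = WINDOW_S, step_s: float = STEP_S,
                           window_stride: int = 1) -> list[SessionWindow]:
    """Filter then segment every recording; optionally keep every
    ``window_stride``-th window (adjacent windows overlap by 100 ms and are
    highly redundant, so a stride > 1 is a cheap way to thin a dataset)."""
    out: list[SessionWindow] = []
    for rec in recordings:
        wins = segment(preprocess_recording(rec, imu_smooth), win_s, step_s)
        out.extend(wins[::window_stride])
    return out
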