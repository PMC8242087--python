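"""Raw tri-channel records -> fixed-length ECG-PPG difference windows.

Pipeline stages, in execution order: artifact sanitization (sentinels and
dead zero-runs repaired by linear interpolation), zero-phase Butterworth
band-pass filtering (2-20 Hz for ECG, 0.5-20 Hz for PPG; ABP is left in
mmHg), Pan-Tompkins-style R-peak detection, two-cycle beat segmentation
[R(n-1), R(n+1)), per-sequence min-max scaling to [-1, 1], the ECG-PPG
difference feature, zero post-padding to 250 samples, and SBP/DBP label
extraction as the mean of systolic peaks / diastolic troughs of the ABP
segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import PhysioRecord

__all__ = [
    "FilterSpec",
    "ECG_FILTER",
    "PPG_FILTER",
    "SequenceWindow",
    "SanitizeReport",
    "sanitize",
    "bandpass",
    "detect_r_peaks",
    "segment",
    "minmax_scale",
    "difference",
    "pad_to_fixed",
    "extract_bp_labels",
    "build_dataset",
    "windows_to_frame",
    "frame_to_windows",
    "save_windows",
    "load_windows",
]

logger = logging.getLogger(__name__)

#: Fixed model input length (two cardiac cycles at 125 Hz, padded).
TARGET_LEN = 250

#: Magnitude at or above which a sample counts as a sentinel.
SENTINEL_ABS = 1e6

#: Minimum run length of exact zeros treated as a dead signal segment.
ZERO_RUN = 8

#: A channel with more than this corrupt fraction is unusable.
MAX_CORRUPT_FRAC = 0.2


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification (low/high edges in Hz, Butterworth order)."""

    low_hz: float
    high_hz: float
    order: int = 4
    kind: str = "band-pass"

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz < fs / 2:
            raise ValueError(
                f"need 0 < low_hz < high_hz < fs/2; got "
                f"({self.low_hz}, {self.high_hz}) at fs={fs}"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")


ECG_FILTER = FilterSpec(2.0, 20.0)
PPG_FILTER = FilterSpec(0.5, 20.0)


@dataclass
class SequenceWindow:
    """One model input: a 250-sample difference sequence with its labels."""

    diff: np.ndarray
    sbp_label: float
    dbp_label: float
    source_beat: int
    valid: bool = True


@dataclass
class SanitizeReport:
    """Outcome of sanitizing one channel."""

    repaired: list[tuple[int, int]] = field(default_factory=list)
    n_corrupt: int = 0
    usable: bool = True


def _corrupt_mask(x: np.ndarray) -> np.ndarray:
    mask = ~np.isfinite(x) | (np.abs(x) >= SENTINEL_ABS)
    # dead segments: runs of >= ZERO_RUN consecutive exact zeros
    z = (x == 0.0) & ~mask
    if z.any():
        edges = np.diff(np.concatenate([[0], z.view(np.int8), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            if e - s >= ZERO_RUN:
                mask[s:e] = True
    return mask


def _mask_ranges(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [(int(s), int(e - 1)) for s, e in zip(starts, ends)]


def sanitize(x: np.ndarray) -> tuple[np.ndarray, SanitizeReport]:
    """Repair sentinel samples and dead zero-runs by linear interpolation.

    Samples with magnitude >= 1e6 (e.g. the -2,147,483,648 sentinel), any
    non-finite values, and runs of >= 8 consecutive exact zeros are replaced
    by linear interpolation from the nearest clean neighbours (edge values
    are held). A channel with more than 20% corrupt samples is additionally
    flagged unusable (still repaired, so callers can inspect it); an
    all-corrupt channel is returned as-is with the unusable flag.
    """
    x = np.asarray(x, dtype=float)
    mask = _corrupt_mask(x)
    report = SanitizeReport(n_corrupt=int(mask.sum()))
    if report.n_corrupt == 0:
        return x.copy(), report
    report.repaired = _mask_ranges(mask)
    if report.n_corrupt > MAX_CORRUPT_FRAC * x.size:
        report.usable = False
    if report.n_corrupt == x.size:
        return x.copy(), report
    out = x.copy()
    good = np.flatnonzero(~mask)
    bad = np.flatnonzero(mask)
    out[bad] = np.interp(bad, good, x[good])
    return out, report


def bandpass(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass; removes DC and baseline wander."""
    spec.validate(fs)
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz],
                     btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def detect_r_peaks(ecg: np.ndarray, fs: float, refractory_s: float = 0.2) -> np.ndarray:
    """Pan-Tompkins-style QRS detection on a filtered ECG.

    Derivative -> squaring -> 150 ms moving-window integration -> threshold
    at a fraction of the upper envelope -> refine each detection to the local
    ECG maximum, with a 200 ms refractory period. Returns strictly increasing
    sample indices (empty for flat signals).
    """
    ecg = np.asarray(ecg, dtype=float)
    n = ecg.size
    if n < int(0.5 * fs):
        return np.array([], dtype=int)
    # five-point derivative (slope emphasised), then energy
    deriv = np.convolve(ecg, np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0),
                        mode="same")
    energy = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(energy, np.ones(win) / win, mode="same")
    if mwi.max() <= 0:
        return np.array([], dtype=int)
    refr = max(1, int(round(refractory_s * fs)))
    thr = 0.25 * np.percentile(mwi, 98)
    if thr <= 0:
        return np.array([], dtype=int)
    cand, _ = sps.find_peaks(mwi, height=thr, distance=refr)
    if cand.size == 0:
        return np.array([], dtype=int)
    # refine to the R wave: local ECG maximum within +-100 ms
    half = int(round(0.100 * fs))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(n, c + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    peaks = np.array(sorted(set(refined)), dtype=int)
    # enforce refractory after refinement, keeping the larger R amplitude
    keep: list[int] = []
    for p in peaks:
        if keep and p - keep[-1] < refr:
            if ecg[p] > ecg[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return np.array(keep, dtype=int)


def segment(
    record: PhysioRecord, r_peaks: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Two-cycle triples [R(n-1), R(n+1)) for every interior peak n.

    K detected peaks yield K-2 aligned (ecg, ppg, abp) slices; indices are
    0-based and windows half-open.
    """
    r = np.asarray(r_peaks, dtype=int)
    if r.size < 3:
        raise ValueError(
            f"segmentation needs >= 3 R-peaks, got {r.size}"
        )
    if not (np.diff(r) > 0).all():
        raise ValueError("r_peaks must be strictly increasing")
    out = []
    for n in range(1, r.size - 1):
        a, b = r[n - 1], r[n + 1]
        out.append((record.ecg[a:b].copy(),
                    record.ppg[a:b].copy(),
                    record.abp[a:b].copy()))
    return out


def minmax_scale(seq: np.ndarray) -> np.ndarray:
    """Affine map of a sequence onto [-1, +1]; constant input maps to zeros."""
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0:
        raise ValueError("cannot scale an empty sequence")
    lo, hi = seq.min(), seq.max()
    if hi == lo:
        return np.zeros_like(seq)
    return 2.0 * (seq - lo) / (hi - lo) - 1.0


def difference(ecg_scaled: np.ndarray, ppg_scaled: np.ndarray) -> np.ndarray:
    """Elementwise ECG minus PPG — the model's input feature."""
    ecg_scaled = np.asarray(ecg_scaled, dtype=float)
    ppg_scaled = np.asarray(ppg_scaled, dtype=float)
    if ecg_scaled.shape != ppg_scaled.shape:
        raise ValueError(
            f"length mismatch: {ecg_scaled.shape} vs {ppg_scaled.shape}"
        )
    return ecg_scaled - ppg_scaled


def pad_to_fixed(seq: np.ndarray, target_len: int = TARGET_LEN) -> tuple[np.ndarray, bool]:
    """Post-pad with zeros to ``target_len``; longer sequences are invalid.

    Returns (sequence, valid). Two-cycle windows exceeding 250 samples
    (RR pairs longer than 2 s at 125 Hz) cannot fit the fixed input layer
    without truncating the second beat, so they are rejected rather than cut.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.size > target_len:
        return seq, False
    if seq.size == target_len:
        return seq.copy(), True
    return np.concatenate([seq, np.zeros(target_len - seq.size)]), True


def extract_bp_labels(
    abp_seq: np.ndarray, fs: float = 125.0
) -> Optional[tuple[float, float]]:
    """Mean systolic-peak and diastolic-trough values of an ABP segment.

    Systolic peaks are local maxima separated by >= 250 ms with prominence
    at least 25% of the segment's range; the diastolic troughs are the
    minima between consecutive peaks (plus the lead-in/tail minima when they
    are interior, i.e. not segment-edge artifacts). Returns (sbp, dbp) in
    mmHg, or None when the segment has no usable extrema or sbp <= dbp.
    """
    abp_seq = np.asarray(abp_seq, dtype=float)
    if abp_seq.size < 3:
        return None
    rng = float(np.ptp(abp_seq))
    if rng <= 0:
        return None
    dist = max(1, int(round(0.25 * fs)))
    peaks, _ = sps.find_peaks(abp_seq, distance=dist, prominence=0.25 * rng)
    if peaks.size == 0:
        return None
    trough_vals = []
    bounds = np.concatenate([[0], peaks, [abp_seq.size - 1]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            continue
        j = a + int(np.argmin(abp_seq[a:b + 1]))
        if j in (a, b) and (a == 0 or b == abp_seq.size - 1):
            continue  # monotone edge interval, not a real trough
        trough_vals.append(abp_seq[j])
    if not trough_vals:
        return None
    sbp = float(abp_seq[peaks].mean())
    dbp = float(np.mean(trough_vals))
    if sbp <= dbp:
        return None
    return sbp, dbp


def build_dataset(
    record: PhysioRecord,
    crop_samples: Optional[int] = None,
    seed: Optional[int] = None,
    ecg_filter: FilterSpec = ECG_FILTER,
    ppg_filter: FilterSpec = PPG_FILTER,
    sign: int = +1,
) -> list[SequenceWindow]:
    """Full preprocessing of one record into valid SequenceWindows.

    sanitize -> band-pass (ECG 2-20 Hz, PPG 0.5-20 Hz; ABP kept in mmHg) ->
    R-peak detection -> [R(n-1), R(n+1)) segmentation -> per-sequence min-max
    scaling -> ECG-PPG difference (``sign=-1`` flips the orientation) ->
    zero padding to 250 -> SBP/DBP labels. Only valid windows are returned;
    an unusable record yields an empty list with a logged reason.

    ``crop_samples`` (e.g. 6000 = 48 s at 125 Hz) takes one seeded random
    contiguous crop of the record before processing.
    """
    rec = record
    if crop_samples is not None and record.n_samples > crop_samples:
        rng = np.random.default_rng(seed)
        start = int(rng.integers(0, record.n_samples - crop_samples + 1))
        rec = PhysioRecord(
            ecg=record.ecg[start:start + crop_samples].copy(),
            ppg=record.ppg[start:start + crop_samples].copy(),
            abp=record.abp[start:start + crop_samples].copy(),
            fs=record.fs,
        )

    channels = {}
    for name in ("ecg", "ppg", "abp"):
        clean, rep = sanitize(getattr(rec, name))
        if not rep.usable:
            logger.warning(
                "record unusable: %s channel %.1f%% corrupt",
                name, 100.0 * rep.n_corrupt / max(1, clean.size),
            )
            return []
        channels[name] = clean

    fs = rec.fs
    ecg_f = bandpass(channels["ecg"], ecg_filter, fs)
    ppg_f = bandpass(channels["ppg"], ppg_filter, fs)
    clean_rec = PhysioRecord(ecg=ecg_f, ppg=ppg_f, abp=channels["abp"], fs=fs)

    r_peaks = detect_r_peaks(ecg_f, fs)
    if r_peaks.size < 3:
        logger.warning("record unusable: %d R-peaks detected", r_peaks.size)
        return []

    windows: list[SequenceWindow] = []
    for i, (e_seq, p_seq, a_seq) in enumerate(segment(clean_rec, r_peaks)):
        beat = i + 1  # interior peak index n
        diff = difference(minmax_scale(e_seq), minmax_scale(p_seq)) * sign
        diff, ok = pad_to_fixed(diff)
        if not ok:
            continue
        labels = extract_bp_labels(a_seq, fs)
        if labels is None:
            continue
        sbp, dbp = labels
        windows.append(SequenceWindow(diff=diff, sbp_label=sbp,
                                      dbp_label=dbp, source_beat=beat))
    return windows


# ---------------------------------------------------------------------------
# Columnar window serialization (one row = 250 diff values + labels + meta)
# ---------------------------------------------------------------------------

def windows_to_frame(windows: list[SequenceWindow]) -> pd.DataFrame:
    cols = {f"d{i:03d}": np.array([w.diff[i] for w in windows])
            for i in range(TARGET_LEN)}
    cols["sbp"] = np.array([w.sbp_label for w in windows])
    cols["dbp"] = np.array([w.dbp_label for w in windows])
    cols["source_beat"] = np.array([w.source_beat for w in windows])
    return pd.DataFrame(cols)


def frame_to_windows(df: pd.DataFrame) -> list[SequenceWindow]:
    dcols = [f"d{i:03d}" for i in range(TARGET_LEN)]
    diffs = df[dcols].to_numpy(dtype=float)
    return [
        SequenceWindow(diff=diffs[i], sbp_label=float(df["sbp"].iloc[i]),
                       dbp_label=float(df["dbp"].iloc[i]),
                       source_beat=int(df["source_beat"].iloc[i]))
        for i in range(len(df))
    ]


def save_windows(windows: list[SequenceWindow], path) -> None:
    df = windows_to_frame(windows)
    if str(path).endswith(".parquet"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.9g")


def load_windows(path) -> list[SequenceWindow]:
    if str(path).endswith(".parquet"):
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    return frame_to_windows(df)
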