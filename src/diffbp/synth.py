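"""Synthetic coupled ECG/PPG/ABP records with a known PAT-BP relationship.

Generates tri-channel physiological records in which the pulse arrival time
(PAT, R-peak to PPG systolic peak) is tied to beatwise systolic pressure by a
controllable linear coupling, so that every downstream stage — filtering,
R-peak detection, beat segmentation, label extraction, model training — can be
tested against exact ground truth without any external dataset.

Morphology choices (deliberately simple; only features consumed downstream are
guaranteed):

* ECG: one sum-of-Gaussians PQRST complex per beat, dominant R wave at the
  truth ``r_peak_index``.
* PPG: a single-peaked raised-cosine pulse whose systolic peak lags the beat's
  R peak by the beat's PAT (electromechanical delay folded into PAT).
* ABP: the same pulse family rescaled per beat so that the systolic maximum
  equals the beat's SBP and the diastolic trough just before the upstroke
  equals its DBP — both attained exactly on noise-free records.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SENTINEL",
    "SynthConfig",
    "BeatTruth",
    "PhysioRecord",
    "generate_record",
    "inject_artifacts",
    "write_record_csv",
    "read_record_csv",
]

#: Sentinel value observed in corrupted ABP streams of monitor databases.
SENTINEL = -2_147_483_648

# PQRST template: (amplitude [a.u.], offset from R [s], Gaussian width [s])
_ECG_WAVES = (
    (0.12, -0.22, 0.040),   # P
    (-0.15, -0.035, 0.012),  # Q
    (1.00, 0.000, 0.018),   # R
    (-0.22, 0.035, 0.014),  # S
    (0.35, 0.28, 0.070),    # T
)

#: Systolic upstroke duration: trough-to-peak time of the pulse pulses [s].
_RISE_S = 0.15


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic record.

    The blood-pressure population follows the beatwise distribution of the
    ICU monitoring data the pipeline targets: SBP ~ N(sbp_mean, sbp_sd)
    truncated to ``sbp_range`` and DBP likewise, at 125 Hz sampling.
    The PAT coupling is ``pat = pat_intercept + emd + pat_slope * (sbp_ref -
    SBP_beat) + N(0, pat_noise_sd)``; with ``pat_noise_sd > 0`` the beatwise
    SBP is an affine function of PAT plus noise of standard deviation
    ``pat_noise_sd / pat_slope`` mmHg.

    When ``pp_mean`` is set, DBP is generated as SBP minus a pulse pressure
    drawn from N(pp_mean, pp_sd) instead of independently, giving a DBP that
    is itself predictable from PAT.
    """

    seed: int = 0
    fs: float = 125.0
    n_beats: int = 60
    hr_mean: float = 75.0
    hr_sd: float = 5.0
    sbp_mean: float = 119.2
    sbp_sd: float = 10.0
    dbp_mean: float = 70.8
    dbp_sd: float = 7.0
    sbp_range: tuple[float, float] = (94.0, 147.0)
    dbp_range: tuple[float, float] = (56.0, 92.0)
    pat_intercept: float = 0.28
    pat_slope: float = 0.002
    sbp_ref: float = 120.0
    emd: float = 0.0
    pat_noise_sd: float = 0.0
    noise_sd: float = 0.02
    wander_amp: float = 0.05
    wander_freq: float = 0.33
    artifact_rate: float = 0.01
    pp_mean: Optional[float] = None
    pp_sd: float = 0.0
    #: explicit per-beat overrides (length n_beats); None -> random draws
    sbp_values: Optional[Sequence[float]] = None
    dbp_values: Optional[Sequence[float]] = None
    hr_values: Optional[Sequence[float]] = None

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.n_beats < 3:
            raise ValueError(f"n_beats must be >= 3, got {self.n_beats}")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError(
                f"artifact_rate must be in [0, 1), got {self.artifact_rate}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = self.sbp_range
        for s in (lo, hi):
            pat = self.pat_intercept + self.emd + self.pat_slope * (self.sbp_ref - s)
            if pat <= 0:
                raise ValueError(
                    "pat_intercept/pat_slope give non-positive PAT at "
                    f"SBP={s} mmHg (pat={pat:.4f} s)"
                )
        for name, vals in (
            ("sbp_values", self.sbp_values),
            ("dbp_values", self.dbp_values),
            ("hr_values", self.hr_values),
        ):
            if vals is not None and len(vals) != self.n_beats:
                raise ValueError(f"{name} must have length n_beats={self.n_beats}")


@dataclass(frozen=True)
class BeatTruth:
    """Ground truth for one generated beat."""

    r_peak_index: int     # sample index of the R wave
    sbp: float            # mmHg, systolic maximum of this beat's ABP pulse
    dbp: float            # mmHg, diastolic trough preceding the upstroke
    pat: float            # s, realized R-to-PPG-systolic-peak lag
    rr: float             # s, interval to the next R peak


@dataclass
class PhysioRecord:
    """Synchronously sampled ECG/PPG/ABP triple at a common rate."""

    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    fs: float
    truth: Optional[list[BeatTruth]] = None

    def __post_init__(self) -> None:
        if not (len(self.ecg) == len(self.ppg) == len(self.abp)):
            raise ValueError("ecg, ppg and abp must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    def copy(self) -> "PhysioRecord":
        return PhysioRecord(
            self.ecg.copy(), self.ppg.copy(), self.abp.copy(), self.fs,
            None if self.truth is None else list(self.truth),
        )


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Gaussian draws redrawn into [lo, hi] (falls back to clip)."""
    x = rng.normal(mean, sd, size)
    for _ in range(20):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(x, lo, hi)


def _pulse_shape(n_rise: int, n_fall: int) -> np.ndarray:
    """Raised-cosine pulse over n_rise + n_fall samples, 0 at both ends and 1
    at index n_rise; single interior maximum."""
    up = 0.5 - 0.5 * np.cos(np.pi * np.arange(n_rise) / n_rise)
    down = 0.5 + 0.5 * np.cos(np.pi * np.arange(n_fall + 1) / n_fall)
    return np.concatenate([up, down])


def generate_record(config: SynthConfig) -> PhysioRecord:
    """Generate one coupled ECG/PPG/ABP record.

    Identical configs (including seed) yield bit-identical records. The
    returned record's ``truth`` holds the realized (sample-grid) beat values;
    on a noise-free record per-beat ABP extrema match truth exactly and the
    PPG systolic peak sits exactly ``pat`` after the R peak.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs, nb = config.fs, config.n_beats

    # Beatwise draws -------------------------------------------------------
    if config.hr_values is not None:
        hr = np.asarray(config.hr_values, dtype=float)
    else:
        hr = _truncnorm(rng, config.hr_mean, config.hr_sd, 40.0, 180.0, nb)
    rr_s = 60.0 / hr

    if config.sbp_values is not None:
        sbp = np.asarray(config.sbp_values, dtype=float)
    else:
        sbp = _truncnorm(rng, config.sbp_mean, config.sbp_sd,
                         config.sbp_range[0], config.sbp_range[1], nb)
    if config.dbp_values is not None:
        dbp = np.asarray(config.dbp_values, dtype=float)
    elif config.pp_mean is not None:
        pp = np.maximum(rng.normal(config.pp_mean, config.pp_sd, nb), 15.0)
        dbp = sbp - pp
    else:
        dbp = _truncnorm(rng, config.dbp_mean, config.dbp_sd,
                         config.dbp_range[0], config.dbp_range[1], nb)
    # keep a physiological pulse pressure
    dbp = np.minimum(dbp, sbp - 15.0)
    if not (sbp > dbp).all():
        raise ValueError("generated sbp must exceed dbp for every beat")

    pat = (config.pat_intercept + config.emd
           + config.pat_slope * (config.sbp_ref - sbp))
    if config.pat_noise_sd > 0:
        pat = pat + rng.normal(0.0, config.pat_noise_sd, nb)
    if not (pat > 0).all():
        raise ValueError("PAT must stay positive for all generated beats")

    # Sample-grid geometry -------------------------------------------------
    r_idx = np.empty(nb, dtype=int)
    r_idx[0] = int(round(0.45 * fs))
    rr_samp = np.round(rr_s * fs).astype(int)
    for k in range(1, nb):
        r_idx[k] = r_idx[k - 1] + rr_samp[k - 1]
    p_idx = r_idx + np.round(pat * fs).astype(int)      # systolic peaks
    rise = int(round(_RISE_S * fs))
    t_idx = p_idx - rise                                # diastolic troughs
    # virtual trough closing the last beat
    t_end = p_idx[-1] + rr_samp[-1] - rise
    n = int(t_end + rise + int(round(0.45 * fs)))
    t = np.arange(n) / fs

    # ECG ------------------------------------------------------------------
    ecg = np.zeros(n)
    for k in range(nb):
        for amp, mu, sig in _ECG_WAVES:
            center = r_idx[k] / fs + mu
            lo = max(0, int((center - 5 * sig) * fs))
            hi = min(n, int((center + 5 * sig) * fs) + 1)
            if lo < hi:
                ecg[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / sig) ** 2)

    # PPG and ABP, trough-to-trough segments -------------------------------
    ppg = np.zeros(n)
    abp = np.empty(n)
    # lead-in: falling tail of a virtual preceding pulse, so the first
    # diastolic trough is a strict local minimum rather than a plateau edge
    prev_p = p_idx[0] - rr_samp[0]
    j = np.arange(t_idx[0])
    frac = (j - prev_p) / max(1, t_idx[0] - prev_p)
    tail = 0.5 + 0.5 * np.cos(np.pi * np.clip(frac, 0.0, 1.0))
    ppg[: t_idx[0]] = tail
    abp[: t_idx[0]] = dbp[0] + tail * (sbp[0] - dbp[0])
    bounds = np.append(t_idx, t_end)
    dbp_ext = np.append(dbp, dbp[-1])   # trough value at each boundary
    for k in range(nb):
        a, b = bounds[k], bounds[k + 1]
        shape = _pulse_shape(p_idx[k] - a, b - p_idx[k])[: b - a]
        ppg[a:b] = shape
        base = np.linspace(dbp_ext[k], dbp_ext[k + 1], b - a, endpoint=False)
        abp[a:b] = base + shape * (sbp[k] - base)
    abp[t_end:] = dbp[-1]

    # Noise & baseline wander ---------------------------------------------
    if config.wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, 2)
        for sig_arr, ph in zip((ecg, ppg), phase):
            amp = config.wander_amp * (np.ptp(sig_arr) or 1.0)
            sig_arr += amp * np.sin(2 * np.pi * config.wander_freq * t + ph)
    if config.noise_sd > 0:
        for sig_arr in (ecg, ppg, abp):
            amp = config.noise_sd * (np.ptp(sig_arr) or 1.0)
            sig_arr += rng.normal(0.0, amp, n)

    truth = [
        BeatTruth(
            r_peak_index=int(r_idx[k]),
            sbp=float(sbp[k]),
            dbp=float(dbp[k]),
            pat=float((p_idx[k] - r_idx[k]) / fs),
            rr=float(rr_samp[k] / fs),
        )
        for k in range(nb)
    ]
    return PhysioRecord(ecg=ecg, ppg=ppg, abp=abp, fs=fs, truth=truth)


def inject_artifacts(
    record: PhysioRecord, config: SynthConfig
) -> tuple[PhysioRecord, dict[str, np.ndarray]]:
    """Corrupt a seeded fraction of samples with monitor-style artifacts.

    Exactly ``round(artifact_rate * n)`` samples per channel are replaced by
    0 or by the sentinel −2,147,483,648. Returns the corrupted copy and, per
    channel, the sorted corrupted positions (for test oracles); the input
    record is left untouched.
    """
    if not 0 <= config.artifact_rate < 1:
        raise ValueError(
            f"artifact_rate must be in [0, 1), got {config.artifact_rate}"
        )
    out = record.copy()
    positions: dict[str, np.ndarray] = {}
    rng = np.random.default_rng((config.seed, 0xA27))
    n = record.n_samples
    k = int(round(config.artifact_rate * n))
    for name in ("ecg", "ppg", "abp"):
        idx = np.sort(rng.choice(n, size=k, replace=False))
        vals = rng.choice(np.array([0.0, float(SENTINEL)]), size=k)
        getattr(out, name)[idx] = vals
        positions[name] = idx
    return out, positions


# ---------------------------------------------------------------------------
# Plain-text record I/O (3-column CSV dialect with a `# fs=` header line)
# ---------------------------------------------------------------------------

def write_record_csv(record: PhysioRecord, path) -> None:
    """Write a record as CSV: ``# fs=<fs>`` line, header ``ecg,ppg,abp``."""
    data = np.column_stack([record.ecg, record.ppg, record.abp])
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        fh.write("ecg,ppg,abp\n")
        np.savetxt(fh, data, fmt="%.9g", delimiter=",")


def read_record_csv(path) -> PhysioRecord:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(first.split("=", 1)[1])
        header = fh.readline().strip().split(",")
        if header != ["ecg", "ppg", "abp"]:
            raise ValueError(f"{path}: expected columns ecg,ppg,abp, got {header}")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return PhysioRecord(ecg=data[:, 0], ppg=data[:, 1], abp=data[:, 2], fs=fs)
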