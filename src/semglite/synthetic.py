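"""Seeded synthetic single-channel sEMG sessions.

Emulates a fixed acquisition protocol: a leading rest period followed by a
block of task trials, all recorded at 1000 Hz. Each session records one
movement class; classes differ in burst envelope amplitude and burst rate so
that a downstream classifier has a real (but synthetic) signal to learn.

The signal model is zero-mean Gaussian noise band-passed to the sEMG energy
band, amplitude-modulated by a smooth per-trial burst envelope. It reproduces
the amplitude-modulated, band-limited character of surface EMG without
claiming physiological fidelity (no motor-unit model, no electrode cross-talk,
independent channels when more than one is requested).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SyntheticProtocol",
    "ClassSignalParams",
    "RawRecording",
    "make_class_params",
    "generate_recording",
    "generate_dataset",
    "write_recording",
    "read_recording",
]


@dataclass(frozen=True)
class SyntheticProtocol:
    """Session/trial timeline of the acquisition protocol.

    Defaults mirror the emulated protocol: 5 s rest then 4 trials of 10 s
    task activity at 1000 Hz, two sessions per able-bodied subject (one for
    amputated subjects, via ``sessions=1``).
    """

    n_classes: int = 15
    fs: int = 1000
    rest_s: float = 5.0
    trial_s: float = 10.0
    n_trials: int = 4
    sessions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.rest_s < 0 or self.trial_s <= 0 or self.n_trials < 1:
            raise ValueError("rest_s >= 0, trial_s > 0 and n_trials >= 1 required")

    @property
    def session_s(self) -> float:
        """Total session length in seconds: rest + n_trials * trial."""
        return self.rest_s + self.n_trials * self.trial_s

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.session_s))


@dataclass(frozen=True)
class ClassSignalParams:
    """Per-class statistics of the synthetic burst process.

    envelope_amp is the peak modulation amplitude in arbitrary units,
    burst_rate the number of activity bursts per second, band_low/band_high
    the band-pass corners in Hz, and noise_floor the std of the baseline
    (rest) noise in the same arbitrary units.
    """

    envelope_amp: float
    burst_rate: float
    band_low: float = 20.0
    band_high: float = 450.0
    noise_floor: float = 0.05

    def validate(self, fs: float) -> None:
        if not (0.0 < self.band_low < self.band_high < fs / 2.0):
            raise ValueError(
                f"band corners must satisfy 0 < {self.band_low} < "
                f"{self.band_high} < fs/2 = {fs / 2.0}"
            )
        if not (self.envelope_amp >= 0.0 and self.noise_floor >= 0.0):
            raise ValueError("envelope_amp and noise_floor must be non-negative")


@dataclass
class RawRecording:
    """One labelled session of single-channel sEMG.

    ``trial_labels`` gives the class index per sample (0 = rest);
    ``trial_ids`` gives the 1-based trial number per sample (0 during rest),
    so windows can later be split by trial without re-deriving the timeline.
    """

    samples: np.ndarray
    fs: int
    trial_labels: np.ndarray
    trial_ids: np.ndarray
    subject_id: int = 0
    session_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.trial_labels = np.asarray(self.trial_labels, dtype=np.int64)
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
        if len(self.trial_labels) != len(self.samples):
            raise ValueError("trial_labels and samples must have equal length")
        if len(self.trial_ids) != len(self.samples):
            raise ValueError("trial_ids and samples must have equal length")


def make_class_params(n_classes: int, seed: int) -> list[ClassSignalParams]:
    """Deterministic, pairwise-distinct signal statistics for each class.

    Envelope amplitudes are spread on an arithmetic grid (0.8 upward in steps
    of 0.5/... depending on class count) with a small seeded jitter that never
    collapses two classes; burst rates cycle through 1-4 bursts/s. Distinctness
    in (envelope_amp, burst_rate) is what makes classes separable downstream.
    """
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E9]))
    params = []
    for i in range(n_classes):
        # amplitude is the primary single-channel discriminative cue (as RMS
        # is in classical myoelectric work): log-spaced levels, factor 1.55,
        # with a bounded multiplicative jitter that keeps classes distinct
        amp = 0.75 * 1.55 ** i * float(np.exp(rng.uniform(-0.05, 0.05)))
        rate = 1.0 + (i % 4) + rng.uniform(-0.2, 0.2)
        # secondary spectral cue: different movements recruit muscle tissue
        # with different dominant frequency content at a fixed electrode, so
        # band centers are spread across the sEMG energy band (+/-60 Hz)
        center = 80.0 + 300.0 * i / max(n_classes - 1, 1)
        params.append(ClassSignalParams(
            envelope_amp=float(amp),
            burst_rate=float(rate),
            band_low=float(max(center - 60.0, 15.0)),
            band_high=float(min(center + 60.0, 470.0)),
        ))
    return params


#: fraction of the peak envelope sustained between bursts; a task trial is a
#: held contraction, so the envelope never drops to zero within a trial
ENVELOPE_BASE = 0.6


def _burst_envelope(n: int, fs: float, rate: float, amp: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Smooth burst envelope on a sustained plateau: amp*(base + (1-base)*lobes).

    Burst onsets are jittered around a regular grid at ~rate bursts/s; each
    burst is a Hann lobe occupying ~60% of the inter-burst interval. The
    plateau models the tonic activity of a held contraction, the lobes its
    rhythmic modulation, so every analysis window inside a trial carries the
    class's amplitude signature.
    """
    if rate <= 0 or amp <= 0:
        return np.zeros(n)
    lobes = np.zeros(n)
    period = fs / rate
    width = max(int(round(0.6 * period)), 4)
    lobe = np.hanning(width)
    onset = 0.0
    while onset < n:
        start = int(round(onset + rng.uniform(-0.1, 0.1) * period))
        if start >= n:
            break
        if start < 0:
            start = 0
        stop = min(start + width, n)
        lobes[start:stop] = np.maximum(lobes[start:stop], lobe[: stop - start])
        onset += period
    return amp * (ENVELOPE_BASE + (1.0 - ENVELOPE_BASE) * lobes)


def _bandpassed_noise(n: int, fs: float, lo: float, hi: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed with a zero-phase Butterworth."""
    white = rng.standard_normal(n)
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_recording(
    protocol: SyntheticProtocol,
    class_index: int,
    params: ClassSignalParams,
    subject_id: int = 0,
    session_id: int = 0,
) -> RawRecording:
    """Generate one session of a single movement class.

    The timeline is rest_s seconds of baseline noise (label 0) followed by
    n_trials trials of trial_s seconds each (label ``class_index``). During
    trials the band-passed carrier noise is amplitude-modulated by the class
    burst envelope and the baseline noise floor is added; the in-trial
    variance therefore strictly exceeds the rest variance whenever
    envelope_amp > noise_floor. Bit-reproducible for a fixed
    (protocol, params, subject_id, session_id).
    """
    if not (1 <= class_index <= protocol.n_classes):
        raise ValueError(
            f"class_index must be in [1, {protocol.n_classes}], got {class_index}"
        )
    params.validate(protocol.fs)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(protocol.seed), class_index, subject_id, session_id])
    )

    fs = protocol.fs
    n_rest = int(round(fs * protocol.rest_s))
    n_trial = int(round(fs * protocol.trial_s))
    n_total = n_rest + protocol.n_trials * n_trial

    samples = np.empty(n_total)
    labels = np.zeros(n_total, dtype=np.int64)
    trial_ids = np.zeros(n_total, dtype=np.int64)

    samples[:n_rest] = params.noise_floor * rng.standard_normal(n_rest)

    pos = n_rest
    for t in range(1, protocol.n_trials + 1):
        carrier = _bandpassed_noise(n_trial, fs, params.band_low, params.band_high, rng)
        env = _burst_envelope(n_trial, fs, params.burst_rate, params.envelope_amp, rng)
        baseline = params.noise_floor * rng.standard_normal(n_trial)
        samples[pos:pos + n_trial] = env * carrier + baseline
        labels[pos:pos + n_trial] = class_index
        trial_ids[pos:pos + n_trial] = t
        pos += n_trial

    return RawRecording(
        samples=samples,
        fs=fs,
        trial_labels=labels,
        trial_ids=trial_ids,
        subject_id=subject_id,
        session_id=session_id,
    )


def generate_dataset(
    protocol: SyntheticProtocol,
    params: list[ClassSignalParams] | None = None,
    n_subjects: int = 1,
) -> list[RawRecording]:
    """All sessions of all classes for ``n_subjects`` subjects.

    One recording per (subject, session, class); ``protocol.sessions``
    controls the session count (1 emulates the amputated-subject protocol).
    """
    if params is None:
        params = make_class_params(protocol.n_classes, protocol.seed)
    if len(params) != protocol.n_classes:
        raise ValueError("need one ClassSignalParams per class")
    recs = []
    for subj in range(n_subjects):
        for sess in range(protocol.sessions):
            for cls in range(1, protocol.n_classes + 1):
                recs.append(
                    generate_recording(protocol, cls, params[cls - 1],
                                       subject_id=subj, session_id=sess)
                )
    return recs


# ---------------------------------------------------------------------------
# plain-text / array-container I/O

def write_recording(rec: RawRecording, out_dir: str | Path, stem: str | None = None,
                    text: bool = False) -> Path:
    """Write a recording as .npz (samples/labels/trial_ids) with a JSON sidecar,
    or as delimited text (sample_value,label per row) when ``text`` is set."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stem is None:
        stem = f"s{rec.subject_id}_sess{rec.session_id}_cls{int(rec.trial_labels.max())}"
    meta = {"fs": rec.fs, "subject_id": rec.subject_id, "session_id": rec.session_id}
    if text:
        path = out_dir / f"{stem}.csv"
        np.savetxt(path, np.column_stack([rec.samples, rec.trial_labels]),
                   fmt="%.8e,%d", delimiter=",")
    else:
        path = out_dir / f"{stem}.npz"
        np.savez(path, samples=rec.samples, trial_labels=rec.trial_labels,
                 trial_ids=rec.trial_ids)
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return path


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_recording` (.npz form)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        return RawRecording(
            samples=z["samples"], fs=int(meta["fs"]),
            trial_labels=z["trial_labels"], trial_ids=z["trial_ids"],
            subject_id=int(meta["subject_id"]), session_id=int(meta["session_id"]),
        )
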