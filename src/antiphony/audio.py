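"""Vocalisation segmentation, spectro-temporal features and call typing.

From a continuous per-bird channel, calls are segmented on a smoothed dB
envelope, summarised by ten spectro-temporal parameters (duration, mean
frequency and its SD, mode frequency and its SD, first spectral peak and its
SD, zero-crossing rate, maximum positive and minimum negative amplitude peak),
sorted automatically into call-type categories with a Gaussian mixture, and
cleaned of partner-leak detections, which sit far below the bird's own calls
in amplitude because the backpack microphone faces its carrier.

The frequency statistics are frame-wise over a magnitude spectrogram (512-pt
Hann window, 75% overlap at 44.1 kHz by default): mean frequency is the
amplitude-weighted spectral centroid, mode frequency the arg-max bin, and the
first peak the lowest-frequency prominent local spectral maximum (a proxy for
the fundamental); each is averaged over frames with its SD taken across
frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d
from scipy.signal import ShortTimeFFT, find_peaks
from scipy.signal.windows import hann
from sklearn.mixture import GaussianMixture

__all__ = [
    "Segment",
    "FeatureVector",
    "FEATURE_NAMES",
    "CALL_CATEGORIES",
    "read_wav",
    "segment_vocalizations",
    "extract_features",
    "feature_table",
    "cluster_calls",
    "apply_label_file",
    "remove_nonfocal",
    "count_songs",
    "call_type_proportions",
]

# Female repertoire categories; males additionally produce Song and
# misplaced introductory syllables.
CALL_CATEGORIES = ("Tet", "Stack", "Distance", "Kackle", "Whine", "Hat", "Unassigned")
MALE_EXTRA_CATEGORIES = ("Song", "Misplaced-introductory")

FEATURE_NAMES = (
    "duration_s", "mean_freq_hz", "mean_freq_sd_hz", "mode_freq_hz",
    "mode_freq_sd_hz", "first_peak_hz", "first_peak_sd_hz",
    "zero_crossing_rate_per_s", "max_positive_peak", "min_negative_peak",
)


@dataclass
class Segment:
    """One detected vocalisation cut from the source channel."""

    onset_s: float
    offset_s: float
    samples: np.ndarray = field(repr=False)
    source_bird: str | None = None

    def __post_init__(self):
        if not self.offset_s > self.onset_s:
            raise ValueError("offset_s must exceed onset_s")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class FeatureVector:
    duration_s: float
    mean_freq_hz: float
    mean_freq_sd_hz: float
    mode_freq_hz: float
    mode_freq_sd_hz: float
    first_peak_hz: float
    first_peak_sd_hz: float
    zero_crossing_rate_per_s: float
    max_positive_peak: float
    min_negative_peak: float
    zero_crossing_count: int = 0
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV as float in [−1, 1]."""
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), int(sr)


def segment_vocalizations(
    waveform,
    sample_rate: int,
    threshold_db: float = -40.0,
    min_dur_s: float = 0.02,
    min_gap_s: float = 0.03,
    smooth_s: float = 0.005,
    source_bird: str | None = None,
) -> list[Segment]:
    """Detect calls as supra-threshold runs of the smoothed dB envelope.

    The envelope is the RMS of the waveform over a ``smooth_s`` moving window,
    in dB relative to full scale (1.0).  Runs closer than ``min_gap_s`` are
    merged; runs shorter than ``min_dur_s`` discarded.  Silence returns an
    empty list.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be mono")
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite samples")
    if x.size == 0 or not np.any(x):
        return []
    win = max(1, int(round(smooth_s * sample_rate)))
    env = np.sqrt(uniform_filter1d(x * x, size=win, mode="nearest"))
    env_db = 20.0 * np.log10(np.maximum(env, 1e-12))
    above = env_db > threshold_db
    if not above.any():
        return []

    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1) if above.size else []
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(x.size)

    merged: list[list[int]] = []
    gap = int(round(min_gap_s * sample_rate))
    for a, b in zip(starts, stops):
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    min_n = int(round(min_dur_s * sample_rate))
    out = []
    for a, b in merged:
        if b - a >= min_n:
            out.append(Segment(a / sample_rate, b / sample_rate, x[a:b], source_bird))
    return out


def _stft_magnitude(x: np.ndarray, sample_rate: int, n_fft: int,
                    hop: int) -> tuple[np.ndarray, np.ndarray]:
    stft = ShortTimeFFT(hann(n_fft, sym=False), hop=hop, fs=sample_rate,
                        mfft=n_fft, scale_to="magnitude")
    S = np.abs(stft.stft(x))
    return S, stft.f


def extract_features(
    segment: Segment | np.ndarray,
    sample_rate: int,
    n_fft: int = 512,
    hop: int | None = None,
    peak_prominence_rel: float = 0.1,
) -> FeatureVector:
    """Ten spectro-temporal parameters of one vocalisation.

    Frame statistics come from a magnitude spectrogram (Hann window of
    ``n_fft`` samples, 75% overlap by default).  A constant or silent input is
    degenerate: frequency features are reported as 0 with the ``degenerate``
    flag set.
    """
    x = segment.samples if isinstance(segment, Segment) else np.asarray(segment, float)
    if hop is None:
        hop = n_fft // 4
    duration = x.size / sample_rate
    if x.size < 2 * hop:
        raise ValueError("segment too short for the requested STFT frames")

    max_pos = float(max(x.max(), 0.0))
    min_neg = float(min(x.min(), 0.0))
    zc = int(np.count_nonzero(np.diff(np.signbit(x))))
    zcr = zc / duration

    ac = x - x.mean()
    if not np.any(np.abs(ac) > 1e-12):
        warnings.warn("degenerate (constant) segment; frequency features set to 0",
                      stacklevel=2)
        return FeatureVector(duration, 0, 0, 0, 0, 0, 0, zcr, max_pos, min_neg,
                             zero_crossing_count=zc, degenerate=True)

    S, freqs = _stft_magnitude(x, sample_rate, n_fft, hop)
    power = S.sum(axis=0)
    keep = power > 1e-10 * power.max()
    S = S[:, keep]
    if S.shape[1] == 0:
        return FeatureVector(duration, 0, 0, 0, 0, 0, 0, zcr, max_pos, min_neg,
                             zero_crossing_count=zc, degenerate=True)

    centroid = (freqs[:, None] * S).sum(axis=0) / S.sum(axis=0)
    mode = freqs[np.argmax(S, axis=0)]

    first_peaks = []
    for j in range(S.shape[1]):
        col = S[:, j]
        pk, _ = find_peaks(col, prominence=peak_prominence_rel * col.max())
        if pk.size:
            first_peaks.append(freqs[pk[0]])
        else:  # fall back to the global maximum when no interior peak exists
            first_peaks.append(freqs[int(np.argmax(col))])
    first_peaks = np.asarray(first_peaks)

    def _sd(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1)) if v.size > 1 else 0.0

    return FeatureVector(
        duration_s=duration,
        mean_freq_hz=float(centroid.mean()), mean_freq_sd_hz=_sd(centroid),
        mode_freq_hz=float(mode.mean()), mode_freq_sd_hz=_sd(mode),
        first_peak_hz=float(first_peaks.mean()), first_peak_sd_hz=_sd(first_peaks),
        zero_crossing_rate_per_s=zcr,
        max_positive_peak=max_pos, min_negative_peak=min_neg,
        zero_crossing_count=zc,
    )


def feature_table(segments: list[Segment], sample_rate: int, **kw) -> pd.DataFrame:
    """Feature matrix for a list of segments (one row per segment)."""
    rows = [extract_features(s, sample_rate, **kw).as_array() for s in segments]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "onset_s", [s.onset_s for s in segments])
    df.insert(1, "offset_s", [s.offset_s for s in segments])
    return df


@dataclass
class ClusterResult:
    labels: np.ndarray            # hard labels, −1 = Unassigned
    responsibilities: np.ndarray  # n × k posterior matrix
    means: np.ndarray             # cluster centers in z-scored feature space
    degenerate: bool = False


def cluster_calls(
    features,
    k: int,
    seed: int = 0,
    unassigned_threshold: float = 0.6,
    n_init: int = 5,
) -> ClusterResult:
    """Sort calls into ``k`` types by a full-covariance Gaussian mixture.

    Features are z-scored per column internally (zero-variance columns are
    dropped).  Segments whose maximum posterior falls below
    ``unassigned_threshold`` are labelled −1 (Unassigned).  The hard labels
    plus the posterior matrix are returned so a label file can be exported,
    hand-edited and re-ingested in place of the automatic sort.
    """
    X = np.asarray(features, dtype=float)
    if isinstance(features, pd.DataFrame):
        X = features[list(FEATURE_NAMES)].to_numpy(dtype=float) \
            if set(FEATURE_NAMES).issubset(features.columns) else features.to_numpy(float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of segments ({n})")

    sd = X.std(axis=0, ddof=0)
    cols = sd > 0
    if not cols.any():
        # all rows identical: one effective cluster
        resp = np.zeros((n, k))
        resp[:, 0] = 1.0
        return ClusterResult(np.zeros(n, dtype=int), resp,
                             np.zeros((k, X.shape[1])), degenerate=True)
    Z = (X[:, cols] - X[:, cols].mean(axis=0)) / sd[cols]

    gm = GaussianMixture(n_components=k, covariance_type="full",
                         random_state=seed, n_init=n_init, reg_covar=1e-6)
    gm.fit(Z)
    resp = gm.predict_proba(Z)
    labels = resp.argmax(axis=1).astype(int)
    labels[resp.max(axis=1) < unassigned_threshold] = -1
    return ClusterResult(labels, resp, gm.means_, degenerate=False)


def remove_nonfocal(
    peak_amplitudes,
    intensity_margin_db: float = 10.0,
) -> np.ndarray:
    """Keep-mask separating own calls from faint partner leak.

    The backpack channel records the carrier's calls at a characteristic
    level; detections whose peak amplitude lies more than
    ``intensity_margin_db`` below the mode of the amplitude distribution (in
    1-dB bins) are partner leak and dropped.  An infinite margin keeps all.
    """
    amp = np.asarray(peak_amplitudes, dtype=float)
    if amp.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(amp <= 0):
        raise ValueError("peak amplitudes must be positive")
    if not np.isfinite(intensity_margin_db):
        return np.ones(amp.size, dtype=bool)
    db = 20.0 * np.log10(amp)
    bins = np.arange(np.floor(db.min()) - 0.5, np.ceil(db.max()) + 1.5, 1.0)
    hist, edges = np.histogram(db, bins=bins)
    mode_db = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    return db > mode_db - intensity_margin_db


def apply_label_file(labels, label_table: pd.DataFrame) -> np.ndarray:
    """Overwrite automatic labels with a hand-edited label file.

    ``label_table`` needs columns ``segment_id`` (0-based row index) and
    ``label``; listed segments take the file's label verbatim, everything
    else keeps its automatic one.  This replaces by-eye cluster refinement
    with an auditable artifact.
    """
    out = np.asarray(labels).copy()
    for col in ("segment_id", "label"):
        if col not in label_table.columns:
            raise ValueError(f"label file needs a {col!r} column")
    ids = label_table["segment_id"].to_numpy(dtype=int)
    if ids.size and (ids.min() < 0 or ids.max() >= out.size):
        raise ValueError("label file references segment ids outside the data")
    out = out.astype(object) if label_table["label"].dtype == object else out
    out[ids] = label_table["label"].to_numpy()
    return out


def count_songs(total_song_syllables: float, mean_syllables_per_song: float) -> tuple[float, int]:
    """Songs = total song syllables / the male's mean syllables per song.

    Returns the unrounded quotient and its rounded convenience value.
    """
    if mean_syllables_per_song <= 0:
        raise ValueError("mean_syllables_per_song must be positive")
    if total_song_syllables < 0:
        raise ValueError("syllable count cannot be negative")
    q = total_song_syllables / mean_syllables_per_song
    return q, int(round(q))


def call_type_proportions(
    events: pd.DataFrame,
    categories: tuple[str, ...] | None = None,
    by: tuple[str, ...] = ("bird_id", "day"),
) -> pd.DataFrame:
    """Per bird-day repertoire proportions (each row sums to 1).

    ``events`` needs the grouping columns plus ``call_type``.  Unassigned is a
    category of its own.  Empty bird-days simply produce no row; callers that
    need them flagged can compare against their expected index.
    """
    if "call_type" not in events.columns:
        raise ValueError("events must have a call_type column")
    missing = [c for c in by if c not in events.columns]
    if missing:
        raise ValueError(f"events missing grouping columns {missing}")
    counts = (events.groupby([*by, "call_type"], observed=True)
              .size().unstack("call_type", fill_value=0))
    if categories is not None:
        for c in categories:
            if c not in counts.columns:
                counts[c] = 0
        counts = counts[list(categories)]
    props = counts.div(counts.sum(axis=1), axis=0)
    return props
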