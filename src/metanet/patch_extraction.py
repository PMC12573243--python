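"""Turn images and audio clips into N x 256 patch matrices.

Images are grayscaled, min-max normalized to [0, 1] and sampled as
random 16 x 16 crops.  Audio is converted to a 16-bin mel spectrogram,
log-scaled and normalized, and sampled as random 16-frame windows.
Every patch is flattened row-major to a 256-vector, so a vision patch
and an audio window share one input format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

PATCH_SIDE = 16
PATCH_DIM = PATCH_SIDE * PATCH_SIDE

#: luminance weights for RGB -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class PatchMatrix:
    """N x 256 matrix of unit-interval intensities plus provenance labels."""

    values: np.ndarray
    source_dataset_id: str
    modality_tag: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != PATCH_DIM:
            raise InputError(f"patch matrix must be N x {PATCH_DIM}, got {self.values.shape}")
        if self.values.shape[0] < 1:
            raise InputError("patch matrix must have at least one row")
        if not np.isfinite(self.values).all():
            raise InputError("patch matrix contains non-finite entries")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise InputError("patch matrix entries must lie in [0, 1]")

    @property
    def n_patches(self) -> int:
        return self.values.shape[0]


def minmax01(arr: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a zero-range input maps to all 0.5."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi - lo == 0.0:
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an (H, W) or (H, W, 3) intensity grid to (H, W) luminance."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        return image @ _LUMA
    raise InputError(f"expected (H, W) or (H, W, 3) image, got shape {image.shape}")


def make_dataset_id(modality_tag: str, class_name: str) -> str:
    """Dataset id: modality prefix plus the first three letters of the class name."""
    prefixes = {"vision": "v", "audio": "a"}
    if modality_tag not in prefixes:
        raise ParameterError(f"unknown modality tag {modality_tag!r}")
    if not class_name:
        raise ParameterError("class name must be non-empty")
    return f"{prefixes[modality_tag]}:{class_name[:3].lower()}"


def image_to_patches(image: np.ndarray, n_patches: int, seed: int,
                     dataset_id: str = "v:unnamed") -> PatchMatrix:
    """Sample ``n_patches`` random 16x16 crops from a grayscaled, normalized image.

    Crops are drawn uniformly over valid top-left corners, with
    replacement, and flattened row-major.
    """
    if n_patches < 1:
        raise ParameterError("n_patches must be >= 1")
    gray = to_grayscale(image)
    if gray.size == 0:
        raise InputError("empty image")
    h, w = gray.shape
    if h < PATCH_SIDE or w < PATCH_SIDE:
        raise InputError(f"image {h}x{w} smaller than {PATCH_SIDE}x{PATCH_SIDE}")
    norm = minmax01(gray)
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - PATCH_SIDE + 1, size=n_patches)
    cols = rng.integers(0, w - PATCH_SIDE + 1, size=n_patches)
    out = np.empty((n_patches, PATCH_DIM))
    for i, (r, c) in enumerate(zip(rows, cols)):
        out[i] = norm[r : r + PATCH_SIDE, c : c + PATCH_SIDE].reshape(-1)
    return PatchMatrix(out, dataset_id, "vision")


def mel_frequencies(n_mels: int, fmin: float, fmax: float) -> np.ndarray:
    """Band edge/center frequencies equally spaced on the HTK mel scale."""

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mels = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    return mel_to_hz(mels)


def mel_filterbank(sample_rate: float, n_fft: int, n_mels: int = 16,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filter bank, shape (n_mels, n_fft // 2 + 1)."""
    if fmax is None:
        fmax = sample_rate / 2.0
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    edges = mel_frequencies(n_mels, fmin, fmax)
    bank = np.zeros((n_mels, freqs.size))
    for m in range(n_mels):
        lo, center, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (freqs - lo) / max(center - lo, 1e-12)
        down = (hi - freqs) / max(hi - center, 1e-12)
        bank[m] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def mel_spectrogram(wave: np.ndarray, sample_rate: float, n_mels: int = 16,
                    n_fft: int = 1024, hop: int = 512) -> np.ndarray:
    """Log-magnitude mel spectrogram, shape (n_mels, n_frames)."""
    wave = np.asarray(wave, dtype=np.float64)
    if wave.ndim == 2:  # average channels of stereo input
        wave = wave.mean(axis=1)
    if wave.ndim != 1 or wave.size == 0:
        raise InputError("waveform must be a non-empty 1-D (or stereo 2-D) array")
    _, _, stft = signal.stft(wave, fs=sample_rate, nperseg=n_fft, noverlap=n_fft - hop,
                             boundary=None, padded=False)
    power = np.abs(stft) ** 2
    bank = mel_filterbank(sample_rate, n_fft, n_mels)
    return np.log10(bank @ power + 1e-10)


def audio_to_patches(wave: np.ndarray, sample_rate: float, n_patches: int, seed: int,
                     dataset_id: str = "a:unnamed", n_fft: int = 1024,
                     hop: int = 512) -> PatchMatrix:
    """Sample ``n_patches`` random 16-frame windows of a normalized mel spectrogram.

    Each 16 (mel bins) x 16 (frames) window is flattened row-major
    (frequency-major), matching the vision patch layout.
    """
    if n_patches < 1:
        raise ParameterError("n_patches must be >= 1")
    spec = mel_spectrogram(wave, sample_rate, n_mels=PATCH_SIDE, n_fft=n_fft, hop=hop)
    n_frames = spec.shape[1]
    if n_frames < PATCH_SIDE:
        raise InputError(f"spectrogram has {n_frames} frames; need >= {PATCH_SIDE}")
    norm = minmax01(spec)
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n_frames - PATCH_SIDE + 1, size=n_patches)
    out = np.empty((n_patches, PATCH_DIM))
    for i, s in enumerate(starts):
        out[i] = norm[:, s : s + PATCH_SIDE].reshape(-1)
    return PatchMatrix(out, dataset_id, "audio")


def load_image(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"), dtype=np.float64)


def load_wav(path) -> tuple[np.ndarray, int]:
    sr, data = wavfile.read(path)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        data = data.astype(np.float64) / max(abs(info.min), info.max)
    else:
        data = np.asarray(data, dtype=np.float64)
    return data, int(sr)


def extract_image_dataset(images: list[np.ndarray], n_patches: int, seed: int,
                          dataset_id: str) -> PatchMatrix:
    """Pool patches from several images, split as evenly as possible."""
    if not images:
        raise InputError("no images supplied")
    counts = np.full(len(images), n_patches // len(images))
    counts[: n_patches % len(images)] += 1
    blocks = []
    for i, (img, cnt) in enumerate(zip(images, counts)):
        if cnt > 0:
            blocks.append(image_to_patches(img, int(cnt), seed + i, dataset_id).values)
    return PatchMatrix(np.concatenate(blocks), dataset_id, "vision")


def extract_audio_dataset(clips: list[tuple[np.ndarray, int]], n_patches: int, seed: int,
                          dataset_id: str, n_fft: int = 1024, hop: int = 512) -> PatchMatrix:
    """Pool windows from several clips; clips too short for one window are skipped."""
    if not clips:
        raise InputError("no clips supplied")
    usable = []
    for wave, sr in clips:
        spec_frames = 1 + max(0, (np.atleast_1d(wave).shape[0] - n_fft)) // hop
        if spec_frames >= PATCH_SIDE:
            usable.append((wave, sr))
        else:
            logger.warning("skipping clip with %d spectrogram frames (< %d)", spec_frames, PATCH_SIDE)
    if not usable:
        raise InputError("no clip long enough for a 16-frame window")
    counts = np.full(len(usable), n_patches // len(usable))
    counts[: n_patches % len(usable)] += 1
    blocks = []
    for i, ((wave, sr), cnt) in enumerate(zip(usable, counts)):
        if cnt > 0:
            blocks.append(audio_to_patches(wave, sr, int(cnt), seed + i, dataset_id,
                                           n_fft=n_fft, hop=hop).values)
    return PatchMatrix(np.concatenate(blocks), dataset_id, "audio")
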