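"""Synthetic two-modality patch generators.

Modality A ("vision-like") draws stationary Gaussian-random-field
16 x 16 textures whose spatial correlation length (and optionally an
anisotropic orientation) differs per category.  Modality B
("audio-like") builds spectrogram-style 16 (frequency) x 16 (time)
windows that concentrate energy on a category-specific harmonic stack
of rows with an AR(1)-smooth temporal amplitude envelope.

The two families differ in their second-order statistics the way image
patches differ from mel-spectrogram windows — A is (near-)isotropic in
the two patch axes, B is strongly row/column asymmetric — which is the
contrast the downstream meta-pipeline is asked to recover.  Every patch
is min-max rescaled to [0, 1] per patch (a constant patch maps to all
0.5), and generation is bit-deterministic given the config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import FormatError, ParameterError
from .patch_extraction import PATCH_DIM, PATCH_SIDE, PatchMatrix

MODALITY_A = "A"  # vision-like
MODALITY_B = "B"  # audio-like

_PREFIX = {MODALITY_A: "sv", MODALITY_B: "sa"}


@dataclass(frozen=True)
class VisionCategoryParams:
    """Gaussian-random-field texture parameters for one modality-A category.

    ``correlation_length`` is in pixels (``inf`` gives a constant
    field); ``anisotropy`` >= 1 stretches the correlation by that factor
    along ``orientation`` (radians).
    """

    correlation_length: float
    orientation: float = 0.0
    anisotropy: float = 1.0

    def __post_init__(self):
        if not (self.correlation_length > 0):
            raise ParameterError("correlation_length must be positive")
        if self.anisotropy < 1.0:
            raise ParameterError("anisotropy must be >= 1")


@dataclass(frozen=True)
class AudioCategoryParams:
    """Harmonic-stack parameters for one modality-B category.

    Energy sits on rows ``fundamental_row * (1, 2, ..., n_harmonics)``
    (clipped to rows <= 15); ``smoothness`` in [0, 1) is the AR(1)
    coefficient of the temporal amplitude envelope.
    """

    fundamental_row: int
    n_harmonics: int = 3
    smoothness: float = 0.5

    def __post_init__(self):
        if not (0 <= self.fundamental_row <= 15):
            raise ParameterError("fundamental_row must be in [0, 15]")
        if self.n_harmonics < 1:
            raise ParameterError("n_harmonics must be >= 1")
        if not (0.0 <= self.smoothness < 1.0):
            raise ParameterError("smoothness must be in [0, 1)")

    def harmonic_rows(self) -> list[int]:
        rows = []
        for k in range(1, self.n_harmonics + 1):
            row = self.fundamental_row * k
            if row <= 15 and row not in rows:
                rows.append(row)
        return rows


@dataclass(frozen=True)
class SyntheticModalityConfig:
    """One synthetic modality: a tag, per-category parameters, noise and a seed."""

    modality_tag: str
    category_params: tuple
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.modality_tag not in (MODALITY_A, MODALITY_B):
            raise ParameterError(f"modality_tag must be {MODALITY_A!r} or {MODALITY_B!r}")
        object.__setattr__(self, "category_params", tuple(self.category_params))
        if len(self.category_params) < 2:
            raise ParameterError("need at least 2 categories")
        expected = VisionCategoryParams if self.modality_tag == MODALITY_A else AudioCategoryParams
        for p in self.category_params:
            if not isinstance(p, expected):
                raise ParameterError(f"modality {self.modality_tag} expects {expected.__name__}")
        if len(set(self.category_params)) != len(self.category_params):
            raise ParameterError("category parameter records must be distinct")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def n_categories(self) -> int:
        return len(self.category_params)


def _check_args(cfg: SyntheticModalityConfig, category: int, n: int) -> None:
    if not (0 <= category < cfg.n_categories):
        raise ParameterError(f"category {category} out of range [0, {cfg.n_categories})")
    if n < 1:
        raise ParameterError("n must be >= 1")


def _rng(cfg: SyntheticModalityConfig, category: int, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, category, seed]))


def _rescale_rows(patches: np.ndarray) -> np.ndarray:
    """Per-patch min-max to [0, 1]; zero-range rows map to 0.5."""
    lo = patches.min(axis=1, keepdims=True)
    hi = patches.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0.0
    span[flat] = 1.0
    out = (patches - lo) / span
    out[flat] = 0.5
    return out


def _grf_cholesky(params: VisionCategoryParams) -> np.ndarray:
    """Cholesky factor of the 256 x 256 field covariance on the 16 x 16 grid."""
    coords = np.stack(np.meshgrid(np.arange(PATCH_SIDE), np.arange(PATCH_SIDE),
                                  indexing="ij"), axis=-1).reshape(-1, 2).astype(np.float64)
    d = coords[:, None, :] - coords[None, :, :]
    c, s = np.cos(params.orientation), np.sin(params.orientation)
    along = d[..., 0] * c + d[..., 1] * s
    across = -d[..., 0] * s + d[..., 1] * c
    l_along = params.correlation_length * params.anisotropy
    l_across = params.correlation_length
    cov = np.exp(-0.5 * ((along / l_along) ** 2 + (across / l_across) ** 2))
    cov[np.diag_indices_from(cov)] += 1e-8
    return np.linalg.cholesky(cov)


def gen_vision_like_patches(cfg: SyntheticModalityConfig, category: int, n: int,
                            seed: int) -> PatchMatrix:
    """Draw ``n`` Gaussian-random-field patches for one modality-A category."""
    if cfg.modality_tag != MODALITY_A:
        raise ParameterError("config is not modality A")
    _check_args(cfg, category, n)
    params = cfg.category_params[category]
    rng = _rng(cfg, category, seed)
    if np.isinf(params.correlation_length):
        field = np.repeat(rng.standard_normal((n, 1)), PATCH_DIM, axis=1)
    else:
        chol = _grf_cholesky(params)
        field = rng.standard_normal((n, PATCH_DIM)) @ chol.T
    if cfg.noise_sd > 0:
        field = field + cfg.noise_sd * rng.standard_normal((n, PATCH_DIM))
    return PatchMatrix(_rescale_rows(field), f"{_PREFIX[MODALITY_A]}:{category}", MODALITY_A)


def gen_audio_like_patches(cfg: SyntheticModalityConfig, category: int, n: int,
                           seed: int) -> PatchMatrix:
    """Draw ``n`` harmonic-stack spectrogram patches for one modality-B category."""
    if cfg.modality_tag != MODALITY_B:
        raise ParameterError("config is not modality B")
    _check_args(cfg, category, n)
    params = cfg.category_params[category]
    rng = _rng(cfg, category, seed)
    rows = params.harmonic_rows()
    weights = 1.0 / np.arange(1, len(rows) + 1)

    rho = params.smoothness
    eps = rng.standard_normal((n, PATCH_SIDE))
    env = np.empty_like(eps)
    env[:, 0] = eps[:, 0]
    for t in range(1, PATCH_SIDE):
        env[:, t] = rho * env[:, t - 1] + np.sqrt(1.0 - rho**2) * eps[:, t]
    amp = np.abs(env)  # nonnegative temporal envelope, stationary unit scale

    patches = np.zeros((n, PATCH_SIDE, PATCH_SIDE))
    for row, w in zip(rows, weights):
        patches[:, row, :] += w * amp
    if cfg.noise_sd > 0:
        patches = patches + cfg.noise_sd * rng.standard_normal(patches.shape)
    return PatchMatrix(_rescale_rows(patches.reshape(n, PATCH_DIM)),
                       f"{_PREFIX[MODALITY_B]}:{category}", MODALITY_B)


@dataclass
class SuiteEntry:
    dataset_id: str
    modality_tag: str
    patches: PatchMatrix


def default_configs(seed: int = 0, n_categories_a: int = 4, n_categories_b: int = 4,
                    noise_sd: float = 0.05) -> tuple[SyntheticModalityConfig, SyntheticModalityConfig]:
    """Desk-scale default: two modalities with clearly separated categories.

    Vision categories differ in correlation length plus one diagonally
    anisotropic texture (diagonal, so it cannot be mistaken for the
    horizontal row structure of modality B).  Audio categories spread
    their fundamentals widely so the coarse vertical energy distribution
    differs strongly between categories.
    """
    vision_params = [
        VisionCategoryParams(correlation_length=2.5),
        VisionCategoryParams(correlation_length=4.0),
        VisionCategoryParams(correlation_length=8.0),
        VisionCategoryParams(correlation_length=4.0, orientation=np.pi / 4, anisotropy=3.0),
        VisionCategoryParams(correlation_length=1.0),
    ][:n_categories_a]
    cfg_a = SyntheticModalityConfig(MODALITY_A, tuple(vision_params),
                                    noise_sd=noise_sd, seed=seed)
    audio_params = [
        AudioCategoryParams(fundamental_row=2, n_harmonics=5, smoothness=0.8),
        AudioCategoryParams(fundamental_row=4, n_harmonics=3, smoothness=0.5),
        AudioCategoryParams(fundamental_row=7, n_harmonics=2, smoothness=0.2),
        AudioCategoryParams(fundamental_row=11, n_harmonics=1, smoothness=0.65),
        AudioCategoryParams(fundamental_row=3, n_harmonics=4, smoothness=0.35),
    ][:n_categories_b]
    cfg_b = SyntheticModalityConfig(MODALITY_B, tuple(audio_params), noise_sd=noise_sd,
                                    seed=seed + 1)
    return cfg_a, cfg_b


def make_synthetic_suite(cfg_a: SyntheticModalityConfig, cfg_b: SyntheticModalityConfig,
                         n_patches_per_dataset: int) -> list[SuiteEntry]:
    """One labelled dataset per (modality, category); ids "sv:<i>" / "sa:<i>"."""
    if n_patches_per_dataset < 1:
        raise ParameterError("n_patches_per_dataset must be >= 1")
    entries = []
    for cfg, gen in ((cfg_a, gen_vision_like_patches), (cfg_b, gen_audio_like_patches)):
        for cat in range(cfg.n_categories):
            pm = gen(cfg, cat, n_patches_per_dataset, cfg.seed)
            entries.append(SuiteEntry(pm.source_dataset_id, cfg.modality_tag, pm))
    ids = [e.dataset_id for e in entries]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate dataset ids in suite")
    return entries


# ---------------------------------------------------------------------------
# HDF5 container (shared with patch_extraction output)

def save_suite(entries: list[SuiteEntry], path, extra_attrs: dict | None = None) -> None:
    """Write the suite to HDF5: one group per dataset plus a JSON manifest attr."""
    import h5py

    manifest = []
    with h5py.File(path, "w") as f:
        for entry in entries:
            grp = f.create_group(entry.dataset_id)
            grp.create_dataset("patches", data=entry.patches.values)
            grp.attrs["dataset_id"] = entry.dataset_id
            grp.attrs["modality_tag"] = entry.modality_tag
            for key, val in (extra_attrs or {}).items():
                grp.attrs[key] = val
            manifest.append({"dataset_id": entry.dataset_id,
                             "modality_tag": entry.modality_tag,
                             "n_patches": entry.patches.n_patches})
        f.attrs["manifest"] = json.dumps(manifest)


def load_suite(path) -> list[SuiteEntry]:
    import h5py

    entries = []
    with h5py.File(path, "r") as f:
        if "manifest" not in f.attrs:
            raise FormatError("suite container missing manifest attribute")
        for name in sorted(f.keys()):
            grp = f[name]
            for attr in ("dataset_id", "modality_tag"):
                if attr not in grp.attrs:
                    raise FormatError(f"group {name!r} missing attribute {attr!r}")
            pm = PatchMatrix(grp["patches"][...], str(grp.attrs["dataset_id"]),
                             str(grp.attrs["modality_tag"]))
            entries.append(SuiteEntry(pm.source_dataset_id, pm.modality_tag, pm))
    return entries


def config_dict(cfg: SyntheticModalityConfig) -> dict:
    """JSON-serializable dump of a modality config (for manifests)."""
    return asdict(cfg)
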