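"""Training-time image augmentation: flips, rotations, Gaussian noise and
hue / saturation / contrast / brightness transformations.

Every stochastic parameter is drawn from a (min, max) range; a range whose
endpoints coincide applies that exact value, and the default config (all
ranges degenerate at identity, flip probabilities 0) is a strict no-op.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import rotate as _rotate

from .errors import ParameterError

Range = tuple[float, float]


def _check_range(name: str, r: Range, lo: float | None = None) -> None:
    if len(r) != 2 or r[0] > r[1]:
        raise ParameterError(f"{name}={r!r} is not a (min, max) range")
    if lo is not None and r[0] < lo:
        raise ParameterError(f"{name}={r!r} below {lo}")


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation switches and ranges. Defaults are the identity."""

    flip_h: float = 0.0  # probability of a horizontal flip
    flip_v: float = 0.0  # probability of a vertical flip
    rot90: bool = False  # random rotation by a multiple of 90 degrees
    rotate_deg: Range = (0.0, 0.0)  # free-angle rotation range
    noise_sd: Range = (0.0, 0.0)  # additive Gaussian sd, 0-255 scale
    hue_deg: Range = (0.0, 0.0)  # hue rotation, degrees
    saturation: Range = (1.0, 1.0)  # multiplicative
    contrast: Range = (1.0, 1.0)  # multiplicative, about the patch mean
    brightness: Range = (1.0, 1.0)  # multiplicative

    def __post_init__(self):
        if not (0.0 <= self.flip_h <= 1.0 and 0.0 <= self.flip_v <= 1.0):
            raise ParameterError("flip probabilities must be in [0, 1]")
        _check_range("rotate_deg", self.rotate_deg)
        _check_range("noise_sd", self.noise_sd, lo=0.0)
        _check_range("hue_deg", self.hue_deg)
        _check_range("saturation", self.saturation, lo=0.0)
        _check_range("contrast", self.contrast, lo=0.0)
        _check_range("brightness", self.brightness, lo=0.0)

    @property
    def is_identity(self) -> bool:
        return (
            self.flip_h == 0.0
            and self.flip_v == 0.0
            and not self.rot90
            and self.rotate_deg == (0.0, 0.0)
            and self.noise_sd == (0.0, 0.0)
            and self.hue_deg == (0.0, 0.0)
            and self.saturation == (1.0, 1.0)
            and self.contrast == (1.0, 1.0)
            and self.brightness == (1.0, 1.0)
        )

    @classmethod
    def default_training(cls) -> "AugmentConfig":
        """The documented default profile used for classifier training.

        Geometric transforms are unrestricted (tissue has no canonical
        orientation); photometric ranges are kept moderate so augmentation
        widens, but does not erase, the inter-center appearance gap.
        """
        return cls(
            flip_h=0.5,
            flip_v=0.5,
            rot90=True,
            noise_sd=(0.0, 4.0),
            hue_deg=(-5.0, 5.0),
            saturation=(0.95, 1.05),
            contrast=(0.95, 1.05),
            brightness=(0.93, 1.07),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def augment(image: np.ndarray, cfg: AugmentConfig, seed: int) -> np.ndarray:
    """Apply one random draw of the configured transforms to an RGB uint8
    image. Deterministic for a fixed (image, cfg, seed); the identity
    config returns an unmodified copy."""
    if cfg.is_identity:
        return image.copy()
    rng = np.random.default_rng(seed)
    out = image.astype(np.float64)

    # geometric
    if cfg.flip_h > 0 and rng.random() < cfg.flip_h:
        out = out[:, ::-1]
    if cfg.flip_v > 0 and rng.random() < cfg.flip_v:
        out = out[::-1]
    if cfg.rot90:
        out = np.rot90(out, k=int(rng.integers(0, 4)))
    if cfg.rotate_deg != (0.0, 0.0):
        angle = float(rng.uniform(*cfg.rotate_deg))
        if angle != 0.0:
            out = _rotate(out / 255.0, angle, mode="reflect", order=1) * 255.0

    # photometric (hue/saturation through HSV; values stay float until the end)
    hue = float(rng.uniform(*cfg.hue_deg))
    sat = float(rng.uniform(*cfg.saturation))
    if hue != 0.0 or sat != 1.0:
        hsv = rgb2hsv(np.clip(out, 0, 255) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + hue / 360.0) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * sat, 0.0, 1.0)
        out = hsv2rgb(hsv) * 255.0
    contrast = float(rng.uniform(*cfg.contrast))
    if contrast != 1.0:
        out = (out - out.mean()) * contrast + out.mean()
    brightness = float(rng.uniform(*cfg.brightness))
    if brightness != 1.0:
        out = out * brightness
    sd = float(rng.uniform(*cfg.noise_sd))
    if sd > 0.0:
        out = out + rng.normal(0.0, sd, size=out.shape)

    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
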