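"""Calibrated center-surround grating stimuli.

Each stimulus is a 6-deg disc of sinusoidal grating on a mean-gray
background: a 0.7-deg central disc and a surrounding annulus whose stripe
orientations are equal (continuous stimulus, C) or orthogonal
(discontinuous, D).  The border between center and surround is sharp; the
exterior edge of the surround is smoothed over 0.25 deg.  Default geometry:
1.4 cycles/deg, Michelson contrast 0.99, phase 0, 40 pixels/deg -- the
center then spans 28 px and the surround 240 px.

Rendering assumes linearized luminance; the physical luminances of the
display (and their neutral-density-filtered scotopic values) travel as
sidecar metadata only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import imageio.v3 as iio
import numpy as np

#: nominal display luminances in cd/m^2 (black, gray, white), metadata only
NOMINAL_LUMINANCE = {
    "photopic": {"black": 0.0945, "gray": 45.0, "white": 85.92},
    "scotopic": {"black": 0.013e-4, "gray": 6.174e-4, "white": 11.701e-4},
}


@dataclass(frozen=True)
class StimulusSpec:
    center_diameter: float = 0.7  # deg
    surround_diameter: float = 6.0  # deg
    spatial_frequency: float = 1.4  # cycles/deg
    contrast: float = 0.99  # Michelson
    phase: float = 0.0  # radians
    edge_smoothing: float = 0.25  # deg
    pixels_per_degree: float = 40.0
    center_orientation: str = "vertical"
    surround_orientation: str = "vertical"

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")
        for name in ("center_orientation", "surround_orientation"):
            if getattr(self, name) not in ("vertical", "horizontal"):
                raise ValueError(f"{name} must be 'vertical' or 'horizontal'")

    @property
    def continuous(self) -> bool:
        return self.center_orientation == self.surround_orientation


def _grating(x: np.ndarray, y: np.ndarray, orientation: str, spec: StimulusSpec):
    # vertical stripes modulate along x, horizontal stripes along y
    coord = x if orientation == "vertical" else y
    return np.sin(2.0 * np.pi * spec.spatial_frequency * coord + spec.phase)


def render(spec: StimulusSpec) -> tuple[np.ndarray, dict]:
    """Render the stimulus to a float image in [0, 1] plus metadata.

    The image is square with side ``surround_diameter * pixels_per_degree``
    px, centered on the disc; mean gray is 0.5.  The exterior edge ramps
    the grating to the background with a raised cosine over
    ``edge_smoothing`` deg; the center-surround border is pixel-sharp.
    """
    cycles_in_center = spec.spatial_frequency * spec.center_diameter
    if cycles_in_center < 0.95:
        warnings.warn(
            f"only {cycles_in_center:.2f} grating cycles span the stimulus "
            "center; the center orientation may be ill-defined",
            UserWarning,
        )
    ppd = spec.pixels_per_degree
    n = int(round(spec.surround_diameter * ppd))
    c = (np.arange(n) - (n - 1) / 2.0) / ppd
    x, y = np.meshgrid(c, c)  # x varies along columns, y along rows
    r = np.hypot(x, y)

    center = r <= spec.center_diameter / 2.0
    grating = np.where(
        center,
        _grating(x, y, spec.center_orientation, spec),
        _grating(x, y, spec.surround_orientation, spec),
    )

    r_out = spec.surround_diameter / 2.0
    r_in = r_out - spec.edge_smoothing
    envelope = np.ones_like(r)
    ramp = (r > r_in) & (r <= r_out)
    envelope[ramp] = 0.5 * (1.0 + np.cos(np.pi * (r[ramp] - r_in) / spec.edge_smoothing))
    envelope[r > r_out] = 0.0

    image = 0.5 + 0.5 * spec.contrast * grating * envelope
    meta = {
        "spec": asdict(spec),
        "stimulus_type": "C" if spec.continuous else "D",
        "image_size_px": n,
        "center_diameter_px": spec.center_diameter * ppd,
        "surround_diameter_px": spec.surround_diameter * ppd,
        "luminance_assumption": "linearized display; image value 0.5 = mean gray",
        "nominal_luminance_cd_m2": NOMINAL_LUMINANCE,
    }
    return image, meta


def michelson_contrast(image: np.ndarray, spec: StimulusSpec) -> float:
    """Michelson contrast of the grating region, smoothed edge excluded."""
    n = image.shape[0]
    c = (np.arange(n) - (n - 1) / 2.0) / spec.pixels_per_degree
    x, y = np.meshgrid(c, c)
    r = np.hypot(x, y)
    core = image[r <= spec.surround_diameter / 2.0 - spec.edge_smoothing]
    lo, hi = core.min(), core.max()
    return float((hi - lo) / (hi + lo))


def save_png(image: np.ndarray, meta: dict, path) -> None:
    """Write the image as 8-bit PNG with a JSON metadata sidecar."""
    path = str(path)
    iio.imwrite(path, np.round(image * 255.0).astype(np.uint8))
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)
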