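"""Seeded synthetic SWIR phantom scenes with exact ground truth.

Each scene emulates one of the tissue-phantom geometries used to validate
subpixel target detection and spectral unmixing on agar ("collagen") phantoms
with embedded lard (lipid):

* ``SlabSeriesScene`` — homogeneous collagen slabs of increasing thickness in
  front of a bright background grid (the penetration-depth experiment).
* ``EmbeddedTargetScene`` — a rectangular lipid block buried at a given depth
  in a collagen slab (the depth-detection experiment).
* ``ConcentrationPanelsScene`` — side-by-side collagen panels at different
  mass concentrations, each pixel a linear mix of the 2 % and 5 % endpoint
  spectra (the concentration-unmixing experiment).
* ``SlopedWedgeScene`` — a lipid layer sloping linearly from the surface down
  to a maximum depth, so the lipid signal fades column by column (the
  depth-gradient unmixing experiment).

Optical forward model
---------------------
Light reaching a buried layer at depth ``z`` and returning to the sensor
traverses ``2 z`` of overlying medium, so the layer's contribution to the
pixel spectrum is weighted by ``f(z) = exp(-2 * mu_eff * z)`` with ``mu_eff``
an effective attenuation coefficient per mm; the remainder ``1 - f`` is the
overlying medium's own spectrum.  This is a deliberately simple
diffuse-reflectance heuristic, not radiative transfer: it preserves the
qualitative structure that matters for validating the analysis chain
(monotone signal loss with depth, exactly linear mixtures with known
abundances) while keeping every ground-truth quantity exact.

Noise is i.i.d. Gaussian per band in reflectance units, clipped so
reflectance stays nonnegative.  Identical ``(scene, seed)`` gives bit-identical
cubes; different seeds change only the noise, never the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cube import DEFAULT_WAVELENGTHS, SpectralCube
from .errors import SceneError
from .spectra import EndmemberSpectrum, collagen_at_concentration, constituent

#: Default effective attenuation, per mm.  Spans strong-to-faint targets over
#: the 7-68 mm depth range: f(7 mm) ~ 0.57 down to f(68 mm) ~ 0.004.
DEFAULT_MU_EFF = 0.04

#: Default per-band Gaussian noise, reflectance units.
DEFAULT_NOISE_SIGMA = 0.005


@dataclass
class Optics:
    """Forward-model knobs shared by every scene."""

    mu_eff: float = DEFAULT_MU_EFF          # effective attenuation [1/mm]
    noise_sigma: float = DEFAULT_NOISE_SIGMA  # per-band noise [reflectance]
    mixing: str = "linear_reflectance"       # or "beer_lambert" (panel spectra)

    def __post_init__(self) -> None:
        if self.mu_eff < 0:
            raise SceneError("mu_eff must be nonnegative")
        if self.noise_sigma < 0:
            raise SceneError("noise sigma must be nonnegative")
        if self.mixing not in ("linear_reflectance", "beer_lambert"):
            raise SceneError(f"unknown mixing mode {self.mixing!r}")

    def fraction(self, depth_mm: float | np.ndarray) -> float | np.ndarray:
        """Two-way attenuation weight ``exp(-2 mu_eff z)`` of a buried layer."""
        return np.exp(-2.0 * self.mu_eff * np.asarray(depth_mm, dtype=np.float64))


@dataclass
class GroundTruth:
    """Exact per-scene truth: a target mask and/or true abundance planes."""

    mask: np.ndarray | None = None            # boolean H x W
    abundance: np.ndarray | None = None       # H x W x p, rows sum to 1
    endmember_names: tuple[str, ...] = ()
    column_depth_mm: np.ndarray | None = None  # wedge only: depth per column
    column_fraction: np.ndarray | None = None  # wedge only: f(z) per column
    panel_concentration: np.ndarray | None = None  # panels only: % per column

    def __post_init__(self) -> None:
        if self.abundance is not None:
            sums = self.abundance.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-12):
                raise SceneError("true abundance rows must sum to 1")


def _add_noise(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return clean
    noisy = clean + rng.normal(0.0, sigma, size=clean.shape)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# slab series (penetration experiment)
# ---------------------------------------------------------------------------

@dataclass
class SlabSeriesScene:
    """Collagen slabs of increasing thickness over a reflective grid pattern.

    Each pixel spectrum is ``grid(x, y) * slab(lambda) * exp(-2 mu_eff d)``:
    the background grid modulates brightness, the slab spectrum shapes the
    bands, and the two-way attenuation dims everything as thickness grows.
    """

    thicknesses_mm: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 60.0, 80.0)
    shape: tuple[int, int] = (120, 120)
    grid_period_px: int = 20
    grid_width_px: int = 3
    grid_bright: float = 1.0
    grid_dark: float = 0.5
    optics: Optics = field(default_factory=Optics)
    seed: int = 0
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        t = np.asarray(self.thicknesses_mm, dtype=np.float64)
        if t.size == 0 or np.any(t <= 0):
            raise SceneError("thicknesses must be positive")
        if np.any(np.diff(t) <= 0):
            raise SceneError("thicknesses must be strictly increasing")

    def grid_pattern(self) -> np.ndarray:
        h, w = self.shape
        rows = np.arange(h) % self.grid_period_px < self.grid_width_px
        cols = np.arange(w) % self.grid_period_px < self.grid_width_px
        on_line = rows[:, None] | cols[None, :]
        return np.where(on_line, self.grid_bright, self.grid_dark)


def simulate_slab_series(scene: SlabSeriesScene) -> list[tuple[float, SpectralCube]]:
    """One cube per slab thickness; thicker slabs are strictly dimmer wherever
    ``mu_eff > 0``."""
    slab = constituent("collagen", scene.wavelengths).reflectance
    grid = scene.grid_pattern()
    rng = np.random.default_rng(scene.seed)
    out = []
    for d in scene.thicknesses_mm:
        clean = grid[:, :, None] * slab[None, None, :] * scene.optics.fraction(d)
        noisy = _add_noise(clean, scene.optics.noise_sigma, rng)
        out.append((float(d), SpectralCube(data=noisy, wavelengths=scene.wavelengths)))
    return out


# ---------------------------------------------------------------------------
# embedded target (depth-detection experiment)
# ---------------------------------------------------------------------------

@dataclass
class EmbeddedTargetScene:
    """A lipid block buried at ``depth_mm`` in a uniform collagen slab.

    Target pixels carry ``f * lipid + (1 - f) * collagen`` with
    ``f = exp(-2 mu_eff depth)``; the mixing fraction can also be pinned
    directly via ``fraction`` to study detection limits independent of the
    optics.  Background pixels are pure collagen.  The ground-truth mask marks
    the block, boundary pixels included.
    """

    depth_mm: float = 20.0
    fraction: float | None = None
    shape: tuple[int, int] = (120, 120)
    target_shape: tuple[int, int] = (40, 40)
    target_origin: tuple[int, int] | None = None   # default: centred
    optics: Optics = field(default_factory=Optics)
    seed: int = 0
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        if self.depth_mm < 0:
            raise SceneError("depth must be nonnegative")
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise SceneError("mixing fraction must lie in [0, 1]")
        h, w = self.shape
        th, tw = self.target_shape
        r0, c0 = self.origin()
        if r0 < 0 or c0 < 0 or r0 + th > h or c0 + tw > w:
            raise SceneError("target block exceeds image bounds")

    def origin(self) -> tuple[int, int]:
        if self.target_origin is not None:
            return self.target_origin
        return ((self.shape[0] - self.target_shape[0]) // 2,
                (self.shape[1] - self.target_shape[1]) // 2)

    def mixing_fraction(self) -> float:
        if self.fraction is not None:
            return float(self.fraction)
        return float(self.optics.fraction(self.depth_mm))


def simulate_embedded_target(scene: EmbeddedTargetScene) -> tuple[SpectralCube, GroundTruth]:
    lipid = constituent("lipid", scene.wavelengths).reflectance
    collagen = constituent("collagen", scene.wavelengths).reflectance
    f = scene.mixing_fraction()

    h, w = scene.shape
    clean = np.broadcast_to(collagen, (h, w, collagen.size)).copy()
    mask = np.zeros((h, w), dtype=bool)
    r0, c0 = scene.origin()
    th, tw = scene.target_shape
    mask[r0:r0 + th, c0:c0 + tw] = True
    clean[mask] = f * lipid + (1.0 - f) * collagen

    rng = np.random.default_rng(scene.seed)
    noisy = _add_noise(clean, scene.optics.noise_sigma, rng)

    abundance = np.zeros((h, w, 2))
    abundance[:, :, 1] = 1.0
    abundance[mask, 0] = f
    abundance[mask, 1] = 1.0 - f
    gt = GroundTruth(mask=mask, abundance=abundance, endmember_names=("lipid", "collagen"))
    return SpectralCube(data=noisy, wavelengths=scene.wavelengths), gt


# ---------------------------------------------------------------------------
# concentration panels (unmixing experiment 1)
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationPanelsScene:
    """Vertical collagen panels at different mass concentrations.

    Every pixel in the panel at concentration ``c`` is the linear mixture
    ``a1 * S(2%) + a2 * S(5%)`` with ``a1 = (5 - c) / 3``, so the 2 % and 5 %
    endpoint spectra are exact endmembers and the true abundances are known in
    closed form.  The endpoint spectra themselves come from Beer-Lambert
    scaling of the base collagen spectrum.
    """

    concentrations: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    panel_shape: tuple[int, int] = (30, 30)   # (rows, cols) per panel
    reference_concentration: float = 4.0
    optics: Optics = field(default_factory=lambda: Optics(noise_sigma=0.002))
    seed: int = 0
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=np.float64)
        if c.size < 2:
            raise SceneError("need at least two panels")
        if np.any(c < 2.0) or np.any(c > 5.0):
            raise SceneError("panel concentrations must lie in [2, 5] %")
        if min(self.panel_shape) < 1:
            raise SceneError("panel must be at least 1 px wide")

    def endpoint_spectra(self) -> tuple[EndmemberSpectrum, EndmemberSpectrum]:
        base = constituent("collagen", self.wavelengths)
        lo = collagen_at_concentration(base, 2.0, self.reference_concentration)
        hi = collagen_at_concentration(base, 5.0, self.reference_concentration)
        return lo, hi


def simulate_concentration_panels(
    scene: ConcentrationPanelsScene,
) -> tuple[SpectralCube, GroundTruth]:
    lo, hi = scene.endpoint_spectra()
    rows, pw = scene.panel_shape
    n = len(scene.concentrations)
    w = pw * n
    b = scene.wavelengths.size

    clean = np.empty((rows, w, b))
    abundance = np.empty((rows, w, 2))
    panel_conc = np.empty(w)
    for k, c in enumerate(scene.concentrations):
        a1 = (5.0 - c) / 3.0
        spec = a1 * lo.reflectance + (1.0 - a1) * hi.reflectance
        clean[:, k * pw:(k + 1) * pw, :] = spec
        abundance[:, k * pw:(k + 1) * pw, 0] = a1
        abundance[:, k * pw:(k + 1) * pw, 1] = 1.0 - a1
        panel_conc[k * pw:(k + 1) * pw] = c

    rng = np.random.default_rng(scene.seed)
    noisy = _add_noise(clean, scene.optics.noise_sigma, rng)
    gt = GroundTruth(
        abundance=abundance,
        endmember_names=(lo.name, hi.name),
        panel_concentration=panel_conc,
    )
    return SpectralCube(data=noisy, wavelengths=scene.wavelengths), gt


# ---------------------------------------------------------------------------
# sloped wedge (unmixing experiment 2)
# ---------------------------------------------------------------------------

@dataclass
class SlopedWedgeScene:
    """Lipid layer sloping from the surface to ``max_depth_mm``.

    The lipid depth under column ``j`` is ``z(j) = j * pitch * tan(slope)``,
    clipped at the maximum depth; by default the pixel pitch is chosen so the
    last column reaches exactly ``max_depth_mm``.  Column spectra are
    ``f(z) * lipid + (1 - f(z)) * collagen`` with ``f = exp(-2 mu_eff z)``.
    """

    n_cols: int = 80
    n_rows: int = 120
    slope_deg: float = 28.25
    max_depth_mm: float = 40.0
    pixel_pitch_mm: float | None = None
    optics: Optics = field(default_factory=Optics)
    seed: int = 0
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        if self.n_cols < 2:
            raise SceneError("wedge needs at least two columns")
        if not 0.0 < self.slope_deg < 90.0:
            raise SceneError("slope must lie in (0, 90) degrees")
        if self.max_depth_mm <= 0:
            raise SceneError("max depth must be positive")

    def pitch(self) -> float:
        if self.pixel_pitch_mm is not None:
            return float(self.pixel_pitch_mm)
        return self.max_depth_mm / (np.tan(np.radians(self.slope_deg)) * (self.n_cols - 1))

    def column_depths(self) -> np.ndarray:
        z = np.arange(self.n_cols) * self.pitch() * np.tan(np.radians(self.slope_deg))
        return np.minimum(z, self.max_depth_mm)


def simulate_sloped_wedge(scene: SlopedWedgeScene) -> tuple[SpectralCube, GroundTruth]:
    lipid = constituent("lipid", scene.wavelengths).reflectance
    collagen = constituent("collagen", scene.wavelengths).reflectance
    z = scene.column_depths()
    f = np.asarray(scene.optics.fraction(z))

    clean = f[None, :, None] * lipid + (1.0 - f)[None, :, None] * collagen
    clean = np.broadcast_to(clean, (scene.n_rows, scene.n_cols, lipid.size)).copy()
    rng = np.random.default_rng(scene.seed)
    noisy = _add_noise(clean, scene.optics.noise_sigma, rng)

    abundance = np.empty((scene.n_rows, scene.n_cols, 2))
    abundance[:, :, 0] = f[None, :]
    abundance[:, :, 1] = 1.0 - f[None, :]
    gt = GroundTruth(
        abundance=abundance,
        endmember_names=("lipid", "collagen"),
        column_depth_mm=z,
        column_fraction=f,
    )
    return SpectralCube(data=noisy, wavelengths=scene.wavelengths), gt


# ---------------------------------------------------------------------------
# config-file dispatch (used by the CLI)
# ---------------------------------------------------------------------------

_SCENES = {
    "slab_series": SlabSeriesScene,
    "embedded_target": EmbeddedTargetScene,
    "concentration_panels": ConcentrationPanelsScene,
    "sloped_wedge": SlopedWedgeScene,
}

_SIMULATORS = {
    "slab_series": simulate_slab_series,
    "embedded_target": simulate_embedded_target,
    "concentration_panels": simulate_concentration_panels,
    "sloped_wedge": simulate_sloped_wedge,
}


def scene_from_config(config: dict):
    """Build a scene dataclass from a flat config mapping.

    The mapping must carry ``geometry``; optics keys (``mu_eff``,
    ``noise_sigma``, ``mixing``) are grouped into :class:`Optics`.  Unknown
    keys are rejected so typos never silently fall back to defaults.
    """
    cfg = dict(config)
    geometry = cfg.pop("geometry", None)
    if geometry not in _SCENES:
        raise SceneError(f"unknown or missing geometry {geometry!r}; options: {sorted(_SCENES)}")
    cls = _SCENES[geometry]

    optics_keys = {k: cfg.pop(k) for k in ("mu_eff", "noise_sigma", "mixing") if k in cfg}
    fields_ok = {f for f in cls.__dataclass_fields__}
    # tuples arrive from TOML as lists
    for key in list(cfg):
        if isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    unknown = set(cfg) - fields_ok
    if unknown:
        raise SceneError(f"unknown scene key(s) for {geometry}: {sorted(unknown)}")
    if optics_keys:
        if geometry == "concentration_panels":
            optics_keys.setdefault("noise_sigma", 0.002)
        cfg["optics"] = Optics(**optics_keys)
    return cls(**cfg)


def simulate(scene):
    """Dispatch a scene dataclass to its simulator."""
    for name, cls in _SCENES.items():
        if isinstance(scene, cls):
            return _SIMULATORS[name](scene)
    raise SceneError(f"not a phantom scene: {type(scene).__name__}")
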