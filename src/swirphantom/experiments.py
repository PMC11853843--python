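"""End-to-end validation pipelines on synthetic phantom scenes.

Four pipelines mirror the phantom validation studies:

* depth detection  — CEM + Otsu on embedded lipid targets at several depths,
  scored with the Tanimoto index against the ground-truth block mask;
* concentration unmixing — FCLS on side-by-side collagen panels, panel-mean
  abundances regressed against the true concentrations (R^2);
* slope unmixing   — FCLS on the sloped lipid wedge, column-mean endmember
  fractions correlated with column depth (Spearman rho at marker depths);
* penetration      — mean reflectance at the 1073 nm band versus slab
  thickness, plus NIR-II pseudocolor renders.

Every pipeline is deterministic given its scene parameters and seed; per-depth
sub-scenes get independent child seeds spawned from the pipeline seed so runs
are reproducible yet statistically independent across scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats

from .cube import nearest_band, pseudocolor
from .detection import cem_detect, otsu_threshold, tanimoto_index
from .errors import OutOfRangeError, SwirPhantomError
from .phantom import (
    EmbeddedTargetScene,
    ConcentrationPanelsScene,
    SlabSeriesScene,
    SlopedWedgeScene,
    simulate_concentration_panels,
    simulate_embedded_target,
    simulate_slab_series,
    simulate_sloped_wedge,
)
from .spectra import constituent
from .unmixing import select_endmembers_from_image, unmix_cube

#: Lard embedding depths (mm) of the depth-detection phantom series.
DEFAULT_DEPTHS_MM = (7.0, 15.0, 20.0, 55.0, 60.0, 68.0)

#: Marker depths (cm) at which wedge correlations are reported.
DEFAULT_MARKER_DEPTHS_CM = (1.0, 2.0, 3.0, 4.0)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived deterministically from ``seed``."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# depth detection
# ---------------------------------------------------------------------------

@dataclass
class DepthDetectionResult:
    """One row per depth: Tanimoto index of CEM+Otsu detection vs. truth."""

    rows: pd.DataFrame   # depth_mm, fraction, threshold, ti, ti_interior
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return self.rows.copy()


def boundary_ring(mask: np.ndarray) -> np.ndarray:
    """1-pixel ring straddling the mask boundary (inner + outer shell).

    Detection errors concentrate at the target/background boundary, so the
    pipeline also reports the index with this ring excluded.
    """
    dil = scipy.ndimage.binary_dilation(mask)
    ero = scipy.ndimage.binary_erosion(mask)
    return dil & ~ero


def run_depth_experiment(
    depths_mm=DEFAULT_DEPTHS_MM,
    scene: EmbeddedTargetScene | None = None,
    seed: int = 0,
) -> DepthDetectionResult:
    """CEM + Otsu + Tanimoto for an embedded lipid target at each depth.

    The CEM signature is the simulator's pure lipid spectrum.  A depth whose
    detection fails (e.g. Otsu on a pathological map) is recorded as NaN
    rather than aborting the sweep.
    """
    base = scene if scene is not None else EmbeddedTargetScene()
    records = []
    for depth, child in zip(depths_mm, _child_seeds(seed, len(depths_mm))):
        sc = replace(base, depth_mm=float(depth), fraction=None, seed=child)
        try:
            cube, gt = simulate_embedded_target(sc)
            d = constituent("lipid", sc.wavelengths).reflectance
            amap, _ = cem_detect(cube, d)
            threshold, mask = otsu_threshold(amap)
            ti = tanimoto_index(mask, gt.mask)
            keep = ~boundary_ring(gt.mask)
            ti_interior = tanimoto_index(mask[keep], gt.mask[keep])
            records.append(
                dict(depth_mm=depth, fraction=sc.mixing_fraction(),
                     threshold=threshold, ti=ti, ti_interior=ti_interior)
            )
        except SwirPhantomError as exc:
            records.append(
                dict(depth_mm=depth, fraction=np.nan, threshold=np.nan,
                     ti=np.nan, ti_interior=np.nan, error=str(exc))
            )
    return DepthDetectionResult(rows=pd.DataFrame.from_records(records), seed=seed)


def detect_embedded_target(scene: EmbeddedTargetScene):
    """Single-scene CEM + Otsu + Tanimoto; returns (ti, threshold, mask, gt)."""
    cube, gt = simulate_embedded_target(scene)
    d = constituent("lipid", scene.wavelengths).reflectance
    amap, _ = cem_detect(cube, d)
    threshold, mask = otsu_threshold(amap)
    return tanimoto_index(mask, gt.mask), threshold, mask, gt


# ---------------------------------------------------------------------------
# concentration unmixing
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationUnmixResult:
    """Panel-mean FCLS abundances and their agreement with concentration."""

    panels: pd.DataFrame     # concentration, alpha1_mean, alpha2_mean
    r_squared: float         # squared Pearson r of alpha2 vs concentration
    endmember_source: str
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        df = self.panels.copy()
        df.attrs["r_squared"] = self.r_squared
        return df


def run_concentration_experiment(
    concentrations=(2.0, 3.0, 4.0, 5.0),
    scene: ConcentrationPanelsScene | None = None,
    seed: int = 0,
) -> ConcentrationUnmixResult:
    """FCLS on the concentration panels with in-image endpoint endmembers.

    Endmember 1 is the mean spectrum of the lowest-concentration panel,
    endmember 2 the mean of the highest; R^2 is the squared Pearson
    correlation between panel-mean endmember-2 abundance and the true
    concentrations (a 4-point linear-trend summary, not per-pixel).
    """
    conc = tuple(float(c) for c in concentrations)
    if len(set(conc)) < 3:
        raise SwirPhantomError("R^2 needs at least three distinct concentrations")
    base = scene if scene is not None else ConcentrationPanelsScene()
    sc = replace(base, concentrations=conc, seed=seed)
    cube, gt = simulate_concentration_panels(sc)

    pw = sc.panel_shape[1]
    lo_panel = np.s_[:, 0:pw]
    hi_panel = np.s_[:, (len(conc) - 1) * pw:len(conc) * pw]
    M = select_endmembers_from_image(
        cube, [lo_panel, hi_panel],
        names=(f"collagen_{min(conc):g}pct", f"collagen_{max(conc):g}pct"),
    )
    planes = unmix_cube(cube, M, model="FCLS")

    records = []
    for k, c in enumerate(conc):
        sl = np.s_[:, k * pw:(k + 1) * pw]
        records.append(
            dict(concentration=c,
                 alpha1_mean=float(planes[sl + (0,)].mean()),
                 alpha2_mean=float(planes[sl + (1,)].mean()))
        )
    panels = pd.DataFrame.from_records(records)
    r = scipy.stats.pearsonr(panels["alpha2_mean"], panels["concentration"]).statistic
    return ConcentrationUnmixResult(
        panels=panels, r_squared=float(r**2),
        endmember_source="panel means (extreme concentrations)", seed=seed,
    )


# ---------------------------------------------------------------------------
# slope unmixing
# ---------------------------------------------------------------------------

@dataclass
class SlopeUnmixResult:
    """Column-mean endmember fractions on the wedge and their depth trend."""

    columns: pd.DataFrame    # depth_mm, frac1, frac2 per image column
    markers: pd.DataFrame    # depth_cm, frac1, frac2, rho1, rho2
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return self.markers.copy()


def run_slope_experiment(
    scene: SlopedWedgeScene | None = None,
    marker_depths_cm=DEFAULT_MARKER_DEPTHS_CM,
    seed: int = 0,
) -> SlopeUnmixResult:
    """FCLS on the sloped wedge with shallowest/deepest columns as endmembers.

    Column-mean fractions are correlated with column depth by Spearman rank
    correlation, computed cumulatively over all columns from the surface down
    to each marker depth.  When fractions sum to one per column the two
    endmembers' correlations are exact negatives of each other.
    """
    base = scene if scene is not None else SlopedWedgeScene()
    sc = replace(base, seed=seed)
    cube, gt = simulate_sloped_wedge(sc)
    z = gt.column_depth_mm

    M = select_endmembers_from_image(
        cube, [np.s_[:, 0:1], np.s_[:, -1:]], names=("lipid_shallow", "collagen_deep")
    )
    planes = unmix_cube(cube, M, model="FCLS")
    frac = planes.mean(axis=0)   # n_cols x 2 column means

    columns = pd.DataFrame(
        dict(depth_mm=z, frac1=frac[:, 0], frac2=frac[:, 1])
    )

    records = []
    for depth_cm in marker_depths_cm:
        depth_mm = float(depth_cm) * 10.0
        if depth_mm <= 0 or depth_mm > z.max() + 1e-9:
            raise OutOfRangeError(
                f"marker depth {depth_cm:g} cm beyond the wedge ({z.max() / 10:g} cm)"
            )
        sel = z <= depth_mm + 1e-9
        if sel.sum() < 2:
            raise OutOfRangeError(f"fewer than two columns above {depth_cm:g} cm")
        rho1 = scipy.stats.spearmanr(z[sel], frac[sel, 0]).statistic
        rho2 = scipy.stats.spearmanr(z[sel], frac[sel, 1]).statistic
        at = int(np.argmin(np.abs(z - depth_mm)))
        records.append(
            dict(depth_cm=float(depth_cm), frac1=frac[at, 0], frac2=frac[at, 1],
                 rho1=float(rho1), rho2=float(rho2))
        )
    return SlopeUnmixResult(
        columns=columns, markers=pd.DataFrame.from_records(records), seed=seed
    )


# ---------------------------------------------------------------------------
# penetration
# ---------------------------------------------------------------------------

@dataclass
class PenetrationResult:
    """Mean reflectance at the 1073 nm band per slab thickness."""

    rows: pd.DataFrame            # thickness_mm, mean_reflectance_1073nm
    pseudocolor: dict[float, np.ndarray] = field(default_factory=dict, repr=False)
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return self.rows.copy()


def run_penetration_experiment(
    thicknesses_mm=(10.0, 20.0, 30.0, 40.0, 60.0, 80.0),
    scene: SlabSeriesScene | None = None,
    seed: int = 0,
    render_pseudocolor: bool = True,
) -> PenetrationResult:
    """Slab-series sweep: deeper slabs return less light at 1073 nm.

    The 1073 nm band sits where water absorption is locally low and collagen
    absorption locally high, making its reflectance a sensitive thickness
    probe; the NIR-II pseudocolor composites are rendered alongside.
    """
    base = scene if scene is not None else SlabSeriesScene()
    sc = replace(base, thicknesses_mm=tuple(float(t) for t in thicknesses_mm), seed=seed)
    cubes = simulate_slab_series(sc)
    records, renders = [], {}
    for thickness, cube in cubes:
        band = nearest_band(cube, 1073.0)
        records.append(
            dict(thickness_mm=thickness,
                 mean_reflectance_1073nm=float(cube.data[:, :, band].mean()))
        )
        if render_pseudocolor:
            renders[thickness] = pseudocolor(cube)
    return PenetrationResult(
        rows=pd.DataFrame.from_records(records), pseudocolor=renders, seed=seed
    )
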