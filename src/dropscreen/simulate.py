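"""Synthetic inputs for the droplet-screening pipeline, with ground truth.

Every input the analysis consumes can be generated here: bright-field-style
droplet micrographs rendered at a known cell-occupancy percentage,
Poisson-loaded droplet populations with strain-specific growth and
fluorescence development, paired pre/post-sort OTU count tables with known
per-OTU enrichment factors, OD600 growth time courses, and linear standard
curves. All generators are deterministic for a fixed seed (one global seed
fans out to per-component substreams), so identical calls are bit-identical.

Rendering model: a light oil background, a dark circular interface ring at
the droplet boundary, and the aqueous lumen at background brightness with
cells drawn as dark, non-overlapping blobs grown to an exact pixel count.
Realistic optics (point-spread, shading, polydispersity) are deliberately
not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .growth import GrowthSeries, baranyi_log_od
from .occupancy import DropletImage, OccupancyMeasurement

__all__ = [
    "ImageSpec",
    "StrainParams",
    "ScreenScenario",
    "EnrichmentScenario",
    "OccupancyUnreachableError",
    "default_image_spec",
    "model_strains",
    "generate_droplet_image",
    "generate_calibration_series",
    "generate_screen_population",
    "generate_otu_tables",
    "enrichment_split_scenario",
    "generate_growth_series",
    "generate_standard_curve_data",
]

#: width of the rendered oil-water interface ring, px
RIM_WIDTH_PX = 2


class OccupancyUnreachableError(ValueError):
    """The requested occupancy cannot be rendered with the given blobs."""


@dataclass(frozen=True)
class ImageSpec:
    """Rendering parameters for one droplet micrograph."""

    width_px: int = 160
    height_px: int = 160
    um_per_px: float = 1.0
    droplet_diameter_um: float = 120.0
    background_level: float = 0.92
    cell_level: float = 0.30
    noise_sd: float = 0.02

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if not (0 <= self.background_level <= 1 and 0 <= self.cell_level <= 1):
            raise ValueError("intensity levels must lie in [0, 1]")
        if self.background_level == self.cell_level:
            raise ValueError("background and cell levels must differ")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        r = 0.5 * self.droplet_diameter_um / self.um_per_px
        if 2 * (r + 2) > min(self.width_px, self.height_px):
            raise ValueError("droplet does not fit fully inside the frame")

    @property
    def outer_radius_px(self) -> float:
        return 0.5 * self.droplet_diameter_um / self.um_per_px

    @property
    def lumen_radius_px(self) -> float:
        return self.outer_radius_px - RIM_WIDTH_PX


def default_image_spec(**overrides) -> ImageSpec:
    """The default 120-um droplet imaging scenario."""
    return ImageSpec(**overrides)


@dataclass(frozen=True)
class StrainParams:
    """Growth and fluorescence parameters of one strain.

    ``fluor_rate`` is the fluorescence produced per unit (OD x hour) of
    cumulative biomass exposure, modelling secreted-protease substrate
    turnover.
    """

    name: str
    lag_h: float
    mu_max_per_h: float
    y0_od: float
    ymax_od: float
    fluor_rate: float

    def __post_init__(self):
        vals = (self.lag_h, self.mu_max_per_h, self.y0_od, self.ymax_od,
                self.fluor_rate)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all strain parameters must be finite")
        if self.lag_h < 0 or self.mu_max_per_h < 0 or self.fluor_rate < 0:
            raise ValueError("rates and lag must be non-negative")
        if self.y0_od <= 0 or self.ymax_od <= self.y0_od:
            raise ValueError("need 0 < y0_od < ymax_od")


def model_strains() -> dict[str, StrainParams]:
    """The two model organisms used to validate the screen.

    A high-protease producer (P. mexicana-like; 8.9 h lag in droplet
    culture, strong fluorescence development) and a low-protease model
    organism (E. coli-like).
    """
    return {
        "P_mexicana": StrainParams(
            name="P_mexicana", lag_h=8.9, mu_max_per_h=0.55,
            y0_od=0.005, ymax_od=2.0, fluor_rate=60.0,
        ),
        "E_coli": StrainParams(
            name="E_coli", lag_h=3.0, mu_max_per_h=0.80,
            y0_od=0.005, ymax_od=1.5, fluor_rate=6.0,
        ),
    }


# ---------------------------------------------------------------------------
# droplet image rendering


def _disk_mask(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def _adjust_mask_to_count(mask, allowed, target, rng):
    """Grow/trim a blob mask to an exact pixel count inside ``allowed``."""
    count = int(mask.sum())
    while count < target:
        frontier = ndimage.binary_dilation(mask) & allowed & ~mask
        if count == 0 and not mask.any():
            frontier = allowed
        n_frontier = int(frontier.sum())
        if n_frontier == 0:
            raise OccupancyUnreachableError(
                "cannot grow blobs to the requested occupancy"
            )
        need = target - count
        if need >= n_frontier:
            mask |= frontier
            count += n_frontier
        else:
            idx = np.flatnonzero(frontier.ravel())
            pick = rng.choice(idx, size=need, replace=False)
            mask.ravel()[pick] = True
            count = target
    while count > target:
        boundary = mask & ~ndimage.binary_erosion(mask)
        idx = np.flatnonzero(boundary.ravel())
        drop = rng.choice(idx, size=min(count - target, len(idx)), replace=False)
        mask.ravel()[drop] = False
        count = int(mask.sum())
    return mask


def _render_cell_mask(spec: ImageSpec, target_pct: float, n_blobs: int, rng):
    h, w = spec.height_px, spec.width_px
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    r_lumen = spec.lumen_radius_px
    lumen = _disk_mask(h, w, cx, cy, r_lumen)
    a_droplet = int(lumen.sum())
    target_px = int(round(target_pct / 100.0 * a_droplet))
    mask = np.zeros((h, w), dtype=bool)
    if target_px == 0:
        return mask, lumen, a_droplet
    if n_blobs < 1:
        raise OccupancyUnreachableError("need at least one blob for occupancy > 0")
    # keep blobs clear of the interface ring so it stays a separable object,
    # unless the target is too high for that to be possible
    gap = 2
    grow_region = _disk_mask(h, w, cx, cy, r_lumen - gap)
    if target_px > int(grow_region.sum()):
        grow_region = lumen
    r_blob = max(2.0, math.sqrt(target_px / (n_blobs * math.pi)))
    # seeds must pack without overlap; cap them at ~25% of the growth region
    # and let the exact-count growth step supply the remaining area
    r_pack = math.sqrt(0.25 * float(grow_region.sum()) / (n_blobs * math.pi))
    r_seed = max(2.0, min(r_blob, r_pack, r_lumen - gap - 1))
    centers: list[tuple[float, float]] = []
    max_attempts = 400 * n_blobs
    attempts = 0
    while len(centers) < n_blobs and attempts < max_attempts:
        attempts += 1
        ang = rng.uniform(0, 2 * math.pi)
        rad = (r_lumen - gap - r_seed) * math.sqrt(rng.uniform())
        px_, py_ = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
        if all((px_ - a) ** 2 + (py_ - b) ** 2 > (2 * r_seed + 1) ** 2
               for a, b in centers):
            centers.append((px_, py_))
    if len(centers) < n_blobs:
        raise OccupancyUnreachableError(
            f"could not place {n_blobs} non-overlapping blobs "
            f"(placed {len(centers)} after {attempts} attempts)"
        )
    for a, b in centers:
        mask |= _disk_mask(h, w, a, b, r_seed)
    mask &= grow_region
    mask = _adjust_mask_to_count(mask, grow_region, target_px, rng)
    return mask, lumen, a_droplet


def generate_droplet_image(
    spec: ImageSpec, target_occupancy_pct: float, n_blobs: int, seed: int
) -> tuple[DropletImage, OccupancyMeasurement]:
    """Render one droplet micrograph at an exact cell occupancy.

    The cell mask is grown to the pixel count matching
    ``target_occupancy_pct`` of the lumen area (so the rendered, pre-noise
    occupancy matches the target to well within 0.5 percentage points), then
    the frame is composited and Gaussian noise added. Returns the image and
    the exact rendered ground truth.
    """
    if not 0 <= target_occupancy_pct <= 100:
        raise ValueError("target occupancy must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    h, w = spec.height_px, spec.width_px
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    mask, lumen, a_droplet = _render_cell_mask(
        spec, target_occupancy_pct, n_blobs, rng
    )
    img = np.full((h, w), spec.background_level, dtype=float)
    ring = _disk_mask(h, w, cx, cy, spec.outer_radius_px) & ~lumen
    img[ring] = spec.cell_level
    img[mask] = spec.cell_level
    if spec.noise_sd > 0:
        img = np.clip(img + rng.normal(0, spec.noise_sd, img.shape), 0.0, 1.0)
    n_cells = int(mask.sum())
    truth = OccupancyMeasurement(
        a_droplet_px=float(a_droplet),
        a_ex_px=float(a_droplet - n_cells),
        occupancy_pct=n_cells / a_droplet * 100.0,
    )
    return DropletImage(pixels=img, um_per_px=spec.um_per_px), truth


def generate_calibration_series(
    spec: ImageSpec,
    od_values,
    occupancy_per_od: float,
    noise_sd: float | None = None,
    seed: int = 0,
) -> list[tuple[DropletImage, float]]:
    """Droplet images of cultures at known OD600, for calibration fitting.

    Each image's target occupancy is ``occupancy_per_od * OD`` — linear by
    construction, emulating droplets sealed with medium of known OD600.
    """
    od_values = list(od_values)
    if any(od < 0 for od in od_values):
        raise ValueError("OD values must be non-negative")
    if od_values and occupancy_per_od * max(od_values) > 100:
        raise ValueError("requested occupancy exceeds 100%: lower occupancy_per_od")
    if noise_sd is not None:
        spec = ImageSpec(**{**spec.__dict__, "noise_sd": noise_sd})
    out = []
    child_seeds = np.random.SeedSequence(seed).generate_state(max(len(od_values), 1))
    for od, s in zip(od_values, child_seeds):
        target = occupancy_per_od * od
        n_blobs = max(3, int(round(target / 5.0)))
        img, _ = generate_droplet_image(spec, target, n_blobs, int(s % 2**31))
        out.append((img, float(od)))
    return out


# ---------------------------------------------------------------------------
# screening populations


@dataclass(frozen=True)
class ScreenScenario:
    """A droplet-screen simulation: loading, culture time and baseline.

    Baseline (empty-droplet) fluorescence is lognormal; the defaults put the
    mode of the intensity histogram in the 10-20 band seen for droplets
    without microbial growth.
    """

    n_droplets: int
    lambdas: dict[str, float]
    culture_time_h: float = 72.0
    empty_fluor_loc: float = math.log(14.0)
    empty_fluor_scale: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        total = sum(self.lambdas.values())
        if not math.isfinite(total) or any(v < 0 for v in self.lambdas.values()):
            raise ValueError("lambdas must be finite and >= 0")
        if self.empty_fluor_scale <= 0:
            raise ValueError("baseline scale must be positive")


def _fluorescence_per_count(strain: StrainParams, max_count: int,
                            culture_time_h: float) -> np.ndarray:
    """Fluorescence accrued by k co-encapsulated cells, k = 0..max_count.

    The droplet culture starts at k times the single-cell inoculum density
    and follows the Baranyi trajectory; fluorescence accumulates as
    ``fluor_rate x integral OD dt``.
    """
    out = np.zeros(max_count + 1)
    t = np.linspace(0.0, culture_time_h, 289)
    h0 = strain.mu_max_per_h * strain.lag_h
    for k in range(1, max_count + 1):
        y0 = min(k * strain.y0_od, strain.ymax_od)
        ln_od = baranyi_log_od(
            t, math.log(y0), math.log(strain.ymax_od), strain.mu_max_per_h, h0
        )
        out[k] = strain.fluor_rate * np.trapezoid(np.exp(ln_od), t)
    return out


def generate_screen_population(
    scn: ScreenScenario, strains: list[StrainParams]
) -> pd.DataFrame:
    """Simulate a Poisson-loaded, cultured droplet population.

    Returns a table with one row per droplet: ``droplet_id``, per-strain
    cell counts (columns ``n_<strain>``), and the end-of-culture green
    fluorescence ``intensity`` (baseline draw plus per-strain growth
    contributions).
    """
    by_name = {s.name: s for s in strains}
    unknown = set(scn.lambdas) - set(by_name)
    if unknown:
        raise ValueError(f"lambdas given for unknown strains: {sorted(unknown)}")
    ss = np.random.SeedSequence(scn.seed)
    rng_counts, rng_base = (np.random.default_rng(s) for s in ss.spawn(2))
    n = scn.n_droplets
    data: dict[str, np.ndarray] = {"droplet_id": np.arange(n)}
    intensity = rng_base.lognormal(scn.empty_fluor_loc, scn.empty_fluor_scale, n)
    for name, lam in scn.lambdas.items():
        counts = rng_counts.poisson(lam, n)
        data[f"n_{name}"] = counts
        kmax = int(counts.max())
        if kmax > 0:
            per_k = _fluorescence_per_count(by_name[name], kmax, scn.culture_time_h)
            intensity = intensity + per_k[counts]
    data["intensity"] = intensity
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# OTU tables


@dataclass(frozen=True)
class EnrichmentScenario:
    """Paired pre/post-sort sequencing libraries with known enrichment."""

    pre_abundances: np.ndarray
    enrichment_factors: np.ndarray
    depth_pre: int = 1_000_000
    depth_post: int = 1_000_000
    seed: int = 0
    otu_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        pre = np.asarray(self.pre_abundances, dtype=float)
        fac = np.asarray(self.enrichment_factors, dtype=float)
        if pre.shape != fac.shape or pre.ndim != 1:
            raise ValueError("abundances and factors must be 1-D and equal length")
        if np.all(pre == 0):
            raise ValueError("pre-sort abundance vector is all zero")
        if abs(pre.sum() - 1.0) > 1e-9:
            raise ValueError("pre_abundances must sum to 1")
        if np.any(fac <= 0) or not np.all(np.isfinite(fac)):
            raise ValueError("enrichment factors must be positive and finite")
        if self.depth_pre <= 0 or self.depth_post <= 0:
            raise ValueError("sequencing depths must be positive")
        ids = self.otu_ids or tuple(f"OTU_{i + 1:03d}" for i in range(len(pre)))
        if len(ids) != len(pre):
            raise ValueError("otu_ids length mismatch")
        object.__setattr__(self, "pre_abundances", pre)
        object.__setattr__(self, "enrichment_factors", fac)
        object.__setattr__(self, "otu_ids", tuple(ids))

    @property
    def n_otus(self) -> int:
        return len(self.pre_abundances)

    @property
    def expected_post_fractions(self) -> np.ndarray:
        w = self.pre_abundances * self.enrichment_factors
        return w / w.sum()


def generate_otu_tables(scn: EnrichmentScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial read sampling of the pre- and post-sort libraries.

    Post-sort expected relative abundances are proportional to
    ``pre_abundance x enrichment_factor``. Column sums equal the requested
    depths exactly.
    """
    rng = np.random.default_rng(scn.seed)
    pre_counts = rng.multinomial(scn.depth_pre, scn.pre_abundances)
    post_counts = rng.multinomial(scn.depth_post, scn.expected_post_fractions)
    idx = pd.Index(scn.otu_ids, name="otu_id")
    pre = pd.DataFrame({"post_cultivation": pre_counts}, index=idx)
    post = pd.DataFrame({"post_sorting": post_counts}, index=idx)
    return pre, post


def enrichment_split_scenario(
    n_enriched: int = 45,
    n_depleted: int = 35,
    depth: int = 1_000_000,
    seed: int = 0,
) -> EnrichmentScenario:
    """A soil-screen-like community with a known enriched/depleted split.

    Enrichment factors are log-uniform in [1.3, 5] (enriched) and
    [1/5, 1/1.3] (depleted); pre-sort abundances are a Dirichlet draw whose
    group masses are rebalanced so the abundance-weighted mean factor is
    exactly 1. Because relative abundances renormalize across the sort, the
    realized enrichment ratio of OTU i is ``factor_i / sum(pre * factor)``;
    the rebalancing makes that denominator 1, so the configured factors are
    the realized ratios and the enriched/depleted split is exact in
    expectation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0711]))
    n = n_enriched + n_depleted
    pre = rng.dirichlet(np.full(n, 5.0))
    is_enriched = np.zeros(n, dtype=bool)
    is_enriched[rng.permutation(n)[:n_enriched]] = True
    factors = np.empty(n)
    factors[is_enriched] = np.exp(
        rng.uniform(math.log(1.3), math.log(5.0), n_enriched)
    )
    factors[~is_enriched] = np.exp(
        rng.uniform(math.log(1 / 5.0), math.log(1 / 1.3), n_depleted)
    )
    # rebalance group masses so sum(pre * factor) == 1: with mean enriched
    # ratio A > 1 and mean depleted ratio B < 1, put mass (1-B)/(A-B) on the
    # enriched group
    a = float((pre * factors)[is_enriched].sum() / pre[is_enriched].sum())
    b = float((pre * factors)[~is_enriched].sum() / pre[~is_enriched].sum())
    mass_e = (1.0 - b) / (a - b)
    pre[is_enriched] *= mass_e / pre[is_enriched].sum()
    pre[~is_enriched] *= (1.0 - mass_e) / pre[~is_enriched].sum()
    return EnrichmentScenario(
        pre_abundances=pre, enrichment_factors=factors,
        depth_pre=depth, depth_post=depth, seed=seed,
    )


# ---------------------------------------------------------------------------
# growth series and standard curves


def generate_growth_series(
    p: StrainParams, times_h, noise_sd: float = 0.0, seed: int = 0
) -> GrowthSeries:
    """An OD600 time course following the Baranyi-Roberts model plus noise."""
    t = np.asarray(list(times_h), dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    h0 = p.mu_max_per_h * p.lag_h
    ln_od = baranyi_log_od(
        t, math.log(p.y0_od), math.log(p.ymax_od), p.mu_max_per_h, h0
    )
    od = np.exp(ln_od)
    if noise_sd > 0:
        # constant-CV measurement noise: sd proportional to the reading
        rng = np.random.default_rng(seed)
        od = np.maximum(od * (1.0 + rng.normal(0, noise_sd, od.shape)), 1e-6)
    return GrowthSeries(times_h=t, od600=od)


def generate_standard_curve_data(
    amounts, slope: float, intercept: float, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Linear standard-curve readings (e.g. Nma fluorescence, Bradford)."""
    x = np.asarray(list(amounts), dtype=float)
    rng = np.random.default_rng(seed)
    y = slope * x + intercept
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, y.shape)
    return pd.DataFrame({"amount": x, "signal": y})
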