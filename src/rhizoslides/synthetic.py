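"""Synthetic scenes, traces and trials with known ground truth.

Everything the pipeline consumes can be generated here at desk scale:

* root scenes — dark polyline root systems on textured bright paper, with
  the two one-sided illumination gradients and per-exposure noise that the
  minimum-tonal fusion is designed to remove, plus a matching RSML trace;
* shoot scenes — green leaf polygons on the blue imaging background, with
  per-channel Gaussian noise, for the segmentation and canopy-proxy tests;
* growth series — straight lines plus Gaussian noise;
* trial tables — trait records drawn from the full genotype x nitrogen
  effects model (random slide effects, per-N residual variances, optional
  random root non-establishment), the generating values of which are kept
  alongside the data.

Generators are deterministic in their seed and emit their truth with the
outputs.  They target pipeline testability, not root biophysics: no
tropisms, no nutrient fields, no leaf optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .raster import DEFAULT_SCALE_MM_PER_PX, RGBImage
from .root_traits import AxileRoot, LateralRoot, RootSystem, polyline_length
from .shoot_imaging import ShootViewSet
from .experiment import TraitTable


# ---------------------------------------------------------------------------
# Root scenes

@dataclass
class RootSceneParams:
    """Rendering parameters of a synthetic root scene."""

    height: int = 512
    width: int = 512
    scale_mm_per_px: float = DEFAULT_SCALE_MM_PER_PX
    n_roots: int = 3
    background_level: float = 200.0
    texture_sigma: float = 8.0
    root_intensity: float = 60.0
    root_halfwidth_px: int = 1
    blur_sigma: float = 1.0
    gradient_strength: float = 140.0
    noise_sigma: float = 3.0


@dataclass
class SceneTruth:
    """Ground truth emitted next to a rendered scene."""

    mask: np.ndarray  # foreground (root or shoot) pixels, pre-noise
    polylines_px: List[np.ndarray] = field(default_factory=list)
    lengths_cm: List[float] = field(default_factory=list)
    shoot_areas_px: Dict[str, int] = field(default_factory=dict)
    params: object = None
    seed: Optional[int] = None


def _wandering_polyline(rng, params: RootSceneParams, fan: float = 0.0) -> np.ndarray:
    """Random downward polyline staying inside the frame, pixel coords.

    Roots emerge near the top centre (where the seed sits) and fan out;
    *fan* in [-1, 1] biases the initial heading left/right so a multi-root
    system spreads over the whole paper width.
    """
    h, w = params.height, params.width
    x = rng.uniform(0.45 * w, 0.55 * w)
    y = rng.uniform(0.02 * h, 0.08 * h)
    pts = [(x, y)]
    heading = np.pi / 2 + fan * np.pi / 3  # downward, fanned sideways
    while y < 0.9 * h:
        heading += rng.normal(0.0, 0.2)
        heading = float(np.clip(heading, np.pi / 6, 5 * np.pi / 6))
        step = rng.uniform(10, 25)
        x = float(np.clip(x + step * np.cos(heading), 3, w - 4))
        y = float(min(y + step * np.sin(heading), 0.95 * h))
        pts.append((x, y))
    return np.asarray(pts)


def _rasterize_polyline(mask: np.ndarray, poly: np.ndarray, halfwidth: int) -> None:
    for (x0, y0), (x1, y1) in zip(poly[:-1], poly[1:]):
        rr, cc = skdraw.line(int(round(y0)), int(round(x0)),
                             int(round(y1)), int(round(x1)))
        mask[rr, cc] = True
    if halfwidth > 0:
        mask |= ndimage.binary_dilation(mask, iterations=halfwidth)


def render_root_scene(
    params: Optional[RootSceneParams] = None,
    seed: int = 0,
    rsml_path=None,
) -> Tuple[RGBImage, RGBImage, SceneTruth, Optional[RootSystem]]:
    """Render the left-lit and right-lit exposures of one root scene.

    The two exposures share the same textured paper and dark root layer and
    differ only by opposite one-sided brightness gradients (clipped at 255,
    like real glare) plus independent Gaussian noise.  Returns the two
    images, the scene truth and the matching :class:`RootSystem` (also
    written to *rsml_path* if given).
    """
    params = params or RootSceneParams()
    rng = np.random.default_rng(seed)
    h, w = params.height, params.width

    texture = ndimage.gaussian_filter(
        rng.normal(0.0, params.texture_sigma, size=(h, w)), 2.0
    )
    base = params.background_level + texture

    mask = np.zeros((h, w), dtype=bool)
    polylines = []
    fans = (np.linspace(-1.0, 1.0, params.n_roots) if params.n_roots > 1
            else [0.0] * params.n_roots)
    for fan in fans:
        poly = _wandering_polyline(rng, params, fan=float(fan))
        _rasterize_polyline(mask, poly, params.root_halfwidth_px)
        polylines.append(poly)
    base[mask] = params.root_intensity
    base = ndimage.gaussian_filter(base, params.blur_sigma)

    # one-sided glare: strongest at the lit edge, decayed to zero by the
    # image centre, so the two exposures carry disjoint glare footprints;
    # integer-valued so it commutes with the 8-bit quantisation
    xs = np.linspace(0.0, 1.0, w)[None, :]
    grad_left = np.rint(params.gradient_strength * np.clip(1.0 - 2.0 * xs, 0.0, 1.0))
    grad_right = np.rint(params.gradient_strength * np.clip(2.0 * xs - 1.0, 0.0, 1.0))

    def _expose(grad):
        img = base + grad + rng.normal(0.0, params.noise_sigma, size=(h, w))
        img = np.clip(img, 0, 255).astype(np.uint8)
        return RGBImage(np.stack([img] * 3, axis=-1), params.scale_mm_per_px)

    left_lit = _expose(grad_left)
    right_lit = _expose(grad_right)

    cm = params.scale_mm_per_px / 10.0
    lengths = [polyline_length(p) * cm for p in polylines]
    truth = SceneTruth(
        mask=mask, polylines_px=polylines, lengths_cm=lengths,
        params=params, seed=seed,
    )

    system = RootSystem(
        timepoint=0,
        axile_roots=[
            AxileRoot(id=f"root_{i + 1}", root_class="crown_whorl1",
                      polyline=p * cm)
            for i, p in enumerate(polylines)
        ],
        slide_id="synthetic",
        scale_mm_per_px=params.scale_mm_per_px,
    )
    if rsml_path is not None:
        from .rsml import write_rsml

        write_rsml(system, rsml_path, unit="pixel",
                   resolution_mm_per_px=params.scale_mm_per_px)
    return left_lit, right_lit, truth, system


# ---------------------------------------------------------------------------
# Shoot scenes

@dataclass
class ShootSceneParams:
    height: int = 200
    width: int = 160
    shoot_color: Tuple[int, int, int] = (45, 150, 55)
    background_color: Tuple[int, int, int] = (30, 60, 170)
    noise_sigma: float = 10.0
    n_leaves: int = 3
    shoot_scale: float = 1.0  # 0 -> empty scene


def _shoot_mask(rng, params: ShootSceneParams) -> np.ndarray:
    h, w = params.height, params.width
    mask = np.zeros((h, w), dtype=bool)
    if params.shoot_scale <= 0:
        return mask
    cx = w / 2 + rng.uniform(-0.05 * w, 0.05 * w)
    stem_w = max(2, int(0.02 * w * params.shoot_scale))
    stem_top = int(h * 0.25)
    rr, cc = skdraw.rectangle(
        (stem_top, int(cx - stem_w)), extent=(h - stem_top - 2, 2 * stem_w),
        shape=mask.shape,
    )
    mask[rr, cc] = True
    for _ in range(params.n_leaves):
        base_y = rng.uniform(stem_top, h * 0.7)
        tip_dx = rng.uniform(0.2, 0.45) * w * rng.choice([-1, 1]) * params.shoot_scale
        tip_dy = -rng.uniform(0.1, 0.25) * h
        half = rng.uniform(0.015, 0.03) * h * params.shoot_scale + 1.5
        poly_r = [base_y - half, base_y + half, base_y + tip_dy]
        poly_c = [cx, cx, cx + tip_dx]
        rr, cc = skdraw.polygon(poly_r, poly_c, shape=mask.shape)
        mask[rr, cc] = True
    return mask


def render_shoot_scene(
    params: Optional[ShootSceneParams] = None,
    seed: int = 0,
) -> Tuple[ShootViewSet, SceneTruth]:
    """Render up to four shoot views with exact per-view foreground truth."""
    params = params or ShootSceneParams()
    rng = np.random.default_rng(seed)
    labels = ("side_front", "side_back", "top_front", "top_back")
    views = {}
    areas = {}
    union_mask = np.zeros((params.height, params.width), dtype=bool)
    for label in labels:
        mask = _shoot_mask(rng, params)
        union_mask |= mask
        img = np.empty((params.height, params.width, 3), dtype=float)
        img[...] = np.asarray(params.background_color, dtype=float)
        img[mask] = np.asarray(params.shoot_color, dtype=float)
        img += rng.normal(0.0, params.noise_sigma, size=img.shape)
        views[label] = RGBImage(np.clip(img, 0, 255).astype(np.uint8))
        areas[label] = int(mask.sum())
    truth = SceneTruth(mask=union_mask, shoot_areas_px=areas, params=params, seed=seed)
    return ShootViewSet(**views), truth


# ---------------------------------------------------------------------------
# Growth series

def simulate_growth_series(
    a: float,
    b: float,
    sigma: float,
    timepoints: Sequence[float],
    seed=0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Straight line ``a + b t`` plus iid Gaussian noise at each timepoint.

    *seed* may be an integer or a ``numpy.random.Generator``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 timepoints")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = a + b * t + rng.normal(0.0, sigma, size=t.shape)
    return t, y


# ---------------------------------------------------------------------------
# Trial tables

N_LEVELS = ("high", "low")
SIDES = ("front", "back")


@dataclass
class TrialTruth:
    """Generating values of a simulated split-nitrogen trial trait.

    Effects are sum-to-zero within each factor.  ``genotype_effects`` maps
    each N level to a length-G vector, which allows per-stratum genotypic
    variances (and hence per-stratum heritabilities) to differ — the
    signature observed for crown-root elongation, which is heritable on the
    high-N side only.
    """

    trait: str
    units: str
    mu: float
    n_effects: Dict[str, float]
    genotype_effects: Dict[str, np.ndarray]
    rep_effects: np.ndarray
    side_effects: Dict[str, float]
    sigma2_gr: float
    sigma2_e: Dict[str, float]
    nonnegative: bool = False  # clip simulated records at 0 (lengths, counts)

    def __post_init__(self):
        for lvl, g in self.genotype_effects.items():
            self.genotype_effects[lvl] = np.asarray(g, dtype=float)
        self.rep_effects = np.asarray(self.rep_effects, dtype=float)
        if any(v < 0 for v in self.sigma2_e.values()) or self.sigma2_gr < 0:
            raise ValueError("variances must be >= 0")

    @property
    def n_genotypes(self) -> int:
        return len(next(iter(self.genotype_effects.values())))

    @property
    def n_reps(self) -> int:
        return len(self.rep_effects)

    def cell_mean(self, genotype_idx: int, n_level: str, rep_idx: int, side: str) -> float:
        return (
            self.mu
            + self.n_effects[n_level]
            + self.genotype_effects[n_level][genotype_idx]
            + self.rep_effects[rep_idx]
            + self.side_effects[side]
        )

    @classmethod
    def sample(
        cls,
        trait: str = "trait",
        units: str = "unit",
        mu: float = 0.0,
        n_effect_delta: float = 0.0,
        sigma2_g: Dict[str, float] | float = 1.0,
        genotype_corr: float = 1.0,
        rep_sd: float = 0.0,
        side_sd: float = 0.0,
        sigma2_gr: float = 0.0,
        sigma2_e: Dict[str, float] | float = 1.0,
        n_genotypes: int = 24,
        n_reps: int = 4,
        nonnegative: bool = False,
        rng=None,
    ) -> "TrialTruth":
        """Draw genotype/replicate/side effects for a new trial truth.

        ``n_effect_delta`` is the high-minus-low difference of the N main
        effect; per-stratum genotype effects are drawn from a bivariate
        normal with correlation *genotype_corr* and centred.
        """
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        if not isinstance(sigma2_g, dict):
            sigma2_g = {lvl: float(sigma2_g) for lvl in N_LEVELS}
        if not isinstance(sigma2_e, dict):
            sigma2_e = {lvl: float(sigma2_e) for lvl in N_LEVELS}
        sds = {lvl: np.sqrt(sigma2_g[lvl]) for lvl in N_LEVELS}
        z = rng.standard_normal((n_genotypes, 2))
        z2 = genotype_corr * z[:, 0] + np.sqrt(max(0.0, 1 - genotype_corr ** 2)) * z[:, 1]
        g_high = z[:, 0] * sds["high"]
        g_low = z2 * sds["low"]
        genotype_effects = {
            "high": g_high - g_high.mean(),
            "low": g_low - g_low.mean(),
        }
        reps = rng.normal(0.0, rep_sd, size=n_reps)
        reps -= reps.mean()
        side = rng.normal(0.0, side_sd)
        return cls(
            trait=trait,
            units=units,
            mu=mu,
            n_effects={"high": n_effect_delta / 2.0, "low": -n_effect_delta / 2.0},
            genotype_effects=genotype_effects,
            rep_effects=reps,
            side_effects={"front": side, "back": -side},
            sigma2_gr=float(sigma2_gr),
            sigma2_e=sigma2_e,
            nonnegative=nonnegative,
        )


def simulate_trial(
    truth: TrialTruth,
    missing_rate: Dict[str, float] | float = 0.0,
    seed=0,
) -> TraitTable:
    """Draw one fully crossed trial table from a :class:`TrialTruth`.

    Random slide effects (genotype x replicate) are shared by the four
    observations of a slide; residuals have the per-N-level variances of
    the truth.  ``missing_rate`` (scalar or per N level) drops records
    completely at random, emulating plants that never establish a traceable
    crown root in a compartment.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not isinstance(missing_rate, dict):
        missing_rate = {lvl: float(missing_rate) for lvl in N_LEVELS}

    G, R = truth.n_genotypes, truth.n_reps
    gr = rng.normal(0.0, np.sqrt(truth.sigma2_gr), size=(G, R))
    records = []
    for i in range(G):
        for k in range(R):
            for lvl in N_LEVELS:
                for side in SIDES:
                    value = (
                        truth.cell_mean(i, lvl, k, side)
                        + gr[i, k]
                        + rng.normal(0.0, np.sqrt(truth.sigma2_e[lvl]))
                    )
                    if truth.nonnegative:
                        value = max(value, 0.0)
                    keep = rng.uniform() >= missing_rate[lvl]
                    if keep:
                        records.append({
                            "genotype": i + 1,
                            "n_level": lvl,
                            "replicate": k + 1,
                            "side": side,
                            "trait": truth.trait,
                            "value": value,
                            "units": truth.units,
                        })
    import pandas as pd

    from .experiment import TRAIT_COLUMNS

    df = pd.DataFrame(records, columns=TRAIT_COLUMNS)
    return TraitTable(df)


# ---------------------------------------------------------------------------
# Trait truths mirroring the published trial conditions

def default_trial_truths(n_genotypes: int = 24, n_reps: int = 4, rng=None) -> Dict[str, TrialTruth]:
    """Trial truths for a set of root traits at the published study's scale.

    Values reflect the reported trait ranges of the 24-genotype trial:
    crown-root elongation ~1.6 cm/d under high N with genotype means
    spanning roughly 1.44-1.77 and a 26 % mean reduction under low N;
    genotypic variance on the low-N side set to zero for elongation (its
    heritability was zero there); intercepts ~11-12 cm with near-zero
    heritability; first-segment lateral counts ~50 (high) vs ~27 (low).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    truths = {}
    # elongation rate of crown roots, cm/d
    mu_h, reduction = 1.60, 0.26
    mu_l = mu_h * (1 - reduction)
    s2g_h = 0.0064  # h2 ~ 0.41 with r = 4 given the residual below
    truths["ER_Cr"] = TrialTruth.sample(
        trait="ER_Cr", units="cm/d",
        mu=(mu_h + mu_l) / 2, n_effect_delta=mu_h - mu_l,
        sigma2_g={"high": s2g_h, "low": 0.0}, genotype_corr=0.0,
        rep_sd=0.02, side_sd=0.01, sigma2_gr=0.004,
        sigma2_e={"high": 4 * s2g_h * (1 - 0.41) / 0.41, "low": 0.04},
        n_genotypes=n_genotypes, n_reps=n_reps, nonnegative=True, rng=rng,
    )
    # crown-root length at solution change, cm (low heritability)
    truths["IC_Cr"] = TrialTruth.sample(
        trait="IC_Cr", units="cm",
        mu=11.5, n_effect_delta=-0.7,
        sigma2_g={"high": 0.02, "low": 0.02}, genotype_corr=0.8,
        rep_sd=0.2, side_sd=0.1, sigma2_gr=0.2,
        sigma2_e={"high": 2.6, "low": 2.6},
        n_genotypes=n_genotypes, n_reps=n_reps, nonnegative=True, rng=rng,
    )
    # lateral count in the first branching-zone segment
    truths["No_Lat_1st"] = TrialTruth.sample(
        trait="No_Lat_1st", units="count",
        mu=38.5, n_effect_delta=24.0,
        sigma2_g={"high": 25.0, "low": 6.0}, genotype_corr=0.5,
        rep_sd=1.0, side_sd=0.5, sigma2_gr=4.0,
        sigma2_e={"high": 144.0, "low": 70.0},
        n_genotypes=n_genotypes, n_reps=n_reps, nonnegative=True, rng=rng,
    )
    # median lateral length in the first segment, cm
    truths["Med_Lat_1st"] = TrialTruth.sample(
        trait="Med_Lat_1st", units="cm",
        mu=0.73, n_effect_delta=0.72,
        sigma2_g={"high": 0.0016, "low": 0.0008}, genotype_corr=0.5,
        rep_sd=0.01, side_sd=0.005, sigma2_gr=0.0008,
        sigma2_e={"high": 0.0025, "low": 0.009},
        n_genotypes=n_genotypes, n_reps=n_reps, nonnegative=True, rng=rng,
    )
    return truths
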