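"""Synthetic neonatal cohorts and cortical-ribbon phantoms.

Every downstream stage of the pipeline (equivolumetric surfaces, volume
sampling, moments, parcel-wise models, eigenmodes, spin tests) is
exercised against phantoms with analytically known structure:

* :func:`simulate_cohort` draws a neonatal cohort whose gestational age
  (GA) has the long left tail of a mixed preterm/term population, whose
  postnatal age (PNA) is right-skewed on [0, 7] weeks, and whose GA-PNA
  sample correlation is driven to a configurable negative target
  (preterm infants tend to be scanned later after birth);
  postmenstrual age (PMA) is GA + PNA exactly.

* :func:`simulate_phantom_geometry` builds a cortical "ribbon" as a
  smoothly perturbed sphere (white surface) offset outward along each
  ray by a thickness field (pial surface), with a contiguous Voronoi
  parcellation and the base sphere as spherical projection.  The
  perturbation is an analytic low-order harmonic of direction, so the
  white/pial radius along any ray — and hence every voxel's fractional
  cortical depth — is known in closed form.

* :func:`simulate_subject_volume` voxelizes a subject: each ribbon voxel
  takes its parcel group's 12-depth intensity template, evaluated at the
  voxel's analytic radial depth fraction with linear interpolation, plus
  i.i.d. Gaussian noise.  The templates carry per-group linear effects
  of GA, PNA, sex and (optionally) GA x PNA, so the regression modules
  have known ground truth (:func:`expected_moments`).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import trimesh
from scipy import optimize, stats
from sklearn.cluster import KMeans

from .equivolume import CorticalRibbon, SurfaceMesh
from .errors import GeometryError, ParameterizationError
from .moments import Parcellation, profile_moments
from .spin import SphereProjection

__all__ = [
    "COHORT_COLUMNS",
    "EffectSpec",
    "GridSpec",
    "PhantomGeometry",
    "simulate_cohort",
    "validate_cohort",
    "simulate_phantom_geometry",
    "simulate_subject_volume",
    "expected_moments",
    "make_recovery_spec",
]

COHORT_COLUMNS = [
    "subject_id", "ga_weeks", "pna_weeks", "pma_weeks", "sex", "thickness_mm",
]

#: default covariate ranges (weeks) of the emulated neonatal cohort
GA_RANGE = (23.0, 42.3)
PNA_RANGE = (0.0, 7.0)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _ga_mixture_sample(rng, n, ga_range, preterm_frac, preterm_loc, preterm_scale,
                       term_loc, term_scale):
    """Truncated two-component (preterm + term) GA mixture."""
    lo, hi = ga_range
    cut = 37.0  # clinical preterm threshold, weeks
    is_preterm = rng.random(n) < preterm_frac
    u = rng.random(n)
    ga = np.empty(n)

    def trunc(loc, scale, a, b, uu):
        a_, b_ = (a - loc) / scale, (b - loc) / scale
        return stats.truncnorm.ppf(uu, a_, b_, loc=loc, scale=scale)

    ga[is_preterm] = trunc(preterm_loc, preterm_scale, lo, cut, u[is_preterm])
    ga[~is_preterm] = trunc(term_loc, term_scale, cut, hi, u[~is_preterm])
    return ga


def _pna_from_latent(z, pna_range, pna_scale):
    """Monotone map of a standard-normal latent to a right-skewed PNA.

    Uses the quantile function of an exponential truncated to the PNA
    range; the median (~0.86 weeks at the default scale) matches a
    cohort scanned mostly within the first postnatal week.
    """
    lo, hi = pna_range
    u = stats.norm.cdf(z)
    span = 1.0 - np.exp(-(hi - lo) / pna_scale)
    return lo - pna_scale * np.log1p(-u * span)


def simulate_cohort(
    n: int,
    seed: int,
    target_corr: float = -0.43,
    ga_range=GA_RANGE,
    pna_range=PNA_RANGE,
    preterm_frac: float = 0.27,
    preterm_loc: float = 33.0,
    preterm_scale: float = 3.5,
    term_loc: float = 39.6,
    term_scale: float = 1.6,
    pna_scale: float = 1.24,
    include_thickness: bool = True,
) -> pd.DataFrame:
    """Simulate a neonatal cohort table.

    GA is drawn from a truncated preterm/term mixture; PNA is a monotone
    transform of a latent Gaussian coupled to GA's ranks.  The latent
    coupling is root-found so that the *sample* Pearson correlation of
    GA and PNA matches ``target_corr`` (up to the achievable range at
    small n).  PMA = GA + PNA exactly; sex is a balanced 0/1 code.

    Deterministic given ``(n, seed)`` and the parameters.
    """
    if n < 3:
        raise ParameterizationError("need n >= 3")
    if not (-1.0 < target_corr <= 0.0):
        raise ParameterizationError("target GA-PNA correlation must be in (-1, 0]")
    if ga_range[0] >= ga_range[1] or pna_range[0] >= pna_range[1]:
        raise ParameterizationError("empty covariate range")
    if not ga_range[0] <= preterm_loc <= ga_range[1]:
        raise ParameterizationError("preterm location outside GA range")

    rng = np.random.default_rng(seed)
    ga_draw = np.sort(
        _ga_mixture_sample(rng, n, ga_range, preterm_frac, preterm_loc,
                           preterm_scale, term_loc, term_scale)
    )
    z1 = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    # GA comonotone with z1: rank-match the sorted margin to z1's ranks
    ga = ga_draw[np.argsort(np.argsort(z1))]

    def sample_corr(c):
        z2 = c * z1 + np.sqrt(1.0 - c * c) * eps
        pna = _pna_from_latent(z2, pna_range, pna_scale)
        return float(np.corrcoef(ga, pna)[0, 1])

    if target_corr == 0.0:
        c_star = 0.0
    else:
        lo_c, hi_c = -0.999, 0.0
        f_lo, f_hi = sample_corr(lo_c) - target_corr, sample_corr(hi_c) - target_corr
        if f_lo * f_hi > 0:  # target outside the achievable range for this draw
            c_star = lo_c if abs(f_lo) < abs(f_hi) else hi_c
        else:
            c_star = optimize.brentq(
                lambda c: sample_corr(c) - target_corr, lo_c, hi_c, xtol=1e-6
            )
    z2 = c_star * z1 + np.sqrt(1.0 - c_star * c_star) * eps
    pna = _pna_from_latent(z2, pna_range, pna_scale)

    sex = np.zeros(n, dtype=int)
    sex[: n // 2] = 1
    rng.shuffle(sex)

    pma = ga + pna
    if include_thickness:
        thickness = np.clip(
            1.1 + 0.015 * (pma - 40.0) + rng.normal(0.0, 0.1, n), 0.5, None
        )
    else:
        thickness = np.full(n, np.nan)

    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "ga_weeks": ga,
            "pna_weeks": pna,
            "pma_weeks": pma,
            "sex": sex,
            "thickness_mm": thickness,
        }
    )
    validate_cohort(df, ga_range=ga_range, pna_range=pna_range)
    return df


def validate_cohort(df: pd.DataFrame, ga_range=GA_RANGE, pna_range=PNA_RANGE):
    """Check the cohort-table invariants; raise ParameterizationError."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterizationError(f"cohort table missing columns {missing}")
    if df["subject_id"].duplicated().any():
        raise ParameterizationError("duplicate subject_id")
    if not np.allclose(df["pma_weeks"], df["ga_weeks"] + df["pna_weeks"], atol=0.0):
        raise ParameterizationError("pma_weeks must equal ga_weeks + pna_weeks")
    if df["ga_weeks"].min() < ga_range[0] or df["ga_weeks"].max() > ga_range[1]:
        raise ParameterizationError("ga_weeks outside configured range")
    if df["pna_weeks"].min() < pna_range[0] or df["pna_weeks"].max() > pna_range[1]:
        raise ParameterizationError("pna_weeks outside configured range")
    if not set(np.unique(df["sex"])) <= {0, 1}:
        raise ParameterizationError("sex must be coded 0/1")


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

@dataclass
class _RadialHarmonic:
    """Smooth analytic scalar field of direction: a.u + u' B u, normalized."""

    linear: np.ndarray
    quadratic: np.ndarray
    norm: float = 1.0

    def __call__(self, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        val = dirs @ self.linear + np.einsum("ni,ij,nj->n", dirs, self.quadratic, dirs)
        return val / self.norm


@dataclass
class GridSpec:
    """Isotropic voxel grid: size, array shape and RAS affine."""

    voxel_size: float
    shape: tuple
    affine: np.ndarray


@dataclass
class PhantomGeometry:
    """Cortical-ribbon phantom with analytic depth ground truth."""

    ribbon: CorticalRibbon
    sphere: SphereProjection
    parcellation: Parcellation
    grid: GridSpec
    white_base: float
    thickness_base: float
    perturb_amp: float
    thickness_amp: float
    white_harmonic: _RadialHarmonic
    thickness_harmonic: _RadialHarmonic
    parcel_centers: np.ndarray
    _depth_field: tuple | None = dc_field(default=None, repr=False, compare=False)

    def white_radius_of(self, dirs: np.ndarray) -> np.ndarray:
        return self.white_base * (1.0 + self.perturb_amp * self.white_harmonic(dirs))

    def thickness_of(self, dirs: np.ndarray) -> np.ndarray:
        return self.thickness_base * (
            1.0 + self.thickness_amp * self.thickness_harmonic(dirs)
        )

    def pial_radius_of(self, dirs: np.ndarray) -> np.ndarray:
        return self.white_radius_of(dirs) + self.thickness_of(dirs)

    def parcel_of(self, dirs: np.ndarray) -> np.ndarray:
        """Voronoi parcel label (1-based) of unit directions."""
        return np.argmax(np.atleast_2d(dirs) @ self.parcel_centers.T, axis=1) + 1

    def interior_vertex_mask(self, margin_mm: float = 1.0) -> np.ndarray:
        """Vertices farther than ``margin_mm`` from any parcel boundary.

        Trilinear sampling mixes voxels within about one voxel of each
        sample point, so vertices close to a Voronoi parcel border pick
        up intensity from the neighbouring parcel's template.  Masking a
        margin of the order of two voxel widths keeps each parcel's
        profile uncontaminated by its neighbours.
        """
        u = self.sphere.coordinates
        dots = u @ self.parcel_centers.T
        part = np.argpartition(-dots, 1, axis=1)[:, :2]
        rows = np.arange(len(u))
        first, second = part[:, 0], part[:, 1]
        # swap so `first` is the nearest centre
        swap = dots[rows, second] > dots[rows, first]
        first[swap], second[swap] = second[swap], first[swap].copy()
        c1 = self.parcel_centers[first]
        c2 = self.parcel_centers[second]
        gap = np.linalg.norm(c1 - c2, axis=1)
        r_mid = self.white_base + 0.5 * self.thickness_base
        dist = r_mid * (dots[rows, first] - dots[rows, second]) / gap
        return dist > margin_mm

    def parcel_thickness(self) -> pd.Series:
        """Mean pial-white radial distance per parcel (mm)."""
        t = self.thickness_of(self.sphere.coordinates)
        return pd.Series(t).groupby(self.parcellation.labels).mean()

    def depth_field(self):
        """Cached per-voxel analytic depth fraction and parcel label.

        Returns (frac, parcel, inside): ``frac`` is the fractional depth
        from pial (0) to white (1) along each voxel's ray, unbounded
        outside the ribbon; ``inside`` marks ribbon voxels.
        """
        if self._depth_field is None:
            shape = self.grid.shape
            idx = np.indices(shape).reshape(3, -1).T.astype(np.float64)
            world = idx @ self.grid.affine[:3, :3].T + self.grid.affine[:3, 3]
            r = np.linalg.norm(world, axis=1)
            safe_r = np.where(r == 0, 1.0, r)
            dirs = world / safe_r[:, None]
            rw = self.white_radius_of(dirs)
            rp = self.pial_radius_of(dirs)
            frac = (rp - r) / (rp - rw)
            frac[r == 0] = (rp[r == 0] - 0.0) / (rp[r == 0] - rw[r == 0])
            parcel = self.parcel_of(dirs)
            inside = (frac >= 0.0) & (frac <= 1.0)
            self._depth_field = (
                frac.reshape(shape), parcel.reshape(shape), inside.reshape(shape),
            )
        return self._depth_field


def simulate_phantom_geometry(
    subdivision: int = 4,
    n_parcels: int = 33,
    white_radius: float = 14.0,
    thickness: float = 2.0,
    perturb_amp: float = 0.03,
    thickness_amp: float = 0.0,
    voxel_size: float = 0.5,
    seed: int = 0,
) -> PhantomGeometry:
    """Build a deterministic cortical-ribbon phantom.

    The white surface is a subdivision-``subdivision`` icosphere of base
    radius ``white_radius`` mm with a smooth random radial perturbation
    of relative amplitude ``perturb_amp``; the pial surface lies
    ``thickness`` mm further out along each ray (optionally modulated by
    ``thickness_amp``).  Parcels are the Voronoi cells of ``n_parcels``
    k-means centres on the unit sphere, hence contiguous.
    """
    if subdivision < 2:
        raise ParameterizationError("subdivision must be >= 2")
    if n_parcels < 2:
        raise ParameterizationError("n_parcels must be >= 2")
    if thickness <= 0 or abs(thickness_amp) >= 1.0:
        raise GeometryError("thickness field must be strictly positive")
    if abs(perturb_amp) >= 0.5:
        raise GeometryError("radial perturbation too large (self-intersection risk)")

    base = trimesh.creation.icosphere(subdivisions=subdivision, radius=1.0)
    dirs = np.asarray(base.vertices, dtype=np.float64)
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    faces = np.asarray(base.faces, dtype=np.int64)

    rng = np.random.default_rng(seed)

    def harmonic():
        a = rng.standard_normal(3)
        b = rng.standard_normal((3, 3))
        b = 0.5 * (b + b.T)
        b -= np.eye(3) * np.trace(b) / 3.0
        h = _RadialHarmonic(linear=a, quadratic=b)
        h.norm = float(np.max(np.abs(h(dirs)))) or 1.0
        return h

    g_white = harmonic()
    g_thick = harmonic()

    white_r = white_radius * (1.0 + perturb_amp * g_white(dirs))
    thick = thickness * (1.0 + thickness_amp * g_thick(dirs))
    if np.any(thick <= 0) or np.any(white_r <= 0):
        raise GeometryError("thickness parameters produce non-positive thickness")
    white = SurfaceMesh(dirs * white_r[:, None], faces)
    pial = SurfaceMesh(dirs * (white_r + thick)[:, None], faces)
    ribbon = CorticalRibbon(pial=pial, white=white)

    km = KMeans(n_clusters=n_parcels, n_init=4,
                random_state=int(seed) % (2**32)).fit(dirs)
    labels = km.labels_.astype(np.int64) + 1
    if len(np.unique(labels)) != n_parcels:
        raise GeometryError("k-means produced an empty parcel; change the seed")
    centers = km.cluster_centers_ / np.linalg.norm(km.cluster_centers_, axis=1)[:, None]
    parcellation = Parcellation(labels=labels)

    max_r = float((white_r + thick).max())
    half = max_r + 4.0 * voxel_size
    n_half = int(np.ceil(half / voxel_size))
    n_vox = 2 * n_half + 1
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -n_half * voxel_size
    grid = GridSpec(voxel_size=voxel_size, shape=(n_vox,) * 3, affine=affine)

    return PhantomGeometry(
        ribbon=ribbon,
        sphere=SphereProjection(dirs),
        parcellation=parcellation,
        grid=grid,
        white_base=white_radius,
        thickness_base=thickness,
        perturb_amp=perturb_amp,
        thickness_amp=thickness_amp,
        white_harmonic=g_white,
        thickness_harmonic=g_thick,
        parcel_centers=centers,
    )


# ---------------------------------------------------------------------------
# effect specification and subject volumes
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Per-parcel-group generative model of the 12-depth intensity template.

    For a subject with covariates (GA, PNA, sex) and parcel group ``g``
    the noiseless template at depth ``d`` is::

        baseline[g, d]
        + slope_ga[g, d]  * (GA - ga_center)
        + slope_pna[g, d] * (PNA - pna_center)
        + slope_sex[g, d] * sex
        + interaction_ga_pna[g, d] * (GA - ga_center) * (PNA - pna_center)

    and must stay strictly positive over the validated covariate box.
    Parcel labels map to groups via ``parcel_to_group`` (default:
    ``label % n_groups``).
    """

    baseline: np.ndarray
    slope_ga: np.ndarray | None = None
    slope_pna: np.ndarray | None = None
    slope_sex: np.ndarray | None = None
    interaction_ga_pna: np.ndarray | None = None
    noise_sd: float = 0.1
    ga_center: float = 33.0
    pna_center: float = 0.0
    ga_range: tuple = GA_RANGE
    pna_range: tuple = PNA_RANGE
    parcel_to_group: dict | None = None

    def __post_init__(self):
        self.baseline = np.atleast_2d(np.asarray(self.baseline, dtype=np.float64))
        G, D = self.baseline.shape
        for name in ("slope_ga", "slope_pna", "slope_sex", "interaction_ga_pna"):
            v = getattr(self, name)
            v = np.zeros((G, D)) if v is None else np.atleast_2d(
                np.asarray(v, dtype=np.float64)
            )
            if v.shape != (G, D):
                raise ParameterizationError(
                    f"{name} must have shape {(G, D)}, got {v.shape}"
                )
            setattr(self, name, v)
        if D != 12:
            raise ParameterizationError("depth templates must have exactly 12 entries")
        if self.noise_sd < 0:
            raise ParameterizationError("noise_sd must be >= 0")
        self._check_positive()

    @property
    def n_groups(self) -> int:
        return self.baseline.shape[0]

    @property
    def n_depths(self) -> int:
        return self.baseline.shape[1]

    def group_of(self, labels) -> np.ndarray:
        labels = np.asarray(labels, dtype=np.int64)
        if self.parcel_to_group is not None:
            lut = np.array(
                [self.parcel_to_group.get(i, i % self.n_groups)
                 for i in range(labels.max() + 1)]
            )
            return lut[labels]
        return labels % self.n_groups

    def expected_profile(self, group: int, ga: float, pna: float, sex: int
                         ) -> np.ndarray:
        """Noiseless 12-depth template for one subject and group."""
        self._check_covariates(ga, pna, sex)
        dga = ga - self.ga_center
        dpna = pna - self.pna_center
        return (
            self.baseline[group]
            + self.slope_ga[group] * dga
            + self.slope_pna[group] * dpna
            + self.slope_sex[group] * sex
            + self.interaction_ga_pna[group] * dga * dpna
        )

    def _check_covariates(self, ga, pna, sex):
        if not (self.ga_range[0] <= ga <= self.ga_range[1]):
            raise ParameterizationError(f"ga {ga} outside validated range")
        if not (self.pna_range[0] <= pna <= self.pna_range[1]):
            raise ParameterizationError(f"pna {pna} outside validated range")
        if sex not in (0, 1):
            raise ParameterizationError("sex must be 0 or 1")

    def _check_positive(self):
        # the template is bilinear in (GA, PNA), so its minimum over the
        # covariate box is attained at a corner
        for ga in self.ga_range:
            for pna in self.pna_range:
                for sex in (0, 1):
                    for g in range(self.n_groups):
                        if np.any(self.expected_profile(g, ga, pna, sex) <= 0):
                            raise ParameterizationError(
                                "expected intensity non-positive at covariate "
                                f"corner (ga={ga}, pna={pna}, sex={sex}, group={g})"
                            )


def make_recovery_spec(
    deep_ga_slope: float = 0.02,
    superficial_pna_slope: float = 0.02,
    noise_sd: float = 0.1,
    flip_depth: bool = False,
    interaction: float = 0.0,
) -> EffectSpec:
    """Two-group spec with effects planted in group 1 only.

    Group 1 carries a GA slope in the deep depths 9-12 and a PNA slope in
    the superficial depths 1-4 (swapped when ``flip_depth``); group 0 is
    null.  The baseline rises gently toward the white matter, mimicking
    the myelin-driven T1w/T2w depth gradient.
    """
    d = np.arange(12)
    baseline = np.tile(1.0 + 0.5 * d / 11.0, (2, 1))
    deep = (d >= 8).astype(float)
    superficial = (d < 4).astype(float)
    if flip_depth:
        deep, superficial = superficial, deep
    slope_ga = np.zeros((2, 12))
    slope_pna = np.zeros((2, 12))
    inter = np.zeros((2, 12))
    slope_ga[1] = deep_ga_slope * deep
    slope_pna[1] = superficial_pna_slope * superficial
    inter[1] = interaction * deep
    return EffectSpec(
        baseline=baseline,
        slope_ga=slope_ga,
        slope_pna=slope_pna,
        interaction_ga_pna=inter,
        noise_sd=noise_sd,
    )


def simulate_subject_volume(
    geom: PhantomGeometry,
    covariates,
    spec: EffectSpec,
    seed: int,
    csf_value: float | None = None,
    wm_value: float | None = None,
):
    """Voxelize one subject of the phantom cohort.

    Ribbon voxels get their parcel group's template evaluated at the
    voxel's analytic fractional depth (linear interpolation across the
    12 depth nodes) plus N(0, noise_sd) noise.  Voxels outside the
    ribbon continue the template's edge value (clamped depth) by
    default; pass ``csf_value`` / ``wm_value`` for constant backgrounds
    beyond the pial / white boundary instead.

    Returns a :class:`~neolaminar.sampling.Volume`; bit-identical for
    identical arguments.
    """
    from .sampling import Volume  # local import to avoid cycle

    ga = float(covariates["ga_weeks"])
    pna = float(covariates["pna_weeks"])
    sex = int(covariates["sex"])
    frac, parcel, inside = geom.depth_field()
    groups = spec.group_of(parcel)
    nodes = np.linspace(0.0, 1.0, spec.n_depths)

    data = np.empty(geom.grid.shape, dtype=np.float64)
    clipped = np.clip(frac, 0.0, 1.0)
    for g in range(spec.n_groups):
        template = spec.expected_profile(g, ga, pna, sex)
        sel = groups == g
        data[sel] = np.interp(clipped[sel], nodes, template)
    if csf_value is not None:
        data[frac < 0.0] = csf_value
    if wm_value is not None:
        data[frac > 1.0] = wm_value

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data[inside] += rng.normal(0.0, spec.noise_sd, int(inside.sum()))
    return Volume(data=data, affine=geom.grid.affine)


def expected_moments(spec: EffectSpec, covariates, parcel_group: int):
    """Analytic (mu1, mu2) of the noiseless template for one subject/group."""
    profile = spec.expected_profile(
        parcel_group,
        float(covariates["ga_weeks"]),
        float(covariates["pna_weeks"]),
        int(covariates["sex"]),
    )
    return profile_moments(profile)
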