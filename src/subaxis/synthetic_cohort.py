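"""Synthetic data: 3-D tube phantoms and cohort tables.

No public hippocampal-subfield dataset accompanies this package, so testing
and calibration rest on two generators:

* **Phantoms** — voxelized curved tubes standing in for subiculum masks.
  The generator stores its ground truth (centerline endpoints, per-voxel
  arc fraction), so parcellation output can be checked against the known
  geometry.

* **Cohort tables** — participant x hemisphere x segment volume records
  joined to demographics and CSF biomarkers.  In *calibration* mode the
  table is built from independent standardized drivers with fixed loadings,
  so every headline association has a known population value:

      V = mu_V + sigma_V (-a A - p P - q M + beta I + e Z)

  with A the age score, P the P-tau score, M the latent memory score, I the
  ICV score and Z independent noise, a = 0.34 (so corr(age, V) = -0.34),
  p = 0.18 sqrt(1 - 0.34^2), beta = 0.20, and q calibrated by pilot
  simulation so that the correlation between V and the *discretized* memory
  error count equals -0.41.  Abeta42 is drawn independently from a bimodal
  two-component Gaussian mixture whose analytic equal-posterior point sits
  at 527 ng/l.  Total volume is distributed over 10 segments with a
  near-uniform share profile; the P-tau and memory channels additionally
  load on the segments with posterior-heavy weights proportional to (11-s),
  so posterior segments carry stronger biomarker effects, as the analysis
  assumes.

  In *study_like* mode the same volume model runs on group-shifted
  age/P-tau/memory distributions (CN/SCD/MCI) with group-specific
  amyloid-positivity rates, plus an optional injected posterior atrophy
  effect; this mode is for power and pipeline demonstrations.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomarker_rules import equal_posterior_point
from .mask_model import BinaryMask

logger = logging.getLogger("subaxis")

N_SEGMENTS = 10

#: Internal pilot-simulation seed for the memory-loading calibration; fixed
#: so that the calibrated loading is a reproducible constant of the package.
_PILOT_SEED = 20170306
_PILOT_N = 100_000


# ---------------------------------------------------------------------------
# tube phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """A tube phantom: centerline control points (world mm, runs posterior ->
    anterior along world +Y), radius profile and optional atrophy profile
    (multiplicative radius factor), both as functions of arc fraction."""

    control_points: np.ndarray
    radius_mm: float | object = 2.5
    atrophy_profile: object | None = None
    voxel_size: float = 1.0
    margin_voxels: int = 2
    centerline_spacing_mm: float = 0.25

    def radius_at(self, frac: np.ndarray) -> np.ndarray:
        r = (
            self.radius_mm(frac)
            if callable(self.radius_mm)
            else np.full_like(np.asarray(frac, dtype=float), self.radius_mm)
        )
        if self.atrophy_profile is not None:
            r = r * self.atrophy_profile(frac)
        return np.asarray(r, dtype=float)


@dataclass(frozen=True)
class PhantomTruth:
    """Generator ground truth stored alongside a phantom mask."""

    endpoint_posterior: np.ndarray
    endpoint_anterior: np.ndarray
    arc_fraction: np.ndarray  # parallel to mask.voxels
    arc_length_mm: float


def _sample_centerline(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Densely sampled centerline points and their arc fractions."""
    cp = np.asarray(spec.control_points, dtype=float).reshape(-1, 3)
    if cp.shape[0] < 2:
        raise ValueError("need at least 2 centerline control points")
    seg_len = np.linalg.norm(np.diff(cp, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = float(s[-1])
    if total < 20.0:
        raise ValueError(f"centerline arc length must be >= 20 mm, got {total:.1f}")
    n = max(2, int(np.ceil(total / spec.centerline_spacing_mm)) + 1)
    si = np.linspace(0.0, total, n)
    pts = np.column_stack([np.interp(si, s, cp[:, d]) for d in range(3)])
    return pts, si / total


def generate_phantom_mask(spec: PhantomSpec) -> tuple[BinaryMask, PhantomTruth]:
    """Voxelize a tube phantom: voxel centers within the (possibly
    atrophied) radius of the centerline are in-mask.

    Returns the mask plus ground truth: the exact centerline endpoints and
    each in-mask voxel's arc fraction (of its nearest centerline sample).
    """
    pts, frac = _sample_centerline(spec)
    radii = spec.radius_at(frac)
    if np.any(radii < spec.voxel_size):
        raise ValueError("radius (after atrophy) must stay >= 1 voxel")
    vs = float(spec.voxel_size)
    margin = spec.margin_voxels * vs + radii.max()
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    origin = np.floor(lo / vs) * vs
    shape = tuple(np.ceil((hi - origin) / vs).astype(int) + 1)
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = origin

    idx = np.indices(shape).reshape(3, -1).T
    centers = idx * vs + origin
    # chunked nearest-centerline-sample search
    keep = np.zeros(len(centers), dtype=bool)
    nearest = np.zeros(len(centers), dtype=np.int64)
    chunk = max(1, int(2e7) // max(len(pts), 1))
    for start in range(0, len(centers), chunk):
        d2 = _sq_dists(centers[start:start + chunk], pts)
        j = np.argmin(d2, axis=1)
        nearest[start:start + chunk] = j
        keep[start:start + chunk] = (
            d2[np.arange(len(j)), j] <= radii[j] ** 2
        )
    if not keep.any():
        raise ValueError("phantom voxelization produced an empty mask")
    voxels = idx[keep]
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
    voxels = voxels[order]
    arc = frac[nearest[keep]][order]
    mask = BinaryMask(voxels=voxels, affine=affine, shape=shape)
    truth = PhantomTruth(
        endpoint_posterior=pts[0],
        endpoint_anterior=pts[-1],
        arc_fraction=arc,
        arc_length_mm=float(
            np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        ),
    )
    return mask, truth


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import cdist
    return cdist(a, b, "sqeuclidean")


def random_phantom_spec(
    seed: int | np.random.Generator,
    length_mm: tuple[float, float] = (35.0, 60.0),
    radius_mm: tuple[float, float] = (2.0, 3.2),
    curvature_mm: float = 6.0,
) -> PhantomSpec:
    """A mildly curved random tube running anteriorly (along world +Y)."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    L = rng.uniform(*length_mm)
    r = rng.uniform(*radius_mm)
    n_ctrl = 5
    y = np.linspace(0.0, L, n_ctrl)
    x = rng.uniform(-curvature_mm, curvature_mm) * np.sin(
        np.linspace(0, np.pi, n_ctrl)
    ) + rng.normal(0, 1.0, n_ctrl)
    zc = rng.uniform(-curvature_mm, curvature_mm) * np.sin(
        np.linspace(0, np.pi, n_ctrl)
    ) + rng.normal(0, 1.0, n_ctrl)
    x[0] = zc[0] = 0.0
    return PhantomSpec(control_points=np.column_stack([x, y, zc]), radius_mm=r)


# ---------------------------------------------------------------------------
# memory-loading calibration
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def discretization_attenuation(
    mean: float = 3.6, sd: float = 2.8,
    n_pilot: int = _PILOT_N, pilot_seed: int = _PILOT_SEED,
) -> float:
    """Pilot-simulation estimate of c = corr(M, round(clip(mean + sd M, 0, 10))).

    Rounding to integer counts and clipping to the 0..10 score range
    attenuate the latent correlation; any loading on the latent M must be
    divided by this constant to hit a target correlation with the observed
    error count.
    """
    rng = np.random.default_rng(pilot_seed)
    m = rng.standard_normal(n_pilot)
    errors = np.round(np.clip(mean + sd * m, 0.0, 10.0))
    return float(np.corrcoef(m, errors)[0, 1])


def calibrated_memory_loading(
    target_r: float = 0.41, mean: float = 3.6, sd: float = 2.8
) -> float:
    """Loading q such that corr(V, discretized errors) = target_r.

    Because the error count depends only on M, corr(V, errors) = -q c with
    c the discretization attenuation, so q = target_r / c (no iteration
    needed); c comes from the fixed-seed pilot simulation.
    """
    return target_r / discretization_attenuation(mean, sd)


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

#: Group-specific study distributions: mean (SD) of age, P-tau, memory
#: errors; female counts; amyloid-positive counts (of group n).
STUDY_GROUPS = {
    "CN": dict(n=302, age=(73.7, 5.0), ptau=(54.0, 19.0), memory=(2.0, 2.0),
               n_female=182, n_abeta_positive=82),
    "SCD": dict(n=183, age=(70.5, 5.7), ptau=(57.0, 25.0), memory=(3.4, 2.0),
                n_female=100, n_abeta_positive=69),
    "MCI": dict(n=171, age=(71.3, 5.3), ptau=(67.0, 29.0), memory=(7.0, 2.0),
                n_female=102, n_abeta_positive=107),
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    The reference (whole-sample) distributions and the volume-model loadings
    are fixed by the calibration targets; mu_V and sigma_V (total per-side
    subicular volume ~ N(500, 80^2) mm^3) are invented defaults chosen to be
    anatomically plausible — no printed per-subfield totals exist to pin
    them down.
    """

    mode: str = "calibration"
    n: int = 656
    seed: int = 0
    # whole-sample reference distributions
    age_mean: float = 72.2
    age_sd: float = 5.5
    ptau_mean: float = 58.0
    ptau_sd: float = 24.0
    memory_mean: float = 3.6
    memory_sd: float = 2.8
    icv_mean: float = 1.45e6
    icv_sd: float = 1.5e5
    female_fraction: float = 352 / 656
    apoe4_fraction: float = 401 / 653
    # Abeta42 mixture (weights from the 398/258 negative/positive split)
    abeta_weight_abnormal: float = 258 / 656
    abeta_mean_abnormal: float = 395.0
    abeta_sd_abnormal: float = 78.0
    abeta_mean_normal: float = 762.0
    abeta_sd_normal: float = 150.0
    # volume model
    volume_mean: float = 500.0
    volume_sd: float = 80.0
    age_loading: float = 0.34
    ptau_loading: float = 0.18 * math.sqrt(1.0 - 0.34 ** 2)
    memory_target_r_left: float = 0.41
    memory_target_r_right: float = 0.36
    icv_loading: float = 0.20
    # segment-share model
    posterior_coupling: float = 0.0012
    share_noise_sd: float = 0.008
    # study_like options
    group_sizes: tuple[int, int, int] = (302, 183, 171)
    atrophy_effect_sd: float = 0.0
    atrophy_segments: tuple[int, ...] = (1, 2, 3, 4, 5)
    atrophy_groups: tuple[str, ...] = ("MCI",)

    def memory_loading(self, hemisphere: str) -> float:
        target = (
            self.memory_target_r_left if hemisphere == "left"
            else self.memory_target_r_right
        )
        return calibrated_memory_loading(
            target, self.memory_mean, self.memory_sd
        )

    def noise_loading(self, hemisphere: str) -> float:
        q = self.memory_loading(hemisphere)
        ss = (
            self.age_loading ** 2 + self.ptau_loading ** 2
            + q ** 2 + self.icv_loading ** 2
        )
        if ss >= 1.0:
            raise ValueError(
                f"loadings violate a^2+p^2+q^2+beta^2 < 1 (got {ss:.3f})"
            )
        return math.sqrt(1.0 - ss)

    def validate(self) -> None:
        if self.mode not in ("calibration", "study_like"):
            raise ValueError(f"unknown mode: {self.mode}")
        for name in ("age_sd", "ptau_sd", "memory_sd", "icv_sd", "volume_sd",
                     "abeta_sd_abnormal", "abeta_sd_normal", "share_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for hemi in ("left", "right"):
            self.noise_loading(hemi)  # raises on invalid loadings


def analytic_abeta_cutoff(config: CohortConfig) -> float:
    """Equal-posterior point of the configured Abeta42 mixture (ng/l).

    For the default parameters this sits at ~527.45 ng/l, i.e. the printed
    527 at integer precision, so no adjustment of the normal-component mean
    is needed.
    """
    return equal_posterior_point(
        config.abeta_weight_abnormal,
        config.abeta_mean_abnormal, config.abeta_sd_abnormal,
        1.0 - config.abeta_weight_abnormal,
        config.abeta_mean_normal, config.abeta_sd_normal,
    )


#: Posterior segment weights for the biomarker/memory channels, scaled to
#: [-1, 1]: w_s = ((11-s) - 5.5)/4.5 for s = 1..10; they sum to zero so the
#: posterior-weighted redistribution conserves the participant's total.
def _posterior_weights(n_segments: int = N_SEGMENTS) -> np.ndarray:
    s = np.arange(1, n_segments + 1, dtype=float)
    w = (n_segments + 1 - s) - (n_segments + 1) / 2.0
    return w / w.max()


def nominal_segment_sd(config: CohortConfig) -> np.ndarray:
    """Approximate per-segment volume SD under the calibration model.

    Used as the effect-size unit when injecting atrophy: combines the base
    share of total-volume variance, the share noise, and the posterior
    coupling channels (P and M, variance 1 each).
    """
    w = _posterior_weights()
    base = (0.1 * config.volume_sd) ** 2
    noise = (config.volume_mean * config.share_noise_sd) ** 2
    coupling = 2.0 * (config.volume_mean * config.posterior_coupling * w) ** 2
    return np.sqrt(base + noise + coupling)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _orthonormal_scores(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """m exactly standardized, exactly uncorrelated score columns.

    Gaussian draws are centered, orthogonalized (QR against the constant and
    each other) and rescaled to unit sample SD.  Each column is still
    Gaussian-shaped, but sample means, SDs and pairwise correlations hit
    their population values (0, 1, 0) exactly, so the associations the
    volume model induces match their target values at the sample level
    rather than only in expectation.
    """
    G = rng.standard_normal((n, m + 1))
    G[:, 0] = 1.0  # orthogonalize against the intercept => exact zero means
    Q, _ = np.linalg.qr(G)
    S = Q[:, 1:]
    # deterministic sign: align with the raw draw
    sign = np.sign(np.einsum("ij,ij->j", S, G[:, 1:]))
    sign[sign == 0] = 1.0
    S = S * sign
    return S / S.std(axis=0, ddof=1)


def _segment_split(
    rng: np.random.Generator,
    total: np.ndarray,
    p_score: np.ndarray,
    m_score: np.ndarray,
    config: CohortConfig,
) -> np.ndarray:
    """Distribute each participant's total volume over 10 segments.

    Shares are 1/10 plus a posterior-weighted (P+M) term plus centered
    noise; shares sum to 1 exactly, so segment volumes sum to the total.
    """
    n = total.size
    w = _posterior_weights()
    eta = rng.normal(0.0, config.share_noise_sd, (n, N_SEGMENTS))
    eta -= eta.mean(axis=1, keepdims=True)
    shares = (
        0.1
        - config.posterior_coupling * np.outer(p_score + m_score, w)
        + eta
    )
    shares = np.clip(shares, 0.0, None)
    shares /= shares.sum(axis=1, keepdims=True)
    return shares * total[:, None]


def _draw_abeta(
    rng: np.random.Generator, config: CohortConfig, status: np.ndarray
) -> np.ndarray:
    """Abeta42 values given per-participant positivity indicators."""
    n = status.size
    v = np.where(
        status,
        rng.normal(config.abeta_mean_abnormal, config.abeta_sd_abnormal, n),
        rng.normal(config.abeta_mean_normal, config.abeta_sd_normal, n),
    )
    return np.clip(v, 1.0, None)


def draw_abeta_sample(
    n: int, rng: np.random.Generator, config: CohortConfig | None = None
) -> np.ndarray:
    """Moment-matched sample of n Abeta42 values from the bimodal mixture.

    The component split uses the exact mixture weight (rounded count) and
    each component's draws are standardized in-sample before scaling, so the
    empirical component moments equal the population ones — the same
    variance-reduction design as the calibration drivers.  Values are
    shuffled and floored at 1 ng/l.
    """
    config = config or CohortConfig()
    n_a = int(round(config.abeta_weight_abnormal * n))
    parts = []
    for mean, sd, k in (
        (config.abeta_mean_abnormal, config.abeta_sd_abnormal, n_a),
        (config.abeta_mean_normal, config.abeta_sd_normal, n - n_a),
    ):
        g = rng.standard_normal(k)
        g = (g - g.mean()) / g.std(ddof=0)
        parts.append(mean + sd * g)
    v = np.concatenate(parts)
    rng.shuffle(v)
    return np.clip(v, 1.0, None)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a long cohort table (participant x hemisphere x segment).

    Deterministic: the same config and seed yield an identical table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    noise_scores: np.ndarray | None = None
    if config.mode == "calibration":
        scores = _orthonormal_scores(rng, n, 6)
        a_score, p_score, m_score, i_score = scores[:, :4].T
        noise_scores = scores[:, 4:6]  # per-hemisphere volume noise
        age = config.age_mean + config.age_sd * a_score
        ptau = np.clip(config.ptau_mean + config.ptau_sd * p_score, 0.0, None)
        mem_latent = config.memory_mean + config.memory_sd * m_score
        icv = config.icv_mean + config.icv_sd * i_score
        abeta = draw_abeta_sample(n, rng, config)
        # group labels carry no distributional structure in calibration mode
        sizes = np.array(config.group_sizes, dtype=float)
        counts = np.floor(sizes / sizes.sum() * n).astype(int)
        counts[0] += n - counts.sum()
        group = np.repeat(["CN", "SCD", "MCI"], counts)
    else:
        sizes = dict(zip(("CN", "SCD", "MCI"), config.group_sizes))
        groups, ages, ptaus, mems, females, apos = [], [], [], [], [], []
        for gname, g in STUDY_GROUPS.items():
            gn = sizes[gname]
            if gn == 0:
                continue
            groups += [gname] * gn
            ages.append(rng.normal(*g["age"], gn))
            ptaus.append(np.clip(rng.normal(*g["ptau"], gn), 0.0, None))
            mems.append(rng.normal(*g["memory"], gn))
            females.append(rng.random(gn) < g["n_female"] / g["n"])
            apos.append(rng.random(gn) < g["n_abeta_positive"] / g["n"])
        group = np.asarray(groups)
        age = np.concatenate(ages)
        ptau = np.concatenate(ptaus)
        mem_latent = np.concatenate(mems)
        female = np.concatenate(females)
        abeta_pos = np.concatenate(apos)
        n = group.size
        icv = rng.normal(config.icv_mean, config.icv_sd, n)
        abeta = _draw_abeta(rng, config, abeta_pos)
        a_score = (age - config.age_mean) / config.age_sd
        p_score = (ptau - config.ptau_mean) / config.ptau_sd
        m_score = (mem_latent - config.memory_mean) / config.memory_sd
        i_score = (icv - config.icv_mean) / config.icv_sd

    memory_errors = np.round(np.clip(mem_latent, 0.0, 10.0)).astype(int)
    if config.mode == "calibration":
        female = rng.random(n) < config.female_fraction
    apoe4 = rng.random(n) < config.apoe4_fraction

    records = []
    seg_sd = nominal_segment_sd(config)
    for h_i, hemi in enumerate(("left", "right")):
        q = config.memory_loading(hemi)
        e = config.noise_loading(hemi)
        z = (
            noise_scores[:, h_i] if noise_scores is not None
            else rng.standard_normal(n)
        )
        total = config.volume_mean + config.volume_sd * (
            -config.age_loading * a_score
            - config.ptau_loading * p_score
            - q * m_score
            + config.icv_loading * i_score
            + e * z
        )
        segs = _segment_split(rng, total, p_score, m_score, config)
        if config.mode == "study_like" and config.atrophy_effect_sd:
            affected = np.isin(group, config.atrophy_groups)
            for s in config.atrophy_segments:
                segs[affected, s - 1] -= (
                    config.atrophy_effect_sd * seg_sd[s - 1]
                )
            segs = np.clip(segs, 0.0, None)
        records.append(segs)

    pid = np.array([f"sub-{i:04d}" for i in range(1, n + 1)])
    frames = []
    for h_i, hemi in enumerate(("left", "right")):
        segs = records[h_i]
        for s in range(N_SEGMENTS):
            frames.append(pd.DataFrame({
                "participant_id": pid,
                "group": group,
                "sex": np.where(female, "F", "M"),
                "age": age,
                "icv": icv,
                "abeta42": abeta,
                "ptau": ptau,
                "memory_errors": memory_errors,
                "apoe4": apoe4,
                "hemisphere": hemi,
                "segment": s + 1,
                "volume_mm3": segs[:, s],
                "excluded": False,
            }))
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(
        ["participant_id", "hemisphere", "segment"], kind="mergesort"
    ).reset_index(drop=True)
    return df


def total_volumes(cohort: pd.DataFrame, hemisphere: str = "left") -> pd.DataFrame:
    """Per-participant total volume (sum of the 10 segments) for one side."""
    sub = cohort[cohort["hemisphere"] == hemisphere]
    totals = sub.groupby("participant_id", sort=True)["volume_mm3"].sum()
    meta = (
        sub.drop_duplicates("participant_id")
        .set_index("participant_id")
        [["group", "sex", "age", "icv", "abeta42", "ptau", "memory_errors"]]
    )
    out = meta.join(totals.rename("total_mm3")).reset_index()
    return out
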