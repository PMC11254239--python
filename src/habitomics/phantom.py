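"""Synthetic phantom cohorts with planted intratumoral habitats.

Each phantom patient is an ellipsoidal "tumor" on a 3-D grid carrying
spatially contiguous habitats (Voronoi regions grown from random
interior seed points).  Every habitat has its own mean intensity per
MRI sequence and its own spatial correlation length, so habitats
differ in both first-order and texture statistics; the habitat count
and archetype composition can vary per patient.  An MSI phenotype adds
a weak diffuse shift everywhere and displaces the parameters of one
designated high-risk habitat of small, variable volume: the focal
signal is diluted in whole-tumor statistics by a patient-dependent
factor while subregion features retain it at full strength — the data
structure the subregion analysis is designed to exploit.

Clinicoradiological covariates, MSI labels (logistic in tumor location
and N stage), and exponential disease-free survival times complete the
cohort.  All randomness flows from one master seed through
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from habitomics.core import SEQUENCES, VolumeSet

#: per-habitat, per-sequence contrast pattern (rows cycle for >6 habitats)
_PATTERN = np.array(
    [
        [1, 1, -1, 0],
        [-1, 1, 1, -1],
        [0, -1, 1, 1],
        [1, -1, 0, -1],
        [-1, 0, -1, 1],
        [1, 0, 1, 0],
    ],
    dtype=float,
)

_DEFAULT_TEXTURE_SCALES = (2.0, 4.0, 1.2, 3.0, 1.6, 2.5)


@dataclass
class MsiEffect:
    """Displacement of the image phenotype under MSI.

    ``mean_shift`` is added to the high-risk habitat's mean intensity in
    every sequence (arbitrary units, same scale as the intensity means)
    and ``texture_scale_factor`` multiplies that habitat's spatial
    correlation length (values < 1 = finer texture).  On top of the
    focal component, ``global_mean_shift`` is a weak diffuse shift
    applied to every habitat.  :meth:`null` produces a cohort with no
    image-level MSI signal at all.
    """

    mean_shift: float = 14.0
    texture_scale_factor: float = 0.3
    #: habitat receiving the focal effect; 0 applies the texture factor
    #: and mean shift to every habitat
    risk_habitat: int = 1
    #: weak shift applied to every habitat (diffuse phenotype component)
    global_mean_shift: float = 2.0

    @property
    def is_null(self) -> bool:
        return (
            self.mean_shift == 0.0
            and self.texture_scale_factor == 1.0
            and self.global_mean_shift == 0.0
        )

    @classmethod
    def null(cls) -> "MsiEffect":
        return cls(mean_shift=0.0, texture_scale_factor=1.0, global_mean_shift=0.0)


@dataclass
class PhantomParams:
    """Generative parameters of one phantom patient volume."""

    grid_shape: Tuple[int, int, int] = (32, 32, 24)
    voxel_spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_habitats_true: int = 3
    habitat_intensity_means: Optional[np.ndarray] = None  # (n_habitats, 4)
    habitat_texture_scale: Optional[Tuple[float, ...]] = None  # mm per habitat
    texture_amplitude: float = 12.0
    intensity_base: float = 120.0
    intensity_separation: float = 25.0
    noise_sd: float = 4.0
    #: per-patient SD of a random offset added to each habitat's mean
    #: intensity in each sequence (biological variability of tissue
    #: archetypes; phenotype independent)
    habitat_mean_jitter_sd: float = 8.0
    bias_field_amplitude: float = 0.0
    msi_effect: MsiEffect = field(default_factory=MsiEffect)
    #: when set, the habitat count is drawn per patient from this
    #: inclusive (low, high) range and the non-risk habitats sample
    #: their intensity/texture archetypes from the library, so tumor
    #: composition varies across patients (the high-risk archetype is
    #: always present)
    n_habitats_range: Optional[Tuple[int, int]] = None
    #: volume fraction of the designated high-risk habitat (phenotype
    #: independent): a (low, high) range sampled per patient, a fixed
    #: float, or None to keep the natural Voronoi cell size.  A small
    #: focal habitat of variable size is what makes whole-tumor
    #: statistics dilute the MSI signal — by a factor that differs from
    #: patient to patient — while subregion features retain it at full,
    #: size-independent strength.
    risk_habitat_volume_frac: object = (0.08, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_habitats_true <= 10):
            raise ValueError("n_habitats_true must be in 1..10")
        if self.noise_sd < 0 or self.bias_field_amplitude < 0:
            raise ValueError("noise_sd and bias_field_amplitude must be >= 0")

    def intensity_means(self) -> np.ndarray:
        if self.habitat_intensity_means is not None:
            m = np.asarray(self.habitat_intensity_means, dtype=float)
            if m.shape != (self.n_habitats_true, len(SEQUENCES)):
                raise ValueError("habitat_intensity_means must be (n_habitats, 4)")
            return m.copy()
        rows = [_PATTERN[h % len(_PATTERN)] for h in range(self.n_habitats_true)]
        return self.intensity_base + self.intensity_separation * np.array(rows)

    def texture_scales(self) -> np.ndarray:
        if self.habitat_texture_scale is not None:
            s = np.asarray(self.habitat_texture_scale, dtype=float)
            if s.size != self.n_habitats_true:
                raise ValueError("habitat_texture_scale must have one entry per habitat")
            return s.copy()
        return np.array(
            [
                _DEFAULT_TEXTURE_SCALES[h % len(_DEFAULT_TEXTURE_SCALES)]
                for h in range(self.n_habitats_true)
            ]
        )


def _ellipsoid_mask(shape, rng: np.random.Generator) -> np.ndarray:
    center = np.array(shape) / 2.0 + rng.uniform(-1.5, 1.5, size=3)
    semi = np.array(shape) / 2.0 * rng.uniform(0.55, 0.72, size=3)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return (d <= 1.0).astype(np.uint8)


def _correlated_field(shape, sigma_vox, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length sigma."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_phantom(
    params: PhantomParams, msi: int
) -> Tuple[VolumeSet, np.ndarray]:
    """Generate one phantom patient.

    Returns the 4-sequence :class:`VolumeSet` and the ground-truth
    habitat label volume (0 outside the tumor, ``1..n_habitats_true``
    inside).  Identical ``params`` (including ``params.seed``) and
    ``msi`` reproduce the volumes bit-identically.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(int(s) for s in params.grid_shape)
    spacing = np.asarray(params.voxel_spacing_mm, dtype=float)

    mask = _ellipsoid_mask(shape, rng)
    n_mask = int(mask.sum())
    k = params.n_habitats_true
    archetypes = None
    if params.n_habitats_range is not None:
        lo, hi = params.n_habitats_range
        if not (1 <= lo <= hi <= len(_PATTERN)):
            raise ValueError("n_habitats_range outside the archetype library")
        k = int(rng.integers(lo, hi + 1))
        archetypes = [0] + list(
            rng.choice(np.arange(1, len(_PATTERN)), size=k - 1, replace=False)
        )
    if k > n_mask:
        raise ValueError(f"{k} habitats exceed {n_mask} tumor voxels")

    # Voronoi habitats from random interior seed points
    mask_idx = np.argwhere(mask)
    seed_rows = rng.choice(n_mask, size=k, replace=False)
    seeds = mask_idx[seed_rows] * spacing
    pts = mask_idx * spacing
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)  # 0..k-1
    frac = params.risk_habitat_volume_frac
    if isinstance(frac, (tuple, list)):
        frac = float(rng.uniform(*frac))
    if frac is not None and k > 1 and params.msi_effect.risk_habitat >= 1:
        # shrink the risk habitat to a focal region of the requested
        # volume: keep its voxels nearest to its seed, hand the rest to
        # the closest other habitat (same geometry for MSS and MSI)
        h = params.msi_effect.risk_habitat - 1
        target = max(int(frac * n_mask), 8)
        in_h = np.flatnonzero(assign == h)
        if len(in_h) > target:
            order = np.argsort(d2[in_h, h], kind="stable")
            kick = in_h[order[target:]]
            other = [j for j in range(k) if j != h]
            assign[kick] = np.asarray(other)[d2[np.ix_(kick, other)].argmin(axis=1)]
    truth = np.zeros(shape, dtype=np.int16)
    truth[tuple(mask_idx.T)] = assign + 1

    if archetypes is None:
        means = params.intensity_means()
        scales = params.texture_scales()
    else:
        means = params.intensity_base + params.intensity_separation * _PATTERN[archetypes]
        scales = np.asarray(_DEFAULT_TEXTURE_SCALES)[
            [a % len(_DEFAULT_TEXTURE_SCALES) for a in archetypes]
        ]
    if params.habitat_mean_jitter_sd > 0:
        means = means + rng.normal(0.0, params.habitat_mean_jitter_sd, size=means.shape)
    if msi:
        eff = params.msi_effect
        means += eff.global_mean_shift
        if eff.risk_habitat == 0:
            means += eff.mean_shift
            scales *= eff.texture_scale_factor
        else:
            h = eff.risk_habitat - 1
            if not 0 <= h < k:
                raise ValueError("risk_habitat outside 0..n_habitats_true")
            means[h] += eff.mean_shift
            scales[h] *= eff.texture_scale_factor

    sequences = {}
    # draw all texture fields regardless of msi so the same seed explores
    # the same random stream for both phenotypes
    fields = {
        (h, s): _correlated_field(shape, scales[h] / spacing, rng)
        for h in range(k)
        for s in range(len(SEQUENCES))
    }
    for s, name in enumerate(SEQUENCES):
        vol = np.full(shape, 60.0)
        for h in range(k):
            region = truth == h + 1
            vol[region] = means[h, s] + params.texture_amplitude * fields[(h, s)][region]
        if params.bias_field_amplitude > 0:
            g = _correlated_field(shape, 10.0 / spacing, rng)
            g = g / max(abs(g.min()), abs(g.max()))
            vol = vol * (1.0 + params.bias_field_amplitude * g)
        if params.noise_sd > 0:
            vol = vol + rng.normal(0.0, params.noise_sd, size=shape)
        sequences[name] = vol

    vs = VolumeSet(
        sequences=sequences,
        tumor_mask=mask,
        voxel_spacing_mm=tuple(spacing),
    )
    return vs, truth


# ---------------------------------------------------------------------------
# clinicoradiological covariates, MSI labels, DFS outcomes
# ---------------------------------------------------------------------------

#: covariate marginals of a rectal-cancer population (fractions)
_MARGINALS = {
    "male": 0.64,
    "cea_high": 0.43,
    "ca199_high": 0.13,
    "location": (0.45, 0.37, 0.18),  # low, middle, high
    "t34": 0.69,
    "n12": 0.34,
}

#: MSI odds ratios for covariate effects (high/middle location vs low, N1-N2 vs N0)
DEFAULT_OR_LOCATION_HIGH = 3.0
DEFAULT_OR_LOCATION_MIDDLE = 1.3
DEFAULT_OR_NSTAGE = 0.4

#: monthly exponential hazards; MSS : MSI hazard ratio 4
DEFAULT_HAZARD_MSS = 0.028
DEFAULT_HR_MSS_VS_MSI = 4.0
ADMIN_CENSOR_MONTHS = 60.0


def _calibrate_intercept(eta_wo_b0: np.ndarray, prevalence: float) -> float:
    lo, hi = -15.0, 15.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(-(eta_wo_b0 + mid)))
        if p.mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_clinical_cohort(
    n_patients: int,
    msi_prevalence: float,
    seed: int,
    or_location_high: float = DEFAULT_OR_LOCATION_HIGH,
    or_location_middle: float = DEFAULT_OR_LOCATION_MIDDLE,
    or_nstage: float = DEFAULT_OR_NSTAGE,
    hazard_mss: float = DEFAULT_HAZARD_MSS,
    hr_mss_vs_msi: float = DEFAULT_HR_MSS_VS_MSI,
    max_retries: int = 20,
) -> pd.DataFrame:
    """Generate the tabular part of a cohort (no images).

    MSI labels follow a logistic model in tumor location (odds up for
    middle/high vs low) and N stage (odds down for N1-N2 vs N0), with
    the intercept calibrated so the expected prevalence matches
    ``msi_prevalence``.  DFS is exponential with an MSS:MSI hazard ratio
    > 1 (MSI does better), censored administratively at 60 months or at
    a uniform loss-to-follow-up time.  Patients are split 80/20 into
    training and external test cohorts; degenerate label draws (a cohort
    with a single class) are redrawn up to ``max_retries`` times.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    if not 0.0 < msi_prevalence < 1.0:
        raise ValueError("msi_prevalence must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    age = np.clip(np.round(rng.normal(63.0, 10.0, n_patients)), 28, 92).astype(int)
    sex = np.where(rng.random(n_patients) < _MARGINALS["male"], "male", "female")
    cea = np.where(rng.random(n_patients) < _MARGINALS["cea_high"], ">5", "<=5")
    ca199 = np.where(rng.random(n_patients) < _MARGINALS["ca199_high"], ">37", "<=37")
    location = rng.choice(
        ["low", "middle", "high"], size=n_patients, p=_MARGINALS["location"]
    )
    t_stage = np.where(rng.random(n_patients) < _MARGINALS["t34"], "T3-T4", "T1-T2")
    n_stage = np.where(rng.random(n_patients) < _MARGINALS["n12"], "N1-N2", "N0")

    eta = (
        np.log(or_location_high) * (location == "high")
        + np.log(or_location_middle) * (location == "middle")
        + np.log(or_nstage) * (n_stage == "N1-N2")
    )
    b0 = _calibrate_intercept(eta, msi_prevalence)
    p = 1.0 / (1.0 + np.exp(-(eta + b0)))

    n_train = int(round(0.8 * n_patients))
    order = rng.permutation(n_patients)
    cohort = np.empty(n_patients, dtype=object)
    cohort[order[:n_train]] = "training"
    cohort[order[n_train:]] = "external_test"

    msi = None
    fallback = None
    n_test = n_patients - n_train
    for attempt in range(max_retries):
        draw = (rng.random(n_patients) < p).astype(int)
        ok_train = len(np.unique(draw[cohort == "training"])) == 2
        ok_test = len(np.unique(draw[cohort == "external_test"])) == 2
        if ok_train and (ok_test or n_test < 4):
            msi = draw
            break
        if ok_train and fallback is None:
            fallback = draw
        warnings.warn("degenerate MSI draw (single class in a cohort); regenerating")
    if msi is None:
        if fallback is not None:
            msi = fallback
        else:
            # tiny cohorts at extreme prevalence: force one minority label
            msi = draw
            minority = 1 if msi.mean() < 0.5 else 0
            tr_idx = np.flatnonzero(cohort == "training")
            msi[tr_idx[0]] = minority
            warnings.warn("forced a minority-class label into the training cohort")

    lam = np.where(msi == 1, hazard_mss / hr_mss_vs_msi, hazard_mss)
    t_event = rng.exponential(1.0 / lam)
    t_cens = np.minimum(ADMIN_CENSOR_MONTHS, rng.uniform(6.0, ADMIN_CENSOR_MONTHS, n_patients))
    dfs_time = np.maximum(np.minimum(t_event, t_cens), 0.25)
    dfs_event = (t_event <= t_cens).astype(int)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_patients)],
            "age": age,
            "sex": sex,
            "cea": cea,
            "ca19_9": ca199,
            "location": location,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "msi": msi,
            "dfs_time": dfs_time,
            "dfs_event": dfs_event,
            "cohort": cohort,
        }
    )


def generate_cohort(
    n_patients: int,
    msi_prevalence: float,
    params: PhantomParams,
    seed: int,
) -> Tuple[List[Tuple[VolumeSet, np.ndarray]], pd.DataFrame]:
    """Generate a full phantom cohort: images plus clinical table.

    Returns ``(patients, table)`` where ``patients[i]`` is the
    ``(VolumeSet, truth_labels)`` pair for row ``i`` of ``table``.
    """
    ss = np.random.SeedSequence(seed)
    table_seed, image_seed = ss.spawn(2)
    table = generate_clinical_cohort(
        n_patients, msi_prevalence, seed=table_seed.generate_state(1)[0] % (2**31)
    )
    child_seeds = image_seed.spawn(n_patients)
    patients = []
    for i in range(n_patients):
        p_i = dataclasses.replace(
            params, seed=int(child_seeds[i].generate_state(1)[0] % (2**31))
        )
        vs, truth = generate_phantom(p_i, int(table["msi"].iloc[i]))
        vs.patient_id = table["patient_id"].iloc[i]
        patients.append((vs, truth))
    return patients, table


def generate_rater_perturbation(
    mask: np.ndarray,
    seed: int,
    flip_prob: float = 0.2,
    decay_mm: float = 1.0,
    dice_floor: float = 0.8,
    spacing_mm=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Simulate a second rater's segmentation of ``mask``.

    Voxels near the mask boundary flip (in or out) with probability
    ``flip_prob * exp(-(d-1)/decay_mm)`` where ``d`` is the distance to
    the boundary; the result is guaranteed nonempty with Dice overlap
    >= ``dice_floor`` (flip probability is halved and the perturbation
    redrawn until both hold).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    if flip_prob == 0.0:
        return mask.astype(np.uint8)
    rng = np.random.default_rng(seed)
    spacing = np.asarray(spacing_mm, dtype=float)

    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    dist = np.where(mask, d_in, d_out)  # distance to boundary

    p = flip_prob
    while True:
        flip_p = p * np.exp(-np.maximum(dist - 1.0, 0.0) / decay_mm)
        flips = rng.random(mask.shape) < flip_p
        out = np.where(flips, ~mask, mask)
        inter = (out & mask).sum()
        dice = 2.0 * inter / (out.sum() + mask.sum()) if out.any() else 0.0
        if out.any() and dice >= dice_floor:
            return out.astype(np.uint8)
        p *= 0.5
        if p < 1e-6:
            return mask.astype(np.uint8)
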