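"""Synthetic 3D brain phantoms with tissue structure, aging and site effects.

The simulator stands in for real multi-site T1-weighted cohorts.  Each
phantom is a set of nested, smoothly deformed ellipsoidal shells — a
white-matter core, a gray-matter shell and a CSF rim — with per-subject
random radial perturbations, so GM/WM boundaries are curved and carry
nontrivial partial-volume structure.  Partial-volume maps are obtained by
Gaussian-smoothing the hard tissue labels and renormalizing inside the brain
mask, which gives the residual-partial-volume metrics a nonzero, controlled
ground truth.

Aging is modelled as gray-matter atrophy: the GM volume fraction of the
brain follows a linear decline with age (GM is converted to CSF; WM and the
tissue intensities are age-independent), isolating the biological covariate
that harmonization must protect.  The configured atrophy line is exposed as
:func:`gm_fraction_line` so downstream checks can compare generated cohorts
against their own ground truth.

Site effects compose, in this fixed order:

1. per-tissue contrast multipliers (weighted by the partial-volume maps),
2. gamma transform of brain intensities rescaled to [0, 1] by the brain max,
3. smooth multiplicative bias field (unit mean over the brain),
4. global intensity scale,
5. additive Gaussian noise inside the mask.

The background stays exactly zero throughout, and for ``noise_sd = 0`` the
transform is invertible given its configuration (see
:func:`invert_site_effect`).  Everything is a pure function of its
parameters and an integer seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DegenerateInputError, TissueSegmentation, Volume, save_volume

__all__ = [
    "Phantom", "Cohort", "SiteEffectConfig", "gm_fraction_line",
    "generate_phantom", "apply_site_effect", "invert_site_effect",
    "generate_cohort", "generate_traveling_cohort", "save_cohort", "load_cohort",
    "SITE_PRESETS",
]

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Brain-relative GM fraction at the reference age (young adult).
GM_FRACTION_YOUNG = 0.45
#: GM fraction lost per year of age past the reference age (GM -> CSF).
ATROPHY_SLOPE = 0.0015
#: Reference age (years) at which the atrophy line starts.
ATROPHY_REF_AGE = 20.0
#: Age-independent WM fraction of the brain.
WM_FRACTION = 0.33
#: Mean tissue intensities (CSF, GM, WM) in arbitrary units, before site effects.
TISSUE_MEANS = (150.0, 300.0, 450.0)
#: SD of the per-subject multiplicative jitter on tissue means.
TISSUE_JITTER = 0.04
#: SD of the within-tissue intensity texture (arbitrary units).
TEXTURE_SD = 8.0
#: Gaussian sigma (voxels) used to turn hard labels into partial volumes.
PV_SIGMA = 0.7


def gm_fraction_line(age: float, young: float = GM_FRACTION_YOUNG,
                     slope: float = ATROPHY_SLOPE,
                     ref_age: float = ATROPHY_REF_AGE) -> float:
    """Configured GM-fraction-vs-age line: young - slope * (age - ref_age)."""
    return young - slope * (max(float(age), ref_age) - ref_age)


@dataclasses.dataclass(frozen=True)
class SiteEffectConfig:
    """Parameters of one simulated scanner/site effect."""

    scale: float = 1.0              # global multiplicative factor (> 0)
    gamma: float = 1.0              # exponent on [0,1]-rescaled brain intensities (> 0)
    bias_amplitude: float = 0.0     # peak fractional deviation of the bias field (>= 0)
    bias_smoothness: float = 8.0    # correlation length of the bias field (voxels, > 0)
    noise_sd: float = 0.0           # additive Gaussian noise SD (intensity units, >= 0)
    contrast: tuple[float, float, float] = (1.0, 1.0, 1.0)  # CSF, GM, WM multipliers

    def validate(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.bias_amplitude < 0 or self.bias_amplitude >= 1:
            raise ValueError("bias_amplitude must be in [0, 1)")
        if self.bias_smoothness <= 0:
            raise ValueError("bias_smoothness must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.contrast) != 3 or any(c <= 0 for c in self.contrast):
            raise ValueError("contrast needs 3 positive multipliers (CSF, GM, WM)")

    @property
    def is_identity(self) -> bool:
        return (self.scale == 1.0 and self.gamma == 1.0 and self.bias_amplitude == 0.0
                and self.noise_sd == 0.0 and tuple(self.contrast) == (1.0, 1.0, 1.0))


#: Illustrative site presets (not calibrated to any real scanner).  The two
#: sites differ in gamma and per-tissue contrast — differences that, like the
#: scanner effects they emulate, survive median normalization — plus a global
#: scale, a smooth bias field and additive noise.  Site B is the "brighter,
#: higher GM/WM contrast" style; site A is flatter with relatively bright CSF.
SITE_PRESETS: dict[str, SiteEffectConfig] = {
    "identity": SiteEffectConfig(),
    "siteA": SiteEffectConfig(scale=0.90, gamma=0.85, bias_amplitude=0.08,
                              bias_smoothness=8.0, noise_sd=5.0,
                              contrast=(1.05, 0.95, 1.00)),
    "siteB": SiteEffectConfig(scale=1.15, gamma=1.20, bias_amplitude=0.08,
                              bias_smoothness=8.0, noise_sd=5.0,
                              contrast=(0.90, 1.10, 1.00)),
}


@dataclasses.dataclass
class Phantom:
    """One synthetic subject: ground-truth volume + segmentation + age."""

    volume: Volume
    segmentation: TissueSegmentation
    age: float
    subject_id: str
    seed: int
    observed: Volume | None = None   # site-effected view, if any


@dataclasses.dataclass
class Cohort:
    """An ordered collection of phantoms sharing one site."""

    phantoms: list[Phantom]
    site_label: str

    def __len__(self) -> int:
        return len(self.phantoms)

    def __iter__(self):
        return iter(self.phantoms)

    @property
    def ages(self) -> np.ndarray:
        return np.array([p.age for p in self.phantoms])

    def volumes(self, observed: bool = True) -> list[Volume]:
        return [(p.observed if observed and p.observed is not None else p.volume)
                for p in self.phantoms]

    def age_summary(self) -> dict[str, float]:
        a = self.ages
        return {"n": len(a), "mean": float(a.mean()), "sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                "min": float(a.min()), "max": float(a.max())}


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(age: float, size: int = 48, seed: int = 0,
                     subject_id: str | None = None) -> Phantom:
    """Generate one deterministic phantom for (age, size, seed).

    GM volume fraction decreases linearly with age along
    :func:`gm_fraction_line`; tissue mean intensities are ordered
    CSF < GM < WM with per-subject jitter controlled by the seed.
    """
    if not 0 < age < 120:
        raise ValueError("age must be in (0, 120)")
    if size < 32:
        raise ValueError("size must be >= 32 to host three nested tissue shells")
    rng = np.random.default_rng(seed)

    # --- geometry: deformed ellipsoid, strictly inside the grid ------------
    center = (size - 1) / 2.0
    ax = np.arange(size) - center
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    semi = 0.40 * size * (1.0 + rng.uniform(-0.03, 0.03, size=3))
    u0 = np.sqrt((x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2)
    # smooth directional perturbation: a few random cosine modes on the unit sphere
    r = np.sqrt(x * x + y * y + z * z)
    r[r == 0] = 1.0
    dirs = np.stack([x / r, y / r, z / r])
    rho = np.ones_like(u0)
    for _ in range(4):
        kvec = rng.normal(0.0, 1.2, size=3)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.01, 0.035)
        rho += amp * np.cos(kvec[0] * dirs[0] + kvec[1] * dirs[1]
                            + kvec[2] * dirs[2] + phase)
    u = u0 * rho

    # --- tissue radii from target volume fractions -------------------------
    # u is homogeneous of degree 1, so the volume inside {u < r} scales as r^3
    # and brain-relative fractions are exact differences of cubed radii.
    wm_frac = WM_FRACTION * (1.0 + rng.uniform(-0.04, 0.04))
    gm_frac = gm_fraction_line(age) * (1.0 + rng.uniform(-0.02, 0.02))
    r_wm = wm_frac ** (1.0 / 3.0)
    r_gm = (wm_frac + gm_frac) ** (1.0 / 3.0)

    mask = u <= 1.0
    if not mask.any():
        raise ValueError("degenerate geometry: empty brain mask")
    labels = np.zeros((3,) + u.shape)          # CSF, GM, WM one-hot
    labels[2] = (u <= r_wm)
    labels[1] = (u > r_wm) & (u <= r_gm)
    labels[0] = (u > r_gm) & mask

    pv = np.stack([ndimage.gaussian_filter(l, PV_SIGMA) for l in labels])
    pv = np.clip(pv, 0.0, None)
    pv[:, ~mask] = 0.0
    total = pv.sum(axis=0)
    total[~mask] = 1.0
    pv /= total
    seg = TissueSegmentation(gm=pv[1], wm=pv[2], csf=pv[0])

    # --- intensities --------------------------------------------------------
    means = np.asarray(TISSUE_MEANS) * (1.0 + rng.normal(0.0, TISSUE_JITTER, size=3))
    means = np.sort(means)                      # keep CSF < GM < WM ordering
    data = pv[0] * means[0] + pv[1] * means[1] + pv[2] * means[2]
    if TEXTURE_SD > 0:
        data = data + rng.normal(0.0, TEXTURE_SD, size=data.shape)
    data = np.clip(data, 0.0, None)
    data[~mask] = 0.0

    vol = Volume(data, mask)
    sid = subject_id if subject_id is not None else f"sub-{seed:08d}"
    return Phantom(volume=vol, segmentation=seg, age=float(age),
                   subject_id=sid, seed=int(seed))


# ---------------------------------------------------------------------------
# site effects
# ---------------------------------------------------------------------------

def _bias_field(shape: tuple[int, ...], mask: np.ndarray,
                cfg: SiteEffectConfig, rng: np.random.Generator) -> np.ndarray:
    """Seeded smooth multiplicative field, unit mean over the brain mask."""
    noise = rng.normal(size=shape)
    f = ndimage.gaussian_filter(noise, cfg.bias_smoothness)
    f = f - f[mask].mean()
    peak = np.abs(f[mask]).max()
    if peak > 0:
        f = f / peak
    field = 1.0 + cfg.bias_amplitude * f
    field = field / field[mask].mean()
    return field


def apply_site_effect(vol: Volume, seg: TissueSegmentation,
                      cfg: SiteEffectConfig, seed: int = 0) -> Volume:
    """Apply a simulated site effect (see module docstring for the order)."""
    cfg.validate()
    if not vol.mask.any():
        raise DegenerateInputError("volume has an empty brain mask")
    rng = np.random.default_rng(seed)
    mask = vol.mask
    out = vol.data.copy()

    if tuple(cfg.contrast) != (1.0, 1.0, 1.0):
        w = (seg.csf * cfg.contrast[0] + seg.gm * cfg.contrast[1]
             + seg.wm * cfg.contrast[2])
        out[mask] = out[mask] * w[mask]

    m = out[mask].max()
    if m > 0 and cfg.gamma != 1.0:
        t = np.clip(out[mask] / m, 0.0, None)
        out[mask] = (t ** cfg.gamma) * m

    field = _bias_field(out.shape, mask, cfg, rng)  # drawn even if amplitude 0,
    if cfg.bias_amplitude > 0:                      # to keep the noise stream stable
        out[mask] = out[mask] * field[mask]

    if cfg.scale != 1.0:
        out[mask] = out[mask] * cfg.scale

    if cfg.noise_sd > 0:
        out[mask] = out[mask] + rng.normal(0.0, cfg.noise_sd, size=int(mask.sum()))

    out[~mask] = 0.0
    return vol.copy_with(out)


def invert_site_effect(vol: Volume, seg: TissueSegmentation,
                       cfg: SiteEffectConfig, seed: int = 0) -> Volume:
    """Invert a noiseless site effect on the brain voxels.

    Valid for ``cfg.noise_sd == 0``: the transform is a monotone intensity
    map composed with strictly positive multiplicative fields.  The bias
    field is regenerated from the same seed.
    """
    cfg.validate()
    if cfg.noise_sd != 0:
        raise ValueError("site effect with additive noise is not invertible")
    rng = np.random.default_rng(seed)
    mask = vol.mask
    out = vol.data.copy()
    field = _bias_field(out.shape, mask, cfg, rng)

    if cfg.scale != 1.0:
        out[mask] = out[mask] / cfg.scale
    if cfg.bias_amplitude > 0:
        out[mask] = out[mask] / field[mask]
    m = out[mask].max()
    if m > 0 and cfg.gamma != 1.0:
        t = np.clip(out[mask] / m, 0.0, None)
        out[mask] = (t ** (1.0 / cfg.gamma)) * m
    if tuple(cfg.contrast) != (1.0, 1.0, 1.0):
        w = (seg.csf * cfg.contrast[0] + seg.gm * cfg.contrast[1]
             + seg.wm * cfg.contrast[2])
        out[mask] = out[mask] / w[mask]
    out[~mask] = 0.0
    return vol.copy_with(out)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(n: int, age_low: float = 20.0, age_high: float = 80.0,
                    cfg: SiteEffectConfig | None = None, size: int = 48,
                    seed: int = 0, site_label: str = "site",
                    ages: np.ndarray | None = None) -> Cohort:
    """Generate ``n`` phantoms with uniform (or supplied) ages and an optional
    shared site effect.  Every phantom keeps its pre-site-effect ground truth
    in ``phantom.volume``; the site-effected view is ``phantom.observed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if age_low >= age_high:
        raise ValueError("age_low must be < age_high")
    rng = np.random.default_rng(seed)
    if ages is None:
        ages = rng.uniform(age_low, age_high, size=n)
    else:
        ages = np.asarray(ages, dtype=float)
        if len(ages) != n:
            raise ValueError("len(ages) != n")
    phantoms = []
    for i in range(n):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        site_seed = int(rng.integers(0, 2 ** 31 - 1))
        p = generate_phantom(float(ages[i]), size=size, seed=sub_seed,
                             subject_id=f"{site_label}-{i:03d}")
        if cfg is not None and not cfg.is_identity:
            p.observed = apply_site_effect(p.volume, p.segmentation, cfg, site_seed)
        elif cfg is not None:
            p.observed = p.volume.copy_with(p.volume.data.copy())
        phantoms.append(p)
    return Cohort(phantoms=phantoms, site_label=site_label)


def generate_traveling_cohort(n: int, cfgA: SiteEffectConfig, cfgB: SiteEffectConfig,
                              size: int = 48, seed: int = 0,
                              age_low: float = 20.0, age_high: float = 80.0
                              ) -> tuple[Cohort, Cohort]:
    """Paired cohorts: the i-th subjects share the same underlying anatomy and
    age and differ only by site effect and noise realization."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_low, age_high, size=n)
    pa, pb = [], []
    for i in range(n):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        seed_a = int(rng.integers(0, 2 ** 31 - 1))
        seed_b = int(rng.integers(0, 2 ** 31 - 1))
        base = generate_phantom(float(ages[i]), size=size, seed=sub_seed,
                                subject_id=f"trav-{i:03d}")
        a = Phantom(base.volume, base.segmentation, base.age, base.subject_id,
                    base.seed,
                    observed=apply_site_effect(base.volume, base.segmentation,
                                               cfgA, seed_a))
        b = Phantom(base.volume, base.segmentation, base.age, base.subject_id,
                    base.seed,
                    observed=apply_site_effect(base.volume, base.segmentation,
                                               cfgB, seed_b))
        pa.append(a)
        pb.append(b)
    return (Cohort(pa, site_label="siteA"), Cohort(pb, site_label="siteB"))


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, out_dir: str | Path, observed: bool = True) -> pd.DataFrame:
    """Write a cohort as NIfTI volumes + masks + partial-volume maps and a
    sidecar participants table; returns the table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort:
        vol = p.observed if observed and p.observed is not None else p.volume
        stem = out / p.subject_id
        save_volume(vol, f"{stem}_T1w.nii.gz", f"{stem}_mask.nii.gz")
        for tissue in ("gm", "wm", "csf"):
            save_volume(Volume(p.segmentation.map_for(tissue), vol.mask),
                        f"{stem}_pv-{tissue}.nii.gz")
        rows.append({"subject_id": p.subject_id, "age": p.age,
                     "site_label": cohort.site_label, "seed": p.seed})
    table = pd.DataFrame(rows)
    table.to_csv(out / "participants.csv", index=False)
    return table


def load_cohort(in_dir: str | Path) -> Cohort:
    from .core import load_volume
    d = Path(in_dir)
    table = pd.read_csv(d / "participants.csv")
    phantoms = []
    site = str(table["site_label"].iloc[0]) if len(table) else "site"
    for _, row in table.iterrows():
        stem = d / str(row["subject_id"])
        vol = load_volume(f"{stem}_T1w.nii.gz", f"{stem}_mask.nii.gz")
        seg = TissueSegmentation(
            gm=load_volume(f"{stem}_pv-gm.nii.gz", f"{stem}_mask.nii.gz").data,
            wm=load_volume(f"{stem}_pv-wm.nii.gz", f"{stem}_mask.nii.gz").data,
            csf=load_volume(f"{stem}_pv-csf.nii.gz", f"{stem}_mask.nii.gz").data)
        phantoms.append(Phantom(volume=vol, segmentation=seg, age=float(row["age"]),
                                subject_id=str(row["subject_id"]),
                                seed=int(row.get("seed", 0))))
    return Cohort(phantoms=phantoms, site_label=site)
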