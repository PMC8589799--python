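"""Synthetic multiparametric MRI cohorts for treated high-grade glioma.

Real surveillance cohorts of this kind are private, so every downstream
stage is exercised on generated data with the statistical structure the
analysis assumes:

* class-dependent lesion perfusion (after z-scoring against a deep-grey
  reference region, progressive disease is markedly hyperperfused,
  pseudoprogression and stable disease are not);
* class-dependent longitudinal trajectories (progression rises across time
  points; pseudoprogression rises then falls — the non-monotone course is
  what makes longitudinal features informative);
* class-dependent enhancement on post-contrast T1 and within-lesion texture
  heterogeneity;
* imperfect simulated rater labels, emulating radiologist accuracy in the
  0.7-0.85 range.

Geometry is deliberately simple: an ellipsoidal brain, a two-compartment
piecewise-constant tissue background (white matter plus a deep-grey
ellipsoid pair that doubles as the reference region) softened by a Gaussian
blur and a smooth random field, and an ellipsoidal lesion whose voxels carry
a mean-normalised lognormal heterogeneity texture.  Everything is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_core import (
    CLASS_LABELS,
    SEQUENCES,
    CohortManifest,
    Mask,
    StudyTimePoint,
    Volume,
    logger,
    write_manifest,
    write_mask,
    write_volume,
)


class GeneratorError(ValueError):
    """Raised when a requested lesion cannot fit the simulation grid."""


@dataclass
class ClassProfile:
    """Lesion phenotype for one response class.

    Perfusion is parameterised on the z-score scale (relative to the
    deep-grey reference region); enhancement in arbitrary units relative to
    the normal-tissue post-contrast level.  Slope tuples give the change per
    time-point transition (tp1→tp2, tp2→tp3), which allows the
    pseudoprogression rise-then-fall course.
    """

    label: str
    lesion_rcbv_z_mean: float
    rcbv_z_slope: tuple[float, float]
    enhancement_mean: float
    enhancement_slope: tuple[float, float]
    lesion_radius_mm: float = 12.0
    lesion_radius_sd_mm: float = 3.0
    radius_growth_mm: tuple[float, float] = (0.0, 0.0)
    texture_heterogeneity_sd: float = 0.15
    rcbv_z_between_subject_sd: float = 0.25
    enhancement_between_subject_sd: float = 0.08

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise GeneratorError(f"unknown class label {self.label!r}")
        for name in (
            "lesion_radius_sd_mm",
            "texture_heterogeneity_sd",
            "rcbv_z_between_subject_sd",
            "enhancement_between_subject_sd",
        ):
            if getattr(self, name) < 0:
                raise GeneratorError(f"{name} must be >= 0")

    def rcbv_z_at(self, tp: int) -> float:
        return self.lesion_rcbv_z_mean + sum(self.rcbv_z_slope[: tp - 1])

    def enhancement_at(self, tp: int) -> float:
        return self.enhancement_mean + sum(self.enhancement_slope[: tp - 1])

    def radius_offset_at(self, tp: int) -> float:
        return sum(self.radius_growth_mm[: tp - 1])


def default_profiles() -> dict[str, ClassProfile]:
    """Split-signal study conditions.

    Progression is separated from the other classes chiefly by perfusion
    (z ≈ 2 vs ≈ 0.3-0.5) while pseudoprogression is separated from stable
    disease chiefly by enhancement (1.5 vs 1.0) — so neither structural-only
    nor perfusion-only features suffice for the full 3-class problem.
    """
    return {
        "PD": ClassProfile(
            label="PD",
            lesion_rcbv_z_mean=2.0,
            rcbv_z_slope=(0.8, 0.8),
            enhancement_mean=1.6,
            enhancement_slope=(0.3, 0.3),
            radius_growth_mm=(2.0, 2.0),
            texture_heterogeneity_sd=0.35,
        ),
        "PsP": ClassProfile(
            label="PsP",
            lesion_rcbv_z_mean=0.5,
            rcbv_z_slope=(-0.4, -0.4),
            enhancement_mean=1.5,
            enhancement_slope=(0.3, -0.4),
            radius_growth_mm=(1.0, -1.0),
            texture_heterogeneity_sd=0.20,
        ),
        "SD": ClassProfile(
            label="SD",
            lesion_rcbv_z_mean=0.3,
            rcbv_z_slope=(0.0, 0.0),
            enhancement_mean=1.0,
            enhancement_slope=(0.0, 0.0),
            radius_growth_mm=(0.0, 0.0),
            texture_heterogeneity_sd=0.15,
        ),
    }


def trajectory_signal_profiles() -> dict[str, ClassProfile]:
    """Conditions where progression and pseudoprogression are identical at
    the first time point and differ only in trajectory direction.

    Single-time-point features cannot separate PD from PsP here; the gain
    from adding a second time point and subtraction features is the quantity
    under test.
    """
    base = default_profiles()
    shared = dict(
        lesion_rcbv_z_mean=1.5,
        enhancement_mean=1.5,
        texture_heterogeneity_sd=0.25,
        lesion_radius_mm=12.0,
        lesion_radius_sd_mm=3.0,
    )
    return {
        "PD": replace(
            base["PD"],
            rcbv_z_slope=(0.8, 0.8),
            enhancement_slope=(0.3, 0.3),
            radius_growth_mm=(2.0, 2.0),
            **shared,
        ),
        "PsP": replace(
            base["PsP"],
            rcbv_z_slope=(-0.6, -0.6),
            enhancement_slope=(-0.4, -0.4),
            radius_growth_mm=(-1.0, -1.0),
            **shared,
        ),
        "SD": base["SD"],
    }


#: Piecewise-constant tissue levels (a.u.) per sequence: white matter,
#: deep grey, and the lesion's non-trajectory sequences.
TISSUE_LEVELS: Mapping[str, Mapping[str, float]] = {
    "T1": {"wm": 1.0, "dg": 0.9, "lesion": 0.85},
    "T1Gad": {"wm": 1.0, "dg": 0.9, "lesion": None},  # trajectory-driven
    "T2": {"wm": 1.0, "dg": 1.1, "lesion": 1.3},
    "FLAIR": {"wm": 1.0, "dg": 1.1, "lesion": 1.4},
    "rCBV": {"wm": 1.0, "dg": 1.4, "lesion": None},  # z-target-driven
    "rCBF": {"wm": 1.0, "dg": 1.4, "lesion": None},
}

#: Amplitude of the smooth tissue-variability field, as a fraction of the
#: white-matter level; this is what gives the reference region a non-zero SD.
FIELD_AMPLITUDE = 0.05
FIELD_SMOOTH_VOX = 2.0
COMPARTMENT_BLUR_VOX = 1.0
LESION_TEXTURE_SMOOTH_VOX = 0.8

#: Fixed anatomy, as fractions of the field of view.
LESION_CENTRE_FRAC = (0.34, 0.34, 0.50)
LESION_AXIS_SCALES = (1.0, 0.85, 0.9)
REFERENCE_CENTRES_FRAC = ((0.72, 0.64, 0.50), (0.72, 0.36, 0.50))
REFERENCE_SEMI_AXES_MM = (7.0, 5.0, 5.0)
BRAIN_SEMI_AXES_FRAC = 0.48
MAX_LESION_RADIUS_FRAC = 0.26  # of the smallest FOV extent

#: Days from the first scan, per time point (follow-up intervals of roughly
#: three months then a further seven).
TIMEPOINT_DAYS = (0, 90, 290)


@dataclass
class CohortConfig:
    """Cohort-level simulation settings.

    ``n_time_points`` is either a single int applied to every subject or a
    length-3 tuple of probabilities for 1, 2 or 3 time points.
    """

    n_per_class: tuple[int, int, int] = (30, 15, 15)  # PD, PsP, SD
    n_time_points: int | tuple[float, float, float] = 2
    grid_shape: tuple[int, int, int] = (36, 36, 36)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_model: str = "gaussian"
    noise_sigma: float = 0.05
    rater_error_rates: Mapping[str, float] = field(
        default_factory=lambda: {"PD": 0.20, "PsP": 0.35, "SD": 0.20}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_class):
            raise GeneratorError("n_per_class entries must be >= 1")
        if self.noise_sigma < 0:
            raise GeneratorError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise GeneratorError(f"unknown noise model {self.noise_model!r}")
        for lbl, r in self.rater_error_rates.items():
            if not 0 <= r <= 1:
                raise GeneratorError(f"rater error rate for {lbl} outside [0, 1]")

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing))


@dataclass
class GeneratedStudy:
    """One generated time point plus the ground truth used to build it."""

    study: StudyTimePoint
    truth: dict


def _coordinate_grids(config: CohortConfig) -> list[np.ndarray]:
    """Voxel-centre world coordinates (mm) per axis, broadcastable to 3-D."""
    axes = [
        (np.arange(n) + 0.5) * s
        for n, s in zip(config.grid_shape, config.spacing)
    ]
    return list(np.meshgrid(*axes, indexing="ij"))


def _ellipsoid(coords: list[np.ndarray], centre_mm, semi_axes_mm) -> np.ndarray:
    q = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, centre_mm, semi_axes_mm))
    return q <= 1.0


def _anatomy(config: CohortConfig) -> dict[str, np.ndarray]:
    coords = _coordinate_grids(config)
    fov = config.fov_mm
    brain = _ellipsoid(
        coords,
        [f / 2 for f in fov],
        [BRAIN_SEMI_AXES_FRAC * f for f in fov],
    )
    reference = np.zeros(config.grid_shape, dtype=bool)
    for frac in REFERENCE_CENTRES_FRAC:
        centre = [f * c for f, c in zip(fov, frac)]
        reference |= _ellipsoid(coords, centre, REFERENCE_SEMI_AXES_MM)
    return {"coords": coords, "brain": brain, "reference": reference}


def _lesion_mask(config: CohortConfig, anatomy: dict, radius_mm: float) -> np.ndarray:
    cap = MAX_LESION_RADIUS_FRAC * min(config.fov_mm)
    if radius_mm > cap:
        raise GeneratorError(
            f"lesion radius {radius_mm:.1f} mm exceeds grid extent "
            f"(max {cap:.1f} mm for FOV {config.fov_mm})"
        )
    centre = [f * c for f, c in zip(config.fov_mm, LESION_CENTRE_FRAC)]
    semi = [radius_mm * s for s in LESION_AXIS_SCALES]
    mask = _ellipsoid(anatomy["coords"], centre, semi)
    if not mask.any():
        raise GeneratorError(f"lesion radius {radius_mm:.1f} mm covers no voxel")
    if (mask & anatomy["reference"]).any():
        raise GeneratorError("lesion overlaps the reference region")
    return mask


def _smooth_field(rng: np.random.Generator, shape, smooth_vox: float) -> np.ndarray:
    raw = gaussian_filter(rng.standard_normal(shape), smooth_vox)
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def _heterogeneity(
    rng: np.random.Generator, shape, lesion: np.ndarray, sd: float
) -> np.ndarray:
    """Mean-normalised lognormal texture over the lesion (1 everywhere if sd=0)."""
    if sd == 0:
        return np.ones(shape)
    g = gaussian_filter(rng.standard_normal(shape), LESION_TEXTURE_SMOOTH_VOX)
    g_sd = g[lesion].std()
    if g_sd > 0:
        g = g / g_sd
    h = np.exp(sd * g - sd**2 / 2)
    h = h / h[lesion].mean()
    return h


def _add_noise(data: np.ndarray, rng: np.random.Generator, config: CohortConfig):
    if config.noise_sigma == 0:
        return data
    if config.noise_model == "gaussian":
        return data + rng.normal(0, config.noise_sigma, data.shape)
    n1 = rng.normal(0, config.noise_sigma, data.shape)
    n2 = rng.normal(0, config.noise_sigma, data.shape)
    return np.sqrt((data + n1) ** 2 + n2**2)


def generate_subject(
    profile: ClassProfile,
    config: CohortConfig,
    subject_seed,
    subject_id: str | None = None,
    n_time_points: int | None = None,
) -> list[GeneratedStudy]:
    """Generate all time points for one subject.

    The generator's contract: at noise sigma 0, the lesion mean of the rCBV
    map — after z-scoring against the reference region — equals the
    profile's z target for that time point exactly in-sample (the
    heterogeneity field is mean-normalised), and in expectation otherwise.
    """
    rng = np.random.default_rng(subject_seed)
    anatomy = _anatomy(config)
    if n_time_points is None:
        n_time_points = _draw_n_time_points(config, rng)
    sid = subject_id or f"{profile.label}-{rng.integers(1e9):09d}"

    z_jitter = rng.normal(0, profile.rcbv_z_between_subject_sd)
    enh_jitter = rng.normal(0, profile.enhancement_between_subject_sd)
    cap = MAX_LESION_RADIUS_FRAC * min(config.fov_mm)
    max_growth = max(0.0, max(
        profile.radius_offset_at(tp) for tp in range(1, n_time_points + 1)
    ))
    r1 = float(
        np.clip(
            rng.normal(profile.lesion_radius_mm, profile.lesion_radius_sd_mm),
            5.0,
            cap - max_growth,
        )
    )

    studies = []
    for tp in range(1, n_time_points + 1):
        radius = max(4.0, r1 + profile.radius_offset_at(tp))
        lesion = _lesion_mask(config, anatomy, radius)
        z_target = profile.rcbv_z_at(tp) + z_jitter
        enh_target = profile.enhancement_at(tp) + enh_jitter
        volumes: dict[str, Volume] = {}
        truth: dict = {
            "radius_mm": radius,
            "rcbv_z_target": z_target,
            "rcbf_z_target": z_target,
            "enhancement_target": enh_target,
            "heterogeneity_sd": profile.texture_heterogeneity_sd,
        }
        for seq in SEQUENCES:
            levels = TISSUE_LEVELS[seq]
            base = np.where(anatomy["brain"], levels["wm"], 0.0)
            base = base + np.where(
                anatomy["reference"], levels["dg"] - levels["wm"], 0.0
            )
            base = gaussian_filter(base, COMPARTMENT_BLUR_VOX)
            fld = _smooth_field(rng, config.grid_shape, FIELD_SMOOTH_VOX)
            base = base + FIELD_AMPLITUDE * levels["wm"] * fld * anatomy["brain"]

            if seq in ("rCBV", "rCBF"):
                ref_vals = base[anatomy["reference"]]
                mu, sd = float(ref_vals.mean()), float(ref_vals.std(ddof=1))
                lesion_level = mu + z_target * sd
                truth[f"{seq}_ref_mean"] = mu
                truth[f"{seq}_ref_sd"] = sd
            elif seq == "T1Gad":
                lesion_level = enh_target * levels["wm"]
            else:
                lesion_level = levels["lesion"]

            h = _heterogeneity(
                rng, config.grid_shape, lesion, profile.texture_heterogeneity_sd
            )
            data = np.where(lesion, lesion_level * h, base)
            data = _add_noise(data, rng, config)
            volumes[seq] = Volume(data=data, spacing=config.spacing)

        study = StudyTimePoint(
            subject_id=sid,
            time_point=tp,
            day=TIMEPOINT_DAYS[tp - 1],
            volumes=volumes,
            lesion=Mask(lesion, role="lesion", spacing=config.spacing),
            reference=Mask(
                anatomy["reference"], role="reference", spacing=config.spacing
            ),
        )
        studies.append(GeneratedStudy(study=study, truth=truth))
    return studies


def _draw_n_time_points(config: CohortConfig, rng: np.random.Generator) -> int:
    if isinstance(config.n_time_points, int):
        return config.n_time_points
    p = np.asarray(config.n_time_points, dtype=float)
    p = p / p.sum()
    return int(rng.choice([1, 2, 3], p=p))


def corrupt_labels(
    labels: Sequence[str],
    error_rates: Mapping[str, float],
    rng: np.random.Generator,
) -> list[str]:
    """Simulated rater labels: flip each true label with its class's error
    rate, uniformly to one of the two other classes."""
    out = []
    for lbl in labels:
        if rng.random() < error_rates.get(lbl, 0.0):
            others = [c for c in CLASS_LABELS if c != lbl]
            out.append(others[int(rng.integers(len(others)))])
        else:
            out.append(lbl)
    return out


@dataclass
class CohortBundle:
    """An in-memory generated cohort."""

    config: CohortConfig
    subjects: dict[str, list[GeneratedStudy]]
    labels: pd.Series  # true class per subject
    rater_labels: pd.Series

    @property
    def manifest(self) -> CohortManifest:
        rows = []
        for sid, studies in self.subjects.items():
            for gs in studies:
                rows.append(
                    {
                        "subject_id": sid,
                        "time_point": gs.study.time_point,
                        "day": gs.study.day,
                        "class_label": self.labels[sid],
                        "rater_label": self.rater_labels[sid],
                    }
                )
        return CohortManifest(table=pd.DataFrame(rows))


def generate_cohort(
    config: CohortConfig,
    profiles: Mapping[str, ClassProfile] | None = None,
    out_dir: str | Path | None = None,
) -> CohortBundle:
    """Generate a full cohort; optionally persist it as NIfTI + manifest CSV.

    Per-class counts are exact.  Rater labels are drawn once per subject by
    corrupting the true label with the configured per-class error rates.
    """
    profiles = profiles or default_profiles()
    subjects: dict[str, list[GeneratedStudy]] = {}
    labels = {}
    idx = 0
    for lbl, n in zip(CLASS_LABELS, config.n_per_class):
        for k in range(n):
            sid = f"{lbl}{k + 1:03d}"
            subjects[sid] = generate_subject(
                profiles[lbl], config, subject_seed=[config.seed, idx], subject_id=sid
            )
            labels[sid] = lbl
            idx += 1
    labels_s = pd.Series(labels, name="class_label")
    rater_rng = np.random.default_rng([config.seed, 10**6])
    rater_s = pd.Series(
        corrupt_labels(list(labels_s), config.rater_error_rates, rater_rng),
        index=labels_s.index,
        name="rater_label",
    )
    bundle = CohortBundle(
        config=config, subjects=subjects, labels=labels_s, rater_labels=rater_s
    )
    logger.info(
        "generated cohort: %s subjects (%s), %d studies",
        len(subjects),
        dict(zip(CLASS_LABELS, config.n_per_class)),
        sum(len(v) for v in subjects.values()),
    )
    if out_dir is not None:
        _write_cohort(bundle, Path(out_dir))
    return bundle


def _write_cohort(bundle: CohortBundle, out_dir: Path) -> None:
    rows = []
    for sid, studies in bundle.subjects.items():
        for gs in studies:
            st = gs.study
            tp_dir = out_dir / sid / f"tp{st.time_point}"
            row = {
                "subject_id": sid,
                "time_point": st.time_point,
                "day": st.day,
                "class_label": bundle.labels[sid],
                "rater_label": bundle.rater_labels[sid],
            }
            for seq in SEQUENCES:
                p = tp_dir / f"{seq}.nii.gz"
                write_volume(st.volumes[seq], p)
                row[f"path_{seq}"] = str(p.relative_to(out_dir))
            row["path_lesion"] = str(
                write_mask(st.lesion, tp_dir / "lesion.nii.gz").relative_to(out_dir)
            )
            row["path_reference"] = str(
                write_mask(st.reference, tp_dir / "reference.nii.gz").relative_to(
                    out_dir
                )
            )
            rows.append(row)
    manifest = CohortManifest(table=pd.DataFrame(rows), base_dir=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")


def fixture_config(seed: int = 0, n_per_class=(2, 2, 2)) -> CohortConfig:
    """A miniature 16-cubed cohort configuration for unit tests."""
    return CohortConfig(
        n_per_class=n_per_class,
        n_time_points=2,
        grid_shape=(16, 16, 16),
        spacing=(4.0, 4.0, 4.0),
        seed=seed,
    )
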