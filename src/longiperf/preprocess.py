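"""Intensity normalisation, perfusion z-scoring and subtraction imaging.

Structural sequences (T1, post-contrast T1, T2, FLAIR) are log-transformed
and robustly z-normalised within the brain mask (median / 1.4826*MAD), a
scanner-agnostic standardisation for images with no absolute intensity
scale.  Perfusion maps (rCBV, rCBF) are z-scored against the deep-grey
reference region — the normalisation that turns raw perfusion values into
the ZrBV / ZrBF maps the classifier consumes.  Longitudinal subtraction
studies are voxelwise differences of the normalised maps over the union of
the two lesion masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import Mask, StudyTimePoint, Volume, logger

#: MAD-to-SD consistency factor for a normal distribution.
MAD_SCALE = 1.4826

#: Map from acquisition sequence to normalised-map name.
NORMALIZED_NAMES = {
    "T1": "T1",
    "T1Gad": "T1Gad",
    "T2": "T2",
    "FLAIR": "FLAIR",
    "rCBV": "ZrBV",
    "rCBF": "ZrBF",
}
NORMALIZED_SEQUENCES = ("T1", "T1Gad", "T2", "FLAIR", "ZrBV", "ZrBF")

MIN_REFERENCE_VOXELS = 10


class DegenerateIntensityError(ValueError):
    """Raised when an image has no usable intensity spread."""


@dataclass
class NormalizedStudy:
    """Normalised maps for one subject time point, with provenance."""

    subject_id: str
    time_point: int
    day: int
    volumes: dict[str, Volume]  # keys: T1, T1Gad, T2, FLAIR, ZrBV, ZrBF
    lesion: Mask
    reference: Mask
    provenance: dict


@dataclass
class SubtractionStudy:
    """Voxelwise difference of two normalised studies (later minus earlier)."""

    subject_id: str
    pair: tuple[int, int]  # (later, earlier)
    volumes: dict[str, Volume]
    lesion: Mask  # union of the two time points' lesion masks

    @property
    def name(self) -> str:
        return f"Diff{self.pair[0]}{self.pair[1]}"


def normalize_structural(
    vol: Volume, brain_mask: Mask, log_transform: bool = True
) -> tuple[Volume, dict]:
    """Log-transform and robustly z-normalise within the brain mask.

    Intensities inside the mask must be positive for the log; if the masked
    minimum is <= 0 a shift is applied first and recorded in provenance.
    Outside-mask voxels are set to 0.  With ``log_transform=False`` the op is
    idempotent (a second application is the identity up to 1e-6); with the
    log a second pass re-logs, which is documented behaviour.
    """
    inside = brain_mask.data
    vals = vol.data[inside].astype(np.float64)
    shift = 0.0
    if log_transform:
        mn = vals.min()
        if mn <= 0:
            shift = -mn + 1e-6
            vals = vals + shift
        vals = np.log(vals)
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    scale = MAD_SCALE * mad
    if scale == 0:
        raise DegenerateIntensityError(
            "degenerate intensities: zero MAD inside brain mask"
        )
    out = np.zeros_like(vol.data)
    out[inside] = (vals - med) / scale
    prov = {
        "log_transform": log_transform,
        "shift": shift,
        "median": med,
        "mad_scale": scale,
    }
    return Volume(out, spacing=vol.spacing, origin=vol.origin), prov


def zscore_perfusion(map_vol: Volume, reference: Mask) -> tuple[Volume, dict]:
    """Z-score a perfusion map against the reference region.

    Every voxel becomes (v - mean_ref) / sd_ref, with the statistics taken
    over reference voxels only, so the reference region itself lands at
    mean 0, SD 1 exactly.
    """
    if reference.n_voxels < MIN_REFERENCE_VOXELS:
        raise DegenerateIntensityError(
            f"reference region too small ({reference.n_voxels} voxels, "
            f"need >= {MIN_REFERENCE_VOXELS})"
        )
    ref_vals = map_vol.data[reference.data]
    mu = float(ref_vals.mean())
    sd = float(ref_vals.std(ddof=1))
    if sd == 0:
        raise DegenerateIntensityError("constant reference region (SD = 0)")
    out = (map_vol.data - mu) / sd
    return (
        Volume(out, spacing=map_vol.spacing, origin=map_vol.origin),
        {"reference_mean": mu, "reference_sd": sd, "n_reference": reference.n_voxels},
    )


def brain_mask_from(study: StudyTimePoint, threshold: float = 0.0) -> Mask:
    """Derive a brain mask as voxels above threshold on every sequence.

    The synthetic generator emits zero background outside the head, so a
    positivity threshold recovers the brain; real data would supply a
    skull-stripped mask through the manifest instead.
    """
    m = np.ones(study.volumes["T1"].shape, dtype=bool)
    for seq in ("T1", "T2", "FLAIR"):
        m &= study.volumes[seq].data > threshold
    return Mask(m, role="brain", spacing=study.volumes["T1"].spacing)


def normalize_study(
    study: StudyTimePoint, brain_mask: Mask | None = None
) -> NormalizedStudy:
    """Produce the full normalised bundle for one time point."""
    if brain_mask is None:
        brain_mask = brain_mask_from(study)
    volumes: dict[str, Volume] = {}
    provenance: dict = {}
    for seq, out_name in NORMALIZED_NAMES.items():
        vol = study.volumes[seq]
        if out_name in ("ZrBV", "ZrBF"):
            volumes[out_name], provenance[out_name] = zscore_perfusion(
                vol, study.reference
            )
        else:
            volumes[out_name], provenance[out_name] = normalize_structural(
                vol, brain_mask
            )
    logger.debug(
        "normalised %s tp%d (lesion %d vox, reference %d vox)",
        study.subject_id,
        study.time_point,
        study.lesion.n_voxels,
        study.reference.n_voxels,
    )
    return NormalizedStudy(
        subject_id=study.subject_id,
        time_point=study.time_point,
        day=study.day,
        volumes=volumes,
        lesion=study.lesion,
        reference=study.reference,
        provenance=provenance,
    )


def subtract_timepoints(
    later: NormalizedStudy, earlier: NormalizedStudy
) -> SubtractionStudy:
    """Voxelwise later-minus-earlier difference of normalised maps.

    The feature region for a subtraction study is the union of the two
    lesion masks, so both growth and shrinkage contribute voxels.
    """
    if later.time_point <= earlier.time_point:
        raise ValueError(
            f"subtraction requires later > earlier, got "
            f"({later.time_point}, {earlier.time_point})"
        )
    volumes: dict[str, Volume] = {}
    for name in NORMALIZED_SEQUENCES:
        a, b = later.volumes[name], earlier.volumes[name]
        if not a.same_grid(b):
            raise ValueError(f"grid mismatch on {name} for {later.subject_id}")
        volumes[name] = Volume(a.data - b.data, spacing=a.spacing, origin=a.origin)
    combined = Mask(
        later.lesion.data | earlier.lesion.data,
        role="lesion",
        spacing=later.lesion.spacing,
    )
    return SubtractionStudy(
        subject_id=later.subject_id,
        pair=(later.time_point, earlier.time_point),
        volumes=volumes,
        lesion=combined,
    )


def subtraction_pairs(n_time_points: int) -> list[tuple[int, int]]:
    """The study's subtraction schedule: (2,1), (3,2), (3,1) as available."""
    pairs = []
    if n_time_points >= 2:
        pairs.append((2, 1))
    if n_time_points >= 3:
        pairs.extend([(3, 2), (3, 1)])
    return pairs
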