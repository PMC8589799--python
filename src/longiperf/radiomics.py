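"""Distribution and GLCM/Haralick texture features over lesion regions.

Features are extracted per sequence over the lesion mask, for every time
point (prefix ``TP{k}_``) and every subtraction pair (prefix ``Diff{j}{i}_``,
computed over the voxelwise difference image on the union mask).  Names
follow ``<region>_<sequence>_<feature>``, e.g. ``Diff21_ZrBF_FirstQuartile``.

Texture is grey-level co-occurrence (GLCM): voxel pairs at the 13 unique
3-D offsets, both ends inside the mask, symmetrised and normalised per
direction, then averaged across directions.  Grey levels are equal-width
bins over the masked region's own min-max — appropriate for z-scored and
difference maps, which carry no global intensity scale.

Degenerate regions (constant intensity, zero variance) resolve to fixed
conventions rather than missing values so the feature matrix is always
complete: sd/skewness/kurtosis/entropy 0, GLCM correlation 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import FeatureVector, Mask, Volume, logger
from .preprocess import (
    NORMALIZED_SEQUENCES,
    NormalizedStudy,
    SubtractionStudy,
    normalize_study,
    subtract_timepoints,
    subtraction_pairs,
)

DISTRIBUTION_FEATURES = (
    "Mean",
    "SD",
    "Min",
    "Max",
    "FirstQuartile",
    "Median",
    "ThirdQuartile",
    "Skewness",
    "Kurtosis",
    "Energy",
    "Entropy",
)
HARALICK_FEATURES = (
    "Contrast",
    "Dissimilarity",
    "Homogeneity",
    "ASM",
    "GLCMEntropy",
    "Correlation",
    "SumAverage",
)
ALL_FEATURES = DISTRIBUTION_FEATURES + HARALICK_FEATURES

#: Bin count for the distribution-entropy histogram.
ENTROPY_BINS = 64


def unique_offsets_3d() -> list[tuple[int, int, int]]:
    """The 13 unique (non-antiparallel) unit offsets in 3-D."""
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                o = (dz, dy, dx)
                if o == (0, 0, 0):
                    continue
                if o > (0, 0, 0):  # lexicographic half-space
                    offs.append(o)
    assert len(offs) == 13
    return offs


@dataclass
class GLCMConfig:
    """Co-occurrence construction settings."""

    n_levels: int = 32
    distance: int = 1
    symmetric: bool = True
    directions: Sequence[tuple[int, int, int]] = field(
        default_factory=unique_offsets_3d
    )

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")


def distribution_features(values: np.ndarray) -> dict[str, float]:
    """First-order statistics of a masked voxel sample.

    Quantiles use linear interpolation; kurtosis is Fisher (excess); energy
    is the mean square; entropy uses 64 equal-width bins and natural log.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty voxel sample")
    constant = np.ptp(values) == 0
    sd = 0.0 if constant else float(values.std(ddof=0))
    out = {
        "Mean": float(values.mean()),
        "SD": sd,
        "Min": float(values.min()),
        "Max": float(values.max()),
        "FirstQuartile": float(np.percentile(values, 25)),
        "Median": float(np.percentile(values, 50)),
        "ThirdQuartile": float(np.percentile(values, 75)),
        "Energy": float(np.mean(values**2)),
    }
    if sd == 0:
        out.update({"Skewness": 0.0, "Kurtosis": 0.0, "Entropy": 0.0})
    else:
        out["Skewness"] = float(stats.skew(values, bias=True))
        out["Kurtosis"] = float(stats.kurtosis(values, fisher=True, bias=True))
        counts, _ = np.histogram(values, bins=ENTROPY_BINS)
        p = counts[counts > 0] / values.size
        out["Entropy"] = float(-(p * np.log(p)).sum())
    return out


def quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width quantisation to integer levels 0..n_levels-1 over the
    sample's own min-max; a constant sample maps entirely to level 0."""
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.intp)
    codes = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(codes, 0, n_levels - 1)


def glcm(vol: Volume | np.ndarray, mask: Mask | np.ndarray, cfg: GLCMConfig | None = None) -> np.ndarray:
    """Direction-averaged, symmetrised, normalised co-occurrence matrix.

    Both voxels of a pair must lie inside the mask; each direction's count
    matrix is normalised to sum 1 before averaging, so directions with
    fewer valid pairs are not down-weighted.
    """
    cfg = cfg or GLCMConfig()
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol, dtype=np.float64)
    m = mask.data if isinstance(mask, Mask) else np.asarray(mask) > 0
    if not m.any():
        raise ValueError("empty mask")
    codes = np.zeros(data.shape, dtype=np.intp)
    codes[m] = quantize(data[m], cfg.n_levels)
    n = cfg.n_levels
    acc = np.zeros((n, n), dtype=np.float64)
    n_dirs = 0
    for off in cfg.directions:
        off = tuple(cfg.distance * o for o in off)
        src = tuple(
            slice(max(0, -o), data.shape[ax] - max(0, o)) for ax, o in enumerate(off)
        )
        dst = tuple(
            slice(max(0, o), data.shape[ax] + min(0, o)) for ax, o in enumerate(off)
        )
        valid = m[src] & m[dst]
        if not valid.any():
            continue
        a = codes[src][valid]
        b = codes[dst][valid]
        counts = np.bincount(a * n + b, minlength=n * n).reshape(n, n).astype(float)
        if cfg.symmetric:
            counts = counts + counts.T
        acc += counts / counts.sum()
        n_dirs += 1
    if n_dirs == 0:
        raise ValueError("mask yields no valid voxel pairs for any direction")
    return acc / n_dirs


def haralick_features(P: np.ndarray) -> dict[str, float]:
    """Haralick statistics of a normalised co-occurrence matrix.

    Sum average uses 1-based level indices (k = i + j ranges 2..2n).  When a
    marginal SD is zero (single occupied level), correlation is 1 by
    convention.
    """
    P = np.asarray(P, dtype=np.float64)
    total = P.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"co-occurrence matrix not normalised (sum {total})")
    n = P.shape[0]
    i = np.arange(1, n + 1)[:, None]
    j = np.arange(1, n + 1)[None, :]
    diff = i - j
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((np.arange(1, n + 1) * pi).sum())
    mu_j = float((np.arange(1, n + 1) * pj).sum())
    var_i = float(((np.arange(1, n + 1) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(1, n + 1) - mu_j) ** 2 * pj).sum())
    nz = P > 0
    sig = np.sqrt(var_i * var_j)
    if sig == 0:
        corr = 1.0
    else:
        corr = float((((i - mu_i) * (j - mu_j)) * P).sum() / sig)
    return {
        "Contrast": float((diff**2 * P).sum()),
        "Dissimilarity": float((np.abs(diff) * P).sum()),
        "Homogeneity": float((P / (1 + diff**2)).sum()),
        "ASM": float((P**2).sum()),
        "GLCMEntropy": float(-(P[nz] * np.log(P[nz])).sum()),
        "Correlation": corr,
        "SumAverage": float(((i + j) * P).sum()),
    }


def region_features(
    data: np.ndarray, mask: np.ndarray, cfg: GLCMConfig | None = None
) -> dict[str, float]:
    """All distribution + texture features for one map over one region."""
    cfg = cfg or GLCMConfig()
    out = distribution_features(data[mask])
    out.update(haralick_features(glcm(data, mask, cfg)))
    return out


def extract_features(
    normalized: Sequence[NormalizedStudy],
    subtractions: Sequence[SubtractionStudy],
    cfg: GLCMConfig | None = None,
) -> FeatureVector:
    """Feature vector for one subject: every time point and subtraction pair.

    The feature count is arithmetic from the configuration —
    n_regions x n_sequences x n_features_per_region — and is logged rather
    than hard-coded.
    """
    if not normalized:
        raise ValueError("need at least one time point")
    cfg = cfg or GLCMConfig()
    feats: dict[str, float] = {}
    for ns in normalized:
        mask = ns.lesion.data
        for seq in NORMALIZED_SEQUENCES:
            vals = region_features(ns.volumes[seq].data, mask, cfg)
            for fname, v in vals.items():
                feats[f"TP{ns.time_point}_{seq}_{fname}"] = v
    for sub in subtractions:
        mask = sub.lesion.data
        for seq in NORMALIZED_SEQUENCES:
            vals = region_features(sub.volumes[seq].data, mask, cfg)
            for fname, v in vals.items():
                feats[f"{sub.name}_{seq}_{fname}"] = v
    n_regions = len(normalized) + len(subtractions)
    logger.debug(
        "extracted %d features (%d regions x %d sequences x %d per region) for %s",
        len(feats),
        n_regions,
        len(NORMALIZED_SEQUENCES),
        len(ALL_FEATURES),
        normalized[0].subject_id,
    )
    return FeatureVector(subject_id=normalized[0].subject_id, features=feats)


def expected_feature_count(n_time_points: int, with_subtractions: bool = True) -> int:
    """Configuration-derived feature count for one subject."""
    n_regions = n_time_points
    if with_subtractions:
        n_regions += len(subtraction_pairs(n_time_points))
    return n_regions * len(NORMALIZED_SEQUENCES) * len(ALL_FEATURES)


def extract_subject_features(
    studies: Sequence, cfg: GLCMConfig | None = None
) -> FeatureVector:
    """Normalise, subtract and extract for one subject's raw time points.

    Accepts a list of :class:`StudyTimePoint` or generated-study wrappers
    (anything with a ``.study`` attribute).
    """
    raw = [getattr(s, "study", s) for s in studies]
    raw = sorted(raw, key=lambda s: s.time_point)
    normalized = [normalize_study(s) for s in raw]
    by_tp = {ns.time_point: ns for ns in normalized}
    subs = [
        subtract_timepoints(by_tp[j], by_tp[i])
        for j, i in subtraction_pairs(len(normalized))
        if j in by_tp and i in by_tp
    ]
    return extract_features(normalized, subs, cfg)


def extract_cohort_features(
    cohort, cfg: GLCMConfig | None = None
) -> pd.DataFrame:
    """Feature table for an in-memory cohort bundle.

    Returns a DataFrame indexed by subject, with ``class_label`` and
    ``rater_label`` columns followed by the feature columns.
    """
    rows = {}
    for sid, studies in cohort.subjects.items():
        fv = extract_subject_features(studies, cfg)
        rows[sid] = fv.features
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.insert(0, "class_label", cohort.labels)
    df.insert(1, "rater_label", cohort.rater_labels)
    df.index.name = "subject_id"
    logger.info(
        "cohort feature table: %d subjects x %d features", len(df), df.shape[1] - 2
    )
    return df


def feature_registry(n_time_points: int = 2) -> list[dict]:
    """Flat registry of the feature inventory (name, region, sequence, kind)."""
    regions = [f"TP{k}" for k in range(1, n_time_points + 1)] + [
        f"Diff{j}{i}" for j, i in subtraction_pairs(n_time_points)
    ]
    reg = []
    for region in regions:
        for seq in NORMALIZED_SEQUENCES:
            for fname in ALL_FEATURES:
                reg.append(
                    {
                        "name": f"{region}_{seq}_{fname}",
                        "region": region,
                        "sequence": seq,
                        "feature": fname,
                        "kind": "distribution"
                        if fname in DISTRIBUTION_FEATURES
                        else "texture",
                    }
                )
    return reg
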