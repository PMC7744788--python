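"""Study outcome estimators: MRI volumetrics, the extruded-cylinder
reference ratio, and the electrophysiology statistics.

The volumetric estimators work on labeled segmentation volumes
(0 = background, 1 = myocardium, 2 = non-myocardial tissue): the
non-myocardial percentage of each specimen, the ablated percentage obtained
by subtracting an age-matched non-ablated control, and a per-specimen
reference ratio against the cylinder swept by the loop catheter through the
thickest part of the wall.  The statistical helpers cover the study's test
battery: one-sample t from summary statistics, paired t (with a Welch
unpaired variant) on pre/post electrogram cohorts, and Kruskal-Wallis with
Dunn's post hoc z-tests (Bonferroni-adjusted).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "SEG_BACKGROUND",
    "SEG_MYOCARDIUM",
    "SEG_NON_MYOCARDIAL",
    "SegmentationVolume",
    "VolumetricsResult",
    "EgmSample",
    "volume_fractions",
    "ablated_fraction",
    "extrusion_reference_ratio",
    "one_sample_t_summary",
    "paired_change_stats",
    "kruskal_dunn",
    "round_half_away",
]

SEG_BACKGROUND = 0
SEG_MYOCARDIUM = 1
SEG_NON_MYOCARDIAL = 2


@dataclass
class SegmentationVolume:
    """Labeled MRI-like volume; slices are taken along axis 0.

    ``voxel_size_mm`` is (slice thickness, in-plane, in-plane); the default
    1 mm slice thickness matches the imaging protocol the volumetrics were
    designed around.
    """

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 0.5, 0.5)

    def __post_init__(self) -> None:
        allowed = {SEG_BACKGROUND, SEG_MYOCARDIUM, SEG_NON_MYOCARDIAL}
        present = set(np.unique(self.labels).tolist())
        if not present <= allowed:
            raise ValueError(f"labels outside {{0,1,2}}: {sorted(present - allowed)}")
        if not (self.labels == SEG_MYOCARDIUM).any():
            raise ValueError("segmentation contains no myocardium voxels")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class VolumetricsResult:
    """Volumetric fractions of one specimen.

    ``v_pct`` is the myocardial fraction of the specimen (background
    excluded); ``nonmyo_pct`` its complement, the quantity the study's
    group means are reported in; ``per_slice`` holds the same two numbers
    per axial slice.
    """

    v_pct: float
    nonmyo_pct: float
    total_volume_mm3: float
    nonmyo_volume_mm3: float
    per_slice: pd.DataFrame = field(repr=False)


def volume_fractions(seg: SegmentationVolume) -> VolumetricsResult:
    """Myocardial / non-myocardial volume percentages of a specimen.

    The specimen volume is myocardium plus non-myocardial voxels
    (background excluded); the myocardial percentage is
    ``(Vtot - Vnot_myo) / Vtot * 100`` and the non-myocardial percentage its
    exact complement.  Per-slice percentages are computed identically per
    axial (axis 0) slice; empty slices are skipped.
    """
    lab = seg.labels
    myo = lab == SEG_MYOCARDIUM
    non = lab == SEG_NON_MYOCARDIAL
    n_tot = int(myo.sum() + non.sum())
    if n_tot == 0:
        raise ValueError("specimen volume is zero")
    v_pct = (n_tot - int(non.sum())) / n_tot * 100.0
    rows = []
    for k in range(lab.shape[0]):
        m = int(myo[k].sum())
        nn = int(non[k].sum())
        if m + nn == 0:
            continue
        rows.append(
            {
                "slice": k,
                "v_pct": (m + nn - nn) / (m + nn) * 100.0,
                "nonmyo_pct": nn / (m + nn) * 100.0,
            }
        )
    vol = seg.voxel_volume_mm3
    return VolumetricsResult(
        v_pct=v_pct,
        nonmyo_pct=100.0 - v_pct,
        total_volume_mm3=n_tot * vol,
        nonmyo_volume_mm3=int(non.sum()) * vol,
        per_slice=pd.DataFrame(rows),
    )


def ablated_fraction(nonmyo_pct: float, control_nonmyo_pct: float) -> float:
    """Ablated tissue percentage: treated minus control non-myocardial
    percentage.  A negative value (control above treated) is returned
    as-is with a warning."""
    for name, v in (("nonmyo_pct", nonmyo_pct), ("control_nonmyo_pct", control_nonmyo_pct)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} must lie in [0, 100], got {v}")
    out = nonmyo_pct - control_nonmyo_pct
    if out < 0:
        warnings.warn(
            "ablated fraction is negative (control exceeds treated specimen)",
            stacklevel=2,
        )
    return out


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero — the convention used for printed values."""
    f = 10.0**decimals
    return math.copysign(math.floor(abs(x) * f + 0.5) / f, x)


def wall_thickness_per_slice(seg: SegmentationVolume) -> np.ndarray:
    """Wall thickness (mm) of each axial slice: twice the deepest in-plane
    distance from specimen to background (exact for slab/shell walls whose
    thickness runs in-plane)."""
    lab = seg.labels
    specimen = lab != SEG_BACKGROUND
    dy, dz = seg.voxel_size_mm[1], seg.voxel_size_mm[2]
    out = np.zeros(lab.shape[0])
    for k in range(lab.shape[0]):
        sl = specimen[k]
        if not sl.any():
            continue
        d = ndimage.distance_transform_edt(sl, sampling=(dy, dz))
        out[k] = 2.0 * float(d.max())
    return out


def extrusion_reference_ratio(
    seg: SegmentationVolume,
    ablated_volume_mm3: float,
    loop_diameter_mm: float,
) -> float:
    """Ablated volume over the loop-catheter extrusion reference.

    The reference is the cylinder obtained by extruding the loop catheter
    (cross-section pi (d/2)^2) through the thickest section of the wall.
    """
    if loop_diameter_mm <= 0:
        raise ValueError("loop_diameter_mm must be > 0")
    thick = wall_thickness_per_slice(seg)
    t_max = float(thick.max())
    if t_max <= 0:
        raise ValueError("specimen has zero wall thickness")
    reference = math.pi * (loop_diameter_mm / 2.0) ** 2 * t_max
    return ablated_volume_mm3 / reference


# ---------------------------------------------------------------------------
# statistics


def one_sample_t_summary(
    mean: float, sd: float, n: int, mu0: float
) -> tuple[float, float]:
    """One-sample two-sided t-test from summary statistics.

    ``t = (mean - mu0) / (sd / sqrt(n))`` with ``n - 1`` degrees of freedom.
    A zero SD with a nonzero effect is reported as (inf-signed t, p = 0)
    with a warning.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        if mean == mu0:
            return 0.0, 1.0
        warnings.warn("zero SD with nonzero effect: p = 0 by convention", stacklevel=2)
        return math.copysign(math.inf, mean - mu0), 0.0
    t = (mean - mu0) / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass(frozen=True)
class EgmSample:
    """Pre/post electrogram record for one application site."""

    pre_amplitude_mv: float
    post_amplitude_mv: float
    pre_duration_ms: float
    post_duration_ms: float
    pre_impedance_ohm: float = math.nan
    post_impedance_ohm: float = math.nan

    def __post_init__(self) -> None:
        if self.pre_amplitude_mv <= 0 or self.post_amplitude_mv <= 0:
            raise ValueError("amplitudes must be > 0")
        if self.pre_duration_ms <= 0 or self.post_duration_ms <= 0:
            raise ValueError("durations must be > 0")


def paired_change_stats(
    samples: list[EgmSample],
    metric: str = "amplitude",
    welch: bool = False,
) -> dict[str, float | str | int]:
    """Pre-to-post change statistics for one electrogram metric.

    Returns the per-pair mean delta (post - pre), its SD, and the two-sided
    p-value from the paired Student's t-test — or, with ``welch=True``, from
    Welch's unequal-variance unpaired t-test on the pre and post groups.
    """
    if metric not in ("amplitude", "duration", "impedance"):
        raise ValueError(f"unknown metric '{metric}'")
    if len(samples) < 2:
        raise ValueError("need at least 2 paired records")
    suffix = {"amplitude": "amplitude_mv", "duration": "duration_ms", "impedance": "impedance_ohm"}[metric]
    pre = np.array([getattr(s, f"pre_{suffix}") for s in samples], dtype=float)
    post = np.array([getattr(s, f"post_{suffix}") for s in samples], dtype=float)
    if np.isnan(pre).any() or np.isnan(post).any():
        raise ValueError(f"metric '{metric}' has missing values")
    delta = post - pre
    if welch:
        t, p = stats.ttest_ind(post, pre, equal_var=False)
        test = "welch_t"
    else:
        if np.allclose(delta, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(post, pre)
        test = "paired_t"
    return {
        "metric": metric,
        "n": len(samples),
        "mean_delta": float(delta.mean()),
        "sd_delta": float(delta.std(ddof=1)),
        "t": float(t),
        "p_value": float(p),
        "test": test,
    }


def kruskal_dunn(groups: list[np.ndarray]) -> dict:
    """Kruskal-Wallis omnibus test plus Dunn's post hoc pairwise z-tests.

    The omnibus H statistic carries the usual tie correction; pairwise Dunn
    z-tests use the pooled-rank variance with tie correction and Bonferroni
    adjustment over all pairs.  Identical data in every group gives an
    omnibus p of 1 and no meaningful pairs.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return {"h": 0.0, "p_omnibus": 1.0, "pairs": pd.DataFrame()}
    h, p_omni = stats.kruskal(*groups)

    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    n_total = pooled.size
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    # tie correction for the pooled ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "group_i": i,
                    "group_j": j,
                    "z": z,
                    "p_unadjusted": p,
                    "p_adjusted": min(1.0, p * m),
                }
            )
    return {"h": float(h), "p_omnibus": float(p_omni), "pairs": pd.DataFrame(rows)}
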