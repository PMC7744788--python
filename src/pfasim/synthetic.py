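"""Seed-deterministic synthetic inputs for every pipeline stage.

These generators emulate the shapes of the study's data without any
download: a lead-III-like ECG spike train at a stated heart rate (gating
only needs R peaks, so no P/T morphology by default), labeled atrial-wall
segmentation volumes with known lesion and native non-myocardial fractions,
paired pre/post electrogram cohorts drawn at the study's effect sizes, and
noisy exponential temperature decays.  Every generator takes a seed and
reproduces byte-identical output for identical arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .study_metrics import (
    SEG_MYOCARDIUM,
    SEG_NON_MYOCARDIAL,
    EgmSample,
    SegmentationVolume,
)

__all__ = [
    "TABLE1_ATRIAL",
    "TABLE1_SEPTAL",
    "gen_ecg",
    "gen_segmentation",
    "gen_egm_cohort",
    "gen_decay_series",
]

#: Atrial electrogram effect sizes (mean, sd): amplitude in mV pre/post,
#: duration in ms pre/post, plus the observed impedance drop in Ohm @100 Hz.
TABLE1_ATRIAL = {
    "pre_amplitude": (2.20, 0.84),
    "post_amplitude": (0.61, 0.18),
    "pre_duration": (45.29, 8.1),
    "post_duration": (58.38, 12.61),
    "impedance_delta": (-31.75, 13.92),
}

#: Septal (interventricular) electrogram effect sizes.
TABLE1_SEPTAL = {
    "pre_amplitude": (1.95, 0.63),
    "post_amplitude": (1.02, 0.41),
    "pre_duration": (38.20, 5.894),
    "post_duration": (75.62, 12.70),
    "impedance_delta": (-31.75, 13.92),
}


def gen_ecg(
    bpm: float = 69.0,
    duration_s: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 1000.0,
    qrs_amplitude_mv: float = 1.0,
    qrs_width_s: float = 0.012,
    t_wave: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic lead-III-like trace: Gaussian QRS spikes plus noise.

    Beats are spaced ``60/bpm`` with the first R peak half a period in;
    ``t_wave=True`` adds a broad low bump 300 ms after each R (for
    gating-failure experiments).  Returns ``(t, trace_mv, true_peaks_s)``.
    """
    if bpm <= 0:
        raise ValueError("bpm must be > 0")
    rng = np.random.default_rng(seed)
    period = 60.0 / bpm
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    peaks = np.arange(period / 2.0, duration_s, period)
    v = np.zeros(n)
    for pk in peaks:
        v += qrs_amplitude_mv * np.exp(-((t - pk) ** 2) / (2.0 * qrs_width_s**2))
        if t_wave:
            v += 0.25 * qrs_amplitude_mv * np.exp(
                -((t - pk - 0.300) ** 2) / (2.0 * 0.05**2)
            )
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return t, v, peaks


def gen_segmentation(
    dims: tuple[int, int, int] = (40, 64, 64),
    wall_mm: float = 5.85,
    lesion_fraction: float = 0.11,
    background_nonmyo_fraction: float = 0.09225,
    seed: int = 0,
    voxel_size_mm: tuple[float, float, float] = (1.0, 0.5, 0.5),
    n_lesions: int = 3,
) -> tuple[SegmentationVolume, dict]:
    """Labeled atrial-wall-like specimen with known non-myocardial content.

    The specimen is a wall slab of thickness ``wall_mm`` whose thickness runs
    in-plane of the axis-0 slices (as in axial scans cutting across the
    wall).  Contiguous lesion-like patches grown by seeded region accretion
    make up ``lesion_fraction`` of the specimen, and a dispersed salt
    scatter — the native endo/epicardial connective lining — a further
    ``background_nonmyo_fraction`` (default the healthy-control level,
    9.225%).  Returns the volume plus ground-truth metadata.
    """
    f, g = lesion_fraction, background_nonmyo_fraction
    if f < 0 or g < 0 or f + g >= 1.0:
        raise ValueError("need 0 <= lesion + background fraction < 1")
    rng = np.random.default_rng(seed)
    labels = np.zeros(dims, dtype=np.int8)
    ny = dims[1]
    wall_vox = max(int(round(wall_mm / voxel_size_mm[1])), 1)
    j0 = (ny - wall_vox) // 2
    if wall_vox > ny:
        raise ValueError("wall thicker than the volume")
    labels[:, j0 : j0 + wall_vox, :] = SEG_MYOCARDIUM
    specimen = np.argwhere(labels == SEG_MYOCARDIUM)
    n_spec = specimen.shape[0]

    n_lesion_vox = int(round(f * n_spec))
    placed = 0
    lesion_mask = np.zeros(dims, dtype=bool)
    in_specimen = labels == SEG_MYOCARDIUM
    targets = _split_counts(n_lesion_vox, n_lesions, rng)
    for target in targets:
        if target == 0:
            continue
        placed += _grow_patch(lesion_mask, in_specimen, target, rng)
    labels[lesion_mask] = SEG_NON_MYOCARDIAL

    n_native = int(round(g * n_spec))
    remaining = np.argwhere(labels == SEG_MYOCARDIUM)
    if n_native > remaining.shape[0]:
        raise ValueError("fractions infeasible on this grid")
    if n_native > 0:
        pick = rng.choice(remaining.shape[0], size=n_native, replace=False)
        sel = remaining[pick]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = SEG_NON_MYOCARDIAL

    seg = SegmentationVolume(labels=labels, voxel_size_mm=voxel_size_mm)
    truth = {
        "lesion_fraction": placed / n_spec,
        "background_nonmyo_fraction": n_native / n_spec,
        "nonmyo_fraction": (placed + n_native) / n_spec,
        "wall_mm": wall_vox * voxel_size_mm[1],
        "n_specimen_voxels": n_spec,
    }
    return seg, truth


def _split_counts(total: int, parts: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` into ``parts`` roughly equal random counts."""
    if total == 0 or parts <= 1:
        return [total]
    w = rng.dirichlet(np.full(parts, 5.0))
    counts = np.floor(w * total).astype(int)
    counts[0] += total - counts.sum()
    return counts.tolist()


def _grow_patch(
    mask: np.ndarray,
    allowed: np.ndarray,
    target: int,
    rng: np.random.Generator,
) -> int:
    """Grow one contiguous patch of ``target`` voxels by random accretion."""
    free = np.argwhere(allowed & ~mask)
    if free.shape[0] == 0:
        return 0
    start = tuple(free[rng.integers(free.shape[0])])
    frontier = [start]
    seen = {start}
    placed = 0
    dims = mask.shape
    while frontier and placed < target:
        i = rng.integers(len(frontier))
        vox = frontier.pop(i)
        if mask[vox]:
            continue
        mask[vox] = True
        placed += 1
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nb = (vox[0] + d[0], vox[1] + d[1], vox[2] + d[2])
            if (
                0 <= nb[0] < dims[0]
                and 0 <= nb[1] < dims[1]
                and 0 <= nb[2] < dims[2]
                and allowed[nb]
                and not mask[nb]
                and nb not in seen
            ):
                frontier.append(nb)
                seen.add(nb)
    return placed


def gen_egm_cohort(
    n: int = 30,
    params: dict | None = None,
    seed: int = 0,
    impedance_pre: tuple[float, float] = (120.0, 20.0),
) -> list[EgmSample]:
    """Paired pre/post electrogram cohort at the study's effect sizes.

    Pre and post values are drawn from the stated normal (mean, sd) pairs
    (defaults: atrial amplitudes/durations), truncated just above zero.
    The impedance pre level is a synthetic convention (the study reports
    only the drop); post = pre + a draw from the stated delta.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    p = dict(TABLE1_ATRIAL if params is None else params)
    rng = np.random.default_rng(seed)

    def draw(mean: float, sd: float, size: int) -> np.ndarray:
        out = rng.normal(mean, sd, size)
        for _ in range(100):
            bad = out <= 1e-6
            if not bad.any():
                break
            out[bad] = rng.normal(mean, sd, int(bad.sum()))
        return np.clip(out, 1e-6, None)

    pre_a = draw(*p["pre_amplitude"], n)
    post_a = draw(*p["post_amplitude"], n)
    pre_d = draw(*p["pre_duration"], n)
    post_d = draw(*p["post_duration"], n)
    pre_z = draw(*impedance_pre, n)
    dz = rng.normal(*p["impedance_delta"], n)
    return [
        EgmSample(
            pre_amplitude_mv=float(pre_a[i]),
            post_amplitude_mv=float(post_a[i]),
            pre_duration_ms=float(pre_d[i]),
            post_duration_ms=float(post_d[i]),
            pre_impedance_ohm=float(pre_z[i]),
            post_impedance_ohm=float(pre_z[i] + dz[i]),
        )
        for i in range(n)
    ]


def gen_decay_series(
    amplitude_c: float = 7.6,
    tau_ms: float = 9.22,
    baseline_c: float = 37.0,
    noise_frac: float = 0.01,
    dt_ms: float = 0.1,
    duration_ms: float = 60.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy exponential temperature decay
    ``T(t) = baseline + A e^(-t/tau) (1 + eps)``, ``eps ~ N(0, noise_frac)``.

    Defaults are the tissue-probe decay parameters of a single burst
    (A = 7.6 C, tau = 9.22 ms).  Returns ``(t_s, temps_c)``.
    """
    if tau_ms <= 0 or dt_ms <= 0:
        raise ValueError("tau_ms and dt_ms must be > 0")
    rng = np.random.default_rng(seed)
    t_ms = np.arange(0.0, duration_ms, dt_ms)
    excess = amplitude_c * np.exp(-t_ms / tau_ms)
    if noise_frac > 0:
        excess = excess * (1.0 + rng.normal(0.0, noise_frac, t_ms.size))
    return t_ms * 1e-3, baseline_c + excess
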