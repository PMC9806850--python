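"""Synthetic two-group resting-state EEG cohorts with known microstate
structure.

Each subject is a semi-Markov chain over a small set of template
topographies: class dwell times are gamma-distributed (mean ≈ 80–120 ms,
shape 4 — far from the geometric-dwell regime of a first-order chain at
125 Hz), the active template is amplitude-modulated by a rectified ~10 Hz
carrier (so GFP maxima occur at a realistic ~20/s), each dwell period
carries a random polarity sign, and spatially correlated Gaussian sensor
noise is mixed in at a configurable signal-to-noise power ratio.

Two groups differ in their template inventory (by default patients carry a
class "E", controls a class "F") and in per-class dwell-time modifiers.
Cognitive/clinical covariates are coupled to *generative* per-subject
microstate parameters so that estimator bias downstream is measurable
against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import sph_harm_y

from .io import (
    EEGRecording,
    TemplateSet,
    build_spherical_montage,
    default_channel_names,
)
from .backfitting import run_lengths

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "CohortResult",
    "make_templates",
    "simulate_state_sequence",
    "synthesize_recording",
    "simulate_cohort",
    "default_two_group_config",
]

CLASS_NAMES = ["A", "B", "C", "D", "E", "F"]


@dataclass
class SyntheticConfig:
    """Generative conditions for one cohort.

    ``sfreq`` is the rate at which recordings are generated (the analysis
    rate); ``sfreq_raw`` documents the emulated acquisition rate and is used
    only when ``generate_at_raw`` is set, to exercise the resampling stage.
    ``group_effects`` maps group → {class letter → dwell-mean multiplier}.
    ``snr`` is the sensor-level template-power / noise-power ratio.
    """

    n_channels: int = 64
    sfreq: float = 125.0
    sfreq_raw: float = 1000.0
    generate_at_raw: bool = False
    duration_s: float = 120.0
    mean_dwell_ms: dict[str, float] = field(
        default_factory=lambda: {
            "A": 100.0, "B": 95.0, "C": 110.0, "D": 90.0, "E": 85.0, "F": 105.0,
        }
    )
    dwell_shape: float = 4.0
    transition_matrix: np.ndarray | None = None  # zero diagonal, rows sum to 1
    gfp_carrier_hz: float = 10.0
    gfp_floor: float = 0.35
    amplitude_uv: float = 30.0
    snr: float = 2.0
    noise_spatial_scale: float = 0.6  # correlation length on the sphere, rad
    polarity_flips: bool = True
    patient_classes: list[str] = field(
        default_factory=lambda: ["A", "B", "C", "D", "E"]
    )
    control_classes: list[str] = field(
        default_factory=lambda: ["A", "B", "C", "D", "F"]
    )
    group_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "patient": {"A": 1.3, "B": 1.2},
            "control": {"D": 1.3},
        }
    )
    subject_dwell_jitter_sd: float = 0.15  # lognormal sigma on class dwell means
    sdmt_beta0: float = 37.0  # with occupancy_A ≈ 0.2 the cohort mean ≈ 57
    sdmt_beta1: float = 100.0  # SDMT points per unit class-A occupancy
    sdmt_target_r2: float = 0.3
    dd_gamma0: float = 6.0
    dd_gamma1: float = 0.05  # years per ms of class-A mean dwell
    dd_target_r2: float = 0.1
    template_smoothness_order: int = 3
    max_template_corr: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if any(v <= 0 for v in self.mean_dwell_ms.values()):
            raise ValueError("dwell means must be positive")
        if self.transition_matrix is not None:
            P = np.asarray(self.transition_matrix)
            if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition rows must sum to 1")
            if not np.allclose(np.diag(P), 0.0):
                raise ValueError("transition matrix must have zero diagonal")

    @property
    def generation_sfreq(self) -> float:
        return self.sfreq_raw if self.generate_at_raw else self.sfreq


@dataclass
class SyntheticGroundTruth:
    """Everything downstream recovery is measured against."""

    templates: TemplateSet  # all classes, letters A.., shared across subjects
    state_sequences: dict[str, np.ndarray]  # subject -> per-sample class index
    realized: pd.DataFrame  # subject × class occupancy/dwell/occurrence
    covariate_coefficients: dict[str, float]
    seed: int


@dataclass
class CohortResult:
    recordings: list[EEGRecording]
    covariates: pd.DataFrame
    ground_truth: SyntheticGroundTruth
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


def _harmonic_basis(montage: np.ndarray, max_order: int) -> np.ndarray:
    """Real spherical-harmonic basis (degrees 1..max_order) at sensor sites."""
    x, y, z = montage[:, 0], montage[:, 1], montage[:, 2]
    theta = np.arccos(np.clip(z, -1, 1))  # polar angle
    phi = np.arctan2(y, x)
    cols = []
    for l in range(1, max_order + 1):
        for m in range(0, l + 1):
            Y = sph_harm_y(l, m, theta, phi)
            cols.append(np.real(Y))
            if m > 0:
                cols.append(np.imag(Y))
    return np.column_stack(cols)


def make_templates(
    montage: np.ndarray,
    K: int,
    smoothness_order: int = 3,
    seed: int | None = None,
    max_corr: float = 0.7,
    max_retries: int = 500,
    class_labels: list[str] | None = None,
    channel_names: list[str] | None = None,
) -> TemplateSet:
    """K zero-mean unit-norm maps from random low-order harmonic mixtures,
    mutually decorrelated to ``|r| ≤ max_corr``."""
    if K > 8:
        raise ValueError("at most 8 templates supported")
    rng = np.random.default_rng(seed)
    B = _harmonic_basis(montage, smoothness_order)

    def draw() -> np.ndarray:
        v = B @ rng.standard_normal(B.shape[1])
        v = v - v.mean()
        n = np.linalg.norm(v)
        if n == 0:
            return draw()
        return v / n

    maps = [draw() for _ in range(K)]
    for _ in range(max_retries):
        M = np.vstack(maps)
        corr = M @ M.T
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        if abs(corr[i, j]) <= max_corr:
            break
        maps[j] = draw()
    else:
        raise ValueError(
            f"could not decorrelate {K} maps below |r|={max_corr} "
            f"after {max_retries} retries; try another seed"
        )
    if channel_names is None:
        channel_names = default_channel_names(montage.shape[0])
    if class_labels is None:
        class_labels = CLASS_NAMES[:K] if K <= 6 else [f"M{i+1}" for i in range(K)]
    return TemplateSet(
        maps=np.vstack(maps),
        class_labels=list(class_labels),
        channel_names=list(channel_names),
        level="population",
    )


# ---------------------------------------------------------------------------
# State sequence
# ---------------------------------------------------------------------------


def simulate_state_sequence(
    n_samples: int,
    sfreq: float,
    mean_dwell_ms: np.ndarray,
    dwell_shape: float,
    transition_matrix: np.ndarray | None,
    seed: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Semi-Markov class sequence with gamma dwell times.

    Returns the per-sample class-index sequence and a table of realized
    per-class statistics (occupancy fraction, mean dwell ms, occurrence/min).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be ≥ 1")
    mean_dwell_ms = np.asarray(mean_dwell_ms, dtype=float)
    K = mean_dwell_ms.size
    rng = np.random.default_rng(seed)
    if transition_matrix is None and K > 1:
        P = np.full((K, K), 1.0 / (K - 1))
        np.fill_diagonal(P, 0.0)
    else:
        P = np.atleast_2d(transition_matrix) if K > 1 else None

    out = np.empty(n_samples, dtype=int)
    pos = 0
    state = int(rng.integers(K))
    while pos < n_samples:
        if dwell_shape > 0:
            dwell_ms = rng.gamma(dwell_shape, mean_dwell_ms[state] / dwell_shape)
        else:  # degenerate: deterministic dwell
            dwell_ms = mean_dwell_ms[state]
        n = max(1, int(round(dwell_ms / 1000.0 * sfreq)))
        out[pos : pos + n] = state
        pos += n
        if K > 1:
            state = int(rng.choice(K, p=P[state]))
    stats = realized_statistics(out, sfreq, K)
    return out, stats


def realized_statistics(states: np.ndarray, sfreq: float, K: int) -> pd.DataFrame:
    """Occupancy, mean dwell and occurrence per class from a label sequence."""
    n = states.size
    duration_min = n / sfreq / 60.0
    _, lengths, vals = run_lengths(states)
    rows = []
    for k in range(K):
        runs_k = lengths[vals == k]
        occ_frac = float((states == k).sum()) / n
        rows.append(
            {
                "class_index": k,
                "occupancy": occ_frac,
                "mean_dwell_ms": float(runs_k.mean()) * 1000.0 / sfreq
                if runs_k.size
                else 0.0,
                "occurrence_per_min": runs_k.size / duration_min,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recording synthesis
# ---------------------------------------------------------------------------


def _gfp_envelope(
    n_samples: int, sfreq: float, carrier_hz: float, floor: float, rng
) -> np.ndarray:
    """Rectified-sinusoid amplitude envelope with a floor, smoothed ~10 ms."""
    t = np.arange(n_samples) / sfreq
    phase = rng.uniform(0, 2 * np.pi)
    a = np.abs(np.sin(2 * np.pi * carrier_hz * t + phase))
    a = gaussian_filter1d(a, sigma=max(1.0, 0.010 * sfreq))
    a /= a.max()
    return floor + (1.0 - floor) * a


def _spatial_noise_chol(montage: np.ndarray, scale: float) -> np.ndarray:
    ang = np.arccos(np.clip(montage @ montage.T, -1, 1))
    cov = np.exp(-(ang**2) / (2.0 * scale**2))
    cov += 1e-6 * np.eye(montage.shape[0])
    return np.linalg.cholesky(cov)


def synthesize_recording(
    templates: TemplateSet,
    states: np.ndarray,
    config: SyntheticConfig,
    montage: np.ndarray,
    seed: int | None = None,
    subject_id: str = "",
    group: str | None = None,
    return_parts: bool = False,
):
    """Mix template dynamics with spatially correlated noise at the target SNR.

    data(t) = a(t) · s_d · T_{L(t)} + noise(t), average-referenced, in µV.
    ``s_d`` is a per-dwell random polarity sign when ``polarity_flips`` is on.
    """
    if templates.maps.shape[1] != montage.shape[0]:
        raise ValueError("template channel count does not match montage")
    config.validate()
    rng = np.random.default_rng(seed)
    sfreq = config.generation_sfreq
    n = states.size

    a = _gfp_envelope(n, sfreq, config.gfp_carrier_hz, config.gfp_floor, rng)
    signs = np.ones(n)
    if config.polarity_flips:
        starts, lengths, _ = run_lengths(states)
        for s, L in zip(starts, lengths):
            signs[s : s + L] = rng.choice([-1.0, 1.0])
    signal = (templates.maps[states].T * (a * signs)) * config.amplitude_uv

    if np.isfinite(config.snr):
        L = _spatial_noise_chol(montage, config.noise_spatial_scale)
        noise = L @ rng.standard_normal((montage.shape[0], n))
        p_sig = float(np.mean(signal**2))
        p_noise = float(np.mean(noise**2))
        noise *= np.sqrt(p_sig / (config.snr * p_noise))
    else:
        noise = np.zeros_like(signal)

    data = signal + noise
    data = data - data.mean(axis=0, keepdims=True)
    rec = EEGRecording(
        data=data,
        sfreq=sfreq,
        channel_names=list(templates.channel_names),
        montage=montage,
        reference="average",
        subject_id=subject_id,
        group=group,
    )
    if return_parts:
        return rec, signal, noise
    return rec


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def _targeted_noise(
    signal: np.ndarray, target_r2: float, rng, fallback_sd: float = 10.0
) -> np.ndarray:
    """Additive noise whose SD makes the linear signal explain ≈ target_r2."""
    sd_sig = float(np.std(signal))
    if sd_sig == 0 or target_r2 >= 1:
        return rng.standard_normal(signal.size) * (0.0 if target_r2 >= 1 else fallback_sd)
    sd_eps = sd_sig * np.sqrt((1.0 - target_r2) / target_r2)
    return rng.standard_normal(signal.size) * sd_eps


def simulate_cohort(
    config: SyntheticConfig,
    n_patients: int,
    n_controls: int,
    seed: int | None = None,
) -> CohortResult:
    """Generate a two-group cohort with ground truth and coupled covariates.

    Patients and controls share classes A–D but differ in the fifth class
    (default E for patients, F for controls) and in per-class dwell
    modifiers. ``SDMT`` is linearly coupled to generative class-A occupancy
    and ``disease_duration`` (patients only) to generative class-A mean
    dwell; noise SDs are derived from configured target R² values against
    the realized between-subject spread.
    """
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    config.validate()
    root = np.random.default_rng(seed if seed is not None else config.seed)
    ss = root.spawn(4)
    rng_templates, rng_subjects, rng_cov, rng_noise = ss

    montage = build_spherical_montage(config.n_channels)
    channel_names = default_channel_names(config.n_channels)
    all_classes = sorted(set(config.patient_classes) | set(config.control_classes))
    templates = make_templates(
        montage,
        len(all_classes),
        smoothness_order=config.template_smoothness_order,
        seed=int(rng_templates.integers(2**31 - 1)),
        max_corr=config.max_template_corr,
        class_labels=all_classes,
        channel_names=channel_names,
    )
    class_to_global = {c: i for i, c in enumerate(all_classes)}

    sfreq = config.generation_sfreq
    n_samples = int(round(config.duration_s * sfreq))
    recordings: list[EEGRecording] = []
    sequences: dict[str, np.ndarray] = {}
    realized_rows = []
    roster = [("patient", i) for i in range(n_patients)] + [
        ("control", i) for i in range(n_controls)
    ]
    for group, idx in roster:
        sid = f"{'P' if group == 'patient' else 'C'}{idx + 1:03d}"
        classes = (
            config.patient_classes if group == "patient" else config.control_classes
        )
        sub_rng = np.random.default_rng(rng_subjects.integers(2**31 - 1))
        dwell = np.array(
            [
                config.mean_dwell_ms[c]
                * config.group_effects.get(group, {}).get(c, 1.0)
                for c in classes
            ]
        )
        if config.subject_dwell_jitter_sd > 0:
            dwell = dwell * np.exp(
                sub_rng.normal(0.0, config.subject_dwell_jitter_sd, size=dwell.size)
            )
        states_local, stats = simulate_state_sequence(
            n_samples,
            sfreq,
            dwell,
            config.dwell_shape,
            config.transition_matrix,
            seed=int(sub_rng.integers(2**31 - 1)),
        )
        global_idx = np.array([class_to_global[c] for c in classes])
        states_global = global_idx[states_local]
        sub_templates = TemplateSet(
            maps=templates.maps[global_idx],
            class_labels=list(classes),
            channel_names=channel_names,
            level="population",
        )
        rec = synthesize_recording(
            sub_templates,
            states_local,
            config,
            montage,
            seed=int(sub_rng.integers(2**31 - 1)),
            subject_id=sid,
            group=group,
        )
        recordings.append(rec)
        sequences[sid] = states_global
        for c in all_classes:
            if c in classes:
                row = stats.iloc[classes.index(c)]
                realized_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "class": c,
                        "occupancy": row["occupancy"],
                        "mean_dwell_ms": row["mean_dwell_ms"],
                        "occurrence_per_min": row["occurrence_per_min"],
                    }
                )
            else:
                realized_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "class": c,
                        "occupancy": 0.0,
                        "mean_dwell_ms": 0.0,
                        "occurrence_per_min": 0.0,
                    }
                )
    realized = pd.DataFrame(realized_rows)

    # --- covariates coupled to generative parameters ---
    cov_rows = []
    occ_a = (
        realized[realized["class"] == "A"].set_index("subject_id")["occupancy"]
    )
    md_a = (
        realized[realized["class"] == "A"].set_index("subject_id")["mean_dwell_ms"]
    )
    sdmt_signal = config.sdmt_beta0 + config.sdmt_beta1 * occ_a
    sdmt = sdmt_signal + _targeted_noise(
        config.sdmt_beta1 * occ_a.values, config.sdmt_target_r2, rng_cov
    )
    dd_signal = config.dd_gamma0 + config.dd_gamma1 * (md_a - md_a.mean())
    dd = dd_signal + _targeted_noise(
        config.dd_gamma1 * md_a.values, config.dd_target_r2, rng_cov
    )
    for (group, idx), rec in zip(roster, recordings):
        sid = rec.subject_id
        is_pat = group == "patient"
        cov_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": float(np.clip(rng_noise.normal(42, 11), 18, 75)),
                "disease_duration": float(max(0.0, dd[sid])) if is_pat else np.nan,
                "EDSS": float(np.clip(rng_noise.normal(1.4, 1.0), 0, 7))
                if is_pat
                else np.nan,
                "ARR": float(np.exp(rng_noise.normal(np.log(0.4), 0.8)))
                if is_pat
                else np.nan,
                "SDMT": float(sdmt[sid]),
                "CVLT2": float(rng_noise.normal(58, 12)),
                "BVMTR": float(rng_noise.normal(54, 9)),
            }
        )
    covariates = pd.DataFrame(cov_rows)

    gt = SyntheticGroundTruth(
        templates=templates,
        state_sequences=sequences,
        realized=realized,
        covariate_coefficients={
            "sdmt_beta0": config.sdmt_beta0,
            "sdmt_beta1": config.sdmt_beta1,
            "sdmt_target_r2": config.sdmt_target_r2,
            "dd_gamma0": config.dd_gamma0,
            "dd_gamma1": config.dd_gamma1,
            "dd_target_r2": config.dd_target_r2,
        },
        seed=seed if seed is not None else config.seed,
    )
    return CohortResult(
        recordings=recordings, covariates=covariates, ground_truth=gt, config=config
    )


def default_two_group_config(**overrides) -> SyntheticConfig:
    """The default two-group scenario: patients carry class E with faster
    A/B dynamics, controls carry class F with a longer-dwelling class D."""
    return replace(SyntheticConfig(), **overrides)
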