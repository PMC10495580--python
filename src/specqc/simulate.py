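"""Synthetic labeled MRSI cohorts for exercising the QC classifiers.

Real short-echo brain MRSI with expert quality labels is rarely shareable, so
this module generates cohorts with the spectral structure the classifiers must
discriminate: prominent NAA / creatine / choline Lorentzian peaks in the
1.4-4.1 ppm window, plus the four artifact families that drive expert quality
verdicts — low SNR, broad linewidth, scalp-lipid contamination leaking in at
the 1.4 ppm edge, and a residual-water baseline tail descending from the
4.1 ppm edge (the 4.7 ppm water resonance itself lies outside the window).

Ground truth is threshold-based on artifact severity.  Each voxel carries a
scalar severity score (the worst of its four criterion severities, signed so
that 0 is exactly the quality threshold); two simulated raters then vote:

* outside a narrow dead band around the threshold a rater simply reports the
  sign of the severity;
* inside the dead band the spectrum is genuinely ambiguous and each rater
  independently draws a biased coin whose bias is calibrated so that the
  consensus (good only if both raters agree) matches the configured bad
  fraction;
* on top of this, near-threshold verdicts flip with probability
  ``rater_noise`` (decaying with distance from the threshold), emulating
  rater disagreement on borderline spectra.

``severity_separation`` scales the severity margins: at 1 the classes are
cleanly separable by thresholding the severity score; at 0 every voxel sits
at the threshold and labels are pure (calibrated) rater coin flips,
independent of the spectral content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import (
    BAD,
    GOOD,
    CohortDataset,
    QCLabel,
    SpectralAxis,
    VoxelSpectrum,
    aggregate_labels,
    canonical_axis,
)

__all__ = [
    "MetabolitePeak",
    "ArtifactProfile",
    "QCThresholds",
    "SimulationConfig",
    "default_peaks",
    "lorentzian",
    "simulate_clean_spectrum",
    "inject_artifacts",
    "severity_score",
    "assign_truth_label",
    "generate_cohort",
]

ND_TAGS = ("healthy", "MDD", "MS", "PD")

#: half-width of the rater dead band on the severity scale
TIE_BAND = 0.05
#: length scale of the near-threshold verdict-flip probability
FLIP_SCALE = 0.1


@dataclass(frozen=True)
class MetabolitePeak:
    """One Lorentzian resonance: name, center (ppm), height, FWHM (ppm)."""

    name: str
    center: float
    amplitude: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")


def default_peaks(tumor: bool = False) -> list[MetabolitePeak]:
    """Nominal short-echo brain peak set (relative heights).

    ``tumor=True`` emulates lesion metabolism: suppressed NAA with elevated
    choline.
    """
    naa_scale, cho_scale = (0.4, 1.6) if tumor else (1.0, 1.0)
    return [
        MetabolitePeak("NAA", 2.01, 1.0 * naa_scale, 0.035),
        MetabolitePeak("Glx", 2.35, 0.25, 0.060),
        MetabolitePeak("Cr", 3.03, 0.80, 0.035),
        MetabolitePeak("Cho", 3.22, 0.70 * cho_scale, 0.035),
        MetabolitePeak("mI", 3.56, 0.35, 0.050),
        MetabolitePeak("Cr2", 3.92, 0.45, 0.040),
    ]


@dataclass(frozen=True)
class ArtifactProfile:
    """Per-voxel artifact intensities, all on the clean-spectrum amplitude scale."""

    lipid_amplitude: float = 0.0
    water_tail_amplitude: float = 0.0
    broadening_factor: float = 1.0
    freq_shift: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.lipid_amplitude < 0 or self.water_tail_amplitude < 0:
            raise ValueError("artifact amplitudes must be >= 0")
        if self.broadening_factor < 1.0:
            raise ValueError("broadening_factor must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class QCThresholds:
    """Quality thresholds on the four rater criteria.

    ``nominal_fwhm`` is the unbroadened reference linewidth used to convert
    the broadening factor into an effective linewidth; ``tie_bad_rate`` is the
    per-rater bad-probability inside the threshold dead band.
    """

    min_snr: float = 8.0
    max_linewidth: float = 0.07  # ppm, effective FWHM
    max_lipid_ratio: float = 1.2  # lipid amplitude / reference peak height
    max_water_ratio: float = 1.5
    nominal_fwhm: float = 0.035
    tie_bad_rate: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 40
    voxels_per_subject: int | tuple[int, int] = 100
    fraction_bad: float = 0.46
    severity_separation: float = 1.0
    rater_noise: float = 0.05
    tumor_mode: bool = False
    lesion_fraction: float = 0.3
    seed: int = 0
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    #: which artifact families are simulated; the rest stay at zero severity
    criteria: tuple[str, ...] = ("snr", "linewidth", "lipid", "water")

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_bad <= 1.0:
            raise ValueError("fraction_bad must be in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.severity_separation <= 1.0:
            raise ValueError("severity_separation must be in [0, 1]")
        if not 0.0 <= self.rater_noise <= 1.0:
            raise ValueError("rater_noise must be in [0, 1]")
        unknown = set(self.criteria) - {"snr", "linewidth", "lipid", "water"}
        if unknown or not self.criteria:
            raise ValueError(f"invalid criteria {self.criteria!r}")
        if self.fraction_bad > 0 and self.severity_separation > 0 and not self.criteria:
            raise ValueError("cannot realize bad voxels with no active artifact criteria")


def lorentzian(x: np.ndarray, center: float, amplitude: float, fwhm: float) -> np.ndarray:
    """Lorentzian with peak value ``amplitude`` and half maximum at center +/- fwhm/2."""
    hw = 0.5 * fwhm
    return amplitude * hw**2 / ((x - center) ** 2 + hw**2)


def simulate_clean_spectrum(
    peaks: list[MetabolitePeak],
    axis: SpectralAxis,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
    cohort_tag: str = "healthy",
    lesion_flag: bool = False,
) -> VoxelSpectrum:
    """Noise-free sum of Lorentzian peaks on the given axis.

    An empty peak list yields a flat (degenerate) spectrum.
    """
    x = axis.ppm_values
    y = np.zeros_like(x)
    for p in peaks:
        y += lorentzian(x, p.center, p.amplitude, p.fwhm)
    return VoxelSpectrum(y, axis, subject_id=subject_id, cohort_tag=cohort_tag, lesion_flag=lesion_flag)


def _broaden(y: np.ndarray, axis: SpectralAxis, kernel_fwhm: float) -> np.ndarray:
    """Convolve with a unit-area Lorentzian kernel of the given FWHM."""
    step = axis.step
    if kernel_fwhm < 0.25 * step:
        return y
    half = max(int(math.ceil(10 * kernel_fwhm / step)), 5)
    grid = np.arange(-half, half + 1) * step
    kernel = lorentzian(grid, 0.0, 1.0, kernel_fwhm)
    kernel /= kernel.sum()
    return np.convolve(y, kernel, mode="same")


def inject_artifacts(
    spectrum: VoxelSpectrum, profile: ArtifactProfile, rng: np.random.Generator
) -> VoxelSpectrum:
    """Apply the artifact chain to a clean spectrum.

    In order: circular frequency shift (rounded to the grid), Lorentzian
    linewidth broadening, lipid contamination (broad resonance at 1.3 ppm,
    truncated at the 1.4 ppm window edge), residual-water tail (broad
    resonance at 4.7 ppm entering at the 4.1 ppm edge), additive Gaussian
    noise.  Deterministic given the generator state.
    """
    axis = spectrum.axis
    x = axis.ppm_values
    y = np.asarray(spectrum.intensities, dtype=float).copy()

    shift_pts = int(round(profile.freq_shift / axis.step))
    if shift_pts != 0:
        y = np.roll(y, shift_pts)

    if profile.broadening_factor > 1.0:
        # Lorentzian-convolved-with-Lorentzian widths add, so a kernel of
        # (factor-1) * nominal width scales a nominal peak's FWHM by factor.
        kernel_fwhm = (profile.broadening_factor - 1.0) * QCThresholds().nominal_fwhm
        y = _broaden(y, axis, kernel_fwhm)

    if profile.lipid_amplitude > 0:
        y += lorentzian(x, 1.3, profile.lipid_amplitude, 0.25)

    if profile.water_tail_amplitude > 0:
        y += lorentzian(x, 4.7, profile.water_tail_amplitude, 1.0)

    if profile.noise_sigma > 0:
        y += rng.normal(0.0, profile.noise_sigma, size=y.shape)

    return replace(spectrum, intensities=y)


# -- severity and labels --------------------------------------------------------


def _criterion_severities(
    profile: ArtifactProfile, ref_amplitude: float, thr: QCThresholds
) -> np.ndarray:
    """Signed per-criterion severities; 0 marks the quality threshold."""
    height = ref_amplitude / profile.broadening_factor
    snr = height / profile.noise_sigma if profile.noise_sigma > 0 else np.inf
    lw = thr.nominal_fwhm * profile.broadening_factor
    return np.array(
        [
            (thr.min_snr - snr) / thr.min_snr,
            (lw - thr.max_linewidth) / thr.max_linewidth,
            (profile.lipid_amplitude / ref_amplitude - thr.max_lipid_ratio) / thr.max_lipid_ratio,
            (profile.water_tail_amplitude / ref_amplitude - thr.max_water_ratio) / thr.max_water_ratio,
        ]
    )


def severity_score(
    profile: ArtifactProfile, clean: VoxelSpectrum, thresholds: QCThresholds = QCThresholds()
) -> float:
    """Worst (maximum) criterion severity; > 0 means at least one criterion exceeded."""
    ref = float(np.max(clean.intensities))
    if ref <= 0:
        raise ValueError("clean spectrum has no positive reference peak")
    return float(np.max(_criterion_severities(profile, ref, thresholds)))


def _rater_verdict(
    s: float, thr: QCThresholds, rater_noise: float, rng: np.random.Generator
) -> str:
    if abs(s) > TIE_BAND:
        verdict = BAD if s > 0 else GOOD
    else:
        verdict = BAD if rng.random() < thr.tie_bad_rate else GOOD
    flip_p = rater_noise * math.exp(-((s / FLIP_SCALE) ** 2))
    if flip_p > 0 and rng.random() < flip_p:
        verdict = GOOD if verdict == BAD else BAD
    return verdict


def assign_truth_label(
    profile: ArtifactProfile,
    clean: VoxelSpectrum,
    thresholds: QCThresholds = QCThresholds(),
    rng: np.random.Generator | None = None,
    rater_noise: float = 0.0,
) -> tuple[str, QCLabel]:
    """Threshold-based truth plus two simulated rater verdicts.

    Truth is ``bad`` iff any criterion severity exceeds its threshold.  Each
    rater applies the dead-band rule described in the module docstring with
    independent randomness; the consensus follows the both-raters-good rule.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    s = severity_score(profile, clean, thresholds)
    truth = BAD if s > 0 else GOOD
    a = _rater_verdict(s, thresholds, rater_noise, rng)
    b = _rater_verdict(s, thresholds, rater_noise, rng)
    return truth, QCLabel(a, b, aggregate_labels(a, b))


# -- cohort generation ----------------------------------------------------------


def _profile_from_severities(c: np.ndarray, thr: QCThresholds, rng: np.random.Generator) -> ArtifactProfile:
    """Invert the severity formulas to concrete artifact parameters."""
    c_snr, c_lw, c_lip, c_wat = c
    ref = 1.0  # canonical clean NAA height
    bf = max(1.0, (1.0 + c_lw) * thr.max_linewidth / thr.nominal_fwhm)
    snr = thr.min_snr * max(0.05, 1.0 - c_snr)
    noise_sigma = (ref / bf) / snr
    return ArtifactProfile(
        lipid_amplitude=max(0.0, ref * thr.max_lipid_ratio * (1.0 + c_lip)),
        water_tail_amplitude=max(0.0, ref * thr.max_water_ratio * (1.0 + c_wat)),
        broadening_factor=bf,
        freq_shift=float(rng.uniform(-0.02, 0.02)),
        noise_sigma=noise_sigma,
    )


def _tie_bad_rate(cfg: SimulationConfig) -> float:
    """Per-rater bad-rate inside the dead band, calibrated so the consensus
    bad-fraction matches ``fraction_bad`` after rater_noise flips."""
    p_cons = 1.0 - math.sqrt(1.0 - min(cfg.fraction_bad, 1.0 - 1e-12))
    f = cfg.rater_noise
    if f >= 0.5:
        return p_cons
    return min(1.0, max(0.0, (p_cons - f) / (1.0 - 2.0 * f)))


def generate_cohort(cfg: SimulationConfig) -> CohortDataset:
    """Generate a subject-grouped labeled cohort on the canonical 850-point axis.

    Seeding is hierarchical (one child stream per subject, one per voxel), so
    identical seeds give bit-identical cohorts and individual subjects can be
    regenerated independently.
    """
    axis = canonical_axis()
    thr = replace(cfg.thresholds, tie_bad_rate=_tie_bad_rate(cfg))
    sep = cfg.severity_separation

    subject_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    rows = []
    spectra = []
    voxel_id = 0
    for si, sseq in enumerate(subject_seeds):
        subject = f"sub{si:03d}"
        tag = "tumor" if cfg.tumor_mode else ND_TAGS[si % len(ND_TAGS)]
        srng = np.random.default_rng(sseq)
        if isinstance(cfg.voxels_per_subject, tuple):
            lo, hi = cfg.voxels_per_subject
            n_vox = int(srng.integers(lo, hi + 1))
        else:
            n_vox = int(cfg.voxels_per_subject)
        voxel_seeds = sseq.spawn(n_vox)
        for vseq in voxel_seeds:
            rng = np.random.default_rng(vseq)
            intended_bad = rng.random() < cfg.fraction_bad
            # class-conditional severity margins, scaled by the separation;
            # inactive artifact families are pinned to severity -1 (absent)
            order = ("snr", "linewidth", "lipid", "water")
            active = [i for i, name in enumerate(order) if name in cfg.criteria]
            margins = -rng.uniform(0.3, 1.0, size=4)
            if intended_bad:
                margins[active[rng.integers(len(active))]] = rng.uniform(0.3, 1.0)
            jitter = rng.uniform(-0.01, 0.01, size=4)
            c = sep * margins + (1.0 - sep) * jitter
            for i in range(4):
                if i not in active:
                    c[i] = -1.0

            lesion = bool(cfg.tumor_mode and rng.random() < cfg.lesion_fraction)
            clean = simulate_clean_spectrum(
                default_peaks(tumor=lesion), axis, subject_id=subject,
                cohort_tag=tag, lesion_flag=lesion,
            )
            profile = _profile_from_severities(c, thr, rng)
            truth, label = assign_truth_label(profile, clean, thr, rng, cfg.rater_noise)
            noisy = inject_artifacts(clean, profile, rng)

            spectra.append(noisy.intensities)
            rows.append(
                {
                    "voxel_id": f"vox{voxel_id:06d}",
                    "subject_id": subject,
                    "cohort_tag": tag,
                    "lesion_flag": lesion,
                    "rater_a": label.rater_a,
                    "rater_b": label.rater_b,
                    "consensus": label.consensus,
                    "truth": truth,
                    "severity": severity_score(profile, clean, thr),
                }
            )
            voxel_id += 1

    manifest = pd.DataFrame(rows)
    return CohortDataset(np.vstack(spectra), axis, manifest)
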