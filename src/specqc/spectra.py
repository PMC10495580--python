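"""Labeled voxel spectra: data model, HDF5/CSV cohort I/O, and input preprocessing.

The central objects are :class:`VoxelSpectrum` (one voxel's spectrum on a ppm
axis plus subject/lesion metadata), :class:`QCLabel` (two rater verdicts and
their consensus), and :class:`CohortDataset` (a subject-grouped collection
backed by a spectra matrix and a pandas manifest).

Preprocessing follows the standard chain for feeding short-echo brain spectra
to a classifier: take the real part of the complex signal, crop to the
metabolite window (default 1.4-4.1 ppm, 850 points), and z-normalize each
spectrum to mean 0 / standard deviation 1.

The ppm axis is stored strictly ascending; the NMR display convention
(ppm decreasing left-to-right) is applied only when plotting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SpectralAxis",
    "VoxelSpectrum",
    "QCLabel",
    "CohortDataset",
    "PreprocessConfig",
    "GOOD",
    "BAD",
    "COHORT_TAGS",
    "canonical_axis",
    "take_real",
    "crop_to_window",
    "znormalize",
    "aggregate_labels",
    "preprocess",
    "preprocess_dataset",
    "read_cohort",
    "write_cohort",
]

GOOD = "good"
BAD = "bad"
_VERDICTS = frozenset({GOOD, BAD})

#: Cohort tags: four neuro/control groups (the "ND" style) plus brain tumor.
COHORT_TAGS = ("healthy", "MDD", "MS", "PD", "tumor")

MANIFEST_COLUMNS = (
    "voxel_id",
    "subject_id",
    "cohort_tag",
    "lesion_flag",
    "rater_a",
    "rater_b",
    "consensus",
)


@dataclass(frozen=True)
class SpectralAxis:
    """Chemical-shift axis in ppm, strictly ascending."""

    ppm_values: np.ndarray

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm_values, dtype=float)
        if ppm.ndim != 1 or ppm.size < 2:
            raise ValueError("axis needs at least 2 points")
        if not np.all(np.isfinite(ppm)):
            raise ValueError("axis contains non-finite ppm values")
        if not np.all(np.diff(ppm) > 0):
            raise ValueError("ppm axis must be strictly ascending")
        object.__setattr__(self, "ppm_values", ppm)

    @property
    def n_points(self) -> int:
        return int(self.ppm_values.size)

    @property
    def step(self) -> float:
        """Median grid spacing in ppm."""
        return float(np.median(np.diff(self.ppm_values)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.ppm_values.shape == other.ppm_values.shape and bool(
            np.array_equal(self.ppm_values, other.ppm_values)
        )

    def __hash__(self) -> int:
        return hash((self.n_points, float(self.ppm_values[0]), float(self.ppm_values[-1])))


def canonical_axis(ppm_lo: float = 1.4, ppm_hi: float = 4.1, n_points: int = 850) -> SpectralAxis:
    """The canonical uniform 850-point axis on [1.4, 4.1] ppm.

    Networks consume fixed-length inputs, so simulated cohorts are generated
    directly on this grid; real data on other grids is cropped then linearly
    resampled onto it.
    """
    return SpectralAxis(np.linspace(ppm_lo, ppm_hi, n_points))


@dataclass(frozen=True)
class VoxelSpectrum:
    """One voxel's spectrum with subject and lesion metadata."""

    intensities: np.ndarray
    axis: SpectralAxis
    subject_id: str
    lesion_flag: bool = False
    cohort_tag: str = "healthy"

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities)
        if y.ndim != 1 or y.size != self.axis.n_points:
            raise ValueError(
                f"intensities length {y.size} does not match axis length {self.axis.n_points}"
            )
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class QCLabel:
    """Per-rater verdicts and their consensus (good only if both agree)."""

    rater_a: str
    rater_b: str
    consensus: str = field(default="")

    def __post_init__(self) -> None:
        for name in ("rater_a", "rater_b"):
            v = getattr(self, name)
            if v not in _VERDICTS:
                raise ValueError(f"{name} must be 'good' or 'bad', got {v!r}")
        expected = aggregate_labels(self.rater_a, self.rater_b)
        if self.consensus == "":
            object.__setattr__(self, "consensus", expected)
        elif self.consensus != expected:
            raise ValueError(
                f"consensus {self.consensus!r} violates the both-raters-good rule "
                f"(raters {self.rater_a!r}/{self.rater_b!r})"
            )


def aggregate_labels(rater_a: str, rater_b: str) -> str:
    """Consensus verdict: ``good`` iff both raters say good.

    A voxel flagged as poor quality by either rater is ``bad`` — the
    conservative consensus used when two experts label the same data.
    """
    for name, v in (("rater_a", rater_a), ("rater_b", rater_b)):
        if v not in _VERDICTS:
            raise ValueError(f"missing or invalid verdict for {name}: {v!r}")
    return GOOD if (rater_a == GOOD and rater_b == GOOD) else BAD


@dataclass(frozen=True)
class PreprocessConfig:
    """Crop window and target length for model input."""

    ppm_lo: float = 1.4
    ppm_hi: float = 4.1
    target_points: int = 850

    def __post_init__(self) -> None:
        if not self.ppm_lo < self.ppm_hi:
            raise ValueError("ppm_lo must be < ppm_hi")
        if self.target_points < 2:
            raise ValueError("target_points must be >= 2")


class CohortDataset:
    """Subject-grouped collection of labeled voxel spectra.

    Backed by a spectra matrix (n_voxels x n_points), a shared
    :class:`SpectralAxis`, and a manifest DataFrame with one row per voxel
    (columns: voxel_id, subject_id, cohort_tag, lesion_flag, rater_a,
    rater_b, consensus).
    """

    def __init__(self, spectra: np.ndarray, axis: SpectralAxis, manifest: pd.DataFrame):
        spectra = np.asarray(spectra)
        if spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D array (n_voxels x n_points)")
        if spectra.shape[1] != axis.n_points:
            raise ValueError(
                f"spectra have {spectra.shape[1]} points but axis has {axis.n_points}"
            )
        manifest = manifest.reset_index(drop=True)
        missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
        if missing:
            raise ValueError(f"manifest missing required column(s): {', '.join(missing)}")
        if len(manifest) != spectra.shape[0]:
            raise ValueError("manifest row count does not match spectra row count")
        if (manifest["subject_id"].astype(str) == "").any():
            raise ValueError("manifest contains empty subject_id")
        for col in ("rater_a", "rater_b", "consensus"):
            bad_vals = set(manifest[col].unique()) - _VERDICTS
            if bad_vals:
                raise ValueError(f"manifest column {col} has invalid verdict(s): {bad_vals}")
        expected = np.where(
            (manifest["rater_a"] == GOOD) & (manifest["rater_b"] == GOOD), GOOD, BAD
        )
        if not (manifest["consensus"].to_numpy() == expected).all():
            raise ValueError("manifest consensus violates the both-raters-good rule")
        manifest = manifest.copy()
        manifest["lesion_flag"] = manifest["lesion_flag"].astype(bool)
        manifest["subject_id"] = manifest["subject_id"].astype(str)
        self.spectra = spectra
        self.axis = axis
        self.manifest = manifest

    # -- basic container protocol ------------------------------------------------

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def __iter__(self) -> Iterator[tuple[VoxelSpectrum, QCLabel]]:
        return iter(self.records())

    def records(self) -> list[tuple[VoxelSpectrum, QCLabel]]:
        out = []
        for i, row in self.manifest.iterrows():
            vs = VoxelSpectrum(
                self.spectra[i],
                self.axis,
                subject_id=row["subject_id"],
                lesion_flag=bool(row["lesion_flag"]),
                cohort_tag=row["cohort_tag"],
            )
            out.append((vs, QCLabel(row["rater_a"], row["rater_b"], row["consensus"])))
        return out

    # -- grouped views -----------------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        """Distinct subject ids, in order of first appearance."""
        return list(dict.fromkeys(self.manifest["subject_id"]))

    @property
    def subject_index(self) -> dict[str, np.ndarray]:
        """Map subject_id -> row indices of that subject's voxels."""
        groups = self.manifest.groupby("subject_id", sort=False).indices
        return {k: np.asarray(v) for k, v in groups.items()}

    @property
    def subject_tags(self) -> dict[str, str]:
        """Map subject_id -> cohort_tag (first occurrence)."""
        return dict(
            self.manifest.drop_duplicates("subject_id")[["subject_id", "cohort_tag"]].values
        )

    @property
    def labels(self) -> np.ndarray:
        """Binary consensus labels with ``good`` as the positive class (1)."""
        return (self.manifest["consensus"].to_numpy() == GOOD).astype(np.int64)

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.manifest["lesion_flag"].to_numpy(dtype=bool)

    def select(self, rows: Sequence[int] | np.ndarray) -> "CohortDataset":
        rows = np.asarray(rows)
        return CohortDataset(self.spectra[rows], self.axis, self.manifest.iloc[rows])

    def subset_subjects(self, subject_ids: Sequence[str]) -> "CohortDataset":
        mask = self.manifest["subject_id"].isin(list(subject_ids)).to_numpy()
        return self.select(np.flatnonzero(mask))


# -- preprocessing operations ---------------------------------------------------


def take_real(spectrum: VoxelSpectrum) -> VoxelSpectrum:
    """Extract the real part of a (possibly complex) spectrum. Idempotent on real input."""
    y = np.real(spectrum.intensities)
    return replace(spectrum, intensities=np.ascontiguousarray(y, dtype=float))


def crop_to_window(spectrum: VoxelSpectrum, cfg: PreprocessConfig = PreprocessConfig()) -> VoxelSpectrum:
    """Keep exactly the axis points inside the closed window [ppm_lo, ppm_hi].

    Raises ``ValueError`` naming the uncovered side if the axis does not span
    the window.
    """
    ppm = spectrum.axis.ppm_values
    if ppm[0] > cfg.ppm_lo:
        raise ValueError(
            f"axis starts at {ppm[0]:.4g} ppm and does not cover the lower window "
            f"bound {cfg.ppm_lo:.4g} ppm"
        )
    if ppm[-1] < cfg.ppm_hi:
        raise ValueError(
            f"axis ends at {ppm[-1]:.4g} ppm and does not cover the upper window "
            f"bound {cfg.ppm_hi:.4g} ppm"
        )
    keep = (ppm >= cfg.ppm_lo) & (ppm <= cfg.ppm_hi)
    return replace(
        spectrum,
        intensities=spectrum.intensities[keep],
        axis=SpectralAxis(ppm[keep]),
    )


def _znorm_rows(y: np.ndarray) -> np.ndarray:
    """Population z-normalization of each row; raises on zero variance."""
    y = np.asarray(y, dtype=float)
    mu = y.mean(axis=-1, keepdims=True)
    sd = y.std(axis=-1, keepdims=True)  # population (divide-by-n) convention
    if np.any(sd <= 0):
        raise ValueError("zero-variance (constant) spectrum cannot be z-normalized")
    return (y - mu) / sd


def znormalize(spectrum: VoxelSpectrum) -> VoxelSpectrum:
    """Normalize intensities to mean 0 / population standard deviation 1."""
    if np.iscomplexobj(spectrum.intensities):
        raise ValueError("znormalize expects real intensities; apply take_real first")
    return replace(spectrum, intensities=_znorm_rows(spectrum.intensities))


def _resample(y: np.ndarray, ppm: np.ndarray, cfg: PreprocessConfig) -> tuple[np.ndarray, np.ndarray]:
    """Linear resampling onto the uniform target grid (extension of the crop contract)."""
    target = np.linspace(cfg.ppm_lo, cfg.ppm_hi, cfg.target_points)
    if y.ndim == 1:
        return np.interp(target, ppm, y), target
    return np.vstack([np.interp(target, ppm, row) for row in y]), target


def preprocess(spectrum: VoxelSpectrum, cfg: PreprocessConfig = PreprocessConfig()) -> VoxelSpectrum:
    """Full input chain: real part -> crop -> (resample if needed) -> z-normalize."""
    s = crop_to_window(take_real(spectrum), cfg)
    if s.axis.n_points != cfg.target_points:
        y, ppm = _resample(s.intensities, s.axis.ppm_values, cfg)
        s = replace(s, intensities=y, axis=SpectralAxis(ppm))
    return znormalize(s)


def preprocess_dataset(dataset: CohortDataset, cfg: PreprocessConfig = PreprocessConfig()) -> CohortDataset:
    """Vectorized preprocessing of a whole cohort onto the target grid."""
    ppm = dataset.axis.ppm_values
    if ppm[0] > cfg.ppm_lo or ppm[-1] < cfg.ppm_hi:
        side = "lower" if ppm[0] > cfg.ppm_lo else "upper"
        raise ValueError(f"cohort axis does not cover the {side} window bound")
    keep = (ppm >= cfg.ppm_lo) & (ppm <= cfg.ppm_hi)
    y = np.real(dataset.spectra)[:, keep].astype(float)
    ppm_c = ppm[keep]
    if ppm_c.size != cfg.target_points:
        y, ppm_c = _resample(y, ppm_c, cfg)
    y = _znorm_rows(y)
    return CohortDataset(y, SpectralAxis(ppm_c), dataset.manifest)


# -- cohort file I/O ------------------------------------------------------------


def _manifest_path(h5_path: str | os.PathLike) -> str:
    base, _ = os.path.splitext(os.fspath(h5_path))
    return base + ".csv"


def write_cohort(dataset: CohortDataset, path: str | os.PathLike, manifest_path: str | os.PathLike | None = None) -> None:
    """Write an HDF5 container (/spectra, /ppm) plus a CSV manifest.

    The manifest defaults to ``<path-without-extension>.csv``.
    """
    if manifest_path is None:
        manifest_path = _manifest_path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=dataset.spectra)
        f.create_dataset("ppm", data=dataset.axis.ppm_values)
    dataset.manifest.to_csv(manifest_path, index=False)


def read_cohort(path: str | os.PathLike, manifest_path: str | os.PathLike | None = None) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort`; validates the schema."""
    if manifest_path is None:
        manifest_path = _manifest_path(path)
    with h5py.File(path, "r") as f:
        for name in ("spectra", "ppm"):
            if name not in f:
                raise ValueError(f"HDF5 container missing dataset /{name}")
        spectra = f["spectra"][()]
        ppm = f["ppm"][()]
    manifest = pd.read_csv(manifest_path)
    return CohortDataset(spectra, SpectralAxis(ppm), manifest)
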