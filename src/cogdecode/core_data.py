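"""Data model and I/O for masked statistical maps and study metadata.

Brain maps live on a common voxel grid (an MNI-like space in real data, a
small synthetic grid in tests).  A :class:`BrainMask` selects the ``p``
grey-matter voxels of interest; every map is handled downstream as a flat
``float64`` vector of length ``p``, obtained by a row-major (C-order) scan of
the grid restricted to in-mask voxels.  This ordering is fixed so that
serialized dictionaries and models remain valid across sessions.

A decoding corpus is a collection of studies.  Study ``j`` contributes
``n^j`` subjects, each with one z-map per experimental contrast; the
``c^j`` contrast names are encoded as integer labels ``1..c^j`` in
lexicographic order of the names, which makes label vectors reproducible
across platforms and reloads.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BrainMask",
    "StudyDataset",
    "MultiStudyCorpus",
    "RestDataset",
    "mask_volume",
    "unmask_vector",
    "load_corpus",
    "write_corpus",
    "summarize_metadata",
]


@dataclass(frozen=True)
class BrainMask:
    """Boolean inclusion volume over a voxel grid with a world affine."""

    include: np.ndarray  # boolean, shape == grid_shape
    affine: np.ndarray  # 4x4 voxel-to-world matrix

    def __post_init__(self):
        include = np.asarray(self.include, dtype=bool)
        affine = np.asarray(self.affine, dtype=float)
        if include.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if include.sum() < 1:
            raise ValueError("mask must include at least one voxel")
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "include", include)
        object.__setattr__(self, "affine", affine)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.include.shape

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels, the map dimension ``p``."""
        return int(self.include.sum())

    def to_image(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.include.astype(np.uint8), self.affine)

    @classmethod
    def from_image(cls, img: nib.Nifti1Image) -> "BrainMask":
        return cls(np.asarray(img.dataobj) > 0, img.affine)


def mask_volume(volume: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Extract in-mask voxels of a 3-D volume as a flat vector.

    The output order is the row-major scan of the grid restricted to
    in-mask voxels, the convention used throughout the package.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != mask.grid_shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match mask grid {mask.grid_shape}"
        )
    values = volume[mask.include]
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite voxel value inside the mask")
    return values


def unmask_vector(v: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Scatter a masked vector back onto the grid; out-of-mask voxels are 0."""
    v = np.asarray(v, dtype=float)
    if v.shape != (mask.n_voxels,):
        raise ValueError(f"vector length {v.shape} does not match mask p={mask.n_voxels}")
    out = np.zeros(mask.grid_shape, dtype=float)
    out[mask.include] = v
    return out


@dataclass
class StudyDataset:
    """All subject-level contrast maps of one study, masked and labelled.

    ``maps`` is ``(n_samples, p)``; ``labels`` holds integers in
    ``[1, n_contrasts]`` mapping to ``contrast_names`` (1-based,
    lexicographic); ``subject_ids`` are integers, one per row.
    """

    study_id: str
    maps: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    contrast_names: list[str]

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids, dtype=int)
        c = len(self.contrast_names)
        if c < 2:
            raise ValueError(f"study {self.study_id!r} has fewer than 2 contrasts")
        if len(set(self.contrast_names)) != c:
            raise ValueError(f"duplicate contrast names in study {self.study_id!r}")
        n = self.maps.shape[0]
        if not (len(self.labels) == len(self.subject_ids) == n):
            raise ValueError("maps, labels and subject_ids must have equal length")
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > c:
            raise ValueError(f"labels outside [1, {c}] in study {self.study_id!r}")

    @property
    def n_contrasts(self) -> int:
        return len(self.contrast_names)

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subject_ids))

    @property
    def n_samples(self) -> int:
        return self.maps.shape[0]

    def subset(self, row_index: np.ndarray) -> "StudyDataset":
        """Row subset sharing the contrast-name encoding (labels unchanged)."""
        return dataclasses.replace(
            self,
            maps=self.maps[row_index],
            labels=self.labels[row_index],
            subject_ids=self.subject_ids[row_index],
        )


@dataclass
class MultiStudyCorpus:
    """Studies sharing one brain mask."""

    studies: list[StudyDataset]
    mask: BrainMask

    def __post_init__(self):
        if len(self.studies) < 1:
            raise ValueError("corpus must contain at least one study")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValueError("study_ids must be unique")
        p = self.mask.n_voxels
        for s in self.studies:
            if s.maps.shape[1] != p:
                raise ValueError(
                    f"study {s.study_id!r} maps have {s.maps.shape[1]} voxels, mask has {p}"
                )

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    def __getitem__(self, study_id: str) -> StudyDataset:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)


@dataclass
class RestDataset:
    """Resting-state data matrix, time-points by in-mask voxels."""

    X: np.ndarray
    mask: BrainMask = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("rest matrix must be 2-D (time-points x voxels)")
        if self.mask is not None and self.X.shape[1] != self.mask.n_voxels:
            raise ValueError("rest matrix column count does not match mask")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite entries in rest matrix")

    @property
    def n_timepoints(self) -> int:
        return self.X.shape[0]


def smooth_maps(maps: np.ndarray, mask: BrainMask, sigma_vox: float) -> np.ndarray:
    """Isotropic Gaussian smoothing of masked maps, in voxel units.

    Standard fMRI preprocessing before spatial decomposition: each row is
    scattered onto the grid, filtered, and re-masked.
    """
    from scipy.ndimage import gaussian_filter

    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if sigma_vox <= 0:
        return maps
    out = np.empty_like(maps)
    for i, row in enumerate(maps):
        out[i] = gaussian_filter(unmask_vector(row, mask), sigma_vox)[mask.include]
    return out


_REQUIRED_COLUMNS = ("study", "subject", "contrast", "path")


def _read_metadata(metadata_path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    return meta


def summarize_metadata(metadata_path: str | os.PathLike) -> dict:
    """Corpus inventory from a metadata TSV alone (no image access).

    Returns the number of studies, the total number of distinct contrasts
    summed over studies, and the total number of distinct subjects summed
    over studies.
    """
    meta = _read_metadata(metadata_path)
    by_study = meta.groupby("study", sort=True)
    n_contrasts = int(by_study["contrast"].nunique().sum())
    n_subjects = int(by_study["subject"].nunique().sum())
    return {
        "n_studies": int(by_study.ngroups),
        "total_contrasts": n_contrasts,
        "total_subjects": n_subjects,
    }


def _load_map(path: str, mask: BrainMask) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"map file not found: {path}")
    img = nib.load(path)
    same_grid = img.shape[:3] == mask.grid_shape and np.allclose(
        img.affine, mask.affine, atol=1e-6
    )
    if not same_grid:
        # Standard practice: trilinear resampling of data onto the mask grid.
        from nilearn.image import resample_img

        img = resample_img(
            img,
            target_affine=mask.affine,
            target_shape=mask.grid_shape,
            interpolation="continuous",
            copy_header=True,
            force_resample=True,
        )
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.shape != mask.grid_shape:
        raise ValueError(
            f"map {path} has grid {data.shape} after resampling, mask is {mask.grid_shape}"
        )
    data = np.nan_to_num(data, nan=0.0)
    return mask_volume(data, mask)


def load_corpus(metadata_path: str | os.PathLike, mask: BrainMask) -> MultiStudyCorpus:
    """Load a multi-study corpus from a TSV table of NIfTI maps.

    The table needs columns ``study``, ``subject``, ``contrast``, ``path``.
    Contrast labels are integers assigned in lexicographic order of the
    contrast names within each study; subject identifiers are re-encoded as
    integers in sorted order of their original values.
    """
    meta = _read_metadata(metadata_path)
    base_dir = os.path.dirname(os.fspath(metadata_path))
    studies = []
    for study_id, group in meta.groupby("study", sort=True):
        names = sorted(group["contrast"].unique())
        if len(names) < 2:
            raise ValueError(f"study {study_id!r} has a single contrast")
        label_of = {name: i + 1 for i, name in enumerate(names)}
        subjects = sorted(group["subject"].unique())
        subject_of = {s: i for i, s in enumerate(subjects)}
        rows, labels, subj = [], [], []
        for _, rec in group.iterrows():
            path = rec["path"]
            if not os.path.isabs(path):
                path = os.path.join(base_dir, path)
            rows.append(_load_map(path, mask))
            labels.append(label_of[rec["contrast"]])
            subj.append(subject_of[rec["subject"]])
        studies.append(
            StudyDataset(
                study_id=str(study_id),
                maps=np.array(rows),
                labels=np.array(labels),
                subject_ids=np.array(subj),
                contrast_names=list(names),
            )
        )
    return MultiStudyCorpus(studies=studies, mask=mask)


def write_corpus(corpus: MultiStudyCorpus, out_dir: str | os.PathLike) -> str:
    """Write a corpus as one NIfTI per map plus a metadata TSV and mask.

    Returns the path of the metadata TSV; ``load_corpus`` on it restores the
    corpus (maps entry-for-entry, identical labels).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    mask = corpus.mask
    nib.save(mask.to_image(), os.path.join(out_dir, "mask.nii.gz"))
    records = []
    for study in corpus.studies:
        sdir = os.path.join(out_dir, study.study_id)
        os.makedirs(sdir, exist_ok=True)
        for i in range(study.n_samples):
            name = study.contrast_names[study.labels[i] - 1]
            fname = f"sub-{study.subject_ids[i]:03d}_{name}.nii.gz"
            vol = unmask_vector(study.maps[i], mask)
            nib.save(nib.Nifti1Image(vol, mask.affine), os.path.join(sdir, fname))
            records.append(
                {
                    "study": study.study_id,
                    "subject": f"sub-{study.subject_ids[i]:03d}",
                    "contrast": name,
                    "path": os.path.join(study.study_id, fname),
                }
            )
    meta_path = os.path.join(out_dir, "metadata.tsv")
    pd.DataFrame.from_records(records).to_csv(meta_path, sep="\t", index=False)
    return meta_path
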