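"""Synthetic multi-study corpora with a known latent generative model.

The generator mirrors the structure the decoding model assumes: activation
maps are non-negative spatial atoms (``D_true``, localized Gaussian blobs),
combined into a handful of latent cognitive networks (``L_true``), which
studies recruit through per-contrast latent codes (``W^j``).  A subject-level
contrast map is

    x = (W^j_c + eta_s) @ L_true @ D_true + eps,

where ``eta_s`` is a per-subject latent perturbation shared across that
subject's contrasts (an inter-subject confound that subject-wise
cross-validation must overcome) and ``eps`` is i.i.d. voxel noise.
Resting-state data is generated as non-negative loadings on the same atoms,
``X = A @ D_true + E``, so the first-layer factorization has a recoverable
target.

A fraction ``rho`` of the latent dimensions is usable by every study (the
shared cognitive structure that makes transfer learning possible); the rest
are private to single studies.

Default condition: a 12x14x12 grid with an ellipsoidal mask of roughly 850
voxels, 24 atoms, 8 latent networks, 6 studies with 3-8 contrasts and 8-40
subjects each, rho=0.75, voxel noise 1.0, subject spread 0.5.  Contrast
codes have Euclidean norm 3, which at these noise levels puts single-study
decoding in an intermediate-accuracy regime rather than at ceiling or floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import (
    BrainMask,
    MultiStudyCorpus,
    RestDataset,
    StudyDataset,
    mask_volume,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_ground_truth",
    "simulate_rest",
    "simulate_corpus",
    "ellipsoid_mask",
]

# Vocabulary for synthetic contrast names: cognitive-domain token plus a
# condition token, mimicking how investigators name contrasts.
_DOMAINS = (
    "motor", "visual", "auditory", "language", "reward",
    "memory", "attention", "calculation",
)
_CONDITIONS = (
    "left", "right", "face", "house", "word", "pseudoword",
    "easy", "hard", "go", "stop", "gain", "loss",
)


@dataclass(frozen=True)
class SimulationConfig:
    grid_shape: tuple[int, int, int] = (12, 14, 12)
    k_true: int = 24
    l_true: int = 8
    n_studies: int = 6
    n_contrasts_range: tuple[int, int] = (3, 8)
    n_subjects_range: tuple[int, int] = (8, 40)
    rho: float = 0.75  # fraction of latent dims shared across studies
    sigma_voxel: float = 1.0
    tau: float = 0.5  # subject-level latent spread
    n_rest: int = 1500
    amplitude: float = 3.0  # Euclidean norm of each contrast code W^j_c
    blob_sigma: float = 1.5  # atom width in voxels
    seed: int = 0

    def __post_init__(self):
        if min(self.k_true, self.l_true, self.n_studies, self.n_rest) < 1:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.sigma_voxel < 0 or self.tau < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass
class GroundTruth:
    """Latent generative parameters behind a synthetic corpus."""

    mask: BrainMask
    D_true: np.ndarray  # (k_true, p), non-negative, unit-norm rows
    L_true: np.ndarray  # (l_true, k_true), non-negative
    contrast_codes: list[np.ndarray]  # per study: (c_j, l_true)
    study_ids: list[str]
    contrast_names: list[list[str]]
    n_subjects: list[int]
    sigma_voxel: float
    tau: float
    seed: int

    @property
    def latent_maps(self) -> np.ndarray:
        """Rows of ``L_true @ D_true`` — the true latent networks in voxel space."""
        return self.L_true @ self.D_true


def ellipsoid_mask(grid_shape: tuple[int, int, int]) -> BrainMask:
    """Ellipsoid inscribed in the grid, a stand-in for a grey-matter mask."""
    shape = tuple(grid_shape)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [max(s / 2.0 - 0.5, 1.0) for s in shape]
    idx = np.indices(shape)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    include = r2 <= 1.0
    affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm voxels, arbitrary origin
    return BrainMask(include=include, affine=affine)


def _place_blobs(mask: BrainMask, k: int, sigma: float, rng: np.random.Generator,
                 min_dist: float = 2.0, max_tries: int = 2000) -> np.ndarray:
    """Truncated Gaussian atoms with distinct in-mask centres; (k, p)."""
    coords = np.argwhere(mask.include)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < k:
        if tries > max_tries:
            raise ValueError(
                f"could not place {k} blob centres at distance {min_dist} "
                f"in a mask of {mask.n_voxels} voxels"
            )
        cand = coords[rng.integers(len(coords))]
        if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
            centers.append(cand)
        tries += 1
    idx = np.indices(mask.grid_shape)
    atoms = np.empty((k, mask.n_voxels))
    for r, c in enumerate(centers):
        d2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
        bump = np.exp(-d2 / (2.0 * sigma**2))
        bump[bump < 0.05 * bump.max()] = 0.0  # truncate tails: sparse support
        v = mask_volume(bump, mask)
        atoms[r] = v / np.linalg.norm(v)
    return atoms


def _study_supports(allowed: np.ndarray, c_j: int, support_size: int,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Cyclic assignment of latent supports so every allowed dim is covered
    whenever the study has enough contrast slots."""
    order = rng.permutation(allowed)
    s = min(support_size, len(order))
    supports = []
    for c in range(c_j):
        pos = (c * s + np.arange(s)) % len(order)
        supports.append(np.unique(order[pos]))
    return supports


def make_ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Draw the latent model: atoms, networks, and per-study contrast codes."""
    rng = np.random.default_rng(cfg.seed)
    mask = ellipsoid_mask(cfg.grid_shape)
    D_true = _place_blobs(mask, cfg.k_true, cfg.blob_sigma, rng)

    # Latent networks: non-negative combinations of a few atoms, unit norm.
    L_true = np.zeros((cfg.l_true, cfg.k_true))
    n_per = min(3, cfg.k_true)
    for r in range(cfg.l_true):
        atoms = rng.choice(cfg.k_true, size=n_per, replace=False)
        L_true[r, atoms] = np.abs(rng.normal(size=n_per)) + 0.1
        L_true[r] /= np.linalg.norm(L_true[r])

    # Shared vs study-private latent dimensions.
    n_shared = int(round(cfg.rho * cfg.l_true))
    perm = rng.permutation(cfg.l_true)
    shared = perm[:n_shared]
    private = perm[n_shared:]

    contrast_codes, study_ids, all_names, n_subjects = [], [], [], []
    lo_c, hi_c = cfg.n_contrasts_range
    lo_n, hi_n = cfg.n_subjects_range
    for j in range(cfg.n_studies):
        c_j = int(rng.integers(lo_c, hi_c + 1))
        n_j = int(rng.integers(lo_n, hi_n + 1))
        own_private = private[private % cfg.n_studies == j] if len(private) else private[:0]
        allowed = np.concatenate([shared, own_private])
        supports = _study_supports(allowed, c_j, support_size=3, rng=rng)
        W = np.zeros((c_j, cfg.l_true))
        for c, sup in enumerate(supports):
            W[c, sup] = rng.normal(size=len(sup))
            W[c] *= cfg.amplitude / np.linalg.norm(W[c])
        names = _draw_names(c_j, rng)
        contrast_codes.append(W)
        study_ids.append(f"study{j:02d}")
        all_names.append(names)
        n_subjects.append(n_j)
    return GroundTruth(
        mask=mask,
        D_true=D_true,
        L_true=L_true,
        contrast_codes=contrast_codes,
        study_ids=study_ids,
        contrast_names=all_names,
        n_subjects=n_subjects,
        sigma_voxel=cfg.sigma_voxel,
        tau=cfg.tau,
        seed=cfg.seed,
    )


def _draw_names(c_j: int, rng: np.random.Generator) -> list[str]:
    names: set[str] = set()
    while len(names) < c_j:
        d = _DOMAINS[rng.integers(len(_DOMAINS))]
        c = _CONDITIONS[rng.integers(len(_CONDITIONS))]
        names.add(f"{d}_{c}")
    return sorted(names)


def simulate_rest(gt: GroundTruth, n_rest: int, seed: int | None = None) -> RestDataset:
    """Rest matrix ``X = A @ D_true + E`` with non-negative loadings A."""
    k_true = gt.D_true.shape[0]
    if n_rest < k_true:
        raise ValueError(f"n_rest={n_rest} must be >= k_true={k_true}")
    rng = np.random.default_rng(gt.seed + 1 if seed is None else seed)
    A = np.abs(rng.normal(size=(n_rest, k_true)))
    X = A @ gt.D_true
    if gt.sigma_voxel > 0:
        X = X + rng.normal(scale=gt.sigma_voxel, size=X.shape)
    return RestDataset(X=X, mask=gt.mask)


def simulate_corpus(gt: GroundTruth, seed: int | None = None) -> MultiStudyCorpus:
    """Subject-level contrast maps for every study of the ground truth.

    Each subject of a study contributes one map per contrast; the subject's
    latent perturbation ``eta_s`` is drawn once and shared across all of that
    subject's contrasts.
    """
    rng = np.random.default_rng(gt.seed + 2 if seed is None else seed)
    LD = gt.latent_maps
    p = LD.shape[1]
    studies = []
    for j, study_id in enumerate(gt.study_ids):
        W = gt.contrast_codes[j]
        c_j, l_true = W.shape
        n_j = gt.n_subjects[j]
        maps = np.empty((n_j * c_j, p))
        labels = np.empty(n_j * c_j, dtype=int)
        subject_ids = np.empty(n_j * c_j, dtype=int)
        row = 0
        for s in range(n_j):
            eta = rng.normal(scale=gt.tau, size=l_true) if gt.tau > 0 else np.zeros(l_true)
            for c in range(c_j):
                x = (W[c] + eta) @ LD
                if gt.sigma_voxel > 0:
                    x = x + rng.normal(scale=gt.sigma_voxel, size=p)
                maps[row] = x
                labels[row] = c + 1
                subject_ids[row] = s
                row += 1
        studies.append(
            StudyDataset(
                study_id=study_id,
                maps=maps,
                labels=labels,
                subject_ids=subject_ids,
                contrast_names=gt.contrast_names[j],
            )
        )
    return MultiStudyCorpus(studies=studies, mask=gt.mask)
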