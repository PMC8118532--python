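"""Second and third layers: shared embedding and per-study classifier heads.

The decoder for study ``j`` is the factorized linear model

    logits = U^j @ L @ s(D x) + b^j,     prediction = argmax over contrasts,

where ``D`` is the frozen first-layer dictionary, ``s`` a per-feature
standardization of the projected features (mean/scale estimated once on the
training fold, then frozen), ``L`` the ``(l, k)`` embedding shared by every
study, and ``(U^j, b^j)`` the head of study ``j`` with one row per contrast.

Training minimizes

    sum_j (1/n^j) sum_i CE(U^j L s(D x_i^j) + b^j, y_i^j) + l2 * ||U^j||^2

by Adam: at each step one study is drawn, a batch of its samples is taken
without replacement from an epoch-shuffled order, and inverted-dropout masks
are applied to the two intermediate activations (the projected features and
the embedded features) during training only.  The ``1/n^j`` weighting (the
subject count, not the sample count) up-weights studies with few subjects.
Sharing ``L`` while regularizing with dropout is what lets small studies
borrow statistical strength from large ones (transfer learning); the heads
remain study-specific because contrasts are never matched across studies.

The product ``U^j L`` is invariant to ``(L, U^j) -> (M L, U^j M^{-1})`` for
any invertible ``M``; identifying meaningful directions despite this
ambiguity is the job of the consensus module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import MultiStudyCorpus
from .functional_units import Dictionary, project_maps

__all__ = [
    "TrainConfig",
    "SharedEmbedding",
    "StudyHead",
    "MultiStudyModel",
    "train_multistudy",
    "forward_logits",
    "predict",
    "study_loss",
    "classification_maps",
]


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the joint training stage.

    The latent width ``l`` is 128 in the full-scale configuration; the
    default here matches the desk-scale synthetic corpus.
    """

    latent_dim: int = 16
    dropout_input: float = 0.25
    dropout_latent: float = 0.5
    l2_head: float = 1e-4
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 32
    n_epochs: int = 400
    study_sampling: str = "uniform"  # or "cyclic"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.dropout_input < 1.0 and 0.0 <= self.dropout_latent < 1.0):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.study_sampling not in ("uniform", "cyclic"):
            raise ValueError("study_sampling must be 'uniform' or 'cyclic'")


@dataclass
class SharedEmbedding:
    """Shared ``(l, k)`` embedding plus the frozen feature standardization."""

    L: np.ndarray
    offset: np.ndarray  # (k,) mean of D x on the training fold
    scale: np.ndarray  # (k,) strictly positive

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.L.ndim != 2 or not np.all(np.isfinite(self.L)):
            raise ValueError("embedding must be a finite 2-D matrix")
        if np.any(self.scale <= 0):
            raise ValueError("standardization scale must be strictly positive")

    @property
    def l(self) -> int:
        return self.L.shape[0]

    @property
    def k(self) -> int:
        return self.L.shape[1]

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Standardize projected features: ``s(D x)``."""
        return (features - self.offset) / self.scale


@dataclass
class StudyHead:
    study_id: str
    U: np.ndarray  # (c_j, l)
    b: np.ndarray  # (c_j,)
    n_subjects: int  # the n^j used in the objective weighting

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.U.shape[0] != self.b.shape[0]:
            raise ValueError("head U and b must agree on the number of contrasts")
        if not (np.all(np.isfinite(self.U)) and np.all(np.isfinite(self.b))):
            raise ValueError("head parameters must be finite")


@dataclass
class MultiStudyModel:
    dictionary: Dictionary
    embedding: SharedEmbedding
    heads: dict[str, StudyHead]
    contrast_names: dict[str, list[str]]
    config: TrainConfig
    seed: int

    def head(self, study_id: str) -> StudyHead:
        if study_id not in self.heads:
            raise KeyError(f"unknown study {study_id!r}")
        return self.heads[study_id]


def _features(model: MultiStudyModel, maps: np.ndarray) -> np.ndarray:
    return model.embedding.transform(project_maps(maps, model.dictionary))


def forward_logits(model: MultiStudyModel, study_id: str, maps: np.ndarray) -> np.ndarray:
    """Per-contrast decision values ``U^j L s(D x) + b^j`` (no dropout)."""
    head = model.head(study_id)
    s = _features(model, maps)
    return s @ model.embedding.L.T @ head.U.T + head.b


def predict(model: MultiStudyModel, study_id: str, maps: np.ndarray) -> np.ndarray:
    """Predicted 1-based contrast labels; ties go to the lowest label."""
    logits = forward_logits(model, study_id, maps)
    return np.argmax(logits, axis=1) + 1


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def study_loss(
    model: MultiStudyModel,
    study_id: str,
    maps: np.ndarray,
    labels: np.ndarray,
) -> float:
    """Objective term of one study on a batch.

    ``(1/n^j) * sum_batch CE + l2 * ||U^j||_F^2`` — the subject-count
    weighting, so that a full pass over the study reproduces its term in the
    training objective.
    """
    head = model.head(study_id)
    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0:
        raise ValueError("empty batch")
    c_j = head.U.shape[0]
    if labels.min() < 1 or labels.max() > c_j:
        raise ValueError(f"labels outside [1, {c_j}]")
    logp = _log_softmax(forward_logits(model, study_id, maps))
    ce = -logp[np.arange(len(labels)), labels - 1].sum()
    return float(ce / head.n_subjects + model.config.l2_head * np.sum(head.U**2))


def _loss_and_grads(L, U, b, s, y0, weight, l2):
    """Weighted cross-entropy loss and exact gradients for one batch.

    ``s`` is (B, k) standardized features, ``y0`` 0-based labels, ``weight``
    the multiplier on the summed batch cross-entropy.  Returns
    (loss, gL, gU, gb) with the l2 head penalty included.
    """
    h = s @ L.T  # (B, l)
    logits = h @ U.T + b
    logp = _log_softmax(logits)
    loss = -weight * logp[np.arange(len(y0)), y0].sum() + l2 * np.sum(U**2)
    dlogits = np.exp(logp)
    dlogits[np.arange(len(y0)), y0] -= 1.0
    dlogits *= weight
    gU = dlogits.T @ h + 2.0 * l2 * U
    gb = dlogits.sum(axis=0)
    gL = (dlogits @ U).T @ s
    return loss, gL, gU, gb


class _Adam:
    """Adam state for one parameter array with its own step counter."""

    def __init__(self, shape, cfg: TrainConfig):
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0
        self.cfg = cfg

    def step(self, param: np.ndarray, grad: np.ndarray) -> None:
        cfg = self.cfg
        self.t += 1
        self.m = cfg.beta1 * self.m + (1 - cfg.beta1) * grad
        self.v = cfg.beta2 * self.v + (1 - cfg.beta2) * grad**2
        m_hat = self.m / (1 - cfg.beta1**self.t)
        v_hat = self.v / (1 - cfg.beta2**self.t)
        param -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.eps)


class _BatchStream:
    """Without-replacement batches from an epoch-shuffled sample order."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.batch_size = min(batch_size, n)
        self.rng = rng
        self.order = rng.permutation(n)
        self.pos = 0

    def next_batch(self) -> np.ndarray:
        if self.pos >= self.n:
            self.order = self.rng.permutation(self.n)
            self.pos = 0
        batch = self.order[self.pos : self.pos + self.batch_size]
        self.pos += len(batch)
        return batch


def train_multistudy(
    corpus: MultiStudyCorpus,
    dictionary: Dictionary,
    cfg: TrainConfig,
) -> MultiStudyModel:
    """Jointly train the shared embedding and all study heads.

    Feature standardization is computed once on the pooled training-fold
    projections and frozen.  ``L`` starts from ``N(0, 1/k)`` entries; heads
    start at zero, so the untrained model predicts at chance.  The run is
    fully reproducible from ``cfg.seed``.
    """
    for s in corpus.studies:
        if s.n_samples == 0:
            raise ValueError(f"study {s.study_id!r} has an empty training fold")
        if s.n_contrasts < 2 or s.n_subjects < 2:
            raise ValueError(
                f"study {s.study_id!r} needs >= 2 contrasts and >= 2 subjects"
            )
    rng = np.random.default_rng(cfg.seed)
    k = dictionary.k
    l = cfg.latent_dim

    feats = {s.study_id: project_maps(s.maps, dictionary) for s in corpus.studies}
    pooled = np.vstack(list(feats.values()))
    if cfg.standardize:
        offset = pooled.mean(axis=0)
        scale = pooled.std(axis=0)
        scale[scale < 1e-8] = 1.0
    else:
        offset = np.zeros(k)
        scale = np.ones(k)
    std_feats = {sid: (f - offset) / scale for sid, f in feats.items()}

    L = rng.normal(scale=1.0 / np.sqrt(k), size=(l, k))
    heads: dict[str, StudyHead] = {}
    adam_U: dict[str, _Adam] = {}
    adam_b: dict[str, _Adam] = {}
    streams: dict[str, _BatchStream] = {}
    y0 = {}
    for s in corpus.studies:
        heads[s.study_id] = StudyHead(
            study_id=s.study_id,
            U=np.zeros((s.n_contrasts, l)),
            b=np.zeros(s.n_contrasts),
            n_subjects=s.n_subjects,
        )
        adam_U[s.study_id] = _Adam((s.n_contrasts, l), cfg)
        adam_b[s.study_id] = _Adam((s.n_contrasts,), cfg)
        streams[s.study_id] = _BatchStream(s.n_samples, cfg.batch_size, rng)
        y0[s.study_id] = s.labels - 1
    adam_L = _Adam((l, k), cfg)

    ids = corpus.study_ids
    total = sum(s.n_samples for s in corpus.studies)
    steps_per_epoch = max(1, int(np.ceil(total / cfg.batch_size)))
    n_steps = cfg.n_epochs * steps_per_epoch
    keep_in = 1.0 - cfg.dropout_input
    keep_lat = 1.0 - cfg.dropout_latent

    for step in range(n_steps):
        if cfg.study_sampling == "uniform":
            sid = ids[rng.integers(len(ids))]
        else:
            sid = ids[step % len(ids)]
        study = corpus[sid]
        head = heads[sid]
        idx = streams[sid].next_batch()
        s_batch = std_feats[sid][idx]
        yb = y0[sid][idx]
        B = len(idx)
        # Inverted dropout on the projected features and on the embedding.
        if cfg.dropout_input > 0:
            mask_in = rng.random(s_batch.shape) < keep_in
            s_batch = s_batch * mask_in / keep_in
        h = s_batch @ L.T
        if cfg.dropout_latent > 0:
            mask_lat = rng.random(h.shape) < keep_lat
            h = h * mask_lat / keep_lat
        logits = h @ head.U.T + head.b
        logp = _log_softmax(logits)
        # Unbiased estimate of the study term: total samples c^j n^j with
        # per-sample weight 1/n^j gives batch weight c^j / B.
        weight = study.n_contrasts / B
        loss = -weight * logp[np.arange(B), yb].sum()
        if not np.isfinite(loss):
            raise DivergenceError(
                f"non-finite loss at step {step} (learning rate {cfg.learning_rate})"
            )
        dlogits = np.exp(logp)
        dlogits[np.arange(B), yb] -= 1.0
        dlogits *= weight
        gU = dlogits.T @ h + 2.0 * cfg.l2_head * head.U
        gb = dlogits.sum(axis=0)
        dh = dlogits @ head.U
        if cfg.dropout_latent > 0:
            dh = dh * mask_lat / keep_lat
        gL = dh.T @ s_batch
        adam_U[sid].step(head.U, gU)
        adam_b[sid].step(head.b, gb)
        adam_L.step(L, gL)

    embedding = SharedEmbedding(L=L, offset=offset, scale=scale)
    return MultiStudyModel(
        dictionary=dictionary,
        embedding=embedding,
        heads=heads,
        contrast_names={s.study_id: list(s.contrast_names) for s in corpus.studies},
        config=cfg,
        seed=cfg.seed,
    )


def classification_maps(model: MultiStudyModel) -> tuple[np.ndarray, list[str]]:
    """Voxel-space linear form of every contrast decision.

    Row for contrast ``c`` of study ``j`` is ``(U^j L diag(1/scale) D)_c`` —
    the weights the model applies to a raw map.  Returns the stacked
    ``(sum_j c_j, p)`` matrix and ``"study::contrast"`` names.  The stacked
    matrix has rank at most ``l`` by construction.
    """
    emb = model.embedding
    basis = (emb.L / emb.scale) @ model.dictionary.D  # (l, p)
    rows, names = [], []
    for sid in sorted(model.heads):
        head = model.heads[sid]
        rows.append(head.U @ basis)
        names.extend(f"{sid}::{c}" for c in model.contrast_names[sid])
    return np.vstack(rows), names
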