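"""Ensemble consensus: identifiable, interpretable task-optimized networks.

A single training run only determines the embedding ``L`` up to an
invertible mixing (``U^j L == U^j M^{-1} M L``), yet the subspace spanned by
``L D`` is remarkably stable across runs.  The consensus procedure exploits
this: train ``R`` models with different seeds, stack their embeddings into a
tall matrix ``L~`` of shape ``(l R, k)``, and factorize

    L~ ~ K @ L_bar,   L_bar >= 0 and sparse,   K unconstrained,

by alternating least squares for ``K`` with block-coordinate non-negative
shrinkage for ``L_bar``.  Rows of ``L_bar @ D`` are then non-negative
spatial networks — the multi-study task-optimized networks (MSTONs) — that
can be read as a soft parcellation tuned to decoding across studies.
Consensus heads are refit on the frozen consensus features by convex
multinomial regression, giving a deterministic consensus decoder.

Rows of ``L~`` are unit-normalized before factorization (the normalization
is absorbed by ``K``), which makes the default l1 penalty scale-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .core_data import MultiStudyCorpus
from .functional_units import Dictionary, project_maps
from .model import MultiStudyModel, TrainConfig, train_multistudy

__all__ = [
    "EnsembleRuns",
    "ConsensusFactorization",
    "ConsensusModel",
    "train_ensemble",
    "extract_mstons",
    "refit_consensus_heads",
    "mston_maps",
    "contrast_association",
    "name_mstons",
]

DEFAULT_CONSENSUS_L1 = 0.02


class EnsembleError(RuntimeError):
    pass


@dataclass
class EnsembleRuns:
    runs: list[MultiStudyModel]
    L_stack: np.ndarray  # (l*R, k), embeddings stacked in seed order

    @property
    def R(self) -> int:
        return len(self.runs)


@dataclass
class ConsensusFactorization:
    K: np.ndarray  # (l*R, l) mixing
    L_bar: np.ndarray  # (l, k) non-negative sparse consensus
    reconstruction_error: float  # relative Frobenius
    objective_trace: list[float] = field(default_factory=list)

    @property
    def zero_fraction(self) -> float:
        return float(np.mean(self.L_bar == 0.0))


@dataclass
class ConsensusModel:
    dictionary: Dictionary
    L_bar: np.ndarray
    offset: np.ndarray
    scale: np.ndarray
    heads: dict[str, tuple[np.ndarray, np.ndarray]]  # study -> (U_bar, b_bar)
    contrast_names: dict[str, list[str]]
    mston_names: list[str] = field(default_factory=list)


def train_ensemble(
    corpus: MultiStudyCorpus,
    dictionary: Dictionary,
    cfg: TrainConfig,
    seeds: list[int],
    allow_duplicate_seeds: bool = False,
) -> EnsembleRuns:
    """Train R models differing only in seed (initialization and sampling
    order), and stack their embeddings."""
    if len(seeds) < 2:
        raise ValueError("an ensemble needs R >= 2 runs")
    if len(set(seeds)) != len(seeds) and not allow_duplicate_seeds:
        raise ValueError("ensemble seeds must be distinct")
    runs = []
    for seed in seeds:
        try:
            runs.append(train_multistudy(corpus, dictionary, replace_seed(cfg, seed)))
        except Exception as exc:  # noqa: BLE001 - annotate the failing seed
            raise EnsembleError(f"ensemble run with seed {seed} failed: {exc}") from exc
    L_stack = np.vstack([m.embedding.L for m in runs])
    return EnsembleRuns(runs=runs, L_stack=L_stack)


def replace_seed(cfg: TrainConfig, seed: int) -> TrainConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)


def _normalize_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def extract_mstons(
    runs: EnsembleRuns | np.ndarray,
    lam: float = DEFAULT_CONSENSUS_L1,
    n_iter: int = 200,
    seed: int = 0,
    n_components: int | None = None,
) -> ConsensusFactorization:
    """Sparse non-negative consensus factorization of stacked embeddings.

    Minimizes ``||L~ - K L_bar||_F^2 + lam * sum ||L_bar row||_1`` with
    ``L_bar >= 0`` by alternating exact least squares for ``K`` and
    block-coordinate descent for ``L_bar``; the objective is tracked per
    alternation and never increases.  On return the rows of ``L_bar`` are
    rescaled to unit Euclidean norm with ``K`` compensating, which leaves
    the product unchanged.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    L_tilde = runs.L_stack if isinstance(runs, EnsembleRuns) else np.asarray(runs, float)
    L_tilde = _normalize_rows(L_tilde)
    if isinstance(runs, EnsembleRuns):
        l = runs.runs[0].embedding.l
    else:
        l = n_components if n_components is not None else L_tilde.shape[0]
    k = L_tilde.shape[1]
    rng = np.random.default_rng(seed)

    # Initialize from the non-negative parts of the first run's rows.
    L_bar = np.maximum(L_tilde[:l].copy(), 0.0)
    for r in range(l):
        if not L_bar[r].any():
            L_bar[r] = np.abs(rng.normal(size=k))
    L_bar = _normalize_rows(L_bar)

    trace: list[float] = []
    reseeded = np.zeros(l, dtype=bool)
    K = np.zeros((L_tilde.shape[0], l))
    for _ in range(n_iter):
        K = np.linalg.lstsq(L_bar.T, L_tilde.T, rcond=None)[0].T  # (lR, l)
        G = K.T @ K
        F = K.T @ L_tilde
        for r in range(l):
            g_rr = G[r, r]
            if g_rr <= 1e-12:
                L_bar[r] = 0.0
            else:
                grad = F[r] - G[r] @ L_bar + g_rr * L_bar[r]
                L_bar[r] = np.maximum(grad - lam, 0.0) / g_rr
            if not L_bar[r].any():
                if reseeded[r]:
                    raise RuntimeError(
                        f"consensus row {r} empty after shrinkage twice; "
                        f"lam={lam} is too large"
                    )
                reseeded[r] = True
                resid = L_tilde - K @ L_bar
                direction = np.maximum(resid[np.argmax(np.linalg.norm(resid, axis=1))], 0.0)
                if not direction.any():
                    direction = np.abs(rng.normal(size=k))
                L_bar[r] = direction / np.linalg.norm(direction) * 1e-10
        resid = L_tilde - K @ L_bar
        trace.append(float(np.sum(resid**2)) + lam * float(np.abs(L_bar).sum()))
        if len(trace) > 1 and trace[-2] - trace[-1] < 1e-12 * max(1.0, trace[-2]):
            break

    # Scale ambiguity removed: unit-norm rows, K compensates.
    norms = np.linalg.norm(L_bar, axis=1)
    norms[norms == 0] = 1.0
    L_bar = L_bar / norms[:, None]
    K = K * norms[None, :]
    rel_err = float(
        np.linalg.norm(L_tilde - K @ L_bar) / max(np.linalg.norm(L_tilde), 1e-12)
    )
    return ConsensusFactorization(
        K=K, L_bar=L_bar, reconstruction_error=rel_err, objective_trace=trace
    )


def refit_consensus_heads(
    corpus: MultiStudyCorpus,
    dictionary: Dictionary,
    L_bar: np.ndarray,
    l2: float = 1e-4,
    standardize: bool = True,
) -> ConsensusModel:
    """Deterministic consensus decoder on frozen features ``L_bar s(D x)``.

    Heads are fit per study by l2-regularized multinomial regression
    (convex, lbfgs, tolerance 1e-8).
    """
    L_bar = np.asarray(L_bar, dtype=float)
    feats = {s.study_id: project_maps(s.maps, dictionary) for s in corpus.studies}
    pooled = np.vstack(list(feats.values()))
    if standardize:
        offset = pooled.mean(axis=0)
        scale = pooled.std(axis=0)
        scale[scale < 1e-8] = 1.0
    else:
        offset = np.zeros(pooled.shape[1])
        scale = np.ones(pooled.shape[1])
    consensus_feats = {
        sid: (f - offset) / scale @ L_bar.T for sid, f in feats.items()
    }
    all_feats = np.vstack(list(consensus_feats.values()))
    centered = all_feats - all_feats.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv.size == 0 or np.sum(sv > max(sv[0], 1e-30) * 1e-8) < 2:
        raise ValueError(
            "degenerate consensus features: fewer than 2 informative components"
        )

    heads: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in corpus.studies:
        F = consensus_feats[s.study_id]
        # sklearn objective 0.5||W||^2 + C * sum CE matches
        # (1/n^j) sum CE + l2 ||U||^2 up to the factor 1/(2 l2 n^j).
        C = 1.0 / (2.0 * l2 * s.n_subjects)
        clf = LogisticRegression(C=C, tol=1e-8, max_iter=5000, solver="lbfgs")
        clf.fit(F, s.labels)
        U = clf.coef_
        b = clf.intercept_
        if U.shape[0] == 1:  # binary: sklearn stores a single row
            U = np.vstack([-U[0] / 2, U[0] / 2])
            b = np.array([-b[0] / 2, b[0] / 2])
        heads[s.study_id] = (U, b)
    return ConsensusModel(
        dictionary=dictionary,
        L_bar=L_bar,
        offset=offset,
        scale=scale,
        heads=heads,
        contrast_names={s.study_id: list(s.contrast_names) for s in corpus.studies},
    )


def consensus_predict(cm: ConsensusModel, study_id: str, maps: np.ndarray) -> np.ndarray:
    if study_id not in cm.heads:
        raise KeyError(f"unknown study {study_id!r}")
    U, b = cm.heads[study_id]
    f = (project_maps(maps, cm.dictionary) - cm.offset) / cm.scale @ cm.L_bar.T
    logits = f @ U.T + b
    return np.argmax(logits, axis=1) + 1


def mston_maps(cm: ConsensusModel) -> np.ndarray:
    """The l task-optimized networks in voxel space: rows of ``L_bar @ D``.

    Non-negative by construction (both factors are)."""
    return cm.L_bar @ cm.dictionary.D


def contrast_association(
    cm: ConsensusModel,
    maps: np.ndarray,
    map_names: list[str],
) -> pd.DataFrame:
    """Cosine similarity of every network to every classification map.

    One row per (network, contrast) pair, sorted per network by descending
    similarity (ties broken by contrast name).  Zero-norm maps get
    similarity 0 with a warning.
    """
    networks = mston_maps(cm)
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    net_norms = np.linalg.norm(networks, axis=1)
    map_norms = np.linalg.norm(maps, axis=1)
    if np.any(map_norms == 0):
        warnings.warn("zero-norm classification map: association set to 0")
    safe_map = np.where(map_norms == 0, 1.0, map_norms)
    safe_net = np.where(net_norms == 0, 1.0, net_norms)
    cos = (networks / safe_net[:, None]) @ (maps / safe_map[:, None]).T
    cos[:, map_norms == 0] = 0.0
    cos[net_norms == 0, :] = 0.0
    records = []
    for r in range(networks.shape[0]):
        order = sorted(range(len(map_names)), key=lambda i: (-cos[r, i], map_names[i]))
        for rank, i in enumerate(order, start=1):
            records.append(
                {
                    "network": r,
                    "contrast": map_names[i],
                    "cosine": float(cos[r, i]),
                    "rank": rank,
                }
            )
    return pd.DataFrame.from_records(records)


def name_mstons(association: pd.DataFrame, top: int = 5) -> list[str]:
    """Readable network names from cosine-weighted contrast-name tokens.

    The machine-readable replacement for per-network word clouds: for each
    network, tokens of its top-associated contrast names are weighted by
    similarity and the two heaviest tokens are joined into a name.
    """
    names = []
    for r in sorted(association["network"].unique()):
        sub = association[association["network"] == r].nsmallest(top, "rank")
        weights: dict[str, float] = {}
        for _, row in sub.iterrows():
            label = row["contrast"].split("::")[-1]
            for tok in label.replace("-", "_").split("_"):
                if tok:
                    weights[tok] = weights.get(tok, 0.0) + max(row["cosine"], 0.0)
        ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))[:2]
        names.append(f"net{r:02d}_" + "_".join(t for t, _ in ranked))
    return names
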