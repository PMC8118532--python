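"""Pipeline orchestration, configuration, and model serialization.

Stages mirror the analysis flow: ``simulate`` (synthetic corpus fixture),
``units`` (first-layer dictionary from rest data), ``fit`` (one joint
model), ``ensemble`` (R seeds), ``consensus`` (MSTON extraction and head
refit), ``evaluate`` (half-split scores, transfer summary, similarity
reports).  Every stage writes a JSON manifest carrying the resolved
configuration hash and seeds; re-running with an unchanged configuration
reuses cached stage outputs, and a changed configuration refuses to
overwrite unless forced.

Model files are a JSON manifest (shapes, config, study ids, contrast names,
sha256 checksums) plus raw little-endian float64 arrays in row-major order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import consensus as consensus_mod
from . import evaluation as eval_mod
from .core_data import BrainMask, MultiStudyCorpus, RestDataset, load_corpus, write_corpus
from .functional_units import (
    Dictionary,
    fit_functional_units,
    load_dictionary,
    save_dictionary,
)
from .model import MultiStudyModel, SharedEmbedding, StudyHead, TrainConfig, train_multistudy
from .synthetic import SimulationConfig, make_ground_truth, simulate_corpus, simulate_rest

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "save_model",
    "load_model",
    "load_config",
]

STAGES = ("simulate", "units", "fit", "ensemble", "consensus", "evaluate")
MODEL_FORMAT_VERSION = 1


class DependencyError(RuntimeError):
    pass


class ChecksumError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    output_dir: str = "cogdecode_output"
    seed: int = 0
    # Either a synthetic configuration or paths to real data.
    synthetic: SimulationConfig | None = field(default_factory=SimulationConfig)
    corpus_tsv: str | None = None
    mask_path: str | None = None
    rest_path: str | None = None
    # First layer.
    n_units: int = 48
    unit_sparsity: float = 0.1
    unit_epochs: int = 15
    rest_smoothing_vox: float = 1.5
    # Joint training.
    train: TrainConfig = field(default_factory=TrainConfig)
    # Ensemble + consensus.
    ensemble_size: int = 4
    consensus_l1: float = consensus_mod.DEFAULT_CONSENSUS_L1
    # Evaluation.
    n_repeats: int = 20
    subject_counts: tuple[int, ...] = ()

    def resolved(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str) -> PipelineConfig:
    """Read a fully explicit YAML or JSON pipeline configuration."""
    with open(path) as f:
        if path.endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(f)
        else:
            raw = json.load(f)
    raw = dict(raw or {})
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        for key in ("grid_shape", "n_contrasts_range", "n_subjects_range"):
            if key in syn:
                syn[key] = tuple(syn[key])
        raw["synthetic"] = SimulationConfig(**syn)
    if "train" in raw:
        raw["train"] = TrainConfig(**raw["train"])
    if "subject_counts" in raw:
        raw["subject_counts"] = tuple(raw["subject_counts"])
    return PipelineConfig(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_array(path: str, arr: np.ndarray) -> dict:
    arr = np.ascontiguousarray(arr, dtype="<f8")
    arr.tofile(path)
    return {"shape": list(arr.shape), "sha256": _sha256(path)}


def _read_array(path: str, meta: dict) -> np.ndarray:
    if _sha256(path) != meta["sha256"]:
        raise ChecksumError(f"checksum mismatch for {path}")
    return np.fromfile(path, dtype="<f8").reshape(meta["shape"])


def save_model(model: MultiStudyModel, path: str | os.PathLike) -> dict:
    """Serialize a trained model; returns the manifest."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    arrays = {
        "L": model.embedding.L,
        "offset": model.embedding.offset,
        "scale": model.embedding.scale,
        "D": model.dictionary.D,
    }
    for sid, head in model.heads.items():
        arrays[f"U__{sid}"] = head.U
        arrays[f"b__{sid}"] = head.b
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "seed": model.seed,
        "config": asdict(model.config),
        "dictionary_sparsity": model.dictionary.sparsity,
        "study_ids": sorted(model.heads),
        "n_subjects": {sid: model.heads[sid].n_subjects for sid in model.heads},
        "contrast_names": model.contrast_names,
        "arrays": {},
    }
    for name, arr in arrays.items():
        manifest["arrays"][name] = _write_array(os.path.join(path, name + ".bin"), arr)
    with open(os.path.join(path, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest


def load_model(path: str | os.PathLike, mask: BrainMask | None = None) -> MultiStudyModel:
    path = os.fspath(path)
    with open(os.path.join(path, "manifest.json")) as f:
        manifest = json.load(f)
    if manifest.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {manifest.get('format_version')} is not supported"
        )
    arrays = {
        name: _read_array(os.path.join(path, name + ".bin"), meta)
        for name, meta in manifest["arrays"].items()
    }
    dictionary = Dictionary(
        D=arrays["D"], sparsity=manifest["dictionary_sparsity"], mask=mask
    )
    embedding = SharedEmbedding(
        L=arrays["L"], offset=arrays["offset"], scale=arrays["scale"]
    )
    heads = {
        sid: StudyHead(
            study_id=sid,
            U=arrays[f"U__{sid}"],
            b=arrays[f"b__{sid}"],
            n_subjects=manifest["n_subjects"][sid],
        )
        for sid in manifest["study_ids"]
    }
    return MultiStudyModel(
        dictionary=dictionary,
        embedding=embedding,
        heads=heads,
        contrast_names=manifest["contrast_names"],
        config=TrainConfig(**manifest["config"]),
        seed=manifest["seed"],
    )


def _stage_dir(cfg: PipelineConfig, stage: str) -> str:
    return os.path.join(cfg.output_dir, stage)


def _stage_done(cfg: PipelineConfig, stage: str, force: bool) -> bool:
    """True if the stage output exists under the same configuration."""
    mpath = os.path.join(_stage_dir(cfg, stage), "stage.json")
    if not os.path.exists(mpath):
        return False
    with open(mpath) as f:
        recorded = json.load(f)
    if recorded.get("config_hash") != cfg.config_hash():
        if force:
            return False
        raise RuntimeError(
            f"stage {stage!r} was produced by a different configuration; "
            f"pass force=True to overwrite"
        )
    return True


def _mark_stage(cfg: PipelineConfig, stage: str, extra: dict | None = None) -> dict:
    record = {"stage": stage, "config_hash": cfg.config_hash(), "seed": cfg.seed}
    record.update(extra or {})
    with open(os.path.join(_stage_dir(cfg, stage), "stage.json"), "w") as f:
        json.dump(record, f, indent=2, default=str)
    return record


def _load_inputs(cfg: PipelineConfig) -> tuple[MultiStudyCorpus, RestDataset]:
    sim_dir = _stage_dir(cfg, "simulate")
    if cfg.corpus_tsv is not None:
        import nibabel as nib

        mask = BrainMask.from_image(nib.load(cfg.mask_path))
        corpus = load_corpus(cfg.corpus_tsv, mask)
        X = np.load(cfg.rest_path)
        rest = RestDataset(X=X, mask=mask)
    elif os.path.exists(os.path.join(sim_dir, "metadata.tsv")):
        import nibabel as nib

        mask = BrainMask.from_image(nib.load(os.path.join(sim_dir, "mask.nii.gz")))
        corpus = load_corpus(os.path.join(sim_dir, "metadata.tsv"), mask)
        rest = RestDataset(X=np.load(os.path.join(sim_dir, "rest.npy")), mask=mask)
    else:
        raise DependencyError("no corpus available: run the 'simulate' stage first")
    return corpus, rest


def run_pipeline(
    cfg: PipelineConfig, stages: tuple[str, ...] = STAGES, force: bool = False
) -> dict:
    """Execute the requested stages in order; returns the run manifest."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    os.makedirs(cfg.output_dir, exist_ok=True)
    manifest: dict = {"config": cfg.resolved(), "config_hash": cfg.config_hash(), "stages": {}}

    for stage in stages:
        sdir = _stage_dir(cfg, stage)
        os.makedirs(sdir, exist_ok=True)
        if _stage_done(cfg, stage, force):
            manifest["stages"][stage] = {"cached": True}
            continue
        runner = _STAGE_RUNNERS[stage]
        manifest["stages"][stage] = runner(cfg)
        _mark_stage(cfg, stage, manifest["stages"][stage])

    with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return manifest


def _run_simulate(cfg: PipelineConfig) -> dict:
    if cfg.synthetic is None:
        raise DependencyError("simulate stage requires a synthetic configuration")
    sim = dataclasses.replace(cfg.synthetic, seed=cfg.synthetic.seed + cfg.seed)
    gt = make_ground_truth(sim)
    corpus = simulate_corpus(gt)
    rest = simulate_rest(gt, sim.n_rest)
    sdir = _stage_dir(cfg, "simulate")
    write_corpus(corpus, sdir)
    np.save(os.path.join(sdir, "rest.npy"), rest.X)
    np.savez(
        os.path.join(sdir, "ground_truth.npz"),
        D_true=gt.D_true,
        L_true=gt.L_true,
    )
    return {
        "n_studies": corpus.n_studies,
        "total_contrasts": sum(s.n_contrasts for s in corpus.studies),
        "total_subjects": sum(s.n_subjects for s in corpus.studies),
    }


def _run_units(cfg: PipelineConfig) -> dict:
    _, rest = _load_inputs(cfg)
    from .core_data import smooth_maps

    X = smooth_maps(rest.X, rest.mask, cfg.rest_smoothing_vox)
    fact = fit_functional_units(
        RestDataset(X=X, mask=rest.mask), k=cfg.n_units, lam=cfg.unit_sparsity,
        n_epochs=cfg.unit_epochs, seed=cfg.seed,
    )
    save_dictionary(fact.dictionary, _stage_dir(cfg, "units"))
    return {
        "k": fact.dictionary.k,
        "zero_fraction": fact.dictionary.zero_fraction,
        "final_objective": fact.objective_trace[-1] if fact.objective_trace else None,
    }


def _require_dictionary(cfg: PipelineConfig) -> Dictionary:
    udir = _stage_dir(cfg, "units")
    if not os.path.exists(os.path.join(udir, "dictionary.json")):
        raise DependencyError("missing dictionary: run the 'units' stage first")
    return load_dictionary(udir)


def _run_fit(cfg: PipelineConfig) -> dict:
    corpus, _ = _load_inputs(cfg)
    dictionary = _require_dictionary(cfg)
    model = train_multistudy(corpus, dictionary, dataclasses.replace(cfg.train, seed=cfg.seed))
    save_model(model, os.path.join(_stage_dir(cfg, "fit"), "model"))
    return {"latent_dim": model.embedding.l}


def _run_ensemble(cfg: PipelineConfig) -> dict:
    corpus, _ = _load_inputs(cfg)
    dictionary = _require_dictionary(cfg)
    seeds = [cfg.seed + 1000 * (r + 1) for r in range(cfg.ensemble_size)]
    runs = consensus_mod.train_ensemble(corpus, dictionary, cfg.train, seeds)
    edir = _stage_dir(cfg, "ensemble")
    for seed, model in zip(seeds, runs.runs):
        save_model(model, os.path.join(edir, f"run_{seed}"))
    with open(os.path.join(edir, "seeds.json"), "w") as f:
        json.dump(seeds, f)
    return {"R": runs.R, "seeds": seeds}


def _run_consensus(cfg: PipelineConfig) -> dict:
    corpus, _ = _load_inputs(cfg)
    dictionary = _require_dictionary(cfg)
    edir = _stage_dir(cfg, "ensemble")
    seeds_path = os.path.join(edir, "seeds.json")
    if not os.path.exists(seeds_path):
        raise DependencyError("missing ensemble runs: run the 'ensemble' stage first")
    with open(seeds_path) as f:
        seeds = json.load(f)
    runs = [load_model(os.path.join(edir, f"run_{seed}"), mask=corpus.mask) for seed in seeds]
    L_stack = np.vstack([m.embedding.L for m in runs])
    ens = consensus_mod.EnsembleRuns(runs=runs, L_stack=L_stack)
    fact = consensus_mod.extract_mstons(ens, lam=cfg.consensus_l1, seed=cfg.seed)
    cm = consensus_mod.refit_consensus_heads(corpus, dictionary, fact.L_bar)
    from .model import classification_maps

    cmaps, cnames = classification_maps(runs[0])
    assoc = consensus_mod.contrast_association(cm, cmaps, cnames)
    cm.mston_names = consensus_mod.name_mstons(assoc)
    cdir = _stage_dir(cfg, "consensus")
    _write_array(os.path.join(cdir, "L_bar.bin"), fact.L_bar)
    assoc.to_csv(os.path.join(cdir, "associations.tsv"), sep="\t", index=False)
    networks = consensus_mod.mston_maps(cm)
    if corpus.mask is not None:
        import nibabel as nib

        from .core_data import unmask_vector

        vols = np.stack([unmask_vector(v, corpus.mask) for v in networks], axis=-1)
        nib.save(
            nib.Nifti1Image(vols, corpus.mask.affine),
            os.path.join(cdir, "mstons.nii.gz"),
        )
    with open(os.path.join(cdir, "mstons.json"), "w") as f:
        json.dump(
            {
                "names": cm.mston_names,
                "reconstruction_error": fact.reconstruction_error,
                "zero_fraction": fact.zero_fraction,
            },
            f,
            indent=2,
        )
    return {
        "reconstruction_error": fact.reconstruction_error,
        "zero_fraction": fact.zero_fraction,
        "names": cm.mston_names,
    }


def _run_evaluate(cfg: PipelineConfig) -> dict:
    corpus, _ = _load_inputs(cfg)
    dictionary = _require_dictionary(cfg)
    splits = eval_mod.subject_half_splits(corpus, n_repeats=cfg.n_repeats, seed=cfg.seed)
    scores = eval_mod.evaluate_methods(corpus, dictionary, cfg.train, splits)
    vdir = _stage_dir(cfg, "evaluate")
    scores.accuracy.to_csv(os.path.join(vdir, "accuracy.tsv"), sep="\t", index=False)
    scores.balanced.to_csv(
        os.path.join(vdir, "balanced_accuracy.tsv"), sep="\t", index=False
    )
    summary = {}
    for baseline in ("voxel", "network"):
        gains = eval_mod.transfer_gain_summary(scores, "multistudy", baseline)
        summary[f"vs_{baseline}"] = {
            k: v for k, v in gains.items() if k != "per_study_mean_delta"
        }
        gains["per_study_mean_delta"].to_csv(
            os.path.join(vdir, f"per_study_gain_vs_{baseline}.tsv"), sep="\t"
        )
    mean_acc = (
        scores.accuracy.groupby("method")["accuracy"].mean().to_dict()
    )
    summary["mean_accuracy"] = mean_acc
    with open(os.path.join(vdir, "summary.json"), "w") as f:
        json.dump(summary, f, indent=2)
    return summary


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "units": _run_units,
    "fit": _run_fit,
    "ensemble": _run_ensemble,
    "consensus": _run_consensus,
    "evaluate": _run_evaluate,
}
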