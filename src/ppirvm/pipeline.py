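"""End-to-end orchestration: extract features, cross-validate, train, predict.

The workflow mirrors how the method is used in practice: per-protein PSSMs
(parsed or simulated) -> low-rank descriptors -> concatenated pair features
-> PCA -> RVM classifier -> stratified cross-validation or a persisted
model for later prediction.  Every run writes a machine-readable run log
(full config echo, library versions, seed) next to its outputs so a result
can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np
import sklearn

from . import __version__ as _pkg_version
from . import evaluation, lra, pca, rvm
from .pssm import PSSM, parse_ascii_pssm, read_pssm_tsv

__all__ = [
    "PipelineConfig",
    "load_pssm_file",
    "run_extract",
    "run_cv",
    "run_train",
    "run_predict",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT = "ppirvm-model-v1"


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings with their defaults materialized.

    The defaults are echoed into every run log, so a log alone suffices to
    re-run the command that produced an output.
    """

    pssm_dir: Optional[str] = None
    pairs_path: Optional[str] = None
    features_path: Optional[str] = None
    out_dir: str = "."
    rank: int = 5
    augment_reversed: bool = False
    variance_target: float = 0.95
    n_components: Optional[int] = None
    gamma: Optional[float] = None
    include_bias: bool = True
    k: int = 5
    seed: int = 0
    max_iter: int = 1000
    tol: float = 1e-3
    prune_threshold: float = 1e12

    def pca_config(self) -> pca.PCAConfig:
        return pca.PCAConfig(self.variance_target, self.n_components)

    def rvm_config(self) -> rvm.RVMConfig:
        return rvm.RVMConfig(
            kernel=rvm.KernelSpec(gamma=self.gamma, include_bias=self.include_bias),
            max_iter=self.max_iter,
            tol=self.tol,
            prune_threshold=self.prune_threshold,
        )


def _write_run_log(config: PipelineConfig, out_dir: Path, command: str, **extra) -> None:
    log = {
        "command": command,
        "config": asdict(config),
        "versions": {
            "ppirvm": _pkg_version,
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
            "python": platform.python_version(),
        },
        **extra,
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"run_log_{command}.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)


def load_pssm_file(pssm_dir, protein_id: str) -> Optional[PSSM]:
    """Locate ``<id>.tsv`` or ``<id>.pssm`` under ``pssm_dir`` and parse it."""
    d = Path(pssm_dir)
    tsv = d / f"{protein_id}.tsv"
    if tsv.exists():
        return read_pssm_tsv(tsv)
    ascii_path = d / f"{protein_id}.pssm"
    if ascii_path.exists():
        return parse_ascii_pssm(ascii_path, protein_id)
    return None


def _read_pairs(pairs_path) -> list[tuple[str, str, Optional[int]]]:
    pairs: list[tuple[str, str, Optional[int]]] = []
    with open(pairs_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id_a", "id_b"]:
            raise ValueError(f"{pairs_path}: expected header id_a<TAB>id_b[<TAB>label]")
        has_label = len(header) >= 3 and header[2] == "label"
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            label: Optional[int] = None
            if has_label and len(fields) >= 3 and fields[2] != "":
                label = int(fields[2])
                if label not in (0, 1):
                    raise ValueError(f"{pairs_path}:{line_no}: label must be 0/1")
            pairs.append((fields[0], fields[1], label))
    if not pairs:
        raise ValueError(f"{pairs_path}: no pairs listed")
    return pairs


def _build_pair_features(
    pssm_dir, pair_list, rank: int, augment_reversed: bool
) -> tuple[list[lra.PairFeature], list[str]]:
    ids = sorted({pid for a, b, _ in pair_list for pid in (a, b)})
    pssms: dict[str, PSSM] = {}
    missing: list[str] = []
    for pid in ids:
        p = load_pssm_file(pssm_dir, pid)
        if p is None:
            missing.append(pid)
        else:
            pssms[pid] = p
    if missing:
        raise FileNotFoundError(
            f"no PSSM file (<id>.tsv or <id>.pssm) under {pssm_dir} for "
            f"{len(missing)} protein id(s): {', '.join(missing)}"
        )

    descriptors: dict[str, lra.Descriptor] = {}
    skipped: list[str] = []
    features: list[lra.PairFeature] = []
    for a, b, label in pair_list:
        try:
            for pid in (a, b):
                if pid not in descriptors:
                    descriptors[pid] = lra.pssm_descriptor(pssms[pid], r=rank)
        except ValueError as exc:
            skipped.append(f"({a}, {b}): {exc}")
            continue
        features.append(lra.pair_feature(descriptors[a], descriptors[b], label))
        if augment_reversed:
            features.append(lra.pair_feature(descriptors[b], descriptors[a], label))
    for reason in skipped:
        logger.warning("skipped pair %s", reason)
    return features, skipped


def run_extract(config: PipelineConfig) -> Path:
    """PSSM directory + pair list -> pair feature table TSV."""
    if config.pssm_dir is None or config.pairs_path is None:
        raise ValueError("extract requires pssm_dir and pairs_path")
    out_dir = Path(config.out_dir)
    pair_list = _read_pairs(config.pairs_path)
    features, skipped = _build_pair_features(
        config.pssm_dir, pair_list, config.rank, config.augment_reversed
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    out_path = out_dir / "features.tsv"
    lra.write_feature_table(features, out_path, rank=config.rank)
    _write_run_log(
        config, out_dir, "extract",
        n_pairs=len(features), n_skipped=len(skipped), skipped=skipped,
    )
    return out_path


def _load_features(config: PipelineConfig) -> tuple[list[lra.PairFeature], int]:
    if config.features_path is None:
        raise ValueError("a feature table path is required (run extract first)")
    return lra.read_feature_table(config.features_path)


def run_cv(config: PipelineConfig) -> Path:
    """Stratified k-fold cross-validation; writes report JSON + ROC TSV."""
    pairs, rank = _load_features(config)
    if any(p.label is None for p in pairs):
        raise ValueError("cross-validation requires labels on every pair")
    report = evaluation.cross_validate(
        pairs,
        pca_config=config.pca_config(),
        rvm_config=config.rvm_config(),
        k=config.k,
        seed=config.seed,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "cv_report.json"
    report_path.write_text(report.to_json())
    with open(out_dir / "roc.tsv", "w") as fh:
        fh.write("curve\tfpr\ttpr\n")
        for f in report.fold_results:
            for fpr, tpr in f.roc_points:
                fh.write(f"fold{f.fold}\t{fpr!r}\t{tpr!r}\n")
        for fpr, tpr in report.pooled_roc:
            fh.write(f"pooled\t{fpr!r}\t{tpr!r}\n")
    _write_run_log(
        config, out_dir, "cv",
        n_pairs=len(pairs), rank=rank,
        mean_accuracy=report.mean.accuracy, pooled_auc=report.pooled_auc,
        pca_k=[f.pca_k for f in report.fold_results],
    )
    return report_path


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(
    path, model: rvm.RVMModel, pca_model: pca.PCAModel, rank: int
) -> None:
    """Persist the full predictor (PCA + RVM + descriptor rank) as JSON.

    The container is self-sufficient for prediction from raw PSSMs: the
    descriptor rank fixes the input dimension, the PCA block the projection,
    the RVM block the kernel and posterior.
    """
    payload = {
        "format": MODEL_FORMAT,
        "rank": rank,
        "pca": {
            "mean": pca_model.mean.tolist(),
            "components": pca_model.components.tolist(),
            "explained_variance": pca_model.explained_variance.tolist(),
            "explained_variance_ratio": pca_model.explained_variance_ratio.tolist(),
        },
        "rvm": {
            "mode": model.mode,
            "kernel": {
                "kind": model.kernel.kind,
                "gamma": model.kernel.gamma,
                "include_bias": model.kernel.include_bias,
            },
            "relevance_vectors": model.relevance_vectors.tolist(),
            "has_bias": model.has_bias,
            "weights_mean": model.weights_mean.tolist(),
            "weights_covariance": model.weights_covariance.tolist(),
            "alphas": model.alphas.tolist(),
            "noise_variance": model.noise_variance,
            "n_features": model.n_features,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> tuple[rvm.RVMModel, pca.PCAModel, int]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: not a {MODEL_FORMAT} container")
    p = payload["pca"]
    pca_model = pca.PCAModel(
        mean=np.array(p["mean"]),
        components=np.array(p["components"]),
        explained_variance=np.array(p["explained_variance"]),
        explained_variance_ratio=np.array(p["explained_variance_ratio"]),
    )
    r = payload["rvm"]
    model = rvm.RVMModel(
        mode=r["mode"],
        kernel=rvm.KernelSpec(**r["kernel"]),
        relevance_vectors=np.array(r["relevance_vectors"], dtype=float).reshape(
            -1, r["n_features"]
        ),
        has_bias=r["has_bias"],
        weights_mean=np.array(r["weights_mean"]),
        weights_covariance=np.array(r["weights_covariance"]),
        alphas=np.array(r["alphas"]),
        noise_variance=r["noise_variance"],
        n_features=r["n_features"],
    )
    return model, pca_model, int(payload["rank"])


def run_train(config: PipelineConfig) -> Path:
    """Fit PCA + RVM on the full labeled feature table and persist them."""
    pairs, rank = _load_features(config)
    if any(p.label is None for p in pairs):
        raise ValueError("training requires labels on every pair")
    X, y = lra.pair_matrix(pairs)
    pc = config.pca_config()
    pca_model = pca.fit_pca(X, variance_target=pc.variance_target,
                            n_components=pc.n_components)
    Z = pca.apply_pca(pca_model, X)
    rc = config.rvm_config()
    model, diag = rvm.fit_rvm_classifier(
        Z, y, kernel=rc.kernel, max_iter=rc.max_iter, tol=rc.tol,
        prune_threshold=rc.prune_threshold,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model_path = out_dir / "model.json"
    save_model(model_path, model, pca_model, rank)
    _write_run_log(
        config, out_dir, "train",
        n_pairs=len(pairs), rank=rank, pca_k=pca_model.k,
        n_relevance_vectors=model.n_relevance_vectors,
        iterations=diag.iterations_run, converged=diag.converged,
    )
    return model_path


def run_predict(config: PipelineConfig, model_path) -> Path:
    """Score query pairs with a persisted model; writes a scored TSV."""
    model, pca_model, model_rank = load_model(model_path)
    pairs, rank = _load_features(config)
    if rank != model_rank:
        raise ValueError(
            f"feature table was extracted at rank {rank} but the model was "
            f"trained at rank {model_rank}"
        )
    X, _ = lra.pair_matrix(pairs)
    if X.shape[1] != pca_model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model's "
            f"expected dimension {pca_model.n_features}"
        )
    Z = pca.apply_pca(pca_model, X)
    scores = rvm.predict(model, Z)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_path = out_dir / "predictions.tsv"
    with open(out_path, "w") as fh:
        fh.write("id_a\tid_b\tprobability\tlabel\n")
        for p, s in zip(pairs, scores):
            fh.write(f"{p.id_a}\t{p.id_b}\t{float(s)!r}\t{int(s >= 0.5)}\n")
    _write_run_log(config, out_dir, "predict", n_pairs=len(pairs),
                   model=str(model_path))
    return out_path
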