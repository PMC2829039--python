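"""Pipeline orchestration: simulate -> segment -> profile -> cluster -> associate.

Each stage reads its inputs from the output directory of the previous stage,
writes CSV/TSV artifacts plus a provenance JSON (stage name, seed, config
hash, package version), and is independently re-runnable.  Identical config
and seed produce byte-identical result CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .association import moderated_t_one_vs_rest, permutation_screen
from .consensus import (DEFAULT_K_RANGE, DEFAULT_N_ITER, DEFAULT_N_SAMPLES,
                        ConsensusKSClustering)
from .morphometry import ZernikeFingerprinter
from .segmentation import GaborTextureSegmenter
from .synthgen import SyntheticStudySpec, generate_study

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "profile", "cluster", "associate", "report")

#: which stage produces each artifact consumed downstream
_PRODUCER = {
    "manifest.csv": "simulate",
    "expression.tsv": "simulate",
    "masks": "segment",
    "regions.csv": "segment",
    "fingerprints.csv": "profile",
    "partition.csv": "cluster",
    "cdf_delta.csv": "cluster",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline; YAML-serializable."""

    output_dir: str = "pipeline_out"
    seed: int = 0
    simulate: dict = field(default_factory=dict)     # SyntheticStudySpec overrides
    segmentation: dict = field(default_factory=dict)  # GaborTextureSegmenter params
    morphometry: dict = field(default_factory=dict)   # ZernikeFingerprinter params
    consensus: dict = field(default_factory=dict)     # ConsensusKSClustering params
    association: dict = field(default_factory=dict)   # M, links, fdr thresholds

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _outdir(config: PipelineConfig) -> Path:
    p = Path(config.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(config: PipelineConfig, artifact: str) -> Path:
    path = _outdir(config) / artifact
    if not path.exists():
        raise PipelineError(
            f"missing upstream artifact {artifact!r}: run the "
            f"'{_PRODUCER[artifact]}' stage first")
    return path


def _write_provenance(config: PipelineConfig, stage: str) -> None:
    prov = {"stage": stage, "seed": config.seed,
            "config_hash": config.config_hash(), "version": __version__}
    path = _outdir(config) / f"{stage}.provenance.json"
    path.write_text(json.dumps(prov, sort_keys=True, indent=1) + "\n")


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               index: bool = False, sep: str = ",") -> None:
    header = f"# seed={config.seed} config={config.config_hash()}\n"
    path.write_text(header + df.to_csv(index=index, sep=sep))


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def _stage_simulate(config: PipelineConfig) -> dict[str, Any]:
    spec = SyntheticStudySpec(seed=config.seed, **config.simulate)
    study = generate_study(spec)
    study.write(_outdir(config))
    return {"n_lines": spec.n_lines, "n_images": len(study.images)}


def _stage_segment(config: PipelineConfig) -> dict[str, Any]:
    outdir = _outdir(config)
    manifest = _read_csv(_require(config, "manifest.csv"))
    seg = GaborTextureSegmenter(**config.segmentation).fit()
    mask_dir = outdir / "masks"
    mask_dir.mkdir(exist_ok=True)
    rows = []
    for _, row in manifest.iterrows():
        img = tifffile.imread(outdir / row["image_path"]).astype(float) / 65535.0
        mask, regions = seg.segment_image(img)
        iio.imwrite(mask_dir / f"{row['colony_id']}.png",
                    mask.astype(np.uint8) * 255)
        for i, r in enumerate(regions):
            rows.append({"colony_id": row["colony_id"], "line_id": row["line_id"],
                         "region": i, "label": r.label_id, "area": r.area_px,
                         "min_row": r.bbox[0], "min_col": r.bbox[1],
                         "max_row": r.bbox[2], "max_col": r.bbox[3],
                         "touches_border": r.touches_border})
    _write_csv(pd.DataFrame(rows), outdir / "regions.csv", config)
    return {"n_regions": len(rows)}


def _stage_profile(config: PipelineConfig) -> dict[str, Any]:
    outdir = _outdir(config)
    manifest = _read_csv(_require(config, "manifest.csv"))
    _require(config, "regions.csv")
    seg = GaborTextureSegmenter(**config.segmentation)  # for min_area only
    fingerprinter = ZernikeFingerprinter(**config.morphometry).fit()
    from .segmentation import extract_colonies

    batches = []
    for _, row in manifest.iterrows():
        img = tifffile.imread(outdir / row["image_path"]).astype(float) / 65535.0
        mask = iio.imread(outdir / "masks" / f"{row['colony_id']}.png") > 0
        regions = extract_colonies(mask, min_area=seg.min_area)
        batches.append((row["line_id"], img, regions))
    table = fingerprinter.transform(batches)
    _write_csv(table, outdir / "fingerprints.csv", config)
    return {"n_fingerprints": len(table)}


def _stage_cluster(config: PipelineConfig) -> dict[str, Any]:
    outdir = _outdir(config)
    fp = _read_csv(_require(config, "fingerprints.csv"))
    feat_cols = [c for c in fp.columns
                 if c == "size" or c.startswith("z_")]
    model = ConsensusKSClustering(random_state=config.seed, **config.consensus)
    model.fit(fp[feat_cols].to_numpy(), groups=fp["line_id"].to_numpy())
    for k, cm in model.consensus_matrices_.items():
        _write_csv(cm.to_frame().reset_index(names="line_id"),
                   outdir / f"consensus_k{k}.csv", config)
    _write_csv(model.cdf_.table, outdir / "cdf_delta.csv", config)
    if model.partition_ is None:
        raise PipelineError("no cluster structure detected; cannot write partition")
    part = model.partition_.to_frame()
    _write_csv(part, outdir / "partition.csv", config)
    return {"k_star": model.n_clusters_,
            "cluster_sizes": part["cluster"].value_counts().to_dict()}


def _stage_associate(config: PipelineConfig) -> dict[str, Any]:
    outdir = _outdir(config)
    expr = _read_csv(_require(config, "expression.tsv"), sep="\t", index_col=0)
    part = _read_csv(_require(config, "partition.csv"))
    fp = _read_csv(_require(config, "fingerprints.csv"))
    labels = dict(zip(part["line_id"], part["cluster"]))
    assoc_cfg = dict(config.association)
    M = int(assoc_cfg.get("n_permutations", 10_000))
    de_fdr = float(assoc_cfg.get("de_fdr", 0.001))
    feature_agg = assoc_cfg.get("feature_aggregate", "median")

    info: dict[str, Any] = {}
    sizes = part["cluster"].value_counts()
    for cluster in sorted(part["cluster"].unique()):
        if sizes[cluster] < 2 or (sizes.sum() - sizes[cluster]) < 2:
            logger.warning("skipping differential test for cluster %s: needs >= 2 "
                           "lines on each side", cluster)
            info[f"n_de_cluster{cluster}"] = None
            continue
        table = moderated_t_one_vs_rest(expr, labels, cluster)
        _write_csv(table.reset_index(), outdir / f"moderated_t_cluster{cluster}.csv",
                   config)
        info[f"n_de_cluster{cluster}"] = int((table["fdr"] < de_fdr).sum())

    agg = fp.groupby("line_id")["size"].median() if feature_agg == "median" \
        else fp.groupby("line_id")["size"].mean()
    missing = set(expr.columns) - set(agg.index)
    if missing:
        raise PipelineError(f"no fingerprints for lines: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    for link in ("linear", "logistic"):
        table = permutation_screen(expr, agg, link=link, M=M, seed=rng)
        _write_csv(table.reset_index(), outdir / f"association_size_{link}.csv",
                   config)
        info[f"n_assoc_{link}"] = int((table["fdr"] < 0.05).sum())
    return info


def _stage_report(config: PipelineConfig) -> dict[str, Any]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = _outdir(config)
    cdf = _read_csv(_require(config, "cdf_delta.csv"))
    part = _read_csv(_require(config, "partition.csv"))
    figures = []
    for k in cdf["k"]:
        path = outdir / f"consensus_k{int(k)}.csv"
        if not path.exists():
            continue
        cm = _read_csv(path).set_index("line_id")
        order = part.sort_values("cluster")["line_id"]
        m = cm.loc[order, order].to_numpy()
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(m, vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"consensus, k={int(k)}")
        ax.set_xticks([]); ax.set_yticks([])
        fig.savefig(outdir / f"consensus_k{int(k)}.png", dpi=120)
        plt.close(fig)
        figures.append(f"consensus_k{int(k)}.png")
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    axes[0].plot(cdf["k"], cdf["area"], "o-")
    axes[0].set_xlabel("k"); axes[0].set_ylabel("area under consensus CDF")
    axes[1].plot(cdf["k"], cdf["delta"], "o-")
    axes[1].set_xlabel("k"); axes[1].set_ylabel("proportional increase")
    fig.tight_layout()
    fig.savefig(outdir / "cdf_delta.png", dpi=120)
    plt.close(fig)
    figures.append("cdf_delta.png")
    return {"figures": figures}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "profile": _stage_profile,
    "cluster": _stage_cluster,
    "associate": _stage_associate,
    "report": _stage_report,
}


def run_stage(stage_name: str, config: PipelineConfig) -> dict[str, Any]:
    """Run one pipeline stage; returns a small info dict for logging."""
    if stage_name not in _STAGE_FN:
        raise PipelineError(f"unknown stage {stage_name!r}; expected one of {STAGES}")
    logger.info("running stage %s", stage_name)
    info = _STAGE_FN[stage_name](config)
    _write_provenance(config, stage_name)
    logger.info("stage %s done: %s", stage_name, info)
    return info


def run_all(config: PipelineConfig) -> dict[str, Any]:
    out = {}
    for stage in STAGES:
        out[stage] = run_stage(stage, config)
    return out


# ---------------------------------------------------------------------------
# In-memory end-to-end run (no file I/O) used by tests and the acceptance
# script: simulate, segment, profile, cluster and associate on one study.
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Outputs of one in-memory end-to-end synthetic-study run."""

    study: Any
    fingerprints: pd.DataFrame
    model: ConsensusKSClustering
    k_star: int | None
    ari: float
    mean_iou: float
    de_table: pd.DataFrame | None
    assoc_linear: pd.DataFrame | None
    assoc_logistic: pd.DataFrame | None


def run_synthetic_study(
    seed: int,
    spec_overrides: Mapping[str, Any] | None = None,
    n_permutations: int = 10_000,
    associate: bool = True,
) -> StudyResult:
    """Simulate a study and run the full analysis chain in memory."""
    from sklearn.metrics import adjusted_rand_score

    spec = SyntheticStudySpec(seed=seed, **dict(spec_overrides or {}))
    study = generate_study(spec)
    seg = GaborTextureSegmenter().fit()
    fingerprinter = ZernikeFingerprinter().fit()

    batches = []
    ious = []
    for _, row in study.manifest.iterrows():
        cid = row["colony_id"]
        img = study.images[cid]
        truth = study.masks[cid]
        mask, regions = seg.segment_image(img)
        inter = (mask & truth).sum()
        union = (mask | truth).sum()
        ious.append(inter / union if union else 0.0)
        batches.append((row["line_id"], img, regions))
    fp = fingerprinter.transform(batches)

    feat_cols = [c for c in fp.columns if c == "size" or c.startswith("z_")]
    model = ConsensusKSClustering(random_state=seed)
    model.fit(fp[feat_cols].to_numpy(), groups=fp["line_id"].to_numpy())

    truth_arch = study.archetype_labels()
    ari = float("nan")
    if model.n_clusters_ is not None:
        pred = [model.partition_.labels[ln] for ln in model.line_ids_]
        true = [truth_arch[ln] for ln in model.line_ids_]
        ari = float(adjusted_rand_score(true, pred))

    de_table = assoc_lin = assoc_log = None
    if associate and model.n_clusters_ is not None:
        labels = model.partition_.labels
        arch_of_cluster = pd.Series(
            [truth_arch[ln] for ln in labels], index=list(labels)
        ).groupby(pd.Series(labels)).agg(lambda s: s.mode().iloc[0])
        target = next((c for c, a in arch_of_cluster.items()
                       if a == spec.de_archetype), 0)
        de_table = moderated_t_one_vs_rest(study.expression, labels, target)
        agg = fp.groupby("line_id")["size"].median()
        rng = np.random.default_rng(seed)
        assoc_lin = permutation_screen(study.expression, agg, link="linear",
                                       M=n_permutations, seed=rng)
        assoc_log = permutation_screen(study.expression, agg, link="logistic",
                                       M=n_permutations, seed=rng)
    return StudyResult(study=study, fingerprints=fp, model=model,
                       k_star=model.n_clusters_, ari=ari,
                       mean_iou=float(np.mean(ious)), de_table=de_table,
                       assoc_linear=assoc_lin, assoc_logistic=assoc_log)
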