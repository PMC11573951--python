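"""End-to-end reproducible pipeline.

``run_pipeline`` chains simulate -> preprocess -> (grading benchmark |
PCL -> patch graph -> TME assignment -> differential analysis -> UMAP)
per config, writing every stage artifact plus a manifest with seeds and
content hashes so a rerun with the same config is bit-checkable for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import bioinsights, grading, pcl, preprocessing, synthetic, tissue_graph, tme

__all__ = ["validate_config", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": None,  # mandatory, no default
    "cohort": {"n_per_grade": 4, "image_size": 128, "separation": 1.0},
    "grading": {
        "enabled": True,
        "architecture": "resnet18",
        "pretrained": True,
        "colorspace": "hsv",
        "k_folds": 5,
        "epochs": 10,
        "lr": 1e-3,
    },
    "pcl": {"patch_size": 16, "stride": 16, "epochs": 2, "temperature": 0.5},
    "tme": {"P": 8, "N": 8, "A": 7, "knn": 8, "hops": 1, "hops_area": 3},
    "umap": {"enabled": False, "n_neighbors": 10, "min_dist": 0.1},
}

_SCHEMA_KEYS = {k: set(v) if isinstance(v, dict) else None for k, v in DEFAULT_CONFIG.items()}


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Merge with defaults and validate; the seed is mandatory."""
    if "seed" not in config or config["seed"] is None:
        raise ValueError("config error at 'seed': a seed is mandatory")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if key not in _SCHEMA_KEYS:
            raise ValueError(f"config error at '{key}': unknown section")
        if isinstance(value, dict):
            unknown = set(value) - _SCHEMA_KEYS[key]
            if unknown:
                raise ValueError(
                    f"config error at '{key}.{sorted(unknown)[0]}': unknown field"
                )
            merged[key].update(value)
        else:
            merged[key] = value
    merged["seed"] = int(config["seed"])
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run every enabled stage; returns the manifest written to disk."""
    cfg = validate_config(config)
    seed = cfg["seed"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- simulate --------------------------------------------------------
    cohort_cfg = synthetic.small_test_config(
        n_per_grade=cfg["cohort"]["n_per_grade"],
        image_size=cfg["cohort"]["image_size"],
        separation=cfg["cohort"]["separation"],
    )
    cohort = synthetic.generate_cohort(cohort_cfg, seed=seed, out_dir=out / "cohort")
    labels = dict(zip(cohort.image_ids, cohort.labels))

    # -- preprocess ------------------------------------------------------
    k = cfg["grading"]["k_folds"]
    folds = preprocessing.stratified_kfold(pd.Series(labels), k=k, seed=seed)
    preprocessing.fold_manifest(folds).to_csv(out / "folds.csv", index=False)

    # -- supervised grading ---------------------------------------------
    if cfg["grading"]["enabled"]:
        spec = grading.ModelSpec(
            cfg["grading"]["architecture"],
            pretrained=cfg["grading"]["pretrained"],
            colorspace=cfg["grading"]["colorspace"],
        )
        images = dict(zip(cohort.image_ids, cohort.images))
        metrics = grading.train_eval(
            spec,
            images,
            labels,
            folds,
            epochs=cfg["grading"]["epochs"],
            lr=cfg["grading"]["lr"],
            seed=seed,
        )
        metrics.per_fold.to_csv(out / "grading_metrics.csv")

    # -- PCL -> graph -> TME --------------------------------------------
    pcl_cfg = pcl.PCLConfig(
        patch_size=cfg["pcl"]["patch_size"],
        temperature=cfg["pcl"]["temperature"],
        epochs=cfg["pcl"]["epochs"],
        seed=seed,
    )
    patches: list[pcl.Patch] = []
    for img, truth, iid in zip(cohort.images, cohort.truths, cohort.image_ids):
        patches.extend(
            pcl.tile_image(
                img, truth.tissue_mask, pcl_cfg.patch_size, cfg["pcl"]["stride"], iid
            )
        )
    encoder = pcl.train_encoder(patches, pcl_cfg)
    embeddings = pcl.embed(encoder, patches)
    embeddings.coords.to_csv(out / "patch_coords.csv", index=False)
    np.save(out / "embeddings.npy", embeddings.embeddings)

    graph = tissue_graph.build_graph(embeddings, knn=cfg["tme"]["knn"])
    nx_edges = pd.DataFrame(
        [(u, v, d["distance"]) for u, v, d in graph.edges(data=True)],
        columns=["src", "dst", "distance"],
    )
    nx_edges.to_csv(out / "graph_edges.csv", index=False)

    assignment = tme.assign_all(
        embeddings,
        graph,
        P=cfg["tme"]["P"],
        N=cfg["tme"]["N"],
        A=cfg["tme"]["A"],
        hops=cfg["tme"]["hops"],
        hops_area=cfg["tme"]["hops_area"],
        seed=seed,
    )
    assignment.frame().to_csv(out / "tme_assignments.csv", index=False)
    abundance = tme.abundance_matrix(assignment, labels)
    abundance.to_csv(out / "abundance.csv")

    binary = tme.evaluate_binary_pairs(abundance, seed=seed)
    binary.to_csv(out / "binary_eval.csv")

    # -- differential analysis ------------------------------------------
    diff = bioinsights.differential_all_pairs(abundance)
    rows = [
        {
            "pair": f"{lo},{hi}",
            "element": r.element,
            "p_value": r.p_value,
            "direction": r.direction,
            "stars": r.stars,
        }
        for (lo, hi), res in diff.items()
        for r in res
    ]
    pd.DataFrame(rows).to_csv(out / "differential.csv", index=False)
    scg = bioinsights.shared_cluster_graph(diff)
    pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in scg.edges(data=True)],
        columns=["grade_a", "grade_b", "weight"],
    ).to_csv(out / "shared_clusters.csv", index=False)

    # -- UMAP (optional; slow at scale) ----------------------------------
    if cfg["umap"]["enabled"]:
        from . import viz

        coords2d = viz.umap_embed(
            abundance.drop(columns="grade").to_numpy(),
            n_neighbors=cfg["umap"]["n_neighbors"],
            min_dist=cfg["umap"]["min_dist"],
            seed=seed,
        )
        pd.DataFrame(coords2d, index=abundance.index, columns=["u1", "u2"]).to_csv(
            out / "umap.csv"
        )

    manifest = {
        "seed": seed,
        "config": cfg,
        "artifacts": {
            p.relative_to(out).as_posix(): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
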