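"""End-to-end pipeline orchestration from a single YAML config.

Stages run in a fixed order (windows -> count -> correct -> matrix -> impute
-> train -> evaluate -> rank -> annotate -> enrich); stages whose inputs are
supplied precomputed (or not configured) are recorded as skipped.  A run
manifest traces every stage output to a content digest, and one master seed
derives all stage seeds.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import os
from dataclasses import replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covmatrix import (
    BiasCorrectionConfig,
    CoverageMatrix,
    CoverageProfile,
    assemble_matrix,
    correct_bias,
    normalize_rows,
    prune_windows,
    sample_qc,
)
from .impute import flag_missing, impute_lowrank
from .model import ModelConfig, attention_weights, predict, split_dataset, train
from .evaluate import bootstrap_auc, evaluate_predictions
from .regions import annotate_genes, ora_enrich, rank_windows, read_gene_bed, read_gmt
from .simulate import SimConfig, simulate_cohort
from .windows import (
    ChromSizes,
    load_chrom_sizes,
    make_windows,
    mask_windows,
    read_bed3,
    read_bedgraph,
    window_track_values,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "windows", "count", "correct", "matrix", "impute",
    "train", "evaluate", "rank", "annotate", "enrich",
)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def validate_config(config: dict) -> None:
    """Schema check: required keys present, no unknown top-level sections."""
    allowed = {"seed", "outdir", "simulate", "inputs", *STAGE_ORDER}
    unknown = set(config) - allowed
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    if "seed" not in config:
        raise ValueError("config missing required field: seed")
    if "outdir" not in config:
        raise ValueError("config missing required field: outdir")
    has_sim = "simulate" in config
    inputs = config.get("inputs", {})
    if not has_sim:
        if "counts" not in inputs:
            raise ValueError("config missing required field: inputs.counts "
                             "(or a simulate section)")
        if "labels" not in inputs:
            raise ValueError("config missing required field: inputs.labels")


def run_pipeline(config_path) -> dict:
    """Execute the configured pipeline; returns the run manifest dict."""
    with open(config_path) as fh:
        raw = fh.read()
    config = yaml.safe_load(raw)
    validate_config(config)
    master_seed = int(config["seed"])
    outdir = config["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seed_children = np.random.SeedSequence(master_seed).spawn(len(STAGE_ORDER) + 1)
    stage_seed = {
        name: int(child.generate_state(1)[0] % (2 ** 31))
        for name, child in zip(("simulate", *STAGE_ORDER), seed_children)
    }

    manifest: dict = {
        "tool_version": __version__,
        "config_sha256": hashlib.sha256(raw.encode()).hexdigest(),
        "master_seed": master_seed,
        "started": _now(),
        "stages": [],
    }

    def record(name, status, outputs=(), **extra):
        manifest["stages"].append(
            {
                "stage": name,
                "status": status,
                "outputs": {str(p): _sha256(p) for p in outputs},
                "timestamp": _now(),
                **extra,
            }
        )

    # ---------------------------------------------------------------- inputs
    ws = None
    counts = None          # samples x all-windows DataFrame
    labels_df = None
    if "simulate" in config:
        sim_cfg = SimConfig(**{**config["simulate"], "seed": stage_seed["simulate"]})
        cohort = simulate_cohort(sim_cfg)
        cohort_dir = os.path.join(outdir, "cohort")
        cohort.write(cohort_dir)
        record("simulate(pre)", "run",
               [os.path.join(cohort_dir, f) for f in
                ("windows.tsv", "labels.tsv", "counts.tsv", "truth.bed")])
        ws = cohort.window_set
        counts = pd.DataFrame(cohort.counts, index=cohort.sample_ids)
        labels_df = pd.DataFrame(
            {"sample_id": cohort.sample_ids, "label": cohort.labels}
        )
    inputs = config.get("inputs", {})

    # ---------------------------------------------------------------- windows
    if ws is not None:
        record("windows", "skipped", reason="window set supplied by simulation")
    elif "windows" in config:
        wcfg = config["windows"]
        try:
            chrom_sizes = load_chrom_sizes(wcfg["chrom_sizes"])
            ws = make_windows(chrom_sizes, int(wcfg.get("size", 10000)))
            if wcfg.get("exclude"):
                ws = mask_windows(
                    ws, read_bed3(wcfg["exclude"]),
                    float(wcfg.get("min_overlap_fraction", 0.5)),
                )
            if wcfg.get("gc"):
                window_track_values(ws, read_bedgraph(wcfg["gc"]), name="gc")
            if wcfg.get("map"):
                window_track_values(ws, read_bedgraph(wcfg["map"]), name="mappability")
        except Exception as exc:
            raise PipelineError("windows", str(exc)) from exc
        path = os.path.join(outdir, "windows.tsv")
        ws.to_tsv(path)
        record("windows", "run", [path])
    else:
        raise PipelineError("windows", "no window set: supply a windows section "
                            "or a simulate section")

    # ------------------------------------------------------------------ count
    if counts is None and "counts" in inputs:
        counts = pd.read_csv(inputs["counts"], sep="\t", index_col=0)
        labels_df = pd.read_csv(inputs["labels"], sep="\t")
        record("count", "skipped", reason="precomputed counts supplied")
    elif counts is not None:
        record("count", "skipped", reason="counts supplied by simulation")
    else:
        raise PipelineError("count", "missing stage input: counts")
    labels = dict(zip(labels_df["sample_id"].astype(str), labels_df["label"]))

    unmasked = ws.unmasked_indices
    count_values = counts.to_numpy(dtype=float)[:, unmasked]
    genome_len = float(ws.lengths[unmasked].sum())
    qc_cfg = config.get("matrix", {}).get("qc", {})
    profiles = []
    for i, sid in enumerate(counts.index.astype(str)):
        p = CoverageProfile(
            sample_id=sid,
            values=count_values[i],
            window_indices=unmasked,
            mean_depth=float(count_values[i].sum() / genome_len),
        )
        profiles.append(p)

    # ---------------------------------------------------------------- correct
    ccfg = config.get("correct", {})
    if ccfg.get("enabled", True) and ws.gc is not None and ws.mappability is not None:
        bias_cfg = BiasCorrectionConfig(
            **{k: v for k, v in ccfg.items() if k != "enabled"}
        )
        try:
            profiles = [
                correct_bias(p, ws.gc[unmasked], ws.mappability[unmasked], bias_cfg)
                for p in profiles
            ]
        except Exception as exc:
            raise PipelineError("correct", str(exc)) from exc
        record("correct", "run")
    else:
        record("correct", "skipped",
               reason="disabled or no gc/mappability tracks")

    # ----------------------------------------------------------------- matrix
    mcfg = config.get("matrix", {})
    try:
        for p in profiles:
            sample_qc(
                p,
                min_mean_depth=float(qc_cfg.get("min_mean_depth", 0.15)),
                min_reads=qc_cfg.get("min_reads"),
            )
        matrix = assemble_matrix(profiles, labels)
        matrix = normalize_rows(matrix)
        pruned, report = prune_windows(
            matrix,
            dropout_frac=float(mcfg.get("dropout_frac", 0.8)),
            dropout_value=float(mcfg.get("dropout_value", 0.1)),
            mean_diff=float(mcfg.get("mean_diff", 0.01)),
        )
    except Exception as exc:
        raise PipelineError("matrix", str(exc)) from exc
    mpath = os.path.join(outdir, "matrix.tsv")
    pruned.to_tsv(mpath)
    with open(os.path.join(outdir, "pruning.json"), "w") as fh:
        json.dump(report.to_dict(), fh)
    record("matrix", "run", [mpath, f"{mpath}.json",
                             os.path.join(outdir, "pruning.json")])

    # ----------------------------------------------------------------- impute
    icfg = config.get("impute", {})
    try:
        mask = flag_missing(pruned, epsilon=float(icfg.get("epsilon", 0.01)))
        imputed, factor = impute_lowrank(
            pruned, mask,
            rank=int(icfg.get("rank", 10)),
            regularization=float(icfg.get("regularization", 0.1)),
            learning_rate=float(icfg.get("learning_rate", 0.05)),
            epochs=int(icfg.get("epochs", 2000)),
            seed=stage_seed["impute"],
        )
    except Exception as exc:
        raise PipelineError("impute", str(exc)) from exc
    ipath = os.path.join(outdir, "imputed.tsv")
    imputed.to_tsv(ipath)
    record("impute", "run", [ipath, f"{ipath}.json"],
           n_missing=mask.n_missing)

    # ------------------------------------------------------------------ train
    tcfg = dict(config.get("train", {}))
    try:
        cfg = ModelConfig(**{**tcfg, "seed": stage_seed["train"]})
        split = split_dataset(imputed.n_samples, seed=stage_seed["train"])
        X = imputed.values
        y = imputed.labels
        tm = train(X[split.train_idx], y[split.train_idx],
                   X[split.val_idx], y[split.val_idx], cfg=cfg)
    except Exception as exc:
        raise PipelineError("train", str(exc)) from exc
    model_dir = os.path.join(outdir, "model")
    tm.save(model_dir)
    record("train", "run",
           [os.path.join(model_dir, f) for f in
            ("config.json", "history.tsv", "params.npz")],
           split_sizes=list(split.sizes))

    # --------------------------------------------------------------- evaluate
    ecfg = config.get("evaluate", {})
    try:
        p_test = predict(tm, X[split.test_idx])
        report_eval = evaluate_predictions(y[split.test_idx], p_test,
                                           threshold=cfg.threshold)
        result = report_eval.to_dict()
        n_boot = int(ecfg.get("bootstrap", 0))
        if n_boot:
            boot = bootstrap_auc(y[split.test_idx], p_test, n_reps=n_boot,
                                 seed=stage_seed["evaluate"])
            result["bootstrap"] = {
                "n_reps": boot.n_reps, "mean_auc": boot.mean_auc,
                "ci95": list(boot.ci95),
            }
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc
    epath = os.path.join(outdir, "evaluation.json")
    with open(epath, "w") as fh:
        json.dump(result, fh, indent=2)
    roc_path = os.path.join(outdir, "roc.tsv")
    pd.DataFrame({"fpr": report_eval.roc.fpr, "tpr": report_eval.roc.tpr}).to_csv(
        roc_path, sep="\t", index=False
    )
    record("evaluate", "run", [epath, roc_path])

    # ------------------------------------------------------------------- rank
    rcfg = config.get("rank", {})
    try:
        weights = attention_weights(tm, X[split.train_idx])
        ranked = rank_windows(
            weights, ws, top_k=int(rcfg.get("top_k", 5000)),
            window_indices=imputed.window_indices,
        )
    except Exception as exc:
        raise PipelineError("rank", str(exc)) from exc
    rpath = os.path.join(outdir, "top_windows.bed")
    ranked.to_bed(rpath)
    wpath = os.path.join(outdir, "attention_weights.tsv")
    pd.DataFrame(
        {"window_index": imputed.window_indices, "weight": weights}
    ).to_csv(wpath, sep="\t", index=False)
    record("rank", "run", [rpath, wpath])

    # --------------------------------------------------------------- annotate
    acfg = config.get("annotate", {})
    genes_selected = None
    if acfg.get("genes"):
        try:
            gene_intervals = read_gene_bed(acfg["genes"])
            genes_selected = annotate_genes(ranked, gene_intervals)
        except Exception as exc:
            raise PipelineError("annotate", str(exc)) from exc
        gpath = os.path.join(outdir, "genes.txt")
        with open(gpath, "w") as fh:
            fh.write("\n".join(genes_selected) + "\n")
        record("annotate", "run", [gpath])
    else:
        record("annotate", "skipped", reason="no gene intervals configured")

    # ----------------------------------------------------------------- enrich
    encfg = config.get("enrich", {})
    if encfg.get("gmt") and genes_selected:
        try:
            gene_sets = read_gmt(encfg["gmt"])
            if encfg.get("universe"):
                with open(encfg["universe"]) as fh:
                    universe = [l.strip() for l in fh if l.strip()]
            else:
                # default universe: all genes overlapping any window
                gene_intervals = read_gene_bed(acfg["genes"])
                all_ranked = rank_windows(
                    np.ones(len(imputed.window_indices)), ws,
                    top_k=len(imputed.window_indices),
                    window_indices=imputed.window_indices,
                )
                universe = annotate_genes(all_ranked, gene_intervals)
            enrichment = ora_enrich(genes_selected, gene_sets, universe)
        except Exception as exc:
            raise PipelineError("enrich", str(exc)) from exc
        enpath = os.path.join(outdir, "enrichment.tsv")
        enrichment.table.to_csv(enpath, sep="\t", index=False)
        record("enrich", "run", [enpath])
    else:
        record("enrich", "skipped", reason="no gene sets configured")

    manifest["finished"] = _now()
    mpath = os.path.join(outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
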