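"""Orchestration of the two-step workflow over plain-text artifacts.

Each step reads the previous step's files through the public readers in
:mod:`dyngrn.io`, so a run on disk exercises the same interfaces as a run
from Python.  Every step appends a log record (parameters, seeds, package
version) and updates a manifest of outputs; re-running a step with the same
config and seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import bootstrap_segment_pvalues, bootstrap_table
from .config import PipelineConfig
from .dbn import (GeneBinding, TimeVaryingDbn, assemble_networks,
                  build_binding_matrix, common_links, segment_cis_region,
                  select_hyperparameters, variance_explained)
from .features import (FEATURE_NAMES, FeatureTable, GenomeContext,
                       assemble_design_matrix, default_de_calls,
                       standardize_features)
from .io import (AnnotationTracks, asinh_transform, assign_cis_regions,
                 read_conservation_track, read_expression_table, read_fasta,
                 read_gene_annotation, read_intervals, read_peaks,
                 read_perturbation_edges, read_signal_track,
                 write_conservation_track, write_expression_table, write_fasta,
                 write_gene_annotation, write_intervals,
                 write_perturbation_edges, write_signal_track)
from .logit import (BindingSiteLogit, LrScoreTrack, fit_logistic, load_model,
                    lotfocv, predict_lr_track, save_model, wald_tests)
from .perturb import computational_perturbation, direction_agreement_test
from .pwm import (label_hits_with_peaks, read_hits, read_pwm_set,
                  resolve_overlapping_hits, scan_sequence, write_hits,
                  write_pwm_set)
from .synthetic import make_dbn_dataset

MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3", "RNAP")


class MissingArtifactError(FileNotFoundError):
    """A required upstream artifact is absent; names the producing step."""


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; run the '{produced_by}' step first"
        )
    return path


def _log_step(cfg: PipelineConfig, step: str, outputs: List[str]) -> None:
    outdir = Path(cfg.outdir)
    log_path = outdir / "run_log.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else []
    log.append({
        "step": step,
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "outputs": outputs,
        "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
    })
    log_path.write_text(json.dumps(log, indent=1))
    manifest_path = outdir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest[step] = outputs
    manifest_path.write_text(json.dumps(manifest, indent=1))


# ---------------------------------------------------------------------------
# steps
# ---------------------------------------------------------------------------

def step_simulate(cfg: PipelineConfig) -> List[str]:
    """Generate the toy dataset and write every input the pipeline reads."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = make_dbn_dataset(
        seed=cfg.seed, n_genes=cfg.n_genes, n_tf=cfg.n_tf,
        region_len=cfg.region_len, sigma=cfg.sigma, T=len(cfg.stages),
        segment_width=cfg.segment_width, segment_step=cfg.segment_step,
    )
    # the generator labels stages S0..; rename to the configured labels
    relabel = dict(zip(ds.stages, cfg.stages))
    write_fasta(ds.seqs, outdir / "genome.fa")
    write_gene_annotation(ds.genes, outdir / "genes.bed", fmt="bed12")
    write_pwm_set(ds.pwms, outdir / "pwms.pfm")
    for tf, pk in ds.peaks.items():
        write_intervals(pk.intervals, outdir / f"peaks_{tf}.bed")
    write_conservation_track(ds.annot.phastcons_vert, outdir / "cons_vert.bedgraph")
    write_conservation_track(ds.annot.phastcons_plac, outdir / "cons_plac.bedgraph")
    write_intervals(ds.annot.cpg_islands, outdir / "cpg.bed")
    write_intervals(ds.annot.repeats, outdir / "repeats.bed")
    for (mark, stage), track in ds.tracks.items():
        write_signal_track(track, outdir / f"track_{mark}_{relabel[stage]}.bedgraph")
    expr = ds.expr.fpkm.copy()
    expr.columns = [relabel[s] for s in expr.columns]
    write_expression_table(type(ds.expr)(expr), outdir / "expression.tsv")
    write_perturbation_edges(ds.truth.P, outdir / "perturbation_edges.tsv")
    pd.DataFrame(ds.truth.edges, columns=["target", "regulator", "weight"]).to_csv(
        outdir / "truth_edges.tsv", sep="\t", index=False
    )
    ds.truth.calls.to_csv(outdir / "truth_calls.tsv", sep="\t", index_label="gene_id")
    lr_rows = []
    for gid, tracks in ds.truth.lr_tracks.items():
        region = ds.cis_regions[gid]
        for t, lr in enumerate(tracks):
            lr_rows.append(pd.DataFrame({
                "gene_id": gid, "transition": t,
                "pos": np.arange(region.start, region.end), "score": lr,
            }))
    pd.concat(lr_rows, ignore_index=True).to_csv(
        outdir / "truth_lr_tracks.tsv", sep="\t", index=False
    )
    meta = {
        "stages": cfg.stages,
        "tf_panel": ds.tf_ids,
        "chrom_sizes": ds.chrom_sizes,
        "cis_width": cfg.region_len,
    }
    (outdir / "dataset.json").write_text(json.dumps(meta, indent=1))
    outputs = sorted(p.name for p in outdir.iterdir() if p.is_file())
    _log_step(cfg, "simulate", outputs)
    return outputs


def load_context(cfg: PipelineConfig) -> GenomeContext:
    """Rebuild the feature-computation context from on-disk artifacts."""
    outdir = Path(cfg.outdir)
    meta = json.loads(_require(outdir / "dataset.json", "simulate").read_text())
    seqs = read_fasta(_require(cfg.artifact("genome.fa"), "simulate"))
    chrom_sizes = {c: len(s) for c, s in seqs.items()}
    genes = read_gene_annotation(cfg.artifact("genes.bed"), fmt="bed12")
    cis = {
        r.gene_id: r
        for r in assign_cis_regions(genes, meta["cis_width"], chrom_sizes)
    }
    annot = AnnotationTracks(
        phastcons_vert=read_conservation_track(cfg.artifact("cons_vert.bedgraph"),
                                               chrom_sizes),
        phastcons_plac=read_conservation_track(cfg.artifact("cons_plac.bedgraph"),
                                               chrom_sizes),
        cpg_islands=read_intervals(cfg.artifact("cpg.bed")),
        repeats=read_intervals(cfg.artifact("repeats.bed")),
    )
    tracks = {}
    for mark in MARKS:
        for stage in meta["stages"]:
            path = _require(cfg.artifact(f"track_{mark}_{stage}.bedgraph"), "simulate")
            tracks[(mark, stage)] = asinh_transform(
                read_signal_track(path, mark, stage, bin_size=10,
                                  chrom_sizes=chrom_sizes)
            )
    expr = read_expression_table(cfg.artifact("expression.tsv"),
                                 fpkm_min=cfg.gene_fpkm_min)
    return GenomeContext(
        seqs=seqs, genes=genes, cis_regions=cis, annot=annot, tracks=tracks,
        expr=expr, stages=meta["stages"], de_calls=default_de_calls(expr),
    )


def step_scan(cfg: PipelineConfig) -> List[str]:
    """Scan every cis-region with every PWM on both strands."""
    outdir = Path(cfg.outdir)
    seqs = read_fasta(_require(cfg.artifact("genome.fa"), "simulate"))
    chrom_sizes = {c: len(s) for c, s in seqs.items()}
    meta = json.loads(_require(outdir / "dataset.json", "simulate").read_text())
    genes = read_gene_annotation(cfg.artifact("genes.bed"), fmt="bed12")
    cis = assign_cis_regions(genes, meta["cis_width"], chrom_sizes)
    pwms = read_pwm_set(_require(cfg.artifact("pwms.pfm"), "simulate"))
    hits = []
    for region in cis:
        seq = seqs[region.chrom][region.start:region.end]
        for pwm in pwms:
            hits += scan_sequence(pwm, seq, cfg.scan_threshold,
                                  offset=region.start, gene_id=region.gene_id,
                                  chrom=region.chrom)
    hits = resolve_overlapping_hits(hits)
    write_hits(hits, bed_path=outdir / "hits.bed", tsv_path=outdir / "hits.tsv")
    _log_step(cfg, "scan", ["hits.bed", "hits.tsv"])
    return ["hits.bed", "hits.tsv"]


def step_features(cfg: PipelineConfig) -> List[str]:
    """Label hits with peaks and assemble the 69-feature design matrix."""
    outdir = Path(cfg.outdir)
    ctx = load_context(cfg)
    hits = read_hits(_require(outdir / "hits.tsv", "scan"))
    meta = json.loads((outdir / "dataset.json").read_text())
    labeled = []
    for tf in meta["tf_panel"]:
        tf_hits = [h for h in hits if h.tf == tf]
        peak_path = cfg.artifact(f"peaks_{tf}.bed")
        peaks = read_peaks(peak_path, tf) if peak_path.exists() else None
        if peaks is None:
            from .io import PeakSet
            peaks = PeakSet(tf, "synthetic", {})
        labeled += label_hits_with_peaks(tf_hits, peaks)
    stage_map = {tf: 0 for tf in meta["tf_panel"]}
    table = assemble_design_matrix(ctx, labeled, stage_map)
    table.to_tsv(outdir / "features.tsv")
    _log_step(cfg, "features", ["features.tsv"])
    return ["features.tsv"]


def step_train_lr(cfg: PipelineConfig) -> List[str]:
    """Standardize, fit the pooled logistic model and evaluate it."""
    outdir = Path(cfg.outdir)
    table = FeatureTable.from_tsv(_require(outdir / "features.tsv", "features"))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = standardize_features(table)
        model = fit_logistic(std)
        auc = lotfocv(table)
    save_model(model, std.scaler, outdir / "model.json")
    auc.to_csv(outdir / "lotfocv_auc.tsv", sep="\t")
    if model.converged_:
        wald_tests(model, FEATURE_NAMES).to_csv(outdir / "wald.tsv", sep="\t")
        outputs = ["model.json", "lotfocv_auc.tsv", "wald.tsv"]
    else:
        outputs = ["model.json", "lotfocv_auc.tsv"]
    _log_step(cfg, "train-lr", outputs)
    return outputs


def step_predict_lr(cfg: PipelineConfig) -> List[str]:
    """Score every base of every cis-region at every transition."""
    outdir = Path(cfg.outdir)
    model, scaler, _names = load_model(_require(outdir / "model.json", "train-lr"))
    ctx = load_context(cfg)
    rows = []
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gid in sorted(ctx.cis_regions):
            for t in range(ctx.n_transitions):
                trk = predict_lr_track(model, scaler, ctx, gid, t)
                rows.append(pd.DataFrame({
                    "gene_id": gid, "transition": t,
                    "pos": np.arange(trk.start, trk.end), "score": trk.scores,
                }))
    pd.concat(rows, ignore_index=True).to_csv(outdir / "lr_tracks.tsv",
                                              sep="\t", index=False)
    _log_step(cfg, "predict-lr", ["lr_tracks.tsv"])
    return ["lr_tracks.tsv"]


def _load_lr_tracks(cfg: PipelineConfig, ctx: GenomeContext,
                    filename: str) -> Dict[str, List[np.ndarray]]:
    outdir = Path(cfg.outdir)
    df = pd.read_csv(_require(outdir / filename, "predict-lr"), sep="\t")
    out: Dict[str, List[np.ndarray]] = {}
    for (gid, t), sub in df.groupby(["gene_id", "transition"]):
        out.setdefault(gid, [None] * ctx.n_transitions)
        out[gid][int(t)] = sub.sort_values("pos")["score"].to_numpy()
    return out


def _build_bindings(cfg: PipelineConfig, ctx: GenomeContext,
                    lr_map: Dict[str, List[np.ndarray]], hits, P, meta):
    binding: Dict[str, GeneBinding] = {}
    gene_data = {}
    X = ctx.expr.X
    for gid, region in sorted(ctx.cis_regions.items()):
        if gid not in lr_map:
            continue
        seg = segment_cis_region(region, cfg.segment_width, cfg.segment_step)
        mats = []
        for t in range(ctx.n_transitions):
            trk = LrScoreTrack(gid, t, region.chrom, region.start,
                               lr_map[gid][t], region.owned)
            mats.append(build_binding_matrix(
                gid, t, trk, hits, P, ctx.expr, seg, meta["tf_panel"],
                ctx.stages, tf_fpkm_min=cfg.tf_fpkm_min,
                pi_default=cfg.pi_default,
            ))
        binding[gid] = GeneBinding(gid, seg, mats)
        B_list = [bm.B for bm in mats]
        X_cols = [X.loc[mats[t].tf_names, ctx.stages[t]].to_numpy()
                  for t in range(ctx.n_transitions)]
        gene_data[gid] = (X.loc[gid].to_numpy(), B_list, X_cols)
    return binding, gene_data


def step_infer_network(cfg: PipelineConfig) -> List[str]:
    """Build binding matrices from LR tracks and solve the network."""
    outdir = Path(cfg.outdir)
    ctx = load_context(cfg)
    meta = json.loads((outdir / "dataset.json").read_text())
    hits = read_hits(_require(outdir / "hits.tsv", "scan"))
    P = read_perturbation_edges(cfg.artifact("perturbation_edges.tsv"),
                                ctx.expr.genes)
    lr_map = _load_lr_tracks(cfg, ctx, "lr_tracks.tsv")
    binding, gene_data = _build_bindings(cfg, ctx, lr_map, hits, P, meta)
    if cfg.lambda1 is not None and cfg.lambda2 is not None:
        l1, l2 = cfg.lambda1, cfg.lambda2
        cv_table = pd.DataFrame()
    else:
        l1, l2, cv_table = select_hyperparameters(
            gene_data, cfg.lambda1_grid, cfg.lambda2_grid, loss=cfg.loss,
            seed=cfg.seed,
        )
    model = TimeVaryingDbn(lambda1=l1, lambda2=l2, loss=cfg.loss)
    model.fit(ctx.expr, binding)
    edges, tfbs = assemble_networks(model)
    edges.to_csv(outdir / "networks.tsv", sep="\t", index=False)
    tfbs.to_csv(outdir / "tfbs.tsv", sep="\t", index=False)
    ve = variance_explained(ctx.expr, model)
    (outdir / "variance_explained.json").write_text(
        json.dumps({k: float(v) for k, v in ve.items()}, indent=1)
    )
    common_links(model).to_csv(outdir / "common_links.tsv", sep="\t", index=False)
    (outdir / "selected_lambda.json").write_text(
        json.dumps({"lambda1": l1, "lambda2": l2}, indent=1)
    )
    if len(cv_table):
        cv_table.to_csv(outdir / "cv_table.tsv", sep="\t", index=False)
    outputs = ["networks.tsv", "tfbs.tsv", "variance_explained.json",
               "common_links.tsv", "selected_lambda.json"]
    _log_step(cfg, "infer-network", outputs)
    return outputs


def step_bootstrap(cfg: PipelineConfig) -> List[str]:
    """Bootstrap p-values for the first few genes' segment weights."""
    outdir = Path(cfg.outdir)
    ctx = load_context(cfg)
    meta = json.loads((outdir / "dataset.json").read_text())
    hits = read_hits(_require(outdir / "hits.tsv", "scan"))
    P = read_perturbation_edges(cfg.artifact("perturbation_edges.tsv"),
                                ctx.expr.genes)
    lam = json.loads(_require(outdir / "selected_lambda.json",
                              "infer-network").read_text())
    lr_map = _load_lr_tracks(cfg, ctx, "lr_tracks.tsv")
    binding, gene_data = _build_bindings(cfg, ctx, lr_map, hits, P, meta)
    tables = []
    for gid in sorted(binding)[: cfg.bootstrap_genes]:
        x_target, _B, X_cols = gene_data[gid]
        res = bootstrap_segment_pvalues(
            gid, lr_map[gid], binding[gid], x_target, X_cols,
            lam["lambda1"], lam["lambda2"], loss=cfg.loss,
            n_boot=cfg.bootstrap_n, seed=cfg.seed,
        )
        tables.append(bootstrap_table(res, binding[gid].segments))
    pd.concat(tables, ignore_index=True).to_csv(outdir / "bootstrap.tsv",
                                                sep="\t", index=False)
    _log_step(cfg, "bootstrap", ["bootstrap.tsv"])
    return ["bootstrap.tsv"]


def step_perturb(cfg: PipelineConfig) -> List[str]:
    """In-silico induction of one TF plus agreement with recorded calls."""
    outdir = Path(cfg.outdir)
    ctx = load_context(cfg)
    meta = json.loads((outdir / "dataset.json").read_text())
    edges = pd.read_csv(_require(outdir / "networks.tsv", "infer-network"), sep="\t")
    genes = ctx.expr.genes
    tf = cfg.perturb_tf or meta["tf_panel"][0]
    A0 = pd.DataFrame(0.0, index=genes, columns=genes)
    for _, row in edges.loc[edges["transition"] == 0].iterrows():
        A0.at[row["target"], row["regulator"]] = row["weight"]
    pred = computational_perturbation(A0, ctx.expr, tf, ctx.stages[0], 0,
                                     fold=cfg.perturb_fold)
    report = {"tf": tf, "fold": cfg.perturb_fold,
              "n_up": int((pred.directions == "up").sum()),
              "n_down": int((pred.directions == "down").sum())}
    calls_path = cfg.artifact("truth_calls.tsv")
    if calls_path.exists():
        calls = pd.read_csv(calls_path, sep="\t", index_col=0)
        if tf in calls.columns:
            exp_dir = calls[tf].map({"up": "up", "down": "down", "none": "unchanged"})
            try:
                p, table = direction_agreement_test(pred.directions, exp_dir)
                report["fisher_p"] = p
                report["table"] = table.tolist()
            except ValueError:
                report["fisher_p"] = None
    pd.DataFrame({
        "gene_id": pred.directions.index,
        "direction": pred.directions.values,
        "delta": pred.delta.values,
    }).to_csv(outdir / f"perturbation_{tf}.tsv", sep="\t", index=False)
    (outdir / f"perturbation_{tf}.json").write_text(json.dumps(report, indent=1))
    outputs = [f"perturbation_{tf}.tsv", f"perturbation_{tf}.json"]
    _log_step(cfg, "perturb", outputs)
    return outputs


STEPS = {
    "simulate": step_simulate,
    "scan": step_scan,
    "features": step_features,
    "train-lr": step_train_lr,
    "predict-lr": step_predict_lr,
    "infer-network": step_infer_network,
    "bootstrap": step_bootstrap,
    "perturb": step_perturb,
}
ALL_ORDER = ["simulate", "scan", "features", "train-lr", "predict-lr",
             "infer-network", "bootstrap", "perturb"]


def run_pipeline(cfg: PipelineConfig, subcommand: str) -> List[str]:
    if subcommand == "all":
        outputs = []
        for step in ALL_ORDER:
            outputs += STEPS[step](cfg)
        return outputs
    if subcommand not in STEPS:
        raise ValueError(f"unknown subcommand {subcommand!r}")
    return STEPS[subcommand](cfg)
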