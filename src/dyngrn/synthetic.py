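"""Synthetic toy datasets with the statistical structure the method assumes.

Every generator is a pure function of its seed and writes/returns the same
objects the readers in :mod:`dyngrn.io` produce, so the whole pipeline can
be exercised end to end without any external download:

* a toy genome of adjacent gene loci with TSS-centered cis-regions;
* a panel of informative motifs planted into the sequence, a subset marked
  as truly bound (ChIP-like peaks, elevated conservation);
* enhancer-like signal bumps around bound sites with a local dip at the
  site itself, on stage-dependent amplitudes, plus Poisson noise;
* expression trajectories simulated from a known sparse ground-truth
  network X^{t+1} = A* X^t + eps; and
* a perturbation matrix derived from the ground truth by simulated
  induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dbn import (BindingMatrix, GeneBinding, SegmentIndex, hit_segment_mask,
                  segment_cis_region, segment_mean_lr)
from .features import GenomeContext, default_de_calls
from .io import (AnnotationTracks, CisRegion, ExpressionMatrix, GeneAnnotation,
                 PeakSet, PerturbationMatrix, SignalTrack, asinh_transform)
from .pwm import ALPHABET, PwmHit, PwmModel

STAGE_FACTORS = (1.0, 1.3, 0.8, 1.15, 0.95)


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated dataset."""

    edges: List[Tuple[str, str, float]]          # (target, regulator, weight)
    u_star: Dict[str, np.ndarray]                # gene -> (T-1) x K
    A_star: List[pd.DataFrame]                   # per transition
    lr_tracks: Dict[str, List[np.ndarray]]       # gene -> per-transition LR
    P: PerturbationMatrix
    calls: pd.DataFrame                          # genes x regulators, {up,down,none}
    sigma: float
    seed: int

    def positive_edges(self) -> set:
        return {(t, r) for t, r, w in self.edges if w > 0}


@dataclass
class SyntheticDataset:
    """A complete toy dataset plus (optionally) its generating truth."""

    seqs: Dict[str, str]
    chrom_sizes: Dict[str, int]
    genes: List[GeneAnnotation]
    cis_regions: Dict[str, CisRegion]
    annot: AnnotationTracks
    pwms: List[PwmModel]
    peaks: Dict[str, PeakSet]
    truth_hits: pd.DataFrame
    tracks: Dict[Tuple[str, str], SignalTrack]   # raw (untransformed)
    expr: ExpressionMatrix
    stages: List[str]
    tf_ids: List[str]
    truth: Optional[SyntheticTruth] = None

    def context(self, de_calls: Optional[pd.DataFrame] = None) -> GenomeContext:
        """Assemble a :class:`GenomeContext` (tracks asinh-transformed)."""
        transformed = {k: asinh_transform(t) for k, t in self.tracks.items()}
        if de_calls is None:
            de_calls = default_de_calls(self.expr)
        return GenomeContext(
            seqs=self.seqs, genes=self.genes, cis_regions=self.cis_regions,
            annot=self.annot, tracks=transformed, expr=self.expr,
            stages=self.stages, de_calls=de_calls,
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_toy_genome(
    n_genes: int = 20,
    region_len: int = 2000,
    seed: int = 0,
    gc: float = 0.5,
    chrom: str = "chrS",
    gene_ids: Optional[Sequence[str]] = None,
):
    """Adjacent gene loci on one chromosome, TSS at each locus center.

    Returns (seqs, chrom_sizes, genes, cis_regions, annot).  The loci tile
    the chromosome, so nearest-TSS ownership boundaries coincide with locus
    boundaries and every cis-region (width = ``region_len``) is fully owned.
    """
    if region_len < 50:
        raise ValueError("region_len must be >= 50")
    rng = np.random.default_rng(seed)
    length = n_genes * region_len
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    seq = "".join(ALPHABET[c] for c in codes)
    if gene_ids is None:
        gene_ids = [f"G{i:02d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    genes = []
    span = min(600, region_len // 2)
    for i, gid in enumerate(gene_ids):
        tss = i * region_len + region_len // 2
        strand = "+" if i % 2 == 0 else "-"
        if tss + span > length or tss - span + 1 < 0:
            raise ValueError("gene span does not fit the chromosome")
        if strand == "+":
            tx = (tss, tss + span)
        else:
            tx = (tss - span + 1, tss + 1)
        s, e = tx
        exon1 = (s, s + span // 4)
        exon2 = (e - span // 4, e)
        cds = (s + span // 8, e - span // 8)
        genes.append(GeneAnnotation(gid, chrom, strand, tx, cds, (exon1, exon2)))
    chrom_sizes = {chrom: length}
    from .io import assign_cis_regions

    regions = {r.gene_id: r for r in assign_cis_regions(genes, region_len, chrom_sizes)}
    vert_score = rng.uniform(0.0, 0.3, size=length)
    vert_avail = rng.random(length) < 0.85
    plac_score = rng.uniform(0.0, 0.3, size=length)
    plac_avail = rng.random(length) < 0.85
    cpg = np.array([[g.tss - 100, g.tss + 100] for g in genes], dtype=np.int64)
    n_rep = max(1, n_genes // 2)
    rep_starts = np.sort(rng.integers(0, length - 60, size=n_rep))
    repeats = np.column_stack([rep_starts, rep_starts + 50])
    annot = AnnotationTracks(
        phastcons_vert={chrom: (vert_score, vert_avail)},
        phastcons_plac={chrom: (plac_score, plac_avail)},
        cpg_islands={chrom: cpg},
        repeats={chrom: repeats},
    )
    return {chrom: seq}, chrom_sizes, genes, regions, annot


def toy_pwm_panel(
    n_tf: int = 5, length: int = 8, seed: int = 0,
    tf_ids: Optional[Sequence[str]] = None,
) -> List[PwmModel]:
    """Informative toy motifs with mutually distant consensus sequences."""
    rng = np.random.default_rng(seed)
    if tf_ids is None:
        tf_ids = [f"TF{j}" for j in range(n_tf)]
    chosen: List[np.ndarray] = []

    def far_enough(cand: np.ndarray) -> bool:
        rc = (3 - cand)[::-1]
        for other in chosen:
            if (cand != other).sum() < 3 or (rc != other).sum() < 3:
                return False
        return (cand != rc).sum() >= 3  # avoid palindromes

    while len(chosen) < n_tf:
        cand = rng.integers(0, 4, size=length)
        if far_enough(cand):
            chosen.append(cand)
    pwms = []
    for tf, cons in zip(tf_ids, chosen):
        counts = np.ones((4, length))
        counts[cons, np.arange(length)] = 20.0
        pwms.append(PwmModel(tf=tf, name=f"{tf}_motif", counts=counts))
    return pwms


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def plant_motif_instances(
    seqs: Dict[str, str],
    cis_regions: Dict[str, CisRegion],
    pwms: Sequence[PwmModel],
    plan: Sequence[Tuple[str, str, bool]],
    seed: int = 0,
    margin: int = 200,
    peak_halfwidth: int = 100,
    annot: Optional[AnnotationTracks] = None,
    conservation: float = 0.8,
    conservation_halfwidth: int = 10,
) -> Tuple[Dict[str, str], pd.DataFrame, Dict[str, PeakSet]]:
    """Write motif instances into the sequence at recorded positions.

    ``plan`` lists (gene_id, tf, positive) requests.  Instances of one gene
    are placed in jittered, well-separated slots across the usable span of
    its cis-region, so no 50-bp cis-segment ever contains two instances.
    Positive instances get a ChIP-like peak (center +/- ``peak_halfwidth``)
    and, when ``annot`` is given, elevated conservation over the footprint.
    """
    rng = np.random.default_rng(seed)
    pwm_by_tf = {p.tf: p for p in pwms}
    codes = {c: np.array(list(s)) for c, s in seqs.items()}
    per_gene: Dict[str, List[Tuple[str, bool]]] = {}
    for gene_id, tf, positive in plan:
        per_gene.setdefault(gene_id, []).append((tf, positive))
    rows = []
    peak_acc: Dict[str, List[Tuple[str, int, int]]] = {}
    for gene_id in sorted(per_gene):
        requests = per_gene[gene_id]
        region = cis_regions[gene_id]
        usable = region.length - 2 * margin
        n = len(requests)
        slot = usable // n
        max_len = max(pwm_by_tf[tf].length for tf, _ in requests)
        if slot < max_len + 70:
            raise ValueError(
                f"cis-region of {gene_id} too short for {n} well-separated instances"
            )
        order = rng.permutation(n)
        for slot_i, req_i in enumerate(order):
            tf, positive = requests[req_i]
            pwm = pwm_by_tf[tf]
            jitter_max = slot - pwm.length - 70
            start = region.start + margin + slot_i * slot + int(rng.integers(0, jitter_max + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            cons = pwm.consensus
            if strand == "-":
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                cons = "".join(comp[b] for b in reversed(cons))
            codes[region.chrom][start:start + pwm.length] = list(cons)
            end = start + pwm.length
            center = (start + end) // 2
            rows.append((gene_id, tf, region.chrom, start, end, strand, positive))
            if positive:
                peak_acc.setdefault(tf, []).append(
                    (region.chrom, center - peak_halfwidth, center + peak_halfwidth)
                )
                if annot is not None:
                    lo = max(0, start - conservation_halfwidth)
                    hi = min(len(codes[region.chrom]), end + conservation_halfwidth)
                    for trk in (annot.phastcons_vert, annot.phastcons_plac):
                        score, avail = trk[region.chrom]
                        score[lo:hi] = conservation
                        avail[lo:hi] = True
    truth = pd.DataFrame(
        rows, columns=["gene_id", "tf", "chrom", "start", "end", "strand", "positive"]
    )
    peaks = {}
    for tf, ivs in peak_acc.items():
        by_chrom: Dict[str, List] = {}
        for chrom, s, e in ivs:
            by_chrom.setdefault(chrom, []).append((s, e))
        peaks[tf] = PeakSet(
            tf, "synthetic",
            {c: np.array(sorted(v), dtype=np.int64) for c, v in by_chrom.items()},
        )
    new_seqs = {c: "".join(v) for c, v in codes.items()}
    return new_seqs, truth, peaks


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

def _bump(dist: np.ndarray, amp: float, flat: float, taper: float) -> np.ndarray:
    """Plateau kernel: ``amp`` within +/- flat, linear decay to 0 at +/- taper."""
    out = np.where(
        dist <= flat, amp,
        np.where(dist < taper, amp * (taper - dist) / (taper - flat), 0.0),
    )
    return out


def simulate_signal_tracks(
    chrom_sizes: Dict[str, int],
    genes: Sequence[GeneAnnotation],
    truth_hits: pd.DataFrame,
    stages: Sequence[str],
    seed: int = 0,
    bin_size: int = 10,
    base_rate: float = 1.0,
    amp: float = 6.0,
    dip_depth: float = 0.6,
    flat: float = 520.0,
    taper: float = 820.0,
    dip_sd: float = 30.0,
    noise: bool = True,
) -> Dict[Tuple[str, str], SignalTrack]:
    """Enhancer-like bumps with a local dip at truly bound sites.

    H3K27ac and H3K4me1 carry a plateau bump around each positive site minus
    a Gaussian dip of relative depth ``dip_depth`` at the site center; the
    bump amplitude is modulated per site and per stage (so the stage-to-stage
    signal changes vary across sites rather than moving in lockstep, as they
    would in real data).  H3K4me3 and RNAP carry promoter bumps at every
    TSS with stage-dependent amplitudes; H3K27me3 is background.  Poisson
    noise with mean ``base_rate`` is added everywhere unless ``noise`` is
    False.
    """
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    rng = np.random.default_rng(seed)
    positives = truth_hits.loc[truth_hits["positive"]].reset_index(drop=True)
    # per-site, per-stage, per-mark amplitude modulation, fixed up front so
    # track generation order does not matter
    site_factor = {
        mark: rng.uniform(0.6, 1.4, size=(len(positives), len(stages)))
        for mark in ("H3K27ac", "H3K4me1")
    }
    tracks: Dict[Tuple[str, str], SignalTrack] = {}
    marks = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3", "RNAP")
    for si, stage in enumerate(stages):
        factor = STAGE_FACTORS[si % len(STAGE_FACTORS)]
        alt = STAGE_FACTORS[(si + 2) % len(STAGE_FACTORS)]
        for mark in marks:
            values = {}
            for chrom, length in chrom_sizes.items():
                n_bins = -(-length // bin_size)
                centers = bin_size * np.arange(n_bins) + bin_size / 2.0
                v = np.zeros(n_bins)
                if mark in ("H3K27ac", "H3K4me1"):
                    base_a = amp if mark == "H3K27ac" else 0.7 * amp
                    for hi, h in positives.iterrows():
                        if h["chrom"] != chrom:
                            continue
                        a = base_a * site_factor[mark][hi, si]
                        site = (h["start"] + h["end"]) // 2
                        d = np.abs(centers - site)
                        near = d < taper
                        v[near] += _bump(d[near], a, flat, taper)
                        dip = d < 6 * dip_sd
                        v[dip] -= dip_depth * a * np.exp(-d[dip] ** 2 / (2 * dip_sd ** 2))
                elif mark in ("H3K4me3", "RNAP"):
                    a = 4.0 * (factor if mark == "RNAP" else alt)
                    for g in genes:
                        if g.chrom != chrom:
                            continue
                        d = np.abs(centers - g.tss)
                        near = d < 400
                        v[near] += _bump(d[near], a, 200.0, 400.0)
                v = np.clip(v, 0.0, None)
                if noise:
                    v = v + rng.poisson(base_rate, size=n_bins)
                values[chrom] = v
            tracks[(mark, stage)] = SignalTrack(mark, stage, bin_size, values)
    return tracks


# ---------------------------------------------------------------------------
# expression dynamics
# ---------------------------------------------------------------------------

def simulate_expression_dynamics(
    A_list,
    X1: np.ndarray,
    sigma: float,
    T: int,
    seed: int = 0,
    gene_ids: Optional[Sequence[str]] = None,
    stages: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, ExpressionMatrix]:
    """Forward-simulate X^{t+1} = A^t X^t + eps, eps ~ N(0, sigma^2 I).

    ``A_list`` is one matrix per transition (or a single matrix reused).
    FPKM is recovered as exp(X) - 1 clipped at 0.  Trajectories exceeding
    |X| > 50 abort with advice to rescale the spectral radius of A*.
    """
    if sigma < 0 or T < 2:
        raise ValueError("need sigma >= 0 and T >= 2")
    X1 = np.asarray(X1, dtype=float)
    p = X1.size
    if isinstance(A_list, (list, tuple)):
        mats = [np.asarray(a, dtype=float) for a in A_list]
    else:
        mats = [np.asarray(A_list, dtype=float)] * (T - 1)
    if len(mats) != T - 1:
        raise ValueError("need one transition matrix per transition")
    rng = np.random.default_rng(seed)
    X = np.empty((p, T))
    X[:, 0] = X1
    for t in range(T - 1):
        X[:, t + 1] = mats[t] @ X[:, t] + rng.normal(0.0, sigma, size=p)
        if np.abs(X[:, t + 1]).max() > 50:
            raise FloatingPointError(
                "expression diverged; rescale A* to spectral radius <= 1"
            )
    if gene_ids is None:
        gene_ids = [f"G{i:02d}" for i in range(p)]
    if stages is None:
        stages = [f"S{t}" for t in range(T)]
    fpkm = np.clip(np.exp(X) - 1.0, 0.0, None)
    expr = ExpressionMatrix(pd.DataFrame(fpkm, index=list(gene_ids), columns=list(stages)))
    return X, expr


def make_perturbation_truth(
    A: pd.DataFrame,
    expr: ExpressionMatrix,
    stage: str,
    fold: float = 5.0,
    threshold: float = 0.2,
) -> Tuple[PerturbationMatrix, pd.DataFrame]:
    """Derive the perturbation matrix P and directional calls from a network.

    Simulated induction of regulator j multiplies its FPKM by ``fold``; the
    one-step response of gene i is A_ij (log(fold F_j + 1) - log(F_j + 1)).
    P_ij = 1 iff |response| > ``threshold``; the call table records the
    response direction.
    """
    genes = list(A.index)
    F = expr.fpkm[stage]
    P = np.zeros((len(genes), len(genes)), dtype=np.int8)
    calls = pd.DataFrame("none", index=genes, columns=genes)
    for j, reg in enumerate(genes):
        fj = float(F.get(reg, 0.0))
        dx = np.log(fold * fj + 1.0) - np.log(fj + 1.0)
        delta = A[reg].to_numpy() * dx
        P[:, j] = np.abs(delta) > threshold
        calls[reg] = np.where(delta > threshold, "up",
                              np.where(delta < -threshold, "down", "none"))
    return (
        PerturbationMatrix(pd.DataFrame(P, index=genes, columns=genes)),
        calls,
    )


# ---------------------------------------------------------------------------
# complete datasets
# ---------------------------------------------------------------------------

def default_stage_map(tf_ids: Sequence[str], n_transitions: int) -> Dict[str, int]:
    """TF -> training transition: the first TFs mimic the early (stem-cell
    like) panel trained on the first transition, the last two mimic the late
    (cardiac-like) panel trained on the second-to-last transition."""
    if n_transitions < 2:
        return {tf: 0 for tf in tf_ids}
    late = n_transitions - 1
    return {tf: (late if j >= len(tf_ids) - 2 and len(tf_ids) > 2 else 0)
            for j, tf in enumerate(tf_ids)}


def make_lr_dataset(
    seed: int = 42,
    n_genes: int = 100,
    region_len: int = 3000,
    n_tf: int = 5,
    per_gene: int = 20,
    positive_fraction: float = 0.6,
    n_stages: int = 4,
) -> SyntheticDataset:
    """Dataset sized for training/evaluating the binding classifier.

    Plants ``per_gene`` motif instances per gene (TFs cycling), marking a
    ``positive_fraction`` of them as truly bound; bound sites receive peaks,
    conservation and the enhancer bump-with-dip signal.
    """
    rng = np.random.default_rng(seed)
    seqs, chrom_sizes, genes, regions, annot = make_toy_genome(
        n_genes, region_len, seed=seed + 1
    )
    tf_ids = [f"TF{j}" for j in range(n_tf)]
    pwms = toy_pwm_panel(n_tf, seed=seed + 2, tf_ids=tf_ids)
    plan = []
    for g in genes:
        for k in range(per_gene):
            tf = tf_ids[int(rng.integers(0, n_tf))]
            plan.append((g.gene_id, tf, bool(rng.random() < positive_fraction)))
    seqs, truth_hits, peaks = plant_motif_instances(
        seqs, regions, pwms, plan, seed=seed + 3, annot=annot
    )
    for tf in tf_ids:
        peaks.setdefault(tf, PeakSet(tf, "synthetic", {}))
    stages = [f"S{t}" for t in range(n_stages)]
    tracks = simulate_signal_tracks(
        chrom_sizes, genes, truth_hits, stages, seed=seed + 4
    )
    fpkm = rng.lognormal(mean=2.0, sigma=1.0, size=(n_genes, n_stages))
    expr = ExpressionMatrix(
        pd.DataFrame(fpkm, index=[g.gene_id for g in genes], columns=stages)
    )
    return SyntheticDataset(
        seqs=seqs, chrom_sizes=chrom_sizes, genes=genes, cis_regions=regions,
        annot=annot, pwms=pwms, peaks=peaks, truth_hits=truth_hits,
        tracks=tracks, expr=expr, stages=stages, tf_ids=tf_ids, truth=None,
    )


# TF genes self-regulate with per-TF geometric factors, so each stays
# abundantly expressed (FPKM > 25) while trajectories remain distinguishable
TF_INITIAL_FPKM = (60.0, 45.0, 80.0, 50.0, 100.0)
TF_SELF_WEIGHTS = (0.97, 1.03, 0.95, 1.02, 0.99)


def _design_edges(rng: np.random.Generator, tf_ids, target_ids):
    """Sparse ground-truth target edges: a hub TF with mixed up/down targets
    (down-targets compensated by a second TF) plus a few extra
    single-regulator edges.  TF self-regulation is added separately."""
    edges = []
    hub, comp = tf_ids[0], tf_ids[1]
    n_t = len(target_ids)
    n_up = min(7, n_t // 2)
    n_down = min(7, n_t - n_up - 1)
    for i in range(n_up):
        edges.append((target_ids[i], hub, float(rng.uniform(0.35, 0.6))))
    for i in range(n_up, n_up + n_down):
        edges.append((target_ids[i], hub, -float(rng.uniform(0.15, 0.28))))
        edges.append((target_ids[i], comp, float(rng.uniform(0.6, 0.9))))
    extras = [(0, 2, 0.3), (1, 3, 0.4), (2, 4, 0.45)]
    for ti, tj, w in extras:
        if ti < n_t and tj < len(tf_ids):
            edges.append((target_ids[ti], tf_ids[tj], w))
    if n_up + n_down < n_t:
        for i in range(n_up + n_down, n_t):
            edges.append((target_ids[i], tf_ids[2], 0.5))
    return edges


def make_dbn_dataset(
    seed: int = 42,
    n_genes: int = 20,
    n_tf: int = 5,
    region_len: int = 2000,
    sigma: float = 0.05,
    T: int = 4,
    lr_baseline: float = 0.02,
    lr_bound: float = 0.8,
    n_decoys: int = 2,
    segment_width: int = 50,
    segment_step: int = 5,
) -> SyntheticDataset:
    """Dataset for network inference with a fully known ground truth.

    The first ``n_tf`` genes are TF genes with geometric self-regulated
    trajectories staying abundantly expressed (FPKM > 25); the remaining
    genes are targets of a sparse designed edge set.  Every edge is mediated
    by one planted bound motif instance of the regulator in the target's
    cis-region; decoy bound instances without regulatory weight are planted
    as well.  A*, u*, per-base LR truth tracks, P and directional calls are
    all recorded.
    """
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{j}" for j in range(n_tf)]
    target_ids = [f"G{i:02d}" for i in range(n_tf, n_genes)]
    gene_ids = tf_ids + target_ids
    seqs, chrom_sizes, genes, regions, annot = make_toy_genome(
        n_genes, region_len, seed=seed + 1, gene_ids=gene_ids
    )
    pwms = toy_pwm_panel(n_tf, seed=seed + 2, tf_ids=tf_ids)
    target_edges = _design_edges(rng, tf_ids, target_ids)
    # TF self-regulation: geometric trajectories X_j^{t+1} = lam_j X_j^t
    lam0 = np.array(TF_SELF_WEIGHTS[:n_tf])
    X_tf = np.empty((n_tf, T))
    X_tf[:, 0] = np.log1p(np.array(TF_INITIAL_FPKM[:n_tf]))
    for t in range(T - 1):
        X_tf[:, t + 1] = lam0 * X_tf[:, t]
    lam = np.tile(lam0[:, None], (1, T - 1))  # n_tf x (T-1), constant in t
    self_edges = [(tf, tf, float(lam0[j])) for j, tf in enumerate(tf_ids)]
    edges = self_edges + target_edges

    # plant one bound instance per edge plus bound/unbound decoys
    plan = [(target, reg, True) for target, reg, _ in edges]
    regulators_of: Dict[str, set] = {}
    for target, reg, _ in edges:
        regulators_of.setdefault(target, set()).add(reg)
    for gid in gene_ids:
        others = [tf for tf in tf_ids if tf not in regulators_of.get(gid, set())]
        for d in range(n_decoys):
            tf = others[int(rng.integers(0, len(others)))] if others else tf_ids[0]
            plan.append((gid, tf, d == 0))  # first decoy bound, second unbound
    seqs, truth_hits, peaks = plant_motif_instances(
        seqs, regions, pwms, plan, seed=seed + 3, annot=annot
    )
    for tf in tf_ids:
        peaks.setdefault(tf, PeakSet(tf, "synthetic", {}))
    stages = [f"S{t}" for t in range(T)]
    tracks = simulate_signal_tracks(chrom_sizes, genes, truth_hits, stages, seed=seed + 4)

    # truth LR tracks: bound footprints high, everything else baseline
    lr_tracks: Dict[str, List[np.ndarray]] = {}
    for gid, region in regions.items():
        lr = np.full(region.length, lr_baseline)
        sub = truth_hits.loc[(truth_hits["gene_id"] == gid) & truth_hits["positive"]]
        for _, h in sub.iterrows():
            lo = max(region.start, h["start"] - 10)
            hi = min(region.end, h["end"] + 10)
            lr[lo - region.start: hi - region.start] = lr_bound
        lr_tracks[gid] = [lr.copy() for _ in range(T - 1)]

    # desired A*_t (targets time-invariant, TF self weights time-varying)
    # -> P (from the first transition) -> B* -> u*; A*_t then reproduces
    # (u*_t)^T B* exactly
    A_desired = [pd.DataFrame(0.0, index=gene_ids, columns=gene_ids)
                 for _ in range(T - 1)]
    for target, reg, w in target_edges:
        for t in range(T - 1):
            A_desired[t].at[target, reg] = w
    for j, tf in enumerate(tf_ids):
        for t in range(T - 1):
            A_desired[t].at[tf, tf] = float(lam[j, t])

    X1 = np.array(
        [X_tf[tf_ids.index(g), 0] if g in tf_ids else rng.uniform(1.2, 2.8)
         for g in gene_ids]
    )
    boot_expr = ExpressionMatrix(
        pd.DataFrame({stages[0]: np.expm1(X1)}, index=gene_ids)
    )
    P, calls = make_perturbation_truth(A_desired[0], boot_expr, stages[0])

    segments = {gid: segment_cis_region(regions[gid], segment_width, segment_step)
                for gid in gene_ids}
    hits_by_gene: Dict[str, List[PwmHit]] = {gid: [] for gid in gene_ids}
    for _, h in truth_hits.loc[truth_hits["positive"]].iterrows():
        hits_by_gene[h["gene_id"]].append(
            PwmHit(h["gene_id"], h["tf"], f"{h['tf']}_motif", h["chrom"],
                   int(h["start"]), int(h["end"]), h["strand"], 1.0,
                   int(h["start"]) + 3, "positive")
        )
    u_star: Dict[str, np.ndarray] = {}
    B_truth: Dict[str, List[np.ndarray]] = {}
    tf_index = {tf: j for j, tf in enumerate(tf_ids)}
    for gid in gene_ids:
        seg = segments[gid]
        mask = hit_segment_mask(hits_by_gene[gid], seg, tf_ids)
        pi = np.array([P.pi(gid, tf) for tf in tf_ids])
        mean_lr = segment_mean_lr(lr_tracks[gid][0], seg)
        B = mask * mean_lr[:, None] * pi[None, :]
        B_truth[gid] = [B.copy() for _ in range(T - 1)]
        U = np.zeros((T - 1, seg.n_segments))
        for target, reg, _w in edges:
            if target != gid:
                continue
            inst = truth_hits.loc[
                (truth_hits["gene_id"] == gid) & (truth_hits["tf"] == reg)
                & truth_hits["positive"]
            ].iloc[0]
            center = (int(inst["start"]) + int(inst["end"])) // 2
            k = int(np.clip(round((center - seg.width // 2 - seg.region_start)
                                  / seg.step), 0, seg.n_segments - 1))
            j = tf_index[reg]
            if not mask[k, j] or B[k, j] <= 0:
                raise AssertionError("designated segment lost its hit")
            if mask[k].sum() != 1:
                raise AssertionError("designated segment carries a second TF")
            for t in range(T - 1):
                U[t, k] = A_desired[t].at[gid, reg] / B[k, j]
        u_star[gid] = U

    A_star = [pd.DataFrame(0.0, index=gene_ids, columns=gene_ids)
              for _ in range(T - 1)]
    for gid in gene_ids:
        for t in range(T - 1):
            A_star[t].loc[gid, tf_ids] = u_star[gid][t] @ B_truth[gid][t]
    for t in range(T - 1):
        if not np.allclose(A_star[t].values, A_desired[t].values, atol=1e-12):
            raise AssertionError("u*^T B* does not reproduce the designed network")

    X, expr = simulate_expression_dynamics(
        [A.values for A in A_star], X1, sigma, T, seed=seed + 5,
        gene_ids=gene_ids, stages=stages,
    )
    if (X[:, 1:] <= 0.1).any():
        raise AssertionError("trajectory design produced near-zero expression")
    for tf in tf_ids:
        if (expr.fpkm.loc[tf] <= 25.0).any():
            raise AssertionError(f"TF {tf} dropped below the abundance threshold")

    truth = SyntheticTruth(
        edges=edges, u_star=u_star, A_star=A_star,
        lr_tracks=lr_tracks, P=P, calls=calls, sigma=sigma, seed=seed,
    )
    return SyntheticDataset(
        seqs=seqs, chrom_sizes=chrom_sizes, genes=genes, cis_regions=regions,
        annot=annot, pwms=pwms, peaks=peaks, truth_hits=truth_hits,
        tracks=tracks, expr=expr, stages=stages, tf_ids=tf_ids, truth=truth,
    )


def make_null_bootstrap_gene(
    seed: int, region_len: int = 500, T: int = 4
) -> Tuple[List[np.ndarray], GeneBinding, np.ndarray, List[np.ndarray], int]:
    """A null gene for bootstrap calibration.

    LR scores are i.i.d. uniform with no planted signal across a region much
    wider than one segment, one TF hit sits at the region center, and the
    expression trajectory is unrelated noise.  Because the segment means are
    then draws from the same distribution the bootstrap resamples from, the
    p-value of the central segment's weight is (discretely) uniform under
    this null.  Returns (lr_tracks, binding, x_target, X_cols, k_center).
    """
    rng = np.random.default_rng(seed)
    gid = "NULL"
    region = CisRegion(gid, "chrN", 0, region_len, region_len,
                       np.ones(region_len, dtype=bool))
    seg = segment_cis_region(region, 50, 5)
    lr_tracks = [rng.uniform(0.0, 1.0, size=region_len) for _ in range(T - 1)]
    center = region_len // 2
    hit = PwmHit(gid, "TF0", "TF0_motif", "chrN", center - 4, center + 4, "+", 1.0,
                 center, "positive")
    mask = hit_segment_mask([hit], seg, ["TF0"])
    pi = np.array([0.25])
    matrices = []
    for t in range(T - 1):
        mean_lr = segment_mean_lr(lr_tracks[t], seg)
        B = mask * mean_lr[:, None] * pi[None, :]
        matrices.append(BindingMatrix(gid, t, B, ["TF0"], seg, mask, pi))
    binding = GeneBinding(gid, seg, matrices)
    x_target = rng.normal(2.0, 0.5, size=T)
    X_cols = [np.array([3.0]) for _ in range(T - 1)]
    k_center = int(np.clip(round((center - seg.width // 2) / seg.step), 0,
                           seg.n_segments - 1))
    return lr_tracks, binding, x_target, X_cols, k_center
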