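"""The 69-feature design matrix for per-base binding prediction.

For any candidate base in a cis-region at a stage transition (t, t+1) the
model sees:

* 15 context-independent sequence/annotation features (conservation scores
  with availability indicators, CpG islands, log distance to the nearest
  TSS, repeats, gene-structure indicators, local GC content);
* 4 nearby-gene expression features (log FPKM at t and t+1, and indicators
  for a significant up-/down-regulation of the owning gene across the
  transition);
* 50 signal features: for each of 5 marks (H3K27ac, H3K4me1, H3K4me3,
  H3K27me3, RNAP) the mean asinh-transformed intensity in centered windows
  of total width 1000/500/100/50/10 nt at time t, and the change of each
  windowed mean from t to t+1.

Columns are standardized to zero mean and unit (sample) standard deviation;
the fitted scaler is reused verbatim at prediction time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (AnnotationTracks, CisRegion, ExpressionMatrix, GeneAnnotation,
                 SignalTrack, intervals_to_mask)
from .pwm import PwmHit, encode_sequence

MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3", "RNAP")
WINDOW_WIDTHS = (1000, 500, 100, 50, 10)

SEQUENCE_FEATURES = [
    "cons_vert_score", "cons_plac_score", "cons_vert_zero", "cons_plac_zero",
    "cons_vert_avail", "cons_plac_avail", "cpg_island", "log_dist_tss",
    "repeat_element", "transcribed", "cds_region", "exon", "coding_exon",
    "intron", "gc_content",
]
EXPRESSION_FEATURES = ["expr_t", "expr_t1", "up_t_t1", "down_t_t1"]
# fixed column order: per mark, 5 windowed means at t then the 5 deltas
SIGNAL_FEATURES: List[str] = []
for _mark in MARKS:
    SIGNAL_FEATURES += [f"{_mark}_mean{w}_t" for w in WINDOW_WIDTHS]
    SIGNAL_FEATURES += [f"{_mark}_dmean{w}" for w in WINDOW_WIDTHS]

FEATURE_NAMES: List[str] = SEQUENCE_FEATURES + EXPRESSION_FEATURES + SIGNAL_FEATURES
assert len(FEATURE_NAMES) == 69

METADATA_COLUMNS = ["gene_id", "tf", "chrom", "center_base", "strand", "norm_score",
                    "transition"]


# ---------------------------------------------------------------------------
# genome context: everything feature computation needs, pre-indexed
# ---------------------------------------------------------------------------

@dataclass
class GenomeContext:
    """Bundle of all inputs needed to compute features for any base.

    ``tracks`` maps (mark, stage) to an asinh-transformed
    :class:`~dyngrn.io.SignalTrack`; ``de_calls`` is a genes x transitions
    frame of {-1, 0, +1} differential-expression directions.
    """

    seqs: Dict[str, str]
    genes: Sequence[GeneAnnotation]
    cis_regions: Dict[str, CisRegion]
    annot: AnnotationTracks
    tracks: Dict[Tuple[str, str], SignalTrack]
    expr: ExpressionMatrix
    stages: Sequence[str]
    de_calls: pd.DataFrame
    marks: Sequence[str] = MARKS
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_transitions(self) -> int:
        return len(self.stages) - 1

    def chrom_length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def gene(self, gene_id: str) -> GeneAnnotation:
        key = ("gene_index",)
        if key not in self._cache:
            self._cache[key] = {g.gene_id: g for g in self.genes}
        return self._cache[key][gene_id]

    def chrom_masks(self, chrom: str) -> dict:
        """Per-chromosome boolean masks for gene-structure features (cached)."""
        key = ("masks", chrom)
        if key in self._cache:
            return self._cache[key]
        n = self.chrom_length(chrom)
        transcribed = np.zeros(n, dtype=bool)
        cds = np.zeros(n, dtype=bool)
        exon = np.zeros(n, dtype=bool)
        coding_exon = np.zeros(n, dtype=bool)
        intron = np.zeros(n, dtype=bool)
        for g in self.genes:
            if g.chrom != chrom:
                continue
            s, e = g.transcript_span
            transcribed[s:e] = True
            g_exon = np.zeros(n, dtype=bool)
            for xs, xe in g.exons:
                g_exon[xs:xe] = True
            exon |= g_exon
            g_tx = np.zeros(n, dtype=bool)
            g_tx[s:e] = True
            intron |= g_tx & ~g_exon
            if g.cds_span is not None:
                cs, ce = g.cds_span
                cds[cs:ce] = True
                coding_exon[cs:ce] |= g_exon[cs:ce]
        gc = np.isin(encode_sequence(self.seqs[chrom]), (1, 2))
        masks = {
            "transcribed": transcribed, "cds": cds, "exon": exon,
            "coding_exon": coding_exon, "intron": intron,
            "cpg": intervals_to_mask(self.annot.cpg_islands.get(chrom, np.empty((0, 2))), n),
            "repeat": intervals_to_mask(self.annot.repeats.get(chrom, np.empty((0, 2))), n),
            "gc_cum": np.concatenate([[0], np.cumsum(gc)]),
            "tss": np.array(sorted(g.tss for g in self.genes if g.chrom == chrom)),
        }
        self._cache[key] = masks
        return masks

    def track_cumsum(self, mark: str, stage: str, chrom: str) -> np.ndarray:
        key = ("cum", mark, stage, chrom)
        if key not in self._cache:
            track = self.tracks[(mark, stage)]
            if not track.transformed:
                raise ValueError(f"track {mark}/{stage} must be asinh-transformed")
            v = track.values[chrom]
            self._cache[key] = np.concatenate([[0.0], np.cumsum(v)])
        return self._cache[key]


# ---------------------------------------------------------------------------
# feature blocks
# ---------------------------------------------------------------------------

def sequence_features(ctx: GenomeContext, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Features 1-15 for an array of base positions on one chromosome."""
    positions = np.asarray(positions, dtype=np.int64)
    n_chrom = ctx.chrom_length(chrom)
    if positions.size and (positions.min() < 0 or positions.max() >= n_chrom):
        raise ValueError("base position outside the genome")
    m = ctx.chrom_masks(chrom)
    out = np.zeros((positions.size, 15))
    for trk, col0 in ((ctx.annot.phastcons_vert, 0), (ctx.annot.phastcons_plac, 1)):
        score, avail = trk.get(chrom, (np.zeros(n_chrom), np.zeros(n_chrom, dtype=bool)))
        av = avail[positions]
        sc = np.where(av, score[positions], 0.0)
        out[:, col0] = sc                               # score, 0 if unavailable
        out[:, col0 + 2] = av & (sc == 0.0)             # available-and-zero flag
        out[:, col0 + 4] = av                           # availability flag
    out[:, 6] = m["cpg"][positions]
    if m["tss"].size:
        i = np.searchsorted(m["tss"], positions)
        left = np.where(i > 0, np.abs(positions - m["tss"][np.maximum(i - 1, 0)]), np.iinfo(np.int64).max)
        right = np.where(i < m["tss"].size, np.abs(m["tss"][np.minimum(i, m["tss"].size - 1)] - positions), np.iinfo(np.int64).max)
        dist = np.minimum(left, right)
    else:
        dist = np.zeros(positions.size, dtype=np.int64)
    out[:, 7] = np.log(dist + 5.0)
    out[:, 8] = m["repeat"][positions]
    out[:, 9] = m["transcribed"][positions]
    out[:, 10] = m["cds"][positions]
    out[:, 11] = m["exon"][positions]
    out[:, 12] = m["coding_exon"][positions]
    out[:, 13] = m["intron"][positions]
    lo = np.maximum(positions - 50, 0)
    hi = np.minimum(positions + 51, n_chrom)
    out[:, 14] = (m["gc_cum"][hi] - m["gc_cum"][lo]) / (hi - lo)
    return out


def expression_features(ctx: GenomeContext, gene_id: str, t: int) -> np.ndarray:
    """Features 16-19 for the owning (nearest) gene at transition ``t``."""
    if not 0 <= t < ctx.n_transitions:
        raise ValueError(f"transition {t} out of range")
    s0, s1 = ctx.stages[t], ctx.stages[t + 1]
    fpkm = ctx.expr.fpkm
    f16 = float(np.log(fpkm.at[gene_id, s0] + 1.0))
    f17 = float(np.log(fpkm.at[gene_id, s1] + 1.0))
    call = int(ctx.de_calls.at[gene_id, t]) if gene_id in ctx.de_calls.index else 0
    return np.array([f16, f17, float(call == 1), float(call == -1)])


def window_mean(
    cum: np.ndarray,
    positions: np.ndarray,
    width: int,
    bin_size: int,
    lo_bound: int,
    hi_bound: int,
) -> np.ndarray:
    """Mean binned signal in a centered window of total ``width`` nt.

    The window [p - width/2, p + width/2) is clipped to [lo_bound, hi_bound)
    (cis-region intersected with the chromosome); the mean is taken over the
    bins overlapping the clipped window, unweighted.
    """
    n_bins = cum.size - 1
    lo = np.clip(positions - width // 2, lo_bound, None)
    hi = np.clip(positions + width // 2, None, hi_bound)
    b0 = np.clip(lo // bin_size, 0, n_bins)
    b1 = np.clip(-(-hi // bin_size), 0, n_bins)
    b1 = np.maximum(b1, b0 + 1)  # the base's own bin is always available
    return (cum[b1] - cum[b0]) / (b1 - b0)


def signal_window_features(
    ctx: GenomeContext,
    chrom: str,
    positions: np.ndarray,
    t: int,
    bounds: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Features 20-69: windowed means at t and their change to t+1."""
    positions = np.asarray(positions, dtype=np.int64)
    s0, s1 = ctx.stages[t], ctx.stages[t + 1]
    for mark in ctx.marks:
        for stage in (s0, s1):
            if (mark, stage) not in ctx.tracks:
                raise ValueError(f"missing signal track for {mark} at stage {stage}")
    lo_bound, hi_bound = bounds if bounds is not None else (0, ctx.chrom_length(chrom))
    lo_bound = max(lo_bound, 0)
    hi_bound = min(hi_bound, ctx.chrom_length(chrom))
    out = np.empty((positions.size, 10 * len(ctx.marks)))
    col = 0
    for mark in ctx.marks:
        bin_size = ctx.tracks[(mark, s0)].bin_size
        cum0 = ctx.track_cumsum(mark, s0, chrom)
        cum1 = ctx.track_cumsum(mark, s1, chrom)
        means0 = [window_mean(cum0, positions, w, bin_size, lo_bound, hi_bound)
                  for w in WINDOW_WIDTHS]
        means1 = [window_mean(cum1, positions, w, bin_size, lo_bound, hi_bound)
                  for w in WINDOW_WIDTHS]
        for m0 in means0:
            out[:, col] = m0
            col += 1
        for m0, m1 in zip(means0, means1):
            out[:, col] = m1 - m0
            col += 1
    return out


def compute_features(
    ctx: GenomeContext, gene_id: str, positions: np.ndarray, t: int
) -> pd.DataFrame:
    """Full 69-column feature frame for bases of one gene at transition ``t``."""
    region = ctx.cis_regions[gene_id]
    chrom = region.chrom
    positions = np.asarray(positions, dtype=np.int64)
    seq = sequence_features(ctx, chrom, positions)
    expr = np.tile(expression_features(ctx, gene_id, t), (positions.size, 1))
    sig = signal_window_features(ctx, chrom, positions, t, bounds=region.interval)
    return pd.DataFrame(np.hstack([seq, expr, sig]), columns=FEATURE_NAMES)


# ---------------------------------------------------------------------------
# DE calls
# ---------------------------------------------------------------------------

def default_de_calls(
    expr: ExpressionMatrix, fold_change: float = 2.0, min_delta: float = 1.0
) -> pd.DataFrame:
    """Simple fold-change DE caller for features 18/19.

    A gene is called up (+1) from t to t+1 when (FPKM_t1 + 1)/(FPKM_t + 1)
    >= ``fold_change`` and FPKM_t1 - FPKM_t >= ``min_delta``; down (-1)
    symmetrically; otherwise 0.  Up and down are mutually exclusive by
    construction.
    """
    F = expr.fpkm.values
    T = F.shape[1]
    calls = np.zeros((F.shape[0], T - 1), dtype=int)
    for t in range(T - 1):
        f0, f1 = F[:, t], F[:, t + 1]
        up = ((f1 + 1) / (f0 + 1) >= fold_change) & (f1 - f0 >= min_delta)
        down = ((f0 + 1) / (f1 + 1) >= fold_change) & (f0 - f1 >= min_delta)
        calls[:, t] = np.where(up, 1, np.where(down, -1, 0))
    return pd.DataFrame(calls, index=expr.genes, columns=range(T - 1))


def validate_de_calls(calls: pd.DataFrame) -> pd.DataFrame:
    if not np.isin(calls.values, (-1, 0, 1)).all():
        raise ValueError("DE calls must be -1/0/+1 (up and down are exclusive)")
    return calls


# ---------------------------------------------------------------------------
# design matrix assembly and standardization
# ---------------------------------------------------------------------------

@dataclass
class Scaler:
    """Per-column standardization parameters (sample sd, ddof=1).

    Constant columns are flagged and mapped to 0 instead of dividing by a
    zero standard deviation.
    """

    mean: pd.Series
    sd: pd.Series
    constant: pd.Series

    @classmethod
    def fit(cls, df: pd.DataFrame) -> "Scaler":
        if len(df) < 2:
            raise ValueError("need >= 2 rows to standardize")
        mean = df.mean()
        sd = df.std(ddof=1)
        constant = sd == 0
        if constant.any():
            warnings.warn(
                f"constant feature columns left at zero: {list(sd.index[constant])}"
            )
        return cls(mean=mean, sd=sd.where(~constant, 1.0), constant=constant)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        z = (df[self.mean.index] - self.mean) / self.sd
        z.loc[:, self.constant[self.constant].index] = 0.0
        return z

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "constant": {k: bool(v) for k, v in self.constant.items()},
            "columns": list(self.mean.index),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        cols = d["columns"]
        return cls(
            mean=pd.Series({c: d["mean"][c] for c in cols}),
            sd=pd.Series({c: d["sd"][c] for c in cols}),
            constant=pd.Series({c: d["constant"][c] for c in cols}),
        )


@dataclass
class FeatureTable:
    """Candidate-base rows: metadata + 69 features + binary response."""

    data: pd.DataFrame
    scaler: Optional[Scaler] = None

    @property
    def features(self) -> pd.DataFrame:
        return self.data[FEATURE_NAMES]

    @property
    def response(self) -> np.ndarray:
        return self.data["response"].to_numpy(dtype=int)

    def to_tsv(self, tsv_path, scaler_path=None) -> None:
        self.data.to_csv(tsv_path, sep="\t", index=False)
        if scaler_path is not None and self.scaler is not None:
            with open(scaler_path, "w") as fh:
                json.dump(self.scaler.to_dict(), fh, indent=1)

    @classmethod
    def from_tsv(cls, tsv_path, scaler_path=None) -> "FeatureTable":
        data = pd.read_csv(tsv_path, sep="\t")
        scaler = None
        if scaler_path is not None:
            with open(scaler_path) as fh:
                scaler = Scaler.from_dict(json.load(fh))
        return cls(data=data, scaler=scaler)


def assemble_design_matrix(
    ctx: GenomeContext,
    hits: Sequence[PwmHit],
    stage_map: Dict[str, int],
    negative_subsample: Optional[float] = None,
    seed: int = 0,
) -> FeatureTable:
    """One row per labeled, overlap-resolved hit center.

    ``stage_map`` assigns each TF its transition index t (features use the
    (t, t+1) stage pair of that TF's training cell type).  The response is
    1 iff the hit is labeled positive; unlabeled hits are an error.
    ``negative_subsample`` optionally keeps only that (seeded) fraction of
    negative hits; by default every hit is used.
    """
    if negative_subsample is not None:
        if not 0 < negative_subsample <= 1:
            raise ValueError("negative_subsample must be in (0, 1]")
        rng = np.random.default_rng(seed)
        hits = [h for h in hits
                if h.label == "positive" or rng.random() < negative_subsample]
    rows: List[pd.DataFrame] = []
    by_group: Dict[Tuple[str, int], List[PwmHit]] = {}
    for h in hits:
        if h.tf not in stage_map:
            raise ValueError(f"TF {h.tf!r} has no stage transition mapping")
        if h.label == "unlabeled":
            raise ValueError("all hits must be labeled before assembly")
        by_group.setdefault((h.gene_id, stage_map[h.tf]), []).append(h)
    for (gene_id, t), group in sorted(by_group.items()):
        centers = np.array([h.center_base for h in group])
        feats = compute_features(ctx, gene_id, centers, t)
        meta = pd.DataFrame({
            "gene_id": gene_id,
            "tf": [h.tf for h in group],
            "chrom": [h.chrom for h in group],
            "center_base": centers,
            "strand": [h.strand for h in group],
            "norm_score": [h.norm_score for h in group],
            "transition": t,
        })
        resp = pd.DataFrame({"response": [int(h.label == "positive") for h in group]})
        rows.append(pd.concat([meta, feats, resp], axis=1))
    if not rows:
        return FeatureTable(pd.DataFrame(columns=METADATA_COLUMNS + FEATURE_NAMES + ["response"]))
    return FeatureTable(pd.concat(rows, ignore_index=True))


def standardize_features(table: FeatureTable) -> FeatureTable:
    """Z-score the 69 feature columns; the fitted scaler rides along."""
    scaler = Scaler.fit(table.features)
    data = table.data.copy()
    data[FEATURE_NAMES] = scaler.transform(table.features)
    return FeatureTable(data=data, scaler=scaler)
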