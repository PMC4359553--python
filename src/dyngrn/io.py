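"""Genomic data model and readers/writers.

All coordinates are 0-based, half-open internally.  BED-family formats are
native; any 1-based format would be converted at the boundary.  Every reader
transparently accepts gzip-compressed files (``.gz`` suffix).

The central containers are small dataclasses rather than anything fancier:
a :class:`GeneAnnotation` per transcript, a :class:`SignalTrack` per
(mark, stage) holding 10-bp binned ChIP intensity, an
:class:`ExpressionMatrix` of FPKM values per gene and developmental stage,
and a binary :class:`PerturbationMatrix` recording which targets responded
when a regulator was perturbed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = Tuple[int, int]
IntervalSet = Dict[str, np.ndarray]  # chrom -> (n, 2) int array, sorted by start


def _open(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """One gene/transcript with its TSS, span, CDS and exon structure.

    ``tss`` equals the transcript start on the + strand and ``end - 1`` on
    the - strand.  Exons and the CDS span must lie inside the transcript
    span; this is validated at construction.
    """

    gene_id: str
    chrom: str
    strand: str
    transcript_span: Interval
    cds_span: Optional[Interval] = None
    exons: Tuple[Interval, ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {self.strand!r} for {self.gene_id}")
        s, e = self.transcript_span
        if not s < e:
            raise FormatError(f"empty transcript span for {self.gene_id}")
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if not (s <= cs <= ce <= e):
                raise FormatError(f"CDS outside transcript for {self.gene_id}")
        for xs, xe in self.exons:
            if not (s <= xs < xe <= e):
                raise FormatError(f"exon outside transcript for {self.gene_id}")

    @property
    def tss(self) -> int:
        s, e = self.transcript_span
        return s if self.strand == "+" else e - 1


def read_gene_annotation(path, fmt: str = "bed12") -> List[GeneAnnotation]:
    """Read gene annotations from BED12 or a minimal GTF-like TSV.

    The TSV format has a header line and columns: gene_id, chrom, strand,
    tx_start, tx_end, cds_start, cds_end (both ``.`` when absent), exons
    (comma-separated ``start-end`` pairs).
    """
    if fmt not in ("bed12", "tsv"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    genes: List[GeneAnnotation] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if fmt == "tsv" and lineno == 1 and line.startswith("gene_id"):
                continue
            try:
                genes.append(_parse_gene_line(line, fmt))
            except Exception as exc:  # malformed field
                raise FormatError(f"{path}: malformed line {lineno}: {exc}") from exc
    return genes


def _parse_gene_line(line: str, fmt: str) -> GeneAnnotation:
    f = line.split("\t") if "\t" in line else line.split()
    if fmt == "bed12":
        if len(f) < 12:
            raise FormatError(f"expected 12 BED fields, got {len(f)}")
        chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        thick_s, thick_e = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise FormatError("block count mismatch")
        exons = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
        cds = None if thick_s == thick_e else (thick_s, thick_e)
        return GeneAnnotation(name, chrom, strand, (start, end), cds, exons)
    # tsv
    gene_id, chrom, strand, txs, txe, cs, ce, ex = f[:8]
    cds = None if cs == "." else (int(cs), int(ce))
    exons = tuple(
        tuple(int(x) for x in pair.split("-")) for pair in ex.split(",") if pair
    )
    return GeneAnnotation(gene_id, chrom, strand, (int(txs), int(txe)), cds, exons)


def write_gene_annotation(genes: Sequence[GeneAnnotation], path, fmt: str = "bed12") -> None:
    with _open(path, "wt") as fh:
        if fmt == "tsv":
            fh.write("gene_id\tchrom\tstrand\ttx_start\ttx_end\tcds_start\tcds_end\texons\n")
        for g in genes:
            s, e = g.transcript_span
            if fmt == "bed12":
                cs, ce = g.cds_span if g.cds_span is not None else (s, s)
                exons = g.exons if g.exons else ((s, e),)
                sizes = ",".join(str(xe - xs) for xs, xe in exons)
                offs = ",".join(str(xs - s) for xs, xe in exons)
                fh.write(
                    f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}\t{cs}\t{ce}\t0\t"
                    f"{len(exons)}\t{sizes}\t{offs}\n"
                )
            else:
                cs, ce = (".", ".") if g.cds_span is None else g.cds_span
                ex = ",".join(f"{xs}-{xe}" for xs, xe in g.exons)
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{s}\t{e}\t{cs}\t{ce}\t{ex}\n")


# ---------------------------------------------------------------------------
# interval sets (BED3+)
# ---------------------------------------------------------------------------

def read_intervals(path) -> IntervalSet:
    """Read a BED3+ file into per-chromosome sorted (n, 2) arrays."""
    acc: Dict[str, List[Interval]] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed line {lineno}: {exc}") from exc
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start {start} >= end {end}")
            acc.setdefault(chrom, []).append((start, end))
    return {
        chrom: np.array(sorted(ivs), dtype=np.int64).reshape(-1, 2)
        for chrom, ivs in acc.items()
    }


def write_intervals(ivs: IntervalSet, path, names: Optional[Dict[str, list]] = None) -> None:
    with _open(path, "wt") as fh:
        for chrom in sorted(ivs):
            for i, (s, e) in enumerate(np.asarray(ivs[chrom])):
                if names:
                    fh.write(f"{chrom}\t{s}\t{e}\t{names[chrom][i]}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def intervals_to_mask(ivs: np.ndarray, length: int) -> np.ndarray:
    """Boolean per-base mask of length ``length`` from an (n, 2) interval array."""
    mask = np.zeros(length, dtype=bool)
    for s, e in np.asarray(ivs).reshape(-1, 2):
        mask[max(0, int(s)):min(length, int(e))] = True
    return mask


def interval_overlap_fraction(query: IntervalSet, reference: IntervalSet) -> float:
    """Fraction of query intervals with >= 1 bp overlap with any reference interval.

    Half-open convention: abutting intervals do not overlap.  Raises on an
    empty query (the fraction is undefined).
    """
    n_query = sum(len(v) for v in query.values())
    if n_query == 0:
        raise ValueError("empty query: overlap fraction is undefined")
    n_hit = 0
    for chrom, qs in query.items():
        refs = np.asarray(reference.get(chrom, np.empty((0, 2), dtype=np.int64)))
        if len(refs) == 0:
            continue
        starts, ends = refs[:, 0], refs[:, 1]
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        # running max of ends to handle contained intervals
        run_end = np.maximum.accumulate(ends)
        for qs_, qe_ in np.asarray(qs):
            i = np.searchsorted(starts, qe_, side="left")  # refs starting before qe
            if i > 0 and run_end[i - 1] > qs_:
                n_hit += 1
    return n_hit / n_query


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

@dataclass
class SignalTrack:
    """Binned intensity for one histone mark / RNAP at one stage.

    ``values`` maps chromosome to a dense per-bin vector (gaps are 0).
    ``transformed`` records whether the inverse hyperbolic sine transform has
    been applied; raw (untransformed) values must be non-negative.
    """

    mark: str
    stage: str
    bin_size: int
    values: Dict[str, np.ndarray]
    transformed: bool = False

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")


def read_signal_track(
    path,
    mark: str,
    stage: str,
    bin_size: int = 10,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> SignalTrack:
    """Read a bedGraph into a dense binned :class:`SignalTrack`.

    Records that do not align with the bin grid are re-binned by a
    coverage-weighted mean, with uncovered bases contributing 0 (equivalent
    to the per-base average over the bin of the piecewise-constant signal).
    """
    acc: Dict[str, Dict[int, float]] = {}
    max_end: Dict[str, int] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed line {lineno}: {exc}") from exc
            if value < 0:
                raise FormatError(f"{path}: line {lineno}: negative raw value {value}")
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end")
            d = acc.setdefault(chrom, {})
            max_end[chrom] = max(max_end.get(chrom, 0), end)
            b0, b1 = start // bin_size, (end - 1) // bin_size
            for b in range(b0, b1 + 1):
                ov = min(end, (b + 1) * bin_size) - max(start, b * bin_size)
                d[b] = d.get(b, 0.0) + value * ov
    values: Dict[str, np.ndarray] = {}
    for chrom, d in acc.items():
        length = chrom_sizes[chrom] if chrom_sizes else max_end[chrom]
        n_bins = -(-length // bin_size)
        v = np.zeros(n_bins, dtype=float)
        for b, tot in d.items():
            if b < n_bins:
                v[b] = tot / bin_size
        values[chrom] = v
    if chrom_sizes:
        for chrom, length in chrom_sizes.items():
            values.setdefault(chrom, np.zeros(-(-length // bin_size)))
    return SignalTrack(mark, stage, bin_size, values, transformed=False)


def write_signal_track(track: SignalTrack, path) -> None:
    s = track.bin_size
    with _open(path, "wt") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            for b in np.nonzero(v)[0]:
                fh.write(f"{chrom}\t{b * s}\t{(b + 1) * s}\t{v[b]:.10g}\n")


def asinh_transform(track: SignalTrack) -> SignalTrack:
    """Apply the inverse hyperbolic sine transform to a raw track.

    asinh compresses large tag counts while behaving linearly near zero; it
    is monotone, so bin rankings are preserved.  Transforming twice is an
    error.
    """
    if track.transformed:
        raise ValueError(f"track {track.mark}/{track.stage} is already transformed")
    return replace(
        track,
        values={c: np.arcsinh(v) for c, v in track.values.items()},
        transformed=True,
    )


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """ChIP-seq peak intervals of one transcription factor in one cell type."""

    tf: str
    cell_type: str
    intervals: IntervalSet


def read_peaks(path, tf: str, cell_type: str = "") -> PeakSet:
    return PeakSet(tf, cell_type, read_intervals(path))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Per-gene, per-stage FPKM; the model state is ``X = log(FPKM + 1)``."""

    fpkm: pd.DataFrame  # genes x stages

    def __post_init__(self):
        if (self.fpkm.values < 0).any():
            raise FormatError("negative FPKM value")
        if self.fpkm.index.duplicated().any():
            dups = self.fpkm.index[self.fpkm.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dups}")

    @property
    def genes(self) -> List[str]:
        return list(self.fpkm.index)

    @property
    def stages(self) -> List[str]:
        return list(self.fpkm.columns)

    @property
    def X(self) -> pd.DataFrame:
        return np.log1p(self.fpkm)


def read_expression_table(
    path, fpkm_min: float = 1.0, apply_filter: bool = True
) -> ExpressionMatrix:
    """Read a gene x stage FPKM TSV (header = stage labels, first column = gene id).

    With ``apply_filter`` genes are kept only if FPKM exceeds ``fpkm_min`` in
    at least one stage.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    em = ExpressionMatrix(df.astype(float))
    if apply_filter:
        keep = (em.fpkm.values > fpkm_min).any(axis=1)
        em = ExpressionMatrix(em.fpkm.loc[keep])
    return em


def write_expression_table(expr: ExpressionMatrix, path) -> None:
    expr.fpkm.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# perturbation matrix
# ---------------------------------------------------------------------------

@dataclass
class PerturbationMatrix:
    """Binary matrix P with P[target, regulator] = 1 iff the target responded."""

    P: pd.DataFrame  # targets x regulators, entries in {0, 1}

    def __post_init__(self):
        vals = self.P.values
        if not np.isin(vals, (0, 1)).all():
            raise FormatError("perturbation matrix entries must be 0/1")

    def pi(self, target: str, regulator: str, default: float = 0.25) -> float:
        """Perturbation adjustment: 1 for a supported edge, ``default`` otherwise."""
        try:
            return 1.0 if self.P.at[target, regulator] == 1 else default
        except KeyError:
            return default


def read_perturbation_edges(path, genes: Sequence[str]) -> PerturbationMatrix:
    """Read (target, regulator) edge rows into a dense binary matrix.

    Unknown gene ids are an error; duplicate rows collapse to a single 1;
    an empty file yields the all-zero matrix.
    """
    genes = list(genes)
    idx = {g: i for i, g in enumerate(genes)}
    P = np.zeros((len(genes), len(genes)), dtype=np.int8)
    unknown = []
    with _open(path) as fh:
        header = fh.readline().strip()
        rows = [header] if header and not header.lower().startswith("target") else []
        rows += [line.strip() for line in fh]
    for line in rows:
        if not line:
            continue
        f = line.split("\t") if "\t" in line else line.split()
        target, regulator = f[0], f[1]
        if target not in idx or regulator not in idx:
            unknown += [g for g in (target, regulator) if g not in idx]
            continue
        P[idx[target], idx[regulator]] = 1
    if unknown:
        raise FormatError(f"unknown gene ids in perturbation edges: {sorted(set(unknown))}")
    return PerturbationMatrix(pd.DataFrame(P, index=genes, columns=genes))


def write_perturbation_edges(pm: PerturbationMatrix, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("target\tregulator\n")
        ti, rj = np.nonzero(pm.P.values)
        for i, j in zip(ti, rj):
            fh.write(f"{pm.P.index[i]}\t{pm.P.columns[j]}\n")


# ---------------------------------------------------------------------------
# cis-regions
# ---------------------------------------------------------------------------

@dataclass
class CisRegion:
    """The (clipped) window around a gene's TSS with its per-base ownership mask.

    ``owned[b]`` is True iff base ``start + b`` is assigned to this gene after
    nearest-gene resolution of overlapping windows.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    width: int
    owned: np.ndarray = field(repr=False)

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def assign_cis_regions(
    genes: Sequence[GeneAnnotation], width: int, chrom_sizes: Dict[str, int]
) -> List[CisRegion]:
    """Build cis-regions of nominal ``width`` centered on each TSS.

    Windows are clipped (not shifted) at chromosome ends.  A base covered by
    several windows is owned by the gene with the nearest TSS; an equidistant
    base goes to the gene with the smaller TSS coordinate.
    """
    if width % 2:
        raise ValueError("width must be even")
    half = width // 2
    regions: List[CisRegion] = []
    by_chrom: Dict[str, List[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        length = chrom_sizes[chrom]
        gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        wins = [(max(0, g.tss - half), min(length, g.tss + half)) for g in gs]
        tss = np.array([g.tss for g in gs])
        masks = [np.ones(e - s, dtype=bool) for s, e in wins]
        # resolve every pair of overlapping windows by nearest TSS
        for a in range(len(gs)):
            for b in range(a + 1, len(gs)):
                lo = max(wins[a][0], wins[b][0])
                hi = min(wins[a][1], wins[b][1])
                if lo >= hi:
                    continue
                bases = np.arange(lo, hi)
                # a is the smaller-TSS gene: it keeps ties
                a_wins = np.abs(bases - tss[a]) <= np.abs(bases - tss[b])
                masks[a][lo - wins[a][0]: hi - wins[a][0]] &= a_wins
                masks[b][lo - wins[b][0]: hi - wins[b][0]] &= ~a_wins
        for g, (s, e), m in zip(gs, wins, masks):
            regions.append(CisRegion(g.gene_id, chrom, s, e, width, m))
    return regions


# ---------------------------------------------------------------------------
# annotation tracks (conservation, CpG, repeats)
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTracks:
    """Static sequence annotations used by the context-independent features.

    Conservation tracks are per-base scores in [0, 1] with an availability
    mask (alignment gaps have no score at all, which is distinct from a
    score of zero).
    """

    phastcons_vert: Dict[str, Tuple[np.ndarray, np.ndarray]]  # chrom -> (score, avail)
    phastcons_plac: Dict[str, Tuple[np.ndarray, np.ndarray]]
    cpg_islands: IntervalSet
    repeats: IntervalSet

    def __post_init__(self):
        for trk in (self.phastcons_vert, self.phastcons_plac):
            for chrom, (score, avail) in trk.items():
                s = score[avail]
                if s.size and (s.min() < 0 or s.max() > 1):
                    raise FormatError(f"conservation scores outside [0, 1] on {chrom}")


def read_conservation_track(path, chrom_sizes: Dict[str, int]):
    """Read a per-base conservation bedGraph; covered bases define the mask."""
    out = {}
    for chrom, length in chrom_sizes.items():
        out[chrom] = (np.zeros(length), np.zeros(length, dtype=bool))
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom in out:
                score, avail = out[chrom]
                score[start:end] = value
                avail[start:end] = True
    return out


def write_conservation_track(trk, path) -> None:
    with _open(path, "wt") as fh:
        for chrom in sorted(trk):
            score, avail = trk[chrom]
            # run-length encode contiguous available stretches of equal value
            pos = 0
            n = len(score)
            while pos < n:
                if not avail[pos]:
                    pos += 1
                    continue
                end = pos + 1
                while end < n and avail[end] and score[end] == score[pos]:
                    end += 1
                fh.write(f"{chrom}\t{pos}\t{end}\t{score[pos]:.6g}\n")
                pos = end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")
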