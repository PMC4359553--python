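"""Position weight matrix scoring, scanning and hit handling.

Scores are min-max normalized: a window's sum of log-odds is rescaled so the
best attainable L-mer scores 1 and the worst scores 0, and scanning keeps
windows at or above a percent-of-maximum threshold (default 0.90) on both
strands.  ``N`` bases contribute the column-minimum log-odds (conservative:
an ambiguous base can only hurt a window's score).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .io import PeakSet, _open

ALPHABET = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3, anything else 4 (N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    rc = np.where(codes == 4, 4, 3 - codes)
    return rc[::-1]


@dataclass
class PwmModel:
    """A column-stochastic 4 x L motif model with min-max normalized scoring.

    ``counts`` keeps the source matrix (so files round-trip exactly);
    ``probs`` adds ``pseudocount`` to every cell before column normalization.
    Log-odds are against the uniform background, in bits.
    """

    tf: str
    name: str
    counts: np.ndarray
    pseudocount: float = 0.01
    probs: np.ndarray = field(init=False, repr=False)
    log_odds: np.ndarray = field(init=False, repr=False)
    raw_min: float = field(init=False)
    raw_max: float = field(init=False)

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4:
            raise ValueError(f"PWM {self.name}: counts must be 4 x L")
        if (c < 0).any():
            raise ValueError(f"PWM {self.name}: negative counts")
        colsum = c.sum(axis=0)
        if (colsum == 0).any():
            raise ValueError(f"PWM {self.name}: all-zero column")
        self.counts = c
        p = c + self.pseudocount
        self.probs = p / p.sum(axis=0, keepdims=True)
        self.log_odds = np.log2(self.probs / 0.25)
        self.raw_min = float(self.log_odds.min(axis=0).sum())
        self.raw_max = float(self.log_odds.max(axis=0).sum())

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    def score_matrix(self) -> np.ndarray:
        """5 x L log-odds with an extra N row holding each column's minimum."""
        return np.vstack([self.log_odds, self.log_odds.min(axis=0)])


@dataclass
class PwmHit:
    """One motif match: a half-open interval with strand and normalized score."""

    gene_id: str
    tf: str
    motif: str
    chrom: str
    start: int
    end: int
    strand: str
    norm_score: float
    center_base: int
    label: str = "unlabeled"


def normalized_score(pwm: PwmModel, seq: str) -> float:
    """Min-max normalized PWM score of an L-mer: (raw - min) / (max - min)."""
    if pwm.raw_max == pwm.raw_min:
        raise ValueError(f"degenerate motif {pwm.name}: raw_max == raw_min")
    codes = encode_sequence(seq)
    if codes.size != pwm.length:
        raise ValueError(f"sequence length {codes.size} != motif length {pwm.length}")
    raw = pwm.score_matrix()[codes, np.arange(pwm.length)].sum()
    return float((raw - pwm.raw_min) / (pwm.raw_max - pwm.raw_min))


def _window_scores(codes: np.ndarray, sm: np.ndarray) -> np.ndarray:
    L = sm.shape[1]
    if codes.size < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    return sm[win, np.arange(L)].sum(axis=1)


def scan_sequence(
    pwm: PwmModel,
    seq: str,
    threshold: float = 0.90,
    offset: int = 0,
    gene_id: str = "",
    chrom: str = "",
    convention: str = "minmax",
) -> List[PwmHit]:
    """Scan both strands and keep windows with normalized score >= threshold.

    A minus-strand window is scored on its reverse complement and reported on
    forward coordinates.  ``offset`` shifts reported coordinates (e.g. the
    cis-region start).  ``convention`` selects the normalization: ``minmax``
    (default, score rescaled over the attainable range) or ``rawmax``
    (fraction of the maximum raw score; requires a positive maximum).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if pwm.raw_max == pwm.raw_min:
        raise ValueError(f"degenerate motif {pwm.name}: raw_max == raw_min")
    L = pwm.length
    codes = encode_sequence(seq)
    sm = pwm.score_matrix()

    def _norm(raw: np.ndarray) -> np.ndarray:
        if convention == "minmax":
            return (raw - pwm.raw_min) / (pwm.raw_max - pwm.raw_min)
        if convention == "rawmax":
            if pwm.raw_max <= 0:
                raise ValueError(f"motif {pwm.name}: rawmax convention needs raw_max > 0")
            return raw / pwm.raw_max
        raise ValueError(f"unknown convention {convention!r}")

    hits: List[PwmHit] = []
    fwd = _norm(_window_scores(codes, sm))
    for i in np.nonzero(fwd >= threshold)[0]:
        start = offset + int(i)
        hits.append(
            PwmHit(gene_id, pwm.tf, pwm.name, chrom, start, start + L, "+",
                   float(fwd[i]), start + (L - 1) // 2)
        )
    rc = reverse_complement_codes(codes)
    rev = _norm(_window_scores(rc, sm))
    n = codes.size
    for i in np.nonzero(rev >= threshold)[0]:
        start = offset + n - L - int(i)  # mirror back to forward coordinates
        hits.append(
            PwmHit(gene_id, pwm.tf, pwm.name, chrom, start, start + L, "-",
                   float(rev[i]), start + (L - 1) // 2)
        )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def resolve_overlapping_hits(hits: Sequence[PwmHit], across_tfs: bool = False) -> List[PwmHit]:
    """Greedy overlap resolution: the higher-scoring hit of any overlapping
    pair survives; score ties keep the 5'-most hit.

    By default resolution is applied within each (gene, TF) group so that
    co-located motifs of different factors can coexist; ``across_tfs=True``
    resolves over all hits of a gene jointly.
    """
    groups: Dict[tuple, List[PwmHit]] = {}
    for h in hits:
        key = (h.gene_id, h.chrom) if across_tfs else (h.gene_id, h.chrom, h.tf)
        groups.setdefault(key, []).append(h)
    kept: List[PwmHit] = []
    for group in groups.values():
        group = sorted(group, key=lambda h: (-h.norm_score, h.start, h.strand))
        chosen: List[PwmHit] = []
        for h in group:
            if all(h.end <= c.start or h.start >= c.end for c in chosen):
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.gene_id, h.chrom, h.start, h.tf, h.strand))
    return kept


def label_hits_with_peaks(hits: Sequence[PwmHit], peaks: PeakSet) -> List[PwmHit]:
    """Label each hit positive iff it overlaps >= 1 bp of a peak of its own TF."""
    out: List[PwmHit] = []
    for h in hits:
        if h.tf != peaks.tf:
            raise ValueError(f"hit TF {h.tf!r} does not match peak set TF {peaks.tf!r}")
        ivs = peaks.intervals.get(h.chrom)
        positive = False
        if ivs is not None and len(ivs):
            ivs = np.asarray(ivs)
            positive = bool(((ivs[:, 0] < h.end) & (ivs[:, 1] > h.start)).any())
        out.append(
            PwmHit(h.gene_id, h.tf, h.motif, h.chrom, h.start, h.end, h.strand,
                   h.norm_score, h.center_base, "positive" if positive else "negative")
        )
    return out


# ---------------------------------------------------------------------------
# JASPAR PFM I/O
# ---------------------------------------------------------------------------

def read_pwm_set(path, pseudocount: float = 0.01) -> List[PwmModel]:
    """Read JASPAR PFM text into :class:`PwmModel` objects.

    The motif header is ``>matrix_id name``; the TF name is taken from the
    motif name (falling back to the matrix id).  Unequal row lengths or
    all-zero columns are errors.
    """
    with _open(path) as fh:
        text = fh.read()
    try:
        records = bio_motifs.parse(_io.StringIO(text), "jaspar")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse JASPAR PFM: {exc}") from exc
    out = []
    for m in records:
        counts = np.array([list(m.counts[b]) for b in ALPHABET], dtype=float)
        name = m.name or m.matrix_id or "motif"
        tf = m.name or m.matrix_id or "motif"
        out.append(PwmModel(tf=tf, name=name, counts=counts, pseudocount=pseudocount))
    return out


def write_pwm_set(pwms: Sequence[PwmModel], path) -> None:
    """Write motifs in JASPAR PFM text with full float precision."""
    with _open(path, "wt") as fh:
        for p in pwms:
            fh.write(f">{p.name} {p.tf}\n")
            for bi, base in enumerate(ALPHABET):
                row = " ".join(f"{x:.10g}" for x in p.counts[bi])
                fh.write(f"{base} [ {row} ]\n")


def write_hits(hits: Sequence[PwmHit], bed_path=None, tsv_path=None) -> None:
    """Export hits as BED6 (score = norm_score x 1000) and/or a TSV with labels."""
    if bed_path is not None:
        with _open(bed_path, "wt") as fh:
            for h in hits:
                fh.write(
                    f"{h.chrom}\t{h.start}\t{h.end}\t{h.tf}:{h.motif}\t"
                    f"{round(h.norm_score * 1000)}\t{h.strand}\n"
                )
    if tsv_path is not None:
        with _open(tsv_path, "wt") as fh:
            fh.write("gene_id\ttf\tmotif\tchrom\tstart\tend\tstrand\tnorm_score\t"
                     "center_base\tlabel\n")
            for h in hits:
                fh.write(
                    f"{h.gene_id}\t{h.tf}\t{h.motif}\t{h.chrom}\t{h.start}\t{h.end}\t"
                    f"{h.strand}\t{h.norm_score:.10g}\t{h.center_base}\t{h.label}\n"
                )


def read_hits(tsv_path) -> List[PwmHit]:
    hits = []
    with _open(tsv_path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(PwmHit(f[0], f[1], f[2], f[3], int(f[4]), int(f[5]), f[6],
                               float(f[7]), int(f[8]), f[9]))
    return hits
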