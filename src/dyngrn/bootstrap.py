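"""Bootstrap significance of cis-segment weights.

For each gene the per-base LR scores of its cis-region are resampled with
replacement (bases keep their positions; values are drawn from the region's
empirical LR distribution), the binding matrices are rebuilt and the network
re-solved.  With N replicates the p-value of a segment weight u is

    p = (sum_n H(u_n > u) + 1) / (N + 1),   H(x) = 1 if x > 0 else 0,

bounded below by exactly 1/(N + 1).  Replicates reuse the hyperparameters of
the point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dbn import (GeneBinding, SolverError, segment_mean_lr, solve_gene_weights)


@dataclass
class BootstrapResult:
    """Point estimates, replicate estimates and p-values for one gene."""

    gene_id: str
    U: np.ndarray              # (T-1) x K point estimate
    replicates: np.ndarray     # N x (T-1) x K
    p_values: np.ndarray       # (T-1) x K
    n_replicates: int


def bootstrap_segment_pvalues(
    gene_id: str,
    lr_tracks: Sequence[np.ndarray],
    binding: GeneBinding,
    x_target: np.ndarray,
    X_cols: Sequence[np.ndarray],
    lambda1: float,
    lambda2: float,
    loss: str = "squared",
    n_boot: int = 100,
    seed: int = 0,
    resample_unit: str = "base",
) -> BootstrapResult:
    """Bootstrap p-values for every segment weight of one gene.

    ``lr_tracks`` holds the per-base LR score vector of the gene's cis-region
    for each transition; each replicate resamples every transition's vector
    independently and rebuilds ``B = hit_mask * segment_mean_LR * pi``.
    ``resample_unit='segment'`` draws whole segment-mean blocks instead of
    individual bases.  A solver failure in a replicate is retried once and
    then conservatively counted as an exceedance for every segment.
    """
    if n_boot < 1:
        raise ValueError("need at least one bootstrap replicate")
    T1 = len(binding.matrices)
    point = solve_gene_weights(
        x_target, [bm.B for bm in binding.matrices], X_cols,
        lambda1, lambda2, loss=loss, gene_id=gene_id,
    )
    K = binding.segments.n_segments
    rng = np.random.default_rng(seed)
    reps = np.full((n_boot, T1, K), np.nan)
    exceed = np.zeros((T1, K))
    for n in range(n_boot):
        draws = []
        for t in range(T1):
            lr = np.asarray(lr_tracks[t])
            if resample_unit == "base":
                mean_lr = segment_mean_lr(
                    lr[rng.integers(0, lr.size, size=lr.size)], binding.segments
                )
            elif resample_unit == "segment":
                m0 = segment_mean_lr(lr, binding.segments)
                mean_lr = m0[rng.integers(0, m0.size, size=m0.size)]
            else:
                raise ValueError(f"unknown resample unit {resample_unit!r}")
            draws.append(mean_lr)
        solved = False
        for attempt in range(2):
            try:
                B_rep = [
                    bm.hit_mask * draws[t][:, None] * bm.pi[None, :]
                    for t, bm in enumerate(binding.matrices)
                ]
                sw = solve_gene_weights(
                    x_target, B_rep, X_cols, lambda1, lambda2, loss=loss,
                    gene_id=gene_id,
                )
                reps[n] = sw.U
                exceed += sw.U > point.U
                solved = True
                break
            except SolverError:
                continue
        if not solved:
            warnings.warn(
                f"bootstrap replicate {n} failed twice for {gene_id}; "
                "counted as exceedance"
            )
            exceed += 1.0
    p = (exceed + 1.0) / (n_boot + 1.0)
    return BootstrapResult(gene_id, point.U, reps, p, n_boot)


def bootstrap_table(result: BootstrapResult, segments) -> pd.DataFrame:
    """Long-format TSV-ready table: one row per (transition, segment)."""
    rows = []
    for t in range(result.U.shape[0]):
        for k in range(result.U.shape[1]):
            s, e = segments.interval(k)
            rows.append((result.gene_id, t, s, e, result.U[t, k], result.p_values[t, k]))
    return pd.DataFrame(
        rows, columns=["gene_id", "transition", "start", "end", "u", "p_value"]
    )
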