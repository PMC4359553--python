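"""In-silico TF perturbation and direction-agreement testing.

A fitted transition network predicts the response to over-expressing one
TF: the TF's FPKM is multiplied by ``fold`` (default 5), re-logged into the
model state, and the change is propagated through A^t.  Predicted response
directions are compared with experimental perturbation calls by a
two-sided Fisher's exact test on the up/down 2x2 agreement table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix


@dataclass
class PerturbationPrediction:
    """Per-gene predicted response directions to one TF induction."""

    tf: str
    fold: float
    transition: int
    directions: pd.Series  # gene -> {"up", "down", "unchanged"}
    delta: pd.Series       # gene -> predicted change of X^{t+1}


def computational_perturbation(
    network: pd.DataFrame,
    expr: ExpressionMatrix,
    tf: str,
    stage: str,
    transition: int,
    fold: float = 5.0,
    tol: float = 1e-8,
) -> PerturbationPrediction:
    """Predict response directions to a ``fold``-change induction of ``tf``.

    The fold change is applied on the FPKM scale and re-logged:
    X'_tf = log(fold * FPKM_tf + 1).  The predicted change for gene g is
    A^t_g . (X' - X); |change| <= ``tol`` is reported as unchanged.
    """
    if tf not in expr.fpkm.index:
        raise KeyError(f"{tf!r} not in the expression matrix")
    X = expr.X[stage]
    if tf not in network.columns or not (network[tf].abs() > tol).any():
        warnings.warn(f"{tf!r} has no outgoing weight in the network; all unchanged")
    fpkm_tf = float(expr.fpkm.at[tf, stage])
    dx = float(np.log(fold * fpkm_tf + 1.0) - np.log(fpkm_tf + 1.0))
    delta = (network[tf] * dx) if tf in network.columns else pd.Series(0.0, index=network.index)
    directions = pd.Series(
        np.where(delta > tol, "up", np.where(delta < -tol, "down", "unchanged")),
        index=network.index,
    )
    return PerturbationPrediction(tf, fold, transition, directions, delta)


def direction_agreement_test(
    predicted: pd.Series, experimental: pd.Series
) -> Tuple[float, np.ndarray]:
    """Two-sided Fisher's exact test on the predicted x experimental 2x2 table.

    Only genes with a non-unchanged prediction AND an up/down experimental
    call enter the table (rows: predicted up/down; columns: experimental
    up/down).  Returns (p, table).
    """
    common = predicted.index.intersection(experimental.index)
    pred = predicted.loc[common]
    exp = experimental.loc[common]
    keep = pred.isin(["up", "down"]) & exp.isin(["up", "down"])
    if not keep.any():
        raise ValueError("no genes with both a directional prediction and a call")
    pred, exp = pred[keep], exp[keep]
    table = np.array([
        [int(((pred == "up") & (exp == "up")).sum()),
         int(((pred == "up") & (exp == "down")).sum())],
        [int(((pred == "down") & (exp == "up")).sum()),
         int(((pred == "down") & (exp == "down")).sum())],
    ])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return p, table


def perturbation_report(
    prediction: PerturbationPrediction, experimental: pd.Series
) -> Dict:
    p, table = direction_agreement_test(prediction.directions, experimental)
    return {
        "tf": prediction.tf,
        "fold": prediction.fold,
        "transition": prediction.transition,
        "fisher_p": p,
        "table": table.tolist(),
        "n_predicted_up": int((prediction.directions == "up").sum()),
        "n_predicted_down": int((prediction.directions == "down").sum()),
    }
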