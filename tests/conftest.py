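"""Shared fixtures: seeded synthetic datasets and derived model inputs.

Expensive artifacts (datasets, scans, design matrices, binding matrices) are
session-scoped so the acceptance tests and unit tests share one copy.
"""

import warnings

import numpy as np
import pytest

from dyngrn.dbn import GeneBinding, build_binding_matrix, segment_cis_region
from dyngrn.features import assemble_design_matrix
from dyngrn.logit import LrScoreTrack
from dyngrn.pwm import (PwmModel, label_hits_with_peaks, resolve_overlapping_hits,
                        scan_sequence)
from dyngrn.synthetic import default_stage_map, make_dbn_dataset, make_lr_dataset


def scan_dataset(ds, threshold=0.9):
    """Scan every cis-region of a synthetic dataset with its PWM panel."""
    hits = []
    for gid in sorted(ds.cis_regions):
        region = ds.cis_regions[gid]
        seq = ds.seqs[region.chrom][region.start:region.end]
        for pwm in ds.pwms:
            hits += scan_sequence(pwm, seq, threshold, offset=region.start,
                                  gene_id=gid, chrom=region.chrom)
    return resolve_overlapping_hits(hits)


def build_dbn_inputs(ds, hits):
    """Binding matrices + solver inputs from a dataset's truth LR tracks."""
    X = ds.expr.X
    T1 = len(ds.stages) - 1
    binding, gene_data = {}, {}
    for gid in sorted(ds.cis_regions):
        region = ds.cis_regions[gid]
        seg = segment_cis_region(region)
        mats = []
        for t in range(T1):
            trk = LrScoreTrack(gid, t, region.chrom, region.start,
                               ds.truth.lr_tracks[gid][t], region.owned)
            mats.append(build_binding_matrix(
                gid, t, trk, hits, ds.truth.P, ds.expr, seg, ds.tf_ids, ds.stages
            ))
        binding[gid] = GeneBinding(gid, seg, mats)
        B_list = [bm.B for bm in mats]
        X_cols = [X.loc[mats[t].tf_names, ds.stages[t]].to_numpy()
                  for t in range(T1)]
        gene_data[gid] = (X.loc[gid].to_numpy(), B_list, X_cols)
    return binding, gene_data


@pytest.fixture(scope="session")
def toy_pwm():
    """A 3-mer PWM with distinct column preferences."""
    counts = np.array([
        [12.0, 1.0, 2.0],
        [2.0, 9.0, 3.0],
        [1.0, 3.0, 10.0],
        [4.0, 2.0, 1.0],
    ])
    return PwmModel(tf="TOY", name="TOY_3mer", counts=counts)


@pytest.fixture(scope="session")
def lr_dataset():
    return make_lr_dataset(seed=42)


@pytest.fixture(scope="session")
def lr_table(lr_dataset):
    """Labeled, standardizable design matrix over all planted + spurious hits."""
    ds = lr_dataset
    ctx = ds.context()
    hits = scan_dataset(ds)
    labeled = []
    for tf in ds.tf_ids:
        labeled += label_hits_with_peaks([h for h in hits if h.tf == tf],
                                         ds.peaks[tf])
    stage_map = default_stage_map(ds.tf_ids, len(ds.stages) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return assemble_design_matrix(ctx, labeled, stage_map)


@pytest.fixture(scope="session")
def dbn_dataset():
    return make_dbn_dataset(seed=42)


@pytest.fixture(scope="session")
def dbn_inputs(dbn_dataset):
    hits = scan_dataset(dbn_dataset)
    binding, gene_data = build_dbn_inputs(dbn_dataset, hits)
    return hits, binding, gene_data


@pytest.fixture(scope="session")
def dbn_noiseless():
    ds = make_dbn_dataset(seed=42, sigma=0.0)
    hits = scan_dataset(ds)
    binding, gene_data = build_dbn_inputs(ds, hits)
    return ds, binding, gene_data
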