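"""TRE and TRE-motif enrichment within behaviour clusters, and the
three-rule candidate filter.

Enrichment asks, for every (cluster, feature) pair, whether contigs
carrying the feature — a single TRE letter or an ordered, contiguous
k-letter motif — are over-represented inside the cluster, by a one-sided
Fisher exact test (alternative "greater") on the 2x2 presence table.
Benjamini-Hochberg correction is applied separately within the
single-TRE family and within each k-mer family, across all cluster x
feature tests.

Candidate promoters must jointly (i) reach a minimum baseline frequency
in the viral library, (ii) exceed a linear fold-change threshold at a
minimum number of post-stimulation timepoints, and (iii) belong to the
smallest descending-abundance prefix of the pooled cell library reaching
the cumulative-mass threshold (ties at the boundary included).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alphabet import SelectionThresholds
from .dynamics import ClusterAssignment, TrajectorySet
from .quantify import ContigCountMatrix


def motif_occurrences(contig: str, k: int) -> set[str]:
    """The set of ordered, contiguous k-letter motifs present in a contig
    (presence, not multiplicity).  k = 1 reduces to single-TRE presence."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return {contig[i : i + k] for i in range(len(contig) - k + 1)}


def fisher_enrichment(
    clusters: "ClusterAssignment | pd.Series",
    k: int = 1,
    contigs: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of k-motifs per cluster.

    ``clusters`` maps contig strings (or arbitrary ids, with the contig
    strings supplied via ``contigs``) to cluster labels.  Every feature
    observed at least once inside a cluster is tested; the 2x2 table is
    (in-cluster with/without feature; out-of-cluster with/without).
    q-values are Benjamini-Hochberg within this feature family.
    """
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) else clusters
    if labels.nunique() < 2:
        raise ValueError("enrichment requires at least two clusters")
    strings = list(labels.index if contigs is None else contigs)
    lab = labels.to_numpy()
    presence: dict[str, np.ndarray] = {}
    for i, s in enumerate(strings):
        for f in motif_occurrences(s, k):
            presence.setdefault(f, np.zeros(len(strings), dtype=bool))[i] = True

    rows = []
    n_total = len(strings)
    for cl in sorted(pd.unique(lab)):
        in_cl = lab == cl
        n_in = int(in_cl.sum())
        for feat in sorted(presence):
            has = presence[feat]
            a = int((has & in_cl).sum())
            if a == 0:
                continue
            b = n_in - a
            c = int(has.sum()) - a
            d = n_total - n_in - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append(
                {"cluster": cl, "feature": feat, "a": a, "b": b, "c": c, "d": d,
                 "p_value": float(p)}
            )
    result = pd.DataFrame(
        rows, columns=["cluster", "feature", "a", "b", "c", "d", "p_value"]
    )
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["q_value"] = pd.Series(dtype=float)
    return result.sort_values(["cluster", "q_value", "p_value"]).reset_index(drop=True)


def select_candidates(
    matrix: ContigCountMatrix,
    traj: TrajectorySet,
    thresholds: SelectionThresholds = SelectionThresholds(),
    cell_samples: Optional[Sequence[str]] = None,
    fc_mode: str = "linear",
) -> pd.DataFrame:
    """Apply the three-rule inducible-candidate filter.

    Rule i: baseline (viral) frequency >= ``min_baseline_freq``.
    Rule ii: fold change (cpm_t + c) / (cpm_baseline + c) >
    ``min_fold_change`` at >= ``min_timepoints_above`` timepoints
    (``fc_mode='log2'`` applies the threshold to the log2 trajectory
    instead).
    Rule iii: membership in the smallest descending-frequency prefix of
    the pooled cell library whose cumulative frequency reaches
    ``cumulative_mass``; contigs tied with the boundary frequency are
    included.

    Returns a per-contig table with the supporting numbers, per-rule
    flags, and the conjunction in ``selected``.
    """
    timepoints = list(traj.log2fc.columns)
    if cell_samples is None:
        cell_samples = timepoints
    missing = set(cell_samples) - set(matrix.samples)
    if missing:
        raise ValueError(f"cell sample(s) missing: {sorted(missing)}")

    baseline_freq = traj.baseline_freq
    pass_baseline = baseline_freq >= thresholds.min_baseline_freq

    if fc_mode == "linear":
        fc = 2.0 ** traj.log2fc
        above = fc > thresholds.min_fold_change
    elif fc_mode == "log2":
        above = traj.log2fc > np.log2(thresholds.min_fold_change)
    else:
        raise ValueError("fc_mode must be 'linear' or 'log2'")
    n_above = above.sum(axis=1)
    pass_fc = n_above >= thresholds.min_timepoints_above

    pooled = matrix.counts[list(cell_samples)].sum(axis=1)
    pooled_freq = pooled / pooled.sum()
    order = pooled_freq.sort_values(ascending=False, kind="mergesort")
    cum = order.cumsum()
    cutoff_pos = int(np.searchsorted(cum.to_numpy(), thresholds.cumulative_mass))
    cutoff_pos = min(cutoff_pos, len(order) - 1)
    boundary_freq = order.iloc[cutoff_pos]
    pass_mass = pooled_freq >= boundary_freq
    if boundary_freq == 0:
        pass_mass = pooled_freq > 0

    out = pd.DataFrame(
        {
            "baseline_freq": baseline_freq,
            "n_timepoints_above": n_above,
            "pooled_cell_freq": pooled_freq,
            "pass_baseline": pass_baseline,
            "pass_fold_change": pass_fc,
            "pass_abundance": pass_mass,
        }
    )
    out["selected"] = out.pass_baseline & out.pass_fold_change & out.pass_abundance
    return out.sort_values("pooled_cell_freq", ascending=False)
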