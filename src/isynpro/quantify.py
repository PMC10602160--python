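"""Contig- and TRE-level quantification of the screen libraries.

Identical contig strings are aggregated — a promoter *is* its TRE string
for counting purposes — and all per-sample normalisations (frequency,
counts per million) derive from the aggregated matrix.  Clonality is
summarised by the Lorenz curve over distinct clones (ascending count
order, clone share on the x axis) and its Gini coefficient; library
similarity by Pearson correlation of log10 frequencies with a Haldane
style pseudo-frequency of half a read; and packaging/selection length
effects by a count-weighted Mann-Whitney comparison of contig lengths in
TRE units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import TREAlphabet


class ContigCountMatrix:
    """Contig-by-sample read counts with frequency and CPM views."""

    def __init__(self, counts: pd.DataFrame):
        if counts.index.duplicated().any():
            counts = counts.groupby(level=0).sum()
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def contigs(self) -> pd.Index:
        return self.counts.index

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def freq(self) -> pd.DataFrame:
        return self.counts / self.totals

    @property
    def cpm(self) -> pd.DataFrame:
        return self.freq * 1e6

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ContigCountMatrix({self.counts.shape[0]} contigs x "
            f"{self.counts.shape[1]} samples)"
        )


def build_counts(
    per_sample_contigs: Mapping[str, "pd.Series | Iterable[str]"],
) -> ContigCountMatrix:
    """Aggregate per-sample contig calls into a count matrix.

    Each value may be an iterable of contig strings (one per accepted
    read/template) or a precomputed ``pd.Series`` of counts indexed by
    contig.  Contigs absent from a sample get count 0.
    """
    columns = {}
    for sample, data in per_sample_contigs.items():
        if isinstance(data, pd.Series):
            columns[sample] = data.groupby(level=0).sum()
        else:
            columns[sample] = pd.Series(list(data), dtype=object).value_counts()
    df = pd.DataFrame(columns).fillna(0)
    df = df[list(per_sample_contigs)]
    df.index.name = "contig"
    return ContigCountMatrix(df.sort_index())


def tre_proportions(
    matrix: ContigCountMatrix,
    alphabet: TREAlphabet,
    samples: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Count-weighted per-sample TRE letter fractions and the per-TRE
    coefficient of variation (sd/mean) across ``samples``.

    Returns (fractions TRE x sample, CV per TRE, summary with
    mean/min/max CV).
    """
    if samples is None:
        samples = list(matrix.samples)
    if not samples:
        raise ValueError("sample set is empty")
    letter_counts = pd.DataFrame(
        {
            code: [c.count(code) for c in matrix.contigs]
            for code in alphabet.codes
        },
        index=matrix.contigs,
    )
    fractions = {}
    for s in samples:
        weighted = letter_counts.mul(matrix.counts[s], axis=0).sum(axis=0)
        total = weighted.sum()
        fractions[s] = weighted / total if total > 0 else weighted * np.nan
    frac = pd.DataFrame(fractions)
    mean = frac.mean(axis=1)
    sd = frac.std(axis=1, ddof=1)
    cv = (sd / mean).where(mean > 0, 0.0).fillna(0.0)
    summary = {
        "mean_cv": float(cv.mean()),
        "min_cv": float(cv.min()),
        "max_cv": float(cv.max()),
    }
    return frac, cv, summary


@dataclass
class LorenzResult:
    x: np.ndarray  # cumulative clone share, starting at 0
    y: np.ndarray  # cumulative read share, starting at 0
    gini: float


def lorenz_gini(counts: "pd.Series | np.ndarray | Sequence[int]") -> LorenzResult:
    """Lorenz curve and Gini coefficient of one sample's clone counts.

    Distinct contigs with positive counts are sorted ascending; the curve
    plots cumulative read share against cumulative clone share and the
    Gini coefficient is one minus twice the trapezoidal area under it.
    """
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("at least one positive count is required")
    arr = np.sort(arr)
    n = arr.size
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(arr) / arr.sum()])
    gini = 1.0 - 2.0 * float(np.trapezoid(y, x))
    return LorenzResult(x=x, y=y, gini=gini)


def library_correlation(
    matrix: ContigCountMatrix,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """Pearson correlation of log10 frequencies between two libraries on
    contigs detected in either, with pseudo-frequency ``pseudocount`` /
    column total.  Returns (r, p)."""
    ca = matrix.counts[sample_a]
    cb = matrix.counts[sample_b]
    shared = (ca > 0) | (cb > 0)
    fa = (ca[shared] + pseudocount) / ca.sum()
    fb = (cb[shared] + pseudocount) / cb.sum()
    r, p = stats.pearsonr(np.log10(fa), np.log10(fb))
    return float(r), float(p)


def length_comparison(
    matrix: ContigCountMatrix,
    alphabet: TREAlphabet,
    sample_a: str,
    sample_b: str,
) -> dict:
    """Count-weighted comparison of promoter lengths (in TRE units)
    between two libraries, with a two-sided Mann-Whitney U test."""
    lengths = np.array([len(c) for c in matrix.contigs])

    def expand(sample: str) -> np.ndarray:
        return np.repeat(lengths, matrix.counts[sample].to_numpy())

    xa, xb = expand(sample_a), expand(sample_b)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both samples need positive counts")
    pooled = np.concatenate([xa, xb])
    if np.all(pooled == pooled[0]):
        u, p = float(xa.size * xb.size / 2), 1.0
    else:
        u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
    return {
        "median_a": float(np.median(xa)),
        "median_b": float(np.median(xb)),
        "U": float(u),
        "p_value": float(p),
        "direction": (
            "a_longer"
            if np.median(xa) > np.median(xb)
            else "b_longer"
            if np.median(xb) > np.median(xa)
            else "equal"
        ),
    }
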