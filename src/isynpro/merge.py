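"""Paired-end template reconstruction by sliding-overlap consensus.

The promoter amplicons are variable in length and there is no alignment
reference, so each template is reconstructed directly from its read pair:
the reverse-complemented mate is slid against read 1, every offset whose
geometric overlap reaches ``min_overlap`` is scored as matches minus
mismatches, and the best-scoring offset is accepted when its mismatch
rate stays below ``max_mismatch_rate``.  Score ties between offsets are
rejected as ambiguous rather than resolved arbitrarily, so downstream
clone counts are never inflated by uncertain merges.

Consensus qualities follow common overlap-merger practice: agreeing
overlap bases get ``min(q1 + q2, 41)``; disagreeing bases take the base
with the higher Phred score and quality ``|q1 - q2|`` (read 1 wins exact
quality ties).  The model is gap-free: amplicon data of this kind is
substitution-dominated, and indels are instead tolerated downstream by
the edit-distance TRE caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[a] = b

MAX_MERGED_QUAL = 41


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP_TABLE[arr][::-1]


def _decode_quals(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33


@dataclass(frozen=True)
class MergeParams:
    min_overlap: int = 20
    max_mismatch_rate: float = 0.10


@dataclass
class MergedTemplate:
    sequence: str
    qualities: np.ndarray  # per-base Phred scores
    overlap_len: int
    overlap_mismatches: int
    source_pair_id: str = ""


@dataclass(frozen=True)
class MergeRejection:
    reason: str  # no_overlap | too_many_mismatches | tie
    source_pair_id: str = ""


REJECT_REASONS = ("no_overlap", "too_many_mismatches", "tie")


def merge_pair(
    r1: tuple[str, str],
    r2: tuple[str, str],
    params: MergeParams = MergeParams(),
    pair_id: str = "",
) -> MergedTemplate | MergeRejection:
    """Merge one read pair.  ``r1``/``r2`` are (sequence, Phred+33 quality
    string) tuples; ``r2`` is the opposite-strand mate.

    The candidate template places read 1 at position 0 and the
    reverse-complemented mate at offset ``s``; the template ends where the
    mate ends, so bases of either read protruding past those limits
    (read-through into adapter) are clipped.
    """
    seq1, qual1 = r1
    seq2, qual2 = r2
    if not seq1 or not seq2:
        raise ValueError("empty read")
    a = _encode(seq1)
    b = _revcomp_arr(_encode(seq2))
    qa = _decode_quals(qual1)
    qb = _decode_quals(qual2)[::-1].copy()
    L1, L2 = a.size, b.size
    min_ov = params.min_overlap

    best_score = None
    best_s = None
    best_mm = 0
    best_ov = 0
    tie = False
    any_offset = False
    max_raw_score = -(10**9)
    for s in range(-(L2 - min_ov), L1 - min_ov + 1):
        lo = max(0, s)
        hi = min(L1, s + L2)
        ov = hi - lo
        if ov < min_ov:
            continue
        any_offset = True
        mm = int(np.count_nonzero(a[lo:hi] != b[lo - s : hi - s]))
        score = ov - 2 * mm
        if score > max_raw_score:
            max_raw_score = score
        if best_score is None or score > best_score:
            best_score, best_s, best_mm, best_ov = score, s, mm, ov
            tie = False
        elif score == best_score:
            tie = True

    if not any_offset:
        return MergeRejection("no_overlap", pair_id)
    assert best_s is not None
    if best_mm / best_ov > params.max_mismatch_rate:
        reason = "no_overlap" if max_raw_score <= 0 else "too_many_mismatches"
        return MergeRejection(reason, pair_id)
    if tie:
        return MergeRejection("tie", pair_id)

    s = best_s
    lo = max(0, s)
    hi = min(L1, s + L2)
    # template spans [max(0, s) clipped left .. s + L2): read 1 anchors the
    # 5' end, the mate's end defines the 3' end; protrusions are clipped.
    parts_seq = []
    parts_q = []
    if s > 0:
        parts_seq.append(a[:s])
        parts_q.append(qa[:s])
    ov_a = a[lo:hi]
    ov_b = b[lo - s : hi - s]
    ov_qa = qa[lo:hi]
    ov_qb = qb[lo - s : hi - s]
    agree = ov_a == ov_b
    cons = np.where(agree | (ov_qa >= ov_qb), ov_a, ov_b)
    consq = np.where(
        agree,
        np.minimum(ov_qa + ov_qb, MAX_MERGED_QUAL),
        np.abs(ov_qa - ov_qb),
    )
    parts_seq.append(cons)
    parts_q.append(consq)
    if s + L2 > L1:
        parts_seq.append(b[hi - s :])
        parts_q.append(qb[hi - s :])
    merged = np.concatenate(parts_seq)
    quals = np.concatenate(parts_q).astype(np.int16)
    return MergedTemplate(
        sequence=merged.tobytes().decode(),
        qualities=quals,
        overlap_len=best_ov,
        overlap_mismatches=best_mm,
        source_pair_id=pair_id,
    )


def merge_sample(
    fastq1: str | Path,
    fastq2: str | Path,
    params: MergeParams = MergeParams(),
    out_fastq: Optional[str | Path] = None,
) -> tuple[list[MergedTemplate], dict]:
    """Merge a whole paired FASTQ sample.

    Returns the merged templates and a report with the input pair count,
    merged count, and per-reason rejection counts.  Read names (up to the
    ``/1``/``/2`` suffix) must agree pairwise.
    """
    merged: list[MergedTemplate] = []
    report = {
        "input_pairs": 0,
        "merged": 0,
        "rejected": {r: 0 for r in REJECT_REASONS},
    }
    out_fh = open(out_fastq, "w") if out_fastq else None
    try:
        with open(fastq1) as fh1, open(fastq2) as fh2:
            it1 = FastqGeneralIterator(fh1)
            it2 = FastqGeneralIterator(fh2)
            for i, (rec1, rec2) in enumerate(zip_longest(it1, it2)):
                if rec1 is None or rec2 is None:
                    raise ValueError(
                        f"paired FASTQ files differ in length at read index {i}"
                    )
                t1, s1, q1 = rec1
                t2, s2, q2 = rec2
                n1 = t1.split()[0].removesuffix("/1")
                n2 = t2.split()[0].removesuffix("/2")
                if n1 != n2:
                    raise ValueError(
                        f"read pair {i}: mismatched names {n1!r} vs {n2!r}"
                    )
                report["input_pairs"] += 1
                result = merge_pair((s1, q1), (s2, q2), params, pair_id=n1)
                if isinstance(result, MergedTemplate):
                    report["merged"] += 1
                    merged.append(result)
                    if out_fh:
                        qstr = (
                            (np.clip(result.qualities, 0, 60) + 33)
                            .astype(np.uint8)
                            .tobytes()
                            .decode()
                        )
                        out_fh.write(f"@{n1}\n{result.sequence}\n+\n{qstr}\n")
                else:
                    report["rejected"][result.reason] += 1
    finally:
        if out_fh:
            out_fh.close()
    return merged, report
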