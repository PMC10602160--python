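"""Noise-tolerant annotation of merged templates as TRE contigs.

A reconstructed amplicon is the invariant 5' flank, a concatemer of TRE
blocks in either orientation, and the invariant 3' flank.  After the
flanks are located and removed by semi-global edit-distance search, the
interior is segmented by a dynamic program over template positions: each
step either consumes one whole TRE block (in + or - orientation, paying
its edit distance to the template, capped per block) or leaves one base
unannotated at a fixed penalty.  The minimum-cost tiling, decoded left to
right with deterministic tie-breaking, yields the contig string used by
all downstream analysis.

Design notes
------------
* The per-block edit cap scales with block length (``ceil(len/8)``) so
  short elements are not over-permissive.
* Blocks tile without overlap, matching the abutting geometry of blunt
  ligation; gaps are modelled explicitly as unannotated bases instead.
* The default unannotated-base penalty (1.5) is deliberately more
  expensive than a single block edit, so the program prefers a slightly
  imperfect block over punching holes in the tiling.
* Orientation is recorded per block but collapsed for downstream
  counting by default; ``TREContig.render(keep_orientation=True)`` writes
  minus-strand blocks in lowercase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .alphabet import TREAlphabet, revcomp
from .merge import MergedTemplate


@dataclass(frozen=True)
class CallParams:
    max_edits_per_block: Optional[int] = None  # None -> ceil(len/8) per block
    unresolved_penalty: float = 1.5
    max_unresolved_frac: float = 0.1
    max_flank_edits: int = 3
    skip_flank5: bool = False
    skip_flank3: bool = False
    keep_orientation: bool = False


@dataclass
class TREContig:
    contig_string: str
    orientations: tuple[str, ...]
    per_block_edits: tuple[int, ...]
    total_edits: int
    unresolved_nt: int
    template_id: str = ""

    def render(self, keep_orientation: bool = False) -> str:
        if not keep_orientation:
            return self.contig_string
        return "".join(
            c if o == "+" else c.lower()
            for c, o in zip(self.contig_string, self.orientations)
        )


@dataclass(frozen=True)
class CallRejection:
    reason: str  # flank_missing | unresolvable
    template_id: str = ""


class FlankError(ValueError):
    pass


def _block_cap(block_len: int, params: CallParams) -> int:
    if params.max_edits_per_block is not None:
        return params.max_edits_per_block
    return math.ceil(block_len / 8)


def trim_flanks(
    sequence: str,
    alphabet: TREAlphabet,
    max_flank_edits: int = 3,
    skip_flank5: bool = False,
    skip_flank3: bool = False,
) -> str:
    """Locate the invariant flanks near the template ends (within
    ``max_flank_edits`` by semi-global edit distance) and return the
    interior.  Raises :class:`FlankError` when a required flank is absent.
    """
    start = 0
    end = len(sequence)
    if not skip_flank5:
        f5 = alphabet.flank5
        if not f5:
            raise FlankError("alphabet defines no 5' flank; use skip_flank5")
        window = sequence[: len(f5) + max_flank_edits + 8]
        hit = edlib.align(f5, window, mode="HW", task="locations", k=max_flank_edits)
        if hit["editDistance"] < 0:
            raise FlankError("flank_missing")
        start = hit["locations"][0][1] + 1
    if not skip_flank3:
        f3 = alphabet.flank3
        if not f3:
            raise FlankError("alphabet defines no 3' flank; use skip_flank3")
        woff = max(start, len(sequence) - len(f3) - max_flank_edits - 8)
        window = sequence[woff:]
        hit = edlib.align(f3, window, mode="HW", task="locations", k=max_flank_edits)
        if hit["editDistance"] < 0:
            raise FlankError("flank_missing")
        end = woff + hit["locations"][0][0]
    if end < start:
        raise FlankError("flank_missing")
    return sequence[start:end]


def _semiglobal_end_distances(block: np.ndarray, text: np.ndarray) -> np.ndarray:
    """For every end position j (1..L) the minimum edit distance between
    ``block`` and some substring of ``text`` ending at j (free start)."""
    L = text.size
    positions = np.arange(L + 1)
    prev = np.zeros(L + 1, dtype=np.int32)
    for i in range(block.size):
        mism = (text != block[i]).astype(np.int32)
        cand = np.minimum(prev[:-1] + mism, prev[1:] + 1)
        row = np.empty(L + 1, dtype=np.int32)
        row[0] = i + 1
        row[1:] = cand
        # left-to-right insertion relaxation via running minimum
        row = np.minimum.accumulate(row - positions) + positions
        prev = row
    return prev[1:]


def _oriented_blocks(alphabet: TREAlphabet) -> list[tuple[str, str, str]]:
    out = []
    for t in alphabet.tres:
        out.append((t.code, "+", t.sequence))
        out.append((t.code, "-", revcomp(t.sequence)))
    return out


def call_tres(
    interior: str,
    alphabet: TREAlphabet,
    params: CallParams = CallParams(),
    template_id: str = "",
) -> TREContig | CallRejection:
    """Segment a flank-trimmed interior into an ordered TRE contig.

    Ties on total cost are broken by fewer unresolved bases, then at each
    decode step by longer block, + orientation, and alphabetical code.
    """
    if not interior:
        raise ValueError("interior must be non-empty")
    text = np.frombuffer(interior.encode(), dtype=np.uint8)
    L = text.size

    # transitions[j] = list of (start, edits, code, orient, block_len)
    transitions: list[list[tuple[int, int, str, str, int]]] = [
        [] for _ in range(L + 1)
    ]
    for code, orient, bseq in _oriented_blocks(alphabet):
        m = len(bseq)
        cap = _block_cap(m, params)
        barr = np.frombuffer(bseq.encode(), dtype=np.uint8)
        dmin = _semiglobal_end_distances(barr, text)
        for j in np.nonzero(dmin <= cap)[0] + 1:
            j = int(j)
            best: dict[int, int] = {}
            for ell in range(max(1, m - cap), min(j, m + cap) + 1):
                sub = interior[j - ell : j]
                d = edlib.align(bseq, sub, mode="NW", k=cap)["editDistance"]
                if 0 <= d <= cap:
                    p = j - ell
                    if p not in best or d < best[p]:
                        best[p] = d
            for p, d in best.items():
                transitions[j].append((p, d, code, orient, m))

    # forward DP over (cost, unresolved) with lexicographic comparison
    INF = (float("inf"), 0)
    value: list[tuple[float, int]] = [INF] * (L + 1)
    back: list[Optional[tuple]] = [None] * (L + 1)
    value[0] = (0.0, 0)
    pen = params.unresolved_penalty
    for j in range(1, L + 1):
        vc, vu = value[j - 1]
        best_val = (vc + pen, vu + 1)
        best_step = ("gap", j - 1)
        # deterministic candidate order: longer block, then '+', then code
        cands = sorted(
            transitions[j], key=lambda t: (-t[4], t[3] != "+", t[2], t[0])
        )
        for p, d, code, orient, m in cands:
            pc, pu = value[p]
            val = (pc + d, pu)
            if val < best_val:
                best_val = val
                best_step = ("block", p, d, code, orient)
        value[j] = best_val
        back[j] = best_step

    unresolved = value[L][1]
    if unresolved > params.max_unresolved_frac * L:
        return CallRejection("unresolvable", template_id)

    codes: list[str] = []
    orients: list[str] = []
    edits: list[int] = []
    j = L
    while j > 0:
        step = back[j]
        assert step is not None
        if step[0] == "gap":
            j = step[1]
        else:
            _, p, d, code, orient = step
            codes.append(code)
            orients.append(orient)
            edits.append(d)
            j = p
    codes.reverse()
    orients.reverse()
    edits.reverse()
    return TREContig(
        contig_string="".join(codes),
        orientations=tuple(orients),
        per_block_edits=tuple(edits),
        total_edits=sum(edits),
        unresolved_nt=unresolved,
        template_id=template_id,
    )


def call_sample(
    merged: Iterable[MergedTemplate | tuple[str, str]],
    alphabet: TREAlphabet,
    params: CallParams = CallParams(),
) -> tuple[pd.DataFrame, dict]:
    """Call TRE contigs for a stream of merged templates.

    Accepts :class:`MergedTemplate` objects or plain ``(id, sequence)``
    tuples.  Identical sequences are called once and the result shared,
    which makes deep samples with many duplicate templates cheap.
    Returns a tidy table (template_id, contig, orientations, total_edits,
    unresolved_nt) and an accepted/rejected report.
    """
    items: list[tuple[str, str]] = []
    for rec in merged:
        if isinstance(rec, MergedTemplate):
            items.append((rec.source_pair_id, rec.sequence))
        else:
            items.append((rec[0], rec[1]))

    cache: dict[str, TREContig | CallRejection] = {}
    rows = []
    report = {
        "input": len(items),
        "accepted": 0,
        "rejected": {"flank_missing": 0, "unresolvable": 0},
    }
    for rid, seq in items:
        if seq not in cache:
            try:
                interior = trim_flanks(
                    seq,
                    alphabet,
                    params.max_flank_edits,
                    params.skip_flank5,
                    params.skip_flank3,
                )
            except FlankError:
                cache[seq] = CallRejection("flank_missing")
            else:
                if interior:
                    cache[seq] = call_tres(interior, alphabet, params)
                else:
                    cache[seq] = CallRejection("unresolvable")
        res = cache[seq]
        if isinstance(res, TREContig):
            report["accepted"] += 1
            rows.append(
                {
                    "template_id": rid,
                    "contig": res.render(params.keep_orientation),
                    "orientations": "".join(res.orientations),
                    "total_edits": res.total_edits,
                    "unresolved_nt": res.unresolved_nt,
                }
            )
        else:
            report["rejected"][res.reason] += 1
    table = pd.DataFrame(
        rows,
        columns=["template_id", "contig", "orientations", "total_edits", "unresolved_nt"],
    )
    return table, report
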