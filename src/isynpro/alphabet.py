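"""TRE alphabet and shared configuration types.

A synthetic promoter library is built by blunt-end ligation of short
double-stranded oligonucleotides, each encoding a transcription-factor
response element (TRE).  Every element carries a single-letter code so an
assembled promoter can be written as a string over the TRE alphabet (a
"TRE contig").  This module defines the element vocabulary, the invariant
amplicon flanks that surround the variable promoter region, and the
parameter blocks shared by the rest of the pipeline.

The alphabet bundled with the package (``data/synthetic_tre_alphabet.fasta``)
is a synthetic stand-in: eleven consensus-style elements (NF-kB, NFAT,
AP-1, CREB, STAT5, ISRE, RUNX, EGR1, ETS, OCT, SRE) used for testing and
simulation.  Analyses of real libraries should load the actual element
FASTA used at the bench.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml
from Bio import SeqIO

_DNA_RE = re.compile(r"^[ACGT]+$")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class AlphabetError(ValueError):
    """Raised when a TRE alphabet violates its invariants."""


@dataclass(frozen=True)
class TREDefinition:
    """One response element: code letter, name, block sequence, and the
    stoichiometric weight it was ligated at."""

    code: str
    name: str
    sequence: str
    ligation_weight: float

    def __post_init__(self) -> None:
        if not (len(self.code) == 1 and self.code.isalpha() and self.code.isupper()):
            raise AlphabetError(
                f"TRE code must be a single uppercase letter, got {self.code!r}"
            )
        if not _DNA_RE.match(self.sequence):
            raise AlphabetError(
                f"TRE {self.code!r}: sequence must be non-empty uppercase A/C/G/T, "
                f"got {self.sequence!r}"
            )
        if not 5 <= len(self.sequence) <= 25:
            raise AlphabetError(
                f"TRE {self.code!r}: block length {len(self.sequence)} outside 5-25 nt"
            )
        if self.ligation_weight <= 0:
            raise AlphabetError(f"TRE {self.code!r}: ligation_weight must be > 0")


@dataclass(frozen=True)
class TREAlphabet:
    """The full element vocabulary plus the invariant amplicon flanks.

    Validation rejects any pair of elements whose sequences are equal or
    reverse complements of each other (including self-palindromic blocks),
    because orientation-aware calling would then be ambiguous, and flanks
    that contain an element sequence.
    """

    tres: tuple[TREDefinition, ...]
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        codes = [t.code for t in self.tres]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise AlphabetError(f"duplicate TRE code(s): {sorted(dupes)}")
        for i, t in enumerate(self.tres):
            if t.sequence == revcomp(t.sequence):
                raise AlphabetError(
                    f"TRE {t.code!r} is self reverse-complementary; orientation "
                    "cannot be resolved"
                )
            for u in self.tres[i + 1 :]:
                if t.sequence == u.sequence or t.sequence == revcomp(u.sequence):
                    raise AlphabetError(
                        f"TREs {t.code!r} and {u.code!r} collide (equal or reverse "
                        "complement sequences)"
                    )
        for flank, label in ((self.flank5, "flank5"), (self.flank3, "flank3")):
            if flank and not _DNA_RE.match(flank):
                raise AlphabetError(f"{label} must be uppercase A/C/G/T")
            for t in self.tres:
                if t.sequence in flank or revcomp(t.sequence) in flank:
                    raise AlphabetError(
                        f"{label} contains TRE {t.code!r} as a substring"
                    )

    # -- lookups -------------------------------------------------------
    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(t.code for t in self.tres)

    def __len__(self) -> int:
        return len(self.tres)

    def __getitem__(self, code: str) -> TREDefinition:
        for t in self.tres:
            if t.code == code:
                return t
        raise KeyError(code)

    def __contains__(self, code: str) -> bool:
        return any(t.code == code for t in self.tres)

    def block_length(self, code: str) -> int:
        return len(self[code].sequence)

    def oriented_sequence(self, code: str, orientation: str) -> str:
        """Block sequence as it appears on the template strand."""
        seq = self[code].sequence
        if orientation == "+":
            return seq
        if orientation == "-":
            return revcomp(seq)
        raise ValueError(f"orientation must be '+' or '-', got {orientation!r}")

    def weights(self) -> dict[str, float]:
        return {t.code: t.ligation_weight for t in self.tres}


@dataclass(frozen=True)
class LigationSpec:
    """Parameters of the random blunt-ligation assembly and gel size
    selection.

    ``weights`` defaults to the alphabet's own ligation weights.  The size
    window bounds the promoter interior (flanks excluded), in nucleotides;
    ``mean_blocks`` is the expected element count of a ligation product
    before size gating.
    """

    weights: Optional[Mapping[str, float]] = None
    min_len_nt: int = 200
    max_len_nt: int = 500
    mean_blocks: float = 35.0

    def __post_init__(self) -> None:
        if not self.min_len_nt < self.max_len_nt:
            raise ValueError("min_len_nt must be < max_len_nt")
        if self.mean_blocks < 1:
            raise ValueError("mean_blocks must be >= 1")

    def resolved_weights(self, alphabet: TREAlphabet) -> dict[str, float]:
        if self.weights is None:
            return alphabet.weights()
        unknown = set(self.weights) - set(alphabet.codes)
        if unknown:
            raise AlphabetError(f"weights for unknown code(s): {sorted(unknown)}")
        return dict(self.weights)


@dataclass(frozen=True)
class SelectionThresholds:
    """The three-rule candidate filter plus the low-abundance detection
    floor used before trajectory clustering.

    Defaults: a candidate must (i) reach a baseline frequency of at least
    0.001 in the viral library, (ii) show a fold change above 1.25 at two
    or more post-stimulation timepoints, and (iii) sit within the top 90%
    cumulative abundance of the pooled cell library.  Contigs never seen
    at >= 4 CPM at any post-stimulation timepoint are treated as
    minimally detected and dropped from clustering.
    """

    min_baseline_freq: float = 0.001
    min_fold_change: float = 1.25
    min_timepoints_above: int = 2
    cumulative_mass: float = 0.90
    min_cpm_detect: float = 4.0

    def __post_init__(self) -> None:
        if min(
            self.min_baseline_freq,
            self.min_fold_change,
            self.min_timepoints_above,
            self.cumulative_mass,
            self.min_cpm_detect,
        ) <= 0:
            raise ValueError("all selection thresholds must be strictly positive")
        if not 0 < self.cumulative_mass <= 1:
            raise ValueError("cumulative_mass must be in (0, 1]")


_HEADER_RE = re.compile(r"name=(?P<name>\S+)")
_WEIGHT_RE = re.compile(r"weight=(?P<weight>[0-9.eE+-]+)")


def default_config() -> dict:
    """The YAML configuration bundled with the synthetic fixture alphabet."""
    with resources.files("isynpro.data").joinpath("default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_alphabet(
    path: Optional[str | Path] = None, config: Optional[Mapping] = None
) -> TREAlphabet:
    """Load a TRE alphabet from a FASTA with ``>CODE name=<text> weight=<float>``
    headers.

    When ``path`` is omitted, the bundled synthetic fixture of eleven
    consensus-style elements is returned.  ``config`` supplies the
    invariant flanks (keys ``flank5``/``flank3``); it defaults to the
    bundled configuration.
    """
    cfg = dict(default_config())
    if config:
        cfg.update(config)
    if path is None:
        source = resources.files("isynpro.data").joinpath(
            "synthetic_tre_alphabet.fasta"
        )
        with source.open() as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))

    tres = []
    for rec in records:
        name_m = _HEADER_RE.search(rec.description)
        weight_m = _WEIGHT_RE.search(rec.description)
        name = name_m.group("name") if name_m else rec.id
        weight = float(weight_m.group("weight")) if weight_m else 1.0
        seq = str(rec.seq).upper()
        if not _DNA_RE.match(seq):
            raise AlphabetError(
                f"record {rec.id!r}: sequence contains non-A/C/G/T characters "
                f"({seq!r})"
            )
        tres.append(TREDefinition(rec.id, name, seq, weight))
    return TREAlphabet(
        tres=tuple(tres),
        flank5=str(cfg.get("flank5", "")),
        flank3=str(cfg.get("flank3", "")),
    )


def template_nt_length(contig: str | Iterable[str], alphabet: TREAlphabet) -> int:
    """Nucleotide length of a TRE contig: the sum of its block lengths
    (flanks excluded).  Accepts a code string or any iterable of codes."""
    total = 0
    for code in contig:
        total += alphabet.block_length(code)  # KeyError for unknown codes
    return total
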