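"""Generative model of the promoter-library screen.

The generator emulates every stage of library construction and selection
for which no public sequencing data exist, retaining ground truth at each
step so that downstream modules can be tested against known answers:

* random blunt ligation of TRE blocks at their stoichiometric weights,
  with random per-block orientation and gel size selection of the
  concatemer interior;
* a clonal bottleneck at the plasmid stage with Dirichlet-multinomial
  skew (differential clonal expansion after bacterial transformation);
* a lentiviral packaging bias toward shorter templates, modelled as an
  exponential reweighting in template length;
* per-timepoint multiplicative enrichment or depletion of clones in the
  sorted GFP+ cell populations, with multinomial read sampling; and
* 300 bp paired-end reads with a substitution-only error model and
  Gaussian Phred qualities.

All randomness flows from a single seed; rerunning with the same seed is
byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import LigationSpec, TREAlphabet, revcomp

CELL_TIMEPOINTS = ("t24", "t48", "t72", "restim")
REFERENCE_SAMPLES = ("raw", "plasmid", "virus")
ALL_SAMPLES = REFERENCE_SAMPLES + CELL_TIMEPOINTS


@dataclass(frozen=True)
class PromoterTemplate:
    """Ground-truth promoter: ordered (code, orientation) blocks plus the
    full nucleotide sequence including both flanks."""

    template_id: str
    blocks: tuple[tuple[str, str], ...]
    sequence: str
    interior_len: int

    @property
    def contig(self) -> str:
        """Orientation-collapsed TRE contig string."""
        return "".join(code for code, _ in self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def nt_len(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PlantSpec:
    """How to plant known selection dynamics into a simulated screen.

    A handful of clones become inducible (multiplier > 1 at the listed
    timepoints) and a larger fraction is mildly depleted at later
    timepoints, mirroring a screen in which most promoters fade while a
    few are enriched.  Inducible clones are drawn preferentially from
    contigs rich in ``favor_code`` (the NF-kB letter in the fixture
    alphabet), planting a sequence-to-behavior association for the
    enrichment stage to recover.
    """

    n_inducible: int = 15
    inducible_mult_range: tuple[float, float] = (3.0, 6.0)
    inducible_timepoints: tuple[str, ...] = CELL_TIMEPOINTS
    min_baseline_freq: float = 0.002
    depleted_frac: float = 0.30
    depleted_mult_range: tuple[float, float] = (0.5, 0.8)
    depleted_timepoints: tuple[str, ...] = ("t48", "t72", "restim")
    favor_code: Optional[str] = "A"


@dataclass(frozen=True)
class ScreenSimSpec:
    """Study conditions for one simulated screen."""

    n_raw_templates: int = 2000
    plasmid_bottleneck_size: int = 300
    skew_dirichlet_alpha: float = 0.7
    packaging_length_bias: float = 0.002  # per-nt log-odds against longer templates
    timepoints: tuple[str, ...] = CELL_TIMEPOINTS
    plant: Optional[PlantSpec] = field(default_factory=PlantSpec)
    planted_multipliers: Optional[Mapping[str, Mapping[str, float]]] = None
    reads_per_sample: int = 100_000
    read_len: int = 300
    per_base_error_rate: float = 0.005
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raw_templates <= 0 or self.reads_per_sample <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.plasmid_bottleneck_size <= self.n_raw_templates:
            raise ValueError(
                "plasmid_bottleneck_size must be in (0, n_raw_templates]"
            )
        if self.packaging_length_bias < 0:
            raise ValueError("packaging_length_bias must be >= 0")


def simulate_ligation(
    alphabet: TREAlphabet,
    spec: LigationSpec,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[PromoterTemplate]:
    """Draw ``n`` size-selected ligation products.

    Block codes are i.i.d. proportional to ligation weight, orientations
    are fair coin flips (blunt double-stranded ligation), and the block
    count is geometric with mean ``spec.mean_blocks``.  Products whose
    interior falls outside the size window are discarded and redrawn.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = spec.resolved_weights(alphabet)
    codes = list(weights)
    probs = np.array([weights[c] for c in codes], dtype=float)
    probs /= probs.sum()
    lengths = np.array([alphabet.block_length(c) for c in codes])

    templates: list[PromoterTemplate] = []
    p_geo = 1.0 / spec.mean_blocks
    while len(templates) < n:
        k = int(rng.geometric(p_geo))
        idx = rng.choice(len(codes), size=k, p=probs)
        interior_len = int(lengths[idx].sum())
        if not spec.min_len_nt <= interior_len <= spec.max_len_nt:
            continue
        orients = np.where(rng.random(k) < 0.5, "+", "-")
        blocks = tuple((codes[i], o) for i, o in zip(idx, orients))
        interior = "".join(
            alphabet.oriented_sequence(code, o) for code, o in blocks
        )
        seq = alphabet.flank5 + interior + alphabet.flank3
        templates.append(
            PromoterTemplate(
                template_id=f"T{len(templates):05d}",
                blocks=blocks,
                sequence=seq,
                interior_len=interior_len,
            )
        )
    return templates


@dataclass
class ScreenResult:
    """Per-sample read counts plus the ground-truth manifest."""

    counts: pd.DataFrame  # rows template_id, columns samples
    manifest: pd.DataFrame  # per-template truth
    templates: list[PromoterTemplate]
    spec: ScreenSimSpec

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)


def _plant_multipliers(
    plant: PlantSpec,
    ids: Sequence[str],
    contigs: Mapping[str, str],
    virus_freq: Mapping[str, float],
    timepoints: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, dict[str, float]]:
    mult: dict[str, dict[str, float]] = {}
    eligible = [i for i in ids if virus_freq[i] >= plant.min_baseline_freq]
    if plant.n_inducible > 0 and eligible:
        if plant.favor_code:
            w = np.array(
                [1.0 + contigs[i].count(plant.favor_code) for i in eligible]
            )
            w /= w.sum()
        else:
            w = None
        n_pick = min(plant.n_inducible, len(eligible))
        picked = rng.choice(eligible, size=n_pick, replace=False, p=w)
        lo, hi = plant.inducible_mult_range
        for i in picked:
            m = float(rng.uniform(lo, hi))
            mult[str(i)] = {
                tp: m for tp in plant.inducible_timepoints if tp in timepoints
            }
    rest = [i for i in ids if i not in mult]
    n_dep = int(round(plant.depleted_frac * len(rest)))
    if n_dep:
        dep = rng.choice(rest, size=n_dep, replace=False)
        lo, hi = plant.depleted_mult_range
        for i in dep:
            m = float(rng.uniform(lo, hi))
            mult[str(i)] = {
                tp: m for tp in plant.depleted_timepoints if tp in timepoints
            }
    return mult


def simulate_screen(
    templates: Sequence[PromoterTemplate], spec: ScreenSimSpec
) -> ScreenResult:
    """Propagate a template pool through the bottlenecks and selection
    stages of the screen and sample read counts for every library."""
    for tp in spec.timepoints:
        if tp not in CELL_TIMEPOINTS:
            raise ValueError(f"unknown timepoint label {tp!r}")
    rng = np.random.default_rng(spec.seed)
    ids = [t.template_id for t in templates]
    contigs = {t.template_id: t.contig for t in templates}
    nt_len = np.array([t.nt_len for t in templates], dtype=float)
    n = len(templates)

    # raw ligation product: each molecule unique, uniform frequencies
    raw_freq = np.full(n, 1.0 / n)

    # plasmid bottleneck: subset of clones, Dirichlet-skewed expansion
    b = spec.plasmid_bottleneck_size
    keep = np.sort(rng.choice(n, size=b, replace=False))
    plasmid_freq = np.zeros(n)
    plasmid_freq[keep] = rng.dirichlet(
        np.full(b, spec.skew_dirichlet_alpha)
    )

    # lentiviral packaging: exponential penalty in template length
    virus_w = plasmid_freq * np.exp(-spec.packaging_length_bias * nt_len)
    virus_freq = virus_w / virus_w.sum()

    # planted selection dynamics
    if spec.planted_multipliers is not None:
        multipliers = {
            str(k): dict(v) for k, v in spec.planted_multipliers.items()
        }
    elif spec.plant is not None:
        vf = {ids[i]: virus_freq[i] for i in range(n)}
        multipliers = _plant_multipliers(
            spec.plant, [ids[i] for i in keep], contigs, vf, spec.timepoints, rng
        )
    else:
        multipliers = {}

    freqs = {"raw": raw_freq, "plasmid": plasmid_freq, "virus": virus_freq}
    for tp in spec.timepoints:
        m = np.array([multipliers.get(i, {}).get(tp, 1.0) for i in ids])
        w = virus_freq * m
        freqs[tp] = w / w.sum()

    samples = list(REFERENCE_SAMPLES) + list(spec.timepoints)
    counts = pd.DataFrame(index=pd.Index(ids, name="template_id"))
    for s in samples:
        counts[s] = rng.multinomial(spec.reads_per_sample, freqs[s])

    manifest = pd.DataFrame(
        {
            "template_id": ids,
            "contig": [contigs[i] for i in ids],
            "n_blocks": [t.n_blocks for t in templates],
            "nt_len": nt_len.astype(int),
            "interior_len": [t.interior_len for t in templates],
            "in_bottleneck": np.isin(np.arange(n), keep),
        }
    ).set_index("template_id")
    for tp in spec.timepoints:
        manifest[f"multiplier_{tp}"] = [
            multipliers.get(i, {}).get(tp, 1.0) for i in ids
        ]
    for s in samples:
        manifest[f"freq_{s}"] = freqs[s]
    return ScreenResult(counts=counts, manifest=manifest, templates=list(templates), spec=spec)


# ---------------------------------------------------------------------------
# read simulation

_PHRED_OFFSET = 33


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in hits:
            choices = bases[bases != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _qual_string(length: int, spec: ScreenSimSpec, rng: np.random.Generator) -> str:
    q = np.clip(
        np.rint(rng.normal(spec.quality_mean, spec.quality_sd, size=length)), 2, 40
    ).astype(np.uint8)
    return (q + _PHRED_OFFSET).tobytes().decode()


def simulate_reads(
    templates: Sequence[PromoterTemplate],
    counts: Mapping[str, int] | pd.Series,
    spec: ScreenSimSpec,
    out_prefix: str | Path,
    seed: Optional[int | np.random.Generator] = None,
) -> dict[str, Path]:
    """Write paired FASTQ for one sample plus a ground-truth sidecar TSV.

    R1 is the first ``read_len`` bases of the template and R2 the reverse
    complement of the last ``read_len`` bases; both are truncated to the
    template length when the template is shorter (emulating adapter
    read-through trimmed upstream).  Substitution errors are i.i.d. at
    ``per_base_error_rate``.  Read names carry only a running pair index;
    the template of origin is recorded in the sidecar, never in the name.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(spec.seed if seed is None else seed)
    )
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    by_id = {t.template_id: t for t in templates}

    pool: list[str] = []
    for tid, c in (counts.items() if hasattr(counts, "items") else counts):
        pool.extend([tid] * int(c))
    order = rng.permutation(len(pool))

    p1 = out_prefix.with_name(out_prefix.name + "_R1.fastq")
    p2 = out_prefix.with_name(out_prefix.name + "_R2.fastq")
    ptruth = out_prefix.with_name(out_prefix.name + "_truth.tsv")
    with open(p1, "w") as f1, open(p2, "w") as f2, open(ptruth, "w") as ft:
        truth = csv.writer(ft, delimiter="\t", lineterminator="\n")
        truth.writerow(["read_id", "template_id"])
        for k, j in enumerate(order):
            t = by_id[pool[j]]
            L = min(spec.read_len, t.nt_len)
            r1 = _mutate(t.sequence[:L], spec.per_base_error_rate, rng)
            r2 = _mutate(
                revcomp(t.sequence[-L:]), spec.per_base_error_rate, rng
            )
            name = f"read_{k:08d}"
            f1.write(f"@{name}/1\n{r1}\n+\n{_qual_string(L, spec, rng)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{_qual_string(L, spec, rng)}\n")
            truth.writerow([name, t.template_id])
    return {"r1": p1, "r2": p2, "truth": ptruth}


def simulate_sample_fastqs(
    screen: ScreenResult, out_dir: str | Path
) -> pd.DataFrame:
    """Write paired FASTQ for every sample of a simulated screen and a
    sample sheet TSV mapping samples to files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(screen.spec.seed)
    children = ss.spawn(len(screen.samples))
    rows = []
    for child, sample in zip(children, screen.samples):
        paths = simulate_reads(
            screen.templates,
            screen.counts[sample],
            screen.spec,
            out_dir / sample,
            seed=np.random.default_rng(child),
        )
        role = sample if sample in REFERENCE_SAMPLES else "cell"
        tp = sample if sample not in REFERENCE_SAMPLES else "-"
        rows.append(
            {
                "sample": sample,
                "role": role,
                "timepoint": tp,
                "fastq1": str(paths["r1"]),
                "fastq2": str(paths["r2"]),
            }
        )
    sheet = pd.DataFrame(rows)
    sheet.to_csv(out_dir / "sample_sheet.tsv", sep="\t", index=False)
    return sheet
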