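"""End-to-end orchestration: simulate -> merge -> call -> quantify ->
dynamics -> enrich -> select, under one configuration and one seed.

Each stage writes its outputs under a stage-named subdirectory of the
run directory, the validated configuration is persisted verbatim, and a
summary JSON aggregates the headline numbers.  The global seed fans out
to per-stage seeds through ``numpy.random.SeedSequence(seed).spawn``, so
stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .alphabet import LigationSpec, SelectionThresholds, load_alphabet
from .caller import CallParams, call_sample
from .dynamics import build_trajectories, cluster_trajectories, hopkins, trajectory_projection
from .enrichment import fisher_enrichment, select_candidates
from .merge import MergeParams, merge_sample
from .quantify import (
    build_counts,
    length_comparison,
    library_correlation,
    lorenz_gini,
    tre_proportions,
)
from .simulate import ScreenSimSpec, simulate_ligation, simulate_sample_fastqs, simulate_screen

log = logging.getLogger("isynpro")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: Path
    alphabet_fasta: Optional[Path] = None
    alphabet_config: Optional[dict] = None
    seed: int = 0
    ligation: LigationSpec = field(default_factory=LigationSpec)
    sim: ScreenSimSpec = field(default_factory=ScreenSimSpec)
    merge: MergeParams = field(default_factory=MergeParams)
    call: CallParams = field(default_factory=CallParams)
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    motif_k: int = 3
    k_range: tuple[int, int] = (2, 15)
    cluster_method: str = "ward"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        kwargs = {}
        for key, sub_cls in [
            ("ligation", LigationSpec),
            ("sim", ScreenSimSpec),
            ("merge", MergeParams),
            ("call", CallParams),
            ("thresholds", SelectionThresholds),
        ]:
            if key in raw:
                block = raw.pop(key)
                kwargs[key] = sub_cls(**block) if isinstance(block, dict) else block
        for key in ("out_dir", "alphabet_fasta"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        kwargs.update(raw)
        if "k_range" in kwargs:
            kwargs["k_range"] = tuple(kwargs["k_range"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _stage_seed(root: int, index: int) -> int:
    return int(np.random.SeedSequence(root).spawn(index + 1)[index].generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full screen analysis on simulated data; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    alphabet = load_alphabet(config.alphabet_fasta, config.alphabet_config)
    summary: dict = {"seed": config.seed}

    # -- simulate -----------------------------------------------------
    log.info("stage simulate")
    sim_dir = out / "simulate"
    templates = simulate_ligation(
        alphabet, config.ligation, config.sim.n_raw_templates,
        seed=_stage_seed(config.seed, 0),
    )
    sim_spec = dataclasses.replace(config.sim, seed=_stage_seed(config.seed, 1))
    screen = simulate_screen(templates, sim_spec)
    sheet = simulate_sample_fastqs(screen, sim_dir)
    screen.manifest.to_csv(sim_dir / "manifest.tsv", sep="\t")

    # -- merge + call -------------------------------------------------
    merged_dir = out / "merge"
    call_dir = out / "call"
    merged_dir.mkdir(exist_ok=True)
    call_dir.mkdir(exist_ok=True)
    per_sample_contigs = {}
    merge_rates, call_rates = {}, {}
    for row in sheet.itertuples():
        log.info("merging and calling sample %s", row.sample)
        merged, mreport = merge_sample(
            row.fastq1, row.fastq2, config.merge,
            out_fastq=merged_dir / f"{row.sample}.fastq",
        )
        table, creport = call_sample(merged, alphabet, config.call)
        table.to_csv(call_dir / f"{row.sample}.tsv", sep="\t", index=False)
        per_sample_contigs[row.sample] = table["contig"]
        merge_rates[row.sample] = mreport
        call_rates[row.sample] = creport
    summary["merge"] = {
        s: {"input_pairs": r["input_pairs"], "merged": r["merged"]}
        for s, r in merge_rates.items()
    }
    summary["call"] = {
        s: {"input": r["input"], "accepted": r["accepted"]}
        for s, r in call_rates.items()
    }

    # -- quantify -----------------------------------------------------
    log.info("stage quantify")
    quant_dir = out / "quantify"
    quant_dir.mkdir(exist_ok=True)
    matrix = build_counts(
        {s: pd.Series(list(v)).value_counts() for s, v in per_sample_contigs.items()}
    )
    matrix.counts.to_csv(quant_dir / "counts.tsv", sep="\t")
    gini = {s: lorenz_gini(matrix.counts[s]).gini for s in matrix.samples}
    _, cv, cv_summary = tre_proportions(
        matrix, alphabet, [tp for tp in sim_spec.timepoints if tp in matrix.samples]
    )
    corr_r, _ = library_correlation(matrix, "plasmid", "virus")
    lc = length_comparison(matrix, alphabet, "t72", "virus")
    summary["quantify"] = {
        "gini": gini,
        "tre_cv": cv_summary,
        "plasmid_virus_log_corr": corr_r,
        "length_comparison_t72_vs_virus": lc,
    }

    # -- dynamics -----------------------------------------------------
    log.info("stage dynamics")
    dyn_dir = out / "dynamics"
    dyn_dir.mkdir(exist_ok=True)
    traj = build_trajectories(matrix, config.thresholds)
    traj.log2fc.to_csv(dyn_dir / "trajectories.tsv", sep="\t")
    trajectory_projection(matrix, retained=traj.retained.index).to_csv(
        dyn_dir / "projection.tsv", sep="\t"
    )
    hres = hopkins(traj.retained, seed=_stage_seed(config.seed, 2))
    with open(dyn_dir / "hopkins.json", "w") as fh:
        json.dump(dataclasses.asdict(hres), fh, indent=2)
    clusters = cluster_trajectories(
        traj, range(config.k_range[0], config.k_range[1] + 1),
        method=config.cluster_method, seed=_stage_seed(config.seed, 3),
    )
    clusters.labels.to_csv(dyn_dir / "clusters.tsv", sep="\t")
    pd.Series(clusters.silhouettes, name="silhouette").rename_axis("k").to_csv(
        dyn_dir / "silhouette_vs_k.tsv", sep="\t"
    )
    summary["dynamics"] = {
        "n_retained": int(traj.detect_mask.sum()),
        "hopkins_H": hres.H,
        "hopkins_p": hres.p_value,
        "chosen_k": clusters.k,
    }

    # -- enrich + select ----------------------------------------------
    log.info("stage enrich/select")
    sel_dir = out / "select"
    sel_dir.mkdir(exist_ok=True)
    enrichment = {}
    if clusters.k >= 2:
        for k in (1, config.motif_k):
            table = fisher_enrichment(clusters, k=k)
            table.to_csv(sel_dir / f"enrichment_k{k}.tsv", sep="\t", index=False)
            enrichment[f"k{k}_hits_q05"] = int((table["q_value"] < 0.05).sum())
    candidates = select_candidates(matrix, traj, config.thresholds)
    candidates.to_csv(sel_dir / "candidates.tsv", sep="\t")
    summary["selection"] = {
        "n_candidates": int(candidates["selected"].sum()),
        **enrichment,
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
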