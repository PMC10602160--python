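import dataclasses

import numpy as np
import pytest

from isynpro import (
    LigationSpec,
    MergedTemplate,
    PlantSpec,
    ScreenSimSpec,
    merge_sample,
    simulate_ligation,
    simulate_reads,
    simulate_screen,
)


class TestSimulateLigation:
    def test_block_usage_follows_ligation_weights(self, alphabet):
        # NF-kB is ligated at 6x, ten other elements at 2x each -> its
        # expected share of all drawn blocks is 6/26.
        templates = simulate_ligation(alphabet, LigationSpec(), 400, seed=11)
        letters = "".join(t.contig for t in templates)
        frac_a = letters.count("A") / len(letters)
        expected = 6 / 26
        se = np.sqrt(expected * (1 - expected) / len(letters))
        assert abs(frac_a - expected) < 5 * se

    def test_size_selection_window(self, small_templates):
        assert all(200 <= t.interior_len <= 500 for t in small_templates)

    def test_sequence_reconstructible_from_blocks(self, alphabet, small_templates):
        for t in small_templates[:20]:
            interior = "".join(
                alphabet.oriented_sequence(code, o) for code, o in t.blocks
            )
            assert t.sequence == alphabet.flank5 + interior + alphabet.flank3
            assert t.interior_len == len(interior)

    def test_same_seed_is_deterministic(self, alphabet):
        a = simulate_ligation(alphabet, LigationSpec(), 50, seed=3)
        b = simulate_ligation(alphabet, LigationSpec(), 50, seed=3)
        assert [t.sequence for t in a] == [t.sequence for t in b]

    def test_rejects_nonpositive_n(self, alphabet):
        with pytest.raises(ValueError):
            simulate_ligation(alphabet, LigationSpec(), 0, seed=1)


def neutral_spec(n, **kw):
    defaults = dict(
        n_raw_templates=n,
        plasmid_bottleneck_size=min(50, n),
        packaging_length_bias=0.0,
        plant=None,
        reads_per_sample=100_000,
        seed=5,
    )
    defaults.update(kw)
    return ScreenSimSpec(**defaults)


class TestSimulateScreen:
    def test_neutral_dynamics_tracks_virus(self, small_templates):
        screen = simulate_screen(small_templates, neutral_spec(len(small_templates)))
        m = screen.manifest
        for tp in ("t24", "t48", "t72", "restim"):
            np.testing.assert_allclose(
                m[f"freq_{tp}"], m["freq_virus"], rtol=0, atol=1e-12
            )

    def test_planted_multiplier_shifts_expected_frequency(self, small_templates):
        # One clone at multiplier 4 at t24 only: its expected t24 frequency
        # is 4 f / (1 + 3 f) where f is its virus frequency; other
        # timepoints stay at baseline.  Verified against the multinomial
        # draw within sampling error.
        base = neutral_spec(len(small_templates))
        probe = simulate_screen(small_templates, base)
        tid = probe.manifest["freq_virus"].idxmax()
        # same seed as the probe run so the bottleneck subset is identical
        spec = dataclasses.replace(base, planted_multipliers={tid: {"t24": 4.0}})
        screen = simulate_screen(small_templates, spec)
        f = screen.manifest.loc[tid, "freq_virus"]
        expected = 4 * f / (1 + 3 * f)
        assert screen.manifest.loc[tid, "freq_t24"] == pytest.approx(expected)
        assert screen.manifest.loc[tid, "freq_t48"] == pytest.approx(f)
        n = spec.reads_per_sample
        observed = screen.counts.loc[tid, "t24"] / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 5 * se

    def test_packaging_bias_shortens_virus_library(self, small_templates):
        spec = neutral_spec(len(small_templates), packaging_length_bias=0.01)
        screen = simulate_screen(small_templates, spec)
        m = screen.manifest
        mean_len_plasmid = np.average(m["nt_len"], weights=m["freq_plasmid"])
        mean_len_virus = np.average(m["nt_len"], weights=m["freq_virus"])
        assert mean_len_virus < mean_len_plasmid

    def test_unknown_timepoint_rejected(self, small_templates):
        with pytest.raises(ValueError, match="timepoint"):
            simulate_screen(
                small_templates, neutral_spec(len(small_templates), timepoints=("t96",))
            )

    def test_planting_prefers_favored_code(self, small_templates):
        spec = neutral_spec(
            len(small_templates),
            plant=PlantSpec(n_inducible=20, min_baseline_freq=0.0, favor_code="A"),
        )
        screen = simulate_screen(small_templates, spec)
        m = screen.manifest
        inducible = m["multiplier_t24"] > 1
        assert inducible.sum() == 20
        a_frac_ind = np.mean([c.count("A") / len(c) for c in m.loc[inducible, "contig"]])
        a_frac_all = np.mean([c.count("A") / len(c) for c in m["contig"]])
        assert a_frac_ind > a_frac_all


class TestSimulateReads:
    def test_noiseless_reads_round_trip(self, alphabet, small_templates, tmp_path):
        spec = neutral_spec(len(small_templates), per_base_error_rate=0.0)
        subset = small_templates[:30]
        counts = {t.template_id: 2 for t in subset}
        paths = simulate_reads(subset, counts, spec, tmp_path / "s", seed=9)
        merged, report = merge_sample(paths["r1"], paths["r2"])
        assert report["merged"] == report["input_pairs"] == 60
        truth = dict(
            line.split("\t")
            for line in paths["truth"].read_text().splitlines()[1:]
        )
        by_id = {t.template_id: t.sequence for t in subset}
        for m in merged:
            assert m.sequence == by_id[truth[m.source_pair_id]]

    def test_true_overlap_length(self, alphabet, small_templates, tmp_path):
        # a template of length T sequenced as 300 bp pairs overlaps by 600 - T
        t = next(t for t in small_templates if t.nt_len > 300)
        spec = neutral_spec(len(small_templates), per_base_error_rate=0.0)
        paths = simulate_reads([t], {t.template_id: 1}, spec, tmp_path / "o", seed=2)
        merged, _ = merge_sample(paths["r1"], paths["r2"])
        assert merged[0].overlap_len == 600 - t.nt_len

    def test_substitution_rate_matches_error_model(self, small_templates, tmp_path):
        rate = 0.005
        spec = neutral_spec(
            len(small_templates), per_base_error_rate=rate, read_len=300
        )
        subset = small_templates[:50]
        counts = {t.template_id: 200 for t in subset}  # 10,000 pairs
        paths = simulate_reads(subset, counts, spec, tmp_path / "e", seed=4)
        truth = dict(
            line.split("\t")
            for line in paths["truth"].read_text().splitlines()[1:]
        )
        by_id = {t.template_id: t for t in subset}
        mismatches = bases = 0
        with open(paths["r1"]) as fh:
            lines = fh.read().splitlines()
        for name_line, seq in zip(lines[::4], lines[1::4]):
            t = by_id[truth[name_line[1:].removesuffix("/1")]]
            ref = t.sequence[: len(seq)]
            mismatches += sum(a != b for a, b in zip(seq, ref))
            bases += len(seq)
        observed = mismatches / bases
        assert abs(observed - rate) / rate < 0.20

    def test_reads_deterministic_given_seed(self, small_templates, tmp_path):
        spec = neutral_spec(len(small_templates))
        subset = small_templates[:5]
        counts = {t.template_id: 3 for t in subset}
        p1 = simulate_reads(subset, counts, spec, tmp_path / "a", seed=8)
        p2 = simulate_reads(subset, counts, spec, tmp_path / "b", seed=8)
        assert p1["r1"].read_text() == p2["r1"].read_text()
        assert p1["r2"].read_text() == p2["r2"].read_text()
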