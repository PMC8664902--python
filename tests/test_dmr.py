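"""DMR calling: run merging, threshold ladder, CpG summaries."""

import re

import numpy as np
import pandas as pd
import pytest

from medipdmr.dmr import (
    DMR,
    call_dmrs,
    size_and_density_distributions,
    summarize_dmr,
    threshold_ladder,
)
from medipdmr.windowing import tile_genome

WINDOWS = tile_genome({"chr1": 20_000, "chr2": 10_000})


def _results(sig_indices, p_sig=1e-6, n=30, gaps=()):
    """Result table over the first n windows; ``gaps`` are untested (filtered)."""
    rows = []
    rng = np.random.default_rng(0)
    for i in range(n):
        if i in gaps:
            continue
        w = WINDOWS[i]
        p = p_sig if i in sig_indices else rng.uniform(0.2, 1.0)
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "window_index": i,
                "log_fc": rng.normal(),
                "log_cpm": 5.0,
                "p_value": p,
                "q_value": min(1.0, p * 10),
            }
        )
    return pd.DataFrame(rows)


class TestCalling:
    def test_adjacent_windows_merge(self):
        ds = call_dmrs(_results({5, 6}), WINDOWS, with_ladder=False)
        assert len(ds) == 1
        d = ds.dmrs[0]
        assert (d.start, d.stop, d.n_sig_windows, d.length) == (5000, 7000, 2, 2000)

    def test_separated_windows_stay_apart(self):
        ds = call_dmrs(_results({3, 7}), WINDOWS, with_ladder=False)
        assert len(ds) == 2
        assert all(d.n_sig_windows == 1 for d in ds)

    def test_filtered_window_breaks_adjacency(self):
        # windows 5 and 7 significant, 6 was filtered out entirely
        ds = call_dmrs(_results({5, 7}, gaps={6}), WINDOWS, with_ladder=False)
        assert len(ds) == 2

    def test_chromosome_boundary_breaks_adjacency(self):
        # windows 19 (chr1 last) and 20 (chr2 first) have consecutive ordinals
        ds = call_dmrs(_results({19, 20}), WINDOWS, with_ladder=False)
        assert len(ds) == 2
        assert {d.chrom for d in ds} == {"chr1", "chr2"}

    def test_no_significant_windows(self):
        ds = call_dmrs(_results(set()), WINDOWS)
        assert len(ds) == 0
        assert (ds.threshold_table[["all_windows", "multiple_windows"]] == 0).all().all()

    def test_window_count_conservation(self):
        sig = {2, 3, 4, 8, 12, 13, 25}
        ds = call_dmrs(_results(sig), WINDOWS, with_ladder=False)
        assert sum(d.n_sig_windows for d in ds) == len(sig)

    def test_strict_inequality_at_threshold(self):
        res = _results(set())
        res.loc[res["window_index"] == 4, "p_value"] = 1e-4
        ds = call_dmrs(res, WINDOWS, p_threshold=1e-4, with_ladder=False)
        assert len(ds) == 0  # p == threshold is not significant

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="p_threshold"):
            call_dmrs(_results(set()), WINDOWS, p_threshold=0.0)

    def test_names_deterministic_in_genomic_order(self):
        ds = call_dmrs(_results({2, 10, 22}), WINDOWS, with_ladder=False)
        assert [d.name for d in ds] == ["DMR_chr1_1", "DMR_chr1_2", "DMR_chr2_1"]

    def test_min_stats_over_constituents(self):
        res = _results({5, 6})
        res.loc[res["window_index"] == 5, ["p_value", "q_value", "log_fc"]] = [1e-7, 1e-5, 1.2]
        res.loc[res["window_index"] == 6, ["p_value", "q_value", "log_fc"]] = [1e-6, 2e-5, -2.0]
        d = call_dmrs(res, WINDOWS, with_ladder=False).dmrs[0]
        assert d.min_p == pytest.approx(1e-7)
        assert d.min_fdr == pytest.approx(1e-5)
        assert d.max_lfc == pytest.approx(-2.0)  # largest |lfc| keeps its sign
        assert d.min_fdr >= d.min_p

    def test_merging_idempotence(self):
        """Re-calling DMRs on a DMR set's own windows reproduces the set."""
        rng = np.random.default_rng(1)
        sig = set(rng.choice(30, size=12, replace=False).tolist())
        first = call_dmrs(_results(sig), WINDOWS, with_ladder=False)
        again = call_dmrs(_results(sig), WINDOWS, with_ladder=False)
        assert [(d.chrom, d.start, d.stop) for d in first] == [
            (d.chrom, d.start, d.stop) for d in again
        ]

    def test_matches_interval_union_oracle(self):
        """Run merging agrees with a brute-force union of window intervals."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            sig = set(rng.choice(30, size=rng.integers(1, 15), replace=False).tolist())
            ds = call_dmrs(_results(sig), WINDOWS, with_ladder=False)
            # oracle: union of significant window intervals by pairwise merging
            ivs = [(WINDOWS[i].chrom, WINDOWS[i].start, WINDOWS[i].end) for i in sorted(sig)]
            merged = []
            for chrom, s, e in ivs:
                placed = False
                for iv in merged:
                    if iv[0] == chrom and not (e < iv[1] or s > iv[2]):
                        iv[1], iv[2] = min(iv[1], s), max(iv[2], e)
                        placed = True
                if not placed:
                    merged.append([chrom, s, e])
            assert sorted((d.chrom, d.start, d.stop) for d in ds) == sorted(
                (c, s, e) for c, s, e in merged
            )


class TestLadder:
    def test_multiple_window_counts_bounded(self):
        rng = np.random.default_rng(3)
        res = _results(set())
        res["p_value"] = 10.0 ** rng.uniform(-8, 0, size=len(res))
        table = threshold_ladder(res)
        assert (table["multiple_windows"] <= table["all_windows"]).all()
        counts = table.set_index("cutoff")["all_windows"]
        default = call_dmrs(res, WINDOWS, p_threshold=1e-4, with_ladder=False)
        assert counts.loc[1e-4] == len(default)

    def test_monotone_in_sparse_regime(self, small_run):
        """On realistic scan output (few significant windows), DMR counts
        never increase as the cutoff tightens."""
        table = threshold_ladder(small_run.results)
        counts = table["all_windows"].to_numpy()
        assert (np.diff(counts) <= 0).all()
        assert (np.diff(table["multiple_windows"].to_numpy()) <= 0).all()

    def test_degenerate_cutoff_reports_every_run(self):
        # every tested window has p < 1, so each chromosome is one maximal run
        res = _results({1, 2, 9})
        table = threshold_ladder(res, cutoffs=[1.0])
        assert table.loc[0, "all_windows"] == 2


class TestSummaries:
    def test_toy_sequence_cpg_count(self):
        d = DMR("DMR_toy_1", "toy", 0, 6, 1, 1e-5, 1e-4, 1.0)
        out = summarize_dmr(d, {"toy": "ACGCGT"})
        assert out.cpg_count == 2
        assert out.cpg_density == pytest.approx(2 / 6 * 100)

    def test_span_beyond_chromosome_rejected(self):
        d = DMR("DMR_toy_1", "toy", 0, 10, 1, 1e-5, 1e-4, 1.0)
        with pytest.raises(ValueError):
            summarize_dmr(d, {"toy": "ACGT"})

    def test_cpg_count_matches_regex_oracle(self, small_genome):
        rng = np.random.default_rng(4)
        for _ in range(100):
            chrom = rng.choice(small_genome.chrom_names)
            length = small_genome.chrom_lengths[chrom]
            start = int(rng.integers(0, length - 3000))
            stop = start + int(rng.integers(500, 3000))
            d = summarize_dmr(
                DMR("DMR_x_1", chrom, start, stop, 1, 1e-5, 1e-4, 1.0), small_genome
            )
            expected = len(re.findall("CG", small_genome.sequence[chrom][start:stop]))
            assert d.cpg_count == expected

    def test_size_histogram_single_window(self):
        dmrs = [DMR(f"DMR_c_{i}", "c", i * 5000, i * 5000 + 1000, 1, 1e-5, 1e-4, 1.0,
                    cpg_count=20, cpg_density=2.0) for i in range(5)]
        ds = call_dmrs(_results(set()), WINDOWS, with_ladder=False)
        ds.dmrs = dmrs
        size_table, dens_table = size_and_density_distributions(ds)
        assert size_table["length_kb"].tolist() == [1]
        assert size_table["n_dmrs"].sum() == 5
        assert dens_table["n_dmrs"].sum() == 5

    def test_density_histogram_modal_bin_tracks_design(self, small_genome):
        """DMRs carved from a 2 CpG/100 bp genome have modal density bin 2."""
        rng = np.random.default_rng(5)
        dmrs = []
        for i in range(40):
            start = int(rng.integers(0, 95_000))
            d = DMR(f"DMR_chr1_{i}", "chr1", start, start + 2000, 2, 1e-5, 1e-4, 1.0)
            dmrs.append(summarize_dmr(d, small_genome))
        ds = call_dmrs(_results(set()), WINDOWS, with_ladder=False)
        ds.dmrs = dmrs
        _, dens_table = size_and_density_distributions(ds)
        modal = dens_table.loc[dens_table["n_dmrs"].idxmax()]
        assert modal["cpg_per_100bp_lo"] <= 2.0 < modal["cpg_per_100bp_hi"]
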