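"""Per-gene density normalization, metagene ramp, wave profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from riboprof import (
    SimulationConfig,
    Transcriptome,
    assign_sites,
    gene_density,
    metagene_profile,
    simulate_footprints,
    simulate_transcriptome,
    wave_profile,
)

from conftest import assigned_from_sites, make_transcript


def make_gene_with_counts(counts, tid="t1", seed=0):
    """A gene whose per-codon A-site counts equal ``counts``."""
    t = make_transcript(tid, n_codons=len(counts), utr5=30, utr3=30, seed=seed)
    sites = [j for j, c in enumerate(counts) for _ in range(c)]
    assigned = assigned_from_sites(t, sites) if sites else assigned_from_sites(t, [])
    return t, assigned


class TestGeneDensity:
    def test_density_normalization(self):
        t, assigned = make_gene_with_counts([2, 0, 4, 2])
        d = gene_density(assigned, t)
        np.testing.assert_allclose(d.density, [1.0, 0.0, 2.0, 1.0])
        assert d.total_reads == 8

    def test_uniform_counts_give_unit_density(self):
        t = make_transcript("t3", n_codons=3)
        a = assigned_from_sites(t, [0, 1, 2] * 3)
        d = gene_density(a, t)
        np.testing.assert_allclose(d.density, [1.0, 1.0, 1.0])

    def test_zero_read_gene_flagged(self):
        t = make_transcript("t0", n_codons=4)
        a = assigned_from_sites(t, [])
        d = gene_density(a, t)
        assert d.zero_read and np.all(d.density == 0)

    @given(st.lists(st.integers(0, 20), min_size=3, max_size=40).filter(lambda c: sum(c) > 0))
    def test_mean_density_is_one(self, counts):
        """Eq.-1 conservation: mean density is exactly 1 for any read pattern."""
        t, assigned = make_gene_with_counts(counts)
        d = gene_density(assigned, t)
        assert abs(d.density.mean() - 1.0) < 1e-9


class TestMetageneProfile:
    def test_two_gene_average(self):
        t1 = make_transcript("t1", n_codons=4, seed=1)
        t2 = make_transcript("t2", n_codons=4, seed=2)
        tx = Transcriptome([t1, t2])
        a = pd.concat(
            [
                assigned_from_sites(t1, [0, 2, 2, 3]),  # F=[1,0,2,1] -> D=[1,0,2,1]
                assigned_from_sites(t2, [0, 1, 1, 3]),  # F=[1,2,0,1] -> D=[1,2,0,1]
            ]
        )
        prof = metagene_profile(a, tx, "start", window=4, min_reads=0, min_len=4)
        np.testing.assert_allclose(prof.values, [1.0, 1.0, 1.0, 1.0])
        assert prof.n_genes == 2

    def test_scale_invariance(self):
        """Duplicating a gene's reads by a constant leaves A_j unchanged."""
        t1 = make_transcript("t1", n_codons=6, seed=1)
        t2 = make_transcript("t2", n_codons=6, seed=2)
        tx = Transcriptome([t1, t2])
        sites1, sites2 = [0, 1, 1, 4], [2, 3, 5, 5]
        a = pd.concat([assigned_from_sites(t1, sites1), assigned_from_sites(t2, sites2)])
        a_scaled = pd.concat(
            [assigned_from_sites(t1, sites1 * 5), assigned_from_sites(t2, sites2)]
        )
        p1 = metagene_profile(a, tx, "start", window=6, min_reads=0, min_len=6)
        p2 = metagene_profile(a_scaled, tx, "start", window=6, min_reads=0, min_len=6)
        np.testing.assert_allclose(p1.values, p2.values)

    def test_stop_anchor_uses_last_codons(self):
        t = make_transcript("t1", n_codons=10)
        tx = Transcriptome([t])
        a = assigned_from_sites(t, [8, 8, 9, 9])  # reads only near the stop
        prof = metagene_profile(a, tx, "stop", window=4, min_reads=0, min_len=4)
        np.testing.assert_allclose(prof.values, [0.0, 0.0, 5.0, 5.0])

    def test_no_passing_genes_raises(self):
        t = make_transcript("t1", n_codons=10)
        tx = Transcriptome([t])
        a = assigned_from_sites(t, [1, 2])
        with pytest.raises(ValueError, match="64"):
            metagene_profile(a, tx, "start", window=4, min_reads=64, min_len=4)

    def test_start_accumulation_elevates_only_first_offsets(self):
        """A multiplier on codons 0-2 shows up at offsets <= 3 only."""
        cfg = SimulationConfig(
            seed=17, n_genes=100, orf_min_codons=100, orf_max_codons=150,
            expression_sigma=0.0, start_multiplier=5.0, total_footprints=500_000,
        )
        tx = simulate_transcriptome(cfg)
        sim = simulate_footprints(tx, cfg)
        a = assign_sites(sim.alignments[["transcript_id", "five_prime", "length"]], tx).assignments
        prof = metagene_profile(a, tx, "start", window=100, min_reads=64, min_len=100)
        assert prof.values[:3].min() > 2.0
        assert np.abs(prof.values[3:] - prof.values[3:].mean()).max() < 0.3


class TestWaveProfile:
    def test_uniform_gene_with_one_cga_is_flat(self):
        codons = ["GCT"] * 98
        codons[49] = "CGA"  # codon index 50 in the full CDS (after ATG)
        t = make_transcript("t1", n_codons=100, codons=codons)
        tx = Transcriptome([t])
        a = assigned_from_sites(t, list(range(100)))  # uniform D = 1
        prof = wave_profile(a, tx, "CGA", min_reads=0, exclude_edges=20)
        assert prof.n_occurrences == 1
        valid = ~np.isnan(prof.enrichment)
        np.testing.assert_allclose(prof.enrichment[valid], 1.0)

    def test_zero_occurrences_raises(self):
        t = make_transcript("t1", n_codons=100, codons=["GCT"] * 98)
        tx = Transcriptome([t])
        a = assigned_from_sites(t, list(range(100)))
        with pytest.raises(ValueError, match="CGA"):
            wave_profile(a, tx, "CGA", min_reads=0, exclude_edges=20)

    def test_invalid_codon_rejected(self, small_sim):
        _, tx, _, assigned = small_sim
        with pytest.raises(ValueError):
            wave_profile(assigned, tx, "XYZ")

    def test_edge_occurrences_skipped(self):
        codons = ["GCT"] * 98
        codons[2] = "CGA"  # codon 3, inside the 20-codon edge zone
        codons[49] = "CGA"
        t = make_transcript("t1", n_codons=100, codons=codons)
        tx = Transcriptome([t])
        a = assigned_from_sites(t, list(range(100)))
        prof = wave_profile(a, tx, "CGA", min_reads=0, exclude_edges=20)
        assert prof.n_occurrences == 1
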