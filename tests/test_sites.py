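"""Frame-dependent A-site assignment rules."""

import numpy as np
import pandas as pd
import pytest

from riboprof import (
    SimulationConfig,
    Transcriptome,
    assign_sites,
    simulate_footprints,
    simulate_transcriptome,
)
from riboprof.types import UTR_EXTENSION_CODONS

from conftest import make_transcript


def brute_force_assign(fp, length, rec, long_range=(29, 31), short_range=(21, 22)):
    """Per-read oracle: locate the A-site nucleotides within the footprint,
    then find the codon containing them on the transcript's codon grid."""
    if long_range[0] <= length <= long_range[1]:
        klass = "long"
    elif short_range[0] <= length <= short_range[1]:
        klass = "short"
    else:
        return None
    frame = (fp - rec.cds_start) % 3
    if frame == 0:
        a_first_nt = fp + 15  # footprint nt 16-18
    elif frame == 2:
        a_first_nt = fp + 16  # footprint nt 17-19
    else:
        return None
    a = (a_first_nt - rec.cds_start) // 3  # codon grid, floor division
    if a < -UTR_EXTENSION_CODONS or a > rec.n_codons + UTR_EXTENSION_CODONS:
        return None
    return a, klass, ("frame0" if frame == 0 else "frameMinus1")


@pytest.fixture()
def one_gene():
    t = make_transcript("t1", n_codons=60, utr5=40, utr3=40)
    return t, Transcriptome([t])


def _assign_one(tx, tid, five_prime, length):
    aln = pd.DataFrame({"transcript_id": [tid], "five_prime": [five_prime], "length": [length]})
    return assign_sites(aln, tx)


class TestOffsetRules:
    def test_frame0_a_site_is_sixth_codon(self, one_gene):
        t, tx = one_gene
        res = _assign_one(tx, "t1", t.cds_start, 30)
        row = res.assignments.iloc[0]
        assert row.frame_class == "frame0"
        assert row.a_site_codon == 5  # footprint nt 16-18 = 6th codon

    def test_frame_minus1_a_site(self, one_gene):
        t, tx = one_gene
        res = _assign_one(tx, "t1", t.cds_start + 2, 30)
        row = res.assignments.iloc[0]
        assert row.frame_class == "frameMinus1"
        assert row.a_site_codon == 6  # footprint nt 17-19

    def test_frame_plus1_discarded(self, one_gene):
        t, tx = one_gene
        res = _assign_one(tx, "t1", t.cds_start + 1, 30)
        assert res.assignments.empty
        assert res.stats.n_frame_plus1 == 1

    def test_length_outside_both_classes_discarded(self, one_gene):
        t, tx = one_gene
        res = _assign_one(tx, "t1", t.cds_start, 25)
        assert res.assignments.empty and res.stats.n_bad_length == 1

    def test_short_class_label(self, one_gene):
        t, tx = one_gene
        res = _assign_one(tx, "t1", t.cds_start, 21)
        assert res.assignments.iloc[0].footprint_class == "short"

    def test_beyond_utr_extension_dropped(self, one_gene):
        t, tx = one_gene
        # A-site codon would be -7, past the 18-nt extension
        res = _assign_one(tx, "t1", t.cds_start - 36, 30)
        assert res.assignments.empty and res.stats.n_outside_extension == 1

    def test_unknown_transcript_raises(self, one_gene):
        _, tx = one_gene
        with pytest.raises(KeyError, match="ghost"):
            _assign_one(tx, "ghost", 0, 30)

    def test_a_site_codon_is_integer_dtype(self, one_gene):
        t, tx = one_gene
        res = _assign_one(tx, "t1", t.cds_start + 2, 30)
        assert np.issubdtype(res.assignments["a_site_codon"].dtype, np.integer)


class TestOracleAgreement:
    def test_matches_brute_force_on_random_footprints(self):
        """Vectorized assignment equals the per-read oracle exactly."""
        cfg = SimulationConfig(seed=13, n_genes=20, orf_min_codons=50, orf_max_codons=120)
        tx = simulate_transcriptome(cfg)
        rng = np.random.default_rng(99)
        ids = tx.ids
        n = 2000
        tids, fps, lens = [], [], []
        for _ in range(n):
            tid = ids[rng.integers(len(ids))]
            rec = tx[tid]
            length = int(rng.integers(18, 36))
            fp = int(rng.integers(0, len(rec.sequence) - length))
            tids.append(tid)
            fps.append(fp)
            lens.append(length)
        aln = pd.DataFrame({"transcript_id": tids, "five_prime": fps, "length": lens})
        res = assign_sites(aln, tx)
        expected = []
        for tid, fp, length in zip(tids, fps, lens):
            out = brute_force_assign(fp, length, tx[tid])
            if out is not None:
                expected.append((tid, out[0], out[1], out[2]))
        got = list(
            zip(
                res.assignments["transcript_id"],
                res.assignments["a_site_codon"],
                res.assignments["footprint_class"],
                res.assignments["frame_class"],
            )
        )
        assert got == expected

    def test_simulator_roundtrip_exact(self, small_sim):
        """Every emitted frame-0/-1 footprint is re-assigned to the codon
        it was drawn from."""
        _, tx, sim, _ = small_sim
        res = assign_sites(sim.alignments[["transcript_id", "five_prime", "length"]], tx)
        keep = sim.alignments["true_frame"].to_numpy() != 1
        assert res.stats.n_assigned == int(keep.sum())
        np.testing.assert_array_equal(
            res.assignments["a_site_codon"].to_numpy(),
            sim.alignments["true_a_site"].to_numpy()[keep],
        )
        assert (
            res.assignments["footprint_class"].to_numpy()
            == sim.alignments["true_class"].to_numpy()[keep]
        ).all()
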