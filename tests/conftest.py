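"""Shared fixtures: toy transcripts and small simulated libraries."""

import numpy as np
import pandas as pd
import pytest

from riboprof import (
    SimulationConfig,
    TranscriptRecord,
    Transcriptome,
    assign_sites,
    simulate_footprints,
    simulate_transcriptome,
)

from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_transcript(tid="tx1", n_codons=40, utr5=30, utr3=30, codons=None, seed=0):
    """A valid transcript with ATG start, chosen body codons, TAA stop."""
    rng = np.random.default_rng(seed)
    sense = [c for c in _sense() if c not in ("ATG",)]
    if codons is None:
        codons = [sense[i] for i in rng.integers(0, len(sense), n_codons - 2)]
    body = "".join(codons)
    cds = "ATG" + body + "TAA"
    nts = "ACGT"
    pad5 = "".join(nts[i] for i in rng.integers(0, 4, utr5))
    pad3 = "".join(nts[i] for i in rng.integers(0, 4, utr3))
    return TranscriptRecord(tid, pad5 + cds + pad3, utr5, utr5 + len(cds))


def _sense():
    from riboprof import SENSE_CODONS

    return SENSE_CODONS


def alignments_from_sites(transcript, a_codons, length=30):
    """Frame-0 alignments whose A-sites land on the given codon indices."""
    fp = [transcript.cds_start + 3 * j - 15 for j in a_codons]
    return pd.DataFrame(
        {
            "transcript_id": transcript.transcript_id,
            "five_prime": fp,
            "length": length,
        }
    )


def assigned_from_sites(transcript, a_codons, length=30):
    tx = Transcriptome([transcript])
    aln = alignments_from_sites(transcript, a_codons, length)
    return assign_sites(aln, tx).assignments


@pytest.fixture(scope="session")
def small_sim():
    """50-gene, 100k-read library with all phenomenology off (flat model)."""
    cfg = SimulationConfig(seed=7, n_genes=50, total_footprints=100_000)
    tx = simulate_transcriptome(cfg)
    sim = simulate_footprints(tx, cfg)
    assigned = assign_sites(
        sim.alignments[["transcript_id", "five_prime", "length"]], tx
    ).assignments
    return cfg, tx, sim, assigned
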