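"""End-to-end convenience pipeline: simulate → QC → assign → profiles → counts.

Every output is a deterministic TSV: the same config (including seed)
produces byte-identical files, which is what makes the whole chain usable
as a regression harness.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from . import counting, io as rio, occupancy, profiles, sites
from .simulate import SimulationConfig, simulate_footprints, simulate_transcriptome

FLOAT_FMT = "%.8g"


def run_pipeline(
    config: SimulationConfig,
    outdir,
    wave_codon: str = "CGA",
    min_reads: int = 64,
    min_len: int = 200,
    window: int = 200,
) -> None:
    """Run the full analysis chain on a simulated library, writing TSVs.

    Writes: qc.tsv, assignments.tsv, ramp_start.tsv, ramp_stop.tsv,
    occupancy_A_long.tsv, wave_<codon>.tsv, counts.tsv, utr_counts.tsv.
    The metagene window is capped at the shortest simulated ORF so the
    chain also runs on small test configurations.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tx = simulate_transcriptome(config)
    sim = simulate_footprints(tx, config)
    aln = sim.alignments[["transcript_id", "five_prime", "length"]]

    qc = rio.frame_length_qc(aln, tx)
    qc.table.to_csv(out / "qc.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    assigned = sites.assign_sites(aln, tx).assignments
    assigned.to_csv(out / "assignments.tsv", sep="\t", index=False)

    window = min(window, config.orf_min_codons)
    min_len = min(min_len, config.orf_min_codons)
    for anchor in ("start", "stop"):
        prof = profiles.metagene_profile(
            assigned, tx, anchor=anchor, window=window, min_reads=min_reads,
            min_len=min_len, footprint_class="long",
        )
        prof.to_frame().to_csv(
            out / f"ramp_{anchor}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )

    occ = occupancy.codon_occupancy(assigned, tx, site="A", footprint_class="long", min_reads=min_reads)
    occ.table.to_csv(out / "occupancy_A_long.tsv", sep="\t", float_format=FLOAT_FMT)

    wave = profiles.wave_profile(
        assigned, tx, wave_codon, min_reads=min_reads,
        exclude_edges=min(20, config.orf_min_codons // 4), footprint_class="long",
    )
    wave.to_frame().to_csv(
        out / f"wave_{wave_codon}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    counted = sites.assign_sites(aln, tx, long_range=counting.COUNT_CLASS_RANGES["long"]).assignments
    mat = counting.build_count_matrix(
        {
            "long": counting.gene_counts(counted, tx, "long"),
            "short": counting.gene_counts(counted, tx, "short"),
        }
    )
    mat.to_csv(out / "counts.tsv", sep="\t")
    counting.utr5_counts(counted, tx).to_frame().to_csv(out / "utr_counts.tsv", sep="\t")
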