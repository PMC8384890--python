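"""Frame-dependent A/P/E-site assignment of footprints to codons.

The A-site is anchored at the footprint 5′ end according to its reading
frame relative to the annotated start: footprints whose 5′ end is codon-
aligned (frame 0) decode nucleotides 16–18 of the footprint in their
A-site; footprints whose 5′ end sits one nucleotide into the previous
codon (frame −1, i.e. ``(five_prime - cds_start) mod 3 == 2``) decode
nucleotides 17–19. In 0-based transcript coordinates:

    frame 0:  a_site_codon = (five_prime - cds_start + 15) / 3
    frame −1: a_site_codon = (five_prime - cds_start + 16) / 3

Both numerators are divisible by 3 in their frame, so the codon index is
always exact. Frame +1 footprints have no defined offset and are dropped
(counted). The P- and E-site codons trail the A-site by one and two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd

from .types import Transcriptome, UTR_EXTENSION_CODONS

#: Default footprint-class length ranges (nt), inclusive. The long range is
#: the human one; mouse (30–32) and yeast (27–29) are set via `long_range`.
LONG_RANGE = (29, 31)
SHORT_RANGE = (21, 22)

#: A-site first-nucleotide offset from the footprint 5′ end, per frame
#: (0-based; the field's 1-based "position 16" and "position 17").
A_SITE_OFFSET = {0: 15, 2: 16}

FRAME_LABELS = {0: "frame0", 2: "frameMinus1"}


@dataclass
class AssignmentStats:
    """Drop counters from :func:`assign_sites`."""

    n_input: int = 0
    n_assigned: int = 0
    n_bad_length: int = 0
    n_frame_plus1: int = 0
    n_outside_extension: int = 0


@dataclass
class AssignmentResult:
    """Assigned footprints plus drop accounting.

    ``assignments`` columns: transcript_id, five_prime, length,
    footprint_class (short/long), frame_class (frame0/frameMinus1),
    a_site_codon (0-based codon index relative to cds_start; negative in
    the 5′ UTR, ``>= L`` at termination). P/E-site codon indices are
    ``a_site_codon - 1`` and ``- 2``.
    """

    assignments: pd.DataFrame
    stats: AssignmentStats = field(default_factory=AssignmentStats)


def assign_sites(
    alignments: pd.DataFrame,
    transcriptome: Transcriptome,
    long_range: Tuple[int, int] = LONG_RANGE,
    short_range: Tuple[int, int] = SHORT_RANGE,
) -> AssignmentResult:
    """Assign footprints to A-site codons by 5′-end frame.

    Footprints with lengths outside both class ranges, in frame +1, or
    with an A-site beyond the 18-nt UTR extension (codon index outside
    ``[-6, L + 6]``) are discarded and counted. Unknown transcript ids
    raise ``KeyError``.
    """
    stats = AssignmentStats(n_input=len(alignments))
    if alignments.empty:
        empty = pd.DataFrame(
            {
                "transcript_id": pd.Series(dtype=str),
                "five_prime": pd.Series(dtype=np.int64),
                "length": pd.Series(dtype=np.int64),
                "footprint_class": pd.Series(dtype=str),
                "frame_class": pd.Series(dtype=str),
                "a_site_codon": pd.Series(dtype=np.int64),
            }
        )
        return AssignmentResult(empty, stats)

    codes, uniq = pd.factorize(alignments["transcript_id"], sort=False)
    cds_start = np.empty(len(uniq), dtype=np.int64)
    n_codons = np.empty(len(uniq), dtype=np.int64)
    for i, tid in enumerate(uniq):
        rec = transcriptome[tid]  # KeyError names the offending id
        cds_start[i] = rec.cds_start
        n_codons[i] = rec.n_codons

    fp = alignments["five_prime"].to_numpy(dtype=np.int64)
    ln = alignments["length"].to_numpy(dtype=np.int64)
    rel = fp - cds_start[codes]
    frame = np.mod(rel, 3)

    is_long = (ln >= long_range[0]) & (ln <= long_range[1])
    is_short = (ln >= short_range[0]) & (ln <= short_range[1])
    good_len = is_long | is_short
    stats.n_bad_length = int(np.sum(~good_len))

    good_frame = frame != 1
    stats.n_frame_plus1 = int(np.sum(good_len & ~good_frame))

    keep = good_len & good_frame
    # numerators are divisible by 3 by construction of the per-frame offset
    offset = np.where(frame == 0, 15, 16)
    a_codon = (rel + offset) // 3

    ext = UTR_EXTENSION_CODONS
    in_ext = (a_codon >= -ext) & (a_codon <= n_codons[codes] + ext)
    stats.n_outside_extension = int(np.sum(keep & ~in_ext))
    keep &= in_ext
    stats.n_assigned = int(keep.sum())

    out = pd.DataFrame(
        {
            "transcript_id": np.asarray(uniq, dtype=object)[codes[keep]],
            "five_prime": fp[keep],
            "length": ln[keep],
            "footprint_class": np.where(is_long[keep], "long", "short"),
            "frame_class": np.where(frame[keep] == 0, FRAME_LABELS[0], FRAME_LABELS[2]),
            "a_site_codon": a_codon[keep],
        }
    )
    out.reset_index(drop=True, inplace=True)
    return AssignmentResult(out, stats)


def write_assignments(result: AssignmentResult, path) -> None:
    """Write the assignment table as TSV."""
    result.assignments.to_csv(path, sep="\t", index=False)
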