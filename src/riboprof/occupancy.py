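"""Transcriptome-wide codon occupancy per ribosomal site, and comparisons.

Occupancy of codon ``c`` at a site is the mean per-gene-normalized density
over all retained codon positions whose codon at that site is ``c``,
pooled across well-expressed genes. The A-site of a ribosome whose
A-site codon index is ``j`` reads codon ``j``; its P- and E-sites read
codons ``j-1`` and ``j-2``, so P/E occupancy relabels each position's
density by the codon one or two positions upstream.

Positions in the first ``exclude_first`` and last ``exclude_last`` codons
are skipped (start/stop accumulation would otherwise leak into codon
preferences), and the density is renormalized over the retained window so
the position-weighted mean occupancy is exactly 1.

Cross-condition agreement is summarized as signed R² = sign(r)·r² of the
Pearson correlation over shared sense codons; the sign is kept because
anti-correlated occupancy does occur between protocols.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .types import (
    CODONS,
    CODON_TO_AA,
    STOP_CODONS,
    CodonOccupancyTable,
    OccupancyComparison,
    Transcriptome,
)

SITE_SHIFT = {"A": 0, "P": -1, "E": -2}


def codon_occupancy(
    assignments: pd.DataFrame,
    transcriptome: Transcriptome,
    site: str = "A",
    footprint_class: Optional[str] = None,
    min_reads: int = 64,
    exclude_first: int = 15,
    exclude_last: int = 5,
) -> CodonOccupancyTable:
    """Per-codon mean normalized density at the A-, P- or E-site.

    Genes contribute if they carry more than ``min_reads`` A-site-assigned
    footprints in the CDS. Codons with no contributing positions are
    reported as missing (NaN), not zero.
    """
    if site not in SITE_SHIFT:
        raise ValueError(f"site must be one of A, P, E; got {site!r}")
    shift = SITE_SHIFT[site]

    sub = assignments
    if footprint_class is not None:
        sub = sub[sub["footprint_class"] == footprint_class]
    grouped = {
        tid: g["a_site_codon"].to_numpy(dtype=np.int64)
        for tid, g in sub.groupby("transcript_id", sort=False)
    }

    sum_d = np.zeros(64)
    n_pos = np.zeros(64, dtype=np.int64)
    n_reads = np.zeros(64, dtype=np.int64)

    for tid in transcriptome.ids:
        rec = transcriptome[tid]
        L = rec.n_codons
        a = grouped.get(tid)
        if a is None:
            continue
        inside = a[(a >= 0) & (a < L)]
        if inside.size <= min_reads:
            continue
        counts = np.bincount(inside, minlength=L).astype(np.float64)
        j0, j1 = exclude_first, L - exclude_last
        if j1 - j0 < 1:
            continue
        window = counts[j0:j1]
        tot = window.sum()
        if tot == 0:
            continue
        dens = window * (j1 - j0) / tot
        # codon read at the requested site for a ribosome positioned at j
        labels = transcriptome.codon_ids(tid)[j0 + shift : j1 + shift]
        np.add.at(sum_d, labels, dens)
        np.add.at(n_pos, labels, 1)
        np.add.at(n_reads, labels, window.astype(np.int64))

    with np.errstate(invalid="ignore"):
        occ = np.where(n_pos > 0, sum_d / np.maximum(n_pos, 1), np.nan)
    table = pd.DataFrame(
        {
            "amino_acid": [CODON_TO_AA[c] for c in CODONS],
            "occupancy": occ,
            "n_positions": n_pos,
            "n_reads": n_reads,
        },
        index=pd.Index(CODONS, name="codon"),
    )
    return CodonOccupancyTable(site=site, footprint_class=footprint_class, table=table)


def compare_occupancy(
    table_x: CodonOccupancyTable,
    table_y: CodonOccupancyTable,
    use_stops: bool = False,
) -> OccupancyComparison:
    """Signed-R² Pearson comparison of two occupancy tables.

    Codons missing in either table are dropped pairwise; stop codons are
    excluded unless ``use_stops``. Requires at least 4 shared codons.
    ``crossed_out`` is True when the correlation p-value exceeds 0.05.
    """
    if table_x.site != table_y.site:
        raise ValueError(
            f"tables are from different sites ({table_x.site} vs {table_y.site})"
        )
    x = table_x.occupancy()
    y = table_y.occupancy()
    pairs = pd.DataFrame({"x": x, "y": y}).dropna()
    if not use_stops:
        pairs = pairs.drop(index=[c for c in STOP_CODONS if c in pairs.index])
    if len(pairs) < 4:
        raise ValueError(f"only {len(pairs)} shared codons; need at least 4")
    res = sstats.pearsonr(pairs["x"], pairs["y"])
    r = float(res.statistic)
    p = float(res.pvalue)
    return OccupancyComparison(
        signed_r2=float(np.sign(r) * r * r),
        r=r,
        p_value=p,
        n_codons=len(pairs),
        crossed_out=bool(p > 0.05),
        pairs=pairs,
    )
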