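"""Per-gene density normalization, metagene ramp, and wave profiles.

The per-gene normalized density of codon position ``j`` in gene ``i`` is

    D_ij = F_ij / ((sum_j F_ij) / L_i)

where ``F_ij`` counts A-site-assigned footprints and ``L_i`` is the ORF
length in codons, so the mean density over each gene is exactly 1. The
metagene profile averages these densities over well-expressed genes at
each aligned offset:

    A_j = (sum_i D_ij) / N

restricted to genes with more than ``min_reads`` assigned footprints and
at least ``min_len`` codons. Wave profiles average ``D_i,(k+d)`` over all
occurrences ``k`` of a query codon to expose excess ribosome density
downstream of that codon.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .types import GeneDensity, MetageneProfile, TranscriptRecord, Transcriptome, WaveProfile, CODONS


def _cds_counts(a_codons: np.ndarray, n_codons: int) -> np.ndarray:
    """A-site footprint counts per CDS codon (UTR/termination hits ignored)."""
    inside = a_codons[(a_codons >= 0) & (a_codons < n_codons)]
    return np.bincount(inside, minlength=n_codons).astype(np.float64)


def gene_density(
    assignments: pd.DataFrame,
    gene: TranscriptRecord,
    footprint_class: Optional[str] = None,
) -> GeneDensity:
    """Normalized A-site density over one gene's ORF.

    Only footprints assigned to this gene with ``a_site_codon`` inside
    ``[0, L)`` contribute. A zero-read gene yields an all-zero density
    with ``zero_read=True``.
    """
    if gene.n_codons == 0:
        raise ValueError(f"{gene.transcript_id}: zero-length ORF")
    sub = assignments[assignments["transcript_id"] == gene.transcript_id]
    if footprint_class is not None:
        sub = sub[sub["footprint_class"] == footprint_class]
    counts = _cds_counts(sub["a_site_codon"].to_numpy(dtype=np.int64), gene.n_codons)
    total = int(counts.sum())
    if total == 0:
        density = np.zeros(gene.n_codons)
        return GeneDensity(gene.transcript_id, gene.n_codons, counts, density, 0, zero_read=True)
    density = counts * gene.n_codons / total
    return GeneDensity(gene.transcript_id, gene.n_codons, counts, density, total)


def gene_densities(
    assignments: pd.DataFrame,
    transcriptome: Transcriptome,
    min_reads: int = 64,
    footprint_class: Optional[str] = None,
) -> Dict[str, GeneDensity]:
    """Eq.-1 densities for every gene with more than ``min_reads`` footprints.

    Returns a dict keyed by transcript id, in transcriptome order.
    """
    sub = assignments
    if footprint_class is not None:
        sub = sub[sub["footprint_class"] == footprint_class]
    grouped = {tid: g["a_site_codon"].to_numpy(dtype=np.int64) for tid, g in sub.groupby("transcript_id", sort=False)}
    out: Dict[str, GeneDensity] = {}
    for tid in transcriptome.ids:
        rec = transcriptome[tid]
        counts = _cds_counts(grouped.get(tid, np.empty(0, dtype=np.int64)), rec.n_codons)
        total = int(counts.sum())
        if total <= min_reads:
            continue
        out[tid] = GeneDensity(tid, rec.n_codons, counts, counts * rec.n_codons / total, total)
    return out


def metagene_profile(
    assignments: pd.DataFrame,
    transcriptome: Transcriptome,
    anchor: str = "start",
    window: int = 200,
    min_reads: int = 64,
    min_len: int = 200,
    footprint_class: Optional[str] = None,
) -> MetageneProfile:
    """Average normalized density per codon offset across genes.

    ``anchor='start'`` averages codons 1..window from the start codon;
    ``anchor='stop'`` the last ``window`` codons aligned at the stop.
    Genes need more than ``min_reads`` assigned footprints in the CDS and
    at least ``max(min_len, window)`` codons. 95% CI per offset is the
    normal approximation across contributing genes.
    """
    if anchor not in ("start", "stop"):
        raise ValueError(f"anchor must be 'start' or 'stop', got {anchor!r}")
    need_len = max(min_len, window)
    dens = gene_densities(assignments, transcriptome, min_reads, footprint_class)
    rows = [d.density[:window] if anchor == "start" else d.density[-window:]
            for d in dens.values() if d.n_codons >= need_len]
    if not rows:
        raise ValueError(
            f"no genes pass the metagene filters (> {min_reads} reads, >= {need_len} codons)"
        )
    mat = np.vstack(rows)
    n = mat.shape[0]
    values = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(window)
    offsets = np.arange(1, window + 1)
    return MetageneProfile(
        anchor=anchor,
        offsets=offsets,
        values=values,
        ci_lo=values - 1.96 * se,
        ci_hi=values + 1.96 * se,
        n_genes=n,
    )


def wave_profile(
    assignments: pd.DataFrame,
    transcriptome: Transcriptome,
    query_codon: str,
    d_min: int = -20,
    d_max: int = 100,
    min_reads: int = 64,
    exclude_edges: int = 20,
    footprint_class: Optional[str] = None,
    densities: Optional[Dict[str, GeneDensity]] = None,
) -> WaveProfile:
    """Mean relative enrichment around every occurrence of ``query_codon``.

    For each occurrence at codon ``k`` of a passing gene (occurrences
    within ``exclude_edges`` codons of the ORF ends are skipped), collects
    ``D_i,(k+d)`` over the in-range offsets ``d`` and averages across
    occurrences. Pass a precomputed ``densities`` dict to amortize Eq.-1
    normalization across many query codons.
    """
    profiles = wave_profiles(
        assignments,
        transcriptome,
        [query_codon],
        d_min=d_min,
        d_max=d_max,
        min_reads=min_reads,
        exclude_edges=exclude_edges,
        footprint_class=footprint_class,
        densities=densities,
    )
    return profiles[query_codon]


def wave_profiles(
    assignments: pd.DataFrame,
    transcriptome: Transcriptome,
    query_codons: Sequence[str],
    d_min: int = -20,
    d_max: int = 100,
    min_reads: int = 64,
    exclude_edges: int = 20,
    footprint_class: Optional[str] = None,
    densities: Optional[Dict[str, GeneDensity]] = None,
) -> Dict[str, WaveProfile]:
    """Wave profiles for several query codons sharing one density pass."""
    for q in query_codons:
        if q not in CODONS:
            raise ValueError(f"not a codon: {q!r}")
    if densities is None:
        densities = gene_densities(assignments, transcriptome, min_reads, footprint_class)
    offsets = np.arange(d_min, d_max + 1)
    nd = len(offsets)
    pad = max(abs(d_min), abs(d_max))

    sums = {q: np.zeros(nd) for q in query_codons}
    cnts = {q: np.zeros(nd, dtype=np.int64) for q in query_codons}
    n_occ = {q: 0 for q in query_codons}

    for tid, d in densities.items():
        L = d.n_codons
        codons = transcriptome.codon_ids(tid)
        padded = np.full(L + 2 * pad, np.nan)
        padded[pad : pad + L] = d.density
        from .types import CODON_TO_ID

        for q in query_codons:
            ks = np.nonzero(codons == CODON_TO_ID[q])[0]
            ks = ks[(ks >= exclude_edges) & (ks < L - exclude_edges)]
            if ks.size == 0:
                continue
            mat = padded[(ks[:, None] + pad) + offsets[None, :]]
            valid = ~np.isnan(mat)
            sums[q] += np.where(valid, mat, 0.0).sum(axis=0)
            cnts[q] += valid.sum(axis=0)
            n_occ[q] += int(ks.size)

    out: Dict[str, WaveProfile] = {}
    for q in query_codons:
        if n_occ[q] == 0:
            raise ValueError(f"no usable occurrences of codon {q} in passing genes")
        with np.errstate(invalid="ignore"):
            enr = np.where(cnts[q] > 0, sums[q] / np.maximum(cnts[q], 1), np.nan)
        out[q] = WaveProfile(codon=q, offsets=offsets, enrichment=enr, n_occurrences=n_occ[q])
    return out
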