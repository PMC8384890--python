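"""Core domain types: transcripts, codon tables, alignment table conventions.

Coordinates are 0-based, half-open everywhere. Footprint alignments and
site assignments are carried as :class:`pandas.DataFrame` objects with the
column sets in :data:`ALIGNMENT_COLUMNS` / :data:`ASSIGNMENT_COLUMNS`;
this keeps multi-million-read libraries vectorisable while the per-object
dataclasses below hold the per-transcript and per-result structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional

import numpy as np
from Bio.Seq import Seq

#: Columns of a footprint alignment table (transcript coordinates).
ALIGNMENT_COLUMNS = ("transcript_id", "five_prime", "length")

#: Columns added by site assignment.
ASSIGNMENT_COLUMNS = ALIGNMENT_COLUMNS + (
    "footprint_class",
    "frame_class",
    "a_site_codon",
)

NUCLEOTIDES = "ACGT"

#: All 64 codons in lexicographic order; codon ids are indices into this list.
CODONS: List[str] = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
CODON_TO_ID: Dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS: List[str] = [c for c in CODONS if c not in STOP_CODONS]

#: One-letter amino acid (``*`` for stop) per codon, standard genetic code.
CODON_TO_AA: Dict[str, str] = {c: str(Seq(c).translate()) for c in CODONS}

#: Number of codons the reference ORFs are conceptually extended into the
#: UTRs (18 nt = 6 codons) to capture initiating and terminating ribosomes.
UTR_EXTENSION_NT = 18
UTR_EXTENSION_CODONS = UTR_EXTENSION_NT // 3


@dataclass
class TranscriptRecord:
    """One transcript: sequence plus its CDS interval.

    ``cds_start``/``cds_end`` are 0-based half-open transcript coordinates;
    the CDS length must be a whole number of codons and at least 3 codons.
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS not a multiple of 3 "
                f"({self.cds_end - self.cds_start} nt)"
            )
        if self.n_codons < 3:
            raise ValueError(f"{self.transcript_id}: CDS shorter than 3 codons")

    @property
    def n_codons(self) -> int:
        """ORF length in codons (incl. the stop codon)."""
        return (self.cds_end - self.cds_start) // 3

    def codon(self, j: int) -> str:
        """Codon at 0-based codon index ``j`` relative to ``cds_start``."""
        start = self.cds_start + 3 * j
        return self.sequence[start : start + 3]

    def codon_ids(self) -> np.ndarray:
        """Integer codon ids (indices into :data:`CODONS`) over the CDS."""
        cds = self.sequence[self.cds_start : self.cds_end]
        return np.array([CODON_TO_ID[cds[k : k + 3]] for k in range(0, len(cds), 3)], dtype=np.int16)


class Transcriptome:
    """An ordered, id-addressable collection of :class:`TranscriptRecord`.

    Order is preserved (annotation order) so every downstream table is
    deterministic. Codon-id arrays are cached per transcript.
    """

    def __init__(self, records: Iterable[TranscriptRecord]):
        self._records: Dict[str, TranscriptRecord] = {}
        for rec in records:
            if rec.transcript_id in self._records:
                raise ValueError(f"duplicate transcript id {rec.transcript_id!r}")
            self._records[rec.transcript_id] = rec
        self._codon_cache: Dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self._records.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._records

    def __getitem__(self, transcript_id: str) -> TranscriptRecord:
        try:
            return self._records[transcript_id]
        except KeyError:
            raise KeyError(f"unknown transcript id {transcript_id!r}") from None

    @property
    def ids(self) -> List[str]:
        return list(self._records)

    def codon_ids(self, transcript_id: str) -> np.ndarray:
        if transcript_id not in self._codon_cache:
            self._codon_cache[transcript_id] = self[transcript_id].codon_ids()
        return self._codon_cache[transcript_id]


@dataclass
class GeneDensity:
    """Per-codon A-site footprint counts and normalized density of one gene.

    ``density[j] = counts[j] * n_codons / total_reads`` so that the mean
    density over the ORF is exactly 1 for any gene with at least one read.
    Zero-read genes carry an all-zero density and ``zero_read=True``.
    """

    gene_id: str
    n_codons: int
    counts: np.ndarray
    density: np.ndarray
    total_reads: int
    zero_read: bool = False


@dataclass
class QcSummary:
    """Footprint-length and reading-frame QC.

    ``table`` has one row per footprint length with columns ``length``,
    ``count`` (all footprints of that length), ``n_framed`` (those whose 5′
    end falls in the frame-evaluation window ``[cds_start-18, cds_end)``)
    and ``frac_frame0/1/2`` (fractions of ``n_framed`` per 5′-end frame;
    zero when ``n_framed`` is 0, otherwise summing to 1).
    """

    table: "pandas.DataFrame"  # noqa: F821 - forward ref, avoids import cycle
    n_total: int
    n_outside_window: int


@dataclass
class MetageneProfile:
    """Average normalized density :math:`A_j` per aligned codon offset.

    Offsets run 1..window; ``anchor='start'`` aligns at the first codon of
    the ORF, ``anchor='stop'`` at the last. ``ci_lo``/``ci_hi`` are normal
    95% confidence bounds of the across-gene mean.
    """

    anchor: str
    offsets: np.ndarray
    values: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_genes: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "anchor": self.anchor,
                "offset": self.offsets,
                "A_j": self.values,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "N": self.n_genes,
            }
        )


@dataclass
class WaveProfile:
    """Mean relative ribosome enrichment around occurrences of one codon."""

    codon: str
    offsets: np.ndarray
    enrichment: np.ndarray
    n_occurrences: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "codon": self.codon,
                "d": self.offsets,
                "enrichment": self.enrichment,
                "n_occurrences": self.n_occurrences,
            }
        )


@dataclass
class CodonOccupancyTable:
    """Per-codon mean normalized density at one ribosomal site.

    ``table`` is indexed by codon with columns ``amino_acid``, ``occupancy``
    (NaN for codons with no contributing positions), ``n_positions`` and
    ``n_reads``. Stop-codon rows are present but excluded from comparisons
    by default.
    """

    site: str
    footprint_class: Optional[str]
    table: "pandas.DataFrame"  # noqa: F821

    def occupancy(self) -> "pandas.Series":  # noqa: F821
        return self.table["occupancy"]


@dataclass
class OccupancyComparison:
    """Pearson comparison of two codon-occupancy tables.

    ``signed_r2 = sign(r) * r**2`` so anti-correlated occupancy (seen when
    a treatment inverts site preferences) is reported as a negative value.
    ``crossed_out`` mirrors correlation-matrix displays that cross out
    cells with p > 0.05.
    """

    signed_r2: float
    r: float
    p_value: float
    n_codons: int
    crossed_out: bool
    pairs: "pandas.DataFrame" = field(repr=False, default=None)  # noqa: F821
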