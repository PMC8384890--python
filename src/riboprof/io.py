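"""Format I/O, raw-read preprocessing, exact mapping, and length/frame QC.

Reads transcript FASTA + CDS annotation TSV, footprint BED6 in transcript
coordinates, and synthetic FASTQ. The mapper here is an exact-substring
unique mapper for synthetic error-free reads; alignment of real libraries
to a genome is deliberately out of scope.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import ALIGNMENT_COLUMNS, QcSummary, TranscriptRecord, Transcriptome, UTR_EXTENSION_NT

logger = logging.getLogger(__name__)

#: Retained insert bounds after adapter clipping (nt). The lower bound is
#: below the shortest informative footprint; the upper is above the gel cut.
MIN_INSERT = 15
MAX_INSERT = 35

#: Length of the randomized linker (the first 4 nt of the 3′ adapter's 5′
#: end), removed after the constant adapter part is clipped.
LINKER_N = 4


# ---------------------------------------------------------------------------
# transcriptome + annotation


def read_transcriptome(fasta_path, annotation_path) -> Transcriptome:
    """Load transcripts from FASTA plus a CDS annotation TSV.

    The TSV must have columns ``transcript_id``, ``cds_start``, ``cds_end``
    (0-based, half-open). Records are returned in annotation order. Missing
    ids in either file and CDS lengths that are not a multiple of 3 raise
    ``ValueError``.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    annot = pd.read_csv(annotation_path, sep="\t")
    required = {"transcript_id", "cds_start", "cds_end"}
    if not required.issubset(annot.columns):
        raise ValueError(f"annotation missing columns {sorted(required - set(annot.columns))}")
    records = []
    for row in annot.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in seqs:
            raise ValueError(f"annotation id {tid!r} not present in FASTA")
        records.append(TranscriptRecord(tid, seqs[tid], int(row.cds_start), int(row.cds_end)))
    annotated = {r.transcript_id for r in records}
    orphans = sorted(set(seqs) - annotated)
    if orphans:
        raise ValueError(f"FASTA ids missing from annotation: {orphans}")
    return Transcriptome(records)


def write_transcriptome(transcriptome: Transcriptome, fasta_path, annotation_path) -> None:
    """Write FASTA + annotation TSV (inverse of :func:`read_transcriptome`)."""
    recs = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in transcriptome
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcriptome],
            "cds_start": [t.cds_start for t in transcriptome],
            "cds_end": [t.cds_end for t in transcriptome],
        }
    ).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED6 + FASTQ


def read_bed(bed_path) -> pd.DataFrame:
    """Read footprints from BED6 (chrom=transcript_id, start=5′ end)."""
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["transcript_id", "start", "end", "name", "score", "strand"],
        dtype={"transcript_id": str},
    )
    out = pd.DataFrame(
        {
            "transcript_id": bed["transcript_id"],
            "five_prime": bed["start"].astype(np.int64),
            "length": (bed["end"] - bed["start"]).astype(np.int64),
        }
    )
    return out


def write_bed(alignments: pd.DataFrame, bed_path) -> None:
    """Write footprint alignments as BED6 on the + strand."""
    n = len(alignments)
    bed = pd.DataFrame(
        {
            "transcript_id": alignments["transcript_id"].astype(str),
            "start": alignments["five_prime"].astype(np.int64),
            "end": (alignments["five_prime"] + alignments["length"]).astype(np.int64),
            "name": [f"fp{i:07d}" for i in range(n)],
            "score": 1,
            "strand": "+",
        }
    )
    bed.to_csv(bed_path, sep="\t", header=False, index=False)


def read_fastq(fastq_path) -> List[Tuple[str, str]]:
    """Read a FASTQ file into ``(read_id, sequence)`` tuples."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fastq_path), "fastq")]


def write_fastq(reads: Iterable[Tuple[str, str]], fastq_path) -> None:
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(fastq_path), "fastq")


# ---------------------------------------------------------------------------
# adapter clipping


@dataclass
class ClipStats:
    """Drop counters from :func:`clip_and_trim`."""

    n_input: int = 0
    n_kept: int = 0
    n_no_adapter: int = 0
    n_too_short: int = 0
    n_too_long: int = 0


def clip_and_trim(
    reads: Iterable[Tuple[str, str]],
    adapter: str,
    min_insert: int = MIN_INSERT,
    max_insert: int = MAX_INSERT,
    require_adapter: bool = True,
) -> Tuple[List[Tuple[str, str]], ClipStats]:
    """Clip the constant 3′ adapter and trim the 4-nt randomized linker.

    Library layout is ``insert + NNNN + adapter``: the output for a read is
    the prefix before the left-most exact adapter occurrence with its last
    4 nt (the randomized linker) removed. Reads without an adapter match
    are dropped and counted unless ``require_adapter=False``, in which case
    they pass through untouched (useful for re-running on already-clipped
    inserts, under which the operation is idempotent). Inserts outside
    ``[min_insert, max_insert]`` are dropped and counted.
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    stats = ClipStats()
    kept: List[Tuple[str, str]] = []
    for rid, seq in reads:
        stats.n_input += 1
        pos = seq.find(adapter)
        if pos < 0:
            if require_adapter:
                stats.n_no_adapter += 1
                continue
            insert = seq
        else:
            insert = seq[: max(pos - LINKER_N, 0)]
        if len(insert) < min_insert:
            stats.n_too_short += 1
            continue
        if len(insert) > max_insert:
            stats.n_too_long += 1
            continue
        kept.append((rid, insert))
        stats.n_kept += 1
    return kept, stats


# ---------------------------------------------------------------------------
# exact unique mapping


@dataclass
class MapStats:
    """Drop counters from :func:`exact_map`."""

    n_input: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_multimapped: int = 0


def exact_map(
    reads: Iterable[Tuple[str, str]], transcriptome: Transcriptome
) -> Tuple[pd.DataFrame, MapStats]:
    """Map error-free reads to transcripts by exact substring match.

    A read is reported only when it occurs at exactly one position across
    the whole transcript set (unique mapping); reads with zero or multiple
    hits are dropped and counted. Returns an alignment table with columns
    ``transcript_id``, ``five_prime``, ``length`` plus ``read_id``.
    """
    ids = transcriptome.ids
    seqs = [transcriptome[t].sequence for t in ids]
    text = "#".join(seqs)
    starts = np.cumsum([0] + [len(s) + 1 for s in seqs[:-1]]).tolist()
    ends = [starts[i] + len(seqs[i]) for i in range(len(seqs))]

    stats = MapStats()
    rows = []
    for rid, seq in reads:
        stats.n_input += 1
        if not seq or "#" in seq:
            stats.n_unmapped += 1
            continue
        first = text.find(seq)
        if first < 0:
            stats.n_unmapped += 1
            continue
        if text.find(seq, first + 1) >= 0:
            stats.n_multimapped += 1
            continue
        ti = bisect.bisect_right(starts, first) - 1
        # '#' separators make cross-transcript matches impossible
        assert first + len(seq) <= ends[ti]
        rows.append((ids[ti], first - starts[ti], len(seq), rid))
        stats.n_mapped += 1
    out = pd.DataFrame(rows, columns=list(ALIGNMENT_COLUMNS) + ["read_id"])
    return out, stats


# ---------------------------------------------------------------------------
# length / frame QC


def frame_length_qc(
    alignments: pd.DataFrame,
    transcriptome: Transcriptome,
    length_range: Tuple[int, int] = (18, 35),
) -> QcSummary:
    """Per-length read counts and 5′-end reading-frame fractions.

    Frame is ``(five_prime - cds_start) mod 3``. Footprints whose 5′ end
    falls outside ``[cds_start - 18, cds_end)`` are counted but excluded
    from the frame tallies (the 18-nt window admits initiating ribosomes).
    """
    lo, hi = length_range
    lengths = np.arange(lo, hi + 1)
    if alignments.empty:
        logger.warning("frame_length_qc: empty alignment table")
        table = pd.DataFrame(
            {
                "length": lengths,
                "count": 0,
                "n_framed": 0,
                "frac_frame0": 0.0,
                "frac_frame1": 0.0,
                "frac_frame2": 0.0,
            }
        )
        return QcSummary(table=table, n_total=0, n_outside_window=0)

    codes, uniq = pd.factorize(alignments["transcript_id"], sort=False)
    cds_start = np.array([transcriptome[t].cds_start for t in uniq])[codes]
    cds_end = np.array([transcriptome[t].cds_end for t in uniq])[codes]
    fp = alignments["five_prime"].to_numpy()
    ln = alignments["length"].to_numpy()

    in_range = (ln >= lo) & (ln <= hi)
    in_window = (fp >= cds_start - UTR_EXTENSION_NT) & (fp < cds_end)
    frame = np.mod(fp - cds_start, 3)

    rows = []
    for L in lengths:
        sel = in_range & (ln == L)
        framed = sel & in_window
        n_framed = int(framed.sum())
        fr = [0.0, 0.0, 0.0]
        if n_framed:
            for k in range(3):
                fr[k] = float(np.sum(frame[framed] == k)) / n_framed
        rows.append((int(L), int(sel.sum()), n_framed, fr[0], fr[1], fr[2]))
    table = pd.DataFrame(
        rows,
        columns=["length", "count", "n_framed", "frac_frame0", "frac_frame1", "frac_frame2"],
    )
    return QcSummary(
        table=table,
        n_total=int(in_range.sum()),
        n_outside_window=int((in_range & ~in_window).sum()),
    )
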