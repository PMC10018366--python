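"""Splicing-associated nonsense-mediated decay (NMD) prediction.

For each differential alternative exon (|dPSI| > 5 percent, FDR < 0.10) the
alternative segment is inserted into every compatible protein-coding isoform
of its gene, the modified cDNA is translated in the annotated reading frame,
and the first in-frame stop codon is located relative to the final
exon-exon junction. Isoform categories: novel_isoform (the segment fits no
annotated isoform), non_coding (no open reading frame), ptc_introduced
(first stop differs from the unmodified isoform's stop) and orf_intact.
An isoform is predicted NMD-sensitive when an introduced premature
termination codon lies more than 50 bp upstream of the final exon-exon
junction (distances in transcript coordinates, measured from the last base
of the stop codon).

Only SE, RI, A5SS and A3SS alternative segments are evaluated; MXE/AFE/ALE
alter transcript structure in ways a single-segment insertion cannot model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .types import Annotation, EventType, Exon, SpliceEvent, Transcript

log = logging.getLogger(__name__)

#: PTC-to-final-junction distance (bp) beyond which NMD is predicted
NMD_DISTANCE_BP = 50
NMD_EVENT_TYPES = {EventType.SE, EventType.RI, EventType.A5SS, EventType.A3SS}

STOP_CODONS = {"TAA", "TAG", "TGA"}


class IncompatibleInsertionError(ValueError):
    pass


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive sequence access for pyfaidx Fasta, dict-of-str or
    dict of Bio.SeqRecord genomes."""
    seq = genome[chrom]
    if hasattr(seq, "seq") and not isinstance(seq, str):  # SeqRecord / FastaRecord
        sub = seq[start - 1:end]
        return str(sub.seq) if hasattr(sub, "seq") else str(sub)
    return str(seq[start - 1:end])


def select_nmd_candidates(diff_splice: pd.DataFrame,
                          delta_psi_min: float = 5.0,
                          fdr_max: float = 0.10) -> list[str]:
    """Event ids with |delta_psi| > 5 (percent) and FDR < 0.10."""
    fdr_cols = [c for c in diff_splice.columns if c.startswith("fdr")]
    if not fdr_cols:
        raise ValueError("differential table has no FDR column")
    fdr = diff_splice[fdr_cols].min(axis=1)
    mask = (diff_splice["delta_psi"].abs() > delta_psi_min) & (fdr < fdr_max)
    return diff_splice.loc[mask.fillna(False), "event_id"].tolist()


@dataclass
class AssembledTranscript:
    """Spliced cDNA with per-base genomic coordinates (transcript orientation)."""

    sequence: str
    genomic_positions: np.ndarray  # 1-based genomic coordinate of each cDNA base
    block_count: int  # merged exon blocks (contiguous blocks fused)
    final_junction_pos: int  # 1-based cDNA coord of last base before final junction; 0 if none


def _assemble(blocks: list[tuple[int, int]], chrom: str, strand: str,
              genome) -> AssembledTranscript:
    blocks = sorted(blocks)
    merged: list[list[int]] = []
    for s, e in blocks:
        if merged and s == merged[-1][1] + 1:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    seq_parts, pos_parts = [], []
    for s, e in merged:
        seq_parts.append(fetch_sequence(genome, chrom, s, e).upper())
        pos_parts.append(np.arange(s, e + 1))
    seq = "".join(seq_parts)
    pos = np.concatenate(pos_parts)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
        pos = pos[::-1]
    # final exon-exon junction: end of the penultimate block in transcription order
    if len(merged) < 2:
        junction = 0
    else:
        lengths = [e - s + 1 for s, e in merged]
        if strand == "-":
            lengths = lengths[::-1]
        junction = int(sum(lengths[:-1]))
    return AssembledTranscript(sequence=seq, genomic_positions=pos,
                               block_count=len(merged),
                               final_junction_pos=junction)


def is_insertable(transcript: Transcript, alt: tuple[int, int]) -> bool:
    """The segment matches an existing exon exactly or fits wholly inside an
    intron between two consecutive exons."""
    s, e = alt
    exons = transcript.genomic_exons
    for ex in exons:
        if (ex.start, ex.end) == (s, e):
            return True
        if ex.overlaps(s, e):
            return False
    for left, right in zip(exons, exons[1:]):
        if left.end < s and e < right.start:
            return True
    return False


def build_modified_transcript(transcript: Transcript, alt: tuple[int, int],
                              genome) -> AssembledTranscript:
    """Assemble the transcript's cDNA with the alternative segment inserted
    at its genomic position (reverse-complemented for the minus strand)."""
    s, e = alt
    exons = transcript.genomic_exons
    blocks = [(ex.start, ex.end) for ex in exons]
    if any((ex.start, ex.end) == (s, e) for ex in exons):
        pass  # segment already part of the isoform: unmodified assembly
    else:
        for ex in exons:
            if ex.overlaps(s, e):
                raise IncompatibleInsertionError(
                    f"segment {s}-{e} partially overlaps exon "
                    f"{ex.start}-{ex.end} of {transcript.transcript_id}")
        if not any(l.end < s and e < r.start for l, r in zip(exons, exons[1:])):
            raise IncompatibleInsertionError(
                f"segment {s}-{e} lies outside the intron space of "
                f"{transcript.transcript_id}")
        blocks.append((s, e))
    return _assemble(blocks, transcript.chrom, transcript.strand, genome)


def coding_start_genomic(transcript: Transcript) -> Optional[int]:
    """Genomic coordinate of the first coding base (from CDS records)."""
    if not transcript.cds:
        return None
    if transcript.strand == "-":
        return max(c.end for c in transcript.cds)
    return min(c.start for c in transcript.cds)


def longest_orf_start(cdna: str) -> Optional[int]:
    """0-based offset of the start codon of the longest ATG-initiated ORF."""
    best = None
    best_len = 0
    for frame in range(3):
        i = frame
        while i + 3 <= len(cdna):
            if cdna[i:i + 3] == "ATG":
                j = i
                while j + 3 <= len(cdna) and cdna[j:j + 3] not in STOP_CODONS:
                    j += 3
                orf_len = j - i
                if j + 3 <= len(cdna):  # found a stop
                    if orf_len > best_len:
                        best, best_len = i, orf_len
                    i = j
            i += 3
    return best


def translate_and_locate_ptc(assembled: AssembledTranscript,
                             cds_offset: int) -> dict:
    """Translate from ``cds_offset`` (0-based cDNA index) and locate the
    first in-frame stop codon.

    Returns dict with: protein, stop_pos (1-based cDNA coordinate of the
    stop codon's last base; None when no stop — flagged nonstop),
    stop_genomic (genomic coordinates of the stop codon bases),
    final_junction_pos, ptc_distance_bp (junction minus stop position).
    """
    seq = assembled.sequence
    stop_pos = None
    stop_genomic: Optional[tuple[int, ...]] = None
    i = cds_offset
    while i + 3 <= len(seq):
        codon = seq[i:i + 3]
        if codon in STOP_CODONS:
            stop_pos = i + 3  # 1-based coordinate of the codon's last base
            stop_genomic = tuple(int(p) for p in
                                 assembled.genomic_positions[i:i + 3])
            break
        i += 3
    coding = seq[cds_offset:(stop_pos if stop_pos else len(seq))]
    coding = coding[:len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())
    distance = (assembled.final_junction_pos - stop_pos
                if stop_pos is not None else None)
    if stop_pos is None:
        log.warning("no in-frame stop codon found (nonstop transcript)")
    return {"protein": protein, "stop_pos": stop_pos,
            "stop_genomic": stop_genomic,
            "final_junction_pos": assembled.final_junction_pos,
            "ptc_distance_bp": distance}


def _transcript_call(event: SpliceEvent, transcript: Transcript,
                     genome) -> dict:
    alt = event.alt_coords[0]
    base = {"event_id": event.event_id, "transcript_id": transcript.transcript_id,
            "gene_id": event.gene_id}
    original = _assemble([(e.start, e.end) for e in transcript.genomic_exons],
                         transcript.chrom, transcript.strand, genome)
    start_gen = coding_start_genomic(transcript)
    if start_gen is None:
        off = longest_orf_start(original.sequence)
        if off is None:
            return {**base, "category": "non_coding", "nmd": "not_applicable",
                    "ptc_distance_bp": None}
        log.info("transcript %s lacks CDS records; using longest ORF",
                 transcript.transcript_id)
        start_gen = int(original.genomic_positions[off])

    modified = build_modified_transcript(transcript, alt, genome)
    where = np.flatnonzero(modified.genomic_positions == start_gen)
    where_orig = np.flatnonzero(original.genomic_positions == start_gen)
    if where.size == 0 or where_orig.size == 0:
        return {**base, "category": "non_coding", "nmd": "not_applicable",
                "ptc_distance_bp": None}
    mod = translate_and_locate_ptc(modified, int(where[0]))
    orig = translate_and_locate_ptc(original, int(where_orig[0]))
    if mod["stop_pos"] is None:
        return {**base, "category": "orf_intact", "nmd": "no",
                "ptc_distance_bp": None, "nonstop": True}
    if orig["stop_genomic"] is not None and mod["stop_genomic"] == orig["stop_genomic"]:
        return {**base, "category": "orf_intact", "nmd": "no",
                "ptc_distance_bp": None}
    distance = mod["ptc_distance_bp"]
    return {**base, "category": "ptc_introduced",
            "nmd": "yes" if distance is not None and distance > NMD_DISTANCE_BP else "no",
            "ptc_distance_bp": distance}


def predict_nmd(events: Sequence[SpliceEvent], diff_splice: pd.DataFrame,
                annotation: Annotation, genome,
                delta_psi_min: float = 5.0,
                fdr_max: float = 0.10) -> pd.DataFrame:
    """NMD prediction for every candidate differential event.

    For each candidate SE/RI/A5SS/A3SS event, all protein-coding isoforms of
    the gene compatible with inserting the alternative segment are
    evaluated; an event whose segment fits no annotated isoform yields a
    single ``novel_isoform`` row.
    """
    candidates = set(select_nmd_candidates(diff_splice, delta_psi_min, fdr_max))
    by_id = {ev.event_id: ev for ev in events}
    rows = []
    for event_id in sorted(candidates):
        ev = by_id.get(event_id)
        if ev is None or ev.event_type not in NMD_EVENT_TYPES or not ev.alt_coords:
            continue
        transcripts = annotation.transcripts_of(ev.gene_id)
        compatible = [t for t in transcripts
                      if t.exons and is_insertable(t, ev.alt_coords[0])]
        if not compatible:
            rows.append({"event_id": event_id, "transcript_id": "",
                         "gene_id": ev.gene_id, "category": "novel_isoform",
                         "nmd": "not_applicable", "ptc_distance_bp": None})
            continue
        for t in compatible:
            rows.append(_transcript_call(ev, t, genome))
    cols = ["event_id", "transcript_id", "gene_id", "category", "nmd",
            "ptc_distance_bp"]
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=cols)
    return table[cols + [c for c in table.columns if c not in cols]]
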