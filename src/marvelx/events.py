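"""Event catalog: AFE/ALE detection, event-to-junction mapping, independent
introns, junction-evidence validation, and droplet junction annotation.

Every event carries the splice junctions that evidence its included and
excluded isoforms; PSI is later a pure ratio of those junction read counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (Annotation, EventType, Exon, IndependentIntron, JunctionKey,
                    SpliceEvent, Transcript)

log = logging.getLogger(__name__)

#: cohort-level evidence floor: total junction reads per event (all cells)
MIN_EVENT_READS = 10


class InvalidEventError(ValueError):
    pass


def _event_id(gene_id: str, etype: EventType, chrom: str, strand: str,
              coords: Iterable[int]) -> str:
    block = "-".join(str(c) for c in coords)
    return f"{gene_id}|{etype.value}|{chrom}|{strand}|{block}"


def _junction(chrom: str, left_exon_end: int, right_exon_start: int) -> JunctionKey:
    """Junction between two exons: first/last intronic base coordinates."""
    if right_exon_start - left_exon_end < 2:
        raise InvalidEventError(
            f"zero-length implied junction between exon end {left_exon_end} "
            f"and exon start {right_exon_start}")
    return JunctionKey(chrom, left_exon_end + 1, right_exon_start - 1)


def detect_afe_ale(annotation: Annotation) -> pd.DataFrame:
    """Detect alternative first/last exon events from the annotation.

    For each gene, every unordered pair of distinct, non-overlapping first
    exons whose transcripts splice directly to a shared downstream exon
    yields one AFE event; the included junction runs from the distal (more
    5' in transcription order) first exon to the shared exon, the excluded
    junction from the proximal one. ALE is the mirror image at the 3' end.
    Events are deduplicated by coordinate block.
    """
    rows = []
    by_gene: dict[str, list[Transcript]] = {}
    for t in annotation.transcripts.values():
        if len(t.exons) >= 2:  # single-exon transcripts have no terminal junction
            by_gene.setdefault(t.gene_id, []).append(t)
    for gene_id, transcripts in sorted(by_gene.items()):
        if len(transcripts) < 2:
            continue
        strand = transcripts[0].strand
        chrom = transcripts[0].chrom
        for kind in ("AFE", "ALE"):
            seen_blocks = set()
            for t1, t2 in itertools.combinations(
                    sorted(transcripts, key=lambda t: t.transcript_id), 2):
                ev = _terminal_event(gene_id, chrom, strand, t1, t2, kind)
                if ev is None:
                    continue
                block = tuple(ev["coords"])
                if block in seen_blocks:
                    continue
                seen_blocks.add(block)
                rows.append(ev)
    cols = ["event_type", "gene_id", "chrom", "strand",
            "distal_start", "distal_end", "proximal_start", "proximal_end",
            "shared_start", "shared_end", "coords"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def _terminal_event(gene_id, chrom, strand, t1: Transcript, t2: Transcript,
                    kind: str) -> Optional[dict]:
    """One AFE/ALE candidate from a transcript pair, or None."""
    if kind == "AFE":
        e1, e2 = t1.first_exon(), t2.first_exon()
        n1, n2 = t1.exons[1], t2.exons[1]  # exon spliced to, transcription order
    else:
        e1, e2 = t1.last_exon(), t2.last_exon()
        n1, n2 = t1.exons[-2], t2.exons[-2]
    if (e1.start, e1.end) == (e2.start, e2.end):
        return None  # identical terminal exons
    if e1.overlaps(e2.start, e2.end):
        return None  # overlapping terminal exons are A5SS/A3SS territory
    if (n1.start, n1.end) != (n2.start, n2.end):
        return None  # no shared flanking exon: junction ratio undefined
    shared = n1
    if shared.overlaps(e1.start, e1.end) or shared.overlaps(e2.start, e2.end):
        return None
    # distal = farther from the gene body in transcription order
    fwd = strand != "-"
    if kind == "AFE":
        distal, proximal = ((e1, e2) if (e1.start < e2.start) == fwd else (e2, e1))
    else:
        distal, proximal = ((e1, e2) if (e1.start > e2.start) == fwd else (e2, e1))
    coords = (distal.start, distal.end, proximal.start, proximal.end,
              shared.start, shared.end)
    return {"event_type": kind, "gene_id": gene_id, "chrom": chrom,
            "strand": strand, "distal_start": distal.start,
            "distal_end": distal.end, "proximal_start": proximal.start,
            "proximal_end": proximal.end, "shared_start": shared.start,
            "shared_end": shared.end, "coords": coords}


def map_event_junctions(raw: pd.Series, annotation: Optional[Annotation] = None
                        ) -> SpliceEvent:
    """Map one raw event row (internal 1-based coordinates) to a SpliceEvent.

    Raises :class:`InvalidEventError` when an implied junction has zero
    length (adjacent exons).
    """
    etype = EventType(raw["event_type"])
    chrom, strand, gene = raw["chrom"], raw["strand"], raw["gene_id"]

    if etype == EventType.SE:
        up_ee, alt_s, alt_e, down_es = (raw["upstreamEE"], raw["exonStart"],
                                        raw["exonEnd"], raw["downstreamES"])
        inc = (_junction(chrom, up_ee, alt_s), _junction(chrom, alt_e, down_es))
        exc = (_junction(chrom, up_ee, down_es),)
        alt = ((alt_s, alt_e),)
        coords = (up_ee, alt_s, alt_e, down_es)
    elif etype == EventType.MXE:
        up_ee, down_es = raw["upstreamEE"], raw["downstreamES"]
        e1s, e1e = raw["1stExonStart"], raw["1stExonEnd"]
        e2s, e2e = raw["2ndExonStart"], raw["2ndExonEnd"]
        inc = (_junction(chrom, up_ee, e1s), _junction(chrom, e1e, down_es))
        exc = (_junction(chrom, up_ee, e2s), _junction(chrom, e2e, down_es))
        alt = ((e1s, e1e), (e2s, e2e))
        coords = (up_ee, e1s, e1e, e2s, e2e, down_es)
    elif etype == EventType.RI:
        up_ee, down_es = raw["upstreamEE"], raw["downstreamES"]
        intron = (up_ee + 1, down_es - 1)
        if intron[1] < intron[0]:
            raise InvalidEventError("RI event with empty intron")
        exc = (JunctionKey(chrom, *intron),)
        inc = ()
        alt = (intron,)
        coords = intron
    elif etype in (EventType.A5SS, EventType.A3SS):
        ls, le = raw["longExonStart"], raw["longExonEnd"]
        ss, se = raw["shortES"], raw["shortEE"]
        fs, fe = raw["flankingES"], raw["flankingEE"]
        if fs > le:  # flanking exon downstream in genomic coordinates
            inc = (_junction(chrom, le, fs),)
            exc = (_junction(chrom, se, fs),)
            alt = ((se + 1, le),)  # alternative extension segment
        else:  # flanking exon upstream
            inc = (_junction(chrom, fe, ls),)
            exc = (_junction(chrom, fe, ss),)
            alt = ((ls, ss - 1),)
        coords = (ls, le, ss, se, fs, fe)
    elif etype in (EventType.AFE, EventType.ALE):
        ds, de = raw["distal_start"], raw["distal_end"]
        ps, pe = raw["proximal_start"], raw["proximal_end"]
        shs, she = raw["shared_start"], raw["shared_end"]
        if shs > de:  # shared exon genomically downstream of terminal exons
            inc = (_junction(chrom, de, shs),)
            exc = (_junction(chrom, pe, shs),)
        else:
            inc = (_junction(chrom, she, ds),)
            exc = (_junction(chrom, she, ps),)
        alt = ((ds, de),)
        coords = (ds, de, ps, pe, shs, she)
    else:  # pragma: no cover
        raise ValueError(f"unhandled event type {etype}")

    return SpliceEvent(
        event_id=_event_id(gene, etype, chrom, strand, coords),
        event_type=etype, gene_id=gene, chrom=chrom, strand=strand,
        included_junctions=inc, excluded_junctions=exc, alt_coords=alt)


def build_events(raw_table: pd.DataFrame,
                 annotation: Optional[Annotation] = None) -> list[SpliceEvent]:
    """Map a raw event table to SpliceEvents, dropping invalid rows with a log."""
    events, seen = [], set()
    for _, row in raw_table.iterrows():
        try:
            ev = map_event_junctions(row, annotation)
        except InvalidEventError as exc:
            log.warning("skipping invalid event: %s", exc)
            continue
        if ev.event_id in seen:
            continue
        seen.add(ev.event_id)
        events.append(ev)
    return events


def derive_independent_introns(annotation: Annotation,
                               ri_events: Iterable[SpliceEvent]) -> list[IndependentIntron]:
    """Retain RI introns that overlap no annotated exon of any gene.

    Exons that exactly span the retained block (upstream exon start through
    downstream exon end, i.e. the retained-intron isoform's own merged exon)
    are disregarded: an RI event implies such an exon exists, and a literal
    overlap scan would otherwise discard every intron.
    """
    exons_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, _, e in annotation.all_exons():
        exons_by_chrom.setdefault(e.chrom, []).append((e.start, e.end))
    out = []
    for ev in ri_events:
        if ev.event_type != EventType.RI:
            continue
        start, end = ev.alt_coords[0]
        independent = True
        for (es, ee) in exons_by_chrom.get(ev.chrom, []):
            if es <= end and start <= ee:
                if es < start and ee > end:
                    continue  # spans the whole retained block: the RI isoform
                independent = False
                break
        if independent:
            out.append(IndependentIntron(
                intron_id=ev.event_id, gene_id=ev.gene_id, chrom=ev.chrom,
                start=start, end=end, skip_junction=ev.excluded_junctions[0]))
    return out


def validate_events(events: Iterable[SpliceEvent],
                    junction_counts: pd.DataFrame,
                    min_reads: int = MIN_EVENT_READS) -> list[SpliceEvent]:
    """Keep events whose junctions all exist in the matrix and whose summed
    read count across all cells and junctions reaches ``min_reads``."""
    index = set(junction_counts.index)
    totals = junction_counts.sum(axis=1)
    kept = []
    for ev in events:
        keys = [str(j) for j in ev.all_junctions()]
        if not keys or any(k not in index for k in keys):
            continue
        if totals.loc[keys].sum() >= min_reads:
            kept.append(ev)
    return kept


def events_to_table(events: Iterable[SpliceEvent]) -> pd.DataFrame:
    """Serialize events to a TSV-ready table with semicolon-joined junction sets."""
    rows = []
    for ev in events:
        rows.append({
            "event_id": ev.event_id, "event_type": ev.event_type.value,
            "gene_id": ev.gene_id, "chrom": ev.chrom, "strand": ev.strand,
            "alt_coords": ";".join(f"{s}-{e}" for s, e in ev.alt_coords),
            "included_junctions": ";".join(str(j) for j in ev.included_junctions),
            "excluded_junctions": ";".join(str(j) for j in ev.excluded_junctions),
        })
    return pd.DataFrame(rows, columns=["event_id", "event_type", "gene_id",
                                       "chrom", "strand", "alt_coords",
                                       "included_junctions", "excluded_junctions"])


def annotate_sj_droplet(junction_ids: Iterable[str],
                        annotation: Annotation) -> pd.DataFrame:
    """Classify droplet junction flanks against annotated exon boundaries.

    Each junction's flanking exonic positions (start-1 and end+1) are matched
    exactly against exon ends/starts in the GTF. A flank is ``annotated``
    when it matches exon boundaries of exactly one gene, ``multi_mapped``
    for >1 gene, ``unannotated`` otherwise. A junction is retained iff both
    flanks are annotated and map to the same gene, which becomes gene[sj].

    Returns a table with columns: junction, flank5_label, flank3_label,
    gene_id, status in {retained, filtered_unannotated, filtered_multimapped,
    filtered_mixed}.
    """
    end_map: dict[tuple[str, int], set[str]] = {}
    start_map: dict[tuple[str, int], set[str]] = {}
    for gene_id, _, e in annotation.all_exons():
        end_map.setdefault((e.chrom, e.end), set()).add(gene_id)
        start_map.setdefault((e.chrom, e.start), set()).add(gene_id)

    def classify(genes: set[str]) -> str:
        if not genes:
            return "unannotated"
        return "annotated" if len(genes) == 1 else "multi_mapped"

    rows = []
    for jid in junction_ids:
        key = JunctionKey.from_string(jid)
        g5 = end_map.get((key.chrom, key.start - 1), set())
        g3 = start_map.get((key.chrom, key.end + 1), set())
        l5, l3 = classify(g5), classify(g3)
        labels = {l5, l3}
        if "unannotated" in labels:
            status, gene = "filtered_unannotated", None
        elif "multi_mapped" in labels:
            status, gene = "filtered_multimapped", None
        else:
            shared = g5 & g3
            if len(shared) == 1:
                status, gene = "retained", next(iter(shared))
            else:
                status, gene = "filtered_mixed", None
        rows.append({"junction": jid, "flank5_label": l5, "flank3_label": l3,
                     "gene_id": gene, "status": status})
    return pd.DataFrame(rows, columns=["junction", "flank5_label",
                                       "flank3_label", "gene_id", "status"])
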