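"""Readers, writers and session assembly for all external formats.

Supported inputs: STAR ``SJ.out.tab`` junction tables, GTF 2.2 annotation,
rMATS ``fromGTF.*.txt`` event coordinate tables, dense TSV matrices (plate),
MatrixMarket triplet + barcodes/features (droplet), TSV cell metadata and a
genome FASTA (consumed downstream by the NMD module).

Internal coordinates are uniformly 1-based inclusive; rMATS 0-based exon
starts are converted here, once.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .types import Annotation, EventType, Exon, Gene, JunctionKey, Session, Transcript

log = logging.getLogger(__name__)

_STRAND_CODE = {0: ".", 1: "+", 2: "-"}

#: rMATS fromGTF column sets per event type (0-based starts, 1-based ends).
_RMATS_COLUMNS = {
    EventType.SE: ["exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
                   "downstreamES", "downstreamEE"],
    EventType.MXE: ["1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base",
                    "2ndExonEnd", "upstreamES", "upstreamEE", "downstreamES",
                    "downstreamEE"],
    EventType.RI: ["riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
                   "downstreamES", "downstreamEE"],
    EventType.A5SS: ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
                     "flankingES", "flankingEE"],
    EventType.A3SS: ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
                     "flankingES", "flankingEE"],
}


class ParseError(ValueError):
    pass


def read_star_sj_tab(path, sample_id: str = "sample",
                     count_column: str = "unique",
                     with_strands: bool = False):
    """Read one STAR ``SJ.out.tab`` file into a junction -> count map.

    Columns follow the STAR convention: chrom, intron start (1-based, first
    intronic base), intron end (last intronic base), strand code {0,1,2},
    motif, annotated flag, unique-read count, multi-read count, overhang.
    Zero-count rows are retained. ``count_column`` selects ``"unique"``
    (default), ``"multi"`` or ``"both"``; ``with_strands`` additionally
    returns the junction -> strand map.

    Raises :class:`ParseError` naming the offending line on malformed input
    and on duplicate (chrom, start, end) rows.
    """
    counts: dict[JunctionKey, int] = {}
    strands: dict[JunctionKey, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=7 tab-separated fields, "
                    f"got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                strand_code = int(fields[3])
                unique = int(fields[6])
                multi = int(fields[7]) if len(fields) > 7 else 0
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field "
                                 f"({exc})") from None
            key = JunctionKey(fields[0], start, end).validate()
            if key in counts:
                raise ParseError(f"{path}: line {lineno}: duplicate junction "
                                 f"{key} (STAR emits unique intron rows)")
            if count_column == "unique":
                n = unique
            elif count_column == "multi":
                n = multi
            else:
                n = unique + multi
            counts[key] = n
            strands[key] = _STRAND_CODE.get(strand_code, ".")
    if with_strands:
        return counts, strands
    return counts


def junction_counts_from_sj_tabs(paths: Mapping[str, str]) -> pd.DataFrame:
    """Assemble a junctions x cells count matrix from per-cell SJ.out.tab files."""
    columns = {}
    for cell, path in paths.items():
        col = read_star_sj_tab(path, cell)
        columns[cell] = {str(k): v for k, v in col.items()}
    mat = pd.DataFrame(columns).fillna(0).astype(int)
    mat.index.name = "junction"
    return mat


def read_gtf(path) -> Annotation:
    """Read a GTF 2.2 file into an :class:`Annotation`.

    Exon rows lacking a transcript_id are skipped with a logged warning.
    ``transcript_biotype`` and ``transcript_type`` are accepted
    interchangeably. Raises on exons with end < start.
    """
    import pyranges

    gr = pyranges.read_gtf(str(path))
    df = gr.df
    # pyranges converts to 0-based half-open; restore 1-based inclusive.
    df = df.assign(Start=df["Start"] + 1)
    biotype_col = None
    for cand in ("transcript_biotype", "transcript_type"):
        if cand in df.columns:
            biotype_col = cand
            break

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}

    for _, row in df[df["Feature"] == "gene"].iterrows():
        gid = row.get("gene_id")
        if not isinstance(gid, str) or not gid:
            continue
        genes[gid] = Gene(
            gene_id=gid,
            gene_name=row.get("gene_name") if isinstance(row.get("gene_name"), str) else gid,
            chrom=str(row["Chromosome"]), strand=str(row["Strand"]),
            start=int(row["Start"]), end=int(row["End"]))

    for _, row in df[df["Feature"] == "transcript"].iterrows():
        tid = row.get("transcript_id")
        gid = row.get("gene_id")
        if not isinstance(tid, str) or not tid:
            log.warning("transcript row without transcript_id skipped")
            continue
        biotype = row.get(biotype_col) if biotype_col else None
        transcripts[tid] = Transcript(
            transcript_id=tid, gene_id=gid, chrom=str(row["Chromosome"]),
            strand=str(row["Strand"]), exons=[],
            biotype=biotype if isinstance(biotype, str) else None)

    for feature, attr in (("exon", "exons"), ("CDS", "cds")):
        sub = df[df["Feature"] == feature]
        for _, row in sub.iterrows():
            tid = row.get("transcript_id")
            if not isinstance(tid, str) or not tid:
                log.warning("%s row without transcript_id skipped (%s:%s-%s)",
                            feature, row["Chromosome"], row["Start"], row["End"])
                continue
            start, end = int(row["Start"]), int(row["End"])
            if end < start:
                raise ValueError(
                    f"{feature} with end < start: {row['Chromosome']}:{start}-{end}")
            if tid not in transcripts:
                # transcript row absent; synthesize from the exon line
                transcripts[tid] = Transcript(
                    transcript_id=tid, gene_id=row.get("gene_id"),
                    chrom=str(row["Chromosome"]), strand=str(row["Strand"]),
                    exons=[])
            getattr(transcripts[tid], attr).append(
                Exon(str(row["Chromosome"]), start, end))

    # order exons/CDS in transcription order and synthesize missing genes
    for t in transcripts.values():
        rev = t.strand == "-"
        t.exons.sort(key=lambda e: e.start, reverse=rev)
        t.cds.sort(key=lambda e: e.start, reverse=rev)
        if t.gene_id and t.gene_id not in genes and t.exons:
            ge = sorted(t.exons, key=lambda e: e.start)
            genes[t.gene_id] = Gene(t.gene_id, t.gene_id, t.chrom, t.strand,
                                    ge[0].start, ge[-1].end)
        elif t.gene_id in genes and t.exons:
            g = genes[t.gene_id]
            ge = sorted(t.exons, key=lambda e: e.start)
            g.start = min(g.start, ge[0].start)
            g.end = max(g.end, ge[-1].end)
    return Annotation(genes=genes, transcripts=transcripts)


def read_rmats_events(paths: Mapping[str, str]) -> pd.DataFrame:
    """Read rMATS ``fromGTF.<TYPE>.txt`` tables into one raw event table.

    ``paths`` maps event-type labels (SE, MXE, RI, A5SS, A3SS) to file paths.
    All 0-based start columns are shifted to the internal 1-based inclusive
    convention; the output table is tagged ``raw`` (never re-convertible).
    """
    frames = []
    for label, path in paths.items():
        try:
            etype = EventType(label)
        except ValueError:
            raise ValueError(f"unknown event-type label {label!r}") from None
        if etype not in _RMATS_COLUMNS:
            raise ValueError(f"{label} is not an rMATS input type")
        tab = pd.read_csv(path, sep="\t")
        required = ["GeneID", "chr", "strand"] + _RMATS_COLUMNS[etype]
        for col in required:
            if col not in tab.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        out = pd.DataFrame({
            "event_type": etype.value,
            "gene_id": tab["GeneID"],
            "chrom": tab["chr"],
            "strand": tab["strand"],
        })
        for col in _RMATS_COLUMNS[etype]:
            vals = tab[col].astype(int)
            # rMATS starts are 0-based ("_0base" suffix or *ES columns)
            if col.endswith("_0base") or col.endswith("ES"):
                vals = vals + 1
            out[col.replace("_0base", "")] = vals
        frames.append(out)
    if not frames:
        return pd.DataFrame(columns=["event_type", "gene_id", "chrom", "strand"])
    table = pd.concat(frames, ignore_index=True, sort=False)
    table.attrs["coordinates"] = "internal-1-based"
    return table


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a dense TSV matrix (rows x cells, first column = row ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_mtx(mtx_path, barcodes_path, features_path) -> pd.DataFrame:
    """Read a MatrixMarket triplet with barcode/feature sidecars (features x cells)."""
    mat = spio.mmread(str(mtx_path)).tocsr()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
    features = pd.read_csv(features_path, sep="\t", header=None)[0].tolist()
    return pd.DataFrame(mat.toarray(), index=features, columns=barcodes)


def write_mtx(matrix: pd.DataFrame, mtx_path, barcodes_path, features_path) -> None:
    spio.mmwrite(str(mtx_path), sparse.csr_matrix(matrix.to_numpy()))
    pd.Series(matrix.columns).to_csv(barcodes_path, sep="\t", header=False,
                                     index=False)
    pd.Series(matrix.index).to_csv(features_path, sep="\t", header=False,
                                   index=False)


def _check_unique(ids: Sequence, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dup}")


def create_session(mode: str,
                   junction_counts: pd.DataFrame,
                   expression: pd.DataFrame,
                   annotation: Optional[Annotation] = None,
                   cell_metadata: Optional[pd.DataFrame] = None,
                   embedding: Optional[pd.DataFrame] = None,
                   intron_coverage: Optional[pd.DataFrame] = None,
                   gene_counts: Optional[pd.DataFrame] = None,
                   junction_strand: Optional[dict[str, str]] = None) -> Session:
    """Assemble a validated :class:`Session`.

    Cell identifiers are intersected across all supplied matrices; dropped
    cells are logged. Matrices are re-ordered to one canonical (sorted) cell
    order, so assembly is independent of input column order.
    """
    if mode not in ("plate", "droplet"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "droplet":
        if cell_metadata is None or "group" not in cell_metadata.columns:
            raise ValueError("droplet mode requires cell metadata with "
                             "a 'group' (cell type) column")
        if gene_counts is None:
            raise ValueError("droplet mode requires a raw gene count matrix")

    matrices: dict[str, pd.DataFrame] = {
        "junction_counts": junction_counts, "expression": expression}
    if gene_counts is not None:
        matrices["gene_counts"] = gene_counts
    for name, mat in matrices.items():
        _check_unique(mat.columns, f"cell ids in {name}")
        _check_unique(mat.index, f"row ids in {name}")
        if (mat.to_numpy() < 0).any():
            raise ValueError(f"negative values in {name}")

    cell_sets = [set(m.columns) for m in matrices.values()]
    if cell_metadata is not None:
        _check_unique(cell_metadata.index, "cell ids in metadata")
        cell_sets.append(set(cell_metadata.index))
    if embedding is not None:
        cell_sets.append(set(embedding.index))
    common = set.intersection(*cell_sets)
    if not common:
        raise ValueError("empty cell intersection across input matrices")
    order = sorted(common)
    for m in matrices.values():
        dropped = set(m.columns) - common
        if dropped:
            log.warning("dropping %d cells absent from other inputs: %s%s",
                        len(dropped), sorted(dropped)[:5],
                        "..." if len(dropped) > 5 else "")

    session = Session(
        mode=mode,
        junction_counts=junction_counts[order],
        expression=expression[order],
        annotation=annotation,
        cell_metadata=cell_metadata.loc[order] if cell_metadata is not None else None,
        embedding=embedding.loc[order] if embedding is not None else None,
        intron_coverage=intron_coverage[order] if intron_coverage is not None else None,
        gene_counts=gene_counts[order] if gene_counts is not None else None,
        junction_strand=junction_strand)
    return session


def cpm_normalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalization (counts per ``scale``); fixture helper only."""
    libsize = counts.sum(axis=0)
    libsize = libsize.replace(0, 1)
    return counts.div(libsize, axis=1) * scale


def write_gtf(annotation: Annotation, path) -> None:
    """Write an :class:`Annotation` back to GTF (round-trip support)."""
    with open(path, "w") as fh:
        for g in annotation.genes.values():
            fh.write(f"{g.chrom}\tmarvelx\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tgene_id \"{g.gene_id}\"; "
                     f"gene_name \"{g.gene_name}\";\n")
        for t in annotation.transcripts.values():
            ge = t.genomic_exons
            if not ge:
                continue
            bt = f' transcript_biotype "{t.biotype}";' if t.biotype else ""
            fh.write(f"{t.chrom}\tmarvelx\ttranscript\t{ge[0].start}\t"
                     f"{ge[-1].end}\t.\t{t.strand}\t.\t"
                     f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                     f"{bt}\n")
            for e in t.exons:
                fh.write(f"{t.chrom}\tmarvelx\texon\t{e.start}\t{e.end}\t.\t"
                         f"{t.strand}\t.\t"
                         f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";\n')
            for c in t.cds:
                fh.write(f"{t.chrom}\tmarvelx\tCDS\t{c.start}\t{c.end}\t.\t"
                         f"{t.strand}\t.\t"
                         f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";\n')
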