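"""Shared fixtures: small simulated cohorts and hand-built annotations."""

import numpy as np
import pandas as pd
import pytest

from marvelx import events as evm
from marvelx import psi as psi_mod
from marvelx import simulate
from marvelx.types import Annotation, Exon, Gene, Transcript


@pytest.fixture(scope="session")
def plate_sim():
    """Small plate cohort reused across unit tests (seed fixed)."""
    cfg = simulate.PlateSimConfig(
        seed=11, n_events=60, n_differential=10, n_events_per_archetype=5,
        n_spurious_bimodal=3, n_ri_introns=5)
    return simulate.simulate_plate(cfg)


@pytest.fixture(scope="session")
def plate_psi(plate_sim):
    validated = evm.validate_events(plate_sim.events, plate_sim.junction_counts)
    return psi_mod.compute_psi_plate(validated, plate_sim.junction_counts)


@pytest.fixture(scope="session")
def droplet_sim():
    cfg = simulate.DropletSimConfig(seed=12, n_junctions=60, n_differential=8,
                                    n_cells_per_group=120)
    return simulate.simulate_droplet(cfg)


def make_transcript(tid, gene_id, exon_coords, strand="+", chrom="chr1",
                    biotype=None, cds=None):
    exons = [Exon(chrom, s, e) for s, e in exon_coords]
    exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
    cds_exons = [Exon(chrom, s, e) for s, e in (cds or [])]
    return Transcript(tid, gene_id, chrom, strand, exons, biotype=biotype,
                      cds=cds_exons)


def make_annotation(transcripts):
    genes = {}
    tdict = {}
    for t in transcripts:
        tdict[t.transcript_id] = t
        ge = t.genomic_exons
        if t.gene_id not in genes:
            genes[t.gene_id] = Gene(t.gene_id, t.gene_id, t.chrom, t.strand,
                                    ge[0].start, ge[-1].end)
        else:
            g = genes[t.gene_id]
            g.start = min(g.start, ge[0].start)
            g.end = max(g.end, ge[-1].end)
    return Annotation(genes=genes, transcripts=tdict)


@pytest.fixture
def afe_annotation():
    """Gene with three alternative first exons all splicing to one shared exon."""
    return make_annotation([
        make_transcript("T1", "G1", [(1, 50), (301, 400), (501, 600)]),
        make_transcript("T2", "G1", [(101, 150), (301, 400), (501, 600)]),
        make_transcript("T3", "G1", [(201, 250), (301, 400), (501, 600)]),
    ])
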