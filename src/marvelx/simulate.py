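"""Synthetic fixtures: toy genome, annotation and count matrices with
planted ground truth for every pipeline stage.

The plate generator is beta-binomial: each event carries per-group beta
shape parameters; a cell's latent inclusion level psi is drawn from its
group's beta, the informative read depth from a negative binomial, and the
included reads from Binomial(depth, psi), split across the event's two
inclusion junctions. Spurious bimodality (the amplification-artifact
signature the bimodality adjustment targets) is planted as monoallelic
capture: an affected cell reports all-or-none inclusion with probability
equal to its latent psi. Retained-intron coverage is generated consistent
with the length-normalized coverage ratio. Expression is log-normal with
group shifts wired to each event's planted gene-splicing relation.

The droplet generator thins gene counts: junction reads are a binomial
fraction (the planted usage) of the cell's gene count, which guarantees
pseudo-bulk usage in [0, 1].

Every planted parameter is recorded in a truth table emitted alongside the
data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import session_io
from .types import Annotation, EventType, Exon, Gene, JunctionKey, SpliceEvent, Transcript

#: modality archetypes: name -> (alpha, beta, expected five-class modality,
#: expected sub-modality)
MODALITY_ARCHETYPES = {
    "included_primary": (100.0, 1.0, "included", "primary"),
    "included_dispersed": (8.0, 1.2, "included", "dispersed"),
    "excluded_primary": (1.0, 100.0, "excluded", "primary"),
    "excluded_dispersed": (1.2, 8.0, "excluded", "dispersed"),
    "bimodal": (0.3, 0.3, "bimodal", "none"),
    "middle": (40.0, 40.0, "middle", "none"),
    "multimodal": (1.2, 1.7, "multimodal", "none"),
}


@dataclass
class PlateSimConfig:
    """Study conditions for the plate-mode cohort."""

    seed: int = 0
    n_cells_per_group: int = 60
    n_events: int = 300              # SE events (differential + null)
    n_differential: int = 40
    delta_psi: float = 0.4           # planted group-2 mean shift, [0, 1] scale
    null_concentration: float = 20.0  # beta concentration of null events
    depth_mean: float = 60.0         # NB mean informative reads per event/cell
    depth_dispersion: float = 3.0    # NB size parameter (smaller = noisier)
    archetype_depth_mean: float = 200.0  # deeper reads for modality fixtures
    n_events_per_archetype: int = 0  # planted modality fixtures (7 classes)
    n_spurious_bimodal: int = 0      # amplification-artifact fixtures
    n_ri_introns: int = 0
    ri_intron_length: int = 300
    ri_skip_mean: float = 40.0
    expression_base_mean: float = 5.0  # log-normal location (log2 scale)
    relation_log2fc: float = 1.5     # planted DE shift for coordinated/opposing

    def __post_init__(self):
        if self.n_cells_per_group <= 0:
            raise ValueError("n_cells_per_group must be positive")
        if self.n_differential > self.n_events:
            raise ValueError("more differential events than events")


@dataclass
class DropletSimConfig:
    """Study conditions for the droplet-mode cohort."""

    seed: int = 0
    n_cells_per_group: int = 200
    n_junctions: int = 300
    n_differential: int = 0
    usage_null: float = 0.3          # shared usage for null junctions
    usage_g1: float = 0.2            # planted differential usage, group 1
    usage_g2: float = 0.5            # planted differential usage, group 2
    gene_mean: float = 20.0          # NB mean gene count per cell
    gene_dispersion: float = 2.0
    dropout: float = 0.3             # extra zero-inflation on gene counts

    def __post_init__(self):
        if self.n_cells_per_group <= 0:
            raise ValueError("n_cells_per_group must be positive")


@dataclass
class PlateSimResult:
    genome: dict[str, str]
    annotation: Annotation
    events: list[SpliceEvent]
    junction_counts: pd.DataFrame
    intron_coverage: pd.DataFrame
    expression: pd.DataFrame
    cell_metadata: pd.DataFrame
    truth: pd.DataFrame


@dataclass
class DropletSimResult:
    gene_counts: pd.DataFrame
    sj_counts: pd.DataFrame
    expression: pd.DataFrame
    cell_metadata: pd.DataFrame
    embedding: pd.DataFrame
    gene_of_junction: dict[str, str]
    truth: pd.DataFrame


_GENE_SPAN = 1000  # bp of genome reserved per toy gene


def _negbin(rng: np.random.Generator, mean: float, size_param: float,
            n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _se_gene_layout(idx: int) -> dict:
    """Three-exon SE gene occupying one span of the toy chromosome."""
    off = idx * _GENE_SPAN
    up = (off + 1, off + 100)
    alt = (off + 201, off + 300)
    down = (off + 401, off + 500)
    return {"up": up, "alt": alt, "down": down, "off": off}


def simulate_plate(config: PlateSimConfig) -> PlateSimResult:
    """Generate a full plate-mode cohort with planted truth."""
    rng = np.random.default_rng(config.seed)
    n_cells = 2 * config.n_cells_per_group
    cells = [f"cell{j:04d}" for j in range(n_cells)]
    group = np.array(["g1"] * config.n_cells_per_group
                     + ["g2"] * config.n_cells_per_group)

    archetype_names = list(MODALITY_ARCHETYPES)
    specs = []  # one dict per event
    for i in range(config.n_events):
        differential = i < config.n_differential
        m1 = rng.uniform(0.15, 0.5)
        m2 = min(m1 + config.delta_psi, 0.95) if differential else m1
        c = config.null_concentration
        specs.append({
            "kind": "differential" if differential else "null",
            "alpha_g1": m1 * c, "beta_g1": (1 - m1) * c,
            "alpha_g2": m2 * c, "beta_g2": (1 - m2) * c,
            "delta_psi_true": (m2 - m1) * 100.0,
            "archetype": "", "depth": config.depth_mean, "spurious": False})
    for name in archetype_names:
        a, b, _, _ = MODALITY_ARCHETYPES[name]
        for _ in range(config.n_events_per_archetype):
            specs.append({"kind": "archetype", "alpha_g1": a, "beta_g1": b,
                          "alpha_g2": a, "beta_g2": b, "delta_psi_true": 0.0,
                          "archetype": name,
                          "depth": config.archetype_depth_mean,
                          "spurious": False})
    for _ in range(config.n_spurious_bimodal):
        # genuinely included event (mean PSI ~ 0.85, the one-sided extreme
        # signature of amplification artifacts) observed through
        # monoallelic capture
        specs.append({"kind": "spurious_bimodal", "alpha_g1": 8.5,
                      "beta_g1": 1.5, "alpha_g2": 8.5, "beta_g2": 1.5,
                      "delta_psi_true": 0.0, "archetype": "",
                      "depth": config.archetype_depth_mean, "spurious": True})

    genes, transcripts, events = {}, {}, []
    junction_rows: dict[str, np.ndarray] = {}
    truth_rows = []
    relations = ["coordinated", "opposing", "isoform_switching"]
    expr_rows, gene_ids = [], []

    for i, spec in enumerate(specs):
        lay = _se_gene_layout(i)
        gid, tid_a, tid_b = f"G{i:04d}", f"G{i:04d}.T1", f"G{i:04d}.T2"
        chrom = "chr1"
        up, alt, down = lay["up"], lay["alt"], lay["down"]
        genes[gid] = Gene(gid, gid, chrom, "+", up[0], down[1])
        transcripts[tid_a] = Transcript(tid_a, gid, chrom, "+",
                                        [Exon(chrom, *up), Exon(chrom, *alt),
                                         Exon(chrom, *down)],
                                        biotype="protein_coding")
        transcripts[tid_b] = Transcript(tid_b, gid, chrom, "+",
                                        [Exon(chrom, *up), Exon(chrom, *down)],
                                        biotype="protein_coding")
        inc1 = JunctionKey(chrom, up[1] + 1, alt[0] - 1)
        inc2 = JunctionKey(chrom, alt[1] + 1, down[0] - 1)
        exc = JunctionKey(chrom, up[1] + 1, down[0] - 1)
        event_id = f"{gid}|SE|{chrom}|+|{up[1]}-{alt[0]}-{alt[1]}-{down[0]}"
        events.append(SpliceEvent(
            event_id=event_id, event_type=EventType.SE, gene_id=gid,
            chrom=chrom, strand="+", included_junctions=(inc1, inc2),
            excluded_junctions=(exc,), alt_coords=(alt,)))

        a = np.where(group == "g1", spec["alpha_g1"], spec["alpha_g2"])
        b = np.where(group == "g1", spec["beta_g1"], spec["beta_g2"])
        psi = rng.beta(a, b)
        if spec["spurious"]:
            psi = (rng.uniform(size=n_cells) < psi).astype(float)
        depth = _negbin(rng, spec["depth"], config.depth_dispersion, n_cells)
        included = rng.binomial(depth, psi)
        inc1_reads = rng.binomial(included, 0.5)
        junction_rows[str(inc1)] = inc1_reads
        junction_rows[str(inc2)] = included - inc1_reads
        junction_rows[str(exc)] = depth - included

        if spec["kind"] == "differential":
            relation = relations[i % len(relations)]
        else:
            relation = "none"
        base = config.expression_base_mean + rng.normal(0, 0.5)
        shift = np.zeros(n_cells)
        if relation in ("coordinated", "opposing"):
            sign = 1.0 if relation == "coordinated" else -1.0
            sign *= np.sign(spec["delta_psi_true"]) or 1.0
            shift = np.where(group == "g2", sign * config.relation_log2fc, 0.0)
        expr = 2.0 ** (base + shift + rng.normal(0, 0.35, n_cells)) - 1.0
        expr_rows.append(np.clip(expr, 0, None))
        gene_ids.append(gid)

        truth_rows.append({
            "event_id": event_id, "gene_id": gid, "event_type": "SE",
            "kind": spec["kind"], "archetype": spec["archetype"],
            "alpha_g1": spec["alpha_g1"], "beta_g1": spec["beta_g1"],
            "alpha_g2": spec["alpha_g2"], "beta_g2": spec["beta_g2"],
            "delta_psi_true": spec["delta_psi_true"],
            "spurious_bimodal": spec["spurious"], "relation": relation,
            "expected_modality": (MODALITY_ARCHETYPES[spec["archetype"]][2]
                                  if spec["archetype"] else ""),
            "expected_sub_modality": (MODALITY_ARCHETYPES[spec["archetype"]][3]
                                      if spec["archetype"] else "")})

    # retained-intron fixtures: two-exon gene with a skippable intron
    coverage_rows, intron_ids = [], []
    n_se_genes = len(specs)
    for k in range(config.n_ri_introns):
        i = n_se_genes + k
        off = i * _GENE_SPAN
        gid, tid = f"RIG{k:03d}", f"RIG{k:03d}.T1"
        chrom = "chr1"
        left = (off + 1, off + 100)
        right = (off + 100 + config.ri_intron_length + 1,
                 off + 200 + config.ri_intron_length)
        intron = (left[1] + 1, right[0] - 1)
        genes[gid] = Gene(gid, gid, chrom, "+", left[0], right[1])
        transcripts[tid] = Transcript(tid, gid, chrom, "+",
                                      [Exon(chrom, *left), Exon(chrom, *right)],
                                      biotype="protein_coding")
        skip = JunctionKey(chrom, *intron)
        event_id = f"{gid}|RI|{chrom}|+|{intron[0]}-{intron[1]}"
        events.append(SpliceEvent(
            event_id=event_id, event_type=EventType.RI, gene_id=gid,
            chrom=chrom, strand="+", included_junctions=(),
            excluded_junctions=(skip,), alt_coords=(intron,)))
        psi = rng.beta(4, 4, n_cells)
        skip_reads = _negbin(rng, config.ri_skip_mean,
                             config.depth_dispersion, n_cells)
        c = skip_reads * psi / np.clip(1 - psi, 1e-6, None)
        coverage = np.round(c * config.ri_intron_length)
        junction_rows[str(skip)] = skip_reads
        coverage_rows.append(coverage)
        intron_ids.append(event_id)
        truth_rows.append({
            "event_id": event_id, "gene_id": gid, "event_type": "RI",
            "kind": "ri", "archetype": "", "alpha_g1": 4.0, "beta_g1": 4.0,
            "alpha_g2": 4.0, "beta_g2": 4.0, "delta_psi_true": 0.0,
            "spurious_bimodal": False, "relation": "none",
            "expected_modality": "", "expected_sub_modality": ""})
        base = config.expression_base_mean
        expr_rows.append(np.clip(2.0 ** (base + rng.normal(0, 0.35, n_cells)) - 1.0,
                                 0, None))
        gene_ids.append(gid)

    genome_len = (len(specs) + config.n_ri_introns) * _GENE_SPAN + _GENE_SPAN
    genome = {"chr1": "".join(rng.choice(list("ACGT"), size=genome_len))}

    junction_counts = pd.DataFrame(junction_rows, index=cells).T.astype(int)
    junction_counts.index.name = "junction"
    intron_coverage = pd.DataFrame(coverage_rows, index=intron_ids,
                                   columns=cells, dtype=float)
    expression = pd.DataFrame(expr_rows, index=gene_ids, columns=cells)
    metadata = pd.DataFrame({"group": group}, index=cells)
    truth = pd.DataFrame(truth_rows)
    annotation = Annotation(genes=genes, transcripts=transcripts)
    return PlateSimResult(genome=genome, annotation=annotation, events=events,
                          junction_counts=junction_counts,
                          intron_coverage=intron_coverage,
                          expression=expression, cell_metadata=metadata,
                          truth=truth)


def simulate_droplet(config: DropletSimConfig) -> DropletSimResult:
    """Generate a droplet-mode cohort: thinned junction counts over NB gene
    counts with zero inflation, planted usage per group."""
    rng = np.random.default_rng(config.seed)
    n_cells = 2 * config.n_cells_per_group
    cells = [f"bc{j:05d}" for j in range(n_cells)]
    group = np.array(["g1"] * config.n_cells_per_group
                     + ["g2"] * config.n_cells_per_group)

    gene_rows, sj_rows, truth_rows = [], [], []
    gene_ids, junction_ids = [], []
    gene_of_junction = {}
    for j in range(config.n_junctions):
        gid = f"DG{j:04d}"
        jid = f"chr1:{j * 1000 + 101}:{j * 1000 + 200}"
        differential = j < config.n_differential
        counts = _negbin(rng, config.gene_mean, config.gene_dispersion, n_cells)
        counts = np.where(rng.uniform(size=n_cells) < config.dropout, 0, counts)
        if differential:
            u = np.where(group == "g1", config.usage_g1, config.usage_g2)
        else:
            u = np.full(n_cells, config.usage_null)
        sj = rng.binomial(counts, u)
        gene_rows.append(counts)
        sj_rows.append(sj)
        gene_ids.append(gid)
        junction_ids.append(jid)
        gene_of_junction[jid] = gid
        truth_rows.append({"junction": jid, "gene_id": gid,
                           "differential": differential,
                           "usage_g1": config.usage_g1 if differential else config.usage_null,
                           "usage_g2": config.usage_g2 if differential else config.usage_null})

    gene_counts = pd.DataFrame(gene_rows, index=gene_ids, columns=cells)
    sj_counts = pd.DataFrame(sj_rows, index=junction_ids, columns=cells)
    expression = session_io.cpm_normalize(gene_counts)
    metadata = pd.DataFrame({"group": group}, index=cells)
    embedding = pd.DataFrame(rng.normal(size=(n_cells, 2)),
                             index=cells, columns=["dim1", "dim2"])
    truth = pd.DataFrame(truth_rows)
    return DropletSimResult(gene_counts=gene_counts, sj_counts=sj_counts,
                            expression=expression, cell_metadata=metadata,
                            embedding=embedding,
                            gene_of_junction=gene_of_junction, truth=truth)


def write_plate_fixtures(result: PlateSimResult, out_dir) -> None:
    """Emit the plate cohort in the standard on-disk formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in result.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    session_io.write_gtf(result.annotation, out / "annotation.gtf")
    session_io.write_matrix_tsv(result.junction_counts, out / "sj_counts.tsv")
    session_io.write_matrix_tsv(result.intron_coverage, out / "intron_coverage.tsv")
    session_io.write_matrix_tsv(result.expression, out / "expression.tsv")
    result.cell_metadata.to_csv(out / "cell_metadata.tsv", sep="\t")
    result.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    from .events import events_to_table
    events_to_table(result.events).to_csv(out / "events.tsv", sep="\t",
                                          index=False)


def write_droplet_fixtures(result: DropletSimResult, out_dir) -> None:
    """Emit the droplet cohort (MTX triplet + sidecars, TSVs, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session_io.write_mtx(result.gene_counts, out / "matrix.mtx",
                         out / "barcodes.tsv", out / "features.tsv")
    session_io.write_matrix_tsv(result.sj_counts, out / "sj_counts.tsv")
    session_io.write_matrix_tsv(result.expression, out / "expression.tsv")
    result.cell_metadata.to_csv(out / "cell_metadata.tsv", sep="\t")
    result.embedding.to_csv(out / "embedding.tsv", sep="\t")
    pd.Series(result.gene_of_junction, name="gene_id").rename_axis(
        "junction").to_csv(out / "gene_of_junction.tsv", sep="\t")
    result.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
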