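"""Synthetic reference, gene models, panels and genotype matrices with
planted structure.

The generator emulates a resequencing panel of inbred lines split into a
target phenotype group and a complement (defaults: 9 vs 15 lines across 12
chromosomes named Chr00–Chr11, Chr00 standing for the unanchored
pseudo-chromosome).  A configurable fraction of SNPs is planted as perfectly
co-segregating diagnostic loci — the target group fixed for one allele, the
complement for the other — and a fraction of those carries an
allele-differential restriction motif written into the reference flank, so
the CAPS conversion stage has guaranteed positives.  Background loci are
rejected-and-redrawn if they would co-segregate by chance, keeping the truth
table exact.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    EnzymeDefinition,
    GeneModel,
    GeneModelSet,
    GenotypeMatrix,
    SamplePanel,
    Zygosity,
    logger,
    read_enzyme_table,
)

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic panel.

    Defaults mirror the emulated study: 24 inbred lines (9 red-flesh targets
    vs 15 non-red), 12 chromosomes, ~20x read depth, biallelic SNPs with low
    residual heterozygosity and missingness as expected for inbred material.
    """

    seed: int = 0
    n_chromosomes: int = 12
    chromosome_length_bp: int = 1_000_000
    genes_per_chromosome: int = 10
    gene_length_bp: int = 3_000
    exons_per_gene: int = 3
    n_target_samples: int = 9
    n_other_samples: int = 15
    n_snps: int = 5_000
    diagnostic_fraction: float = 0.01
    diagnostic_genic_prob: float = 0.9
    het_rate: float = 0.0
    missing_rate: float = 0.0
    ambiguous_rate: float = 0.0
    depth_mean: float = 20.0
    depth_dispersion: float = 5.0
    depth_floor: int = 3
    enzyme_site_plant_rate: float = 0.5

    def __post_init__(self):
        for name in ("diagnostic_fraction", "diagnostic_genic_prob", "het_rate",
                     "missing_rate", "ambiguous_rate", "enzyme_site_plant_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_chromosomes, self.n_target_samples, self.n_other_samples,
               self.n_snps, self.genes_per_chromosome) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def chromosome_names(self) -> list[str]:
        return ["Chr00" if i == 0 else f"Chr{i}" for i in range(self.n_chromosomes)]

    @property
    def n_diagnostic(self) -> int:
        return round(self.diagnostic_fraction * self.n_snps)


# ---------------------------------------------------------------------------
# Reference + gene models
# ---------------------------------------------------------------------------

def simulate_reference(cfg: SimulationConfig) -> tuple[dict, GeneModelSet]:
    """I.i.d. uniform nucleotide chromosomes plus non-overlapping gene models
    with exon/intron structure, deterministic under the seed."""
    rng = np.random.default_rng(cfg.seed)
    slot = cfg.chromosome_length_bp // cfg.genes_per_chromosome
    if cfg.gene_length_bp + 2 > slot:
        raise ValueError("gene demand exceeds chromosome capacity")

    reference: dict[str, str] = {}
    genes: list[GeneModel] = []
    counter = 1
    for chrom in cfg.chromosome_names:
        seq = rng.choice(BASES, size=cfg.chromosome_length_bp)
        reference[chrom] = "".join(seq)
        for g in range(cfg.genes_per_chromosome):
            slot_start = g * slot + 1
            jitter = int(rng.integers(0, slot - cfg.gene_length_bp))
            start = slot_start + jitter
            end = start + cfg.gene_length_bp - 1
            # split the gene into exons_per_gene exons with introns between
            n_ex = cfg.exons_per_gene
            cuts = np.sort(rng.choice(np.arange(1, 2 * n_ex), size=2 * n_ex - 2,
                                      replace=False)) * (cfg.gene_length_bp // (2 * n_ex))
            bounds = np.concatenate([[0], cuts, [cfg.gene_length_bp]])
            exons = tuple((start + int(bounds[2 * i]),
                           start + int(bounds[2 * i + 1]) - 1) for i in range(n_ex))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"Syn{counter:05d}", chrom, start, end, strand, exons))
            counter += 1
    return reference, GeneModelSet(genes)


def write_gff3(genes: GeneModelSet, path):
    """Emit the gene models as GFF3 (gene + exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.genes:
            fh.write(f"{g.chrom}\tcapsforge\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.accession}\n")
            for n, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tcapsforge\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.accession}.exon{n};Parent={g.accession}\n")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _plant_motif(reference: dict, chrom: str, pos: int, enzyme: EnzymeDefinition,
                 rng, occupied: set) -> tuple[str, str] | None:
    """Write the enzyme's recognition motif into the reference so that the
    SNP sits on a non-degenerate motif position: the reference (cut) allele
    completes the motif, the alternative breaks it.  Returns (ref, alt), or
    None when the motif cannot be placed without touching another SNP or
    without yielding allele-differential cut sites."""
    from .diagnostic_caps import find_cut_sites
    from .genotype_io import IUPAC_CODES

    motif = enzyme.recognition
    fixed = [i for i, c in enumerate(motif) if c in "ACGT"]
    if not fixed:
        return None
    offset = int(rng.choice(fixed))
    start = pos - 1 - offset  # 0-based motif start
    seq = reference[chrom]
    if start < 0 or start + len(motif) > len(seq):
        return None
    span = {(chrom, p) for p in range(start + 1, start + len(motif) + 1)}
    if span & occupied - {(chrom, pos)}:
        return None  # motif would overwrite another variant's context
    concrete = "".join(c if c in "ACGT" else str(rng.choice(list(IUPAC_CODES[c])))
                       for c in motif)
    reference[chrom] = seq[:start] + concrete + seq[start + len(motif):]
    ref_allele = concrete[offset]
    alt_allele = str(rng.choice([b for b in "ACGT" if b != ref_allele]))
    # confirm the alleles really differ in cut map over a local window
    lo, hi = max(0, start - 30), min(len(reference[chrom]), start + len(motif) + 30)
    window = reference[chrom][lo:hi]
    i = pos - 1 - lo
    cuts = {a: tuple(find_cut_sites(window[:i] + a + window[i + 1:], enzyme))
            for a in (ref_allele, alt_allele)}
    if cuts[ref_allele] == cuts[alt_allele]:
        return None
    return ref_allele, alt_allele


def simulate_genotypes(cfg: SimulationConfig, reference: dict,
                       genes: GeneModelSet,
                       enzyme_panel: list[EnzymeDefinition] | None = None,
                       ) -> tuple[GenotypeMatrix, SamplePanel, pd.DataFrame]:
    """Draw the genotype matrix, sample panel, and truth table.

    Diagnostic loci are fixed within each group for different alleles;
    background loci draw per-sample homozygous genotypes at a random allele
    frequency and are redrawn when they would perfectly co-segregate with the
    groups.  Het/missing/ambiguous noise is then applied per call, and read
    depths and allele-depth fractions are drawn so that re-classifying from
    read fractions reproduces the intended zygosity.  Note the reference is
    modified in place where allele-differential motifs are planted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    enzyme_panel = enzyme_panel if enzyme_panel is not None else read_enzyme_table()
    chroms = cfg.chromosome_names
    n_s = cfg.n_target_samples + cfg.n_other_samples
    samples = [f"red{i + 1:02d}" for i in range(cfg.n_target_samples)] + \
              [f"oth{i + 1:02d}" for i in range(cfg.n_other_samples)]
    is_target = np.array([True] * cfg.n_target_samples + [False] * cfg.n_other_samples)
    panel = SamplePanel(pd.DataFrame({
        "sample_id": samples,
        "group_label": ["red"] * cfg.n_target_samples
                       + (["yellow", "orange"] * cfg.n_other_samples)[:cfg.n_other_samples],
        "is_target_group": is_target,
    }))

    # -- positions ---------------------------------------------------------
    n_diag = cfg.n_diagnostic
    if cfg.diagnostic_fraction > 0 and n_diag < 1:
        logger.warning("diagnostic_fraction x n_snps < 1: no diagnostic loci planted")
    genic_pool = [(g.chrom, p) for g in genes.genes
                  for p in range(g.start, g.end + 1, 97)]
    rng.shuffle(genic_pool)
    used: set[tuple[str, int]] = set()
    positions: list[tuple[str, int, bool]] = []  # chrom, pos, is_diagnostic
    gi = 0
    for _ in range(n_diag):
        if gi < len(genic_pool) and rng.random() < cfg.diagnostic_genic_prob:
            key = genic_pool[gi]; gi += 1
        else:
            key = (chroms[int(rng.integers(len(chroms)))],
                   int(rng.integers(1, cfg.chromosome_length_bp + 1)))
        while key in used:
            key = (chroms[int(rng.integers(len(chroms)))],
                   int(rng.integers(1, cfg.chromosome_length_bp + 1)))
        used.add(key)
        positions.append((*key, True))
    while len(positions) < cfg.n_snps:
        key = (chroms[int(rng.integers(len(chroms)))],
               int(rng.integers(1, cfg.chromosome_length_bp + 1)))
        if key in used:
            continue
        used.add(key)
        positions.append((*key, False))
    positions.sort(key=lambda t: (chroms.index(t[0]), t[1]))

    # -- alleles and genotypes --------------------------------------------
    n_v = cfg.n_snps
    aa = np.empty((n_s, n_v), dtype="<U1")
    truth_rows = []
    plant_cycle = 0
    for j, (chrom, pos, is_diag) in enumerate(positions):
        ref = reference[chrom][pos - 1]
        planted_enzyme = ""
        if is_diag and rng.random() < cfg.enzyme_site_plant_rate:
            enz = enzyme_panel[plant_cycle % len(enzyme_panel)]
            plant_cycle += 1
            planted = _plant_motif(reference, chrom, pos, enz, rng, used)
            if planted is not None:
                ref, alt = planted
                planted_enzyme = enz.name
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        else:
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))

        if is_diag:
            target_allele, other_allele = (ref, alt) if rng.random() < 0.5 else (alt, ref)
            aa[:, j] = np.where(is_target, target_allele, other_allele)
        else:
            target_allele = other_allele = ""
            while True:
                f = rng.uniform(0.05, 0.95)
                col = np.where(rng.random(n_s) < f, alt, ref)
                fixed_t = len(set(col[is_target])) == 1
                fixed_o = len(set(col[~is_target])) == 1
                if not (fixed_t and fixed_o and col[is_target][0] != col[~is_target][0]):
                    break  # reject accidental co-segregation
            aa[:, j] = col
        truth_rows.append((chrom, pos, ref, alt, is_diag, target_allele,
                           other_allele, planted_enzyme))

    ab = aa.copy()

    # -- noise -------------------------------------------------------------
    noise = rng.random((n_s, n_v))
    het_mask = noise < cfg.het_rate
    miss_mask = (noise >= cfg.het_rate) & (noise < cfg.het_rate + cfg.missing_rate)
    ambi_mask = ((noise >= cfg.het_rate + cfg.missing_rate)
                 & (noise < cfg.het_rate + cfg.missing_rate + cfg.ambiguous_rate))
    if het_mask.any():
        # het partner: flip to the other allele of the locus
        ref_grid = np.broadcast_to(np.array([r[2] for r in truth_rows]), (n_s, n_v))
        alt_grid = np.broadcast_to(np.array([r[3] for r in truth_rows]), (n_s, n_v))
        partner = np.where(aa == ref_grid, alt_grid, ref_grid)
        ab[het_mask] = partner[het_mask]
    aa[miss_mask] = MISSING
    ab[miss_mask] = MISSING

    # -- depth and zygosity ------------------------------------------------
    # negative-binomial-like depth with a configurable floor; the floor sits
    # at the default depth filter so that masking cannot distort planted
    # structure unless the caller lowers it deliberately
    mean_excess = max(cfg.depth_mean - cfg.depth_floor, 1e-9)
    p = cfg.depth_dispersion / (cfg.depth_dispersion + mean_excess)
    depth = (cfg.depth_floor
             + rng.negative_binomial(cfg.depth_dispersion, p, size=(n_s, n_v))
             ).astype(np.int32)
    depth[miss_mask] = 0
    zy = GenotypeMatrix._derive_zygosity(aa, ab)
    zy[ambi_mask & ~miss_mask & ~het_mask] = Zygosity.AMBIGUOUS

    variants = pd.DataFrame(truth_rows, columns=[
        "chrom", "pos", "ref", "alt", "is_diagnostic", "target_allele",
        "other_allele", "planted_enzyme"])
    matrix = GenotypeMatrix(samples, variants[["chrom", "pos", "ref", "alt"]],
                            aa, ab, depth, zy)
    matrix.variants["mq"] = 60.0
    truth = variants.copy()
    truth["location_class"] = [
        "genic" if any(g.start <= pos <= g.end for g in genes.on(chrom)) else "intergenic"
        for chrom, pos in zip(truth["chrom"], truth["pos"])]
    return matrix, panel, truth


def simulate_bundle(cfg: SimulationConfig, out_dir=None):
    """Full synthetic bundle: reference, gene models, genotypes, panel, truth.
    When ``out_dir`` is given, writes FASTA, GFF3, VCF, panel TSV and truth
    TSV there and returns the paths as well."""
    from .genotype_io import (write_genotype_vcf, write_reference,
                              write_sample_panel)

    reference, genes = simulate_reference(cfg)
    matrix, panel, truth = simulate_genotypes(cfg, reference, genes)
    bundle = {"reference": reference, "genes": genes, "matrix": matrix,
              "panel": panel, "truth": truth, "config": cfg}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_reference(reference, out / "reference.fa")
        write_gff3(genes, out / "genes.gff3")
        lengths = {c: len(s) for c, s in reference.items()}
        write_genotype_vcf(matrix, out / "genotypes.vcf", contig_lengths=lengths)
        write_sample_panel(panel, out / "panel.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        bundle["paths"] = {k: out / v for k, v in {
            "reference": "reference.fa", "genes": "genes.gff3",
            "vcf": "genotypes.vcf", "panel": "panel.tsv", "truth": "truth.tsv"}.items()}
    return bundle
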