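"""Zygosity classification, variant filtering, substitution typing, and genic
annotation.

The filter chain mirrors a resequencing SNP-matrix workflow: site mapping
quality, per-call read depth, biallelic state, then minor allele frequency,
applied in that fixed order so removal counts are reproducible.  The upstream
"unmapped reads" criterion acts before a VCF exists and is carried only as a
zero-count placeholder in the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GeneModelSet,
    GenotypeMatrix,
    Zygosity,
    logger,
)


@dataclass
class FilterConfig:
    """Thresholds for the SNP-matrix filters and zygosity classes.

    min_depth
        Reads required per call (calls below become missing; default 3).
    min_mapping_quality
        Phred-scaled site mapping quality (default 30).
    min_maf
        Minor allele frequency cutoff, exclusive of values below it
        (default 0.05).
    hom_fraction, het_low, het_high
        Read-fraction boundaries of the homozygous (>= 0.90 of reads) and
        heterozygous (0.40 to 0.60 of reads) classes; everything between is
        "ambiguous" (indistinguishable as either).
    ambiguous_as_missing
        Treat ambiguous-zygosity calls as missing in downstream allele
        counting (default True).
    """

    min_depth: int = 3
    min_mapping_quality: float = 30.0
    min_maf: float = 0.05
    require_biallelic: bool = True
    hom_fraction: float = 0.90
    het_low: float = 0.40
    het_high: float = 0.60
    ambiguous_as_missing: bool = True

    def __post_init__(self):
        if not (0.0 <= self.het_low <= self.het_high <= 1.0):
            raise ValueError("need 0 <= het_low <= het_high <= 1")
        if not (0.5 < self.hom_fraction <= 1.0):
            raise ValueError("need 0.5 < hom_fraction <= 1")


class SubstitutionClass(str, Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"


class LocationClass(str, Enum):
    EXON = "exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"


def classify_zygosity(ref_reads: int, alt_reads: int,
                      cfg: FilterConfig | None = None) -> Zygosity:
    """Classify a call from its ref/alt read counts.

    Homozygous when either allele holds >= ``hom_fraction`` of the reads,
    heterozygous when the alt fraction lies in [het_low, het_high], otherwise
    ambiguous.  Zero total reads is a missing call, not an error.
    """
    cfg = cfg or FilterConfig()
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total == 0:
        return Zygosity.MISSING
    frac_alt = alt_reads / total
    if max(frac_alt, 1.0 - frac_alt) >= cfg.hom_fraction:
        return Zygosity.HOM
    if cfg.het_low <= frac_alt <= cfg.het_high:
        return Zygosity.HET
    return Zygosity.AMBIGUOUS


def allele_counts(matrix: GenotypeMatrix, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Per-variant counted allele copies: homozygotes contribute 2 copies of
    their allele, heterozygotes 1 of each, half-missing calls 1 copy of the
    observed allele; missing (and, by default, ambiguous) calls contribute
    nothing.  Returns columns ref_copies, alt_copies, other_copies."""
    cfg = cfg or FilterConfig()
    drop = [Zygosity.MISSING]
    if cfg.ambiguous_as_missing:
        drop.append(Zygosity.AMBIGUOUS)
    # half-missing calls are zygosity AMBIGUOUS but keep their observed allele
    half = (matrix.allele_a == MISSING) ^ (matrix.allele_b == MISSING)
    usable = ~np.isin(matrix.zygosity, drop) | half

    ref = matrix.variants["ref"].to_numpy()[None, :]
    alt = matrix.variants["alt"].to_numpy()[None, :]
    out = np.zeros((matrix.n_variants, 3), dtype=np.int64)
    for allele_grid in (matrix.allele_a, matrix.allele_b):
        obs = usable & (allele_grid != MISSING)
        out[:, 0] += (obs & (allele_grid == ref)).sum(axis=0)
        out[:, 1] += (obs & (allele_grid == alt)).sum(axis=0)
        out[:, 2] += (obs & (allele_grid != ref) & (allele_grid != alt)).sum(axis=0)
    return pd.DataFrame(out, columns=["ref_copies", "alt_copies", "other_copies"])


def filter_variants(matrix: GenotypeMatrix,
                    cfg: FilterConfig | None = None) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the SNP-matrix filters in fixed order and log removals.

    Order: mapping quality -> read depth -> biallelic -> minor allele
    frequency.  The depth rule masks individual calls below ``min_depth`` to
    missing and removes variants left with no observed call.  Filtering is
    idempotent: a second pass removes nothing.
    """
    cfg = cfg or FilterConfig()
    log_rows = [("unmapped_reads", 0)]  # applied upstream of any VCF
    m = matrix

    # 1. site mapping quality
    if "mq" in m.variants.columns:
        mq = m.variants["mq"].to_numpy(dtype=float)
        keep = ~(mq < cfg.min_mapping_quality)  # NaN passes
    else:
        keep = np.ones(m.n_variants, dtype=bool)
    log_rows.append(("mapping_quality", int((~keep).sum())))
    m = m.subset_variants(keep)

    # 2. read depth: mask low-depth calls, drop fully-missing variants
    low = m.depth < cfg.min_depth
    if low.any():
        m = GenotypeMatrix(m.samples, m.variants,
                           np.where(low, MISSING, m.allele_a),
                           np.where(low, MISSING, m.allele_b),
                           np.where(low, 0, m.depth))
    keep = (m.zygosity != Zygosity.MISSING).any(axis=0)
    log_rows.append(("read_depth", int((~keep).sum())))
    m = m.subset_variants(keep)

    # 3. biallelic: no third allele among observed calls, ref != alt
    counts = allele_counts(m, cfg)
    if cfg.require_biallelic:
        keep = (counts["other_copies"].to_numpy() == 0) & \
               (m.variants["ref"].to_numpy() != m.variants["alt"].to_numpy())
        log_rows.append(("biallelic", int((~keep).sum())))
        m = m.subset_variants(keep)
        counts = counts[keep].reset_index(drop=True)
    else:
        log_rows.append(("biallelic", 0))

    # 4. minor allele frequency
    ref_c = counts["ref_copies"].to_numpy(dtype=float)
    alt_c = counts["alt_copies"].to_numpy(dtype=float)
    total = ref_c + alt_c
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(ref_c, alt_c) / total
    keep = np.where(total > 0, maf >= cfg.min_maf, False)
    log_rows.append(("minor_allele_frequency", int((~keep).sum())))
    m = m.subset_variants(keep)

    log = pd.DataFrame(log_rows, columns=["criterion", "removed"])
    log.loc[len(log)] = ("retained", m.n_variants)
    logger.info("filter_variants: %s", dict(log_rows))
    return m, log


def classify_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Transition (purine<->purine, pyrimidine<->pyrimidine) or transversion."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    for a in (ref, alt):
        if a not in "ACGT":
            raise ValueError(f"invalid nucleotide {a!r}")
    return (SubstitutionClass.TRANSITION
            if {ref, alt} in ({"A", "G"}, {"C", "T"})
            else SubstitutionClass.TRANSVERSION)


def summarize_tstv(annotations: pd.DataFrame) -> tuple[float, float]:
    """Fractions of transitions and transversions among annotated variants."""
    counts = annotations["substitution_class"].value_counts()
    ts = int(counts.get(SubstitutionClass.TRANSITION, 0))
    tv = int(counts.get(SubstitutionClass.TRANSVERSION, 0))
    if ts + tv == 0:
        raise ValueError("no classified substitutions")
    return ts / (ts + tv), tv / (ts + tv)


def annotate_location(chrom: str, pos: int,
                      genes: GeneModelSet) -> tuple[LocationClass, str | None]:
    """Exon when inside an exon interval, intron when inside a gene but not an
    exon, else intergenic.  Overlapping genes: the gene whose exon contains the
    position wins, else the first covering gene in coordinate order."""
    intron_hit = None
    for g in genes.on(chrom):
        if g.start <= pos <= g.end:
            if any(s <= pos <= e for s, e in g.exons):
                return LocationClass.EXON, g.accession
            if intron_hit is None:
                intron_hit = g.accession
    if intron_hit is not None:
        return LocationClass.INTRON, intron_hit
    return LocationClass.INTERGENIC, None


def annotate_variants(matrix: GenotypeMatrix, genes: GeneModelSet,
                      cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Per-variant annotation table: position, alleles, substitution class,
    genic context, PIC and mean call depth."""
    from .diversity_selection import pic_from_counts

    cfg = cfg or FilterConfig()
    counts = allele_counts(matrix, cfg)
    rows = []
    observed = matrix.zygosity != int(Zygosity.MISSING)
    for j, v in matrix.variants.iterrows():
        loc, acc = annotate_location(v["chrom"], int(v["pos"]), genes)
        try:
            sub = classify_substitution(v["ref"], v["alt"])
        except ValueError:
            sub = None
        copies = [int(counts.at[j, "ref_copies"]), int(counts.at[j, "alt_copies"])]
        pic = pic_from_counts(copies) if sum(copies) else np.nan
        obs_j = observed[:, j]
        mean_depth = float(matrix.depth[obs_j, j].mean()) if obs_j.any() else 0.0
        rows.append((v["chrom"], int(v["pos"]), v["ref"], v["alt"], sub, loc, acc,
                     pic, mean_depth))
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "substitution_class", "location_class",
        "gene_accession", "pic", "mean_depth",
    ])
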