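"""Marker informativeness (PIC), evenly spaced subset selection, window
densities and hotspots, identity-by-state distances, neighbor-joining trees,
and PCA on genotype dosages.

PIC follows the Botstein formula

    PIC = 1 - sum_i p_i^2 - sum_i sum_{j>i} 2 p_i^2 p_j^2

with allele frequencies counted from allele copies (homozygote = 2 copies,
heterozygote = 1 of each, half-missing = 1 of the observed allele; missing and
ambiguous calls excluded).  For a biallelic locus PIC is bounded by 0.375,
attained at p = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeCall, GenotypeMatrix, Zygosity, logger, normalize_chrom
from .variant_processing import LocationClass


@dataclass
class SelectionConfig:
    """Evenly spaced genome-wide subset selection.

    interval_bp
        Physical window size per chromosome (default 0.5 Mb).
    max_per_interval
        Markers kept per window (default 4).
    min_pic, min_depth
        Exclusive lower bounds on PIC (> 0) and mean read depth (> 3).
    prefer_genic
        Rank genic candidates ahead of intergenic ones rather than excluding
        intergenic outright.
    """

    interval_bp: int = 500_000
    max_per_interval: int = 4
    min_pic: float = 0.0
    min_depth: float = 3.0
    prefer_genic: bool = True

    def __post_init__(self):
        if self.interval_bp <= 0 or self.max_per_interval < 1:
            raise ValueError("interval_bp > 0 and max_per_interval >= 1 required")


# ---------------------------------------------------------------------------
# PIC
# ---------------------------------------------------------------------------

def pic_from_counts(copies: Sequence[int]) -> float:
    """Botstein PIC from counted allele copies (any number of alleles)."""
    copies = [c for c in copies if c > 0]
    total = sum(copies)
    if total == 0:
        raise ValueError("no counted allele copies")
    p = np.asarray(copies, dtype=float) / total
    hom = float(np.sum(p ** 2))
    cross = sum(2.0 * p[i] ** 2 * p[j] ** 2 for i, j in combinations(range(len(p)), 2))
    return 1.0 - hom - cross


def compute_pic(column: Iterable[GenotypeCall]) -> float:
    """PIC of one marker column.  Ambiguous-zygosity full calls are excluded;
    half-missing calls contribute their single observed allele."""
    counts: dict[str, int] = {}
    n_obs = 0
    for call in column:
        if call.zygosity == Zygosity.MISSING:
            continue
        if call.zygosity == Zygosity.AMBIGUOUS and not call.is_half_missing:
            continue
        for a in call.observed_alleles:
            counts[a] = counts.get(a, 0) + 1
        n_obs += 1
    if not counts:
        raise ValueError("PIC undefined: no usable calls in column")
    return pic_from_counts(list(counts.values()))


# ---------------------------------------------------------------------------
# Window densities & hotspots
# ---------------------------------------------------------------------------

def count_window_density(variants: pd.DataFrame,
                         chromosome_lengths: Mapping[str, int],
                         window_bp: int = 100_000) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows of ``window_bp`` and
    count SNPs (and InDels when a ``kind`` column marks them) per window.

    Windows are 1-based inclusive [start, end]; the last window is truncated
    at the chromosome end.  Counts partition the variant set.
    """
    kinds = variants["kind"] if "kind" in variants.columns else pd.Series("snp", index=variants.index)
    rows = []
    for chrom, length in chromosome_lengths.items():
        chrom = normalize_chrom(chrom)
        sel = variants["chrom"].map(normalize_chrom) == chrom
        pos = variants.loc[sel, "pos"].to_numpy(dtype=np.int64)
        kind = kinds[sel].to_numpy()
        if (pos < 1).any() or (pos > length).any():
            raise ValueError(f"variant position outside {chrom} [1, {length}]")
        n_win = max(1, -(-length // window_bp))
        idx = (pos - 1) // window_bp
        snp = np.bincount(idx[kind == "snp"], minlength=n_win)
        indel = np.bincount(idx[kind != "snp"], minlength=n_win)
        for w in range(n_win):
            rows.append((chrom, w * window_bp + 1, min((w + 1) * window_bp, length),
                         int(snp[w]), int(indel[w])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "snp_count", "indel_count"])


def find_hotspots(variants: pd.DataFrame, densities: pd.DataFrame,
                  region: tuple[str, int, int]) -> dict:
    """Sum of SNPs inside ``region`` (chrom, start, end; 1-based inclusive),
    computed from raw positions rather than binned counts, plus the region's
    windows ranked by SNP count descending."""
    chrom, start, end = normalize_chrom(region[0]), int(region[1]), int(region[2])
    dens_c = densities[densities["chrom"] == chrom]
    if dens_c.empty:
        raise ValueError(f"no windows on chromosome {chrom}")
    chrom_end = int(dens_c["end"].max())
    if start < 1 or end > chrom_end or start > end:
        raise ValueError(f"region {region} outside {chrom} [1, {chrom_end}]")
    kinds = variants["kind"] if "kind" in variants.columns else pd.Series("snp", index=variants.index)
    sel = ((variants["chrom"].map(normalize_chrom) == chrom)
           & (variants["pos"] >= start) & (variants["pos"] <= end)
           & (kinds == "snp"))
    overlapping = dens_c[(dens_c["end"] >= start) & (dens_c["start"] <= end)]
    ranked = overlapping.sort_values(["snp_count", "start"],
                                     ascending=[False, True]).reset_index(drop=True)
    return {"region": (chrom, start, end),
            "snp_sum": int(sel.sum()),
            "windows": ranked}


# ---------------------------------------------------------------------------
# Evenly spaced subset
# ---------------------------------------------------------------------------

def select_marker_subset(annotations: pd.DataFrame,
                         cfg: SelectionConfig | None = None) -> pd.DataFrame:
    """Select up to ``max_per_interval`` markers per physical interval.

    Candidates must exceed the depth and PIC bounds (both exclusive).  Within
    an interval they are ranked genic before intergenic (when prefer_genic),
    then PIC descending, then position ascending — a deterministic order, so
    the result is invariant to input ordering.  Output is coordinate-sorted.
    """
    cfg = cfg or SelectionConfig()
    ann = annotations.copy()
    ann["_genic"] = ann["location_class"].isin([LocationClass.EXON, LocationClass.INTRON])
    ok = (ann["mean_depth"] > cfg.min_depth) & (ann["pic"] > cfg.min_pic)
    ann = ann[ok.fillna(False)]
    ann = ann.assign(_interval=(ann["pos"].astype(np.int64) - 1) // cfg.interval_bp)
    sort_cols = ["chrom", "_interval", "pic", "pos"]
    ascending = [True, True, False, True]
    if cfg.prefer_genic:
        sort_cols.insert(2, "_genic")
        ascending.insert(2, False)
    picked = (ann.sort_values(sort_cols, ascending=ascending, kind="mergesort")
              .groupby(["chrom", "_interval"], sort=False)
              .head(cfg.max_per_interval))
    return (picked.sort_values(["chrom", "pos"])
            .drop(columns=["_genic", "_interval"])
            .reset_index(drop=True))


def summarize_selection(selected: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome counts of selected markers split genic/intergenic."""
    genic = selected["location_class"].isin([LocationClass.EXON, LocationClass.INTRON])
    df = pd.DataFrame({"chrom": selected["chrom"], "genic": genic})
    out = (df.groupby("chrom").agg(n_selected=("genic", "size"),
                                   n_genic=("genic", "sum")).reset_index())
    out["n_intergenic"] = out["n_selected"] - out["n_genic"]
    total = pd.DataFrame([{"chrom": "Total", "n_selected": out["n_selected"].sum(),
                           "n_genic": out["n_genic"].sum(),
                           "n_intergenic": out["n_intergenic"].sum()}])
    return pd.concat([out, total], ignore_index=True)[
        ["chrom", "n_selected", "n_intergenic", "n_genic"]]


# ---------------------------------------------------------------------------
# IBS / NJ / PCA
# ---------------------------------------------------------------------------

def ibs_distance(matrix: GenotypeMatrix) -> "skbio.DistanceMatrix":
    """Pairwise 1 - IBS distances.

    Per locus the sharing score is 1 for identical genotypes, 0.5 when exactly
    one allele is shared, 0 otherwise; with both alleles drawn from {ref, alt}
    this is 1 - |dosage_i - dosage_j| / 2.  Loci where either call is missing,
    half-missing or ambiguous are excluded for that pair; a pair with no
    co-called locus is an error naming the pair.
    """
    from skbio import DistanceMatrix

    if matrix.n_samples < 2:
        raise ValueError("IBS needs at least 2 samples")
    dosage = matrix.dosage()
    n = matrix.n_samples
    dist = np.zeros((n, n))
    valid = ~np.isnan(dosage)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            if not both.any():
                raise ValueError(
                    f"no co-called loci for pair ({matrix.samples[i]}, {matrix.samples[j]})")
            ibs = 1.0 - np.abs(dosage[i, both] - dosage[j, both]).mean() / 2.0
            dist[i, j] = dist[j, i] = 1.0 - ibs
    return DistanceMatrix(dist, ids=matrix.samples)


def build_nj_tree(distance_matrix) -> "skbio.TreeNode":
    """Neighbor-joining tree (Saitou–Nei Q-criterion) from a distance matrix.
    Negative branch-length estimates are clamped to zero.  Requires n >= 3."""
    from skbio.tree import nj

    if distance_matrix.shape[0] < 3:
        raise ValueError("NJ requires at least 3 taxa")
    return nj(distance_matrix, neg_as_zero=True)


def tree_to_newick(tree) -> str:
    """Serialize a tree to a newick string."""
    import io

    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def pca_genotypes(matrix: GenotypeMatrix,
                  n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA on the dosage matrix (hom-ref 0, het 1, hom-alt 2), with missing
    dosages imputed by the per-variant mean.  Returns (coordinates indexed by
    sample, explained-variance fractions)."""
    from sklearn.decomposition import PCA

    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.dosage()
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_mean = np.nan_to_num(col_mean)  # all-missing columns -> 0
    x = np.where(np.isnan(x), col_mean[None, :], x)
    k = min(n_components, matrix.n_samples - 1, max(1, matrix.n_variants))
    cols = [f"PC{i + 1}" for i in range(k)]
    if x.var(axis=0).sum() == 0:  # degenerate constant matrix
        return (pd.DataFrame(np.zeros((matrix.n_samples, k)),
                             index=matrix.samples, columns=cols), np.zeros(k))
    pca = PCA(n_components=k)
    coords = pca.fit_transform(x)
    return (pd.DataFrame(coords, index=matrix.samples, columns=cols),
            np.asarray(pca.explained_variance_ratio_))
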