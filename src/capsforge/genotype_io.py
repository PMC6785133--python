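"""Readers, writers, and the in-memory genotype data model.

All coordinates are 1-based inclusive internally (VCF/GFF convention).
The canonical container is :class:`GenotypeMatrix`, a samples x variants grid
of diploid calls backed by numpy arrays, with per-call read depth and a
zygosity class attached to every call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("capsforge")

MISSING = "."
NUCLEOTIDES = frozenset("ACGT")

#: IUPAC ambiguity codes for the six heterozygous nucleotide pairs.
IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

#: Full IUPAC alphabet -> set of matching nucleotides (used by the motif scanner).
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


class Zygosity(IntEnum):
    HOM = 0
    HET = 1
    AMBIGUOUS = 2
    MISSING = 3


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class DuplicateKeyError(FormatError):
    """Two records share a (chromosome, position) key."""


# ---------------------------------------------------------------------------
# Scalar call
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCall:
    """One diploid call: two alleles (either may be missing), read depth and
    a zygosity class.

    A *half-missing* call ("G/-" in the tabular dialect) keeps its observed
    allele; its zygosity is AMBIGUOUS and downstream operations decide its
    treatment explicitly.
    """

    allele_a: str = MISSING
    allele_b: str = MISSING
    depth: int = 0
    zygosity: Zygosity | None = None

    def __post_init__(self):
        for a in (self.allele_a, self.allele_b):
            if a != MISSING and a not in NUCLEOTIDES:
                raise ValueError(f"invalid allele {a!r}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.zygosity is None:
            object.__setattr__(self, "zygosity", self._default_zygosity())
        if (self.zygosity == Zygosity.MISSING) != self.is_missing:
            raise ValueError("zygosity MISSING iff both alleles missing")

    def _default_zygosity(self) -> Zygosity:
        if self.is_missing:
            return Zygosity.MISSING
        if self.is_half_missing:
            return Zygosity.AMBIGUOUS
        return Zygosity.HOM if self.allele_a == self.allele_b else Zygosity.HET

    @property
    def is_missing(self) -> bool:
        return self.allele_a == MISSING and self.allele_b == MISSING

    @property
    def is_half_missing(self) -> bool:
        return (self.allele_a == MISSING) != (self.allele_b == MISSING)

    @property
    def observed_alleles(self) -> tuple[str, ...]:
        return tuple(a for a in (self.allele_a, self.allele_b) if a != MISSING)

    def __str__(self) -> str:
        a, b = sorted(self.observed_alleles) + [MISSING] * (2 - len(self.observed_alleles))
        if self.zygosity == Zygosity.HET:
            for code, pair in IUPAC_HET.items():
                if pair == (a, b):
                    return f"{code}/{code}"
        return f"{'-' if a == MISSING else a}/{'-' if b == MISSING else b}"


def parse_genotype_cell(cell: str) -> GenotypeCall:
    """Parse one cell of the tabular genotype dialect.

    Supported forms: "A/A" (homozygote), "R/R" (IUPAC heterozygote, here A/G),
    "Y/C" (heterozygote written with one expanded allele), "G/-" (half
    missing), "-/-" (missing).
    """
    parts = cell.strip().upper().split("/")
    if len(parts) != 2:
        raise FormatError(f"genotype cell {cell!r} is not of the form x/y")
    left, right = parts
    for sym in (left, right):
        if sym not in NUCLEOTIDES and sym not in IUPAC_HET and sym != "-":
            raise FormatError(f"unrecognized genotype symbol {sym!r} in {cell!r}")
    if left in IUPAC_HET or right in IUPAC_HET:
        code = left if left in IUPAC_HET else right
        pair = IUPAC_HET[code]
        other = right if code == left else left
        if other not in ("-",) + pair and other != code:
            raise FormatError(f"cell {cell!r}: {other!r} inconsistent with {code!r}")
        return GenotypeCall(pair[0], pair[1])
    a = MISSING if left == "-" else left
    b = MISSING if right == "-" else right
    return GenotypeCall(a, b)


def _expand_symbol(sym: str) -> GenotypeCall:
    """One-symbol genotype shorthand: nucleotide = homozygote, IUPAC two-fold
    code = heterozygote, '-' = no call."""
    sym = sym.strip().upper()
    if sym == "-":
        return GenotypeCall()
    if sym in IUPAC_HET:
        return GenotypeCall(*IUPAC_HET[sym])
    if sym in NUCLEOTIDES:
        return GenotypeCall(sym, sym)
    raise FormatError(f"unrecognized genotype symbol {sym!r}")


# ---------------------------------------------------------------------------
# Matrix
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


class GenotypeMatrix:
    """Samples x variants grid of diploid calls.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    variants
        DataFrame with at least columns chrom, pos (1-based), ref, alt; an
        optional ``mq`` column carries site-level mapping quality.
    allele_a, allele_b
        (n_samples, n_variants) arrays of single characters; "." is missing.
    depth
        (n_samples, n_variants) integer read depths.
    zygosity
        (n_samples, n_variants) int8 array of :class:`Zygosity` codes; derived
        from the alleles when omitted.
    """

    def __init__(self, samples, variants, allele_a, allele_b, depth=None, zygosity=None):
        self.samples = list(samples)
        self.variants = variants.reset_index(drop=True)
        self.allele_a = np.asarray(allele_a, dtype="<U1")
        self.allele_b = np.asarray(allele_b, dtype="<U1")
        n_s, n_v = len(self.samples), len(self.variants)
        if self.allele_a.shape != (n_s, n_v) or self.allele_b.shape != (n_s, n_v):
            raise ValueError("allele grid dimensions do not match samples x variants")
        self.depth = (np.zeros((n_s, n_v), dtype=np.int32) if depth is None
                      else np.asarray(depth, dtype=np.int32))
        if self.depth.shape != (n_s, n_v):
            raise ValueError("depth grid dimensions do not match samples x variants")
        if (self.depth < 0).any():
            raise ValueError("negative read depth")
        if zygosity is None:
            zygosity = self._derive_zygosity(self.allele_a, self.allele_b)
        self.zygosity = np.asarray(zygosity, dtype=np.int8)
        if self.zygosity.shape != (n_s, n_v):
            raise ValueError("zygosity grid dimensions do not match samples x variants")
        self._validate()

    @staticmethod
    def _derive_zygosity(aa, ab):
        miss_a, miss_b = aa == MISSING, ab == MISSING
        z = np.where(aa == ab, Zygosity.HOM, Zygosity.HET).astype(np.int8)
        z[miss_a ^ miss_b] = Zygosity.AMBIGUOUS
        z[miss_a & miss_b] = Zygosity.MISSING
        return z

    def _validate(self):
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        keys = list(zip(self.variants["chrom"], self.variants["pos"]))
        if len(set(keys)) != len(keys):
            dups = pd.Series(keys)[pd.Series(keys).duplicated()].unique()
            raise DuplicateKeyError(f"duplicate variant keys: {list(dups)[:5]}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        both_missing = (self.allele_a == MISSING) & (self.allele_b == MISSING)
        if ((self.zygosity == Zygosity.MISSING) != both_missing).any():
            raise ValueError("zygosity MISSING must coincide with both alleles missing")

    # -- accessors ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def get_call(self, sample_index: int, variant_index: int) -> GenotypeCall:
        return GenotypeCall(
            self.allele_a[sample_index, variant_index],
            self.allele_b[sample_index, variant_index],
            int(self.depth[sample_index, variant_index]),
            Zygosity(int(self.zygosity[sample_index, variant_index])),
        )

    def column_calls(self, variant_index: int) -> list[GenotypeCall]:
        return [self.get_call(i, variant_index) for i in range(self.n_samples)]

    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(
            self.samples, self.variants.iloc[idx],
            self.allele_a[:, idx], self.allele_b[:, idx],
            self.depth[:, idx], self.zygosity[:, idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.variants,
            self.allele_a[idx], self.allele_b[idx],
            self.depth[idx], self.zygosity[idx],
        )

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage matrix (n_samples, n_variants): 0/1/2, NaN for
        calls without two observed alleles (missing, half-missing) and for
        ambiguous-zygosity calls."""
        alt = self.variants["alt"].to_numpy()[None, :]
        d = (self.allele_a == alt).astype(float) + (self.allele_b == alt).astype(float)
        bad = np.isin(self.zygosity, (Zygosity.AMBIGUOUS, Zygosity.MISSING))
        d[bad] = np.nan
        return d

    def __repr__(self):
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"


# ---------------------------------------------------------------------------
# Sample panel / gene models / enzymes
# ---------------------------------------------------------------------------

@dataclass
class SamplePanel:
    """Sample identifiers with phenotype group labels and a target-group flag."""

    table: pd.DataFrame  # columns: sample_id, group_label, is_target_group

    def __post_init__(self):
        req = {"sample_id", "group_label", "is_target_group"}
        if not req <= set(self.table.columns):
            raise ValueError(f"panel table needs columns {sorted(req)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample in panel")
        flags = self.table["is_target_group"].astype(bool)
        if flags.all() or not flags.any():
            raise ValueError("panel must contain both target and non-target samples")

    @property
    def target_samples(self) -> list[str]:
        t = self.table
        return list(t.loc[t["is_target_group"].astype(bool), "sample_id"])

    @property
    def other_samples(self) -> list[str]:
        t = self.table
        return list(t.loc[~t["is_target_group"].astype(bool), "sample_id"])

    def validate_against(self, matrix: GenotypeMatrix):
        missing = set(matrix.samples) - set(self.table["sample_id"])
        if missing:
            raise ValueError(f"panel lacks matrix samples: {sorted(missing)}")


@dataclass(frozen=True)
class GeneModel:
    accession: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.accession}: start > end")
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.accession}: exon ({s},{e}) outside gene bounds")


class GeneModelSet:
    """Gene models grouped by chromosome, sorted by start coordinate."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end))
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)

    def __len__(self):
        return len(self.genes)

    def on(self, chrom: str) -> list[GeneModel]:
        return self.by_chrom.get(normalize_chrom(chrom), [])


@dataclass(frozen=True)
class EnzymeDefinition:
    """A restriction enzyme: IUPAC recognition plus top/bottom-strand cut
    offsets in top-strand coordinates from the recognition start.  Offsets may
    lie outside the recognition span (Type IIS enzymes such as BsrI, BbsI)."""

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self):
        bad = set(self.recognition.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC letters {sorted(bad)}")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition


def normalize_chrom(name: str) -> str:
    """Accept "Chr1" and "1" alike; "Chr00"/"0" is the unanchored
    pseudo-chromosome.  Canonical form: "Chr00", "Chr1".. "Chr11"."""
    s = str(name).strip()
    core = s[3:] if s.lower().startswith("chr") else s
    if core.isdigit():
        return "Chr00" if int(core) == 0 else f"Chr{int(core)}"
    return s


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotype_vcf(path, sample_subset: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read a VCF 4.x into a GenotypeMatrix.

    Biallelic SNV records become matrix columns; symbolic, multi-allelic or
    multi-base records are skipped and counted in the log.  Per-call depth is
    taken from FORMAT/DP, zygosity from FORMAT/AD read fractions when present
    (else from GT), site mapping quality from INFO/MQ.
    """
    import pysam

    from .variant_processing import FilterConfig, classify_zygosity

    cfg = FilterConfig()
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise FormatError(f"{path}: VCF lacks a GT FORMAT field")
    samples = list(vf.header.samples)
    if sample_subset is not None:
        missing = set(sample_subset) - set(samples)
        if missing:
            raise ValueError(f"samples not in VCF: {sorted(missing)}")
        samples = list(sample_subset)

    rows, aa_cols, ab_cols, dp_cols, zy_cols = [], [], [], [], []
    skipped = 0
    seen = set()
    for rec in vf:
        alts = rec.alts or ()
        if (len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1
                or rec.ref.upper() not in NUCLEOTIDES or alts[0].upper() not in NUCLEOTIDES):
            skipped += 1
            continue
        chrom = normalize_chrom(rec.chrom)
        key = (chrom, rec.pos)
        if key in seen:
            raise DuplicateKeyError(f"duplicate VCF record at {chrom}:{rec.pos}")
        seen.add(key)
        ref, alt = rec.ref.upper(), alts[0].upper()
        mq = rec.info.get("MQ", None)
        rows.append((chrom, rec.pos, ref, alt, np.nan if mq is None else float(mq)))
        aa, ab, dp, zy = [], [], [], []
        alleles = (ref, alt)
        for s in samples:
            call = rec.samples[s]
            gt = call.get("GT", (None, None))
            pair = [MISSING if g is None else alleles[g] for g in (gt + (None, None))[:2]]
            depth = call.get("DP", None)
            depth = 0 if depth is None else int(depth)
            ad = call.get("AD", None)
            zy_tag = call.get("ZY", None)
            if pair[0] == MISSING and pair[1] == MISSING:
                z = Zygosity.MISSING
            elif MISSING in pair:
                z = Zygosity.AMBIGUOUS
            elif zy_tag is not None:
                z = Zygosity[str(zy_tag).upper()]
            elif ad is not None and ad[0] is not None and sum(x or 0 for x in ad[:2]) > 0:
                z = classify_zygosity(int(ad[0] or 0), int(ad[1] or 0), cfg)
            else:
                z = Zygosity.HOM if pair[0] == pair[1] else Zygosity.HET
            aa.append(pair[0]); ab.append(pair[1]); dp.append(depth); zy.append(int(z))
        aa_cols.append(aa); ab_cols.append(ab); dp_cols.append(dp); zy_cols.append(zy)
    vf.close()
    if skipped:
        logger.info("read_genotype_vcf: skipped %d non-biallelic/non-SNV records", skipped)

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["mq"])
    shape_t = lambda cols: np.asarray(cols).T if cols else np.empty((len(samples), 0))
    m = GenotypeMatrix(samples, variants, shape_t(aa_cols), shape_t(ab_cols),
                       shape_t(dp_cols).astype(np.int32),
                       shape_t(zy_cols).astype(np.int8))
    m.n_skipped_records = skipped
    return m


def write_genotype_vcf(matrix: GenotypeMatrix, path,
                       contig_lengths: Mapping[str, int] | None = None):
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 with GT/DP and
    half-missing calls emitted as half-called genotypes."""
    import pysam

    header = pysam.VariantHeader()
    chroms = list(dict.fromkeys(matrix.variants["chrom"]))
    maxpos = matrix.variants.groupby("chrom")["pos"].max() if len(matrix.variants) else {}
    for c in chroms:
        length = (contig_lengths or {}).get(c, int(maxpos[c]) + 1000)
        header.contigs.add(c, length=length)
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("ZY", 1, "String", "Zygosity class (hom/het/ambiguous/missing)")
    for s in matrix.samples:
        header.add_sample(s)

    order = matrix.variants.sort_values(["chrom", "pos"],
                                        key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s).index
    zy_names = {0: "hom", 1: "het", 2: "ambiguous", 3: "missing"}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            v = matrix.variants.iloc[j]
            rec = out.new_record(contig=v["chrom"], start=int(v["pos"]) - 1,
                                 alleles=(v["ref"], v["alt"]))
            if "mq" in matrix.variants.columns and pd.notna(v.get("mq", np.nan)):
                rec.info["MQ"] = float(v["mq"])
            idx = {v["ref"]: 0, v["alt"]: 1}
            for i, s in enumerate(matrix.samples):
                call = rec.samples[s]
                a, b = matrix.allele_a[i, j], matrix.allele_b[i, j]
                call["GT"] = tuple(None if x == MISSING else idx[x] for x in (a, b))
                call["DP"] = int(matrix.depth[i, j])
                call["ZY"] = zy_names[int(matrix.zygosity[i, j])]
            out.write(rec)


def _chrom_sort_key(name: str):
    core = name[3:] if str(name).lower().startswith("chr") else name
    return (0, int(core)) if str(core).isdigit() else (1, str(name))


# ---------------------------------------------------------------------------
# Tabular genotype dialect
# ---------------------------------------------------------------------------

def read_genotype_table(path) -> GenotypeMatrix:
    """Read the TSV genotype-matrix dialect: columns marker?, chrom, pos, ref,
    alt?, then one column per sample holding cells like "A/A", "R/R", "Y/C",
    "G/-", "-/-".  Parse errors carry row/column coordinates."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    meta_cols = [c for c in ("marker", "chrom", "pos", "ref", "alt") if c in df.columns]
    if "chrom" not in meta_cols or "pos" not in meta_cols:
        raise FormatError(f"{path}: genotype table needs chrom and pos columns")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    aa = np.full((len(sample_cols), len(df)), MISSING, dtype="<U1")
    ab = aa.copy()
    for j, (_, row) in enumerate(df.iterrows()):
        for i, s in enumerate(sample_cols):
            try:
                call = parse_genotype_cell(str(row[s]))
            except FormatError as exc:
                raise FormatError(f"{path} row {j + 1} column {s!r}: {exc}") from exc
            aa[i, j], ab[i, j] = call.allele_a, call.allele_b

    variants = pd.DataFrame({
        "chrom": df["chrom"].map(normalize_chrom),
        "pos": df["pos"].astype(int),
        "ref": df["ref"] if "ref" in df else MISSING,
        "alt": df["alt"] if "alt" in df else MISSING,
    })
    if "alt" not in df:
        # infer alt as the most common non-reference allele per column
        for j in range(len(variants)):
            ref = variants.at[j, "ref"]
            obs = [x for x in np.concatenate([aa[:, j], ab[:, j]]) if x != MISSING and x != ref]
            variants.at[j, "alt"] = max(set(obs), key=obs.count) if obs else MISSING
    if "marker" in df:
        variants["marker"] = df["marker"].to_numpy()
    return GenotypeMatrix(sample_cols, variants, aa, ab)


def read_validation_table(path=None) -> tuple[GenotypeMatrix, GenotypeMatrix, pd.DataFrame]:
    """Read a paired validation matrix whose cells are "seq/caps" call pairs
    written with one-symbol genotypes (nucleotide = hom, IUPAC code = het,
    '-' = no call).  Returns (sequencing matrix, assay matrix, marker table).

    With no path, loads the packaged WMHL red-flesh validation panel.
    """
    if path is None:
        path = resources.files("capsforge").joinpath("data/wmhl_validation.tsv")
    with resources.as_file(path) if not isinstance(path, (str, Path)) else _nullctx(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    df = df.rename(columns={"position": "pos"})
    meta = [c for c in ("marker", "chrom", "pos", "ref", "match_rate") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta]
    shape = (len(sample_cols), len(df))
    grids = {side: (np.full(shape, MISSING, dtype="<U1"), np.full(shape, MISSING, dtype="<U1"))
             for side in ("seq", "caps")}
    for j, (_, row) in enumerate(df.iterrows()):
        for i, s in enumerate(sample_cols):
            cell = str(row[s]).strip()
            parts = cell.split("/")
            if len(parts) != 2:
                raise FormatError(f"{path} row {j + 1} column {s!r}: cell {cell!r}")
            for side, sym in zip(("seq", "caps"), parts):
                call = _expand_symbol(sym)
                grids[side][0][i, j] = call.allele_a
                grids[side][1][i, j] = call.allele_b
    variants = pd.DataFrame({
        "chrom": df["chrom"].map(normalize_chrom),
        "pos": df["pos"].astype(int),
        "ref": df["ref"],
        "alt": MISSING,
        "marker": df["marker"],
    })
    seq = GenotypeMatrix(sample_cols, variants, *grids["seq"])
    caps = GenotypeMatrix(sample_cols, variants, *grids["caps"])
    marker_table = df[meta].copy()
    if "match_rate" in marker_table:
        marker_table["match_rate"] = marker_table["match_rate"].astype(float)
    return seq, caps, marker_table


from contextlib import contextmanager


@contextmanager
def _nullctx(x):
    yield x


# ---------------------------------------------------------------------------
# Panel / GFF / FASTA / enzymes / reports
# ---------------------------------------------------------------------------

def read_sample_panel(path) -> SamplePanel:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    df["is_target_group"] = df["is_target_group"].astype(bool)
    return SamplePanel(df)


def write_sample_panel(panel: SamplePanel, path):
    panel.table.to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> GeneModelSet:
    """Parse gene models from GFF3 (via gffutils).  Malformed lines are
    skipped with a warning; a gene without exon children gets one exon
    spanning the gene."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(sorted((e.start, e.end) for e in db.children(g, featuretype="exon")))
        acc = g.attributes.get("ID", [g.id])[0]
        genes.append(GeneModel(acc, normalize_chrom(g.seqid), g.start, g.end,
                               g.strand or ".", exons or ((g.start, g.end),)))
    return GeneModelSet(genes)


def read_reference(path) -> dict[str, str]:
    """Load a FASTA into {chromosome: sequence} with normalized names."""
    from Bio import SeqIO

    return {normalize_chrom(rec.id): str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_reference(reference: Mapping[str, str], path, width: int = 70):
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def validate_reference_gff(reference: Mapping[str, str], genes: GeneModelSet):
    unknown = {g.chrom for g in genes.genes} - set(reference)
    if unknown:
        raise ValueError(f"gene models on chromosomes absent from FASTA: {sorted(unknown)}")


def read_enzyme_table(path=None) -> list[EnzymeDefinition]:
    """Read a TSV enzyme panel (name, recognition, cut_top, cut_bottom).
    With no path, loads the packaged 22-enzyme REBASE panel."""
    if path is None:
        path = resources.files("capsforge").joinpath("data/enzymes.tsv")
    with resources.as_file(path) if not isinstance(path, (str, Path)) else _nullctx(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return [EnzymeDefinition(r["name"], str(r["recognition"]).upper(),
                             int(r["cut_top"]), int(r["cut_bottom"]))
            for _, r in df.iterrows()]


def read_marker_panel(path=None) -> pd.DataFrame:
    """Read a CAPS marker panel report (packaged WMHL panel when no path)."""
    if path is None:
        path = resources.files("capsforge").joinpath("data/wmhl_markers.tsv")
    with resources.as_file(path) if not isinstance(path, (str, Path)) else _nullctx(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def write_report(df: pd.DataFrame, path):
    """TSV report writer with a fixed column order as given."""
    df.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
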