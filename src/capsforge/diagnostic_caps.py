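"""Trait-diagnostic SNP screening and CAPS assay design.

The screen keeps a variant when one phenotype group is fixed (monomorphic,
homozygous) for one allele, the complement group is fixed for a different
allele, and the two alleles differ — the classic within-group-monomorphic /
between-group-polymorphic criterion for a trait-diagnostic marker.

A passing SNP becomes a CAPS (cleaved amplified polymorphic sequence) assay
when, inside a PCR amplicon spanning it, some restriction enzyme's cut-site
set differs between the two alleles; the predicted gel pattern is the list of
digestion fragment lengths per allele.  Cut sites are found by explicit IUPAC
motif scanning of both strands, honoring cut offsets outside the recognition
span (Type IIS enzymes).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import (
    IUPAC_CODES,
    MISSING,
    EnzymeDefinition,
    GenotypeCall,
    GenotypeMatrix,
    SamplePanel,
    Zygosity,
    logger,
    reverse_complement,
)


@dataclass
class ScreenConfig:
    """Rules of the diagnostic screen.

    allow_missing
        Missing calls never disqualify a variant (default True); a group left
        empty after exclusions skips the variant with a log entry.
    allow_het
        When False (default), any heterozygous call inside a group counts as
        a deviation.
    max_discordant_per_group
        Deviating samples tolerated per group (default 0: strictly
        monomorphic).
    """

    allow_missing: bool = True
    allow_het: bool = False
    max_discordant_per_group: int = 0

    def __post_init__(self):
        if self.max_discordant_per_group < 0:
            raise ValueError("max_discordant_per_group must be >= 0")


@dataclass(frozen=True)
class DiagnosticSNP:
    """A SNP fixed for ``target_allele`` in the target group and for
    ``other_allele`` in the complement group."""

    chrom: str
    pos: int
    target_allele: str
    other_allele: str
    n_target_concordant: int = 0
    n_other_concordant: int = 0
    n_target_discordant: int = 0
    n_other_discordant: int = 0

    def __post_init__(self):
        if self.target_allele == self.other_allele:
            raise ValueError("diagnostic alleles must differ")


@dataclass(frozen=True)
class AmpliconPair:
    """The two allele versions of one amplicon, with the SNP offset inside it
    (0-based) and the amplicon's genomic start (1-based)."""

    chrom: str
    snp_pos: int
    start: int
    snp_offset: int
    sequences: dict  # allele -> sequence

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


@dataclass(frozen=True)
class CapsCandidate:
    """A diagnostic SNP convertible to a CAPS assay by one enzyme."""

    snp: DiagnosticSNP
    enzyme: str
    amplicon_length: int
    cut_positions: dict  # allele -> tuple of cut offsets within the amplicon
    fragments: dict      # allele -> tuple of fragment lengths

    def __post_init__(self):
        for allele, frags in self.fragments.items():
            if sum(frags) != self.amplicon_length:
                raise ValueError(
                    f"{self.enzyme}/{allele}: fragments {frags} do not sum to "
                    f"amplicon length {self.amplicon_length}")
        sets = [tuple(v) for v in self.cut_positions.values()]
        if len(set(sets)) < 2:
            raise ValueError("alleles share an identical cut map")


@dataclass(frozen=True)
class ValidationResult:
    marker: str
    compared: int
    concordant: int
    excluded_missing: int
    match_rate: float

    def __post_init__(self):
        if self.concordant > self.compared:
            raise ValueError("concordant exceeds compared")


# ---------------------------------------------------------------------------
# Screen
# ---------------------------------------------------------------------------

def _group_consensus(calls: list[GenotypeCall], cfg: ScreenConfig):
    """Fixed allele of a sample group, or None when the group deviates beyond
    cfg.max_discordant_per_group.  Returns (allele, n_concordant,
    n_discordant); allele is None for an empty or non-fixed group."""
    hom_alleles: list[str] = []
    half_alleles: list[str] = []
    n_het = 0
    for c in calls:
        if c.zygosity == Zygosity.MISSING:
            continue
        if c.is_half_missing:
            half_alleles.append(c.observed_alleles[0])
        elif c.zygosity == Zygosity.HET:
            n_het += 1
        elif c.zygosity == Zygosity.HOM:
            hom_alleles.append(c.allele_a)
        # full ambiguous calls are indistinguishable -> excluded
    if not hom_alleles and not half_alleles:
        return None, 0, 0
    pool = hom_alleles + half_alleles
    consensus = max(sorted(set(pool)), key=pool.count)
    discordant = sum(1 for a in pool if a != consensus)
    if not cfg.allow_het:
        discordant += n_het
    concordant = sum(1 for a in pool if a == consensus)
    if discordant > cfg.max_discordant_per_group:
        return None, concordant, discordant
    return consensus, concordant, discordant


def diagnostic_screen(matrix: GenotypeMatrix, panel: SamplePanel,
                      cfg: ScreenConfig | None = None) -> list[DiagnosticSNP]:
    """Scan every variant for the monomorphic-within / polymorphic-between
    pattern.  Variants with an empty group after missing-exclusion are skipped
    and counted in the log."""
    cfg = cfg or ScreenConfig()
    panel.validate_against(matrix)
    t_idx = [matrix.samples.index(s) for s in panel.target_samples
             if s in matrix.samples]
    o_idx = [matrix.samples.index(s) for s in panel.other_samples
             if s in matrix.samples]
    if not t_idx or not o_idx:
        raise ValueError("panel does not partition matrix samples into two groups")

    hits: list[DiagnosticSNP] = []
    n_empty = 0
    for j in range(matrix.n_variants):
        t_calls = [matrix.get_call(i, j) for i in t_idx]
        o_calls = [matrix.get_call(i, j) for i in o_idx]
        t_allele, t_con, t_dis = _group_consensus(t_calls, cfg)
        o_allele, o_con, o_dis = _group_consensus(o_calls, cfg)
        if (t_allele is None and t_con == 0 and t_dis == 0) or \
           (o_allele is None and o_con == 0 and o_dis == 0):
            n_empty += 1
            continue
        if t_allele is None or o_allele is None or t_allele == o_allele:
            continue
        v = matrix.variants.iloc[j]
        hits.append(DiagnosticSNP(v["chrom"], int(v["pos"]), t_allele, o_allele,
                                  t_con, o_con, t_dis, o_dis))
    if n_empty:
        logger.info("diagnostic_screen: %d variants skipped (empty group)", n_empty)
    return hits


# ---------------------------------------------------------------------------
# Amplicons
# ---------------------------------------------------------------------------

class AmbiguousAmpliconError(ValueError):
    """A primer is absent, or found more than once, in its search window."""


def extract_amplicon(reference: dict, chrom: str, snp_pos: int,
                     alleles: tuple[str, str],
                     flank_bp: int | None = None,
                     primer_pair: tuple[str, str] | None = None,
                     search_radius: int = 2000) -> AmpliconPair:
    """Cut the amplicon around a SNP and return both allele sequences.

    Either ``flank_bp`` (amplicon = SNP +/- flank) or ``primer_pair``
    (forward primer on the plus strand upstream of the SNP; reverse primer
    whose reverse complement lies downstream), each required to match exactly
    once within ``search_radius`` of the SNP.  Amplicons outside a 50–2000 bp
    guard range raise a size warning.
    """
    from .genotype_io import normalize_chrom

    chrom = normalize_chrom(chrom)
    if chrom not in reference:
        raise KeyError(f"chromosome {chrom} not in reference")
    seq = reference[chrom]
    if not (1 <= snp_pos <= len(seq)):
        raise ValueError(f"SNP position {snp_pos} outside {chrom}")

    if (flank_bp is None) == (primer_pair is None):
        raise ValueError("provide exactly one of flank_bp or primer_pair")

    if flank_bp is not None:
        start = max(1, snp_pos - flank_bp)
        end = min(len(seq), snp_pos + flank_bp)
    else:
        fwd, rev = (p.upper() for p in primer_pair)
        lo = max(0, snp_pos - 1 - search_radius)
        hi = min(len(seq), snp_pos + search_radius)
        window = seq[lo:hi]
        f_hits = [m.start() for m in re.finditer(re.escape(fwd), window)
                  if lo + m.start() < snp_pos]
        rev_rc = reverse_complement(rev)
        r_hits = [m.start() for m in re.finditer(re.escape(rev_rc), window)
                  if lo + m.start() + len(rev_rc) >= snp_pos]
        for name, hits in (("forward", f_hits), ("reverse", r_hits)):
            if not hits:
                raise AmbiguousAmpliconError(f"{name} primer not found near {chrom}:{snp_pos}")
            if len(hits) > 1:
                raise AmbiguousAmpliconError(f"{name} primer found {len(hits)} times")
        start = lo + f_hits[0] + 1
        end = lo + r_hits[0] + len(rev_rc)

    length = end - start + 1
    if not (50 <= length <= 2000):
        warnings.warn(f"amplicon length {length} bp outside the 50-2000 bp guard range")
    template = seq[start - 1:end]
    offset = snp_pos - start
    sequences = {a: template[:offset] + a + template[offset + 1:] for a in alleles}
    return AmpliconPair(chrom, snp_pos, start, offset, sequences)


# ---------------------------------------------------------------------------
# Restriction-site scanning & digestion
# ---------------------------------------------------------------------------

def _iupac_regex(motif: str) -> re.Pattern:
    # lookahead makes overlapping occurrences visible
    body = "".join(f"[{IUPAC_CODES[c]}]" if len(IUPAC_CODES[c]) > 1 else IUPAC_CODES[c]
                   for c in motif.upper())
    return re.compile(f"(?=({body}))")


def find_cut_sites(sequence: str, enzyme: EnzymeDefinition) -> list[int]:
    """Top-strand cut positions of ``enzyme`` in ``sequence``.

    Both strands are scanned for the (possibly degenerate) recognition motif.
    A cut position c means the enzyme cleaves the top strand between bases c
    and c+1 (0-based; 0 < c < len).  For a plus-strand site starting at s the
    cut is s + cut_offset_top; for a minus-strand site the geometry mirrors to
    s - (cut_offset_bottom - len(motif)).  Cuts falling outside the sequence
    are discarded; palindromic sites deduplicate naturally.
    """
    seq = sequence.upper()
    k = len(enzyme.recognition)
    cuts: set[int] = set()
    for m in _iupac_regex(enzyme.recognition).finditer(seq):
        cuts.add(m.start() + enzyme.cut_offset_top)
    # minus-strand recognition: the break mirrors to s + k - cut_offset_bottom
    # (for a palindromic motif this lands on the plus-strand position again)
    for m in _iupac_regex(reverse_complement(enzyme.recognition)).finditer(seq):
        cuts.add(m.start() + k - enzyme.cut_offset_bottom)
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest_fragments(sequence_length: int, cut_positions) -> list[int]:
    """Fragment lengths from cut positions strictly inside (0, length)."""
    cuts = sorted(set(int(c) for c in cut_positions))
    if cuts and (cuts[0] <= 0 or cuts[-1] >= sequence_length):
        raise ValueError(f"cut positions {cuts} outside (0, {sequence_length})")
    bounds = [0] + cuts + [sequence_length]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def snp_to_caps(diagnostic: DiagnosticSNP, amplicon: AmpliconPair,
                enzyme_panel: list[EnzymeDefinition]) -> list[CapsCandidate]:
    """Convert a diagnostic SNP into CAPS candidates.

    For every enzyme the cut sites are computed on both allele amplicons; a
    candidate is emitted iff the two cut-position sets differ (two different
    single-cut positions already give distinguishable fragments).
    """
    out: list[CapsCandidate] = []
    for enz in enzyme_panel:
        cut_maps = {allele: tuple(find_cut_sites(seq, enz))
                    for allele, seq in amplicon.sequences.items()}
        if len(set(cut_maps.values())) < 2:
            continue
        frags = {allele: tuple(digest_fragments(amplicon.length, cuts))
                 for allele, cuts in cut_maps.items()}
        out.append(CapsCandidate(diagnostic, enz.name, amplicon.length, cut_maps, frags))
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _calls_consistent(a: GenotypeCall, b: GenotypeCall) -> bool:
    """True when the observed alleles of the two calls do not contradict:
    full calls must share the same allele multiset; a half-missing call is
    consistent iff its single observed allele appears in the other call."""
    oa, ob = a.observed_alleles, b.observed_alleles
    if not oa or not ob:
        return True  # nothing observed on one side: no contradiction
    if len(oa) == 2 and len(ob) == 2:
        return sorted(oa) == sorted(ob)
    if len(oa) == 1:
        return oa[0] in ob
    return ob[0] in oa


def compute_match_rate(calls_a, calls_b, marker: str = "") -> ValidationResult:
    """Concordance between two equal-length call vectors over the same samples
    (e.g. sequencing calls vs CAPS assay calls).

    A sample pair is excluded only when both calls are fully missing; a pair
    where one assay gave no call cannot show a mismatch and counts toward
    agreement, matching the published convention for CAPS validation panels.
    Half-missing calls are concordant iff their observed allele is consistent
    with the partner call.  The rate is concordant / compared, rounded to two
    decimals.
    """
    calls_a, calls_b = list(calls_a), list(calls_b)
    if len(calls_a) != len(calls_b):
        raise ValueError("call vectors differ in length")
    compared = concordant = excluded = 0
    for a, b in zip(calls_a, calls_b):
        if a.is_missing and b.is_missing:
            excluded += 1
            continue
        compared += 1
        if _calls_consistent(a, b):
            concordant += 1
    if compared == 0:
        raise ValueError(f"match rate undefined for {marker or 'marker'}: "
                         "no comparable call pairs")
    return ValidationResult(marker, compared, concordant, excluded,
                            round(concordant / compared, 2))


def validate_matrix_pair(seq_matrix: GenotypeMatrix, caps_matrix: GenotypeMatrix,
                         marker_names=None) -> pd.DataFrame:
    """Per-variant match rates between two matrices over identical samples."""
    if seq_matrix.samples != caps_matrix.samples:
        raise ValueError("matrices carry different sample sets")
    if seq_matrix.n_variants != caps_matrix.n_variants:
        raise ValueError("matrices carry different variant sets")
    if marker_names is None:
        if "marker" in seq_matrix.variants.columns:
            marker_names = list(seq_matrix.variants["marker"])
        else:
            marker_names = [f"{c}:{p}" for c, p in
                            zip(seq_matrix.variants["chrom"], seq_matrix.variants["pos"])]
    rows = []
    for j, name in enumerate(marker_names):
        r = compute_match_rate(seq_matrix.column_calls(j),
                               caps_matrix.column_calls(j), name)
        rows.append((name, r.compared, r.concordant, r.excluded_missing, r.match_rate))
    return pd.DataFrame(rows, columns=["marker", "compared", "concordant",
                                       "excluded_missing", "match_rate"])
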