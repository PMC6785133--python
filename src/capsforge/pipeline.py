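"""End-to-end orchestration: filter -> annotate -> select -> structure ->
screen -> CAPS conversion -> (optional) validation, with TSV reports.

Reports use fixed, documented column orders so runs are diffable:

* ``filter_log.tsv``            — removal counts per filter criterion
* ``selected_markers.tsv``      — the evenly spaced marker subset
* ``selection_summary.tsv``     — per-chromosome counts, genic/intergenic split
* ``window_density.tsv``        — SNP/InDel counts per 100-kb window
* ``diagnostic_caps.tsv``       — diagnostic SNPs with their CAPS conversions
* ``match_rates.tsv``           — concordance vs a second call set, if given
* ``ibs_distance.tsv`` / ``nj_tree.nwk`` / ``pca_coordinates.tsv``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genotype_io as gio
from .diagnostic_caps import (
    ScreenConfig,
    diagnostic_screen,
    extract_amplicon,
    snp_to_caps,
    validate_matrix_pair,
)
from .diversity_selection import (
    SelectionConfig,
    build_nj_tree,
    count_window_density,
    ibs_distance,
    pca_genotypes,
    select_marker_subset,
    summarize_selection,
    tree_to_newick,
)
from .genotype_io import logger
from .variant_processing import (
    FilterConfig,
    annotate_variants,
    filter_variants,
    summarize_tstv,
)


@dataclass
class PipelineConfig:
    vcf: str
    reference: str
    gff: str
    panel: str
    out_dir: str
    enzymes: str | None = None          # packaged 22-enzyme panel when None
    caps_calls: str | None = None       # second call set for validation
    flank_bp: int = 200
    window_bp: int = 100_000
    filter: FilterConfig = field(default_factory=FilterConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("filter", FilterConfig), ("selection", SelectionConfig),
                         ("screen", ScreenConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def validate_paths(self):
        for name in ("vcf", "reference", "gff", "panel"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")
        for name in ("enzymes", "caps_calls"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")


@dataclass
class PipelineResult:
    matrix: "gio.GenotypeMatrix"
    filter_log: pd.DataFrame
    annotations: pd.DataFrame
    selected: pd.DataFrame
    selection_summary: pd.DataFrame
    densities: pd.DataFrame
    diagnostics: list
    caps_report: pd.DataFrame
    tree_newick: str
    pca: pd.DataFrame
    match_rates: pd.DataFrame | None
    ts_fraction: float
    out_dir: Path


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage on the configured inputs and write the report bundle."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- load --------------------------------------------------------------
    matrix = gio.read_genotype_vcf(cfg.vcf)
    panel = gio.read_sample_panel(cfg.panel)
    panel.validate_against(matrix)
    reference = gio.read_reference(cfg.reference)
    genes = gio.read_gene_models(cfg.gff)
    gio.validate_reference_gff(reference, genes)
    enzymes = gio.read_enzyme_table(cfg.enzymes)
    logger.info("loaded %s, %d panel samples, %d genes, %d enzymes",
                matrix, len(panel.table), len(genes), len(enzymes))

    # -- filter + annotate -------------------------------------------------
    filtered, filter_log = filter_variants(matrix, cfg.filter)
    annotations = annotate_variants(filtered, genes, cfg.filter)
    ts_frac, _ = summarize_tstv(annotations)

    # -- selection + densities --------------------------------------------
    selected = select_marker_subset(annotations, cfg.selection)
    summary = summarize_selection(selected)
    lengths = {c: len(s) for c, s in reference.items()}
    densities = count_window_density(annotations, lengths, cfg.window_bp)

    # -- panel structure ---------------------------------------------------
    sel_mask = filtered.variants.set_index(["chrom", "pos"]).index.isin(
        selected.set_index(["chrom", "pos"]).index)
    subset_matrix = filtered.subset_variants(sel_mask) if sel_mask.any() else filtered
    dm = ibs_distance(subset_matrix)
    newick = tree_to_newick(build_nj_tree(dm)) if subset_matrix.n_samples >= 3 else ""
    pca_coords, pca_var = pca_genotypes(subset_matrix)

    # -- diagnostic screen + CAPS -----------------------------------------
    diagnostics = diagnostic_screen(filtered, panel, cfg.screen)
    caps_rows = []
    ann_idx = annotations.set_index(["chrom", "pos"])
    for k, d in enumerate(diagnostics, 1):
        amp = extract_amplicon(reference, d.chrom, d.pos,
                               (d.target_allele, d.other_allele),
                               flank_bp=cfg.flank_bp)
        candidates = snp_to_caps(d, amp, enzymes)
        a = ann_idx.loc[(d.chrom, d.pos)]
        base = {
            "marker": f"DM{k:04d}", "chrom": d.chrom, "pos": d.pos,
            "ref": a["ref"], "target_allele": d.target_allele,
            "other_allele": d.other_allele,
            "gene_accession": a["gene_accession"] or "",
            "location": getattr(a["location_class"], "value", a["location_class"]),
            "pic": round(float(a["pic"]), 4),
        }
        if not candidates:
            caps_rows.append({**base, "enzyme": "", "amplicon_bp": amp.length,
                              "product_size_target": "", "product_size_other": ""})
        for c in candidates:
            caps_rows.append({**base, "enzyme": c.enzyme, "amplicon_bp": c.amplicon_length,
                              "product_size_target": ",".join(map(str, c.fragments[d.target_allele])),
                              "product_size_other": ",".join(map(str, c.fragments[d.other_allele]))})
    caps_report = pd.DataFrame(caps_rows, columns=[
        "marker", "chrom", "pos", "ref", "target_allele", "other_allele",
        "gene_accession", "location", "pic", "enzyme", "amplicon_bp",
        "product_size_target", "product_size_other"])

    # -- optional validation ----------------------------------------------
    match_rates = None
    if cfg.caps_calls is not None:
        seq_m, caps_m, _ = gio.read_validation_table(cfg.caps_calls)
        match_rates = validate_matrix_pair(seq_m, caps_m)

    # -- reports -----------------------------------------------------------
    gio.write_report(filter_log, out / "filter_log.tsv")
    gio.write_report(selected.assign(
        substitution_class=selected["substitution_class"].map(lambda v: getattr(v, "value", v)),
        location_class=selected["location_class"].map(lambda v: getattr(v, "value", v))),
        out / "selected_markers.tsv")
    gio.write_report(summary, out / "selection_summary.tsv")
    gio.write_report(densities, out / "window_density.tsv")
    gio.write_report(caps_report, out / "diagnostic_caps.tsv")
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        out / "ibs_distance.tsv", sep="\t")
    (out / "nj_tree.nwk").write_text(newick)
    pca_out = pca_coords.copy()
    pca_out.index.name = "sample_id"
    pca_out.to_csv(out / "pca_coordinates.tsv", sep="\t")
    if match_rates is not None:
        gio.write_report(match_rates, out / "match_rates.tsv")

    logger.info("pipeline: %d filtered variants, %d selected, %d diagnostic, "
                "%d CAPS rows", filtered.n_variants, len(selected),
                len(diagnostics), len(caps_report))
    return PipelineResult(filtered, filter_log, annotations, selected, summary,
                          densities, diagnostics, caps_report, newick,
                          pca_coords, match_rates, ts_frac, out)
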