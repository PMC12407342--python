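"""End-to-end orchestration: simulate or load inputs, then run QC,
normalization, profiles, marker screening, subgenome dominance, motif
profiling and (when scores are provided) orthology, writing a deterministic
output bundle plus a machine-readable summary JSON."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as kio
from .comparative import reciprocal_best_hits
from .dominance import dominance_report, family_weights
from .expression import celltype_means, normalize_cp10k, qc_filter
from .markers import find_markers
from .motifs import MotifConsensus, call_environment_triggered, call_predominant, \
    count_elements, normalize_frequency, scan_promoters
from .sim import SimConfig, SimBundle, simulate_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything `run_full` needs: either input paths or a simulate block."""

    out_dir: str = "kranz_out"
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: dict = field(default_factory=dict)  # paths: matrix, genes, cells, ...
    min_umi: int = 500
    min_genes: int = 200
    fc_min: float = 1.5
    alpha: float = 0.05
    adjust_method: str = "bonferroni"
    pseudocount: float = 0.1
    tau_pred: float = 0.10
    tau_high: float = 0.10
    tau_low: float = 0.05
    count_mode: str = "element"
    strand_mode: str = "both"
    dominance_cell_a: str = "IMC"
    dominance_cell_b: str = "KC"
    dominance_condition: str = "terrestrial"
    env_condition_1: str = "terrestrial"
    env_condition_2: str = "submerged"
    marker_contrasts: list = field(default_factory=lambda: [
        (("IMC", "terrestrial"), ("IMC", "submerged")),
        (("IMC", "terrestrial"), ("KC", "terrestrial")),
    ])
    promoter_consensus: list = field(default_factory=lambda: [
        {"family": "bZIP", "patterns": ["TGACGTCA"]},
        {"family": "Homeobox", "patterns": ["TAATNATTA"]},
    ])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = SimConfig.from_dict(d["simulate"])
        if "marker_contrasts" in d:
            d["marker_contrasts"] = [
                (tuple(a), tuple(b)) for a, b in d["marker_contrasts"]
            ]
        cfg = cls(**d)
        if (cfg.simulate is None) == (not cfg.inputs):
            # exactly one source of inputs must be configured
            if cfg.simulate is None:
                raise ValueError("config needs either a 'simulate' block or 'inputs' paths")
            raise ValueError("config must not set both 'simulate' and 'inputs'")
        return cfg


def _load_inputs(cfg: PipelineConfig) -> SimBundle:
    if cfg.simulate is not None:
        return simulate_all(cfg.simulate, cfg.seed)
    paths = cfg.inputs
    counts = kio.read_count_matrix(paths["matrix"], paths["genes"], paths["cells"])
    cells = kio.read_cell_annotation(paths["cell_annotation"])
    genes = kio.read_gene_annotation(paths["gene_annotation"])
    homeologs = kio.read_homeolog_table(paths["homeologs"], genes)
    links = kio.read_peak_links(paths["peak_links"]) if "peak_links" in paths else None
    promoters = kio.read_fasta(paths["promoters"]) if "promoters" in paths else None
    scores = kio.read_ortholog_scores(paths["ortholog_scores"]) if "ortholog_scores" in paths else None
    return SimBundle(counts, cells, genes, homeologs, links, promoters, scores, None)


def run_full(config: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict (also written to
    ``summary.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_umi": config.min_umi, "min_genes": config.min_genes,
            "fc_min": config.fc_min, "alpha": config.alpha,
            "adjust_method": config.adjust_method,
            "tau_pred": config.tau_pred, "tau_high": config.tau_high,
            "tau_low": config.tau_low, "count_mode": config.count_mode,
            "strand_mode": config.strand_mode,
        },
        "outputs": {},
    }

    bundle = _load_inputs(config)

    # qc + normalize + profile
    counts_f, cells_f = qc_filter(bundle.counts, bundle.cells, config.min_umi, config.min_genes)
    norm = normalize_cp10k(counts_f)
    profile = celltype_means(norm, cells_f)
    kio.write_table(profile, out / "expression_profile.tsv",
                    sort_by=("gene_id", "cell_type", "condition"))
    summary["outputs"]["expression_profile"] = "expression_profile.tsv"
    summary["n_cells_after_qc"] = len(cells_f)
    summary["n_genes"] = len(counts_f.gene_ids)

    # markers
    marker_files = []
    for g1, g2 in config.marker_contrasts:
        res = find_markers(norm, cells_f, g1, g2, fc_min=config.fc_min,
                           alpha=config.alpha, pseudocount=config.pseudocount,
                           method=config.adjust_method)
        name = f"markers_{g1[0]}-{g1[1]}_vs_{g2[0]}-{g2[1]}.tsv"
        kio.write_table(res, out / name, sort_by=("gene_id",))
        marker_files.append({"contrast": [list(g1), list(g2)], "file": name, "n_markers": len(res)})
    summary["outputs"]["markers"] = marker_files

    # subgenome dominance
    weights = family_weights(profile, bundle.homeologs,
                             config.dominance_cell_a, config.dominance_cell_b,
                             config.dominance_condition)
    report = dominance_report(weights)
    kio.write_table(report, out / "dominance.tsv", sort_by=("set_id",))
    summary["outputs"]["dominance"] = "dominance.tsv"
    summary["dominance_calls"] = {
        r["set_id"]: {"weight_B_AB": round(r["weight_B_AB"], 6), "call": r["call"]}
        for _, r in report.iterrows()
    }

    # motif frequency profiles and calls
    if bundle.links is not None:
        gene_sets = (bundle.truth.link_gene_sets if bundle.truth is not None
                     else {"all": sorted(bundle.links["gene_id"].unique())})
        calls_env_all = []
        for gs, genes in sorted(gene_sets.items()):
            counts_m = count_elements(bundle.links, genes,
                                      group_by=("cell_type", "condition"),
                                      count_mode=config.count_mode)
            freq = normalize_frequency(counts_m)
            kio.write_matrix_tsv(freq.rates, out / f"motif_frequency_{gs}.tsv")
            pred = call_predominant(freq, config.tau_pred)
            kio.write_table(pred, out / f"motif_predominant_{gs}.tsv")
            # split by condition for environment-triggered calls
            c1, c2 = config.env_condition_1, config.env_condition_2
            cols1 = [c for c in freq.rates.columns if c[1] == c1]
            cols2 = [c for c in freq.rates.columns if c[1] == c2]
            shared_ct = sorted({c[0] for c in cols1} & {c[0] for c in cols2})
            if shared_ct:
                fams = sorted(bundle.links["motif_family"].unique())
                sel = bundle.links["cell_type"].isin(shared_ct)
                links1 = bundle.links[sel & (bundle.links["condition"] == c1)]
                links2 = bundle.links[sel & (bundle.links["condition"] == c2)]
                f1 = normalize_frequency(count_elements(
                    links1, genes, group_by=("cell_type",),
                    count_mode=config.count_mode, families=fams))
                f2 = normalize_frequency(count_elements(
                    links2, genes, group_by=("cell_type",),
                    count_mode=config.count_mode, families=fams))
                env = call_environment_triggered(f1, f2, config.tau_high, config.tau_low)
                env.insert(0, "gene_set", gs)
                calls_env_all.append(env)
            summary["outputs"][f"motif_frequency_{gs}"] = f"motif_frequency_{gs}.tsv"
        if calls_env_all:
            env_df = pd.concat(calls_env_all, ignore_index=True)
            kio.write_table(env_df, out / "motif_environment_triggered.tsv")
            summary["outputs"]["motif_environment_triggered"] = "motif_environment_triggered.tsv"
            summary["environment_triggered"] = [
                {"gene_set": r["gene_set"], "family": r["family"], "group": r["group"]}
                for _, r in env_df.iterrows()
            ]

    # promoter scan
    if bundle.promoters is not None:
        consensus = [MotifConsensus(c["family"], list(c["patterns"]))
                     for c in config.promoter_consensus]
        scan = scan_promoters(bundle.promoters, consensus, config.strand_mode)
        kio.write_matrix_tsv(scan, out / "promoter_scan.tsv")
        summary["outputs"]["promoter_scan"] = "promoter_scan.tsv"

    # orthology
    if bundle.ortholog_scores is not None:
        rbh = reciprocal_best_hits(bundle.ortholog_scores)
        kio.write_table(rbh, out / "orthologs_rbh.tsv", sort_by=("gene_sp1",))
        summary["outputs"]["orthologs_rbh"] = "orthologs_rbh.tsv"
        summary["n_rbh_pairs"] = len(rbh)

    kio.write_json(summary, out / "summary.json")
    return summary
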