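"""Synthetic data generator for every pipeline input, with recorded ground truth.

The generator emulates the shapes of a single-nucleus study of an
allotetraploid C3-C4 sedge: three growth conditions (terrestrial,
submerged, submerged + ABA), eight culm cell types including inner/outer
mesophyll (IMC/OMC) and Kranz cells (KC), sparse UMI counts averaging
~1232 per cell, A/B homeolog pairs for the C4 enzyme families (beta-CA,
PEPC, PPDK, NAD-ME, RuBisCO-SSU), accessible-element link tables with
per-group motif-family rate vectors, promoters with planted IUPAC motif
occurrences, and an all-vs-all ortholog similarity table.

Counts follow a gamma-Poisson (negative binomial) model with one shared
dispersion.  Subgenome dominance is planted at expectation level: the
extra expression a homeolog family gains in its enriched cell type is
split between the A and B copies so that the expected Weight_B/AB equals
the configured true weight.

All generators derive independent substreams from a single master seed via
fixed labels, so outputs are bit-identical for identical (config, seed)
and adding one generator never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io import CountMatrix
from .motifs import IUPAC

DEFAULT_CELL_TYPES = [
    "IMC", "OMC", "KC", "epidermis", "xylem", "phloem", "sclerenchyma", "guard_cell",
]
DEFAULT_CONDITIONS = ["terrestrial", "submerged", "submerged_ABA"]

MOTIF_FAMILIES = [
    "NAC", "C2H2", "bZIP", "Homeobox", "MYB-related",
    "G2-like", "C2C2dof", "bHLH", "MYB", "other",
]


class ConfigError(ValueError):
    """A SimConfig field is invalid; the message names the field."""


@dataclass
class FamilySpec:
    """One homeolog enzyme family: where it is enriched and how biased."""

    name: str
    n_pairs: int
    enriched_cell_type: str
    true_weight_B_AB: float
    enrichment_fold: float = 3.0
    enriched_condition: str = "terrestrial"


@dataclass
class DEEffectSpec:
    """A planted differential-expression gene set."""

    name: str
    n_genes: int
    condition: str
    fold: float
    cell_type: str | None = None  # None = effect in every cell type


@dataclass
class PlantedMotif:
    """IUPAC consensus planted in every promoter a fixed number of times."""

    family: str
    consensus: str
    n_occurrences: int


def _default_family_specs() -> list[FamilySpec]:
    # Weights follow the study system's reported family biases: the three
    # carboxylation-side families are B-dominant in IMC, the two
    # decarboxylation/RuBisCO families A-dominant in KC.
    return [
        FamilySpec("betaCA", 40, "IMC", 0.63),
        FamilySpec("PEPC", 40, "IMC", 0.56),
        FamilySpec("PPDK", 40, "IMC", 0.67),
        FamilySpec("NAD-ME", 40, "KC", 0.31),
        FamilySpec("RuBisCO-SSU", 40, "KC", 0.29),
    ]


def _default_motif_rates() -> dict:
    """Per (gene set, cell type, condition) family rate vectors.

    Patterned on the study system's contrasts (NAC/C2H2 dominant in IMC,
    bZIP in KC; Homeobox, MYB-related and G2-like present under terrestrial
    but depleted under submerged growth), with rates placed at least ~3
    multinomial standard deviations from the default call thresholds at
    1000 elements so the planted calls are identifiable.
    """
    imc_t = {"NAC": 0.242, "C2H2": 0.28, "bZIP": 0.02, "Homeobox": 0.216,
             "MYB-related": 0.18, "G2-like": 0.01, "C2C2dof": 0.01,
             "bHLH": 0.02, "MYB": 0.01, "other": 0.012}
    imc_s = {"NAC": 0.30, "C2H2": 0.34, "bZIP": 0.05, "Homeobox": 0.0,
             "MYB-related": 0.02, "G2-like": 0.01, "C2C2dof": 0.02,
             "bHLH": 0.05, "MYB": 0.03, "other": 0.18}
    kc_t = {"NAC": 0.099, "C2H2": 0.0, "bZIP": 0.348, "Homeobox": 0.02,
            "MYB-related": 0.03, "G2-like": 0.15, "C2C2dof": 0.05,
            "bHLH": 0.05, "MYB": 0.08, "other": 0.173}
    kc_s = {"NAC": 0.12, "C2H2": 0.0, "bZIP": 0.40, "Homeobox": 0.02,
            "MYB-related": 0.04, "G2-like": 0.0, "C2C2dof": 0.06,
            "bHLH": 0.06, "MYB": 0.09, "other": 0.21}
    return {
        "C4": {
            "IMC": {"terrestrial": imc_t, "submerged": imc_s},
            "KC": {"terrestrial": kc_t, "submerged": kc_s},
        },
    }


@dataclass
class SimConfig:
    """Full parameterization of the synthetic study."""

    n_genes: int = 500  # background genes, in addition to homeolog genes
    cell_types: list[str] = field(default_factory=lambda: list(DEFAULT_CELL_TYPES))
    conditions: list[str] = field(default_factory=lambda: list(DEFAULT_CONDITIONS))
    cells_per_group: int = 300
    n_replicates: int = 2
    mean_library_size: float = 1232.0
    library_size_sigma: float = 0.35  # lognormal sd of per-cell library size
    nb_dispersion: float = 0.5
    family_specs: list[FamilySpec] = field(default_factory=_default_family_specs)
    de_effects: list[DEEffectSpec] = field(default_factory=lambda: [
        DEEffectSpec("submergence_response", 50, "submerged", 3.0),
    ])
    motif_rate_vectors: dict = field(default_factory=_default_motif_rates)
    contrast_cell_types: tuple = ("IMC", "KC")  # contrast the planted weights target
    n_elements_per_group: int = 1000
    link_genes_per_set: int = 50
    planted_motifs: list[PlantedMotif] = field(default_factory=lambda: [
        PlantedMotif("bZIP", "TGACGTCA", 3),
        PlantedMotif("Homeobox", "TAATNATTA", 2),
    ])
    promoter_length: int = 1000
    n_promoters: int = 60
    n_species2_genes: int = 100
    n_true_orthologs: int = 80
    decoy_hits_per_gene: int = 3
    seed: int = 0

    @property
    def n_homeolog_pairs(self) -> int:
        return sum(f.n_pairs for f in self.family_specs)

    def validate(self) -> "SimConfig":
        for name in ("n_genes", "cells_per_group", "n_replicates",
                     "n_elements_per_group", "link_genes_per_set",
                     "promoter_length", "n_promoters", "n_species2_genes",
                     "n_true_orthologs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.mean_library_size <= 0:
            raise ConfigError(f"mean_library_size must be > 0, got {self.mean_library_size}")
        if self.nb_dispersion <= 0:
            raise ConfigError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        for f in self.family_specs:
            if not 0.0 <= f.true_weight_B_AB <= 1.0:
                raise ConfigError(
                    f"family_specs[{f.name}].true_weight_B_AB must be in [0, 1], "
                    f"got {f.true_weight_B_AB}"
                )
            if f.enrichment_fold <= 0:
                raise ConfigError(f"family_specs[{f.name}].enrichment_fold must be > 0")
            if f.enriched_cell_type not in self.cell_types:
                raise ConfigError(
                    f"family_specs[{f.name}].enriched_cell_type "
                    f"{f.enriched_cell_type!r} not in cell_types"
                )
            if f.n_pairs < 1:
                raise ConfigError(f"family_specs[{f.name}].n_pairs must be >= 1")
        for e in self.de_effects:
            if e.fold <= 0:
                raise ConfigError(f"de_effects[{e.name}].fold must be > 0")
            if e.condition not in self.conditions:
                raise ConfigError(f"de_effects[{e.name}].condition {e.condition!r} not in conditions")
        for gs, by_ct in self.motif_rate_vectors.items():
            for ct, by_cond in by_ct.items():
                for cond, rates in by_cond.items():
                    total = sum(rates.values())
                    if abs(total - 1.0) > 1e-9:
                        raise ConfigError(
                            f"motif_rate_vectors[{gs}][{ct}][{cond}] sums to "
                            f"{total}, expected 1"
                        )
                    if any(r < 0 for r in rates.values()):
                        raise ConfigError(
                            f"motif_rate_vectors[{gs}][{ct}][{cond}] has a negative rate"
                        )
        for m in self.planted_motifs:
            bad = set(m.consensus.upper()) - set(IUPAC)
            if bad:
                raise ConfigError(
                    f"planted_motifs[{m.family}].consensus: invalid IUPAC symbol(s) {sorted(bad)}"
                )
            if len(m.consensus) > self.promoter_length:
                raise ConfigError(
                    f"planted_motifs[{m.family}].consensus longer than promoter_length"
                )
            if m.n_occurrences < 0:
                raise ConfigError(f"planted_motifs[{m.family}].n_occurrences must be >= 0")
        if self.n_true_orthologs > self.n_species2_genes:
            raise ConfigError("n_true_orthologs cannot exceed n_species2_genes")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "family_specs" in d:
            d["family_specs"] = [FamilySpec(**f) for f in d["family_specs"]]
        if "de_effects" in d:
            d["de_effects"] = [DEEffectSpec(**e) for e in d["de_effects"]]
        if "planted_motifs" in d:
            d["planted_motifs"] = [PlantedMotif(**m) for m in d["planted_motifs"]]
        if "contrast_cell_types" in d:
            d["contrast_cell_types"] = tuple(d["contrast_cell_types"])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contrast_cell_types"] = list(d["contrast_cell_types"])
        return d


@dataclass
class SimTruth:
    """Ground truth for every planted signal, keyed by emitted ids."""

    family_weights: dict = field(default_factory=dict)       # family -> true w
    family_enrichment: dict = field(default_factory=dict)    # family -> (cell_type, condition, fold)
    homeolog_pairs: dict = field(default_factory=dict)       # family -> [(gene_A, gene_B)]
    de_genes: dict = field(default_factory=dict)             # set -> {genes, condition, cell_type, fold}
    motif_rates: dict = field(default_factory=dict)          # "set|ct|cond" -> {family: rate}
    link_gene_sets: dict = field(default_factory=dict)       # set -> [gene ids]
    promoter_occurrences: dict = field(default_factory=dict) # gene -> family -> {count, positions}
    ortholog_pairs: list = field(default_factory=list)       # [(gene_sp1, gene_sp2)]

    def to_dict(self) -> dict:
        return asdict(self)


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible substream for one generator."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimConfig, seed: int | None = None):
    """Generate counts, cell/gene annotation and the homeolog table.

    Returns ``(CountMatrix, cell_annotation, gene_annotation, homeolog_table,
    SimTruth)``.  See the module docstring for the generative model.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = derive_rng(seed, "expression")
    truth = SimTruth()

    # --- gene roster and baseline means ------------------------------------
    bg_genes = [f"bg{i:04d}" for i in range(config.n_genes)]
    gene_rows = [{"gene_id": g, "subgenome": "unassigned", "family": ""} for g in bg_genes]
    hom_rows = []
    for fam in config.family_specs:
        pairs = []
        for i in range(fam.n_pairs):
            ga, gb = f"{fam.name}_p{i:03d}_A", f"{fam.name}_p{i:03d}_B"
            gene_rows.append({"gene_id": ga, "subgenome": "A", "family": fam.name})
            gene_rows.append({"gene_id": gb, "subgenome": "B", "family": fam.name})
            hom_rows.append({"gene_A": ga, "gene_B": gb, "family": fam.name})
            pairs.append((ga, gb))
        truth.homeolog_pairs[fam.name] = pairs
        truth.family_weights[fam.name] = fam.true_weight_B_AB
        truth.family_enrichment[fam.name] = (
            fam.enriched_cell_type, fam.enriched_condition, fam.enrichment_fold
        )
    gene_ann = pd.DataFrame(gene_rows)
    homeologs = pd.DataFrame(hom_rows)
    gene_ids = list(gene_ann["gene_id"])
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    # homeolog copies share the pair baseline so the planted split is clean
    for fam in config.family_specs:
        for ga, gb in truth.homeolog_pairs[fam.name]:
            baseline[gene_index[gb]] = baseline[gene_index[ga]]

    # --- group-level expected expression -----------------------------------
    groups = [(ct, cond) for ct in config.cell_types for cond in config.conditions]
    group_index = {g: j for j, g in enumerate(groups)}
    M = np.tile(baseline[:, None], (1, len(groups)))

    for eff in config.de_effects:
        chosen = rng.choice(config.n_genes, size=min(eff.n_genes, config.n_genes), replace=False)
        genes = sorted(bg_genes[i] for i in chosen)
        truth.de_genes[eff.name] = {
            "genes": genes, "condition": eff.condition,
            "cell_type": eff.cell_type, "fold": eff.fold,
        }
        rows = [gene_index[g] for g in genes]
        for (ct, cond), j in group_index.items():
            if cond == eff.condition and (eff.cell_type is None or ct == eff.cell_type):
                M[rows, j] *= eff.fold

    # Expectation-level dominance planting.  Downstream, expression is
    # normalized per cell (cp10k), so a gene's expected profile value is its
    # mean divided by the group's column sum; enrichment mass in one group
    # dilutes everything else there.  The A/B split of each pair's extra
    # mass is therefore solved on the normalized scale so that the expected
    # Weight_B/AB for the configured contrast equals the true weight.
    delta_tot = {}  # (family, pair index) -> total extra mass in enriched group
    extra = np.zeros(len(groups))
    for fam in config.family_specs:
        j = group_index[(fam.enriched_cell_type, fam.enriched_condition)]
        for k, (ga, _) in enumerate(truth.homeolog_pairs[fam.name]):
            d = 2.0 * (fam.enrichment_fold - 1.0) * baseline[gene_index[ga]]
            delta_tot[(fam.name, k)] = d
            extra[j] += d
    colsum = M.sum(axis=0) + extra
    ct_a, ct_b = config.contrast_cell_types
    for fam in config.family_specs:
        w = fam.true_weight_B_AB
        j_star = group_index[(fam.enriched_cell_type, fam.enriched_condition)]
        other_ct = ct_b if fam.enriched_cell_type == ct_a else ct_a
        j_other = group_index.get((other_ct, fam.enriched_condition))
        for k, (ga, gb) in enumerate(truth.homeolog_pairs[fam.name]):
            b = baseline[gene_index[ga]]
            d = delta_tot[(fam.name, k)]
            if j_other is None or fam.enriched_cell_type not in (ct_a, ct_b):
                da, db = d * (1.0 - w), d * w  # naive split: no contrast configured
            else:
                s_star, s_o = colsum[j_star], colsum[j_other]
                c = b * (1.0 / s_star - 1.0 / s_o)
                q = d / s_star + 2.0 * c
                if q <= 0:
                    da, db = d * (1.0 - w), d * w  # dilution swamps the signal
                else:
                    da = s_star * ((1.0 - w) * q - c)
                    db = s_star * (w * q - c)
            M[gene_index[ga], j_star] += da
            M[gene_index[gb], j_star] += db

    # --- cells and counts ---------------------------------------------------
    cell_rows = []
    count_blocks = []
    mu_lib = np.log(config.mean_library_size) - config.library_size_sigma**2 / 2
    cell_counter = 0
    for (ct, cond), j in sorted(group_index.items(), key=lambda kv: kv[1]):
        n = config.cells_per_group
        lib = rng.lognormal(mean=mu_lib, sigma=config.library_size_sigma, size=n)
        p = M[:, j] / M[:, j].sum()
        mu = p[:, None] * lib[None, :]  # genes x cells expected counts
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape=shape, scale=mu * config.nb_dispersion)
        counts = rng.poisson(lam)
        count_blocks.append(sp.csr_matrix(counts))
        for k in range(n):
            cell_rows.append({
                "cell_id": f"c{cell_counter:05d}",
                "cell_type": ct,
                "condition": cond,
                "replicate": f"r{k % config.n_replicates + 1}",
            })
            cell_counter += 1
    cells = pd.DataFrame(cell_rows)
    matrix = sp.hstack(count_blocks, format="csr")
    cm = CountMatrix(gene_ids, list(cells["cell_id"]), matrix)
    return cm, cells, gene_ann, homeologs, truth


# ---------------------------------------------------------------------------
# peak-to-gene links
# ---------------------------------------------------------------------------

def simulate_peak_links(
    config: SimConfig,
    seed: int | None = None,
    gene_sets: dict[str, list[str]] | None = None,
):
    """Generate an accessible-element link table from the configured rate vectors.

    ``gene_sets`` maps each gene-set name in ``motif_rate_vectors`` to the
    gene ids its elements link to; synthetic ids are minted when omitted.
    Returns ``(PeakLinkTable DataFrame, SimTruth)``.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = derive_rng(seed, "peak_links")
    truth = SimTruth()
    rows = []
    for gs in sorted(config.motif_rate_vectors):
        if gene_sets and gs in gene_sets:
            genes = list(gene_sets[gs])
        else:
            genes = [f"{gs}_g{i:03d}" for i in range(config.link_genes_per_set)]
        truth.link_gene_sets[gs] = genes
        by_ct = config.motif_rate_vectors[gs]
        for ct in sorted(by_ct):
            for cond in sorted(by_ct[ct]):
                rates = by_ct[ct][cond]
                fams = sorted(rates)
                probs = np.array([rates[f] for f in fams], dtype=float)
                truth.motif_rates[f"{gs}|{ct}|{cond}"] = dict(rates)
                n = config.n_elements_per_group
                fam_draw = rng.choice(len(fams), size=n, p=probs)
                gene_draw = rng.integers(0, len(genes), size=n)
                starts = rng.integers(0, 1_000_000, size=n)
                for i in range(n):
                    rows.append({
                        "element_id": f"{gs}_{ct}_{cond}_e{i:05d}",
                        "chromosome": "chr1",
                        "start": int(starts[i]),
                        "end": int(starts[i]) + 200,
                        "gene_id": genes[gene_draw[i]],
                        "motif_family": fams[fam_draw[i]],
                        "cell_type": ct,
                        "condition": cond,
                        "link_score": round(float(rng.uniform(0.5, 1.0)), 6),
                    })
    links = pd.DataFrame(rows)
    return links, truth


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _realize_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[s][rng.integers(0, len(IUPAC[s]))] for s in consensus)


def simulate_promoters(config: SimConfig, seed: int | None = None):
    """Uniform-ACGT promoters with planted motif occurrences.

    Every promoter receives each planted family's configured number of
    occurrences at recorded, non-overlapping positions.  Returns
    ``({gene: sequence}, SimTruth)``.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = derive_rng(seed, "promoters")
    truth = SimTruth()
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    for i in range(config.n_promoters):
        gene = f"prom{i:04d}"
        seq = list(bases[rng.integers(0, 4, size=config.promoter_length)])
        occupied: list[tuple[int, int]] = []
        truth.promoter_occurrences[gene] = {}
        for m in config.planted_motifs:
            positions = []
            L = len(m.consensus)
            for _ in range(m.n_occurrences):
                for _try in range(1000):
                    pos = int(rng.integers(0, config.promoter_length - L + 1))
                    if all(pos + L <= s or pos >= e for s, e in occupied):
                        break
                else:
                    raise ConfigError(
                        f"could not place {m.n_occurrences} non-overlapping "
                        f"occurrences of {m.family} in {config.promoter_length} bp"
                    )
                occupied.append((pos, pos + L))
                seq[pos:pos + L] = list(_realize_iupac(m.consensus.upper(), rng))
                positions.append(pos)
            truth.promoter_occurrences[gene][m.family] = {
                "count": m.n_occurrences,
                "positions": sorted(positions),
            }
        sequences[gene] = "".join(seq)
    return sequences, truth


# ---------------------------------------------------------------------------
# ortholog scores
# ---------------------------------------------------------------------------

def simulate_ortholog_scores(config: SimConfig, seed: int | None = None):
    """All-vs-all similarity table with planted reciprocal-best pairs.

    True pairs carry the highest mutual scores; decoy rows score strictly
    lower; a few sub-threshold rows exercise the e-value filter.  E-values
    decrease monotonically with score (evalue = 10^(-score/5)).
    Returns ``(score DataFrame, SimTruth)``.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = derive_rng(seed, "orthologs")
    truth = SimTruth()
    n1 = config.n_true_orthologs
    n2 = config.n_species2_genes
    sp1 = [f"s1g{i:04d}" for i in range(n1)]
    sp2 = [f"s2g{i:04d}" for i in range(n2)]
    rows = []
    seen = set()

    def add(g1, g2, score):
        if (g1, g2) in seen:
            return
        seen.add((g1, g2))
        rows.append({
            "gene_sp1": g1, "gene_sp2": g2,
            "score": round(float(score), 4),
            "evalue": float(10.0 ** (-score / 5.0)),
        })

    true_scores = rng.uniform(150.0, 300.0, size=n1)
    for i in range(n1):
        add(sp1[i], sp2[i], true_scores[i])
        truth.ortholog_pairs.append((sp1[i], sp2[i]))
    for i in range(n1):
        for _ in range(config.decoy_hits_per_gene):
            j = int(rng.integers(0, n2))
            if j == i:
                continue
            # strictly below both genes' true scores so true pairs stay mutual best
            cap = true_scores[i] if j >= n1 else min(true_scores[i], true_scores[j])
            add(sp1[i], sp2[j], cap * rng.uniform(0.5, 0.8))
        # occasional weak hit that fails the e-value ceiling
        if rng.uniform() < 0.2:
            j = int(rng.integers(0, n2))
            if j != i:
                add(sp1[i], sp2[j], rng.uniform(10.0, 30.0))
    scores = pd.DataFrame(rows)
    return scores, truth


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    counts: CountMatrix
    cells: pd.DataFrame
    genes: pd.DataFrame
    homeologs: pd.DataFrame
    links: pd.DataFrame
    promoters: dict[str, str]
    ortholog_scores: pd.DataFrame
    truth: SimTruth


def simulate_all(config: SimConfig, seed: int | None = None) -> SimBundle:
    """Run every generator coherently: link-table gene sets reference the
    simulated C4 homeolog genes when a ``C4`` set is configured."""
    config.validate()
    seed = config.seed if seed is None else seed
    cm, cells, genes, homeologs, truth = simulate_expression(config, seed)
    c4_genes = sorted(set(homeologs["gene_A"]) | set(homeologs["gene_B"]))
    gene_sets = {"C4": c4_genes} if "C4" in config.motif_rate_vectors else None
    links, t_links = simulate_peak_links(config, seed, gene_sets=gene_sets)
    promoters, t_prom = simulate_promoters(config, seed)
    scores, t_orth = simulate_ortholog_scores(config, seed)
    truth.motif_rates = t_links.motif_rates
    truth.link_gene_sets = t_links.link_gene_sets
    truth.promoter_occurrences = t_prom.promoter_occurrences
    truth.ortholog_pairs = t_orth.ortholog_pairs
    return SimBundle(cm, cells, genes, homeologs, links, promoters, scores, truth)
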