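import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from kranz.io import CountMatrix
from kranz.sim import DEEffectSpec, FamilySpec, SimConfig


@pytest.fixture
def toy_counts():
    """5 genes x 6 cells with hand-assigned groups, all cells passing QC off."""
    rng = np.random.default_rng(7)
    mat = rng.integers(0, 20, size=(5, 6))
    genes = [f"g{i}" for i in range(5)]
    cells = [f"c{i}" for i in range(6)]
    ann = pd.DataFrame({
        "cell_id": cells,
        "cell_type": ["IMC", "IMC", "KC", "KC", "IMC", "KC"],
        "condition": ["terrestrial"] * 4 + ["submerged"] * 2,
        "replicate": ["r1"] * 6,
    })
    return CountMatrix(genes, cells, sp.csr_matrix(mat)), ann


def small_sim_config(**overrides):
    """Trimmed two-cell-type config for fast recovery simulations."""
    defaults = dict(
        n_genes=100,
        cell_types=["IMC", "KC"],
        conditions=["terrestrial"],
        cells_per_group=300,
        family_specs=[FamilySpec("fam", 200, "IMC", 0.7)],
        de_effects=[],
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def small_config_factory():
    return small_sim_config


def permutation_rank_sum_p(a, b):
    """Full-permutation two-sided rank-sum p: independent oracle."""
    from itertools import combinations

    from scipy.stats import rankdata

    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n, m = len(a), len(b)
    mid = n * m / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - n * (n + 1) / 2

    u_obs = u_of(range(n))
    extreme = total = 0
    for idx in combinations(range(n + m), n):
        total += 1
        if abs(u_of(idx) - mid) >= abs(u_obs - mid) - 1e-12:
            extreme += 1
    return extreme / total


def brute_force_scan(sequence, pattern):
    """Position-by-position IUPAC matcher: independent oracle."""
    from kranz.motifs import IUPAC

    sequence, pattern = sequence.upper(), pattern.upper()
    hits = 0
    for i in range(len(sequence) - len(pattern) + 1):
        if all(sequence[i + j] in IUPAC[sym] for j, sym in enumerate(pattern)):
            hits += 1
    return hits


def brute_force_rbh(scores, evalue_max=1e-10):
    """Exhaustive double-loop RBH: independent oracle."""
    rows = [r for _, r in scores.iterrows()
            if "evalue" not in scores.columns or pd.isna(r.get("evalue"))
            or r["evalue"] <= evalue_max]
    pairs = set()
    g1s = {r["gene_sp1"] for r in rows}
    g2s = {r["gene_sp2"] for r in rows}
    for g1 in g1s:
        for g2 in g2s:
            mine = [r for r in rows if r["gene_sp1"] == g1 and r["gene_sp2"] == g2]
            if not mine:
                continue
            s = mine[0]["score"]
            best1 = max(r["score"] for r in rows if r["gene_sp1"] == g1)
            best2 = max(r["score"] for r in rows if r["gene_sp2"] == g2)
            if s == best1 and s == best2:
                # tie-break: lexicographically smallest partner on each side
                top1 = min(r["gene_sp2"] for r in rows
                           if r["gene_sp1"] == g1 and r["score"] == best1)
                top2 = min(r["gene_sp1"] for r in rows
                           if r["gene_sp2"] == g2 and r["score"] == best2)
                if top1 == g2 and top2 == g1:
                    pairs.add((g1, g2))
    return pairs
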