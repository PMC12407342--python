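"""Cross-species orthology by reciprocal best hits and the conserved
cell-specialized gene screen.

RBH: after discarding rows above the e-value ceiling, a pair is an ortholog
call when each gene is the other's top-scoring partner.  Score ties are
broken by the lexicographically smallest partner id and logged.

The conserved screen intersects, through the ortholog map, genes highly
expressed in a cell class exclusively in the C4 form of each species
(present in the species' C4-condition DE set, absent from its C3-condition
set, for the same cell class in both species).
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)


def reciprocal_best_hits(scores: pd.DataFrame, evalue_max: float = 1e-10) -> pd.DataFrame:
    """Mutual best-hit ortholog pairs from an all-vs-all similarity table.

    ``scores`` has columns gene_sp1, gene_sp2, score and optionally evalue.
    Rows with evalue > ``evalue_max`` are removed first (when present).
    Returns a frame (gene_sp1, gene_sp2, score) sorted by gene_sp1; empty
    input yields an empty frame.
    """
    df = scores
    if "evalue" in df.columns:
        df = df[df["evalue"].isna() | (df["evalue"] <= evalue_max)]
    if df.empty:
        return pd.DataFrame(columns=["gene_sp1", "gene_sp2", "score"])

    def best_partner(frame: pd.DataFrame, key: str, partner: str) -> dict[str, str]:
        best: dict[str, tuple[float, str]] = {}
        for g, p, s in zip(frame[key], frame[partner], frame["score"]):
            cur = best.get(g)
            # higher score wins; ties -> lexicographically smallest partner
            if cur is None or s > cur[0] or (s == cur[0] and p < cur[1]):
                if cur is not None and s == cur[0]:
                    logger.info("tie for %s at score %s: chose %s over %s", g, s, min(p, cur[1]), max(p, cur[1]))
                best[g] = (s, p)
        return {g: p for g, (s, p) in best.items()}

    fwd = best_partner(df, "gene_sp1", "gene_sp2")
    rev = best_partner(df, "gene_sp2", "gene_sp1")
    score_of = {(a, b): s for a, b, s in zip(df["gene_sp1"], df["gene_sp2"], df["score"])}
    pairs = [
        {"gene_sp1": g1, "gene_sp2": g2, "score": score_of[(g1, g2)]}
        for g1, g2 in fwd.items()
        if rev.get(g2) == g1
    ]
    out = pd.DataFrame(pairs, columns=["gene_sp1", "gene_sp2", "score"])
    return out.sort_values("gene_sp1").reset_index(drop=True)


def conserved_exclusive_sets(
    de_sp1_c4: dict[str, set],
    de_sp1_c3: dict[str, set],
    de_sp2_c4: dict[str, set],
    de_sp2_c3: dict[str, set],
    ortholog_map: pd.DataFrame,
) -> pd.DataFrame:
    """Genes cell-specialized exclusively in the C4 form of both species.

    Each DE argument maps a cell class (e.g. ``M-type``, ``BS-type``) to
    the set of genes highly expressed in that class under the given form.
    An entry (g1, g2, class) is emitted when g1 is in species 1's C4 set
    but not its C3 set for the class, g1 has an ortholog g2, and g2
    likewise is exclusive to species 2's C4 set for the same class.
    """
    classes = set(de_sp1_c4) | set(de_sp2_c4)
    for name, d in (("de_sp1_c4", de_sp1_c4), ("de_sp2_c4", de_sp2_c4)):
        missing = classes - set(d)
        if missing:
            raise KeyError(f"{name} lacks cell class(es) {sorted(missing)}")
    orth = dict(zip(ortholog_map["gene_sp1"], ortholog_map["gene_sp2"]))
    rows = []
    for cls in sorted(classes):
        excl1 = de_sp1_c4[cls] - de_sp1_c3.get(cls, set())
        excl2 = de_sp2_c4[cls] - de_sp2_c3.get(cls, set())
        for g1 in sorted(excl1):
            g2 = orth.get(g1)
            if g2 is not None and g2 in excl2:
                rows.append({"gene_sp1": g1, "gene_sp2": g2, "cell_class": cls})
    return pd.DataFrame(rows, columns=["gene_sp1", "gene_sp2", "cell_class"])
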