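"""Cellular subgenome-dominance statistics for homeolog pairs.

For a gene g and two cell types a, b under one condition, the D-value is
the absolute difference of mean normalized expression:

    D(g) = | Exp(g, a, cond) - Exp(g, b, cond) |

For a set of homeolog pairs the expression weight of subgenome B is

    Weight_B/AB = sum(D over B copies) / (sum(D over A copies) + sum(D over B copies))

A weight above 0.5 indicates subgenome-B dominance of the cell-type
contrast, below 0.5 subgenome-A dominance.  The weight is invariant to a
common rescaling of all expression values and flips to 1 - w when the A/B
labels are swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedWeightError(ValueError):
    """All D-values of a set are zero; the weight is undefined, not 0.5."""


def compute_dvalues(
    profile: pd.DataFrame,
    cell_a: str,
    cell_b: str,
    condition: str,
    genes=None,
) -> pd.DataFrame:
    """Per-gene D-values between two cell types under one condition.

    ``profile`` is the long-format frame from
    :func:`kranz.expression.celltype_means`.  Returns columns gene_id,
    condition, cell_a, cell_b, D.
    """
    sub = profile[profile["condition"] == condition]
    wide = sub.pivot_table(index="gene_id", columns="cell_type", values="mean")
    for ct in (cell_a, cell_b):
        if ct not in wide.columns:
            raise KeyError(f"profile has no group ({ct!r}, {condition!r})")
    if genes is None:
        genes = list(wide.index)
    missing = [g for g in genes if g not in wide.index]
    if missing:
        raise KeyError(f"genes missing from profile: {missing[:10]}")
    exp_a = wide.loc[genes, cell_a].to_numpy(dtype=float)
    exp_b = wide.loc[genes, cell_b].to_numpy(dtype=float)
    return pd.DataFrame({
        "gene_id": genes,
        "condition": condition,
        "cell_a": cell_a,
        "cell_b": cell_b,
        "D": np.abs(exp_a - exp_b),
    })


@dataclass
class SubgenomeWeight:
    set_id: str
    sum_D_A: float
    sum_D_B: float
    weight_B_AB: float
    n_pairs: int
    n_zero: int  # pairs whose both D-values are exactly zero


def subgenome_weight(
    dvalues: pd.DataFrame,
    homeologs: pd.DataFrame,
    set_id: str,
    member_pairs=None,
) -> SubgenomeWeight:
    """Aggregate D-values of homeolog pairs into Weight_B/AB.

    ``member_pairs`` restricts to a list of (gene_A, gene_B) tuples; by
    default all pairs of ``homeologs`` whose family equals ``set_id`` are
    used (or all pairs if no family matches).  Every member pair must have
    D-values for both copies.
    """
    if member_pairs is None:
        fam = homeologs[homeologs["family"] == set_id]
        pairs = fam if len(fam) else homeologs
        member_pairs = list(zip(pairs["gene_A"], pairs["gene_B"]))
    d = dvalues.set_index("gene_id")["D"]
    missing = [g for ab in member_pairs for g in ab if g not in d.index]
    if missing:
        raise KeyError(f"no D-value for genes: {missing[:10]}")
    d_a = np.array([d[a] for a, _ in member_pairs], dtype=float)
    d_b = np.array([d[b] for _, b in member_pairs], dtype=float)
    n_zero = int(np.sum((d_a == 0) & (d_b == 0)))
    sum_a, sum_b = float(d_a.sum()), float(d_b.sum())
    denom = sum_a + sum_b
    if denom == 0:
        raise UndefinedWeightError(
            f"set {set_id!r}: all D-values are zero; Weight_B/AB is undefined"
        )
    return SubgenomeWeight(
        set_id=set_id,
        sum_D_A=sum_a,
        sum_D_B=sum_b,
        weight_B_AB=sum_b / denom,
        n_pairs=len(member_pairs),
        n_zero=n_zero,
    )


def dominance_report(weights, margin: float = 0.0) -> pd.DataFrame:
    """Classify each set's weight as A-dominant, B-dominant or balanced.

    B-dominant when w > 0.5 + margin, A-dominant when w < 0.5 - margin.
    """
    rows = []
    for w in weights:
        if w.weight_B_AB > 0.5 + margin:
            call = "B-dominant"
        elif w.weight_B_AB < 0.5 - margin:
            call = "A-dominant"
        else:
            call = "balanced"
        rows.append({
            "set_id": w.set_id,
            "sum_D_A": w.sum_D_A,
            "sum_D_B": w.sum_D_B,
            "weight_B_AB": w.weight_B_AB,
            "n_pairs": w.n_pairs,
            "n_zero": w.n_zero,
            "call": call,
        })
    return pd.DataFrame(rows)


def family_weights(
    profile: pd.DataFrame,
    homeologs: pd.DataFrame,
    cell_a: str,
    cell_b: str,
    condition: str,
    restrict_genes=None,
) -> list[SubgenomeWeight]:
    """Weight_B/AB for every enzyme family in the homeolog table.

    ``restrict_genes`` optionally limits the computation to pairs with at
    least one member in the given set (e.g. genes differentially expressed
    between the two cell types); by default all pairs are used.
    """
    if restrict_genes is not None:
        restrict = set(restrict_genes)
        keep = homeologs["gene_A"].isin(restrict) | homeologs["gene_B"].isin(restrict)
        homeologs = homeologs.loc[keep].reset_index(drop=True)
    genes = sorted(set(homeologs["gene_A"]) | set(homeologs["gene_B"]))
    dvals = compute_dvalues(profile, cell_a, cell_b, condition, genes)
    out = []
    for fam in sorted(homeologs["family"].unique()):
        sub = homeologs[homeologs["family"] == fam]
        pairs = list(zip(sub["gene_A"], sub["gene_B"]))
        out.append(subgenome_weight(dvals, homeologs, fam, pairs))
    return out
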