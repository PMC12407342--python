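"""Motif-family frequency profiles of accessible cis-regulatory elements,
predominant / environment-triggered family calls, and IUPAC promoter scanning.

Frequency matrices are families x groups; each non-degenerate group column
is normalized to sum to 1.  The promoter scanner slides an IUPAC consensus
over every position (overlapping matches counted); in ``both`` mode the
reverse complement is scanned as well and hits are counted separately, so a
palindrome on its own site yields two hits unless deduplication is requested.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifConsensus:
    """One motif family with one or more IUPAC consensus patterns."""

    family: str
    patterns: list[str]

    def __post_init__(self) -> None:
        for p in self.patterns:
            bad = set(p.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"pattern {p!r}: invalid IUPAC symbol(s) {sorted(bad)}")
        self.patterns = [p.upper() for p in self.patterns]


@dataclass
class MotifFrequencyMatrix:
    """families x groups rates; non-degenerate columns sum to 1."""

    rates: pd.DataFrame
    degenerate: set = field(default_factory=set)  # all-zero group columns


# ---------------------------------------------------------------------------
# element counting and normalization
# ---------------------------------------------------------------------------

def count_elements(
    links: pd.DataFrame,
    gene_set,
    group_by=("cell_type", "condition"),
    count_mode: str = "element",
    families=None,
) -> pd.DataFrame:
    """Count accessible elements per (motif family x group) for a gene set.

    ``element`` mode counts distinct (element_id, family) pairs per group,
    so an element linked through several rows counts once; ``occurrence``
    mode counts rows.  Returns a families x groups integer frame (group
    columns are tuples over ``group_by``).  ``families`` fixes the row axis
    explicitly (useful to align matrices across condition-filtered tables);
    by default the families observed in ``links`` are used.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    if count_mode not in ("element", "occurrence"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    sub = links[links["gene_id"].isin(set(gene_set))]
    families = sorted(links["motif_family"].unique()) if families is None else sorted(families)
    group_by = list(group_by)
    all_groups = sorted(map(tuple, links[group_by].drop_duplicates().itertuples(index=False)))
    counts = pd.DataFrame(
        0, index=families,
        columns=pd.MultiIndex.from_tuples(all_groups, names=group_by),
        dtype=int,
    )
    if sub.empty:
        logger.warning("gene set matched no link rows; returning all-zero counts")
        return counts
    if count_mode == "element":
        sub = sub.drop_duplicates(subset=group_by + ["element_id", "motif_family"])
    grouped = sub.groupby(group_by + ["motif_family"], observed=True).size()
    for key, n in grouped.items():
        group, fam = tuple(key[:-1]), key[-1]
        counts.loc[fam, group] = int(n)
    return counts


def normalize_frequency(counts: pd.DataFrame) -> MotifFrequencyMatrix:
    """Divide each group column by its total; all-zero columns stay zero and
    are flagged degenerate (never NaN)."""
    totals = counts.sum(axis=0)
    degenerate = {c for c in counts.columns if totals[c] == 0}
    safe = totals.replace(0, 1)
    rates = counts.astype(float).div(safe, axis=1)
    return MotifFrequencyMatrix(rates=rates, degenerate=degenerate)


# ---------------------------------------------------------------------------
# family calls
# ---------------------------------------------------------------------------

def call_predominant(freq: MotifFrequencyMatrix, tau_pred: float = 0.10) -> pd.DataFrame:
    """Maximal-rate family per group, reported when the rate >= tau_pred.

    Ties at the maximum are all reported, in lexicographic family order.
    Degenerate groups are skipped with a warning.
    """
    rows = []
    for group in freq.rates.columns:
        if group in freq.degenerate:
            logger.warning("group %s is degenerate (all-zero); skipped", group)
            continue
        col = freq.rates[group]
        top = col.max()
        if top < tau_pred:
            continue
        for fam in sorted(col.index[col == top]):
            rows.append({
                "family": fam,
                "group": group if isinstance(group, str) else "|".join(map(str, group)),
                "call": "predominant",
                "rate": float(top),
            })
    return pd.DataFrame(rows, columns=["family", "group", "call", "rate"])


def call_environment_triggered(
    freq_cond1: MotifFrequencyMatrix,
    freq_cond2: MotifFrequencyMatrix,
    tau_high: float = 0.10,
    tau_low: float = 0.05,
) -> pd.DataFrame:
    """Families with a high rate under condition 1 but a low rate under
    condition 2 in the same group: rate1 >= tau_high and rate2 <= tau_low.

    The symmetric call is obtained by swapping the inputs.  The two
    matrices must share family and group axes.
    """
    r1, r2 = freq_cond1.rates, freq_cond2.rates
    if not (r1.index.equals(r2.index) and r1.columns.equals(r2.columns)):
        raise ValueError("frequency matrices must share family and group axes")
    rows = []
    for group in r1.columns:
        if group in freq_cond1.degenerate or group in freq_cond2.degenerate:
            continue
        hit = (r1[group] >= tau_high) & (r2[group] <= tau_low)
        for fam in sorted(r1.index[hit]):
            rows.append({
                "family": fam,
                "group": group if isinstance(group, str) else "|".join(map(str, group)),
                "call": "environment_triggered",
                "rate_cond1": float(r1.loc[fam, group]),
                "rate_cond2": float(r2.loc[fam, group]),
            })
    return pd.DataFrame(rows, columns=["family", "group", "call", "rate_cond1", "rate_cond2"])


# ---------------------------------------------------------------------------
# promoter scanning
# ---------------------------------------------------------------------------

def _pattern_regex(pattern: str) -> re.Pattern:
    # N in the *sequence* never matches: classes expand to ACGT only
    parts = []
    for sym in pattern:
        cls = IUPAC[sym]
        parts.append(cls if len(cls) == 1 else f"[{cls}]")
    return re.compile("(?=" + "".join(parts) + ")")


def count_matches(sequence: str, pattern: str) -> int:
    """Overlapping forward-strand matches of one IUPAC pattern."""
    bad = set(pattern.upper()) - set(IUPAC)
    if bad:
        raise ValueError(f"pattern {pattern!r}: invalid IUPAC symbol(s) {sorted(bad)}")
    if len(pattern) > len(sequence):
        return 0
    return len(_pattern_regex(pattern.upper()).findall(sequence.upper()))


def scan_promoters(
    sequences: dict[str, str],
    consensus: list[MotifConsensus],
    strand_mode: str = "both",
) -> pd.DataFrame:
    """Count motif-family matches in each promoter sequence.

    Returns a families x genes integer frame.  ``both`` mode also scans the
    reverse complement of each pattern; hits on the two strands are counted
    separately (no palindrome deduplication).
    """
    if strand_mode not in ("both", "forward"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    families = sorted(c.family for c in consensus)
    genes = list(sequences)
    out = pd.DataFrame(0, index=families, columns=genes, dtype=int)
    for cons in consensus:
        for pattern in cons.patterns:
            patterns = [pattern]
            if strand_mode == "both":
                patterns.append(reverse_complement(pattern))
            for gene, seq in sequences.items():
                for p in patterns:
                    out.loc[cons.family, gene] += count_matches(seq, p)
    return out


def aggregate_scan(scan: pd.DataFrame, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Sum per-gene scan counts into families x gene-set columns."""
    cols = {}
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in scan.columns]
        cols[name] = scan[present].sum(axis=1)
    return pd.DataFrame(cols, index=scan.index)
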