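"""Ks-based divergence timing.

With K the mean synonymous substitutions per synonymous site between two
lineages and r the substitution rate per site per year, divergence time is
T = K / (2 r); conversely a known divergence time calibrates the rate as
r = K / (2 T).  Units are substitutions/site and years; use
:func:`years_to_mya` for reporting.
"""

from __future__ import annotations


def time_from_ks(K: float, r: float) -> float:
    """Divergence time in years: T = K / (2 r)."""
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    if r <= 0:
        raise ValueError(f"rate must be > 0, got {r}")
    return K / (2.0 * r)


def rate_from_ks(K: float, T: float) -> float:
    """Substitution rate per site per year: r = K / (2 T)."""
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    if T <= 0:
        raise ValueError(f"time must be > 0, got {T}")
    return K / (2.0 * T)


def years_to_mya(t_years: float) -> float:
    return t_years / 1e6


def mya_to_years(t_mya: float) -> float:
    return t_mya * 1e6
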