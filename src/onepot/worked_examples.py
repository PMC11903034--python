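"""Small arithmetic helpers for summary statistics over eQTL count tables.

These operate on plain counts (how many eQTLs of each class showed some
property) and reproduce the kind of headline contingency statistics a
one-pot eQTL study reports: the odds ratio contrasting cell-cycle
interaction rates of local vs distant eQTLs, replication percentages
against a bulk experiment, and the cross-uniqueness of hotspots.
"""

from __future__ import annotations

# Worked-example inputs: eQTL classification counts from a three-cross
# yeast one-pot experiment (local/distant eQTLs with significant
# cell-cycle interactions, bulk replication of one-pot local eQTLs in
# the BY x RM cross, and hotspot sharing across crosses).
EXAMPLE_COUNTS = {
    "local_interacting": 116,
    "local_total": 2945,
    "distant_interacting": 790,
    "distant_total": 3238,
    "local_eqtl_onepot": 1031,
    "local_eqtl_bulk_significant": 717,
    "local_eqtl_bulk_same_direction": 108,
    "hotspots_total": 25,
    "hotspots_single_cross": 14,
}


def odds_ratio(a_hit: int, a_total: int, b_hit: int, b_total: int) -> float:
    """Sample odds ratio contrasting hit rates of class b vs class a.

    Classes enter as (hits, totals); e.g. with local eQTLs as class a
    and distant as class b, a value > 1 means distant eQTLs show the
    property more often.
    """
    if min(a_hit, b_hit) < 0 or a_hit > a_total or b_hit > b_total:
        raise ValueError("counts must satisfy 0 <= hits <= total")
    a_miss = a_total - a_hit
    b_miss = b_total - b_hit
    if a_hit == 0 or b_miss == 0:
        raise ValueError("odds ratio undefined for zero cells")
    return (b_hit * a_miss) / (b_miss * a_hit)


def percentage(part: int, whole: int) -> float:
    """part / whole as a percentage."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return 100.0 * part / whole


def interaction_odds_ratio(counts: dict | None = None) -> float:
    """Odds ratio of cell-cycle interaction for distant vs local eQTLs."""
    c = counts or EXAMPLE_COUNTS
    return odds_ratio(c["local_interacting"], c["local_total"],
                      c["distant_interacting"], c["distant_total"])


def bulk_support_percentage(counts: dict | None = None) -> float:
    """Percent of one-pot local eQTLs supported by the bulk experiment
    (significant in bulk, or same direction of effect)."""
    c = counts or EXAMPLE_COUNTS
    supported = (c["local_eqtl_bulk_significant"]
                 + c["local_eqtl_bulk_same_direction"])
    return percentage(supported, c["local_eqtl_onepot"])


def hotspot_uniqueness_percentage(counts: dict | None = None) -> float:
    """Percent of hotspots unique to a single cross."""
    c = counts or EXAMPLE_COUNTS
    return percentage(c["hotspots_single_cross"], c["hotspots_total"])
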