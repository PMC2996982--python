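"""Aggregation of classified rearrangements into usage tables.

Counts are tabulated per constant gene (columns) against JH segments or VH
families (rows), with column-normalised proportions.  Reads whose JH could
not be uniquely resolved between the two loci can be attributed
fractionally (1/k per candidate) or excluded.  Unresolved reads are always
excluded from denominators and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .repertoire import RearrangementCall

__all__ = ["UsageTable", "jh_usage", "vh_family_usage", "category_fractions"]


@dataclass
class UsageTable:
    counts: pd.DataFrame  # rows x constant genes
    proportions: pd.DataFrame  # column-normalised; NaN for empty columns

    @property
    def row_labels(self):
        return list(self.counts.index)

    @property
    def column_labels(self):
        return list(self.counts.columns)


def _finish(counts: pd.DataFrame) -> UsageTable:
    sums = counts.sum(axis=0)
    proportions = counts.divide(sums.where(sums > 0, np.nan), axis=1)
    return UsageTable(counts=counts, proportions=proportions)


def _classified(calls):
    return [c for c in calls if c.category != "unresolved"]


def jh_usage(
    calls: list[RearrangementCall],
    ambiguity_policy: str = "fractional",
    pool_ambiguous_columns: bool = False,
) -> UsageTable:
    """JH x constant-gene usage.

    A read with k candidate JH ids contributes 1/k to each under the
    ``fractional`` policy (default) or is dropped under ``strict``.  With
    ``pool_ambiguous_columns`` the delta columns of the two loci are pooled
    into one (they are generally too similar to distinguish).
    """
    if ambiguity_policy not in ("fractional", "strict"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    cells: dict[tuple, float] = {}
    for call in _classified(calls):
        if not call.jh_ids or call.ch_gene is None:
            continue
        if len(call.jh_ids) > 1 and ambiguity_policy == "strict":
            continue
        column = call.ch_gene
        if pool_ambiguous_columns and column.startswith("Cdelta"):
            column = "Cdelta_(pooled)"
        weight = 1.0 / len(call.jh_ids)
        for jh in sorted(call.jh_ids):
            cells[(jh, column)] = cells.get((jh, column), 0.0) + weight
    rows = sorted({r for r, _ in cells})
    cols = sorted({c for _, c in cells})
    counts = pd.DataFrame(0.0, index=rows, columns=cols)
    for (r, c), w in cells.items():
        counts.loc[r, c] = w
    return _finish(counts)


def vh_family_usage(
    calls: list[RearrangementCall], family_labels: dict
) -> UsageTable:
    """VH-family x constant-gene usage; every vh_id must have a family label."""
    cells: dict[tuple, float] = {}
    for call in _classified(calls):
        if call.vh_id is None or call.ch_gene is None:
            continue
        if call.vh_id not in family_labels:
            raise KeyError(f"no family label for VH gene {call.vh_id!r}")
        family = family_labels[call.vh_id]
        cells[(family, call.ch_gene)] = cells.get((family, call.ch_gene), 0.0) + 1.0
    rows = sorted({r for r, _ in cells})
    cols = sorted({c for _, c in cells})
    counts = pd.DataFrame(0.0, index=rows, columns=cols)
    for (r, c), w in cells.items():
        counts.loc[r, c] = w
    return _finish(counts)


def category_fractions(calls: list[RearrangementCall]) -> dict:
    """Category fractions over resolved reads, plus delta-conditional ones.

    Returns overall fractions per category, the number of unresolved reads,
    and — when any delta-containing read is present — the fraction of delta
    reads that are chimeric (Cmu1-containing) versus noncanonical.  With no
    delta reads the conditional entries are absent rather than zero.
    """
    resolved = _classified(calls)
    out: dict = {"n_resolved": len(resolved),
                 "n_unresolved": sum(1 for c in calls if c.category == "unresolved")}
    if not resolved:
        return out
    for category in sorted({c.category for c in resolved}):
        out[category] = sum(1 for c in resolved if c.category == category) / len(resolved)
    delta = [
        c
        for c in resolved
        if c.category in ("chimeric_mu1_delta", "noncanonical_delta")
        or (c.ch_gene or "").startswith("Cdelta")
    ]
    if delta:
        chimeric = sum(1 for c in delta if c.category == "chimeric_mu1_delta")
        out["delta_chimeric_fraction"] = chimeric / len(delta)
        out["delta_noncanonical_fraction"] = (
            sum(1 for c in delta if c.category == "noncanonical_delta") / len(delta)
        )
    return out
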