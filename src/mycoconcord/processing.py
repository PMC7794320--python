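"""Normalisation, filtering and abundance transforms for zOTU profiles.

The processing chain used by the pipeline is::

    counts -> blacklist filter -> relative abundance -> prevalence filter
           -> {logit | log10 | hellinger} transform

Feature removal happens before any transform, and the table is *not*
renormalised after columns are dropped: the retained relative abundances keep
their original per-sample denominators, so the value fed into the logit and
log10 formulas is always the fraction of all mapped reads, not of the
retained subset.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import FeatureTable, FeatureTableError

#: Taxonomic ranks in a UNITE-style lineage string, in order.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIXES = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__")))

#: Minimal non-zero relative abundance used to clamp the logit input and as
#: the pseudo-value in the log10 transform.
EPSILON = 1e-6


def normalize_relative(table: FeatureTable) -> FeatureTable:
    """Convert a count table to per-sample relative abundances.

    Each row is divided by its total count.  Samples with zero total are a
    hard error because a relative profile is undefined for them.
    """
    if table.units != "counts":
        raise FeatureTableError(f"normalize_relative expects counts, got {table.units!r}")
    totals = table.data.sum(axis=1)
    empty = totals.index[totals <= 0].tolist()
    if empty:
        raise FeatureTableError(f"samples with zero total count: {empty}")
    rel = table.data.div(totals, axis=0)
    return table.derive(rel, units="relative", step="normalize_relative")


def filter_blacklist(table: FeatureTable, blacklist: Iterable[str]) -> FeatureTable:
    """Drop features flagged as non-fungal (e.g. zOTUs mapping to bacterial genomes).

    Blacklist entries absent from the table are reported as a warning, not an
    error, so a shared blacklist can be applied to subset tables.
    """
    blacklist = set(blacklist)
    present = [f for f in table.feature_ids if f in blacklist]
    absent = blacklist.difference(table.feature_ids)
    if absent:
        warnings.warn(
            f"{len(absent)} blacklisted feature(s) not present in table", stacklevel=2
        )
    if len(present) == len(table.feature_ids):
        raise FeatureTableError("blacklist would remove every feature")
    if not present:
        return table
    kept = table.data.drop(columns=present)
    return table.derive(kept, step=f"filter_blacklist(removed={len(present)})")


def filter_prevalence(table: FeatureTable, min_fraction: float = 0.10) -> FeatureTable:
    """Retain features observed in strictly more than ``min_fraction`` of samples.

    The boundary is strict: with 10 samples and ``min_fraction=0.10`` a
    feature present in exactly one sample is dropped.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    n = table.shape[0]
    prevalence = (table.data > 0).sum(axis=0)
    keep = prevalence.index[prevalence > min_fraction * n]
    kept = table.data[list(keep)]
    return table.derive(
        kept, step=f"filter_prevalence(min_fraction={min_fraction}, kept={len(keep)})"
    )


def logit_transform(table: FeatureTable, epsilon: float = EPSILON) -> FeatureTable:
    """Apply ``f(x) = ln(x / (1 - x))`` to relative abundances.

    The logit is undefined at 0 and 1, so entries are clamped to
    ``[epsilon, 1 - epsilon]`` first; the default clamp reuses the 1e-6
    minimal non-zero value of the log10 transform.
    """
    if table.units != "relative":
        raise FeatureTableError(f"logit_transform expects relative abundances, got {table.units!r}")
    x = table.values
    if (x < 0).any() or (x > 1).any():
        raise FeatureTableError("logit input must lie in [0, 1]")
    x = np.clip(x, epsilon, 1 - epsilon)
    out = pd.DataFrame(
        np.log(x / (1 - x)), index=table.data.index, columns=table.data.columns
    )
    return table.derive(out, units="logit", step=f"logit_transform(epsilon={epsilon})")


def log10_transform(table: FeatureTable) -> FeatureTable:
    """Apply ``f(x) = log10(x + 1e-6) + 6`` elementwise.

    The pseudo-value 1e-6 acts as a minimal non-zero abundance and the offset
    of six makes the output non-negative: a zero maps exactly to zero, and the
    transform is strictly increasing.
    """
    if table.units not in {"relative", "intensity"}:
        raise FeatureTableError(
            f"log10_transform expects relative or intensity units, got {table.units!r}"
        )
    x = table.values
    if (x < 0).any():
        raise FeatureTableError("log10 input must be non-negative")
    out = pd.DataFrame(
        np.log10(x + 1e-6) + 6, index=table.data.index, columns=table.data.columns
    )
    return table.derive(out, units="log10", step="log10_transform")


def hellinger_transform(table: FeatureTable) -> FeatureTable:
    """Square-root of per-sample relative abundances (rows get unit norm)."""
    if table.units not in {"counts", "relative"}:
        raise FeatureTableError(
            f"hellinger_transform expects counts or relative units, got {table.units!r}"
        )
    x = table.values
    if (x < 0).any():
        raise FeatureTableError("hellinger input must be non-negative")
    sums = x.sum(axis=1)
    zero = np.asarray(table.data.index)[sums <= 0].tolist()
    if zero:
        raise FeatureTableError(f"all-zero samples have no Hellinger transform: {zero}")
    out = pd.DataFrame(
        np.sqrt(x / sums[:, None]), index=table.data.index, columns=table.data.columns
    )
    return table.derive(out, units="hellinger", step="hellinger_transform")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a semicolon-delimited ``k__...;g__...;s__...`` lineage into ranks.

    Missing or empty fields yield an empty string at that rank.
    """
    out = {rank: "" for rank in RANKS}
    for token in lineage.split(";"):
        token = token.strip()
        for rank, prefix in _RANK_PREFIXES.items():
            if token.startswith(prefix):
                out[rank] = token[len(prefix):].strip()
    return out


def aggregate_taxonomy(
    table: FeatureTable, taxonomy: Mapping[str, str], rank: str
) -> FeatureTable:
    """Sum feature columns sharing the same label at ``rank``.

    Features with no assignment at the requested rank are pooled under
    ``"unclassified"``.  Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    missing = [f for f in table.feature_ids if f not in taxonomy]
    if missing:
        raise KeyError(f"features missing from taxonomy: {missing[:5]}" +
                       (f" (+{len(missing) - 5} more)" if len(missing) > 5 else ""))
    labels = {
        f: (parse_lineage(taxonomy[f])[rank] or "unclassified") for f in table.feature_ids
    }
    grouped = table.data.T.groupby(table.data.columns.map(labels)).sum().T
    return table.derive(grouped, step=f"aggregate_taxonomy(rank={rank})")
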