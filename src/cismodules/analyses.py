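"""Downstream procedures: positional quartiles, group attribute
aggregation, orientation-based gene partition with enrichment, and greedy
extra-gene search."""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .discovery import pair_occurrences
from .model import (
    ModuleAttributes,
    ModuleInstance,
    MotifModel,
    MotifOccurrence,
    UpstreamRegion,
)
from .stats import (
    base_frequencies,
    motif_match_probability,
    sig_value,
    total_scan_windows,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Positional quartiles

def quartile_fractions(
    occurrences: Sequence[MotifOccurrence],
    length: int = 800,
    n_bins: int = 4,
) -> list[float]:
    """Fraction of occurrences per upstream distance bin.

    Bin ``i`` covers ``distance_to_atg`` in ``[i*length/n_bins,
    (i+1)*length/n_bins)``; bin 0 is proximal to the translation start.
    Fractions sum to 1.
    """
    if not occurrences:
        raise ValueError("no occurrences to bin")
    if length % n_bins != 0:
        raise ValueError(f"length {length} not divisible by n_bins {n_bins}")
    bin_width = length // n_bins
    counts = [0] * n_bins
    for occ in occurrences:
        distance = occ.distance_to_atg
        if distance is None:
            raise ValueError(
                f"occurrence {occ.gene_id}/{occ.motif} lacks distance_to_atg"
            )
        if not 0 <= distance < length:
            raise ValueError(
                f"distance_to_atg {distance} outside [0, {length})"
            )
        counts[distance // bin_width] += 1
    total = len(occurrences)
    return [count / total for count in counts]


def proximal_majority_flag(fractions: Sequence[float]) -> bool:
    """True iff the proximal bin holds the strict maximum fraction."""
    if not fractions:
        raise ValueError("empty fraction list")
    rest_max = max(fractions[1:], default=0.0)
    if fractions[0] == rest_max:
        log.warning("proximal bin tied with another bin; flag is False")
        return False
    return fractions[0] > rest_max


# ---------------------------------------------------------------------------
# Group aggregation

@dataclass
class GroupSummary:
    """Mean module attributes for one (group x module order).

    Display transforms follow the box-plot conventions: ABC shifted by +1
    into [0, 2], upstream position reported as an absolute distance.
    """

    group: str
    order: str
    n_members: int
    means: dict[str, float]
    abc_display: float
    upstream_display: float


def aggregate_group_attributes(
    members: Sequence[tuple[str, ModuleAttributes]],
    grouping: Mapping[str, str],
) -> list[GroupSummary]:
    """Arithmetic means of every attribute per (group x order).

    ``members`` holds (gene-set label, attributes) pairs; ``grouping`` maps
    gene-set labels to group names.
    """
    buckets: dict[tuple[str, str], list[ModuleAttributes]] = defaultdict(list)
    for label, attrs in members:
        if label not in grouping:
            raise ValueError(f"unknown group label {label!r}")
        buckets[(grouping[label], attrs.order)].append(attrs)
    summaries: list[GroupSummary] = []
    for (group, order) in sorted(buckets):
        rows = buckets[(group, order)]
        means = {
            fld: float(np.mean([getattr(a, fld) for a in rows]))
            for fld in ModuleAttributes.NUMERIC_FIELDS
        }
        summaries.append(GroupSummary(
            group=group,
            order=order,
            n_members=len(rows),
            means=means,
            abc_display=means["abc"] + 1.0,
            upstream_display=abs(means["median_upstream_position"]),
        ))
    return summaries


# ---------------------------------------------------------------------------
# Orientation partition and enrichment

def partition_by_orientation(
    genes: Iterable[str],
    modules: Iterable[ModuleInstance],
    order1: str,
    order2: str,
) -> tuple[set[str], set[str], set[str]]:
    """Split genes into exclusive-orientation subsets.

    subset1 holds genes all of whose modules have ``order1`` (and >= 1
    module); subset2 likewise for ``order2``.  Genes with both orders, other
    orders, or no modules are excluded.
    """
    if order1 == order2:
        raise ValueError("orders must be distinct")
    labels_by_gene: dict[str, set[str]] = defaultdict(set)
    for module in modules:
        labels_by_gene[module.gene_id].add(module.order_label)
    genes = set(genes)
    subset1 = {g for g in genes if labels_by_gene.get(g) == {order1}}
    subset2 = {g for g in genes if labels_by_gene.get(g) == {order2}}
    return subset1, subset2, genes - subset1 - subset2


@dataclass(frozen=True)
class TermEnrichment:
    term: str
    p_value: float
    k_subset: int
    k_universe: int
    enriched: bool


def hypergeometric_enrichment(
    subset: Iterable[str],
    universe: Iterable[str],
    annotations: Mapping[str, set[str]],
    alpha: float = 1e-3,
    bh_correction: bool = False,
) -> list[TermEnrichment]:
    """Exact hypergeometric upper-tail enrichment of annotation terms.

    ``p = P(X >= k)`` for ``X ~ Hypergeom(N=|universe|, K=term count,
    n=|subset|)``.  Terms with ``p <= alpha`` are flagged enriched; with
    ``bh_correction`` the Benjamini-Hochberg adjusted p is compared instead.
    Results sorted by p, then term.
    """
    subset = set(subset)
    universe = set(universe)
    stray = subset - universe
    if stray:
        raise ValueError(f"subset genes absent from universe: {sorted(stray)}")
    big_n, small_n = len(universe), len(subset)
    term_universe: dict[str, int] = defaultdict(int)
    term_subset: dict[str, int] = defaultdict(int)
    for gene in universe:
        for term in annotations.get(gene, ()):
            term_universe[term] += 1
            if gene in subset:
                term_subset[term] += 1
    records = []
    for term in sorted(term_universe):
        big_k = term_universe[term]
        k = term_subset[term]
        p = float(hypergeom.sf(k - 1, big_n, big_k, small_n))
        p = min(p, 1.0)
        records.append((term, p, k, big_k))
    records.sort(key=lambda r: (r[1], r[0]))
    if bh_correction and records:
        m = len(records)
        adjusted, running_min = [], 1.0
        for rank in range(m, 0, -1):
            running_min = min(running_min, records[rank - 1][1] * m / rank)
            adjusted.append(running_min)
        adjusted.reverse()
        flags = [q <= alpha for q in adjusted]
    else:
        flags = [p <= alpha for _, p, _, _ in records]
    return [
        TermEnrichment(term, p, k, big_k, flag)
        for (term, p, k, big_k), flag in zip(records, flags)
    ]


# ---------------------------------------------------------------------------
# Extra-gene search

@dataclass
class ExtraGeneResult:
    gene_id: str
    sig_after: float
    occurrences: list[MotifOccurrence]
    modules: list[ModuleInstance] = field(default_factory=list)


def extra_gene_search(
    gene_set_regions: Sequence[UpstreamRegion],
    candidate_regions: Sequence[UpstreamRegion],
    motif: MotifModel,
    p0: float | None = None,
    max_added: int = 20,
    *,
    background_regions: Sequence[UpstreamRegion] | None = None,
    partner: MotifModel | None = None,
    max_gap: int = 200,
) -> list[ExtraGeneResult]:
    """Greedily add candidate genes that increase the motif's Sig value.

    At each step the candidate whose inclusion maximally increases the Sig
    value of the enlarged set is added; the loop stops when no candidate
    improves Sig or ``max_added`` genes were added.  Candidates with zero
    occurrences are never added.  When ``partner`` is given, each added
    gene's modules with the partner motif are reported too.
    """
    from .scan import scan_region

    set_ids = {r.gene_id for r in gene_set_regions}
    overlap = set_ids & {r.gene_id for r in candidate_regions}
    if overlap:
        raise ValueError(
            f"candidates must be disjoint from the gene set: {sorted(overlap)}"
        )
    if max_added < 0:
        raise ValueError("max_added must be >= 0")
    if p0 is None:
        background = background_regions or (
            list(gene_set_regions) + list(candidate_regions)
        )
        p0 = motif_match_probability(motif, base_frequencies(background))

    k_total = sum(
        len(scan_region(region, motif)) for region in gene_set_regions
    )
    n_total = total_scan_windows(gene_set_regions, motif.width)
    current_sig = sig_value(k_total, n_total, p0)

    pool: dict[str, tuple[int, int, list[MotifOccurrence], UpstreamRegion]] = {}
    for region in candidate_regions:
        occs = scan_region(region, motif)
        if not occs:
            continue  # zero-occurrence candidates are never added
        pool[region.gene_id] = (
            len(occs),
            2 * max(0, region.length - motif.width + 1),
            occs,
            region,
        )

    results: list[ExtraGeneResult] = []
    while pool and len(results) < max_added:
        best_id, best_sig = None, current_sig
        for gene_id in sorted(pool):
            k_g, n_g, _, _ = pool[gene_id]
            candidate_sig = sig_value(k_total + k_g, n_total + n_g, p0)
            if candidate_sig > best_sig + 1e-12:
                best_id, best_sig = gene_id, candidate_sig
        if best_id is None:
            break
        k_g, n_g, occs, region = pool.pop(best_id)
        k_total += k_g
        n_total += n_g
        current_sig = best_sig
        modules: list[ModuleInstance] = []
        if partner is not None:
            partner_occs = scan_region(region, partner)
            modules = pair_occurrences(
                occs, partner_occs, max_gap, {region.gene_id: region.length}
            )
        results.append(
            ExtraGeneResult(best_id, current_sig, occs, modules)
        )
    return results
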