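"""Pairing of motif occurrences into module instances."""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .model import ModuleInstance, MotifOccurrence

log = logging.getLogger(__name__)


def order_label(first: MotifOccurrence, second: MotifOccurrence) -> str:
    """5'->3' order label ``"first-second"`` toward the translation start.

    Requires ``first.start <= second.start``; at equal starts the tie is
    broken by lexicographic motif name (logged).
    """
    if first.start > second.start:
        raise ValueError("first occurrence must not start after second")
    if first.start == second.start:
        log.warning(
            "equal starts for %s and %s in %s; breaking tie by motif name",
            first.motif, second.motif, first.gene_id,
        )
        a, b = sorted((first.motif, second.motif))
        return f"{a}-{b}"
    return f"{first.motif}-{second.motif}"


def build_module(
    occ_a: MotifOccurrence,
    occ_b: MotifOccurrence,
    region_length: int,
) -> ModuleInstance:
    """Build a :class:`ModuleInstance` from two occurrences of one gene.

    Inputs may be given in any order; the 5'-most occurrence becomes
    ``first``.  Midpoint is rounded half-up.
    """
    first, second = sorted(
        (occ_a, occ_b), key=lambda o: (o.start, o.motif, o.strand)
    )
    gap = second.start - first.end
    midpoint = (first.start + second.end + 1) // 2
    return ModuleInstance(
        gene_id=first.gene_id,
        first=first,
        second=second,
        order_label=order_label(first, second),
        gap=gap,
        same_strand=first.strand == second.strand,
        module_midpoint_distance=region_length - midpoint,
    )


def _by_gene(
    occurrences: Iterable[MotifOccurrence],
) -> dict[str, list[MotifOccurrence]]:
    grouped: dict[str, list[MotifOccurrence]] = defaultdict(list)
    for occ in occurrences:
        grouped[occ.gene_id].append(occ)
    return grouped


def pair_occurrences(
    occs_a: Sequence[MotifOccurrence],
    occs_b: Sequence[MotifOccurrence],
    max_gap: int,
    region_lengths: Mapping[str, int],
) -> list[ModuleInstance]:
    """All non-overlapping ordered pairs with edge-to-edge gap <= max_gap.

    One occurrence comes from each list, in either order along the
    sequence.  When both lists hold the same motif, each unordered pair is
    counted once.  Multiple modules per gene are allowed.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")

    names_a = {occ.motif for occ in occs_a}
    names_b = {occ.motif for occ in occs_b}
    same_motif = names_a == names_b and len(names_a | names_b) <= 1

    modules: list[ModuleInstance] = []
    if same_motif:
        pooled = _by_gene(set(occs_a) | set(occs_b))
        for gene_id in sorted(pooled):
            length = _region_length(region_lengths, gene_id)
            occs = sorted(
                pooled[gene_id], key=lambda o: (o.start, o.end, o.strand)
            )
            for first, second in itertools.combinations(occs, 2):
                _maybe_add(modules, first, second, max_gap, length)
    else:
        grouped_a = _by_gene(occs_a)
        grouped_b = _by_gene(occs_b)
        for gene_id in sorted(set(grouped_a) & set(grouped_b)):
            length = _region_length(region_lengths, gene_id)
            for occ_a, occ_b in itertools.product(
                grouped_a[gene_id], grouped_b[gene_id]
            ):
                _maybe_add(modules, occ_a, occ_b, max_gap, length)
    modules.sort(key=lambda m: (m.gene_id, m.first.start, m.second.start))
    return modules


def _region_length(region_lengths: Mapping[str, int], gene_id: str) -> int:
    try:
        return region_lengths[gene_id]
    except KeyError:
        raise ValueError(f"no region length known for gene {gene_id!r}")


def _maybe_add(
    modules: list[ModuleInstance],
    occ_a: MotifOccurrence,
    occ_b: MotifOccurrence,
    max_gap: int,
    region_length: int,
) -> None:
    first, second = sorted(
        (occ_a, occ_b), key=lambda o: (o.start, o.motif, o.strand)
    )
    gap = second.start - first.end
    if 0 <= gap <= max_gap:
        modules.append(build_module(first, second, region_length))


def modules_by_label(
    modules: Iterable[ModuleInstance],
) -> dict[str, list[ModuleInstance]]:
    grouped: dict[str, list[ModuleInstance]] = defaultdict(list)
    for module in modules:
        grouped[module.order_label].append(module)
    return dict(grouped)
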