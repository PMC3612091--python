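"""IUPAC consensus scanning of upstream regions on both strands."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .model import (
    IUPAC_COMPLEMENT,
    IUPAC_SETS,
    MotifModel,
    MotifOccurrence,
    UpstreamRegion,
)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# Per-code boolean lookup over (A, C, G, T, N); an N in the *sequence*
# matches no motif position, so column 4 is always False.
_ALLOWED = {
    code: np.array([base in allowed for base in "ACGTN"])
    for code, allowed in IUPAC_SETS.items()
}


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC string (involution)."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r}") from None


def iupac_matches(window: str, consensus: str, max_mismatches: int) -> bool:
    """True iff ``window`` matches ``consensus`` with at most
    ``max_mismatches`` positions outside the code's allowed set.

    An ``N`` in the window matches nothing and always counts as a mismatch.
    """
    if len(window) != len(consensus):
        raise ValueError(
            f"window length {len(window)} != consensus length {len(consensus)}"
        )
    mismatches = 0
    for base, code in zip(window.upper(), consensus.upper()):
        try:
            allowed = IUPAC_SETS[code]
        except KeyError:
            raise ValueError(f"non-IUPAC consensus character {code!r}") from None
        if base not in allowed:
            mismatches += 1
            if mismatches > max_mismatches:
                return False
    return True


def _encode(sequence: str) -> np.ndarray:
    return np.array([_BASE_INDEX[c] for c in sequence], dtype=np.int8)


def _mismatch_profile(codes: np.ndarray, consensus: str) -> np.ndarray:
    """Mismatch count of every window of ``len(consensus)`` against it."""
    width = len(consensus)
    n_offsets = len(codes) - width + 1
    if n_offsets <= 0:
        return np.empty(0, dtype=np.int32)
    mismatches = np.zeros(n_offsets, dtype=np.int32)
    for j, code in enumerate(consensus):
        mismatches += ~_ALLOWED[code][codes[j:j + n_offsets]]
    return mismatches


def scan_region(
    region: UpstreamRegion, motif: MotifModel
) -> list[MotifOccurrence]:
    """All occurrences of ``motif`` on both strands of ``region``.

    Occurrences are reported in + (gene) coordinates, sorted by start with
    + before - at equal starts.  Overlapping and palindromic double matches
    are all reported.  A motif wider than the region yields an empty list.
    """
    codes = _encode(region.sequence)
    forward = _mismatch_profile(codes, motif.consensus)
    reverse = _mismatch_profile(codes, reverse_complement(motif.consensus))
    length, width = region.length, motif.width
    occurrences: list[MotifOccurrence] = []
    for start in range(len(forward)):
        end = start + width
        if forward[start] <= motif.max_mismatches:
            occurrences.append(MotifOccurrence(
                region.gene_id, motif.name, start, end, "+",
                int(forward[start]), length - end,
            ))
        if reverse[start] <= motif.max_mismatches:
            occurrences.append(MotifOccurrence(
                region.gene_id, motif.name, start, end, "-",
                int(reverse[start]), length - end,
            ))
    return occurrences


def scan_regions(
    regions: Iterable[UpstreamRegion], motifs: Iterable[MotifModel]
) -> list[MotifOccurrence]:
    """Scan every region with every motif; concatenated, region-major."""
    motifs = list(motifs)
    occurrences: list[MotifOccurrence] = []
    for region in regions:
        for motif in motifs:
            occurrences.extend(scan_region(region, motif))
    return occurrences
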