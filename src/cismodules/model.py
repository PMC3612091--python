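"""Core domain objects shared across the package.

Coordinate convention: every upstream region is stored 5'->3' in the gene's
reading direction.  Index 0 is the most upstream base and index ``length - 1``
abuts the translation start, so the upstream distance of position ``i`` is
``length - i``.  Feature coordinates are 0-based, end-exclusive, and a
feature's distance to the translation start is ``length - end`` (bases
between its 3' edge and the ATG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Allowed-base sets for every IUPAC nucleotide code (over the concrete
#: alphabet only; an ``N`` in a *sequence* is never a member of any set and
#: therefore never matches a motif position).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

SEQUENCE_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class UpstreamRegion:
    """One gene's upstream sequence (default 800 bp) in gene orientation."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"region {self.gene_id!r}: invalid sequence characters "
                f"{sorted(bad)}; expected A/C/G/T/N"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def upstream_distance(self, index: int) -> int:
        """Distance (bp) from position ``index`` to the translation start."""
        return self.length - index


@dataclass(frozen=True)
class MotifModel:
    """A named IUPAC consensus with an allowed-mismatch budget."""

    name: str
    consensus: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        consensus = self.consensus.upper()
        bad = [c for c in consensus if c not in IUPAC_SETS]
        if bad:
            raise ValueError(
                f"motif {self.name!r}: invalid IUPAC characters {bad}"
            )
        if len(consensus) < 1:
            raise ValueError(f"motif {self.name!r}: empty consensus")
        if not 0 <= self.max_mismatches < len(consensus):
            raise ValueError(
                f"motif {self.name!r}: max_mismatches must satisfy "
                f"0 <= m < width ({self.max_mismatches} vs width "
                f"{len(consensus)})"
            )
        object.__setattr__(self, "consensus", consensus)

    @property
    def width(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif match on an upstream region, in + (gene) coordinates.

    ``strand`` is relative to the gene; a ``-`` occurrence means the
    reverse complement of the consensus was matched on the stored string.
    ``distance_to_atg`` is ``region.length - end`` and may be ``None`` for
    occurrences read from minimal tables.
    """

    gene_id: str
    motif: str
    start: int
    end: int
    strand: str
    mismatches: int = 0
    distance_to_atg: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"occurrence {self.gene_id}/{self.motif}: strand must be "
                f"'+' or '-', got {self.strand!r}"
            )
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"occurrence {self.gene_id}/{self.motif}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ModuleInstance:
    """An ordered pair of motif occurrences in one upstream region.

    ``first`` is the 5'-most occurrence (smaller start).  ``gap`` is
    edge-to-edge (``second.start - first.end``); overlapping pairs are not
    modules.  ``module_midpoint_distance`` is the upstream distance of the
    midpoint of the spanned interval, rounded half-up.
    """

    gene_id: str
    first: MotifOccurrence
    second: MotifOccurrence
    order_label: str
    gap: int
    same_strand: bool
    module_midpoint_distance: int

    def __post_init__(self) -> None:
        if self.first.gene_id != self.second.gene_id:
            raise ValueError(
                "module components come from different genes: "
                f"{self.first.gene_id!r} vs {self.second.gene_id!r}"
            )
        if self.gap < 0:
            raise ValueError(f"module gap must be >= 0, got {self.gap}")

    @property
    def signed_upstream_position(self) -> int:
        """Module position as a negative upstream coordinate."""
        return -self.module_midpoint_distance

    @property
    def span(self) -> int:
        return self.second.end - self.first.start


@dataclass
class ModuleAttributes:
    """The five score components plus summary counts for one
    (gene set x module order)."""

    order: str
    sig_first: float
    sig_second: float
    abc: float
    position_score: float
    coverage: float
    orientation_f_same: float
    n_occurrences: int
    median_gap: float
    median_upstream_position: float
    module_score: float = math.nan
    gene_set: str = "set"

    NUMERIC_FIELDS = (
        "sig_first",
        "sig_second",
        "abc",
        "position_score",
        "coverage",
        "orientation_f_same",
        "n_occurrences",
        "median_gap",
        "median_upstream_position",
        "module_score",
    )


@dataclass(frozen=True)
class ScoreWeights:
    """User-adjustable weights for the five module-score components."""

    w_sig: float = 1.0
    w_abc: float = 1.0
    w_position: float = 1.0
    w_coverage: float = 1.0
    w_orientation: float = 1.0

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(w < 0 for w in vals):
            raise ValueError("weights must be non-negative")
        if sum(vals) <= 0:
            raise ValueError("at least one weight must be positive")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.w_sig,
            self.w_abc,
            self.w_position,
            self.w_coverage,
            self.w_orientation,
        )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ScoreWeights":
        """Build from short (``sig``) or long (``w_sig``) key names."""
        kwargs = {}
        for fld in ("sig", "abc", "position", "coverage", "orientation"):
            for key in (fld, "w_" + fld):
                if key in mapping:
                    kwargs["w_" + fld] = float(mapping[key])
        unknown = set(mapping) - {
            k for f in ("sig", "abc", "position", "coverage", "orientation")
            for k in (f, "w_" + f)
        }
        if unknown:
            raise ValueError(f"unknown weight keys: {sorted(unknown)}")
        return cls(**kwargs)
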