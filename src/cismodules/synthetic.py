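"""Synthetic promoter generator with planted motif modules.

Every statistic in the package can be exercised against known ground truth:
background bases are i.i.d. at a configured GC content and module instances
(two motif sites with a configured gap, order, strand relation and position
bias) overwrite the background in a configured fraction of genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .discovery import build_module
from .model import (
    IUPAC_SETS,
    ModuleInstance,
    MotifModel,
    MotifOccurrence,
    UpstreamRegion,
)
from .scan import reverse_complement

_BASES = "ACGT"


@dataclass
class PlantSpec:
    """Parameters of a synthetic dataset with planted modules."""

    n_genes: int
    motif_a: MotifModel
    motif_b: MotifModel
    length: int = 800
    gc_content: float = 0.40
    coverage: float = 0.5
    gap: int = 12
    gap_distribution: str = "constant"  # "constant" | "geometric"
    position_distribution: str = "uniform"  # "uniform" | "proximal"
    p_same_strand: float = 0.5
    mismatch_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0.0 <= self.p_same_strand <= 1.0:
            raise ValueError("p_same_strand must be in [0, 1]")
        if not 0.0 <= self.mismatch_rate <= 1.0:
            raise ValueError("mismatch_rate must be in [0, 1]")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.gap_distribution not in ("constant", "geometric"):
            raise ValueError(
                f"unknown gap_distribution {self.gap_distribution!r}"
            )
        if self.position_distribution not in ("uniform", "proximal"):
            raise ValueError(
                f"unknown position_distribution {self.position_distribution!r}"
            )
        min_span = self.motif_a.width + self.motif_b.width + (
            self.gap if self.gap_distribution == "constant" else 0
        )
        if min_span > self.length:
            raise ValueError(
                f"planted module span {min_span} exceeds region length "
                f"{self.length}"
            )

    @property
    def order(self) -> str:
        return f"{self.motif_a.name}-{self.motif_b.name}"

    @property
    def n_planted(self) -> int:
        return int(round(self.coverage * self.n_genes))


@dataclass
class SyntheticTruth:
    """Exact planted coordinates, strands and gaps for a dataset."""

    occurrences: list[MotifOccurrence]
    modules: list[ModuleInstance]
    planted_genes: list[str]
    spec: PlantSpec
    truncated_gaps: int = 0


def _random_background(
    n_bases: int, gc_content: float, rng: np.random.Generator
) -> np.ndarray:
    probs = [
        (1 - gc_content) / 2, gc_content / 2,
        gc_content / 2, (1 - gc_content) / 2,
    ]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), n_bases, p=probs)


def _instantiate_site(
    motif: MotifModel, rng: np.random.Generator, mismatch_rate: float
) -> tuple[str, int]:
    """Concrete site drawn from the consensus; optionally one mismatch."""
    site = [
        sorted(IUPAC_SETS[code])[rng.integers(0, len(IUPAC_SETS[code]))]
        for code in motif.consensus
    ]
    mismatches = 0
    if mismatch_rate > 0 and rng.random() < mismatch_rate:
        mutable = [
            i for i, code in enumerate(motif.consensus)
            if len(IUPAC_SETS[code]) < 4
        ]
        if mutable:
            pos = mutable[int(rng.integers(0, len(mutable)))]
            forbidden = sorted(
                set(_BASES) - IUPAC_SETS[motif.consensus[pos]]
            )
            site[pos] = forbidden[int(rng.integers(0, len(forbidden)))]
            mismatches = 1
    return "".join(site), mismatches


def generate_dataset(
    spec: PlantSpec,
) -> tuple[list[UpstreamRegion], SyntheticTruth]:
    """Emit upstream regions and the exact planted truth.

    Deterministic given ``spec.seed``.  Planted sites never overlap each
    other; accidental background matches are left in place (they are part
    of realistic noise).
    """
    rng = np.random.default_rng(spec.seed)
    planted_ids = set(
        rng.choice(spec.n_genes, spec.n_planted, replace=False).tolist()
    )
    width = len(str(spec.n_genes))
    regions: list[UpstreamRegion] = []
    occurrences: list[MotifOccurrence] = []
    modules: list[ModuleInstance] = []
    planted_genes: list[str] = []
    truncated = 0

    w_a, w_b = spec.motif_a.width, spec.motif_b.width
    for index in range(spec.n_genes):
        gene_id = f"g{index:0{width}d}"
        bases = _random_background(spec.length, spec.gc_content, rng)
        if index in planted_ids:
            max_gap_fit = spec.length - w_a - w_b
            if spec.gap_distribution == "constant":
                gap = spec.gap
            else:
                gap = int(rng.geometric(1.0 / (spec.gap + 1))) - 1
                if gap > max_gap_fit:
                    gap = max_gap_fit
                    truncated += 1
            span = w_a + gap + w_b
            free = spec.length - span
            if spec.position_distribution == "uniform":
                start = int(rng.integers(0, free + 1))
            else:
                # distance of the module's 3' edge to the ATG, biased
                # toward the translation start
                distance = min(int((free + 1) * rng.beta(1.0, 5.0)), free)
                start = free - distance
            strand_a = "+-"[int(rng.integers(0, 2))]
            same = rng.random() < spec.p_same_strand
            strand_b = strand_a if same else ("+-"[strand_a == "+"])
            site_a, mm_a = _instantiate_site(
                spec.motif_a, rng, spec.mismatch_rate
            )
            site_b, mm_b = _instantiate_site(
                spec.motif_b, rng, spec.mismatch_rate
            )
            placed = []
            for motif, site, mm, strand, offset in (
                (spec.motif_a, site_a, mm_a, strand_a, start),
                (spec.motif_b, site_b, mm_b, strand_b, start + w_a + gap),
            ):
                written = site if strand == "+" else reverse_complement(site)
                bases[offset:offset + motif.width] = np.frombuffer(
                    written.encode(), dtype="S1"
                )
                occ = MotifOccurrence(
                    gene_id, motif.name, offset, offset + motif.width,
                    strand, mm, spec.length - (offset + motif.width),
                )
                placed.append(occ)
                occurrences.append(occ)
            modules.append(build_module(placed[0], placed[1], spec.length))
            planted_genes.append(gene_id)
        regions.append(UpstreamRegion(gene_id, bases.tobytes().decode()))

    truth = SyntheticTruth(
        occurrences=occurrences,
        modules=modules,
        planted_genes=planted_genes,
        spec=spec,
        truncated_gaps=truncated,
    )
    return regions, truth
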