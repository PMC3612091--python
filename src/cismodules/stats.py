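"""Module score components and their combination.

Five statistics are computed for each (gene set x module order):

* Sig value of each component motif: binomial-tail overrepresentation in
  bits, ``Sig = -log2 P(X >= k)`` with ``X ~ Binomial(n_windows, p0)``.
* ABC score: signed area between the empirical CDFs of actual vs
  shuffled-null inter-motif distances, normalized to [-1, +1].  Positive
  means the motifs sit closer together than chance.
* Position score: Kolmogorov-Smirnov distance of module upstream positions
  from Uniform[0, L].
* Coverage: fraction of genes carrying at least one module instance.
* Orientation: strength of strand co-orientation preference,
  ``|2 f_same - 1|`` (same-strand and opposite-strand preference both
  score high).

The weighted average of the five normalized components is the module score
in [0, 1].
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .discovery import modules_by_label, pair_occurrences
from .model import (
    IUPAC_SETS,
    ModuleAttributes,
    ModuleInstance,
    MotifModel,
    MotifOccurrence,
    ScoreWeights,
    UpstreamRegion,
)

log = logging.getLogger(__name__)

_LN2 = math.log(2.0)
_BASE_ORDER = "ACGT"

DEFAULT_SIG_REF = 240.0


# ---------------------------------------------------------------------------
# Sig value

def sig_value(k: int, n: int, p0: float) -> float:
    """Overrepresentation significance in bits: ``-log2 P(X >= k)``.

    Computed in log space so that extreme tails (e.g. 2**-240) do not
    underflow.  ``k = 0`` gives 0 bits.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 0.0
    tail = binom.sf(k - 1, n, p0)
    if tail > 0.0:
        return max(0.0, -math.log2(tail))
    # Tail underflowed double precision: sum dominated log-pmf terms.  The
    # pmf is decreasing beyond the mode, so a truncated window suffices.
    upper = min(n, k + 2000)
    support = np.arange(k, upper + 1)
    log_tail = logsumexp(binom.logpmf(support, n, p0))
    return float(-log_tail / _LN2)


def base_frequencies(regions: Iterable[UpstreamRegion]) -> np.ndarray:
    """Strand-symmetrized A/C/G/T frequencies of a region set (N ignored)."""
    counts = Counter()
    for region in regions:
        counts.update(region.sequence)
    total = sum(counts[b] for b in _BASE_ORDER)
    if total == 0:
        raise ValueError("regions contain no A/C/G/T bases")
    at = (counts["A"] + counts["T"]) / (2 * total)
    cg = (counts["C"] + counts["G"]) / (2 * total)
    return np.array([at, cg, cg, at])


def motif_match_probability(
    motif: MotifModel, frequencies: np.ndarray
) -> float:
    """Per-window match probability under an i.i.d. base model.

    Accounts for the mismatch budget via a Poisson-binomial tail over the
    per-position match probabilities.
    """
    freq = {b: float(frequencies[i]) for i, b in enumerate(_BASE_ORDER)}
    per_position = [
        sum(freq[b] for b in IUPAC_SETS[code]) for code in motif.consensus
    ]
    # dp[j] = P(exactly j mismatches so far); overflow beyond the budget
    # is dropped since only P(<= budget) is needed.
    dp = np.zeros(motif.max_mismatches + 1)
    dp[0] = 1.0
    for q in per_position:
        shifted = np.concatenate(([0.0], dp[:-1])) * (1.0 - q)
        dp = dp * q + shifted
    p = float(dp.sum())
    return min(max(p, 1e-300), 1.0 - 1e-12)


def total_scan_windows(
    regions: Iterable[UpstreamRegion], width: int
) -> int:
    """Number of scanned windows over both strands of a region set."""
    return sum(2 * max(0, r.length - width + 1) for r in regions)


def gene_set_sig(
    regions: Sequence[UpstreamRegion],
    occurrences: Iterable[MotifOccurrence],
    motif: MotifModel,
    p0: float,
) -> float:
    """Sig value of ``motif`` over a whole gene set."""
    k = sum(1 for occ in occurrences if occ.motif == motif.name)
    n = total_scan_windows(regions, motif.width)
    return sig_value(k, n, p0)


# ---------------------------------------------------------------------------
# Shuffling null model for inter-motif distances

def _place_nonoverlapping(
    length: int,
    widths: Sequence[int],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> list[int] | None:
    """Uniform draw of non-overlapping start offsets, one per width.

    Rejection sampling from independent uniform offsets conditioned on
    pairwise non-overlap, i.e. uniform over all valid placements.
    """
    if sum(widths) > length:
        return None
    for _ in range(max_tries):
        starts = [int(rng.integers(0, length - w + 1)) for w in widths]
        intervals = sorted(zip(starts, widths))
        if all(
            intervals[i][0] + intervals[i][1] <= intervals[i + 1][0]
            for i in range(len(intervals) - 1)
        ):
            return starts
    return None


def occurrence_counts_per_gene(
    occurrences: Iterable[MotifOccurrence],
) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for occ in occurrences:
        counts[occ.gene_id] += 1
    return dict(counts)


def sample_null_modules(
    region_lengths: Mapping[str, int],
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    motif_a: MotifModel,
    motif_b: MotifModel,
    max_gap: int,
    replicates: int,
    seed,
) -> list[ModuleInstance]:
    """Shuffled-null modules: reposition the observed per-gene numbers of
    instances uniformly at random (non-overlapping, random strand) and
    re-pair them.  Deterministic given ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    same_motif = motif_a.name == motif_b.name
    genes = sorted(set(counts_a) | set(counts_b))
    skipped: set[str] = set()
    null_modules: list[ModuleInstance] = []
    strands = "+-"
    for _ in range(replicates):
        for gene_id in genes:
            n_a = counts_a.get(gene_id, 0)
            n_b = 0 if same_motif else counts_b.get(gene_id, 0)
            if same_motif:
                if n_a < 2:
                    continue
            elif n_a == 0 or n_b == 0:
                continue
            length = region_lengths[gene_id]
            widths = [motif_a.width] * n_a + [motif_b.width] * n_b
            starts = _place_nonoverlapping(length, widths, rng)
            if starts is None:
                if gene_id not in skipped:
                    log.warning(
                        "gene %s: region too short to place %d instances; "
                        "skipped in null sampling", gene_id, len(widths),
                    )
                    skipped.add(gene_id)
                continue
            occs_a, occs_b = [], []
            for idx, start in enumerate(starts):
                motif = motif_a if idx < n_a else motif_b
                occ = MotifOccurrence(
                    gene_id, motif.name, start, start + motif.width,
                    strands[int(rng.integers(0, 2))], 0,
                    length - (start + motif.width),
                )
                (occs_a if idx < n_a else occs_b).append(occ)
            if same_motif:
                occs_b = occs_a
            null_modules.extend(pair_occurrences(
                occs_a, occs_b, max_gap, {gene_id: length}
            ))
    return null_modules


def sample_null_distances(
    region_lengths: Mapping[str, int],
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    motif_a: MotifModel,
    motif_b: MotifModel,
    max_gap: int,
    replicates: int,
    seed,
) -> list[int]:
    """Pooled inter-motif gaps of the shuffling null (all order labels)."""
    return [
        module.gap
        for module in sample_null_modules(
            region_lengths, counts_a, counts_b, motif_a, motif_b,
            max_gap, replicates, seed,
        )
    ]


# ---------------------------------------------------------------------------
# Score components

def abc_score(
    actual_gaps: Sequence[float],
    null_gaps: Sequence[float],
    d_max: int,
) -> float:
    """Area between empirical gap CDFs, normalized to [-1, +1].

    Equals ``(mean(null) - mean(actual)) / d_max``; positive when actual
    modules are tighter than the shuffled null.
    """
    if len(actual_gaps) == 0 or len(null_gaps) == 0:
        raise ValueError("gap samples must be non-empty")
    actual = np.asarray(actual_gaps, dtype=float)
    null = np.asarray(null_gaps, dtype=float)
    for name, sample in (("actual", actual), ("null", null)):
        if np.any((sample < 0) | (sample > d_max)):
            raise ValueError(f"{name} gaps outside [0, {d_max}]")
    score = (null.mean() - actual.mean()) / d_max
    return float(min(1.0, max(-1.0, score)))


def position_score(positions: Sequence[float], length: int) -> float:
    """KS distance of upstream positions from Uniform[0, length]."""
    if len(positions) == 0:
        raise ValueError("position sample must be non-empty")
    x = np.sort(np.asarray(positions, dtype=float))
    if np.any((x < 0) | (x > length)):
        raise ValueError(f"positions outside [0, {length}]")
    u = x / length
    n = len(u)
    ranks = np.arange(1, n + 1)
    d_plus = np.max(ranks / n - u)
    d_minus = np.max(u - (ranks - 1) / n)
    return float(max(d_plus, d_minus))


def module_coverage(genes_with_module: int, genes_total: int) -> float:
    """Fraction of genes carrying >= 1 module instance (de-duplicated)."""
    if genes_total <= 0:
        raise ValueError("genes_total must be > 0")
    if not 0 <= genes_with_module <= genes_total:
        raise ValueError("need 0 <= genes_with_module <= genes_total")
    return genes_with_module / genes_total


def orientation_score(f_same: float) -> float:
    """Strand-preference strength ``|2 f_same - 1|``; 0 = no preference."""
    if not 0.0 <= f_same <= 1.0:
        raise ValueError(f"f_same must be in [0, 1], got {f_same}")
    return abs(2.0 * f_same - 1.0)


def combine_module_score(
    attrs: ModuleAttributes,
    weights: ScoreWeights | None = None,
    sig_ref: float = DEFAULT_SIG_REF,
) -> float:
    """Weighted mean of the five normalized components, in [0, 1]."""
    if sig_ref <= 0:
        raise ValueError("sig_ref must be > 0")
    weights = weights or ScoreWeights()
    sig_norm = min(min(attrs.sig_first, attrs.sig_second) / sig_ref, 1.0)
    components = (
        sig_norm,
        (attrs.abc + 1.0) / 2.0,
        attrs.position_score,
        attrs.coverage,
        orientation_score(attrs.orientation_f_same),
    )
    w = weights.as_tuple()
    return float(
        sum(wi * ci for wi, ci in zip(w, components)) / sum(w)
    )


# ---------------------------------------------------------------------------
# Gene-set scoring pipeline

def score_gene_set(
    regions: Sequence[UpstreamRegion],
    motifs: Mapping[str, MotifModel],
    pairs: Sequence[tuple[str, str]],
    *,
    occurrences: Sequence[MotifOccurrence] | None = None,
    background_regions: Sequence[UpstreamRegion] | None = None,
    max_gap: int = 200,
    replicates: int = 1000,
    seed: int = 0,
    weights: ScoreWeights | None = None,
    sig_ref: float = DEFAULT_SIG_REF,
    d_max: int | None = None,
    gene_set: str = "set",
) -> list[ModuleAttributes]:
    """Compute :class:`ModuleAttributes` (plus module score) for every
    observed order label of the requested motif pairs.

    ``occurrences`` may be supplied to bypass scanning (e.g. from a table);
    missing motifs are scanned on demand.  Background composition for the
    Sig value comes from ``background_regions`` when given, else from the
    gene set itself.
    """
    from .scan import scan_regions  # local import avoids cycle at import time

    weights = weights or ScoreWeights()
    d_max = max_gap if d_max is None else d_max
    if occurrences is None:
        occurrences = scan_regions(regions, motifs.values())
    lengths = {r.gene_id: r.length for r in regions}
    max_length = max(lengths.values())
    frequencies = base_frequencies(background_regions or regions)

    occ_by_motif: dict[str, list[MotifOccurrence]] = defaultdict(list)
    for occ in occurrences:
        occ_by_motif[occ.motif].append(occ)

    sig: dict[str, float] = {}
    for name, motif in motifs.items():
        p0 = motif_match_probability(motif, frequencies)
        sig[name] = gene_set_sig(
            regions, occ_by_motif.get(name, []), motif, p0
        )

    results: list[ModuleAttributes] = []
    for pair_index, (name_a, name_b) in enumerate(pairs):
        motif_a, motif_b = motifs[name_a], motifs[name_b]
        occs_a = occ_by_motif.get(name_a, [])
        occs_b = occ_by_motif.get(name_b, [])
        modules = pair_occurrences(occs_a, occs_b, max_gap, lengths)
        if not modules:
            log.info("no modules found for pair %s,%s", name_a, name_b)
            continue
        null_modules = sample_null_modules(
            lengths,
            occurrence_counts_per_gene(occs_a),
            occurrence_counts_per_gene(occs_b),
            motif_a,
            motif_b,
            max_gap,
            replicates,
            np.random.SeedSequence([int(seed), pair_index]),
        )
        null_by_label = modules_by_label(null_modules)
        pooled_null_gaps = [m.gap for m in null_modules]
        for label, label_modules in sorted(
            modules_by_label(modules).items()
        ):
            gaps = [m.gap for m in label_modules]
            null_gaps = [
                m.gap for m in null_by_label.get(label, [])
            ] or pooled_null_gaps
            abc = abc_score(gaps, null_gaps, d_max) if null_gaps else 0.0
            positions = [m.module_midpoint_distance for m in label_modules]
            f_same = sum(m.same_strand for m in label_modules) / len(
                label_modules
            )
            first_name = label_modules[0].first.motif
            second_name = label_modules[0].second.motif
            attrs = ModuleAttributes(
                order=label,
                sig_first=sig[first_name],
                sig_second=sig[second_name],
                abc=abc,
                position_score=position_score(positions, max_length),
                coverage=module_coverage(
                    len({m.gene_id for m in label_modules}), len(regions)
                ),
                orientation_f_same=f_same,
                n_occurrences=len(label_modules),
                median_gap=float(np.median(gaps)),
                median_upstream_position=-float(np.median(positions)),
                gene_set=gene_set,
            )
            attrs.module_score = combine_module_score(attrs, weights, sig_ref)
            results.append(attrs)
    return results
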