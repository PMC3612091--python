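"""End-to-end pipeline: scan -> modules -> score -> quartiles -> aggregate."""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Mapping

import yaml

from . import io
from .analyses import aggregate_group_attributes, quartile_fractions
from .discovery import pair_occurrences
from .manifest import build_manifest, write_manifest
from .model import ScoreWeights
from .scan import scan_regions
from .stats import score_gene_set

log = logging.getLogger(__name__)

REQUIRED_KEYS = ("fasta", "motifs", "pairs", "weights", "seed")


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    config = dict(config)
    config.setdefault("_base_dir", Path(path).parent)
    return config


def _resolve(config: Mapping, key: str) -> Path:
    path = Path(config[key])
    base = Path(config.get("_base_dir", "."))
    return path if path.is_absolute() else base / path


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> Path:
    """Run all stages on one gene set; fail fast on the first error.

    Config keys: ``fasta``, ``motifs`` (path or inline mapping), ``pairs``
    (list of ``[A, B]`` or ``"A,B"``), ``weights`` (inline mapping or path),
    ``seed``; optional ``max_gap``, ``replicates``, ``expected_length``,
    ``background_fasta``, ``sig_ref``, ``gene_set``, ``groups`` (gene-set
    label -> group name).
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    for key in REQUIRED_KEYS:
        if key not in config:
            raise ValueError(f"missing key: {key}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    seed = int(config["seed"])
    max_gap = int(config.get("max_gap", 200))
    replicates = int(config.get("replicates", 1000))
    sig_ref = float(config.get("sig_ref", 240.0))
    gene_set = str(config.get("gene_set", "set"))
    expected_length = config.get("expected_length")
    if expected_length is not None:
        expected_length = int(expected_length)

    input_paths = []

    fasta_path = _resolve(config, "fasta")
    input_paths.append(fasta_path)
    regions = io.read_upstream_fasta(fasta_path, expected_length)
    log.info("stage read_fasta: %d regions", len(regions))

    if isinstance(config["motifs"], Mapping):
        motifs = io.load_motif_definitions(config["motifs"])
    else:
        motif_path = _resolve(config, "motifs")
        input_paths.append(motif_path)
        motifs = io.load_motif_definitions(motif_path)

    if isinstance(config["weights"], Mapping):
        weights = ScoreWeights.from_mapping(config["weights"])
    else:
        weight_path = _resolve(config, "weights")
        input_paths.append(weight_path)
        with open(weight_path) as handle:
            weights = ScoreWeights.from_mapping(yaml.safe_load(handle))

    background = None
    if config.get("background_fasta"):
        background_path = _resolve(config, "background_fasta")
        input_paths.append(background_path)
        background = io.read_upstream_fasta(background_path)

    pairs = []
    for pair in config["pairs"]:
        if isinstance(pair, str):
            pair = pair.split(",")
        if len(pair) != 2:
            raise ValueError(f"pair must name two motifs, got {pair!r}")
        for name in pair:
            if name not in motifs:
                raise ValueError(f"pair references unknown motif {name!r}")
        pairs.append((pair[0], pair[1]))

    tic = time.perf_counter()
    occurrences = scan_regions(regions, motifs.values())
    io.write_occurrences(occurrences, out_dir / "occ.tsv")
    log.info(
        "stage scan: %d occurrences (%.2fs)",
        len(occurrences), time.perf_counter() - tic,
    )

    lengths = {r.gene_id: r.length for r in regions}
    occ_by_motif: dict[str, list] = {}
    for occ in occurrences:
        occ_by_motif.setdefault(occ.motif, []).append(occ)
    tic = time.perf_counter()
    modules = []
    for name_a, name_b in pairs:
        modules.extend(pair_occurrences(
            occ_by_motif.get(name_a, []),
            occ_by_motif.get(name_b, []),
            max_gap,
            lengths,
        ))
    io.write_modules(modules, out_dir / "modules.tsv")
    log.info(
        "stage modules: %d modules (%.2fs)",
        len(modules), time.perf_counter() - tic,
    )

    tic = time.perf_counter()
    attributes = score_gene_set(
        regions, motifs, pairs,
        occurrences=occurrences,
        background_regions=background,
        max_gap=max_gap,
        replicates=replicates,
        seed=seed,
        weights=weights,
        sig_ref=sig_ref,
        gene_set=gene_set,
    )
    io.write_attributes(attributes, out_dir / "attrs.tsv")
    log.info(
        "stage score: %d attribute rows (%.2fs)",
        len(attributes), time.perf_counter() - tic,
    )

    length = max(lengths.values())
    n_bins = int(config.get("n_bins", 4))
    bin_width = length // n_bins
    with open(out_dir / "q.tsv", "w") as handle:
        handle.write("motif\t" + "\t".join(
            f"q{i * bin_width}_{(i + 1) * bin_width}" for i in range(n_bins)
        ) + "\n")
        rows = [("all", occurrences)] + sorted(occ_by_motif.items())
        for label, occs in rows:
            if not occs:
                continue
            fractions = quartile_fractions(occs, length, n_bins)
            handle.write(label + "\t" + "\t".join(
                f"{f:.6f}" for f in fractions
            ) + "\n")
    log.info("stage quartiles: done")

    grouping = dict(config.get("groups") or {gene_set: "all"})
    summaries = aggregate_group_attributes(
        [(a.gene_set, a) for a in attributes], grouping
    )
    with open(out_dir / "aggregate.tsv", "w") as handle:
        from .model import ModuleAttributes
        numeric = list(ModuleAttributes.NUMERIC_FIELDS)
        header = ["group", "order", "n_members"] + [
            f"mean_{f}" for f in numeric
        ] + ["abc_display", "upstream_display"]
        handle.write("\t".join(header) + "\n")
        for summary in summaries:
            row = [summary.group, summary.order, str(summary.n_members)]
            row += [repr(summary.means[f]) for f in numeric]
            row += [repr(summary.abc_display), repr(summary.upstream_display)]
            handle.write("\t".join(row) + "\n")
    log.info("stage aggregate: %d group rows", len(summaries))

    parameters = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in config.items() if not k.startswith("_")
    }
    parameters.setdefault("max_gap", max_gap)
    parameters.setdefault("replicates", replicates)
    parameters.setdefault("sig_ref", sig_ref)
    parameters.setdefault("n_bins", n_bins)
    manifest = build_manifest("run", parameters, seed, input_paths)
    write_manifest(manifest, out_dir)
    return out_dir
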