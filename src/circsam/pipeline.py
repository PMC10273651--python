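"""End-to-end orchestration: consensus -> annotate -> flanking -> diffexp ->
sponge -> enrich, from a single config mapping, with a reproducibility
manifest (config hash, seed, per-stage row counts)."""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_catalog, annotations_to_frame, summarize_catalog
from .consensus import (
    catalog_from_frame,
    catalog_to_frame,
    filter_supported,
    merge_tools_and_conditions,
    read_calls,
)
from .diffexp import (
    consecutive_pairs,
    de_probability,
    de_results_to_frame,
    expression_pattern_sets,
    read_design,
    tmm_factors,
)
from .enrichment import fisher_enrichment, read_go_map
from .flanking import (
    ScoringScheme,
    catalog_exon_count_distribution,
    run_flanking_comparison,
    sample_control_exons,
)
from .genome import read_annotation, read_fasta_dict, read_genome
from .sponge import MiRNA, build_cerna_network, circular_sequence, scan_transcript

DEFAULT_PARAMS: dict = {
    "min_reads": 2,
    "min_replicates": 3,
    "pooled_reads": False,
    "slack": 0,
    "controls_n": 150,
    "seed": 0,
    "bins": [0, 500, 1000, 2000, 5000],
    "window_width": 2000,
    "include_windows": True,
    "q_threshold": 0.8,
    "k_pseudo": 0.5,
    "cutoff": 4.0,
    "go_alpha": 0.05,
    "rcm_min_score": 16,
}

INPUT_KEYS = (
    "genome", "annotation", "calls", "counts", "design",
    "mirnas", "transcripts", "go_map", "go_terms",
)


class PipelineError(RuntimeError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return normalize_config(cfg)


def normalize_config(cfg: dict) -> dict:
    out = {"inputs": dict(cfg.get("inputs", {})), "params": dict(DEFAULT_PARAMS)}
    out["params"].update(cfg.get("params", {}))
    out["outdir"] = cfg.get("outdir", "circsam_out")
    return out


def config_hash(cfg: dict) -> str:
    # outdir is excluded: the same analysis in two directories is one run
    canon = yaml.safe_dump(
        {"inputs": cfg.get("inputs", {}), "params": cfg.get("params", {})},
        sort_keys=True,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, default=str) + "\n")


def _venn_jsonable(venn: dict) -> dict:
    return {"+".join(sorted(k)): v for k, v in venn.items()}


def run_pipeline(cfg: dict) -> Path:
    """Execute every stage; returns the report directory.

    Missing inputs abort before any stage runs; a stage failure raises a
    stage-named :class:`PipelineError` and leaves completed outputs behind.
    """
    cfg = normalize_config(cfg)
    inputs = cfg["inputs"]
    params = cfg["params"]
    outdir = Path(cfg["outdir"])

    missing = [k for k in INPUT_KEYS if k not in inputs or not Path(inputs[k]).exists()]
    if missing:
        raise PipelineError(f"missing inputs before any stage ran: {missing}")
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "tool": "circsam",
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": params["seed"],
        "stages": {},
    }
    state: dict = {}
    stages = [
        ("consensus", _stage_consensus),
        ("annotate", _stage_annotate),
        ("flanking", _stage_flanking),
        ("diffexp", _stage_diffexp),
        ("sponge", _stage_sponge),
        ("enrich", _stage_enrich),
    ]
    for name, fn in stages:
        try:
            counts = fn(inputs, params, outdir, state)
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = counts
    _json_dump(manifest, outdir / "manifest.json")
    return outdir


# ---------------------------------------------------------------------------
# stages (shared by `circsam run` and the per-stage subcommands)


def _stage_consensus(inputs, params, outdir: Path, state: dict) -> dict:
    calls = read_calls(inputs["calls"])
    design_df = read_design(inputs["design"])
    design = {
        c: set(sub["replicate"]) for c, sub in design_df.groupby("condition")
    }
    supported = filter_supported(
        calls,
        design,
        min_replicates=params["min_replicates"],
        min_reads=params["min_reads"],
        pooled_reads=params["pooled_reads"],
    )
    catalog, venn = merge_tools_and_conditions(supported)
    catalog_to_frame(catalog).to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    _json_dump(_venn_jsonable(venn), outdir / "venn.json")
    state["catalog"] = catalog
    state["design_df"] = design_df
    return {"calls": len(calls), "catalog": len(catalog)}


def _stage_annotate(inputs, params, outdir: Path, state: dict) -> dict:
    genome = read_genome(inputs["genome"])
    genes = read_annotation(inputs["annotation"])
    annotations = annotate_catalog(state["catalog"], genes, slack=params["slack"])
    annotations_to_frame(annotations).to_csv(
        outdir / "annotation.tsv", sep="\t", index=False
    )
    summary = summarize_catalog(annotations)
    _json_dump(summary, outdir / "summary.json")
    state.update(genome=genome, genes=genes, annotations=annotations)
    return {"annotated": len(annotations)}


def _stage_flanking(inputs, params, outdir: Path, state: dict) -> dict:
    genes = state["genes"]
    genes_by_id = {g.gene_id: g for g in genes}
    exonic = [
        a for a in state["annotations"]
        if a.category == "exonic" and len(a.parent_genes) == 1 and a.exon_indices
    ]
    circ_items = [(genes_by_id[a.parent_genes[0]], a.exon_indices) for a in exonic]
    excluded = {g for a in state["annotations"] for g in a.parent_genes}
    dist = catalog_exon_count_distribution([a.exon_count for a in exonic])
    controls = sample_control_exons(
        genes, excluded, dist, n_controls=params["controls_n"], seed=params["seed"]
    )
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in controls],
            "exon_indices": [",".join(map(str, c.exon_indices)) for c in controls],
            "chrom": [c.locus.chromosome for c in controls],
            "start": [c.locus.start + 1 for c in controls],
            "end": [c.locus.end for c in controls],
            "exon_count": [c.exon_count for c in controls],
        }
    ).to_csv(outdir / "controls.tsv", sep="\t", index=False)
    scheme = ScoringScheme(min_score=params["rcm_min_score"])
    bins = tuple(params["bins"]) + (math.inf,)
    report = run_flanking_comparison(
        circ_items,
        controls,
        state["genome"],
        genes_by_id,
        scheme=scheme,
        bins=bins,
        window_width=params["window_width"],
        include_windows=params["include_windows"],
    )
    _json_dump(report, outdir / "flanking.json")
    state["flanking_report"] = report
    return {"circ_items": len(circ_items), "controls": len(controls)}


def _stage_diffexp(inputs, params, outdir: Path, state: dict) -> dict:
    counts = pd.read_csv(inputs["counts"], sep="\t", index_col=0)
    design_df = state.get("design_df")
    if design_df is None:
        design_df = read_design(inputs["design"])
    factors = tmm_factors(counts)
    results_by_pair = {}
    for pair in consecutive_pairs(design_df):
        res = de_probability(
            counts,
            design_df,
            pair,
            k_pseudo=params["k_pseudo"],
            q_threshold=params["q_threshold"],
            factors=factors,
        )
        name = f"{pair[0]}:{pair[1]}"
        results_by_pair[name] = res
        de_results_to_frame(res).to_csv(
            outdir / f"de_{pair[0]}_{pair[1]}.tsv", sep="\t", index=False
        )
    sets = expression_pattern_sets(results_by_pair)
    sets_json = dict(sets)
    sets_json["venn"] = {"+".join(sorted(k)): v for k, v in sets["venn"].items()}
    _json_dump(sets_json, outdir / "expression_sets.json")
    state["de_results"] = results_by_pair
    state["de_called"] = sorted(
        {r.circ_id for res in results_by_pair.values() for r in res if r.called}
    )
    return {"comparisons": len(results_by_pair), "called": len(state["de_called"])}


def _stage_sponge(inputs, params, outdir: Path, state: dict) -> dict:
    mirnas = [MiRNA(k, v) for k, v in read_fasta_dict(inputs["mirnas"]).items()]
    transcripts = read_fasta_dict(inputs["transcripts"])
    genes_by_id = {g.gene_id: g for g in state["genes"]}
    called = set(state["de_called"])
    circ_sites = []
    for a in state["annotations"]:
        if a.circ_id not in called or a.category != "exonic":
            continue
        if len(a.parent_genes) != 1 or not a.exon_indices:
            continue
        seq = circular_sequence(
            a.exon_indices, genes_by_id[a.parent_genes[0]], state["genome"]
        )
        circ_sites.extend(
            scan_transcript(mirnas, a.circ_id, seq, circular=True, cutoff=params["cutoff"])
        )
    bound = {s.mirna for s in circ_sites}
    mrna_sites = []
    scan_mirnas = [m for m in mirnas if m.name in bound]
    if scan_mirnas:
        for tid, seq in sorted(transcripts.items()):
            mrna_sites.extend(
                scan_transcript(scan_mirnas, tid, seq, circular=False, cutoff=params["cutoff"])
            )
    for name, sites in (("sites_circ", circ_sites), ("sites_mrna", mrna_sites)):
        pd.DataFrame(
            {
                "transcript_id": [s.transcript_id for s in sites],
                "mirna": [s.mirna for s in sites],
                "start": [s.start for s in sites],
                "window_length": [s.window_length for s in sites],
                "penalty": [s.penalty_score for s in sites],
                "pairing": [s.pairing for s in sites],
                "spans_junction": [s.spans_junction for s in sites],
            }
        ).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    network = build_cerna_network(circ_sites, mrna_sites)
    network["edges"].to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    _json_dump(
        {k: v for k, v in network.items() if k != "edges"},
        outdir / "network_summary.json",
    )
    state["network"] = network
    return {
        "circ_sites": len(circ_sites),
        "mrna_sites": len(mrna_sites),
        "edges": len(network["edges"]),
    }


def _stage_enrich(inputs, params, outdir: Path, state: dict) -> dict:
    go = read_go_map(inputs["go_map"], inputs["go_terms"])
    universe = {g.gene_id for g in state["genes"]}
    called = set(state["de_called"])
    parents = {
        g
        for a in state["annotations"]
        if a.circ_id in called
        for g in a.parent_genes
    } & universe
    edges = state["network"]["edges"]
    targets = set(edges.loc[edges["type"] == "miRNA-mRNA", "target"]) & universe
    n_rows = {}
    for label, study in (("parents", parents), ("targets", targets)):
        if study:
            df = fisher_enrichment(study, universe, go)
        else:
            df = pd.DataFrame(
                columns=["term_id", "name", "namespace", "k", "K", "n", "N", "p", "p_adjusted"]
            )
        df.to_csv(outdir / f"enrichment_{label}.tsv", sep="\t", index=False)
        state[f"enrichment_{label}"] = df
        n_rows[label] = len(df)
    return n_rows
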