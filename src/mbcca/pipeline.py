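"""End-to-end orchestration of the integration pipeline.

Stage order mirrors the analysis design: diversity statistics on the
taxa table -> differential features per data layer -> preprocessing
(taxon-specific scaling of the gene layer, log2 transform of the
amplicon layer, sparse-variable filtering) -> two sparse-CCA
integrations (taxa x host and microbial genes x host) -> per-group
Spearman association networks with clusters, centralities, hubs, and
aaRS-host-gene association extraction. Every artifact is written under
the output directory and listed in a reproducible run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import FeatureTable, GroupDesign, PipelineConfig, ValidationError
from .differential import (
    classify_deg_modules,
    differential_features,
    filter_sparse_variables,
    log2_transform,
    taxon_scale,
)
from .diversity import alpha_diversity_table, anosim, bray_curtis, pcoa
from .io import (
    export_network,
    read_feature_metadata,
    read_feature_table,
    read_go_annotation,
    read_sample_metadata,
    write_results_table,
)
from .network import (
    build_network,
    centrality_metrics,
    community_clusters,
    extract_gene_family_associations,
    identify_hubs,
    spearman_edges,
)
from .scca import (
    loocv_extract,
    penalty_grid,
    permutation_significance,
    scca_fit,
    tune_penalty,
)

log = logging.getLogger("mbcca")


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    input_hashes: dict[str, str]
    seed: int
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        log.info("stage %s", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.stage_seconds[self.name] = round(
            time.perf_counter() - self.t0, 3
        )
        if exc is not None:
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc


def _scca_stage(
    X: FeatureTable,
    Y: FeatureTable,
    config: PipelineConfig,
    seed: int,
    out_dir: Path,
    tag: str,
    manifest: RunManifest,
) -> dict:
    """One integration run: tune -> fit -> permutation test -> LOOCV."""
    n = X.n_samples
    k_cap = min(X.n_features, Y.n_features, n - 1)
    K = min(config.n_components or min(n - 1, 10), k_cap)
    grid = penalty_grid(config.grid_lo, config.grid_hi, config.grid_n)
    best, tuning = tune_penalty(X, Y, K, grid, seed=seed)
    fit = scca_fit(X, Y, K, best)
    sig = permutation_significance(
        X, Y, best, K=K, n_perm=config.n_permutations, seed=seed
    )
    for comp, row in zip(fit.components, sig.itertuples(index=False)):
        comp.raw_p = float(row.raw_p)
        comp.adjusted_p = float(row.adjusted_p)
    loocv_extract(X, Y, best, K=K, retention=config.loocv_retention)
    fit.tuning_table = tuning
    weights_path = out_dir / f"scca_{tag}_weights.tsv"
    write_results_table(fit.weights_frame(), weights_path)
    summary = {
        "penalty": best,
        "K": K,
        "correlations": [c.canonical_correlation for c in fit.components],
        "raw_p": [c.raw_p for c in fit.components],
        "adjusted_p": [c.adjusted_p for c in fit.components],
        "significant_components": [i + 1 for i in fit.significant(config.alpha)],
        "robust_x": {
            i + 1: c.robust_x for i, c in enumerate(fit.components)
        },
        "robust_y": {
            i + 1: c.robust_y for i, c in enumerate(fit.components)
        },
        "tuning_table": tuning.to_dict(orient="records"),
    }
    json_path = out_dir / f"scca_{tag}.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest.outputs += [str(weights_path), str(json_path)]
    return summary


def run_pipeline(
    config: PipelineConfig,
    input_dir,
    out_dir,
) -> RunManifest:
    """Run every stage on the tables found in ``input_dir``.

    Expects ``taxa.tsv``, ``host.tsv``, ``sample_metadata.tsv`` and
    optionally ``genes.tsv`` (+ ``gene_metadata.tsv``) and
    ``go_annotation.tsv`` — the layout ``mbcca simulate`` writes.
    """
    config.validate()
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        p.name: p
        for p in sorted(input_dir.glob("*.tsv"))
        if p.name != "truth.json"
    }
    for required in ("taxa.tsv", "host.tsv", "sample_metadata.tsv"):
        if required not in paths:
            raise ValidationError(f"missing input file {required}")
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        input_hashes={name: _sha256(p) for name, p in paths.items()},
        seed=config.seed,
    )
    rng = np.random.default_rng(config.seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, 8)]

    sample_meta = read_sample_metadata(paths["sample_metadata.tsv"])
    design = GroupDesign.from_sample_meta(sample_meta)
    groups = design.groups()
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    control, treated = groups[0], groups[1:]
    taxa = read_feature_table(paths["taxa.tsv"], sample_meta=sample_meta)
    host = read_feature_table(
        paths["host.tsv"], value_kind="normalized", sample_meta=sample_meta
    )
    genes = None
    if "genes.tsv" in paths:
        gene_meta = (
            read_feature_metadata(paths["gene_metadata.tsv"])
            if "gene_metadata.tsv" in paths
            else None
        )
        genes = read_feature_table(
            paths["genes.tsv"], value_kind="rpk",
            sample_meta=sample_meta, feature_meta=gene_meta,
        )
    go_annotation = None
    if (input_dir / "go_annotation.tsv").exists():
        go_annotation = read_go_annotation(input_dir / "go_annotation.tsv")

    with _Stage(manifest, "diversity"):
        alpha = alpha_diversity_table(taxa)
        alpha.index.name = "sample_id"
        alpha.reset_index().to_csv(out_dir / "alpha_diversity.tsv",
                                   sep="\t", index=False)
        dist = bray_curtis(taxa)
        dist.to_frame().to_csv(out_dir / "bray_curtis.tsv", sep="\t")
        ord_res = pcoa(dist, k=min(3, taxa.n_samples - 1))
        ord_res.to_frame().to_csv(out_dir / "pcoa.tsv", sep="\t")
        ano = anosim(dist, design, config.n_permutations, seeds[0])
        with open(out_dir / "anosim.json", "w") as fh:
            json.dump(
                {"R": ano.r, "p": ano.p_value, "n_permutations": ano.n_permutations},
                fh, indent=2,
            )
        manifest.outputs += [
            str(out_dir / f) for f in
            ("alpha_diversity.tsv", "bray_curtis.tsv", "pcoa.tsv", "anosim.json")
        ]

    diff_taxa: dict[str, object] = {}
    diff_host: dict[str, object] = {}
    with _Stage(manifest, "differential"):
        for g in treated:
            res = differential_features(taxa, design, control, g, config.alpha)
            diff_taxa[g] = res
            path = out_dir / f"diff_taxa_{g}.tsv"
            write_results_table(res, path)
            manifest.outputs.append(str(path))
            res_h = differential_features(host, design, control, g, config.alpha)
            diff_host[g] = res_h
            path = out_dir / f"diff_host_{g}.tsv"
            write_results_table(res_h, path)
            manifest.outputs.append(str(path))
        genes_scaled = None
        diff_genes = None
        if genes is not None:
            genes_scaled = taxon_scale(genes, config.taxon_scale_constant)
            diff_genes = differential_features(
                genes_scaled, design, control, treated[0], config.alpha
            )
            path = out_dir / "diff_genes.tsv"
            write_results_table(diff_genes, path)
            manifest.outputs.append(str(path))

    with _Stage(manifest, "modules"):
        if len(treated) >= 2:
            day3, day6 = treated[0], treated[1]
            modules = classify_deg_modules(
                diff_host[day3].up_ids(), diff_host[day6].up_ids(),
                diff_host[day3].down_ids(), diff_host[day6].down_ids(),
            )
            path = out_dir / "host_modules.tsv"
            write_results_table(modules, path)
            manifest.outputs.append(str(path))

    def significant_union(results: dict) -> list[str]:
        ids: set[str] = set()
        for res in results.values():
            ids.update(res.significant_ids())
        return sorted(ids)

    sig_taxa = significant_union(diff_taxa)
    sig_host = significant_union(diff_host)

    def restrict(table: FeatureTable, ids: list[str], label: str) -> FeatureTable:
        if len(ids) >= 3:
            return table.subset_features(ids)
        log.warning(
            "only %d significant %s features; using the full table",
            len(ids), label,
        )
        return table

    with _Stage(manifest, "scca_taxa_host"):
        taxa_sel = restrict(taxa, sig_taxa, "taxa")
        # amplicon layer: sparse filter then log2 transform
        taxa_prep = log2_transform(
            filter_sparse_variables(taxa_sel), config.pseudocount
        )
        host_prep = filter_sparse_variables(
            restrict(host, sig_host, "host")
        )
        scca_taxa = _scca_stage(
            host_prep, taxa_prep, config, seeds[1], out_dir, "taxa", manifest
        )

    scca_genes = None
    if genes_scaled is not None:
        with _Stage(manifest, "scca_genes_host"):
            sig_genes = diff_genes.significant_ids()
            genes_prep = filter_sparse_variables(
                restrict(genes_scaled, sig_genes, "gene")
            )
            scca_genes = _scca_stage(
                host_prep, genes_prep, config, seeds[2], out_dir, "genes",
                manifest,
            )

    network_summaries = {}
    with _Stage(manifest, "networks"):
        # combined differential feature table per group
        blocks = [host.data[[f for f in sig_host if f in host.data]]]
        layers = {f: "host_gene" for f in blocks[0].columns}
        blocks.append(taxa.data[[f for f in sig_taxa if f in taxa.data]])
        layers.update({f: "microbial_taxon" for f in blocks[-1].columns})
        if genes_scaled is not None:
            sig_g = [
                f for f in diff_genes.significant_ids()
                if f in genes_scaled.data
            ]
            blocks.append(genes_scaled.data[sig_g])
            layers.update({f: "microbial_gene" for f in sig_g})
        combined = pd.concat(blocks, axis=1)
        node_meta = pd.DataFrame(
            {"layer": pd.Series(layers)}, index=list(layers)
        )
        if genes is not None and genes.feature_meta is not None:
            node_meta = node_meta.join(
                genes.feature_meta[["taxon", "is_aaRS"]], how="left"
            )
            node_meta["is_aaRS"] = node_meta["is_aaRS"].eq(True)
        control_net = None
        for g in groups:
            ids = [s for s in combined.index if design.group_of(s) == g]
            if len(ids) < 4:
                log.warning("group %s has <4 samples; skipping network", g)
                continue
            sub = FeatureTable(
                combined.loc[ids], "normalized", feature_meta=None
            )
            try:
                edges = spearman_edges(
                    sub, config.p_max, config.rho_min, config.rho_mode
                )
            except ValidationError as exc:
                log.warning("group %s network skipped: %s", g, exc)
                continue
            net = build_network(edges, node_meta)
            if g == control:
                control_net = net
            summary = dict(net.properties)
            if net.n_edges >= 1:
                clusters, modularity = community_clusters(net, seeds[3])
                summary["n_clusters"] = len(set(clusters.values()))
                summary["modularity"] = modularity
            else:
                clusters, modularity = {}, float("nan")
                summary["n_clusters"] = 0
                summary["modularity"] = None
            records = centrality_metrics(net)
            if not records.empty:
                hubs = identify_hubs(
                    records, config.hub_quantile, config.hub_min_degree,
                    clusters,
                )
                path = out_dir / f"hubs_{g}.tsv"
                write_results_table(hubs, path)
                manifest.outputs.append(str(path))
                summary["n_hubs"] = len(hubs.hub_ids())
            gpath = out_dir / f"network_{g}.graphml"
            export_network(net, gpath, "graphml")
            manifest.outputs.append(str(gpath))
            network_summaries[g] = summary
        with open(out_dir / "network_summary.json", "w") as fh:
            json.dump(network_summaries, fh, indent=2)
        manifest.outputs.append(str(out_dir / "network_summary.json"))

    with _Stage(manifest, "aars_associations"):
        if control_net is not None and go_annotation is not None:
            assoc = extract_gene_family_associations(
                control_net, go_annotation,
                max_term_size=config.max_go_term_size,
            )
            path = out_dir / "aars_associations.tsv"
            write_results_table(assoc, path)
            manifest.outputs.append(str(path))

    manifest.to_json(out_dir / "manifest.json")
    manifest.outputs.append(str(out_dir / "manifest.json"))
    return manifest
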