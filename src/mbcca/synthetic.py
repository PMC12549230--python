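"""Synthetic multi-omics data with known ground truth.

Three generators emulate the statistical structure the analysis assumes:

* :func:`simulate_paired_omics` — two feature tables sharing K sparse
  latent canonical components (the structure sparse CCA estimates);
* :func:`simulate_count_table` — grouped count tables with planted
  log2 fold-changes (the structure the Wilcoxon/BH differential tests
  detect), drawn from a log-normal -> Poisson hierarchy;
* :func:`simulate_deg_sets` — up/down regulated gene-id sets covering the
  two-comparison Venn partition that the six-module classifier consumes.

All generators are pure functions of their arguments including ``seed``.
:func:`simulate_study` composes them into a coherent three-group study
(taxa counts, per-organism gene table with aaRS flags, host expression,
GO annotation) for end-to-end runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import FeatureTable, GroupDesign, ValidationError


@dataclass
class PairedOmicsTruth:
    """Planted structure behind a paired-omics simulation."""

    loadings_x: np.ndarray  # (p_x, K), unit-norm sparse columns
    loadings_y: np.ndarray  # (p_y, K)
    latent_scores: np.ndarray  # (n, K)
    planted_correlations: np.ndarray  # (K,)
    noise_sd: float
    seed: int

    def support_x(self, k: int) -> set[str]:
        return {f"x{j:04d}" for j in np.flatnonzero(self.loadings_x[:, k])}

    def support_y(self, k: int) -> set[str]:
        return {f"y{j:04d}" for j in np.flatnonzero(self.loadings_y[:, k])}


@dataclass
class CountTruth:
    """Planted differential features behind a count-table simulation."""

    diff_feature_ids: list[str]
    log2_fold_change: pd.Series  # signed, 0 for non-differential features
    baseline_log_mean: float
    baseline_log_sd: float
    dispersion: float
    seed: int


def simulate_paired_omics(
    n: int,
    p_x: int,
    p_y: int,
    K: int,
    nonzeros_per_component: int,
    correlation_strengths: Sequence[float],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable, PairedOmicsTruth]:
    """Simulate two matrices sharing K sparse latent canonical components.

    Model: shared latent scores Z ~ N(0, I) with
    ``X = Z diag(s) A^T + E_x`` and ``Y = Z diag(s) B^T + E_y`` where the
    loading columns of A, B have exactly ``nonzeros_per_component``
    entries of equal magnitude and random sign (unit L2 norm), and the
    noise is i.i.d. Gaussian with sd ``noise_sd``. The signal amplitude
    ``s_k = noise_sd * sqrt(r_k / (1 - r_k))`` is chosen so that the
    population correlation of the true projections, corr(X a_k, Y b_k),
    equals the requested strength r_k. With ``noise_sd = 0`` the
    projections are perfectly correlated and s_k = 1.

    Because downstream correlation analyses are invariant to per-feature
    shifts, each feature column is shifted to be non-negative so the
    result is a valid :class:`FeatureTable`.
    """
    if n < 4:
        raise ValidationError("need n >= 4 samples")
    if K > min(p_x, p_y):
        raise ValidationError(f"K={K} exceeds min(p_x, p_y)={min(p_x, p_y)}")
    if nonzeros_per_component < 1:
        raise ValidationError("nonzeros_per_component must be >= 1")
    if nonzeros_per_component > min(p_x, p_y):
        raise ValidationError("nonzeros_per_component exceeds feature count")
    strengths = np.asarray(correlation_strengths, dtype=float)
    if strengths.shape != (K,):
        raise ValidationError(f"need exactly K={K} correlation strengths")
    if ((strengths <= 0) | (strengths > 1)).any():
        raise ValidationError("correlation strengths must lie in (0, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if noise_sd > 0 and (strengths >= 1).any():
        raise ValidationError("strength 1 requires noise_sd = 0")

    rng = np.random.default_rng(seed)

    def sparse_loadings(p: int) -> np.ndarray:
        A = np.zeros((p, K))
        mag = 1.0 / np.sqrt(nonzeros_per_component)
        for k in range(K):
            support = rng.choice(p, nonzeros_per_component, replace=False)
            signs = rng.choice([-1.0, 1.0], nonzeros_per_component)
            A[support, k] = signs * mag
        return A

    A = sparse_loadings(p_x)
    B = sparse_loadings(p_y)
    Z = rng.standard_normal((n, K))
    if noise_sd > 0:
        amp = noise_sd * np.sqrt(strengths / (1.0 - strengths))
    else:
        amp = np.ones(K)
    X = Z @ (A * amp).T + noise_sd * rng.standard_normal((n, p_x))
    Y = Z @ (B * amp).T + noise_sd * rng.standard_normal((n, p_y))
    # shift columns to be non-negative (harmless to correlation structure)
    X = X - np.minimum(X.min(axis=0), 0.0)
    Y = Y - np.minimum(Y.min(axis=0), 0.0)

    samples = [f"s{i:04d}" for i in range(n)]
    tx = FeatureTable(
        pd.DataFrame(X, index=samples, columns=[f"x{j:04d}" for j in range(p_x)]),
        value_kind="normalized",
    )
    ty = FeatureTable(
        pd.DataFrame(Y, index=samples, columns=[f"y{j:04d}" for j in range(p_y)]),
        value_kind="normalized",
    )
    truth = PairedOmicsTruth(A, B, Z, strengths, noise_sd, seed)
    return tx, ty, truth


def simulate_count_table(
    n_per_group: Mapping[str, int],
    n_features: int,
    n_diff: int,
    log2_effect: float,
    dispersion: float = 0.5,
    baseline_log_mean: float = 3.0,
    baseline_log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[FeatureTable, GroupDesign, CountTruth]:
    """Simulate a grouped count table with planted fold-changes.

    Counts follow a log-normal -> Poisson hierarchy: each feature gets a
    log-normal baseline mean, each (sample, feature) mean is jittered by
    log-normal dispersion noise, and the first listed group is the
    reference — planted features have their means in every non-reference
    group multiplied by ``2**(±log2_effect)`` (random sign per feature).
    """
    if n_diff > n_features:
        raise ValidationError("n_diff cannot exceed n_features")
    if not np.isfinite(log2_effect):
        raise ValidationError("log2_effect must be finite")
    groups = list(n_per_group)
    if len(groups) < 1:
        raise ValidationError("need at least one group")
    for g, n in n_per_group.items():
        if n < 2:
            raise ValidationError(f"group {g!r} has {n} samples; need >= 2")

    rng = np.random.default_rng(seed)
    features = [f"f{j:04d}" for j in range(n_features)]
    base = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, n_features))
    diff_idx = np.sort(rng.choice(n_features, n_diff, replace=False))
    signs = rng.choice([-1.0, 1.0], n_diff)
    lfc = np.zeros(n_features)
    lfc[diff_idx] = signs * log2_effect

    rows, sample_ids, labels = [], [], []
    for g in groups:
        effect = np.ones(n_features)
        if g != groups[0]:
            effect = 2.0 ** lfc
        for i in range(n_per_group[g]):
            mean = base * effect * np.exp(rng.normal(0.0, dispersion, n_features))
            rows.append(rng.poisson(mean))
            sample_ids.append(f"{g}_{i:02d}")
            labels.append(g)

    data = pd.DataFrame(
        np.asarray(rows, dtype=float), index=sample_ids, columns=features
    )
    meta = pd.DataFrame({"group": labels}, index=sample_ids)
    table = FeatureTable(data, "count", sample_meta=meta)
    design = GroupDesign(dict(zip(sample_ids, labels)))
    truth = CountTruth(
        [features[j] for j in diff_idx],
        pd.Series(lfc, index=features),
        baseline_log_mean,
        baseline_log_sd,
        dispersion,
        seed,
    )
    return table, design, truth


DEG_REGIONS = (
    "up_day3_only",
    "up_both",
    "up_day6_only",
    "down_day3_only",
    "down_both",
    "down_day6_only",
    "discordant",
)


def simulate_deg_sets(
    region_counts: Mapping[str, int], seed: int = 0
) -> tuple[set[str], set[str], set[str], set[str]]:
    """Emit disjoint synthetic gene ids populating the requested Venn regions.

    The six concordant regions are the up/down x day3-only/both/day6-only
    cells; ``discordant`` genes are up on day 3 and down on day 6.
    Returns ``(up_day3, up_day6, down_day3, down_day6)``.
    """
    unknown = set(region_counts) - set(DEG_REGIONS)
    if unknown:
        raise ValidationError(f"unknown Venn regions: {sorted(unknown)}")
    if any(c < 0 for c in region_counts.values()):
        raise ValidationError("region counts must be >= 0")
    rng = np.random.default_rng(seed)
    counts = {r: int(region_counts.get(r, 0)) for r in DEG_REGIONS}
    total = sum(counts.values())
    ids = [f"gene{j:05d}" for j in rng.permutation(max(total, 1))[:total]]

    up3, up6, down3, down6 = set(), set(), set(), set()
    cursor = 0
    membership = {
        "up_day3_only": (up3,),
        "up_both": (up3, up6),
        "up_day6_only": (up6,),
        "down_day3_only": (down3,),
        "down_both": (down3, down6),
        "down_day6_only": (down6,),
        "discordant": (up3, down6),
    }
    for region in DEG_REGIONS:
        for _ in range(counts[region]):
            gid = ids[cursor]
            cursor += 1
            for target in membership[region]:
                target.add(gid)
    return up3, up6, down3, down6


@dataclass
class StudyTruth:
    """Ground truth of a composed synthetic study."""

    taxa_truth: CountTruth
    gene_truth: CountTruth
    host_deg_sets: tuple[set[str], set[str], set[str], set[str]]
    coupled_taxa: list[str]
    coupled_host_genes: list[str]
    seed: int


def simulate_study(
    n_per_group: Mapping[str, int] | None = None,
    n_taxa: int = 60,
    n_diff_taxa: int = 20,
    n_host_genes: int = 120,
    n_organisms: int = 6,
    genes_per_organism: int = 10,
    n_diff_genes: int = 18,
    log2_effect: float = 4.0,
    coupling_strength: float = 1.5,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Compose a coherent three-group synthetic study.

    Emulates the study layout: a taxa count table and a per-organism gene
    table (``EC|taxon`` composite ids, some genes flagged as aaRS) with
    planted group effects, a host expression table whose DEG sets cover
    all six expression modules, a latent factor coupling a subset of
    differential taxa to a subset of host DEGs (so the sparse CCA stage
    has real structure to find), and a GO annotation table including one
    oversized term that the aaRS association extractor must drop.

    When ``out_dir`` is given, all tables plus a truth JSON are written
    there as TSV.
    """
    if n_per_group is None:
        n_per_group = {"control": 5, "dss3": 5, "dss6": 5}
    groups = list(n_per_group)
    if len(groups) != 3:
        raise ValidationError("simulate_study expects exactly three groups")
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, 8)]

    taxa, design, taxa_truth = simulate_count_table(
        n_per_group, n_taxa, n_diff_taxa, log2_effect,
        baseline_log_mean=3.5, seed=sub[0],
    )

    # per-organism gene table: composite "EC|taxon" ids, aaRS flags
    organisms = [f"s__Org_{chr(65 + i)}" for i in range(n_organisms)]
    gene_ids, is_aars = [], []
    for oi, org in enumerate(organisms):
        for gi in range(genes_per_organism):
            ec = f"EC_{oi + 1}.{gi + 1}.1.1"
            gene_ids.append(f"{ec}|{org}")
            is_aars.append(gi < 3)  # first three genes per organism are aaRS
    n_genes = len(gene_ids)
    genes_raw, _, gene_truth = simulate_count_table(
        n_per_group, n_genes, n_diff_genes, log2_effect, seed=sub[1]
    )
    gene_data = genes_raw.data.copy()
    gene_data.columns = gene_ids
    gene_truth.log2_fold_change.index = gene_ids
    gene_truth.diff_feature_ids = [
        gene_ids[int(f[1:])] for f in gene_truth.diff_feature_ids
    ]
    gene_meta = pd.DataFrame(
        {
            "taxon": [split_gene_id(g)[1] for g in gene_ids],
            "gene_family": [split_gene_id(g)[0] for g in gene_ids],
            "is_aaRS": is_aars,
        },
        index=gene_ids,
    )
    genes = FeatureTable(gene_data, "rpk", taxa.sample_meta, gene_meta)

    # host expression: log-normal baseline with planted module structure
    host_ids = [f"hg{j:04d}" for j in range(n_host_genes)]
    region_size = max(2, n_host_genes // 12)
    regions = {r: region_size for r in DEG_REGIONS if r != "discordant"}
    regions["discordant"] = max(1, region_size // 2)
    up3, up6, down3, down6 = simulate_deg_sets(regions, seed=sub[2])
    # remap generated ids onto host gene ids
    all_deg = sorted(up3 | up6 | down3 | down6)
    mapping = dict(zip(all_deg, host_ids))
    up3 = {mapping[g] for g in up3}
    up6 = {mapping[g] for g in up6}
    down3 = {mapping[g] for g in down3}
    down6 = {mapping[g] for g in down6}

    n_total = sum(n_per_group.values())
    sample_ids = taxa.sample_ids
    labels = np.array([design.group_of(s) for s in sample_ids])
    hrng = np.random.default_rng(sub[3])
    base = np.exp(hrng.normal(3.0, 0.8, n_host_genes))
    log_expr = np.tile(np.log2(base), (n_total, 1))
    day3 = labels == groups[1]
    day6 = labels == groups[2]
    for j, gid in enumerate(host_ids):
        if gid in up3:
            log_expr[day3, j] += log2_effect
        if gid in down3:
            log_expr[day3, j] -= log2_effect
        if gid in up6:
            log_expr[day6, j] += log2_effect
        if gid in down6:
            log_expr[day6, j] -= log2_effect
    log_expr += hrng.normal(0.0, 0.5, log_expr.shape)

    # latent coupling between differential taxa and host DEGs for sCCA
    z = hrng.standard_normal(n_total)
    coupled_taxa = taxa_truth.diff_feature_ids[:4]
    coupled_host = sorted(up3 | up6)[: max(4, region_size * 2)]
    taxa_data = taxa.data.copy()
    for t in coupled_taxa:
        taxa_data[t] = np.round(
            taxa_data[t] * 2.0 ** (coupling_strength * z)
        )
    for g in coupled_host:
        log_expr[:, host_ids.index(g)] += coupling_strength * z
    host = FeatureTable(
        pd.DataFrame(2.0 ** log_expr, index=sample_ids, columns=host_ids),
        "normalized",
        taxa.sample_meta,
    )
    taxa = FeatureTable(taxa_data, "count", taxa.sample_meta, taxa.feature_meta)

    # GO annotation: small terms over host genes + one oversized term
    grng = np.random.default_rng(sub[4])
    records = []
    small_terms = [f"GO:{7000000 + t}" for t in range(8)]
    for gid in host_ids:
        for term in grng.choice(small_terms, 2, replace=False):
            records.append((gid, term))
    # oversized term: annotates >= 100 genes, must be dropped downstream
    big_members = [f"bg{j:04d}" for j in range(100)] + host_ids[:20]
    for gid in big_members:
        records.append((gid, "GO:0009999"))
    go_annotation = pd.DataFrame(records, columns=["gene", "go_term"])

    truth = StudyTruth(
        taxa_truth, gene_truth, (up3, up6, down3, down6),
        coupled_taxa, coupled_host, seed,
    )
    study = {
        "taxa": taxa,
        "genes": genes,
        "host": host,
        "design": design,
        "go_annotation": go_annotation,
        "truth": truth,
    }
    if out_dir is not None:
        _write_study(study, Path(out_dir))
    return study


def split_gene_id(gene_id: str) -> tuple[str, str | None]:
    from .datamodel import split_composite_id

    return split_composite_id(gene_id)


def _write_study(study: dict, out_dir: Path) -> None:
    from .io import write_feature_table

    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("taxa", "genes", "host"):
        write_feature_table(study[name], out_dir / f"{name}.tsv")
    table = study["taxa"]
    table.sample_meta.to_csv(out_dir / "sample_metadata.tsv", sep="\t")
    study["genes"].feature_meta.to_csv(out_dir / "gene_metadata.tsv", sep="\t")
    study["go_annotation"].to_csv(
        out_dir / "go_annotation.tsv", sep="\t", index=False
    )
    truth = study["truth"]
    up3, up6, down3, down6 = truth.host_deg_sets
    payload = {
        "seed": truth.seed,
        "diff_taxa": truth.taxa_truth.diff_feature_ids,
        "diff_genes": truth.gene_truth.diff_feature_ids,
        "host_up_day3": sorted(up3),
        "host_up_day6": sorted(up6),
        "host_down_day3": sorted(down3),
        "host_down_day6": sorted(down6),
        "coupled_taxa": truth.coupled_taxa,
        "coupled_host_genes": truth.coupled_host_genes,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2)
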