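"""Differential features, abundance transforms, and the six-module classifier.

Group comparisons use the Wilcoxon rank-sum test (exact enumeration for
small tie-free samples, tie-corrected normal approximation with
continuity correction otherwise) with one Benjamini-Hochberg family per
comparison; adjusted p < alpha flags significance. Metatranscriptomic
gene tables are renormalized within each organism (taxon-specific
scaling), amplicon tables are log2(x + pseudocount) transformed, and
features observed in at most one sample are dropped before integration.
Host DEG sets from the day-3 and day-6 comparisons are partitioned into
the six expression modules (plus an explicit discordant label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .datamodel import FeatureTable, GroupDesign, ValidationError

log = logging.getLogger("mbcca")

EXACT_MAX_N = 12  # exact Wilcoxon enumeration limit (tie-free only)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank-sum of ``x`` in the pooled
    ranking. Exact p by enumeration when n1+n2 <= 12 with no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction. Constant pooled data gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least two observations")
    pooled = np.concatenate([x, y])
    n1 = len(x)
    w_null = n1 * (n1 + 1) / 2.0  # rank-sum offset
    if np.ptp(pooled) == 0:
        return float(w_null + len(x) * len(y) / 2.0), 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= EXACT_MAX_N and tie_free:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    return float(res.statistic + w_null), float(min(res.pvalue, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DiffResult:
    """Per-feature differential test results for one group comparison."""

    table: pd.DataFrame  # feature_id, statistic, p, q, direction, significant
    group_a: str
    group_b: str
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return self.table.sort_values("feature_id").reset_index(drop=True)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, group_a: str = "", group_b: str = "",
        alpha: float = 0.05,
    ) -> "DiffResult":
        return cls(df.reset_index(drop=True), group_a, group_b, alpha)

    def significant_ids(self) -> list[str]:
        return self.table.loc[self.table["significant"], "feature_id"].tolist()

    def up_ids(self) -> list[str]:
        m = self.table["significant"] & (self.table["direction"] == "up")
        return self.table.loc[m, "feature_id"].tolist()

    def down_ids(self) -> list[str]:
        m = self.table["significant"] & (self.table["direction"] == "down")
        return self.table.loc[m, "feature_id"].tolist()


def differential_features(
    table: FeatureTable,
    design: GroupDesign,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> DiffResult:
    """Per-feature Wilcoxon rank-sum test between two groups, one BH family.

    Direction is the sign of (median in group_b - median in group_a):
    ``up`` means higher in group_b. Equal medians leave direction unset.
    """
    design.require_groups([group_a, group_b], min_size=2)
    a_ids = [s for s in table.sample_ids if design.group_of(s) == group_a]
    b_ids = [s for s in table.sample_ids if design.group_of(s) == group_b]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValidationError(
            f"fewer than two samples of {group_a!r}/{group_b!r} in the table"
        )
    A = table.data.loc[a_ids]
    B = table.data.loc[b_ids]
    rows = []
    for f in table.feature_ids:
        stat, p = wilcoxon_rank_sum(A[f], B[f])
        med_a, med_b = float(A[f].median()), float(B[f].median())
        if med_b > med_a:
            direction = "up"
        elif med_b < med_a:
            direction = "down"
        else:
            direction = "none"
        rows.append((f, stat, p, direction))
    df = pd.DataFrame(rows, columns=["feature_id", "statistic", "p", "direction"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha
    df = df[["feature_id", "statistic", "p", "q", "direction", "significant"]]
    return DiffResult(df, group_a, group_b, alpha)


def taxon_scale(
    gene_table: FeatureTable, constant: float = 1e6
) -> FeatureTable:
    """Taxon-specific scaling of a per-organism gene table.

    Within each (taxon, sample), gene abundances are renormalized to sum
    to ``constant`` — a within-organism CPM analogue — so expression is
    interpreted relative to that organism's total activity. Taxa with
    zero total in a sample yield zeros there.
    """
    if constant <= 0:
        raise ValidationError("scaling constant must be positive")
    taxa = gene_table.taxon_labels()
    missing = taxa.index[taxa.isna()].tolist()
    if missing:
        raise ValidationError(f"features without a taxon label: {missing}")
    values = gene_table.values.copy()
    for taxon, cols in taxa.groupby(taxa).groups.items():
        idx = [gene_table.data.columns.get_loc(c) for c in cols]
        block = values[:, idx]
        totals = block.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(totals > 0, block / totals * constant, 0.0)
        values[:, idx] = scaled
    return gene_table.with_values(values, value_kind="normalized")


def log2_transform(
    table: FeatureTable, pseudocount: float = 1.0
) -> FeatureTable:
    """Element-wise log2(x + pseudocount); tags the result as log2 scale."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return table.with_values(
        np.log2(table.values + pseudocount), value_kind="log2"
    )


def filter_sparse_variables(table: FeatureTable) -> FeatureTable:
    """Drop features observed (nonzero) in at most one sample.

    Variables carried by a single sample cannot support correlation
    structure; dropped ids are logged.
    """
    nonzero = (table.values > 0).sum(axis=0)
    keep = [f for f, c in zip(table.feature_ids, nonzero) if c >= 2]
    dropped = [f for f, c in zip(table.feature_ids, nonzero) if c < 2]
    if dropped:
        log.info("filter_sparse_variables dropped %d features: %s",
                 len(dropped), dropped[:10])
    return table.subset_features(keep)


MODULE_LABELS = (1, 2, 3, 4, 5, 6, "discordant")


@dataclass
class ModuleAssignment:
    """Gene -> expression-module partition.

    Modules: 1 up on day 3 only, 2 commonly up, 3 up on day 6 only,
    4 down on day 3 only, 5 commonly down, 6 down on day 6 only;
    genes up in one comparison and down in the other are labelled
    ``discordant`` rather than silently excluded.
    """

    assignments: dict[str, int | str] = field(default_factory=dict)

    def modules_present(self) -> list:
        return sorted({m for m in self.assignments.values() if m != "discordant"})

    def genes_in(self, module) -> list[str]:
        return sorted(g for g, m in self.assignments.items() if m == module)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignments.items()), columns=["gene_id", "module"]
        )


def classify_deg_modules(
    up_day3, up_day6, down_day3, down_day6
) -> ModuleAssignment:
    """Partition DEG sets from the two comparisons into six modules.

    Every input gene receives exactly one label. A gene both up and down
    within the same day is contradictory input and raises.
    """
    up3, up6 = set(up_day3), set(up_day6)
    down3, down6 = set(down_day3), set(down_day6)
    for day, up, down in (("day 3", up3, down3), ("day 6", up6, down6)):
        both = up & down
        if both:
            raise ValidationError(
                f"genes both up- and downregulated on {day}: {sorted(both)[:5]}"
            )
    out: dict[str, int | str] = {}
    discordant = (up3 & down6) | (down3 & up6)
    for g in discordant:
        out[g] = "discordant"
    for g in up3 - up6 - discordant:
        out[g] = 1
    for g in up3 & up6:
        out[g] = 2
    for g in up6 - up3 - discordant:
        out[g] = 3
    for g in down3 - down6 - discordant:
        out[g] = 4
    for g in down3 & down6:
        out[g] = 5
    for g in down6 - down3 - discordant:
        out[g] = 6
    return ModuleAssignment(out)
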