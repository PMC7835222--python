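"""Regulator-conditioned differential-expression directionality analysis.

Given two DE tables — one where the enzyme (e.g. ALDH1A1) is up while its
inhibitory partner (PRMT3) is down, one where both are up — and a literature
list of pathway targets with documented direction, the analysis:

1. classifies each table against a regulator rule (sign + significance of
   each regulator's fold change);
2. intersects the targets of the requested direction class present in every
   table (a class below ``min_class_size`` is excluded with a reason, as a
   handful of genes cannot support a distributional comparison);
3. compares the two shared fold-change vectors: per-condition medians,
   Wilcoxon rank-sum on the distributions, Fisher's exact test on the 2x2
   up/down counts, and a per-gene delta table ordered by delta (heatmap
   input).

Gene symbols match case-insensitively; an exact-zero fold change counts as
"up" and is flagged (zeros are vanishingly rare in continuous fold-change
data, but the dichotomy must be total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DifferentialExpressionTable, TargetList
from .stats import TestResult, fisher_exact_2x2, wilcoxon_rank_sum


@dataclass
class RegulatorRule:
    """Condition class defined by required regulator directions."""

    label: str
    requirements: list[tuple[str, str, bool]]  # (gene, "up"|"down", require_significant)

    def __post_init__(self) -> None:
        if not self.requirements:
            raise ValueError("rule needs at least one regulator requirement")
        genes = [g for g, _, _ in self.requirements]
        if len(set(g.upper() for g in genes)) != len(genes):
            raise ValueError("duplicate regulator gene in rule")
        for _, direction, _ in self.requirements:
            if direction not in ("up", "down"):
                raise ValueError(f"invalid direction {direction!r}")


@dataclass
class Classification:
    label: str  # rule label or "unclassified"
    diagnostics: dict[str, str]  # per-regulator status


def _gene_index(table: DifferentialExpressionTable) -> pd.DataFrame:
    df = table.frame.copy()
    upper = df["gene"].str.upper()
    if upper.duplicated().any():
        clash = sorted(df["gene"][upper.duplicated(keep=False)])
        raise ValueError(f"case-insensitive gene symbol collision: {clash}")
    df.index = upper
    return df


def classify_condition(table: DifferentialExpressionTable, rule: RegulatorRule) -> Classification:
    """Assign the rule's label iff every regulator matches sign and significance."""
    df = _gene_index(table)
    diagnostics: dict[str, str] = {}
    ok = True
    for gene, direction, require_sig in rule.requirements:
        key = gene.upper()
        if key not in df.index:
            diagnostics[gene] = "regulator_missing"
            ok = False
            continue
        row = df.loc[key]
        if require_sig and not bool(row["significant"]):
            diagnostics[gene] = "not_significant"
            ok = False
            continue
        sign_ok = row["log2fc"] > 0 if direction == "up" else row["log2fc"] < 0
        if not sign_ok:
            diagnostics[gene] = "wrong_direction"
            ok = False
            continue
        diagnostics[gene] = "ok"
    return Classification(label=rule.label if ok else "unclassified", diagnostics=diagnostics)


@dataclass
class SharedTargets:
    """Direction-class targets present in every table, with per-table log2FC."""

    table: pd.DataFrame | None  # gene + log2fc_<label> per condition
    condition_labels: list[str]
    direction_class: str
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (class, reason)


def intersect_targets(
    tables: list[DifferentialExpressionTable],
    targets: TargetList,
    direction_class: str = "up",
    min_class_size: int = 6,
) -> SharedTargets:
    if len(tables) < 2:
        raise ValueError("need at least two DE tables")
    labels = [t.condition_label for t in tables]
    class_genes = targets.genes(direction_class)
    excluded: list[tuple[str, str]] = []
    # report any direction class too small to analyse
    for cls in ("up", "down"):
        if len(targets.genes(cls)) < min_class_size:
            excluded.append((cls, "class_too_small"))
    if (direction_class, "class_too_small") in excluded:
        return SharedTargets(
            table=None, condition_labels=labels, direction_class=direction_class, excluded=excluded
        )
    indexed = [_gene_index(t) for t in tables]
    rows = []
    for gene in class_genes:
        key = gene.upper()
        if all(key in df.index for df in indexed):
            rows.append([gene] + [float(df.loc[key, "log2fc"]) for df in indexed])
    if not rows:
        raise ValueError("empty intersection: no shared targets across all tables")
    cols = ["gene"] + [f"log2fc_{lab}" for lab in labels]
    return SharedTargets(
        table=pd.DataFrame(rows, columns=cols),
        condition_labels=labels,
        direction_class=direction_class,
        excluded=excluded,
    )


@dataclass
class PartitionReport:
    condition_labels: list[str]
    n_shared: int
    medians: dict[str, float]
    up_counts: dict[str, int]
    down_counts: dict[str, int]
    rank_sum: TestResult
    fisher: TestResult
    per_gene: pd.DataFrame  # gene, log2FC per condition, delta; ordered by delta
    zero_flagged: list[str] = field(default_factory=list)
    degenerate: bool = False
    excluded: list[tuple[str, str]] = field(default_factory=list)


def directionality_analysis(shared: SharedTargets) -> PartitionReport:
    """Medians, rank-sum, Fisher up/down 2x2, and the per-gene delta table."""
    if shared.table is None:
        raise ValueError(f"shared target set excluded: {shared.excluded}")
    if len(shared.table) < 3:
        raise ValueError("need >= 3 shared targets")
    if len(shared.condition_labels) != 2:
        raise ValueError("directionality analysis compares exactly two conditions")
    lab_a, lab_b = shared.condition_labels
    fc_a = shared.table[f"log2fc_{lab_a}"].to_numpy(dtype=float)
    fc_b = shared.table[f"log2fc_{lab_b}"].to_numpy(dtype=float)

    zero_flagged = list(shared.table["gene"][(fc_a == 0) | (fc_b == 0)])
    up_a, up_b = int((fc_a >= 0).sum()), int((fc_b >= 0).sum())  # zeros count as up
    n = len(shared.table)
    counts_table = [[up_a, n - up_a], [up_b, n - up_b]]

    degenerate = bool(np.all(fc_a == fc_b))
    if degenerate:
        rank_sum = TestResult(statistic=float("nan"), p_value=1.0, method="degenerate", n=(n, n))
    else:
        rank_sum = wilcoxon_rank_sum(fc_a, fc_b)
    fisher = fisher_exact_2x2(counts_table)

    per_gene = shared.table.copy()
    per_gene["delta"] = fc_a - fc_b
    per_gene = per_gene.sort_values("delta", ascending=False, kind="stable").reset_index(drop=True)

    return PartitionReport(
        condition_labels=[lab_a, lab_b],
        n_shared=n,
        medians={lab_a: float(np.median(fc_a)), lab_b: float(np.median(fc_b))},
        up_counts={lab_a: up_a, lab_b: up_b},
        down_counts={lab_a: n - up_a, lab_b: n - up_b},
        rank_sum=rank_sum,
        fisher=fisher,
        per_gene=per_gene,
        zero_flagged=zero_flagged,
        degenerate=degenerate,
        excluded=shared.excluded,
    )
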