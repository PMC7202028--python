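"""Eight-group classification of differentially expressed genes.

Four pairwise genotype x treatment comparisons each define an up- and a
down-regulated group:

====================  ======  =====================================
comparison            groups  interpretation
====================  ======  =====================================
WTABA_vs_WTMS         I/II    ABA response in wildtype
MUTMS_vs_WTMS         III/IV  response to loss of RdDM
MUTABA_vs_MUTMS       V/VI    ABA response in the RdDM mutant
MUTABA_vs_WTABA       VII/VIII differential ABA response, mutant vs WT
====================  ======  =====================================

A gene enters a group when |log2FC| >= ``lfc_min`` (default 0.95, i.e. a
twofold change) at FDR <= ``fdr_max`` (default 0.05); both boundaries are
inclusive. Genes in several groups are "shared"; genes up in one comparison
and down in another are "contra-regulated".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import AnalysisConfig

logger = logging.getLogger(__name__)

COMPARISONS = (
    "WTABA_vs_WTMS",
    "MUTMS_vs_WTMS",
    "MUTABA_vs_MUTMS",
    "MUTABA_vs_WTABA",
)

#: comparison -> (up-group, down-group), roman numerals I..VIII
GROUP_MAP = {
    "WTABA_vs_WTMS": ("I", "II"),
    "MUTMS_vs_WTMS": ("III", "IV"),
    "MUTABA_vs_MUTMS": ("V", "VI"),
    "MUTABA_vs_WTABA": ("VII", "VIII"),
}

ALL_GROUPS = tuple(g for pair in GROUP_MAP.values() for g in pair)
UP_GROUPS = frozenset(pair[0] for pair in GROUP_MAP.values())
DOWN_GROUPS = frozenset(pair[1] for pair in GROUP_MAP.values())


@dataclass(frozen=True)
class GroupAssignment:
    gene_id: str
    groups: frozenset[str]

    @property
    def unique(self) -> bool:
        return len(self.groups) == 1

    @property
    def contra(self) -> bool:
        return bool(self.groups & UP_GROUPS) and bool(self.groups & DOWN_GROUPS)


@dataclass
class OverlapSummary:
    total: int
    shared: int
    unique: int
    group_sizes: dict[str, int]
    contra_genes: frozenset[str] = field(default_factory=frozenset)


def filter_low_abundance(
    count_table: pd.DataFrame,
    libsizes: pd.Series,
    cpm_min: float = 0.58,
    min_samples: int | None = None,
    sample_groups: pd.Series | None = None,
) -> pd.Index:
    """Genes retained by the counts-per-million floor.

    A gene is kept when its CPM (count / library size x 1e6) reaches
    ``cpm_min`` (inclusive) in at least ``min_samples`` samples. When
    ``min_samples`` is not given it defaults to the size of the smallest
    experimental group (from ``sample_groups``), or 2.
    """
    missing = libsizes.index.difference(count_table.columns)
    if len(missing):
        raise ValueError(f"count table is missing sample columns: {list(missing)}")
    if (libsizes <= 0).any():
        raise ValueError("library sizes must be positive")
    if min_samples is None:
        if sample_groups is not None:
            min_samples = int(sample_groups.value_counts().min())
        else:
            min_samples = 2
    cpm = count_table[libsizes.index].div(libsizes, axis=1) * 1e6
    keep = (cpm >= cpm_min).sum(axis=1) >= min_samples
    removed = count_table.index[~keep]
    if len(removed):
        logger.info("low-abundance filter removed %d genes", len(removed))
    return count_table.index[keep]


def bh_adjust(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (for synthetic tables that only
    carry raw p-values)."""
    adj = multipletests(pvalues.to_numpy(), method="fdr_bh")[1]
    return pd.Series(adj, index=pvalues.index)


def classify_groups(
    stats: pd.DataFrame, config: AnalysisConfig | None = None
) -> list[GroupAssignment]:
    """Assign genes to groups I..VIII from a long-format statistics table.

    ``stats`` needs columns ``gene_id``, ``comparison``, ``log2fc``, ``fdr``
    (a ``pvalue`` column may be present but is not used for the decision).
    """
    config = config or AnalysisConfig()
    unknown = set(stats["comparison"]) - set(COMPARISONS)
    if unknown:
        raise ValueError(f"unknown comparison labels: {sorted(unknown)}")
    dup = stats.duplicated(subset=["gene_id", "comparison"])
    if dup.any():
        raise ValueError(
            "duplicate (gene, comparison) records: "
            f"{stats.loc[dup, 'gene_id'].unique()[:5]}"
        )

    membership: dict[str, set[str]] = {}
    sig = stats["fdr"] <= config.fdr_max
    up = sig & (stats["log2fc"] >= config.lfc_min)
    down = sig & (stats["log2fc"] <= -config.lfc_min)
    for mask, which in ((up, 0), (down, 1)):
        for _, row in stats[mask].iterrows():
            group = GROUP_MAP[row["comparison"]][which]
            membership.setdefault(row["gene_id"], set()).add(group)
    return [
        GroupAssignment(gene_id=g, groups=frozenset(groups))
        for g, groups in sorted(membership.items())
    ]


def overlap_summary(assignments: list[GroupAssignment]) -> OverlapSummary:
    """Totals mirroring the group-accounting table: distinct DEGs, genes in
    more than one group (shared), genes unique to one group, per-group sizes,
    and the contra-regulated gene set."""
    total = len(assignments)
    shared = sum(1 for a in assignments if len(a.groups) > 1)
    sizes = {g: 0 for g in ALL_GROUPS}
    contra = frozenset(a.gene_id for a in assignments if a.contra)
    for a in assignments:
        for g in a.groups:
            sizes[g] += 1
    return OverlapSummary(
        total=total,
        shared=shared,
        unique=total - shared,
        group_sizes=sizes,
        contra_genes=contra,
    )


def unique_to_comparison(
    assignments: list[GroupAssignment],
    groupset_a: set[str],
    groupset_b: set[str],
) -> dict[str, set[str]]:
    """Genes in any group of ``groupset_a`` but no group of ``groupset_b``.

    Returns the full set plus per-direction splits (by membership in the
    up- vs down-groups of ``groupset_a``).
    """
    for gs in (groupset_a, groupset_b):
        bad = set(gs) - set(ALL_GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")
    hits = [
        a for a in assignments
        if a.groups & groupset_a and not (a.groups & groupset_b)
    ]
    all_genes = {a.gene_id for a in hits}
    up = {a.gene_id for a in hits if a.groups & groupset_a & UP_GROUPS}
    down = {a.gene_id for a in hits if a.groups & groupset_a & DOWN_GROUPS}
    return {"all": all_genes, "up": up, "down": down}


def identifier_coverage(n_named: int, n_total: int) -> float:
    """Percentage of genes carrying a known gene-model identifier."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_named <= n_total:
        raise ValueError("n_named must be between 0 and n_total")
    return 100.0 * n_named / n_total


def assignments_to_frame(assignments: list[GroupAssignment]) -> pd.DataFrame:
    """Groups table: gene_id, comma-joined roman numerals, unique/contra flags."""
    order = {g: i for i, g in enumerate(ALL_GROUPS)}
    return pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in assignments],
            "groups": [
                ",".join(sorted(a.groups, key=order.__getitem__))
                for a in assignments
            ],
            "unique": [a.unique for a in assignments],
            "contra": [a.contra for a in assignments],
        }
    )


def genes_in_groups(
    assignments: list[GroupAssignment], groups: set[str]
) -> set[str]:
    return {a.gene_id for a in assignments if a.groups & groups}
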