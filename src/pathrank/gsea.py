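"""Rank-based gene-set enrichment with overlap discarding.

A gene set is scored directly from the position of its members in the
genome-wide ranking of differential-expression p-values — no significance
cutoff partitions the gene list.  The statistic is a one-sided rank-sum
(Wilcoxon/Mann-Whitney) test asking whether member genes sit at better
(lower) ranks than non-members: exact enumeration of the rank-sum null for
small problems, normal approximation with continuity correction otherwise.

Significant sets are then pruned for redundancy: processing them from most
to least significant, a set whose significance disappears once the genes it
shares with an already-retained set are removed is discarded, with the
retained set recorded as the explanation.  This prevents one true signal
from dressing up every overlapping collection entry as an independent hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .preprocess import DomainError, InputError, PathrankError

logger = logging.getLogger("pathrank.gsea")

#: below this many members (after universe intersection) the rank-sum
#: statistic degenerates and a set is untestable
MIN_TESTABLE_SIZE = 2

#: exact-enumeration limits for the rank-sum null
EXACT_MAX_MEMBERS = 8
EXACT_MAX_UNIVERSE = 25

SET_RESULT_COLUMNS = [
    "set_id", "database", "name", "n_members_tested",
    "p_set", "p_set_adj", "status", "explained_by",
]


class UntestableSetError(PathrankError):
    """Set empty, too small, or equal to the universe after intersection."""


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    database: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets, each tagged with its source database."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def merge(self, other: "GeneSetCollection") -> "GeneSetCollection":
        clash = self.sets.keys() & other.sets.keys()
        if clash:
            raise InputError(f"duplicate set ids across collections: {sorted(clash)[:5]}")
        return GeneSetCollection(sets={**self.sets, **other.sets})

    @classmethod
    def from_gmt(cls, path: str | Path, database: str) -> "GeneSetCollection":
        """Read a GMT file (name, description, members...; description may
        be missing)."""
        sets: dict[str, GeneSet] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise InputError(f"{path}:{lineno}: GMT line has no members")
                name = fields[0]
                members = frozenset(g for g in fields[2:] if g) or frozenset(
                    g for g in fields[1:] if g
                )
                description = fields[1] if len(fields) > 2 else ""
                if name in sets:
                    raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
                sets[name] = GeneSet(name, description or name, database, members)
        return cls(sets=sets)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid in sorted(self.sets):
                s = self.sets[sid]
                members = "\t".join(sorted(s.members))
                fh.write(f"{s.set_id}\t{s.name}\t{members}\n")


# ---------------------------------------------------------------------------
# Ranking and the set statistic
# ---------------------------------------------------------------------------

def rank_genes(de: pd.DataFrame) -> list[str]:
    """Genes in ascending raw-p order, ties broken lexicographically."""
    if de.empty:
        raise InputError("empty differential-expression table")
    if de.index.has_duplicates:
        raise InputError("duplicate gene ids in differential-expression table")
    order = np.lexsort((de.index.astype(str), de["p"].to_numpy()))
    return [str(g) for g in de.index[order]]


def set_pvalue(ranking: list[str], set_members: frozenset[str] | set[str]) -> float:
    """One-sided rank-sum p-value that member genes occupy low ranks.

    Exact when |members| <= 8 and |universe| <= 25, otherwise normal
    approximation with continuity correction.
    """
    universe = ranking
    n = len(universe)
    member_ranks = np.array(
        [r for r, g in enumerate(universe, start=1) if g in set_members], dtype=float
    )
    m = len(member_ranks)
    if m < MIN_TESTABLE_SIZE:
        raise UntestableSetError(
            f"set has {m} testable members (< {MIN_TESTABLE_SIZE})"
        )
    if m >= n:
        raise UntestableSetError("set covers the whole universe")
    other_ranks = np.array(
        [r for r, g in enumerate(universe, start=1) if g not in set_members],
        dtype=float,
    )
    method = (
        "exact" if (m <= EXACT_MAX_MEMBERS and n <= EXACT_MAX_UNIVERSE) else "asymptotic"
    )
    res = stats.mannwhitneyu(
        member_ranks, other_ranks, alternative="less", method=method,
        use_continuity=True,
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Overlap pruning
# ---------------------------------------------------------------------------

def overlap_prune(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    ranking: list[str],
    alpha: float,
) -> pd.DataFrame:
    """Discard significant sets whose signal is carried by overlap.

    Initially significant sets (``p_set_adj <= alpha``) are processed in
    ascending ``p_set`` order.  A later set B that overlaps an
    already-retained set A is re-tested on B minus A's members; if the
    difference set is untestable or no longer significant at ``alpha``, B is
    discarded with ``explained_by = A``.  Non-significant sets are reported
    as retained without pruning.
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    out = results.copy()
    out["status"] = "retained"
    out["explained_by"] = ""
    significant = out[out["p_set_adj"] <= alpha]
    order = significant.sort_values(["p_set", "set_id"]).index
    universe = set(ranking)
    retained: list[str] = []
    for idx in order:
        sid = out.at[idx, "set_id"]
        members = collection.sets[sid].members & universe
        discarded_by = None
        for a_sid in retained:
            a_members = collection.sets[a_sid].members & universe
            if not (members & a_members):
                continue
            difference = members - a_members
            try:
                p_diff = set_pvalue(ranking, difference)
            except UntestableSetError:
                discarded_by = a_sid
                break
            if p_diff > alpha:
                discarded_by = a_sid
                break
        if discarded_by is None:
            retained.append(sid)
        else:
            out.at[idx, "status"] = "discarded"
            out.at[idx, "explained_by"] = discarded_by
            logger.info("set %s discarded: explained by overlap with %s", sid, discarded_by)
    return out


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_gsea(
    de: pd.DataFrame,
    collections: list[GeneSetCollection] | GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every set in every collection against the DE gene ranking.

    Set p-values are corrected with one BH family pooled over all tested
    sets (per-database membership is reported as a column), then overlap
    pruning is applied across the pooled results.  Rows are sorted by
    ascending adjusted then raw p-value.
    """
    if isinstance(collections, GeneSetCollection):
        collections = [collections]
    if not collections or all(len(c) == 0 for c in collections):
        raise InputError("no gene-set collections supplied")
    merged = collections[0]
    for extra in collections[1:]:
        merged = merged.merge(extra)

    ranking = rank_genes(de)
    universe = set(ranking)
    rows = []
    for sid in sorted(merged.sets):
        gene_set = merged.sets[sid]
        tested = gene_set.members & universe
        try:
            p = set_pvalue(ranking, tested)
        except UntestableSetError as exc:
            logger.warning("set %s dropped: %s", sid, exc)
            continue
        rows.append(
            {
                "set_id": sid,
                "database": gene_set.database,
                "name": gene_set.name,
                "n_members_tested": len(tested),
                "p_set": p,
            }
        )
    if not rows:
        raise InputError("no testable sets: empty universe intersection")
    table = pd.DataFrame(rows)
    table["p_set_adj"] = bh_adjust(table["p_set"])
    table = overlap_prune(table, merged, ranking, alpha)
    table = table.sort_values(
        ["p_set_adj", "p_set", "set_id"], kind="mergesort"
    ).reset_index(drop=True)
    return table[SET_RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# Export tables
# ---------------------------------------------------------------------------

def write_set_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_set_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"set_id": str, "explained_by": str})
    df["explained_by"] = df["explained_by"].fillna("")
    return df


def membership_table(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    de: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Long per-set-per-gene table for dot-plot style pathway figures.

    One row per (retained significant set, member gene) with the gene's
    log-fold change, its significance rank, and the set's adjusted p-value.
    """
    keep = results[(results["status"] == "retained") & (results["p_set_adj"] <= alpha)]
    rows = []
    for _, r in keep.iterrows():
        for gene in sorted(collection.sets[r["set_id"]].members):
            if gene not in de.index:
                continue
            rows.append(
                {
                    "set_id": r["set_id"],
                    "gene": gene,
                    "logfc": float(de.at[gene, "logfc"]),
                    "gene_rank": int(de.at[gene, "rank"]),
                    "set_p_adj": float(r["p_set_adj"]),
                }
            )
    return pd.DataFrame(
        rows, columns=["set_id", "gene", "logfc", "gene_rank", "set_p_adj"]
    )
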