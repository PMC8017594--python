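"""Signed intersection of two differential-expression contrasts.

A gene is *mis-expressed* when its response to a perturbation (e.g. knockdown
of a migration gene) is discordant with its expression difference in a
clinical contrast (e.g. low-risk stage 4S vs. higher stages): up in one,
down in the other, with both raw p-values at or below the gate (default 0.05)
and no log-fold-change magnitude requirement.

Also provides ranked fingerprint mapping: where the members of a gene set
fall in another profile ranked by logFC (or signed -log10 p), with a
one-sided rank-sum enrichment p-value toward the top of the ranking.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Category",
    "MisexpressionResult",
    "read_de_table",
    "classify_misexpression",
    "ranked_fingerprint",
]

DE_COLUMNS = ["gene_id", "logFC", "p_value"]


class Category(enum.Enum):
    MIS_UP = "mis_up"  # up after perturbation, down in the clinical contrast
    MIS_DOWN = "mis_down"
    CONCORDANT_UP = "concordant_up"
    CONCORDANT_DOWN = "concordant_down"
    UNCLASSIFIED = "unclassified"


@dataclass
class MisexpressionResult:
    categories: pd.Series  # gene_id -> Category, over the table intersection
    p_max: float
    lfc_min: float
    only_in_first: list[str] = field(default_factory=list)
    only_in_second: list[str] = field(default_factory=list)

    def counts(self) -> dict[Category, int]:
        c = self.categories.value_counts()
        return {cat: int(c.get(cat, 0)) for cat in Category}

    def genes(self, category: Category) -> list[str]:
        return sorted(self.categories.index[self.categories == category])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.categories.index,
                "category": [c.value for c in self.categories],
            }
        )


def read_de_table(path) -> pd.DataFrame:
    """Read a gene-level DE table (TSV: gene_id, logFC, p_value)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE column(s) {missing}")
    return validate_de_table(df)


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()[:5]
        raise ValueError(f"duplicate gene ids, e.g. {list(dupes)}")
    p = df["p_value"]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p_value must lie in (0, 1]")
    return df


def classify_misexpression(
    kd: pd.DataFrame,
    clinical: pd.DataFrame,
    p_max: float = 0.05,
    lfc_min: float = 0.0,
) -> MisexpressionResult:
    """Quadrant-classify genes shared by two DE tables.

    ``kd`` is the perturbation contrast, ``clinical`` the reference contrast.
    Over the gene intersection: MIS_UP when kd logFC > lfc_min and clinical
    logFC < -lfc_min, MIS_DOWN for the mirror, CONCORDANT_* for sign
    agreement; any gene failing the p-value gate (p > p_max in either table)
    or without a direction (|logFC| <= lfc_min) is UNCLASSIFIED.  Genes absent
    from either table are reported separately, never silently dropped.
    """
    kd = validate_de_table(kd)
    clinical = validate_de_table(clinical)
    merged = kd.merge(clinical, on="gene_id", suffixes=("_kd", "_cl"))
    if merged.empty:
        raise ValueError("the two DE tables share no genes")
    lfc_kd = merged["logFC_kd"].to_numpy()
    lfc_cl = merged["logFC_cl"].to_numpy()
    significant = (merged["p_value_kd"] <= p_max) & (merged["p_value_cl"] <= p_max)
    kd_up = lfc_kd > lfc_min
    kd_down = lfc_kd < -lfc_min
    cl_up = lfc_cl > lfc_min
    cl_down = lfc_cl < -lfc_min
    cats = np.full(len(merged), Category.UNCLASSIFIED, dtype=object)
    cats[significant & kd_up & cl_down] = Category.MIS_UP
    cats[significant & kd_down & cl_up] = Category.MIS_DOWN
    cats[significant & kd_up & cl_up] = Category.CONCORDANT_UP
    cats[significant & kd_down & cl_down] = Category.CONCORDANT_DOWN
    shared = set(merged["gene_id"])
    return MisexpressionResult(
        categories=pd.Series(cats, index=merged["gene_id"], name="category"),
        p_max=p_max,
        lfc_min=lfc_min,
        only_in_first=sorted(set(kd["gene_id"]) - shared),
        only_in_second=sorted(set(clinical["gene_id"]) - shared),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional gate for other uses)."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


def ranked_fingerprint(
    query_genes,
    profile: pd.DataFrame,
    rank_key: str = "logFC",
) -> dict:
    """Positions of ``query_genes`` in ``profile`` ranked by ``rank_key``.

    The profile is sorted descending by ``logFC`` or by ``signed_logp``
    (sign(logFC) * -log10 p); ties break lexicographically on gene_id so the
    ranking is total and reproducible.  Returns 1-based ranks, the median
    rank quantile (rank / n) and a one-sided Mann–Whitney rank-sum p-value
    for enrichment of the query toward the top.
    """
    profile = validate_de_table(profile)
    if rank_key == "logFC":
        key = profile["logFC"]
    elif rank_key == "signed_logp":
        key = np.sign(profile["logFC"]) * -np.log10(profile["p_value"])
    else:
        raise ValueError(f"unknown rank_key {rank_key!r}")
    order = (
        pd.DataFrame({"gene_id": profile["gene_id"], "key": key})
        .sort_values(["key", "gene_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    order["rank"] = np.arange(1, len(order) + 1)
    query = set(query_genes)
    hits = order[order["gene_id"].isin(query)]
    if hits.empty:
        raise ValueError("no query gene is present in the profile")
    n = len(order)
    in_ranks = hits["rank"].to_numpy()
    out_ranks = order.loc[~order["gene_id"].isin(query), "rank"].to_numpy()
    if len(out_ranks) == 0:
        p_top = 1.0
    else:
        # smaller ranks = nearer the top of the profile
        p_top = float(
            stats.mannwhitneyu(in_ranks, out_ranks, alternative="less").pvalue
        )
    return {
        "ranks": pd.Series(in_ranks, index=hits["gene_id"].to_numpy()),
        "n_profile": n,
        "n_query_found": len(in_ranks),
        "median_rank_quantile": float(np.median(in_ranks)) / n,
        "p_enrichment_top": p_top,
        "rank_key": rank_key,
    }
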