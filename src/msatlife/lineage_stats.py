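"""Lineage-level repeat-length statistics for the felid radiation.

Modern cats fall into eight recognised lineages (Panthera, Bay cat,
Caracal, Ocelot, Lynx, Puma, Leopard cat, Domestic cat).  This module
summarises allele repeat numbers per lineage, tests for between-lineage
differences in repeat number by one-way ANOVA, scores stepwise-mutation
support from within-species allele ladders, and exports tip annotations for
external tree viewers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

#: divergence order of the eight felid lineages, oldest split first
FELID_LINEAGE_ORDER = (
    "Panthera",
    "Bay cat",
    "Caracal",
    "Ocelot",
    "Lynx",
    "Puma",
    "Leopard cat",
    "Domestic cat",
)

#: default species -> lineage assignments; overridable via a TSV map
FELID_LINEAGES: dict[str, str] = {
    "Panthera tigris": "Panthera",
    "Panthera leo": "Panthera",
    "Panthera pardus": "Panthera",
    "Panthera onca": "Panthera",
    "Panthera uncia": "Panthera",
    "Neofelis nebulosa": "Panthera",
    "Neofelis diardi": "Panthera",
    "Catopuma temminckii": "Bay cat",
    "Catopuma badia": "Bay cat",
    "Pardofelis marmorata": "Bay cat",
    "Caracal caracal": "Caracal",
    "Caracal aurata": "Caracal",
    "Leptailurus serval": "Caracal",
    "Leopardus pardalis": "Ocelot",
    "Leopardus geoffroyi": "Ocelot",
    "Leopardus wiedii": "Ocelot",
    "Lynx lynx": "Lynx",
    "Lynx canadensis": "Lynx",
    "Lynx pardinus": "Lynx",
    "Lynx rufus": "Lynx",
    "Puma concolor": "Puma",
    "Puma yagouaroundi": "Puma",
    "Acinonyx jubatus": "Puma",
    "Prionailurus bengalensis": "Leopard cat",
    "Prionailurus viverrinus": "Leopard cat",
    "Prionailurus iriomotensis": "Leopard cat",
    "Otocolobus manul": "Leopard cat",
    "Felis catus": "Domestic cat",
    "Felis silvestris": "Domestic cat",
    "Felis bieti": "Domestic cat",
    "Felis chaus": "Domestic cat",
    "Felis nigripes": "Domestic cat",
    "Felis margarita": "Domestic cat",
}

#: lineage-level felid topology (divergence order, branch lengths nominal)
FELID_LINEAGE_TREE = (
    "(Panthera:1,(BayCat:1,(Caracal:1,(Ocelot:1,(Lynx:1,(Puma:1,"
    "(LeopardCat:1,DomesticCat:1):1):1):1):1):1):1):1;"
)


def make_lineage_table(
    rows: list[tuple[str, str, str, int]] | pd.DataFrame,
) -> pd.DataFrame:
    """Build/validate a (lineage, species, allele, major_count) table."""
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(
            rows, columns=["lineage", "species", "allele", "major_count"]
        )
    missing = {"lineage", "species", "allele", "major_count"} - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (rows["major_count"] < 0).any():
        raise ValueError("major_count must be >= 0")
    multi = rows.groupby("species")["lineage"].nunique()
    if (multi > 1).any():
        bad = multi[multi > 1].index.tolist()
        raise ValueError(f"species in more than one lineage: {bad}")
    return rows


def anova_lineages(
    table: pd.DataFrame, lineages: tuple[str, ...] | None = None
) -> tuple[float, float, dict[str, float]]:
    """One-way fixed-effects ANOVA on allele major counts between lineages.

    Returns ``(F, p, group_means)``.  Requires at least two groups with at
    least two observations each.
    """
    table = make_lineage_table(table)
    if lineages is not None:
        table = table[table["lineage"].isin(lineages)]
    groups = {
        lin: sub["major_count"].to_numpy(dtype=float)
        for lin, sub in table.groupby("lineage")
    }
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise InsufficientDataError(
            "need >= 2 lineages with >= 2 observations each"
        )
    names = sorted(groups)
    f_stat, p_value = stats.f_oneway(*(groups[n] for n in names))
    means = {n: float(groups[n].mean()) for n in names}
    return float(f_stat), float(p_value), means


def consensus_repeat(alleles: list[int]) -> int:
    """Modal repeat count; ties broken toward the smaller value."""
    if not alleles:
        raise InsufficientDataError("empty allele list")
    counts = Counter(alleles)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


@dataclass
class StepwiseReport:
    """Within-species allele-ladder diagnostic for stepwise mutation.

    Under strict single-step slippage, the sorted unique allele sizes of a
    species form a ladder with unit gaps; ``stepwise_support`` is the
    fraction of adjacent pairs (pooled over species with >= 2 alleles)
    differing by exactly one repeat unit.
    """

    per_species: dict[str, list[int]] = field(default_factory=dict)
    n_gaps: int = 0
    stepwise_support: float = float("nan")


def stepwise_support(alleles_by_species: dict[str, list[int]]) -> StepwiseReport:
    """Score support for the stepwise mutation model from allele ladders."""
    per_species = {
        sp: sorted(set(counts)) for sp, counts in alleles_by_species.items()
    }
    if not any(len(v) >= 2 for v in per_species.values()):
        raise InsufficientDataError("no species with >= 2 distinct alleles")
    single_step = 0
    gaps = 0
    pairs = 0
    for ladder in per_species.values():
        for lo, hi in zip(ladder, ladder[1:]):
            pairs += 1
            if hi - lo == 1:
                single_step += 1
            else:
                gaps += 1
    return StepwiseReport(
        per_species=per_species,
        n_gaps=gaps,
        stepwise_support=single_step / pairs,
    )


def lineage_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-lineage allele-count summary (n, mean, min, max, consensus)."""
    table = make_lineage_table(table)
    rows = []
    for lin, sub in table.groupby("lineage"):
        counts = sub["major_count"].tolist()
        rows.append(
            {
                "lineage": lin,
                "n_alleles": len(counts),
                "mean_count": sum(counts) / len(counts),
                "min_count": min(counts),
                "max_count": max(counts),
                "consensus": consensus_repeat(counts),
            }
        )
    return pd.DataFrame(rows).sort_values("lineage").reset_index(drop=True)


def itol_annotation(
    tip_values: dict[str, str | int | float], color_classes: dict | None = None
) -> pd.DataFrame:
    """Tip annotation table (tip, value, color_class) for tree viewers."""
    color_classes = color_classes or {}
    return pd.DataFrame(
        [
            {
                "tip": tip,
                "value": value,
                "color_class": color_classes.get(value, str(value)),
            }
            for tip, value in sorted(tip_values.items())
        ]
    )
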