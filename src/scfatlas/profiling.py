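"""Community-level producer statistics from species abundance tables.

Joins a Bracken-style relative-abundance table (species x sample, percent
scale) with taxonomy and per-genome producer calls to quantify how much of
each community is made of putative butyrate/propionate producers: per-sample
category sums, route-level breakdowns, order-level aggregates, distribution
statistics across samples, and the dominance set (the smallest set of
producer species covering a given share of total producer abundance).

Abundances are averaged across samples (not pooled); species missing from the
table are treated as absent (0), and species without a producer call as
non-producers. Because the denominator of published producer percentages is
ambiguous (total reads vs total bacteria), per-sample sums are emitted both
on the table's own scale and as a share of the table's per-sample total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .delineate import TaxonRecord

_SUM_TOL = 1e-6


@dataclass
class AbundanceTable:
    """Species x sample relative abundances in percent.

    Per-sample sums may be below 100 (a table restricted to Clostridia) but
    never above it.
    """

    data: pd.DataFrame  # index: species IDs; columns: sample IDs

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate species IDs in abundance table")
        if not np.issubdtype(np.asarray(df.values).dtype, np.number):
            raise ValueError("non-numeric abundance values")
        if (df.values < 0).any():
            raise ValueError("negative abundance values")
        sums = df.sum(axis=0)
        if (sums > 100 + _SUM_TOL).any():
            bad = sums[sums > 100 + _SUM_TOL].index.tolist()
            raise ValueError(f"per-sample abundance exceeds 100%: {bad}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def read_abundance(path: str | Path) -> AbundanceTable:
    """Read a Bracken-like TSV: ``name`` column (plus optional
    ``taxonomy_id``), then one numeric column per sample."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "name" not in df.columns:
        raise ValueError("abundance TSV needs a 'name' column")
    df = df.set_index("name")
    df.index = df.index.astype(str)
    df.index.name = None
    if "taxonomy_id" in df.columns:
        df = df.drop(columns=["taxonomy_id"])
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric abundance cell: {exc}") from exc
    return AbundanceTable(df)


def write_abundance(
    table: AbundanceTable, path: str | Path, config: Mapping | None = None
) -> None:
    from .io import write_tsv

    df = table.data.copy()
    df.insert(0, "name", df.index)
    write_tsv(df, path, config=config, index=False)


def group_stats(values: Sequence[float]) -> dict[str, float]:
    """Mean, median (midpoint for even n), min, max and quartiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    return {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "q1": float(np.percentile(arr, 25)),
        "q3": float(np.percentile(arr, 75)),
    }


def _producer_sets(calls: pd.DataFrame) -> dict[str, set[str]]:
    """Category -> species set from a producer-call table (batch_classify
    output or the equivalent TSV)."""
    calls = calls.set_index("genome_id") if "genome_id" in calls.columns else calls
    but = set(calls.index[calls["butyrate"].astype(bool)])
    prop = set(calls.index[calls["propionate"].astype(bool)])
    sets = {"butyrate": but, "propionate": prop, "both": but & prop}

    def routed(col: str, route: str) -> set[str]:
        if col not in calls.columns:
            return set()
        vals = calls[col].fillna("")
        return set(calls.index[vals.astype(str).str.contains(route, regex=False)])

    sets["butyrate_acetylCoA"] = but & routed("butyrate_routes", "B1_acetylCoA")
    sets["butyrate_other_routes"] = but - sets["butyrate_acetylCoA"]
    sets["butyrate_but"] = but & routed("butyrate_terminals", "but")
    sets["butyrate_buk"] = but & routed("butyrate_terminals", "buk")
    sets["propionate_propanediol"] = prop & routed("propionate_routes", "P3_propanediol")
    sets["propionate_acrylate"] = prop & routed("propionate_routes", "P2_acrylate")
    return sets


@dataclass
class CommunitySummary:
    per_sample: pd.DataFrame  # samples x categories, table scale (percent)
    per_sample_share: pd.DataFrame  # same, as share of each sample's total
    stats: dict[str, dict[str, float]]  # category -> distribution stats
    by_order: pd.DataFrame | None  # order x category mean abundance
    producer_sets: dict[str, set[str]]


def producer_abundance(
    table: AbundanceTable,
    calls: pd.DataFrame,
    taxa: Sequence[TaxonRecord] | None = None,
) -> CommunitySummary:
    """Per-sample producer abundance by category, with distribution stats.

    A species producing both acids contributes once to each of the butyrate
    and propionate categories and once to "both" — never double-counted
    within a category.
    """
    sets = _producer_sets(calls)
    df = table.data
    cols = {"total": df.sum(axis=0)}
    for cat, members in sets.items():
        present = [s for s in df.index if s in members]
        cols[cat] = df.loc[present].sum(axis=0) if present else pd.Series(0.0, index=df.columns)
    per_sample = pd.DataFrame(cols)
    per_sample.index.name = "sample"

    totals = per_sample["total"].replace(0.0, np.nan)
    per_sample_share = per_sample.div(totals, axis=0).mul(100.0).fillna(0.0)

    stats = {cat: group_stats(per_sample[cat].values) for cat in per_sample.columns}

    by_order = None
    if taxa is not None:
        order_of = {t.species_id: t.ranks["order"] for t in taxa}
        rows = {}
        for order in sorted({o for o in order_of.values() if o}):
            species = [s for s in df.index if order_of.get(s) == order]
            if not species:
                continue
            sub = df.loc[species]
            rows[order] = {
                "total": float(sub.sum(axis=0).mean()),
                "butyrate": float(
                    sub.loc[[s for s in species if s in sets["butyrate"]]].sum(axis=0).mean()
                    if any(s in sets["butyrate"] for s in species) else 0.0
                ),
                "propionate": float(
                    sub.loc[[s for s in species if s in sets["propionate"]]].sum(axis=0).mean()
                    if any(s in sets["propionate"] for s in species) else 0.0
                ),
            }
        by_order = pd.DataFrame.from_dict(rows, orient="index")
        by_order.index.name = "order"

    return CommunitySummary(per_sample, per_sample_share, stats, by_order, sets)


def dominance_set(
    table: AbundanceTable,
    calls: pd.DataFrame,
    share: float = 0.80,
    category: str = "butyrate",
) -> tuple[str, ...]:
    """Smallest prefix of producers (by mean abundance, descending; ties
    lexicographic) whose cumulative share of total producer abundance
    reaches ``share``."""
    if not 0 < share <= 1:
        raise ValueError("share must be in (0, 1]")
    producers = _producer_sets(calls)[category]
    means = table.data.mean(axis=1)
    means = means[[s for s in means.index if s in producers]]
    means = means[means > 0]
    total = float(means.sum())
    if total == 0.0 or means.empty:
        warnings.warn(f"no {category} producers with positive abundance")
        return ()
    ordered = means.sort_index().sort_values(ascending=False, kind="stable")
    cum = 0.0
    chosen = []
    for species, val in ordered.items():
        chosen.append(species)
        cum += float(val)
        if cum / total >= share - 1e-12:
            break
    return tuple(chosen)


def overlap_report(
    n_butyrate: int, n_propionate: int, n_both: int
) -> tuple[int, int]:
    """Exclusive producer counts from totals and the overlap."""
    if min(n_butyrate, n_propionate, n_both) < 0:
        raise ValueError("counts must be non-negative")
    if n_both > min(n_butyrate, n_propionate):
        raise ValueError("overlap exceeds a category total")
    return n_butyrate - n_both, n_propionate - n_both


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def completeness_report(counts, total: int):
    """Percentages (half-up, one decimal) of bin counts over a total.

    ``counts`` may be a single count, a sequence or a mapping; the return
    mirrors the input shape.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if isinstance(counts, Mapping):
        if sum(counts.values()) > total:
            raise ValueError("bin counts exceed total")
        return {k: _round_half_up(100.0 * v / total) for k, v in counts.items()}
    if isinstance(counts, (list, tuple)):
        if sum(counts) > total:
            raise ValueError("bin counts exceed total")
        return type(counts)(_round_half_up(100.0 * v / total) for v in counts)
    if counts > total:
        raise ValueError("count exceeds total")
    return _round_half_up(100.0 * counts / total)


def top_species(
    table: AbundanceTable,
    n: int,
    taxa: Sequence[TaxonRecord] | None = None,
    calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Top-n species by mean abundance, with max abundance, order labels and
    producer flags where available. Ties break lexicographically, so the
    ranking is stable under sample permutation."""
    if n > len(table.species):
        raise ValueError("n exceeds number of species")
    df = table.data
    out = pd.DataFrame(
        {"mean_abundance": df.mean(axis=1), "max_abundance": df.max(axis=1)}
    )
    out = out.sort_index().sort_values(
        "mean_abundance", ascending=False, kind="stable"
    ).head(n)
    out.index.name = "species"
    if taxa is not None:
        order_of = {t.species_id: t.ranks["order"] for t in taxa}
        rs_of = {t.species_id: t.rs_flag for t in taxa}
        out["order"] = [order_of.get(s, "") for s in out.index]
        out["rs_flag"] = [rs_of.get(s, False) for s in out.index]
    if calls is not None:
        sets = _producer_sets(calls)
        out["butyrate"] = [s in sets["butyrate"] for s in out.index]
        out["propionate"] = [s in sets["propionate"] for s in out.index]
    return out.reset_index()
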