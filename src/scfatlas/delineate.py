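"""Threshold-based genus delineation from AAI/POCP matrices.

For every nominal genus with two or more species, the minimum pairwise AAI
(minAAI) and POCP (minPOCP) over its members decide its group:

- **A**: minAAI >= 65 and minPOCP >= 50 (genus coherent under both indices);
- **B**: minAAI >= 65 only;
- **C**: minPOCP >= 50 only;
- **D**: neither threshold met.

Comparisons are inclusive (meeting the threshold passes). Pairs whose AAI is
undefined (no reciprocal best hits) are excluded from the AAI minimum but
counted and reported; for graph construction they count as below threshold.

For under-threshold genera the module searches for a single outlier species
whose removal restores both minima, and proposes partitions as connected
components of the within-genus graph whose edges join pairs meeting both
thresholds (each proposed cluster is re-verified against the thresholds).
GTDB polyphyly suffixes ("Blautia A", "Clostridium Q") are part of the genus
label and preserved verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_AAI_THRESHOLD = 65.0
DEFAULT_POCP_THRESHOLD = 50.0

RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")


class TaxonomyParseError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonRecord:
    species_id: str
    ranks: dict[str, str]  # rank name -> label (may be empty)
    rs_flag: bool = True

    @property
    def genus(self) -> str:
        return self.ranks["genus"]

    @property
    def species(self) -> str:
        return self.ranks["species"]

    @property
    def missing_ranks(self) -> tuple[str, ...]:
        return tuple(r for r, v in self.ranks.items() if not v)


@dataclass
class GenusVerdict:
    genus: str
    n_species: int
    members: tuple[str, ...]
    min_aai: float | None  # None when every pair's AAI is undefined
    min_pocp: float | None
    n_undefined_aai_pairs: int
    group: str  # A | B | C | D | singleton
    outliers: tuple[str, ...] = ()
    proposed_partitions: tuple[tuple[str, ...], ...] = ()
    unresolved: tuple[str, ...] = ()


def parse_gtdb_taxonomy(s: str) -> dict[str, str]:
    """Parse a GTDB seven-rank taxonomy string into rank -> label.

    Prefix order d__;p__;c__;o__;f__;g__;s__ is enforced; empty labels are
    allowed (and surface via ``TaxonRecord.missing_ranks``). Polyphyly
    suffixes are kept verbatim.
    """
    parts = [p.strip() for p in s.split(";")]
    if len(parts) != 7:
        raise TaxonomyParseError(f"expected 7 ranks, got {len(parts)}: {s!r}")
    ranks = {}
    for part, prefix, rank in zip(parts, RANK_PREFIXES, RANK_NAMES):
        if not part.startswith(prefix):
            raise TaxonomyParseError(
                f"rank {rank} must start with {prefix!r}, got {part!r}"
            )
        ranks[rank] = part[len(prefix):].strip()
    return ranks


def read_taxonomy_tsv(path: str | Path) -> list[TaxonRecord]:
    """Read a taxonomy TSV: ``species_id``, ``gtdb_taxonomy``, ``rs_flag``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"species_id", "gtdb_taxonomy"}
    if not required <= set(df.columns):
        raise ValueError(f"taxonomy TSV needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        rs = bool(row["rs_flag"]) if "rs_flag" in df.columns else True
        records.append(
            TaxonRecord(
                species_id=str(row["species_id"]),
                ranks=parse_gtdb_taxonomy(row["gtdb_taxonomy"]),
                rs_flag=rs,
            )
        )
    if len({r.species_id for r in records}) != len(records):
        raise ValueError("duplicate species IDs in taxonomy")
    return records


def _check_members(members: Sequence[str], matrix: pd.DataFrame) -> None:
    missing = [m for m in members if m not in matrix.index]
    if missing:
        raise KeyError(f"species missing from matrix: {missing}")


def genus_min_stats(
    members: Sequence[str],
    aai: pd.DataFrame,
    pocp: pd.DataFrame,
) -> tuple[float | None, float | None, int]:
    """Minimum AAI and POCP over all unordered member pairs.

    Undefined (NaN) AAI pairs are excluded from the AAI minimum; their count
    is returned so callers can report them rather than guess.
    """
    if len(members) < 2:
        raise ValueError("need at least two members")
    _check_members(members, aai)
    _check_members(members, pocp)
    aai_vals, pocp_vals = [], []
    n_undef = 0
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            v = aai.at[a, b]
            if np.isnan(v):
                n_undef += 1
            else:
                aai_vals.append(float(v))
            pocp_vals.append(float(pocp.at[a, b]))
    min_aai = min(aai_vals) if aai_vals else None
    min_pocp = min(pocp_vals) if pocp_vals else None
    return min_aai, min_pocp, n_undef


def classify_genus(
    min_aai: float | None,
    min_pocp: float,
    aai_threshold: float = DEFAULT_AAI_THRESHOLD,
    pocp_threshold: float = DEFAULT_POCP_THRESHOLD,
) -> str:
    """Group A/B/C/D by inclusive threshold comparison.

    An undefined minAAI (all pairs undefined) is classified from POCP alone:
    C when POCP passes, D otherwise — callers flag this separately.
    """
    pocp_ok = min_pocp >= pocp_threshold
    if min_aai is None:
        return "C" if pocp_ok else "D"
    aai_ok = min_aai >= aai_threshold
    if aai_ok and pocp_ok:
        return "A"
    if aai_ok:
        return "B"
    if pocp_ok:
        return "C"
    return "D"


def _pair_meets(
    a: str, b: str, aai: pd.DataFrame, pocp: pd.DataFrame,
    aai_threshold: float, pocp_threshold: float,
) -> bool:
    """Edge predicate: both indices at/above threshold; undefined AAI fails."""
    v = aai.at[a, b]
    if np.isnan(v):
        return False
    return v >= aai_threshold and pocp.at[a, b] >= pocp_threshold


def find_outliers(
    members: Sequence[str],
    aai: pd.DataFrame,
    pocp: pd.DataFrame,
    aai_threshold: float = DEFAULT_AAI_THRESHOLD,
    pocp_threshold: float = DEFAULT_POCP_THRESHOLD,
) -> tuple[str, ...]:
    """Species whose single removal lifts both genus minima above thresholds.

    Only meaningful for genera already failing a threshold (groups B/C/D);
    calling it on a passing genus is a precondition violation.
    """
    min_aai, min_pocp, _ = genus_min_stats(members, aai, pocp)
    if classify_genus(min_aai, min_pocp) == "A":
        raise ValueError("genus already meets both thresholds")
    if len(members) < 3:
        return ()
    rescuers = []
    for excluded in members:
        rest = [m for m in members if m != excluded]
        if len(rest) < 2:
            continue
        ma, mp, n_undef = genus_min_stats(rest, aai, pocp)
        if (
            ma is not None and n_undef == 0
            and classify_genus(ma, mp, aai_threshold, pocp_threshold) == "A"
        ):
            rescuers.append(excluded)
    return tuple(sorted(rescuers))


def propose_partitions(
    members: Sequence[str],
    aai: pd.DataFrame,
    pocp: pd.DataFrame,
    aai_threshold: float = DEFAULT_AAI_THRESHOLD,
    pocp_threshold: float = DEFAULT_POCP_THRESHOLD,
) -> tuple[tuple[tuple[str, ...], ...], tuple[str, ...]]:
    """Partition a genus into clusters via the threshold graph.

    Edges join member pairs meeting both thresholds; connected components are
    candidate clusters. Every multi-member cluster is re-verified internally
    (its own minima must pass); clusters failing verification are returned as
    unresolved members rather than proposed.
    """
    if len(members) < 3:
        raise ValueError("need at least three members to propose partitions")
    g = nx.Graph()
    g.add_nodes_from(members)
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if _pair_meets(a, b, aai, pocp, aai_threshold, pocp_threshold):
                g.add_edge(a, b)
    clusters, unresolved = [], []
    for comp in nx.connected_components(g):
        comp = tuple(sorted(comp))
        if len(comp) == 1:
            clusters.append(comp)
            continue
        ma, mp, n_undef = genus_min_stats(list(comp), aai, pocp)
        ok = (
            ma is not None and n_undef == 0
            and classify_genus(ma, mp, aai_threshold, pocp_threshold) == "A"
        )
        if ok:
            clusters.append(comp)
        else:
            unresolved.extend(comp)
    clusters.sort()
    return tuple(clusters), tuple(sorted(unresolved))


def delineate(
    taxa: Sequence[TaxonRecord],
    aai: pd.DataFrame,
    pocp: pd.DataFrame,
    aai_threshold: float = DEFAULT_AAI_THRESHOLD,
    pocp_threshold: float = DEFAULT_POCP_THRESHOLD,
) -> tuple[list[GenusVerdict], dict]:
    """One verdict per genus plus summary counts (singletons and groups A-D).

    Singleton + A + B + C + D always sums to the number of genera.
    """
    by_genus: dict[str, list[str]] = {}
    for t in taxa:
        if not t.genus:
            raise ValueError(f"{t.species_id}: empty genus label")
        by_genus.setdefault(t.genus, []).append(t.species_id)
    verdicts = []
    for genus in sorted(by_genus):
        members = tuple(sorted(by_genus[genus]))
        if len(members) == 1:
            verdicts.append(
                GenusVerdict(genus, 1, members, None, None, 0, "singleton")
            )
            continue
        min_aai, min_pocp, n_undef = genus_min_stats(list(members), aai, pocp)
        group = classify_genus(min_aai, min_pocp, aai_threshold, pocp_threshold)
        outliers: tuple[str, ...] = ()
        partitions: tuple[tuple[str, ...], ...] = ()
        unresolved: tuple[str, ...] = ()
        if group != "A":
            outliers = find_outliers(
                list(members), aai, pocp, aai_threshold, pocp_threshold
            )
            if len(members) >= 3:
                partitions, unresolved = propose_partitions(
                    list(members), aai, pocp, aai_threshold, pocp_threshold
                )
        verdicts.append(
            GenusVerdict(
                genus, len(members), members, min_aai, min_pocp, n_undef,
                group, outliers, partitions, unresolved,
            )
        )
    counts = {"singleton": 0, "A": 0, "B": 0, "C": 0, "D": 0}
    for v in verdicts:
        counts[v.group] += 1
    summary = {
        "n_genera": len(verdicts),
        "n_singletons": counts["singleton"],
        "n_multi": len(verdicts) - counts["singleton"],
        "groups": {g: counts[g] for g in "ABCD"},
        "aai_threshold": aai_threshold,
        "pocp_threshold": pocp_threshold,
    }
    assert summary["n_singletons"] + sum(summary["groups"].values()) == summary["n_genera"]
    return verdicts, summary


def family_min_aai(
    taxa: Sequence[TaxonRecord], aai: pd.DataFrame
) -> pd.DataFrame:
    """Lowest pairwise AAI within each family (>=2 members), with the count
    of undefined pairs reported separately rather than folded in."""
    by_family: dict[str, list[str]] = {}
    for t in taxa:
        fam = t.ranks["family"]
        if fam:
            by_family.setdefault(fam, []).append(t.species_id)
    rows = []
    for fam in sorted(by_family):
        members = sorted(by_family[fam])
        if len(members) < 2:
            continue
        vals, n_undef = [], 0
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                v = aai.at[a, b]
                if np.isnan(v):
                    n_undef += 1
                else:
                    vals.append(float(v))
        rows.append(
            {
                "family": fam,
                "n_species": len(members),
                "min_aai": min(vals) if vals else np.nan,
                "n_undefined_pairs": n_undef,
            }
        )
    return pd.DataFrame(rows)


def merged_genus_report(
    taxa: Sequence[TaxonRecord],
    aai: pd.DataFrame,
    pocp: pd.DataFrame,
    aai_threshold: float = DEFAULT_AAI_THRESHOLD,
    pocp_threshold: float = DEFAULT_POCP_THRESHOLD,
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Cross-genus merge candidates: connected components of the global
    threshold graph that span more than one nominal genus label. Returns
    (component species, distinct genus labels) pairs; no renaming attempted."""
    genus_of = {t.species_id: t.genus for t in taxa}
    species = sorted(genus_of)
    g = nx.Graph()
    g.add_nodes_from(species)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            if _pair_meets(a, b, aai, pocp, aai_threshold, pocp_threshold):
                g.add_edge(a, b)
    merges = []
    for comp in nx.connected_components(g):
        genera = sorted({genus_of[s] for s in comp})
        if len(genera) > 1:
            merges.append((tuple(sorted(comp)), tuple(genera)))
    merges.sort()
    return merges


def verdicts_to_frame(verdicts: Iterable[GenusVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        rows.append(
            {
                "genus": v.genus,
                "n_species": v.n_species,
                "min_aai": np.nan if v.min_aai is None else v.min_aai,
                "min_pocp": np.nan if v.min_pocp is None else v.min_pocp,
                "n_undefined_aai_pairs": v.n_undefined_aai_pairs,
                "group": v.group,
                "outliers": ",".join(v.outliers),
                "proposed_partitions": ";".join(
                    ",".join(c) for c in v.proposed_partitions
                ),
                "unresolved": ",".join(v.unresolved),
            }
        )
    return pd.DataFrame(rows)


def load_published_genus_groups() -> pd.DataFrame:
    """Packaged transcription of the published genus-group table (A-D)."""
    ref = resources.files("scfatlas").joinpath("data/published_genus_groups.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
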