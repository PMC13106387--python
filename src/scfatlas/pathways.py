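"""Declarative SCFA pathway catalog and completeness rule engine.

The engine consumes per-genome reaction *presence/absence* (a ``ReactionProfile``
is just a genome ID plus the set of metabolic blocks detected in it) and calls
butyrate/propionate production capability:

- butyrate requires the crotonyl-CoA -> butyryl-CoA gateway (``TB_bcd``), at
  least one complete route yielding crotonyl-CoA (acetyl-CoA, succinate
  semialdehyde, glutarate or lysine), and at least one terminal branch
  (*but* or *buk*);
- propionate requires at least one complete route yielding propionyl-CoA
  (succinate, acrylate or propanediol) and at least one terminal branch
  (phosphate propionyltransferase + propionate kinase, or
  propionyl-CoA:lactate/acetate transferase).

``max_missing`` relaxes "complete" to "at most N blocks missing" per pathway
(0 = strictly complete, 1 = the near-complete convention of counting pathways
lacking one metabolic block). Terminal *but*/*buk* branches present without
the upstream machinery are flagged as orphans, never counted as producers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

VALID_ROLES = {"route", "terminal", "crossfeed"}

BUTYRATE_ROUTES = ("B1_acetylCoA", "B2_succinate_semialdehyde", "B3_glutarate", "B4_lysine")
PROPIONATE_ROUTES = ("P1_succinate", "P2_acrylate", "P3_propanediol")
BUTYRATE_GATEWAY = "TB_bcd"
BUTYRATE_TERMINALS = ("TB_but", "TB_buk")
PROPIONATE_TERMINALS = ("TP_pta_pk", "TP_ct")
ACETATE_CROSSFEED = ("XF_acetate_akpta", "XF_acetate_acs")
LACTATE_CROSSFEED = "XF_lactate"

_TERMINAL_SHORT = {"TB_but": "but", "TB_buk": "buk", "TP_pta_pk": "pta_pk", "TP_ct": "ct"}


class CatalogError(ValueError):
    """Raised on schema violations, duplicate IDs or unknown references."""


@dataclass(frozen=True)
class Block:
    block_id: str
    name: str
    ec: str | None = None


@dataclass(frozen=True)
class PathwayDef:
    pathway_id: str
    name: str
    role: str  # route | terminal | crossfeed
    product: str
    blocks: tuple[str, ...]  # ordered block IDs


@dataclass
class PathwayCatalog:
    blocks: dict[str, Block]
    pathways: dict[str, PathwayDef]
    description: str = ""

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        for pw in self.pathways.values():
            if pw.role not in VALID_ROLES:
                raise CatalogError(f"{pw.pathway_id}: invalid role {pw.role!r}")
            if not pw.product:
                raise CatalogError(f"{pw.pathway_id}: missing product metabolite")
            if not pw.blocks:
                raise CatalogError(f"{pw.pathway_id}: empty block list")
            for bid in pw.blocks:
                if bid not in self.blocks:
                    raise CatalogError(f"{pw.pathway_id}: unknown block {bid!r}")

    def validate_engine_ids(self) -> None:
        """Check the pathway IDs the producer rules key off are all present."""
        needed = (
            set(BUTYRATE_ROUTES) | set(PROPIONATE_ROUTES) | {BUTYRATE_GATEWAY}
            | set(BUTYRATE_TERMINALS) | set(PROPIONATE_TERMINALS)
            | set(ACETATE_CROSSFEED) | {LACTATE_CROSSFEED}
        )
        missing = needed - set(self.pathways)
        if missing:
            raise CatalogError(f"catalog lacks engine pathways: {sorted(missing)}")

    def all_block_ids(self) -> set[str]:
        return set(self.blocks)

    def to_dict(self) -> dict:
        return {
            "description": self.description,
            "blocks": {
                b.block_id: {"name": b.name, **({"ec": b.ec} if b.ec else {})}
                for b in self.blocks.values()
            },
            "pathways": [
                {
                    "pathway_id": p.pathway_id,
                    "name": p.name,
                    "role": p.role,
                    "product": p.product,
                    "blocks": list(p.blocks),
                }
                for p in self.pathways.values()
            ],
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _catalog_from_dict(data: Mapping) -> PathwayCatalog:
    try:
        raw_blocks = data["blocks"]
        raw_pathways = data["pathways"]
    except KeyError as exc:
        raise CatalogError(f"catalog missing top-level key: {exc}") from exc
    blocks: dict[str, Block] = {}
    for bid, spec in raw_blocks.items():
        if bid in blocks:
            raise CatalogError(f"duplicate block ID {bid!r}")
        blocks[bid] = Block(block_id=bid, name=spec.get("name", bid), ec=spec.get("ec"))
    pathways: dict[str, PathwayDef] = {}
    for spec in raw_pathways:
        try:
            pid = spec["pathway_id"]
            pw = PathwayDef(
                pathway_id=pid,
                name=spec.get("name", pid),
                role=spec["role"],
                product=spec["product"],
                blocks=tuple(spec["blocks"]),
            )
        except KeyError as exc:
            raise CatalogError(f"pathway entry missing key {exc}") from exc
        if pid in pathways:
            raise CatalogError(f"duplicate pathway ID {pid!r}")
        pathways[pid] = pw
    return PathwayCatalog(blocks=blocks, pathways=pathways,
                          description=data.get("description", ""))


def load_catalog(path: str | Path | None = None) -> PathwayCatalog:
    """Load a pathway catalog from JSON; with no path, the packaged default."""
    if path is None:
        ref = resources.files("scfatlas").joinpath("data/pathway_catalog.json")
        data = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            data = json.load(fh)
    catalog = _catalog_from_dict(data)
    if path is None:
        catalog.validate_engine_ids()
    return catalog


@dataclass
class ReactionProfile:
    """Per-genome presence set of metabolic blocks (the GapSeq-style output)."""

    genome_id: str
    blocks: frozenset[str]

    @classmethod
    def validated(cls, genome_id: str, blocks: Iterable[str],
                  catalog: PathwayCatalog) -> "ReactionProfile":
        blocks = frozenset(blocks)
        unknown = blocks - catalog.all_block_ids()
        if unknown:
            raise CatalogError(f"{genome_id}: unknown block IDs {sorted(unknown)}")
        return cls(genome_id=genome_id, blocks=blocks)


@dataclass(frozen=True)
class PathwayCall:
    pathway_id: str
    status: str  # complete | near_complete | incomplete
    missing: tuple[str, ...]  # in catalog order


@dataclass(frozen=True)
class ProducerCall:
    genome_id: str
    butyrate: bool
    propionate: bool
    butyrate_routes: frozenset[str]
    butyrate_terminals: frozenset[str]  # subset of {"but", "buk"}
    propionate_routes: frozenset[str]
    propionate_terminals: frozenset[str]  # subset of {"pta_pk", "ct"}
    acetate_crossfeed: bool
    lactate_crossfeed: bool
    orphan_but: bool  # but/buk branch complete without the bcd gateway
    max_missing: int


def evaluate_pathway(profile: ReactionProfile, pathway: PathwayDef) -> PathwayCall:
    """Completeness of one pathway: 0 missing blocks -> complete, exactly one
    -> near_complete, two or more -> incomplete."""
    missing = tuple(b for b in pathway.blocks if b not in profile.blocks)
    if not missing:
        status = "complete"
    elif len(missing) == 1:
        status = "near_complete"
    else:
        status = "incomplete"
    return PathwayCall(pathway.pathway_id, status, missing)


def _passes(profile: ReactionProfile, catalog: PathwayCatalog,
            pathway_id: str, max_missing: int) -> bool:
    call = evaluate_pathway(profile, catalog.pathways[pathway_id])
    return len(call.missing) <= max_missing


def crossfeed_flags(profile: ReactionProfile, catalog: PathwayCatalog) -> dict[str, bool]:
    """Acetate/lactate utilisation capability (strict completeness)."""
    acetate = any(_passes(profile, catalog, pid, 0) for pid in ACETATE_CROSSFEED)
    lactate = _passes(profile, catalog, LACTATE_CROSSFEED, 0)
    return {"acetate": acetate, "lactate": lactate}


def classify_producer(profile: ReactionProfile, catalog: PathwayCatalog,
                      max_missing: int = 0) -> ProducerCall:
    """Final butyrate/propionate producer call for one genome."""
    if max_missing not in (0, 1):
        raise ValueError("max_missing must be 0 or 1")
    but_routes = frozenset(
        pid for pid in BUTYRATE_ROUTES if _passes(profile, catalog, pid, max_missing)
    )
    but_terms = frozenset(
        _TERMINAL_SHORT[pid]
        for pid in BUTYRATE_TERMINALS
        if _passes(profile, catalog, pid, max_missing)
    )
    gateway_ok = _passes(profile, catalog, BUTYRATE_GATEWAY, max_missing)
    butyrate = gateway_ok and bool(but_routes) and bool(but_terms)

    prop_routes = frozenset(
        pid for pid in PROPIONATE_ROUTES if _passes(profile, catalog, pid, max_missing)
    )
    prop_terms = frozenset(
        _TERMINAL_SHORT[pid]
        for pid in PROPIONATE_TERMINALS
        if _passes(profile, catalog, pid, max_missing)
    )
    propionate = bool(prop_routes) and bool(prop_terms)

    # Orphan: a finished but/buk branch with no bcd gateway (strictly present),
    # so crotonyl-CoA can never be reduced; reported, never a producer.
    strict_terms = any(_passes(profile, catalog, pid, 0) for pid in BUTYRATE_TERMINALS)
    orphan = strict_terms and not _passes(profile, catalog, BUTYRATE_GATEWAY, 0)

    xf = crossfeed_flags(profile, catalog)
    return ProducerCall(
        genome_id=profile.genome_id,
        butyrate=butyrate,
        propionate=propionate,
        butyrate_routes=but_routes if butyrate else frozenset(),
        butyrate_terminals=but_terms if butyrate else frozenset(),
        propionate_routes=prop_routes if propionate else frozenset(),
        propionate_terminals=prop_terms if propionate else frozenset(),
        acetate_crossfeed=xf["acetate"],
        lactate_crossfeed=xf["lactate"],
        orphan_but=orphan,
        max_missing=max_missing,
    )


def batch_classify(
    profiles: Sequence[ReactionProfile],
    catalog: PathwayCatalog,
    max_missing: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Classify a cohort; returns the per-genome table and summary counts.

    Summary invariants hold by construction: ``n_both <= min(n_butyrate,
    n_propionate)`` and exclusive counts are totals minus both.
    """
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome IDs in profile list")
    calls = [classify_producer(p, catalog, max_missing) for p in profiles]
    rows = []
    for c in calls:
        rows.append(
            {
                "genome_id": c.genome_id,
                "butyrate": c.butyrate,
                "propionate": c.propionate,
                "butyrate_routes": ",".join(sorted(c.butyrate_routes)),
                "butyrate_terminals": ",".join(sorted(c.butyrate_terminals)),
                "propionate_routes": ",".join(sorted(c.propionate_routes)),
                "propionate_terminals": ",".join(sorted(c.propionate_terminals)),
                "acetate_crossfeed": c.acetate_crossfeed,
                "lactate_crossfeed": c.lactate_crossfeed,
                "orphan_but": c.orphan_but,
                "max_missing": c.max_missing,
            }
        )
    table = pd.DataFrame(rows)
    n_but = sum(c.butyrate for c in calls)
    n_prop = sum(c.propionate for c in calls)
    n_both = sum(c.butyrate and c.propionate for c in calls)
    route_counts = {
        pid: sum(pid in c.butyrate_routes for c in calls) for pid in BUTYRATE_ROUTES
    }
    route_counts.update(
        {pid: sum(pid in c.propionate_routes for c in calls) for pid in PROPIONATE_ROUTES}
    )
    terminal_counts = {
        "but": sum("but" in c.butyrate_terminals for c in calls),
        "buk": sum("buk" in c.butyrate_terminals for c in calls),
        "pta_pk": sum("pta_pk" in c.propionate_terminals for c in calls),
        "ct": sum("ct" in c.propionate_terminals for c in calls),
    }
    summary = {
        "n_genomes": len(calls),
        "n_butyrate": n_but,
        "n_propionate": n_prop,
        "n_both": n_both,
        "n_butyrate_only": n_but - n_both,
        "n_propionate_only": n_prop - n_both,
        "n_orphan_but": sum(c.orphan_but for c in calls),
        "n_acetate_crossfeed": sum(c.acetate_crossfeed for c in calls),
        "n_lactate_crossfeed": sum(c.lactate_crossfeed for c in calls),
        "route_counts": route_counts,
        "terminal_counts": terminal_counts,
        "max_missing": max_missing,
    }
    return table, summary


def read_profiles_tsv(path: str | Path, catalog: PathwayCatalog) -> list[ReactionProfile]:
    """Read reaction profiles from TSV, wide (genome x block, 0/1) or long
    (``genome_id``, ``block_id``) — detected from the header."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) == ["genome_id", "block_id"] and df.shape[1] == 2:
        grouped = df.groupby("genome_id")["block_id"].apply(list)
        return [
            ReactionProfile.validated(gid, blocks, catalog)
            for gid, blocks in grouped.items()
        ]
    if df.columns[0] != "genome_id":
        raise ValueError("profile TSV must start with a genome_id column")
    df = df.set_index("genome_id")
    profiles = []
    for gid, row in df.iterrows():
        present = [bid for bid, v in row.items() if int(v) == 1]
        profiles.append(ReactionProfile.validated(str(gid), present, catalog))
    return profiles


def profiles_to_wide_frame(
    profiles: Sequence[ReactionProfile], catalog: PathwayCatalog
) -> pd.DataFrame:
    block_ids = sorted(catalog.all_block_ids())
    rows = [
        {"genome_id": p.genome_id, **{b: int(b in p.blocks) for b in block_ids}}
        for p in profiles
    ]
    return pd.DataFrame(rows)
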