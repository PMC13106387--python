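"""Synthetic proteomes, reaction profiles and abundance tables with ground truth.

Every downstream stage of the pipeline is exercised against data generated
here, where the answer is known by construction:

- **Proteome pairs** with a planted shared-ortholog fraction and per-ortholog
  target identity. Orthologs are linked by point substitutions only (each
  mutated position gets a uniformly random *different* residue), so realized
  identity is directly countable; pair simulation substitutes an exact count
  of positions so every ortholog's realized identity sits within half a
  residue of the target. Unique proteins are independent random sequences
  with no planted homology.
- **Reaction profiles** with planted producer labels: a genome's profile is
  exactly the block set of its planted pathways, with independent per-block
  dropout at a chosen rate.
- **Abundance tables**: symmetric Dirichlet compositions on the percent scale
  (columns sum to 100), so the expected abundance share of any species group
  equals its fraction of the species list.

Default label frequencies for producer cohorts follow the observed prevalence
of butyrate/propionate capability among gut Clostridia species (roughly 23%
butyrate-only, 10% propionate-only, 4% both). All generators take a single
integer seed; sub-streams are derived deterministically from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Proteome, write_proteome, write_tsv
from .pathways import (
    BUTYRATE_GATEWAY,
    BUTYRATE_ROUTES,
    BUTYRATE_TERMINALS,
    PROPIONATE_ROUTES,
    PROPIONATE_TERMINALS,
    CatalogError,
    PathwayCatalog,
    ReactionProfile,
    load_catalog,
    profiles_to_wide_frame,
)
from .profiling import AbundanceTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

#: Default planted label frequencies for producer cohorts (study prevalence).
DEFAULT_LABEL_PROBS: dict[str, float] = {
    "butyrate": 0.233,
    "propionate": 0.095,
    "both": 0.041,
    "neither": 0.631,
}

LABELS = ("butyrate", "propionate", "both", "neither")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Uniform random protein over the 20 canonical residues."""
    if length < 1:
        raise ValueError("length must be positive")
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate(seq: str, identity: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) >= identity
    n = int(hit.sum())
    if n:
        # offset 1..19 from the current residue's alphabet index: always a
        # different residue, uniform over the other 19
        idx = np.searchsorted(_AA_ARR, arr[hit])
        new_idx = (idx + rng.integers(1, 20, size=n)) % 20
        arr[hit] = _AA_ARR[new_idx]
    return arr.tobytes().decode()


def _mutate_exact(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute an exact count of positions, ``round((1 - identity) * L)``,
    so realized identity sits within half a position of the target."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_mut = int(round((1.0 - identity) * arr.size))
    if n_mut:
        pos = rng.choice(arr.size, size=n_mut, replace=False)
        idx = np.searchsorted(_AA_ARR, arr[pos])
        new_idx = (idx + rng.integers(1, 20, size=n_mut)) % 20
        arr[pos] = _AA_ARR[new_idx]
    return arr.tobytes().decode()


def mutate_protein(seq: str, identity: float, seed: int) -> str:
    """Substitute each position independently with probability ``1 - identity``.

    The returned string has the same length, and the expected fraction of
    positions equal to the input is exactly ``identity``.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    if not seq:
        raise ValueError("sequence must be non-empty")
    if set(seq) - set(AMINO_ACIDS):
        raise ValueError("sequence must use the 20 canonical residues")
    return _mutate(seq, identity, _rng(seed))


@dataclass(frozen=True)
class ProteomePairTruth:
    """Planted structure of a synthetic proteome pair."""

    n_orthologs: int
    n_unique_a: int
    n_unique_b: int
    target_identity: float
    length_range: tuple[int, int] = (150, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_orthologs, self.n_unique_a, self.n_unique_b) < 0:
            raise ValueError("counts must be non-negative")
        if not 0 < self.target_identity <= 1:
            raise ValueError("target_identity must be in (0, 1]")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length_range")


def simulate_proteome_pair(
    truth: ProteomePairTruth,
    genome_a: str = "GENOME_A",
    genome_b: str = "GENOME_B",
) -> tuple[Proteome, Proteome, dict[str, str]]:
    """Two proteomes sharing ``n_orthologs`` planted ortholog pairs.

    Returns the proteomes and the truth map (A protein ID -> B protein ID).
    Byte-identical output for identical truth and genome IDs.
    """
    rng = _rng(truth.seed)
    lo, hi = truth.length_range
    a_prot: dict[str, str] = {}
    b_prot: dict[str, str] = {}
    ortho_map: dict[str, str] = {}
    for i in range(truth.n_orthologs):
        length = int(rng.integers(lo, hi + 1))
        seq = random_protein(length, rng)
        aid = f"{genome_a}_orth{i:04d}"
        bid = f"{genome_b}_orth{i:04d}"
        a_prot[aid] = seq
        b_prot[bid] = _mutate_exact(seq, truth.target_identity, rng)
        ortho_map[aid] = bid
    for i in range(truth.n_unique_a):
        length = int(rng.integers(lo, hi + 1))
        a_prot[f"{genome_a}_uniq{i:04d}"] = random_protein(length, rng)
    for i in range(truth.n_unique_b):
        length = int(rng.integers(lo, hi + 1))
        b_prot[f"{genome_b}_uniq{i:04d}"] = random_protein(length, rng)
    return (
        Proteome(genome_a, a_prot),
        Proteome(genome_b, b_prot),
        ortho_map,
    )


@dataclass(frozen=True)
class ProfileTruth:
    """Planted producer label and pathway content of one synthetic genome."""

    genome_id: str
    planted_label: str  # butyrate | propionate | both | neither
    planted_routes: tuple[str, ...]  # pathway IDs, terminals included
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.planted_label not in LABELS:
            raise ValueError(f"unknown label {self.planted_label!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


def make_profile_truth(
    genome_id: str,
    label: str,
    rng: np.random.Generator,
    dropout_rate: float = 0.0,
) -> ProfileTruth:
    """Plant a random route/terminal combination consistent with ``label``."""
    pathways: list[str] = []
    if label in ("butyrate", "both"):
        pathways.append(str(rng.choice(BUTYRATE_ROUTES)))
        pathways.append(BUTYRATE_GATEWAY)
        pathways.append(str(rng.choice(BUTYRATE_TERMINALS)))
    if label in ("propionate", "both"):
        pathways.append(str(rng.choice(PROPIONATE_ROUTES)))
        pathways.append(str(rng.choice(PROPIONATE_TERMINALS)))
    return ProfileTruth(genome_id, label, tuple(pathways), dropout_rate)


def simulate_reaction_profiles(
    truths: Sequence[ProfileTruth],
    catalog: PathwayCatalog | None = None,
    seed: int = 0,
) -> list[ReactionProfile]:
    """Block sets of the planted pathways, with independent per-block dropout."""
    catalog = catalog if catalog is not None else load_catalog()
    rng = _rng(seed)
    profiles = []
    for truth in truths:
        unknown = set(truth.planted_routes) - set(catalog.pathways)
        if unknown:
            raise CatalogError(
                f"{truth.genome_id}: planted pathways not in catalog: {sorted(unknown)}"
            )
        blocks = sorted(
            {b for pid in truth.planted_routes for b in catalog.pathways[pid].blocks}
        )
        if truth.dropout_rate > 0 and blocks:
            keep = rng.random(len(blocks)) >= truth.dropout_rate
            blocks = [b for b, k in zip(blocks, keep) if k]
        profiles.append(ReactionProfile.validated(truth.genome_id, blocks, catalog))
    return profiles


def simulate_producer_cohort(
    n_genomes: int,
    seed: int = 0,
    label_probs: Mapping[str, float] | None = None,
    dropout_rate: float = 0.0,
) -> list[ProfileTruth]:
    """Planted truths for a cohort, labels drawn at the default (study-like)
    frequencies unless overridden."""
    probs = dict(DEFAULT_LABEL_PROBS if label_probs is None else label_probs)
    p = np.array([probs[label] for label in LABELS], dtype=float)
    p = p / p.sum()
    rng = _rng(seed)
    labels = rng.choice(LABELS, size=n_genomes, p=p)
    return [
        make_profile_truth(f"G{i:05d}", str(label), rng, dropout_rate)
        for i, label in enumerate(labels)
    ]


def simulate_abundance_table(
    n_samples: int,
    species: Sequence[str],
    concentration: float = 1.0,
    seed: int = 0,
) -> AbundanceTable:
    """Symmetric Dirichlet compositions, percent scale (columns sum to 100)."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if len(species) < 1:
        raise ValueError("need at least one species")
    if len(set(species)) != len(species):
        raise ValueError("duplicate species names")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = _rng(seed)
    draws = rng.dirichlet([concentration] * len(species), size=n_samples).T * 100.0
    df = pd.DataFrame(
        draws,
        index=list(species),
        columns=[f"S{j:04d}" for j in range(n_samples)],
    )
    return AbundanceTable(df)


# ---------------------------------------------------------------------------
# Full synthetic community: genus structure + proteomes + profiles + abundances
# ---------------------------------------------------------------------------

_SYNTH_ORDERS = ("Oscillospirales", "Lachnospirales", "Christensenellales")


@dataclass
class CommunityTruth:
    """Everything planted into a synthetic community, for downstream checks."""

    proteomes: list[Proteome]
    taxonomy: pd.DataFrame  # species_id, gtdb_taxonomy, rs_flag
    genus_of: dict[str, str]
    within_genus_identity: dict[str, float]
    profile_truths: list[ProfileTruth]
    profiles: list[ReactionProfile]
    abundance: AbundanceTable
    config: dict = field(default_factory=dict)

    @property
    def label_of(self) -> dict[str, str]:
        return {t.genome_id: t.planted_label for t in self.profile_truths}

    def expected_share(self, category: str) -> float:
        """Expected percent abundance of a producer category under the
        symmetric Dirichlet (fraction of labelled species x 100)."""
        labels = self.label_of
        if category == "butyrate":
            members = [g for g, l in labels.items() if l in ("butyrate", "both")]
        elif category == "propionate":
            members = [g for g, l in labels.items() if l in ("propionate", "both")]
        elif category == "both":
            members = [g for g, l in labels.items() if l == "both"]
        else:
            raise ValueError(f"unknown category {category!r}")
        return 100.0 * len(members) / len(labels)


def simulate_community(
    n_genomes: int = 30,
    n_samples: int = 10,
    seed: int = 0,
    n_proteins: int = 20,
    protein_length_range: tuple[int, int] = (80, 160),
    ortholog_fraction: float = 0.8,
    dropout_rate: float = 0.0,
    concentration: float = 5.0,
    catalog: PathwayCatalog | None = None,
) -> CommunityTruth:
    """A study-in-miniature: genomes grouped into genera with a planted
    within-genus protein identity, producer labels, reaction profiles and a
    Dirichlet abundance table.

    Genera hold 1-4 genomes; members of a genus share ``ortholog_fraction``
    of their proteins at the genus's planted identity (drawn in [0.70, 0.90])
    and carry the rest as unrelated proteins, so within-genus AAI is high and
    cross-genus AAI is undefined or far below any genus threshold.
    """
    if n_genomes < 2:
        raise ValueError("need at least two genomes")
    catalog = catalog if catalog is not None else load_catalog()
    ss = np.random.SeedSequence(seed)
    rng_tax, rng_prot, seed_profiles, rng_labels, seed_abund = (
        _rng(s) for s in ss.spawn(5)
    )

    # genus sizes 1-4 until n_genomes reached
    sizes = []
    remaining = n_genomes
    while remaining > 0:
        k = int(min(remaining, rng_tax.integers(1, 5)))
        sizes.append(k)
        remaining -= k

    genome_ids = [f"G{i:05d}" for i in range(n_genomes)]
    genus_of: dict[str, str] = {}
    within_identity: dict[str, float] = {}
    proteomes: list[Proteome] = []
    tax_rows = []
    lo, hi = protein_length_range
    n_shared = int(round(ortholog_fraction * n_proteins))
    idx = 0
    for gi, size in enumerate(sizes):
        genus = f"Genus{gi:03d}"
        identity = float(rng_tax.uniform(0.70, 0.90))
        within_identity[genus] = identity
        ancestor = [
            random_protein(int(rng_prot.integers(lo, hi + 1)), rng_prot)
            for _ in range(n_shared)
        ]
        order = _SYNTH_ORDERS[gi % len(_SYNTH_ORDERS)]
        for _ in range(size):
            gid = genome_ids[idx]
            idx += 1
            genus_of[gid] = genus
            proteins: dict[str, str] = {}
            for k, anc in enumerate(ancestor):
                proteins[f"{gid}_orth{k:04d}"] = _mutate_exact(anc, identity, rng_prot)
            for k in range(n_proteins - n_shared):
                proteins[f"{gid}_uniq{k:04d}"] = random_protein(
                    int(rng_prot.integers(lo, hi + 1)), rng_prot
                )
            proteomes.append(Proteome(gid, proteins))
            tax_rows.append(
                {
                    "species_id": gid,
                    "gtdb_taxonomy": (
                        f"d__Bacteria;p__Bacillota;c__Clostridia;o__{order};"
                        f"f__Fam{gi % 2:02d};g__{genus};s__{genus} sp{idx:06d}"
                    ),
                    "rs_flag": bool(rng_tax.random() < 0.6),
                }
            )
    taxonomy = pd.DataFrame(tax_rows)

    probs = np.array([DEFAULT_LABEL_PROBS[label] for label in LABELS])
    labels = rng_labels.choice(LABELS, size=n_genomes, p=probs / probs.sum())
    truths = [
        make_profile_truth(gid, str(label), rng_labels, dropout_rate)
        for gid, label in zip(genome_ids, labels)
    ]
    profiles = simulate_reaction_profiles(truths, catalog, seed=seed_profiles)

    abundance = simulate_abundance_table(
        n_samples, genome_ids, concentration=concentration, seed=seed_abund
    )

    config = {
        "n_genomes": n_genomes,
        "n_samples": n_samples,
        "seed": seed,
        "n_proteins": n_proteins,
        "protein_length_range": list(protein_length_range),
        "ortholog_fraction": ortholog_fraction,
        "dropout_rate": dropout_rate,
        "concentration": concentration,
    }
    return CommunityTruth(
        proteomes, taxonomy, genus_of, within_identity, truths, profiles,
        abundance, config,
    )


def write_community(truth: CommunityTruth, out_dir: str | Path) -> None:
    """Write a simulated community to disk in the pipeline's input formats."""
    out_dir = Path(out_dir)
    (out_dir / "proteomes").mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    for p in truth.proteomes:
        write_proteome(p, out_dir / "proteomes" / f"{p.genome_id}.faa")
    write_tsv(truth.taxonomy, out_dir / "taxonomy.tsv", config=cfg)
    catalog = load_catalog()
    write_tsv(
        profiles_to_wide_frame(truth.profiles, catalog),
        out_dir / "profiles.tsv",
        config=cfg,
    )
    abund = truth.abundance.data.copy()
    abund.insert(0, "name", abund.index)
    write_tsv(abund, out_dir / "abundance.tsv", config=cfg)
    truth_df = pd.DataFrame(
        [
            {
                "genome_id": t.genome_id,
                "planted_label": t.planted_label,
                "planted_routes": ",".join(t.planted_routes),
                "dropout_rate": t.dropout_rate,
                "genus": truth.genus_of[t.genome_id],
            }
            for t in truth.profile_truths
        ]
    )
    write_tsv(truth_df, out_dir / "truth.tsv", config=cfg)
    with open(out_dir / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
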