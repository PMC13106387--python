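"""Pairwise proteome relatedness: AAI and POCP from first principles.

Two protein-level indices drive prokaryotic genus delineation:

- **AAI** (average amino acid identity): the mean percent identity over
  reciprocal-best-hit (RBH) protein pairs between two proteomes.
- **POCP** (percentage of conserved proteins): ``100 x (C1 + C2) / (T1 + T2)``
  where ``C1``/``C2`` count proteins of each genome with at least one hit in
  the other passing the identity and coverage thresholds, and ``T1``/``T2``
  are the proteome sizes.

Both use Smith-Waterman local alignment (BLOSUM62, affine gaps: the first gap
residue costs 11, each further residue 1) with default thresholds of 40%
identity and 50% coverage of the shorter sequence — the conventional cutoffs
for conserved-protein detection. Alignments are computed once per unordered
proteome pair, so AAI and POCP are symmetric by construction.

AAI is *undefined* (``None``/NaN, never 0) when no RBH pair passes the
thresholds; downstream minima must exclude such pairs explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

from .io import Proteome

DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_MIN_COVERAGE = 50.0
GAP_OPEN = 11
GAP_EXTEND = 1

_BLOSUM62 = SubstitutionMatrix.std_protein_matrix()


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of one local alignment between a query and a target protein."""

    query_id: str
    target_id: str
    percent_identity: float  # identical columns / alignment columns x 100
    alignment_length: int  # alignment columns (including gap columns)
    coverage: float  # aligned residues of the shorter sequence / its length x 100
    score: int


@dataclass(frozen=True)
class AAIResult:
    aai: float | None  # None when no reciprocal best hits pass thresholds
    n_rbh: int


@dataclass(frozen=True)
class RelatednessRecord:
    """Pairwise AAI/POCP record with its supporting counts."""

    genome_a: str
    genome_b: str
    aai: float | None
    n_rbh: int
    pocp: float
    c1: int
    c2: int
    t1: int
    t2: int

    def swapped(self) -> "RelatednessRecord":
        return RelatednessRecord(
            self.genome_b, self.genome_a, self.aai, self.n_rbh,
            self.pocp, self.c2, self.c1, self.t2, self.t1,
        )


def local_align(
    a: str,
    b: str,
    query_id: str = "query",
    target_id: str = "target",
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> AlignmentStats:
    """Optimal Smith-Waterman local alignment of two amino-acid strings.

    Identity is identical columns over all alignment columns; coverage is the
    number of aligned (non-gap) positions of the shorter sequence over that
    sequence's full length.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return _align_pair(ProteinSequence(a), ProteinSequence(b), query_id, target_id,
                       gap_open, gap_extend)


def _align_pair(
    seq_a: ProteinSequence,
    seq_b: ProteinSequence,
    query_id: str,
    target_id: str,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> AlignmentStats:
    aln = align_optimal(
        seq_a, seq_b, _BLOSUM62,
        gap_penalty=(-gap_open, -gap_extend),
        local=True, max_number=1,
    )[0]
    trace = aln.trace
    n_cols = trace.shape[0]
    if n_cols == 0:
        return AlignmentStats(query_id, target_id, 0.0, 0, 0.0, int(aln.score))
    both = (trace[:, 0] != -1) & (trace[:, 1] != -1)
    code_a = seq_a.code[trace[both, 0]]
    code_b = seq_b.code[trace[both, 1]]
    n_identical = int(np.count_nonzero(code_a == code_b))
    shorter = 0 if len(seq_a) <= len(seq_b) else 1
    aligned_in_shorter = int(np.count_nonzero(trace[:, shorter] != -1))
    shorter_len = min(len(seq_a), len(seq_b))
    return AlignmentStats(
        query_id=query_id,
        target_id=target_id,
        percent_identity=100.0 * n_identical / n_cols,
        alignment_length=n_cols,
        coverage=100.0 * aligned_in_shorter / shorter_len,
        score=int(aln.score),
    )


def _all_vs_all(a: Proteome, b: Proteome) -> list[AlignmentStats]:
    """Alignment stats for every (protein in A) x (protein in B) pair."""
    seqs_a = {pid: ProteinSequence(s) for pid, s in a.proteins.items()}
    seqs_b = {pid: ProteinSequence(s) for pid, s in b.proteins.items()}
    stats = []
    for qid, sa in seqs_a.items():
        for tid, sb in seqs_b.items():
            stats.append(_align_pair(sa, sb, qid, tid))
    return stats


def _passing(stats: Iterable[AlignmentStats], min_identity: float, min_coverage: float):
    return [
        s for s in stats
        if s.percent_identity >= min_identity and s.coverage >= min_coverage
    ]


def _best_hits(
    passing: Iterable[AlignmentStats], by_query: bool
) -> dict[str, AlignmentStats]:
    """Best passing hit per query (or per target when ``by_query`` is False).

    Ties break on higher score, then higher identity, then lexicographically
    smaller partner ID — fully deterministic.
    """
    best: dict[str, AlignmentStats] = {}
    for s in passing:
        key = s.query_id if by_query else s.target_id
        partner = s.target_id if by_query else s.query_id
        cur = best.get(key)
        if cur is None:
            best[key] = s
            continue
        cur_partner = cur.target_id if by_query else cur.query_id
        if (s.score, s.percent_identity) > (cur.score, cur.percent_identity) or (
            (s.score, s.percent_identity) == (cur.score, cur.percent_identity)
            and partner < cur_partner
        ):
            best[key] = s
    return best


def best_hit_map(
    a: Proteome,
    b: Proteome,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> dict[str, str]:
    """Map each protein of A to its best passing hit in B (if any)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("proteomes must be non-empty")
    stats = _all_vs_all(a, b)
    best = _best_hits(_passing(stats, min_identity, min_coverage), by_query=True)
    return {qid: s.target_id for qid, s in best.items()}


def _pair_metrics(
    a: Proteome,
    b: Proteome,
    min_identity: float,
    min_coverage: float,
) -> RelatednessRecord:
    """AAI and POCP from a single all-vs-all alignment pass."""
    stats = _all_vs_all(a, b)
    passing = _passing(stats, min_identity, min_coverage)
    best_a = _best_hits(passing, by_query=True)
    best_b = _best_hits(passing, by_query=False)
    rbh_identities = [
        s.percent_identity
        for qid, s in best_a.items()
        if best_b.get(s.target_id) is not None
        and best_b[s.target_id].query_id == qid
    ]
    n_rbh = len(rbh_identities)
    aai = float(np.mean(rbh_identities)) if n_rbh else None
    c1 = len({s.query_id for s in passing})
    c2 = len({s.target_id for s in passing})
    t1, t2 = len(a), len(b)
    pocp = 100.0 * (c1 + c2) / (t1 + t2)
    return RelatednessRecord(a.genome_id, b.genome_id, aai, n_rbh, pocp, c1, c2, t1, t2)


def compute_aai(
    a: Proteome,
    b: Proteome,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> AAIResult:
    """AAI between two proteomes: mean identity over reciprocal best hits.

    Returns an explicit undefined result (``aai=None``) when no RBH pair
    passes the thresholds; this is a defined outcome, not an error.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("proteomes must be non-empty")
    rec = _pair_metrics(a, b, min_identity, min_coverage)
    return AAIResult(rec.aai, rec.n_rbh)


def compute_pocp(
    a: Proteome,
    b: Proteome,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> RelatednessRecord:
    """Full relatedness record (POCP with C/T counts, plus AAI and n_RBH).

    A protein is *conserved* when it has at least one hit in the other
    proteome passing both thresholds; reciprocity is not required for POCP
    (it is for AAI).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("proteomes must be non-empty")
    return _pair_metrics(a, b, min_identity, min_coverage)


def relatedness_matrix(
    proteomes: Sequence[Proteome],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> tuple[pd.DataFrame, pd.DataFrame, list[RelatednessRecord]]:
    """All unordered pairwise comparisons.

    Returns symmetric AAI and POCP matrices (diagonal 100; undefined AAI as
    NaN) and the long-format records for the upper triangle.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    ids = [p.genome_id for p in proteomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome IDs")
    aai = pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)
    pocp = pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)
    records = []
    for i, pa in enumerate(proteomes):
        aai.iloc[i, i] = 100.0
        pocp.iloc[i, i] = 100.0
        for j in range(i + 1, len(proteomes)):
            rec = _pair_metrics(pa, proteomes[j], min_identity, min_coverage)
            records.append(rec)
            val = np.nan if rec.aai is None else rec.aai
            aai.iloc[i, j] = aai.iloc[j, i] = val
            pocp.iloc[i, j] = pocp.iloc[j, i] = rec.pocp
    return aai, pocp, records


def records_to_frame(records: Sequence[RelatednessRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_a": r.genome_a,
                "genome_b": r.genome_b,
                "aai": np.nan if r.aai is None else r.aai,
                "n_rbh": r.n_rbh,
                "pocp": r.pocp,
                "c1": r.c1,
                "c2": r.c2,
                "t1": r.t1,
                "t2": r.t2,
            }
            for r in records
        ]
    )
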