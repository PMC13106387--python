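"""Independent brute-force oracles used by the test suite.

These are deliberately simple re-derivations (full DP tables, exhaustive
enumeration, direct counting) kept separate from the package so that tests
compare two independent routes to the same answer.
"""

from __future__ import annotations

from biotite.sequence.align import SubstitutionMatrix

_BL62 = SubstitutionMatrix.std_protein_matrix()
_ALPH = _BL62.get_alphabet1()
_SCORE = _BL62.score_matrix()

NEG = float("-inf")


def blosum62(a: str, b: str) -> int:
    return int(_SCORE[_ALPH.encode(a), _ALPH.encode(b)])


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Smith-Waterman local alignment score by full Gotoh DP.

    Affine gaps: the first residue of a gap costs ``gap_open``, each further
    residue ``gap_extend``. Gap states may open from either other state.
    """
    n, m = len(a), len(b)
    best = 0
    m_prev = [0.0] * (m + 1)
    ix_prev = [NEG] * (m + 1)
    iy_prev = [NEG] * (m + 1)
    for i in range(1, n + 1):
        m_row = [0.0] * (m + 1)
        ix_row = [NEG] * (m + 1)
        iy_row = [NEG] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            iy_row[j] = max(
                m_prev[j] - gap_open,
                iy_prev[j] - gap_extend,
                ix_prev[j] - gap_open,
            )
            ix_row[j] = max(
                m_row[j - 1] - gap_open,
                ix_row[j - 1] - gap_extend,
                iy_row[j - 1] - gap_open,
            )
            diag = max(m_prev[j - 1], ix_prev[j - 1], iy_prev[j - 1])
            m_row[j] = max(0.0, diag + blosum62(ai, b[j - 1]))
            if m_row[j] > best:
                best = m_row[j]
        m_prev, ix_prev, iy_prev = m_row, ix_row, iy_row
    return int(best)


def hamming_identity(a: str, b: str) -> float:
    """Fraction of equal positions of two equal-length strings."""
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def producer_call_oracle(blocks: frozenset[str], catalog, max_missing: int):
    """Producer labels by direct set containment, independent of the engine's
    pathway-call machinery."""

    def n_missing(pid: str) -> int:
        return sum(1 for b in catalog.pathways[pid].blocks if b not in blocks)

    def ok(pid: str) -> bool:
        return n_missing(pid) <= max_missing

    butyrate = (
        ok("TB_bcd")
        and any(ok(p) for p in ("B1_acetylCoA", "B2_succinate_semialdehyde",
                                "B3_glutarate", "B4_lysine")
                if p in catalog.pathways)
        and any(ok(p) for p in ("TB_but", "TB_buk") if p in catalog.pathways)
    )
    propionate = (
        any(ok(p) for p in ("P1_succinate", "P2_acrylate", "P3_propanediol")
            if p in catalog.pathways)
        and any(ok(p) for p in ("TP_pta_pk", "TP_ct") if p in catalog.pathways)
    )
    return butyrate, propionate
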