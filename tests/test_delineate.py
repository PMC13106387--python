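"""Genus delineation: taxonomy parsing, threshold groups, outliers, splits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scfatlas.delineate import (
    TaxonRecord,
    TaxonomyParseError,
    classify_genus,
    delineate,
    family_min_aai,
    find_outliers,
    genus_min_stats,
    load_published_genus_groups,
    merged_genus_report,
    parse_gtdb_taxonomy,
    propose_partitions,
)


def _matrices(members, values, default=30.0):
    """Symmetric AAI and POCP matrices from {(a, b): (aai, pocp)}."""
    aai = pd.DataFrame(default, index=members, columns=members, dtype=float)
    pocp = pd.DataFrame(default, index=members, columns=members, dtype=float)
    np.fill_diagonal(aai.values, 100.0)
    np.fill_diagonal(pocp.values, 100.0)
    for (a, b), (va, vp) in values.items():
        aai.at[a, b] = aai.at[b, a] = va
        pocp.at[a, b] = pocp.at[b, a] = vp
    return aai, pocp


def _taxon(sid, genus, family="Famx", order="Ordx", rs=True):
    return TaxonRecord(
        species_id=sid,
        ranks={
            "domain": "Bacteria", "phylum": "Bacillota", "class": "Clostridia",
            "order": order, "family": family, "genus": genus,
            "species": f"{genus} {sid}",
        },
        rs_flag=rs,
    )


class TestTaxonomyParsing:
    def test_seven_ranks_extracted(self):
        s = ("d__Bacteria;p__Bacillota;c__Clostridia;o__Oscillospirales;"
             "f__Ruminococcaceae;g__Faecalibacterium;s__Faecalibacterium prausnitzii")
        ranks = parse_gtdb_taxonomy(s)
        assert ranks["genus"] == "Faecalibacterium"
        assert ranks["species"] == "Faecalibacterium prausnitzii"

    def test_polyphyly_suffix_preserved(self):
        s = ("d__Bacteria;p__Bacillota;c__Clostridia;o__Lachnospirales;"
             "f__Lachnospiraceae;g__Blautia A;s__Blautia A wexlerae")
        assert parse_gtdb_taxonomy(s)["genus"] == "Blautia A"

    def test_missing_species_allowed_and_flagged(self):
        s = "d__Bacteria;p__Bacillota;c__Clostridia;o__O;f__F;g__G;s__"
        ranks = parse_gtdb_taxonomy(s)
        rec = TaxonRecord("x", ranks)
        assert rec.species == ""
        assert "species" in rec.missing_ranks

    @pytest.mark.parametrize(
        "bad",
        [
            "p__Bacillota;d__Bacteria;c__C;o__O;f__F;g__G;s__S",  # order swapped
            "d__Bacteria;p__Bacillota;c__C;o__O;f__F;g__G",  # six ranks
            "d__Bacteria;x__oops;c__C;o__O;f__F;g__G;s__S",  # bad prefix
        ],
    )
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(TaxonomyParseError):
            parse_gtdb_taxonomy(bad)


class TestGenusStats:
    def test_pair_minimum(self):
        aai, pocp = _matrices(["a", "b"], {("a", "b"): (70.0, 60.0)})
        assert genus_min_stats(["a", "b"], aai, pocp)[0] == pytest.approx(70.0)

    def test_three_member_minimum(self):
        members = ["a", "b", "c"]
        aai, pocp = _matrices(members, {
            ("a", "b"): (70, 55), ("a", "c"): (66, 55), ("b", "c"): (64, 55),
        })
        min_aai, min_pocp, n_undef = genus_min_stats(members, aai, pocp)
        assert min_aai == pytest.approx(64.0)
        assert min_pocp == pytest.approx(55.0)
        assert n_undef == 0

    def test_undefined_pairs_excluded_but_counted(self):
        members = ["a", "b", "c"]
        aai, pocp = _matrices(members, {
            ("a", "b"): (70, 55), ("a", "c"): (np.nan, 55), ("b", "c"): (66, 55),
        })
        min_aai, _, n_undef = genus_min_stats(members, aai, pocp)
        assert min_aai == pytest.approx(66.0)
        assert n_undef == 1

    def test_missing_member_rejected(self):
        aai, pocp = _matrices(["a", "b"], {})
        with pytest.raises(KeyError):
            genus_min_stats(["a", "zz"], aai, pocp)

    def test_family_min_aai_recovers_planted_low_pair(self):
        # a family whose most divergent recognized-species pair sits at 43.9
        taxa = [_taxon(s, g, family="FamLow")
                for s, g in [("s1", "g1"), ("s2", "g2"), ("s3", "g3")]]
        aai, _ = _matrices(["s1", "s2", "s3"], {
            ("s1", "s2"): (43.9, 0), ("s1", "s3"): (55.0, 0), ("s2", "s3"): (60.0, 0),
        })
        fam = family_min_aai(taxa, aai).set_index("family")
        assert fam.at["FamLow", "min_aai"] == pytest.approx(43.9)


class TestClassifyGenus:
    @pytest.mark.parametrize(
        "min_aai,min_pocp,expected",
        [
            (70, 60, "A"),
            (66, 49, "B"),
            (60, 55, "C"),
            (60, 45, "D"),
            (65.0, 50.0, "A"),  # inclusive boundary
            (64.999, 50.0, "C"),
            (None, 55, "C"),  # undefined AAI: POCP decides
            (None, 45, "D"),
        ],
    )
    def test_group_assignment(self, min_aai, min_pocp, expected):
        assert classify_genus(min_aai, min_pocp) == expected

    @given(
        min_aai=st.floats(0, 100),
        min_pocp=st.floats(0, 100),
        bump_aai=st.floats(0, 35),
        bump_pocp=st.floats(0, 50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_raising_thresholds_never_promotes_into_a(
        self, min_aai, min_pocp, bump_aai, bump_pocp
    ):
        before = classify_genus(min_aai, min_pocp)
        after = classify_genus(min_aai, min_pocp,
                               aai_threshold=65 + bump_aai,
                               pocp_threshold=50 + bump_pocp)
        if before != "A":
            assert after != "A"


class TestDelineate:
    def test_bookkeeping_over_mixed_genera(self):
        taxa = [
            _taxon("s1", "Solo1"), _taxon("s2", "Solo2"),
            _taxon("s3", "Pair"), _taxon("s4", "Pair"),
            _taxon("s5", "Trio"), _taxon("s6", "Trio"), _taxon("s7", "Trio"),
            _taxon("s8", "Duo"), _taxon("s9", "Duo"),
        ]
        members = [f"s{i}" for i in range(1, 10)]
        aai, pocp = _matrices(members, {
            ("s3", "s4"): (80, 70),           # A
            ("s5", "s6"): (80, 70), ("s5", "s7"): (80, 70), ("s6", "s7"): (60, 45),  # D
            ("s8", "s9"): (70, 40),           # B
        })
        verdicts, summary = delineate(taxa, aai, pocp)
        assert summary["n_singletons"] == 2
        assert sum(summary["groups"].values()) == 3
        assert summary["n_singletons"] + sum(summary["groups"].values()) == summary["n_genera"]
        by_genus = {v.genus: v.group for v in verdicts}
        assert by_genus == {"Solo1": "singleton", "Solo2": "singleton",
                            "Pair": "A", "Trio": "D", "Duo": "B"}

    def test_identical_proteome_metrics_all_group_a(self):
        taxa = [_taxon(f"s{i}", "G1") for i in range(3)]
        members = [f"s{i}" for i in range(3)]
        aai, pocp = _matrices(members, {
            (a, b): (100, 100) for a, b in itertools.combinations(members, 2)
        })
        _, summary = delineate(taxa, aai, pocp)
        assert summary["groups"] == {"A": 1, "B": 0, "C": 0, "D": 0}


class TestOutliers:
    def _divergent_genus(self):
        members = ["a", "b", "c", "d"]
        vals = {p: (80.0, 70.0) for p in itertools.combinations(members, 2)}
        for other in "abc":
            vals[(other, "d")] = (50.0, 30.0)
        return members, _matrices(members, vals)

    def test_single_divergent_member_found(self):
        members, (aai, pocp) = self._divergent_genus()
        assert find_outliers(members, aai, pocp) == ("d",)

    def test_brute_force_agreement(self):
        members, (aai, pocp) = self._divergent_genus()
        expected = []
        for out in members:
            rest = [m for m in members if m != out]
            ma, mp, nu = genus_min_stats(rest, aai, pocp)
            if nu == 0 and classify_genus(ma, mp) == "A":
                expected.append(out)
        assert find_outliers(members, aai, pocp) == tuple(sorted(expected))

    def test_passing_genus_rejected(self):
        members = ["a", "b"]
        aai, pocp = _matrices(members, {("a", "b"): (80, 70)})
        with pytest.raises(ValueError):
            find_outliers(members, aai, pocp)

    def test_two_divergent_halves_have_no_single_fix(self):
        members = ["a", "b", "c", "d"]
        vals = {("a", "b"): (80, 70), ("c", "d"): (80, 70),
                ("a", "c"): (50, 30), ("a", "d"): (50, 30),
                ("b", "c"): (50, 30), ("b", "d"): (50, 30)}
        aai, pocp = _matrices(members, vals)
        assert find_outliers(members, aai, pocp) == ()


def _components_oracle(members, aai, pocp, at=65.0, pt=50.0):
    """Independent connected components: union-find over brute-force edges."""
    parent = {m: m for m in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(members, 2):
        v = aai.at[a, b]
        if not np.isnan(v) and v >= at and pocp.at[a, b] >= pt:
            parent[find(a)] = find(b)
    comps = {}
    for m in members:
        comps.setdefault(find(m), []).append(m)
    return sorted(tuple(sorted(c)) for c in comps.values())


class TestPartitions:
    def test_two_planted_blocks_split_in_two(self):
        members = ["a", "b", "c", "d", "e", "f"]
        vals = {}
        for pair in itertools.combinations(members, 2):
            within = set(pair) <= {"a", "b", "c"} or set(pair) <= {"d", "e", "f"}
            vals[pair] = (80.0, 70.0) if within else (55.0, 40.0)
        aai, pocp = _matrices(members, vals)
        clusters, unresolved = propose_partitions(members, aai, pocp)
        assert clusters == (("a", "b", "c"), ("d", "e", "f"))
        assert unresolved == ()
        assert sorted(clusters) == _components_oracle(members, aai, pocp)

    def test_fully_connected_genus_is_one_cluster(self):
        members = ["a", "b", "c"]
        vals = {p: (80.0, 70.0) for p in itertools.combinations(members, 2)}
        aai, pocp = _matrices(members, vals)
        clusters, unresolved = propose_partitions(members, aai, pocp)
        assert clusters == (("a", "b", "c"),)
        assert unresolved == ()

    def test_star_hub_failing_internal_minima_reported_unresolved(self):
        # hub h passes thresholds against each leaf, but the leaves fail
        # against each other, so the component flunks verification
        members = ["h", "x", "y", "z"]
        vals = {("h", l): (70.0, 60.0) for l in "xyz"}
        vals.update({p: (50.0, 30.0) for p in itertools.combinations("xyz", 2)})
        aai, pocp = _matrices(members, vals)
        clusters, unresolved = propose_partitions(members, aai, pocp)
        assert clusters == ()
        assert unresolved == ("h", "x", "y", "z")

    def test_random_matrices_match_component_oracle(self):
        rng = np.random.default_rng(23)
        members = [f"m{i}" for i in range(6)]
        for _ in range(20):
            vals = {
                p: (float(rng.uniform(40, 90)), float(rng.uniform(30, 80)))
                for p in itertools.combinations(members, 2)
            }
            aai, pocp = _matrices(members, vals)
            clusters, unresolved = propose_partitions(members, aai, pocp)
            oracle = _components_oracle(members, aai, pocp)
            # every proposed cluster and every unresolved member comes from
            # exactly one oracle component, and together they cover the genus
            emitted = sorted(list(clusters) + [(m,) for m in unresolved])
            assert sorted(m for c in emitted for m in c) == sorted(members)
            for c in clusters:
                assert any(set(c) == set(o) for o in oracle)


class TestMergesAndPublishedGroups:
    def test_cross_genus_component_reported_as_merge(self):
        taxa = [_taxon("s1", "GenX"), _taxon("s2", "GenY"), _taxon("s3", "GenZ")]
        aai, pocp = _matrices(["s1", "s2", "s3"], {
            ("s1", "s2"): (70, 60), ("s1", "s3"): (30, 20), ("s2", "s3"): (30, 20),
        })
        merges = merged_genus_report(taxa, aai, pocp)
        assert merges == [(("s1", "s2"), ("GenX", "GenY"))]

    def test_published_genus_group_counts(self):
        t1 = load_published_genus_groups()
        counts = t1["group"].value_counts().to_dict()
        assert counts == {"A": 51, "B": 12, "C": 6, "D": 8}
        assert len(t1) == 77
        assert t1["genus"].is_unique
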