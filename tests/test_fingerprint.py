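"""Fingerprint databases, duplicate detection, core markers and matching."""

import itertools

import numpy as np
import pandas as pd
import pytest

from kaspfp import (
    GenotypeMatrix,
    PopulationSimConfig,
    build_fingerprint_db,
    discrimination_count,
    export_fingerprint_matrix,
    find_duplicates,
    greedy_core_markers,
    match_query,
    simulate_population,
)
from kaspfp.fingerprint import COLOR_LEGEND, FingerprintDB, genotype_color


def db_from(profiles: dict, markers: list) -> FingerprintDB:
    return build_fingerprint_db(GenotypeMatrix(pd.DataFrame(profiles, index=markers).T))


def random_db(rng, n, m, missing=0.05) -> FingerprintDB:
    cells = {}
    for j in range(m):
        col = []
        for i in range(n):
            if rng.random() < missing:
                col.append(None)
            else:
                col.append(("AA", "AG", "GG")[rng.integers(3)])
        cells[f"M{j}"] = col
    return build_fingerprint_db(
        GenotypeMatrix(pd.DataFrame(cells, index=[f"a{i}" for i in range(n)]))
    )


def fully_discriminates(db, subset) -> bool:
    return discrimination_count(db, list(subset)) == len(db.accessions)


class TestDatabase:
    def test_csv_round_trip_identity(self, tmp_path, pop30):
        gm, _ = pop30
        db = build_fingerprint_db(gm)
        path = tmp_path / "db.csv"
        db.to_csv(path)
        back = FingerprintDB.from_csv(path)
        pd.testing.assert_frame_equal(db.genotypes.df, back.genotypes.df)

    def test_missing_preserved_never_imputed(self):
        db = db_from({"a": ["AA", None], "b": ["AG", "GG"]}, ["m1", "m2"])
        assert db.profile("a")["m2"] is None

    def test_duplicate_accessions_rejected(self):
        df = pd.DataFrame({"m1": ["AA", "AG"]}, index=["a", "a"])
        with pytest.raises(ValueError):
            GenotypeMatrix(df)


class TestFindDuplicates:
    def test_identical_profiles(self):
        db = db_from({"a": ["AA", "AG"], "b": ["AA", "AG"]}, ["m1", "m2"])
        pairs = find_duplicates(db, max_mismatch=1)
        assert len(pairs) == 1 and pairs.iloc[0]["mismatches"] == 0

    def test_one_locus_difference_thresholds(self):
        db = db_from({"a": ["AA", "AG"], "b": ["AA", "GG"]}, ["m1", "m2"])
        assert len(find_duplicates(db, max_mismatch=1)) == 1
        assert len(find_duplicates(db, max_mismatch=0)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_quadratic_oracle_recount(self, seed):
        rng = np.random.default_rng(seed)
        db = random_db(rng, n=8, m=6)
        reported = find_duplicates(db, max_mismatch=2)
        reported_pairs = {
            (r["accession_a"], r["accession_b"]): (r["mismatches"], r["loci_compared"])
            for _, r in reported.iterrows()
        }
        for a, b in itertools.combinations(db.accessions, 2):
            mism = comp = 0
            for m in db.marker_order:
                ga, gb = db.profile(a)[m], db.profile(b)[m]
                if ga is None or gb is None:
                    continue
                comp += 1
                mism += ga != gb
            if mism <= 2:
                assert reported_pairs[(a, b)] == (mism, comp)
            else:
                assert (a, b) not in reported_pairs


class TestGreedySelection:
    def test_hand_worked_two_marker_solution(self):
        db = db_from(
            {
                "a1": ["AA", "AA", "AA"],
                "a2": ["AA", "GG", "AA"],
                "a3": ["GG", "AA", "AA"],
                "a4": ["GG", "GG", "GG"],
            },
            ["M1", "M2", "M3"],
        )
        chosen, curve = greedy_core_markers(db)
        assert chosen == ["M1", "M2"]
        assert curve.complete
        assert curve.steps["n_distinct"].iloc[-1] == 4
        # exhaustive check: no single marker separates all four
        assert all(not fully_discriminates(db, [m]) for m in db.marker_order)

    def test_single_discriminating_marker_suffices(self):
        db = db_from({"a": ["AA", "AA"], "b": ["AG", "AA"], "c": ["GG", "AA"]},
                     ["m1", "m2"])
        chosen, curve = greedy_core_markers(db)
        assert chosen == ["m1"] and curve.complete

    def test_identical_profiles_reported_unseparated(self):
        db = db_from({"a": ["AA", "AG"], "b": ["AA", "AG"], "c": ["GG", "AA"]},
                     ["m1", "m2"])
        _, curve = greedy_core_markers(db)
        assert curve.unseparated_pairs == [("a", "b")]

    @pytest.mark.parametrize("seed", range(10))
    def test_curve_monotone(self, seed):
        rng = np.random.default_rng(seed + 100)
        db = random_db(rng, n=10, m=8)
        _, curve = greedy_core_markers(db)
        steps = curve.steps
        assert (steps["n_distinct"].diff().dropna() >= 0).all()
        assert (steps["pairs_separated_fraction"].diff().dropna() >= -1e-12).all()

    def test_greedy_discriminates_whenever_full_set_does(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            db = random_db(rng, n=7, m=6, missing=0.0)
            chosen, curve = greedy_core_markers(db)
            if fully_discriminates(db, db.marker_order):
                assert curve.complete and fully_discriminates(db, chosen)


class TestDiscriminationCount:
    def test_full_set_on_distinct_db(self, pop30):
        gm, _ = pop30
        db = build_fingerprint_db(gm)
        n_distinct = discrimination_count(db, db.marker_order)
        profiles = {tuple(db.profile(a)) for a in db.accessions}
        assert n_distinct == len(profiles)

    def test_empty_subset_collapses(self, pop30):
        gm, _ = pop30
        assert discrimination_count(build_fingerprint_db(gm), []) == 1

    def test_unknown_marker_rejected(self, pop30):
        gm, _ = pop30
        with pytest.raises(KeyError):
            discrimination_count(build_fingerprint_db(gm), ["nope"])

    def test_missing_equals_missing_only(self):
        db = db_from({"a": ["AA"], "b": [None], "c": [None]}, ["m1"])
        assert discrimination_count(db, ["m1"]) == 2


class TestMatchQuery:
    @pytest.fixture()
    def db31(self):
        gm, _ = simulate_population(
            PopulationSimConfig(n_accessions=40, n_markers=31, missing_rate=0.0, seed=13)
        )
        return build_fingerprint_db(gm)

    def test_entry_with_two_missing_loci_still_matches(self, db31):
        target = db31.accessions[0]
        q = db31.profile(target).copy()
        q.iloc[0] = None
        q.iloc[5] = None
        rep = match_query(db31, q, min_overlap=20)
        assert rep.verdict == target
        assert rep.nearest.loc[target, "mismatches"] == 0
        assert rep.nearest.loc[target, "loci_compared"] == 29

    def test_one_mismatch_is_no_match(self, db31):
        target = db31.accessions[1]
        q = db31.profile(target).copy()
        m = db31.marker_order[3]
        q[m] = "GG" if q[m] != "GG" else "AA"
        # with 31 markers no other accession coincides with the mutant
        assert all((q != db31.profile(a)).any() for a in db31.accessions)
        rep = match_query(db31, q, min_overlap=20)
        assert rep.verdict == "no match"
        assert rep.nearest.iloc[0]["mismatches"] == 1

    def test_stored_profiles_match_themselves(self, db31):
        for a in db31.accessions[:5]:
            rep = match_query(db31, db31.profile(a), min_overlap=20)
            assert rep.verdict == a

    def test_insufficient_overlap(self, db31):
        q = db31.profile(db31.accessions[0]).copy()
        q.iloc[5:] = None
        rep = match_query(db31, q, min_overlap=20)
        assert rep.verdict == "insufficient data"


class TestExport:
    def test_legend_and_colormap_exact(self, tmp_path):
        db = db_from(
            {"a": ["AA", "GG", "CC"], "b": ["TT", "AG", None]},
            ["m1", "m2", "m3"],
        )
        out = tmp_path / "fp.csv"
        export_fingerprint_matrix(db, out)
        legend = pd.read_csv(tmp_path / "fp.csv.legend.csv")
        assert dict(zip(legend["genotype"], legend["color"])) == COLOR_LEGEND
        assert len(legend) == 6
        assert genotype_color("AA") == "yellow"
        assert genotype_color("GG") == "orange"
        assert genotype_color("CC") == "blue"
        assert genotype_color("TT") == "purple"
        assert genotype_color("AG") == "green"
        assert genotype_color(None) == "grey"

    def test_exported_csv_reimports_identically(self, tmp_path, pop30):
        gm, _ = pop30
        db = build_fingerprint_db(gm)
        out = tmp_path / "fp.csv"
        export_fingerprint_matrix(db, out)
        back = FingerprintDB.from_csv(out)
        pd.testing.assert_frame_equal(db.genotypes.df, back.genotypes.df)

    def test_heatmap_rendering(self, tmp_path):
        db = db_from({"a": ["AA", "AG"], "b": ["GG", None]}, ["m1", "m2"])
        img = tmp_path / "fp.png"
        export_fingerprint_matrix(db, tmp_path / "fp.csv", render_image=img)
        assert img.exists() and img.stat().st_size > 0
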