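"""Immune-editing statistics: consensus, clonality, smoking, neoantigen
enumeration, hotspot matching, fractions, immunogenicity and comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from immunoedit import editing
from immunoedit.editing import ImmunogenicityModel


def _caller_table(rows):
    return pd.DataFrame(
        rows, columns=["patient", "protein", "position", "ref", "alt", "effect"]
    )


class TestConsensus:
    VAR = ("P1", "GENE1", 10, "A", "T")

    def test_two_of_four_kept_one_dropped(self):
        tables = {
            "c1": _caller_table([[*self.VAR, "missense"]]),
            "c2": _caller_table([[*self.VAR, "missense"]]),
            "c3": _caller_table([["P1", "GENE2", 5, "G", "C", "missense"]]),
            "c4": _caller_table([]),
        }
        out = editing.consensus_mutations(tables)
        assert len(out) == 1
        assert out.iloc[0]["caller_support"] == 2
        assert out.iloc[0]["protein"] == "GENE1"

    def test_majority_resolves_attribute_conflict(self):
        tables = {
            "c1": _caller_table([[*self.VAR, "missense"]]),
            "c2": _caller_table([[*self.VAR, "missense"]]),
            "c3": _caller_table([[*self.VAR, "silent"]]),
        }
        out = editing.consensus_mutations(tables)
        assert out.iloc[0]["effect"] == "missense"

    def test_two_two_tie_rejected(self):
        tables = {
            "c1": _caller_table([[*self.VAR, "missense"]]),
            "c2": _caller_table([[*self.VAR, "missense"]]),
            "c3": _caller_table([[*self.VAR, "silent"]]),
            "c4": _caller_table([[*self.VAR, "silent"]]),
        }
        assert editing.consensus_mutations(tables).empty

    def test_within_caller_duplicates_deduplicated(self):
        tables = {
            "c1": _caller_table([[*self.VAR, "missense"], [*self.VAR, "missense"]]),
            "c2": _caller_table([[*self.VAR, "missense"]]),
        }
        out = editing.consensus_mutations(tables)
        assert len(out) == 1 and out.iloc[0]["caller_support"] == 2


def clonality_oracle(count, n, offset):
    """Literal restatement of the classification rule."""
    if count >= n - offset:
        return "truncal"
    if count <= 2:
        return "private"
    return "shared"


class TestClonality:
    @pytest.mark.parametrize("offset", [1, 2, 3])
    def test_all_31_presence_vectors_match_oracle(self, offset):
        vectors = [v for v in itertools.product([0, 1], repeat=5) if any(v)]
        presence = pd.DataFrame(vectors, columns=[f"r{i}" for i in range(5)])
        labels = editing.classify_clonality(presence, truncal_offset=offset)
        for i, v in enumerate(vectors):
            assert labels[i] == clonality_oracle(sum(v), 5, offset), (v, offset)

    def test_truncal_precedence_over_private(self):
        # n=3, present in 2, offset 1: both rules fire, truncal wins
        presence = pd.DataFrame([[1, 1, 0]])
        assert editing.classify_clonality(presence, truncal_offset=1)[0] == "truncal"

    def test_empty_presence_errors(self):
        with pytest.raises(ValueError):
            editing.classify_clonality(pd.DataFrame([[0, 0, 0]]))

    def test_truncal_fraction(self):
        labels = pd.Series(["truncal", "truncal", "private", "shared"])
        assert editing.truncal_fraction(labels) == 0.5


class TestSmoking:
    def test_binary(self):
        assert editing.classify_smoking(0.6) == "smoker"
        assert editing.classify_smoking(0.5) == "nonsmoker"

    def test_light_boundary(self):
        assert editing.classify_smoking(0.30, scheme="three_level") == "light"
        assert editing.classify_smoking(0.31, pack_years=10, scheme="three_level") == "intermediate"

    def test_heavy_requires_both_conditions(self):
        assert editing.classify_smoking(0.75, pack_years=80, scheme="three_level") == "heavy"
        assert editing.classify_smoking(0.75, pack_years=50, scheme="three_level") == "intermediate"
        assert editing.classify_smoking(0.69, pack_years=80, scheme="three_level") == "intermediate"

    def test_missing_pack_years(self):
        assert editing.classify_smoking(0.8, None, scheme="three_level") == "intermediate"

    def test_contribution_range_guard(self):
        with pytest.raises(ValueError):
            editing.classify_smoking(1.2)


class TestEnumerateMutantPeptides:
    SEQ = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"  # length 40

    def test_interior_position_window_count(self):
        out = editing.enumerate_mutant_peptides(self.SEQ, 20, "Y", "A")
        assert len(out) == 9 + 10 + 11 + 12
        assert set(out["length"]) == {9, 10, 11, 12}

    def test_terminal_position_window_count(self):
        out = editing.enumerate_mutant_peptides(self.SEQ, 1, "A", "G")
        assert len(out) == 4
        assert (out["start"] == 1).all()

    def test_windows_cover_position_and_differ_from_wildtype(self):
        out = editing.enumerate_mutant_peptides(self.SEQ, 20, "Y", "A")
        for _, row in out.iterrows():
            assert row["start"] <= 20 <= row["start"] + row["length"] - 1
            assert row["mutant"] != row["wildtype"]
            assert row["wildtype"] == self.SEQ[row["start"] - 1 : row["start"] - 1 + row["length"]]

    def test_synonymous_mutant_equals_wildtype(self):
        out = editing.enumerate_mutant_peptides(self.SEQ, 20, "Y", "Y")
        assert (out["mutant"] == out["wildtype"]).all()

    def test_wildtype_identity_filter(self):
        out_all = editing.enumerate_mutant_peptides(self.SEQ, 20, "Y", "A")
        drop = set(out_all["mutant"].iloc[:5])
        out = editing.enumerate_mutant_peptides(self.SEQ, 20, "Y", "A", reference_peptides=drop)
        assert len(out) == len(out_all) - 5
        assert not set(out["mutant"]) & drop

    def test_position_and_ref_guards(self):
        with pytest.raises(ValueError):
            editing.enumerate_mutant_peptides(self.SEQ, 0, "A", "G")
        with pytest.raises(ValueError):
            editing.enumerate_mutant_peptides(self.SEQ, 41, "A", "G")
        with pytest.raises(ValueError, match="mismatch"):
            editing.enumerate_mutant_peptides(self.SEQ, 1, "C", "G")


class TestHotspotMatching:
    def test_exact_iff_wildtype_in_db(self):
        neo = pd.DataFrame(
            {"mutation_id": [1, 2], "wildtype": ["AAAAAAAAA", "CCCCCCCCC"],
             "mutant": ["AAAAWAAAA", "CCCCWCCCC"], "best_rank": [1.0, 1.0]}
        )
        out = editing.match_hotspot_exact(neo, {"AAAAAAAAA", "AAAAWAAAA"})
        assert out["exact"].tolist() == [True, False]  # mutant presence is irrelevant

    def test_mutation_rollup_requires_exact_binder(self):
        neo = pd.DataFrame(
            {"mutation_id": [1, 1, 2], "wildtype": ["AAAAAAAAA", "DDDDDDDDD", "AAAAAAAAA"],
             "mutant": ["x", "y", "z"], "best_rank": [50.0, 1.0, 1.0]}
        )
        out = editing.match_hotspot_exact(neo, {"AAAAAAAAA"})
        # mutation 1's only exact peptide is not a binder -> not exact
        assert not out.loc[out["mutation_id"] == 1, "mutation_exact"].any()
        assert out.loc[out["mutation_id"] == 2, "mutation_exact"].all()

    def test_random_queries_match_linear_scan_oracle(self, rng):
        db = ["".join(rng.choice(list("ACDEFG"), 9)) for _ in range(300)]
        queries = db[:100] + ["".join(rng.choice(list("ACDEFG"), 9)) for _ in range(900)]
        neo = pd.DataFrame(
            {"mutation_id": range(len(queries)), "wildtype": queries,
             "best_rank": 1.0}
        )
        out = editing.match_hotspot_exact(neo, set(db))
        for wt, flag in zip(out["wildtype"], out["exact"]):
            assert flag == any(wt == entry for entry in db)  # naive scan


class TestFractionsAndEnrichment:
    def _neo(self, region, synonymous, exact, n, rank=1.0):
        return pd.DataFrame(
            {"region": region, "synonymous": synonymous, "exact": exact,
             "best_rank": rank, "mutation_id": 0},
            index=range(n),
        )

    def test_basic_fractions(self):
        neo = pd.concat([
            self._neo("r1", False, True, 2), self._neo("r1", False, False, 8),
            self._neo("r1", True, True, 1), self._neo("r1", True, False, 9),
        ])
        out = editing.exact_fraction_and_enrichment(neo).set_index("region")
        assert out.loc["r1", "F_ex"] == pytest.approx(0.2)
        assert out.loc["r1", "F_ex_syn"] == pytest.approx(0.1)
        assert out.loc["r1", "enrichment"] == pytest.approx(2.0)

    def test_nonbinders_not_counted(self):
        neo = pd.concat([
            self._neo("r1", False, True, 5),
            self._neo("r1", False, True, 100, rank=50.0),
        ])
        out = editing.exact_fraction_and_enrichment(neo).set_index("region")
        assert out.loc["r1", "N_total"] == 5

    def test_group_min_imputation(self):
        neo = pd.concat([
            self._neo("r1", False, True, 4), self._neo("r1", False, False, 6),
            self._neo("r1", True, False, 2),
            self._neo("r2", False, True, 6), self._neo("r2", False, False, 4),
            self._neo("r2", True, False, 2),
            self._neo("r3", False, False, 3),  # no synonymous binders at all
        ])
        neo.loc[neo["region"] == "r3", "synonymous"] = False
        out = editing.exact_fraction_and_enrichment(
            neo, annotation_group={"r1": "g", "r2": "g", "r3": "g"}
        ).set_index("region")
        # r3's F_ex_syn imputed with the group minimum (0.0 from r1/r2)
        assert out.loc["r3", "F_ex_syn"] == 0.0

    def test_imputation_replay_with_nonzero_minimum(self):
        neo = pd.concat([
            self._neo("r1", True, True, 4), self._neo("r1", True, False, 6),
            self._neo("r2", True, True, 2), self._neo("r2", True, False, 3),
            self._neo("r3", True, True, 1, rank=50.0),  # no syn binders
        ])
        neo["synonymous"] = True
        for r in ("r1", "r2", "r3"):
            neo = pd.concat([neo, self._neo(r, False, False, 1)])
        out = editing.exact_fraction_and_enrichment(
            neo, annotation_group={"r1": "g", "r2": "g", "r3": "g"}
        ).set_index("region")
        assert out.loc["r3", "F_ex_syn"] == pytest.approx(0.4)  # min(0.4, 2/5)

    def test_units_without_syn_droppable(self):
        neo = pd.concat([
            self._neo("r1", False, True, 4), self._neo("r1", True, False, 2),
            self._neo("r2", False, True, 4),
        ])
        out = editing.exact_fraction_and_enrichment(neo, drop_units_without_syn=True)
        assert list(out["region"]) == ["r1"]

    def test_duplication_invariance(self, rng):
        neo = pd.concat([
            self._neo("r1", False, True, 3), self._neo("r1", False, False, 7),
            self._neo("r1", True, True, 2), self._neo("r1", True, False, 8),
        ])
        doubled = pd.concat([neo, neo])
        a = editing.exact_fraction_and_enrichment(neo).set_index("region")
        b = editing.exact_fraction_and_enrichment(doubled).set_index("region")
        assert a.loc["r1", "F_ex"] == b.loc["r1", "F_ex"]
        assert a.loc["r1", "enrichment"] == b.loc["r1", "enrichment"]


class TestImmunogenicityModel:
    def _mutations(self, n_exact, k_exact, n_nonexact, k_nonexact):
        rows = (
            [{"exact": True, "immunogenicity": "immunogenic"}] * k_exact
            + [{"exact": True, "immunogenicity": "nonimmunogenic"}] * (n_exact - k_exact)
            + [{"exact": False, "immunogenicity": "immunogenic"}] * k_nonexact
            + [{"exact": False, "immunogenicity": "nonimmunogenic"}] * (n_nonexact - k_nonexact)
        )
        return pd.DataFrame(rows)

    def test_empirical_fractions(self):
        model = editing.learn_immunogenicity_probs(self._mutations(100, 2, 500, 1))
        assert model.f_ex == pytest.approx(0.02)
        assert model.f_nonex == pytest.approx(0.002)
        assert model.ratio == pytest.approx(10.0)

    def test_not_tested_excluded_by_default(self):
        df = self._mutations(10, 1, 10, 1)
        df = pd.concat([df, pd.DataFrame([{"exact": True, "immunogenicity": "not_tested"}] * 10)])
        model = editing.learn_immunogenicity_probs(df)
        assert model.f_ex == pytest.approx(0.1)
        model_incl = editing.learn_immunogenicity_probs(df, include_not_tested=True)
        assert model_incl.f_ex == pytest.approx(0.05)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            editing.learn_immunogenicity_probs(self._mutations(10, 1, 0, 0))

    def test_consistency_as_n_grows(self):
        """Estimation error shrinks toward 0 with sample size."""
        rng = np.random.default_rng(7)
        f_ex, f_nonex = 0.0195, 0.00392
        errors = []
        for n in (500, 5_000, 50_000):
            reps = []
            for _ in range(10):
                exact = rng.random(n) < 0.3
                immuno = np.where(
                    rng.random(n) < np.where(exact, f_ex, f_nonex),
                    "immunogenic", "nonimmunogenic",
                )
                model = editing.learn_immunogenicity_probs(
                    pd.DataFrame({"exact": exact, "immunogenicity": immuno})
                )
                reps.append(abs(model.f_ex - f_ex) + abs(model.f_nonex - f_nonex))
            errors.append(np.mean(reps))
        assert errors[0] > errors[1] > errors[2]


class TestRelativeImmunogenicity:
    MODEL = ImmunogenicityModel(f_ex=0.0195, f_nonex=0.00392)

    def test_boundary_cases(self):
        assert editing.relative_immunogenicity(0, 10, self.MODEL) == pytest.approx(0.00392)
        assert editing.relative_immunogenicity(10, 0, self.MODEL) == pytest.approx(0.0195)

    def test_hand_value(self):
        ri = editing.relative_immunogenicity(10, 90, self.MODEL)
        assert ri == pytest.approx(0.005478, abs=1e-9)

    def test_convex_combination(self, rng):
        for _ in range(50):
            n_ex = int(rng.integers(0, 100))
            n_other = int(rng.integers(1, 100))
            ri = editing.relative_immunogenicity(n_ex, n_other, self.MODEL)
            assert self.MODEL.f_nonex <= ri <= self.MODEL.f_ex

    def test_empty_unit_missing(self):
        assert np.isnan(editing.relative_immunogenicity(0, 0, self.MODEL))


class TestQualityRatio:
    def test_ratio_of_group_means(self):
        q = pd.Series([2.0, 2.0, 1.0, 1.0])
        labels = pd.Series(["truncal", "truncal", "private", "private"])
        assert editing.quality_ratio(q, labels) == pytest.approx(2.0)

    def test_identical_distributions_give_one(self):
        q = pd.Series([1.5, 2.5, 1.5, 2.5])
        labels = pd.Series(["truncal", "truncal", "private", "private"])
        assert editing.quality_ratio(q, labels) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        q = pd.Series(rng.uniform(0.1, 5.0, 20))
        labels = pd.Series(["truncal"] * 8 + ["private"] * 7 + ["shared"] * 5)
        assert editing.quality_ratio(q * 7.3, labels) == pytest.approx(
            editing.quality_ratio(q, labels)
        )

    def test_empty_private_group_missing(self):
        q = pd.Series([1.0, 2.0])
        labels = pd.Series(["truncal", "truncal"])
        assert np.isnan(editing.quality_ratio(q, labels))


class TestCompareGroups:
    def test_exact_enumeration_p(self):
        # {1,2,3} vs {4,5,6}, "less": only 1 of C(6,3)=20 arrangements as extreme
        _, p = editing.compare_groups([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(0.05)

    def test_identical_groups(self):
        _, p = editing.compare_groups([1, 2, 3], [1, 2, 3], alternative="less")
        assert p >= 0.5

    def test_alternative_reversal(self):
        _, p_less = editing.compare_groups([1, 2, 3], [4, 5, 6], alternative="less")
        _, p_greater = editing.compare_groups([1, 2, 3], [4, 5, 6], alternative="greater")
        assert p_less + p_greater == pytest.approx(1.0 + 0.05)  # overlap at U=0

    def test_constant_pooled_degenerate(self):
        _, p = editing.compare_groups([2.0, 2.0], [2.0, 2.0], alternative="less")
        assert p == 1.0
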