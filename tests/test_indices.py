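"""Index formulas against printed values, a naive recount oracle, and
invariance properties."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethnosurvey import (
    SurveyDataset,
    UseRecord,
    ValidationError,
    choice_value,
    cultural_importance,
    fidelity_level,
    informant_consensus_factor,
    relative_frequency_of_citation,
    relative_importance,
    round_half_up,
    summarize,
    tally,
    use_value,
)

from conftest import make_dataset


def naive_recount(records, n_informants):
    """Independent oracle: explicit set enumeration, no pandas, no grouping."""
    triples = {(r.informant_id, r.species_id, r.category_id) for r in records}
    species = sorted({s for _, s, _ in triples})
    categories = sorted({c for _, _, c in triples})
    out = {
        "UR": {s: sum(1 for t in triples if t[1] == s) for s in species},
        "FC": {s: len({i for i, s2, _ in triples if s2 == s}) for s in species},
        "NU": {s: len({c for _, s2, c in triples if s2 == s}) for s in species},
        "Nur": {c: sum(1 for t in triples if t[2] == c) for c in categories},
        "Ntaxa": {c: len({s for _, s, c2 in triples if c2 == c})
                  for c in categories},
        "Np": {
            (s, c): len({i for i, s2, c2 in triples if s2 == s and c2 == c})
            for s in species
            for c in categories
            if any(t[1] == s and t[2] == c for t in triples)
        },
    }
    return out


triples_strategy = st.lists(
    st.tuples(
        st.sampled_from([f"i{k}" for k in range(20)]),
        st.sampled_from([f"s{k}" for k in range(8)]),
        st.sampled_from([f"c{k}" for k in range(5)]),
    ),
    min_size=0,
    max_size=120,
)


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "ur,n,expected", [(88, 200, 0.44), (0, 200, 0.0), (16, 200, 0.08)]
    )
    def test_use_value(self, ur, n, expected):
        assert use_value(ur, n) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "fc,n,expected", [(58, 200, 0.29), (200, 200, 1.0), (14, 200, 0.07)]
    )
    def test_relative_frequency_of_citation(self, fc, n, expected):
        assert relative_frequency_of_citation(fc, n) == pytest.approx(expected)

    def test_cultural_importance_equals_use_value(self):
        assert cultural_importance(88, 200) == use_value(88, 200)
        assert cultural_importance(1, 200) == pytest.approx(0.005)

    @pytest.mark.parametrize(
        "nur,ntaxa,expected",
        [(70, 11, 0.86), (2, 1, 1.0), (3, 3, 0.0), (1, 1, 0.0), (40, 9, 0.79),
         (30, 10, 0.69)],
    )
    def test_informant_consensus_factor(self, nur, ntaxa, expected):
        assert round_half_up(
            informant_consensus_factor(nur, ntaxa), 2
        ) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "np_,fc,expected", [(47, 58, 81.03), (1, 58, 1.72), (14, 14, 100.0)]
    )
    def test_fidelity_level(self, np_, fc, expected):
        assert round_half_up(fidelity_level(np_, fc), 2) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "np_,ntaxa,expected", [(47, 11, 4.27), (13, 10, 1.3), (29, 9, 3.22)]
    )
    def test_choice_value(self, np_, ntaxa, expected):
        assert round_half_up(choice_value(np_, ntaxa), 2) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "rfc,nu,expected",
        [(0.29, 9, 1.0), (0.07, 3, 0.287), (0.005, 1, 0.064)],
    )
    def test_relative_importance(self, rfc, nu, expected):
        assert round_half_up(
            relative_importance(rfc, nu, 0.29, 9), 3
        ) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            use_value(5, 0)
        with pytest.raises(ValidationError):
            relative_frequency_of_citation(5, 4)
        with pytest.raises(ValidationError):
            informant_consensus_factor(3, 5)
        with pytest.raises(ValidationError):
            fidelity_level(5, 4)
        with pytest.raises(ValidationError):
            choice_value(5, 0)
        with pytest.raises(ValidationError):
            relative_importance(0.1, 1, 0.0, 9)


class TestTally:
    def test_single_record(self):
        t = tally(make_dataset([("i1", "s1", "c1")], 10))
        assert t.species.iloc[0][["UR", "FC", "NU"]].tolist() == [1, 1, 1]
        assert t.categories.iloc[0][["Nur", "Ntaxa"]].tolist() == [1, 1]

    def test_empty_dataset_yields_empty_tables(self):
        tables = summarize(SurveyDataset(records=(), n_informants=5))
        assert tables.species.empty and tables.categories.empty
        assert tables.fidelity.empty and tables.choice.empty

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(triples=triples_strategy)
    def test_matches_naive_recount_oracle(self, triples):
        ds = make_dataset(triples, 20)
        oracle = naive_recount(ds.records, 20)
        t = tally(ds)
        assert t.species.set_index("species_id")["UR"].to_dict() == oracle["UR"]
        assert t.species.set_index("species_id")["FC"].to_dict() == oracle["FC"]
        assert t.species.set_index("species_id")["NU"].to_dict() == oracle["NU"]
        assert t.categories.set_index("category_id")["Nur"].to_dict() == oracle["Nur"]
        assert (t.categories.set_index("category_id")["Ntaxa"].to_dict()
                == oracle["Ntaxa"])
        observed_np = {
            (r.species_id, r.category_id): r.Np
            for r in t.cells.itertuples(index=False)
        }
        assert observed_np == oracle["Np"]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(triples=triples_strategy)
    def test_conservation_of_cell_sums(self, triples):
        t = tally(make_dataset(triples, 20))
        if t.cells.empty:
            return
        by_species = t.cells.groupby("species_id")["Np"].sum()
        assert by_species.to_dict() == t.species.set_index("species_id")[
            "UR"
        ].to_dict()
        by_cat = t.cells.groupby("category_id")["Np"].sum()
        assert by_cat.to_dict() == t.categories.set_index("category_id")[
            "Nur"
        ].to_dict()


class TestSummaryInvariants:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(triples=triples_strategy)
    def test_uv_equals_ci_for_all_species(self, triples):
        tables = summarize(make_dataset(triples, 20), rounded=False)
        assert (tables.species["UV"] == tables.species["CI"]).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(triples=triples_strategy)
    def test_duplicating_every_informant_leaves_ratio_indices_unchanged(
        self, triples
    ):
        ds = make_dataset(triples, 20)
        doubled = SurveyDataset(
            records=tuple(
                UseRecord(r.informant_id + suffix, r.species_id, r.category_id)
                for r in ds.records
                for suffix in ("", "#copy")
            ),
            n_informants=40,
        )
        a = summarize(ds, rounded=False)
        b = summarize(doubled, rounded=False)
        for col in ("UV", "RFC", "CI", "RI"):
            assert a.species[col].tolist() == pytest.approx(
                b.species[col].tolist()
            )
        assert a.fidelity["FL"].tolist() == pytest.approx(
            b.fidelity["FL"].tolist()
        )
        # ICF and CV are counts-per-taxon, not per-informant proportions:
        # they transform deterministically rather than staying fixed
        for row_a, row_b in zip(
            a.categories.itertuples(index=False),
            b.categories.itertuples(index=False),
        ):
            assert row_b.Nur == 2 * row_a.Nur
            assert row_b.Ntaxa == row_a.Ntaxa
            expected = (row_b.Nur - row_b.Ntaxa) / (row_b.Nur - 1)
            assert row_b.ICF == pytest.approx(expected)
        assert b.choice["Np"].tolist() == [2 * v for v in a.choice["Np"].tolist()]

    def test_icf_monotone_in_nur_for_fixed_ntaxa(self):
        values = [informant_consensus_factor(nur, 4) for nur in range(4, 40)]
        assert values == sorted(values)
        assert all(0 <= v <= 1 for v in values)


def test_rounding_is_half_up_not_bankers():
    assert round_half_up(0.855, 2) == 0.86
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(2.5) == 3.0
    assert round_half_up(46.9974) == 47.0
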