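import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mutualinet.core_data import (
    ConfigurationError,
    DataError,
    SiteCovariates,
    TraitTable,
    build_metaweb,
    fit_allometry,
    impute_climate,
    impute_trait_allometric,
    impute_trait_taxonomic,
    read_trait_table,
    sqrt_transform,
)

TYPES = {"size": "matching", "mass": "energy", "height": "foraging"}


def make_table(values, species=None, types=TYPES):
    species = species or [f"sp{i}" for i in range(len(values))]
    df = pd.DataFrame(values, index=pd.Index(species, name="species_id"), columns=list(types))
    return TraitTable(df, dict(types), "plant")


class TestReadTraitTable:
    def test_round_trip(self, tmp_path):
        t = make_table([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        p = tmp_path / "traits.csv"
        t.data.to_csv(p)
        back = read_trait_table(p, dict(TYPES), "plant")
        pd.testing.assert_frame_equal(back.data, t.data)

    def test_missing_trait_type_label_rejected(self, tmp_path):
        t = make_table([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        p = tmp_path / "traits.csv"
        t.data.to_csv(p)
        with pytest.raises(ConfigurationError):
            read_trait_table(p, {"size": "matching", "mass": "energy"}, "plant")

    def test_blank_cells_become_missing_markers(self, tmp_path):
        p = tmp_path / "traits.csv"
        p.write_text("species_id,size,mass,height\nsp1,1.0,,3.0\nsp2,,5.0,6.0\nsp3,7,8,9\n")
        with pytest.warns(UserWarning, match="2 missing"):
            t = read_trait_table(p, dict(TYPES), "plant")
        assert int(t.data.isna().sum().sum()) == 2

    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "traits.csv"
        p.write_text("species_id,size,mass,height\nsp1,1,2,3\nsp1,4,5,6\n")
        with pytest.raises(DataError, match="duplicated"):
            read_trait_table(p, dict(TYPES), "plant")


class TestSqrtTransform:
    def test_elementwise_squares_of_integers(self):
        t = make_table(np.arange(1, 10, dtype=float).reshape(3, 3) ** 2)
        out = sqrt_transform(t)
        np.testing.assert_allclose(
            out.data.to_numpy(), np.arange(1, 10, dtype=float).reshape(3, 3)
        )
        assert out.trait_types == t.trait_types

    def test_negative_rejected(self):
        with pytest.raises(DataError):
            sqrt_transform(make_table([[1.0, -2.0, 3.0], [4.0, 5.0, 6.0]]))

    @given(
        st.lists(
            st.lists(st.floats(0, 1e6, allow_nan=False), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        )
    )
    def test_sqrt_of_square_is_identity(self, values):
        t = make_table([[v**2 for v in row] for row in values])
        np.testing.assert_allclose(
            sqrt_transform(t).data.to_numpy(), np.asarray(values), rtol=1e-12, atol=1e-12
        )


class TestBuildMetaweb:
    def test_direct_tally(self, toy_records):
        L = build_metaweb(toy_records)
        assert L.shape == (2, 2)
        assert L.to_numpy().sum() == 3
        assert L.loc["p2", "a2"] == 0

    def test_repeated_pair_collapses_to_one(self, toy_records):
        L = build_metaweb(toy_records)
        assert L.loc["p1", "a1"] == 1  # seen at both sites, counts 3 and 5

    def test_zero_count_species_pruned(self, toy_records):
        rec = pd.concat(
            [
                toy_records,
                pd.DataFrame(
                    [{"site_id": "s1", "mutualism": "bird-fruit", "plant_id": "p9", "animal_id": "a9", "count": 0}]
                ),
            ],
            ignore_index=True,
        )
        L = build_metaweb(rec)
        assert "p9" not in L.index and "a9" not in L.columns

    def test_empty_records_rejected(self, toy_records):
        with pytest.raises(DataError):
            build_metaweb(toy_records.iloc[:0])

    @pytest.mark.parametrize("state,scale", [(0, 1), (1, 7), (2, 50), (3, 13)])
    def test_invariant_to_record_order_and_count_magnitude(self, toy_records, state, scale):
        shuffled = toy_records.sample(frac=1, random_state=state).reset_index(drop=True)
        shuffled["count"] = shuffled["count"] * scale
        pd.testing.assert_frame_equal(build_metaweb(shuffled), build_metaweb(toy_records))


def _cov_frame(n=52, seed=0, missing=("S00",)):
    rng = np.random.default_rng(seed)
    elev = np.linspace(900, 4300, n)
    habitat = np.repeat(["savanna", "forest", "alpine", "farmland"], int(np.ceil(n / 4)))[:n]
    offsets = {"savanna": 0.0, "forest": 1.5, "alpine": -2.0, "farmland": 0.7}
    e = (elev - elev.mean()) / 1000
    mat = 24 - 5 * e + 0.3 * e**2 - 0.05 * e**3 + np.array([offsets[h] for h in habitat])
    map_ = 1200 + 800 * e - 300 * e**2 + np.array([offsets[h] for h in habitat]) * 100
    df = pd.DataFrame(
        {"MAT": mat, "MAP": map_, "LU": rng.integers(0, 2, n), "elevation": elev, "habitat": habitat},
        index=pd.Index([f"S{i:02d}" for i in range(n)], name="site_id"),
    )
    df.loc[list(missing), ["MAT", "MAP"]] = np.nan
    return df


class TestImputeClimate:
    def test_noiseless_cubic_recovered_exactly(self):
        cov = SiteCovariates(_cov_frame())
        done, r2 = impute_climate(cov)
        assert r2["MAT"] == pytest.approx(1.0, abs=1e-10)
        truth = _cov_frame(missing=())
        np.testing.assert_allclose(done.data["MAT"], truth["MAT"], atol=1e-8)
        np.testing.assert_allclose(done.data["MAP"], truth["MAP"], atol=1e-6)

    def test_only_missing_rows_change(self):
        raw = _cov_frame(missing=("S05",))
        done, _ = impute_climate(SiteCovariates(raw))
        changed = (done.data["MAT"] != raw["MAT"]) & raw["MAT"].notna()
        assert not changed.any()
        assert done.data["MAT"].notna().all()
        assert (done.data.drop(index="S05") == raw.drop(index="S05")).all().all()

    def test_r2_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        raw = _cov_frame(seed=3)
        raw["MAT"] += rng.normal(0, 0.5, len(raw))
        obs = raw["MAT"].notna()
        done, r2 = impute_climate(SiteCovariates(raw))
        # independent oracle: solve the normal equations directly
        e = (raw.loc[obs, "elevation"] - raw["elevation"].mean()) / 1000
        X = np.column_stack(
            [np.ones(obs.sum()), e, e**2, e**3]
            + [
                (raw.loc[obs, "habitat"] == h).astype(float)
                for h in sorted(raw["habitat"].unique())[1:]
            ]
        )
        y = raw.loc[obs, "MAT"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r2["MAT"] == pytest.approx(r2_oracle, abs=1e-10)

    def test_rank_deficient_design_names_columns(self):
        raw = _cov_frame()
        raw["elevation"] = 2000.0  # constant elevation => polynomial collinear
        with pytest.raises(DataError, match="collinear"):
            impute_climate(SiteCovariates(raw))


class TestAllometry:
    @pytest.mark.parametrize(
        "intercept,slope,expected",
        [(1.89, 0.518, 6.619), (-1.32, 1.54, 0.2671)],
    )
    def test_published_equations_at_unit_predictor(self, intercept, slope, expected):
        # ln(predictor)=0, so the prediction is exp(intercept)
        assert impute_trait_allometric([1.0], intercept, slope)[0] == pytest.approx(
            expected, rel=1e-3
        )

    def test_monotone_in_predictor_for_positive_slope(self):
        x = np.linspace(0.2, 9.0, 50)
        y = impute_trait_allometric(x, 1.89, 0.518)
        assert (np.diff(y) > 0).all()

    def test_nonpositive_predictor_rejected(self):
        with pytest.raises(DataError):
            impute_trait_allometric([2.0, 0.0], 1.0, 1.0)

    def test_fit_recovers_exact_loglog_relation(self):
        x = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        y = np.exp(1.89 + 0.518 * np.log(x))
        b0, b1, r2 = fit_allometry(x, y)
        assert (b0, b1) == (pytest.approx(1.89, abs=1e-10), pytest.approx(0.518, abs=1e-10))
        assert r2 == pytest.approx(1.0, abs=1e-12)


class TestTaxonomicImputation:
    taxonomy = pd.DataFrame(
        {
            "species_id": ["sp0", "sp1", "sp2", "sp3", "sp4"],
            "genus": ["A", "A", "A", "B", "C"],
            "family": ["F1", "F1", "F1", "F1", "F2"],
            "order": ["O1", "O1", "O1", "O1", "O1"],
        }
    )

    def test_genus_mean_then_family_fallback(self):
        t = make_table(
            [
                [np.nan, 1.0, 1.0],  # sp0: two congeners with 2 and 4 -> 3
                [2.0, 1.0, 1.0],
                [4.0, 1.0, 1.0],
                [5.0, np.nan, 1.0],  # sp3: no congener, family mean of 'mass'
                [9.0, 7.0, 1.0],
            ]
        )
        filled, prov = impute_trait_taxonomic(t, self.taxonomy)
        assert filled.data.loc["sp0", "size"] == pytest.approx(3.0)
        assert prov.set_index("species_id").loc["sp0", "level"] == "genus"
        assert filled.data.loc["sp3", "mass"] == pytest.approx(1.0)  # family mean of sp0..sp2
        assert prov.set_index("species_id").loc["sp3", "level"] == "family"

    def test_unresolvable_species_flagged(self):
        t = make_table(
            [[np.nan, 1.0, 1.0], [2.0, 1.0, 1.0]],
            species=["sp4", "sp3"],
        )
        # sp4 is sole member of family F2; order-level mean exists via sp3
        filled, prov = impute_trait_taxonomic(t, self.taxonomy)
        assert prov.loc[0, "level"] == "order"
        lonely = pd.DataFrame(
            {"species_id": ["x", "y"], "genus": ["G", "H"], "family": ["F", "G"], "order": ["O", "P"]}
        )
        t2 = make_table([[np.nan, 1.0, 1.0], [2.0, 1.0, 1.0]], species=["x", "y"])
        _, prov2 = impute_trait_taxonomic(t2, lonely)
        assert (prov2["level"] == "unresolved").any()

    def test_idempotent_on_complete_table(self):
        t = make_table([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]], species=["sp0", "sp1"])
        filled, prov = impute_trait_taxonomic(t, self.taxonomy)
        pd.testing.assert_frame_equal(filled.data, t.data)
        assert prov.empty
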