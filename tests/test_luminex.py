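"""Plate-cleaning rules: LOD, bead filter, triplicate outliers, sparse drop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cytosig import luminex
from cytosig.errors import QcError
from cytosig.luminex import (
    CytokineMatrix,
    censor_lod,
    clean_plate,
    drop_sparse_cytokines,
    filter_bead_count,
    resolve_triplicates,
)
from cytosig.synthetic import CytokineSimConfig, gen_cytokine_study


def make_plate(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "cytokine", "replicate",
                                     "value_pg_ml", "bead_count"])
    df["genotype"] = "AD"
    df["sex"] = "M"
    df["timepoint_days"] = 30
    return df


class TestCensorLod:
    @pytest.mark.parametrize(
        "value,expected",
        [(3.1, 0.0), (3.2, 3.2), (0.0, 0.0), (100.0, 100.0), (3.1999, 0.0)],
    )
    def test_strictly_below_goes_to_zero(self, value, expected):
        plate = make_plate([("s1", "c1", 1, value, 50)])
        out = censor_lod(plate)
        assert out["value_pg_ml"].iloc[0] == expected

    def test_idempotent_and_flagged(self):
        plate = make_plate([("s1", "c1", 1, 1.0, 50), ("s1", "c1", 2, 5.0, 50)])
        once = censor_lod(plate)
        twice = censor_lod(once)
        assert once["value_pg_ml"].tolist() == twice["value_pg_ml"].tolist()
        assert once["lod_censored"].tolist() == [True, False]


class TestBeadFilter:
    def test_boundary(self):
        plate = make_plate(
            [("s1", "c1", 1, 10.0, 19), ("s1", "c1", 2, 10.0, 20)]
        )
        kept, removed = filter_bead_count(plate)
        assert kept["bead_count"].tolist() == [20]
        assert removed["bead_count"].tolist() == [19]

    def test_identity_when_all_pass(self):
        plate = make_plate([("s1", "c1", r, 10.0, 50) for r in (1, 2, 3)])
        kept, removed = filter_bead_count(plate)
        pd.testing.assert_frame_equal(kept, plate)
        assert removed.empty


def brute_force_triplicate(vals):
    """Independent oracle: test each of the 3 removal candidates directly."""
    vals = list(vals)
    qual = []
    for i in range(3):
        others = [vals[j] for j in range(3) if j != i]
        d = min(abs(vals[i] - o) for o in others)
        if d > 2 * abs(others[0] - others[1]):
            qual.append((d, i))
    if not qual:
        return np.mean(vals), None
    qual.sort(reverse=True)
    if len(qual) > 1 and qual[0][0] == qual[1][0]:
        return np.mean(vals), None
    i = qual[0][1]
    keep = [vals[j] for j in range(3) if j != i]
    return np.mean(keep), i


class TestResolveTriplicates:
    @pytest.mark.parametrize(
        "vals,mean,removed",
        [
            ((10, 11, 30), 10.5, 2),  # |30-11|=19 > 2*1
            ((10, 20, 30), 20.0, None),  # equally spread: no candidate
            ((5, 5), 5.0, None),  # rule needs 3 replicates
            ((7,), 7.0, None),
            ((0, 0, 9), 0.0, 2),  # LOD zeros participate as 0
        ],
    )
    def test_examples(self, vals, mean, removed):
        m, r = resolve_triplicates(vals)
        assert m == pytest.approx(mean)
        assert r == removed

    def test_empty_errors(self):
        with pytest.raises(QcError, match="no surviving replicates"):
            resolve_triplicates([])

    @given(
        st.lists(st.floats(0, 1e4, allow_nan=False, width=32), min_size=3,
                 max_size=3),
        st.permutations([0, 1, 2]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_permutation_invariant_mean(self, vals, perm):
        m1, _ = resolve_triplicates(vals)
        m2, _ = resolve_triplicates([vals[i] for i in perm])
        assert m1 == pytest.approx(m2, rel=1e-9, abs=1e-9)

    def test_matches_bruteforce_on_random_triplets(self, rng):
        for _ in range(300):
            vals = rng.uniform(0, 100, 3)
            m, r = resolve_triplicates(vals)
            mo, ro = brute_force_triplicate(vals)
            assert m == pytest.approx(mo)
            assert r == ro


class TestDropSparse:
    def _matrix(self, values, genotype):
        vals = pd.DataFrame(values)
        meta = pd.DataFrame(
            {"genotype": genotype, "timepoint_days": 30, "sex": "M"},
            index=vals.index,
        )
        return CytokineMatrix(
            values=vals, metadata=meta, provenance=pd.DataFrame(), dropped={}
        )

    def test_uniform_sparse_dropped(self):
        m = self._matrix(
            {"cyt": [0, 0, 0, 1, 0, 0, 0, 2, 0, 0]},
            ["AD"] * 5 + ["WT"] * 5,
        )
        out = drop_sparse_cytokines(m)
        assert "cyt" in out.dropped
        assert "cyt" not in out.values.columns

    def test_group_partitioned_retained(self):
        # absent in WT, measurable in all AD: overall 50% zeros -> retained
        m = self._matrix(
            {"cyt": [5, 6, 7, 8, 9, 0, 0, 0, 0, 0]},
            ["AD"] * 5 + ["WT"] * 5,
        )
        out = drop_sparse_cytokines(m)
        assert "cyt" in out.values.columns

    def test_partitioned_above_half_retained(self):
        # 60% zeros overall, but all AD samples measurable -> partitioned
        m = self._matrix(
            {"cyt": [5, 6, 7, 8, 0, 0, 0, 0, 0, 0]},
            ["AD"] * 4 + ["WT"] * 6,
        )
        out = drop_sparse_cytokines(m)
        assert "cyt" in out.values.columns

    def test_no_zeros_retained_and_bad_grouping(self):
        m = self._matrix({"cyt": [1.0] * 6}, ["AD"] * 3 + ["WT"] * 3)
        assert "cyt" in drop_sparse_cytokines(m).values.columns
        with pytest.raises(QcError, match="grouping key"):
            drop_sparse_cytokines(m, grouping=("nonsense",))


class TestCleanPlate:
    def test_noise_free_equals_replicate_means(self):
        cfg = CytokineSimConfig(
            seed=5, n_per_group=2, noise_sd=0.0, triplicate_cv=0.0,
            p_outlier=0.0, p_low_bead=0.0, latent_loadings=0.0,
        )
        plate, _ = gen_cytokine_study(cfg)
        matrix = clean_plate(plate)
        censored = plate.assign(
            value_pg_ml=np.where(plate["value_pg_ml"] < 3.2, 0.0,
                                 plate["value_pg_ml"])
        )
        expected = censored.pivot_table(
            index="sample_id", columns="cytokine", values="value_pg_ml"
        )[matrix.values.columns]
        pd.testing.assert_frame_equal(
            matrix.values, expected, check_names=False
        )

    def test_planted_outliers_removed(self):
        """Inject one x3 outlier per cell; the rule removes each one and the
        cell mean equals the mean of the two clean replicates."""
        cfg = CytokineSimConfig(
            seed=6, n_per_group=2, noise_sd=0.1, triplicate_cv=0.0,
            p_outlier=0.0, p_low_bead=0.0,
        )
        plate, _ = gen_cytokine_study(cfg)
        tampered = plate.copy()
        hit = tampered["replicate"] == 3
        tampered.loc[hit, "value_pg_ml"] *= 3
        matrix = clean_plate(tampered)
        assert matrix.provenance["outlier_removed"].all()
        censored = plate.assign(
            value_pg_ml=np.where(plate["value_pg_ml"] < 3.2, 0.0,
                                 plate["value_pg_ml"])
        )
        clean_means = (
            censored[censored["replicate"] != 3]
            .groupby(["sample_id", "cytokine"])["value_pg_ml"].mean()
        )
        for _, row in matrix.provenance.iterrows():
            assert row["value"] == pytest.approx(
                clean_means[row["sample_id"], row["cytokine"]]
            )

    def test_four_low_bead_removals_logged(self):
        cfg = CytokineSimConfig(seed=7, n_per_group=2, p_low_bead=0.0,
                                p_outlier=0.0)
        plate, _ = gen_cytokine_study(cfg)
        plate = plate.copy()
        # four scattered replicates in distinct cells (rows come in
        # consecutive triplets per cell)
        plate.loc[plate.index[[0, 5, 10, 15]], "bead_count"] = 10
        matrix = clean_plate(plate)
        assert len(matrix.bead_removals) == 4

    def test_cell_with_no_replicates_errors(self):
        cfg = CytokineSimConfig(seed=8, n_per_group=2, p_low_bead=0.0,
                                p_outlier=0.0)
        plate, _ = gen_cytokine_study(cfg)
        plate = plate.copy()
        cell = (plate["sample_id"] == plate["sample_id"].iloc[0]) & (
            plate["cytokine"] == plate["cytokine"].iloc[0]
        )
        plate.loc[cell, "bead_count"] = 5
        with pytest.raises(QcError, match="zero surviving replicates"):
            clean_plate(plate)

    def test_idempotent_on_clean_single_replicates(self):
        rows = []
        rng = np.random.default_rng(0)
        for s in range(4):
            for c in range(3):
                rows.append((f"s{s}", f"c{c}", 1, rng.uniform(10, 100), 50))
        plate = make_plate(rows)
        m1 = clean_plate(plate)
        again = plate.copy()
        for s in m1.values.index:
            for c in m1.values.columns:
                again.loc[
                    (again["sample_id"] == s) & (again["cytokine"] == c),
                    "value_pg_ml",
                ] = m1.values.loc[s, c]
        m2 = clean_plate(again)
        pd.testing.assert_frame_equal(m1.values, m2.values)
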