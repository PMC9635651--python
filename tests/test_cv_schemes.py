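"""Partition constraints of the CV1/CV2/CV0/CV00 breeding scenarios."""

import numpy as np
import pandas as pd
import pytest

from metml import cv_schemes as cvs


def grid_pheno(n_geno, env_ids, drop=()):
    rows = [
        (f"G{i:03d}", e) for i in range(n_geno) for e in env_ids
        if (f"G{i:03d}", e) not in drop
    ]
    pheno = pd.DataFrame(rows, columns=["genotype_id", "env_id"])
    pheno["location"] = pheno["env_id"].str.rsplit("_", n=1).str[0]
    pheno["year"] = pheno["env_id"].str.rsplit("_", n=1).str[1].astype(int)
    pheno["y"] = 0.0
    return pheno


def env_info_from(pheno):
    envs = pheno[["env_id", "location", "year"]].drop_duplicates().reset_index(drop=True)
    envs["longitude"] = -90.0
    envs["latitude"] = 40.0
    envs["planting_date"] = pd.Timestamp("2000-05-01")
    envs["harvest_date"] = pd.Timestamp("2000-09-01")
    return envs


ENVS_3 = ["A_2019", "A_2020", "B_2020"]


# ---------------------------------------------------------------------------
# CV1
# ---------------------------------------------------------------------------

def test_cv1_holds_out_whole_genotypes():
    pheno = grid_pheno(10, ENVS_3)
    parts = cvs.make_cv1(pheno, n_folds=5, seed=1)
    assert len(parts) == 5
    geno = pheno["genotype_id"].to_numpy()
    for p in parts:
        assert len(p.test_index) == 2 * 3  # 2 genotypes x 3 environments
        assert set(geno[p.test_index]).isdisjoint(geno[p.train_index])
    # each genotype is tested exactly once over the folds
    tested = np.concatenate([p.test_index for p in parts])
    assert sorted(tested) == list(range(len(pheno)))


def test_cv1_repeats_use_distinct_assignments():
    pheno = grid_pheno(10, ENVS_3)
    parts = cvs.make_cv1(pheno, n_folds=5, repeats=2, seed=1)
    assert len(parts) == 10
    first = [tuple(p.test_index) for p in parts[:5]]
    second = [tuple(p.test_index) for p in parts[5:]]
    assert first != second


def test_cv1_leave_one_genotype_out_degenerate():
    pheno = grid_pheno(10, ENVS_3)
    parts = cvs.make_cv1(pheno, n_folds=10, seed=0)
    geno = pheno["genotype_id"].to_numpy()
    assert all(len(set(geno[p.test_index])) == 1 for p in parts)


def test_cv1_more_folds_than_genotypes_errors():
    pheno = grid_pheno(4, ENVS_3)
    with pytest.raises(ValueError, match="exceeds"):
        cvs.make_cv1(pheno, n_folds=5)


# ---------------------------------------------------------------------------
# CV2
# ---------------------------------------------------------------------------

def test_cv2_every_test_genotype_keeps_a_training_observation():
    pheno = grid_pheno(4, ["A_1", "B_1", "C_1", "D_1"])
    parts = cvs.make_cv2(pheno, n_folds=4, seed=3)
    geno = pheno["genotype_id"].to_numpy()
    sizes = []
    for p in parts:
        sizes.append(len(p.test_index))
        for g in set(geno[p.test_index]):
            assert g in set(geno[p.train_index])
    assert max(sizes) - min(sizes) <= 1  # balanced assignment
    tested = np.concatenate([p.test_index for p in parts])
    assert sorted(tested) == list(range(len(pheno)))


def test_cv2_singleton_genotype_stays_in_train_with_warning():
    pheno = grid_pheno(5, ["A_1", "B_1"])
    pheno = pheno.drop(index=pheno.index[pheno["genotype_id"] == "G000"][1:]).reset_index(drop=True)
    with pytest.warns(UserWarning, match="observed once"):
        parts = cvs.make_cv2(pheno, n_folds=2, seed=0)
    single_idx = pheno.index[pheno["genotype_id"] == "G000"][0]
    for p in parts:
        assert single_idx in p.train_index


def test_cv2_impossible_when_all_genotypes_single_env():
    pheno = grid_pheno(6, ["A_1"])
    with pytest.raises(ValueError, match="single environment"):
        cvs.make_cv2(pheno, n_folds=2)


# ---------------------------------------------------------------------------
# CV0
# ---------------------------------------------------------------------------

def test_forward_prediction_rice_years():
    pheno = grid_pheno(8, [f"T_{y}" for y in range(2009, 2014)])
    parts = cvs.make_cv0(pheno, env_info_from(pheno), config="forward", min_train_years=2)
    assert [p.config["test_year"] for p in parts] == [2011, 2012, 2013]
    assert [p.config["train_years"] for p in parts] == [
        [2009, 2010], [2009, 2010, 2011], [2009, 2010, 2011, 2012]
    ]
    years = pheno["year"].to_numpy()
    for p in parts:
        assert set(years[p.train_index]) == set(p.config["train_years"])
        assert set(years[p.test_index]) == {p.config["test_year"]}


def test_leave_one_environment_out_counts(g2f_met):
    met, _ = g2f_met
    parts = cvs.make_cv0(met.pheno, met.env_info, config="leave-one-environment-out")
    assert len(parts) == 22
    env = met.pheno["env_id"].to_numpy()
    for p in parts:
        assert len(set(env[p.test_index])) == 1
    tested = np.concatenate([p.test_index for p in parts])
    assert sorted(tested) == list(range(len(met.pheno)))


def test_leave_one_site_out_counts(g2f_met):
    met, _ = g2f_met
    parts = cvs.make_cv0(met.pheno, met.env_info, config="leave-one-site-out")
    assert len(parts) == 6
    loc = met.pheno["location"].to_numpy()
    for p in parts:
        assert len(set(loc[p.test_index])) == 1
        assert set(loc[p.test_index]).isdisjoint(loc[p.train_index])


def test_leave_one_year_out_counts(g2f_met):
    met, _ = g2f_met
    parts = cvs.make_cv0(met.pheno, met.env_info, config="leave-one-year-out")
    assert len(parts) == 4
    yr = met.pheno["year"].to_numpy()
    for p in parts:
        assert len(set(yr[p.test_index])) == 1


def test_cv0_single_environment_errors():
    pheno = grid_pheno(5, ["A_1"])
    with pytest.raises(ValueError, match="two environments"):
        cvs.make_cv0(pheno, env_info_from(pheno))


def test_forward_with_too_few_years_warns_and_returns_empty():
    pheno = grid_pheno(5, ["A_2019", "A_2020"])
    with pytest.warns(UserWarning, match="fewer"):
        parts = cvs.make_cv0(pheno, env_info_from(pheno), config="forward",
                             min_train_years=2)
    assert parts == []


# ---------------------------------------------------------------------------
# CV00
# ---------------------------------------------------------------------------

def test_cv00_has_no_genotype_or_environment_overlap():
    pheno = grid_pheno(20, ["A_1", "B_1", "C_1", "D_1"])
    parts = cvs.make_cv00(pheno, env_info_from(pheno), seed=2,
                          test_genotype_fraction=0.5)
    geno = pheno["genotype_id"].to_numpy()
    env = pheno["env_id"].to_numpy()
    for p in parts:
        assert set(geno[p.test_index]).isdisjoint(geno[p.train_index])
        assert set(env[p.test_index]).isdisjoint(env[p.train_index])
        # sampled half of the genotypes form the test set
        assert len(set(geno[p.test_index])) == 10


def test_cv00_full_fraction_on_complete_grid_empties_training():
    pheno = grid_pheno(8, ["A_1", "B_1"])
    with pytest.raises(ValueError, match="emptied"):
        cvs.make_cv00(pheno, env_info_from(pheno), seed=0, test_genotype_fraction=1.0)


def test_cv00_keeps_other_genotypes_in_training_environments():
    pheno = grid_pheno(20, ["A_1", "B_1", "C_1"])
    parts = cvs.make_cv00(pheno, env_info_from(pheno), seed=5,
                          test_genotype_fraction=0.5)
    geno = pheno["genotype_id"].to_numpy()
    for p in parts:
        untouched = set(geno) - set(geno[p.test_index])
        assert untouched <= set(geno[p.train_index])


# ---------------------------------------------------------------------------
# cross-scheme properties
# ---------------------------------------------------------------------------

def random_met_shape(rng):
    n_geno = int(rng.integers(5, 51))
    n_env = int(rng.integers(2, 9))
    locs = [f"L{i}" for i in range(int(rng.integers(1, min(n_env, 4) + 1)))]
    envs = []
    y = 2000
    while len(envs) < n_env:
        for loc in locs:
            if len(envs) < n_env:
                envs.append(f"{loc}_{y}")
        y += 1
    pheno = grid_pheno(n_geno, envs)
    # random sparsity: drop up to 20% of cells but keep >= 2 obs per genotype
    mask = rng.random(len(pheno)) < 0.8
    counts = pheno[mask].groupby("genotype_id").size()
    ok = pheno["genotype_id"].map(counts).fillna(0) >= 2
    pheno = pheno[mask | ~ok.astype(bool)].reset_index(drop=True)
    return pheno, env_info_from(pheno)


@pytest.mark.parametrize("case", range(20))
def test_scheme_invariants_on_random_shapes(case):
    rng = np.random.default_rng(1000 + case)
    pheno, env_info = random_met_shape(rng)
    geno = pheno["genotype_id"].to_numpy()
    env = pheno["env_id"].to_numpy()

    for p in cvs.make_cv1(pheno, n_folds=min(5, pheno["genotype_id"].nunique()), seed=case):
        assert set(geno[p.test_index]).isdisjoint(geno[p.train_index])

    counts = pd.Series(geno).value_counts()
    if (counts >= 2).any():
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for p in cvs.make_cv2(pheno, n_folds=3, seed=case):
                for g in set(geno[p.test_index]):
                    assert g in set(geno[p.train_index])

    for p in cvs.make_cv0(pheno, env_info, config="leave-one-environment-out"):
        assert len(set(env[p.test_index])) == 1
        assert set(env[p.test_index]).isdisjoint(env[p.train_index])

    for p in cvs.make_cv00(pheno, env_info, seed=case, test_genotype_fraction=0.5):
        assert set(geno[p.test_index]).isdisjoint(geno[p.train_index])
        assert set(env[p.test_index]).isdisjoint(env[p.train_index])


def test_same_seed_reproduces_partitions_exactly():
    pheno = grid_pheno(15, ENVS_3)
    a = cvs.make_cv1(pheno, n_folds=5, repeats=2, seed=7)
    b = cvs.make_cv1(pheno, n_folds=5, repeats=2, seed=7)
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.test_index, pb.test_index)
        assert np.array_equal(pa.train_index, pb.train_index)


def test_partitions_serialize_to_json(tmp_path):
    pheno = grid_pheno(8, ENVS_3)
    parts = cvs.make_cv1(pheno, n_folds=4, seed=0)
    path = tmp_path / "partitions.json"
    cvs.write_partitions(parts, path)
    import json

    loaded = json.loads(path.read_text())
    assert len(loaded) == 4 and loaded[0]["scheme"] == "cv1"
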