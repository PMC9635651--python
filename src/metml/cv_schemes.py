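"""Train/test partition generators for multi-environment-trial prediction problems.

Four scenarios breeders face, with matching partition constraints:

* **CV1** — newly developed genotypes: whole genotypes held out, so no test
  genotype has any training observation.
* **CV2** — sparse testing: single (genotype, environment) cells held out, but
  every test genotype keeps at least one training observation elsewhere.
* **CV0** — new environments: whole environments held out, in four
  configurations (leave-one-environment-out, leave-one-site-out,
  leave-one-year-out, forward prediction from strictly earlier years).
* **CV00** — new genotypes in new environments: a CV0 partition from which the
  test genotypes' remaining observations are purged from the training set.

Partitions index rows of the phenotype table positionally (0-based), so every
scheme invariant can be re-checked from the partition plus the table alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

SCHEMES = ("cv1", "cv2", "cv0", "cv00")
CV0_CONFIGS = (
    "leave-one-environment-out",
    "leave-one-site-out",
    "leave-one-year-out",
    "forward",
)


@dataclass
class CVPartition:
    """One train/test split with its scheme metadata."""

    train_index: np.ndarray
    test_index: np.ndarray
    scheme: str
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        self.train_index = np.asarray(sorted(self.train_index), dtype=int)
        self.test_index = np.asarray(sorted(self.test_index), dtype=int)
        if len(self.test_index) == 0:
            raise ValueError("test set must be non-empty")
        if np.intersect1d(self.train_index, self.test_index).size:
            raise ValueError("train and test sets overlap")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["train_index"] = self.train_index.tolist()
        d["test_index"] = self.test_index.tolist()
        return d


def write_partitions(partitions, path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in partitions], fh, indent=1)


def _derive_seed(seed: int | None, repeat: int) -> int:
    base = 0 if seed is None else int(seed)
    return int(np.random.SeedSequence([base, repeat]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# CV1: new genotypes
# ---------------------------------------------------------------------------

def make_cv1(pheno: pd.DataFrame, n_folds: int = 5, repeats: int = 1,
             seed: int | None = None) -> list[CVPartition]:
    """Grouped k-fold over genotypes: every observation of a test genotype is test."""
    genotypes = np.array(sorted(pheno["genotype_id"].astype(str).unique()))
    if n_folds > len(genotypes):
        raise ValueError(
            f"n_folds={n_folds} exceeds the {len(genotypes)} distinct genotypes"
        )
    geno_of = pheno["genotype_id"].astype(str).to_numpy()
    partitions = []
    for rep in range(repeats):
        rep_seed = _derive_seed(seed, rep)
        rng = np.random.default_rng(rep_seed)
        shuffled = genotypes[rng.permutation(len(genotypes))]
        for fold in range(n_folds):
            test_geno = set(shuffled[fold::n_folds])  # round-robin after shuffle
            test_mask = np.isin(geno_of, list(test_geno))
            partitions.append(
                CVPartition(
                    train_index=np.nonzero(~test_mask)[0],
                    test_index=np.nonzero(test_mask)[0],
                    scheme="cv1",
                    config={"fold": fold, "repeat": rep, "n_folds": n_folds},
                    seed=rep_seed,
                )
            )
    return partitions


# ---------------------------------------------------------------------------
# CV2: sparse testing
# ---------------------------------------------------------------------------

def make_cv2(pheno: pd.DataFrame, n_folds: int = 5, repeats: int = 1,
             seed: int | None = None) -> list[CVPartition]:
    """Random cell partition such that each test genotype keeps a training cell.

    Observations of each genotype are spread over distinct folds (shuffled
    greedy balance), so a genotype observed in >= 2 environments never has all
    its cells in the same test fold.  Genotypes observed only once cannot
    satisfy the constraint and stay in training with a warning.
    """
    geno_of = pheno["genotype_id"].astype(str).to_numpy()
    counts = pd.Series(geno_of).value_counts()
    singles = set(counts.index[counts < 2])
    if singles:
        if len(singles) == len(counts):
            raise ValueError(
                "cv2 impossible: every genotype is observed in a single environment"
            )
        warnings.warn(
            f"cv2: {len(singles)} genotype(s) observed once stay in training",
            stacklevel=2,
        )
    eligible_geno = [g for g in sorted(counts.index) if g not in singles]

    partitions = []
    n_obs = len(pheno)
    for rep in range(repeats):
        rep_seed = _derive_seed(seed, rep)
        rng = np.random.default_rng(rep_seed)
        fold_of = np.full(n_obs, -1, dtype=int)
        fold_sizes = np.zeros(n_folds, dtype=int)
        order = list(eligible_geno)
        rng.shuffle(order)
        for g in order:
            obs = np.nonzero(geno_of == g)[0]
            rng.shuffle(obs)
            used: set[int] = set()
            for o in obs:
                # smallest fold not yet used by this genotype (cycle if > n_folds obs)
                if len(used) == n_folds:
                    used.clear()
                candidates = [f for f in range(n_folds) if f not in used]
                f = min(candidates, key=lambda c: (fold_sizes[c], c))
                fold_of[o] = f
                fold_sizes[f] += 1
                used.add(f)
        for fold in range(n_folds):
            test_mask = fold_of == fold
            if not test_mask.any():
                raise ValueError(f"cv2: fold {fold} received no observations")
            partitions.append(
                CVPartition(
                    train_index=np.nonzero(~test_mask)[0],
                    test_index=np.nonzero(test_mask)[0],
                    scheme="cv2",
                    config={"fold": fold, "repeat": rep, "n_folds": n_folds},
                    seed=rep_seed,
                )
            )
    return partitions


# ---------------------------------------------------------------------------
# CV0: new environments
# ---------------------------------------------------------------------------

def make_cv0(pheno: pd.DataFrame, env_info: pd.DataFrame,
             config: str = "leave-one-environment-out",
             min_train_years: int = 2) -> list[CVPartition]:
    """Hold out whole environments, sites, years, or predict forward in time."""
    if config not in CV0_CONFIGS:
        raise ValueError(f"cv0 config must be one of {CV0_CONFIGS}, got {config!r}")
    env_of = pheno["env_id"].astype(str).to_numpy()
    env_meta = env_info.set_index("env_id")
    if env_meta.shape[0] < 2:
        raise ValueError("cv0 needs at least two environments")

    partitions = []
    if config == "leave-one-environment-out":
        units = [(e, [e]) for e in sorted(env_meta.index)]
    elif config == "leave-one-site-out":
        units = [
            (loc, list(grp.index))
            for loc, grp in env_meta.groupby(env_meta["location"].astype(str), sort=True)
        ]
    elif config == "leave-one-year-out":
        units = [
            (int(yr), list(grp.index))
            for yr, grp in env_meta.groupby(env_meta["year"].astype(int), sort=True)
        ]
    else:  # forward
        years = sorted(env_meta["year"].astype(int).unique())
        units = []
        for i, yr in enumerate(years):
            if i >= min_train_years:
                test_envs = list(env_meta.index[env_meta["year"].astype(int) == yr])
                train_years = years[:i]
                units.append(((yr, tuple(train_years)), test_envs))
        if not units:
            warnings.warn(
                f"forward cv0: fewer than {min_train_years + 1} years; no partitions",
                stacklevel=2,
            )
            return []

    for unit, test_envs in units:
        test_mask = np.isin(env_of, test_envs)
        if not test_mask.any():
            continue  # environment without phenotypes
        train_mask = ~test_mask
        if config == "forward":
            yr, train_years = unit
            year_of = pheno["year"].astype(int).to_numpy()
            train_mask = np.isin(year_of, list(train_years))
            conf = {"config": "forward", "test_year": int(yr),
                    "train_years": [int(y) for y in train_years]}
        else:
            conf = {"config": config, "held_out": unit}
        partitions.append(
            CVPartition(
                train_index=np.nonzero(train_mask)[0],
                test_index=np.nonzero(test_mask)[0],
                scheme="cv0",
                config=conf,
            )
        )
    return partitions


# ---------------------------------------------------------------------------
# CV00: new genotypes in new environments
# ---------------------------------------------------------------------------

def make_cv00(pheno: pd.DataFrame, env_info: pd.DataFrame,
              config: str = "leave-one-environment-out",
              seed: int | None = None,
              test_genotype_fraction: float = 0.5,
              min_train_years: int = 2) -> list[CVPartition]:
    """CV0 partitions with the sampled test genotypes purged from training.

    From each CV0 partition, a fraction of the genotypes observed in the test
    environments is sampled; their observations in the test environments form
    the test set and *all* their observations are removed from training, so
    test genotypes and test environments are both unseen during training.
    """
    if not 0 < test_genotype_fraction <= 1:
        raise ValueError("test_genotype_fraction must be in (0, 1]")
    base = make_cv0(pheno, env_info, config=config, min_train_years=min_train_years)
    geno_of = pheno["genotype_id"].astype(str).to_numpy()
    partitions = []
    for k, part in enumerate(base):
        part_seed = _derive_seed(seed, k)
        rng = np.random.default_rng(part_seed)
        test_geno = np.array(sorted(set(geno_of[part.test_index])))
        n_take = max(1, int(round(test_genotype_fraction * len(test_geno))))
        sampled = set(rng.choice(test_geno, size=n_take, replace=False))
        test_idx = part.test_index[np.isin(geno_of[part.test_index], list(sampled))]
        train_idx = part.train_index[~np.isin(geno_of[part.train_index], list(sampled))]
        if len(train_idx) == 0:
            raise ValueError(
                "cv00: removing test genotypes emptied the training set; "
                "lower test_genotype_fraction"
            )
        conf = dict(part.config)
        conf.update(scheme_base="cv0", test_genotype_fraction=test_genotype_fraction)
        partitions.append(
            CVPartition(
                train_index=train_idx,
                test_index=test_idx,
                scheme="cv00",
                config=conf,
                seed=part_seed,
            )
        )
    return partitions


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def make_partitions(pheno: pd.DataFrame, env_info: pd.DataFrame, cv_type: str = "cv0",
                    cv0_type: str = "leave-one-environment-out",
                    nb_folds_cv1: int = 5, repeats_cv1: int = 1,
                    nb_folds_cv2: int = 5, repeats_cv2: int = 1,
                    seed: int | None = None,
                    test_genotype_fraction: float = 0.5,
                    min_train_years: int = 2) -> list[CVPartition]:
    """Build the partition list for any scheme from a single argument set."""
    cv_type = cv_type.lower()
    cv0_type = "forward" if cv0_type in ("forward", "forward-prediction") else cv0_type
    if cv_type == "cv1":
        return make_cv1(pheno, n_folds=nb_folds_cv1, repeats=repeats_cv1, seed=seed)
    if cv_type == "cv2":
        return make_cv2(pheno, n_folds=nb_folds_cv2, repeats=repeats_cv2, seed=seed)
    if cv_type == "cv0":
        return make_cv0(pheno, env_info, config=cv0_type, min_train_years=min_train_years)
    if cv_type == "cv00":
        return make_cv00(pheno, env_info, config=cv0_type, seed=seed,
                         test_genotype_fraction=test_genotype_fraction,
                         min_train_years=min_train_years)
    raise ValueError(f"unknown cv_type {cv_type!r}; use one of {SCHEMES}")
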