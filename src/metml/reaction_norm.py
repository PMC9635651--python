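"""Linear reaction-norm benchmark: y_ij = mu + g_i + w_j + gw_ij + e_ij.

Random effects and their covariance kernels:

* genomic main effect ``g ~ N(0, G sigma_g^2)`` with ``G = XX'/p`` on the
  centered/scaled marker matrix X (p markers);
* environmental main effect ``w ~ N(0, Omega sigma_w^2)`` with
  ``Omega = WW'/q`` on the centered/scaled covariate matrix W (q covariates);
* interaction ``gw ~ N(0, [Z_g G Z_g'] o Omega_obs sigma_gw^2)`` where ``o``
  is the Hadamard (cell-by-cell) product and Z_g maps observations to
  genotypes;
* residual ``e ~ IID N(0, sigma_e^2)``.

The model is fitted by Gibbs sampling with scaled-inverse-chi-squared variance
priors, working in the eigenbasis of each observation-level kernel so each
sweep costs a handful of matrix-vector products.  The default chain matches
the benchmark convention (20,000 iterations, 2,000 burn-in, thinning 5);
shorter chains are appropriate for tests.

The interface follows the Model/Results convention: build a
:class:`ReactionNormModel` from data, call :meth:`~ReactionNormModel.fit`, and
read estimates, uncertainties and predictions off the returned
:class:`ReactionNormResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import METData

_PSD_TOL = 1e-8
_VAR_FLOOR = 1e-10


def _center_scale(values: np.ndarray, means=None, sds=None):
    values = np.asarray(values, dtype=float)
    if means is None:
        means = values.mean(axis=0)
        sds = values.std(axis=0, ddof=0)
    keep = sds > 0
    return (values[:, keep] - means[keep]) / sds[keep], means, sds, keep


def check_psd(K: np.ndarray, name: str, tol: float = _PSD_TOL) -> None:
    evals = np.linalg.eigvalsh(K)
    scale = max(abs(evals[-1]), 1.0)
    if evals[0] < -tol * scale:
        raise ValueError(
            f"kernel {name} is not positive semi-definite "
            f"(min eigenvalue {evals[0]:.3e}); consider a small diagonal jitter"
        )


@dataclass
class KernelSet:
    """Genomic, environmental and interaction kernels with their obs-level expansions."""

    G: np.ndarray            # n_geno x n_geno, XX'/p
    omega: np.ndarray        # n_env x n_env, WW'/q
    Zg: np.ndarray           # observation -> genotype incidence
    Ze: np.ndarray           # observation -> environment incidence
    K_g: np.ndarray          # Zg G Zg'
    K_w: np.ndarray          # Ze omega Ze'
    K_gw: np.ndarray         # K_g o K_w (Hadamard)
    genotype_ids: list[str]
    env_ids: list[str]
    Xs: np.ndarray           # centered/scaled training markers (n_geno x p)
    Ws: np.ndarray           # centered/scaled training ECs (n_env x q)
    scaling: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.K_g.shape[0]

    def cross_kernels(self, markers_new: pd.DataFrame, ecs_new: pd.DataFrame,
                      pheno_new: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Kernels between new observations and the training observations.

        New markers/ECs are centered and scaled with the *training* statistics,
        so a new environment with covariates at the training mean contributes
        zero through the environmental kernel.
        """
        s = self.scaling
        Xn = markers_new[s["marker_cols"]].to_numpy(dtype=float)
        Xn = (Xn[:, s["marker_keep"]] - s["x_means"][s["marker_keep"]]) / s["x_sds"][s["marker_keep"]]
        missing = [c for c in s["ec_cols"] if c not in ecs_new.columns]
        if missing:
            raise ValueError(f"new ECs lack training columns: {missing[:5]}")
        Wn = ecs_new[s["ec_cols"]].to_numpy(dtype=float)
        Wn = (Wn[:, s["ec_keep"]] - s["w_means"][s["ec_keep"]]) / s["w_sds"][s["ec_keep"]]

        G_cross = Xn @ self.Xs.T / self.Xs.shape[1]
        O_cross = Wn @ self.Ws.T / self.Ws.shape[1]

        geno_pos = pd.Index(list(markers_new.index)).get_indexer(pheno_new["genotype_id"])
        env_pos = pd.Index(list(ecs_new.index)).get_indexer(pheno_new["env_id"])
        if (geno_pos < 0).any() or (env_pos < 0).any():
            raise KeyError("pheno_new references genotypes/environments not in the new tables")

        train_geno = self.Zg.argmax(axis=1)
        train_env = self.Ze.argmax(axis=1)
        Kg_c = G_cross[np.ix_(geno_pos, train_geno)]
        Kw_c = O_cross[np.ix_(env_pos, train_env)]
        return Kg_c, Kw_c, Kg_c * Kw_c


def build_kernels(
    markers: pd.DataFrame,
    ecs: pd.DataFrame,
    pheno: pd.DataFrame,
    omega_override: np.ndarray | None = None,
) -> KernelSet:
    """Assemble the kernel set for the observations in ``pheno``.

    Zero-variance marker and EC columns are removed before scaling.  The
    ``omega_override`` hook replaces the environmental kernel (e.g. an
    all-ones matrix turns the interaction kernel into ``Z_g G Z_g'`` exactly),
    for validation purposes.
    """
    genotype_ids = sorted(set(pheno["genotype_id"].astype(str)))
    env_ids = sorted(set(pheno["env_id"].astype(str)))
    missing_ec = [e for e in env_ids if e not in ecs.index]
    if missing_ec:
        raise ValueError(f"EC matrix lacks rows for environments: {missing_ec[:5]}")

    X_raw = markers.loc[genotype_ids].to_numpy(dtype=float)
    W_raw = ecs.loc[env_ids].to_numpy(dtype=float)
    Xs, x_means, x_sds, x_keep = _center_scale(X_raw)
    Ws, w_means, w_sds, w_keep = _center_scale(W_raw)
    p, q = Xs.shape[1], Ws.shape[1]
    if p == 0 or q == 0:
        raise ValueError("no variable markers or ECs left after zero-variance removal")

    G = Xs @ Xs.T / p
    omega = Ws @ Ws.T / q if omega_override is None else np.asarray(omega_override, dtype=float)
    check_psd(G, "G")
    check_psd(omega, "Omega")

    geno_pos = pd.Index(genotype_ids).get_indexer(pheno["genotype_id"].astype(str))
    env_pos = pd.Index(env_ids).get_indexer(pheno["env_id"].astype(str))
    n = len(pheno)
    Zg = np.zeros((n, len(genotype_ids)))
    Zg[np.arange(n), geno_pos] = 1.0
    Ze = np.zeros((n, len(env_ids)))
    Ze[np.arange(n), env_pos] = 1.0

    K_g = G[np.ix_(geno_pos, geno_pos)]          # = Zg G Zg'
    K_w = omega[np.ix_(env_pos, env_pos)]        # = Ze Omega Ze'
    K_gw = K_g * K_w

    return KernelSet(
        G=G, omega=omega, Zg=Zg, Ze=Ze, K_g=K_g, K_w=K_w, K_gw=K_gw,
        genotype_ids=genotype_ids, env_ids=env_ids, Xs=Xs, Ws=Ws,
        scaling={
            "marker_cols": list(markers.columns),
            "ec_cols": list(ecs.columns),
            "x_means": x_means, "x_sds": x_sds, "marker_keep": x_keep,
            "w_means": w_means, "w_sds": w_sds, "ec_keep": w_keep,
        },
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ReactionNormModel:
    """Bayesian Gaussian kernel regression with g, w and gw random effects."""

    effect_names = ("g", "w", "gw")

    def __init__(self, y, kernels: KernelSet):
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 1 or len(self.y) != kernels.n_obs:
            raise ValueError("y must be one value per observation in the kernel set")
        if len(self.y) < 20:
            raise ValueError("reaction-norm fit needs at least 20 observations")
        if not np.isfinite(self.y).all():
            raise ValueError("y contains non-finite values")
        self.kernels = kernels

    @classmethod
    def from_met_data(cls, met: METData, trait: str,
                      omega_override: np.ndarray | None = None) -> "ReactionNormModel":
        pheno = met.pheno[met.pheno[trait].notna()].reset_index(drop=True)
        kernels = build_kernels(met.markers, met.ecs, pheno, omega_override=omega_override)
        return cls(pheno[trait].to_numpy(dtype=float), kernels)

    def fit(self, iterations: int = 20000, burn_in: int = 2000, thinning: int = 5,
            seed: int | None = None, prior_df: float = 5.0, prior_r2: float = 0.5,
            jitter: float = 0.0) -> "ReactionNormResults":
        """Run the Gibbs sampler and return posterior summaries.

        ``prior_r2`` is the prior fraction of variance attributed to the three
        random effects jointly (split equally); scaled-inverse-chi-squared
        priors with ``prior_df`` degrees of freedom are used throughout.
        """
        if burn_in >= iterations:
            raise ValueError("burn_in must be smaller than iterations")
        rng = np.random.default_rng(seed)
        y = self.y
        n = len(y)
        ks = self.kernels

        eig = {}
        for name, K in (("g", ks.K_g), ("w", ks.K_w), ("gw", ks.K_gw)):
            Kj = K + jitter * np.eye(n) if jitter else K
            evals, evecs = np.linalg.eigh(Kj)
            scale = max(abs(evals[-1]), 1.0)
            if evals[0] < -_PSD_TOL * scale:
                raise ValueError(
                    f"kernel {name} not PSD (min eig {evals[0]:.3e}); add jitter"
                )
            keep = evals > 1e-10 * scale
            eig[name] = (evecs[:, keep], evals[keep])

        var_y = max(y.var(ddof=0), _VAR_FLOOR)
        share = prior_r2 / len(self.effect_names)
        s0 = {
            name: share * var_y * (prior_df + 2.0) / prior_df
            / max(np.mean(np.diag(K)), 1e-12)
            for name, K in (("g", ks.K_g), ("w", ks.K_w), ("gw", ks.K_gw))
        }
        s0_e = (1.0 - prior_r2) * var_y * (prior_df + 2.0) / prior_df

        mu = float(y.mean())
        b = {name: np.zeros(len(eig[name][1])) for name in self.effect_names}
        u = {name: np.zeros(n) for name in self.effect_names}
        sigma2 = {name: share * var_y for name in self.effect_names}
        sigma2_e = max((1.0 - prior_r2) * var_y, _VAR_FLOOR)

        n_samples = 0
        mu_sum = 0.0
        u_sum = {name: np.zeros(n) for name in self.effect_names}
        sigma2_draws = {name: [] for name in (*self.effect_names, "e")}
        mu_draws = []

        resid = y - mu - sum(u.values())
        for it in range(iterations):
            # intercept
            r_mu = resid + mu
            mu_new = rng.normal(r_mu.mean(), np.sqrt(sigma2_e / n))
            resid += mu - mu_new
            mu = mu_new

            for name in self.effect_names:
                V, d = eig[name]
                r_k = resid + u[name]
                rt = V.T @ r_k
                prec = 1.0 / sigma2_e + 1.0 / (d * sigma2[name])
                mean = rt / (sigma2_e * prec)
                b[name] = mean + rng.standard_normal(len(d)) / np.sqrt(prec)
                u_new = V @ b[name]
                resid += u[name] - u_new
                u[name] = u_new
                ss = float(np.sum(b[name] ** 2 / d))
                df_post = prior_df + len(d)
                sigma2[name] = max(
                    (prior_df * s0[name] + ss) / rng.chisquare(df_post), _VAR_FLOOR
                )

            ss_e = float(resid @ resid)
            sigma2_e = max(
                (prior_df * s0_e + ss_e) / rng.chisquare(prior_df + n), _VAR_FLOOR
            )
            if not np.isfinite(sigma2_e) or not all(np.isfinite(v) for v in sigma2.values()):
                raise RuntimeError("divergent chain: non-finite variance draw")

            if it >= burn_in and (it - burn_in) % thinning == 0:
                n_samples += 1
                mu_sum += mu
                mu_draws.append(mu)
                for name in self.effect_names:
                    u_sum[name] += u[name]
                    sigma2_draws[name].append(sigma2[name])
                sigma2_draws["e"].append(sigma2_e)

        u_mean = {name: u_sum[name] / n_samples for name in self.effect_names}
        mu_mean = mu_sum / n_samples
        samples = pd.DataFrame(
            {"mu": mu_draws,
             **{f"sigma2_{k}": v for k, v in sigma2_draws.items()}}
        )
        return ReactionNormResults(
            model=self,
            mu=mu_mean,
            varcomps={k: float(np.mean(v)) for k, v in sigma2_draws.items()},
            u_g=u_mean["g"], u_w=u_mean["w"], u_gw=u_mean["gw"],
            samples=samples,
            settings={"iterations": iterations, "burn_in": burn_in,
                      "thinning": thinning, "seed": seed,
                      "prior_df": prior_df, "prior_r2": prior_r2},
        )


@dataclass
class ReactionNormResults:
    """Posterior summaries of the fitted reaction-norm model."""

    model: ReactionNormModel
    mu: float
    varcomps: dict[str, float]  # sigma2_g / sigma2_w / sigma2_gw / sigma2_e (keys g,w,gw,e)
    u_g: np.ndarray
    u_w: np.ndarray
    u_gw: np.ndarray
    samples: pd.DataFrame
    settings: dict

    def __post_init__(self):
        self._alpha = None

    @property
    def fitted_values(self) -> np.ndarray:
        return self.mu + self.u_g + self.u_w + self.u_gw

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fitted_values

    def variance_proportions(self) -> dict[str, float]:
        total = sum(self.varcomps.values())
        return {k: v / total for k, v in self.varcomps.items()}

    def summary(self) -> str:
        sd = self.samples.std(ddof=1)
        lines = [
            "Reaction-norm model (g + w + gw kernels), Gibbs posterior summary",
            f"  observations: {len(self.model.y)}   "
            f"genotypes: {len(self.model.kernels.genotype_ids)}   "
            f"environments: {len(self.model.kernels.env_ids)}",
            f"  chain: {self.settings['iterations']} iterations, "
            f"{self.settings['burn_in']} burn-in, thinning {self.settings['thinning']}",
            f"  intercept mu: {self.mu:.4f} (posterior sd {sd['mu']:.4f})",
            "  variance components (posterior mean / sd):",
        ]
        labels = {"g": "sigma2_g (genomic)", "w": "sigma2_w (environment)",
                  "gw": "sigma2_gw (interaction)", "e": "sigma2_e (residual)"}
        for k, label in labels.items():
            lines.append(
                f"    {label:26s} {self.varcomps[k]:.4f} / {sd[f'sigma2_{k}']:.4f}"
            )
        return "\n".join(lines)

    # -- prediction -----------------------------------------------------------
    def _alphas(self):
        """Pseudo-inverse coefficients alpha_k = K_k^+ u_k for BLUP-type prediction."""
        if self._alpha is None:
            ks = self.model.kernels
            alpha = {}
            for name, K, u in (("g", ks.K_g, self.u_g), ("w", ks.K_w, self.u_w),
                               ("gw", ks.K_gw, self.u_gw)):
                evals, evecs = np.linalg.eigh(K)
                keep = evals > 1e-10 * max(abs(evals[-1]), 1.0)
                alpha[name] = evecs[:, keep] @ ((evecs[:, keep].T @ u) / evals[keep])
            self._alpha = alpha
        return self._alpha

    def predict(self, markers_new: pd.DataFrame, ecs_new: pd.DataFrame,
                pheno_new: pd.DataFrame) -> np.ndarray:
        """Predict new observations: mu + sum_k K_cross,k alpha_k.

        New genotypes draw on marker similarity through G; new environments on
        EC similarity through Omega and the interaction kernel.
        """
        Kg_c, Kw_c, Kgw_c = self.model.kernels.cross_kernels(
            markers_new, ecs_new, pheno_new
        )
        a = self._alphas()
        return self.mu + Kg_c @ a["g"] + Kw_c @ a["w"] + Kgw_c @ a["gw"]

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "varcomps": self.varcomps,
            "settings": self.settings,
        }


def fit_reaction_norm(y, kernels: KernelSet, iterations: int = 20000,
                      burn_in: int = 2000, thinning: int = 5,
                      seed: int | None = None, **kwargs) -> ReactionNormResults:
    """Functional wrapper around :class:`ReactionNormModel`."""
    return ReactionNormModel(y, kernels).fit(
        iterations=iterations, burn_in=burn_in, thinning=thinning, seed=seed, **kwargs
    )


def evaluate_partitions(met: METData, trait: str, partitions, cv_type: str = "cv0",
                        seed: int | None = None, iterations: int = 2000,
                        burn_in: int = 200, thinning: int = 5):
    """Evaluate the reaction-norm benchmark over a list of CV partitions.

    Kernels and scaling are rebuilt from each training split alone; test
    observations are predicted through cross-kernels, so new genotypes and
    environments are handled by marker/EC similarity.
    """
    from .models import EvaluationResult, within_env_metrics

    pheno = met.pheno[met.pheno[trait].notna()].reset_index(drop=True)
    pred_rows, params = [], []
    for i, part in enumerate(partitions):
        part_seed = int(np.random.SeedSequence([int(seed or 0), i]).generate_state(1)[0] % (2**31))
        train = pheno.iloc[part.train_index].reset_index(drop=True)
        test = pheno.iloc[part.test_index].reset_index(drop=True)
        kernels = build_kernels(met.markers, met.ecs, train)
        res = ReactionNormModel(train[trait].to_numpy(dtype=float), kernels).fit(
            iterations=iterations, burn_in=burn_in, thinning=thinning, seed=part_seed
        )
        pred = res.predict(met.markers, met.ecs, test)
        pred_rows.append(
            pd.DataFrame(
                {
                    "partition": i,
                    "obs_index": part.test_index,
                    "genotype_id": test["genotype_id"].to_numpy(),
                    "env_id": test["env_id"].to_numpy(),
                    "location": test["location"].to_numpy(),
                    "year": test["year"].to_numpy(),
                    "observed": test[trait].to_numpy(dtype=float),
                    "predicted": pred,
                }
            )
        )
        params.append({"iterations": iterations, "burn_in": burn_in,
                       "thinning": thinning, "seed": part_seed})
    predictions = pd.concat(pred_rows, ignore_index=True)
    return EvaluationResult(
        model_id="reaction_norm",
        trait=trait,
        cv_type=cv_type,
        predictions=predictions,
        metrics_by_env=within_env_metrics(predictions),
        hyperparameters=params,
        seed=seed,
        partitions=list(partitions),
    )
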