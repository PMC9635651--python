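"""Model interpretation: permutation importance, gain importance, ALE curves.

All methods operate on the post-preprocessing features (marker PCs, ECs, ...)
because those are what the fitted model consumes.

* Permutation importance of variable j is the increase in loss after shuffling
  that column: ``vip_diff_j = L(y, f(X_permuted)) - L(y, f(X_original))``,
  averaged over repeated permutations; it can be computed on the training
  split or on stored unseen data.
* Gain-based importance applies to tree ensembles only and is rescaled so the
  largest value is 100.
* Accumulated local effects (ALE) average the prediction change across each
  quantile window of a feature, using only the observations inside the window
  (which keeps correlated features from biasing the curve), then accumulate
  and center the averages so their count-weighted mean is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import FittedPipeline, rmse


@dataclass
class ImportanceTable:
    """Per-variable importances with per-permutation detail."""

    table: pd.DataFrame  # variable, importance, (perm_1..perm_B for permutation method)
    method: str  # "permutation" or "model_specific"
    split: str | None = None

    def top(self, n: int = 40) -> pd.DataFrame:
        return self.table.nlargest(n, "importance").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _resolve_predict(pipeline_or_fn):
    if isinstance(pipeline_or_fn, FittedPipeline):
        return pipeline_or_fn.predict_processed
    if callable(pipeline_or_fn):
        return pipeline_or_fn
    raise TypeError("expected a FittedPipeline or a predict(X) callable")


def permutation_importance(
    pipeline: FittedPipeline,
    split: str = "train",
    loss=rmse,
    n_permutations: int = 10,
    seed: int | None = None,
    shuffler=None,
) -> ImportanceTable:
    """Permutation-based variable importance on the chosen data split.

    ``shuffler(rng, values) -> permuted values`` can override the default
    random shuffle (e.g. the identity, under which every importance is exactly
    zero because predictions are unchanged).
    """
    X, y = pipeline.split_data(split)
    if X is None:
        raise ValueError(f"pipeline stores no {split!r} data")
    predict = pipeline.predict_processed
    base_loss = loss(y, predict(X))
    if shuffler is None:
        shuffler = lambda rng, v: rng.permutation(v)  # noqa: E731

    rows = []
    for j, var in enumerate(X.columns):
        diffs = []
        for b in range(n_permutations):
            rng = np.random.default_rng(
                np.random.SeedSequence([0 if seed is None else int(seed), j, b])
            )
            Xp = X.copy()
            Xp[var] = shuffler(rng, X[var].to_numpy())
            diffs.append(loss(y, predict(Xp)) - base_loss)
        row = {"variable": var, "importance": float(np.mean(diffs))}
        row.update({f"perm_{b + 1}": d for b, d in enumerate(diffs)})
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("importance", ascending=False, kind="mergesort")
    return ImportanceTable(table=table.reset_index(drop=True),
                           method="permutation", split=split)


def model_specific_importance(pipeline: FittedPipeline) -> ImportanceTable:
    """Gain-based importances from a tree ensemble, scaled to [0, 100]."""
    model = pipeline.model
    raw = getattr(model, "feature_importances_", None)
    is_tree = hasattr(model, "get_booster") or type(model).__name__ in (
        "RandomForestRegressor", "GradientBoostingRegressor", "DecisionTreeRegressor",
        "ExtraTreesRegressor",
    )
    if raw is None or not is_tree:
        raise TypeError(
            f"model {type(model).__name__} is not tree-based; use the "
            "model-agnostic permutation_importance instead"
        )
    raw = np.asarray(raw, dtype=float)
    top = raw.max()
    scaled = raw * (100.0 / top) if top > 0 else raw
    table = pd.DataFrame(
        {"variable": pipeline.feature_names, "importance": scaled}
    ).sort_values("importance", ascending=False, kind="mergesort")
    return ImportanceTable(table=table.reset_index(drop=True), method="model_specific")


# ---------------------------------------------------------------------------
# accumulated local effects
# ---------------------------------------------------------------------------

@dataclass
class ALECurve:
    """Accumulated local effects of one feature, centered at zero."""

    variable: str
    edges: np.ndarray    # n_bins + 1 quantile edges covering the observed range
    values: np.ndarray   # accumulated effect per bin (at the bin's upper edge)
    counts: np.ndarray   # observations per bin (centering weights)
    ticks: np.ndarray    # unique observed feature values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lower": self.edges[:-1], "upper": self.edges[1:],
             "ale": self.values, "count": self.counts}
        )

    def plot(self, path=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(self.edges[1:], self.values, marker=".", drawstyle="default")
        ax.plot(self.ticks, np.full_like(self.ticks, float(np.min(self.values))),
                "|", color="black", markersize=8)
        ax.axhline(0.0, lw=0.6, color="gray")
        ax.set(xlabel=self.variable, ylabel="accumulated local effect")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def ale_curve(pipeline_or_fn, X: pd.DataFrame, variable: str, n_bins: int = 20) -> ALECurve:
    """Accumulated local effects of ``variable`` under the fitted model.

    Bin edges are empirical quantiles (midpoint interpolation; duplicate edges
    merged, so at most as many bins as distinct values).  Within each bin the
    prediction difference between the bin's upper and lower edge is averaged
    over the in-bin observations, the averages are accumulated across bins,
    and the curve is centered by its count-weighted mean.
    """
    predict = _resolve_predict(pipeline_or_fn)
    if variable not in X.columns:
        raise KeyError(f"variable {variable!r} not among the model features")
    x = X[variable].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"variable {variable!r} is constant; ALE undefined")

    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.unique(np.quantile(x, qs, method="midpoint"))
    edges[0], edges[-1] = x.min(), x.max()
    n_eff = len(edges) - 1

    bin_of = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_eff - 1)
    local = np.zeros(n_eff)
    counts = np.zeros(n_eff, dtype=int)
    for j in range(n_eff):
        mask = bin_of == j
        counts[j] = int(mask.sum())
        if counts[j] == 0:
            continue
        X_hi = X[mask].copy()
        X_lo = X[mask].copy()
        X_hi[variable] = edges[j + 1]
        X_lo[variable] = edges[j]
        local[j] = float(np.mean(predict(X_hi) - predict(X_lo)))

    accumulated = np.cumsum(local)
    center = float(np.sum(counts * accumulated) / counts.sum())
    values = accumulated - center
    return ALECurve(
        variable=variable, edges=edges, values=values, counts=counts,
        ticks=np.unique(x),
    )
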