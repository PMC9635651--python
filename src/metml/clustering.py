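"""K-means environment clustering with elbow and silhouette diagnostics.

Environments are clustered on their climate covariates, their soil variables,
or both, after standardization (the blocks mix units).  One result per K in
the requested range is returned; the package deliberately stops at diagnostics
(total within-cluster sum of squares and average silhouette) and leaves the
choice of K to the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

INPUT_BLOCKS = ("climate", "soil", "all")


@dataclass
class ClusteringResult:
    K: int
    assignments: dict[str, int]  # env_id -> cluster label in 1..K
    wss: float
    silhouette: float
    input_block: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"env_id": list(self.assignments), "K": self.K,
             "label": list(self.assignments.values())}
        )


def _feature_block(ecs, soil, block):
    if block == "climate":
        X = ecs
    elif block == "soil":
        if soil is None or soil.empty:
            raise ValueError("soil block requested but no soil table available")
        X = soil
    elif block == "all":
        X = ecs if soil is None or soil.empty else ecs.join(soil, how="inner")
    else:
        raise ValueError(f"input_block must be one of {INPUT_BLOCKS}")
    if X is None or X.empty:
        raise ValueError(f"no features available for block {block!r}")
    return X


def cluster_environments(
    ecs: pd.DataFrame,
    soil: pd.DataFrame | None = None,
    block: str = "climate",
    k_range=range(2, 11),
    n_init: int = 25,
    seed: int | None = None,
) -> list[ClusteringResult]:
    """Cluster environments for each K, keeping the best of ``n_init`` starts.

    Features are standardized to zero mean / unit variance (constant columns
    dropped).  K values exceeding the number of environments are skipped with
    a warning.  To keep the elbow curve monotone, each K also tries an
    initialization that splits the best K-1 solution, and the better of the
    two is kept; WSS is therefore non-increasing in K.
    """
    X = _feature_block(ecs, soil, block)
    env_ids = list(X.index)
    vals = X.to_numpy(dtype=float)
    sds = vals.std(axis=0)
    vals = (vals[:, sds > 0] - vals[:, sds > 0].mean(axis=0)) / sds[sds > 0]
    n = len(env_ids)

    results = []
    prev_centers = None
    for K in k_range:
        if K > n:
            warnings.warn(f"K={K} exceeds {n} environments; skipped", stacklevel=2)
            continue
        km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
        km.fit(vals)
        best_labels, best_wss, best_centers = km.labels_, km.inertia_, km.cluster_centers_
        if prev_centers is not None and len(prev_centers) == K - 1:
            # warm start: previous centers plus the point farthest from its center
            dists = ((vals - prev_centers[best_of(prev_centers, vals)]) ** 2).sum(axis=1)
            init = np.vstack([prev_centers, vals[np.argmax(dists)]])
            km2 = KMeans(n_clusters=K, n_init=1, init=init, random_state=seed)
            km2.fit(vals)
            if km2.inertia_ < best_wss:
                best_labels, best_wss, best_centers = km2.labels_, km2.inertia_, km2.cluster_centers_
        prev_centers = best_centers

        if 2 <= K <= n - 1:
            sil = float(silhouette_score(vals, best_labels))
        else:
            sil = float("nan")  # silhouette undefined for singleton-only clusterings
        results.append(
            ClusteringResult(
                K=int(K),
                assignments={e: int(l) + 1 for e, l in zip(env_ids, best_labels)},
                wss=float(best_wss),
                silhouette=sil,
                input_block=block,
            )
        )
    return results


def best_of(centers: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Index of the nearest center for each row of ``vals``."""
    d2 = ((vals[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def diagnostics_frame(results: list[ClusteringResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"K": r.K, "wss": r.wss, "silhouette": r.silhouette, "block": r.input_block}
         for r in results]
    )


def plot_diagnostics(results, path=None):
    """Elbow and silhouette curves; returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    diag = diagnostics_frame(results)
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    axes[0].plot(diag["K"], diag["wss"], marker="o")
    axes[0].set(xlabel="K", ylabel="total within-cluster SS")
    axes[1].plot(diag["K"], diag["silhouette"], marker="o", color="darkgreen")
    axes[1].set(xlabel="K", ylabel="average silhouette")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
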