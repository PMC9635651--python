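"""Train-fitted feature preprocessing applied unchanged to test data.

The contract is strict no-leakage: every statistic (dropped columns, means,
standard deviations, principal-component loadings) is a pure function of the
training rows, and the identical transform is applied to test rows.  The
marker block can be replaced by its top principal components, computed either
from the centered/scaled dosage matrix or from the genomic relationship
matrix G = XX'/p (the two give the same column space; the GRM route is the
convention of kernel models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PC_SOURCES = ("marker_matrix", "grm")


def default_num_pcs(n_train: int, p: int, cap: int = 100) -> int:
    return int(min(cap, n_train - 1, p))


@dataclass
class Preprocessor:
    """Zero-variance removal, standardization, and marker-PC extraction.

    Parameters
    ----------
    num_pcs : number of marker principal components; ``None`` keeps raw
        (standardized) marker dosages.
    pc_source : ``marker_matrix`` (SVD of the centered/scaled dosages) or
        ``grm`` (eigenvectors of XX'/p; identical scores up to sign).
    """

    num_pcs: int | None = None
    pc_source: str = "marker_matrix"
    # fitted state
    dropped_: list[str] = field(default_factory=list)
    means_: pd.Series | None = None
    sds_: pd.Series | None = None
    marker_cols_: list[str] = field(default_factory=list)
    loadings_: np.ndarray | None = None  # p x k, applied to standardized markers
    pc_sds_: np.ndarray | None = None
    feature_names_: list[str] = field(default_factory=list)
    fitted_: bool = False

    def fit(self, X: pd.DataFrame, marker_cols: list[str] | None = None) -> "Preprocessor":
        if self.pc_source not in PC_SOURCES:
            raise ValueError(f"pc_source must be one of {PC_SOURCES}")
        marker_cols = list(marker_cols or [])
        X = X.copy()

        sds = X.std(axis=0, ddof=0)
        self.dropped_ = list(X.columns[sds == 0])
        kept = [c for c in X.columns if c not in self.dropped_]
        self.means_ = X[kept].mean(axis=0)
        self.sds_ = sds[kept]
        self.marker_cols_ = [c for c in marker_cols if c in kept]

        if self.num_pcs is not None:
            if not self.marker_cols_:
                raise ValueError("num_pcs requested but no (non-constant) marker columns")
            k_max = min(len(X) - 1, len(self.marker_cols_))
            if self.num_pcs > k_max:
                raise ValueError(
                    f"num_pcs={self.num_pcs} exceeds the admissible maximum {k_max} "
                    f"(min(n_train - 1, p))"
                )
            Z = self._standardized(X, self.marker_cols_).to_numpy()
            if self.pc_source == "marker_matrix":
                # loadings = right singular vectors of the standardized dosages
                _, _, vt = np.linalg.svd(Z, full_matrices=False)
                self.loadings_ = vt[: self.num_pcs].T
            else:  # grm: eigenvectors of ZZ'/p mapped back to marker loadings
                p = Z.shape[1]
                grm = Z @ Z.T / p
                evals, evecs = np.linalg.eigh(grm)
                order = np.argsort(evals)[::-1][: self.num_pcs]
                lam = np.maximum(evals[order], 1e-12)
                # loadings chosen so Z_train @ loadings = eigenvector scores
                self.loadings_ = Z.T @ evecs[:, order] / np.sqrt(lam * p)
            scores = Z @ self.loadings_
            self.pc_sds_ = scores.std(axis=0, ddof=0)
            self.pc_sds_[self.pc_sds_ == 0] = 1.0

        non_marker = [c for c in kept if c not in self.marker_cols_]
        if self.num_pcs is not None:
            pc_names = [f"PC{i + 1}" for i in range(self.num_pcs)]
            self.feature_names_ = pc_names + non_marker
        else:
            self.feature_names_ = kept
        self.fitted_ = True
        return self

    def _standardized(self, X: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        sds = self.sds_[cols].replace(0, 1.0)
        return (X[cols] - self.means_[cols]) / sds

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored training transform to any table (name-keyed columns)."""
        if not self.fitted_:
            raise RuntimeError("preprocessor not fitted")
        kept = [c for c in self.means_.index]
        missing = [c for c in kept if c not in X.columns]
        if missing:
            raise KeyError(f"table lacks required column(s): {missing[:5]}")
        out_blocks = []
        if self.num_pcs is not None:
            Z = self._standardized(X, self.marker_cols_).to_numpy()
            scores = Z @ self.loadings_ / self.pc_sds_
            out_blocks.append(
                pd.DataFrame(scores, index=X.index,
                             columns=[f"PC{i + 1}" for i in range(self.num_pcs)])
            )
            rest = [c for c in kept if c not in self.marker_cols_]
        else:
            rest = kept
        if rest:
            out_blocks.append(self._standardized(X, rest))
        out = pd.concat(out_blocks, axis=1)
        return out[self.feature_names_]

    def fit_transform(self, X: pd.DataFrame, marker_cols: list[str] | None = None) -> pd.DataFrame:
        return self.fit(X, marker_cols=marker_cols).transform(X)

    # -- serialization for exact reuse in step-3 predictions -----------------
    def to_dict(self) -> dict:
        return {
            "version": 1,
            "num_pcs": self.num_pcs,
            "pc_source": self.pc_source,
            "dropped": self.dropped_,
            "means": {} if self.means_ is None else self.means_.to_dict(),
            "sds": {} if self.sds_ is None else self.sds_.to_dict(),
            "marker_cols": self.marker_cols_,
            "loadings": None if self.loadings_ is None else self.loadings_.tolist(),
            "pc_sds": None if self.pc_sds_ is None else self.pc_sds_.tolist(),
            "feature_names": self.feature_names_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Preprocessor":
        pp = cls(num_pcs=d["num_pcs"], pc_source=d["pc_source"])
        pp.dropped_ = list(d["dropped"])
        pp.means_ = pd.Series(d["means"], dtype=float)
        pp.sds_ = pd.Series(d["sds"], dtype=float)
        pp.marker_cols_ = list(d["marker_cols"])
        pp.loadings_ = None if d["loadings"] is None else np.asarray(d["loadings"])
        pp.pc_sds_ = None if d["pc_sds"] is None else np.asarray(d["pc_sds"])
        pp.feature_names_ = list(d["feature_names"])
        pp.fitted_ = True
        return pp

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "Preprocessor":
        return cls.from_dict(json.loads(Path(path).read_text()))
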