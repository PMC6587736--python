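"""Ordination of mixed quantitative/qualitative melanosome traits.

`MixedOrdination` implements the PCAmix factorization (Chavent-style
fusion of PCA and multiple correspondence analysis): quantitative columns
are z-standardized, qualitative variables enter as centered level
indicators with column weight n/n_s, and the weighted matrix is factored
by SVD with uniform row weights 1/n. Quantitative variables each carry
inertia 1, a qualitative variable with m_s levels carries m_s - 1, so the
eigenvalues sum to p1 + (m - p2). Fitted ordinations can project new
(e.g. fossil) samples using the training standardization.

`fit_ppca` is the phylogenetic PCA: an eigendecomposition of the
evolutionary (GLS, tree-corrected) covariance matrix, used to check that
morphospace volumes are not artifacts of phylogenetic structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateVariableError, TreeError
from .io_core import vcv_matrix
from .morphometrics import QUANTITATIVE_DEFAULT, QUALITATIVE_DEFAULT

_EIG_TOL = 1e-10


def _as_level(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return "yes" if value else "no"
    return str(value)


@dataclass
class MixedOrdination:
    """Fitted PCAmix ordination; all state needed to project new samples."""

    quantitative_vars: list
    qualitative_vars: list
    means: np.ndarray
    stds: np.ndarray
    levels: dict  # var -> ordered level labels
    level_freqs: dict  # var -> frequencies (n_s / n)
    v: np.ndarray  # (total columns x k) right singular vectors
    col_weights: np.ndarray
    eigenvalues: np.ndarray
    scores: pd.DataFrame | None = None

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def variance_explained(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    # -- construction -----------------------------------------------------

    @classmethod
    def fit(
        cls,
        summaries: pd.DataFrame,
        quantitative_vars: Sequence[str] = QUANTITATIVE_DEFAULT,
        qualitative_vars: Sequence[str] = QUALITATIVE_DEFAULT,
    ) -> "MixedOrdination":
        n = len(summaries)
        if n < 3:
            raise ValueError("need at least 3 samples to fit an ordination")
        X = summaries[list(quantitative_vars)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing values in quantitative variables")
        means = X.mean(axis=0)
        stds = X.std(axis=0)  # population sd, as in correspondence analysis
        degenerate = [v for v, s in zip(quantitative_vars, stds) if s == 0]
        levels: dict = {}
        freqs: dict = {}
        blocks = [(X - means) / np.where(stds == 0, 1.0, stds)]
        weights = [np.ones(X.shape[1])]
        for var in qualitative_vars:
            labels = [_as_level(v) for v in summaries[var]]
            uniq = sorted(set(labels))
            if len(uniq) < 2:
                degenerate.append(var)
                uniq = uniq or [""]
            levels[var] = uniq
            counts = np.array([labels.count(u) for u in uniq], dtype=float)
            fr = counts / n
            freqs[var] = fr
            G = np.array([[1.0 if lab == u else 0.0 for u in uniq] for lab in labels])
            blocks.append(G - fr)
            weights.append(np.where(counts > 0, n / np.where(counts == 0, 1, counts), 0.0))
        if degenerate:
            raise DegenerateVariableError(
                f"constant variable(s), cannot ordinate: {degenerate}"
            )
        Z = np.hstack(blocks)
        w = np.concatenate(weights)
        W = (Z * np.sqrt(w)) / np.sqrt(n)
        U, s, Vt = np.linalg.svd(W, full_matrices=False)
        lam = s**2
        keep = lam > _EIG_TOL
        lam, V = lam[keep], Vt[keep].T
        # canonical sign: the largest-|entry| element of each axis is positive
        for k in range(V.shape[1]):
            j = int(np.argmax(np.abs(V[:, k])))
            if V[j, k] < 0:
                V[:, k] = -V[:, k]
        ordn = cls(
            quantitative_vars=list(quantitative_vars),
            qualitative_vars=list(qualitative_vars),
            means=means,
            stds=stds,
            levels=levels,
            level_freqs=freqs,
            v=V,
            col_weights=w,
            eigenvalues=lam,
        )
        ordn.scores = ordn.project(summaries, index=summaries.get("sample_id"))
        return ordn

    # -- projection --------------------------------------------------------

    def _preprocess(self, summaries: pd.DataFrame) -> np.ndarray:
        missing = [
            v
            for v in (*self.quantitative_vars, *self.qualitative_vars)
            if v not in summaries.columns
        ]
        if missing:
            raise KeyError(f"missing variable(s) for projection: {missing}")
        X = summaries[self.quantitative_vars].to_numpy(dtype=float)
        blocks = [(X - self.means) / self.stds]
        for var in self.qualitative_vars:
            uniq = self.levels[var]
            labels = [_as_level(v) for v in summaries[var]]
            bad = sorted(set(labels) - set(uniq))
            if bad:
                raise ValueError(f"unseen level(s) of {var}: {bad}")
            G = np.array([[1.0 if lab == u else 0.0 for u in uniq] for lab in labels])
            blocks.append(G - self.level_freqs[var])
        return np.hstack(blocks)

    def project(self, summaries: pd.DataFrame, index=None) -> pd.DataFrame:
        """Scores of new samples in the fitted morphospace.

        Projecting the training table reproduces the training scores.
        """
        Z = self._preprocess(summaries)
        F = (Z * np.sqrt(self.col_weights)) @ self.v
        cols = [f"PC{k + 1}" for k in range(F.shape[1])]
        idx = list(index) if index is not None else list(range(len(summaries)))
        return pd.DataFrame(F, columns=cols, index=pd.Index(idx, name="sample_id"))

    def squared_loadings_for(self, summaries: pd.DataFrame) -> pd.DataFrame:
        """Per-variable contribution to each axis: squared correlation for
        quantitative variables, correlation ratio (eta^2) for qualitative.
        On the training table, each column sums to the axis eigenvalue."""
        F = self.project(summaries).to_numpy()
        n = len(summaries)
        rows = {}
        for var in self.quantitative_vars:
            x = summaries[var].to_numpy(dtype=float)
            rows[var] = [
                float(np.corrcoef(x, F[:, k])[0, 1] ** 2) for k in range(F.shape[1])
            ]
        for var in self.qualitative_vars:
            labels = np.array([_as_level(v) for v in summaries[var]])
            etas = []
            for k in range(F.shape[1]):
                f = F[:, k]
                tot = f.var()
                between = sum(
                    (labels == u).mean() * (f[labels == u].mean() - f.mean()) ** 2
                    for u in self.levels[var]
                    if (labels == u).any()
                )
                etas.append(float(between / tot) if tot > 0 else 0.0)
            rows[var] = etas
        return pd.DataFrame(
            rows, index=[f"PC{k + 1}" for k in range(F.shape[1])]
        ).T

    # -- persistence -------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = dict(
            quantitative_vars=self.quantitative_vars,
            qualitative_vars=self.qualitative_vars,
            means=self.means.tolist(),
            stds=self.stds.tolist(),
            levels=self.levels,
            level_freqs={k: v.tolist() for k, v in self.level_freqs.items()},
            v=self.v.tolist(),
            col_weights=self.col_weights.tolist(),
            eigenvalues=self.eigenvalues.tolist(),
        )
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MixedOrdination":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
        return cls(
            quantitative_vars=payload["quantitative_vars"],
            qualitative_vars=payload["qualitative_vars"],
            means=np.array(payload["means"]),
            stds=np.array(payload["stds"]),
            levels=payload["levels"],
            level_freqs={k: np.array(v) for k, v in payload["level_freqs"].items()},
            v=np.array(payload["v"]),
            col_weights=np.array(payload["col_weights"]),
            eigenvalues=np.array(payload["eigenvalues"]),
        )


def fit_pcamix(
    summaries: pd.DataFrame,
    quantitative_vars: Sequence[str] = QUANTITATIVE_DEFAULT,
    qualitative_vars: Sequence[str] = QUALITATIVE_DEFAULT,
) -> MixedOrdination:
    """Functional alias for :meth:`MixedOrdination.fit`."""
    return MixedOrdination.fit(summaries, quantitative_vars, qualitative_vars)


# ---------------------------------------------------------------------------
# Phylogenetic PCA
# ---------------------------------------------------------------------------


@dataclass
class PhyloOrdination:
    species: list
    variables: list
    phylo_mean: np.ndarray
    evolutionary_cov: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scores: pd.DataFrame = field(repr=False, default=None)


def fit_ppca(
    summaries: pd.DataFrame,
    tree,
    variables: Sequence[str] = QUANTITATIVE_DEFAULT,
    species_col: str = "species",
) -> PhyloOrdination:
    """Phylogenetic PCA on quantitative variables (one row per tip).

    The evolutionary covariance R = (X - 1a)' C^-1 (X - 1a) / (n - 1) is
    computed under the Brownian tree covariance C with GLS mean a; scores
    are projections of the (non-phylogenetically-whitened) centered data on
    the eigenvectors of R, so ordinary and phylogenetic PCA scores differ
    by an invertible linear map.
    """
    species = summaries[species_col].tolist()
    if len(set(species)) != len(species):
        raise ValueError("multiple rows per species; average samples first")
    try:
        C = vcv_matrix(tree, species)
    except TreeError:
        raise
    X = summaries[list(variables)].to_numpy(dtype=float)
    n = len(species)
    Cinv = np.linalg.inv(C)
    one = np.ones((n, 1))
    denom = (one.T @ Cinv @ one).item()
    a = (one.T @ Cinv @ X) / denom
    Xc = X - a
    R = Xc.T @ Cinv @ Xc / (n - 1)
    lam, V = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    scores = pd.DataFrame(
        Xc @ V,
        columns=[f"pPC{k + 1}" for k in range(V.shape[1])],
        index=pd.Index(species, name="species"),
    )
    return PhyloOrdination(
        species=species,
        variables=list(variables),
        phylo_mean=a.ravel(),
        evolutionary_cov=R,
        eigenvalues=lam,
        eigenvectors=V,
        scores=scores,
    )
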