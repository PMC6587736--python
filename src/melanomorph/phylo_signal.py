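"""Phylogenetic signal in morphospace and ancestral-state estimation.

K (Blomberg) compares observed trait similarity among relatives with the
Brownian-motion expectation on the given tree: K = 1 under BM, K < 1 when
relatives resemble each other less than BM predicts. `kmult` is the
multivariate generalization operating on Euclidean distances across all
morphospace axes at once, with significance from permuting species across
tips. Pagel's lambda instead rescales the off-diagonal tree covariance by
a factor in [0, 1] estimated by maximum likelihood. Ancestral states are
the ML (equivalently GLS) Brownian estimates used to draw the
phylomorphospace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import TreeError
from .io_core import vcv_matrix, _node_depths

_EIG_FLOOR = 1e-12


@dataclass
class SignalResult:
    statistic_name: str
    value: float
    p_value: float | None
    n_permutations: int = 0
    extra: dict | None = None


def _gls_mean(C_inv: np.ndarray, Y: np.ndarray) -> np.ndarray:
    one = np.ones((C_inv.shape[0], 1))
    return (one.T @ C_inv @ Y) / (one.T @ C_inv @ one).item()


def _inv_sqrt(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, V = np.linalg.eigh(C)
    if lam.min() < _EIG_FLOOR:
        raise TreeError(
            "tree covariance is singular (zero-length duplicate tips?); "
            "jitter branch lengths"
        )
    return V @ np.diag(1.0 / np.sqrt(lam)) @ V.T, V @ np.diag(1.0 / lam) @ V.T


def _kmult_stat(Y: np.ndarray, C: np.ndarray, C_inv_sqrt: np.ndarray,
                C_inv: np.ndarray) -> float:
    n = Y.shape[0]
    a = _gls_mean(C_inv, Y)
    Yc = Y - a
    num = float(np.sum(Yc**2))
    U = C_inv_sqrt @ Yc
    den = float(np.sum(U**2))
    one = np.ones((n, 1))
    expected = (np.trace(C) - n / (one.T @ C_inv @ one).item()) / (n - 1)
    return (num / den) / expected


def kmult(
    data: pd.DataFrame | np.ndarray,
    tree,
    species=None,
    n_perm: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Multivariate Blomberg K with a species-shuffling permutation test.

    ``data`` is (species x axes); ``species`` gives tip labels (defaults to
    the DataFrame index). p = (1 + #{K_perm >= K_obs}) / (1 + n_perm).
    """
    if isinstance(data, pd.DataFrame):
        species = list(data.index) if species is None else list(species)
        Y = data.to_numpy(dtype=float)
    else:
        Y = np.asarray(data, dtype=float)
        species = list(species)
    if Y.ndim == 1:
        Y = Y[:, None]
    C = vcv_matrix(tree, species)
    C_inv_sqrt, C_inv = _inv_sqrt(C)
    obs = _kmult_stat(Y, C, C_inv_sqrt, C_inv)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        if _kmult_stat(Y[perm], C, C_inv_sqrt, C_inv) >= obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    name = "K_mult" if Y.shape[1] > 1 else "K"
    return SignalResult(name, float(obs), float(p), n_perm)


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------


def _lambda_loglik(lam: float, y: np.ndarray, C: np.ndarray) -> float:
    n = len(y)
    Cl = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    sign, logdet = np.linalg.slogdet(Cl)
    if sign <= 0:
        return -np.inf
    Ci = np.linalg.inv(Cl)
    a = _gls_mean(Ci, y[:, None]).item()
    r = y - a
    sigma2 = (r @ Ci @ r).item() / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagels_lambda(data, tree, species=None) -> SignalResult:
    """ML estimate of Pagel's lambda for a univariate trait.

    The off-diagonal entries of the Brownian covariance are multiplied by
    lambda in [0, 1]; mean and rate are profiled out analytically. The
    p-value is a likelihood-ratio test against lambda = 0 (chi-square,
    1 df)."""
    if isinstance(data, pd.Series):
        species = list(data.index) if species is None else list(species)
        y = data.to_numpy(dtype=float)
    else:
        y = np.asarray(data, dtype=float).ravel()
        species = list(species)
    C = vcv_matrix(tree, species)
    if len(y) < 4:
        import warnings

        warnings.warn("fewer than 4 tips: lambda likelihood is nearly flat")
    res = minimize_scalar(
        lambda l: -_lambda_loglik(l, y, C),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    cands = [(res.x, -res.fun), (0.0, _lambda_loglik(0.0, y, C)),
             (1.0, _lambda_loglik(1.0, y, C))]
    lam_hat, ll_hat = max(cands, key=lambda t: t[1])
    ll0 = _lambda_loglik(0.0, y, C)
    from scipy.stats import chi2

    lr = max(0.0, 2 * (ll_hat - ll0))
    p = float(chi2.sf(lr, df=1))
    return SignalResult("lambda", float(lam_hat), p, 0,
                        extra={"loglik": ll_hat, "loglik_lambda0": ll0})


# ---------------------------------------------------------------------------
# Ancestral states
# ---------------------------------------------------------------------------


def ancestral_states(data: pd.DataFrame, tree, species=None) -> pd.DataFrame:
    """ML (GLS) Brownian ancestral estimates at every internal node.

    The root estimate is the phylogenetic mean; other nodes are the BM
    conditional expectations given the tips. Internal nodes are labeled
    ``node0, node1, ...`` in preorder when unnamed.
    """
    if isinstance(data, pd.DataFrame):
        species = list(data.index) if species is None else list(species)
        Y = data.to_numpy(dtype=float)
        cols = list(data.columns)
    else:
        Y = np.asarray(data, dtype=float)
        species = list(species)
        cols = [f"axis{j}" for j in range(Y.shape[1])]
    if Y.ndim == 1:
        Y = Y[:, None]
    C = vcv_matrix(tree, species)
    _, C_inv = _inv_sqrt(C)
    a = _gls_mean(C_inv, Y)
    Yc = Y - a
    depths = _node_depths(tree)
    idx = {sp: i for i, sp in enumerate(species)}

    labels, rows = [], []
    for k, node in enumerate(tree.preorder_internal_node_iter()):
        tips_below = [leaf.taxon.label for leaf in node.leaf_iter()]
        j = idx[tips_below[0]]
        c_v = np.minimum(C[j], depths[node])
        est = a.ravel() + c_v @ C_inv @ Yc
        label = node.label if node.label else f"node{k}"
        node.label = label
        labels.append(label)
        rows.append(est)
    return pd.DataFrame(rows, index=pd.Index(labels, name="node"), columns=cols)


def phylomorphospace_edges(
    tip_scores: pd.DataFrame, anc: pd.DataFrame, tree
) -> pd.DataFrame:
    """Edge list (parent/child node positions) for phylomorphospace plots."""
    pos = {}
    for k, node in enumerate(tree.preorder_internal_node_iter()):
        pos[id(node)] = anc.iloc[k].to_numpy()
    rows = []
    cols = list(anc.columns)
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        child = (
            tip_scores.loc[node.taxon.label].to_numpy()
            if node.is_leaf()
            else pos[id(node)]
        )
        rec = {"child": node.taxon.label if node.is_leaf() else node.label}
        for c, a_val, b_val in zip(cols, pos[id(parent)], child):
            rec[f"parent_{c}"], rec[f"child_{c}"] = float(a_val), float(b_val)
        rows.append(rec)
    return pd.DataFrame.from_records(rows)
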