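"""Wheatsheaf index: strength of convergent evolution per melanosome type.

w = mean phylogenetically corrected phenotypic distance over all species
pairs divided by the same mean over pairs of the focal (putatively
convergent) group; w > 1 means the focal species are phenotypically closer
than average. The phylogenetic correction inflates distances between close
relatives, because resemblance among relatives is weak evidence of
convergence: d'_ij = d_ij * (1 + s_ij) with s_ij the proportion of the
root-to-tip path the pair shares, so the correction vanishes on a star
tree. Traits are z-standardized per axis first, making w invariant to
units, uniform scaling, and rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_core import vcv_matrix, tree_depth
from .morphometrics import species_means


@dataclass
class WheatsheafResult:
    focal_group: list
    w: float
    ci95: tuple
    p_value: float
    trait_space: str
    n_boot: int


def _corrected_distances(
    X: np.ndarray, C: np.ndarray, depth: float,
    penalty: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Pairwise standardized Euclidean distances with phylogenetic penalty."""
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - X.mean(axis=0)) / sd
    diff = Z[:, None, :] - Z[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    shared = C.copy()
    np.fill_diagonal(shared, 0.0)
    S = shared / depth
    if penalty is None:
        return D * (1.0 + S)
    return penalty(D, S)


def _w_from_matrix(Dp: np.ndarray, focal_idx: np.ndarray) -> float:
    n = Dp.shape[0]
    iu = np.triu_indices(n, k=1)
    mean_all = Dp[iu].mean()
    sub = Dp[np.ix_(focal_idx, focal_idx)]
    iuf = np.triu_indices(len(focal_idx), k=1)
    mean_focal = sub[iuf].mean()
    return float(mean_all / mean_focal)


def wheatsheaf(
    data: pd.DataFrame,
    tree,
    focal: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    trait_space: str = "traits",
    penalty: Callable | None = None,
) -> WheatsheafResult:
    """Wheatsheaf index for a focal group of species.

    ``data`` is (species x axes) with species as index. The focal group
    should contain one representative per independent origin of the
    convergent phenotype. The 95% CI is a percentile bootstrap over species
    (focal membership kept with each resampled species); the p-value is the
    proportion of random equal-sized focal sets with w at least as large,
    with +1 smoothing.
    """
    species = list(data.index)
    focal = list(focal)
    if len(focal) < 2:
        raise ValueError("focal group needs at least 2 species")
    missing = sorted(set(focal) - set(species))
    if missing:
        raise ValueError(f"focal species not in data: {missing}")
    X = data.to_numpy(dtype=float)
    C = vcv_matrix(tree, species)
    depth = tree_depth(tree)
    Dp = _corrected_distances(X, C, depth, penalty)
    focal_idx = np.array([species.index(s) for s in focal])
    w_obs = _w_from_matrix(Dp, focal_idx)

    rng = np.random.default_rng(seed)
    n = len(species)
    boots = []
    while len(boots) < n_boot:
        idx = rng.integers(0, n, size=n)
        fmask = np.isin(idx, focal_idx)
        f_here = np.unique(idx[fmask])
        others = np.unique(idx[~fmask])
        if len(f_here) < 2 or len(np.unique(idx)) < 3:
            continue
        keep = np.concatenate([f_here, others[~np.isin(others, f_here)]])
        sub = Dp[np.ix_(keep, keep)]
        boots.append(_w_from_matrix(sub, np.arange(len(f_here))))
    lo, hi = np.percentile(boots, [2.5, 97.5])

    n_ge = 0
    for _ in range(n_boot):
        rand_focal = rng.choice(n, size=len(focal_idx), replace=False)
        if _w_from_matrix(Dp, rand_focal) >= w_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_boot)
    return WheatsheafResult(
        focal_group=focal,
        w=w_obs,
        ci95=(float(lo), float(hi)),
        p_value=float(p),
        trait_space=trait_space,
        n_boot=n_boot,
    )


def convergence_report(
    summaries: pd.DataFrame,
    tree,
    traits: pd.DataFrame,
    pcamix_scores: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Wheatsheaf index per melanosome type on two trait spaces.

    ``traits`` must carry species, melanosome_type and origin (independent
    origin index, as produced by the synthetic generator or user metadata).
    The focal group takes one species per origin. Tested spaces: all PCAmix
    axes (if scores given) and the standardized quantitative traits (mean
    length, mean width, aspect ratio). Types with fewer than two
    independent origins are skipped with a note.
    """
    per_species = species_means(summaries).set_index("species")
    quant = per_species[["mean_length_um", "mean_width_um", "aspect_ratio"]]
    rows = []
    types = [t for t in traits["melanosome_type"].unique() if t]
    for k, mtype in enumerate(sorted(types)):
        sub = traits[traits["melanosome_type"] == mtype]
        focal = (
            sub.sort_values("species").groupby("origin")["species"].first().tolist()
        )
        if len(focal) < 2:
            rows.append(
                dict(melanosome_type=mtype, trait_space="traits", w=np.nan,
                     ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                     note="single origin; skipped")
            )
            continue
        spaces = {"traits": quant}
        if pcamix_scores is not None:
            spaces["pcamix_scores"] = pcamix_scores
        for space_name, X in spaces.items():
            X = X.loc[[s for s in X.index if s in set(per_species.index)]]
            res = wheatsheaf(
                X, tree, focal, n_boot=n_boot, seed=seed + k,
                trait_space=space_name,
            )
            rows.append(
                dict(melanosome_type=mtype, trait_space=space_name, w=res.w,
                     ci_low=res.ci95[0], ci_high=res.ci95[1],
                     p_value=res.p_value, note="")
            )
    return pd.DataFrame.from_records(rows)
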