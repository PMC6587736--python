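"""Synthetic data with the statistical structure the analyses assume.

The generator emulates a comparative dataset of feather melanosome
measurements: an ultrametric phylogeny; species mean log-dimensions evolving
by Brownian motion; four plumage-color categories (black, brown, grey,
iridescent) with distinct size optima; four iridescence-generating
melanosome types (solid/hollow x cylindrical/flat) each painted onto
several phylogenetically disjoint clades so the types arise convergently;
and per-melanosome measurements drawn lognormally around the species means
with a realistic within-species coefficient of variation (~20%).

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import dendropy
import numpy as np
import pandas as pd

from .errors import MelanomorphError
from .io_core import COLOR_CATEGORIES


@dataclass
class TypeRegime:
    """One convergently evolving melanosome type.

    ``n_origins`` disjoint clades are painted with this regime; painted
    species are displaced a fraction ``gamma`` (set on the config) from
    their Brownian value toward the regime optimum on the log scale.
    """

    melanosome_type: str
    n_origins: int
    optimum_length_um: float
    optimum_width_um: float
    flatness: bool
    hollowness: bool


def default_regimes() -> list[TypeRegime]:
    # Optima reflect typical dimensions: solid cylindrical melanosomes are
    # long and narrow; flat ones wider; hollow flat ones unusually large
    # (up to ~2.5 um in hummingbirds against a ~1 um overall average).
    return [
        TypeRegime("solid_cylindrical", 3, 1.10, 0.25, False, False),
        TypeRegime("solid_flat", 2, 1.20, 0.45, True, False),
        TypeRegime("hollow_cylindrical", 3, 1.05, 0.35, False, True),
        TypeRegime("hollow_flat", 2, 2.20, 0.90, True, True),
    ]


# Non-iridescent category optima (length um, width um): black melanosomes are
# long rods, brown short and stubby, grey low-aspect sausages.
CATEGORY_OPTIMA = {
    "black": (1.00, 0.28),
    "brown": (0.70, 0.38),
    "grey": (0.80, 0.50),
    "iridescent": (1.10, 0.28),  # baseline solid-cylindrical iridescence
}


@dataclass
class SimulationConfig:
    n_species: int = 96
    seed: int = 0
    birth_rate: float = 1.0
    category_proportions: dict = field(
        default_factory=lambda: {
            "black": 0.25,
            "brown": 0.20,
            "grey": 0.20,
            "iridescent": 0.35,
        }
    )
    type_regimes: list = field(default_factory=default_regimes)
    bm_rate: float = 0.04  # variance per unit depth on the log scale
    gamma: float = 0.85  # displacement fraction toward regime/category optimum
    within_species_cv: float = 0.20
    melanosomes_per_sample: int = 25
    clade_size_range: tuple = (2, 3)

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("category_proportions must sum to 1")
        if self.within_species_cv <= 0:
            raise ValueError("within_species_cv must be > 0")
        for reg in self.type_regimes:
            if reg.n_origins < 1:
                raise ValueError("each regime needs n_origins >= 1")


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(config: SimulationConfig, rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_species`` tips, depth rescaled to 1.

    All lineages survive to the present, so the tree is ultrametric by
    construction. Deterministic given the config seed.
    """
    if config.n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    # each active lineage: (node, birth_time)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child()
        active.append(child)
    births = {id(node): 0.0 for node in active}
    t = 0.0
    while len(active) < config.n_species:
        k = len(active)
        t += rng.exponential(1.0 / (config.birth_rate * k))
        i = int(rng.integers(k))
        node = active.pop(i)
        node.edge.length = t - births[id(node)]
        for _ in range(2):
            child = node.new_child()
            active.append(child)
            births[id(child)] = t
    k = len(active)
    t += rng.exponential(1.0 / (config.birth_rate * k))
    for node in active:
        node.edge.length = t - births[id(node)]
    root.edge.length = 0.0

    # name tips in a stable order and rescale depth to 1
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxon_ns.new_taxon(label=f"Genus{i // 2}_sp{i % 2 + 1}")
    scale = 1.0 / t
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


# ---------------------------------------------------------------------------
# Species traits
# ---------------------------------------------------------------------------


def _brownian_tips(tree: dendropy.Tree, rate: float, root_state: float,
                   rng: np.random.Generator) -> dict:
    """Simulate BM along the tree; return {tip label: value}."""
    states = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            states[node] = root_state
        else:
            bl = node.edge.length or 0.0
            states[node] = states[parent] + rng.normal(0.0, math.sqrt(rate * bl))
    return {leaf.taxon.label: states[leaf] for leaf in tree.leaf_node_iter()}


def _disjoint_clades(tree: dendropy.Tree, n_clades: int, size_range: tuple,
                     rng: np.random.Generator, taken: set) -> list[list[str]]:
    """Pick ``n_clades`` disjoint clades with tip counts in size_range,
    avoiding tips already in ``taken``."""
    lo, hi = size_range
    candidates = []
    for node in tree.preorder_internal_node_iter():
        tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        if lo <= len(tips) <= hi and not (set(tips) & taken):
            candidates.append(tips)
    order = rng.permutation(len(candidates))
    chosen: list[list[str]] = []
    used: set = set()
    for j in order:
        tips = candidates[j]
        if set(tips) & used:
            continue
        chosen.append(tips)
        used.update(tips)
        if len(chosen) == n_clades:
            return chosen
    raise MelanomorphError(
        f"could not find {n_clades} disjoint clades of size {size_range}; "
        "use fewer origins or a larger tree"
    )


def simulate_species_traits(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign per-species color category, melanosome type, and true mean
    log-dimensions.

    Log length and log width evolve by Brownian motion from the root state
    (the log of the 1-um-scale category baseline). Convergent regimes are
    painted on disjoint clades; painted species are pulled a fraction
    ``gamma`` toward the regime optimum. Remaining species get categories
    i.i.d. with probabilities chosen so the overall composition matches
    ``category_proportions`` in expectation; their log-dimensions are pulled
    toward the category optimum by the same gamma.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n = len(tips)

    root_logL, root_logW = math.log(0.9), math.log(0.35)
    bm_logL = _brownian_tips(tree, config.bm_rate, root_logL, rng)
    bm_logW = _brownian_tips(tree, config.bm_rate, root_logW, rng)

    taken: set = set()
    regime_of: dict = {}
    origin_of: dict = {}
    for reg in config.type_regimes:
        clades = _disjoint_clades(tree, reg.n_origins, config.clade_size_range, rng, taken)
        for origin_idx, clade in enumerate(clades):
            for sp in clade:
                regime_of[sp] = reg
                origin_of[sp] = origin_idx
            taken.update(clade)

    n_painted = len(taken)
    rest = [sp for sp in tips if sp not in taken]
    props = config.category_proportions
    extra_irid = max(0.0, props["iridescent"] * n - n_painted)
    weights = np.array(
        [props["black"] * n, props["brown"] * n, props["grey"] * n, extra_irid],
        dtype=float,
    )
    weights /= weights.sum()
    cats = rng.choice(np.array(COLOR_CATEGORIES), size=len(rest), p=weights)

    records = []
    g = config.gamma
    for sp in tips:
        if sp in regime_of:
            reg = regime_of[sp]
            cat, mtype = "iridescent", reg.melanosome_type
            optL, optW = math.log(reg.optimum_length_um), math.log(reg.optimum_width_um)
            origin = origin_of[sp]
            flat, hollow = reg.flatness, reg.hollowness
        else:
            cat = cats[rest.index(sp)]
            mtype = "solid_cylindrical" if cat == "iridescent" else ""
            oL, oW = CATEGORY_OPTIMA[cat]
            optL, optW = math.log(oL), math.log(oW)
            origin = -1
            flat = hollow = False
        logL = bm_logL[sp] + g * (optL - bm_logL[sp])
        logW = bm_logW[sp] + g * (optW - bm_logW[sp])
        logW = min(logW, logL)  # widths cannot exceed lengths
        records.append(
            dict(
                species=sp,
                color_category=cat,
                melanosome_type=mtype,
                origin=origin,
                flatness=flat,
                hollowness=hollow,
                true_mean_log_length=logL,
                true_mean_log_width=logW,
            )
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Per-melanosome measurements
# ---------------------------------------------------------------------------


def sample_melanosomes(
    species_traits: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-melanosome length/width measurements for every species.

    Dimensions are lognormal around the species mean with coefficient of
    variation ``within_species_cv`` (lognormal guarantees positivity);
    width > length draws are swapped.
    """
    if config.melanosomes_per_sample < 1:
        raise ValueError("melanosomes_per_sample must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    cv = config.within_species_cv
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)

    rows = []
    for rec in species_traits.itertuples(index=False):
        m = config.melanosomes_per_sample
        # arithmetic mean of lognormal(mu, sigma) is exp(mu + sigma^2/2)
        muL = rec.true_mean_log_length - sigma2 / 2.0
        muW = rec.true_mean_log_width - sigma2 / 2.0
        L = np.exp(rng.normal(muL, sigma, size=m))
        W = np.exp(rng.normal(muW, sigma, size=m))
        swap = W > L
        L[swap], W[swap] = W[swap], L[swap]
        for l_um, w_um in zip(L, W):
            rows.append(
                dict(
                    sample_id=f"{rec.species}_s1",
                    species=rec.species,
                    color_category=rec.color_category,
                    melanosome_type=rec.melanosome_type,
                    length_um=float(l_um),
                    width_um=float(w_um),
                )
            )
    return pd.DataFrame.from_records(rows)


def apply_shrinkage(table: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Shrink linear dimensions multiplicatively by ``fraction``.

    Mimics taphonomic volume loss during fossilization/maturation; flags and
    per-melanosome aspect ratios are unchanged.
    """
    if not 0 <= fraction < 1:
        raise ValueError("shrinkage fraction must be in [0, 1)")
    out = table.copy()
    out["length_um"] = out["length_um"] * (1.0 - fraction)
    out["width_um"] = out["width_um"] * (1.0 - fraction)
    return out


def make_dataset(
    config: SimulationConfig,
) -> tuple[dendropy.Tree, pd.DataFrame, pd.DataFrame]:
    """Convenience: tree, species traits, and measurement table in one call."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    traits = simulate_species_traits(tree, config, rng)
    table = sample_melanosomes(traits, config, rng)
    return tree, traits, table
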