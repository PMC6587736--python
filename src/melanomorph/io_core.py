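"""Measurement-table and tree I/O, dataset filters, and reference-tree grafting.

Measurement tables are per-melanosome rows (one sample = one feather patch
from one species) carrying length and width in micrometres plus the
qualitative flags used downstream. Trees are Newick with branch lengths in
time units; species missing from a reference tree can be grafted next to
congeners as polytomies.
"""

from __future__ import annotations

import io
import json
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import SchemaError, TreeError, UnresolvableTaxonError, ValidationError

COLOR_CATEGORIES = ("black", "brown", "grey", "iridescent")
MELANOSOME_TYPES = (
    "solid_cylindrical",
    "solid_flat",
    "hollow_cylindrical",
    "hollow_flat",
)

REQUIRED_COLUMNS = (
    "sample_id",
    "species",
    "color_category",
    "melanosome_type",
    "length_um",
    "width_um",
)


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def validate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a measurement table in place and return it.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If any row violates the invariants (nonpositive dimensions, unknown
        categories, or a sample_id mapped to more than one species/category).
        The message names the offending rows.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    bad: list[str] = []
    for col in ("length_um", "width_um"):
        vals = pd.to_numeric(table[col], errors="coerce")
        mask = ~(vals > 0)
        if mask.any():
            rows = table.index[mask].tolist()
            bad.append(f"{col} not a positive number at rows {rows}")
        table[col] = vals

    unknown_cat = ~table["color_category"].isin(COLOR_CATEGORIES)
    if unknown_cat.any():
        bad.append(
            f"unknown color_category at rows {table.index[unknown_cat].tolist()}"
        )
    typed = table["melanosome_type"].notna() & (table["melanosome_type"] != "")
    unknown_type = typed & ~table["melanosome_type"].isin(MELANOSOME_TYPES)
    if unknown_type.any():
        bad.append(
            f"unknown melanosome_type at rows {table.index[unknown_type].tolist()}"
        )

    for key in ("species", "color_category"):
        per_sample = table.groupby("sample_id")[key].nunique()
        multi = per_sample[per_sample > 1]
        if len(multi):
            bad.append(f"sample_id with more than one {key}: {multi.index.tolist()}")

    if bad:
        raise ValidationError("; ".join(bad))
    return table


def read_measurements(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read and validate a per-melanosome measurement table (CSV or TSV).

    The delimiter is auto-detected from the header line when not given.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    if not text.strip():
        raise SchemaError(f"empty measurement file: {path}")
    if delimiter is None:
        delimiter = _detect_delimiter(text.splitlines()[0])
    table = pd.read_csv(io.StringIO(text), sep=delimiter, dtype={"sample_id": str})
    return validate_measurements(table)


def write_measurements(table: pd.DataFrame, path, delimiter: str = ",") -> None:
    table.to_csv(path, sep=delimiter, index=False)


def filter_dataset(
    table: pd.DataFrame,
    exclude_species: Sequence[str] = (),
    min_n: int = 10,
    drop_flagged: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Apply dataset filters and return (filtered table, JSON-able report).

    Rows of excluded species (e.g. penguins, whose melanosome shape tracks
    an aquatic lifestyle rather than color) are removed. Samples with fewer
    than ``min_n`` melanosomes are flagged in the report and removed only
    when ``drop_flagged`` is set; small samples are otherwise kept because
    sample-size-sensitive statistics are excluded downstream instead.
    """
    if min_n < 0:
        raise ValueError("min_n must be >= 0")
    report: dict = {"excluded_species": {}, "flagged_small_samples": {}, "warnings": []}

    present = set(table["species"])
    for sp in exclude_species:
        if sp not in present:
            report["warnings"].append(f"exclusion list species not in table: {sp}")
    keep = ~table["species"].isin(set(exclude_species))
    for sp in sorted(set(table.loc[~keep, "species"])):
        report["excluded_species"][sp] = int((table["species"] == sp).sum())
    out = table.loc[keep].copy()

    sizes = out.groupby("sample_id").size()
    small = sizes[sizes < min_n] if min_n > 0 else sizes.iloc[:0]
    report["flagged_small_samples"] = {str(k): int(v) for k, v in small.items()}
    if drop_flagged and len(small):
        out = out[~out["sample_id"].isin(set(small.index))]
    report["n_rows_out"] = int(len(out))
    report["n_samples_out"] = int(out["sample_id"].nunique())
    return out.reset_index(drop=True), report


def write_filter_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(source) -> dendropy.Tree:
    """Parse a Newick tree (path or string); polytomies are allowed.

    Raises TreeError for malformed Newick, unnamed tips, duplicate tip
    names, or negative branch lengths.
    """
    try:
        if isinstance(source, str) and "(" in source:
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=str(source), schema="newick", preserve_underscores=True
            )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick: {exc}") from exc
    tree.is_rooted = True  # comparative analyses need a rooted tree
    names = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise TreeError("tree has unnamed tip(s)")
        names.append(leaf.taxon.label)
    if len(set(names)) != len(names):
        raise TreeError("duplicate tip names")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeError(f"negative branch length on edge to {edge.head_node}")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path), schema="newick", suppress_rooting=True,
        unquoted_underscores=True,
    )


def tree_tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        base = depths[parent] if parent is not None else 0.0
        depths[node] = base + (node.edge.length or 0.0)
    return depths


def tree_depth(tree: dendropy.Tree) -> float:
    depths = _node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = _node_depths(tree)
    tips = [depths[leaf] for leaf in tree.leaf_node_iter()]
    span = max(tips)
    return span == 0 or (max(tips) - min(tips)) <= rel_tol * span


def vcv_matrix(tree: dendropy.Tree, order: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance matrix: C[i, j] = shared root-to-MRCA path.

    ``order`` fixes the row/column order by tip label.
    """
    depths = _node_depths(tree)
    label_to_leaf = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [sp for sp in order if sp not in label_to_leaf]
    if missing:
        raise TreeError(f"taxa not in tree: {missing}")
    # bitmask of descendant tips per node, over `order`
    idx = {sp: i for i, sp in enumerate(order)}
    n = len(order)
    C = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._mm_tips = (
                [idx[node.taxon.label]] if node.taxon.label in idx else []
            )
        else:
            tips: list[int] = []
            children = node.child_nodes()
            depth = depths[node]
            for a in range(len(children)):
                ta = children[a]._mm_tips
                for b in range(a + 1, len(children)):
                    tb = children[b]._mm_tips
                    for i in ta:
                        C[i, tb] = depth
                        C[np.array(tb, dtype=int), i] = depth
                tips.extend(ta)
            node._mm_tips = tips
    for sp, i in idx.items():
        C[i, i] = depths[label_to_leaf[sp]]
    for node in tree.postorder_node_iter():
        del node._mm_tips
    return C


def _mrca(nodes) -> "dendropy.Node":
    paths = []
    for node in nodes:
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent_node
        paths.append(path[::-1])
    deepest = None
    for ancestors in zip(*paths):
        if all(a is ancestors[0] for a in ancestors):
            deepest = ancestors[0]
        else:
            break
    return deepest


def _genus_of(species: str) -> str:
    return species.replace(" ", "_").split("_")[0]


def prune_and_graft(
    tree: dendropy.Tree,
    species: Sequence[str],
    genus_map: Mapping[str, str] | None = None,
    graft_fraction: float = 0.5,
) -> dendropy.Tree:
    """Prune a reference tree to ``species``, grafting absent taxa by genus.

    A species not in the tree is attached to its congeners: with two or more
    congeneric tips it becomes an extra child of their MRCA (a polytomy, as
    the branch length makes the new tip contemporaneous with the others);
    with a single congener the terminal branch is split at ``graft_fraction``
    of its length (measured from the parent) and both species hang from the
    new node. Ultrametric inputs therefore stay ultrametric.

    Raises UnresolvableTaxonError listing species whose genus is absent.
    """
    if not 0 < graft_fraction < 1:
        raise ValueError("graft_fraction must be in (0, 1)")
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    genus_map = dict(genus_map or {})
    label_to_leaf = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}

    to_graft = [sp for sp in species if sp not in label_to_leaf]
    unresolved = []
    for sp in to_graft:
        genus = genus_map.get(sp, _genus_of(sp))
        congeners = [
            leaf
            for label, leaf in label_to_leaf.items()
            if genus_map.get(label, _genus_of(label)) == genus
        ]
        if not congeners:
            unresolved.append(sp)
    if unresolved:
        raise UnresolvableTaxonError(
            f"no congeneric tips in tree for: {sorted(unresolved)}"
        )

    for sp in to_graft:
        genus = genus_map.get(sp, _genus_of(sp))
        congeners = [
            leaf
            for label, leaf in label_to_leaf.items()
            if genus_map.get(label, _genus_of(label)) == genus
        ]
        depths = _node_depths(tree)
        taxon = tree.taxon_namespace.new_taxon(label=sp)
        if len(congeners) >= 2:
            mrca = _mrca(congeners)
            tip_depth = max(depths[c] for c in congeners)
            new = mrca.new_child(taxon=taxon, edge_length=tip_depth - depths[mrca])
        else:
            sib = congeners[0]
            parent = sib.parent_node
            stem = sib.edge.length or 0.0
            split_at = stem * graft_fraction
            mid = parent.new_child(edge_length=split_at)
            parent.remove_child(sib)
            mid.add_child(sib)
            sib.edge.length = stem - split_at
            mid.new_child(taxon=taxon, edge_length=stem - split_at)
        label_to_leaf[sp] = [
            leaf for leaf in tree.leaf_node_iter() if leaf.taxon is taxon
        ][0]

    keep_taxa = [label_to_leaf[sp].taxon for sp in species]
    tree.retain_taxa(keep_taxa)
    tree.purge_taxon_namespace()
    return tree
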