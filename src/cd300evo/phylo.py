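"""Distance-based phylogenetics for the paired-receptor analysis.

Trees are built by neighbor joining on p- or Poisson-corrected protein
distances with column-resampling bootstrap.  The headline statistic is
:func:`paralog_sister_fraction`: the fraction of species whose CD300A/CD300C
paralogs form a cherry (sister pair) in the tree.  Under independent
divergence the paralogs form two gene clades and the fraction is near 0;
under concerted evolution (gene conversion homogenizing the paralogs within
species) sequences cluster by species and the fraction approaches 1.

Trees are represented as :class:`dendropy.Tree` objects; leaf taxa are
labelled ``species|gene``.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .align import Alignment

__all__ = [
    "DistanceMatrix",
    "protein_distance",
    "nj_tree",
    "bootstrap",
    "paralog_sister_fraction",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.diag(v).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("distances must be finite and non-negative")
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)


class SaturationError(ValueError):
    """Poisson correction undefined: a pair differs at every usable column."""


def protein_distance(msa: Alignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise protein distances with pairwise deletion of gapped columns.

    ``model="p"`` is the raw proportion of differing columns; ``"poisson"``
    applies the correction ``-ln(1 - p)`` for multiple hits.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"model must be 'p' or 'poisson', got {model!r}")
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 rows")
    arr = np.array([list(r) for r in msa.rows])
    gap = arr == "-"
    n = len(msa.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~gap[i] & ~gap[j]
            n_use = int(usable.sum())
            if n_use == 0:
                raise ValueError(
                    f"no usable columns between {msa.labels[i]!r} and {msa.labels[j]!r}"
                )
            p = float((arr[i, usable] != arr[j, usable]).sum()) / n_use
            if model == "poisson":
                if p >= 1.0:
                    raise SaturationError(
                        f"saturated pair {msa.labels[i]!r} vs {msa.labels[j]!r} (p={p})"
                    )
                p = -np.log1p(-p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(msa.labels), d)


def _quote(label: str) -> str:
    return f"'{label}'" if set(label) & set("()[]:;,|' \t") else label


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor joining.

    Q-matrix ties are broken by the lowest (i, j) index pair in the current
    matrix; negative branch lengths are clamped to zero.  Returns an
    unrooted tree (trifurcation at the seed node).
    """
    n = len(d)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    active = [ _quote(lab) for lab in d.labels ]
    dist = d.values.copy()

    while len(active) > 3:
        m = len(active)
        r = dist.sum(axis=1)
        q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among the minima, row-major
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_label = f"({active[i]}:{li:.6f},{active[j]}:{lj:.6f})"
        new_dist = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        dist = np.vstack([dist[keep][:, keep], new_dist[keep]])
        dist = np.hstack([dist, np.append(new_dist[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [new_label]

    a, b, c = active
    dab, dac, dbc = dist[0, 1], dist[0, 2], dist[1, 2]
    la = max((dab + dac - dbc) / 2, 0.0)
    lb = max((dab + dbc - dac) / 2, 0.0)
    lc = max((dac + dbc - dab) / 2, 0.0)
    newick = f"({a}:{la:.6f},{b}:{lb:.6f},{c}:{lc:.6f});"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


def bootstrap(
    msa: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "poisson",
) -> dendropy.Tree:
    """NJ tree with bootstrap supports from column resampling.

    Supports (% of replicate trees containing each internal bipartition) are
    stored as internal node labels of the point-estimate tree.  Replicates
    whose resampled columns leave a pair saturated (or unusable) are redrawn,
    which keeps the replicate count at ``n_reps``.
    """
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    main = nj_tree(protein_distance(msa, model))
    ns = main.taxon_namespace
    main.encode_bipartitions()
    counts = {edge.bipartition.split_bitmask: 0 for edge in main.preorder_edge_iter()}

    rng = np.random.default_rng(seed)
    ncol = msa.n_columns
    done = 0
    attempts = 0
    while done < n_reps:
        attempts += 1
        if attempts > 100 * n_reps:
            raise SaturationError(
                "bootstrap replicates persistently saturated; use model='p'"
            )
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(r[c] for c in cols) for r in msa.rows]
        try:
            rep_tree = nj_tree(
                protein_distance(Alignment(list(msa.labels), rows, msa.kind), model)
            )
        except (SaturationError, ValueError):
            continue
        rep_tree = dendropy.Tree.get(
            data=rep_tree.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=ns,
            preserve_underscores=True,
        )
        rep_tree.is_rooted = False
        rep_tree.encode_bipartitions()
        rep_masks = {e.bipartition.split_bitmask for e in rep_tree.preorder_edge_iter()}
        for mask in counts:
            if mask in rep_masks:
                counts[mask] += 1
        done += 1

    for node in main.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        support = 100.0 * counts[node.edge.bipartition.split_bitmask] / n_reps
        node.label = f"{support:.0f}"
    return main


def _unrooted_degree(node: dendropy.Node) -> int:
    return len(node.child_nodes()) + (0 if node.parent_node is None else 1)


def paralog_sister_fraction(tree: dendropy.Tree, delimiter: str = "|") -> float:
    """Fraction of two-paralog species whose A and C copies form a cherry.

    A cherry is a pair of leaves adjacent to the same internal node of
    unrooted degree 3.  Only species carrying both paralogs are counted.
    """
    leaves: dict[tuple[str, str], dendropy.Node] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        parts = label.split(delimiter)
        if len(parts) < 2:
            raise ValueError(f"leaf label {label!r} lacks species{delimiter}gene form")
        leaves[(parts[0], parts[1])] = leaf

    species = sorted({s for s, _ in leaves})
    counted = 0
    cherries = 0
    for sp in species:
        a, c = leaves.get((sp, "A")), leaves.get((sp, "C"))
        if a is None or c is None:
            continue
        counted += 1
        if a.parent_node is c.parent_node and _unrooted_degree(a.parent_node) == 3:
            cherries += 1
    if counted == 0:
        raise ValueError("no species carries both paralogs")
    return cherries / counted
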