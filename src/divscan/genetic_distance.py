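"""Nei's standard genetic distance between individuals and neighbor-joining.

Each diploid individual is treated as a one-member population whose
reference-allele frequency at a biallelic locus is 1, 0.5 or 0 according to
its genotype class.  For two individuals X and Y over the loci where both
have passing genotypes (pairwise-complete: loci missing in either individual
are excluded from all means),

    J_X  = mean(p_X^2 + q_X^2)
    J_Y  = mean(p_Y^2 + q_Y^2)
    J_XY = mean(p_X p_Y + q_X q_Y)
    D    = -ln( J_XY / sqrt(J_X * J_Y) )

The Cauchy-Schwarz inequality over the shared loci guarantees the identity
I = J_XY / sqrt(J_X J_Y) <= 1, hence D >= 0.  The tree is built by
neighbor-joining (Studier-Keppler Q criterion) and rooted on the wild
outgroup.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .io_formats import MISSING, PopulationMap, VariantTable
from .variant_filtering import (DEFAULT_DP_HI, DEFAULT_DP_LO, DEFAULT_MIN_GQ,
                                SEGREGATING, SiteClassifications, passing_mask)

logger = logging.getLogger(__name__)

DEFAULT_MIN_POPULATIONS = 9


def select_shared_sites(classifications: SiteClassifications,
                        k: int = DEFAULT_MIN_POPULATIONS,
                        mode: str = "called") -> np.ndarray:
    """Boolean mask of sites usable for the distance analysis.

    ``mode="called"`` keeps sites with genotypes called in at least ``k``
    populations, whether or not they segregate there; ``mode="segregating"``
    requires segregating status in at least ``k``.
    """
    if mode == "called":
        return classifications.n_populations_called >= k
    if mode == "segregating":
        return np.sum(classifications.status == SEGREGATING, axis=1) >= k
    raise ValueError("mode must be 'called' or 'segregating'")


def frequency_matrix(table: VariantTable, min_gq: int = DEFAULT_MIN_GQ,
                     dp_lo: int = DEFAULT_DP_LO,
                     dp_hi: int = DEFAULT_DP_HI) -> np.ndarray:
    """Per-individual reference-allele frequencies, NaN where not passing.

    Genotype classes map to p in {1, 0.5, 0}.
    """
    ok = passing_mask(table, min_gq, dp_lo, dp_hi)
    p = 1.0 - table.gt.astype(float) / 2.0
    p[table.gt == MISSING] = np.nan
    p[~ok] = np.nan
    return p


def nei_distance(px: np.ndarray, py: np.ndarray) -> float:
    """Nei's standard distance from two frequency vectors (NaN = missing)."""
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    shared = ~np.isnan(px) & ~np.isnan(py)
    if not np.any(shared):
        return float("nan")
    x, y = px[shared], py[shared]
    jx = float(np.mean(x * x + (1 - x) * (1 - x)))
    jy = float(np.mean(y * y + (1 - y) * (1 - y)))
    jxy = float(np.mean(x * y + (1 - x) * (1 - y)))
    if jxy == 0.0:
        return float("inf")
    return -math.log(jxy / math.sqrt(jx * jy))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        self.matrix = m

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{v:.6f}" for v in self.matrix[i])
                fh.write(f"{lab:<10s} {row}\n")

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.labels,
                     columns=self.labels).to_csv(path, sep="\t")


def nei_distance_matrix(table: VariantTable,
                        population_map: PopulationMap | None = None,
                        site_mask: np.ndarray | None = None,
                        min_gq: int = DEFAULT_MIN_GQ,
                        dp_lo: int = DEFAULT_DP_LO,
                        dp_hi: int = DEFAULT_DP_HI) -> DistanceMatrix:
    """All-pairs Nei distance among the table's individuals."""
    p = frequency_matrix(table, min_gq, dp_lo, dp_hi)
    if site_mask is not None:
        p = p[site_mask]
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(p[:, i], p[:, j])
    return DistanceMatrix(list(table.samples), d)


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True
                     ) -> dendropy.Tree:
    """Saitou-Nei agglomeration with the Studier-Keppler Q criterion.

    Ties in Q are broken by the lexicographically smallest pair of cluster
    labels (a cluster is labelled by its smallest leaf).  Negative branch
    lengths are clamped to zero unless ``clamp_negative`` is False.  The
    returned tree is unrooted (trifurcating seed node for >= 3 taxa).
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    d = dm.matrix.astype(float).copy()
    if np.any(~np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries")

    frags = [_quote(lab) for lab in labels]
    reps = list(labels)  # tie-break representative: smallest leaf label
    active = list(range(n))

    def fmt(x: float) -> str:
        if clamp_negative and x < 0:
            x = 0.0
        return repr(float(x))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((reps[active[a]], reps[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        # distances from the new node to the remaining clusters
        new_d = 0.5 * (sub[a] + sub[b] - dij)
        u = len(frags)
        frags.append(f"({frags[i]}:{fmt(li)},{frags[j]}:{fmt(lj)})")
        reps.append(min(reps[i], reps[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        keep = [x for x in active if x not in (i, j)]
        for idx, k in enumerate([x for x in range(m) if x not in (a, b)]):
            d[u, keep[idx]] = d[keep[idx], u] = new_d[k]
        active = keep + [u]

    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        newick = (f"({frags[i]}:{fmt(li)},{frags[j]}:{fmt(lj)},"
                  f"{frags[k]}:{fmt(lk)});")
    else:  # 2 taxa
        i, j = active
        half = d[i, j] / 2
        newick = f"({frags[i]}:{fmt(half)},{frags[j]}:{fmt(half)});"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def _quote(label: str) -> str:
    if any(c in label for c in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def root_at_outgroup(tree: dendropy.Tree, outgroup_labels) -> dendropy.Tree:
    """Root the tree on the branch separating the outgroup from the rest.

    If the outgroup is not monophyletic in the unrooted tree this is reported
    and the root is placed at the midpoint of the edge above the outgroup's
    MRCA.  Re-rooting an already-rooted tree is a no-op.
    """
    outgroup = set(outgroup_labels)
    all_leaves = leaf_labels(tree)
    if not outgroup or not outgroup <= all_leaves:
        raise ValueError("outgroup labels must be a non-empty subset of leaves")
    tree = tree.clone(depth=1)

    root = tree.seed_node
    kids = root.child_nodes()
    if len(kids) == 2:
        for child in kids:
            below = {lf.taxon.label for lf in child.leaf_iter()}
            if below == outgroup:
                return tree  # already rooted here: idempotent

    # hang the tree from an ingroup leaf so the outgroup MRCA is well defined
    ingroup_leaf = next(lf for lf in tree.leaf_node_iter()
                        if lf.taxon.label not in outgroup)
    tree.is_rooted = True
    tree.reroot_at_node(ingroup_leaf.parent_node,
                        update_bipartitions=False)
    mrca = tree.mrca(taxon_labels=list(outgroup))
    below = {lf.taxon.label for lf in mrca.leaf_iter()}
    if below != outgroup:
        logger.warning("outgroup %s is not monophyletic (clade spans %s); "
                       "rooting at the MRCA edge midpoint", sorted(outgroup),
                       sorted(below))
    edge = mrca.edge
    length = edge.length if edge.length is not None else 0.0
    tree.reroot_at_edge(edge, length1=length / 2, length2=length / 2,
                        update_bipartitions=True)
    return tree
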