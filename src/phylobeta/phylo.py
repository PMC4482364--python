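"""Phylogenies and phylogenetic covariance matrices.

A rooted, branch-length-bearing phylogeny induces the phylogenetic
variance--covariance matrix (VCV) ``C`` whose entry ``C[i, j]`` is the sum of
branch lengths shared by taxa *i* and *j* on their paths from the root, i.e.
the root-to-MRCA distance. The diagonal holds root-to-tip depths. Under a
Brownian-motion model of trait evolution, species effects are multivariate
normal with covariance proportional to ``C``.

Pagel's lambda rescales the off-diagonal of ``C`` by a factor ``lam``:
``lam = 0`` collapses the matrix to a star phylogeny (no phylogenetic
signal), ``lam = 1`` leaves the Brownian covariance untouched. Values up to
1.2 are admitted (the prior support used in the regression model); above 1
the transformed matrix can lose positive definiteness, which is flagged
rather than silently repaired.

Analysis taxa need not map one-to-one onto tree tips: a species whose range
spans both study regions enters the analysis twice (one taxon per regional
population), with both taxa attached to the same tip. Such duplicates are
treated as sister lineages of zero divergence, so their between-taxon
covariance is the tip's full root-to-tip depth, scaled by lambda like any
other off-diagonal entry.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "LAMBDA_UPPER",
    "PSD_RTOL",
    "NewickParseError",
    "TreeValidationError",
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "phylo_vcv",
    "lambda_transform",
    "expand_duplicated_taxa",
    "normalize_depth",
]

#: Upper bound of the admissible range for Pagel's lambda (the support of the
#: Uniform prior used by the regression model).
LAMBDA_UPPER = 1.2

#: Relative tolerance for positive-semidefiniteness checks: a matrix is
#: accepted when its smallest eigenvalue is >= -PSD_RTOL * trace(C).
PSD_RTOL = 1e-8


class NewickParseError(ValueError):
    """Malformed Newick input (position information from the parser kept)."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates the package's tree contract."""


@dataclass
class PhyloCovariance:
    """Taxon-ordered phylogenetic covariance, optionally lambda-transformed.

    Attributes
    ----------
    taxa:
        Ordered taxon labels; rows/columns of ``C`` follow this order.
    C:
        Base (lambda-free) covariance matrix of shared root-to-MRCA path
        lengths, in the units of the tree's branch lengths.
    lambda_value:
        Pagel's lambda applied to produce ``C_lambda``, or ``None`` when no
        transform has been applied.
    C_lambda:
        The transformed matrix (same diagonal as ``C``, off-diagonals scaled
        by ``lambda_value``); present iff ``lambda_value`` is set.
    positive_definite:
        Whether ``C_lambda`` passed the eigenvalue check; ``None`` until a
        transform is applied.
    """

    taxa: list[str]
    C: np.ndarray
    lambda_value: float | None = None
    C_lambda: np.ndarray | None = None
    positive_definite: bool | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.taxa)
        if self.C.shape != (n, n):
            raise ValueError(
                f"covariance shape {self.C.shape} does not match {n} taxa"
            )

    @property
    def matrix(self) -> np.ndarray:
        """The matrix in effect: ``C_lambda`` if transformed, else ``C``."""
        return self.C if self.C_lambda is None else self.C_lambda

    def index_of(self, taxa: Sequence[str]) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in pos]
        if missing:
            raise KeyError(f"taxa absent from covariance: {missing}")
        return np.array([pos[t] for t in taxa], dtype=int)

    def to_csv(self, path) -> None:
        """Write the effective matrix as CSV with taxon-labelled header/index."""
        pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PhyloCovariance":
        df = pd.read_csv(path, index_col=0)
        return cls(taxa=[str(t) for t in df.columns], C=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick string into a validated tree.

    Branch lengths are required on every non-root edge (they carry the
    covariance information); a length on the root edge, if present, is
    ignored with a warning, as are internal node labels. Tip labels must be
    unique and non-empty, and every internal node must have at least two
    children.

    Raises
    ------
    NewickParseError
        On malformed Newick (the parser's message, which names the offending
        position, is preserved).
    TreeValidationError
        On duplicate/empty tip labels, missing branch lengths, negative
        branch lengths, or unifurcating internal nodes.
    """
    if not text.strip().endswith(";"):
        raise NewickParseError("Newick string must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(
                f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(str(exc)) from exc
    _validate_tree(tree)
    return tree


def _validate_tree(tree: dendropy.Tree) -> None:
    root = tree.seed_node
    labels: list[str] = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else None
        if not label:
            raise TreeValidationError("tree contains an unlabelled tip")
        labels.append(label)
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise TreeValidationError(f"duplicate tip labels: {dupes}")
    internal_labels = [
        nd.taxon.label
        for nd in tree.preorder_internal_node_iter()
        if nd.taxon is not None and nd.taxon.label
    ]
    if internal_labels:
        warnings.warn(
            f"ignoring internal node labels: {internal_labels}", stacklevel=3
        )
    if root.edge.length not in (None, 0.0):
        warnings.warn("root edge length present; ignored", stacklevel=3)
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        if nd.edge.length is None:
            raise TreeValidationError(
                "branch length missing on a non-root edge"
            )
        if nd.edge.length < 0:
            raise TreeValidationError(
                f"negative branch length {nd.edge.length}"
            )
    for nd in tree.preorder_internal_node_iter():
        if nd is root and len(root.child_nodes()) == 1:
            raise TreeValidationError("root has a single child")
        if nd is not root and len(nd.child_nodes()) < 2:
            raise TreeValidationError("internal node with fewer than 2 children")


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree back to Newick (round-trips with :func:`read_newick`)."""
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return out.getvalue().strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length (root edge excluded)."""
    depths = _node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        depths[nd] = depths[nd.parent_node] + float(nd.edge.length)
    return depths


# ---------------------------------------------------------------------------
# Covariance construction and transforms
# ---------------------------------------------------------------------------

def phylo_vcv(tree: dendropy.Tree, order: Sequence[str] | None = None) -> PhyloCovariance:
    """Build the phylogenetic VCV with rows/columns in a requested order.

    ``C[i, j]`` is the root-to-MRCA path length of taxa ``order[i]`` and
    ``order[j]``; the diagonal is the root-to-tip depth. ``order`` may be a
    subset of the tree's tips; by default all tips are used in tree order.
    """
    all_tips = tip_labels(tree)
    if order is None:
        order = all_tips
    order = list(order)
    missing = [t for t in order if t not in set(all_tips)]
    if missing:
        raise KeyError(f"taxa not found in tree: {missing}")
    if len(set(order)) != len(order):
        raise ValueError("order contains repeated taxa")

    idx = {label: i for i, label in enumerate(order)}
    depths = _node_depths(tree)
    n = len(order)
    C = np.zeros((n, n))

    # Postorder pass: collect, per node, the row indices of requested tips in
    # its subtree; at each internal node the cross-child tip pairs share
    # exactly that node as MRCA.
    tipsets: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label
            rows = [idx[label]] if label in idx else []
            tipsets[nd] = rows
            if rows:
                C[rows[0], rows[0]] = depths[nd]
        else:
            children = [tipsets[ch] for ch in nd.child_nodes()]
            d = depths[nd]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    if children[a] and children[b]:
                        ia = np.array(children[a])
                        ib = np.array(children[b])
                        C[np.ix_(ia, ib)] = d
                        C[np.ix_(ib, ia)] = d
            tipsets[nd] = [i for rows in children for i in rows]
    return PhyloCovariance(taxa=order, C=C)


def _apply_lambda(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal of ``C`` by ``lam``, keeping the diagonal."""
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def lambda_transform(cov: PhyloCovariance, lam: float,
                     upper: float = LAMBDA_UPPER) -> PhyloCovariance:
    """Apply Pagel's lambda to the base covariance.

    The transformed matrix keeps the diagonal of ``C`` and multiplies every
    off-diagonal entry by ``lam``. For ``lam <= 1`` the result is always
    positive semidefinite; for ``lam`` in (1, ``upper``] it may not be, and
    the ``positive_definite`` flag records the outcome of an eigenvalue check
    with tolerance ``PSD_RTOL * trace(C)``.
    """
    if not (0.0 <= lam <= upper):
        raise ValueError(f"lambda must lie in [0, {upper}], got {lam}")
    C_lam = _apply_lambda(cov.C, lam)
    tol = PSD_RTOL * float(np.trace(cov.C))
    min_eig = float(np.linalg.eigvalsh(C_lam)[0])
    return replace(
        cov,
        lambda_value=float(lam),
        C_lambda=C_lam,
        positive_definite=bool(min_eig >= -tol),
    )


def expand_duplicated_taxa(cov: PhyloCovariance,
                           mapping: Mapping[str, str]) -> PhyloCovariance:
    """Expand a tip-level covariance to analysis taxa (species x region).

    ``mapping`` sends each analysis taxon to a tip label of ``cov``; several
    taxa may share one tip (a species straddling both regions). Entries are
    copied from the underlying tip pair, so two taxa on the same tip get a
    base between-taxon covariance equal to that tip's root-to-tip depth —
    i.e. they are treated as sister lineages of zero divergence, and any
    subsequent lambda transform scales that entry like every other
    off-diagonal. If ``cov`` already carries a lambda, the same lambda is
    re-applied to the expanded matrix.
    """
    unknown = sorted({tip for tip in mapping.values()} - set(cov.taxa))
    if unknown:
        raise KeyError(f"mapping references tips absent from covariance: {unknown}")
    taxa = list(mapping)
    rows = cov.index_of([mapping[t] for t in taxa])
    base = cov.C[np.ix_(rows, rows)].copy()
    out = PhyloCovariance(taxa=taxa, C=base)
    if cov.lambda_value is not None:
        out = lambda_transform(out, cov.lambda_value)
    return out


def normalize_depth(cov: PhyloCovariance) -> PhyloCovariance:
    """Rescale the covariance so the mean root-to-tip depth is 1.

    Optional: tree depth units trade off against the scale of the
    phylogenetic random effect, and no rescaling is applied by default.
    """
    scale = float(np.mean(np.diag(cov.C)))
    if scale <= 0:
        raise ValueError("cannot normalise a covariance with non-positive mean depth")
    out = PhyloCovariance(taxa=list(cov.taxa), C=cov.C / scale)
    if cov.lambda_value is not None:
        out = lambda_transform(out, cov.lambda_value)
    return out
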