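"""Phylogenetically independent contrasts for a binary predictor (brunch).

The brunch algorithm of the CAIC family tests whether a continuous response
(here: a species' network increase rate) is associated with a binary
predictor (aerobic vs anaerobic) while controlling for shared ancestry.
Contrasts are computed at nodes whose two daughters differ in (nodal)
predictor state; each tip enters at most one contrast, and the standardized
response contrasts are tested against zero with a one-sample t test
(equivalent to a through-origin regression on unit predictor contrasts).

Trees are handled through :mod:`dendropy`; newick is the interchange format.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np
import scipy.stats as st

from .errors import ValidationError

logger = logging.getLogger("oxymet")

#: floor for branch lengths and for the ladder branches used to resolve
#: polytomies; zero-length branches would make contrast standardization
#: divide by zero.
MIN_EPSILON = 1e-8
DEFAULT_EPSILON = 1e-6

#: two nodal predictor values are "different" beyond this tolerance; nodal
#: predictors are continuous weighted averages, so exact comparison would be
#: numerically fragile.
PREDICTOR_TOL = 1e-10


@dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts and the through-origin test summary."""

    contrasts: tuple[tuple[str, float], ...]  # (node label, response contrast)
    k: int
    estimate: float
    se: float
    t_value: float
    p_value: float
    tested: bool
    n_zero_length_replaced: int = 0

    @property
    def values(self) -> np.ndarray:
        return np.array([c for _, c in self.contrasts], dtype=float)


# ---------------------------------------------------------------------------
# Tree I/O and surgery
# ---------------------------------------------------------------------------

def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip() + "\n"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_to(organism_ids: Iterable[str], tree: dendropy.Tree) -> dendropy.Tree:
    """Restrict a tree to the requested tips.

    Degree-two internal nodes left by the pruning are collapsed with their
    branch lengths summed, so pairwise path lengths are preserved; the root
    is retained.  Requested organisms missing from the tree are reported in
    a warning and the analysis proceeds with the intersection.
    """
    requested = set(organism_ids)
    present = requested & set(tip_labels(tree))
    missing = sorted(requested - present)
    if missing:
        logger.warning(
            "%d requested organism(s) absent from tree: %s",
            len(missing), ", ".join(missing[:10]),
        )
    if len(present) < 2:
        raise ValidationError("fewer than 2 requested tips present on the tree")
    pruned = tree.extract_tree_with_taxa_labels(sorted(present))
    return pruned


def resolve_polytomies(tree: dendropy.Tree, epsilon: float = DEFAULT_EPSILON) -> dendropy.Tree:
    """Replace every polytomy by a deterministic ladder of binary nodes.

    Children are sorted by their smallest descendant tip label and folded
    left-to-right; each inserted internal branch has length ``epsilon``, so
    pairwise path lengths change by at most (order of polytomy)·epsilon.
    """
    if epsilon < MIN_EPSILON:
        raise ValidationError(f"epsilon must be >= {MIN_EPSILON}")
    tree = tree.clone(depth=1)

    def min_tip(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return min(leaf.taxon.label for leaf in node.leaf_iter())

    for node in list(tree.preorder_node_iter()):
        children = node.child_nodes()
        if len(children) <= 2:
            continue
        children = sorted(children, key=min_tip)
        for ch in children:
            node.remove_child(ch)
        # fold: ((c1,c2):eps, c3):eps ... keeping original child edges
        current = children[0]
        for ch in children[1:-1]:
            joint = dendropy.Node(edge_length=epsilon)
            joint.add_child(current)
            joint.add_child(ch)
            current = joint
        node.add_child(current)
        node.add_child(children[-1])
    return tree


# ---------------------------------------------------------------------------
# Brunch contrasts
# ---------------------------------------------------------------------------

@dataclass
class _NodeState:
    predictor: float
    response: float
    length: float  # adjusted branch length above this (possibly merged) node
    rep: str  # smallest participating tip label, used to name contrasts


def brunch_contrasts(
    tree: dendropy.Tree,
    predictor: Mapping[str, float],
    response: Mapping[str, float],
    epsilon: float = DEFAULT_EPSILON,
) -> ContrastSet:
    """Compute brunch contrasts of ``response`` on a binary ``predictor``.

    Post-order traversal; nodal values are branch-length-weighted averages
    of daughter values (weights proportional to 1/adjusted branch length,
    with the Felsenstein adjustment v' = v + v1·v2/(v1+v2)).  At each node
    whose daughters differ in nodal predictor value, the standardized
    response contrast (value of the higher-predictor daughter minus the
    lower, over sqrt(v1'+v2')) is emitted and the whole clade is retired, so
    every tip informs at most one contrast.  The contrasts are tested
    against zero with a one-sample t test on k−1 degrees of freedom.
    """
    tips = set(tip_labels(tree))
    for name, mapping in (("predictor", predictor), ("response", response)):
        missing = tips - set(mapping)
        if missing:
            raise ValidationError(f"{name} missing for tip(s): {sorted(missing)[:10]}")
    states = {predictor[t] for t in tips}
    if len(states) < 2:
        raise ValidationError("predictor is constant across tips")

    zero_replaced = 0

    def edge_len(node: dendropy.Node) -> float:
        nonlocal zero_replaced
        length = node.edge.length
        if length is None:
            return 0.0 if node.parent_node is None else epsilon
        if length <= 0 and node.parent_node is not None:
            zero_replaced += 1
            return epsilon
        return float(length)

    contrasts: list[tuple[str, float]] = []
    state: dict[dendropy.Node, _NodeState | None] = {}

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            state[node] = _NodeState(
                predictor=float(predictor[label]),
                response=float(response[label]),
                length=edge_len(node),
                rep=label,
            )
            continue
        children = node.child_nodes()
        if len(children) > 2:
            raise ValidationError(
                "tree contains polytomies; call resolve_polytomies first"
            )
        active = [state[ch] for ch in children if state[ch] is not None]
        if not active:
            state[node] = None
        elif len(active) == 1:
            only = active[0]
            state[node] = _NodeState(
                predictor=only.predictor,
                response=only.response,
                length=edge_len(node) + only.length,
                rep=only.rep,
            )
        else:
            d1, d2 = active
            if abs(d1.predictor - d2.predictor) > PREDICTOR_TOL:
                hi, lo = (d1, d2) if d1.predictor > d2.predictor else (d2, d1)
                value = (hi.response - lo.response) / math.sqrt(d1.length + d2.length)
                contrasts.append((min(d1.rep, d2.rep), value))
                state[node] = None  # clade retired
            else:
                w1, w2 = 1.0 / d1.length, 1.0 / d2.length
                state[node] = _NodeState(
                    predictor=(w1 * d1.predictor + w2 * d2.predictor) / (w1 + w2),
                    response=(w1 * d1.response + w2 * d2.response) / (w1 + w2),
                    length=edge_len(node) + d1.length * d2.length / (d1.length + d2.length),
                    rep=min(d1.rep, d2.rep),
                )

    k = len(contrasts)
    values = np.array([v for _, v in contrasts], dtype=float)
    if k < 2:
        logger.warning("only %d contrast(s); no through-origin test possible", k)
        estimate = float(values.mean()) if k else math.nan
        return ContrastSet(
            contrasts=tuple(contrasts), k=k, estimate=estimate,
            se=math.nan, t_value=math.nan, p_value=math.nan,
            tested=False, n_zero_length_replaced=zero_replaced,
        )
    estimate = float(values.mean())
    sd = float(values.std(ddof=1))
    se = sd / math.sqrt(k)
    if se == 0.0:
        t_value = 0.0 if estimate == 0.0 else math.copysign(math.inf, estimate)
        p_value = 1.0 if estimate == 0.0 else 0.0
    else:
        t_value = estimate / se
        p_value = float(2.0 * st.t.sf(abs(t_value), df=k - 1))
    return ContrastSet(
        contrasts=tuple(contrasts), k=k, estimate=estimate, se=se,
        t_value=t_value, p_value=p_value, tested=True,
        n_zero_length_replaced=zero_replaced,
    )
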