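"""Phylogenetic comparative methods: independent contrasts and signal tests.

Trait values observed at the tips of a phylogeny are not independent; under a
Brownian-motion (BM) model their covariance equals the shared path length to
the root.  This module implements Felsenstein's independent contrasts (the
pruning recursion that converts n tip values into n-1 independent
standardized differences), Pagel's lambda (maximum-likelihood multiplier on
the off-diagonal phylogenetic covariance) and Blomberg's K (variance-ratio
statistic calibrated to 1 under BM, with a tip-permutation test on the
variance of contrasts), plus extraction of mixed-label sister pairs for
paired group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import linalg, optimize
from scipy import stats as sps

__all__ = [
    "ContrastSet",
    "SignalResult",
    "tip_labels",
    "vcv_matrix",
    "pic",
    "filter_low_variance_contrasts",
    "pagel_lambda",
    "blomberg_k",
    "phylogenetic_signal",
    "sister_pairs",
    "load_tree",
]


def load_tree(path) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _as_trait_map(trait, labels) -> dict[str, float]:
    if hasattr(trait, "to_dict"):
        trait = trait.to_dict()
    missing = [lab for lab in labels if lab not in trait]
    if missing:
        raise ValueError(f"trait values missing for tips: {missing}")
    return {lab: float(trait[lab]) for lab in labels}


def vcv_matrix(tree: dendropy.Tree, taxa: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix among tips (shared root-path length).

    Returns ``(C, labels)`` with rows/columns ordered by ``taxa`` when given.
    The seed-node (root) edge is ignored.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if taxa is not None:
        if set(taxa) != set(labels):
            raise ValueError("taxa do not match the tree's tip labels")
        labels = list(taxa)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            below[node] = [i]
            C[i, i] = depth[node]
        else:
            children = node.child_nodes()
            tips = []
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in below[children[a]]:
                        for j in below[children[b]]:
                            C[i, j] = C[j, i] = depth[node]
                tips.extend(below[children[a]])
            below[node] = tips
    return C, labels


@dataclass
class ContrastSet:
    """Standardized independent contrasts with their expected SDs."""

    contrasts: np.ndarray
    expected_sd: np.ndarray
    node_ids: list[str]

    def __len__(self) -> int:
        return len(self.contrasts)


def _prepare_binary(tree: dendropy.Tree) -> dendropy.Tree:
    work = tree.clone(depth=1)
    work.suppress_unifurcations()
    polytomies = [
        nd for nd in work.preorder_node_iter() if len(nd.child_nodes()) > 2
    ]
    if polytomies:
        warnings.warn(
            f"{len(polytomies)} polytomies resolved arbitrarily with "
            "zero-length branches",
            UserWarning,
            stacklevel=3,
        )
        work.resolve_polytomies(limit=2)
    return work


def pic(tree: dendropy.Tree, trait) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    ``trait`` maps tip labels to values (dict or pandas Series).  At each
    internal node the contrast is ``(x_i - x_j)/sqrt(v_i + v_j)``, the node's
    value is the precision-weighted average of its children and its branch is
    lengthened by ``v_i v_j / (v_i + v_j)``.
    """
    work = _prepare_binary(tree)
    trait_map = _as_trait_map(trait, tip_labels(work))

    values: dict = {}
    variances: dict = {}
    contrasts, sds, node_ids = [], [], []
    counter = 0
    for node in work.postorder_node_iter():
        edge = node.edge.length or 0.0
        if node.is_leaf():
            values[node] = trait_map[node.taxon.label]
            variances[node] = edge
            continue
        children = node.child_nodes()
        if len(children) != 2:  # pragma: no cover - resolved above
            raise ValueError("tree is not binary after polytomy resolution")
        c1, c2 = children
        x1, x2 = values[c1], values[c2]
        v1, v2 = variances[c1], variances[c2]
        vsum = v1 + v2
        if vsum == 0.0:
            if x1 != x2:
                raise ZeroDivisionError(
                    "zero-length sibling pair with unequal trait values: "
                    "contrast undefined"
                )
            contrast, node_value, extra = 0.0, x1, 0.0
        else:
            contrast = (x1 - x2) / np.sqrt(vsum)
            node_value = (x1 * v2 + x2 * v1) / vsum
            extra = v1 * v2 / vsum
        counter += 1
        contrasts.append(contrast)
        sds.append(np.sqrt(vsum))
        node_ids.append(node.label or f"node{counter}")
        values[node] = node_value
        variances[node] = edge + extra
    return ContrastSet(
        contrasts=np.asarray(contrasts),
        expected_sd=np.asarray(sds),
        node_ids=node_ids,
    )


def filter_low_variance_contrasts(
    contrast_set: ContrastSet, threshold: float = 0.21
) -> tuple[ContrastSet, int]:
    """Drop contrasts whose expected SD is below ``threshold``.

    Contrasts between near-identical taxa (tiny summed branch lengths) have
    unreliable standardization; returns the retained set and the removed count.
    """
    keep = contrast_set.expected_sd >= threshold
    removed = int((~keep).sum())
    filtered = ContrastSet(
        contrasts=contrast_set.contrasts[keep],
        expected_sd=contrast_set.expected_sd[keep],
        node_ids=[nid for nid, k in zip(contrast_set.node_ids, keep) if k],
    )
    return filtered, removed


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    d = np.diag(np.diag(C))
    return lam * (C - d) + d


def _bm_profile_loglik(V: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    try:
        cf = linalg.cho_factor(V)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular phylogenetic covariance") from exc
    one = np.ones(n)
    Vi_x = linalg.cho_solve(cf, x)
    Vi_1 = linalg.cho_solve(cf, one)
    mu = (one @ Vi_x) / (one @ Vi_1)
    r = x - mu
    Vi_r = linalg.cho_solve(cf, r)
    sigma2 = (r @ Vi_r) / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


@dataclass
class SignalResult:
    lambda_: float
    lambda_loglik: float
    lambda_p: float
    K: float
    K_p: float | None


def pagel_lambda(tree: dendropy.Tree, trait) -> tuple[float, float, float]:
    """ML estimate of Pagel's lambda in [0, 1] with a LRT p-value vs lambda=0.

    Returns ``(lambda_hat, loglik, p_value)``.
    """
    C, labels = vcv_matrix(tree)
    if len(labels) < 4:
        raise ValueError("Pagel's lambda needs at least 4 tips")
    trait_map = _as_trait_map(trait, labels)
    x = np.array([trait_map[lab] for lab in labels])
    if np.allclose(x, x[0]):
        raise ValueError("trait has zero variance")

    def negloglik(lam: float) -> float:
        return -_bm_profile_loglik(_lambda_transform(C, lam), x)

    res = optimize.minimize_scalar(
        negloglik, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
    )
    candidates = [(float(res.x), -res.fun)]
    for lam in (0.0, 1.0):
        candidates.append((lam, -negloglik(lam)))
    lam_hat, loglik = max(candidates, key=lambda c: c[1])
    loglik0 = -negloglik(0.0)
    lrt = max(0.0, 2.0 * (loglik - loglik0))
    p = float(sps.chi2.sf(lrt, df=1))
    return lam_hat, loglik, p


def blomberg_k(
    tree: dendropy.Tree, trait, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float | None]:
    """Blomberg's K with a tip-permutation p-value.

    K is the ratio of observed to BM-expected ``MSE0/MSE`` (MSE0 the mean
    squared deviation from the phylogenetic mean, MSE its GLS analogue).  The
    p-value is the fraction of tip permutations whose variance of independent
    contrasts is at most the observed one (low variance = signal);
    ``n_perm=0`` returns ``(K, None)``.
    """
    C, labels = vcv_matrix(tree)
    if len(labels) < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    trait_map = _as_trait_map(trait, labels)
    x = np.array([trait_map[lab] for lab in labels])
    n = len(x)
    cf = linalg.cho_factor(C)
    one = np.ones(n)
    Vi_1 = linalg.cho_solve(cf, one)
    mu = (one @ linalg.cho_solve(cf, x)) / (one @ Vi_1)
    d = x - mu
    mse0 = (d @ d) / (n - 1)
    mse = (d @ linalg.cho_solve(cf, d)) / (n - 1)
    expected = (np.trace(C) - n / (one @ Vi_1)) / (n - 1)
    K = float((mse0 / mse) / expected)

    if n_perm == 0:
        return K, None
    rng = np.random.default_rng(seed)
    obs_stat = float(np.var(pic(tree, trait_map).contrasts))
    count = 0
    vals = x.copy()
    for _ in range(int(n_perm)):
        rng.shuffle(vals)
        perm_map = dict(zip(labels, vals))
        if float(np.var(pic(tree, perm_map).contrasts)) <= obs_stat:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return K, float(p)


def phylogenetic_signal(
    tree: dendropy.Tree, trait, n_perm: int = 999, seed: int | None = None
) -> SignalResult:
    """Pagel's lambda and Blomberg's K for one trait, bundled."""
    lam, loglik, lam_p = pagel_lambda(tree, trait)
    K, K_p = blomberg_k(tree, trait, n_perm=n_perm, seed=seed)
    return SignalResult(
        lambda_=lam, lambda_loglik=loglik, lambda_p=lam_p, K=K, K_p=K_p
    )


def sister_pairs(tree: dendropy.Tree, group_labels) -> list[tuple[str, str]]:
    """Disjoint cherries whose two tips carry different group labels.

    Suitable for a paired comparison of a trait between two groups while
    controlling for phylogeny.  Returns [] (with a warning) when the tree has
    no mixed-label cherries.
    """
    if hasattr(group_labels, "to_dict"):
        group_labels = group_labels.to_dict()
    missing = [lab for lab in tip_labels(tree) if lab not in group_labels]
    if missing:
        raise ValueError(f"group labels missing for tips: {missing}")
    pairs: list[tuple[str, str]] = []
    for node in tree.postorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            a, b = (c.taxon.label for c in children)
            if group_labels[a] != group_labels[b]:
                pairs.append((a, b))
    if not pairs:
        warnings.warn("no mixed-label sister pairs found", UserWarning, stacklevel=2)
    return pairs
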