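"""Marginal ancestral sequence reconstruction under an empirical model.

The reconstruction is empirical Bayes: given a fixed amino-acid
substitution model (CpREV by default) and one tree — or a posterior
sample of trees, optionally with burn-in — per-site posterior state
distributions are computed at a chosen internal node with the pruning
algorithm, the maximum-posterior residue is taken at every column, and a
parsimony gap correction decides which columns the ancestor possessed at
all.  Columns inferred absent are deleted from the final sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "RateModel",
    "SitePosterior",
    "AncestralReconstruction",
    "McmcSampleSpec",
    "build_cprev",
    "site_likelihood",
    "log_likelihood",
    "marginal_posteriors",
    "average_over_trees",
    "retained_samples",
    "hall_gap_correction",
    "reconstruct",
    "find_clade_node",
    "discrete_gamma_rates",
]

# canonical (PAML) state order used by all 20-vectors in this module
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_STATE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_MISSING = set("-.?XBZJ*")


@dataclass
class RateModel:
    """Reversible amino-acid substitution model.

    ``exchangeabilities`` is the symmetric matrix S, ``frequencies`` the
    equilibrium distribution π.  The rate matrix Q with q_ij = s_ij π_j
    is normalised to one expected substitution per unit branch length
    (−Σ π_i q_ii = 1) and satisfies detailed balance π_i q_ij = π_j q_ji.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    name: str = "custom"
    Q: np.ndarray = field(init=False)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (20, 20) or not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be symmetric 20×20")
        if pi.shape != (20,) or not np.isclose(pi.sum(), 1.0, atol=1e-6):
            raise ValueError("frequencies must be a 20-vector summing to 1")
        pi = pi / pi.sum()
        self.frequencies = pi
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.sum(pi * np.diag(q))
        q /= scale
        self.Q = q
        # symmetric similarity transform: B = D^{1/2} Q D^{-1/2} is
        # symmetric for reversible Q, so eigh is stable and exact
        sqrt_pi = np.sqrt(pi)
        b = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
        self._eigvals = vals
        self._right = vecs / sqrt_pi[:, None]
        self._left = vecs * sqrt_pi[:, None]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self._right * np.exp(self._eigvals * t)) @ self._left.T
        return np.clip(p, 0.0, None)


@dataclass
class SitePosterior:
    """Posterior state distribution at one alignment column."""

    site: int
    pp: np.ndarray

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (20,) or not np.isclose(self.pp.sum(), 1.0,
                                                    atol=1e-6):
            raise ValueError("pp must be a 20-vector summing to 1")


@dataclass
class AncestralReconstruction:
    """Reconstruction at one node: posteriors, max-PP sequence, gap mask."""

    node: str
    posteriors: np.ndarray          # (n_columns, 20)
    mpp_sequence: str               # max-PP residue at every column
    presence_mask: np.ndarray       # bool per column after gap correction
    final_sequence: str             # mpp residues at present columns
    coverage: float = 1.0           # fraction of trees containing the clade

    @property
    def site_posteriors(self) -> list[SitePosterior]:
        return [SitePosterior(i, p) for i, p in enumerate(self.posteriors)]

    def max_pp(self) -> np.ndarray:
        return self.posteriors.max(axis=1)

    def pp_histogram(self, bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
        """Histogram of per-site max PP over retained columns."""
        return np.histogram(self.max_pp()[self.presence_mask],
                            bins=bins, range=(0.0, 1.0))


@dataclass
class McmcSampleSpec:
    """Bookkeeping for an MCMC tree sample: generations, thinning, runs,
    burn-in fraction."""

    n_generations: int
    sample_frequency: int
    n_runs: int = 1
    burnin_fraction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_generations, self.sample_frequency, self.n_runs) <= 0:
            raise ValueError("generations, frequency and runs must be positive")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must be in [0, 1)")


def build_cprev() -> RateModel:
    """The CpREV empirical model from the bundled plain-text data file."""
    text = resources.files("halo_adapt").joinpath("data/cprev.dat").read_text()
    rows = [line.split() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]
    if len(rows) != 20:
        raise ValueError("corrupted cprev.dat: expected 19 triangle rows "
                         "+ 1 frequency row")
    s = np.zeros((20, 20))
    for i, row in enumerate(rows[:19], start=1):
        if len(row) != i:
            raise ValueError(f"corrupted cprev.dat: row {i} has {len(row)} "
                             f"entries, expected {i}")
        s[i, :i] = [float(x) for x in row]
    s = s + s.T
    pi = np.array([float(x) for x in rows[19]])
    if len(pi) != 20:
        raise ValueError("corrupted cprev.dat: frequency row must have 20 "
                         "entries")
    return RateModel(exchangeabilities=s, frequencies=pi, name="CpREV")


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of equal-probability discrete gamma categories (mean 1)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    k = n_categories
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1, edges * alpha), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, edges * alpha)])
    return k * (upper - lower)


# ---------------------------------------------------------------------------
# encoding and tree utilities

def _encode_alignment(alignment: dict[str, str]) -> dict[str, np.ndarray]:
    """taxon → int codes per column; −1 marks gap/ambiguity (missing)."""
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences differ in length")
    encoded = {}
    for taxon, seq in alignment.items():
        codes = np.array([_STATE_INDEX.get(c.upper(), -1) for c in seq],
                         dtype=int)
        unknown = [c for c in seq
                   if c.upper() not in _STATE_INDEX
                   and c.upper() not in _MISSING]
        if unknown:
            logger.warning("%s: %d unrecognised symbols treated as missing",
                           taxon, len(unknown))
        encoded[taxon] = codes
    return encoded


def _check_taxa(tree: dendropy.Tree, alignment: dict[str, str]) -> None:
    tree_taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    aln_taxa = set(alignment)
    if tree_taxa != aln_taxa:
        missing = sorted(tree_taxa - aln_taxa)
        extra = sorted(aln_taxa - tree_taxa)
        raise ValueError(
            f"taxon mismatch: in tree only {missing}; in alignment only {extra}")


def find_clade_node(tree: dendropy.Tree,
                    clade: set[str]) -> dendropy.Node | None:
    """Internal node whose descendant leaf set equals ``clade`` exactly."""
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        leaves = {leaf.taxon.label for leaf in node.leaf_iter()}
        if leaves == clade:
            return node
    return None


def _resolve_node(tree: dendropy.Tree, node) -> dendropy.Node:
    if isinstance(node, dendropy.Node):
        resolved = node
    else:
        resolved = find_clade_node(tree, set(node))
        if resolved is None:
            raise ValueError(f"no internal node with leaf set {sorted(node)}")
    if resolved.is_leaf():
        raise ValueError("requested node is a leaf; leaves are observed")
    return resolved


# ---------------------------------------------------------------------------
# pruning

def _edge_length(node: dendropy.Node) -> float:
    return node.edge.length if node.edge.length is not None else 0.0


def _postorder_partials(tree: dendropy.Tree, codes: dict[str, np.ndarray],
                        model: RateModel, rate: float = 1.0,
                        ) -> tuple[dict, np.ndarray]:
    """Partial likelihoods F_v(s) for every node, with per-site log scaling.

    Gaps and ambiguity are missing data: a leaf with no observed state
    contributes a partial of 1 for every state.
    """
    n_sites = len(next(iter(codes.values())))
    partials: dict[dendropy.Node, np.ndarray] = {}
    log_scale = np.zeros(n_sites)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            f = np.zeros((n_sites, 20))
            site_codes = codes[node.taxon.label]
            observed = site_codes >= 0
            f[observed, site_codes[observed]] = 1.0
            f[~observed, :] = 1.0
            partials[node] = f
        else:
            f = np.ones((n_sites, 20))
            for child in node.child_nodes():
                p = model.transition_matrix(rate * _edge_length(child))
                f *= partials[child] @ p.T
            scale = f.max(axis=1)
            scale[scale == 0.0] = 1.0
            partials[node] = f / scale[:, None]
            log_scale += np.log(scale)
    return partials, log_scale


def log_likelihood(tree: dendropy.Tree, alignment: dict[str, str],
                   model: RateModel, rates: np.ndarray | None = None,
                   ) -> np.ndarray:
    """Per-site log-likelihoods under the pruning algorithm.

    ``rates`` (optional) are discrete rate-category multipliers with equal
    weights; the site likelihood is then the category average.
    """
    _check_taxa(tree, alignment)
    codes = _encode_alignment(alignment)
    pi = model.frequencies
    if rates is None:
        rates = np.array([1.0])
    site_likes = []
    for rate in rates:
        partials, log_scale = _postorder_partials(tree, codes, model, rate)
        root_partial = partials[tree.seed_node]
        site_likes.append(np.log(root_partial @ pi) + log_scale)
    stacked = np.stack(site_likes)
    peak = stacked.max(axis=0)
    return peak + np.log(np.mean(np.exp(stacked - peak), axis=0))


def site_likelihood(tree: dendropy.Tree, column: dict[str, str],
                    model: RateModel) -> float:
    """Log-likelihood of a single alignment column (dict taxon → symbol)."""
    return float(log_likelihood(tree, {t: c for t, c in column.items()},
                                model)[0])


def _posteriors_single_tree(tree: dendropy.Tree, codes: dict[str, np.ndarray],
                            model: RateModel, target: dendropy.Node,
                            rates: np.ndarray) -> np.ndarray:
    """Marginal posteriors at ``target``, averaged over rate categories
    weighted by each category's site likelihood."""
    n_sites = len(next(iter(codes.values())))
    pp_by_cat, like_by_cat = [], []
    for rate in rates:
        partials, log_scale = _postorder_partials(tree, codes, model, rate)
        # outside pass: A_v(s) = prob of all data outside v's subtree given
        # state s at v, including the root prior
        outside: dict[dendropy.Node, np.ndarray] = {
            tree.seed_node: np.tile(model.frequencies, (n_sites, 1))}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            child_terms = {
                child: partials[child] @ model.transition_matrix(
                    rate * _edge_length(child)).T
                for child in node.child_nodes()}
            for child in node.child_nodes():
                b = outside[node].copy()
                for sibling, term in child_terms.items():
                    if sibling is not child:
                        b *= term
                a = b @ model.transition_matrix(rate * _edge_length(child))
                norm = a.sum(axis=1, keepdims=True)
                norm[norm == 0.0] = 1.0
                outside[child] = a / norm
        joint = partials[target] * outside[target]
        total = joint.sum(axis=1)
        pp_by_cat.append(joint / total[:, None])
        root_like = partials[tree.seed_node] @ model.frequencies
        like_by_cat.append(np.log(root_like) + log_scale)
    if len(rates) == 1:
        return pp_by_cat[0]
    log_w = np.stack(like_by_cat)
    log_w -= log_w.max(axis=0)
    w = np.exp(log_w)
    w /= w.sum(axis=0)
    return np.einsum("cs,csk->sk", w, np.stack(pp_by_cat))


def marginal_posteriors(tree: dendropy.Tree, alignment: dict[str, str],
                        model: RateModel, node,
                        rates: np.ndarray | None = None) -> np.ndarray:
    """Per-site marginal posterior distributions at an internal node.

    ``node`` is a dendropy Node or an iterable of leaf labels naming the
    clade.  Returns an (n_columns, 20) array in :data:`AMINO_ACIDS` order.
    Because the model is reversible, the result does not depend on where
    the tree is rooted.
    """
    _check_taxa(tree, alignment)
    target = _resolve_node(tree, node)
    codes = _encode_alignment(alignment)
    if rates is None:
        rates = np.array([1.0])
    return _posteriors_single_tree(tree, codes, model, target, rates)


def average_over_trees(trees: list[dendropy.Tree], alignment: dict[str, str],
                       model: RateModel, clade: set[str],
                       rates: np.ndarray | None = None,
                       ) -> tuple[np.ndarray, float]:
    """Mean posteriors over the trees that contain the target clade.

    The node is mapped between trees by its exact descendant leaf set.
    Returns (posteriors, coverage) where coverage is the fraction of
    trees containing the clade; zero coverage is an error.
    """
    clade = set(clade)
    used, total = [], 0
    for tree in trees:
        total += 1
        node = find_clade_node(tree, clade)
        if node is None:
            continue
        used.append(marginal_posteriors(tree, alignment, model, node, rates))
    if not used:
        raise ValueError(f"clade {sorted(clade)} present in none of "
                         f"{total} trees")
    return np.mean(used, axis=0), len(used) / total


def retained_samples(spec: McmcSampleSpec) -> int:
    """Trees kept after thinning and burn-in.

    total = n_runs × n_generations / sample_frequency (floored with a
    warning when not divisible); retained = round(total × (1 − burn-in)).
    """
    if spec.n_generations % spec.sample_frequency:
        logger.warning("generations not divisible by sampling frequency; "
                       "flooring")
    total = spec.n_runs * (spec.n_generations // spec.sample_frequency)
    return int(round(total * (1.0 - spec.burnin_fraction)))


# ---------------------------------------------------------------------------
# gap correction (binary presence/absence parsimony)

def hall_gap_correction(alignment: dict[str, str], tree: dendropy.Tree,
                        node) -> np.ndarray:
    """Per-column presence mask at the target node by Fitch parsimony.

    Each column is coded present (residue) / absent (gap) at the leaves;
    a two-state Sankoff up/down pass gives the set of most-parsimonious
    states at the node.  Ambiguous columns resolve to PRESENT — the
    correction only deletes confidently absent positions.
    """
    _check_taxa(tree, alignment)
    target = _resolve_node(tree, node)
    n_cols = len(next(iter(alignment.values())))
    big = 1e9

    # state 0 = present, 1 = absent; costs shape (n_cols, 2)
    up: dict[dendropy.Node, np.ndarray] = {}
    for tnode in tree.postorder_node_iter():
        if tnode.is_leaf():
            present = np.array([c not in "-." for c in
                                alignment[tnode.taxon.label]])
            cost = np.zeros((n_cols, 2))
            cost[present, 1] = big
            cost[~present, 0] = big
            up[tnode] = cost
        else:
            cost = np.zeros((n_cols, 2))
            for child in tnode.child_nodes():
                cost += _min_transition(up[child])
            up[tnode] = cost

    down: dict[dendropy.Node, np.ndarray] = {
        tree.seed_node: np.zeros((n_cols, 2))}
    for tnode in tree.preorder_node_iter():
        if tnode.is_leaf():
            continue
        for child in tnode.child_nodes():
            other = down[tnode].copy()
            for sibling in tnode.child_nodes():
                if sibling is not child:
                    other += _min_transition(up[sibling])
            down[child] = _min_transition(other)

    total = up[target] + down[target]
    # present unless strictly cheaper to be absent
    return total[:, 0] <= total[:, 1]


def _min_transition(cost: np.ndarray) -> np.ndarray:
    """min over child state of (unit change cost + child cost), per parent
    state, for the two-state character."""
    out = np.empty_like(cost)
    out[:, 0] = np.minimum(cost[:, 0], cost[:, 1] + 1.0)
    out[:, 1] = np.minimum(cost[:, 1], cost[:, 0] + 1.0)
    return out


# ---------------------------------------------------------------------------
# top-level reconstruction

# alphabetical tie-break order for equal max posterior probabilities
_LEX_ORDER = np.argsort(list(AMINO_ACIDS))


def _mpp_sequence(posteriors: np.ndarray) -> str:
    reordered = posteriors[:, _LEX_ORDER]
    choice = reordered.argmax(axis=1)  # first max = lexicographic smallest
    return "".join(AMINO_ACIDS[_LEX_ORDER[c]] for c in choice)


def reconstruct(trees, alignment: dict[str, str], node,
                model: RateModel | None = None,
                mcmc_spec: McmcSampleSpec | None = None,
                burnin_fraction: float | None = None,
                gamma_alpha: float | None = None,
                n_rate_categories: int = 4) -> AncestralReconstruction:
    """Full marginal reconstruction at one internal node.

    ``trees`` is a single tree or a posterior sample (list).  For a
    sample, the leading ``burnin_fraction`` (or the fraction from
    ``mcmc_spec``) is discarded, posteriors are averaged over the
    retained trees containing the clade, and the gap-correction verdict
    is the majority over those trees (ties → present).  Site-rate
    heterogeneity is off unless ``gamma_alpha`` is given.
    """
    model = model or build_cprev()
    rates = (discrete_gamma_rates(gamma_alpha, n_rate_categories)
             if gamma_alpha is not None else None)

    if isinstance(trees, dendropy.Tree):
        tree_list = [trees]
    else:
        tree_list = list(trees)
        frac = burnin_fraction if burnin_fraction is not None else \
            (mcmc_spec.burnin_fraction if mcmc_spec else 0.0)
        n_burn = int(len(tree_list) * frac)
        tree_list = tree_list[n_burn:]
        if not tree_list:
            raise ValueError("burn-in discarded every tree")

    if isinstance(node, dendropy.Node):
        if len(tree_list) > 1:
            raise ValueError("pass a clade (leaf label set) when averaging "
                             "over a tree sample")
        clade = {leaf.taxon.label for leaf in node.leaf_iter()}
    else:
        clade = set(node)

    if len(tree_list) == 1:
        posteriors = marginal_posteriors(tree_list[0], alignment, model,
                                         node, rates)
        coverage = 1.0
        masks = [hall_gap_correction(alignment, tree_list[0], node)]
    else:
        posteriors, coverage = average_over_trees(tree_list, alignment,
                                                  model, clade, rates)
        masks = []
        for tree in tree_list:
            tnode = find_clade_node(tree, clade)
            if tnode is not None:
                masks.append(hall_gap_correction(alignment, tree, tnode))
    presence = np.mean(masks, axis=0) >= 0.5  # majority; ties → present

    mpp = _mpp_sequence(posteriors)
    final = "".join(c for c, keep in zip(mpp, presence) if keep)
    return AncestralReconstruction(
        node="+".join(sorted(clade)),
        posteriors=posteriors,
        mpp_sequence=mpp,
        presence_mask=presence,
        final_sequence=final,
        coverage=coverage,
    )
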