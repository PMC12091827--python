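"""Maximum-likelihood ancestral reconstruction of binned niches.

Each bin of each variable is treated as an independent binary character
(absent/present) under a single-rate symmetric two-state continuous-time
Markov chain (the "equal rates" model) with a stationary (0.5, 0.5) root
prior.  Uncertain tips ('?') enter the pruning algorithm as fully
ambiguous partial likelihoods (1, 1).  The per-character rate is fitted by
bounded one-dimensional ML, marginal ancestral probabilities come from
the standard two-pass (inside/outside) computation, and states are
discretized with a configurable threshold: P(present) >= theta -> present,
P(present) <= 1 - theta -> absent, otherwise uncertain.

State order throughout: index 0 = absent, index 1 = present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .bar_coding import ABSENT, PRESENT, UNCERTAIN, BRMatrix
from .errors import InvalidInputError, MismatchError
from .trees import DatedTree

RATE_BOUNDS = (1e-8, 1e3)
BRANCH_FLOOR = 1e-8  # Myr; zero-length branches are floored
DEFAULT_THETA = 0.8

_PARTIALS = {
    ABSENT: np.array([1.0, 0.0]),
    PRESENT: np.array([0.0, 1.0]),
    UNCERTAIN: np.array([1.0, 1.0]),
}


@dataclass
class BinaryCharModel:
    """Symmetric 2-state CTMC with stationary root prior."""

    rate: float
    root_prior: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise InvalidInputError("rate must be > 0")


def transition_prob(rate: float, t: float) -> np.ndarray:
    """2x2 transition matrix; P(stay) = 0.5 + 0.5 exp(-2 r t)."""
    if t < 0:
        raise InvalidInputError("elapsed time must be >= 0")
    stay = 0.5 + 0.5 * np.exp(-2.0 * rate * t)
    move = 1.0 - stay
    return np.array([[stay, move], [move, stay]])


def _tip_partial(state: str) -> np.ndarray:
    try:
        return _PARTIALS[state]
    except KeyError:
        raise InvalidInputError(f"unknown tip state {state!r}") from None


def _check_tips(tree: DatedTree, tip_states: dict[str, str]) -> None:
    missing = [lb for lb in tree.tip_labels() if lb not in tip_states]
    if missing:
        raise MismatchError(f"tips without states: {missing}")


def _branch_t(tree: DatedTree, nid: int) -> float:
    return max(tree.nodes[nid].length, BRANCH_FLOOR)


def _inside(tree: DatedTree, tip_states: dict[str, str], rate: float):
    """Postorder partial likelihoods F and per-node log scaling factors."""
    F: dict[int, np.ndarray] = {}
    logscale = 0.0
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if not node.children:
            F[nid] = _tip_partial(tip_states[node.label])
            continue
        part = np.ones(2)
        for c in node.children:
            P = transition_prob(rate, _branch_t(tree, c))
            part = part * (P @ F[c])
        s = part.max()
        if s > 0:
            part = part / s
            logscale += np.log(s)
        F[nid] = part
    return F, logscale


def character_loglik(
    tree: DatedTree, tip_states: dict[str, str], model: BinaryCharModel
) -> float:
    """Log-likelihood of one binary character by Felsenstein pruning."""
    _check_tips(tree, tip_states)
    F, logscale = _inside(tree, tip_states, model.rate)
    prior = np.asarray(model.root_prior)
    lik = float(prior @ F[tree.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


def is_invariant_certain(states) -> str | None:
    """The shared state if all tips are certain and identical, else None."""
    vals = set(states)
    if vals == {PRESENT} or vals == {ABSENT}:
        return vals.pop()
    return None


def estimate_rate(
    tree: DatedTree,
    tip_states: dict[str, str],
    bounds: tuple[float, float] = RATE_BOUNDS,
    xtol: float = 1e-10,
) -> float:
    """ML rate by a coarse log-grid bracket plus bounded 1-D refinement.

    The profile likelihood in the rate can be bimodal (a diffuse plateau
    as rate -> infinity competes with a sharp low-rate optimum), so a
    49-point log-spaced scan locates the global basin before Brent
    refinement within the bracketing grid interval.

    Invariant, fully certain characters must be handled by the caller
    (their likelihood is maximized at rate -> 0 and the ancestral state is
    fixed clade-wide); calling this on one raises.
    """
    _check_tips(tree, tip_states)
    states = [tip_states[lb] for lb in tree.tip_labels()]
    if is_invariant_certain(states) is not None:
        raise InvalidInputError(
            "invariant certain character: bypass rate estimation"
        )
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def neg_ll(u: float) -> float:
        model = BinaryCharModel(rate=float(np.exp(u)))
        return -character_loglik(tree, tip_states, model)

    grid = np.linspace(lo, hi, 49)
    vals = np.array([neg_ll(u) for u in grid])
    i = int(np.argmin(vals))
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        neg_ll, bounds=(blo, bhi), method="bounded", options={"xatol": xtol}
    )
    u = res.x if res.fun <= vals[i] else grid[i]
    return float(np.exp(u))


def marginal_states(
    tree: DatedTree,
    tip_states: dict[str, str],
    model: BinaryCharModel,
    theta: float = DEFAULT_THETA,
) -> tuple[dict[int, float], dict[int, str]]:
    """Marginal P(present) and discretized state per internal node.

    Inside pass gives subtree likelihoods F; the outside pass propagates
    G (likelihood of the rest of the tree given the node's state,
    including the root prior); marginal(v) is proportional to F(v)*G(v).
    """
    if not 0.5 < theta <= 1.0:
        raise InvalidInputError("theta must be in (0.5, 1]")
    _check_tips(tree, tip_states)
    rate = model.rate
    F, _ = _inside(tree, tip_states, rate)
    G: dict[int, np.ndarray] = {tree.root: np.asarray(model.root_prior, dtype=float)}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        for c in node.children:
            outer = G[nid].copy()
            for s in node.children:
                if s == c:
                    continue
                Ps = transition_prob(rate, _branch_t(tree, s))
                outer = outer * (Ps @ F[s])
            Pc = transition_prob(rate, _branch_t(tree, c))
            g = outer @ Pc
            tot = g.sum()
            G[c] = g / tot if tot > 0 else g

    probs: dict[int, float] = {}
    states: dict[int, str] = {}
    for nid in tree.internal_ids():
        post = F[nid] * G[nid]
        tot = post.sum()
        p1 = float(post[1] / tot) if tot > 0 else 0.5
        probs[nid] = p1
        if p1 >= theta:
            states[nid] = PRESENT
        elif p1 <= 1.0 - theta:
            states[nid] = ABSENT
        else:
            states[nid] = UNCERTAIN
    return probs, states


@dataclass
class AncestralNiche:
    """Reconstructed per-node binned niche for one variable."""

    variable: str
    node_ids: list[int]  # internal nodes, stable postorder
    states: np.ndarray  # (n_internal, n_bins) of {"1","0","?"}
    probs: np.ndarray  # (n_internal, n_bins) P(present)
    rates: np.ndarray = field(default=None)  # per-bin ML rate (NaN if bypassed)

    def vector(self, node_id: int) -> np.ndarray:
        return self.states[self.node_ids.index(node_id)]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.states,
            index=self.node_ids,
            columns=[f"bin{i}" for i in range(self.states.shape[1])],
        )
        df.index.name = "node"
        df.to_csv(path, sep="\t")

    def probs_to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.probs,
            index=self.node_ids,
            columns=[f"bin{i}" for i in range(self.probs.shape[1])],
        )
        df.index.name = "node"
        df.to_csv(path, sep="\t")


def reconstruct_matrix(
    br: BRMatrix, tree: DatedTree, theta: float = DEFAULT_THETA,
    rate_bounds: tuple[float, float] = RATE_BOUNDS,
) -> AncestralNiche:
    """Reconstruct every bin of a BR matrix independently.

    Invariant fully-certain bins bypass optimization (the state is fixed
    clade-wide with probability 1); bins with no certain tip at all are
    uninformative and reconstructed as uncertain with P = 0.5.
    """
    tips = tree.tip_labels()
    if set(tips) != set(br.species):
        raise MismatchError(
            f"tree/matrix mismatch: {sorted(set(tips) ^ set(br.species))}"
        )
    internal = tree.internal_ids()
    n_bins = br.states.shape[1]
    states = np.full((len(internal), n_bins), UNCERTAIN, dtype="<U1")
    probs = np.full((len(internal), n_bins), 0.5)
    rates = np.full(n_bins, np.nan)
    row_of = {sp: i for i, sp in enumerate(br.species)}
    for b in range(n_bins):
        col = {sp: br.states[row_of[sp], b] for sp in tips}
        vals = list(col.values())
        inv = is_invariant_certain(vals)
        if inv is not None:
            states[:, b] = inv
            probs[:, b] = 1.0 if inv == PRESENT else 0.0
            continue
        if all(v == UNCERTAIN for v in vals):
            continue  # uninformative: stays uncertain at 0.5
        rate = estimate_rate(tree, col, bounds=rate_bounds)
        rates[b] = rate
        p, s = marginal_states(tree, col, BinaryCharModel(rate=rate), theta=theta)
        for i, nid in enumerate(internal):
            probs[i, b] = p[nid]
            states[i, b] = s[nid]
    return AncestralNiche(
        variable=br.variable, node_ids=internal, states=states, probs=probs,
        rates=rates,
    )
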