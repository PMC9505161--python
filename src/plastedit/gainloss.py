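"""Gain/loss reconstruction of editing sites on a fixed rooted phylogeny.

Presence/absence characters evolve under a two-state Markov chain with
gain rate g (0 -> 1) and loss rate l (1 -> 0) per unit branch length.
The likelihood uses Felsenstein pruning; expected per-branch gain and
loss events use the analytic endpoint-conditioned expected-transition
formula for the two-state chain summed over branch-endpoint posteriors;
a seeded stochastic-mapping sampler (exact conditional, by rejection
from forward simulation) and Fitch parsimony serve as oracles.

Missing entries (NaN) contribute partial likelihood 1 to both states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import ValidationError


@dataclass
class GainLossModel:
    gain: float
    loss: float
    rate_multipliers: Sequence[float] = (1.0,)
    weights: Sequence[float] = (1.0,)
    root_prior: Optional[Tuple[float, float]] = None  # None -> stationary

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.loss <= 0:
            raise ValidationError("gain and loss rates must be positive")
        if len(self.rate_multipliers) != len(self.weights):
            raise ValidationError("rate multipliers and weights differ in length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")

    def stationary(self, mult: float = 1.0) -> np.ndarray:
        lam = self.gain + self.loss
        return np.array([self.loss / lam, self.gain / lam])

    def prior(self, mult: float = 1.0) -> np.ndarray:
        if self.root_prior is not None:
            return np.asarray(self.root_prior, dtype=float)
        return self.stationary(mult)

    def transition(self, t: float, mult: float = 1.0) -> np.ndarray:
        """2x2 transition matrix over branch length t."""
        g, l = self.gain * mult, self.loss * mult
        lam = g + l
        pi1 = g / lam
        pi0 = l / lam
        decay = np.exp(-lam * t)
        return np.array([
            [pi0 + pi1 * decay, pi1 * (1 - decay)],
            [pi0 * (1 - decay), pi1 + pi0 * decay],
        ])


@dataclass
class GainLossResult:
    model: GainLossModel
    log_likelihood: float
    branches: pd.DataFrame  # branch, length, expected_gains, expected_losses
    total_gains: float
    total_losses: float
    node_posteriors: Dict[str, np.ndarray]  # P(state=1) per site, keyed by clade


class TreeIndex:
    """Array view of a rooted dendropy tree for vectorised pruning."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.full(len(self.nodes), -1)
        self.length = np.zeros(len(self.nodes))
        self.children: List[List[int]] = [[] for _ in self.nodes]
        self.tip_label: Dict[int, str] = {}
        for i, n in enumerate(self.nodes):
            if n.parent_node is not None:
                self.parent[i] = self.index[id(n.parent_node)]
                self.length[i] = n.edge.length or 0.0
            for c in n.child_nodes():
                self.children[i].append(self.index[id(c)])
            if n.is_leaf():
                self.tip_label[i] = n.taxon.label
        self.root = self.index[id(tree.seed_node)]

    def clade_label(self, i: int) -> str:
        """Stable branch identifier: sorted descendant tips."""
        node = self.nodes[i]
        tips = sorted(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        return "|".join(tips)


def _tip_partials(matrix: pd.DataFrame, ti: TreeIndex) -> Dict[int, np.ndarray]:
    """(nsites, 2) partial likelihoods at each tip; missing -> [1, 1]."""
    missing = set(matrix.index) - set(ti.tip_label.values())
    if missing:
        raise ValidationError(f"matrix rows not on the tree: {sorted(missing)}")
    nsites = matrix.shape[1]
    partials = {}
    for i, label in ti.tip_label.items():
        p = np.ones((nsites, 2))
        if label in matrix.index:
            v = matrix.loc[label].to_numpy(dtype=float)
            obs = ~np.isnan(v)
            p[obs, 0] = (v[obs] == 0).astype(float)
            p[obs, 1] = (v[obs] == 1).astype(float)
        partials[i] = p
    return partials


def _pruning(matrix: pd.DataFrame, ti: TreeIndex, model: GainLossModel,
             mult: float) -> Tuple[Dict[int, np.ndarray], np.ndarray]:
    """Upward pass. Returns per-node partials and per-site likelihoods."""
    tip = _tip_partials(matrix, ti)
    partials: Dict[int, np.ndarray] = {}
    for i, node in enumerate(ti.nodes):
        if not ti.children[i]:
            partials[i] = tip[i]
            continue
        p = np.ones((matrix.shape[1], 2))
        for c in ti.children[i]:
            P = model.transition(ti.length[c], mult)
            p = p * (partials[c] @ P.T)
        partials[i] = p
    site_lik = partials[ti.root] @ model.prior(mult)
    return partials, site_lik


def likelihood(matrix: pd.DataFrame, tree: dendropy.Tree,
               model: GainLossModel) -> float:
    """Total log-likelihood of the presence/absence matrix; mixture
    likelihood is the weighted sum over rate categories per site."""
    ti = TreeIndex(tree)
    nsites = matrix.shape[1]
    mix = np.zeros(nsites)
    for w, m in zip(model.weights, model.rate_multipliers):
        _, site_lik = _pruning(matrix, ti, model, m)
        mix += w * site_lik
    if (mix <= 0).any():
        return -np.inf
    return float(np.log(mix).sum())


def fit_rates(matrix: pd.DataFrame, tree: dendropy.Tree, K: int = 1,
              rate_multipliers: Optional[Sequence[float]] = None,
              bounds: Tuple[float, float] = (1e-4, 1e3)) -> GainLossModel:
    """Maximum-likelihood gain/loss rates (deterministic; starts at
    g = l = 1 in log space, Nelder-Mead)."""
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 sites to fit rates")
    if rate_multipliers is None:
        rate_multipliers = tuple(float(x) for x in (np.linspace(0.5, 1.5, K) if K > 1 else [1.0]))
    weights = tuple([1.0 / len(rate_multipliers)] * len(rate_multipliers))
    ti = TreeIndex(tree)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def nll(x):
        g, l = np.exp(np.clip(x, lo, hi))
        model = GainLossModel(g, l, rate_multipliers, weights)
        mix = np.zeros(matrix.shape[1])
        for w, m in zip(weights, rate_multipliers):
            _, site_lik = _pruning(matrix, ti, model, m)
            mix += w * site_lik
        if (mix <= 0).any():
            return np.inf
        return -np.log(mix).sum()

    res = minimize(nll, x0=np.log([1.0, 1.0]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    g, l = np.exp(np.clip(res.x, lo, hi))
    col = matrix.to_numpy(dtype=float)
    if np.nanmin(col) == np.nanmax(col):
        import logging

        logging.getLogger(__name__).warning(
            "degenerate all-%d matrix: fitted rates sit at the bounds",
            int(np.nanmax(col)),
        )
    return GainLossModel(float(g), float(l), rate_multipliers, weights)


def _expected_transition_integrals(g: float, l: float, t: float):
    """E[#(0->1)] and E[#(1->0)] on a branch of length t, conditioned on
    the endpoint states: arrays E01[a, b], E10[a, b].

    Uses the closed form of \\int_0^t P_{a i}(s) q_{i j} P_{j b}(t-s) ds
    for the two-state chain (eigenvalues 0 and -(g+l)).
    """
    lam = g + l
    pi = np.array([l / lam, g / lam])

    def coeffs(a, b):
        # P_ab(s) = pi[b] + (delta_ab - pi[b]) e^{-lam s}
        return pi[b], (1.0 if a == b else 0.0) - pi[b]

    decay = np.exp(-lam * t)

    def integral(a, i, j, b):
        A1, A2 = coeffs(a, i)
        B1, B2 = coeffs(j, b)
        return (
            A1 * B1 * t
            + (A1 * B2 + A2 * B1) * (1 - decay) / lam
            + A2 * B2 * t * decay
        )

    P = np.empty((2, 2))
    for a in (0, 1):
        for b in (0, 1):
            A1, A2 = coeffs(a, b)
            P[a, b] = A1 + A2 * decay
    E01 = np.empty((2, 2))
    E10 = np.empty((2, 2))
    for a in (0, 1):
        for b in (0, 1):
            E01[a, b] = g * integral(a, 0, 1, b) / P[a, b]
            E10[a, b] = l * integral(a, 1, 0, b) / P[a, b]
    return E01, E10


def expected_events(matrix: pd.DataFrame, tree: dendropy.Tree,
                    model: GainLossModel) -> GainLossResult:
    """Per-branch expected numbers of gains and losses summed over sites.

    Branch-endpoint joint posteriors come from the up-down algorithm;
    expected transition counts conditioned on the endpoints use the
    analytic two-state formula. With a rate mixture, categories are
    weighted by their per-site posterior probability.
    """
    ti = TreeIndex(tree)
    nsites = matrix.shape[1]
    ncat = len(model.rate_multipliers)
    # per-category pruning
    partials_c, sitelik_c = [], []
    for m in model.rate_multipliers:
        partials, site_lik = _pruning(matrix, ti, model, m)
        partials_c.append(partials)
        sitelik_c.append(site_lik)
    mix = np.zeros(nsites)
    for w, sl in zip(model.weights, sitelik_c):
        mix += w * sl
    cat_post = np.stack([
        w * sl / mix for w, sl in zip(model.weights, sitelik_c)
    ])  # (ncat, nsites)

    branch_rows = []
    gains_total = 0.0
    losses_total = 0.0
    node_post = {i: np.zeros(nsites) for i in range(len(ti.nodes))}
    branch_ids = [b for b in range(len(ti.nodes)) if ti.parent[b] >= 0]
    acc = {b: [0.0, 0.0] for b in branch_ids}
    for ci, m in enumerate(model.rate_multipliers):
        partials = partials_c[ci]
        prior = model.prior(m)
        # downward (outside) pass, root first
        outside = {ti.root: np.tile(prior, (nsites, 1))}
        sib_msg: Dict[int, np.ndarray] = {}  # product of sibling messages, per child
        for i in reversed(range(len(ti.nodes))):  # preorder on the postorder list
            for c in ti.children[i]:
                sib = np.ones((nsites, 2))
                for c2 in ti.children[i]:
                    if c2 == c:
                        continue
                    P2 = model.transition(ti.length[c2], m)
                    sib = sib * (partials[c2] @ P2.T)
                sib_msg[c] = sib
                P = model.transition(ti.length[c], m)
                outside[c] = (outside[i] * sib) @ P
        # node marginal posteriors within this category
        for i in range(len(ti.nodes)):
            marg = outside[i] * partials[i]
            marg = marg / marg.sum(axis=1, keepdims=True)
            node_post[i] += cat_post[ci] * marg[:, 1]
        # per-branch expected events from endpoint joint posteriors
        g_eff = model.gain * m
        l_eff = model.loss * m
        for b in branch_ids:
            t = ti.length[b]
            P = model.transition(t, m)
            up = outside[ti.parent[b]] * sib_msg[b]  # parent-state outside term
            joint = up[:, :, None] * P[None, :, :] * partials[b][:, None, :]
            joint = joint / joint.sum(axis=(1, 2), keepdims=True)
            if t > 0:
                E01, E10 = _expected_transition_integrals(g_eff, l_eff, t)
            else:
                E01 = np.zeros((2, 2)); E10 = np.zeros((2, 2))
            w_site = cat_post[ci]
            acc[b][0] += float((w_site * (joint * E01[None]).sum(axis=(1, 2))).sum())
            acc[b][1] += float((w_site * (joint * E10[None]).sum(axis=(1, 2))).sum())
    for b in branch_ids:
        branch_rows.append({
            "branch": ti.clade_label(b),
            "length": ti.length[b],
            "expected_gains": acc[b][0],
            "expected_losses": acc[b][1],
        })
        gains_total += acc[b][0]
        losses_total += acc[b][1]
    branches = pd.DataFrame(branch_rows)
    posteriors = {ti.clade_label(i): node_post[i] for i in range(len(ti.nodes))}
    ll = likelihood(matrix, tree, model)
    return GainLossResult(
        model=model, log_likelihood=ll, branches=branches,
        total_gains=gains_total, total_losses=losses_total,
        node_posteriors=posteriors,
    )


# ---------------------------------------------------------------------------
# Stochastic mapping oracle (exact conditional sampling by rejection
# from forward simulation; intended for small trees).


def stochastic_mapping(
    pattern: Dict[str, float],
    tree: dendropy.Tree,
    model: GainLossModel,
    m: int = 10_000,
    seed: int = 17,
    max_batches: int = 2000,
) -> pd.DataFrame:
    """Sample per-branch gain/loss counts conditioned on one tip pattern.

    NaN tip values are unconstrained. Returns mean sampled gains and
    losses per branch over ``m`` accepted histories. Only single-category
    models are supported (the oracle's role is to validate the analytic
    expectations).
    """
    if len(model.rate_multipliers) != 1:
        raise ValidationError("stochastic mapping oracle supports K=1 only")
    rng = np.random.default_rng(seed)
    ti = TreeIndex(tree)
    g, l = model.gain, model.loss
    prior1 = model.prior()[1]
    tips = list(ti.tip_label.items())
    want = np.array([pattern.get(label, np.nan) for _, label in tips])
    branch_ids = [b for b in range(len(ti.nodes)) if ti.parent[b] >= 0]
    gains = {b: 0.0 for b in branch_ids}
    losses = {b: 0.0 for b in branch_ids}
    accepted = 0
    batch = max(1000, m)
    for _ in range(max_batches):
        states = {ti.root: (rng.random(batch) < prior1).astype(np.int8)}
        bg = {b: np.zeros(batch) for b in branch_ids}
        bl = {b: np.zeros(batch) for b in branch_ids}
        for i in reversed(range(len(ti.nodes))):  # preorder
            for c in ti.children[i]:
                t = ti.length[c]
                s = states[i].copy()
                remaining = np.full(batch, t)
                active = np.ones(batch, dtype=bool)
                while active.any():
                    rate = np.where(s == 0, g, l)
                    wait = rng.exponential(1.0 / rate)
                    flip = active & (wait < remaining)
                    remaining = remaining - np.where(active, wait, 0.0)
                    bg[c][flip & (s == 0)] += 1
                    bl[c][flip & (s == 1)] += 1
                    s = np.where(flip, 1 - s, s)
                    active = flip
                states[c] = s.astype(np.int8)
        ok = np.ones(batch, dtype=bool)
        for (node_i, _), w in zip(tips, want):
            if np.isnan(w):
                continue
            ok &= states[node_i] == int(w)
        idx = np.nonzero(ok)[0]
        take = idx[: m - accepted]
        for b in branch_ids:
            gains[b] += bg[b][take].sum()
            losses[b] += bl[b][take].sum()
        accepted += len(take)
        if accepted >= m:
            break
    if accepted == 0:
        raise ValidationError("no accepted histories; pattern probability too small")
    rows = [{
        "branch": ti.clade_label(b),
        "length": ti.length[b],
        "mean_gains": gains[b] / accepted,
        "mean_losses": losses[b] / accepted,
        "n_samples": accepted,
    } for b in branch_ids]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fitch parsimony oracle


def fitch_parsimony(matrix: pd.DataFrame, tree: dendropy.Tree):
    """Minimal binary state changes per site, with one optimal
    assignment and per-branch change totals.

    Missing (NaN) tips are unconstrained ({0,1}). Returns
    (per_site_changes, branch_totals DataFrame).
    """
    ti = TreeIndex(tree)
    nsites = matrix.shape[1]
    # state sets encoded as bitmasks: 1 -> {0}, 2 -> {1}, 3 -> {0,1}
    sets: Dict[int, np.ndarray] = {}
    changes = np.zeros(nsites, dtype=np.int64)
    for i in range(len(ti.nodes)):
        if not ti.children[i]:
            label = ti.tip_label[i]
            if label in matrix.index:
                v = matrix.loc[label].to_numpy(dtype=float)
                s = np.full(nsites, 3, dtype=np.int8)
                s[v == 0] = 1
                s[v == 1] = 2
            else:
                s = np.full(nsites, 3, dtype=np.int8)
            sets[i] = s
            continue
        inter = np.full(nsites, 3, dtype=np.int8)
        union = np.zeros(nsites, dtype=np.int8)
        for c in ti.children[i]:
            inter = inter & sets[c]
            union = union | sets[c]
        empty = inter == 0
        changes += empty.astype(np.int64)
        sets[i] = np.where(empty, union, inter).astype(np.int8)
    # top-down assignment: prefer absence (0) at the root on ties
    assign: Dict[int, np.ndarray] = {}
    root_set = sets[ti.root]
    assign[ti.root] = np.where(root_set & 1, 0, 1).astype(np.int8)
    branch_ids = [b for b in range(len(ti.nodes)) if ti.parent[b] >= 0]
    branch_changes = {b: np.zeros(nsites, dtype=np.int64) for b in branch_ids}
    for i in reversed(range(len(ti.nodes))):
        for c in ti.children[i]:
            parent_state = assign[i]
            mask = 1 << parent_state  # parent state as bitmask
            keeps = (sets[c] & mask) > 0
            child_state = np.where(
                keeps, parent_state, np.where(sets[c] & 1, 0, 1)
            ).astype(np.int8)
            branch_changes[c] = (child_state != parent_state).astype(np.int64)
            assign[c] = child_state
    totals = pd.DataFrame([
        {
            "branch": ti.clade_label(b),
            "length": ti.length[b],
            "changes": int(branch_changes[b].sum()),
        }
        for b in branch_ids
    ])
    return changes, totals
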