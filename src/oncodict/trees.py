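"""Mixtures of oncogenetic trees over binary atom patterns.

An oncogenetic tree is a branching rooted at a non-event node R: each
atom (alteration pattern) appears once, with one parent and an edge
probability p(child | parent). A binary pattern x has probability

    P(x | T) = prod over edges (u -> v), u present or u = R:
                   p_uv   if v present
                   1-p_uv if v absent

and probability 0 when some present atom's parent is absent (ancestor
closure). Patterns thus accumulate along root-to-leaf paths, modeling
the ordered acquisition of alterations during tumor progression.

A mixture M = sum_k a_k T_k (weights summing to 1) combines K structured
trees with a mandatory *star* noise component — all atoms at depth one —
that represents independent random alterations and absorbs patterns
incompatible with every structured tree.

Structure learning follows the classical recipe: per-edge log-likelihood
weights from (responsibility-weighted) marginal and pair counts — plus a
charge of ln(eps) for every observation that contradicts the edge — and
a maximum-weight branching (Chu-Liu/Edmonds, implemented here with a
deterministic smallest-parent tie-break); edge probabilities are the
pseudo-counted conditional frequencies. Mixtures are fitted by EM on the
matching error-tolerant pseudo-likelihood, with eps annealed from loose
to sharp and an ascent safeguard so the reported trace never decreases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

ROOT = -1
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class OncogeneticTree:
    """Rooted branching over J atoms.

    parent[v] is the parent atom index of atom v, or ROOT (-1); prob[v]
    is the conditional probability of v given its parent.
    """

    parent: np.ndarray   # (J,) int
    prob: np.ndarray     # (J,) float in (0, 1)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.prob = np.asarray(self.prob, dtype=float)
        J = self.parent.size
        if self.prob.shape != (J,):
            raise ValueError("parent and prob must have equal length")
        if np.any((self.prob <= 0) | (self.prob >= 1)):
            raise ValueError("edge probabilities must lie strictly in (0, 1)")
        # reject cycles / out-of-range parents
        for v in range(J):
            seen = set()
            u = v
            while u != ROOT:
                if u in seen:
                    raise ValueError(f"cycle through atom {v}")
                seen.add(u)
                u = int(self.parent[u])
                if u != ROOT and not 0 <= u < J:
                    raise ValueError(f"parent index {u} out of range")

    @property
    def J(self) -> int:
        return self.parent.size

    def depth(self, v: int) -> int:
        d = 0
        u = int(self.parent[v])
        while u != ROOT:
            d += 1
            u = int(self.parent[u])
        return d + 1

    def is_star(self) -> bool:
        return bool(np.all(self.parent == ROOT))


@dataclass
class TreeMixture:
    """K+1 trees with convex weights; component 0 is the star noise tree."""

    trees: list[OncogeneticTree]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.trees) != self.weights.size:
            raise ValueError("one weight per tree required")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        if not self.trees[0].is_star():
            raise ValueError("component 0 must be the star noise tree")

    @property
    def K(self) -> int:
        """Number of structured (non-star) components."""
        return len(self.trees) - 1


@dataclass
class PatternSet:
    """n binary atom patterns (rows) over J atoms."""

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2 or not np.isin(self.X, (0, 1)).all():
            raise ValueError("patterns must be a binary n x J matrix")
        self.X = self.X.astype(np.int8)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def J(self) -> int:
        return self.X.shape[1]


def _as_patterns(patterns) -> np.ndarray:
    X = patterns.X if isinstance(patterns, PatternSet) else np.asarray(patterns)
    if X.ndim == 1:
        X = X[None, :]
    return X


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def pattern_likelihood(x: np.ndarray, T: OncogeneticTree) -> float:
    """P(x | T); zero when a present atom's parent is absent."""
    x = np.asarray(x).ravel()
    if x.size != T.J:
        raise ValueError("pattern length must equal number of atoms")
    p = 1.0
    for v in range(T.J):
        u = int(T.parent[v])
        parent_present = u == ROOT or x[u] == 1
        if x[v] == 1:
            if not parent_present:
                return 0.0
            p *= T.prob[v]
        elif parent_present:
            p *= 1.0 - T.prob[v]
        # absent parent, absent child: factor 1
    return float(p)


def pattern_log_likelihoods(patterns, T: OncogeneticTree) -> np.ndarray:
    """Vectorized P(x_i | T) for a whole pattern set (returns probabilities)."""
    X = _as_patterns(patterns)
    n, J = X.shape
    out = np.ones(n)
    for v in range(J):
        u = int(T.parent[v])
        parent_ok = np.ones(n, dtype=bool) if u == ROOT else X[:, u] == 1
        present = X[:, v] == 1
        out[present & ~parent_ok] = 0.0
        out[present & parent_ok] *= T.prob[v]
        out[~present & parent_ok] *= 1.0 - T.prob[v]
    return out


def mixture_likelihood(x: np.ndarray, M: TreeMixture) -> float:
    """Weighted mixture likelihood sum_k a_k P(x | T_k)."""
    return float(sum(a * pattern_likelihood(x, T) for a, T in zip(M.weights, M.trees)))


# ---------------------------------------------------------------------------
# Maximum-weight branching (Chu-Liu/Edmonds)
# ---------------------------------------------------------------------------

def edmonds_branching(weights: np.ndarray) -> np.ndarray:
    """Maximum-weight spanning branching rooted at R.

    ``weights`` is a (J+1) x J matrix: row 0 holds root->atom weights,
    row u+1 holds atom u -> atom v weights; -inf forbids an edge.
    Returns the parent array (ROOT = -1). Ties in the greedy incoming-
    edge choice break toward the lexicographically smallest parent
    (the root first), so equal weights yield the star.
    """
    W = np.asarray(weights, dtype=float)
    J = W.shape[1]
    if W.shape != (J + 1, J):
        raise ValueError("weights must be (J+1) x J")
    if J == 0:
        return np.empty(0, dtype=int)
    # internal node ids: 0 = root, 1..J = atoms
    edges = {}
    for u in range(J + 1):
        for v in range(J):
            if np.isfinite(W[u, v]) and u != v + 1:
                edges[(u, v + 1)] = float(W[u, v])
    parent_of = _cle(set(range(J + 1)), edges, root=0, next_id=J + 1)
    out = np.empty(J, dtype=int)
    for v in range(1, J + 1):
        if v not in parent_of:
            raise ValueError(f"atom {v - 1} is unreachable from the root")
        out[v - 1] = parent_of[v] - 1 if parent_of[v] != 0 else ROOT
    return out


def _best_incoming(nodes, edges, root):
    best = {}
    for v in nodes:
        if v == root:
            continue
        cands = [(w, -u, u) for (u, vv), w in edges.items() if vv == v]
        if not cands:
            raise ValueError("node unreachable from the root")
        w, _, u = max(cands)  # max weight; ties -> smallest parent id
        best[v] = (u, w)
    return best


def _find_cycle(best):
    for start in best:
        path = {start}
        v = start
        while v in best:
            v = best[v][0]
            if v == start:
                # walk again to collect the cycle
                cyc = [start]
                u = best[start][0]
                while u != start:
                    cyc.append(u)
                    u = best[u][0]
                return set(cyc)
            if v in path:
                break
            path.add(v)
    return None


def _cle(nodes, edges, root, next_id):
    best = _best_incoming(nodes, edges, root)
    cycle = _find_cycle(best)
    if cycle is None:
        return {v: u for v, (u, _) in best.items()}
    c = next_id
    new_nodes = (nodes - cycle) | {c}
    new_edges = {}
    into = {}    # (u, c) -> real target v in cycle
    outof = {}   # (c, v) -> real source u in cycle
    for (u, v), w in edges.items():
        if u in cycle and v in cycle:
            continue
        if v in cycle:
            adj = w - best[v][1]
            key = (u, c)
            if key not in new_edges or (adj, -v) > (new_edges[key], -into[key]):
                new_edges[key] = adj
                into[key] = v
        elif u in cycle:
            key = (c, v)
            if key not in new_edges or (w, -u) > (new_edges[key], -outof[key]):
                new_edges[key] = w
                outof[key] = u
        else:
            new_edges[(u, v)] = w
    sub = _cle(new_nodes, new_edges, root, next_id + 1)
    parent = {v: u for v, u in sub.items() if v != c and u != c}
    for v, u in sub.items():
        if u == c:
            parent[v] = outof[(c, v)]
    entry_u = sub[c]
    entry_v = into[(entry_u, c)]
    for v in cycle:
        parent[v] = best[v][0] if v != entry_v else entry_u
    return parent


# ---------------------------------------------------------------------------
# Tree and mixture estimation
# ---------------------------------------------------------------------------

def _weighted_counts(X: np.ndarray, resp: np.ndarray):
    n_tot = float(resp.sum())
    n_v = resp @ X                       # (J,)
    n_uv = (X * resp[:, None]).T @ X     # (J, J), n_uv[u, v]
    return n_tot, n_v, n_uv


DEFAULT_VIOLATION_RATE = 0.01


def fit_single_tree(patterns, responsibilities: np.ndarray | None = None,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT,
                    violation_rate: float = DEFAULT_VIOLATION_RATE) -> OncogeneticTree:
    """Maximum-weight-branching estimate of one oncogenetic tree.

    Candidate edge u -> v scores W = n(u,v) ln p + (n(u) - n(u,v)) ln(1-p)
    with p = (n(u,v) + c) / (n(u) + 2c) from (weighted) marginal and pair
    counts; n(R) is the total weight. Observations of v *without* u
    contradict the edge — a tree containing it would give such patterns
    probability zero — so each one also charges ln(violation_rate),
    treating it as a rare error event. The count-only score without this
    term would actually favor the *reversed* edge on chain-generated
    data (a child that never occurs without its parent gets p ~ 1 and
    weight ~ 0); with it, the maximum-weight branching over W is the
    maximum-likelihood tree of the error-tolerant model (and, as
    violation_rate -> 0, of the strict model, where the per-edge
    decomposition is exact). Edge probabilities are the p of the chosen
    edges; atoms never observed are attached directly to the root.
    """
    X = _as_patterns(patterns).astype(float)
    n, J = X.shape
    if n < 1:
        raise ValueError("need at least one pattern")
    resp = np.ones(n) if responsibilities is None else np.asarray(responsibilities, dtype=float)
    if resp.shape != (n,) or np.any(resp < 0):
        raise ValueError("responsibilities must be nonnegative, one per pattern")
    if not 0 <= violation_rate < 1:
        raise ValueError("violation_rate must lie in [0, 1)")
    c = pseudocount
    n_tot, n_v, n_uv = _weighted_counts(X, resp)

    # parents: row 0 = root with n(R) = n_tot, rows 1..J = atoms
    n_u = np.concatenate(([n_tot], n_v))            # (J+1,)
    pair = np.vstack([n_v[None, :], n_uv])          # (J+1, J)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = (pair + c) / (n_u[:, None] + 2 * c)
        W = pair * np.log(p_hat) + (n_u[:, None] - pair) * np.log1p(-p_hat)
    W[~np.isfinite(W)] = -np.inf
    # charge observations of v without u against the edge u -> v
    violations = np.maximum(n_v[None, :] - n_uv, 0.0)
    log_eps = np.log(violation_rate) if violation_rate > 0 else -np.inf
    with np.errstate(invalid="ignore"):
        W[1:] = W[1:] + np.where(violations > 1e-9 * max(n_tot, 1.0),
                                 violations * log_eps, 0.0)
    W[1:][np.isnan(W[1:])] = -np.inf
    for v in range(J):
        W[v + 1, v] = -np.inf                        # no self-loops
        if n_v[v] == 0:                              # unobserved: root only
            W[1:, v] = -np.inf
    parent = edmonds_branching(W)
    prob = np.array([
        p_hat[(parent[v] + 1) if parent[v] != ROOT else 0, v] for v in range(J)
    ])
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    return OncogeneticTree(parent=parent, prob=prob)


def noise_star_tree(patterns, responsibilities: np.ndarray | None = None,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> OncogeneticTree:
    """Star tree: every atom a root child with pseudo-counted marginal p."""
    X = _as_patterns(patterns).astype(float)
    n, J = X.shape
    resp = np.ones(n) if responsibilities is None else np.asarray(responsibilities, dtype=float)
    n_tot = float(resp.sum())
    n_v = resp @ X
    p = (n_v + pseudocount) / (n_tot + 2 * pseudocount)
    return OncogeneticTree(parent=np.full(J, ROOT), prob=np.clip(p, 1e-12, 1 - 1e-12))


@dataclass
class MixtureFit:
    mixture: TreeMixture
    log_likelihood: float            # strict-model observed log-likelihood
    trace: list[float] = field(default_factory=list)  # fitting (pseudo) trace
    converged: bool = False
    responsibilities: np.ndarray | None = None
    pseudo_log_likelihood: float = float("nan")


def _mixture_loglik(X: np.ndarray, trees, weights) -> tuple[float, np.ndarray]:
    Lmat = np.vstack([pattern_log_likelihoods(X, T) for T in trees])  # (K+1, n)
    mix = weights @ Lmat
    if np.any(mix <= 0):
        raise FloatingPointError("a pattern has zero likelihood under every component")
    return float(np.sum(np.log(mix))), Lmat


def _pseudo_likelihoods(X: np.ndarray, T: OncogeneticTree, eps: float) -> np.ndarray:
    """Per-pattern error-tolerant likelihood: like the strict model, but a
    present atom under an absent parent contributes ``eps`` instead of 0
    (an absent atom under an absent parent still contributes 1)."""
    n, J = X.shape
    out = np.ones(n)
    for v in range(J):
        u = int(T.parent[v])
        parent_ok = np.ones(n, dtype=bool) if u == ROOT else X[:, u] == 1
        present = X[:, v] == 1
        out[present & parent_ok] *= T.prob[v]
        out[~present & parent_ok] *= 1.0 - T.prob[v]
        out[present & ~parent_ok] *= eps
    return out


def fit_mixture(patterns, K: int, seed: int = 0, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                anneal: tuple[float, ...] = (0.1, 0.01, 0.001),
                restarts: int = 8, max_iter: int = 300, tol: float = 1e-8) -> MixtureFit:
    """EM fit of a K-structured-tree mixture plus the mandatory star.

    Fitting uses the error-tolerant pseudo-likelihood of
    :func:`_pseudo_likelihoods`: a present atom whose parent is absent is
    treated as an error event with probability eps rather than an
    impossibility. This removes the zero-likelihood cliffs of the strict
    model, makes the maximum-weight-branching refit (with the matching
    eps term, :func:`fit_single_tree`) the *exact* M-step, and therefore
    makes each EM sweep monotone in the pseudo-log-likelihood. eps is
    annealed over the ``anneal`` schedule: large values let structure
    emerge while the components are still mixed, small values sharpen it
    once the responsibilities have separated.

    E-step: gamma_ks proportional to a_k L_eps(x_s | T_k); M-step:
    a_k = mean responsibility, star refit from weighted marginals,
    structured trees refit by weighted maximum-weight branching.

    The likelihood surface is multimodal, so the fit is restarted
    ``restarts`` times from seeded random initializations alternating
    two families — random hard splits, and splits induced by
    burden-weighted prototype patterns (Jaccard assignment) — and the
    best final pseudo-likelihood wins. The reported ``trace`` is the
    final annealing stage of the winning restart (non-decreasing);
    ``log_likelihood`` is the strict-model observed log-likelihood of
    the returned mixture.
    """
    if K < 1:
        raise ValueError("K must be >= 1 structured component")
    X = _as_patterns(patterns)
    n, J = X.shape
    rng = np.random.default_rng(seed)

    def em_run(assign: np.ndarray):
        trees = [noise_star_tree(X, pseudocount=pseudocount)]
        for k in range(K):
            resp = (assign == k).astype(float)
            if resp.sum() == 0:
                resp[rng.integers(0, n)] = 1.0
            trees.append(fit_single_tree(X, resp, pseudocount, anneal[0]))
        weights = np.full(K + 1, 1.0 / (K + 1))

        def stage_ll(trs, wts, eps):
            Lmat = np.vstack([_pseudo_likelihoods(X, T, eps) for T in trs])
            mix = wts @ Lmat
            return float(np.sum(np.log(np.maximum(mix, 1e-300)))), Lmat, mix

        ll = -np.inf
        gamma = None
        trace: list[float] = []
        for eps in anneal:
            ll, Lmat, mix = stage_ll(trees, weights, eps)
            trace = [ll]
            for _ in range(max_iter):
                gamma = (weights[:, None] * Lmat) / mix[None, :]
                cand_w = gamma.mean(axis=1)
                cand_t = [noise_star_tree(X, gamma[0], pseudocount)] + [
                    fit_single_tree(X, gamma[k], pseudocount, eps)
                    for k in range(1, K + 1)
                ]
                cand_ll, cand_L, cand_mix = stage_ll(cand_t, cand_w, eps)
                if cand_ll < ll - 1e-12 * (1 + abs(ll)):
                    break  # pseudo-counted M-step can dip slightly; keep current
                improved = cand_ll - ll
                trees, weights, ll, Lmat, mix = cand_t, cand_w, cand_ll, cand_L, cand_mix
                trace.append(ll)
                if improved <= tol * (1 + abs(ll)):
                    break
        return trees, weights, ll, trace, gamma

    burden = X.sum(axis=1).astype(float)
    best = None
    for r in range(restarts):
        if r % 2 == 0 and burden.sum() > 0:
            # prototype split: K burden-weighted anchor patterns, Jaccard
            w_p = burden + 0.1
            protos = []
            for _ in range(K):
                i = rng.choice(n, p=w_p / w_p.sum())
                protos.append(X[i].astype(float))
                overlap = (X @ X[i]).astype(float) / max(X[i].sum(), 1)
                w_p = np.maximum(w_p * (1.0 - overlap), 1e-6)
            P = np.vstack(protos)
            inter = X @ P.T
            union = burden[:, None] + P.sum(axis=1)[None, :] - inter
            assign = (inter / np.maximum(union, 1.0)).argmax(axis=1)
        else:
            assign = rng.integers(0, K, size=n)
        out = em_run(assign)
        if best is None or out[2] > best[2]:
            best = out
    trees, weights, pseudo_ll, trace, gamma = best
    weights = weights / weights.sum()
    mixture = TreeMixture(trees=trees, weights=weights)
    strict_ll, _ = _mixture_loglik(X, trees, weights)
    converged = len(trace) < max_iter
    return MixtureFit(mixture=mixture, log_likelihood=strict_ll, trace=trace,
                      converged=converged, responsibilities=gamma,
                      pseudo_log_likelihood=pseudo_ll)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_NODE_COLORS = {"gain": "red", "loss": "green", "both": "orange", "none": "gray"}


def _atom_direction(labels: list[str]) -> str:
    has_gain = any(l.startswith("+") for l in labels)
    has_loss = any(l.startswith("-") for l in labels)
    if has_gain and has_loss:
        return "both"
    if has_gain:
        return "gain"
    if has_loss:
        return "loss"
    return "none"


def mixture_to_json(M: TreeMixture, atom_ids: list[str] | None = None) -> dict:
    J = M.trees[0].J
    if atom_ids is None:
        atom_ids = [f"A{j + 1}" for j in range(J)]
    return {
        "atom_ids": list(atom_ids),
        "weights": M.weights.tolist(),
        "trees": [
            {"parent": T.parent.tolist(), "prob": T.prob.tolist()}
            for T in M.trees
        ],
    }


def mixture_from_json(doc: dict) -> TreeMixture:
    trees = [OncogeneticTree(np.array(t["parent"]), np.array(t["prob"]))
             for t in doc["trees"]]
    return TreeMixture(trees=trees, weights=np.array(doc["weights"]))


def export_tree(M: TreeMixture, atom_ids: list[str] | None = None,
                atom_labels: dict[int, list[str]] | None = None) -> tuple[list[str], dict]:
    """Render each mixture component as a DOT digraph; plus a JSON document.

    Edges are annotated with their conditional probability; nodes are
    colored by the direction of the atom's alterations (red gain, green
    loss) when band labels are supplied. The JSON round-trips to an
    identical TreeMixture via :func:`mixture_from_json`.
    """
    J = M.trees[0].J
    if atom_ids is None:
        atom_ids = [f"A{j + 1}" for j in range(J)]
    atom_labels = atom_labels or {}
    dots = []
    for k, (a, T) in enumerate(zip(M.weights, M.trees)):
        name = "star_noise" if k == 0 else f"tree_{k}"
        lines = [f'digraph {name} {{',
                 f'  R [shape=box, label="R (a={a:.3f})"];']
        for v in range(J):
            lbls = atom_labels.get(v, [])
            color = _NODE_COLORS[_atom_direction(lbls)]
            text = atom_ids[v] + (r"\n" + ", ".join(lbls) if lbls else "")
            lines.append(f'  n{v} [label="{text}", style=filled, fillcolor={color}];')
        for v in range(J):
            src = "R" if T.parent[v] == ROOT else f"n{int(T.parent[v])}"
            lines.append(f'  {src} -> n{v} [label="{T.prob[v]:.2f}"];')
        lines.append("}")
        dots.append("\n".join(lines))
    return dots, mixture_to_json(M, atom_ids)
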