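"""Plackett-Luce ranking models: likelihood, MM fitting, EM mixtures, BIC
model selection, cross-iteration consolidation, and aggregate orderings.

Each sample contributes a total order over its *own* subset of the event
catalog; under the Plackett-Luce model items are drawn sequentially with
probability proportional to their positive worths, the denominator
shrinking over the sample's remaining items.  Worths are estimated with
Hunter's minorize-maximize algorithm, optionally regularized by a gamma
prior (a Dirichlet-style pseudocount) that keeps the comparison graph
effectively connected.  Mixtures over K latent trajectories are fitted by
EM with the MM update as the weighted M-step, and K is selected by the
lowest median BIC across ordering iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from .core import ValidationError

logger = logging.getLogger(__name__)

UNCLASSIFIABLE = "UNCLASSIFIABLE"


# ---------------------------------------------------------------------------
# Ranking container


class RankingMatrix:
    """Rankings of item subsets encoded as a padded integer matrix.

    Row r holds the item indices of ranking r from first to last; unused
    cells are -1.  Items that appear in no ranking are dropped (with a
    warning) since their worths are not identified.
    """

    def __init__(self, orders, items=None):
        observed = []
        seen = set()
        for order in orders:
            for item in order:
                if item not in seen:
                    seen.add(item)
                    observed.append(item)
        if items is None:
            self.items = observed
        else:
            dropped = [i for i in items if i not in seen]
            if dropped:
                logger.warning("dropping %d items absent from all rankings",
                               len(dropped))
            self.items = [i for i in items if i in seen]
        extra = [i for i in observed if i not in set(self.items)]
        if extra:
            raise ValidationError(f"rankings contain unknown items: {extra}")
        self.index = {item: i for i, item in enumerate(self.items)}
        self.n = len(orders)
        self.m = len(self.items)
        length = max((len(o) for o in orders), default=0)
        self.R = np.full((self.n, max(length, 1)), -1, dtype=np.int64)
        for r, order in enumerate(orders):
            if len(set(order)) != len(order):
                raise ValidationError("ranking repeats an item")
            self.R[r, :len(order)] = [self.index[i] for i in order]
        self.valid = self.R >= 0
        self.lengths = self.valid.sum(axis=1)
        # position of each row's last item (choices are made at all
        # positions before it)
        last = self.lengths - 1
        self.choice = self.valid.copy()
        rows = np.arange(self.n)
        nonempty = self.lengths > 0
        self.choice[rows[nonempty], last[nonempty]] = False
        self._Rsafe = np.where(self.valid, self.R, 0)

    def loglik_rows(self, worths: np.ndarray) -> np.ndarray:
        """Per-ranking log-likelihood under a worth vector."""
        w = np.asarray(worths, dtype=float)
        if np.any(w <= 0):
            raise ValidationError("worths must be strictly positive")
        W = np.where(self.valid, w[self._Rsafe], 0.0)
        suffix = np.cumsum(W[:, ::-1], axis=1)[:, ::-1]
        with np.errstate(divide="ignore"):
            terms = np.where(self.choice,
                             np.log(np.where(self.valid, W, 1.0))
                             - np.log(np.where(suffix > 0, suffix, 1.0)),
                             0.0)
        return terms.sum(axis=1)

    def win_counts(self, row_weights: np.ndarray) -> np.ndarray:
        flat = self.R[self.choice]
        weights = np.broadcast_to(row_weights[:, None],
                                  self.R.shape)[self.choice]
        return np.bincount(flat, weights=weights, minlength=self.m)

    def mm_denominators(self, worths: np.ndarray,
                        row_weights: np.ndarray) -> np.ndarray:
        """D_i = sum over (ranking, choice position j with i still
        available) of row_weight / (sum of remaining worths at j)."""
        W = np.where(self.valid, worths[self._Rsafe], 0.0)
        suffix = np.cumsum(W[:, ::-1], axis=1)[:, ::-1]
        with np.errstate(divide="ignore"):
            inv = np.where(self.choice & (suffix > 0), 1.0 / suffix, 0.0)
        inv = inv * row_weights[:, None]
        contrib = np.cumsum(inv, axis=1)      # item at position k was
        flat = self.R[self.valid]             # available for all j <= k
        weights = contrib[self.valid]
        return np.bincount(flat, weights=weights, minlength=self.m)

    def strongly_connected(self) -> bool:
        """Whether the directed beats-graph is strongly connected (the
        Ford condition for a finite unregularized MLE)."""
        if self.m <= 1:
            return True
        rows, cols = [], []
        for r in range(self.n):
            order = self.R[r, self.valid[r]]
            for a in range(len(order)):
                for b in range(a + 1, len(order)):
                    rows.append(order[a])
                    cols.append(order[b])
        if not rows:
            return False
        graph = csr_matrix((np.ones(len(rows)), (rows, cols)),
                           shape=(self.m, self.m))
        n_comp, _ = connected_components(graph, directed=True,
                                         connection="strong")
        return n_comp == 1


def pl_loglik(order, worths: dict) -> float:
    """Log-likelihood of one ranking (first to last) of a subset of items
    under a worth map: sum_j log(w_{r_j} / sum_{k>=j} w_{r_k})."""
    values = []
    for item in order:
        if item not in worths:
            raise ValidationError(f"no worth for ranked item {item!r}")
        w = worths[item]
        if w <= 0:
            raise ValidationError(f"non-positive worth for {item!r}")
        values.append(float(w))
    total = 0.0
    remaining = sum(values)
    for j, w in enumerate(values[:-1]):
        total += np.log(w / remaining)
        remaining -= w
    return float(total)


# ---------------------------------------------------------------------------
# Single-component fit


@dataclass
class PLFit:
    worths: dict                    # item -> worth, normalized to sum 1
    loglik: float
    n_iter: int
    converged: bool
    history: list = field(default_factory=list)   # objective per MM update
    items: list = field(default_factory=list)

    @property
    def worth_vector(self) -> np.ndarray:
        return np.array([self.worths[i] for i in self.items])


def _mm_iterate(data: RankingMatrix, w: np.ndarray, row_weights: np.ndarray,
                pseudocount: float, tol: float, max_iter: int,
                track: list | None = None):
    """Run MM updates in place; returns (worths, n_iter, converged).

    With pseudocount c the update is the MAP step for independent
    Gamma(1 + c, c * m) worth priors: w_i <- (W_i + c) / (D_i + c * m).
    The (penalized) objective is non-decreasing at every update.
    """
    wins = data.win_counts(row_weights)
    b = pseudocount * data.m

    def objective(wv):
        raw = float(np.dot(row_weights, data.loglik_rows(wv)))
        if pseudocount == 0:
            return raw, raw
        pen = raw + pseudocount * float(np.sum(np.log(wv))) - b * float(np.sum(wv))
        return raw, pen

    raw, pen = objective(w)
    if track is not None:
        track.append(pen)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = data.mm_denominators(w, row_weights)
        w = (wins + pseudocount) / np.where(denom + b > 0, denom + b, 1.0)
        w = np.maximum(w, 1e-300)
        new_raw, new_pen = objective(w)
        if track is not None:
            track.append(new_pen)
        if abs(new_pen - pen) <= tol * (abs(pen) + 1e-12):
            raw, pen = new_raw, new_pen
            converged = True
            break
        raw, pen = new_raw, new_pen
    return w, raw, it, converged


def fit_pl(orders, items=None, tol: float = 1e-6, max_iter: int = 500,
           pseudocount: float = 0.1, row_weights=None) -> PLFit:
    """Maximum-likelihood (or MAP, with pseudocount > 0) Plackett-Luce
    worths via Hunter's MM algorithm.

    ``orders`` may be raw item sequences or :class:`RankingMatrix`.
    """
    data = orders if isinstance(orders, RankingMatrix) \
        else RankingMatrix(orders, items)
    if data.m == 0:
        raise ValidationError("no items to fit")
    if pseudocount == 0 and not data.strongly_connected():
        raise ValidationError(
            "comparison graph is not strongly connected; the unregularized "
            "MLE does not exist — use prior_pseudocount > 0")
    weights = np.ones(data.n) if row_weights is None \
        else np.asarray(row_weights, dtype=float)
    w0 = np.full(data.m, 1.0 / data.m)
    history: list[float] = []
    w, loglik, n_iter, converged = _mm_iterate(
        data, w0, weights, pseudocount, tol, max_iter, track=history)
    w = w / w.sum()
    return PLFit(worths=dict(zip(data.items, w)), loglik=loglik,
                 n_iter=n_iter, converged=converged, history=history,
                 items=list(data.items))


# ---------------------------------------------------------------------------
# Mixtures


@dataclass
class PLMixtureFit:
    K: int
    weights: np.ndarray
    components: list                # K worth dicts over the same items
    responsibilities: np.ndarray    # N x K
    loglik: float
    bic: float
    history: list = field(default_factory=list)
    converged: bool = False
    items: list = field(default_factory=list)

    def map_labels(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)


def _mixture_params(K: int, m: int) -> int:
    return (K - 1) + K * (m - 1)


def _em_once(data: RankingMatrix, K: int, rng, tol, max_iter, pseudocount,
             inner_mm: int = 5, init=None):
    n, m = data.n, data.m
    if init is not None:
        weights = np.asarray(init[0], dtype=float).copy()
        W = np.asarray(init[1], dtype=float).copy()
    else:
        resp = rng.dirichlet(np.ones(K), size=n)
        weights = resp.mean(axis=0)
        W = np.full((K, m), 1.0 / m)
        for k in range(K):
            W[k], *_ = _mm_iterate(data, W[k].copy(), resp[:, k],
                                   pseudocount, 1e-4, inner_mm)
    history = []
    loglik = -np.inf
    converged = False
    for _ in range(max_iter):
        comp_ll = np.stack([data.loglik_rows(W[k] / W[k].sum())
                            for k in range(K)], axis=1)
        log_joint = np.log(np.maximum(weights, 1e-300))[None, :] + comp_ll
        row_norm = logsumexp(log_joint, axis=1)
        new_loglik = float(row_norm.sum())
        history.append(new_loglik)
        resp = np.exp(log_joint - row_norm[:, None])
        weights = resp.mean(axis=0)
        if np.any(weights < 1e-8):
            return None  # empty component: caller restarts
        for k in range(K):
            W[k], *_ = _mm_iterate(data, W[k].copy(), resp[:, k],
                                   pseudocount, 1e-4, inner_mm)
        if np.isfinite(loglik) and \
                abs(new_loglik - loglik) <= tol * (abs(loglik) + 1e-12):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    # final E-step quantities at the last parameters
    comp_ll = np.stack([data.loglik_rows(W[k] / W[k].sum())
                        for k in range(K)], axis=1)
    log_joint = np.log(np.maximum(weights, 1e-300))[None, :] + comp_ll
    row_norm = logsumexp(log_joint, axis=1)
    loglik = float(row_norm.sum())
    resp = np.exp(log_joint - row_norm[:, None])
    W = W / W.sum(axis=1, keepdims=True)
    return weights, W, resp, loglik, history, converged


def fit_pl_mixture(orders, K: int, items=None, n_restarts: int = 5,
                   seed: int = 0, tol: float = 1e-6, max_iter: int = 200,
                   pseudocount: float = 0.1, init=None) -> PLMixtureFit:
    """EM fit of a K-component Plackett-Luce mixture, best of
    ``n_restarts`` random initializations (plus one start from ``init``
    = (weights, worth matrix) when supplied, e.g. a warm start from a
    neighbouring ordering iteration).  K=1 reduces exactly to
    :func:`fit_pl`."""
    data = orders if isinstance(orders, RankingMatrix) \
        else RankingMatrix(orders, items)
    if K < 1:
        raise ValidationError("K must be >= 1")
    if data.n < K:
        raise ValidationError(f"need at least K={K} rankings, have {data.n}")

    if K == 1:
        single = fit_pl(data, tol=tol, max_iter=max_iter * 3,
                        pseudocount=pseudocount)
        bic = -2.0 * single.loglik + _mixture_params(1, data.m) * np.log(data.n)
        return PLMixtureFit(
            K=1, weights=np.array([1.0]), components=[single.worths],
            responsibilities=np.ones((data.n, 1)), loglik=single.loglik,
            bic=float(bic), history=list(single.history),
            converged=single.converged, items=list(data.items))

    best = None
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(K,)))
    if init is not None:
        best = _em_once(data, K, rng, tol, max_iter, pseudocount, init=init)
    attempts = 0
    restarts_done = 0
    while restarts_done < n_restarts and attempts < max(n_restarts, 1) * 4:
        attempts += 1
        result = _em_once(data, K, rng, tol, max_iter, pseudocount)
        if result is None:
            logger.info("EM restart: a mixture component emptied")
            continue
        restarts_done += 1
        if best is None or result[3] > best[3]:
            best = result
    if best is None:
        raise ValidationError(
            f"all EM starts collapsed to empty components at K={K}")
    weights, W, resp, loglik, history, converged = best
    bic = -2.0 * loglik + _mixture_params(K, data.m) * np.log(data.n)
    return PLMixtureFit(
        K=K, weights=weights,
        components=[dict(zip(data.items, W[k])) for k in range(K)],
        responsibilities=resp, loglik=loglik, bic=float(bic),
        history=history, converged=converged, items=list(data.items))


# ---------------------------------------------------------------------------
# Model selection across ordering iterations


@dataclass
class KSelection:
    best_k: int
    median_bic: dict                 # K -> median BIC across iterations
    fits: dict                       # (iteration, K) -> PLMixtureFit


def _fit_init(fit: PLMixtureFit, items) -> tuple:
    W = np.array([[comp[i] for i in items] for comp in fit.components])
    return fit.weights.copy(), W


def fit_iterations(per_iteration_orders: dict, K: int, items=None,
                   n_restarts: int = 5, seed: int = 0,
                   pseudocount: float = 0.1, tol: float = 1e-6) -> dict:
    """Fit a K-component mixture on every ordering iteration.

    Consecutive iterations differ only in the random tie-breaking of the
    within-sample orders, so each fit after the first is warm-started
    from its predecessor's solution (one fresh random start is kept as a
    safeguard against tracking a poor optimum)."""
    fits = {}
    previous = None
    for it in sorted(per_iteration_orders):
        data = RankingMatrix(per_iteration_orders[it], items)
        if previous is None:
            fit = fit_pl_mixture(data, K, n_restarts=n_restarts,
                                 seed=seed + 9973 * it, tol=tol,
                                 pseudocount=pseudocount)
        else:
            fit = fit_pl_mixture(data, K, n_restarts=1,
                                 seed=seed + 9973 * it, tol=tol,
                                 pseudocount=pseudocount,
                                 init=_fit_init(previous, data.items))
        fits[it] = fit
        previous = fit
    return fits


def select_k(per_iteration_orders: dict, k_max: int = 5, items=None,
             n_restarts: int = 5, seed: int = 0,
             pseudocount: float = 0.1, tol: float = 1e-6) -> KSelection:
    """Fit K = 1..k_max on every ordering iteration and pick the K with
    the lowest median BIC (ties favour the smaller K)."""
    if k_max < 1 or not per_iteration_orders:
        raise ValidationError("need k_max >= 1 and at least one iteration")
    fits = {}
    bics = {}
    for k in range(1, k_max + 1):
        per_k = fit_iterations(per_iteration_orders, k, items=items,
                               n_restarts=n_restarts, seed=seed,
                               pseudocount=pseudocount, tol=tol)
        for it, fit in per_k.items():
            fits[(it, k)] = fit
        bics[k] = [per_k[it].bic for it in sorted(per_k)]
    median_bic = {k: float(np.median(v)) for k, v in bics.items()}
    best_k = min(median_bic, key=lambda k: (median_bic[k], k))
    return KSelection(best_k=best_k, median_bic=median_bic, fits=fits)


# ---------------------------------------------------------------------------
# Consolidation of per-iteration fits into one assignment


@dataclass
class TrajectoryAssignment:
    labels: dict                     # sample_id -> int label or UNCLASSIFIABLE
    votes: np.ndarray                # n_samples x K vote fractions
    sample_ids: list
    K: int

    def members(self, label) -> list:
        return [sid for sid in self.sample_ids if self.labels[sid] == label]


def _align_mapping(reference: np.ndarray, labels: np.ndarray,
                   K: int) -> np.ndarray:
    """Permutation mapping[src] -> dst of component labels maximizing MAP
    overlap with the reference assignment (Hungarian matching)."""
    overlap = np.zeros((K, K))
    for k in range(K):
        for j in range(K):
            overlap[k, j] = np.sum((labels == k) & (reference == j))
    rows, cols = linear_sum_assignment(-overlap)
    mapping = np.empty(K, dtype=int)
    mapping[rows] = cols
    return mapping


def consolidate_assignments(per_iteration_fits: dict, sample_ids,
                            unclassifiable=()) -> TrajectoryAssignment:
    """One label per sample from many per-iteration mixture fits.

    Component labels are aligned across iterations by maximum-overlap
    matching of MAP assignments to the first iteration; the final label is
    the per-sample modal aligned MAP label, ties going to the component
    with the higher mean responsibility.
    """
    iterations = sorted(per_iteration_fits)
    if not iterations:
        raise ValidationError("no fits to consolidate")
    Ks = {per_iteration_fits[it].K for it in iterations}
    if len(Ks) != 1:
        raise ValidationError(f"fits disagree on K: {sorted(Ks)}")
    K = Ks.pop()
    n = len(sample_ids)

    reference = per_iteration_fits[iterations[0]].map_labels()
    votes = np.zeros((n, K))
    resp_sum = np.zeros((n, K))
    for it in iterations:
        fit = per_iteration_fits[it]
        labels = fit.map_labels()
        mapping = _align_mapping(reference, labels, K)
        aligned_labels = mapping[labels]
        for i in range(n):
            votes[i, aligned_labels[i]] += 1
        aligned_resp = np.zeros_like(fit.responsibilities)
        for src in range(K):
            aligned_resp[:, mapping[src]] = fit.responsibilities[:, src]
        resp_sum += aligned_resp
    votes /= len(iterations)
    mean_resp = resp_sum / len(iterations)

    labels = {}
    for i, sid in enumerate(sample_ids):
        top = np.flatnonzero(votes[i] == votes[i].max())
        if len(top) == 1:
            labels[sid] = int(top[0])
        else:
            labels[sid] = int(top[np.argmax(mean_resp[i, top])])
    for sid in unclassifiable:
        labels[sid] = UNCLASSIFIABLE
    return TrajectoryAssignment(labels=labels, votes=votes,
                                sample_ids=list(sample_ids), K=K)


# ---------------------------------------------------------------------------
# Aggregate orderings


@dataclass
class AggregateOrdering:
    """Per-event aggregate rank summary for one trajectory subset."""

    table: dict   # event -> {median_rank, ci_low, ci_high, prevalence}
    n_samples: int

    def ranked_events(self) -> list:
        return sorted(self.table, key=lambda e: (self.table[e]["median_rank"],
                                                 -self.table[e]["prevalence"]))


def aggregate_ordering(subset_orders_per_iteration: dict, n_samples: int,
                       min_carriers: int = 2, pseudocount: float = 0.1,
                       tol: float = 1e-6) -> AggregateOrdering:
    """Collate an overall event order across a subset's samples.

    Per ordering iteration the subset's rankings are fitted with a single
    Plackett-Luce component and events are ranked by descending worth;
    the median rank and the 2.5th/97.5th percentile ranks across
    iterations are reported, alongside each event's subset prevalence.
    Events carried by fewer than ``min_carriers`` samples are dropped (a
    rare event in a subset is not part of that subset's trajectory).
    """
    if n_samples < 2:
        raise ValidationError("aggregate ordering needs >= 2 samples")
    iterations = sorted(subset_orders_per_iteration)
    if not iterations:
        raise ValidationError("no iterations provided")

    first = subset_orders_per_iteration[iterations[0]]
    carriers: dict[str, int] = {}
    for order in first:
        for event in order:
            carriers[event] = carriers.get(event, 0) + 1
    kept = [e for e, k in carriers.items() if k >= min_carriers]
    dropped = [e for e in carriers if e not in set(kept)]
    if dropped:
        logger.info("aggregate ordering drops %d low-prevalence events: %s",
                    len(dropped), ", ".join(sorted(dropped)))
    if not kept:
        raise ValidationError("no events pass the subset prevalence floor")
    kept_set = set(kept)

    ranks_per_event: dict[str, list] = {e: [] for e in kept}
    for it in iterations:
        orders = [[e for e in order if e in kept_set]
                  for order in subset_orders_per_iteration[it]]
        orders = [o for o in orders if o]
        fit = fit_pl(orders, items=kept, pseudocount=pseudocount, tol=tol)
        ranked = sorted(fit.worths, key=lambda e: -fit.worths[e])
        for rank, event in enumerate(ranked, start=1):
            ranks_per_event[event].append(rank)

    table = {}
    for event in kept:
        ranks = np.array(ranks_per_event[event], dtype=float)
        if ranks.size == 0:
            continue
        table[event] = {
            "median_rank": float(np.median(ranks)),
            "ci_low": float(np.percentile(ranks, 2.5)),
            "ci_high": float(np.percentile(ranks, 97.5)),
            "prevalence": carriers[event] / n_samples,
        }
    return AggregateOrdering(table=table, n_samples=n_samples)
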