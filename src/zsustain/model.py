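"""Z-score event-based subtype-and-stage mixture model.

A subtype is an ordered sequence of *events*, each event being one biomarker
crossing one z-score waypoint (default waypoints z = 1, 2, 3 per biomarker).
A subject's *stage* k means the first k events of their subtype's sequence
have occurred.  The expected z-score of biomarker b at stage k is a
piecewise-linear curve through (0, 0), the biomarker's waypoint positions in
the sequence, and a terminal anchor (E, z_max); observed z-scores are the
expected curve plus Gaussian noise.  Subjects are modelled as a K-component
mixture over subtypes, with a uniform prior over stages 0..E within each
subtype.

Inference: expectation-maximisation with greedy single-event repositioning
for the sequences, a Metropolis-Hastings sampler over event orderings, and
hierarchical splitting to grow the number of subtypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ZScoreEventModelSpec",
    "EventSequence",
    "SubtypeModel",
    "SubjectAssignment",
    "FitSettings",
    "expected_value",
    "stage_expectations",
    "subject_loglik",
    "mixture_loglik",
    "random_sequence",
    "is_valid_order",
    "optimize_sequences_em",
    "mcmc_sequences",
    "fit",
    "assign",
]


# ---------------------------------------------------------------------------
# Model specification and sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZScoreEventModelSpec:
    """Event grid of the model: biomarkers x waypoints, terminal z_max, noise.

    Parameters
    ----------
    biomarkers:
        Ordered biomarker (ROI) names; data columns must follow this order.
    waypoints:
        Strictly increasing z-score severity waypoints shared by all
        biomarkers. Default (1, 2, 3).
    z_max:
        Expected z-score at the final stage E (default 5); a replication mode
        with z_max = 4 is obtained by passing ``z_max=4.0``.
    sigma:
        Observation noise SD per biomarker (scalar broadcasts). Inputs are
        normative z-scores, so the default is 1.
    """

    biomarkers: tuple[str, ...]
    waypoints: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    sigma: float | tuple[float, ...] = 1.0

    def __post_init__(self) -> None:
        if len(self.biomarkers) < 1:
            raise ValueError("at least one biomarker required")
        wps = tuple(float(w) for w in self.waypoints)
        if any(nxt <= prev for prev, nxt in zip(wps, wps[1:])):
            raise ValueError("waypoints must be strictly increasing")
        if wps[0] <= 0:
            raise ValueError("waypoints must be positive")
        if self.z_max < wps[-1]:
            raise ValueError("z_max must be >= the last waypoint")
        sig = self.sigma_array
        if np.any(sig <= 0):
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "waypoints", wps)

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    @property
    def n_waypoints(self) -> int:
        return len(self.waypoints)

    @property
    def n_events(self) -> int:
        return self.n_biomarkers * self.n_waypoints

    @property
    def sigma_array(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.sigma, dtype=float), (len(self.biomarkers),)
        ).copy()

    def event_label(self, event_id: int) -> tuple[str, float]:
        b, j = divmod(int(event_id), self.n_waypoints)
        return self.biomarkers[b], self.waypoints[j]


@dataclass(frozen=True)
class EventSequence:
    """Ordered (biomarker, z-waypoint) events; position 1 is the first event.

    Each (biomarker, waypoint) pair appears exactly once and within a
    biomarker the waypoints appear in increasing order.
    """

    events: tuple[tuple[str, float], ...]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def validate(self, spec: ZScoreEventModelSpec) -> None:
        expected = {
            (b, w) for b in spec.biomarkers for w in spec.waypoints
        }
        if set(self.events) != expected or len(self.events) != len(expected):
            raise ValueError("sequence must contain each (biomarker, z) pair exactly once")
        last: dict[str, float] = {}
        for b, w in self.events:
            if b in last and w <= last[b]:
                raise ValueError(f"waypoints for {b!r} out of order")
            last[b] = w

    def to_order(self, spec: ZScoreEventModelSpec) -> np.ndarray:
        """Encode as an array of event ids, id = biomarker_index * W + waypoint_index."""
        self.validate(spec)
        bidx = {b: i for i, b in enumerate(spec.biomarkers)}
        widx = {w: j for j, w in enumerate(spec.waypoints)}
        return np.array(
            [bidx[b] * spec.n_waypoints + widx[w] for b, w in self.events], dtype=np.int64
        )

    @classmethod
    def from_order(cls, order: np.ndarray, spec: ZScoreEventModelSpec) -> "EventSequence":
        return cls(tuple(spec.event_label(e) for e in np.asarray(order)))


def is_valid_order(order: np.ndarray, spec: ZScoreEventModelSpec) -> bool:
    order = np.asarray(order)
    E = spec.n_events
    if order.shape != (E,) or not np.array_equal(np.sort(order), np.arange(E)):
        return False
    pos = np.empty(E, dtype=np.int64)
    pos[order] = np.arange(E)
    W = spec.n_waypoints
    for b in range(spec.n_biomarkers):
        p = pos[b * W : (b + 1) * W]
        if np.any(np.diff(p) <= 0):
            return False
    return True


def random_sequence(spec: ZScoreEventModelSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform random valid order: shuffle all events, then sort each
    biomarker's occupied slots by waypoint (uniform over linear extensions of
    a disjoint union of chains)."""
    order = rng.permutation(spec.n_events)
    return _canonicalize(order, spec)


def _canonicalize(order: np.ndarray, spec: ZScoreEventModelSpec) -> np.ndarray:
    out = np.asarray(order).copy()
    W = spec.n_waypoints
    b_of = out // W
    for b in range(spec.n_biomarkers):
        slots = np.where(b_of == b)[0]
        out[slots] = b * W + np.arange(len(slots))
    return out


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def stage_expectations_batch(orders: np.ndarray, spec: ZScoreEventModelSpec) -> np.ndarray:
    """Expected z-score curves for C sequences at once: (C, E+1, B).

    Piecewise-linear through (0, 0), each biomarker's waypoint positions, and
    (E, z_max); the terminal anchor is dropped when the biomarker's last
    waypoint sits at position E itself (implemented by pushing the anchor to
    E+1, outside the stage grid, so stage E evaluates to the last waypoint).
    """
    orders = np.atleast_2d(np.asarray(orders))
    C, E = orders.shape
    W, B = spec.n_waypoints, spec.n_biomarkers
    pos = np.argsort(orders, axis=1) + 1  # inverse permutation: position of event e
    p = pos.reshape(C, B, W).astype(float)
    xp = np.empty((C, B, W + 2))
    xp[..., 0] = 0.0
    xp[..., 1 : W + 1] = p
    xp[..., W + 1] = np.where(p[..., -1] >= E, E + 1.0, float(E))
    fp = np.concatenate(([0.0], spec.waypoints, [spec.z_max]))
    k = np.arange(E + 1, dtype=float)
    left = np.clip((xp[..., :, None] <= k).sum(axis=2) - 1, 0, W + 1)  # (C,B,E+1)
    right = np.minimum(left + 1, W + 1)
    x0 = np.take_along_axis(xp, left, axis=2)
    x1 = np.take_along_axis(xp, right, axis=2)
    f0, f1 = fp[left], fp[right]
    denom = np.where(x1 > x0, x1 - x0, 1.0)
    S = f0 + (k[None, None, :] - x0) * (f1 - f0) / denom
    return S.transpose(0, 2, 1)


def stage_expectations(order: np.ndarray, spec: ZScoreEventModelSpec) -> np.ndarray:
    """Expected z-score matrix S of shape (E+1, B): S[k, b] at stage k."""
    return stage_expectations_batch(np.asarray(order)[None, :], spec)[0]


def expected_value(
    seq: "EventSequence | np.ndarray",
    stage: int,
    biomarker: "str | int",
    spec: ZScoreEventModelSpec,
) -> float:
    """Expected z-score of one biomarker at one stage under a sequence."""
    if not 0 <= stage <= spec.n_events:
        raise ValueError(f"stage must be in 0..{spec.n_events}")
    order = seq.to_order(spec) if isinstance(seq, EventSequence) else np.asarray(seq)
    if not is_valid_order(order, spec):
        raise ValueError("invalid event sequence")
    b = spec.biomarkers.index(biomarker) if isinstance(biomarker, str) else int(biomarker)
    return float(stage_expectations(order, spec)[stage, b])


class _DataCache:
    """Per-dataset precomputations for fast repeated likelihood evaluation."""

    def __init__(self, X: np.ndarray, spec: ZScoreEventModelSpec):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != spec.n_biomarkers:
            raise ValueError(
                f"data must be (n, {spec.n_biomarkers}); got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("data contains non-finite values")
        self.spec = spec
        self.X = X
        self.n = X.shape[0]
        sig = spec.sigma_array
        self.inv_var = 1.0 / sig**2
        self.Xw = X * self.inv_var  # X / sigma^2
        self.q = np.einsum("nb,nb->n", X, self.Xw)  # sum_b (x/sigma)^2
        self.Xw32 = self.Xw.astype(np.float32)
        self.log_norm = -0.5 * spec.n_biomarkers * math.log(2 * math.pi) - float(
            np.sum(np.log(sig))
        )
        self.log_stage_prior = -math.log(spec.n_events + 1)

    def stage_logdensity(self, S: np.ndarray) -> np.ndarray:
        """(n, E+1) matrix of log p(x_n | stage k) for one sequence."""
        s2 = np.einsum("kb,kb,b->k", S, S, self.inv_var)
        return self.log_norm - 0.5 * (
            self.q[:, None] - 2.0 * self.Xw @ S.T + s2[None, :]
        )

    def marginal(self, order: np.ndarray) -> np.ndarray:
        """(n,) stage-marginal log-likelihood under one sequence."""
        ll = self.stage_logdensity(stage_expectations(order, self.spec))
        mx = ll.max(axis=1)
        np.exp(ll - mx[:, None], out=ll)
        return np.log(ll.sum(axis=1)) + mx + self.log_stage_prior

    def marginal_batch(self, orders: "list[np.ndarray] | np.ndarray") -> np.ndarray:
        """(C, n) stage-marginal log-likelihoods for many candidate sequences."""
        spec = self.spec
        orders = np.asarray(orders)
        C = orders.shape[0]
        K1 = spec.n_events + 1
        S = stage_expectations_batch(orders, spec)  # (C, E+1, B)
        s2 = np.einsum("ckb,ckb,b->ck", S, S, self.inv_var)
        A = self.Xw @ S.reshape(C * K1, -1).T  # (n, C*(E+1))
        ll = self.log_norm - 0.5 * (
            self.q[:, None, None]
            - 2.0 * A.reshape(self.n, C, K1)
            + s2[None, :, :]
        )
        mx = ll.max(axis=2)
        np.exp(ll - mx[..., None], out=ll)
        return (np.log(ll.sum(axis=2)) + mx).T + self.log_stage_prior

    def wll_screen(self, orders: np.ndarray, w: np.ndarray | None) -> np.ndarray:
        """Fast float32 weighted stage-marginal log-likelihood per candidate,
        up to a candidate-independent constant — only for ranking moves; the
        chosen move is re-scored in float64 before acceptance."""
        spec = self.spec
        orders = np.asarray(orders)
        C = orders.shape[0]
        K1 = spec.n_events + 1
        S = stage_expectations_batch(orders, spec).astype(np.float32)
        Sw = S * self.inv_var.astype(np.float32)[None, None, :]
        s2 = np.einsum("ckb,ckb->ck", S, Sw, dtype=np.float32)
        A = self.Xw32 @ S.reshape(C * K1, -1).T.astype(np.float32)
        ll = A.reshape(self.n, C, K1) - 0.5 * s2[None, :, :]
        mx = ll.max(axis=2)
        np.exp(ll - mx[..., None], out=ll)
        marg = np.log(ll.sum(axis=2)) + mx  # (n, C)
        if w is None:
            return marg.sum(axis=0)
        return w.astype(np.float32) @ marg


def subject_loglik(
    z_row: np.ndarray,
    seq: "EventSequence | np.ndarray",
    spec: ZScoreEventModelSpec,
) -> "float | np.ndarray":
    """Stage-marginal log-likelihood of one subject (or an (n, B) table).

    log (1/(E+1)) * sum_k prod_b Normal(z_b; expected_value(seq, k, b), sigma_b^2),
    evaluated in log space.
    """
    Z = np.atleast_2d(np.asarray(z_row, dtype=float))
    order = seq.to_order(spec) if isinstance(seq, EventSequence) else np.asarray(seq)
    if not is_valid_order(order, spec):
        raise ValueError("invalid event sequence")
    out = _DataCache(Z, spec).marginal(order)
    return float(out[0]) if np.ndim(z_row) == 1 else out


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class SubtypeModel:
    """Fitted K-subtype model: sequences, mixture fractions, diagnostics."""

    spec: ZScoreEventModelSpec
    orders: list[np.ndarray]
    fractions: np.ndarray
    log_likelihood: float = float("-inf")
    mcmc_orders: np.ndarray | None = None  # (n_iter, K, E) int16
    mcmc_loglik: np.ndarray | None = None  # (n_iter,)
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.orders),):
            raise ValueError("one mixture fraction per subtype required")
        if np.any(self.fractions < 0) or abs(self.fractions.sum() - 1.0) > 1e-8:
            raise ValueError("fractions must be in [0,1] and sum to 1")
        for o in self.orders:
            if not is_valid_order(o, self.spec):
                raise ValueError("invalid subtype sequence")

    @property
    def n_subtypes(self) -> int:
        return len(self.orders)

    @property
    def sequences(self) -> list[EventSequence]:
        return [EventSequence.from_order(o, self.spec) for o in self.orders]

    def to_dict(self) -> dict:
        return {
            "biomarkers": list(self.spec.biomarkers),
            "waypoints": list(self.spec.waypoints),
            "z_max": self.spec.z_max,
            "sigma": list(self.spec.sigma_array),
            "sequences": [
                [[b, z] for b, z in seq.events] for seq in self.sequences
            ],
            "fractions": self.fractions.tolist(),
            "log_likelihood": self.log_likelihood,
            "settings": self.settings,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeModel":
        spec = ZScoreEventModelSpec(
            biomarkers=tuple(d["biomarkers"]),
            waypoints=tuple(d["waypoints"]),
            z_max=d["z_max"],
            sigma=tuple(d["sigma"]),
        )
        orders = [
            EventSequence(tuple((b, float(z)) for b, z in seq)).to_order(spec)
            for seq in d["sequences"]
        ]
        return cls(
            spec=spec,
            orders=orders,
            fractions=np.asarray(d["fractions"]),
            log_likelihood=d.get("log_likelihood", float("-inf")),
            settings=d.get("settings", {}),
        )


@dataclass
class SubjectAssignment:
    """Per-subject subtype probabilities, hard labels and ML stages."""

    proba: np.ndarray  # (n, K)
    labels: np.ndarray  # (n,) argmax subtype, ties -> lower index
    stages: np.ndarray  # (n,) ML stage within hard subtype, ties -> lower stage
    stage_posterior: np.ndarray  # (n, E+1) within hard subtype

    def to_frame(self, index=None):
        import pandas as pd

        K = self.proba.shape[1]
        df = pd.DataFrame(
            {f"p_subtype{c + 1}": self.proba[:, c] for c in range(K)}, index=index
        )
        df["subtype"] = self.labels
        df["stage"] = self.stages
        return df


@dataclass(frozen=True)
class FitSettings:
    """Inference effort knobs.

    Defaults are the reduced test-scale settings (5 starts, 10,000 MCMC
    iterations); :meth:`full_scale` returns the 25 / 100,000 settings.
    """

    n_starts: int = 5
    n_mcmc: int = 10_000
    em_max_iter: int = 15
    em_tol: float = 1e-4
    greedy_max_sweeps: int = 8
    split_restarts: int = 10
    split_em_iter: int = 5

    @classmethod
    def full_scale(cls) -> "FitSettings":
        return cls(n_starts=25, n_mcmc=100_000)

    def scaled(self, **kw) -> "FitSettings":
        return replace(self, **kw)


def mixture_loglik(
    data: np.ndarray, model: SubtypeModel, spec: ZScoreEventModelSpec | None = None
) -> float:
    """Total log-likelihood: sum_n log sum_c f_c exp(subject_loglik(x_n, seq_c))."""
    spec = spec or model.spec
    cache = _DataCache(np.asarray(data, dtype=float), spec)
    M = np.column_stack([cache.marginal(o) for o in model.orders])
    return _mixture_from_marginals(M, model.fractions)


def _mixture_from_marginals(M: np.ndarray, fractions: np.ndarray) -> float:
    logf = np.log(np.maximum(fractions, 1e-300))
    return float(np.sum(logsumexp(M + logf[None, :], axis=1)))


# ---------------------------------------------------------------------------
# Greedy sequence optimisation and EM
# ---------------------------------------------------------------------------


def _insertion_window(rest_order: np.ndarray, event: int, spec: ZScoreEventModelSpec):
    """Inclusive range [lo, hi] of valid insertion indices for `event` into
    `rest_order` (the sequence with `event` removed), preserving the
    within-biomarker waypoint order."""
    W = spec.n_waypoints
    b, j = divmod(int(event), W)
    lo = 0
    hi = len(rest_order)
    if j > 0:
        lo = int(np.where(rest_order == b * W + (j - 1))[0][0]) + 1
    if j < W - 1:
        hi = int(np.where(rest_order == b * W + (j + 1))[0][0])
    return lo, hi


def _greedy_optimize(
    cache: _DataCache,
    order: np.ndarray,
    weights: np.ndarray | None,
    rng: np.random.Generator,
    max_sweeps: int = 8,
) -> tuple[np.ndarray, float]:
    """Repeated single-event repositioning; each event is moved to its best
    insertion slot (candidates ranked by a float32 screen, the winner
    re-scored in float64) until a full sweep produces no improvement."""
    spec = cache.spec
    w = None if weights is None else np.asarray(weights, dtype=float)
    order = np.asarray(order).copy()

    def score(o: np.ndarray) -> float:
        marg = cache.marginal(o)
        return float(marg.sum() if w is None else w @ marg)

    best = score(order)
    for _ in range(max_sweeps):
        improved = False
        for e in rng.permutation(spec.n_events):
            i = int(np.where(order == e)[0][0])
            rest = np.delete(order, i)
            lo, hi = _insertion_window(rest, e, spec)
            if hi - lo < 1:
                continue
            cands = np.stack([np.insert(rest, p, e) for p in range(lo, hi + 1)])
            k = int(np.argmax(cache.wll_screen(cands, w)))
            if np.array_equal(cands[k], order):
                continue
            cand_score = score(cands[k])
            if cand_score > best + 1e-9:
                order = cands[k]
                best = cand_score
                improved = True
        if not improved:
            break
    return order, best


def _estep(
    cache: _DataCache, orders: list[np.ndarray], fractions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Responsibilities, per-subtype marginals, and total log-likelihood."""
    M = np.column_stack([cache.marginal(o) for o in orders])
    logf = np.log(np.maximum(fractions, 1e-300))
    A = M + logf[None, :]
    norm = logsumexp(A, axis=1)
    R = np.exp(A - norm[:, None])
    return R, M, float(norm.sum())


def _em(
    cache: _DataCache,
    orders: list[np.ndarray],
    fractions: np.ndarray,
    rng: np.random.Generator,
    settings: FitSettings,
    max_iter: int | None = None,
    active: "list[int] | None" = None,
) -> tuple[list[np.ndarray], np.ndarray, float]:
    orders = [np.asarray(o).copy() for o in orders]
    fractions = np.asarray(fractions, dtype=float).copy()
    max_iter = settings.em_max_iter if max_iter is None else max_iter
    if len(orders) == 1:
        # responsibilities are constant; EM reduces to sequence optimisation
        orders[0], ll = _greedy_optimize(
            cache, orders[0], None, rng, settings.greedy_max_sweeps
        )
        return orders, fractions, ll + cache.n * 0.0
    prev = -np.inf
    ll = prev
    # few greedy sweeps per EM iteration: sequences and responsibilities
    # co-evolve, the outer loop provides convergence
    inner = min(2, settings.greedy_max_sweeps)
    for _ in range(max_iter):
        R, _, ll = _estep(cache, orders, fractions)
        fractions = R.mean(axis=0)
        fractions = np.maximum(fractions, 1e-12)
        fractions /= fractions.sum()
        for c in range(len(orders)) if active is None else active:
            orders[c], _ = _greedy_optimize(cache, orders[c], R[:, c], rng, inner)
        if ll - prev < settings.em_tol and np.isfinite(prev):
            break
        prev = ll
    _, _, ll = _estep(cache, orders, fractions)
    return orders, fractions, ll


def optimize_sequences_em(
    data: np.ndarray,
    K: int,
    spec: ZScoreEventModelSpec,
    n_starts: int = 5,
    seed: "int | np.random.Generator" = 0,
    settings: FitSettings | None = None,
) -> SubtypeModel:
    """Best-of-`n_starts` EM fit of a K-subtype model from random sequences."""
    settings = settings or FitSettings(n_starts=n_starts)
    cache = _DataCache(np.asarray(data, dtype=float), spec)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > cache.n:
        raise ValueError("K cannot exceed the number of subjects")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    best: tuple[float, list[np.ndarray], np.ndarray] | None = None
    for _ in range(n_starts):
        orders = [random_sequence(spec, rng) for _ in range(K)]
        fractions = np.full(K, 1.0 / K)
        orders, fractions, ll = _em(cache, orders, fractions, rng, settings)
        if best is None or ll > best[0]:
            best = (ll, orders, fractions)
    ll, orders, fractions = best
    return SubtypeModel(
        spec=spec,
        orders=orders,
        fractions=fractions,
        log_likelihood=ll,
        settings={"n_starts": n_starts, "K": K},
    )


# ---------------------------------------------------------------------------
# MCMC over event orderings
# ---------------------------------------------------------------------------


def mcmc_sequences(
    data: np.ndarray,
    model: SubtypeModel,
    spec: ZScoreEventModelSpec | None = None,
    n_iter: int = 10_000,
    seed: "int | np.random.Generator" = 0,
) -> SubtypeModel:
    """Metropolis-Hastings over sequences: remove one event of one subtype and
    reinsert it uniformly among order-preserving positions; accept with
    min(1, exp(delta log-likelihood)).  Returns a refined model whose
    sequences are the maximum-likelihood archive sample and whose archive is
    retained for assignment averaging."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    spec = spec or model.spec
    cache = _DataCache(np.asarray(data, dtype=float), spec)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    K = model.n_subtypes
    E = spec.n_events
    orders = [np.asarray(o).copy() for o in model.orders]
    M = np.column_stack([cache.marginal(o) for o in orders])
    logf = np.log(np.maximum(model.fractions, 1e-300))
    cur_ll = float(np.sum(logsumexp(M + logf[None, :], axis=1)))

    arch_orders = np.empty((n_iter, K, E), dtype=np.int16)
    arch_ll = np.empty(n_iter, dtype=float)
    for t in range(n_iter):
        c = int(rng.integers(K))
        e = int(rng.integers(E))
        i = int(np.where(orders[c] == e)[0][0])
        rest = np.delete(orders[c], i)
        lo, hi = _insertion_window(rest, e, spec)
        p = int(rng.integers(lo, hi + 1))
        prop = np.insert(rest, p, e)
        m_new = cache.marginal(prop)
        M_prop = M.copy()
        M_prop[:, c] = m_new
        new_ll = float(np.sum(logsumexp(M_prop + logf[None, :], axis=1)))
        if new_ll >= cur_ll or math.log(rng.random()) < new_ll - cur_ll:
            orders[c] = prop
            M = M_prop
            cur_ll = new_ll
        for k in range(K):
            arch_orders[t, k] = orders[k]
        arch_ll[t] = cur_ll

    ml = int(np.argmax(arch_ll))
    ml_orders = [arch_orders[ml, k].astype(np.int64) for k in range(K)]
    R, _, _ = _estep(cache, ml_orders, model.fractions)
    fractions = R.mean(axis=0)
    fractions = np.maximum(fractions, 1e-12)
    fractions /= fractions.sum()
    _, _, ll = _estep(cache, ml_orders, fractions)
    return SubtypeModel(
        spec=spec,
        orders=ml_orders,
        fractions=fractions,
        log_likelihood=ll,
        mcmc_orders=arch_orders,
        mcmc_loglik=arch_ll,
        settings={**model.settings, "n_mcmc": n_iter},
    )


# ---------------------------------------------------------------------------
# Hierarchical fit
# ---------------------------------------------------------------------------


def _profile_partition(Xm: np.ndarray, rng: np.random.Generator) -> np.ndarray | None:
    """Shape-based split seed: 2-means on unit-norm z-profiles.

    Normalising each subject's deviation vector removes the severity (stage)
    axis, so the clustering keys on *which* regions are affected — the signal
    that distinguishes subtypes.  Used as the first split candidate alongside
    the random binary partitions."""
    if len(Xm) < 4:
        return None
    from sklearn.cluster import KMeans

    norms = np.linalg.norm(Xm, axis=1)
    P = Xm / np.maximum(norms, 1e-9)[:, None]
    km = KMeans(n_clusters=2, n_init=4, random_state=int(rng.integers(2**31)))
    return km.fit_predict(P) == 0


def fit(
    data: np.ndarray,
    K: int,
    spec: ZScoreEventModelSpec,
    settings: FitSettings | None = None,
    seed: "int | np.random.Generator" = 0,
    return_levels: bool = False,
):
    """Hierarchical fit: EM at K=1; each further level splits the subtype
    whose two-way split (random binary partition, one sequence fitted per
    half) yields the best full-data likelihood after EM refinement, then
    refines the new level with EM and MCMC."""
    settings = settings or FitSettings()
    X = np.asarray(data, dtype=float)
    cache = _DataCache(X, spec)
    if not 1 <= K <= cache.n:
        raise ValueError("K must be in 1..n_subjects")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def _refine(orders, fractions, tag):
        orders, fractions, ll = _em(cache, orders, fractions, rng, settings)
        model = SubtypeModel(
            spec=spec,
            orders=orders,
            fractions=fractions,
            log_likelihood=ll,
            settings={"K": len(orders), "stage": tag, **settings.__dict__},
        )
        if settings.n_mcmc > 0:
            model = mcmc_sequences(X, model, spec, settings.n_mcmc, rng)
        return model

    levels: dict[int, SubtypeModel] = {}
    m1 = optimize_sequences_em(X, 1, spec, settings.n_starts, rng, settings)
    if settings.n_mcmc > 0:
        m1 = mcmc_sequences(X, m1, spec, settings.n_mcmc, rng)
    levels[1] = m1

    for C in range(2, K + 1):
        parent = levels[C - 1]
        R, _, _ = _estep(cache, parent.orders, parent.fractions)
        labels = np.argmax(R, axis=1)
        best: tuple[float, list[np.ndarray], np.ndarray] | None = None
        for c in range(C - 1):
            members = np.where(labels == c)[0]
            if len(members) < 4:
                continue
            partitions = [_profile_partition(X[members], rng)]
            for _ in range(settings.split_restarts):
                for _try in range(20):
                    half = rng.random(len(members)) < 0.5
                    if 2 <= half.sum() <= len(members) - 2:
                        break
                partitions.append(half)
            for half in partitions:
                if half is None or not 2 <= half.sum() <= len(members) - 2:
                    continue
                new_orders = []
                for sel in (half, ~half):
                    sub = _DataCache(X[members[sel]], spec)
                    o, _ = _greedy_optimize(
                        sub, random_sequence(spec, rng), None, rng, max_sweeps=3
                    )
                    new_orders.append(o)
                orders = [parent.orders[k] for k in range(C - 1) if k != c] + new_orders
                f_par = parent.fractions
                fractions = np.concatenate(
                    (
                        [f_par[k] for k in range(C - 1) if k != c],
                        f_par[c] * np.array(
                            [half.mean(), 1 - half.mean()]
                        ),
                    )
                )
                fractions = np.maximum(fractions, 1e-12)
                fractions /= fractions.sum()
                # candidate ranking: short EM touching only the two children;
                # the winning split is refined over all subtypes below
                orders, fractions, ll = _em(
                    cache, orders, fractions, rng, settings,
                    max_iter=settings.split_em_iter,
                    active=[C - 2, C - 1],
                )
                if best is None or ll > best[0]:
                    best = (ll, orders, fractions)
        if best is None:
            raise RuntimeError(f"no subtype large enough to split at K={C}")
        _, orders, fractions = best
        levels[C] = _refine(orders, fractions, f"level{C}")

    return levels if return_levels else levels[K]


# ---------------------------------------------------------------------------
# Subject assignment
# ---------------------------------------------------------------------------


def assign(
    data: np.ndarray,
    model: SubtypeModel,
    spec: ZScoreEventModelSpec | None = None,
    archive_max: int = 50,
) -> SubjectAssignment:
    """Subtype probabilities (averaged over a thinned MCMC archive when one is
    available), hard labels, and the maximum-likelihood stage within the hard
    subtype.  Ties resolve toward the lower index / lower stage."""
    spec = spec or model.spec
    if not np.isfinite(model.log_likelihood):
        raise ValueError("model has not been fitted")
    cache = _DataCache(np.asarray(data, dtype=float), spec)
    logf = np.log(np.maximum(model.fractions, 1e-300))
    K = model.n_subtypes

    if model.mcmc_orders is not None and len(model.mcmc_orders) > 0:
        n_samp = len(model.mcmc_orders)
        take = np.unique(
            np.linspace(0, n_samp - 1, min(archive_max, n_samp)).astype(int)
        )
        proba = np.zeros((cache.n, K))
        for t in take:
            M = np.column_stack(
                [cache.marginal(model.mcmc_orders[t, k].astype(np.int64)) for k in range(K)]
            )
            A = M + logf[None, :]
            proba += np.exp(A - logsumexp(A, axis=1)[:, None])
        proba /= len(take)
    else:
        M = np.column_stack([cache.marginal(o) for o in model.orders])
        A = M + logf[None, :]
        proba = np.exp(A - logsumexp(A, axis=1)[:, None])

    labels = np.argmax(proba, axis=1)  # first max -> lower index

    post = np.empty((cache.n, spec.n_events + 1))
    for c in range(K):
        rows = labels == c
        if not rows.any():
            continue
        ld = cache.stage_logdensity(stage_expectations(model.orders[c], spec))[rows]
        post[rows] = np.exp(ld - logsumexp(ld, axis=1)[:, None])
    stages = np.argmax(post, axis=1)
    return SubjectAssignment(
        proba=proba, labels=labels, stages=stages, stage_posterior=post
    )
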