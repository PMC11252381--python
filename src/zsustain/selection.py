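"""Clustering tendency and choice of the number of subtypes.

The number of subtypes K is chosen by cross-validated label consistency:
patients are split into two folds, a model is fitted on each fold, both
models label every patient, and the agreement of the two labelings (after
optimal label matching) is summarised by the Dice coefficient.  The Hopkins
statistic answers the prior question of whether the data cluster at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import beta
from sklearn.neighbors import NearestNeighbors

from .model import FitSettings, ZScoreEventModelSpec, assign, fit

__all__ = [
    "HopkinsResult",
    "DiceCurve",
    "hopkins",
    "match_labels",
    "dice_consistency",
    "select_K",
]


@dataclass(frozen=True)
class HopkinsResult:
    """Hopkins clustering-tendency statistic with a Beta(m, m) verdict.

    H near 0.5 indicates spatially uniform data; H toward 1 indicates
    clustering. ``clustered`` is true when H exceeds the upper quantile of
    the Beta(m, m) null at the stated one-sided confidence level.
    """

    H: float
    m: int
    confidence_level: float
    clustered: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.H < 1.0:
            raise ValueError("H must lie strictly between 0 and 1")


def hopkins(
    data: np.ndarray,
    m: int | None = None,
    seed: "int | np.random.Generator" = 0,
    confidence_level: float = 0.90,
) -> HopkinsResult:
    """Hopkins statistic H = sum(u) / (sum(u) + sum(w)).

    u: nearest-real-neighbour distances of m uniform probe points over the
    data's bounding box; w: nearest-other-real-neighbour distances of m
    sampled real points (excluded from their own search).
    """
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("hopkins needs at least 10 points")
    if m is None:
        m = max(1, int(0.1 * n))
    if m >= n:
        raise ValueError("m must be smaller than the number of points")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    lo, hi = X.min(axis=0), X.max(axis=0)
    probes = rng.uniform(lo, hi, size=(m, X.shape[1]))
    sample_idx = rng.choice(n, size=m, replace=False)

    nn = NearestNeighbors(n_neighbors=2).fit(X)
    u = nn.kneighbors(probes, n_neighbors=1)[0][:, 0]
    w = nn.kneighbors(X[sample_idx], n_neighbors=2)[0][:, 1]  # skip self

    H = float(u.sum() / (u.sum() + w.sum()))
    crit = beta(m, m).ppf(confidence_level)
    return HopkinsResult(H=H, m=m, confidence_level=confidence_level, clustered=H > crit)


def match_labels(labels_a: np.ndarray, labels_b: np.ndarray, K: int) -> np.ndarray:
    """Permutation ``perm`` (indices 0..K-1) maximizing agreement of
    ``perm[labels_b]`` with ``labels_a``, via optimal assignment over the
    K x K contingency table."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same subjects")
    for lab in (a, b):
        if lab.min() < 0 or lab.max() >= K:
            raise ValueError(f"labels must lie in 0..{K - 1}")
    C = np.zeros((K, K), dtype=np.int64)
    np.add.at(C, (a, b), 1)
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(K, dtype=np.int64)
    perm[cols] = rows
    return perm


@dataclass
class DiceResult:
    overall: float
    per_subtype: np.ndarray  # NaN for a subtype empty in both labelings
    transitions: np.ndarray  # (K, K) fraction of subjects moving a=c -> b=c'
    permutation: np.ndarray


def dice_consistency(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    K: int,
    match: bool = True,
) -> DiceResult:
    """Per-subtype Dice 2|A_c & B_c| / (|A_c| + |B_c|) after optimal label
    matching; overall value is the subject-weighted mean, which equals the
    fraction of subjects with consistent labels."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    perm = match_labels(a, b, K) if match else np.arange(K)
    b = perm[b]
    per = np.full(K, np.nan)
    num = 0.0
    den = 0.0
    for c in range(K):
        na, nb = int((a == c).sum()), int((b == c).sum())
        inter = int(((a == c) & (b == c)).sum())
        if na + nb == 0:
            warnings.warn(f"subtype {c} empty in both labelings; Dice undefined")
            continue
        per[c] = 2.0 * inter / (na + nb)
        num += 2.0 * inter
        den += na + nb
    trans = np.zeros((K, K))
    np.add.at(trans, (a, b), 1.0)
    trans /= len(a)
    return DiceResult(
        overall=num / den, per_subtype=per, transitions=trans, permutation=perm
    )


@dataclass
class DiceCurve:
    """Cross-validated Dice values per candidate K and the chosen K."""

    k_values: list[int]
    dice: dict  # K -> list of per-repeat Dice values
    median: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    chosen_k: int = 0

    def finalize(self) -> "DiceCurve":
        self.median = {k: float(np.median(v)) for k, v in self.dice.items() if v}
        self.sd = {k: float(np.std(v)) for k, v in self.dice.items() if v}
        # argmax of the median; ties resolve toward the smaller K
        best = max(self.median.values())
        self.chosen_k = min(k for k, m in self.median.items() if m >= best - 1e-12)
        return self

    def to_dict(self) -> dict:
        return {
            "k_values": self.k_values,
            "dice": {str(k): v for k, v in self.dice.items()},
            "median": {str(k): v for k, v in self.median.items()},
            "sd": {str(k): v for k, v in self.sd.items()},
            "chosen_k": self.chosen_k,
        }


def select_K(
    data: np.ndarray,
    spec: ZScoreEventModelSpec,
    k_range: "tuple[int, ...] | range" = range(2, 7),
    n_repeats: int = 10,
    settings: FitSettings | None = None,
    seed: int = 0,
    holdout_only: bool = False,
) -> DiceCurve:
    """Two-fold cross-validated Dice consistency over candidate K.

    Per repeat: random half-split of the subjects; one hierarchical model per
    fold fitted up to max(k_range) (per-level models are read off the same
    hierarchical fit); each fold model labels all subjects (or only the
    held-out fold with ``holdout_only=True``); Dice after label matching.
    K = 1 is excluded — its Dice is trivially 1 and the Hopkins statistic
    carries the "is there any clustering" question.
    """
    X = np.asarray(data, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if min(ks) < 2:
        raise ValueError("k_range must start at 2; K=1 is excluded from the Dice criterion")
    settings = settings or FitSettings()
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    curve = DiceCurve(k_values=ks, dice={k: [] for k in ks})
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        folds = (perm[: n // 2], perm[n // 2 :])
        if min(len(f) for f in folds) < max(ks):
            warnings.warn(f"repeat {rep}: folds too small for K={max(ks)}; skipped")
            continue
        try:
            models = [
                fit(X[f], max(ks), spec, settings, seed=rng, return_levels=True)
                for f in folds
            ]
        except RuntimeError as err:
            warnings.warn(f"repeat {rep}: {err}; skipped")
            continue
        for k in ks:
            if holdout_only:
                # each model labels the fold it did NOT see; agreement is
                # measured on the union of held-out labelings
                la = assign(X[folds[1]], models[0][k]).labels
                lb = assign(X[folds[1]], models[1][k]).labels
            else:
                la = assign(X, models[0][k]).labels
                lb = assign(X, models[1][k]).labels
            curve.dice[k].append(dice_consistency(la, lb, k).overall)
    return curve.finalize()
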