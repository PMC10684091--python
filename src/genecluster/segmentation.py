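"""Window-free model-averaged clustering profiles of 0/1 label vectors.

The label sequence is partitioned into contiguous segments; each segment
carries an independent Bernoulli rate estimated at its MLE k/m.  Every
partition into at most ``max_segments`` parts is a model, scored by an
information criterion (AIC, AICc or BIC) with 2s-1 free parameters for s
segments (s rates + s-1 breakpoints), and models are combined with weights
proportional to exp(-(IC - IC_min)/2).  The per-position model-averaged
rate and a 95% model-uncertainty envelope (weighted 2.5%/97.5% quantiles of
per-position rates over the model distribution) form the profile.

Two routes produce identical profiles on their shared model space:

* :func:`model_average` — exhaustive enumeration of all 2^(n-1) partitions,
  feasible for n <= 20; the testing oracle.
* :func:`dp_model_average` — exact dynamic programming over (position,
  segment count) with log-sum-exp accumulation, scaling to chromosome-length
  vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.special import logsumexp, xlogy

__all__ = [
    "SegmentationModel",
    "ClusterProfile",
    "segment_loglik",
    "enumerate_models",
    "model_average",
    "dp_model_average",
]

CRITERIA = ("AIC", "AICc", "BIC")

#: Models with IC - IC_min above this are pruned in the exhaustive route;
#: each pruned model has relative weight < e^-50, so the pruned mass is
#: far below the 1e-8 bookkeeping bound even for millions of models.
PRUNE_DELTA = 100.0

MAX_EXHAUSTIVE_N = 20


@dataclass
class SegmentationModel:
    """One partition of positions 0..n-1 into contiguous segments."""

    breakpoints: tuple[int, ...]  # interior cut positions, ascending, in (0, n)
    segment_rates: tuple[float, ...]
    log_likelihood: float
    ic_value: float
    weight: float = 0.0

    @property
    def n_segments(self) -> int:
        return len(self.segment_rates)


@dataclass
class ClusterProfile:
    rate: np.ndarray  # per-position model-averaged label rate
    lower95: np.ndarray
    upper95: np.ndarray
    criterion: str
    model_count: int
    max_segments: int

    def __len__(self) -> int:
        return len(self.rate)


def segment_loglik(k: int, m: int) -> float:
    """Bernoulli segment log-likelihood at the MLE rate k/m, 0*ln 0 == 0."""
    if m < 1:
        raise ValueError(f"segment length must be >= 1, got {m}")
    if not 0 <= k <= m:
        raise ValueError(f"need 0 <= k <= m, got k={k}, m={m}")
    r = k / m
    return float(xlogy(k, r) + xlogy(m - k, 1.0 - r))


def _penalty(s: int, n: int, criterion: str) -> float:
    """IC penalty term for a model with s segments on n positions."""
    kappa = 2 * s - 1
    if criterion == "BIC":
        return kappa * math.log(n)
    if criterion == "AIC":
        return 2.0 * kappa
    if criterion == "AICc":
        if n - kappa - 1 <= 0:
            return math.inf
        return 2.0 * kappa + 2.0 * kappa * (kappa + 1) / (n - kappa - 1)
    raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")


def _compositions(n: int, max_parts: int) -> Iterator[tuple[int, ...]]:
    """All compositions of n into at most max_parts positive parts."""

    def rec(remaining: int, parts_left: int, prefix: tuple[int, ...]):
        if remaining == 0:
            yield prefix
            return
        if parts_left == 0:
            return
        for first in range(1, remaining + 1):
            yield from rec(remaining - first, parts_left - 1, prefix + (first,))

    yield from rec(n, max_parts, ())


def enumerate_models(
    labels: Sequence[int],
    max_segments: int | None = None,
    criterion: str = "BIC",
) -> list[SegmentationModel]:
    """All partition models of the label vector, with likelihoods and ICs.

    Exhaustive: one model per composition of n into <= max_segments parts
    (2^(n-1) in total when unrestricted), so n is capped at 20; longer
    vectors must go through :func:`dp_model_average`.
    """
    x = np.asarray(labels, dtype=np.int64)
    n = len(x)
    if n < 1:
        raise ValueError("labels must be non-empty")
    if n > MAX_EXHAUSTIVE_N:
        raise ValueError(
            f"n={n} is too large for exhaustive enumeration (2^(n-1) models); "
            "use dp_model_average instead"
        )
    if max_segments is None:
        max_segments = n
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")
    prefix = np.concatenate([[0], np.cumsum(x)])
    models = []
    for comp in _compositions(n, max_segments):
        bounds = np.cumsum(comp)
        rates, ll = [], 0.0
        a = 0
        for b in bounds:
            k, m = int(prefix[b] - prefix[a]), int(b - a)
            rates.append(k / m)
            ll += segment_loglik(k, m)
            a = b
        s = len(comp)
        ic = -2.0 * ll + _penalty(s, n, criterion)
        models.append(
            SegmentationModel(
                breakpoints=tuple(int(b) for b in bounds[:-1]),
                segment_rates=tuple(rates),
                log_likelihood=ll,
                ic_value=ic,
            )
        )
    return models


def _weighted_quantiles(
    values: np.ndarray, weights: np.ndarray, qs=(0.025, 0.975)
) -> list[float]:
    """Quantiles of a discrete weighted distribution: smallest value whose
    cumulative weight reaches q."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    total = cum[-1]
    out = []
    for q in qs:
        idx = int(np.searchsorted(cum, q * total - 1e-12, side="left"))
        out.append(float(v[min(idx, len(v) - 1)]))
    return out


def model_average(
    labels: Sequence[int],
    criterion: str = "BIC",
    max_segments: int | None = None,
    prune_delta: float = PRUNE_DELTA,
) -> ClusterProfile:
    """Exhaustively enumerated model-averaged profile with 95% envelope."""
    x = np.asarray(labels, dtype=np.int64)
    n = len(x)
    models = enumerate_models(x, max_segments=max_segments, criterion=criterion)
    ics = np.array([m.ic_value for m in models])
    ic_min = ics.min()
    raw = np.exp(-(ics - ic_min) / 2.0)
    weights = raw / raw.sum()
    keep = (ics - ic_min) <= prune_delta
    pruned_mass = float(weights[~keep].sum())
    assert pruned_mass < 1e-8, f"pruned model mass {pruned_mass} exceeds bound"
    models = [m for m, k in zip(models, keep) if k]
    weights = weights[keep]
    weights = weights / weights.sum()
    for m, w in zip(models, weights):
        m.weight = float(w)

    # per-position rate matrix (models x positions)
    rates = np.empty((len(models), n))
    for i, m in enumerate(models):
        bounds = list(m.breakpoints) + [n]
        a = 0
        for r, b in zip(m.segment_rates, bounds):
            rates[i, a:b] = r
            a = b
    mean = weights @ rates
    lower = np.empty(n)
    upper = np.empty(n)
    for j in range(n):
        lower[j], upper[j] = _weighted_quantiles(rates[:, j], weights)
    # the envelope must bracket the average of a discrete weighted
    # distribution, which raw quantiles need not do in extreme-skew cases
    lower = np.minimum(lower, mean)
    upper = np.maximum(upper, mean)
    return ClusterProfile(
        rate=mean,
        lower95=lower,
        upper95=upper,
        criterion=criterion,
        model_count=len(models),
        max_segments=max_segments if max_segments is not None else n,
    )


# ---------------------------------------------------------------------------
# Dynamic-programming route


def _loglik_matrix(x: np.ndarray) -> np.ndarray:
    """LL[a, b] = Bernoulli MLE log-likelihood of segment [a, b), -inf if b<=a."""
    n = len(x)
    prefix = np.concatenate([[0], np.cumsum(x)]).astype(float)
    K = prefix[None, :] - prefix[:, None]  # labels in [a, b)
    M = np.arange(n + 1)[None, :] - np.arange(n + 1)[:, None].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(M > 0, K / np.where(M > 0, M, 1.0), 0.0)
        LL = xlogy(K, R) + xlogy(M - K, 1.0 - R)
    LL = np.where(M > 0, LL, -np.inf)
    return LL


def dp_model_average(
    labels: Sequence[int],
    criterion: str = "BIC",
    max_segments: int = 30,
    n_bins: int = 2048,
    exact_quantile_max_n: int = 64,
) -> ClusterProfile:
    """Model-averaged profile over all partitions with <= max_segments parts,
    computed exactly by dynamic programming (no pruning).

    Identical in contract to :func:`model_average` restricted to the same
    model space.  Per-position means are exact; the 95% envelope is exact for
    n <= ``exact_quantile_max_n`` and is otherwise computed on a rate
    histogram with ``n_bins`` bins (quantile values then carry a
    discretization error of at most 1/(n_bins - 1)).
    """
    if max_segments < 1:
        raise ValueError(f"max_segments must be >= 1, got {max_segments}")
    x = np.asarray(labels, dtype=np.int64)
    n = len(x)
    if n < 1:
        raise ValueError("labels must be non-empty")
    S = min(max_segments, n)
    LL = _loglik_matrix(x)

    # log penalty weight per total segment count: lg[s] = -penalty(s)/2
    lg = np.full(S + 1, -np.inf)
    for s in range(1, S + 1):
        pen = _penalty(s, n, criterion)
        lg[s] = -pen / 2.0 if math.isfinite(pen) else -np.inf

    NEG = -np.inf
    # A[i, s]: logsumexp of segment log-likelihood sums over partitions of
    # the prefix [0, i) into exactly s segments (A[0, 0] = 0)
    A = np.full((n + 1, S + 1), NEG)
    A[0, 0] = 0.0
    for s in range(1, S + 1):
        prev = A[:, s - 1][:, None] + LL  # (a, b)
        with np.errstate(invalid="ignore"):
            A[:, s] = logsumexp(prev, axis=0)
    # B[i, s]: same for the suffix [i, n)
    B = np.full((n + 1, S + 1), NEG)
    B[n, 0] = 0.0
    for s in range(1, S + 1):
        nxt = LL + B[:, s - 1][None, :]  # (a, b)
        with np.errstate(invalid="ignore"):
            B[:, s] = logsumexp(nxt, axis=1)

    log_z = logsumexp(A[n, 1 : S + 1] + lg[1 : S + 1])
    if not math.isfinite(log_z):
        raise ValueError("no admissible model (criterion penalty infinite everywhere)")

    # total (unnormalized) log weight of every segment [a, b):
    # ll(a,b) + logsumexp over s1 prefix parts, s2 suffix parts of
    #   A[a, s1] + B[b, s2] + lg[s1 + s2 + 1]
    lgmat = np.full((S, S), NEG)  # indexed by (s1, s2)
    for s1 in range(S):
        for s2 in range(S - s1):
            lgmat[s1, s2] = lg[s1 + s2 + 1]
    logw = np.full((n + 1, n + 1), NEG)
    for a in range(n):
        with np.errstate(invalid="ignore"):
            v = logsumexp(A[a, :S][:, None] + lgmat, axis=0)  # by s2
        row = np.full(n + 1, NEG)
        for s2 in range(S):
            if v[s2] == NEG:
                continue
            np.logaddexp(row, v[s2] + B[:, s2], out=row)
        logw[a, :] = LL[a, :] + row
    W = np.exp(logw - log_z)
    W[~np.isfinite(logw)] = 0.0

    prefix = np.concatenate([[0], np.cumsum(x)]).astype(float)
    K = prefix[None, :] - prefix[:, None]
    M = np.arange(n + 1)[None, :] - np.arange(n + 1)[:, None].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(M > 0, K / np.where(M > 0, M, 1.0), 0.0)

    # position j is covered by segments with a <= j < b:
    # sum_{a<=j} sum_{b>j} G[a, b] via a reverse cumsum then a forward cumsum
    def position_sums(G: np.ndarray) -> np.ndarray:
        tail = np.cumsum(G[:, ::-1], axis=1)[:, ::-1]  # tail[a, b] = sum_{b'>=b}
        col = np.cumsum(tail, axis=0)  # col[a, b] = sum_{a'<=a}
        return np.array([col[j, j + 1] for j in range(n)])

    coverage = position_sums(W)
    if not np.allclose(coverage, 1.0, atol=1e-6):
        raise AssertionError("per-position segment weights do not sum to 1")
    mean = position_sums(W * R) / coverage

    if n <= exact_quantile_max_n:
        lower = np.empty(n)
        upper = np.empty(n)
        for j in range(n):
            sub_w = W[: j + 1, j + 1 :].ravel()
            sub_r = R[: j + 1, j + 1 :].ravel()
            keep = sub_w > 0
            lower[j], upper[j] = _weighted_quantiles(sub_r[keep], sub_w[keep])
    else:
        lower, upper = _histogram_quantiles(W, R, n, n_bins)

    lower = np.minimum(lower, mean)
    upper = np.maximum(upper, mean)
    model_count = sum(math.comb(n - 1, s - 1) for s in range(1, S + 1))
    return ClusterProfile(
        rate=mean,
        lower95=lower,
        upper95=upper,
        criterion=criterion,
        model_count=model_count,
        max_segments=S,
    )


def _histogram_quantiles(
    W: np.ndarray, R: np.ndarray, n: int, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position weighted rate quantiles on a fixed [0, 1] grid.

    Each segment [a, b) contributes its weight to positions a..b-1; the
    contribution is spread with a difference array along positions so the
    total cost is one scatter-add per segment plus two cumsums.
    """
    ai, bi = np.nonzero(W > 0)
    wi = W[ai, bi]
    ri = R[ai, bi]
    bins = np.rint(ri * (n_bins - 1)).astype(np.int64)
    diff = np.zeros((n_bins, n + 1))
    np.add.at(diff, (bins, ai), wi)
    np.add.at(diff, (bins, bi), -wi)
    mass = np.cumsum(diff, axis=1)[:, :n]  # (bin, position)
    cum = np.cumsum(mass, axis=0)
    total = cum[-1, :]
    grid = np.arange(n_bins) / (n_bins - 1)
    lower_idx = np.argmax(cum >= (0.025 * total - 1e-12)[None, :], axis=0)
    upper_idx = np.argmax(cum >= (0.975 * total - 1e-12)[None, :], axis=0)
    return grid[lower_idx], grid[upper_idx]


def profile_to_frame(profile: ClusterProfile, gene_ids: Sequence[str] | None = None):
    """Long-form per-position table (gene, position, rate, lower95, upper95)."""
    import pandas as pd

    n = len(profile)
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids) if gene_ids is not None else [""] * n,
            "position": np.arange(n),
            "rate": profile.rate,
            "lower95": profile.lower95,
            "upper95": profile.upper95,
        }
    )


def plot_profile(profile: ClusterProfile, labels=None, ax=None):
    """Optional matplotlib rendering of a profile with its 95% envelope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    pos = np.arange(len(profile))
    ax.fill_between(pos, profile.lower95, profile.upper95, color="0.8", label="95% envelope")
    ax.plot(pos, profile.rate, color="crimson", lw=1.5, label="model-averaged rate")
    if labels is not None:
        lab = np.asarray(labels)
        ax.scatter(np.flatnonzero(lab), np.ones(int(lab.sum())) * 1.02, s=4, color="k")
    ax.set_xlabel("gene position")
    ax.set_ylabel("clustered probability")
    ax.set_ylim(-0.02, 1.06)
    ax.legend(loc="upper right", fontsize=8)
    return ax
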