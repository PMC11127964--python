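"""Genome co-occupancy segmentation with a Bernoulli-emission HMM.

The genome is tiled into fixed bins (200 bp by default), per-mark binned
ChIP signal is binarized by a Poisson upper-tail test against the
genome-wide mean, and the resulting multi-mark 0/1 matrix is segmented by
an HMM with independent Bernoulli emissions per mark given the hidden
state.  Chromosomes are independent chains, each restarted from the
initial distribution.

The model is exposed statsmodels-style: ``CooccupancyHMM(data, k_states)``
with ``fit(seed=...)`` returning a :class:`CooccupancyHMMResults` carrying
the estimated parameters, the per-iteration log-likelihood trace, decoding
and state labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    BinnedTrack,
    GenomeIndex,
    Interval,
    distance_to_nearest_tss,
    n_bins,
    signed_tss_distance,
)

_LOG_TINY = 1e-300


def binarize(track: BinnedTrack, p_threshold: float = 1e-4) -> dict[str, np.ndarray]:
    """Binarize one mark's binned counts with a Poisson upper-tail test.

    A bin is called enriched (1) iff P(X >= round(count)) < ``p_threshold``
    under X ~ Poisson(lambda) with lambda the genome-wide mean bin count.
    An all-zero track yields an all-zero column.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    lam = float(np.mean(track.flat()))
    out = {}
    for chrom, vec in track.values.items():
        if lam == 0:
            out[chrom] = np.zeros(len(vec), dtype=np.uint8)
            continue
        k = np.round(vec).astype(int)
        # P(X >= k) = sf(k - 1)
        tail = stats.poisson.sf(k - 1, lam)
        out[chrom] = (tail < p_threshold).astype(np.uint8)
    return out


@dataclass
class BinaryMatrix:
    """Binarized multi-mark signal over the binned genome."""

    bin_size: int
    marks: Tuple[str, ...]
    data: Mapping[str, np.ndarray]  # chrom -> (n_bins, n_marks) 0/1 array
    genome: GenomeIndex

    def __post_init__(self):
        self.marks = tuple(self.marks)
        for chrom, arr in self.data.items():
            expected = n_bins(self.genome[chrom], self.bin_size)
            if arr.shape != (expected, len(self.marks)):
                raise ValueError(
                    f"{chrom}: shape {arr.shape}, expected ({expected}, {len(self.marks)})"
                )
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{chrom}: non-binary cell")

    @classmethod
    def from_tracks(
        cls,
        tracks: Mapping[str, BinnedTrack],
        p_threshold: float = 1e-4,
    ) -> "BinaryMatrix":
        marks = tuple(tracks)
        first = tracks[marks[0]]
        cols = {m: binarize(tracks[m], p_threshold) for m in marks}
        data = {
            chrom: np.column_stack([cols[m][chrom] for m in marks]).astype(np.uint8)
            for chrom in first.genome.names
        }
        return cls(first.bin_size, marks, data, first.genome)

    @property
    def n_bins_total(self) -> int:
        return sum(arr.shape[0] for arr in self.data.values())

    def chains(self):
        for chrom in self.genome.names:
            yield chrom, self.data[chrom]


@dataclass
class HmmParams:
    """Parameters of a Bernoulli-emission HMM.

    ``emissions[k, m]`` is the probability that mark m is enriched (1) in
    state k.
    """

    startprob: np.ndarray  # (K,)
    transmat: np.ndarray  # (K, K)
    emissions: np.ndarray  # (K, M)

    def __post_init__(self):
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        K = len(self.startprob)
        if self.transmat.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if abs(self.startprob.sum() - 1) > tol:
            raise ValueError("startprob does not sum to 1")
        if np.abs(self.transmat.sum(axis=1) - 1).max() > tol:
            raise ValueError("transition rows do not sum to 1")
        if ((self.emissions < 0) | (self.emissions > 1)).any():
            raise ValueError("emissions outside [0, 1]")

    @property
    def k_states(self) -> int:
        return len(self.startprob)

    @property
    def n_marks(self) -> int:
        return self.emissions.shape[1]


def _log_emission_probs(params: HmmParams, X: np.ndarray) -> np.ndarray:
    """(T, K) log P(x_t | state k) under independent Bernoulli marks."""
    logE = np.log(np.maximum(params.emissions, _LOG_TINY))
    log1mE = np.log(np.maximum(1.0 - params.emissions, _LOG_TINY))
    return X @ logE.T + (1 - X) @ log1mE.T


def _forward_scaled(params: HmmParams, logB: np.ndarray):
    """Scaled forward pass; returns (alpha, log c_t per step, loglik)."""
    T, K = logB.shape
    alpha = np.empty((T, K))
    logc = np.empty(T)
    # work with shifted emission probs for numerical safety
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    a = params.startprob * B[0]
    s = a.sum()
    alpha[0] = a / s
    logc[0] = np.log(s) + shift[0]
    AT = params.transmat
    for t in range(1, T):
        a = (alpha[t - 1] @ AT) * B[t]
        s = a.sum()
        alpha[t] = a / s
        logc[t] = np.log(s) + shift[t]
    return alpha, logc, float(logc.sum())


def _backward_scaled(params: HmmParams, logB: np.ndarray) -> np.ndarray:
    T, K = logB.shape
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    beta = np.empty((T, K))
    beta[-1] = 1.0
    A = params.transmat
    for t in range(T - 2, -1, -1):
        b = A @ (B[t + 1] * beta[t + 1])
        beta[t] = b / b.sum()
    return beta


def forward_loglik(params: HmmParams, data: BinaryMatrix) -> float:
    """log P(data | params); chromosomes are independent chains from startprob."""
    if params.n_marks != len(data.marks):
        raise ValueError("model/data mark dimension mismatch")
    total = 0.0
    for _, X in data.chains():
        logB = _log_emission_probs(params, X.astype(float))
        total += _forward_scaled(params, logB)[2]
    return total


try:  # jitted forward-backward core; numpy fallback keeps results identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap(a[0]) if a and callable(a[0]) else wrap


@_njit(cache=True)
def _fb_kernel(startprob, transmat, B, shift):  # pragma: no cover - jitted
    T, K = B.shape
    alpha = np.empty((T, K))
    logc = np.empty(T)
    a = startprob * B[0]
    s = a.sum()
    alpha[0] = a / s
    logc[0] = np.log(s) + shift[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transmat) * B[t]
        s = a.sum()
        alpha[t] = a / s
        logc[t] = np.log(s) + shift[t]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        b = transmat @ (B[t + 1] * beta[t + 1])
        beta[t] = b / b.sum()
    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        xi = transmat * np.outer(alpha[t], B[t + 1] * beta[t + 1])
        xi_sum += xi / xi.sum()
    return gamma, xi_sum, logc.sum()


def _posteriors(params: HmmParams, X: np.ndarray):
    """Per-chain forward-backward: returns (gamma, xi_sum, loglik)."""
    logB = _log_emission_probs(params, X)
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    if _HAVE_NUMBA:
        gamma, xi_sum, ll = _fb_kernel(
            params.startprob, params.transmat, B, shift
        )
        return gamma, xi_sum, float(ll)
    alpha, logc, ll = _forward_scaled(params, logB)
    beta = _backward_scaled(params, logB)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    T = len(X)
    xi_sum = np.zeros((params.k_states, params.k_states))
    A = params.transmat
    for t in range(T - 1):
        xi = A * np.outer(alpha[t], B[t + 1] * beta[t + 1])
        xi_sum += xi / xi.sum()
    return gamma, xi_sum, float(ll)


class CooccupancyHMM:
    """Bernoulli-emission HMM over a binarized multi-mark genome matrix.

    Parameters
    ----------
    data : BinaryMatrix
        Binarized per-bin signal for all marks.
    k_states : int
        Number of hidden states (six in the co-occupancy analysis this
        package reimplements: background plus solo/shared enrichment
        combinations of SPT6L, NRPE1 and Pol II).
    """

    def __init__(self, data: BinaryMatrix, k_states: int = 6):
        if k_states < 1:
            raise ValueError("k_states must be >= 1")
        if data.n_bins_total < k_states:
            raise ValueError("fewer bins than states")
        self.data = data
        self.k_states = k_states

    def _init_params(self, seed: int, strategy: str = "random") -> HmmParams:
        rng = np.random.default_rng(seed)
        K, M = self.k_states, len(self.data.marks)
        startprob = np.full(K, 1.0 / K)
        transmat = rng.uniform(0.5, 1.5, size=(K, K))
        np.fill_diagonal(transmat, transmat.diagonal() + 5.0)  # sticky start
        transmat /= transmat.sum(axis=1, keepdims=True)
        if strategy == "patterns":
            emissions = self._pattern_emissions(K, M)
        else:
            emissions = rng.uniform(0.1, 0.9, size=(K, M))
        return HmmParams(startprob, transmat, emissions)

    def _pattern_emissions(self, K: int, M: int) -> np.ndarray:
        """Emission init from the K most frequent observed mark patterns.

        Each state's row is a softened copy (0.1/0.9) of one distinct
        observed 0/1 pattern, most frequent first; surplus states fall
        back to spread constants.  Deterministic.
        """
        X = np.concatenate([arr for _, arr in self.chains_arrays()])
        codes = X @ (1 << np.arange(M))
        counts = np.bincount(codes, minlength=1 << M)
        order = np.argsort(-counts, kind="stable")
        rows = []
        for code in order[:K]:
            if counts[code] == 0:
                break
            bits = (code >> np.arange(M)) & 1
            rows.append(0.1 + 0.8 * bits)
        k = len(rows)
        for i in range(K - k):  # more states than observed patterns
            rows.append(np.full(M, 0.2 + 0.6 * (i + 1) / (K - k + 1)))
        return np.array(rows, dtype=float)

    def chains_arrays(self):
        return [(chrom, arr) for chrom, arr in self.data.chains()]

    def loglike(self, params: HmmParams) -> float:
        return forward_loglik(params, self.data)

    def fit(
        self,
        seed: int = 0,
        max_iter: int = 200,
        tol: float = 1e-4,
        n_init: int = 5,
        params_start: Optional[HmmParams] = None,
    ) -> "CooccupancyHMMResults":
        """Baum-Welch EM, best of ``n_init`` seeded random restarts.

        The first restart initializes emissions from the most frequent
        observed mark patterns (deterministic); restart r > 0 starts from
        the random initialization seeded with ``seed + r``.  The fit with
        the highest final log-likelihood is returned (EM on binarized
        multi-mark data is multimodal, and rare states are easily merged
        from a single start).  Identical data and seed give a bit-identical
        fit.
        """
        if params_start is not None:
            return self._fit_once(params_start, max_iter, tol)
        best = None
        for r in range(max(1, n_init)):
            strategy = "patterns" if r == 0 else "random"
            res = self._fit_once(
                self._init_params(seed + r, strategy), max_iter, tol
            )
            if best is None or res.llf > best.llf:
                best = res
        return best

    def _fit_once(
        self, params: HmmParams, max_iter: int, tol: float
    ) -> "CooccupancyHMMResults":
        chains = [X.astype(float) for _, X in self.data.chains()]
        K = self.k_states
        history = []
        prev_ll = -np.inf
        for _ in range(max_iter):
            g0 = np.zeros(K)
            xi_tot = np.zeros((K, K))
            occ = np.zeros(K)
            weighted_x = np.zeros((K, len(self.data.marks)))
            ll = 0.0
            for X in chains:
                gamma, xi_sum, ll_c = _posteriors(params, X)
                ll += ll_c
                g0 += gamma[0]
                xi_tot += xi_sum
                occ += gamma.sum(axis=0)
                weighted_x += gamma.T @ X
            history.append(ll)
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
            startprob = g0 / g0.sum()
            transmat = xi_tot / np.maximum(xi_tot.sum(axis=1, keepdims=True), _LOG_TINY)
            # guard against empty states: keep the row stochastic
            dead = xi_tot.sum(axis=1) == 0
            transmat[dead] = 1.0 / K
            emissions = weighted_x / np.maximum(occ[:, None], _LOG_TINY)
            params = HmmParams(startprob, transmat, np.clip(emissions, 0.0, 1.0))
        return CooccupancyHMMResults(self, params, np.array(history))


@dataclass
class StateSegmentation:
    """Decoded per-bin states with merged run-length segments."""

    bin_size: int
    states: Mapping[str, np.ndarray]  # chrom -> per-bin state index
    genome: GenomeIndex
    labels: Optional[Mapping[int, str]] = None

    @property
    def segments(self) -> list[Tuple[Interval, int]]:
        """Maximal same-state runs as (Interval, state) in genome order."""
        segs = []
        for chrom in self.genome.names:
            s = self.states[chrom]
            L, b = self.genome[chrom], self.bin_size
            boundaries = np.flatnonzero(np.diff(s)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(s)]])
            for i0, i1 in zip(starts, ends):
                segs.append(
                    (Interval(chrom, int(i0) * b, min(int(i1) * b, L)), int(s[i0]))
                )
        return segs

    def state_regions(self, state: int) -> list[Interval]:
        return [iv for iv, s in self.segments if s == state]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iv, s in self.segments:
            label = self.labels.get(s, str(s)) if self.labels else str(s)
            rows.append((iv.chrom, iv.start, iv.end, s, label))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "label"])


class CooccupancyHMMResults:
    """Fitted co-occupancy HMM: parameters, fit trace, decoding, labels."""

    def __init__(
        self, model: CooccupancyHMM, params: HmmParams, loglik_history: np.ndarray
    ):
        self.model = model
        self.params = params
        self.loglik_history = loglik_history

    @property
    def llf(self) -> float:
        return float(self.loglik_history[-1])

    @property
    def converged(self) -> bool:
        h = self.loglik_history
        return len(h) >= 2 and h[-1] - h[-2] < 1e-4 * 10  # last gain small

    def decode(self, data: Optional[BinaryMatrix] = None, method: str = "posterior"):
        return decode(self.params, data if data is not None else self.model.data, method)

    def label_states(self, tau: float = 0.5) -> dict[int, str]:
        return label_states(self.params, self.model.data.marks, tau)

    def summary(self) -> str:
        p = self.params
        marks = self.model.data.marks
        labels = self.label_states()
        lines = [
            "Co-occupancy Bernoulli HMM",
            f"states: {p.k_states}   marks: {', '.join(marks)}",
            f"bins: {self.model.data.n_bins_total} x {self.model.data.bin_size} bp",
            f"log-likelihood: {self.llf:.3f}   EM iterations: {len(self.loglik_history)}",
            "",
            "state  " + "  ".join(f"{m:>8s}" for m in marks) + "  pi       label",
        ]
        for k in range(p.k_states):
            em = "  ".join(f"{p.emissions[k, m]:8.3f}" for m in range(len(marks)))
            lines.append(f"{k:>5d}  {em}  {p.startprob[k]:.3f}  {labels[k]}")
        return "\n".join(lines)

    def to_table(self) -> pd.DataFrame:
        """Flat parameter table (pi, A, E) for plain-text output."""
        p = self.params
        rows = []
        for k in range(p.k_states):
            rows.append(("pi", str(k), "", p.startprob[k]))
        for i in range(p.k_states):
            for j in range(p.k_states):
                rows.append(("A", str(i), str(j), p.transmat[i, j]))
        for k in range(p.k_states):
            for m, mark in enumerate(self.model.data.marks):
                rows.append(("E", str(k), mark, p.emissions[k, m]))
        return pd.DataFrame(rows, columns=["param", "row", "col", "value"])


def params_from_table(table: pd.DataFrame, marks: Sequence[str]) -> HmmParams:
    """Rebuild HmmParams from the flat parameter table written by results."""
    pi_rows = table[table["param"] == "pi"].sort_values("row")
    K = len(pi_rows)
    startprob = pi_rows["value"].to_numpy()
    transmat = np.zeros((K, K))
    for r in table[table["param"] == "A"].itertuples():
        transmat[int(r.row), int(r.col)] = r.value
    emissions = np.zeros((K, len(marks)))
    col_of = {m: i for i, m in enumerate(marks)}
    for r in table[table["param"] == "E"].itertuples():
        emissions[int(r.row), col_of[r.col]] = r.value
    return HmmParams(startprob, transmat, emissions)


def decode(
    params: HmmParams, data: BinaryMatrix, method: str = "posterior"
) -> StateSegmentation:
    """Per-bin state assignment: posterior-maximal (default) or Viterbi."""
    if method not in ("posterior", "viterbi"):
        raise ValueError(f"unknown decoding method {method!r}")
    states = {}
    for chrom, X in data.chains():
        Xf = X.astype(float)
        if method == "posterior":
            gamma, _, _ = _posteriors(params, Xf)
            states[chrom] = np.argmax(gamma, axis=1)
        else:
            states[chrom] = _viterbi(params, Xf)
    return StateSegmentation(data.bin_size, states, data.genome)


def _viterbi(params: HmmParams, X: np.ndarray) -> np.ndarray:
    logB = _log_emission_probs(params, X)
    logA = np.log(np.maximum(params.transmat, _LOG_TINY))
    T, K = logB.shape
    delta = np.log(np.maximum(params.startprob, _LOG_TINY)) + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def label_states(
    params: HmmParams, marks: Sequence[str], tau: float = 0.5
) -> dict[int, str]:
    """Name each state from its emission row.

    Requires the SPT6L, NRPE1 and Pol II marks.  A mark is "high" in a
    state when its emission probability is >= tau.  Rules: no mark high ->
    background; NRPE1 high alone -> NRPE1-only (G2-like); NRPE1 and SPT6L
    high without Pol II -> NRPE1-SPT6L shared (G3-like); SPT6L and Pol II
    high -> genic SPT6L; anything else is named by its high-mark set.
    """
    norm = {m.upper().replace(" ", "").replace("II", "2"): i for i, m in enumerate(marks)}
    try:
        i_spt6l = norm["SPT6L"]
        i_nrpe1 = norm["NRPE1"]
        i_pol2 = next(norm[k] for k in norm if k in ("POL2", "POLII", "RNAPOL2"))
    except (KeyError, StopIteration):
        raise ValueError("marks must include SPT6L, NRPE1 and Pol II") from None
    labels = {}
    for k in range(params.k_states):
        high = params.emissions[k] >= tau
        s, n, p2 = high[i_spt6l], high[i_nrpe1], high[i_pol2]
        if not high.any():
            labels[k] = "background"
        elif n and not s and not p2 and high.sum() == 1:
            labels[k] = "NRPE1-only"
        elif n and s and not p2:
            labels[k] = "NRPE1-SPT6L shared"
        elif s and p2:
            labels[k] = "genic SPT6L"
        else:
            labels[k] = "+".join(marks[i] for i in np.flatnonzero(high))
    return labels


def state_tss_profile(
    seg: StateSegmentation,
    tss_set: Sequence[Tuple[int, str]],
    window: int = 1000,
    resolution: int = 200,
) -> pd.DataFrame:
    """Per-state histogram of signed segment-center-to-nearest-TSS distances.

    Distances in [-window, +window) are binned at ``resolution`` and each
    state's row is normalized to frequencies (rows with no in-window
    segments stay all-zero).
    """
    if window % resolution:
        raise ValueError("window must be a multiple of resolution")
    edges = np.arange(-window, window + resolution, resolution)
    k_states = int(max(int(s.max()) for s in seg.states.values()) + 1)
    mat = np.zeros((k_states, len(edges) - 1))
    for iv, state in seg.segments:
        d = distance_to_nearest_tss(iv, tss_set)
        if -window <= d < window:
            mat[state, int((d + window) // resolution)] += 1
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(sums > 0, mat / np.maximum(sums, 1), 0.0)
    cols = [f"[{edges[i]},{edges[i+1]})" for i in range(len(edges) - 1)]
    return pd.DataFrame(mat, columns=cols)


def nearest_downstream_tss(
    regions: Sequence[Interval], genes: pd.DataFrame
) -> pd.DataFrame:
    """Assign each region the gene with the nearest downstream TSS.

    "Downstream" is taken in each gene's own orientation: a gene is a
    candidate when travelling 5'->3' along that gene, its TSS lies at or
    ahead of the region center.  Ties on distance break to the smaller
    gene id; regions with no downstream gene are reported unassigned.
    """
    rows = []
    for i, reg in enumerate(regions):
        c = reg.center
        best = None
        for g in genes.itertuples():
            if g.chrom != reg.chrom:
                continue
            downstream = (g.strand != "-" and g.tss >= c) or (
                g.strand == "-" and g.tss <= c
            )
            if not downstream:
                continue
            dist = abs(g.tss - c)
            key = (dist, g.gene_id)
            if best is None or key < best[0]:
                best = (key, g.gene_id, dist)
        if best is None:
            rows.append((i, reg.chrom, reg.start, reg.end, None, np.nan))
        else:
            rows.append((i, reg.chrom, reg.start, reg.end, best[1], best[2]))
    return pd.DataFrame(
        rows, columns=["region", "chrom", "start", "end", "gene_id", "distance"]
    )
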