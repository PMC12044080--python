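"""Three-state HMM genotyping of low-coverage F2 individuals.

Per-marker allele counts are summed in fixed windows (default 5 kb) and each
individual's chromosome is decoded into an AA/AB/BB state path with the
Viterbi algorithm. Emissions are binomial on the raw window counts — at
sub-1x coverage most windows hold 0-5 reads, and the count pair carries the
depth information a bare A-read proportion would lose. Windows with no
covered marker emit likelihood 1 for every state so paths stay
coordinate-addressable and transitions bridge gaps.

Transitions follow the two-gamete F2 model with per-window recombination
fraction r: a crossover in either gamete moves the state one dosage step,
so AA<->BB requires two crossovers (probability r^2) and is flagged when
decoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .errors import ConsistencyError, InvalidSpecError
from .simulate import STATE_LABELS, AlleleCounts, MarkerSet

_MIN_R = 1e-9


@dataclass(frozen=True)
class HMMParams:
    """Decoding parameters.

    ``r`` is the probability of a crossover per gamete between adjacent
    windows; it is clamped to at least 1e-9 so that log transitions stay
    finite, and must be < 0.5.
    """

    window_size: int = 5000
    error: float = 0.02
    r: float = 3e-4
    pi: tuple[float, float, float] = (0.25, 0.5, 0.25)

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise InvalidSpecError("window_size must be > 0")
        if not 0 <= self.error < 0.5:
            raise InvalidSpecError("emission error must be in [0, 0.5)")
        if not self.r < 0.5:
            raise InvalidSpecError("per-window recombination fraction must be < 0.5")
        if abs(sum(self.pi) - 1.0) > 1e-9 or any(p < 0 for p in self.pi):
            raise InvalidSpecError("pi must be a probability distribution")

    @property
    def r_eff(self) -> float:
        return max(self.r, _MIN_R)

    def log_transitions(self) -> np.ndarray:
        """Log transition matrix of the two-gamete F2 chain."""
        r = self.r_eff
        t = np.array(
            [
                [(1 - r) ** 2, 2 * r * (1 - r), r**2],
                [r * (1 - r), (1 - r) ** 2 + r**2, r * (1 - r)],
                [r**2, 2 * r * (1 - r), (1 - r) ** 2],
            ]
        )
        return np.log(t)

    def state_allele_probs(self) -> np.ndarray:
        """P(read supports A | state) for AA, AB, BB."""
        e = self.error
        return np.array([1.0 - e, 0.5, e])


def recombination_fraction(
    crossover_rate: float, window_size: int, chrom_length: int
) -> float:
    """Per-window, per-gamete crossover probability implied by a genetic map."""
    return crossover_rate * window_size / chrom_length


@dataclass
class WindowObservations:
    """Windowed allele counts for a cohort: per chromosome (n_samples, n_windows)."""

    samples: list[str]
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    window_size: int
    n_a: dict[str, np.ndarray]
    n_b: dict[str, np.ndarray]

    def n_windows(self, chrom: str) -> int:
        return self.n_a[chrom].shape[1]

    def proportions(self, chrom: str) -> np.ndarray:
        """A-read proportion per window; NaN where no read was observed."""
        tot = self.n_a[chrom] + self.n_b[chrom]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.n_a[chrom] / np.maximum(tot, 1), np.nan)


def n_windows_for(length: int, window_size: int) -> int:
    return -(-length // window_size)


def aggregate_windows(
    counts: AlleleCounts, markers: MarkerSet, window_size: int
) -> WindowObservations:
    """Sum per-marker allele counts in fixed half-open windows [k*w, (k+1)*w)."""
    if window_size <= 0:
        raise InvalidSpecError("window_size must be > 0")
    n_a: dict[str, np.ndarray] = {}
    n_b: dict[str, np.ndarray] = {}
    for chrom in markers.chrom_names:
        pos = markers.positions[chrom]
        if counts.n_a[chrom].shape[1] != len(pos):
            raise ConsistencyError(
                f"{chrom}: counts cover {counts.n_a[chrom].shape[1]} markers, "
                f"marker set has {len(pos)}"
            )
        n_win = n_windows_for(markers.chrom_lengths[chrom], window_size)
        widx = (pos // window_size).astype(np.intp)
        if len(pos) and widx.max() >= n_win:
            raise ConsistencyError(f"{chrom}: marker position beyond chromosome end")
        s = len(counts.samples)
        a_win = np.zeros((s, n_win), dtype=np.int64)
        b_win = np.zeros((s, n_win), dtype=np.int64)
        for i in range(s):
            a_win[i] = np.bincount(widx, weights=counts.n_a[chrom][i], minlength=n_win)
            b_win[i] = np.bincount(widx, weights=counts.n_b[chrom][i], minlength=n_win)
        n_a[chrom] = a_win
        n_b[chrom] = b_win
    return WindowObservations(
        samples=list(counts.samples),
        chrom_names=list(markers.chrom_names),
        chrom_lengths=dict(markers.chrom_lengths),
        window_size=window_size,
        n_a=n_a,
        n_b=n_b,
    )


def _log_emissions(n_a: np.ndarray, n_b: np.ndarray, params: HMMParams) -> np.ndarray:
    """Binomial log-likelihood of each state; shape (..., T, 3).

    Empty windows (zero total depth) get log-likelihood 0 for every state.
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    tot = n_a + n_b
    log_c = gammaln(tot + 1) - gammaln(n_a + 1) - gammaln(n_b + 1)
    p = params.state_allele_probs()
    ll = (
        log_c[..., None]
        + xlogy(n_a[..., None], p)
        + xlogy(n_b[..., None], 1.0 - p)
    )
    return np.where(tot[..., None] > 0, ll, 0.0)


def viterbi_decode(
    n_a: np.ndarray, n_b: np.ndarray, params: HMMParams
) -> tuple[np.ndarray, float]:
    """Decode one chromosome of one individual.

    Returns the maximum-probability state path (0=AA, 1=AB, 2=BB) and its
    joint log-likelihood. Ties between predecessors are broken in favour of
    the predecessor equal to the current state (no spurious crossover).
    """
    states, logp = viterbi_decode_batch(
        np.atleast_2d(n_a), np.atleast_2d(n_b), params
    )
    return states[0], float(logp[0])


def viterbi_decode_batch(
    n_a: np.ndarray, n_b: np.ndarray, params: HMMParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Viterbi over a cohort: inputs shaped (n_samples, T)."""
    n_a = np.asarray(n_a)
    n_b = np.asarray(n_b)
    if n_a.ndim != 2 or n_a.shape != n_b.shape or n_a.shape[1] == 0:
        raise InvalidSpecError("observations must be non-empty (n_samples, T) arrays")
    if (n_a < 0).any() or (n_b < 0).any():
        raise InvalidSpecError("allele counts must be non-negative")
    s, t_len = n_a.shape
    em = _log_emissions(n_a, n_b, params)  # (S, T, 3)
    log_a = params.log_transitions()
    with np.errstate(divide="ignore"):
        delta = np.log(np.asarray(params.pi)) + em[:, 0, :]
    back = np.empty((s, t_len, 3), dtype=np.int8)
    idx3 = np.arange(3)
    for t in range(1, t_len):
        scores = delta[:, :, None] + log_a[None, :, :]  # (S, from, to)
        col_max = scores.max(axis=1)
        bp = scores.argmax(axis=1).astype(np.int8)
        # stay-put tie-break: keep the current state as its own predecessor
        diag = scores[:, idx3, idx3]
        stay = diag >= col_max - 0.0
        bp = np.where(stay, idx3[None, :].astype(np.int8), bp)
        back[:, t, :] = bp
        delta = col_max + em[:, t, :]
    states = np.empty((s, t_len), dtype=np.int8)
    states[:, -1] = delta.argmax(axis=1)
    logp = delta.max(axis=1)
    rows = np.arange(s)
    for t in range(t_len - 1, 0, -1):
        states[:, t - 1] = back[rows, t, states[:, t]]
    return states, logp


@dataclass
class GenotypePaths:
    """Decoded window-state paths for a cohort."""

    samples: list[str]
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    window_size: int
    states: dict[str, np.ndarray]   # (n_samples, n_windows) int8
    log_prob: dict[str, np.ndarray]  # (n_samples,)


def decode_cohort(
    windows: WindowObservations,
    params: HMMParams | None = None,
    crossover_rate: float | None = None,
    error: float = 0.02,
) -> GenotypePaths:
    """Viterbi-decode every individual on every chromosome.

    When ``params`` is None the per-window recombination fraction is derived
    per chromosome from ``crossover_rate`` (crossovers per gamete per
    chromosome).
    """
    states: dict[str, np.ndarray] = {}
    log_prob: dict[str, np.ndarray] = {}
    for chrom in windows.chrom_names:
        if params is None:
            if crossover_rate is None:
                raise InvalidSpecError("either params or crossover_rate is required")
            r = recombination_fraction(
                crossover_rate, windows.window_size, windows.chrom_lengths[chrom]
            )
            p = HMMParams(window_size=windows.window_size, error=error, r=r)
        else:
            p = params
        st, lp = viterbi_decode_batch(windows.n_a[chrom], windows.n_b[chrom], p)
        states[chrom] = st
        log_prob[chrom] = lp
    return GenotypePaths(
        samples=list(windows.samples),
        chrom_names=list(windows.chrom_names),
        chrom_lengths=dict(windows.chrom_lengths),
        window_size=windows.window_size,
        states=states,
        log_prob=log_prob,
    )


def call_crossovers(paths: GenotypePaths) -> pd.DataFrame:
    """One call per adjacent state change of any individual.

    Breakpoints sit on the shared window boundary. AA<->BB changes need a
    double crossover within one window span: step distance 2, flagged.
    """
    rows: list[dict] = []
    for chrom in paths.chrom_names:
        st = paths.states[chrom]
        w = paths.window_size
        for i, sample in enumerate(paths.samples):
            change = np.nonzero(np.diff(st[i]) != 0)[0]
            for t in change:
                frm, to = int(st[i, t]), int(st[i, t + 1])
                dist = abs(frm - to)
                rows.append(
                    {
                        "sample": sample,
                        "chrom": chrom,
                        "pos": int((t + 1) * w),
                        "from_state": STATE_LABELS[frm],
                        "to_state": STATE_LABELS[to],
                        "distance": dist,
                        "double": dist == 2,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "from_state", "to_state", "distance", "double"],
    )
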