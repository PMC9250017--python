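"""Delayed stochastic bursty-transcription model of the her1/her7 clock.

The model is a cell-autonomous delayed negative-feedback oscillator with
transcriptional bursting:

* *her1* and *her7* mRNAs are produced in bursts.  A gene's bursts fire
  either alone (frequency ``km (1 - alpha)`` each) or jointly with the
  other gene (frequency ``km alpha``), so ``alpha`` is the co-firing
  fraction and the total burst initiation rate per gene is ``km`` for any
  ``alpha``.
* The Her1:Her7 heterodimer (p17) represses the *mean burst size* — not
  the frequency — through a Hill function ``f(p17) = 1 / (1 +
  (p17/pdcrit)^hill_n)``; the instantaneous mean burst size is ``<B> =
  Bmax f(p17)``.  Burst sizes are geometric with success ``1/<B>`` when
  ``<B> >= 1`` and Bernoulli(<B>) on {0, 1} otherwise (a continuous-mean
  extension of the geometric rule below one molecule).
* Transcriptional and translational delays ``tau_m``/``tau_p`` are
  realised as Erlang chains of ``n_delay`` sequential first-order steps
  with per-step rate ``n_delay / tau`` (mean tau, variance tau^2/n_delay).
* Mature mRNAs are translated (``kp1``/``kp7``), mature proteins dimerise
  reversibly (``kb``/``ku``; dissociation restores both monomers), and all
  mature species degrade first-order.  Chain intermediates are not degraded
  unless ``degrade_intermediates`` is set.

Trajectories are generated with the exact (direct-method) Gillespie
algorithm — no tau-leaping — in a numba-compiled kernel.  One trajectory
is one cell; a population is many cells run from the same initial
condition on independent RNG substreams.  After a burn-in ``T0`` the full
state is recorded every ``dt_obs`` minutes up to ``Tmax``, and
correlated/uncorrelated variability is computed across cells per time
point, then binned by population-mean total mRNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
from numba import njit

from .exceptions import ValidationError
from .variability import (
    BinnedCurve,
    bin_curve,
    correlated_variability,
    uncorrelated_variability,
)

__all__ = [
    "SimParams",
    "SimState",
    "PopulationSnapshots",
    "hill_repression",
    "mean_burst_size",
    "draw_burst_size",
    "propensities",
    "gillespie_step",
    "simulate_cell",
    "simulate_population",
    "sim_variability_curve",
    "deletion_mutant",
    "chain_transit_times",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimParams:
    """Full parameterisation of the stochastic clock model.

    Rates are per minute, counts in molecules.  The defaults target the
    printed biology of the zebrafish segmentation clock — a ~30 min
    oscillation period, mRNA/protein half-lives of 3-5 min, and a
    population-mean total mRNA (her1+her7) of roughly 49 molecules — and
    are frozen here as the package's wild-type reference parameter set.
    """

    km: float = 1.0          # total burst frequency per gene (1/min)
    alpha: float = 0.85      # correlated-burst (co-firing) fraction
    Bmax: float = 12.0       # maximum mean burst size (molecules)
    pdcrit: float = 250.0    # heterodimer count at half repression
    hill_n: int = 2
    n_delay: int = 10        # intermediate steps per delay chain
    tau_m: float = 6.0       # transcriptional delay (min)
    tau_p: float = 2.0       # translational delay (min)
    kp1: float = 4.5         # translation rates (1/min per mRNA)
    kp7: float = 4.5
    gamma_m1: float = _LN2 / 3.0   # degradations (1/min); 3-min half-life
    gamma_m7: float = _LN2 / 3.0
    gamma_p1: float = _LN2 / 3.0
    gamma_p7: float = _LN2 / 3.0
    gamma_p17: float = _LN2 / 3.0
    kb: float = 0.01         # dimerisation (1/molecule/min)
    ku: float = 1.0          # dissociation (1/min)
    T0: float = 300.0        # burn-in (min), ~10 periods
    Tmax: float = 900.0      # end of recording (min)
    dt_obs: float = 2.0      # observation interval (min), << period
    shared_burst_size: bool = False   # joint bursts share one size draw
    degrade_intermediates: bool = False

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        if self.pdcrit <= 0:
            raise ValidationError("pdcrit must be > 0")
        if self.n_delay < 1:
            raise ValidationError("n_delay must be >= 1")
        if self.Tmax <= self.T0:
            raise ValidationError("Tmax must exceed T0")
        if self.dt_obs <= 0:
            raise ValidationError("dt_obs must be > 0")
        for name in ("km", "Bmax", "tau_m", "tau_p", "kp1", "kp7", "kb", "ku"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("gamma_m1", "gamma_m7", "gamma_p1", "gamma_p7", "gamma_p17"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def state_size(self) -> int:
        return 4 * self.n_delay + 5

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimState:
    """Instantaneous molecular state of one cell."""

    m1_chain: np.ndarray  # nascent her1 mRNA intermediates (len n_delay)
    m7_chain: np.ndarray
    m1n: int              # mature mRNAs
    m7n: int
    p1_chain: np.ndarray  # nascent protein intermediates
    p7_chain: np.ndarray
    p1: int               # mature proteins
    p7: int
    p17: int              # heterodimer
    t: float = 0.0
    absorbed: bool = False

    @classmethod
    def zero(cls, params: SimParams) -> "SimState":
        n = params.n_delay
        return cls(
            m1_chain=np.zeros(n, dtype=np.int64),
            m7_chain=np.zeros(n, dtype=np.int64),
            m1n=0, m7n=0,
            p1_chain=np.zeros(n, dtype=np.int64),
            p7_chain=np.zeros(n, dtype=np.int64),
            p1=0, p7=0, p17=0, t=0.0,
        )

    def to_vector(self) -> np.ndarray:
        n = len(self.m1_chain)
        v = np.empty(4 * n + 5, dtype=np.int64)
        v[0:n] = self.m1_chain
        v[n] = self.m1n
        v[n + 1:2 * n + 1] = self.m7_chain
        v[2 * n + 1] = self.m7n
        v[2 * n + 2:3 * n + 2] = self.p1_chain
        v[3 * n + 2] = self.p1
        v[3 * n + 3:4 * n + 3] = self.p7_chain
        v[4 * n + 3] = self.p7
        v[4 * n + 4] = self.p17
        return v

    @classmethod
    def from_vector(cls, v: np.ndarray, n_delay: int, t: float = 0.0) -> "SimState":
        n = n_delay
        return cls(
            m1_chain=v[0:n].copy(), m1n=int(v[n]),
            m7_chain=v[n + 1:2 * n + 1].copy(), m7n=int(v[2 * n + 1]),
            p1_chain=v[2 * n + 2:3 * n + 2].copy(), p1=int(v[3 * n + 2]),
            p7_chain=v[3 * n + 3:4 * n + 3].copy(), p7=int(v[4 * n + 3]),
            p17=int(v[4 * n + 4]), t=t,
        )


def hill_repression(p17: float, pdcrit: float, hill_n: int = 2) -> float:
    """Hill repression factor ``1 / (1 + (p17/pdcrit)^hill_n)`` in (0, 1]."""
    if pdcrit <= 0:
        raise ValidationError("pdcrit must be > 0")
    return 1.0 / (1.0 + (p17 / pdcrit) ** hill_n)


def mean_burst_size(p17: float, params: SimParams) -> float:
    """Current mean burst size ``Bmax * f(p17)``."""
    return params.Bmax * hill_repression(p17, params.pdcrit, params.hill_n)


def draw_burst_size(mean_b: float, rng: np.random.Generator) -> int:
    """Draw one burst size.

    Geometric on {1, 2, ...} with success ``1/mean_b`` when ``mean_b >= 1``;
    Bernoulli(mean_b) on {0, 1} when ``mean_b < 1`` (keeps the mean exact
    and continuous through 1).
    """
    if mean_b < 0:
        raise ValidationError("mean burst size must be >= 0")
    if mean_b < 1.0:
        return int(rng.random() < mean_b)
    s = 1.0 / mean_b
    if s >= 1.0:
        return 1
    return int(rng.geometric(s))


# ---------------------------------------------------------------------------
# reaction channels
#
# 0 burst her1 only      km (1-alpha)
# 1 burst her7 only      km (1-alpha)
# 2 joint burst          km alpha
# 3 m1 chain step        (n/tau_m) * sum(m1_chain)
# 4 m7 chain step        (n/tau_m) * sum(m7_chain)
# 5 p1 chain step        (n/tau_p) * sum(p1_chain)
# 6 p7 chain step        (n/tau_p) * sum(p7_chain)
# 7 translation her1     kp1 * m1n
# 8 translation her7     kp7 * m7n
# 9 deg m1n              gamma_m1 * m1n
# 10 deg m7n             gamma_m7 * m7n
# 11 deg p1              gamma_p1 * p1
# 12 deg p7              gamma_p7 * p7
# 13 deg p17             gamma_p17 * p17
# 14 dimerisation        kb * p1 * p7
# 15 dissociation        ku * p17
# 16-19 intermediate degradation (optional)
# ---------------------------------------------------------------------------

N_CHANNELS = 20


def propensities(state: SimState, params: SimParams) -> np.ndarray:
    """Reaction propensities (1/min) of every channel at ``state``."""
    p = params
    a = np.zeros(N_CHANNELS)
    a[0] = p.km * (1.0 - p.alpha)
    a[1] = p.km * (1.0 - p.alpha)
    a[2] = p.km * p.alpha
    if p.tau_m > 0:
        a[3] = p.n_delay / p.tau_m * state.m1_chain.sum()
        a[4] = p.n_delay / p.tau_m * state.m7_chain.sum()
    if p.tau_p > 0:
        a[5] = p.n_delay / p.tau_p * state.p1_chain.sum()
        a[6] = p.n_delay / p.tau_p * state.p7_chain.sum()
    a[7] = p.kp1 * state.m1n
    a[8] = p.kp7 * state.m7n
    a[9] = p.gamma_m1 * state.m1n
    a[10] = p.gamma_m7 * state.m7n
    a[11] = p.gamma_p1 * state.p1
    a[12] = p.gamma_p7 * state.p7
    a[13] = p.gamma_p17 * state.p17
    a[14] = p.kb * state.p1 * state.p7
    a[15] = p.ku * state.p17
    if p.degrade_intermediates:
        a[16] = p.gamma_m1 * state.m1_chain.sum()
        a[17] = p.gamma_m7 * state.m7_chain.sum()
        a[18] = p.gamma_p1 * state.p1_chain.sum()
        a[19] = p.gamma_p7 * state.p7_chain.sum()
    return a


def _pick_stage(chain: np.ndarray, rng: np.random.Generator) -> int:
    w = chain.astype(float)
    return int(rng.choice(len(chain), p=w / w.sum()))


def _advance_chain(chain: np.ndarray, mature_attr: str, state: SimState,
                   rng: np.random.Generator) -> None:
    j = _pick_stage(chain, rng)
    chain[j] -= 1
    if j == len(chain) - 1:
        setattr(state, mature_attr, getattr(state, mature_attr) + 1)
    else:
        chain[j + 1] += 1


def gillespie_step(state: SimState, params: SimParams,
                   rng: np.random.Generator) -> SimState:
    """Advance the state by one exact stochastic event (reference path).

    Pure-Python mirror of the compiled kernel, used for single-step
    semantics and as a cross-check.  If every propensity is zero the state
    is returned unchanged with ``absorbed=True``.
    """
    a = propensities(state, params)
    total = a.sum()
    st = SimState(
        m1_chain=state.m1_chain.copy(), m7_chain=state.m7_chain.copy(),
        m1n=state.m1n, m7n=state.m7n,
        p1_chain=state.p1_chain.copy(), p7_chain=state.p7_chain.copy(),
        p1=state.p1, p7=state.p7, p17=state.p17, t=state.t,
    )
    if total <= 0.0:
        st.absorbed = True
        return st
    st.t += rng.exponential(1.0 / total)
    ch = int(rng.choice(N_CHANNELS, p=a / total))
    p = params

    def _burst_into(chain: np.ndarray, mature_attr: str, size: int) -> None:
        if p.tau_m > 0:
            chain[0] += size
        else:
            setattr(st, mature_attr, getattr(st, mature_attr) + size)

    if ch in (0, 1, 2):
        mb = mean_burst_size(st.p17, p)
        if ch == 0:
            _burst_into(st.m1_chain, "m1n", draw_burst_size(mb, rng))
        elif ch == 1:
            _burst_into(st.m7_chain, "m7n", draw_burst_size(mb, rng))
        else:
            b1 = draw_burst_size(mb, rng)
            b7 = b1 if p.shared_burst_size else draw_burst_size(mb, rng)
            _burst_into(st.m1_chain, "m1n", b1)
            _burst_into(st.m7_chain, "m7n", b7)
    elif ch == 3:
        _advance_chain(st.m1_chain, "m1n", st, rng)
    elif ch == 4:
        _advance_chain(st.m7_chain, "m7n", st, rng)
    elif ch == 5:
        _advance_chain(st.p1_chain, "p1", st, rng)
    elif ch == 6:
        _advance_chain(st.p7_chain, "p7", st, rng)
    elif ch == 7:
        if p.tau_p > 0:
            st.p1_chain[0] += 1
        else:
            st.p1 += 1
    elif ch == 8:
        if p.tau_p > 0:
            st.p7_chain[0] += 1
        else:
            st.p7 += 1
    elif ch == 9:
        st.m1n -= 1
    elif ch == 10:
        st.m7n -= 1
    elif ch == 11:
        st.p1 -= 1
    elif ch == 12:
        st.p7 -= 1
    elif ch == 13:
        st.p17 -= 1
    elif ch == 14:
        st.p1 -= 1
        st.p7 -= 1
        st.p17 += 1
    elif ch == 15:
        st.p17 -= 1
        st.p1 += 1
        st.p7 += 1
    elif ch == 16:
        st.m1_chain[_pick_stage(st.m1_chain, rng)] -= 1
    elif ch == 17:
        st.m7_chain[_pick_stage(st.m7_chain, rng)] -= 1
    elif ch == 18:
        st.p1_chain[_pick_stage(st.p1_chain, rng)] -= 1
    elif ch == 19:
        st.p7_chain[_pick_stage(st.p7_chain, rng)] -= 1
    return st


@njit(cache=False)
def _draw_burst_nb(mean_b: float) -> np.int64:
    if mean_b <= 0.0:
        return np.int64(0)
    if mean_b < 1.0:
        return np.int64(1) if np.random.random() < mean_b else np.int64(0)
    s = 1.0 / mean_b
    if s >= 1.0:
        return np.int64(1)
    u = np.random.random()
    if u <= 0.0:
        u = 1e-300
    return np.int64(1) + np.int64(np.log(u) / np.log(1.0 - s))


@njit(cache=False)
def _pick_stage_nb(S, lo, n, u_scaled):
    acc = 0.0
    for j in range(n):
        acc += S[lo + j]
        if u_scaled < acc:
            return j
    return n - 1


@njit(cache=False)
def _simulate_kernel(
    S, obs_times, seed,
    km, alpha, Bmax, pdcrit, hill_n, n_delay,
    tau_m, tau_p, kp1, kp7,
    gm1, gm7, gp1, gp7, gp17, kb, ku,
    shared_burst, degrade_intermediates,
):
    """Exact Gillespie evolution of the state vector S, recording at
    obs_times.  Returns (records, absorbed_flag)."""
    np.random.seed(seed)
    n = n_delay
    i_m1n = n
    i_m7n = 2 * n + 1
    i_p1 = 3 * n + 2
    i_p7 = 4 * n + 3
    i_p17 = 4 * n + 4
    lo_m1, lo_m7 = 0, n + 1
    lo_p1, lo_p7 = 2 * n + 2, 3 * n + 3

    n_obs = obs_times.shape[0]
    out = np.zeros((n_obs, S.shape[0]), dtype=np.int64)
    a = np.zeros(20)
    t = 0.0
    k = 0
    absorbed = False
    rate_mc = n / tau_m if tau_m > 0.0 else 0.0
    rate_pc = n / tau_p if tau_p > 0.0 else 0.0

    while k < n_obs:
        sum_m1c = 0.0
        sum_m7c = 0.0
        sum_p1c = 0.0
        sum_p7c = 0.0
        for j in range(n):
            sum_m1c += S[lo_m1 + j]
            sum_m7c += S[lo_m7 + j]
            sum_p1c += S[lo_p1 + j]
            sum_p7c += S[lo_p7 + j]

        a[0] = km * (1.0 - alpha)
        a[1] = km * (1.0 - alpha)
        a[2] = km * alpha
        a[3] = rate_mc * sum_m1c
        a[4] = rate_mc * sum_m7c
        a[5] = rate_pc * sum_p1c
        a[6] = rate_pc * sum_p7c
        a[7] = kp1 * S[i_m1n]
        a[8] = kp7 * S[i_m7n]
        a[9] = gm1 * S[i_m1n]
        a[10] = gm7 * S[i_m7n]
        a[11] = gp1 * S[i_p1]
        a[12] = gp7 * S[i_p7]
        a[13] = gp17 * S[i_p17]
        a[14] = kb * S[i_p1] * S[i_p7]
        a[15] = ku * S[i_p17]
        if degrade_intermediates:
            a[16] = gm1 * sum_m1c
            a[17] = gm7 * sum_m7c
            a[18] = gp1 * sum_p1c
            a[19] = gp7 * sum_p7c

        total = 0.0
        for c in range(20):
            total += a[c]
        if total <= 0.0:
            # absorbing state: nothing can ever fire again
            while k < n_obs:
                out[k] = S
                k += 1
            absorbed = True
            break

        u = np.random.random()
        if u <= 0.0:
            u = 1e-300
        t_new = t - np.log(u) / total
        while k < n_obs and obs_times[k] < t_new:
            out[k] = S
            k += 1
        if k >= n_obs:
            break
        t = t_new

        r = np.random.random() * total
        ch = 0
        acc = a[0]
        while r >= acc and ch < 19:
            ch += 1
            acc += a[ch]

        if ch <= 2:
            f = 1.0 / (1.0 + (S[i_p17] / pdcrit) ** hill_n)
            mb = Bmax * f
            if ch == 0:
                b = _draw_burst_nb(mb)
                if tau_m > 0.0:
                    S[lo_m1] += b
                else:
                    S[i_m1n] += b
            elif ch == 1:
                b = _draw_burst_nb(mb)
                if tau_m > 0.0:
                    S[lo_m7] += b
                else:
                    S[i_m7n] += b
            else:
                b1 = _draw_burst_nb(mb)
                b7 = b1 if shared_burst else _draw_burst_nb(mb)
                if tau_m > 0.0:
                    S[lo_m1] += b1
                    S[lo_m7] += b7
                else:
                    S[i_m1n] += b1
                    S[i_m7n] += b7
        elif ch == 3:
            j = _pick_stage_nb(S, lo_m1, n, np.random.random() * sum_m1c)
            S[lo_m1 + j] -= 1
            if j == n - 1:
                S[i_m1n] += 1
            else:
                S[lo_m1 + j + 1] += 1
        elif ch == 4:
            j = _pick_stage_nb(S, lo_m7, n, np.random.random() * sum_m7c)
            S[lo_m7 + j] -= 1
            if j == n - 1:
                S[i_m7n] += 1
            else:
                S[lo_m7 + j + 1] += 1
        elif ch == 5:
            j = _pick_stage_nb(S, lo_p1, n, np.random.random() * sum_p1c)
            S[lo_p1 + j] -= 1
            if j == n - 1:
                S[i_p1] += 1
            else:
                S[lo_p1 + j + 1] += 1
        elif ch == 6:
            j = _pick_stage_nb(S, lo_p7, n, np.random.random() * sum_p7c)
            S[lo_p7 + j] -= 1
            if j == n - 1:
                S[i_p7] += 1
            else:
                S[lo_p7 + j + 1] += 1
        elif ch == 7:
            if tau_p > 0.0:
                S[lo_p1] += 1
            else:
                S[i_p1] += 1
        elif ch == 8:
            if tau_p > 0.0:
                S[lo_p7] += 1
            else:
                S[i_p7] += 1
        elif ch == 9:
            S[i_m1n] -= 1
        elif ch == 10:
            S[i_m7n] -= 1
        elif ch == 11:
            S[i_p1] -= 1
        elif ch == 12:
            S[i_p7] -= 1
        elif ch == 13:
            S[i_p17] -= 1
        elif ch == 14:
            S[i_p1] -= 1
            S[i_p7] -= 1
            S[i_p17] += 1
        elif ch == 15:
            S[i_p17] -= 1
            S[i_p1] += 1
            S[i_p7] += 1
        elif ch == 16:
            j = _pick_stage_nb(S, lo_m1, n, np.random.random() * sum_m1c)
            S[lo_m1 + j] -= 1
        elif ch == 17:
            j = _pick_stage_nb(S, lo_m7, n, np.random.random() * sum_m7c)
            S[lo_m7 + j] -= 1
        elif ch == 18:
            j = _pick_stage_nb(S, lo_p1, n, np.random.random() * sum_p1c)
            S[lo_p1 + j] -= 1
        elif ch == 19:
            j = _pick_stage_nb(S, lo_p7, n, np.random.random() * sum_p7c)
            S[lo_p7 + j] -= 1

    return out, absorbed


@dataclass
class CellTrajectory:
    """Recorded observations of one simulated cell."""

    times: np.ndarray          # observation times (min)
    states: np.ndarray         # (n_obs, state_size) species counts
    params: SimParams
    seed: int
    absorbed: bool = False

    def _col(self, idx: int) -> np.ndarray:
        return self.states[:, idx]

    @property
    def m1n(self) -> np.ndarray:
        return self._col(self.params.n_delay)

    @property
    def m7n(self) -> np.ndarray:
        return self._col(2 * self.params.n_delay + 1)

    @property
    def p1(self) -> np.ndarray:
        return self._col(3 * self.params.n_delay + 2)

    @property
    def p7(self) -> np.ndarray:
        return self._col(4 * self.params.n_delay + 3)

    @property
    def p17(self) -> np.ndarray:
        return self._col(4 * self.params.n_delay + 4)


def _obs_times(params: SimParams) -> np.ndarray:
    return np.arange(params.T0, params.Tmax + 1e-9, params.dt_obs)


def simulate_cell(params: SimParams, seed: int,
                  initial_state: SimState | None = None) -> CellTrajectory:
    """Run one cell with the exact Gillespie kernel; deterministic in seed."""
    obs = _obs_times(params)
    S = (initial_state.to_vector() if initial_state is not None
         else SimState.zero(params).to_vector()).copy()
    out, absorbed = _simulate_kernel(
        S, obs, np.uint32(seed & 0xFFFFFFFF),
        params.km, params.alpha, params.Bmax, params.pdcrit,
        float(params.hill_n), params.n_delay,
        params.tau_m, params.tau_p, params.kp1, params.kp7,
        params.gamma_m1, params.gamma_m7, params.gamma_p1, params.gamma_p7,
        params.gamma_p17, params.kb, params.ku,
        params.shared_burst_size, params.degrade_intermediates,
    )
    return CellTrajectory(times=obs, states=out, params=params, seed=seed,
                          absorbed=absorbed)


@dataclass
class PopulationSnapshots:
    """Mature mRNA counts of every cell at every observation time."""

    times: np.ndarray   # (n_obs,)
    m1: np.ndarray      # (n_obs, n_cells)
    m7: np.ndarray
    params: SimParams
    seed: int

    @property
    def n_cells(self) -> int:
        return self.m1.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n_obs, n_cells = self.m1.shape
        return pd.DataFrame({
            "time": np.repeat(self.times, n_cells),
            "cell": np.tile(np.arange(n_cells), n_obs),
            "m1": self.m1.ravel(),
            "m7": self.m7.ravel(),
        })


def simulate_population(params: SimParams, n_cells: int,
                        seed: int) -> PopulationSnapshots:
    """Run ``n_cells`` independent cells from the same initial condition.

    Per-cell seeds are derived from a master :class:`numpy.random.SeedSequence`,
    so the population is reproducible and cells are statistically independent.
    """
    if n_cells < 2:
        raise ValidationError("a population needs n_cells >= 2 "
                              "(variability is undefined for one cell)")
    obs = _obs_times(params)
    cell_seeds = np.random.SeedSequence(seed).generate_state(n_cells)
    m1 = np.empty((obs.size, n_cells), dtype=np.int64)
    m7 = np.empty((obs.size, n_cells), dtype=np.int64)
    for i in range(n_cells):
        traj = simulate_cell(params, int(cell_seeds[i]))
        m1[:, i] = traj.m1n
        m7[:, i] = traj.m7n
    return PopulationSnapshots(times=obs, m1=m1, m7=m7, params=params, seed=seed)


def sim_variability_curve(snapshots: PopulationSnapshots,
                          n_bins: int = 5) -> BinnedCurve:
    """Bin per-time-point variability by population-mean total mRNA.

    At each observation time, correlated and uncorrelated variability are
    computed across cells (m1 vs m7 vectors); time points are then grouped
    into ``n_bins`` quantile bins of mean total mRNA and averaged.  Time
    points where either gene's population mean is zero are skipped.
    """
    rows = []
    for i, t in enumerate(snapshots.times):
        x = snapshots.m1[i].astype(float)
        y = snapshots.m7[i].astype(float)
        if x.mean() <= 0 or y.mean() <= 0:
            continue
        corr = correlated_variability(x, y)
        unc = uncorrelated_variability(x, y)
        rows.append((f"t{i}", float(x.mean() + y.mean()), corr, unc, corr + unc))
    if len(rows) < n_bins:
        raise ValidationError(
            f"only {len(rows)} usable time points; need >= n_bins={n_bins}"
        )
    points = pd.DataFrame(
        rows, columns=["slice_key", "mean_her", "correlated", "uncorrelated",
                       "total"]
    )
    return BinnedCurve(**{
        **bin_curve(points, n_bins=n_bins).__dict__,
        "genotype": "simulation",
    })


def deletion_mutant(params: SimParams) -> SimParams:
    """Heterozygous locus-deletion parameterisation: halve Bmax.

    With perfectly correlated firing of the two homologous alleles, removing
    one chromosome copy halves the maximum burst size and leaves every other
    parameter untouched.
    """
    return replace(params, Bmax=params.Bmax / 2.0)


def chain_transit_times(n_delay: int, tau: float, n_tracers: int,
                        seed: int) -> np.ndarray:
    """Transit times of single tracer molecules through a delay chain.

    Each tracer starts at the head of an otherwise empty mRNA chain with
    every other reaction switched off and is stepped with
    :func:`gillespie_step` until it matures.  The transit time is Erlang:
    mean ``tau``, variance ``tau^2 / n_delay``.
    """
    params = SimParams(
        km=0.0, alpha=0.0, Bmax=0.0, kp1=0.0, kp7=0.0, kb=0.0, ku=0.0,
        n_delay=n_delay, tau_m=tau, tau_p=tau, T0=0.0, Tmax=1.0,
    )
    rng = np.random.default_rng(seed)
    times = np.empty(n_tracers)
    for i in range(n_tracers):
        state = SimState.zero(params)
        state.m1_chain[0] = 1
        while state.m1_chain.sum() > 0:
            state = gillespie_step(state, params, rng)
        times[i] = state.t
    return times
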