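"""Piecewise-constant rate model for the fossilized birth-death (FBD) process.

The FBD process runs from an origin (or crown) age toward the present.  Time is
measured as *age*: the present is 0 and ages increase into the past.  The time
axis is divided into ``l`` intervals by ages ``t_1 > t_2 > ... > t_l = 0``;
interval ``i`` spans ``[t_{i-1}, t_i)`` in age and carries a birth rate
``lambda_i`` (speciation events per lineage per time unit), a death rate
``mu_i`` (extinctions) and a fossil-recovery rate ``psi_i`` (fossil
observations).  At each boundary age ``t_i`` every lineage alive at that moment
is additionally sampled with probability ``rho_i``; ``rho_l`` is the sampling
probability of extant taxa at the present.

Two functions drive every density computation:

``p_i(t)``
    probability that a single lineage alive at age ``t`` (in interval ``i``)
    leaves *no* sampled descendant (neither a fossil nor a sampled extant tip).

``q_i(t)``
    the per-interval branch density factor, normalised so ``q_i(t_i) = 1``.

Both have closed forms in terms of the per-interval constants

    A_i = sqrt((lambda_i - mu_i - psi_i)^2 + 4 lambda_i psi_i)
    B_i = ((1 - 2 (1 - rho_i) p_{i+1}(t_i)) lambda_i + mu_i + psi_i) / A_i

obtained by a backward recursion from the present (``p_{l+1}(t_l) = 1``).
All branch factors are handled in log space; the exponent ``A_i (t_i - t)`` is
non-positive for ages inside interval ``i``, so the closed forms never
overflow.  The degenerate limit ``A_i -> 0`` (critical process with no fossil
sampling) is evaluated analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateSkyline",
    "CanonicalParams",
    "params_to_rates",
    "rates_to_params",
    "diversified_F",
    "EQUAL_RATE_TOL",
]

#: below this value the A_i -> 0 / lambda_k -> mu_k limits are used
EQUAL_RATE_TOL = 1e-9


# ---------------------------------------------------------------------------
# (d, r, s) <-> (lambda, mu, psi) transforms
# ---------------------------------------------------------------------------

def params_to_rates(d, r, s):
    """Map (net diversification, turnover, fossil-sampling proportion) to rates.

    ``d = lambda - mu``, ``r = mu / lambda`` and ``s = psi / (mu + psi)``, so

        lambda = d / (1 - r),   mu = d r / (1 - r),   psi = mu s / (1 - s).

    Requires ``d > 0``, ``0 <= r < 1`` and ``0 <= s < 1``.
    """
    d = np.asarray(d, dtype=float)
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(d <= 0):
        raise ValueError("net diversification d must be positive")
    if np.any((r < 0) | (r >= 1)):
        raise ValueError("turnover r must lie in [0, 1)")
    if np.any((s < 0) | (s >= 1)):
        raise ValueError("fossil sampling proportion s must lie in [0, 1)")
    birth = d / (1.0 - r)
    death = d * r / (1.0 - r)
    fossil = death * s / (1.0 - s)
    return birth, death, fossil


def rates_to_params(birth, death, fossil):
    """Inverse of :func:`params_to_rates` (exact round trip for d > 0)."""
    birth = np.asarray(birth, dtype=float)
    death = np.asarray(death, dtype=float)
    fossil = np.asarray(fossil, dtype=float)
    if np.any(birth <= 0):
        raise ValueError("birth rate must be positive")
    d = birth - death
    r = death / birth
    denom = death + fossil
    s = np.where(denom > 0, fossil / np.where(denom > 0, denom, 1.0), 0.0)
    return d, r, s


@dataclass(frozen=True)
class CanonicalParams:
    """Per-interval (d, r, s) parameter vector used by the samplers."""

    d: np.ndarray
    r: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "d", np.atleast_1d(np.asarray(self.d, float)))
        object.__setattr__(self, "r", np.atleast_1d(np.asarray(self.r, float)))
        object.__setattr__(self, "s", np.atleast_1d(np.asarray(self.s, float)))
        if not (self.d.shape == self.r.shape == self.s.shape):
            raise ValueError("d, r, s must have equal lengths")

    def to_rates(self):
        return params_to_rates(self.d, self.r, self.s)

    @classmethod
    def from_rates(cls, birth, death, fossil):
        return cls(*rates_to_params(birth, death, fossil))


# ---------------------------------------------------------------------------
# The skyline itself
# ---------------------------------------------------------------------------

class RateSkyline:
    """Immutable piecewise-constant (lambda, mu, psi, rho) specification.

    Parameters
    ----------
    birth, death, fossil : array-like, length l
        Per-interval rates; ``birth`` must be positive, the others
        non-negative.
    sampling : array-like, length l
        Event-sampling probabilities ``rho_i`` at ages ``t_1..t_l``;
        ``sampling[-1]`` is the extant sampling probability.
    shift_ages : array-like, length l
        The interval boundary ages ``t_1 > t_2 > ... > t_l = 0``.
    condition_age : float, optional
        Upper age bound ``t_0`` (the conditioning age).  ``inf`` (default)
        leaves interval 1 unbounded above, which is the natural choice when
        the root age itself is a random variable.
    """

    __slots__ = ("birth", "death", "fossil", "sampling", "shift_ages",
                 "condition_age", "_A", "_C", "_p_below", "_logq_below",
                 "_asc_interior")

    def __init__(self, birth, death, fossil, sampling, shift_ages,
                 condition_age=np.inf):
        self.birth = np.atleast_1d(np.asarray(birth, dtype=float))
        self.death = np.atleast_1d(np.asarray(death, dtype=float))
        self.fossil = np.atleast_1d(np.asarray(fossil, dtype=float))
        self.sampling = np.atleast_1d(np.asarray(sampling, dtype=float))
        self.shift_ages = np.atleast_1d(np.asarray(shift_ages, dtype=float))
        self.condition_age = float(condition_age)
        l = self.l
        for name, arr in (("death", self.death), ("fossil", self.fossil),
                          ("sampling", self.sampling),
                          ("shift_ages", self.shift_ages)):
            if arr.shape != (l,):
                raise ValueError(f"{name} must have length {l}")
        if np.any(self.birth <= 0):
            raise ValueError("birth rates must be positive")
        if np.any(self.death < 0) or np.any(self.fossil < 0):
            raise ValueError("death and fossil rates must be non-negative")
        if np.any((self.sampling < 0) | (self.sampling > 1)):
            raise ValueError("sampling probabilities must lie in [0, 1]")
        if self.shift_ages[-1] != 0.0:
            raise ValueError("the youngest boundary t_l must be 0 (present)")
        if np.any(np.diff(self.shift_ages) >= 0):
            raise ValueError("shift ages must be strictly decreasing")
        if self.condition_age <= self.shift_ages[0]:
            raise ValueError("condition age t_0 must exceed t_1")
        # ascending interior boundaries t_{l-1} .. t_1, used by interval_index
        self._asc_interior = self.shift_ages[:-1][::-1].copy()
        self._recurse_coefficients()

    # -- basic introspection -------------------------------------------------

    @property
    def l(self) -> int:
        """Number of intervals."""
        return len(self.birth)

    @property
    def boundaries(self) -> np.ndarray:
        """Full boundary vector ``(t_0, t_1, ..., t_l)``."""
        return np.concatenate(([self.condition_age], self.shift_ages))

    @classmethod
    def constant(cls, birth, death, fossil, sampling, condition_age=np.inf):
        """Single-interval skyline with extant sampling probability."""
        return cls([birth], [death], [fossil], [sampling], [0.0],
                   condition_age=condition_age)

    def __repr__(self):  # pragma: no cover - debugging aid
        return (f"RateSkyline(l={self.l}, birth={self.birth}, "
                f"death={self.death}, fossil={self.fossil}, "
                f"sampling={self.sampling}, shift_ages={self.shift_ages})")

    # -- coefficients --------------------------------------------------------

    def _recurse_coefficients(self):
        l = self.l
        A = np.sqrt((self.birth - self.death - self.fossil) ** 2
                    + 4.0 * self.birth * self.fossil)
        C = np.empty(l)
        p_below = np.empty(l)       # p_below[i-1] = p_{i+1}(t_i)
        logq_below = np.zeros(l)    # logq_below[i-1] = log q_{i+1}(t_i)
        pb = 1.0                    # p_{l+1}(t_l) = 1
        self._A, self._C = A, C
        for i in range(l - 1, -1, -1):
            p_below[i] = pb
            C[i] = ((1.0 - 2.0 * (1.0 - self.sampling[i]) * pb) * self.birth[i]
                    + self.death[i] + self.fossil[i])
            if i > 0:
                # value of p_i at its older boundary t_{i-1}, feeding B_{i-1}
                pb, lq = self._pq(np.array([i + 1]),
                                  np.array([self.shift_ages[i - 1]]))
                pb = float(pb[0])
                logq_below[i - 1] = float(lq[0])
        self._p_below = p_below
        self._logq_below = logq_below

    @property
    def A(self) -> np.ndarray:
        """Per-interval ``A_i = sqrt((lambda-mu-psi)^2 + 4 lambda psi)``."""
        return self._A

    @property
    def B(self) -> np.ndarray:
        """Per-interval ``B_i = C_i / A_i`` (inf-safe only when A_i > 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self._C / self._A

    @property
    def p_below_boundary(self) -> np.ndarray:
        """``p_{i+1}(t_i)`` for i = 1..l (the last entry is 1)."""
        return self._p_below

    @property
    def log_q_below_boundary(self) -> np.ndarray:
        """``log q_{i+1}(t_i)`` for i = 1..l (the last entry is 0)."""
        return self._logq_below

    # -- interval lookup -----------------------------------------------------

    def interval_index(self, t):
        """1-based interval index ``I(t)``: the unique i with t_i < t <= t_{i-1}.

        A boundary age belongs to the younger-side interval (strict
        inequality on the young side); ``t = 0`` maps to ``l``.
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0) or np.any(t_arr > self.condition_age):
            raise ValueError("age outside [0, t_0]")
        idx = self.l - np.searchsorted(self._asc_interior, t_arr, side="left")
        return int(idx[0]) if np.isscalar(t) or np.ndim(t) == 0 else idx

    def interval_index_unchecked(self, ages: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`interval_index` without domain validation."""
        return self.l - np.searchsorted(self._asc_interior, ages, side="left")

    # -- p and q -------------------------------------------------------------

    def _pq(self, iv1, t):
        """Evaluate (p, log q) for ages ``t`` with 1-based interval ids ``iv1``."""
        i0 = iv1 - 1
        lam = self.birth[i0]
        mu = self.death[i0]
        psi = self.fossil[i0]
        A = self._A[i0]
        C = self._C[i0]
        dt = self.shift_ages[i0] - t          # t_i - t <= 0
        e = np.exp(A * dt)
        safe_A = np.where(A > EQUAL_RATE_TOL, A, 1.0)
        # w = (1 - e^{A dt}) / A, with its A -> 0 limit -dt
        w = np.where(A > EQUAL_RATE_TOL, -np.expm1(A * dt) / safe_A, -dt)
        v = (1.0 + e) + C * w                 # (1+B) + (1-B) e^{A dt}, times 1
        logq = np.log(4.0) + A * dt - 2.0 * np.log(v)
        p = (lam + mu + psi - (A * (1.0 - e) + C * (1.0 + e)) / v) / (2.0 * lam)
        return p, logq

    def p_hat(self, t):
        """Probability that a lineage alive at age ``t`` has no sampled descendant."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        iv = np.atleast_1d(self.interval_index(t_arr))
        p, _ = self._pq(iv, t_arr)
        p = np.clip(p, 0.0, 1.0)
        return float(p[0]) if np.ndim(t) == 0 else p

    def log_q_hat(self, t):
        """``log q_{I(t)}(t)``, the per-interval branch density factor."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        iv = np.atleast_1d(self.interval_index(t_arr))
        _, lq = self._pq(iv, t_arr)
        return float(lq[0]) if np.ndim(t) == 0 else lq

    def pq_at(self, t, iv=None):
        """Vectorised (p, log q) evaluation; ``iv`` may carry cached indices."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if iv is None:
            iv = np.atleast_1d(self.interval_index(t_arr))
        return self._pq(np.asarray(iv), t_arr)

    # -- derived skylines ----------------------------------------------------

    def insert_boundary(self, age, sampling=0.0):
        """Return a new skyline with an extra boundary at ``age`` (rho given).

        The interval containing ``age`` is split; both halves keep its rates.
        With ``sampling=0`` the density of any tree is unchanged (seam
        invisibility).
        """
        age = float(age)
        if age <= 0 or age >= self.condition_age:
            raise ValueError("new boundary must lie strictly inside (0, t_0)")
        if np.any(np.isclose(self.shift_ages, age, rtol=1e-12, atol=0.0)):
            raise ValueError("boundary already present")
        i0 = self.interval_index(age) - 1
        def ins(arr, value):
            return np.concatenate([arr[:i0], [value], arr[i0:]])
        return RateSkyline(
            ins(self.birth, self.birth[i0]),
            ins(self.death, self.death[i0]),
            ins(self.fossil, self.fossil[i0]),
            ins(self.sampling, sampling),
            ins(self.shift_ages, age),
            condition_age=self.condition_age,
        )

    def with_extant_sampling(self, rho_l):
        """Return a copy with the extant sampling probability replaced."""
        sampling = self.sampling.copy()
        sampling[-1] = rho_l
        return RateSkyline(self.birth, self.death, self.fossil, sampling,
                           self.shift_ages, condition_age=self.condition_age)


# ---------------------------------------------------------------------------
# Diversified sampling: expected clade-size generating function F
# ---------------------------------------------------------------------------

def diversified_F(skyline: RateSkyline, t: float) -> float:
    """Evaluate ``F(t)`` for the diversified-sampling correction.

    ``1 - 1/F(x_cut)`` is the probability that a lineage alive at the cutoff
    age leaves more than one extant descendant; the sampled tree's density
    under diversified sampling is the complete-sampling density times
    ``(1 - 1/F(x_cut))**eta_l`` with ``eta_l`` unsampled extant taxa.

    ``t`` must coincide with an interval boundary (it is the older edge
    ``t_{i-1}`` of the interval it heads); fossil and rho sampling play no
    role in ``F``, only birth and death rates below ``t`` do.
    """
    t = float(t)
    if t == 0.0:
        return 1.0
    matches = np.flatnonzero(np.isclose(skyline.shift_ages, t,
                                        rtol=1e-9, atol=1e-12))
    if len(matches) != 1:
        raise ValueError(
            "F(t) is defined at skyline boundaries only; insert a boundary "
            f"at age {t} first")
    # t == t_{i-1} with i-1 = matches[0]+1 (1-based), so the sum runs over
    # intervals i..l, i.e. 0-based indices matches[0]+1 .. l-1
    k0 = int(matches[0]) + 1
    lam = skyline.birth[k0:]
    mu = skyline.death[k0:]
    upper = np.concatenate(([t], skyline.shift_ages[k0:-1]))
    dur = upper - skyline.shift_ages[k0:]
    net = lam - mu
    # growth factor accumulated over the intervals *below* interval k
    tail = np.concatenate((np.cumsum((net * dur)[::-1])[::-1][1:], [0.0]))
    with np.errstate(over="raise"):
        grow = np.where(np.abs(net) > EQUAL_RATE_TOL,
                        lam / np.where(np.abs(net) > EQUAL_RATE_TOL, net, 1.0)
                        * np.expm1(np.where(np.abs(net) > EQUAL_RATE_TOL,
                                            net, 0.0) * dur),
                        lam * dur)
        G = grow * np.exp(tail)
    return float(1.0 + np.sum(G))
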