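"""Exact log-density of an FBD tree under the piecewise-constant FBD process.

The density of an *oriented* tree conditioned on its crown age ``x_1`` is

    f(T | x_1) = q_{1}(x_1)^2 / (1 - p_1(x_1))^2
               * prod_{sampled ancestors} psi_{I(y)}
               * prod_{non-root branchings} lambda_{I(x)} q_{I(x)}(x)
               * prod_{fossil tips} psi_{I(y)} p_{I(y)}(y) / q_{I(y)}(y)
               * prod_i [(1-rho_i) q_{i+1}(t_i)]^{n_i} rho_i^{N_i}
                        q_{i+1}(t_i)^{K_i} p_{i+1}(t_i)^{M_i}

with p, q and I(t) as in :mod:`fbdsky.skyline`.  Conditioning on the stem
(origin) age ``x_0`` instead replaces the first factor by
``q_1(x_0) / (1 - p_1(x_0))`` and includes the root branching in the product.
The density is *not* conditioned on the number of extant taxa.

Under diversified sampling of extant taxa exactly one extant descendant of
each lineage crossing the cutoff age ``x_cut`` is kept.  The tree density is
then the complete-sampling density (extant sampling probability 1) times
``(1 - 1/F(x_cut))**eta_l`` where ``eta_l`` counts the unsampled extant taxa.
The cutoff must coincide with a skyline boundary carrying rho = 0, with zero
fossil-recovery rate below it.

Densities are for oriented trees; :func:`oriented_to_labeled` supplies the
log conversion factor ``2^(m+M-1) / (m+M+k+K)!`` to labeled trees.  Everything
is computed and returned in log space; an impossible observation (e.g. a
rate-sampled fossil in an interval with psi = 0) yields ``-inf`` rather than
an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .skyline import RateSkyline, diversified_F
from .tree import FBDTree

__all__ = [
    "TreeStatistics",
    "compute_tree_statistics",
    "log_density_crown",
    "log_density_stem",
    "log_density_diversified",
    "oriented_to_labeled",
    "CrownDensityEvaluator",
]

_HORIZON_ATOL = 1e-9


@dataclass
class TreeStatistics:
    """Per-interval sampling counts and the node-age arrays of a tree.

    The count vectors follow the field notation: ``m_i``/``k_i`` are
    rate-sampled fossil tips/ancestors with ages inside interval i, ``M_i`` /
    ``K_i`` are tips/ancestors sampled exactly at boundary age ``t_i``
    (``M_l`` counts the extant tips), ``N_i = M_i + K_i`` and ``n_i`` is the
    number of lineages crossing ``t_i`` without being sampled there.
    """

    l: int
    m_i: np.ndarray
    k_i: np.ndarray
    M_i: np.ndarray
    K_i: np.ndarray
    n_i: np.ndarray
    # node-age arrays with 1-based interval indices, used by the density
    branching_ages: np.ndarray = field(default_factory=lambda: np.empty(0))
    branching_iv: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    anc_ages: np.ndarray = field(default_factory=lambda: np.empty(0))
    anc_iv: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    tip_fossil_ages: np.ndarray = field(default_factory=lambda: np.empty(0))
    tip_fossil_iv: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    root_age: float = 0.0
    origin_age: float | None = None
    root_is_branching: bool = True

    @property
    def N_i(self) -> np.ndarray:
        return self.M_i + self.K_i

    @property
    def m(self) -> int:
        return int(self.m_i.sum())

    @property
    def k(self) -> int:
        return int(self.k_i.sum())

    @property
    def M(self) -> int:
        return int(self.M_i.sum())

    @property
    def K(self) -> int:
        return int(self.K_i.sum())


def compute_tree_statistics(tree: FBDTree, skyline: RateSkyline,
                            include_stem: bool = False) -> TreeStatistics:
    """Tally sampling counts and node ages of ``tree`` against ``skyline``.

    Horizon (rho) samples are recognised by their explicit flag; a fossil
    whose flag and age disagree with the skyline boundaries raises.  With
    ``include_stem`` the origin-to-root segment contributes to the crossing
    counts ``n_i`` (stem conditioning).
    """
    l = skyline.l
    t_shift = skyline.shift_ages
    M_i = np.zeros(l, dtype=int)
    K_i = np.zeros(l, dtype=int)

    branch_ages, anc_ages, tip_ages = [], [], []
    child_ages, parent_ages = [], []

    top_age = tree.origin_age if (include_stem and tree.origin_age is not None) \
        else tree.root.age
    if top_age > skyline.condition_age:
        raise ValueError("tree extends beyond the skyline condition age t_0")

    root = tree.root
    for node in tree.preorder():
        fossil = node.fossil
        if fossil is not None:
            sa = (node.parent is not None and node.parent.age == node.age)
            if fossil.kind == "horizon":
                h = fossil.horizon
                if not (1 <= h <= l):
                    raise ValueError(f"horizon index {h} outside 1..{l}")
                if abs(node.age - t_shift[h - 1]) > _HORIZON_ATOL * max(1.0, node.age):
                    raise ValueError(
                        f"horizon fossil {node.label!r} at age {node.age} "
                        f"does not sit on boundary t_{h} = {t_shift[h - 1]}")
                if sa:
                    K_i[h - 1] += 1
                else:
                    M_i[h - 1] += 1
            elif sa:
                anc_ages.append(node.age)
            else:
                tip_ages.append(node.age)
        elif not node.children:
            M_i[l - 1] += 1  # extant tip sampled at the present
        elif node.sa_child is None and node is not root:
            branch_ages.append(node.age)
        if node.parent is not None:
            child_ages.append(node.age)
            parent_ages.append(node.parent.age)
    if include_stem:
        child_ages.append(root.age)
        parent_ages.append(top_age)

    # crossing counts: a branch crosses t_i iff child age < t_i < parent age
    ca = np.asarray(child_ages)
    pa = np.asarray(parent_ages)
    n_i = np.zeros(l, dtype=int)
    for j in range(l - 1):
        tb = t_shift[j]
        n_i[j] = int(np.count_nonzero((ca < tb) & (tb < pa)))

    branch_ages = np.asarray(branch_ages, dtype=float)
    anc_ages = np.asarray(anc_ages, dtype=float)
    tip_ages = np.asarray(tip_ages, dtype=float)
    iv = skyline.interval_index_unchecked
    k_i = np.bincount(iv(anc_ages) - 1, minlength=l) if anc_ages.size else \
        np.zeros(l, dtype=int)
    m_i = np.bincount(iv(tip_ages) - 1, minlength=l) if tip_ages.size else \
        np.zeros(l, dtype=int)
    return TreeStatistics(
        l=l, m_i=m_i, k_i=k_i, M_i=M_i, K_i=K_i, n_i=n_i,
        branching_ages=branch_ages,
        branching_iv=iv(branch_ages) if branch_ages.size else np.empty(0, int),
        anc_ages=anc_ages,
        anc_iv=iv(anc_ages) if anc_ages.size else np.empty(0, int),
        tip_fossil_ages=tip_ages,
        tip_fossil_iv=iv(tip_ages) if tip_ages.size else np.empty(0, int),
        root_age=tree.root.age,
        origin_age=tree.origin_age,
        root_is_branching=bool(tree.root.children)
        and not tree.root.is_attachment,
    )


def oriented_to_labeled(stats: TreeStatistics) -> float:
    """Log factor converting an oriented-tree density to a labeled-tree one.

    Equals ``(m+M-1) log 2 - log((m+M+k+K)!)``.
    """
    tips = stats.m + stats.M
    samples = tips + stats.k + stats.K
    return (tips - 1) * np.log(2.0) - float(gammaln(samples + 1))


def _shared_terms(stats: TreeStatistics, sky: RateSkyline) -> float:
    """Log of all density factors common to crown and stem conditioning."""
    ll = 0.0
    # non-root true branchings: lambda * q at each age
    if stats.branching_ages.size:
        lam = sky.birth[stats.branching_iv - 1]
        _, lq = sky.pq_at(stats.branching_ages, stats.branching_iv)
        ll += float(np.sum(np.log(lam)) + np.sum(lq))
    # rate-sampled ancestors: psi
    if stats.anc_ages.size:
        psi = sky.fossil[stats.anc_iv - 1]
        if np.any(psi == 0.0):
            return -np.inf
        ll += float(np.sum(np.log(psi)))
    # rate-sampled fossil tips: psi * p / q
    if stats.tip_fossil_ages.size:
        psi = sky.fossil[stats.tip_fossil_iv - 1]
        if np.any(psi == 0.0):
            return -np.inf
        p, lq = sky.pq_at(stats.tip_fossil_ages, stats.tip_fossil_iv)
        if np.any(p == 0.0):
            return -np.inf
        ll += float(np.sum(np.log(psi)) + np.sum(np.log(p)) - np.sum(lq))
    # boundary factors
    rho = sky.sampling
    n_i = stats.n_i
    N_i = stats.N_i
    with np.errstate(divide="ignore"):
        log_rho = np.where(N_i > 0, np.log(np.where(rho > 0, rho, 1.0)), 0.0)
        if np.any((N_i > 0) & (rho == 0.0)):
            return -np.inf
        log_1mrho = np.where(n_i > 0,
                             np.log(np.where(rho < 1, 1.0 - rho, 1.0)), 0.0)
        if np.any((n_i > 0) & (rho == 1.0)):
            return -np.inf
        pb = sky.p_below_boundary
        log_pb = np.where(stats.M_i > 0, np.log(np.where(pb > 0, pb, 1.0)), 0.0)
        if np.any((stats.M_i > 0) & (pb == 0.0)):
            return -np.inf
    ll += float(np.sum(n_i * (log_1mrho + sky.log_q_below_boundary)))
    ll += float(np.sum(N_i * log_rho))
    ll += float(np.sum(stats.K_i * sky.log_q_below_boundary))
    ll += float(np.sum(stats.M_i * log_pb))
    return ll


def log_density_crown(tree, skyline: RateSkyline,
                      stats: TreeStatistics | None = None) -> float:
    """Log density of an oriented FBD tree conditioned on its crown age.

    ``tree`` may be an :class:`FBDTree` or a precomputed
    :class:`TreeStatistics` (the skyline boundaries must then match the one
    the statistics were computed against).
    """
    if stats is None:
        stats = compute_tree_statistics(tree, skyline)
    x1 = stats.root_age
    p_root, lq_root = skyline.pq_at(np.array([x1]))
    p_root = float(p_root[0])
    if p_root >= 1.0:
        return -np.inf
    ll = 2.0 * float(lq_root[0]) - 2.0 * np.log1p(-p_root)
    shared = _shared_terms(stats, skyline)
    return ll + shared if np.isfinite(shared) else -np.inf


def log_density_stem(tree, skyline: RateSkyline,
                     stats: TreeStatistics | None = None) -> float:
    """Log density conditioned on the stem (origin) age ``x_0``.

    The stem segment contributes to the crossing counts, and the root
    branching carries a ``lambda q`` factor like any other.
    """
    if stats is None:
        if tree.origin_age is None:
            raise ValueError("stem conditioning requires an origin age")
        stats = compute_tree_statistics(tree, skyline, include_stem=True)
    x0 = stats.origin_age
    if x0 is None:
        raise ValueError("statistics lack an origin age")
    if x0 <= stats.root_age:
        raise ValueError("origin age must exceed the root age")
    p0, lq0 = skyline.pq_at(np.array([x0]))
    p0 = float(p0[0])
    if p0 >= 1.0:
        return -np.inf
    ll = float(lq0[0]) - np.log1p(-p0)
    if stats.root_is_branching:
        # under stem conditioning the root branching carries lambda q too
        x1 = stats.root_age
        iv1 = skyline.interval_index(x1)
        _, lq1 = skyline.pq_at(np.array([x1]), np.array([iv1]))
        ll += np.log(skyline.birth[iv1 - 1]) + float(lq1[0])
    shared = _shared_terms(stats, skyline)
    return ll + shared if np.isfinite(shared) else -np.inf


def log_density_diversified(tree: FBDTree, skyline: RateSkyline,
                            x_cut: float, eta_l: int,
                            condition: str = "crown") -> float:
    """Log density of an FBD tree under diversified extant sampling.

    ``skyline`` must contain a boundary at ``x_cut`` with rho = 0 and zero
    fossil-recovery rate below it; the extant sampling probability is forced
    to 1 (complete sampling of the represented lineages) and the correction
    ``eta_l * log(1 - 1/F(x_cut))`` accounts for the ``eta_l`` pruned extant
    taxa.  A tree with an internal node or fossil younger than ``x_cut``
    violates the diversified structure and raises.
    """
    if eta_l < 0:
        raise ValueError("eta_l must be non-negative")
    matches = np.flatnonzero(np.isclose(skyline.shift_ages, x_cut,
                                        rtol=1e-9, atol=1e-12))
    if len(matches) != 1:
        raise ValueError("x_cut must coincide with a skyline boundary")
    j = int(matches[0])
    if skyline.sampling[j] != 0.0:
        raise ValueError("the boundary at x_cut must carry rho = 0")
    if np.any(skyline.fossil[j + 1:] != 0.0):
        raise ValueError("fossil-recovery rate must vanish below x_cut")
    for node in tree.preorder():
        if node.children and node.age < x_cut:
            raise ValueError(
                "internal node younger than x_cut: tree violates the "
                "diversified sampling structure")
        if node.fossil is not None and node.age < x_cut:
            raise ValueError("fossil younger than x_cut")
    sky = skyline.with_extant_sampling(1.0)
    if condition == "crown":
        base = log_density_crown(tree, sky)
    elif condition == "stem":
        base = log_density_stem(tree, sky)
    else:
        raise ValueError("condition must be 'crown' or 'stem'")
    if eta_l == 0:
        return base
    F = diversified_F(sky, x_cut)
    return base + eta_l * np.log1p(-1.0 / F)


# ---------------------------------------------------------------------------
# Fast repeated evaluation on a fixed tree (prior-only chains)
# ---------------------------------------------------------------------------

import math


def _pq_scalar(lam, mu, psi, A, C, dt):
    """Scalar (p, log q) for one age with dt = t_i - t <= 0."""
    e = math.exp(A * dt)
    w = -math.expm1(A * dt) / A if A > 1e-9 else -dt
    v = (1.0 + e) + C * w
    logq = math.log(4.0) + A * dt - 2.0 * math.log(v)
    p = (lam + mu + psi - (A * (1.0 - e) + C * (1.0 + e)) / v) / (2.0 * lam)
    return p, logq


class CrownDensityEvaluator:
    """Repeated crown-conditioned density evaluation on one fixed tree.

    The tree statistics (node ages, interval assignments, boundary counts)
    are frozen at construction; each call supplies new per-interval rates and
    runs the A/B recursion with scalar arithmetic plus a single vectorised
    pass over the node ages.  Optionally adds the diversified-sampling
    correction for a fixed cutoff boundary and the orientation/labelling
    conversion factor, so the result matches
    ``log_density_crown + oriented_to_labeled`` exactly.
    """

    def __init__(self, stats: TreeStatistics, shift_ages, sampling,
                 x_cut: float | None = None, eta_l: int = 0):
        self.shift = np.asarray(shift_ages, dtype=float)
        self.rho = np.asarray(sampling, dtype=float)
        self.l = len(self.shift)
        self.stats = stats
        self.x_cut = x_cut
        self.eta_l = int(eta_l)
        if x_cut is not None:
            matches = np.flatnonzero(np.isclose(self.shift, x_cut))
            if len(matches) != 1:
                raise ValueError("x_cut must be one of the boundaries")
            self._cut_idx = int(matches[0])
        # concatenated age vector: [branchings, ancestors, fossil tips, root]
        self.ages = np.concatenate([stats.branching_ages, stats.anc_ages,
                                    stats.tip_fossil_ages, [stats.root_age]])
        self.iv0 = np.concatenate([stats.branching_iv, stats.anc_iv,
                                   stats.tip_fossil_iv,
                                   [_iv_of(stats.root_age, self.shift)]]) - 1
        nb = len(stats.branching_ages)
        na = len(stats.anc_ages)
        nt = len(stats.tip_fossil_ages)
        self.sl_br = slice(0, nb)
        self.sl_anc = slice(nb, nb + na)
        self.sl_tip = slice(nb + na, nb + na + nt)
        self.idx_root = nb + na + nt
        self.dt = self.shift[self.iv0] - self.ages
        self.conversion = oriented_to_labeled(stats)

    def __call__(self, birth, death, fossil) -> float:
        st = self.stats
        lam = np.broadcast_to(np.asarray(birth, float), (self.l,))
        mu = np.broadcast_to(np.asarray(death, float), (self.l,))
        psi = np.asarray(np.broadcast_to(np.asarray(fossil, float),
                                         (self.l,))).copy()
        if self.x_cut is not None:
            psi[self._cut_idx + 1:] = 0.0
        rho = self.rho
        l = self.l
        A = np.sqrt((lam - mu - psi) ** 2 + 4.0 * lam * psi)
        C = np.empty(l)
        pb = np.empty(l)       # p_{i+1}(t_i)
        lqb = np.zeros(l)      # log q_{i+1}(t_i)
        p_next = 1.0
        for i in range(l - 1, -1, -1):
            pb[i] = p_next
            C[i] = ((1.0 - 2.0 * (1.0 - rho[i]) * p_next) * lam[i]
                    + mu[i] + psi[i])
            if i > 0:
                p_next, lq = _pq_scalar(
                    lam[i], mu[i], psi[i], A[i], C[i],
                    self.shift[i] - self.shift[i - 1])
                lqb[i - 1] = lq

        Ai = A[self.iv0]
        Ci = C[self.iv0]
        e = np.exp(Ai * self.dt)
        safe = np.where(Ai > 1e-9, Ai, 1.0)
        w = np.where(Ai > 1e-9, -np.expm1(Ai * self.dt) / safe, -self.dt)
        v = (1.0 + e) + Ci * w
        logq = np.log(4.0) + Ai * self.dt - 2.0 * np.log(v)
        lam_i = lam[self.iv0]
        p = ((lam_i + mu[self.iv0] + psi[self.iv0]
              - (Ai * (1.0 - e) + Ci * (1.0 + e)) / v) / (2.0 * lam_i))

        p_root = p[self.idx_root]
        if p_root >= 1.0:
            return -np.inf
        ll = 2.0 * logq[self.idx_root] - 2.0 * math.log1p(-p_root)
        ll += float(np.sum(np.log(lam_i[self.sl_br])) +
                    np.sum(logq[self.sl_br]))
        psi_anc = psi[self.iv0[self.sl_anc]]
        psi_tip = psi[self.iv0[self.sl_tip]]
        if np.any(psi_anc == 0.0) or np.any(psi_tip == 0.0):
            return -np.inf
        ll += float(np.sum(np.log(psi_anc)))
        p_tip = p[self.sl_tip]
        if np.any(p_tip <= 0.0):
            return -np.inf
        ll += float(np.sum(np.log(psi_tip)) + np.sum(np.log(p_tip))
                    - np.sum(logq[self.sl_tip]))
        # boundary factors
        for i in range(l):
            n_i = st.n_i[i]
            N_i = st.M_i[i] + st.K_i[i]
            if n_i:
                if rho[i] == 1.0:
                    return -np.inf
                ll += n_i * (math.log1p(-rho[i]) + lqb[i])
            if N_i:
                if rho[i] == 0.0:
                    return -np.inf
                ll += N_i * math.log(rho[i])
            if st.K_i[i]:
                ll += st.K_i[i] * lqb[i]
            if st.M_i[i] and pb[i] != 1.0:
                if pb[i] <= 0.0:
                    return -np.inf
                ll += st.M_i[i] * math.log(pb[i])
        if self.x_cut is not None and self.eta_l:
            F = _diversified_F_values(lam, mu, self.shift, self._cut_idx)
            ll += self.eta_l * math.log1p(-1.0 / F)
        return ll + self.conversion


def _iv_of(age, shift):
    l = len(shift)
    asc = shift[:-1][::-1]
    return int(l - np.searchsorted(asc, age, side="left"))


def _diversified_F_values(lam, mu, shift, cut_idx):
    """F(x_cut) from per-interval birth/death rates below the cutoff."""
    k0 = cut_idx + 1
    lamk = lam[k0:]
    muk = mu[k0:]
    upper = np.concatenate(([shift[cut_idx]], shift[k0:-1]))
    dur = upper - shift[k0:]
    net = lamk - muk
    arr = net * dur
    tail = np.concatenate((np.cumsum(arr[::-1])[::-1][1:], [0.0]))
    grow = np.where(np.abs(net) > 1e-9,
                    lamk / np.where(np.abs(net) > 1e-9, net, 1.0)
                    * np.expm1(np.where(np.abs(net) > 1e-9, net, 0.0) * dur),
                    lamk * dur)
    return float(1.0 + np.sum(grow * np.exp(tail)))
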