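"""Metropolis-Hastings / reversible-jump sampler over FBD trees and rates.

The state consists of a labelled FBD tree (topology, node ages, fossil
attachment configurations), the canonical rate parameters (d, r, s) per rate
class, and optionally a strict-clock rate when sequence data are attached.
The posterior factorises as

    f(T, d, r, s, c | D)  ∝  f(D | T, c) f(T | rates) f(d) f(r) f(s) f(c)

with ``f(T | rates)`` the labelled-tree FBD density (oriented density times
the orientation/labelling conversion factor) conditioned on the crown age.

Tree proposals:

* **add-branch** — a sampled ancestor (chosen 1/k') becomes a fossil tip by
  drawing the new bifurcation age uniformly on ``(y_f, c_f)``; Hastings
  ratio ``k'/(m'+1)``, Jacobian ``c_f - y_f``.
* **delete-branch** — a fossil tip (chosen 1/m') is merged onto its sibling
  lineage at unchanged age, becoming a sampled ancestor; Hastings ratio
  ``m'/(k'+1)``, Jacobian ``1/(c_f - y_f)``; invalid (auto-rejected) when
  the tip fossil is younger than its sibling.
* **fossil SPR** — an ancestral fossil is re-attached at identical age to a
  uniformly chosen branch among those crossing its age (Hastings ratio 1;
  the candidate count is the same in both directions).
* **fossil slider** — slides an ancestral fossil (and its attachment) along
  its branch within the stratigraphic age bounds, with reflection
  (Hastings ratio 1); only available when the fossil has age bounds.
* **node-age / root-age moves** — uniform redraw between the adjacent node
  ages, and a reflected sliding window for the root.
* **subtree prune-and-regraft** with a uniform reattachment-age draw for
  the non-fossil topology.
* **scale / reflected-slide moves** on d, r, s and the clock rate.

Under diversified sampling the cutoff age is not a free parameter: it is
recomputed after every accepted tree change as ``(1 - 1e-6)`` times the
minimum of the youngest true branching age and the youngest fossil age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .density import (CrownDensityEvaluator, TreeStatistics,
                      compute_tree_statistics, log_density_crown,
                      oriented_to_labeled)
from .priors import PriorSpec
from .seqmodel import Alignment, TreeLikelihood
from .skyline import CanonicalParams, RateSkyline, diversified_F
from .tree import FBDNode, FBDTree

__all__ = ["FBDModel", "ChainConfig", "FBDChain", "Trace", "update_xcut",
           "run_chain"]

XCUT_EPSILON = 1e-6


def add_branch_log_hastings(k: int, m: int, c_f: float, y_f: float) -> float:
    """log of Hastings ratio k'/(m'+1) times Jacobian (c_f - y_f)."""
    return np.log(k) - np.log(m + 1) + np.log(c_f - y_f)


def delete_branch_log_hastings(m: int, k: int, c_f: float, y_f: float) -> float:
    """log of Hastings ratio m'/(k'+1) times Jacobian 1/(c_f - y_f)."""
    return np.log(m) - np.log(k + 1) - np.log(c_f - y_f)


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class FBDModel:
    """Skyline structure and extant-sampling scheme assumed by inference.

    ``shift_ages``/``sampling`` give the fixed boundary ages (ending at 0)
    and their rho values; ``n_classes`` is 1 for rates shared across all
    intervals or equal to the number of intervals for free per-interval
    rates.  Under ``sampling_mode="diversified"`` an extra boundary at the
    (tree-dependent) cutoff age is inserted with rho = 0, the fossil rate
    is zeroed below it, the extant sampling probability becomes 1, and the
    pruned-taxon correction uses ``fraction`` (the sampled proportion of
    extant taxa).
    """

    shift_ages: np.ndarray
    sampling: np.ndarray
    n_classes: int = 1
    sampling_mode: str = "random"
    fraction: float = 1.0
    condition_age: float = np.inf

    def __post_init__(self):
        self.shift_ages = np.atleast_1d(np.asarray(self.shift_ages, float))
        self.sampling = np.atleast_1d(np.asarray(self.sampling, float))
        l = len(self.shift_ages)
        if self.n_classes not in (1, l):
            raise ValueError("n_classes must be 1 or the number of intervals")
        if self.sampling_mode not in ("random", "diversified"):
            raise ValueError("sampling_mode must be 'random' or 'diversified'")
        if self.sampling_mode == "diversified" and self.n_classes != 1:
            raise ValueError("diversified sampling assumes shared rates")
        if self.sampling_mode == "diversified" and not 0 < self.fraction < 1:
            raise ValueError("diversified sampling needs fraction in (0, 1)")

    @property
    def interval_classes(self) -> np.ndarray:
        l = len(self.shift_ages)
        if self.n_classes == 1:
            return np.zeros(l, dtype=int)
        return np.arange(l, dtype=int)

    def build_skyline(self, params: CanonicalParams,
                      x_cut: Optional[float] = None) -> RateSkyline:
        lam, mu, psi = params.to_rates()
        cls = self.interval_classes
        lam_i = np.asarray(lam)[cls]
        mu_i = np.asarray(mu)[cls]
        psi_i = np.asarray(psi)[cls]
        if self.sampling_mode == "random":
            return RateSkyline(lam_i, mu_i, psi_i, self.sampling,
                               self.shift_ages, self.condition_age)
        if x_cut is None:
            raise ValueError("diversified skylines need the cutoff age")
        if np.any(np.isclose(self.shift_ages, x_cut)):
            raise ValueError("cutoff age collides with a fixed boundary")
        # insert the cutoff boundary: rho = 0 there, psi = 0 and full extant
        # sampling below it
        shifts = np.sort(np.append(self.shift_ages, x_cut))[::-1]
        rho_map = dict(zip(self.shift_ages, self.sampling))
        rho = np.array([0.0 if a == x_cut else rho_map[a] for a in shifts])
        rho[-1] = 1.0
        # rates of each new interval come from the old interval containing it
        lam_n, mu_n, psi_n = [], [], []
        uppers = np.concatenate(([np.inf], shifts[:-1]))
        for lo, hi in zip(shifts, uppers):
            if lo > 0:
                old = int(np.sum(self.shift_ages[:-1] > lo))
            else:
                old = int(np.sum(self.shift_ages[:-1] >= hi))
            old = min(old, len(self.shift_ages) - 1)
            lam_n.append(lam_i[old])
            mu_n.append(mu_i[old])
            psi_n.append(0.0 if hi <= x_cut else psi_i[old])
        return RateSkyline(lam_n, mu_n, psi_n, rho, shifts,
                           self.condition_age)


def update_xcut(tree: FBDTree, epsilon: float = XCUT_EPSILON) -> float:
    """Cutoff age just below the youngest branching and the youngest fossil."""
    ages = [n.age for n in tree.true_branchings()]
    ages += [f.age for f in tree.fossils()]
    youngest = min(ages)
    if youngest <= 0.0:
        raise ValueError("diversified sampling violated: a branching or "
                         "fossil sits at the present")
    return (1.0 - epsilon) * youngest


# ---------------------------------------------------------------------------
# Chain configuration and trace
# ---------------------------------------------------------------------------

@dataclass
class ChainConfig:
    iterations: int = 100_000
    thin: int = 200
    burnin: float = 0.25
    # relative move weights (normalised internally)
    w_params: float = 0.40
    w_node_ages: float = 0.30
    w_rj: float = 0.15          # add-branch / delete-branch, equal split
    w_fossil: float = 0.10      # fossil slider + fossil SPR
    w_topology: float = 0.05
    # tuning
    d_tune: float = 0.8
    clock_tune: float = 0.5
    rs_window: float = 0.15
    root_window: float = 2.0
    fossil_window: float = 1.0
    sample_trees: bool = False
    check_every: int = 0        # debug: cached-vs-fresh posterior check


@dataclass
class Trace:
    """Posterior samples plus bookkeeping."""

    records: pd.DataFrame
    trees: list = field(default_factory=list)
    burnin: float = 0.25
    acceptance: dict = field(default_factory=dict)

    def burned(self) -> pd.DataFrame:
        cut = int(np.floor(self.burnin * len(self.records)))
        return self.records.iloc[cut:]

    def burned_trees(self) -> list:
        cut = int(np.floor(self.burnin * len(self.trees)))
        return self.trees[cut:]


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

class FBDChain:
    """Single-chain Metropolis-Hastings sampler for the FBD posterior."""

    def __init__(self, model: FBDModel, priors: PriorSpec, tree: FBDTree,
                 params: CanonicalParams, rng: np.random.Generator,
                 alignment: Optional[Alignment] = None,
                 clock_rate: Optional[float] = None,
                 fixed_tree: bool = False,
                 config: Optional[ChainConfig] = None):
        self.model = model
        self.priors = priors
        self.tree = tree
        self.params = params
        self.rng = rng
        self.fixed_tree = fixed_tree
        self.config = config or ChainConfig()
        self.clock_rate = clock_rate
        if alignment is not None and clock_rate is None:
            raise ValueError("sequence data need an initial clock rate")
        self.likelihood = (TreeLikelihood(tree, alignment, clock_rate)
                           if alignment is not None else None)
        if not fixed_tree and priors.root_age is not None:
            # crown-conditioned inference has no origin-age parameter; the
            # simulator's recorded origin must not constrain root-age moves
            tree.origin_age = None
        self._stats: Optional[TreeStatistics] = None
        self._x_cut: Optional[float] = None
        self._refresh_tree_caches()
        self._evaluator = None
        if fixed_tree:
            # the tree statistics never change: freeze them into a fast
            # repeated-evaluation kernel
            sky0 = self.model.build_skyline(self.params, self._x_cut)
            eta = 0
            if self.model.sampling_mode == "diversified":
                f = self.model.fraction
                eta = int(round(int(self._stats.M_i[-1]) * (1 - f) / f))
            self._evaluator = CrownDensityEvaluator(
                self._stats, sky0.shift_ages, sky0.sampling,
                x_cut=self._x_cut, eta_l=eta)
        self._log_tree_prior = self._tree_prior(self.params)
        self._log_param_prior = self._param_prior(self.params, self.clock_rate)
        if not np.isfinite(self._log_tree_prior):
            raise ValueError("initial state has zero FBD prior density; "
                             "check rates, sampling scheme and tree ages")
        if not np.isfinite(self._log_param_prior):
            raise ValueError("initial parameters outside the prior support")

    # -- targets -------------------------------------------------------------

    def _refresh_tree_caches(self):
        if self.model.sampling_mode == "diversified":
            self._x_cut = update_xcut(self.tree)
        sky = self.model.build_skyline(self.params, self._x_cut)
        self._stats = compute_tree_statistics(self.tree, sky)
        self._sky_boundaries = sky.shift_ages

    def _tree_prior(self, params: CanonicalParams,
                    stats: Optional[TreeStatistics] = None) -> float:
        if self._evaluator is not None and stats is None:
            lam, mu, psi = params.to_rates()
            if self.model.n_classes == 1:
                lp = self._evaluator(float(lam[0]), float(mu[0]),
                                     float(psi[0]))
            else:
                cls = self.model.interval_classes
                lp = self._evaluator(np.asarray(lam)[cls],
                                     np.asarray(mu)[cls],
                                     np.asarray(psi)[cls])
            if self.priors.root_age is not None and np.isfinite(lp):
                lp += self.priors.root_age.logpdf(self.tree.root.age)
            return float(lp)
        stats = stats if stats is not None else self._stats
        sky = self.model.build_skyline(params, self._x_cut)
        lp = log_density_crown(None, sky, stats=stats)
        if not np.isfinite(lp):
            return -np.inf
        if self.model.sampling_mode == "diversified":
            f = self.model.fraction
            n_ext = int(stats.M_i[-1])
            eta = int(round(n_ext * (1.0 - f) / f))
            if eta > 0:
                F = diversified_F(sky, self._x_cut)
                lp += eta * np.log1p(-1.0 / F)
        lp += oriented_to_labeled(stats)
        if self.priors.root_age is not None:
            lp += self.priors.root_age.logpdf(stats.root_age)
        return float(lp)

    def _param_prior(self, params: CanonicalParams, clock) -> float:
        lp = self.priors.params_logpdf(params)
        if self.priors.clock is not None and clock is not None:
            lp += self.priors.clock.logpdf(clock)
        return float(lp)

    @property
    def log_posterior(self) -> float:
        ll = self.likelihood.loglik if self.likelihood is not None else 0.0
        return self._log_tree_prior + self._log_param_prior + ll

    def fresh_log_posterior(self) -> float:
        """Recompute every factor from scratch (debug consistency check)."""
        saved = self._stats, self._x_cut
        self._refresh_tree_caches()
        lp = self._tree_prior(self.params) + self._param_prior(
            self.params, self.clock_rate)
        if self.likelihood is not None:
            lp += self.likelihood.full_refresh()
        return lp

    # -- parameter moves -----------------------------------------------------

    def _move_param(self):
        rng = self.rng
        # the clock move forces a full pruning refresh, so it is proposed
        # less often than the cheap rate-parameter moves
        if self.clock_rate is not None and rng.random() < 0.12:
            which = 6
        else:
            which = rng.integers(6)
        d = self.params.d.copy()
        r = self.params.r.copy()
        s = self.params.s.copy()
        clock = self.clock_rate
        log_h = 0.0
        if which == 0:
            i = rng.integers(len(d))
            fac = np.exp(self.config.d_tune * (rng.random() - 0.5))
            d[i] *= fac
            log_h = np.log(fac)
        elif which == 1:
            i = rng.integers(len(r))
            r[i] = _reflect(r[i] + self.config.rs_window * (rng.random() - 0.5),
                            0.0, 1.0)
        elif which == 2:
            i = rng.integers(len(s))
            s[i] = _reflect(s[i] + self.config.rs_window * (rng.random() - 0.5),
                            0.0, 1.0)
        elif which in (3, 4, 5):
            # multipliers in (lambda, mu, psi) space: the tree informs the
            # natural rates, so these decorrelate the canonical parameters;
            # the Hastings factor carries the (d, r, s) change of variables
            i = rng.integers(len(d))
            lam = d[i] / (1.0 - r[i])
            mu = lam * r[i]
            psi = mu * s[i] / (1.0 - s[i]) if s[i] < 1.0 else 0.0
            fac = np.exp(self.config.d_tune * (rng.random() - 0.5))
            if which == 3:                 # birth rate, (mu, psi) fixed
                lam2, mu2, psi2 = fac * lam, mu, psi
                if lam2 <= mu2:
                    return False
                log_h = -np.log(fac) + np.log(lam2 - mu2) - np.log(d[i])
            elif which == 4:               # death rate, (lambda, psi) fixed
                if mu == 0.0:
                    return False
                lam2, mu2, psi2 = lam, fac * mu, psi
                if lam2 <= mu2:
                    return False
                log_h = (2 * np.log(fac)
                         + np.log(lam2 - mu2) - np.log(d[i])
                         + 2 * (np.log(mu + psi) - np.log(mu2 + psi2)))
            else:                          # fossil rate, (lambda, mu) fixed
                if psi == 0.0 or mu == 0.0:
                    return False
                lam2, mu2, psi2 = lam, mu, fac * psi
                log_h = (np.log(fac)
                         + 2 * (np.log(mu + psi) - np.log(mu2 + psi2)))
            d[i] = lam2 - mu2
            r[i] = mu2 / lam2
            s[i] = psi2 / (mu2 + psi2) if (mu2 + psi2) > 0 else 0.0
        else:
            fac = np.exp(self.config.clock_tune * (rng.random() - 0.5))
            clock = clock * fac
            log_h = np.log(fac)
        new_params = CanonicalParams(d, r, s)
        if np.any(r >= 1.0) or np.any(s >= 1.0) or np.any(d <= 0):
            return False
        new_param_prior = self._param_prior(new_params, clock)
        if not np.isfinite(new_param_prior):
            return False
        clock_changed = which == 6
        new_tree_prior = (self._log_tree_prior if clock_changed
                          else self._tree_prior(new_params))
        delta = (new_tree_prior - self._log_tree_prior
                 + new_param_prior - self._log_param_prior)
        token = None
        if clock_changed and self.likelihood is not None:
            ll_new, token = self.likelihood.propose(clock_rate=clock)
            delta += ll_new - self.likelihood.loglik
        if np.log(self.rng.random()) < delta + log_h:
            self.params = new_params
            self.clock_rate = clock
            self._log_param_prior = new_param_prior
            self._log_tree_prior = new_tree_prior
            if token is not None:
                self.likelihood.accept(token)
            return True
        return False

    # -- tree move helpers ---------------------------------------------------

    def _ancestors(self, node: FBDNode):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def _accept_tree_move(self, log_hastings, dirty) -> bool:
        """Shared accept/reject logic after an in-place tree mutation."""
        saved = (self._stats, self._x_cut)
        try:
            self._refresh_tree_caches()
            new_tree_prior = self._tree_prior(self.params)
        except ValueError:
            self._stats, self._x_cut = saved
            return False
        delta = new_tree_prior - self._log_tree_prior
        token = None
        if self.likelihood is not None:
            ll_new, token = self.likelihood.propose(dirty=dirty)
            delta += ll_new - self.likelihood.loglik
        if np.isfinite(delta) and np.log(self.rng.random()) < delta + log_hastings:
            self._log_tree_prior = new_tree_prior
            if token is not None:
                self.likelihood.accept(token)
            return True
        self._stats, self._x_cut = saved
        return False

    def _sampled_ancestors(self):
        return [f for f in self.tree.fossils() if f.is_sampled_ancestor]

    def _fossil_tips(self):
        return [f for f in self.tree.fossils() if not f.is_sampled_ancestor]

    # -- rjMCMC pair ---------------------------------------------------------

    def _move_add_branch(self):
        sas = self._sampled_ancestors()
        if not sas:
            return False          # abort counts as a rejected iteration
        k = len(sas)
        m = len(self._fossil_tips())
        f = sas[int(self.rng.integers(k))]
        att = f.parent
        if att.parent is None:
            return False
        c_f = att.parent.age
        y_f = f.age
        if c_f <= y_f:
            return False
        new_age = y_f + self.rng.random() * (c_f - y_f)
        old_age = att.age
        att.age = new_age
        log_h = add_branch_log_hastings(k, m, c_f, y_f)
        if self._accept_tree_move(log_h, self._ancestors(att)):
            return True
        att.age = old_age
        return False

    def _move_delete_branch(self):
        tips = self._fossil_tips()
        if not tips:
            return False
        m = len(tips)
        k = len(self._sampled_ancestors())
        f = tips[int(self.rng.integers(m))]
        bif = f.parent
        if bif is None or bif.parent is None:
            return False          # cannot merge at (or above) the root
        sib = bif.children[0] if bif.children[1] is f else bif.children[1]
        if sib.age >= f.age:
            return False          # tip fossil younger than its sibling
        c_f = bif.parent.age
        y_f = f.age
        old_age = bif.age
        bif.age = y_f             # collapse: fossil becomes a sampled ancestor
        log_h = delete_branch_log_hastings(m, k, c_f, y_f)
        if self._accept_tree_move(log_h, self._ancestors(bif)):
            return True
        bif.age = old_age
        return False

    def _move_rj(self):
        if self.rng.random() < 0.5:
            return self._move_add_branch()
        return self._move_delete_branch()

    # -- fossil repositioning ------------------------------------------------

    def _move_fossil_spr(self):
        sas = self._sampled_ancestors()
        if not sas:
            return False
        f = sas[int(self.rng.integers(len(sas)))]
        att = f.parent
        if att.parent is None:
            return False
        y = f.age
        candidates = [n for n in self.tree.preorder()
                      if n.parent is not None
                      and n.age < y < n.parent.age]
        if not candidates:
            return False
        target = candidates[int(self.rng.integers(len(candidates)))]
        # detach the attachment point and re-insert it above `target`
        parent = att.parent
        cont = att.children[0] if att.children[1] is f else att.children[1]
        t_parent = target.parent
        att.remove_child(cont)
        parent.remove_child(att)
        parent.add_child(cont)
        t_parent.remove_child(target)
        att.add_child(target)
        t_parent.add_child(att)
        dirty = set(self._ancestors(att)) | set(self._ancestors(parent))
        if self._accept_tree_move(0.0, list(dirty)):
            return True
        t_parent.remove_child(att)
        att.remove_child(target)
        t_parent.add_child(target)
        parent.remove_child(cont)
        att.add_child(cont)
        parent.add_child(att)
        return False

    def _move_fossil_slider(self):
        """Slide a fossil's age within its stratigraphic bounds (reflection)."""
        movable = [f for f in self.tree.fossils()
                   if f.fossil.age_lower is not None
                   and f.fossil.age_upper is not None
                   and f.fossil.age_upper > f.fossil.age_lower]
        if not movable:
            return False
        f = movable[int(self.rng.integers(len(movable)))]
        att = f.parent
        was_sa = f.is_sampled_ancestor
        if was_sa:
            # the fossil and its attachment point move together
            cont = att.children[0] if att.children[1] is f else att.children[1]
            lo = max(f.fossil.age_lower, cont.age)
            hi = min(f.fossil.age_upper,
                     att.parent.age if att.parent is not None else np.inf)
        else:
            lo = f.fossil.age_lower
            hi = min(f.fossil.age_upper, att.age)
        if hi <= lo:
            return False
        new_age = _reflect(f.age + self.config.fossil_window
                           * (self.rng.random() - 0.5), lo, hi)
        old = f.age
        f.age = new_age
        if was_sa:
            att.age = new_age
        if self._accept_tree_move(0.0, self._ancestors(att)):
            return True
        f.age = old
        if was_sa:
            att.age = old
        return False

    # -- node ages -----------------------------------------------------------

    def _move_node_age(self):
        nodes = [n for n in self.tree.true_branchings() if n.parent is not None]
        if not nodes:
            return False
        node = nodes[int(self.rng.integers(len(nodes)))]
        lo = max(c.age for c in node.children)
        hi = node.parent.age
        if hi <= lo:
            return False
        old = node.age
        node.age = lo + self.rng.random() * (hi - lo)
        if self._accept_tree_move(0.0, self._ancestors(node)):
            return True
        node.age = old
        return False

    def _move_root_age(self):
        if self.priors.root_age is None:
            return False
        root = self.tree.root
        lo = max(c.age for c in root.children)
        hi = getattr(self.priors.root_age, "high", np.inf)
        old = root.age
        prop = old + self.config.root_window * (self.rng.random() - 0.5)
        if np.isfinite(hi):
            prop = _reflect(prop, lo, hi)
        elif prop <= lo:
            return False
        root.age = prop
        if self._accept_tree_move(0.0, [root]):
            return True
        root.age = old
        return False

    def _move_ages(self):
        if self.priors.root_age is not None and self.rng.random() < 0.2:
            return self._move_root_age()
        return self._move_node_age()

    # -- topology ------------------------------------------------------------

    def _spr_candidates(self):
        return [n for n in self.tree.preorder()
                if n.parent is not None and n.parent.parent is not None
                and not n.parent.is_attachment
                and not n.is_sampled_ancestor]

    def _move_topology(self):
        """Subtree prune-and-regraft with a uniform reattachment-age draw."""
        cand = self._spr_candidates()
        if not cand:
            return False
        n_cand_fwd = len(cand)
        z = cand[int(self.rng.integers(len(cand)))]
        p = z.parent
        g = p.parent
        sib = p.children[0] if p.children[1] is z else p.children[1]
        # reverse-draw window: the merged segment (sib -> g) vs z's age
        rev_len = g.age - max(z.age, sib.age)
        if rev_len <= 0:
            return False
        # detach
        g.remove_child(p)
        p.remove_child(sib)
        g.add_child(sib)
        # feasible segments in the intermediate tree
        segs = [(n, n.parent) for n in self.tree.preorder()
                if n.parent is not None and n.parent.age > z.age
                and n.parent.age > n.age]
        segs = [(c, par) for (c, par) in segs if par.age > max(z.age, c.age)]
        if not segs:
            p.add_child(sib)  # restore
            g.remove_child(sib)
            g.add_child(p)
            return False
        c, par = segs[int(self.rng.integers(len(segs)))]
        fwd_lo = max(z.age, c.age)
        fwd_len = par.age - fwd_lo
        new_age = fwd_lo + self.rng.random() * fwd_len
        par.remove_child(c)
        p.add_child(c)
        par.add_child(p)
        old_age = p.age
        p.age = new_age
        n_cand_rev = len(self._spr_candidates())
        log_h = (np.log(fwd_len) - np.log(rev_len)
                 + np.log(n_cand_fwd) - np.log(n_cand_rev))
        dirty = set(self._ancestors(p)) | set(self._ancestors(g))
        if self._accept_tree_move(log_h, list(dirty)):
            return True
        # undo
        par.remove_child(p)
        p.remove_child(c)
        par.add_child(c)
        g.remove_child(sib)
        p.add_child(sib)
        p.age = old_age
        g.add_child(p)
        return False

    # -- main loop -----------------------------------------------------------

    def run(self, iterations: Optional[int] = None,
            thin: Optional[int] = None) -> Trace:
        cfg = self.config
        iterations = cfg.iterations if iterations is None else iterations
        thin = cfg.thin if thin is None else thin
        if self.fixed_tree:
            moves = [("params", self._move_param, 1.0)]
        else:
            moves = [("params", self._move_param, cfg.w_params),
                     ("ages", self._move_ages, cfg.w_node_ages),
                     ("rj", self._move_rj, cfg.w_rj),
                     ("fossil_spr", self._move_fossil_spr, cfg.w_fossil / 2),
                     ("fossil_slide", self._move_fossil_slider, cfg.w_fossil / 2),
                     ("topology", self._move_topology, cfg.w_topology)]
        names = [m[0] for m in moves]
        weights = np.array([m[2] for m in moves])
        weights = weights / weights.sum()
        fns = [m[1] for m in moves]
        tried = dict.fromkeys(names, 0)
        accepted = dict.fromkeys(names, 0)
        rows = []
        trees = []

        def record(it):
            row = {"iteration": it, "log_posterior": self.log_posterior,
                   "root_age": self.tree.root.age,
                   "n_anc": self.tree.n_sampled_ancestors(),
                   "n_tip_fossils": self.tree.n_fossil_tips()}
            for j in range(len(self.params.d)):
                row[f"d_{j}"] = self.params.d[j]
                row[f"r_{j}"] = self.params.r[j]
                row[f"s_{j}"] = self.params.s[j]
            if self.clock_rate is not None:
                row["clock"] = self.clock_rate
            if self._x_cut is not None:
                row["x_cut"] = self._x_cut
            rows.append(row)
            if cfg.sample_trees:
                trees.append(self.tree.copy())

        record(0)
        choices = self.rng.random(iterations)
        cum = np.cumsum(weights)
        for it in range(1, iterations + 1):
            j = int(np.searchsorted(cum, choices[it - 1]))
            tried[names[j]] += 1
            if fns[j]():
                accepted[names[j]] += 1
            if it % thin == 0:
                record(it)
            if cfg.check_every and it % cfg.check_every == 0:
                cached = self.log_posterior
                fresh = self.fresh_log_posterior()
                if not np.isclose(cached, fresh, rtol=0, atol=1e-6):
                    raise AssertionError(
                        f"cached posterior {cached} != fresh {fresh} at {it}")
        acc = {n: (accepted[n] / tried[n] if tried[n] else np.nan)
               for n in names}
        return Trace(records=pd.DataFrame(rows), trees=trees,
                     burnin=cfg.burnin, acceptance=acc)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect ``x`` into ``(lo, hi)`` (handles multiple reflections)."""
    span = hi - lo
    if span <= 0:
        raise ValueError("empty reflection interval")
    y = (x - lo) % (2.0 * span)
    if y > span:
        y = 2.0 * span - y
    return lo + y


def run_chain(model: FBDModel, priors: PriorSpec, tree: FBDTree,
              params: CanonicalParams, seed: int,
              alignment: Optional[Alignment] = None,
              clock_rate: Optional[float] = None,
              fixed_tree: bool = False,
              config: Optional[ChainConfig] = None) -> Trace:
    """Convenience wrapper: build an :class:`FBDChain` and run it."""
    rng = np.random.default_rng(seed)
    chain = FBDChain(model, priors, tree, params, rng, alignment=alignment,
                     clock_rate=clock_rate, fixed_tree=fixed_tree,
                     config=config)
    return chain.run()
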