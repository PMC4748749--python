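"""Forward simulation of birth-death trees, fossilization and taxon sampling.

The simulator produces *complete* trees — every extinct and extant lineage —
from a single origin lineage under a constant-rate birth-death process, then
overlays fossil observations (Poisson along branches and/or Bernoulli at
fixed horizon ages), samples extant taxa (uniformly at random or diversified)
and prunes everything without a sampled descendant, yielding the observed
:class:`~fbdsky.tree.FBDTree`.

Conditioning on ``n`` extant taxa uses the general-sampling approach:
the process is run forward well past ``n`` (or to extinction), every time
span during which exactly ``n`` lineages are extant is recorded, and the
stopping time is drawn uniformly over the union of those spans.  This avoids
the bias of stopping at the first moment the count reaches ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .tree import FBDNode, FBDTree, FossilInfo

__all__ = [
    "CompleteTree",
    "FossilEvent",
    "simulate_complete_tree",
    "sample_fossils_poisson",
    "sample_fossils_at_horizon",
    "sample_extant",
    "prune_to_fbd",
    "simulate_fbd_tree",
]


@dataclass
class FossilEvent:
    """A fossil observation on the branch *above* ``node`` at ``age``."""

    node: FBDNode
    age: float
    kind: str = "psi"            # "psi" or "horizon"
    horizon: Optional[int] = None


class CompleteTree:
    """Full realization of the birth-death process (extinct lineages kept).

    Node ages follow the usual convention: a node's age is the age at which
    its lineage ends (speciation, extinction, or the present); the branch
    above it spans ``(node.age, parent.age)``.
    """

    def __init__(self, root: FBDNode, origin_age: float):
        self.root = root
        self.origin_age = float(origin_age)

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def extant_tips(self):
        return [n for n in self.preorder() if n.is_tip and n.age == 0.0]

    def total_branch_length(self, include_stem: bool = True) -> float:
        total = 0.0
        for node in self.preorder():
            upper = node.parent.age if node.parent is not None else (
                self.origin_age if include_stem else None)
            if upper is not None:
                total += upper - node.age
        return total

    def segments(self, include_stem: bool = True):
        """Yield ``(node, upper_age)`` for every branch of the tree."""
        for node in self.preorder():
            upper = node.parent.age if node.parent is not None else (
                self.origin_age if include_stem else None)
            if upper is not None and upper > node.age:
                yield node, upper


# ---------------------------------------------------------------------------
# Birth-death simulation conditioned on the number of extant taxa
# ---------------------------------------------------------------------------

def simulate_complete_tree(birth: float, death: float, n_extant: int,
                           rng: np.random.Generator,
                           n_max_factor: float = 4.0,
                           max_tries: int = 10_000) -> CompleteTree:
    """Simulate a complete birth-death tree with exactly ``n_extant`` tips.

    Runs a Gillespie simulation from one origin lineage until extinction or
    until the extant count reaches ``max(n_max_factor * n, n + 20)``, then
    draws the stopping time uniformly over the total time during which the
    count equalled ``n_extant``.  Realizations that never attain ``n_extant``
    are retried (up to ``max_tries``).
    """
    if n_extant < 2:
        raise ValueError("need at least 2 extant taxa")
    if birth <= 0:
        raise ValueError("birth rate must be positive")
    n_cap = int(max(n_max_factor * n_extant, n_extant + 20))
    for _ in range(max_tries):
        result = _gillespie_once(birth, death, n_extant, n_cap, rng)
        if result is not None:
            return result
    raise RuntimeError(
        f"no realization reached {n_extant} extant lineages in "
        f"{max_tries} attempts (birth={birth}, death={death})")


def _gillespie_once(birth, death, n_target, n_cap, rng):
    # forward-time bookkeeping: each record is [t_birth, t_end, left, right]
    # t_end None while alive; children indices set on speciation
    t_birth = [0.0]
    t_end: list[Optional[float]] = [None]
    kids: list[Optional[tuple[int, int]]] = [None]
    active = [0]
    t = 0.0
    epochs = []          # (start, stop) spans with exactly n_target alive
    epoch_start = None
    total = birth + death
    while active:
        n_alive = len(active)
        if n_alive == n_target and epoch_start is None:
            epoch_start = t
        t_next = t + rng.exponential(1.0 / (n_alive * total))
        if epoch_start is not None:
            epochs.append((epoch_start, t_next))
            epoch_start = None
        t = t_next
        idx = active[int(rng.integers(n_alive))]
        if rng.random() < birth / total:
            # speciation: two daughters
            a, b = len(t_birth), len(t_birth) + 1
            t_birth += [t, t]
            t_end += [None, None]
            kids += [None, None]
            t_end[idx] = t
            kids[idx] = (a, b)
            active.remove(idx)
            active += [a, b]
            if len(active) >= n_cap:
                break
        else:
            t_end[idx] = t
            active.remove(idx)
    if not epochs:
        return None
    spans = np.array([e[1] - e[0] for e in epochs])
    pick = int(rng.choice(len(epochs), p=spans / spans.sum()))
    s = epochs[pick][0] + rng.random() * spans[pick]

    # build the truncated tree: everything born before s, cut at s
    def build(i: int) -> FBDNode:
        end = t_end[i]
        if end is None or end >= s:       # alive at the stopping time
            return FBDNode(age=0.0)
        node = FBDNode(age=s - end)
        if kids[i] is not None:
            a, b = kids[i]
            node.add_child(build(a))
            node.add_child(build(b))
        return node

    root = build(0)
    tree = CompleteTree(root, origin_age=s)
    # sanity: the conditioning must have produced n_target extant tips
    assert len(tree.extant_tips()) == n_target
    return tree


# ---------------------------------------------------------------------------
# Fossilization
# ---------------------------------------------------------------------------

def sample_fossils_poisson(tree: CompleteTree, psi, rng: np.random.Generator,
                           shift_ages=None,
                           include_stem: bool = True) -> list[FossilEvent]:
    """Poisson fossil observations along every branch.

    ``psi`` may be a scalar (constant rate) or a per-interval vector matched
    with ``shift_ages`` (``t_1 > ... > t_l = 0``, same convention as
    :class:`~fbdsky.skyline.RateSkyline`).  Each branch receives
    ``Poisson(psi_i * overlap)`` events at uniform ages within its overlap
    with interval i.
    """
    if shift_ages is None:
        psi_arr = np.array([float(psi)])
        shift_arr = np.array([0.0])
    else:
        psi_arr = np.asarray(psi, dtype=float)
        shift_arr = np.asarray(shift_ages, dtype=float)
    uppers = np.concatenate(([np.inf], shift_arr[:-1]))
    events = []
    for node, top in tree.segments(include_stem=include_stem):
        for lo, hi, rate in zip(shift_arr, uppers, psi_arr):
            if rate <= 0.0:
                continue
            a = max(node.age, lo)
            b = min(top, hi)
            if b <= a:
                continue
            for _ in range(rng.poisson(rate * (b - a))):
                events.append(FossilEvent(node, a + rng.random() * (b - a)))
    return events


def sample_fossils_at_horizon(tree: CompleteTree, horizon_age: float,
                              prob: float, rng: np.random.Generator,
                              horizon_index: int = 1,
                              include_stem: bool = True) -> list[FossilEvent]:
    """Bernoulli sampling of every lineage crossing ``horizon_age``."""
    events = []
    for node, top in tree.segments(include_stem=include_stem):
        if node.age < horizon_age < top and rng.random() < prob:
            events.append(FossilEvent(node, horizon_age, kind="horizon",
                                      horizon=horizon_index))
    return events


# ---------------------------------------------------------------------------
# Extant-taxon sampling
# ---------------------------------------------------------------------------

def _extant_descendants(node: FBDNode) -> list[FBDNode]:
    return [n for n in _subtree(node) if n.is_tip and n.age == 0.0]


def _subtree(node: FBDNode):
    stack = [node]
    while stack:
        cur = stack.pop()
        yield cur
        stack.extend(cur.children)


def sample_extant(tree: CompleteTree, mode: str, fraction: float,
                  rng: np.random.Generator):
    """Select extant tips to retain.

    ``mode="random"``: i.i.d. Bernoulli(``fraction``) per extant tip; returns
    ``(retained_tips, None)``.

    ``mode="diversified"``: finds the cutoff age ``x_cut`` such that exactly
    ``round(fraction * n)`` ancestral lineages of the extant taxa cross it
    (the midpoint between the two adjacent branching ages of the
    extant-reconstructed tree), then keeps one extant descendant per crossing
    lineage, chosen uniformly; returns ``(retained_tips, x_cut)``.
    """
    tips = tree.extant_tips()
    n = len(tips)
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if mode == "random":
        return [tip for tip in tips if rng.random() < fraction], None
    if mode != "diversified":
        raise ValueError(f"unknown sampling mode {mode!r}")
    target = int(round(fraction * n))
    if target < 2:
        raise ValueError("diversified sampling needs at least 2 retained taxa")
    if target == n:
        return list(tips), None
    # branching ages of the extant-reconstructed tree: internal nodes whose
    # two child lineages both lead to extant tips
    has_extant: dict[int, bool] = {}
    for node in reversed(list(tree.preorder())):
        if node.is_tip:
            has_extant[id(node)] = node.age == 0.0
        else:
            has_extant[id(node)] = any(has_extant[id(c)] for c in node.children)
    recon_ages = sorted(
        (node.age for node in tree.preorder()
         if len(node.children) == 2
         and all(has_extant[id(c)] for c in node.children)),
        reverse=True)
    # exactly "target" extant-ancestor lineages (stem included) cross any age
    # strictly between the (target-1)-th and target-th oldest reconstructed
    # branching ages; take the midpoint
    x_cut = 0.5 * (recon_ages[target - 2] + recon_ages[target - 1])
    retained = []
    count = 0
    # crossing lineages with extant descendants, one retained tip each
    stack = [(tree.root, np.inf)]
    while stack:
        node, upper = stack.pop()
        if not has_extant[id(node)]:
            continue
        if node.age < x_cut < upper:
            count += 1
            desc = _extant_descendants(node)
            retained.append(desc[int(rng.integers(len(desc)))])
        else:
            for child in node.children:
                stack.append((child, node.age))
    assert count == target, (count, target)
    return retained, x_cut


# ---------------------------------------------------------------------------
# Pruning to the observed FBD tree
# ---------------------------------------------------------------------------

def prune_to_fbd(tree: CompleteTree, fossil_events: list[FossilEvent],
                 retained_extant: list[FBDNode],
                 label_prefix: str = "") -> FBDTree:
    """Prune every lineage without a fossil or retained extant descendant.

    Fossils whose lineage carries a later sample become sampled ancestors
    (zero-length side branches); fossils terminating their lineage become
    fossil tips.  Raises if fewer than two samples remain.
    """
    if len(retained_extant) + len(fossil_events) < 2:
        raise ValueError("need at least two samples to build an FBD tree")
    retained_ids = {id(tip) for tip in retained_extant}
    events_by_node: dict[int, list[FossilEvent]] = {}
    for ev in fossil_events:
        events_by_node.setdefault(id(ev.node), []).append(ev)
    counter = {"extant": 0, "fossil": 0}

    def fossil_node(ev: FossilEvent) -> FBDNode:
        counter["fossil"] += 1
        return FBDNode(age=ev.age,
                       label=f"{label_prefix}F{counter['fossil']}",
                       fossil=FossilInfo(kind=ev.kind, horizon=ev.horizon))

    def process(node: FBDNode) -> Optional[FBDNode]:
        # sampled structure strictly below this node's branch
        if node.is_tip:
            if id(node) in retained_ids:
                counter["extant"] += 1
                below = FBDNode(age=0.0, label=f"{label_prefix}T{counter['extant']}")
            else:
                below = None
        else:
            sub = [process(c) for c in node.children]
            sub = [s for s in sub if s is not None]
            if len(sub) == 2:
                below = FBDNode(age=node.age, children=sub)
            elif len(sub) == 1:
                below = sub[0]
            else:
                below = None
        # overlay this branch's fossil events, youngest first
        for ev in sorted(events_by_node.get(id(node), []), key=lambda e: e.age):
            fn = fossil_node(ev)
            if below is None:
                below = fn                        # fossil tip ends the lineage
            else:
                below = FBDNode(age=ev.age, children=[below, fn])
        return below

    root = process(tree.root)
    if root is None or root.is_tip:
        raise ValueError("fewer than two samples after pruning")
    return FBDTree(root, origin_age=tree.origin_age)


# ---------------------------------------------------------------------------
# One-call strategy simulators (study conditions)
# ---------------------------------------------------------------------------

@dataclass
class StrategyResult:
    """An observed FBD tree plus everything inference needs to score it."""

    tree: FBDTree
    strategy: int
    shift_ages: np.ndarray          # inference skyline boundaries
    sampling: np.ndarray            # fixed rho_i values
    x_cut: Optional[float] = None   # diversified cutoff (strategies 3, 4)
    eta_l: int = 0                  # unsampled extant taxa (diversified)
    n_extant_complete: int = 0


def simulate_fbd_tree(strategy: int, rng: np.random.Generator,
                      n_extant: int = 100, birth: float = 0.3,
                      death: float = 0.2, psi: float = 0.1,
                      rho: float = 0.5, horizon_age: float = 10.0,
                      horizon_prob: float = 0.5,
                      max_tries: int = 1000) -> StrategyResult:
    """Simulate one replicate under one of the four sampling strategies.

    1. random extant sampling (prob ``rho``), constant fossil rate ``psi``;
    2. as 1, plus horizon fossil sampling at ``horizon_age`` with
       probability ``horizon_prob``;
    3. diversified extant sampling of a ``rho`` fraction (cutoff ``x_cut``),
       fossil rate ``psi`` above ``x_cut`` and zero below;
    4. as 3, plus horizon fossil sampling at ``horizon_age`` (which must be
       older than ``x_cut``).

    Replicates whose sampled tree would carry a sample above its own crown
    (a stem fossil, outside the crown-conditioned model) are redrawn, as are
    degenerate ones with fewer than two samples.
    """
    if strategy not in (1, 2, 3, 4):
        raise ValueError("strategy must be 1, 2, 3 or 4")
    for _ in range(max_tries):
        complete = simulate_complete_tree(birth, death, n_extant, rng)
        mode = "random" if strategy in (1, 2) else "diversified"
        try:
            retained, x_cut = sample_extant(complete, mode, rho, rng)
        except ValueError:
            continue
        if strategy == 4 and (x_cut is None or x_cut >= horizon_age):
            continue  # cutoff must stay younger than the horizon age
        events = []
        if mode == "random":
            events += sample_fossils_poisson(complete, psi, rng)
        else:
            if x_cut is None:
                continue
            events += sample_fossils_poisson(
                complete, [psi, 0.0], rng, shift_ages=[x_cut, 0.0])
        horizon_idx = 1
        if strategy in (2, 4):
            events += sample_fossils_at_horizon(
                complete, horizon_age, horizon_prob, rng,
                horizon_index=horizon_idx)
        if len(retained) + len(events) < 2 or not retained:
            continue
        try:
            fbd = prune_to_fbd(complete, events, retained)
        except ValueError:
            continue
        # crown conditioning: no sample may sit on the stem above the root
        if fbd.root.is_attachment or fbd.root.sa_child is not None:
            continue
        if strategy == 1:
            shift, sampling = [0.0], [rho]
        elif strategy == 2:
            shift, sampling = [horizon_age, 0.0], [horizon_prob, rho]
        elif strategy == 3:
            shift, sampling = [x_cut, 0.0], [0.0, 1.0]
        else:
            shift, sampling = [horizon_age, x_cut, 0.0], [horizon_prob, 0.0, 1.0]
        # horizon index refers to the inference skyline's boundary list
        for node in fbd.preorder():
            if node.fossil is not None and node.fossil.kind == "horizon":
                node.fossil.horizon = 1
        eta = (n_extant - len(retained)) if mode == "diversified" else 0
        return StrategyResult(
            tree=fbd, strategy=strategy,
            shift_ages=np.asarray(shift, dtype=float),
            sampling=np.asarray(sampling, dtype=float),
            x_cut=x_cut, eta_l=eta, n_extant_complete=n_extant)
    raise RuntimeError(f"failed to simulate a usable strategy-{strategy} "
                       f"replicate in {max_tries} tries")
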