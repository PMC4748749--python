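"""JC69 sequence evolution along FBD trees under a strict clock.

The clock maps ages to expected substitutions: a branch from age ``a`` down
to age ``b`` carries ``d = c (a - b)`` expected substitutions per site, with
``c`` the strict clock rate.  Under JC69 the transition probability is fully
determined by ``d``:

    P(same)  = 1/4 + 3/4 exp(-4d/3)
    P(other) = 1/4 - 1/4 exp(-4d/3)

The likelihood uses Felsenstein's pruning algorithm with per-pattern scaling;
sampled ancestors are zero-length-branch tips, whose transition matrix is the
identity, so they simply constrain the state at their attachment point.
Missing characters ('-' or '?') contribute an all-ones partial vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import FBDNode, FBDTree

__all__ = ["Alignment", "ClockModel", "jc69_transition", "jc69_match_prob",
           "simulate_alignment", "log_likelihood", "TreeLikelihood"]

_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "-": 4, "?": 4, "N": 4}
_LETTERS = np.array(list("ACGT?"))


@dataclass(frozen=True)
class ClockModel:
    """Strict molecular clock: ``rate`` substitutions per site per time unit."""

    rate: float

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("clock rate must be non-negative")


class Alignment:
    """Labelled DNA matrix over {A, C, G, T} with '-'/'?' as missing."""

    def __init__(self, labels, data):
        self.labels = list(labels)
        self.data = np.asarray(data, dtype=np.uint8)
        if self.data.ndim != 2 or len(self.labels) != self.data.shape[0]:
            raise ValueError("data must be (n_taxa, n_sites) matching labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        if self.data.size and self.data.max() > 4:
            raise ValueError("states must be coded 0..4")

    @classmethod
    def from_strings(cls, records: dict[str, str]) -> "Alignment":
        labels = list(records)
        lengths = {len(s) for s in records.values()}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        data = np.array([[_CODES[ch] for ch in records[lab].upper()]
                         for lab in labels], dtype=np.uint8)
        return cls(labels, data)

    def to_strings(self) -> dict[str, str]:
        return {lab: "".join(_LETTERS[row])
                for lab, row in zip(self.labels, self.data)}

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"taxon {label!r} not in alignment") from None


# ---------------------------------------------------------------------------
# JC69 primitives
# ---------------------------------------------------------------------------

def jc69_match_prob(d: float) -> float:
    """Probability that a site is in the same state after ``d`` substitutions."""
    if d < 0:
        raise ValueError("expected substitutions must be non-negative")
    return 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)


def jc69_transition(d: float) -> np.ndarray:
    """The 4x4 JC69 transition probability matrix for branch length ``d``."""
    same = jc69_match_prob(d)
    diff = (1.0 - same) / 3.0
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_alignment(tree: FBDTree, clock: ClockModel, length: int,
                       rng: np.random.Generator) -> Alignment:
    """Evolve ``length`` JC69 sites down the tree from a uniform root state.

    Every tip — extant, fossil tip, or sampled ancestor — receives a
    sequence; a sampled ancestor's zero-length branch copies the state of
    its attachment point exactly.
    """
    if length < 1:
        raise ValueError("alignment length must be at least 1")
    states = {id(tree.root): rng.integers(0, 4, size=length)}
    records: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        cur = states.pop(id(node))
        if node.is_tip:
            if node.label is None:
                raise ValueError("all tips need labels to simulate sequences")
            records[node.label] = cur
            continue
        for child in node.children:
            d = clock.rate * (node.age - child.age)
            keep = jc69_match_prob(d)
            out = cur.copy()
            flip = rng.random(length) >= keep
            if flip.any():
                # a substitution moves to one of the three other states
                out[flip] = (out[flip] + rng.integers(1, 4, size=int(flip.sum()))) % 4
            states[id(child)] = out
    labels = sorted(records)
    return Alignment(labels, np.array([records[lab] for lab in labels]))


# ---------------------------------------------------------------------------
# Pruning likelihood with cached partials
# ---------------------------------------------------------------------------

def _child_contribution(partial: np.ndarray, d: float) -> np.ndarray:
    """JC69 P(d) applied to a child's partial vector, vectorised over sites."""
    e = np.exp(-4.0 * d / 3.0)
    tot = partial.sum(axis=1, keepdims=True)
    return e * partial + (1.0 - e) * 0.25 * tot


class TreeLikelihood:
    """Felsenstein pruning over an FBD tree with per-node partial caching.

    Site patterns are compressed once.  A proposal declares its *dirty*
    nodes (those whose partials must be refreshed: the changed node and all
    of its ancestors); :meth:`propose` computes the new log-likelihood
    without touching the cache, and :meth:`accept` commits it.  Passing
    ``dirty=None`` refreshes everything (needed after a clock-rate change).
    """

    def __init__(self, tree: FBDTree, alignment: Alignment, clock_rate: float):
        self.tree = tree
        self.clock_rate = float(clock_rate)
        cols, inverse, counts = np.unique(
            alignment.data, axis=1, return_inverse=True, return_counts=True)
        self.pattern_counts = counts.astype(float)
        self._tip_partials: dict[str, np.ndarray] = {}
        for lab, row in zip(alignment.labels, alignment.data):
            pat = cols[alignment.labels.index(lab)]
            part = np.zeros((cols.shape[1], 4))
            miss = pat == 4
            part[np.arange(len(pat)), np.where(miss, 0, pat)] = 1.0
            part[miss] = 1.0
            self._tip_partials[lab] = part
        tip_labels = {n.label for n in tree.leaves()}
        missing = tip_labels - set(alignment.labels)
        if missing:
            raise KeyError(f"tree tips missing from alignment: {sorted(missing)}")
        self._partials: dict[int, np.ndarray] = {}
        self._loglik = None
        self.full_refresh()

    # -- internals -----------------------------------------------------------

    def _node_partial(self, node: FBDNode, store: dict[int, np.ndarray]):
        out = None
        scale = 0.0
        for child in node.children:
            if child.is_tip:
                cp = self._tip_partials[child.label]
            else:
                cp = store.get(id(child), self._partials.get(id(child)))
            d = self.clock_rate * (node.age - child.age)
            contrib = _child_contribution(cp, d) if d > 0 else cp
            out = contrib if out is None else out * contrib
        # per-pattern rescaling; the log-scale is folded into row 0 trick:
        # we store scaled partials plus a per-pattern log factor
        mx = out.max(axis=1, keepdims=True)
        mx[mx == 0.0] = 1.0
        store[id(node)] = out / mx
        return np.log(mx[:, 0])

    def _compute(self, dirty_nodes):
        """Recompute partials for ``dirty_nodes`` (postorder) into a scratch map."""
        store: dict[int, np.ndarray] = {}
        scales: dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            if node.children and (dirty_nodes is None or id(node) in dirty_nodes):
                scales[id(node)] = self._node_partial(node, store)
        return store, scales

    def full_refresh(self):
        self._partials.clear()
        self._scales: dict[int, np.ndarray] = {}
        store, scales = self._compute(None)
        self._partials.update(store)
        self._scales = scales
        self._total_scale = sum(scales.values())
        self._loglik = self._site_loglik(self._partials[id(self.tree.root)],
                                         self._total_scale)
        return self._loglik

    def _site_loglik(self, root_partial, total_scale):
        site = 0.25 * root_partial.sum(axis=1)
        return float(np.dot(self.pattern_counts, np.log(site) + total_scale))

    # -- public API ----------------------------------------------------------

    @property
    def loglik(self) -> float:
        return self._loglik

    def propose(self, dirty=None, clock_rate=None):
        """Log-likelihood of the current tree state with ``dirty`` partials
        refreshed; returns (loglik, commit_token)."""
        old_rate = self.clock_rate
        if clock_rate is not None:
            self.clock_rate = float(clock_rate)
            dirty = None
        dirty_ids = None if dirty is None else {id(n) for n in dirty}
        store, scales = self._compute(dirty_ids)
        if dirty_ids is None:
            total = sum(scales.values())
        else:
            total = self._total_scale.copy() if np.ndim(self._total_scale) \
                else np.zeros(len(self.pattern_counts))
            for key, new_scale in scales.items():
                old = self._scales.get(key)
                if old is not None:
                    total -= old
                total += new_scale
        root_partial = store.get(id(self.tree.root),
                                 self._partials.get(id(self.tree.root)))
        ll = self._site_loglik(root_partial, total)
        token = (ll, store, scales, total, self.clock_rate)
        self.clock_rate = old_rate
        return ll, token

    def accept(self, token):
        ll, store, scales, total, rate = token
        self.clock_rate = rate
        self._partials.update(store)
        self._scales.update(scales)
        self._total_scale = total
        self._loglik = ll

    def prune_cache(self):
        """Drop cache entries for nodes no longer in the tree."""
        live = {id(n) for n in self.tree.preorder()}
        for d in (self._partials, self._scales):
            for key in [k for k in d if k not in live]:
                del d[key]


def log_likelihood(alignment: Alignment, tree: FBDTree,
                   clock: ClockModel) -> float:
    """One-shot pruning log-likelihood of ``alignment`` on ``tree``."""
    return TreeLikelihood(tree, alignment, clock.rate).loglik
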