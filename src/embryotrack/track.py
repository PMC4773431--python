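"""Three-stage cell tracking: nearest-neighbour initialization, simulated
annealing under biological constraints, and lineage repair.

The tracker links nucleus centres at consecutive time steps into a lineage
forest.  Links point from mother (time t) to daughter (time t+1); daughters
choose mothers, which makes divisions (two daughters sharing one mother)
representable without special cases.  Biological requirements are encoded
as a weighted cost:

* hard (large weights): at most one mother per cell, at most two daughters;
* soft: no cell appears without a mother, no cell disappears (no cell death
  at the developmental stages modelled), displacements bounded relative to
  ``d_max``, successive divisions on one branch separated by ``tau_div``
  frames, velocity changes damped (inertia), sister cells behave
  symmetrically at division.

Cost-increasing moves are accepted with probability ``min(1, exp(-delta/T))``
with the temperature annealed linearly from ``T0`` to 0; at T = 0 the walk
is strict descent.  The whole stage is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import Centre, CentreSet, LineageForest

__all__ = [
    "AnnealConfig",
    "CostBreakdown",
    "init_nearest_neighbour",
    "forest_cost",
    "anneal",
    "repair",
    "propagate_labels",
    "track",
]

DEFAULT_WEIGHTS = {
    "motherless": 10.0,
    "multi_mother": 1.0e4,
    "excess_daughters": 1.0e4,
    "displacement": 1.0,
    "division_interval": 5.0,
    "inertia": 0.5,
    "sister_symmetry": 0.5,
    "disappearance": 10.0,
}


@dataclass
class AnnealConfig:
    """Configuration of the annealing tracker.

    d_max : maximum plausible displacement per frame (µm); normalizes all
        distance-based terms.
    tau_div : minimum frames between successive divisions on one branch.
    T0 : initial temperature; the schedule decreases linearly to 0.
    n_sweeps : proposal sweeps (one sweep ≈ one proposal per linkable centre).
    k_candidates : nearest predecessor candidates considered per rewiring.
    L_min : minimum track span (frames) below which an isolated branch is a
        deletion candidate during repair.
    allow_disappearance : zero the disappearance term (for systems with
        cell death).
    """

    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    d_max: float = 10.0
    tau_div: int = 10
    T0: float = 1.0
    n_sweeps: int = 100
    k_candidates: int = 6
    seed: int = 0
    L_min: int = 3
    allow_disappearance: bool = False

    def __post_init__(self):
        w = dict(DEFAULT_WEIGHTS)
        w.update(self.weights)
        self.weights = w
        if any(v < 0 for v in self.weights.values()):
            raise ValueError("weights must be >= 0")
        if self.T0 <= 0:
            raise ValueError("T0 must be > 0")
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")

    def effective_weights(self) -> dict:
        w = dict(self.weights)
        if self.allow_disappearance:
            w["disappearance"] = 0.0
        return w


@dataclass
class CostBreakdown:
    total: float
    per_term: dict
    per_centre: dict | None = None


# ----------------------------------------------------------------------
# cost function
# ----------------------------------------------------------------------

def _centre_terms(forest: LineageForest, cid: int, cfg: AnnealConfig,
                  t_min: int, t_max: int) -> dict:
    """Raw (unweighted) cost contributions owned by centre ``cid``.

    Ownership: a centre owns its motherless/disappearance state, its own
    out-degree excess, the displacement and inertia of its incoming link,
    and — as a mother — the sister-symmetry and division-interval penalties
    of its division.
    """
    c = forest.centres[cid]
    terms = {k: 0.0 for k in DEFAULT_WEIGHTS}
    m = forest.mother(cid)
    if m is None:
        if c.t > t_min:
            terms["motherless"] = 1.0
    else:
        d = np.asarray(c.pos) - np.asarray(forest.centres[m].pos)
        terms["displacement"] = float(d @ d) / cfg.d_max**2
        gm = forest.mother(m)
        if gm is not None:
            vm = np.asarray(forest.centres[m].pos) - np.asarray(forest.centres[gm].pos)
            dv = d - vm
            terms["inertia"] = float(dv @ dv) / cfg.d_max**2
    out = forest.out_degree(cid)
    if out == 0 and c.t < t_max:
        terms["disappearance"] = 1.0
    if out > 2:
        terms["excess_daughters"] = float(out - 2)
    if out == 2:
        a, b = sorted(forest.daughters(cid))
        va = np.asarray(forest.centres[a].pos) - np.asarray(c.pos)
        vb = np.asarray(forest.centres[b].pos) - np.asarray(c.pos)
        dv = va - vb
        terms["sister_symmetry"] = float(dv @ dv) / cfg.d_max**2
        # walk back along the branch: an earlier division within tau_div frames
        anc = forest.mother(cid)
        while anc is not None and c.t - forest.centres[anc].t <= cfg.tau_div:
            if forest.out_degree(anc) >= 2:
                terms["division_interval"] = 1.0
                break
            anc = forest.mother(anc)
    return terms


def _centre_cost(forest, cid, cfg, t_min, t_max, weights) -> float:
    terms = _centre_terms(forest, cid, cfg, t_min, t_max)
    return sum(weights[k] * v for k, v in terms.items())


def forest_cost(forest: LineageForest, cfg: AnnealConfig,
                per_centre: bool = False) -> CostBreakdown:
    """Full cost of a lineage forest as a weighted sum of local terms.

    ``total == sum(per_term.values())`` to 1e-9; the multi-mother count is
    structurally zero in this representation but reported for completeness.
    """
    weights = cfg.effective_weights()
    t_min, t_max = forest.min_t, forest.max_t
    totals = {k: 0.0 for k in DEFAULT_WEIGHTS}
    per_c = {} if per_centre else None
    for cid in forest.centres:
        terms = _centre_terms(forest, cid, cfg, t_min, t_max)
        for k, v in terms.items():
            totals[k] += v
        if per_centre:
            per_c[cid] = sum(weights[k] * v for k, v in terms.items())
    per_term = {k: weights[k] * v for k, v in totals.items()}
    return CostBreakdown(total=sum(per_term.values()), per_term=per_term,
                         per_centre=per_c)


# ----------------------------------------------------------------------
# stage 1: nearest-neighbour initialization
# ----------------------------------------------------------------------

def init_nearest_neighbour(centres_by_t: list[CentreSet], d_max: float) -> LineageForest:
    """Link every centre at t+1 to its nearest centre at t within ``d_max``.

    Centres are re-labelled with globally unique sequential ids (ordered by
    time, then input id).  The result may violate the two-daughter
    constraint; violations are left in place for the annealing stage.
    """
    if len(centres_by_t) < 2:
        raise ValueError("need at least two time steps to track")
    forest = LineageForest()
    id_maps: list[dict] = []
    next_id = 0
    for cs in centres_by_t:
        id_map = {}
        for c in sorted(cs.centres, key=lambda c: c.id):
            forest.add_centre(Centre(id=next_id, t=cs.t, pos=c.pos,
                                     intensity=c.intensity, virtual=c.virtual))
            id_map[c.id] = next_id
            next_id += 1
        id_maps.append(id_map)

    for t in range(1, len(centres_by_t)):
        prev, cur = centres_by_t[t - 1], centres_by_t[t]
        if len(prev) == 0 or len(cur) == 0:
            continue
        tree = cKDTree(prev.positions())
        dist, idx = tree.query(cur.positions())
        prev_sorted = sorted(prev.centres, key=lambda c: c.id)
        cur_sorted = sorted(cur.centres, key=lambda c: c.id)
        for ci, (d, j) in enumerate(zip(dist, idx)):
            if d <= d_max:
                mother = id_maps[t - 1][prev_sorted[j].id]
                daughter = id_maps[t][cur_sorted[ci].id]
                forest.add_link(mother, daughter)
    return forest


# ----------------------------------------------------------------------
# stage 2: simulated annealing
# ----------------------------------------------------------------------

def _candidate_mothers(forest: LineageForest, k: int) -> dict[int, list[int]]:
    """k nearest predecessors (previous frame) per centre, nearest first."""
    by_t: dict[int, list[int]] = {}
    for cid, c in forest.centres.items():
        by_t.setdefault(c.t, []).append(cid)
    for ids in by_t.values():
        ids.sort()
    cands: dict[int, list[int]] = {}
    for t, ids in sorted(by_t.items()):
        prev = by_t.get(t - 1)
        if not prev:
            continue
        tree = cKDTree(np.array([forest.centres[i].pos for i in prev]))
        pos = np.array([forest.centres[i].pos for i in ids])
        kk = min(k, len(prev))
        dist, idx = tree.query(pos, k=kk)
        idx = np.atleast_2d(idx.T).T if kk == 1 else idx
        for row, cid in zip(np.atleast_2d(idx), ids):
            cands[cid] = [prev[j] for j in np.atleast_1d(row)]
    return cands


def _affected(forest: LineageForest, seeds, cfg: AnnealConfig) -> set[int]:
    """Centres whose owned cost terms can change when the mother links of
    ``seeds`` (or their division status) change."""
    out: set[int] = set()
    for s in seeds:
        if s is None or s not in forest.centres:
            continue
        out.add(s)
        out.update(forest.daughters(s))
        # division-interval lookback: descendants within tau_div frames
        out.update(forest.descendants(s, max_frames=cfg.tau_div))
    return out


def _move_delta(forest, cfg, weights, t_min, t_max, seeds, apply, revert) -> float:
    """Cost change of a move, measured over the union of the centres affected
    in the pre- and post-move states; leaves the forest in the post state."""
    aff = _affected(forest, seeds, cfg)
    apply()
    aff |= _affected(forest, seeds, cfg)
    revert()
    before = sum(_centre_cost(forest, a, cfg, t_min, t_max, weights) for a in aff)
    apply()
    after = sum(_centre_cost(forest, a, cfg, t_min, t_max, weights) for a in aff)
    return after - before


def anneal(forest: LineageForest, cfg: AnnealConfig) -> LineageForest:
    """Optimize the link set by Metropolis annealing; enforces the hard
    constraints exactly in the returned forest.  Deterministic given seed."""
    forest = forest.copy()
    rng = np.random.default_rng(cfg.seed)
    weights = cfg.effective_weights()
    t_min, t_max = forest.min_t, forest.max_t
    cands = _candidate_mothers(forest, cfg.k_candidates)
    linkable = sorted(cands)
    if not linkable:
        return forest

    n_props = cfg.n_sweeps * len(linkable)
    for i in range(n_props):
        temp = cfg.T0 * (1.0 - (i + 1) / n_props)
        move = rng.integers(0, 4)
        if move == 3:
            # adopt + displace: attach a centre to a candidate mother while
            # rewiring one existing daughter of that mother elsewhere — a
            # single proposal for exchanges that would otherwise require an
            # uphill intermediate state
            cid = linkable[rng.integers(len(linkable))]
            cand = cands[cid]
            new_m = cand[rng.integers(len(cand))]
            old_m = forest.mother(cid)
            if new_m == old_m:
                continue
            ds = sorted(forest.daughters(new_m) - {cid})
            if not ds:
                continue
            d = ds[rng.integers(len(ds))]
            d_cand = [m for m in cands.get(d, []) if m != new_m] + [None]
            d_new_m = d_cand[rng.integers(len(d_cand))]
            d_old_m = new_m

            def _apply(a=cid, am=new_m, b=d, bm=d_new_m):
                forest.set_mother(b, bm)
                forest.set_mother(a, am)

            def _revert(a=cid, am=old_m, b=d, bm=d_old_m):
                forest.set_mother(a, am)
                forest.set_mother(b, bm)

            delta = _move_delta(forest, cfg, weights, t_min, t_max,
                                [cid, old_m, new_m, d, d_new_m],
                                apply=_apply, revert=_revert)
            if not _accept(delta, temp, rng):
                _revert()
            continue
        if move == 0 or move == 1:
            # rewire a centre's mother among its candidates, or delete its link
            cid = linkable[rng.integers(len(linkable))]
            cand = cands[cid]
            new_m = None if move == 1 else cand[rng.integers(len(cand))]
            old_m = forest.mother(cid)
            if new_m == old_m:
                continue
            delta = _move_delta(
                forest, cfg, weights, t_min, t_max, [cid, old_m, new_m],
                apply=lambda: forest.set_mother(cid, new_m),
                revert=lambda: forest.set_mother(cid, old_m),
            )
            if not _accept(delta, temp, rng):
                forest.set_mother(cid, old_m)
        else:
            # swap the mothers of two same-frame centres
            cid1 = linkable[rng.integers(len(linkable))]
            cid2 = linkable[rng.integers(len(linkable))]
            if cid1 == cid2 or forest.centres[cid1].t != forest.centres[cid2].t:
                continue
            m1, m2 = forest.mother(cid1), forest.mother(cid2)
            if m1 == m2:
                continue

            def _swap(a=cid1, b=cid2, ma=m2, mb=m1):
                forest.set_mother(a, ma)
                forest.set_mother(b, mb)

            def _unswap(a=cid1, b=cid2, ma=m1, mb=m2):
                forest.set_mother(a, ma)
                forest.set_mother(b, mb)

            delta = _move_delta(forest, cfg, weights, t_min, t_max,
                                [cid1, cid2, m1, m2], apply=_swap, revert=_unswap)
            if not _accept(delta, temp, rng):
                _unswap()

    _enforce_hard(forest, cfg)
    return forest


def _accept(delta: float, temp: float, rng) -> bool:
    if delta < 0:
        return True
    if temp <= 0:
        return False
    if delta == 0:
        return False
    return rng.random() < math.exp(-delta / temp)


def _enforce_hard(forest: LineageForest, cfg: AnnealConfig):
    """Drop the farthest excess daughters of any >2-daughter centre."""
    violations = []
    for cid in list(forest.centres):
        while forest.out_degree(cid) > 2:
            ds = forest.daughters(cid)
            pos_m = np.asarray(forest.centres[cid].pos)
            worst = max(ds, key=lambda d: (
                float(np.sum((np.asarray(forest.centres[d].pos) - pos_m) ** 2)),
                d,
            ))
            forest.unlink(worst)
            violations.append((cid, worst))
    if violations:
        warnings.warn(
            f"hard-constraint enforcement removed {len(violations)} excess links"
        )


# ----------------------------------------------------------------------
# stage 3: repair
# ----------------------------------------------------------------------

@dataclass
class _Edit:
    kind: str                  # "delete_branch" | "bridge_gap"
    payload: tuple


def _short_branches(forest: LineageForest, L_min: int) -> list[tuple[int, ...]]:
    out = []
    for root in forest.roots():
        sub = [root] + forest.descendants(root)
        span = max(forest.centres[i].t for i in sub) - forest.centres[root].t + 1
        if span < L_min:
            out.append(tuple(sub))
    return out


def _gap_pairs(forest: LineageForest, d_max: float) -> list[tuple[int, int]]:
    """(leaf at t, root at t+2) pairs within 2*d_max."""
    t_max = forest.max_t
    leaves_by_t: dict[int, list[int]] = {}
    roots_by_t: dict[int, list[int]] = {}
    for cid, c in forest.centres.items():
        if forest.out_degree(cid) == 0 and c.t < t_max - 1:
            leaves_by_t.setdefault(c.t, []).append(cid)
        if forest.mother(cid) is None and c.t > forest.min_t:
            roots_by_t.setdefault(c.t, []).append(cid)
    pairs = []
    for t, leaves in sorted(leaves_by_t.items()):
        roots = roots_by_t.get(t + 2)
        if not roots:
            continue
        rpos = np.array([forest.centres[r].pos for r in roots])
        tree = cKDTree(rpos)
        for leaf in sorted(leaves):
            hits = tree.query_ball_point(forest.centres[leaf].pos, 2.0 * d_max)
            for j in sorted(hits):
                pairs.append((leaf, roots[j]))
    return pairs


def repair(forest: LineageForest, cfg: AnnealConfig) -> LineageForest:
    """Delete short spurious branches and bridge 1-frame gaps with virtual
    centres, choosing edits by annealing over the candidate-edit set."""
    forest = forest.copy()
    rng = np.random.default_rng(cfg.seed + 1)

    edits: list[_Edit] = []
    branch_members: set[int] = set()
    for branch in _short_branches(forest, cfg.L_min):
        edits.append(_Edit("delete_branch", branch))
        branch_members.update(branch)
    for leaf, root in _gap_pairs(forest, cfg.d_max):
        # keep edit resources disjoint: never bridge onto a deletable branch
        if leaf not in branch_members and root not in branch_members:
            edits.append(_Edit("bridge_gap", (leaf, root)))
    if not edits:
        return forest

    applied: dict[int, object] = {}     # edit index -> undo payload
    cost = forest_cost(forest, cfg).total
    next_vid = forest.next_id()         # virtual ids are never reused

    def try_apply(i: int):
        nonlocal next_vid
        e = edits[i]
        if e.kind == "delete_branch":
            if not all(cid in forest.centres for cid in e.payload):
                return None
            removed = []
            for cid in e.payload:
                c = forest.centres[cid]
                removed.append((c, forest.mother(cid)))
            for cid in e.payload:
                forest.remove_centre(cid)
            return ("delete_branch", removed)
        leaf, root = e.payload
        if leaf not in forest.centres or root not in forest.centres:
            return None
        if forest.out_degree(leaf) != 0 or forest.mother(root) is not None:
            return None
        mid = 0.5 * (np.asarray(forest.centres[leaf].pos)
                     + np.asarray(forest.centres[root].pos))
        vid = next_vid
        next_vid += 1
        forest.add_centre(Centre(id=vid, t=forest.centres[leaf].t + 1,
                                 pos=tuple(mid), virtual=True))
        forest.add_link(leaf, vid)
        forest.add_link(vid, root)
        return ("bridge_gap", vid)

    def undo_apply(undo):
        kind, payload = undo
        if kind == "delete_branch":
            for c, _m in payload:
                forest.add_centre(c)
            for c, m in payload:
                if m is not None and m in forest.centres:
                    forest.add_link(m, c.id)
        else:
            forest.remove_centre(payload)

    n_props = max(40, 8 * len(edits))
    for p in range(n_props):
        temp = cfg.T0 * (1.0 - (p + 1) / n_props)
        i = int(rng.integers(len(edits)))
        if i in applied:
            undo_apply(applied[i])
            new_cost = forest_cost(forest, cfg).total
            if _accept(new_cost - cost, temp, rng):
                del applied[i]
                cost = new_cost
            else:
                applied[i] = try_apply(i)
        else:
            undo = try_apply(i)
            if undo is None:
                continue
            new_cost = forest_cost(forest, cfg).total
            if _accept(new_cost - cost, temp, rng):
                applied[i] = undo
                cost = new_cost
            else:
                undo_apply(undo)
    return forest


# ----------------------------------------------------------------------
# label propagation
# ----------------------------------------------------------------------

def propagate_labels(forest: LineageForest, labels: dict[int, object]) -> dict[int, object]:
    """Propagate each labelled centre's label to all its descendants.

    Conflicts are impossible because every centre has a single mother.
    """
    for cid in labels:
        if cid not in forest.centres:
            raise KeyError(f"unknown centre id {cid}")
    out = dict(labels)
    for cid in sorted(labels, key=lambda i: forest.centres[i].t):
        lab = labels[cid]
        for d in forest.descendants(cid):
            out[d] = lab
    return out


# ----------------------------------------------------------------------
# convenience front door
# ----------------------------------------------------------------------

def track(centres_by_t: list[CentreSet], cfg: AnnealConfig) -> LineageForest:
    """Full three-stage tracking: NN init → anneal → repair."""
    forest = init_nearest_neighbour(centres_by_t, cfg.d_max)
    forest = anneal(forest, cfg)
    forest = repair(forest, cfg)
    forest.validate()
    return forest
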