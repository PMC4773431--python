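"""Validation metrics against a gold-standard lineage.

A reconstruction is scored in three categories — nucleus centres, links
(each cell's mother, i.e. tracking one step into the past) and mitoses —
by matching detected centres to gold centres frame by frame and counting
true positives (TP), false positives (FP) and false negatives (FN).  For
links, FN splits into wrong links (WL, a link to an incorrect target,
counted in both FP and FN) and missing links (ML, no link at all, FN only).

Derived rates:

    sensitivity          = TP / (TP + FN)
    false detection rate = FP / (TP + FP)
    FN rate              = FN / (TP + FN)
    lineage score        = centre sensitivity × linkage sensitivity

Centre matching is one-to-one: maximum-cardinality, minimum-total-distance
bipartite matching with a pairing radius of ``r_factor`` times the mean
internuclear distance of the gold frame, so a single detected centre can
never stand in for two gold nuclei.  Link and mitosis accounting is
restricted to the TP centres, which means TP+FN equals the gold centre
count for centres but not for the other two categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .model import CentreSet, LineageForest

__all__ = [
    "GoldStandard",
    "ScopeBox",
    "ConfusionCounts",
    "MetricReport",
    "mean_internuclear_distance",
    "match_centres",
    "match_forests",
    "link_errors",
    "mitosis_errors",
    "metrics",
    "lineage_score",
    "score_forest",
]


@dataclass(frozen=True)
class ScopeBox:
    """Axis-aligned spatial box (µm) and time window where scoring is valid."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    t_start: int = 0
    t_end: int = 10 ** 9

    def __post_init__(self):
        if any(h <= l for l, h in zip(self.lo, self.hi)) or self.t_end < self.t_start:
            raise ValueError("degenerate scope box")

    def contains(self, pos, t: int) -> bool:
        return (self.t_start <= t <= self.t_end
                and all(l <= p <= h for p, l, h in zip(pos, self.lo, self.hi)))


@dataclass
class GoldStandard:
    """A curated lineage forest, optionally restricted to scope boxes."""

    forest: LineageForest
    scope: list[ScopeBox] = field(default_factory=list)

    def __post_init__(self):
        self.forest.validate()

    def in_scope(self, pos, t: int) -> bool:
        if not self.scope:
            return True
        return any(b.contains(pos, t) for b in self.scope)


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    WL: int = 0
    ML: int = 0

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.WL, self.ML) < 0:
            raise ValueError("counts must be >= 0")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.FN + other.FN, self.WL + other.WL,
                               self.ML + other.ML)


@dataclass
class MetricReport:
    sensitivity: float | None
    false_detection_rate: float | None
    fn_rate: float | None
    category: str = "centres"


def mean_internuclear_distance(centres: CentreSet) -> float:
    """Mean nearest-neighbour distance (µm) among centres of one frame."""
    if len(centres) < 2:
        raise ValueError("need >= 2 centres for an internuclear distance")
    pos = centres.positions()
    tree = cKDTree(pos)
    dist, _ = tree.query(pos, k=2)
    return float(dist[:, 1].mean())


def match_centres(detected: CentreSet, gold: CentreSet, r_factor: float = 0.5,
                  radius: float | None = None):
    """One-to-one centre matching at one time step.

    Returns ``(matching, counts)`` where ``matching`` maps detected id →
    gold id.  Pairs farther than ``r_factor × mean internuclear distance``
    of the gold frame (or an explicit ``radius`` in µm) are not allowed;
    among maximum-cardinality matchings the one with minimum total distance
    is chosen.  ``TP + FN == |gold|`` and ``TP + FP == |detected|``.
    """
    if r_factor <= 0:
        raise ValueError("r_factor must be > 0")
    nd, ng = len(detected), len(gold)
    if nd == 0 or ng == 0:
        return {}, ConfusionCounts(TP=0, FP=nd, FN=ng)
    if radius is None:
        if ng >= 2:
            radius = r_factor * mean_internuclear_distance(gold)
        else:
            radius = r_factor * float("inf")
    dpos, gpos = detected.positions(), gold.positions()
    dist = np.sqrt(((dpos[:, None, :] - gpos[None, :, :]) ** 2).sum(-1))
    allowed = dist <= radius
    # forbidden pairs get a cost so large that one extra match always wins
    big = (dist[allowed].max() if allowed.any() else 1.0) * (nd + ng + 1) + 1.0
    cost = np.where(allowed, dist, big)
    n = max(nd, ng)
    pad = np.full((n, n), big)
    pad[:nd, :ng] = cost
    rows, cols = linear_sum_assignment(pad)
    matching = {}
    dlist, glist = detected.centres, gold.centres  # positions() keeps this order
    for r, c in zip(rows, cols):
        if r < nd and c < ng and allowed[r, c]:
            matching[dlist[r].id] = glist[c].id
    tp = len(matching)
    return matching, ConfusionCounts(TP=tp, FP=nd - tp, FN=ng - tp)


def match_forests(detected: LineageForest, gold: GoldStandard,
                  r_factor: float = 0.5):
    """Frame-by-frame centre matching of two forests.

    Gold centres outside the gold scope are ignored entirely; detected
    centres outside the scope are likewise excluded rather than counted as
    false positives.  Returns ``(matching, counts)`` with the matching as a
    detected-id → gold-id dict over all frames.
    """
    gf = gold.forest
    t_lo = min(gf.min_t, detected.min_t)
    t_hi = max(gf.max_t, detected.max_t)
    matching: dict[int, int] = {}
    total = ConfusionCounts()
    for t in range(t_lo, t_hi + 1):
        gcs = CentreSet(t, [c for c in gf.centres_at(t)
                            if gold.in_scope(c.pos, t)])
        dcs = CentreSet(t, [c for c in detected.centres_at(t)
                            if gold.in_scope(c.pos, t)])
        m, counts = match_centres(dcs, gcs, r_factor=r_factor)
        matching.update(m)
        total = total + counts
    return matching, total


def link_errors(matching: dict[int, int], detected: LineageForest,
                gold: LineageForest) -> ConfusionCounts:
    """Link accounting restricted to TP centres whose gold twin has a mother.

    For each such centre: a correct mother under the matching is a TP link,
    a mother matched elsewhere (or unmatched) is a wrong link (WL, counted
    in FP and FN), no mother at all is a missing link (ML, FN only).
    """
    inv = {g: d for d, g in matching.items()}
    tp = fp = wl = ml = 0
    for d_id, g_id in matching.items():
        g_mother = gold.mother(g_id)
        if g_mother is None:
            continue
        if g_mother not in inv:
            continue  # gold mother not detected: link not assessable
        d_mother = detected.mother(d_id)
        if d_mother is None:
            ml += 1
        elif matching.get(d_mother) == g_mother:
            tp += 1
        else:
            wl += 1
    fp = wl
    return ConfusionCounts(TP=tp, FP=fp, FN=wl + ml, WL=wl, ML=ml)


def mitosis_errors(matching: dict[int, int], detected: LineageForest,
                   gold: LineageForest) -> ConfusionCounts:
    """Division accounting within the TP centres.

    A gold division whose mother and both daughters are TP counts as a TP
    division if the detected forest links the matched mother to both matched
    daughters, FN otherwise.  A detected division whose (TP) mother does not
    correspond to a gold division reproduced this way — e.g. a nucleus
    erroneously split in two — counts as FP.
    """
    inv = {g: d for d, g in matching.items()}
    tp = fn = fp = 0
    tp_division_mothers = set()
    for gm in gold.divisions():
        ga, gb = sorted(gold.daughters(gm))
        if gm not in inv or ga not in inv or gb not in inv:
            continue  # not all three detected: outside the assessable set
        dm = inv[gm]
        if detected.daughters(dm) == {inv[ga], inv[gb]}:
            tp += 1
            tp_division_mothers.add(dm)
        else:
            fn += 1
    for dm in detected.divisions():
        if dm not in matching:
            continue  # mother is not a TP centre: outside the assessable set
        if dm not in tp_division_mothers:
            fp += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn)


def metrics(counts: ConfusionCounts, category: str = "centres") -> MetricReport:
    """Sensitivity, false-detection rate and FN rate from raw counts.

    Zero denominators yield ``None`` (undefined), never 0.
    """
    sens = fnr = fdr = None
    if counts.TP + counts.FN > 0:
        sens = counts.TP / (counts.TP + counts.FN)
        fnr = counts.FN / (counts.TP + counts.FN)
    if counts.TP + counts.FP > 0:
        fdr = counts.FP / (counts.TP + counts.FP)
    return MetricReport(sensitivity=sens, false_detection_rate=fdr,
                        fn_rate=fnr, category=category)


def lineage_score(centre_report: MetricReport, link_report: MetricReport) -> float | None:
    """Global lineage score: centre sensitivity × linkage sensitivity."""
    if centre_report.sensitivity is None or link_report.sensitivity is None:
        return None
    return centre_report.sensitivity * link_report.sensitivity


def score_forest(detected: LineageForest, gold: GoldStandard,
                 r_factor: float = 0.5) -> dict:
    """Full three-category report of a reconstruction against a gold standard."""
    matching, centre_counts = match_forests(detected, gold, r_factor=r_factor)
    lc = link_errors(matching, detected, gold.forest)
    mc = mitosis_errors(matching, detected, gold.forest)
    centre_rep = metrics(centre_counts, "centres")
    link_rep = metrics(lc, "links")
    mito_rep = metrics(mc, "mitoses")
    return {
        "counts": {"centres": centre_counts, "links": lc, "mitoses": mc},
        "reports": {"centres": centre_rep, "links": link_rep, "mitoses": mito_rep},
        "lineage_score": lineage_score(centre_rep, link_rep),
        "matching": matching,
    }
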