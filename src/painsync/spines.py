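"""Dendritic protrusion classification, longitudinal matching, turnover.

A protrusion is a filopodium when it is long and thin — head/neck diameter
ratio < 1.2 and length/neck ratio > 3 — and a spine otherwise.  Spines are
matched across imaging sessions by arc-length position along the branch
(landmark registration is assumed done upstream): a spine is the same when
it sits within 0.7 μm of its expected position.  Formation/elimination
rates divide the spines gained/lost by the spine count of the first view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "classify_protrusion",
    "classify_table",
    "MatchResult",
    "match_protrusions",
    "turnover_rates",
    "InclusionReport",
    "inclusion_filter",
]

PROTRUSION_COLUMNS = ("id", "branch_id", "position_um", "length_um",
                      "head_diameter_um", "neck_diameter_um")


def classify_protrusion(length_um: float, head_diameter_um: float,
                        neck_diameter_um: float) -> str:
    """'filopodium' iff head/neck < 1.2 and length/neck > 3, else 'spine'."""
    if min(length_um, head_diameter_um, neck_diameter_um) <= 0:
        raise ValueError("protrusion geometry must be > 0")
    thin = head_diameter_um / neck_diameter_um < 1.2
    long_ = length_um / neck_diameter_um > 3.0
    return "filopodium" if (thin and long_) else "spine"


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a protrusion table with the 'class' column filled."""
    _check_table(table)
    out = table.copy()
    out["class"] = [classify_protrusion(r.length_um, r.head_diameter_um,
                                        r.neck_diameter_um)
                    for r in table.itertuples(index=False)]
    return out


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in PROTRUSION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"protrusion table missing columns {missing}")
    if table["id"].duplicated().any():
        dup = table.loc[table["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate protrusion id {dup!r} within session")
    if (table["position_um"] < 0).any():
        raise ValueError("positions must be non-negative")
    geom = table[["length_um", "head_diameter_um", "neck_diameter_um"]]
    if (geom.to_numpy() <= 0).any():
        raise ValueError("protrusion geometry must be > 0")


def _spines_only(table: pd.DataFrame) -> pd.DataFrame:
    if "class" not in table.columns:
        table = classify_table(table)
    return table[table["class"] == "spine"]


@dataclass
class MatchResult:
    """Greedy position matching between two sessions of one dendrite set.

    ``matched`` has one row per accepted pair (id_a, id_b, branch_id,
    distance_um); unmatched ids are listed per side.
    """

    matched: pd.DataFrame
    unmatched_a: list
    unmatched_b: list


def match_protrusions(view_a: pd.DataFrame, view_b: pd.DataFrame,
                      tol_um: float = 0.7,
                      spines_only: bool = True) -> MatchResult:
    """Match spines across two views by 1-D position along each branch.

    Candidate pairs within ``tol_um`` are accepted greedily in order of
    increasing distance (ties broken by lowest id on each side), each spine
    matched at most once.  Filopodia are excluded by default — turnover is
    a spine measure.  A warning is logged when several candidates fall
    within tolerance of one spine, since the tie rule then decides.
    """
    _check_table(view_a)
    _check_table(view_b)
    if spines_only:
        view_a, view_b = _spines_only(view_a), _spines_only(view_b)

    rows = []
    matched_a: set = set()
    matched_b: set = set()
    for branch in sorted(set(view_a["branch_id"]) & set(view_b["branch_id"])):
        sub_a = view_a[view_a["branch_id"] == branch]
        sub_b = view_b[view_b["branch_id"] == branch]
        pa = sub_a["position_um"].to_numpy()
        pb = sub_b["position_um"].to_numpy()
        dist = np.abs(pa[:, None] - pb[None, :])
        ia, ib = np.nonzero(dist <= tol_um)
        cands = sorted(
            ((float(dist[i, j]), str(sub_a["id"].iloc[i]),
              str(sub_b["id"].iloc[j]), sub_a["id"].iloc[i],
              sub_b["id"].iloc[j]) for i, j in zip(ia, ib)),
            key=lambda c: (c[0], c[1], c[2]))
        # ambiguity: one spine with several in-tolerance candidates
        if len(ia) > len(np.unique(ia)) or len(ib) > len(np.unique(ib)):
            warnings.warn(f"branch {branch!r}: multiple candidate matches "
                          f"within {tol_um} um; tie rule applied",
                          stacklevel=2)
        for d, _, _, id_a, id_b in cands:
            if id_a in matched_a or id_b in matched_b:
                continue
            matched_a.add(id_a)
            matched_b.add(id_b)
            rows.append(dict(id_a=id_a, id_b=id_b, branch_id=branch,
                             distance_um=d))
    matched = pd.DataFrame(rows, columns=["id_a", "id_b", "branch_id",
                                          "distance_um"])
    unmatched_a = [i for i in view_a["id"] if i not in matched_a]
    unmatched_b = [i for i in view_b["id"] if i not in matched_b]
    return MatchResult(matched=matched, unmatched_a=unmatched_a,
                       unmatched_b=unmatched_b)


def turnover_rates(views: list[pd.DataFrame], tol_um: float = 0.7,
                   reference: str = "first") -> pd.DataFrame:
    """Formation/elimination rates for each later view.

    With ``reference="first"`` (the rate definition) every view is compared
    against the first: eliminated spines are first-view spines with no
    match in that view, formed spines are that view's spines with no match
    in the first view, and both counts are divided by the first-view spine
    count (x100 for percent).  ``reference="consecutive"`` compares each
    view with its predecessor instead and divides by the predecessor's
    count — some designs mark changes between consecutive views.
    """
    if reference not in ("first", "consecutive"):
        raise ValueError(f"unknown reference mode {reference!r}")
    if len(views) < 2:
        raise ValueError("need at least 2 views")
    spine_views = [_spines_only(v) for v in views]
    if len(spine_views[0]) == 0:
        raise ValueError("first view holds no spines")
    rows = []
    for k in range(1, len(views)):
        ref_idx = 0 if reference == "first" else k - 1
        ref = spine_views[ref_idx]
        cur = spine_views[k]
        if len(ref) == 0:
            raise ValueError(f"reference view {ref_idx} holds no spines")
        m = match_protrusions(ref, cur, tol_um=tol_um)
        n_ref = len(ref)
        n_elim = len(m.unmatched_a)
        n_form = len(m.unmatched_b)
        rows.append(dict(interval=f"view{ref_idx}->view{k}",
                         n_first_view=n_ref, n_formed=n_form,
                         n_eliminated=n_elim,
                         formation_pct=100.0 * n_form / n_ref,
                         elimination_pct=100.0 * n_elim / n_ref))
    return pd.DataFrame(rows)


@dataclass
class InclusionReport:
    """Outcome of the analysis inclusion screen.

    Branches at or under the minimum length are dropped; animals at or
    under the minimum spine count are flagged (never silently dropped).
    """

    filtered: list[pd.DataFrame]
    excluded_branches: pd.DataFrame
    flagged_animals: pd.DataFrame


def inclusion_filter(tables: list[pd.DataFrame], min_branch_um: float = 30.0,
                     min_spines_per_animal: int = 150,
                     branch_lengths_um: dict | None = None) -> InclusionReport:
    """Apply the branch-length and spines-per-animal inclusion criteria.

    Branch length is taken from ``branch_lengths_um`` when given, otherwise
    inferred as the maximum spine position observed on the branch across
    sessions.  Branches must be strictly longer than ``min_branch_um``;
    animals (from an optional 'animal' column, else one implicit animal)
    must contribute strictly more than ``min_spines_per_animal`` spines,
    counted in the first session after branch filtering.
    """
    for t in tables:
        _check_table(t)
    if branch_lengths_um is None:
        lengths: dict = {}
        for t in tables:
            for b, g in t.groupby("branch_id"):
                lengths[b] = max(lengths.get(b, 0.0),
                                 float(g["position_um"].max()))
    else:
        lengths = dict(branch_lengths_um)

    short = {b for b, ln in lengths.items() if ln <= min_branch_um}
    excluded = pd.DataFrame(
        [dict(branch_id=b, length_um=lengths[b]) for b in sorted(short)],
        columns=["branch_id", "length_um"])
    filtered = [t[~t["branch_id"].isin(short)].reset_index(drop=True)
                for t in tables]

    first = _spines_only(filtered[0]) if filtered else pd.DataFrame()
    if "animal" in first.columns:
        counts = first.groupby("animal").size()
    else:
        counts = pd.Series({"animal0": len(first)})
    flagged = pd.DataFrame(
        [dict(animal=a, n_spines=int(n))
         for a, n in counts.items() if n <= min_spines_per_animal],
        columns=["animal", "n_spines"])
    return InclusionReport(filtered=filtered, excluded_branches=excluded,
                           flagged_animals=flagged)
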