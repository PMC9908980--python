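"""Mechanical-threshold and place-preference behavioural readouts.

Implements the Dixon up-down von Frey procedure: filaments step up after a
non-withdrawal and down after a withdrawal; once the response first
changes, the two straddling responses open a scored series of six, and the
50% withdrawal threshold follows

    threshold_g = 10 ** (Xf + kappa * delta) / 10,000

with Xf the log10 of the final filament force in 0.1 mg units, kappa a
pattern-dependent lookup value and delta the mean log-unit filament
spacing (0.2699 by default).  Also scores conditioned place preference
(time difference between drug- and vehicle-paired compartments) with the
pre-conditioning side-bias exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "FilamentSeries",
    "UpDownTrial",
    "load_kappa_table",
    "run_updown",
    "fifty_percent_threshold",
    "cpp_preference",
    "cpp_precondition_excluded",
]

#: standard 10-filament von Frey series, grams
DEFAULT_FORCES_G = (0.008, 0.02, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0, 4.0)

#: conventional mean log-unit spacing delta for this series
DEFAULT_DELTA_LOG = 0.2699

WITHDRAW, NO_WITHDRAW = "X", "O"


@dataclass(frozen=True)
class FilamentSeries:
    """Ordered filament forces plus the log-unit spacing used for kappa."""

    forces_g: tuple[float, ...] = DEFAULT_FORCES_G
    delta_log: float = DEFAULT_DELTA_LOG

    def __post_init__(self) -> None:
        if len(self.forces_g) < 2:
            raise ValueError("need at least two filaments")
        if any(f <= 0 for f in self.forces_g):
            raise ValueError("filament forces must be > 0")
        if any(b <= a for a, b in zip(self.forces_g, self.forces_g[1:])):
            raise ValueError("filament forces must be strictly increasing")
        if not (self.delta_log > 0):
            raise ValueError("delta_log must be > 0")

    def delta_from_series(self) -> float:
        """Mean log10 spacing computed from the forces themselves.

        For the standard series this is ~0.2999, which differs from the
        conventional constant 0.2699; both are exposed and the constant is
        the default.
        """
        logs = np.log10(self.forces_g)
        return float(np.mean(np.diff(logs)))


@dataclass
class UpDownTrial:
    """One complete up-down sequence and the threshold it implies.

    ``presented_indices``/``responses`` record every presentation (response
    True = withdrawal).  ``scored_start`` marks where the six scored
    presentations begin (the presentation just before the first response
    change); ``pattern`` is their X/O string.  Boundary-flagged trials exit
    the filament range before the score completes and carry the boundary
    force as threshold with no kappa.
    """

    presented_indices: list[int]
    responses: list[bool]
    crossing_index: int | None
    scored_start: int | None
    pattern: str
    kappa: float
    xf_log: float
    threshold_g: float
    boundary_flag: bool


def load_kappa_table(path: str | Path | None = None) -> dict[str, float]:
    """Load a pattern -> kappa lookup from a two-column text table.

    Lines are ``PATTERN<TAB-or-space>KAPPA``; patterns use X (withdrawal)
    and O (no withdrawal); ``#`` starts a comment.  With no path, the
    bundled default table is used.  The bundled values follow the
    simplified up-down convention (kappa = +0.5 when the final scored
    response is O, -0.5 when it is X); labs holding the full tabulated
    values can point this loader at their own file.
    """
    if path is None:
        text = (resources.files("painsync") / "data" /
                "kappa_default.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        pattern, value = line.split()
        if set(pattern) - {WITHDRAW, NO_WITHDRAW}:
            raise ValueError(f"bad pattern {pattern!r} in kappa table")
        table[pattern] = float(value)
    return table


def fifty_percent_threshold(xf_log: float, kappa: float,
                            delta: float = DEFAULT_DELTA_LOG) -> float:
    """50% withdrawal threshold in grams: 10^(Xf + kappa*delta) / 10,000.

    ``xf_log`` is log10 of the final filament force expressed in 0.1 mg
    units, i.e. ``log10(force_g * 1e4)`` — the /10,000 converts back to
    grams.
    """
    if not math.isfinite(xf_log):
        raise ValueError("xf_log must be finite")
    if not (delta > 0):
        raise ValueError("delta must be > 0")
    return 10.0 ** (xf_log + kappa * delta) / 10_000.0


def xf_log_of_force(force_g: float) -> float:
    """log10 of a filament force in 0.1 mg units."""
    if not (force_g > 0):
        raise ValueError("force must be > 0")
    return math.log10(force_g * 1e4)


def run_updown(responder, series: FilamentSeries | None = None,
               start_index: int = 4,
               kappa_table: dict[str, float] | None = None,
               n_scored: int = 6) -> UpDownTrial:
    """Drive one up-down trial against a responder callable.

    No withdrawal steps to the next stronger filament, withdrawal to the
    next weaker one.  Once the response first changes, the two responses
    straddling the threshold retrospectively open the scored series, which
    runs to ``n_scored`` presentations; the final filament and the scored
    X/O pattern then feed the 50% threshold formula.

    If the sequence needs a filament outside the series before the score
    completes (e.g. a subject that never withdraws at the strongest
    filament, or withdraws at the weakest), the trial is boundary-flagged
    and carries the boundary force as its threshold.
    """
    if series is None:
        series = FilamentSeries()
    if kappa_table is None:
        kappa_table = load_kappa_table()
    n_fil = len(series.forces_g)
    if not 0 <= start_index < n_fil:
        raise ValueError("start_index outside the filament series")

    presented: list[int] = []
    responses: list[bool] = []
    crossing: int | None = None
    boundary_exit = False
    i = start_index
    while True:
        presented.append(i)
        resp = bool(responder(series.forces_g[i]))
        responses.append(resp)
        t = len(responses) - 1
        if crossing is None and t >= 1 and resp != responses[0]:
            crossing = t
        # scored series complete?
        if crossing is not None and t - (crossing - 1) + 1 >= n_scored:
            break
        i = i - 1 if resp else i + 1
        if not 0 <= i < n_fil:
            boundary_exit = True
            break

    if boundary_exit:
        # exited the range before completing the score: assign boundary force
        bounds_force = series.forces_g[presented[-1]]
        scored_start = crossing - 1 if crossing is not None else None
        pattern = "".join(WITHDRAW if r else NO_WITHDRAW
                          for r in responses[scored_start:]) \
            if scored_start is not None else ""
        return UpDownTrial(presented_indices=presented, responses=responses,
                           crossing_index=crossing, scored_start=scored_start,
                           pattern=pattern, kappa=float("nan"),
                           xf_log=xf_log_of_force(bounds_force),
                           threshold_g=bounds_force, boundary_flag=True)

    scored_start = crossing - 1
    scored = responses[scored_start:scored_start + n_scored]
    pattern = "".join(WITHDRAW if r else NO_WITHDRAW for r in scored)
    try:
        kappa = kappa_table[pattern]
    except KeyError:
        raise KeyError(f"response pattern {pattern!r} missing from the "
                       "kappa table") from None
    xf = xf_log_of_force(series.forces_g[presented[-1]])
    thr = fifty_percent_threshold(xf, kappa, series.delta_log)
    return UpDownTrial(presented_indices=presented, responses=responses,
                       crossing_index=crossing, scored_start=scored_start,
                       pattern=pattern, kappa=kappa, xf_log=xf,
                       threshold_g=thr, boundary_flag=False)


def cpp_preference(time_paired_s: float, time_vehicle_s: float,
                   session_s: float = 600.0) -> float:
    """CPP preference score: time in drug-paired minus vehicle compartment."""
    for name, v in (("time_paired_s", time_paired_s),
                    ("time_vehicle_s", time_vehicle_s)):
        if not (0 <= v <= session_s):
            raise ValueError(f"{name}={v} outside [0, {session_s}] s")
    return float(time_paired_s) - float(time_vehicle_s)


def cpp_precondition_excluded(time_a_s: float, time_b_s: float,
                              limit_s: float = 400.0,
                              session_s: float = 600.0) -> bool:
    """Pre-conditioning screen: strong unconditioned side bias (>400 s).

    Returns True when the subject should be discarded before conditioning.
    """
    for v in (time_a_s, time_b_s):
        if not (0 <= v <= session_s):
            raise ValueError("compartment times must lie within the session")
    return max(time_a_s, time_b_s) > limit_s
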