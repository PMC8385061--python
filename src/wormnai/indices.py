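"""Neuronal Activation Index (NAI), Chemotaxis Index (CI), and the
single-worm chemotaxis score, with session aggregation.

NAI = 2(N_act/N_tot - 0.5), where N_act is the number of viable worms
whose olfactory neuron activated upon odor removal and N_tot the number
of viable worms tested. The centering at 1/2 forces symmetry around zero
and the prefactor 2 bounds |NAI| <= 1, putting the index on the same
[-1, 1] scale as the chemotaxis index

CI = (worms in odorant areas - worms in control areas) / total worms

so the two assays are directly comparable. Dispersion is propagated
assuming binomial counts.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SessionResult:
    """Activation counts and NAI for one sample in one session."""

    sample_id: str
    n_act: int
    n_tot: int

    def __post_init__(self) -> None:
        if self.n_tot < 1:
            raise ValueError("no viable nematodes (n_tot must be >= 1)")
        if not 0 <= self.n_act <= self.n_tot:
            raise ValueError("need 0 <= n_act <= n_tot")

    @property
    def nai(self) -> float:
        return compute_nai(self.n_act, self.n_tot)


@dataclass(frozen=True)
class PlateCount:
    """Worm counts per region of one quadrant chemotaxis plate."""

    plate_id: str
    n_odorant: int
    n_control: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_odorant, self.n_control, self.n_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_odorant + self.n_control > self.n_total:
            raise ValueError("scored worms exceed total worms")

    @property
    def ci(self) -> float:
        return compute_ci(self)


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject aggregated indices with dispersion and group label."""

    subject_id: str
    group: str  # "cancer" | "control"
    nai_mean: float
    nai_sd: float  # across sessions
    nai_sd_binomial: float  # from pooled counts
    ci_mean: float
    ci_sd: float
    n_worms_total: int


def compute_nai(n_act: int, n_tot: int) -> float:
    """Neuronal activation index 2(N_act/N_tot - 1/2), in [-1, 1]."""
    if n_tot < 1:
        raise ValueError("no viable nematodes (n_tot must be >= 1)")
    if not 0 <= n_act <= n_tot:
        raise ValueError("need 0 <= n_act <= n_tot")
    return 2.0 * (n_act / n_tot - 0.5)


def compute_ci(count: PlateCount) -> float:
    """Chemotaxis index (n_odorant - n_control)/n_total, in [-1, 1]."""
    if count.n_total < 1:
        raise ValueError("n_total must be >= 1")
    return (count.n_odorant - count.n_control) / count.n_total


def binomial_sd(index_value: float, n: int, kind: str = "nai") -> float:
    """Standard deviation of an index assuming binomial counts.

    For NAI = 2p - 1 with p estimated from n trials:
    sd = 2 sqrt(p(1-p)/n). The CI uses the same two-outcome
    approximation among the n worms that chose a scored area (callers
    pass the scored count as n; worms in neutral zones reduce it).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not -1.0 <= index_value <= 1.0:
        raise ValueError("index must lie in [-1, 1]")
    if kind not in ("nai", "ci"):
        raise ValueError("kind must be 'nai' or 'ci'")
    p = (index_value + 1.0) / 2.0
    return 2.0 * math.sqrt(p * (1.0 - p) / n)


#: study session policy: at least 2 sessions of at least 25 worms each,
#: hence at least 50 worms per subject
MIN_SESSIONS = 2
MIN_WORMS_PER_SESSION = 25


def aggregate_subject(
    subject_id: str,
    group: str,
    sessions: Sequence[SessionResult],
    plates: Sequence[PlateCount] = (),
    enforce_policy: bool = True,
) -> SubjectRecord:
    """Aggregate session NAIs and plate CIs into one subject record.

    Session NAIs are averaged unweighted (each experimental day counts
    once); the across-session sd and the binomial sd from the pooled
    counts are both reported. Policy violations (fewer than 2 sessions,
    or a session with fewer than 25 worms) warn but do not fail.
    """
    if len(sessions) == 0:
        raise ValueError(f"{subject_id}: no sessions to aggregate")
    if enforce_policy:
        if len(sessions) < MIN_SESSIONS:
            warnings.warn(
                f"{subject_id}: only {len(sessions)} session(s); study "
                f"policy asks for >= {MIN_SESSIONS}",
                stacklevel=2,
            )
        small = [s for s in sessions if s.n_tot < MIN_WORMS_PER_SESSION]
        if small:
            warnings.warn(
                f"{subject_id}: {len(small)} session(s) below "
                f"{MIN_WORMS_PER_SESSION} worms",
                stacklevel=2,
            )
    nais = np.array([s.nai for s in sessions], dtype=float)
    n_act = sum(s.n_act for s in sessions)
    n_tot = sum(s.n_tot for s in sessions)
    pooled_nai = compute_nai(n_act, n_tot)
    record_ci = float("nan")
    ci_sd = float("nan")
    if plates:
        cis = np.array([p.ci for p in plates], dtype=float)
        record_ci = float(cis.mean())
        ci_sd = float(cis.std(ddof=1)) if len(plates) > 1 else 0.0
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        nai_mean=float(nais.mean()),
        nai_sd=float(nais.std(ddof=1)) if len(sessions) > 1 else 0.0,
        nai_sd_binomial=binomial_sd(pooled_nai, n_tot, kind="nai"),
        ci_mean=record_ci,
        ci_sd=ci_sd,
        n_worms_total=n_tot,
    )


#: default sector scores for the single-worm track assay: concentric
#: sectors around the odor source score +2 (closest), +1, 0, -1, -2
#: (farthest / opposite side)
DEFAULT_SECTOR_SCORES: Mapping[str, int] = {
    "A": 2,
    "B": 1,
    "C": 0,
    "D": -1,
    "E": -2,
}


def single_worm_score(
    visited_sectors: Iterable[str],
    sector_scores: Mapping[str, float] | None = None,
) -> float:
    """Single-worm chemotaxis score: sum of the scores of the distinct
    plate sectors the animal's track crossed (repeat visits count once).
    """
    scores = DEFAULT_SECTOR_SCORES if sector_scores is None else sector_scores
    total = 0.0
    seen: set[str] = set()
    for sector in visited_sectors:
        if sector not in scores:
            raise KeyError(f"unknown sector {sector!r}")
        if sector in seen:
            continue
        seen.add(sector)
        total += scores[sector]
    return total
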