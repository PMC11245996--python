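"""Brute-force search for matched-mean, extreme-variance image quartets.

The goal is two four-image sets with the *same* mid-scale mean beauty
but opposite spread: a high-variance ("disputed") quartet whose ratings
scatter across the scale, and a low-variance ("undisputed") one that
everyone rates about the same.  Candidate images must have mean beauty
inside a window (default [3.5, 4.0], boundaries inclusive) and mean
typicality at or above a floor (default 3).  All C(n, 4) combinations of
eligible images are enumerated; each is scored by its *range statistic*
— the mean over participants of (max - min) of that participant's four
ratings — and the top (or bottom) quantile by that statistic is then
ranked by *group variance*, the mean of the four images'
across-participant SDs.  The final pick among ranked candidates (image
category diversity, faces, copyright) is left to the caller, supported
by an exclusion list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data import ImageSummary, RatingTable


@dataclass(frozen=True)
class SearchCriteria:
    """Eligibility filters and ranking mode for the quartet search."""

    beauty_mean_range: tuple[float, float] = (3.5, 4.0)
    typicality_min: float = 3.0
    quantile: float = 0.25
    mode: Literal["high_variance", "low_variance"] = "high_variance"
    exclusions: frozenset[str] = field(default_factory=frozenset)
    max_eligible: int = 200  # guard: C(n, 4) grows quartically

    def __post_init__(self) -> None:
        lo, hi = self.beauty_mean_range
        if lo > hi:
            raise ValueError("beauty_mean_range lower bound exceeds upper")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        if self.mode not in ("high_variance", "low_variance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "exclusions", frozenset(self.exclusions))


@dataclass(frozen=True)
class QuartetCandidate:
    """A four-image set with its spread statistics and rank."""

    image_ids: tuple[str, str, str, str]
    range_stat: float       # mean over participants of (max - min) rating
    group_sd_mean: float    # mean over images of across-participant SD
    n_participants: int     # participants with complete quartet coverage
    rank: int = -1


def eligible_images(summaries: Sequence[ImageSummary],
                    criteria: SearchCriteria) -> list[str]:
    """Image ids passing the mean-beauty window and typicality floor."""
    lo, hi = criteria.beauty_mean_range
    keep = []
    for s in summaries:
        if s.image_id in criteria.exclusions:
            continue
        if not (lo <= s.beauty_mean <= hi):
            continue
        if math.isnan(s.typicality_mean) or s.typicality_mean < criteria.typicality_min:
            continue
        keep.append(s.image_id)
    return sorted(keep)


def quartet_range_stat(table: RatingTable, quartet: Sequence[str],
                       session: int = 1) -> tuple[float, int]:
    """Mean over participants of (max - min) of their four ratings.

    Participants missing any quartet image are dropped; returns the
    statistic and the retained participant count.
    """
    if len(set(quartet)) != 4:
        raise ValueError("quartet must contain exactly 4 distinct image ids")
    mat = table.ratings_matrix(session=session, images=list(quartet), complete_only=True)
    if mat.empty:
        raise ValueError(f"no participant rated all of {sorted(quartet)}")
    vals = mat.to_numpy(dtype=float)
    return float(np.mean(vals.max(axis=1) - vals.min(axis=1))), len(mat)


def search_quartets(table: RatingTable, summaries: Sequence[ImageSummary],
                    criteria: SearchCriteria, session: int = 1) -> list[QuartetCandidate]:
    """Exhaustive quartet enumeration, quantile filter, group-variance rank.

    Enumerates all C(n, 4) combinations of eligible images, keeps the
    ceil(quantile * n_combinations) best by range statistic (largest for
    high-variance mode, smallest for low), and ranks survivors by group
    variance (descending for high, ascending for low).  Ties break by
    range statistic, then lexicographic image ids, so output is a pure
    function of the ratings.
    """
    ids = eligible_images(summaries, criteria)
    if len(ids) < 4:
        lo, hi = criteria.beauty_mean_range
        raise ValueError(
            f"only {len(ids)} eligible image(s) (need >= 4) after filters: "
            f"beauty mean in [{lo}, {hi}], typicality >= {criteria.typicality_min}, "
            f"{len(criteria.exclusions)} excluded, {len(summaries)} total")
    if len(ids) > criteria.max_eligible:
        raise ValueError(
            f"{len(ids)} eligible images exceed max_eligible={criteria.max_eligible}; "
            f"tighten the filters or raise the cap")

    sd_by_image = {s.image_id: s.beauty_sd for s in summaries}
    # one participant x image matrix up front; per-quartet slices are cheap
    mat = table.ratings_matrix(session=session, images=ids)
    vals = mat.to_numpy(dtype=float)
    col = {img: j for j, img in enumerate(mat.columns)}

    candidates = []
    for quartet in combinations(ids, 4):
        sub = vals[:, [col[i] for i in quartet]]
        complete = ~np.isnan(sub).any(axis=1)
        if not complete.any():
            continue
        sub = sub[complete]
        candidates.append(QuartetCandidate(
            image_ids=quartet,
            range_stat=float(np.mean(sub.max(axis=1) - sub.min(axis=1))),
            group_sd_mean=float(np.mean([sd_by_image[i] for i in quartet])),
            n_participants=int(complete.sum()),
        ))

    high = criteria.mode == "high_variance"
    # quantile filter on the range statistic
    n_keep = math.ceil(criteria.quantile * len(candidates))
    candidates.sort(key=lambda c: (-c.range_stat if high else c.range_stat,
                                   -c.group_sd_mean if high else c.group_sd_mean,
                                   c.image_ids))
    survivors = candidates[:n_keep]
    # rank survivors by group variance
    survivors.sort(key=lambda c: (-c.group_sd_mean if high else c.group_sd_mean,
                                  -c.range_stat if high else c.range_stat,
                                  c.image_ids))
    return [QuartetCandidate(c.image_ids, c.range_stat, c.group_sd_mean,
                             c.n_participants, rank=i + 1)
            for i, c in enumerate(survivors)]


def candidates_to_frame(candidates: Sequence[QuartetCandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "rank": c.rank,
        "image_ids": ";".join(c.image_ids),
        "range_stat": c.range_stat,
        "group_sd_mean": c.group_sd_mean,
        "n_participants": c.n_participants,
    } for c in candidates])
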