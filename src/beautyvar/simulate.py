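"""Synthetic rating-study generator.

Emulates the data structure of a two-quartet beauty-rating study so the
whole analysis pipeline is testable without any deposited dataset:

* per image, a latent-Gaussian-mixture "archetype": one component for
  consensus ("undisputed-like") images, two well-separated components
  for contested ("disputed-like") images whose ratings pile up at both
  ends of the scale;
* per participant x image, a latent affect value drawn from the
  archetype, discretized to the 1-7 Likert scale by round-half-away-
  from-zero then clipping;
* a second rating session whose latent values correlate with session 1
  at a configurable test-retest rho (induced pre-discretization, so the
  observed correlation is slightly attenuated);
* self-estimates of each participant's quartet mean and SD, and of
  number-set means and SDs, generated so the population correlation
  between estimate and actual equals a configured fidelity.

One RNG stream per logical block (ratings, retest, estimations), each
spawned from the master seed, with per-participant substreams for the
ratings so enlarging the sample leaves earlier participants' data
unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (EstimationRecord, LIKERT_MAX, LIKERT_MIN, NumberSet,
                   RatingTable)
from .stats import quartet_actuals


@dataclass(frozen=True)
class ImageArchetype:
    """Latent generating mixture for one image.

    ``components`` is a tuple of (weight, latent_mean, latent_sd); one
    component makes a unimodal, consensus-like image, two separated
    components a bimodal, contested-like one.
    """

    image_id: str
    components: tuple[tuple[float, float, float], ...]
    typicality_mean: float = 4.0
    condition: str | None = None

    def __post_init__(self) -> None:
        w = [c[0] for c in self.components]
        if abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
            raise ValueError(f"{self.image_id}: component weights must be "
                             f"nonnegative and sum to 1")
        if any(c[2] <= 0 for c in self.components):
            raise ValueError(f"{self.image_id}: latent SDs must be positive")
        if not LIKERT_MIN <= self.typicality_mean <= LIKERT_MAX:
            raise ValueError(f"{self.image_id}: typicality_mean outside [1, 7]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror the emulated study: 52 participants rating every
    image twice, high test-retest reliability (rho = 0.93), good mean-
    estimation fidelity (0.74) and near-absent SD-estimation fidelity
    (0.18).
    """

    n_participants: int = 52
    archetypes: tuple[ImageArchetype, ...] = ()
    test_retest_rho: float = 0.93
    estimation_mean_fidelity: float = 0.74
    estimation_sd_fidelity: float = 0.18
    two_sessions: bool = True
    typicality_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name in ("test_retest_rho", "estimation_mean_fidelity",
                     "estimation_sd_fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# study-condition archetype parameters: two components at 2 and 6
# (within-component SD 1) give an overall rating SD near 2.2, matching a
# contested image; a single component at 3.75 with SD 1.5 lands near 1.4
# after discretization, matching a consensus image.  Both keep the mean
# inside the 3.5-4 selection window.
DISPUTED_COMPONENTS = ((0.5, 2.0, 1.0), (0.5, 6.0, 1.0))
UNDISPUTED_COMPONENTS = ((1.0, 3.75, 1.5),)


def default_archetypes(n_disputed: int = 4, n_undisputed: int = 4,
                       n_foils: int = 0) -> tuple[ImageArchetype, ...]:
    """The standard simulated image set: contested and consensus quartet
    images (all eligible: mid-window mean, typicality >= 3) plus optional
    unimodal foils spread over the scale."""
    arch = []
    for i in range(n_disputed):
        arch.append(ImageArchetype(f"disputed_{i + 1}", DISPUTED_COMPONENTS,
                                   typicality_mean=4.5, condition="disputed"))
    for i in range(n_undisputed):
        arch.append(ImageArchetype(f"undisputed_{i + 1}", UNDISPUTED_COMPONENTS,
                                   typicality_mean=4.5, condition="undisputed"))
    foil_means = np.linspace(2.5, 5.5, n_foils) if n_foils else []
    for i, m in enumerate(foil_means):
        arch.append(ImageArchetype(f"foil_{i + 1}", ((1.0, float(m), 1.2),),
                                   typicality_mean=3.5, condition="foil"))
    return tuple(arch)


def _discretize(latent: np.ndarray) -> np.ndarray:
    """Round half away from zero, then clip to the Likert range."""
    rounded = np.sign(latent) * np.floor(np.abs(latent) + 0.5)
    return np.clip(rounded, LIKERT_MIN, LIKERT_MAX).astype(int)


def simulate_ratings(config: SimulationConfig) -> RatingTable:
    """Draw the full participant x image x session rating table."""
    if not config.archetypes:
        raise ValueError("config.archetypes is empty")
    ratings_ss, _retest_ss, _est_ss = np.random.SeedSequence(config.seed).spawn(3)
    part_streams = ratings_ss.spawn(config.n_participants)

    rows = []
    rho = config.test_retest_rho
    for p_idx, p_ss in enumerate(part_streams):
        rng = np.random.default_rng(p_ss)
        pid = f"p{p_idx + 1:03d}"
        for arch in config.archetypes:
            weights = np.array([c[0] for c in arch.components])
            j = rng.choice(len(weights), p=weights)
            _, m, s = arch.components[j]
            e1 = rng.standard_normal()
            e2 = rng.standard_normal()
            typ_latent = rng.normal(arch.typicality_mean, config.typicality_sd)
            beauty1 = int(_discretize(np.array([m + s * e1]))[0])
            typicality = int(_discretize(np.array([typ_latent]))[0])
            rows.append({"participant_id": pid, "image_id": arch.image_id,
                         "session": 1, "beauty": beauty1,
                         "typicality": typicality, "condition": arch.condition})
            if config.two_sessions:
                latent2 = m + s * (rho * e1 + np.sqrt(1.0 - rho * rho) * e2)
                rows.append({"participant_id": pid, "image_id": arch.image_id,
                             "session": 2,
                             "beauty": int(_discretize(np.array([latent2]))[0]),
                             "typicality": pd.NA, "condition": arch.condition})
    return RatingTable(pd.DataFrame(rows))


def _blend_to_fidelity(actual: np.ndarray, fidelity: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Estimates whose population correlation with ``actual`` is ``fidelity``.

    est = mean + fidelity * (actual - mean) + sqrt(1 - fidelity^2) * sd * z
    keeps the estimate on the actual's scale; fidelity 1 reproduces the
    actual exactly, fidelity 0 is pure independent noise.
    """
    actual = np.asarray(actual, dtype=float)
    mu = actual.mean()
    sd = actual.std(ddof=1) if actual.size > 1 else 0.0
    z = rng.standard_normal(actual.size)
    return mu + fidelity * (actual - mu) + np.sqrt(1.0 - fidelity ** 2) * sd * z


def simulate_estimations(table: RatingTable,
                         quartets: dict[str, Sequence[str]],
                         number_sets: Sequence[NumberSet],
                         config: SimulationConfig) -> list[EstimationRecord]:
    """Noisy self-estimates of quartet and number-set means and SDs.

    Quartet actuals come from each participant's session-1 ratings;
    number-set actuals are the sets' true statistics.  Estimates are
    fidelity-blended per stratum (one quartet; one set size).
    """
    _ratings_ss, _retest_ss, est_ss = np.random.SeedSequence(config.seed).spawn(3)
    rng = np.random.default_rng(est_ss)
    records: list[EstimationRecord] = []

    for qid in sorted(quartets):
        quartet = list(quartets[qid])
        if len(set(quartet)) != 4:
            raise ValueError(f"quartet {qid!r} must contain 4 distinct images")
        actuals = quartet_actuals(table, quartet, session=1).sort_index()
        est_mean = _blend_to_fidelity(actuals["actual_mean"].to_numpy(),
                                      config.estimation_mean_fidelity, rng)
        est_sd = _blend_to_fidelity(actuals["actual_sd"].to_numpy(),
                                    config.estimation_sd_fidelity, rng)
        for i, pid in enumerate(actuals.index):
            records.append(EstimationRecord(
                participant_id=str(pid), target_kind="quartet", target_id=qid,
                estimated_mean=float(est_mean[i]), estimated_sd=float(est_sd[i]),
                actual_mean=float(actuals["actual_mean"].iloc[i]),
                actual_sd=float(actuals["actual_sd"].iloc[i])))

    participants = table.participant_ids
    by_size: dict[int, list[NumberSet]] = {}
    for s in number_sets:
        by_size.setdefault(s.set_size, []).append(s)
    for size in sorted(by_size):
        sets = by_size[size]
        act_mean = np.array([s.mean for s in sets for _ in participants])
        act_sd = np.array([s.sd for s in sets for _ in participants])
        est_mean = _blend_to_fidelity(act_mean, config.estimation_mean_fidelity, rng)
        est_sd = _blend_to_fidelity(act_sd, config.estimation_sd_fidelity, rng)
        i = 0
        for s in sets:
            for pid in participants:
                records.append(EstimationRecord(
                    participant_id=pid, target_kind="number_set", target_id=s.set_id,
                    estimated_mean=float(est_mean[i]), estimated_sd=float(est_sd[i]),
                    actual_mean=float(act_mean[i]), actual_sd=float(act_sd[i])))
                i += 1
    return records


def simulate_model_histogram(weights: Sequence[float], means: Sequence[float],
                             sigma: float = 1.43, n_total: int = 200,
                             seed: int | np.random.SeedSequence = 0):
    """Histogram drawn from the Poisson-count mixture model itself.

    Each Likert bin's count is an independent Poisson draw with intensity
    ``n_total * sum_j A_j f(x_i; mu_j, sigma)`` — the self-consistent
    design for parameter-recovery checks of the mixture fitter (no
    latent-rating discretization, so the model is correctly specified).
    """
    from .data import RatingHistogram
    from .mixture import MixtureSpec, mixture_intensity

    spec = MixtureSpec(tuple(float(w) for w in weights),
                       tuple(float(m) for m in means),
                       sigma=sigma, count_scale=float(n_total))
    rng = np.random.default_rng(seed)
    x = np.arange(LIKERT_MIN, LIKERT_MAX + 1, dtype=float)
    lam = np.asarray(mixture_intensity(x, spec))
    counts = rng.poisson(lam)
    return RatingHistogram(counts=tuple(int(c) for c in counts))


def make_number_sets(seed: int = 0, sizes: Sequence[int] = (2, 4, 8),
                     sets_per_size: int = 8) -> list[NumberSet]:
    """Stimulus number sets: ``sets_per_size`` sets of each size, integer
    values uniform on 1..7 (the control task's scale)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 97)))
    out = []
    for size in sizes:
        for i in range(sets_per_size):
            vals = rng.integers(LIKERT_MIN, LIKERT_MAX + 1, size=size)
            out.append(NumberSet(f"set{size}_{i + 1}", tuple(float(v) for v in vals)))
    return out


def generating_manifest(config: SimulationConfig) -> dict:
    """JSON-ready record of the true generating parameters (for recovery
    tests and reproducibility)."""
    return {
        "n_participants": config.n_participants,
        "test_retest_rho": config.test_retest_rho,
        "estimation_mean_fidelity": config.estimation_mean_fidelity,
        "estimation_sd_fidelity": config.estimation_sd_fidelity,
        "two_sessions": config.two_sessions,
        "seed": config.seed,
        "archetypes": [dataclasses.asdict(a) for a in config.archetypes],
    }


def write_manifest(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(generating_manifest(config), indent=2) + "\n")
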