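"""Neutral single-locus Wright-Fisher simulation under piecewise demography.

Estimates the probability that a neutral polymorphism started at a given
frequency is still segregating after a population-size history such as one
inferred by PSMC.  The history is a piecewise-constant schedule of
(generations before present, Ne) segments; within a segment of diploid
size N the allele count evolves as Binomial(2N, p) per generation with no
recurrent mutation, so fixation and loss are absorbing.

The most recent PSMC segments are typically unreliable and can be dropped
with :func:`truncate_recent`, which shortens the simulated span by their
combined generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DemographySchedule",
    "RetentionResult",
    "dominant_freq",
    "truncate_recent",
    "wf_run",
    "retention_probability",
    "constant_schedule",
]

LOST, FIXED, SEGREGATING = "lost", "fixed", "segregating"


@dataclass
class DemographySchedule:
    """Piecewise-constant (generation before present, Ne) history.

    ``segments`` is ordered from the oldest to the most recent: start
    generations strictly decreasing toward the present.  A segment with
    start g applies from generation g (before present) down to the next
    segment's start (or ``end_generation``).  ``mutation_rate`` and
    ``generation_time_years`` are carried for scaling helpers only; the
    simulation itself is mutation-free at the focal site.
    """

    segments: list[tuple[int, float]]
    end_generation: int = 0
    mutation_rate: float = 3.5e-9
    generation_time_years: float = 0.5

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        starts = [int(g) for g, _ in self.segments]
        if any(b >= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start generations must strictly decrease")
        if any(ne <= 0 for _, ne in self.segments):
            raise ValueError("all Ne values must be positive")
        if starts[-1] <= self.end_generation and self.end_generation > 0:
            raise ValueError("end_generation must precede the youngest segment start")

    @property
    def span_generations(self) -> int:
        return int(self.segments[0][0]) - self.end_generation

    def ne_per_generation(self) -> np.ndarray:
        """Diploid N for each simulated generation, oldest first.

        Ne values are rounded to the nearest integer >= 1 (binomial
        sampling needs integer chromosome counts; PSMC emits reals).
        """
        starts = np.array([int(g) for g, _ in self.segments])
        nes = np.array([max(1, round(ne)) for _, ne in self.segments], dtype=np.int64)
        bounds = np.append(starts, self.end_generation)
        out = np.empty(self.span_generations, dtype=np.int64)
        offset = 0
        for i in range(len(starts)):
            span = int(bounds[i] - bounds[i + 1])
            out[offset : offset + span] = nes[i]
            offset += span
        return out

    @classmethod
    def from_table(cls, path_or_df, **kwargs) -> "DemographySchedule":
        """Build from a TSV/DataFrame with columns generation_before_present
        and Ne (ordered or not; sorted oldest-first here)."""
        df = (
            path_or_df
            if isinstance(path_or_df, pd.DataFrame)
            else pd.read_csv(path_or_df, sep="\t")
        )
        df = df.sort_values("generation_before_present", ascending=False)
        segments = list(
            zip(df["generation_before_present"].astype(int), df["Ne"].astype(float))
        )
        return cls(segments=segments, **kwargs)

    def to_table(self, path: str) -> None:
        pd.DataFrame(
            self.segments, columns=["generation_before_present", "Ne"]
        ).to_csv(path, sep="\t", index=False)


def constant_schedule(ne: float, generations: int, **kwargs) -> DemographySchedule:
    """Single-segment schedule: constant Ne for the given number of
    generations."""
    return DemographySchedule(segments=[(int(generations), float(ne))], **kwargs)


@dataclass
class RetentionResult:
    """Outcome tally of replicate drift simulations."""

    n_reps: int
    n_segregating: int
    n_fixed: int
    n_lost: int
    p0: float
    seed: int
    retention_prob: float = field(init=False)
    retention_se: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_segregating + self.n_fixed + self.n_lost != self.n_reps:
            raise ValueError("outcome counts must sum to n_reps")
        self.retention_prob = self.n_segregating / self.n_reps
        self.retention_se = math.sqrt(
            self.retention_prob * (1.0 - self.retention_prob) / self.n_reps
        )

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "n_segregating": self.n_segregating,
            "n_fixed": self.n_fixed,
            "n_lost": self.n_lost,
            "retention_prob": self.retention_prob,
            "retention_se": self.retention_se,
            "p0": self.p0,
            "seed": self.seed,
        }


def dominant_freq(f_pheno: float) -> float:
    """Expected allele frequency of a fully dominant allele observed at
    phenotype frequency ``f_pheno`` under HWE: ``1 - sqrt(1 - f)``."""
    if not 0.0 <= f_pheno <= 1.0:
        raise ValueError(f"phenotype frequency must be in [0, 1], got {f_pheno}")
    return 1.0 - math.sqrt(1.0 - f_pheno)


def truncate_recent(
    schedule: DemographySchedule, n_segments: int = 4
) -> DemographySchedule:
    """Drop the ``n_segments`` most recent segments.

    The simulation then stops at the start generation of the oldest
    removed segment, shortening the simulated span by exactly the removed
    segments' combined generations.
    """
    if n_segments == 0:
        return schedule
    if len(schedule.segments) <= n_segments:
        raise ValueError(
            f"cannot remove {n_segments} segments from a "
            f"{len(schedule.segments)}-segment schedule"
        )
    kept = schedule.segments[:-n_segments]
    new_end = int(schedule.segments[-n_segments][0])
    return DemographySchedule(
        segments=kept,
        end_generation=new_end,
        mutation_rate=schedule.mutation_rate,
        generation_time_years=schedule.generation_time_years,
    )


def wf_run(schedule: DemographySchedule, p0: float, seed: int = 0) -> str:
    """One Wright-Fisher trajectory; returns 'lost', 'fixed' or
    'segregating' (both alleles present at the final generation)."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if p0 == 0.0:
        return LOST
    if p0 == 1.0:
        return FIXED
    rng = np.random.default_rng(seed)
    ne = schedule.ne_per_generation()
    count = int(round(p0 * 2 * ne[0]))
    two_n_prev = 2 * ne[0]
    if count == 0:
        return LOST
    if count == two_n_prev:
        return FIXED
    for n in ne:
        two_n = 2 * n
        count = rng.binomial(two_n, count / two_n_prev)
        two_n_prev = two_n
        if count == 0:
            return LOST
        if count == two_n:
            return FIXED
    return SEGREGATING


def retention_probability(
    schedule: DemographySchedule,
    p0: float,
    n_reps: int = 10_000,
    seed: int = 0,
) -> RetentionResult:
    """Fraction of replicate trajectories still polymorphic at the end.

    Replicates are advanced in a single vectorized batch (one binomial
    draw per generation across all unabsorbed replicates) from one seeded
    generator, so results are reproducible given (schedule, p0, n_reps,
    seed).
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ne = schedule.ne_per_generation()
    two_n0 = 2 * ne[0]
    counts = np.full(n_reps, int(round(p0 * two_n0)), dtype=np.int64)
    two_n_prev = two_n0
    alive = (counts > 0) & (counts < two_n0)
    n_lost = int(np.count_nonzero(counts == 0))
    n_fixed = int(np.count_nonzero(counts == two_n0))
    for n in ne:
        if not alive.any():
            break
        two_n = 2 * int(n)
        idx = np.flatnonzero(alive)
        counts[idx] = rng.binomial(two_n, counts[idx] / two_n_prev)
        newly_lost = idx[counts[idx] == 0]
        newly_fixed = idx[counts[idx] == two_n]
        n_lost += newly_lost.size
        n_fixed += newly_fixed.size
        alive[newly_lost] = False
        alive[newly_fixed] = False
        two_n_prev = two_n
    n_seg = int(np.count_nonzero(alive))
    return RetentionResult(
        n_reps=n_reps,
        n_segregating=n_seg,
        n_fixed=n_fixed,
        n_lost=n_lost,
        p0=p0,
        seed=seed,
    )
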