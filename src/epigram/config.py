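"""Genetic-algorithm configuration shared by both search stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class GAConfig:
    """Tunables for the mark/regenerate genetic algorithm.

    Both GA stages (train/test split search and sequence-length search) use
    the same loop: each iteration regenerates every solution marked
    ``to_be_modified``, accepts a candidate only if its fitness beats the
    running best, then marks solutions whose fitness exceeds
    ``mean(fitness) * mu`` as survivors for the next iteration.

    Parameters
    ----------
    ns : int
        Number of solutions held per iteration. Defaults to
        ``population_size``.
    ni : int
        Number of iterations. Defaults to ``max_iterations``.
    mu : float
        Mutation factor in (0, 1]; scales the mean-fitness survival
        threshold. Defaults to ``mutation_rate``.
    tr : float
        Train-to-test ratio in (0, 1): fraction of rows placed in the
        training partition (rounded to keep per-class counts equal).
    population_size, chromosome_length, n_runs, max_iterations,
    selection_rate, crossover_rate, mutation_rate :
        The published parameter table. ``selection_rate`` and
        ``crossover_rate`` are carried for completeness but unused: the
        search procedure implemented here has no pairwise selection or
        crossover step, only the mark/regenerate scheme.
    max_regen : int
        Cap on regeneration attempts per solution slot per iteration; when
        exhausted the best rejected candidate is kept (guarantees
        termination).
    seed : int
        Seed for the single random generator driving every stochastic draw.
    """

    ns: int | None = None
    ni: int | None = None
    mu: float | None = None
    tr: float = 0.7
    population_size: int = 100
    chromosome_length: int = 20
    n_runs: int = 10
    max_iterations: int = 100
    selection_rate: float = 0.8
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    max_regen: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ns is None:
            self.ns = self.population_size
        if self.ni is None:
            self.ni = self.max_iterations
        if self.mu is None:
            self.mu = self.mutation_rate
        if self.ns < 1 or self.ni < 1:
            raise ValueError("ns and ni must be >= 1")
        if not (0.0 < self.mu <= 1.0):
            raise ValueError("mu must lie in (0, 1]")
        if not (0.0 < self.tr < 1.0):
            raise ValueError("tr must lie in (0, 1)")
        for name in ("selection_rate", "crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict, required: tuple[str, ...] = ()) -> "GAConfig":
        """Build from a config mapping; unknown or missing keys raise."""
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown GA config field(s): {sorted(unknown)}")
        missing = [k for k in required if k not in d]
        if missing:
            raise ValueError(f"missing required GA config field(s): {missing}")
        return cls(**d)
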