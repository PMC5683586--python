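"""Scenario parameterization for the forward simulator.

Times are in generations before sampling (BP); epoch entries apply from
their time down to the next (younger) entry. The root population exists for
the whole run (burn-in plus the oldest event time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Split:
    time_bp: int
    source: str
    daughter: str
    n_founders: int


@dataclass
class Pulse:
    time_bp: int
    donor: str
    recipient: str
    fraction: float


@dataclass
class Sweep:
    """Beneficial allele injected into a population at a point in time."""

    time_bp: int
    population: str
    chrom: str
    pos: int
    s_benefit: float  # fitness advantage of the homozygote
    init_freq: float = 0.3


@dataclass
class SimScenario:
    chrom_lengths: dict[str, int]
    mu: float  # per bp per gamete per generation
    cm_per_mb: float
    root: str
    epochs: dict[str, list[tuple[int, int]]]  # pop -> [(time_bp, diploid size), ...]
    burn_in: int
    splits: list[Split] = field(default_factory=list)
    pulses: list[Pulse] = field(default_factory=list)
    sweeps: list[Sweep] = field(default_factory=list)
    frac_deleterious: float = 0.0
    s_mean: float = 0.02
    s_shape: float | None = None  # None: point mass at s_mean, else gamma shape
    h: float = 0.2
    kin_structured: bool = False
    sibship_size: int = 4
    sib_mating_pop: str | None = None  # plant parents-are-siblings for sample 0
    n_sample: int = 6
    origin: tuple[float, float] = (0.0, -100.0)
    step_km: float = 1000.0
    pop_steps: dict[str, int] = field(default_factory=dict)
    reference_pop: str | None = None
    ancestry_marker_bp: int | None = None  # auto grid when pulses present
    prune_interval: int = 5

    def __post_init__(self) -> None:
        if self.mu < 0 or self.cm_per_mb < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.frac_deleterious <= 1.0:
            raise ValueError("frac_deleterious must be in [0,1]")
        for p in self.pulses:
            if not 0.0 < p.fraction < 1.0:
                raise ValueError("pulse fraction must be in (0,1)")
        for s in self.splits:
            if s.n_founders < 1:
                raise ValueError("founder count must be >= 1")
        names = set(self.epochs)
        for s in self.splits:
            if s.source not in names or s.daughter not in names:
                raise ValueError(f"split references unknown population: {s}")
        for p in self.pulses:
            if p.donor not in names or p.recipient not in names:
                raise ValueError(f"pulse references unknown population: {p}")
        founded = {s.daughter: s.time_bp for s in self.splits}
        for pop, entries in self.epochs.items():
            times = [t for t, _ in entries]
            if times != sorted(times, reverse=True):
                raise ValueError(f"{pop}: epoch times must be ordered old to young")
            if any(n < 1 for _, n in entries):
                raise ValueError(f"{pop}: sizes must be >= 1")
            if pop != self.root and pop not in founded:
                raise ValueError(f"{pop} has epochs but is never founded by a split")

    # -- schedule helpers ---------------------------------------------------

    @property
    def total_generations(self) -> int:
        event_times = [s.time_bp for s in self.splits]
        event_times += [p.time_bp for p in self.pulses]
        event_times += [s.time_bp for s in self.sweeps]
        for pop, entries in self.epochs.items():
            if pop != self.root:
                event_times += [t for t, _ in entries]
        return self.burn_in + (max(event_times) if event_times else 0)

    def founding_time(self, pop: str) -> int:
        if pop == self.root:
            return self.total_generations
        for s in self.splits:
            if s.daughter == pop:
                return s.time_bp
        raise KeyError(pop)

    def size_at(self, pop: str, time_bp: int) -> int:
        size = None
        for t, n in self.epochs[pop]:
            if t >= time_bp:
                size = n
            else:
                break
        if size is None:
            # before the first epoch entry: use the oldest size
            size = self.epochs[pop][0][1]
        return size

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    @property
    def total_cm(self) -> float:
        return self.genome_length * self.cm_per_mb / 1e6

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "chrom_lengths": dict(self.chrom_lengths),
            "mu": self.mu,
            "cm_per_mb": self.cm_per_mb,
            "root": self.root,
            "epochs": {k: [list(e) for e in v] for k, v in self.epochs.items()},
            "burn_in": self.burn_in,
            "splits": [vars(s) for s in self.splits],
            "pulses": [vars(p) for p in self.pulses],
            "sweeps": [vars(s) for s in self.sweeps],
            "frac_deleterious": self.frac_deleterious,
            "s_mean": self.s_mean,
            "s_shape": self.s_shape,
            "h": self.h,
            "kin_structured": self.kin_structured,
            "sibship_size": self.sibship_size,
            "sib_mating_pop": self.sib_mating_pop,
            "n_sample": self.n_sample,
            "origin": list(self.origin),
            "step_km": self.step_km,
            "pop_steps": dict(self.pop_steps),
            "reference_pop": self.reference_pop,
            "ancestry_marker_bp": self.ancestry_marker_bp,
            "prune_interval": self.prune_interval,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        d["epochs"] = {k: [tuple(e) for e in v] for k, v in d["epochs"].items()}
        d["splits"] = [Split(**s) for s in d.get("splits", [])]
        d["pulses"] = [Pulse(**p) for p in d.get("pulses", [])]
        d["sweeps"] = [Sweep(**s) for s in d.get("sweeps", [])]
        d["origin"] = tuple(d.get("origin", (0.0, -100.0)))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_scenario(**overrides) -> SimScenario:
    """Documented default: ancestral N=500 source; bottleneck to N=50 for 100
    generations then recovery to 500; serial founder chain of 4 daughters with
    20 founders each (step_km=1000); constant N=1000 donor; pulse f=0.1 into
    the second chain step 30 generations before sampling; 10 x 1 Mb genome,
    mu=1e-7, 1 cM/Mb; 6 diploids sampled per population."""
    chrom_lengths = {f"chr{i}": 1_000_000 for i in range(1, 11)}
    base = dict(
        chrom_lengths=chrom_lengths,
        mu=1e-7,
        cm_per_mb=1.0,
        root="source",
        epochs={
            "source": [(10**9, 500)],
            "donor": [(600, 1000)],
            "domesticate": [(400, 50), (300, 500)],
            "step1": [(240, 200)],
            "step2": [(180, 200)],
            "step3": [(120, 200)],
            "step4": [(60, 200)],
        },
        burn_in=5000,
        splits=[
            Split(600, "source", "donor", 200),
            Split(400, "source", "domesticate", 50),
            Split(240, "domesticate", "step1", 20),
            Split(180, "step1", "step2", 20),
            Split(120, "step2", "step3", 20),
            Split(60, "step3", "step4", 20),
        ],
        pulses=[Pulse(30, "donor", "step2", 0.1)],
        frac_deleterious=0.25,
        s_mean=0.015,
        s_shape=None,
        h=0.2,
        n_sample=6,
        step_km=1000.0,
        pop_steps={
            "source": 0,
            "donor": 0,
            "domesticate": 0,
            "step1": 1,
            "step2": 2,
            "step3": 3,
            "step4": 4,
        },
        reference_pop="domesticate",
    )
    base.update(overrides)
    return SimScenario(**base)


def neutral_scenario(
    n: int = 200,
    theta_per_bp: float = 1e-3,
    chrom_bp: int = 50_000,
    burn_in_n: int = 10,
    **overrides,
) -> SimScenario:
    """Constant-size neutral population for estimator calibration: mutation
    rate chosen so 4*N*mu per bp equals ``theta_per_bp``."""
    base = dict(
        chrom_lengths={"chr1": chrom_bp},
        mu=theta_per_bp / (4.0 * n),
        cm_per_mb=1.0,
        root="pop",
        epochs={"pop": [(10**9, n)]},
        burn_in=burn_in_n * n,
        n_sample=10,
        pop_steps={"pop": 0},
    )
    base.update(overrides)
    return SimScenario(**base)


def introgression_scenario(fraction: float | None = 0.1, **overrides) -> SimScenario:
    """Compact three-population tree for D / f_d replicate suites:
    P1 = source, P2 = daughter with an optional donor pulse, P3 = donor."""
    pulses = [Pulse(16, "donor", "p2", fraction)] if fraction else []
    # dense map: short chromosomes need extra recombination to decorrelate
    # jackknife blocks (otherwise the genome is ~3 independent loci)
    base = dict(
        chrom_lengths={f"chr{i}": 250_000 for i in range(1, 5)},
        mu=1.75e-6,
        cm_per_mb=30.0,
        root="source",
        epochs={
            "source": [(10**9, 80)],
            "donor": [(340, 96)],
            "p2": [(64, 40)],
        },
        burn_in=480,
        splits=[
            Split(340, "source", "donor", 80),
            Split(64, "source", "p2", 21),
        ],
        pulses=pulses,
        n_sample=6,
        pop_steps={"source": 0, "donor": 0, "p2": 1},
    )
    base.update(overrides)
    return SimScenario(**base)


def roh_scenario(sib_mating: bool = True, **overrides) -> SimScenario:
    """Single population with megabase chromosomes so that long runs of
    homozygosity can form; optionally plants a child of full siblings as the
    first sampled individual."""
    base = dict(
        chrom_lengths={f"chr{i}": 2_000_000 for i in range(1, 7)},
        mu=4e-7,
        cm_per_mb=1.0,
        root="pop",
        epochs={"pop": [(10**9, 80)]},
        burn_in=600,
        sib_mating_pop="pop" if sib_mating else None,
        n_sample=6,
        pop_steps={"pop": 0},
    )
    base.update(overrides)
    return SimScenario(**base)


def desk_scenario(**overrides) -> SimScenario:
    """Scaled-down variant of the default scenario for fast test runs: same
    event structure with smaller populations, a 4 x 300 kb genome, and a
    higher mutation rate to retain usable site counts."""
    chrom_lengths = {f"chr{i}": 300_000 for i in range(1, 5)}
    base = dict(
        chrom_lengths=chrom_lengths,
        mu=4e-7,
        cm_per_mb=30.0,
        root="source",
        epochs={
            "source": [(10**9, 120)],
            "donor": [(420, 300)],
            "domesticate": [(300, 16), (220, 120)],
            "step1": [(180, 40)],
            "step2": [(140, 40)],
            "step3": [(100, 40)],
            "step4": [(60, 40)],
        },
        burn_in=800,
        splits=[
            Split(420, "source", "donor", 100),
            Split(300, "source", "domesticate", 20),
            Split(180, "domesticate", "step1", 6),
            Split(140, "step1", "step2", 6),
            Split(100, "step2", "step3", 6),
            Split(60, "step3", "step4", 6),
        ],
        pulses=[Pulse(25, "donor", "step2", 0.1)],
        frac_deleterious=0.35,
        s_mean=0.015,
        s_shape=None,
        h=0.2,
        n_sample=8,
        step_km=1000.0,
        pop_steps={
            "source": 0,
            "donor": 0,
            "domesticate": 0,
            "step1": 1,
            "step2": 2,
            "step3": 3,
            "step4": 4,
        },
        reference_pop="domesticate",
    )
    base.update(overrides)
    return SimScenario(**base)
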