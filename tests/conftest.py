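"""Shared fixtures: small deterministic genotype fixtures for oracle tests
and session-scoped simulation batteries reused across property and
acceptance tests (they are expensive, so they are built once)."""

from __future__ import annotations

import numpy as np
import pytest

from popload.io_core import GenotypeMatrix, SiteAnnotation, attach_scores, polarize
from popload.synthetic_data import desk_scenario, simulate
from popload.synthetic_data.scenario import introgression_scenario


def random_matrix(
    rng: np.random.Generator,
    n_samples: int = 8,
    n_sites: int = 200,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    missing_rate: float = 0.05,
    populations: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Random biallelic matrix with sorted sites and some missing calls."""
    per = max(1, n_sites // len(chroms))
    chrom, pos = [], []
    for k, c in enumerate(chroms):
        n_here = n_sites - per * (len(chroms) - 1) if k == len(chroms) - 1 else per
        if n_here <= 0:
            continue
        p = np.sort(rng.choice(np.arange(1, 10_000_000), size=n_here, replace=False))
        chrom.extend([c] * n_here)
        pos.extend(p.tolist())
    n_sites = len(pos)
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_sites)]
    alt = np.array([bases[(bases != r)][rng.integers(0, 3)] for r in ref], dtype=object)
    dosage = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    miss = rng.random((n_samples, n_sites)) < missing_rate
    dosage[miss] = -1
    samples = [f"s{i}" for i in range(n_samples)]
    pops = populations or {s: ("A" if i < n_samples // 2 else "B") for i, s in enumerate(samples)}
    return GenotypeMatrix(
        samples=samples,
        populations=pops,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=ref.astype(object),
        alt=alt,
        dosage=dosage,
    )


def random_annotation(
    rng: np.random.Generator, gm: GenotypeMatrix, score_scale: float = 2.0
) -> SiteAnnotation:
    """Random polarization + scores for ``gm`` (some sites excluded)."""
    out_alleles = {}
    for j in range(gm.n_sites):
        r = rng.random()
        if r < 0.45:
            out_alleles[(gm.chrom[j], int(gm.pos[j]))] = gm.ref[j]
        elif r < 0.9:
            out_alleles[(gm.chrom[j], int(gm.pos[j]))] = gm.alt[j]
        elif r < 0.95:
            out_alleles[(gm.chrom[j], int(gm.pos[j]))] = "N"  # mismatch -> excluded
        # else: uncovered
    ann = polarize(gm, out_alleles)
    scores = {
        (gm.chrom[j], int(gm.pos[j])): float(rng.normal(0.5, score_scale))
        for j in range(gm.n_sites)
    }
    return attach_scores(ann, gm, scores)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def desk_ds():
    """One desk-scale end-to-end dataset for integration-style tests."""
    return simulate(desk_scenario(), seed=1000)


@pytest.fixture(scope="session")
def desk_battery():
    """Ten desk-scenario datasets (fixed seeds) shared by the qualitative
    demography-load contrast suites."""
    return [simulate(desk_scenario(), seed=1000 + s) for s in range(10)]


@pytest.fixture(scope="session")
def intro_pulse_battery():
    """Ten introgression datasets per pulse fraction (fixed seeds)."""
    out = {}
    for f in (0.05, 0.1, 0.2):
        out[f] = [simulate(introgression_scenario(f), seed=40 + s) for s in range(10)]
    return out


@pytest.fixture(scope="session")
def intro_null_battery():
    """Fifty no-gene-flow replicates of the introgression scenario."""
    return [simulate(introgression_scenario(None), seed=40 + s) for s in range(50)]
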