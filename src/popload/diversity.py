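"""Windowed and per-individual diversity statistics.

All frequency computations use pairwise deletion: frequencies are taken over
the non-missing chromosomes at each site. The sample size entering the
harmonic-sum and neutrality-test constants is the median non-missing
chromosome count in the window.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from popload.io_core import GenotypeMatrix, SamplePanel, SiteAnnotation, Window

EARTH_RADIUS_KM = 6371.0


@dataclass
class DiversityWindow:
    window: Window
    theta_w: float
    theta_pi: float
    tajimas_d: float


def _window_site_data(
    gm: GenotypeMatrix, window: Window, sample_idx: np.ndarray | None = None
):
    """Per-site (alt count, called chromosomes) for sites in the window."""
    mask = gm.site_mask(window.chrom, window.start, window.end)
    d = gm.dosage[:, mask] if sample_idx is None else gm.dosage[np.ix_(sample_idx, np.flatnonzero(mask))]
    called = d >= 0
    n_chrom = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    keep = n_chrom >= 2
    return alt[keep], n_chrom[keep]


def harmonic_number(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i^power (Watterson / Tajima constants)."""
    return float(sum(1.0 / i**power for i in range(1, n)))


def watterson_theta(
    gm: GenotypeMatrix,
    window: Window,
    per_bp: bool = False,
    sample_idx: np.ndarray | None = None,
) -> float:
    """Watterson's theta: S / a_n over the window (NaN if no usable sites)."""
    alt, n_chrom = _window_site_data(gm, window, sample_idx)
    if len(alt) == 0:
        return float("nan")
    seg = (alt > 0) & (alt < n_chrom)
    s = int(seg.sum())
    n = int(np.rint(np.median(n_chrom)))
    if n < 2:
        return float("nan")
    theta = s / harmonic_number(n)
    return theta / window.length if per_bp else theta


def nucleotide_diversity(
    gm: GenotypeMatrix,
    window: Window,
    per_bp: bool = False,
    sample_idx: np.ndarray | None = None,
) -> float:
    """Pairwise diversity: sum over sites of 2p(1-p) * n/(n-1)."""
    alt, n_chrom = _window_site_data(gm, window, sample_idx)
    if len(alt) == 0:
        return float("nan")
    p = alt / n_chrom
    pi = float(np.sum(2.0 * p * (1.0 - p) * n_chrom / (n_chrom - 1.0)))
    return pi / window.length if per_bp else pi


def tajimas_d(
    gm: GenotypeMatrix, window: Window, sample_idx: np.ndarray | None = None
) -> float:
    """Tajima's D with the standard 1989 constants; NaN when S = 0 or n < 4."""
    alt, n_chrom = _window_site_data(gm, window, sample_idx)
    if len(alt) == 0:
        return float("nan")
    seg = (alt > 0) & (alt < n_chrom)
    s = int(seg.sum())
    n = int(np.rint(np.median(n_chrom)))
    if s == 0 or n < 4:
        return float("nan")
    a1 = harmonic_number(n)
    a2 = harmonic_number(n, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    p = alt / n_chrom
    theta_pi = float(np.sum(2.0 * p * (1.0 - p) * n_chrom / (n_chrom - 1.0)))
    theta_w = s / a1
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return float("nan")
    return (theta_pi - theta_w) / math.sqrt(var)


def windowed_diversity(
    gm: GenotypeMatrix,
    windows: list[Window],
    per_bp: bool = True,
    sample_idx: np.ndarray | None = None,
) -> list[DiversityWindow]:
    out = []
    for w in windows:
        out.append(
            DiversityWindow(
                window=w,
                theta_w=watterson_theta(gm, w, per_bp=per_bp, sample_idx=sample_idx),
                theta_pi=nucleotide_diversity(gm, w, per_bp=per_bp, sample_idx=sample_idx),
                tajimas_d=tajimas_d(gm, w, sample_idx=sample_idx),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Per-individual statistics
# ---------------------------------------------------------------------------


def individual_heterozygosity(gm: GenotypeMatrix, sample: str) -> float:
    """Fraction of non-missing genotyped sites that are heterozygous."""
    row = gm.dosage[gm.sample_index(sample)]
    called = row >= 0
    n = int(called.sum())
    if n == 0:
        return float("nan")
    return float((row == 1).sum() / n)


def derived_hom_fraction(gm: GenotypeMatrix, ann: SiteAnnotation, sample: str) -> float:
    """Fraction of polarized non-missing sites homozygous for the derived allele."""
    dd = ann.derived_dosage(gm)[gm.sample_index(sample)]
    called = dd >= 0
    n = int(called.sum())
    if n == 0:
        return float("nan")
    return float((dd == 2).sum() / n)


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points, R = 6371 km."""
    lat1, lon1 = map(math.radians, a)
    lat2, lon2 = map(math.radians, b)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class DistanceDecayFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def distance_decay_regression(
    panel: SamplePanel,
    het: dict[str, float],
    origin: tuple[float, float],
) -> DistanceDecayFit:
    """OLS of a per-sample statistic on great-circle distance from an origin."""
    samples = [s for s in panel.samples if s in het and s in panel.coordinates]
    if len(samples) < 3:
        raise ValueError("need at least 3 samples with coordinates and values")
    x = np.array([haversine_km(panel.coordinates[s], origin) for s in samples])
    y = np.array([het[s] for s in samples])
    if np.ptp(x) == 0:
        raise ValueError("all distances equal; slope undefined")
    res = sp_stats.linregress(x, y)
    return DistanceDecayFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(samples),
    )


# ---------------------------------------------------------------------------
# Site frequency spectrum
# ---------------------------------------------------------------------------


@dataclass
class SFS:
    population: str
    counts: np.ndarray  # float, index = derived-allele count 0..n

    @property
    def n_chromosomes(self) -> int:
        return len(self.counts) - 1

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def project_sfs_site(d: int, n: int, n_proj: int) -> np.ndarray:
    """Hypergeometric down-projection of one site (d derived of n) to n_proj."""
    j = np.arange(n_proj + 1)
    return sp_stats.hypergeom.pmf(j, n, d, n_proj)


def sfs(
    gm: GenotypeMatrix,
    ann: SiteAnnotation,
    population: str,
    n_project: int | None = None,
) -> SFS:
    """Direct genotype-count SFS of polarized sites for one population.

    Sites with missing genotypes are projected down to the smallest complete
    chromosome count (or ``n_project``) via the hypergeometric expectation, so
    the spectrum conserves the number of sites used.
    """
    idx = gm.sample_indices(population)
    dd = ann.derived_dosage(gm)[idx]
    called = dd >= 0
    n_chrom = 2 * called.sum(axis=0)
    der = np.where(called, dd, 0).sum(axis=0)
    use = (~ann.excluded) & (n_chrom >= 2)
    if not use.any():
        return SFS(population, np.zeros(1))
    n_proj = n_project if n_project is not None else int(n_chrom[use].min())
    counts = np.zeros(n_proj + 1)
    for d, n in zip(der[use], n_chrom[use]):
        if n == n_proj:
            counts[int(d)] += 1.0
        else:
            counts += project_sfs_site(int(d), int(n), n_proj)
    return SFS(population, counts)


# ---------------------------------------------------------------------------
# Exact rank-sum test
# ---------------------------------------------------------------------------


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sp_stats.rankdata(pooled, method="average")


def exact_rank_sum(
    x,
    y,
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> float:
    """Wilcoxon rank-sum p-value, exact by enumeration for small samples.

    Exact branch enumerates all C(n_x+n_y, n_x) assignments of the pooled
    midranks when n_x + n_y <= ``exact_max_n``; otherwise uses the normal
    approximation with tie correction. ``alternative`` is 'less' (x tends
    smaller), 'greater', or 'two-sided'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"bad alternative {alternative!r}")
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = float(ranks[:nx].sum())

    if nx + ny <= exact_max_n:
        stats = [
            sum(ranks[i] for i in combo)
            for combo in itertools.combinations(range(nx + ny), nx)
        ]
        stats = np.asarray(stats)
        total = len(stats)
        eps = 1e-9
        p_less = float((stats <= w_obs + eps).sum() / total)
        p_greater = float((stats >= w_obs - eps).sum() / total)
        if alternative == "less":
            return p_less
        if alternative == "greater":
            return p_greater
        return min(1.0, 2.0 * min(p_less, p_greater))

    # normal approximation with midranks and tie correction
    n = nx + ny
    mean_w = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return 1.0
    z_less = (w_obs - mean_w + 0.5) / math.sqrt(var_w)
    z_greater = (w_obs - mean_w - 0.5) / math.sqrt(var_w)
    p_less = float(sp_stats.norm.cdf(z_less))
    p_greater = float(sp_stats.norm.sf(z_greater))
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))
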