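"""Conservation-score-weighted deleterious-allele burden models.

Deleterious sites are polarized sites with corrected score > 0. Individual
burdens weight heterozygous genotypes by 0.5 and homozygous-derived by 1
(additive) or count only homozygous-derived (recessive). Severity classes
partition the score range into nearly-neutral (-2, 0], slightly (0, 2],
moderately (2, 4], strongly (> 4); scores <= -2 never contribute.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from popload.diversity import nucleotide_diversity
from popload.io_core import GenotypeMatrix, SiteAnnotation, Window

SEVERITY_BOUNDS = {
    "nearly_neutral": (-2.0, 0.0),
    "slightly": (0.0, 2.0),
    "moderately": (2.0, 4.0),
    "strongly": (4.0, float("inf")),
}


def severity_class(gerp: float) -> str | None:
    """Severity partition for a score; None when excluded (<= -2) or NaN."""
    if np.isnan(gerp) or gerp <= -2.0:
        return None
    for name, (lo, hi) in SEVERITY_BOUNDS.items():
        if lo < gerp <= hi:
            return name
    return "strongly"  # gerp > 4


def severity_mask(scores: np.ndarray, partition: str) -> np.ndarray:
    if partition not in SEVERITY_BOUNDS:
        raise ValueError(f"unknown severity partition {partition!r}")
    lo, hi = SEVERITY_BOUNDS[partition]
    with np.errstate(invalid="ignore"):
        return (scores > lo) & (scores <= hi)


# ---------------------------------------------------------------------------
# Reference-bias correction
# ---------------------------------------------------------------------------


def correct_gerp(
    ann: SiteAnnotation,
    gm: GenotypeMatrix,
    panel_freqs: dict[tuple[str, int], float] | pd.DataFrame,
) -> SiteAnnotation:
    """Reference-bias correction of conservation scores.

    Sites where the reference allele is ancestral keep their raw score and
    define, per 1% derived-frequency bin of a large reference panel, an
    empirical score distribution. Each reference-derived site receives the
    mean score of its bin (nearest non-empty bin if its own is empty).
    """
    if isinstance(panel_freqs, pd.DataFrame):
        panel_freqs = {
            (c, int(p)): float(f)
            for c, p, f in zip(panel_freqs["chrom"], panel_freqs["pos"], panel_freqs["freq"])
        }
    n = ann.n_sites
    freqs = np.full(n, np.nan)
    for j in range(n):
        v = panel_freqs.get((gm.chrom[j], int(gm.pos[j])))
        if v is not None:
            freqs[j] = v
    scored = ~np.isnan(ann.gerp_raw) & ~ann.excluded
    if scored.any() and np.isnan(freqs[scored]).any():
        raise ValueError("every scored site needs a panel derived frequency")
    bins = np.minimum((freqs * 100).astype(int, copy=False), 99)

    ref_ancestral = ann.derived_is_alt  # derived == alt means ref is ancestral
    bin_scores: dict[int, list[float]] = {}
    for j in np.flatnonzero(scored & ref_ancestral):
        bin_scores.setdefault(int(bins[j]), []).append(float(ann.gerp_raw[j]))
    bin_means = {k: float(np.mean(v)) for k, v in bin_scores.items()}
    if not bin_means:
        raise ValueError("no reference-ancestral sites to build bin distributions")
    filled_bins = np.array(sorted(bin_means))

    corrected = ann.gerp_raw.copy()
    for j in np.flatnonzero(scored & ~ref_ancestral):
        b = int(bins[j])
        if b not in bin_means:
            b = int(filled_bins[np.argmin(np.abs(filled_bins - b))])
        corrected[j] = bin_means[b]
    return dataclasses.replace(ann, gerp_corrected=corrected)


# ---------------------------------------------------------------------------
# Burdens
# ---------------------------------------------------------------------------


@dataclass
class BurdenReport:
    sample: str
    model: str  # additive | recessive
    partition: str | None
    burden: float
    n_sites: int  # contributing (non-missing deleterious) sites
    n_skipped: int  # unpolarized/missing sites encountered


def _deleterious_mask(ann: SiteAnnotation, partition: str | None) -> np.ndarray:
    scores = ann.gerp_corrected
    with np.errstate(invalid="ignore"):
        base = ~ann.excluded & ~np.isnan(scores)
    if partition is None:
        return base & (scores > 0)
    return base & severity_mask(scores, partition)


def individual_burden(
    gm: GenotypeMatrix,
    ann: SiteAnnotation,
    sample: str,
    model: str = "additive",
    partition: str | None = None,
) -> BurdenReport:
    """Score-weighted genotype burden for one individual."""
    if model not in ("additive", "recessive"):
        raise ValueError(f"unknown model {model!r}")
    sel = _deleterious_mask(ann, partition)
    dd = ann.derived_dosage(gm)[gm.sample_index(sample)]
    callable_ = sel & (dd >= 0)
    g = ann.gerp_corrected[callable_]
    d = dd[callable_]
    if model == "additive":
        burden = float(np.sum(g * (0.5 * (d == 1) + 1.0 * (d == 2))))
    else:
        burden = float(np.sum(g * (d == 2)))
    return BurdenReport(
        sample=sample,
        model=model,
        partition=partition,
        burden=burden,
        n_sites=int(callable_.sum()),
        n_skipped=int((sel & (dd < 0)).sum()),
    )


def population_load(
    gm: GenotypeMatrix,
    ann: SiteAnnotation,
    population: str,
    model: str = "additive",
    partition: str | None = None,
    windows: list[Window] | None = None,
) -> float | list[float]:
    """Population-level score x frequency load.

    Additive sums score * derived frequency; recessive sums score * frequency
    of homozygous-derived genotypes. With ``windows`` given, returns the load
    of each window instead of the genome-wide sum.
    """
    if model not in ("additive", "recessive"):
        raise ValueError(f"unknown model {model!r}")
    sel = _deleterious_mask(ann, partition)
    idx = gm.sample_indices(population)
    dd = ann.derived_dosage(gm)[idx]
    called = dd >= 0
    n_chrom = 2 * called.sum(axis=0)
    n_ind = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if model == "additive":
            freq = np.where(n_chrom > 0, np.where(called, dd, 0).sum(axis=0) / np.maximum(n_chrom, 1), 0.0)
        else:
            freq = np.where(n_ind > 0, np.where(called, dd == 2, False).sum(axis=0) / np.maximum(n_ind, 1), 0.0)
    contrib = np.where(sel, ann.gerp_corrected * freq, 0.0)
    contrib = np.nan_to_num(contrib)
    if windows is None:
        return float(contrib.sum())
    return [float(contrib[gm.site_mask(w.chrom, w.start, w.end)].sum()) for w in windows]


# ---------------------------------------------------------------------------
# Fixed vs segregating accounting
# ---------------------------------------------------------------------------


@dataclass
class FixedSegCounts:
    population: str
    n_sub: int
    replicate: int
    fixed: int
    segregating: int


def fixed_segregating(
    gm: GenotypeMatrix,
    ann: SiteAnnotation,
    population: str,
    n_sub: int,
    partition: str | None = None,
    max_replicates: int = 200,
    seed: int = 0,
) -> list[FixedSegCounts]:
    """Fixed vs segregating deleterious-site counts in subsamples of n_sub.

    All combinations are enumerated when there are at most ``max_replicates``
    of them; otherwise ``max_replicates`` seeded random draws are used.
    """
    sel = _deleterious_mask(ann, partition)
    idx = gm.sample_indices(population)
    if n_sub > len(idx):
        raise ValueError("subsample larger than population")
    dd_all = ann.derived_dosage(gm)[idx][:, sel]

    from math import comb

    n_comb = comb(len(idx), n_sub)
    if n_comb <= max_replicates:
        combos = list(itertools.combinations(range(len(idx)), n_sub))
    else:
        rng = np.random.default_rng(seed)
        combos = [
            tuple(rng.choice(len(idx), size=n_sub, replace=False))
            for _ in range(max_replicates)
        ]
    out = []
    for r, combo in enumerate(combos):
        dd = dd_all[list(combo)]
        called = dd >= 0
        n_chrom = 2 * called.sum(axis=0)
        der = np.where(called, dd, 0).sum(axis=0)
        has_data = n_chrom > 0
        fixed = int(np.sum(has_data & (der == n_chrom)))
        seg = int(np.sum(has_data & (der > 0) & (der < n_chrom)))
        out.append(FixedSegCounts(population, n_sub, r, fixed, seg))
    return out


def mean_fixed_segregating(counts: list[FixedSegCounts]) -> tuple[float, float]:
    return (
        float(np.mean([c.fixed for c in counts])),
        float(np.mean([c.segregating for c in counts])),
    )


# ---------------------------------------------------------------------------
# Gene-set burdens and nulls
# ---------------------------------------------------------------------------


def merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union of half-open intervals, merged per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        if e > s:
            by_chrom.setdefault(c, []).append((s, e))
    out = []
    for c in sorted(by_chrom):
        merged: list[list[int]] = []
        for s, e in sorted(by_chrom[c]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.extend((c, s, e) for s, e in merged)
    return out


def geneset_burden(
    gm: GenotypeMatrix,
    ann: SiteAnnotation,
    genes: list[tuple[str, int, int]],
    flank_bp: int = 5000,
    weighted: bool = False,
    population: str | None = None,
) -> float:
    """Deleterious sites (or summed scores) per bp over the union of
    gene +/- flank intervals. A site counts when its derived allele is present
    in the (optionally population-restricted) matrix."""
    merged = merge_intervals([(c, max(0, s - flank_bp), e + flank_bp) for c, s, e in genes])
    total_bp = sum(e - s for _, s, e in merged)
    if total_bp == 0:
        return float("nan")
    sel = _deleterious_mask(ann, None)
    idx = gm.sample_indices(population) if population else np.arange(gm.n_samples)
    dd = ann.derived_dosage(gm)[idx]
    present = np.where(dd >= 0, dd, 0).sum(axis=0) > 0
    in_union = np.zeros(gm.n_sites, dtype=bool)
    for c, s, e in merged:
        in_union |= gm.site_mask(c, s, e)
    use = sel & present & in_union
    if weighted:
        return float(np.nan_to_num(ann.gerp_corrected[use]).sum() / total_bp)
    return float(use.sum() / total_bp)


def null_distribution(
    gm: GenotypeMatrix,
    ann: SiteAnnotation,
    all_genes: list[tuple[str, int, int]],
    n_genes: int,
    n_reps: int,
    seed: int,
    flank_bp: int = 5000,
    weighted: bool = False,
    population: str | None = None,
) -> np.ndarray:
    """Burden statistic on ``n_reps`` random same-size gene sets."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for r in range(n_reps):
        pick = rng.choice(len(all_genes), size=n_genes, replace=False)
        out[r] = geneset_burden(
            gm,
            ann,
            [all_genes[i] for i in pick],
            flank_bp=flank_bp,
            weighted=weighted,
            population=population,
        )
    return out


def empirical_p(observed: float, null: np.ndarray, sided: str = "two") -> float:
    """Resampling p-value with the (r+1)/(n+1) correction."""
    null = np.asarray(null, dtype=float)
    n = len(null)
    p_low = (np.sum(null <= observed) + 1) / (n + 1)
    p_high = (np.sum(null >= observed) + 1) / (n + 1)
    if sided == "less":
        return float(p_low)
    if sided == "greater":
        return float(p_high)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def pi_ratio_test(
    gm_a: GenotypeMatrix,
    gm_b: GenotypeMatrix,
    genes: list[tuple[str, int, int]],
    all_genes: list[tuple[str, int, int]],
    n_reps: int,
    seed: int,
) -> tuple[float, float]:
    """Ratio of pairwise diversity (a / b) over a gene set vs random sets.

    Returns (observed ratio, lower-tail empirical p): small p means the gene
    set is unusually depleted of diversity in ``a`` relative to ``b``.
    """

    def ratio(gene_set):
        merged = merge_intervals(gene_set)
        pi_a = pi_b = 0.0
        for c, s, e in merged:
            w = Window(c, s, e)
            va = nucleotide_diversity(gm_a, w)
            vb = nucleotide_diversity(gm_b, w)
            pi_a += 0.0 if np.isnan(va) else va
            pi_b += 0.0 if np.isnan(vb) else vb
        return pi_a / pi_b if pi_b > 0 else float("nan")

    observed = ratio(genes)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_reps):
        pick = rng.choice(len(all_genes), size=len(genes), replace=False)
        null.append(ratio([all_genes[i] for i in pick]))
    null = np.asarray(null)
    null = null[~np.isnan(null)]
    return observed, empirical_p(observed, null, sided="less")


# ---------------------------------------------------------------------------
# Load vs introgression regression
# ---------------------------------------------------------------------------


@dataclass
class LoadRegression:
    fd_coef: float
    fd_p: float
    density_coef: float
    density_p: float
    intercept: float
    n_windows: int
    r_squared: float


def load_vs_introgression(table: pd.DataFrame) -> LoadRegression:
    """OLS of per-window deleterious count on f_d and gene density.

    ``table`` needs columns fd, count, gene_density; windows with undefined
    (NaN) f_d are dropped before fitting.
    """
    df = table.dropna(subset=["fd", "count", "gene_density"])
    if len(df) < 3:
        raise ValueError("need at least 3 windows with defined f_d")
    X = sm.add_constant(df[["fd", "gene_density"]].to_numpy())
    fit = sm.OLS(df["count"].to_numpy(), X).fit()
    return LoadRegression(
        fd_coef=float(fit.params[1]),
        fd_p=float(fit.pvalues[1]),
        density_coef=float(fit.params[2]),
        density_p=float(fit.pvalues[2]),
        intercept=float(fit.params[0]),
        n_windows=len(df),
        r_squared=float(fit.rsquared),
    )


def window_deleterious_counts(
    gm: GenotypeMatrix,
    ann: SiteAnnotation,
    windows: list[Window],
    population: str | None = None,
    mode: str = "sites",
) -> np.ndarray:
    """Per-window deleterious count.

    ``mode='sites'`` counts deleterious sites whose derived allele is present
    in the population; ``mode='alleles'`` sums the derived-allele dosage over
    individuals (the additive-model count); ``mode='hom'`` counts
    homozygous-derived genotypes (the recessive-model count, sensitive to
    drift load that introgressed haplotypes replace).
    """
    if mode not in ("sites", "alleles", "hom"):
        raise ValueError(f"unknown mode {mode!r}")
    sel = _deleterious_mask(ann, None)
    idx = gm.sample_indices(population) if population else np.arange(gm.n_samples)
    dd = ann.derived_dosage(gm)[idx]
    total = np.where(dd >= 0, dd, 0).sum(axis=0)
    if mode == "sites":
        per_site = np.where(sel, total > 0, 0)
    elif mode == "alleles":
        per_site = np.where(sel, total, 0)
    else:
        per_site = np.where(sel, (dd == 2).sum(axis=0), 0)
    return np.array(
        [per_site[gm.site_mask(w.chrom, w.start, w.end)].sum() for w in windows]
    )


def gene_density(
    windows: list[Window],
    exons: list[tuple[str, int, int]],
    gmap,
) -> np.ndarray:
    """Exonic bp per cM for each window (NaN for zero-cM windows)."""
    merged = merge_intervals(exons)
    out = np.empty(len(windows))
    for i, w in enumerate(windows):
        bp = 0
        for c, s, e in merged:
            if c == w.chrom:
                bp += max(0, min(e, w.end) - max(s, w.start))
        cm = float(gmap.cm_at(w.chrom, w.end) - gmap.cm_at(w.chrom, w.start))
        out[i] = bp / cm if cm > 0 else float("nan")
    return out
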