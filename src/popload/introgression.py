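"""ABBA-BABA (Patterson's D) with block jackknife, and windowed f_d scans.

Derived-allele frequencies come from polarized genotypes with pairwise
deletion; a single-sample "population" contributes its dosage/2, which makes
per-individual D deterministic. When polarization already used the outgroup,
the outgroup derived frequency is fixed at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from popload.io_core import GenotypeMatrix, SiteAnnotation, Window


@dataclass
class DStatResult:
    d: float
    se: float
    z: float
    n_blocks: int
    abba_total: float
    baba_total: float
    degenerate: bool = False  # SE == 0


@dataclass
class FdWindow:
    window: Window
    fd: float  # NaN when undefined
    s_num: float
    s_den: float
    d_window: float


def site_patterns(p1, p2, p3, po=0.0):
    """Frequency-form ABBA and BABA weights for one site (or arrays)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    po = np.asarray(po, dtype=float)
    abba = (1.0 - p1) * p2 * p3 * (1.0 - po)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - po)
    return abba, baba


def _derived_freqs(gm: GenotypeMatrix, ann: SiteAnnotation, pop: str) -> np.ndarray:
    dd = ann.derived_dosage(gm)[gm.sample_indices(pop)]
    called = dd >= 0
    n = called.sum(axis=0) * 2
    der = np.where(called, dd, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, der / np.maximum(n, 1), np.nan)


def _pattern_arrays(gm, ann, p1_pop, p2_pop, p3_pop, outgroup):
    f1 = _derived_freqs(gm, ann, p1_pop)
    f2 = _derived_freqs(gm, ann, p2_pop)
    f3 = _derived_freqs(gm, ann, p3_pop)
    fo = _derived_freqs(gm, ann, outgroup) if outgroup else np.zeros(gm.n_sites)
    ok = ~(ann.excluded | np.isnan(f1) | np.isnan(f2) | np.isnan(f3) | np.isnan(fo))
    return f1, f2, f3, fo, ok


def patterson_d(
    gm: GenotypeMatrix,
    ann: SiteAnnotation,
    p1_pop: str,
    p2_pop: str,
    p3_pop: str,
    outgroup: str | None = None,
    block_bp: int = 1000,
) -> DStatResult:
    """Patterson's D over all informative sites with delete-one-block jackknife.

    Blocks are fixed-bp tiles; a block enters the jackknife when it holds at
    least one informative site (abba + baba > 0 there).
    """
    f1, f2, f3, fo, ok = _pattern_arrays(gm, ann, p1_pop, p2_pop, p3_pop, outgroup)
    abba, baba = site_patterns(f1[ok], f2[ok], f3[ok], fo[ok])
    informative = (abba + baba) > 0
    if not informative.any():
        raise ValueError("no informative sites for D statistic")
    abba, baba = abba[informative], baba[informative]
    chrom = gm.chrom[ok][informative]
    block_id = gm.pos[ok][informative] // block_bp
    keys = np.array([f"{c}:{b}" for c, b in zip(chrom, block_id)])
    uniq, inv = np.unique(keys, return_inverse=True)
    m = len(uniq)
    a_blk = np.bincount(inv, weights=abba, minlength=m)
    b_blk = np.bincount(inv, weights=baba, minlength=m)
    a_tot, b_tot = float(abba.sum()), float(baba.sum())
    d = (a_tot - b_tot) / (a_tot + b_tot)
    if m < 2:
        raise ValueError("single jackknife block; SE undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        d_loo = (a_tot - a_blk - (b_tot - b_blk)) / (a_tot - a_blk + b_tot - b_blk)
    se = float(np.sqrt((m - 1) / m * np.sum((d_loo - d_loo.mean()) ** 2)))
    degenerate = se == 0.0
    z = d / se if se > 0 else float("inf") if d != 0 else 0.0
    return DStatResult(
        d=float(d),
        se=se,
        z=float(z),
        n_blocks=m,
        abba_total=a_tot,
        baba_total=b_tot,
        degenerate=degenerate,
    )


def fd_window(
    gm: GenotypeMatrix,
    ann: SiteAnnotation,
    window: Window,
    p1_pop: str,
    p2_pop: str,
    p3_pop: str,
    outgroup: str | None = None,
) -> FdWindow:
    """f_d for one window: D numerator normalized by its value with the donor
    frequency (the larger of p2, p3) substituted for both P2 and P3.

    Undefined (NaN) when the window D is not positive or the denominator is
    not positive; such windows are excluded downstream.
    """
    f1, f2, f3, fo, ok = _pattern_arrays(gm, ann, p1_pop, p2_pop, p3_pop, outgroup)
    in_win = gm.site_mask(window.chrom, window.start, window.end) & ok
    if not in_win.any():
        return FdWindow(window, float("nan"), 0.0, 0.0, float("nan"))
    p1, p2, p3, po = f1[in_win], f2[in_win], f3[in_win], fo[in_win]
    abba, baba = site_patterns(p1, p2, p3, po)
    s_num = float(np.sum(abba - baba))
    pd_freq = np.maximum(p2, p3)
    abba_d, baba_d = site_patterns(p1, pd_freq, pd_freq, po)
    s_den = float(np.sum(abba_d - baba_d))
    tot = float(np.sum(abba + baba))
    d_window = s_num / tot if tot > 0 else float("nan")
    if d_window > 0 and s_den > 0:
        fd = s_num / s_den
        # the statistic lives in [0,1]; a ratio above 1 means the donor
        # substitution denominator is noise-dominated -> undefined
        if fd > 1.0:
            fd = float("nan")
    else:
        fd = float("nan")
    return FdWindow(window, fd, s_num, s_den, d_window)


def fd_scan(
    gm: GenotypeMatrix,
    ann: SiteAnnotation,
    windows: list[Window],
    p1_pop: str,
    p2_pop: str,
    p3_pop: str,
    outgroup: str | None = None,
) -> list[FdWindow]:
    return [
        fd_window(gm, ann, w, p1_pop, p2_pop, p3_pop, outgroup) for w in windows
    ]


def fd_threshold(reference_fd, q: float = 0.95) -> float:
    """Empirical quantile (linear interpolation) of defined f_d values."""
    vals = np.asarray(reference_fd, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no defined f_d values in reference")
    return float(np.quantile(vals, q))


def fd_outliers(scan: list[FdWindow], cutoff: float) -> list[FdWindow]:
    return [w for w in scan if not np.isnan(w.fd) and w.fd > cutoff]


def write_fd_table(path, scan: list[FdWindow]) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (w.window.chrom, w.window.start, w.window.end, w.fd, w.s_num, w.s_den, w.d_window)
            for w in scan
        ],
        columns=["chrom", "start", "end", "fd", "s_num", "s_den", "d_window"],
    ).to_csv(path, sep="\t", index=False)
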