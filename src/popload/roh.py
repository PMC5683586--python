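"""Run-of-homozygosity detection, genetic-length conversion, and dating.

Detection follows a simplified PLINK-style scheme: after thinning to at most
one SNP per fixed-size bin, a 20-SNP window slides one SNP at a time; a
window passes when it contains at most ``max_het`` heterozygous and
``max_missing`` missing calls, a SNP is in ROH state when at least
``hit_fraction`` of the windows overlapping it pass, and maximal runs of
in-state SNPs spanning at least ``min_length_bp`` become segments. No
density or max-gap filters are applied unless explicitly enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from popload.io_core import GeneticMap, GenotypeMatrix


@dataclass
class ROHParams:
    window_snps: int = 20
    max_missing: int = 2
    max_het: int = 1
    min_length_bp: int = 300_000
    hit_fraction: float = 0.05
    max_gap_bp: int | None = None  # off by default
    min_density_bp_per_snp: int | None = None  # off by default


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int  # 0-based, first SNP position
    end: int  # exclusive, last SNP position + 1
    n_snps: int
    length_cM: float = field(default=float("nan"))

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def thin_sites(gm: GenotypeMatrix, bin_bp: int = 2000) -> GenotypeMatrix:
    """Keep the first site in each tiled ``bin_bp`` bin per chromosome."""
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    keep = np.zeros(gm.n_sites, dtype=bool)
    last: dict[str, int] = {}
    for j in range(gm.n_sites):
        b = int(gm.pos[j]) // bin_bp
        c = gm.chrom[j]
        if last.get(c) != b:
            keep[j] = True
            last[c] = b
    return gm.take_sites(keep)


def detect_roh(
    gm_thinned: GenotypeMatrix, sample: str, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Call ROH segments for one sample on a thinned matrix."""
    params = params or ROHParams()
    w = params.window_snps
    row = gm_thinned.dosage[gm_thinned.sample_index(sample)]
    segments: list[ROHSegment] = []
    for chrom in dict.fromkeys(gm_thinned.chrom):  # preserves order
        on = gm_thinned.chrom == chrom
        pos = gm_thinned.pos[on]
        geno = row[on]
        s = len(pos)
        if s < w:
            continue
        het = (geno == 1).astype(np.int32)
        miss = (geno < 0).astype(np.int32)
        # window i covers SNPs [i, i+w); passes on het/missing thresholds
        k = np.ones(w, dtype=np.int32)
        het_in_win = np.convolve(het, k, mode="valid")
        miss_in_win = np.convolve(miss, k, mode="valid")
        passes = (het_in_win <= params.max_het) & (miss_in_win <= params.max_missing)
        # SNP j is covered by windows max(0, j-w+1) .. min(j, s-w)
        n_win = s - w + 1
        cum = np.concatenate([[0], np.cumsum(passes)])
        j = np.arange(s)
        lo = np.maximum(0, j - w + 1)
        hi = np.minimum(j, n_win - 1)
        n_pass = cum[hi + 1] - cum[lo]
        n_cover = hi - lo + 1
        in_state = n_pass / n_cover >= params.hit_fraction
        segments.extend(
            _segments_from_state(sample, chrom, pos, in_state, params)
        )
    return segments


def _segments_from_state(sample, chrom, pos, in_state, params: ROHParams):
    out = []
    s = len(pos)
    i = 0
    while i < s:
        if not in_state[i]:
            i += 1
            continue
        j = i
        while j + 1 < s and in_state[j + 1]:
            if params.max_gap_bp is not None and pos[j + 1] - pos[j] > params.max_gap_bp:
                break
            j += 1
        start, end = int(pos[i]), int(pos[j]) + 1
        n_snps = j - i + 1
        ok = (end - start) >= params.min_length_bp
        if ok and params.min_density_bp_per_snp is not None:
            ok = (end - start) / n_snps <= params.min_density_bp_per_snp
        if ok:
            out.append(ROHSegment(sample, chrom, start, end, n_snps))
        i = j + 1
    return out


def segment_cM(seg: ROHSegment, gmap: GeneticMap) -> float:
    """Genetic length of a segment: cM at end minus cM at start."""
    return float(gmap.cm_at(seg.chrom, seg.end) - gmap.cm_at(seg.chrom, seg.start))


def annotate_cM(segments: list[ROHSegment], gmap: GeneticMap) -> list[ROHSegment]:
    for seg in segments:
        seg.length_cM = segment_cM(seg, gmap)
    return segments


def cumulative_roh(
    segments: list[ROHSegment], lo_cM: float = 0.0, hi_cM: float = float("inf")
) -> float:
    """Total genetic length of segments whose length falls in [lo_cM, hi_cM)."""
    return float(sum(s.length_cM for s in segments if lo_cM <= s.length_cM < hi_cM))


def generations_for_length(length_cM: float) -> float:
    """Generation depth of the inbreeding loop implied by a segment length.

    A segment inherited intact from an ancestor g generations back has
    expected genetic length 100/(2g) cM, so g = 100 / (2 L).
    """
    if length_cM <= 0:
        raise ValueError("length must be positive")
    return 100.0 / (2.0 * length_cM)


def simple_inbreeding_F(
    gm: GenotypeMatrix, sample: str, population: str | None = None
) -> float:
    """Moment-based F: 1 - observed het / expected het under the sample's
    population allele frequencies (pairwise deletion)."""
    i = gm.sample_index(sample)
    pop = population or gm.populations[sample]
    idx = gm.sample_indices(pop)
    p = gm.alt_frequency(idx)
    row = gm.dosage[i]
    called = (row >= 0) & ~np.isnan(p)
    exp_het = float(np.sum(2.0 * p[called] * (1.0 - p[called])))
    if exp_het == 0:
        return float("nan")
    obs_het = float((row[called] == 1).sum())
    return 1.0 - obs_het / exp_het


def write_segments(path, segments: list[ROHSegment]) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (s.chrom, s.start, s.end, s.sample, s.n_snps, s.length_cM)
            for s in segments
        ],
        columns=["chrom", "start", "end", "sample", "n_snps", "length_cM"],
    ).to_csv(path, sep="\t", index=False)
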