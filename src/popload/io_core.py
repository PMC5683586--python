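"""Core data structures and readers/writers shared by every pipeline stage.

Coordinates are 0-based half-open internally; VCF positions are converted on
read and write. Missing genotypes are encoded as -1 in the dosage matrix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_DNA = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SamplePanel:
    """Sample -> (population label, latitude, longitude)."""

    populations: dict[str, str]
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, (lat, lon) in self.coordinates.items():
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                raise ValueError(f"sample {s}: coordinates ({lat}, {lon}) out of range")

    @property
    def samples(self) -> list[str]:
        return list(self.populations)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.populations.items() if p == population]

    @classmethod
    def read(cls, path: str | Path) -> "SamplePanel":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
        pops = dict(zip(df["sample"], df["population"]))
        coords = {}
        if "lat" in df.columns and "lon" in df.columns:
            coords = {
                s: (float(lat), float(lon))
                for s, lat, lon in zip(df["sample"], df["lat"], df["lon"])
            }
        return cls(pops, coords)

    def write(self, path: str | Path) -> None:
        rows = []
        for s, p in self.populations.items():
            lat, lon = self.coordinates.get(s, (float("nan"), float("nan")))
            rows.append((s, p, lat, lon))
        pd.DataFrame(rows, columns=["sample", "population", "lat", "lon"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosage matrix (samples x biallelic sites).

    ``pos`` is 0-based. ``dosage`` holds values in {0, 1, 2} with -1 for
    missing genotypes. Sites are strictly sorted by (chrom, pos).
    """

    samples: list[str]
    populations: dict[str, str]
    chrom: np.ndarray  # str per site
    pos: np.ndarray  # int64, 0-based
    ref: np.ndarray  # str per site
    alt: np.ndarray  # str per site
    dosage: np.ndarray  # int8 (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.pos)):
            raise ValueError("dosage shape does not match samples x sites")
        order_ok = True
        for i in range(1, self.n_sites):
            c0, c1 = self.chrom[i - 1], self.chrom[i]
            if c0 == c1 and self.pos[i] <= self.pos[i - 1]:
                order_ok = False
                break
        if not order_ok:
            raise ValueError("sites must be strictly sorted by (chrom, pos)")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2} or -1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def sample_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.populations.get(s) == population]
        if not idx:
            raise KeyError(f"no samples with population label {population!r}")
        return np.asarray(idx, dtype=np.intp)

    def site_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of sites within [start, end) on ``chrom``."""
        return (self.chrom == chrom) & (self.pos >= start) & (self.pos < end)

    def take_sites(self, mask_or_idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask_or_idx) if mask_or_idx.dtype == bool else mask_or_idx
        return GenotypeMatrix(
            samples=self.samples,
            populations=self.populations,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
        )

    def alt_frequency(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-site alt-allele frequency with pairwise deletion (NaN if no calls)."""
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        called = d >= 0
        n_chrom = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)


_SEVERITY_CLASSES = ("nearly_neutral", "slightly", "moderately", "strongly")


@dataclass
class SiteAnnotation:
    """Per-site ancestral/derived polarity and conservation scores.

    ``excluded`` flags sites whose outgroup allele matched neither ref nor
    alt (or was not covered); these are skipped by polarized analyses but
    retained for unpolarized diversity statistics.
    """

    ancestral_source: str
    derived_is_alt: np.ndarray  # bool per site
    excluded: np.ndarray  # bool per site
    gerp_raw: np.ndarray  # float, NaN if no score
    gerp_corrected: np.ndarray  # float, NaN if no score

    def __post_init__(self) -> None:
        n = len(self.derived_is_alt)
        for name in ("excluded", "gerp_raw", "gerp_corrected"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.derived_is_alt)

    @property
    def b73_state(self) -> np.ndarray:
        """State of the reference allele: 'ancestral' when derived==alt."""
        out = np.where(self.derived_is_alt, "ancestral", "derived").astype(object)
        out[self.excluded] = ""
        return out

    def derived_dosage(self, gm: GenotypeMatrix) -> np.ndarray:
        """Derived-allele counts per individual; -1 missing, -1 at excluded sites."""
        if gm.n_sites != self.n_sites:
            raise ValueError("annotation does not match matrix")
        d = gm.dosage.astype(np.int8)
        flip = ~self.derived_is_alt
        out = np.where(d >= 0, np.where(flip[None, :], 2 - d, d), MISSING).astype(np.int8)
        out[:, self.excluded] = MISSING
        return out


@dataclass
class Window:
    """Half-open genomic window [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    n_informative: int = 0
    partial: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneticMap:
    """Piecewise-linear physical <-> genetic map, one anchor list per chromosome.

    Interpolates linearly between anchors; beyond the terminal anchors the
    terminal interval's cM/bp rate is extrapolated.
    """

    def __init__(self, anchors: Mapping[str, Sequence[tuple[float, float]]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in anchors.items():
            arr = sorted(pairs)
            if len(arr) < 2:
                raise ValueError(f"chromosome {chrom}: need at least 2 anchors")
            bp = np.asarray([a[0] for a in arr], dtype=float)
            cm = np.asarray([a[1] for a in arr], dtype=float)
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom}: cM must be non-decreasing")
            self._anchors[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    @classmethod
    def uniform(cls, chrom_lengths: Mapping[str, int], cm_per_mb: float) -> "GeneticMap":
        return cls(
            {c: [(0.0, 0.0), (float(l), l * cm_per_mb / 1e6)] for c, l in chrom_lengths.items()}
        )

    @classmethod
    def read(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        anchors: dict[str, list[tuple[float, float]]] = {}
        for chrom, pos, cm in zip(df["chrom"], df["pos"], df["cM"]):
            anchors.setdefault(chrom, []).append((float(pos), float(cm)))
        return cls(anchors)

    def write(self, path: str | Path) -> None:
        rows = []
        for chrom, (bp, cm) in self._anchors.items():
            rows.extend((chrom, int(p), c) for p, c in zip(bp, cm))
        pd.DataFrame(rows, columns=["chrom", "pos", "cM"]).to_csv(path, sep="\t", index=False)

    def cm_at(self, chrom: str, pos) -> np.ndarray | float:
        """Genetic position (cM) for physical position(s) on ``chrom``."""
        if chrom not in self._anchors:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        bp, cm = self._anchors[chrom]
        p = np.asarray(pos, dtype=float)
        out = np.interp(p, bp, cm)
        # np.interp clamps; extrapolate with the terminal interval's rate
        lo_rate = (cm[1] - cm[0]) / (bp[1] - bp[0]) if bp[1] > bp[0] else 0.0
        hi_rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2]) if bp[-1] > bp[-2] else 0.0
        out = np.where(p < bp[0], cm[0] + (p - bp[0]) * lo_rate, out)
        out = np.where(p > bp[-1], cm[-1] + (p - bp[-1]) * hi_rate, out)
        return float(out) if np.isscalar(pos) else out


@dataclass
class LoadReport:
    """Counts of records dropped while reading a VCF."""

    n_kept: int = 0
    n_multiallelic: int = 0
    n_indel: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_multiallelic + self.n_indel


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(
    vcf_path: str | Path, panel: SamplePanel
) -> tuple[GenotypeMatrix, LoadReport]:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and indel records are dropped and counted in the returned
    :class:`LoadReport`. Dosage is the alt-allele count; ``./.`` becomes -1.
    """
    from cyvcf2 import VCF

    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(vcf_path)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    missing_samples = [s for s in panel.samples if s not in vcf_samples]
    if missing_samples:
        raise KeyError(f"panel samples absent from VCF: {missing_samples}")
    col = [vcf_samples.index(s) for s in panel.samples]

    report = LoadReport()
    chroms, poss, refs, alts, rows = [], [], [], [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1:
            report.n_multiallelic += 1
            continue
        if var.REF not in _DNA or var.ALT[0] not in _DNA:
            report.n_indel += 1
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)  # to 0-based
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(gt_map[var.gt_types[col]])
        report.n_kept += 1
    vcf.close()

    dosage = (
        np.asarray(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(panel.samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        samples=list(panel.samples),
        populations=dict(panel.populations),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        dosage=dosage,
    )
    return gm, report


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(
    gm: GenotypeMatrix,
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 (GT only)."""
    if chrom_lengths is None:
        chrom_lengths = {}
        for c, p in zip(gm.chrom, gm.pos):
            chrom_lengths[c] = max(chrom_lengths.get(c, 0), int(p) + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, l in chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for j in range(gm.n_sites):
            gts = "\t".join(_GT_STR[int(gm.dosage[i, j])] for i in range(gm.n_samples))
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j] + 1}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_site_table(path: str | Path, value_col: str) -> pd.DataFrame:
    """Read a (chrom, pos[1-based], <value>) tab-delimited site table."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if value_col not in df.columns:
        raise ValueError(f"column {value_col!r} not in {path}")
    df["pos"] = df["pos"].astype(np.int64) - 1  # to 0-based
    return df


def _site_value_map(df: pd.DataFrame, value_col: str) -> dict[tuple[str, int], object]:
    return {
        (c, int(p)): v for c, p, v in zip(df["chrom"], df["pos"], df[value_col])
    }


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------


def polarize(
    gm: GenotypeMatrix,
    outgroup_alleles: Mapping[tuple[str, int], str] | pd.DataFrame,
    ancestral_source: str = "outgroup",
) -> SiteAnnotation:
    """Assign ancestral/derived states from an outgroup allele per site.

    The ancestral allele is the outgroup allele when it equals ref or alt;
    sites not covered, or whose outgroup allele matches neither, are flagged
    excluded. Never changes the number of sites.
    """
    if isinstance(outgroup_alleles, pd.DataFrame):
        outgroup_alleles = _site_value_map(outgroup_alleles, "outgroup_allele")
    n = gm.n_sites
    derived_is_alt = np.zeros(n, dtype=bool)
    excluded = np.ones(n, dtype=bool)
    for j in range(n):
        anc = outgroup_alleles.get((gm.chrom[j], int(gm.pos[j])))
        if anc is None:
            continue
        if anc == gm.ref[j]:
            derived_is_alt[j] = True
            excluded[j] = False
        elif anc == gm.alt[j]:
            derived_is_alt[j] = False
            excluded[j] = False
    nan = np.full(n, np.nan)
    return SiteAnnotation(
        ancestral_source=ancestral_source,
        derived_is_alt=derived_is_alt,
        excluded=excluded,
        gerp_raw=nan.copy(),
        gerp_corrected=nan.copy(),
    )


def attach_scores(
    ann: SiteAnnotation,
    gm: GenotypeMatrix,
    scores: Mapping[tuple[str, int], float] | pd.DataFrame,
) -> SiteAnnotation:
    """Return a copy of ``ann`` with raw conservation scores filled in.

    ``gerp_corrected`` is initialised to the raw score; run
    :func:`popload.load.correct_gerp` to apply the reference-bias correction.
    """
    if isinstance(scores, pd.DataFrame):
        scores = _site_value_map(scores, "gerp")
    raw = np.full(gm.n_sites, np.nan)
    for j in range(gm.n_sites):
        v = scores.get((gm.chrom[j], int(gm.pos[j])))
        if v is not None:
            raw[j] = float(v)
    return dataclasses.replace(ann, gerp_raw=raw, gerp_corrected=raw.copy())


# ---------------------------------------------------------------------------
# Window grids
# ---------------------------------------------------------------------------


def make_windows(
    chrom_lengths: Mapping[str, int],
    size_bp: int,
    step_bp: int | None = None,
) -> list[Window]:
    """Tile half-open windows over each chromosome.

    With ``step_bp`` omitted windows are non-overlapping; a final partial
    window is retained and marked ``partial``.
    """
    if size_bp < 1:
        raise ValueError("size_bp must be >= 1")
    step = step_bp if step_bp is not None else size_bp
    if step < 1:
        raise ValueError("step_bp must be >= 1")
    out = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            end = min(start + size_bp, length)
            out.append(Window(chrom, start, end, partial=(end - start) < size_bp))
            start += step
    return out


def count_informative(gm: GenotypeMatrix, windows: Iterable[Window]) -> list[Window]:
    """Fill ``n_informative`` with the count of matrix sites in each window."""
    out = []
    for w in windows:
        n = int(gm.site_mask(w.chrom, w.start, w.end).sum())
        out.append(dataclasses.replace(w, n_informative=n))
    return out


def write_window_table(path: str | Path, windows: Sequence[Window], stats: Mapping[str, Sequence]) -> None:
    """Write windows + named statistic columns as a BED-compatible TSV."""
    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_informative": [w.n_informative for w in windows],
        }
    )
    for name, vals in stats.items():
        df[name] = list(vals)
    df.to_csv(path, sep="\t", index=False)
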