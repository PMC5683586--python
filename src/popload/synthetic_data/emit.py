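"""Write a SyntheticDataset as the plain-text fixture directory the
pipeline consumes: VCF, site tables (1-based positions), genetic map, sample
panel, gene BED, and truth tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from popload.io_core import write_genotypes
from popload.synthetic_data.engine import SyntheticDataset


def emit(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    paths = {}

    paths["vcf"] = out / "genotypes.vcf"
    write_genotypes(ds.gm, paths["vcf"], chrom_lengths=ds.scenario.chrom_lengths)

    gm = ds.gm
    paths["outgroup"] = out / "outgroup.tsv"
    pd.DataFrame(
        {
            "chrom": gm.chrom,
            "pos": gm.pos + 1,
            "outgroup_allele": [ds.outgroup_alleles[(c, int(p))] for c, p in zip(gm.chrom, gm.pos)],
        }
    ).to_csv(paths["outgroup"], sep="\t", index=False)

    paths["scores"] = out / "scores.tsv"
    df = ds.scores.copy()
    df["pos"] = df["pos"] + 1
    df.to_csv(paths["scores"], sep="\t", index=False, float_format="%.6f")

    paths["panel_freqs"] = out / "panel_freqs.tsv"
    pd.DataFrame(
        {
            "chrom": gm.chrom,
            "pos": gm.pos + 1,
            "freq": [ds.panel_freqs[(c, int(p))] for c, p in zip(gm.chrom, gm.pos)],
        }
    ).to_csv(paths["panel_freqs"], sep="\t", index=False, float_format="%.6f")

    paths["map"] = out / "map.tsv"
    ds.gmap.write(paths["map"])

    paths["panel"] = out / "panel.tsv"
    ds.panel.write(paths["panel"])

    paths["genes"] = out / "genes.bed"
    with open(paths["genes"], "w") as fh:
        cand = set(ds.candidate_genes)
        for i, (c, s, e) in enumerate(sorted(ds.genes)):
            flag = "candidate" if (c, s, e) in cand else "background"
            fh.write(f"{c}\t{s}\t{e}\tgene{i}\t{flag}\n")

    paths["truth_sites"] = truth_dir / "sites.tsv"
    df = ds.truth_sites.copy()
    df["pos"] = df["pos"] + 1
    df.to_csv(paths["truth_sites"], sep="\t", index=False, float_format="%.6f")

    paths["tracts"] = truth_dir / "tracts.tsv"
    ds.tracts.to_csv(paths["tracts"], sep="\t", index=False)

    paths["pedigree"] = truth_dir / "pedigree.tsv"
    ds.pedigree.to_csv(paths["pedigree"], sep="\t", index=False)

    paths["scenario"] = out / "scenario.yaml"
    ds.scenario.to_yaml(paths["scenario"])
    return paths


def read_genes_bed(path: str | Path) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """Read a gene BED; returns (all genes, candidate subset)."""
    genes, candidates = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or line.startswith(("#", "track")):
                continue
            g = (parts[0], int(parts[1]), int(parts[2]))
            genes.append(g)
            if len(parts) >= 5 and parts[4] == "candidate":
                candidates.append(g)
    return genes, candidates
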