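# popload

Population-genetic analysis toolkit for studying how demography (bottlenecks,
serial founder expansions) and introgression from a large-`Ne` donor shape the
burden of deleterious alleles — together with a built-in forward Wright-Fisher
simulator that generates every input the pipeline consumes.

## What it does

| module | contents |
| --- | --- |
| `popload.io_core` | VCF read/write (biallelic SNPs, alt-dosage matrix), outgroup polarization, genetic-map interpolation, window grids, sample panels |
| `popload.diversity` | Watterson's θ, θπ, Tajima's D in windows; per-individual heterozygosity and derived-homozygote fraction; haversine distance-decay regression; SFS with hypergeometric projection; exact Wilcoxon rank-sum test |
| `popload.roh` | SNP thinning, PLINK-style run-of-homozygosity detection, cM conversion, cumulative-length bins, and the g = 100/(2L) length→generations dating |
| `popload.introgression` | ABBA-BABA / Patterson's D with delete-one block jackknife, windowed f̂d scans, empirical quantile outlier cutoffs |
| `popload.load` | conservation-score (GERP-like) burden models: reference-bias bin-mean correction, additive/recessive individual burdens, severity partitions, population load, fixed/segregating subsample accounting, gene-set nulls, θπ-ratio candidate tests, load ~ f̂d + gene-density regression |
| `popload.synthetic_data` | forward diploid Wright-Fisher engine with selection + dominance, splits (optionally kin-structured), admixture pulses with tract tracking, sweeps, score emulation, and plain-text emission of VCF / score / map / panel / gene / truth files |
| `popload.pipeline_cli` | `popload` command-line interface and `run_all` orchestration with deterministic seeding |

## Quick start

```python
from popload.synthetic_data import desk_scenario, simulate
from popload.io_core import polarize, make_windows
from popload import introgression as intro

ds = simulate(desk_scenario(), seed=1)
ann = polarize(ds.gm, ds.outgroup_alleles)
d = intro.patterson_d(ds.gm, ann, "step1", "step2", "donor")
print(d.d, d.z)
```

### CLI

```bash
popload simulate --seed 1 --out out/sim              # write a fixture directory
popload diversity --data out/sim --out out/div.tsv
popload roh --data out/sim --out out/roh.tsv
popload dstat --data out/sim --p1 step1 --p2 step2 --p3 donor
popload fd --data out/sim --p1 step1 --p2 step2 --p3 donor --out out/fd.tsv
popload load --data out/sim --model recessive --out out/burden.tsv
popload run-all --seed 1 --out out/run               # everything, one summary.json
```

Scenario files are YAML (`SimScenario.to_yaml` / `--scenario`); every
threshold (window sizes, ROH parameters, f̂d quantile, flanks, replicates) is a
flag with the published defaults.

## Scenarios

* `default_scenario()` — the documented reference parameterization (ancestral
  N=500; bottleneck to 50 for 100 generations; four 20-founder serial founder
  steps; N=1000 donor with a 10% pulse; 10×1 Mb genome).
* `desk_scenario()` — the same event structure scaled for desk-speed testing
  (smaller populations, 4×300 kb genome, denser genetic map).
* `neutral_scenario()`, `introgression_scenario(f)`, `roh_scenario()` —
  single-purpose calibration scenarios used by the test suite.

## Tests and acceptance

```bash
python -m pytest -q tests/                 # full suite (simulation batteries; ~20 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion: the
ROH-dating conversions, exact oracle equivalences (θπ, Patterson's D +
jackknife SE, ROH detection, score correction) against brute-force
re-implementations, neutral θ_W calibration against 4Nμ, pulse-fraction
recovery by f̂d and D/Z, and the qualitative demography-load contrasts.
`scripts/acceptance.py` writes the acceptance-target values as JSON.
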