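"""Forward diploid Wright-Fisher engine.

Individuals are monoecious; each child draws two parents (with replacement)
with probability proportional to multiplicative fitness across selected
sites (1, 1-hs, 1-s by genotype; negative s encodes a beneficial allele).
Mutation is infinite-sites on the bp grid, recombination follows the uniform
map with independent assortment across chromosomes, splits copy (or, when
kin-structured, breed sibships of) founder individuals, and admixture pulses
draw gametes from the donor population. Donor ancestry is tracked by neutral
marker loci on a fixed grid that recombine with the rest of the genome.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from popload.io_core import GeneticMap, GenotypeMatrix, SamplePanel
from popload.synthetic_data.scenario import SimScenario
from popload.synthetic_data.scores import apply_reference_bias, assign_scores

_BASES = np.array(list("ACGT"))

MAX_POP_SIZE = 2000
MAX_LOCI = 200_000


@dataclass
class SyntheticDataset:
    """Simulated genotypes plus every companion table the pipeline reads."""

    scenario: SimScenario
    seed: int
    gm: GenotypeMatrix
    outgroup_alleles: dict[tuple[str, int], str]
    scores: pd.DataFrame  # chrom, pos (0-based), gerp
    panel_freqs: dict[tuple[str, int], float]
    gmap: GeneticMap
    panel: SamplePanel
    genes: list[tuple[str, int, int]]
    candidate_genes: list[tuple[str, int, int]]
    truth_sites: pd.DataFrame  # chrom, pos, s, h, derived_freq per pop
    tracts: pd.DataFrame  # sample, hap, chrom, start, end, donor
    pedigree: pd.DataFrame  # time_bp, population, child, parent_a, parent_b
    n_fixed_substitutions: int = 0


class _Engine:
    def __init__(self, scenario: SimScenario, seed: int):
        self.sc = scenario
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.chrom_names = list(scenario.chrom_lengths)
        self.chrom_len = np.array(
            [scenario.chrom_lengths[c] for c in self.chrom_names], dtype=np.int64
        )
        self.chrom_p = self.chrom_len / self.chrom_len.sum()
        self.n_chrom = len(self.chrom_names)
        # site registry
        self.site_chrom = np.empty(0, dtype=np.int32)
        self.site_pos = np.empty(0, dtype=np.int64)
        self.site_s = np.empty(0, dtype=np.float64)
        self.site_h = np.empty(0, dtype=np.float64)
        self.site_marker = np.empty(0, dtype=bool)
        self.used: set[tuple[int, int]] = set()
        self.n_fixed = 0
        self.pedigree_rows: list[tuple] = []
        self._marker_grid()

    # -- setup --------------------------------------------------------------

    def _marker_grid(self) -> None:
        if not self.sc.pulses:
            return
        step = self.sc.ancestry_marker_bp or max(
            5000, int(min(self.chrom_len) // 25)
        )
        chroms, poss = [], []
        for ci, length in enumerate(self.chrom_len):
            for p in range(step // 2, int(length), step):
                chroms.append(ci)
                poss.append(p)
                self.used.add((ci, p))
        k = len(poss)
        self.site_chrom = np.array(chroms, dtype=np.int32)
        self.site_pos = np.array(poss, dtype=np.int64)
        self.site_s = np.zeros(k)
        self.site_h = np.zeros(k)
        self.site_marker = np.ones(k, dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.site_pos)

    def _chrom_cols(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.site_chrom == c) for c in range(self.n_chrom)]

    # -- genetics -----------------------------------------------------------

    def _fitness_probs(self, H: np.ndarray) -> np.ndarray:
        n_ind = H.shape[0] // 2
        sel = np.flatnonzero((self.site_s != 0.0) & ~self.site_marker)
        if sel.size == 0:
            return np.full(n_ind, 1.0 / n_ind)
        dos = (H[0::2][:, sel] + H[1::2][:, sel]).astype(np.float32)
        s = self.site_s[sel]
        h = self.site_h[sel]
        log_het = np.log1p(-h * s).astype(np.float32)
        log_hom = np.log1p(-s).astype(np.float32)
        # dosage 1 contributes log_het, dosage 2 contributes log_hom
        logw = dos @ log_het + (dos == 2.0) @ (log_hom - 2.0 * log_het)
        logw = logw.astype(np.float64)
        logw -= logw.max()
        w = np.exp(logw)
        return w / w.sum()

    def _make_gametes(self, H: np.ndarray, par: np.ndarray) -> np.ndarray:
        """One recombined gamete per entry of ``par`` (parent indices)."""
        rng = self.rng
        G = len(par)
        cols = self._chrom_cols()
        starts = rng.integers(0, 2, size=(G, self.n_chrom))
        gam = H[2 * par + starts[:, 0]]
        for c in range(1, self.n_chrom):
            gi = np.flatnonzero(starts[:, c] != starts[:, 0])
            if gi.size and cols[c].size:
                rows = 2 * par[gi] + starts[gi, c]
                gam[gi[:, None], cols[c][None, :]] = H[rows[:, None], cols[c][None, :]]
        ncross = rng.poisson(self.sc.total_cm / 100.0, size=G)
        for g in np.flatnonzero(ncross):
            xs_by_chrom: dict[int, list[int]] = defaultdict(list)
            for _ in range(int(ncross[g])):
                c = int(rng.choice(self.n_chrom, p=self.chrom_p))
                xs_by_chrom[c].append(int(rng.integers(0, self.chrom_len[c])))
            for c, xs in xs_by_chrom.items():
                cc = cols[c]
                if cc.size == 0:
                    continue
                cnt = np.searchsorted(np.sort(xs), self.site_pos[cc], side="right")
                flip = (cnt % 2) == 1
                if flip.any():
                    selcols = cc[flip]
                    other = 2 * par[g] + 1 - starts[g, c]
                    gam[g, selcols] = H[other, selcols]
        return gam

    def _draw_s(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        rng = self.rng
        s = np.zeros(n)
        h = np.zeros(n)
        if self.sc.frac_deleterious > 0:
            dele = rng.random(n) < self.sc.frac_deleterious
            k = int(dele.sum())
            if k:
                if self.sc.s_shape is None:
                    vals = np.full(k, self.sc.s_mean)
                else:
                    vals = rng.gamma(
                        self.sc.s_shape, self.sc.s_mean / self.sc.s_shape, size=k
                    )
                s[dele] = np.minimum(vals, 0.9)
                h[dele] = self.sc.h
        return s, h

    # -- per-generation steps ----------------------------------------------

    def _reproduce(self, pop: str, old: dict[str, np.ndarray], t_child: int) -> np.ndarray:
        sc = self.sc
        H = old[pop]
        n_par = H.shape[0] // 2
        n_child = sc.size_at(pop, t_child)
        if n_child > MAX_POP_SIZE:
            raise ValueError(f"{pop}: size {n_child} exceeds desk-scale cap")
        probs = self._fitness_probs(H)
        parents = self.rng.choice(n_par, size=(n_child, 2), p=probs)
        if sc.sib_mating_pop == pop and n_par >= 2:
            # plant a stacked sib-mating pedigree so sample 0 is strongly
            # autozygous: full sibs at t=2, sib x sib at t=1 and t=0
            if t_child == 2 and n_child >= 2:
                pair = self.rng.choice(n_par, size=2, replace=False)
                parents[0] = pair
                parents[1] = pair
            elif t_child == 1 and n_child >= 2:
                parents[0] = (0, 1)
                parents[1] = (0, 1)
            elif t_child == 0:
                parents[0] = (0, 1)
        gam = self._make_gametes(H, parents.reshape(-1))
        for pulse in sc.pulses:
            if pulse.time_bp == t_child and pulse.recipient == pop:
                donor_H = old.get(pulse.donor)
                if donor_H is None:
                    raise ValueError(f"pulse donor {pulse.donor} not alive at {t_child}")
                take = np.flatnonzero(self.rng.random(2 * n_child) < pulse.fraction)
                if take.size:
                    dpar = self.rng.integers(0, donor_H.shape[0] // 2, size=take.size)
                    gam[take] = self._make_gametes(donor_H, dpar)
                    marker_cols = np.flatnonzero(self.site_marker)
                    gam[np.ix_(take, marker_cols)] = 1
        if t_child <= 2:
            for i, (a, b) in enumerate(parents):
                self.pedigree_rows.append((t_child, pop, i, int(a), int(b)))
        return gam

    def _mutate(self, new: dict[str, np.ndarray]) -> None:
        sc = self.sc
        L = sc.genome_length
        per_pop = {
            pop: int(self.rng.poisson(H.shape[0] * sc.mu * L))
            for pop, H in new.items()
        }
        k_total = sum(per_pop.values())
        if k_total == 0:
            return
        if self.n_sites + k_total > MAX_LOCI:
            raise RuntimeError("locus grid overflow")
        # vectorized position draws; collisions redrawn in batched rounds
        cs = np.empty(k_total, dtype=np.int64)
        ps = np.empty(k_total, dtype=np.int64)
        pending = np.arange(k_total)
        for _ in range(100):
            if pending.size == 0:
                break
            c_try = self.rng.choice(self.n_chrom, size=pending.size, p=self.chrom_p)
            p_try = (self.rng.random(pending.size) * self.chrom_len[c_try]).astype(np.int64)
            still = []
            for i, c, p in zip(pending, c_try, p_try):
                key = (int(c), int(p))
                if key in self.used:
                    still.append(i)
                else:
                    self.used.add(key)
                    cs[i], ps[i] = c, p
            pending = np.asarray(still, dtype=np.int64)
        if pending.size:
            raise RuntimeError("locus grid exhausted")
        s, h = self._draw_s(k_total)
        self.site_chrom = np.append(self.site_chrom, cs.astype(np.int32))
        self.site_pos = np.append(self.site_pos, ps)
        self.site_s = np.append(self.site_s, s)
        self.site_h = np.append(self.site_h, h)
        self.site_marker = np.append(self.site_marker, np.zeros(k_total, dtype=bool))
        j = 0
        for pop, k in per_pop.items():
            H = new[pop]
            ext = np.zeros((H.shape[0], k_total), dtype=np.uint8)
            if k:
                rows = self.rng.integers(0, H.shape[0], size=k)
                ext[rows, np.arange(j, j + k)] = 1
            new[pop] = np.concatenate([H, ext], axis=1)
            j += k

    def _inject_sweeps(self, pops: dict[str, np.ndarray], t_child: int) -> None:
        for sw in self.sc.sweeps:
            if sw.time_bp != t_child or sw.population not in pops:
                continue
            ci = self.chrom_names.index(sw.chrom)
            key = (ci, int(sw.pos))
            if key in self.used:
                continue
            self.used.add(key)
            self.site_chrom = np.append(self.site_chrom, np.int32(ci))
            self.site_pos = np.append(self.site_pos, np.int64(sw.pos))
            self.site_s = np.append(self.site_s, -abs(sw.s_benefit))
            self.site_h = np.append(self.site_h, 0.5)
            self.site_marker = np.append(self.site_marker, False)
            for pop, H in pops.items():
                col = np.zeros((H.shape[0], 1), dtype=np.uint8)
                if pop == sw.population:
                    col[self.rng.random(H.shape[0]) < sw.init_freq] = 1
                pops[pop] = np.concatenate([H, col], axis=1)

    def _split(self, pops: dict[str, np.ndarray], t_child: int) -> None:
        sc = self.sc
        for sp in sc.splits:
            if sp.time_bp != t_child:
                continue
            src = pops[sp.source]
            n_src = src.shape[0] // 2
            if sp.n_founders > n_src:
                raise ValueError(f"split {sp.daughter}: founders exceed source size")
            if sc.kin_structured:
                n_fam = math.ceil(sp.n_founders / sc.sibship_size)
                par_list = []
                for _ in range(n_fam):
                    pair = self.rng.choice(n_src, size=2, replace=False)
                    par_list.extend([pair] * sc.sibship_size)
                parents = np.array(par_list[: sp.n_founders])
                pops[sp.daughter] = self._make_gametes(src, parents.reshape(-1))
            else:
                picks = self.rng.choice(n_src, size=sp.n_founders, replace=False)
                rows = np.column_stack([2 * picks, 2 * picks + 1]).reshape(-1)
                pops[sp.daughter] = src[rows].copy()

    def _prune(self, pops: dict[str, np.ndarray]) -> None:
        if self.n_sites == 0:
            return
        tot = np.zeros(self.n_sites, dtype=np.int64)
        rows = 0
        for H in pops.values():
            tot += H.sum(axis=0, dtype=np.int64)
            rows += H.shape[0]
        lost = tot == 0
        fixed = tot == rows
        keep = self.site_marker | (~lost & ~fixed)
        self.n_fixed += int((fixed & ~self.site_marker).sum())
        if keep.all():
            return
        # positions of lost mutations may be reused; fixed ones stay reserved
        for j in np.flatnonzero(lost & ~keep):
            self.used.discard((int(self.site_chrom[j]), int(self.site_pos[j])))
        idx = np.flatnonzero(keep)
        self.site_chrom = self.site_chrom[idx]
        self.site_pos = self.site_pos[idx]
        self.site_s = self.site_s[idx]
        self.site_h = self.site_h[idx]
        self.site_marker = self.site_marker[idx]
        for pop in pops:
            pops[pop] = pops[pop][:, idx]

    # -- main loop ----------------------------------------------------------

    def run(self) -> dict[str, np.ndarray]:
        sc = self.sc
        T = sc.total_generations
        n0 = sc.size_at(sc.root, T)
        pops: dict[str, np.ndarray] = {
            sc.root: np.zeros((2 * n0, self.n_sites), dtype=np.uint8)
        }
        for t_child in range(T - 1, -1, -1):
            old = pops
            new = {pop: self._reproduce(pop, old, t_child) for pop in old}
            self._mutate(new)
            self._inject_sweeps(new, t_child)
            self._split(new, t_child)
            pops = new
            if t_child % sc.prune_interval == 0:
                self._prune(pops)
        return pops


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def _tracts_for_hap(
    hap: np.ndarray,
    marker_cols: np.ndarray,
    site_chrom: np.ndarray,
    site_pos: np.ndarray,
    chrom_names: list[str],
    chrom_len: np.ndarray,
) -> list[tuple[str, int, int, int]]:
    """Partition a haplotype's genome into donor/non-donor tracts from the
    marker alleles (boundaries at midpoints between adjacent markers)."""
    out = []
    for ci, cname in enumerate(chrom_names):
        cc = marker_cols[site_chrom[marker_cols] == ci]
        length = int(chrom_len[ci])
        if cc.size == 0:
            out.append((cname, 0, length, 0))
            continue
        order = np.argsort(site_pos[cc])
        cc = cc[order]
        pos = site_pos[cc]
        states = hap[cc].astype(int)
        start = 0
        cur = int(states[0])
        for k in range(1, len(cc)):
            if int(states[k]) != cur:
                mid = int((pos[k - 1] + pos[k]) // 2)
                out.append((cname, start, mid, cur))
                start = mid
                cur = int(states[k])
        out.append((cname, start, length, cur))
    return out


def _random_genes(
    rng: np.random.Generator,
    chrom_names: list[str],
    chrom_len: np.ndarray,
    n_genes: int,
    gene_len: tuple[int, int] = (2000, 5000),
) -> list[tuple[str, int, int]]:
    genes: list[tuple[str, int, int]] = []
    per_chrom = max(1, n_genes // len(chrom_names))
    for ci, cname in enumerate(chrom_names):
        starts = np.sort(rng.integers(0, max(1, int(chrom_len[ci]) - gene_len[1]), size=per_chrom))
        last_end = -1
        for s in starts:
            e = int(s) + int(rng.integers(gene_len[0], gene_len[1]))
            if s <= last_end:
                continue
            e = min(e, int(chrom_len[ci]))
            genes.append((cname, int(s), e))
            last_end = e
    return genes


def simulate(
    scenario: SimScenario,
    seed: int,
    n_genes: int = 80,
    score_noise_sd: float = 0.5,
    inject_reference_bias: bool = False,
) -> SyntheticDataset:
    """Run the forward simulation and assemble the full synthetic dataset.

    Deterministic: the same scenario and seed give identical output.
    """
    eng = _Engine(scenario, seed)
    pops = eng.run()
    sc = scenario
    rng = np.random.default_rng(seed + 777_777)  # emission randomness

    pop_names = sorted(pops)
    samples: list[str] = []
    sample_pop: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for pop in pop_names:
        H = pops[pop]
        n_ind = H.shape[0] // 2
        take = min(sc.n_sample, n_ind)
        for i in range(take):
            name = f"{pop}_{i}"
            samples.append(name)
            sample_pop[name] = pop
            rows.append(H[2 * i] + H[2 * i + 1])
    geno = np.array(rows, dtype=np.int8)  # derived dosage, (n_samples, S_all)

    ref_pop = sc.reference_pop or sc.root
    ref_H = pops[ref_pop]
    ref_ind = sc.n_sample % (ref_H.shape[0] // 2)
    ref_hap = ref_H[2 * ref_ind]

    not_marker = ~eng.site_marker
    order = np.flatnonzero(not_marker)
    order = order[np.lexsort((eng.site_pos[order], eng.site_chrom[order]))]

    ref_derived = ref_hap[order] == 1
    dd = geno[:, order]  # derived dosage at ordered sites
    alt_dosage = np.where(ref_derived[None, :], 2 - dd, dd)
    variant = alt_dosage.sum(axis=0) > 0
    order = order[variant]
    ref_derived = ref_derived[variant]
    alt_dosage = alt_dosage[:, variant]

    n_sites = len(order)
    anc_base = _BASES[rng.integers(0, 4, size=n_sites)]
    der_base = np.array(
        [
            _BASES[(np.flatnonzero(_BASES != a))[rng.integers(0, 3)]]
            for a in anc_base
        ],
        dtype=object,
    )
    ref_allele = np.where(ref_derived, der_base, anc_base).astype(object)
    alt_allele = np.where(ref_derived, anc_base, der_base).astype(object)

    chrom = np.array([eng.chrom_names[c] for c in eng.site_chrom[order]], dtype=object)
    pos = eng.site_pos[order]

    gm = GenotypeMatrix(
        samples=samples,
        populations=sample_pop,
        chrom=chrom,
        pos=pos,
        ref=ref_allele,
        alt=alt_allele,
        dosage=alt_dosage.astype(np.int8),
    )

    outgroup = {(c, int(p)): a for c, p, a in zip(chrom, pos, anc_base)}

    # panel frequencies: derived-allele frequency in the full root population
    panel_H = pops[sc.root]
    panel_freq = panel_H[:, order].mean(axis=0)
    panel_freqs = {(c, int(p)): float(f) for c, p, f in zip(chrom, pos, panel_freq)}

    s_vals = eng.site_s[order]
    score_vals = assign_scores(s_vals, noise_sd=score_noise_sd, rng=rng)
    if inject_reference_bias:
        # reference-derived sites lose their signal, as in an alignment that
        # includes the reference genome; correct_gerp partially undoes this
        score_vals = apply_reference_bias(
            score_vals, ref_derived, rng, noise_sd=score_noise_sd
        )
    scores = pd.DataFrame({"chrom": chrom, "pos": pos, "gerp": score_vals})

    gmap = GeneticMap.uniform(sc.chrom_lengths, sc.cm_per_mb)

    lat0, lon0 = sc.origin
    km_per_deg = 111.194926  # pi * 6371 / 180
    coords = {}
    for name in samples:
        step = sc.pop_steps.get(sample_pop[name], 0)
        coords[name] = (lat0 - step * sc.step_km / km_per_deg, lon0)
    panel = SamplePanel(dict(sample_pop), coords)

    genes = _random_genes(rng, eng.chrom_names, eng.chrom_len, n_genes)
    candidates = []
    for sw in sc.sweeps:
        hit = [
            g
            for g in genes
            if g[0] == sw.chrom and g[1] - 5000 <= sw.pos < g[2] + 5000
        ]
        if hit:
            candidates.extend(hit)
        else:
            g = (sw.chrom, max(0, sw.pos - 1500), sw.pos + 1500)
            genes.append(g)
            candidates.append(g)
    genes = sorted(set(genes))
    candidates = sorted(set(candidates))

    truth_cols = {
        "chrom": chrom,
        "pos": pos,
        "s": s_vals,
        "h": eng.site_h[order],
        "derived_base": der_base,
        "ancestral_base": anc_base,
    }
    for pop in pop_names:
        H = pops[pop]
        truth_cols[f"freq_{pop}"] = H[:, order].mean(axis=0)
    truth_sites = pd.DataFrame(truth_cols)

    marker_cols = np.flatnonzero(eng.site_marker)
    tract_rows = []
    for pop in pop_names:
        H = pops[pop]
        take = min(sc.n_sample, H.shape[0] // 2)
        for i in range(take):
            for hap_i in (0, 1):
                hap = H[2 * i + hap_i]
                for c, s0, e0, d in _tracts_for_hap(
                    hap, marker_cols, eng.site_chrom, eng.site_pos,
                    eng.chrom_names, eng.chrom_len,
                ):
                    tract_rows.append((f"{pop}_{i}", hap_i, c, s0, e0, d))
    tracts = pd.DataFrame(
        tract_rows, columns=["sample", "hap", "chrom", "start", "end", "donor"]
    )

    pedigree = pd.DataFrame(
        eng.pedigree_rows,
        columns=["time_bp", "population", "child", "parent_a", "parent_b"],
    )

    return SyntheticDataset(
        scenario=scenario,
        seed=seed,
        gm=gm,
        outgroup_alleles=outgroup,
        scores=scores,
        panel_freqs=panel_freqs,
        gmap=gmap,
        panel=panel,
        genes=genes,
        candidate_genes=candidates,
        truth_sites=truth_sites,
        tracts=tracts,
        pedigree=pedigree,
        n_fixed_substitutions=eng.n_fixed,
    )
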