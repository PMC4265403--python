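"""Simulation of structured breeding populations for genomic selection.

The generator emulates a two-breeding-group, two-site conifer progeny
trial: a small set of unrelated founders per closed breeding group, a
partial diallel of full-sib crosses within each group (each parent used a
bounded number of times), gene dropping of biallelic SNP genotypes through
the pedigree, and two-site phenotypes whose additive genetic basis has a
controlled across-site genetic correlation (the G-by-E signal) and
site-specific narrow-sense heritabilities.

Defaults correspond to the trial the package was designed around: 2
groups of 19-20 founders (Ne about 20 per group), 59 crosses with each
parent used up to 4 times, 25-33 offspring per cross (about 1,748 offspring),
2 sites x 8 blocks, 6,932 unlinked SNPs with mean minor-allele frequency
0.20, and four traits with heritabilities 0.30-0.57 and across-site
genetic correlations of 0.73 (growth) or 0.83 (wood).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from sprucegs.genotypes import MISSING, GenotypeMatrix
from sprucegs.pedigree import Pedigree

__all__ = [
    "SimConfig",
    "TrueGeneticValues",
    "SimulatedPopulation",
    "simulate_pedigree",
    "drop_genotypes",
    "mask_missing",
    "simulate_phenotypes",
    "simulate_population",
]

#: heritability per trait and site and across-site genetic correlation of
#: the default four-trait layout (two wood traits, two growth traits).
DEFAULT_TRAITS = ("ADEN", "AMFA", "HT17", "DBH17")
DEFAULT_H2 = ((0.33, 0.34), (0.30, 0.32), (0.39, 0.57), (0.39, 0.32))
DEFAULT_R12 = (0.83, 0.83, 0.73, 0.73)


class SimConfigError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass
class SimConfig:
    """Parameters of the simulated breeding trial.

    ``founders_per_group`` and ``crosses_per_group`` accept either a
    single count applied to every group or a per-group sequence.
    ``map_length_cM`` is ``"unlinked"`` (independent markers) or a genetic
    length in centimorgans (single chromosome, Haldane mapping).
    ``founder_maf_spec`` is the target mean minor-allele frequency;
    founder frequencies are drawn uniformly on (0.01, 2*target - 0.01).
    """

    n_groups: int = 2
    founders_per_group: tuple | int = (19, 20)
    crosses_per_group: tuple | int = (27, 32)
    parent_use_range: tuple = (1, 4)
    offspring_per_cross_range: tuple = (25, 33)
    n_sites: int = 2
    n_blocks_per_site: int = 8
    n_markers: int = 6932
    n_causal: int = 300
    founder_maf_spec: float = 0.20
    map_length_cM: float | str = "unlinked"
    trait_names: tuple = DEFAULT_TRAITS
    h2_per_trait_site: tuple = DEFAULT_H2
    r12_per_trait: tuple = DEFAULT_R12
    block_sd: float = 0.5
    missing_rate: float = 0.027
    causal_on_panel: bool = True
    seed: int = 0

    def per_group(self, value) -> list[int]:
        if np.isscalar(value):
            return [int(value)] * self.n_groups
        if len(value) != self.n_groups:
            raise SimConfigError("per-group sequence length must equal n_groups")
        return [int(v) for v in value]

    def validate(self) -> None:
        if self.n_groups < 1 or self.n_sites < 1 or self.n_blocks_per_site < 1:
            raise SimConfigError("counts must be >= 1")
        if self.n_markers < 1 or not (1 <= self.n_causal <= self.n_markers):
            raise SimConfigError("need 1 <= n_causal <= n_markers")
        lo, hi = self.parent_use_range
        if not (1 <= lo <= hi):
            raise SimConfigError("parent_use_range must satisfy 1 <= min <= max")
        olo, ohi = self.offspring_per_cross_range
        if not (1 <= olo <= ohi):
            raise SimConfigError("offspring_per_cross_range must satisfy 1 <= min <= max")
        if not 0.0 < self.founder_maf_spec <= 0.5:
            raise SimConfigError("target mean MAF must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimConfigError("missing_rate must lie in [0, 1)")
        h2 = np.atleast_2d(np.asarray(self.h2_per_trait_site, dtype=float))
        r12 = np.atleast_1d(np.asarray(self.r12_per_trait, dtype=float))
        if h2.shape != (len(self.trait_names), self.n_sites):
            raise SimConfigError("h2_per_trait_site must be (n_traits, n_sites)")
        if r12.shape != (len(self.trait_names),):
            raise SimConfigError("r12_per_trait must have one entry per trait")
        if np.any(h2 <= 0) or np.any(h2 > 1):
            raise SimConfigError("heritabilities must lie in (0, 1]")
        if np.any(np.abs(r12) > 1):
            raise SimConfigError("|r12| must be <= 1")
        for nf, nc in zip(self.per_group(self.founders_per_group),
                          self.per_group(self.crosses_per_group)):
            if nf < 2:
                raise SimConfigError("each group needs at least 2 founders")
            if not (nf * lo <= 2 * nc <= nf * hi):
                raise SimConfigError(
                    f"group with {nf} founders cannot host {nc} crosses with "
                    f"parent usage in [{lo}, {hi}]"
                )

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class TrueGeneticValues:
    """Ground-truth additive genetic values and causal effects.

    ``values`` holds one column per (trait, site) pair named
    ``{trait}@{site}`` for every individual (founders included); the
    value is what the individual's genotype would express at that site.
    """

    values: pd.DataFrame
    causal_markers: list[str]
    causal_effects: pd.DataFrame  # index = causal markers, columns = trait@site

    def column(self, trait: str, site: str) -> pd.Series:
        return self.values[f"{trait}@{site}"]


@dataclass
class SimulatedPopulation:
    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: TrueGeneticValues

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pedigree.to_csv(outdir / "pedigree.csv")
        self.genotypes.to_tsv(outdir / "genotypes.tsv")
        self.genotypes.to_plink_raw(outdir / "genotypes.raw", self.pedigree)
        self.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
        self.truth.values.to_csv(outdir / "true_genetic_values.csv")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def _pair_parents(founders: list[str], n_crosses: int, use_lo: int, use_hi: int,
                  rng: np.random.Generator) -> list[tuple[str, str]]:
    """Draw a partial diallel: ``n_crosses`` distinct within-group pairs
    with every founder used between ``use_lo`` and ``use_hi`` times."""
    n = len(founders)
    for _ in range(1000):
        counts = np.full(n, use_lo, dtype=int)
        deficit = 2 * n_crosses - counts.sum()
        if deficit < 0:
            # more slots than crosses need: relax the lower bound for some
            counts = np.zeros(n, dtype=int)
            deficit = 2 * n_crosses
        while deficit > 0:
            open_idx = np.flatnonzero(counts < use_hi)
            counts[rng.choice(open_idx)] += 1
            deficit -= 1
        slots = np.repeat(np.arange(n), counts)
        rng.shuffle(slots)
        pairs = set()
        ok = True
        for a, b in zip(slots[0::2], slots[1::2]):
            if a == b:
                ok = False
                break
            key = (min(a, b), max(a, b))
            if key in pairs:
                ok = False
                break
            pairs.add(key)
        if ok and len(pairs) == n_crosses:
            return [(founders[a], founders[b]) for a, b in sorted(pairs)]
    raise SimConfigError(
        f"could not realize {n_crosses} distinct crosses among {n} founders "
        f"with parent usage in [{use_lo}, {use_hi}]"
    )


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Founders plus one generation of within-group full-sib crosses.

    Founders are unrelated within and across groups.  Offspring counts per
    cross are uniform over ``offspring_per_cross_range``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    founders_n = config.per_group(config.founders_per_group)
    crosses_n = config.per_group(config.crosses_per_group)
    lo, hi = config.parent_use_range
    olo, ohi = config.offspring_per_cross_range
    records = []
    for g in range(config.n_groups):
        group = f"BG{g + 1}"
        founders = [f"{group}_F{i + 1:02d}" for i in range(founders_n[g])]
        for fid in founders:
            records.append((fid, None, None, group))
        pairs = _pair_parents(founders, crosses_n[g], lo, hi, rng)
        for c, (sire, dam) in enumerate(pairs):
            n_off = int(rng.integers(olo, ohi + 1))
            for k in range(n_off):
                records.append((f"{group}_C{c + 1:02d}_O{k + 1:02d}", sire, dam, group))
    return Pedigree.from_records(records)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _recomb_fractions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Recombination fraction between adjacent markers (length m-1)."""
    m = config.n_markers
    if isinstance(config.map_length_cM, str):
        if config.map_length_cM != "unlinked":
            raise SimConfigError("map_length_cM must be a number or 'unlinked'")
        return np.full(m - 1, 0.5)
    pos = np.sort(rng.uniform(0.0, float(config.map_length_cM), size=m))
    d = np.diff(pos)  # cM
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def drop_genotypes(pedigree: Pedigree, config: SimConfig,
                   rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Gene dropping: Hardy-Weinberg founders, Mendelian transmission.

    Founder haplotypes are drawn in linkage equilibrium at per-marker
    allele frequencies sampled from the founder MAF distribution; gametes
    recombine with per-interval fractions (0.5 everywhere when markers are
    declared unlinked, Haldane fractions otherwise).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[1])
    m = config.n_markers
    n = len(pedigree)
    target = config.founder_maf_spec
    low = min(0.01, target)
    freqs = rng.uniform(low, 2 * target - low, size=m)
    r = _recomb_fractions(config, rng)

    hap = np.zeros((n, 2, m), dtype=np.int8)
    sire_idx, dam_idx = pedigree.parent_indices()

    def gamete(parent: int) -> np.ndarray:
        start = rng.integers(0, 2)
        which = np.empty(m, dtype=np.int64)
        which[0] = start
        if m > 1:
            switches = rng.random(m - 1) < r
            which[1:] = (start + np.cumsum(switches)) % 2
        return np.where(which == 0, hap[parent, 0], hap[parent, 1])

    for i in pedigree.topological_order:
        if sire_idx[i] < 0 and dam_idx[i] < 0:
            hap[i, 0] = rng.random(m) < freqs
            hap[i, 1] = rng.random(m) < freqs
        else:
            hap[i, 0] = gamete(sire_idx[i])
            hap[i, 1] = gamete(dam_idx[i])
    data = hap.sum(axis=1, dtype=np.int8)
    markers = [f"M{k + 1:05d}" for k in range(m)]
    return GenotypeMatrix(data, pedigree.ids, markers)


def mask_missing(G: GenotypeMatrix, rate: float,
                 rng: np.random.Generator | None = None,
                 seed: int | None = None) -> GenotypeMatrix:
    """Set a random fraction of calls to missing (missing-at-random)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    data = G.data.copy()
    mask = rng.random(data.shape) < rate
    data[mask] = MISSING
    return GenotypeMatrix(data, G.ids, G.markers)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _assign_sites_blocks(pedigree: Pedigree, config: SimConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Offspring of every family are split evenly (round-robin) across
    sites; within a site, individuals rotate through the blocks."""
    fam = pedigree.family_of()
    offspring = [iid for iid in pedigree.ids if fam[iid] is not None]
    site_of: dict[str, int] = {}
    by_family: dict[str, list[str]] = {}
    for iid in offspring:
        by_family.setdefault(fam[iid], []).append(iid)
    for members in by_family.values():
        start = int(rng.integers(0, config.n_sites))
        for k, iid in enumerate(members):
            site_of[iid] = (start + k) % config.n_sites
    rows = []
    counter = [0] * config.n_sites
    for iid in offspring:
        s = site_of[iid]
        b = counter[s] % config.n_blocks_per_site
        counter[s] += 1
        rows.append((iid, f"S{s + 1}", f"S{s + 1}B{b + 1}"))
    return pd.DataFrame(rows, columns=["id", "site", "block"])


def simulate_phenotypes(pedigree: Pedigree, genotypes: GenotypeMatrix,
                        config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, TrueGeneticValues]:
    """Two-site phenotypes with controlled h2 and across-site correlation.

    Per trait, each causal locus gets a per-site effect
    ``sqrt(r12) * shared + sqrt(1 - r12) * site_specific`` so that the
    additive genetic correlation between any two sites equals ``r12``.
    Genetic values are rescaled so the population additive variance at
    each site equals the target heritability on the unit phenotypic
    scale; residuals then carry variance ``1 - h2``.
    """
    config.validate()
    if genotypes.missing_mask.any():
        raise ValueError("phenotype simulation requires complete genotypes")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    layout = _assign_sites_blocks(pedigree, config, rng)
    n_sites = config.n_sites
    site_names = [f"S{s + 1}" for s in range(n_sites)]

    causal_pos = np.sort(rng.choice(genotypes.n_markers, size=config.n_causal,
                                    replace=False))
    causal_markers = [genotypes.markers[k] for k in causal_pos]
    Z = genotypes.data[:, causal_pos].astype(float)
    Z -= Z.mean(axis=0)

    offspring_idx = np.asarray(
        [k for k, iid in enumerate(genotypes.ids) if iid in set(layout["id"])]
    )

    h2 = np.atleast_2d(np.asarray(config.h2_per_trait_site, dtype=float))
    r12 = np.atleast_1d(np.asarray(config.r12_per_trait, dtype=float))

    blocks = sorted(layout["block"].unique())
    block_eff = dict(zip(blocks, rng.normal(0.0, config.block_sd, size=len(blocks))))

    truth_cols: dict[str, np.ndarray] = {}
    effect_cols: dict[str, np.ndarray] = {}
    pheno = layout.copy()
    for t, trait in enumerate(config.trait_names):
        shared = rng.normal(size=config.n_causal)
        g_site = np.empty((len(genotypes.ids), n_sites))
        for s in range(n_sites):
            specific = rng.normal(size=config.n_causal)
            b = np.sqrt(abs(r12[t])) * np.sign(r12[t]) * shared \
                + np.sqrt(1.0 - abs(r12[t])) * specific
            g = Z @ b
            sd = g[offspring_idx].std()
            if sd == 0:
                raise SimConfigError("degenerate genetic variance; increase n_causal")
            scale = np.sqrt(h2[t, s]) / sd
            g_site[:, s] = g * scale
            truth_cols[f"{trait}@{site_names[s]}"] = g_site[:, s]
            effect_cols[f"{trait}@{site_names[s]}"] = b * scale
        id_pos = {iid: k for k, iid in enumerate(genotypes.ids)}
        values = np.empty(len(pheno))
        for i, row in enumerate(pheno.itertuples(index=False)):
            s = site_names.index(row.site)
            gi = g_site[id_pos[row.id], s]
            e = rng.normal(0.0, np.sqrt(1.0 - h2[t, s]))
            values[i] = block_eff[row.block] + gi + e
        pheno[trait] = values

    truth = TrueGeneticValues(
        values=pd.DataFrame(truth_cols, index=pd.Index(genotypes.ids, name="id")),
        causal_markers=causal_markers,
        causal_effects=pd.DataFrame(effect_cols,
                                    index=pd.Index(causal_markers, name="marker")),
    )
    return pheno, truth


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Run the full generator under one splittable seed stream."""
    config.validate()
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(4)]
    ped = simulate_pedigree(config, streams[0])
    geno = drop_genotypes(ped, config, streams[1])
    pheno, truth = simulate_phenotypes(ped, geno, config, streams[3])
    if not config.causal_on_panel:
        # trait loci stay un-genotyped: the released panel carries only
        # markers that are in linkage equilibrium with every causal locus
        keep = [k for k, m in enumerate(geno.markers)
                if m not in set(truth.causal_markers)]
        geno = geno.take_markers(np.asarray(keep))
    if config.missing_rate > 0:
        geno = mask_missing(geno, config.missing_rate, streams[2])
    return SimulatedPopulation(config, ped, geno, pheno, truth)
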