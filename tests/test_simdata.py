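"""Breeding-population generator: mating design, gene dropping, phenotypes."""

import numpy as np
import pytest

from sprucegs.pedigree import Pedigree
from sprucegs.relatedness import build_A
from sprucegs.simdata import (SimConfig, SimConfigError, drop_genotypes,
                              simulate_pedigree, simulate_phenotypes,
                              simulate_population)


def _trial_scale_config(**kw):
    base = dict(n_groups=2, founders_per_group=(19, 20),
                crosses_per_group=(27, 32), offspring_per_cross_range=(25, 33),
                n_markers=50, n_causal=10, trait_names=("T1",),
                h2_per_trait_site=((0.4, 0.4),), r12_per_trait=(0.8,),
                missing_rate=0.0, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestPedigreeSimulation:
    def test_trial_scale_family_structure(self):
        """19 + 20 founders with 27 + 32 crosses give 59 full-sib families
        of 25-33 offspring, all crosses within their breeding group."""
        cfg = _trial_scale_config()
        ped = simulate_pedigree(cfg)
        fam = ped.family_of().dropna()
        assert fam.nunique() == 59
        sizes = fam.value_counts()
        assert sizes.between(25, 33).all()
        assert 59 * 25 <= len(fam) <= 59 * 33
        groups = ped.groups
        for iid in fam.index:
            s, d = ped.parents_of(iid)
            assert groups[s] == groups[d] == groups[iid]

    def test_parent_usage_within_range(self):
        cfg = _trial_scale_config()
        ped = simulate_pedigree(cfg)
        tab = ped.table.dropna(subset=["sire"])
        crosses = tab[["sire", "dam"]].drop_duplicates()
        usage = crosses.melt()["value"].value_counts()
        lo, hi = cfg.parent_use_range
        assert usage.between(lo, hi).all()

    def test_single_cross_gives_full_sibs(self):
        cfg = _trial_scale_config(n_groups=1, founders_per_group=2,
                                  crosses_per_group=1,
                                  offspring_per_cross_range=(4, 4),
                                  parent_use_range=(1, 1))
        ped = simulate_pedigree(cfg)
        A = build_A(ped).to_dataframe()
        offspring = [i for i in ped.ids if ped.parents_of(i)[0] is not None]
        for i in offspring:
            for j in offspring:
                if i != j:
                    assert A.loc[i, j] == 0.5

    def test_seed_reproducibility(self):
        cfg = _trial_scale_config(seed=9)
        p1 = simulate_pedigree(cfg)
        p2 = simulate_pedigree(cfg)
        assert p1.table.equals(p2.table)

    def test_infeasible_design_raises(self):
        with pytest.raises(SimConfigError):
            _trial_scale_config(founders_per_group=(3, 3),
                                crosses_per_group=(10, 10),
                                parent_use_range=(1, 2)).validate()


class TestGeneDropping:
    def test_mendelian_transmission_oracle(self):
        """Offspring of het x het segregate 1:2:1 and of 0 x 2 are all
        het, checked against the binomial oracle on pooled markers."""
        cfg = SimConfig(n_groups=1, founders_per_group=2, crosses_per_group=1,
                        parent_use_range=(1, 1),
                        offspring_per_cross_range=(300, 300), n_markers=800,
                        n_causal=10, founder_maf_spec=0.35,
                        trait_names=("T1",), h2_per_trait_site=((0.4, 0.4),),
                        r12_per_trait=(1.0,), missing_rate=0.0, seed=3)
        ped = simulate_pedigree(cfg)
        G = drop_genotypes(ped, cfg)
        founder_rows = G.data[:2]
        child = G.data[2:]
        # forced heterozygote: parents 0 and 2
        forced = (founder_rows[0] + founder_rows[1] == 2) & (
            founder_rows[0] != 1)
        assert forced.sum() > 0
        assert (child[:, forced] == 1).all()
        # het x het: pooled genotype proportions ~ (1/4, 1/2, 1/4)
        hh = (founder_rows[0] == 1) & (founder_rows[1] == 1)
        pooled = child[:, hh].ravel()
        n = pooled.size
        assert n > 5000
        for code, expected in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            frac = (pooled == code).mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(frac - expected) < 3 * se + 1e-9

    def test_allele_frequency_drift(self, small_config):
        """Mean offspring allele frequency tracks the founder frequency."""
        cfg = small_config.replace(missing_rate=0.0, seed=11)
        ped = simulate_pedigree(cfg)
        G = drop_genotypes(ped, cfg)
        founder = ped.founder_mask
        pf = G.take_individuals(founder).allele_freq()
        po = G.take_individuals(~founder).allele_freq()
        # aggregate: mean deviation ~ 0 within 3 SE of the mean
        diffs = po - pf
        se = diffs.std() / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 5e-3

    def test_unlinked_founder_ld(self):
        """Unlinked markers show only sampling-noise LD among founders
        (expected r-squared is about 1/n_founders)."""
        cfg = _trial_scale_config(offspring_per_cross_range=(2, 3),
                                  n_markers=300, seed=13)
        ped = simulate_pedigree(cfg)
        G = drop_genotypes(ped, cfg)
        F = G.take_individuals(ped.founder_mask).data.astype(float)
        keep = F.std(axis=0) > 0
        F = F[:, keep][:, :120]
        corr = np.corrcoef(F.T)
        iu = np.triu_indices_from(corr, k=1)
        r2 = corr[iu] ** 2
        n_founders = int(ped.founder_mask.sum())
        assert np.nanmean(r2) <= 1.0 / (2 * n_founders) + 0.02

    def test_linked_map_produces_ld(self):
        """A short genetic map induces strong adjacent-marker LD in a
        full-sib family (co-segregating blocks)."""
        base = dict(n_groups=1, founders_per_group=2, crosses_per_group=1,
                    parent_use_range=(1, 1),
                    offspring_per_cross_range=(200, 200), n_markers=200,
                    n_causal=10, trait_names=("T1",),
                    h2_per_trait_site=((0.4, 0.4),), r12_per_trait=(1.0,),
                    missing_rate=0.0, seed=5)
        linked = SimConfig(**base, map_length_cM=100.0)
        ped = simulate_pedigree(linked)
        G = drop_genotypes(ped, linked).data[2:].astype(float)
        keep = G.std(axis=0) > 0
        G = G[:, keep]
        adj = [abs(np.corrcoef(G[:, k], G[:, k + 1])[0, 1])
               for k in range(G.shape[1] - 1)]
        unlinked_cfg = SimConfig(**base)
        Gu = drop_genotypes(simulate_pedigree(unlinked_cfg), unlinked_cfg)
        Gu = Gu.data[2:].astype(float)
        keep = Gu.std(axis=0) > 0
        Gu = Gu[:, keep]
        adj_u = [abs(np.corrcoef(Gu[:, k], Gu[:, k + 1])[0, 1])
                 for k in range(Gu.shape[1] - 1)]
        assert np.mean(adj) > np.mean(adj_u) + 0.1


class TestPhenotypes:
    def test_no_noise_limit(self):
        """h2 = 1 with zero block effects: phenotype equals the genetic
        value exactly; r12 = 1 makes both sites' values identical."""
        cfg = SimConfig(n_groups=1, founders_per_group=4, crosses_per_group=4,
                        parent_use_range=(1, 4),
                        offspring_per_cross_range=(10, 10), n_markers=100,
                        n_causal=40, trait_names=("T1",),
                        h2_per_trait_site=((1.0, 1.0),), r12_per_trait=(1.0,),
                        block_sd=0.0, missing_rate=0.0, seed=21)
        pop = simulate_population(cfg)
        truth = pop.truth.values
        assert np.allclose(truth["T1@S1"], truth["T1@S2"])
        for row in pop.phenotypes.itertuples(index=False):
            assert row.T1 == pytest.approx(truth.loc[row.id, f"T1@{row.site}"])

    def test_r12_convergence_large_n(self):
        """Realized across-site genetic correlation approaches the target
        within +-0.05 once n exceeds ~2,000."""
        cfg = SimConfig(founders_per_group=(19, 20),
                        crosses_per_group=(30, 34),
                        offspring_per_cross_range=(30, 36), n_markers=600,
                        n_causal=200, trait_names=("T1",),
                        h2_per_trait_site=((0.4, 0.4),), r12_per_trait=(0.8,),
                        missing_rate=0.0, seed=23)
        pop = simulate_population(cfg)
        offspring = ~pop.pedigree.founder_mask
        tv = pop.truth.values.loc[offspring]
        r = np.corrcoef(tv["T1@S1"], tv["T1@S2"])[0, 1]
        assert abs(r - 0.8) < 0.05

    def test_realized_heritability(self):
        """Block-corrected phenotypic regression recovers the target h2
        on average over replicate simulations."""
        vals = []
        for seed in range(5):
            cfg = SimConfig(founders_per_group=(10, 10),
                            crosses_per_group=(14, 14),
                            offspring_per_cross_range=(25, 30), n_markers=300,
                            n_causal=100, trait_names=("T1",),
                            h2_per_trait_site=((0.4, 0.4),),
                            r12_per_trait=(1.0,), missing_rate=0.0,
                            seed=100 + seed)
            pop = simulate_population(cfg)
            ph = pop.phenotypes
            g = np.array([pop.truth.values.loc[r.id, f"T1@{r.site}"]
                          for r in ph.itertuples(index=False)])
            resid = ph["T1"] - ph.groupby("block")["T1"].transform("mean")
            vals.append(np.var(g) / np.var(resid))
        assert abs(np.mean(vals) - 0.4) < 0.05

    def test_sites_split_families_evenly(self, small_pop):
        ph = small_pop.phenotypes
        fam = small_pop.pedigree.family_of()
        counts = ph.assign(fam=ph["id"].map(fam)).groupby(
            ["fam", "site"]).size().unstack(fill_value=0)
        assert (counts.max(axis=1) - counts.min(axis=1) <= 1).all()

    def test_invalid_parameters_raise(self):
        with pytest.raises(SimConfigError):
            _trial_scale_config(h2_per_trait_site=((1.3, 0.4),)).validate()
        with pytest.raises(SimConfigError):
            _trial_scale_config(r12_per_trait=(1.2,)).validate()
        with pytest.raises(SimConfigError):
            _trial_scale_config(n_causal=100, n_markers=50).validate()


def test_population_files_round_trip(tmp_path, small_pop):
    from sprucegs.genotypes import GenotypeMatrix

    small_pop.write(tmp_path)
    ped = Pedigree.from_csv(tmp_path / "pedigree.csv")
    assert ped.ids == small_pop.pedigree.ids
    G = GenotypeMatrix.from_tsv(tmp_path / "genotypes.tsv")
    assert np.array_equal(G.data, small_pop.genotypes.data)
    Graw = GenotypeMatrix.from_plink_raw(tmp_path / "genotypes.raw")
    assert np.array_equal(Graw.data, small_pop.genotypes.data)
    assert Graw.markers == small_pop.genotypes.markers
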