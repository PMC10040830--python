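import numpy as np
import pytest
from scipy import stats as sps

from indolepath.concordance import accuracy_report, phenotype_from_concentrations
from indolepath.phylo import global_identity
from indolepath.predict import PredictionProfile, predict_metabolites, round_percent
from indolepath.synthetic import (
    BACKGROUND_AA_FREQS,
    CohortSpec,
    MetabolomicsSpec,
    SpeciesSpec,
    default_cohort_spec,
    generate_cohort,
    generate_metabolomics,
    mutate_to_identity,
    random_protein,
)


class TestRandomProtein:
    def test_deterministic_per_seed(self):
        assert random_protein(80, 42).sequence == random_protein(80, 42).sequence
        assert random_protein(80, 42).sequence != random_protein(80, 43).sequence

    def test_length(self):
        assert len(random_protein(300, 1)) == 300

    def test_residue_frequencies_match_background(self):
        seq = "".join(random_protein(1000, 100 + i).sequence for i in range(10))
        aas = list(BACKGROUND_AA_FREQS)
        observed = np.array([seq.count(a) for a in aas])
        expected = np.array([BACKGROUND_AA_FREQS[a] for a in aas])
        expected = expected / expected.sum() * len(seq)
        p = sps.chisquare(observed, expected).pvalue
        assert p > 0.001


class TestMutateToIdentity:
    def test_target_100_unchanged(self):
        s = random_protein(200, 7).sequence
        mut, achieved = mutate_to_identity(s, 100.0, seed=1)
        assert mut.sequence == s
        assert achieved == 100.0

    def test_target_40_lands_in_band(self):
        s = random_protein(300, 9).sequence
        mut, achieved = mutate_to_identity(s, 40.0, seed=2)
        assert 38.0 <= achieved <= 42.0
        assert 38.0 <= global_identity(s, mut.sequence) <= 42.0

    def test_monotone_identity_sweep(self):
        s = random_protein(250, 15).sequence
        achieved = [
            mutate_to_identity(s, t, seed=3)[1] for t in (90, 75, 60, 45, 30)
        ]
        assert all(a > b for a, b in zip(achieved, achieved[1:]))

    def test_indels_supported(self):
        s = random_protein(200, 21).sequence
        mut, achieved = mutate_to_identity(s, 60.0, indel_rate=0.02, seed=4)
        assert 58.0 <= achieved <= 62.0
        assert len(mut.sequence) != 0

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            mutate_to_identity("MKLV" * 20, 10.0, seed=1)


class TestGenerateCohort:
    def test_planted_enzymes_recovered(self, refdb):
        from indolepath.homology import search_homologs
        from indolepath.predict import enzymes_present

        spec = CohortSpec(
            species=(SpeciesSpec("sp", 5, ("ArAT", "LDH")),),
            decoys_per_proteome=5,
            seed=2,
        )
        cohort = generate_cohort(spec, refdb)
        assert len(cohort.proteomes) == 5
        for strain, prots in cohort.proteomes.items():
            ann = search_homologs(prots, refdb, strain_id=strain)
            assert enzymes_present(ann) == cohort.truth[strain] == {"ArAT", "LDH"}

    def test_decoys_only_cohort_annotates_empty(self, refdb):
        from indolepath.homology import search_homologs

        spec = CohortSpec(
            species=(SpeciesSpec("sp", 2, ()),), decoys_per_proteome=8, seed=3
        )
        cohort = generate_cohort(spec, refdb)
        for prots in cohort.proteomes.values():
            assert search_homologs(prots, refdb).count == {}

    def test_unknown_enzyme_rejected(self, refdb):
        spec = CohortSpec(species=(SpeciesSpec("sp", 1, ("NotAnEnzyme",)),), seed=1)
        with pytest.raises(ValueError, match="NotAnEnzyme"):
            generate_cohort(spec, refdb)

    def test_deterministic_per_seed(self, refdb):
        spec = CohortSpec(species=(SpeciesSpec("sp", 2, ("amiE",)),), seed=5,
                          decoys_per_proteome=3)
        c1 = generate_cohort(spec, refdb)
        c2 = generate_cohort(spec, refdb)
        for s in c1.proteomes:
            assert [p.sequence for p in c1.proteomes[s]] == [
                p.sequence for p in c2.proteomes[s]
            ]

    def test_default_cohort_mirrors_study_sizes(self):
        spec = default_cohort_spec()
        sizes = sorted(sp.n_strains for sp in spec.species)
        assert sum(sizes) == 148
        assert len(spec.species) == 13


class TestGenerateMetabolomics:
    def _profiles(self, network):
        spec = default_cohort_spec()
        profiles, smap = [], {}
        for sp in spec.species:
            for k in range(sp.n_strains):
                sid = f"{sp.name.replace(' ', '_')}_S{k + 1:02d}"
                plants = frozenset(sp.enzymes) | {
                    e for e, n in sp.extra_enzymes.items() if k < n
                }
                profiles.append(
                    PredictionProfile(sid, plants, predict_metabolites(plants, network))
                )
                smap[sid] = sp.name
        return profiles, smap

    def test_no_noise_gives_perfect_concordance(self, network):
        profiles, smap = self._profiles(network)
        conc = generate_metabolomics(profiles, MetabolomicsSpec(seed=1), smap)
        rep = accuracy_report(
            profiles, phenotype_from_concentrations(conc), smap, network
        )
        assert all(v == 100.0 for v in rep.per_metabolite_accuracy.values())

    def test_single_species_injection_closed_form(self, network):
        profiles, smap = self._profiles(network)
        n = len(profiles)
        inj_species = "L. helveticus"
        n_inj = sum(1 for s in smap.values() if s == inj_species)
        spec = MetabolomicsSpec(
            seed=1, phenotype_injections=((inj_species, "TA"),)
        )
        conc = generate_metabolomics(profiles, spec, smap)
        rep = accuracy_report(
            profiles, phenotype_from_concentrations(conc), smap, network
        )
        assert rep.per_metabolite_accuracy["TA"] == round_percent(
            100.0 * (n - n_inj) / n
        )
        others = {m: v for m, v in rep.per_metabolite_accuracy.items() if m != "TA"}
        assert all(v == 100.0 for v in others.values())

    def test_false_negatives_lower_accuracy_only_downward(self, network):
        profiles, smap = self._profiles(network)
        conc = generate_metabolomics(
            profiles, MetabolomicsSpec(seed=2, false_negative_rate=0.2), smap
        )
        rep = accuracy_report(
            profiles, phenotype_from_concentrations(conc), smap, network
        )
        cells = rep.cells
        assert (cells.loc[cells["cell"] == "GA_PE"].shape[0]) == 0
        assert rep.per_metabolite_accuracy["ILA"] < 100.0

    def test_determinism_per_seed(self, network):
        profiles, smap = self._profiles(network)
        spec = MetabolomicsSpec(seed=9)
        c1 = generate_metabolomics(profiles, spec, smap)
        c2 = generate_metabolomics(profiles, spec, smap)
        assert c1.equals(c2)

    def test_paper_like_conditions(self, network):
        """Anomaly spec: TA present in every L. helveticus strain, IA in every
        L. mucosae strain, IAM never observed, L. salivarius ILA elevated."""
        from indolepath.synthetic import paper_like_metabolomics_spec

        profiles, smap = self._profiles(network)
        conc = generate_metabolomics(profiles, paper_like_metabolomics_spec(seed=5), smap)
        helv = [s for s, sp in smap.items() if sp == "L. helveticus"]
        muco = [s for s, sp in smap.items() if sp == "L. mucosae"]
        sal = [s for s, sp in smap.items() if sp == "L. salivarius"]
        curv = [s for s, sp in smap.items() if sp == "L. curvatus"]
        assert (conc.loc[helv, "TA"] > 0).all()
        assert (conc.loc[muco, "IA"] > 0).all()
        assert (conc["IAM"] == 0).all()
        assert conc.loc[sal, "ILA"].mean() > 5 * conc.drop(sal)["ILA"].mean()
        assert (conc.loc[curv] == 0).all().all()

    def test_detection_limit_floors_values(self, network):
        profiles, smap = self._profiles(network)
        spec = MetabolomicsSpec(seed=3, detection_limit=1e9)
        conc = generate_metabolomics(profiles, spec, smap)
        assert (conc.to_numpy() == 0).all()
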