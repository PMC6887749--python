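import filecmp

import numpy as np
import pytest
from Bio.Seq import Seq

from famsurvey.exceptions import ParameterError, SizingError
from famsurvey.homology import confirm_domain
from famsurvey.io import read_gff3
from famsurvey.synthetic import (SyntheticConfig, generate_survey_dataset,
                                 mutate_protein, write_survey_dataset)


def positional_identity(a, b):
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestMutateProtein:
    def test_identity_one_returns_input(self):
        seq = "MKVLTAEQRRG" * 5
        assert mutate_protein(seq, 1.0, seed=3) == seq

    def test_target_identity_realized(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        mutant = mutate_protein(seq, 0.85, seed=5)
        assert len(mutant) == len(seq)
        assert 0.83 <= positional_identity(seq, mutant) <= 0.87

    def test_different_seeds_differ_same_band(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        m1 = mutate_protein(seq, 0.8, seed=1)
        m2 = mutate_protein(seq, 0.8, seed=2)
        assert m1 != m2
        assert positional_identity(seq, m1) == positional_identity(seq, m2)

    def test_invalid_target_rejected(self):
        with pytest.raises(ParameterError):
            mutate_protein("MKVL", 0.0, seed=1)
        with pytest.raises(ParameterError):
            mutate_protein("", 0.5, seed=1)


class TestGenerateSurveyDataset:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        config = SyntheticConfig(rng_seed=19)
        dir1, dir2 = tmp_path / "a", tmp_path / "b"
        paths1 = write_survey_dataset(generate_survey_dataset(config), dir1)
        paths2 = write_survey_dataset(
            generate_survey_dataset(SyntheticConfig(rng_seed=19)), dir2)
        for name in paths1:
            assert filecmp.cmp(paths1[name], paths2[name], shallow=False), name

    def test_no_family_genes(self):
        config = SyntheticConfig(n_family_genes=0, n_tandem_clusters=0,
                                 n_segmental_pairs=0, n_distractor_pairs=0,
                                 rng_seed=2)
        dataset = generate_survey_dataset(config)
        assert dataset.truth.family_members == set()
        assert len(dataset.proteome) == config.n_decoy_genes
        for protein in dataset.proteome.values():
            assert not confirm_domain(protein).confirmed

    def test_decoys_carry_no_nbd_motifs(self, survey_dataset):
        decoys = set(survey_dataset.proteome) - survey_dataset.truth.family_members
        for gene_id in decoys:
            evidence = confirm_domain(survey_dataset.proteome[gene_id])
            assert evidence.walker_a is None
            assert evidence.signature is None
            assert evidence.walker_b is None

    def test_family_proteins_confirm(self, survey_dataset):
        for gene_id in survey_dataset.truth.family_members:
            assert confirm_domain(survey_dataset.proteome[gene_id]).confirmed

    def test_tandem_geometry_recounted_from_gff(self, tmp_path):
        """With one intervening gene configured, every truth tandem pair is
        separated by exactly one gene in emitted GFF3 order."""
        config = SyntheticConfig(n_tandem_clusters=3,
                                 intervening_per_cluster=1,
                                 n_family_genes=18, rng_seed=23)
        dataset = generate_survey_dataset(config)
        paths = write_survey_dataset(dataset, tmp_path)
        models = read_gff3(paths["annotation"])
        rank = {m.gene_id: (m.chromosome, m.rank_on_chromosome) for m in models}
        assert len(dataset.truth.tandem_pairs) == 3
        for a, b in dataset.truth.tandem_pairs:
            chrom_a, rank_a = rank[a]
            chrom_b, rank_b = rank[b]
            assert chrom_a == chrom_b
            assert abs(rank_b - rank_a) == 2  # exactly one gene between

    def test_adjacent_geometry_without_intervening(self):
        config = SyntheticConfig(n_tandem_clusters=2,
                                 intervening_per_cluster=0, rng_seed=29)
        dataset = generate_survey_dataset(config)
        rank = {m.gene_id: m.rank_on_chromosome for m in dataset.models}
        for a, b in dataset.truth.tandem_pairs:
            assert abs(rank[b] - rank[a]) == 1

    def test_segmental_pairs_cross_chromosome(self, survey_dataset):
        by_id = {m.gene_id: m for m in survey_dataset.models}
        for a, b in survey_dataset.truth.segmental_pairs:
            assert by_id[a].chromosome != by_id[b].chromosome
            identity = positional_identity(survey_dataset.proteome[a],
                                           survey_dataset.proteome[b])
            assert identity > 0.84  # comfortably above the 80% boundary

    def test_tandem_and_segmental_truth_disjoint(self, survey_dataset):
        assert survey_dataset.truth.tandem_pairs.isdisjoint(
            survey_dataset.truth.segmental_pairs)

    def test_translation_round_trip(self, survey_dataset):
        """The emitted proteome equals conceptual translation of every
        emitted CDS under the standard code."""
        for model in survey_dataset.models:
            contig = survey_dataset.genome[model.chromosome]
            cds = "".join(contig[s - 1:e] for s, e in model.cds)
            if model.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            protein = str(Seq(cds).translate())
            assert protein.endswith("*")
            assert protein[:-1] == survey_dataset.proteome[model.gene_id]

    def test_truth_ids_all_annotated(self, survey_dataset):
        annotated = {m.gene_id for m in survey_dataset.models}
        truth = survey_dataset.truth
        referenced = (truth.family_members | truth.intronless
                      | {g for p in truth.tandem_pairs for g in p}
                      | {g for p in truth.segmental_pairs for g in p})
        assert referenced <= annotated

    def test_infeasible_chromosome_rejected(self):
        config = SyntheticConfig(chromosome_length=12_000, rng_seed=1)
        with pytest.raises(SizingError, match="chromosome_length"):
            generate_survey_dataset(config)

    def test_pair_budget_rejected(self):
        config = SyntheticConfig(n_family_genes=4, n_tandem_clusters=2,
                                 n_segmental_pairs=2)
        with pytest.raises(SizingError, match="n_family_genes"):
            generate_survey_dataset(config)

    def test_planted_elements_recorded_offsets(self, survey_dataset):
        """Planted counts are recoverable by scanning the emitted genome."""
        from famsurvey.motifs import extract_promoter, scan_cis_elements
        from famsurvey.resources import default_cis_elements

        dictionary = default_cis_elements()
        by_id = {m.gene_id: m for m in survey_dataset.models}
        for gene_id in sorted(survey_dataset.truth.family_members):
            record = extract_promoter(survey_dataset.genome, by_id[gene_id])
            scan_cis_elements(record, dictionary)
            for element in dictionary:
                expected = survey_dataset.truth.element_counts.get(
                    (gene_id, element.name), 0)
                assert record.element_counts[element.name] == expected, \
                    (gene_id, element.name)
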