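import numpy as np
import pytest

from mycoscreen.codes import MITO, STANDARD
from mycoscreen.config import Config
from mycoscreen.orfs import translate
from mycoscreen.pssm import build_profile, scan
from mycoscreen.roster import HostIsolate
from mycoscreen.simulate import (SurveyParams, TranscriptomeParams,
                                 TruthRecord, PlantedVirus, back_translate,
                                 expected_unique_virus_count, gen_genome,
                                 gen_panel, gen_reads, gen_survey,
                                 gen_transcriptome)


class TestGenPanel:
    def test_every_member_carries_gdd_motif(self, panel_bundle):
        for fam in panel_bundle.families:
            for _, seq in fam.alignment:
                assert seq[fam.motif_col:fam.motif_col + 3] == "GDD"

    def test_family_shape_floor(self, panel_bundle):
        assert len(panel_bundle.families) >= 2
        for fam in panel_bundle.families:
            assert len(fam.alignment) >= 8
            assert len(fam.alignment[0][1]) >= 120

    def test_deterministic(self):
        assert gen_panel(3) == gen_panel(3)
        assert gen_panel(3) != gen_panel(4)

    def test_reference_labels(self, panel_bundle):
        branches = {r.branch for r in panel_bundle.refs if r.is_viral}
        assert branches == {"1", "2", "3", "4", "5"}
        assert any(r.is_mitovirus for r in panel_bundle.refs)
        assert any(not r.is_viral for r in panel_bundle.refs)

    def test_consensus_scores_maximally_against_own_profile(self,
                                                            panel_bundle):
        fam = panel_bundle.families[2]
        prof = build_profile(list(fam.alignment), name=fam.name)
        best = scan(prof.consensus, prof, min_bits=1.0)
        worse = scan(fam.alignment[0][1], prof, min_bits=1.0)
        assert best.bit_score >= worse.bit_score

    def test_mito_family_has_single_mid_trp(self, panel_bundle):
        fam = panel_bundle.family("fam_mito")
        for _, seq in fam.alignment:
            assert seq.count("W") == 1
            w = seq.index("W")
            assert 0.35 < w / len(seq) < 0.55


def _host(hid="H0", genome="own"):
    return HostIsolate(hid, "Chytridiomycota", order="Cladochytriales",
                       morphology="polycentric", genome_available=genome)


def _truth(hid="H0", **kw):
    defaults = dict(member_id="fam_branch4_m0", family="fam_branch4",
                    branch="4", completeness="complete",
                    is_endogenous=False, uses_mito_code=False)
    defaults.update(kw)
    return TruthRecord(hid, [PlantedVirus(**defaults)])


class TestGenTranscriptome:
    def test_zero_substitution_plants_identical_protein(self, panel_bundle):
        truth = _truth()
        contigs = gen_transcriptome(_host(), truth, panel_bundle,
                                    TranscriptomeParams(), seed=2)
        plant = truth.planted[0]
        member = panel_bundle.family("fam_branch4").member("fam_branch4_m0")
        s, e = plant.orf_span
        assert translate(plant.contig_seq[s:e], STANDARD) == member
        assert plant.contig_id in {cid for cid, _ in contigs}

    def test_cterm_fragment_covers_last_half(self, panel_bundle):
        truth = _truth(completeness="c_term")
        gen_transcriptome(_host(), truth, panel_bundle,
                          TranscriptomeParams(), seed=2)
        plant = truth.planted[0]
        member = panel_bundle.family("fam_branch4").member("fam_branch4_m0")
        s, e = plant.orf_span
        assert translate(plant.contig_seq[s:e], STANDARD) == \
            member[len(member) - len(member) // 2:]

    def test_mito_plant_standard_code_hits_internal_stop(self, panel_bundle):
        truth = _truth(member_id="fam_mito_m1", family="fam_mito",
                       branch="1", uses_mito_code=True)
        gen_transcriptome(_host(), truth, panel_bundle,
                          TranscriptomeParams(), seed=2)
        s, e = truth.planted[0].orf_span
        cds = truth.planted[0].contig_seq[s:e]
        std = translate(cds, STANDARD)
        assert "*" in std
        assert "*" not in translate(cds, MITO)

    def test_truth_bookkeeping(self, panel_bundle):
        truth = TruthRecord("H0", [
            PlantedVirus("fam_branch1_m0", "fam_branch1", "1", "complete",
                         False, False),
            PlantedVirus("fam_branch2_m3", "fam_branch2", "2", "n_term",
                         False, False),
        ])
        contigs = gen_transcriptome(_host(), truth, panel_bundle,
                                    TranscriptomeParams(n_host_contigs=5),
                                    seed=4)
        planted_ids = {p.contig_id for p in truth.planted}
        assert len(planted_ids) == 2
        assert len(contigs) == 7
        assert planted_ids <= {cid for cid, _ in contigs}

    def test_substitution_rate_bounds(self, panel_bundle):
        with pytest.raises(ValueError):
            TranscriptomeParams(viral_sub_rate=0.5)


class TestGenReads:
    def test_error_free_reads_are_substrings(self, rng):
        template = "".join(rng.choice(list("ACGT"), 400))
        for read in gen_reads(template, 10, 80, 0.0, seed=3):
            assert read.seq in template

    def test_mean_coverage_near_depth(self, rng):
        template = "".join(rng.choice(list("ACGT"), 600))
        reads = gen_reads(template, 20, 100, 0.0, seed=3)
        cover = np.zeros(len(template))
        for read in reads:
            start = template.index(read.seq)
            cover[start:start + 100] += 1
        assert abs(cover.mean() - 20) / 20 < 0.2

    def test_seeded_determinism(self, rng):
        template = "".join(rng.choice(list("ACGT"), 300))
        assert gen_reads(template, 5, 50, 0.01, seed=9) == \
            gen_reads(template, 5, 50, 0.01, seed=9)

    def test_strict_and_loose_filters_differ(self, rng):
        from mycoscreen.extension import filter_reads
        template = "".join(rng.choice(list("ACGT"), 500))
        reads = gen_reads(template, 30, 100, 0.0, seed=3)
        strict = filter_reads(reads, 20)
        loose = filter_reads(reads, 5)
        assert len(loose) == len(reads)
        assert 0 < len(strict) < len(reads)

    def test_read_longer_than_template_rejected(self):
        with pytest.raises(ValueError):
            gen_reads("ACGT", 5, 10, 0.0, seed=1)


class TestGenGenome:
    def test_endogenous_plant_is_substring(self, panel_bundle):
        truth = _truth(is_endogenous=True)
        gen_transcriptome(_host(), truth, panel_bundle,
                          TranscriptomeParams(), seed=5)
        genome = gen_genome(_host(), truth, seed=6)
        assert truth.planted[0].contig_seq in genome

    def test_exogenous_plant_below_endogeny_thresholds(self, panel_bundle,
                                                       cfg):
        from mycoscreen.endogeny import endogeny_call, genome_match
        truth = _truth(is_endogenous=False)
        gen_transcriptome(_host(), truth, panel_bundle,
                          TranscriptomeParams(), seed=5)
        genome = gen_genome(_host(), truth, seed=6)
        match = genome_match(truth.planted[0].contig_seq, genome)
        call = endogeny_call("c", match, "own", cfg)
        assert call.status == "exogenous"

    def test_no_genome_when_unavailable(self, panel_bundle):
        truth = _truth()
        assert gen_genome(_host(genome="none"), truth, seed=1) is None


class TestGenSurvey:
    def test_seeded_determinism(self):
        a = gen_survey(SurveyParams(n_hosts=6), seed=21)
        b = gen_survey(SurveyParams(n_hosts=6), seed=21)
        assert a.roster == b.roster
        assert a.contigs == b.contigs
        assert a.genomes == b.genomes

    def test_truth_bookkeeping_and_vitro_consistency(self, survey_small):
        for host in survey_small.roster:
            truth = survey_small.truth_for(host.id)
            planted_ids = {p.contig_id for p in truth.planted}
            contig_ids = {cid for cid, _ in survey_small.contigs
                          if cid.startswith(host.id + "|v")}
            assert planted_ids == contig_ids
            if host.in_vitro_result != "not_done":
                expected = "positive" if truth.exogenous else "negative"
                assert host.in_vitro_result == expected
            for p in truth.planted:
                if p.is_endogenous:
                    assert host.genome_available != "none"
                    assert p.contig_seq in survey_small.genomes[host.id]


class TestExpectedCensus:
    def test_fragment_pair_counts_once(self):
        truth = TruthRecord("H0", [
            PlantedVirus("m0", "fam_branch1", "1", "n_term", False, False),
            PlantedVirus("m1", "fam_branch1", "1", "c_term", False, False),
        ])
        assert expected_unique_virus_count(truth) == 1

    def test_completes_count_individually(self):
        truth = TruthRecord("H0", [
            PlantedVirus("m0", "fam_branch1", "1", "complete", False, False),
            PlantedVirus("m1", "fam_branch1", "1", "complete", False, False),
            PlantedVirus("m2", "fam_branch4", "4", "n_term", False, False),
        ])
        assert expected_unique_virus_count(truth) == 3

    def test_endogenous_excluded(self):
        truth = TruthRecord("H0", [
            PlantedVirus("m0", "fam_branch1", "1", "complete", True, False),
        ])
        assert expected_unique_virus_count(truth) == 0
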