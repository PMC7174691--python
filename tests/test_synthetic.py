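"""Generator contracts: determinism, planted truth, count model."""

from collections import Counter
from pathlib import Path

import numpy as np
import pytest

from cerna.diffexpr import call_differential
from cerna.io import write_fasta
from cerna.mimic import evaluate_etm_site, find_etm_sites
from cerna.seq import random_dna, revcomp_dna
from cerna.synthetic import (
    SimulationConfig,
    TruthSet,
    plant_mimic_site,
    simulate,
    simulate_counts,
)


class TestConfigValidation:
    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_chromosomes=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_ref_mrna=0)
        with pytest.raises(ValueError):
            SimulationConfig(replicates=1)
        with pytest.raises(ValueError):
            SimulationConfig(mirna_length=12)
        with pytest.raises(ValueError):
            SimulationConfig(bulge_length_range=(3, 11))
        with pytest.raises(ValueError):
            SimulationConfig(dispersion=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(mean_expression=-1)


class TestGenerateReference:
    def test_candidate_cohort_counts(self, dataset):
        truth = dataset.truth.class_code_truth
        cohort = Counter(c for c in truth.values() if c != "=")
        assert cohort == {"i": 2, "j": 2, "o": 2, "u": 2, "x": 2}
        assert sum(1 for c in truth.values() if c == "=") == 2

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        paths = []
        for name in ("a", "b"):
            ds = simulate(SimulationConfig(seed=42))
            p = tmp_path / f"{name}.fasta"
            write_fasta(ds.sequences, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_coordinates_consistent_between_gtf_and_fasta(self, dataset):
        for t in dataset.transcripts:
            assert len(t.sequence) == t.length

    def test_every_planted_id_exists(self, dataset):
        ids = {t.id for t in dataset.transcripts}
        for r in dataset.truth.planted_etm_sites:
            assert r.lncrna in ids and r.mirna in dataset.mirnas
        for r in dataset.truth.planted_cleavage_sites:
            assert r.mrna in ids and r.mirna in dataset.mirnas
        for tid in dataset.truth.class_code_truth:
            assert tid in ids


class TestPlantMimicSite:
    MIR = "ACGAUCGAUCGAUCGAUCGAU"

    def plant(self, **kw):
        rng = np.random.default_rng(0)
        lnc = random_dna(rng, 200)
        return plant_mimic_site(lnc, self.MIR, 50, rng=rng, **kw)

    def test_compliance_flag(self):
        assert self.plant(bulge_len=3)[1].rule_compliant

    def test_bulge_six_not_compliant(self):
        assert not self.plant(bulge_len=6)[1].rule_compliant

    def test_five_mismatches_not_compliant(self):
        _, rec = self.plant(bulge_len=4, mismatches=[2, 4, 6, 8, 13])
        assert not rec.rule_compliant

    def test_three_consecutive_not_compliant(self):
        _, rec = self.plant(bulge_len=4, mismatches=[3, 4, 5])
        assert not rec.rule_compliant

    def test_planted_site_content(self):
        seq, rec = self.plant(bulge_len=4)
        site = seq[rec.start : rec.end]
        mir = self.MIR.replace("U", "T")
        assert site[:11] == revcomp_dna(mir[10:])
        assert site[15:] == revcomp_dna(mir[:10])

    def test_overlap_rejected(self):
        rng = np.random.default_rng(0)
        lnc = random_dna(rng, 200)
        lnc, rec = plant_mimic_site(lnc, self.MIR, 50, 3, rng=rng)
        with pytest.raises(ValueError, match="overlaps"):
            plant_mimic_site(
                lnc, self.MIR, 60, 3, rng=rng,
                occupied=[(rec.start, rec.end)],
            )

    def test_central_mismatch_position_rejected(self):
        with pytest.raises(ValueError, match="non-central"):
            self.plant(bulge_len=3, mismatches=[10])

    def test_site_must_fit(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="fit"):
            plant_mimic_site(random_dna(rng, 30), self.MIR, 20, 3, rng=rng)


class TestPlantedSiteRecovery:
    def test_compliant_sites_found_violations_rejected(
        self, dataset, lnc_sequences
    ):
        for r in dataset.truth.planted_etm_sites:
            mir = dataset.mirnas[r.mirna]
            found = {
                (s.duplex.start, s.duplex.bulge_len)
                for s in find_etm_sites(mir, lnc_sequences[r.lncrna])
            }
            if r.rule_compliant:
                assert (r.start, r.bulge_len) in found
            else:
                assert (r.start, r.bulge_len) not in found
                if r.violation != "protrusion":
                    site = evaluate_etm_site(
                        mir, lnc_sequences[r.lncrna], r.start, r.bulge_len
                    )
                    assert not site.accepted

    def test_planted_cleavage_penalties(self, dataset):
        from cerna.mimic import score_cleavage_site

        seqs = dataset.sequences
        for r in dataset.truth.planted_cleavage_sites:
            window = seqs[r.mrna][r.start : r.start + len(
                dataset.mirnas[r.mirna]
            )]
            d = score_cleavage_site(dataset.mirnas[r.mirna], window)
            assert d.penalty == pytest.approx(r.penalty)
            assert d.accepted == r.accepted_expected


class TestSimulateCounts:
    def test_twelve_columns_for_default_design(self, dataset):
        assert dataset.expression.counts.shape[1] == 12

    def test_null_log2fc_shrinks_with_expression(self):
        meds = []
        for mean in (5.0, 5000.0):
            cfg = SimulationConfig(seed=3, mean_expression=mean,
                                   expression_log2_sd=0.0)
            tab = simulate_counts(
                cfg, TruthSet(), {f"t{i}": 1000 for i in range(300)}
            )
            res = call_differential(
                tab,
                tab.design.group("tolerant", "control"),
                tab.design.group("tolerant", "salt"),
            )
            meds.append(res["log2fc"].abs().median())
        assert meds[1] < meds[0]

    def test_planted_log2fc_recovered_across_replicates(self):
        """Monte-Carlo: estimator within +-0.5 of the planted 2.0 in >= 95%
        of 200 seeded replicates (mean FPKM 50, n = 3)."""
        hits = 0
        for s in range(200):
            cfg = SimulationConfig(seed=5000 + s, expression_log2_sd=0.0)
            truth = TruthSet(planted_de={"t0": {"tolerant": 2.0}})
            tab = simulate_counts(
                cfg, truth, {f"t{i}": 1000 for i in range(100)}
            )
            res = call_differential(
                tab,
                tab.design.group("tolerant", "control"),
                tab.design.group("tolerant", "salt"),
            )
            if abs(res.loc["t0", "log2fc"] - 2.0) <= 0.5:
                hits += 1
        assert hits >= 190

    def test_empty_lengths_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts(SimulationConfig(), TruthSet(), {})
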