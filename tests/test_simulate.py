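import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from ctc_concord import simulate as sim
from ctc_concord.io_core import SampleClass, ValidationError


def _dir_hash(d):
    h = hashlib.sha256()
    for p in sorted(Path(d).rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(d)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def _one_patient_config(**kwargs):
    scenario = sim.PatientScenario(
        patient_id="P1",
        n_ctc_singles=kwargs.pop("n_ctc_singles", 3),
        ctc_pool_sizes=kwargs.pop("ctc_pool_sizes", ()),
        bulk_purity=kwargs.pop("bulk_purity", 0.3),
        wga_ctc=kwargs.pop("wga_ctc", sim.WGAModel()),
        wga_wbc=kwargs.pop("wga_wbc", sim.WGAModel(fp_rate=60.0)),
        clones=[
            sim.CloneSpec("A", None, 1.0, ctc_fraction=1.0,
                          n_private_mutations=kwargs.pop("n_truncal", 60)),
        ],
    )
    return sim.SimConfig(patients=[scenario], **kwargs)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        config = _one_patient_config(n_truncal=30)
        sim.simulate_run(config, seed=5, outdir=tmp_path / "a")
        config2 = _one_patient_config(n_truncal=30)
        sim.simulate_run(config2, seed=5, outdir=tmp_path / "b")
        assert _dir_hash(tmp_path / "a") == _dir_hash(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        sim.simulate_run(_one_patient_config(n_truncal=30), seed=5,
                         outdir=tmp_path / "a")
        sim.simulate_run(_one_patient_config(n_truncal=30), seed=6,
                         outdir=tmp_path / "b")
        assert _dir_hash(tmp_path / "a") != _dir_hash(tmp_path / "b")


class TestReadSampling:
    def test_total_locus_dropout_gives_zero_depth(self):
        wga = sim.WGAModel(locus_dropout_rate=1.0)
        rng = np.random.default_rng(0)
        assert all(
            sim.sample_reads_at_site(0.5, wga, rng) == (0, 0) for _ in range(50)
        )

    def test_no_alt_allele_gives_zero_alt_reads(self):
        wga = sim.WGAModel(locus_dropout_rate=0.0, ado_rate=0.2)
        rng = np.random.default_rng(0)
        assert all(
            sim.sample_reads_at_site(0.0, wga, rng)[1] == 0 for _ in range(200)
        )

    def test_mean_vaf_unbiased_without_dropout(self):
        # law of large numbers on the binomial read model
        wga = sim.WGAModel(ado_rate=0.0, locus_dropout_rate=0.0,
                           coverage_mean=60, coverage_dispersion=5)
        rng = np.random.default_rng(1)
        vafs = []
        for _ in range(100_000):
            d, a = sim.sample_reads_at_site(0.5, wga, rng)
            if d > 0:
                vafs.append(a / d)
        assert np.mean(vafs) == pytest.approx(0.5, abs=0.002)

    def test_ado_zeroes_or_doubles_the_fraction(self):
        wga = sim.WGAModel(ado_rate=0.5, locus_dropout_rate=0.0,
                           coverage_mean=5000, coverage_dispersion=50)
        rng = np.random.default_rng(2)
        vafs = [sim.sample_reads_at_site(0.5, wga, rng) for _ in range(2000)]
        vafs = [a / d for d, a in vafs if d > 0]
        # at deep coverage the post-dropout fraction is ~0, ~0.5 or ~1
        groups = {round(v, 1) for v in vafs}
        assert groups <= {0.0, 0.5, 1.0}
        assert {0.0, 0.5, 1.0} <= groups


class TestNoiseModel:
    def test_noiseless_limit_all_truncal_called_everywhere(self, tmp_path):
        wga = sim.WGAModel(ado_rate=0.0, fp_rate=0.0, locus_dropout_rate=0.0,
                           coverage_mean=200, coverage_dispersion=50)
        config = _one_patient_config(
            wga_ctc=wga, wga_wbc=sim.WGAModel(fp_rate=0.0, ado_rate=0.0,
                                              locus_dropout_rate=0.0),
            n_truncal=80,
        )
        truths, _ = sim.simulate_run(config, seed=3, outdir=tmp_path)
        truth = truths[0]
        truncal = truth.sites["origin"] == "truncal"
        for meta in truth.samples:
            if not meta.sample_class.is_ctc:
                continue
            table = _read_sites(tmp_path, meta.sample_id)
            assert table.loc[truncal.to_numpy(), "called"].all()

    def test_detection_fraction_matches_closed_form(self, tmp_path):
        # detection of a het truncal mutation in one CTC =
        # (1 - locus_dropout) * (1 - ado), up to a small caller loss
        ado, dropout = 0.3, 0.4
        wga = sim.WGAModel(ado_rate=ado, fp_rate=0.0,
                           locus_dropout_rate=dropout,
                           coverage_mean=200, coverage_dispersion=5)
        config = _one_patient_config(wga_ctc=wga, n_truncal=600,
                                     n_ctc_singles=2)
        truths, _ = sim.simulate_run(config, seed=4, outdir=tmp_path)
        truth = truths[0]
        truncal = (truth.sites["origin"] == "truncal").to_numpy()
        expected = (1 - ado) * (1 - dropout)
        for sid in ("P1_CTC1", "P1_CTC2"):
            table = _read_sites(tmp_path, sid)
            frac = table.loc[truncal, "called"].mean()
            # 3 sigma binomial envelope around the closed form
            se = np.sqrt(expected * (1 - expected) / truncal.sum())
            assert abs(frac - expected) < 3 * se + 0.02

    def test_bulk_truncal_vaf_is_half_purity_in_diploid_regions(self, tmp_path):
        config = _one_patient_config(bulk_purity=0.3, n_truncal=400)
        truths, _ = sim.simulate_run(config, seed=5, outdir=tmp_path)
        truth = truths[0]
        table = _read_sites(tmp_path, "P1_BULK")
        truncal = (truth.sites["origin"] == "truncal").to_numpy()
        covered = (table["depth"] > 0).to_numpy()
        sel = truncal & covered
        vaf = (table["alt_reads"] / table["depth"])[sel]
        assert vaf.mean() == pytest.approx(0.15, abs=0.01)

    def test_bulk_window_ratio_matches_purity_mixture(self, tmp_path):
        # expected tumor/control count ratio per segment:
        # (rho*q + 2(1-rho)) / (rho*tau + 2(1-rho))
        rho = 0.3
        scenario = sim.PatientScenario(
            patient_id="P1", bulk_purity=rho, n_ctc_singles=1,
            clones=[sim.CloneSpec(
                "A", None, 1.0, ctc_fraction=1.0, n_private_mutations=10,
                cn_events=[("chr1", 0, 500_000, 6)],
            )],
        )
        config = sim.SimConfig(patients=[scenario], reads_per_window=5000,
                               window_dispersion_bulk=500)
        truths, _ = sim.simulate_run(config, seed=6, outdir=tmp_path)
        truth = truths[0]
        import pandas as pd
        b = pd.read_csv(tmp_path / "samples" / "P1_BULK.windows.tsv", sep="\t")
        g = pd.read_csv(tmp_path / "samples" / "P1_GERM.windows.tsv", sep="\t")
        ratio = (b["count"] / b["count"].sum()) / (g["count"] / g["count"].sum())
        tau = truth.tumor_ploidy
        denom = rho * tau + 2 * (1 - rho)
        amp = (b["chrom"] == "chr1") & (b["end"] <= 500_000)
        assert ratio[amp].mean() == pytest.approx((rho * 6 + 1.4) / denom,
                                                  rel=0.02)
        assert ratio[~amp].mean() == pytest.approx((rho * 2 + 1.4) / denom,
                                                   rel=0.02)


class TestArtifacts:
    def test_zero_fp_rate_gives_no_artifacts(self, tiny_genome):
        wga = sim.WGAModel(fp_rate=0.0)
        rows = sim.inject_artifacts("S", wga, tiny_genome, sim.SimConfig(),
                                    np.random.default_rng(0), set())
        assert rows == []

    def test_wbc_and_ctc_artifact_loads_differ_by_order_of_magnitude(
        self, tiny_genome
    ):
        cfg = sim.SimConfig()
        rng = np.random.default_rng(1)
        n_ctc = len(sim.inject_artifacts("C", sim.WGAModel(fp_rate=800),
                                         tiny_genome, cfg, rng, set()))
        n_wbc = len(sim.inject_artifacts("W", sim.WGAModel(fp_rate=60),
                                         tiny_genome, cfg, rng, set()))
        assert n_ctc >= 10 * n_wbc > 0

    def test_disjoint_spectra_give_uncorrelated_context_histograms(
        self, tiny_genome
    ):
        from ctc_concord.io_core import MutationKey
        from ctc_concord.spectra import context_spectrum

        cfg = sim.SimConfig()
        spectra = sim.disjoint_artifact_spectra(2, np.random.default_rng(2))
        seqs = tiny_genome.sequences()
        cors = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            hists = []
            for spec in spectra:
                rows = sim.inject_artifacts(
                    "S", sim.WGAModel(fp_rate=800, artifact_spectrum=spec,
                                      kmer_artifact_fraction=0.0),
                    tiny_genome, cfg, rng, set())
                keys = [MutationKey(r["chrom"], r["pos"], r["ref"], r["alt"])
                        for r in rows]
                hists.append(context_spectrum(keys, seqs).counts)
            cors.append(stats.pearsonr(hists[0], hists[1]).statistic)
        assert max(cors) < 0.2

    def test_artifact_contexts_follow_requested_spectrum(self, tiny_genome):
        from ctc_concord.io_core import MutationKey
        from ctc_concord.spectra import context_spectrum

        spec = np.zeros(96)
        spec[[3, 40, 77]] = (0.5, 0.3, 0.2)
        rng = np.random.default_rng(3)
        rows = sim.inject_artifacts(
            "S", sim.WGAModel(fp_rate=600, artifact_spectrum=spec,
                              kmer_artifact_fraction=0.0),
            tiny_genome, sim.SimConfig(), rng, set())
        keys = [MutationKey(r["chrom"], r["pos"], r["ref"], r["alt"])
                for r in rows]
        observed = context_spectrum(keys, tiny_genome.sequences()).frequencies
        assert set(np.flatnonzero(observed)) <= {3, 40, 77}
        assert observed[[3, 40, 77]] == pytest.approx((0.5, 0.3, 0.2), abs=0.08)


class TestTruthTables:
    def test_every_call_traceable_to_one_truth_category(self, default_bundle):
        import pandas as pd

        truth = pd.read_csv(default_bundle["data_dir"] / "truth" / "mutations.tsv",
                            sep="\t")
        keyed = truth.set_index(["patient_id", "chrom", "pos", "ref", "alt"])
        assert keyed.index.is_unique
        assert set(truth["origin"]) == {"truncal", "subclonal", "artifact"}
        for truths in default_bundle["truths"]:
            sheet = pd.read_csv(
                default_bundle["data_dir"] / "samples" /
                f"{truths.samples[0].sample_id}.sites.tsv", sep="\t")
            merged = sheet.merge(
                truth[truth["patient_id"] == truths.patient_id],
                on=["chrom", "pos", "ref", "alt"], how="left")
            assert merged["origin"].notna().all()

    def test_infeasible_clone_tree_rejected(self, tmp_path):
        scenario = sim.PatientScenario(
            patient_id="P1", bulk_purity=0.3, n_ctc_singles=1,
            clones=[
                sim.CloneSpec("A", None, 1.0, ctc_fraction=1.0,
                              n_private_mutations=5),
                sim.CloneSpec("B", "A", 1.2, n_private_mutations=5),
            ],
        )
        with pytest.raises(ValidationError, match="exceeds"):
            sim.simulate_run(sim.SimConfig(patients=[scenario]), 0, tmp_path)


def _read_sites(outdir, sample_id):
    import pandas as pd

    return pd.read_csv(outdir / "samples" / f"{sample_id}.sites.tsv", sep="\t")
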