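import numpy as np
import pytest

from mutevo.signatures import build_spectrum, bundled_signatures
from mutevo.synthetic import (
    PRESETS,
    Reference,
    SimConfig,
    SimError,
    make_reference,
    preset,
    simulate_counts,
    simulate_depth_profile,
    simulate_expression,
    simulate_timecourse,
)
from mutevo.variants import FilterConfig, apply_filters, subtract


class TestSimConfig:
    def test_bad_process_rejected(self):
        with pytest.raises(SimError):
            SimConfig(process="XXX")

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(SimError):
            SimConfig(signature_weights={"SYN_FLAT": 0.5})

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(SimError):
            SimConfig(depth_mean=0.0)

    def test_fractional_cn_rejected(self):
        with pytest.raises(SimError):
            SimConfig(ploidy_profile=((10, 1.5),))

    def test_presets_construct(self):
        for name in PRESETS:
            assert preset(name, seed=0).seed == 0


class TestMakeReference:
    def test_same_seed_identical(self):
        cfg = SimConfig(seed=5, n_genes=10)
        r1, r2 = make_reference(cfg), make_reference(cfg)
        assert r1.genome == r2.genome
        assert r1.gene_model.equals(r2.gene_model)

    def test_different_seed_differs(self):
        a = make_reference(SimConfig(seed=1, n_genes=10)).genome
        b = make_reference(SimConfig(seed=2, n_genes=10)).genome
        assert a != b

    def test_transcript_count_and_frame(self):
        ref = make_reference(SimConfig(seed=0, n_genes=20))
        assert len(ref.transcripts) == 20
        for tx in ref.transcripts.values():
            assert (tx.cds_end - tx.cds_start + 1) % 3 == 0
            assert tx.cdna.startswith("ATG")
            assert "*" not in tx.protein

    def test_gene_model_matches_genome(self):
        ref = make_reference(SimConfig(seed=0, n_genes=12))
        for row in ref.gene_model.itertuples():
            seq = ref.genome[row.chrom][row.start - 1 : row.end]
            assert seq == ref.transcripts[row.transcript].cdna

    def test_mmrd_genes_carry_homopolymers(self):
        ref = make_reference(SimConfig(seed=0, n_genes=15, process="MMRd"))
        for tx in ref.transcripts.values():
            assert any(
                base * 6 in tx.cdna for base in "ACGT"
            ), f"no homopolymer in {tx.id}"


class TestSimulateTimecourse:
    def test_zero_rates_static(self):
        cfg = SimConfig(seed=3, snv_rate=0.0, indel_rate=0.0, lost_fraction=0.0)
        course = simulate_timecourse(cfg, make_reference(cfg))
        assert course.catalogs["T0"].keys() == course.catalogs["T90"].keys()
        assert course.gained_truth["T90"] == 0

    def test_mmrd_indel_rich(self):
        cfg = preset("msi", seed=7)
        ref = make_reference(cfg)
        course = simulate_timecourse(cfg, ref)
        res = subtract(course.catalogs["T90"], course.catalogs["T0"])
        n_snv = sum(1 for v in res.gained if v.vclass == "SNV")
        n_indel = len(res.gained) - n_snv
        total_rate = (cfg.snv_rate + cfg.indel_rate) * 90
        assert abs(len(res.gained) - total_rate) < 3 * np.sqrt(total_rate) + 40
        assert n_indel > n_snv  # MMR-deficient: indels dominate

    def test_pole_snv_rich(self):
        cfg = preset("pole", seed=11)
        course = simulate_timecourse(cfg, make_reference(cfg))
        res = subtract(course.catalogs["T90"], course.catalogs["T0"])
        n_snv = sum(1 for v in res.gained if v.vclass == "SNV")
        n_indel = len(res.gained) - n_snv
        assert n_snv > 5 * max(n_indel, 1)

    def test_lineage_walk(self):
        cfg = preset("pdx", seed=2)
        course = simulate_timecourse(cfg, make_reference(cfg))
        assert set(course.catalogs) == {"F1", "F2", "F3", "F4"}
        assert course.parents["F2"] == "F1"
        tree = course.tree()
        tree.validate()

    def test_deterministic(self):
        cfg = preset("msi", seed=9)
        ref = make_reference(cfg)
        a = simulate_timecourse(cfg, ref)
        b = simulate_timecourse(cfg, ref)
        assert a.catalogs["T90"].keys() == b.catalogs["T90"].keys()

    def test_signature_mixture_round_trip(self):
        # spectra of simulated catalogs refit close to the generating mixture
        cfg = preset("pole", seed=4, n_genes=60)
        ref = make_reference(cfg)
        course = simulate_timecourse(cfg, ref)
        res = subtract(course.catalogs["T90"], course.catalogs["T0"])
        spec = build_spectrum(res.gained, ref.genome)
        assert spec.total >= 1000
        matrix = bundled_signatures()
        from mutevo.signatures import fit_exposures

        exp = fit_exposures(spec, matrix)
        norm = dict(zip(exp.names, exp.normalized))
        target = cfg.signature_weights
        # cosine similarity between fitted and generating weight vectors
        v1 = np.array([norm.get(n, 0.0) for n in matrix.names])
        v2 = np.array([target.get(n, 0.0) for n in matrix.names])
        cosine = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        assert cosine >= 0.95


class TestSimulateCounts:
    def test_mean_af_matches_truth(self):
        cfg = SimConfig(seed=6, n_genes=40, depth_mean=200.0, snv_rate=6.0, n_initial=500)
        ref = make_reference(cfg)
        course = simulate_timecourse(cfg, ref)
        cat = course.catalogs["T0"]
        af_true = {k: 0.5 for k in course.af_true["T0"]}
        obs = simulate_counts(cat, cfg, af_true, ref=ref)
        afs = [v.af for v in obs]
        assert np.mean(afs) == pytest.approx(0.5, abs=0.02)

    def test_artifacts_removed_by_filters(self):
        cfg = SimConfig(seed=8, n_genes=40, n_artifacts=200, n_initial=50)
        ref = make_reference(cfg)
        course = simulate_timecourse(cfg, ref)
        obs = simulate_counts(
            course.catalogs["T0"], cfg, course.af_true["T0"], ref=ref
        )
        true_keys = set(course.af_true["T0"])
        artifact_keys = obs.keys() - true_keys
        assert len(artifact_keys) == 200
        kept = apply_filters(obs, FilterConfig()).keys()
        surviving = kept & artifact_keys
        assert len(surviving) <= 0.05 * len(artifact_keys)

    def test_strand_counts_consistent(self):
        cfg = SimConfig(seed=2, n_initial=100)
        ref = make_reference(cfg)
        course = simulate_timecourse(cfg, ref)
        obs = simulate_counts(course.catalogs["T0"], cfg, course.af_true["T0"])
        for v in obs:
            assert v.alt_fwd + v.alt_rev <= v.alt_count
            assert v.alt_count <= v.depth


class TestSimulateDepthProfile:
    def test_all_diploid(self):
        cfg = SimConfig(seed=1, n_genes=30)
        ref = make_reference(cfg)
        truth = simulate_depth_profile(cfg, ref)
        from mutevo.ploidy import DepthProfile, relative_gcn

        table = relative_gcn(DepthProfile(truth.profile))
        assert np.allclose(table["relative_gcn"], 2.0, atol=0.4)

    def test_cn3_arc_bimodal(self):
        cfg = SimConfig(seed=3, n_genes=30, ploidy_profile=((30, 3),), het_per_gene=30)
        ref = make_reference(cfg)
        truth = simulate_depth_profile(cfg, ref)
        afs = [a for g in truth.afs_by_gene.values() for a in g]
        from mutevo.ploidy import af_density, density_modes

        grid, dens = af_density(afs)
        modes = sorted(density_modes(grid, dens))
        assert abs(modes[0] - 1 / 3) < 0.05 and abs(modes[-1] - 2 / 3) < 0.05

    def test_truth_segments_cover_all_ordinals(self):
        cfg = SimConfig(seed=4, n_genes=40, ploidy_profile=((10, 3), (5, 1)))
        ref = make_reference(cfg)
        truth = simulate_depth_profile(cfg, ref)
        covered = set()
        for _, start, end, _cn in truth.segments:
            covered |= set(range(start, end + 1))
        assert covered == set(truth.cn_by_ordinal)


class TestSimulateExpression:
    def test_deterministic(self):
        cfg = SimConfig(seed=5)
        ref = make_reference(cfg)
        a = simulate_expression(ref, cfg)
        b = simulate_expression(ref, cfg)
        assert a.equals(b)

    def test_low_expression_fraction(self):
        cfg = SimConfig(seed=5, n_genes=50, low_expression_fraction=0.3)
        ref = make_reference(cfg)
        table = simulate_expression(ref, cfg)
        assert (table["fpkm"] >= 0).all()
        assert (table["fpkm"] < 10).sum() >= 15


class TestEndToEndRecovery:
    @pytest.mark.parametrize("name,expect", [("mss", "STABLE"), ("msi", "EVOLVING")])
    def test_preset_classification(self, name, expect):
        from mutevo.evolvability import classify, mutation_rate

        cfg = preset(name, seed=0)
        ref = make_reference(cfg)
        course = simulate_timecourse(cfg, ref)
        rng = cfg.streams()["counts"]
        obs = {
            node: simulate_counts(course.catalogs[node], cfg, course.af_true[node], rng, ref)
            for node in course.catalogs
        }
        fcfg = FilterConfig()
        filtered = {node: apply_filters(cat, fcfg) for node, cat in obs.items()}
        res = subtract(filtered["T90"], filtered["T0"])
        rate = mutation_rate(len(res.gained), 90.0)
        assert classify(rate) == expect
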