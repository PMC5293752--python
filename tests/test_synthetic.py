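"""Tests of the synthetic-data generator: determinism, geometric
constraints of the fabricated annotation, and exact recoverability of
everything that was planted."""

import numpy as np
import pandas as pd
import pytest

from melroot import io as mio
from melroot import motifscan as ms
from melroot import phenotype as ph
from melroot import quantify as q
from melroot import synthetic as syn


class TestAnnotation:
    def test_genes_nonoverlapping_with_clear_upstream(self):
        spec = syn.SimulationSpec(n_genes=10, chrom_length=100_000, seed=3)
        genome, ann = syn.generate_annotation(spec)
        assert len(ann) == 10
        assert len(genome["chr1"]) == 100_000
        intervals = sorted(zip(ann["start"], ann["end"]))
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 < s2, "gene bodies overlap"
        # every promoter window stays on the contig and clear of gene bodies
        proms = ms.promoter_intervals(ann, spec.promoter_length)
        assert (proms["start"] >= 0).all()
        assert (proms["end"] <= 100_000).all()
        bodies = [(s - 1, e) for s, e in intervals]  # 0-based half-open
        for row in proms.itertuples():
            for bs, be in bodies:
                assert row.end <= bs or row.start >= be, "promoter overlaps a gene body"

    def test_empty_universe_is_valid(self):
        genome, ann = syn.generate_annotation(
            syn.SimulationSpec(n_genes=0, chrom_length=5_000, seed=0)
        )
        assert ann.empty
        assert len(genome["chr1"]) == 5_000

    def test_infeasible_packing_names_deficit(self):
        spec = syn.SimulationSpec(n_genes=50, chrom_length=10_000, seed=0)
        with pytest.raises(ValueError, match=r"\d+ bp short"):
            syn.generate_annotation(spec)

    def test_same_seed_byte_identical_outputs(self, small_spec, tmp_path):
        outs = []
        for run in ("a", "b"):
            genome, ann = syn.generate_annotation(small_spec)
            counts, _ = syn.generate_counts(ann, small_spec)
            fa, gff = tmp_path / f"{run}.fa", tmp_path / f"{run}.gff3"
            mio.write_fasta(genome, fa)
            mio.write_gff3(ann, gff)
            outs.append((fa.read_bytes(), gff.read_bytes(), counts.to_csv()))
        assert outs[0] == outs[1]


class TestPlantMotifs:
    def test_planted_carriers_rescan_exactly(self):
        spec = syn.SimulationSpec(n_genes=51, chrom_length=400_000, seed=11)
        genome, ann = syn.generate_annotation(spec)
        genes = tuple(ann["gene_id"])
        plan = syn.MotifPlan("rse", "ATATT", genes, n_carriers=46)
        genome, carriers = syn.plant_motifs(genome, ann, [plan], seed=5)
        assert len(carriers["rse"]) == 46
        promoters = ms.extract_promoters(genome, ann)
        table = ms.carrier_table(promoters, {"rse": "ATATT"})
        found = set(table.index[table["rse"]])
        assert found == set(carriers["rse"])

    def test_zero_fraction_gives_zero_carriers(self):
        spec = syn.SimulationSpec(n_genes=12, chrom_length=120_000, seed=2)
        genome, ann = syn.generate_annotation(spec)
        genome, carriers = syn.plant_motifs(
            genome, ann, [syn.MotifPlan("m", "ATATT", None, 0.0)], seed=1
        )
        assert carriers["m"] == frozenset()
        table = ms.carrier_table(ms.extract_promoters(genome, ann), {"m": "ATATT"})
        assert not table["m"].any()

    def test_minus_strand_carrier_found_strand_aware(self):
        spec = syn.SimulationSpec(n_genes=30, chrom_length=250_000, seed=4)
        genome, ann = syn.generate_annotation(spec)
        minus = tuple(ann.loc[ann["strand"] == "-", "gene_id"])
        assert minus, "seed produced no minus-strand genes"
        genome, carriers = syn.plant_motifs(
            genome, ann, [syn.MotifPlan("m2", "TACACAT", minus, 1.0)], seed=9
        )
        assert carriers["m2"] == frozenset(minus)
        table = ms.carrier_table(ms.extract_promoters(genome, ann), {"m2": "TACACAT"})
        found = set(table.index[table["m2"]])
        # every planted minus-strand carrier is recovered strand-aware;
        # untouched plus-strand promoters may hit by chance in random sequence
        assert set(minus) <= found

    def test_motif_longer_than_promoter_errors(self):
        spec = syn.SimulationSpec(n_genes=3, chrom_length=10_000, promoter_length=4, seed=0)
        genome, ann = syn.generate_annotation(spec)
        with pytest.raises(ValueError, match="longer than promoter"):
            syn.plant_motifs(
                genome, ann, [syn.MotifPlan("m", "ATATT", None, 1.0)],
                seed=0, promoter_length=4,
            )


class TestCounts:
    def test_planted_effect_gives_expected_fpkm_ratio(self):
        """Monte-Carlo mean of the FPKM ratio for a +2 log2 effect is
        near 4 (slightly below, from library-composition renormalization)."""
        ratios = []
        for seed in range(30):
            spec = syn.SimulationSpec(
                n_genes=500, chrom_length=3_000_000, seed=seed,
                de_spec=(syn.DEPattern(5, "up", 2.0, ("M10",)),),
            )
            _, ann = syn.generate_annotation(spec)
            counts, truth = syn.generate_counts(ann, spec)
            fpkm = q.compute_fpkm(counts, ann.set_index("gene_id")["length"])
            up = sorted(truth.de_up["M0-vs-M10"])
            ratios.append(float((fpkm.loc[up, "M10"] / fpkm.loc[up, "M0"]).mean()))
        assert 3.5 < np.mean(ratios) < 4.5

    def test_column_sums_near_library_size(self, small_spec):
        """Column sums land within ~4 sd of the nominal depth, where the
        sd follows from the NB variance mu + phi*mu^2 summed over genes."""
        _, ann = syn.generate_annotation(small_spec)
        counts, _ = syn.generate_counts(ann, small_spec)
        phi = small_spec.nb_dispersion
        for col in counts:
            c = counts[col].to_numpy(float)
            sd = np.sqrt((c + phi * c**2).sum())
            assert abs(c.sum() - 10_000_000) < 4 * sd

    def test_null_false_positive_rate_low_at_high_mean(self):
        fp = total = 0
        for seed in range(5):
            spec = syn.SimulationSpec(n_genes=400, chrom_length=2_400_000, seed=seed)
            _, ann = syn.generate_annotation(spec)
            counts, truth = syn.generate_counts(ann, spec)
            fpkm = q.compute_fpkm(counts, ann.set_index("gene_id")["length"])
            calls = q.call_degs(fpkm, "M10", "M0")
            high = [g for g, m in truth.baseline_means.items() if m >= 500]
            fp += int((calls.loc[high, "direction"] != "none").sum())
            total += len(high)
        assert fp / total < 0.05

    def test_planted_de_baseline_means_clear_floor(self, study_ds):
        """DE-planted genes sit at baseline means >= 500 counts, where the
        fold-change rule is reliable (cluster genes are exempt: their
        prototype shape may legitimately dip in the control condition)."""
        truth = study_ds.truth
        de_genes = set().union(*truth.de_up.values(), *truth.de_down.values())
        assert min(truth.baseline_means[g] for g in de_genes) >= 500


class TestQpcrGenerator:
    def test_noiseless_table_inverts_exactly(self):
        true = pd.DataFrame(
            {"M0": [0.0, 0.0], "M10": [2.0, -1.5], "M20": [0.0, 3.25]},
            index=["geneA", "geneB"],
        )
        table = syn.generate_qpcr(true, noise_sd=0.0, seed=1)
        rel = ph.relative_expression(table, control="M0")
        pivot = rel.pivot(index="gene_id", columns="condition", values="log2_ratio")
        assert np.allclose(pivot.loc[true.index, true.columns], true)

    def test_zero_true_ratio_gives_zero_ddct(self):
        true = pd.DataFrame({"M0": [0.0], "M10": [0.0]}, index=["g"])
        rel = ph.relative_expression(syn.generate_qpcr(true, 0.0, seed=0), control="M0")
        assert rel["log2_ratio"].abs().max() == 0.0

    def test_replicate_floor_enforced(self):
        true = pd.DataFrame({"M0": [0.0]}, index=["g"])
        with pytest.raises(ValueError, match="replicates"):
            syn.generate_qpcr(true, 0.1, replicates=1, seed=0)

    def test_noisy_recovery_slope_near_one(self, rng):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            local = np.random.default_rng(seed)
            true = pd.DataFrame(
                {"M0": 0.0, "M10": local.uniform(-3, 3, 40)},
                index=[f"g{i}" for i in range(40)],
            )
            table = syn.generate_qpcr(true, noise_sd=0.2, seed=seed)
            rel = ph.relative_expression(table, control="M0")
            est = rel[rel["condition"] == "M10"].set_index("gene_id")["log2_ratio"]
            fit = ph.concordance_regression(true["M10"], est[true.index])
            hits += abs(fit.slope - 1) < 0.1
        assert hits >= 0.95 * n_seeds


class TestGravitropism:
    def test_mean_recovery(self):
        within = 0
        for seed in range(20):
            table = syn.generate_gravitropism({"M0": 55.9}, sd=10, n=30, seed=seed)
            within += abs(table["angle"].mean() - 55.9) <= 4
        assert within >= 19

    def test_zero_sd_gives_constant_angles(self):
        table = syn.generate_gravitropism({"M10": 71.9}, sd=0, n=5, seed=0)
        assert (table["angle"] == 71.9).all()

    def test_empty_population(self):
        assert syn.generate_gravitropism({"M0": 50.0}, sd=5, n=0, seed=0).empty

    def test_angles_clipped_to_physical_range(self):
        table = syn.generate_gravitropism({"M50": 85.0}, sd=30, n=200, seed=1)
        assert table["angle"].between(0, 90).all()


def test_go_map_flattening():
    plans = (
        syn.GOPlan("GO:1", ("g1", "g2"), enriched=True),
        syn.GOPlan("GO:2", ("g2",)),
    )
    df, enriched = syn.generate_go_map(plans)
    assert enriched == {"GO:1"}
    assert set(map(tuple, df.values)) == {("g1", "GO:1"), ("g2", "GO:1"), ("g2", "GO:2")}


def test_spec_validation_rejects_bad_inputs():
    with pytest.raises(ValueError):
        syn.SimulationSpec(nb_dispersion=0.0)
    with pytest.raises(ValueError):
        syn.MotifPlan("m", "ATAQT", None, 0.5)
    with pytest.raises(ValueError):
        syn.MotifPlan("m", "ATATT", None, 1.5)
    with pytest.raises(ValueError):
        syn.DEPattern(5, "sideways", 1.0)
    with pytest.raises(ValueError):
        syn.SimulationSpec(n_genes=10, de_spec=(syn.DEPattern(11, "up", 1.0),))


def test_dataset_write_roundtrip(tmp_path, small_spec):
    ds = syn.simulate(small_spec)
    ds.write(tmp_path)
    genome = mio.read_fasta(tmp_path / "genome.fa")
    ann = mio.read_gff3(tmp_path / "genes.gff3")
    counts = mio.read_counts(tmp_path / "counts.tsv")
    assert genome["chr1"] == ds.genome["chr1"]
    pd.testing.assert_frame_equal(
        ann.sort_values("gene_id", ignore_index=True),
        ds.annotation.sort_values("gene_id", ignore_index=True),
    )
    pd.testing.assert_frame_equal(counts, ds.counts)
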