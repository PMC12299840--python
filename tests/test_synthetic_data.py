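import numpy as np
import pytest

from ghx.linker_features import scan_sequons
from ghx.synthetic_data import (
    GeneratorConfig,
    generate_dataset,
    generate_saccharification_table,
    generate_tree,
    make_reference,
)
from ghx.tree_congruence import mixing_index, read_newick
from ghx.wetlab_metrics import SugarMeasurement, glucan_conversion


class TestMakeReference:
    def test_reference_contains_single_fsnik_and_qcgg(self):
        ref, model = make_reference(GeneratorConfig(seed=2))
        assert ref.sequence.count("FSNIK") == 1
        assert ref.sequence.count("QCGG") == 1

    def test_deterministic_for_seed(self):
        r1, _ = make_reference(GeneratorConfig(seed=3))
        r2, _ = make_reference(GeneratorConfig(seed=3))
        r3, _ = make_reference(GeneratorConfig(seed=4))
        assert r1.sequence == r2.sequence
        assert r1.sequence != r3.sequence

    def test_loop_windows_inside_catalytic_stub(self):
        cfg = GeneratorConfig(seed=2)
        _, model = make_reference(cfg)
        for w in model.loop_windows:
            assert 0 <= w.start < w.end <= cfg.catalytic_len

    def test_too_short_stub_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            GeneratorConfig(catalytic_len=40)


class TestGenerateDataset:
    def test_record_and_truth_counts(self):
        ds = generate_dataset(GeneratorConfig(n_class_a=10, n_class_b=8, seed=6))
        assert len(ds.records) == 18 == len(ds.truths)
        assert len(ds.labels) == 18

    def test_class_sizes_in_labels(self, small_dataset):
        counts = {}
        for lab in small_dataset.labels.labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        assert counts == {"Sordariomycetes": 20, "Eurotiomycetes": 20}

    def test_sample_linker_lengths_near_planted_means(self):
        cfg = GeneratorConfig(n_class_a=98, n_class_b=96, seed=7)
        ds = generate_dataset(cfg)
        by_class = {cfg.class_a_name: [], cfg.class_b_name: []}
        for t in ds.truths:
            by_class[t.class_label].append(len(t.linker_span))
        # CLT: SD 4, n ~ 100 -> sample mean within 1.5 of planted
        assert abs(np.mean(by_class[cfg.class_a_name]) - cfg.linker_mean_a) < 1.5
        assert abs(np.mean(by_class[cfg.class_b_name]) - cfg.linker_mean_b) < 1.5

    def test_truths_partition_each_sequence(self, decoy_dataset):
        for rec, t in zip(decoy_dataset.records, decoy_dataset.truths):
            assert t.catalytic_span.start == 0
            assert t.catalytic_span.end == t.linker_span.start
            if t.cbm1_span is not None:
                assert t.linker_span.end == t.cbm1_span.start
                assert t.cbm1_span.end == len(rec.sequence)
            else:  # QCGG-less decoy: the C-terminal domain region still exists
                assert t.linker_span.end < len(rec.sequence)

    def test_planted_sequons_are_exactly_the_scanned_ones(self, small_dataset):
        for rec, t in zip(small_dataset.records, small_dataset.truths):
            linker = rec.sequence[t.linker_span.start : t.linker_span.end]
            calls = scan_sequons(linker)
            assert [c.position for c in calls] == t.sequon_positions
            assert [c.x_residue for c in calls] == t.sequon_x

    def test_x_pro_fraction_near_default(self):
        ds = generate_dataset(GeneratorConfig(n_class_a=150, n_class_b=150, seed=8))
        xs = [x for t in ds.truths for x in t.sequon_x]
        frac = sum(x == "P" for x in xs) / len(xs)
        assert abs(frac - 283.0 / 297.0) < 0.05

    def test_decoys_marked_in_truth(self, decoy_dataset):
        by_type = {}
        for t in decoy_dataset.truths:
            by_type.setdefault(t.decoy_type, []).append(t)
        assert len(by_type[None]) == 50
        for d in ("no_qcgg", "loop_deleted", "truncated"):
            assert len(by_type[d]) == 5
            assert all(not t.passes_filters for t in by_type[d])
        assert all("QCGG" not in r.sequence
                   for r, t in zip(decoy_dataset.records, decoy_dataset.truths)
                   if t.decoy_type == "no_qcgg")

    def test_determinism_bit_identical(self):
        cfg = GeneratorConfig(n_class_a=5, n_class_b=5, seed=9, decoy_frac_no_qcgg=0.2)
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        assert [(r.id, r.sequence) for r in d1.records] == [
            (r.id, r.sequence) for r in d2.records
        ]

    def test_empirical_frequencies_converge_to_planted(self):
        # sequon planting disabled to isolate the composition machinery
        cfg = GeneratorConfig(n_class_a=700, n_class_b=0, seed=10, sequon_rate=0.0)
        ds = generate_dataset(cfg)
        residues = "".join(
            r.sequence[t.linker_span.start : t.linker_span.end]
            for r, t in zip(ds.records, ds.truths)
        )
        assert len(residues) >= 19_000
        for aa, planted in cfg.linker_freqs_a.items():
            observed = residues.count(aa) / len(residues)
            assert abs(observed - planted) <= 0.03, aa


class TestGenerateTree:
    LABELS = {f"a{i}": "A" for i in range(12)} | {f"b{i}": "B" for i in range(12)}

    def test_monophyletic_at_zero_mixing(self):
        nwk = generate_tree(self.LABELS, 0.0, seed=1)
        steps, idx = mixing_index(read_newick(nwk, self.LABELS))
        assert steps == 1 and idx == 0.0

    def test_full_mixing_interleaves(self):
        hits = 0
        for seed in range(30):
            nwk = generate_tree(self.LABELS, 1.0, seed=seed)
            _, idx = mixing_index(read_newick(nwk, self.LABELS))
            hits += idx > 0.3
        assert hits >= 27

    def test_same_seed_same_newick(self):
        assert generate_tree(self.LABELS, 0.5, 3) == generate_tree(self.LABELS, 0.5, 3)

    def test_supports_in_range(self):
        nwk = generate_tree(self.LABELS, 0.2, seed=2)
        t = read_newick(nwk, self.LABELS)
        vals = t.supports()
        assert vals and all(0 <= v <= 100 for v in vals)

    def test_invalid_mixing_rejected(self):
        with pytest.raises(ValueError, match="mixing"):
            generate_tree(self.LABELS, 1.5, seed=1)


class TestSaccharificationTable:
    def test_conversions_reproduce_planted_truth(self):
        df, truth = generate_saccharification_table(seed=5)
        for row in df.itertuples():
            got = glucan_conversion(SugarMeasurement(
                row.glucose_gL, row.cellobiose_gL, row.glucan_gL, row.time_h
            ))
            assert got == pytest.approx(truth[(row.sample, row.time_h)], abs=1e-9)

    def test_zero_sugar_rows_have_zero_conversion(self):
        df, truth = generate_saccharification_table(seed=5)
        t0 = df[df.time_h == 0.0]
        assert (t0.glucose_gL == 0).all() and (t0.cellobiose_gL == 0).all()
        assert all(truth[(s, 0.0)] == 0.0 for s in t0["sample"])

    def test_time_courses_monotone(self):
        df, _ = generate_saccharification_table(seed=6)
        for _, grp in df.groupby("sample"):
            g = grp.sort_values("time_h")
            assert (np.diff(g.glucose_gL) >= -1e-12).all()

    def test_deterministic(self):
        d1, t1 = generate_saccharification_table(seed=7)
        d2, t2 = generate_saccharification_table(seed=7)
        assert d1.equals(d2) and t1 == t2
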