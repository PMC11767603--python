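"""Benchmark loading, Kd binarization, balancing and pair-file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcfdti.davis import (
    DatasetSummary,
    InteractionRecord,
    balance_by_downsampling,
    binarize,
    deduplicate,
    load_davis,
    load_davis_files,
    read_pairs_tsv,
    write_pairs_tsv,
)


def _grid(n_drugs=2, n_targets=3):
    ligands = {f"D{i}": "CCO" + "C" * i for i in range(n_drugs)}
    proteins = {f"T{j}": "MKVL" + "A" * j for j in range(n_targets)}
    return ligands, proteins


class TestLoadDavis:
    def test_dense_matrix_yields_one_record_per_cell(self):
        ligands, proteins = _grid()
        records = load_davis(ligands, proteins, np.full((2, 3), 50.0))
        assert len(records) == 6
        assert records[0].drug_id == "D0" and records[0].target_id == "T0"

    def test_pkd_converts_to_nanomolar(self):
        ligands, proteins = _grid(1, 1)
        records = load_davis(ligands, proteins, np.array([[7.0]]),
                             value_scale="pKd")
        assert records[0].kd_nM == pytest.approx(100.0)

    def test_missing_cells_are_skipped(self):
        ligands, proteins = _grid()
        matrix = np.full((2, 3), 50.0)
        matrix[1, 2] = np.nan
        records = load_davis(ligands, proteins, matrix)
        assert len(records) == 5
        assert ("D1", "T2") not in {(r.drug_id, r.target_id) for r in records}

    def test_dimension_mismatch_rejected(self):
        ligands, proteins = _grid()
        with pytest.raises(ValueError, match="expected"):
            load_davis(ligands, proteins, np.zeros((3, 2)))

    def test_non_positive_kd_rejected(self):
        ligands, proteins = _grid(1, 1)
        with pytest.raises(ValueError, match="positive"):
            load_davis(ligands, proteins, np.array([[0.0]]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 10))
    def test_record_count_equals_non_missing_cells(self, nd, nt, n_missing):
        ligands, proteins = _grid(nd, nt)
        rng = np.random.default_rng(nd * 7 + nt)
        matrix = rng.uniform(1.0, 1000.0, size=(nd, nt))
        flat = rng.choice(nd * nt, size=min(n_missing, nd * nt), replace=False)
        matrix.reshape(-1)[flat] = np.nan
        records = load_davis(ligands, proteins, matrix)
        assert len(records) == np.isfinite(matrix).sum()


class TestBinarize:
    @pytest.mark.parametrize("kd,label", [(29.9, 1), (30.0, 0), (10000.0, 0),
                                          (1.0, 1)])
    def test_strict_threshold_at_30_nM(self, kd, label):
        rec = InteractionRecord("D", "CC", "T", "MK", kd_nM=kd)
        assert binarize(rec).label == label

    def test_missing_kd_rejected(self):
        rec = InteractionRecord("D", "CC", "T", "MK", label=1)
        with pytest.raises(ValueError, match="no kd_nM"):
            binarize(rec)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(1.0, 100.0), st.floats(1.0, 100.0))
    def test_raising_threshold_never_loses_positives(self, t1, t2):
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(3)
        records = [InteractionRecord(f"D{i}", "C", f"T{i}", "M",
                                     kd_nM=float(k))
                   for i, k in enumerate(rng.uniform(0.5, 200.0, size=50))]
        n_lo = sum(binarize(r, lo).label for r in records)
        n_hi = sum(binarize(r, hi).label for r in records)
        assert n_hi >= n_lo


class TestBalance:
    def _records(self, n_pos, n_neg):
        out = []
        for i in range(n_pos):
            out.append(InteractionRecord(f"D{i}", "C", "Tp", "M", label=1))
        for i in range(n_neg):
            out.append(InteractionRecord(f"D{i}", "C", "Tn", "M", label=0))
        return out

    def test_keeps_all_positives_and_equal_negatives(self):
        balanced, summary = balance_by_downsampling(self._records(3, 10), seed=0)
        assert summary.n_positive == summary.n_negative == 3
        assert summary.n_records == 6
        pairs = [(r.drug_id, r.target_id) for r in balanced]
        assert len(set(pairs)) == len(pairs)

    def test_seeded_sampling_is_reproducible(self):
        records = self._records(5, 40)
        b1, _ = balance_by_downsampling(records, seed=11)
        b2, _ = balance_by_downsampling(records, seed=11)
        b3, _ = balance_by_downsampling(records, seed=12)
        key = lambda recs: [(r.drug_id, r.target_id) for r in recs]
        assert key(b1) == key(b2)
        assert key(b1) != key(b3)

    def test_full_protocol_size(self):
        # 1506 positives + 1506 sampled negatives -> 3012 balanced records
        balanced, summary = balance_by_downsampling(
            self._records(1506, 2000), seed=0)
        assert len(balanced) == 3012
        assert summary.n_positive == summary.n_negative == 1506

    def test_insufficient_negatives_rejected(self):
        with pytest.raises(ValueError, match="cannot balance"):
            balance_by_downsampling(self._records(5, 3), seed=0)

    def test_duplicates_resolved_first_occurrence_wins(self):
        records = [InteractionRecord("D0", "C", "T0", "M", label=1),
                   InteractionRecord("D0", "CC", "T0", "M", label=0),
                   InteractionRecord("D1", "C", "T0", "M", label=0)]
        unique = deduplicate(records)
        assert len(unique) == 2
        assert unique[0].smiles == "C"


class TestPairsTsv:
    def _records(self):
        return [InteractionRecord(f"D{i}", f"CC{'O' * i}", f"T{i}",
                                  "MKVL" * (i + 1), kd_nM=10.0 * (i + 1),
                                  label=i % 2)
                for i in range(5)]

    def test_round_trip_preserves_records(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        records = self._records()
        write_pairs_tsv(records, path)
        assert read_pairs_tsv(path) == records

    def test_empty_smiles_reported_with_line_number(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("drug_id\tsmiles\ttarget_id\tsequence\tlabel\n"
                        "D0\tCC\tT0\tMKVL\t1\nD1\t\tT1\tMKVL\t0\n")
        with pytest.raises(ValueError, match="line 3"):
            read_pairs_tsv(path)

    def test_label_only_file_is_valid(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("drug_id\tsmiles\ttarget_id\tsequence\tlabel\n"
                        "D0\tCC\tT0\tMKVL\t1\n")
        records = read_pairs_tsv(path)
        assert records[0].label == 1 and records[0].kd_nM is None

    def test_missing_mandatory_column_rejected(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("drug_id\tsmiles\tsequence\nD0\tCC\tMKVL\n")
        with pytest.raises(ValueError, match="target_id"):
            read_pairs_tsv(path)


class TestDavisFiles:
    def test_text_dialect_round_trip(self, tmp_path):
        ligands, proteins = _grid()
        matrix = np.array([[10.0, np.nan, 45.0], [5.0, 400.0, 29.0]])
        import json
        (tmp_path / "ligands.json").write_text(json.dumps(ligands))
        (tmp_path / "proteins.json").write_text(json.dumps(proteins))
        (tmp_path / "Y.txt").write_text(
            "\n".join("\t".join(str(v) for v in row) for row in matrix))
        records = load_davis_files(tmp_path / "ligands.json",
                                   tmp_path / "proteins.json",
                                   tmp_path / "Y.txt")
        assert len(records) == 5
        labels = [binarize(r).label for r in records]
        assert labels == [1, 0, 1, 0, 1]  # 10, 45, 5, 400, 29 nM

    def test_unparseable_matrix_reported(self, tmp_path):
        import json
        ligands, proteins = _grid(1, 1)
        (tmp_path / "ligands.json").write_text(json.dumps(ligands))
        (tmp_path / "proteins.json").write_text(json.dumps(proteins))
        (tmp_path / "Y.txt").write_text("abc\n")
        with pytest.raises(ValueError, match="unparseable"):
            load_davis_files(tmp_path / "ligands.json",
                             tmp_path / "proteins.json", tmp_path / "Y.txt")


def test_summary_counts_are_consistent():
    records = [InteractionRecord("D0", "C", "T0", "M", label=1),
               InteractionRecord("D0", "C", "T1", "M", label=0),
               InteractionRecord("D1", "C", "T0", "M", label=0)]
    s = DatasetSummary.from_records(records)
    assert (s.n_drugs, s.n_targets, s.n_records) == (2, 2, 3)
    assert s.n_positive + s.n_negative == s.n_records
    assert s.n_records <= s.n_drugs * s.n_targets
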