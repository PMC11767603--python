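"""Davis-style benchmark loading and training-set construction.

The Davis kinase benchmark distributes a keyed collection of ligand SMILES, a
keyed collection of protein sequences, and a dense drug × target affinity
matrix (Kd in nM, possibly with missing entries; some public copies store pKd
instead, so the caller declares the scale). Training-set construction follows
the standard protocol: binarize at Kd < 30 nM (strict) for positives, enforce
pair uniqueness, keep every positive and down-sample an equal number of
negatives uniformly at random.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

KD_POSITIVE_THRESHOLD_NM = 30.0


@dataclass
class InteractionRecord:
    """One drug–target pair with identifiers, raw sequences and affinity/label."""

    drug_id: str
    smiles: str
    target_id: str
    sequence: str
    kd_nM: float | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        if self.kd_nM is None and self.label is None:
            raise ValueError(
                f"record ({self.drug_id}, {self.target_id}) needs kd_nM or label")
        if self.kd_nM is not None and self.kd_nM <= 0:
            raise ValueError(
                f"Kd must be positive, got {self.kd_nM} for "
                f"({self.drug_id}, {self.target_id})")


@dataclass
class DatasetSummary:
    n_drugs: int
    n_targets: int
    n_records: int
    n_positive: int
    n_negative: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_records(cls, records: list[InteractionRecord]) -> "DatasetSummary":
        n_pos = sum(1 for r in records if r.label == 1)
        n_neg = sum(1 for r in records if r.label == 0)
        return cls(n_drugs=len({r.drug_id for r in records}),
                   n_targets=len({r.target_id for r in records}),
                   n_records=len(records), n_positive=n_pos, n_negative=n_neg)


def load_davis(ligands: dict[str, str], proteins: dict[str, str],
               affinity_matrix: np.ndarray,
               value_scale: str = "kd_nM") -> list[InteractionRecord]:
    """One record per non-missing affinity cell.

    Key insertion order of the two collections fixes row/column identity.
    ``value_scale`` is ``"kd_nM"`` for raw dissociation constants or ``"pKd"``
    for −log10 molar affinities (converted via kd_nM = 10^(9 − pKd)).
    """
    if value_scale not in ("kd_nM", "pKd"):
        raise ValueError(f"unknown value_scale {value_scale!r}")
    matrix = np.asarray(affinity_matrix, dtype=float)
    if matrix.shape != (len(ligands), len(proteins)):
        raise ValueError(
            f"affinity matrix is {matrix.shape}, expected "
            f"({len(ligands)}, {len(proteins)})")
    drug_items = list(ligands.items())
    target_items = list(proteins.items())
    records: list[InteractionRecord] = []
    for i, (did, smiles) in enumerate(drug_items):
        for j, (tid, seq) in enumerate(target_items):
            value = matrix[i, j]
            if np.isnan(value):
                continue
            kd = 10.0 ** (9.0 - value) if value_scale == "pKd" else float(value)
            records.append(InteractionRecord(did, smiles, tid, seq, kd_nM=kd))
    return records


def load_davis_files(ligands_path: str | Path, proteins_path: str | Path,
                     affinity_path: str | Path,
                     value_scale: str = "kd_nM") -> list[InteractionRecord]:
    """Load the Davis text dialect: two keyed JSON files + a dense matrix.

    The matrix is whitespace- or comma-delimited with ``nan`` for missing
    entries, one drug per row.
    """
    try:
        ligands = json.loads(Path(ligands_path).read_text())
        proteins = json.loads(Path(proteins_path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"unparseable keyed collection: {exc}") from exc
    text = Path(affinity_path).read_text().replace(",", " ")
    rows = [ln.split() for ln in text.splitlines() if ln.strip()]
    try:
        matrix = np.array([[float(v) for v in row] for row in rows])
    except ValueError as exc:
        raise ValueError(f"unparseable affinity matrix: {exc}") from exc
    return load_davis(ligands, proteins, matrix, value_scale=value_scale)


def binarize(record: InteractionRecord,
             threshold_nM: float = KD_POSITIVE_THRESHOLD_NM) -> InteractionRecord:
    """Label 1 iff Kd < threshold (strict); Kd at or above it is negative."""
    if record.kd_nM is None:
        raise ValueError(
            f"record ({record.drug_id}, {record.target_id}) has no kd_nM")
    return InteractionRecord(record.drug_id, record.smiles, record.target_id,
                             record.sequence, kd_nM=record.kd_nM,
                             label=int(record.kd_nM < threshold_nM))


def deduplicate(records: list[InteractionRecord]) -> list[InteractionRecord]:
    """Keep the first occurrence of every (drug_id, target_id) pair."""
    seen: set[tuple[str, str]] = set()
    out: list[InteractionRecord] = []
    for r in records:
        key = (r.drug_id, r.target_id)
        if key in seen:
            logger.warning("dropping duplicate pair %s", key)
            continue
        seen.add(key)
        out.append(r)
    return out


def balance_by_downsampling(records: list[InteractionRecord], seed: int,
                            ) -> tuple[list[InteractionRecord], DatasetSummary]:
    """Keep all positives; sample an equal number of negatives uniformly.

    Pairs are de-duplicated first. Sampling is without replacement and fully
    determined by ``seed``.
    """
    unique = deduplicate(records)
    if any(r.label is None for r in unique):
        raise ValueError("all records must be labeled before balancing")
    positives = [r for r in unique if r.label == 1]
    negatives = [r for r in unique if r.label == 0]
    if len(negatives) < len(positives):
        raise ValueError(
            f"cannot balance: {len(negatives)} negatives < "
            f"{len(positives)} positives")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(negatives), size=len(positives), replace=False)
    sampled = [negatives[i] for i in sorted(chosen)]
    balanced = positives + sampled
    return balanced, DatasetSummary.from_records(balanced)


# ---------------------------------------------------------------------------
# pair-file I/O

_MANDATORY = ("drug_id", "smiles", "target_id", "sequence")


def read_pairs_tsv(path: str | Path) -> list[InteractionRecord]:
    """Read a TSV pair file; malformed rows are reported with line numbers."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _MANDATORY if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing mandatory columns {missing}")
        records: list[InteractionRecord] = []
        for line_no, row in enumerate(reader, start=2):
            for col in _MANDATORY:
                if not (row.get(col) or "").strip():
                    raise ValueError(f"{path}: line {line_no}: empty {col!r}")
            kd = row.get("kd_nM")
            label = row.get("label")
            try:
                records.append(InteractionRecord(
                    row["drug_id"], row["smiles"].strip(),
                    row["target_id"], row["sequence"].strip(),
                    kd_nM=float(kd) if kd not in (None, "") else None,
                    label=int(label) if label not in (None, "") else None))
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from exc
    return records


def write_pairs_tsv(records: list[InteractionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([*_MANDATORY, "kd_nM", "label"])
        for r in records:
            writer.writerow([
                r.drug_id, r.smiles, r.target_id, r.sequence,
                "" if r.kd_nM is None else repr(float(r.kd_nM)),
                "" if r.label is None else r.label])
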