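"""Synthetic benchmark generator with a plantable interaction rule.

Drugs are random SMILES-like strings and targets random protein-like strings;
a drug motif and a target motif are each planted with a configurable
probability, and the ground-truth interaction rule is conjunctive: a pair
interacts iff the drug contains the drug motif AND the target contains the
target motif. The rule is learnable by both convolutional (local motif) and
attention (cross-sequence pairing) components, which is exactly what the
architecture claims to capture. Observed labels can be flipped with a noise
probability; affinities are drawn log-uniformly inside class-specific Kd
ranges that straddle the 30 nM decision boundary, so the generated bundle
round-trips through the benchmark loader and binarizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .davis import (
    DatasetSummary,
    InteractionRecord,
    binarize,
    load_davis,
    write_pairs_tsv,
)

#: single-character SMILES-like alphabet (a learnability fixture, not chemistry)
DEFAULT_SMILES_ALPHABET = "CNOSPFI()=#12"
DEFAULT_PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Generation parameters; the defaults define the study conditions."""

    n_drugs: int = 60
    n_targets: int = 60
    smiles_alphabet: str = DEFAULT_SMILES_ALPHABET
    protein_alphabet: str = DEFAULT_PROTEIN_ALPHABET
    drug_motif: str = "NC(=O)"
    target_motif: str = "GKSTW"
    motif_plant_probability: float = 0.5
    label_noise: float = 0.0
    smiles_length_range: tuple[int, int] = (20, 48)
    protein_length_range: tuple[int, int] = (60, 120)
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.drug_motif) <= set(self.smiles_alphabet):
            raise ValueError("drug motif uses characters outside the alphabet")
        if not set(self.target_motif) <= set(self.protein_alphabet):
            raise ValueError("target motif uses characters outside the alphabet")
        if len(self.drug_motif) > self.smiles_length_range[0]:
            raise ValueError("drug motif longer than the shortest SMILES")
        if len(self.target_motif) > self.protein_length_range[0]:
            raise ValueError("target motif longer than the shortest protein")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")


def _random_string(rng: np.random.Generator, alphabet: str,
                   length_range: tuple[int, int], motif: str,
                   plant_probability: float) -> str:
    lo, hi = length_range
    length = int(rng.integers(lo, hi + 1))
    chars = rng.choice(list(alphabet), size=length)
    s = "".join(chars)
    if rng.random() < plant_probability:
        start = int(rng.integers(0, length - len(motif) + 1))
        s = s[:start] + motif + s[start + len(motif):]
    return s


def _entities(spec: SyntheticSpec, rng: np.random.Generator,
              ) -> tuple[dict[str, str], dict[str, str]]:
    drugs = {f"D{i:04d}": _random_string(
        rng, spec.smiles_alphabet, spec.smiles_length_range,
        spec.drug_motif, spec.motif_plant_probability)
        for i in range(spec.n_drugs)}
    targets = {f"T{i:04d}": _random_string(
        rng, spec.protein_alphabet, spec.protein_length_range,
        spec.target_motif, spec.motif_plant_probability)
        for i in range(spec.n_targets)}
    return drugs, targets


def true_label(spec: SyntheticSpec, smiles: str, sequence: str) -> int:
    """Ground-truth conjunctive rule, decided by substring search."""
    return int(spec.drug_motif in smiles and spec.target_motif in sequence)


def generate_pairs(spec: SyntheticSpec, n_pairs: int,
                   ) -> tuple[list[InteractionRecord], dict]:
    """Sample labeled pairs without replacement from the drug × target grid."""
    if n_pairs > spec.n_drugs * spec.n_targets:
        raise ValueError(
            f"n_pairs={n_pairs} exceeds the {spec.n_drugs}x{spec.n_targets} grid")
    rng = np.random.default_rng(spec.seed)
    drugs, targets = _entities(spec, rng)
    drug_items = list(drugs.items())
    target_items = list(targets.items())
    cells = rng.choice(spec.n_drugs * spec.n_targets, size=n_pairs, replace=False)
    records: list[InteractionRecord] = []
    true_labels: list[int] = []
    for cell in cells:
        did, smiles = drug_items[cell // spec.n_targets]
        tid, seq = target_items[cell % spec.n_targets]
        truth = true_label(spec, smiles, seq)
        observed = truth ^ int(rng.random() < spec.label_noise)
        records.append(InteractionRecord(did, smiles, tid, seq, label=observed))
        true_labels.append(truth)
    rule = {"drug_motif": spec.drug_motif, "target_motif": spec.target_motif,
            "true_labels": true_labels}
    return records, rule


def generate_kd_matrix(spec: SyntheticSpec,
                       positive_kd_range: tuple[float, float] = (1.0, 29.0),
                       negative_kd_range: tuple[float, float] = (100.0, 10000.0),
                       ) -> tuple[dict[str, str], dict[str, str], np.ndarray]:
    """Dense benchmark-dialect triple whose binarization matches the rule.

    Kd is log-uniform within the class range selected by the (possibly
    noise-flipped) motif rule; positive ranges must lie strictly below the
    30 nM boundary and negative ranges at or above it.
    """
    if positive_kd_range[1] >= 30.0 or negative_kd_range[0] < 30.0:
        raise ValueError("Kd class ranges must not straddle the 30 nM boundary")
    rng = np.random.default_rng(spec.seed)
    drugs, targets = _entities(spec, rng)
    matrix = np.empty((spec.n_drugs, spec.n_targets))
    for i, smiles in enumerate(drugs.values()):
        for j, seq in enumerate(targets.values()):
            label = true_label(spec, smiles, seq)
            label ^= int(rng.random() < spec.label_noise)
            lo, hi = positive_kd_range if label else negative_kd_range
            matrix[i, j] = np.exp(rng.uniform(np.log(lo), np.log(hi)))
    return drugs, targets, matrix


def write_fixture_bundle(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write benchmark files (JSON collections + matrix), FASTA, TSV pairs and
    a ground-truth manifest; byte-identical for identical specs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    drugs, targets, matrix = generate_kd_matrix(spec)

    (out / "ligands.json").write_text(json.dumps(drugs, indent=0, sort_keys=False))
    (out / "proteins.json").write_text(json.dumps(targets, indent=0, sort_keys=False))
    lines = ["\t".join(repr(float(v)) for v in row) for row in matrix]
    (out / "affinities.txt").write_text("\n".join(lines) + "\n")
    with open(out / "targets.fasta", "w") as fh:
        for tid, seq in targets.items():
            fh.write(f">{tid}\n{seq}\n")

    records = [binarize(r) for r in load_davis(drugs, targets, matrix)]
    write_pairs_tsv(records, out / "pairs.tsv")
    summary = DatasetSummary.from_records(records)

    manifest = {
        "spec": {k: list(v) if isinstance(v, tuple) else v
                 for k, v in asdict(spec).items()},
        "summary": json.loads(summary.to_json()),
        "files": ["ligands.json", "proteins.json", "affinities.txt",
                  "targets.fasta", "pairs.tsv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
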