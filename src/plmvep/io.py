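"""Readers and writers for the package's plain-text formats: FASTA
sequences and the TSV tables used for variants, benchmarks, isoform
maps, junctions, DMS assays and score reports."""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .backend import ALPHABET, ProteinSequence, _AA_SET
from .errors import ValidationError
from .evaluation import DmsAssay, LabeledScoreSet
from .isoforms import ABSENT, VariantIsoformMap
from .scoring import LLRMatrix

logger = logging.getLogger("plmvep")


def read_backend_config(path) -> "BackendSpec":
    """Load a backend specification from JSON (as written by fixture
    bundles): keys kind, seed, max_input_length, domain_motifs."""
    import json

    from .backend import BackendSpec

    with open(path) as fh:
        data = json.load(fh)
    return BackendSpec(
        kind=data.get("kind", "synthetic"),
        seed=int(data.get("seed", 0)),
        max_input_length=int(data.get("max_input_length", 1022)),
        domain_motifs=tuple(tuple(m) for m in data.get("domain_motifs", [])),
    )

#: Residues outside the canonical alphabet that sanitization may remap.
NON_CANONICAL = "UXBZOJ"
DEFAULT_PLACEHOLDER = "A"

SCORE_DECIMALS = 4


def sanitize_residues(raw: str, placeholder: str = DEFAULT_PLACEHOLDER):
    """Map non-canonical residues to a placeholder.

    Returns ``(cleaned, flagged_positions)`` where positions are 1-based.
    """
    if placeholder not in _AA_SET:
        raise ValidationError(f"placeholder {placeholder!r} is not canonical")
    cleaned = []
    flagged = []
    for pos0, aa in enumerate(raw):
        if aa in _AA_SET:
            cleaned.append(aa)
        elif aa in NON_CANONICAL:
            cleaned.append(placeholder)
            flagged.append(pos0 + 1)
        else:
            cleaned.append(aa)  # let ProteinSequence raise with position info
    return "".join(cleaned), flagged


def read_fasta(
    path,
    sanitize: bool = False,
    placeholder: str = DEFAULT_PLACEHOLDER,
) -> list:
    """Read protein sequences from FASTA.

    Ids are taken up to the first whitespace; sequences are uppercased;
    a single trailing stop symbol ``*`` is stripped with a warning. By
    default non-canonical residues raise; with ``sanitize=True`` the
    residues in :data:`NON_CANONICAL` are replaced by ``placeholder``
    and the affected positions logged.
    """
    sequences = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        seq_id = record.id
        if not seq_id:
            raise ValidationError(f"record without id in {path}")
        if seq_id in seen:
            raise ValidationError(f"duplicate sequence id {seq_id!r} in {path}")
        seen.add(seq_id)
        residues = str(record.seq).upper()
        if residues.endswith("*"):
            logger.warning("stripping trailing stop symbol from %r", seq_id)
            residues = residues[:-1]
        if not residues:
            raise ValidationError(f"empty sequence for record {seq_id!r}")
        if sanitize:
            residues, flagged = sanitize_residues(residues, placeholder)
            if flagged:
                logger.warning(
                    "sanitized %d non-canonical residue(s) in %r at %s",
                    len(flagged), seq_id, flagged,
                )
        sequences.append(ProteinSequence(id=seq_id, residues=residues))
    if not sequences:
        raise ValidationError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(sequences, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# LLR matrices
# ---------------------------------------------------------------------------


def write_llr_matrix(matrix: LLRMatrix, sequence: ProteinSequence, path,
                     decimals: Optional[int] = SCORE_DECIMALS) -> None:
    """LLR matrix as TSV: rows = amino acids in canonical order, columns
    = 1-based positions, with protein id and sequence in header comments."""
    values = matrix.values
    fmt = (
        (lambda v: f"{v:.{decimals}f}")
        if decimals is not None
        else (lambda v: f"{v:.17g}")
    )
    with open(path, "w") as fh:
        fh.write(f"# protein_id: {matrix.protein_id}\n")
        fh.write(f"# sequence: {sequence.residues}\n")
        fh.write("aa\t" + "\t".join(str(p) for p in range(1, matrix.length + 1)) + "\n")
        for i, aa in enumerate(ALPHABET):
            fh.write(aa + "\t" + "\t".join(fmt(v) for v in values[i]) + "\n")


def read_llr_matrix(path) -> LLRMatrix:
    protein_id = None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("# protein_id:"):
            protein_id = line.split(":", 1)[1].strip()
        if line.startswith("#"):
            body_start += 1
        else:
            break
    if protein_id is None:
        raise ValidationError(f"missing protein_id header in {path}")
    df = pd.read_csv(path, sep="\t", skiprows=body_start, index_col=0)
    if list(df.index) != list(ALPHABET):
        raise ValidationError(f"unexpected amino-acid row order in {path}")
    return LLRMatrix(protein_id=protein_id, values=df.to_numpy(dtype=np.float64))


# ---------------------------------------------------------------------------
# Variant and score tables
# ---------------------------------------------------------------------------


def read_variant_table(path) -> pd.DataFrame:
    """Variant TSV with columns variant_id, protein_id, hgvs_p."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "protein_id", "hgvs_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"variant table missing columns {sorted(missing)}")
    return df


def write_score_table(rows, path, decimals: Optional[int] = SCORE_DECIMALS) -> None:
    """Per-variant scores as TSV with fixed decimal formatting."""
    df = pd.DataFrame(rows)
    if decimals is not None and "score" in df.columns:
        df["score"] = df["score"].map(lambda v: f"{v:.{decimals}f}")
    df.to_csv(path, sep="\t", index=False)


def read_benchmark(path) -> LabeledScoreSet:
    """Benchmark TSV: variant_id, gene_id, label, then one score column
    per method. Labels are ``pathogenic`` / ``benign``."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"benchmark missing columns {sorted(missing)}")
    methods = [c for c in df.columns if c not in required]
    if not methods:
        raise ValidationError("benchmark has no score columns")
    bad = set(df["label"]) - {"pathogenic", "benign"}
    if bad:
        raise ValidationError(f"unknown labels {sorted(bad)}")
    return LabeledScoreSet(
        variant_ids=tuple(df["variant_id"].astype(str)),
        labels=(df["label"] == "pathogenic").to_numpy(),
        scores={m: df[m].to_numpy(dtype=np.float64) for m in methods},
        gene_ids=tuple(df["gene_id"].astype(str)),
    )


def read_isoform_map(path) -> list:
    """Isoform-map TSV: variant_id, isoform_id, position, ref, alt.

    A position value of ``ABSENT`` marks a variant spliced out of that
    isoform. Returns one :class:`VariantIsoformMap` per variant, in
    first-appearance order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "isoform_id", "position", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"isoform map missing columns {sorted(missing)}")
    maps = []
    for variant_id, group in df.groupby("variant_id", sort=False):
        entries = []
        for _, row in group.iterrows():
            if row["position"] == ABSENT:
                entries.append((row["isoform_id"], ABSENT))
            else:
                entries.append(
                    (row["isoform_id"], int(row["position"]), row["ref"], row["alt"])
                )
        maps.append(VariantIsoformMap(variant_id=variant_id, entries=tuple(entries)))
    return maps


def read_junctions(path) -> dict:
    """Junction TSV: isoform_id, junction_aa_position -> dict of lists."""
    df = pd.read_csv(path, sep="\t")
    required = {"isoform_id", "junction_aa_position"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"junction table missing columns {sorted(missing)}")
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["isoform_id"]), []).append(
            int(row["junction_aa_position"])
        )
    return out


def read_dms_table(path):
    """DMS TSV: gene_id, assay_id, variant_id, measurement, x_wt,
    center_transform and optionally a prediction column.

    Returns ``(assays, predictions)`` where predictions maps assay id to
    an aligned vector (empty dict when the column is absent).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "assay_id", "variant_id", "measurement"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"DMS table missing columns {sorted(missing)}")
    assays, predictions = [], {}
    for assay_id, group in df.groupby("assay_id", sort=False):
        x_wt = None
        if "x_wt" in group.columns and not group["x_wt"].isna().all():
            x_wt = float(group["x_wt"].iloc[0])
        center = False
        if "center_transform" in group.columns:
            center = bool(group["center_transform"].iloc[0])
        assays.append(
            DmsAssay(
                gene_id=str(group["gene_id"].iloc[0]),
                assay_id=str(assay_id),
                variant_ids=tuple(group["variant_id"].astype(str)),
                measurements=group["measurement"].to_numpy(dtype=np.float64),
                x_wt=x_wt,
                center_transform=center,
            )
        )
        if "prediction" in group.columns:
            predictions[str(assay_id)] = group["prediction"].to_numpy(dtype=np.float64)
    return assays, predictions
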