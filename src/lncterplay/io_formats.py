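"""Readers and writers for the standard formats the pipeline touches.

TSV expression matrices, GTF 2.2 / BED6 annotation, FASTA transcript
sequences, and GMT gene sets.  Everything is validated at the boundary so
downstream modules only ever see well-formed domain objects.  Coordinates
are converted to the package-wide 0-based half-open convention here:
GTF is 1-based closed, BED is already 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    ExpressionMatrix,
    Feature,
    FeatureAnnotation,
    GeneSetCollection,
    RNA_ALPHABET,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation",
    "write_annotation_gtf",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
]

# ---------------------------------------------------------------------------
# expression TSV


def read_expression_tsv(path: str | Path, group_map: dict[str, str]) -> ExpressionMatrix:
    """Read a probes-x-samples TSV (header = sample ids, first column = probe ids).

    Every sample in the file must be present in ``group_map``; parsing is
    locale-independent (dot decimal separator).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    probe_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    missing = [s for s in sample_ids if s not in group_map]
    if missing:
        raise ValidationError(
            f"{path}: sample(s) absent from group map: {missing}"
        )
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric value {raw!r} at probe "
                    f"{probe_ids[i]!r}, sample {col!r}"
                ) from None
    return ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        groups={s: group_map[s] for s in sample_ids},
        values=values,
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with full float precision (round-trip safe)."""
    df = matrix.to_frame()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# annotation (GTF / BED)

GTF_BIOTYPE_KEY = "gene_biotype"


def read_annotation(path: str | Path, dialect: str = "gtf") -> FeatureAnnotation:
    """Read feature annotation from GTF 2.2 or BED6.

    GTF coordinates (1-based closed) and BED coordinates (0-based half-open)
    are both converted to the internal 0-based half-open convention.  Records
    with an unknown biotype are skipped with a warning; malformed lines are
    collected and the first is reported as a hard error.
    """
    if dialect not in ("gtf", "bed"):
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    features: list[Feature] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = (_parse_gtf_line if dialect == "gtf" else _parse_bed_line)(line)
            except ValidationError as exc:
                errors.append(f"{path}:{lineno}: {exc}")
                continue
            if feat is not None:
                features.append(feat)
    if errors:
        raise ValidationError(
            f"{len(errors)} malformed line(s); first: {errors[0]}"
        )
    return FeatureAnnotation(features)


def _parse_gtf_line(line: str) -> Feature | None:
    fields = line.split("\t")
    if len(fields) != 9:
        raise ValidationError(f"expected 9 GTF fields, got {len(fields)}")
    chrom, _source, _ftype, start_s, end_s, _score, strand, _frame, attrs = fields
    try:
        start1, end1 = int(start_s), int(end_s)
    except ValueError:
        raise ValidationError(f"non-integer coordinates {start_s!r}/{end_s!r}") from None
    start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
    if start > end or start < 0:
        raise ValidationError(f"invalid interval after conversion: [{start}, {end})")
    attr_map = _parse_gtf_attrs(attrs)
    feature_id = attr_map.get("gene_id")
    if not feature_id:
        raise ValidationError("missing gene_id attribute")
    biotype = attr_map.get(GTF_BIOTYPE_KEY, "")
    if biotype not in ("lncRNA", "mRNA"):
        logger.warning("skipping %s: unknown biotype %r", feature_id, biotype)
        return None
    return Feature(
        feature_id=feature_id,
        biotype=biotype,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand if strand in "+-." else ".",
        gene_symbol=attr_map.get("gene_name"),
    )


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _parse_bed_line(line: str) -> Feature | None:
    fields = line.split("\t")
    if len(fields) < 4:
        raise ValidationError(f"expected >=4 BED fields, got {len(fields)}")
    chrom, start_s, end_s, name = fields[:4]
    strand = fields[5] if len(fields) >= 6 else "."
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ValidationError(f"non-integer coordinates {start_s!r}/{end_s!r}") from None
    if start > end or start < 0:
        raise ValidationError(f"invalid interval: [{start}, {end})")
    # BED has no attribute column; encode biotype as "<id>|<biotype>" in name
    feature_id, _, biotype = name.partition("|")
    if biotype not in ("lncRNA", "mRNA"):
        logger.warning("skipping %s: unknown biotype %r", feature_id, biotype)
        return None
    return Feature(
        feature_id=feature_id,
        biotype=biotype,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand if strand in "+-." else ".",
    )


def write_annotation_gtf(annotation: FeatureAnnotation, path: str | Path) -> None:
    """Write features as GTF 2.2 gene records (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        for f in annotation:
            attrs = f'gene_id "{f.feature_id}"; {GTF_BIOTYPE_KEY} "{f.biotype}";'
            if f.gene_symbol:
                attrs += f' gene_name "{f.gene_symbol}";'
            fh.write(
                f"{f.chrom}\tlncterplay\tgene\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (set id, description, members...); deduplicates by id."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: gene set {fields[0]!r} has no members"
                )
            set_id, desc = fields[0], fields[1]
            members = {m for m in fields[2:] if m}
            if not members:
                raise ValidationError(
                    f"{path}:{lineno}: gene set {set_id!r} has no members"
                )
            if set_id in sets:
                logger.warning("duplicate gene set id %r: keeping first", set_id)
                continue
            sets[set_id] = members
            names[set_id] = desc or set_id
    return GeneSetCollection(sets=sets, names=names, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[sid]))
            fh.write(f"{sid}\t{collection.names.get(sid, sid)}\t{members}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> RNA sequence map (uppercased, T mapped to U)."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValidationError(f"duplicate sequence id: {record.id}")
        seq = str(record.seq).upper().replace("T", "U")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {record.id!r} contains invalid characters: {sorted(bad)}"
            )
        seqs[record.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid in sorted(seqs):
            fh.write(f">{sid}\n")
            s = seqs[sid]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
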