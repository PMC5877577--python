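"""Reading and writing annotated plastomes.

GenBank flat files and FASTA are read through Biopython; features are
converted to 0-based half-open coordinates on input and back to GenBank's
1-based inclusive convention on output.  GFF3 and TSV writers cover the
downstream report formats.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .records import FEATURE_KINDS, AnnotatedPlastome, GeneFeature


class PlastomeParseError(ValueError):
    pass


def read_genbank(path: str | Path) -> AnnotatedPlastome:
    """Read an annotated plastome from a GenBank flat file.

    Captures all CDS/tRNA/rRNA features; ``join()`` locations become
    multi-part features.  Raises :class:`PlastomeParseError` on a missing
    sequence, and a coordinate error naming the offending feature if one lies
    beyond the sequence end.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise PlastomeParseError(f"{path}: not a parseable GenBank record ({exc})")
    seq = str(record.seq).upper()
    if not seq:
        raise PlastomeParseError(f"{path}: record has no ORIGIN sequence")

    circular = record.annotations.get("topology", "circular") == "circular"
    features: list[GeneFeature] = []
    n = len(seq)
    for feat in record.features:
        if feat.type not in FEATURE_KINDS:
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("locus_tag", [None])[0]
            or feat.type
        )
        parts = []
        for loc in feat.location.parts:
            s, e = int(loc.start), int(loc.end)
            if e > n:
                raise PlastomeParseError(
                    f"{path}: feature {name} extends to {e}, beyond the "
                    f"sequence end at {n}"
                )
            parts.append((s, e))
        strand = "-" if feat.location.strand == -1 else "+"
        if strand == "-":
            parts = parts[::-1]
        wraps = len(parts) > 1 and parts == sorted(parts) and any(
            parts[i][1] == n and parts[i + 1][0] == 0 for i in range(len(parts) - 1)
        )
        features.append(
            GeneFeature(
                name=name,
                kind=feat.type,
                strand=strand,
                parts=sorted(parts),
                pseudo="pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers,
                wraps_origin=wraps,
            )
        )
    return AnnotatedPlastome(
        id=record.id or record.name or path.stem,
        sequence=seq,
        circular=circular,
        features=features,
    )


def read_fasta(path: str | Path) -> AnnotatedPlastome:
    """Read a plastome sequence (no features) from a single-record FASTA."""
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "fasta")
    except ValueError as exc:
        raise PlastomeParseError(f"{path}: not a single-record FASTA ({exc})")
    return AnnotatedPlastome(
        id=record.id, sequence=str(record.seq).upper(), features=[]
    )


def write_genbank(plastome: AnnotatedPlastome, path: str | Path) -> None:
    """Write a plastome as a GenBank flat file; read_genbank round-trips it."""
    record = SeqRecord(
        Seq(plastome.sequence),
        id=plastome.id,
        name=plastome.id.split(".")[0][:16],
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if plastome.circular else "linear",
        },
    )
    for f in plastome.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in f.parts]
        if strand == -1:
            locs = locs[::-1]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [f.name]}
        if f.pseudo:
            qualifiers["pseudo"] = [""]
        record.features.append(
            SeqFeature(location, type=f.kind, qualifiers=qualifiers)
        )
    SeqIO.write(record, str(path), "genbank")


def write_fasta(plastome: AnnotatedPlastome, path: str | Path) -> None:
    SeqIO.write(
        SeqRecord(Seq(plastome.sequence), id=plastome.id, description=""),
        str(path),
        "fasta",
    )


def write_gff3(plastome: AnnotatedPlastome, path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive, per the format)."""
    lines = ["##gff-version 3"]
    lines.append(f"##sequence-region {plastome.id} 1 {plastome.length}")
    type_map = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    for i, f in enumerate(plastome.features):
        gid = f"gene{i:04d}"
        for j, (s, e) in enumerate(f.parts):
            attrs = f"ID={gid}.{j};Name={f.name}"
            if f.pseudo:
                attrs += ";pseudo=true"
            lines.append(
                "\t".join(
                    [
                        plastome.id,
                        "plastokit",
                        type_map[f.kind],
                        str(s + 1),
                        str(e),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        attrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_tsv(rows: list[dict], path: str | Path) -> None:
    """Write a list of homogeneous dicts as a TSV table (stable column order)."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
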