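"""File formats and in-memory containers for the pipeline.

Coordinate conventions: internal intervals are 0-based half-open; GFF3 input
and output is 1-based inclusive; BED is 0-based half-open.  All nucleotide
sequences are normalized to the DNA alphabet (U -> T, uppercase) on ingest.

Missing spectral-count cells are kept as NaN and are semantically distinct
from zero: the proteomics filters exclude inconsistently quantified proteins
rather than treating them as undetected-at-zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "IntronAnnotation",
    "ClassedCountMatrix",
    "SplicingEventRecord",
    "SpectralCountTable",
    "read_fasta",
    "write_fasta",
    "read_gff_introns",
    "write_gff_introns",
    "read_bed_introns",
    "read_counts_table",
    "write_counts_table",
    "read_splicing_events",
    "write_splicing_events",
    "events_to_frame",
    "read_spectral_counts",
    "write_spectral_counts",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_CLASSES = frozenset({"unspliced", "spliced", "intronless"})


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over ACGTN."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_sequence(raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters after normalization: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class GenomeSequence:
    """A chromosome/contig: ``name`` plus an uppercase ACGTN DNA string."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("empty sequence name")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.name}")
        object.__setattr__(self, "sequence", _normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IntronAnnotation:
    """One intron as a 0-based half-open genomic interval.

    ``three_prime_ss`` is the genomic coordinate of the last intron base in
    transcript orientation: ``end - 1`` on the + strand, ``start`` on -.
    """

    intron_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.intron_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.intron_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def three_prime_ss(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ClassedCountMatrix:
    """Transcript x sample counts (or TPM-like abundances) with class labels.

    ``data`` rows are transcript ids, columns sample ids.  ``classes`` and
    ``genes`` map transcript -> {unspliced, spliced, intronless} / gene id;
    ``conditions`` optionally maps sample -> condition label.
    """

    data: pd.DataFrame
    classes: pd.Series
    genes: pd.Series
    conditions: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate transcript ids: {dups}")
        if (self.data.values < 0).any():
            raise ValueError("negative values in count matrix")
        missing = self.data.index.difference(self.classes.index)
        if len(missing):
            raise ValueError(f"transcripts without class label: {list(missing)}")
        bad = set(self.classes.loc[self.data.index]) - VALID_CLASSES
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        self.classes = self.classes.loc[self.data.index]
        self.genes = self.genes.loc[self.data.index]
        # every unspliced row needs a spliced sibling for the same gene
        cls, gen = self.classes, self.genes
        spliced_genes = set(gen[cls == "spliced"])
        orphans = sorted(set(gen[cls == "unspliced"]) - spliced_genes)
        if orphans:
            raise ValueError(f"unspliced rows without spliced sibling: {orphans}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def samples_for(self, condition: str) -> list[str]:
        if self.conditions is None:
            raise ValueError("no condition labels attached")
        return list(self.conditions.index[self.conditions == condition])


@dataclass(frozen=True)
class SplicingEventRecord:
    """One alternative-splicing event with per-contrast dPSI / MVdPSI95.

    dPSI is in percent units in [-100, 100]; MVdPSI95 (the minimum dPSI of
    the 95% confidence interval) is >= 0, with > 0 marking confident change.
    """

    event_id: str
    event_type: str
    gene_id: str
    dpsi: Mapping[str, float]
    mv: Mapping[str, float]

    def __post_init__(self) -> None:
        for contrast, value in self.dpsi.items():
            if not -100.0 <= value <= 100.0:
                raise ValueError(
                    f"{self.event_id}: dPSI {value} outside [-100, 100] "
                    f"({contrast})"
                )
        for contrast, value in self.mv.items():
            if value < 0:
                raise ValueError(f"{self.event_id}: negative MVdPSI95 ({contrast})")


@dataclass
class SpectralCountTable:
    """Protein x condition normalized spectral counts / DIA quantities.

    ``roles`` maps every column to one of {"NE", "APT", "substrate"} or, for
    replicate designs, a group label ("replicate:<group>").  NaN cells mean
    "not quantified" and are never coerced to zero.
    """

    data: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate protein ids")
        if self.data.size and (self.data.values < 0).any():
            raise ValueError("negative spectral counts")
        missing = [c for c in self.data.columns if c not in self.roles]
        if missing:
            raise ValueError(f"columns without a role: {missing}")

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] == role]

    def replicate_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for col, role in self.roles.items():
            if role.startswith("replicate:"):
                groups.setdefault(role.split(":", 1)[1], []).append(col)
        return groups


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into normalized :class:`GenomeSequence` records."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeSequence(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.name, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 / BED introns


def _introns_from_exon_gaps(db: gffutils.FeatureDB) -> list[IntronAnnotation]:
    introns = []
    by_parent: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        for parent in exon.attributes.get("Parent", ["?"]):
            by_parent.setdefault(parent, []).append(exon)
    for parent, exons in sorted(by_parent.items()):
        exons = sorted(exons, key=lambda f: f.start)
        for i, (left, right) in enumerate(zip(exons, exons[1:]), start=1):
            if right.start - 1 <= left.end:
                raise ValueError(f"{parent}: overlapping/adjacent exons")
            gene = (left.attributes.get("gene_id") or [parent])[0]
            introns.append(
                IntronAnnotation(
                    intron_id=f"{parent}.intron{i}",
                    gene_id=gene,
                    chrom=left.seqid,
                    start=left.end,  # GFF end is 1-based inclusive == 0-based open
                    end=right.start - 1,
                    strand=left.strand,
                )
            )
    return introns


def read_gff_introns(path: str | Path) -> list[IntronAnnotation]:
    """Read introns from GFF3: direct ``intron`` features, or exon gaps.

    GFF3 1-based inclusive coordinates become 0-based half-open.  When the
    file carries no intron features, introns are inferred per transcript from
    the gaps between consecutive exons (grouped by ``Parent``).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    introns = []
    for feat in db.features_of_type("intron"):
        intron_id = (feat.attributes.get("ID") or [f"{feat.seqid}:{feat.start}"])[0]
        gene = (feat.attributes.get("gene_id") or feat.attributes.get("Parent") or ["?"])[0]
        introns.append(
            IntronAnnotation(
                intron_id=intron_id,
                gene_id=gene,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
            )
        )
    if not introns:
        introns = _introns_from_exon_gaps(db)
    introns.sort(key=lambda i: (i.chrom, i.start))
    return introns


def write_gff_introns(introns: Iterable[IntronAnnotation], path: str | Path) -> None:
    """Write introns as GFF3 ``intron`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i in introns:
            attrs = f"ID={i.intron_id};gene_id={i.gene_id}"
            fh.write(
                f"{i.chrom}\tbpcompete\tintron\t{i.start + 1}\t{i.end}\t.\t"
                f"{i.strand}\t.\t{attrs}\n"
            )


def read_bed_introns(path: str | Path) -> list[IntronAnnotation]:
    """Read introns from BED6 (0-based half-open; name -> intron id)."""
    introns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            introns.append(
                IntronAnnotation(
                    intron_id=name,
                    gene_id=name.rsplit(".", 1)[0],
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                )
            )
    introns.sort(key=lambda i: (i.chrom, i.start))
    return introns


# ---------------------------------------------------------------------------
# Tabular inputs


def read_counts_table(
    path: str | Path,
    class_map: Mapping[str, tuple[str, str]],
    conditions: Mapping[str, str] | None = None,
) -> tuple[ClassedCountMatrix, list[str]]:
    """Read a transcript x sample TSV and join class labels.

    ``class_map`` maps transcript id -> (class, gene_id).  Transcripts absent
    from the map are excluded and returned in the ``unclassified`` list.
    Negative values and duplicate transcript ids are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate transcript ids: {dups}")
    if (df.values < 0).any():
        raise ValueError("negative values in counts table")
    unclassified = [t for t in df.index if t not in class_map]
    kept = df.drop(index=unclassified)
    classes = pd.Series({t: class_map[t][0] for t in kept.index}, dtype=object)
    genes = pd.Series({t: class_map[t][1] for t in kept.index}, dtype=object)
    cond = pd.Series(dict(conditions)) if conditions is not None else None
    return ClassedCountMatrix(kept, classes, genes, cond), unclassified


def write_counts_table(matrix: ClassedCountMatrix, path: str | Path) -> None:
    matrix.data.rename_axis("transcript_id").to_csv(path, sep="\t")


def read_class_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a TSV with columns transcript_id, class, gene_id."""
    df = pd.read_csv(path, sep="\t")
    return {
        t: (c, g)
        for t, c, g in zip(df["transcript_id"], df["class"], df["gene_id"])
    }


def read_splicing_events(path: str | Path) -> list[SplicingEventRecord]:
    """Read a VAST-tools-like event TSV.

    Expected columns: ``event_id``, ``type``, ``gene`` plus paired
    ``dPSI_<contrast>`` / ``MV_<contrast>`` columns; contrasts are discovered
    from the header.
    """
    df = pd.read_csv(path, sep="\t")
    contrasts = [c[len("dPSI_"):] for c in df.columns if c.startswith("dPSI_")]
    if not contrasts:
        raise ValueError("no dPSI_<contrast> columns found")
    for contrast in contrasts:
        if f"MV_{contrast}" not in df.columns:
            raise ValueError(f"missing MV_{contrast} column")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            SplicingEventRecord(
                event_id=d["event_id"],
                event_type=d["type"],
                gene_id=d["gene"],
                dpsi={c: float(d[f"dPSI_{c}"]) for c in contrasts},
                mv={c: float(d[f"MV_{c}"]) for c in contrasts},
            )
        )
    return records


def write_splicing_events(
    events: Sequence[SplicingEventRecord], path: str | Path
) -> None:
    contrasts = sorted({c for e in events for c in e.dpsi})
    rows = []
    for e in events:
        row = {"event_id": e.event_id, "type": e.event_type, "gene": e.gene_id}
        for c in contrasts:
            row[f"dPSI_{c}"] = e.dpsi[c]
            row[f"MV_{c}"] = e.mv[c]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def events_to_frame(
    events: Sequence[SplicingEventRecord], contrast: str
) -> pd.DataFrame:
    """Flatten one contrast into a frame with columns
    event_id, event_type, gene_id, dpsi, mv."""
    rows = []
    for e in events:
        if contrast not in e.dpsi:
            raise KeyError(f"unknown contrast {contrast!r} for {e.event_id}")
        rows.append(
            {
                "event_id": e.event_id,
                "event_type": e.event_type,
                "gene_id": e.gene_id,
                "dpsi": e.dpsi[contrast],
                "mv": e.mv[contrast],
            }
        )
    return pd.DataFrame(
        rows, columns=["event_id", "event_type", "gene_id", "dpsi", "mv"]
    )


def read_spectral_counts(
    path: str | Path, roles: Mapping[str, str]
) -> SpectralCountTable:
    """Read a protein x condition TSV; empty cells stay NaN (missing != 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    missing_roles = [c for c in df.columns if c not in roles]
    if missing_roles:
        raise ValueError(f"no role for columns: {missing_roles}")
    return SpectralCountTable(df, dict(roles))


def write_spectral_counts(table: SpectralCountTable, path: str | Path) -> None:
    table.data.rename_axis("protein_id").to_csv(path, sep="\t")
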