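"""Readers and writers for the external formats the screen consumes.

Every downstream stage works on the domain types defined here: contigs,
strand-aware ORF records, protein-search hit records with optional KEGG
orthology (KO) labels and taxonomic lineages, and Pfam-style domain hits.
All external coordinates are 1-based inclusive (GFF3 convention); a position
printed in any report can be looked up directly in the source FASTA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
KO_PATTERN_LEN = 6  # 'K' + 5 digits


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class TaxonomyPath:
    """Ordered lineage from root to leaf, as (rank_name, taxon_name) pairs."""

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("TaxonomyPath must be non-empty")
        names = [r for r, _ in self.ranks]
        if len(set(names)) != len(names):
            raise ValueError(f"repeated rank name in lineage: {names}")

    def __len__(self) -> int:
        return len(self.ranks)

    def is_prefix_of(self, other: "TaxonomyPath") -> bool:
        return self.ranks == other.ranks[: len(self.ranks)]

    @classmethod
    def from_string(cls, text: str) -> "TaxonomyPath":
        """Parse a semicolon-joined ``rank:name`` lineage string."""
        ranks = []
        for part in text.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            if ":" not in part:
                raise FormatError(f"lineage element {part!r} lacks 'rank:name' form")
            rank, name = part.split(":", 1)
            ranks.append((rank.strip(), name.strip()))
        return cls(tuple(ranks))

    def to_string(self) -> str:
        return ";".join(f"{r}:{n}" for r, n in self.ranks)


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r} has empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"contig {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """A called gene on a contig; coordinates 1-based inclusive."""

    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"ORF {self.id!r}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"ORF {self.id!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class HitRecord:
    """One protein-search match (BLAST/DIAMOND tabular row)."""

    orf_id: str
    subject_id: str
    bitscore: float
    ko_id: Optional[str] = None
    function_label: Optional[str] = None
    taxonomy_path: Optional[TaxonomyPath] = None

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError(f"hit {self.orf_id}->{self.subject_id}: negative bitscore")
        if self.ko_id is not None:
            k = self.ko_id
            if not (len(k) == KO_PATTERN_LEN and k[0] == "K" and k[1:].isdigit()):
                raise ValueError(f"malformed KO accession {k!r}")


@dataclass(frozen=True)
class DomainHit:
    """One Pfam-style conserved-domain hit for an ORF's protein."""

    orf_id: str
    domain_id: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass(frozen=True)
class MotifLibrary:
    """An aligned library of equal-length DNA binding sites."""

    ids: tuple[str, ...]
    sites: tuple[str, ...]
    width: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.sites}
        if len(widths) > 1:
            raise FormatError(f"sites have unequal lengths: {sorted(widths)}")
        object.__setattr__(self, "width", widths.pop() if widths else 0)

    def __len__(self) -> int:
        return len(self.sites)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[Contig]:
    """Read contigs from FASTA.

    The id is the first whitespace-delimited header token; sequences are
    upper-cased and must be over {A,C,G,T,N} (RNA 'U' is rejected).
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {rec.id!r} in {path} contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )
        contigs.append(Contig(id=rec.id, sequence=seq))
    if not contigs:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by the first header token."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def read_orfs_gff(path: str | Path, contigs: Sequence[Contig]) -> list[OrfRecord]:
    """Read CDS features from a GFF3 file as OrfRecords.

    Every feature must sit on a known contig, lie within its bounds, and be
    stranded ('.' is rejected: ORFs are directional by definition).
    """
    by_id = {c.id: c for c in contigs}
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True
    )
    orfs: list[OrfRecord] = []
    seen: set[str] = set()
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in by_id:
            raise FormatError(f"CDS on unknown contig {feat.seqid!r}")
        contig = by_id[feat.seqid]
        if not (1 <= feat.start <= feat.end <= len(contig)):
            raise FormatError(
                f"CDS {feat.id!r}: coordinates {feat.start}..{feat.end} outside "
                f"contig {contig.id!r} (length {len(contig)})"
            )
        if feat.strand not in ("+", "-"):
            raise FormatError(f"CDS {feat.id!r}: unstranded feature (strand '.')")
        orf_id = feat.attributes.get("ID", [feat.id])[0]
        if orf_id in seen:
            raise FormatError(f"duplicate ORF id {orf_id!r}")
        seen.add(orf_id)
        orfs.append(
            OrfRecord(
                id=orf_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return orfs


def write_orfs_gff(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            fh.write(
                f"{o.contig_id}\tluxscreen\tCDS\t{o.start}\t{o.end}\t.\t"
                f"{o.strand}\t0\tID={o.id}\n"
            )


#: column order of the standard 12-column tabular search format
STANDARD_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

_EXTENSION_COLUMNS = ("ko_id", "function_label", "taxonomy")


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tabular search file with optional named extensions.

    A header line starting with '#' may name the columns; otherwise the
    standard 12 columns are assumed, optionally followed by
    ko_id / function_label / taxonomy in that order. Empty extension cells
    ('' or '-') mean absent.
    """
    path = Path(path)
    columns: list[str] | None = None
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header = line.lstrip("#").strip()
                if header:
                    columns = header.split("\t")
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 12 tab-separated "
                    f"columns, got {len(fields)}"
                )
            names = columns or (
                STANDARD_COLUMNS + list(_EXTENSION_COLUMNS[: len(fields) - 12])
            )
            row = dict(zip(names, fields))
            raw = row.get("bitscore", fields[11])
            try:
                bitscore = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric bitscore {raw!r}"
                ) from None
            ko = row.get("ko_id", "").strip() or None
            if ko == "-":
                ko = None
            func = row.get("function_label", "").strip() or None
            if func == "-":
                func = None
            tax_raw = row.get("taxonomy", "").strip()
            tax = (
                TaxonomyPath.from_string(tax_raw)
                if tax_raw and tax_raw != "-"
                else None
            )
            try:
                hits.append(
                    HitRecord(
                        orf_id=row.get("qseqid", fields[0]),
                        subject_id=row.get("sseqid", fields[1]),
                        bitscore=bitscore,
                        ko_id=ko,
                        function_label=func,
                        taxonomy_path=tax,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits in the extended tabular format read_hit_table consumes."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(STANDARD_COLUMNS + list(_EXTENSION_COLUMNS)) + "\n")
        for h in hits:
            std = [
                h.orf_id, h.subject_id, "0.0", "0", "0", "0",
                "0", "0", "0", "0", "0.0", f"{h.bitscore:g}",
            ]
            ext = [
                h.ko_id or "-",
                h.function_label or "-",
                h.taxonomy_path.to_string() if h.taxonomy_path else "-",
            ]
            fh.write("\t".join(std + ext) + "\n")


def read_domain_table(path: str | Path) -> list[DomainHit]:
    """Read a 4-column TSV of domain hits: orf_id, domain_id, score, evalue."""
    path = Path(path)
    out: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                out.append(
                    DomainHit(
                        orf_id=fields[0],
                        domain_id=fields[1],
                        score=float(fields[2]),
                        evalue=float(fields[3]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#orf_id\tdomain_id\tscore\tevalue\n")
        for h in hits:
            fh.write(f"{h.orf_id}\t{h.domain_id}\t{h.score:g}\t{h.evalue:g}\n")


def read_motif_library(path: str | Path) -> MotifLibrary:
    """Read an aligned FASTA of equal-length DNA sites (the lux-box library)."""
    path = Path(path)
    ids: list[str] = []
    sites: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"site {rec.id!r} contains disallowed characters {sorted(bad)} "
                "(only N is accepted as ambiguity)"
            )
        ids.append(rec.id)
        sites.append(seq)
    widths = {len(s) for s in sites}
    if len(widths) > 1:
        offenders = [i for i, s in zip(ids, sites) if len(s) != max(widths)]
        raise FormatError(
            f"aligned sites must share one length; offending ids: {offenders}"
        )
    return MotifLibrary(ids=tuple(ids), sites=tuple(sites))
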