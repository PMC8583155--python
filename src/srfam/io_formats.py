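"""Readers and writers for the external formats the pipeline touches.

All downstream modules consume only the domain types defined here. Internal
coordinates are uniformly 0-based half-open; every user-facing table is
written 1-based inclusive, so this module is the single conversion point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# 20 standard residues plus X for an unknown residue.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

DomainKind = Literal["RRM", "ZF_CCHC", "OTHER"]

#: Pfam accession/name -> internal domain kind.
DOMAIN_NAME_MAP = {
    "RRM_1": "RRM",
    "RRM": "RRM",
    "PF00076": "RRM",
    "zf-CCHC": "ZF_CCHC",
    "ZF_CCHC": "ZF_CCHC",
    "PF00098": "ZF_CCHC",
}

#: Default per-domain E-value cutoff used when reading hit tables.
DEFAULT_EVALUE_CUTOFF = 1e-5


class FormatError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence flowing through detection and classification."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"protein id must be a whitespace-free token: {self.id!r}")
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue(s) {sorted(bad)}; "
                "allowed are the 20 standard amino acids plus X"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DomainHit:
    """A structured-domain hit (e.g. Pfam RRM) on a protein, 0-based half-open."""

    protein_id: str
    domain_kind: DomainKind
    start: int
    end: int
    evalue: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.protein_id}: bad hit coordinates [{self.start}, {self.end})"
            )
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}: negative E-value {self.evalue}")


@dataclass(frozen=True)
class GeneModel:
    """A transcript's exon chain in 0-based half-open genomic coordinates."""

    gene_id: str
    transcript_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    chromosome: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.transcript_id}: empty exon ({start}, {end})")
            if start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class CollinearPair:
    """A collinear (syntenic) gene pair, optionally with its CDS alignment."""

    gene_a: str
    gene_b: str
    block_id: str = ""
    alignment: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are upper-cased; residues outside the 20 standard letters
    plus X are rejected, as are duplicate identifiers. An empty file
    yields an empty list.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("*", "")
        try:
            records.append(ProteinRecord(rec.id, seq, rec.description))
        except ValueError as exc:
            raise FormatError(f"{path}: record {rec.id!r}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Domain hit tables


def _map_domain_kind(name: str) -> DomainKind:
    kind = DOMAIN_NAME_MAP.get(name)
    if kind is None:
        base = name.split(".")[0]  # strip Pfam accession version
        kind = DOMAIN_NAME_MAP.get(base)
    if kind is None:
        logger.warning("unknown domain accession %r mapped to OTHER", name)
        return "OTHER"
    return kind


def read_domain_hits(
    path: str | Path,
    dialect: Literal["domtblout", "tsv"] = "tsv",
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[DomainHit]:
    """Read per-domain hits from HMMER3 ``--domtblout`` output or a 5-column TSV.

    The TSV dialect carries ``protein_id  domain  start  end  evalue`` with
    1-based inclusive coordinates, matching the envelope convention of the
    HMMER table; both are converted to 0-based half-open here. Hits with an
    E-value above ``evalue_cutoff`` (default 1e-5) are dropped.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "domtblout":
                    # hmmscan: target (domain model) name, query (protein)
                    # name in col 4; i-Evalue col 13; envelope col 20/21.
                    if len(fields) < 22:
                        raise FormatError(
                            f"{path}:{lineno}: domtblout row has "
                            f"{len(fields)} fields, expected >= 22"
                        )
                    name, protein_id = fields[0], fields[3]
                    evalue = float(fields[12])
                    start1, end1 = int(fields[19]), int(fields[20])
                else:
                    if len(fields) != 5:
                        if lineno == 1 and not _looks_numeric(fields, (2, 3)):
                            continue  # header row
                        raise FormatError(
                            f"{path}:{lineno}: expected 5 columns "
                            "(protein_id, domain, start, end, evalue)"
                        )
                    if lineno == 1 and not _looks_numeric(fields, (2, 3)):
                        continue  # header row
                    protein_id, name = fields[0], fields[1]
                    start1, end1 = int(fields[2]), int(fields[3])
                    evalue = float(fields[4])
            except (ValueError, IndexError) as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if evalue > evalue_cutoff:
                continue
            hits.append(
                DomainHit(
                    protein_id=protein_id,
                    domain_kind=_map_domain_kind(name),
                    start=start1 - 1,
                    end=end1,
                    evalue=evalue,
                    source=name,
                )
            )
    return hits


def _looks_numeric(fields: list[str], idx: tuple[int, ...]) -> bool:
    try:
        for i in idx:
            int(fields[i])
    except (ValueError, IndexError):
        return False
    return True


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits as the 5-column TSV dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain\tstart\tend\tevalue\n")
        for h in hits:
            name = h.source or h.domain_kind
            fh.write(f"{h.protein_id}\t{name}\t{h.start + 1}\t{h.end}\t{h.evalue:g}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon features from a GFF3 file, one model per mRNA.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Exons without a parent mRNA are skipped with a warning.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    known_mrnas = {f.id for f in db.features_of_type("mRNA")}
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else mrna.id
        exons = sorted(
            (exon.start - 1, exon.end)
            for exon in db.children(mrna, featuretype="exon", order_by="start")
        )
        if not exons:
            logger.warning("mRNA %s has no exons; skipped", mrna.id)
            continue
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                strand=mrna.strand if mrna.strand in "+-" else "+",
                exons=tuple(exons),
                chromosome=mrna.seqid,
            )
        )
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or all(p not in known_mrnas for p in parents):
            logger.warning(
                "exon at %s:%d-%d has no parent mRNA; skipped",
                exon.seqid, exon.start, exon.end,
            )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon features for the supplied models."""
    models = list(models)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[GeneModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gene_id, mrnas in by_gene.items():
            start = min(m.span[0] for m in mrnas)
            end = max(m.span[1] for m in mrnas)
            chrom = mrnas[0].chromosome or "."
            strand = mrnas[0].strand
            fh.write(
                f"{chrom}\tsrfam\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for m in mrnas:
                s, e = m.span
                fh.write(
                    f"{chrom}\tsrfam\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id};Parent={gene_id}\n"
                )
                for i, (xs, xe) in enumerate(m.exons, start=1):
                    fh.write(
                        f"{chrom}\tsrfam\texon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\t"
                        f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Collinearity pair lists


def read_collinearity(path: str | Path) -> list[CollinearPair]:
    """Read MCScanX ``.collinearity`` output or a two-column TSV of gene pairs.

    Comment lines (``#``) and alignment headers are ignored; self-pairs are
    dropped with a warning.
    """
    path = Path(path)
    pairs: list[CollinearPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            block_id = ""
            if ":" in line:
                # MCScanX body line: " 0-  0:\tgeneA\tgeneB\t  1e-50"
                head, _, rest = line.partition(":")
                block_id = head.strip().replace(" ", "")
                fields = rest.split()
            else:
                fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least two gene ids")
            gene_a, gene_b = fields[0], fields[1]
            if lineno == 1 and gene_a.lower() in {"gene_a", "genea", "gene1"}:
                continue  # header row of the TSV dialect
            if gene_a == gene_b:
                logger.warning("%s:%d: self-pair %s dropped", path, lineno, gene_a)
                continue
            pairs.append(CollinearPair(gene_a, gene_b, block_id))
    return pairs


# ---------------------------------------------------------------------------
# Aligned CDS pair tables (for Ks estimation)


def read_alignment_pairs(path: str | Path) -> list[CollinearPair]:
    """Read a TSV of (id_a, id_b, aligned_a, aligned_b) rows."""
    path = Path(path)
    pairs: list[CollinearPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"id_a", "gene_a"}:
                continue
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 columns (id_a, id_b, aln_a, aln_b)"
                )
            a, b = fields[2].upper(), fields[3].upper()
            if len(a) != len(b):
                raise FormatError(f"{path}:{lineno}: aligned lengths differ")
            pairs.append(CollinearPair(fields[0], fields[1], alignment=(a, b)))
    return pairs


def write_alignment_pairs(pairs: Iterable[CollinearPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\taln_a\taln_b\n")
        for p in pairs:
            if p.alignment is None:
                raise ValueError(f"pair {p.gene_a}/{p.gene_b} has no alignment")
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.alignment[0]}\t{p.alignment[1]}\n")
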