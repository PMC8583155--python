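"""Exon/intron structure summaries per gene and per subfamily."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .architecture import SubfamilyCall
from .io_formats import GeneModel


@dataclass(frozen=True)
class StructureSummary:
    gene_id: str
    transcript_id: str
    n_exons: int
    n_introns: int
    intron_lengths: tuple[int, ...]


def count_introns(model: GeneModel) -> StructureSummary:
    """Introns are the gaps between consecutive sorted exons."""
    lengths = tuple(
        nxt[0] - prev[1] for prev, nxt in zip(model.exons, model.exons[1:])
    )
    if any(length <= 0 for length in lengths):
        raise ValueError(f"{model.transcript_id}: non-positive intron length")
    return StructureSummary(
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
        n_exons=len(model.exons),
        n_introns=len(model.exons) - 1,
        intron_lengths=lengths,
    )


def representative_transcript(models: list[GeneModel]) -> dict[str, GeneModel]:
    """Pick one transcript per gene: the one with the longest summed exon length.

    Ties break on transcript id for determinism. Phytozome-style annotations
    mark a primary transcript; when only exon chains are available the
    longest isoform is the usual stand-in.
    """
    best: dict[str, GeneModel] = {}
    for m in models:
        key = (sum(e - s for s, e in m.exons), m.transcript_id)
        incumbent = best.get(m.gene_id)
        if incumbent is None:
            best[m.gene_id] = m
        else:
            inc_key = (sum(e - s for s, e in incumbent.exons), incumbent.transcript_id)
            if key > inc_key:
                best[m.gene_id] = m
    return best


def subfamily_structure_table(
    summaries: list[StructureSummary],
    calls: list[SubfamilyCall],
    gene_to_protein: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Group intron counts by subfamily; flag subfamilies with a uniform count.

    ``gene_to_protein`` maps gene ids to protein ids when they differ;
    genes without a subfamily call are grouped under UNCLASSIFIED.
    """
    call_by_protein = {c.protein_id: c.subfamily for c in calls}
    rows = []
    for s in summaries:
        protein_id = (gene_to_protein or {}).get(s.gene_id, s.gene_id)
        subfamily = call_by_protein.get(protein_id, "UNCLASSIFIED")
        rows.append((subfamily, s.gene_id, s.n_introns))
    if not rows:
        return pd.DataFrame(
            columns=["subfamily", "n_genes", "min_introns", "max_introns",
                     "mode_introns", "uniform"]
        )
    df = pd.DataFrame(rows, columns=["subfamily", "gene_id", "n_introns"])
    out = []
    for subfamily, grp in df.groupby("subfamily", sort=True):
        counts = grp["n_introns"]
        mode = Counter(counts).most_common(1)[0][0]
        out.append(
            {
                "subfamily": subfamily,
                "n_genes": len(grp),
                "min_introns": int(counts.min()),
                "max_introns": int(counts.max()),
                "mode_introns": int(mode),
                "uniform": bool(counts.nunique() == 1),
            }
        )
    return pd.DataFrame(out)


def structure_table(summaries: list[StructureSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tn_exons\tn_introns\tintron_lengths\n")
        for s in summaries:
            lengths = ",".join(str(x) for x in s.intron_lengths)
            fh.write(
                f"{s.gene_id}\t{s.transcript_id}\t{s.n_exons}\t{s.n_introns}\t"
                f"{lengths}\n"
            )
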