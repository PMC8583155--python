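"""Seeded generators for every input the pipeline consumes.

The generators plant known subfamily architectures, RS-domain spans, Ks
values and fold changes, and emit a truth ledger alongside each output so
recovery can be tested offline. Domain-hit tables are emitted by the
generator itself (placeholder RRM/zinc-knuckle segments are not required to
be recognisable by real profile HMMs), so no external scanner is needed.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import SIGNATURE_MOTIF, SUBFAMILIES
from .io_formats import (
    DomainHit,
    GeneModel,
    ProteinRecord,
    write_domain_hits,
    write_fasta,
    write_gff3,
)
from .ks_dating import (
    CODON_TO_AA,
    NUCLEOTIDES,
    STOP_CODONS,
    CodonAlignmentPair,
    ng86_sites,
)

# Filler alphabets contain no serine (and, inside dipeptide-bearing
# segments, no arginine/proline either), so RS/SR/SP/PS pairs can only
# arise where the generator plants them.
GENERIC_FILLER = "ACDEFGHIKLMNPQRTVWY"
SEGMENT_FILLER = "ADEGKNQT"

DECOY_CLASSES = ("RRM_only", "RS_only", "random")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the generators.

    Defaults give clear-margin positives: RS stretches of 60 residues at
    ~50% dipeptide coverage (well above the 20% identification threshold),
    exact SWQDLKD signatures, and unambiguous domain counts.
    """

    seed: int = 0
    subfamily_counts: dict = field(
        default_factory=lambda: {s: 6 for s in SUBFAMILIES}
    )
    decoy_counts: dict = field(
        default_factory=lambda: {"RRM_only": 2, "RS_only": 2, "random": 1}
    )
    rs_content_target: float = 0.5
    rs_len_target: int = 60
    ks_targets: tuple = ((0.3, 10), (1.8, 10))
    n_codons: int = 300
    qpcr_folds: tuple = (1.0, 4.0, 0.25)
    qpcr_replicates: int = 3
    ct_noise_sd: float = 0.1
    exon_count_ranges: dict = field(
        default_factory=lambda: {
            "SR": (13, 14),
            "RS2Z": (7, 7),
            "default": (5, 10),
        }
    )

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.subfamily_counts.values()):
            raise ValueError("subfamily counts must be >= 0")
        if any(v < 0 for v in self.decoy_counts.values()):
            raise ValueError("decoy counts must be >= 0")
        if self.rs_content_target <= 0.20:
            raise ValueError(
                "rs_content_target must exceed the 20% identification threshold"
            )


def _filler(rng: np.random.Generator, n: int, alphabet: str = GENERIC_FILLER) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n > 0 else ""


def _rs_stretch(rng: np.random.Generator, length: int, content: float) -> str:
    """A serine/arginine-rich segment of the given length and RS/SR coverage."""
    n_units = max(1, round(content * length / 2))
    filler_len = length - 2 * n_units
    if filler_len < 0:
        raise ValueError("content target too high for length")
    # Distribute filler residues as evenly as possible between the units.
    gaps = np.full(n_units + 1, filler_len // (n_units + 1))
    gaps[: filler_len % (n_units + 1)] += 1
    parts = []
    for i in range(n_units):
        parts.append(_filler(rng, int(gaps[i]), SEGMENT_FILLER))
        parts.append(rng.choice(["RS", "SR"]))
    parts.append(_filler(rng, int(gaps[-1]), SEGMENT_FILLER))
    return "".join(parts)


def _sp_stretch(rng: np.random.Generator, length: int, content: float) -> str:
    """An SP-dipeptide-rich segment (RS2Z tail)."""
    n_units = max(1, round(content * length / 2))
    filler_len = length - 2 * n_units
    gaps = np.full(n_units + 1, filler_len // (n_units + 1))
    gaps[: filler_len % (n_units + 1)] += 1
    parts = []
    for i in range(n_units):
        parts.append(_filler(rng, int(gaps[i]), SEGMENT_FILLER))
        parts.append(rng.choice(["SP", "PS"]))
    parts.append(_filler(rng, int(gaps[-1]), SEGMENT_FILLER))
    return "".join(parts)


def _rrm_placeholder(rng: np.random.Generator, with_motif: bool = False) -> str:
    """A 70-90 residue placeholder RRM segment, optionally carrying SWQDLKD."""
    n = int(rng.integers(70, 91))
    seq = _filler(rng, n)
    if with_motif:
        pos = n // 2
        seq = seq[:pos] + SIGNATURE_MOTIF + seq[pos + len(SIGNATURE_MOTIF):]
    return seq


def _zf_placeholder(rng: np.random.Generator) -> str:
    """A CCHC zinc-knuckle placeholder: C-x2-C-x4-H-x4-C."""
    return (
        "C" + _filler(rng, 2) + "C" + _filler(rng, 4)
        + "H" + _filler(rng, 4) + "C"
    )


def _n_terminal_extension(rng: np.random.Generator) -> str:
    """A short extension with four RS/SP dipeptides (the SCL hallmark)."""
    parts = ["M"]
    for _ in range(4):
        parts.append(_filler(rng, int(rng.integers(1, 3)), SEGMENT_FILLER))
        parts.append(str(rng.choice(["RS", "SP"])))
    return "".join(parts)


def generate_protein(
    subfamily: str, spec: SyntheticSpec, rng: np.random.Generator, index: int = 0
) -> tuple[ProteinRecord, list[DomainHit], dict]:
    """Generate one protein with a planted architecture and matching hits.

    ``subfamily`` is one of the six subfamily labels or a decoy class
    (RRM_only, RS_only, random).
    """
    if subfamily not in SUBFAMILIES + DECOY_CLASSES:
        raise ValueError(f"unknown subfamily/decoy class {subfamily!r}")
    pid = f"syn_{subfamily}_{index:03d}"
    segments: list[tuple[str, str]] = []  # (segment_kind, sequence)

    def linker(lo: int = 8, hi: int = 20) -> tuple[str, str]:
        return ("linker", _filler(rng, int(rng.integers(lo, hi))))

    if subfamily == "SCL":
        segments.append(("n_ext", _n_terminal_extension(rng)))
    else:
        segments.append(("prefix", "M" + _filler(rng, int(rng.integers(3, 10)))))

    if subfamily in ("SR", "RS"):
        segments.append(("RRM", _rrm_placeholder(rng)))
        segments.append(linker())
        segments.append(("RRM", _rrm_placeholder(rng, with_motif=subfamily == "SR")))
    elif subfamily in ("RSZ", "RS2Z", "SCL", "SC", "RRM_only"):
        segments.append(("RRM", _rrm_placeholder(rng)))
    if subfamily == "RSZ":
        segments.append(linker())
        segments.append(("ZF", _zf_placeholder(rng)))
    elif subfamily == "RS2Z":
        segments.append(linker())
        segments.append(("ZF", _zf_placeholder(rng)))
        segments.append(linker())
        segments.append(("ZF", _zf_placeholder(rng)))

    if subfamily in SUBFAMILIES + ("RS_only",):
        segments.append(linker())
        segments.append(
            ("RS_STRETCH", _rs_stretch(rng, spec.rs_len_target, spec.rs_content_target))
        )
    if subfamily == "RS2Z":
        segments.append(("SP_TAIL", _sp_stretch(rng, 30, 0.5)))
    if subfamily in ("RRM_only", "random"):
        segments.append(("tail", _filler(rng, int(rng.integers(60, 120)))))

    seq_parts: list[str] = []
    hits: list[DomainHit] = []
    truth: dict = {"protein_id": pid, "label": subfamily,
                   "rs_start": -1, "rs_end": -1, "n_rrm": 0, "n_zf": 0}
    offset = 0
    for kind, seg in segments:
        if kind == "RRM":
            hits.append(DomainHit(pid, "RRM", offset, offset + len(seg),
                                  evalue=1e-20, source="RRM_1"))
            truth["n_rrm"] += 1
        elif kind == "ZF":
            hits.append(DomainHit(pid, "ZF_CCHC", offset, offset + len(seg),
                                  evalue=1e-10, source="zf-CCHC"))
            truth["n_zf"] += 1
        elif kind == "RS_STRETCH":
            truth["rs_start"], truth["rs_end"] = offset, offset + len(seg)
        seq_parts.append(seg)
        offset += len(seg)
    record = ProteinRecord(pid, "".join(seq_parts), f"synthetic {subfamily}")
    return record, hits, truth


@dataclass
class ProteomeBundle:
    records: list[ProteinRecord]
    hits: list[DomainHit]
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteome.fasta",
            "hits": out / "domain_hits.tsv",
            "truth": out / "proteome_truth.tsv",
        }
        write_fasta(self.records, paths["fasta"])
        write_domain_hits(self.hits, paths["hits"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_proteome(spec: SyntheticSpec) -> ProteomeBundle:
    """Generate a shuffled synthetic proteome with its hit table and truth ledger."""
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    truth_rows: list[dict] = []
    for subfamily in SUBFAMILIES:
        for i in range(spec.subfamily_counts.get(subfamily, 0)):
            rec, h, t = generate_protein(subfamily, spec, rng, i)
            records.append(rec)
            hits.extend(h)
            truth_rows.append(t)
    for decoy in DECOY_CLASSES:
        for i in range(spec.decoy_counts.get(decoy, 0)):
            rec, h, t = generate_protein(decoy, spec, rng, i)
            records.append(rec)
            hits.extend(h)
            truth_rows.append(t)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = pd.DataFrame(
        [truth_rows[i] for i in order],
        columns=["protein_id", "label", "rs_start", "rs_end", "n_rrm", "n_zf"],
    )
    return ProteomeBundle(records, hits, truth)


def generate_gene_models(
    labels: dict[str, str], spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Generate one gene model per protein, with subfamily-typical exon counts.

    ``labels`` maps protein/gene id -> subfamily label. Defaults plant
    13-14 exons for SR genes (12-13 introns), 7 for RS2Z (uniformly six
    introns) and 5-10 elsewhere.
    """
    models: list[GeneModel] = []
    truth_rows = []
    for gene_id in sorted(labels):
        subfamily = labels[gene_id]
        lo, hi = spec.exon_count_ranges.get(
            subfamily, spec.exon_count_ranges["default"]
        )
        n_exons = int(rng.integers(lo, hi + 1))
        pos = int(rng.integers(1000, 100_000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(50, 301))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(50, 501))
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.1",
                strand=str(rng.choice(["+", "-"])),
                exons=tuple(exons),
                chromosome=f"Chr{int(rng.integers(1, 20)):02d}",
            )
        )
        truth_rows.append(
            {"gene_id": gene_id, "label": subfamily, "n_introns": n_exons - 1}
        )
    return models, pd.DataFrame(truth_rows, columns=["gene_id", "label", "n_introns"])


# ---------------------------------------------------------------------------
# Codon-pair evolution

_NONSTOP_CODONS = sorted(CODON_TO_AA)


def _substitution_opportunities(codon: str, synonymous: bool) -> list[str]:
    """One-step non-stop mutants of a codon, synonymous or nonsynonymous."""
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            if (CODON_TO_AA[mutant] == aa) == synonymous:
                out.append(mutant)
    return out


_SYN_OPPORTUNITIES = {c: _substitution_opportunities(c, True) for c in _NONSTOP_CODONS}
_NONSYN_OPPORTUNITIES = {c: _substitution_opportunities(c, False) for c in _NONSTOP_CODONS}


def _apply_events(
    codons: list[str], n_events: int, table: dict, rng: np.random.Generator
) -> int:
    """Apply substitution events at uniformly chosen opportunities; returns
    the number actually applied (an event on a codon with no opportunity of
    the requested class is redrawn across the remaining opportunities)."""
    applied = 0
    counts = np.fromiter((len(table[c]) for c in codons), dtype=int)
    for _ in range(n_events):
        total = int(counts.sum())
        if total == 0:
            break
        pick = int(rng.integers(total))
        cum = np.cumsum(counts)
        idx = int(np.searchsorted(cum, pick, side="right"))
        within = pick - (int(cum[idx - 1]) if idx else 0)
        codons[idx] = table[codons[idx]][within]
        counts[idx] = len(table[codons[idx]])
        applied += 1
    return applied


def generate_codon_pair(
    ks_true: float,
    n_codons: int,
    rng: np.random.Generator,
    ka_true: float = 0.0,
    id_prefix: str = "pair",
) -> tuple[CodonAlignmentPair, dict]:
    """Evolve a stop-free ancestor to a target synonymous divergence.

    One copy receives Poisson(ks_true x s_sites) synonymous one-step
    substitutions at uniformly chosen synonymous opportunities (stop codons
    rejected), plus optionally Poisson(ka_true x n_sites) nonsynonymous
    ones. The truth dict records the realised event counts.
    """
    if ks_true < 0 or ka_true < 0:
        raise ValueError("divergence targets must be >= 0")
    ancestor = [
        _NONSTOP_CODONS[i]
        for i in rng.integers(len(_NONSTOP_CODONS), size=n_codons)
    ]
    seq_a = "".join(ancestor)
    s_sites, n_sites = ng86_sites(seq_a)
    derived = list(ancestor)
    n_syn = _apply_events(
        derived, int(rng.poisson(ks_true * s_sites)), _SYN_OPPORTUNITIES, rng
    )
    n_nonsyn = 0
    if ka_true > 0:
        n_nonsyn = _apply_events(
            derived, int(rng.poisson(ka_true * n_sites)), _NONSYN_OPPORTUNITIES, rng
        )
    pair = CodonAlignmentPair(
        f"{id_prefix}_a", f"{id_prefix}_b", seq_a, "".join(derived)
    )
    truth = {
        "ks_true": ks_true,
        "ka_true": ka_true,
        "n_syn_events": n_syn,
        "n_nonsyn_events": n_nonsyn,
        "s_sites": s_sites,
        "n_sites": n_sites,
    }
    return pair, truth


# ---------------------------------------------------------------------------
# qPCR and expression tables


def generate_qpcr_table(
    folds, spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triplicate Ct table with planted fold changes.

    Reference genes REF1/REF2 sit at a constant baseline; each target gene
    G<i> is shifted by -log2(fold) cycles in the treatment condition.
    Returns (long-format Ct table, truth table).
    """
    rows = []
    truth_rows = []
    conditions = {"control": 0.0}
    for i, fold in enumerate(folds, start=1):
        if fold <= 0:
            raise ValueError("planted folds must be positive")
        gene = f"G{i}"
        truth_rows.append({"gene": gene, "fold_true": fold})
        for condition in ("control", "treatment"):
            shift = -np.log2(fold) if condition == "treatment" else 0.0
            for rep in range(1, spec.qpcr_replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "replicate": rep,
                        "ct": 24.0 + shift + rng.normal(0.0, spec.ct_noise_sd),
                    }
                )
    for ref in ("REF1", "REF2"):
        base = 19.0 if ref == "REF1" else 21.0
        for condition in ("control", "treatment"):
            for rep in range(1, spec.qpcr_replicates + 1):
                rows.append(
                    {
                        "gene": ref,
                        "condition": condition,
                        "replicate": rep,
                        "ct": base + rng.normal(0.0, spec.ct_noise_sd),
                    }
                )
    del conditions
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def generate_expression_table(
    n_deg: int, n_background: int, rng: np.random.Generator
) -> pd.DataFrame:
    """An RNA-seq summary table with known DEG labels in column ``is_deg``.

    DEG rows pass all three threshold criteria (TMM sum >= 5, |log2FC| > 1,
    FDR < 0.05); background rows fail at least one, chosen at random.
    """
    rows = []
    for i in range(n_deg):
        rows.append(
            {
                "gene": f"deg_{i:03d}",
                "tmm_sum": float(5.0 + rng.uniform(0.0, 95.0)),
                "log2fc": float(rng.choice([-1.0, 1.0]) * rng.uniform(1.1, 5.0)),
                "fdr": float(rng.uniform(1e-6, 0.049)),
                "is_deg": True,
            }
        )
    for i in range(n_background):
        tmm = float(5.0 + rng.uniform(0.0, 95.0))
        fc = float(rng.choice([-1.0, 1.0]) * rng.uniform(1.1, 5.0))
        fdr = float(rng.uniform(1e-6, 0.049))
        fail = rng.choice(["tmm", "fc", "fdr"])
        if fail == "tmm":
            tmm = float(rng.uniform(0.0, 4.9))
        elif fail == "fc":
            fc = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.0, 0.99))
        else:
            fdr = float(rng.uniform(0.051, 1.0))
        rows.append(
            {"gene": f"bg_{i:03d}", "tmm_sum": tmm, "log2fc": fc,
             "fdr": fdr, "is_deg": False}
        )
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


def write_gene_models(models: list[GeneModel], path: str | Path) -> None:
    write_gff3(models, path)
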