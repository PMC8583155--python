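"""RS-domain detection.

A plant RS domain is a serine/arginine-rich region of at least ``min_len``
residues (default 50) in which more than ``min_content`` (default 20%) of
residues are covered by consecutive RS or SR dipeptides. Detection scans all
windows of length exactly ``min_len``; every window whose covered fraction
passes the threshold qualifies, and each maximal run of the union of
qualifying windows is reported as one domain. The reported ``content`` is
computed over the merged span and may fall below the threshold even though
every generating window passed — the threshold applies to windows, not to
the merged report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ProteinRecord


@dataclass(frozen=True)
class RSDomainParams:
    """Tunable parameters of the RS-domain definition.

    ``strict`` selects a strictly-greater content comparison ("over 20%");
    set it to False for >=.
    """

    min_len: int = 50
    min_content: float = 0.20
    strict: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if not (0.0 < self.min_content < 1.0):
            raise ValueError("min_content must lie in (0, 1)")

    def passes(self, covered: int, length: int) -> bool:
        frac = covered / length
        return frac > self.min_content if self.strict else frac >= self.min_content


@dataclass(frozen=True)
class RSDomain:
    """A maximal reported RS-rich region, 0-based half-open."""

    protein_id: str
    start: int
    end: int
    covered: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def content(self) -> float:
        return self.covered / self.length


def dipeptide_coverage(seq: str) -> np.ndarray:
    """Boolean mask marking residues lying in an adjacent RS or SR pair.

    Overlaps are allowed ("RSR" is fully covered); X never participates.
    """
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    if n < 2:
        return mask
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    r, s = ord("R"), ord("S")
    pair = ((arr[:-1] == r) & (arr[1:] == s)) | ((arr[:-1] == s) & (arr[1:] == r))
    mask[:-1] |= pair
    mask[1:] |= pair
    return mask


def window_content(mask: np.ndarray, start: int, end: int) -> float:
    """Fraction of covered residues in [start, end)."""
    if not (0 <= start < end <= len(mask)):
        raise ValueError(f"window [{start}, {end}) out of range for length {len(mask)}")
    return float(np.count_nonzero(mask[start:end])) / (end - start)


def find_rs_domains(
    record: ProteinRecord, params: RSDomainParams = RSDomainParams()
) -> list[RSDomain]:
    """Detect RS domains as maximal unions of qualifying fixed-length windows."""
    n = len(record.seq)
    L = params.min_len
    if n < L:
        return []
    mask = dipeptide_coverage(record.seq)
    prefix = np.concatenate(([0], np.cumsum(mask)))
    counts = prefix[L:] - prefix[:-L]  # covered residues per window start
    if params.strict:
        ok = counts > params.min_content * L
    else:
        ok = counts >= params.min_content * L
    starts = np.flatnonzero(ok)
    if starts.size == 0:
        return []
    # Union of [s, s+L) for qualifying starts; maximal runs of the union.
    domains: list[RSDomain] = []
    run_start = int(starts[0])
    run_end = run_start + L
    for s in starts[1:]:
        s = int(s)
        if s <= run_end:  # windows overlap or touch: same run
            run_end = s + L
        else:
            covered = int(prefix[run_end] - prefix[run_start])
            domains.append(RSDomain(record.id, run_start, run_end, covered))
            run_start, run_end = s, s + L
    covered = int(prefix[run_end] - prefix[run_start])
    domains.append(RSDomain(record.id, run_start, run_end, covered))
    return domains


def has_rs_domain(
    record: ProteinRecord, params: RSDomainParams = RSDomainParams()
) -> bool:
    """True iff the protein carries at least one RS domain under ``params``."""
    return bool(find_rs_domains(record, params))


def rs_domain_table(domains: list[RSDomain], path) -> None:
    """Write detected domains as TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tlength\tcovered\tcontent\n")
        for d in domains:
            fh.write(
                f"{d.protein_id}\t{d.start + 1}\t{d.end}\t{d.length}\t"
                f"{d.covered}\t{d.content:.6f}\n"
            )
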