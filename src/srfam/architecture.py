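"""Domain-architecture assembly and the six-subfamily rule classifier.

Plant SR proteins carry one or two RNA recognition motifs (RRMs) followed
by an RS domain; subfamilies are distinguished by the RRM count, the
SWQDLKD heptamer in the second RRM (SR vs RS), CCHC zinc knuckles (one for
RSZ, two for RS2Z), and an N-terminal RS/SP-dipeptide extension (SCL vs
SC). Proteins with three or more RRMs fall outside the described
architectures and are left UNCLASSIFIED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import DomainHit, ProteinRecord
from .rs_domain import RSDomain, RSDomainParams, find_rs_domains

SUBFAMILIES = ("SR", "SC", "RSZ", "RS", "SCL", "RS2Z")

SIGNATURE_MOTIF = "SWQDLKD"


@dataclass(frozen=True)
class ClassifierConfig:
    """Parameters for the qualitative architecture descriptors.

    The SP-rich and N-terminal-extension thresholds quantify descriptors
    that are usually stated only qualitatively; they are explicit here so
    every run logs them.
    """

    swqdlkd_max_mismatch: int = 0
    sp_rich_min_len: int = 20
    sp_rich_min_content: float = 0.20
    n_ext_min_dipeptides: int = 2

    def __post_init__(self) -> None:
        if min(self.swqdlkd_max_mismatch, self.sp_rich_min_len,
               self.n_ext_min_dipeptides) < 0 or self.sp_rich_min_content < 0:
            raise ValueError("classifier thresholds must be non-negative")


@dataclass(frozen=True)
class Architecture:
    """Ordered structured-domain layout of one protein."""

    protein_id: str
    rrm_regions: tuple[tuple[int, int], ...]
    zf_regions: tuple[tuple[int, int], ...]
    rs_domains: tuple[RSDomain, ...]
    has_swqdlkd_in_rrm2: bool = False
    has_sp_rich: bool = False
    has_n_terminal_extension: bool = False

    @property
    def n_rrm(self) -> int:
        return len(self.rrm_regions)

    @property
    def n_zf(self) -> int:
        return len(self.zf_regions)

    @property
    def n_rs(self) -> int:
        return len(self.rs_domains)


@dataclass(frozen=True)
class SubfamilyCall:
    protein_id: str
    subfamily: str  # one of SUBFAMILIES or "UNCLASSIFIED"
    rule_trace: tuple[str, ...] = ()


@dataclass(frozen=True)
class Reject:
    protein_id: str
    reasons: tuple[str, ...]  # subset of {"NO_RRM", "NO_RS_DOMAIN"}


def merge_regions(
    regions: list[tuple[int, int]], min_reciprocal_overlap: float = 0.5
) -> tuple[tuple[int, int], ...]:
    """Merge same-kind hit regions that overlap by >= 50% of the shorter hit.

    hmmscan frequently reports split envelopes for one structural domain;
    merging prevents double-counting RRMs. Regions below the overlap
    threshold are kept distinct.
    """
    if not regions:
        return ()
    regions = sorted(regions)
    merged = [list(regions[0])]
    for start, end in regions[1:]:
        prev = merged[-1]
        overlap = min(prev[1], end) - max(prev[0], start)
        shorter = min(prev[1] - prev[0], end - start)
        if overlap > 0 and overlap >= min_reciprocal_overlap * shorter:
            prev[1] = max(prev[1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def _sp_coverage(seq: str) -> np.ndarray:
    """Residue mask for adjacent SP or PS pairs (same semantics as RS coverage)."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    if n < 2:
        return mask
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    s, p = ord("S"), ord("P")
    pair = ((arr[:-1] == s) & (arr[1:] == p)) | ((arr[:-1] == p) & (arr[1:] == s))
    mask[:-1] |= pair
    mask[1:] |= pair
    return mask


def detect_signature_motif(
    seq: str,
    rrm_regions: tuple[tuple[int, int], ...],
    config: ClassifierConfig = ClassifierConfig(),
) -> bool:
    """True iff SWQDLKD occurs (within the mismatch budget) inside the second RRM."""
    if len(rrm_regions) < 2:
        return False
    start, end = rrm_regions[1]
    region = seq[start:end]
    k = len(SIGNATURE_MOTIF)
    for i in range(len(region) - k + 1):
        mismatches = sum(a != b for a, b in zip(region[i:i + k], SIGNATURE_MOTIF))
        if mismatches <= config.swqdlkd_max_mismatch:
            return True
    return False


def detect_sp_rich_region(
    seq: str,
    rs_domains: tuple[RSDomain, ...],
    config: ClassifierConfig = ClassifierConfig(),
) -> bool:
    """True iff downstream of the last RS domain some window of length
    >= ``sp_rich_min_len`` has SP/PS-dipeptide coverage >= ``sp_rich_min_content``.

    Without an RS domain the whole sequence is scanned.
    """
    tail_start = max((d.end for d in rs_domains), default=0)
    tail = seq[tail_start:]
    L = config.sp_rich_min_len
    if len(tail) < L:
        return False
    mask = _sp_coverage(tail)
    prefix = np.concatenate(([0.0], np.cumsum(mask)))
    c = config.sp_rich_min_content
    # Window [i, j) with j-i >= L and coverage >= c exists iff
    # g(j) >= g(i) for some admissible i, with g(x) = prefix[x] - c*x.
    g = prefix - c * np.arange(len(prefix))
    best_prev = np.minimum.accumulate(g)
    j = np.arange(L, len(prefix))
    return bool(np.any(g[j] >= best_prev[j - L]))


def detect_n_terminal_extension(
    seq: str,
    rrm_regions: tuple[tuple[int, int], ...],
    config: ClassifierConfig = ClassifierConfig(),
) -> bool:
    """True iff the prefix before the first RRM holds enough RS/SR/SP/PS dipeptides.

    The count is overlap-free, greedy left-to-right.
    """
    if not rrm_regions:
        return False
    prefix = seq[: rrm_regions[0][0]]
    count = 0
    i = 0
    while i < len(prefix) - 1:
        if prefix[i:i + 2] in ("RS", "SR", "SP", "PS"):
            count += 1
            i += 2
        else:
            i += 1
    return count >= config.n_ext_min_dipeptides


def build_architecture(
    record: ProteinRecord,
    hits: list[DomainHit],
    rs_domains: list[RSDomain] | None = None,
    config: ClassifierConfig = ClassifierConfig(),
    rs_params: RSDomainParams = RSDomainParams(),
) -> Architecture:
    """Assemble the structured-domain layout of one protein."""
    n = len(record.seq)
    for h in hits:
        if h.protein_id != record.id:
            raise ValueError(f"hit for {h.protein_id} supplied with record {record.id}")
        if h.end > n:
            raise ValueError(
                f"{record.id}: hit [{h.start}, {h.end}) exceeds length {n}"
            )
    if rs_domains is None:
        rs_domains = find_rs_domains(record, rs_params)
    rrm = merge_regions([(h.start, h.end) for h in hits if h.domain_kind == "RRM"])
    zf = merge_regions([(h.start, h.end) for h in hits if h.domain_kind == "ZF_CCHC"])
    rs = tuple(sorted(rs_domains, key=lambda d: d.start))
    return Architecture(
        protein_id=record.id,
        rrm_regions=rrm,
        zf_regions=zf,
        rs_domains=rs,
        has_swqdlkd_in_rrm2=detect_signature_motif(record.seq, rrm, config),
        has_sp_rich=detect_sp_rich_region(record.seq, rs, config),
        has_n_terminal_extension=detect_n_terminal_extension(record.seq, rrm, config),
    )


def classify_subfamily(arch: Architecture) -> SubfamilyCall:
    """Apply the six-subfamily rules in fixed order; UNCLASSIFIED if none fires."""
    pid = arch.protein_id
    if arch.n_rs < 1 or arch.n_rrm < 1:
        return SubfamilyCall(pid, "UNCLASSIFIED")
    if arch.n_rrm == 2:
        if arch.has_swqdlkd_in_rrm2:
            return SubfamilyCall(pid, "SR", ("R1:two_rrm+swqdlkd",))
        return SubfamilyCall(pid, "RS", ("R2:two_rrm-no_swqdlkd",))
    if arch.n_rrm == 1:
        if arch.n_zf == 2:
            return SubfamilyCall(pid, "RS2Z", ("R3:one_rrm+two_zf",))
        if arch.n_zf == 1:
            return SubfamilyCall(pid, "RSZ", ("R4:one_rrm+one_zf",))
        if arch.has_n_terminal_extension:
            return SubfamilyCall(pid, "SCL", ("R5:one_rrm+n_ext",))
        return SubfamilyCall(pid, "SC", ("R6:one_rrm-no_ext",))
    return SubfamilyCall(pid, "UNCLASSIFIED")  # >= 3 RRMs


@dataclass
class Catalogue:
    """Identification result: accepted SR proteins and rejected candidates."""

    entries: list[tuple[ProteinRecord, Architecture, SubfamilyCall]] = field(
        default_factory=list
    )
    rejects: list[Reject] = field(default_factory=list)

    def subfamily_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in SUBFAMILIES + ("UNCLASSIFIED",)}
        for _, _, call in self.entries:
            counts[call.subfamily] += 1
        return counts


def identify_sr_proteins(
    proteome: list[ProteinRecord],
    hits: list[DomainHit],
    params: RSDomainParams = RSDomainParams(),
    config: ClassifierConfig = ClassifierConfig(),
) -> Catalogue:
    """Screen a proteome for SR proteins and classify each into a subfamily.

    A protein enters the catalogue iff it has at least one RRM hit and at
    least one RS domain; failures are listed in the rejects with reason
    codes NO_RRM / NO_RS_DOMAIN.
    """
    hits_by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    catalogue = Catalogue()
    for record in sorted(proteome, key=lambda r: r.id):
        phits = sorted(
            hits_by_protein.get(record.id, []), key=lambda h: (h.start, h.end)
        )
        rs = find_rs_domains(record, params)
        has_rrm = any(h.domain_kind == "RRM" for h in phits)
        reasons = []
        if not has_rrm:
            reasons.append("NO_RRM")
        if not rs:
            reasons.append("NO_RS_DOMAIN")
        if reasons:
            catalogue.rejects.append(Reject(record.id, tuple(reasons)))
            continue
        arch = build_architecture(record, phits, rs, config, params)
        catalogue.entries.append((record, arch, classify_subfamily(arch)))
    return catalogue


def catalogue_table(catalogue: Catalogue, path) -> None:
    """Write the catalogue TSV (coordinates 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tsubfamily\tn_rrm\tn_zf\tn_rs_domains\trs_coords\t"
            "flags\trule_trace\n"
        )
        for _, arch, call in catalogue.entries:
            coords = ";".join(f"{d.start + 1}-{d.end}" for d in arch.rs_domains)
            flags = ",".join(
                name
                for name, value in [
                    ("SWQDLKD", arch.has_swqdlkd_in_rrm2),
                    ("SP_RICH", arch.has_sp_rich),
                    ("N_EXT", arch.has_n_terminal_extension),
                ]
                if value
            )
            fh.write(
                f"{arch.protein_id}\t{call.subfamily}\t{arch.n_rrm}\t{arch.n_zf}\t"
                f"{arch.n_rs}\t{coords}\t{flags}\t{';'.join(call.rule_trace)}\n"
            )


def rejects_table(catalogue: Catalogue, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\treasons\n")
        for reject in catalogue.rejects:
            fh.write(f"{reject.protein_id}\t{','.join(reject.reasons)}\n")
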