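"""Ka/Ks estimation for collinear CDS pairs and duplication-event dating.

The estimator is Nei–Gojobori (1986) counting with Jukes–Cantor multiple-hit
correction: fractional synonymous/nonsynonymous site counts per codon,
pathway-averaged difference counts over all orderings of the differing
positions (pathways through stop codons excluded unless none remain), and
d = -(3/4)·ln(1 - 4p/3). Collinear pairs are then assigned to the two
polyploidy events that shaped the Populus genome — the core-eudicot γ
triplication and the recent salicoid whole-genome duplication — by their Ks
value against configurable thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)
NUCLEOTIDES = "ACGT"

MIN_CODONS = 10


class TooShortError(ValueError):
    """Fewer than MIN_CODONS comparable codons remain after filtering."""


@dataclass(frozen=True)
class CodonAlignmentPair:
    """An aligned CDS pair; after :func:`filter_codons` it is gap- and stop-free."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.id_a}/{self.id_b}: aligned lengths differ")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


@dataclass(frozen=True)
class KsEstimate:
    pair_id: str
    ks: float          # NaN when saturated
    ka: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    saturated: bool


@dataclass(frozen=True)
class EventThresholds:
    """Ks windows for the two duplication events.

    Defaults bracket the Ks ranges typical of the salicoid WGD
    (recent, Ks up to ~1) and the γ triplication (Ks roughly 1.2–2.8).
    """

    recent_max: float = 1.0
    gamma_min: float = 1.2
    gamma_max: float = 2.8

    def __post_init__(self) -> None:
        if not (self.recent_max < self.gamma_min < self.gamma_max):
            raise ValueError("thresholds must satisfy recent_max < gamma_min < gamma_max")


@dataclass(frozen=True)
class EventCall:
    pair_id: str
    category: str  # RECENT_WGD | GAMMA | AMBIGUOUS
    ks: float


def filter_codons(pair: CodonAlignmentPair) -> CodonAlignmentPair:
    """Drop codon columns containing a gap, an ambiguity, or a stop codon."""
    a, b = pair.seq_a.upper(), pair.seq_b.upper()
    n = len(a) - len(a) % 3
    kept_a: list[str] = []
    kept_b: list[str] = []
    for i in range(0, n, 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(ch not in NUCLEOTIDES for ch in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        kept_a.append(ca)
        kept_b.append(cb)
    if len(kept_a) < MIN_CODONS:
        raise TooShortError(
            f"{pair.id_a}/{pair.id_b}: only {len(kept_a)} comparable codons "
            f"(TOO_SHORT, need >= {MIN_CODONS})"
        )
    return CodonAlignmentPair(pair.id_a, pair.id_b, "".join(kept_a), "".join(kept_b))


def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one codon.

    One-step changes to stop codons count as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


_SITE_CACHE = {codon: _codon_site_fractions(codon) for codon in CODON_TO_AA}


def ng86_sites(seq: str) -> tuple[float, float]:
    """Total (synonymous, nonsynonymous) site counts of one gap-free CDS."""
    s_total = n_total = 0.0
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at position {i}; filter first")
        s, n = _SITE_CACHE[codon]
        s_total += s
        n_total += n
    return s_total, n_total


def _codon_pair_differences(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences of one codon pair.

    Averages over all orderings of the differing positions; pathways whose
    intermediate codons are stops are excluded, unless every pathway hits a
    stop, in which case all are used (stop steps counted nonsynonymous).
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float, bool]] = []  # (sd, nd, valid)
    for order in permutations(diff_pos):
        current = ca
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1:]
            if nxt in STOP_CODONS or current in STOP_CODONS:
                nd += 1.0
                valid = False
            elif CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        paths.append((sd, nd, valid))
    usable = [(sd, nd) for sd, nd, valid in paths if valid] or [
        (sd, nd) for sd, nd, _ in paths
    ]
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def ng86_differences(pair: CodonAlignmentPair) -> tuple[float, float]:
    """Total pathway-averaged (sd, nd) over all codon columns of the pair."""
    sd_total = nd_total = 0.0
    for i in range(0, 3 * pair.n_codons, 3):
        key = (pair.seq_a[i:i + 3], pair.seq_b[i:i + 3])
        if key not in _DIFF_CACHE:
            _DIFF_CACHE[key] = _codon_pair_differences(*key)
        sd, nd = _DIFF_CACHE[key]
        sd_total += sd
        nd_total += nd
    return sd_total, nd_total


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4)·ln(1 - 4p/3); undefined for p >= 0.75."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_ka_ks(pair: CodonAlignmentPair, prefiltered: bool = False) -> KsEstimate:
    """NG86 Ka/Ks estimate of one aligned pair (filtering applied unless told not to)."""
    if not prefiltered:
        pair = filter_codons(pair)
    sa, na = ng86_sites(pair.seq_a)
    sb, nb = ng86_sites(pair.seq_b)
    s_sites = 0.5 * (sa + sb)
    n_sites = 0.5 * (na + nb)
    sd, nd = ng86_differences(pair)
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    return KsEstimate(
        pair_id=f"{pair.id_a}|{pair.id_b}",
        ks=ks,
        ka=ka,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        saturated=math.isnan(ks),
    )


def classify_duplication_event(
    estimate: KsEstimate, thresholds: EventThresholds = EventThresholds()
) -> EventCall:
    """Assign a pair to the recent WGD or γ-triplication window by its Ks."""
    if estimate.saturated or math.isnan(estimate.ks):
        return EventCall(estimate.pair_id, "AMBIGUOUS", estimate.ks)
    ks = estimate.ks
    if ks <= thresholds.recent_max:
        return EventCall(estimate.pair_id, "RECENT_WGD", ks)
    if thresholds.gamma_min <= ks <= thresholds.gamma_max:
        return EventCall(estimate.pair_id, "GAMMA", ks)
    return EventCall(estimate.pair_id, "AMBIGUOUS", ks)


def ks_histogram(
    estimates: list[KsEstimate], bin_width: float = 0.1
) -> tuple[dict[tuple[float, float], int], int]:
    """Bin Ks values into half-open bins [k·w, (k+1)·w).

    Returns (bins, n_saturated); saturated estimates are excluded from the
    bins but counted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_saturated = 0
    bins: dict[tuple[float, float], int] = {}
    for est in estimates:
        if est.saturated or math.isnan(est.ks):
            n_saturated += 1
            continue
        k = int(np.floor(est.ks / bin_width))
        key = (k * bin_width, (k + 1) * bin_width)
        bins[key] = bins.get(key, 0) + 1
    return dict(sorted(bins.items())), n_saturated


def ks_table(
    estimates: list[KsEstimate], calls: list[EventCall], path
) -> None:
    call_by_pair = {c.pair_id: c.category for c in calls}
    with open(path, "w") as fh:
        fh.write("pair\ts_sites\tn_sites\tsd\tnd\tka\tks\tcategory\n")
        for e in estimates:
            fh.write(
                f"{e.pair_id}\t{e.s_sites:.4f}\t{e.n_sites:.4f}\t{e.sd:.4f}\t"
                f"{e.nd:.4f}\t{e.ka:.4f}\t{e.ks:.4f}\t"
                f"{call_by_pair.get(e.pair_id, '')}\n"
            )
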