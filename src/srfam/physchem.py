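"""Protein physicochemical characterisation.

Molecular weight (average isotopic), Kyte–Doolittle GRAVY, and the
isoelectric point obtained by bisection of a Henderson–Hasselbalch net
charge with the Bjellqvist pKa set, matching the behaviour of the ExPASy
ProtParam tool. The unknown residue X contributes zero mass, is excluded
from the GRAVY denominator, and carries no ionizable group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Average (not monoisotopic) residue masses, Da.
RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 0.0,
}

WATER_MASS = 18.0153

# Kyte & Doolittle hydropathy values.
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Bjellqvist pKa set (ExPASy-compatible). Terminal pKas depend on the
# terminal residue where a specific value is tabulated.
POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PK_NTERMINAL = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
                "V": 7.44, "E": 7.7}
PK_CTERMINAL = {"D": 4.55, "E": 4.75}


@dataclass(frozen=True)
class ChemTables:
    """Chemical constants; swappable as data so alternative sets can be used."""

    residue_masses: dict = field(default_factory=lambda: dict(RESIDUE_MASSES))
    hydropathy: dict = field(default_factory=lambda: dict(HYDROPATHY))
    positive_pks: dict = field(default_factory=lambda: dict(POSITIVE_PKS))
    negative_pks: dict = field(default_factory=lambda: dict(NEGATIVE_PKS))
    pk_nterminal: dict = field(default_factory=lambda: dict(PK_NTERMINAL))
    pk_cterminal: dict = field(default_factory=lambda: dict(PK_CTERMINAL))
    water_mass: float = WATER_MASS


DEFAULT_TABLES = ChemTables()


@dataclass(frozen=True)
class PhyschemProfile:
    protein_id: str
    length: int
    mw: float          # Da
    pi: float          # pH units
    gravy: float
    pi_at_boundary: bool = False


def molecular_weight(seq: str, tables: ChemTables = DEFAULT_TABLES) -> float:
    """Average molecular weight in daltons (residue masses + one water)."""
    if not seq:
        raise ValueError("empty sequence")
    return sum(tables.residue_masses[aa] for aa in seq) + tables.water_mass


def gravy(seq: str, tables: ChemTables = DEFAULT_TABLES) -> float:
    """Grand average of hydropathy over non-X residues."""
    values = [tables.hydropathy[aa] for aa in seq if aa != "X"]
    if not values:
        raise ValueError("sequence has no non-X residues")
    return sum(values) / len(values)


def net_charge(seq: str, pH: float, tables: ChemTables = DEFAULT_TABLES) -> float:
    """Henderson–Hasselbalch net charge at the given pH, in elementary charges."""
    if not seq:
        raise ValueError("empty sequence")

    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))

    def neg(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - pH))

    charge = pos(tables.pk_nterminal.get(seq[0], tables.positive_pks["Nterm"]))
    charge += neg(tables.pk_cterminal.get(seq[-1], tables.negative_pks["Cterm"]))
    for aa in seq:
        if aa in ("K", "R", "H"):
            charge += pos(tables.positive_pks[aa])
        elif aa in ("D", "E", "C", "Y"):
            charge += neg(tables.negative_pks[aa])
    return charge


def isoelectric_point(
    seq: str, tables: ChemTables = DEFAULT_TABLES, tol: float = 1e-4
) -> tuple[float, bool]:
    """pH of zero net charge by bisection over [0, 14].

    Returns ``(pI, at_boundary)``; ``at_boundary`` is True when the charge
    does not change sign over the interval (the boundary value is returned
    with a warning flag instead of failing). The charge curve is strictly
    decreasing in pH, so bisection always converges.
    """
    lo, hi = 0.0, 14.0
    c_lo, c_hi = net_charge(seq, lo, tables), net_charge(seq, hi, tables)
    if c_lo <= 0:
        return lo, True
    if c_hi >= 0:
        return hi, True
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c_mid = net_charge(seq, mid, tables)
        if abs(c_mid) < tol:
            return mid, False
        if c_mid > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi), False


def profile(
    protein_id: str, seq: str, tables: ChemTables = DEFAULT_TABLES
) -> PhyschemProfile:
    pi, at_boundary = isoelectric_point(seq, tables)
    return PhyschemProfile(
        protein_id=protein_id,
        length=len(seq),
        mw=molecular_weight(seq, tables),
        pi=pi,
        gravy=gravy(seq, tables),
        pi_at_boundary=at_boundary,
    )


def physchem_table(profiles: list[PhyschemProfile], path) -> None:
    """Write profiles as TSV (MW in kDa to 2 dp, pI 2 dp, GRAVY 3 dp)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tlength\tmw_kda\tpi\tgravy\n")
        for p in profiles:
            fh.write(
                f"{p.protein_id}\t{p.length}\t{p.mw / 1000:.2f}\t"
                f"{p.pi:.2f}\t{p.gravy:.3f}\n"
            )
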