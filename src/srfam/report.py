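"""Summary report tying the pipeline stages together.

The report aggregates the subfamily count table, physicochemical ranges,
per-subfamily intron-count ranges, Ks duplication-event counts, and the
stress-response fraction into one flat key/value TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .architecture import SUBFAMILIES, Catalogue
from .expression_stats import StressSummary
from .gene_structure import StructureSummary, subfamily_structure_table
from .ks_dating import EventCall
from .physchem import PhyschemProfile


def build_report(
    catalogue: Catalogue | None = None,
    profiles: list[PhyschemProfile] | None = None,
    structures: list[StructureSummary] | None = None,
    event_calls: list[EventCall] | None = None,
    stress: StressSummary | None = None,
) -> dict[str, object]:
    """Assemble the flat summary mapping; absent stages contribute zeros."""
    report: dict[str, object] = {}
    counts = catalogue.subfamily_counts() if catalogue else {}
    report["n_sr_proteins"] = len(catalogue.entries) if catalogue else 0
    report["n_rejected"] = len(catalogue.rejects) if catalogue else 0
    for s in SUBFAMILIES + ("UNCLASSIFIED",):
        report[f"n_{s}"] = counts.get(s, 0)
    if profiles:
        mws = [p.mw / 1000 for p in profiles]
        pis = [p.pi for p in profiles]
        gravies = [p.gravy for p in profiles]
        report["mw_kda_min"] = round(min(mws), 2)
        report["mw_kda_mean"] = round(sum(mws) / len(mws), 2)
        report["mw_kda_max"] = round(max(mws), 2)
        report["pi_min"] = round(min(pis), 2)
        report["pi_max"] = round(max(pis), 2)
        report["gravy_min"] = round(min(gravies), 3)
        report["gravy_max"] = round(max(gravies), 3)
    if structures and catalogue:
        calls = [call for _, _, call in catalogue.entries]
        table = subfamily_structure_table(structures, calls)
        for _, row in table.iterrows():
            report[f"introns_{row['subfamily']}_min"] = row["min_introns"]
            report[f"introns_{row['subfamily']}_max"] = row["max_introns"]
            report[f"introns_{row['subfamily']}_uniform"] = row["uniform"]
    if event_calls is not None:
        for category in ("RECENT_WGD", "GAMMA", "AMBIGUOUS"):
            report[f"ks_{category}"] = sum(
                1 for c in event_calls if c.category == category
            )
    if stress is not None:
        report["stress_responding"] = stress.responding
        report["stress_total"] = stress.total
        report["stress_fraction"] = round(stress.fraction, 3)
    return report


def write_report(report: dict[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in report.items():
            fh.write(f"{key}\t{value}\n")


def read_report(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["key"], df["value"]))
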