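"""Deterministic report files for enrichment results.

All floats are written at 4 decimals with a stable column order, so a fixed
input produces byte-identical output.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .enrichment import DiscoveryReport

REPORT_COLUMNS = [
    "motif_id", "auc", "z_score", "cutoff_rank", "n_targets", "significant", "targets",
]


def report_frame(report: DiscoveryReport) -> pd.DataFrame:
    df = report.to_frame()[REPORT_COLUMNS].copy()
    df["auc"] = df["auc"].map(lambda v: f"{v:.4f}")
    df["z_score"] = df["z_score"].map(lambda v: f"{v:.4f}")
    return df


def write_report(report: DiscoveryReport, outdir, fmt: str = "tsv") -> Path:
    """Write the per-motif enrichment table as TSV or JSON; returns the path."""
    if not report.results:
        raise ValueError("cannot write an empty report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        path = outdir / "enrichment_report.tsv"
        report_frame(report).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path = outdir / "enrichment_report.json"
        payload = {
            "gene_set": report.gene_set_label,
            "z_threshold": report.z_threshold,
            "motifs": [
                {
                    "motif_id": r.model_id,
                    "auc": round(r.auc, 4),
                    "z_score": round(r.z_score, 4),
                    "cutoff_rank": r.optimal_cutoff_rank,
                    "n_targets": len(r.leading_edge),
                    "significant": r.significant,
                    "targets": list(r.leading_edge),
                }
                for r in report.results
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def read_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_target_details(report: DiscoveryReport, rankings, outdir) -> Path:
    """Per-target detail: motif, gene, its rank and best region."""
    rows = []
    for r in report.results:
        if not r.leading_edge:
            continue
        table = rankings[r.model_id].table.set_index("gene_id")
        for gene in r.leading_edge:
            rows.append(
                {
                    "motif_id": r.model_id,
                    "gene_id": gene,
                    "gene_rank": int(table.loc[gene, "rank"]),
                    "best_region_id": table.loc[gene, "best_region_id"],
                }
            )
    path = Path(outdir) / "target_details.tsv"
    pd.DataFrame(rows, columns=["motif_id", "gene_id", "gene_rank", "best_region_id"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_curves_csv(curves: dict, outdir) -> Path:
    """Optional recovery-curve points (rank, cumulative recovery per motif)."""
    path = Path(outdir) / "recovery_curves.csv"
    df = pd.DataFrame({mid: c.y for mid, c in sorted(curves.items())})
    df.insert(0, "rank", range(1, len(df) + 1))
    df.to_csv(path, index=False)
    return path


def write_edge_list(report: DiscoveryReport, tf_name: str, outdir) -> Path:
    """SIF-like 3-column TF -> target edges for flagged motifs."""
    path = Path(outdir) / "edges.sif"
    with open(path, "w") as fh:
        for r in report.significant_results():
            for gene in r.leading_edge:
                fh.write(f"{tf_name}\tregulates\t{gene}\n")
    return path
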