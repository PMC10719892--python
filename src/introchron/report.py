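"""Report assembly over stage output files.

Collects the per-stage outputs written by the CLI into one summary JSON
with seven sections (region-class enrichment, SAV sharing, DR sharing,
per-tissue eQTL tiers, direction curve, cline pass list, adaptive
support). The assembler only reads and reformats stage outputs; it never
recomputes a statistic.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["assemble_report", "SECTIONS"]

SECTIONS = {
    "region_enrichment": "lineage_enrichment.tsv",
    "sav_sharing": "sav_calls.tsv",
    "dr_sharing": "dr_sharing.tsv",
    "eqtl_tissue_tiers": "eqtl_per_tissue.tsv",
    "direction_curve": "direction_curve.tsv",
    "cline_passes": "clines.tsv",
    "adaptive_support": "adaptive_support.tsv",
}


def _section(stage_dir: Path, filename: str):
    path = stage_dir / filename
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t")
    return df


def assemble_report(stage_dir: str | Path, out_path: str | Path | None = None) -> dict:
    """Assemble the summary report from a directory of stage outputs.

    Missing stages are marked absent rather than failing; at least one
    section must be present.
    """
    stage_dir = Path(stage_dir)
    report: dict = {"sections": {}}
    n_present = 0
    for name, filename in SECTIONS.items():
        df = _section(stage_dir, filename)
        if df is None:
            report["sections"][name] = {"status": "absent"}
            continue
        n_present += 1
        entry: dict = {"status": "present", "n_rows": int(len(df))}
        if name == "region_enrichment":
            entry["rows"] = df.to_dict(orient="records")
        elif name == "sav_sharing":
            entry["sharing_counts"] = (
                df["sharing_class"].value_counts().sort_index().to_dict()
            )
            entry["n_sav_genes"] = int(df["gene_id"].nunique())
        elif name == "dr_sharing":
            entry["rows"] = df.to_dict(orient="records")
        elif name == "eqtl_tissue_tiers":
            entry["tier_counts"] = (
                df["significance_tier"].value_counts().sort_index().to_dict()
            )
        elif name == "direction_curve":
            if len(df):
                entry["final_fraction"] = float(df["cum_fraction"].iloc[-1])
        elif name == "cline_passes":
            entry["n_pass"] = int(df["passed"].sum()) if "passed" in df else 0
            if "passed" in df and "variant" in df:
                entry["pass_variants"] = sorted(df.loc[df["passed"], "variant"].astype(str))
        elif name == "adaptive_support":
            entry["n_genes"] = int(df["gene"].nunique()) if len(df) else 0
        report["sections"][name] = entry
    if n_present == 0:
        raise FileNotFoundError(f"no stage outputs found under {stage_dir}")
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
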