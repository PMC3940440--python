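"""Accessors for the packaged reference evaluation tables.

These TSVs transcribe the published evaluation of the EOL annotation and
association workflows on its 21 test species: confusion counts for the
association workflow and for the GNRD-alone baseline, the categorized URI
annotation errors, and the per-species URI annotation metrics.  They serve
as fixed inputs for re-deriving every published summary statistic with the
evaluation module — nothing in them is produced by this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import ConfusionCounts

__all__ = [
    "load_reference_table",
    "reference_confusion_counts",
    "ASSOC_WORKFLOW_COUNTS",
    "ASSOC_BASELINE_COUNTS",
    "URI_ERROR_CATEGORIES",
    "URI_ANNOTATION_METRICS",
    "WORKFLOW_SUMMARY",
]

ASSOC_WORKFLOW_COUNTS = "assoc_workflow_counts.tsv"
ASSOC_BASELINE_COUNTS = "assoc_baseline_counts.tsv"
URI_ERROR_CATEGORIES = "uri_error_categories.tsv"
URI_ANNOTATION_METRICS = "uri_annotation_metrics.tsv"
WORKFLOW_SUMMARY = "workflow_summary.tsv"


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one packaged reference TSV as a DataFrame."""
    ref = resources.files("taxatext") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def reference_confusion_counts(name: str) -> dict[str, ConfusionCounts]:
    """A counts table (unit, tp, fp, fn, tn) as a per-unit mapping."""
    df = load_reference_table(name)
    return {
        row["unit"]: ConfusionCounts(int(row["tp"]), int(row["fp"]),
                                     int(row["fn"]), int(row["tn"]))
        for _, row in df.iterrows()
    }
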