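"""Score predictions against gold standards.

Definitions follow standard information-extraction practice.  Precision is
the fraction of assigned tags (or extracted edges) that are correct; recall
the fraction of gold tags that were assigned; F1 the harmonic mean of the
two, computed from unrounded precision and recall.  Degenerate 0/0 ratios
evaluate to 0 by convention, so a unit with nothing assigned and nothing
expected reports 0/0/0 rather than failing.

Micro-averaged totals are computed from summed confusion counts, i.e. the
TOTAL row of a report equals ``compute_metrics(sum of per-unit counts)``.

Inter-annotator agreement uses Fleiss' kappa for a fixed number of raters
assigning items to categories.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotator import AnnotationResult
from .errors import UndefinedKappaError, UsageError
from .network import AssociationSet

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "GoldAnnotationSet",
    "GoldAssociationSet",
    "compute_metrics",
    "f1_from_pr",
    "compare_uri_annotations",
    "compare_associations",
    "error_category_report",
    "fleiss_kappa",
    "relative_improvement",
    "metrics_report",
    "render_report",
    "round_half_up",
    "format_percent",
    "load_gold_annotations",
    "save_gold_annotations",
    "load_gold_associations",
    "save_gold_associations",
    "load_ratings",
    "ERROR_CATEGORIES",
]

#: The five manual false-positive classes used in gold fixtures and reports.
ERROR_CATEGORIES = ("negation", "related_taxa", "word_part", "generality", "homonym")


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (0.9375 → 0.938), as printed tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(x: float) -> int:
    """A fraction as a whole percentage, half-up (0.3684 → 37)."""
    return int(round_half_up(100.0 * x, 0))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise UsageError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Precision, recall and F1 from confusion counts (0/0 → 0 convention)."""
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    return MetricSet(precision, recall, f1_from_pr(precision, recall))


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise UsageError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def relative_improvement(new_f1: float, base_f1: float) -> float:
    """(new − base) / base; the fractional gain over a baseline score."""
    if base_f1 <= 0:
        raise UsageError("baseline F1 must be positive")
    return (new_f1 - base_f1) / base_f1


# --------------------------------------------------------------------------
# Gold standards


@dataclass
class GoldAnnotationSet:
    """Human gold URIs per object, plus expected false positives.

    ``uris`` maps object_id → the set of URIs a human annotator assigned.
    ``expected_fps`` lists planted trap tags as (object_id, uri, category):
    URIs whose key occurs in the text but which a human would reject, with
    the error-category label explaining why.  They are not gold positives.
    """

    uris: dict[str, set[str]] = field(default_factory=dict)
    expected_fps: list[tuple[str, str, str]] = field(default_factory=list)


@dataclass
class GoldAssociationSet:
    """Human gold (subject_taxon_id, object_taxon_id) pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)


def compare_uri_annotations(
    pred: Mapping[str, AnnotationResult],
    gold: GoldAnnotationSet,
) -> tuple[dict[str, ConfusionCounts], ConfusionCounts]:
    """Per-object confusion counts over unique-URI sets, plus the micro total.

    tp = |pred ∩ gold|, fp = |pred \\ gold|, fn = |gold \\ pred|; tn = 0
    (the URI task has no candidate universe).  Objects absent from one side
    are treated as having an empty set there.
    """
    per_object: dict[str, ConfusionCounts] = {}
    total = ConfusionCounts()
    for oid in sorted(set(pred) | set(gold.uris)):
        p = pred[oid].unique_uris if oid in pred else set()
        g = gold.uris.get(oid, set())
        c = ConfusionCounts(tp=len(p & g), fp=len(p - g), fn=len(g - p), tn=0)
        per_object[oid] = c
        total = total + c
    return per_object, total


def compare_associations(
    pred: AssociationSet | Iterable[tuple[str, str]],
    gold: GoldAssociationSet,
    universe: Iterable[tuple[str, str]],
) -> ConfusionCounts:
    """Confusion counts for extracted edges against gold pairs.

    ``universe`` supplies the candidate pairs from which true negatives are
    counted; it must cover every predicted and gold pair.
    """
    pred_pairs = pred.pairs() if isinstance(pred, AssociationSet) else set(pred)
    gold_pairs = set(gold.pairs)
    uni = set(universe)
    missing = (pred_pairs | gold_pairs) - uni
    if missing:
        raise UsageError(
            f"universe is missing {len(missing)} predicted/gold pairs, "
            f"e.g. {sorted(missing)[:3]}"
        )
    return ConfusionCounts(
        tp=len(pred_pairs & gold_pairs),
        fp=len(pred_pairs - gold_pairs),
        fn=len(gold_pairs - pred_pairs),
        tn=len(uni - (pred_pairs | gold_pairs)),
    )


def error_category_report(
    pred: Mapping[str, AnnotationResult],
    gold: GoldAnnotationSet,
) -> pd.DataFrame:
    """Tally planted trap tags that actually fired, by error category.

    Classification is *not* automatic: categories come from the gold
    fixture's labels.  A trap "fires" when the predicted unique-URI set of
    its object contains the trap URI.
    """
    planted = {cat: 0 for cat in ERROR_CATEGORIES}
    fired = {cat: 0 for cat in ERROR_CATEGORIES}
    for oid, uri, cat in gold.expected_fps:
        planted.setdefault(cat, 0)
        fired.setdefault(cat, 0)
        planted[cat] += 1
        if oid in pred and uri in pred[oid].unique_uris:
            fired[cat] += 1
    rows = [{"category": c, "planted": planted[c], "fired": fired[c]}
            for c in planted]
    df = pd.DataFrame(rows).set_index("category")
    df.loc["TOTAL"] = [sum(planted.values()), sum(fired.values())]
    return df


# --------------------------------------------------------------------------
# Fleiss' kappa


def fleiss_kappa(matrix: Sequence[Sequence[int]] | np.ndarray | pd.DataFrame) -> float:
    """Fleiss' kappa for an items × categories table of rater counts.

    Every row must sum to the same number of raters n ≥ 2.  Raises
    :class:`UndefinedKappaError` when chance agreement is 1 (all ratings in
    a single category), where the statistic is undefined.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise UsageError("rating matrix must be a non-empty 2-D table")
    row_sums = m.sum(axis=1)
    n = row_sums[0]
    if n < 2 or not np.all(row_sums == n):
        raise UsageError("each item must have the same number of raters (>= 2)")
    n_items = m.shape[0]
    p_cat = m.sum(axis=0) / (n_items * n)          # category marginals
    p_bar = ((m * m).sum(axis=1) - n).sum() / (n_items * n * (n - 1))
    p_e = float((p_cat ** 2).sum())
    if p_e >= 1.0:
        raise UndefinedKappaError(
            "all ratings fall in a single category; kappa is undefined"
        )
    return (p_bar - p_e) / (1.0 - p_e)


# --------------------------------------------------------------------------
# Report tables


def metrics_report(per_unit: Mapping[str, ConfusionCounts]) -> pd.DataFrame:
    """Per-unit counts and 3-decimal metrics plus a micro-averaged TOTAL row.

    Metrics are left blank (NaN) for units whose tp, fp and fn are all zero,
    matching how published tables leave cells empty where nothing was
    assigned or expected.  The TOTAL row is always computed, from the summed
    counts.
    """
    rows = []
    total = ConfusionCounts()
    for unit in per_unit:
        c = per_unit[unit]
        total = total + c
        if c.tp == 0 and c.fp == 0 and c.fn == 0:
            p = r = f = float("nan")
        else:
            ms = compute_metrics(c)
            p, r, f = (round_half_up(ms.precision), round_half_up(ms.recall),
                       round_half_up(ms.f1))
        rows.append({"unit": unit, "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
                     "precision": p, "recall": r, "f1": f})
    ms = compute_metrics(total)
    rows.append({"unit": "TOTAL", "tp": total.tp, "fp": total.fp, "fn": total.fn,
                 "tn": total.tn, "precision": round_half_up(ms.precision),
                 "recall": round_half_up(ms.recall), "f1": round_half_up(ms.f1)})
    return pd.DataFrame(rows).set_index("unit")


def render_report(df: pd.DataFrame) -> str:
    """Aligned text rendering of a metrics report, blanks for NaN cells."""
    out = df.copy()
    for col in ("precision", "recall", "f1"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    return out.to_string()


# --------------------------------------------------------------------------
# Gold-file I/O (TSV)


def load_gold_annotations(path: str | Path) -> GoldAnnotationSet:
    """gold_annotations.tsv: object_id, uri, error_category (blank = gold positive)."""
    gold = GoldAnnotationSet()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            cat = (row.get("error_category") or "").strip()
            if cat:
                gold.expected_fps.append((row["object_id"], row["uri"], cat))
            else:
                gold.uris.setdefault(row["object_id"], set()).add(row["uri"])
            gold.uris.setdefault(row["object_id"], set())
    return gold


def save_gold_annotations(gold: GoldAnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["object_id", "uri", "error_category"])
        for oid in sorted(gold.uris):
            for uri in sorted(gold.uris[oid]):
                w.writerow([oid, uri, ""])
        for oid, uri, cat in sorted(gold.expected_fps):
            w.writerow([oid, uri, cat])


def load_gold_associations(path: str | Path) -> GoldAssociationSet:
    """gold_associations.tsv: subject_taxon_id, object_taxon_id."""
    gold = GoldAssociationSet()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            gold.pairs.add((row["subject_taxon_id"], row["object_taxon_id"]))
    return gold


def save_gold_associations(gold: GoldAssociationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["subject_taxon_id", "object_taxon_id"])
        for s, o in sorted(gold.pairs):
            w.writerow([s, o])


def load_ratings(path: str | Path) -> pd.DataFrame:
    """ratings.tsv: an 'item' column plus one integer column per category."""
    df = pd.read_csv(path, sep="\t", dtype={"item": str}).set_index("item")
    return df.astype(int)
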