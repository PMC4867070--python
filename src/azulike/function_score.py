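"""Annotation-odds similarity scoring against a control protein.

Functional-annotation predictors of the ProtFun family report, for each
sequence and each functional category, a probability and an odds number (the
probability divided by the category's prior, treated here as an opaque
non-negative real).  A candidate's similarity to the control (azurin) is
scored as

    score(seq) = log10( odds_F * odds_EZ * odds_GO )

where the three odds are those the candidate attains in the control's
top-odds category of each group: cellular function (F), enzyme class (EZ)
and gene-ontology category (GO).  The three factors enter unweighted.
Candidates with score > 0 (odds product > 1) are selected; the selection is
invariant to the logarithm base, base 10 is used for report readability.

A parallel probability score is computed with the same formula over the
probabilities; its Pearson correlation with the odds score is reported as a
consistency diagnostic.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "AnnotationEntry",
    "AnnotationSet",
    "ReferenceCategories",
    "SimilarityScore",
    "CorrelationResult",
    "parse_annotation_table",
    "reference_categories",
    "azurin_similarity_score",
    "score_all",
    "rank_and_select",
    "odds_probability_correlation",
    "write_score_report",
]

#: Annotation category groups: cellular function, enzyme class, gene ontology.
GROUPS = ("F", "EZ", "GO")


@dataclass(frozen=True)
class AnnotationEntry:
    seq_id: str
    group: str
    category: str
    probability: float
    odds: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"{self.seq_id}/{self.group}/{self.category}: probability "
                f"{self.probability} outside [0, 1]"
            )
        if self.odds < 0:
            raise ValueError(
                f"{self.seq_id}/{self.group}/{self.category}: negative odds {self.odds}"
            )


class AnnotationSet:
    """Collection of annotation entries keyed by (seq_id, group, category)."""

    def __init__(self, entries: Iterable[AnnotationEntry] = ()) -> None:
        self._entries: dict[tuple[str, str, str], AnnotationEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: AnnotationEntry) -> None:
        key = (entry.seq_id, entry.group, entry.category)
        if key in self._entries:
            raise ValueError(f"duplicate annotation entry {key}")
        self._entries[key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def sequence_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for entry in self._entries.values():
            seen.setdefault(entry.seq_id, None)
        return list(seen)

    def entries_for(self, seq_id: str, group: str | None = None) -> list[AnnotationEntry]:
        return [
            e
            for e in self._entries.values()
            if e.seq_id == seq_id and (group is None or e.group == group)
        ]

    def get(self, seq_id: str, group: str, category: str) -> AnnotationEntry | None:
        return self._entries.get((seq_id, group, category))

    def is_scorable(self, seq_id: str) -> bool:
        """True when the sequence carries >= 1 entry in each of F, EZ, GO."""
        return all(self.entries_for(seq_id, g) for g in GROUPS)


@dataclass(frozen=True)
class ReferenceCategories:
    """The control's top-odds category per group."""

    f_category: str
    ez_category: str
    go_category: str

    def for_group(self, group: str) -> str:
        return {"F": self.f_category, "EZ": self.ez_category, "GO": self.go_category}[group]


@dataclass(frozen=True)
class SimilarityScore:
    seq_id: str
    odds_product: float
    score: float  # -inf sentinel when any odds factor is zero
    prob_product: float
    prob_score: float

    @property
    def is_sentinel(self) -> bool:
        return math.isinf(self.score) and self.score < 0


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int


def parse_annotation_table(path: str | Path) -> AnnotationSet:
    """Parse a TSV annotation table with header seq_id/group/category/probability/odds.

    Malformed rows, out-of-range probabilities, negative odds and duplicate
    (seq_id, group, category) keys raise ``ValueError`` naming the line.
    """
    expected = ["seq_id", "group", "category", "probability", "odds"]
    annotations = AnnotationSet()
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header {expected}")
        if [h.strip() for h in header] != expected:
            raise ValueError(f"{path}: bad header {header!r}, expected {expected}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            seq_id, group, category = (f.strip() for f in row[:3])
            try:
                probability = float(row[3])
                odds = float(row[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            try:
                annotations.add(
                    AnnotationEntry(seq_id, group, category, probability, odds)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return annotations


def reference_categories(
    annotations: AnnotationSet, control_id: str = "azurin"
) -> ReferenceCategories:
    """Pick the control's maximal-odds category in each group.

    Ties are broken by lexicographic category name, with a logged warning.
    """
    chosen: dict[str, str] = {}
    for group in GROUPS:
        entries = annotations.entries_for(control_id, group)
        if not entries:
            raise ValueError(
                f"control {control_id!r} has no entries in group {group!r}"
            )
        best = max(entries, key=lambda e: (e.odds, ))
        tied = sorted(e.category for e in entries if e.odds == best.odds)
        if len(tied) > 1:
            logger.warning(
                "control %s group %s: odds tie among %s; choosing %s",
                control_id, group, tied, tied[0],
            )
        chosen[group] = tied[0]
    return ReferenceCategories(
        f_category=chosen["F"], ez_category=chosen["EZ"], go_category=chosen["GO"]
    )


def azurin_similarity_score(
    annotations: AnnotationSet,
    refs: ReferenceCategories,
    seq_id: str,
    weights: Sequence[float] = (1.0, 1.0, 1.0),
) -> SimilarityScore:
    """Score one sequence: log10 of the product of its odds in the control's
    three reference categories.

    A zero odds (or probability) factor yields a negative-infinity sentinel
    score rather than an error, so one failed category does not abort a
    batch; sentinel-scored sequences are never selected.  *weights* are
    exponents on the three factors and default to the unweighted (1, 1, 1).
    """
    odds_product = 1.0
    prob_product = 1.0
    for group, weight in zip(GROUPS, weights):
        category = refs.for_group(group)
        entry = annotations.get(seq_id, group, category)
        if entry is None:
            raise ValueError(
                f"{seq_id}: no annotation for reference category "
                f"{group}/{category}"
            )
        odds_product *= entry.odds ** weight
        prob_product *= entry.probability ** weight
    if odds_product == 0.0:
        logger.warning("%s: zero odds factor; score is -inf sentinel", seq_id)
        score = float("-inf")
    else:
        score = math.log10(odds_product)
    prob_score = math.log10(prob_product) if prob_product > 0 else float("-inf")
    return SimilarityScore(
        seq_id=seq_id,
        odds_product=odds_product,
        score=score,
        prob_product=prob_product,
        prob_score=prob_score,
    )


def score_all(
    annotations: AnnotationSet,
    refs: ReferenceCategories,
    seq_ids: Sequence[str] | None = None,
    weights: Sequence[float] = (1.0, 1.0, 1.0),
) -> list[SimilarityScore]:
    """Score every scorable sequence (or the given ids) in the set."""
    ids = list(seq_ids) if seq_ids is not None else annotations.sequence_ids
    return [
        azurin_similarity_score(annotations, refs, sid, weights=weights)
        for sid in ids
    ]


def rank_and_select(
    scores: Iterable[SimilarityScore],
) -> tuple[list[SimilarityScore], list[SimilarityScore]]:
    """Sort descending by score (sentinels last, ties by seq_id) and select
    the strictly positive scores."""
    ranked = sorted(scores, key=lambda s: (-s.score, s.seq_id))
    selected = [s for s in ranked if s.score > 0]
    return ranked, selected


def odds_probability_correlation(
    scores: Iterable[SimilarityScore],
) -> CorrelationResult:
    """Pearson correlation between odds scores and probability scores.

    Sentinel-scored sequences are excluded.  Fewer than two usable pairs, or
    zero variance in either coordinate, is an error.
    """
    pairs = [(s.score, s.prob_score) for s in scores if not s.is_sentinel
             and not math.isinf(s.prob_score)]
    if len(pairs) < 2:
        raise ValueError(f"need >= 2 non-sentinel score pairs, got {len(pairs)}")
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("zero variance in scores; correlation undefined")
    r = float(stats.pearsonr(xs, ys).statistic)
    return CorrelationResult(r=r, n=len(pairs))


def write_score_report(
    path: str | Path, ranked: Sequence[SimilarityScore],
    selected: Sequence[SimilarityScore],
) -> None:
    """Write the ranked score report as TSV (scores are log10)."""
    selected_ids = {s.seq_id for s in selected}
    lines = ["seq_id\todds_product\tscore_log10\tprob_score_log10\trank\tselected"]
    for rank, s in enumerate(ranked, start=1):
        lines.append(
            f"{s.seq_id}\t{s.odds_product:.6g}\t{s.score:.6g}"
            f"\t{s.prob_score:.6g}\t{rank}\t{str(s.seq_id in selected_ids).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
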