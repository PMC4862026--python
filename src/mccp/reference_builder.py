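"""Curation of the positive reference set and balanced negative resampling.

The positive set is built by rule: keep proteins annotated with the target
location at high evidence, drop any whose annotation also matches an
ambiguity keyword (e.g. "nucleus", "reticulum"), then apply explicit
manual exclusion/inclusion lists standing in for a literature review.

Negative training sets are drawn uniformly without replacement from the
pool of proteins carrying no target annotation in any supplied catalog.
Training is balanced — each negative set has as many proteins as the
positive set — because unbalanced training skews the resulting scores;
k independent draws feed the k classifiers of the ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrix_io import AnnotationCatalog, RatioMatrix

logger = logging.getLogger(__name__)


@dataclass
class CurationRules:
    """Rule set defining the high-confidence positive reference.

    target_label
        Location label defining the organelle (e.g. "mitochondrion").
    min_annotation_score
        Minimum evidence score in [0, 5]; entries without a score pass
        only when this is 0.
    exclusion_keywords
        Case-insensitive substrings; a protein whose location annotation
        matches any of them is considered ambiguous and dropped.
    manual_exclusions / manual_inclusions
        Explicit id lists applied last (the curation step a human review
        would otherwise perform).
    """

    target_label: str
    min_annotation_score: int = 0
    exclusion_keywords: list[str] = field(default_factory=list)
    manual_exclusions: list[str] = field(default_factory=list)
    manual_inclusions: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.min_annotation_score <= 5:
            raise ValueError("min_annotation_score must be in [0, 5]")

    def summary(self) -> str:
        return (
            f"target={self.target_label!r} min_score={self.min_annotation_score} "
            f"exclude={sorted(k.lower() for k in self.exclusion_keywords)} "
            f"manual(-{len(self.manual_exclusions)}/+{len(self.manual_inclusions)})"
        )


@dataclass
class ReferenceSet:
    """Training ground truth: curated positives plus the eligible negative pool."""

    positives: set[str]
    negative_pool: set[str]
    provenance: str = ""

    def __post_init__(self):
        overlap = self.positives & self.negative_pool
        if overlap:
            raise ValueError(
                f"positives and negative pool overlap on {len(overlap)} ids, "
                f"e.g. {sorted(overlap)[:3]}"
            )


def curate_positive_set(catalog: AnnotationCatalog, rules: CurationRules) -> set[str]:
    """Apply the curation rules to a catalog; returns the positive id set.

    A protein passes when its locations contain the target label, its
    annotation score meets the minimum, and no location string contains
    an exclusion keyword (case-insensitive substring).  Manual exclusions
    are then removed and manual inclusions added; an inclusion id absent
    from the catalog is kept with a warning.
    """
    keywords = [k.lower() for k in rules.exclusion_keywords]
    out: set[str] = set()
    for pid, entry in catalog.entries.items():
        if not catalog.has_label(pid, rules.target_label):
            continue
        score = entry.annotation_score
        if score is None:
            if rules.min_annotation_score > 0:
                continue
        elif score < rules.min_annotation_score:
            continue
        blob = ";".join(sorted(entry.locations)).lower()
        if any(k in blob for k in keywords):
            continue
        out.add(pid)
    out -= set(rules.manual_exclusions)
    for pid in rules.manual_inclusions:
        if pid not in catalog:
            logger.warning("manual inclusion %r not present in catalog %s", pid, catalog.source)
        out.add(pid)
    return out


def restrict_to_detected(ids: set[str], m: RatioMatrix) -> set[str]:
    """Intersect an id set with the proteins present in the matrix."""
    return set(ids) & set(m.protein_ids)


def build_negative_pool(
    m: RatioMatrix, catalogs: list[AnnotationCatalog], target_label: str
) -> set[str]:
    """Proteins of the matrix with no target annotation in any catalog."""
    pool = set(m.protein_ids)
    for cat in catalogs:
        pool -= cat.ids_with_label(target_label)
    return pool


def draw_negative_sets(
    m: RatioMatrix,
    excluded: set[str],
    n_per_set: int,
    k: int,
    seed: int,
) -> list[set[str]]:
    """Draw k negative training sets of size n_per_set.

    Each set is sampled uniformly without replacement from the matrix's
    proteins minus *excluded*; draws are independent (overlap between
    draws is allowed).  Draw i uses seed + i, so the whole list is
    reproducible and individual draws can be re-derived.
    """
    pool = sorted(set(m.protein_ids) - set(excluded))
    if len(pool) < n_per_set:
        raise ValueError(
            f"negative pool has {len(pool)} proteins, need n_per_set={n_per_set}"
        )
    pool_arr = np.array(pool, dtype=object)
    sets = []
    for i in range(k):
        rng = np.random.default_rng(seed + i)
        pick = rng.choice(len(pool_arr), size=n_per_set, replace=False)
        sets.append(set(pool_arr[pick]))
    return sets


def build_reference_set(
    catalog: AnnotationCatalog,
    rules: CurationRules,
    m: RatioMatrix,
    extra_catalogs: list[AnnotationCatalog] | None = None,
) -> ReferenceSet:
    """Curate positives and assemble the negative pool against a matrix.

    Positives are restricted to proteins detected in the matrix; the
    negative pool is every detected protein lacking the target label in
    the curation catalog and in every extra catalog.
    """
    positives_all = curate_positive_set(catalog, rules)
    positives = restrict_to_detected(positives_all, m)
    pool = build_negative_pool(
        m, [catalog] + list(extra_catalogs or []), rules.target_label
    )
    pool -= positives
    prov = (
        f"{rules.summary()}; curated={len(positives_all)} detected={len(positives)} "
        f"negative_pool={len(pool)}"
    )
    return ReferenceSet(positives=positives, negative_pool=pool, provenance=prov)
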