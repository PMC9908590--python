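"""Decision-to-reason annotation data model.

The annotation schema is hierarchical: a whole-slide image (WSI) document
carries *decision-layer* regions (diagnosis classes such as adenocarcinoma /
adenoma / normal, optionally refined to a subtype) and *reason-layer* feature
regions whose captions justify those decisions with morphological terms drawn
from a three-level unified terminology (class -> subtype -> reason label).
Regions sharing one description are grouped into bundles so the annotator can
apply a single caption to many lesions at once.

All label vocabulary lives in a :class:`TerminologyTree`; documents reference
terminology entries by id.  Free-text tokens are allowed in captions and
reason lists and are simply tokens that do not resolve in the tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import (
    AmbiguousBundleError,
    EmptyCohortError,
    StructureError,
    UnknownTermError,
)

LEVELS = ("class", "subtype", "reason")
PENCIL_SHAPES = ("curve", "rectangle", "brush")
LAYERS = ("decision", "reason")
PHASES = ("coarse", "fine")
AUDIT_STATUSES = ("draft", "submitted", "audited")


# ---------------------------------------------------------------------------
# terminology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermEntry:
    """One vocabulary entry at one of the three levels."""

    id: str
    level: str
    parent_id: str | None
    name: str
    order: int = 0

    def __post_init__(self):
        if self.level not in LEVELS:
            raise StructureError(f"unknown level {self.level!r}", entry=self.id)


class TerminologyTree:
    """Forest of class -> subtype -> reason entries with id/name lookup.

    The tree is validated on construction: ids unique, parents exist and sit
    one level up, classes are roots, and (level, name) resolves unambiguously.
    """

    def __init__(self, entries: Sequence[TermEntry], version: str = "1.0"):
        self.version = version
        self.entries = list(entries)
        self._by_id: dict[str, TermEntry] = {}
        self._children: dict[str, list[str]] = {}
        self._by_level_name: dict[tuple[str, str], list[str]] = {}
        self._validate()

    def _validate(self) -> None:
        for e in self.entries:
            if e.id in self._by_id:
                raise StructureError(f"duplicate terminology id {e.id!r}", entry=e.id)
            self._by_id[e.id] = e
            self._by_level_name.setdefault((e.level, e.name), []).append(e.id)
        for e in self.entries:
            if e.level == "class":
                if e.parent_id is not None:
                    raise StructureError(
                        f"class entry {e.id!r} must have no parent", entry=e.id
                    )
                continue
            if e.parent_id is None:
                raise StructureError(f"{e.level} entry {e.id!r} lacks a parent", entry=e.id)
            parent = self._by_id.get(e.parent_id)
            if parent is None:
                raise StructureError(
                    f"entry {e.id!r} references unknown parent {e.parent_id!r}",
                    entry=e.id,
                )
            want = "class" if e.level == "subtype" else "subtype"
            if parent.level != want:
                raise StructureError(
                    f"entry {e.id!r} ({e.level}) must hang off a {want}, "
                    f"got {parent.level}",
                    entry=e.id,
                )
            self._children.setdefault(e.parent_id, []).append(e.id)

    # -- lookup -------------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._by_id

    def get(self, term_id: str) -> TermEntry:
        try:
            return self._by_id[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown terminology id {term_id!r}", term=term_id)

    def children(self, term_id: str) -> list[TermEntry]:
        return [self._by_id[c] for c in self._children.get(term_id, [])]

    def ancestors(self, term_id: str) -> list[TermEntry]:
        """Path from the root class down to (and including) the entry."""
        path = [self.get(term_id)]
        while path[0].parent_id is not None:
            path.insert(0, self.get(path[0].parent_id))
        return path

    def classes(self) -> list[TermEntry]:
        out = [e for e in self.entries if e.level == "class"]
        return sorted(out, key=lambda e: (e.order, e.id))

    def at_level(self, level: str) -> list[TermEntry]:
        return sorted(
            (e for e in self.entries if e.level == level),
            key=lambda e: (e.order, e.id),
        )


def resolve_label(tree: TerminologyTree, query) -> tuple[TermEntry, list[TermEntry]]:
    """Resolve an id or a ``(level, name)`` pair to an entry plus its path.

    The path runs class -> ... -> entry, so a class resolves to a path of
    length 1 and a reason label to a path of length 3.
    """
    if isinstance(query, str):
        entry = tree.get(query)
    else:
        level, name = query
        ids = tree._by_level_name.get((level, name), [])
        if not ids:
            raise UnknownTermError(
                f"no {level} entry named {name!r}", level=level, name=name
            )
        if len(ids) > 1:
            raise UnknownTermError(
                f"name {name!r} is ambiguous at level {level}", level=level, name=name
            )
        entry = tree.get(ids[0])
    return entry, tree.ancestors(entry.id)


def terminology_counts(tree: TerminologyTree) -> dict:
    """Per-class subtype / reason-label counts plus grand totals.

    Returns ``{"per_class": {class_id: (n_subtypes, n_reasons)},
    "totals": (n_classes, n_subtypes, n_reasons)}``.
    """
    per_class: dict[str, tuple[int, int]] = {}
    for cls in tree.classes():
        subs = tree.children(cls.id)
        n_reasons = sum(len(tree.children(s.id)) for s in subs)
        per_class[cls.id] = (len(subs), n_reasons)
    totals = (
        len(per_class),
        sum(v[0] for v in per_class.values()),
        sum(v[1] for v in per_class.values()),
    )
    return {"per_class": per_class, "totals": totals}


# ---------------------------------------------------------------------------
# annotation documents
# ---------------------------------------------------------------------------

@dataclass
class Caption:
    """Ordered reason terms (terminology ids or free-text tokens) plus an
    optional diagnosis phrase."""

    terms: list[str]
    diagnosis_phrase: str | None = None

    @property
    def term_count(self) -> int:
        return len(self.terms)


@dataclass
class Region:
    """A polygonal annotation on one WSI, on the decision or reason layer."""

    id: str
    wsi_id: str
    polygon: list[tuple[int, int]]  # level-0 pixels, implicitly closed
    layer: str
    class_label: str
    subtype_label: str | None = None
    reason_labels: list[str] = field(default_factory=list)
    pencil_shape: str = "curve"
    free_text: str | None = None
    voice_ref: str | None = None
    created_ms: int = 0


@dataclass
class Bundle:
    """Regions sharing one caption, described once."""

    id: str
    member_region_ids: list[str]
    caption: Caption


@dataclass
class WSIAnnotation:
    """One annotator's document for one slide."""

    wsi_id: str
    annotator_id: str
    phase: str
    regions: list[Region] = field(default_factory=list)
    bundles: list[Bundle] = field(default_factory=list)
    slide_caption: str | None = None
    audit_status: str = "draft"
    events_ref: str | None = None


# ---------------------------------------------------------------------------
# geometry helpers (plain shoelace; shapely is used where topology matters)
# ---------------------------------------------------------------------------

def polygon_area(polygon: Sequence[tuple[float, float]]) -> float:
    """Unsigned shoelace area of an implicitly-closed vertex list."""
    n = len(polygon)
    s = 0.0
    for k in range(n):
        x0, y0 = polygon[k]
        x1, y1 = polygon[(k + 1) % n]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    code: str
    message: str
    ref: str | None = None


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def codes(self) -> list[str]:
        return [v.code for v in self.violations]

    def add(self, code: str, message: str, ref: str | None = None) -> None:
        self.violations.append(Violation(code, message, ref))


def validate_annotation(doc: WSIAnnotation, tree: TerminologyTree) -> ValidationReport:
    """Check every structural invariant of a document against the terminology.

    Pure and idempotent; returns a report whose emptiness means validity.
    Violation codes are stable strings keyed to region / bundle ids.
    """
    rep = ValidationReport()

    if doc.phase not in PHASES:
        rep.add("BAD_PHASE", f"unknown phase {doc.phase!r}")
    if doc.audit_status not in AUDIT_STATUSES:
        rep.add("BAD_AUDIT_STATUS", f"unknown audit status {doc.audit_status!r}")

    seen_ids: set[str] = set()
    for r in doc.regions:
        if r.id in seen_ids:
            rep.add("DUPLICATE_REGION_ID", f"region id {r.id!r} repeated", r.id)
        seen_ids.add(r.id)
        if r.wsi_id != doc.wsi_id:
            rep.add("WSI_MISMATCH", f"region {r.id!r} belongs to {r.wsi_id!r}", r.id)
        if r.layer not in LAYERS:
            rep.add("BAD_LAYER", f"region {r.id!r} layer {r.layer!r}", r.id)
        if r.pencil_shape not in PENCIL_SHAPES:
            rep.add("BAD_PENCIL", f"region {r.id!r} pencil {r.pencil_shape!r}", r.id)
        if len(r.polygon) < 3:
            rep.add("BAD_POLYGON", f"region {r.id!r} has <3 vertices", r.id)
        elif polygon_area(r.polygon) <= 0:
            rep.add("BAD_POLYGON", f"region {r.id!r} has zero area", r.id)

        if r.class_label not in tree:
            rep.add("UNKNOWN_TERM", f"region {r.id!r} class {r.class_label!r}", r.id)
        elif tree.get(r.class_label).level != "class":
            rep.add("LABEL_LINEAGE", f"region {r.id!r} class_label is not a class", r.id)

        if r.subtype_label is not None:
            if r.subtype_label not in tree:
                rep.add("UNKNOWN_TERM", f"region {r.id!r} subtype {r.subtype_label!r}", r.id)
            else:
                sub = tree.get(r.subtype_label)
                if sub.level != "subtype" or sub.parent_id != r.class_label:
                    rep.add(
                        "LABEL_LINEAGE",
                        f"region {r.id!r}: subtype {r.subtype_label!r} is not a "
                        f"child of class {r.class_label!r}",
                        r.id,
                    )
        if r.reason_labels and r.layer != "reason":
            rep.add("BAD_LAYER", f"decision region {r.id!r} carries reason labels", r.id)
        for term in r.reason_labels:
            if term not in tree:
                continue  # free-text extension, allowed
            entry = tree.get(term)
            if entry.level != "reason":
                rep.add("LABEL_LINEAGE", f"region {r.id!r}: {term!r} is not a reason", r.id)
            elif r.subtype_label is not None and entry.parent_id != r.subtype_label:
                rep.add(
                    "LABEL_LINEAGE",
                    f"region {r.id!r}: reason {term!r} descends from "
                    f"{entry.parent_id!r}, not {r.subtype_label!r}",
                    r.id,
                )

    membership: dict[str, str] = {}
    seen_bundles: set[str] = set()
    for b in doc.bundles:
        if b.id in seen_bundles:
            rep.add("DUPLICATE_BUNDLE_ID", f"bundle id {b.id!r} repeated", b.id)
        seen_bundles.add(b.id)
        if not b.member_region_ids:
            rep.add("EMPTY_BUNDLE", f"bundle {b.id!r} has no members", b.id)
        if b.caption.term_count < 1:
            rep.add("EMPTY_CAPTION", f"bundle {b.id!r} caption has no terms", b.id)
        for rid in b.member_region_ids:
            if rid not in seen_ids:
                rep.add(
                    "DANGLING_BUNDLE_MEMBER",
                    f"bundle {b.id!r} references missing region {rid!r}",
                    b.id,
                )
            elif rid in membership:
                rep.add(
                    "AMBIGUOUS_BUNDLE",
                    f"region {rid!r} is in bundles {membership[rid]!r} and {b.id!r}",
                    rid,
                )
            else:
                membership[rid] = b.id

    if doc.phase == "coarse":
        for r in doc.regions:
            if r.layer != "decision":
                rep.add("COARSE_PHASE_CONTENT", f"coarse doc has reason region {r.id!r}", r.id)
            elif r.subtype_label is not None:
                rep.add("COARSE_PHASE_CONTENT", f"coarse region {r.id!r} has a subtype", r.id)
        if not doc.slide_caption:
            rep.add("COARSE_PHASE_CONTENT", "coarse doc lacks a slide caption")

    return rep


# ---------------------------------------------------------------------------
# bundle expansion and cohort statistics
# ---------------------------------------------------------------------------

def expand_bundles(doc: WSIAnnotation) -> list[tuple[str, Caption]]:
    """Flatten bundles to per-region captions.

    Each bundle contributes one ``(region_id, caption)`` pair per member;
    reason-layer regions outside any bundle contribute their own
    ``reason_labels`` as a caption.  Every reason-layer region is covered
    exactly once.  A region claimed by two bundles raises
    :class:`AmbiguousBundleError`.
    """
    membership: dict[str, str] = {}
    for b in doc.bundles:
        for rid in b.member_region_ids:
            if rid in membership:
                raise AmbiguousBundleError(
                    f"region {rid!r} is in bundles {membership[rid]!r} and {b.id!r}",
                    region=rid,
                )
            membership[rid] = b.id

    pairs: list[tuple[str, Caption]] = []
    by_bundle = {b.id: b for b in doc.bundles}
    for r in doc.regions:
        if r.id in membership:
            pairs.append((r.id, by_bundle[membership[r.id]].caption))
        elif r.layer == "reason":
            pairs.append((r.id, Caption(terms=list(r.reason_labels), diagnosis_phrase=r.free_text)))
    return pairs


@dataclass
class CaptionStats:
    n_docs: int
    n_captions: int
    terms_per_caption_mean: float
    terms_per_caption_max: int
    terms_per_caption_min: int
    captions_per_wsi_mean: float
    regions_per_wsi_mean: float
    bundles_per_wsi_mean: float


def caption_stats(docs: Iterable[WSIAnnotation]) -> CaptionStats:
    """Cohort-level caption/region/bundle statistics over expanded bundles."""
    docs = list(docs)
    if not docs:
        raise EmptyCohortError("caption_stats needs at least one document")
    term_counts: list[int] = []
    per_wsi_captions: list[int] = []
    per_wsi_regions: list[int] = []
    per_wsi_bundles: list[int] = []
    for doc in docs:
        pairs = expand_bundles(doc)
        term_counts.extend(c.term_count for _, c in pairs if c.term_count > 0)
        distinct = {tuple(c.terms) for _, c in pairs if c.term_count > 0}
        per_wsi_captions.append(len(distinct))
        per_wsi_regions.append(len(doc.regions))
        per_wsi_bundles.append(len(doc.bundles))
    if not term_counts:
        raise EmptyCohortError("cohort contains no captions")
    n = len(term_counts)
    return CaptionStats(
        n_docs=len(docs),
        n_captions=n,
        terms_per_caption_mean=sum(term_counts) / n,
        terms_per_caption_max=max(term_counts),
        terms_per_caption_min=min(term_counts),
        captions_per_wsi_mean=sum(per_wsi_captions) / len(docs),
        regions_per_wsi_mean=sum(per_wsi_regions) / len(docs),
        bundles_per_wsi_mean=sum(per_wsi_bundles) / len(docs),
    )
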